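"""Readers and writers for the standard population-genetics file formats.

Two container types anchor the whole package:

* :class:`MsatGenotypeTable` — a diploid allele-size matrix (individuals ×
  loci × 2) with population labels, an optional population→group level, a
  missing-data mask and optional coordinates.  Allele sizes are stored on the
  scale found in the file (base pairs or repeat counts); the ``repeat_unit``
  metadata field converts base pairs to repeat counts where a stepwise scale
  is required (allele-size statistics such as R_ST, and stepwise mutation).
* :class:`SeqAlignment` — aligned haploid sequences (chloroplast fragments in
  the motivating use case) with optional clade labels.

Supported formats: GenePop (2- or 3-digit diploid codes), STRUCTURE
(two-row-per-individual, ``-9`` missing) and FASTA alignments.  A YAML
sidecar supplies the population→group mapping and optional coordinates,
because neither GenePop nor STRUCTURE carries a grouping level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MsatGenotypeTable",
    "SeqAlignment",
    "ParseError",
    "read_genepop",
    "write_genepop",
    "read_structure",
    "write_structure",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_grouping_yaml",
    "apply_grouping",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass
class MsatGenotypeTable:
    """Diploid microsatellite genotypes for a set of individuals.

    Parameters
    ----------
    individual_ids:
        One identifier per individual (row order is preserved on write).
    locus_names:
        One name per locus.
    alleles:
        Integer array of shape ``(n_individuals, n_loci, 2)`` holding allele
        sizes.  Entries under the missing mask are ignored (kept at 0).
    missing:
        Boolean array of shape ``(n_individuals, n_loci)``; ``True`` marks a
        missing genotype (both copies).
    pop_labels:
        One population label per individual.
    group_labels:
        Optional higher-level label per individual (e.g. ``"east"``/
        ``"west"``); must be constant within each population.
    coords:
        Optional ``(n_individuals, 2)`` array of x/y coordinates.
    repeat_unit:
        Size in base pairs of one repeat unit on the stored scale; 1 means
        the table is already in repeat counts.
    """

    individual_ids: list[str]
    locus_names: list[str]
    alleles: np.ndarray
    missing: np.ndarray
    pop_labels: np.ndarray
    group_labels: np.ndarray | None = None
    coords: np.ndarray | None = None
    repeat_unit: int = 1

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.pop_labels = np.asarray(self.pop_labels, dtype=object)
        if self.group_labels is not None:
            self.group_labels = np.asarray(self.group_labels, dtype=object)
        n, L = len(self.individual_ids), len(self.locus_names)
        if self.alleles.shape != (n, L, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} != ({n}, {L}, 2)"
            )
        if self.missing.shape != (n, L):
            raise ValueError(f"missing shape {self.missing.shape} != ({n}, {L})")
        if self.pop_labels.shape != (n,):
            raise ValueError("one population label per individual required")
        present = self.alleles[~self.missing]
        if present.size and (present <= 0).any():
            raise ValueError("non-missing allele sizes must be positive integers")
        if self.group_labels is not None:
            if self.group_labels.shape != (n,):
                raise ValueError("one group label per individual required")
            # groups must partition populations
            for pop in np.unique(self.pop_labels.astype(str)):
                g = np.unique(
                    self.group_labels[self.pop_labels == pop].astype(str)
                )
                if len(g) > 1:
                    raise ValueError(
                        f"population {pop!r} spans several groups: {list(g)}"
                    )
        if self.repeat_unit < 1:
            raise ValueError("repeat_unit must be a positive integer")

    # -- convenience ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def pops(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(str(p), None)
        return list(seen)

    def groups(self) -> list[str]:
        if self.group_labels is None:
            raise ValueError("table carries no group labels")
        seen: dict[str, None] = {}
        for g in self.group_labels:
            seen.setdefault(str(g), None)
        return list(seen)

    def to_repeat_scale(self) -> "MsatGenotypeTable":
        """Convert base-pair allele sizes to repeat counts (integer division
        by ``repeat_unit``); identity when already on the repeat scale."""
        if self.repeat_unit == 1:
            return self
        alleles = self.alleles // self.repeat_unit
        alleles[np.repeat(self.missing[:, :, None], 2, axis=2)] = 0
        return replace(self, alleles=alleles, repeat_unit=1)

    def subset(self, mask: np.ndarray) -> "MsatGenotypeTable":
        idx = np.flatnonzero(np.asarray(mask))
        return MsatGenotypeTable(
            individual_ids=[self.individual_ids[i] for i in idx],
            locus_names=list(self.locus_names),
            alleles=self.alleles[idx],
            missing=self.missing[idx],
            pop_labels=self.pop_labels[idx],
            group_labels=None if self.group_labels is None else self.group_labels[idx],
            coords=None if self.coords is None else np.asarray(self.coords)[idx],
            repeat_unit=self.repeat_unit,
        )

    def equals(self, other: "MsatGenotypeTable") -> bool:
        """Content equality (used by the round-trip tests)."""
        if self.individual_ids != other.individual_ids:
            return False
        if self.locus_names != other.locus_names:
            return False
        if not np.array_equal(self.missing, other.missing):
            return False
        a, b = self.alleles.copy(), other.alleles.copy()
        m = np.repeat(self.missing[:, :, None], 2, axis=2)
        a[m], b[m] = 0, 0
        if not np.array_equal(a, b):
            return False
        return list(map(str, self.pop_labels)) == list(map(str, other.pop_labels))


@dataclass
class SeqAlignment:
    """Aligned haploid sequences over the alphabet ``{A, C, G, T, -, N}``."""

    sequence_ids: list[str]
    sequences: list[str]
    clade_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment must contain at least one sequence")
        self.sequences = [s.upper() for s in self.sequences]
        L = len(self.sequences[0])
        if L == 0:
            raise ValueError("alignment length must be positive")
        ragged = [
            sid
            for sid, s in zip(self.sequence_ids, self.sequences)
            if len(s) != L
        ]
        if ragged:
            raise ValueError(f"sequences with deviating length: {ragged}")
        if self.clade_labels is not None:
            self.clade_labels = np.asarray(self.clade_labels, dtype=object)
            if self.clade_labels.shape != (len(self.sequences),):
                raise ValueError("one clade label per sequence required")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def matrix(self) -> np.ndarray:
        """Alignment as a ``(n, L)`` array of single characters."""
        return np.array([list(s) for s in self.sequences], dtype="U1")


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

def _split_genotype(code: str, lineno: int) -> tuple[int, int, int]:
    """Return (allele1, allele2, digit width) from a diploid GenePop code."""
    if len(code) not in (4, 6) or not code.isdigit():
        raise ParseError(
            f"line {lineno}: genotype code {code!r} is not 4 or 6 digits"
        )
    w = len(code) // 2
    return int(code[:w]), int(code[w:]), w


def read_genepop(path: str | Path) -> MsatGenotypeTable:
    """Read a GenePop file (2- or 3-digit diploid codes).

    All-zero codes (``0000``/``000000``) are mapped to the missing mask.
    Populations are labelled ``Pop1``, ``Pop2``, … in file order.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ParseError("file too short to be GenePop")
    # locus names: either one per line until the first "Pop", or a single
    # comma-separated line
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise ParseError("no 'Pop' separator found")
    if not locus_names:
        raise ParseError("no locus names before first 'Pop'")

    ids: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    miss_rows: list[list[bool]] = []
    pop_labels: list[str] = []
    pop_idx = 0
    width: int | None = None
    for lineno, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in line:
            raise ParseError(f"line {lineno}: expected 'id , genotypes'")
        ind_id, _, geno_part = line.partition(",")
        codes = geno_part.split()
        if len(codes) != len(locus_names):
            raise ParseError(
                f"line {lineno}: {len(codes)} genotypes for "
                f"{len(locus_names)} loci"
            )
        geno_row: list[tuple[int, int]] = []
        miss_row: list[bool] = []
        for code in codes:
            a1, a2, w = _split_genotype(code, lineno)
            if width is None:
                width = w
            elif w != width:
                raise ParseError(
                    f"line {lineno}: mixed {2 * width}- and {2 * w}-digit codes"
                )
            missing = a1 == 0 and a2 == 0
            if (a1 == 0) != (a2 == 0):
                raise ParseError(
                    f"line {lineno}: half-missing genotype {code!r}"
                )
            geno_row.append((a1, a2))
            miss_row.append(missing)
        ids.append(ind_id.strip())
        rows.append(geno_row)
        miss_rows.append(miss_row)
        pop_labels.append(f"Pop{pop_idx}")
    if not rows:
        raise ParseError("no individuals found")
    alleles = np.array(rows, dtype=np.int64)
    return MsatGenotypeTable(
        individual_ids=ids,
        locus_names=locus_names,
        alleles=alleles,
        missing=np.array(miss_rows, dtype=bool),
        pop_labels=np.array(pop_labels, dtype=object),
    )


def write_genepop(
    table: MsatGenotypeTable,
    path: str | Path,
    *,
    title: str = "consgen export",
    digits: int = 3,
) -> None:
    """Write a table as GenePop; ``digits`` selects the 2- or 3-digit dialect.

    Raises if any allele size does not fit the chosen width, or the table is
    empty.  Output is byte-stable for a fixed table.
    """
    if table.n_individuals == 0 or table.n_loci == 0:
        raise ValueError("refusing to write an empty table")
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    limit = 10**digits - 1
    present = table.alleles[~table.missing]
    if present.size and present.max() > limit:
        raise ValueError(
            f"allele size {present.max()} does not fit {digits} digits; "
            "convert to repeat scale first"
        )
    out: list[str] = [title]
    out.extend(table.locus_names)
    last_pop = None
    for i in range(table.n_individuals):
        pop = str(table.pop_labels[i])
        if pop != last_pop:
            out.append("Pop")
            last_pop = pop
        codes = []
        for l in range(table.n_loci):
            if table.missing[i, l]:
                a1 = a2 = 0
            else:
                a1, a2 = table.alleles[i, l]
            codes.append(f"{a1:0{digits}d}{a2:0{digits}d}")
        out.append(f"{table.individual_ids[i]} , " + " ".join(codes))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# STRUCTURE (two-row-per-individual)
# ---------------------------------------------------------------------------

def read_structure(path: str | Path) -> MsatGenotypeTable:
    """Read a two-row-per-individual STRUCTURE file.

    Expected columns: individual id, population label, then one allele per
    locus; two consecutive rows per individual; ``-9`` marks missing.  An
    optional first header row carries locus names (detected when its second
    column is not numeric-or-label-shaped, i.e. the row has one fewer column).
    """
    raw = [
        ln.split()
        for ln in Path(path).read_text().splitlines()
        if ln.strip()
    ]
    if not raw:
        raise ParseError("empty STRUCTURE file")
    locus_names: list[str] | None = None
    body = raw
    if len(raw) > 1 and len(raw[0]) == len(raw[1]) - 2:
        locus_names = raw[0]
        body = raw[1:]
    if len(body) % 2:
        raise ParseError(
            f"odd number of data rows ({len(body)}); two rows per individual "
            "required"
        )
    n_loci = len(body[0]) - 2
    if n_loci < 1:
        raise ParseError("rows must contain id, pop and at least one locus")
    if locus_names is None:
        locus_names = [f"L{j + 1}" for j in range(n_loci)]
    ids, pops, rows, miss = [], [], [], []
    for k in range(0, len(body), 2):
        r1, r2 = body[k], body[k + 1]
        if len(r1) != n_loci + 2 or len(r2) != n_loci + 2:
            raise ParseError(f"row {k + 1}: inconsistent column count")
        if r1[0] != r2[0]:
            raise ParseError(
                f"rows {k + 1}/{k + 2}: ids {r1[0]!r} and {r2[0]!r} differ"
            )
        try:
            a1 = [int(x) for x in r1[2:]]
            a2 = [int(x) for x in r2[2:]]
        except ValueError as exc:
            raise ParseError(f"row {k + 1}: non-integer allele") from exc
        geno, mrow = [], []
        for x, y in zip(a1, a2):
            if (x == -9) != (y == -9):
                raise ParseError(f"row {k + 1}: half-missing genotype")
            if x == -9:
                geno.append((0, 0))
                mrow.append(True)
            else:
                geno.append((x, y))
                mrow.append(False)
        ids.append(r1[0])
        pops.append(r1[1])
        rows.append(geno)
        miss.append(mrow)
    return MsatGenotypeTable(
        individual_ids=ids,
        locus_names=locus_names,
        alleles=np.array(rows, dtype=np.int64),
        missing=np.array(miss, dtype=bool),
        pop_labels=np.array(pops, dtype=object),
    )


def write_structure(table: MsatGenotypeTable, path: str | Path) -> None:
    if table.n_individuals == 0 or table.n_loci == 0:
        raise ValueError("refusing to write an empty table")
    out = [" ".join(table.locus_names)]
    for i in range(table.n_individuals):
        for copy in range(2):
            vals = [
                "-9" if table.missing[i, l] else str(table.alleles[i, l, copy])
                for l in range(table.n_loci)
            ]
            out.append(
                f"{table.individual_ids[i]} {table.pop_labels[i]} "
                + " ".join(vals)
            )
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------

def read_fasta_alignment(path: str | Path) -> SeqAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError("no FASTA records found")
    seqs = [str(r.seq).upper() for r in records]
    ids = [r.id for r in records]
    L = len(seqs[0])
    ragged = [i for i, s in zip(ids, seqs) if len(s) != L]
    if ragged:
        raise ParseError(f"unequal sequence lengths for ids: {ragged}")
    return SeqAlignment(sequence_ids=ids, sequences=seqs)


def write_fasta_alignment(aln: SeqAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(aln.sequence_ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Grouping sidecar
# ---------------------------------------------------------------------------

def read_grouping_yaml(path: str | Path) -> dict:
    """Read the population→group sidecar.

    Schema::

        groups: {popname: groupname, ...}
        coords: {popname: [x, y], ...}   # optional
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "groups" not in data:
        raise ParseError("sidecar must be a mapping with a 'groups' key")
    return data


def apply_grouping(
    table: MsatGenotypeTable, mapping: Mapping[str, str] | str | Path
) -> MsatGenotypeTable:
    """Attach group labels (and coordinates, when present) from a mapping or
    a sidecar YAML path."""
    coords_map = None
    if isinstance(mapping, (str, Path)):
        sidecar = read_grouping_yaml(mapping)
        coords_map = sidecar.get("coords")
        mapping = sidecar["groups"]
    missing_pops = [p for p in table.pops() if p not in mapping]
    if missing_pops:
        raise ValueError(f"no group assigned for populations: {missing_pops}")
    groups = np.array(
        [mapping[str(p)] for p in table.pop_labels], dtype=object
    )
    coords = table.coords
    if coords_map:
        coords = np.array(
            [coords_map[str(p)] for p in table.pop_labels], dtype=float
        )
    return replace(table, group_labels=groups, coords=coords)
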