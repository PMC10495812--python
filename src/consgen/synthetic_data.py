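"""Synthetic genotype tables and haplotype alignments with controlled
structure, so every downstream stage is testable without external data.

Two generators produce microsatellite tables:

* :func:`balding_nichols_table` — the F-model: group allele frequencies are
  Dirichlet draws around ancestral frequencies with concentration
  ``(1−F)/F``, giving direct control of the expected Wright F_ST.  Used to
  calibrate differentiation statistics independently of the coalescent
  machinery.
* :func:`coalescent_table` — delegates to the structured-coalescent
  simulator when temporal structure (divergence times, size changes)
  matters.

:func:`two_clade_cpdna` builds a haploid alignment of two star-like
haplotype clusters separated by a fixed number of mutations, with clade
labels attached and spatial labels randomized — the pattern of two old
organelle lineages admixed in space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coalescent_sim import DemographicModel, MutationModel, simulate_msat_dataset
from .io_formats import MsatGenotypeTable, SeqAlignment

__all__ = [
    "SynthSpec",
    "balding_nichols_table",
    "coalescent_table",
    "two_clade_cpdna",
]


@dataclass
class SynthSpec:
    """Specification for the F-model genotype generator.

    Defaults emulate the motivating study's design: two groups of diploid
    trees genotyped at 8 unlinked microsatellite loci with moderate
    differentiation (F_ST ≈ 0.11), allele sizes on a 10–40 repeat support.
    """

    n_groups: int = 2
    n_ind_per_group: Sequence[int] = (234, 233)
    n_loci: int = 8
    target_fst: float = 0.11
    n_alleles: int = 6
    msat_range: tuple[int, int] = (10, 40)
    ancestral_freqs: list[np.ndarray] | None = None
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.target_fst < 1.0:
            raise ValueError("target_fst must lie in [0, 1)")
        if self.n_groups < 1 or self.n_loci < 1 or self.n_alleles < 1:
            raise ValueError("counts must be positive")
        if len(self.n_ind_per_group) != self.n_groups:
            raise ValueError("one sample size per group required")
        if any(n < 1 for n in self.n_ind_per_group):
            raise ValueError("counts must be positive")
        if self.msat_range[1] - self.msat_range[0] + 1 < self.n_alleles:
            raise ValueError("msat_range too narrow for n_alleles")
        if self.ancestral_freqs is not None:
            if len(self.ancestral_freqs) != self.n_loci:
                raise ValueError("one frequency vector per locus required")
            for p in self.ancestral_freqs:
                if not np.isclose(np.sum(p), 1.0):
                    raise ValueError("frequencies must sum to 1 per locus")


def balding_nichols_table(spec: SynthSpec) -> MsatGenotypeTable:
    """Genotypes under the Balding–Nichols F-model.

    Per group g and locus l the allele frequencies are drawn from
    ``Dirichlet(p_ancestral · (1−F)/F)`` with ``F = target_fst`` (identical
    frequencies across groups at F = 0); genotypes are two independent
    multinomial draws from the group frequencies (Hardy–Weinberg within
    groups).  Reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.msat_range
    sizes_support = np.arange(lo, hi + 1)
    n_ind = int(np.sum(spec.n_ind_per_group))
    alleles = np.zeros((n_ind, spec.n_loci, 2), dtype=np.int64)
    group_names = [f"group{g + 1}" for g in range(spec.n_groups)]
    group_of_ind = np.concatenate(
        [np.repeat(g, n) for g, n in enumerate(spec.n_ind_per_group)]
    )
    for l in range(spec.n_loci):
        if spec.ancestral_freqs is not None:
            p_anc = np.asarray(spec.ancestral_freqs[l], dtype=float)
            k = p_anc.size
        else:
            k = spec.n_alleles
            p_anc = np.full(k, 1.0 / k)
        support = rng.choice(sizes_support, size=k, replace=False)
        support.sort()
        for g in range(spec.n_groups):
            if spec.target_fst == 0.0:
                p_g = p_anc
            else:
                conc = p_anc * (1.0 - spec.target_fst) / spec.target_fst
                p_g = rng.dirichlet(conc)
            sel = np.flatnonzero(group_of_ind == g)
            draws = rng.choice(support, size=(sel.size, 2), p=p_g)
            alleles[sel, l, :] = draws
    pop_labels = np.array(
        [group_names[g] for g in group_of_ind], dtype=object
    )
    return MsatGenotypeTable(
        individual_ids=[f"ind{i + 1}" for i in range(n_ind)],
        locus_names=[f"L{l + 1}" for l in range(spec.n_loci)],
        alleles=alleles,
        missing=np.zeros((n_ind, spec.n_loci), dtype=bool),
        pop_labels=pop_labels,
        group_labels=pop_labels.copy(),
        repeat_unit=1,
    )


def coalescent_table(
    model: DemographicModel,
    mutation: MutationModel,
    sample_sizes: Sequence[int],
    n_loci: int = 8,
    seed: int | None = None,
) -> MsatGenotypeTable:
    """Genotype table simulated under a demographic model (thin wrapper over
    the coalescent simulator; used for parameter-recovery tests)."""
    return simulate_msat_dataset(
        model, mutation, n_loci, sample_sizes, seed=seed
    )


def two_clade_cpdna(
    n_seq: int = 40,
    seq_len: int = 500,
    n_mut_within: int = 3,
    n_mut_between: int = 5,
    seed: int | None = None,
    n_hap_per_clade: tuple[int, int] | None = None,
) -> SeqAlignment:
    """Haploid alignment with two star-like haplotype clusters.

    The two clades differ at exactly ``n_mut_between`` fixed sites.  By
    default every sequence carries ``n_mut_within`` private singleton
    mutations at its own sites (star phylogeny, every sequence a distinct
    haplotype).  With ``n_hap_per_clade = (ka, kb)`` the within-clade
    variation is organized into that many shared haplotype prototypes
    instead — a central haplotype plus satellites ``n_mut_within`` steps
    away — and sequences are assigned to prototypes with Zipf-like
    (1/rank) abundances, mimicking the skewed haplotype frequency spectra
    of real organelle samples.  Clade labels are attached; sequence order
    (the stand-in for sampling location) is randomized so that clades are
    spatially admixed.
    """
    if n_mut_between < 1:
        raise ValueError("n_mut_between must be at least 1")
    if n_seq < 2:
        raise ValueError("need at least two sequences")
    n_a = n_seq // 2
    n_b = n_seq - n_a
    n_private_blocks = (
        n_seq if n_hap_per_clade is None else sum(n_hap_per_clade)
    )
    needed = n_mut_between + n_mut_within * n_private_blocks
    if needed > seq_len:
        raise ValueError(
            f"seq_len={seq_len} too small for {needed} mutated sites"
        )
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    ancestral = rng.choice(bases, size=seq_len)
    sites = rng.choice(seq_len, size=needed, replace=False)
    between_sites = sites[:n_mut_between]
    private_sites = (
        sites[n_mut_between:].reshape(n_private_blocks, n_mut_within)
        if n_mut_within > 0
        else None
    )

    def _mutate(base: str) -> str:
        alt = [b for b in "ACGT" if b != base]
        return alt[int(rng.integers(0, 3))]

    # one derived base per between-clade site, shared by the whole B clade
    derived = {int(j): _mutate(ancestral[j]) for j in between_sites}

    def _core(clade: str) -> np.ndarray:
        s = ancestral.copy()
        if clade == "cladeB":
            for j in between_sites:
                s[j] = derived[int(j)]
        return s

    def _with_private(core: np.ndarray, block: int) -> np.ndarray:
        s = core.copy()
        if private_sites is not None:
            for j in private_sites[block]:
                s[j] = _mutate(s[j])
        return s

    seqs: list[str] = []
    clades: list[str] = []
    if n_hap_per_clade is None:
        for i in range(n_seq):
            clade = "cladeA" if i < n_a else "cladeB"
            seqs.append("".join(_with_private(_core(clade), i)))
            clades.append(clade)
    else:
        block = 0
        for clade, k, n_c in (
            ("cladeA", n_hap_per_clade[0], n_a),
            ("cladeB", n_hap_per_clade[1], n_b),
        ):
            protos = [_core(clade)]
            for _j in range(1, k):
                protos.append(_with_private(_core(clade), block))
                block += 1
            if n_mut_within == 0 and k > 1:
                raise ValueError(
                    "n_mut_within must be positive for multiple "
                    "haplotypes per clade"
                )
            w = 1.0 / np.arange(1, k + 1)
            w /= w.sum()
            picks = rng.choice(k, size=n_c, p=w)
            for p in picks:
                seqs.append("".join(protos[p]))
                clades.append(clade)
    order = rng.permutation(n_seq)
    return SeqAlignment(
        sequence_ids=[f"seq{i + 1}" for i in range(n_seq)],
        sequences=[seqs[i] for i in order],
        clade_labels=np.array([clades[i] for i in order], dtype=object),
    )
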