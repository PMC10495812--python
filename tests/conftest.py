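import numpy as np
import pytest

from consgen.io_formats import MsatGenotypeTable, SeqAlignment


def make_table(alleles, pops, groups=None, missing=None, locus_names=None):
    """Build a small genotype table from nested lists."""
    alleles = np.asarray(alleles, dtype=np.int64)
    n, L = alleles.shape[:2]
    return MsatGenotypeTable(
        individual_ids=[f"i{k + 1}" for k in range(n)],
        locus_names=locus_names or [f"L{j + 1}" for j in range(L)],
        alleles=alleles,
        missing=(
            np.zeros((n, L), dtype=bool) if missing is None
            else np.asarray(missing, dtype=bool)
        ),
        pop_labels=np.array(pops, dtype=object),
        group_labels=None if groups is None else np.array(groups, dtype=object),
    )


@pytest.fixture
def two_pop_table():
    """4 individuals, 2 pops, 2 loci, no missing data."""
    return make_table(
        [
            [[100, 102], [10, 10]],
            [[100, 100], [10, 12]],
            [[104, 104], [12, 12]],
            [[102, 104], [12, 14]],
        ],
        pops=["A", "A", "B", "B"],
        groups=["west", "west", "east", "east"],
    )


@pytest.fixture
def random_table():
    """Randomly generated valid 8-locus table with canonical pop labels."""
    rng = np.random.default_rng(123)
    n, L = 12, 8
    alleles = rng.integers(10, 41, size=(n, L, 2))
    missing = rng.random((n, L)) < 0.1
    return make_table(
        alleles,
        pops=["Pop1"] * 6 + ["Pop2"] * 6,
        missing=missing,
    )


def make_alignment(seqs, ids=None, clades=None):
    return SeqAlignment(
        sequence_ids=ids or [f"s{k + 1}" for k in range(len(seqs))],
        sequences=list(seqs),
        clade_labels=None if clades is None else np.array(clades, dtype=object),
    )
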