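"""Haploid-sequence diversity, neutrality tests and differentiation.

Implements the classical summaries for an alignment of non-recombining
haploid sequences (chloroplast fragments in the motivating use case):
haplotype collapse and Nei's unbiased haplotype diversity h, per-site
nucleotide diversity π, and the frequency-spectrum neutrality tests —
Tajima's D and Fu & Li's D* and F* (no outgroup).  φ_ST between groups of
sequences comes from an AMOVA on pairwise nucleotide differences, with the
standardized φ'_ST = φ_ST/φ_ST(max) obtained by recoding haplotypes so that
no two groups share one.

Missing-data policy: sites containing a gap or an ambiguous base in any
sequence are excluded alignment-wide (complete deletion) for the SNP-based
statistics (π, S, D, D*, F*, φ_ST); haplotype collapse compares the full
sequence including indels, optionally masking ambiguous columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import SeqAlignment
from .popgen_stats import AmovaResult, amova_from_distance

__all__ = [
    "SeqDiversityReport",
    "NeutralityReport",
    "PhiStResult",
    "usable_sites",
    "collapse_haplotypes",
    "hap_diversity",
    "nucleotide_diversity",
    "seq_diversity",
    "tajimas_d",
    "fu_li_star_tests",
    "phi_st",
]

_BASES = frozenset("ACGT")


@dataclass
class SeqDiversityReport:
    n: int
    H: int
    h: float
    pi: float
    S: int
    eta: int
    eta_s: int


@dataclass
class NeutralityReport:
    tajima_D: float
    fu_li_D_star: float
    fu_li_F_star: float


@dataclass
class PhiStResult:
    phi_st: float
    phi_st_max: float
    phi_st_prime: float
    p_value: float
    amova: AmovaResult


# ---------------------------------------------------------------------------
# Site filtering and haplotypes
# ---------------------------------------------------------------------------

def usable_sites(aln: SeqAlignment) -> np.ndarray:
    """Indices of sites containing only A/C/G/T in every sequence."""
    m = aln.matrix()
    ok = np.ones(aln.length, dtype=bool)
    for b in np.unique(m):
        if b not in _BASES:
            ok &= ~(m == b).any(axis=0)
    return np.flatnonzero(ok)


def collapse_haplotypes(
    aln: SeqAlignment, *, mask_ambiguous: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Group identical sequences into haplotypes.

    Returns ``(hap_index, freqs)``: a per-sequence haplotype index (ordered
    by first appearance) and the haplotype frequencies (summing to n).
    Comparison uses the full sequence including indels; with
    ``mask_ambiguous`` columns containing N are dropped before comparing.
    """
    m = aln.matrix()
    if mask_ambiguous:
        keep = ~(m == "N").any(axis=0)
        m = m[:, keep]
    keys = ["".join(row) for row in m]
    seen: dict[str, int] = {}
    idx = np.empty(len(keys), dtype=np.int64)
    for i, k in enumerate(keys):
        idx[i] = seen.setdefault(k, len(seen))
    freqs = np.bincount(idx, minlength=len(seen))
    return idx, freqs


def hap_diversity(freqs: np.ndarray, n: int | None = None) -> float:
    """Nei's unbiased haplotype diversity h = n/(n−1) · (1 − Σ(f_i/n)²)."""
    freqs = np.asarray(freqs, dtype=float)
    if n is None:
        n = int(freqs.sum())
    if n < 2:
        return np.nan
    if freqs.sum() != n:
        raise ValueError("haplotype frequencies must sum to n")
    p = freqs / n
    return n / (n - 1) * (1.0 - float(np.sum(p**2)))


# ---------------------------------------------------------------------------
# Pairwise differences and π
# ---------------------------------------------------------------------------

def _site_counts(aln: SeqAlignment):
    """Per usable site, the allele counts; returns (counts list, n_sites)."""
    sites = usable_sites(aln)
    m = aln.matrix()[:, sites]
    out = []
    for j in range(m.shape[1]):
        _vals, counts = np.unique(m[:, j], return_counts=True)
        out.append(counts)
    return out, sites.size


def mean_pairwise_differences(aln: SeqAlignment) -> float:
    """Average number of differing usable sites over all unordered pairs
    (π on the per-alignment scale)."""
    n = aln.n_sequences
    if n < 2:
        return np.nan
    counts, _L = _site_counts(aln)
    npairs = n * (n - 1) / 2.0
    tot = 0.0
    for c in counts:
        # pairs differing at this site
        tot += (n * n - float(np.sum(c.astype(float) ** 2))) / 2.0
    return tot / npairs


def nucleotide_diversity(aln: SeqAlignment) -> float:
    """π per site: mean pairwise proportion of differing usable sites."""
    _counts, L = _site_counts(aln)
    if L == 0:
        return np.nan
    return mean_pairwise_differences(aln) / L


def _spectrum(aln: SeqAlignment) -> tuple[int, int, int]:
    """(S, η, η_s): segregating usable sites, total mutations (alleles − 1
    per site), and singleton mutations (capped at η per site)."""
    counts, _L = _site_counts(aln)
    S = eta = eta_s = 0
    for c in counts:
        k = len(c)
        if k < 2:
            continue
        S += 1
        eta += k - 1
        eta_s += min(int(np.sum(c == 1)), k - 1)
    return S, eta, eta_s


def seq_diversity(aln: SeqAlignment) -> SeqDiversityReport:
    idx, freqs = collapse_haplotypes(aln)
    S, eta, eta_s = _spectrum(aln)
    return SeqDiversityReport(
        n=aln.n_sequences,
        H=int(freqs.size),
        h=hap_diversity(freqs),
        pi=nucleotide_diversity(aln),
        S=S,
        eta=eta,
        eta_s=eta_s,
    )


# ---------------------------------------------------------------------------
# Neutrality tests
# ---------------------------------------------------------------------------

def _harmonics(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i)), float(np.sum(1.0 / i**2))


def tajimas_d(aln: SeqAlignment) -> float:
    """Tajima's D from π (per alignment) and the number of segregating
    sites; NaN when S = 0."""
    n = aln.n_sequences
    S, _eta, _eta_s = _spectrum(aln)
    if S == 0 or n < 2:
        return np.nan
    a1, a2 = _harmonics(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi_total = mean_pairwise_differences(aln)
    return (pi_total - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def fu_li_star_tests(aln: SeqAlignment) -> tuple[float, float]:
    """Fu & Li's D* and F* without an outgroup (corrected constants, as in
    the DnaSP lineage of implementations); (NaN, NaN) when S = 0."""
    n = aln.n_sequences
    S, eta, eta_s = _spectrum(aln)
    if S == 0 or n < 3:
        return np.nan, np.nan
    nf = float(n)
    a, b = _harmonics(n)          # a_n = Σ_{1}^{n-1} 1/i, b_n = Σ 1/i²
    a1 = a + 1.0 / nf             # a_{n+1}
    if n == 2:
        cn = 1.0
    else:
        cn = 2.0 * (nf * a - 2.0 * (nf - 1)) / ((nf - 1) * (nf - 2))
    dn = (
        cn
        + (nf - 2) / (nf - 1) ** 2
        + (2.0 / (nf - 1)) * (1.5 - (2.0 * a1 - 3.0) / (nf - 2) - 1.0 / nf)
    )
    v_d = (
        (nf / (nf - 1)) ** 2 * b
        + a**2 * dn
        - 2.0 * (nf * a * (a + 1)) / (nf - 1) ** 2
    ) / (a**2 + b)
    u_d = (nf / (nf - 1)) * (a - nf / (nf - 1)) - v_d
    d_star = ((nf / (nf - 1)) * eta - a * eta_s) / np.sqrt(
        u_d * eta + v_d * eta**2
    )

    pi_total = mean_pairwise_differences(aln)
    v_f = (
        (2.0 * nf**3 + 110.0 * nf**2 - 255.0 * nf + 153.0)
        / (9.0 * nf**2 * (nf - 1))
        + 2.0 * (nf - 1) * a / nf**2
        - 8.0 * b / nf
    ) / (a**2 + b)
    u_f = (
        (
            nf / (nf - 1)
            + (nf + 1) / (3.0 * (nf - 1))
            - 4.0 / (nf * (nf - 1))
            + 2.0 * (nf + 1) / (nf - 1) ** 2 * (a1 - 2.0 * nf / (nf + 1))
        )
        / a
        - v_f
    )
    f_star = (pi_total - (nf - 1) / nf * eta_s) / np.sqrt(
        u_f * eta + v_f * eta**2
    )
    return float(d_star), float(f_star)


def neutrality_tests(aln: SeqAlignment) -> NeutralityReport:
    d = tajimas_d(aln)
    ds, fs = fu_li_star_tests(aln)
    return NeutralityReport(tajima_D=d, fu_li_D_star=ds, fu_li_F_star=fs)


# ---------------------------------------------------------------------------
# φ_ST
# ---------------------------------------------------------------------------

def _pairwise_diff_matrix(aln: SeqAlignment) -> np.ndarray:
    sites = usable_sites(aln)
    m = aln.matrix()[:, sites]
    n = aln.n_sequences
    d = np.zeros((n, n))
    for i in range(n):
        diff = (m[i + 1 :] != m[i]).sum(axis=1).astype(float)
        d[i, i + 1 :] = diff
        d[i + 1 :, i] = diff
    return d


def phi_st(
    aln: SeqAlignment,
    grouping,
    n_perm: int = 999,
    seed: int | None = None,
) -> PhiStResult:
    """φ_ST, φ'_ST and a permutation p-value between groups of sequences.

    ``phi_st`` (and its permutation p-value) comes from an AMOVA on the
    matrix of pairwise nucleotide differences (complete deletion).  The
    standardized ``phi_st_prime`` is computed on the haplotype-identity
    scale — the only distance on which the maximal-differentiation
    recoding (no haplotype shared between groups, frequencies preserved)
    is well defined: it is φ_id/φ_id(max) where both use the 0/1 identity
    distance.  With distance-weighted φ in the numerator the ratio could
    exceed 1, which is incoherent.
    """
    labels = np.asarray(
        aln.clade_labels if isinstance(grouping, str) and grouping == "clade"
        else grouping,
        dtype=object,
    )
    if labels.shape != (aln.n_sequences,):
        raise ValueError("one group label per sequence required")
    for g, c in zip(*np.unique(labels.astype(str), return_counts=True)):
        if c < 2:
            raise ValueError(f"group {g!r} has fewer than 2 sequences")
    d2 = _pairwise_diff_matrix(aln)
    res = amova_from_distance(d2, labels, n_perm=n_perm, seed=seed)
    phi = res.indices["FST"]

    hap_idx, _freqs = collapse_haplotypes(aln)
    _ugroups, ginv = np.unique(labels.astype(str), return_inverse=True)
    d2_id = (hap_idx[:, None] != hap_idx[None, :]).astype(float)
    res_id = amova_from_distance(d2_id, labels, n_perm=1, seed=seed)
    recoded = hap_idx + ginv * (hap_idx.max() + 1)
    d2max = (recoded[:, None] != recoded[None, :]).astype(float)
    res_max = amova_from_distance(d2max, labels, n_perm=1, seed=seed)
    phi_max = res_max.indices["FST"]
    prime = (
        res_id.indices["FST"] / phi_max
        if phi_max and np.isfinite(phi_max)
        else np.nan
    )
    return PhiStResult(
        phi_st=phi,
        phi_st_max=phi_max,
        phi_st_prime=prime,
        p_value=res.p_values["FST"],
        amova=res,
    )
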