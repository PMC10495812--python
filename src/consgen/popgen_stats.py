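"""Nuclear-marker diversity and differentiation statistics.

The module centres on a distance-based analysis of molecular variance
(AMOVA): squared inter-individual genetic distances are partitioned into
hierarchical variance components, fixation indices are formed from the
components, and inference uses label permutations.  On top of the AMOVA core
sit Wright's F_ST and its standardized form F'_ST = F_ST / F_ST(max)
(computed by recoding every group's alleles to be private while preserving
frequencies), Slatkin's allele-size based R_ST with the allele-size
permutation test (R_ST vs. pR_ST), per-locus diversity statistics
(Na, Ne, Ho, He, F_IS), a Monte-Carlo Hardy–Weinberg test, and principal
coordinate analysis.

Conventions (they matter for comparability with the GenAlEx/SPAGeDi family
of tools):

* codominant inter-individual distance: half the squared Euclidean distance
  between allele-count vectors, summed over loci (0 for identical genotypes,
  1 for one shared allele, 4 for AA vs BB);
* missing genotypes are dropped pairwise in distances and excluded from
  frequency counts;
* F_IS = (He − Ho)/He, negative values allowed, undefined (NaN) when He = 0;
* permutation p-values use the (hits + 1)/(n_perm + 1) estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .io_formats import MsatGenotypeTable

__all__ = [
    "DiversityReport",
    "AmovaResult",
    "FstPrimeResult",
    "RstTestResult",
    "diversity",
    "hwe_test",
    "sequential_bonferroni",
    "codominant_distance",
    "wright_fst",
    "amova",
    "amova_from_distance",
    "fst_prime",
    "rst_permutation_test",
    "pcoa",
]


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass
class DiversityReport:
    """Per-stratum, per-locus diversity table plus across-locus means.

    ``per_locus`` is indexed by (stratum, locus) with columns
    Na, Ne, Ho, He, FIS; ``means`` holds the across-locus mean per stratum.
    Undefined entries (monomorphic He = 0 for FIS) are NaN, never silent
    zeros.
    """

    per_locus: pd.DataFrame
    means: pd.DataFrame


@dataclass
class AmovaResult:
    """Hierarchical variance decomposition with permutation p-values."""

    components: dict[str, float]
    percent: dict[str, float]
    indices: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    df: dict[str, float] = field(default_factory=dict)


@dataclass
class FstPrimeResult:
    fst: float
    fst_max: float
    fst_prime: float


@dataclass
class RstTestResult:
    rst: float
    p_rst: float
    p_value: float
    n_permutations: int
    permuted: np.ndarray


# ---------------------------------------------------------------------------
# Frequencies and diversity
# ---------------------------------------------------------------------------

def _allele_freqs(table: MsatGenotypeTable, idx: np.ndarray, locus: int):
    """Allele sizes and frequencies among non-missing copies of a locus."""
    ok = idx[~table.missing[idx, locus]]
    copies = table.alleles[ok, locus, :].ravel()
    if copies.size == 0:
        return np.array([]), np.array([])
    sizes, counts = np.unique(copies, return_counts=True)
    return sizes, counts / counts.sum()


def _strata_indices(table: MsatGenotypeTable, by: str) -> dict[str, np.ndarray]:
    if by == "total":
        return {"total": np.arange(table.n_individuals)}
    if by == "pop":
        labels = table.pop_labels
        order = table.pops()
    elif by == "group":
        if table.group_labels is None:
            raise ValueError("table carries no group labels")
        labels = table.group_labels
        order = table.groups()
    else:
        raise ValueError(f"unknown stratification {by!r}")
    return {s: np.flatnonzero(labels.astype(str) == s) for s in order}


def diversity(
    table: MsatGenotypeTable, by: str = "total", *, unbiased: bool = False
) -> DiversityReport:
    """Na, Ne, Ho, He and F_IS per locus within each stratum.

    He = 1 − Σ p_i² from stratum allele frequencies (multiplied by
    2n/(2n−1) when ``unbiased``), Ne = 1/Σ p_i², Ho = fraction heterozygous
    among non-missing genotypes, F_IS = (He − Ho)/He (NaN when He = 0).
    """
    rows = []
    for stratum, idx in _strata_indices(table, by).items():
        for l, locus in enumerate(table.locus_names):
            ok = idx[~table.missing[idx, l]]
            if ok.size == 0:
                rows.append(
                    (stratum, locus, np.nan, np.nan, np.nan, np.nan, np.nan)
                )
                continue
            sizes, p = _allele_freqs(table, idx, l)
            sum_p2 = float(np.sum(p**2))
            he = 1.0 - sum_p2
            if unbiased:
                ncop = 2 * ok.size
                he *= ncop / (ncop - 1)
            ne = 1.0 / sum_p2
            ho = float(
                np.mean(table.alleles[ok, l, 0] != table.alleles[ok, l, 1])
            )
            fis = (he - ho) / he if he > 0 else np.nan
            rows.append((stratum, locus, float(len(sizes)), ne, ho, he, fis))
    per_locus = pd.DataFrame(
        rows, columns=["stratum", "locus", "Na", "Ne", "Ho", "He", "FIS"]
    ).set_index(["stratum", "locus"])
    means = per_locus.groupby(level="stratum", sort=False).mean()
    return DiversityReport(per_locus=per_locus, means=means)


def hwe_test(
    table: MsatGenotypeTable,
    locus: str | int,
    pop: str,
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo Hardy–Weinberg test for one locus in one population.

    The 2n observed allele copies are shuffled into random diploids; the test
    statistic is the absolute deviation of the heterozygote count from its
    permutation mean, and p = (hits + 1)/(n_perm + 1).  Monomorphic loci
    return p = 1 with a warning.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be a positive integer")
    l = locus if isinstance(locus, int) else table.locus_names.index(locus)
    idx = np.flatnonzero(table.pop_labels.astype(str) == str(pop))
    if idx.size == 0:
        raise ValueError(f"unknown population {pop!r}")
    ok = idx[~table.missing[idx, l]]
    genos = table.alleles[ok, l, :]
    copies = genos.ravel().copy()
    if np.unique(copies).size < 2:
        warnings.warn(f"locus {table.locus_names[l]!r} monomorphic in {pop!r}")
        return 1.0
    het_obs = int(np.sum(genos[:, 0] != genos[:, 1]))
    rng = np.random.default_rng(seed)
    het_perm = np.empty(n_perm, dtype=np.int64)
    for k in range(n_perm):
        rng.shuffle(copies)
        pairs = copies.reshape(-1, 2)
        het_perm[k] = np.sum(pairs[:, 0] != pairs[:, 1])
    mean = het_perm.mean()
    stat_obs = abs(het_obs - mean)
    hits = int(np.sum(np.abs(het_perm - mean) >= stat_obs - 1e-12))
    return (hits + 1) / (n_perm + 1)


def sequential_bonferroni(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm's sequentially rejective Bonferroni procedure.

    Returns a boolean rejection mask in the input order: p-values are
    ranked, the i-th smallest is compared against alpha/(m−i), and testing
    stops at the first non-rejection.  The usual multiple-testing guard for
    batteries of per-locus×per-population tests (e.g. Hardy–Weinberg).
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] <= alpha / (m - i):
            reject[idx] = True
        else:
            break
    return reject


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def codominant_distance(table: MsatGenotypeTable) -> np.ndarray:
    """Squared codominant genotypic distance between all individual pairs.

    Per locus d² = ½‖y_i − y_j‖² on allele-count vectors y (entries sum
    to 2), summed over the loci non-missing in both individuals.
    """
    n = table.n_individuals
    d2 = np.zeros((n, n))
    for l in range(table.n_loci):
        present = ~table.missing[:, l]
        copies = table.alleles[:, l, :]
        sizes = np.unique(copies[present])
        if sizes.size == 0:
            continue
        y = np.zeros((n, sizes.size))
        for c in range(2):
            pos = np.searchsorted(sizes, copies[:, c])
            pos = np.clip(pos, 0, sizes.size - 1)
            np.add.at(y, (np.arange(n), pos), 1.0)
        y[~present] = 0.0
        sq = np.einsum("ij,ij->i", y, y)
        g = y @ y.T
        dl = 0.5 * (sq[:, None] + sq[None, :] - 2.0 * g)
        mask = np.outer(present, present)
        d2 += np.where(mask, dl, 0.0)
    np.fill_diagonal(d2, 0.0)
    return d2


# ---------------------------------------------------------------------------
# AMOVA core (works on any squared-distance matrix)
# ---------------------------------------------------------------------------

def _ss(d2: np.ndarray, idx: np.ndarray) -> float:
    """SS(X) = (1/n_X) Σ_{i<j∈X} d²_ij."""
    if idx.size < 2:
        return 0.0
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / 2.0 / idx.size)


def _two_level_components(d2, labels):
    strata, inv = np.unique(np.asarray(labels, dtype=str), return_inverse=True)
    n = d2.shape[0]
    P = strata.size
    sizes = np.bincount(inv, minlength=P).astype(float)
    ssd_wp = sum(_ss(d2, np.flatnonzero(inv == s)) for s in range(P))
    ssd_total = _ss(d2, np.arange(n))
    ssd_ap = ssd_total - ssd_wp
    df_ap, df_wp = P - 1, n - P
    ms_ap = ssd_ap / df_ap
    ms_wp = ssd_wp / df_wp if df_wp > 0 else 0.0
    n0 = (n - np.sum(sizes**2) / n) / df_ap
    sigma_w = ms_wp
    sigma_a = (ms_ap - ms_wp) / n0
    total = sigma_a + sigma_w
    phi = sigma_a / total if total != 0 else np.nan
    return sigma_a, sigma_w, phi, (df_ap, df_wp, ssd_ap, ssd_wp)


def _three_level_components(d2, pop_labels, group_labels):
    pops = np.asarray(pop_labels, dtype=str)
    groups = np.asarray(group_labels, dtype=str)
    n = d2.shape[0]
    upops, pinv = np.unique(pops, return_inverse=True)
    ugroups, ginv = np.unique(groups, return_inverse=True)
    P, G = upops.size, ugroups.size
    # group of each pop (must be unique)
    pop_group = np.full(P, -1)
    for i in range(n):
        pop_group[pinv[i]] = ginv[i]
    n_p = np.bincount(pinv, minlength=P).astype(float)
    n_g = np.bincount(ginv, minlength=G).astype(float)

    ss_pops = sum(_ss(d2, np.flatnonzero(pinv == p)) for p in range(P))
    ss_groups = sum(_ss(d2, np.flatnonzero(ginv == g)) for g in range(G))
    ss_total = _ss(d2, np.arange(n))
    ssd_wp = ss_pops
    ssd_ap_wg = ss_groups - ss_pops
    ssd_ag = ss_total - ss_groups
    df_ag, df_ap, df_wp = G - 1, P - G, n - P
    ms_ag = ssd_ag / df_ag
    ms_ap = ssd_ap_wg / df_ap if df_ap > 0 else 0.0
    ms_wp = ssd_wp / df_wp if df_wp > 0 else 0.0
    # coefficients for unequal sizes (Excoffier's scheme)
    sum_np2_over_ng = sum(
        np.sum(n_p[pop_group == g] ** 2) / n_g[g] for g in range(G)
    )
    n1 = (n - sum_np2_over_ng) / df_ap if df_ap > 0 else 1.0
    n2 = (sum_np2_over_ng - np.sum(n_p**2) / n) / df_ag
    n3 = (n - np.sum(n_g**2) / n) / df_ag
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1 if df_ap > 0 else 0.0
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    total = sigma_a + sigma_b + sigma_c
    fct = sigma_a / total if total != 0 else np.nan
    fsc = (
        sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else np.nan
    )
    fst = (sigma_a + sigma_b) / total if total != 0 else np.nan
    return (sigma_a, sigma_b, sigma_c), (fct, fsc, fst)


def amova_from_distance(
    d2: np.ndarray,
    labels,
    group_labels=None,
    n_perm: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """AMOVA on a precomputed squared-distance matrix.

    With ``labels`` only: a two-level decomposition (among/within strata)
    with the among-strata index tested by permuting units among strata.
    With ``group_labels``: a three-level decomposition (groups / populations
    within groups / within populations).  Permutation schemes: F_CT — whole
    populations permuted among groups; F_SC — units permuted among
    populations within groups; F_ST — units permuted among populations.
    """
    labels = np.asarray(labels, dtype=str)
    n = d2.shape[0]
    if d2.shape != (n, n):
        raise ValueError("distance matrix must be square")
    rng = np.random.default_rng(seed)
    for s, c in zip(*np.unique(labels, return_counts=True)):
        if c < 2:
            raise ValueError(f"stratum {s!r} has fewer than 2 members")
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 strata")

    if group_labels is None:
        sa, sw, phi, (df_a, df_w, *_q) = _two_level_components(d2, labels)
        hits = 0
        perm = labels.copy()
        for _ in range(n_perm):
            rng.shuffle(perm)
            _, _, phi_p, _ = _two_level_components(d2, perm)
            if phi_p >= phi - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
        total = sa + sw
        return AmovaResult(
            components={"among": sa, "within": sw},
            percent={
                "among": 100.0 * sa / total if total else np.nan,
                "within": 100.0 * sw / total if total else np.nan,
            },
            indices={"FST": phi},
            p_values={"FST": p},
            n_permutations=n_perm,
            df={"among": df_a, "within": df_w},
        )

    group_labels = np.asarray(group_labels, dtype=str)
    comps, (fct, fsc, fst) = _three_level_components(d2, labels, group_labels)
    sa, sb, sc = comps
    # permutation tests
    upops = np.unique(labels)
    pop_group = {
        p: group_labels[labels == p][0] for p in upops
    }
    hits = {"FCT": 0, "FSC": 0, "FST": 0}
    for _ in range(n_perm):
        # FCT: permute populations among groups
        perm_groups_of_pops = rng.permutation([pop_group[p] for p in upops])
        gmap = dict(zip(upops, perm_groups_of_pops))
        gl = np.array([gmap[p] for p in labels])
        _, (fct_p, _f1, _f2) = _three_level_components(d2, labels, gl)
        if fct_p >= fct - 1e-12:
            hits["FCT"] += 1
        # FSC: permute individuals among pops within groups
        perm_pops = labels.copy()
        for g in np.unique(group_labels):
            sel = np.flatnonzero(group_labels == g)
            perm_pops[sel] = perm_pops[sel[rng.permutation(sel.size)]]
        _, (_f3, fsc_p, _f4) = _three_level_components(
            d2, perm_pops, group_labels
        )
        if fsc_p >= fsc - 1e-12:
            hits["FSC"] += 1
        # FST: permute individuals among pops (groups follow the pops)
        order = rng.permutation(n)
        pl = labels[order]
        gl2 = np.array([pop_group[p] for p in pl])
        _, (_f5, _f6, fst_p) = _three_level_components(d2, pl, gl2)
        if fst_p >= fst - 1e-12:
            hits["FST"] += 1
    p_values = {k: (v + 1) / (n_perm + 1) for k, v in hits.items()}
    total = sa + sb + sc
    pct = {
        "among_groups": 100.0 * sa / total if total else np.nan,
        "among_pops_within_groups": 100.0 * sb / total if total else np.nan,
        "within_pops": 100.0 * sc / total if total else np.nan,
    }
    return AmovaResult(
        components={
            "among_groups": sa,
            "among_pops_within_groups": sb,
            "within_pops": sc,
        },
        percent=pct,
        indices={"FCT": fct, "FSC": fsc, "FST": fst},
        p_values=p_values,
        n_permutations=n_perm,
    )


def amova(
    table: MsatGenotypeTable,
    strata: str | tuple[str, str] = "pop",
    n_perm: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """AMOVA on codominant genotypes.

    ``strata`` is ``"pop"`` or ``"group"`` for a two-level decomposition, or
    ``("group", "pop")`` for the three-level groups/populations/individuals
    decomposition.
    """
    d2 = codominant_distance(table)
    if isinstance(strata, str):
        labels = (
            table.pop_labels if strata == "pop" else _require_groups(table)
        )
        return amova_from_distance(d2, labels, n_perm=n_perm, seed=seed)
    if tuple(strata) != ("group", "pop"):
        raise ValueError("three-level strata must be ('group', 'pop')")
    return amova_from_distance(
        d2,
        table.pop_labels,
        group_labels=_require_groups(table),
        n_perm=n_perm,
        seed=seed,
    )


def _require_groups(table: MsatGenotypeTable) -> np.ndarray:
    if table.group_labels is None:
        raise ValueError("table carries no group labels")
    return table.group_labels


# ---------------------------------------------------------------------------
# Wright's F_ST (allele-copy level) and standardized differentiation
# ---------------------------------------------------------------------------

def wright_fst(table: MsatGenotypeTable, grouping: str = "group") -> float:
    """Wright's F_ST from an allele-copy-level variance decomposition.

    Gene copies are the units and the distance is allele identity (0/1);
    per-locus among/within variance components are summed across loci and
    F_ST = Σσ_a / Σ(σ_a + σ_w).  Unlike the genotype-level AMOVA φ (which
    approaches 2F/(1+F) under Hardy–Weinberg), this estimator is calibrated
    to the frequency-model F.
    """
    labels = (
        table.pop_labels if grouping == "pop" else _require_groups(table)
    ) if isinstance(grouping, str) else np.asarray(grouping, dtype=object)
    _ustrata, sinv = np.unique(labels.astype(str), return_inverse=True)
    num = den = 0.0
    for l in range(table.n_loci):
        ok = ~table.missing[:, l]
        copies = table.alleles[ok, l, :].ravel()
        strata = np.repeat(sinv[ok], 2)
        groups_here = np.unique(strata)
        P = groups_here.size
        n = copies.size
        if P < 2 or n - P <= 0:
            continue
        ssw = sst = 0.0
        for g in groups_here:
            sub = copies[strata == g]
            _v, c = np.unique(sub, return_counts=True)
            ssw += (sub.size - np.sum(c.astype(float) ** 2) / sub.size) / 2.0
        _v, C = np.unique(copies, return_counts=True)
        sst = (n - np.sum(C.astype(float) ** 2) / n) / 2.0
        ssa = sst - ssw
        ms_a = ssa / (P - 1)
        ms_w = ssw / (n - P)
        sizes = np.bincount(strata, minlength=int(strata.max()) + 1).astype(
            float
        )
        sizes = sizes[sizes > 0]
        n0 = (n - np.sum(sizes**2) / n) / (P - 1)
        num += (ms_a - ms_w) / n0
        den += (ms_a - ms_w) / n0 + ms_w
    return num / den if den != 0 else np.nan


def _recode_private(table: MsatGenotypeTable, labels: np.ndarray):
    """Recode alleles so that no two strata share an allele (frequencies
    preserved).  Used for the F_ST(max) denominator of F'_ST."""
    alleles = table.alleles.copy()
    ulabels = np.unique(labels.astype(str))
    for l in range(table.n_loci):
        step = int(table.alleles[:, :, :].max()) + 1
        for k, g in enumerate(ulabels):
            sel = np.flatnonzero(labels.astype(str) == g)
            alleles[sel, l, :] = table.alleles[sel, l, :] + k * step
    return replace(table, alleles=alleles, group_labels=table.group_labels)


def fst_prime(
    table: MsatGenotypeTable,
    grouping: str = "group",
    n_perm: int = 0,
    seed: int | None = None,
) -> FstPrimeResult:
    """Standardized differentiation F'_ST = F_ST / F_ST(max).

    F_ST(max) is the F_ST of a recoded table in which each stratum's alleles
    are made private (distinct across strata, frequencies preserved) —
    the maximal differentiation compatible with the observed within-stratum
    frequencies.  Both numerator and denominator use the allele-copy-level
    estimator :func:`wright_fst`.
    """
    labels = (
        table.pop_labels if grouping == "pop" else _require_groups(table)
    ) if isinstance(grouping, str) else np.asarray(grouping, dtype=object)
    fst = wright_fst(table, labels)
    recoded = _recode_private(table, labels)
    fst_max = wright_fst(recoded, labels)
    if fst_max == 0 or not np.isfinite(fst_max):
        return FstPrimeResult(fst=fst, fst_max=fst_max, fst_prime=np.nan)
    return FstPrimeResult(fst=fst, fst_max=fst_max, fst_prime=fst / fst_max)


# ---------------------------------------------------------------------------
# R_ST and the allele-size permutation test
# ---------------------------------------------------------------------------

def _rst_locus_components(x: np.ndarray, strata: np.ndarray, n_strata: int):
    """One-locus allele-size variance components (σ_a, σ_w) over gene
    copies; equivalent to AMOVA with d² = (x_i − x_j)²."""
    n = x.size
    counts = np.bincount(strata, minlength=n_strata).astype(float)
    used = counts >= 1
    P = int(np.sum(counts > 0))
    if P < 2 or n - P <= 0:
        return 0.0, 0.0
    sums = np.bincount(strata, weights=x, minlength=n_strata)
    sqsums = np.bincount(strata, weights=x * x, minlength=n_strata)
    with np.errstate(invalid="ignore", divide="ignore"):
        ssw = float(np.sum((sqsums - sums**2 / np.maximum(counts, 1))[used]))
    sst = float(np.sum(x * x) - np.sum(x) ** 2 / n)
    ssa = sst - ssw
    df_a, df_w = P - 1, n - P
    ms_a, ms_w = ssa / df_a, ssw / df_w
    n0 = (n - np.sum(counts**2) / n) / df_a
    return (ms_a - ms_w) / n0, ms_w


def rst_permutation_test(
    table: MsatGenotypeTable,
    grouping: str = "group",
    n_perm: int = 10000,
    seed: int | None = None,
) -> RstTestResult:
    """Slatkin's R_ST and its allele-size permutation null (pR_ST).

    R_ST is the among-stratum fraction of allele-size variance, combined
    across loci by summing variance components.  The null distribution is
    built by permuting the size values assigned to the allelic states within
    each locus and recomputing R_ST; pR_ST is the mean permuted value and
    p = (#{perm ≥ obs} + 1)/(n_perm + 1).  A significantly larger R_ST than
    pR_ST indicates that mutation (stepwise similarity) contributes to
    differentiation, i.e. phylogeographic structure.

    Allele sizes must be on the repeat scale (convert with
    :meth:`MsatGenotypeTable.to_repeat_scale`).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be a positive integer")
    labels = (
        table.pop_labels if grouping == "pop" else _require_groups(table)
    ) if isinstance(grouping, str) else np.asarray(grouping, dtype=object)
    ustrata, sinv = np.unique(labels.astype(str), return_inverse=True)
    n_strata = ustrata.size
    rng = np.random.default_rng(seed)

    loci = []
    for l in range(table.n_loci):
        ok = ~table.missing[:, l]
        x = table.alleles[ok, l, :].astype(float).ravel()
        st = np.repeat(sinv[ok], 2)
        states = np.unique(x)
        if states.size < 2:
            warnings.warn(
                f"locus {table.locus_names[l]!r} has a single allele; "
                "excluded from the size permutation"
            )
            continue
        state_idx = np.searchsorted(states, x)
        loci.append((x, st, states, state_idx))
    if not loci:
        raise ValueError("no polymorphic locus available")

    def _rst(values_by_locus):
        num = den = 0.0
        for (x, st, _states, _sidx), vals in zip(loci, values_by_locus):
            sa, sw = _rst_locus_components(vals, st, n_strata)
            num += sa
            den += sa + sw
        return num / den if den != 0 else np.nan

    obs = _rst([x for (x, *_r) in loci])
    perm_vals = np.empty(n_perm)
    for k in range(n_perm):
        vals = []
        for x, st, states, sidx in loci:
            vals.append(rng.permutation(states)[sidx])
        perm_vals[k] = _rst(vals)
    hits = int(np.sum(perm_vals >= obs - 1e-12))
    return RstTestResult(
        rst=obs,
        p_rst=float(np.mean(perm_vals)),
        p_value=(hits + 1) / (n_perm + 1),
        n_permutations=n_perm,
        permuted=perm_vals,
    )


# ---------------------------------------------------------------------------
# Principal coordinate analysis
# ---------------------------------------------------------------------------

def pcoa(distance_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classical metric scaling of a symmetric zero-diagonal distance matrix.

    Returns ``(coordinates, eigenvalues)`` with eigenvalues non-increasing.
    Delegates to scikit-bio's eigendecomposition.
    """
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.allclose(d, 0.0):
        return np.zeros_like(d), np.zeros(d.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(DistanceMatrix(d), method="eigh")
    coords = res.samples.to_numpy()
    eigvals = res.eigvals.to_numpy()
    order = np.argsort(eigvals)[::-1]
    return coords[:, order], eigvals[order]
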