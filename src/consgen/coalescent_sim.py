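"""Structured-coalescent simulation of microsatellites under competing
demographies, with generalized stepwise mutation (GSM).

Demographic models (sizes in diploid individuals, times in generations
before present, migration per gene copy per generation):

* ``SNM(N)`` — constant size.
* ``PGM(N, G, t)`` — exponential growth: the population reached its current
  size ``N`` growing at forward rate ``G`` since ``t`` generations ago, from
  an ancestral size ``N·exp(−G·t)``.
* ``SRM(N, Nb, t1)`` — instantaneous decline at ``t1`` from an ancestral
  size ``Nb > N`` to the current ``N``.
* ``DVM(N_cur1, N_cur2, N_anc, T, m12, m21)`` — two demes of constant size
  split from an ancestor of size ``N_anc`` at ``T``; migration is active
  between ``T`` and the present.  ``m21`` is the forward rate of gene flow
  from deme 2 into deme 1 (fraction of deme-1 gene copies that are
  immigrants per generation), so the expected migrant count is
  ``Nm21 = N_cur1·m21``; unidirectional variants set the other rate to 0.

The coalescent runs backwards in time: within a deme of (time-dependent)
size ``N`` each lineage pair coalesces at rate ``1/(2N)`` per generation;
exponential trajectories are handled by time-rescaling; lineages migrate
individually and demes merge at the split time.  Mutations are laid on
branches as a Poisson process; each mutation moves the allele size by ±k
repeat units with equiprobable sign and geometric step size
``P(k) = (1−P_GSM)·P_GSM^(k−1)`` — ``P_GSM = 0`` is the strict stepwise
model.  No allele-size boundaries are imposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .io_formats import MsatGenotypeTable

__all__ = [
    "SNM",
    "PGM",
    "SRM",
    "DVM",
    "MutationModel",
    "Genealogy",
    "simulate_genealogy",
    "overlay_gsm",
    "simulate_msat_dataset",
]


# ---------------------------------------------------------------------------
# Model types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SNM:
    """Standard neutral model: constant diploid size N."""

    N: float

    def __post_init__(self):
        if self.N <= 0:
            raise ValueError("N must be positive")


@dataclass(frozen=True)
class PGM:
    """Population growth: current size N reached by exponential growth at
    forward rate G starting t generations ago (ancestral size N·exp(−G·t))."""

    N: float
    G: float
    t: float

    def __post_init__(self):
        if self.N <= 0 or self.t < 0:
            raise ValueError("N must be positive and t non-negative")

    @property
    def ancestral_size(self) -> float:
        return self.N * np.exp(-self.G * self.t)


@dataclass(frozen=True)
class SRM:
    """Size reduction: ancestral size Nb dropped instantaneously to N at t1
    generations ago (N < Nb)."""

    N: float
    Nb: float
    t1: float

    def __post_init__(self):
        if self.N <= 0 or self.Nb <= 0 or self.t1 < 0:
            raise ValueError("sizes must be positive, t1 non-negative")
        if not self.N < self.Nb:
            raise ValueError("size reduction requires N < Nb")


@dataclass(frozen=True)
class DVM:
    """Divergence of two demes from an ancestor at time T with migration
    active between T and the present."""

    N_cur1: float
    N_cur2: float
    N_anc: float
    T: float
    m12: float = 0.0
    m21: float = 0.0

    def __post_init__(self):
        if min(self.N_cur1, self.N_cur2, self.N_anc) <= 0 or self.T < 0:
            raise ValueError("sizes must be positive, T non-negative")
        for m in (self.m12, self.m21):
            if not 0.0 <= m <= 1.0:
                raise ValueError("migration rates must lie in [0, 1]")
        if max(self.N_cur1, self.N_cur2) >= self.N_anc:
            # the motivating analysis constrains N_cur < N_anc; warn-free
            # acceptance here keeps the simulator generic
            pass


DemographicModel = SNM | PGM | SRM | DVM


@dataclass(frozen=True)
class MutationModel:
    """GSM mutation with gamma-distributed per-locus rate heterogeneity.

    Per-locus rates are drawn from Gamma(shape, rate) and, when
    ``normalize_mu`` is set, rescaled so that their across-locus mean equals
    ``mu_mean`` (default 5e-4 per generation).  ``p_gsm`` is the geometric
    parameter of the mutation step size; 0 gives the strict stepwise model.
    """

    mu_mean: float = 5e-4
    gamma_shape: float = 2.0
    gamma_rate: float = 2.0
    p_gsm: float = 0.0
    normalize_mu: bool = True

    def __post_init__(self):
        if self.mu_mean < 0:
            raise ValueError("mu_mean must be non-negative")
        if not 0.0 <= self.p_gsm < 1.0:
            raise ValueError("p_gsm must lie in [0, 1)")
        if self.gamma_shape <= 0 or self.gamma_rate <= 0:
            raise ValueError("gamma parameters must be positive")

    def draw_locus_rates(self, n_loci: int, rng: np.random.Generator):
        raw = rng.gamma(self.gamma_shape, 1.0 / self.gamma_rate, size=n_loci)
        if self.normalize_mu:
            return raw * (self.mu_mean / raw.mean())
        return raw


# ---------------------------------------------------------------------------
# Genealogy container
# ---------------------------------------------------------------------------

@dataclass
class Genealogy:
    """Binary ultrametric genealogy: ``parent[i]`` (−1 at the root) and
    ``time[i]`` in generations for nodes 0..2n−2 (tips first)."""

    parent: np.ndarray
    time: np.ndarray
    n_tips: int
    tip_demes: np.ndarray

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def tmrca(self) -> float:
        return float(self.time.max())

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros_like(self.time)
        has_parent = self.parent >= 0
        bl[has_parent] = (
            self.time[self.parent[has_parent]] - self.time[has_parent]
        )
        return bl


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sim_kernel(seed, n0, n1, epoch_start, sizes, growth, mig):
    """Event-driven structured coalescent for ≤2 demes.

    epoch arrays: per epoch e, ``sizes[e, d]`` is the deme size at the epoch
    start, ``growth[e, d]`` the backward growth rate (size(τ) =
    sizes·exp(growth·(τ−start))), ``mig[e, d]`` the per-lineage rate of
    jumping out of deme d.  At the start of the final epoch all lineages are
    moved into deme 0 when deme 1 is closed (size 0).
    """
    np.random.seed(seed)
    n = n0 + n1
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes, dtype=np.float64)
    # active lineages
    nodes = np.empty(n, dtype=np.int64)
    deme = np.empty(n, dtype=np.int64)
    for i in range(n0):
        nodes[i] = i
        deme[i] = 0
    for i in range(n1):
        nodes[n0 + i] = n0 + i
        deme[n0 + i] = 1
    k = n
    next_node = n
    tau = 0.0
    e = 0
    n_epochs = epoch_start.shape[0]
    while k > 1:
        if e + 1 < n_epochs:
            t_end = epoch_start[e + 1]
        else:
            t_end = np.inf
        # counts per deme
        k0 = 0
        for i in range(k):
            if deme[i] == 0:
                k0 += 1
        k1 = k - k0
        N0 = sizes[e, 0]
        N1 = sizes[e, 1]
        g0 = growth[e, 0]
        g1 = growth[e, 1]
        if g0 != 0.0 or g1 != 0.0:
            # growth handled only for a single active deme, no migration
            g = g0 if k0 > 0 else g1
            N_start = N0 if k0 > 0 else N1
            kk = k0 if k0 > 0 else k1
            if kk < 2:
                if t_end == np.inf:
                    return parent, time, -1
                tau = t_end
                e += 1
                if e == n_epochs - 1 and sizes[e, 1] == 0.0:
                    for i in range(k):
                        deme[i] = 0
                continue
            Ntau = N_start * np.exp(g * (tau - epoch_start[e]))
            r0 = kk * (kk - 1) / (4.0 * Ntau)
            E = np.random.exponential(1.0)
            arg = 1.0 - g * E / r0
            if g == 0.0:
                w = E / r0
            elif arg <= 0.0:
                w = np.inf
            else:
                w = -np.log(arg) / g
            if tau + w >= t_end:
                tau = t_end
                e += 1
                if e == n_epochs - 1 and sizes[e, 1] == 0.0:
                    for i in range(k):
                        deme[i] = 0
                continue
            tau += w
            d_ev = 0 if k0 > 0 else 1
        else:
            c0 = k0 * (k0 - 1) / (4.0 * N0) if N0 > 0.0 else 0.0
            c1 = k1 * (k1 - 1) / (4.0 * N1) if N1 > 0.0 else 0.0
            mi0 = k0 * mig[e, 0]
            mi1 = k1 * mig[e, 1]
            R = c0 + c1 + mi0 + mi1
            if R <= 0.0:
                if t_end == np.inf:
                    # cannot progress: should not happen with valid input
                    return parent, time, -1
                tau = t_end
                e += 1
                if e == n_epochs - 1 and sizes[e, 1] == 0.0:
                    for i in range(k):
                        deme[i] = 0
                continue
            w = np.random.exponential(1.0 / R)
            if tau + w >= t_end:
                tau = t_end
                e += 1
                if e == n_epochs - 1 and sizes[e, 1] == 0.0:
                    for i in range(k):
                        deme[i] = 0
                continue
            tau += w
            u = np.random.random() * R
            if u < mi0:
                # migration out of deme 0
                j = int(np.random.random() * k0)
                cnt = -1
                for i in range(k):
                    if deme[i] == 0:
                        cnt += 1
                        if cnt == j:
                            deme[i] = 1
                            break
                continue
            elif u < mi0 + mi1:
                j = int(np.random.random() * k1)
                cnt = -1
                for i in range(k):
                    if deme[i] == 1:
                        cnt += 1
                        if cnt == j:
                            deme[i] = 0
                            break
                continue
            elif u < mi0 + mi1 + c0:
                d_ev = 0
            else:
                d_ev = 1
        # coalescence in deme d_ev: pick two distinct lineages
        kd = 0
        for i in range(k):
            if deme[i] == d_ev:
                kd += 1
        j1 = int(np.random.random() * kd)
        j2 = int(np.random.random() * (kd - 1))
        if j2 >= j1:
            j2 += 1
        i1 = -1
        i2 = -1
        cnt = -1
        for i in range(k):
            if deme[i] == d_ev:
                cnt += 1
                if cnt == j1:
                    i1 = i
                if cnt == j2:
                    i2 = i
        a = nodes[i1]
        b = nodes[i2]
        parent[a] = next_node
        parent[b] = next_node
        time[next_node] = tau
        lo, hi = (i1, i2) if i1 < i2 else (i2, i1)
        nodes[lo] = next_node
        deme[lo] = d_ev
        nodes[hi] = nodes[k - 1]
        deme[hi] = deme[k - 1]
        k -= 1
        next_node += 1
    return parent, time, 0


def _epochs_for(model: DemographicModel):
    if isinstance(model, SNM):
        start = np.array([0.0])
        sizes = np.array([[model.N, 0.0]])
        growth = np.zeros((1, 2))
        mig = np.zeros((1, 2))
    elif isinstance(model, PGM):
        start = np.array([0.0, model.t])
        sizes = np.array(
            [[model.N, 0.0], [model.ancestral_size, 0.0]]
        )
        growth = np.array([[-model.G, 0.0], [0.0, 0.0]])
        mig = np.zeros((2, 2))
    elif isinstance(model, SRM):
        start = np.array([0.0, model.t1])
        sizes = np.array([[model.N, 0.0], [model.Nb, 0.0]])
        growth = np.zeros((2, 2))
        mig = np.zeros((2, 2))
    elif isinstance(model, DVM):
        start = np.array([0.0, model.T])
        sizes = np.array(
            [[model.N_cur1, model.N_cur2], [model.N_anc, 0.0]]
        )
        growth = np.zeros((2, 2))
        # backward: a deme-1 lineage's parent was in deme 2 with prob m21
        mig = np.array([[model.m21, model.m12], [0.0, 0.0]])
    else:
        raise TypeError(f"unknown model {model!r}")
    return start, sizes, growth, mig


def simulate_genealogy(
    model: DemographicModel,
    sample_config: Sequence[int],
    seed: int | None = None,
) -> Genealogy:
    """Simulate one genealogy of ``sample_config`` gene copies per deme.

    ``sample_config`` holds one entry for single-deme models and two for the
    divergence model; entries are counts of sampled gene copies (haploid).
    """
    cfg = [int(x) for x in sample_config]
    if isinstance(model, DVM):
        if len(cfg) != 2:
            raise ValueError("divergence model needs two sample sizes")
        n0, n1 = cfg
    else:
        if len(cfg) != 1:
            raise ValueError("single-deme models need one sample size")
        n0, n1 = cfg[0], 0
    if n0 + n1 < 1 or min(n0, n1) < 0:
        raise ValueError("need at least one sampled gene copy")
    start, sizes, growth, mig = _epochs_for(model)
    kernel_seed = int(
        np.random.default_rng(seed).integers(0, 2**31 - 1)
    )
    parent, time, status = _sim_kernel(
        kernel_seed, n0, n1, start, sizes, growth, mig
    )
    if status != 0:
        raise RuntimeError("coalescent failed to reach a common ancestor")
    tip_demes = np.concatenate(
        [np.zeros(n0, dtype=np.int64), np.ones(n1, dtype=np.int64)]
    )
    return Genealogy(
        parent=parent, time=time, n_tips=n0 + n1, tip_demes=tip_demes
    )


# ---------------------------------------------------------------------------
# GSM mutation overlay
# ---------------------------------------------------------------------------

def overlay_gsm(
    genealogy: Genealogy,
    mu_locus: float,
    p_gsm: float = 0.0,
    root_size: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Allele sizes at the tips after GSM mutation along the branches.

    Mutations are Poisson with rate ``mu_locus`` per generation on each
    branch; each mutation adds ±k with equiprobable sign and geometric k
    (parameter ``p_gsm``; strict SMM at 0).  Sizes are unconstrained.
    """
    if mu_locus < 0:
        raise ValueError("mutation rate must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    bl = genealogy.branch_lengths()
    n_nodes = bl.size
    nmut = rng.poisson(mu_locus * bl)
    delta = np.zeros(n_nodes, dtype=np.int64)
    total = int(nmut.sum())
    if total:
        if p_gsm == 0.0:
            steps = np.ones(total, dtype=np.int64)
        else:
            steps = rng.geometric(1.0 - p_gsm, size=total)
        signs = rng.integers(0, 2, size=total) * 2 - 1
        per_branch = np.split(steps * signs, np.cumsum(nmut))[:-1]
        delta = np.array(
            [int(x.sum()) for x in per_branch], dtype=np.int64
        )
    value = np.empty(n_nodes, dtype=np.int64)
    order = np.argsort(genealogy.time)[::-1]  # root first
    value[order[0]] = root_size
    for node in order[1:]:
        value[node] = value[genealogy.parent[node]] + delta[node]
    return value[: genealogy.n_tips]


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------

def simulate_msat_dataset(
    model: DemographicModel,
    mutation: MutationModel,
    n_loci: int,
    sample_sizes: Sequence[int],
    seed: int | None = None,
    group_names: Sequence[str] | None = None,
) -> MsatGenotypeTable:
    """Simulate a diploid genotype table of unlinked loci.

    ``sample_sizes`` are diploid counts per group (one entry for single-deme
    models, two for the divergence model).  Gene copies are paired randomly
    into diploids within each deme (Hardy–Weinberg).  Per-locus mutation
    rates are drawn once per dataset from the gamma model.  Allele sizes are
    shifted per locus to stay positive when necessary (all downstream
    statistics are translation-invariant).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be positive")
    diploids = [int(x) for x in sample_sizes]
    copies = [2 * d for d in diploids]
    rng = np.random.default_rng(seed)
    mus = mutation.draw_locus_rates(n_loci, rng)
    n_ind = sum(diploids)
    alleles = np.zeros((n_ind, n_loci, 2), dtype=np.int64)
    for l in range(n_loci):
        gen = simulate_genealogy(
            model, copies, seed=int(rng.integers(0, 2**31 - 1))
        )
        tips = overlay_gsm(
            gen, mus[l], mutation.p_gsm, rng=rng
        )
        if tips.min() <= 0:
            tips = tips - tips.min() + 1
        # random pairing within each deme
        pos = 0
        ind = 0
        for d, ncop in enumerate(copies):
            perm = rng.permutation(ncop)
            pair = tips[pos : pos + ncop][perm].reshape(-1, 2)
            alleles[ind : ind + ncop // 2, l, :] = pair
            pos += ncop
            ind += ncop // 2
    if group_names is None:
        group_names = [f"group{d + 1}" for d in range(len(diploids))]
    pop_labels = np.concatenate(
        [np.repeat(g, d) for g, d in zip(group_names, diploids)]
    )
    ids = [f"ind{i + 1}" for i in range(n_ind)]
    return MsatGenotypeTable(
        individual_ids=ids,
        locus_names=[f"L{l + 1}" for l in range(n_loci)],
        alleles=alleles,
        missing=np.zeros((n_ind, n_loci), dtype=bool),
        pop_labels=np.array(pop_labels, dtype=object),
        group_labels=np.array(pop_labels, dtype=object),
        repeat_unit=1,
    )
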