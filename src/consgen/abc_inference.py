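"""Approximate Bayesian computation: reference tables, random-forest model
choice, regression-adjusted posteriors and posterior-predictive checks.

The workflow mirrors the modern ABC practice for microsatellite demography:

1. draw parameters from their priors, simulate datasets under each candidate
   demographic model and reduce each to a summary-statistic vector (mean and
   SD across loci of allele number, expected heterozygosity and allele-size
   range; for two-group data additionally the pooled allele-size range and
   Nei's G_ST between groups) — the ARLSUMSTAT-style summaries;
2. choose among models with a classification random forest on the reference
   table (majority vote at the observed vector); the out-of-bag (OOB)
   misclassification rate is the prior error rate, and the posterior
   probability of the selected model is estimated by regressing the OOB
   outcome (correct/incorrect) on the summaries and evaluating at the
   observation;
3. estimate parameters from the best model's reference table by rejection
   on normalized Euclidean distance followed by regression adjustment
   (weighted local-linear by default, single-hidden-layer neural network
   optionally), with the posterior mode from a Gaussian KDE and the 95% HPD
   as the narrowest interval holding 95% of the adjusted draws;
4. check goodness of fit by simulating pseudo-observed datasets from the
   posterior and locating the observed summaries in their distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.neural_network import MLPRegressor

from .coalescent_sim import (
    DVM,
    PGM,
    SNM,
    SRM,
    DemographicModel,
    MutationModel,
    simulate_msat_dataset,
)
from .io_formats import MsatGenotypeTable

__all__ = [
    "Prior",
    "PriorSpec",
    "ModelSpec",
    "ReferenceTable",
    "ModelChoiceResult",
    "PosteriorResult",
    "summarize",
    "snm_spec",
    "pgm_spec",
    "srm_spec",
    "dvm_spec",
    "build_reference_table",
    "save_reference_table",
    "load_reference_table",
    "rf_model_choice",
    "estimate_posterior",
    "goodness_of_fit",
]


# ---------------------------------------------------------------------------
# Priors and model specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Prior:
    """Scalar prior: ``uniform``, ``loguniform`` or ``fixed``."""

    dist: str
    lo: float
    hi: float = np.nan

    def __post_init__(self):
        if self.dist not in ("uniform", "loguniform", "fixed"):
            raise ValueError(f"unknown prior family {self.dist!r}")
        if self.dist == "fixed":
            object.__setattr__(self, "hi", self.lo)
            return
        if not (np.isfinite(self.lo) and np.isfinite(self.hi)):
            raise ValueError("prior bounds must be finite")
        if not self.lo < self.hi:
            raise ValueError("prior requires lo < hi")
        if self.dist == "loguniform" and self.lo <= 0:
            raise ValueError("loguniform requires positive bounds")

    def draw(self, rng: np.random.Generator) -> float:
        if self.dist == "fixed":
            return self.lo
        if self.dist == "uniform":
            return float(rng.uniform(self.lo, self.hi))
        return float(
            np.exp(rng.uniform(np.log(self.lo), np.log(self.hi)))
        )


class PriorSpec(dict):
    """Mapping parameter name → :class:`Prior`."""

    def draw(self, rng: np.random.Generator) -> dict[str, float]:
        return {k: v.draw(rng) for k, v in self.items()}


_MUTATION_PRIORS = {
    # gamma shape of per-locus rate heterogeneity and the GSM geometric
    # parameter; both hyperpriors are implementer-set (see methods note)
    "shape": Prior("uniform", 0.5, 5.0),
    "p_gsm": Prior("uniform", 0.0, 1.0),
}


@dataclass
class ModelSpec:
    """A named demographic model with priors and a builder mapping one prior
    draw to (DemographicModel, MutationModel)."""

    name: str
    priors: PriorSpec
    build: Callable[
        [dict[str, float]], tuple[DemographicModel, MutationModel]
    ]

    def draw_and_build(self, rng):
        params = self.priors.draw(rng)
        model, mut = self.build(params)
        return params, model, mut


def _mutation_from(params: dict[str, float]) -> MutationModel:
    return MutationModel(
        mu_mean=5e-4,
        gamma_shape=params["shape"],
        gamma_rate=params["shape"],
        p_gsm=min(params["p_gsm"], 0.999999),
    )


def snm_spec(n_prior: Prior = Prior("uniform", 100, 10_000)) -> ModelSpec:
    priors = PriorSpec(N=n_prior, **_MUTATION_PRIORS)
    return ModelSpec(
        "SNM", priors, lambda p: (SNM(N=p["N"]), _mutation_from(p))
    )


def pgm_spec(
    n_prior: Prior = Prior("uniform", 100, 10_000),
    g_prior: Prior = Prior("loguniform", 1e-4, 1e-1),
    t_prior: Prior = Prior("uniform", 1, 10_000),
) -> ModelSpec:
    priors = PriorSpec(N=n_prior, G=g_prior, t=t_prior, **_MUTATION_PRIORS)
    return ModelSpec(
        "PGM",
        priors,
        lambda p: (PGM(N=p["N"], G=p["G"], t=p["t"]), _mutation_from(p)),
    )


def srm_spec(
    n_prior: Prior = Prior("uniform", 100, 10_000),
    ratio_prior: Prior = Prior("uniform", 1.5, 20.0),
    t1_prior: Prior = Prior("uniform", 1, 10_000),
) -> ModelSpec:
    priors = PriorSpec(
        N=n_prior, Nb_over_N=ratio_prior, t1=t1_prior, **_MUTATION_PRIORS
    )
    return ModelSpec(
        "SRM",
        priors,
        lambda p: (
            SRM(N=p["N"], Nb=p["N"] * p["Nb_over_N"], t1=p["t1"]),
            _mutation_from(p),
        ),
    )


def dvm_spec(
    n_cur1: float,
    n_cur2: float,
    flow: str = "2to1",
    name: str | None = None,
    t_prior: Prior = Prior("uniform", 1, 10_000),
    nanc_prior: Prior | None = None,
    m_prior: Prior = Prior("uniform", 1e-5, 0.3),
) -> ModelSpec:
    """Divergence model with fixed current sizes and a gene-flow direction:
    ``"2to1"`` (deme 2 → deme 1), ``"1to2"``, or ``"both"``.

    The ancestral-size prior is uniform on (100, 10000) truncated to exceed
    both current sizes (the divergence analysis assumes N_cur < N_anc).
    """
    if flow not in ("2to1", "1to2", "both"):
        raise ValueError("flow must be '2to1', '1to2' or 'both'")
    if nanc_prior is None:
        lo = max(100.0, n_cur1, n_cur2) + 1.0
        nanc_prior = Prior("uniform", lo, 10_000.0)
    priors = PriorSpec(
        N_anc=nanc_prior, T=t_prior, m=m_prior, **_MUTATION_PRIORS
    )

    def build(p):
        m12 = p["m"] if flow in ("1to2", "both") else 0.0
        m21 = p["m"] if flow in ("2to1", "both") else 0.0
        return (
            DVM(
                N_cur1=n_cur1,
                N_cur2=n_cur2,
                N_anc=p["N_anc"],
                T=p["T"],
                m12=m12,
                m21=m21,
            ),
            _mutation_from(p),
        )

    return ModelSpec(name or f"DVM_{flow}", priors, build)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def _per_locus_stats(alleles: np.ndarray):
    """(allele count, expected heterozygosity, size range) per locus for a
    (n_ind, n_loci, 2) block without missing data."""
    n_loci = alleles.shape[1]
    A = np.empty(n_loci)
    He = np.empty(n_loci)
    R = np.empty(n_loci)
    for l in range(n_loci):
        copies = alleles[:, l, :].ravel()
        vals, counts = np.unique(copies, return_counts=True)
        p = counts / counts.sum()
        A[l] = vals.size
        He[l] = 1.0 - float(np.sum(p**2))
        R[l] = float(vals.max() - vals.min())
    return A, He, R


SINGLE_STAT_NAMES = [
    "mean_A", "sd_A", "mean_He", "sd_He", "mean_R", "sd_R",
]


def summarize(table: MsatGenotypeTable, mode: str = "single") -> np.ndarray:
    """ARLSUMSTAT-style summary-statistic vector.

    ``single``: mean and SD across loci of allele count, expected
    heterozygosity and allele-size range (6 stats, whole table pooled).
    ``pair``: the same 6 per group (the table must carry exactly 2 groups),
    plus the mean pooled total allele-size range and Nei's G_ST between the
    groups (14 stats).
    """
    if table.n_loci < 1:
        raise ValueError("table has no loci")
    if table.missing.any():
        raise ValueError("summaries require complete data")
    if mode == "single":
        A, He, R = _per_locus_stats(table.alleles)
        return np.array(
            [A.mean(), A.std(ddof=1) if A.size > 1 else 0.0,
             He.mean(), He.std(ddof=1) if He.size > 1 else 0.0,
             R.mean(), R.std(ddof=1) if R.size > 1 else 0.0]
        )
    if mode != "pair":
        raise ValueError("mode must be 'single' or 'pair'")
    if table.group_labels is None:
        raise ValueError("pair mode requires group labels")
    groups = table.groups()
    if len(groups) != 2:
        raise ValueError(f"pair mode requires exactly 2 groups, got {groups}")
    blocks = []
    hs_l = []
    ht_l = []
    n_loci = table.n_loci
    freqs_by_group = []
    for g in groups:
        sel = table.group_labels.astype(str) == g
        block = table.alleles[sel]
        A, He, R = _per_locus_stats(block)
        blocks.append(
            [A.mean(), A.std(ddof=1) if A.size > 1 else 0.0,
             He.mean(), He.std(ddof=1) if He.size > 1 else 0.0,
             R.mean(), R.std(ddof=1) if R.size > 1 else 0.0]
        )
        freqs_by_group.append(block)
    # pooled range and Nei's G_ST
    _A, _He, R_tot = _per_locus_stats(table.alleles)
    gst_num = gst_den = 0.0
    for l in range(n_loci):
        union = np.unique(table.alleles[:, l, :])
        ps = []
        for block in freqs_by_group:
            copies = block[:, l, :].ravel()
            counts = np.array([np.sum(copies == v) for v in union], float)
            ps.append(counts / counts.sum())
        p_bar = (ps[0] + ps[1]) / 2.0
        ht = 1.0 - float(np.sum(p_bar**2))
        hs = 1.0 - 0.5 * float(np.sum(ps[0] ** 2) + np.sum(ps[1] ** 2))
        ht_l.append(ht)
        hs_l.append(hs)
    ht_m, hs_m = float(np.mean(ht_l)), float(np.mean(hs_l))
    gst = (ht_m - hs_m) / ht_m if ht_m > 0 else 0.0
    return np.array(blocks[0] + blocks[1] + [R_tot.mean(), gst])


def pair_stat_names() -> list[str]:
    return (
        [f"g1_{s}" for s in SINGLE_STAT_NAMES]
        + [f"g2_{s}" for s in SINGLE_STAT_NAMES]
        + ["mean_R_total", "GST"]
    )


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """Rows of (model label, parameter draw, summary statistics)."""

    model_labels: np.ndarray
    params: pd.DataFrame
    stats: np.ndarray
    stat_names: list[str]
    param_bounds: dict[str, tuple[float, float]] | None = None
    seed: int | None = None
    n_retries: int = 0

    @property
    def n_rows(self) -> int:
        return self.stats.shape[0]

    def subset_model(self, label: str) -> "ReferenceTable":
        sel = self.model_labels == label
        return ReferenceTable(
            model_labels=self.model_labels[sel],
            params=self.params.loc[sel].reset_index(drop=True),
            stats=self.stats[sel],
            stat_names=list(self.stat_names),
            param_bounds=self.param_bounds,
            seed=self.seed,
        )


def save_reference_table(ref: ReferenceTable, path) -> None:
    """Persist a reference table as TSV preceded by a JSON header line
    (a ``#``-prefixed metadata record)."""
    import json
    from pathlib import Path

    header = {
        "stat_names": list(ref.stat_names),
        "param_names": list(ref.params.columns),
        "param_bounds": {
            k: list(v) for k, v in (ref.param_bounds or {}).items()
        },
        "seed": ref.seed,
        "n_retries": ref.n_retries,
    }
    body = pd.concat(
        [
            pd.Series(ref.model_labels, name="model"),
            ref.params.reset_index(drop=True),
            pd.DataFrame(ref.stats, columns=ref.stat_names),
        ],
        axis=1,
    )
    with Path(path).open("w") as fh:
        fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
        body.to_csv(fh, sep="\t", index=False)


def load_reference_table(path) -> ReferenceTable:
    import json
    from pathlib import Path

    with Path(path).open() as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError("missing JSON header line")
        header = json.loads(first[1:])
        body = pd.read_csv(fh, sep="\t")
    return ReferenceTable(
        model_labels=body["model"].to_numpy(dtype=object).astype(str),
        params=body[header["param_names"]].copy(),
        stats=body[header["stat_names"]].to_numpy(dtype=float),
        stat_names=header["stat_names"],
        param_bounds={
            k: (float(v[0]), float(v[1]))
            for k, v in header["param_bounds"].items()
        }
        or None,
        seed=header.get("seed"),
        n_retries=int(header.get("n_retries", 0)),
    )


def build_reference_table(
    models: Sequence[ModelSpec],
    n_sims: int,
    sample_sizes: Sequence[int],
    n_loci: int = 8,
    seed: int | None = None,
) -> ReferenceTable:
    """Prior-predictive reference table with equal allocation per model.

    ``sample_sizes`` (diploids per group) sets the sampling design: one
    entry for single-population models, two (with pair-mode summaries) for
    divergence models.  Deterministic under ``seed``; failed simulations are
    retried and counted.
    """
    if n_sims < len(models):
        raise ValueError("n_sims must be at least the number of models")
    mode = "pair" if len(sample_sizes) == 2 else "single"
    rng = np.random.default_rng(seed)
    n_per = n_sims // len(models)
    labels, param_rows, stat_rows = [], [], []
    n_retries = 0
    for spec in models:
        for _ in range(n_per):
            for _attempt in range(10):
                try:
                    params, model, mut = spec.draw_and_build(rng)
                    table = simulate_msat_dataset(
                        model,
                        mut,
                        n_loci,
                        sample_sizes,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                    stats = summarize(table, mode)
                    break
                except (ValueError, RuntimeError):
                    n_retries += 1
            else:
                raise RuntimeError(
                    f"simulation under {spec.name} failed 10 times in a row"
                )
            labels.append(spec.name)
            param_rows.append(params)
            stat_rows.append(stats)
    stat_names = (
        pair_stat_names() if mode == "pair" else list(SINGLE_STAT_NAMES)
    )
    bounds: dict[str, tuple[float, float]] = {}
    for spec in models:
        for name, prior in spec.priors.items():
            if prior.dist != "fixed":
                lo, hi = bounds.get(name, (prior.lo, prior.hi))
                bounds[name] = (min(lo, prior.lo), max(hi, prior.hi))
    return ReferenceTable(
        model_labels=np.array(labels),
        params=pd.DataFrame(param_rows),
        stats=np.vstack(stat_rows),
        stat_names=stat_names,
        param_bounds=bounds,
        seed=seed,
        n_retries=n_retries,
    )


# ---------------------------------------------------------------------------
# Random-forest model choice
# ---------------------------------------------------------------------------

@dataclass
class ModelChoiceResult:
    votes: dict[str, int]
    selected: str
    oob_error: dict[str, float]
    oob_error_mean: float
    posterior_probability: float
    n_trees: int


def rf_model_choice(
    ref: ReferenceTable,
    obs: np.ndarray,
    n_trees: int = 1000,
    seed: int | None = None,
) -> ModelChoiceResult:
    """Model choice by classification random forest.

    The selected model takes the majority of per-tree votes at the observed
    summary vector; the prior error rate is the OOB misclassification rate
    (overall mean and per model); the posterior probability of the selected
    model is a regression-forest estimate of P(correct choice | summaries)
    trained on the OOB outcomes and evaluated at the observation.
    """
    labels = np.unique(ref.model_labels)
    if labels.size < 2:
        raise ValueError("model choice requires at least 2 models")
    X, y = ref.stats, ref.model_labels
    obs = np.asarray(obs, dtype=float).reshape(1, -1)
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        random_state=(
            None if seed is None else int(seed) % (2**32)
        ),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    votes = {lab: 0 for lab in labels}
    for tree in clf.estimators_:
        k = int(np.argmax(tree.predict_proba(obs)[0]))
        votes[str(clf.classes_[k])] += 1
    selected = max(votes, key=votes.get)

    oob = clf.oob_decision_function_
    valid = ~np.isnan(oob).any(axis=1)
    pred = clf.classes_[np.argmax(oob[valid], axis=1)]
    truth = y[valid]
    correct = (pred == truth).astype(float)
    per_model = {
        str(lab): float(np.mean(pred[truth == lab] != lab))
        for lab in labels
    }
    mean_err = float(np.mean(list(per_model.values())))

    reg = RandomForestRegressor(
        n_estimators=min(n_trees, 500),
        random_state=(
            None if seed is None else (int(seed) + 1) % (2**32)
        ),
        n_jobs=1,
    )
    reg.fit(X[valid], correct)
    post = float(np.clip(reg.predict(obs)[0], 0.0, 1.0))
    return ModelChoiceResult(
        votes=votes,
        selected=selected,
        oob_error=per_model,
        oob_error_mean=mean_err,
        posterior_probability=post,
        n_trees=n_trees,
    )


# ---------------------------------------------------------------------------
# Posterior estimation
# ---------------------------------------------------------------------------

@dataclass
class PosteriorResult:
    draws: pd.DataFrame
    modes: dict[str, float]
    hpd: dict[str, tuple[float, float]]
    tolerance: float
    method: str


def _hpd_interval(x: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``mass`` of the draws."""
    xs = np.sort(x)
    n = xs.size
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(xs[0]), float(xs[-1])
    widths = xs[m - 1 :] - xs[: n - m + 1]
    j = int(np.argmin(widths))
    return float(xs[j]), float(xs[j + m - 1])


def _kde_mode(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return float(x[0])
    kde = gaussian_kde(x)  # Silverman-style default bandwidth
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def estimate_posterior(
    ref_best: ReferenceTable,
    obs: np.ndarray,
    tolerance: float = 0.1,
    method: str = "loclinear",
    seed: int | None = None,
    log_params: bool = True,
    min_draws: int = 50,
) -> PosteriorResult:
    """Rejection + regression-adjusted posterior for one model.

    Retains the nearest ``ceil(tolerance·n)`` rows by Euclidean distance in
    SD-normalized summary space, then adjusts the retained parameter draws
    by regressing parameters on summaries and translating to the observed
    vector (``rejection`` skips the adjustment; ``loclinear`` uses weighted
    local-linear regression with Epanechnikov weights; ``neuralnet`` a
    single-hidden-layer perceptron).  Strictly positive parameters are
    log-transformed before adjustment when ``log_params`` is set.
    """
    if not 0.0 < tolerance <= 1.0:
        raise ValueError("tolerance must lie in (0, 1]")
    if method not in ("rejection", "loclinear", "neuralnet"):
        raise ValueError(f"unknown method {method!r}")
    if np.unique(ref_best.model_labels).size != 1:
        raise ValueError("posterior estimation requires a single model")
    obs = np.asarray(obs, dtype=float).ravel()
    X = ref_best.stats
    n = X.shape[0]
    n_keep = int(np.ceil(tolerance * n))
    if n_keep < min_draws:
        raise ValueError(
            f"tolerance retains only {n_keep} draws (<{min_draws}); "
            "increase n_sims or the tolerance"
        )
    sd = X.std(axis=0, ddof=0)
    informative = sd > 0
    if not informative.any():
        warnings.warn(
            "all summary statistics are degenerate; adjustment is a no-op"
        )
        method = "rejection"
        dist = np.zeros(n)
    else:
        Z = (X[:, informative] - obs[informative]) / sd[informative]
        dist = np.sqrt(np.einsum("ij,ij->i", Z, Z))
    order = np.argsort(dist, kind="stable")[:n_keep]
    kept = ref_best.params.iloc[order].reset_index(drop=True)
    kept_dist = dist[order]

    # drop fixed parameters from the estimation targets
    variable = [
        c for c in kept.columns if np.ptp(kept[c].to_numpy()) > 0
    ]
    theta = kept[variable].to_numpy(dtype=float)
    # transform before regression: logit to the prior bounds when known
    # (keeps adjusted draws inside the prior support), log otherwise
    transforms: dict[str, tuple[str, float, float]] = {}
    bounds = ref_best.param_bounds or {}
    if log_params:
        for j, c in enumerate(variable):
            col = theta[:, j]
            if c in bounds:
                lo, hi = bounds[c]
                z = np.clip((col - lo) / (hi - lo), 1e-8, 1.0 - 1e-8)
                theta[:, j] = np.log(z / (1.0 - z))
                transforms[c] = ("logit", lo, hi)
            elif (col > 0).all():
                theta[:, j] = np.log(col)
                transforms[c] = ("log", 0.0, 0.0)

    if method == "rejection" or not informative.any():
        adjusted = theta
    else:
        delta = np.maximum(kept_dist.max(), 1e-300)
        w = 1.0 - (kept_dist / delta) ** 2
        w = np.maximum(w, 1e-6)
        S = (X[order][:, informative] - obs[informative]) / sd[informative]
        if method == "loclinear":
            # weighted least squares of theta on the (centred) summaries
            A = np.hstack([np.ones((n_keep, 1)), S])
            sw = np.sqrt(w)[:, None]
            coef, *_ = np.linalg.lstsq(A * sw, theta * sw, rcond=None)
            adjusted = theta - S @ coef[1:, :]
        else:
            rng_state = None if seed is None else int(seed) % (2**32)
            adjusted = np.empty_like(theta)
            for j in range(theta.shape[1]):
                mlp = MLPRegressor(
                    hidden_layer_sizes=(10,),
                    max_iter=2000,
                    random_state=rng_state,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mlp.fit(S, theta[:, j])
                m_at_obs = mlp.predict(np.zeros((1, S.shape[1])))[0]
                adjusted[:, j] = m_at_obs + (theta[:, j] - mlp.predict(S))

    draws = pd.DataFrame(adjusted, columns=variable)
    for c, (kind, lo, hi) in transforms.items():
        if kind == "logit":
            z = 1.0 / (1.0 + np.exp(-draws[c].to_numpy()))
            draws[c] = lo + (hi - lo) * z
        else:
            draws[c] = np.exp(draws[c])
    modes = {c: _kde_mode(draws[c].to_numpy()) for c in variable}
    hpd = {c: _hpd_interval(draws[c].to_numpy()) for c in variable}
    return PosteriorResult(
        draws=draws, modes=modes, hpd=hpd, tolerance=tolerance, method=method
    )


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

def goodness_of_fit(
    model_spec: ModelSpec,
    posterior: PosteriorResult,
    obs: np.ndarray,
    n_ppc: int,
    sample_sizes: Sequence[int],
    n_loci: int = 8,
    seed: int | None = None,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Posterior-predictive discrepancy p-values per summary statistic.

    Parameters are resampled jointly from the adjusted posterior draws,
    datasets simulated, and each observed statistic located in its
    posterior-predictive distribution: p = 2·min(P(sim ≥ obs), P(sim ≤ obs))
    with the (hits+1)/(n+1) estimator, capped at 1.
    """
    if n_ppc < 1:
        raise ValueError("n_ppc must be a positive integer")
    if posterior.draws.empty:
        raise ValueError("posterior is empty")
    obs = np.asarray(obs, dtype=float).ravel()
    mode = "pair" if len(sample_sizes) == 2 else "single"
    rng = np.random.default_rng(seed)
    sims = []
    for _ in range(n_ppc):
        row = posterior.draws.iloc[
            int(rng.integers(0, len(posterior.draws)))
        ].to_dict()
        params = {
            k: v.draw(rng) for k, v in model_spec.priors.items()
        }
        params.update({k: float(v) for k, v in row.items()})
        # clamp regression-adjusted draws back into their prior support
        for k, pr in model_spec.priors.items():
            if pr.dist != "fixed":
                params[k] = float(np.clip(params[k], pr.lo, pr.hi))
        model, mut = model_spec.build(params)
        table = simulate_msat_dataset(
            model, mut, n_loci, sample_sizes,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        sims.append(summarize(table, mode))
    sims = np.vstack(sims)
    names = (
        pair_stat_names() if mode == "pair" else list(SINGLE_STAT_NAMES)
    )
    out = {}
    for j, name in enumerate(names):
        ge = (np.sum(sims[:, j] >= obs[j] - 1e-12) + 1) / (n_ppc + 1)
        le = (np.sum(sims[:, j] <= obs[j] + 1e-12) + 1) / (n_ppc + 1)
        out[name] = float(min(1.0, 2.0 * min(ge, le)))
    out["n_flagged"] = int(
        np.sum([out[nm] < alpha for nm in names])
    )
    return out
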