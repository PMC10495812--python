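"""End-to-end orchestration and the conservation-unit decision rule.

The decision rule distinguishes the two unit concepts used in conservation
genetics:

* **Management units (MUs)** — groups of populations with significant
  divergence of nuclear allele frequencies *and* inter-group dispersal below
  10% per generation (per direction).  Two groups qualify as distinct MUs
  iff the nuclear differentiation p-value is below ``alpha`` and
  ``max(m12, m21) < migration_threshold``.
* **Evolutionarily significant units (ESUs)** — additionally require
  organelle lineages that are reciprocally monophyletic *and* spatially
  segregated.  Organelle clades admixed in space — old lineages surviving
  side by side in a single refugium — argue for a single ESU even when the
  nuclear markers split the range.

:func:`run_pipeline` wires the whole analysis: genotype/alignment input (or
synthetic generation), diversity and differentiation statistics, optional
ABC demographic inference, and the unit decision, with a JSON report, TSV
tables and a seed-logging plain-text log.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__ as _pkg_version
from .io_formats import (
    MsatGenotypeTable,
    SeqAlignment,
    apply_grouping,
    read_fasta_alignment,
    read_genepop,
    read_structure,
)
from .popgen_stats import amova, diversity, fst_prime, rst_permutation_test
from .seq_stats import neutrality_tests, phi_st, seq_diversity
from .synthetic_data import SynthSpec, balding_nichols_table, two_clade_cpdna

__all__ = [
    "UnitDecision",
    "PipelineReport",
    "delimit_units",
    "run_pipeline",
    "generations_to_years",
    "migrants_to_rate",
]


def generations_to_years(
    generations: float, generation_years: float = 25.0
) -> float:
    """Convert a time in generations to years (default 25 years per
    generation, the conifer value used throughout the reports)."""
    return generations * generation_years


def migrants_to_rate(nm: float, n: float) -> float:
    """Per-generation migration rate m = Nm / N from a migrant count and
    the recipient effective population size."""
    if n <= 0:
        raise ValueError("effective size must be positive")
    return nm / n


class UnitDecision(BaseModel):
    """Outcome of the conservation-unit rule for a two-group comparison."""

    n_ESU: int = Field(ge=1)
    n_MU: int = Field(ge=1)
    nuclear_divergence_significant: bool
    nuclear_p: float
    migration_below_threshold: bool
    max_migration: float
    plastid_reciprocal_monophyly_spatial: bool | None
    esu_indeterminate: bool
    rationale: list[str]


class PipelineReport(BaseModel):
    """Schema of the JSON report written by :func:`run_pipeline`."""

    package_version: str
    seed: int
    config: dict[str, Any]
    nuclear: dict[str, Any]
    cpdna: dict[str, Any] | None
    abc: dict[str, Any] | None
    units: UnitDecision | None
    failures: list[str]
    log: list[str]


def delimit_units(
    nuclear_p: float,
    migration_rates: Mapping[str, float],
    plastid_segregated: bool | None,
    alpha: float = 0.05,
    migration_threshold: float = 0.10,
) -> UnitDecision:
    """Apply the MU/ESU rule to a two-group comparison.

    Parameters
    ----------
    nuclear_p:
        Permutation p-value of the nuclear between-group differentiation
        (AMOVA F_ST test).
    migration_rates:
        Per-direction dispersal rates per generation, keys ``m12``/``m21``
        (from the package's own demographic inference or an external
        estimate).
    plastid_segregated:
        Whether the organelle clades are reciprocally monophyletic and
        spatially segregated; ``None`` marks the ESU decision indeterminate.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    m_max = float(max(migration_rates.get("m12", 0.0),
                      migration_rates.get("m21", 0.0)))
    sig = bool(nuclear_p < alpha)
    low_m = bool(m_max < migration_threshold)
    rationale = []
    if sig:
        rationale.append(
            f"nuclear differentiation significant (p={nuclear_p:.4g} < "
            f"{alpha})"
        )
    else:
        rationale.append(
            f"nuclear differentiation not significant (p={nuclear_p:.4g})"
        )
    rationale.append(
        f"max inter-group migration {m_max:.4g} "
        + ("<" if low_m else ">=")
        + f" {migration_threshold} per generation"
    )
    n_mu = 2 if (sig and low_m) else 1
    if plastid_segregated is None:
        n_esu = 1
        rationale.append(
            "plastid evidence missing: ESU decision indeterminate, "
            "defaulting to a single ESU"
        )
    elif plastid_segregated and n_mu == 2:
        n_esu = 2
        rationale.append(
            "plastid clades monophyletic and spatially segregated: "
            "distinct ESUs"
        )
    else:
        n_esu = 1
        if not plastid_segregated:
            rationale.append(
                "plastid clades admixed in space: a single ESU"
            )
    return UnitDecision(
        n_ESU=n_esu,
        n_MU=max(n_mu, n_esu),
        nuclear_divergence_significant=sig,
        nuclear_p=float(nuclear_p),
        migration_below_threshold=low_m,
        max_migration=m_max,
        plastid_reciprocal_monophyly_spatial=plastid_segregated,
        esu_indeterminate=plastid_segregated is None,
        rationale=rationale,
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _load_table(cfg: Mapping[str, Any], log: list[str]) -> MsatGenotypeTable:
    inp = cfg["input"]
    if "genepop" in inp:
        table = read_genepop(inp["genepop"])
        log.append(f"read GenePop table from {inp['genepop']}")
    elif "structure" in inp:
        table = read_structure(inp["structure"])
        log.append(f"read STRUCTURE table from {inp['structure']}")
    elif "synthetic" in inp:
        spec = SynthSpec(**inp["synthetic"])
        table = balding_nichols_table(spec)
        log.append(f"generated synthetic table (seed={spec.seed})")
    else:
        raise ValueError(
            "config input must name 'genepop', 'structure' or 'synthetic'"
        )
    if "grouping" in inp:
        table = apply_grouping(table, inp["grouping"])
        log.append(f"applied grouping sidecar {inp['grouping']}")
    if table.group_labels is None:
        raise ValueError(
            "no grouping available: supply input.grouping or a synthetic "
            "spec with groups"
        )
    return table


def _load_cpdna(cfg, rng, log) -> SeqAlignment | None:
    inp = cfg["input"]
    if "cpdna_fasta" in inp:
        aln = read_fasta_alignment(inp["cpdna_fasta"])
        clades = inp.get("cpdna_clades")
        if clades:
            aln.clade_labels = np.array(
                [clades[i] for i in aln.sequence_ids], dtype=object
            )
        log.append(f"read cpDNA alignment from {inp['cpdna_fasta']}")
        return aln
    if "cpdna_synthetic" in inp:
        aln = two_clade_cpdna(**inp["cpdna_synthetic"])
        log.append("generated synthetic two-clade cpDNA alignment")
        return aln
    return None


def run_pipeline(
    config: Mapping[str, Any] | str | Path,
    output_dir: str | Path | None = None,
) -> PipelineReport:
    """Run statistics → (optional) ABC → unit delimitation from a config.

    ``config`` is a mapping or a YAML path; see the package README for the
    schema.  When ``output_dir`` (or ``config['output_dir']``) is set, the
    JSON report, per-statistic TSV tables and a plain-text log (seeds and
    versions) are written there.  Identical config + seed give a
    byte-identical JSON report.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    cfg = dict(config)
    if "input" not in cfg:
        raise ValueError("config must contain an 'input' section")
    seed = int(cfg.get("seed", 0))
    n_perm = int(cfg.get("stats", {}).get("n_perm", 999))
    alpha = float(cfg.get("delimitation", {}).get("alpha", 0.05))
    mig_threshold = float(
        cfg.get("delimitation", {}).get("migration_threshold", 0.10)
    )
    phi_threshold = float(
        cfg.get("delimitation", {}).get("plastid_phi_threshold", 0.2)
    )
    rng = np.random.default_rng(seed)
    log: list[str] = [f"consgen {_pkg_version} on {platform.python_version()}",
                      f"master seed: {seed}"]
    failures: list[str] = []
    nuclear: dict[str, Any] = {}
    cpdna_report: dict[str, Any] | None = None
    abc_report: dict[str, Any] | None = None
    units: UnitDecision | None = None
    tables_out: dict[str, pd.DataFrame] = {}

    table = _load_table(cfg, log)

    # --- nuclear statistics ------------------------------------------------
    try:
        div = diversity(table, by="group")
        tables_out["diversity"] = div.per_locus.reset_index()
        nuclear["diversity_means"] = {
            str(k): {c: float(v) for c, v in row.items()}
            for k, row in div.means.iterrows()
        }
        s1 = int(rng.integers(0, 2**31 - 1))
        log.append(f"AMOVA seed: {s1}")
        am = amova(table, strata="group", n_perm=n_perm, seed=s1)
        nuclear["amova"] = {
            "percent": am.percent,
            "indices": am.indices,
            "p_values": am.p_values,
            "n_permutations": am.n_permutations,
        }
        fp = fst_prime(table, grouping="group", seed=s1)
        nuclear["fst"] = fp.fst
        nuclear["fst_prime"] = fp.fst_prime
        s2 = int(rng.integers(0, 2**31 - 1))
        log.append(f"RST permutation seed: {s2}")
        rst = rst_permutation_test(
            table.to_repeat_scale(), grouping="group",
            n_perm=min(n_perm, 10_000), seed=s2,
        )
        nuclear["rst"] = {
            "RST": rst.rst,
            "pRST": rst.p_rst,
            "p_value": rst.p_value,
        }
        nuclear_p = am.p_values["FST"]
    except Exception as exc:  # partial report with failure record
        failures.append(f"nuclear statistics failed: {exc}")
        nuclear_p = None

    # --- cpDNA -------------------------------------------------------------
    aln = _load_cpdna(cfg, rng, log)
    plastid_segregated: bool | None = None
    if aln is not None:
        try:
            rep = seq_diversity(aln)
            neut = neutrality_tests(aln)
            cpdna_report = {
                "diversity": asdict(rep),
                "neutrality": asdict(neut),
            }
            if aln.clade_labels is not None:
                s3 = int(rng.integers(0, 2**31 - 1))
                log.append(f"phiST permutation seed: {s3}")
                # spatial segregation: do the clades coincide with space?
                spatial = cfg["input"].get("spatial_labels")
                if spatial is not None:
                    labels = np.array(
                        [spatial[i] for i in aln.sequence_ids], dtype=object
                    )
                else:
                    # sequence order stands in for sampling location:
                    # first half vs second half of the transect
                    n = aln.n_sequences
                    labels = np.array(
                        ["site1"] * (n // 2) + ["site2"] * (n - n // 2),
                        dtype=object,
                    )
                ph_clade = phi_st(
                    aln, aln.clade_labels, n_perm=n_perm, seed=s3
                )
                ph_space = phi_st(aln, labels, n_perm=n_perm, seed=s3 + 1)
                cpdna_report["phi_st_by_clade"] = {
                    "phi_st": ph_clade.phi_st,
                    "phi_st_prime": ph_clade.phi_st_prime,
                    "p_value": ph_clade.p_value,
                }
                cpdna_report["phi_st_by_space"] = {
                    "phi_st": ph_space.phi_st,
                    "phi_st_prime": ph_space.phi_st_prime,
                    "p_value": ph_space.p_value,
                }
                plastid_segregated = bool(
                    ph_space.phi_st > phi_threshold
                    and ph_space.p_value < alpha
                )
                cpdna_report["spatially_segregated"] = plastid_segregated
        except Exception as exc:
            failures.append(f"cpDNA statistics failed: {exc}")

    # --- demographic inference / migration ---------------------------------
    migration = dict(cfg.get("migration", {}))
    abc_cfg = cfg.get("abc", {})
    if abc_cfg.get("enabled", False):
        try:
            from .abc_inference import (
                build_reference_table,
                dvm_spec,
                estimate_posterior,
                rf_model_choice,
                summarize,
            )

            groups = table.groups()
            sizes = [
                int(np.sum(table.group_labels.astype(str) == g))
                for g in groups
            ]
            obs = summarize(table, mode="pair")
            n1 = float(abc_cfg.get("n_cur1", 1000.0))
            n2 = float(abc_cfg.get("n_cur2", 500.0))
            specs = [
                dvm_spec(n1, n2, flow="2to1", name="DVM_2to1"),
                dvm_spec(n1, n2, flow="1to2", name="DVM_1to2"),
                dvm_spec(n1, n2, flow="both", name="DVM_both"),
            ]
            s4 = int(rng.integers(0, 2**31 - 1))
            log.append(f"ABC reference-table seed: {s4}")
            ref = build_reference_table(
                specs,
                int(abc_cfg.get("n_sims", 3000)),
                sizes,
                n_loci=table.n_loci,
                seed=s4,
            )
            mc = rf_model_choice(
                ref, obs, n_trees=int(abc_cfg.get("n_trees", 500)),
                seed=s4 + 1,
            )
            best = ref.subset_model(mc.selected)
            post = estimate_posterior(
                best, obs,
                tolerance=float(abc_cfg.get("tolerance", 0.2)),
                method=str(abc_cfg.get("method", "loclinear")),
                seed=s4 + 2,
            )
            gen_years = float(cfg.get("generation_years", 25.0))
            abc_report = {
                "selected_model": mc.selected,
                "votes": mc.votes,
                "oob_error_mean": mc.oob_error_mean,
                "posterior_probability": mc.posterior_probability,
                "posterior": {
                    p: {
                        "mode": post.modes[p],
                        "hpd95": list(post.hpd[p]),
                    }
                    for p in post.modes
                },
            }
            if "T" in post.modes:
                abc_report["divergence_years_mode"] = (
                    post.modes["T"] * gen_years
                )
            if "m" in post.modes:
                m_hat = post.modes["m"]
                flow = mc.selected.split("_")[-1]
                migration.setdefault(
                    "m12", m_hat if flow in ("1to2", "both") else 0.0
                )
                migration.setdefault(
                    "m21", m_hat if flow in ("2to1", "both") else 0.0
                )
            tables_out["abc_posterior"] = pd.DataFrame(
                {
                    "parameter": list(post.modes),
                    "mode": [post.modes[p] for p in post.modes],
                    "hpd_lower": [post.hpd[p][0] for p in post.modes],
                    "hpd_upper": [post.hpd[p][1] for p in post.modes],
                }
            )
        except Exception as exc:
            failures.append(f"ABC stage failed: {exc}")

    # --- delimitation -------------------------------------------------------
    if nuclear_p is not None and migration:
        units = delimit_units(
            nuclear_p,
            migration,
            plastid_segregated,
            alpha=alpha,
            migration_threshold=mig_threshold,
        )
    elif nuclear_p is not None:
        failures.append(
            "no migration estimate available (supply config.migration or "
            "enable the ABC stage); unit delimitation skipped"
        )

    report = PipelineReport(
        package_version=_pkg_version,
        seed=seed,
        config=_jsonable(cfg),
        nuclear=_jsonable(nuclear),
        cpdna=_jsonable(cpdna_report),
        abc=_jsonable(abc_report),
        units=units,
        failures=failures,
        log=log,
    )

    out_dir = output_dir or cfg.get("output_dir")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report.model_dump(), indent=2, sort_keys=True)
            + "\n"
        )
        for name, df in tables_out.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        (out / "run.log").write_text("\n".join(log) + "\n")
    return report


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays for JSON serialization."""
    if obj is None:
        return None
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
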