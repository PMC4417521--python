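"""End-to-end study runs: paired-arm simulation and report tables.

A scenario run synthesizes one household population, assigns risk factors,
resolves service eligibility once, and then draws uptake for the control
and intervention arms on that same population (paired arms, independent
uptake streams).  The resulting score summaries feed the sample-size
formulas for each clustering assumption, producing one row per cluster
spec of a report table shaped like the published sample-size table; a full
study additionally writes the eligibility-by-type table and a manifest of
seeds, hashes and warnings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from ._version import __version__ as _pkg_version
from .crci import (
    SampleSummary,
    compute_crci_all,
    eligibility_by_household_type,
    summarize_sample,
    weighted_eligibility_totals,
)
from .demographics import (
    DemographicSpec,
    load_demographic_spec,
    population_to_frame,
    sample_households,
)
from .samplesize import ClusterSpec, SampleSizeInputs, SampleSizeResult, clustered_sample_size
from .scenario import ScenarioConfig, assign_risk_factors, clamping_deficit, simulate_uptake
from .services import ServiceDefinition, eligibility_table, load_registry

__all__ = ["StudyRunConfig", "ScenarioRunResult", "run_scenario", "run_full_study"]

logger = logging.getLogger("crcisim")


@dataclass(frozen=True)
class StudyRunConfig:
    """Configuration of a full study run (grids of scenarios and clusterings)."""

    spec_path: str = "default"
    registry_path: str = "default"
    scenario_grid: tuple[tuple[float, str, str], ...] = (
        (0.1, "none", "none"),
        (0.2, "none", "none"),
        (0.3, "none", "none"),
    )
    cluster_grid: tuple[tuple[int, float], ...] = (
        (100, 0.0),
        (100, 0.01),
        (100, 0.02),
        (100, 0.05),
    )
    n_households: int = 20_000
    seed: int = 0
    output_dir: str = "study_output"

    def __post_init__(self) -> None:
        if not self.scenario_grid or not self.cluster_grid:
            raise ValueError("scenario and cluster grids must be non-empty")
        if self.n_households < 1:
            raise ValueError("n_households must be >= 1")


@dataclass
class ScenarioRunResult:
    """Everything one scenario run produced."""

    config: ScenarioConfig
    control_summary: SampleSummary
    intervention_summary: SampleSummary
    sample_sizes: list[tuple[ClusterSpec, SampleSizeResult]]
    crci_control: pd.DataFrame
    crci_intervention: pd.DataFrame
    population_hash: str
    warnings: list[str] = field(default_factory=list)


def _population_hash(households) -> str:
    frame = population_to_frame(households)
    payload = frame.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()


def run_scenario(
    config: ScenarioConfig,
    spec: DemographicSpec | None = None,
    registry: list[ServiceDefinition] | None = None,
    cluster_specs: list[ClusterSpec] | None = None,
) -> ScenarioRunResult:
    """Simulate control and intervention arms on one shared population and
    derive sample sizes for each clustering assumption.

    The valid-CRCI fraction used to inflate sample sizes is the control
    arm's (eligibility is identical in both arms by construction).
    """
    spec = spec if spec is not None else load_demographic_spec()
    registry = registry if registry is not None else load_registry()
    cluster_specs = cluster_specs if cluster_specs is not None else [ClusterSpec(100, 0.01)]

    logger.info("sampling %d households (seed %d)", config.n_households, config.seed)
    households = sample_households(spec, config.n_households, config.seed)
    households = assign_risk_factors(
        households, spec, mode=config.risk_clustering, seed=config.seed
    )
    elig = eligibility_table(households, registry, config.period_years, seed=config.seed)
    logger.info("eligibility records: %d", len(elig))

    control_cfg = ScenarioConfig(
        intervention_effect=0.0,
        risk_clustering=config.risk_clustering,
        compliance_clustering=config.compliance_clustering,
        compliant_household_share=config.compliant_household_share,
        n_households=config.n_households,
        seed=config.seed,
        period_years=config.period_years,
    )
    out_c = simulate_uptake(households, elig, registry, control_cfg, arm="control")
    if config.intervention_effect == 0:
        out_i = out_c  # a null intervention is the control arm
    else:
        out_i = simulate_uptake(households, elig, registry, config, arm="intervention")

    crci_c = compute_crci_all(households, out_c)
    crci_i = compute_crci_all(households, out_i)
    summary_c = summarize_sample(crci_c)
    summary_i = summarize_sample(crci_i)

    warnings: list[str] = []
    if config.compliance_clustering == "high":
        deficits = {
            s.name: clamping_deficit(s.baseline_uptake)
            for s in registry
            if s.included_in_crci
        }
        worst = max(deficits.values())
        if worst > 0:
            warnings.append(f"compliance clamping deficit up to {worst:.4f}")

    sample_sizes: list[tuple[ClusterSpec, SampleSizeResult]] = []
    if summary_i.mean != summary_c.mean:
        inputs = SampleSizeInputs(
            mean_control=summary_c.mean,
            mean_intervention=summary_i.mean,
            sd_control=summary_c.sd,
            sd_intervention=summary_i.sd,
            valid_fraction=summary_c.valid_fraction,
        )
        for cs in cluster_specs:
            sample_sizes.append((cs, clustered_sample_size(inputs, cs)))
    else:
        warnings.append("zero mean difference between arms; sample size undefined")

    return ScenarioRunResult(
        config=config,
        control_summary=summary_c,
        intervention_summary=summary_i,
        sample_sizes=sample_sizes,
        crci_control=crci_c,
        crci_intervention=crci_i,
        population_hash=_population_hash(households),
        warnings=warnings,
    )


def _scenario_row(result: ScenarioRunResult) -> dict[str, Any]:
    cfg = result.config
    row: dict[str, Any] = {
        "risk_clustering": cfg.risk_clustering,
        "compliance_clustering": cfg.compliance_clustering,
        "effect_pct": round(100 * cfg.intervention_effect),
        "mean_control": round(result.control_summary.mean, 2),
        "sd_control": round(result.control_summary.sd, 2),
        "mean_intervention": round(result.intervention_summary.mean, 2),
        "sd_intervention": round(result.intervention_summary.sd, 2),
        "valid_fraction_pct": round(100 * result.control_summary.valid_fraction, 1),
    }
    for cs, res in result.sample_sizes:
        label = f"n_m{cs.m}_icc{cs.icc:g}"
        row[label] = res.n_reported
    return row


def run_full_study(config: StudyRunConfig) -> dict[str, Any]:
    """Run the whole scenario grid and write the report bundle.

    Writes ``eligibility_by_type.csv`` (per-type eligibility distribution
    with weighted totals), ``sample_sizes.csv`` (one row per scenario,
    clustered sizes in columns), and ``manifest.json`` (seed, config, file
    hashes, warnings).  Returns the tables and manifest in memory as well.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable") from exc

    spec = load_demographic_spec(
        None if config.spec_path == "default" else config.spec_path
    )
    registry = load_registry(
        None if config.registry_path == "default" else config.registry_path
    )
    cluster_specs = [ClusterSpec(m, icc) for m, icc in config.cluster_grid]

    rows = []
    eligibility_table_df: pd.DataFrame | None = None
    totals = None
    warnings: list[str] = []
    population_hashes: set[str] = set()
    for e, risk_mode, comp_mode in config.scenario_grid:
        sc = ScenarioConfig(
            intervention_effect=e,
            risk_clustering=risk_mode,
            compliance_clustering=comp_mode,
            n_households=config.n_households,
            seed=config.seed,
        )
        result = run_scenario(sc, spec, registry, cluster_specs)
        rows.append(_scenario_row(result))
        warnings.extend(result.warnings)
        population_hashes.add(result.population_hash)
        if eligibility_table_df is None and risk_mode == "none":
            by_type = eligibility_by_household_type(result.crci_control)
            totals = weighted_eligibility_totals(by_type)
            total_row = {"household_type": "TOTAL (weighted)", "prevalence_pct": 100.0}
            total_row.update(totals.to_dict())
            eligibility_table_df = pd.concat(
                [by_type, pd.DataFrame([total_row])], ignore_index=True
            )

    sizes_df = pd.DataFrame(rows)
    sizes_path = outdir / "sample_sizes.csv"
    sizes_df.to_csv(sizes_path, index=False)
    paths = {"sample_sizes": str(sizes_path)}
    if eligibility_table_df is not None:
        elig_path = outdir / "eligibility_by_type.csv"
        eligibility_table_df.round(2).to_csv(elig_path, index=False)
        paths["eligibility_by_type"] = str(elig_path)

    manifest = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "n_households": config.n_households,
        "spec_path": config.spec_path,
        "registry_path": config.registry_path,
        "scenario_grid": [list(s) for s in config.scenario_grid],
        "cluster_grid": [list(c) for c in config.cluster_grid],
        "population_hashes": sorted(population_hashes),
        "warnings": warnings,
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "seed": config.seed,
                    "n": config.n_households,
                    "grid": [list(s) for s in config.scenario_grid],
                    "clusters": [list(c) for c in config.cluster_grid],
                },
                sort_keys=True,
            ).encode()
        ).hexdigest(),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    paths["manifest"] = str(manifest_path)

    return {
        "sample_sizes": sizes_df,
        "eligibility_by_type": eligibility_table_df,
        "weighted_totals": totals,
        "manifest": manifest,
        "paths": paths,
    }
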