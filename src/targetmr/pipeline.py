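"""Config-driven orchestration of the full analysis.

A run reproduces the study workflow end to end: instrument selection for
the drug-target exposure, harmonization against the outcome, the
five-estimator battery with sensitivity diagnostics, an optional
positive-control outcome, and the two-step mediation screen.  Inputs are
either summary-statistic files or a fully specified synthetic scenario;
every random draw flows from the single config seed, so reruns are
byte-identical.  Each stage's in/out SNP counts are logged and written
to a JSON run manifest alongside the result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimators import all_methods, ivw, wald_ratio
from .harmonize import harmonize, retained, write_pairs
from .instruments import (
    PRESETS,
    GeneLocus,
    InstrumentCriteria,
    read_blocklist,
    select_instruments,
)
from .io import SummaryStatSet, read_summary_table, write_summary_table
from .mediation import screen_mediators
from .sensitivity import diagnostics_table
from .simulate import (
    BlockLDProvider,
    CausalScenario,
    simulate_exposure_stats,
    simulate_mediation_panel,
    simulate_outcome_stats,
)

log = logging.getLogger("targetmr")


class PipelineError(RuntimeError):
    """A stage failed in a way the run cannot recover from."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from YAML via :func:`load_config`."""

    seed: int = 0
    outdir: str = "targetmr_results"
    preset: str = "drug-target"
    scenario: dict = field(default_factory=dict)       # synthetic exposure/outcome
    exposure_file: str | None = None
    exposure_dialect: dict | None = None
    outcome_file: str | None = None
    outcome_dialect: dict | None = None
    control: dict | None = None                        # positive-control scenario/file
    mediator_panel: dict = field(default_factory=dict) # n_mediators, true_index
    locus: dict | None = None                          # gene_id, chromosome, start, end
    blocklist_file: str | None = None
    criteria: dict = field(default_factory=dict)       # overrides on the preset
    estimator: dict = field(default_factory=dict)      # n_boot, phi, presso_n_sim
    maf_ambiguous_max: float = 0.42

    def resolve_criteria(self) -> InstrumentCriteria:
        base = PRESETS[self.preset]
        if not self.criteria:
            return base
        return InstrumentCriteria(**{**asdict(base), **self.criteria})

    def resolve_scenario(self, overrides: dict | None = None) -> CausalScenario:
        params = dict(self.scenario)
        params.update(overrides or {})
        params.setdefault("seed", self.seed)
        if "maf_range" in params:
            params["maf_range"] = tuple(params["maf_range"])
        if params.get("ld_blocks"):
            params["ld_blocks"] = tuple(tuple(b) for b in params["ld_blocks"])
        return CausalScenario(**params)


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**data)


def _synthetic_locus(scenario: CausalScenario) -> GeneLocus:
    # the generator places cis instruments from 5 Mb upward at 10 kb spacing
    return GeneLocus(
        gene_id="target",
        chromosome="1",
        start=5_000_000,
        end=5_000_000 + (scenario.n_snps - 1) * 10_000,
    )


def _load_role(config: PipelineConfig, role: str, overrides=None):
    """Materialize exposure+outcome sets from files or the scenario."""
    if config.exposure_file and config.outcome_file and role == "primary":
        exposure, _ = read_summary_table(config.exposure_file, config.exposure_dialect)
        outcome, _ = read_summary_table(config.outcome_file, config.outcome_dialect)
        locus = GeneLocus(**config.locus) if config.locus else None
        return exposure, outcome, locus, None
    scenario = config.resolve_scenario(overrides)
    exposure, truth = simulate_exposure_stats(scenario)
    outcome = simulate_outcome_stats(scenario, truth)
    ld = BlockLDProvider(truth, scenario.ld_blocks) if scenario.ld_blocks else None
    return exposure, outcome, _synthetic_locus(scenario), ld


def run_uvmr(config: PipelineConfig, outcome_label: str = "outcome",
             scenario_overrides: dict | None = None) -> dict:
    """Instrument selection -> harmonization -> estimators -> diagnostics.

    Returns a dict with the results/diagnostics tables and stage counts;
    writes them (plus a manifest) under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    criteria = config.resolve_criteria()
    exposure, outcome, locus, ld = _load_role(config, "primary", scenario_overrides)
    blocklist = (
        read_blocklist(config.blocklist_file) if config.blocklist_file else ()
    )

    instruments, counts = select_instruments(
        exposure, criteria, ld=ld, locus=locus,
        blocklist=blocklist, outcome=outcome,
    )
    for stage, n in counts.items():
        log.info("%s: %s -> %d SNPs", outcome_label, stage, n)
    if len(instruments) == 0:
        stage = min((k for k, v in counts.items() if v == 0),
                    key=list(counts).index, default="selection")
        raise PipelineError(stage, "zero surviving instruments")

    pairs, report = harmonize(exposure=instruments, outcome=outcome,
                              maf_ambiguous_max=config.maf_ambiguous_max)
    analysable = retained(pairs)
    counts["harmonized"] = len(analysable)
    if len(analysable) == 0:
        raise PipelineError("harmonize", "zero analysable pairs")

    est_cfg = config.estimator
    results = all_methods(
        analysable,
        n_boot=est_cfg.get("n_boot", 1000),
        phi=est_cfg.get("phi", 1.0),
        seed=config.seed,
    )
    diagnostics = (
        diagnostics_table(
            analysable, n_sim=est_cfg.get("presso_n_sim", 1000), seed=config.seed
        )
        if len(analysable) >= 4
        else pd.DataFrame()
    )

    prefix = outdir / outcome_label
    write_summary_table(instruments, f"{prefix}_instruments.tsv")
    write_pairs(pairs, f"{prefix}_harmonized.tsv")
    results.to_csv(f"{prefix}_mr_results.tsv", sep="\t", index=False)
    if not diagnostics.empty:
        diagnostics.to_csv(f"{prefix}_diagnostics.tsv", sep="\t", index=False)
    _write_manifest(config, counts, prefix)
    return {
        "results": results,
        "diagnostics": diagnostics,
        "pairs": pairs,
        "instruments": instruments,
        "counts": counts,
        "harmonize_report": report,
    }


def run_positive_control(config: PipelineConfig) -> dict | None:
    """UVMR against the positive-control outcome, if one is configured.

    Prints a direction + significance judgment for the primary (IVW)
    estimate; returns None (with a log notice) when no control is set.
    """
    if not config.control:
        log.info("no positive-control outcome configured; skipping")
        return None
    out = run_uvmr(config, outcome_label="positive_control",
                   scenario_overrides=config.control)
    ivw_row = out["results"].iloc[0]
    direction = "protective" if ivw_row["beta"] < 0 else "risk-increasing"
    significant = ivw_row["pvalue"] < 0.05
    out["judgment"] = (
        f"positive control: {direction}, "
        f"{'significant' if significant else 'not significant'} "
        f"(OR {ivw_row['OR']:.3f}, p {ivw_row['pvalue']:.3g})"
    )
    log.info(out["judgment"])
    return out


def run_mediation(config: PipelineConfig) -> dict:
    """Two-step mediation screen over the mediator panel."""
    panel_cfg = config.mediator_panel
    if not panel_cfg:
        raise PipelineError("mediation", "no mediator panel configured")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    scenario = config.resolve_scenario()
    exp_set, mediators, out_set, truth = simulate_mediation_panel(
        scenario,
        n_mediators=panel_cfg.get("n_mediators", 10),
        true_index=panel_cfg.get("true_index", 0),
    )
    criteria = config.resolve_criteria()
    instruments, counts = select_instruments(
        exp_set, criteria, locus=_synthetic_locus(scenario), outcome=out_set
    )
    if len(instruments) == 0:
        raise PipelineError("selection", "zero surviving exposure instruments")
    pairs3, _ = harmonize(instruments, out_set, config.maf_ambiguous_max)
    analysable = retained(pairs3)
    total = ivw(analysable) if len(analysable) >= 2 else wald_ratio(analysable)

    table = screen_mediators(
        instruments, mediators, out_set, total_effect=total,
        maf_ambiguous_max=config.maf_ambiguous_max,
    )
    table.to_csv(outdir / "mediation_table.tsv", sep="\t", index=False)
    hits = table[table["hit"]]
    lines = [
        f"total effect beta3 = {total.beta:.3f} "
        f"(OR {total.or_:.3f}, p {total.pvalue:.3g})",
        f"{len(hits)} reportable mediator(s) of {len(table)} screened",
    ]
    for row in hits.itertuples(index=False):
        lines.append(
            f"  {row.mediator}: proportion mediated "
            f"{row.proportion_pct:.1f}% ({row.ci_low:.1f} to {row.ci_high:.1f})"
        )
    report = "\n".join(lines)
    (outdir / "mediation_report.txt").write_text(report + "\n")
    log.info("%s", report)
    _write_manifest(config, counts, outdir / "mediation")
    return {"table": table, "total_effect": total, "report": report,
            "truth": truth, "counts": counts}


def _write_manifest(config: PipelineConfig, counts: dict, prefix) -> None:
    cfg = asdict(config)
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = {"config_sha256": digest, "seed": config.seed,
                "stage_counts": counts, "config": cfg}
    Path(f"{prefix}_manifest.json").write_text(json.dumps(manifest, indent=2,
                                                          default=str))
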