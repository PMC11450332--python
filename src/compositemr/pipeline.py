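"""End-to-end orchestration: simulate/read -> QC -> derive variables ->
composite SNPs -> IV screening -> MR per stratum -> descriptives/report.

A run is fully determined by its :class:`RunConfig` and seed. The single
seed is expanded into per-stage substreams with
``numpy.random.SeedSequence([seed, stage_index])`` (stage 0: simulation,
stage 1: bootstrap), so stages rerun standalone reproduce the monolithic
run exactly.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortTable, derive_variables, read_phenotypes, write_phenotypes
from .composite import build_composites, composites_to_matrix, write_composite_plink
from .ivselect import audit_table, select_ivs
from .mr import MROptions, MRResultSet, run_mr_stratified
from .plink import GenotypeMatrix, read_plink, write_plink
from .qc import QCReport, QCThresholds, qc_filter
from .simulate import SimulationConfig, simulate_cohort
from .survival import descriptive_table, kaplan_meier

REPORT_FILES = [
    "config.yaml", "qc_report.json", "exclusions.tsv", "composites.tsv",
    "iv_audit.tsv", "iv_stats.tsv", "mr_results.tsv", "mr_results.json",
    "km_curves.tsv", "descriptive_table.tsv",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def stage_seed(seed: int, stage_index: int) -> int:
    """Deterministic per-stage substream seed below 2^31."""
    return int(np.random.SeedSequence([seed, stage_index]).generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; exactly one of ``simulate`` or
    ``input_prefix`` must be set."""

    seed: int = 0
    output_dir: str = "run"
    simulate: SimulationConfig | None = None
    input_prefix: str | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    pairing_scope: str = "all_pairs"
    include_single_snps: bool = False
    mode: str = "candidate_gene"
    alpha: float = 0.05
    f_min: float = 10.0
    r2_max: float = 0.3
    related: bool = False
    bonferroni: bool = False
    n_boot: int = 1000
    penalty_factor: float = 20.0
    evalue_conversion: str = "common_outcome_sqrt"
    strata: list[str] = field(default_factory=list)
    schema_version: int = 1

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_prefix is None):
            raise ValueError("exactly one of 'simulate' or 'input_prefix' must be given")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 < self.r2_max <= 1.0):
            raise ValueError("r2_max must be in (0, 1]")
        if self.f_min < 0:
            raise ValueError("f_min must be >= 0")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("schema_version", 1) != 1:
            raise ValueError(f"unsupported config schema_version {raw.get('schema_version')}")
        sim = raw.pop("simulate", None)
        qc = raw.pop("qc", None)
        return cls(
            simulate=SimulationConfig(**sim) if sim is not None else None,
            qc=QCThresholds(**qc) if qc else QCThresholds(),
            **{k: v for k, v in raw.items()},
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            sim = d["simulate"]
            for k, v in list(sim.items()):
                if isinstance(v, tuple):
                    sim[k] = list(v)
        return d


def load_inputs(config: RunConfig) -> tuple[GenotypeMatrix, CohortTable]:
    if config.simulate is not None:
        cfg = dataclasses.replace(config.simulate, seed=stage_seed(config.seed, 0))
        return simulate_cohort(cfg)
    g = read_plink(config.input_prefix)
    cohort = read_phenotypes(config.input_prefix)
    return g, cohort


def mr_options(config: RunConfig) -> MROptions:
    return MROptions(alpha=config.alpha, n_boot=config.n_boot,
                     penalty_factor=config.penalty_factor,
                     evalue_conversion=config.evalue_conversion,
                     seed=stage_seed(config.seed, 1))


def mr_results_frame(results: dict[str, MRResultSet], n_by_stratum: dict[str, int]) -> pd.DataFrame:
    """Flatten stratified MR results into a Table-2-style frame."""
    rows = []
    for label, rs in results.items():
        row: dict = {"stratum": label, "n_indiv": n_by_stratum.get(label, np.nan),
                     "n_ivs": rs.n_ivs}
        for key in ("ivw", "penalized_ivw", "weighted_median", "egger_slope"):
            r = rs.results.get(key)
            row[f"{key}_estimate"] = r.estimate if r else np.nan
            row[f"{key}_ci_low"] = r.ci95[0] if r else np.nan
            row[f"{key}_ci_high"] = r.ci95[1] if r else np.nan
            row[f"{key}_p"] = r.p if r else np.nan
        r = rs.egger_intercept
        row["egger_intercept"] = r.estimate if r else np.nan
        row["egger_intercept_ci_low"] = r.ci95[0] if r else np.nan
        row["egger_intercept_ci_high"] = r.ci95[1] if r else np.nan
        ev = rs.evalue_summary
        row["evalue_avg"], row["evalue_min"], row["evalue_max"] = ev if ev else (np.nan,) * 3
        row["verdict"] = rs.verdict
        row["messages"] = "; ".join(rs.messages)
        rows.append(row)
    return pd.DataFrame(rows)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the artifact dict and writes the
    run directory. Raises :class:`StageError` naming the failing stage."""
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    art: dict = {"config": config}

    try:
        g, cohort = load_inputs(config)
    except Exception as exc:
        raise StageError("input", str(exc)) from exc

    g, qc_report = qc_filter(g, config.qc)
    art["qc_report"] = qc_report
    if g.n_variants == 0:
        raise StageError("qc", "no variant survived QC")

    try:
        cohort = derive_variables(cohort)
    except ValueError as exc:
        raise StageError("derive_variables", str(exc)) from exc
    art["cohort"] = cohort

    composites = build_composites(g, config.pairing_scope)
    if not composites and not config.include_single_snps:
        raise StageError("composite", "no composite SNP could be formed")
    candidates = composites_to_matrix(composites, g.fam) if composites else None
    if config.include_single_snps:
        if candidates is None:
            candidates = g
        else:
            candidates = GenotypeMatrix(
                np.hstack([g.dosages, candidates.dosages]),
                pd.concat([g.variants, candidates.variants], ignore_index=True),
                g.fam,
            )
    art["g"], art["composites"], art["candidates"] = g, composites, candidates

    records, confounders = select_ivs(
        candidates, cohort, mode=config.mode, alpha=config.alpha,
        f_min=config.f_min, r2_max=config.r2_max, related=config.related,
        bonferroni=config.bonferroni,
    )
    art["iv_records"], art["confounders"] = records, confounders
    qualified_ids = [r.variant_id for r in records if r.qualified]
    if not qualified_ids:
        write_report(out, art, complete=False)
        raise StageError("mr", "no qualified IVs; MR refuses to run")
    keep = candidates.variants["id"].isin(qualified_ids).to_numpy()
    qualified = candidates.subset(variants=keep)
    art["qualified"] = qualified

    art["mr"] = run_mr_stratified(qualified, cohort, config.strata, mr_options(config))

    art["descriptives"] = descriptive_table(cohort)
    art["km"] = kaplan_meier(cohort)
    write_report(out, art, complete=True)
    return art


def write_report(out: str, art: dict, complete: bool) -> None:
    """Write the run directory: config echo, QC report, audit trails, MR
    results (TSV + JSON), KM curves, descriptives and a Markdown summary."""
    os.makedirs(out, exist_ok=True)
    config: RunConfig = art["config"]
    with open(os.path.join(out, "config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    if "qc_report" in art:
        with open(os.path.join(out, "qc_report.json"), "w") as fh:
            json.dump(dataclasses.asdict(art["qc_report"]), fh, indent=2)
    cohort: CohortTable | None = art.get("cohort")
    if cohort is not None and cohort.derived:
        cohort.data.loc[cohort.data["excluded"], ["iid", "exclusion_reason"]].to_csv(
            os.path.join(out, "exclusions.tsv"), sep="\t", index=False)
    if art.get("composites") is not None:
        pd.DataFrame({
            "id": [c.id for c in art["composites"]],
            "constituent_a": [c.constituents[0] for c in art["composites"]],
            "constituent_b": [c.constituents[1] for c in art["composites"]],
            "gene_a": [c.genes[0] for c in art["composites"]],
            "gene_b": [c.genes[1] for c in art["composites"]],
        }).to_csv(os.path.join(out, "composites.tsv"), sep="\t", index=False)
    if "iv_records" in art:
        audit_table(art["iv_records"]).to_csv(os.path.join(out, "iv_audit.tsv"), sep="\t", index=False)
    if "mr" in art:
        mr: dict[str, MRResultSet] = art["mr"]
        n_by = {"all": len(cohort.retained)}
        for label in mr:
            if label != "all":
                crit = dict(part.split("=") for part in label.split("/"))
                m = np.ones(len(cohort.retained), dtype=bool)
                for c, v in crit.items():
                    m &= cohort.retained[c].astype(str) == v
                n_by[label] = int(m.sum())
        frame = mr_results_frame(mr, n_by)
        frame.to_csv(os.path.join(out, "mr_results.tsv"), sep="\t", index=False)
        frame.to_json(os.path.join(out, "mr_results.json"), orient="records", indent=2)
        pd.concat([rs.stats.assign(stratum=label) for label, rs in mr.items() if len(rs.stats)],
                  ignore_index=True).to_csv(os.path.join(out, "iv_stats.tsv"), sep="\t", index=False)
    if "km" in art:
        pd.concat([c.table.assign(group=name) for name, c in art["km"].items()],
                  ignore_index=True).to_csv(os.path.join(out, "km_curves.tsv"), sep="\t", index=False)
    if "descriptives" in art:
        art["descriptives"].to_csv(os.path.join(out, "descriptive_table.tsv"), sep="\t", index=False)
    build_report(out, complete_hint=complete)


def build_report(run_dir: str, complete_hint: bool | None = None) -> dict:
    """Assemble manifest + human-readable summary for a run directory.

    Scans for the expected stage outputs; a missing file marks the run
    incomplete in ``manifest.json``.
    """
    present = {f: os.path.exists(os.path.join(run_dir, f)) for f in REPORT_FILES}
    complete = all(present.values()) and (complete_hint is not False)
    manifest = {"version": __version__, "complete": complete, "files": present}
    with open(os.path.join(run_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)

    lines = ["# Run summary", ""]
    lines.append(f"Status: {'complete' if complete else 'INCOMPLETE'}")
    mr_path = os.path.join(run_dir, "mr_results.tsv")
    if os.path.exists(mr_path):
        frame = pd.read_csv(mr_path, sep="\t")
        lines.append("")
        lines.append("## MR results")
        lines.append("")
        lines.append(frame.to_string(index=False))
    audit_path = os.path.join(run_dir, "iv_audit.tsv")
    if os.path.exists(audit_path):
        audit = pd.read_csv(audit_path, sep="\t")
        counts = audit["stage"].value_counts().to_dict()
        lines.append("")
        lines.append("## IV screening")
        lines.append("")
        lines.append(f"candidates: {len(audit)}; by stage: {counts}")
    with open(os.path.join(run_dir, "summary.md"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return manifest


# --------------------------------------------------- standalone stage files

def stage_write_inputs(config: RunConfig, prefix: str) -> None:
    g, cohort = load_inputs(config)
    write_plink(g, prefix)
    write_phenotypes(cohort, prefix)
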