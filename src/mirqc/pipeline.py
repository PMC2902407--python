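"""End-to-end analysis orchestration: config in, report bundle out.

``run`` executes the full analysis in a fixed order — ingest or simulate,
optional pre-filter, stratification and duplicate agreement, well
failures, concordance, abundance-shift tests and migration tables,
clustering and PCA — writing every module's CSV outputs plus a manifest,
a run log and a plain-text summary into the output directory.  Any stage
failure aborts with the stage name; outputs already written are kept.

All randomness flows through the single seed in the config.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance import (
    stratified_pairwise_correlations,
    summarize_ct,
)
from .errors import MirqcError, PipelineError, ValidationError
from .failures import summarize_duplicate_failures
from .io import (
    SampleCondition,
    prefilter_all_censored,
    read_ct_table,
    read_metadata_table,
    write_ct_table,
    write_metadata_table,
)
from .shift import compare_methods_shift, migration_from_groups
from .simulate import (
    SimConfig,
    simulate_clinical_study,
    simulate_concentration_series,
    simulate_dilution_series,
)
from .strata import (
    StratumCutoffs,
    assign_strata,
    duplicate_agreement,
    fit_smoothing_spline,
    stratum_counts,
)
from .structure import correlation_distance, hierarchical_cluster, pca

__all__ = ["RunConfig", "run"]

_DESIGNS = {
    "clinical": simulate_clinical_study,
    "concentration": simulate_concentration_series,
    "dilution": simulate_dilution_series,
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs; defaults match the analysis choices
    documented in docs/methods.md (30/35 cutoffs, per-sample-average
    counts, censored wells excluded from correlations, complete linkage).
    """

    ct_table: str | None = None
    metadata: str | None = None
    dialect: str = "long"
    simulate: dict[str, Any] | None = None  # {"design": ..., **SimConfig overrides}
    out_dir: str = "mirqc_out"
    seed: int = 0
    prefilter: bool = True
    cutoff_high: float = 30.0
    cutoff_low: float = 35.0
    aggregation: str = "per_sample_average"
    censor_policy: str = "exclude_any_40"
    include_censored: bool = True
    linkage: str = "complete"
    run_concordance: bool = True
    run_failures: bool = True
    run_shift: bool = True
    run_structure: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValidationError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    @property
    def cutoffs(self) -> StratumCutoffs:
        return StratumCutoffs(self.cutoff_high, self.cutoff_low)


def _duplicate_pairs(conditions: Sequence[SampleCondition]):
    """Group conditions identical up to replicate_index."""
    groups: dict[tuple, list[SampleCondition]] = {}
    for c in conditions:
        key = (
            c.subject_id, c.tissue_source, c.extraction_method,
            c.disease_state, c.input_rna_conc, c.cdna_dilution,
        )
        groups.setdefault(key, []).append(c)
    pairs = []
    for g in groups.values():
        g = sorted(g, key=lambda c: c.replicate_index)
        pairs.extend(zip(g, g[1:]))
    return pairs


def run(config: RunConfig) -> dict[str, Any]:
    """Execute the pipeline; returns a manifest of written outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"outputs": [], "skipped": []}

    def emit(name: str, text_or_df) -> None:
        path = out / name
        if isinstance(text_or_df, pd.DataFrame):
            text_or_df.to_csv(path)
        else:
            path.write_text(str(text_or_df))
        manifest["outputs"].append(name)

    report_lines: list[str] = [f"mirqc {__version__} run, seed={config.seed}", ""]

    def stage(name: str):
        class _Stage:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, exc) from exc
                return False

        return _Stage()

    # -- ingest / simulate --------------------------------------------------
    with stage("ingest"):
        if config.simulate is not None:
            sim = dict(config.simulate)
            design = sim.pop("design", "clinical")
            if design not in _DESIGNS:
                raise ValidationError(f"unknown simulate design {design!r}")
            sim_cfg = SimConfig(**sim).with_(seed=config.seed)
            matrix, truth = _DESIGNS[design](sim_cfg)
            emit("ct_long.csv", write_ct_table(matrix, dialect="long"))
            emit("metadata.csv", write_metadata_table(matrix.conditions))
            emit(
                "sim_truth_assays.csv",
                pd.DataFrame(
                    {
                        "baseline_ct": truth.baseline,
                        "ffpe_shift": truth.ffpe_shift,
                        "de_effect": truth.de_effect,
                    }
                ),
            )
        elif config.ct_table is not None:
            matrix = read_ct_table(Path(config.ct_table), config.dialect)
            if config.metadata is not None:
                matrix = matrix.attach_metadata(
                    read_metadata_table(Path(config.metadata))
                )
        else:
            raise ValidationError("config needs either ct_table or simulate")
        report_lines.append(
            f"ingested {len(matrix.mir_ids)} microRNA assays x "
            f"{len(matrix.conditions)} conditions"
        )

    # -- pre-filter ---------------------------------------------------------
    with stage("prefilter"):
        if config.prefilter:
            before = len(matrix.mir_ids)
            matrix = prefilter_all_censored(matrix)
            removed = before - len(matrix.mir_ids)
            report_lines.append(
                f"pre-filter removed {removed} all-censored microRNAs "
                f"({len(matrix.mir_ids)} retained)"
            )

    cutoffs = config.cutoffs
    conds = matrix.conditions

    # -- stratification + agreement -----------------------------------------
    with stage("stratify"):
        vals = matrix.mir_values()
        cen = matrix.mir_censored()
        long = vals.stack(future_stack=True).rename("ct").reset_index()
        long.columns = ["assay_id", "condition_id", "ct"]
        long["censored"] = cen.stack(future_stack=True).to_numpy()
        long = long.dropna(subset=["ct"])
        long["stratum"] = assign_strata(long["ct"].to_numpy(), cutoffs).to_numpy()
        emit("stratum_map.csv", long.set_index("assay_id"))
        counts = stratum_counts(
            matrix,
            {c.condition_id: [c.condition_id] for c in conds},
            cutoffs=cutoffs,
            aggregation="per_sample_average",
            include_censored=config.include_censored,
        )
        emit("stratum_counts_per_condition.csv", counts)

    pairs = _duplicate_pairs(conds)
    with stage("agreement"):
        if pairs:
            frames = []
            for a, b in pairs:
                res = duplicate_agreement(matrix, a.condition_id, b.condition_id)
                pts = res.points.copy()
                pts.insert(0, "pair", f"{a.condition_id}|{b.condition_id}")
                frames.append(pts)
            allpts = pd.concat(frames, ignore_index=True)
            try:
                fit = fit_smoothing_spline(allpts)
                allpts["fitted"] = fit.predict(allpts["mean_ct"].to_numpy())
            except MirqcError as e:
                manifest["skipped"].append(f"spline: {e}")
            emit("duplicate_agreement.csv", allpts.set_index("pair"))
        else:
            manifest["skipped"].append("agreement: no duplicate pairs in design")

    # -- failures -----------------------------------------------------------
    with stage("failures"):
        if config.run_failures and pairs:
            rows = []
            for a, b in pairs:
                refs = [
                    c.condition_id
                    for c in conds
                    if c.subject_id == a.subject_id
                    and c.condition_id not in (a.condition_id, b.condition_id)
                ]
                summ, _rep = summarize_duplicate_failures(
                    matrix, a.condition_id, b.condition_id, refs
                )
                rows.append(
                    {
                        "pair": f"{a.condition_id}|{b.condition_id}",
                        "n_failures_plate_a": summ.n_failures_plate_a,
                        "n_failures_plate_b": summ.n_failures_plate_b,
                        "average_failures": summ.average_failures,
                        "n_expressed": summ.n_expressed,
                        "percent_failures": summ.percent_failures,
                    }
                )
            emit("failure_summary.csv", pd.DataFrame(rows).set_index("pair"))
        elif config.run_failures:
            manifest["skipped"].append("failures: no duplicate pairs in design")

    # -- concordance --------------------------------------------------------
    with stage("concordance"):
        if config.run_concordance and len(conds) >= 2:
            sc = stratified_pairwise_correlations(
                matrix,
                matrix.condition_ids,
                cutoffs=cutoffs,
                censor_policy=config.censor_policy,  # type: ignore[arg-type]
            )
            emit("stratified_correlations.csv", sc.table.set_index("condition_a"))
            groups = {}
            for c in conds:
                groups.setdefault(c.tissue_source, []).append(c.condition_id)
            emit(
                "ct_summary.csv",
                summarize_ct(matrix, groups, config.include_censored).set_index(
                    "group"
                ),
            )

    # -- shift --------------------------------------------------------------
    with stage("shift"):
        if config.run_shift:
            by_tissue: dict[str, list[str]] = {}
            for c in conds:
                by_tissue.setdefault(c.tissue_source, []).append(c.condition_id)
            chi_rows = []
            if "FFPE" in by_tissue and "frozen" in by_tissue:
                table, chi = compare_methods_shift(
                    matrix,
                    by_tissue["frozen"],
                    by_tissue["FFPE"],
                    cutoffs=cutoffs,
                    aggregation=config.aggregation,  # type: ignore[arg-type]
                    labels=("frozen", "FFPE"),
                    include_censored=config.include_censored,
                )
                emit("stratum_counts_frozen_vs_ffpe.csv", table)
                chi_rows.append(
                    ("frozen_vs_FFPE", chi.statistic, chi.df, chi.p)
                )
                emit(
                    "migration_ffpe_vs_frozen.csv",
                    migration_from_groups(
                        matrix, by_tissue["FFPE"], by_tissue["frozen"],
                        cutoffs=cutoffs, labels=("FFPE", "frozen"),
                    ),
                )
            concs = sorted({c.input_rna_conc for c in conds})
            if len(concs) >= 2:
                lo, hi = concs[0], concs[-1]
                ga = [c.condition_id for c in conds if c.input_rna_conc == lo]
                gb = [c.condition_id for c in conds if c.input_rna_conc == hi]
                table, chi = compare_methods_shift(
                    matrix, ga, gb, cutoffs=cutoffs,
                    aggregation=config.aggregation,  # type: ignore[arg-type]
                    labels=(f"{lo:g}ng", f"{hi:g}ng"),
                    include_censored=config.include_censored,
                )
                emit("stratum_counts_concentration.csv", table)
                chi_rows.append(
                    (f"{lo:g}ng_vs_{hi:g}ng", chi.statistic, chi.df, chi.p)
                )
            if chi_rows:
                emit(
                    "chi_square.csv",
                    pd.DataFrame(
                        chi_rows, columns=["comparison", "statistic", "df", "p"]
                    ).set_index("comparison"),
                )
            else:
                manifest["skipped"].append("shift: no contrasting groups in design")

    # -- structure ----------------------------------------------------------
    with stage("structure"):
        if config.run_structure and len(conds) >= 3:
            dist = correlation_distance(
                matrix, include_censored=config.include_censored, cutoffs=cutoffs
            )
            emit("correlation_distance.csv", dist)
            dendro = hierarchical_cluster(dist, config.linkage)  # type: ignore[arg-type]
            emit("dendrogram.newick", dendro.to_newick() + "\n")
            emit(
                "cluster_labels.csv",
                dendro.cut(2).rename("cluster").to_frame(),
            )
            n_comp = min(3, len(conds) - 1)
            p = pca(
                matrix, n_components=n_comp,
                include_censored=config.include_censored, cutoffs=cutoffs,
            )
            scores = p.scores.copy()
            emit("pca_scores.csv", scores)
            report_lines.append(
                "PCA variance explained: "
                + ", ".join(f"{v:.1%}" for v in p.variance_ratio)
            )
        elif config.run_structure:
            manifest["skipped"].append("structure: fewer than 3 conditions")

    # -- report -------------------------------------------------------------
    with stage("report"):
        manifest["seed"] = config.seed
        manifest["version"] = __version__
        emit("report.txt", "\n".join(report_lines) + "\n")
        log = {
            "mirqc_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
        emit("run_log.json", json.dumps(log, indent=2) + "\n")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return manifest
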