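"""End-to-end orchestration: read -> select transcript -> featurize ->
filter -> fit -> select -> VIF / partial correlations / RCVE -> report.

One run analyses one species' 5'UTR set (a FASTA file or a synthetic
specification).  Every stage logs its row counts so filtering diagnostics
(e.g. what fraction of UTRs carried zero trinucleotide OE ratios) are
visible on any dataset, and the resolved configuration is echoed verbatim
into the JSON summary so a run can be reproduced from the summary alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import filtering
from .features import PREDICTORS, features_frame, uorfs_to_bed
from .io import HeaderRule, read_utr_fasta, select_one_transcript_per_gene
from .regression import (
    backward_select,
    fit_ols,
    partial_correlation,
    rcve,
    vif,
)
from .simulate import SyntheticSpec, generate_dataset

logger = logging.getLogger(__name__)

STAGES = ("read", "select", "featurize", "filter", "fit")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved options for one pipeline run (defaults = reference choices).

    Exactly one of ``fasta`` / ``synthetic`` must be set.  ``windows``
    selects the expected-count convention (``"L"`` or ``"L-k+1"``);
    ``filter_mode`` is ``"zero_oe"`` (drop rows with >1 zero trinucleotide
    OE), ``"length_threshold"`` (drop L < min_length) or ``"none"``;
    ``partial_set`` controls whether partial correlations condition on the
    backward-selected predictor set or on all candidates.
    """

    fasta: str | None = None
    synthetic: SyntheticSpec | None = None
    header_delimiter: str = "|"
    gene_field: int = 0
    transcript_field: int = 1
    alpha: float = 0.05
    filter_mode: str = "zero_oe"
    min_length: int = 30
    windows: str = "L"
    rcve_r2: str = "unadjusted"
    partial_set: str = "selected"
    include_uorf: bool = False
    fit_model: bool = True
    write_bed: bool = False
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if (self.fasta is None) == (self.synthetic is None):
            raise ValueError("exactly one of fasta/synthetic must be given")
        if self.filter_mode not in ("zero_oe", "length_threshold", "none"):
            raise ValueError(f"unknown filter_mode {self.filter_mode!r}")
        if self.windows not in ("L", "L-k+1"):
            raise ValueError(f"unknown windows convention {self.windows!r}")
        if self.rcve_r2 not in ("unadjusted", "adjusted"):
            raise ValueError(f"unknown rcve_r2 {self.rcve_r2!r}")
        if self.partial_set not in ("selected", "all"):
            raise ValueError(f"unknown partial_set {self.partial_set!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            syn = dict(d["synthetic"])
            syn["motif_modifiers"] = {
                m: tuple(v) if isinstance(v, (list, tuple)) else v
                for m, v in (syn.get("motif_modifiers") or {}).items()
            }
            if isinstance(syn.get("transcripts_per_gene"), list):
                syn["transcripts_per_gene"] = tuple(syn["transcripts_per_gene"])
            d["synthetic"] = SyntheticSpec(**syn)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _fmt_cell(value: float | None) -> str:
    return "ns" if value is None else f"{value:.6g}"


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; return (and optionally write) the run summary."""
    timings: dict[str, float] = {}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        timings[name] = time.perf_counter()

    def _done(name):
        timings[name] = round(time.perf_counter() - timings[name], 4)

    summary: dict[str, Any] = {"config": RunConfig.to_dict(config)}

    # --- read ---------------------------------------------------------
    _stage("read")
    try:
        if config.fasta is not None:
            rule = HeaderRule(
                config.header_delimiter, config.gene_field, config.transcript_field
            )
            records, drop_io = read_utr_fasta(config.fasta, rule)
            truth = None
        else:
            records, truth = generate_dataset(config.synthetic)
            drop_io = pd.DataFrame(
                columns=["gene_id", "transcript_id", "reason"]
            )
    except (OSError, ValueError) as exc:
        raise PipelineError("read", str(exc)) from exc
    _done("read")
    n_input = len(records) + len(drop_io)
    summary["n_input"] = n_input
    summary["n_dropped_io"] = int(len(drop_io))

    # --- select one transcript per gene -------------------------------
    _stage("select")
    selected = select_one_transcript_per_gene(records, config.seed)
    _done("select")
    summary["n_genes"] = len(selected)
    summary["n_dropped_transcript"] = len(records) - len(selected)

    # --- featurize ----------------------------------------------------
    _stage("featurize")
    feats, drop_short = features_frame(selected, windows=config.windows)
    if feats.empty:
        raise PipelineError("featurize", "no featurizable records")
    _done("featurize")
    summary["n_dropped_short"] = int(len(drop_short))
    summary["n_featurized"] = int(len(feats))
    zero_counts = filtering.zero_tri_oe_counts(feats)
    summary["frac_with_any_zero_tri_oe"] = float((zero_counts > 0).mean())

    # --- filter -------------------------------------------------------
    _stage("filter")
    try:
        if config.filter_mode == "zero_oe":
            table = filtering.apply_zero_oe_filter(feats)
        elif config.filter_mode == "length_threshold":
            table = filtering.apply_length_threshold_filter(
                feats, config.min_length
            )
        else:
            table = feats.copy()
            table.attrs["filter"] = {
                "rule": "none",
                "n_in": int(len(feats)),
                "n_retained": int(len(feats)),
                "n_removed": 0,
            }
    except ValueError as exc:
        raise PipelineError("filter", str(exc)) from exc
    _done("filter")
    summary["n_removed_filter"] = int(len(feats) - len(table))
    summary["n_retained"] = int(len(table))
    summary["length_report"] = filtering.length_distribution_report(table)

    # --- fit ----------------------------------------------------------
    candidates = list(PREDICTORS) + (
        ["uorf_present"] if config.include_uorf else []
    )
    fit_feasible = (
        config.fit_model and len(table) > len(candidates) + 2
    )
    summary["fit_performed"] = bool(fit_feasible)
    table1 = table2 = vif_df = rcve_series = None
    if fit_feasible:
        _stage("fit")
        try:
            # drop candidates without variation in the filtered table
            usable = [c for c in candidates if table[c].nunique() > 1]
            vif_df = vif(table, usable) if len(usable) >= 2 else None
            result, trace = backward_select(
                table, usable, alpha=config.alpha
            )
            full = fit_ols(table, usable)
            rcve_series = rcve(
                table,
                usable,
                use_adjusted=(config.rcve_r2 == "adjusted"),
            )
            partial_base = (
                trace.final_predictors
                if config.partial_set == "selected"
                else usable
            )
            partials: dict[str, float | None] = {}
            for name in usable:
                if name not in partial_base:
                    partials[name] = None
                    continue
                others = [p for p in partial_base if p != name]
                partials[name] = partial_correlation(table, name, others)
        except ValueError as exc:
            raise PipelineError("fit", str(exc)) from exc
        _done("fit")

        coef = result.coef
        table1 = pd.DataFrame(
            {
                "coefficient": [
                    _fmt_cell(coef[p] if p in trace.final_predictors else None)
                    for p in usable
                ]
            },
            index=pd.Index(usable, name="predictor"),
        )
        table2 = pd.DataFrame(
            {"partial_correlation": [_fmt_cell(partials[p]) for p in usable]},
            index=pd.Index(usable, name="predictor"),
        )
        summary["candidates"] = usable
        summary["selected_predictors"] = trace.final_predictors
        summary["selection_steps"] = [
            {"removed": s.removed, "p_value": s.p_value, "r2_after": s.r2_after}
            for s in trace.steps
        ]
        summary["r2"] = result.r2
        summary["adjusted_r2"] = result.adjusted_r2
        summary["full_model_r2"] = full.r2
        summary["coefficients"] = {
            p: float(coef[p]) for p in ["intercept"] + trace.final_predictors
        }
        summary["rcve"] = {k: float(v) for k, v in rcve_series.items()}
        summary["partial_correlations"] = partials
        summary["vif"] = (
            {k: float(v) for k, v in vif_df["vif"].items()} if vif_df is not None else {}
        )
        summary["vif_flagged"] = (
            [k for k, f in vif_df["flagged"].items() if f] if vif_df is not None else []
        )
    else:
        logger.info(
            "model fit skipped (fit_model=%s, n_retained=%d, candidates=%d)",
            config.fit_model, len(table), len(candidates),
        )

    summary["seed"] = config.seed
    summary["timings"] = timings

    # --- outputs ------------------------------------------------------
    if outdir:
        feats.to_csv(outdir / "features.tsv", sep="\t", index=False)
        table.to_csv(outdir / "features_filtered.tsv", sep="\t", index=False)
        drops = pd.concat([drop_io, drop_short], ignore_index=True)
        drops.to_csv(outdir / "drop_report.tsv", sep="\t", index=False)
        filtering.filter_report(table).to_csv(
            outdir / "filter_report.tsv", sep="\t", index=False
        )
        if truth is not None:
            truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
        if table1 is not None:
            table1.to_csv(outdir / "coefficients.tsv", sep="\t")
            table2.to_csv(outdir / "partial_correlations.tsv", sep="\t")
            vif_df.to_csv(outdir / "vif.tsv", sep="\t")
            rcve_series.rename_axis("predictor").to_frame().to_csv(
                outdir / "rcve.tsv", sep="\t"
            )
        if config.write_bed:
            uorfs_to_bed(selected, outdir / "uorfs.bed")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=_json_default)

    return summary


def run_batch(configs: Sequence[RunConfig]) -> pd.DataFrame:
    """Run several species and concatenate coefficient reports column-wise.

    Each config must have a distinct label (its FASTA stem or the synthetic
    seed).  The returned frame has one row per candidate predictor plus an
    ``adjusted_r2`` footer row and one column per species, with ``ns`` for
    eliminated predictors — the shape used for multi-species comparisons.
    """
    columns: dict[str, pd.Series] = {}
    for config in configs:
        summary = run_pipeline(config)
        if config.fasta is not None:
            label = Path(config.fasta).stem
        else:
            label = f"synthetic_{config.synthetic.seed}"
        if label in columns:
            label = f"{label}_{len(columns)}"
        coefs = summary.get("coefficients", {})
        cells = {
            p: (f"{coefs[p]:.6g}" if p in coefs else "ns")
            for p in summary.get("candidates", [])
        }
        cells["adjusted_r2"] = f"{summary.get('adjusted_r2', float('nan')):.6g}"
        columns[label] = pd.Series(cells)
    return pd.DataFrame(columns)


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
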