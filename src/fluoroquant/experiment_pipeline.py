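"""End-to-end orchestration: batch image analysis, per-plant time series,
group mean +/- SE aggregation, ANOVA/SNK on period means, SPAD correlation,
health classification, and report/figure output."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .errors import ConfigurationError, InsufficientDataError, ReconciliationError
from .imaging_core import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_EPS,
    DEFAULT_HEALTH_THRESHOLD,
    FvFmMap,
    FvFmSummary,
    ImagePair,
    RawImage,
    compute_fvfm_map,
    render_pseudocolor,
    segment_plant,
    summarize_fvfm,
)
from .stats_suite import (
    AnovaResult,
    CorrelationResult,
    GroupSample,
    SnkResult,
    mean_se,
    one_way_anova,
    pearson,
    snk_test,
)

__all__ = [
    "AnalysisParams",
    "BatchResult",
    "PeriodComparison",
    "ExperimentReport",
    "analyze_pair",
    "analyze_pairs",
    "run_batch",
    "aggregate_by_group_day",
    "compare_period_means",
    "correlate_with_spad",
    "build_report",
    "write_report",
    "run_synthetic_experiment",
]

RECORD_COLUMNS = [
    "plant_id",
    "group",
    "day",
    "fvfm_mode",
    "fvfm_mean",
    "n_valid",
    "clipped_fraction",
    "health",
    "spad",
]


@dataclass(frozen=True)
class AnalysisParams:
    """Settings for the per-image analysis chain."""

    segment_method: str = "otsu"        # segmentation runs on the Fm frame
    threshold: Optional[float] = None   # used when segment_method == "fixed"
    eps: float = DEFAULT_EPS
    bin_width: float = DEFAULT_BIN_WIDTH
    health_threshold: float = DEFAULT_HEALTH_THRESHOLD
    colormap: str = "jet"


def analyze_pair(
    pair: ImagePair, params: AnalysisParams = AnalysisParams()
) -> tuple[FvFmMap, FvFmSummary]:
    """Segment (on Fm), map, and summarize one image pair."""
    mask = segment_plant(pair.fm, method=params.segment_method, threshold=params.threshold)
    fvfm = compute_fvfm_map(pair, mask, eps=params.eps)
    summary = summarize_fvfm(
        fvfm, bin_width=params.bin_width, health_threshold=params.health_threshold
    )
    return fvfm, summary


def _record(pair: ImagePair, summary: FvFmSummary, spad: float = float("nan")) -> dict:
    return {
        "plant_id": pair.plant_id,
        "group": pair.group,
        "day": pair.day,
        "fvfm_mode": summary.mode,
        "fvfm_mean": summary.mean,
        "n_valid": summary.n_valid,
        "clipped_fraction": summary.clipped_fraction,
        "health": summary.health,
        "spad": spad,
    }


def analyze_pairs(
    pairs: Iterable[ImagePair],
    params: AnalysisParams = AnalysisParams(),
    spad_by_key: Optional[dict[tuple[str, int], float]] = None,
) -> pd.DataFrame:
    """One PlantRecord row per image pair; SPAD looked up by (plant_id, day)."""
    rows = []
    for pair in pairs:
        _, summary = analyze_pair(pair, params)
        spad = float("nan")
        if spad_by_key is not None:
            spad = spad_by_key.get((pair.plant_id, pair.day), float("nan"))
        rows.append(_record(pair, summary, spad))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


@dataclass(frozen=True)
class BatchResult:
    records: pd.DataFrame
    skipped: tuple[dict, ...]  # metadata rows whose image files were missing

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def _load_raw(path: Path, channel: str) -> RawImage:
    px = tifffile.imread(path)
    bit_depth = 8 if px.dtype == np.uint8 else 16
    return RawImage(px, bit_depth=bit_depth, channel=channel)


def run_batch(
    input_dir: Union[str, Path],
    params: AnalysisParams = AnalysisParams(),
    metadata_name: str = "metadata.csv",
) -> BatchResult:
    """Analyze every plant-day listed in the metadata table.

    Metadata schema: plant_id, group, day, fo_path, fm_path, spad (optional);
    image paths are relative to ``input_dir``. Rows with missing image files
    are skipped and counted; unresolvable group labels abort with a
    reconciliation error listing the offenders.
    """
    input_dir = Path(input_dir)
    meta_path = input_dir / metadata_name
    if not meta_path.exists():
        raise ReconciliationError(f"metadata table not found: {meta_path}")
    meta = pd.read_csv(meta_path)
    required = {"plant_id", "group", "day", "fo_path", "fm_path"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ReconciliationError(f"metadata missing columns: {sorted(missing_cols)}")
    bad = meta[meta["group"].isna() | meta["plant_id"].isna()]
    if len(bad):
        raise ReconciliationError(
            f"{len(bad)} metadata rows lack plant_id/group: "
            f"rows {bad.index.tolist()[:10]}"
        )

    rows, skipped = [], []
    for rec in meta.to_dict("records"):
        fo_path = input_dir / rec["fo_path"]
        fm_path = input_dir / rec["fm_path"]
        if not fo_path.exists() or not fm_path.exists():
            skipped.append(rec)
            continue
        pair = ImagePair(
            fo=_load_raw(fo_path, "Fo"),
            fm=_load_raw(fm_path, "Fm"),
            plant_id=str(rec["plant_id"]),
            group=str(rec["group"]),
            day=int(rec["day"]),
        )
        _, summary = analyze_pair(pair, params)
        rows.append(_record(pair, summary, float(rec.get("spad", float("nan")))))
    return BatchResult(
        records=pd.DataFrame(rows, columns=RECORD_COLUMNS), skipped=tuple(skipped)
    )


def aggregate_by_group_day(
    records: pd.DataFrame, value_col: str = "fvfm_mode"
) -> pd.DataFrame:
    """Mean +/- SE of the per-plant scalar for every (group, day) cell.

    Cells with fewer than two plants get se = NaN and flagged = True.
    """
    if records.empty:
        raise InsufficientDataError("no records to aggregate")
    rows = []
    for (group, day), sub in records.groupby(["group", "day"], sort=True):
        vals = sub[value_col].to_numpy(dtype=float)
        if vals.size >= 2:
            mean, se = mean_se(vals)
            flagged = False
        else:
            mean, se, flagged = float(vals.mean()), float("nan"), True
        rows.append(
            {"group": group, "day": day, "mean": mean, "se": se, "n": int(vals.size),
             "flagged": flagged}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PeriodComparison:
    """ANOVA + SNK on per-plant period-average Fv/Fm."""

    anova: AnovaResult
    snk: SnkResult
    group_means: dict[str, float]
    value_col: str
    per_day: Optional[dict[int, SnkResult]] = None

    def to_dict(self) -> dict:
        return {
            "value_col": self.value_col,
            "anova": self.anova.to_dict(),
            "snk": self.snk.to_dict(),
            "group_means": dict(self.group_means),
            "per_day": (
                {str(d): s.to_dict() for d, s in self.per_day.items()}
                if self.per_day is not None
                else None
            ),
        }


def _group_samples(records: pd.DataFrame, value_col: str) -> list[GroupSample]:
    per_plant = (
        records.groupby(["group", "plant_id"], sort=True)[value_col].mean().reset_index()
    )
    return [
        GroupSample(label=group, values=sub[value_col].to_numpy(dtype=float))
        for group, sub in per_plant.groupby("group", sort=True)
    ]


def compare_period_means(
    records: pd.DataFrame,
    alpha: float = 0.05,
    value_col: str = "fvfm_mode",
    per_day: bool = False,
) -> PeriodComparison:
    """Average each plant over the observation period, then ANOVA + SNK
    across groups. ``per_day=True`` additionally runs SNK day by day."""
    samples = _group_samples(records, value_col)
    anova = one_way_anova(samples)
    snk = snk_test(samples, alpha=alpha)
    per_day_results = None
    if per_day:
        per_day_results = {}
        for day, sub in records.groupby("day", sort=True):
            day_samples = [
                GroupSample(label=g, values=s[value_col].to_numpy(dtype=float))
                for g, s in sub.groupby("group", sort=True)
            ]
            per_day_results[int(day)] = snk_test(day_samples, alpha=alpha)
    return PeriodComparison(
        anova=anova,
        snk=snk,
        group_means={s.label: s.mean for s in samples},
        value_col=value_col,
        per_day=per_day_results,
    )


def correlate_with_spad(
    records: pd.DataFrame,
    pairing: str = "per-record",
    value_col: str = "fvfm_mode",
) -> CorrelationResult:
    """Pearson r between the Fv/Fm scalar and SPAD.

    pairing: "per-record" (every plant-day), "per-plant" (period means), or
    "per-group-day-mean" (cell means).
    """
    if "spad" not in records.columns or records["spad"].isna().all():
        raise ConfigurationError("records carry no SPAD readings")
    sub = records.dropna(subset=["spad", value_col])
    if pairing == "per-record":
        x, y = sub[value_col], sub["spad"]
    elif pairing == "per-plant":
        per_plant = sub.groupby("plant_id", sort=True)[[value_col, "spad"]].mean()
        x, y = per_plant[value_col], per_plant["spad"]
    elif pairing == "per-group-day-mean":
        per_cell = sub.groupby(["group", "day"], sort=True)[[value_col, "spad"]].mean()
        x, y = per_cell[value_col], per_cell["spad"]
    else:
        raise ConfigurationError(f"unknown pairing {pairing!r}")
    return pearson(x.to_numpy(dtype=float), y.to_numpy(dtype=float))


@dataclass(frozen=True)
class ExperimentReport:
    records: pd.DataFrame
    summaries: pd.DataFrame
    period: Optional[PeriodComparison]  # None when only one group is present
    correlation: Optional[CorrelationResult]
    health_counts: dict[str, dict[str, int]]
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "provenance": dict(self.provenance),
            "period": self.period.to_dict() if self.period else None,
            "correlation": self.correlation.to_dict() if self.correlation else None,
            "health_counts": {g: dict(c) for g, c in self.health_counts.items()},
            "group_day_summaries": self.summaries.to_dict(orient="records"),
        }


def _config_hash(config_dict: Optional[dict]) -> Optional[str]:
    if config_dict is None:
        return None
    blob = yaml.safe_dump(config_dict, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def build_report(
    records: pd.DataFrame,
    alpha: float = 0.05,
    value_col: str = "fvfm_mode",
    spad_pairing: str = "per-record",
    config_dict: Optional[dict] = None,
    seed: Optional[int] = None,
) -> ExperimentReport:
    summaries = aggregate_by_group_day(records, value_col=value_col)
    if records["group"].nunique() >= 2:
        period = compare_period_means(records, alpha=alpha, value_col=value_col)
    else:
        period = None
    try:
        correlation = correlate_with_spad(records, pairing=spad_pairing, value_col=value_col)
    except ConfigurationError:
        correlation = None
    health_counts = {
        group: sub["health"].value_counts().to_dict()
        for group, sub in records.groupby("group", sort=True)
    }
    provenance = {
        "software_version": __version__,
        "config_hash": _config_hash(config_dict),
        "seed": seed,
        "n_records": int(len(records)),
        "alpha": alpha,
        "value_col": value_col,
        "spad_pairing": spad_pairing,
    }
    return ExperimentReport(
        records=records,
        summaries=summaries,
        period=period,
        correlation=correlation,
        health_counts=health_counts,
        provenance=provenance,
    )


def _plot_timeseries(summaries: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for group, sub in summaries.groupby("group", sort=True):
        sub = sub.sort_values("day")
        ax.errorbar(sub["day"], sub["mean"], yerr=sub["se"], marker="o", capsize=3,
                    label=group)
    ax.set_xlabel("observation day")
    ax.set_ylabel("Fv/Fm")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_period_means(period: PeriodComparison, path: Path) -> None:
    labels = list(period.snk.labels)
    means = list(period.snk.ordered_means)
    letters = [period.snk.letters[lab] for lab in labels]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    bars = ax.bar(labels, means, color="tab:green")
    for bar, letter in zip(bars, letters):
        ax.text(bar.get_x() + bar.get_width() / 2, bar.get_height(), letter,
                ha="center", va="bottom")
    ax.set_ylabel("period-mean Fv/Fm")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_scatter(records: pd.DataFrame, value_col: str, path: Path) -> None:
    sub = records.dropna(subset=["spad", value_col])
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    ax.scatter(sub["spad"], sub[value_col], s=8, alpha=0.6)
    ax.set_xlabel("SPAD value")
    ax.set_ylabel("Fv/Fm")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(report: ExperimentReport, out_dir: Union[str, Path]) -> Path:
    """Write records.csv, group_day_summary.csv, report.json, and figures."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    report.records.to_csv(out / "records.csv", index=False, float_format="%.10g")
    report.summaries.to_csv(out / "group_day_summary.csv", index=False, float_format="%.10g")
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    _plot_timeseries(report.summaries, out / "timeseries.png")
    if report.period is not None:
        _plot_period_means(report.period, out / "period_means.png")
    if report.correlation is not None:
        _plot_scatter(report.records, report.provenance["value_col"], out / "spad_scatter.png")
    return out


def run_synthetic_experiment(
    config,
    params: AnalysisParams = AnalysisParams(),
    alpha: float = 0.05,
    value_col: str = "fvfm_mode",
):
    """Generate a synthetic experiment and stream it through the analyzer.

    Returns ``(records, report, bundle)``; images are produced lazily so the
    full default experiment fits in memory.
    """
    from .synth_data import config_to_dict, gen_experiment

    bundle = gen_experiment(config)
    spad_by_key = {
        (row.plant_id, int(row.day)): float(row.spad)
        for row in bundle.truth.itertuples()
    }
    records = analyze_pairs(bundle.iter_image_pairs(), params, spad_by_key)
    report = build_report(
        records,
        alpha=alpha,
        value_col=value_col,
        config_dict=config_to_dict(config),
        seed=config.seed,
    )
    return records, report, bundle
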