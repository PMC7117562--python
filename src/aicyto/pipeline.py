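"""End-to-end study pipeline: measure every sample, summarize, compare.

``run_pipeline`` walks a study layout, measures each slide, derives each
sample's DI profile, then emits:

* ``samples/<id>.json``   — per-sample result (modal control IOD, DI list,
  histogram, peak DI, ploidy class, warnings);
* ``group_summary.csv``   — one row per condition (n, mean/SD/range of peak
  DI, ploidy grade of the mean, aneuploid fraction);
* ``ttest_matrix.csv``    — the upper-triangular one-tailed p-value matrix,
  rounded to two decimals (full precision in ``ttest_pairs.csv``).

Every output embeds the configuration hash; identical inputs and config
give byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .cohort_stats import GroupSummary, TTestResult, comparison_matrix, summarize_group
from .config import RunConfig
from .densitometry import measure_sample
from .ploidy import PloidyThresholds, SampleResult, analyze_sample, classify_ploidy
from .roi_io import StudyLayout, load_image, load_rois

__all__ = ["StudyReport", "run_pipeline", "sample_result_to_dict", "analyze_one"]

log = logging.getLogger("aicyto.pipeline")


@dataclass(frozen=True)
class StudyReport:
    sample_results: tuple[SampleResult, ...]
    group_summaries: tuple[GroupSummary, ...]
    ttests: dict[tuple[str, str], TTestResult]
    warnings: tuple[str, ...]
    config_hash: str


def analyze_one(
    image_path: str | Path,
    roi_path: str | Path,
    config: RunConfig,
    sample_id: str = "",
    condition: str = "",
) -> SampleResult:
    """Measure and analyze a single sample from its image + ROI files."""
    image = load_image(image_path, channel_policy=config.channel_policy)
    rois = load_rois(roi_path)
    thresholds = PloidyThresholds(config.mild_threshold, config.moderate_threshold)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        measurements = measure_sample(
            image,
            rois,
            white_level=config.white_level,
            epsilon=config.epsilon,
            min_area=config.min_area,
            on_overlap=config.on_overlap,
        )
        result = analyze_sample(
            measurements,
            sample_id=sample_id,
            condition=condition,
            bin_width=config.di_bin_width,
            modal_bin_width=config.modal_bin_width,
            thresholds=thresholds,
        )
    notes = tuple(dict.fromkeys(list(result.warnings) + [str(w.message) for w in caught]))
    return dataclasses.replace(result, warnings=notes)


def run_pipeline(
    layout: StudyLayout,
    config: RunConfig,
    out_dir: str | Path,
) -> StudyReport:
    """Run the full study: per-sample analysis, group tables, t-test matrix."""
    config = config.validate()
    out = Path(out_dir)
    (out / "samples").mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    thresholds = PloidyThresholds(config.mild_threshold, config.moderate_threshold)

    results: list[SampleResult] = []
    collected: list[str] = []
    for entry in layout.samples:
        log.info("sample %s (%s)", entry.sample_id, entry.condition)
        try:
            res = analyze_one(
                entry.image_path,
                entry.roi_path,
                config,
                sample_id=entry.sample_id,
                condition=entry.condition,
            )
        except Exception as exc:
            raise RuntimeError(f"sample {entry.sample_id!r}: {exc}") from exc
        for note in res.warnings:
            collected.append(f"{entry.sample_id}: {note}")
        results.append(res)
        _write_sample_json(out / "samples" / f"{entry.sample_id}.json", res, chash)

    groups = [
        summarize_group([r for r in results if r.condition == cond], thresholds)
        for cond in layout.conditions
    ]
    ttests = comparison_matrix(
        groups,
        variant=config.t_variant,
        order=list(layout.conditions),
        alternative_policy=config.alternative_policy,
        alpha=config.alpha,
    )

    _write_group_csv(out / "group_summary.csv", groups, thresholds, chash)
    _write_matrix_csv(out / "ttest_matrix.csv", layout.conditions, ttests, chash)
    _write_pairs_csv(out / "ttest_pairs.csv", ttests, chash)
    if collected:
        (out / "warnings.log").write_text("\n".join(collected) + "\n")

    return StudyReport(
        sample_results=tuple(results),
        group_summaries=tuple(groups),
        ttests=ttests,
        warnings=tuple(collected),
        config_hash=chash,
    )


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

def sample_result_to_dict(res: SampleResult, config_hash: str = "") -> dict:
    return {
        "config_hash": config_hash,
        "sample_id": res.sample_id,
        "condition": res.condition,
        "modal_control_iod": res.modal_control_iod,
        "n_controls": res.n_controls,
        "n_epithelial": res.n_epithelial,
        "peak_di": res.peak_di,
        "ploidy_class": res.ploidy_class,
        "aneuploid": res.aneuploid,
        "di_values": list(res.di_values),
        "histogram": {
            "bin_width": res.histogram.bin_width,
            "bin_edges": res.histogram.bin_edges.tolist(),
            "counts": res.histogram.counts.tolist(),
        },
        "warnings": list(res.warnings),
    }


def _write_sample_json(path: Path, res: SampleResult, chash: str) -> None:
    path.write_text(json.dumps(sample_result_to_dict(res, chash), indent=1))


def _csv_with_header(path: Path, df: pd.DataFrame, chash: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, index=False)


def _write_group_csv(
    path: Path,
    groups: Sequence[GroupSummary],
    thresholds: PloidyThresholds,
    chash: str,
) -> None:
    rows = []
    for g in groups:
        rows.append(
            {
                "condition": g.condition,
                "n": g.n,
                "mean_di": round(g.mean_di, 4),
                "sd_di": round(g.sd_di, 4),
                "min_di": round(g.di_range[0], 4),
                "max_di": round(g.di_range[1], 4),
                "ploidy": classify_ploidy(g.mean_di, thresholds),
                "aneuploid_count": g.aneuploid_count,
                "aneuploid_fraction": round(g.aneuploid_fraction, 4),
            }
        )
    _csv_with_header(path, pd.DataFrame(rows), chash)


def _write_matrix_csv(
    path: Path,
    order: Sequence[str],
    ttests: dict[tuple[str, str], TTestResult],
    chash: str,
) -> None:
    rows = []
    for a in order:
        row: dict[str, object] = {"condition": a}
        for b in order:
            if (a, b) in ttests:
                row[b] = f"{ttests[(a, b)].p_one_tailed:.2f}"
            else:
                row[b] = "X"
        rows.append(row)
    _csv_with_header(path, pd.DataFrame(rows), chash)


def _write_pairs_csv(
    path: Path, ttests: dict[tuple[str, str], TTestResult], chash: str
) -> None:
    rows = [
        {
            "group_a": r.group_a,
            "group_b": r.group_b,
            "variant": r.variant,
            "t": r.t,
            "df": r.df,
            "p_one_tailed": r.p_one_tailed,
            "significant": r.significant,
        }
        for r in ttests.values()
    ]
    _csv_with_header(path, pd.DataFrame(rows), chash)
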