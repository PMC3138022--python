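"""Assessment orchestration: read → filter → per-sample metrics per policy
→ summary, grouping and statistics files, with a plain-text run log."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .._markers import is_defined
from ..errors import ValidationError
from ..exposure import load_default_permitted_doses, load_permitted_doses
from ..pipeline import (
    NonDetectPolicy,
    SampleMetrics,
    WaterSample,
    compute_sample_metrics,
    filter_samples,
    group_by_n,
    summarize_dataset,
)
from ..stats import correlation_suite, mcr_comparison_by_hi_class
from .io import RunConfig, read_monitoring_csv, write_metrics_csv

logger = logging.getLogger(__name__)


def run_assessment(
    config: RunConfig, samples: Sequence[WaterSample] | None = None
) -> dict[str, Path]:
    """Run the full assessment and write output files into ``config.out_dir``.

    Returns a mapping of artifact name to path. ``samples`` may be supplied
    directly (e.g. from the generator) to skip reading ``config.input_path``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    if samples is None:
        samples = read_monitoring_csv(config.input_path, dialect=config.dialect)
    log_lines.append(f"samples read: {len(samples)}")

    if config.pd_table_path is None:
        pd_table = load_default_permitted_doses()
        log_lines.append("permitted-dose table: packaged fixture")
    else:
        pd_table = load_permitted_doses(config.pd_table_path)
        log_lines.append(f"permitted-dose table: {config.pd_table_path}")

    kept = filter_samples(samples, config.min_detects)
    removed = len(samples) - len(kept)
    log_lines.append(
        f"samples removed by <{config.min_detects}-detect filter: {removed}"
    )
    log_lines.append(f"samples in final dataset: {len(kept)}")
    if not kept:
        raise ValidationError(
            f"no samples remain after the {config.min_detects}-detect filter "
            f"({removed} removed of {len(samples)})"
        )

    outputs: dict[str, Path] = {}
    all_metrics: list[SampleMetrics] = []
    stats_rows: list[dict[str, object]] = []

    for policy in config.policies:
        metrics = [
            compute_sample_metrics(s, pd_table, config.scenario, policy) for s in kept
        ]
        all_metrics.extend(metrics)
        n_undef = sum(1 for m in metrics if not m.defined)
        log_lines.append(f"[{policy.value}] undefined-metric samples: {n_undef}")

        metrics_path = out_dir / f"metrics_{policy.value}.csv"
        write_metrics_csv(metrics, metrics_path, hi_cutoff=config.hi_cutoff)
        outputs[f"metrics_{policy.value}"] = metrics_path

        groups = group_by_n(metrics)
        groups_path = out_dir / f"groups_{policy.value}.csv"
        pd.DataFrame(
            {
                "n_value": [g.n_value for g in groups],
                "sample_count": [g.sample_count for g in groups],
                "median_hi": [g.median_hi if is_defined(g.median_hi) else "" for g in groups],
                "median_mcr": [g.median_mcr if is_defined(g.median_mcr) else "" for g in groups],
            }
        ).to_csv(groups_path, index=False)
        outputs[f"groups_{policy.value}"] = groups_path

        for corr in correlation_suite(metrics, groups):
            stats_rows.append(
                {
                    "analysis_name": corr.analysis,
                    "policy": policy.value,
                    "level": corr.level,
                    "statistic": corr.tau_b if is_defined(corr.tau_b) else "",
                    "p_value": corr.p_value if is_defined(corr.p_value) else "",
                    "n": corr.n_pairs,
                }
            )
        try:
            comp = mcr_comparison_by_hi_class(metrics, config.hi_cutoff)
            stats_rows.append(
                {
                    "analysis_name": f"mcr_by_hi_class_{comp.method}",
                    "policy": policy.value,
                    "level": "per_sample",
                    "statistic": comp.statistic,
                    "p_value": comp.p_value,
                    "n": sum(comp.group_sizes),
                }
            )
        except ValidationError as exc:
            log_lines.append(f"[{policy.value}] rank-sum comparison skipped: {exc}")

    summary_path = out_dir / "summary.csv"
    summarize_dataset(all_metrics, config.hi_cutoff).to_csv(summary_path, index=False)
    outputs["summary"] = summary_path

    stats_path = out_dir / "statistics.csv"
    pd.DataFrame(
        stats_rows,
        columns=["analysis_name", "policy", "level", "statistic", "p_value", "n"],
    ).to_csv(stats_path, index=False)
    outputs["statistics"] = stats_path

    if pd_table.miss_counts:
        for chem, count in sorted(pd_table.miss_counts.items()):
            log_lines.append(
                f"chemical without permitted dose excluded: {chem} ({count} occurrences)"
            )
    else:
        log_lines.append("chemicals without permitted dose: none encountered")

    log_path = out_dir / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    outputs["log"] = log_path
    for line in log_lines:
        logger.info("%s", line)
    return outputs
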