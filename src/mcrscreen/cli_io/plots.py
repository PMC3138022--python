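"""Diagnostic figures for assessment outputs."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from ..errors import ValidationError
from ..pipeline import SampleMetrics

_POLICY_STYLE = {
    "case1_zero": {"color": "tab:blue", "marker": "o"},
    "case2_dl_sqrt2": {"color": "tab:orange", "marker": "^"},
}


def _defined(metrics: Sequence[SampleMetrics]) -> list[SampleMetrics]:
    return [m for m in metrics if m.defined]


def make_plots(
    metrics_by_policy: Mapping[str, Sequence[SampleMetrics]],
    out_dir: str | Path,
    hi_cutoff: float = 1.0,
    fmt: str = "png",
) -> dict[str, Path]:
    """Produce the standard figure set.

    * ``mcr_vs_hi``: MCR against HI (log HI axis), one series per policy;
    * ``mcr_vs_hi_above``: the same restricted to HI > cutoff;
    * per policy, ``hi_vs_n`` and ``mcr_vs_n`` scatter of metric vs n.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    usable = {p: _defined(ms) for p, ms in metrics_by_policy.items()}
    if not any(usable.values()):
        raise ValidationError("no defined metrics to plot")
    paths: dict[str, Path] = {}

    for name, subset_above in (("mcr_vs_hi", False), ("mcr_vs_hi_above", True)):
        fig, ax = plt.subplots(figsize=(6, 4.5))
        empty = True
        for policy, ms in usable.items():
            pts = [m for m in ms if (m.metrics.hi > hi_cutoff or not subset_above)]
            if not pts:
                continue
            empty = False
            style = _POLICY_STYLE.get(policy, {})
            ax.scatter(
                [m.metrics.hi for m in pts],
                [m.metrics.mcr for m in pts],
                s=12, alpha=0.6, label=policy, **style,
            )
        if empty:
            plt.close(fig)
            continue
        ax.set_xscale("log")
        ax.set_xlabel("HI")
        ax.set_ylabel("MCR")
        title = "MCR vs HI" + (f" (HI > {hi_cutoff:g})" if subset_above else "")
        ax.set_title(title)
        ax.legend()
        path = out_dir / f"{name}.{fmt}"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths[name] = path

    for policy, ms in usable.items():
        if not ms:
            continue
        for metric_name, getter in (
            ("hi", lambda m: m.metrics.hi),
            ("mcr", lambda m: m.metrics.mcr),
        ):
            fig, ax = plt.subplots(figsize=(6, 4.5))
            style = _POLICY_STYLE.get(policy, {})
            ax.scatter(
                [m.n_effective for m in ms], [getter(m) for m in ms],
                s=12, alpha=0.6, **style,
            )
            if metric_name == "hi":
                ax.set_yscale("log")
            ax.set_xlabel("n")
            ax.set_ylabel(metric_name.upper())
            ax.set_title(f"{metric_name.upper()} vs n ({policy})")
            path = out_dir / f"{metric_name}_vs_n_{policy}.{fmt}"
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
            paths[f"{metric_name}_vs_n_{policy}"] = path
    return paths
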