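"""Figures mirroring the analysis outputs, rendered from a run directory.

Each panel is drawn from a CSV the pipeline already wrote (profiles or
model-prediction tables); alongside every figure the exact plotted series
is written again as a ``*_series.csv`` twin, so the figures are fully
auditable.  Missing stage outputs produce a partial report with the gaps
flagged in the return value rather than an error.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

logger = logging.getLogger(__name__)


def _plot_frequency_profile(run: Path, written: list[Path]) -> None:
    src = run / "profile_by_size.csv"
    if not src.exists():
        logger.warning("report: %s missing; frequency panel skipped", src.name)
        return
    prof = pd.read_csv(src)
    fig, ax = plt.subplots(figsize=(7, 4))
    for size, grp in prof.groupby("size"):
        if size % 4 == 1 or size in (3, prof["size"].max()):
            ax.plot(grp["index"], grp["mean_frequency"], marker="o",
                    markersize=2.5, linewidth=0.9, label=f"{size}")
    ax.set_xlabel("word position in turn")
    ax.set_ylabel("mean frequency (per 1,000 words)")
    ax.set_title("Mean word frequency per turn position, by turn size")
    ax.legend(title="turn size", fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(run / "fig_frequency_profile.png", dpi=150)
    plt.close(fig)
    prof.to_csv(run / "fig_frequency_profile_series.csv", index=False)
    written += [run / "fig_frequency_profile.png",
                run / "fig_frequency_profile_series.csv"]


def _plot_curves(run: Path, written: list[Path], src_name: str,
                 out_stem: str, group: str | None, x: str, ylabel: str,
                 title: str) -> None:
    src = run / src_name
    if not src.exists():
        logger.warning("report: %s missing; %s panel skipped", src_name, out_stem)
        return
    pred = pd.read_csv(src)
    fig, ax = plt.subplots(figsize=(6, 4))
    if group is None:
        ax.plot(pred[x], pred["predicted"])
    else:
        for lev, grp in pred.groupby(group):
            ax.plot(grp[x], grp["predicted"], label=str(lev))
        ax.legend(title=group)
    ax.set_xlabel(x.replace("_", " "))
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(run / f"{out_stem}.png", dpi=150)
    plt.close(fig)
    pred.to_csv(run / f"{out_stem}_series.csv", index=False)
    written += [run / f"{out_stem}.png", run / f"{out_stem}_series.csv"]


def render_report(run_dir: str | Path) -> list[Path]:
    """Render all available panels; returns the artifact paths written."""
    run = Path(run_dir)
    written: list[Path] = []
    _plot_frequency_profile(run, written)
    _plot_curves(run, written, "pred_frequency.csv", "fig_frequency_model",
                 None, "norm_position", "frequency (per 1,000 words)",
                 "Modelled word frequency across the turn")
    _plot_curves(run, written, "pred_wordclass.csv", "fig_wordclass",
                 "word_class", "norm_position", "share of tokens (%)",
                 "Modelled word-class percentages across the turn")
    _plot_curves(run, written, "pred_hapax.csv", "fig_hapax",
                 None, "norm_position", "hapax nouns / all words (%)",
                 "Modelled hapax-noun share across the turn")
    _plot_curves(run, written, "pred_pupil.csv", "fig_pupil",
                 "role", "norm_position", "baselined pupil size (px)",
                 "Modelled pupil size across the turn, by role")
    _plot_curves(run, written, "pred_coupling.csv", "fig_coupling",
                 "role", "slope_frequency", "pupil slope (px / turn)",
                 "Pupil-slope vs frequency-slope coupling, by role")
    return written
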