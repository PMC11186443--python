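"""End-to-end orchestration: select -> frequencies -> classes -> pupil ->
slopes -> fits -> report, with a manifest and plain-CSV intermediates.

Every stage writes tidy CSV/TSV artifacts into the run directory so each
step is independently re-runnable and diffable; the manifest records the
seed, per-stage row counts and every exclusion with its reason.  Reruns
with identical inputs reproduce identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .corpus import (
    build_frequency_table,
    mean_frequency_profile,
    read_vertical_corpus,
    select_turns,
)
from .inference import predict_position_curve
from .models import (
    ROLE_CODES,
    frequency_trend_model,
    hapax_profile_model,
    pupil_trend_model,
    slope_coupling_model,
    wordclass_profile_model,
)
from .pupil import preprocess_pupil, read_pupil_streams, read_turn_windows
from .simulate import SimConfig, generate_dataset
from .slopes import assemble_slope_pairs, frequency_slopes, pupil_slopes
from .wordclass import (
    ClassMap,
    class_position_profile,
    hapax_noun_profile,
    noun_function_insert_profile,
    proform_early_share,
    token_table,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("select", "frequencies", "classes", "pupil", "slopes", "fits",
              "report")


class PipelineError(RuntimeError):
    """A stage failed; the message names the failing stage."""


@dataclass
class RunConfig:
    """Inputs, stage toggles and output location for a pipeline run.

    Exactly one input source: either the three file paths, or
    ``simulate=True`` with a :class:`SimConfig`.
    """

    out_dir: str | Path
    transcript: str | Path | None = None
    pupil: str | Path | None = None
    windows: str | Path | None = None
    simulate: bool = False
    sim_config: SimConfig | None = None
    tagset: str = "c7"
    min_size: int = 3
    max_size: int = 25
    profile_sizes: tuple[int, ...] = tuple(range(3, 26, 2))
    max_degree: int = 6
    batch: int = 600
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    def validate(self) -> None:
        has_files = self.transcript is not None
        if self.simulate == has_files:
            raise PipelineError(
                "configure exactly one input source: file paths or simulate=True"
            )
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PipelineError(f"unknown stage(s): {sorted(unknown)}")
        if "pupil" in self.stages and not self.simulate and self.pupil is None:
            raise PipelineError(
                "stage 'pupil' enabled but no pupil stream file configured"
            )


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False)
    return len(df)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in order; returns the run directory.

    The manifest (``manifest.json``) lists the package version, seed, the
    row count each stage produced, and itemised exclusion counts.  A stage
    failure aborts the run with the stage named; artifacts written by the
    completed stages are preserved.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "turnload",
        "version": __version__,
        "seed": config.seed,
        "tagset": config.tagset,
        "stages": {},
        "exclusions": {},
    }
    stage = "input"
    try:
        if config.simulate:
            sim = config.sim_config or SimConfig()
            paths = generate_dataset(sim, out / "input", seed=config.seed)
            transcript, pupil_path, windows_path = (
                paths["transcript"], paths["pupil"], paths["windows"])
        else:
            transcript = Path(config.transcript)
            pupil_path = Path(config.pupil) if config.pupil else None
            windows_path = Path(config.windows) if config.windows else None
        turns = read_vertical_corpus(transcript, tagset=config.tagset)
        manifest["stages"]["input"] = {"n_turns": len(turns)}

        subset = None
        cmap = ClassMap.default(config.tagset)
        table = None
        tokens = None
        binned = None
        pairs = None
        fits: dict = {}

        for stage in config.stages:
            if stage == "select":
                subset = select_turns(turns, config.min_size, config.max_size)
                manifest["stages"]["select"] = {
                    "n_retained": len(subset),
                    "n_input": subset.n_input,
                    "retention": subset.retention,
                    "total_tokens": subset.total_tokens,
                }
                manifest["exclusions"]["short_or_long_turns"] = (
                    subset.n_input - len(subset))
            elif stage == "frequencies":
                subset = subset or select_turns(turns, config.min_size,
                                                config.max_size)
                table = build_frequency_table(subset)
                freq_df = pd.DataFrame(
                    [(f, t, c, table.per_thousand[(f, t)])
                     for (f, t), c in sorted(table.counts.items())],
                    columns=["form", "tag", "count", "per_thousand"],
                )
                n = _write(freq_df, out / "frequency_table.csv")
                prof_size = mean_frequency_profile(subset, table, by="turn_size")
                _write(prof_size, out / "profile_by_size.csv")
                prof_rel = mean_frequency_profile(subset, table,
                                                  by="relative_position")
                _write(prof_rel, out / "profile_relative.csv")
                tokens = token_table(subset, table, cmap)
                _write(tokens, out / "tokens.csv")
                manifest["stages"]["frequencies"] = {
                    "n_types": n, "n_tokens": int(table.total)}
            elif stage == "classes":
                subset = subset or select_turns(turns, config.min_size,
                                                config.max_size)
                table = table or build_frequency_table(subset)
                sizes = [s for s in config.profile_sizes
                         if config.min_size <= s <= config.max_size]
                class_prof = class_position_profile(subset, cmap, sizes=sizes)
                _write(class_prof, out / "class_profile.csv")
                hapax_prof = hapax_noun_profile(subset, table, cmap)
                _write(hapax_prof, out / "hapax_profile.csv")
                share = proform_early_share(subset)
                manifest["stages"]["classes"] = {
                    "n_class_cells": len(class_prof),
                    "n_hapax_cells": len(hapax_prof),
                    "proform_early_share": share,
                }
            elif stage == "pupil":
                subset = subset or select_turns(turns, config.min_size,
                                                config.max_size)
                if pupil_path is None or windows_path is None:
                    raise PipelineError("pupil stage needs stream and window files")
                streams = read_pupil_streams(pupil_path)
                windows = read_turn_windows(windows_path)
                sizes_map = {(t.conversation_id, t.turn_id): t.size
                             for t in subset}
                binned, excl = preprocess_pupil(streams, windows, sizes_map,
                                                batch=config.batch)
                _write(binned, out / "binned_pupil.csv")
                _write(excl, out / "pupil_exclusions.csv")
                manifest["stages"]["pupil"] = {
                    "n_bins": len(binned),
                    "n_pairs": int(binned.groupby(
                        ["conversation_id", "turn_id", "participant_id"]
                    ).ngroups) if len(binned) else 0,
                    "mean_samples_per_bin": (float(binned["bin_count"].mean())
                                             if len(binned) else float("nan")),
                }
                manifest["exclusions"]["pupil_pairs"] = (
                    excl["reason"].value_counts().to_dict() if len(excl) else {})
            elif stage == "slopes":
                if tokens is None:
                    subset = subset or select_turns(turns, config.min_size,
                                                    config.max_size)
                    table = table or build_frequency_table(subset)
                    tokens = token_table(subset, table, cmap)
                fs = frequency_slopes(tokens)
                _write(fs, out / "frequency_slopes.csv")
                if binned is not None and len(binned):
                    ps = pupil_slopes(binned)
                    pairs = assemble_slope_pairs(fs, ps)
                    _write(pairs, out / "slope_pairs.csv")
                    manifest["stages"]["slopes"] = {
                        "n_turn_slopes": len(fs), "n_pairs": len(pairs)}
                else:
                    manifest["stages"]["slopes"] = {
                        "n_turn_slopes": len(fs), "n_pairs": 0}
            elif stage == "fits":
                fits = _run_fits(config, out, tokens, subset, table, cmap,
                                 binned, pairs, manifest)
            elif stage == "report":
                from .report import render_report
                written = render_report(out)
                manifest["stages"]["report"] = {
                    "artifacts": [p.name for p in written]}
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - name the failing stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    manifest["completed_stages"] = [s for s in config.stages
                                    if s in manifest["stages"] or s == "fits"]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _run_fits(config, out, tokens, subset, table, cmap, binned, pairs,
              manifest) -> dict:
    """Fit whichever of the five headline models have inputs available."""
    fits: dict = {}
    grid = np.linspace(0.0, 1.0, 101)
    summary: dict = {}
    if tokens is not None:
        res = frequency_trend_model(tokens, max_degree=config.max_degree)
        fits["frequency"] = res
        _write(res.table, out / "fit_frequency.csv")
        _write(pd.DataFrame(res.trace), out / "fit_frequency_trace.csv")
        pred = predict_position_curve(res, grid)
        _write(pd.DataFrame({"norm_position": grid, "predicted": pred}),
               out / "pred_frequency.csv")
        summary["frequency_degree"] = res.selected_degree
    if subset is not None and table is not None:
        sizes = [s for s in config.profile_sizes
                 if config.min_size <= s <= config.max_size]
        class_prof = noun_function_insert_profile(subset, cmap, sizes=sizes)
        wc = wordclass_profile_model(class_prof, max_degree=config.max_degree)
        fits["wordclass"] = wc
        _write(wc.table, out / "fit_wordclass.csv")
        _write(pd.DataFrame(wc.trace), out / "fit_wordclass_trace.csv")
        centre = class_prof["norm_position"].dropna().mean()
        rows = []
        for cls, (noun_c, insert_c) in {
            "function": (-1.0, -1.0), "noun": (1.0, 0.0), "insert": (0.0, 1.0),
        }.items():
            pred = predict_position_curve(
                wc, grid - centre,
                extras={"Wordclass_noun": noun_c, "Wordclass_insert": insert_c})
            rows.append(pd.DataFrame({"norm_position": grid,
                                      "word_class": cls, "predicted": pred}))
        _write(pd.concat(rows, ignore_index=True), out / "pred_wordclass.csv")
        hapax_prof = hapax_noun_profile(subset, table, cmap)
        hx = hapax_profile_model(hapax_prof, max_degree=config.max_degree)
        fits["hapax"] = hx
        _write(hx.table, out / "fit_hapax.csv")
        _write(pd.DataFrame(hx.trace), out / "fit_hapax_trace.csv")
        centre_h = hapax_prof["norm_position"].mean()
        pred = predict_position_curve(hx, grid - centre_h)
        _write(pd.DataFrame({"norm_position": grid, "predicted": pred}),
               out / "pred_hapax.csv")
        summary["wordclass_degree"] = wc.selected_degree
        summary["hapax_degree"] = hx.selected_degree
    if binned is not None and len(binned):
        pt = pupil_trend_model(binned, max_degree=config.max_degree)
        fits["pupil"] = pt
        _write(pt.result.table, out / "fit_pupil.csv")
        _write(pd.DataFrame(pt.result.trace), out / "fit_pupil_trace.csv")
        _write(pt.posthoc, out / "fit_pupil_posthoc.csv")
        rows = []
        for role, code in ROLE_CODES.items():
            pred = predict_position_curve(pt.result, grid,
                                          extras={"Role": code})
            rows.append(pd.DataFrame({"norm_position": grid, "role": role,
                                      "predicted": pred}))
        _write(pd.concat(rows, ignore_index=True), out / "pred_pupil.csv")
        summary["pupil_degree"] = pt.result.selected_degree
    if pairs is not None and len(pairs):
        cp = slope_coupling_model(pairs)
        fits["coupling"] = cp
        _write(cp.result.table, out / "fit_coupling.csv")
        _write(cp.posthoc, out / "fit_coupling_posthoc.csv")
        sf_grid = np.linspace(pairs["slope_frequency"].quantile(0.05),
                              pairs["slope_frequency"].quantile(0.95), 101)
        rows = []
        p = cp.result.params
        for role, code in ROLE_CODES.items():
            pred = (p["Intercept"] + p["Role"] * code
                    + (p["Slope_frequency"]
                       + p["Slope_frequency:Role"] * code) * sf_grid)
            rows.append(pd.DataFrame({"slope_frequency": sf_grid,
                                      "role": role, "predicted": pred}))
        _write(pd.concat(rows, ignore_index=True), out / "pred_coupling.csv")
        summary["coupling_speaker"] = float(
            cp.posthoc.loc[cp.posthoc["level"] == "speaker", "estimate"].iloc[0])
    manifest["stages"]["fits"] = summary
    return fits
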