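"""Pupillometry preprocessing: eye averaging, blink interpolation, baselining,
word-aligned binning.

Raw streams are per-participant time series of left/right pupil areas in
pixels at a nominal 60 Hz, with blinks encoded as missing samples.  The
pipeline averages the two eyes, linearly interpolates missing runs within
fixed-length batches of observations, extracts each turn's window, baselines
it to zero at turn start, and splits it into as many contiguous equal bins
as the turn has words.  The per-bin means are the word-aligned pupil series
the slope and growth-curve stages consume.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STREAM_COLUMNS = ("participant_id", "timestamp_ms", "pupil_left_px", "pupil_right_px")
WINDOW_COLUMNS = ("conversation_id", "turn_id", "onset_ms", "offset_ms",
                  "participant_id", "role")
ROLES = ("speaker", "recipient")


class AlignmentError(ValueError):
    """Raised when paired series disagree in length."""


def read_pupil_streams(path: str | Path) -> pd.DataFrame:
    """Read a pupil-stream CSV (empty cells = missing samples).

    Validates the column contract and strictly increasing timestamps per
    participant.
    """
    df = pd.read_csv(path)
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df["participant_id"] = df["participant_id"].astype(str)
    for pid, grp in df.groupby("participant_id"):
        ts = grp["timestamp_ms"].to_numpy()
        if not np.all(np.diff(ts) > 0):
            raise ValueError(f"{path}: non-increasing timestamps for participant {pid}")
        if grp[["pupil_left_px", "pupil_right_px"]].notna().any(axis=1).sum() == 0:
            raise ValueError(f"{path}: participant {pid} has no valid samples")
    return df


def read_turn_windows(path: str | Path) -> pd.DataFrame:
    """Read a turn-window CSV mapping turns to stream intervals and roles."""
    df = pd.read_csv(path)
    missing = [c for c in WINDOW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in ("conversation_id", "turn_id", "participant_id", "role"):
        df[col] = df[col].astype(str)
    if (df["onset_ms"] >= df["offset_ms"]).any():
        bad = df[df["onset_ms"] >= df["offset_ms"]]
        raise ValueError(f"{path}: {len(bad)} window(s) with onset >= offset")
    unknown_roles = set(df["role"].unique()) - set(ROLES)
    if unknown_roles:
        raise ValueError(f"{path}: unknown role(s) {sorted(unknown_roles)}")
    return df


def average_eyes(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Elementwise mean of the two pupils.

    If one eye is missing at a sample, the other eye's value is used; a
    sample is missing in the output only when both eyes are missing.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise AlignmentError(
            f"eye series length mismatch: {left.shape} vs {right.shape}"
        )
    stacked = np.vstack([left, right])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs
        out = np.nanmean(stacked, axis=0)
    return out


def _interpolate_block(block: np.ndarray) -> np.ndarray:
    """Linear interpolation of NaN runs; edge runs take the nearest valid value."""
    valid = np.flatnonzero(~np.isnan(block))
    if valid.size == 0:
        return block  # fully-missing block: caller decides
    out = block.copy()
    nan_idx = np.flatnonzero(np.isnan(block))
    out[nan_idx] = np.interp(nan_idx, valid, block[valid])
    return out


def interpolate_blinks(
    series: np.ndarray, batch: int = 600, whole_series: bool = False
) -> np.ndarray:
    """Fill missing (blink) samples by linear interpolation in fixed batches.

    The series is cut into consecutive non-overlapping batches of ``batch``
    observations; within each batch, missing values are linearly interpolated
    between the nearest valid neighbours, and leading/trailing missing runs
    take the nearest valid value of that batch.  Valid samples are never
    altered.  A fully-missing batch is left missing (dropped downstream) with
    a warning.  ``whole_series=True`` ignores batch seams and interpolates
    over the entire series at once.
    """
    series = np.asarray(series, dtype=float)
    if whole_series:
        return _interpolate_block(series)
    out = series.copy()
    n_dropped = 0
    for start in range(0, len(series), batch):
        block = series[start:start + batch]
        if np.all(np.isnan(block)):
            n_dropped += 1
            continue
        out[start:start + batch] = _interpolate_block(block)
    if n_dropped:
        logger.warning("%d fully-missing batch(es) of %d samples left unfilled",
                       n_dropped, batch)
    return out


def baseline_to_turn_start(window: np.ndarray) -> np.ndarray:
    """Subtract the first datum of a turn window from all its values."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("cannot baseline an empty turn window")
    return window - window[0]


def bin_sizes(n_samples: int, n_bins: int) -> np.ndarray:
    """Contiguous bin sizes summing to n_samples, differing by at most one.

    The remainder goes to the earliest bins (deterministic, order-preserving):
    10 samples over 3 words gives [4, 3, 3].
    """
    if n_bins < 1:
        raise ValueError("need at least one bin")
    if n_samples < n_bins:
        raise ValueError(f"{n_samples} samples cannot fill {n_bins} bins")
    base, extra = divmod(n_samples, n_bins)
    return np.array([base + 1] * extra + [base] * (n_bins - extra))


@dataclass
class BinnedPupil:
    """Word-aligned baselined bin means for one turn x participant pair."""

    conversation_id: str
    turn_id: str
    participant_id: str
    role: str
    bin_means: np.ndarray
    bin_counts: np.ndarray

    @property
    def n_words(self) -> int:
        return len(self.bin_means)


def bin_by_words(
    window: np.ndarray,
    n_words: int,
    *,
    conversation_id: str = "",
    turn_id: str = "",
    participant_id: str = "",
    role: str = "",
) -> BinnedPupil:
    """Split a baselined window into as many equal bins as the turn has words.

    Bin sizes differ by at most one sample and sum to the window's sample
    count (e.g. 100 samples in a 4-word turn give four bins of 25).
    """
    window = np.asarray(window, dtype=float)
    sizes = bin_sizes(len(window), n_words)
    edges = np.concatenate([[0], np.cumsum(sizes)])
    means = np.array(
        [window[edges[i]:edges[i + 1]].mean() for i in range(n_words)]
    )
    return BinnedPupil(
        conversation_id=conversation_id, turn_id=turn_id,
        participant_id=participant_id, role=role,
        bin_means=means, bin_counts=sizes,
    )


def preprocess_pupil(
    streams: pd.DataFrame,
    windows: pd.DataFrame,
    turn_sizes: Mapping[tuple[str, str], int],
    batch: int = 600,
    whole_series: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full preprocessing: average eyes, interpolate, baseline, bin.

    Parameters
    ----------
    streams, windows : DataFrames with the stream / window column contracts.
    turn_sizes : mapping (conversation_id, turn_id) -> turn size in words.
    batch : interpolation batch length in observations.

    Returns
    -------
    binned : tidy frame, one row per turn x participant x bin, with columns
        conversation_id, turn_id, participant_id, role, size, bin_index
        (1-based), norm_position, pupil_mean, bin_count.
    exclusions : frame of dropped turn x participant pairs with reasons
        (``no_samples``, ``too_few_samples``, ``missing_after_interpolation``,
        ``unknown_turn_size``).
    """
    rows = []
    excl = []
    for pid, grp in streams.groupby("participant_id"):
        ts = grp["timestamp_ms"].to_numpy(dtype=float)
        merged = average_eyes(
            grp["pupil_left_px"].to_numpy(dtype=float),
            grp["pupil_right_px"].to_numpy(dtype=float),
        )
        filled = interpolate_blinks(merged, batch=batch, whole_series=whole_series)
        wins = windows[windows["participant_id"] == str(pid)]
        for win in wins.itertuples(index=False):
            key = (win.conversation_id, win.turn_id)
            if key not in turn_sizes:
                excl.append((*key, pid, win.role, "unknown_turn_size"))
                continue
            n_words = turn_sizes[key]
            lo = np.searchsorted(ts, win.onset_ms, side="left")
            hi = np.searchsorted(ts, win.offset_ms, side="left")
            segment = filled[lo:hi]
            if segment.size == 0:
                excl.append((*key, pid, win.role, "no_samples"))
                continue
            if np.isnan(segment).any():
                excl.append((*key, pid, win.role, "missing_after_interpolation"))
                continue
            if segment.size < n_words:
                excl.append((*key, pid, win.role, "too_few_samples"))
                continue
            baselined = baseline_to_turn_start(segment)
            binned = bin_by_words(
                baselined, n_words,
                conversation_id=win.conversation_id, turn_id=win.turn_id,
                participant_id=str(pid), role=win.role,
            )
            for b in range(n_words):
                rows.append((
                    win.conversation_id, win.turn_id, str(pid), win.role,
                    n_words, b + 1,
                    b / (n_words - 1) if n_words > 1 else 0.0,
                    binned.bin_means[b], int(binned.bin_counts[b]),
                ))
    binned_df = pd.DataFrame(
        rows,
        columns=["conversation_id", "turn_id", "participant_id", "role",
                 "size", "bin_index", "norm_position", "pupil_mean",
                 "bin_count"],
    )
    excl_df = pd.DataFrame(
        excl,
        columns=["conversation_id", "turn_id", "participant_id", "role",
                 "reason"],
    )
    if len(excl_df):
        logger.info("excluded %d turn-participant pair(s): %s",
                    len(excl_df),
                    excl_df["reason"].value_counts().to_dict())
    return binned_df, excl_df
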