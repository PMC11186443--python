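"""Per-turn least-squares slopes of frequency and pupil size, and their pairing.

Each selected turn gets a simple OLS slope of per-thousand word frequency
against normalised position; each turn x participant pair gets the analogous
slope of baselined pupil bin means against the bins' normalised positions.
Because positions are normalised to [0, 1], both slopes read as "change over
the whole turn".  The inner join of the two is the slope-pair table on which
the coupling model is fitted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SlopeError(ValueError):
    """Raised when a least-squares slope is undefined."""


def ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y on x: sum((x-x̄)(y-ȳ)) / sum((x-x̄)²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SlopeError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise SlopeError("need at least two points for a slope")
    dx = x - x.mean()
    sxx = dx @ dx
    if sxx == 0.0:
        raise SlopeError("slope undefined for constant x")
    return float(dx @ (y - y.mean()) / sxx)


def frequency_slopes(token_df: pd.DataFrame) -> pd.DataFrame:
    """Per-turn OLS slope of per-thousand frequency vs normalised position.

    ``token_df`` is the tidy token table (needs conversation_id, turn_id,
    speaker_id, size, norm_position, freq_per_thousand).  Returns one row per
    turn with columns conversation_id, turn_id, speaker_id, size,
    slope_frequency.
    """
    rows = []
    for (conv, tid), grp in token_df.groupby(["conversation_id", "turn_id"],
                                             sort=True):
        rows.append((
            conv, tid, grp["speaker_id"].iloc[0], int(grp["size"].iloc[0]),
            ols_slope(grp["norm_position"].to_numpy(),
                      grp["freq_per_thousand"].to_numpy()),
        ))
    return pd.DataFrame(
        rows, columns=["conversation_id", "turn_id", "speaker_id", "size",
                       "slope_frequency"],
    )


def pupil_slopes(binned_df: pd.DataFrame) -> pd.DataFrame:
    """Per turn x participant OLS slope of pupil bin means vs bin position.

    ``binned_df`` is the binned-pupil tidy frame from preprocessing.  Returns
    one row per (conversation_id, turn_id, participant_id) with the role and
    slope_pupil.
    """
    rows = []
    keys = ["conversation_id", "turn_id", "participant_id"]
    for (conv, tid, pid), grp in binned_df.groupby(keys, sort=True):
        rows.append((
            conv, tid, pid, grp["role"].iloc[0],
            ols_slope(grp["norm_position"].to_numpy(),
                      grp["pupil_mean"].to_numpy()),
        ))
    return pd.DataFrame(
        rows, columns=[*keys, "role", "slope_pupil"],
    )


def assemble_slope_pairs(
    freq_slopes: pd.DataFrame, pupil_slopes_df: pd.DataFrame
) -> pd.DataFrame:
    """Inner-join frequency and pupil slopes into the coupling-model table.

    Joins on (conversation_id, turn_id); each matched turn contributes one
    row per tracked participant.  Unmatched rows on either side are counted
    and logged.  Turn size is z-scaled on the assembled table
    (``size_scaled``), ready to act as the control covariate.
    """
    keys = ["conversation_id", "turn_id"]
    merged = pupil_slopes_df.merge(freq_slopes, on=keys, how="inner")
    if merged.empty:
        raise SlopeError("no overlap between frequency and pupil slope tables")
    n_pupil_unmatched = len(pupil_slopes_df) - len(merged)
    matched_turns = merged[keys].drop_duplicates()
    n_freq_unmatched = len(freq_slopes) - len(matched_turns)
    if n_pupil_unmatched or n_freq_unmatched:
        logger.info(
            "slope join: %d pupil row(s) and %d frequency turn(s) unmatched",
            n_pupil_unmatched, n_freq_unmatched,
        )
    sd = merged["size"].std(ddof=0)
    merged["size_scaled"] = (
        (merged["size"] - merged["size"].mean()) / sd if sd > 0 else 0.0
    )
    return merged[[*keys, "participant_id", "speaker_id", "role", "size",
                   "size_scaled", "slope_frequency", "slope_pupil"]]
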