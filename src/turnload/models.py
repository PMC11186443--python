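"""The pipeline's five headline analyses, as one builder per model shape.

Each builder takes a tidy frame from the upstream stages, constructs the
coded design (orthogonal position polynomials, contrast-coded role,
deviation-coded word class, z-scaled turn size), runs the incremental
polynomial selection where the trend order is open, and returns the fitted
result (plus post-hoc per-role contrasts where the question is asymmetric
between speakers and recipients).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import (
    ModelResult,
    ModelSpec,
    contrast_code,
    deviation_code,
    emm_simple_effects,
    fit_mixed,
    select_polynomial_model,
)

#: Role contrast codes: positive for the turn's producer.
ROLE_CODES = {"speaker": 0.5, "recipient": -0.5}
WORDCLASS_LEVELS = ("function", "noun", "insert")


def zscale(values: pd.Series) -> pd.Series:
    """Centre and scale to unit SD (population SD); constant input maps to 0."""
    sd = values.std(ddof=0)
    if sd == 0:
        return values * 0.0
    return (values - values.mean()) / sd


def frequency_trend_model(
    token_df: pd.DataFrame, max_degree: int = 6
) -> ModelResult:
    """Positional trend of per-thousand word frequency within turns.

    Mixed model on token-level data: orthogonal polynomials of normalised
    position, z-scaled turn size as control (its interactions with position
    subject to pruning), random intercepts by speaker and by conversation.
    """
    df = token_df.copy()
    df["Size"] = zscale(df["size"])
    return select_polynomial_model(
        df, response="freq_per_thousand", position="norm_position",
        controls=["Size"], control_interactions=True,
        groups=("speaker_id", "conversation_id"),
        max_degree=max_degree,
    )


def wordclass_profile_model(
    profile_df: pd.DataFrame, max_degree: int = 6
) -> ModelResult:
    """Word-class percentage curves across position, by deviation-coded class.

    Fixed-effects fit on the per-(size, position, class) percentage cells
    (``word_class`` in {noun, function, insert}): percentages are
    aggregates, so no participant or conversation grouping survives, and
    the model is plain least squares.  Function word is the omitted
    deviation level; the noun and insert columns are offsets.
    """
    df = profile_df.dropna(subset=["norm_position"]).copy()
    codes = deviation_code(df["word_class"], WORDCLASS_LEVELS, omit="function")
    df["Wordclass_noun"] = codes["noun"]
    df["Wordclass_insert"] = codes["insert"]
    df["Position_c"] = df["norm_position"] - df["norm_position"].mean()
    return select_polynomial_model(
        df, response="percentage", position="Position_c",
        factors={"Wordclass": ["Wordclass_noun", "Wordclass_insert"]},
        max_degree=max_degree,
    )


def hapax_profile_model(
    hapax_df: pd.DataFrame, max_degree: int = 6
) -> ModelResult:
    """Positional trend of the hapax-noun percentage (aggregated cells, OLS)."""
    df = hapax_df.copy()
    df["Position_c"] = df["norm_position"] - df["norm_position"].mean()
    return select_polynomial_model(
        df, response="percentage", position="Position_c",
        max_degree=max_degree,
    )


@dataclass
class PupilTrendFit:
    """Pupil growth-curve fit plus per-role post-hoc trend contrasts."""

    result: ModelResult
    posthoc: pd.DataFrame


def pupil_trend_model(
    binned_df: pd.DataFrame, max_degree: int = 6
) -> PupilTrendFit:
    """Baselined pupil size across bin position, by participant role.

    Mixed model on the word-aligned bin means: polynomial position terms,
    contrast-coded role and their interactions, z-scaled turn size as
    control, random intercepts by participant and conversation.  Post-hoc
    marginal-means contrasts give the per-role linear and (if selected)
    curvature trends with Bonferroni adjustment.
    """
    df = binned_df.copy()
    df["Role"] = contrast_code(df["role"], ROLE_CODES)
    df["Size"] = zscale(df["size"])
    result = select_polynomial_model(
        df, response="pupil_mean", position="norm_position",
        factors={"Role": ["Role"]},
        controls=["Size"], control_interactions=True,
        groups=("participant_id", "conversation_id"),
        max_degree=max_degree,
    )
    degree = result.selected_degree or 1
    trend_terms = ["Position"] + [f"Position^{k}" for k in range(2, degree + 1)]
    posthoc = emm_simple_effects(result, trend_terms, by="Role",
                                 levels=ROLE_CODES)
    return PupilTrendFit(result=result, posthoc=posthoc)


@dataclass
class CouplingFit:
    """Slope-coupling fit plus per-role frequency-slope contrasts."""

    result: ModelResult
    posthoc: pd.DataFrame


def slope_coupling_model(slope_pairs: pd.DataFrame) -> CouplingFit:
    """Coupling of per-turn pupil slopes to per-turn frequency slopes by role.

    Mixed model: pupil slope ~ frequency slope x role + scaled size, random
    intercepts by participant and conversation.  The interaction tests
    whether the coupling differs between speakers and recipients; the
    post-hoc contrasts give the within-role couplings.
    """
    df = slope_pairs.copy()
    df["Role"] = contrast_code(df["role"], ROLE_CODES)
    df["Slope_frequency"] = df["slope_frequency"].astype(float)
    df["Size"] = df["size_scaled"].astype(float)
    df["Slope_frequency:Role"] = df["Slope_frequency"] * df["Role"]
    spec = ModelSpec(
        response="slope_pupil",
        terms=["Slope_frequency", "Role", "Size", "Slope_frequency:Role"],
        groups=("participant_id", "conversation_id"),
    )
    result = fit_mixed(spec, df)
    posthoc = emm_simple_effects(result, ["Slope_frequency"], by="Role",
                                 levels=ROLE_CODES)
    return CouplingFit(result=result, posthoc=posthoc)
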