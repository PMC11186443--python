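"""Growth-curve inference: orthogonal polynomials, factor codings, fixed and
mixed fits, incremental polynomial selection, and marginal-means contrasts.

The positional trends are modelled with orthonormal polynomial predictors
(pairwise inner product zero, unit norm, constant excluded), so that each
degree's coefficient is estimated independently of the lower degrees.  Model
selection proceeds in two phases: control-variable interactions that do not
reach significance are pruned first, then polynomial degree is grown one
step at a time and the new term kept only while it is significant.  Mixed
fits carry random intercepts by participant and by conversation; fixed
fits are ordinary least squares for aggregated percentage profiles.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05


class RankError(ValueError):
    """Raised when a design matrix (or polynomial basis) is rank deficient."""


# ---------------------------------------------------------------------------
# Orthogonal polynomial basis (three-term recurrence, evaluable at new points)
# ---------------------------------------------------------------------------

@dataclass
class PolyBasis:
    """Orthonormal polynomial transforms of an input vector.

    Column k is a degree-k polynomial of the input; columns are mutually
    orthogonal with unit norm over the fitting points, and the constant term
    is excluded.  The recurrence coefficients are stored so the basis can be
    evaluated at new points (for predictions and plotting).
    """

    degree: int
    alpha: np.ndarray          # recurrence shifts, length degree
    beta: np.ndarray           # recurrence ratios, length degree (beta[0] unused)
    scale: np.ndarray          # column norms at fit, length degree
    columns: np.ndarray        # (n, degree) orthonormal columns at the fit points

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the basis polynomials at new points."""
        x = np.asarray(x, dtype=float)
        cols = np.empty((x.size, self.degree))
        p_prev = np.ones_like(x)
        p_curr = x - self.alpha[0]
        cols[:, 0] = p_curr / self.scale[0]
        for j in range(1, self.degree):
            p_next = (x - self.alpha[j]) * p_curr - self.beta[j] * p_prev
            p_prev, p_curr = p_curr, p_next
            cols[:, j] = p_curr / self.scale[j]
        return cols


def orthogonal_poly(x: np.ndarray, degree: int) -> PolyBasis:
    """Orthonormal polynomial basis of x up to ``degree``, constant excluded.

    Uses the classical three-term recurrence for discrete orthogonal
    polynomials; equivalent to a Gram-Schmidt orthonormalisation of
    ``[x, x**2, ..., x**degree]`` against the constant and each other.
    """
    x = np.asarray(x, dtype=float)
    if degree < 1:
        raise ValueError("degree must be at least 1")
    if np.unique(x).size < degree + 1:
        raise RankError(
            f"need at least {degree + 1} distinct x values for degree {degree}"
        )
    n = x.size
    alpha = np.empty(degree)
    beta = np.zeros(degree)
    scale = np.empty(degree)
    cols = np.empty((n, degree))
    p_prev = np.ones(n)
    norm2_prev = float(n)
    # degree 1
    alpha[0] = x.mean()
    p_curr = x - alpha[0]
    norm2_curr = p_curr @ p_curr
    scale[0] = np.sqrt(norm2_curr)
    cols[:, 0] = p_curr / scale[0]
    for j in range(1, degree):
        alpha[j] = (x * p_curr**2).sum() / norm2_curr
        beta[j] = norm2_curr / norm2_prev
        p_next = (x - alpha[j]) * p_curr - beta[j] * p_prev
        p_prev, p_curr = p_curr, p_next
        norm2_prev, norm2_curr = norm2_curr, p_curr @ p_curr
        if norm2_curr <= 0 or not np.isfinite(norm2_curr):
            raise RankError(f"basis degenerates at degree {j + 1}")
        scale[j] = np.sqrt(norm2_curr)
        cols[:, j] = p_curr / scale[j]
    return PolyBasis(degree=degree, alpha=alpha, beta=beta, scale=scale,
                     columns=cols)


# ---------------------------------------------------------------------------
# Factor codings
# ---------------------------------------------------------------------------

def contrast_code(values: pd.Series, codes: Mapping[str, float]) -> pd.Series:
    """Numeric contrast coding of a factor (e.g. speaker +0.5 / recipient -0.5).

    Codes must sum to zero over the levels.
    """
    if abs(sum(codes.values())) > 1e-12:
        raise ValueError(f"contrast codes must sum to zero, got {codes}")
    unknown = set(values.unique()) - set(codes)
    if unknown:
        raise ValueError(f"levels {sorted(unknown)} missing from codes {codes}")
    return values.map(codes).astype(float)


def deviation_code(
    values: pd.Series, levels: Sequence[str], omit: str
) -> pd.DataFrame:
    """Deviation (sum-to-zero) coding: one column per non-omitted level.

    A level's column is 1 on that level, -1 on the omitted level, 0
    elsewhere, so each coefficient contrasts the level against the grand
    mean across levels.
    """
    if omit not in levels:
        raise ValueError(f"omitted level {omit!r} not among levels {levels}")
    unknown = set(values.unique()) - set(levels)
    if unknown:
        raise ValueError(f"unexpected levels {sorted(unknown)}")
    out = {}
    for lev in levels:
        if lev == omit:
            continue
        col = np.where(values == lev, 1.0, np.where(values == omit, -1.0, 0.0))
        out[lev] = col
    return pd.DataFrame(out, index=values.index)


# ---------------------------------------------------------------------------
# Model spec / result containers
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """A fitted-model recipe: response, fixed-term columns, random groupings.

    ``terms`` name numeric columns that must already exist in the data
    (polynomial transforms, coded factors, interactions as products).
    ``groups`` names 0-2 random-intercept grouping factors.
    """

    response: str
    terms: list[str]
    groups: tuple[str, ...] = ()

    def validate(self, data: pd.DataFrame) -> None:
        missing = [c for c in [self.response, *self.terms, *self.groups]
                   if c not in data.columns]
        if missing:
            raise ValueError(f"spec names columns absent from data: {missing}")


@dataclass
class ModelResult:
    """Fixed-effect estimates with SEs, test statistics and fit metadata."""

    table: pd.DataFrame            # term, estimate, se, stat, p
    params: pd.Series              # includes Intercept
    cov: pd.DataFrame              # covariance of the fixed effects
    method: str                    # "ols" | "reml" | "ml"
    converged: bool
    singular: bool = False
    selected_degree: int | None = None
    random_variances: dict = field(default_factory=dict)
    trace: list = field(default_factory=list)
    n: int = 0
    loglike: float = float("nan")
    basis: PolyBasis | None = None
    spec: ModelSpec | None = None

    def pvalue(self, term: str) -> float:
        row = self.table.loc[self.table["term"] == term]
        if row.empty:
            raise KeyError(f"term {term!r} not in model")
        return float(row["p"].iloc[0])


def _result_table(params, bse, stats_, pvals, stat_name: str) -> pd.DataFrame:
    return pd.DataFrame({
        "term": list(params.index),
        "estimate": params.to_numpy(),
        "se": bse.to_numpy(),
        stat_name: stats_.to_numpy(),
        "p": pvals.to_numpy(),
    }).rename(columns={stat_name: "stat"})


# ---------------------------------------------------------------------------
# Fixed-effects (OLS) fit
# ---------------------------------------------------------------------------

def fit_lm(spec: ModelSpec, data: pd.DataFrame) -> ModelResult:
    """Ordinary least squares with classical SEs and two-sided t-tests."""
    spec.validate(data)
    X = sm.add_constant(data[spec.terms].astype(float), has_constant="add")
    X = X.rename(columns={"const": "Intercept"})
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the aliased columns by checking rank without each in turn
        aliased = []
        for col in X.columns:
            if np.linalg.matrix_rank(X.drop(columns=col).to_numpy()) == rank:
                aliased.append(col)
        raise RankError(f"design matrix rank deficient; aliased terms: {aliased}")
    res = sm.OLS(data[spec.response].astype(float), X).fit()
    return ModelResult(
        table=_result_table(res.params, res.bse, res.tvalues, res.pvalues, "t"),
        params=res.params,
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        method="ols", converged=True, n=int(res.nobs),
        loglike=float(res.llf), spec=spec,
    )


# ---------------------------------------------------------------------------
# Mixed-effects fit (random intercepts)
# ---------------------------------------------------------------------------

def _sanitize(df: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, dict]:
    """Rename response/terms/groups to formula-safe names."""
    mapping = {spec.response: "y__"}
    for i, t in enumerate(spec.terms):
        mapping[t] = f"x{i}__"
    for i, g in enumerate(spec.groups):
        mapping[g] = f"g{i}__"
    safe = df[list(mapping)].rename(columns=mapping)
    return safe, mapping


def fit_mixed(
    spec: ModelSpec, data: pd.DataFrame, reml: bool = True
) -> ModelResult:
    """Linear mixed model with random intercepts for the given grouping factors.

    With two grouping factors where the second is nested in the first
    (e.g. participant within conversation), the first factor is the model's
    grouping structure and the second enters as a variance component; if the
    factors are crossed, both enter as variance components of a single
    super-group.  Wald tests use a normal (z) approximation for p-values.
    Singular fits (a variance estimated at zero) are flagged, not rejected.
    """
    spec.validate(data)
    if not spec.groups:
        raise ValueError("fit_mixed requires at least one grouping factor")
    for g in spec.groups:
        if data[g].nunique() < 2:
            raise ValueError(f"grouping factor {g!r} has < 2 levels")
    safe, mapping = _sanitize(data, spec)
    x_names = [mapping[t] for t in spec.terms]
    formula = "y__ ~ " + (" + ".join(x_names) if x_names else "1")
    if len(spec.groups) == 1:
        model = smf.mixedlm(formula, safe, groups=safe["g0__"])
    else:
        g0, g1 = "g0__", "g1__"
        # use whichever factor contains the other as the grouping structure
        if (safe.groupby(g1)[g0].nunique() <= 1).all():
            outer, inner, vc_name = g0, g1, "vc1"
        elif (safe.groupby(g0)[g1].nunique() <= 1).all():
            outer, inner, vc_name = g1, g0, "vc0"
        else:
            outer = None
        if outer is not None:
            model = smf.mixedlm(
                formula, safe, groups=safe[outer], re_formula="1",
                vc_formula={vc_name: f"0 + C({inner})"},
            )
        else:
            safe = safe.assign(one__="all")
            model = smf.mixedlm(
                formula, safe, groups=safe["one__"], re_formula="0",
                vc_formula={"vc0": f"0 + C({g0})", "vc1": f"0 + C({g1})"},
            )
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        res = model.fit(reml=reml, maxiter=200)
    if not np.all(np.isfinite(np.asarray(res.params))):
        raise RuntimeError(
            "mixed model did not converge to finite estimates; "
            f"optimizer state: converged={res.converged}"
        )
    k_fe = model.k_fe
    fe_names = ["Intercept"] + spec.terms
    params = pd.Series(res.params.iloc[:k_fe].to_numpy(), index=fe_names)
    bse = pd.Series(res.bse.iloc[:k_fe].to_numpy(), index=fe_names)
    zvals = params / bse
    pvals = pd.Series(2 * stats.norm.sf(np.abs(zvals)), index=fe_names)
    # random-intercept variances on the response scale
    variances: dict[str, float] = {}
    vc_map = {"vc0": spec.groups[0] if len(spec.groups) > 1 else None,
              "vc1": spec.groups[1] if len(spec.groups) > 1 else None}
    if len(spec.groups) == 1:
        variances[spec.groups[0]] = float(np.asarray(res.cov_re)[0, 0])
    else:
        if model.k_re > 0:
            # the plain random intercept belongs to the outer grouping factor
            outer_name = (spec.groups[0]
                          if outer == "g0__" else spec.groups[1])
            variances[outer_name] = float(np.asarray(res.cov_re)[0, 0])
        vcomp = np.asarray(res.vcomp)
        vc_names = list(model.exog_vc.names) if model.exog_vc is not None else []
        for nm, v in zip(vc_names, vcomp):
            variances[vc_map.get(nm, nm)] = float(v)
    variances["residual"] = float(res.scale)
    singular = any(
        v < 1e-8 * max(variances["residual"], 1e-12)
        for k, v in variances.items() if k != "residual"
    )
    if singular:
        logger.info("singular mixed fit: a random-intercept variance is ~0")
    cov_fe = pd.DataFrame(
        np.asarray(res.cov_params())[:k_fe, :k_fe],
        index=fe_names, columns=fe_names,
    )
    return ModelResult(
        table=_result_table(params, bse, zvals, pvals, "z"),
        params=params, cov=cov_fe,
        method="reml" if reml else "ml",
        converged=bool(res.converged), singular=singular,
        random_variances=variances, n=len(safe),
        loglike=float(res.llf), spec=spec,
    )


# ---------------------------------------------------------------------------
# Incremental polynomial model selection
# ---------------------------------------------------------------------------

def _interaction(df: pd.DataFrame, a: str, b: str) -> str:
    """Add a product column named 'a:b' and return its name."""
    name = f"{a}:{b}"
    df[name] = df[a].to_numpy() * df[b].to_numpy()
    return name


def select_polynomial_model(
    data: pd.DataFrame,
    response: str,
    position: str,
    *,
    factors: Mapping[str, Sequence[str]] | None = None,
    controls: Sequence[str] = (),
    control_interactions: bool = True,
    groups: tuple[str, ...] = (),
    max_degree: int = 6,
    alpha: float = ALPHA_DEFAULT,
    reml: bool = True,
) -> ModelResult:
    """Two-phase incremental polynomial selection on the positional trend.

    Phase 1 fits the linear-position model with all candidate interactions
    of position with the control variables and prunes, one at a time, the
    least significant control interaction with p > alpha.  Phase 2 adds the
    next-degree polynomial term (plus its interactions with the factors of
    interest and with any retained control) and keeps it only if the newly
    added main term is significant at alpha, stopping at the first
    non-significant addition or at ``max_degree``.

    ``factors`` maps a factor label to its coded numeric column(s); every
    polynomial degree interacts with every factor column.  Returns the final
    fit, whose ``trace`` records each step and whose ``selected_degree`` is
    the retained polynomial order.
    """
    factors = dict(factors or {})
    df = data.copy()
    basis = orthogonal_poly(df[position].to_numpy(), max_degree)
    poly_names = ["Position"] + [f"Position^{k}" for k in range(2, max_degree + 1)]
    for name, col in zip(poly_names, basis.columns.T):
        df[name] = col

    factor_cols = [c for cols in factors.values() for c in cols]

    def terms_for(degree: int, ctrl_inter: list[str]) -> list[str]:
        terms = list(poly_names[:degree])
        terms += factor_cols
        terms += list(controls)
        for k in range(degree):
            for fc in factor_cols:
                terms.append(_interaction(df, poly_names[k], fc))
        for k in range(degree):
            for ctrl in ctrl_inter:
                terms.append(_interaction(df, poly_names[k], ctrl))
        return terms

    def fit(terms: list[str]) -> ModelResult:
        spec = ModelSpec(response=response, terms=terms, groups=groups)
        if groups:
            return fit_mixed(spec, df, reml=reml)
        return fit_lm(spec, df)

    trace: list[dict] = []

    # Phase 1: prune non-significant control interactions at degree 1.
    retained_controls = list(controls) if control_interactions else []
    while True:
        result = fit(terms_for(1, retained_controls))
        if not retained_controls:
            break
        pvs = {c: result.pvalue(f"Position:{c}") for c in retained_controls}
        worst = max(pvs, key=pvs.get)
        if pvs[worst] > alpha:
            trace.append({"phase": "prune", "term": f"Position:{worst}",
                          "p": pvs[worst], "action": "removed"})
            retained_controls.remove(worst)
        else:
            for c, p in pvs.items():
                trace.append({"phase": "prune", "term": f"Position:{c}",
                              "p": p, "action": "kept"})
            break

    # Phase 2: grow the polynomial degree while the new term is significant.
    degree = 1
    trace.append({"phase": "grow", "term": "Position", "p": result.pvalue("Position"),
                  "action": "kept"})
    while degree < max_degree:
        candidate = fit(terms_for(degree + 1, retained_controls))
        new_term = poly_names[degree]
        p_new = candidate.pvalue(new_term)
        if p_new < alpha:
            degree += 1
            result = candidate
            trace.append({"phase": "grow", "term": new_term, "p": p_new,
                          "action": "kept"})
        else:
            trace.append({"phase": "grow", "term": new_term, "p": p_new,
                          "action": "rejected"})
            break

    result.selected_degree = degree
    result.trace = trace
    result.basis = basis
    return result


def fit_polynomial_model(
    data: pd.DataFrame,
    response: str,
    position: str,
    degree: int,
    *,
    factors: Mapping[str, Sequence[str]] | None = None,
    controls: Sequence[str] = (),
    control_interactions: bool = True,
    groups: tuple[str, ...] = (),
    reml: bool = True,
) -> ModelResult:
    """Fit the positional-trend model at a fixed polynomial degree.

    Same design construction as :func:`select_polynomial_model` but with the
    degree pinned and no pruning; useful for refitting a known model shape.
    """
    factors = dict(factors or {})
    df = data.copy()
    basis = orthogonal_poly(df[position].to_numpy(), degree)
    poly_names = ["Position"] + [f"Position^{k}" for k in range(2, degree + 1)]
    for name, col in zip(poly_names, basis.columns.T):
        df[name] = col
    factor_cols = [c for cols in factors.values() for c in cols]
    terms = list(poly_names) + factor_cols + list(controls)
    for pn in poly_names:
        for fc in factor_cols:
            terms.append(_interaction(df, pn, fc))
        if control_interactions:
            for ctrl in controls:
                terms.append(_interaction(df, pn, ctrl))
    spec = ModelSpec(response=response, terms=terms, groups=groups)
    result = fit_mixed(spec, df, reml=reml) if groups else fit_lm(spec, df)
    result.selected_degree = degree
    result.basis = basis
    return result


def predict_position_curve(
    result: ModelResult,
    grid: np.ndarray,
    extras: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Model-implied positional curve over a grid of (transformed) positions.

    ``extras`` fixes non-positional terms (coded factors, controls) at given
    values; unlisted terms are held at zero.  Interaction terms named
    ``Position^k:X`` pick up the product of the polynomial column and the
    value supplied for ``X``.
    """
    if result.basis is None:
        raise ValueError("model has no polynomial basis attached")
    extras = dict(extras or {})
    degree = result.selected_degree or result.basis.degree
    cols = result.basis.transform(np.asarray(grid, dtype=float))
    poly_names = ["Position"] + [f"Position^{k}" for k in range(2, degree + 1)]
    poly_map = dict(zip(poly_names, cols.T[:degree]))
    out = np.full(len(grid), float(result.params.get("Intercept", 0.0)))
    for term, beta in result.params.items():
        if term == "Intercept":
            continue
        parts = term.split(":")
        val = np.ones(len(grid))
        for p in parts:
            if p in poly_map:
                val = val * poly_map[p]
            else:
                val = val * extras.get(p, 0.0)
        out = out + beta * val
    return out


# ---------------------------------------------------------------------------
# Estimated-marginal-means simple effects
# ---------------------------------------------------------------------------

@dataclass
class EMMContrast:
    """A per-level trend estimate with its multiplicity-adjusted p-value."""

    contrast: str
    level: str
    estimate: float
    se: float
    stat: float
    p_unadjusted: float
    p_adjusted: float


def emm_simple_effects(
    result: ModelResult,
    trend_terms: Sequence[str],
    by: str,
    levels: Mapping[str, float],
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Per-level trend coefficients from a model with factor interactions.

    For a factor coded numerically (e.g. role speaker +0.5 / recipient
    -0.5), the trend within level L is the trend main effect plus
    code(L) times the trend-by-factor interaction.  Each family (one trend
    term across the factor levels) is multiplicity-adjusted; Bonferroni by
    default.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    params = result.params
    cov = result.cov.to_numpy()
    index = list(params.index)
    rows = []
    for term in trend_terms:
        inter = f"{term}:{by}"
        if term not in index:
            raise KeyError(f"trend term {term!r} absent from model")
        if inter not in index:
            raise KeyError(f"factor {by!r} does not interact with {term!r} "
                           f"(no {inter!r} term)")
        for level, code in levels.items():
            L = np.zeros(len(index))
            L[index.index(term)] = 1.0
            L[index.index(inter)] = code
            est = float(L @ params.to_numpy())
            se = float(np.sqrt(L @ cov @ L))
            z = est / se
            p = float(2 * stats.norm.sf(abs(z)))
            p_adj = min(1.0, p * len(levels)) if adjust == "bonferroni" else p
            rows.append(EMMContrast(term, level, est, se, z, p, p_adj))
    return pd.DataFrame([r.__dict__ for r in rows])
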