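"""Multimodel inference over environmental covariates.

Every subset of a candidate variable set (polynomial pairs entering and
leaving as units, intercept-only model included) is fitted by GLS; the
models are scored with AICc, converted to Akaike weights, and combined
by conditional (natural) model averaging with unconditional standard
errors.  The relative importance of a variable, w+(j), is the sum of the
Akaike weights of the models containing it; a variable whose averaged
95% CI excludes zero is flagged as having an effect.  When bathymetry is
collinear with the other static covariates two disjoint model sets are
fitted and compared by their minimum AICc.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from fintrack.gls import Design, FittedModel, ModelSpec, build_design, fit_gls

logger = logging.getLogger(__name__)

Z_95 = 1.96


# ---------------------------------------------------------------------------
# per-individual summaries
# ---------------------------------------------------------------------------

@dataclass
class IndividualSummary:
    """Per-individual distribution summary with ANOVA and Tukey HSD."""

    means: pd.Series
    counts: pd.Series
    histograms: dict
    anova_f: float | None = None
    anova_p: float | None = None
    anova_df: tuple[int, int] | None = None
    tukey: pd.DataFrame | None = None


def summarize_individuals(
    values: np.ndarray, individuals: np.ndarray, bin_width: float | None = None
) -> IndividualSummary:
    """Histograms and means per individual, one-way ANOVA across
    individuals, and post hoc pairwise Tukey HSD tests.

    With a single individual the distribution summary is returned and the
    tests are skipped with a notice.
    """
    df = pd.DataFrame({"value": np.asarray(values, float),
                       "id": np.asarray(individuals)}).dropna()
    means = df.groupby("id")["value"].mean()
    counts = df.groupby("id")["value"].count()
    if bin_width is None:
        lo, hi = df["value"].min(), df["value"].max()
        bin_width = (hi - lo) / 30 if hi > lo else 1.0
    edges = np.arange(df["value"].min(), df["value"].max() + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([df["value"].min(), df["value"].min() + bin_width])
    if edges[-1] < df["value"].max():  # guard float endpoint shortfall
        edges = np.append(edges, edges[-1] + bin_width)
    hists = {g: np.histogram(sub["value"], bins=edges)
             for g, sub in df.groupby("id")}

    groups = [sub["value"].to_numpy() for _, sub in df.groupby("id")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        logger.info("ANOVA/Tukey skipped: need >= 2 individuals with >= 2 values")
        return IndividualSummary(means, counts, hists)

    f, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    res = stats.tukey_hsd(*groups)
    ids = list(means.index)
    rows = [
        {"a": ids[i], "b": ids[j], "p": float(res.pvalue[i, j])}
        for i in range(len(ids)) for j in range(i + 1, len(ids))
    ]
    return IndividualSummary(
        means, counts, hists,
        anova_f=float(f), anova_p=float(p), anova_df=(df1, df2),
        tukey=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# enumeration, weights, averaging
# ---------------------------------------------------------------------------

@dataclass
class FailedFit:
    """Placeholder for a candidate model whose fit raised."""

    terms: tuple[str, ...]
    error: str


def enumerate_and_fit(
    table: pd.DataFrame,
    variable_set,
    response: str,
    **fit_kwargs,
) -> tuple[Design, list]:
    """Fit every subset of ``variable_set`` (bitmask-ascending order).

    The design is built once over the full variable set so that all
    candidate models share rows and standardization; each subset is then
    fitted by :func:`fit_gls`.  A failing member is recorded as a
    :class:`FailedFit` and excluded from averaging downstream.
    """
    variable_set = tuple(variable_set)
    design = build_design(table, ModelSpec(response, variable_set))
    models: list = []
    for mask in range(2 ** len(variable_set)):
        terms = tuple(v for b, v in enumerate(variable_set) if mask >> b & 1)
        try:
            models.append(fit_gls(design, terms=terms, **fit_kwargs))
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
            logger.warning("model %s failed: %s", terms, exc)
            models.append(FailedFit(terms, str(exc)))
    return design, models


def akaike_weights(models) -> np.ndarray:
    """Akaike weights exp(-Delta_i/2) / sum_j exp(-Delta_j/2) over AICc."""
    fitted = [m for m in models if isinstance(m, FittedModel)]
    if not fitted:
        raise ValueError("no converged models")
    aicc = np.array([m.aicc for m in fitted])
    if not np.all(np.isfinite(aicc)):
        raise ValueError("AICc undefined for some model (n - k - 1 <= 0): "
                         "sample too small")
    delta = aicc - aicc.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class AveragedResult:
    """Model-averaged coefficients, importances and fit summaries."""

    response: str
    table: pd.DataFrame  # term, column, beta, se, ci_low, ci_high, w_plus, effect
    weights: np.ndarray
    model_terms: list
    aicc: np.ndarray
    r2_mean: float
    r2_min: float
    r2_max: float
    n: int
    label: str = ""

    @property
    def aicc_min(self) -> float:
        return float(np.min(self.aicc))


def model_average(models, weights: np.ndarray | None = None,
                  response: str = "", label: str = "") -> AveragedResult:
    """Conditional (natural) model averaging with unconditional SEs.

    For each term unit j: w+(j) sums the Akaike weights of the models
    containing j.  Coefficients are averaged over the containing models
    with renormalized weights; the unconditional standard error folds in
    the between-model spread,
    ``SE = sum_i w_i * sqrt(se_i^2 + (beta_i - beta_bar)^2)``; the 95% CI
    is ``beta_bar +- 1.96 SE`` and a unit whose CI excludes 0 is flagged
    as an effect.  Polynomial pairs share one w+(j) but report one row
    per coefficient.  Averaging operates on input-scale coefficients.
    """
    fitted = [m for m in models if isinstance(m, FittedModel)]
    if weights is None:
        weights = akaike_weights(models)
    weights = np.asarray(weights, float)
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be normalized")

    units: list[str] = []
    col_order: list[tuple[str, str]] = []
    for m in fitted:
        for c in m.columns:
            key = (c.term or "(Intercept)", c.name)
            if key not in col_order:
                col_order.append(key)
        for t in m.terms:
            if t not in units:
                units.append(t)

    raw = [m.coef_raw().set_index("column") for m in fitted]
    w_plus = {
        u: float(sum(w for w, m in zip(weights, fitted) if u in m.terms))
        for u in units
    }

    rows = []
    for term, col in col_order:
        has = np.array([col in r.index for r in raw])
        if not has.any():
            continue
        w_in = weights[has]
        if w_in.sum() <= 0:
            rows.append({"term": term, "column": col, "beta": np.nan, "se": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "w_plus": w_plus.get(term, 0.0), "effect": False})
            warnings.warn(f"term {term!r} appears only in zero-weight models")
            continue
        w_in = w_in / w_in.sum()
        b = np.array([r.loc[col, "beta"] for r, h in zip(raw, has) if h])
        s = np.array([r.loc[col, "se"] for r, h in zip(raw, has) if h])
        bbar = float(w_in @ b)
        se_u = float(w_in @ np.sqrt(s**2 + (b - bbar) ** 2))
        lo, hi = bbar - Z_95 * se_u, bbar + Z_95 * se_u
        rows.append({
            "term": term, "column": col, "beta": bbar, "se": se_u,
            "ci_low": lo, "ci_high": hi,
            "w_plus": w_plus.get(term, np.nan) if term != "(Intercept)" else np.nan,
            "effect": bool(lo > 0 or hi < 0),
        })
    for u in units:  # variables present in no converged model
        if not any(r["term"] == u for r in rows):
            rows.append({"term": u, "column": u, "beta": np.nan, "se": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "w_plus": 0.0,
                         "effect": False})

    r2 = np.array([m.r2 for m in fitted])
    return AveragedResult(
        response=response,
        table=pd.DataFrame(rows),
        weights=weights,
        model_terms=[m.terms for m in fitted],
        aicc=np.array([m.aicc for m in fitted]),
        r2_mean=float(r2.mean()),
        r2_min=float(r2.min()),
        r2_max=float(r2.max()),
        n=fitted[0].n,
        label=label,
    )


@dataclass
class ModelSetChoice:
    """Outcome of comparing two candidate model sets by minimum AICc."""

    selected: str  # "A" or "B"
    delta_aicc: float  # min AICc of the losing set minus the winning set
    tie: bool


def compare_model_sets(result_a: AveragedResult, result_b: AveragedResult) -> ModelSetChoice:
    """Pick the model set whose best (minimum-AICc) member is better.

    Both sets must be fitted on identical rows; an exact tie goes to set
    A (the bathymetry set) by convention.
    """
    if result_a.n != result_b.n:
        raise ValueError(
            f"model sets are incomparable: fitted on {result_a.n} vs "
            f"{result_b.n} rows"
        )
    a, b = result_a.aicc_min, result_b.aicc_min
    if a <= b:
        return ModelSetChoice("A", b - a, tie=(a == b))
    return ModelSetChoice("B", a - b, tie=False)


# ---------------------------------------------------------------------------
# marginal predictions
# ---------------------------------------------------------------------------

def predict_marginal(
    design: Design,
    model: FittedModel,
    covariate: str,
    grid: np.ndarray | None = None,
    n_grid: int = 100,
    z: float = Z_95,
) -> pd.DataFrame:
    """Marginal (population-level) prediction curve for one covariate.

    Predictions come from the supplied model (use the full, all-terms
    model) across the covariate grid with every other covariate held at
    its mean; the band is ``prediction +- z * SE`` from the coefficient
    covariance, and both are back-transformed through ``10^(.)`` when the
    response was log10-transformed.
    """
    if covariate not in model.terms:
        raise ValueError(f"{covariate!r} is not a term of the supplied model")
    lo, hi = design.covariate_range[covariate]
    if grid is None:
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, float)
    extrapolated = (grid < lo) | (grid > hi)
    if extrapolated.any():
        warnings.warn(f"{int(extrapolated.sum())} grid point(s) outside the "
                      f"observed range of {covariate!r}; extrapolating")

    raw = {}
    for c in model.columns:
        if c.kind == "intercept" or c.term == covariate:
            continue
        raw.setdefault(c.term, c.centre if c.kind == "quadratic" else c.offset)
    frame = pd.DataFrame({t: np.full(len(grid), v) for t, v in raw.items()})
    frame[covariate] = grid
    Xr = design.transform_raw(frame, model.columns)
    pred = Xr @ model.beta
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", Xr, model.cov, Xr), 0.0, None))
    lo_b, hi_b = pred - z * se, pred + z * se
    if design.spec.transform == "log10":
        pred, lo_b, hi_b = 10.0**pred, 10.0**lo_b, 10.0**hi_b
    return pd.DataFrame({
        covariate: grid, "prediction": pred, "lower": lo_b, "upper": hi_b,
        "extrapolated": extrapolated,
    })
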