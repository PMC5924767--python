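"""Generalized least squares with AR(1) errors and per-individual
variance weights, fitted by maximum likelihood.

The error model for records ordered within individual ``g`` is

    cov(e_a, e_b) = sigma^2 * delta_g^2 * rho^(|a - b|)

with ``delta_1 = 1`` (variance-identity structure over individuals) and a
first-order autoregressive correlation by within-individual record rank.
``beta`` and ``sigma`` are profiled out analytically; the likelihood is
maximized over ``(atanh(rho), log(delta_2..m))``.  ML (not REML) is used
throughout so that information-criterion comparisons across different
fixed-effects structures remain valid.

Movement-parameter responses are log10-transformed (turning angle is the
exception and stays on its identity scale); sea-surface height and hour
of day always enter as centred second-order polynomial pairs.  Predictor
columns are standardized internally; reported coefficients can be mapped
back to input scale through the design's bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import qr as _qr

#: Movement parameters accepted as the response.
RESPONSES = (
    "speed",
    "turning_angle",
    "dive_duration",
    "dive_depth",
    "dive_wiggliness",
    "post_dive_duration",
)

#: Covariates always entered as linear + quadratic pairs.
POLY_UNITS = ("ssh", "hour_of_day")

_RHO_BOUND = 0.99


class NonPositiveResponseError(ValueError):
    """log10 transform requested on non-positive response values."""

    def __init__(self, rows):
        self.rows = list(rows)
        super().__init__(
            f"{len(self.rows)} response value(s) are <= 0 and cannot be "
            f"log10-transformed (first rows: {self.rows[:10]})"
        )


class RankDeficiencyError(ValueError):
    """Design matrix is singular; carries the aliased column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design is rank deficient; aliased columns: {self.columns}")


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries the best state found."""

    def __init__(self, best):
        self.best = best
        super().__init__("GLS likelihood optimization failed to converge")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate regression: response plus a set of term units.

    ``terms`` are covariate units; ``ssh`` and ``hour_of_day`` expand to
    linear + quadratic column pairs.  The response transform is log10 for
    every movement parameter except turning angle.
    """

    response: str
    terms: tuple[str, ...] = ()

    def __post_init__(self):
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        object.__setattr__(self, "terms", tuple(self.terms))

    @property
    def transform(self) -> str:
        return "identity" if self.response == "turning_angle" else "log10"


@dataclass(frozen=True)
class ColumnInfo:
    """Bookkeeping for one standardized design column.

    The column holds ``(u - offset) / scale`` where ``u`` is the raw
    covariate (linear terms) or the centred square ``(x - centre)^2``
    (quadratic terms).
    """

    name: str
    term: str  # owning unit ("" for the intercept)
    kind: str  # "intercept" | "linear" | "quadratic"
    offset: float = 0.0
    scale: float = 1.0
    centre: float = 0.0  # raw-covariate centre for quadratic columns


@dataclass
class Design:
    """Response vector, full design matrix and grouping for one table."""

    spec: ModelSpec
    y: np.ndarray
    X: np.ndarray
    columns: list[ColumnInfo]
    groups: np.ndarray  # integer codes, rows sorted by group then time
    group_levels: np.ndarray
    n_dropped: int = 0
    covariate_range: dict = field(default_factory=dict)

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def term_units(self) -> list[str]:
        seen = []
        for c in self.columns:
            if c.term and c.term not in seen:
                seen.append(c.term)
        return seen

    def subset(self, terms) -> tuple[np.ndarray, list[ColumnInfo]]:
        """Columns for the intercept plus the requested term units."""
        terms = set(terms)
        idx = [i for i, c in enumerate(self.columns)
               if c.kind == "intercept" or c.term in terms]
        return self.X[:, idx], [self.columns[i] for i in idx]

    def transform_raw(self, raw: pd.DataFrame, columns: list[ColumnInfo]) -> np.ndarray:
        """Standardized design rows from raw covariate values."""
        out = np.empty((len(raw), len(columns)))
        for j, c in enumerate(columns):
            if c.kind == "intercept":
                out[:, j] = 1.0
            elif c.kind == "linear":
                out[:, j] = (raw[c.term].to_numpy(float) - c.offset) / c.scale
            else:
                u = (raw[c.term].to_numpy(float) - c.centre) ** 2
                out[:, j] = (u - c.offset) / c.scale
        return out


def build_design(table: pd.DataFrame, spec: ModelSpec) -> Design:
    """Assemble the response and the full standardized design matrix.

    Rows are sorted by individual then time; rows with a missing
    covariate or response are dropped and counted.  The response is
    log10-transformed unless it is the turning angle (non-positive
    values under log10 raise, listing the offending rows).  ``ssh`` and
    ``hour_of_day`` contribute centred linear + quadratic column pairs;
    every column is standardized (centred, unit sd).
    """
    needed = [spec.response, "id", "time", *spec.terms]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise KeyError(f"table lacks required columns: {missing}")
    df = table[needed].copy()
    n0 = len(df)
    df = df.dropna().sort_values(["id", "time"], kind="stable")
    n_dropped = n0 - len(df)

    resp = df[spec.response].to_numpy(float)
    if spec.transform == "log10":
        bad = np.flatnonzero(resp <= 0)
        if len(bad):
            raise NonPositiveResponseError(df.index[bad])
        y = np.log10(resp)
    else:
        y = resp.copy()

    columns = [ColumnInfo("(Intercept)", "", "intercept")]
    mats = [np.ones(len(df))]
    cov_range: dict = {}
    for term in spec.terms:
        x = df[term].to_numpy(float)
        cov_range[term] = (float(x.min()), float(x.max())) if len(x) else (np.nan, np.nan)
        if term in POLY_UNITS:
            centre = float(x.mean())
            xc = x - centre
            for u, kind, suffix in ((xc, "linear", ""), (xc**2, "quadratic", "^2")):
                off = float(u.mean())
                sc = float(u.std())
                sc = sc if sc > 0 else 1.0
                columns.append(ColumnInfo(f"{term}{suffix}", term, kind, off, sc, centre))
                mats.append((u - off) / sc)
        else:
            off = float(x.mean())
            sc = float(x.std())
            sc = sc if sc > 0 else 1.0
            columns.append(ColumnInfo(term, term, "linear", off, sc))
            mats.append((x - off) / sc)

    codes, levels = pd.factorize(df["id"], sort=True)
    return Design(
        spec=spec,
        y=y,
        X=np.column_stack(mats),
        columns=columns,
        groups=codes.astype(np.int64),
        group_levels=np.asarray(levels),
        n_dropped=n_dropped,
        covariate_range=cov_range,
    )


@dataclass
class FittedModel:
    """One GLS fit: coefficients, error-structure estimates and scores."""

    terms: tuple[str, ...]
    columns: list[ColumnInfo]
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    sigma: float
    rho: float
    delta: np.ndarray  # per group level, first fixed to 1
    group_levels: np.ndarray
    loglik: float
    n: int
    k: int
    aicc: float
    r2: float

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def coef_raw(self) -> pd.DataFrame:
        """Coefficients mapped back to input (unstandardized) scale.

        For polynomial units the input scale is the centred covariate.
        The intercept absorbs the standardization offsets: its row is the
        expected response with every linear covariate at zero and every
        polynomial covariate at its centre.
        """
        p = len(self.columns)
        rows = []
        for j, c in enumerate(self.columns):
            if c.kind == "intercept":
                contrast = np.zeros(p)
                contrast[j] = 1.0
                for i, ci in enumerate(self.columns):
                    if ci.kind != "intercept":
                        contrast[i] = -ci.offset / ci.scale
                b = float(contrast @ self.beta)
                s = float(np.sqrt(contrast @ self.cov @ contrast))
            else:
                b = float(self.beta[j] / c.scale)
                s = float(self.se[j] / c.scale)
            rows.append({"column": c.name, "term": c.term or "(Intercept)",
                         "beta": b, "se": s})
        return pd.DataFrame(rows)


def _whiten(arr, groups, rho, delta_row, first_mask):
    out = arr / (delta_row if arr.ndim == 1 else delta_row[:, None])
    prev = np.roll(out, 1, axis=0)
    s = math.sqrt(max(1.0 - rho * rho, 1e-12))
    inner = (out - rho * prev) / s
    if arr.ndim == 1:
        return np.where(first_mask, out, inner)
    return np.where(first_mask[:, None], out, inner)


def fit_gls(
    design: Design,
    terms=None,
    estimate_rho: bool = True,
    estimate_delta: bool = True,
    rho: float = 0.0,
    starts: str = "auto",
) -> FittedModel:
    """Maximum-likelihood GLS fit for one term subset of a design.

    ``beta`` and ``sigma`` are profiled analytically; the optimizer works
    on ``atanh(rho)`` and ``log(delta)``.  ``starts="auto"`` begins from
    moment estimates of the OLS residuals (lag-1 autocorrelation and
    per-group residual sds); ``starts="full"`` adds restarts from
    ``rho in {0, +0.5, -0.5}`` and keeps the best optimum.  With
    ``estimate_rho=False`` (and optionally a fixed ``rho``) and
    ``estimate_delta=False`` the fit reduces to ordinary least squares.
    """
    if terms is None:
        terms = design.spec.terms
    X, columns = design.subset(terms)
    y = design.y
    groups = design.groups
    n, p = X.shape
    m = len(design.group_levels)

    # rank screen with pivoted QR, naming the aliased columns
    _, R, piv = _qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.size else 0.0
    bad = piv[np.flatnonzero(diag <= tol)]
    if len(bad):
        raise RankDeficiencyError([columns[int(b)].name for b in bad])

    k = p + 1 + (1 if estimate_rho else 0) + ((m - 1) if estimate_delta and m > 1 else 0)
    if n <= k + 2:
        raise ValueError(f"too few rows (n={n}) for k={k} parameters")

    first_mask = np.r_[True, groups[1:] != groups[:-1]]
    block_sizes = np.bincount(groups, minlength=m)
    n_inner = n - int(first_mask.sum())  # rows that get the AR(1) inner transform

    def profile(rho_v: float, log_d: np.ndarray):
        delta = np.ones(m)
        if log_d.size:
            delta[1:] = np.exp(log_d)
        drow = delta[groups]
        yw = _whiten(y, groups, rho_v, drow, first_mask)
        Xw = _whiten(X, groups, rho_v, drow, first_mask)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        sigma2 = max(rss / n, 1e-300)
        ll = (
            -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
            - 0.5 * n_inner * math.log(max(1.0 - rho_v * rho_v, 1e-12))
            - float(np.sum(block_sizes * np.log(delta)))
        )
        return ll, beta, sigma2, Xw, delta

    def unpack(theta: np.ndarray):
        i = 0
        rho_v = rho
        if estimate_rho:
            rho_v = math.tanh(theta[0])
            i = 1
        log_d = theta[i:] if (estimate_delta and m > 1) else np.empty(0)
        return rho_v, log_d

    def negll(theta: np.ndarray) -> float:
        rho_v, log_d = unpack(theta)
        if abs(rho_v) > _RHO_BOUND:
            return 1e12
        return -profile(rho_v, log_d)[0]

    n_free = (1 if estimate_rho else 0) + ((m - 1) if estimate_delta and m > 1 else 0)
    if n_free == 0:
        rho_hat, log_d_hat = rho, np.empty(0)
        converged = True
    else:
        # moment-based warm start from OLS residuals
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        r0 = y - X @ beta0
        sds = np.array([max(r0[groups == g].std(), 1e-6) for g in range(m)])
        d0 = np.log(np.maximum(sds[1:] / sds[0], 1e-3)) if (estimate_delta and m > 1) else np.empty(0)
        rn = r0 / (np.exp(np.r_[0.0, d0])[groups] if d0.size else 1.0)
        num = float(np.sum(rn[1:][~first_mask[1:]] * rn[:-1][~first_mask[1:]]))
        den = float(rn @ rn)
        rho0 = min(max(num / den if den > 0 else 0.0, -0.9), 0.9)

        start_list = []
        if estimate_rho:
            start_list.append(np.r_[math.atanh(rho0), d0])
            if starts == "full":
                for r_alt in (0.0, 0.5, -0.5):
                    start_list.append(np.r_[math.atanh(r_alt), d0])
        else:
            start_list.append(d0.copy())

        best = None
        converged = False
        for theta0 in start_list:
            res = optimize.minimize(
                negll, theta0, method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 4000},
            )
            if best is None or res.fun < best.fun:
                best = res
            converged = converged or bool(res.success)
        if not converged and starts != "full":
            # one retry from the neutral start before giving up
            res = optimize.minimize(
                negll, np.zeros(n_free), method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 4000},
            )
            if res.fun < best.fun:
                best = res
            converged = bool(res.success)
        if not converged:
            raise ConvergenceError(best)
        rho_hat, log_d_hat = unpack(best.x)

    ll, beta, sigma2, Xw, delta = profile(rho_hat, log_d_hat)
    XtX_inv = np.linalg.pinv(Xw.T @ Xw)
    cov = sigma2 * XtX_inv
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    fitted = X @ beta
    if np.std(fitted) > 0 and np.std(y) > 0:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    else:
        r2 = 0.0
    aicc = compute_aicc(ll, k, n)
    return FittedModel(
        terms=tuple(terms),
        columns=columns,
        beta=beta,
        se=se,
        cov=cov,
        sigma=math.sqrt(sigma2),
        rho=float(rho_hat),
        delta=delta,
        group_levels=design.group_levels,
        loglik=float(ll),
        n=n,
        k=k,
        aicc=aicc,
        r2=r2,
    )


def compute_aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 log L + 2k + 2k(k+1)/(n-k-1); infinite when the
    small-sample correction is undefined (n - k - 1 <= 0)."""
    if n - k - 1 <= 0:
        return math.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
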