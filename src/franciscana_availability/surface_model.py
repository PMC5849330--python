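"""Mixed-effects modelling of the log proportion-at-surface.

The response is the natural log of each cycle's proportion at surface,
``log(s_i / (s_i + d_i))``.  Because cycles of one tracked group are
dependent, every model carries a group random intercept, and candidate
models may add serial correlation (AR-1 or ARMA(p,q)) on the cycle order
within a group.  Marginally, group ``g``'s response vector is Gaussian with

    Cov = sigma_group^2 * J + sigma_resid^2 * R(phi)

where ``J`` is the all-ones matrix and ``R`` the residual correlation matrix.
Models are fitted by maximum likelihood (profiling the fixed effects and the
residual scale), compared by AIC, and summarised by Akaike weights, relative
variable importance and model-averaged coefficients with unconditional
standard errors.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import solve_triangular
from statsmodels.tsa.arima_process import ArmaProcess, arma_acf

from .records import GroupSession

logger = logging.getLogger(__name__)

#: The five candidate predictors, in reporting order.
PREDICTORS = (
    "group_size_class",
    "calves",
    "depth_m",
    "transparency_cm",
    "tide_m",
)

#: Design-matrix column backing each predictor (factors enter as dummies).
_DESIGN_COLUMNS = {
    "group_size_class": "large",
    "calves": "calves",
    "depth_m": "depth_m",
    "transparency_cm": "transparency_cm",
    "tide_m": "tide_m",
}

_PRETTY = {
    "group_size_class": "Group size (large)",
    "calves": "Presence of calves",
    "depth_m": "Depth",
    "transparency_cm": "Water transparency",
    "tide_m": "Tidal level",
}


def prepare_response(sessions: Sequence[GroupSession]) -> pd.DataFrame:
    """Build the modelling table: log proportion plus session covariates.

    Rows are ordered by (group_id, cycle_index).  Raises if any proportion
    falls outside (0, 1) — impossible for positive durations, but guarded.
    """
    rows = []
    for s in sessions:
        for c in s.cycles:
            p = c.proportion_at_surface
            if not 0.0 < p < 1.0:
                raise ValueError(
                    f"proportion {p} outside (0,1) in cycle {c.cycle_index} "
                    f"of group {s.group_id}"
                )
            rows.append(
                {
                    "group_id": s.group_id,
                    "cycle_index": c.cycle_index,
                    "y": math.log(p),
                    "large": 1.0 if s.size_class == "large" else 0.0,
                    "calves": 1.0 if s.calves else 0.0,
                    "depth_m": s.depth_m,
                    "transparency_cm": s.transparency_cm,
                    "tide_m": s.tide_m,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["group_id", "cycle_index"], kind="stable").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# Correlation structures


@dataclass(frozen=True)
class CorrelationStructure:
    """Within-group residual correlation on the cycle-order lag."""

    kind: str = "ar1"  # "independent" | "ar1" | "arma"
    p: int = 1
    q: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("independent", "ar1", "arma"):
            raise ValueError(f"unknown correlation kind {self.kind!r}")
        if self.kind == "arma":
            if self.p not in (1, 2) or self.q not in (0, 1):
                raise ValueError(
                    f"ARMA orders restricted to p in 1-2, q in 0-1; "
                    f"got ({self.p},{self.q})"
                )

    @property
    def n_params(self) -> int:
        if self.kind == "independent":
            return 0
        if self.kind == "ar1":
            return 1
        return self.p + self.q

    @property
    def label(self) -> str:
        if self.kind == "independent":
            return "none"
        if self.kind == "ar1":
            return "AR-1"
        return f"ARMA({self.p},{self.q})"


INDEPENDENT = CorrelationStructure("independent")
AR1 = CorrelationStructure("ar1")


def correlation_matrix(
    structure: CorrelationStructure, n: int, params: Sequence[float]
) -> np.ndarray:
    """n x n residual correlation matrix at unit lag spacing.

    AR-1: entry (i, j) = phi^|i-j|.  ARMA(p, q): the stationary
    autocorrelation function of the process with the given coefficients.
    Raises for nonstationary (or noninvertible) parameters.
    """
    params = np.asarray(params, dtype=float)
    if len(params) != structure.n_params:
        raise ValueError(
            f"{structure.label} needs {structure.n_params} parameter(s), "
            f"got {len(params)}"
        )
    if structure.kind == "independent":
        return np.eye(n)
    lags = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    if structure.kind == "ar1":
        phi = params[0]
        if not abs(phi) < 1:
            raise ValueError(f"AR-1 parameter must satisfy |phi| < 1, got {phi}")
        return phi**lags
    ar = np.r_[1.0, -params[: structure.p]]
    ma = np.r_[1.0, params[structure.p :]]
    proc = ArmaProcess(ar, ma)
    if not (proc.isstationary and proc.isinvertible):
        raise ValueError(
            f"nonstationary/noninvertible ARMA parameters {params.tolist()}"
        )
    acf = arma_acf(ar, ma, lags=n)
    return acf[lags]


# ---------------------------------------------------------------------------
# Candidate models and fits


@dataclass(frozen=True)
class CandidateModel:
    """A fixed-effect subset plus a residual correlation structure."""

    predictors: frozenset[str] = frozenset()
    correlation: CorrelationStructure = AR1
    random_intercept: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.predictors) - set(PREDICTORS)
        if unknown:
            raise ValueError(f"unknown predictors: {sorted(unknown)}")
        object.__setattr__(self, "predictors", frozenset(self.predictors))

    @property
    def label(self) -> str:
        if not self.predictors:
            return "Intercept only"
        ordered = [p for p in PREDICTORS if p in self.predictors]
        return " + ".join(_PRETTY[p].split(" (")[0] for p in ordered)

    def design_columns(self) -> list[str]:
        return [_DESIGN_COLUMNS[p] for p in PREDICTORS if p in self.predictors]


@dataclass(frozen=True)
class ModelFit:
    """A fitted candidate model."""

    model: CandidateModel
    coefficients: dict  # design column -> (beta, se); includes "intercept"
    sigma_group: float
    sigma_resid: float
    phi: tuple[float, ...]
    loglik: float
    k: int
    aic: float
    converged: bool

    def beta(self, predictor: str) -> float | None:
        col = _DESIGN_COLUMNS.get(predictor, predictor)
        pair = self.coefficients.get(col)
        return None if pair is None else pair[0]

    def se(self, predictor: str) -> float | None:
        col = _DESIGN_COLUMNS.get(predictor, predictor)
        pair = self.coefficients.get(col)
        return None if pair is None else pair[1]

    def to_dict(self) -> dict:
        return {
            "model": self.model.label,
            "correlation": self.model.correlation.label,
            "coefficients": {
                k: {"beta": b, "se": s} for k, (b, s) in self.coefficients.items()
            },
            "sigma_group": self.sigma_group,
            "sigma_resid": self.sigma_resid,
            "phi": list(self.phi),
            "loglik": self.loglik,
            "k": self.k,
            "aic": self.aic,
            "converged": self.converged,
        }


def _group_blocks(
    table: pd.DataFrame, columns: list[str]
) -> list[tuple[np.ndarray, np.ndarray]]:
    blocks = []
    for _, grp in table.groupby("group_id", sort=True):
        grp = grp.sort_values("cycle_index")
        y = grp["y"].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(len(grp))]
            + [grp[c].to_numpy(dtype=float) for c in columns]
        )
        blocks.append((y, X))
    return blocks


def _profile_negloglik(
    theta: np.ndarray,
    blocks: list[tuple[np.ndarray, np.ndarray]],
    structure: CorrelationStructure,
    random_intercept: bool,
) -> float:
    """-2x profile log-likelihood over (log lambda, corr params).

    lambda = sigma_group^2 / sigma_resid^2; beta and sigma_resid^2 are
    profiled out analytically.
    """
    val = _gls_pieces(theta, blocks, structure, random_intercept)
    if val is None:
        return 1e10
    n, logdet, rss = val[0], val[1], val[2]
    sigma2 = rss / n
    if sigma2 <= 0 or not np.isfinite(sigma2):
        return 1e10
    ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return -2.0 * ll


def _corr_from_raw(structure: CorrelationStructure, raw: np.ndarray):
    """Map unconstrained optimizer parameters to correlation parameters."""
    if structure.kind == "ar1":
        return np.array([math.tanh(raw[0])])
    return np.asarray(raw, dtype=float)


def _gls_pieces(theta, blocks, structure, random_intercept):
    """(n, sum logdet W, GLS rss, beta, XtWiX) at the given parameters."""
    i = 0
    lam = 0.0
    if random_intercept:
        lam = math.exp(theta[0])
        i = 1
    raw = np.asarray(theta[i:], dtype=float)
    try:
        corr_params = _corr_from_raw(structure, raw)
        sizes = sorted({len(y) for y, _ in blocks})
        corrs = {n: correlation_matrix(structure, n, corr_params) for n in sizes}
    except ValueError:
        return None
    p = blocks[0][1].shape[1]
    XtWiX = np.zeros((p, p))
    XtWiy = np.zeros(p)
    chols = {}
    for n_g in sizes:
        W = lam * np.ones((n_g, n_g)) + corrs[n_g]
        try:
            chols[n_g] = np.linalg.cholesky(W)
        except np.linalg.LinAlgError:
            return None
    # W (hence its Cholesky and log-determinant) depends only on block size
    logdets = {
        n_g: 2.0 * float(np.log(np.diag(L)).sum()) for n_g, L in chols.items()
    }
    n_total = 0
    logdet = 0.0
    yWiy = 0.0
    for y, X in blocks:
        L = chols[len(y)]
        logdet += logdets[len(y)]
        n_total += len(y)
        zy = solve_triangular(L, y, lower=True)
        zX = solve_triangular(L, X, lower=True)
        XtWiX += zX.T @ zX
        XtWiy += zX.T @ zy
        yWiy += zy @ zy
    try:
        beta = np.linalg.solve(XtWiX, XtWiy)
    except np.linalg.LinAlgError:
        return None
    rss = yWiy - beta @ XtWiy
    return n_total, logdet, rss, beta, XtWiX, lam, _corr_from_raw(structure, raw)


def fit_mixed_model(table: pd.DataFrame, model: CandidateModel) -> ModelFit:
    """Fit one candidate model by maximum likelihood.

    The fixed effects and the residual variance are profiled out; the
    optimizer works on (log variance ratio, transformed correlation
    parameters).  ``k`` counts the intercept, the fixed effects, both
    variance components and the correlation parameters.
    """
    columns = model.design_columns()
    blocks = _group_blocks(table, columns)
    if len(blocks) < 2:
        raise ValueError("need at least two groups to fit a mixed model")
    structure = model.correlation
    n_free = (1 if model.random_intercept else 0) + structure.n_params

    if n_free == 0:
        theta_opt = np.empty(0)
        converged = True
    else:
        x0 = np.zeros(n_free)
        if model.random_intercept:
            x0[0] = math.log(0.5)
        if structure.kind == "ar1":
            x0[-1] = np.arctanh(0.2)
        res = optimize.minimize(
            _profile_negloglik,
            x0,
            args=(blocks, structure, model.random_intercept),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000},
        )
        theta_opt = res.x
        converged = bool(res.success and np.isfinite(res.fun))

    pieces = _gls_pieces(theta_opt, blocks, structure, model.random_intercept)
    if pieces is None:
        raise RuntimeError(f"likelihood not evaluable for {model.label}")
    n, logdet, rss, beta, XtWiX, lam, corr_params = pieces
    sigma2 = rss / n
    loglik = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    cov_beta = sigma2 * np.linalg.inv(XtWiX)
    ses = np.sqrt(np.diag(cov_beta))
    names = ["intercept"] + columns
    coefficients = {
        name: (float(b), float(se)) for name, b, se in zip(names, beta, ses)
    }
    k = len(names) + 1 + (1 if model.random_intercept else 0) + structure.n_params
    fit = ModelFit(
        model=model,
        coefficients=coefficients,
        sigma_group=float(math.sqrt(lam * sigma2)),
        sigma_resid=float(math.sqrt(sigma2)),
        phi=tuple(float(v) for v in corr_params),
        loglik=float(loglik),
        k=k,
        aic=float(-2.0 * loglik + 2.0 * k),
        converged=converged,
    )
    if not converged:
        warnings.warn(f"fit did not converge: {model.label}", stacklevel=2)
    return fit


# ---------------------------------------------------------------------------
# Model set, weights, averaging


def all_subsets(
    predictors: Sequence[str] = PREDICTORS,
    correlation: CorrelationStructure = AR1,
) -> list[CandidateModel]:
    """All 2^k predictor subsets (including the null model)."""
    models = []
    preds = list(predictors)
    for r in range(len(preds) + 1):
        for combo in itertools.combinations(preds, r):
            models.append(
                CandidateModel(
                    predictors=frozenset(combo), correlation=correlation
                )
            )
    return models


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2), delta vs the minimum."""
    aics = np.asarray(aics, dtype=float)
    if aics.size == 0:
        raise ValueError("need at least one AIC value")
    delta = aics - np.min(aics)
    raw = np.exp(-0.5 * delta)
    return raw / raw.sum()


@dataclass(frozen=True)
class MultiModelSummary:
    """All-subsets fits with AIC weights, RI and averaged coefficients."""

    fits: tuple[ModelFit, ...]
    delta: tuple[float, ...]
    weights: tuple[float, ...]
    ri: dict  # predictor -> relative importance
    averaged: dict  # predictor -> (beta_bar, unconditional se)

    @property
    def best(self) -> ModelFit:
        return self.fits[int(np.argmin([f.aic for f in self.fits]))]

    def model_table(self) -> pd.DataFrame:
        """AIC ranking table (one row per candidate model)."""
        df = pd.DataFrame(
            {
                "model": [f.model.label for f in self.fits],
                "aic": [f.aic for f in self.fits],
                "delta_aic": self.delta,
                "weight": self.weights,
            }
        )
        return df.sort_values("delta_aic", kind="stable").reset_index(drop=True)

    def coefficient_table(self) -> pd.DataFrame:
        """Averaged coefficient / RI table (one row per predictor)."""
        rows = []
        for p in PREDICTORS:
            beta, se = self.averaged[p]
            rows.append(
                {
                    "variable": _PRETTY[p],
                    "beta": beta,
                    "se": se,
                    "ri": self.ri[p],
                }
            )
        return pd.DataFrame(rows).sort_values(
            "ri", ascending=False, kind="stable"
        ).reset_index(drop=True)


def relative_importance(
    fits: Sequence[ModelFit], weights: Sequence[float]
) -> dict:
    """RI(v) = sum of Akaike weights of the models containing v."""
    ri = {}
    for p in PREDICTORS:
        ri[p] = float(
            sum(w for f, w in zip(fits, weights) if p in f.model.predictors)
        )
    return ri


def model_average(
    fits: Sequence[ModelFit],
    weights: Sequence[float],
    mode: str = "full",
) -> dict:
    """Model-averaged coefficients with unconditional standard errors.

    ``full`` averaging treats a coefficient as 0 (with 0 variance) in models
    that omit its predictor, shrinking weakly supported effects toward zero;
    ``conditional`` averages only over the models containing the predictor.
    The unconditional SE follows the Burnham-Anderson form
    ``sum_i w_i * sqrt(var_i + (beta_i - beta_bar)^2)``.
    """
    if mode not in ("full", "conditional"):
        raise ValueError(f"unknown averaging mode {mode!r}")
    averaged = {}
    for p in PREDICTORS:
        entries = []  # (weight, beta, var)
        for f, w in zip(fits, weights):
            b, s = f.beta(p), f.se(p)
            if b is None:
                if mode == "full":
                    entries.append((w, 0.0, 0.0))
            else:
                entries.append((w, b, s**2))
        wsum = sum(w for w, _, _ in entries)
        if wsum == 0:
            averaged[p] = (0.0, 0.0)
            continue
        beta_bar = sum(w * b for w, b, _ in entries) / wsum
        se = (
            sum(
                w * math.sqrt(v + (b - beta_bar) ** 2) for w, b, v in entries
            )
            / wsum
        )
        averaged[p] = (float(beta_bar), float(se))
    return averaged


def fit_all_subsets(
    table: pd.DataFrame,
    models: Sequence[CandidateModel] | None = None,
    averaging: str = "full",
) -> MultiModelSummary:
    """Fit every candidate model and assemble the multimodel summary.

    Non-converged fits are dropped from the weight normalisation with a
    warning.
    """
    models = all_subsets() if models is None else list(models)
    fits = [fit_mixed_model(table, m) for m in models]
    kept = [f for f in fits if f.converged]
    dropped = len(fits) - len(kept)
    if dropped:
        warnings.warn(
            f"{dropped} non-converged model(s) excluded from weights",
            stacklevel=2,
        )
    if not kept:
        raise RuntimeError("no candidate model converged")
    aics = [f.aic for f in kept]
    weights = akaike_weights(aics)
    delta = tuple(float(a - min(aics)) for a in aics)
    return MultiModelSummary(
        fits=tuple(kept),
        delta=delta,
        weights=tuple(float(w) for w in weights),
        ri=relative_importance(kept, weights),
        averaged=model_average(kept, weights, mode=averaging),
    )


@dataclass(frozen=True)
class AutocorrelationReport:
    """AIC comparison of the global model with and without AR-1 residuals."""

    aic_with_ar1: float
    aic_without: float
    phi: float

    @property
    def prefers_ar1(self) -> bool:
        return self.aic_with_ar1 < self.aic_without

    @property
    def delta(self) -> float:
        return self.aic_without - self.aic_with_ar1


def select_autocorrelation(table: pd.DataFrame) -> AutocorrelationReport:
    """Compare the global (all-predictor) model with vs without AR-1.

    Both fits keep the group random intercept; the one with the smaller AIC
    is recommended.
    """
    global_preds = frozenset(PREDICTORS)
    g1 = fit_mixed_model(table, CandidateModel(global_preds, AR1))
    g2 = fit_mixed_model(table, CandidateModel(global_preds, INDEPENDENT))
    return AutocorrelationReport(
        aic_with_ar1=g1.aic, aic_without=g2.aic, phi=g1.phi[0]
    )
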