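"""Conditional logistic regression for matched case-crossover strata.

Within stratum i (one decedent: case day plus referent days) the per-stratum
intercept is conditioned out, leaving the conditional likelihood

    l(beta) = sum_i [ x_case . beta - log sum_j exp(x_ij . beta) ],

maximised directly by Newton-Raphson with analytic gradient and Hessian and
log-sum-exp stabilisation. Strata whose covariate rows are identical carry no
information about beta (they contribute the constant -log m_i) and are
counted but kept. The likelihood is invariant to any stratum-constant
covariate — exactly the fixed-effect elimination the design relies on.

Model terms are named columns of the long design table produced by
``aerxover.design.build_strata``: PM2.5 enters per 10 µg/m³, temperature per
10 °C, relative humidity per 10 %, day-of-week as six indicators (Sunday
reference), and effect modification as a PM2.5-by-AER product term whose
coefficient is a log-odds per 10 µg/m³ per unit (hour^-1) AER. A smooth-term
linearity check replaces a linear term with an unpenalised cubic B-spline
basis and performs a likelihood-ratio test of the extra curvature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

DOW_NAMES = ("mon", "tue", "wed", "thu", "fri", "sat")  # Sunday = reference


class SeparationError(RuntimeError):
    """The conditional likelihood has no finite maximiser."""


class SingularHessianError(np.linalg.LinAlgError):
    """The observed information is singular at the current iterate."""


@dataclass(frozen=True)
class ModelSpec:
    """Which columns of the design rows enter the linear predictor."""
    covariates: tuple[str, ...] = ("pm10u", "temp10u", "rh10u")
    dow: bool = True
    interaction: tuple[str, str] | None = None   # e.g. ("pm10u", "aer")

    def term_names(self) -> list[str]:
        names = list(self.covariates)
        if self.dow:
            names += [f"dow_{d}" for d in DOW_NAMES]
        if self.interaction is not None:
            names.append(f"{self.interaction[0]}:{self.interaction[1]}")
        return names


@dataclass
class FitResult:
    """Conditional-logistic fit: coefficients, covariance and diagnostics."""
    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    names: list[str]
    n_strata: int
    n_informative: int
    converged: bool
    iterations: int

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(np.sqrt(self.vcov[self.names.index(name),
                                       self.names.index(name)]))

    def cov(self, name_a: str, name_b: str) -> float:
        return float(self.vcov[self.names.index(name_a),
                               self.names.index(name_b)])

    def z(self, name: str) -> float:
        return self.coef(name) / self.se(name)

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.vcov))
        z = self.beta / se
        return pd.DataFrame({
            "coef": self.beta,
            "se": se,
            "or": np.exp(self.beta),
            "or_low": np.exp(self.beta - 1.959963984540054 * se),
            "or_high": np.exp(self.beta + 1.959963984540054 * se),
            "p": 2 * stats.norm.sf(np.abs(z)),
        }, index=self.names)


# ---------------------------------------------------------------------------
# design matrix assembly
# ---------------------------------------------------------------------------

def _derived_columns(rows: pd.DataFrame) -> pd.DataFrame:
    out = rows.copy()
    if "temp10u" not in out.columns and "temp" in out.columns:
        out["temp10u"] = out["temp"] / 10.0
    if "rh10u" not in out.columns and "rh" in out.columns:
        out["rh10u"] = out["rh"] / 10.0
    return out


def build_design_matrix(rows: pd.DataFrame, spec: ModelSpec
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Long design rows -> (y, X, stratum start offsets, term names).

    Rows are sorted by stratum so each stratum occupies a contiguous block;
    ``starts`` indexes the first row of each block.
    """
    df = _derived_columns(rows).sort_values(
        ["person_id"], kind="stable").reset_index(drop=True)
    cols = []
    names = []
    for c in spec.covariates:
        cols.append(df[c].to_numpy(float))
        names.append(c)
    if spec.dow:
        dow = df["dow"].to_numpy(int)
        for k, d in enumerate(DOW_NAMES):     # Monday=0 ... Saturday=5
            cols.append((dow == k).astype(float))
            names.append(f"dow_{d}")
    if spec.interaction is not None:
        a, b = spec.interaction
        cols.append(df[a].to_numpy(float) * df[b].to_numpy(float))
        names.append(f"{a}:{b}")
    X = np.column_stack(cols)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariate values in the design")
    y = df["case"].to_numpy(int)
    _, starts = np.unique(df["person_id"].to_numpy(), return_index=True)
    starts = np.sort(starts)
    return y, X, starts, names


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def conditional_loglik(beta: np.ndarray, y: np.ndarray, X: np.ndarray,
                       starts: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """Conditional log-likelihood with analytic gradient and Hessian.

    ``starts`` marks the first row of each contiguous stratum block; exactly
    one y=1 row per block. All per-stratum sums use segmented reductions, and
    the within-stratum softmax is log-sum-exp stabilised.
    """
    beta = np.asarray(beta, float)
    eta = X @ beta
    gmax = np.maximum.reduceat(eta, starts)
    sizes = np.diff(np.append(starts, len(eta)))
    rep = np.repeat(np.arange(len(starts)), sizes)
    ex = np.exp(eta - gmax[rep])
    denom = np.add.reduceat(ex, starts)
    p = ex / denom[rep]

    ll = float(np.sum(eta[y == 1]) - np.sum(np.log(denom) + gmax))
    resid = y - p
    grad = X.T @ resid
    S = np.add.reduceat(p[:, None] * X, starts, axis=0)     # per-stratum E[x]
    hess = -(X.T @ (p[:, None] * X) - S.T @ S)
    return ll, grad, hess


def count_informative(X: np.ndarray, starts: np.ndarray) -> int:
    """Number of strata with any within-stratum covariate variation."""
    hi = np.maximum.reduceat(X, starts, axis=0)
    lo = np.minimum.reduceat(X, starts, axis=0)
    return int(np.any(hi - lo > 0, axis=1).sum())


# ---------------------------------------------------------------------------
# Newton-Raphson fit
# ---------------------------------------------------------------------------

def fit_matrix(y: np.ndarray, X: np.ndarray, starts: np.ndarray,
               names: list[str] | None = None, max_iter: int = 50,
               grad_tol: float = 1e-8, ll_tol: float = 1e-10,
               separation_bound: float = 15.0, max_halvings: int = 20
               ) -> FitResult:
    """Maximise the conditional likelihood from beta = 0.

    The likelihood is concave, so Newton-Raphson with step-halving converges
    globally unless the data are separated, in which case the maximiser runs
    to infinity and a :class:`SeparationError` is raised once a coefficient
    passes ``separation_bound`` with a non-vanishing gradient.
    """
    names = names or [f"x{i}" for i in range(X.shape[1])]
    n_informative = count_informative(X, starts)
    if n_informative == 0:
        raise ValueError("no informative strata: every covariate is "
                         "within-stratum constant")

    beta = np.zeros(X.shape[1])
    ll, grad, hess = conditional_loglik(beta, y, X, starts)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as err:
            raise SingularHessianError(
                "singular Hessian: collinear covariates or no within-stratum "
                "variation in some term") from err
        new_beta, new_ll = beta, ll
        scale = 1.0
        for _ in range(max_halvings + 1):
            cand = beta + scale * step
            cand_ll, cand_grad, cand_hess = conditional_loglik(
                cand, y, X, starts)
            if np.isfinite(cand_ll) and cand_ll >= ll - 1e-12:
                new_beta, new_ll = cand, cand_ll
                grad, hess = cand_grad, cand_hess
                break
            scale *= 0.5
        rel = abs(new_ll - ll) / (abs(ll) + 1e-300)
        beta, ll = new_beta, new_ll
        if np.max(np.abs(grad)) < grad_tol and rel < ll_tol:
            converged = True
            break
        if np.max(np.abs(beta)) > separation_bound and \
                np.max(np.abs(grad)) > grad_tol:
            raise SeparationError(
                "separation detected: a coefficient exceeded "
                f"{separation_bound} with a non-vanishing gradient")

    try:
        vcov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError as err:
        raise SingularHessianError("singular Hessian at the optimum") from err

    return FitResult(beta=beta, vcov=vcov, loglik=ll, names=list(names),
                     n_strata=len(starts), n_informative=n_informative,
                     converged=converged, iterations=it)


def fit(spec: ModelSpec, rows: pd.DataFrame, **kwargs) -> FitResult:
    """Fit a :class:`ModelSpec` on long design rows."""
    y, X, starts, names = build_design_matrix(rows, spec)
    return fit_matrix(y, X, starts, names, **kwargs)


# ---------------------------------------------------------------------------
# tests on fits
# ---------------------------------------------------------------------------

@dataclass
class LRTest:
    statistic: float
    df: int
    pvalue: float


def lr_test(full: FitResult, reduced: FitResult, df: int | None = None
            ) -> LRTest:
    """Likelihood-ratio test of a reduced model nested in a full model.

    ``df`` defaults to the parameter-count difference; pass it explicitly for
    spline augmentations where term names do not align. Raises when the
    reduced model is not nested by name (unless df is given).
    """
    if df is None:
        if not set(reduced.names) <= set(full.names):
            raise ValueError("models are not nested by term names; "
                             "pass df explicitly if nesting holds by span")
        df = len(full.names) - len(reduced.names)
    if df < 0:
        raise ValueError("full model has fewer parameters than reduced")
    stat = 2.0 * (full.loglik - reduced.loglik)
    stat = max(stat, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return LRTest(statistic=stat, df=df, pvalue=p)


# ---------------------------------------------------------------------------
# spline linearity check
# ---------------------------------------------------------------------------

def bspline_basis(x: np.ndarray, n_knots: int = 4, degree: int = 3,
                  drop_first: bool = True) -> np.ndarray:
    """Unpenalised B-spline basis with interior knots at quantiles.

    The raw basis is a partition of unity, so its columns sum to a constant
    that the conditional likelihood cannot identify; the first column is
    dropped by default to keep the information matrix nonsingular. Raises
    when the covariate has too few distinct values to place strictly
    increasing knots.
    """
    x = np.asarray(x, float)
    lo, hi = x.min(), x.max()
    interior = np.quantile(x, np.linspace(0, 1, n_knots + 2)[1:-1])
    knots = np.r_[lo, interior, hi]
    if np.any(np.diff(knots) <= 0):
        raise ValueError("insufficient unique covariate values for "
                         f"{n_knots} interior knots")
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    B = BSpline.design_matrix(x, t, degree, extrapolate=True).toarray()
    return B[:, 1:] if drop_first else B


def nonlinearity_check(spec: ModelSpec, rows: pd.DataFrame,
                       target: str = "pm10u", n_knots: int = 4,
                       degree: int = 3) -> LRTest:
    """LR test of curvature in a term assumed linear.

    target='pm10u' (or any main-effect column): the linear term is replaced
    by a B-spline basis in that covariate. target='aer_x_pm': the linear
    PM-by-AER product term is replaced by PM times a B-spline basis in AER,
    testing whether effect modification is linear in AER while the PM main
    effect stays linear. The declared significance level for nonlinearity is
    0.05. Degenerate empty bases give p = 1.
    """
    df_rows = _derived_columns(rows)
    if target == "aer_x_pm":
        if spec.interaction is None:
            raise ValueError("interaction term required for target aer_x_pm")
        a, b = spec.interaction                      # (pm10u, aer)
        basis = bspline_basis(df_rows[b].to_numpy(float), n_knots, degree)
        if basis.shape[1] == 0:
            return LRTest(0.0, 0, 1.0)
        aug = df_rows.copy()
        bnames = []
        for k in range(basis.shape[1]):
            col = f"_sp_{b}_{k}"
            aug[col] = df_rows[a].to_numpy(float) * basis[:, k]
            bnames.append(col)
        full_spec = ModelSpec(covariates=tuple(spec.covariates) + tuple(bnames),
                              dow=spec.dow, interaction=None)
        reduced = fit(spec, rows)
        full = fit(full_spec, aug)
        return lr_test(full, reduced, df=basis.shape[1] - 1)

    if target not in spec.covariates:
        raise ValueError(f"{target!r} is not a covariate of the model")
    basis = bspline_basis(df_rows[target].to_numpy(float), n_knots, degree)
    if basis.shape[1] == 0:
        return LRTest(0.0, 0, 1.0)
    aug = df_rows.copy()
    bnames = []
    for k in range(basis.shape[1]):
        col = f"_sp_{target}_{k}"
        aug[col] = basis[:, k]
        bnames.append(col)
    others = tuple(c for c in spec.covariates if c != target)
    full_spec = ModelSpec(covariates=others + tuple(bnames), dow=spec.dow,
                          interaction=spec.interaction)
    reduced = fit(spec, rows)
    full = fit(full_spec, aug)
    return lr_test(full, reduced, df=basis.shape[1] - 1)
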