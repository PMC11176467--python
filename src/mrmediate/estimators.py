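"""Causal-effect estimators for two-sample Mendelian randomization.

Five methods operate on per-SNP summary effects (exposure beta ``bx`` with
SE ``sx``, outcome beta ``by`` with SE ``sy``): the inverse-variance-weighted
(IVW) precision-weighted mean of Wald ratios, MR-Egger weighted regression
with a free pleiotropy intercept, the (penalized) weighted median, and a
profile maximum-likelihood estimator. Each is exposed both as an
sklearn-style estimator class (``fit`` on exposure betas ``X`` and outcome
betas ``y`` with SE keywords; fitted attributes ``beta_``, ``se_``, ...) and
as a module-level function consuming a :class:`~mrmediate.gwas_io.HarmonizedDataset`.

All effects are on the log-odds (or trait-SD) scale; odds ratios are views
produced by :func:`to_odds_ratio`, never stored as primary results.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from ._stats import chi2_sf, normal_ci, two_sided_normal_p
from .exceptions import (
    ConvergenceError,
    DegenerateWeightsError,
    EmptyInputError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from .gwas_io import HarmonizedDataset


@dataclass(frozen=True)
class OddsRatioView:
    """Exponentiated view of a log-odds estimate and its CI."""

    or_point: float
    or_low: float
    or_high: float


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log-odds scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None

    def to_odds_ratio(self) -> OddsRatioView:
        return OddsRatioView(
            or_point=float(np.exp(self.beta)),
            or_low=float(np.exp(self.ci_low)),
            or_high=float(np.exp(self.ci_high)),
        )

    def as_row(self) -> dict:
        """Flat dict for tidy per-method TSV rows (Table-2 shape)."""
        orv = self.to_odds_ratio()
        return {
            "method": self.method,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "or": orv.or_point,
            "or_low": orv.or_low,
            "or_high": orv.or_high,
            "pval": self.pval,
            "q_stat": self.q_stat,
            "q_df": self.q_df,
            "q_pval": self.q_pval,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_pval": self.intercept_pval,
        }


def to_odds_ratio(e: MREstimate) -> OddsRatioView:
    """Exponentiate an estimate's beta and CI bounds."""
    return e.to_odds_ratio()


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr.ravel()
    if arr.ndim != 1:
        raise ValueError(f"{name} must be a 1-d array (or single column)")
    return arr


def _check_inputs(X, y, outcome_se, exposure_se=None, min_snps=1, method=""):
    bx = _as_1d(X, "X")
    by = _as_1d(y, "y")
    if outcome_se is None:
        raise ValueError("outcome_se is required")
    sy = _as_1d(outcome_se, "outcome_se")
    sx = None if exposure_se is None else _as_1d(exposure_se, "exposure_se")
    sizes = {bx.size, by.size, sy.size} | ({sx.size} if sx is not None else set())
    if len(sizes) != 1:
        raise ValueError("X, y and SE arrays must have equal length")
    if bx.size == 0:
        raise EmptyInputError(f"{method or 'estimator'} received no instruments")
    if bx.size < min_snps:
        raise InsufficientInstrumentsError(
            f"{method} requires at least {min_snps} instruments, got {bx.size}"
        )
    if np.any(sy <= 0) or (sx is not None and np.any(sx <= 0)):
        raise ValueError("standard errors must be strictly positive")
    if np.any(bx == 0):
        raise UndefinedRatioError(
            "zero exposure beta makes the Wald ratio undefined"
        )
    return bx, by, sy, sx


class _MRBase(BaseEstimator, RegressorMixin):
    """Shared surface: fit from arrays or a harmonized dataset, predict
    outcome betas from exposure betas, export an :class:`MREstimate`."""

    alpha: float

    def fit_dataset(self, d: HarmonizedDataset):
        return self.fit(
            d.beta_exposure,
            d.beta_outcome,
            exposure_se=d.se_exposure,
            outcome_se=d.se_outcome,
        )

    def predict(self, X) -> np.ndarray:
        bx = _as_1d(X, "X")
        intercept = getattr(self, "intercept_", 0.0)
        return intercept + self.beta_ * bx

    def _finish(self, method: str) -> None:
        self.method_ = method
        self.ci_low_, self.ci_high_ = normal_ci(self.beta_, self.se_, self.alpha)
        self.pval_ = float(two_sided_normal_p(self.beta_ / self.se_))

    def to_estimate(self) -> MREstimate:
        return MREstimate(
            method=self.method_,
            beta=float(self.beta_),
            se=float(self.se_),
            ci_low=float(self.ci_low_),
            ci_high=float(self.ci_high_),
            pval=float(self.pval_),
            n_snps=int(self.n_snps_),
            intercept=getattr(self, "intercept_fit_", None),
            intercept_se=getattr(self, "intercept_se_", None),
            intercept_pval=getattr(self, "intercept_pval_", None),
            q_stat=getattr(self, "q_stat_", None),
            q_df=getattr(self, "q_df_", None),
            q_pval=getattr(self, "q_pval_", None),
        )


def _ivw_core(bx, by, sy):
    """Precision-weighted mean of Wald ratios; returns (beta, se_fixed, Q)."""
    theta = by / bx
    w = bx**2 / sy**2
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (theta - beta) ** 2))
    return beta, se_fixed, q, theta, w


class IVWEstimator(_MRBase):
    """Inverse-variance-weighted estimator.

    The point estimate is the precision-weighted mean of per-SNP Wald ratios
    with weights ``w_j = bx_j² / sy_j²`` — algebraically the zero-intercept
    weighted least-squares slope of ``by`` on ``bx``. ``mode='fixed'`` uses
    SE ``(Σw)^(-1/2)``; ``mode='random'`` inflates it multiplicatively by
    ``sqrt(max(1, Q/(J−1)))``; ``mode='auto'`` picks random effects iff
    Cochran's Q has p < 0.05, the rule used for headline results.
    """

    def __init__(self, mode: str = "auto", alpha: float = 0.05):
        self.mode = mode
        self.alpha = alpha

    def fit(self, X, y, *, outcome_se=None, exposure_se=None):
        if self.mode not in ("fixed", "random", "auto"):
            raise ValueError(f"unknown IVW mode '{self.mode}'")
        bx, by, sy, _ = _check_inputs(X, y, outcome_se, exposure_se, 1, "IVW")
        j = bx.size
        beta, se_fixed, q, _, _ = _ivw_core(bx, by, sy)
        self.n_snps_ = j
        self.beta_ = beta
        self.intercept_ = 0.0
        self.q_stat_ = q
        self.q_df_ = max(j - 1, 0)
        self.q_pval_ = float(chi2_sf(q, j - 1)) if j >= 2 else 1.0
        if j >= 2:
            inflation = np.sqrt(max(1.0, q / (j - 1)))
        else:
            inflation = 1.0
        if self.mode == "fixed":
            self.se_, resolved = se_fixed, "ivw_fixed"
        elif self.mode == "random":
            self.se_, resolved = se_fixed * inflation, "ivw_random"
        else:
            if self.q_pval_ < 0.05:
                self.se_, resolved = se_fixed * inflation, "ivw_random"
            else:
                self.se_, resolved = se_fixed, "ivw_fixed"
        self._finish(resolved)
        return self


class EggerEstimator(_MRBase):
    """MR-Egger: weighted regression of outcome on exposure betas with a
    free intercept (weights ``1/sy²``).

    The slope is the pleiotropy-adjusted causal estimate; a nonzero intercept
    indicates directional horizontal pleiotropy. Each SNP is re-signed so its
    exposure beta is non-negative before fitting (the conventional
    orientation), and both coefficient SEs are inflated multiplicatively by
    ``sqrt(max(1, Q_egger/(J−2)))``.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y, *, outcome_se=None, exposure_se=None):
        bx, by, sy, _ = _check_inputs(X, y, outcome_se, exposure_se, 3, "MR-Egger")
        j = bx.size
        sign = np.where(bx < 0, -1.0, 1.0)
        bxs, bys = sign * bx, sign * by
        design = sm.add_constant(bxs)
        fit = sm.WLS(bys, design, weights=1.0 / sy**2).fit()
        q = float(fit.ssr)  # weighted residual sum of squares
        inflation = max(1.0, q / (j - 2))
        ses = np.sqrt(np.diag(fit.normalized_cov_params) * inflation)
        self.n_snps_ = j
        self.beta_ = float(fit.params[1])
        self.se_ = float(ses[1])
        self.intercept_ = float(fit.params[0])
        self.intercept_fit_ = self.intercept_
        self.intercept_se_ = float(ses[0])
        self.intercept_pval_ = float(
            two_sided_normal_p(self.intercept_ / self.intercept_se_)
        ) if self.intercept_se_ > 0 else 1.0
        self.q_stat_ = q
        self.q_df_ = j - 2
        self.q_pval_ = float(chi2_sf(q, j - 2))
        self._finish("egger")
        return self


def _weighted_median_batch(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted empirical-median by interpolation, batched over rows.

    ``theta`` and ``w`` are (B, J); cumulative standardized weights
    ``s_j = (Σ_{k≤j} w_k − w_j/2) / Σ w`` are interpolated at 0.5.
    """
    order = np.argsort(theta, axis=1)
    th = np.take_along_axis(theta, order, axis=1)
    ws = np.take_along_axis(w, order, axis=1)
    total = ws.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise DegenerateWeightsError("all instrument weights are zero")
    s = (np.cumsum(ws, axis=1) - ws / 2.0) / total
    b, j = th.shape
    idx = np.sum(s < 0.5, axis=1)  # first index with s >= 0.5
    out = np.empty(b)
    low = idx == 0
    high = idx == j
    out[low] = th[low, 0]
    out[high] = th[high, -1]
    mid = ~(low | high)
    if np.any(mid):
        i = idx[mid]
        rows = np.nonzero(mid)[0]
        x0, x1 = s[rows, i - 1], s[rows, i]
        y0, y1 = th[rows, i - 1], th[rows, i]
        span = np.where(x1 > x0, x1 - x0, 1.0)
        out[mid] = y0 + (0.5 - x0) * (y1 - y0) / span
    return out


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    return float(_weighted_median_batch(theta[None, :], w[None, :])[0])


def _penalize_weights(theta, w, penalty_constant):
    """Down-weight SNPs by their one-df heterogeneity contribution.

    Each SNP's Q contribution around the unpenalized weighted median is
    referred to a chi-square(1) upper tail q_j; the weight is multiplied by
    min(1, penalty_constant * q_j), so only clearly outlying SNPs lose weight.
    """
    wm = _weighted_median_batch(theta, w)
    contrib = w * (theta - wm[:, None]) ** 2
    qp = chi2_sf(contrib, 1)
    return w * np.minimum(1.0, penalty_constant * qp)


class WeightedMedianEstimator(_MRBase):
    """(Penalized) weighted-median estimator of the causal effect.

    The point estimate is the weighted empirical median of per-SNP Wald
    ratios with inverse-variance weights: consistent whenever valid
    instruments carry more than half the weight. The penalized variant
    multiplies each weight by ``min(1, penalty_constant·q_j)`` with ``q_j``
    the chi-square(1) upper tail of the SNP's heterogeneity contribution.
    The SE is the standard deviation of the estimate over ``n_boot``
    parametric-bootstrap resamples (per-SNP betas redrawn from their normal
    sampling distributions), which is why the exposure SEs are required.
    """

    def __init__(
        self,
        penalized: bool = False,
        penalty_constant: float = 20.0,
        n_boot: int = 1000,
        random_state: int | None = 0,
        alpha: float = 0.05,
    ):
        self.penalized = penalized
        self.penalty_constant = penalty_constant
        self.n_boot = n_boot
        self.random_state = random_state
        self.alpha = alpha

    def _point(self, bx, by, sy):
        theta = (by / bx)[None, :]
        w = (bx**2 / sy**2)[None, :]
        if self.penalized:
            w = _penalize_weights(theta, w, self.penalty_constant)
            if np.all(w <= 0):
                raise DegenerateWeightsError(
                    "penalization removed all instrument weight"
                )
        return _weighted_median_batch(theta, w)[0]

    def fit(self, X, y, *, outcome_se=None, exposure_se=None):
        bx, by, sy, sx = _check_inputs(
            X, y, outcome_se, exposure_se, 3, "weighted median"
        )
        if sx is None:
            raise ValueError("exposure_se is required for the bootstrap SE")
        self.n_snps_ = bx.size
        self.beta_ = float(self._point(bx, by, sy))
        self.intercept_ = 0.0

        rng = np.random.default_rng(self.random_state)
        b = int(self.n_boot)
        bx_star = bx + sx * rng.standard_normal((b, bx.size))
        by_star = by + sy * rng.standard_normal((b, bx.size))
        theta = by_star / bx_star
        w = bx_star**2 / sy**2
        if self.penalized:
            w = _penalize_weights(theta, w, self.penalty_constant)
        boots = _weighted_median_batch(theta, w)
        self.boot_estimates_ = boots
        self.se_ = float(np.std(boots, ddof=1))
        self._finish("penalized_weighted_median" if self.penalized
                     else "weighted_median")
        return self


class MaximumLikelihoodEstimator(_MRBase):
    """Profile maximum-likelihood estimator.

    Observed ``(bx_j, by_j)`` are modelled as independent normals around
    ``(γ_j, θ·γ_j)`` with known SEs. Profiling out the nuisance instrument
    strengths γ_j gives the concentrated objective
    ``f(θ) = ½ Σ (by_j − θ·bx_j)² / (sy_j² + θ²·sx_j²)``, minimized
    numerically from the IVW starting value; the SE comes from the numeric
    second derivative (observed information) at the optimum.
    """

    def __init__(self, max_iter: int = 500, alpha: float = 0.05):
        self.max_iter = max_iter
        self.alpha = alpha

    def fit(self, X, y, *, outcome_se=None, exposure_se=None):
        bx, by, sy, sx = _check_inputs(
            X, y, outcome_se, exposure_se, 2, "maximum likelihood"
        )
        if sx is None:
            raise ValueError("exposure_se is required for the likelihood")

        def nll(theta: float) -> float:
            var = sy**2 + theta**2 * sx**2
            return 0.5 * float(np.sum((by - theta * bx) ** 2 / var))

        theta0, _, _, _, _ = _ivw_core(bx, by, sy)
        res = optimize.minimize(
            lambda t: nll(t[0]),
            x0=[theta0],
            method="Nelder-Mead",
            options={"maxiter": self.max_iter, "xatol": 1e-10, "fatol": 1e-12},
        )
        if not res.success:
            raise ConvergenceError(
                f"ML optimizer did not converge: {res.message}", diagnostics=res
            )
        theta_hat = float(res.x[0])
        h = 1e-5 * (1.0 + abs(theta_hat))
        info = (nll(theta_hat + h) - 2 * nll(theta_hat) + nll(theta_hat - h)) / h**2
        if not np.isfinite(info) or info <= 0:
            raise ConvergenceError(
                "observed information non-positive at the ML optimum",
                diagnostics=res,
            )
        self.n_snps_ = bx.size
        self.beta_ = theta_hat
        self.intercept_ = 0.0
        self.se_ = float(info**-0.5)
        self._finish("max_likelihood")
        return self


# ---------------------------------------------------------------------------
# Functional surface over HarmonizedDataset
# ---------------------------------------------------------------------------

def wald_ratio(bx: float, sx: float, by: float, sy: float,
               alpha: float = 0.05) -> MREstimate:
    """Single-SNP Wald ratio: beta = by/bx with first-order SE sy/|bx|.

    ``sx`` is accepted for interface symmetry but does not enter the
    first-order SE.
    """
    if bx == 0:
        raise UndefinedRatioError("wald_ratio undefined for bx = 0")
    beta = by / bx
    se = sy / abs(bx)
    lo, hi = normal_ci(beta, se, alpha)
    return MREstimate(
        method="wald",
        beta=float(beta),
        se=float(se),
        ci_low=lo,
        ci_high=hi,
        pval=float(two_sided_normal_p(beta / se)),
        n_snps=1,
    )


def ivw(d: HarmonizedDataset, mode: str = "auto", alpha: float = 0.05) -> MREstimate:
    """IVW causal estimate from a harmonized dataset (see :class:`IVWEstimator`)."""
    return IVWEstimator(mode=mode, alpha=alpha).fit_dataset(d).to_estimate()


def egger(d: HarmonizedDataset, alpha: float = 0.05) -> MREstimate:
    """MR-Egger slope/intercept fit (see :class:`EggerEstimator`)."""
    return EggerEstimator(alpha=alpha).fit_dataset(d).to_estimate()


def weighted_median(
    d: HarmonizedDataset,
    penalized: bool = False,
    n_boot: int = 1000,
    seed: int | None = 0,
    penalty_constant: float = 20.0,
    alpha: float = 0.05,
) -> MREstimate:
    """(Penalized) weighted-median estimate (see :class:`WeightedMedianEstimator`)."""
    est = WeightedMedianEstimator(
        penalized=penalized,
        penalty_constant=penalty_constant,
        n_boot=n_boot,
        random_state=seed,
        alpha=alpha,
    )
    return est.fit_dataset(d).to_estimate()


def max_likelihood(d: HarmonizedDataset, alpha: float = 0.05) -> MREstimate:
    """Profile-likelihood estimate (see :class:`MaximumLikelihoodEstimator`)."""
    return MaximumLikelihoodEstimator(alpha=alpha).fit_dataset(d).to_estimate()


METHOD_REGISTRY = {
    "ivw": lambda d, seed=None: ivw(d, mode="auto"),
    "ivw_fixed": lambda d, seed=None: ivw(d, mode="fixed"),
    "ivw_random": lambda d, seed=None: ivw(d, mode="random"),
    "egger": lambda d, seed=None: egger(d),
    "weighted_median": lambda d, seed=None: weighted_median(d, seed=seed),
    "penalized_weighted_median": lambda d, seed=None: weighted_median(
        d, penalized=True, seed=seed
    ),
    "max_likelihood": lambda d, seed=None: max_likelihood(d),
}


def run_methods(d: HarmonizedDataset, methods, seed: int | None = 0):
    """Run several named methods on one dataset; returns a list of estimates."""
    out = []
    for name in methods:
        if name not in METHOD_REGISTRY:
            raise ValueError(f"unknown MR method '{name}'")
        out.append(METHOD_REGISTRY[name](d, seed=seed))
    return out
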