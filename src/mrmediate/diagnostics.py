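"""Heterogeneity, pleiotropy and influence diagnostics for MR analyses.

Cochran's Q (under the IVW or Egger model), the Egger-intercept pleiotropy
test, leave-one-out influence analysis, and tidy per-SNP tables for forest
and funnel plots. Tables are plain DataFrames ready for export; rendering
lives in :mod:`mrmediate.plots`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import chi2_sf
from .estimators import (
    EggerEstimator,
    MREstimate,
    egger,
    ivw,
    wald_ratio,
)
from .exceptions import InsufficientInstrumentsError
from .gwas_io import HarmonizedDataset


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its per-SNP decomposition."""

    method: str  # "ivw" or "egger"
    q_stat: float
    q_df: int
    q_pval: float
    per_snp_q: np.ndarray
    snp_ids: list = field(default_factory=list)


def cochran_q(d: HarmonizedDataset, method: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q heterogeneity statistic under the IVW or Egger model.

    Per-SNP contributions are ``w_j (θ_j − fitted_j)²`` with the fitted value
    from the respective model: the pooled IVW slope (df = J−1) or the Egger
    regression line (df = J−2).
    """
    j = d.n_snps
    bx, by = d.beta_exposure, d.beta_outcome
    sy = d.se_outcome
    if method == "ivw":
        if j < 2:
            raise InsufficientInstrumentsError(
                f"Cochran's Q (IVW) needs at least 2 instruments, got {j}"
            )
        theta = by / bx
        w = bx**2 / sy**2
        pooled = float(np.sum(w * theta) / np.sum(w))
        per = w * (theta - pooled) ** 2
        df = j - 1
    elif method == "egger":
        if j < 3:
            raise InsufficientInstrumentsError(
                f"Cochran's Q (Egger) needs at least 3 instruments, got {j}"
            )
        fit = EggerEstimator().fit_dataset(d)
        sign = np.where(bx < 0, -1.0, 1.0)
        resid = sign * by - (fit.intercept_ + fit.beta_ * sign * bx)
        per = (resid / sy) ** 2
        df = j - 2
    else:
        raise ValueError(f"unknown heterogeneity model '{method}'")
    q = float(per.sum())
    return HeterogeneityResult(
        method=method,
        q_stat=q,
        q_df=df,
        q_pval=float(chi2_sf(q, df)),
        per_snp_q=per,
        snp_ids=d.snp_ids,
    )


@dataclass(frozen=True)
class InterceptTest:
    """MR-Egger intercept triple with the directional-pleiotropy flag."""

    intercept: float
    se: float
    pval: float
    pleiotropic: bool  # p < threshold


def egger_intercept_test(
    d: HarmonizedDataset, threshold: float = 0.05
) -> InterceptTest:
    """Test for directional horizontal pleiotropy via the Egger intercept."""
    e = egger(d)
    return InterceptTest(
        intercept=float(e.intercept),
        se=float(e.intercept_se),
        pval=float(e.intercept_pval),
        pleiotropic=bool(e.intercept_pval < threshold),
    )


@dataclass
class LeaveOneOutResult:
    """Leave-one-out re-estimates, one row per dropped SNP."""

    table: pd.DataFrame  # snp, beta, se, ci_low, ci_high, flagged
    full: MREstimate
    flagged_snps: list

    @property
    def any_influential(self) -> bool:
        return bool(self.flagged_snps)


def leave_one_out(d: HarmonizedDataset, mode: str = "auto") -> LeaveOneOutResult:
    """Re-estimate (IVW) with each SNP removed in turn.

    A SNP is flagged as influential when its removal moves the estimate
    outside the all-SNP confidence interval, when the all-SNP estimate falls
    outside the leave-one-out CI, or when the sign flips. The second
    direction matters because a strong outlier inflates the random-effects
    full CI enough to swallow its own removal; the leave-one-out CI (clean
    of the outlier) still exposes it.
    """
    if d.n_snps < 2:
        raise InsufficientInstrumentsError(
            f"leave-one-out needs at least 2 instruments, got {d.n_snps}"
        )
    full = ivw(d, mode=mode)
    rows = []
    flagged = []
    for snp in d.snp_ids:
        sub = d.drop_snps([snp])
        est = ivw(sub, mode=mode)
        outside = not (full.ci_low <= est.beta <= full.ci_high)
        full_outside_loo = not (est.ci_low <= full.beta <= est.ci_high)
        sign_flip = np.sign(est.beta) != np.sign(full.beta) and full.beta != 0
        is_flagged = bool(outside or full_outside_loo or sign_flip)
        if is_flagged:
            flagged.append(snp)
        rows.append(
            {
                "snp": snp,
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "flagged": is_flagged,
            }
        )
    return LeaveOneOutResult(
        table=pd.DataFrame(rows), full=full, flagged_snps=flagged
    )


def single_snp_forest(d: HarmonizedDataset) -> pd.DataFrame:
    """Per-SNP Wald estimates plus IVW (and Egger, when J ≥ 3) summary rows.

    Tidy table for forest plotting; column ``kind`` distinguishes ``snp``
    rows from ``summary`` rows.
    """
    if d.n_snps < 1:
        raise InsufficientInstrumentsError("forest table needs ≥ 1 instrument")
    rows = []
    for snp, bx, sx, by, sy in zip(
        d.snp_ids, d.beta_exposure, d.se_exposure, d.beta_outcome, d.se_outcome
    ):
        est = wald_ratio(bx, sx, by, sy)
        rows.append(
            {
                "label": snp,
                "kind": "snp",
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    summaries = [("IVW", ivw(d))]
    if d.n_snps >= 3:
        summaries.append(("MR-Egger", egger(d)))
    for label, est in summaries:
        rows.append(
            {
                "label": label,
                "kind": "summary",
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FunnelData:
    """Per-SNP ratio/precision table with a quantitative symmetry summary."""

    table: pd.DataFrame  # snp, ratio, precision
    skewness: float
    symmetric: bool
    threshold: float


def funnel_data(d: HarmonizedDataset, skew_threshold: float = 0.5) -> FunnelData:
    """Funnel-plot data: Wald ratios against precision (1/SE of the ratio).

    Symmetry is summarized by the precision-weighted skewness of the ratios
    around the IVW estimate; |skewness| below ``skew_threshold`` is reported
    as symmetric (no sign of directional pleiotropy).
    """
    if d.n_snps < 1:
        raise InsufficientInstrumentsError("funnel table needs ≥ 1 instrument")
    theta = d.beta_outcome / d.beta_exposure
    se_ratio = d.se_outcome / np.abs(d.beta_exposure)
    precision = 1.0 / se_ratio
    table = pd.DataFrame({"snp": d.snp_ids, "ratio": theta, "precision": precision})
    center = ivw(d).beta
    w = precision**2
    m2 = float(np.sum(w * (theta - center) ** 2) / np.sum(w))
    m3 = float(np.sum(w * (theta - center) ** 3) / np.sum(w))
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    return FunnelData(
        table=table,
        skewness=float(skew),
        symmetric=bool(abs(skew) < skew_threshold),
        threshold=skew_threshold,
    )
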