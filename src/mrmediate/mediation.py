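"""Two-step MR mediation: total, direct, indirect effects, proportion mediated.

The total effect β1 (exposure→outcome), the exposure→mediator effect β2 and
the mediator→outcome effect β3 each come from a separate two-sample MR
analysis. The indirect effect is the coefficient product β2·β3 with a
first-order (Sobel-type) delta-method SE — the covariance term is zero
because the two steps use non-overlapping two-sample estimates — the direct
effect is the difference β1 − β2·β3, and the proportion mediated is
(β2·β3)/β1, all on the log-odds scale.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import normal_ci, two_sided_normal_p
from .estimators import MREstimate
from .exceptions import MRMediateError

logger = logging.getLogger(__name__)


class ProportionUndefinedError(MRMediateError):
    """Total effect is zero, so the proportion mediated is undefined."""


@dataclass(frozen=True)
class MediationResult:
    """Mediation decomposition for one exposure–mediator–outcome triple."""

    beta1: float
    se1: float
    beta2: float
    se2: float
    beta3: float
    se3: float
    indirect: float
    indirect_se: float
    indirect_ci_low: float
    indirect_ci_high: float
    indirect_pval: float
    direct: float
    direct_se: float
    direct_ci_low: float
    direct_ci_high: float
    proportion: float | None
    proportion_se: float | None
    proportion_ci_low: float | None
    proportion_ci_high: float | None
    consistent: bool  # |β2·β3| < |β1|
    label: str = ""

    def as_row(self) -> dict:
        row = {
            "label": self.label,
            "beta1_total": self.beta1,
            "se1": self.se1,
            "beta2_exposure_mediator": self.beta2,
            "se2": self.se2,
            "beta3_mediator_outcome": self.beta3,
            "se3": self.se3,
            "indirect": self.indirect,
            "indirect_se": self.indirect_se,
            "indirect_ci_low": self.indirect_ci_low,
            "indirect_ci_high": self.indirect_ci_high,
            "indirect_pval": self.indirect_pval,
            "direct": self.direct,
            "direct_se": self.direct_se,
            "direct_ci_low": self.direct_ci_low,
            "direct_ci_high": self.direct_ci_high,
            "proportion_mediated": self.proportion,
            "proportion_se": self.proportion_se,
            "proportion_ci_low": self.proportion_ci_low,
            "proportion_ci_high": self.proportion_ci_high,
            "consistent": self.consistent,
        }
        return row


def _coef(est: "MREstimate | tuple[float, float]") -> tuple[float, float]:
    if isinstance(est, MREstimate):
        return float(est.beta), float(est.se)
    beta, se = est
    return float(beta), float(se)


def two_step_mediation(
    total,
    exp_to_med,
    med_to_out,
    alpha: float = 0.05,
    label: str = "",
    require_proportion: bool = True,
) -> MediationResult:
    """Product-of-coefficients mediation decomposition with delta-method SEs.

    Parameters
    ----------
    total, exp_to_med, med_to_out
        The β1, β2, β3 estimates — :class:`MREstimate` objects or plain
        ``(beta, se)`` pairs, all on the same log-odds scale.
    alpha
        CI level for the normal-approximation intervals.
    require_proportion
        When the total effect is zero the proportion mediated is undefined;
        with this flag a :class:`ProportionUndefinedError` is raised,
        otherwise proportion fields come back as ``None``.

    Notes
    -----
    indirect = β2·β3, SE = sqrt(β3²·se2² + β2²·se3²) (first-order delta,
    zero covariance across the two independent samples);
    direct = β1 − β2·β3, SE = sqrt(se1² + indirect_se²);
    proportion = indirect/β1, with a delta-method SE on the ratio that is
    approximate (and reported as such). A result with |indirect| ≥ |β1| is
    returned with ``consistent=False`` and a logged warning, since it
    signals a logical inconsistency in the inputs.
    """
    beta1, se1 = _coef(total)
    beta2, se2 = _coef(exp_to_med)
    beta3, se3 = _coef(med_to_out)

    indirect = beta2 * beta3
    indirect_se = float(np.sqrt(beta3**2 * se2**2 + beta2**2 * se3**2))
    direct = beta1 - indirect
    direct_se = float(np.sqrt(se1**2 + indirect_se**2))

    ind_lo, ind_hi = normal_ci(indirect, indirect_se, alpha)
    dir_lo, dir_hi = normal_ci(direct, direct_se, alpha)
    if indirect_se > 0:
        indirect_pval = float(two_sided_normal_p(indirect / indirect_se))
    else:
        indirect_pval = 1.0 if indirect == 0 else float(two_sided_normal_p(np.inf))

    if beta1 == 0:
        if require_proportion:
            raise ProportionUndefinedError(
                "total effect is zero; proportion mediated undefined"
            )
        proportion = proportion_se = prop_lo = prop_hi = None
    else:
        proportion = indirect / beta1
        # Delta method on the ratio, zero covariance between numerator and
        # denominator; approximate, and reported as such. Written without
        # dividing by the (possibly tiny) indirect effect.
        proportion_se = float(
            np.hypot(indirect_se / beta1, indirect * se1 / beta1**2)
        )
        prop_lo, prop_hi = normal_ci(proportion, proportion_se, alpha)

    consistent = abs(indirect) < abs(beta1)
    if not consistent:
        logger.warning(
            "mediation triple %s: |indirect| = %.4g >= |total| = %.4g — "
            "possible logical inconsistency in inputs",
            label or "<unlabelled>",
            abs(indirect),
            abs(beta1),
        )

    return MediationResult(
        beta1=beta1,
        se1=se1,
        beta2=beta2,
        se2=se2,
        beta3=beta3,
        se3=se3,
        indirect=float(indirect),
        indirect_se=indirect_se,
        indirect_ci_low=ind_lo,
        indirect_ci_high=ind_hi,
        indirect_pval=indirect_pval,
        direct=float(direct),
        direct_se=direct_se,
        direct_ci_low=dir_lo,
        direct_ci_high=dir_hi,
        proportion=proportion,
        proportion_se=proportion_se,
        proportion_ci_low=prop_lo,
        proportion_ci_high=prop_hi,
        consistent=bool(consistent),
        label=label,
    )


def mediation_report(results, labels=None) -> pd.DataFrame:
    """Tidy table: one row per exposure–mediator–outcome triple.

    ``labels``, when given, overrides the labels stored on the results
    (must match in length). Order is preserved.
    """
    results = list(results)
    if labels is not None:
        labels = list(labels)
        if len(labels) != len(results):
            raise ValueError("labels must match results in length")
    rows = []
    for i, res in enumerate(results):
        row = res.as_row()
        if labels is not None:
            row["label"] = labels[i]
        rows.append(row)
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


_REPORT_COLUMNS = [
    "label",
    "beta1_total", "se1",
    "beta2_exposure_mediator", "se2",
    "beta3_mediator_outcome", "se3",
    "indirect", "indirect_se", "indirect_ci_low", "indirect_ci_high",
    "indirect_pval",
    "direct", "direct_se", "direct_ci_low", "direct_ci_high",
    "proportion_mediated", "proportion_se",
    "proportion_ci_low", "proportion_ci_high",
    "consistent",
]
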