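"""MR-PRESSO: residual-sum global test, per-SNP outlier test, distortion test.

The global test compares the observed leave-one-out weighted residual sum of
squares against a parametric null built by redrawing outcome effects around
their fitted values; the outlier test refers each SNP's contribution to its
own simulated distribution with Bonferroni adjustment; the distortion test
asks whether removing the identified outliers changes the IVW estimate more
than removing random SNP subsets of the same size would.

All empirical p-values use the add-one rule ``(1 + #{sim ≥ obs})/(n + 1)``,
so they are never exactly zero, and every result is bit-reproducible from
its seed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import spawn_rngs
from .estimators import MREstimate, ivw
from .exceptions import EmptyInputError, InsufficientInstrumentsError
from .gwas_io import HarmonizedDataset

_MIN_SNPS = 4


def _loo_slopes(bx, by, sy):
    """Leave-one-out IVW slopes, vectorized: θ̂_(−j) for every j."""
    w = bx**2 / sy**2
    theta = by / bx
    num = np.sum(w * theta)
    den = np.sum(w)
    return (num - w * theta) / (den - w)


def _observed_contributions(bx, by, sy):
    slopes = _loo_slopes(bx, by, sy)
    return (by - slopes * bx) ** 2 / sy**2


def _simulated_contributions(bx, by, sy, n_dist, rng):
    """Null per-SNP residual contributions, (n_dist, J).

    Outcome effects are redrawn from normals centered on the leave-one-out
    fitted values with the observed SEs; each simulated dataset gets its own
    leave-one-out slopes, mirroring the observed-statistic computation.
    """
    mu = _loo_slopes(bx, by, sy) * bx
    by_sim = mu + sy * rng.standard_normal((n_dist, bx.size))
    w = bx**2 / sy**2
    theta = by_sim / bx
    num = np.sum(w * theta, axis=1, keepdims=True)
    den = np.sum(w)
    slopes = (num - w * theta) / (den - w)
    return (by_sim - slopes * bx) ** 2 / sy**2


def _require(d: HarmonizedDataset) -> None:
    if d.n_snps < _MIN_SNPS:
        raise InsufficientInstrumentsError(
            f"MR-PRESSO requires at least {_MIN_SNPS} instruments, got {d.n_snps}"
        )


@dataclass(frozen=True)
class GlobalTest:
    rss_obs: float
    pval: float
    n_distributions: int
    seed: int | None


def presso_global(
    d: HarmonizedDataset, n_dist: int = 1000, seed: int | None = 0
) -> GlobalTest:
    """Global heterogeneity (residual-sum) test."""
    _require(d)
    rng = np.random.default_rng(seed)
    bx, by, sy = d.beta_exposure, d.beta_outcome, d.se_outcome
    rss_obs = float(_observed_contributions(bx, by, sy).sum())
    sims = _simulated_contributions(bx, by, sy, n_dist, rng).sum(axis=1)
    pval = (1.0 + np.sum(sims >= rss_obs)) / (n_dist + 1.0)
    return GlobalTest(rss_obs=rss_obs, pval=float(pval),
                      n_distributions=n_dist, seed=seed)


@dataclass
class OutlierTest:
    table: pd.DataFrame  # snp, pval_raw, pval_adjusted, outlier
    outliers: list

    @property
    def any_outliers(self) -> bool:
        return bool(self.outliers)


def presso_outlier(
    d: HarmonizedDataset,
    n_dist: int = 1000,
    seed: int | None = 0,
    significance: float = 0.05,
) -> OutlierTest:
    """Per-SNP outlier test with Bonferroni multiplicity adjustment."""
    _require(d)
    rng = np.random.default_rng(seed)
    bx, by, sy = d.beta_exposure, d.beta_outcome, d.se_outcome
    obs = _observed_contributions(bx, by, sy)
    sims = _simulated_contributions(bx, by, sy, n_dist, rng)
    raw = (1.0 + np.sum(sims >= obs[None, :], axis=0)) / (n_dist + 1.0)
    adjusted = np.minimum(1.0, raw * d.n_snps)
    outlier_mask = adjusted < significance
    table = pd.DataFrame(
        {
            "snp": d.snp_ids,
            "pval_raw": raw,
            "pval_adjusted": adjusted,
            "outlier": outlier_mask,
        }
    )
    outliers = [s for s, o in zip(d.snp_ids, outlier_mask) if o]
    return OutlierTest(table=table, outliers=outliers)


@dataclass(frozen=True)
class DistortionTest:
    distortion: float  # (corrected - raw) / raw
    pval: float
    estimate_raw: MREstimate
    estimate_corrected: MREstimate


def presso_distortion(
    d: HarmonizedDataset,
    outliers,
    n_sim: int = 1000,
    seed: int | None = 0,
) -> DistortionTest:
    """Distortion test: does outlier removal change the IVW estimate more
    than removing random same-size SNP subsets would?"""
    outliers = list(outliers)
    raw = ivw(d, mode="auto")
    if not outliers:
        return DistortionTest(
            distortion=0.0, pval=1.0, estimate_raw=raw, estimate_corrected=raw
        )
    if set(outliers) >= set(d.snp_ids):
        raise EmptyInputError("all instruments flagged as outliers; nothing left")
    corrected = ivw(d.drop_snps(outliers), mode="auto")
    d_obs = (corrected.beta - raw.beta) / raw.beta

    rng = np.random.default_rng(seed)
    bx, by, sy = d.beta_exposure, d.beta_outcome, d.se_outcome
    j, k = d.n_snps, len(outliers)
    w = bx**2 / sy**2
    theta = by / bx
    num, den = np.sum(w * theta), np.sum(w)
    d_sim = np.empty(n_sim)
    for i in range(n_sim):
        drop = rng.choice(j, size=k, replace=False)
        slope = (num - np.sum(w[drop] * theta[drop])) / (den - np.sum(w[drop]))
        d_sim[i] = (slope - raw.beta) / raw.beta
    pval = (1.0 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (n_sim + 1.0)
    return DistortionTest(
        distortion=float(d_obs),
        pval=float(pval),
        estimate_raw=raw,
        estimate_corrected=corrected,
    )


@dataclass
class PressoResult:
    """Bundle of the three MR-PRESSO tests for one trait pair."""

    rss_obs: float
    global_pval: float
    outlier_table: pd.DataFrame
    outliers: list
    distortion_pval: float | None
    estimate_raw: MREstimate
    estimate_corrected: MREstimate
    n_distributions: int
    seed: int | None

    def summary_row(self) -> dict:
        return {
            "rss_obs": self.rss_obs,
            "global_pval": self.global_pval,
            "n_outliers": len(self.outliers),
            "outliers": ",".join(self.outliers),
            "distortion_pval": self.distortion_pval,
            "beta_raw": self.estimate_raw.beta,
            "beta_corrected": self.estimate_corrected.beta,
            "n_distributions": self.n_distributions,
            "seed": self.seed,
        }


def run_presso(
    d: HarmonizedDataset,
    n_dist: int = 1000,
    seed: int | None = 0,
    significance: float = 0.05,
) -> PressoResult:
    """Full MR-PRESSO sequence: global test, then (if the global test fires)
    the outlier test, then the distortion test on any identified outliers.

    One shared simulation pass drives the global and outlier tests so the
    whole result is reproducible from the single seed.
    """
    _require(d)
    rng_global, rng_distortion = spawn_rngs(seed if seed is not None else 0, 2)
    bx, by, sy = d.beta_exposure, d.beta_outcome, d.se_outcome
    obs = _observed_contributions(bx, by, sy)
    rss_obs = float(obs.sum())
    sims = _simulated_contributions(bx, by, sy, n_dist, rng_global)
    global_pval = float(
        (1.0 + np.sum(sims.sum(axis=1) >= rss_obs)) / (n_dist + 1.0)
    )

    raw = ivw(d, mode="auto")
    if global_pval < significance:
        raw_p = (1.0 + np.sum(sims >= obs[None, :], axis=0)) / (n_dist + 1.0)
        adjusted = np.minimum(1.0, raw_p * d.n_snps)
        outlier_mask = adjusted < significance
        outliers = [s for s, o in zip(d.snp_ids, outlier_mask) if o]
        outlier_table = pd.DataFrame(
            {
                "snp": d.snp_ids,
                "pval_raw": raw_p,
                "pval_adjusted": adjusted,
                "outlier": outlier_mask,
            }
        )
    else:
        outliers = []
        outlier_table = pd.DataFrame(
            {
                "snp": d.snp_ids,
                "pval_raw": np.nan,
                "pval_adjusted": np.nan,
                "outlier": False,
            }
        )

    if outliers and len(outliers) < d.n_snps:
        dist = presso_distortion(
            d, outliers, n_sim=n_dist,
            seed=int(rng_distortion.integers(2**31)),
        )
        corrected = dist.estimate_corrected
        distortion_pval = dist.pval
    else:
        corrected = raw
        distortion_pval = 1.0 if not outliers else None

    return PressoResult(
        rss_obs=rss_obs,
        global_pval=global_pval,
        outlier_table=outlier_table,
        outliers=outliers,
        distortion_pval=distortion_pval,
        estimate_raw=raw,
        estimate_corrected=corrected,
        n_distributions=n_dist,
        seed=seed,
    )
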