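"""Synthetic two-sample GWAS summary statistics with known ground truth.

Simulation happens at the summary level: per-SNP instrument strengths γ_j
are drawn once, and the observed exposure/outcome effects are those
strengths (respectively θ·γ_j plus any pleiotropic shift α_j) perturbed by
normal sampling noise at the stated SEs. This is sufficient for every
summary-statistic MR method and orders of magnitude faster than
individual-level genotype simulation; linkage, sample overlap and
liability-scale subtleties of real GWAS are deliberately not emulated.

Defaults describe a well-powered two-sample study: 50 instruments with
per-SNP F around 30, a causal log-odds effect of 0.278 per exposure unit,
and — for the mediation scenario — an exposure→mediator effect of 0.084 and
mediator→outcome effect of 0.569, so the true proportion mediated is 17.2%.

One root seed drives everything through ``numpy.random.SeedSequence``
stream-splitting: each stage (strengths, pleiotropy assignment, noise,
alleles) has its own child stream, so outputs are bit-reproducible.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._stats import two_sided_normal_p
from .exceptions import ConfigurationError
from .gwas_io import STANDARD_ROLES

_NONPALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class GammaDistribution:
    """Instrument-strength distribution: normal, bounded away from zero.

    The bound keeps every Wald ratio defined; the default minimum (0.06 with
    exposure SE 0.018) keeps each per-SNP F above 10, matching the
    conventional adequacy rule.
    """

    mean: float = 0.10
    sd: float = 0.02
    min_abs: float = 0.06


@dataclass(frozen=True)
class Pleiotropy:
    """Pleiotropy regime for the invalid-instrument fraction.

    ``none``: α = 0. ``balanced``: α ~ N(0, sd²). ``directional``:
    α ~ N(mean, sd²). ``correlated``: α = slope·γ + N(0, sd²), which violates
    the InSIDE assumption.
    """

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0
    slope: float = 0.0


@dataclass(frozen=True)
class AlleleModel:
    """Synthetic allele/frequency model.

    Defaults emulate instruments that already survived palindrome filtering
    (no palindromic SNPs); raise ``palindromic_fraction`` to exercise the
    harmonization policies.
    """

    palindromic_fraction: float = 0.0
    eaf_low: float = 0.05
    eaf_high: float = 0.95


@dataclass(frozen=True)
class MediationDesign:
    """Three-trait path structure: exposure → mediator → outcome.

    The true total effect is ``direct_effect + beta2*beta3``; the default
    values give β1 = 0.278, β2 = 0.084, β3 = 0.569 and a true proportion
    mediated of 17.2%.
    """

    beta2: float = 0.084
    beta3: float = 0.569
    direct_effect: float = 0.230204
    n_mediator_snps: int = 36
    se_mediator: float = 0.010

    @property
    def beta1(self) -> float:
        return self.direct_effect + self.beta2 * self.beta3

    @property
    def proportion(self) -> float:
        return self.beta2 * self.beta3 / self.beta1


@dataclass(frozen=True)
class LDBlocks:
    """Optional block LD structure for fixture bundles: SNPs are grouped
    into consecutive blocks placed within 1 kb of each other, with the
    stated within-block r²."""

    block_size: int = 1
    r2: float = 0.0


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic two-sample dataset."""

    seed: int
    n_snps: int = 50
    theta: float = 0.278
    gamma: GammaDistribution = field(default_factory=GammaDistribution)
    se_exposure: float = 0.018
    se_outcome: float = 0.03
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    frac_invalid: float = 0.0
    mediation: MediationDesign | None = None
    alleles: AlleleModel = field(default_factory=AlleleModel)
    ld: LDBlocks | None = None
    n_exposure: int = 500_199
    n_outcome: int = 873_341

    def __post_init__(self):
        if self.seed is None:
            raise ConfigurationError("a simulation seed is mandatory")
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if self.se_exposure < 0 or self.se_outcome < 0:
            raise ConfigurationError("SE scales must be non-negative")
        if not (0.0 <= self.frac_invalid <= 1.0):
            raise ConfigurationError("frac_invalid must lie in [0, 1]")
        if self.pleiotropy.kind not in ("none", "balanced", "directional",
                                        "correlated"):
            raise ConfigurationError(
                f"unknown pleiotropy kind '{self.pleiotropy.kind}'"
            )


@dataclass
class TruthRecord:
    """Ground truth stored alongside every simulated dataset."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    invalid_mask: np.ndarray
    beta1: float | None = None
    beta2: float | None = None
    beta3: float | None = None
    proportion_mediated: float | None = None

    def scalars(self) -> dict:
        out = {"theta": self.theta}
        for key in ("beta1", "beta2", "beta3", "proportion_mediated"):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        return out


def _positions(n: int, ld: LDBlocks | None, rng: np.random.Generator):
    """Chromosome/position layout. Blocks of linked SNPs sit within 1 kb;
    distinct blocks are ≥ 15 Mb apart (outside any ±10 Mb clumping window)."""
    block_size = ld.block_size if ld else 1
    block = np.arange(n) // block_size
    within = np.arange(n) % block_size
    chrom = (block % 22 + 1).astype(int)
    pos = 1_000_000 + (block // 22) * 15_000_000 + within * 1_000
    return chrom.astype(str), pos.astype(int), block


def _alleles(n: int, model: AlleleModel, rng: np.random.Generator):
    n_pal = int(round(model.palindromic_fraction * n))
    is_pal = np.zeros(n, dtype=bool)
    if n_pal:
        is_pal[rng.choice(n, size=n_pal, replace=False)] = True
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    for i in range(n):
        pool = _PALINDROMIC_PAIRS if is_pal[i] else _NONPALINDROMIC_PAIRS
        ea[i], oa[i] = pool[rng.integers(len(pool))]
    eaf = rng.uniform(model.eaf_low, model.eaf_high, size=n)
    return ea, oa, eaf


def _draw_gamma(n: int, dist: GammaDistribution, rng: np.random.Generator):
    g = rng.normal(dist.mean, dist.sd, size=n)
    sign = np.where(g < 0, -1.0, 1.0)
    return sign * np.maximum(np.abs(g), dist.min_abs)


def _draw_alpha(gamma, cfg: SimulationConfig, rng: np.random.Generator):
    n = gamma.size
    n_invalid = int(round(cfg.frac_invalid * n))
    mask = np.zeros(n, dtype=bool)
    if n_invalid:
        mask[rng.permutation(n)[:n_invalid]] = True
    alpha = np.zeros(n)
    p = cfg.pleiotropy
    if n_invalid and p.kind != "none":
        if p.kind == "balanced":
            alpha[mask] = rng.normal(0.0, p.sd, size=n_invalid)
        elif p.kind == "directional":
            alpha[mask] = rng.normal(p.mean, p.sd, size=n_invalid)
        else:  # correlated — violates InSIDE
            alpha[mask] = p.slope * gamma[mask] + rng.normal(
                0.0, p.sd, size=n_invalid
            )
    return alpha, mask


def _stats_frame(snp, chrom, pos, ea, oa, eaf, beta, se, n) -> pd.DataFrame:
    beta = np.asarray(beta, dtype=float)
    se_arr = np.broadcast_to(np.asarray(se, dtype=float), beta.shape)
    with np.errstate(divide="ignore"):
        z = np.where(se_arr > 0, beta / np.where(se_arr > 0, se_arr, 1.0), np.inf)
    pval = np.where(
        se_arr > 0, two_sided_normal_p(z), np.nextafter(0.0, 1.0)
    )
    frame = pd.DataFrame(
        {
            "snp": snp,
            "chr": chrom,
            "pos": pos,
            "ea": ea,
            "oa": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se_arr,
            "pval": pval,
            "n": n,
        }
    )
    return frame[list(STANDARD_ROLES)]


def simulate_two_sample(cfg: SimulationConfig):
    """Simulate exposure and outcome summary statistics for one trait pair.

    Returns ``(exposure_df, outcome_df, truth)`` where the frames use the
    standard role columns and the truth record stores θ and all per-SNP
    strengths and pleiotropic effects.
    """
    rng_gamma, rng_pleio, rng_xnoise, rng_ynoise, rng_allele = (
        np.random.SeedSequence(cfg.seed).spawn(5)
    )
    rng_gamma = np.random.default_rng(rng_gamma)
    rng_pleio = np.random.default_rng(rng_pleio)
    rng_xnoise = np.random.default_rng(rng_xnoise)
    rng_ynoise = np.random.default_rng(rng_ynoise)
    rng_allele = np.random.default_rng(rng_allele)

    n = cfg.n_snps
    gamma = _draw_gamma(n, cfg.gamma, rng_gamma)
    alpha, invalid = _draw_alpha(gamma, cfg, rng_pleio)
    bx = gamma + cfg.se_exposure * rng_xnoise.standard_normal(n)
    by = cfg.theta * gamma + alpha + cfg.se_outcome * rng_ynoise.standard_normal(n)

    chrom, pos, _ = _positions(n, cfg.ld, rng_allele)
    ea, oa, eaf = _alleles(n, cfg.alleles, rng_allele)
    snp = np.array([f"rs{100000 + i}" for i in range(n)])

    se_x = np.full(n, cfg.se_exposure) if cfg.se_exposure > 0 else np.zeros(n)
    se_y = np.full(n, cfg.se_outcome) if cfg.se_outcome > 0 else np.zeros(n)
    exposure = _stats_frame(snp, chrom, pos, ea, oa, eaf, bx, se_x, cfg.n_exposure)
    outcome = _stats_frame(snp, chrom, pos, ea, oa, eaf, by, se_y, cfg.n_outcome)
    truth = TruthRecord(theta=cfg.theta, gamma=gamma, alpha=alpha,
                        invalid_mask=invalid)
    return exposure, outcome, truth


def simulated_dataset(cfg: SimulationConfig):
    """Simulate one trait pair and return it as an already-harmonized dataset.

    Convenience for estimator studies that do not exercise the selection and
    harmonization stages: effects are aligned by construction.
    """
    from .gwas_io import HarmonizedDataset

    exposure, outcome, truth = simulate_two_sample(cfg)
    d = HarmonizedDataset.from_arrays(
        exposure["beta"].to_numpy(),
        exposure["se"].to_numpy(),
        outcome["beta"].to_numpy(),
        outcome["se"].to_numpy(),
        snp_ids=list(exposure["snp"]),
    )
    return d, truth


@dataclass
class MediationScenario:
    """Three GWAS summary tables spanning exposure and mediator instruments."""

    exposure: pd.DataFrame
    mediator: pd.DataFrame
    outcome: pd.DataFrame
    truth: TruthRecord
    exposure_snps: list
    mediator_snps: list


def simulate_mediation_scenario(cfg: SimulationConfig) -> MediationScenario:
    """Simulate the three-trait path: exposure → mediator → outcome.

    Exposure instruments G_X (strengths γ) act on the mediator with β2·γ and
    on the outcome with (direct + β2·β3)·γ, so the true total effect is
    β1 = direct + β2·β3. Independent mediator instruments G_M (strengths δ)
    act on the outcome with β3·δ. The three returned tables each cover all
    G_X ∪ G_M SNPs, as a real GWAS would.
    """
    if cfg.mediation is None:
        raise ConfigurationError("cfg.mediation must be set for this scenario")
    med = cfg.mediation
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_gamma = np.random.default_rng(seeds[0])
    rng_delta = np.random.default_rng(seeds[1])
    rng_noise = np.random.default_rng(seeds[2])
    rng_allele = np.random.default_rng(seeds[3])

    n_x, n_m = cfg.n_snps, med.n_mediator_snps
    n = n_x + n_m
    gamma = _draw_gamma(n_x, cfg.gamma, rng_gamma)
    delta = _draw_gamma(n_m, cfg.gamma, rng_delta)
    beta1 = med.beta1

    # true per-SNP effects in each GWAS
    true_exposure = np.concatenate([gamma, np.zeros(n_m)])
    true_mediator = np.concatenate([med.beta2 * gamma, delta])
    true_outcome = np.concatenate([beta1 * gamma, med.beta3 * delta])

    se_x = np.concatenate([np.full(n_x, cfg.se_exposure),
                           np.full(n_m, cfg.se_exposure)])
    se_m = np.full(n, med.se_mediator)
    se_y = np.full(n, cfg.se_outcome)

    def noisy(mu, se):
        if np.all(se == 0):
            return mu.copy()
        return mu + se * rng_noise.standard_normal(mu.size)

    obs_exposure = noisy(true_exposure, se_x)
    obs_mediator = noisy(true_mediator, se_m)
    obs_outcome = noisy(true_outcome, se_y)

    chrom, pos, _ = _positions(n, cfg.ld, rng_allele)
    ea, oa, eaf = _alleles(n, cfg.alleles, rng_allele)
    snp = np.array(
        [f"rsX{100000 + i}" for i in range(n_x)]
        + [f"rsM{200000 + i}" for i in range(n_m)]
    )

    exposure = _stats_frame(snp, chrom, pos, ea, oa, eaf, obs_exposure, se_x,
                            cfg.n_exposure)
    mediator = _stats_frame(snp, chrom, pos, ea, oa, eaf, obs_mediator, se_m,
                            cfg.n_exposure)
    outcome = _stats_frame(snp, chrom, pos, ea, oa, eaf, obs_outcome, se_y,
                           cfg.n_outcome)
    truth = TruthRecord(
        theta=beta1,
        gamma=np.concatenate([gamma, delta]),
        alpha=np.zeros(n),
        invalid_mask=np.zeros(n, dtype=bool),
        beta1=beta1,
        beta2=med.beta2,
        beta3=med.beta3,
        proportion_mediated=med.proportion,
    )
    return MediationScenario(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        truth=truth,
        exposure_snps=list(snp[:n_x]),
        mediator_snps=list(snp[n_x:]),
    )


def _ld_pairs(snp_ids, ld: LDBlocks) -> pd.DataFrame:
    rows = []
    bs = ld.block_size
    for start in range(0, len(snp_ids), bs):
        block = snp_ids[start:start + bs]
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                rows.append({"snp_a": block[i], "snp_b": block[j], "r2": ld.r2})
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])


def write_fixture_bundle(cfg: SimulationConfig, out_dir: str | Path) -> dict:
    """Write a self-contained fixture bundle to ``out_dir``.

    Contents: exposure/outcome (and mediator, when configured) summary TSVs,
    an LD pair list when block LD is configured, the ground-truth record as
    key=value text, and a YAML echo of the configuration. Filenames are
    deterministic; returns a name→path mapping.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if cfg.mediation is not None:
        scen = simulate_mediation_scenario(cfg)
        frames = {
            "exposure": scen.exposure,
            "mediator": scen.mediator,
            "outcome": scen.outcome,
        }
        truth = scen.truth
    else:
        exposure, outcome, truth = simulate_two_sample(cfg)
        frames = {"exposure": exposure, "outcome": outcome}

    for name, frame in frames.items():
        path = out / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = path

    if cfg.ld is not None and cfg.ld.block_size > 1:
        ld_path = out / "ld_pairs.tsv"
        _ld_pairs(list(frames["exposure"]["snp"]), cfg.ld).to_csv(
            ld_path, sep="\t", index=False
        )
        paths["ld_pairs"] = ld_path

    truth_path = out / "truth.txt"
    with open(truth_path, "w") as fh:
        for key, val in truth.scalars().items():
            fh.write(f"{key}={float(val)!r}\n")
        fh.write("gamma=" + ",".join(repr(float(g)) for g in truth.gamma) + "\n")
        fh.write("alpha=" + ",".join(repr(float(a)) for a in truth.alpha) + "\n")
        fh.write(
            "invalid=" + ",".join(str(int(m)) for m in truth.invalid_mask) + "\n"
        )
    paths["truth"] = truth_path

    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    paths["config"] = cfg_path
    return paths


def read_truth(path: str | Path) -> dict:
    """Parse a truth record written by :func:`write_fixture_bundle`."""
    out: dict = {}
    for line in Path(path).read_text().splitlines():
        key, _, value = line.partition("=")
        if key in ("gamma", "alpha"):
            out[key] = np.array([float(v) for v in value.split(",")])
        elif key == "invalid":
            out[key] = np.array([bool(int(v)) for v in value.split(",")])
        else:
            out[key] = float(value)
    return out
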