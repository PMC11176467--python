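"""Optional SVG rendering of diagnostic panels (scatter, forest, funnel, LOO).

Kept intentionally minimal: the analysis tables are the primary interface;
these panels exist for quick visual inspection, not publication styling.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .diagnostics import funnel_data, leave_one_out, single_snp_forest  # noqa: E402
from .estimators import egger, ivw  # noqa: E402
from .gwas_io import HarmonizedDataset  # noqa: E402


def plot_scatter(d: HarmonizedDataset, path: str | Path) -> Path:
    """Exposure vs outcome effects with IVW and (J ≥ 3) Egger lines."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.errorbar(
        d.beta_exposure, d.beta_outcome,
        xerr=d.se_exposure, yerr=d.se_outcome,
        fmt="o", ms=3, lw=0.6, color="0.3",
    )
    xs = sorted([0.0, *d.beta_exposure])
    est = ivw(d)
    ax.plot(xs, [est.beta * x for x in xs], label=f"IVW ({est.beta:.3f})")
    if d.n_snps >= 3:
        e = egger(d)
        ax.plot(xs, [e.intercept + e.beta * x for x in xs],
                label=f"MR-Egger ({e.beta:.3f})")
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
    return Path(path)


def plot_forest(d: HarmonizedDataset, path: str | Path) -> Path:
    table = single_snp_forest(d)
    fig, ax = plt.subplots(figsize=(4, 0.25 * len(table) + 1))
    y = range(len(table))
    ax.hlines(y, table["ci_low"], table["ci_high"], color="0.4", lw=1)
    ax.plot(table["beta"], y, "s", ms=3, color="0.1")
    ax.axvline(0, color="0.7", lw=0.8)
    ax.set_yticks(list(y), table["label"], fontsize=6)
    ax.set_xlabel("causal estimate (log odds)")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
    return Path(path)


def plot_funnel(d: HarmonizedDataset, path: str | Path) -> Path:
    fd = funnel_data(d)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fd.table["ratio"], fd.table["precision"], "o", ms=3, color="0.3")
    ax.axvline(ivw(d).beta, color="C0", lw=1)
    ax.set_xlabel("per-SNP Wald ratio")
    ax.set_ylabel("precision (1/SE)")
    ax.set_title(f"weighted skewness {fd.skewness:.2f}", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
    return Path(path)


def plot_leave_one_out(d: HarmonizedDataset, path: str | Path) -> Path:
    loo = leave_one_out(d)
    table = loo.table
    fig, ax = plt.subplots(figsize=(4, 0.25 * len(table) + 1))
    y = range(len(table))
    ax.hlines(y, table["ci_low"], table["ci_high"], color="0.4", lw=1)
    ax.plot(table["beta"], y, "o", ms=3, color="0.1")
    ax.axvline(loo.full.beta, color="C0", lw=1)
    ax.set_yticks(list(y), table["snp"], fontsize=6)
    ax.set_xlabel("IVW estimate with SNP removed")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
    return Path(path)


def render_pair_panels(d: HarmonizedDataset, out_dir: str | Path,
                       label: str) -> dict:
    """Write all four panels for one trait pair; returns name→path."""
    out = Path(out_dir)
    paths = {
        "scatter": plot_scatter(d, out / f"scatter_{label}.svg"),
        "forest": plot_forest(d, out / f"forest_{label}.svg"),
        "funnel": plot_funnel(d, out / f"funnel_{label}.svg"),
    }
    if d.n_snps >= 2:
        paths["loo"] = plot_leave_one_out(d, out / f"loo_{label}.svg")
    return paths
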