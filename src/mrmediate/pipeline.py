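"""Config-driven orchestration of the full analysis.

A YAML study configuration names trait summary-statistics files, selection
and harmonization settings, the MR methods to run, MR-PRESSO settings and
the mediation triples. :func:`run_study` then reproduces the study shape
end-to-end per trait pair — instruments → harmonization → estimators →
diagnostics → PRESSO — and finishes with the two-step mediation
decomposition, writing tidy TSV report tables plus a run manifest that
suffices to re-run the study bit-identically.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diagnostics import funnel_data, leave_one_out, single_snp_forest
from .estimators import METHOD_REGISTRY, MREstimate, run_methods
from .exceptions import ConfigurationError, MRMediateError
from .gwas_io import (
    DEFAULT_P_THRESHOLD,
    DEFAULT_R2_MAX,
    DEFAULT_WINDOW_KB,
    LDMatrix,
    f_statistics,
    harmonize,
    read_summary_stats,
    select_instruments,
    write_harmonized,
)
from .mediation import mediation_report, two_step_mediation
from .presso import run_presso

logger = logging.getLogger(__name__)

DEFAULT_METHODS = [
    "ivw",
    "egger",
    "weighted_median",
    "max_likelihood",
    "penalized_weighted_median",
]


@dataclass
class TraitSource:
    """One trait's summary-statistics file plus its column mapping."""

    name: str
    file: str
    column_map: dict = field(default_factory=dict)
    sep: str = "\t"


@dataclass
class MediationTriple:
    exposure: str
    mediator: str
    outcome: str
    label: str = ""

    def __post_init__(self):
        if not self.label:
            self.label = f"{self.exposure}->{self.mediator}->{self.outcome}"


@dataclass
class StudyConfig:
    """Normalized study configuration with every default filled in."""

    traits: dict[str, TraitSource]
    pairs: list[tuple[str, str]]
    mediation: list[MediationTriple] = field(default_factory=list)
    p_threshold: float = DEFAULT_P_THRESHOLD
    r2_max: float = DEFAULT_R2_MAX
    window_kb: float = DEFAULT_WINDOW_KB
    palindrome_policy: str = "drop_ambiguous_frequency"
    ambiguity_window: float = 0.08
    methods: list[str] = field(default_factory=lambda: list(DEFAULT_METHODS))
    presso_enabled: bool = True
    presso_n_dist: int = 1000
    ld_file: str | None = None
    output_dir: str = "mr_output"
    seed: int = 0
    plots: bool = False
    log_level: str = "INFO"


def _as_violations(raw: dict) -> tuple[StudyConfig | None, list[str]]:
    """Normalize a parsed YAML mapping, collecting every violation."""
    errors: list[str] = []
    if not isinstance(raw, dict):
        return None, ["config root must be a mapping"]

    traits: dict[str, TraitSource] = {}
    for name, spec in (raw.get("traits") or {}).items():
        if not isinstance(spec, dict) or "file" not in spec:
            errors.append(f"trait '{name}' must be a mapping with a 'file' key")
            continue
        traits[name] = TraitSource(
            name=name,
            file=str(spec["file"]),
            column_map=dict(spec.get("columns") or {}),
            sep=str(spec.get("sep", "\t")),
        )
    if not traits:
        errors.append("at least one trait must be configured")

    mediation: list[MediationTriple] = []
    for item in raw.get("mediation") or []:
        missing = {"exposure", "mediator", "outcome"} - set(item)
        if missing:
            errors.append(f"mediation triple {item} missing keys {sorted(missing)}")
            continue
        triple = MediationTriple(
            exposure=item["exposure"],
            mediator=item["mediator"],
            outcome=item["outcome"],
            label=item.get("label", ""),
        )
        for role in (triple.exposure, triple.mediator, triple.outcome):
            if role not in traits:
                errors.append(
                    f"mediation triple '{triple.label}' references undefined "
                    f"trait '{role}'"
                )
        mediation.append(triple)

    pairs: list[tuple[str, str]] = []
    for item in raw.get("pairs") or []:
        if not isinstance(item, dict) or {"exposure", "outcome"} - set(item):
            errors.append(f"pair {item} must name 'exposure' and 'outcome'")
            continue
        for role in (item["exposure"], item["outcome"]):
            if role not in traits:
                errors.append(f"pair {item} references undefined trait '{role}'")
        pairs.append((item["exposure"], item["outcome"]))
    # every mediation triple needs its three pairwise analyses
    for t in mediation:
        for pair in ((t.exposure, t.outcome), (t.exposure, t.mediator),
                     (t.mediator, t.outcome)):
            if pair not in pairs:
                pairs.append(pair)
    if not pairs:
        errors.append("no trait pairs to analyse (configure 'pairs' or 'mediation')")

    selection = raw.get("selection") or {}
    presso = raw.get("presso") or {}
    harmonization = raw.get("harmonization") or {}

    cfg = StudyConfig(
        traits=traits,
        pairs=pairs,
        mediation=mediation,
        p_threshold=float(selection.get("p_threshold", DEFAULT_P_THRESHOLD)),
        r2_max=float(selection.get("r2_max", DEFAULT_R2_MAX)),
        window_kb=float(selection.get("window_kb", DEFAULT_WINDOW_KB)),
        palindrome_policy=str(
            harmonization.get("policy", "drop_ambiguous_frequency")
        ),
        ambiguity_window=float(harmonization.get("ambiguity_window", 0.08)),
        methods=list(raw.get("methods") or DEFAULT_METHODS),
        presso_enabled=bool(presso.get("enabled", True)),
        presso_n_dist=int(presso.get("n_dist", 1000)),
        ld_file=raw.get("ld_file"),
        output_dir=str(raw.get("output_dir", "mr_output")),
        seed=int(raw.get("seed", 0)),
        plots=bool(raw.get("plots", False)),
        log_level=str(raw.get("log_level", "INFO")),
    )

    if not (0 < cfg.p_threshold < 1):
        errors.append("selection.p_threshold must lie in (0, 1)")
    if cfg.presso_n_dist <= 0:
        errors.append("presso.n_dist must be positive")
    if cfg.palindrome_policy not in ("drop_all", "drop_ambiguous_frequency"):
        errors.append(
            f"unknown harmonization.policy '{cfg.palindrome_policy}'"
        )
    for m in cfg.methods:
        if m not in METHOD_REGISTRY:
            errors.append(f"unknown method '{m}'")
    return (cfg if not errors else None), errors


def validate_config(path: str | Path):
    """Parse and validate a YAML study config.

    Returns ``(StudyConfig, [])`` on success or ``(None, errors)`` with every
    violation listed at once.
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError:
        return None, [f"config file not found: {path}"]
    except yaml.YAMLError as exc:
        return None, [f"cannot parse {path}: {exc}"]
    return _as_violations(raw or {})


def load_config(path: str | Path) -> StudyConfig:
    cfg, errors = validate_config(path)
    if errors:
        raise ConfigurationError("; ".join(errors))
    return cfg


@dataclass
class StudyReport:
    """Paths of everything :func:`run_study` wrote, plus in-memory tables."""

    output_dir: Path
    estimates: pd.DataFrame
    mediation: pd.DataFrame
    presso: pd.DataFrame
    skipped_pairs: list
    paths: dict = field(default_factory=dict)


def _pair_seed(root_seed: int, index: int) -> int:
    return int((root_seed * 1_000_003 + index) % 2**31)


def run_study(cfg: StudyConfig) -> StudyReport:
    """Run the configured study end-to-end and write the report bundle."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    ld = LDMatrix.from_pairs_file(cfg.ld_file) if cfg.ld_file else None
    tables: dict[str, pd.DataFrame] = {}
    for name, source in cfg.traits.items():
        tables[name] = read_summary_stats(
            source.file, column_map=source.column_map, sep=source.sep
        )
        logger.info(
            "trait %s: %d rows read, %d dropped",
            name, tables[name].shape[0], tables[name].attrs.get("n_dropped", 0),
        )

    estimate_rows = []
    presso_rows = []
    skipped = []
    headline: dict[tuple[str, str], MREstimate] = {}
    paths: dict[str, Path] = {}

    for index, (exp_name, out_name) in enumerate(cfg.pairs):
        pair_label = f"{exp_name}-{out_name}"
        seed = _pair_seed(cfg.seed, index)
        instruments = select_instruments(
            tables[exp_name],
            p_threshold=cfg.p_threshold,
            ld=ld,
            r2_max=cfg.r2_max,
            window_kb=cfg.window_kb,
            trait_label=exp_name,
        )
        if instruments.n_snps == 0:
            logger.warning("pair %s: no instruments survive selection", pair_label)
            skipped.append((pair_label, "no instruments"))
            continue
        d = harmonize(
            instruments,
            tables[out_name],
            palindrome_policy=cfg.palindrome_policy,
            ambiguity_window=cfg.ambiguity_window,
            exposure_label=exp_name,
            outcome_label=out_name,
        )
        if d.n_snps == 0:
            skipped.append((pair_label, "no SNPs survive harmonization"))
            continue
        d.audit.to_csv(out / f"audit_{pair_label}.tsv", sep="\t", index=False)
        fstats = f_statistics(d)

        try:
            estimates = run_methods(d, cfg.methods, seed=seed)
        except MRMediateError as exc:
            skipped.append((pair_label, str(exc)))
            continue
        for est in estimates:
            row = {"exposure": exp_name, "outcome": out_name,
                   "mean_f": fstats.mean, **est.as_row()}
            estimate_rows.append(row)
            if est.method.startswith("ivw"):
                headline[(exp_name, out_name)] = est

        if d.n_snps >= 2:
            loo = leave_one_out(d)
            loo.table.to_csv(out / f"loo_{pair_label}.tsv", sep="\t", index=False)
        single_snp_forest(d).to_csv(
            out / f"forest_{pair_label}.tsv", sep="\t", index=False
        )
        funnel = funnel_data(d)
        funnel.table.to_csv(out / f"funnel_{pair_label}.tsv", sep="\t", index=False)
        write_harmonized(d, out / f"harmonized_{pair_label}.tsv")

        if cfg.presso_enabled and d.n_snps >= 4:
            presso = run_presso(d, n_dist=cfg.presso_n_dist, seed=seed)
            presso_rows.append(
                {"exposure": exp_name, "outcome": out_name, **presso.summary_row()}
            )
            presso.outlier_table.to_csv(
                out / f"presso_{pair_label}.tsv", sep="\t", index=False
            )

        if cfg.plots:
            from . import plots

            plots.render_pair_panels(d, out, pair_label)

    estimates_df = pd.DataFrame(estimate_rows)
    estimates_df.to_csv(out / "estimates.tsv", sep="\t", index=False)
    paths["estimates"] = out / "estimates.tsv"

    presso_df = pd.DataFrame(presso_rows)
    presso_df.to_csv(out / "presso_summary.tsv", sep="\t", index=False)
    paths["presso"] = out / "presso_summary.tsv"

    mediation_results = []
    for triple in cfg.mediation:
        keys = [
            (triple.exposure, triple.outcome),
            (triple.exposure, triple.mediator),
            (triple.mediator, triple.outcome),
        ]
        missing = [k for k in keys if k not in headline]
        if missing:
            skipped.append(
                (triple.label, f"missing headline estimates for {missing}")
            )
            continue
        mediation_results.append(
            two_step_mediation(
                headline[keys[0]], headline[keys[1]], headline[keys[2]],
                label=triple.label,
            )
        )
    mediation_df = mediation_report(mediation_results)
    mediation_df.to_csv(out / "mediation.tsv", sep="\t", index=False)
    paths["mediation"] = out / "mediation.tsv"

    manifest = {
        "package": "mrmediate",
        "version": __version__,
        "seed": cfg.seed,
        "selection": {
            "p_threshold": cfg.p_threshold,
            "r2_max": cfg.r2_max,
            "window_kb": cfg.window_kb,
            "distance_only_clumping": ld is None,
        },
        "harmonization": {
            "policy": cfg.palindrome_policy,
            "ambiguity_window": cfg.ambiguity_window,
        },
        "methods": cfg.methods,
        "headline_rule": "random-effects IVW when Cochran Q p < 0.05, else fixed",
        "egger_orientation": "exposure betas re-signed non-negative",
        "presso": {
            "enabled": cfg.presso_enabled,
            "n_dist": cfg.presso_n_dist,
            "outlier_rule": "Bonferroni-adjusted p < 0.05",
        },
        "weighted_median": {"n_boot": 1000, "penalty_constant": 20.0},
        "traits": {n: s.file for n, s in cfg.traits.items()},
        "pairs": [list(p) for p in cfg.pairs],
        "mediation": [t.label for t in cfg.mediation],
        "skipped": [list(s) for s in skipped],
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    paths["manifest"] = out / "manifest.yaml"

    return StudyReport(
        output_dir=out,
        estimates=estimates_df,
        mediation=mediation_df,
        presso=presso_df,
        skipped_pairs=skipped,
        paths=paths,
    )
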