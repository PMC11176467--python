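"""Read, validate, filter, clump, and harmonize GWAS summary statistics.

Summary statistics travel as :class:`pandas.DataFrame` objects with the
standard role columns ``snp, chr, pos, ea, oa, eaf, beta, se, pval, n``
(one row per SNP); :class:`GwasRecord` is the row-level view used for
validation and by callers that prefer typed records. Instrument selection
produces an :class:`InstrumentSet`, and allele harmonization of an exposure
instrument set against outcome statistics produces a
:class:`HarmonizedDataset`, the unit all estimators consume.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    EmptyInputError,
    HarmonizationError,
    InsufficientInstrumentsError,
)

#: Standard column roles for a summary-statistics table.
STANDARD_ROLES = ("snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n")
#: Roles that must be present (eaf and n may be missing).
MANDATORY_ROLES = ("snp", "chr", "pos", "ea", "oa", "beta", "se", "pval")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Default thresholds for instrument selection: genome-wide significance and
# strict LD-independence (r^2 < 0.001 within a +/-10,000 kb window).
DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_R2_MAX = 0.001
DEFAULT_WINDOW_KB = 10_000.0


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's association summary for one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: float | None = None

    def violations(self) -> list[str]:
        """Return the list of invariant violations (empty when valid)."""
        problems = []
        if not (math.isfinite(self.se) and self.se > 0):
            problems.append("se must be > 0")
        if not math.isfinite(self.beta):
            problems.append("beta must be finite")
        if not (0 < self.pval <= 1):
            problems.append("pval must lie in (0, 1]")
        if self.eaf is not None and not math.isnan(self.eaf):
            if not (0.0 <= self.eaf <= 1.0):
                problems.append("eaf must lie in [0, 1]")
        if self.effect_allele.upper() == self.other_allele.upper():
            problems.append("effect and other allele must differ")
        if self.pos <= 0:
            problems.append("pos must be a positive 1-based coordinate")
        return problems

    @property
    def is_valid(self) -> bool:
        return not self.violations()


def records_to_frame(records: Iterable[GwasRecord]) -> pd.DataFrame:
    """Assemble typed records into the standard summary-statistics frame."""
    rows = [
        {
            "snp": r.snp_id,
            "chr": r.chrom,
            "pos": r.pos,
            "ea": r.effect_allele.upper(),
            "oa": r.other_allele.upper(),
            "eaf": np.nan if r.eaf is None else r.eaf,
            "beta": r.beta,
            "se": r.se,
            "pval": r.pval,
            "n": np.nan if r.n is None else r.n,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(STANDARD_ROLES))


def frame_to_records(table: pd.DataFrame) -> list[GwasRecord]:
    """Row-wise typed view of a standard summary-statistics frame."""
    out = []
    for row in table.itertuples(index=False):
        eaf = getattr(row, "eaf", np.nan)
        n = getattr(row, "n", np.nan)
        out.append(
            GwasRecord(
                snp_id=str(row.snp),
                chrom=str(row.chr),
                pos=int(row.pos),
                effect_allele=str(row.ea),
                other_allele=str(row.oa),
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                eaf=None if pd.isna(eaf) else float(eaf),
                n=None if pd.isna(n) else float(n),
            )
        )
    return out


def _validate_frame(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows violating GwasRecord invariants; count drops per reason."""
    reasons: dict[str, int] = {}
    keep = pd.Series(True, index=table.index)

    def _flag(mask: pd.Series, reason: str) -> None:
        bad = mask & keep
        if bad.any():
            reasons[reason] = int(bad.sum())
            keep[bad] = False

    _flag(~(np.isfinite(table["se"]) & (table["se"] > 0)), "nonpositive_se")
    _flag(~np.isfinite(table["beta"]), "nonfinite_beta")
    _flag(~((table["pval"] > 0) & (table["pval"] <= 1)), "pval_out_of_range")
    eaf = table["eaf"]
    _flag(eaf.notna() & ~((eaf >= 0) & (eaf <= 1)), "eaf_out_of_range")
    _flag(table["ea"].str.upper() == table["oa"].str.upper(), "identical_alleles")
    _flag(table["pos"] <= 0, "nonpositive_pos")
    return table[keep].copy(), reasons


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a delimited summary-statistics file into the standard frame.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Mapping from standard roles (``snp``, ``chr``, ``pos``, ``ea``,
        ``oa``, ``eaf``, ``beta``, ``se``, ``pval``, ``n``) to the file's
        column names. Roles already named by their standard name need no
        entry; ``eaf`` and ``n`` are optional and filled with NaN if absent.
    sep
        Field delimiter (tab by default).

    Returns
    -------
    pandas.DataFrame
        Standard-role columns, validated: rows violating the per-record
        invariants are dropped; the per-reason counts are stored in
        ``df.attrs["drop_log"]`` and the total in ``df.attrs["n_dropped"]``.
    """
    raw = pd.read_csv(path, sep=sep, dtype={0: str})
    if raw.shape[0] == 0:
        raise EmptyInputError(f"no data rows in {path}")
    column_map = dict(column_map or {})

    table = pd.DataFrame(index=raw.index)
    for role in STANDARD_ROLES:
        source = column_map.get(role, role)
        if source in raw.columns:
            table[role] = raw[source]
        elif role in MANDATORY_ROLES:
            raise ConfigurationError(
                f"mandatory column for role '{role}' not found in {path} "
                f"(looked for '{source}')"
            )
        else:
            table[role] = np.nan

    table["snp"] = table["snp"].astype(str)
    table["chr"] = table["chr"].astype(str)
    table["pos"] = pd.to_numeric(table["pos"], errors="coerce").astype("Int64")
    for col in ("eaf", "beta", "se", "pval", "n"):
        table[col] = pd.to_numeric(table[col], errors="coerce")
    table["ea"] = table["ea"].astype(str).str.upper()
    table["oa"] = table["oa"].astype(str).str.upper()
    table = table.dropna(subset=["pos", "beta", "se", "pval"])
    table["pos"] = table["pos"].astype(int)

    clean, reasons = _validate_frame(table)
    clean = clean.reset_index(drop=True)
    clean.attrs["drop_log"] = reasons
    clean.attrs["n_dropped"] = int(raw.shape[0] - clean.shape[0])
    return clean


class LDMatrix:
    """Symmetric pairwise r-squared lookup keyed by SNP id.

    Pairs absent from the lookup are treated as unlinked (r² = 0); callers
    are expected to supply a lookup covering every candidate pair they care
    about.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._pairs: dict[tuple[str, str], float] = {}
        for (a, b), r2 in (pairs or {}).items():
            self.set(a, b, float(r2))

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ConfigurationError(f"r2 must lie in [0, 1], got {r2}")
        self._pairs[self._key(a, b)] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._pairs.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._pairs)

    @classmethod
    def from_pairs_file(cls, path: str | Path, sep: str = "\t") -> "LDMatrix":
        """Load a 3-column (snp_a, snp_b, r2) pair list."""
        table = pd.read_csv(path, sep=sep)
        if table.shape[1] < 3:
            raise ConfigurationError(
                f"LD pair list {path} needs 3 columns (snp_a, snp_b, r2)"
            )
        a_col, b_col, r_col = table.columns[:3]
        obj = cls()
        for row in table.itertuples(index=False):
            obj.set(str(getattr(row, a_col)), str(getattr(row, b_col)),
                    float(getattr(row, r_col)))
        return obj

    @classmethod
    def from_matrix_file(cls, path: str | Path, sep: str = "\t") -> "LDMatrix":
        """Load a square r² matrix whose header and first column hold SNP ids."""
        table = pd.read_csv(path, sep=sep, index_col=0)
        obj = cls()
        ids = [str(c) for c in table.columns]
        values = table.to_numpy(dtype=float)
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                if values[i, j] > 0:
                    obj.set(a, ids[j], values[i, j])
        return obj


@dataclass
class InstrumentSet:
    """Independent genome-wide-significant instruments for one trait."""

    table: pd.DataFrame
    trait_label: str = ""
    selection_log: dict = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return int(self.table.shape[0])

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp"].tolist()


def select_instruments(
    records: pd.DataFrame,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    ld: LDMatrix | None = None,
    r2_max: float = DEFAULT_R2_MAX,
    window_kb: float = DEFAULT_WINDOW_KB,
    trait_label: str = "",
) -> InstrumentSet:
    """Select independent instruments by p-value filter plus greedy clumping.

    Candidates passing ``pval < p_threshold`` are sorted by ascending p
    (ties broken by chromosome, position, then SNP id) and accepted greedily:
    a SNP is kept iff no already-accepted SNP lies within
    ``± window_kb * 1000`` bp on the same chromosome with r² ≥ ``r2_max``.
    Without an LD lookup the distance rule alone decides (any accepted SNP in
    the window excludes the candidate) and the relaxation is recorded in the
    selection log.
    """
    if not (0 < p_threshold < 1):
        raise ConfigurationError("p_threshold must lie in (0, 1)")
    n_input = int(records.shape[0])
    candidates = records[records["pval"] < p_threshold].copy()
    n_after_p = int(candidates.shape[0])
    candidates = candidates.sort_values(
        ["pval", "chr", "pos", "snp"], kind="mergesort"
    )

    window_bp = window_kb * 1000.0
    accepted: list[int] = []
    acc_chr: list[str] = []
    acc_pos: list[int] = []
    acc_snp: list[str] = []
    for idx, row in candidates.iterrows():
        conflict = False
        for c, p, s in zip(acc_chr, acc_pos, acc_snp):
            if row["chr"] != c or abs(int(row["pos"]) - p) > window_bp:
                continue
            if ld is None or ld.r2(row["snp"], s) >= r2_max:
                conflict = True
                break
        if not conflict:
            accepted.append(idx)
            acc_chr.append(row["chr"])
            acc_pos.append(int(row["pos"]))
            acc_snp.append(row["snp"])

    selected = candidates.loc[accepted].sort_values(
        ["chr", "pos", "snp"], kind="mergesort"
    ).reset_index(drop=True)
    log = {
        "n_input": n_input,
        "removed_p_filter": n_input - n_after_p,
        "removed_clumping": n_after_p - len(accepted),
        "n_selected": len(accepted),
        "p_threshold": p_threshold,
        "r2_max": r2_max,
        "window_kb": window_kb,
        "distance_only": ld is None,
    }
    return InstrumentSet(table=selected, trait_label=trait_label, selection_log=log)


@dataclass
class HarmonizedDataset:
    """Per-SNP exposure and outcome effects aligned to one effect allele.

    ``table`` holds the retained rows (columns ``snp``, ``ea``, ``oa``,
    ``beta_exposure``, ``se_exposure``, ``eaf_exposure``, ``beta_outcome``,
    ``se_outcome``, ``eaf_outcome``, ``action``); ``audit`` records every
    removed SNP with its reason code.
    """

    table: pd.DataFrame
    audit: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "reason"])
    )
    exposure_label: str = ""
    outcome_label: str = ""

    @property
    def n_snps(self) -> int:
        return int(self.table.shape[0])

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp"].tolist()

    @property
    def beta_exposure(self) -> np.ndarray:
        return self.table["beta_exposure"].to_numpy(dtype=float)

    @property
    def se_exposure(self) -> np.ndarray:
        return self.table["se_exposure"].to_numpy(dtype=float)

    @property
    def beta_outcome(self) -> np.ndarray:
        return self.table["beta_outcome"].to_numpy(dtype=float)

    @property
    def se_outcome(self) -> np.ndarray:
        return self.table["se_outcome"].to_numpy(dtype=float)

    @classmethod
    def from_arrays(
        cls,
        beta_exposure: Sequence[float],
        se_exposure: Sequence[float],
        beta_outcome: Sequence[float],
        se_outcome: Sequence[float],
        snp_ids: Sequence[str] | None = None,
    ) -> "HarmonizedDataset":
        """Build an already-aligned dataset directly from effect arrays."""
        bx = np.asarray(beta_exposure, dtype=float)
        sx = np.asarray(se_exposure, dtype=float)
        by = np.asarray(beta_outcome, dtype=float)
        sy = np.asarray(se_outcome, dtype=float)
        if not (bx.shape == sx.shape == by.shape == sy.shape):
            raise ValueError("effect/SE arrays must share one shape")
        if snp_ids is None:
            snp_ids = [f"snp{i + 1}" for i in range(bx.size)]
        table = pd.DataFrame(
            {
                "snp": list(snp_ids),
                "ea": "A",
                "oa": "G",
                "beta_exposure": bx,
                "se_exposure": sx,
                "eaf_exposure": np.nan,
                "beta_outcome": by,
                "se_outcome": sy,
                "eaf_outcome": np.nan,
                "action": "kept",
            }
        )
        return cls(table=table)

    def drop_snps(self, snp_ids: Iterable[str]) -> "HarmonizedDataset":
        """Return a copy with the listed SNPs removed (e.g. PRESSO outliers)."""
        drop = set(snp_ids)
        kept = self.table[~self.table["snp"].isin(drop)].reset_index(drop=True)
        return HarmonizedDataset(
            table=kept,
            audit=self.audit,
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
        )


def _is_palindromic(ea: str, oa: str) -> bool:
    return len(ea) == 1 and _COMPLEMENT.get(ea) == oa


def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[b] for b in allele)
    except KeyError:
        return None


def harmonize(
    exposure: InstrumentSet | pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_policy: str = "drop_ambiguous_frequency",
    ambiguity_window: float = 0.08,
    exposure_label: str = "",
    outcome_label: str = "",
) -> HarmonizedDataset:
    """Align outcome effects to each exposure SNP's effect allele.

    Matching proceeds per SNP: identical orientation is kept; swapped alleles
    flip the outcome beta's sign and complement its frequency; alleles that
    match only after strand complementation are complemented first.
    Palindromic SNPs (A/T or C/G) cannot be resolved from allele letters:
    under ``drop_all`` they are removed, under ``drop_ambiguous_frequency``
    those whose effect-allele frequency is missing or within
    ``ambiguity_window`` of 0.5 (on either trait) are removed, and the rest
    are oriented by comparing which side of 0.5 the two frequencies fall on.
    Incompatible allele pairs are always removed. SNPs absent from the
    outcome table are dropped and logged.
    """
    if palindrome_policy not in ("drop_all", "drop_ambiguous_frequency"):
        raise ConfigurationError(
            f"unknown palindrome_policy '{palindrome_policy}'"
        )
    exp_table = exposure.table if isinstance(exposure, InstrumentSet) else exposure
    if not exposure_label and isinstance(exposure, InstrumentSet):
        exposure_label = exposure.trait_label

    for name, tab in (("exposure", exp_table), ("outcome", outcome)):
        dup = tab["snp"][tab["snp"].duplicated()]
        if len(dup):
            raise HarmonizationError(
                f"duplicate snp ids in {name} input: {sorted(set(dup))[:5]}"
            )

    out_idx = outcome.set_index("snp")
    rows = []
    audit = []
    for exp in exp_table.itertuples(index=False):
        snp = exp.snp
        if snp not in out_idx.index:
            audit.append((snp, "absent_in_outcome"))
            continue
        out = out_idx.loc[snp]
        ea, oa = exp.ea, exp.oa
        oea, ooa = str(out["ea"]), str(out["oa"])
        by, o_eaf = float(out["beta"]), float(out["eaf"])
        action = None

        if _is_palindromic(ea, oa):
            if palindrome_policy == "drop_all":
                audit.append((snp, "removed_palindromic"))
                continue
            e_eaf = float(exp.eaf) if not pd.isna(exp.eaf) else np.nan
            if {oea, ooa} != {ea, oa}:
                audit.append((snp, "removed_incompatible"))
                continue
            if (
                np.isnan(e_eaf)
                or np.isnan(o_eaf)
                or abs(e_eaf - 0.5) <= ambiguity_window
                or abs(o_eaf - 0.5) <= ambiguity_window
            ):
                audit.append((snp, "removed_palindromic"))
                continue
            # Allele letters are uninformative for palindromes: align
            # nominally by label, then trust the frequencies — both traits
            # must put the effect allele on the same side of 0.5.
            negated = (oea, ooa) != (ea, oa)
            p_out = 1.0 - o_eaf if negated else o_eaf
            if (e_eaf - 0.5) * (p_out - 0.5) <= 0:
                negated = not negated
                p_out = 1.0 - p_out
            by = -by if negated else by
            o_eaf = p_out
            action = "flipped" if negated else "kept"
        else:
            if (oea, ooa) == (ea, oa):
                action = "kept"
            elif (oea, ooa) == (oa, ea):
                action = "flipped"
            else:
                c_ea, c_oa = _complement(oea), _complement(ooa)
                if (c_ea, c_oa) == (ea, oa):
                    action = "kept"
                elif (c_ea, c_oa) == (oa, ea):
                    action = "flipped"
                else:
                    audit.append((snp, "removed_incompatible"))
                    continue
            if action == "flipped":
                by = -by
                o_eaf = 1.0 - o_eaf if not np.isnan(o_eaf) else o_eaf

        rows.append(
            {
                "snp": snp,
                "ea": ea,
                "oa": oa,
                "beta_exposure": float(exp.beta),
                "se_exposure": float(exp.se),
                "eaf_exposure": float(exp.eaf) if not pd.isna(exp.eaf) else np.nan,
                "beta_outcome": by,
                "se_outcome": float(out["se"]),
                "eaf_outcome": o_eaf,
                "action": action,
            }
        )

    table = pd.DataFrame(
        rows,
        columns=[
            "snp", "ea", "oa", "beta_exposure", "se_exposure", "eaf_exposure",
            "beta_outcome", "se_outcome", "eaf_outcome", "action",
        ],
    )
    audit_df = pd.DataFrame(audit, columns=["snp", "reason"])
    return HarmonizedDataset(
        table=table,
        audit=audit_df,
        exposure_label=exposure_label,
        outcome_label=outcome_label,
    )


@dataclass(frozen=True)
class FStatistics:
    """Per-SNP instrument-strength F values and their mean."""

    values: np.ndarray
    mean: float
    weak: bool  # mean F below the conventional threshold of 10


def f_statistics(d: HarmonizedDataset, threshold: float = 10.0) -> FStatistics:
    """Per-SNP F_j = (beta_exposure_j / se_exposure_j)^2 and the mean.

    Mean F below ``threshold`` (conventionally 10) flags weak instruments.
    """
    if d.n_snps == 0:
        raise EmptyInputError("cannot compute F statistics on an empty dataset")
    values = (d.beta_exposure / d.se_exposure) ** 2
    mean = float(values.mean())
    return FStatistics(values=values, mean=mean, weak=bool(mean < threshold))


def write_harmonized(d: HarmonizedDataset, path: str | Path) -> None:
    """Serialize a harmonized dataset (retained rows) to TSV."""
    d.table.to_csv(path, sep="\t", index=False)


def read_harmonized(path: str | Path) -> HarmonizedDataset:
    """Read a harmonized dataset previously written by :func:`write_harmonized`."""
    table = pd.read_csv(path, sep="\t", dtype={"snp": str})
    required = {"snp", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigurationError(f"harmonized file {path} missing columns {missing}")
    return HarmonizedDataset(table=table)


def require_min_snps(d: HarmonizedDataset, minimum: int, method: str) -> None:
    """Raise InsufficientInstrumentsError when fewer than ``minimum`` SNPs."""
    if d.n_snps < minimum:
        raise InsufficientInstrumentsError(
            f"{method} requires at least {minimum} instruments, got {d.n_snps}"
        )
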