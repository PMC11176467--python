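"""Reading, validation, clumping and harmonization of summary statistics."""
import itertools

import numpy as np
import pandas as pd
import pytest

from mrmediate import (
    HarmonizedDataset,
    LDMatrix,
    f_statistics,
    harmonize,
    read_summary_stats,
    select_instruments,
)
from mrmediate.exceptions import (
    ConfigurationError,
    EmptyInputError,
    HarmonizationError,
)
from mrmediate.gwas_io import read_harmonized, write_harmonized

from conftest import make_summary_frame


def _write(tmp_path, frame, name="stats.tsv"):
    path = tmp_path / name
    frame.to_csv(path, sep="\t", index=False)
    return path


class TestReadSummaryStats:
    def test_well_formed_rows_all_kept(self, tmp_path):
        frame = make_summary_frame([{}, {"pos": 2_000_000}, {"pos": 3_000_000}])
        got = read_summary_stats(_write(tmp_path, frame))
        assert got.shape[0] == 3
        assert got.attrs["n_dropped"] == 0

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        frame = make_summary_frame(
            [{}, {"se": 0.0}, {"pval": 0.0}, {"ea": "G", "oa": "G"}]
        )
        got = read_summary_stats(_write(tmp_path, frame))
        assert got.shape[0] == 1
        assert got.attrs["n_dropped"] == 3
        assert got.attrs["drop_log"]["nonpositive_se"] == 1

    def test_scientific_notation_pvalue(self, tmp_path):
        # p-values printed like 6.17E-07 must parse exactly
        frame = make_summary_frame([{}])
        frame["pval"] = "6.17E-07"
        got = read_summary_stats(_write(tmp_path, frame))
        assert got["pval"].iloc[0] == pytest.approx(6.17e-7, rel=0, abs=0)

    def test_column_remapping(self, tmp_path):
        frame = make_summary_frame([{}]).rename(
            columns={"snp": "MarkerName", "beta": "Effect"}
        )
        path = _write(tmp_path, frame)
        with pytest.raises(ConfigurationError, match="snp"):
            read_summary_stats(path)
        got = read_summary_stats(
            path, column_map={"snp": "MarkerName", "beta": "Effect"}
        )
        assert got.shape[0] == 1

    def test_empty_file_is_explicit_error(self, tmp_path):
        path = _write(tmp_path, make_summary_frame([]).iloc[:0])
        with pytest.raises(EmptyInputError):
            read_summary_stats(path)


def brute_force_clump(frame, window_bp, ld, r2_max):
    """Independent oracle: greedy acceptance re-derived with explicit loops."""
    ordered = frame.sort_values(["pval", "chr", "pos", "snp"], kind="mergesort")
    kept = []
    for _, row in ordered.iterrows():
        ok = True
        for prev in kept:
            if row["chr"] != prev["chr"]:
                continue
            if abs(row["pos"] - prev["pos"]) > window_bp:
                continue
            if ld is None or ld.r2(row["snp"], prev["snp"]) >= r2_max:
                ok = False
        if ok:
            kept.append(row)
    return sorted(r["snp"] for r in kept)


class TestSelectInstruments:
    def test_all_above_threshold_gives_empty_set(self):
        frame = make_summary_frame([{"pval": 1e-6}, {"pval": 1e-7}])
        got = select_instruments(frame)
        assert got.n_snps == 0
        assert got.selection_log["removed_p_filter"] == 2

    def test_hand_traced_greedy_example(self):
        frame = make_summary_frame(
            [
                {"snp": "s1", "pos": 1_000_000, "pval": 1e-10},
                {"snp": "s2", "pos": 2_000_000, "pval": 1e-9},
                {"snp": "s3", "pos": 50_000_000, "pval": 1e-9},
            ]
        )
        ld = LDMatrix({("s1", "s2"): 0.5, ("s1", "s3"): 0.0})
        got = select_instruments(frame, ld=ld, r2_max=0.001, window_kb=10_000)
        assert sorted(got.snp_ids) == ["s1", "s3"]
        assert got.selection_log["removed_clumping"] == 1

    def test_distance_only_rule_logged_without_ld(self):
        frame = make_summary_frame(
            [
                {"snp": "s1", "pos": 1_000_000, "pval": 1e-10},
                {"snp": "s2", "pos": 2_000_000, "pval": 1e-9},
            ]
        )
        got = select_instruments(frame)
        assert got.snp_ids == ["s1"]
        assert got.selection_log["distance_only"] is True

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            j = int(rng.integers(2, 10))
            rows = [
                {
                    "snp": f"s{i}",
                    "chr": str(rng.integers(1, 3)),
                    "pos": int(rng.integers(1, 30) * 1_000_000),
                    "pval": float(10.0 ** -rng.uniform(8.1, 20)),
                }
                for i in range(j)
            ]
            frame = make_summary_frame(rows)
            ld = LDMatrix()
            for a, b in itertools.combinations([r["snp"] for r in rows], 2):
                if rng.random() < 0.4:
                    ld.set(a, b, float(rng.random()))
            got = select_instruments(frame, ld=ld)
            expected = brute_force_clump(frame, 10_000 * 1000, ld, 0.001)
            assert sorted(got.snp_ids) == expected, f"trial {trial}"

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        rows = [
            {
                "snp": f"s{i}",
                "chr": "2",
                "pos": int(p),
                "pval": float(10.0 ** -rng.uniform(9, 15)),
            }
            for i, p in enumerate(rng.integers(1, 200, size=8) * 1_000_000)
        ]
        frame = make_summary_frame(rows)
        first = select_instruments(frame)
        second = select_instruments(first.table)
        assert first.snp_ids == second.snp_ids


class TestHarmonize:
    def test_identical_alleles_kept(self):
        exp = make_summary_frame([{"ea": "A", "oa": "G", "beta": 0.1}])
        out = make_summary_frame([{"ea": "A", "oa": "G", "beta": 0.2}])
        d = harmonize(exp, out)
        assert d.table["action"].tolist() == ["kept"]
        assert d.beta_outcome[0] == pytest.approx(0.2)

    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = make_summary_frame([{"ea": "A", "oa": "G", "beta": 0.1}])
        out = make_summary_frame([{"ea": "G", "oa": "A", "beta": 0.2, "eaf": 0.3}])
        d = harmonize(exp, out)
        assert d.table["action"].tolist() == ["flipped"]
        assert d.beta_outcome[0] == pytest.approx(-0.2)
        assert d.table["eaf_outcome"].iloc[0] == pytest.approx(0.7)

    def test_strand_complement_resolved(self):
        exp = make_summary_frame([{"ea": "A", "oa": "G", "beta": 0.1}])
        out = make_summary_frame([{"ea": "T", "oa": "C", "beta": 0.2}])
        d = harmonize(exp, out)
        assert d.table["action"].tolist() == ["kept"]
        assert d.beta_outcome[0] == pytest.approx(0.2)

    def test_incompatible_alleles_removed(self):
        exp = make_summary_frame([{"ea": "A", "oa": "G"}])
        out = make_summary_frame([{"ea": "A", "oa": "C"}])
        d = harmonize(exp, out)
        assert d.n_snps == 0
        assert d.audit["reason"].tolist() == ["removed_incompatible"]

    def test_palindromic_ambiguous_frequency_removed(self):
        exp = make_summary_frame([{"ea": "A", "oa": "T", "eaf": 0.5}])
        out = make_summary_frame([{"ea": "A", "oa": "T", "eaf": 0.5}])
        d = harmonize(exp, out, palindrome_policy="drop_ambiguous_frequency")
        assert d.n_snps == 0
        assert d.audit["reason"].tolist() == ["removed_palindromic"]

    def test_palindromic_missing_eaf_always_removed(self):
        exp = make_summary_frame([{"ea": "A", "oa": "T", "eaf": np.nan}])
        out = make_summary_frame([{"ea": "A", "oa": "T", "eaf": 0.2}])
        d = harmonize(exp, out)
        assert d.n_snps == 0

    def test_palindromic_drop_all_policy(self):
        exp = make_summary_frame([{"ea": "C", "oa": "G", "eaf": 0.1}])
        out = make_summary_frame([{"ea": "C", "oa": "G", "eaf": 0.1}])
        d = harmonize(exp, out, palindrome_policy="drop_all")
        assert d.n_snps == 0

    def test_palindromic_inferable_frequency_oriented(self):
        exp = make_summary_frame([{"ea": "A", "oa": "T", "eaf": 0.1, "beta": 0.1}])
        same = make_summary_frame([{"ea": "A", "oa": "T", "eaf": 0.12, "beta": 0.2}])
        opposite = make_summary_frame(
            [{"ea": "A", "oa": "T", "eaf": 0.88, "beta": 0.2}]
        )
        kept = harmonize(exp, same)
        flipped = harmonize(exp, opposite)
        assert kept.beta_outcome[0] == pytest.approx(0.2)
        assert flipped.beta_outcome[0] == pytest.approx(-0.2)

    def test_missing_in_outcome_logged(self):
        exp = make_summary_frame([{"snp": "rsA"}, {"snp": "rsB"}])
        out = make_summary_frame([{"snp": "rsA"}])
        d = harmonize(exp, out)
        assert d.n_snps == 1
        assert ("rsB", "absent_in_outcome") in list(
            d.audit.itertuples(index=False, name=None)
        )

    def test_duplicate_ids_hard_error(self):
        exp = make_summary_frame([{"snp": "rsA"}, {"snp": "rsA"}])
        out = make_summary_frame([{"snp": "rsA"}])
        with pytest.raises(HarmonizationError):
            harmonize(exp, out)

    def test_involution_safe(self):
        """Harmonizing an already-aligned dataset changes nothing."""
        exp = make_summary_frame(
            [{"snp": f"rs{i}", "pos": i * 1_000_000, "beta": 0.1 * i}
             for i in range(1, 5)]
        )
        out = make_summary_frame(
            [{"snp": f"rs{i}", "pos": i * 1_000_000, "beta": 0.05 * i}
             for i in range(1, 5)]
        )
        once = harmonize(exp, out)
        again_out = out.copy()
        twice = harmonize(exp, again_out)
        pd.testing.assert_frame_equal(once.table, twice.table)
        assert (once.table["action"] == "kept").all()

    def test_flip_symmetry_preserves_ivw(self):
        """Swapping every outcome allele negates stored betas but leaves the
        causal estimate untouched."""
        from mrmediate import ivw

        exp = make_summary_frame(
            [{"snp": f"rs{i}", "beta": 0.1 + 0.02 * i} for i in range(4)]
        )
        out = make_summary_frame(
            [{"snp": f"rs{i}", "beta": 0.05 + 0.01 * i} for i in range(4)]
        )
        flipped = out.copy()
        flipped["ea"], flipped["oa"] = out["oa"], out["ea"]
        flipped["beta"] = -out["beta"]
        flipped["eaf"] = 1.0 - out["eaf"]
        d1 = harmonize(exp, out)
        d2 = harmonize(exp, flipped)
        assert (d2.table["action"] == "flipped").all()
        np.testing.assert_allclose(d1.beta_outcome, d2.beta_outcome)
        assert ivw(d1).beta == pytest.approx(ivw(d2).beta, abs=1e-14)


class TestFStatistics:
    def test_single_snp_value(self):
        d = HarmonizedDataset.from_arrays([0.02], [0.005], [0.01], [0.01])
        got = f_statistics(d)
        assert got.values[0] == pytest.approx(16.0)
        assert got.mean == pytest.approx(16.0)
        assert not got.weak

    def test_zero_beta_flags_weak(self):
        d = HarmonizedDataset.from_arrays([0.0, 0.0], [0.01, 0.02], [0.0, 0.0],
                                          [0.01, 0.01])
        got = f_statistics(d)
        assert got.mean == 0.0
        assert got.weak

    def test_mean_is_arithmetic(self):
        # F values 10 and 20 -> mean 15
        d = HarmonizedDataset.from_arrays(
            [np.sqrt(10) * 0.01, np.sqrt(20) * 0.01], [0.01, 0.01],
            [0.0, 0.0], [0.01, 0.01],
        )
        assert f_statistics(d).mean == pytest.approx(15.0)


def test_harmonized_roundtrip(tmp_path, toy3):
    path = tmp_path / "h.tsv"
    write_harmonized(toy3, path)
    back = read_harmonized(path)
    np.testing.assert_allclose(back.beta_exposure, toy3.beta_exposure)
    np.testing.assert_allclose(back.se_outcome, toy3.se_outcome)
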