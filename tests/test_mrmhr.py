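import math

import numpy as np
import pandas as pd
import pytest

from vitreoquant import mrmhr, synthdata
from vitreoquant.mrmhr import (MrmConfig, TransitionListSpec,
                               DegenerateVarianceError,
                               MissingHousekeepingError)


class TestPeptideIntensity:
    def test_mean_of_top_three(self):
        out = mrmhr.peptide_intensity([40.0, 30.0, 20.0, 10.0],
                                      [25, 25, 25, 25])
        assert out == pytest.approx(30.0)

    def test_short_list_averaged_as_is(self):
        out = mrmhr.peptide_intensity([40.0, 30.0], [25, 25])
        assert out == pytest.approx(35.0)

    def test_snr_gate_default_inclusive(self):
        assert mrmhr.peptide_intensity([10.0], [20.0]) == 10.0
        strict = MrmConfig(snr_strict=True)
        assert mrmhr.peptide_intensity([10.0], [20.0], strict) is None

    def test_all_below_threshold_missing(self):
        assert mrmhr.peptide_intensity([40.0, 30.0], [5.0, 19.9]) is None


class TestProteinIntensity:
    def test_mean_of_top_three_peptides(self):
        assert mrmhr.protein_intensity([30.0, 20.0, 10.0, 5.0]) == 20.0

    def test_single_peptide(self):
        assert mrmhr.protein_intensity([12.0]) == 12.0

    def test_empty_missing(self):
        assert mrmhr.protein_intensity([]) is None
        assert mrmhr.protein_intensity([None, float("nan")]) is None

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            vals = list(rng.uniform(1, 100, rng.integers(1, 9)))
            k = int(rng.integers(1, 5))
            expected = float(np.mean(sorted(vals, reverse=True)[:k]))
            got = mrmhr.protein_intensity(vals, MrmConfig(top_peptides=k))
            assert got == pytest.approx(expected)


class TestTransitionList:
    def _catalog(self, rows):
        return pd.DataFrame(rows, columns=[
            "peptide", "ion_type", "fragment_charge", "precursor_charge",
            "mz", "intensity"])

    def _library(self, peptides):
        return pd.DataFrame({
            "protein": ["P1"] * len(peptides), "peptide": peptides,
            "confidence": [0.99] * len(peptides),
            "source_injection": ["s"] * len(peptides)})

    def test_top_five_by_intensity(self):
        rows = [("a", "y", 1, 2, 300.0 + i, 100.0 - i) for i in range(8)]
        table, excluded = mrmhr.build_transition_list(
            self._library(["a"]), self._catalog(rows))
        assert len(table) == 5
        assert list(table["intensity"]) == [100.0, 99.0, 98.0, 97.0, 96.0]
        assert excluded == []

    def test_ion_type_and_charge_filters(self):
        rows = [("a", "z", 1, 2, 300.0, 999.0),   # wrong ion type
                ("a", "y", 2, 2, 301.0, 999.0),   # wrong fragment charge
                ("a", "y", 1, 4, 302.0, 999.0),   # wrong precursor charge
                ("a", "b", 1, 3, 303.0, 10.0)]
        table, excluded = mrmhr.build_transition_list(
            self._library(["a"]), self._catalog(rows))
        assert len(table) == 1 and table["mz"].iloc[0] == 303.0

    def test_unmatched_peptide_reported(self):
        rows = [("a", "y", 1, 2, 300.0, 50.0)]
        table, excluded = mrmhr.build_transition_list(
            self._library(["a", "ghost"]), self._catalog(rows))
        assert excluded == ["ghost"]

    def test_intensity_tie_broken_by_mz(self):
        rows = [("a", "y", 1, 2, 400.0, 50.0), ("a", "y", 1, 2, 200.0, 50.0)]
        table, _ = mrmhr.build_transition_list(
            self._library(["a"]), self._catalog(rows),
            TransitionListSpec(top_products=1))
        assert table["mz"].iloc[0] == 200.0

    def test_matches_brute_force_on_random_catalogs(self):
        rng = np.random.default_rng(3)
        spec = TransitionListSpec()
        for _ in range(100):
            rows = [("a", rng.choice(["y", "b", "z"]),
                     int(rng.choice([1, 2])), int(rng.choice([2, 3, 4])),
                     float(rng.integers(200, 1200)),
                     float(rng.integers(1, 50)))
                    for _ in range(12)]
            table, _ = mrmhr.build_transition_list(
                self._library(["a"]), self._catalog(rows), spec)
            ok = [r for r in rows if r[1] in ("y", "b") and r[2] == 1
                  and r[3] in (2, 3)]
            expected = sorted(ok, key=lambda r: (-r[5], r[4]))[:5]
            got = list(zip(table["mz"], table["intensity"]))
            assert got == [(r[4], r[5]) for r in expected]


class TestHousekeepingNormalization:
    def _table(self):
        return pd.DataFrame(
            {"i1": [200.0, 100.0], "i2": [300.0, 150.0]},
            index=["TARGET", "GAPDH"])

    def test_housekeeping_row_exactly_one(self):
        out = mrmhr.normalize_housekeeping(self._table(), "GAPDH")
        assert (out.loc["GAPDH"] == 1.0).all()

    def test_ratio(self):
        out = mrmhr.normalize_housekeeping(self._table(), "GAPDH")
        assert out.loc["TARGET", "i1"] == pytest.approx(2.0)
        assert out.loc["TARGET", "i2"] == pytest.approx(2.0)

    def test_per_injection_scaling_invariance(self):
        table = self._table()
        scaled = table.copy()
        scaled["i1"] *= 7.5
        a = mrmhr.normalize_housekeeping(table, "GAPDH")
        b = mrmhr.normalize_housekeeping(scaled, "GAPDH")
        pd.testing.assert_frame_equal(a, b)

    def test_missing_housekeeping_names_injection(self):
        table = self._table()
        table.loc["GAPDH", "i2"] = np.nan
        with pytest.raises(MissingHousekeepingError, match="i2"):
            mrmhr.normalize_housekeeping(table, "GAPDH")


class TestGroupFoldChange:
    def _samples(self):
        return pd.DataFrame({
            "sample_id": [f"d7_{i}" for i in range(4)]
            + [f"d14_{i}" for i in range(4)],
            "eye": ["OD"] * 8, "day": [7] * 4 + [14] * 4,
            "replicate": list(range(1, 5)) * 2,
            "cohort": ["MRMHR"] * 8}).set_index("sample_id")

    def test_doubling(self):
        samples = self._samples()
        norm = pd.DataFrame([np.r_[np.ones(4), 2 * np.ones(4)]],
                            index=["T"], columns=samples.index)
        assert mrmhr.group_fold_change(norm, "T", samples) == 2.0

    def test_identical_groups_unity(self):
        samples = self._samples()
        norm = pd.DataFrame([np.r_[np.full(4, 3.3), np.full(4, 3.3)]],
                            index=["T"], columns=samples.index)
        assert mrmhr.group_fold_change(norm, "T", samples) == 1.0


def _student_oracle(a, b):
    """Textbook pooled-variance two-sample t-test, coded independently."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
           / (na + nb - 2))
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    from scipy.stats import t as tdist
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


class TestUnpairedTTest:
    def test_identical_groups(self):
        t, df, p = mrmhr.unpaired_t_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert t == 0.0 and p == pytest.approx(1.0)
        assert df == 6.0

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a = rng.normal(size=rng.integers(2, 9))
            b = rng.normal(loc=0.5, size=rng.integers(2, 9))
            t, df, p = mrmhr.unpaired_t_test(a, b)
            ot, odf, op = _student_oracle(a, b)
            assert t == pytest.approx(ot, abs=1e-10)
            assert df == odf
            assert p == pytest.approx(op, abs=1e-10)

    def test_swap_negates_t_keeps_p(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        t1, _, p1 = mrmhr.unpaired_t_test(a, b)
        t2, _, p2 = mrmhr.unpaired_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_welch_df_not_pooled(self):
        a = [1.0, 1.1, 0.9, 1.0]
        b = [2.0, 4.0, 0.5, 3.5]
        _, df, _ = mrmhr.unpaired_t_test(a, b, "welch")
        assert df < 6.0

    def test_degenerate_variance_raises(self):
        with pytest.raises(DegenerateVarianceError):
            mrmhr.unpaired_t_test([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


class TestRunValidation:
    def test_noise_free_fold_change_exact(self):
        config = synthdata.SynthConfig(
            n_proteins=40, de_fraction=0.25, decoy_fraction=0.0,
            de_log2_fc_range=(1.0, 1.0), eye_jitter_sd_log2=0.0,
            replicate_cv=0.0, bio_cv_mrmhr=0.0,
            bias_log2_range=(0.0, 0.0), snr_below_cutoff_fraction=0.0,
            seed=13)
        transitions, samples, truth = synthdata.generate_mrmhr(config, [])
        de_up = sorted(
            set(truth.proteins.index[truth.proteins["is_de"]])
            & set(truth.effects[(truth.effects["day"] == 14)
                                & (truth.effects["log2_fc"] > 0)]
                  ["protein"]))
        target = de_up[0]
        transitions, samples, truth = synthdata.generate_mrmhr(
            config, [target])
        results = mrmhr.run_validation(transitions, samples, [target])
        assert results[0].fold_change == pytest.approx(2.0, rel=1e-9)
        # zero variance between animals: flagged degenerate, no p faked
        assert results[0].degenerate

    def test_housekeeping_as_target_never_significant(self, small_config):
        transitions, samples, _ = synthdata.generate_mrmhr(
            small_config, ["P0002"])
        results = mrmhr.run_validation(transitions, samples, ["GAPDH"])
        assert results[0].fold_change == pytest.approx(1.0)
        assert not results[0].significant

    def test_global_injection_scaling_changes_nothing(self, small_config):
        transitions, samples, _ = synthdata.generate_mrmhr(
            small_config, ["P0002", "P0003"])
        scaled = transitions.copy()
        first = samples["sample_id"].iloc[0]
        mask = scaled["sample_id"] == first
        scaled.loc[mask, "area"] *= 11.0  # snr is scale-free
        a = mrmhr.run_validation(transitions, samples,
                                 ["P0002", "P0003"])
        b = mrmhr.run_validation(scaled, samples, ["P0002", "P0003"])
        for ra, rb in zip(a, b):
            assert ra.fold_change == pytest.approx(rb.fold_change)
            assert ra.p == pytest.approx(rb.p)
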