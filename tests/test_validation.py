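"""Cross-validation, comparison statistics, bootstrap and PERMANOVA."""

import numpy as np
import pandas as pd
import pytest

from fluorotax.chemotax import GROUPS, GroupComposition
from fluorotax.conversion import (
    FluorescenceSpectrum,
    ReferenceDatabase,
    ReferenceRecord,
    standardize_spectrum,
)
from fluorotax.validation import (
    PairedCompositions,
    _sequential_permanova,
    aggregate_groups,
    bootstrap_sensitivity,
    comparison_stats,
    leave_area_out_conversion,
    loocv_conversion,
    permanova_fluorescence,
)


def _record(channels, fractions, **meta):
    spec = standardize_spectrum(FluorescenceSpectrum(np.asarray(channels, float)))
    comp = GroupComposition.from_array(np.asarray(fractions, float))
    return ReferenceRecord(spectrum=spec, composition=comp, tchla=1.0, **meta)


class TestLoocv:
    def test_same_key_records_both_excluded(self, rng):
        """Replicates sharing (cruise, station, depth) never vouch for each other."""
        q_a = np.zeros(9); q_a[0] = 1.0
        q_b = np.zeros(9); q_b[8] = 1.0
        spec_a = rng.uniform(0.1, 1, 9)
        recs = [
            _record(spec_a, q_a, cruise="C1", station="S1", depth_m=10.0),
            _record(spec_a, q_a, cruise="C1", station="S1", depth_m=10.0),
            _record(rng.uniform(0.1, 1, 9), q_b, cruise="C1", station="S2", depth_m=10.0),
            _record(rng.uniform(0.1, 1, 9), q_b, cruise="C1", station="S3", depth_m=30.0),
        ]
        pairs = loocv_conversion(ReferenceDatabase(recs))
        # the two S1 replicates are pure diatoms; with both excluded, only
        # pure-prochlorophyte references remain, so no diatom signal survives
        assert pairs.estimated[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert pairs.estimated[1, 0] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_identical_db(self, rng):
        spec = rng.uniform(0.1, 1, 9)
        q = np.full(9, 1 / 9)
        recs = [_record(spec, q, station=f"S{i}", depth_m=float(i)) for i in range(5)]
        pairs = loocv_conversion(ReferenceDatabase(recs))
        assert np.allclose(pairs.estimated, pairs.truth, atol=1e-9)

    def test_exclusion_count(self, small_db):
        db, _ = small_db
        pairs = loocv_conversion(db)
        assert len(pairs) == db.n_active


class TestLeaveAreaOut:
    def test_partition_by_area(self, rng):
        """Targets in one area are reconstructed from the other area only."""
        q_a = np.zeros(9); q_a[0] = 1.0
        q_b = np.zeros(9); q_b[7] = 1.0
        recs = []
        for i in range(4):
            recs.append(_record(rng.uniform(0.1, 1, 9), q_a, station=f"A{i}",
                                depth_m=float(i), area="Oyashio"))
            recs.append(_record(rng.uniform(0.1, 1, 9), q_b, station=f"B{i}",
                                depth_m=float(i), area="Kuroshio"))
        pairs = leave_area_out_conversion(ReferenceDatabase(recs))
        # every Oyashio target (pure diatoms) is forced onto Kuroshio
        # references (pure cyanophytes) and vice versa
        for k in range(len(pairs)):
            truth_group = int(np.argmax(pairs.truth[k]))
            other_group = 7 if truth_group == 0 else 0
            assert pairs.estimated[k, other_group] == pytest.approx(1.0, abs=1e-9)

    def test_single_area_rejected(self, rng):
        recs = [_record(rng.uniform(0.1, 1, 9), np.full(9, 1 / 9),
                        station=f"S{i}", depth_m=float(i), area="JS")
                for i in range(4)]
        with pytest.raises(ValueError, match="areas"):
            leave_area_out_conversion(ReferenceDatabase(recs))

    def test_correlates_with_truth_when_areas_share_structure(self, small_db):
        db, _ = small_db
        stats = comparison_stats(leave_area_out_conversion(db))
        assert (stats.table.loc[~stats.table["skipped"], "slope"] > 0).all()


class TestComparisonStats:
    def test_identity(self, rng):
        truth = rng.dirichlet(np.ones(9), size=30)
        pairs = PairedCompositions(truth.copy(), truth, np.arange(30))
        t = comparison_stats(pairs).table
        assert np.allclose(t["slope"], 1.0)
        assert np.allclose(t["r2"], 1.0)
        assert np.allclose(t["mean_abs_diff_pct"], 0.0)
        assert np.allclose(t["ci_halfwidth_pct"], 0.0)

    def test_folded_normal_mean_abs_difference(self):
        """est = truth + N(0, σ) gives mean |diff| ≈ σ·√(2/π)."""
        rng = np.random.default_rng(77)
        sigma = 0.04
        truth = rng.dirichlet(np.ones(9), size=4000)
        est = truth + rng.normal(0, sigma, truth.shape)
        t = comparison_stats(PairedCompositions(est, truth, np.arange(4000))).table
        expected = 100 * sigma * np.sqrt(2 / np.pi)
        assert np.allclose(t["mean_abs_diff_pct"], expected, rtol=0.05)

    def test_anticorrelation_sign_preserved(self, rng):
        x = np.linspace(0, 1, 50)
        truth = np.column_stack([x] * 9) / 9
        est = np.column_stack([1 - x] * 9) / 9
        t = comparison_stats(PairedCompositions(est, truth, np.arange(50))).table
        assert (t["slope"] < 0).all()

    def test_zero_variance_group_skipped(self, rng):
        truth = rng.dirichlet(np.ones(9), size=20)
        truth[:, 0] = 0.2
        truth /= truth.sum(axis=1, keepdims=True)
        truth[:, 0] = 0.2  # exactly constant in group 0
        est = rng.dirichlet(np.ones(9), size=20)
        t = comparison_stats(PairedCompositions(est, truth, np.arange(20))).table
        assert t.loc["diatoms", "skipped"]
        assert np.isnan(t.loc["diatoms", "slope"])


class TestBootstrap:
    def _db(self, rng, n=12, identical=False):
        recs = []
        base_spec = rng.uniform(0.1, 1, 9)
        base_q = rng.dirichlet(np.ones(9))
        for i in range(n):
            spec = base_spec if identical else rng.uniform(0.1, 1, 9)
            q = base_q if identical else rng.dirichlet(np.ones(9))
            recs.append(_record(spec, q, station=f"S{i}", depth_m=float(i)))
        return ReferenceDatabase(recs)

    def test_identical_references_zero_cv(self, rng):
        rep = bootstrap_sensitivity(self._db(rng, identical=True), R=20, seed=1)
        assert np.nanmax(rep.cv_jm.to_numpy()) == pytest.approx(0.0, abs=1e-9)

    def test_determinism(self, rng):
        db = self._db(rng)
        r1 = bootstrap_sensitivity(db, R=25, seed=42)
        r2 = bootstrap_sensitivity(db, R=25, seed=42)
        pd.testing.assert_frame_equal(r1.cv_jm, r2.cv_jm)
        pd.testing.assert_frame_equal(r1.cv_m, r2.cv_m)

    def test_upper95_dominates_mean(self, rng):
        rep = bootstrap_sensitivity(self._db(rng), R=25, seed=7)
        ok = rep.cv_m.dropna(subset=["sd"])
        assert (ok["upper95"] >= ok["mean"] - 1e-12).all()

    def test_small_R_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_sensitivity(self._db(rng), R=1, seed=0)


class TestAggregateGroups:
    def test_pure_chlorophyte_becomes_eukaryote(self):
        q = np.zeros(9)
        q[GROUPS.index("chlorophytes")] = 1.0
        merged = aggregate_groups(GroupComposition.from_array(q), "eukaryotes_merge")
        assert merged.fractions["eukaryotes"] == 1.0

    def test_additivity(self):
        q = np.zeros(9)
        q[GROUPS.index("haptophytes3")] = 0.2
        q[GROUPS.index("haptophytes4")] = 0.3
        q[GROUPS.index("diatoms")] = 0.5
        merged = aggregate_groups(GroupComposition.from_array(q), "eukaryotes_merge")
        assert merged.fractions["eukaryotes"] == pytest.approx(0.5)
        assert merged.fractions["diatoms"] == pytest.approx(0.5)

    def test_conservation_under_both(self, rng):
        q = rng.dirichlet(np.ones(9))
        merged = aggregate_groups(GroupComposition.from_array(q), "both")
        assert sum(merged.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert merged.fractions["cyanobacteria"] == pytest.approx(
            q[GROUPS.index("cyanophytes")] + q[GROUPS.index("prochlorophytes")])

    def test_unknown_scheme_rejected(self):
        q = GroupComposition.from_array(np.full(9, 1 / 9))
        with pytest.raises(ValueError):
            aggregate_groups(q, "everything_merge")


class TestPermanova:
    def test_matches_vegan_adonis2_partition(self):
        """Frozen oracle: sequential SS/R²/F computed by R vegan::adonis2
        (by='terms', method='bray') on the same 20×5 Dirichlet data."""
        rng = np.random.default_rng(42)
        Y = rng.dirichlet(np.ones(5), size=20)
        X = rng.normal(size=(20, 3))
        tab = _sequential_permanova(Y, X, ["x1", "x2", "x3"], n_perm=99, seed=0)
        assert tab.loc["x1", "SS"] == pytest.approx(0.04289, abs=2e-5)
        assert tab.loc["x2", "SS"] == pytest.approx(0.08067, abs=2e-5)
        assert tab.loc["x3", "SS"] == pytest.approx(0.04635, abs=2e-5)
        assert tab.loc["x1", "R2"] == pytest.approx(0.02245, abs=2e-5)
        assert tab.loc["x2", "R2"] == pytest.approx(0.04223, abs=2e-5)
        assert tab.loc["Residual", "R2"] == pytest.approx(0.91106, abs=2e-5)
        assert tab.loc["x1", "F"] == pytest.approx(0.3943, abs=2e-4)

    def test_r2_decomposition_sums_to_one(self, small_db):
        db, _ = small_db
        tab = permanova_fluorescence(db, n_perm=99, seed=1)
        assert tab["R2"].dropna().sum() == pytest.approx(1.0, abs=1e-9)

    def test_last_channel_aliased_by_standardization(self, small_db):
        # standardized channels sum to 1, so one term is collinear and skipped
        db, _ = small_db
        tab = permanova_fluorescence(db, n_perm=49, seed=1)
        assert tab["skipped"].sum() == 1

    def test_power_against_deterministic_dependence(self):
        """Compositions driven by one predictor: that term dominates R²."""
        local = np.random.default_rng(123)
        n, n_perm = 40, 199
        x = local.uniform(0, 1, n)
        Y = np.column_stack([x, 1 - x]) @ np.array(
            [[0.8, 0.1, 0.1], [0.1, 0.1, 0.8]])
        Y = np.abs(Y + local.normal(0, 0.01, Y.shape))
        X = np.column_stack([x, local.normal(size=n)])
        tab = _sequential_permanova(Y, X, ["drive", "noise"], n_perm=n_perm, seed=3)
        assert tab.loc["drive", "R2"] > 0.9
        assert tab.loc["drive", "p_value"] == pytest.approx(1 / (n_perm + 1))

    def test_type_one_error_calibrated(self, rng):
        """Independent compositions: first-term rejection rate ≈ α."""
        n_sims, rejections = 60, 0
        for s in range(n_sims):
            Y = rng.dirichlet(np.ones(5), size=30)
            X = rng.normal(size=(30, 2))
            tab = _sequential_permanova(Y, X, ["a", "b"], n_perm=99, seed=1000 + s)
            rejections += tab.loc["a", "p_value"] <= 0.05
        from scipy.stats import binom
        lo, hi = binom.ppf([0.005, 0.995], n_sims, 0.05)
        assert lo <= rejections <= hi
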