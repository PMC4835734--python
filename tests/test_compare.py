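import numpy as np
import pytest

import sirthresh as st
from sirthresh import ThresholdSet
from sirthresh.compare import METHODS


def record_from_thresholds(net, ts, lambda_c, name="net", structure=None):
    spectral_a = st.adjacency_leading(net)
    try:
        spectral_m = st.nb_leading(net)
    except st.NoCycleError:
        spectral_m = None
    return st.build_record(net, name, spectral_a, spectral_m, ts, lambda_c,
                           structure=structure)


class TestBuildRecord:
    def test_tie_resolves_to_dmp_with_flag(self, regular_4_10):
        ts = ThresholdSet(mfl=1 / 3, qmf=1 / 4, dmp=1 / 3)
        rec = record_from_thresholds(regular_4_10, ts, 0.30)
        assert rec.abs_err["MFL"] == pytest.approx(1 / 30)
        assert rec.abs_err["QMF"] == pytest.approx(0.05)
        assert rec.abs_err["DMP"] == pytest.approx(1 / 30)
        assert rec.closest_method == "DMP"
        assert rec.closest_tie

    def test_qmf_wins_when_closest(self, regular_4_10):
        ts = ThresholdSet(mfl=1 / 3, qmf=1 / 4, dmp=1 / 3)
        rec = record_from_thresholds(regular_4_10, ts, 0.25)
        assert rec.closest_method == "QMF"
        assert not rec.closest_tie

    def test_tree_record_still_valid(self, star4):
        ts = st.threshold_set(star4)
        rec = record_from_thresholds(star4, ts, 0.5)
        assert rec.lambda_M is None
        assert "DMP" not in rec.abs_err
        assert rec.closest_method in ("MFL", "QMF")

    def test_rel_err_definition(self, regular_4_10):
        ts = ThresholdSet(mfl=1 / 3, qmf=1 / 4, dmp=1 / 3)
        rec = record_from_thresholds(regular_4_10, ts, 0.25)
        for u in rec.abs_err:
            assert rec.rel_err[u] == pytest.approx(rec.abs_err[u] / 0.25)

    def test_abs_and_rel_winner_agree(self, regular_4_10):
        # lambda_c > 0 is shared, so both error scales induce the same winner
        ts = ThresholdSet(mfl=0.30, qmf=0.22, dmp=0.34)
        rec = record_from_thresholds(regular_4_10, ts, 0.28)
        by_rel = min(rec.rel_err, key=rec.rel_err.get)
        assert rec.closest_method == by_rel

    def test_regular_graph_mfl_equals_dmp_error(self, regular_4_10):
        ts = st.threshold_set(regular_4_10)
        rec = record_from_thresholds(regular_4_10, ts, 0.30)
        assert rec.abs_err["MFL"] == pytest.approx(rec.abs_err["DMP"],
                                                   abs=1e-8)


class TestClosestFrequency:
    def fake(self, regular_4_10, winner):
        vals = {m: (0.2 if m == winner else 0.3) for m in METHODS}
        ts = ThresholdSet(mfl=vals["MFL"], qmf=vals["QMF"], dmp=vals["DMP"])
        return record_from_thresholds(regular_4_10, ts, 0.2)

    def test_fractions(self, regular_4_10):
        recs = [self.fake(regular_4_10, "DMP") for _ in range(3)]
        recs.append(self.fake(regular_4_10, "MFL"))
        freq = st.closest_frequency(recs)
        assert freq == {"DMP": 0.75, "MFL": 0.25, "QMF": 0.0}

    def test_single_record(self, regular_4_10):
        freq = st.closest_frequency([self.fake(regular_4_10, "QMF")])
        assert freq["QMF"] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            st.closest_frequency([])

    def test_fractions_sum_to_one(self, regular_4_10):
        recs = [self.fake(regular_4_10, m) for m in METHODS]
        assert sum(st.closest_frequency(recs).values()) == pytest.approx(1.0)


def synthetic_record(regular_4_10, r_value, rel_errors):
    """A record with a prescribed assortativity and MFL/QMF/DMP rel errors."""
    lam_c = 0.2
    ts = ThresholdSet(
        mfl=lam_c * (1 + rel_errors["MFL"]),
        qmf=lam_c * (1 + rel_errors["QMF"]),
        dmp=lam_c * (1 + rel_errors["DMP"]),
    )
    structure = st.StructureMetrics(r=r_value, c=0.0, Q=0.0, kcore_max=2,
                                    transitivity=0.0)
    return record_from_thresholds(regular_4_10, ts, lam_c,
                                  structure=structure)


class TestBinnedErrors:
    def test_window_mean(self, regular_4_10):
        recs = [
            synthetic_record(regular_4_10, -0.21,
                             {"MFL": 0.1, "QMF": 0.1, "DMP": 0.1}),
            synthetic_record(regular_4_10, -0.19,
                             {"MFL": 0.3, "QMF": 0.3, "DMP": 0.3}),
        ]
        table = st.binned_errors(recs, "r")
        assert table.mean_rel_err.loc[-0.2, "MFL"] == pytest.approx(0.2)

    def test_empty_bin_reported_empty(self, regular_4_10):
        recs = [
            synthetic_record(regular_4_10, -0.2, {"MFL": 0.1, "QMF": 0.1,
                                                  "DMP": 0.1}),
            synthetic_record(regular_4_10, 0.2, {"MFL": 0.3, "QMF": 0.3,
                                                 "DMP": 0.3}),
        ]
        table = st.binned_errors(recs, "r")
        middle = table.mean_rel_err.loc[np.isclose(table.centers, 0.0)]
        assert middle.isna().all(axis=None)
        assert table.counts[np.isclose(table.centers, 0.0)][0] == 0

    def test_delta_x_override(self, regular_4_10):
        recs = [synthetic_record(regular_4_10, x, {"MFL": 0.1, "QMF": 0.1,
                                                   "DMP": 0.1})
                for x in (-0.05, 0.05)]
        table = st.binned_errors(recs, "r", delta_x=0.2)
        assert table.centers.size == 1
        assert table.counts[0] == 2

    def test_undefined_covariate_excluded(self, regular_4_10):
        rec_ok = synthetic_record(regular_4_10, 0.1,
                                  {"MFL": 0.1, "QMF": 0.1, "DMP": 0.1})
        ts = st.threshold_set(regular_4_10)
        structure = st.StructureMetrics(r=None, c=0.0, Q=0.0, kcore_max=2,
                                        transitivity=0.0)
        rec_undef = record_from_thresholds(regular_4_10, ts, 0.3,
                                           structure=structure)
        table = st.binned_errors([rec_ok, rec_undef], "r")
        assert table.n_excluded == 1

    def test_grand_mean_consistency(self, regular_4_10):
        # count-weighted mean of bin means equals the pooled mean rel error
        rng = np.random.default_rng(0)
        recs = []
        for _ in range(25):
            e = float(rng.uniform(0.05, 0.5))
            recs.append(synthetic_record(
                regular_4_10, float(rng.uniform(-0.4, 0.4)),
                {"MFL": e, "QMF": e, "DMP": e}))
        table = st.binned_errors(recs, "r")
        col = table.mean_rel_err["MFL"].to_numpy()
        mask = table.counts > 0
        grand = np.sum(col[mask] * table.counts[mask]) / table.counts.sum()
        pooled = np.mean([r.rel_err["MFL"] for r in recs])
        assert grand == pytest.approx(pooled)


class TestSizeScaling:
    def test_deterministic_and_well_formed(self):
        kwargs = dict(nu_D=3.0, sizes=[300, 600], n_realizations=200,
                      master_seed=4, grid_points=10)
        a = st.size_scaling_experiment(**kwargs)
        b = st.size_scaling_experiment(**kwargs)
        assert a.equals(b)
        assert list(a["N"]) == [300, 600]
        assert np.all(a["lc_qmf"] <= a["lc_dmp"] + 1e-9)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            st.size_scaling_experiment(3.0, [600, 300])
        with pytest.raises(ValueError):
            st.size_scaling_experiment(1.5, [300, 600])
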