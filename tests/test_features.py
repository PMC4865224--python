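"""PCHIP coefficients, moving averages and conventional summary parameters."""

import numpy as np
import pytest

from coagclass.cohort import Cohort, FACTORS
from coagclass.features import (
    CONVENTIONAL_NAMES,
    N_PIECES,
    N_WINDOWS,
    assemble_feature_matrix,
    conventional_features,
    fit_pchip,
    ma_window_centre,
    moving_averages,
    normalize_profile,
    pchip_knots,
    reference_peaks,
)
from coagclass.kinetics import SimulationProfile
from conftest import make_profile

import pandas as pd
from scipy.interpolate import PchipInterpolator

TIMES = np.linspace(0.0, 3600.0, 3601)


def _profile_34(seed: int = 0) -> SimulationProfile:
    """A 34-variable synthetic profile set (smooth random trajectories)."""
    rng = np.random.default_rng(seed)
    names = [f"X{i:02d}" for i in range(34)]
    rows = {
        n: np.abs(np.sin(TIMES / rng.uniform(300, 900)) + rng.normal(0, 0.01))
        for n in names
    }
    return make_profile(TIMES, rows)


def _tiny_cohort(n: int) -> Cohort:
    df = pd.DataFrame(100.0, index=range(n), columns=list(FACTORS))
    return Cohort(df, pd.Series(["A", "B"] * (n // 2), name="group"))


class TestReferencePeaks:
    def test_monotone_species_peak_is_final_value(self, toy_network):
        peaks = reference_peaks(toy_network)
        from coagclass.kinetics import simulate

        prof = simulate(toy_network)
        atiia = prof.trajectory("AT-IIa")  # product complex, non-decreasing
        assert peaks["AT-IIa"] == pytest.approx(atiia[-1])
        assert peaks["IIa"] > 0

    def test_never_produced_species_gets_unit_reference(self, caplog):
        import logging

        from coagclass.kinetics import parse_model_text
        from coagclass.features import reference_peaks

        text = (
            "[species]\n"
            + "\n".join(f"{f} = 0" for f in FACTORS)
            + "\nTf = 0\nOrphan = 0\n[reactions]\nfII -> fII, k=0.0\n"
        )
        net = parse_model_text(text)
        with caplog.at_level(logging.WARNING):
            peaks = reference_peaks(net)
        assert peaks["Orphan"] == 1.0
        assert any("Orphan" in r.message for r in caplog.records)

    def test_normalized_mean_profile_attains_one(self, toy_network):
        """Each produced species' normalized mean-composition profile peaks at 1."""
        from coagclass.kinetics import simulate
        from coagclass.cohort import to_initial_conditions

        peaks = reference_peaks(toy_network)
        x0 = to_initial_conditions({f: 100.0 for f in FACTORS}, toy_network)
        prof = simulate(toy_network, x0)
        norm = normalize_profile(prof, peaks)
        for name in ("IIa", "fXa", "fII"):
            assert norm.trajectory(name).max() == pytest.approx(1.0)


class TestPchip:
    def test_constant_profile_coefficients(self):
        prof = make_profile(TIMES, {"A": np.full_like(TIMES, 3.25)})
        coefs = fit_pchip(prof)["A"]
        assert coefs.shape == (N_PIECES, 4)
        np.testing.assert_allclose(coefs[:, :3], 0.0, atol=1e-12)
        np.testing.assert_allclose(coefs[:, 3], 3.25)

    def test_linear_profile_reproduced_exactly(self):
        a = 2.5e-3
        prof = make_profile(TIMES, {"A": a * TIMES})
        coefs = fit_pchip(prof)["A"]
        knots = pchip_knots()
        np.testing.assert_allclose(coefs[:, 0], 0.0, atol=1e-15)
        np.testing.assert_allclose(coefs[:, 1], 0.0, atol=1e-15)
        np.testing.assert_allclose(coefs[:, 2], a, rtol=1e-9)
        np.testing.assert_allclose(coefs[:, 3], a * knots[:-1], rtol=1e-9)

    def test_c0_equals_knot_value(self):
        prof = make_profile(TIMES, {"A": np.tanh((TIMES - 1500) / 400)})
        coefs = fit_pchip(prof)["A"]
        knots = pchip_knots()
        expected = np.interp(knots[:-1], TIMES, prof.concentrations[0])
        np.testing.assert_allclose(coefs[:, 3], expected, rtol=1e-12)

    def test_34_species_coefficient_count(self):
        coefs = fit_pchip(_profile_34())
        total = sum(c.size for c in coefs.values())
        assert total == 18904

    def test_monotone_data_monotone_interpolant(self):
        """Sigmoid samples: the fitted interpolant never overshoots on a
        10x denser grid (shape preservation)."""
        y = 1.0 / (1.0 + np.exp(-(TIMES - 1800.0) / 150.0))
        knots = pchip_knots()
        vals = np.interp(knots, TIMES, y)
        interp = PchipInterpolator(knots, vals)
        dense = np.linspace(0.0, 3600.0, 36001)
        out = interp(dense)
        assert np.all(np.diff(out) >= -1e-15)

    def test_profile_not_covering_knots_rejected(self):
        t = np.linspace(0.0, 1800.0, 1801)
        prof = make_profile(t, {"A": np.ones_like(t)})
        with pytest.raises(ValueError, match="knots"):
            fit_pchip(prof, t_end=3600.0)


class TestMovingAverages:
    def test_constant_profile(self):
        prof = make_profile(TIMES, {"A": np.full_like(TIMES, 0.7)})
        vals = moving_averages(prof)["A"]
        assert vals.shape == (N_WINDOWS,)
        np.testing.assert_allclose(vals, 0.7, rtol=1e-12)

    def test_linear_ramp_first_window(self):
        prof = make_profile(TIMES, {"A": TIMES.copy()})
        vals = moving_averages(prof)["A"]
        assert vals[0] == pytest.approx(100.0, rel=1e-12)

    def test_34_species_count_is_612(self):
        ma = moving_averages(_profile_34())
        assert sum(v.size for v in ma.values()) == 612

    def test_window_centres(self):
        assert ma_window_centre(0) == 100.0
        assert ma_window_centre(7) == 1500.0
        assert ma_window_centre(17) == 3500.0

    def test_window_sum_equals_auc(self):
        """The 18 windows partition [0, 3600]: 200 x sum(means) == AUC."""
        rng = np.random.default_rng(7)
        y = np.cumsum(rng.normal(size=TIMES.size)) * 1e-3 + 5.0
        prof = make_profile(TIMES, {"A": y})
        vals = moving_averages(prof)["A"]
        auc = np.trapezoid(y, TIMES)
        assert 200.0 * vals.sum() == pytest.approx(auc, rel=1e-9)


class TestConventionalFeatures:
    def test_linear_ramp_crossing_time(self):
        iia = 1e-12 * TIMES
        fxa = np.zeros_like(TIMES)
        feats = conventional_features(iia, fxa, TIMES)
        named = dict(zip(CONVENTIONAL_NAMES, feats))
        assert named["IIa|conv|t_2nM"] == pytest.approx(2000.0)

    def test_constant_profile_zero_rate_at_time_zero(self):
        iia = np.full_like(TIMES, 5e-9)
        feats = dict(zip(CONVENTIONAL_NAMES,
                         conventional_features(iia, iia, TIMES)))
        assert feats["IIa|conv|max_rate"] == pytest.approx(0.0, abs=1e-30)
        assert feats["IIa|conv|t_max_rate"] == 0.0
        assert feats["IIa|conv|t_max_level"] == 0.0

    def test_triangle_auc(self):
        rise = np.linspace(0.0, 1e-9, 1801)
        fall = np.linspace(1e-9, 0.0, 1801)[1:]
        tri = np.concatenate([rise, fall])
        feats = dict(zip(CONVENTIONAL_NAMES,
                         conventional_features(tri, tri, TIMES)))
        assert feats["IIa|conv|auc"] == pytest.approx(1.8e-6, rel=1e-9)
        assert feats["IIa|conv|max_level"] == pytest.approx(1e-9)
        assert feats["IIa|conv|t_max_level"] == pytest.approx(1800.0)

    def test_never_reaching_threshold_censored_at_end(self):
        iia = np.full_like(TIMES, 1e-12)
        feats = dict(zip(CONVENTIONAL_NAMES,
                         conventional_features(iia, iia, TIMES)))
        assert feats["IIa|conv|t_2nM"] == 3600.0


class TestAssembly:
    @pytest.mark.parametrize(
        "which,expected_cols",
        [("pchip", 34 * 139 * 4), ("ma", 34 * 18), ("conventional", 11),
         ("initial", 8)],
    )
    def test_feature_counts(self, which, expected_cols):
        n = 4
        cohort = _tiny_cohort(n)
        profiles = None
        peaks = None
        if which != "initial":
            profiles = [_profile_34(seed=i) for i in range(n)]
            if which == "conventional":
                # conventional features need IIa and fXa trajectories
                for p in profiles:
                    p.species_names[0] = "IIa"
                    p.species_names[1] = "fXa"
            peaks = {nme: 1.0 for nme in profiles[0].species_names}
        fm = assemble_feature_matrix(cohort, profiles, which, peaks=peaks)
        assert fm.shape == (n, expected_cols)
        assert len(fm.feature_labels) == expected_cols

    def test_iia_and_miia_are_distinct_features(self):
        """Both thrombin forms carry their own feature columns."""
        names = ["IIa", "mIIa", "fXa"]
        rows = {n: np.linspace(0, 1, TIMES.size) for n in names}
        prof = make_profile(TIMES, rows)
        cohort = _tiny_cohort(2)
        fm = assemble_feature_matrix(
            cohort, [prof, prof], "ma", peaks={n: 1.0 for n in names})
        assert any(lab.startswith("IIa|") for lab in fm.feature_labels)
        assert any(lab.startswith("mIIa|") for lab in fm.feature_labels)

    def test_normalization_scale_invariance(self):
        """Scaling a species' profile and its peak together leaves
        normalized features unchanged."""
        y = np.abs(np.sin(TIMES / 500.0)) + 0.1
        prof1 = make_profile(TIMES, {"A": y})
        prof2 = make_profile(TIMES, {"A": 10.0 * y})
        cohort = _tiny_cohort(2)
        fm1 = assemble_feature_matrix(
            cohort, [prof1, prof1], "ma", peaks={"A": 2.0})
        fm2 = assemble_feature_matrix(
            cohort, [prof2, prof2], "ma", peaks={"A": 20.0})
        np.testing.assert_allclose(fm1.values, fm2.values, rtol=1e-12)

    def test_profile_count_mismatch_rejected(self):
        cohort = _tiny_cohort(4)
        prof = make_profile(TIMES, {"A": np.ones_like(TIMES)})
        with pytest.raises(ValueError, match="one profile per cohort sample"):
            assemble_feature_matrix(cohort, [prof], "ma", peaks={"A": 1.0})

    def test_select_unknown_label_rejected(self):
        cohort = _tiny_cohort(2)
        fm = assemble_feature_matrix(cohort, None, "initial")
        with pytest.raises(KeyError, match="unknown feature label"):
            fm.select(["nope|ma|w00"])

    def test_export_layout(self, tmp_path):
        cohort = _tiny_cohort(2)
        fm = assemble_feature_matrix(cohort, None, "initial")
        path = tmp_path / "fm.csv"
        fm.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns[:2]) == ["sample_id", "group"]
        assert df.shape == (2, 10)
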