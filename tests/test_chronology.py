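"""CRS dating: supported level, inventories, missing-inventory correction,
age/MAR recovery against simulator ground truth, and extrapolation."""

import warnings

import numpy as np
import pandas as pd
import pytest

from sedflux.chronology import (
    PB210_LAMBDA,
    ActivityProfile,
    ChronologyError,
    EquilibriumWarning,
    MEASURED,
    build_chronology,
    correct_missing_inventory,
    crs_model,
    cumulative_residual_inventory,
    estimate_supported,
    extrapolate_ages,
    unsupported_profile,
)
from sedflux.core_io import CoreProfile
from sedflux.synthetic import build_synthetic_core, preset


def _profile(depths, pb210=None, ra226=None, dbd=0.2):
    n = len(depths) - 1
    df = pd.DataFrame(
        {
            "depth_top_cm": depths[:-1],
            "depth_bottom_cm": depths[1:],
            "dbd_g_cm3": [dbd] * n,
        }
    )
    if pb210 is not None:
        df["pb210_bq_kg"] = pb210
    if ra226 is not None:
        df["ra226_bq_kg"] = ra226
    return CoreProfile(df)


def _activity_profile(activities, dm=0.1, supported=0.0):
    a = np.asarray(activities, float)
    bottom = dm * np.arange(1, len(a) + 1)
    return ActivityProfile(
        data=pd.DataFrame(
            {
                "layer_id": np.arange(len(a)),
                "unsupported": a,
                "unsupported_sd": np.zeros_like(a),
                "mass_top": bottom - dm,
                "mass_bottom": bottom,
                "clipped": False,
            }
        ),
        supported=supported,
    )


class TestSupported:
    def test_ra226_mean(self):
        p = _profile([0, 0.5, 1.0, 1.5], pb210=[100, 80, 60], ra226=[20, 22, 18])
        assert estimate_supported(p, "ra226-mean") == pytest.approx(20.0)

    def test_deep_asymptote_recovers_simulated_level(self):
        """A core long enough to reach equilibrium: deepest-layer mean
        recovers the generating supported level within 5%."""
        import dataclasses

        base = preset("remote-highland").noise_free()
        sc = dataclasses.replace(
            base,
            span_years=320,
            mar_control_points=((1694.0, 69.0),) + base.mar_control_points[1:],
        )
        profile, truth = build_synthetic_core(sc, seed=0)
        est = estimate_supported(profile, "deep-asymptote")
        assert est == pytest.approx(truth.supported, rel=0.05)

    def test_no_equilibrium_warns_but_returns(self):
        p = _profile([0, 0.5, 1.0, 1.5, 2.0], pb210=[200, 180, 160, 150])
        with pytest.warns(EquilibriumWarning):
            est = estimate_supported(p, "deep-asymptote")
        assert est > 0

    def test_no_data_raises(self):
        p = _profile([0, 0.5], pb210=[100.0])
        with pytest.raises(ChronologyError):
            estimate_supported(p, "ra226-mean")


class TestUnsupported:
    def test_subtraction_and_clipping(self):
        p = _profile([0, 0.5, 1.0], pb210=[120.0, 15.0])
        ap = unsupported_profile(p, supported=20.0)
        assert ap.data["unsupported"].tolist() == [100.0, 0.0]
        assert ap.data["clipped"].tolist() == [False, True]

    def test_cumulative_mass_steps(self):
        p = _profile([0, 0.5, 1.0, 1.5], pb210=[100, 80, 60], dbd=0.2)
        ap = unsupported_profile(p, supported=0.0)
        assert ap.data["mass_bottom"].tolist() == pytest.approx([0.1, 0.2, 0.3])


class TestInventory:
    def test_single_layer_closed_form(self):
        # two layers so the integral is defined; deepest has zero activity
        ap = _activity_profile([50.0, 0.0], dm=0.1)
        inv = cumulative_residual_inventory(ap)
        assert inv[0] == pytest.approx(50.0 * 0.1 * 10.0)  # Bq m⁻²
        assert inv[-1] == 0.0

    def test_zero_activity_zero_inventory(self):
        inv = cumulative_residual_inventory(_activity_profile([0.0, 0.0, 0.0]))
        assert np.all(inv == 0.0)

    def test_exponential_profile_matches_closed_form_integral(self):
        """Midpoint-sampled exponential: summed inventory within 1% of
        A0/k·(1−e^{−kM}) at 0.5 cm resolution."""
        k, a0, dm, n = 2.0, 100.0, 0.1, 30
        mid = dm * (np.arange(n) + 0.5)
        ap = _activity_profile(a0 * np.exp(-k * mid), dm=dm)
        inv = cumulative_residual_inventory(ap)
        closed = a0 / k * (1 - np.exp(-k * n * dm)) * 10.0
        assert inv[0] == pytest.approx(closed, rel=0.01)


class TestMissingInventory:
    def test_equilibrium_profile_has_negligible_tail(self, remote_nf):
        profile, truth, _ = remote_nf
        ap = unsupported_profile(profile, truth.supported)
        corrected = correct_missing_inventory(ap, tail_k=4)
        total = cumulative_residual_inventory(ap)[0]
        assert corrected.missing_inventory < 0.01 * total

    def test_hand_calculated_tail(self):
        """Activities halving over equal mass steps: fitted decay per unit
        mass is ln2/dm and the tail integral has a closed form."""
        dm = 1.0
        ap = _activity_profile([8.0, 4.0, 2.0, 1.0], dm=dm)
        corrected = correct_missing_inventory(ap, tail_k=4)
        k = np.log(2.0) / dm
        a_bottom = 8.0 * np.sqrt(2.0) * 2.0 ** (-4.0)  # fitted activity at m=4
        assert corrected.missing_inventory == pytest.approx(a_bottom / k * 10.0, rel=1e-6)

    def test_non_decaying_tail_raises(self):
        ap = _activity_profile([1.0, 2.0, 4.0, 8.0])
        with pytest.raises(ChronologyError, match="not decaying"):
            correct_missing_inventory(ap)

    def test_truncated_core_ages_restored_within_2yr(self):
        """Removing the deepest ~10% of inventory and correcting restores
        CRS ages within 2 yr of the full-core ages.

        Uses a constant-MAR scenario so the activity tail is exactly
        exponential in cumulative mass — the regime the log-linear tail
        fit models."""
        import dataclasses

        sc = dataclasses.replace(
            preset("remote-highland").noise_free(),
            mar_control_points=((1754.0, 69.0), (2014.0, 69.0)),
        )
        profile, truth = build_synthetic_core(sc, seed=0)
        ap = unsupported_profile(profile, truth.supported)
        ap_full = correct_missing_inventory(ap, tail_k=4)
        full_model = crs_model(ap_full, 2014, profile=profile, max_age=200.0)
        inv = cumulative_residual_inventory(ap)
        cut = int(np.argmax(inv < 0.10 * inv[0]))  # first boundary below 10%
        short = CoreProfile(profile.data.iloc[:cut].copy())
        ap_short = unsupported_profile(short, truth.supported)
        ap_short = correct_missing_inventory(ap_short, tail_k=4)
        model = crs_model(ap_short, 2014, profile=short, max_age=200.0)
        merged = model.data.merge(
            full_model.data, on="layer_id", suffixes=("_short", "_full")
        )
        both = (merged["source_flag_short"] == MEASURED) & (
            merged["source_flag_full"] == MEASURED
        )
        err = (merged.loc[both, "year_short"] - merged.loc[both, "year_full"]).abs()
        assert both.sum() > 5
        assert err.max() < 2.0


class TestCRS:
    def test_halflife_identity(self):
        """I(m) = I(0)/2 at a boundary ⇔ age exactly one half-life."""
        ap = _activity_profile([10.0, 10.0], dm=0.1)
        model = crs_model(ap, coring_year=2014)
        # equal-activity equal-mass layers: boundary between them holds I0/2
        assert model.data["year_top"].iloc[1] == pytest.approx(2014 - 22.3, abs=1e-9)

    def test_surface_age_is_zero(self):
        ap = _activity_profile([10.0, 5.0, 2.0], dm=0.1)
        model = crs_model(ap, coring_year=2014)
        assert model.data["year_top"].iloc[0] == pytest.approx(2014.0)

    def test_forward_inverse_recovery(self, remote_nf):
        """Noise-free forward-simulated core: CRS years within ±1 yr and
        MAR within 2% of truth over the last 150 yr at 0.5 cm layers."""
        profile, truth, model = remote_nf
        m = model.data.merge(truth.layers, on="layer_id")
        recent = (m["source_flag"] == MEASURED) & (m["year_true"] > 2014 - 150)
        assert recent.sum() >= 10
        year_err = (m.loc[recent, "year"] - m.loc[recent, "year_true"]).abs()
        mar_rel = (
            (m.loc[recent, "mar_g_m2_yr"] - m.loc[recent, "mar_true"])
            / m.loc[recent, "mar_true"]
        ).abs()
        assert year_err.max() < 1.0
        assert mar_rel.max() < 0.02

    def test_recovery_error_shrinks_with_layer_thickness(self):
        """Forward–inverse consistency: discretization error decreases as
        layers get thinner (1.0 / 0.5 / 0.25 cm)."""
        errs = []
        for thickness in (1.0, 0.5, 0.25):
            sc = preset("remote-highland").noise_free().with_thickness(thickness)
            profile, truth = build_synthetic_core(sc, seed=0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = build_chronology(profile, coring_year=2014)
            m = model.data.merge(truth.layers, on="layer_id")
            recent = (m["source_flag"] == MEASURED) & (m["year_true"] > 2014 - 120)
            errs.append((m.loc[recent, "year"] - m.loc[recent, "year_true"]).abs().max())
        assert errs[0] > errs[1] > errs[2]

    def test_mar_positive_and_ages_monotone(self, remote_noisy):
        _, _, model = remote_noisy
        dated = model.data[model.data["source_flag"] == MEASURED]
        assert (dated["mar_g_m2_yr"] > 0).all()
        assert model.data["age_yr"].is_monotonic_increasing


class TestExtrapolation:
    def test_ols_hand_check(self):
        """Dated years {1908, 1902, 1896, 1891} at equal depth steps
        extrapolate to ≈1885 at the next step (OLS slope −5.7 yr/step)."""
        depths = np.arange(0, 3.0, 0.5)
        pb = [100.0, 50.0, 25.0, 12.0, np.nan]
        p = _profile(depths, pb210=pb + [])
        # build a model by hand: 4 dated layers + 1 undated
        ap = unsupported_profile(
            CoreProfile(p.data.fillna({"pb210_bq_kg": 0.0})), supported=0.0
        )
        model = crs_model(ap, 2014, profile=p)
        model.data.loc[:3, "year"] = [1908.0, 1902.0, 1896.0, 1891.0]
        model.data.loc[:3, "source_flag"] = MEASURED
        model.data.loc[4, "source_flag"] = ""
        model.data.loc[4, "year"] = np.nan
        out = extrapolate_ages(model, p, n_anchor=4)
        assert out.data.loc[4, "year"] == pytest.approx(1885.0, abs=1.0)
        assert out.data.loc[4, "source_flag"] == "extrapolated"

    def test_constant_mar_extrapolation_matches_truth(self, remote_nf):
        """Pre-1950 MAR is constant, so linear extrapolation recovers true
        deposition years within 2 yr down to 250 yr before coring."""
        profile, truth, model = remote_nf
        m = model.data.merge(truth.layers, on="layer_id")
        extra = (m["source_flag"] == "extrapolated") & (m["year_true"] > 2014 - 250)
        assert extra.any()
        err = (m.loc[extra, "year"] - m.loc[extra, "year_true"]).abs()
        assert err.max() < 2.0

    def test_extrapolated_never_younger_than_deepest_dated(self, remote_nf):
        _, _, model = remote_nf
        d = model.data
        oldest_dated = d.loc[d["source_flag"] == MEASURED, "year"].min()
        extra = d[d["source_flag"] == "extrapolated"]
        assert (extra["year"] <= oldest_dated).all()

    def test_too_few_anchors_raises(self):
        p = _profile([0, 0.5, 1.0], pb210=[100.0, 50.0])
        ap = unsupported_profile(p, supported=0.0)
        model = crs_model(ap, 2014, profile=p)
        with pytest.raises(ChronologyError):
            extrapolate_ages(model, p, n_anchor=4)
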