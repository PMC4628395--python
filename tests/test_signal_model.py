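"""Signal-model unit and property tests.

Oracles: direct evaluation of the Freeman-Hill closed form, numeric
maximization over flip angle for the sqrt(T2/T1) limit, and parameter
sweeps for the monotone MT/T1/T2 contrast mechanisms.
"""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from bssfp2pt import (
    AcquisitionParams,
    ParameterError,
    TissueParams,
    bssfp_signal_single_pool,
    bssfp_signal_two_pool,
    delta_s_predicted,
    signal_sweep,
)

# Direct hand evaluation of the closed form at tr=3.2, te=1.2, a=45 deg,
# t1=950, t2=46, m0=1:  E1=exp(-3.2/950), E2=exp(-3.2/46),
# S = sin(a)(1-E1)/(1-(E1-E2)cos(a)-E1E2) * exp(-1.2/46) = 0.0919386
HAND_SINGLE_POOL_45 = 0.0919386


class TestSinglePool:
    def test_matches_hand_evaluated_closed_form(self, acq45):
        s = bssfp_signal_single_pool(acq45, TissueParams(t1=950, t2=46))
        assert s == pytest.approx(HAND_SINGLE_POOL_45, rel=1e-5)

    def test_zero_excitation_limit(self):
        tissue = TissueParams(t1=950, t2=46)
        acq = AcquisitionParams(tr=3.2, te=1.2, flip_angle=1e-6)
        assert bssfp_signal_single_pool(acq, tissue) < 1e-6

    def test_optimal_angle_approaches_sqrt_t2_over_t1(self):
        """For TR << T1, T2 the maximum over flip angle approaches
        (m0/2) sqrt(T2/T1) at cos(a*) = (T1/T2-1)/(T1/T2+1)."""
        t1, t2 = 1000.0, 100.0
        tissue = TissueParams(t1=t1, t2=t2)

        def neg_signal(a_deg):
            return -bssfp_signal_single_pool(
                AcquisitionParams(tr=1.0, te=0.5, flip_angle=a_deg, rf_duration=0.3),
                tissue,
            )

        res = minimize_scalar(neg_signal, bounds=(1.0, 90.0), method="bounded")
        s_max = -res.fun
        assert s_max == pytest.approx(0.5 * math.sqrt(t2 / t1), rel=0.02)
        ratio = t1 / t2
        a_star = math.degrees(math.acos((ratio - 1) / (ratio + 1)))
        assert res.x == pytest.approx(a_star, abs=2.0)

    @pytest.mark.parametrize("alpha", [5.0, 15.0, 45.0, 70.0, 90.0])
    @pytest.mark.parametrize("t1,t2", [(300, 40), (950, 46), (1600, 250), (2000, 100)])
    def test_signal_bounded_by_m0(self, alpha, t1, t2):
        acq = AcquisitionParams(tr=3.2, te=1.2, flip_angle=alpha)
        m0 = 2.5
        s = bssfp_signal_single_pool(acq, TissueParams(t1=t1, t2=t2, m0=m0))
        assert 0 < s <= m0


class TestTwoPool:
    def test_single_pool_reduction_over_grid(self):
        """F = 0 must reduce to the closed form within 1e-6 relative over a
        grid of >= 100 (flip angle, T1, T2) combinations."""
        count = 0
        for alpha in (5, 15, 30, 45, 60, 75, 90):
            for t1 in (300, 700, 950, 1200, 1600):
                for t2 in (30, 46, 100, 250):
                    if t2 > t1:
                        continue
                    acq = AcquisitionParams(tr=3.2, te=1.2, flip_angle=alpha)
                    tissue = TissueParams(t1=t1, t2=t2, bound_fraction=0.0)
                    s_closed = bssfp_signal_single_pool(acq, tissue)
                    s_iter = bssfp_signal_two_pool(acq, tissue)
                    assert abs(s_iter - s_closed) / s_closed < 1e-6
                    count += 1
        assert count >= 100

    def test_signal_decreases_with_bound_fraction(self, acq45):
        signals = [
            bssfp_signal_two_pool(acq45, TissueParams(t1=950, t2=46, bound_fraction=f))
            for f in np.linspace(0.0, 0.2, 9)
        ]
        assert all(a > b for a, b in zip(signals, signals[1:]))

    @pytest.mark.parametrize("alpha", [5.0, 20.0, 45.0, 70.0])
    def test_mt_attenuation_monotone_at_every_angle(self, alpha):
        acq = AcquisitionParams(tr=3.2, te=1.2, flip_angle=alpha)
        signals = [
            bssfp_signal_two_pool(acq, TissueParams(t1=950, t2=46, bound_fraction=f))
            for f in (0.0, 0.05, 0.12, 0.2)
        ]
        assert all(a >= b for a, b in zip(signals, signals[1:]))

    def test_attenuation_weaker_at_low_flip_angle(self, acq5, acq45):
        """W scales with the square of the flip angle, so the two-pool /
        single-pool ratio must be closer to 1 at 5 than at 45 degrees."""
        tissue = TissueParams(t1=950, t2=46, bound_fraction=0.12)
        single = TissueParams(t1=950, t2=46, bound_fraction=0.0)
        ratio5 = bssfp_signal_two_pool(acq5, tissue) / bssfp_signal_two_pool(acq5, single)
        ratio45 = bssfp_signal_two_pool(acq45, tissue) / bssfp_signal_two_pool(
            acq45, single
        )
        assert ratio45 < ratio5 <= 1.0

    def test_signal_positive_and_bounded(self, acq45):
        tissue = TissueParams(t1=950, t2=46, m0=3.0, bound_fraction=0.12)
        s = bssfp_signal_two_pool(acq45, tissue)
        assert 0 < s <= 3.0


class TestDeltaSPredicted:
    def test_identical_flip_angles_rejected(self, acq45):
        with pytest.raises(ParameterError):
            delta_s_predicted(acq45, acq45, TissueParams(t1=950, t2=46))

    def test_equal_angle_limit_is_zero(self, acq5):
        """dS/S0 -> 0 as the two flip angles coincide."""
        almost = acq5.with_flip_angle(5.0 + 1e-9)
        val = delta_s_predicted(acq5, almost, TissueParams(t1=950, t2=46))
        assert abs(val) < 1e-4

    def test_lesion_exceeds_remote(self, acq5, acq45):
        """Edema-like tissue (longer T2, depleted bound pool) must show
        higher dS/S0 than healthy remote myocardium — the core contrast."""
        remote = TissueParams(t1=950, t2=46, bound_fraction=0.12)
        lesion = TissueParams(t1=1200, t2=130, bound_fraction=0.01)
        assert delta_s_predicted(acq5, acq45, lesion) > delta_s_predicted(
            acq5, acq45, remote
        )

    def test_increasing_t1_alone_decreases_delta_s(self, acq5, acq45):
        vals = [
            delta_s_predicted(acq5, acq45, TissueParams(t1=t1, t2=46, bound_fraction=0.1))
            for t1 in (800, 1000, 1200, 1400)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_increasing_t2_alone_increases_delta_s(self, acq5, acq45):
        vals = [
            delta_s_predicted(acq5, acq45, TissueParams(t1=1200, t2=t2, bound_fraction=0.1))
            for t2 in (40, 60, 90, 130)
        ]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(tr=-1, te=0.5, flip_angle=45),
            dict(tr=3.2, te=0.0, flip_angle=45),
            dict(tr=3.2, te=3.3, flip_angle=45),
            dict(tr=3.2, te=1.2, flip_angle=0),
            dict(tr=3.2, te=1.2, flip_angle=95),
            dict(tr=3.2, te=1.2, flip_angle=45, rf_duration=3.5),
        ],
    )
    def test_invalid_acquisition_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            AcquisitionParams(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(t1=40, t2=46),
            dict(t1=950, t2=0),
            dict(t1=950, t2=46, m0=0),
            dict(t1=950, t2=46, bound_fraction=1.0),
            dict(t1=950, t2=46, bound_fraction=-0.1),
            dict(t1=950, t2=46, exchange_rate=-1),
        ],
    )
    def test_invalid_tissue_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            TissueParams(**kwargs)


def test_signal_sweep_table(acq45, tmp_path):
    df = signal_sweep(
        acq45,
        flip_angles_deg=[5.0, 45.0],
        t1s_ms=[950.0, 1200.0],
        t2s_ms=[46.0, 130.0],
        bound_fractions=[0.0, 0.12],
    )
    assert set(df.columns) == {
        "flip_angle_deg", "t1_ms", "t2_ms", "bound_fraction", "signal", "delta_s_pct",
    }
    # reference angle rows have dS/S0 = 0 by definition
    ref = df[df.flip_angle_deg == 5.0]
    assert np.allclose(ref.delta_s_pct, 0.0, atol=1e-9)
    out = tmp_path / "sweep.csv"
    df.to_csv(out, index=False)
    assert out.exists() and out.stat().st_size > 0
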