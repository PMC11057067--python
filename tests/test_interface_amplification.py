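import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from lungstress import (
    DomainError,
    InterfacePair,
    PlausibilityWarning,
    UsageError,
    amplifiers,
    interface_state,
    mead_pressure_amplifier,
)

ratio_st = st.floats(min_value=0.1, max_value=10.0, allow_nan=False)


def sphere_radius_oracle(volume: float) -> float:
    """Radius by root-finding on the volume cubic, independent of the package."""
    return brentq(lambda r: 4.0 / 3.0 * math.pi * r**3 - volume, 0.0, 1e3, xtol=1e-13)


class TestAmplifiers:
    def test_tenfold_ratio(self, tenfold_pair):
        amp = amplifiers(tenfold_pair)
        assert amp.stress_multiplier == pytest.approx(2.15443, abs=1e-5)
        assert amp.strain_multiplier == pytest.approx(4.64159, abs=1e-5)
        assert amp.energy_ratio == pytest.approx(10.0, rel=1e-12)

    def test_equal_compliances_identity(self):
        amp = amplifiers(InterfacePair(c1=7.0, c2=7.0))
        assert amp.stress_multiplier == amp.strain_multiplier == amp.energy_ratio == 1.0

    def test_reciprocity(self):
        a = amplifiers(InterfacePair(c1=4.0, c2=1.0))
        b = amplifiers(InterfacePair(c1=1.0, c2=4.0))
        assert a.stress_multiplier * b.stress_multiplier == pytest.approx(1.0, rel=1e-12)

    @given(ratio_st)
    def test_product_identity(self, ratio):
        """stress x strain == energy ratio == C1/C2, to 1e-12."""
        amp = amplifiers(InterfacePair(c1=ratio, c2=1.0), plausibility_band=(0.0, math.inf))
        assert amp.stress_multiplier * amp.strain_multiplier == pytest.approx(
            amp.energy_ratio, rel=1e-12
        )
        assert amp.energy_ratio == pytest.approx(ratio, rel=1e-12)

    @given(st.floats(1.0, 10.0), st.floats(1e-3, 1e3))
    def test_scale_invariance(self, ratio, k):
        a = amplifiers(InterfacePair(c1=ratio, c2=1.0))
        b = amplifiers(InterfacePair(c1=k * ratio, c2=k))
        assert a.stress_multiplier == pytest.approx(b.stress_multiplier, rel=1e-12)

    def test_monotone_in_ratio(self):
        ratios = np.linspace(1.01, 10.0, 50)
        stresses = [amplifiers(InterfacePair(c1=r, c2=1.0)).stress_multiplier for r in ratios]
        assert all(b > a for a, b in zip(stresses, stresses[1:]))

    def test_implausible_ratio_warns_not_errors(self):
        with pytest.warns(PlausibilityWarning):
            amp = amplifiers(InterfacePair(c1=50.0, c2=1.0))
        assert amp.energy_ratio == pytest.approx(50.0)

    def test_flexible_first_orientation(self):
        amp = amplifiers(InterfacePair(c1=1.0, c2=8.0), orient="flexible_first")
        assert amp.stress_multiplier == pytest.approx(2.0, rel=1e-12)

    def test_nonpositive_compliance_rejected(self):
        with pytest.raises(Exception):
            InterfacePair(c1=0.0, c2=1.0)


class TestInterfaceState:
    def test_tension_ratio_cube_root_of_eight(self):
        state = interface_state(InterfacePair(c1=10.0, c2=1.25, delta_p=5.0))
        assert state.tension_ratio == pytest.approx(2.0, rel=1e-9)
        assert state.area_ratio == pytest.approx(4.0, rel=1e-9)

    def test_equal_pair_identical_states(self):
        state = interface_state(InterfacePair(c1=3.0, c2=3.0, delta_p=7.0))
        assert state.flexible == state.stiff

    def test_missing_delta_p_usage_error(self, tenfold_pair):
        with pytest.raises(UsageError):
            interface_state(tenfold_pair)

    def test_matches_radius_oracle_on_random_pairs(self):
        """Tension/area ratios from numerically inverted volumes equal the closed forms."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            c1, c2 = rng.uniform(0.5, 20.0, size=2)
            dp = rng.uniform(1.0, 20.0)
            state = interface_state(InterfacePair(c1=c1, c2=c2, delta_p=dp))
            r1 = sphere_radius_oracle(c1 * dp)
            r2 = sphere_radius_oracle(c2 * dp)
            assert state.tension_ratio == pytest.approx(r1 / r2, rel=1e-9)
            assert state.area_ratio == pytest.approx((r1 / r2) ** 2, rel=1e-9)
            amp = amplifiers(
                InterfacePair(c1=c1, c2=c2), plausibility_band=(0.0, math.inf)
            )
            assert state.tension_ratio == pytest.approx(amp.stress_multiplier, rel=1e-9)
            assert state.area_ratio == pytest.approx(amp.strain_multiplier, rel=1e-9)

    def test_baseline_volumes_shift_ratios_toward_one(self):
        pair = InterfacePair(c1=10.0, c2=1.0, delta_p=5.0)
        with_base = interface_state(pair, baseline_volumes=(100.0, 100.0))
        without = interface_state(pair)
        assert 1.0 < with_base.tension_ratio < without.tension_ratio


class TestMeadAmplifier:
    def test_tenfold_exceeds_fourfold_bound(self):
        value = mead_pressure_amplifier(10.0)
        assert value == pytest.approx(4.6416, abs=1e-4)
        assert value >= 4.0  # the classical "fourfold" estimate is a lower bound

    def test_identity_and_perfect_cube(self):
        assert mead_pressure_amplifier(1.0) == 1.0
        assert mead_pressure_amplifier(8.0) == pytest.approx(4.0, rel=1e-12)

    def test_ratio_below_one_rejected(self):
        with pytest.raises(DomainError):
            mead_pressure_amplifier(0.5)

    @given(st.floats(1.0, 10.0))
    def test_shares_exponent_with_strain_multiplier(self, r):
        amp = amplifiers(InterfacePair(c1=r, c2=1.0))
        assert mead_pressure_amplifier(r) == pytest.approx(amp.strain_multiplier, rel=1e-12)
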