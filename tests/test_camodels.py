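"""Closed-form allosteric QC(V, Ca) curves vs brute-force enumeration."""

import itertools

import numpy as np
import pytest

from bkgating import camodels
from bkgating.camodels import (
    AllostericModelSpec,
    SiteConfig,
    channel_occupancy_distribution,
    qc_scheme1,
    qc_scheme2,
    subunit_occupancy,
)
from bkgating.errors import InvalidParameterError
from bkgating.thermo import thermal_voltage_mv


def brute_force_qc(v, ca, m, temperature=295.0):
    """Statistical-mechanical oracle: enumerate every subunit binding
    configuration of the tetramer and average the activated-sensor fraction.

    Kept deliberately independent of the closed forms: binding weights are
    multiplied out per configuration and sensors are equilibrated state by
    state.
    """
    vt = thermal_voltage_mv(temperature)
    J = m.j0 * np.exp(m.zj * v / vt)
    if m.sites.n_sites == 1:
        states = [0, 1]  # per-subunit bound count
        weight = {0: 1.0, 1: ca / m.sites.kd}
        site_factor = {0: 1.0, 1: m.e_factor}
        event = {0: 1.0, 1: m.e_factor ** 0.25}
    else:
        states = [(0, 0), (1, 0), (0, 1), (1, 1)]
        kd1, kd2, g = m.sites.kd1, m.sites.kd2, m.sites.g
        weight = {(0, 0): 1.0, (1, 0): ca / kd1, (0, 1): ca / kd2,
                  (1, 1): g * ca * ca / (kd1 * kd2)}
        site_factor = {s: m.e_s1 ** s[0] * m.e_s2 ** s[1] for s in states}
        event = {s: (m.e_s1 ** 0.25) ** s[0] * (m.e_s2 ** 0.25) ** s[1]
                 for s in states}

    total_w = 0.0
    total_q = 0.0
    for config in itertools.product(states, repeat=4):
        w = 1.0
        for s in config:
            w *= weight[s]
        if m.scheme == "I":
            frac = 0.0
            for s in config:
                je = J * site_factor[s]
                frac += je / (1.0 + je) / 4.0
        else:
            amp = 1.0
            for s in config:
                amp *= event[s]
            je = J * amp
            frac = je / (1.0 + je)
        total_w += w
        total_q += w * frac
    return total_q / total_w


class TestSubunitOccupancy:
    def test_one_site_half_occupancy_at_kd(self):
        occ = subunit_occupancy(11.0, SiteConfig(kd=11.0))
        assert occ.x == pytest.approx(0.5)

    def test_two_site_independent_factorizes(self):
        s = SiteConfig(n_sites=2, kd1=4.9, kd2=6.9, g=1.0)
        occ = subunit_occupancy(10.0, s)
        x1 = 10.0 / (10.0 + 4.9)
        x2 = 10.0 / (10.0 + 6.9)
        expected = [(1 - x1) * (1 - x2), x1 * (1 - x2), (1 - x1) * x2, x1 * x2]
        assert np.allclose(occ.probs, expected, rtol=1e-12)

    def test_two_site_double_occupancy_value(self):
        s = SiteConfig(n_sites=2, kd1=4.9, kd2=6.9, g=1.0)
        occ = subunit_occupancy(10.0, s)
        assert occ.probs[3] == pytest.approx(0.397, abs=5e-4)

    def test_negative_ca_rejected(self):
        with pytest.raises(InvalidParameterError):
            subunit_occupancy(-1.0, SiteConfig(kd=11.0))


class TestChannelOccupancy:
    def test_half_occupancy_is_symmetric_binomial(self):
        occ = subunit_occupancy(11.0, SiteConfig(kd=11.0))
        dist = channel_occupancy_distribution(occ)
        assert np.allclose(dist, np.array([1, 4, 6, 4, 1]) / 16.0)

    def test_zero_ca_is_point_mass(self):
        occ = subunit_occupancy(0.0, SiteConfig(kd=11.0))
        dist = channel_occupancy_distribution(occ)
        assert dist[0] == pytest.approx(1.0)
        assert np.allclose(dist[1:], 0.0)

    def test_two_site_joint_matches_enumeration(self):
        s = SiteConfig(n_sites=2, kd1=4.9, kd2=6.9, g=2.0)
        occ = subunit_occupancy(5.0, s)
        dist = channel_occupancy_distribution(occ)
        # brute-force over all 4^4 subunit configurations
        expected = np.zeros((5, 5))
        states = [(0, 0), (1, 0), (0, 1), (1, 1)]
        for config in itertools.product(range(4), repeat=4):
            p = np.prod([occ.probs[c] for c in config])
            n1 = sum(states[c][0] for c in config)
            n2 = sum(states[c][1] for c in config)
            expected[n1, n2] += p
        assert np.allclose(dist, expected, atol=1e-14)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)


class TestClosedForms:
    def test_scheme1_zero_ca_is_bare_boltzmann(self, scheme1_demo):
        v = np.linspace(-90, 350, 20)
        vt = thermal_voltage_mv(295.0)
        J = 0.018 * np.exp(0.58 * v / vt)
        assert np.allclose(qc_scheme1(v, 0.0, scheme1_demo), J / (1 + J), rtol=1e-12)

    def test_scheme1_saturation_is_amplified_boltzmann(self, scheme1_demo):
        v = np.linspace(-90, 350, 20)
        vt = thermal_voltage_mv(295.0)
        JE = 25.0 * 0.018 * np.exp(0.58 * v / vt)
        assert np.allclose(
            qc_scheme1(v, 1e9, scheme1_demo), JE / (1 + JE), rtol=1e-6
        )

    def test_scheme1_reference_value(self, scheme1_demo):
        assert qc_scheme1(100.0, 3.0, scheme1_demo) == pytest.approx(0.293, abs=1e-3)

    def test_scheme2_reference_value(self, scheme2_demo):
        assert qc_scheme2(100.0, 3.0, scheme2_demo) == pytest.approx(0.277, abs=1e-3)

    def test_scheme2_zero_ca_is_bare_boltzmann(self, scheme2_demo):
        v = np.linspace(-90, 350, 20)
        vt = thermal_voltage_mv(295.0)
        J = 0.018 * np.exp(0.58 * v / vt)
        assert np.allclose(qc_scheme2(v, 0.0, scheme2_demo), J / (1 + J), rtol=1e-12)

    def test_unit_event_factor_gives_single_boltzmann(self):
        m = AllostericModelSpec(scheme="II", sites=SiteConfig(kd=11.0),
                                zj=0.58, j0=0.018, e_factor=1.0)
        v = np.linspace(-90, 350, 20)
        for ca in (0.0, 1.0, 11.0, 1000.0):
            assert np.allclose(
                qc_scheme2(v, ca, m), qc_scheme2(v, 0.0, m), rtol=1e-12
            )

    def test_scheme_mismatch_rejected(self, scheme1_demo, scheme2_demo):
        with pytest.raises(InvalidParameterError):
            qc_scheme1(0.0, 0.0, scheme2_demo)
        with pytest.raises(InvalidParameterError):
            qc_scheme2(0.0, 0.0, scheme1_demo)

    def test_schemes_agree_at_both_ca_limits(self, scheme1_demo, scheme2_demo):
        v = np.linspace(-90, 350, 20)
        assert np.allclose(qc_scheme1(v, 0.0, scheme1_demo),
                           qc_scheme2(v, 0.0, scheme2_demo), rtol=1e-12)
        assert np.allclose(qc_scheme1(v, 1e8, scheme1_demo),
                           qc_scheme2(v, 1e8, scheme2_demo), rtol=1e-5)

    def test_monotone_in_v_and_ca(self, scheme1_demo, scheme2_demo):
        v = np.linspace(-90, 350, 45)
        cas = [0.0, 0.5, 2.0, 11.0, 50.0, 1000.0]
        for m, fn in ((scheme1_demo, qc_scheme1), (scheme2_demo, qc_scheme2)):
            prev = None
            for ca in cas:
                q = fn(v, ca, m)
                assert np.all(np.diff(q) > 0)
                if prev is not None:
                    assert np.all(q >= prev - 1e-12)
                prev = q


class TestBruteForceEquivalence:
    """Closed forms vs enumeration of all subunit binding configurations."""

    @pytest.mark.parametrize("ca", [0.0, 0.7, 3.0, 11.0, 120.0])
    def test_one_site_both_schemes(self, ca, scheme1_demo, scheme2_demo):
        v = np.linspace(-90, 350, 20)
        for m, fn in ((scheme1_demo, qc_scheme1), (scheme2_demo, qc_scheme2)):
            closed = np.array([fn(float(x), ca, m) for x in v])
            oracle = np.array([brute_force_qc(float(x), ca, m) for x in v])
            assert np.allclose(closed, oracle, atol=1e-12, rtol=1e-12)

    @pytest.mark.parametrize("scheme", ["I", "II"])
    @pytest.mark.parametrize("g", [1.0, 3.5])
    def test_two_site_with_and_without_cooperativity(self, scheme, g):
        m = AllostericModelSpec(
            scheme=scheme, sites=SiteConfig(n_sites=2, kd1=4.9, kd2=6.9, g=g),
            zj=0.61, j0=0.019, e_s1=4.57, e_s2=5.35,
        )
        fn = qc_scheme1 if scheme == "I" else qc_scheme2
        v = np.linspace(-90, 350, 20)
        for ca in (0.0, 2.0, 6.0, 30.0):
            closed = np.array([fn(float(x), ca, m) for x in v])
            oracle = np.array([brute_force_qc(float(x), ca, m) for x in v])
            assert np.allclose(closed, oracle, atol=1e-12, rtol=1e-12)

    @pytest.mark.parametrize("scheme", ["I", "II"])
    def test_two_site_reduces_to_one_site(self, scheme):
        # silent second site (factor 1, negligible affinity) recovers the
        # one-site formula with the first site's parameters
        two = AllostericModelSpec(
            scheme=scheme, sites=SiteConfig(n_sites=2, kd1=11.0, kd2=1e9, g=1.0),
            zj=0.58, j0=0.018, e_s1=25.0, e_s2=1.0,
        )
        one = AllostericModelSpec(
            scheme=scheme, sites=SiteConfig(kd=11.0),
            zj=0.58, j0=0.018, e_factor=25.0,
        )
        fn = qc_scheme1 if scheme == "I" else qc_scheme2
        v = np.linspace(-90, 350, 20)
        for ca in (0.0, 3.0, 11.0, 100.0):
            assert np.allclose(fn(v, ca, two), fn(v, ca, one), rtol=1e-9)


class TestDoseCurves:
    def test_saturating_vh_is_scheme_independent(self, scheme1_demo, scheme2_demo,
                                                 v_protocol):
        ca = np.array([1e5])
        d1 = camodels.predicted_dose_curves(scheme1_demo, ca, v_protocol)
        d2 = camodels.predicted_dose_curves(scheme2_demo, ca, v_protocol)
        assert d1["vh_mV"].iloc[0] == pytest.approx(d2["vh_mV"].iloc[0], abs=0.5)

    def test_scheme2_vh_shifts_monotonically_left(self, scheme2_demo, v_protocol):
        cas = np.array([0.01, 0.1, 1.0, 5.0, 11.0, 50.0, 1000.0])
        d = camodels.predicted_dose_curves(scheme2_demo, cas, v_protocol)
        assert np.all(np.diff(d["vh_mV"].to_numpy()) < 0)

    def test_scheme1_zq_has_interior_minimum_near_kd(self, scheme1_demo, v_protocol):
        cas = np.array([0.01, 0.3, 1.0, 3.0, 11.0, 30.0, 100.0, 3000.0])
        d = camodels.predicted_dose_curves(scheme1_demo, cas, v_protocol)
        zq = d["zq"].to_numpy()
        k = int(np.argmin(zq))
        assert 0 < k < len(cas) - 1  # interior
        assert 1.0 <= cas[k] <= 30.0  # near KD = 11 uM
        assert zq[k] < 0.9 * scheme1_demo.zj


def test_model_spec_json_round_trip(tmp_path, scheme2_demo):
    path = tmp_path / "model.json"
    scheme2_demo.to_json(path)
    back = AllostericModelSpec.from_json(path)
    assert back == scheme2_demo
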