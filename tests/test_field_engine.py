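import numpy as np
import pytest

from hemoloop import (
    BLOOD,
    HO,
    DiscreteFlowField,
    StreamlineHistory,
    StressIntegral,
    cell_effective_stress,
    damage_index,
    effective_stress,
    lagrangian_damage,
    outlet_damage,
    source_term,
    stress_volume_integral,
)
from hemoloop.field_engine import (
    read_field_csv,
    read_field_vtu,
    write_field_csv,
    write_field_vtu,
)
from hemoloop.synthetic_data import generate_pump_like_field, generate_uniform_field

Q = 5.0 / 60000.0  # 5 L/min in m^3/s


def uniform_field(tau=50.0, volume=2e-5, n_cells=10):
    field, _ = generate_uniform_field(tau, volume, Q, n_cells)
    return field


class TestFieldValidation:
    def test_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError, match="volume"):
            DiscreteFlowField(
                volumes=[1e-6, 0.0], eps_vis=[1.0, 1.0], eps_turb=[0.0, 0.0], Q=Q
            )

    def test_rejects_negative_dissipation(self):
        with pytest.raises(ValueError, match="eps_turb"):
            DiscreteFlowField(
                volumes=[1e-6], eps_vis=[1.0], eps_turb=[-0.1], Q=Q
            )

    def test_rejects_empty_and_mismatched(self):
        with pytest.raises(ValueError):
            DiscreteFlowField(volumes=[], eps_vis=[], eps_turb=[], Q=Q)
        with pytest.raises(ValueError, match="shape"):
            DiscreteFlowField(
                volumes=[1e-6, 1e-6], eps_vis=[1.0], eps_turb=[0.0], Q=Q
            )

    def test_total_volume(self):
        f = uniform_field(volume=2e-5, n_cells=8)
        assert f.total_volume == pytest.approx(2e-5, rel=1e-12)


class TestCellStress:
    def test_zero_field_gives_zero_stress(self):
        f = uniform_field(tau=0.0)
        assert np.all(cell_effective_stress(f) == 0.0)

    def test_dissipation_components_add(self):
        f = DiscreteFlowField(
            volumes=[1e-6], eps_vis=[0.6], eps_turb=[0.4], Q=Q
        )
        assert cell_effective_stress(f)[0] == pytest.approx(1.9216, abs=1e-4)
        assert cell_effective_stress(f)[0] == pytest.approx(
            effective_stress(1.0), rel=1e-14
        )


class TestStressIntegral:
    def test_zero_field_gives_zero_S(self, constants):
        si = stress_volume_integral(uniform_field(tau=0.0), constants)
        assert si.S == 0.0

    @pytest.mark.parametrize("n_cells", [1, 10, 1000])
    def test_partition_invariance(self, n_cells, constants):
        """S is exactly invariant under dissipation-preserving subdivision."""
        volume = 2e-5
        si = stress_volume_integral(
            uniform_field(tau=50.0, volume=volume, n_cells=n_cells), constants
        )
        expected = source_term(50.0, constants) * volume
        assert si.S == pytest.approx(expected, rel=1e-12)

    def test_pump_like_field_deterministic(self, constants):
        s1 = stress_volume_integral(generate_pump_like_field(7, 500), constants).S
        s2 = stress_volume_integral(generate_pump_like_field(7, 500), constants).S
        assert s1 == s2  # bit-identical

    def test_invalid_S_rejected(self):
        with pytest.raises(ValueError):
            StressIntegral(S=-1.0, constants_name="HO", Q=Q)


class TestOutletDamage:
    def test_zero_S_gives_zero_damage(self, constants):
        si = StressIntegral(S=0.0, constants_name=constants.name, Q=Q)
        assert outlet_damage(si, constants) == 0.0

    def test_reduces_to_power_law_with_residence_time(self, constants):
        """Uniform field: D = damage_index(tau, V/Q) exactly."""
        tau, volume = 80.0, 3e-5
        si = stress_volume_integral(
            uniform_field(tau=tau, volume=volume), constants
        )
        d = outlet_damage(si, constants)
        assert d == pytest.approx(
            damage_index(tau, volume / Q, constants), rel=1e-10
        )

    def test_flow_rate_scaling(self, constants):
        si = StressIntegral(S=1e-3, constants_name=constants.name, Q=Q)
        si2 = StressIntegral(S=1e-3, constants_name=constants.name, Q=2 * Q)
        assert outlet_damage(si2, constants) == pytest.approx(
            2**-constants.beta * outlet_damage(si, constants), rel=1e-12
        )

    def test_constants_mismatch_rejected(self):
        si = StressIntegral(S=1.0, constants_name="TZ", Q=Q)
        with pytest.raises(ValueError, match="TZ"):
            outlet_damage(si, HO)


class TestLagrangian:
    def test_constant_history_matches_power_law(self, constants):
        t_end, tau = 0.4, 60.0
        hist = StreamlineHistory(
            times=np.linspace(0, t_end, 50), taus=np.full(50, tau)
        )
        assert lagrangian_damage(hist, constants) == pytest.approx(
            damage_index(tau, t_end, constants), rel=1e-10
        )

    def test_two_segment_history_matches_hand_sum(self, constants):
        t1, t2, tau1, tau2 = 0.2, 0.3, 40.0, 90.0
        eps = 1e-10
        hist = StreamlineHistory(
            times=[0.0, t1, t1 + eps, t1 + t2],
            taus=[tau1, tau1, tau2, tau2],
        )
        di = source_term(tau1, constants) * t1 + source_term(tau2, constants) * (
            t2 - eps
        )
        assert lagrangian_damage(hist, constants) == pytest.approx(
            di**constants.beta, rel=1e-8
        )

    def test_plug_flow_equals_eulerian(self, constants):
        """Eulerian-Lagrangian equivalence on a uniform field."""
        tau, volume = 50.0, 2e-5
        f = uniform_field(tau=tau, volume=volume)
        d_euler = outlet_damage(stress_volume_integral(f, constants), constants)
        hist = StreamlineHistory(
            times=np.linspace(0, volume / Q, 20), taus=np.full(20, tau)
        )
        assert lagrangian_damage(hist, constants) == pytest.approx(
            d_euler, rel=1e-6
        )

    def test_short_history_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            lagrangian_damage(StreamlineHistory(times=[0.0], taus=[1.0]), HO)

    def test_history_validation(self):
        with pytest.raises(ValueError, match="t=0"):
            StreamlineHistory(times=[0.1, 0.2], taus=[1.0, 1.0])
        with pytest.raises(ValueError, match="increasing"):
            StreamlineHistory(times=[0.0, 0.2, 0.2], taus=[1.0, 1.0, 1.0])


class TestFieldIO:
    @pytest.mark.parametrize(
        "writer,reader,suffix",
        [
            (write_field_csv, read_field_csv, "csv"),
            (write_field_vtu, read_field_vtu, "vtu"),
        ],
    )
    def test_round_trip_and_bit_stability(self, tmp_path, writer, reader, suffix):
        f = generate_pump_like_field(3, 200, label="roundtrip")
        p1, p2 = tmp_path / f"a.{suffix}", tmp_path / f"b.{suffix}"
        writer(f, p1)
        writer(f, p2)
        assert p1.read_bytes() == p2.read_bytes()  # bit-stable writer
        g = reader(p1)
        np.testing.assert_array_equal(g.volumes, f.volumes)
        np.testing.assert_array_equal(g.eps_vis, f.eps_vis)
        np.testing.assert_array_equal(g.eps_turb, f.eps_turb)
        assert g.Q == f.Q
        assert g.fluid == f.fluid
        assert g.label == f.label

    def test_csv_missing_eps_turb_defaults_to_zero(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text("# Q = 8e-5\nvolume,eps_vis\n1e-6,10.0\n2e-6,5.0\n")
        g = read_field_csv(p)
        assert np.all(g.eps_turb == 0.0)
        assert g.fluid == BLOOD  # header defaults

    def test_csv_missing_Q_rejected(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text("volume,eps_vis,eps_turb\n1e-6,1,0\n")
        with pytest.raises(ValueError, match="Q"):
            read_field_csv(p)
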