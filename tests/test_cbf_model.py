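import numpy as np
import pytest
from scipy.interpolate import CubicSpline

from cbf3select.cbf_model import (
    ArchitectureSpec,
    CBFParameters,
    count_free_parameters,
    enumerate_ensemble,
    production_rate,
    simulate_cbf3,
)
from cbf3select.clock_driver import REGIMES, simulate_clock

TABLE_LABELS = [
    "EC↓:TOC1↓:LHY/CCA1↑",
    "EC↓:TOC1↓",
    "EC↓:LHY/CCA1↑",
    "EC↓",
    "LHY/CCA1↑:TOC1↓",
    "TOC1↓",
    "LHY/CCA1↑",
    "LHY/CCA1↑:NI↓:PRR7↓:PRR9↓",
    "EC↑",
    "NI↓:PRR7↓:PRR9↓",
    "NI↓",
    "PRR7↓",
    "PRR9↓",
]


def params_for(arch, k=0.3, d=1.0, v_max=1.0, hill_n=2.0):
    return CBFParameters(v_max=v_max, K={sp: k for sp in arch.regulators}, d=d, hill_n=hill_n)


class TestEnsemble:
    def test_thirteen_members_with_published_labels(self):
        assert [a.label for a in enumerate_ensemble()] == TABLE_LABELS

    def test_top_member_regulator_signs(self):
        top = enumerate_ensemble()[0]
        assert set(top.activators) == {"LHY_CCA1"}
        assert set(top.repressors) == {"EC", "TOC1"}

    def test_last_member_is_prr9_repression_only(self):
        last = enumerate_ensemble()[-1]
        assert last.activators == ()
        assert set(last.repressors) == {"PRR9"}

    @pytest.mark.parametrize(
        "arch_idx, expected_k",
        [(6, 3), (1, 4), (0, 5), (7, 6), (9, 5)],
        ids=["one-regulator", "two-regulator", "three-regulator", "lhy+3prr", "3prr"],
    )
    def test_free_parameter_counts(self, arch_idx, expected_k):
        assert count_free_parameters(enumerate_ensemble()[arch_idx]) == expected_k

    def test_overlapping_roles_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(activators=("EC",), repressors=("EC",))

    def test_empty_architecture_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec()


class TestProductionRate:
    def test_half_saturation_of_single_activator(self):
        arch = ArchitectureSpec(activators=("LHY_CCA1",))
        p = params_for(arch, k=0.7, v_max=2.0)
        rate = production_rate(arch, p, {"LHY_CCA1": 0.7})
        assert rate == pytest.approx(1.0)

    def test_zero_activator_silences_transcription(self):
        arch = enumerate_ensemble()[0]
        p = params_for(arch)
        rate = production_rate(arch, p, {"LHY_CCA1": 0.0, "EC": 0.2, "TOC1": 0.2})
        assert rate == 0.0

    def test_three_regulator_product_hand_value(self):
        arch = enumerate_ensemble()[0]
        p = CBFParameters(v_max=1.0, K={"LHY_CCA1": 1.0, "EC": 1.0, "TOC1": 1.0}, d=1.0)
        state = {"LHY_CCA1": 1.0, "EC": 1.0, "TOC1": 1.0}
        assert production_rate(arch, p, state) == pytest.approx(0.125)

    @pytest.mark.parametrize("arch", enumerate_ensemble(), ids=lambda a: a.label)
    def test_bounded_and_monotone(self, arch):
        rng = np.random.default_rng(42)
        p = params_for(arch)
        state = {sp: rng.uniform(0.0, 2.0) for sp in arch.regulators}
        base = production_rate(arch, p, state)
        assert 0.0 <= base <= p.v_max
        for sp in arch.activators:
            up = dict(state, **{sp: state[sp] + 0.5})
            assert production_rate(arch, p, up) >= base
        for sp in arch.repressors:
            up = dict(state, **{sp: state[sp] + 0.5})
            assert production_rate(arch, p, up) <= base

    def test_negative_abundance_rejected(self):
        arch = ArchitectureSpec(activators=("LHY_CCA1",))
        with pytest.raises(ValueError):
            production_rate(arch, params_for(arch), {"LHY_CCA1": -0.1})

    def test_non_positive_half_saturation_rejected(self):
        with pytest.raises(ValueError):
            CBFParameters(v_max=1.0, K={"EC": 0.0}, d=1.0)


def rk4_reference(clock, arch, params, t_end, dt=0.001):
    """Fixed-step 4th-order Runge-Kutta oracle on splined clock inputs."""
    splines = {sp: CubicSpline(clock.times, clock.abundances[sp]) for sp in arch.regulators}
    half = np.arange(0, int(round(t_end / dt)) * 2 + 1) * (dt / 2.0)
    state = {sp: np.clip(splines[sp](half), 0.0, None) for sp in arch.regulators}
    p = np.broadcast_to(
        np.asarray(production_rate(arch, params, state), dtype=float), half.shape
    )
    d = params.d
    c = p[0] / d
    out = [c]
    for k in range(int(round(t_end / dt))):
        p0, pm, p1 = p[2 * k], p[2 * k + 1], p[2 * k + 2]
        k1 = p0 - d * c
        k2 = pm - d * (c + 0.5 * dt * k1)
        k3 = pm - d * (c + 0.5 * dt * k2)
        k4 = p1 - d * (c + dt * k3)
        c = c + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(c)
    return half[::2], np.asarray(out)


@pytest.fixture(scope="module")
def clock():
    return simulate_clock(REGIMES["12L/12D"], duration=48.0, step=0.5)


class TestSimulateCbf3:
    def test_frozen_clock_converges_to_rate_over_degradation(self):
        clock = simulate_clock(REGIMES["12L/12D"], duration=96.0, step=0.5)
        frozen = {sp: np.full_like(clock.times, 0.6) for sp in clock.abundances}
        clock = type(clock)(
            times=clock.times, abundances=frozen, regime=clock.regime, baseline=frozen
        )
        arch = ArchitectureSpec(activators=("LHY_CCA1",))
        p = params_for(arch, k=0.3, d=0.5)
        traj = simulate_cbf3(clock, arch, p, initial_mrna=0.0)
        expected = production_rate(arch, p, {"LHY_CCA1": 0.6}) / p.d
        assert traj.mrna[-1] == pytest.approx(expected, rel=1e-6)

    def test_knocked_out_sole_activator_decays_exponentially(self, clock):
        from cbf3select.clock_driver import GENOTYPES

        arch = ArchitectureSpec(activators=("LHY_CCA1",))
        p = params_for(arch, d=0.8)
        mut = clock.with_genotype(GENOTYPES["lhy cca1"])
        traj = simulate_cbf3(mut, arch, p, initial_mrna=2.0)
        np.testing.assert_allclose(
            traj.mrna, 2.0 * np.exp(-p.d * traj.times), rtol=1e-9, atol=1e-12
        )

    @pytest.mark.parametrize("arch", enumerate_ensemble(), ids=lambda a: a.label)
    def test_matches_fine_step_rk4_oracle(self, clock, arch):
        p = params_for(arch, k=0.3, d=1.5)
        traj = simulate_cbf3(clock, arch, p)
        t_ref, c_ref = rk4_reference(clock, arch, p, t_end=48.0)
        on_grid = c_ref[::500]  # 0.001 h oracle grid -> 0.5 h clock grid
        err = np.max(np.abs(traj.mrna - on_grid)) / np.max(np.abs(on_grid))
        assert err < 1e-4

    def test_bounded_by_vmax_over_d(self, clock):
        arch = enumerate_ensemble()[0]
        p = params_for(arch, d=0.3, v_max=2.0)
        traj = simulate_cbf3(clock, arch, p)
        assert np.all(traj.mrna >= 0.0)
        assert np.all(traj.mrna <= p.v_max / p.d + 1e-9)

    def test_periodic_after_transient(self):
        clock = simulate_clock(REGIMES["12L/12D"], duration=168.0, step=0.5)
        arch = enumerate_ensemble()[0]
        p = params_for(arch, d=1.0)
        traj = simulate_cbf3(clock, arch, p)
        per_day = int(round(24.0 / clock.step))
        last = traj.mrna[-per_day:]
        prev = traj.mrna[-2 * per_day : -per_day]
        # tolerance matches the integrator's 1e-4 relative accuracy class
        assert np.max(np.abs(last - prev)) < 1e-4 * np.max(last)

    def test_negative_initial_condition_rejected(self, clock):
        arch = enumerate_ensemble()[0]
        with pytest.raises(ValueError):
            simulate_cbf3(clock, arch, params_for(arch), initial_mrna=-1.0)

    def test_monotone_response_to_pointwise_activator_increase(self, clock):
        arch = ArchitectureSpec(activators=("LHY_CCA1",), repressors=("EC",))
        p = params_for(arch)
        boosted = {
            sp: (1.5 * arr if sp == "LHY_CCA1" else arr)
            for sp, arr in clock.abundances.items()
        }
        clock_up = type(clock)(
            times=clock.times, abundances=boosted, regime=clock.regime, baseline=boosted
        )
        lo = simulate_cbf3(clock, arch, p)
        hi = simulate_cbf3(clock_up, arch, p)
        assert np.all(hi.mrna >= lo.mrna - 1e-12)
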