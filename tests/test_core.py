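"""Unit and property tests for the deterministic stage dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jab.core import (PARAM_NAMES, Constants, PlotForcing, SpeciesParams, StageState,
                      dd_rates, derive_constants, seedling_input, simulate, step)

TINY = 1e-300  # effectively-zero positive rate (parameters must stay positive)


def make_params(species, **overrides):
    base = {name: [TINY] * len(species) for name in PARAM_NAMES}
    base.update({k: np.atleast_1d(v) for k, v in overrides.items()})
    return SpeciesParams.from_natural(species, base)


class TestConstants:
    def test_beta_uA_from_threshold_diameter(self):
        consts = derive_constants(dbh_AB_cm=18.0)
        assert consts.beta_uA == pytest.approx(math.pi * 0.09**2, abs=1e-12)
        assert consts.beta_uA == pytest.approx(0.0254469, abs=1e-7)

    def test_unit_circle_diameter(self):
        # dbh 200 cm = radius 1 m: basal area is exactly pi
        assert derive_constants(dbh_AB_cm=200.0).beta_uA == pytest.approx(math.pi, abs=1e-12)

    def test_default_mean_basal_areas(self):
        consts = derive_constants()
        np.testing.assert_array_equal(consts.beta_mA, [0.01586, 0.01611])
        assert 0 < consts.dbh_JA_cm < consts.dbh_AB_cm

    @pytest.mark.parametrize("kwargs", [
        {"dbh_AB_cm": -1.0}, {"beta_mA": [0.01, -0.01]}, {"dbh_JA_cm": 30.0},
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            derive_constants(**{"dbh_AB_cm": 18.0, **kwargs})


class TestSeedlingInput:
    def test_fitted_rates_give_published_input(self):
        # l from the fitted posterior means, B_p the mean initial basal areas
        L = seedling_input(np.exp([4.018, 5.398]), [5.1049, 18.395])
        assert L == pytest.approx([283.78, 4064.63], abs=0.05)

    def test_zero_regional_basal_area(self):
        np.testing.assert_array_equal(seedling_input([1.0, 2.0], [0.0, 0.0]), [0.0, 0.0])

    def test_identity_scaling(self):
        np.testing.assert_array_equal(seedling_input([1.0, 1.0], [2.0, 3.0]), [2.0, 3.0])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            seedling_input([1.0, 1.0], [2.0, 3.0, 4.0])


class TestStep:
    def test_identity_when_all_rates_vanish(self):
        consts = Constants(beta_uA=0.025, beta_mA=np.array([0.02, 0.02]))
        params = make_params(["a", "b"])
        forcing = PlotForcing(B_p=np.zeros(2), L_p=np.zeros(2))
        s0 = StageState.from_stages([10.0, 5.0], [3.0, 2.0], [1.0, 0.5], consts)
        s1 = step(s0, params, forcing, consts)
        np.testing.assert_allclose(s1.J, s0.J, rtol=1e-12)
        np.testing.assert_allclose(s1.A, s0.A, rtol=1e-12)
        np.testing.assert_allclose(s1.B, s0.B, rtol=1e-12)
        np.testing.assert_allclose(s1.BA, s1.A * consts.beta_mA + s1.B, atol=1e-9)

    def test_full_transition_boundary_g_equals_one(self):
        # g = 1 empties the sapling stage: J' is exactly the external input
        consts = Constants(beta_uA=0.025, beta_mA=np.array([0.02]))
        params = make_params(["sp"], g=1.0)
        forcing = PlotForcing(B_p=np.array([1.0]), L_p=np.array([2.0]))
        s0 = StageState.from_stages([100.0], [1.0], [1.0], consts)
        s1 = step(s0, params, forcing, consts)
        assert s1.J[0] == pytest.approx(2.0, rel=1e-12)

    def test_hand_computed_single_species_step(self, single_species):
        # independent scalar computation of one step
        state, params, forcing, consts = single_species
        s1 = step(state, params, forcing, consts)
        assert s1.J[0] == pytest.approx(96.14603, abs=1e-4)
        assert s1.A[0] == pytest.approx(44.46194, abs=1e-4)
        assert s1.B[0] == pytest.approx(10.63304, abs=1e-4)
        assert s1.BA[0] == pytest.approx(11.52228, abs=1e-4)

    def test_transition_rates_above_one_rejected(self):
        with pytest.raises(ValueError):
            make_params(["sp"], g=1.5)
        with pytest.raises(ValueError):
            make_params(["sp"], h=1.0 + 1e-9)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            StageState(J=[-1.0], A=[1.0], B=[1.0], BA=[1.0])


class TestSimulate:
    def test_zero_horizon(self, single_species):
        state, params, forcing, consts = single_species
        traj = simulate(state, params, forcing, consts, 0)
        assert len(traj) == 1 and traj[0] is state

    def test_replay_determinism(self, single_species):
        state, params, forcing, consts = single_species
        t1 = simulate(state, params, forcing, consts, 30)
        t2 = simulate(state, params, forcing, consts, 30)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.J, b.J) and np.array_equal(a.B, b.B)
        # replaying step over the trajectory reproduces it bitwise
        for k in range(30):
            s = step(t1[k], params, forcing, consts)
            assert np.array_equal(s.J, t1[k + 1].J)
            assert np.array_equal(s.A, t1[k + 1].A)
            assert np.array_equal(s.B, t1[k + 1].B)

    def test_overstory_recursion_matches_scalar_oracle(self):
        # with J = A = L_p = 0 the B stage follows B' = (1+b)B / (1+c_B·B),
        # a scalar recursion converging monotonically to b/c_B
        consts = Constants(beta_uA=0.025, beta_mA=np.array([0.02]))
        b, c_B = 0.05, 1e-3
        params = make_params(["sp"], b=b, c_B=c_B)
        forcing = PlotForcing(B_p=np.zeros(1), L_p=np.zeros(1))
        s0 = StageState.from_stages([0.0], [0.0], [1.0], consts)
        traj = simulate(s0, params, forcing, consts, 3000)
        B_oracle = 1.0
        for k in range(1, 101):
            B_oracle = (1 + b) * B_oracle / (1 + c_B * B_oracle)
            assert traj[k].B[0] == pytest.approx(B_oracle, rel=1e-9)
        assert traj[-1].B[0] == pytest.approx(b / c_B, rel=1e-6)
        diffs = np.diff([s.B[0] for s in traj.states])
        assert np.all(diffs > -1e-12)  # monotone approach

    def test_trajectory_frame_layout(self, single_species):
        state, params, forcing, consts = single_species
        df = simulate(state, params, forcing, consts, 3).to_frame(["sp"])
        assert list(df.columns) == ["t", "species", "J", "A", "B", "BA"]
        assert df["t"].tolist() == [0, 1, 2, 3]


class TestDensityDependentRates:
    def test_empty_forest_returns_log_rates(self):
        consts = Constants(beta_uA=0.025, beta_mA=np.array([0.02]))
        params = make_params(["sp"], g=0.1, h=0.2, b=0.05)
        s = StageState.from_stages([0.0], [0.0], [0.0], consts)
        dd = dd_rates(s, params)
        assert dd["log_g_dd"][0] == pytest.approx(np.log(0.1), abs=1e-12)
        assert dd["log_h_dd"][0] == pytest.approx(np.log(0.2), abs=1e-12)
        assert dd["log_b_dd"][0] == pytest.approx(np.log(0.05), abs=1e-12)

    def test_fitted_rates_at_equilibrium_state(self, fitted_params):
        from jab.datasets import reference_stage_state

        params, _ = fitted_params
        dd = dd_rates(reference_stage_state("equilibrium"), params)
        assert dd["log_b_dd"][0] == pytest.approx(-4.806, abs=0.01)   # Fagus
        assert dd["log_h_dd"][1] == pytest.approx(-2.886, abs=0.01)   # others


def _random_setup(data, n_species=2):
    """Random parameters within the vague prior ranges and a random state."""
    prior = {"r": (4.0, 2.0), "l": (4.0, 2.0), "c_J": (-10.0, 2.0), "s": (-6.0, 2.0),
             "g": (-5.0, 2.0), "c_A": (-7.0, 2.0), "h": (-4.0, 2.0), "b": (-3.2, 1.0),
             "c_B": (-7.0, 2.0)}
    logv = {}
    for name, (mu, sd) in prior.items():
        vals = [data.draw(st.floats(mu - 2 * sd, min(mu + 2 * sd, 0.0) if name in ("g", "h")
                                    else mu + 2 * sd)) for _ in range(n_species)]
        logv[name] = np.array(vals)
    params = SpeciesParams(["a", "b"][:n_species], logv)
    consts = Constants(beta_uA=0.0254469, beta_mA=np.full(n_species, 0.016))
    pos = st.floats(1e-3, 1e4)
    state = StageState.from_stages([data.draw(pos) for _ in range(n_species)],
                                   [data.draw(pos) for _ in range(n_species)],
                                   [data.draw(st.floats(1e-3, 1e2)) for _ in range(n_species)],
                                   consts)
    forcing = PlotForcing.from_l(params.l, np.array([data.draw(st.floats(0.0, 40.0))
                                                     for _ in range(n_species)]))
    return state, params, forcing, consts


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.data())
def test_positivity_and_ba_consistency(data):
    """Strictly positive inputs keep every simulated state strictly positive."""
    state, params, forcing, consts = _random_setup(data)
    traj = simulate(state, params, forcing, consts, 60)
    for s in traj:
        assert np.all(s.J > 0) and np.all(s.A > 0) and np.all(s.B > 0)
        np.testing.assert_allclose(s.BA, s.A * consts.beta_mA + s.B, atol=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.data())
def test_stronger_competition_never_increases_the_affected_stage(data):
    state, params, forcing, consts = _random_setup(data)
    base = step(state, params, forcing, consts)
    for name, stage in (("c_J", "J"), ("s", "J"), ("c_A", "A"), ("c_B", "B")):
        harder = params.replace(**{name: params.log(name) + np.log(3.0)})
        nxt = step(state, harder, forcing, consts)
        assert np.all(getattr(nxt, stage) <= getattr(base, stage) + 1e-12)
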