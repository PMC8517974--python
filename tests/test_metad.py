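"""Hill deposition, bias evaluation, walls, walkers."""

import math

import numpy as np
import pytest

from znmt.constants import KB_KCAL_MOL_K
from znmt.dynamics import ToySystem, double_well
from znmt.errors import ValidationError
from znmt.metad import (
    BiasParams,
    Hill,
    HillsLog,
    WallParams,
    _BiasGrid,
    bias_potential,
    pb_bias_potential,
    pbmetad_deposition_weights,
    run_pbmetad,
    run_wt_metad,
    wall_energy,
    wt_hill_height,
)


class TestBiasPotential:
    def test_no_hills_is_zero(self):
        assert bias_potential(0.3, []) == 0.0

    def test_height_at_center(self):
        h = Hill("s", center=1.0, sigma=0.12, height=0.6)
        assert bias_potential(1.0, [h]) == pytest.approx(0.6)

    def test_brute_force_sum_oracle(self, rng):
        hills = [Hill("s", float(c), 0.12, float(h))
                 for c, h in zip(rng.normal(0, 1, 40), rng.uniform(0.1, 0.6, 40))]
        log = HillsLog("s")
        for h in hills:
            log.append(h)
        for s in rng.uniform(-2, 2, 10):
            expect = sum(h.height * math.exp(-(s - h.center) ** 2
                                             / (2 * h.sigma**2)) for h in hills)
            assert bias_potential(float(s), hills) == pytest.approx(expect,
                                                                    rel=1e-12)
            assert log.potential(float(s)) == pytest.approx(expect, rel=1e-10)


class TestWtHeight:
    def test_initial_height_at_zero_bias(self):
        assert wt_hill_height(0.0, BiasParams()) == pytest.approx(0.6)

    def test_unit_exponent(self):
        p = BiasParams()
        v = KB_KCAL_MOL_K * p.delta_t
        assert wt_hill_height(v, p) == pytest.approx(0.6 / math.e)

    def test_large_gamma_recovers_standard_metadynamics(self):
        p = BiasParams(gamma=1e9)
        assert wt_hill_height(50.0, p) == pytest.approx(0.6, rel=1e-4)

    def test_strictly_decreasing(self):
        p = BiasParams()
        hs = [wt_hill_height(v, p) for v in (0.0, 1.0, 3.0, 10.0)]
        assert all(a > b for a, b in zip(hs, hs[1:]))

    def test_boost_temperature_is_5100K(self):
        assert BiasParams(gamma=18.0, temperature=300.0).delta_t == (
            pytest.approx(5100.0)
        )


class TestDepositionWeights:
    def test_equal_bias_uniform(self):
        w = pbmetad_deposition_weights([1.0, 1.0, 1.0], 300.0)
        assert np.allclose(w, 1 / 3)

    def test_single_cv(self):
        assert pbmetad_deposition_weights([2.0], 300.0) == pytest.approx([1.0])

    def test_ten_kbt_split(self):
        kbt = KB_KCAL_MOL_K * 300.0
        w = pbmetad_deposition_weights([0.0, 10.0 * kbt], 300.0)
        expect = 1.0 / (1.0 + math.exp(-10.0))
        assert w[0] == pytest.approx(expect, rel=1e-10)
        assert w[1] == pytest.approx(1.0 - expect, rel=1e-6)

    def test_sum_to_one(self, rng):
        w = pbmetad_deposition_weights(rng.uniform(0, 20, 7), 300.0)
        assert w.sum() == pytest.approx(1.0)


class TestWalls:
    def test_inside_region_zero(self):
        w = WallParams(4.0, 10.0, "upper")
        assert wall_energy(2.0, w) == 0.0
        assert wall_energy(4.0, w) == 0.0

    def test_quadratic_beyond(self):
        assert wall_energy(5.0, WallParams(4.0, 10.0, "upper")) == (
            pytest.approx(10.0)
        )
        assert wall_energy(-1.0, WallParams(0.0, 7.0, "lower")) == (
            pytest.approx(7.0)
        )


class TestBiasGridCache:
    def test_matches_direct_summation_to_1e6(self, rng):
        grid = _BiasGrid(-2.0, 2.0, 801)
        log = HillsLog("s")
        for c, h in zip(rng.uniform(-1.5, 1.5, 300),
                        rng.uniform(0.05, 0.6, 300)):
            hill = Hill("s", float(c), 0.12, float(h))
            log.append(hill)
            grid.add_gaussian(hill.center, hill.sigma, hill.height)
        for s in rng.uniform(-1.9, 1.9, 50):
            v_grid, f_grid = grid.value_force(float(s))
            v_direct = log.potential(float(s))
            assert abs(v_grid - v_direct) < 1e-6
            # force consistent with a central difference of the direct sum
            eps = 1e-5
            f_direct = -(log.potential(float(s) + eps)
                         - log.potential(float(s) - eps)) / (2 * eps)
            assert abs(f_grid - f_direct) < 1e-3


class TestWtMetadRuns:
    def test_zero_height_matches_unbiased_and_deposits_nothing(self):
        system = ToySystem(potentials=[double_well(a=3.0)])
        p1 = BiasParams(h0=0.0, stride=500)
        p2 = BiasParams(h0=0.0, stride=173)
        r1 = run_wt_metad(system, p1, n_steps=20_000, seed=5)
        r2 = run_wt_metad(system, p2, n_steps=20_000, seed=5)
        assert len(r1.hills) == 0
        assert np.array_equal(r1.colvar, r2.colvar)

    def test_seed_determinism(self):
        system = ToySystem(potentials=[double_well(a=3.0)])
        r1 = run_wt_metad(system, BiasParams(), n_steps=30_000, n_walkers=2,
                          seed=8)
        r2 = run_wt_metad(system, BiasParams(), n_steps=30_000, n_walkers=2,
                          seed=8)
        assert np.array_equal(r1.colvar, r2.colvar)
        assert r1.hills.arrays()[2].tolist() == r2.hills.arrays()[2].tolist()

    def test_bias_drives_barrier_crossing(self):
        """With deposition on, both wells are visited in a run whose
        unbiased counterpart stays trapped."""
        system = ToySystem(potentials=[double_well(a=5.0)])
        run = run_wt_metad(system, BiasParams(), n_steps=250_000, n_walkers=2,
                           seed=1)
        s = run.colvar.ravel()
        assert (s > 0.5).any() and (s < -0.5).any()

    def test_hills_log_replay_matches_internal_bias(self):
        system = ToySystem(potentials=[double_well(a=3.0)])
        run = run_wt_metad(system, BiasParams(), n_steps=60_000, seed=3)
        v_replay = bias_potential(run.final_point, run.hills)
        assert abs(v_replay - run.final_bias) < 1e-9

    def test_first_hill_full_height_then_decay(self):
        system = ToySystem(potentials=[double_well(a=5.0)])
        # walls confine the walker to the left basin
        walls = [WallParams(-0.2, 200.0, "upper"),
                 WallParams(-1.6, 200.0, "lower")]
        run = run_wt_metad(system, BiasParams(), walls=walls,
                           n_steps=150_000, seed=2)
        heights = run.hills.arrays()[2]
        assert heights[0] == pytest.approx(0.6, rel=1e-9)
        assert heights[-20:].mean() < heights[:20].mean()

    def test_hills_file_round_trip(self, tmp_path):
        system = ToySystem(potentials=[double_well(a=3.0)])
        run = run_wt_metad(system, BiasParams(), n_steps=20_000, seed=4)
        path = tmp_path / "HILLS"
        run.hills.write(path)
        back = HillsLog.read(path)
        assert len(back) == len(run.hills)
        s = 0.37
        assert back.potential(s) == pytest.approx(run.hills.potential(s),
                                                  rel=1e-6)

    def test_walker_count_validation(self):
        system = ToySystem(potentials=[double_well(a=3.0)])
        with pytest.raises(ValidationError):
            run_wt_metad(system, BiasParams(), n_steps=100, n_walkers=0)


class TestPBMetad:
    def test_one_hill_per_cv_per_deposition(self):
        system = ToySystem(potentials=[double_well(a=2.0), double_well(a=2.0)])
        run = run_pbmetad(system, BiasParams(), n_steps=20_000, n_walkers=2,
                          seed=6)
        n_dep = (20_000 // 500) * 2
        assert [len(h) for h in run.hills] == [n_dep, n_dep]

    def test_symmetric_cvs_statistically_exchangeable(self):
        """Identical independent CVs on the same potential accumulate
        comparable total bias."""
        system = ToySystem(potentials=[double_well(a=2.0), double_well(a=2.0)])
        run = run_pbmetad(system, BiasParams(), n_steps=120_000, n_walkers=2,
                          seed=7)
        totals = [h.arrays()[2].sum() for h in run.hills]
        assert abs(totals[0] - totals[1]) / max(totals) < 0.25

    def test_pb_bias_combination(self, rng):
        logs = [HillsLog("s0"), HillsLog("s1")]
        for log in logs:
            for c in rng.uniform(-1, 1, 20):
                log.append(Hill(log.cv_id, float(c), 0.12, 0.3))
        s = rng.uniform(-1, 1, (15, 2))
        kbt = KB_KCAL_MOL_K * 300.0
        expect = -kbt * np.log(
            np.exp(-np.asarray(logs[0].potential(s[:, 0])) / kbt)
            + np.exp(-np.asarray(logs[1].potential(s[:, 1])) / kbt)
        )
        assert np.allclose(pb_bias_potential(logs, s, 300.0), expect,
                           atol=1e-10)
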