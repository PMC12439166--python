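"""Weighted-ensemble engine: conservation, resampler contracts, lineage,
free-energy profiles."""

import numpy as np
import pytest

import flavokit as fk
from flavokit import we
from flavokit.errors import FlavokitError, IntegrityError
from flavokit.synthetic import make_harmonic_propagator


def uniform_walkers(n, spread=1.0, seed=0):
    rng = np.random.default_rng(seed)
    states = list(rng.uniform(-spread, spread, size=n))
    weights = np.full(n, 1.0 / n)
    return states, weights


class TestDistances:
    def test_identical_states_zero(self):
        assert we.scalar_distance(0.7, 0.7) == 0.0

    def test_rgyr_distance_definition(self):
        dist = fk.make_rgyr_distance()
        assert dist(1.2, 0.9) == pytest.approx(0.3)
        # coordinate states: two-atom configurations with known RGYR d/2
        a = np.array([[0.0, 0, 0], [2.4, 0, 0]])  # rgyr 1.2
        b = np.array([[0.0, 0, 0], [1.8, 0, 0]])  # rgyr 0.9
        assert dist(a, b) == pytest.approx(0.3)

    def test_symmetry(self, rng):
        dist = fk.make_rgyr_distance()
        for _ in range(10):
            a, b = rng.normal(size=(2, 5, 3))
            assert dist(a, b) == pytest.approx(dist(b, a))


class TestResampler:
    def params(self, **kw):
        kw.setdefault("n_walkers", 8)
        return fk.REVOParams(**kw)

    def test_identical_walkers_unchanged(self):
        states = [0.5] * 8
        weights = np.full(8, 1 / 8)
        s2, w2, rec = we.resample_revo(states, weights, self.params(), np.random.default_rng(0))
        assert s2 == states
        np.testing.assert_array_equal(w2, weights)
        assert rec.empty

    def test_two_distant_walkers_cannot_merge(self):
        states = [0.0, 10.0]
        weights = np.array([0.5, 0.5])
        s2, w2, rec = we.resample_revo(
            states, weights, fk.REVOParams(n_walkers=2), np.random.default_rng(0)
        )
        assert s2 == states
        assert rec.empty

    def test_weight_conservation_and_bounds(self, rng):
        params = self.params()
        states, weights = uniform_walkers(8, seed=5)
        s2, w2, rec = we.resample_revo(states, weights, params, rng)
        assert abs(w2.sum() - weights.sum()) <= 1e-12
        assert np.all(w2 >= params.pmin)
        assert np.all(w2 <= params.pmax)
        assert len(s2) == len(states)

    def test_resampling_happens_for_spread_ensembles(self, rng):
        states, weights = uniform_walkers(8, spread=0.05, seed=2)
        _, _, rec = we.resample_revo(states, weights, self.params(), rng)
        assert not rec.empty  # close walkers merge, spread ones clone

    def test_bad_weight_sum_rejected(self):
        with pytest.raises(FlavokitError):
            we.resample_revo(
                [0.0, 1.0], np.array([0.5, 0.6]), fk.REVOParams(n_walkers=2),
                np.random.default_rng(0),
            )

    def test_clone_children_have_half_weight(self, rng):
        states, weights = uniform_walkers(8, spread=0.05, seed=2)
        s2, w2, rec = we.resample_revo(states, weights, self.params(), rng)
        for parent, children in rec.clones.items():
            assert len(children) >= 2


class TestRunWeightedEnsemble:
    def test_zero_cycles_returns_initial_ensemble(self):
        prop = fk.make_double_well_propagator(fk.DoubleWellSpec())
        params = fk.REVOParams(n_walkers=10, n_cycles=0)
        res = fk.run_weighted_ensemble(prop, np.linspace(-1, 1, 10), params, seed=0)
        assert res.values.shape == (1, 10)
        np.testing.assert_allclose(res.values[0], np.linspace(-1, 1, 10))

    def test_weight_conservation_every_cycle(self):
        prop = fk.make_double_well_propagator(fk.DoubleWellSpec(barrier=3.0))
        params = fk.REVOParams(n_walkers=20, n_cycles=100, steps_per_cycle=20)
        res = fk.run_weighted_ensemble(prop, np.ones(20), params, seed=3)
        totals = res.weights.sum(axis=1)
        assert np.abs(totals - 1.0).max() <= 1e-12
        assert res.weights.min() >= params.pmin
        assert res.weights.max() <= params.pmax

    def test_same_seed_identical_results(self):
        prop = fk.make_double_well_propagator(fk.DoubleWellSpec(barrier=2.0))
        params = fk.REVOParams(n_walkers=10, n_cycles=30, steps_per_cycle=10)
        r1 = fk.run_weighted_ensemble(prop, np.ones(10), params, seed=11)
        r2 = fk.run_weighted_ensemble(prop, np.ones(10), params, seed=11)
        np.testing.assert_array_equal(r1.values, r2.values)
        np.testing.assert_array_equal(r1.weights, r2.weights)

    def test_aggregate_vs_per_walker_time(self):
        prop = fk.make_double_well_propagator(fk.DoubleWellSpec())
        params = fk.REVOParams(n_walkers=5, n_cycles=4, steps_per_cycle=2)
        res = fk.run_weighted_ensemble(prop, np.zeros(5), params, seed=0)
        t = res.aggregate_time(per_walker_time=0.01)
        assert t["aggregate"] == pytest.approx(5 * t["per_walker"])

    def test_well_occupancy_matches_brute_force(self):
        """Unbiasedness: WE weighted well occupancy agrees with a much longer
        plain simulation of the same double well (within 3 standard errors)."""
        spec = fk.DoubleWellSpec(barrier=1.5, dt=2e-3, seed=0)
        prop = fk.make_double_well_propagator(spec)
        params = fk.REVOParams(n_walkers=24, n_cycles=250, steps_per_cycle=25)
        res = fk.run_weighted_ensemble(prop, np.full(24, 1.0), params, seed=4)
        burn = params.n_cycles // 5
        vals = res.values[burn:].ravel()
        wts = res.weights[burn:].ravel()
        p_left_we = wts[vals < 0].sum() / wts.sum()

        rng = np.random.default_rng(10)
        x = prop(np.full(200, 1.0), 8000, rng)  # long independent ensembles
        p_left_ref = np.mean(x < 0)
        se = np.sqrt(p_left_ref * (1 - p_left_ref) / 200) + 0.02
        assert abs(p_left_we - p_left_ref) < 3 * se


class TestFreeEnergyProfile:
    def test_flat_distribution_constant_f(self):
        vals = np.linspace(0.05, 0.95, 10)
        prof = fk.free_energy_profile(vals, np.full(10, 0.1), bins=10, bin_range=(0, 1))
        occ = prof.occupied()
        assert occ.all()
        np.testing.assert_allclose(prof.f[occ], prof.f[occ][0], atol=1e-12)

    def test_weight_scale_invariance(self, rng):
        vals = rng.normal(size=200)
        w = rng.uniform(0.1, 1.0, size=200)
        p1 = fk.free_energy_profile(vals, w, bins=20)
        p2 = fk.free_energy_profile(vals, 2.0 * w, bins=20)
        np.testing.assert_allclose(p1.p, p2.p, atol=1e-15)

    def test_normalisation(self, rng):
        vals = rng.normal(size=500)
        w = rng.uniform(0.0, 1.0, size=500)
        prof = fk.free_energy_profile(vals, w, bins=30)
        assert prof.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_samples_rejected(self):
        with pytest.raises(FlavokitError):
            fk.free_energy_profile(np.array([5.0]), np.array([1.0]), bins=5, bin_range=(0, 1))

    def test_harmonic_boltzmann_recovery(self):
        """Equilibrated harmonic-well WE reproduces F(x) = k x^2 / (2 kT)
        within 0.3 kT across the central 80 %-mass region."""
        # one relaxation time (1/Dk = 1000 steps) per cycle decorrelates
        # walkers between resampling events
        prop = make_harmonic_propagator(k=1.0, diffusion=1.0, dt=1e-3)
        params = fk.REVOParams(n_walkers=50, n_cycles=600, steps_per_cycle=1000)
        res = fk.run_weighted_ensemble(prop, np.zeros(50), params, seed=12)
        prof = fk.free_energy_profile(
            res.values, res.weights, bins=30, burn_in_frac=0.2, bin_range=(-2.5, 2.5)
        )
        centers = prof.bin_centers
        occ = prof.occupied() & (np.abs(centers) <= 1.2816)  # central 80 % mass
        f = prof.f[occ] - np.nanmin(prof.f)
        ref = centers[occ] ** 2 / 2.0
        ref = ref - ref.min()
        assert np.max(np.abs(f - ref)) < 0.3


class TestLineage:
    def make_result(self, n_cycles=20):
        prop = fk.make_double_well_propagator(fk.DoubleWellSpec(barrier=2.0))
        params = fk.REVOParams(n_walkers=10, n_cycles=n_cycles, steps_per_cycle=10)
        return fk.run_weighted_ensemble(prop, np.ones(10), params, seed=21)

    def test_zero_cycles_single_point(self):
        prop = fk.make_double_well_propagator(fk.DoubleWellSpec())
        params = fk.REVOParams(n_walkers=4, n_cycles=0)
        res = fk.run_weighted_ensemble(prop, np.zeros(4), params, seed=0)
        lin = fk.trace_lineage(res, 2)
        assert len(lin["values"]) == 1

    def test_every_final_walker_traces_to_an_initial_walker(self):
        res = self.make_result()
        for k in range(10):
            lin = fk.trace_lineage(res, k)
            assert len(lin["values"]) == res.n_cycles + 1
            assert 0 <= lin["slots"][0] < 10

    def test_clone_children_share_ancestry(self):
        res = self.make_result()
        rec = next(r for r in res.records if r.clones)
        parent, children = next(iter(rec.clones.items()))
        assert all(rec.parent_idx[ch] == rec.parent_idx[parent] for ch in children)

    def test_bad_index_rejected(self):
        res = self.make_result(n_cycles=2)
        with pytest.raises(IntegrityError):
            fk.trace_lineage(res, 99)
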