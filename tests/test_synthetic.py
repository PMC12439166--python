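"""Generators: determinism, validity, and the statistical structure they claim."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import flavokit as fk
from flavokit.errors import PlacementError, SpecValidationError
from flavokit.synthetic import (
    double_well_potential,
    expected_fiber_topology,
    make_overdamped_propagator,
)


class TestInhibitionPanel:
    def test_zero_noise_matches_logistic_exactly(self):
        spec = fk.SyntheticPanelSpec(
            true_ic50=pd.DataFrame({"E1": [1e-6]}, index=["A"]), noise_sd=0.0
        )
        table = fk.gen_inhibition_panel(spec)
        logc = np.log10(table["concentration_m"])
        expected = fk.logistic4(logc, 0.0, 100.0, 1.0, np.log10(1e-6))
        np.testing.assert_allclose(table["percent_inhibition"], expected, rtol=1e-12)

    def test_absent_truth_gives_flat_baseline(self):
        spec = fk.SyntheticPanelSpec(
            true_ic50=pd.DataFrame({"E1": [np.nan]}, index=["A"]), noise_sd=0.0
        )
        table = fk.gen_inhibition_panel(spec)
        assert len(table) == 20  # 10 concentrations x 2 replicates
        assert (table["percent_inhibition"] == 0.0).all()

    def test_same_seed_identical_tables(self):
        spec, _ = fk.study_panel_spec(seed=5)
        t1 = fk.gen_inhibition_panel(spec)
        t2 = fk.gen_inhibition_panel(spec)
        pd.testing.assert_frame_equal(t1, t2)

    def test_study_design_shape(self, study_panel):
        table, truth = study_panel
        # 58 compounds x 7 enzymes x 10 concentrations x 2 replicates
        assert len(table) == 58 * 7 * 10 * 2
        assert table["compound_id"].nunique() == 58
        assert table["enzyme_id"].nunique() == 7
        conc = np.sort(table["concentration_m"].unique())
        assert conc.size == 10
        assert conc[0] == pytest.approx(5e-9)
        assert conc[-1] == pytest.approx(1e-4)
        assert truth["true_category"].value_counts().to_dict() == {
            "BASELINE": 251,
            "IN_RANGE": 106,
            "EXTRAPOLATED": 49,
        }

    @pytest.mark.parametrize(
        "field,kwargs",
        [
            ("concentrations", {"concentrations": (1e-6, 1e-7)}),
            ("concentrations", {"concentrations": (0.0, 1e-6)}),
            ("n_replicates", {"n_replicates": 0}),
            ("noise_sd", {"noise_sd": -1.0}),
        ],
    )
    def test_invalid_spec_names_field(self, field, kwargs):
        with pytest.raises(SpecValidationError) as err:
            fk.SyntheticPanelSpec(
                true_ic50=pd.DataFrame({"E1": [1e-6]}, index=["A"]), **kwargs
            )
        assert err.value.field == field


class TestCollapseTrajectory:
    def test_positive_collapse_rate_contracts_rgyr(self):
        for seed in range(20):
            spec = fk.CollapseTrajSpec(seed=seed, n_frames=200)
            series = fk.radius_of_gyration(fk.gen_collapse_trajectory(spec))
            assert series.values[-1] < series.values[0]

    def test_zero_collapse_rate_has_no_trend(self):
        """Mean RGYR slope over 50 seeds is statistically indistinguishable
        from zero when the centripetal drift is off."""
        slopes = []
        for seed in range(50):
            spec = fk.CollapseTrajSpec(
                seed=seed, collapse_rate=0.0, n_frames=100, n_molecules=8,
                atoms_per_molecule=4,
            )
            s = fk.radius_of_gyration(fk.gen_collapse_trajectory(spec))
            slopes.append(stats.linregress(s.times, s.values).slope)
        ci = stats.t.interval(
            0.95, len(slopes) - 1, loc=np.mean(slopes), scale=stats.sem(slopes)
        )
        assert ci[0] < 0 < ci[1]

    def test_single_molecule_internal_rgyr_constant(self):
        spec = fk.CollapseTrajSpec(n_molecules=1, n_frames=50, seed=2)
        series = fk.radius_of_gyration(fk.gen_collapse_trajectory(spec))
        np.testing.assert_allclose(series.values, series.values[0], rtol=1e-9)

    def test_coordinates_bounded_and_finite(self):
        for seed in range(5):
            spec = fk.CollapseTrajSpec(seed=seed, n_frames=150)
            traj = fk.gen_collapse_trajectory(spec)
            assert np.all(np.isfinite(traj.coordinates))
            diag = np.sqrt(3) * spec.box_edge
            assert np.abs(traj.coordinates).max() <= 2 * diag

    def test_determinism(self):
        spec = fk.CollapseTrajSpec(seed=9, n_frames=20)
        t1 = fk.gen_collapse_trajectory(spec)
        t2 = fk.gen_collapse_trajectory(spec)
        np.testing.assert_array_equal(t1.coordinates, t2.coordinates)

    def test_overcrowded_box_raises_placement_error(self):
        with pytest.raises(PlacementError):
            fk.gen_collapse_trajectory(
                fk.CollapseTrajSpec(
                    n_molecules=50, box_edge=0.5, min_separation=0.4, max_retries=200
                )
            )


class TestRingFiber:
    def test_linear_fiber_geometry(self):
        struct = fk.gen_ring_fiber(fk.FiberSpec(n_units=5, rise=3.5))
        assert len(struct.rings) == 5
        cents = np.array([r.centroid(struct.coordinates) for r in struct.rings])
        gaps = np.linalg.norm(np.diff(cents, axis=0), axis=1)
        np.testing.assert_allclose(gaps, 3.5, rtol=1e-12)

    def test_branch_adds_rings_and_degree(self):
        struct = fk.gen_ring_fiber(fk.FiberSpec(n_units=5, branch_points=((3, 2),)))
        assert len(struct.rings) == 7
        thr = fk.StackingThresholds(include_t_shaped=True)
        contacts = fk.detect_stacking_contacts(struct.coordinates, struct.rings, thr)
        graph = fk.build_assembly_graph(contacts, struct.molecule_ids)
        assert graph.degree("U003") == 3

    def test_single_unit_no_contacts(self):
        struct = fk.gen_ring_fiber(fk.FiberSpec(n_units=1))
        assert len(struct.rings) == 1
        contacts = fk.detect_stacking_contacts(
            struct.coordinates, struct.rings, fk.StackingThresholds(include_t_shaped=True)
        )
        assert contacts == []

    def test_glycoside_atoms_tagged(self):
        struct = fk.gen_ring_fiber(fk.FiberSpec(n_units=3, with_glycoside=True))
        counts = struct.atom_tags["group"].value_counts()
        assert counts["flavonoid_core"] == 18
        assert counts["glycoside"] == 12

    def test_end_unit_branch_stays_a_path(self):
        spec = fk.FiberSpec(n_units=4, branch_points=((4, 2),))
        assert expected_fiber_topology(spec)["topology"] == "PRIMARY"
        spec = fk.FiberSpec(n_units=4, branch_points=((2, 1),))
        assert expected_fiber_topology(spec)["topology"] == "SECONDARY"

    def test_branch_index_validated(self):
        with pytest.raises(SpecValidationError):
            fk.FiberSpec(n_units=3, branch_points=((4, 1),))


class TestDoubleWellPropagator:
    def test_free_diffusion_variance(self):
        """barrier=0 reduces to Brownian motion: Var[x] = 2 D n dt."""
        spec = fk.DoubleWellSpec(barrier=0.0, diffusion=0.7, dt=1e-3)
        prop = fk.make_double_well_propagator(spec)
        rng = np.random.default_rng(42)
        x = prop(np.zeros(10_000), 500, rng)
        expected = 2 * spec.diffusion * 500 * spec.dt
        assert np.var(x) == pytest.approx(expected, rel=0.05)

    def test_high_barrier_no_crossings(self):
        """Kramers regime: 20 kT barrier confines short runs to one well."""
        spec = fk.DoubleWellSpec(barrier=20.0, dt=1e-4)
        prop = fk.make_double_well_propagator(spec)
        rng = np.random.default_rng(7)
        x = prop(np.full(100, spec.well_half_separation), 1000, rng)
        assert np.all(x > 0)

    def test_zero_steps_identity(self):
        prop = fk.make_double_well_propagator(fk.DoubleWellSpec())
        rng = np.random.default_rng(0)
        x = np.array([0.3, -1.2])
        np.testing.assert_array_equal(prop(x, 0, rng), x)

    def test_equilibrium_kl_decreases_with_run_length(self):
        """Long brute-force runs converge to the Boltzmann density."""
        spec = fk.DoubleWellSpec(barrier=2.0, dt=2e-3, seed=0)
        prop = fk.make_double_well_propagator(spec)
        edges = np.linspace(-2.0, 2.0, 41)
        centers = 0.5 * (edges[:-1] + edges[1:])
        boltz = np.exp(-double_well_potential(centers, spec) / spec.kT)
        boltz /= boltz.sum()

        def kl(n_steps, seed):
            rng = np.random.default_rng(seed)
            x = prop(np.zeros(400), n_steps, rng)
            h, _ = np.histogram(x, bins=edges)
            p = (h + 1e-9) / (h.sum() + 1e-9 * len(centers))
            return float(np.sum(p * np.log(p / boltz)))

        assert kl(8000, 3) < kl(100, 3)

    def test_deterministic_given_rng_stream(self):
        prop = fk.make_double_well_propagator(fk.DoubleWellSpec())
        x1 = prop(np.ones(5), 100, np.random.default_rng(8))
        x2 = prop(np.ones(5), 100, np.random.default_rng(8))
        np.testing.assert_array_equal(x1, x2)
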