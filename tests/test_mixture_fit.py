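"""Mixture fitting: self-consistency, invariances, bootstrap, model ranking."""

import numpy as np
import pytest

from fibrilkit import (
    FitParameter,
    FitSpec,
    ScatteringCurve,
    SpeciesMixture,
    SphereSpecies,
    WormLikeChainSpecies,
    fit_mixture,
    mixture_intensity,
)
from fibrilkit.mixture_fit import bootstrap_uncertainties, compare_models
from fibrilkit.synthetic_data import simulate_saxs


def chain_mixture(rcs=9.5, scale=1.0, background=1e-4):
    return SpeciesMixture(
        species=[WormLikeChainSpecies(contour_length=300.0, kuhn_length=40.0,
                                      cross_radius=rcs, scale=scale)],
        background=background,
    )


def chain_spec(seed=0, n_starts=2, init_rcs=12.0, init_scale=0.6):
    return FitSpec(
        mixture=chain_mixture(),
        free_parameters=[
            FitParameter("species[0].cross_radius", init_rcs, 2.0, 30.0),
            FitParameter("species[0].scale", init_scale, 0.05, 5.0),
            FitParameter("background", 1e-4, 0.0, 0.01),
        ],
        seed=seed,
        n_starts=n_starts,
    )


@pytest.fixture
def q():
    return np.linspace(0.008, 0.35, 100)


class TestFitMixture:
    def test_noise_free_self_consistency(self, q):
        # data generated from the template's own initial values are recovered
        spec = chain_spec(init_rcs=9.5, init_scale=1.0)
        truth = spec.build(np.array([9.5, 1.0, 1e-4]))
        curve = mixture_intensity(q, truth)
        res = fit_mixture(curve, spec)
        assert res.best_parameters["species[0].cross_radius"] == pytest.approx(9.5, rel=1e-4)
        assert res.best_parameters["species[0].scale"] == pytest.approx(1.0, rel=1e-4)
        assert res.chi2_reduced < 1e-10

    def test_recovers_from_distant_start(self, q):
        curve = simulate_saxs(chain_mixture(), q, noise=0.005, seed=1)
        res = fit_mixture(curve, chain_spec(seed=3, init_rcs=25.0, init_scale=0.1))
        assert res.best_parameters["species[0].cross_radius"] == pytest.approx(9.5, rel=0.05)

    def test_fractions_sum_to_one(self, q):
        mix = SpeciesMixture(
            species=[WormLikeChainSpecies(contour_length=300.0, kuhn_length=40.0,
                                          cross_radius=9.5, scale=0.7),
                     SphereSpecies(radius=20.0, scale=0.3)],
            background=1e-4,
        )
        spec = FitSpec(
            mixture=mix,
            free_parameters=[
                FitParameter("species[0].scale", 0.5, 0.01, 3.0),
                FitParameter("species[1].scale", 0.5, 0.01, 3.0),
            ],
            seed=0, n_starts=2,
        )
        curve = simulate_saxs(mix, q, noise=0.005, seed=2)
        res = fit_mixture(curve, spec)
        assert res.species_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.species_fractions >= 0)

    def test_fractions_invariant_under_global_rescale(self, q):
        curve = simulate_saxs(chain_mixture(), q, noise=0.005, seed=4)
        res1 = fit_mixture(curve, chain_spec())
        c = 37.0
        scaled = ScatteringCurve(curve.q, c * curve.intensity, c * curve.sigma)
        spec2 = chain_spec()
        for p in spec2.free_parameters:
            if p.name == "species[0].scale":
                p.max *= c
            if p.name == "background":
                p.max *= c
        res2 = fit_mixture(scaled, spec2)
        assert res2.species_fractions == pytest.approx(res1.species_fractions, abs=1e-6)

    def test_objective_trace_monotone(self, q):
        curve = simulate_saxs(chain_mixture(), q, noise=0.005, seed=5)
        res = fit_mixture(curve, chain_spec())
        assert all(b < a for a, b in zip(res.trace, res.trace[1:]))

    def test_bound_pinning_is_flagged(self, q):
        curve = mixture_intensity(q, chain_mixture(rcs=9.5))
        spec = FitSpec(
            mixture=chain_mixture(),
            free_parameters=[
                # upper bound below the generating value pins the parameter
                FitParameter("species[0].cross_radius", 6.0, 2.0, 7.0),
                FitParameter("species[0].scale", 0.6, 0.05, 5.0),
            ],
            seed=0, n_starts=1,
        )
        res = fit_mixture(curve, spec)
        assert "species[0].cross_radius" in res.at_bounds

    def test_requires_enough_points(self):
        q = np.linspace(0.01, 0.03, 5)
        curve = ScatteringCurve(q, np.ones_like(q))
        with pytest.raises(ValueError, match="3x"):
            fit_mixture(curve, chain_spec())

    def test_initial_value_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            FitParameter("species[0].scale", 10.0, 0.0, 1.0)

    def test_unknown_parameter_path_rejected(self):
        with pytest.raises(ValueError):
            FitParameter("species[0]->scale", 0.5, 0.0, 1.0)


class TestBootstrap:
    def test_zero_noise_gives_vanishing_spread(self, q):
        spec = chain_spec(init_rcs=9.5, init_scale=1.0)
        curve = mixture_intensity(q, spec.build(np.array([9.5, 1.0, 1e-4])))
        sig = bootstrap_uncertainties(curve, spec, n_boot=20, seed=0)
        assert sig["species[0].cross_radius"] < 1e-6

    def test_deterministic_given_seed(self, q):
        curve = simulate_saxs(chain_mixture(), q, noise=0.01, seed=6)
        spec = chain_spec()
        a = bootstrap_uncertainties(curve, spec, n_boot=20, seed=11)
        b = bootstrap_uncertainties(curve, spec, n_boot=20, seed=11)
        assert a == b

    def test_consistent_with_curvature_uncertainty(self, q):
        curve = simulate_saxs(chain_mixture(), q, noise=0.01, seed=7)
        spec = chain_spec()
        res = fit_mixture(curve, spec)
        boot = bootstrap_uncertainties(curve, spec, n_boot=40, seed=1, fit=res)
        curv = res.uncertainties["species[0].cross_radius"]
        assert boot["species[0].cross_radius"] == pytest.approx(curv, rel=1.0)

    def test_refuses_too_few_resamples(self, q):
        curve = simulate_saxs(chain_mixture(), q, noise=0.01, seed=8)
        with pytest.raises(ValueError, match="20"):
            bootstrap_uncertainties(curve, chain_spec(), n_boot=5)


class TestCompareModels:
    def overparam_spec(self, seed=0):
        mix = SpeciesMixture(
            species=[WormLikeChainSpecies(contour_length=300.0, kuhn_length=40.0,
                                          cross_radius=9.5, scale=0.5),
                     SphereSpecies(radius=30.0, scale=0.5)],
            background=1e-4,
        )
        return FitSpec(
            mixture=mix,
            free_parameters=[
                FitParameter("species[0].cross_radius", 12.0, 2.0, 30.0),
                FitParameter("species[0].scale", 0.5, 0.01, 5.0),
                FitParameter("species[1].radius", 30.0, 5.0, 80.0),
                FitParameter("species[1].scale", 0.2, 0.0, 5.0),
                FitParameter("background", 1e-4, 0.0, 0.01),
            ],
            seed=seed, n_starts=2,
        )

    def test_true_model_beats_overparameterized(self, q):
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            curve = simulate_saxs(chain_mixture(), q, noise=0.01, seed=100 + seed)
            report = compare_models(curve, [chain_spec(seed=seed),
                                            self.overparam_spec(seed=seed)])
            if report[0]["index"] == 0:
                wins += 1
        assert wins >= 0.8 * n_rep

    def test_identical_specs_rank_in_input_order(self, q):
        curve = simulate_saxs(chain_mixture(), q, noise=0.01, seed=9)
        report = compare_models(curve, [chain_spec(seed=1), chain_spec(seed=1)])
        assert [r["index"] for r in report] == [0, 1]
        assert report[0]["score"] == pytest.approx(report[1]["score"])

    def test_wrong_family_ranks_below_right_family(self, q):
        # chain-generated data: a cylinder-only model must rank below
        from fibrilkit import CylinderSpecies

        curve = simulate_saxs(chain_mixture(), q, noise=0.01, seed=10)
        cyl_spec = FitSpec(
            mixture=SpeciesMixture(
                species=[CylinderSpecies(radius=30.0, length=2000.0, scale=0.5)],
                background=1e-4,
            ),
            free_parameters=[
                FitParameter("species[0].radius", 30.0, 5.0, 100.0),
                FitParameter("species[0].scale", 0.5, 0.01, 5.0),
                FitParameter("background", 1e-4, 0.0, 0.01),
            ],
            seed=0, n_starts=2,
        )
        report = compare_models(curve, [cyl_spec, chain_spec()])
        assert report[0]["index"] == 1

    def test_needs_at_least_two_specs(self, q):
        curve = simulate_saxs(chain_mixture(), q, noise=0.01, seed=11)
        with pytest.raises(ValueError):
            compare_models(curve, [chain_spec()])
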