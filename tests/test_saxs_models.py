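"""Forward-model tests: closed forms, brute-force quadrature oracles, limits."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fibrilkit import (
    AtomicStructure,
    CylinderSpecies,
    ScatteringCurve,
    SpeciesMixture,
    SphereSpecies,
    WormLikeChainSpecies,
    cylinder_intensity,
    debye_intensity_from_structure,
    guinier_fit,
    kratky_transform,
    mixture_intensity,
    rodlike_guinier_fit,
    sphere_form_factor,
    wormlike_intensity,
)
from fibrilkit.saxs_models import (
    brute_force_cylinder_oracle,
    debye_coil,
    wormlike_rg_squared,
)


def smallest_tan_root():
    """Bisection oracle: smallest positive root of tan(x) = x (in (π, 3π/2))."""
    f = lambda x: np.tan(x) - x
    lo, hi = np.pi + 1e-6, 1.5 * np.pi - 1e-6
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestSphere:
    def test_normalized_at_zero_angle(self):
        assert sphere_form_factor(np.array([1e-12]), 50.0)[0] == pytest.approx(1.0)

    @given(st.floats(min_value=1.0, max_value=500.0))
    def test_bounded_between_zero_and_one(self, radius):
        q = np.linspace(1e-4, 1.0, 200)
        p = sphere_form_factor(q, radius)
        assert np.all(p >= 0) and np.all(p <= 1.0 + 1e-12)

    def test_guinier_radius_matches_closed_form(self):
        # Rg of a uniform sphere is sqrt(3/5)*R
        q = np.linspace(0.005, 0.2, 200)
        curve = ScatteringCurve(q, sphere_form_factor(q, 20.66))
        res = guinier_fit(curve)
        assert res.size == pytest.approx(np.sqrt(3.0 / 5.0) * 20.66, abs=0.2)

    def test_first_intensity_zero_at_tan_root(self):
        root = smallest_tan_root()  # ~4.4934
        radius = 30.0
        q = np.linspace(3.5, 5.5, 4001) / radius
        p = sphere_form_factor(q, radius)
        assert q[np.argmin(p)] * radius == pytest.approx(root, rel=1e-3)

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            sphere_form_factor(np.array([0.01]), -1.0)


class TestCylinder:
    def test_long_rod_cross_section_radius(self, low_q):
        # rod-like Guinier of a long cylinder gives Rc = R/sqrt(2)
        sp = CylinderSpecies(radius=108.9, length=4000.0)
        curve = ScatteringCurve(low_q, cylinder_intensity(low_q, sp))
        res = rodlike_guinier_fit(curve)
        assert res.size == pytest.approx(108.9 / np.sqrt(2), rel=0.01)

    @pytest.mark.parametrize("dist,pd", [("gaussian", 0.3), ("schulz", 0.25)])
    def test_matches_brute_force_oracle(self, dist, pd):
        sp = CylinderSpecies(radius=40.0, length=2000.0, polydispersity=pd,
                             scale=2.0, distribution=dist)
        q = np.linspace(0.005, 0.3, 50)
        ours = cylinder_intensity(q, sp)
        oracle = brute_force_cylinder_oracle(q, sp)
        assert np.max(np.abs(ours / oracle - 1.0)) < 1e-3

    def test_monodisperse_limit(self, wide_q):
        mono = CylinderSpecies(radius=40.0, length=2000.0, polydispersity=0.0)
        tiny = CylinderSpecies(radius=40.0, length=2000.0, polydispersity=1e-4)
        a = cylinder_intensity(wide_q, mono)
        b = cylinder_intensity(wide_q, tiny)
        assert np.max(np.abs(b / a - 1.0)) < 1e-3

    def test_zero_scale_gives_zero(self, wide_q):
        sp = CylinderSpecies(radius=40.0, length=2000.0, scale=0.0)
        assert np.all(cylinder_intensity(wide_q, sp) == 0.0)

    def test_forward_intensity_equals_scale(self):
        sp = CylinderSpecies(radius=40.0, length=2000.0, polydispersity=0.3,
                             scale=3.7)
        assert cylinder_intensity(np.array([1e-7]), sp)[0] == pytest.approx(3.7, rel=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CylinderSpecies(radius=-1.0, length=100.0)
        with pytest.raises(ValueError):
            CylinderSpecies(radius=10.0, length=100.0, polydispersity=0.9)


class TestWormLikeChain:
    def test_flexible_limit_matches_debye_function(self):
        # L >> b and Q*b << 1: chain scatters like a Gaussian coil with
        # Rg^2 = L*b/6
        sp = WormLikeChainSpecies(contour_length=5000.0, kuhn_length=50.0)
        rg = np.sqrt(5000.0 * 50.0 / 6.0)
        q = np.linspace(1e-4, 1.0 / rg, 40)  # Q*b <= 0.25
        ours = wormlike_intensity(q, sp)
        assert np.max(np.abs(ours / debye_coil(q, rg) - 1.0)) < 0.05

    def test_rod_regime_log_slope(self):
        sp = WormLikeChainSpecies(contour_length=5000.0, kuhn_length=50.0)
        q = np.linspace(0.5, 1.0, 30)
        slope = np.gradient(np.log(wormlike_intensity(q, sp)), np.log(q))
        assert np.mean(slope) == pytest.approx(-1.0, abs=0.05)

    def test_forward_limit_is_scale(self):
        sp = WormLikeChainSpecies(contour_length=300.0, kuhn_length=40.0,
                                  cross_radius=9.5, scale=2.5)
        assert wormlike_intensity(np.array([1e-7]), sp)[0] == pytest.approx(2.5, rel=1e-5)

    def test_benoit_doty_limits_and_bounds(self):
        # n -> inf: Rg^2 -> L*b/6; at finite stiffness the chain is always
        # more compact than a rigid rod (L^2/12) and than the pure coil
        assert wormlike_rg_squared(1e6, 1.0) == pytest.approx(1e6 / 6.0, rel=1e-3)
        for L, b in [(50.0, 50.0), (200.0, 50.0), (5000.0, 50.0)]:
            rg2 = wormlike_rg_squared(L, b)
            assert rg2 < L**2 / 12.0
            assert rg2 < L * b / 6.0
        # Rg grows with contour length at fixed stiffness
        rgs = [wormlike_rg_squared(L, 40.0) for L in (40.0, 100.0, 400.0, 1000.0)]
        assert np.all(np.diff(rgs) > 0)

    def test_contour_shorter_than_kuhn_rejected(self):
        with pytest.raises(ValueError):
            WormLikeChainSpecies(contour_length=10.0, kuhn_length=50.0)

    def test_cross_radius_of_gyration_convention(self):
        sp = WormLikeChainSpecies(contour_length=300.0, kuhn_length=40.0,
                                  cross_radius=9.5)
        assert sp.cross_radius_of_gyration == pytest.approx(9.5 / np.sqrt(2))


class TestAtomicDebye:
    def test_single_atom_is_flat(self):
        st_ = AtomicStructure(atoms=[("C", 0.0, 0.0, 0.0, 1.0)])
        q = np.linspace(0.01, 0.5, 20)
        assert np.allclose(debye_intensity_from_structure(q, st_), 1.0)

    def test_two_atom_closed_form(self):
        # P(Q) = (1 + sinc(Q d)) / 2 for two identical point scatterers
        d = 10.0
        st_ = AtomicStructure(atoms=[("C", 0, 0, 0, 1.0), ("C", d, 0, 0, 1.0)],
                              shell_contrast=0.0)
        q = np.linspace(0.01, 0.5, 40)
        expected = 0.5 * (1.0 + np.sinc(q * d / np.pi))
        assert np.max(np.abs(debye_intensity_from_structure(q, st_) - expected)) < 1e-12

    def test_unknown_element_is_named_in_error(self):
        with pytest.raises(ValueError, match="XX"):
            AtomicStructure(atoms=[("Xx", 0.0, 0.0, 0.0, 1.0)])

    def test_shell_increases_apparent_size(self):
        from fibrilkit.synthetic_data import synthetic_globular_structure

        st_ = synthetic_globular_structure(n_atoms=400, seed=3)
        bare = AtomicStructure(atoms=st_.atoms, shell_contrast=0.0)
        q = np.linspace(0.01, 0.2, 80)
        rg_shell = guinier_fit(ScatteringCurve(q, debye_intensity_from_structure(q, st_))).size
        rg_bare = guinier_fit(ScatteringCurve(q, debye_intensity_from_structure(q, bare))).size
        assert rg_shell > rg_bare


class TestMixture:
    def test_single_species_identity(self, wide_q):
        sp = CylinderSpecies(radius=40.0, length=2000.0, scale=1.3)
        mix = SpeciesMixture(species=[sp], background=0.0)
        direct = cylinder_intensity(wide_q, sp)
        assert np.allclose(mixture_intensity(wide_q, mix).intensity, direct)

    def test_linearity_in_scales(self, wide_q):
        mix = SpeciesMixture(
            species=[CylinderSpecies(radius=40.0, length=2000.0, scale=1.0),
                     SphereSpecies(radius=20.0, scale=0.5)],
            background=0.01,
        )
        doubled = SpeciesMixture(
            species=[CylinderSpecies(radius=40.0, length=2000.0, scale=2.0),
                     SphereSpecies(radius=20.0, scale=1.0)],
            background=0.01,
        )
        a = mixture_intensity(wide_q, mix).intensity
        b = mixture_intensity(wide_q, doubled).intensity
        assert np.allclose(b - 0.01, 2.0 * (a - 0.01))

    def test_two_cylinder_additivity(self, low_q):
        c1 = CylinderSpecies(radius=108.9, length=4000.0, scale=1.0)
        c2 = CylinderSpecies(radius=42.4, length=4000.0, scale=0.7)
        mix = mixture_intensity(low_q, SpeciesMixture(species=[c1, c2]))
        summed = cylinder_intensity(low_q, c1) + cylinder_intensity(low_q, c2)
        assert np.allclose(mix.intensity, summed)

    def test_empty_mixture_rejected(self):
        with pytest.raises(ValueError):
            SpeciesMixture(species=[])

    def test_intensities_nonnegative(self, wide_q):
        mix = SpeciesMixture(
            species=[CylinderSpecies(radius=40.0, length=2000.0,
                                     polydispersity=0.3, scale=0.9),
                     WormLikeChainSpecies(contour_length=300.0, kuhn_length=40.0,
                                          cross_radius=9.5, scale=0.1)],
            background=1e-4,
        )
        assert np.all(mixture_intensity(wide_q, mix).intensity >= 0)


class TestKratky:
    def test_flat_intensity_gives_q_squared(self, wide_q):
        curve = ScatteringCurve(wide_q, np.ones_like(wide_q))
        q, y = kratky_transform(curve)
        assert np.allclose(y, wide_q**2)

    def test_debye_coil_plateau_value(self):
        # Q^2 * I -> 2*scale/Rg^2 at high Q for a Gaussian coil
        rg, scale = 30.0, 1.7
        q = np.linspace(0.01, 8.0 / rg, 300)
        curve = ScatteringCurve(q, scale * debye_coil(q, rg))
        _, y = kratky_transform(curve)
        assert y[-1] == pytest.approx(2.0 * scale / rg**2, rel=0.05)

    def test_globular_curve_is_bell_shaped(self):
        q = np.linspace(0.01, 0.5, 200)
        curve = ScatteringCurve(q, sphere_form_factor(q, 20.0) + 1e-9)
        _, y = kratky_transform(curve)
        peak = np.argmax(y)
        assert 0 < peak < len(q) - 1
        assert y[-1] < 0.5 * y[peak]


class TestScatteringCurve:
    def test_rejects_nonincreasing_grid(self):
        with pytest.raises(ValueError):
            ScatteringCurve(np.array([0.01, 0.01, 0.02]), np.ones(3))

    def test_rejects_nonpositive_q(self):
        with pytest.raises(ValueError):
            ScatteringCurve(np.array([0.0, 0.01]), np.ones(2))

    def test_rejects_mismatched_sigma(self):
        with pytest.raises(ValueError):
            ScatteringCurve(np.array([0.01, 0.02]), np.ones(2), np.ones(3))
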