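"""Seeded synthetic-data generators emulating the beamline and spectrometers.

No experimental curves from the study conditions are publicly deposited, so
every analysis stage in this package is exercised on synthetic data with the
statistical structure the methods assume:

* SAXS curves of species mixtures with counting-statistics noise,
* Congo-Red spectra as two overlapping absorption bands (free dye ≈505 nm,
  bound dye ≈540 nm) whose bound fraction follows a sigmoidal fibrillation
  time course drawn from a shipped scenario table,
* CD spectra as linear combinations of canonical α+β (native), β-sheet and
  random-coil basis bands,
* a deterministic fixture bundle reproducing the end-state mixtures of the
  lysozyme and insulin fibrillation experiments (generating parameters in a
  JSON manifest).

Every generator is a pure function of (configuration, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .cr_spectra import AbsorbanceSpectrum
from .cd_spectra import CDSpectrum
from .saxs_models import (
    AtomicStructure,
    CylinderSpecies,
    ScatteringCurve,
    SpeciesMixture,
    WormLikeChainSpecies,
    mixture_intensity,
)

__all__ = [
    "ScenarioConfig",
    "load_scenario_table",
    "simulate_saxs",
    "fibrillation_timecourse",
    "simulate_cr_spectrum",
    "simulate_cd_spectrum",
    "synthetic_globular_structure",
    "end_state_mixtures",
    "recovery_problem",
    "simulate_kinetic_trace",
    "study_fixtures",
]

# Congo-Red band model: Gaussian bands of equal 50 nm FWHM.  Equal widths
# keep the two-band overlap broad (the composite signal seen during
# fibrillation) while making the area ratio of the decomposed bands track
# their peak-intensity ratio, the empirical equivalence that licenses the
# simple intensity-ratio kinetics statistic.
_CR_FREE_CENTER = 505.0
_CR_BOUND_CENTER = 540.0
_CR_FREE_SIGMA = 50.0 / 2.3548
_CR_BOUND_SIGMA = 50.0 / 2.3548

# CD basis bands (center nm, amplitude mdeg, sigma nm): canonical α+β
# native doublet (208/222 minima), single-β (215 minimum), disordered coil.
_CD_BASIS = {
    "native": [(193.0, 14.0, 5.5), (208.0, -9.0, 4.5), (222.0, -8.5, 5.0)],
    "beta": [(198.0, 7.0, 5.0), (215.0, -10.0, 8.0)],
    "coil": [(198.0, -11.0, 6.0), (222.0, 1.0, 9.0)],
}


@dataclass
class ScenarioConfig:
    """One fibrillation experiment condition.

    Combinations are restricted to those actually studied: lysozyme with
    trehalose {0, 150, 300} mM × NaCl {0, 25, 50} mM; insulin with trehalose
    {0, 300} mM × NaCl {0, 100} mM.
    """

    protein: str
    trehalose_mM: int = 0
    nacl_mM: int = 0
    time_grid: np.ndarray | None = None
    seed: int = 0
    noise: float = 0.01

    def __post_init__(self) -> None:
        if self.time_grid is None:
            self.time_grid = np.arange(0.0, 250.0, 10.0)
        else:
            self.time_grid = np.asarray(self.time_grid, dtype=float)


def load_scenario_table() -> dict:
    """The shipped scenario table (logistic lag/rate/plateau per condition)."""
    with resources.files("fibrilkit.data").joinpath("scenarios.yaml").open() as fh:
        return yaml.safe_load(fh)


def _scenario_entry(config: ScenarioConfig) -> dict:
    table = load_scenario_table()
    try:
        return table[config.protein][f"trehalose_{config.trehalose_mM}"][
            f"nacl_{config.nacl_mM}"
        ]
    except KeyError:
        valid = [
            f"{prot}/trehalose_{t.split('_')[1]}/{n}"
            for prot, tt in table.items()
            for t, nn in tt.items()
            for n in nn
        ]
        raise ValueError(
            f"unknown scenario {config.protein}/trehalose_{config.trehalose_mM}/"
            f"nacl_{config.nacl_mM}; valid combinations: " + ", ".join(valid)
        ) from None


def fibrillation_timecourse(config: ScenarioConfig) -> np.ndarray:
    """Bound-CR fraction f(t) ∈ [0, 1] for a scenario, noise-free.

    Logistic trajectory with lag, rate and plateau looked up from the
    scenario table; t_half follows the tangent-intercept convention,
    t_half = lag + 2/rate.
    """
    entry = _scenario_entry(config)
    lag, rate, plateau = entry["lag_min"], entry["rate_per_min"], entry["plateau"]
    t = config.time_grid
    t_half = lag + 2.0 / rate
    f = plateau / (1.0 + np.exp(-rate * (t - t_half)))
    return np.clip(f, 0.0, 1.0)


def simulate_saxs(
    mixture: SpeciesMixture,
    q_grid: np.ndarray,
    noise: float = 0.01,
    seed: int = 0,
    label: str = "",
) -> ScatteringCurve:
    """Model intensity plus counting-statistics-shaped Gaussian noise.

    The per-point standard deviation is σ(Q) = noise·√(I(Q)·ΔQ), the shape
    photon-counting statistics imprint on an azimuthally averaged detector
    image (more pixels per Q-bin at larger Q).  ``noise = 0`` returns the
    exact model curve with no σ column.  Deterministic for a given seed.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    model = mixture_intensity(q_grid, mixture).intensity
    if noise == 0.0:
        return ScatteringCurve(q=q_grid, intensity=model, sigma=None, label=label)
    dq = np.gradient(q_grid)
    sigma = noise * np.sqrt(np.clip(model, 0.0, None) * dq)
    sigma = np.clip(sigma, 1e-12, None)
    rng = np.random.default_rng(seed)
    noisy = model + rng.normal(0.0, sigma)
    return ScatteringCurve(q=q_grid, intensity=noisy, sigma=sigma, label=label)


def simulate_cr_spectrum(
    bound_fraction: float,
    wavelength: np.ndarray | None = None,
    seed: int = 0,
    noise: float = 0.0,
    amplitude: float = 1.0,
) -> AbsorbanceSpectrum:
    """Two-band Congo-Red spectrum for a given bound-dye fraction.

    A(λ) = amplitude·[(1 − f)·G505(λ) + f·G540(λ)] + seeded Gaussian noise,
    with Gaussian bands for the free and fibril-bound dye.  The 538/505
    ratio of the noise-free spectrum is a strictly increasing function of f,
    which is what licenses the ratio as a β-structure proxy.
    """
    if not 0.0 <= bound_fraction <= 1.0:
        raise ValueError("bound_fraction must lie in [0, 1]")
    if wavelength is None:
        wavelength = np.arange(400.0, 700.0 + 1e-9, 1.0)
    wavelength = np.asarray(wavelength, dtype=float)
    free = np.exp(-0.5 * ((wavelength - _CR_FREE_CENTER) / _CR_FREE_SIGMA) ** 2)
    bound = np.exp(-0.5 * ((wavelength - _CR_BOUND_CENTER) / _CR_BOUND_SIGMA) ** 2)
    ab = amplitude * ((1.0 - bound_fraction) * free + bound_fraction * bound)
    if noise > 0:
        rng = np.random.default_rng(seed)
        ab = ab + rng.normal(0.0, noise, size=ab.shape)
    return AbsorbanceSpectrum(wavelength=wavelength, absorbance=ab)


def simulate_cd_spectrum(
    fractions: dict[str, float],
    wavelength: np.ndarray | None = None,
    seed: int = 0,
    noise: float = 0.0,
) -> CDSpectrum:
    """CD spectrum as a linear combination of secondary-structure bases.

    ``fractions`` maps any of {"native", "beta", "coil"} to non-negative
    weights summing to at most 1; missing keys count as 0.  Gaussian basis
    bands reproduce the canonical signatures: native α+β doublet with minima
    at 208 and 222 nm, cross-β single minimum at 215 nm, disordered coil
    minimum near 198 nm.
    """
    unknown = set(fractions) - set(_CD_BASIS)
    if unknown:
        raise ValueError(f"unknown basis state(s): {sorted(unknown)}")
    vals = {k: float(fractions.get(k, 0.0)) for k in _CD_BASIS}
    if any(v < 0 for v in vals.values()):
        raise ValueError("fractions must be >= 0")
    if sum(vals.values()) > 1.0 + 1e-9:
        raise ValueError("fractions must sum to at most 1")
    if wavelength is None:
        wavelength = np.arange(190.0, 260.0 + 1e-9, 0.5)
    wavelength = np.asarray(wavelength, dtype=float)
    sig = np.zeros_like(wavelength)
    for state, weight in vals.items():
        if weight == 0:
            continue
        for center, amp, width in _CD_BASIS[state]:
            sig = sig + weight * amp * np.exp(
                -0.5 * ((wavelength - center) / width) ** 2
            )
    if noise > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, noise, size=sig.shape)
    return CDSpectrum(wavelength=wavelength, signal=sig)


def simulate_kinetic_trace(config: ScenarioConfig):
    """Seeded β-ratio kinetic trace for a scenario, in raw 538/505 units.

    The bound fraction trajectory is mapped to ratio units with a linear
    dye-response calibration anchored at the generator's own endpoints,
    ratio(t) = r₀ + (r₁ − r₀)·f(t) with r₀/r₁ the 538/505 ratios of the
    fully-free and fully-bound two-band spectra.  A linear response keeps
    the logistic shape (and hence lag, rate and relative plateau) of the
    underlying fibrillation kinetics intact; the mild nonlinearity of the
    real dye response within the transition is deliberately not emulated.
    Gaussian noise of scale ``config.noise`` is added and recorded in the
    s.e.m. column.
    """
    from .cr_spectra import KineticTrace, beta_ratio

    f = fibrillation_timecourse(config)
    r0 = beta_ratio(simulate_cr_spectrum(0.0)).ratio
    r1 = beta_ratio(simulate_cr_spectrum(1.0)).ratio
    ratio = r0 + (r1 - r0) * f
    if config.noise > 0:
        rng = np.random.default_rng(config.seed)
        ratio = np.clip(
            ratio + rng.normal(0.0, config.noise, size=ratio.shape), 0.0, None
        )
        sem = np.full(ratio.shape, config.noise)
    else:
        sem = None
    return KineticTrace(config.time_grid, ratio, sem)


def synthetic_globular_structure(
    n_atoms: int = 1000,
    semi_axes: tuple[float, float, float] = (24.0, 14.0, 14.0),
    seed: int = 7,
) -> AtomicStructure:
    """Synthetic globular protein stand-in (NOT a real structure).

    Heavy atoms drawn uniformly inside an ellipsoid with protein-like
    composition (C/N/O/S in roughly their proteome proportions) and a heavy
    -atom density near 0.06 Å⁻³.  The default dimensions give a compact
    particle the size of a lysozyme monomer (bare-coordinate Rg ≈ 14 Å,
    ≈ 15–16 Å once the hydration shell contributes).  Used where an atomic
    model is needed but no experimental structure is available offline.
    """
    rng = np.random.default_rng(seed)
    a, b, c = semi_axes
    pts = []
    while len(pts) < n_atoms:
        cand = rng.uniform(-1.0, 1.0, size=(4 * n_atoms, 3))
        keep = np.sum(cand**2, axis=1) <= 1.0
        pts.extend(cand[keep])
    xyz = np.array(pts[:n_atoms]) * np.array([a, b, c])
    elements = rng.choice(
        ["C", "N", "O", "S"], size=n_atoms, p=[0.61, 0.19, 0.19, 0.01]
    )
    atoms = [
        (el, float(x), float(y), float(z), 1.0)
        for el, (x, y, z) in zip(elements, xyz)
    ]
    return AtomicStructure(atoms=atoms)


def end_state_mixtures() -> dict[str, SpeciesMixture]:
    """The fibrillation end-state SAXS scenarios as species mixtures.

    Dimensions follow the study conditions; quantities the experiments left
    unconstrained (cylinder lengths, chain contour/Kuhn lengths, population
    scales) are fixed at documented defaults — fibril lengths far exceed the
    probed scale, so only cross-sectional parameters are meaningful.
    Population shares are forward-intensity fractions.
    """
    return {
        # final state without trehalose: polydisperse fibril cylinders + a
        # disordered (unfolded) species
        "lysozyme_final": SpeciesMixture(
            species=[
                CylinderSpecies(radius=40.0, length=2000.0, polydispersity=0.30,
                                scale=0.85),
                WormLikeChainSpecies(contour_length=300.0, kuhn_length=40.0,
                                     cross_radius=8.0, aggregation_number=1,
                                     scale=0.15),
            ],
            background=1e-4,
        ),
        # trehalose blocks fibrillation: only disordered worm-like chains,
        # a lightly aggregated and a more aggregated family
        "lysozyme_trehalose_final": SpeciesMixture(
            species=[
                WormLikeChainSpecies(contour_length=150.0, kuhn_length=40.0,
                                     cross_radius=9.5, aggregation_number=3,
                                     scale=0.5),
                WormLikeChainSpecies(contour_length=400.0, kuhn_length=50.0,
                                     cross_radius=15.8, aggregation_number=10,
                                     scale=0.5),
            ],
            background=1e-4,
        ),
        # the two rod families seen in the rod-like Guinier decomposition:
        # mature fibrils (Rc 77 Å) and protofibrils (Rc 30 Å), equal scales
        "lysozyme_two_rod_families": SpeciesMixture(
            species=[
                CylinderSpecies(radius=108.9, length=4000.0, scale=1.0),
                CylinderSpecies(radius=42.4, length=4000.0, scale=1.0),
            ],
            background=0.0,
        ),
        # insulin end state: dominant highly polydisperse fibril cylinders
        # plus a minor disordered-chain population (cross radius ~20 Å)
        "insulin_final": SpeciesMixture(
            species=[
                CylinderSpecies(radius=38.0, length=2000.0, polydispersity=0.30,
                                scale=0.90),
                WormLikeChainSpecies(contour_length=400.0, kuhn_length=60.0,
                                     cross_radius=20.0, aggregation_number=2,
                                     scale=0.10),
            ],
            background=1e-4,
        ),
        # insulin with trehalose: disordered chains dominate (~85%), wider
        # but sparse cylinders (~60 Å radius)
        "insulin_trehalose_final": SpeciesMixture(
            species=[
                WormLikeChainSpecies(contour_length=400.0, kuhn_length=60.0,
                                     cross_radius=20.0, aggregation_number=2,
                                     scale=0.85),
                CylinderSpecies(radius=60.0, length=2000.0, polydispersity=0.30,
                                scale=0.15),
            ],
            background=1e-4,
        ),
        # native monomer control (globular; Guinier Rg ≈ 16 Å regime)
        "lysozyme_native": SpeciesMixture(
            species=[synthetic_globular_structure()],
            background=0.0,
        ),
    }


def recovery_problem(scenario: str, seed: int = 0, noise: float = 0.01):
    """A seeded parameter-recovery problem for one end-state scenario.

    Returns (true_mixture, fit_spec, q_grid): the generating mixture, a
    :class:`~fibrilkit.mixture_fit.FitSpec` whose template matches the
    scenario's species types with the geometry the experiments left
    unconstrained held fixed and the physically meaningful parameters free
    (initialized away from the generating values), and the Q grid to
    simulate on.  Used by the recovery tests and the acceptance analysis.
    """
    from .mixture_fit import FitParameter, FitSpec

    mixtures = end_state_mixtures()
    if scenario not in ("lysozyme_final", "insulin_final",
                        "lysozyme_trehalose_final"):
        raise ValueError(f"no recovery problem defined for {scenario!r}")
    true = mixtures[scenario]
    template = end_state_mixtures()[scenario]  # independent copy
    q = np.linspace(0.008, 0.35, 120)
    if scenario in ("lysozyme_final", "insulin_final"):
        free = [
            FitParameter("species[0].radius", 30.0, 15.0, 80.0),
            FitParameter("species[0].polydispersity", 0.2, 0.05, 0.55),
            FitParameter("species[0].scale", 0.5, 0.05, 3.0),
            FitParameter("species[1].scale", 0.3, 0.005, 2.0),
            FitParameter("background", 1e-4, 0.0, 0.01),
        ]
    else:
        free = [
            FitParameter("species[0].cross_radius", 12.0, 3.0, 30.0),
            FitParameter("species[0].scale", 0.4, 0.01, 2.0),
            FitParameter("species[1].cross_radius", 12.0, 3.0, 30.0),
            FitParameter("species[1].scale", 0.4, 0.01, 2.0),
            FitParameter("background", 1e-4, 0.0, 0.01),
        ]
    spec = FitSpec(mixture=template, free_parameters=free, seed=seed,
                   n_starts=2)
    return true, spec, q


_DEFAULT_Q = {
    "lysozyme_final": (0.008, 0.45, 150),
    "lysozyme_trehalose_final": (0.008, 0.45, 150),
    "lysozyme_two_rod_families": (0.002, 0.06, 150),
    "insulin_final": (0.008, 0.45, 150),
    "insulin_trehalose_final": (0.008, 0.45, 150),
    "lysozyme_native": (0.01, 0.40, 120),
}


def _mixture_manifest(mix: SpeciesMixture) -> list[dict]:
    out = []
    for sp in mix.species:
        if isinstance(sp, AtomicStructure):
            out.append({"type": "atomic", "n_atoms": len(sp.atoms),
                        "shell_contrast": sp.shell_contrast,
                        "shell_thickness": sp.shell_thickness})
        else:
            d = asdict(sp)
            d["type"] = type(sp).__name__
            out.append(d)
    return out


def study_fixtures(outdir, seed: int = 0, noise: float = 0.01) -> dict:
    """Write the deterministic fixture bundle and return its manifest.

    Produces the six SAXS end-state scenarios (``end_state_mixtures``) as
    3-column .dat files and every kinetic scenario of the study grid as a
    β-ratio trace CSV, together with ``manifest.json`` recording the
    generating parameters of each file.  Bit-identical for a given seed.
    """
    from .io import write_saxs_dat  # local import avoids a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "noise": noise, "saxs": {}, "kinetics": {}}

    rng = np.random.default_rng(seed)
    for name, mix in end_state_mixtures().items():
        lo, hi, n = _DEFAULT_Q[name]
        q = np.linspace(lo, hi, n)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        curve = simulate_saxs(mix, q, noise=noise, seed=sub_seed, label=name)
        path = outdir / f"saxs_{name}.dat"
        write_saxs_dat(curve, path)
        manifest["saxs"][name] = {
            "file": path.name,
            "seed": sub_seed,
            "q_range": [lo, hi],
            "n_points": n,
            "noise": noise,
            "background": mix.background,
            "species": _mixture_manifest(mix),
        }

    table = load_scenario_table()
    for protein, tt in table.items():
        for tkey, nn in tt.items():
            for nkey, entry in nn.items():
                treh = int(tkey.split("_")[1])
                nacl = int(nkey.split("_")[1])
                sub_seed = int(rng.integers(0, 2**31 - 1))
                cfg = ScenarioConfig(protein=protein, trehalose_mM=treh,
                                     nacl_mM=nacl, seed=sub_seed, noise=noise)
                trace = simulate_kinetic_trace(cfg)
                name = f"{protein}_treh{treh}_nacl{nacl}"
                path = outdir / f"kinetics_{name}.csv"
                trace.to_csv(path)
                manifest["kinetics"][name] = {
                    "file": path.name, "seed": sub_seed, **entry,
                }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
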