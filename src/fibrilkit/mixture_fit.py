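"""Full-curve nonlinear least-squares fitting of species mixtures to SAXS data.

A :class:`FitSpec` names the free parameters of a :class:`SpeciesMixture`
template by path — ``"species[0].radius"``, ``"species[1].scale"``,
``"background"`` — each with bounds and an initial value.  Fitting minimizes
the σ-weighted sum of squared residuals with a bounded trust-region
least-squares solver, restarted from a seeded Latin-hypercube sample of the
bound box (multi-start), and reports curvature-based 1-σ uncertainties, the
reduced χ², and per-species fractions of the total forward intensity
(population shares are reported as I(0) fractions throughout the package).
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .saxs_models import (
    ScatteringCurve,
    SpeciesMixture,
    mixture_intensity,
    species_intensity,
)

__all__ = [
    "FitParameter",
    "FitSpec",
    "FitResult",
    "FitError",
    "fit_mixture",
    "bootstrap_uncertainties",
    "compare_models",
]

_PATH_RE = re.compile(r"^(?:species\[(\d+)\]\.(\w+)|background)$")


class FitError(RuntimeError):
    """All optimizer starts failed; carries per-start diagnostics."""

    def __init__(self, msg: str, diagnostics: list | None = None):
        super().__init__(msg)
        self.diagnostics = diagnostics or []


@dataclass
class FitParameter:
    name: str
    value: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.min, self.max, self.value]).all():
            raise ValueError(f"parameter {self.name}: bounds and value must be finite")
        if not self.min <= self.value <= self.max:
            raise ValueError(
                f"parameter {self.name}: initial value {self.value} outside "
                f"bounds [{self.min}, {self.max}]"
            )
        if not _PATH_RE.match(self.name):
            raise ValueError(
                f"parameter path {self.name!r} not understood "
                "(use 'species[i].attr' or 'background')"
            )


@dataclass
class FitSpec:
    """Mixture template plus the parameters to float, with bounds and seed."""

    mixture: SpeciesMixture
    free_parameters: list[FitParameter]
    fixed_parameters: dict = field(default_factory=dict)
    seed: int = 0
    n_starts: int = 8

    def build(self, values: np.ndarray) -> SpeciesMixture:
        """Return a mixture with free (and fixed) parameter values applied."""
        mix = copy.deepcopy(self.mixture)
        for name, val in self.fixed_parameters.items():
            _assign(mix, name, float(val))
        for p, v in zip(self.free_parameters, values):
            _assign(mix, p.name, float(v))
        return mix


def _assign(mix: SpeciesMixture, path: str, value: float) -> None:
    m = _PATH_RE.match(path)
    if m is None:
        raise ValueError(f"parameter path {path!r} not understood")
    if m.group(1) is None:
        mix.background = value
    else:
        idx, attr = int(m.group(1)), m.group(2)
        sp = mix.species[idx]
        if not hasattr(sp, attr):
            raise AttributeError(f"species[{idx}] ({type(sp).__name__}) has no field {attr!r}")
        setattr(sp, attr, value)
        sp.__post_init__()  # re-validate invariants


@dataclass
class FitResult:
    best_parameters: dict[str, float]
    uncertainties: dict[str, float]
    chi2_reduced: float
    species_fractions: np.ndarray
    convergence: dict
    mixture: SpeciesMixture
    at_bounds: list[str] = field(default_factory=list)
    trace: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "best_parameters": self.best_parameters,
            "uncertainties": self.uncertainties,
            "chi2_reduced": self.chi2_reduced,
            "species_fractions": list(map(float, self.species_fractions)),
            "convergence": self.convergence,
            "at_bounds": self.at_bounds,
        }


def _forward_fractions(mixture: SpeciesMixture) -> np.ndarray:
    """Share of total forward intensity I(0) per species (background excluded)."""
    tiny_q = np.array([1e-6])
    fw = np.array([float(species_intensity(tiny_q, sp)[0]) for sp in mixture.species])
    total = fw.sum()
    if total <= 0:
        return np.full(len(fw), np.nan)
    return fw / total


def fit_mixture(curve: ScatteringCurve, spec: FitSpec) -> FitResult:
    """Fit the mixture template to a scattering curve.

    Multi-start bounded least squares: the first start is the spec's initial
    values, the remaining ``n_starts − 1`` are drawn from a seeded
    Latin-hypercube sample of the bound box.  Residuals are
    (I_obs − I_model)/σ (σ = 1 when the curve carries no uncertainties).
    1-σ uncertainties come from the inverse curvature (JᵀJ)⁻¹ at the optimum
    scaled by the residual variance.  Parameters pinned at a bound are
    flagged in ``at_bounds``.
    """
    k = len(spec.free_parameters)
    if k == 0:
        raise ValueError("spec has no free parameters")
    if len(curve) < 3 * k:
        raise ValueError(
            f"need at least 3x more data points ({len(curve)}) than free "
            f"parameters ({k})"
        )
    sigma = curve.sigma if curve.sigma is not None else np.ones_like(curve.q)
    lo = np.array([p.min for p in spec.free_parameters])
    hi = np.array([p.max for p in spec.free_parameters])
    x0 = np.array([p.value for p in spec.free_parameters])

    trace: list[float] = []

    def residuals(x: np.ndarray) -> np.ndarray:
        mix = spec.build(x)
        model = mixture_intensity(curve.q, mix, fast=True).intensity
        r = (curve.intensity - model) / sigma
        cost = float(np.sum(r**2))
        if not trace or cost < trace[-1]:
            trace.append(cost)  # accepted (improving) evaluations only
        return r

    starts = [x0]
    if spec.n_starts > 1:
        sampler = qmc.LatinHypercube(d=k, seed=spec.seed)
        pts = sampler.random(spec.n_starts - 1)
        starts.extend(qmc.scale(pts, lo, hi))

    best = None
    diagnostics = []
    for s_idx, start in enumerate(starts):
        try:
            sol = least_squares(
                residuals, np.clip(start, lo, hi), bounds=(lo, hi),
                method="trf", x_scale="jac", xtol=1e-6, ftol=1e-6,
            )
        except Exception as exc:  # noqa: BLE001 - collected as diagnostics
            diagnostics.append({"start": s_idx, "status": "error", "message": str(exc)})
            continue
        diagnostics.append(
            {"start": s_idx, "status": int(sol.status), "cost": float(sol.cost),
             "nfev": int(sol.nfev)}
        )
        if sol.status > 0 and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("no optimizer start converged", diagnostics)

    n, dof = len(curve), max(len(curve) - k, 1)
    chi2_red = float(2.0 * best.cost / dof)
    # curvature-based uncertainties
    J = best.jac
    try:
        cov = np.linalg.inv(J.T @ J) * (2.0 * best.cost / dof)
        perr = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        perr = np.full(k, np.nan)

    names = [p.name for p in spec.free_parameters]
    span = hi - lo
    at_bounds = [
        nm for nm, v, l, h, s in zip(names, best.x, lo, hi, span)
        if s > 0 and (v - l < 1e-3 * s or h - v < 1e-3 * s)
    ]
    mixture = spec.build(best.x)
    return FitResult(
        best_parameters=dict(zip(names, map(float, best.x))),
        uncertainties=dict(zip(names, map(float, perr))),
        chi2_reduced=chi2_red,
        species_fractions=_forward_fractions(mixture),
        convergence={
            "status": int(best.status),
            "message": best.message,
            "nfev": int(best.nfev),
            "n_starts": len(starts),
            "starts": diagnostics,
        },
        mixture=mixture,
        at_bounds=at_bounds,
        trace=trace,
    )


def bootstrap_uncertainties(
    curve: ScatteringCurve,
    spec: FitSpec,
    n_boot: int = 50,
    seed: int = 0,
    fit: FitResult | None = None,
) -> dict[str, float]:
    """Residual-resampling bootstrap 1-σ per free parameter.

    Refits ``n_boot`` surrogate curves built as model + resampled residuals,
    each refit started from the converged best parameters (single start).
    Residuals are standardized by σ before resampling and rescaled to the
    destination point's σ, so the strongly Q-dependent counting-noise scale
    survives the permutation.  Deterministic for a given seed.
    """
    if n_boot < 20:
        raise ValueError("n_boot must be at least 20 for a meaningful spread")
    if fit is None:
        fit = fit_mixture(curve, spec)
    model = mixture_intensity(curve.q, fit.mixture, fast=True).intensity
    scale = curve.sigma if curve.sigma is not None else np.ones_like(model)
    resid = (curve.intensity - model) / scale
    rng = np.random.default_rng(seed)
    names = [p.name for p in spec.free_parameters]
    samples = []
    base = FitSpec(
        mixture=spec.mixture,
        free_parameters=[
            FitParameter(p.name, fit.best_parameters[p.name], p.min, p.max)
            for p in spec.free_parameters
        ],
        fixed_parameters=spec.fixed_parameters,
        seed=spec.seed,
        n_starts=1,
    )
    for _ in range(n_boot):
        boot = model + scale * rng.choice(resid, size=resid.size, replace=True)
        bcurve = ScatteringCurve(q=curve.q, intensity=boot, sigma=curve.sigma)
        try:
            bres = fit_mixture(bcurve, base)
        except FitError:
            continue
        samples.append([bres.best_parameters[nm] for nm in names])
    if len(samples) < max(2, n_boot // 2):
        raise FitError(
            f"bootstrap: only {len(samples)}/{n_boot} refits converged"
        )
    arr = np.asarray(samples)
    return dict(zip(names, np.std(arr, axis=0, ddof=1)))


def compare_models(curve: ScatteringCurve, specs: list[FitSpec]) -> list[dict]:
    """Rank candidate mixture models on one curve.

    Score = total χ² + 2k (an Akaike-style parsimony penalty on the χ²
    scale, k the number of free parameters).  Failed fits rank last with
    infinite score but stay in the report.  Ties preserve input order.
    """
    if len(specs) < 2:
        raise ValueError("need at least two specs to compare")
    rows = []
    for idx, spec in enumerate(specs):
        k = len(spec.free_parameters)
        try:
            res = fit_mixture(curve, spec)
            dof = max(len(curve) - k, 1)
            chi2_total = res.chi2_reduced * dof
            rows.append(
                {"index": idx, "status": "ok", "score": chi2_total + 2 * k,
                 "chi2_reduced": res.chi2_reduced, "n_free": k, "result": res}
            )
        except (FitError, ValueError) as exc:
            rows.append(
                {"index": idx, "status": f"failed: {exc}", "score": np.inf,
                 "chi2_reduced": np.nan, "n_free": k, "result": None}
            )
    rows.sort(key=lambda r: (r["score"], r["index"]))
    for rank, row in enumerate(rows, start=1):
        row["rank"] = rank
    return rows
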