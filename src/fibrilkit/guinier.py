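"""Model-free SAXS size analysis.

Implements the classical Guinier approximation for globular particles,
dΣ/dΩ(Q) = dΣ/dΩ(0)·exp(−Q²Rg²/3), the rod-like (cross-sectional) variant
for elongated particles, Q·dΣ/dΩ(Q) = dΣ/dΩ(0)·exp(−Q²Rc²/2), a sequential
two-population rod decomposition for samples containing both mature fibrils
and thinner protofibrils, and a Kratky-plot shape classifier.

Fits are weighted linear regressions in log space with iterative selection
of the valid low-Q window (Q·Rg ≤ 1.3 globular, Q·Rc ≤ 1.0 rod by default).
Failure of the window iteration is meaningful: a fibrillar sample has no
globular Guinier regime at all, and the explicit error is the analysis
signal for that.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from .saxs_models import ScatteringCurve

__all__ = [
    "GuinierResult",
    "GuinierError",
    "NoGuinierRegimeError",
    "AmbiguousWindowsError",
    "guinier_fit",
    "rodlike_guinier_fit",
    "two_population_rod_fit",
    "kratky_shape_score",
]


class GuinierError(ValueError):
    """Base class for Guinier-analysis failures."""


class NoGuinierRegimeError(GuinierError):
    """No convergent low-Q window exists (sample not globular/rod-like)."""


class AmbiguousWindowsError(GuinierError):
    """Two-population decomposition could not separate low/high-Q windows."""

    def __init__(self, msg: str, window_large=None, window_small=None):
        super().__init__(msg)
        self.window_large = window_large
        self.window_small = window_small


@dataclass
class GuinierResult:
    """Outcome of a (rod-like) Guinier fit.

    ``size`` is Rg for kind='globular' and the cross-sectional radius of
    gyration Rc for kind='rod'; ``forward`` is the extrapolated zero-angle
    intensity dΣ/dΩ(0) in cm⁻¹.
    """

    kind: Literal["globular", "rod"]
    size: float
    forward: float
    q_range: tuple[float, float]
    r_squared: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "size": self.size,
            "forward": self.forward,
            "q_range": list(self.q_range),
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


def _weighted_linfit(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least-squares line y = a + b·x; returns (a, b, r²)."""
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    sxy = np.sum(w * (x - xm) * (y - ym))
    if sxx == 0:
        raise GuinierError("degenerate fit window (no spread in Q²)")
    b = sxy / sxx
    a = ym - b * xm
    ss_res = np.sum(w * (y - a - b * x) ** 2)
    ss_tot = np.sum(w * (y - ym) ** 2)
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return a, b, r2


def _iterative_guinier(
    q: np.ndarray,
    logy: np.ndarray,
    w: np.ndarray,
    qmax_rule: float,
    slope_to_size,
    min_points: int = 5,
    max_iter: int = 50,
    trim_k: float = 2.0,
    trim_floor: float = 1e-4,
):
    """Shared iterative low-Q window selection with straight-segment trim.

    ``logy`` is ln(I) or ln(Q·I); ``slope_to_size`` maps the fitted slope to
    Rg or Rc.  Starting from all points, the window is repeatedly truncated
    to Q·size ≤ qmax_rule until it stabilizes (if the selection oscillates
    between two windows, the wider one wins).  The converged window is then
    refined by trimming end points whose fit residuals stand out above the
    interior scatter (|r_end| > trim_k · interior RMS, with an absolute floor
    of ``trim_floor`` log units) — the automated version of picking the
    straight Guinier segment by eye.  On data generated from the defining
    equation residuals vanish and no trimming occurs, so exact inputs are
    recovered to machine precision.
    """
    x = q**2
    n_all = q.size
    if n_all < min_points:
        raise NoGuinierRegimeError(
            f"no Guinier regime: only {n_all} usable points (< {min_points})"
        )

    def fit(i0: int, i1: int):
        sl = slice(i0, i1)
        a, b, r2 = _weighted_linfit(x[sl], logy[sl], w[sl])
        if b >= 0:
            raise NoGuinierRegimeError(
                "no Guinier regime: non-negative log-slope (intensity does "
                "not decay over the fitted window)"
            )
        return a, b, r2, slope_to_size(b)

    # phase 1: iterate the Q·size <= qmax_rule upper bound (prefix windows).
    # When the target window would collapse below min_points the shrink is
    # damped (halving) — a fit over a too-wide window overestimates the size
    # and must not be trusted to discard the regime outright; only a window
    # already at min_points that still wants to shrink signals a real
    # absence of the regime.
    n_cur = n_all
    seen: list[int] = []
    for _ in range(max_iter):
        a, b, r2, size = fit(0, n_cur)
        n_new = int(np.count_nonzero(q * size <= qmax_rule))
        if n_new == n_cur:
            break
        if n_new < min_points:
            if n_cur <= min_points:
                raise NoGuinierRegimeError(
                    "no Guinier regime: valid low-Q window has fewer than "
                    f"{min_points} points"
                )
            n_new = max(n_cur // 2, min_points)
        if n_new in seen:  # oscillation: the wider window wins
            n_cur = max(n_new, n_cur)
            a, b, r2, size = fit(0, n_cur)
            break
        seen.append(n_cur)
        n_cur = n_new
    else:  # pragma: no cover - max_iter is generous
        raise NoGuinierRegimeError("window iteration did not converge")

    # phase 2: trim end points that deviate from the straight segment
    i0, i1 = 0, n_cur
    while i1 - i0 > min_points:
        a, b, r2, size = fit(i0, i1)
        resid = logy[i0:i1] - (a + b * x[i0:i1])
        interior = resid[1:-1]
        tol = max(trim_k * float(np.sqrt(np.mean(interior**2))), trim_floor)
        r_lo, r_hi = abs(float(resid[0])), abs(float(resid[-1]))
        if r_lo >= r_hi and r_lo > tol:
            i0 += 1
        elif r_hi > tol:
            i1 -= 1
        else:
            break
    a, b, r2, size = fit(i0, i1)
    mask = np.zeros(n_all, dtype=bool)
    mask[i0:i1] = True
    return a, b, r2, size, mask


def _prepare(curve: ScatteringCurve, rod: bool):
    q = curve.q
    i = curve.intensity
    pos = i > 0
    if np.count_nonzero(pos) < 5:
        raise NoGuinierRegimeError("fewer than 5 positive-intensity points")
    q, i = q[pos], i[pos]
    sig = curve.sigma[pos] if curve.sigma is not None else None
    y = q * i if rod else i
    logy = np.log(y)
    # propagated log-space weights 1/sigma_ln² = (I/σ)²; unweighted fallback
    w = (i / sig) ** 2 if sig is not None else np.ones_like(i)
    return q, logy, w


def guinier_fit(curve: ScatteringCurve, qmax_rule: float = 1.3) -> GuinierResult:
    """Classical Guinier fit for globular particles.

    Weighted linear regression of ln I vs Q² with slope −Rg²/3, the fit
    window chosen iteratively so that Q·Rg ≤ ``qmax_rule`` at convergence.
    Raises :class:`NoGuinierRegimeError` when no such window exists — the
    model-free signal that the sample is not globular (e.g. mature fibrils).
    """
    q, logy, w = _prepare(curve, rod=False)
    a, b, r2, size, mask = _iterative_guinier(
        q, logy, w, qmax_rule, lambda s: float(np.sqrt(-3.0 * s))
    )
    qm = q[mask]
    return GuinierResult(
        kind="globular",
        size=size,
        forward=float(np.exp(a)),
        q_range=(float(qm[0]), float(qm[-1])),
        r_squared=float(r2),
        n_points=int(np.count_nonzero(mask)),
    )


def rodlike_guinier_fit(curve: ScatteringCurve, qmax_rule: float = 1.0) -> GuinierResult:
    """Cross-sectional Guinier fit for long rod-like particles.

    Weighted linear regression of ln(Q·I) vs Q² with slope −Rc²/2 over an
    iteratively selected window Q·Rc ≤ ``qmax_rule``; Rc is the
    cross-sectional radius of gyration (R/√2 for a uniform circular cross
    section of geometric radius R).
    """
    q, logy, w = _prepare(curve, rod=True)
    a, b, r2, size, mask = _iterative_guinier(
        q, logy, w, qmax_rule, lambda s: float(np.sqrt(-2.0 * s))
    )
    qm = q[mask]
    return GuinierResult(
        kind="rod",
        size=size,
        forward=float(np.exp(a)),
        q_range=(float(qm[0]), float(qm[-1])),
        r_squared=float(r2),
        n_points=int(np.count_nonzero(mask)),
    )


def _rod_model(q: np.ndarray, res: GuinierResult) -> np.ndarray:
    return res.forward / q * np.exp(-0.5 * q**2 * res.size**2)


def two_population_rod_fit(
    curve: ScatteringCurve,
    qmax_rule: float = 1.0,
    min_r_squared: float = 0.95,
) -> tuple[GuinierResult, GuinierResult | None]:
    """Decompose a curve into two rod populations (fibrils + protofibrils).

    A single rod-like Guinier fit is run first; where its residuals are
    significant (above 3σ when the curve carries uncertainties, and above a
    5% systematic floor) a second population is indicated, and both
    rod-Guinier laws, I(Q) = A/Q·exp(−Q²Rc²/2), are then fitted jointly by
    bounded multi-start least squares over the region below the thin
    population's Guinier limit (Q·Rc ≤ ``qmax_rule``, iterated to
    consistency).  The joint fit is what makes comparable-scale populations
    separable: at low Q both populations contribute to the log-slope
    everywhere, so the classical subtract-and-refit sequence cannot unmix
    them, and near the thick population's form-factor zero its local slope
    mimics an arbitrarily large apparent radius.

    Returns (thick, thin) sorted with the larger Rc first, each reported in
    its own window (thick: Q·Rc(thick) ≤ rule; thin: the remaining region up
    to its own limit).  The second element is None when no thin population
    is detected.  Raises :class:`AmbiguousWindowsError` when the two radii
    are too close (within 30%) to separate.
    """
    q, i = curve.q, curve.intensity
    sig = curve.sigma
    # residuals must clear both the statistical noise floor (3σ) and a 5%
    # systematic floor (Guinier-window curvature leaks small residuals even
    # on noise-free data)
    threshold = np.maximum(3.0 * sig, 0.05 * i) if sig is not None else 0.05 * i

    initial = rodlike_guinier_fit(curve, qmax_rule)
    detect = (i - _rod_model(q, initial)) > threshold
    if np.count_nonzero(detect) < 5:
        return initial, None  # single rod population describes the curve

    # joint refinement: both rod-Guinier laws fitted simultaneously.  The
    # single-population fit mixes the two slopes at every Q (the two Guinier
    # windows overlap at low Q), so sequential subtraction cannot separate
    # comparable-scale populations; the joint fit can.
    a_tot, r_init = initial.forward, initial.size
    # σ-weighted when uncertainties exist; otherwise counting-statistics
    # shaped weights √(I·ΔQ), the error model of azimuthally averaged data
    weights = (sig if sig is not None
               else np.sqrt(np.maximum(i, 1e-300) * np.gradient(q)))

    def model(p, qv):
        a1, r1, a2, r2 = p
        return (a1 * np.exp(-0.5 * qv**2 * r1**2)
                + a2 * np.exp(-0.5 * qv**2 * r2**2)) / qv

    lo = np.array([0.0, r_init * 0.999, 0.0, 1e-3])
    hi = np.array([np.inf, 20.0 * r_init, np.inf, r_init * 1.001])
    best = None
    r2_win = 0.5 * r_init
    for _outer in range(4):
        win = q <= qmax_rule / r2_win
        win[: min(10, q.size)] = True  # always keep the lowest-Q points
        qq, ii, ww = q[win], i[win], weights[win]

        def cost_resid(p):
            return (model(p, qq) - ii) / ww

        best_local = None
        for f1 in (1.0, 1.3, 1.6):
            for f2 in (0.3, 0.5, 0.7):
                for split in (0.3, 0.7):
                    x0 = np.clip(
                        [split * a_tot, f1 * r_init, (1 - split) * a_tot,
                         f2 * r_init], lo, hi)
                    sol = least_squares(cost_resid, x0, bounds=(lo, hi),
                                        x_scale="jac")
                    if best_local is None or sol.cost < best_local.cost:
                        best_local = sol
        best = best_local
        new_r2 = float(min(best.x[1], best.x[3]))
        if abs(new_r2 - r2_win) < 1e-3 * r2_win:
            break
        r2_win = new_r2

    a1, r1, a2, r2 = best.x
    if a2 * np.exp(-0.5 * q[0] ** 2 * r2**2) < 1e-3 * a1 or r2 < 1e-2:
        return initial, None
    if r1 < r2:
        a1, r1, a2, r2 = a2, r2, a1, r1  # deterministic: larger Rc first

    def window_result(a_fwd: float, r_c: float, lo_q: float, hi_q: float):
        m = (q >= lo_q) & (q <= hi_q)
        if np.count_nonzero(m) < 2:
            m = np.zeros_like(q, dtype=bool)
            m[: 2] = True
        logy = np.log(q[m] * i[m])
        pred = np.log(q[m] * model(best.x, q[m]))
        ss_res = float(np.sum((logy - pred) ** 2))
        ss_tot = float(np.sum((logy - np.mean(logy)) ** 2))
        r_sq = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
        return GuinierResult(
            kind="rod", size=float(r_c), forward=float(a_fwd),
            q_range=(float(q[m][0]), float(q[m][-1])),
            r_squared=min(r_sq, 1.0),
            n_points=int(np.count_nonzero(m)),
        )

    q_split = qmax_rule / r1
    large = window_result(a1, r1, float(q[0]), q_split)
    small = window_result(a2, r2, q_split, qmax_rule / r2)
    if r1 < 1.3 * r2 or small.q_range[0] <= large.q_range[1]:
        raise AmbiguousWindowsError(
            "fit windows overlap after range selection; the two rod "
            f"populations are not separable (large: {large.q_range}, "
            f"small: {small.q_range})",
            window_large=large.q_range,
            window_small=small.q_range,
        )
    if small.r_squared < min_r_squared:
        return initial, None
    return large, small


def kratky_shape_score(
    curve: ScatteringCurve,
    tail_fraction: float = 0.25,
    bell_threshold: float = 0.5,
    plateau_band: float = 0.15,
) -> tuple[float, str]:
    """Classify the Kratky-plot shape of a scattering curve.

    Computes y = Q²I, finds its global maximum and compares it with the mean
    over the high-Q tail (the top ``tail_fraction`` of the Q range):

    * ``"bell"``    — tail mean below ``bell_threshold`` of the maximum
      (compact, globular particle);
    * ``"plateau"`` — tail stays within ±``plateau_band`` of its own mean
      (flexible chain);
    * ``"rising"``  — anything else (e.g. flat intensity or strong upturn).

    Returns (score, label) with score = 1 − tail_mean/maximum clipped to
    [0, 1]: high for bell-shaped (globular), near 0 for plateau/rising.
    """
    if len(curve) < 20:
        raise ValueError("need at least 20 points for Kratky classification")
    if np.any(curve.intensity <= 0):
        raise ValueError("Kratky classification requires positive intensities")
    q, y = curve.q, curve.q**2 * curve.intensity
    ymax = float(np.max(y))
    tail = y[q >= q[-1] - tail_fraction * (q[-1] - q[0])]
    tail_mean = float(np.mean(tail))
    score = float(np.clip(1.0 - tail_mean / ymax, 0.0, 1.0))
    if tail_mean < bell_threshold * ymax:
        return score, "bell"
    if np.all(np.abs(tail - tail_mean) <= plateau_band * tail_mean):
        return score, "plateau"
    return score, "rising"
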