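"""Far-UV circular dichroism band-shape analysis.

Native α+β proteins such as lysozyme show two negative CD bands near 208 and
222 nm; conversion to the cross-β amyloid state collapses them into a single
intense negative band near 215 nm.  The analysis here is deliberately
band-shape-based (no secondary-structure deconvolution): baseline
subtraction, natural smoothing-spline denoising, minima location with
shoulder suppression, and a three-way classification
native-like / β-rich / indeterminate that is invariant under rescaling of
the signal (path length or concentration changes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.signal import find_peaks

__all__ = [
    "CDSpectrum",
    "preprocess",
    "locate_minima",
    "classify_state",
]


@dataclass
class CDSpectrum:
    """CD spectrum: wavelength (nm) over roughly 190–260 nm, ellipticity
    signal in millidegrees, and the number of instrument scans averaged."""

    wavelength: np.ndarray
    signal: np.ndarray
    n_scans_averaged: int = 1

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.wavelength[0] < 185.0 or self.wavelength[-1] > 265.0:
            raise ValueError("CD grid must lie within [185, 265] nm")
        if self.signal.shape != self.wavelength.shape:
            raise ValueError("signal and wavelength must match in length")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")

    @classmethod
    def from_csv(cls, path) -> "CDSpectrum":
        df = pd.read_csv(path)
        return cls(df["wavelength_nm"].to_numpy(), df["mdeg"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"wavelength_nm": self.wavelength, "mdeg": self.signal}).to_csv(
            path, index=False
        )


def preprocess(
    raw: CDSpectrum,
    buffer_baseline: CDSpectrum | None = None,
    smoothing_strength: float = 1.0,
) -> CDSpectrum:
    """Baseline-subtract and smooth a CD spectrum.

    The buffer baseline is interpolated onto the sample grid (the grids must
    overlap) and subtracted; the result is smoothed with a natural smoothing
    spline whose penalty is ``smoothing_strength`` (0 disables smoothing and,
    with no baseline, the operation is the identity).
    """
    wl, sig = raw.wavelength, raw.signal.copy()
    if buffer_baseline is not None:
        bwl = buffer_baseline.wavelength
        if bwl[-1] < wl[0] or bwl[0] > wl[-1]:
            raise ValueError("baseline and sample wavelength ranges do not overlap")
        sig = sig - np.interp(wl, bwl, buffer_baseline.signal)
    if smoothing_strength > 0:
        spline = make_smoothing_spline(wl, sig, lam=smoothing_strength)
        sig = spline(wl)
    return CDSpectrum(wl, sig, raw.n_scans_averaged)


def locate_minima(
    spectrum: CDSpectrum,
    prominence_fraction: float = 0.05,
) -> list[tuple[float, float]]:
    """All local minima with negative signal, sorted by wavelength.

    Shoulders are suppressed by requiring a prominence of at least
    ``prominence_fraction`` of the deepest minimum's depth.  Returns
    (wavelength nm, depth mdeg) pairs; the list may be empty.
    """
    sig = spectrum.signal
    depth_ref = float(np.max(-sig))
    if depth_ref <= 0:
        return []
    idx, _ = find_peaks(-sig, prominence=prominence_fraction * depth_ref)
    out = [
        (float(spectrum.wavelength[i]), float(sig[i]))
        for i in idx
        if sig[i] < 0
    ]
    return sorted(out)


def classify_state(
    spectrum: CDSpectrum,
    prominence_fraction: float = 0.05,
) -> tuple[str, float]:
    """Classify a smoothed CD spectrum as native-like or β-rich.

    * ``native_like``   — minima in both 204–212 nm and 218–226 nm (the
      208/222 doublet of the α+β native fold);
    * ``beta_rich``     — otherwise, exactly one minimum in 210–222 nm (the
      single ≈215 nm cross-β band);
    * ``indeterminate`` — anything else (e.g. a flat spectrum).

    The score is the depth-weighted margin of the classifying bands: the
    depth of the shallowest classifying minimum divided by the largest
    signal magnitude, clipped to [0, 1]; 0 for indeterminate.  Both label
    and score are invariant under positive rescaling of the signal.
    """
    minima = locate_minima(spectrum, prominence_fraction)
    scale = float(np.max(np.abs(spectrum.signal)))
    if scale == 0 or not minima:
        return "indeterminate", 0.0
    in_208 = [m for m in minima if 204.0 <= m[0] <= 212.0]
    in_222 = [m for m in minima if 218.0 <= m[0] <= 226.0]
    in_beta = [m for m in minima if 210.0 <= m[0] <= 222.0]
    if in_208 and in_222:
        depth = min(-in_208[0][1], -in_222[0][1])
        return "native_like", float(np.clip(depth / scale, 0.0, 1.0))
    if len(in_beta) == 1:
        return "beta_rich", float(np.clip(-in_beta[0][1] / scale, 0.0, 1.0))
    return "indeterminate", 0.0
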