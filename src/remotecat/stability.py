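"""Thermal-shift melting temperatures and fluorescence difference spectra.

Thermal shift (thermofluor) curves report dye fluorescence (RFU) against
temperature as a protein unfolds; the melting temperature Tm is read from
the peak of the first-derivative plot of the melt transition. Ligand
binding stabilizes the fold, so a Tm increase of the holo sample beyond a
threshold (default 2 °C) is called stabilization.

Intrinsic tryptophan fluorescence probes ligand binding directly: after
normalizing all emission spectra to the apo-protein maximum, the difference

    D(lambda) = S_mixture - S_apo - S_substrate + S_buffer

is identically zero when protein and substrate do not interact, and shows a
peak near 310 nm on binding-induced environment changes of the tryptophans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "MeltCurve",
    "TmResult",
    "SpectrumSet",
    "tm_from_curve",
    "stabilization_call",
    "difference_spectrum",
    "peak_call",
]


@dataclass
class MeltCurve:
    temperature: np.ndarray   # °C, strictly increasing
    rfu: np.ndarray
    sample: str = ""
    ligand: str = "apo"       # apo | CP | ORN | CIT

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if len(self.temperature) < 50:
            raise ValueError("melt curve needs >= 50 points")
        if not (np.diff(self.temperature) > 0).all():
            raise ValueError("temperature grid must be strictly increasing")


@dataclass
class TmResult:
    tm: float                  # °C
    peak_height: float
    at_boundary: bool = False
    secondary_tm: float | None = None
    sd: float | None = None


@dataclass
class SpectrumSet:
    """Emission spectra (300–400 nm) of mixture, apo protein, buffer and
    substrate alone; each may carry replicate scans (rows)."""

    wavelength: np.ndarray
    mixture: np.ndarray
    apo: np.ndarray
    buffer: np.ndarray
    substrate: np.ndarray

    def __post_init__(self):
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        for name in ("mixture", "apo", "buffer", "substrate"):
            arr = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if arr.shape[1] != self.wavelength.size:
                raise ValueError(f"{name} spectrum not on the common wavelength grid")
            setattr(self, name, arr)


def tm_from_curve(
    curve: MeltCurve,
    smoothing_window_C: float = 2.0,
    polyorder: int = 3,
) -> TmResult:
    """Tm as the location of the highest melt-transition derivative peak.

    The curve is Savitzky–Golay smoothed (window in °C, order 3) and
    differentiated; the reported Tm is the highest peak of |dRFU/dT|,
    refined by parabolic interpolation around the grid argmax. A second
    transition, when present, is reported as ``secondary_tm``. A boundary
    peak is flagged; a flat curve raises.
    """
    T, y = curve.temperature, curve.rfu
    if np.ptp(y) == 0:
        raise ValueError("flat melt curve: no transition")
    step = float(np.median(np.diff(T)))
    win = max(polyorder + 2, int(round(smoothing_window_C / step)) | 1)
    win = min(win if win % 2 == 1 else win + 1, len(T) - (1 - len(T) % 2))
    deriv = savgol_filter(y, window_length=win, polyorder=polyorder, deriv=1, delta=step)
    mag = np.abs(deriv)
    i = int(np.argmax(mag))
    at_boundary = i in (0, len(T) - 1)
    if at_boundary:
        warnings.warn("derivative peak at grid boundary; curve may not span the transition")
        tm = float(T[i])
    else:
        # refine by a local parabola over ~±1.5 °C around the grid argmax;
        # beats both grid resolution and residual derivative noise
        half = max(2, int(round(1.5 / step)))
        lo, hi = max(0, i - half), min(len(T), i + half + 1)
        c2, c1, _ = np.polyfit(T[lo:hi], mag[lo:hi], 2)
        if c2 < 0:
            tm = float(np.clip(-c1 / (2 * c2), T[lo], T[hi - 1]))
        else:
            tm = float(T[i])
    if np.ptp(mag) == 0:
        raise ValueError("flat derivative: no transition detected")

    secondary = None
    peaks, props = find_peaks(mag, height=0.2 * mag[i], distance=max(1, int(5.0 / step)))
    peaks = [p for p in peaks if abs(T[p] - tm) > 5.0]
    if peaks:
        p = max(peaks, key=lambda p: mag[p])
        secondary = float(T[p])
    return TmResult(tm=tm, peak_height=float(mag[i]), at_boundary=at_boundary,
                    secondary_tm=secondary)


def stabilization_call(apo: TmResult, holo: TmResult, threshold_C: float = 2.0) -> str:
    """'stabilized' iff Tm(holo) - Tm(apo) >= threshold, else 'unchanged'."""
    return "stabilized" if (holo.tm - apo.tm) >= threshold_C else "unchanged"


def difference_spectrum(spectra: SpectrumSet) -> tuple[np.ndarray, np.ndarray]:
    """Binding difference spectrum D(lambda), replicate mean and SD.

    Every spectrum is normalized by the apo-protein maximum (replicate-mean
    apo), then D = mixture - apo - substrate + buffer. Under the
    non-interaction null (mixture = apo + substrate - buffer) D is
    identically zero.
    """
    apo_mean = spectra.apo.mean(axis=0)
    scale = float(apo_mean.max())
    if scale == 0:
        raise ValueError("apo spectrum maximum is zero; cannot normalize")

    n_rep = max(s.shape[0] for s in (spectra.mixture, spectra.apo, spectra.buffer, spectra.substrate))

    def rep(arr):
        return arr if arr.shape[0] == n_rep else np.repeat(arr.mean(axis=0)[None, :], n_rep, axis=0)

    mix, apo, buf, sub = (rep(s) / scale for s in
                          (spectra.mixture, spectra.apo, spectra.buffer, spectra.substrate))
    D = mix - apo - sub + buf
    return D.mean(axis=0), D.std(axis=0, ddof=1) if n_rep > 1 else np.zeros_like(D.mean(axis=0))


def peak_call(
    wavelength: np.ndarray,
    D: np.ndarray,
    D_sd: np.ndarray | None = None,
    window: tuple[float, float] = (305.0, 315.0),
    min_height: float | None = None,
    sd_factor: float = 3.0,
) -> bool:
    """True iff the difference spectrum has a peak in the window.

    The default detection threshold is ``sd_factor`` times the mean
    replicate SD inside the window; with a single replicate (no SD) an
    absolute ``min_height`` must be supplied.
    """
    wavelength = np.asarray(wavelength, dtype=float)
    D = np.asarray(D, dtype=float)
    mask = (wavelength >= window[0]) & (wavelength <= window[1])
    if not mask.any():
        raise ValueError("window outside the wavelength grid")
    if min_height is None:
        if D_sd is None or not np.any(np.asarray(D_sd) > 0):
            raise ValueError("single-replicate data: an absolute min_height is required")
        min_height = sd_factor * float(np.asarray(D_sd)[mask].mean())
    return bool(D[mask].max() >= min_height)
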