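"""Steady-state Michaelis–Menten kinetics reduction.

Reduces a colorimetric citrulline assay to enzyme parameters: a linear
standard curve converts absorbance to product concentration, initial rates
are the slopes of the early linear window of progress curves, and rates
versus substrate concentration are fit to v = Vmax*S/(KM + S) by nonlinear
least squares. Catalytic efficiency kcat/KM and wild-type-relative ratios
(relative kcat, relative kcat/KM, fold-decrease) summarize variants.

Units: substrate concentrations in mM, rates in mM/s (or s^-1 after
normalizing by enzyme concentration), kcat in s^-1, kcat/KM reported in
10^4 M^-1 s^-1 (kcat[s^-1] / KM[mM] * 1e3 / 1e4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "StandardCurve",
    "MMFit",
    "fit_standard_curve",
    "initial_rate",
    "fit_mm",
    "efficiency_1e4",
    "compare_to_wt",
    "round_sig",
]


@dataclass
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def to_concentration(self, absorbance: np.ndarray) -> np.ndarray:
        return (np.asarray(absorbance, dtype=float) - self.intercept) / self.slope


@dataclass
class MMFit:
    vmax: float                # mM/s
    km: float                  # mM
    kcat: float | None = None  # s^-1, = vmax / [E]
    vmax_se: float = np.nan
    km_se: float = np.nan
    converged: bool = True
    substrate: str = ""
    enzyme_nM: float | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def efficiency_1e4(self) -> float | None:
        """kcat/KM in units of 10^4 M^-1 s^-1."""
        if self.kcat is None:
            return None
        return efficiency_1e4(self.kcat, self.km)


def efficiency_1e4(kcat: float, km_mM: float) -> float:
    """kcat/KM in 10^4 M^-1 s^-1 from kcat (s^-1) and KM (mM)."""
    return kcat / km_mM * 1e3 / 1e4


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention)."""
    if x == 0 or not np.isfinite(x):
        return x
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def fit_standard_curve(
    concentration: np.ndarray, absorbance: np.ndarray, r2_warn: float = 0.98
) -> StandardCurve:
    """Ordinary least-squares calibration line A = slope*c + intercept."""
    c = np.asarray(concentration, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if len(c) < 3:
        raise ValueError("need at least 3 calibration points")
    if np.ptp(c) == 0:
        raise ValueError("calibration concentrations have zero spread")
    res = stats.linregress(c, a)
    r2 = float(res.rvalue**2)
    if r2 < r2_warn:
        warnings.warn(f"standard curve R^2 = {r2:.4f} < {r2_warn}")
    return StandardCurve(float(res.slope), float(res.intercept), r2, len(c))


def initial_rate(
    time_s: np.ndarray,
    product_mM: np.ndarray,
    substrate_mM: float | None = None,
    max_conversion: float = 0.10,
    min_points: int = 3,
) -> float:
    """Initial slope v0 (mM/s) of a progress curve.

    The fit window is the prefix of points with product below
    ``max_conversion`` of the initial substrate (when given), at least
    ``min_points`` points. A non-monotone early series beyond noise level
    warns but still fits.
    """
    t = np.asarray(time_s, dtype=float)
    p = np.asarray(product_mM, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    if t.min() > 0.2 * t.max():
        warnings.warn("no time point near t=0; initial rate may be biased")
    order = np.argsort(t)
    t, p = t[order], p[order]
    if substrate_mM is not None:
        in_window = p <= max_conversion * substrate_mM
        n_win = max(int(in_window.sum()), min_points)
    else:
        n_win = len(t)
    n_win = min(n_win, len(t))
    tw, pw = t[:n_win], p[:n_win]
    diffs = np.diff(pw)
    if np.ptp(pw) > 0 and (diffs < -0.1 * np.ptp(pw)).any():
        warnings.warn("non-monotone early progress curve; fitting anyway")
    res = stats.linregress(tw, pw)
    return float(res.slope)


def fit_mm(
    substrate_mM: np.ndarray,
    rates: np.ndarray,
    enzyme_nM: float | None = None,
    substrate: str = "",
    weighting: str = "none",
) -> MMFit:
    """Nonlinear least-squares Michaelis–Menten fit.

    Initialization: Vmax0 = max rate, KM0 = substrate at half-max rate by
    interpolation. ``weighting='1/v2'`` selects relative weighting.
    Rates in mM/s; with ``enzyme_nM`` given, kcat = Vmax/[E] in s^-1.
    A failed optimization is returned flagged, never silently replaced.
    """
    S = np.asarray(substrate_mM, dtype=float)
    v = np.asarray(rates, dtype=float)
    if len(np.unique(S)) < 5:
        raise ValueError("need at least 5 distinct substrate concentrations")
    if (S <= 0).any():
        raise ValueError("substrate concentrations must be positive")

    vmax0 = float(v.max())
    half = vmax0 / 2.0
    order = np.argsort(S)
    km0 = float(np.interp(half, v[order], S[order]))
    if not np.isfinite(km0) or km0 <= 0:
        km0 = float(np.median(S))

    def mm(S, vmax, km):
        return vmax * S / (km + S)

    sigma = None
    if weighting == "1/v2":
        sigma = np.abs(v) + 1e-12
    try:
        popt, pcov = optimize.curve_fit(
            mm, S, v, p0=[vmax0, km0], sigma=sigma,
            bounds=([0, 0], [np.inf, np.inf]), maxfev=10_000,
            xtol=1e-13, ftol=1e-13, gtol=1e-13, x_scale=[max(vmax0, 1e-12), max(km0, 1e-12)],
        )
        perr = np.sqrt(np.diag(pcov))
        converged = bool(np.isfinite(popt).all())
    except RuntimeError as exc:
        return MMFit(np.nan, np.nan, converged=False, substrate=substrate,
                     enzyme_nM=enzyme_nM, diagnostics={"error": str(exc)})
    vmax, km = float(popt[0]), float(popt[1])
    if not (S.min() <= km <= S.max()):
        warnings.warn(
            f"fitted KM {km:.3g} mM outside the sampled range "
            f"[{S.min():.3g}, {S.max():.3g}] mM"
        )
    kcat = None
    if enzyme_nM is not None:
        kcat = vmax / (enzyme_nM * 1e-6)  # mM/s over mM of enzyme -> s^-1
    return MMFit(
        vmax=vmax, km=km, kcat=kcat,
        vmax_se=float(perr[0]), km_se=float(perr[1]),
        converged=converged, substrate=substrate, enzyme_nM=enzyme_nM,
    )


def compare_to_wt(
    wt: MMFit | dict,
    variants: dict[str, "MMFit | dict"],
    sig: int = 2,
) -> pd.DataFrame:
    """Wild-type-relative comparison table.

    Accepts MMFit objects or dicts with keys ``kcat`` (s^-1), ``km`` (mM)
    and optionally ``eff_1e4`` (kcat/KM in 10^4 M^-1 s^-1, e.g. an average
    over replicate ratios, which need not equal kcat(avg)/KM(avg)).

    Columns: kcat/KM, relative kcat, relative kcat/KM, fold-decrease, with
    display values rounded to ``sig`` significant figures. Before rounding,
    fold_decrease * relative_eff == 1 exactly.
    """

    def unpack(f):
        if isinstance(f, MMFit):
            return f.kcat, f.km, f.efficiency_1e4
        kcat, km = f["kcat"], f["km"]
        eff = f.get("eff_1e4", efficiency_1e4(kcat, km))
        return kcat, km, eff

    wt_kcat, wt_km, wt_eff = unpack(wt)
    rows = []
    for name, fit in variants.items():
        kcat, km, eff = unpack(fit)
        rel_kcat = kcat / wt_kcat
        rel_eff = eff / wt_eff
        if eff == 0:
            fold = np.inf
        else:
            fold = wt_eff / eff
        rows.append(
            {
                "variant": name,
                "km_mM": km,
                "kcat_s": kcat,
                "eff_1e4": eff,
                "relative_kcat": round_sig(rel_kcat, sig),
                "relative_eff": round_sig(rel_eff, sig),
                "fold_decrease": round_sig(fold, sig),
                "_relative_eff_exact": rel_eff,
                "_fold_decrease_exact": fold,
            }
        )
    return pd.DataFrame(rows)
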