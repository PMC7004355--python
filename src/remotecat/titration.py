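"""Theoretical titration curves, anomaly features and protonation coupling.

Ionizable sites in a protein do not titrate independently: charged sites
interact electrostatically, which perturbs, broadens and couples their
protonation equilibria. Residues whose theoretical titration curves deviate
from the ideal Henderson–Hasselbalch (HH) shape are enriched in catalytic
function, and the *shape anomaly* of the curve is usable as a per-residue
feature for functional-site ranking.

The model here is a rigid-geometry microstate model with a screened-Coulomb
pair interaction:

    E(s; pH) = sum_i  2.303 kT * gamma_i(s) * (pH - pKa_int,i)
             + sum_{i<j}  K_ij * c_i(s) * c_j(s)

where gamma_i is the protonation indicator of site i, c_i(s) the charge of
site i in microstate s (acid: 0 protonated / -1 deprotonated; base: +1 / 0)
and K_ij = 332.06 * exp(-r_ij/lambda_D) / (eps * r_ij) kcal/mol per unit
charge product. The protonation term applies identically to acids and bases,
so every isolated site reduces exactly to the HH curve
theta = 1/(1 + 10^(pH - pKa)).

Mean protonation theta(pH) is computed by exact Boltzmann enumeration for
small systems (<= 20 sites) and by Metropolis single-flip Monte Carlo
otherwise. kT = 0.593 kcal/mol (298 K) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .structure import Structure

__all__ = [
    "IonizableSite",
    "TitrationCurve",
    "AnomalyFeatures",
    "DEFAULT_PKA",
    "COULOMB_KCAL",
    "KT_KCAL",
    "build_sites",
    "interaction_matrix",
    "titration_curves",
    "hh_curve",
    "anomaly_features",
    "protonation_coupling",
]

KT_KCAL = 0.593           # kcal/mol at 298 K
LN10_KT = np.log(10.0) * KT_KCAL
COULOMB_KCAL = 332.06     # kcal*Å/(mol*e^2)

# model-compound intrinsic pKa values
DEFAULT_PKA = {
    "ASP": 3.9, "GLU": 4.1, "HIS": 6.5, "CYS": 8.3, "TYR": 10.1,
    "LYS": 10.5, "ARG": 12.5, "NTR": 8.0, "CTR": 3.2,
}

_ACIDS = {"ASP", "GLU", "CYS", "TYR", "CTR"}
_BASES = {"HIS", "LYS", "ARG", "NTR"}

# titratable-group representative atom per site type
_SITE_ATOM = {
    "ASP": ("OD2", "OD1", "CG"),
    "GLU": ("OE2", "OE1", "CD"),
    "HIS": ("NE2", "ND1", "CG"),
    "CYS": ("SG",),
    "TYR": ("OH",),
    "LYS": ("NZ",),
    "ARG": ("CZ", "NH1"),
}


@dataclass(frozen=True)
class IonizableSite:
    name: str                     # e.g. "ASP140:A" or "NTR:A"
    site_type: str                # ASP/GLU/HIS/CYS/TYR/LYS/ARG/NTR/CTR
    pka: float
    position: tuple[float, float, float]
    residue_id: tuple[str, int] | None = None

    def __post_init__(self):
        if not (0.0 <= self.pka <= 16.0):
            raise ValueError(f"intrinsic pKa {self.pka} outside [0, 16] for {self.name}")
        if self.site_type not in _ACIDS | _BASES:
            raise ValueError(f"unknown site type {self.site_type!r}")

    @property
    def is_acid(self) -> bool:
        return self.site_type in _ACIDS

    @property
    def charge_protonated(self) -> int:
        return 0 if self.is_acid else 1

    @property
    def charge_deprotonated(self) -> int:
        return -1 if self.is_acid else 0

    @property
    def charged_form_charge(self) -> int:
        """Charge of the ionized form (acid: -1, base: +1)."""
        return -1 if self.is_acid else 1


@dataclass
class TitrationCurve:
    """theta(pH) per site on a shared uniform pH grid."""

    ph: np.ndarray                      # shape (n_ph,)
    theta: np.ndarray                   # shape (n_sites, n_ph)
    site_names: list[str]

    def for_site(self, name: str) -> np.ndarray:
        return self.theta[self.site_names.index(name)]


@dataclass
class AnomalyFeatures:
    """Shape-anomaly summary of one titration curve.

    f(pH) = -dtheta/dpH treated as a normalized density; ``m3``/``m4`` are
    its third/fourth central moments, ``hh_area`` the integrated absolute
    deviation from the best-fit HH curve. ``defined`` is False for curves
    that do not titrate inside the pH window.
    """

    site_name: str
    m3: float
    m4: float
    hh_area: float
    fitted_pka: float
    defined: bool = True

    @property
    def anomaly_score(self) -> float:
        """Scalar anomaly summary (larger = less HH-like): hh_area."""
        return self.hh_area if self.defined else 0.0


# ---------------------------------------------------------------------------
# site construction


def build_sites(
    structure: Structure,
    pka_table: dict[str, float] | None = None,
    include_termini: bool = True,
) -> list[IonizableSite]:
    """One site per ionizable residue (D/E/H/C/Y/K/R) plus chain termini.

    The representative position is the titratable-group atom; residues
    lacking it are skipped with a warning.
    """
    import warnings

    pka_table = {**DEFAULT_PKA, **(pka_table or {})}
    sites: list[IonizableSite] = []
    residues = structure.residue_ids(het=False)
    if not residues:
        return sites

    chains: dict[str, list] = {}
    for rid in residues:
        chains.setdefault(rid[0], []).append(rid)

    for rid in residues:
        name = structure.residue_name(rid)
        if name not in _SITE_ATOM:
            continue
        atoms = {a.name: a for a in structure.residue_atoms(rid)}
        pos = None
        for atom_name in _SITE_ATOM[name]:
            if atom_name in atoms:
                pos = atoms[atom_name].pos
                break
        if pos is None:
            warnings.warn(
                f"{name}{rid[1]}:{rid[0]} lacks its titratable-group atom; site skipped"
            )
            continue
        sites.append(
            IonizableSite(
                name=f"{name}{rid[1]}:{rid[0]}",
                site_type=name,
                pka=pka_table[name],
                position=tuple(pos),
                residue_id=rid,
            )
        )

    if include_termini:
        for ch, rids in chains.items():
            first_atoms = {a.name: a for a in structure.residue_atoms(rids[0])}
            last_atoms = {a.name: a for a in structure.residue_atoms(rids[-1])}
            if "N" in first_atoms:
                sites.append(
                    IonizableSite(
                        name=f"NTR:{ch}", site_type="NTR", pka=pka_table["NTR"],
                        position=tuple(first_atoms["N"].pos), residue_id=rids[0],
                    )
                )
            for cname in ("OXT", "C"):
                if cname in last_atoms:
                    sites.append(
                        IonizableSite(
                            name=f"CTR:{ch}", site_type="CTR", pka=pka_table["CTR"],
                            position=tuple(last_atoms[cname].pos), residue_id=rids[-1],
                        )
                    )
                    break
    return sites


# ---------------------------------------------------------------------------
# interactions


def interaction_matrix(
    sites: Sequence[IonizableSite],
    dielectric: float = 20.0,
    debye_length: float = 8.0,
) -> np.ndarray:
    """Screened-Coulomb pair energies W_ij (kcal/mol) for simultaneous
    charging, using the full charges of the ionized form of each site.

    W_ij = 332.06 * q_i * q_j * exp(-r_ij / lambda_D) / (eps * r_ij).
    ``debye_length=None`` (or inf) disables screening.
    """
    n = len(sites)
    if n < 2:
        raise ValueError("need at least 2 sites")
    pos = np.array([s.position for s in sites], dtype=float)
    q = np.array([s.charged_form_charge for s in sites], dtype=float)
    diff = pos[:, None, :] - pos[None, :, :]
    r = np.sqrt((diff**2).sum(axis=2))
    close = (r < 0.5) & ~np.eye(n, dtype=bool)
    if close.any():
        i, j = np.argwhere(close)[0]
        raise ValueError(
            f"sites {sites[i].name} and {sites[j].name} are closer than 0.5 Å (r={r[i, j]:.3f})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        screen = np.ones_like(r) if not np.isfinite(debye_length or np.inf) or debye_length is None \
            else np.exp(-r / debye_length)
        W = COULOMB_KCAL * np.outer(q, q) * screen / (dielectric * r)
    np.fill_diagonal(W, 0.0)
    return W


def _charge_kernel(sites: Sequence[IonizableSite], W: np.ndarray) -> np.ndarray:
    """K_ij such that pair energy = sum_{i<j} K_ij c_i(s) c_j(s), recovered
    from W by dividing out the ionized-form charge product (which is ±1)."""
    q = np.array([s.charged_form_charge for s in sites], dtype=float)
    qq = np.outer(q, q)
    K = np.zeros_like(W)
    mask = qq != 0
    K[mask] = W[mask] / qq[mask]
    return K


# ---------------------------------------------------------------------------
# titration


def hh_curve(ph: np.ndarray, pka: float) -> np.ndarray:
    """Henderson–Hasselbalch protonation fraction."""
    return 1.0 / (1.0 + 10.0 ** (np.asarray(ph, dtype=float) - pka))


def _state_charges(sites, gamma: np.ndarray) -> np.ndarray:
    """Charge per site given protonation indicators (vectorized over states)."""
    cp = np.array([s.charge_protonated for s in sites], dtype=float)
    cd = np.array([s.charge_deprotonated for s in sites], dtype=float)
    return gamma * cp + (1.0 - gamma) * cd


def _enumerate_theta(sites, K: np.ndarray, ph_grid: np.ndarray) -> np.ndarray:
    n = len(sites)
    n_states = 1 << n
    states = ((np.arange(n_states)[:, None] >> np.arange(n)) & 1).astype(float)
    pka = np.array([s.pka for s in sites], dtype=float)
    charges = _state_charges(sites, states)                      # (S, n)
    e_pair = 0.5 * np.einsum("si,ij,sj->s", charges, K, charges)  # diag(K)=0
    # protonation term: E = LN10_KT * sum_i gamma_i (pH - pKa_i)
    g_sum = states.sum(axis=1)                                   # coefficient of pH
    g_pka = states @ pka
    theta = np.empty((n, ph_grid.size))
    for k, ph in enumerate(ph_grid):
        E = LN10_KT * (g_sum * ph - g_pka) + e_pair
        E = E - E.min()
        w = np.exp(-E / KT_KCAL)
        w /= w.sum()
        theta[:, k] = w @ states
    return theta


def _mc_sample(
    sites, K: np.ndarray, ph: float,
    n_samples: int, burn_in: int, rng: np.random.Generator,
    collect_pairs: bool = False,
    pair_move_prob: float = 0.25,
    pair_coupling_kcal: float = 1.2,
):
    """Metropolis sampling of protonation microstates at one pH.

    Proposes single-site flips plus simultaneous flips of strongly coupled
    pairs (|K_ij| above ~2 kT), which restores mixing across salt-bridge-like
    locked pairs. Returns (mean gamma, mean outer product or None).
    """
    n = len(sites)
    pka = np.array([s.pka for s in sites], dtype=float)
    cp = np.array([s.charge_protonated for s in sites], dtype=float)
    cd = np.array([s.charge_deprotonated for s in sites], dtype=float)
    pairs = np.argwhere(np.triu(np.abs(K) >= pair_coupling_kcal, k=1))
    use_pairs = len(pairs) > 0

    gamma = (rng.random(n) < hh_curve(ph, pka)).astype(float)
    c = gamma * cp + (1 - gamma) * cd
    s1 = np.zeros(n)
    s2 = np.zeros((n, n)) if collect_pairs else None

    n_steps = burn_in + n_samples
    singles = rng.integers(0, n, size=n_steps)
    pair_idx = rng.integers(0, max(len(pairs), 1), size=n_steps)
    move_u = rng.random(n_steps)
    acc_u = rng.random(n_steps)

    def delta_single(i):
        new_g = 1.0 - gamma[i]
        new_c = cp[i] if new_g else cd[i]
        dE = LN10_KT * (new_g - gamma[i]) * (ph - pka[i]) + (new_c - c[i]) * (K[i] @ c)
        return new_g, new_c, dE

    for t in range(n_steps):
        if use_pairs and move_u[t] < pair_move_prob:
            i, j = pairs[pair_idx[t]]
            gi, ci_new = 1.0 - gamma[i], (cp[i] if gamma[i] == 0.0 else cd[i])
            gj, cj_new = 1.0 - gamma[j], (cp[j] if gamma[j] == 0.0 else cd[j])
            # dE = E(new) - E(old) restricted to terms involving i, j
            dE = (
                LN10_KT * ((gi - gamma[i]) * (ph - pka[i]) + (gj - gamma[j]) * (ph - pka[j]))
                + (ci_new - c[i]) * (K[i] @ c - K[i, j] * c[j])
                + (cj_new - c[j]) * (K[j] @ c - K[i, j] * c[i])
                + K[i, j] * (ci_new * cj_new - c[i] * c[j])
            )
            if dE <= 0 or acc_u[t] < np.exp(-dE / KT_KCAL):
                gamma[i], c[i] = gi, ci_new
                gamma[j], c[j] = gj, cj_new
        else:
            i = singles[t]
            new_g, new_c, dE = delta_single(i)
            if dE <= 0 or acc_u[t] < np.exp(-dE / KT_KCAL):
                gamma[i], c[i] = new_g, new_c
        if t >= burn_in:
            s1 += gamma
            if collect_pairs:
                s2 += np.outer(gamma, gamma)
    mean = s1 / n_samples
    return mean, (s2 / n_samples if collect_pairs else None)


def _mc_theta(
    sites, K: np.ndarray, ph_grid: np.ndarray,
    n_samples: int, burn_in: int, rng: np.random.Generator,
) -> np.ndarray:
    theta = np.empty((len(sites), ph_grid.size))
    for k, ph in enumerate(ph_grid):
        theta[:, k], _ = _mc_sample(sites, K, float(ph), n_samples, burn_in, rng)
    return theta


def titration_curves(
    sites: Sequence[IonizableSite],
    W: np.ndarray | None = None,
    ph_grid: np.ndarray | None = None,
    method: str = "auto",
    n_samples: int = 100_000,
    burn_in: int = 1_000,
    seed: int = 1234,
    enumerate_limit: int = 20,
) -> TitrationCurve:
    """Mean protonation theta(pH) for every site.

    method: 'enumerate' (exact Boltzmann sum, <= ``enumerate_limit`` sites),
    'mc' (Metropolis single-site flips, seeded), or 'auto'.
    W=None means non-interacting sites (pure HH curves).
    """
    if len(sites) < 1:
        raise ValueError("need at least one site")
    if ph_grid is None:
        ph_grid = np.arange(0.0, 14.0 + 1e-9, 0.1)
    ph_grid = np.asarray(ph_grid, dtype=float)
    n = len(sites)
    if W is None:
        W = np.zeros((n, n))
    W = np.asarray(W, dtype=float)
    if not np.isfinite(W).all():
        raise FloatingPointError("non-finite interaction energies")
    K = _charge_kernel(sites, W)

    if method == "auto":
        method = "enumerate" if n <= enumerate_limit else "mc"
    if method == "enumerate":
        if n > enumerate_limit:
            raise ValueError(f"enumeration requested for {n} sites (> {enumerate_limit})")
        theta = _enumerate_theta(sites, K, ph_grid)
    elif method == "mc":
        rng = np.random.default_rng(seed)
        theta = _mc_theta(sites, K, ph_grid, n_samples, burn_in, rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TitrationCurve(ph=ph_grid, theta=theta, site_names=[s.name for s in sites])


# ---------------------------------------------------------------------------
# anomaly features


def anomaly_features(
    curve: TitrationCurve,
    site: str | int = 0,
    flat_tolerance: float = 1e-3,
) -> AnomalyFeatures:
    """Moments of the buffering density f = -dtheta/dpH and the deviation
    area from the best-fit Henderson–Hasselbalch curve.

    A site that does not titrate inside the window (total theta change
    below ``flat_tolerance``) is flagged undefined rather than scored 0.
    """
    idx = curve.site_names.index(site) if isinstance(site, str) else site
    name = curve.site_names[idx]
    ph, th = curve.ph, curve.theta[idx]
    span = th[0] - th[-1]
    if abs(span) < flat_tolerance:
        return AnomalyFeatures(name, np.nan, np.nan, np.nan, np.nan, defined=False)

    f = -np.gradient(th, ph)
    f = np.clip(f, 0.0, None)
    mass = np.trapezoid(f, ph)
    if mass <= 0:
        return AnomalyFeatures(name, np.nan, np.nan, np.nan, np.nan, defined=False)
    fn = f / mass
    mu = np.trapezoid(ph * fn, ph)
    m3 = np.trapezoid((ph - mu) ** 3 * fn, ph)
    m4 = np.trapezoid((ph - mu) ** 4 * fn, ph)

    def sse(pka):
        return float(((th - hh_curve(ph, pka)) ** 2).sum())

    res = minimize_scalar(sse, bounds=(ph[0] - 2.0, ph[-1] + 2.0), method="bounded")
    pka_fit = float(res.x)
    area = float(np.trapezoid(np.abs(th - hh_curve(ph, pka_fit)), ph))
    return AnomalyFeatures(name, float(m3), float(m4), area, pka_fit)


# ---------------------------------------------------------------------------
# coupling


def protonation_coupling(
    sites: Sequence[IonizableSite],
    W: np.ndarray,
    ph: float,
    method: str = "auto",
    n_samples: int = 400_000,
    burn_in: int = 1_000,
    seed: int = 1234,
    enumerate_limit: int = 20,
    coupled_threshold: float = 0.3,
) -> tuple[np.ndarray, list[tuple[str, str, float]]]:
    """Pearson correlation of protonation indicators across microstates at a
    fixed pH.

    Returns (corr matrix, list of coupled pairs with |r| >= threshold).
    Sites with no protonation variance at this pH get NaN rows/columns.
    """
    n = len(sites)
    K = _charge_kernel(sites, np.asarray(W, dtype=float))
    if method == "auto":
        method = "enumerate" if n <= enumerate_limit else "mc"

    if method == "enumerate":
        n_states = 1 << n
        states = ((np.arange(n_states)[:, None] >> np.arange(n)) & 1).astype(float)
        pka = np.array([s.pka for s in sites], dtype=float)
        charges = _state_charges(sites, states)
        e_pair = 0.5 * np.einsum("si,ij,sj->s", charges, K, charges)
        E = LN10_KT * (states.sum(axis=1) * ph - states @ pka) + e_pair
        E -= E.min()
        w = np.exp(-E / KT_KCAL)
        w /= w.sum()
        mean = w @ states
        cov = (states * w[:, None]).T @ states - np.outer(mean, mean)
    else:
        rng = np.random.default_rng(seed)
        mean, second = _mc_sample(
            sites, K, float(ph), n_samples, burn_in, rng, collect_pairs=True
        )
        cov = second - np.outer(mean, mean)

    var = np.diag(cov).copy()
    sd = np.sqrt(np.clip(var, 0.0, None))
    # theta within ~1e-9 of 0 or 1 counts as "no protonation variance"
    degenerate = var < 1e-9
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[np.outer(degenerate, np.ones(n, bool)) | np.outer(np.ones(n, bool), degenerate)] = np.nan
    np.fill_diagonal(corr, np.where(~degenerate, 1.0, np.nan))
    corr = np.where(np.isnan(corr), np.nan, np.clip(corr, -1.0, 1.0))

    coupled = []
    for i in range(n):
        for j in range(i + 1, n):
            r = corr[i, j]
            if np.isfinite(r) and abs(r) >= coupled_threshold:
                coupled.append((sites[i].name, sites[j].name, float(r)))
    return corr, coupled
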