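"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator emulates the statistical structure of one assay's raw data
so the whole analysis chain is testable without downloads:

* ``gen_structure`` — toy Cα + pseudo-side-chain geometry with a placed
  ligand and *known* first/second/third-layer membership under the default
  cutoffs, plus an ionizable-site layout for the titration model;
* ``gen_kinetics`` — Michaelis–Menten initial rates on the ornithine
  (0.05–48 mM) or carbamoyl phosphate (0.04–16 mM) concentration designs
  with multiplicative Gaussian noise (default CV 3%);
* ``gen_meltcurve`` — two-state melt sigmoids on the 4–100 °C, 0.2 °C grid
  with baselines and additive noise (melting points drawn from the 50–76 °C
  range typical of the OTC variant panel);
* ``gen_spectra`` — 300–400 nm emission spectra with a binding-induced
  Gaussian difference peak at 310 nm;
* ``gen_scattering`` — sphere / Gaussian (Guinier) / ideal-coil model
  curves or Debye curves from a structure, with optional noise;
* ``gen_trajectory`` — harmonic fluctuations about a reference with a
  chosen per-residue amplitude profile and an optional planted collective
  mode.

All generators are deterministic under a fixed seed and return a manifest
recording the generating truth.
"""

from __future__ import annotations

import numpy as np
import gemmi

from .structure import LigandMoiety, Structure, read_structure

__all__ = [
    "gen_structure",
    "gen_kinetics",
    "gen_meltcurve",
    "gen_spectra",
    "gen_scattering",
    "gen_trajectory",
    "ORN_DESIGN",
    "CP_DESIGN",
]

#: Substrate concentration designs (mM): 10 log-spaced points over the
#: assay ranges.
ORN_DESIGN = np.geomspace(0.05, 48.0, 10)
CP_DESIGN = np.geomspace(0.04, 16.0, 10)

_IONIZABLE_ATOM = {
    "ASP": "OD2", "GLU": "OE2", "HIS": "NE2", "CYS": "SG",
    "TYR": "OH", "LYS": "NZ", "ARG": "CZ",
}

# shell radii (Å) chosen so that, with perpendicular atom offsets, the min
# heavy-atom distance of a residue equals its radial placement minus the
# ligand cluster radius (0.35): layer 1 within the 4.0 Å contact cutoff,
# consecutive shells 4.2 Å apart (inside the 5.0 Å shell cutoff), and
# cross-shell skips beyond it.
_LAYER_RADII = {1: 3.8, 2: 8.0, 3: 12.2, None: 18.0}


def _ray_directions(n: int) -> np.ndarray:
    """n well-separated unit vectors (golden-angle spiral on the sphere)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _perpendiculars(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(u, a)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(u, t1)
    return t1, t2


def gen_structure(
    layer_plan: dict[int, int] | None = None,
    n_none: int = 2,
    ionizable: tuple[str, ...] = ("ASP", "HIS", "GLU", "LYS"),
    include_ligand: bool = True,
    contact_cutoff: float = 4.0,
    shell_cutoff: float = 5.0,
    chain: str = "A",
) -> tuple[str, dict]:
    """Toy structure with known layer ground truth.

    Returns (pdb_text, manifest). The manifest records the planned layer of
    every residue ({res_num: 1|2|3|None}), the ligand moiety atom names, and
    the ionizable-residue layout. The construction is validated against its
    own plan (feasibility) before emission.
    """
    layer_plan = dict(layer_plan or {1: 3, 2: 2, 3: 1})
    for lvl, cnt in layer_plan.items():
        if lvl not in (1, 2, 3) or cnt < 0:
            raise ValueError(f"bad layer plan entry {lvl}: {cnt}")
    if layer_plan.get(1, 0) == 0 and (layer_plan.get(2, 0) or layer_plan.get(3, 0)):
        raise ValueError("plan is infeasible: outer shells require a first layer")
    n_rays = max([*layer_plan.values(), 1])
    if layer_plan.get(2, 0) > layer_plan.get(1, 0) or \
       layer_plan.get(3, 0) > layer_plan.get(2, 0):
        raise ValueError(
            "plan is infeasible: each shell must be reachable from the previous one"
        )
    rays = _ray_directions(max(n_rays, 3))

    # residues in placement order: (layer, direction)
    placements: list[tuple[int | None, np.ndarray]] = []
    for lvl in (1, 2, 3):
        for i in range(layer_plan.get(lvl, 0)):
            placements.append((lvl, rays[i]))
    for i in range(n_none):
        placements.append((None, rays[i % len(rays)]))

    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain)

    truth_layers: dict[int, int | None] = {}
    site_rows = []
    ion_cycle = list(ionizable)
    n_ion = 0
    for idx, (lvl, u) in enumerate(placements, start=1):
        R = _LAYER_RADII[lvl]
        t1, t2 = _perpendiculars(u)
        ca = R * u
        res = gemmi.Residue()
        resname = "ALA"
        if ion_cycle and lvl is not None:
            resname = ion_cycle[n_ion % len(ion_cycle)]
            n_ion += 1
        res.name = resname
        res.seqid = gemmi.SeqId(idx, " ")
        res.het_flag = "A"
        atoms = [("N", "N", ca - 0.7 * t1), ("CA", "C", ca), ("C", "C", ca + 0.7 * t1),
                 ("CB", "C", ca + 1.2 * t2)]
        if resname in _IONIZABLE_ATOM:
            atoms.append((_IONIZABLE_ATOM[resname], "O" if resname in ("ASP", "GLU", "TYR") else "N",
                          ca + 1.9 * t2))
            site_rows.append({"res_num": idx, "res_name": resname, "layer": lvl})
        for name, el, pos in atoms:
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(el)
            at.pos = gemmi.Position(*pos)
            at.occ = 1.0
            res.add_atom(at)
        ch.add_residue(res)
        truth_layers[idx] = lvl

    if include_ligand:
        lig = gemmi.Residue()
        lig.name = "LIG"
        lig.seqid = gemmi.SeqId(900, " ")
        lig.het_flag = "H"
        for name, el, pos in (
            ("P1", "P", (0.35, 0.0, 0.0)),
            ("O1", "O", (-0.35, 0.0, 0.0)),
            ("N1", "N", (0.0, 0.35, 0.0)),
            ("C1", "C", (0.0, -0.35, 0.0)),
        ):
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(el)
            at.pos = gemmi.Position(*pos)
            at.occ = 1.0
            lig.add_atom(at)
        ch.add_residue(lig)

    model.add_chain(ch)
    st.add_model(model)
    pdb_text = st.make_pdb_string()

    manifest = {
        "layers": truth_layers,
        "contact_cutoff": contact_cutoff,
        "shell_cutoff": shell_cutoff,
        "ligand": {"res_name": "LIG", "CP-like": ["P1", "O1"], "ORN-like": ["N1", "C1"]}
        if include_ligand else None,
        "ionizable_sites": site_rows,
        "chain": chain,
    }

    # closed-loop feasibility check against the plan
    if include_ligand and layer_plan.get(1, 0) > 0:
        from .structure import assign_layers, first_layer

        s = read_structure(pdb_text)
        lig_m = LigandMoiety("whole-ligand", s.het_atoms())
        fl = first_layer(s, lig_m, contact_cutoff)
        assignment = assign_layers(s, fl, shell_cutoff)
        got = {rid[1]: lab for rid, lab in assignment.layers.items()}
        if got != truth_layers:
            raise RuntimeError(
                f"infeasible layer plan: constructed {got}, planned {truth_layers}"
            )
    return pdb_text, manifest


def ligand_moieties(structure: Structure, manifest: dict) -> list[LigandMoiety]:
    """CP-like and ORN-like moieties of a generated structure's ligand."""
    lig = manifest["ligand"]
    het = structure.het_atoms()
    out = []
    for label in ("CP-like", "ORN-like"):
        names = set(lig[label])
        out.append(LigandMoiety(label, [a for a in het if a.name in names]))
    return out


def gen_kinetics(
    km_mM: float = 0.53,
    kcat_s: float = 440.0,
    enzyme_nM: float = 20.0,
    design: np.ndarray | None = None,
    noise_cv: float = 0.03,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Initial rates v = kcat*[E]*S/(KM+S) with multiplicative Gaussian
    noise. Defaults are the wild-type ornithine truth on the ornithine
    design. Returns (S mM, v mM/s, manifest)."""
    if km_mM <= 0 or kcat_s <= 0 or enzyme_nM <= 0:
        raise ValueError("truth parameters must be positive")
    S = np.asarray(ORN_DESIGN if design is None else design, dtype=float)
    rng = np.random.default_rng(seed)
    e_mM = enzyme_nM * 1e-6
    v = kcat_s * e_mM * S / (km_mM + S)
    if noise_cv > 0:
        v = v * (1.0 + noise_cv * rng.standard_normal(S.shape))
    manifest = {"km_mM": km_mM, "kcat_s": kcat_s, "enzyme_nM": enzyme_nM,
                "noise_cv": noise_cv, "seed": seed}
    return S, v, manifest


def gen_meltcurve(
    tm_C: float = 68.0,
    width_C: float = 1.5,
    baseline: float = 100.0,
    amplitude: float = 1000.0,
    post_slope: float = 0.0,
    noise_sd: float = 0.0,
    t_min: float = 4.0,
    t_max: float = 100.0,
    t_step: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Two-state melt sigmoid RFU(T) with baselines and additive noise."""
    T = np.arange(t_min, t_max + 1e-9, t_step)
    if not (T[0] < tm_C < T[-1]):
        raise ValueError("Tm must lie inside the temperature grid")
    rfu = baseline + amplitude / (1.0 + np.exp(-(T - tm_C) / width_C)) + post_slope * (T - t_min)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rfu = rfu + noise_sd * rng.standard_normal(T.shape)
    return T, rfu, {"tm_C": tm_C, "width_C": width_C, "noise_sd": noise_sd, "seed": seed}


def gen_spectra(
    binding_amplitude: float = 0.1,
    binding_center: float = 310.0,
    binding_width: float = 4.0,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Emission SpectrumSet (300–400 nm) with a binding-induced difference
    peak. ``binding_amplitude`` is in apo-normalized units: after
    normalization by the apo maximum the difference spectrum peaks at that
    height. Returns (SpectrumSet, manifest)."""
    from .stability import SpectrumSet

    wl = np.arange(300.0, 400.0 + 1e-9, 1.0)
    rng = np.random.default_rng(seed)
    apo0 = 100.0 + 1000.0 * np.exp(-((wl - 335.0) ** 2) / (2 * 25.0**2))
    buffer0 = np.full_like(wl, 20.0)
    substrate0 = np.full_like(wl, 60.0)
    peak = binding_amplitude * apo0.max() * np.exp(
        -((wl - binding_center) ** 2) / (2 * binding_width**2)
    )
    mixture0 = apo0 + substrate0 - buffer0 + peak

    def reps(base):
        return base[None, :] + noise_sd * rng.standard_normal((n_replicates, wl.size))

    spectra = SpectrumSet(
        wavelength=wl, mixture=reps(mixture0), apo=reps(apo0),
        buffer=reps(buffer0), substrate=reps(substrate0),
    )
    manifest = {"binding_amplitude": binding_amplitude, "center_nm": binding_center,
                "width_nm": binding_width, "noise_sd": noise_sd, "seed": seed}
    return spectra, manifest


def gen_scattering(
    model: str = "sphere",
    radius: float = 40.0,
    rg: float = 33.3,
    i0: float = 1.0,
    q: np.ndarray | None = None,
    noise_cv: float = 0.0,
    structure: Structure | None = None,
    seed: int = 0,
):
    """Model scattering curve. models: 'sphere' (radius), 'gaussian'
    (Guinier with given Rg), 'coil' (ideal Debye chain with given Rg),
    'debye' (from a Structure). Returns (ScatteringCurve, manifest)."""
    from .saxs import ScatteringCurve, debye_profile

    if q is None:
        # detector-binned SEC-SAXS curves are finely sampled in q
        q = np.linspace(0.004, 0.45, 1000)
    q = np.asarray(q, dtype=float)
    rng = np.random.default_rng(seed)

    if model == "sphere":
        x = q * radius
        form = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
        I = i0 * form**2
        truth = {"model": model, "radius": radius, "rg": radius * np.sqrt(3.0 / 5.0)}
    elif model == "gaussian":
        I = i0 * np.exp(-(q**2) * rg**2 / 3.0)
        truth = {"model": model, "rg": rg}
    elif model == "coil":
        x2 = (q * rg) ** 2
        I = i0 * 2.0 * (np.exp(-x2) - 1.0 + x2) / x2**2
        truth = {"model": model, "rg": rg}
    elif model == "debye":
        if structure is None:
            raise ValueError("model 'debye' needs a structure")
        curve = debye_profile(structure, q)
        I = i0 * curve.intensity / curve.intensity[0]
        truth = {"model": model}
    else:
        raise ValueError(
            f"invalid model {model!r}; valid: sphere, gaussian, coil, debye"
        )
    sigma = None
    if noise_cv > 0:
        sigma = noise_cv * I
        I = I * (1.0 + noise_cv * rng.standard_normal(q.shape))
    truth.update({"i0": i0, "noise_cv": noise_cv, "seed": seed})
    return ScatteringCurve(q=q, intensity=I, sigma=sigma), truth


def gen_trajectory(
    n_sites: int = 60,
    n_frames: int = 400,
    amplitude_profile: np.ndarray | float = 0.5,
    mode: np.ndarray | None = None,
    mode_amplitude: float = 0.0,
    rigid_motion: bool = False,
    seed: int = 0,
):
    """Harmonic Cα fluctuations about a helical reference.

    ``amplitude_profile`` gives the target per-site RMSF (Å); a planted
    collective mode (unit 3N vector) with Gaussian amplitude
    ``mode_amplitude`` can be superimposed, and random rigid-body
    rotations/translations per frame are optional. Returns
    (Trajectory, manifest with the reference and truth).
    """
    from scipy.spatial.transform import Rotation

    from .trajectory import Trajectory

    rng = np.random.default_rng(seed)
    t = np.arange(n_sites)
    ref = np.stack(
        [2.3 * np.cos(t * 100 * np.pi / 180), 2.3 * np.sin(t * 100 * np.pi / 180), 1.5 * t],
        axis=1,
    )
    amp = np.broadcast_to(np.asarray(amplitude_profile, dtype=float), (n_sites,)).copy()
    sigma = amp / np.sqrt(3.0)
    frames = ref[None, :, :] + sigma[None, :, None] * rng.standard_normal(
        (n_frames, n_sites, 3)
    )
    planted = None
    if mode is not None and mode_amplitude > 0:
        m = np.asarray(mode, dtype=float).reshape(n_sites, 3)
        # project out rigid-body translations and infinitesimal rotations so
        # the planted mode is purely internal and survives superposition
        center = ref - ref.mean(axis=0)
        rigid = []
        for k in range(3):
            t = np.zeros((n_sites, 3))
            t[:, k] = 1.0
            rigid.append(t.ravel())
        for axis in np.eye(3):
            rigid.append(np.cross(center, axis).ravel())
        basis, _ = np.linalg.qr(np.stack(rigid, axis=1))
        mv = m.ravel()
        mv = mv - basis @ (basis.T @ mv)
        norm = np.linalg.norm(mv)
        if norm < 1e-9:
            raise ValueError("planted mode is purely rigid-body motion")
        mv /= norm
        planted = mv.copy()
        z = mode_amplitude * rng.standard_normal(n_frames)
        frames = frames + z[:, None, None] * mv.reshape(n_sites, 3)[None, :, :]
    if rigid_motion:
        for k in range(n_frames):
            R = Rotation.random(random_state=int(rng.integers(0, 2**31))).as_matrix()
            frames[k] = frames[k] @ R.T + 20.0 * rng.standard_normal(3)
    manifest = {
        "reference": ref,
        "rmsf_truth": amp,
        "mode": planted,
        "mode_amplitude": mode_amplitude,
        "seed": seed,
    }
    return Trajectory(frames, labels=[("A", i + 1) for i in range(n_sites)]), manifest
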