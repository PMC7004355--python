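"""Generate one example synthetic dataset per assay, with truth manifests.

Writes raw inputs (the same formats the CLI subcommands read) under
scratch/inputs/ and prints where each file went. Every downstream driver
regenerates its own inputs in memory; these files are a browsable sample.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from remotecat import simulate

OUT = Path(__file__).resolve().parents[1] / "scratch" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)


def save_manifest(name, manifest):
    clean = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in manifest.items()
    }
    (OUT / f"{name}.manifest.json").write_text(json.dumps(clean, indent=2, default=str))


pdb, manifest = simulate.gen_structure()
(OUT / "structure.pdb").write_text(pdb)
save_manifest("structure", manifest)

S, v, manifest = simulate.gen_kinetics(seed=1)
pd.DataFrame({"substrate_mM": S, "v0": v}).to_csv(OUT / "kinetics.tsv", sep="\t", index=False)
save_manifest("kinetics", manifest)

T, rfu, manifest = simulate.gen_meltcurve(tm_C=68.0, noise_sd=5.0, seed=1)
pd.DataFrame({"temperature_C": T, "rfu": rfu, "sample": "wt_apo"}).to_csv(
    OUT / "melt.tsv", sep="\t", index=False
)
save_manifest("melt", manifest)

spectra, manifest = simulate.gen_spectra(binding_amplitude=0.1, noise_sd=2.0, seed=1)
rows = []
for comp in ("mixture", "apo", "buffer", "substrate"):
    arr = getattr(spectra, comp)
    for rep in range(arr.shape[0]):
        rows.extend(
            {"wavelength_nm": wl, "intensity": inten, "component": comp, "replicate": rep}
            for wl, inten in zip(spectra.wavelength, arr[rep])
        )
pd.DataFrame(rows).to_csv(OUT / "spectra.tsv", sep="\t", index=False)
save_manifest("spectra", manifest)

curve, manifest = simulate.gen_scattering("sphere", radius=40.0, noise_cv=0.005, seed=1)
np.savetxt(OUT / "scattering.dat", np.column_stack([curve.q, curve.intensity, curve.sigma]))
save_manifest("scattering", manifest)

for f in sorted(OUT.iterdir()):
    print(f"wrote {f.relative_to(OUT.parents[1])}")
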