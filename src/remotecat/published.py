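"""Reference result tables for E. coli ornithine transcarbamoylase (OTC).

Small reported datasets for the OTC wild type and active-site variants,
shipped as package data and used as worked-example inputs and regression
anchors throughout the pipeline:

* ``pool_scores()`` — normalized catalytic-likelihood scores with shell
  layer labels and distances (Å) from the substrate for the top-ranked and
  control residues of the 333-residue OTC subunit.
* ``kinetics_table("CP"|"ORN")`` — steady-state Michaelis–Menten parameters
  (KM in mM, kcat in s^-1, kcat/KM in 10^4 M^-1 s^-1) per variant with
  wild-type-relative ratios.
* ``tm_table()`` — thermal-shift melting temperatures (°C) per variant in
  the apo state and with carbamoyl phosphate (CP), ornithine (ORN) or
  citrulline (CIT).

Residues previously established as catalytic for OTC and the subunit size
used for SAXS bead-model reconstruction are exposed as constants.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "pool_scores",
    "kinetics_table",
    "tm_table",
    "KNOWN_CATALYTIC",
    "SUBUNIT_RESIDUES",
    "trimer_bead_count",
]

#: Residues with prior experimental evidence of catalytic involvement.
KNOWN_CATALYTIC = frozenset(
    {"Arg57", "Arg106", "His133", "Gln136", "Asp231", "Cys273", "Arg319"}
)

#: Length of one OTC subunit; the enzyme is a homotrimer.
SUBUNIT_RESIDUES = 333


def trimer_bead_count(n_subunits: int = 3) -> int:
    """Residue (bead) count of the assembled construct used for envelope
    reconstruction: one bead per residue over all subunits."""
    return n_subunits * SUBUNIT_RESIDUES


def _load(name: str) -> pd.DataFrame:
    with resources.files("remotecat.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def pool_scores() -> pd.DataFrame:
    return _load("pool_scores.tsv")


def kinetics_table(substrate: str) -> pd.DataFrame:
    """Steady-state parameters per variant. substrate: 'CP' or 'ORN'."""
    key = substrate.strip().upper()
    if key not in ("CP", "ORN"):
        raise ValueError("substrate must be 'CP' or 'ORN'")
    return _load(f"kinetics_{key.lower()}.tsv")


def tm_table() -> pd.DataFrame:
    return _load("tm_values.tsv")
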