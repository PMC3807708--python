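"""Bundled reference datasets.

Small published experimental tables for the IFN-gamma / IFN-gamma receptor 1
(extracellular domain) system that the design pipeline was developed around:

* ``spr_affinities.csv`` — SPR kinetic constants (ka, kd), equilibrium Kd,
  replicate counts and esd for the wild-type receptor and its engineered
  variants binding single-chain IFN-gamma at 25 C.
* ``experimental_ddg.csv`` — the corresponding experimentally derived
  binding free-energy changes (kJ/mol) relative to wild type.

These are measurement tables consumed as pipeline *inputs* (e.g. for
additivity analysis and Kd -> ddG conversion); nothing in the package
recomputes the wet-lab values themselves.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .thermo import AffinityMeasurement, read_affinity_csv

__all__ = ["load_reference_affinities", "load_reference_ddg", "reference_affinity_path"]


def reference_affinity_path():
    return resources.files("mutbind") / "data" / "spr_affinities.csv"


def load_reference_affinities() -> list[AffinityMeasurement]:
    """SPR kinetics table for the IFN-gamma receptor variant panel (SI units)."""
    with resources.as_file(reference_affinity_path()) as path:
        return read_affinity_csv(path)


def load_reference_ddg() -> pd.DataFrame:
    """Experimental binding ddG (kJ/mol) per variant, with esd where replicated."""
    with resources.as_file(resources.files("mutbind") / "data" / "experimental_ddg.csv") as path:
        return pd.read_csv(path)
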