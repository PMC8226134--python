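"""Packaged reference inputs.

Small plain-text inputs for arithmetic-consistency checks: the
published free-energy decomposition and contact/water-environment
counts for the buffered lysozyme-polyanion systems (used as *inputs*
to normalisation and bookkeeping checks, never reproduced from
simulation at this scale), and the hen-egg-white lysozyme sequence.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_PKG = resources.files(__name__)


def _read(name: str, index_col: str) -> pd.DataFrame:
    with resources.as_file(_PKG / name) as p:
        return pd.read_csv(p, index_col=index_col)


def reference_free_energy_decomposition() -> pd.DataFrame:
    """Per-species dG/dH/TdS (kJ mol^-1) for the TPP and CIT systems."""
    return _read("reference_free_energy_decomposition.csv", "species")


def reference_contacts_separated() -> pd.DataFrame:
    """Species-species contact counts in the separated reference systems."""
    return _read("reference_contacts_separated.csv", "species")


def reference_water_environments() -> pd.DataFrame:
    """Water-environment counts (WP/WPP/WEP/WEPP) per system."""
    return _read("reference_water_environments.csv", "environment")


def lysozyme_sequence_path():
    """Path-like handle to the packaged lysozyme FASTA."""
    return _PKG / "hewl.fasta"
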