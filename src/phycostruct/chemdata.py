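"""Cached access to the shipped chemistry reference tables."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml


@lru_cache(maxsize=1)
def chemistry() -> dict:
    with resources.files("phycostruct._data").joinpath("chemistry.yaml").open() as fh:
        return yaml.safe_load(fh)


def vdw_radius(element: str, default: float | None = None) -> float:
    chem = chemistry()
    if default is None:
        default = chem["default_radius"]
    return chem["vdw_radii"].get(element.upper(), default)


def residue_volume(one_letter: str) -> float:
    return chemistry()["residue_volumes"][one_letter.upper()]


def apolar_atoms(resname: str) -> list[str]:
    return chemistry()["apolar_atoms"].get(resname.upper(), [])


def sequence_mass(sequence: str) -> float:
    """Average mass (Da) of a peptide chain: residue masses + one water."""
    chem = chemistry()
    masses = chem["residue_masses"]
    return sum(masses[aa.upper()] for aa in sequence if aa.isalpha()) + chem["water_mass"]


def ligand_mass(code: str) -> float:
    return chemistry()["ligand_masses"][code.upper()]
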