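"""Shared fixtures: synthetic structures, alignments and spectra.

Everything is generated programmatically with fixed seeds; nothing is read
from checked-in data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from phycostruct.assembly import build_assembly_map
from phycostruct.structure_io import extract_chromophores
from phycostruct.synthetic import (make_compensation_structure,
                                   make_tetrapyrrole, make_toy_assembly,
                                   table1_alignments)


@pytest.fixture(scope="session")
def toy_hexamer():
    """Six-monomer toy assembly with the frozen distance-table layout."""
    structure, manifest = make_toy_assembly(n_monomers=6, seed=11)
    return structure, manifest


@pytest.fixture(scope="session")
def toy_hexamer_chromophores(toy_hexamer):
    structure, _ = toy_hexamer
    return extract_chromophores(structure)


@pytest.fixture(scope="session")
def toy_hexamer_map(toy_hexamer, toy_hexamer_chromophores):
    structure, _ = toy_hexamer
    return build_assembly_map(structure, toy_hexamer_chromophores)


@pytest.fixture(scope="session")
def distorted_chromophore():
    """Single bilin with the distorted B-C ring-plane angle planted."""
    structure, manifest = make_tetrapyrrole(
        ring_angles={"AB": 15.0, "BC": 31.71, "CD": 25.0}, seed=7)
    (chrom,) = extract_chromophores(structure)
    return chrom, manifest


@pytest.fixture(scope="session")
def table1_fixture(tmp_path_factory):
    """Packaged substitution-table alignments written as FASTA files."""
    outdir = tmp_path_factory.mktemp("table1")
    produced = table1_alignments(seed=3, outdir=outdir)
    paths = {s: outdir / f"{s}.fasta" for s in produced}
    return paths, produced


@pytest.fixture(scope="session")
def compensation_fixture():
    return make_compensation_structure(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
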