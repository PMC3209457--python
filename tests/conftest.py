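from __future__ import annotations

import numpy as np
import pytest

from motifdyn.structio import Structure
from motifdyn.synthetic_data import ToySpec, make_structure
from motifdyn import enm


def format_pdb_atom(
    serial: int,
    name: str,
    res_name: str,
    chain: str,
    res_num: int,
    xyz,
    altloc: str = " ",
    icode: str = " ",
    element: str = "C",
) -> str:
    """Hand-format one ATOM record per the wwPDB v3.3 fixed columns."""
    x, y, z = xyz
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field}{altloc}{res_name:<3s} {chain}"
        f"{res_num:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def dimer_structure() -> Structure:
    return Structure(
        chain_ids=["A", "A"],
        residue_numbers=[1, 2],
        residue_names=["ALA", "ALA"],
        coords=[[0.0, 0.0, 0.0], [3.8, 0.0, 0.0]],
    )


@pytest.fixture
def dimer_model(dimer_structure) -> enm.ENMModel:
    return enm.build_hessian(dimer_structure, cutoff=13.0, gamma=1.0)


@pytest.fixture
def helix30() -> Structure:
    return make_structure(ToySpec(kind="helix", n_residues=30))


@pytest.fixture
def hlh40() -> Structure:
    return make_structure(ToySpec(kind="helix_loop_helix", n_residues=40))


@pytest.fixture
def cloud30() -> Structure:
    return make_structure(ToySpec(kind="cloud", n_residues=30, seed=7))
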