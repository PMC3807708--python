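"""Shared fixtures and independent oracles.

Oracles here are deliberately naive (all-pairs scans, power-set filters,
two-pass statistics, ODE integration) and never call the code paths they
check.
"""

from __future__ import annotations

import numpy as np
import pytest

from mutbind import structio as st
from mutbind import synthdata as sd


def brute_force_interface(s, receptor_chain, ligand_chains, cutoff):
    """Exhaustive all-pairs distance scan (O(N*M)); the detection oracle."""
    lig = np.vstack([
        r.heavy_coords()
        for c in sorted(ligand_chains)
        for r in s.chain(c)
        if not r.is_hetero
    ])
    hits = []
    for res in s.chain(receptor_chain):
        if res.is_hetero:
            continue
        xyz = res.heavy_coords()
        d2 = ((xyz[:, None, :] - lig[None, :, :]) ** 2).sum(axis=-1)
        if np.sqrt(d2.min()) <= cutoff:
            hits.append(res.key())
    return tuple(sorted(hits))


def pdb_atom_line(serial, name, resname, chain, resnum, x, y, z,
                  occ=1.0, altloc=" ", element="C", icode=" "):
    name_field = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:>5d} {name_field}{altloc}{resname:>3s} {chain}"
        f"{resnum:>4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def toy_complex():
    return sd.make_toy_complex(seed=1, n_receptor_res=60, n_ligand_res=30,
                               n_interface=12, contact_distance=4.5)


@pytest.fixture
def toy_pdb(tmp_path, toy_complex):
    structure, truth = toy_complex
    path = tmp_path / "toy.pdb"
    st.write_pdb(structure, path)
    return path, truth


def receptor_selection(structure, numbers, chain="R"):
    return st.ResidueSelection(
        structure_ref=structure.entry_id,
        residues=tuple((chain, n, "") for n in numbers),
    )


def random_rigid_transform(rng):
    """A proper rotation (det +1) and a translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=rng).as_matrix()
    tran = rng.uniform(-50, 50, 3)
    return rot, tran


def apply_rigid(structure, rot, tran):
    """Return a deep-copied structure with all coordinates transformed."""
    import copy

    out = copy.deepcopy(structure)
    for chain in out.chains.values():
        for res in chain:
            for atom in res.atoms:
                atom.coords = rot @ atom.coords + tran
    return out
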