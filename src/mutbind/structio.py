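"""Structure I/O, interface detection, superposition and ensemble fluctuations.

Reads receptor-ligand complex structures (PDB or mmCIF), identifies the
receptor residues forming the binding interface by an atom-atom distance
criterion, unions interfaces across crystallographically independent copies,
and computes least-squares superposition RMSDs and per-residue ensemble
fluctuations (RMSF).

Conventions
-----------
* Only model 1 of multi-model files is used.
* For alternate conformations the highest-occupancy conformer is kept
  (ties broken by altloc letter, ascending).
* Interface detection uses non-hydrogen atoms only and, by default, skips
  waters and other non-amino-acid heterogroups.
* The distance cutoff is inclusive: a residue at exactly the cutoff is in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import gemmi
import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "Residue",
    "Structure",
    "ResidueSelection",
    "SuperpositionResult",
    "parse_structure",
    "interface_residues",
    "union_selections",
    "superpose_rmsd",
    "random_control_selection",
    "ensemble_rmsf",
    "write_pdb",
    "selection_to_tsv",
    "selection_from_tsv",
]

MAIN_CHAIN_ATOMS = ("N", "CA", "C", "O")

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass
class AtomRecord:
    """A single atom: name, element, altloc, occupancy and coordinates (A)."""

    serial: int
    name: str
    element: str
    altloc: str
    occupancy: float
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """One residue identified by (chain_id, number, insertion_code)."""

    chain_id: str
    number: int
    insertion_code: str
    name: str
    atoms: list[AtomRecord]
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.key()} has no atoms")

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_amino_acid(self) -> bool:
        return self.name in STANDARD_AA

    def heavy_coords(self) -> np.ndarray:
        xyz = [a.coords for a in self.atoms if not a.is_hydrogen]
        return np.array(xyz) if xyz else np.empty((0, 3))


@dataclass
class Structure:
    """Model 1 of a parsed entry: chains mapped to ordered residue lists."""

    entry_id: str
    model_index: int
    chains: dict[str, list[Residue]]

    def __post_init__(self) -> None:
        if self.model_index < 1:
            raise ValueError("model_index must be >= 1")

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise KeyError(
                f"chain {chain_id!r} not in structure {self.entry_id!r} "
                f"(has {sorted(self.chains)})"
            ) from None

    def residue(self, chain_id: str, number: int, icode: str = "") -> Residue:
        for r in self.chain(chain_id):
            if r.number == number and r.insertion_code == icode:
                return r
        raise KeyError(f"residue {chain_id}/{number}{icode} not found")


@dataclass
class ResidueSelection:
    """An ordered, duplicate-free set of residue identities on named chains.

    Residues are ``(chain_id, number, insertion_code)`` triples kept in
    deterministic (chain, number, icode) ascending order.
    """

    structure_ref: str
    residues: tuple[tuple[str, int, str], ...]
    label: str = ""

    def __post_init__(self) -> None:
        ordered = tuple(sorted(set(self.residues)))
        if len(ordered) != len(self.residues):
            raise ValueError("duplicate residues in selection")
        self.residues = ordered

    def __len__(self) -> int:
        return len(self.residues)

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        return key in set(self.residues)

    def numbers(self) -> tuple[tuple[int, str], ...]:
        """Residue identities with the chain stripped (number, icode)."""
        return tuple(sorted({(n, ic) for _, n, ic in self.residues}))


@dataclass
class SuperpositionResult:
    """Optimal rigid-body superposition: rotation, translation and RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        det = float(np.linalg.det(self.rotation))
        if abs(det - 1.0) > 1e-6:
            raise ValueError(f"rotation determinant {det} != +1")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")

    def to_json(self) -> str:
        return json.dumps(
            {
                "rotation": [list(map(float, row)) for row in self.rotation],
                "translation": [float(x) for x in self.translation],
                "rmsd": float(self.rmsd),
                "n_atoms": int(self.n_atoms),
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# Parsing


def parse_structure(path, fmt: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure` (model 1 only).

    Alternate locations are collapsed to the highest-occupancy conformer;
    ties are broken by altloc letter. Hydrogens are retained (they are
    flagged and skipped by the distance criteria downstream).
    """
    path = str(path)
    if fmt == "auto":
        st = gemmi.read_structure(path)
    elif fmt == "pdb":
        st = gemmi.read_pdb(path)
    elif fmt == "mmcif":
        st = gemmi.make_structure_from_block(gemmi.cif.read(path)[0])
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if len(st) == 0 or len(st[0]) == 0:
        raise ValueError(f"{path}: no chains in model 1")

    model = st[0]
    chains: dict[str, list[Residue]] = {}
    serial = 0
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            # collapse altlocs: keep highest occupancy, tie -> altloc letter
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if (
                    prev is None
                    or atom.occ > prev.occ
                    or (atom.occ == prev.occ and (atom.altloc or "~") < (prev.altloc or "~"))
                ):
                    best[atom.name] = atom
            atoms = []
            for atom in best.values():
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=atom.name,
                        element=atom.element.name,
                        altloc=atom.altloc or "",
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    )
                )
            if not atoms:
                continue
            residues.append(
                Residue(
                    chain_id=chain.name,
                    number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    name=res.name,
                    atoms=atoms,
                    is_hetero=res.name not in STANDARD_AA,
                )
            )
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise ValueError(f"{path}: structure has zero non-empty chains")
    return Structure(entry_id=st.name or path, model_index=1, chains=chains)


def write_pdb(s: Structure, path) -> None:
    """Write a minimal, valid single-model PDB file."""
    lines = []
    serial = 0
    for chain_id in s.chains:
        for res in s.chains[chain_id]:
            for a in res.atoms:
                serial += 1
                record = "HETATM" if res.is_hetero else "ATOM  "
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                x, y, z = a.coords
                lines.append(
                    f"{record}{serial:>5d} {name}{'':1s}{res.name:>3s} "
                    f"{chain_id[:1]}{res.number:>4d}{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Interface detection


def interface_residues(
    s: Structure,
    receptor_chain: str,
    ligand_chains,
    cutoff: float = 6.0,
    include_hetero: bool = False,
) -> ResidueSelection:
    """Receptor residues with any non-hydrogen atom within ``cutoff`` A of
    any non-hydrogen ligand-chain atom (boundary inclusive).

    Waters and other non-amino-acid groups are skipped unless
    ``include_hetero`` is set.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ligand_chains = set(ligand_chains)
    receptor = s.chain(receptor_chain)
    lig_xyz = []
    for cid in sorted(ligand_chains):
        for res in s.chain(cid):
            if res.is_hetero and not include_hetero:
                continue
            lig_xyz.append(res.heavy_coords())
    lig_xyz = [x for x in lig_xyz if len(x)]
    if not lig_xyz:
        return ResidueSelection(structure_ref=s.entry_id, residues=(), label="interface")
    tree = cKDTree(np.vstack(lig_xyz))

    hits = []
    for res in receptor:
        if res.is_hetero and not include_hetero:
            continue
        xyz = res.heavy_coords()
        if not len(xyz):
            continue
        dmin, _ = tree.query(xyz, k=1)
        if float(np.min(dmin)) <= cutoff:
            hits.append(res.key())
    return ResidueSelection(
        structure_ref=s.entry_id,
        residues=tuple(hits),
        label=f"interface<= {cutoff:g}A vs {','.join(sorted(ligand_chains))}",
    )


def union_selections(
    selections,
    chain_id: str | None = None,
    offsets=None,
    label: str = "union",
) -> ResidueSelection:
    """Union residue selections mapped onto a common numbering.

    The selections typically come from crystallographically independent
    copies of the same chain, so residues are equivalenced by
    ``(number, insertion_code)``; ``offsets`` (one per selection) optionally
    shift each selection onto the reference numbering first. The result is
    reported on ``chain_id`` (default: the first selection's chain).
    """
    selections = list(selections)
    if not selections:
        raise ValueError("no selections to union")
    if offsets is None:
        offsets = [0] * len(selections)
    if len(offsets) != len(selections):
        raise ValueError(
            f"numbering maps incompatible: {len(offsets)} offsets for {len(selections)} selections"
        )
    if chain_id is None:
        chain_id = next(
            (sel.residues[0][0] for sel in selections if sel.residues), "A"
        )
    merged = set()
    for sel, off in zip(selections, offsets):
        for _, num, icode in sel.residues:
            merged.add((chain_id, num + off, icode))
    return ResidueSelection(
        structure_ref=selections[0].structure_ref,
        residues=tuple(sorted(merged)),
        label=label,
    )


# ---------------------------------------------------------------------------
# Superposition


def _paired_coords(
    mobile: Structure,
    mobile_sel: ResidueSelection,
    target: Structure,
    target_sel: ResidueSelection,
    atom_names,
) -> tuple[np.ndarray, np.ndarray]:
    mob_keys = mobile_sel.numbers()
    tgt_keys = target_sel.numbers()
    if mob_keys != tgt_keys:
        raise ValueError(
            "selections do not pair 1:1 by residue number/insertion code"
        )
    mob_chain = mobile_sel.residues[0][0]
    tgt_chain = target_sel.residues[0][0]
    mob_xyz, tgt_xyz = [], []
    for num, icode in mob_keys:
        rm = mobile.residue(mob_chain, num, icode)
        rt = target.residue(tgt_chain, num, icode)
        for name in atom_names:
            am, at = rm.atom(name), rt.atom(name)
            if am is None or at is None:
                raise ValueError(
                    f"residue {num}{icode}: atom {name!r} missing in one structure"
                )
            mob_xyz.append(am.coords)
            tgt_xyz.append(at.coords)
    return np.array(mob_xyz), np.array(tgt_xyz)


def superpose_rmsd(
    mobile: Structure,
    mobile_sel: ResidueSelection,
    target: Structure,
    target_sel: ResidueSelection,
    atom_names=MAIN_CHAIN_ATOMS,
    fit_on_same_atoms: bool = True,
) -> SuperpositionResult:
    """Least-squares rigid superposition of paired residues and the RMSD of
    the selected atoms after the fit.

    With ``fit_on_same_atoms`` (default) the rotation is optimised on the
    very atoms the RMSD is evaluated on. Otherwise the fit uses the
    main-chain atoms of all residues common to both structures (paired by
    number/insertion code on the selections' chains) and only the RMSD is
    restricted to the selection — a sensitivity-check mode.
    """
    atom_names = tuple(atom_names)
    eval_mob, eval_tgt = _paired_coords(mobile, mobile_sel, target, target_sel, atom_names)
    if len(eval_mob) < 3:
        raise ValueError(f"need >= 3 paired atoms, got {len(eval_mob)}")

    if fit_on_same_atoms:
        fit_mob, fit_tgt = eval_mob, eval_tgt
    else:
        mob_chain = mobile_sel.residues[0][0]
        tgt_chain = target_sel.residues[0][0]
        mob_ids = {(r.number, r.insertion_code) for r in mobile.chain(mob_chain)}
        tgt_ids = {(r.number, r.insertion_code) for r in target.chain(tgt_chain)}
        common = sorted(mob_ids & tgt_ids)
        fm, ft = [], []
        for num, icode in common:
            rm = mobile.residue(mob_chain, num, icode)
            rt = target.residue(tgt_chain, num, icode)
            for name in atom_names:
                am, at = rm.atom(name), rt.atom(name)
                if am is not None and at is not None:
                    fm.append(am.coords)
                    ft.append(at.coords)
        fit_mob, fit_tgt = np.array(fm), np.array(ft)
        if len(fit_mob) < 3:
            raise ValueError("fewer than 3 common atoms for the whole-chain fit")

    sup = SVDSuperimposer()
    sup.set(fit_tgt, fit_mob)  # reference, coords-to-move
    sup.run()
    rot, tran = sup.get_rotran()
    moved = eval_mob @ rot + tran
    rmsd = float(np.sqrt(np.mean(np.sum((moved - eval_tgt) ** 2, axis=1))))
    # SVDSuperimposer applies x @ rot + tran; expose the row-major matrix R
    # such that R @ x + t is the same map.
    return SuperpositionResult(
        rotation=rot.T, translation=tran, rmsd=rmsd, n_atoms=len(eval_mob)
    )


def random_control_selection(
    s: Structure,
    exclude: ResidueSelection,
    n: int,
    seed: int,
    chain_id: str | None = None,
) -> ResidueSelection:
    """Uniform sample (without replacement) of ``n`` amino-acid residues
    outside ``exclude`` — the control set for interface-vs-random
    comparisons. Reproducible for a fixed seed.
    """
    excluded = set(exclude.residues)
    pool = []
    chains = [chain_id] if chain_id else sorted(s.chains)
    for cid in chains:
        for res in s.chain(cid):
            if res.is_amino_acid and res.key() not in excluded:
                pool.append(res.key())
    if n > len(pool):
        raise ValueError(f"requested {n} residues but only {len(pool)} eligible")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return ResidueSelection(
        structure_ref=s.entry_id,
        residues=tuple(pool[i] for i in idx),
        label=f"random-control(n={n}, seed={seed})",
    )


# ---------------------------------------------------------------------------
# Ensemble fluctuations


def ensemble_rmsf(frames, selection: ResidueSelection) -> dict[tuple[str, int, str], float]:
    """Per-residue RMSF about the ensemble mean position.

    ``frames`` are Structures with identical residue/atom layout (e.g. MD
    snapshots). For each selected residue the fluctuation is computed per
    atom about its mean position across frames and averaged over the
    residue's atoms.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    out: dict[tuple[str, int, str], float] = {}
    for chain_id, num, icode in selection.residues:
        per_frame = []
        for fr in frames:
            res = fr.residue(chain_id, num, icode)
            per_frame.append(np.array([a.coords for a in res.atoms]))
        n_atoms = {len(x) for x in per_frame}
        if len(n_atoms) != 1:
            raise ValueError(
                f"residue {chain_id}/{num}{icode}: atom count differs across frames"
            )
        stack = np.stack(per_frame)            # (n_frames, n_atoms, 3)
        mean = stack.mean(axis=0)
        sq = np.sum((stack - mean) ** 2, axis=2)  # (n_frames, n_atoms)
        rmsf_per_atom = np.sqrt(sq.mean(axis=0))
        out[(chain_id, num, icode)] = float(rmsf_per_atom.mean())
    return out


# ---------------------------------------------------------------------------
# Serialization


def selection_to_tsv(sel: ResidueSelection, path, structure: Structure | None = None) -> None:
    """Write a selection as TSV: chain, resnum, icode, resname, label."""
    with open(path, "w") as fh:
        fh.write("chain\tresnum\ticode\tresname\tlabel\n")
        for chain_id, num, icode in sel.residues:
            name = ""
            if structure is not None:
                try:
                    name = structure.residue(chain_id, num, icode).name
                except KeyError:
                    pass
            fh.write(f"{chain_id}\t{num}\t{icode or '.'}\t{name or '.'}\t{sel.label}\n")


def selection_from_tsv(path) -> ResidueSelection:
    residues = []
    label = ""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chain\t"):
            raise ValueError(f"{path}: not a selection TSV")
        for line in fh:
            chain, num, icode, _name, label = line.rstrip("\n").split("\t")
            residues.append((chain, int(num), "" if icode == "." else icode))
    return ResidueSelection(structure_ref=str(path), residues=tuple(residues), label=label)
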