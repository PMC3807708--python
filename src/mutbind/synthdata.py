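"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of (seed, parameters) and returns its
planted truth alongside the data, so interface detection, conservation
filtering, candidate selection, SPR fitting and Tm estimation can all be
validated by recovery of known answers without any external data.

The toy complex uses an idealized backbone (3.8 A CA spacing, fixed
main-chain offsets, no side chains): enough geometry for distance and
superposition logic, with a planted interface at an exact contact distance
and a guard band (> 8 A) around every non-interface residue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .conservation import Alignment
from .meltcurve import MeltCurve
from .mutscan import AA_CODES, DdgMatrix, Mutation
from .sprkin import KineticParams, Sensorgram, simulate_sensorgram
from .structio import AtomRecord, Residue, Structure

__all__ = [
    "GroundTruth",
    "child_seed",
    "make_toy_complex",
    "make_msa",
    "make_ddg_matrix",
    "make_sensorgram_set",
    "make_melt_curve",
]

# fixed fan-out offsets so each generator's child seed is documented
SEED_OFFSETS = {
    "complex": 1,
    "msa": 2,
    "ddg": 3,
    "sensorgram": 4,
    "melt": 5,
}


def child_seed(master_seed: int, offset: int) -> int:
    """Derive a per-generator child seed from one master seed."""
    return (master_seed * 100_003 + offset) % (2**31)


@dataclass
class GroundTruth:
    """Planted truth serialized alongside every generated dataset."""

    kind: str
    master_seed: int
    params: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {
                "kind": self.kind,
                "master_seed": self.master_seed,
                "params": self.params,
                "truth": self.truth,
            },
            indent=2,
            default=str,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# Toy receptor-ligand complex

_BACKBONE_OFFSETS = {            # relative to CA, in the chain (x) and z axes
    "N": np.array([-0.7, 0.0, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([0.7, 0.0, 0.0]),
    "O": np.array([1.0, 0.0, 0.6]),
}
_CA_SPACING = 3.8   # A
_LIGAND_PLANE = 9.0  # A above the receptor trace; guard band > 8 A

_RESIDUE_NAMES = (
    "ALA", "ARG", "ASN", "ASP", "GLN", "GLU", "GLY", "HIS", "LEU", "LYS",
    "MET", "PHE", "SER", "THR", "TRP", "TYR", "VAL",
)


def _backbone_residue(chain_id, number, name, ca_xyz, serial0):
    atoms = []
    for i, (atom_name, off) in enumerate(_BACKBONE_OFFSETS.items()):
        atoms.append(
            AtomRecord(
                serial=serial0 + i,
                name=atom_name,
                element=atom_name[0],
                altloc="",
                occupancy=1.0,
                coords=np.asarray(ca_xyz) + off,
            )
        )
    return Residue(chain_id=chain_id, number=number, insertion_code="", name=name, atoms=atoms)


def make_toy_complex(
    seed: int,
    n_receptor_res: int = 60,
    n_ligand_res: int = 30,
    n_interface: int = 12,
    contact_distance: float = 4.5,
    interface_indices=None,
) -> tuple[Structure, GroundTruth]:
    """A two-chain complex with exactly ``n_interface`` planted interface
    residues on the receptor chain R.

    The receptor is a straight backbone trace; planted residues are lifted
    toward a ligand atom placed ``contact_distance`` A above them, while
    every other receptor atom stays > 8 A from all ligand atoms. At any
    cutoff in (contact_distance, 8) interface detection must return exactly
    the planted set. ``interface_indices`` (0-based residue indices)
    overrides the random choice — used to build multi-complex bundles with a
    prescribed union.
    """
    if not 0 < contact_distance < 6.0:
        raise ValueError("contact_distance must be in (0, 6.0)")
    if n_interface > n_receptor_res:
        raise ValueError("more interface residues than receptor residues")
    if n_interface > n_ligand_res:
        raise ValueError(
            f"infeasible geometry: {n_interface} contacts need {n_interface} ligand "
            f"residues, have {n_ligand_res}"
        )
    rng = np.random.default_rng(seed)
    if interface_indices is None:
        interface_indices = sorted(
            rng.choice(n_receptor_res, size=n_interface, replace=False).tolist()
        )
    else:
        interface_indices = sorted(int(i) for i in interface_indices)
        if len(interface_indices) != n_interface:
            raise ValueError("interface_indices length != n_interface")
        if interface_indices and not (0 <= interface_indices[0] and interface_indices[-1] < n_receptor_res):
            raise ValueError("interface_indices out of range")
    planted = set(interface_indices)

    receptor, serial = [], 1
    lift = _LIGAND_PLANE - contact_distance
    for i in range(n_receptor_res):
        y = lift if i in planted else 0.0
        ca = np.array([_CA_SPACING * i, y, 0.0])
        name = _RESIDUE_NAMES[int(rng.integers(len(_RESIDUE_NAMES)))]
        receptor.append(_backbone_residue("R", i + 1, name, ca, serial))
        serial += 4

    ligand = []
    x_far = _CA_SPACING * n_receptor_res + 10.0
    contact_x = [_CA_SPACING * i for i in interface_indices]
    for j in range(n_ligand_res):
        if j < len(contact_x):
            ca = np.array([contact_x[j], _LIGAND_PLANE, 0.0])
        else:
            ca = np.array([x_far + _CA_SPACING * j, _LIGAND_PLANE, 0.0])
        ligand.append(
            Residue(
                chain_id="L",
                number=j + 1,
                insertion_code="",
                name="GLY",
                atoms=[
                    AtomRecord(
                        serial=serial,
                        name="CA",
                        element="C",
                        altloc="",
                        occupancy=1.0,
                        coords=ca,
                    )
                ],
            )
        )
        serial += 1

    structure = Structure(
        entry_id=f"TOY{seed}",
        model_index=1,
        chains={"R": receptor, "L": ligand},
    )
    truth = GroundTruth(
        kind="toy_complex",
        master_seed=seed,
        params={
            "n_receptor_res": n_receptor_res,
            "n_ligand_res": n_ligand_res,
            "n_interface": n_interface,
            "contact_distance": contact_distance,
        },
        truth={"interface_residue_numbers": [i + 1 for i in interface_indices]},
    )
    return structure, truth


# ---------------------------------------------------------------------------
# Multiple sequence alignment


def make_msa(
    seed: int,
    ref_sequence: str,
    n_seq: int = 32,
    per_position_identity=None,
    reference_id: str = "REF",
) -> tuple[Alignment, GroundTruth]:
    """An alignment in which column j matches the reference in a planted
    fraction of the ``n_seq`` sequences.

    The match count is ``round(identity * n_seq)``, clamped to [1, n_seq]
    (the reference always matches itself), so the realized fraction is the
    planted one up to that deterministic rounding.
    """
    ref_sequence = ref_sequence.upper()
    if per_position_identity is None:
        per_position_identity = [1.0] * len(ref_sequence)
    if len(per_position_identity) != len(ref_sequence):
        raise ValueError("per_position_identity length != reference length")
    rng = np.random.default_rng(seed)
    others = sorted(AA_CODES)
    n_cols = len(ref_sequence)
    seqs = np.empty((n_seq, n_cols), dtype="<U1")
    realized = []
    for j, (ref_res, identity) in enumerate(zip(ref_sequence, per_position_identity)):
        k = int(round(identity * n_seq))
        k = min(max(k, 1), n_seq)
        matching = {0}
        if k > 1:
            matching |= set(1 + rng.choice(n_seq - 1, size=k - 1, replace=False))
        alternatives = [aa for aa in others if aa != ref_res]
        for i in range(n_seq):
            if i in matching:
                seqs[i, j] = ref_res
            else:
                seqs[i, j] = alternatives[int(rng.integers(len(alternatives)))]
        realized.append(k / n_seq)
    records = [(reference_id, ref_sequence)]
    for i in range(1, n_seq):
        records.append((f"seq{i:03d}", "".join(seqs[i])))
    truth = GroundTruth(
        kind="msa",
        master_seed=seed,
        params={"n_seq": n_seq, "reference_id": reference_id},
        truth={
            "planted_identity": list(per_position_identity),
            "realized_fraction": realized,
        },
    )
    return Alignment(records=records), truth


def write_fasta(a: Alignment, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in a.records:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# ddG matrices


def make_ddg_matrix(
    seed: int,
    positions: dict[int, str],
    n_interfaces: int = 4,
    planted_stabilizing=(),
    planted_destabilizing=(),
    noise_sd: float = 1.0,
    background_per_position: int = 2,
) -> tuple[DdgMatrix, GroundTruth]:
    """A per-interface ddG matrix with planted favorable/unfavorable
    mutations.

    Planted stabilizing mutations are negative on both energy types on every
    interface with margin >= 3 * noise_sd; planted destabilizing ones have
    positive affinity but negative stability everywhere. Background
    mutations take sign-unconstrained draws, except that each is forced to
    have at least one unfavorable-affinity interface so that exactly the
    planted stabilizing set qualifies under the all-interface criterion.
    """
    rng = np.random.default_rng(seed)
    interfaces = tuple(f"iface{i + 1}" for i in range(n_interfaces))
    planted_stabilizing = [
        m if isinstance(m, Mutation) else Mutation.parse(m) for m in planted_stabilizing
    ]
    planted_destabilizing = [
        m if isinstance(m, Mutation) else Mutation.parse(m) for m in planted_destabilizing
    ]
    planted = set(planted_stabilizing) | set(planted_destabilizing)
    margin = 3.0 * noise_sd + 0.5

    entries: dict[tuple[Mutation, str, str], float] = {}

    def fill(mut, sign_affinity, sign_stability):
        for iface in interfaces:
            entries[(mut, iface, "affinity")] = sign_affinity * (
                margin + abs(rng.normal(0.0, noise_sd))
            )
            entries[(mut, iface, "stability")] = sign_stability * (
                margin + abs(rng.normal(0.0, noise_sd))
            )

    for mut in planted_stabilizing:
        fill(mut, -1.0, -1.0)
    for mut in planted_destabilizing:
        fill(mut, +1.0, -1.0)

    alternatives = sorted(AA_CODES)
    for pos, wt in sorted(positions.items()):
        choices = [aa for aa in alternatives if aa != wt]
        picked = rng.choice(len(choices), size=min(background_per_position, len(choices)),
                            replace=False)
        for idx in picked:
            mut = Mutation(position=pos, wt=wt, mut=choices[int(idx)])
            if mut in planted or (mut, interfaces[0], "affinity") in entries:
                continue
            for iface in interfaces:
                entries[(mut, iface, "affinity")] = float(rng.normal(0.0, 4.0))
                entries[(mut, iface, "stability")] = float(rng.normal(0.0, 4.0))
            # guarantee at least one unfavorable-affinity interface
            spoil = interfaces[int(rng.integers(n_interfaces))]
            entries[(mut, spoil, "affinity")] = abs(entries[(mut, spoil, "affinity")]) + 0.5

    matrix = DdgMatrix(entries=entries, interface_ids=interfaces)
    truth = GroundTruth(
        kind="ddg_matrix",
        master_seed=seed,
        params={"n_interfaces": n_interfaces, "noise_sd": noise_sd},
        truth={
            "planted_stabilizing": [str(m) for m in planted_stabilizing],
            "planted_destabilizing": [str(m) for m in planted_destabilizing],
        },
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Sensorgrams

DEFAULT_CONCENTRATIONS = (99e-9, 33e-9, 11e-9, 3.7e-9, 1.2e-9)  # 3-fold series


def make_sensorgram_set(
    seed: int,
    p: KineticParams,
    concentrations=DEFAULT_CONCENTRATIONS,
    noise_sd: float = 0.0,
    t_assoc: float = 90.0,
    t_dissoc: float = 600.0,
    dt: float = 0.1,
    emit_reference: bool = True,
) -> tuple[list[Sensorgram], GroundTruth]:
    """One active curve per analyte concentration, plus drift-only reference
    and blank interspot channels when ``emit_reference`` is set."""
    out: list[Sensorgram] = []
    for i, conc in enumerate(concentrations):
        out.append(
            simulate_sensorgram(
                p, conc, t_assoc=t_assoc, t_dissoc=t_dissoc, dt=dt,
                noise_sd=noise_sd, seed=child_seed(seed, 10 + i), channel="active",
            )
        )
    if emit_reference and concentrations:
        t = out[0].time
        rng_ref = np.random.default_rng(child_seed(seed, 97))
        rng_spot = np.random.default_rng(child_seed(seed, 98))
        ref = p.drift * t + (rng_ref.normal(0, noise_sd, t.shape) if noise_sd > 0 else 0.0)
        spot = np.zeros_like(t) + (rng_spot.normal(0, noise_sd, t.shape) if noise_sd > 0 else 0.0)
        phase = out[0].phase
        out.append(Sensorgram(time=t, response=ref, phase=phase,
                              analyte_concentration=0.0, channel="reference"))
        out.append(Sensorgram(time=t, response=spot, phase=phase,
                              analyte_concentration=0.0, channel="interspot"))
    truth = GroundTruth(
        kind="sensorgram_set",
        master_seed=seed,
        params={
            "concentrations_M": list(concentrations),
            "noise_sd_RU": noise_sd,
            "t_assoc_s": t_assoc,
            "t_dissoc_s": t_dissoc,
            "dt_s": dt,
        },
        truth={
            "ka_per_M_s": p.ka,
            "kd_per_s": p.kd_rate,
            "Rmax_RU": p.Rmax,
            "drift_RU_s": p.drift,
            "Kd_M": p.Kd,
        },
    )
    return out, truth


# ---------------------------------------------------------------------------
# Melt curves


def make_melt_curve(
    seed: int,
    tm: float = 55.0,
    slope: float = 1.5,
    baselines: tuple[float, float] = (0.0, 0.0),
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    t_min: float = 20.0,
    t_max: float = 75.0,
    dt: float = 0.5,
    label: str = "",
) -> tuple[MeltCurve, GroundTruth]:
    """Two-state melt curve f(T) = b0 + b1 T + A / (1 + exp((tm - T)/slope))
    on the standard thermal-shift grid (20-75 C, 0.5 C steps by default)."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    temperature = np.arange(t_min, t_max + dt / 2, dt)
    b0, b1 = baselines
    signal = b0 + b1 * temperature + amplitude / (1.0 + np.exp((tm - temperature) / slope))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, temperature.shape)
    truth = GroundTruth(
        kind="melt_curve",
        master_seed=seed,
        params={
            "slope_C": slope,
            "baselines": list(baselines),
            "amplitude": amplitude,
            "noise_sd": noise_sd,
            "grid": [t_min, t_max, dt],
        },
        truth={"tm_C": tm},
    )
    return MeltCurve(temperature=temperature, fluorescence=signal, label=label), truth
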