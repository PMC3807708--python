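"""Mutational-scan bookkeeping, candidate selection and multi-mutant design.

Holds per-interface ddG matrices produced by an external empirical-force-field
scan (two energy types per mutation: *stability* of the mutated complex and
*affinity* of the receptor-ligand interaction, both in kJ/mol, negative =
favorable), averages them over structural-snapshot ensembles, applies the
selection criteria (favorable on all crystallographic interfaces, position
not conserved), and combines compatible single mutations into double/triple
mutants subject to sequence- and space-separation rules.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conservation import ConservationProfile, NumberingMap
from .structio import Structure

__all__ = [
    "Mutation",
    "MultiMutation",
    "DdgMatrix",
    "SelectionCriteria",
    "CandidateReport",
    "load_ddg_tsv",
    "write_ddg_tsv",
    "ensemble_average",
    "summarize_best_worst",
    "select_candidates",
    "design_combinations",
]

AA_CODES = set("ACDEFGHIKLMNPQRSTVWY")
ENERGY_TYPES = ("stability", "affinity")
KCAL_TO_KJ = 4.184


@dataclass(frozen=True, order=True)
class Mutation:
    """A point substitution in reference numbering, e.g. N96W."""

    position: int
    wt: str
    mut: str

    def __post_init__(self) -> None:
        if self.wt not in AA_CODES or self.mut not in AA_CODES:
            raise ValueError(f"invalid amino-acid code in {self.wt}{self.position}{self.mut}")
        if self.wt == self.mut:
            raise ValueError(f"{self.wt}{self.position}{self.mut}: wt == mut")

    def __str__(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"

    @classmethod
    def parse(cls, text: str) -> "Mutation":
        text = text.strip()
        return cls(wt=text[0], position=int(text[1:-1]), mut=text[-1])


@dataclass(frozen=True)
class MultiMutation:
    mutations: frozenset[Mutation]

    def __post_init__(self) -> None:
        positions = [m.position for m in self.mutations]
        if len(set(positions)) != len(positions):
            raise ValueError("multi-mutation touches one position twice")
        if len(self.mutations) < 2:
            raise ValueError("multi-mutation needs >= 2 mutations")

    def __str__(self) -> str:
        return ";".join(str(m) for m in sorted(self.mutations))

    @classmethod
    def parse(cls, text: str) -> "MultiMutation":
        parts = [p for p in text.replace("+", ";").split(";") if p.strip()]
        return cls(frozenset(Mutation.parse(p) for p in parts))


@dataclass
class DdgMatrix:
    """(mutation, interface, energy type) -> ddG in kJ/mol."""

    entries: dict[tuple[Mutation, str, str], float]
    interface_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        for (mut, iface, etype), val in self.entries.items():
            if etype not in ENERGY_TYPES:
                raise ValueError(f"unknown energy type {etype!r}")
            if iface not in self.interface_ids:
                raise ValueError(f"interface {iface!r} not declared")
            if not np.isfinite(val):
                raise ValueError(f"non-finite ddG for {mut}/{iface}/{etype}")

    @property
    def mutations(self) -> tuple[Mutation, ...]:
        return tuple(sorted({m for m, _, _ in self.entries}))

    def values(self, mutation: Mutation, energy_type: str) -> np.ndarray:
        """Per-interface values in declared interface order."""
        try:
            return np.array(
                [self.entries[(mutation, i, energy_type)] for i in self.interface_ids]
            )
        except KeyError as err:
            raise KeyError(f"{mutation}/{energy_type}: missing interface {err}") from None


def load_ddg_tsv(path, kcal: bool = False) -> DdgMatrix:
    """Load a ddG matrix from TSV with columns
    position, wt, mut, interface_id, energy_type, ddg_kj_mol.

    ``kcal=True`` converts values from kcal/mol on import (x 4.184).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["position", "wt", "mut", "interface_id", "energy_type", "ddg_kj_mol"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    entries: dict[tuple[Mutation, str, str], float] = {}
    interfaces: list[str] = []
    for row in df.itertuples(index=False):
        if row.energy_type not in ENERGY_TYPES:
            raise ValueError(f"{path}: unknown energy_type {row.energy_type!r}")
        try:
            val = float(row.ddg_kj_mol)
        except ValueError:
            raise ValueError(f"{path}: non-numeric ddg {row.ddg_kj_mol!r}") from None
        if kcal:
            val *= KCAL_TO_KJ
        mut = Mutation(position=int(row.position), wt=row.wt, mut=row.mut)
        key = (mut, row.interface_id, row.energy_type)
        if key in entries:
            raise ValueError(f"{path}: duplicate entry {mut}/{row.interface_id}/{row.energy_type}")
        entries[key] = val
        if row.interface_id not in interfaces:
            interfaces.append(row.interface_id)
    return DdgMatrix(entries=entries, interface_ids=tuple(interfaces))


def write_ddg_tsv(m: DdgMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\twt\tmut\tinterface_id\tenergy_type\tddg_kj_mol\n")
        for (mut, iface, etype) in sorted(
            m.entries, key=lambda k: (k[0], k[1], k[2])
        ):
            fh.write(
                f"{mut.position}\t{mut.wt}\t{mut.mut}\t{iface}\t{etype}\t"
                f"{float(m.entries[(mut, iface, etype)])!r}\n"
            )


def ensemble_average(matrices) -> tuple[DdgMatrix, DdgMatrix]:
    """Arithmetic mean and standard deviation over snapshot matrices.

    All matrices must share the same key set (snapshots of the same scan).
    Returns ``(mean_matrix, sd_matrix)``; the sd is the population standard
    deviation across snapshots.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to average")
    keys = set(matrices[0].entries)
    for m in matrices[1:]:
        if set(m.entries) != keys:
            raise ValueError("snapshot matrices have mismatched keys")
    mean_entries, sd_entries = {}, {}
    for key in keys:
        vals = np.array([m.entries[key] for m in matrices])
        mean_entries[key] = float(vals.mean())
        sd_entries[key] = float(vals.std())
    ifaces = matrices[0].interface_ids
    return (
        DdgMatrix(entries=mean_entries, interface_ids=ifaces),
        DdgMatrix(entries=sd_entries, interface_ids=ifaces),
    )


def summarize_best_worst(
    m: DdgMatrix, mutation: Mutation, energy_type: str, mode: str = "stabilize"
) -> tuple[float, float]:
    """Best/worst per-interface ddG for a mutation.

    stabilize: best = most negative (most stabilizing) interface value,
    worst = maximum. destabilize: best = least positive (least
    destabilizing) value among the positive ones; worst = maximum.
    """
    vals = m.values(mutation, energy_type)
    worst = float(vals.max())
    if mode == "stabilize":
        return float(vals.min()), worst
    if mode == "destabilize":
        positive = vals[vals > 0]
        if not len(positive):
            raise ValueError(f"{mutation}/{energy_type}: no destabilizing interface value")
        return float(positive.min()), worst
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class SelectionCriteria:
    """Which mutations qualify as design candidates.

    stabilize mode: affinity and stability ddG strictly below their
    thresholds (default 0 — 'favorable means negative') on *all* interfaces,
    and position conservation <= conservation_threshold.
    destabilize mode: affinity ddG > 0 on all interfaces while stability
    ddG < 0 on all interfaces (lower the binding without unfolding the
    receptor); no conservation veto.
    """

    mode: str = "stabilize"
    require_all_interfaces: bool = True
    affinity_threshold: float = 0.0
    stability_threshold: float = 0.0
    conservation_threshold: float = 0.65

    def __post_init__(self) -> None:
        if self.mode not in ("stabilize", "destabilize"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for v in (self.affinity_threshold, self.stability_threshold, self.conservation_threshold):
            if not np.isfinite(v):
                raise ValueError("criteria thresholds must be finite")


@dataclass
class CandidateRow:
    mutation: Mutation
    passed: bool
    checks: dict[str, bool]
    best_affinity: float
    worst_affinity: float
    best_stability: float
    worst_stability: float
    conservation: float
    rank: int | None = None


@dataclass
class CandidateReport:
    mode: str
    rows: list[CandidateRow] = field(default_factory=list)

    @property
    def selected(self) -> list[Mutation]:
        return [r.mutation for r in sorted(
            (r for r in self.rows if r.passed), key=lambda r: r.rank
        )]

    def row(self, mutation: Mutation) -> CandidateRow:
        for r in self.rows:
            if r.mutation == mutation:
                return r
        raise KeyError(str(mutation))

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in sorted(self.rows, key=lambda r: (not r.passed, r.rank if r.rank is not None else 0,
                                                  r.mutation)):
            rec = {
                "mutation": str(r.mutation),
                "passed": r.passed,
                "rank": r.rank if r.rank is not None else "",
                "best_affinity_kJ_mol": r.best_affinity,
                "worst_affinity_kJ_mol": r.worst_affinity,
                "best_stability_kJ_mol": r.best_stability,
                "worst_stability_kJ_mol": r.worst_stability,
                "conservation_fraction": r.conservation,
            }
            rec.update({f"check_{k}": v for k, v in r.checks.items()})
            recs.append(rec)
        return pd.DataFrame(recs)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mode": self.mode,
                    "selected": [str(m) for m in self.selected],
                    "rows": self.to_frame().to_dict(orient="records"),
                },
                fh,
                indent=2,
            )


def select_candidates(
    m: DdgMatrix,
    profile: ConservationProfile | None,
    criteria: SelectionCriteria,
    numbering_map: NumberingMap | None = None,
) -> CandidateReport:
    """Apply the selection criteria to every mutation in the matrix.

    Mutation positions are in reference numbering; if the conservation
    profile uses a different numbering, ``numbering_map`` converts
    (``profile position = structure position + offset``). Ranking of passing
    candidates: best affinity ddG ascending in stabilize mode (most
    stabilizing first), descending in destabilize mode; ties broken by
    position then mutant residue.
    """
    report = CandidateReport(mode=criteria.mode)
    stabilize = criteria.mode == "stabilize"
    for mut in m.mutations:
        aff = m.values(mut, "affinity")
        stab = m.values(mut, "stability")
        checks: dict[str, bool] = {}
        if stabilize:
            checks["affinity_all_interfaces"] = bool(np.all(aff < criteria.affinity_threshold)) \
                if criteria.require_all_interfaces else bool(np.any(aff < criteria.affinity_threshold))
            checks["stability_all_interfaces"] = bool(np.all(stab < criteria.stability_threshold)) \
                if criteria.require_all_interfaces else bool(np.any(stab < criteria.stability_threshold))
        else:
            checks["affinity_all_interfaces"] = bool(np.all(aff > 0))
            checks["stability_all_interfaces"] = bool(np.all(stab < 0))

        conservation = float("nan")
        if profile is not None:
            ref_pos = mut.position
            if numbering_map is not None:
                ref_pos = numbering_map.to_reference(mut.position)
            if ref_pos not in profile.positions:
                raise ValueError(
                    f"{mut}: position {ref_pos} not covered by conservation profile"
                )
            conservation = profile.fraction(ref_pos)
            if stabilize:
                checks["not_conserved"] = conservation <= criteria.conservation_threshold

        passed = all(checks.values())
        best_aff = float(aff.min()) if stabilize else (
            float(aff[aff > 0].min()) if np.any(aff > 0) else float(aff.min())
        )
        report.rows.append(
            CandidateRow(
                mutation=mut,
                passed=passed,
                checks=checks,
                best_affinity=best_aff,
                worst_affinity=float(aff.max()),
                best_stability=float(stab.min()),
                worst_stability=float(stab.max()),
                conservation=conservation,
            )
        )
    sign = 1.0 if stabilize else -1.0
    passing = sorted(
        (r for r in report.rows if r.passed),
        key=lambda r: (sign * r.best_affinity, r.mutation.position, r.mutation.mut),
    )
    for rank, row in enumerate(passing, start=1):
        row.rank = rank
    return report


def design_combinations(
    singles,
    s: Structure,
    chain_id: str,
    numbering_map: NumberingMap | None = None,
    min_seq_sep: int = 25,
    min_spatial_sep: float = 20.0,
    max_order: int = 3,
) -> list[MultiMutation]:
    """Combine compatible single mutations into multi-mutants.

    Two singles are compatible when their positions are at least
    ``min_seq_sep`` residues apart in sequence and their wild-type CA atoms
    are more than ``min_spatial_sep`` A apart in the structure — distant
    mutations are the ones expected to act additively. Emits every subset of
    size 2..max_order whose pairs are all compatible.
    """
    singles = sorted(set(singles))
    ca = {}
    for mut in singles:
        pos = mut.position
        if numbering_map is not None:
            pos = numbering_map.to_structure(pos)
        try:
            res = s.residue(chain_id, pos)
        except KeyError:
            raise ValueError(f"{mut}: structure position {pos} absent from chain {chain_id}")
        atom = res.atom("CA")
        if atom is None:
            raise ValueError(f"{mut}: residue {pos} has no CA atom")
        ca[mut] = atom.coords

    def compatible(a: Mutation, b: Mutation) -> bool:
        if abs(a.position - b.position) < min_seq_sep:
            return False
        return float(np.linalg.norm(ca[a] - ca[b])) > min_spatial_sep

    out: list[MultiMutation] = []
    for order in range(2, max_order + 1):
        for combo in itertools.combinations(singles, order):
            if all(compatible(a, b) for a, b in itertools.combinations(combo, 2)):
                out.append(MultiMutation(frozenset(combo)))
    return out


def combinations_to_tsv(combos, path) -> None:
    with open(path, "w") as fh:
        fh.write("multi_mutation\n")
        for c in combos:
            fh.write(f"{c}\n")
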