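"""Per-position sequence conservation from a multiple sequence alignment.

Receptor positions that are conserved across species are vetoed from
mutation: a strongly conserved residue is likely to carry a structural or
functional role that an engineered substitution would disrupt. Conservation
is measured as identity to the reference sequence (the receptor being
engineered), with gaps counted as mismatches and the reference itself
included in the denominator. The modal (consensus) residue is reported
alongside for display parity.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass

from Bio import AlignIO

__all__ = [
    "Alignment",
    "ConservationProfile",
    "NumberingMap",
    "read_alignment",
    "column_conservation",
    "conserved_positions",
    "map_numbering",
    "profile_to_tsv",
    "veto_set_to_json",
]

GAP = "-"


@dataclass
class Alignment:
    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("alignment needs >= 2 records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in alignment")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def sequence(self, record_id: str) -> str:
        for rid, seq in self.records:
            if rid == record_id:
                return seq
        raise KeyError(f"record {record_id!r} not in alignment")


@dataclass
class ConservationProfile:
    """Per ungapped-reference-position conservation.

    ``positions`` maps reference position (1-based) to
    ``(ref_residue, fraction, consensus_residue)``.
    """

    reference_id: str
    positions: dict[int, tuple[str, float, str]]

    def fraction(self, pos: int) -> float:
        return self.positions[pos][1]


@dataclass
class NumberingMap:
    """Constant offset between reference (UniProt-style) and structure
    numbering: ``structure = reference - offset``.

    ``ref_range`` optionally bounds the mapped reference positions.
    """

    offset: int
    ref_range: tuple[int, int] | None = None

    def to_structure(self, ref_pos: int) -> int:
        self._check(ref_pos)
        return ref_pos - self.offset

    def to_reference(self, struct_pos: int) -> int:
        ref_pos = struct_pos + self.offset
        self._check(ref_pos)
        return ref_pos

    def _check(self, ref_pos: int) -> None:
        if self.ref_range is not None:
            lo, hi = self.ref_range
            if not lo <= ref_pos <= hi:
                raise ValueError(f"reference position {ref_pos} outside mapped range [{lo}, {hi}]")


def read_alignment(path) -> Alignment:
    """Read an aligned-FASTA file, preserving record order."""
    msa = AlignIO.read(str(path), "fasta")
    return Alignment(records=[(rec.id, str(rec.seq).upper()) for rec in msa])


def column_conservation(
    a: Alignment, reference_id: str, include_reference: bool = True
) -> ConservationProfile:
    """Identity-to-reference fraction for every ungapped reference position.

    For each alignment column where the reference has a residue, the
    fraction is the share of sequences whose aligned residue equals the
    reference residue; gaps count as mismatches. With ``include_reference``
    (default) the reference sequence is part of both numerator and
    denominator — the 32-of-32 convention.
    """
    ref_seq = a.sequence(reference_id)
    seqs = [seq for rid, seq in a.records]
    n_all = len(seqs)
    positions: dict[int, tuple[str, float, str]] = {}
    ref_pos = 0
    for col in range(a.length):
        ref_res = ref_seq[col]
        if ref_res == GAP:
            continue
        ref_pos += 1
        column = [seq[col] for seq in seqs]
        matches = sum(1 for c in column if c == ref_res)
        if include_reference:
            frac = matches / n_all
        else:
            frac = (matches - 1) / (n_all - 1)
        counts = Counter(c for c in column if c != GAP)
        consensus = min(
            counts, key=lambda aa: (-counts[aa], aa)
        )  # modal residue, ties alphabetical
        positions[ref_pos] = (ref_res, frac, consensus)
    return ConservationProfile(reference_id=reference_id, positions=positions)


def conserved_positions(p: ConservationProfile, threshold: float = 0.65) -> set[int]:
    """Reference positions conserved *strictly* above ``threshold`` — the
    veto set excluded from mutation design."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return {pos for pos, (_, frac, _) in p.positions.items() if frac > threshold}


def map_numbering(pos: int, m: NumberingMap, direction: str = "ref_to_structure") -> int:
    if direction in ("ref_to_structure", "ref->structure"):
        return m.to_structure(pos)
    if direction in ("structure_to_ref", "structure->ref"):
        return m.to_reference(pos)
    raise ValueError(f"unknown direction {direction!r}")


def profile_to_tsv(p: ConservationProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tref_residue\tfraction\tconsensus\n")
        for pos in sorted(p.positions):
            ref_res, frac, consensus = p.positions[pos]
            fh.write(f"{pos}\t{ref_res}\t{frac:.6f}\t{consensus}\n")


def veto_set_to_json(p: ConservationProfile, threshold: float, path) -> None:
    veto = sorted(conserved_positions(p, threshold))
    with open(path, "w") as fh:
        json.dump(
            {
                "reference_id": p.reference_id,
                "threshold": threshold,
                "conserved_positions": veto,
            },
            fh,
            indent=2,
        )
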