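"""Residue-residue contact scores (RRCS) and activation score changes (ΔRRCS).

The contact score of a residue pair is the sum, over all inter-residue
heavy-atom pairs, of a plateau-linear-plateau atomic score of the
interatomic distance d:

    score(d) = 1                              d <= d_plateau
             = (d_zero - d)/(d_zero - d_plateau)   d_plateau < d < d_zero
             = 0                              d >= d_zero

a form adopted from the hydrophobic term of ChemScore. Each atom-pair score
is weighted by the product of the two occupancies, so alternate conformations
contribute in proportion to their refined occupancies. For residue pairs
within ``adjacency_window`` positions in sequence (default 4) only
side-chain atoms are counted, since backbone contacts of near neighbours
barely change on activation.

ΔRRCS = RRCS_active − RRCS_inactive for the same receptor: positive means a
contact gained on activation, negative a contact lost.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist

from .positions import pair_key
from .structures import AnnotatedStructure, PartnerEntity, ResidueRecord

__all__ = [
    "ContactParams",
    "DEFAULT_PARAMS",
    "RRCSTable",
    "DeltaRecord",
    "atom_contact_score",
    "residue_pair_rrcs",
    "structure_rrcs",
    "delta_rrcs",
]


@dataclass(frozen=True)
class ContactParams:
    """Parameters of the atomic contact score.

    The distances (Å) are the published defaults of the authors' released
    scoring code; they are configurable, not printed constants.
    """

    d_plateau: float = 3.23
    d_zero: float = 4.63
    adjacency_window: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.d_plateau < self.d_zero):
            raise ValueError("require 0 < d_plateau < d_zero")
        if self.adjacency_window < 0:
            raise ValueError("adjacency_window must be >= 0")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ContactParams":
        with open(path) as fh:
            cfg = json.load(fh)
        return cls(**{k: cfg[k] for k in ("d_plateau", "d_zero", "adjacency_window") if k in cfg})


DEFAULT_PARAMS = ContactParams()


def atom_contact_score(d, params: ContactParams = DEFAULT_PARAMS):
    """Plateau-linear-plateau score of an interatomic distance (scalar or array)."""
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distances must be non-negative")
    score = np.clip((params.d_zero - d_arr) / (params.d_zero - params.d_plateau), 0.0, 1.0)
    return float(score) if np.isscalar(d) or d_arr.ndim == 0 else score


def _atom_arrays(atoms) -> tuple[np.ndarray, np.ndarray]:
    coords = np.array([a.coords for a in atoms], dtype=float)
    occ = np.array([a.occupancy for a in atoms], dtype=float)
    return coords, occ


def _pair_score(atoms_a, atoms_b, params: ContactParams) -> float:
    if not atoms_a or not atoms_b:
        return 0.0
    ca, oa = _atom_arrays(atoms_a)
    cb, ob = _atom_arrays(atoms_b)
    scores = atom_contact_score(cdist(ca, cb), params)
    return float(np.einsum("i,j,ij->", oa, ob, scores))


def residue_pair_rrcs(
    a: ResidueRecord,
    b: ResidueRecord,
    seq_separation: Optional[int],
    params: ContactParams = DEFAULT_PARAMS,
) -> float:
    """RRCS of one residue pair.

    *seq_separation* is the absolute sequence-number difference within a
    chain; pass ``None`` for cross-chain or residue-vs-partner pairs (all
    heavy atoms count). For separations at or below the adjacency window
    only side-chain atoms are counted. A residue with no qualifying atoms
    (e.g. glycine under the side-chain-only rule) contributes score 0.
    """
    side_only = seq_separation is not None and seq_separation <= params.adjacency_window
    return _pair_score(
        a.heavy_atoms(side_chain_only=side_only),
        b.heavy_atoms(side_chain_only=side_only),
        params,
    )


@dataclass
class RRCSTable:
    """Positive contact scores of one structure.

    ``per_chain`` maps chain id -> {canonical pair key -> score}; ``averaged``
    is the chain-averaged table (a pair is averaged over the chains in which
    both positions are present and unexcluded; a chain missing a position
    never contributes a zero). ``partner`` maps partner kind ("ligand",
    "gprotein") -> {position -> chain-averaged score vs that entity treated
    as a single residue}. Excluded residues appear in no score map; their
    labels are listed in ``excluded_positions`` so that downstream deltas
    can distinguish missing from zero.
    """

    pdb_id: str
    receptor_id: str = ""
    state_label: str = "unknown"
    per_chain: dict[str, dict[str, float]] = field(default_factory=dict)
    chain_positions: dict[str, set[str]] = field(default_factory=dict)
    averaged: dict[str, float] = field(default_factory=dict)
    averaged_n: dict[str, int] = field(default_factory=dict)
    partner: dict[str, dict[str, float]] = field(default_factory=dict)
    excluded_positions: set[str] = field(default_factory=set)

    def to_frame(self):
        import pandas as pd

        rows = [
            {"pdb_id": self.pdb_id, "pair": p, "score": s, "n_chains": self.averaged_n.get(p, 1)}
            for p, s in sorted(self.averaged.items())
        ]
        return pd.DataFrame(rows, columns=["pdb_id", "pair", "score", "n_chains"])

    def to_json_dict(self) -> dict:
        return {
            "pdb_id": self.pdb_id,
            "receptor_id": self.receptor_id,
            "state": self.state_label,
            "averaged": dict(sorted(self.averaged.items())),
            "partner": {k: dict(sorted(v.items())) for k, v in self.partner.items()},
            "excluded_positions": sorted(self.excluded_positions),
        }


@dataclass(frozen=True)
class DeltaRecord:
    receptor_id: str
    pair: str
    rrcs_active: float
    rrcs_inactive: float

    @property
    def delta(self) -> float:
        return self.rrcs_active - self.rrcs_inactive


def _prescreen(residues: Sequence[ResidueRecord], d_zero: float) -> np.ndarray:
    """Boolean matrix of residue pairs that may have a non-zero score.

    Bounding-sphere check: the closest atom pair of residues i, j is at least
    |centroid_i - centroid_j| - r_i - r_j apart, so pairs beyond d_zero by
    that bound are provably zero. Exactness vs the all-pairs oracle is
    enforced by tests.
    """
    cents = np.array([np.mean([a.coords for a in r.atoms], axis=0) for r in residues])
    radii = np.array(
        [max(np.linalg.norm(a.coords - c) for a in r.atoms) for r, c in zip(residues, cents)]
    )
    dmat = cdist(cents, cents)
    return dmat - radii[:, None] - radii[None, :] < d_zero


def structure_rrcs(s: AnnotatedStructure, params: ContactParams = DEFAULT_PARAMS) -> RRCSTable:
    """All positive residue-pair scores of a structure, per chain and chain-averaged.

    Pairs are computed within each receptor chain (sequence separation from
    residue numbering, insertion-code variants counted as separation 0 when
    numbers are equal). Partner entities (ligand, G protein or mimetic) are
    each treated as a single residue and scored against every receptor
    residue with all heavy atoms. Excluded residues are skipped entirely.
    """
    if s.rejected:
        raise ValueError(f"structure {s.pdb_id} was rejected by quality filters")
    if not s.residues:
        raise EmptyTableError(f"structure {s.pdb_id} has no residues")

    table = RRCSTable(pdb_id=s.pdb_id, receptor_id=s.receptor_id, state_label=s.state_label)
    table.excluded_positions = s.excluded_positions()

    # group partner entities by kind: one pseudo-residue per kind
    partners_by_kind: dict[str, list[PartnerEntity]] = {}
    for p in s.partner_entities:
        partners_by_kind.setdefault(p.kind, []).append(p)

    partner_chain_scores: dict[str, dict[str, list[float]]] = {k: {} for k in partners_by_kind}

    for chain_id in s.chains:
        residues = [r for r in s.residues_in_chain(chain_id) if not r.excluded]
        if not residues:
            continue
        table.chain_positions[chain_id] = {r.label for r in residues}
        scores: dict[str, float] = {}
        keep = _prescreen(residues, params.d_zero)
        for i in range(len(residues)):
            ri = residues[i]
            for j in range(i + 1, len(residues)):
                if not keep[i, j]:
                    continue
                rj = residues[j]
                sep = abs(ri.seq_number - rj.seq_number)
                val = residue_pair_rrcs(ri, rj, sep, params)
                if val > 0:
                    key = pair_key(ri.label, rj.label)
                    # insertion-code twins can map to the same key; keep the sum
                    scores[key] = scores.get(key, 0.0) + val
        table.per_chain[chain_id] = scores

        for kind, entities in partners_by_kind.items():
            merged_atoms = [a for e in entities for a in e.atoms]
            for r in residues:
                val = _pair_score(r.heavy_atoms(), merged_atoms, params)
                if val > 0:
                    partner_chain_scores[kind].setdefault(r.label, []).append(val)

    # chain averaging over chains where both positions are present & unexcluded
    all_pairs = {p for scores in table.per_chain.values() for p in scores}
    for pair in all_pairs:
        a, _, b = pair.partition(":")
        chains = [
            c
            for c, pos in table.chain_positions.items()
            if a in pos and b in pos
        ]
        if not chains:
            continue
        avg = sum(table.per_chain[c].get(pair, 0.0) for c in chains) / len(chains)
        if avg > 0:
            table.averaged[pair] = avg
            table.averaged_n[pair] = len(chains)

    for kind, by_pos in partner_chain_scores.items():
        table.partner[kind] = {
            pos: sum(vals) / len(vals) for pos, vals in by_pos.items() if sum(vals) > 0
        }
    return table


class EmptyTableError(ValueError):
    pass


class PairingError(ValueError):
    pass


def delta_rrcs(active: RRCSTable, inactive: RRCSTable) -> list[DeltaRecord]:
    """ΔRRCS records (active − inactive) for every pair present in either table.

    A pair missing from one table scores 0 there, unless one of its positions
    is RSR-excluded in either structure — such pairs are dropped as missing
    rather than entering downstream statistics as spurious zeros.
    """
    if active.receptor_id and inactive.receptor_id and active.receptor_id != inactive.receptor_id:
        raise PairingError(
            f"receptor mismatch: {active.receptor_id!r} vs {inactive.receptor_id!r}"
        )
    excluded = active.excluded_positions | inactive.excluded_positions
    records = []
    for pair in sorted(set(active.averaged) | set(inactive.averaged)):
        a, _, b = pair.partition(":")
        if a in excluded or b in excluded:
            continue
        records.append(
            DeltaRecord(
                receptor_id=active.receptor_id or inactive.receptor_id,
                pair=pair,
                rrcs_active=active.averaged.get(pair, 0.0),
                rrcs_inactive=inactive.averaged.get(pair, 0.0),
            )
        )
    return records
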