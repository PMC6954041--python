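"""Shared fixtures and the independent all-pairs scoring oracle.

The oracle recomputes structure-level contact tables with explicit Python
loops and no prescreening or vectorization, staying independent of the
library's optimized path.
"""

from __future__ import annotations

import math

import pytest

from rrcskit.contacts import ContactParams
from rrcskit.positions import pair_key


@pytest.fixture
def params() -> ContactParams:
    return ContactParams()


def naive_atom_score(d: float, p: ContactParams) -> float:
    if d <= p.d_plateau:
        return 1.0
    if d >= p.d_zero:
        return 0.0
    return (p.d_zero - d) / (p.d_zero - p.d_plateau)


def naive_pair_score(res_a, res_b, side_only: bool, p: ContactParams) -> float:
    total = 0.0
    backbone = {"N", "CA", "C", "O"}
    for a in res_a.atoms:
        if side_only and a.atom_name in backbone:
            continue
        for b in res_b.atoms:
            if side_only and b.atom_name in backbone:
                continue
            d = math.dist(tuple(a.coords), tuple(b.coords))
            total += naive_atom_score(d, p) * a.occupancy * b.occupancy
    return total


def naive_structure_rrcs(s, p: ContactParams) -> dict[str, dict[str, float]]:
    """Chain -> pair key -> score, by exhaustive double loops."""
    out: dict[str, dict[str, float]] = {}
    for chain in s.chains:
        residues = [r for r in s.residues if r.chain_id == chain and not r.excluded]
        scores: dict[str, float] = {}
        for i, ra in enumerate(residues):
            for rb in residues[i + 1 :]:
                sep = abs(ra.seq_number - rb.seq_number)
                val = naive_pair_score(ra, rb, sep <= p.adjacency_window, p)
                if val > 0:
                    key = pair_key(ra.label, rb.label)
                    scores[key] = scores.get(key, 0.0) + val
        out[chain] = scores
    return out
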