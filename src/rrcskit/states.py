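"""Activation-state descriptors from inter-helical contact scores.

Receptor activation switches the cytoplasmic contacts of TM3 from TM6 to
TM7: inactive structures have zero (or near-zero) TM3-TM7 score over a wide
range of TM3-TM6 scores, while active structures have strictly zero TM3-TM6
and high TM3-TM7. Summing the pathway's inter-helical pair scores over the
two interfaces therefore places every structure in a 2D plane where the two
states form compact, separable clusters; a third score reports the collapse
(denser repacking) of the Na+ pocket.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from sklearn.base import BaseEstimator

from . import reference
from .contacts import RRCSTable

__all__ = [
    "StateDescriptor",
    "interface_score",
    "compute_descriptor",
    "classify_state",
    "ActivationStateClassifier",
]

DEFAULT_TAU_ACTIVE = 0.2
DEFAULT_TAU_ZERO = 0.05


@dataclass(frozen=True)
class StateDescriptor:
    pdb_id: str
    rrcs_tm3_tm6: float
    rrcs_tm3_tm7: float
    rrcs_sodium_pocket: float


def interface_score(t: RRCSTable, pair_subset: Sequence[str]) -> float:
    """Sum of chain-averaged scores over a pair subset; missing pairs count 0."""
    if not pair_subset:
        raise ValueError("pair_subset must be non-empty")
    return sum(t.averaged.get(p, 0.0) for p in pair_subset)


def compute_descriptor(
    t: RRCSTable,
    tm3_tm6: Sequence[str] = reference.TM3_TM6_PAIRS,
    tm3_tm7: Sequence[str] = reference.TM3_TM7_PAIRS,
    sodium_pocket: Sequence[str] = reference.SODIUM_POCKET_PAIRS,
) -> StateDescriptor:
    return StateDescriptor(
        pdb_id=t.pdb_id,
        rrcs_tm3_tm6=interface_score(t, tm3_tm6),
        rrcs_tm3_tm7=interface_score(t, tm3_tm7),
        rrcs_sodium_pocket=interface_score(t, sodium_pocket),
    )


def classify_state(
    d: StateDescriptor,
    tau_active: float = DEFAULT_TAU_ACTIVE,
    tau_zero: float = DEFAULT_TAU_ZERO,
) -> str:
    """Threshold call in the 2D contact plane.

    active: TM3-TM6 at (near) zero and TM3-TM7 formed; inactive: TM3-TM7 at
    (near) zero; anything else indeterminate. Thresholds are tooling defaults
    chosen to separate the state clusters, not published constants.
    """
    if not tau_zero < tau_active:
        raise ValueError("require tau_zero < tau_active")
    if d.rrcs_tm3_tm6 <= tau_zero and d.rrcs_tm3_tm7 >= tau_active:
        return "active"
    if d.rrcs_tm3_tm7 <= tau_zero:
        return "inactive"
    return "indeterminate"


class ActivationStateClassifier(BaseEstimator):
    """Stateless classifier of activation state from RRCS tables.

    ``transform`` maps tables to descriptor rows; ``predict`` returns the
    state call per table. ``fit`` is a no-op provided for pipeline
    compatibility.
    """

    def __init__(
        self,
        tau_active: float = DEFAULT_TAU_ACTIVE,
        tau_zero: float = DEFAULT_TAU_ZERO,
        tm3_tm6_pairs: Sequence[str] = reference.TM3_TM6_PAIRS,
        tm3_tm7_pairs: Sequence[str] = reference.TM3_TM7_PAIRS,
        sodium_pocket_pairs: Sequence[str] = reference.SODIUM_POCKET_PAIRS,
    ):
        self.tau_active = tau_active
        self.tau_zero = tau_zero
        self.tm3_tm6_pairs = tm3_tm6_pairs
        self.tm3_tm7_pairs = tm3_tm7_pairs
        self.sodium_pocket_pairs = sodium_pocket_pairs

    def fit(self, X=None, y=None) -> "ActivationStateClassifier":
        return self

    def transform(self, X: Sequence[RRCSTable]) -> list[StateDescriptor]:
        return [
            compute_descriptor(
                t, self.tm3_tm6_pairs, self.tm3_tm7_pairs, self.sodium_pocket_pairs
            )
            for t in X
        ]

    def predict(self, X: Sequence[RRCSTable]) -> list[str]:
        return [
            classify_state(d, self.tau_active, self.tau_zero) for d in self.transform(X)
        ]

    def to_frame(self, X: Sequence[RRCSTable]):
        import pandas as pd

        rows = []
        for t, d in zip(X, self.transform(X)):
            rows.append(
                {
                    "pdb_id": d.pdb_id,
                    "receptor_id": t.receptor_id,
                    "state_label": t.state_label,
                    "rrcs_tm3_tm6": d.rrcs_tm3_tm6,
                    "rrcs_tm3_tm7": d.rrcs_tm3_tm7,
                    "rrcs_sodium_pocket": d.rrcs_sodium_pocket,
                    "call": classify_state(d, self.tau_active, self.tau_zero),
                }
            )
        return pd.DataFrame(rows)
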