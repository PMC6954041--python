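"""Two-round discovery of conserved contact rearrangements upon activation.

Round 1 works on the receptors with paired active/inactive structures: a
residue pair is *strict* when its ΔRRCS has the same sign and magnitude
above the cutoff (default 0.2) in every receptor. Pairs passing in all but
one receptor are candidates for rescue, either because the failing receptor
is exempt for biological reasons (rhodopsin lacks the Na+ pocket) or because
auxiliary active/inactive receptor pairs confirm the rearrangement.

Round 2 asks whether each surviving pair separates the family-wide inactive
and active structure ensembles: a two-tailed two-sample t-test on the
per-structure RRCS values, pair kept at p < alpha (default 0.001). Receptor
exemptions carry over (rhodopsin structures are dropped from the test for
Na+-pocket pairs). The surviving intra-receptor pairs plus the
receptor/G-protein pairs form the activation pathway, with residues
assigned to four layers from the packaged layer table.

:class:`PathwayDiscovery` wraps the two rounds as a scikit-learn style
estimator; the module-level functions expose each step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from . import reference
from .contacts import DeltaRecord, RRCSTable
from .positions import position_key, split_pair

__all__ = [
    "Round1Config",
    "RescueException",
    "CandidatePair",
    "RescuedPair",
    "TTestResult",
    "PathwayModel",
    "DiscoveryCohort",
    "PathwayDiscovery",
    "round1_select",
    "select_partner_pairs",
    "apply_rescue_rules",
    "round2_test",
    "group_scores",
    "assemble_pathway",
]


class ConfigError(ValueError):
    pass


class UndefinedTestError(ValueError):
    pass


@dataclass(frozen=True)
class RescueException:
    """Receptor exempted from the selection/test for a specific set of pairs."""

    pairs: frozenset
    exempt_receptor: str
    tag: str = ""


def default_rescue_exceptions() -> list[RescueException]:
    return [
        RescueException(
            pairs=frozenset(reference.NA_POCKET_EXEMPT_PAIRS),
            exempt_receptor=reference.NA_POCKET_EXEMPT_RECEPTOR,
            tag="na_pocket",
        )
    ]


@dataclass
class Round1Config:
    delta_cutoff: float = 0.2
    rescue_exceptions: list[RescueException] = field(default_factory=default_rescue_exceptions)
    partner_kind: str = "gprotein"

    def __post_init__(self) -> None:
        if self.delta_cutoff <= 0:
            raise ConfigError("delta_cutoff must be positive")


@dataclass(frozen=True)
class CandidatePair:
    pair: str
    failing_receptor: str
    consensus_sign: int  # sign of the passing receptors' deltas


@dataclass(frozen=True)
class RescuedPair:
    pair: str
    failing_receptor: str
    reason: str


@dataclass(frozen=True)
class TTestResult:
    pair: str
    n_inactive: int
    n_active: int
    mean_inactive: float
    mean_active: float
    t_statistic: float
    p_value: float
    passed: bool


def _deltas_as_map(records: Sequence[DeltaRecord]) -> dict[str, float]:
    return {r.pair: r.delta for r in records}


def round1_select(
    deltas_by_receptor: Mapping[str, Sequence[DeltaRecord]],
    cfg: Optional[Round1Config] = None,
) -> tuple[list[str], list[CandidatePair]]:
    """Select pairs with same-sign |ΔRRCS| > cutoff in all receptors (strict)
    or in all but one (rescue candidates, annotated with the failing receptor).

    A pair without a delta record in some receptor counts as ΔRRCS = 0 there.
    The strict inequality matters: |Δ| equal to the cutoff does not pass.
    """
    cfg = cfg or Round1Config()
    receptors = sorted(deltas_by_receptor)
    if len(receptors) < 2:
        raise ConfigError("round 1 needs at least two receptors")
    maps = {rec: _deltas_as_map(deltas_by_receptor[rec]) for rec in receptors}
    all_pairs = sorted({p for m in maps.values() for p in m}, key=lambda p: tuple(map(position_key, split_pair(p))))

    strict: list[str] = []
    candidates: list[CandidatePair] = []
    for pair in all_pairs:
        deltas = {rec: maps[rec].get(pair, 0.0) for rec in receptors}
        passing = {rec: d for rec, d in deltas.items() if abs(d) > cfg.delta_cutoff}
        signs = {1 if d > 0 else -1 for d in passing.values()}
        if len(signs) != 1:
            continue
        if len(passing) == len(receptors):
            strict.append(pair)
        elif len(passing) == len(receptors) - 1:
            (failing,) = set(receptors) - set(passing)
            candidates.append(CandidatePair(pair, failing, signs.pop()))
    return strict, candidates


def apply_rescue_rules(
    five_of_six: Sequence[CandidatePair],
    cfg: Optional[Round1Config] = None,
    auxiliary_deltas: Optional[Mapping[str, Sequence[DeltaRecord]]] = None,
) -> list[RescuedPair]:
    """Rescue candidates failing in exactly one receptor.

    Rule (a): the failing receptor is exempted for that pair by configuration.
    Rule (b): the pair passes the same sign/cutoff criterion in *every*
    auxiliary receptor pair. Candidates failing in more than one receptor
    never reach this stage (round 1 emits only one-failure candidates).
    """
    cfg = cfg or Round1Config()
    aux_maps = {
        rec: _deltas_as_map(recs) for rec, recs in (auxiliary_deltas or {}).items()
    }
    rescued: list[RescuedPair] = []
    for cand in five_of_six:
        exempt = any(
            cand.pair in exc.pairs and cand.failing_receptor == exc.exempt_receptor
            for exc in cfg.rescue_exceptions
        )
        if exempt:
            rescued.append(RescuedPair(cand.pair, cand.failing_receptor, "exemption"))
            continue
        if aux_maps and all(
            abs(m.get(cand.pair, 0.0)) > cfg.delta_cutoff
            and math.copysign(1, m.get(cand.pair, 0.0)) == cand.consensus_sign
            for m in aux_maps.values()
        ):
            rescued.append(
                RescuedPair(cand.pair, cand.failing_receptor, "auxiliary_confirmation")
            )
    return rescued


def select_partner_pairs(
    active_tables: Sequence[RRCSTable],
    inactive_tables: Sequence[RRCSTable] = (),
    cfg: Optional[Round1Config] = None,
) -> list[str]:
    """Receptor positions whose contact with the intracellular partner
    (G protein or mimetic, one pseudo-residue) rises from 0 to above the
    cutoff consistently in every active-state table.

    Inactive structures carry no bound partner, so any partner score there
    vetoes a position. Returns sorted positions; empty (with a warning) when
    no active structure has an annotated partner entity.
    """
    cfg = cfg or Round1Config()
    kind = cfg.partner_kind
    with_partner = [t for t in active_tables if t.partner.get(kind)]
    if not with_partner:
        warnings.warn("no active structure has an annotated intracellular partner")
        return []
    common: Optional[set[str]] = None
    for t in active_tables:
        hits = {pos for pos, sc in t.partner.get(kind, {}).items() if sc > cfg.delta_cutoff}
        common = hits if common is None else common & hits
    vetoed = {
        pos
        for t in inactive_tables
        for pos, sc in t.partner.get(kind, {}).items()
        if sc > cfg.delta_cutoff
    }
    return sorted((common or set()) - vetoed, key=position_key)


def round2_test(
    pair: str,
    inactive_scores: Sequence[float],
    active_scores: Sequence[float],
    alpha: float = 0.001,
    equal_var: bool = True,
) -> TTestResult:
    """Two-tailed two-sample t-test of per-structure RRCS between state groups.

    Missing values (NaN) are removed first; each group then needs at least
    two observations. Pooled-variance (Student) by default; Welch via
    ``equal_var=False``. The degenerate all-constant case is reported as
    no difference (t = 0, p = 1); constant groups with different values give
    p = 0.
    """
    inact = np.asarray(inactive_scores, dtype=float)
    act = np.asarray(active_scores, dtype=float)
    inact = inact[~np.isnan(inact)]
    act = act[~np.isnan(act)]
    if len(inact) < 2 or len(act) < 2:
        raise UndefinedTestError(
            f"pair {pair}: need >=2 values per group, got {len(inact)}/{len(act)}"
        )
    if np.var(inact) == 0 and np.var(act) == 0:
        same = float(inact.mean()) == float(act.mean())
        t_stat, p = (0.0, 1.0) if same else (math.inf, 0.0)
    else:
        t_stat, p = stats.ttest_ind(inact, act, equal_var=equal_var)
        t_stat, p = float(t_stat), float(p)
    return TTestResult(
        pair=pair,
        n_inactive=len(inact),
        n_active=len(act),
        mean_inactive=float(inact.mean()),
        mean_active=float(act.mean()),
        t_statistic=t_stat,
        p_value=p,
        passed=p < alpha,
    )


def group_scores(
    tables: Sequence[RRCSTable],
    pairs: Sequence[str],
    exclusions: Sequence[RescueException] = (),
) -> dict[str, list[float]]:
    """Per-structure scores for each pair over a group of tables.

    A pair absent from a table scores 0 (the residues are present but not in
    contact); a pair touching an RSR-excluded position in that structure is a
    missing value (NaN). Structures of a receptor exempted for a pair are
    skipped for that pair.
    """
    out: dict[str, list[float]] = {p: [] for p in pairs}
    for t in tables:
        for p in pairs:
            if any(
                p in exc.pairs and t.receptor_id == exc.exempt_receptor for exc in exclusions
            ):
                continue
            a, b = split_pair(p)
            if a in t.excluded_positions or b in t.excluded_positions:
                out[p].append(math.nan)
            else:
                out[p].append(t.averaged.get(p, 0.0))
    return out


@dataclass
class PathwayModel:
    """The assembled conserved-rearrangement pathway."""

    intra_pairs: list[dict]  # {pair, p_value, mean_inactive, mean_active}
    partner_pairs: list[tuple[str, str]]  # (receptor position, partner name)
    layer_of: dict[str, int]
    residues: list[str]
    unassigned: list[str] = field(default_factory=list)

    @property
    def pair_names(self) -> list[str]:
        return [d["pair"] for d in self.intra_pairs]

    def to_json_dict(self) -> dict:
        return {
            "intra_pairs": self.intra_pairs,
            "partner_pairs": [list(p) for p in self.partner_pairs],
            "layer_of": self.layer_of,
            "residues": self.residues,
            "unassigned": self.unassigned,
            "n_intra_pairs": len(self.intra_pairs),
            "n_residues": len(self.residues),
        }


def assemble_pathway(
    strict_plus_rescued: Sequence[str],
    partner_positions: Sequence[str],
    t_results: Sequence[TTestResult],
    layer_table: Optional[Mapping[str, int]] = None,
    partner_name: str = "G protein",
) -> PathwayModel:
    """Assemble the pathway from pairs passing Round 2 plus partner pairs.

    Every intra pair must carry a t-test result. Positions without a layer
    assignment are reported in ``unassigned``, never dropped.
    """
    layer_table = dict(layer_table if layer_table is not None else reference.LAYER_OF)
    by_pair = {t.pair: t for t in t_results}
    missing = [p for p in strict_plus_rescued if p not in by_pair]
    if missing:
        raise ConfigError(f"pairs without a round-2 result: {missing}")
    intra = [
        {
            "pair": p,
            "p_value": by_pair[p].p_value,
            "mean_inactive": by_pair[p].mean_inactive,
            "mean_active": by_pair[p].mean_active,
        }
        for p in strict_plus_rescued
        if by_pair[p].passed
    ]
    residues: set[str] = set()
    for d in intra:
        residues.update(split_pair(d["pair"]))
    residues.update(partner_positions)
    ordered = sorted(residues, key=position_key)
    layer_of = {pos: layer_table[pos] for pos in ordered if pos in layer_table}
    unassigned = [pos for pos in ordered if pos not in layer_table]
    return PathwayModel(
        intra_pairs=intra,
        partner_pairs=[(pos, partner_name) for pos in partner_positions],
        layer_of=layer_of,
        residues=ordered,
        unassigned=unassigned,
    )


@dataclass
class DiscoveryCohort:
    """Inputs to :meth:`PathwayDiscovery.fit`.

    ``deltas_by_receptor``: ΔRRCS records of the representative
    active/inactive pair of each receptor. ``family_inactive`` /
    ``family_active``: RRCS tables of every usable structure in each state
    group (each structure is one observation in Round 2).
    ``auxiliary_deltas``: extra receptors used only for rescue confirmation.
    """

    deltas_by_receptor: Mapping[str, Sequence[DeltaRecord]]
    family_inactive: Sequence[RRCSTable]
    family_active: Sequence[RRCSTable]
    auxiliary_deltas: Mapping[str, Sequence[DeltaRecord]] = field(default_factory=dict)
    representative_active: Sequence[RRCSTable] = ()
    representative_inactive: Sequence[RRCSTable] = ()


class PathwayDiscovery(BaseEstimator):
    """Fit the two-round conserved-rearrangement selection on a structure cohort.

    Parameters
    ----------
    delta_cutoff : float, default 0.2
        Round-1 threshold on |ΔRRCS| (strict inequality).
    alpha : float, default 0.001
        Round-2 significance level of the two-sample t-test.
    equal_var : bool, default True
        Pooled-variance (Student) t-test; False selects Welch.
    rescue_exceptions : list of RescueException or None
        Receptor exemptions; None installs the Na+-pocket/rhodopsin default.
    layer_table : mapping position -> int or None
        Layer assignment; None uses the packaged published table.

    Attributes (after fit)
    ----------------------
    strict_pairs_, candidate_pairs_, rescued_pairs_, partner_positions_,
    ttest_results_, removed_pairs_, pathway_ : see the module functions.
    """

    def __init__(
        self,
        delta_cutoff: float = 0.2,
        alpha: float = 0.001,
        equal_var: bool = True,
        rescue_exceptions: Optional[list[RescueException]] = None,
        layer_table: Optional[Mapping[str, int]] = None,
        partner_kind: str = "gprotein",
    ):
        self.delta_cutoff = delta_cutoff
        self.alpha = alpha
        self.equal_var = equal_var
        self.rescue_exceptions = rescue_exceptions
        self.layer_table = layer_table
        self.partner_kind = partner_kind

    def _config(self) -> Round1Config:
        exc = (
            self.rescue_exceptions
            if self.rescue_exceptions is not None
            else default_rescue_exceptions()
        )
        return Round1Config(
            delta_cutoff=self.delta_cutoff,
            rescue_exceptions=list(exc),
            partner_kind=self.partner_kind,
        )

    def fit(self, X: DiscoveryCohort, y=None) -> "PathwayDiscovery":
        cfg = self._config()
        strict, candidates = round1_select(X.deltas_by_receptor, cfg)
        rescued = apply_rescue_rules(candidates, cfg, X.auxiliary_deltas)
        partner_positions = select_partner_pairs(
            list(X.representative_active) or list(X.family_active),
            list(X.representative_inactive) or list(X.family_inactive),
            cfg,
        )
        kept = strict + [r.pair for r in rescued]
        inact_scores = group_scores(X.family_inactive, kept, cfg.rescue_exceptions)
        act_scores = group_scores(X.family_active, kept, cfg.rescue_exceptions)
        t_results = [
            round2_test(p, inact_scores[p], act_scores[p], self.alpha, self.equal_var)
            for p in kept
        ]
        self.strict_pairs_ = strict
        self.candidate_pairs_ = candidates
        self.rescued_pairs_ = rescued
        self.partner_positions_ = partner_positions
        self.ttest_results_ = t_results
        self.removed_pairs_ = [t.pair for t in t_results if not t.passed]
        self.pathway_ = assemble_pathway(
            kept, partner_positions, t_results, self.layer_table
        )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "pathway_"):
            raise NotFittedError("PathwayDiscovery is not fitted; call fit first")

    @property
    def selected_pairs_(self) -> list[str]:
        self._check_fitted()
        return self.pathway_.pair_names
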