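"""Round 1 selection, rescue rules, the family-wide t-test and pathway assembly."""

import math

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

from rrcskit import reference
from rrcskit.contacts import DeltaRecord, RRCSTable
from rrcskit.discovery import (
    CandidatePair,
    ConfigError,
    PathwayDiscovery,
    RescueException,
    Round1Config,
    UndefinedTestError,
    apply_rescue_rules,
    assemble_pathway,
    group_scores,
    round1_select,
    round2_test,
    select_partner_pairs,
)
from rrcskit.synth import CohortSpec, simulate_cohort


def _deltas(receptor, pairs_to_delta):
    return [
        DeltaRecord(receptor, pair, rrcs_active=max(d, 0.0), rrcs_inactive=max(-d, 0.0))
        for pair, d in pairs_to_delta.items()
    ]


RECEPTORS = ["R0", "R1", "R2", "R3", "R4", "R5"]


def _cohort_deltas(planted, background_sd=0.03, seed=0):
    rng = np.random.default_rng(seed)
    out = {}
    for rec in RECEPTORS:
        deltas = {p: d + rng.normal(0, background_sd) for p, d in planted.items()}
        deltas.update({f"9×{40 + i}:9×{50 + i}": rng.normal(0, background_sd) for i in range(30)})
        out[rec] = _deltas(rec, deltas)
    return out


def test_round1_recovers_planted_pairs_exactly():
    planted = {f"1×{40 + i}:2×{40 + i}": (1.0 if i % 2 else -1.0) for i in range(10)}
    strict, candidates = round1_select(_cohort_deltas(planted))
    assert set(strict) == set(planted)
    assert candidates == []


def test_round1_boundary_is_strict_inequality():
    planted = {"1×40:2×40": 1.0}
    deltas = _cohort_deltas(planted, background_sd=0.0)
    # one receptor exactly at the cutoff
    deltas["R3"] = _deltas("R3", {"1×40:2×40": 0.2})
    strict, candidates = round1_select(deltas)
    assert strict == []
    assert [c.pair for c in candidates] == ["1×40:2×40"]
    assert candidates[0].failing_receptor == "R3"


def test_round1_sign_consistency_and_order_invariance():
    planted = {"1×40:2×40": 1.0}
    deltas = _cohort_deltas(planted, background_sd=0.0)
    deltas["R3"] = _deltas("R3", {"1×40:2×40": -1.0})  # opposite sign, passes cutoff
    strict, candidates = round1_select(deltas)
    assert strict == [] and candidates == []
    # order of receptors does not matter
    planted = {f"3×{40 + i}:5×{40 + i}": 0.7 for i in range(4)}
    deltas = _cohort_deltas(planted)
    shuffled = dict(reversed(list(deltas.items())))
    assert round1_select(deltas) == round1_select(shuffled)


def test_round1_cutoff_anti_monotone():
    rng = np.random.default_rng(4)
    deltas = {
        rec: _deltas(rec, {f"1×{40 + i}:2×{40 + i}": rng.normal(0, 0.5) for i in range(40)})
        for rec in RECEPTORS
    }
    strict_lo, _ = round1_select(deltas, Round1Config(delta_cutoff=0.1))
    strict_hi, _ = round1_select(deltas, Round1Config(delta_cutoff=0.3))
    assert set(strict_hi) <= set(strict_lo)


def test_round1_requires_two_receptors():
    with pytest.raises(ConfigError):
        round1_select({"R0": []})


def test_rescue_by_exemption():
    cfg = Round1Config(
        rescue_exceptions=[
            RescueException(frozenset({"2×50:7×49"}), "bRho", tag="na_pocket")
        ]
    )
    cand = [CandidatePair("2×50:7×49", "bRho", +1)]
    rescued = apply_rescue_rules(cand, cfg)
    assert [(r.pair, r.reason) for r in rescued] == [("2×50:7×49", "exemption")]
    # exemption is pair-specific and receptor-specific
    assert apply_rescue_rules([CandidatePair("2×50:7×49", "R1", +1)], cfg) == []
    assert apply_rescue_rules([CandidatePair("3×40:6×48", "bRho", +1)], cfg) == []


def test_rescue_by_auxiliary_confirmation_requires_all():
    cfg = Round1Config(rescue_exceptions=[])
    cand = [CandidatePair("3×46:3×50", "R5", +1)]
    both_pass = {
        "AUX0": _deltas("AUX0", {"3×46:3×50": 0.9}),
        "AUX1": _deltas("AUX1", {"3×46:3×50": 0.5}),
    }
    assert [r.reason for r in apply_rescue_rules(cand, cfg, both_pass)] == [
        "auxiliary_confirmation"
    ]
    one_fails = {
        "AUX0": _deltas("AUX0", {"3×46:3×50": 0.9}),
        "AUX1": _deltas("AUX1", {"3×46:3×50": 0.1}),
    }
    assert apply_rescue_rules(cand, cfg, one_fails) == []
    wrong_sign = {
        "AUX0": _deltas("AUX0", {"3×46:3×50": 0.9}),
        "AUX1": _deltas("AUX1", {"3×46:3×50": -0.9}),
    }
    assert apply_rescue_rules(cand, cfg, wrong_sign) == []


def _partner_table(pdb_id, positions, score=1.0, state="active"):
    return RRCSTable(
        pdb_id=pdb_id,
        state_label=state,
        partner={"gprotein": {pos: score for pos in positions}},
    )


def test_partner_pair_selection_planted_and_empty_cases():
    active = [_partner_table(f"A{i}", ["3×50", "6×33"]) for i in range(4)]
    active[0].partner["gprotein"]["5×61"] = 0.9  # not consistent across receptors
    assert select_partner_pairs(active) == ["3×50", "6×33"]
    with pytest.warns(UserWarning):
        assert select_partner_pairs([RRCSTable(pdb_id="I", state_label="inactive")]) == []


def _pooled_t(x, y):
    """Closed-form Student t with pooled variance (hand oracle)."""
    nx, ny = len(x), len(y)
    sx = sum((v - sum(x) / nx) ** 2 for v in x) / (nx - 1)
    sy = sum((v - sum(y) / ny) ** 2 for v in y) / (ny - 1)
    sp2 = ((nx - 1) * sx + (ny - 1) * sy) / (nx + ny - 2)
    return (sum(x) / nx - sum(y) / ny) / math.sqrt(sp2 * (1 / nx + 1 / ny))


def test_round2_matches_pooled_t_oracle():
    # a classic small two-group comparison, computed by the closed form above
    x = [19.8, 20.4, 19.6, 17.8, 18.5, 18.9, 18.3, 18.9, 19.5, 22.0]
    y = [28.2, 26.6, 20.1, 23.3, 25.2, 22.1, 17.7, 27.6, 20.6, 13.7, 23.2, 17.5, 20.6]
    res = round2_test("1×40:2×40", x, y, alpha=0.05)
    assert res.t_statistic == pytest.approx(_pooled_t(x, y), abs=1e-10)
    assert res.n_inactive == 10 and res.n_active == 13


def test_round2_jittered_separation_and_degenerate_cases():
    rng = np.random.default_rng(42)
    inact = (np.zeros(4) + rng.normal(0, 1e-3, 4)).tolist()
    act = (np.ones(4) + rng.normal(0, 1e-3, 4)).tolist()
    res = round2_test("1×40:2×40", inact, act)
    assert res.p_value < 1e-5 and res.passed

    const = round2_test("1×40:2×40", [1.0, 1.0, 1.0], [1.0, 1.0])
    assert const.p_value == 1.0 and not const.passed
    apart = round2_test("1×40:2×40", [0.0, 0.0], [1.0, 1.0])
    assert apart.p_value == 0.0

    with pytest.raises(UndefinedTestError):
        round2_test("1×40:2×40", [1.0], [0.0, 0.5])
    # NaNs are removed before the count check
    res = round2_test("1×40:2×40", [0.0, 0.0, math.nan], [1.0, 1.01, math.nan])
    assert res.n_inactive == 2 and res.n_active == 2


def test_group_scores_missing_vs_zero_and_exclusions():
    t1 = RRCSTable(pdb_id="a", receptor_id="R0", averaged={"1×40:2×40": 1.0})
    t2 = RRCSTable(pdb_id="b", receptor_id="R1")  # pair absent -> 0
    t3 = RRCSTable(pdb_id="c", receptor_id="R2", excluded_positions={"1×40"})  # missing
    scores = group_scores([t1, t2, t3], ["1×40:2×40"])
    assert scores["1×40:2×40"][:2] == [1.0, 0.0]
    assert math.isnan(scores["1×40:2×40"][2])
    exc = [RescueException(frozenset({"1×40:2×40"}), "R1")]
    assert len(group_scores([t1, t2, t3], ["1×40:2×40"], exc)["1×40:2×40"]) == 2


def test_assembly_reproduces_published_pair_and_residue_counts():
    """32 strict − 4 failing the family t-test + 6 rescued = 34 pairs, 35 residues."""
    kept = list(reference.ROUND1_STRICT_PAIRS) + list(reference.RESCUED_PAIRS)
    t_results = [
        round2_test(p, [0.0, 0.0, 0.0], [1.0, 1.001, 0.999])
        if p not in reference.ROUND2_REMOVED_PAIRS
        else round2_test(p, [1.0, 1.0, 1.0], [1.0, 1.0])
        for p in kept
    ]
    model = assemble_pathway(kept, reference.PARTNER_POSITIONS, t_results)
    assert len(model.intra_pairs) == 34
    assert len(model.residues) == 35
    assert model.unassigned == []
    assert set(model.pair_names) == set(reference.pathway_intra_pairs())
    assert model.layer_of["3×50"] == 4 and model.layer_of["2×50"] == 1


def test_assembly_edge_cases():
    with pytest.raises(ConfigError):
        assemble_pathway(["1×40:2×40"], [], [])
    failed = round2_test("1×40:2×40", [1.0, 1.0, 1.0], [1.0, 1.0])
    model = assemble_pathway(["1×40:2×40"], ["3×50"], [failed])
    assert model.intra_pairs == [] and model.partner_pairs == [("3×50", "G protein")]
    # a position without a layer entry is reported, never dropped
    ok = round2_test("9×40:9×41", [0.0, 0.0, 0.0], [1.0, 1.001, 0.999])
    model = assemble_pathway(["9×40:9×41"], [], [ok])
    assert model.unassigned == ["9×40", "9×41"]


def test_estimator_api_and_full_pipeline_recovery():
    sim = simulate_cohort(CohortSpec(seed=11, partner_positions=("3×50", "6×33")))
    est = PathwayDiscovery()
    with pytest.raises(NotFittedError):
        _ = est.selected_pairs_
    cloned = clone(est)
    assert cloned.get_params() == est.get_params()
    est.fit(sim.cohort)
    assert set(est.pathway_.pair_names) == set(sim.truth)
    assert est.partner_positions_ == ["3×50", "6×33"]
    assert est.removed_pairs_ == []
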