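"""Contact-score contracts: the atomic score shape, occupancy weighting,
adjacency rule, structure tables vs the exhaustive oracle, and ΔRRCS."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import naive_structure_rrcs
from rrcskit.contacts import (
    ContactParams,
    PairingError,
    atom_contact_score,
    delta_rrcs,
    residue_pair_rrcs,
    structure_rrcs,
)
from rrcskit.structures import AtomRecord, ResidueRecord
from rrcskit.synth import make_random_structure, make_toy_pair_pdb
from rrcskit import parse_structure


@pytest.mark.parametrize(
    "d,expected",
    [
        (10.0, 0.0),  # beyond the outer cutoff
        (2.5, 1.0),  # inside the plateau
        (3.23, 1.0),  # plateau edge
        (4.63, 0.0),  # zero edge
        (3.93, 0.5),  # midpoint of the linear ramp
    ],
)
def test_atom_contact_score_shape(d, expected, params):
    assert atom_contact_score(d, params) == pytest.approx(expected, abs=1e-12)
    assert (params.d_plateau + params.d_zero) / 2 == pytest.approx(3.93)


def test_atom_contact_score_continuous_and_rejects_negative(params):
    grid = np.linspace(0, 6, 1201)
    vals = atom_contact_score(grid, params)
    assert np.all(np.abs(np.diff(vals)) < 0.005)  # no jumps
    with pytest.raises(ValueError):
        atom_contact_score(-0.1, params)


def _res(chain, num, atoms):
    return ResidueRecord(chain, num, "", "ALA", atoms)


def _atom(name, x, y=0.0, z=0.0, occ=1.0):
    return AtomRecord(name, name[0], np.array([x, y, z], float), occ)


def test_adjacency_rule_drops_backbone_pairs(params):
    """Within the 4-residue window only side-chain atoms count."""
    a = _res("A", 10, [_atom("CA", 0.0), _atom("CB", 0.0, 1.0)])
    b = _res("A", 12, [_atom("CA", 2.0), _atom("CB", 30.0)])
    close_backbone_only = residue_pair_rrcs(a, b, 2, params)
    assert close_backbone_only == 0.0
    # same geometry beyond the window: CA-CA and CA-CB pairs now count
    far = residue_pair_rrcs(a, b, 10, params)
    assert far > 0.0


def test_occupancy_product_rule(params):
    s = parse_structure(make_toy_pair_pdb(2.0, occupancies=(0.5, 0.5)))
    t = structure_rrcs(s, params)
    assert list(t.averaged.values()) == [pytest.approx(0.25)]
    s = parse_structure(make_toy_pair_pdb(2.0, occupancies=(1.0, 1.0)))
    assert list(structure_rrcs(s, params).averaged.values()) == [pytest.approx(1.0)]


def test_pair_score_symmetric(params):
    s = make_random_structure(seed=5)
    for i in range(0, len(s.residues) - 1, 2):
        a, b = s.residues[i], s.residues[i + 1]
        sep = abs(a.seq_number - b.seq_number)
        assert residue_pair_rrcs(a, b, sep, params) == residue_pair_rrcs(b, a, sep, params)


def _transform_structure(s, fn):
    residues = []
    for r in s.residues:
        atoms = [dataclasses.replace(a, coords=fn(a.coords)) for a in r.atoms]
        residues.append(dataclasses.replace(r, atoms=atoms))
    return dataclasses.replace(s, residues=residues)


@pytest.mark.parametrize("seed", range(5))
def test_rigid_motion_invariance(seed, params):
    s = make_random_structure(seed=seed)
    rot = Rotation.random(random_state=seed).as_matrix()
    shift = np.array([7.0, -3.0, 11.0])
    s2 = _transform_structure(s, lambda c: rot @ c + shift)
    t1, t2 = structure_rrcs(s, params), structure_rrcs(s2, params)
    assert set(t1.averaged) == set(t2.averaged)
    for k in t1.averaged:
        assert t1.averaged[k] == pytest.approx(t2.averaged[k], abs=1e-9)


@pytest.mark.parametrize("factor", [1.1, 1.5, 2.5])
def test_expansion_never_increases_scores(factor, params):
    s = make_random_structure(seed=11)
    coords = np.concatenate([[a.coords for a in r.atoms] for r in s.residues])
    centroid = coords.mean(axis=0)
    s2 = _transform_structure(s, lambda c: centroid + factor * (c - centroid))
    t1, t2 = structure_rrcs(s, params), structure_rrcs(s2, params)
    for k, v in t2.averaged.items():
        assert v <= t1.averaged.get(k, 0.0) + 1e-12


def test_structure_rrcs_matches_oracle_on_random_fixtures(params):
    for seed in range(25):
        s = make_random_structure(seed=seed, chain_ids=("A", "B"))
        t = structure_rrcs(s, params)
        oracle = naive_structure_rrcs(s, params)
        for chain in s.chains:
            assert t.per_chain[chain] == pytest.approx(oracle[chain], abs=1e-12)


def test_distant_residues_give_empty_table(params):
    s = parse_structure(make_toy_pair_pdb(50.0))
    assert structure_rrcs(s, params).averaged == {}


def test_delta_identity_antisymmetry_and_pairing():
    s1 = structure_rrcs(parse_structure(make_toy_pair_pdb(2.0)))
    s2 = structure_rrcs(parse_structure(make_toy_pair_pdb(4.0)))
    same = delta_rrcs(s1, s1)
    assert all(r.delta == 0.0 for r in same) and len(same) == 1
    fwd = {r.pair: r.delta for r in delta_rrcs(s1, s2)}
    rev = {r.pair: r.delta for r in delta_rrcs(s2, s1)}
    assert fwd.keys() == rev.keys()
    assert all(fwd[k] == -rev[k] for k in fwd)
    s1.receptor_id, s2.receptor_id = "A2AR", "b2AR"
    with pytest.raises(PairingError):
        delta_rrcs(s1, s2)


def test_excluded_residue_yields_missing_not_zero():
    active = structure_rrcs(parse_structure(make_toy_pair_pdb(2.0)))
    inactive = structure_rrcs(parse_structure(make_toy_pair_pdb(2.0)))
    inactive.excluded_positions = {"1"}  # label of the first residue
    assert delta_rrcs(active, inactive) == []  # dropped, not delta=score-0


def test_chain_average_skips_chains_missing_a_position(params):
    """A pair present in one chain and absent in the other is averaged only
    over chains containing both positions."""
    s = make_random_structure(seed=2, chain_ids=("A", "B"))
    s = dataclasses.replace(s, residues=[r for r in s.residues
                                         if not (r.chain_id == "B" and r.seq_number == 1)])
    t = structure_rrcs(s, params)
    first_label = next(r.label for r in s.residues if r.chain_id == "A" and r.seq_number == 1)
    for pair, n in t.averaged_n.items():
        if first_label in pair.split(":"):
            assert n == 1


def test_contact_params_validation():
    with pytest.raises(ValueError):
        ContactParams(d_plateau=5.0, d_zero=4.0)
    with pytest.raises(ValueError):
        ContactParams(adjacency_window=-1)
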