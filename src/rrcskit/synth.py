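"""Synthetic structures and cohorts with planted contact rearrangements.

Nothing here aims at physically realistic protein geometry: fixtures only
need exact control over interatomic distances, occupancies, sequence
separations and state labels, so that every stage of the pipeline can be
exercised and its output compared with a known planted truth.

Two fidelity modes:

* ``score`` — receptors and structures are realized directly as RRCS tables
  (baseline contacts plus Gaussian score noise per structure, planted pairs
  shifted by the effect size between states). This scales to family-size
  cohorts (hundreds of structures) in milliseconds.
* ``geometry`` — full PDB-text structures whose side-chain atoms are placed
  at distances realizing the planted contacts, exercising the parse →
  score → delta path end to end.

One integer seed drives a hierarchical random stream (cohort → receptor →
structure), so any subset of the cohort is reproducible and PDB output is
byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contacts import DEFAULT_PARAMS, ContactParams, DeltaRecord, RRCSTable, delta_rrcs, structure_rrcs
from .discovery import DiscoveryCohort
from .positions import SEP, pair_key, split_pair
from .structures import (
    AnnotatedStructure,
    AtomRecord,
    ResidueRecord,
    format_atom_line,
    parse_structure,
)

__all__ = ["CohortSpec", "SimulatedCohort", "make_toy_pair_pdb", "simulate_cohort", "write_cohort", "make_random_structure"]


class SpecError(ValueError):
    pass


def make_toy_pair_pdb(
    d_sidechain: float,
    occupancies: tuple[float, float] = (1.0, 1.0),
    seq_gap: int = 10,
    n_extra_sidechain: int = 0,
    params: ContactParams = DEFAULT_PARAMS,
) -> str:
    """Two-residue PDB whose single side-chain contact distance is *d_sidechain*.

    Backbones sit >15 Å from everything in the other residue, so the CB-CB
    pair is the only cross-residue atom pair within scoring range. Optional
    extra side-chain atoms are placed 6 Å below their own CB, outside the
    outer cutoff of every atom of the other residue.
    """
    if d_sidechain <= 0.1:
        raise SpecError(f"side-chain distance {d_sidechain} would overlap atoms")
    lines = ["REMARK   2 RESOLUTION.    2.00 ANGSTROMS."]
    serial = 1

    def residue(resnum: int, x0: float, y_bb: float, occ: float) -> None:
        nonlocal serial
        bb = {"N": (-1.2, 0.0), "CA": (0.0, 0.0), "C": (1.2, 0.0), "O": (1.2, 1.2)}
        for name, (dx, dz) in bb.items():
            lines.append(
                format_atom_line(serial, name, "ALA", "A", resnum, (x0 + dx, y_bb, dz),
                                 1.0, name[0]),
            )
            serial += 1
        lines.append(
            format_atom_line(serial, "CB", "ALA", "A", resnum, (x0, 0.0, 0.0), occ, "C")
        )
        serial += 1
        for k in range(n_extra_sidechain):
            lines.append(
                format_atom_line(serial, "CG" if k == 0 else f"CD{k}", "ALA", "A",
                                 resnum, (x0, -6.0 - 1.5 * k, 0.0), 1.0, "C")
            )
            serial += 1

    residue(1, 0.0, 20.0, occupancies[0])
    residue(1 + seq_gap, d_sidechain, -20.0, occupancies[1])
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_random_structure(
    seed: int,
    n_residues: int = 8,
    atoms_per_residue: tuple[int, int] = (3, 6),
    box: float = 14.0,
    altloc_prob: float = 0.2,
    chain_ids: Sequence[str] = ("A",),
) -> AnnotatedStructure:
    """Random heavy-atom structure for oracle cross-checks.

    Atom coordinates are uniform in a box small enough that many residue
    pairs fall inside the scoring range; some atoms get two alternate
    locations with complementary occupancies.
    """
    rng = np.random.default_rng(seed)
    names = ["N", "CA", "C", "O", "CB", "CG", "CD1", "CE1"]
    residues = []
    for chain in chain_ids:
        for i in range(n_residues):
            n_at = int(rng.integers(atoms_per_residue[0], atoms_per_residue[1] + 1))
            atoms = []
            for j in range(n_at):
                coords = rng.uniform(0, box, size=3)
                if rng.random() < altloc_prob:
                    occ = float(rng.uniform(0.3, 0.7))
                    atoms.append(AtomRecord(names[j], names[j][0], coords, occ, "A"))
                    atoms.append(
                        AtomRecord(
                            names[j], names[j][0], coords + rng.normal(0, 0.8, 3), 1 - occ, "B"
                        )
                    )
                else:
                    atoms.append(AtomRecord(names[j], names[j][0], coords, 1.0, ""))
            residues.append(
                ResidueRecord(chain, i + 1, "", "ALA", atoms, generic_number=f"{1 + i % 7}{SEP}{40 + i // 7}")
            )
    return AnnotatedStructure(
        pdb_id=f"SYN{seed}", receptor_id="synthetic", resolution=2.0,
        chains=list(chain_ids), residues=residues,
    )


@dataclass
class CohortSpec:
    """Study conditions of a simulated activation cohort.

    Defaults mirror the real analysis scale: six receptors with paired
    representative structures drive Round 1, and family groups of 140
    inactive / 27 active structures drive the Round-2 t-test.
    """

    n_receptors: int = 6
    n_positions: int = 40
    n_planted: int = 10
    effect_size: float = 1.0
    noise_sd: float = 0.05
    n_inactive: int = 140
    n_active: int = 27
    n_background_pairs: int = 150
    partner_positions: tuple[str, ...] = ()
    n_auxiliary: int = 0
    seed: int = 0
    mode: str = "score"

    def __post_init__(self) -> None:
        if self.mode not in ("score", "geometry"):
            raise SpecError(f"unknown mode {self.mode!r}")
        if self.mode == "geometry" and abs(self.effect_size) > 1.0:
            raise SpecError(
                "geometry mode realizes each pair with one atom contact; |effect| must be <= 1"
            )
        if self.effect_size <= 0:
            raise SpecError("effect_size must be positive")
        max_pairs = self.n_positions // 2 if self.mode == "geometry" else (
            self.n_positions * (self.n_positions - 1) // 2
        )
        if self.n_planted > max_pairs:
            raise SpecError("more planted pairs than available position pairs")


@dataclass
class SimulatedCohort:
    spec: CohortSpec
    cohort: DiscoveryCohort
    truth: dict[str, float]  # planted pair -> planted ΔRRCS
    positions: list[str]
    pdb_texts: dict[str, str] = field(default_factory=dict)  # geometry mode
    generic_map: Optional[pd.DataFrame] = None
    metadata: Optional[pd.DataFrame] = None


def _position_labels(n: int) -> list[str]:
    return [f"{1 + i % 7}{SEP}{40 + i // 7}" for i in range(n)]


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate a cohort with planted conserved rearrangements and known truth."""
    if spec.mode == "score":
        return _simulate_scores(spec)
    return _simulate_geometry(spec)


# --- score mode -----------------------------------------------------------


def _simulate_scores(spec: CohortSpec) -> SimulatedCohort:
    root = np.random.SeedSequence(spec.seed)
    ss_layout, ss_receptors, ss_structs = root.spawn(3)
    rng = np.random.default_rng(ss_layout)

    positions = _position_labels(spec.n_positions)
    all_pairs = [
        pair_key(positions[i], positions[j])
        for i in range(len(positions))
        for j in range(i + 1, len(positions))
    ]
    chosen = rng.permutation(len(all_pairs))
    planted = [all_pairs[k] for k in chosen[: spec.n_planted]]
    background = [
        all_pairs[k] for k in chosen[spec.n_planted : spec.n_planted + spec.n_background_pairs]
    ]
    # alternate gained/lost contacts
    truth = {
        p: (spec.effect_size if i % 2 == 0 else -spec.effect_size)
        for i, p in enumerate(planted)
    }

    n_total_receptors = spec.n_receptors + spec.n_auxiliary
    receptor_ids = [f"R{i}" for i in range(spec.n_receptors)] + [
        f"AUX{i}" for i in range(spec.n_auxiliary)
    ]
    rec_rngs = [np.random.default_rng(s) for s in ss_receptors.spawn(n_total_receptors)]

    base_inactive: dict[str, dict[str, float]] = {}
    base_active: dict[str, dict[str, float]] = {}
    for rec, rrng in zip(receptor_ids, rec_rngs):
        bi: dict[str, float] = {}
        ba: dict[str, float] = {}
        for pair in background:
            level = float(rrng.uniform(0.3, 3.0))
            bi[pair] = level
            ba[pair] = level
        for pair, d in truth.items():
            if d > 0:
                lo = float(rrng.uniform(0.3, 1.5))
                bi[pair], ba[pair] = lo, lo + d
            else:
                hi = float(rrng.uniform(-d + 0.3, -d + 1.5))
                bi[pair], ba[pair] = hi, hi + d
        base_inactive[rec], base_active[rec] = bi, ba

    struct_rng = np.random.default_rng(ss_structs)

    def realize(rec: str, base: dict[str, float], pdb_id: str, state: str,
                with_partner: bool) -> RRCSTable:
        noisy = {
            p: v + float(struct_rng.normal(0, spec.noise_sd)) if spec.noise_sd else v
            for p, v in base.items()
        }
        t = RRCSTable(
            pdb_id=pdb_id,
            receptor_id=rec,
            state_label=state,
            averaged={p: max(0.0, v) for p, v in noisy.items() if v > 0},
        )
        t.averaged_n = {p: 1 for p in t.averaged}
        if with_partner and spec.partner_positions:
            t.partner["gprotein"] = {
                pos: max(
                    0.05,
                    1.0 + float(struct_rng.normal(0, spec.noise_sd)) if spec.noise_sd else 1.0,
                )
                for pos in spec.partner_positions
            }
        return t

    deltas: dict[str, list[DeltaRecord]] = {}
    aux_deltas: dict[str, list[DeltaRecord]] = {}
    rep_active: list[RRCSTable] = []
    rep_inactive: list[RRCSTable] = []
    for rec in receptor_ids:
        t_in = realize(rec, base_inactive[rec], f"{rec}_I", "inactive", False)
        t_ac = realize(rec, base_active[rec], f"{rec}_A", "active", True)
        records = delta_rrcs(t_ac, t_in)
        if rec.startswith("AUX"):
            aux_deltas[rec] = records
        else:
            deltas[rec] = records
            rep_inactive.append(t_in)
            rep_active.append(t_ac)

    primary = receptor_ids[: spec.n_receptors]
    family_inactive = [
        realize(rec := primary[k % spec.n_receptors], base_inactive[rec], f"FI{k}", "inactive", False)
        for k in range(spec.n_inactive)
    ]
    family_active = [
        realize(rec := primary[k % spec.n_receptors], base_active[rec], f"FA{k}", "active", True)
        for k in range(spec.n_active)
    ]

    cohort = DiscoveryCohort(
        deltas_by_receptor=deltas,
        family_inactive=family_inactive,
        family_active=family_active,
        auxiliary_deltas=aux_deltas,
        representative_active=rep_active,
        representative_inactive=rep_inactive,
    )
    return SimulatedCohort(spec=spec, cohort=cohort, truth=truth, positions=positions)


# --- geometry mode --------------------------------------------------------


def _score_to_distance(score: float, params: ContactParams = DEFAULT_PARAMS) -> float:
    """Distance realizing a given atomic contact score (linear branch inverse)."""
    if not 0 < score <= 1:
        raise SpecError("realizable scores are in (0, 1]")
    if score == 1.0:
        return params.d_plateau - 0.2
    return params.d_zero - score * (params.d_zero - params.d_plateau)


def _geometry_structure_pdb(
    positions: Sequence[str],
    contacts: dict[str, float],
    noise_sd: float,
    rng: np.random.Generator,
    resolution: float = 2.0,
) -> str:
    """PDB text for one structure: one CB per position on a sparse grid,
    contacting pairs moved next to each other.

    Residues are laid out on a 25 Å grid (even slots lift their backbone to
    z=+12, odd to z=-12 so backbones of a contacting pair never touch). Each
    contact pair uses exactly one CB-CB atom pair at the distance realizing
    its score; positions may appear in at most one contact.
    """
    n = len(positions)
    used: set[int] = set()
    centers = {}
    side = int(np.ceil(np.sqrt(n)))
    z_of = {}
    for i in range(n):
        centers[i] = np.array([25.0 * (i % side), 25.0 * (i // side), 0.0])
        z_of[i] = 12.0
    idx_of = {p: i for i, p in enumerate(positions)}
    for pair, score in contacts.items():
        a, b = split_pair(pair)
        ia, ib = idx_of[a], idx_of[b]
        if ia in used or ib in used:
            raise SpecError(f"position reused in geometry contacts: {pair}")
        used.update((ia, ib))
        d = _score_to_distance(score)
        centers[ib] = centers[ia] + np.array([d, 0.0, 0.0])
        z_of[ib] = -z_of[ia]  # keep the contacting pair's backbones apart

    lines = [f"REMARK   2 RESOLUTION.    {resolution:.2f} ANGSTROMS."]
    serial = 1
    for i, pos in enumerate(positions):
        c = centers[i]
        z_bb = z_of[i]
        resnum = 10 * (i + 1)  # separation > adjacency window
        for name, dx in (("N", -1.2), ("CA", 0.0), ("C", 1.2), ("O", 2.0)):
            xyz = c + np.array([dx, 0.0, z_bb])
            if noise_sd:
                xyz = xyz + rng.normal(0, noise_sd, 3)
            lines.append(format_atom_line(serial, name, "ALA", "A", resnum, xyz, 1.0, name[0]))
            serial += 1
        xyz = c if not noise_sd else c + rng.normal(0, noise_sd, 3)
        lines.append(format_atom_line(serial, "CB", "ALA", "A", resnum, xyz, 1.0, "C"))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _simulate_geometry(spec: CohortSpec) -> SimulatedCohort:
    root = np.random.SeedSequence(spec.seed)
    ss_layout, ss_structs = root.spawn(2)
    rng = np.random.default_rng(ss_layout)

    positions = _position_labels(spec.n_positions)
    slots = rng.permutation(spec.n_positions)
    planted = [
        pair_key(positions[slots[2 * k]], positions[slots[2 * k + 1]])
        for k in range(spec.n_planted)
    ]
    n_bg = min(spec.n_background_pairs, (spec.n_positions - 2 * spec.n_planted) // 2)
    bg_slots = slots[2 * spec.n_planted : 2 * spec.n_planted + 2 * n_bg]
    background = [
        pair_key(positions[bg_slots[2 * k]], positions[bg_slots[2 * k + 1]])
        for k in range(n_bg)
    ]
    truth = {
        p: (spec.effect_size if i % 2 == 0 else -spec.effect_size)
        for i, p in enumerate(planted)
    }

    bg_scores = {p: float(rng.uniform(0.4, 1.0)) for p in background}
    inactive_contacts = dict(bg_scores)
    active_contacts = dict(bg_scores)
    for pair, d in truth.items():
        if d > 0:
            active_contacts[pair] = d
        else:
            inactive_contacts[pair] = -d

    struct_rng = np.random.default_rng(ss_structs)
    receptor_ids = [f"R{i}" for i in range(spec.n_receptors)]
    pdb_texts: dict[str, str] = {}
    meta_rows = []
    gmap_rows = []

    def build(rec: str, state: str, idx: int) -> RRCSTable:
        contacts = active_contacts if state == "active" else inactive_contacts
        pdb_id = f"{rec}{state[0].upper()}{idx}"
        text = _geometry_structure_pdb(positions, contacts, spec.noise_sd, struct_rng)
        pdb_texts[pdb_id] = text
        s = parse_structure(text, pdb_id=pdb_id)
        for i, pos in enumerate(positions):
            s.residues[i].generic_number = pos
            gmap_rows.append(
                {"pdb_id": pdb_id, "chain": "A", "seq_number": 10 * (i + 1), "generic_number": pos}
            )
        s.receptor_id = rec
        s.state_label = state
        meta_rows.append(
            {"pdb_id": pdb_id, "receptor_id": rec, "state": state, "resolution": 2.0, "partner_chains": ""}
        )
        t = structure_rrcs(s)
        t.receptor_id, t.state_label = rec, state
        return t

    deltas: dict[str, list[DeltaRecord]] = {}
    rep_active, rep_inactive = [], []
    for rec in receptor_ids:
        t_in = build(rec, "inactive", 0)
        t_ac = build(rec, "active", 0)
        deltas[rec] = delta_rrcs(t_ac, t_in)
        rep_inactive.append(t_in)
        rep_active.append(t_ac)

    family_inactive = [
        build(receptor_ids[k % spec.n_receptors], "inactive", k + 1) for k in range(spec.n_inactive)
    ]
    family_active = [
        build(receptor_ids[k % spec.n_receptors], "active", k + 1) for k in range(spec.n_active)
    ]

    cohort = DiscoveryCohort(
        deltas_by_receptor=deltas,
        family_inactive=family_inactive,
        family_active=family_active,
        representative_active=rep_active,
        representative_inactive=rep_inactive,
    )
    return SimulatedCohort(
        spec=spec,
        cohort=cohort,
        truth=truth,
        positions=positions,
        pdb_texts=pdb_texts,
        generic_map=pd.DataFrame(gmap_rows),
        metadata=pd.DataFrame(meta_rows).drop_duplicates("pdb_id"),
    )


def simulate_state_tables(
    n_per_state: int,
    seed: int = 0,
    noise_sd: float = 0.05,
) -> tuple[list[RRCSTable], list[str]]:
    """Score tables with planted active/inactive inter-helical geometry.

    Inactive structures carry TM3-TM6 contacts over a wide score range and
    no TM3-TM7 contacts; active structures the reverse, plus a repacked
    (higher-scoring) Na+ pocket — the cluster structure of the 2D state
    plane. Returns (tables, true state labels).
    """
    from . import reference

    rng = np.random.default_rng(seed)
    tables: list[RRCSTable] = []
    labels: list[str] = []

    def noisy(level: float) -> float:
        return max(0.0, level + float(rng.normal(0, noise_sd))) if noise_sd else level

    for k in range(n_per_state):
        inact = {p: noisy(float(rng.uniform(0.8, 4.0))) for p in reference.TM3_TM6_PAIRS}
        inact.update({p: noisy(0.2) for p in reference.SODIUM_POCKET_PAIRS})
        tables.append(RRCSTable(pdb_id=f"SI{k}", state_label="inactive", averaged=inact))
        labels.append("inactive")
        act = {p: noisy(float(rng.uniform(0.8, 4.0))) for p in reference.TM3_TM7_PAIRS}
        act.update({p: noisy(1.0) for p in reference.SODIUM_POCKET_PAIRS})
        tables.append(RRCSTable(pdb_id=f"SA{k}", state_label="active", averaged=act))
        labels.append("active")
    return tables, labels


def write_cohort(sim: SimulatedCohort, outdir) -> None:
    """Write a geometry-mode cohort to disk: PDB files, annotation TSVs, truth JSON."""
    import json

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for pdb_id, text in sim.pdb_texts.items():
        (out / f"{pdb_id}.pdb").write_text(text)
    if sim.generic_map is not None:
        sim.generic_map.to_csv(out / "generic_map.tsv", sep="\t", index=False)
    if sim.metadata is not None:
        sim.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps({"planted": sim.truth}, indent=2, ensure_ascii=False))
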