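"""Reading and annotating receptor structures.

Structures arrive as fixed-column PDB text. Parsing keeps heavy atoms only
(hydrogens never enter contact scores), retains alternate locations with
their occupancies, and separates the receptor chains from partner entities
(ligands from HETATM records; G-protein or mimetic chains named in the
metadata table). Generic residue numbers ("3×50"-style), per-residue RSR
quality values and structure-level metadata are attached from plain tables.

Quality control follows two rules: structures at or above the resolution
cutoff (default 3.8 Å) are flagged rejected as a whole, and residues whose
real-space R-value exceeds the RSR cutoff (default 0.35) are flagged
excluded. Filters only ever set flags — excluded residues later yield
*missing* contact scores, never zeros.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional

import gemmi
import numpy as np
import pandas as pd

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

DEFAULT_RESOLUTION_MAX = 3.8
DEFAULT_RSR_MAX = 0.35

STATE_LABELS = ("inactive", "active", "intermediate", "unknown")


class StructureError(Exception):
    """Base class for structure-handling errors."""


class ParseError(StructureError):
    pass


class EmptyStructureError(StructureError):
    pass


class AnnotationConflictError(StructureError):
    pass


@dataclass(frozen=True)
class AtomRecord:
    atom_name: str
    element: str
    coords: np.ndarray  # (3,) in Å
    occupancy: float
    altloc: str = ""

    @property
    def is_backbone(self) -> bool:
        return self.atom_name in BACKBONE_ATOMS


@dataclass
class ResidueRecord:
    chain_id: str
    seq_number: int
    icode: str
    aa_type: str
    atoms: list[AtomRecord]
    generic_number: Optional[str] = None
    rsr: Optional[float] = None
    excluded: bool = False

    @property
    def label(self) -> str:
        """Generic number if annotated, else sequence number + insertion code."""
        return self.generic_number or f"{self.seq_number}{self.icode}".strip()

    def heavy_atoms(self, side_chain_only: bool = False) -> list[AtomRecord]:
        if side_chain_only:
            return [a for a in self.atoms if not a.is_backbone]
        return list(self.atoms)


@dataclass
class PartnerEntity:
    name: str
    kind: str  # "ligand" or "gprotein"
    atoms: list[AtomRecord]


@dataclass
class AnnotatedStructure:
    pdb_id: str
    receptor_id: str = ""
    resolution: Optional[float] = None
    state_label: str = "unknown"
    chains: list[str] = field(default_factory=list)
    residues: list[ResidueRecord] = field(default_factory=list)
    partner_entities: list[PartnerEntity] = field(default_factory=list)
    rejected: bool = False
    rejection_reason: Optional[str] = None

    def residues_in_chain(self, chain_id: str) -> list[ResidueRecord]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def excluded_positions(self) -> set[str]:
        return {r.label for r in self.residues if r.excluded}


def _validate_coordinate_lines(pdb_text: str) -> int:
    """Pre-check ATOM/HETATM lines; returns the number of ATOM records."""
    n_atom = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if line.startswith("ATOM"):
            n_atom += 1
        try:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                float(line[lo:hi])
        except (ValueError, IndexError):
            raise ParseError(f"malformed coordinate field on line {lineno}: {line!r}")
    return n_atom


def parse_structure(pdb_text: str, model_index: int = 0, pdb_id: str = "") -> AnnotatedStructure:
    """Parse PDB text into an :class:`AnnotatedStructure`.

    Hydrogens (and deuterium) are dropped; alternate locations are retained
    with their occupancies; zero-occupancy atoms are dropped. Waters are
    ignored; other HETATM residues become ligand partner entities, each
    treated downstream as a single pseudo-residue. Multi-model files are
    resolved through *model_index* (default: first model).
    """
    n_atom = _validate_coordinate_lines(pdb_text)
    if n_atom == 0:
        raise EmptyStructureError("no ATOM records in input")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise ParseError(str(exc)) from exc
    if model_index >= len(st):
        raise ParseError(f"model index {model_index} out of range ({len(st)} models)")
    model = st[model_index]

    residues: list[ResidueRecord] = []
    partners: list[PartnerEntity] = []
    chains: list[str] = []
    for chain in model:
        has_polymer = False
        for res in chain:
            atoms = []
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                if atom.occ <= 0:
                    continue
                atoms.append(
                    AtomRecord(
                        atom_name=atom.name,
                        element=atom.element.name,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=float(atom.occ),
                        altloc=atom.altloc.strip("\x00") if atom.altloc else "",
                    )
                )
            if not atoms:
                continue
            if res.het_flag == "H":
                if res.name in ("HOH", "DOD", "WAT"):
                    continue
                partners.append(
                    PartnerEntity(
                        name=f"{res.name}_{chain.name}{res.seqid.num}",
                        kind="ligand",
                        atoms=atoms,
                    )
                )
            else:
                has_polymer = True
                residues.append(
                    ResidueRecord(
                        chain_id=chain.name,
                        seq_number=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        aa_type=res.name,
                        atoms=atoms,
                    )
                )
        if has_polymer:
            chains.append(chain.name)

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return AnnotatedStructure(
        pdb_id=pdb_id or st.name.strip() or "",
        resolution=resolution,
        chains=chains,
        residues=residues,
        partner_entities=partners,
    )


def _rows_for(table: Optional[pd.DataFrame], pdb_id: str) -> pd.DataFrame:
    if table is None or len(table) == 0:
        return pd.DataFrame()
    if "pdb_id" in table.columns:
        return table[table["pdb_id"].astype(str).str.upper() == pdb_id.upper()]
    return table


def attach_annotations(
    s: AnnotatedStructure,
    generic_map: Optional[pd.DataFrame] = None,
    rsr_table: Optional[pd.DataFrame] = None,
    metadata: Optional[pd.DataFrame] = None,
) -> AnnotatedStructure:
    """Return a copy of *s* with generic numbers, RSR values and metadata attached.

    ``generic_map`` columns: pdb_id, chain, seq_number, generic_number.
    ``rsr_table`` columns: pdb_id, chain, seq_number, rsr.
    ``metadata`` columns: pdb_id, receptor_id, state, resolution, partner_chains
    (semicolon list of ``chain=kind`` items, kind in {gprotein, ligand}).
    Metadata resolution always overrides the header value. Unmatched residues
    keep ``generic_number=None`` and are invisible to pathway analyses.
    """
    out = dataclasses.replace(
        s,
        residues=[dataclasses.replace(r) for r in s.residues],
        partner_entities=list(s.partner_entities),
        chains=list(s.chains),
    )

    gmap: dict[tuple[str, int], str] = {}
    per_chain_seen: dict[tuple[str, str], tuple[str, int]] = {}
    for _, row in _rows_for(generic_map, s.pdb_id).iterrows():
        chain, num, gn = str(row["chain"]), int(row["seq_number"]), str(row["generic_number"])
        prev = per_chain_seen.get((chain, gn))
        if prev is not None and prev != (chain, num):
            raise AnnotationConflictError(
                f"generic number {gn} assigned to residues {prev[1]} and {num} in chain {chain}"
            )
        per_chain_seen[(chain, gn)] = (chain, num)
        gmap[(chain, num)] = gn

    rsr_map: dict[tuple[str, int], float] = {}
    for _, row in _rows_for(rsr_table, s.pdb_id).iterrows():
        rsr_map[(str(row["chain"]), int(row["seq_number"]))] = float(row["rsr"])

    for r in out.residues:
        key = (r.chain_id, r.seq_number)
        if key in gmap:
            r.generic_number = gmap[key]
        if key in rsr_map:
            r.rsr = rsr_map[key]

    meta_rows = _rows_for(metadata, s.pdb_id)
    if len(meta_rows):
        row = meta_rows.iloc[0]
        if "receptor_id" in row and pd.notna(row["receptor_id"]):
            out.receptor_id = str(row["receptor_id"])
        if "state" in row and pd.notna(row["state"]):
            state = str(row["state"])
            if state not in STATE_LABELS:
                raise AnnotationConflictError(f"unknown state label {state!r}")
            out.state_label = state
        if "resolution" in row and pd.notna(row["resolution"]):
            out.resolution = float(row["resolution"])
        if "partner_chains" in row and pd.notna(row["partner_chains"]) and str(row["partner_chains"]):
            out = _move_partner_chains(out, str(row["partner_chains"]))
    return out


def _move_partner_chains(s: AnnotatedStructure, spec_str: str) -> AnnotatedStructure:
    """Move chains named ``"B=gprotein;C=ligand"`` out of the receptor into partners."""
    kinds: dict[str, str] = {}
    for item in spec_str.replace(",", ";").split(";"):
        item = item.strip()
        if not item:
            continue
        chain, _, kind = item.partition("=")
        kinds[chain.strip()] = (kind.strip() or "gprotein")
    moved: dict[str, list[AtomRecord]] = {}
    kept = []
    for r in s.residues:
        if r.chain_id in kinds:
            moved.setdefault(r.chain_id, []).extend(r.atoms)
        else:
            kept.append(r)
    partners = list(s.partner_entities)
    for chain, atoms in moved.items():
        partners.append(PartnerEntity(name=f"{kinds[chain]}_{chain}", kind=kinds[chain], atoms=atoms))
    return dataclasses.replace(
        s,
        residues=kept,
        partner_entities=partners,
        chains=[c for c in s.chains if c not in kinds],
    )


def apply_quality_filters(
    s: AnnotatedStructure,
    resolution_max: float = DEFAULT_RESOLUTION_MAX,
    rsr_max: float = DEFAULT_RSR_MAX,
) -> AnnotatedStructure:
    """Flag low-quality data: whole-structure rejection at resolution >= cutoff,
    per-residue exclusion at RSR strictly above the cutoff. Idempotent; never deletes."""
    out = dataclasses.replace(s, residues=[dataclasses.replace(r) for r in s.residues])
    if s.resolution is not None and s.resolution >= resolution_max:
        out.rejected = True
        out.rejection_reason = f"resolution {s.resolution:.2f} Å >= {resolution_max} Å"
    for r in out.residues:
        if r.rsr is not None and r.rsr > rsr_max:
            r.excluded = True
    return out


def quality_report(s: AnnotatedStructure) -> dict:
    """JSON-ready summary of parse counts and quality flags."""
    excluded = [
        {"chain": r.chain_id, "seq_number": r.seq_number, "label": r.label, "rsr": r.rsr}
        for r in s.residues
        if r.excluded
    ]
    return {
        "pdb_id": s.pdb_id,
        "receptor_id": s.receptor_id,
        "state": s.state_label,
        "resolution": s.resolution,
        "rejected": s.rejected,
        "rejection_reason": s.rejection_reason,
        "n_chains": len(s.chains),
        "n_residues": len(s.residues),
        "n_atoms": sum(len(r.atoms) for r in s.residues),
        "n_partner_entities": len(s.partner_entities),
        "n_excluded_residues": len(excluded),
        "excluded_residues": excluded,
    }


def format_atom_line(
    serial: int,
    atom_name: str,
    res_name: str,
    chain_id: str,
    seq_number: int,
    coords: Iterable[float],
    occupancy: float = 1.0,
    element: str = "C",
    altloc: str = "",
    record: str = "ATOM",
) -> str:
    """One fixed-column PDB coordinate line."""
    x, y, z = coords
    name = atom_name if len(atom_name) >= 4 else f" {atom_name:<3s}"
    return (
        f"{record:<6s}{serial:>5d} {name:<4s}{altloc or ' ':1s}{res_name:>3s} "
        f"{chain_id:1s}{seq_number:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def to_pdb_text(s: AnnotatedStructure) -> str:
    """Serialize retained atoms back to PDB text (coordinates at 3 decimals)."""
    lines = []
    if s.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {s.resolution:.2f} ANGSTROMS.")
    serial = 1
    for r in s.residues:
        for a in r.atoms:
            lines.append(
                format_atom_line(
                    serial, a.atom_name, r.aa_type, r.chain_id, r.seq_number,
                    a.coords, a.occupancy, a.element, a.altloc,
                )
            )
            serial += 1
    for p in s.partner_entities:
        for a in p.atoms:
            lines.append(
                format_atom_line(
                    serial, a.atom_name, p.name[:3].upper(), "Z", 1,
                    a.coords, a.occupancy, a.element, a.altloc, record="HETATM",
                )
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
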