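"""Packaged reference data for the published class A GPCR activation pathway.

The conserved-rearrangement analysis of the six receptors with paired
active/inactive crystal structures yields, in Round 1, 32 strict
intra-receptor pairs plus 5 receptor/G-protein pairs; six further pairs are
rescued under receptor-specific exceptions; Round 2 (family-wide t-test)
removes four pairs, leaving the canonical 34-pair / 35-residue pathway.
Those published lists are shipped here so downstream modules (state
descriptors, mutation mapping) work without any structure files.

The layer table and the TM3-TM6 / TM3-TM7 / Na+-pocket pair subsets are
reconstructions from the published per-layer descriptions (the source
enumerates layer membership only graphically); they are configurable
defaults, not measured quantities.
"""

from __future__ import annotations

from .positions import pair_key, split_pair

#: Round 1 strict selection: same sign of dRRCS and |dRRCS| > 0.2 in all six receptors.
ROUND1_STRICT_PAIRS: tuple[str, ...] = (
    "1×49:7×50", "1×53:7×53", "1×53:7×54", "2×37:2×40", "2×42:4×45",
    "2×43:7×53", "2×45:4×50", "2×46:2×50", "2×50:3×39", "2×57:7×42",
    "3×40:6×48", "3×43:6×40", "3×43:6×41", "3×43:7×49", "3×43:7×53",
    "3×46:6×37", "3×46:7×53", "3×49:3×50", "3×50:3×53", "3×50:6×37",
    "3×50:7×53", "3×51:5×57", "5×51:6×44", "5×58:6×40", "5×62:6×37",
    "6×40:7×49", "6×44:6×48", "7×50:7×55", "7×52:7×53", "7×53:8×50",
    "7×54:8×50", "7×54:8×51",
)

#: Receptor-side positions whose contact with the intracellular partner
#: (G protein or mimetic) appears on activation.
PARTNER_POSITIONS: tuple[str, ...] = ("3×50", "3×53", "3×54", "5×61", "6×33")

#: Na+-pocket pairs analysed for five receptors only: rhodopsin has no Na+ pocket.
NA_POCKET_EXEMPT_PAIRS: tuple[str, ...] = ("2×50:7×49", "6×44:7×45", "6×48:7×45")

#: Receptor exempted for the pairs above.
NA_POCKET_EXEMPT_RECEPTOR = "bRho"

#: Pairs failing in one receptor (kappa-OR) but confirmed by auxiliary
#: Gi-bound active/inactive receptor pairs (A1R, 5-HT1B).
AUXILIARY_RESCUED_PAIRS: tuple[str, ...] = ("3×46:3×50", "5×55:6×41", "7×45:7×49")

#: All six pairs rescued after the five-of-six analysis, with the rescue route.
RESCUED_PAIRS: dict[str, str] = {
    "2×50:7×49": "na_pocket_exemption",
    "6×44:7×45": "na_pocket_exemption",
    "6×48:7×45": "na_pocket_exemption",
    "3×46:3×50": "auxiliary_confirmation",
    "5×55:6×41": "auxiliary_confirmation",
    "7×45:7×49": "auxiliary_confirmation",
}

#: Round 2 removals: family-wide two-sample t-test p-values at or above 0.001.
ROUND2_REMOVED_PAIRS: dict[str, float] = {
    "2×37:2×40": 0.01,
    "2×42:4×45": 0.96,
    "2×45:4×50": 0.02,
    "2×57:7×42": 0.014,
}

#: Representative high-quality structure pairs used in Round 1
#: (receptor -> (inactive PDB, active PDB)).
REPRESENTATIVE_STRUCTURES: dict[str, tuple[str, str]] = {
    "bRho": ("1GZM", "3PQR"),
    "b2AR": ("2RH1", "3SN6"),
    "M2R": ("3UON", "4MQS"),
    "muOR": ("4DKL", "5C1M"),
    "A2AR": ("3EML", "5G53"),
    "kOR": ("4DJH", "6B73"),
}

#: Layer assignment for the 35 pathway residues (reconstruction; see module docstring).
#: 1: signal initiation (transmission switch + Na+ pocket); 2: hydrophobic-lock
#: opening; 3: microswitch rewiring; 4: G-protein coupling.
LAYER_OF: dict[str, int] = {
    # layer 1 — transmission switch (3×40, 5×51, 6×44, 6×48), Na+ pocket (2×50, 3×39, 7×45, 7×49)
    "2×50": 1, "3×39": 1, "3×40": 1, "5×51": 1,
    "6×44": 1, "6×48": 1, "7×45": 1, "7×49": 1,
    # layer 2 — hydrophobic lock (3×43, 6×40, 6×41) and its rewired partners
    "2×46": 2, "3×43": 2, "5×55": 2, "5×58": 2, "6×40": 2, "6×41": 2,
    # layer 3 — microswitches (6×37, 7×53) and the positions they rewire against
    "1×49": 3, "1×53": 3, "2×43": 3, "3×46": 3, "5×62": 3, "6×37": 3,
    "7×50": 3, "7×52": 3, "7×53": 3, "7×54": 3, "7×55": 3, "8×50": 3, "8×51": 3,
    # layer 4 — DRY release and G-protein-contacting positions
    "3×49": 4, "3×50": 4, "3×51": 4, "3×53": 4, "3×54": 4,
    "5×57": 4, "5×61": 4, "6×33": 4,
}

# --- state-descriptor pair subsets (reconstructed defaults, configurable) ---

TM3_TM6_PAIRS: tuple[str, ...] = ("3×43:6×40", "3×43:6×41", "3×46:6×37", "3×50:6×37")
TM3_TM7_PAIRS: tuple[str, ...] = ("3×43:7×49", "3×43:7×53", "3×46:7×53", "3×50:7×53")
#: Six residues / five pairs whose repacking reports Na+-pocket collapse.
SODIUM_POCKET_PAIRS: tuple[str, ...] = (
    "2×50:3×39", "2×50:7×49", "6×44:7×45", "6×48:7×45", "7×45:7×49",
)


def pathway_intra_pairs() -> list[str]:
    """The 34 intra-receptor pairs: strict minus Round-2 removals plus rescued."""
    kept = [p for p in ROUND1_STRICT_PAIRS if p not in ROUND2_REMOVED_PAIRS]
    return kept + list(RESCUED_PAIRS)


def pathway_residues() -> list[str]:
    """The 35 pathway residues: intra-pair positions plus partner-side positions."""
    seen: set[str] = set()
    for p in pathway_intra_pairs():
        seen.update(split_pair(p))
    seen.update(PARTNER_POSITIONS)
    from .positions import position_key

    return sorted(seen, key=position_key)


def _check() -> None:
    assert len(ROUND1_STRICT_PAIRS) == 32
    assert all(pair_key(*split_pair(p)) == p for p in ROUND1_STRICT_PAIRS)
    assert set(LAYER_OF) == set(pathway_residues())


_check()
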