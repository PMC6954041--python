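"""Mapping mutations onto the activation pathway and region enrichment.

Disease-associated and constitutively activating/inactivating mutations are
located by generic position and assigned to structural regions: the four
pathway layers, the ligand-binding pocket, the G-protein-coupling region, or
elsewhere. Two summaries follow: the percentage of mutations falling in each
region, and the mean number of mutations per residue of each region with
fold ratios relative to the pathway (the enrichment readout).

The packaged region annotation covers only the 35 pathway positions and
their layers; ligand-pocket and G-protein-region residue sets are
receptor-family curation choices and must be supplied by the user.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import reference
from .positions import SEP, is_generic

__all__ = [
    "MutationRecord",
    "RegionAnnotation",
    "read_mutation_table",
    "assign_region",
    "fraction_in_pathway",
    "enrichment_summary",
    "default_region_annotation",
]

PATHWAY_REGIONS = tuple(f"pathway_layer_{i}" for i in (1, 2, 3, 4))
CATEGORIES = ("disease", "CAM", "CIM", "other")

_AA_RE = re.compile(r"^[A-Z]$")


class MutationFormatError(ValueError):
    pass


@dataclass(frozen=True)
class MutationRecord:
    receptor_id: str
    generic_position: str
    wt_aa: str
    mut_aa: str
    category: str = "other"
    phenotype: str = ""

    def __post_init__(self) -> None:
        if not is_generic(self.generic_position):
            raise MutationFormatError(
                f"malformed generic position {self.generic_position!r}"
            )
        if not (_AA_RE.match(self.wt_aa) and _AA_RE.match(self.mut_aa)):
            raise MutationFormatError(f"bad amino-acid codes {self.wt_aa}>{self.mut_aa}")
        if self.wt_aa == self.mut_aa:
            raise MutationFormatError("wild-type and mutant amino acid are identical")

    @property
    def dedup_key(self) -> tuple[str, str, str]:
        return (self.receptor_id, self.generic_position, self.mut_aa)


@dataclass
class RegionAnnotation:
    """Region membership of generic positions plus region sizes (residue counts).

    ``region_of`` assigns each annotated position exactly one region label;
    ``residues_per_region`` gives the number of residues per region, needed
    for per-residue enrichment (the size of "other" cannot be inferred from
    the mapping and must be supplied for enrichment summaries).
    """

    region_of: dict[str, str]
    residues_per_region: dict[str, int] = field(default_factory=dict)

    def region(self, position: str) -> str:
        return self.region_of.get(position, "other")


def default_region_annotation(
    ligand_pocket: Iterable[str] = (),
    gprotein_region: Iterable[str] = (),
    n_other_residues: Optional[int] = None,
) -> RegionAnnotation:
    """Annotation with the packaged 35 pathway positions and optional
    user-supplied pocket/G-protein residue sets."""
    region_of = {pos: f"pathway_layer_{layer}" for pos, layer in reference.LAYER_OF.items()}
    for pos in ligand_pocket:
        region_of.setdefault(pos, "ligand_pocket")
    for pos in gprotein_region:
        region_of.setdefault(pos, "gprotein_region")
    counts: dict[str, int] = {}
    for region in region_of.values():
        counts[region] = counts.get(region, 0) + 1
    if n_other_residues is not None:
        counts["other"] = n_other_residues
    return RegionAnnotation(region_of=region_of, residues_per_region=counts)


def read_mutation_table(path_or_frame) -> list[MutationRecord]:
    """Read a mutation TSV (receptor, generic_position, wt, mut, category[, phenotype]).

    Rows with malformed positions or amino-acid codes are skipped with a
    warning naming the row, never silently."""
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame
    else:
        df = pd.read_csv(path_or_frame, sep="\t", dtype=str).fillna("")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                MutationRecord(
                    receptor_id=str(row["receptor"]),
                    generic_position=str(row["generic_position"]).replace("x", SEP),
                    wt_aa=str(row["wt"]),
                    mut_aa=str(row["mut"]),
                    category=str(row.get("category", "other") or "other"),
                    phenotype=str(row.get("phenotype", "") or ""),
                )
            )
        except (MutationFormatError, KeyError) as exc:
            warnings.warn(f"skipping mutation row {idx}: {exc}")
    return records


def assign_region(m: MutationRecord, ra: RegionAnnotation) -> str:
    """Deterministic single region label for one mutation."""
    return ra.region(m.generic_position)


def _dedup(muts: Sequence[MutationRecord]) -> list[MutationRecord]:
    seen: set = set()
    out = []
    for m in muts:
        if m.dedup_key not in seen:
            seen.add(m.dedup_key)
            out.append(m)
    return out


def fraction_in_pathway(
    muts: Sequence[MutationRecord], ra: RegionAnnotation
) -> dict[str, float]:
    """Percentage of (deduplicated) mutations per region.

    The aggregate ``"pathway"`` entry sums the four layer regions; region
    percentages other than the aggregate sum to 100.
    """
    muts = _dedup(muts)
    if not muts:
        raise ValueError("mutation list is empty")
    counts: dict[str, int] = {}
    for m in muts:
        region = assign_region(m, ra)
        counts[region] = counts.get(region, 0) + 1
    total = len(muts)
    pct = {region: 100.0 * n / total for region, n in counts.items()}
    pct["pathway"] = sum(pct.get(r, 0.0) for r in PATHWAY_REGIONS)
    return pct


def enrichment_summary(
    muts: Sequence[MutationRecord], ra: RegionAnnotation
) -> pd.DataFrame:
    """Mean mutations per residue for each region and fold vs the pathway.

    The pathway rows (layers 1-4) are pooled into one ``pathway`` row whose
    mean is the reference of the fold column. Regions of size zero are
    excluded with a warning.
    """
    muts = _dedup(muts)
    if not muts:
        raise ValueError("mutation list is empty")
    counts: dict[str, int] = {}
    for m in muts:
        counts[assign_region(m, ra)] = counts.get(assign_region(m, ra), 0) + 1

    sizes = dict(ra.residues_per_region)
    pooled_counts = {"pathway": 0}
    pooled_sizes = {"pathway": 0}
    for region in set(counts) | set(sizes):
        if region in PATHWAY_REGIONS:
            pooled_counts["pathway"] += counts.get(region, 0)
            pooled_sizes["pathway"] += sizes.get(region, 0)
        else:
            pooled_counts[region] = counts.get(region, 0)
            pooled_sizes[region] = sizes.get(region, 0)

    rows = []
    for region in sorted(pooled_counts):
        size = pooled_sizes.get(region, 0)
        if size == 0:
            warnings.warn(f"region {region!r} has no residues; excluded from enrichment")
            continue
        rows.append(
            {
                "region": region,
                "n_mutations": pooled_counts[region],
                "n_residues": size,
                "mean_per_residue": pooled_counts[region] / size,
            }
        )
    df = pd.DataFrame(rows)
    ref_rows = df[df["region"] == "pathway"]
    ref = float(ref_rows["mean_per_residue"].iloc[0]) if len(ref_rows) else float("nan")
    df["fold_vs_pathway"] = ref / df["mean_per_residue"]
    return df
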