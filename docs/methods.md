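# Methods

## Contact score

The atomic contact score is a plateau–linear–plateau function of heavy-atom
distance: 1 at or below `d_plateau`, 0 at or above `d_zero`, linear between.
The defaults `d_plateau = 3.23 Å`, `d_zero = 4.63 Å` follow the released
scoring code of the original analysis; they are configurable
(`ContactParams`, or a JSON file for the CLI) because the primary
literature describes the functional form but not the numeric cutoffs. The
residue-pair score sums this function over all inter-residue heavy-atom
pairs. Hydrogens are removed at parse time; the score is therefore
insensitive to whether a deposition includes them.

Occupancy weighting: each atom-pair contribution is multiplied by
`occ_a · occ_b` and summed over all alternate-location combinations. We do
not restrict to matching altloc labels (A with A): this is the simplest
reading of occupancy-weighted summation, and with complementary occupancies
it bounds the score between the pure-A and pure-B conformers. A
label-matched variant would change scores only for residues whose altlocs
are correlated; structures in this family rarely annotate that.

Adjacency rule: residue pairs separated by at most `adjacency_window = 4`
sequence positions count side-chain atoms only (backbone N, CA, C, O
excluded on both sides), since backbone contacts of near neighbours are
invariant under activation and would swamp the signal of side-chain
rewiring (e.g. the intra-helical D/E3×49–R3×50 disengagement). Sequence
separation is the absolute residue-number difference within a chain;
cross-chain and residue-versus-partner pairs always use all heavy atoms.

Structure tables: scores are computed within each receptor chain and
chain-averaged, where a pair is averaged only over chains in which both
positions are present and unexcluded — a chain missing a position does not
push the average toward zero. The bound ligand and the intracellular
partner (G protein or mimetic; possibly several chains merged per kind) are
each treated as one pseudo-residue. A bounding-sphere prescreen skips
residue pairs that provably score zero; tests enforce exact agreement with
an exhaustive double-loop recomputation, so the prescreen is an
optimization, never an approximation.

Missing versus zero: residues flagged by the quality filters (structure
resolution ≥ 3.8 Å → whole structure rejected; residue RSR > 0.35 →
residue excluded, both strict rules on the stated side of the boundary)
produce *missing* scores. A pair absent from a table because its residues
simply do not touch scores 0; a pair touching an excluded residue is NaN in
group statistics and dropped from ΔRRCS records. Conflating the two would
bias the family-wide t-test toward zero in poorly resolved regions.

## Two-round discovery

Round 1 operates on receptors with paired representative active/inactive
structures. A pair is kept when ΔRRCS has the same sign and |ΔRRCS| > 0.2
in *every* receptor (strict inequality at the boundary). Pairs passing in
all but one receptor are rescue candidates; a candidate is rescued when
(a) the failing receptor is exempted for that pair (packaged default:
rhodopsin for the three Na⁺-pocket pairs, as rhodopsin has no Na⁺ pocket),
or (b) every auxiliary receptor pair supplied for confirmation passes the
same sign-and-cutoff test. Candidates failing in two or more receptors are
never rescued. Partner pairs are receptor positions whose contact with the
intracellular partner exceeds the cutoff in every active structure and is
absent in inactive structures (which carry no bound partner).

Round 2 treats each structure in the family-wide inactive and active groups
as one observation and applies a two-tailed two-sample t-test per pair.
The default is Student's pooled-variance test — the plain reading of
"two-sample t-test" — with Welch available via `equal_var=False`. One
structure = one observation means receptors with many depositions weigh
more (pseudo-replication); this mirrors the published procedure and is
surfaced here rather than corrected. No multiple-testing correction is
applied, again matching the published procedure; the α = 0.001 gate and the
stricter 1e-5 reporting tier are both visible in the per-pair results.
Degenerate input (both groups constant and equal) is reported as
no-difference with p = 1 by convention.

Receptor-specific exemptions carry into Round 2: structures of an exempt
receptor are dropped from the test of the exempted pairs.

The packaged reference lists (32 strict pairs, 6 rescued pairs, 5 partner
positions, the 4 pairs removed in Round 2 with their printed p-values)
reconstruct the published analysis so that downstream modules work with no
structure files; assembling them through the same `assemble_pathway` logic
yields 34 intra-receptor pairs and 35 residues.

Layer table: the published pathway figure assigns the 35 residues to four
layers graphically; the packaged table is a reconstruction from the
per-layer text (layer 1: transmission switch 3×40/5×51/6×44/6×48 and Na⁺
pocket 2×50/3×39/7×45/7×49; layer 2: hydrophobic lock 3×43/6×40/6×41 and
its rewired partners 2×46/5×55/5×58; layer 3: microswitches 6×37 and 7×53
with the positions they rewire against; layer 4: the DRY positions
3×49–3×51 and G-protein-contacting 3×53/3×54/5×57/5×61/6×33). It is
replaceable via `PathwayDiscovery(layer_table=...)`.

## State descriptors

The TM3–TM6 and TM3–TM7 interface scores sum the pathway's inter-helical
pairs on each interface. The published analysis names the two axes but not
their member pairs; the defaults here take the pathway pairs linking TM3
positions (3×43, 3×46, 3×50) to TM6 (6×37, 6×40, 6×41) and TM7 (7×49,
7×53) respectively, and the Na⁺-pocket score uses the five pathway pairs
among the six pocket residues. All three subsets are constructor arguments.
Classification thresholds (`tau_zero = 0.05`, `tau_active = 0.2`) are a
tooling choice: the original analysis labels states by bound ligand and
partner, not by score; the defaults separate the two described clusters
(active: TM3–TM6 strictly zero, TM3–TM7 formed; inactive: TM3–TM7 at or
near zero) with margin.

## Mutation mapping

Mutations are deduplicated on (receptor, generic position, mutant amino
acid) — the merged public databases overlap, and this key is the finest one
available in all of them. Region assignment is a single deterministic
label; pathway layers take precedence over user-supplied ligand-pocket or
G-protein-region sets, so the regions partition the annotated positions.
Enrichment is mutations-per-residue per region, with folds relative to the
pooled pathway; region sizes must be supplied for non-pathway regions
because residue universes differ by receptor family. The packaged
annotation covers only the 35 pathway positions — pocket and G-protein
residue sets are curation choices we deliberately do not hard-code, which
also means the published 28%/20%/7% split and 2.5/3.5/3.5-fold enrichment
are reproducible only with the externally curated mutation and region
tables supplied as input.

## Synthetic cohorts

The generator emulates the study design, not protein physics: six receptors
with paired representative structures, family groups of 140 inactive and 27
active structures, ten planted rearrangements of |Δ| = 1.0 (alternating
gained and lost contacts), Gaussian score noise of sd 0.05, and ~150
background contact pairs whose level is constant across states. Score mode
realizes structures directly as score tables; geometry mode writes PDB text
whose single CB–CB atom pair per planted contact realizes the requested
score exactly (which bounds geometric effect sizes at |Δ| ≤ 1 per pair).
One seed drives a hierarchical stream (cohort → receptor → structure), so
fixed seeds give byte-identical PDB output.

What passing these tests shows — and does not: recovery of the planted set
at these settings demonstrates the selection logic and its boundary
behaviour, not performance on real ensembles, where noise is structural
(refinement error, crystal contacts, missing side chains) rather than
additive Gaussian, and where receptors are unevenly sampled. The
no-noise identity and unbiasedness checks show the generator itself does
not leak the answer through systematic offsets.

## Numerical choices

* Scores are kept at full double precision; comparisons against printed
  two-decimal values use absolute tolerance 0.01.
* Pair keys are canonical sorted "a:b" strings ordered by (helix, index),
  so tables are symmetric by construction.
* Insertion codes are part of residue identity; insertion-code twins that
  map to the same generic pair key have their scores summed.
* Zero-occupancy atoms are dropped at parse time (they carry no weight and
  often mark unmodelled density).
* The t-test with a constant-and-equal pair of groups returns p = 1;
  constant-but-different groups return p = 0.

## Problem sizes

Tests and the acceptance script run at desk scale: random oracle fixtures
of ~8 residues × 100 structures, planted cohorts of 6 receptors with
40 positions and 140 + 27 score-mode structures over 20 seeds, geometry
cohorts of ~20 positions and a dozen structures, 30 replicate draws of 435
uniform mutations. These sizes were chosen to exercise every code path and
statistical contract at comfortable interactive latency.

## Known limitations

* No atom-type or orientation weighting in the contact function (by design:
  such parameterizations are arbitrary in a lipid environment and the
  distance-only score already captures the rearrangement signal).
* No water-mediated or energy-interpreted contacts.
* Generic numbers must be supplied; the package never infers them from
  sequence.
* Multi-model (NMR-style) files are handled by selecting one model
  (`model_index`, default first); models are never averaged.
* Layer and interface pair memberships are documented reconstructions, not
  published enumerations.
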