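# rrcskit

Quantitative residue-contact analysis of receptor activation. `rrcskit`
computes **residue–residue contact scores (RRCS)** from heavy-atom
coordinates, the contact rewiring between conformational states
(**ΔRRCS = RRCS_active − RRCS_inactive**), and discovers family-wide
conserved contact rearrangements across ensembles of class A
G-protein-coupled receptor (GPCR) structures. It is aimed at structural
bioinformaticians studying activation mechanisms, and at anyone who needs a
finer-grained alternative to Boolean residue-contact maps.

## The score

For residues *i*, *j* the contact score sums a plateau–linear–plateau
atomic score over all inter-residue heavy-atom pairs, weighted by
occupancies:

    RRCS(i,j) = Σ_{a∈i} Σ_{b∈j}  f(d_ab) · occ_a · occ_b

    f(d) = 1                         d ≤ 3.23 Å
         = (4.63 − d) / 1.40         3.23 Å < d < 4.63 Å
         = 0                         d ≥ 4.63 Å

(a form adopted from the hydrophobic term of ChemScore). Residue pairs
within four sequence positions count side-chain atoms only; structures with
several receptor chains are chain-averaged; a bound ligand or G protein is
treated as a single pseudo-residue. Quality control flags whole structures
at resolution ≥ 3.8 Å and residues with real-space R-value > 0.35 — flagged
residues yield *missing* scores, never zeros.

On top of the score the package implements:

* **Two-round discovery** — Round 1 keeps pairs with same-sign |ΔRRCS| > 0.2
  in every receptor with paired active/inactive structures (with
  receptor-specific rescue rules, e.g. rhodopsin lacks the Na⁺ pocket);
  Round 2 keeps pairs whose per-structure RRCS separates the family-wide
  inactive and active ensembles (two-sample t-test, p < 0.001). The packaged
  published result is the 34-pair / 35-residue activation pathway in four
  layers.
* **State descriptors** — RRCS summed over TM3–TM6 and TM3–TM7 interface
  pairs places any structure in a 2D plane where inactive and active states
  form separable clusters; a Na⁺-pocket score reports pocket collapse.
* **Mutation mapping** — disease/CAM/CIM mutations assigned to pathway
  layers and regions, with per-residue enrichment folds.
* **Synthetic cohorts** — generators that plant known contact
  rearrangements, at score level or as full PDB files, so the whole
  pipeline is testable without downloading structures.

## Worked example

```python
import rrcskit as rk

# a two-residue structure whose single side-chain contact sits at 3.93 Å,
# the midpoint of the linear ramp
pdb_text = rk.make_toy_pair_pdb(3.93)
structure = rk.parse_structure(pdb_text)
table = rk.structure_rrcs(structure)
print(table.averaged)            # {'1:11': 0.49999999999999983}

# plant ten conserved rearrangements (Δ = 1.0, score noise sd 0.05) in a
# six-receptor cohort with 140 inactive / 27 active structures, then rerun
# the two-round discovery
sim = rk.simulate_cohort(rk.CohortSpec(seed=7))
est = rk.PathwayDiscovery().fit(sim.cohort)
print(len(est.pathway_.intra_pairs))          # 10
print(set(est.pathway_.pair_names) == set(sim.truth))  # True
```

The first block prints the pair's score `0.499…`: the single CB–CB atom pair
sits halfway down the linear ramp and both occupancies are 1. The second
block recovers exactly the ten planted pairs — Round 1 screens the
per-receptor ΔRRCS, Round 2 confirms each survivor on the family-wide
groups, and nothing else passes.

From the shell:

```sh
rrcskit simulate cohort/ --seed 5            # synthetic PDBs + truth
rrcskit pathway cohort/ --out pathway.json   # two-round discovery
rrcskit rrcs cohort/R0I0.pdb --generic-map cohort/generic_map.tsv \
        --metadata cohort/metadata.tsv       # score table as TSV
rrcskit state cohort/R0A0.pdb --generic-map cohort/generic_map.tsv \
        --metadata cohort/metadata.tsv       # 2D descriptors + state call
```

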