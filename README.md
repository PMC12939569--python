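# collapep

In-silico prospecting of angiotensin-converting-enzyme (ACE) inhibitory
peptides from collagen α-chains.

ACE converts angiotensin I to the vasoconstrictor angiotensin II, so
inhibiting it lowers blood pressure; food-derived peptides that inhibit ACE
are a practical alternative to synthetic inhibitors such as lisinopril.
Collagen — two α1(I) chains and one α2(I) chain per triple helix — is a
rich precursor of such peptides, and computational screening can shortlist
candidates long before any wet-lab hydrolysis. `collapep` implements that
screening workflow end to end for bioinformaticians working on food-derived
bioactive peptides:

1. **Sequence preprocessing** (`seqmodel`) — FASTA loading, signal-peptide
   trimming from annotation (a SignalP-style TSV), chain stoichiometry.
2. **Simulated proteolysis** (`digestion`) — enzyme cleavage specificities
   expressed over the P2/P1/P1′/P2′ bond context, single- and multi-enzyme
   (simultaneous) digestion, the theoretical degree of hydrolysis
   *DH*<sub>T</sub> = *d*/*D* × 100 (cleaved over total peptide bonds), and
   combinatorial enzyme-cocktail ranking.
3. **Bioactivity profiling** (`bioprofile`) — the occurrence frequency of
   bioactive fragments *A* = *a*/*N* against an activity-annotated
   reference peptide database, both for intact precursors (overlapping
   substring occurrences) and for hydrolysates (released-fragment
   multiplicity), pooled 2:1 across the α1/α2 chains.
4. **Candidate screening** (`screen`) — a fixed cascade
   novelty → toxicity/allergenicity → activity-classifier vote → docking
   energy, consuming external tool exports as TSVs and keeping a complete
   per-peptide audit trail. Docking selection keeps peptides whose
   −CDOCKER energy (−CE) and −CDOCKER interaction energy (−CIE) both
   exceed a reference ligand's.
5. **Property panel** (`pepprops`) — average molecular weight, side-chain
   net charge, Henderson–Hasselbalch isoelectric point (bisection,
   configurable pKa set), scale-labelled hydrophobicity.
6. **Network pharmacology** (`netpharm`) — confidence-filtered
   protein–protein-interaction graphs, the eight CytoHubba-style
   centralities (MCC, MNC, Degree, EPC, Closeness, Betweenness, Radiality,
   Stress), strict top-k hub consensus, and hypergeometric fold-enrichment.
7. **Synthetic data** (`synthdata`) — seeded generators for collagen-like
   Gly-X-Y chains with planted reference peptides, annotation tables with
   planted pass/fail outcomes, and hub-planted interaction graphs, each
   with machine-readable ground truth.

## Worked example

The four collagen-derived candidate peptides that survive the full screen
of the bundled 27-peptide panel, through the property panel:

```sh
$ collapep props --sequences QICVCDS,DVWK,IIEY,APMDVG
QICVCDS  MW=766.89  charge=-1  pI=3.75  hydrophobicity=5.90 (kyte-doolittle-sum)
DVWK     MW=546.63  charge=+0  pI=6.34  hydrophobicity=-4.10 (kyte-doolittle-sum)
IIEY     MW=536.63  charge=-1  pI=3.85  hydrophobicity=4.20 (kyte-doolittle-sum)
APMDVG   MW=588.68  charge=-1  pI=3.75  hydrophobicity=2.40 (kyte-doolittle-sum)
```

All four are short (4–7 residues) and below 1 kDa, the size range where ACE
inhibition is typically strongest; three are acidic (net charge −1, pI < 4)
while DVWK is near-neutral, consistent with a binding mode dominated by
hydrophobic contacts rather than electrostatics.

A fully synthetic end-to-end run (no downloads; every count is checked
against the generator's ground truth):

```sh
$ collapep synth --seed 11 --outdir demo --n-candidates 107 --n-known 2 \
      --plant "VY:ACE inhibitor:2"
wrote demo; cascade counts {'input': 107, 'novelty': 105, 'safety': 103, 'activity': 27, 'docking': 4}

$ collapep pipeline --datadir demo --out report.json
[
  {"stage": "novelty",  "in": 107, "out": 105},
  {"stage": "safety",   "in": 105, "out": 103},
  {"stage": "activity", "in": 103, "out": 27},
  {"stage": "docking",  "in": 27,  "out": 4}
]
```

Reading the counts: 2 of the 107 generated peptides were planted as
already-catalogued ACE inhibitors (dropped by the novelty stage), one
planted toxic and one planted allergenic record fall at the safety stage,
27 carry at least one "high activity" classifier vote, and 4 beat the
reference ligand on both docking energies. `report.json` also carries the
per-chain digest statistics, pooled *DH*<sub>T</sub>, precursor/release *A*
values, input hashes, and a property-panel row per selected peptide.

Library use mirrors the CLI:

```python
import collapep as cp

panel = cp.bundled_candidate_panel()
selected = cp.docking_select(panel, cp.LISINOPRIL)
print([r.sequence for r in selected])
# ['QICVCDS', 'DVWK', 'IIEY', 'APMDVG']

hubs = cp.consensus(cp.bundled_hub_lists())
print(sorted(hubs.members))
# ['BCL2', 'HSP90AA1', 'SRC', 'STAT3']
```

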