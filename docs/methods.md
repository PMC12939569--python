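# Methods

This note documents the models, conventions and numerical choices behind
`collapep`, and what its synthetic tests do and do not establish about real
data.

## Sequence model and coordinates

Chains are strings over the 20 standard amino acids plus `X` (unknown).
`X` is legal but inert: it matches no reference peptide, and no peptide
bond adjacent to an `X` is ever cleaved, so an unknown residue can only
make results more conservative. User-facing coordinates are 1-based
inclusive (the biology convention); peptide-bond indices are 0-based, bond
*i* sitting between residues *i* and *i*+1, which keeps site/fragment
arithmetic off-by-one-free.

Signal peptides are removed by annotation, not prediction: a two-column
TSV (chain id, 1-based last signal residue) matching a SignalP export. All
downstream statistics are defined on the mature chain; digestion refuses
untrimmed chains rather than silently including the signal.

Type I collagen assembles two α1 chains with one α2 chain, so pooled
statistics (*A*, *DH*<sub>T</sub>) are copy-number-weighted means with
weights 2:1 by default, carried on the chain's `copy_number`.

## Simulated proteolysis

An enzyme rule is a disjunction of cleavage specs minus a disjunction of
exception specs, each spec constraining any subset of the P2/P1/P1′/P2′
positions around the scissile bond to a residue set. A constraint placed
on an out-of-range position (chain terminus) fails, so e.g. a P2
requirement can never be met at the first bond. Multi-enzyme digestion is
simultaneous: the site set is the union of per-enzyme sites, matching the
"enzymes acting together" semantics of simulated-hydrolysis databases
rather than sequential re-digestion.

The theoretical degree of hydrolysis is *DH*<sub>T</sub> = *d*/*D* × 100
with *d* cleaved and *D* = length − 1 total bonds; a single-residue chain
has no bonds and is rejected rather than reported as 0/0.

The shipped enzyme table covers trypsin, chymotrypsin A, pancreatic
elastase, papain, ficin, stem bromelain and calpain 2. The serine-protease
entries follow the classical PeptideCutter encodings. The cysteine
proteases have broad subsite-driven specificities with no published
database encoding; the shipped entries are simplified encodings of their
reported subsite preferences, and the YAML is deliberately user-editable
because fragment-level counts (number of distinct peptides, their length
distribution) are sensitive to the encoding. Any fragment-count comparison
against an external simulator should therefore start with a rule-table
audit, not a tolerance adjustment.

Distinct-fragment statistics collapse duplicates by sequence; positional
records are kept separately. Length-1 fragments (free amino acids) are
counted in the length distribution but excluded from peptide-level
screening, since free amino acids are not ACE-inhibitory peptides.

Combinatorial cocktail search enumerates all 2- and 3-enzyme subsets of a
selected enzyme list and ranks by the release frequency of the target
activity, ties broken by higher *DH*<sub>T</sub>, then lexicographic
enzyme names — a deterministic total order.

## Occurrence-frequency profiling

*A* = *a*/*N* with *N* the mature-chain residue count. For precursor
profiling, *a* counts positional substring occurrences of reference
peptides, overlaps allowed (a `distinct-patterns-only` switch exists
because databases differ on this; overlapping is the default as the most
literal reading of "number of fragments with the activity"). For
hydrolysates, *a* counts released fragments whose sequence is catalogued,
with positional multiplicity. *A* is a per-residue frequency, not a
probability, and is intentionally not clamped at 1.

Matching runs on an Aho–Corasick automaton built per activity class; a
property test holds it equal to a naive quadratic scan on random inputs.
The bundled reference set contains the collagen-released di-/tripeptide
ACE inhibitors of a public-database snapshot plus literature-reported
peptides (including VY, IC50 5.2 µM); one dipeptide that appears twice in
its source listing is deduplicated at load with a logged warning.

## Screening cascade

Stages run in fixed order — novelty, safety, activity, docking — and a
peptide rejected at stage *k* receives no later-stage decisions, so every
input ends in exactly one terminal state and stage counts are
non-increasing. All predictions (toxicity, allergenicity, activity votes,
docking energies) are ingested tool exports; the cascade never re-predicts.

* Novelty: exact full-sequence match against the reference DB.
* Safety: keep iff non-toxic AND non-allergenic. Strict mode (default)
  rejects unannotated peptides; permissive mode passes them, for partial
  annotation tables.
* Activity: keep iff at least one of the three classifier votes
  (logistic regression, SVM, MLP) is "high" — an any-of-three OR, the
  inclusive screening convention.
* Docking: keep iff both −CE and −CIE strictly exceed the reference
  ligand's. "Higher binding energy than the control" is ambiguous between
  −CIE-only and both-energies; both-strict is the conservative reading,
  and on the bundled panel the two readings select the same four
  peptides. Output is sorted by −CIE descending.

The minimum candidate length is 2 (free amino acids excluded); no maximum
is imposed. External label vocabularies are normalised through a
configurable mapping (e.g. "high activity" → `high`,
"low & non-activity" → `low_non`), not hard-coded per tool.

## Property panel

* **Molecular weight**: sum of standard average residue masses plus one
  water (18.02 Da), reported to 2 decimals; monoisotopic masses behind a
  flag. Average masses are the convention that matches peptide-panel
  reports from web calculators.
* **Net charge**: (#K + #R) − (#D + #E), side chains only, at neutral pH.
  Histidine (pKa ≈ 6) and the termini are deliberately excluded — the
  common "charge at pH 7" shorthand for peptide panels.
* **Isoelectric point**: bisection on pH ∈ [0, 14] of the
  Henderson–Hasselbalch net charge over termini and the D/E/C/Y/H/K/R
  side chains, tolerance 1e-4 pH; the returned pH has |charge| < 1e-3.
  The default pKa set is the EMBOSS table; web calculators use varying
  sets, so cross-tool pI comparisons should allow roughly ±1 pH unit.
  The charge is strictly decreasing in pH, so the root is unique.
* **Hydrophobicity**: reported per named residue scale (Kyte–Doolittle
  sum and mean ship by default; custom scales register at run time). The
  scale label travels with the value because published "hydrophobicity in
  kcal/mol" panels use undocumented scales that cannot be reproduced from
  the number alone — this panel makes no claim to match them.

## Network pharmacology

Edges are kept when their confidence score strictly exceeds the threshold
(default 0.9, the "highest confidence" STRING convention); scores are then
discarded and all path-based methods run unweighted. Isolated nodes drop
at load.

Centralities follow the CytoHubba definitions: Degree; MNC (largest
connected component of the open neighbourhood); MCC (sum over maximal
cliques containing the node of (|C|−1)!); harmonic Closeness (Σ 1/d);
unnormalized Betweenness; Stress (count of shortest paths with the node
interior, computed from per-source BFS distance/path-count tables);
Radiality, computed per connected component as
diameter + 1 − mean distance to the other members (the component-local
convention; conventions differ on multi-component graphs, so this one is
documented and oracle-tested rather than claimed bit-identical to any GUI
tool); and EPC, the Monte-Carlo mean size of the node's component when
each edge is retained independently with probability 0.5 (default 1000
repetitions, explicit seed mandatory — the stochastic score is otherwise
irreproducible). The seven deterministic methods are verified against
exhaustive brute-force enumeration on every connected graph with ≤ 7
nodes (the networkx Graph Atlas, 995 graphs); EPC is verified against the
exact expectation obtained by summing over all 2^E edge subsets on graphs
with ≤ 10 edges, both pointwise (4000 repetitions, 5% relative) and by
rank agreement (Spearman ≥ 0.9 at 1500 repetitions). Full 7-node graphs
reach 2^21 subsets, so the exact-EPC check is restricted to the
low-edge-count atlas slice.

Hub consensus is the strict intersection of the eight top-k lists
(k = 10 by default); ties inside a list break lexicographically on gene
symbol, since published hub tables state no tie rule. Note EPC ties are
real on dense graphs: every node that survives percolation in the giant
component every repetition scores identically, so consensus on dense
graphs can be driven by tie-breaking — one reason the synthetic graphs
are sparse (below).

Enrichment is plain fold enrichment (k/n)/(K/N) with an upper-tail
hypergeometric p-value. This is not the EASE-adjusted statistic some
enrichment servers report, and it is labelled as such.

## Synthetic data

The generator emulates the study-shaped inputs: by default 2 chains of
1000 residues with a 22-residue signal peptide (a typical collagen
preprotein signal length) and 90% Gly-X-Y triplet content with a
proline-rich X/Y pool; screening cascades of 107 candidates with 1 planted
toxic and 1 planted allergenic record, 27 planted high-activity calls and
4 planted docking passes; and 112-node interaction graphs with 4 planted
hubs wired to 30% of a preferential-attachment background. Each artifact
draws from its own RNG stream derived from the master seed by a stable
label, so generators are independently reproducible and adding one never
perturbs another.

The background graph is tree-like (attachment parameter 1) on purpose:
edge percolation at keep-probability 0.5 must actually fragment the graph
for EPC to separate planted hubs from well-connected background nodes
(see the tie caveat above).

What the generator does **not** emulate: real collagen repeat
periodicity, hydroxyproline chemistry, realistic docking-energy
distributions, classifier error structure, or scale-free degree exponents
matched to real interactomes. Passing the planted-recovery and
cascade-count tests therefore shows the pipeline's bookkeeping and
algorithms are correct, not that any particular biological discovery
would replicate; conclusions about a real protein require its real
sequence, a curated reference snapshot, and real tool exports spliced in
at the documented TSV boundaries.

Test problem sizes (20 seeds, 60-candidate cascades, 300–600-residue
chains, ≤ 7-node oracle graphs) were chosen as the smallest sizes at
which every planted structure is non-trivially exercised.

## Known limitations

* Cysteine-protease cleavage encodings are simplified; distinct-fragment
  counts are encoding-sensitive (see the rule-table audit note above).
* The pI depends on the pKa set; only same-set comparisons are exact.
* Hydrophobicity values are scale-relative by design.
* The reference database ships as a small snapshot; occurrence
  frequencies against a different snapshot will differ, and users should
  supply their own TSV for any quantitative comparison.
* Radiality and EPC conventions vary across tools; ours are documented
  and oracle-tested but not guaranteed bit-identical to GUI plugins.
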