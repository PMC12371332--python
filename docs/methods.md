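# Methods

## Problem and model

The package automates the curation step between geometric pocket detection
and docking setup: deciding which of the many cavities a detector reports
are the literature-supported binding sites, and giving those sites a clean
volumetric definition. The model of the problem has three layers — a
text layer (binding-site descriptions in articles, as residue lists), a
sequence/structure layer (those residues resolved onto a specific PDB
entry), and a geometry layer (alpha-sphere pockets and grids). Each layer
only trusts the previous one up to explicit thresholds, because every
hand-off is noisy: language models hallucinate and split sites, papers
misnumber residues and misname chains, and geometric detectors fragment or
fuse physical sites.

## Extraction stages

Relevance assessment, extraction and refinement all run over a single
`complete(prompt, document)` backend; prompts are editable text assets that
demand an answer inside a fenced JSON block. The parser takes the first
valid block and re-asks up to `retries` times (default 2) before raising —
a deliberate loud failure rather than a guess. Documents are prompted
whole; a configurable character budget (default 600 000) raises instead of
silently truncating. Residue tokens are validated against a fixed grammar
(`A:TYR:123`, `TYR123`, `Y123`, optional insertion-code suffix; standard
amino acids plus MSE/SEC/PYL and a few phospho/hydroxy variants); invalid
tokens are dropped with warnings and a pocket survives while at least one
valid residue remains. Refinement may merge, split, drop or augment
pockets; if its backend call fails the unrefined output is kept (flag to
disable). The mock backend is keyed by `(stage, doc_id)` — stage read from
a machine-readable `TASK CODE:` line in the prompt, document resolved by
exact text match — so the whole pipeline is bit-reproducible offline.

## Matching and metrics

The matching criterion between an extracted and an annotated pocket is
annotated-residue recall |A∩E|/|A| with greedy one-to-one assignment in
decreasing overlap (ties broken by annotated then extracted index) and an
inclusive threshold, default 0.5; a zero-overlap pair never matches, so at
threshold 0 "any nonzero overlap" pairs. Greedy was chosen over optimal
assignment for transparency; a brute-force maximum-cardinality oracle in
the test suite confirms they agree whenever overlap values are distinct.
Pocket Recall pools counts across papers by default (a macro option
exists); residue precision/recall/F1 are macro-averaged over matched pairs
only, since unmatched pockets are already penalized at the pocket level.
Degenerate denominators are defined, not NaN: no extracted pockets ⇒
specificity 1.0; no annotated pockets ⇒ recall 1.0; empty extracted residue
set ⇒ precision 0.

## Residue mapping

Chain similarity is positional — the fraction of pocket residues whose
(number, insertion code) exists in the chain with an agreeing name — not an
alignment; this is cheap, robust for the deposited-construct use case, and
an optional ±k constant-offset scan (default off) covers renumbered
constructs. Quoted chain ids are only a tie-breaking hint. The chain
threshold is 0.6 and the cluster-match threshold 0.7, both inclusive.
Clustering uses MeanShift on heavy-atom centroids (representative point
chosen over Cα to survive residues without Cα in idealized fixtures);
MeanShift needs no preset cluster count and is deterministic given input
order. The bandwidth default is 8 Å — roughly the diameter of a small
binding site — and is configurable. Cluster-to-pocket overlap is
normalized by pocket size (the question is whether the cluster represents
the pocket); when a pocket maps to several candidate chains, residue
identity for this comparison drops the chain (numbers + icodes only),
because the chain assignment is exactly what is ambiguous. A matched
cluster spanning ≥2 chains yields one interface pocket per such cluster;
otherwise the mapped residues are replicated per candidate chain. A
cluster matching several pockets goes to the first by pocket order.

## Geometric selection, merging

"In contact" for atom vs alpha sphere is center-within (radius +
contact_tol), default tolerance 1.0 Å: Fpocket's own four-atom tangency is
not recoverable from its output files, so a distance rule with a small
slack is used. Residue membership in a geometric pocket needs a contact
fraction ≥ residue_match (default 0.5) and at least one contacting atom.
Selection keeps a geometric pocket when its residue-set Jaccard with some
mapped pocket is ≥ pocket_match (default 0.3, inclusive — a "minimum");
merging joins pockets whose Jaccard strictly exceeds merge_overlap
(default 0.5 — an "exceeds") or that share a supporting literature pocket,
closed transitively with union–find. Shared-support merging is what
re-unifies detector-fragmented sites and blends multiple papers describing
one physical site; sphere sets union without duplication (keyed on rounded
center + radius). Jaccard was preferred over recall-normalized overlap for
merging because it is symmetric. The residue_match/pocket_match/
merge_overlap defaults are this package's documented choices, exposed in
`PipelineConfig`.

## Grids

The lattice has 1.5 Å spacing, is anchored at the per-axis minimum of the
pocket heavy atoms and includes the max face when it lands on a node (a
zero-extent axis degenerates to one layer with a warning). Memberships:
inside-sphere and inside-hull are inclusive (≤, boundary kept, ε = 1e-9);
Van der Waals pruning is strict (< radius removed), per-element Bondi-type
radii with a 1.70 Å carbon-like fallback for unknown elements. The hull is
built on pocket heavy atoms only (not sphere extents): spheres protruding
into solvent are precisely what the hull pass is meant to cut. Fewer than
four or coplanar atoms leave the grid unchanged with a warning. VdW
pruning is cosmetic for docking engines that handle clashes themselves and
can be disabled. The staged build→hull→prune path is verified against a
node-by-node brute-force evaluation of the three predicates on random
small pockets (≤10 spheres, ≤50 atoms, 100 instances).

## Synthetic fixtures: what they do and do not show

The generator plants cavities with exactly known ground truth: chains on
straight 3.8 Å-step traces 10 Å apart, pocket residues moved onto a ~5 Å
ring around a cavity center lifted 15 Å off the traces, five heavy atoms
per planted residue on radial shells 4.0–5.6 Å so a central 4 Å alpha
sphere (+1 Å tolerance) contacts 3/5 of them — comfortably above the 0.5
residue-match default. Cavity centers are ≥ ~25 Å apart, well beyond the
8 Å bandwidth, so clusters never bleed between replicas. Corpora come in
three tiers (negative controls, single-site papers, a multi-site paper
when ≥2 pockets are planted) with canned backend responses consistent with
the planted truth; noise knobs inject numbering offsets, wrong residue
names, malformed tokens, split pocket entries and hallucinated residues,
with refinement responses scripted to return the clean truth. Everything
is deterministic under the spec's seed.

These fixtures exercise every predicate and threshold the pipeline
evaluates, but they are idealized: no real protein geometry, no sequence
homology between non-identical chains, no genuinely ambiguous prose, and
the mock backend never errs beyond its scripted corruptions. Passing tests
therefore demonstrate the correctness of the algorithmic machinery, not
the extraction quality of any particular language model on real articles —
that depends on the backend and must be measured per model with the
benchmark evaluation tools.

## Problem sizes and defaults used in checks

Acceptance-style checks run on two-chain interface and four-chain homomer
fixtures of 30 residues/chain with 1–2 planted pockets and 1–2 decoys,
1000 random match fixtures for the specificity identity, and 100 random
small pockets for the grid oracle; these sizes make every check exact
while keeping the whole suite in seconds. All thresholds named above live
in `PipelineConfig` with the defaults stated here.

## Known limitations

- Chain similarity is positional; constructs with insertions/deletions
  (not just constant shifts) will under-score and may need the offset scan
  or manual renumbering.
- One pocket per matched cluster and first-match-wins for clusters
  matching several pockets; closely adjacent distinct sites can fuse,
  mirroring the underlying detector's behaviour.
- The relevance filter's quality is entirely backend-dependent; the
  package only guarantees strict parsing and validation of whatever the
  backend returns.
- PDB input only (first MODEL, highest-occupancy altlocs); no mmCIF, no
  assembly generation.
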