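# pocketlit

Literature-driven prioritization of protein binding pockets.

Geometric pocket detectors happily report every cavity, pit and groove on a
protein surface, but only a few of those are functionally relevant binding
sites — and for docking you need the geometric extent of exactly the site
the literature supports. `pocketlit` automates the manual curation step in
between: it extracts residue-level binding-site descriptions from research
articles with a prompted language model, maps those residues onto a
specific PDB structure, uses them to filter and merge Fpocket's candidate
pockets, and converts the surviving pockets into cleaned volumetric grids
ready for docking-box definition. It is aimed at structural bioinformatics
and drug-discovery practitioners who already run Fpocket and have a stack
of papers about their target.

## Method

1. **Extraction** — each article (GROBID-style markdown) passes three
   prompted stages over a pluggable text-completion backend: a relevance
   filter (is this the right protein, with residue-level site
   descriptions?), pocket extraction (named sites with residue tokens
   `CHAIN:RESNAME:RESID`), and refinement (re-unifying split sites, adding
   missed residues, dropping PPI/nucleic-acid sites and hallucinated
   residues). A deterministic mock backend replays canned responses for
   offline work and testing.
2. **Evaluation** — extracted pockets are matched one-to-one to annotated
   pockets greedily by annotated-residue recall |A∩E|/|A| (threshold 0.5).
   Reported metrics: Pocket Number Accuracy (fraction of papers with the
   right pocket count), Pocket Recall = n_matched/n_annotated, Pocket
   Specificity = 1 − n_misses/n_extracted, residue-level P/R/F1, and
   binary-classifier metrics for the relevance filter.
3. **Mapping** — literature residues are assigned to chains by positional
   sequence similarity (id + name agreement fraction, threshold 0.6),
   spatially clustered with MeanShift (bandwidth 8 Å), and matched back to
   pockets (overlap threshold 0.7). Matched clusters spanning ≥2 chains
   become interface pockets; otherwise the pocket is replicated per
   matching chain (the homomer case).
4. **Selection and merging** — Fpocket output (`pocket<N>_atm.pdb` +
   `pocket<N>_vert.pqr`) is read back; a pocket's residues are those with
   ≥50% of heavy atoms within (sphere radius + 1 Å) of an alpha sphere; a
   pocket survives iff its residue-set Jaccard with some mapped literature
   pocket is ≥0.3; survivors merge (union–find) when their residue Jaccard
   exceeds 0.5 or they share a supporting literature pocket.
5. **Grids** — each final pocket becomes a 1.5 Å point lattice over its
   atoms' bounding box, keeping nodes inside the alpha spheres, then
   dropping nodes outside the convex hull of the pocket atoms and nodes
   closer than the Van der Waals radius to any protein atom. Export as
   pseudo-atom PDB, OpenDX mask, or XYZ.

## Worked example

Everything below runs offline on generated inputs:

```sh
pocketlit fixtures --out demo          # synthetic target, papers, Fpocket dir, mock responses
pocketlit run \
  --papers demo/papers --target "Synthetic target protein STP-1" \
  --pdb demo/structure.pdb --fpocket demo/fpocket \
  --backend mock --responses demo/responses --out demo/out
```

which prints

```
2 paper(s): 1 filtered, 1 extracted; 1 final pocket(s); grids: [15]
```

The demo target is a two-chain structure with one planted interface site
and two decoy cavities, described by one negative-control paper and one
relevant paper. The negative control is filtered at stage one, the planted
interface site is recovered across both chains, both decoys are rejected
for lack of literature support, and the final pocket yields a 15-point
volumetric grid (`demo/out/pocket1_grid.pdb`); `demo/out/report.json`
carries the per-stage counts. Stage-wise subcommands (`extract`, `map`,
`select`, `gridify`, `evaluate`) expose the same intermediates
individually.

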