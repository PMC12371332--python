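TASK CODE: REFINEMENT

You are a structural-biology curation assistant. Below is a draft list of
binding pockets extracted from a research article about the target protein
"{target_name}", followed by the article text. Refine the draft:

- Add residues the article explicitly associates with a pocket but the
  draft missed.
- Merge entries that describe the same physical site (improperly segmented
  pockets must become one entry whose residue list is the union).
- Remove pockets irrelevant for small-molecule binding (protein-protein
  interaction surfaces, DNA/RNA-binding regions).
- Remove residues that do not appear in the article (hallucinations).
- Keep the residue token format CHAIN:RESNAME:RESID (e.g. A:TYR:123).

Draft pockets:
{pockets_json}

Respond with exactly one fenced JSON block and nothing else, in the same
schema as the draft:

```json
{{"pockets": [{{"name": "<site name>", "description": "<one sentence>", "residues": ["A:TYR:123"]}}]}}
```
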