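# gradientkit

Functional connectome gradient analysis: how inter-individual variation in
a continuous phenotype — here body-mass index — relates to the macroscale
organization of the functional connectome.

Regional rs-fMRI signals are condensed into a parcel × parcel Fisher-z
correlation connectome; a normalized-angle affinity at 10% connection
density is embedded with diffusion maps (α = 0.5, t = 0), giving a small
set of *gradients* E1–E3 — smooth axes of connectivity variation.
Individual manifolds are Procrustes-aligned to a group template so that,
for each parcel *p* and subject *i*, the coordinates
`Y_ip = (E1, E2, E3)` are comparable. The central model is the parcel-wise
multivariate regression

    Y_p = b0 + b1·Age + b2·Sex + b3·BMI ,

with the BMI term tested by Hotelling's T² (exact-F conversion) and
Benjamini–Hochberg FDR across parcels. Around it sit manifold eccentricity
(per-parcel distance from the template center), permutation and spin
(sphere-rotation) nulls, graph-theoretic context (within-module degree,
participation coefficient, Louvain modules, centralities), group
contrasts, density/scale sensitivity sweeps, and transcriptomic spatial
decoding of the resulting statistic map against donor-wise gene expression
panels with gene-set and cell-type enrichment.

Because the imaging cohorts such analyses run on are access-restricted,
the package ships a first-class synthetic-data module: modular correlated
time series whose between-module coupling is modulated by standardized
BMI, plus structural maps, expression panels and cell-type specificity
tables — all with recorded ground truth, so every stage is testable end to
end. See `docs/methods.md` for the model, the generator's design and its
limitations.

## Worked example

```python
import json
import pandas as pd
import gradientkit as gk

cfg = gk.PipelineConfig(out_dir="runs/demo", seed=7, n_subjects=80,
                        n_perm=1000)
record = gk.run_pipeline(cfg)

truth = json.load(open("runs/demo/data/truth.json"))
sm = pd.read_csv("runs/demo/statmap_main.tsv", sep="\t")
tmpl = json.load(open("runs/demo/template_embedding.json"))
aff = set(truth["affected_parcels"])
sig = set(sm.loc[sm.significant == 1, "parcel_id"])
print(f"variance explained E1-E3: {100*sum(tmpl['variance_explained']):.1f}%")
print(f"parcels significant at FDR<0.05: {len(sig)} / {len(sm)}")
print(f"  of which truly affected: {len(sig & aff)} / {len(aff)} planted")
```

prints

```
variance explained E1-E3: 20.2%
parcels significant at FDR<0.05: 13 / 100
  of which truly affected: 11 / 17 planted
genes surviving spin+consistency filtering: 20 (20 of 20 planted)
top cell type at pSI=0.05: cortex_neuron (q=3.15e-19)
```

(the last two lines come from reading `gene_associations.tsv` and
`enrichment_cell_types.tsv` in the same run directory). The run simulated
an 80-subject cohort in which the coupling between two designated modules
decreases with BMI; the multivariate model recovers most of the planted
parcels, E1–E3 jointly carry ~20% of the connectome's spectral
information on this synthetic system, and the decoding chain recovers all
20 planted genes and ranks the planted cell population first. Every run
writes a `run_record.json` with the config snapshot and SHA-256 digests
of all outputs; rerunning with the same seed reproduces the digests
exactly.

A command-line interface mirrors the library
(`gradientkit simulate | connectome | embed | metrics | associate |
decode | run-all | sensitivity`); `run-all --config cfg.yaml` executes the
full pipeline from a YAML config.

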