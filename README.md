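# tlomap

3D spatial-transcriptomics analysis of inflamed synovium: spatial
clustering of barcoded spots, marker-signature cell-type scoring,
tertiary lymphoid organ (TLO) detection from cell density,
serial-section registration and interpolation, receptor–ligand
permutation statistics, and nested mixed-model power analysis — plus a
synthetic volume generator that carries full ground truth for every
stage.

## The problem

Rheumatoid-arthritis synovium contains organized leukocyte aggregates
(TLOs) surrounded by radially arranged stromal zones. Spatial
transcriptomics of consecutive cryosections can map these structures in
3D, but the analysis requires a chain of nonstandard steps: variable
genes by the CV² − median statistic, a permutation test for the number
of informative principal components, ward.D2 clustering of a
3-component tSNE, negative-binomial likelihood-ratio tests for cluster
markers, a marker-sum cell-type score with a co-expression validity
filter, within-section percentile density scores for TLO candidacy,
rigid / scaled-rotation registration of sections into a volume, a
CellPhoneDB-style permutation statistic for receptor–ligand pairs, and
a Monte-Carlo power analysis over the nested patient → section → spot
design. `tlomap` implements each step as a tested, reusable function
for analysts working with spot-level ST data (counts + spot geometry +
optional nucleus tables); it consumes plain MTX/TSV/GMT files and never
requires raw sequencing data.

## The core model

**Cell-type scores.** For cell type *l* with validated markers *M_l*
(pairwise-positively co-expressed, applied when >3 markers are present)
and normalized expression *Y* over spots *r*:

    c_{l,r} = Σ_{m ∈ M_l} Y_{m,r}            (marker sum)
    C_{l,r} = c_{l,r} / max_r c_{l,r}        (max-scaled, ∈ [0,1])
    P_{l,r} = C_{l,r} / Σ_{l'} C_{l',r}      (per-spot proportions)

**Density/TLO rule.** The cell-density score of a spot is the
within-section percentile of its 200×200 px window nucleus count; spots
scoring > 70 are TLO candidates.

**Power model.** `y = β·group + u_patient + v_section + ε` with
Gaussian random effects; the group test is a pooled t on patient means
(exact under the model), and a design "saturates" at 80% power.

See `docs/methods.md` for the full treatment, including every default
and its rationale.

## Worked example

```python
import numpy as np
from tlomap import (SimParams, make_reference, simulate_volume, filter_spots,
                    normalize, select_variable_genes, variable_gene_names,
                    pca_with_permutation, embed_tsne, cluster_ward,
                    score_cell_types, aggregate_cells_to_spots, density_score,
                    annotation_overlap, register_sections, PowerDesign,
                    simulate_power)

# a 3-section synthetic volume: one TLO core, two rings, lining
params = SimParams(n_sections=3, spots_per_section=250, n_genes=1000,
                   n_cell_types=8, seed=0)
signatures, matrix = make_reference(params)
counts, spots, truth, cells = simulate_volume(params, matrix)

# preprocess -> embed -> cluster
counts = filter_spots(counts, min_genes=200)
counts = normalize(counts, "regression_residual")
hvg = select_variable_genes(counts, n_top=500)
X = np.asarray(counts[:, variable_gene_names(hvg)].layers["normalized"])
emb = embed_tsne(pca_with_permutation(X, max_pcs=15, seed=0), seed=0)
clusters = cluster_ward(emb, k=4)
print(f"{emb.n_pcs_selected} PCs selected; cluster sizes:",
      np.bincount(clusters.labels)[1:])

# cell-type proportions and TLO detection
scores = score_cell_types(counts, signatures)
dens = density_score(aggregate_cells_to_spots(cells, spots))
overlap = annotation_overlap(dens, spots["annotation"], "infiltrate")
print(f"annotated infiltrates above the 70% density score: {overlap:.0%}")

# 3D registration and a power estimate
volume = register_sections(spots, mode="rigid")
power = simulate_power(PowerDesign(n_patients_per_group=3,
                                   n_sections_per_patient=4,
                                   n_spots_per_condition=80,
                                   effect_size=2.5, seed=0))
print(f"power at 3 patients / 4 sections / 80 spots: {power.power:.2f}")
```

Output:

```
3 PCs selected; cluster sizes: [264 258 179  49]
annotated infiltrates above the 70% density score: 100%
power at 3 patients / 4 sections / 80 spots: 0.86
```

The permutation test keeps 3 PCs (four zones span three mixture
directions); the four clusters match the planted zones, the smallest
being the 49-spot TLO core. Every simulated infiltrate-annotated spot
exceeds the 70th density percentile, and a 3-patient / 4-section /
80-spot design reaches 86% power for a 2.5-residual-SD group effect.

A command-line interface mirrors the library
(`tlomap simulate|preprocess|cluster|score|density|register|interact|enrich|power`),
each subcommand taking a YAML config; see `tlomap --help`.

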