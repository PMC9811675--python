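# ssrsa — spatiotemporal searchlight RSA for model-to-brain comparison

`ssrsa` compares the evolving internal representations of an artificial
network (for example, the hidden layers of a speech-recognition acoustic
model) with spatiotemporal brain recordings reconstructed onto a cortical
surface.  It is written for researchers doing multivariate pattern analysis
on MEG/EEG source estimates who want the full chain — dynamic model RDMs,
searchlight brain RDMs, latency matching, cluster-enhanced permutation
inference, and clustering evaluation of the model's own representational
space — as composable, tested Python, runnable end-to-end on synthetic data
with known planted structure.

## The analysis

**Representational dissimilarity.** For a set of stimulus conditions, a
representational dissimilarity matrix (RDM) has entries
`D_ij = 1 − r(x_i, x_j)`, the Pearson correlation distance between the
response vectors to conditions *i* and *j*.  RDMs abstract away from the
response format, so network layers and cortical patches become directly
comparable; two RDMs are compared by Spearman's rank correlation ρ of their
upper triangles.

**Dynamic model RDMs.** Acoustic features come in 25 ms frames shifted by
10 ms; base features are augmented with first-derivative (delta) components
and stacked over nine consecutive frames (40 → 80 → 720 dimensions, with
boundary frames duplicated, a 125 ms effective receptive field).  Frame
index *t* enters the analysis when `10·t + 25 ≤ D_min`, the shortest
stimulus duration — 27 frames for a 285 ms shortest word — giving one model
RDM per reserved frame, per layer.

**Searchlight brain RDMs.** Source-space epochs (1 ms resolution) are scanned
with a spatial patch (all vertices within 20 mm of a centre, within one
hemisphere) and a sliding 25 ms window stepped by 10 ms.  The concatenated
patch × sample response per condition gives one brain RDM per
(vertex, window).

**Latency matching.** Cortex lags the stimulus, so the model RDM at stimulus
time τ is matched to the brain RDM at epoch time τ + k for a hypothesised
processing latency k, and

    ρ_{v,k} = mean_τ  Spearman( model RDM(τ), brain RDM at v (τ + k) )

is computed per subject over k = 0, 10, …, 250 ms.  Subjects combine by a
one-sample t-test per (vertex, latency) cell.

**Inference.** The t-map is enhanced with threshold-free cluster enhancement,

    TFCE(t_{v,k}) = Σ_{i ≥ 0, i·Δh ≤ t_{v,k}} (i·Δh)² · e(i·Δh),   Δh = 0.1,

where `e(h)` is the extent of the connected component of (v, k) at threshold
h on the spatiotemporal graph (mesh edges at equal latency, same-vertex
links across adjacent latencies).  Family-wise-corrected p-values come from
a map-maximum sign-flip randomization: each subject's ρ-map is given a random
sign, per hemisphere the maximum of the enhanced null t-map is recorded over
1,000 permutations, and a cell's corrected p is
`(1 + #{null maxima > observed}) / n_perm`.

**Clustering evaluation.** Layer activations averaged over contiguous
phonetic segments are labelled by phone or articulatory feature (place,
manner, vowel frontness and closeness) and scored by the Davies–Bouldin
index — mean over clusters of the worst-case `(s_i + s_j) / d(c_i, c_j)`
ratio, lower is better — with a label-permutation p-value (5,000
permutations), plus Sammon non-linear MDS for visualisation.

**Synthetic data.** `ssrsa.synthetic` generates every input: a two-hemisphere
triangulated mesh, phonetic segmentations, layer activations with
label-driven cluster structure, and multi-subject source epochs in which a
chosen vertex set carries, at a chosen latency, condition patterns whose
correlation distances realise a target model RDM stream exactly (mixed as
`effect_size · pattern + (1 − effect_size) · noise`).  Planted effects are
recoverable by the full pipeline and everything is deterministic given one
seed.

## Worked example

```python
import numpy as np
from ssrsa import (
    SynthConfig, make_conditions, make_segments, make_layer_activations,
    make_mesh, make_source_epochs, build_model_stream, SearchlightConfig,
    group_mean_rho, group_inference,
)
from ssrsa.latency import all_subject_rho_maps

cfg = SynthConfig(seed=1)               # 40 words, 6 subjects, planted latency 70 ms
conditions = make_conditions(cfg)
segments = make_segments(cfg, conditions)
activations = make_layer_activations(cfg, segments, conditions=conditions)
model_stream = build_model_stream(activations["L7"])
print(f"model stream: {model_stream.n_times} RDM frames of "
      f"{model_stream.conditions.n}x{model_stream.conditions.n}")

mesh = make_mesh(cfg.n_vertices_per_hemisphere, cfg.mesh_radius_mm, cfg.seed)
epochs = make_source_epochs(cfg, mesh, model_stream)
rho_maps = all_subject_rho_maps(model_stream, epochs, mesh, SearchlightConfig())

mean_rho = group_mean_rho(rho_maps)
vi, ki = np.unravel_index(np.argmax(mean_rho), mean_rho.shape)
print(f"peak mean rho {mean_rho[vi, ki]:.3f} at vertex {mesh.ids[vi]}, "
      f"latency {rho_maps[0].latencies_ms[ki]:.0f} ms")

result = group_inference(rho_maps, mesh, n_perm=200, alpha=0.05, seed=1)
print(f"min corrected p = {result.min_p():.3f}; "
      f"{result.report.n_clusters} suprathreshold cluster(s)")
```

Output:

```
model stream: 27 RDM frames of 40x40
peak mean rho 0.777 at vertex 0, latency 70 ms
min corrected p = 0.005; 1 suprathreshold cluster(s)
```

The group map peaks exactly at the planted site (vertex 0 is one of the six
effect vertices) and the planted 70 ms latency; with 200 sign-flip
permutations the smallest attainable corrected p is 1/200 = 0.005, and the
planted cluster reaches it.

The same run is available from the shell:

```bash
ssrsa run-all --seed 1 --out runs/demo     # simulate → … → cluster-eval
```

which writes mesh TSVs, activation/epoch HDF5 files, ρ-maps, the corrected
inference report, the clustering-evaluation table, and a `manifest.json`
with content hashes and per-stage seeds (re-running a config reproduces the
hashes bit-for-bit).

## Layout

| module | contents |
| --- | --- |
| `ssrsa.core` | `ConditionSet`, `RDM`, `RDMStream`, correlation-distance RDMs, Spearman comparison, averaging |
| `ssrsa.model_rdms` | delta features, context stacking, frame reservation, model RDM streams |
| `ssrsa.mesh` / `ssrsa.searchlight` | cortical mesh, patches, windows, brain RDM streams |
| `ssrsa.latency` | latency-offset ρ-maps, group t-maps |
| `ssrsa.tfce` | spatiotemporal TFCE, sign-flip nulls, corrected p, cluster reports |
| `ssrsa.clustering` | segment averaging, Davies–Bouldin, permutation p, Sammon MDS |
| `ssrsa.synthetic` | mesh/segment/activation/epoch generators with planted structure |
| `ssrsa.pipeline` / `ssrsa.cli` | staged runs, manifests, `ssrsa` command |

See `docs/methods.md` for the model, parameter and calibration details.
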