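# scalehub

Scale-integrated network hubs of white-matter structural connectomes.

## The problem

Structural brain networks are built by parcellating the cortex into K
regions (nodes) and counting the tractography streamlines connecting each
pair of regions (edges).  Network *hubs* — nodes with high betweenness
centrality — are then read off the resulting graph.  But the hub map
depends strongly on K: a region that dominates shortest paths at 100 nodes
can dissolve into unremarkable fragments at 600, partly because short
association fibers (U-fibers) absorb different amounts of inter-regional
traffic at different parcel sizes.  Committing to a single K therefore
biases which cortex is called a hub.

`scalehub` implements a scale-integrated alternative.  For each nodal
scale K in a set M, the cortex is randomly parcellated R times (spherical
k-means on the template sphere, similar-size parcels), a weighted
fiber-count network is built per subject and repeat (edges require at
least 3 supporting streamlines), and nodal betweenness centrality

    BC(i) = Σ_{j≠i≠k} ρ_jk(i) / ρ_jk

is computed on inverse-weight edge lengths, z-normalized, projected to the
template surface, averaged over repeats, smoothed (20 mm FWHM), and
averaged over subjects into a group hub map X_K.  The scale-integrated hub
strength and score are

    H_IS_ST(v) = (1/|M|) Σ_{K∈M} X_K(v),
    H_IS_SC(v) = (H_IS_ST(v) − μ) / σ,

and hub regions are the vertices with H_IS_SC more than one standard
deviation above the mean.  A validation contrast checks that hubs
confirmed by integration carry higher nodal local efficiency
(E(i) = Σ_{j≠i} d_ij⁻¹ / (n−1)) than single-scale hubs that integration
rejects.

Because clinical tractography cohorts are rarely shareable, the package
ships a synthetic cohort generator: a modular architecture is planted on
an icosphere template, with designated *connector* caps on module
boundaries that mediate most inter-module fibers.  Connector cortex
acquires elevated betweenness at every scale, giving a known ground truth
against which hub detection is verified end to end.

## Who it is for

Network-neuroscience researchers who have streamline endpoint tables (or
connectivity matrices) on a template surface and want hub maps that do not
hinge on one arbitrary parcellation scale — plus a reproducible synthetic
benchmark for methods work on multi-scale connectomes.

## Worked example

```python
import scalehub as sh

cohort = sh.simulate_cohort(sh.SimulationConfig(), master_seed=1)
model = sh.ScaleIntegratedHubModel(cohort, scales=(50, 100, 150), n_repeats=5)
res = model.fit()
print(res.summary())
```

prints (about half a minute):

```
Scale-integrated hub analysis
================================================================
subjects: 10   vertices: 2562
scales: [50, 100, 150]   repeats/scale: 5
edge threshold: >= 3 fibers   smoothing FWHM: 20.0 mm
hub threshold: mean + 1.0 SD   seed: 1
----------------------------------------------------------------
integrated hub score: mean +0.00e+00, SD 1.000000
integrated hubs: 296 vertices (11.6% of cortex)
----------------------------------------------------------------
short-association ratio by scale (cohort mean, %):
  K=  50: 6.6090
  K= 100: 5.8279
  K= 150: 4.4039
----------------------------------------------------------------
local-efficiency contrast (integrated vs other hubs):
  K=  50: t=+9.768 p=4.78e-20 ** (n=272/73, mean 20.9522 vs 19.3322)
  K= 100: t=+4.984 p=1.09e-06 ** (n=273/13, mean 6.9200 vs 6.3480)
  K= 150: t=+3.050 p=0.00254 * (n=234/12, mean 3.8814 vs 3.7078)
----------------------------------------------------------------
planted-connector recovery: score +2.275 (connector) vs -0.310 (other), Jaccard(hubs, connectors) = 0.774
```

Reading the output: the integrated hub score is a z-map (mean 0, SD 1) over
the 2562 template vertices; 296 vertices exceed the mean + 1 SD hub
threshold.  The share of possible connections occupied by short
association fibers falls as parcels shrink (6.6% → 4.4%).  At every scale
the hubs confirmed by integration carry significantly higher local
efficiency than the single-scale hubs integration rejects (t > 0), and the
detected hub set overlaps the planted connector cortex with Jaccard 0.77 —
the generator's ground truth is recovered.

`res.save("out/")` writes `his_st.tsv`, `his_sc.tsv`, `hubs.tsv`,
per-scale maps and hub lists, `short_ratios.tsv`, `validation.tsv` and a
`run.json` provenance record.  The same pipeline is available from the
shell:

```
scalehub simulate --out-dir cohort --seed 1
scalehub run --cohort-dir cohort --scales 50,100,150 --repeats 5 --seed 1 --out-dir out
scalehub check-consistency
```

with additional per-stage subcommands (`parcellate`, `connect`, `hubness`,
`integrate`, `validate`) for working with data on disk.

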