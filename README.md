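# promshape

Shape analysis of mammalian promoters from CAGE (Cap Analysis of Gene
Expression) 5′-tag data.

A promoter's transcription-start-site distribution (TSSD) — the per-nucleotide
histogram of CAGE tag 5′ ends within one tag cluster — carries regulatory
information: broad, CpG-island promoters initiate over tens of nucleotides,
while sharp TATA-driven promoters focus initiation on a few bases. `promshape`
implements a complete toolkit for classifying promoters by distribution shape:

* **TSSD construction** — chains same-strand tags overlapping by ≥ 2 bp into
  clusters, keeps clusters with ≥ 100 tags, applies Laplace's rule of
  succession (add-one smoothing) to dampen background noise.
* **GM-distance** — a shape dissimilarity between normalised TSSDs based on
  MDPA (minimum difference of pair assignments), the 1-D transport distance
  `Σᵢ |Σ_{j≤i}(aⱼ − bⱼ)|`, minimised over all translational alignments of the
  two zero-padded histograms. It is symmetric, non-negative, and invariant to
  genomic location and tag magnitude.
* **Two-level hybrid clustering** — Ward-linkage hierarchical clustering of
  the GM-distance matrix cut into k₁ fine clusters, then exact 1-D k-means on
  the intra-cluster mean peakedness `P = (m/n)/w` (mode mass m, total tags n,
  width w) into k₂ = 3 tiers: **ultra-dense** (single-nucleotide spikes),
  **dense** (sharp, TATA-like) and **scattered** (broad) promoters.
* **Bootstrap stability** — clusterboot-style resampling: B pseudo data sets
  are re-clustered, each original cluster is matched to its most similar
  pseudo cluster by the Jaccard coefficient, and the clustering's overall
  stability is the size-weighted mean `S = Σ n_k J̄_k / Σ n_k`.
* **Peak calling** — positions carrying ≥ 5% of a TSSD's tags, merged when
  closer than half the 20-nt peak span; TSSDs with no such position are
  "uniform".
* **Tissue specificity** — the relative entropy (Kullback–Leibler divergence,
  bits) between a TSSD's tissue profile and the all-tag background.
* **Sequence diagnostics** — TATA-PWM scanning at a 70% relative log-odds
  score and pyrimidine–purine (PyPu) initiator density on user-supplied
  windows aligned at dominant peaks.
* **Synthetic data** — a generator planting the three shape classes, peak
  counts and tissue profiles, so the whole pipeline is testable without any
  download.

The clustering components are scikit-learn-style estimators
(`TSSDShapeClassifier`, `KMedoids`, `KMeans1D`) with plain-function wrappers.

## Worked example

```python
import promshape as ps

# 300 synthetic TSSDs: 100 scattered, 100 dense, 100 ultra-dense, 200 tags each
tssds, truth = ps.simulate_tssds((100, 100, 100), seed=1)

labels, est = ps.two_level_classify(tssds, k1=30, k2=3)
from collections import Counter
print("class counts:", dict(Counter(labels.values())))

rep = ps.bootstrap_stability(est.distance_matrix_, clusterer="ward",
                             k=est.level1_.k, B=20, seed=7,
                             reference=est.level1_)
print("overall stability S:", round(rep.overall, 3))

t = tssds[0]
pc = ps.call_peaks(t)
print("first TSSD:", t.id, "width", t.w, "peaks at", pc.peaks,
      "planted", truth.by_id()[t.id].peak_offsets)
```

prints

```
class counts: {'scattered': 100, 'dense': 100, 'ultra-dense': 100}
overall stability S: 0.897
first TSSD: sim_0001 width 72 peaks at [21, 54] planted [21, 54]
```

All 300 planted class labels are recovered (adjusted Rand index 1.0 against
the simulation truth); the 30 fine clusters have a size-weighted mean
bootstrap Jaccard of 0.897, with the ultra-dense cluster perfectly stable
(J̄ = 1.0); and the peak caller finds exactly the two planted peaks of the
first scattered TSSD.

The same pipeline from the shell:

```bash
promshape simulate --n-per-class 100,100,100 --seed 1 --out sim.ctss --truth truth.json
promshape run --in sim.ctss --outdir out/ --k1 30 --k2 3 --min-tags 100 \
    --config <(echo "extend_to: 21")
```

which writes `tssd.bed`, `distmat.tsv`, `labels.bed` (class, peakedness and
peak count per TSSD), `report.json`, `stability.json`, `peaks.json` and
`specificity.json` under `out/`.

## Layout

```
src/promshape/
  core.py       Tag / TSSD / NormalizedTSSD domain types
  io.py         CTSS and BED parsing, TSSD assembly, smoothing, serialisation
  metric.py     MDPA / GM-distance and the dissimilarity matrix
  shape.py      peakedness, peak calling, KL tissue specificity
  cluster.py    Ward linkage, tree cutting, k-medoids, 1-D k-means,
                two-level shape classifier
  stability.py  bootstrap-Jaccard cluster stability
  seqfeat.py    PWM scan and PyPu initiator density
  simulate.py   synthetic TSSD generator with planted truth
  cli.py        `promshape` command-line interface
```

See `docs/methods.md` for the model details, parameter defaults, and the
scope and limits of the synthetic data.
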