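# nucleome

Desk-scale analytics for integrative 3D-genome data: contact-map and
genome-architecture-mapping (GAM) statistics, A/B compartments,
insulation and domain calculus, chromatin-loop integration and
clustering, SPIN-style spatial-state inference, and per-locus structural
features from populations of 3D genome structures — all exercised
end-to-end on synthetic data with planted, recorded ground truth.

## Who this is for

Different assays see the same genome through different lenses: ligation
methods (Hi-C, Micro-C, ChIA-PET, PLAC-seq), ligation-free proximity
methods (GAM, SPRITE), nuclear-position assays (TSA-seq, DamID) and
ensembles of whole-genome 3D structure models. Comparing them requires a
common battery of quantities — compartment strength, insulation
boundaries, loop unions, spatial-state segmentations, radial and
nuclear-body association features — each with its own normalization
conventions. This package implements that battery as a tested library,
with simulators that plant every feature the analyses are supposed to
recover, so each stage's calibration can be verified exactly.

## What is computed

- **Contact-map primitives** (`nucleome.contact`): iterative-correction
  balancing (weights *w* with equal marginals of
  *w*<sub>i</sub>·O(i,j)·*w*<sub>j</sub>), distance-decay expected model
  E(i,j) and O/E, contact-probability curves P(s) with log-log slopes,
  cis fraction, and the stratum-adjusted correlation coefficient
  SCC = Σ<sub>k</sub> w<sub>k</sub> r<sub>k</sub> / Σ<sub>k</sub> w<sub>k</sub>
  with w<sub>k</sub> = N<sub>k</sub>·sd<sub>k</sub>(x)·sd<sub>k</sub>(y)
  for cross-assay reproducibility.
- **GAM** (`nucleome.gam`): window calling by the orphan-minimizing
  coverage percentile; sample QC (≤40% orphan windows, ≤60% genome
  coverage, >50,000 reads, cross-well Jaccard <0.4); window-detection-
  frequency curation (ND = (raw−smoothed)/smoothed over 11-window
  smoothing, masking ND>5 ±2 windows, mappability <0.2); co-segregation
  and NPMI = ln(p(i,j)/p(i)p(j)) / (−ln p(i,j)).
- **Compartments** (`nucleome.compartments`): per-chromosome
  eigenvectors of the Pearson-correlation matrix of the z-scored O/E
  map, oriented by gene density/GC; saddle plots with the top-20%
  corner strengths top(AA)/(AB+BA) and top(BB)/(BA+AB); the same
  sorting machinery for preferential interactions against any
  nuclear-position track.
- **Domains** (`nucleome.domains`): diamond insulation (100-kb window,
  first two diagonals ignored), prominence-based boundary calling,
  dot/dotless domain classification (loop at the apex ±20% of the
  domain size), Jaccard co-registration (threshold 0.70), rescaled
  pileups (60% flanks, stretched to a common length), and the
  compartment-matched resampling test for replication initiation zones
  with one-tailed empirical p = (1 + #{null ≥ obs})/(1 + N).
- **Loops** (`nucleome.loops`): the union-merge rule
  |i−i′| < min(0.2|i−j|, 15 kb) with finest-resolution representatives;
  capture overlap at min(0.3|i−j|, 80 kb); APA on 21×21 O/E windows
  with 1st/99th-percentile trimming; anchor chromatin-state
  featurization with consensus Leiden clustering over k-NN graphs
  (k = 50…2000, resolution 0.5); shuffle-null state-pair and TF
  enrichment; enhancer–promoter linking; expression breadth
  (log₂(TPM+1), quantile normalization, threshold 3) and quartile
  classes.
- **SPIN** (`nucleome.spin`): a joint hidden Markov random field over
  per-cell-type graphs with shared Gaussian emissions,
  P(H,O) ∝ Π<sub>c</sub> Π<sub>i</sub> P(O<sub>i</sub><sup>c</sup>|H<sub>i</sub><sup>c</sup>)
  Π<sub>(i,j)∈E<sup>c</sup></sub> ψ(H<sub>i</sub><sup>c</sup>,H<sub>j</sub><sup>c</sup>),
  fitted by hard-EM with exact per-chromosome dynamic programming plus
  ICM; Yeo–Johnson track normalization on spatially stable bins; state
  number by elbow/AIC/BIC; per-state track and caRNA enrichment.
- **Structure populations** (`nucleome.struct3d`): RAD (normalized
  radial position on an ellipsoid), local radius of gyration, ICP, ILF,
  transAB, nuclear-body prediction by Markov clustering of the
  chromatin interaction network (partitions >3 regions), SpD/NuD/LaD,
  SAF/NAF/LAF (500 nm / 1,000 nm / 0.2 radial units), cell-to-cell
  variability δf, class I/II gene categorization by SAF quartiles, and
  spatial enhancer counts within 350 nm.
- **Simulators** (`nucleome.simdata`): multinomial block-model contact
  maps (distance decay × compartment × TAD × loop factors), confined
  biased-random-walk diploid structure populations, GAM slab sampling,
  state-conditional Gaussian observation tracks, loop sets with planted
  anchor-state signatures, and expression tables with planted breadth.

## Worked example

`analysis/` contains the numbered study scripts; running them in order
reproduces the full synthetic study. For example:

```
$ python analysis/01_simulate_data.py
wrote synthetic study inputs to .../scratch/data
  contact maps: 500 bins at 200 kb, depth 1,000,000
  ...
$ python analysis/03_compartments_domains.py
compartment eigenvector label accuracy vs planted: 1.000
compartment strength at planted 1.5: AA=0.735, BB=0.749 (null level 0.5)
20 compartment domains, median size 5.0 Mb
boundary recovery: 24 called, recall 1.00 within 1 bin of 24 planted
...
$ python analysis/05_spin.py
state-number selection: BIC argmin K = 5 (planted 5)
label-matched accuracy per cell type: 98.8%, 98.5%
hard-EM iterations: 8, objective -16556 -> -12842 (non-decreasing)
```

The compartment eigenvector labels every bin of the planted A/B pattern
correctly; the saddle corner ratio 0.735 sits above the 0.5 value an
unstructured map produces, reflecting the planted 1.5× same-compartment
enrichment; every planted TAD boundary is recovered at its exact bin;
and the spatial-state model recovers the five planted states and their
number from the data alone. Small summary tables land in `results/`.

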