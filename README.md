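# qpaintlib

Quantitative DNA-PAINT (qPAINT) analysis of membrane-protein nanoclusters:
from drift-corrected single-molecule localization tables to calibrated
protein-copy-number cluster maps — together with a synthetic DNA-PAINT data
generator with known ground truth, so every pipeline stage can be validated
by parameter recovery without any microscope data.

## The problem and the method

DNA-PAINT imaging makes targets blink by design: dye-labelled *imager*
strands in solution transiently hybridise to antibody-coupled *docking*
strands, so each labelled protein produces a cluster of single-molecule
localizations whose blinking statistics are governed by binding kinetics
rather than photophysics.  qPAINT turns this into molecular counting.  With
N docking strands in a cluster, binding events arrive N times faster, so
the mean dark time τ_OFF between events obeys

    N = 1 / (k_ON · [I] · τ_OFF) = τ_OFF,1 / τ_OFF

where k_ON is the imager association rate, [I] the imager concentration and
τ_OFF,1 the single-protein dark time.  The inverse fitted dark time of a
cluster is its qPAINT index q_i; the single-protein index q_i1 is calibrated
from the multi-peak histogram of small (<100 nm) clusters, and the copy
number is the rounded ratio q_i / q_i1.

The pipeline implemented here:

1. **quality filter** — drop localizations with uncertainty > 13 nm;
2. **NeNA** — localization precision σ from nearest-neighbour displacements
   in adjacent frames (supplies the DBSCAN radius);
3. **DBSCAN** — eps = σ (rounded to nm), minPts from an exact Poisson tail
   cut on the expected per-site localization yield
   n_frames · τ_bright · k_ON · [I] (= 40 at the default settings → minPts 15);
4. **mean-frame filter** — reject clusters whose temporal centre of mass
   falls outside mean ± SD of the per-cluster mean-frame distribution
   (transient nonspecific signal is not visited throughout the acquisition);
5. **dark-time fit** — per cluster, least-squares fit of the empirical
   cumulative gap distribution with 1 − exp(−t/τ_d);
6. **calibration** — multi-peak Gaussian fit with centres constrained to
   integer multiples of a shared fundamental q_i1;
7. **counting and mapping** — N = round(q_i/q_i1), k-means partition of each
   cluster's localizations into its N protein positions;
8. **per-ROI statistics** — protein and cluster densities, % clustered
   proteins (clusters = groups of ≥ 3), small/medium/large cluster counts
   (<6, 6–12, >12 proteins), median equivalent cluster diameter, median
   first-neighbour distance.

The synthetic generator emulates the matching acquisition: a ground-truth
protein map (Poisson-distributed total, nanocluster mixture), exponential
dark/bright kinetics per docking site, camera-frame discretization,
Gaussian localization error, uniform background and transient nonspecific
sites.  See `docs/methods.md` for the model details and design choices.

## Worked example

`examples/03_cluster_statistics.py` simulates one 3.5 × 3.5 µm ROI at
23 proteins/µm² with 44% of proteins in nanoclusters, then runs the full
analysis:

```
simulated 16693 localizations from 296 proteins
clustering used eps = 9 nm (NeNA), minPts = 15 (Poisson cut at the ~40-localization yield)
calibration: q_i1 = 0.01076 Hz, counting precision 0.33 proteins
clusters: 175 detected, 47 rejected by the mean-frame filter
protein density          16.7 per um^2
cluster density           1.6 per um^2
clustered proteins       41.0 %
small/medium/large     15/4/0 (<6, 6-12, >12 proteins)
median cluster diam.       48 nm
median first-neighbour     25 nm
```

Reading the numbers: the fitted single-protein index (~0.011 Hz) is the
inverse mean dark time of one docking strand; its first-peak width gives a
counting precision of ±0.33 proteins.  The clustered percentage recovers
the planted 44% closely; the absolute density is biased low by the ±1 SD
mean-frame band and by monomer clouds sitting at the DBSCAN core-density
margin — see `docs/methods.md` for the quantitative discussion.

The other examples cover the generator (`01`), dark-time calibration and
counting (`02`) and NeNA precision estimation (`04`).  A thin CLI wraps the
same pipeline: `qpaint simulate|analyze|calibrate|summarize --help`.

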