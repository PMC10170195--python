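# Methods

## Binding-kinetics model

Each docking site alternates between a dark state (waiting time
Exponential with rate k_ON·[I], default 10⁷ M⁻¹s⁻¹ × 1 nM = 0.01 s⁻¹) and
a bright state (duration Exponential with mean τ_bright = 0.27 s).  A
cluster of N independent sites therefore shows dark times with mean
τ_OFF,1/N — the relation qPAINT counting inverts.  The simulation runs in
continuous time over the acquisition (default 15 000 frames × 100 ms =
1500 s) and keeps the sampled event durations, so bright-time statistics
can be checked before any camera discretization.

Two small but consequential properties of this process are worth stating
explicitly because they propagate into every downstream estimate:

- **Finite-window truncation.**  Only dark intervals with both flanking
  events inside the acquisition are observable; censored boundary gaps are
  excluded (they would bias the mean upward), but the remaining complete
  gaps are slightly depleted of long intervals.  At the default settings
  (mean dark time ~100 s, window 1500 s) the observed mean dark time is
  ~7–9% short of the true mean.  Counting is a ratio of dark times measured
  under identical conditions, so the bias cancels between calibration and
  counting.
- **Event statistics per site.**  ~15–18 binding events per site in 1500 s
  means every per-site quantity (mean frame, fitted dark time) carries
  substantial sampling noise; per-cluster estimates are meaningful, but
  population statements need averages over many sites.

## Camera discretization

A bright event of duration d overlapping the frame grid can be rendered
into localizations in three ways (config switch `discretization`):

- `threshold` (default): a frame records the event iff the event covers at
  least half of that frame's integration time.  The expected number of
  localizations per event is then d/frame_time, so the per-site yield
  matches the closed-form prediction n_frames·τ_bright·k_ON·[I] (40.5 at
  the defaults; measured 40.9 ± 0.6 over 500 sites).  Events much shorter
  than half a frame go undetected (~21% at the defaults), as they do in a
  real camera with a detection threshold; absolute dark times are inflated
  correspondingly, and again the counting ratio cancels the bias.
- `overlap`: every overlapped frame records a localization; no event is
  lost.  Used where the planted dark-time distribution itself is the
  quantity under test (e.g. calibration recovery), since it preserves every
  binding event.
- `round`: round(d/frame_time) frames, minimum one — a simpler alternative
  kept for comparison.

No merging is performed: a k-frame event contributes k localization rows.

## Ground-truth protein maps

Protein count ~ Poisson(density × area); a fraction (default 0.44) sits in
nanoclusters whose sizes are drawn from a small/medium/large mixture
(default weights 0.75/0.20/0.05 over sizes 3–5, 6–12, 13–20) — chosen so
that cluster densities land near ~2 µm⁻² at 23 proteins/µm², the regime of
resting fibroblast membranes.  Cluster members scatter around their centre
as an isotropic Gaussian (SD `cluster_radius_nm`, default 20 nm; a uniform
disc is available, since the true spatial law of membrane nanoclusters is
not known).  The 20 nm scale is deliberate: it keeps intra-cluster protein
spacing (~15–25 nm) inside the density-connectivity range of DBSCAN at
eps ≈ 10 nm, matching the observed behaviour of real data where
multi-protein clusters are detected as single localization clusters.  At a
40 nm scale the simulated clusters fragment (measured pairwise merge
probability drops to ~50% beyond 30 nm separation), which no analysis
setting faithful to the published parameters can undo.

The generator's per-protein binding rate is 1.2× the nominal k_ON·[I]
product (`binding_rate_multiplier`).  This matches the measured
single-protein qPAINT index of 0.012 Hz — somewhat above the nominal
0.010 Hz, consistent with a repetitive docking motif binding imagers
faster than a single site — while the analysis side keeps deriving its
minPts cut from the nominal constants, as the published derivation does.

## Nonspecific signal

Two populations emulate nonspecific events:

- a uniform spatio-temporal Poisson background of single-frame
  localizations (default 0.01 µm⁻²frame⁻¹), which DBSCAN rejects as noise;
- transient "sticky" sites (default 3.5 µm⁻², 3× binding rate, residence
  uniform over 150–450 s, onset uniform over the acquisition), which do
  form DBSCAN clusters and are the realistic target of the mean-frame
  filter.  Uniform single-frame background alone can never exercise that
  filter: at any realistic rate its local density (~0.05 events per
  eps-disc) never reaches minPts.

## What the generator does not emulate

Antibody size and linkage error (the localization cloud is centred exactly
on the protein), label/detection efficiency below one, drift (flag is a
stub), z-dimension, photobleaching of the dye pool, and spatially
correlated backgrounds.  Passing recovery tests therefore demonstrate the
correctness of the analysis chain under the stated kinetic and spatial
model, not robustness to every artefact of real membranes.

## Analysis chain: numerical choices

- **Uncertainty filter**: strictly-greater semantics (13.0 nm is kept).
- **NeNA**: nearest-neighbour distances between localizations in frames f
  and f+1, capped at 200 nm; histogram (1 nm bins) fitted with
  A·(d/2σ²)exp(−d²/4σ²) + B·d.  The linear term absorbs uniform background
  pairs (tested to 20% contamination).  A median-based closed-form
  estimator (median d = 2σ√ln2) provides the initial value and the
  fallback in degenerate regimes (e.g. noiseless data).
- **DBSCAN**: eps defaults to the NeNA σ rounded to the nearest nm; minPts
  to the largest m with P(Poisson(yield) ≤ m−1) ≤ 2×10⁻⁶, the tail
  probability frozen once so the default configuration reproduces the
  published operating point (yield 40 → minPts 15).  Border points
  reachable from two clusters follow scikit-learn's deterministic
  first-discovered assignment; tests check equivalence with a brute-force
  reference on the noise set and the core-point partition.
- **Mean-frame filter**: Gaussian "fit" = sample mean/SD of per-cluster
  mean frames (equivalent to a least-squares histogram fit at large n,
  with no binning choice); rejection band exactly ±1 SD.  With fewer than
  3 clusters, or zero SD, the filter passes everything through with a
  warning.
- **Dark times**: gaps before the first and after the last event are
  censored draws and are excluded.  Gaps of a single empty frame are also
  excluded by default (`min_dark_frames=2`): a one-frame hole inside a
  bright run is indistinguishable from a localization lost to quality
  filtering, and such dropout holes otherwise contaminate a monomer's gap
  list with up to ~45% spurious 0.1 s entries — enough to flip the CDF fit
  to absurd τ_d values.  The cost is the loss of true dark times below
  0.2 s (probability 0.24% at the single-site rate; still <5% for clusters
  of ~20 sites).
- **Dark-time fit**: least-squares fit of the empirical CDF (each gap its
  own abscissa, plotting positions (i−½)/n) with 1 − exp(−t/τ_d).  The
  growing-exponent form sometimes printed for this model is not a CDF; the
  standard negative exponent is used.  Fewer than 5 gaps → sample mean
  (the exponential MLE), flagged; identical gaps → that value exactly.
- **Calibration**: clusters with maximum pairwise extent < 100 nm enter a
  histogram of q_i (bins ≈ 3√n up to the 99.5th percentile); model = sum of
  K = 4 Gaussians with centres k·q_i1, per-peak free amplitudes and widths;
  q_i1 initialised at the histogram mode; fit failure falls back to the
  mode with a degraded-precision flag.  Counting precision is reported as
  first-peak σ divided by q_i1, in protein units.
- **Counting**: N = q_i/q_i1 rounded half away from zero, minimum 1.
- **k-means**: k = N, k-means++ with 10 restarts, best inertia, seeded;
  fewer localizations than proteins → centroid replicated with a warning.
- **Grouping**: proteins of one localization cluster always stay together
  (they were counted as one kinetic unit).  An optional single-linkage
  radius can merge nearby parent groups; the default (off) mirrors the
  convention that one localization cluster is one candidate protein
  cluster.
- **Statistics**: protein clusters are groups of ≥ 3; size classes small
  (<6), medium (6–12 inclusive), large (>12).  Equivalent diameter =
  diameter of the circle with the area of the convex hull of the member
  localizations (protein-position hulls available as an option);
  first-neighbour distances among protein positions, edge effects
  uncorrected, median reported.  An ROI with zero proteins reports its
  percentage as missing, not zero.
- **Morphology index** (cell-shape measure): perimeter²/(4π·area) of a
  simple polygon; 1 for a circle, scale invariant.

## Known biases of the full pipeline (quantified on synthetic data)

Recovery at the default study conditions (20 ROIs, 23 µm⁻², 44%
clustered): the clustered-protein percentage is recovered within ~1–3
points, but the absolute protein density is recovered at only ~75% of
truth.  Two mechanisms, both faithful to the published operating point,
account for the deficit:

1. The ±1 SD mean-frame band removes ~20–25% of genuine clusters whenever
   genuine temporal variance is not dominated by contamination.  With ~17
   binding events per site the per-cluster mean frame has SD ≈ 1100–1300
   frames, and a band of about one such SD necessarily cuts the tails of
   the genuine distribution — monomers (widest mean-frame spread)
   preferentially.
2. At eps = σ and minPts = 15, a monomer cloud of ~45 localizations with
   9 nm scatter has an expected in-eps neighbour count of ~15–18 at its
   centre — right at the core-point margin — so a fraction of monomers
   never seeds a cluster.

Both effects cancel out of *relative* comparisons between conditions
analysed identically, which is how such cluster statistics are used; they
do bias absolute densities low.  The recovery harness reports both the
recovered and ground-truth values so the bias stays visible.

## Problem sizes

Default validation sizes were chosen to keep every statistical tolerance
well-powered: 500 sites for yield and mean-frame checks (SE < 1%), ≥10⁴
events for bright-time and ≥10⁴ pairs for NeNA checks, 300 clusters for
calibration, 20 ROIs for full-pipeline recovery (SE ≈ 1.4 points on the
clustered percentage).
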