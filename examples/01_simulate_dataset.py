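"""Simulate a DNA-PAINT acquisition of a membrane-protein distribution.

Builds a 3.5 x 3.5 um ground-truth protein map (23 proteins/um^2, 44% of
them in nanoclusters of >= 3), runs the two-state imager-binding kinetics
per docking site over 15000 frames at 100 ms, and renders the resulting
localization table with 9 nm localization error plus nonspecific signal.
"""

import numpy as np

from qpaintlib import AcquisitionParams, GeneratorConfig, KineticsModel, simulate_dataset

acq = AcquisitionParams()          # 15000 frames, 100 ms, 130 nm px, sigma 9 nm
kin = KineticsModel()              # k_on 1e7 /M/s, 1 nM imager, tau_bright 0.27 s
config = GeneratorConfig()         # 23 um^-2, 44% clustered, mostly small clusters

ds = simulate_dataset(config, acq, kin, seed=7)

truth = ds.truth
print(f"ground truth: {truth.n_proteins} proteins over {config.area_um2:.2f} um^2 "
      f"({truth.realized_density:.1f} um^-2)")
print(f"  fraction in clusters of >= 3: {100 * truth.fraction_clustered:.1f} %")
n_clusters = len(np.unique(truth.cluster_assignment[truth.cluster_assignment > 0]))
print(f"  nanoclusters planted: {n_clusters}")
print(f"localization table: {len(ds.table)} rows")
src = ds.table.df["source"].to_numpy()
print(f"  from proteins: {(src >= 0).sum()}, uniform background: {(src == -1).sum()}, "
      f"transient nonspecific sites: {(src == -2).sum()}")
per_site = (src >= 0).sum() / truth.n_proteins
print(f"  localizations per docking site: {per_site:.1f} "
      "(the closed-form kinetic prediction is n_frames*tau_bright*k_on*[I] ~ 40, "
      "scaled by the motif's 1.2x binding-rate enhancement)")

# ds.table.to_csv("localizations.csv") and truth.to_csv("ground_truth.csv")
# write the standard CSV outputs when files are needed.
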