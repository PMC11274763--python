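"""Diagonal NCA feature ranking of whole-brain graph measures.

One row per subject (ten whole-brain features: CC, SW, LE, PL, GE, Ass,
PC, FC, Mod, BC), class = group. NCA learns one weight per feature by
minimizing the expected leave-one-out soft-nearest-neighbor
misclassification loss plus an L2 penalty; importance = weight^2.
"""

import warnings

import pandas as pd

import fconnet as fc

atlas = fc.make_atlas(40)
design = fc.default_design(atlas, seed=4, match_mean_connectivity=True)
cohort = fc.generate_cohort(atlas, design)
mats = [fc.pearson_matrix(ts) for ts in cohort]
grid = fc.default_sparsity_grid()
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    frames = [
        fc.metrics_over_grid(
            cm, grid, labels=list(atlas.labels),
            null_config=fc.NullConfig(n_nulls=6, swaps_per_edge=3, seed=4),
            louvain_restarts=3, seed=1000 * i,
        )
        for i, cm in enumerate(mats)
    ]
integ = fc.integrate_over_sparsity(pd.concat(frames, ignore_index=True))

ft = fc.build_feature_table(integ, mats)
rr = fc.nca_rank(ft)
print(fc.rank_report(rr).to_string(index=False))
print("\nTop-ranked features are the measures most sensitive to the "
      "three-group distinction; with effects injected through segregation, "
      "small-worldness and the clustering/local-efficiency family dominate.")
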