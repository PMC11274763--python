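"""Group comparisons of integrated clustering: whole-brain, network-level
(normalized clustering for DMN and cingulo-opercular) and nodal with FDR.

Each measure is integrated over the sparsity grid (area under the
metric-versus-sparsity curve) before testing, so no single threshold
drives the result.
"""

import pandas as pd

import fconnet as fc

atlas = fc.make_atlas(40)
cohort = fc.generate_cohort(atlas, fc.default_design(atlas, seed=3))
mats = [fc.pearson_matrix(ts) for ts in cohort]
grid = fc.default_sparsity_grid()
frames = [
    fc.metrics_over_grid(cm, grid, labels=list(atlas.labels), metrics=("clustering",))
    for cm in mats
]
integ = fc.integrate_over_sparsity(pd.concat(frames, ignore_index=True))

comp = fc.global_comparison(integ, ("HC", "ODP"), "clustering")
print(f"whole-brain clustering, HC vs ODP: t = {comp.t:.2f}, p = {comp.p:.2g} "
      "(negative t: ODP lower)")

for net in ("default", "cingulo-opercular"):
    res = fc.network_level_summary(integ, atlas, net)
    means = res["summary"].set_index("group")["mean"]
    print(f"{net} normalized clustering: "
          + ", ".join(f"{g}={means[g]:.3f}" for g in ("HC", "ODN", "ODP")))

nodal = fc.nodal_comparison(integ, atlas, ("HC", "ODP"), mode="fdr05")
sig = nodal[nodal["significant"]]
print(f"nodal comparison (FDR<0.05 over {len(nodal)} ROIs): "
      f"{len(sig)} significant nodes")
print(sig[["label", "network", "t", "p", "q"]].head(8).to_string(index=False))
print("\nExpected pattern: DMN normalized clustering rises HC -> ODN -> ODP "
      "while cingulo-opercular falls, mirroring the designed double dissociation.")
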