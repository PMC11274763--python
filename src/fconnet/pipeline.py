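"""End-to-end pipeline: time series -> connectivity -> graphs -> metrics ->
group statistics -> feature ranking, with every artifact written as
delimited text and a run log recording config, seed and library versions.
Re-running with identical config and inputs is bit-identical."""

from __future__ import annotations

import itertools
import os
import warnings

import networkx
import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .connectivity import SparsityGrid, pearson_matrix
from .io import PipelineConfig, read_atlas, read_cohort, write_matrix, write_node_export
from .metrics import integrate_over_sparsity, metrics_over_grid
from .ranking import build_feature_table, nca_rank, rank_report
from .stats import StatsError, global_comparison, network_level_summary, nodal_comparison

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all artifacts under ``config.outdir``.

    Returns a dict with the in-memory results and the paths written.
    """
    config.validate()
    atlas = read_atlas(config.atlas)
    cohort = read_cohort(config.manifest, atlas)
    groups_in_order = list(dict.fromkeys(ts.group for ts in cohort))
    if len(groups_in_order) < 2:
        raise PipelineError(
            f"need at least 2 groups for comparisons, manifest has {groups_in_order}"
        )
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    conn_dir = os.path.join(outdir, "connectivity")
    os.makedirs(conn_dir, exist_ok=True)
    paths: dict[str, str] = {}

    grid = SparsityGrid(config.sparsity)
    matrices = []
    for ts in cohort:
        cm = pearson_matrix(ts)
        matrices.append(cm)
        write_matrix(cm, os.path.join(conn_dir, f"{ts.subject_id}_fisherz.tsv"), atlas.labels)

    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # isolated nodes at sparse thresholds
        for i, cm in enumerate(matrices):
            frames.append(
                metrics_over_grid(
                    cm,
                    grid,
                    labels=list(atlas.labels),
                    null_config=config.null,
                    louvain_restarts=config.louvain_restarts,
                    seed=config.seed + 1000 * i,
                    edge_rank=config.edge_rank,
                )
            )
    table = pd.concat(frames, ignore_index=True)
    paths["metrics"] = os.path.join(outdir, "metrics_long.tsv")
    table.to_csv(paths["metrics"], sep="\t", index=False, float_format=_FLOAT_FMT)

    integrated = integrate_over_sparsity(table)
    paths["integrated"] = os.path.join(outdir, "metrics_integrated.tsv")
    integrated.to_csv(paths["integrated"], sep="\t", index=False, float_format=_FLOAT_FMT)

    stats_dir = os.path.join(outdir, "stats")
    os.makedirs(stats_dir, exist_ok=True)
    nodal = {}
    global_rows = []
    for g1, g2 in itertools.combinations(groups_in_order, 2):
        comp = nodal_comparison(
            integrated, atlas, (g1, g2), metric=config.stats_metric, mode=config.stats_mode
        )
        nodal[(g1, g2)] = comp
        p = os.path.join(stats_dir, f"nodal_{config.stats_metric}_{g1}_vs_{g2}.tsv")
        comp.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
        paths[f"nodal_{g1}_vs_{g2}"] = p
        write_node_export(comp, os.path.join(stats_dir, f"nodes_{g1}_vs_{g2}.tsv"))
        for metric in ("clustering", "path_length", "local_efficiency",
                       "global_efficiency", "sigma", "modularity",
                       "participation", "assortativity", "betweenness"):
            if metric not in set(integrated["metric"]):
                continue
            try:
                global_rows.append(global_comparison(integrated, (g1, g2), metric).__dict__)
            except StatsError as exc:  # undefined metric for too many subjects
                warnings.warn(f"skipping global contrast: {exc}", stacklevel=2)
    global_df = pd.DataFrame(global_rows)
    paths["global_stats"] = os.path.join(stats_dir, "global_comparisons.tsv")
    global_df.to_csv(paths["global_stats"], sep="\t", index=False, float_format=_FLOAT_FMT)

    networks = {}
    net_frames = []
    for net in atlas.network_names:
        res = network_level_summary(integrated, atlas, net, metric=config.stats_metric)
        networks[net] = res
        s = res["summary"].copy()
        s.insert(0, "network", net)
        net_frames.append(s)
    paths["network_summary"] = os.path.join(stats_dir, "network_normalized_summary.tsv")
    pd.concat(net_frames, ignore_index=True).to_csv(
        paths["network_summary"], sep="\t", index=False, float_format=_FLOAT_FMT
    )

    ft = build_feature_table(integrated, matrices)
    rr = nca_rank(
        ft,
        beta=config.nca_beta,
        kernel_width=config.nca_kernel_width,
        max_iter=config.nca_max_iter,
        seed=config.seed,
    )
    report = rank_report(rr)
    paths["ranking"] = os.path.join(outdir, "ranking.tsv")
    report.to_csv(paths["ranking"], sep="\t", index=False, float_format=_FLOAT_FMT)

    paths["run_log"] = os.path.join(outdir, "run_log.yaml")
    with open(paths["run_log"], "w") as fh:
        yaml.safe_dump(
            {
                "config": config.to_dict(),
                "seed": config.seed,
                "versions": {
                    "fconnet": __version__,
                    "numpy": np.__version__,
                    "scipy": scipy.__version__,
                    "pandas": pd.__version__,
                    "networkx": networkx.__version__,
                },
            },
            fh,
            sort_keys=True,
        )

    return {
        "atlas": atlas,
        "matrices": matrices,
        "metrics": table,
        "integrated": integrated,
        "nodal": nodal,
        "global": global_df,
        "networks": networks,
        "ranking": report,
        "paths": paths,
    }
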