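"""Group comparisons of graph measures with multiple-comparison control.

Two-sample two-tailed t-tests (equal-variance by default, matching the
classical formulation; Welch available via a flag) compare groups on
cross-sparsity integrated measures, per node or globally. Nodal families
are corrected per contrast with Benjamini–Hochberg FDR; an uncorrected
p < 0.005 mode is provided for exploratory nodal maps. Network-level
summaries report the normalized clustering coefficient: a subject's mean
nodal clustering over one functional network divided by the whole-brain
mean nodal clustering. (The normalization is an interpretation choice —
it expresses each network relative to the subject's overall segregation
level — and is applied identically to every group.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .atlas import AtlasSpec
from .metrics import GLOBAL

MODES = ("fdr05", "uncorrected_p005")


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class ComparisonResult:
    """One group contrast on one measure at one level (GLOBAL, node or
    network). Reported t carries the sign of (second - first), so a
    negative t means the second group in the contrast is lower — the usual
    patient-versus-control table convention. Swapping the contrast order
    flips every sign exactly."""

    contrast: str
    metric: str
    level: str
    t: float
    p: float
    q: float
    significant: bool


def two_sample_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[float, float]:
    """Classical two-sample two-tailed t-test; sign = mean(a) - mean(b).

    Raises on n < 2 per group or zero pooled variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise StatsError("non-finite values in t-test input")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise StatsError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def fdr_bh(p: np.ndarray, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: adjusted q-values and rejection mask."""
    p = np.asarray(p, dtype=float)
    reject, qvals, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return qvals, reject


def nodal_comparison(
    table: pd.DataFrame,
    atlas: AtlasSpec,
    contrast: tuple[str, str],
    metric: str = "clustering",
    mode: str = "fdr05",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-node group comparison on an integrated metric table.

    Parameters
    ----------
    table : long-format integrated table (subject, group, metric, node, value)
    contrast : (group_first, group_second); reported t sign = second -
        first, so negative t means the second group is lower
    mode : 'fdr05' (BH over the node family at q < 0.05) or
        'uncorrected_p005' (p < 0.005, no correction)

    Returns a table in reporting layout: x, y, z, label, network, t, p, q,
    significant — one row per node, sorted by p.
    """
    if mode not in MODES:
        raise StatsError(f"mode must be one of {MODES}, got {mode!r}")
    g1, g2 = contrast
    present = set(table["group"])
    for g in contrast:
        if g not in present:
            raise StatsError(f"group {g!r} not present in table")
    sub = table[(table["metric"] == metric) & (table["node"] != GLOBAL)]
    if sub.empty:
        raise StatsError(f"no nodal rows for metric {metric!r}")
    wide = sub.pivot_table(index="node", columns="subject", values="value")
    subj_group = table.drop_duplicates("subject").set_index("subject")["group"]
    cols1 = [s for s in wide.columns if subj_group[s] == g1]
    cols2 = [s for s in wide.columns if subj_group[s] == g2]

    labels = list(atlas.labels)
    missing = set(wide.index) - set(labels)
    if missing:
        raise StatsError(f"table nodes not in atlas: {sorted(missing)[:5]}")
    wide = wide.reindex([l for l in labels if l in wide.index])

    ts, ps = [], []
    for _, row in wide.iterrows():
        t, p = two_sample_t(row[cols2].to_numpy(), row[cols1].to_numpy(), equal_var)
        ts.append(t)
        ps.append(p)
    ts = np.asarray(ts)
    ps = np.asarray(ps)
    qs, reject = fdr_bh(ps, 0.05)
    sig = reject if mode == "fdr05" else ps < 0.005

    idx = [labels.index(l) for l in wide.index]
    out = pd.DataFrame(
        {
            "x": atlas.coords[idx, 0],
            "y": atlas.coords[idx, 1],
            "z": atlas.coords[idx, 2],
            "label": wide.index,
            "network": [atlas.networks[i] for i in idx],
            "t": ts,
            "p": ps,
            "q": qs,
            "significant": sig,
        }
    )
    out.insert(0, "contrast", f"{g1}_vs_{g2}")
    out.insert(1, "metric", metric)
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def global_comparison(
    table: pd.DataFrame,
    contrast: tuple[str, str],
    metric: str,
    equal_var: bool = True,
) -> ComparisonResult:
    """Group contrast on the GLOBAL (whole-brain) value of one metric."""
    g1, g2 = contrast
    sub = table[(table["metric"] == metric) & (table["node"] == GLOBAL)]
    if sub.empty:
        raise StatsError(f"no GLOBAL rows for metric {metric!r}")
    a = sub[sub["group"] == g1]["value"].to_numpy()
    b = sub[sub["group"] == g2]["value"].to_numpy()
    # metrics can be undefined for single subjects (e.g. assortativity of a
    # regular graph); such subjects are excluded from the contrast
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise StatsError(
            f"contrast {contrast} on {metric!r}: fewer than 2 defined values per group"
        )
    t, p = two_sample_t(b, a, equal_var)
    return ComparisonResult(
        contrast=f"{g1}_vs_{g2}", metric=metric, level=GLOBAL,
        t=t, p=p, q=p, significant=bool(p < 0.05),
    )


def network_level_summary(
    table: pd.DataFrame,
    atlas: AtlasSpec,
    network: str,
    metric: str = "clustering",
    equal_var: bool = True,
) -> dict:
    """Per-subject normalized clustering for one functional network.

    normalized value = mean nodal metric over the network's ROIs divided by
    the whole-brain mean nodal metric, per subject. Returns a dict with
    ``per_subject`` (subject, group, value), ``summary`` (group mean/sd/n,
    in table group order) and ``tests`` (pairwise equal-variance t-tests).
    A zero whole-brain mean yields NaN for that subject.
    """
    net_idx = atlas.network_indices(network)
    if net_idx.size == 0:
        raise StatsError(f"network {network!r} has no ROIs in this atlas")
    net_labels = [atlas.labels[i] for i in net_idx]
    sub = table[(table["metric"] == metric) & (table["node"] != GLOBAL)]
    if sub.empty:
        raise StatsError(f"no nodal rows for metric {metric!r}")
    per = []
    for (subject, group), grp in sub.groupby(["subject", "group"], sort=False):
        whole = grp["value"].mean()
        net = grp[grp["node"].isin(net_labels)]["value"].mean()
        val = net / whole if whole != 0 else float("nan")
        per.append({"subject": subject, "group": group, "value": val})
    per_subject = pd.DataFrame(per)
    summary = (
        per_subject.groupby("group", sort=False)["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    groups = list(summary["group"])
    tests = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a = per_subject[per_subject["group"] == groups[i]]["value"].to_numpy()
            b = per_subject[per_subject["group"] == groups[j]]["value"].to_numpy()
            t, p = two_sample_t(b, a, equal_var)
            tests.append(
                {"contrast": f"{groups[i]}_vs_{groups[j]}", "t": t, "p": p}
            )
    return {
        "network": network,
        "per_subject": per_subject,
        "summary": summary,
        "tests": pd.DataFrame(tests),
    }
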