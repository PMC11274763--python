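"""Diagonal neighborhood-component-analysis (NCA) feature ranking.

Given one row of whole-brain measures per subject and a class label
(group), diagonal NCA learns one non-negative weight per feature by
minimizing the expected leave-one-out soft-nearest-neighbor
misclassification loss plus an L2 penalty on the weights:

    F(w) = (1/n) sum_i sum_{j != i} p_ij * [y_i != y_j]  +  beta * sum_r w_r^2

with reference-point probabilities

    p_ij = exp(-d_w(x_i, x_j) / sigma) / sum_{j' != i} exp(-d_w(x_i, x_j') / sigma)

and the weighted L1 distance d_w(x_i, x_j) = sum_r w_r^2 |x_ir - x_jr|
(the form implemented by MATLAB's fscnca). Leave-one-out is implicit in
the j != i sum; no outer CV loop. Feature importance is w_r^2; features
are ranked by importance.

The ten standard whole-brain features are, in fixed order:
CC (clustering coefficient), SW (small-worldness sigma), LE (local
efficiency), PL (characteristic path length), GE (global efficiency),
Ass (assortativity), PC (participation coefficient), FC (mean
upper-triangle Fisher-z connectivity), Mod (modularity), BC (mean
betweenness centrality).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .connectivity import ConnectivityMatrix
from .metrics import GLOBAL

#: Feature short-names in canonical order, and the metric-table name backing
#: each (FC comes from the connectivity matrices, not the metric table).
FEATURES: tuple[str, ...] = ("CC", "SW", "LE", "PL", "GE", "Ass", "PC", "FC", "Mod", "BC")
_FEATURE_METRIC: dict[str, str] = {
    "CC": "clustering",
    "SW": "sigma",
    "LE": "local_efficiency",
    "PL": "path_length",
    "GE": "global_efficiency",
    "Ass": "assortativity",
    "PC": "participation",
    "Mod": "modularity",
    "BC": "betweenness",
}


class RankingError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureTable:
    """Standardized n-subjects x p-features design matrix with class labels."""

    X: np.ndarray = field(repr=False)
    y: tuple[str, ...]
    feature_names: tuple[str, ...]
    means: np.ndarray = field(repr=False)
    sds: np.ndarray = field(repr=False)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class RankingResult:
    """Learned diagonal NCA weights and the induced feature ordering."""

    w: np.ndarray = field(repr=False)
    feature_names: tuple[str, ...]
    beta: float
    kernel_width: float
    objective: float
    trace: tuple[float, ...] = field(repr=False)
    converged: bool = True

    @property
    def importance(self) -> np.ndarray:
        return self.w**2

    @property
    def ordering(self) -> tuple[str, ...]:
        """Features sorted by importance, descending (stable for ties)."""
        idx = np.argsort(-self.importance, kind="stable")
        return tuple(self.feature_names[i] for i in idx)


def standardize(X: np.ndarray, feature_names: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """z-score each column; a constant column is an error (named)."""
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    dead = np.flatnonzero(sds == 0)
    if dead.size:
        raise RankingError(
            f"constant feature(s) cannot be standardized: "
            f"{[feature_names[i] for i in dead]}"
        )
    return (X - means) / sds, means, sds


def build_feature_table(
    integrated: pd.DataFrame,
    matrices: list[ConnectivityMatrix],
    features: tuple[str, ...] = FEATURES,
) -> FeatureTable:
    """Assemble the subjects x features matrix.

    Parameters
    ----------
    integrated : long-format integrated metric table (from
        :func:`fconnet.metrics.integrate_over_sparsity`) containing GLOBAL
        rows for every metric backing the requested features.
    matrices : the subjects' connectivity matrices (for the FC feature).
    """
    if len(features) < 1:
        raise RankingError("at least one feature required")
    fc = {m.subject_id: m.mean_connectivity() for m in matrices}
    glob = integrated[integrated["node"] == GLOBAL]
    wide = glob.pivot_table(index="subject", columns="metric", values="value")
    subj_group = integrated.drop_duplicates("subject").set_index("subject")["group"]
    subjects = list(wide.index)
    cols = []
    for f in features:
        if f == "FC":
            missing = [s for s in subjects if s not in fc]
            if missing:
                raise RankingError(f"no connectivity matrix for subject(s) {missing}")
            cols.append(np.array([fc[s] for s in subjects]))
        else:
            metric = _FEATURE_METRIC[f]
            if metric not in wide.columns:
                raise RankingError(f"metric {metric!r} (feature {f}) not in table")
            cols.append(wide[metric].to_numpy(dtype=float))
    X = np.column_stack(cols)
    if not np.all(np.isfinite(X)):
        bad = [features[j] for j in np.unique(np.nonzero(~np.isfinite(X))[1])]
        raise RankingError(f"non-finite values in feature(s) {bad}")
    y = tuple(subj_group[s] for s in subjects)
    if len(set(y)) < 2:
        raise RankingError("feature table needs at least 2 classes")
    Xs, means, sds = standardize(X, tuple(features))
    return FeatureTable(Xs, y, tuple(features), means, sds)


def _nca_objective(
    w: np.ndarray, D: np.ndarray, L: np.ndarray, beta: float, sigma: float
) -> tuple[float, np.ndarray]:
    """Value and gradient of the diagonal-NCA objective.

    D : (n, n, p) per-feature absolute differences |x_ir - x_jr|
    L : (n, n) 0/1 label-disagreement matrix
    """
    n = D.shape[0]
    d = D @ (w**2)  # (n, n) weighted L1 distances
    np.fill_diagonal(d, np.inf)
    a = -d / sigma
    a -= a.max(axis=1, keepdims=True)  # row-wise shift for stability
    k = np.exp(a)
    np.fill_diagonal(k, 0.0)
    p = k / k.sum(axis=1, keepdims=True)
    eps = (p * L).sum(axis=1)  # per-subject expected LOO loss
    value = eps.mean() + beta * float(w @ w)
    # dF/dw_r = (2 w_r / (n sigma)) sum_i [ eps_i <D^r>_i - <L D^r>_i ] + 2 beta w_r
    pd_mean = np.einsum("ij,ijr->ir", p, D)  # <D^r>_i
    pld_mean = np.einsum("ij,ij,ijr->ir", p, L, D)  # <L D^r>_i
    inner = (eps[:, None] * pd_mean - pld_mean).sum(axis=0)
    grad = (2.0 * w / (n * sigma)) * inner + 2.0 * beta * w
    return value, grad


def nca_rank(
    ft: FeatureTable,
    beta: float | None = None,
    kernel_width: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-8,
    seed: int = 0,
) -> RankingResult:
    """Learn diagonal NCA feature weights.

    Deterministic: optimization is L-BFGS-B from the fixed start w_r = 1;
    ``seed`` is accepted for interface uniformity but unused by the
    deterministic optimizer. ``beta`` defaults to 1/n. The objective trace
    over accepted iterates is returned; non-convergence within ``max_iter``
    flags the result instead of raising.
    """
    del seed  # deterministic optimizer; kept for interface uniformity
    X, y = ft.X, np.asarray(ft.y)
    n, p = X.shape
    if beta is None:
        beta = 1.0 / n
    D = np.abs(X[:, None, :] - X[None, :, :])
    L = (y[:, None] != y[None, :]).astype(float)
    trace: list[float] = []

    def fun(w):
        return _nca_objective(w, D, L, beta, kernel_width)

    w0 = np.ones(p)
    trace.append(_nca_objective(w0, D, L, beta, kernel_width)[0])
    res = minimize(
        fun,
        w0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
        callback=lambda wk: trace.append(
            _nca_objective(wk, D, L, beta, kernel_width)[0]
        ),
    )
    w = np.abs(res.x)  # objective depends on w only through w^2
    return RankingResult(
        w=w,
        feature_names=ft.feature_names,
        beta=float(beta),
        kernel_width=float(kernel_width),
        objective=float(res.fun),
        trace=tuple(trace),
        converged=bool(res.success),
    )


def rank_report(rr: RankingResult) -> pd.DataFrame:
    """Ordered ranking table: feature, weight, importance, normalized
    importance (sums to 1; uniform if all importances are 0), rank."""
    imp = rr.importance
    total = imp.sum()
    norm = imp / total if total > 0 else np.full_like(imp, 1.0 / imp.size)
    df = pd.DataFrame(
        {
            "feature": rr.feature_names,
            "weight": rr.w,
            "importance": imp,
            "normalized_importance": norm,
        }
    )
    df = df.sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
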