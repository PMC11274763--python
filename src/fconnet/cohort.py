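"""Synthetic three-group cohort generator.

Each subject's ROI time series is drawn from a zero-mean multivariate normal
whose correlation matrix is block-structured: within-network off-diagonal
entries take a per-group, per-network target value, all other off-diagonals
take a (smaller) between-network value, with unit diagonal. Independent
Gaussian observation noise of standard deviation ``noise_sd`` is added.

The default design emulates a three-group resting-state study (healthy
controls HC, cognitively normal patients ODN, severely hyposmic patients
ODP, 15 subjects each): within-network correlation — the generator's handle
on network segregation — decreases progressively HC > ODN > ODP, with a
default-mode-network-specific increase and a cingulo-opercular decrease in
the patient groups, so the downstream double dissociation (DMN up,
cingulo-opercular down) is recoverable from the generated data.

Note on observation noise: adding i.i.d. noise of variance ``s**2`` to unit
variance signals attenuates every correlation by ``1 / (1 + s**2)``; the
empirical matrices therefore converge to the *attenuated* block structure,
not the raw targets, unless ``noise_sd=0``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import AtlasSpec, CANONICAL_NETWORKS

DEFAULT_GROUPS: tuple[tuple[str, int], ...] = (("HC", 15), ("ODN", 15), ("ODP", 15))

#: Default per-group within-network correlation targets.
DEFAULT_WITHIN_CORR: dict[str, dict[str, float]] = {
    "HC": {net: 0.60 for net in CANONICAL_NETWORKS},
    "ODN": {
        net: {"default": 0.58, "cingulo-opercular": 0.46}.get(net, 0.52)
        for net in CANONICAL_NETWORKS
    },
    "ODP": {
        net: {"default": 0.62, "cingulo-opercular": 0.36}.get(net, 0.42)
        for net in CANONICAL_NETWORKS
    },
}


class DesignError(ValueError):
    """Raised for invalid cohort designs."""


class GenerationError(RuntimeError):
    """Raised when the target correlation matrix is unusable."""


@dataclass(frozen=True)
class CohortDesign:
    """Specification of a synthetic multi-group cohort.

    Attributes
    ----------
    groups : ordered tuple of (group_name, n_subjects)
    n_timepoints : samples per subject (default 150, a conventional run
        length at TR = 2.5 s; configurable)
    within_corr : group -> network -> target within-network correlation
    between_corr : scalar in [0, min within) or per-group map
    noise_sd : observation-noise standard deviation
    seed : master seed; identical seed => bit-identical cohort
    """

    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUPS
    n_timepoints: int = 150
    within_corr: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_WITHIN_CORR.items()}
    )
    between_corr: float | dict[str, float] = 0.10
    noise_sd: float = 0.3
    seed: int = 0

    def group_between(self, group: str) -> float:
        if isinstance(self.between_corr, dict):
            return float(self.between_corr[group])
        return float(self.between_corr)

    def validate(self) -> None:
        if self.n_timepoints < 3:
            raise DesignError("n_timepoints must be at least 3")
        if self.noise_sd < 0:
            raise DesignError("noise_sd must be non-negative")
        names = [g for g, _ in self.groups]
        if len(set(names)) != len(names):
            raise DesignError("duplicate group names")
        for g, n in self.groups:
            if n < 1:
                raise DesignError(f"group {g!r} has no subjects")
            if g not in self.within_corr:
                raise DesignError(f"no within_corr map for group {g!r}")
            b = self.group_between(g)
            if b < 0:
                raise DesignError(f"between_corr for group {g!r} is negative")
            for net, w in self.within_corr[g].items():
                if not (0.0 <= w < 1.0):
                    raise DesignError(
                        f"within_corr[{g!r}][{net!r}]={w} outside [0, 1)"
                    )
                # within must exceed between, except for the degenerate
                # identity design (both zero: pure independence null)
                if w <= b and not (w == 0.0 and b == 0.0):
                    raise DesignError(
                        f"within_corr[{g!r}][{net!r}]={w} must exceed "
                        f"between_corr={b}"
                    )


@dataclass(frozen=True)
class SubjectTimeSeries:
    """One subject's T x N ROI signal matrix (BOLD-like arbitrary units)."""

    subject_id: str
    group: str
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (T x N)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id}: non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


def target_correlation(
    atlas: AtlasSpec, design: CohortDesign, group: str
) -> np.ndarray:
    """Block-structured target correlation matrix for one group."""
    n = atlas.n_rois
    b = design.group_between(group)
    r = np.full((n, n), b)
    for net in atlas.network_names:
        idx = atlas.network_indices(net)
        w = design.within_corr[group].get(net)
        if w is None:
            raise DesignError(f"group {group!r} missing within_corr for {net!r}")
        r[np.ix_(idx, idx)] = w
    np.fill_diagonal(r, 1.0)
    return r


def check_positive_definite(
    r: np.ndarray, atlas: AtlasSpec | None = None, group: str = ""
) -> np.ndarray:
    """Cholesky factor of ``r``; on failure, name the offending network block.

    With the design invariants (within > between >= 0, within < 1) the block
    matrix is provably positive definite; this check is a safety net for
    correlation matrices supplied from outside the design path.
    """
    try:
        return np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        where = "global structure"
        if atlas is not None:
            for net in atlas.network_names:
                idx = atlas.network_indices(net)
                block = r[np.ix_(idx, idx)]
                if np.linalg.eigvalsh(block)[0] <= 0:
                    where = f"network block {net!r}"
                    break
        tag = f" (group {group!r})" if group else ""
        raise GenerationError(
            f"target correlation matrix is not positive definite: {where}{tag}"
        ) from None


def generate_cohort(
    atlas: AtlasSpec, design: CohortDesign
) -> list[SubjectTimeSeries]:
    """Draw a full cohort of subject time series.

    Deterministic: the same ``design.seed`` yields a bit-identical cohort.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    cohort: list[SubjectTimeSeries] = []
    t = design.n_timepoints
    for group, n_subj in design.groups:
        r = target_correlation(atlas, design, group)
        chol = check_positive_definite(r, atlas, group)
        for k in range(n_subj):
            z = rng.standard_normal((t, atlas.n_rois))
            data = z @ chol.T
            if design.noise_sd > 0:
                data = data + design.noise_sd * rng.standard_normal(data.shape)
            cohort.append(
                SubjectTimeSeries(f"sub-{group}{k + 1:02d}", group, data)
            )
    return cohort


def default_design(
    atlas: AtlasSpec | None = None,
    n_subjects: int = 15,
    n_timepoints: int = 150,
    noise_sd: float = 0.3,
    seed: int = 0,
    match_mean_connectivity: bool = False,
) -> CohortDesign:
    """The study-emulating three-group design (HC / ODN / ODP).

    With ``match_mean_connectivity=True`` the per-group between-network
    correlation is solved so that the weighted mean off-diagonal correlation
    is identical across groups: group differences are then injected purely
    through segregation (the within/between contrast), not through overall
    connectivity strength. Requires ``atlas`` (the within-pair fraction
    depends on network sizes).
    """
    groups = tuple((g, n_subjects) for g, _ in DEFAULT_GROUPS)
    design = CohortDesign(
        groups=groups,
        n_timepoints=n_timepoints,
        noise_sd=noise_sd,
        seed=seed,
    )
    if not match_mean_connectivity:
        return design
    if atlas is None:
        raise DesignError("match_mean_connectivity requires an atlas")
    # within-pair count per network and total pair count
    n = atlas.n_rois
    pairs_total = n * (n - 1) // 2
    within_pairs = {
        net: len(atlas.network_indices(net)) * (len(atlas.network_indices(net)) - 1) // 2
        for net in atlas.network_names
    }
    f_within = sum(within_pairs.values()) / pairs_total
    # mean within target per group, weighted by pair counts
    mean_within = {}
    for g, _ in groups:
        wsum = sum(within_pairs[net] * design.within_corr[g][net] for net in within_pairs)
        mean_within[g] = wsum / sum(within_pairs.values())
    # pin every group's overall mean correlation to the largest value
    # reachable with non-negative between_corr
    target = max(
        f_within * mean_within[g] + (1 - f_within) * 0.10 for g, _ in groups
    )
    between = {}
    for g, _ in groups:
        b = (target - f_within * mean_within[g]) / (1 - f_within)
        min_w = min(design.within_corr[g].values())
        if not (0.0 <= b < min_w):
            raise DesignError(
                f"cannot match mean connectivity for group {g!r}: "
                f"required between_corr={b:.3f} outside [0, {min_w})"
            )
        between[g] = b
    return replace(design, between_corr=between)


def write_cohort(
    cohort: list[SubjectTimeSeries],
    directory: str | os.PathLike,
    atlas: AtlasSpec,
) -> str:
    """Write one TSV per subject (T rows x N labeled columns) plus a
    manifest TSV (subject_id, group, file). Returns the manifest path."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    rows = []
    for ts in cohort:
        if ts.n_rois != atlas.n_rois:
            raise ValueError(
                f"subject {ts.subject_id}: {ts.n_rois} columns, "
                f"atlas has {atlas.n_rois} ROIs"
            )
        fname = f"{ts.subject_id}_timeseries.tsv"
        df = pd.DataFrame(ts.data, columns=list(atlas.labels))
        df.to_csv(os.path.join(directory, fname), sep="\t", index=False,
                  float_format="%.10g")
        rows.append({"subject_id": ts.subject_id, "group": ts.group, "file": fname})
    manifest = os.path.join(directory, "manifest.tsv")
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
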