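"""Group-level metabolic connectivity networks from cohort SUVR tables.

One group network is one symmetric ROI x ROI matrix of Pearson correlations
computed across subjects after removing nuisance covariates (age, sex) from
every ROI by ordinary least squares within the group.  Negative correlations
are zeroed, then the matrix is binarized by keeping the strongest edges up
to a fixed density, so compared groups always have identical edge counts.

The covariate-adjusted pairwise correlation is deliberately NOT the full
inverse-covariance partial correlation among all ROIs: with far fewer
subjects than regions the precision matrix is not identifiable, and the
group-covariance convention in this field is pairwise correlation of
residualized regional values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = [
    "GroupNetwork",
    "ThresholdedGraph",
    "residualize",
    "correlation_network",
    "zero_negatives",
    "threshold_by_density",
    "build_group_network",
]

logger = logging.getLogger(__name__)


@dataclass
class GroupNetwork:
    """Symmetric weighted connectivity matrix for one group of subjects."""

    weights: np.ndarray
    roi_names: list[str]
    n_subjects: int
    covariates_removed: list[str] = field(default_factory=list)
    n_zeroed_negative: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if w.shape[0] != len(self.roi_names):
            raise ValueError("roi_names length must match matrix size")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite entries")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        self.weights = w

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.weights, index=self.roi_names, columns=self.roi_names).to_csv(path)

    def sidecar(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_rois": self.n_rois,
            "covariates_removed": self.covariates_removed,
            "n_zeroed_negative": self.n_zeroed_negative,
        }


@dataclass
class ThresholdedGraph:
    """Binary undirected graph at fixed density, with retained weights."""

    adjacency: np.ndarray
    retained_weights: np.ndarray
    roi_names: list[str]
    density: float
    edge_count: int = field(init=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        self.adjacency = a.astype(np.int8)
        self.edge_count = int(a.sum() // 2)
        w = np.asarray(self.retained_weights, dtype=float)
        if np.any((w != 0) & (a == 0)):
            raise ValueError("retained_weights nonzero off the adjacency support")
        self.retained_weights = w

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def to_csv(self, path) -> None:
        """Write the weight-retaining matrix; adjacency is its support."""
        pd.DataFrame(
            self.retained_weights, index=self.roi_names, columns=self.roi_names
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path, density: float | None = None) -> "ThresholdedGraph":
        frame = pd.read_csv(path, index_col=0)
        w = frame.to_numpy(dtype=float)
        adj = (w > 0).astype(np.int8)
        n = w.shape[0]
        dens = density if density is not None else adj.sum() / (n * (n - 1))
        return cls(adj, w, list(frame.columns), dens)


def residualize(
    cohort: CohortTable, covariate_names: list[str]
) -> np.ndarray:
    """Remove covariate effects from every ROI column by OLS within the cohort.

    Returns the subjects x ROIs residual matrix of a fit on intercept plus
    the named covariates.  With an empty covariate list this is plain column
    centering.  Sex enters as a single 0/1 indicator.
    """
    n = cohort.n_subjects
    if n < 4:
        raise ValueError(f"need at least 4 subjects to residualize, got {n}")
    covars = cohort.covariate_matrix(covariate_names)
    design = np.column_stack([np.ones(n), covars])
    if n <= design.shape[1]:
        raise ValueError(
            f"{n} subjects cannot support {design.shape[1] - 1} covariates plus intercept"
        )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate design matrix is rank deficient")
    y = cohort.suvr_matrix()
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def correlation_network(
    residuals: np.ndarray,
    roi_names: list[str],
    n_subjects: int | None = None,
    covariates_removed: list[str] | None = None,
) -> GroupNetwork:
    """Pairwise Pearson correlation of residual ROI columns across subjects."""
    resid = np.asarray(residuals, dtype=float)
    if resid.ndim != 2:
        raise ValueError("residuals must be a subjects x ROIs matrix")
    n, r = resid.shape
    if n < 4:
        raise ValueError(f"need at least 4 subjects, got {n}")
    sd = resid.std(axis=0)
    constant = np.flatnonzero(sd < 1e-14)
    if constant.size:
        names = [roi_names[i] for i in constant[:5]]
        raise ValueError(f"constant ROI column(s): {names}")
    corr = np.corrcoef(resid, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return GroupNetwork(
        corr,
        list(roi_names),
        n_subjects if n_subjects is not None else n,
        list(covariates_removed or []),
    )


def zero_negatives(net: GroupNetwork) -> GroupNetwork:
    """Set negative correlations to zero (their count is logged and recorded)."""
    w = net.weights.copy()
    neg = w < 0
    n_zeroed = int(neg.sum() // 2)
    w[neg] = 0.0
    if n_zeroed:
        logger.info("zeroed %d negative correlations", n_zeroed)
    return GroupNetwork(
        w, net.roi_names, net.n_subjects, net.covariates_removed, n_zeroed
    )


def threshold_by_density(net: GroupNetwork, density: float) -> ThresholdedGraph:
    """Keep the ``floor(density * R(R-1)/2)`` strongest positive edges.

    Ties at the cut are broken deterministically by ascending (i, j) node
    index, which keeps thresholding reproducible inside permutation loops.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError("density must be in (0, 1]")
    w = net.weights
    if np.any(w < 0):
        raise ValueError("network has negative weights; apply zero_negatives first")
    r = net.n_rois
    n_possible = r * (r - 1) // 2
    target = int(np.floor(density * n_possible))
    iu, ju = np.triu_indices(r, k=1)
    vals = w[iu, ju]
    positive = vals > 0
    n_positive = int(positive.sum())
    if n_positive < target:
        achievable = n_positive / n_possible
        raise ValueError(
            f"only {n_positive} positive weights for {target} requested edges; "
            f"achievable density {achievable:.4f}"
        )
    order = np.lexsort((ju, iu, -vals))[:target]
    adjacency = np.zeros((r, r), dtype=np.int8)
    adjacency[iu[order], ju[order]] = 1
    adjacency |= adjacency.T
    retained = np.where(adjacency > 0, w, 0.0)
    graph = ThresholdedGraph(adjacency, retained, net.roi_names, density)
    assert graph.edge_count == target
    return graph


def build_group_network(
    cohort: CohortTable,
    covariate_names: list[str],
    density: float,
) -> tuple[GroupNetwork, ThresholdedGraph]:
    """Full single-group chain: residualize, correlate, zero negatives,
    threshold.  Returns both the weighted network (negatives zeroed) and the
    density-thresholded graph."""
    resid = residualize(cohort, covariate_names)
    net = correlation_network(
        resid, cohort.roi_names, cohort.n_subjects, covariate_names
    )
    net = zero_negatives(net)
    return net, threshold_by_density(net, density)


def write_network_outputs(
    net: GroupNetwork, graph: ThresholdedGraph, prefix: str
) -> None:
    """Write weighted matrix, thresholded matrix, and a JSON sidecar."""
    net.to_csv(f"{prefix}.weights.csv")
    graph.to_csv(f"{prefix}.thresholded.csv")
    meta = net.sidecar()
    meta.update({"density": graph.density, "edge_count": graph.edge_count})
    with open(f"{prefix}.json", "w") as fh:
        json.dump(meta, fh, indent=2)
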