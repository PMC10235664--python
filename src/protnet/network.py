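"""Weighted correlation-network core.

Implements the unsigned soft-thresholded correlation network: Pearson
correlation, adjacency a_ij = |r_ij|^beta, scale-free-topology diagnostics,
topological overlap, average-linkage hierarchical clustering with dynamic
branch decomposition, module eigenproteins (first principal component of a
module) and module membership (kME).

Branch detection works on the dendrogram of the chosen dissimilarity
(1 - TOM by default).  A branch qualifies as a module when it (a) reaches
the minimum size, (b) completes below the cut height (99 % of the range
between the 5th percentile and the maximum of the merge heights), and
(c) is separated from its surroundings by a merge-height gap of at least a
configurable fraction of that range.  Qualifying branches are additionally
validated statistically: the mean within-branch |r| must exceed
``validation_z / sqrt(n_subjects - 1)`` — a few standard errors of a null
correlation — which suppresses chance branches in uncorrelated data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .containers import (
    EigenproteinSet,
    ModulePartition,
    ProteinMatrix,
    ValidationError,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkConfig:
    """Settings of the correlation network and module detection."""

    #: soft-threshold power applied to |r|
    beta: float = 4.0
    mode: str = "unsigned"
    min_module_size: int = 5
    #: base of the clustering dissimilarity: "tom" or "adjacency"
    dissimilarity: str = "tom"
    linkage: str = "average"
    cut_method: str = "dynamic_tree"
    #: branch-splitting sensitivity, 0 (coarse) .. 3 (fine); the parent-gap
    #: fraction of the height range is 0.20 - 0.05 * deep_split
    deep_split: int = 2
    #: branch validation: required mean within-branch |r| in units of the
    #: null correlation scale 1/sqrt(n_subjects - 1); 0 disables the check
    validation_z: float = 2.6

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValidationError("beta must be >= 1")
        if self.min_module_size < 2:
            raise ValidationError("min_module_size must be >= 2")
        if self.mode != "unsigned":
            raise ValidationError("only the unsigned network mode is supported")
        if self.dissimilarity not in ("tom", "adjacency"):
            raise ValidationError("dissimilarity must be 'tom' or 'adjacency'")
        if self.linkage != "average":
            raise ValidationError("only average linkage is supported")
        if not 0 <= self.deep_split <= 3:
            raise ValidationError("deep_split must be in 0..3")

    @property
    def gap_frac(self) -> float:
        return 0.20 - 0.05 * self.deep_split


@dataclass(frozen=True)
class ScaleFreeFit:
    """Scale-free topology diagnostic: log-log regression of the binned
    connectivity distribution."""

    r_squared: float
    slope: float
    n_bins_used: int


def correlation_matrix(matrix: ProteinMatrix) -> pd.DataFrame:
    """Pearson correlation between analytes (symmetric, unit diagonal)."""
    if matrix.stage != "transformed":
        raise ValidationError("correlation expects a transformed matrix")
    X = matrix.values.to_numpy()
    if np.isnan(X).any():
        raise ValidationError("correlation requires a complete matrix")
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = list(matrix.analyte_ids[sd == 0])
        raise ValidationError(f"zero-variance analytes: {bad}")
    C = np.corrcoef(X, rowvar=False)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=matrix.analyte_ids, columns=matrix.analyte_ids)


def soft_threshold_adjacency(
    cor: pd.DataFrame | np.ndarray, config: NetworkConfig | None = None
) -> pd.DataFrame | np.ndarray:
    """Unsigned adjacency a_ij = |r_ij|^beta with unit diagonal."""
    config = config or NetworkConfig()
    arr = cor.to_numpy() if isinstance(cor, pd.DataFrame) else np.asarray(cor, float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError("correlation matrix must be square")
    if np.nanmax(np.abs(arr)) > 1 + 1e-9:
        raise ValidationError("correlations must lie in [-1, 1]")
    A = np.abs(arr) ** config.beta
    np.fill_diagonal(A, 1.0)
    if isinstance(cor, pd.DataFrame):
        return pd.DataFrame(A, index=cor.index, columns=cor.columns)
    return A


def scale_free_fit(
    adjacency: pd.DataFrame | np.ndarray, n_bins: int = 10
) -> ScaleFreeFit:
    """Fit of the connectivity distribution to a power law.

    Connectivity k_i is the row sum of the adjacency without the diagonal.
    Connectivities are binned into ``n_bins`` equal-width bins; log10 of the
    bin frequency is regressed on log10 of the bin-mean connectivity.
    Reported, not enforced: beta is fixed by configuration.
    """
    A = (
        adjacency.to_numpy()
        if isinstance(adjacency, pd.DataFrame)
        else np.asarray(adjacency, float)
    )
    k = A.sum(axis=1) - np.diag(A)
    if np.ptp(k) == 0:
        raise ValidationError("degenerate connectivity: all nodes identical (single bin)")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_f = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0 or members.mean() <= 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_f.append(np.log10(members.size))
    if len(log_k) < 3:
        raise ValidationError("fewer than 3 non-empty connectivity bins")
    res = stats.linregress(log_k, log_f)
    return ScaleFreeFit(
        r_squared=float(res.rvalue**2), slope=float(res.slope), n_bins_used=len(log_k)
    )


def topological_overlap(
    adjacency: pd.DataFrame | np.ndarray,
) -> pd.DataFrame | np.ndarray:
    """Unsigned topological overlap matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_u a_iu a_uj over u distinct from i and j, and unit diagonal.
    """
    A = (
        adjacency.to_numpy()
        if isinstance(adjacency, pd.DataFrame)
        else np.asarray(adjacency, float)
    )
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValidationError("adjacency must be symmetric")
    if A.min() < -1e-12 or A.max() > 1 + 1e-9:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    L = A0 @ A0
    T = (L + A0) / (np.minimum.outer(k, k) + 1.0 - A0)
    np.fill_diagonal(T, 1.0)
    T = np.clip((T + T.T) / 2.0, 0.0, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(T, index=adjacency.index, columns=adjacency.columns)
    return T


def _dendrogram_arrays(Z: np.ndarray, n: int):
    m = Z.shape[0]
    size = np.ones(n + m, dtype=int)
    height = np.zeros(n + m)
    left = np.full(n + m, -1)
    right = np.full(n + m, -1)
    for i in range(m):
        a, b = int(Z[i, 0]), int(Z[i, 1])
        size[n + i] = size[a] + size[b]
        height[n + i] = Z[i, 2]
        left[n + i] = a
        right[n + i] = b
    return size, height, left, right


def _leaves(node: int, n: int, left: np.ndarray, right: np.ndarray) -> list:
    out, stack = [], [node]
    while stack:
        x = stack.pop()
        if x < n:
            out.append(x)
        else:
            stack.extend((left[x], right[x]))
    return out


def detect_modules(
    dissimilarity: pd.DataFrame | np.ndarray,
    config: NetworkConfig | None = None,
    *,
    cor: pd.DataFrame | np.ndarray | None = None,
    n_subjects: int | None = None,
) -> ModulePartition:
    """Average-linkage clustering with dynamic branch decomposition.

    ``dissimilarity`` is typically 1 - TOM.  When ``cor`` and ``n_subjects``
    are supplied, candidate branches are validated against the null
    correlation scale (see module docstring); without them only the
    dendrogram-shape criteria apply.

    Analytes in no qualifying branch are labelled 0.  Module labels are
    1..K by descending size (ties: lowest analyte index first).
    """
    config = config or NetworkConfig()
    if isinstance(dissimilarity, pd.DataFrame):
        names = dissimilarity.index
        D = dissimilarity.to_numpy()
    else:
        D = np.asarray(dissimilarity, float)
        names = pd.RangeIndex(D.shape[0])
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValidationError("dissimilarity must be square and symmetric")
    n = D.shape[0]
    if n < config.min_module_size:
        warnings.warn("fewer analytes than min_module_size; nothing to cluster")
        return ModulePartition(
            assignment=pd.Series(np.zeros(n, dtype=int), index=names, name="module")
        )
    D = D.copy()
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method=config.linkage)

    heights = Z[:, 2]
    q05 = float(np.quantile(heights, 0.05))
    h_max = float(heights.max())
    h_range = max(h_max - q05, 1e-300)
    cut_height = q05 + 0.99 * h_range
    gap = config.gap_frac * h_range

    size, height, left, right = _dendrogram_arrays(Z, n)

    C = None
    if cor is not None and n_subjects is not None and config.validation_z > 0:
        C = cor.to_numpy() if isinstance(cor, pd.DataFrame) else np.asarray(cor, float)
        threshold = config.validation_z / np.sqrt(max(n_subjects - 1, 1))
    else:
        threshold = None

    def qualifies(node: int, parent_h: float) -> bool:
        return (
            size[node] >= config.min_module_size
            and height[node] <= cut_height
            and parent_h - height[node] >= gap
        )

    def validated(node: int) -> bool:
        if threshold is None:
            return True
        idx = np.array(_leaves(node, n, left, right))
        sub = np.abs(C[np.ix_(idx, idx)])
        iu = np.triu_indices(len(idx), 1)
        return float(sub[iu].mean()) >= threshold

    branches = []
    stack = [(n + Z.shape[0] - 1, np.inf)]
    while stack:
        node, parent_h = stack.pop()
        if size[node] < config.min_module_size:
            continue
        if qualifies(node, parent_h):
            l, r = left[node], right[node]
            if l >= 0 and qualifies(l, height[node]) and qualifies(r, height[node]):
                stack.append((l, height[node]))
                stack.append((r, height[node]))
            elif validated(node):
                branches.append(node)
        elif left[node] >= 0:
            stack.append((left[node], height[node]))
            stack.append((right[node], height[node]))

    labels = np.zeros(n, dtype=int)
    branch_leaves = [sorted(_leaves(b, n, left, right)) for b in branches]
    branch_leaves.sort(key=lambda lv: (-len(lv), lv[0]))
    for lab, lv in enumerate(branch_leaves, start=1):
        labels[lv] = lab
    return ModulePartition(
        assignment=pd.Series(labels, index=names, name="module"), linkage=Z
    )


def eigenprotein(
    matrix: ProteinMatrix | pd.DataFrame, module: list
) -> tuple[pd.Series, float]:
    """First principal component of a module, scaled to mean 0 / SD 1.

    The sign is chosen so that the mean correlation between the scores and
    the module's analytes is positive.  Returns (scores, variance
    explained), the latter being the leading eigenvalue's share of the
    module's standardized variance.
    """
    values = matrix.values if isinstance(matrix, ProteinMatrix) else matrix
    if len(module) < 2:
        raise ValidationError("eigenprotein requires a module of size >= 2")
    X = values[list(module)].to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValidationError("zero-variance analyte inside module")
    X = X / sd
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, 0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    # orient: positive mean correlation with the module's analytes
    if np.mean([np.corrcoef(scores, X[:, j])[0, 1] for j in range(X.shape[1])]) < 0:
        scores = -scores
    scores = (scores - scores.mean()) / scores.std(ddof=1)
    return pd.Series(scores, index=values.index, name="eigenprotein"), var_explained


def eigenprotein_set(
    matrix: ProteinMatrix, partition: ModulePartition
) -> EigenproteinSet:
    """Eigenproteins of every module in a partition, with kME."""
    scores = {}
    var_exp = {}
    for label in sorted(set(partition.assignment) - {0}):
        s, v = eigenprotein(matrix, partition.analytes_in(label))
        scores[f"M{label}"] = s
        var_exp[f"M{label}"] = v
    if not scores:
        raise ValidationError("partition contains no modules")
    eig = EigenproteinSet(
        scores=pd.DataFrame(scores),
        variance_explained=pd.Series(var_exp, name="variance_explained"),
    )
    eig.kme, eig.kme_p = module_membership(matrix, eig)
    return eig


def module_membership(
    matrix: ProteinMatrix, eigenproteins: EigenproteinSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """kME: Pearson r of each analyte with each eigenprotein, with the
    two-sided p-value from the t distribution on n - 2 df."""
    X = matrix.values.to_numpy(dtype=float)
    E = eigenproteins.scores.to_numpy(dtype=float)
    n = X.shape[0]
    Xc = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    Ec = (E - E.mean(axis=0)) / E.std(axis=0, ddof=1)
    R = np.clip(Xc.T @ Ec / (n - 1), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = R * np.sqrt((n - 2) / np.maximum(1 - R**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    kme = pd.DataFrame(R, index=matrix.analyte_ids, columns=eigenproteins.scores.columns)
    kme_p = pd.DataFrame(p, index=matrix.analyte_ids, columns=eigenproteins.scores.columns)
    return kme, kme_p


def mean_abs_within_correlation(cor: pd.DataFrame, module: list) -> float:
    """Mean |r| over the unordered distinct analyte pairs of a module."""
    if len(module) < 2:
        raise ValidationError("module must contain at least 2 analytes")
    sub = cor.loc[list(module), list(module)].to_numpy()
    iu = np.triu_indices(len(module), 1)
    return float(np.abs(sub[iu]).mean())
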