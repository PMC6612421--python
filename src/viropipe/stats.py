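"""Community statistics: diversity, Bray-Curtis, PCoA, AU-supported clustering.

The hierarchical clustering reproduces the pvclust-style procedure:
complete linkage on Euclidean distances between the columns of a
Bray-Curtis dissimilarity matrix, with multiscale bootstrap support. For
each scale r, bootstrap replicates resample round(r * n_features) feature
rows with replacement; each reference node's per-scale bootstrap
probability BP_r is fitted by weighted least squares to

    Phi^{-1}(1 - BP_r) = v * sqrt(r) + c / sqrt(r)

giving the approximately unbiased support AU = 1 - Phi(v - c) and the
bias-corrected BP = 1 - Phi(v + c). Clustering a Bray-Curtis matrix by
Euclidean column distance is an unusual double transform but is retained
as the default for comparability; ``feature_matrix="abundance"`` clusters
the abundance table directly (features = vOTUs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .recruit import AbundanceMatrix

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 1))


def _values(matrix) -> pd.DataFrame:
    if isinstance(matrix, AbundanceMatrix):
        return matrix.values
    return matrix


def diversity(matrix) -> pd.DataFrame:
    """Per-sample richness R, Shannon H (natural log), Pielou evenness J.

    J = H / ln(R); it is undefined (NaN) for samples with R <= 1. An
    all-zero sample reports R = 0, H = 0, J = NaN.
    """
    vals = _values(matrix)
    rows = []
    for s in vals.columns:
        x = vals[s].to_numpy(dtype=float)
        x = x[x > 0]
        r = int(x.size)
        if r == 0:
            h = 0.0
        else:
            p = x / x.sum()
            h = float(-(p * np.log(p)).sum())
        j = h / np.log(r) if r >= 2 else np.nan
        rows.append({"sample_id": s, "R": r, "H": h, "J": j})
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(matrix) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity.

    BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i); a pair of all-zero
    samples is defined as 0 dissimilar (with no abundance there is no
    evidence of difference).
    """
    vals = _values(matrix)
    x = vals.to_numpy(dtype=float).T  # samples x features
    n = x.shape[0]
    bc = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = (x[i] + x[j]).sum()
            bc[i, j] = bc[j, i] = (np.abs(x[i] - x[j]).sum() / denom) if denom > 0 else 0.0
    return pd.DataFrame(bc, index=vals.columns, columns=vals.columns)


@dataclass
class ClusterTree:
    """A complete-linkage sample tree with per-node multiscale supports.

    ``linkage_matrix`` is in scipy format over ``labels``; ``nodes`` has
    one row per internal node (in linkage order) with AU, BP (percent)
    and the fitted v, c parameters.
    """

    labels: list[str]
    linkage_matrix: np.ndarray
    nodes: pd.DataFrame
    #: raw bootstrap proportions, one row per scale, one column per node
    bp_per_scale: pd.DataFrame | None = None

    def node_leafsets(self) -> list[frozenset]:
        return _leafsets(self.linkage_matrix, len(self.labels), self.labels)

    def support_for(self, leafset: set[str]) -> tuple[float, float] | None:
        """(AU, BP) for the node whose leaf set equals ``leafset``, if any."""
        target = frozenset(leafset)
        for i, ls in enumerate(self.node_leafsets()):
            if ls == target:
                return float(self.nodes["AU"].iloc[i]), float(self.nodes["BP"].iloc[i])
        return None

    def to_newick(self) -> str:
        n = len(self.labels)
        au = self.nodes["AU"].to_numpy()
        bp = self.nodes["BP"].to_numpy()

        def render(node: int) -> str:
            if node < n:
                return self.labels[node]
            i = node - n
            a = render(int(self.linkage_matrix[i, 0]))
            b = render(int(self.linkage_matrix[i, 1]))
            h = self.linkage_matrix[i, 2]
            return f"({a},{b})[&AU={au[i]:.1f},BP={bp[i]:.1f}]:{h:.6g}"

        root = render(2 * n - 2)
        # strip the root's branch length
        return root.rsplit(":", 1)[0] + ";"


def _leafsets(Z: np.ndarray, n: int, labels: list[str]) -> list[frozenset]:
    sets: list[frozenset] = []
    for i in range(Z.shape[0]):
        members: set[str] = set()
        for child in (int(Z[i, 0]), int(Z[i, 1])):
            if child < n:
                members.add(labels[child])
            else:
                members |= sets[child - n]
        sets.append(frozenset(members))
    return sets


def _cluster_sets(features: np.ndarray, labels: list[str]) -> set[frozenset]:
    d = pdist(features.T, metric="euclidean")
    Z = linkage(d, method="complete")
    return set(_leafsets(Z, len(labels), labels))


def hclust_au(
    matrix,
    n_boot: int = 1000,
    seed: int = 0,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    feature_matrix: str = "bc",
) -> ClusterTree:
    """Complete-linkage sample clustering with multiscale-bootstrap support.

    feature_matrix="bc" (default) uses the Bray-Curtis matrix as the
    feature matrix (samples as columns), mirroring pvclust applied to a
    dissimilarity matrix; "abundance" uses the vOTU x sample table
    directly. Deterministic given ``seed``.
    """
    vals = _values(matrix)
    labels = [str(c) for c in vals.columns]
    if len(labels) < 3:
        raise ValueError("hierarchical clustering needs >= 3 samples")
    if feature_matrix == "bc":
        X = bray_curtis(vals).to_numpy()
    elif feature_matrix == "abundance":
        X = vals.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown feature_matrix {feature_matrix!r}")
    n_feat = X.shape[0]
    ref_Z = linkage(pdist(X.T, metric="euclidean"), method="complete")
    ref_sets = _leafsets(ref_Z, len(labels), labels)
    rng = np.random.default_rng(seed)
    scales = tuple(scales)
    counts = np.zeros((len(scales), len(ref_sets)), dtype=np.int64)
    for si, r in enumerate(scales):
        m = max(2, int(round(r * n_feat)))
        for _ in range(n_boot):
            idx = rng.integers(0, n_feat, size=m)
            try:
                reps = _cluster_sets(X[idx], labels)
            except ValueError:
                continue
            for ni, ls in enumerate(ref_sets):
                if ls in reps:
                    counts[si, ni] += 1
    bp_r = counts / n_boot
    lo, hi = 1.0 / (n_boot + 1), n_boot / (n_boot + 1.0)
    bp_clip = np.clip(bp_r, lo, hi)
    sq = np.sqrt(np.asarray(scales))
    design = np.column_stack([sq, 1.0 / sq])
    rows = []
    for ni in range(len(ref_sets)):
        raw = counts[:, ni]
        if (raw == n_boot).all():
            # at ceiling on every scale: support is saturated, the probit
            # fit is degenerate; report full support
            rows.append({"AU": 100.0, "BP": 100.0, "v": 0.0, "c": 0.0})
            continue
        if (raw == 0).all():
            rows.append({"AU": 0.0, "BP": 0.0, "v": 0.0, "c": 0.0})
            continue
        z = norm.ppf(1.0 - bp_clip[:, ni])
        w = n_boot * norm.pdf(z) ** 2 / (bp_clip[:, ni] * (1.0 - bp_clip[:, ni]))
        wsqrt = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * wsqrt[:, None], z * wsqrt, rcond=None)
        v, c = float(coef[0]), float(coef[1])
        au = 100.0 * (1.0 - norm.cdf(v - c))
        bp = 100.0 * (1.0 - norm.cdf(v + c))
        rows.append({"AU": au, "BP": bp, "v": v, "c": c})
    nodes = pd.DataFrame(rows)
    per_scale = pd.DataFrame(bp_r, index=list(scales), columns=range(len(ref_sets)))
    return ClusterTree(labels=labels, linkage_matrix=ref_Z, nodes=nodes, bp_per_scale=per_scale)


def bootstrap_proportion(
    matrix,
    leafset: set[str],
    n_boot: int = 10_000,
    seed: int = 0,
    feature_matrix: str = "bc",
) -> float:
    """Direct scale-1 bootstrap proportion of one cluster (reference check)."""
    vals = _values(matrix)
    labels = [str(c) for c in vals.columns]
    X = bray_curtis(vals).to_numpy() if feature_matrix == "bc" else vals.to_numpy(dtype=float)
    n_feat = X.shape[0]
    target = frozenset(leafset)
    rng = np.random.default_rng(seed)
    hit = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n_feat, size=n_feat)
        if target in _cluster_sets(X[idx], labels):
            hit += 1
    return hit / n_boot


def pcoa(bc: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling (principal coordinate analysis) of a dissimilarity.

    Double-centers -0.5 * D^2, eigendecomposes, and returns coordinates on
    the positive-eigenvalue axes (ordered by eigenvalue) together with the
    full eigenvalue spectrum including any negative values.
    """
    d = bc.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("PCoA requires a symmetric dissimilarity matrix")
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    tol = 1e-10 * max(1.0, float(np.abs(eigval).max()))
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=bc.index, columns=cols), eigval
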