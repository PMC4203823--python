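"""Organization step: choose k by the within-cluster SSQ curve, decompose by
PCA, and delimit BGC types by k-means.

The number of BGC types is chosen from the "least-squares structuring" curve:
best-of-``n_init`` k-means within-cluster sum of squared distances (WCSS) for
k = 1..15.  The curve's inflexion is located with the discrete second
difference; the full profile is always reported so a user can override the
automatic choice.  Clustering runs by default on the full correlation rows —
squared-Euclidean k-means is rotation invariant, so this is identical to
clustering on all PC scores — with a 2-D PC-score space offered to reproduce
the score-plot delimitation exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from bgctype.association import CorrelationMatrix


@dataclass
class WCSSCurve:
    """Within-cluster sum-of-squares for k = 1..k_max (best of ``n_init``)."""

    k_values: np.ndarray
    wcss: np.ndarray
    n_init: int
    seed: int

    def second_differences(self) -> dict[int, float]:
        """Discrete second difference wcss[k-1] - 2*wcss[k] + wcss[k+1] for interior k."""
        out = {}
        for i, k in enumerate(self.k_values[1:-1], start=1):
            out[int(k)] = float(self.wcss[i - 1] - 2 * self.wcss[i] + self.wcss[i + 1])
        return out


@dataclass
class PCAResult:
    """Scores (OTUs x components) and loadings (chemical variables x components).

    Loading columns are orthonormal; the sign of each component is fixed so
    that its largest-magnitude loading entry is positive.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    centering: str


@dataclass
class TypingResult:
    """BGC-type assignment of every filtered OTU.

    Labels run 1..k and are numbered by descending cluster size (ties broken
    by the lexicographically smallest member id) so that "BGC type I" is the
    largest cluster in any run.
    """

    labels: dict[str, int]
    k: int
    curve: WCSSCurve | None
    pca: PCAResult
    cluster_space: str
    seed: int

    def members(self, bgc_type: int) -> list[str]:
        return [o for o, t in self.labels.items() if t == bgc_type]


def _cluster_matrix(m: CorrelationMatrix) -> np.ndarray:
    x = np.asarray(m.rho, dtype=float)
    if np.isnan(x).any():
        # undefined correlations carry no trend information; treat as zero association
        x = np.nan_to_num(x, nan=0.0)
    return x


def _kmeans(x: np.ndarray, k: int, seed: int, n_init: int) -> KMeans:
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points can yield < k distinct clusters
        km.fit(x)
    return km


def wcss_curve(
    m: CorrelationMatrix, k_max: int = 15, seed: int = 0, n_init: int = 50
) -> WCSSCurve:
    """Best-of-``n_init`` k-means WCSS for each k in 1..k_max."""
    x = _cluster_matrix(m)
    if k_max > x.shape[0]:
        raise ValueError(f"k_max={k_max} exceeds number of OTUs ({x.shape[0]})")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    ks = np.arange(1, k_max + 1)
    wcss = np.array([_kmeans(x, int(k), seed, n_init).inertia_ for k in ks])
    return WCSSCurve(k_values=ks, wcss=wcss, n_init=n_init, seed=seed)


def select_k_by_elbow(curve: WCSSCurve, tol: float = 1e-9) -> tuple[int, dict[int, float]]:
    """Locate the curve inflexion: the k maximising the discrete second difference.

    Returns ``(k, profile)`` where ``profile`` maps each interior k to its
    second difference so the automatic choice can be inspected or overridden.
    Ties break toward smaller k.  If no second difference is positive the
    curve has no elbow; the smallest maximising k is returned with a warning.
    """
    if len(curve.k_values) < 3:
        raise ValueError("elbow selection needs k_max >= 3")
    profile = curve.second_differences()
    best_k = min(profile, key=lambda k: (-profile[k], k))
    scale = float(np.max(np.abs(curve.wcss))) or 1.0
    if profile[best_k] <= tol * scale:
        warnings.warn(
            "no elbow: WCSS curve has no positive second difference; "
            f"returning k={best_k}",
            stacklevel=2,
        )
    return best_k, profile


def pca_decompose(m: CorrelationMatrix, centering: str = "mean") -> PCAResult:
    """PCA of the OTU-row correlation matrix via singular value decomposition.

    ``centering="mean"`` removes the per-chemical-variable column mean (the
    default; all entries already share the correlation scale, so no variance
    scaling is applied); ``"none"`` decomposes the raw matrix.
    """
    if centering not in ("mean", "none"):
        raise ValueError(f"centering must be 'mean' or 'none', got {centering!r}")
    x = _cluster_matrix(m)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError(f"PCA needs at least 2 rows and 2 columns, got {x.shape}")
    work = x - x.mean(axis=0) if centering == "mean" else x
    if not np.any(work):
        raise ValueError("matrix has rank 0 after centering")
    u, s, vt = np.linalg.svd(work, full_matrices=False)
    # deterministic sign: largest-magnitude loading entry positive per component
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    scores = u * s
    expl = s**2 / (x.shape[0] - 1)
    return PCAResult(
        scores=scores, loadings=vt.T, explained_variance=expl, centering=centering
    )


def _renumber(raw_labels: np.ndarray, otu_ids: list[str]) -> dict[str, int]:
    """Renumber clusters by descending size, ties by smallest member id."""
    order = []
    for lab in np.unique(raw_labels):
        members = [otu_ids[i] for i in np.flatnonzero(raw_labels == lab)]
        order.append((-len(members), min(members), lab))
    ranks = {lab: i + 1 for i, (_, _, lab) in enumerate(sorted(order))}
    return {otu_ids[i]: ranks[raw_labels[i]] for i in range(len(otu_ids))}


def cluster_bgc_types(
    m: CorrelationMatrix,
    k: int,
    cluster_space: str = "corr_rows",
    seed: int = 0,
    n_init: int = 50,
    curve: WCSSCurve | None = None,
    centering: str = "mean",
) -> TypingResult:
    """Delimit k BGC types by k-means (k-means++ seeding, best of ``n_init``).

    ``cluster_space="corr_rows"`` clusters the full correlation rows;
    ``"pc_scores_2d"`` clusters the first two PC scores, reproducing a
    delimitation drawn on the PC1/PC2 score plot.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    x = _cluster_matrix(m)
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds number of OTUs ({x.shape[0]})")
    pca = pca_decompose(m, centering=centering)
    if cluster_space == "corr_rows":
        space = x
    elif cluster_space == "pc_scores_2d":
        space = pca.scores[:, :2]
    else:
        raise ValueError(f"unknown cluster_space {cluster_space!r}")
    km = _kmeans(space, k, seed, n_init)
    labels = _renumber(km.labels_, list(m.otu_ids))
    return TypingResult(
        labels=labels,
        k=len(set(labels.values())),
        curve=curve,
        pca=pca,
        cluster_space=cluster_space,
        seed=seed,
    )
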