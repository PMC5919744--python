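"""Population structure: k-means clusters on PCs, DAPC loadings, corrected kinship.

Genetic clusters are inferred the DAPC way: principal components of the
(centered, frequency-scaled) dosage matrix summarize the panel, k-means is
run over a range of K with the winner chosen at minimum BIC, and linear
discriminant functions of the PC scores are back-projected to per-marker
loadings that flag the markers driving differentiation. A PC-residual
kinship — each marker regressed on the leading PCs before the cross-product —
serves as the structure-corrected relationship matrix for prediction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotypes import GenotypeMatrix
from .gwas import KinshipMatrix


def _scaled_dosages(G: GenotypeMatrix) -> np.ndarray:
    """Mean-filled, centered dosages scaled by sqrt(2 p (1-p)) per marker."""
    X = G.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    p = col_mean / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    keep = sd > 0
    return (X[:, keep] - col_mean[keep]) / sd[keep]


@dataclasses.dataclass
class PCScores:
    scores: np.ndarray          # n x n_pcs
    loadings: np.ndarray        # m x n_pcs (marker-space eigenvectors)
    explained_ratio: np.ndarray


def pca_scores(G: GenotypeMatrix, n_pcs: int | None = None) -> PCScores:
    """PCA of the scaled dosage matrix; ``n_pcs=None`` keeps 90% of variance."""
    Z = _scaled_dosages(G)
    U, s, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
    var = s**2
    ratio = var / var.sum()
    if n_pcs is None:
        n_pcs = int(np.searchsorted(np.cumsum(ratio), 0.90) + 1)
    n_pcs = min(n_pcs, len(s))
    return PCScores(
        scores=U[:, :n_pcs] * s[:n_pcs],
        loadings=Vt[:n_pcs].T,
        explained_ratio=ratio[:n_pcs],
    )


@dataclasses.dataclass
class ClusterSolution:
    K: int
    labels: np.ndarray           # 1..K
    bic: dict[int, float]
    pc_scores: np.ndarray

    def __post_init__(self) -> None:
        if self.labels.min() < 1 or self.labels.max() > self.K:
            raise ValueError("labels must lie in 1..K")


def _kmeans_bic(scores: np.ndarray, k: int, seed: int) -> tuple[float, np.ndarray]:
    n, d = scores.shape
    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    labels = km.fit_predict(scores)
    wss = float(km.inertia_)
    # spherical-Gaussian likelihood with common variance WSS/(n d)
    wss = max(wss, np.finfo(float).tiny)
    bic = n * d * np.log(wss / (n * d)) + k * d * np.log(n)
    return bic, labels + 1


def find_clusters(
    G: GenotypeMatrix,
    k_range=range(1, 11),
    n_pcs: int | None = None,
    seed: int = 0,
) -> ClusterSolution:
    """k-means over PC scores; K chosen at the BIC minimum, 20 restarts per K."""
    k_range = list(k_range)
    if max(k_range) >= G.n_individuals:
        raise ValueError("k_range upper bound must be below the number of individuals")
    pcs = pca_scores(G, n_pcs=n_pcs)
    bic: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        bic[k], labels_by_k[k] = _kmeans_bic(pcs.scores, k, seed)
    best = min(bic, key=bic.get)
    return ClusterSolution(
        K=best, labels=labels_by_k[best], bic=bic, pc_scores=pcs.scores
    )


@dataclasses.dataclass
class LoadingsTable:
    """Per-marker loadings on each discriminant function (unit squared sum)."""

    loadings: pd.DataFrame  # index: marker names; columns: DA1..DAn

    def top_markers(self, function: str = "DA1", k: int = 10) -> pd.Index:
        return self.loadings[function].abs().nlargest(k).index


def dapc_loadings(
    G: GenotypeMatrix,
    labels: np.ndarray,
    n_pcs: int | None = None,
    n_da: int | None = None,
) -> LoadingsTable:
    """Discriminant analysis of principal components, back-projected to markers.

    LDA on the retained PC scores maximizes between/within cluster variance;
    composing the PCA rotation with the discriminant coefficients gives a
    marker-space loading per discriminant function, normalized so squared
    loadings sum to one.
    """
    labels = np.asarray(labels)
    k = len(np.unique(labels))
    if n_da is None:
        n_da = k - 1
    if n_da >= k:
        raise ValueError("number of discriminant functions must be below K")
    pcs = pca_scores(G, n_pcs=n_pcs)
    lda = LinearDiscriminantAnalysis(n_components=n_da)
    lda.fit(pcs.scores, labels)
    W = lda.scalings_[:, :n_da]          # pcs x n_da
    L = pcs.loadings @ W                  # markers x n_da
    L = L / np.sqrt((L**2).sum(axis=0))
    return LoadingsTable(
        loadings=pd.DataFrame(
            L, index=G.marker_names, columns=[f"DA{i + 1}" for i in range(n_da)]
        )
    )


def significant_pcs(G: GenotypeMatrix, margin: float = 1.1) -> int:
    """Number of PCs whose eigenvalue exceeds the Marchenko–Pastur bulk edge.

    Eigenvalues of Z Z'/m for standardized dosages Z concentrate below
    (1 + sqrt(n/m))² in the absence of individual-level structure; PCs above
    that edge (times a safety margin) are taken to represent structure.
    """
    Z = _scaled_dosages(G)
    n, m = Z.shape
    s = np.linalg.svd(Z - Z.mean(axis=0), compute_uv=False)
    lam = s**2 / m
    edge = margin * (1.0 + np.sqrt(n / m)) ** 2
    return int(np.sum(lam > edge))


def pc_adjusted_kinship(G: GenotypeMatrix, n_pcs: int | None = None) -> KinshipMatrix:
    """Structure-corrected kinship from PC-residual dosages.

    Each marker's centered dosages are regressed on the top ``n_pcs`` PC
    scores and the kinship built from the residuals — a light-weight analogue
    of individual-specific-allele-frequency correction that removes the
    between-cluster component of relatedness. ``n_pcs=None`` keeps only PCs
    above the random-matrix bulk edge, so an unstructured panel is left
    essentially uncorrected.
    """
    if n_pcs is None:
        n_pcs = significant_pcs(G)
    if n_pcs >= G.n_individuals:
        raise ValueError("n_pcs must be below the number of individuals")
    X = G.dosages
    if np.isnan(X).any():
        raise ValueError("corrected kinship requires a complete dosage matrix")
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    Xc = X[:, poly] - 2.0 * p[poly]
    S = pca_scores(G, n_pcs=n_pcs).scores
    Q = np.column_stack([np.ones(G.n_individuals), S])
    resid = Xc - Q @ np.linalg.lstsq(Q, Xc, rcond=None)[0]
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    Kv = resid @ resid.T / denom
    Kv[np.diag_indices_from(Kv)] += 1e-6
    return KinshipMatrix(values=Kv, ids=list(G.ids), method=f"pc_adjusted_{n_pcs}")


def pc_variance_explained(
    trait_means: np.ndarray,
    pc_scores: np.ndarray,
    n_pcs: int = 3,
) -> pd.Series:
    """R² of the trait on each leading PC from univariate regressions."""
    y = np.asarray(trait_means, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("trait is constant")
    S = np.asarray(pc_scores, dtype=float)
    if S.shape[0] != y.size:
        raise ValueError("trait and PC scores must share individuals")
    n_pcs = min(n_pcs, S.shape[1])
    out = {}
    yc = y - y.mean()
    sst = float(yc @ yc)
    for j in range(n_pcs):
        s = S[:, j] - S[:, j].mean()
        denom = float(s @ s)
        r2 = (float(s @ yc) ** 2 / denom) / sst if denom > 0 else 0.0
        out[f"PC{j + 1}"] = r2
    return pd.Series(out)
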