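"""Ordination: PCA of haplogroup frequency tables and non-metric MDS of
genetic distance matrices, with Kruskal stress-1 reporting.

nMDS runs SMACOF with a non-metric (isotonic) disparity fit, best of a
configurable number of random restarts; the reported stress is Kruskal's
stress-1 recomputed from the final embedding, sqrt(sum (d - dhat)^2 /
sum d^2), where d are configuration distances and dhat the monotone
(pool-adjacent-violators) fit to the input dissimilarity order.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS


@dataclasses.dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # population x k
    explained_variance: np.ndarray | None = None  # PCA eigenvalue fractions
    stress: float | None = None  # nMDS Kruskal stress-1
    converged: bool = True
    n_iter: int = 0


def pca(freq_matrix: pd.DataFrame, scale: bool = False, k: int = 2) -> OrdinationResult:
    """PCA of a population x haplogroup frequency table.

    Columns are centered (optionally standardized); scores come from the
    SVD of the centered matrix. Sign convention: within each component the
    largest-magnitude loading is made positive.
    """
    x = np.asarray(freq_matrix, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least two rows")
    xc = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        xc = xc / sd
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # sign convention
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u * s
    eig = s**2
    total = eig.sum()
    frac = eig / total if total > 0 else np.zeros_like(eig)
    k_eff = min(k, scores.shape[1])
    coords = pd.DataFrame(
        scores[:, :k_eff],
        index=freq_matrix.index if isinstance(freq_matrix, pd.DataFrame) else None,
        columns=[f"PC{i+1}" for i in range(k_eff)],
    )
    return OrdinationResult(coordinates=coords, explained_variance=frac)


def kruskal_stress(dissimilarities: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding against a dissimilarity matrix."""
    dvec = squareform(np.asarray(dissimilarities, dtype=float), checks=False)
    emb = pdist(coords)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    # primary tie approach: within tied dissimilarities, order by embedded
    # distance so the monotone fit is not penalized by ties
    order = np.lexsort((emb, dvec))
    dhat = np.empty_like(emb)
    dhat[order] = iso.fit_transform(np.arange(order.size), emb[order])
    denom = float(np.sum(emb**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((emb - dhat) ** 2) / denom))


def nmds(
    distance_matrix: np.ndarray | pd.DataFrame,
    k: int = 2,
    seed: int | None = None,
    max_iter: int = 500,
    n_restarts: int = 20,
    floor_negative: bool = True,
) -> OrdinationResult:
    """Non-metric MDS of a distance matrix, best of ``n_restarts`` restarts.

    Negative entries (possible for phi-st estimates) are floored at zero by
    default before the rank-based fit; disable with ``floor_negative``.
    """
    labels = None
    if isinstance(distance_matrix, pd.DataFrame):
        labels = list(distance_matrix.index)
        d = distance_matrix.to_numpy(dtype=float)
    else:
        d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n < 3:
        raise ValueError("need a square distance matrix with n >= 3")
    if k >= n:
        raise ValueError(f"embedding dimension k={k} must be < n={n}")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    if floor_negative:
        d = np.maximum(d, 0.0)
        np.fill_diagonal(d, 0.0)
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, int] | None = None
    for _ in range(n_restarts):
        model = MDS(
            n_components=k,
            metric_mds=False,
            metric="precomputed",
            init="random",
            n_init=1,
            max_iter=max_iter,
            eps=1e-12,
            random_state=int(rng.integers(0, 2**31 - 1)),
            normalized_stress=True,
        )
        coords = model.fit_transform(d)
        stress = kruskal_stress(d, coords)
        if best is None or stress < best[0]:
            best = (stress, coords, model.n_iter_)
    assert best is not None
    stress, coords, n_iter = best
    df = pd.DataFrame(coords, index=labels, columns=[f"Dim{i+1}" for i in range(k)])
    return OrdinationResult(
        coordinates=df, stress=stress, converged=n_iter < max_iter, n_iter=n_iter
    )


def plot_ordination(result: OrdinationResult, path, groups: dict | None = None) -> None:
    """Scatter plot of the first two ordination axes (SVG/PNG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = result.coordinates
    fig, ax = plt.subplots(figsize=(6, 5))
    xs, ys = coords.iloc[:, 0], coords.iloc[:, 1]
    ax.scatter(xs, ys, s=30)
    for name, x, y in zip(coords.index, xs, ys):
        ax.annotate(str(name), (x, y), fontsize=8)
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    if result.stress is not None:
        ax.set_title(f"nMDS (stress = {result.stress:.3f})")
    elif result.explained_variance is not None:
        ax.set_title(
            f"PCA ({100 * result.explained_variance[0]:.1f}% / "
            f"{100 * result.explained_variance[1]:.1f}%)"
        )
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
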