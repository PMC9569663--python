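"""PCA projection, density heatmaps and per-family statistics of the latent cloud.

These are the descriptive tools used to inspect how encoded molecule sets
occupy the continuous latent space: a 2-component PCA with explained-variance
ratios, 2-D occupancy histograms of the scores, and per-family range
statistics (overall range, range of the centroid vector, range of the
per-dimension standard-deviation vector).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass
class PCAResult:
    scores: np.ndarray  # n x 2, zero column mean
    explained_variance_ratio: tuple[float, float]
    component_loadings: np.ndarray  # 2 x d


def pca_project(latent: np.ndarray) -> PCAResult:
    """Project a latent matrix on its top-2 principal components.

    The PCA is fit on the union of whatever sets are being co-visualised, so
    families and background share one pair of axes.  A rank-0 input (all rows
    identical) yields zero scores and ratios (0, 0) with a warning.
    """
    latent = np.asarray(latent, dtype=float)
    n, d = latent.shape
    if n < 3:
        raise ValueError("PCA projection needs at least 3 points")
    centered = latent - latent.mean(axis=0)
    if not np.any(centered):
        warnings.warn("degenerate latent cloud: all points identical; ratios set to 0")
        return PCAResult(np.zeros((n, 2)), (0.0, 0.0), np.zeros((2, d)))
    pca = PCA(n_components=2, svd_solver="full").fit(latent)
    scores = pca.transform(latent)
    r1, r2 = (float(v) for v in pca.explained_variance_ratio_)
    return PCAResult(scores, (r1, r2), pca.components_.copy())


def density_heatmap(
    scores: np.ndarray, bins: int | tuple[int, int] = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D occupancy grid over PCA scores.

    Returns (counts, x_edges, y_edges); counts sum to the number of points and
    the edges cover the score range.
    """
    scores = np.asarray(scores, dtype=float)
    bx, by = (bins, bins) if isinstance(bins, int) else bins
    if bx < 2 or by < 2:
        raise ValueError("need at least 2 bins per axis")
    counts, xe, ye = np.histogram2d(scores[:, 0], scores[:, 1], bins=(bx, by))
    return counts, xe, ye


def plot_heatmap(scores: np.ndarray, path: str, bins: int = 50) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts, xe, ye = density_heatmap(scores, bins)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.pcolormesh(xe, ye, counts.T, cmap="viridis")
    fig.colorbar(im, ax=ax, label="molecules per bin")
    ax.set_xlabel("PC-1")
    ax.set_ylabel("PC-2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class FamilyStats:
    """Range statistics of one family's latent cloud.

    general_range: (min, max) over every entry of every member vector.
    centroid_range: (min, max) over the entries of the family mean vector.
    std_range: (min, max) over the per-dimension standard deviations
    (population convention, i.e. divide by n, so singleton families give 0).
    """

    n: int
    general_range: tuple[float, float]
    centroid_range: tuple[float, float]
    std_range: tuple[float, float]
    singleton: bool = False


def family_stats(
    latent: np.ndarray, labels: Sequence[str]
) -> dict[str, FamilyStats]:
    """Per-family latent range statistics; row order of the input is irrelevant."""
    latent = np.asarray(latent, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    if latent.shape[0] != labels.shape[0]:
        raise ValueError("latent rows and labels must align")
    out: dict[str, FamilyStats] = {}
    for fam in sorted(set(labels)):
        block = latent[labels == fam]
        centroid = block.mean(axis=0)
        std = block.std(axis=0)  # population (ddof=0)
        singleton = block.shape[0] == 1
        if singleton:
            warnings.warn(f"family {fam!r} has a single member; std range is (0, 0)")
        out[fam] = FamilyStats(
            n=block.shape[0],
            general_range=(float(block.min()), float(block.max())),
            centroid_range=(float(centroid.min()), float(centroid.max())),
            std_range=(float(std.min()), float(std.max())),
            singleton=singleton,
        )
    return out


def family_stats_table(stats: Mapping[str, FamilyStats]) -> pd.DataFrame:
    rows = [
        {
            "family": fam,
            "n": s.n,
            "general_min": s.general_range[0],
            "general_max": s.general_range[1],
            "centroid_min": s.centroid_range[0],
            "centroid_max": s.centroid_range[1],
            "std_min": s.std_range[0],
            "std_max": s.std_range[1],
        }
        for fam, s in stats.items()
    ]
    return pd.DataFrame(rows).set_index("family")
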