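"""Aitchison-distance PCoA and per-ASV axis loadings.

Compositions are CLR-transformed (with a pseudocount), pairwise
Euclidean distances between days are taken — the Aitchison distance —
and classical PCoA (double-centered Gram eigendecomposition) embeds
the days.  Because the distance is Euclidean in CLR space, the
coordinates coincide, up to axis sign, with a PCA of the CLR matrix;
the test suite exploits that identity as a cross-check.

A taxon's *loading* on an axis is the biplot projection: the Pearson
correlation between its CLR column and the axis scores, scaled by the
square root of the axis eigenvalue.  The scalar "PC1 + PC2 loading"
used elsewhere in the pipeline is |l1| + |l2|.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as skbio_pcoa

from .preprocess import clr_transform
from .table import AbundanceSeriesTable

__all__ = ["aitchison_pcoa", "feature_loadings", "OrdinationResult"]


@dataclasses.dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # days x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    feature_loadings: pd.DataFrame | None = None  # ASVs x (pc1, pc2)


def _fix_axis_signs(coords: np.ndarray) -> np.ndarray:
    """Resolve PCoA sign indeterminacy: the largest-|value| coordinate
    of each axis is made positive."""
    out = coords.copy()
    for a in range(out.shape[1]):
        col = out[:, a]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            out[:, a] = -col
    return out


def aitchison_pcoa(
    table: AbundanceSeriesTable | pd.DataFrame,
    pseudocount: float = 1.0,
    n_axes: int | None = None,
) -> OrdinationResult:
    """Classical PCoA of the between-day Aitchison distance matrix.

    Intended for interpolated, *non-rarefied* counts (CLR already
    removes the depth effect).  Negative eigenvalues — not expected for
    a Euclidean distance — are truncated to zero with a warning.
    """
    df = table.data if isinstance(table, AbundanceSeriesTable) else pd.DataFrame(table)
    if df.shape[0] < 3:
        raise ValueError("need at least 3 days for ordination")
    clr_df = clr_transform(df, pseudocount)
    dist = squareform(pdist(clr_df.to_numpy(), metric="euclidean"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = skbio_pcoa(DistanceMatrix(dist, ids=[str(d) for d in df.index]))
    eigvals = res.eigvals.to_numpy()
    if (eigvals < -1e-8 * max(eigvals.max(), 1.0)).any():
        warnings.warn("negative PCoA eigenvalues truncated to zero", stacklevel=2)
    eigvals = np.clip(eigvals, 0.0, None)
    coords = _fix_axis_signs(res.samples.to_numpy())
    if n_axes is not None:
        coords = coords[:, :n_axes]
        eigvals = eigvals[:n_axes]
    coordinates = pd.DataFrame(
        coords,
        index=df.index,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    ordination = OrdinationResult(
        coordinates=coordinates,
        eigenvalues=eigvals,
        proportion_explained=res.proportion_explained.to_numpy()[: coords.shape[1]],
    )
    ordination.feature_loadings = feature_loadings(clr_df, ordination)
    return ordination


def feature_loadings(clr_df: pd.DataFrame, ordination: OrdinationResult) -> pd.DataFrame:
    """Biplot loadings of every ASV on the first two axes.

    loading(j, a) = corr(CLR column j, axis-a scores) * sqrt(eig_a);
    constant CLR columns get a loading of 0.
    """
    coords = ordination.coordinates.to_numpy()
    if coords.shape[0] != clr_df.shape[0]:
        raise ValueError("CLR matrix and ordination cover different day sets")
    loadings = np.zeros((clr_df.shape[1], 2))
    x = clr_df.to_numpy()
    for a in range(min(2, coords.shape[1])):
        axis = coords[:, a]
        axis_sd = axis.std()
        scale = np.sqrt(max(ordination.eigenvalues[a], 0.0))
        if axis_sd == 0:
            continue
        for j in range(x.shape[1]):
            col = x[:, j]
            if col.std() == 0:
                continue
            r = np.corrcoef(col, axis)[0, 1]
            loadings[j, a] = r * scale
    return pd.DataFrame(loadings, index=clr_df.columns, columns=["pc1", "pc2"])
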