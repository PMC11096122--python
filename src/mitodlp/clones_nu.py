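"""Clone assignment from nuclear copy-number bin profiles.

The pluggable backend mirrors the embedding/density-clustering configuration
used for scWGS clone calling (UMAP with ``min_dist=0.0`` and correlation
metric, HDBSCAN with ``cluster_selection_epsilon=0.2``); it is an optional
adapter because those algorithms are off-the-shelf. The default,
dependency-free backend clusters correlation distances hierarchically and is
what the test suite exercises. A cross-check against mtDNA-derived clones
(contingency + adjusted Rand index) supports the consistency argument that
diploid and tetraploid cells of the same clone share mtDNA variants.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

UMAP_DEFAULTS = {"min_dist": 0.0, "metric": "correlation", "n_components": 2}
HDBSCAN_DEFAULTS = {
    "cluster_selection_epsilon": 0.2,
    "approx_min_span_tree": False,
    "gen_min_span_tree": True,
}


@dataclass
class CloneLabeling:
    """Per-cell clone letters (or ``"noise"``), with the method and parameters used."""

    labels: pd.Series
    method: str
    params: dict = field(default_factory=dict)


def _correlation_distances(X: np.ndarray) -> np.ndarray:
    """Pairwise correlation distance, defined for zero-variance rows:
    identical rows are at distance 0, otherwise a zero-variance row is at
    distance 1 from everything."""
    n = X.shape[0]
    sd = X.std(axis=1)
    D = np.ones((n, n))
    ok = sd > 0
    if ok.sum() >= 2:
        Xo = X[ok]
        corr = np.corrcoef(Xo)
        D[np.ix_(ok, ok)] = 1.0 - corr
    eq = np.all(X[:, None, :] == X[None, :, :], axis=2)
    D[eq] = 0.0
    np.fill_diagonal(D, 0.0)
    return np.clip((D + D.T) / 2.0, 0.0, None)


def _canonical_letters(raw: np.ndarray, cell_ids: pd.Index) -> pd.Series:
    """Map raw cluster ids to letters ordered by (size desc, min cell id);
    id -1 becomes ``"noise"``. Ordering depends only on the partition and the
    cell identifiers, so labels are stable under cell-order permutation."""
    out = pd.Series(index=cell_ids, dtype=object)
    clusters = [c for c in np.unique(raw) if c != -1]
    keyed = sorted(
        clusters, key=lambda c: (-int((raw == c).sum()), min(cell_ids[raw == c]))
    )
    letters = {c: string.ascii_uppercase[i % 26] * (i // 26 + 1) for i, c in enumerate(keyed)}
    for c in clusters:
        out[raw == c] = letters[c]
    out[raw == -1] = "noise"
    return out


def cluster_cells_nu(
    bin_matrix: pd.DataFrame,
    n_clones: int | None = None,
    distance_threshold: float = 0.5,
    method: str = "fallback",
    seed: int = 0,
    umap_params: dict | None = None,
    hdbscan_params: dict | None = None,
    allow_fallback: bool = True,
) -> CloneLabeling:
    """Cluster cells by nuclear bin-state profile.

    ``bin_matrix`` is cells x bins (index = cell ids). With
    ``method="fallback"`` (default): average-linkage hierarchical clustering
    on correlation distance, cut either at ``n_clones`` clusters or at
    ``distance_threshold``. With ``method="umap_hdbscan"``: the external
    embedding/density adapter with the standard parameters; if those packages
    are unavailable the fallback is used (or an ImportError raised when
    ``allow_fallback=False``).
    """
    if len(bin_matrix) < 10:
        raise ValueError("need at least 10 cells to cluster")
    X = bin_matrix.to_numpy(dtype=float)
    cell_ids = bin_matrix.index

    if method == "umap_hdbscan":
        try:
            import hdbscan  # type: ignore
            import umap  # type: ignore
        except ImportError:
            if not allow_fallback:
                raise ImportError(
                    "umap-learn and hdbscan are required for the umap_hdbscan backend"
                )
            method = "fallback"
        else:
            up = {**UMAP_DEFAULTS, **(umap_params or {}), "random_state": seed}
            hp = {**HDBSCAN_DEFAULTS, **(hdbscan_params or {})}
            emb = umap.UMAP(**up).fit_transform(X)
            raw = hdbscan.HDBSCAN(**hp).fit_predict(emb)
            return CloneLabeling(
                labels=_canonical_letters(np.asarray(raw), cell_ids),
                method="umap_hdbscan",
                params={"umap": up, "hdbscan": hp},
            )

    if np.all(X == X[0]):
        raw = np.zeros(len(X), dtype=int)
    else:
        D = _correlation_distances(X)
        Zl = linkage(squareform(D, checks=False), method="average")
        if n_clones is not None:
            raw = fcluster(Zl, t=n_clones, criterion="maxclust")
        else:
            raw = fcluster(Zl, t=distance_threshold, criterion="distance")
    return CloneLabeling(
        labels=_canonical_letters(np.asarray(raw), cell_ids),
        method="fallback_hierarchical",
        params={"n_clones": n_clones, "distance_threshold": distance_threshold},
    )


def crosscheck_clones(nu_labels: pd.Series, mt_labels: pd.Series) -> dict:
    """Agreement between nuclear-profile clones and mtDNA clones.

    Returns the contingency table over shared cells, the adjusted Rand index
    (symmetric in its arguments) and each nuclear clone's modal mtDNA clone.
    Raises when the cell sets are disjoint.
    """
    shared = nu_labels.index.intersection(mt_labels.index)
    if len(shared) == 0:
        raise ValueError("nuclear and mtDNA labelings share no cells")
    a = nu_labels.loc[shared].astype(str)
    b = mt_labels.loc[shared].astype(str)
    table = pd.crosstab(a.rename("nu_clone"), b.rename("mt_clone"))
    ari = float(adjusted_rand_score(a, b))
    modal = table.idxmax(axis=1).to_dict()
    return {"contingency": table, "ari": ari, "modal_mt_clone": modal, "n_shared": int(len(shared))}
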