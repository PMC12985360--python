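"""Neighborhood-level differential abundance between conditions.

Neighborhoods are index cells plus their k nearest neighbors on an embedding
(k = 60 by default, matching kNN-graph differential-abundance practice).
Per-neighborhood cell counts per sample are tested for a condition effect
with the NB LRT (sample totals as offsets) and BH-corrected across
neighborhoods.  For visualization-grade labeling, each neighborhood is
expanded to all cells within a fixed radius of its index cell's 2-D
coordinates and labeled Young-/Aged-enriched when one condition strictly
exceeds 70.5% of the expanded membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .diffexpr import bh_adjust, nb_lrt


@dataclass
class NeighborhoodSet:
    embedding: np.ndarray          # cells x dims (first two used for expansion)
    cell_ids: list[str]
    index_cells: np.ndarray        # indices into cell_ids
    members: list[np.ndarray]      # per neighborhood, indices incl. the index cell
    kth_distance: np.ndarray       # distance from index cell to its k-th neighbor
    sample_counts: pd.DataFrame | None = None   # neighborhood x sample
    results: pd.DataFrame | None = None         # logFC, p, FDR per neighborhood
    labels: pd.DataFrame | None = None          # after expansion
    expansion_radius: float | None = None

    @property
    def n_neighborhoods(self) -> int:
        return len(self.members)

    def default_radius(self) -> float:
        """Median index-to-k-th-neighbor distance; the expansion default."""
        return float(np.median(self.kth_distance))


def build_neighborhoods(embedding: np.ndarray, cell_ids: list[str], k: int = 60,
                        sampling_fraction: float = 0.1, seed: int = 0
                        ) -> NeighborhoodSet:
    """Sample index cells and collect each one's k nearest neighbors.

    Euclidean kNN on the full embedding; every neighborhood has k+1 members
    (its index cell plus k neighbors).  ``sampling_fraction`` = 1 indexes
    every cell.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    rng = np.random.default_rng(seed)
    n_index = max(1, int(round(sampling_fraction * n)))
    index_cells = np.sort(rng.choice(n, size=n_index, replace=False))

    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    dist, idx = nn.kneighbors(embedding[index_cells])
    members = []
    for i, row in zip(index_cells, idx):
        m = row.copy()
        if i not in m:  # ties in distance can push self out of the k+1 set
            m[-1] = i
        members.append(np.unique(m))
    return NeighborhoodSet(
        embedding=embedding, cell_ids=list(cell_ids), index_cells=index_cells,
        members=members, kth_distance=dist[:, -1])


def count_cells(nhoods: NeighborhoodSet, sample_of_cell: pd.Series) -> pd.DataFrame:
    """Neighborhood x sample membership counts."""
    samples = sorted(sample_of_cell.dropna().unique())
    cell_sample = sample_of_cell.reindex(nhoods.cell_ids).to_numpy()
    rows = []
    for m in nhoods.members:
        vals, counts = np.unique(cell_sample[m], return_counts=True)
        rows.append(dict(zip(vals, counts)))
    out = pd.DataFrame(rows).reindex(columns=samples).fillna(0).astype(int)
    out.index.name = "neighborhood"
    nhoods.sample_counts = out
    return out


def test_neighborhood_abundance(nhoods: NeighborhoodSet,
                                condition_of_sample: dict[str, str],
                                reference: str,
                                fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Per-neighborhood NB LRT on sample counts with sample-total offsets.

    Requires >= 2 samples per condition; samples with zero cells overall are
    excluded with a warning.  logFC is alt vs ``reference`` on normalized
    counts (pseudocount 0.5); BH across neighborhoods.
    """
    import warnings

    counts = nhoods.sample_counts
    if counts is None:
        raise ValueError("run count_cells() first")
    totals = counts.sum(axis=0)
    empty = totals[totals == 0].index.tolist()
    if empty:
        warnings.warn(f"excluding samples with zero cells: {empty}")
        counts = counts.drop(columns=empty)
        totals = totals.drop(empty)
    cond = np.array([condition_of_sample[s] for s in counts.columns])
    levels = sorted(set(cond))
    if len(levels) != 2 or any((cond == c).sum() < 2 for c in levels):
        raise ValueError("need two conditions with >= 2 samples each")
    alt = [c for c in levels if c != reference][0]
    ordered = np.where(cond == reference, "0_" + reference, "1_" + alt)

    s = totals.to_numpy(dtype=float)
    pvals = np.empty(len(counts))
    lfc = np.empty(len(counts))
    norm = counts.to_numpy(dtype=float) / s  # per-sample neighborhood fraction
    for i, (_, y) in enumerate(counts.iterrows()):
        pvals[i], _ = nb_lrt(y.to_numpy(dtype=float), ordered, s)
        m_ref = norm[i, cond == reference].mean()
        m_alt = norm[i, cond == alt].mean()
        c = 0.5 / s.mean()
        lfc[i] = np.log2((m_alt + c) / (m_ref + c))
    res = pd.DataFrame({
        "neighborhood": counts.index,
        "log2fc": lfc,
        "p": pvals,
        "fdr": bh_adjust(pvals),
    })
    res["significant"] = res["fdr"] < fdr_threshold
    nhoods.results = res
    return res


def expand_and_label(nhoods: NeighborhoodSet, condition_of_cell: pd.Series,
                     radius: float | None = None, threshold: float = 0.705,
                     conditions: tuple[str, str] = ("young", "aged")
                     ) -> pd.DataFrame:
    """Expand neighborhoods by a fixed 2-D radius and label by composition.

    Expanded membership = original members plus every cell within ``radius``
    of the index cell's first-two embedding coordinates.  A neighborhood is
    labeled ``<Condition>-enriched`` iff that condition's raw proportion of
    the expanded membership STRICTLY exceeds ``threshold`` (default 70.5%);
    otherwise it stays unlabeled.
    """
    if radius is None:
        radius = nhoods.default_radius()
    if radius <= 0:
        raise ValueError("radius must be > 0")
    xy = nhoods.embedding[:, :2]
    cond = condition_of_cell.reindex(nhoods.cell_ids).to_numpy()
    young, aged = conditions

    rows = []
    for j, (i, m) in enumerate(zip(nhoods.index_cells, nhoods.members)):
        d = np.linalg.norm(xy - xy[i], axis=1)
        expanded = np.union1d(m, np.flatnonzero(d <= radius))
        sub = cond[expanded]
        n = len(sub)
        p_young = float((sub == young).sum() / n)
        p_aged = float((sub == aged).sum() / n)
        if p_young > threshold:
            label = f"{young.capitalize()}-enriched"
        elif p_aged > threshold:
            label = f"{aged.capitalize()}-enriched"
        else:
            label = "unlabeled"
        rows.append({
            "neighborhood": j, "index_cell": nhoods.cell_ids[i],
            "x": xy[i, 0], "y": xy[i, 1], "n_expanded": n,
            f"prop_{young}": p_young, f"prop_{aged}": p_aged, "label": label,
        })
    out = pd.DataFrame(rows)
    nhoods.labels = out
    nhoods.expansion_radius = float(radius)
    return out


def pca_embedding(X, n_components: int = 2, seed: int = 0) -> np.ndarray:
    """Simple log-CPM PCA embedding utility (any external embedding works too)."""
    import scipy.sparse as sp
    from sklearn.decomposition import PCA

    X = sp.csr_matrix(X, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0
    Z = np.log1p(np.asarray((sp.diags(1e4 / totals) @ X).todense()))
    return PCA(n_components=n_components,
               random_state=int(seed) % (2 ** 31)).fit_transform(Z)
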