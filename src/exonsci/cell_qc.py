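"""Cell quality filtering and doublet scoring.

``filter_cells`` keeps a cell iff it reaches both the UMI and the
unique-gene threshold (brain preset: >= 500 UMIs and >= 100 genes; cell-line
preset: >= 1000 UMIs).

``doublet_scores`` reimplements the simulated-doublet nearest-neighbor
classifier: synthetic doublets are sums of random observed cell pairs; after
gene filtering, variable-gene selection at a v-score percentile, and PCA, a
kNN graph over observed + simulated cells yields each observed cell's
simulated-neighbor fraction, calibrated into a doublet score.  Calibration
(for expected doublet rate rho and simulated:observed ratio r, with q the
Bayesian-smoothed simulated-neighbor fraction):

    score = q * rho / r / (1 - rho - q * (1 - rho - rho / r))

which is the posterior probability that the cell's neighborhood density is
dominated by doublets.  Cells with score > 0.2 are called doublets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .quantify import CountMatrix


@dataclass
class QCConfig:
    min_umis: int = 500          # brain preset; cell-line preset uses 1000
    min_genes: int = 100
    # doublet-scorer parameters
    min_count: int = 3
    min_cells: int = 3
    vscore_percentile: float = 85.0
    n_pc: int = 30
    expected_doublet_rate: float = 0.06
    sim_doublet_ratio: float = 2.0
    n_neighbors: int = 30
    doublet_score_threshold: float = 0.2

    def __post_init__(self):
        if self.min_umis < 0 or self.min_genes < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0 < self.expected_doublet_rate < 1:
            raise ValueError("expected_doublet_rate must be in (0,1)")

    @classmethod
    def preset(cls, name: str, **kw) -> "QCConfig":
        base = {"brain": 500, "cellline": 1000}[name]
        return cls(min_umis=base, **kw)


@dataclass
class QCReport:
    kept: list[str]
    discarded: pd.DataFrame  # cell, n_umis, n_genes, reason


def filter_cells(matrix: CountMatrix, config: QCConfig) -> tuple[CountMatrix, QCReport]:
    """Drop cells below the UMI or unique-gene threshold.

    Keep iff ``total UMIs >= min_umis`` AND ``detected genes >= min_genes``
    (both boundaries inclusive); the report lists each discarded cell with the
    failed criterion.  Idempotent.
    """
    totals = matrix.totals
    ngenes = np.asarray((matrix.X > 0).sum(axis=1)).ravel()
    keep = (totals >= config.min_umis) & (ngenes >= config.min_genes)

    reasons = np.where(
        totals < config.min_umis,
        np.where(ngenes < config.min_genes, "low_umis;low_genes", "low_umis"),
        "low_genes")
    discarded = pd.DataFrame({
        "cell": np.asarray(matrix.cell_ids)[~keep],
        "n_umis": totals[~keep].astype(int),
        "n_genes": ngenes[~keep].astype(int),
        "reason": reasons[~keep],
    })
    if not keep.any():
        warnings.warn("all cells were discarded by QC filters")
    kept_cells = [c for c, k in zip(matrix.cell_ids, keep) if k]
    filtered = CountMatrix(kept_cells, list(matrix.feature_ids), matrix.kind,
                           matrix.X[keep])
    return filtered, QCReport(kept=kept_cells, discarded=discarded)


def _vscores(E: sp.csr_matrix, totals: np.ndarray) -> np.ndarray:
    """Above-Poisson variability score per gene (Fano factor of the
    total-count-normalized expression); used to rank variable genes."""
    norm = sp.diags(totals.mean() / totals) @ E
    mean = np.asarray(norm.mean(axis=0)).ravel()
    sq = np.asarray(norm.multiply(norm).mean(axis=0)).ravel()
    var = sq - mean ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        fano = np.where(mean > 0, var / mean, 0.0)
    return fano


def doublet_scores(matrix: CountMatrix, config: QCConfig | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Per-cell doublet score in [0,1] and the score > threshold call.

    Requires at least ``2 * n_neighbors`` cells.  The pair sampling for
    synthetic doublets is seeded, so scores are reproducible and invariant
    under cell permutation up to that sampling.
    """
    config = config or QCConfig()
    n_obs = len(matrix.cell_ids)
    if n_obs < 2 * config.n_neighbors:
        raise ValueError(
            f"need >= {2 * config.n_neighbors} cells for doublet scoring, got {n_obs}")
    rng = np.random.default_rng(seed)
    E = sp.csr_matrix(matrix.X, dtype=float)
    totals = matrix.totals.astype(float)
    totals[totals == 0] = 1.0

    # gene filter: detected in >= min_cells cells with >= min_count counts
    det = np.asarray((E >= config.min_count).sum(axis=0)).ravel()
    E = E[:, det >= config.min_cells]

    # simulated doublets = sums of random observed pairs
    n_sim = int(round(config.sim_doublet_ratio * n_obs))
    pairs = rng.integers(0, n_obs, size=(n_sim, 2))
    D = E[pairs[:, 0]] + E[pairs[:, 1]]
    d_totals = totals[pairs[:, 0]] + totals[pairs[:, 1]]

    # variable genes from the observed matrix only
    v = _vscores(E, totals)
    thresh = np.percentile(v[v > 0], config.vscore_percentile) if (v > 0).any() else 0
    hv = v >= thresh
    if hv.sum() < 2:
        hv = np.ones_like(hv, dtype=bool)

    def embed(M, t):
        norm = sp.diags(totals.mean() / t) @ M[:, hv]
        return np.log1p(np.asarray(norm.todense()))

    Z = np.vstack([embed(E, totals), embed(D, d_totals)])
    Z = Z - Z[:n_obs].mean(axis=0)  # center on observed cells
    n_pc = min(config.n_pc, Z.shape[1], n_obs - 1)
    pca = PCA(n_components=n_pc, random_state=int(seed) % (2 ** 31))
    pca.fit(Z[:n_obs])
    Y = pca.transform(Z)

    k = config.n_neighbors
    # adjust k for the enlarged graph, as in the simulated-doublet literature
    k_adj = int(round(k * (1 + config.sim_doublet_ratio)))
    nn = NearestNeighbors(n_neighbors=k_adj + 1).fit(Y)
    _, idx = nn.kneighbors(Y[:n_obs])
    idx = idx[:, 1:]  # drop self
    n_sim_neighbors = (idx >= n_obs).sum(axis=1)

    rho = config.expected_doublet_rate
    r = config.sim_doublet_ratio
    q = (n_sim_neighbors + 1) / (k_adj + 2)  # Bayesian-smoothed fraction
    score = q * rho / r / (1.0 - rho - q * (1.0 - rho - rho / r))
    score = np.clip(score, 0.0, 1.0)
    return pd.DataFrame({
        "cell": matrix.cell_ids,
        "doublet_score": score,
        "is_doublet": score > config.doublet_score_threshold,
    })
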