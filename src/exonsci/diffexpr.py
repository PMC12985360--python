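"""Negative-binomial likelihood-ratio differential expression over a combined
gene + exon feature set, with DEG/DEE calling and DEG-derived classification.

Model per feature: counts ``y_i ~ NB(mu_i, alpha)`` with ``log mu_i =
log s_i + x_i beta`` where ``s_i`` is the cell's total molecule count (the
size factor, consistent with the CPM framing) and ``x_i`` the condition
indicator.  The LRT compares the full model (intercept + condition) against
intercept-only; p from chi-square with 1 df.  The overdispersion ``alpha`` is
a per-feature method-of-moments estimate around the per-condition means,
shared between both models, floored at ``dispersion_floor``.

Fold change is mean-ratio, not model-derived: ``log2((CPM_alt + c) /
(CPM_ref + c))`` with pseudocount ``c`` (default 1 CPM), averaged over cells
per condition.  A single Benjamini-Hochberg correction runs across the
concatenated gene and exon feature list (the combined test improves power at
the weakly expressed exon level).

Calling rules: a gene is a DEG when FDR < 0.05, |FC| > 1.5 and max-condition
mean CPM > 25; an exon is a DEE at the same FDR/FC cutoffs but CPM > 10.  A
DEE is "DEG-derived" when its parent gene passes the FDR/FC cutoffs at the
*exon* CPM cutoff (> 10) - the parent may fail the gene-level CPM > 25 filter
and therefore not itself be a DEG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy import stats

from .quantify import CountMatrix


@dataclass
class DEConfig:
    fdr_threshold: float = 0.05
    fold_change_threshold: float = 1.5
    gene_cpm_threshold: float = 25.0
    exon_cpm_threshold: float = 10.0
    pseudocount: float = 1.0  # CPM units
    dispersion_floor: float = 1e-4

    def __post_init__(self):
        for name in ("fdr_threshold", "fold_change_threshold",
                     "gene_cpm_threshold", "exon_cpm_threshold",
                     "pseudocount", "dispersion_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def cpm(matrix: CountMatrix) -> tuple[sp.csr_matrix, list[str]]:
    """Per-cell counts-per-million; zero-total cells are excluded with a warning.

    Returns (CPM matrix over kept cells, kept cell ids).
    """
    totals = matrix.totals
    keep = totals > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-total cells from CPM")
    X = matrix.X[keep].astype(float)
    scale = sp.diags(1e6 / totals[keep])
    return scale @ X, [c for c, k in zip(matrix.cell_ids, keep) if k]


def condition_mean_cpm(matrix: CountMatrix, labels: pd.Series) -> pd.DataFrame:
    """Per-feature mean CPM per condition (mean over that condition's cells)."""
    X, cells = cpm(matrix)
    labels = labels.reindex(cells)
    out = {}
    for cond in sorted(labels.dropna().unique()):
        mask = (labels == cond).to_numpy()
        out[cond] = np.asarray(X[mask].mean(axis=0)).ravel()
    return pd.DataFrame(out, index=matrix.feature_ids)


# ---------------------------------------------------------------------------
# NB LRT
# ---------------------------------------------------------------------------

def _mom_dispersion(y: np.ndarray, s: np.ndarray, groups: np.ndarray,
                    floor: float) -> float:
    """Method-of-moments alpha around per-condition means, with a small-sample
    degrees-of-freedom correction; shared across conditions."""
    mu = np.empty_like(y, dtype=float)
    p = 0
    for g in np.unique(groups):
        m = groups == g
        mu[m] = s[m] * (y[m].sum() / s[m].sum())
        p += 1
    denom = (mu ** 2).sum()
    if denom == 0:
        return floor
    n = len(y)
    alpha = (((y - mu) ** 2 - mu).sum() * n / max(n - p, 1)) / denom
    return float(min(max(alpha, floor), 100.0))


def nb_lrt(y: np.ndarray, condition: np.ndarray, size_factors: np.ndarray,
           dispersion_floor: float = 1e-4) -> tuple[float, bool]:
    """NB likelihood-ratio test of a condition effect on one feature's counts.

    Returns (p value, poisson_fallback flag).  All-zero features give p = 1.
    Non-convergent NB fits fall back to a Poisson LRT, flagged.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(size_factors, dtype=float)
    if y.sum() == 0:
        return 1.0, False
    groups = np.asarray(condition)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError("nb_lrt requires exactly two condition levels")
    x = (groups == levels[1]).astype(float)
    X_full = np.column_stack([np.ones_like(x), x])
    X_null = X_full[:, :1]
    offset = np.log(s)

    alpha = _mom_dispersion(y, s, groups, dispersion_floor)
    for family, fallback in ((sm.families.NegativeBinomial(alpha=alpha), False),
                             (sm.families.Poisson(), True)):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = sm.GLM(y, X_full, family=family, offset=offset).fit()
                null = sm.GLM(y, X_null, family=family, offset=offset).fit()
            lrt = max(0.0, 2.0 * (full.llf - null.llf))
            if np.isfinite(lrt):
                return float(stats.chi2.sf(lrt, df=1)), fallback
        except Exception:
            continue
    return 1.0, True


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg FDR (monotone step-up)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# combined gene + exon DE
# ---------------------------------------------------------------------------

def _feature_tests(matrix: CountMatrix, labels: pd.Series, reference: str,
                   config: DEConfig) -> pd.DataFrame:
    totals = matrix.totals
    keep = totals > 0
    cells = np.asarray(matrix.cell_ids)[keep]
    lab = labels.reindex(cells).to_numpy()
    if pd.isna(lab).any():
        raise ValueError("labels missing for some cells in the matrix")
    levels = sorted(set(lab))
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not among labels {levels}")
    alt = [l for l in levels if l != reference]
    if len(alt) != 1:
        raise ValueError("combined DE requires exactly two conditions")
    alt = alt[0]
    # order so the fold change is alt vs reference
    cond = np.where(lab == reference, "0_" + reference, "1_" + alt)

    X = sp.csc_matrix(matrix.X[keep])
    s = totals[keep].astype(float)
    mean_cpm = condition_mean_cpm(
        CountMatrix(list(cells), matrix.feature_ids, matrix.kind, matrix.X[keep]),
        labels)

    pvals = np.empty(X.shape[1])
    fallback = np.zeros(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        y = np.asarray(X[:, j].todense()).ravel()
        pvals[j], fallback[j] = nb_lrt(y, cond, s, config.dispersion_floor)

    c = config.pseudocount
    lfc = np.log2((mean_cpm[alt].to_numpy() + c) / (mean_cpm[reference].to_numpy() + c))
    return pd.DataFrame({
        "feature_id": matrix.feature_ids,
        "kind": matrix.kind,
        "p": pvals,
        "poisson_fallback": fallback,
        f"mean_cpm_{reference}": mean_cpm[reference].to_numpy(),
        f"mean_cpm_{alt}": mean_cpm[alt].to_numpy(),
        "max_cpm": mean_cpm[[reference, alt]].max(axis=1).to_numpy(),
        "log2fc": lfc,
    })


def run_combined_de(gene_matrix: CountMatrix | None, exon_matrix: CountMatrix | None,
                    labels: pd.Series, reference: str,
                    config: DEConfig | None = None) -> pd.DataFrame:
    """LRT per feature over genes and exons with one BH correction across both.

    ``labels`` maps cell id -> condition; fold changes are alt vs
    ``reference``.  Exon feature ids are ``gene:index`` and carry their parent
    gene.  Matrices must share their cell set.
    """
    config = config or DEConfig()
    frames = []
    cellsets = []
    for m in (gene_matrix, exon_matrix):
        if m is not None:
            frames.append(_feature_tests(m, labels, reference, config))
            cellsets.append(tuple(m.cell_ids))
    if not frames:
        raise ValueError("at least one of gene/exon matrix is required")
    if len(cellsets) == 2 and set(cellsets[0]) != set(cellsets[1]):
        raise ValueError("gene and exon matrices must share the same cells")
    table = pd.concat(frames, ignore_index=True)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table["parent_gene"] = np.where(
        table["kind"] == "exon",
        table["feature_id"].str.rsplit(":", n=1).str[0],
        table["feature_id"])
    return call_and_classify(table, config)


def call_and_classify(table: pd.DataFrame, config: DEConfig | None = None
                      ) -> pd.DataFrame:
    """Flag DEGs/DEEs and classify DEEs as DEG-derived or not.

    The DEG-derived re-filter applies the gene FDR/FC cutoffs at the *exon*
    CPM threshold, so a parent gene detectable only at exon-level expression
    still anchors its exons as DEG-derived.
    """
    config = config or DEConfig()
    t = table.copy()
    fc_ok = np.abs(t["log2fc"]) > np.log2(config.fold_change_threshold)
    sig = (t["fdr"] < config.fdr_threshold) & fc_ok
    t["is_DEG"] = (t["kind"] == "gene") & sig & (t["max_cpm"] > config.gene_cpm_threshold)
    t["is_DEE"] = (t["kind"] == "exon") & sig & (t["max_cpm"] > config.exon_cpm_threshold)

    genes = t[t["kind"] == "gene"].set_index("feature_id")
    exons = t["kind"] == "exon"
    if exons.any() and len(genes) == 0:
        # exon-only input: testing and flagging proceed, classification
        # (which needs the parent gene's test) is undefined
        t["dee_class"] = pd.NA
        return t
    missing = set(t.loc[exons, "parent_gene"]) - set(genes.index)
    if exons.any() and missing:
        raise ValueError(f"exons lack parent gene rows: {sorted(missing)[:5]}")
    # parent gene at the exon CPM cutoff
    parent_ok = (
        (genes["fdr"] < config.fdr_threshold)
        & (np.abs(genes["log2fc"]) > np.log2(config.fold_change_threshold))
        & (genes["max_cpm"] > config.exon_cpm_threshold)
    )
    t["dee_class"] = pd.NA
    if exons.any():
        derived = t.loc[exons, "parent_gene"].map(parent_ok).fillna(False)
        t.loc[exons & t["is_DEE"], "dee_class"] = np.where(
            derived[t.loc[exons, "is_DEE"]], "DEG-derived", "non-DEG-derived")
    return t


def shared_logfc_correlation(table_a: pd.DataFrame, table_b: pd.DataFrame,
                             flag: str = "is_DEG") -> dict:
    """Pearson correlation of log2 fold changes over features flagged in both.

    Mirrors the shared-DEG/DEE concordance analysis between two subtypes.
    With fewer than 3 shared features r is undefined.
    """
    a = table_a[table_a[flag]].set_index("feature_id")["log2fc"]
    b = table_b[table_b[flag]].set_index("feature_id")["log2fc"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        return {"r": None, "p": None, "n_shared": int(len(shared))}
    r, p = stats.pearsonr(a.loc[shared], b.loc[shared])
    return {"r": float(r), "p": float(p), "n_shared": int(len(shared))}
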