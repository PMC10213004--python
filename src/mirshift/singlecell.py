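"""Single-cell QC, normalization, rank-sum differential expression, markers,
and proteome concordance.

Cells live in an :class:`anndata.AnnData`: raw counts in ``layers["counts"]``,
the 10k-total natural-log-normalized matrix in ``X`` after :func:`normalize`,
QC covariates in ``obs``.  Differential expression between conditions within
one cell type uses the two-sided Wilcoxon rank-sum test — exact (full
enumeration of the permutation distribution of the rank sum, ties included)
when both sides have at most 12 cells, otherwise the normal approximation
with tie and continuity corrections — with Bonferroni correction by default.
The fold-change convention is the Seurat one: natural log of pseudocounted
means of de-logged normalized values, ln((mean expm1 + 1)_A / (mean expm1 + 1)_B).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "load_mtx",
    "qc_filter",
    "normalize",
    "exact_ranksum_p",
    "wilcoxon_de",
    "find_markers",
    "pseudobulk_corr",
]

EXACT_MAX_N = 12  # both groups at most this size -> exact enumeration


def load_mtx(mtx_path, features_path, barcodes_path, metadata_path=None) -> ad.AnnData:
    """Assemble an AnnData from Matrix Market counts plus TSV sidecars.

    The MTX is genes x cells (exchange convention); features/barcodes are
    one-column TSVs; optional metadata TSV is indexed by barcode.
    """
    counts = sio.mmread(mtx_path).tocsr().astype(np.int64)
    features = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    adata = ad.AnnData(
        X=counts.T.tocsr(),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(features, name="gene")),
    )
    adata.layers["counts"] = adata.X.copy()
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
        adata.obs = meta.reindex(adata.obs_names)
    return adata


def _counts(adata: ad.AnnData) -> sparse.csr_matrix:
    m = adata.layers.get("counts", adata.X)
    return m.tocsr() if sparse.issparse(m) else sparse.csr_matrix(m)


def qc_filter(
    adata: ad.AnnData,
    min_genes: int = 500,
    max_mito: float = 0.15,
    max_doublet: float = 0.25,
    mito_prefix: str = "mt-",
    strict: bool = False,
) -> tuple[ad.AnnData, dict[str, int]]:
    """Remove low-quality cells and report counts removed per rule.

    Rules: fewer than ``min_genes`` expressed genes; mitochondrial UMI
    fraction greater than ``max_mito`` (taken from ``obs["mito_frac"]`` when
    present, else computed from genes with ``mito_prefix``); doublet score
    greater than ``max_doublet`` (skipped with a warning, or an error under
    ``strict``, when no doublet column exists).  Boundary semantics are
    strict inequalities: a cell at exactly 500 genes, 15% mito, or 0.25
    doublet score is retained.
    """
    counts = _counts(adata)
    n_genes = np.asarray((counts > 0).sum(axis=1)).ravel()
    fail_genes = n_genes < min_genes

    if "mito_frac" in adata.obs.columns:
        mito = adata.obs["mito_frac"].to_numpy(dtype=float)
    else:
        is_mito = adata.var_names.str.lower().str.startswith(mito_prefix.lower())
        tot = np.asarray(counts.sum(axis=1)).ravel().astype(float)
        mt = np.asarray(counts[:, np.where(is_mito)[0]].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito = np.where(tot > 0, mt / np.maximum(tot, 1), 0.0)
    fail_mito = mito > max_mito

    if "doublet_score" in adata.obs.columns:
        fail_dbl = adata.obs["doublet_score"].to_numpy(dtype=float) > max_doublet
    elif strict:
        raise ValueError("doublet_score column required in strict mode")
    else:
        warnings.warn("no doublet_score column; doublet rule skipped")
        fail_dbl = np.zeros(adata.n_obs, dtype=bool)

    report = {
        "n_input": int(adata.n_obs),
        "removed_min_genes": int(fail_genes.sum()),
        "removed_mito": int(fail_mito.sum()),
        "removed_doublet": int(fail_dbl.sum()),
    }
    keep = ~(fail_genes | fail_mito | fail_dbl)
    report["n_removed"] = int((~keep).sum())
    report["n_kept"] = int(keep.sum())
    return adata[keep].copy(), report


def normalize(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Scale each cell's counts to ``target_sum`` total, then ln(1+x).

    A zero-count cell is an error — QC should have removed it.  Raw counts
    are preserved in ``layers["counts"]``.
    """
    counts = _counts(adata)
    totals = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    if (totals == 0).any():
        bad = list(adata.obs_names[totals == 0][:5])
        raise ValueError(f"zero-count cells present (QC should remove them): {bad}")
    adata = adata.copy()
    adata.layers["counts"] = counts
    scaled = sparse.diags(target_sum / totals) @ counts
    adata.X = scaled.log1p().tocsr() if sparse.issparse(scaled) else np.log1p(scaled)
    adata.uns["target_sum"] = target_sum
    return adata


# ---------------------------------------------------------------------------
# Rank-sum testing
# ---------------------------------------------------------------------------

def exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by full enumeration, ties included.

    The permutation distribution of the group-x rank sum W over all
    C(n+m, n) relabelings of the pooled (mid)ranks is computed with a
    subset-sum dynamic program (midranks doubled to stay integral);
    p = P(|W - E[W]| >= |w_obs - E[W]|).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    r2 = np.rint(2 * ranks).astype(np.int64)  # doubled midranks, exact integers
    w_obs = int(r2[:n].sum())
    total = int(r2.sum())
    # dp[k, s] = number of size-k subsets of the pooled ranks with doubled-sum s
    dp = np.zeros((n + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in r2:
        for k in range(n, 0, -1):  # descending k so each rank is used once
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    dist = dp[n]
    n_subsets = dist.sum()
    mean2 = n * (n + m + 1)  # doubled mean of W
    dev = abs(w_obs - mean2)
    sums = np.arange(total + 1)
    p = dist[np.abs(sums - mean2) >= dev - 1e-9].sum() / n_subsets
    return float(min(p, 1.0))


def _ranksum_asymptotic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided normal-approximation p per column, tie+continuity corrected."""
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", axis=0)
    return np.atleast_1d(res.pvalue)


def _log_fold_change(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Seurat-style natural-log FC of pseudocounted de-logged means."""
    return np.log((np.expm1(a).mean(axis=0) + 1.0) / (np.expm1(b).mean(axis=0) + 1.0))


def _adjust(p: np.ndarray, correction: str, m: int | None = None) -> np.ndarray:
    m = len(p) if m is None else m
    if correction == "bonferroni":
        return np.minimum(p * m, 1.0)
    if correction == "bh":
        return bh_adjust(p)
    raise ValueError(f"unknown correction {correction!r}")


def _dense(x) -> np.ndarray:
    return x.toarray() if sparse.issparse(x) else np.asarray(x)


def wilcoxon_de(
    adata: ad.AnnData,
    cell_type: str | None,
    contrast: tuple[str, str],
    correction: str = "bonferroni",
    condition_key: str = "condition",
    cell_type_key: str = "cell_type",
    min_cells: int = 3,
    correct_over_all_genes: bool = False,
) -> pd.DataFrame:
    """Per-gene rank-sum DE between two conditions within one cell type.

    ``contrast=(A, B)``: positive logFC means higher in A.  Genes tested are
    those expressed in at least one cell of the subset; the multiplicity
    count is the number of tested genes unless ``correct_over_all_genes``.
    Returns an empty table with a warning when either side has fewer than
    ``min_cells`` cells.  Exact enumeration is used when both sides have at
    most 12 cells.
    """
    sub = adata if cell_type is None else adata[adata.obs[cell_type_key] == cell_type]
    cond = sub.obs[condition_key].astype(str)
    a = _dense(sub[cond == contrast[0]].X)
    b = _dense(sub[cond == contrast[1]].X)
    if a.shape[0] < min_cells or b.shape[0] < min_cells:
        warnings.warn(
            f"wilcoxon_de: fewer than {min_cells} cells per side "
            f"({a.shape[0]} vs {b.shape[0]}); empty result"
        )
        return pd.DataFrame(columns=["logFC", "p", "p_adj", "comparison"])

    expressed = (np.abs(a).sum(axis=0) + np.abs(b).sum(axis=0)) > 0
    genes = np.asarray(sub.var_names)[expressed]
    aa, bb = a[:, expressed], b[:, expressed]

    if a.shape[0] <= EXACT_MAX_N and b.shape[0] <= EXACT_MAX_N:
        p = np.array([exact_ranksum_p(aa[:, j], bb[:, j]) for j in range(aa.shape[1])])
    else:
        p = _ranksum_asymptotic(aa, bb)
        # Constant pooled columns have undefined ranks; they carry no signal.
        const = np.all(aa == aa[:1], axis=0) & np.all(bb == bb[:1], axis=0) & np.all(
            aa[:1] == bb[:1], axis=0
        )
        p = np.where(const, 1.0, p)

    m = sub.n_vars if correct_over_all_genes else len(p)
    out = pd.DataFrame(
        {
            "logFC": _log_fold_change(aa, bb),
            "p": p,
            "p_adj": _adjust(p, correction, m),
            "comparison": f"{contrast[0]} vs {contrast[1]}"
            + (f" [{cell_type}]" if cell_type else ""),
        },
        index=pd.Index(genes, name="gene"),
    )
    return out


def find_markers(
    adata: ad.AnnData,
    cluster_key: str = "state",
    screen_logfc: float = 0.25,
    marker_logfc: float = 0.5,
    marker_p: float = 0.05,
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest cluster markers.

    Genes passing the ``screen_logfc`` natural-log prefilter (cluster vs rest)
    are rank-sum tested; markers are genes with logFC > ``marker_logfc`` and
    raw p < ``marker_p``.  Clusters with fewer than ``min_cells`` cells are
    skipped with a warning.
    """
    clusters = adata.obs[cluster_key].astype(str)
    X = _dense(adata.X)
    frames = []
    for cl in sorted(clusters.unique()):
        in_cl = (clusters == cl).to_numpy()
        if in_cl.sum() < min_cells or (~in_cl).sum() < min_cells:
            warnings.warn(f"cluster {cl!r} skipped: too few cells")
            continue
        a, b = X[in_cl], X[~in_cl]
        logfc = _log_fold_change(a, b)
        screened = np.where(logfc > screen_logfc)[0]
        if screened.size == 0:
            continue
        if a.shape[0] <= EXACT_MAX_N and b.shape[0] <= EXACT_MAX_N:
            p = np.array([exact_ranksum_p(a[:, j], b[:, j]) for j in screened])
        else:
            p = _ranksum_asymptotic(a[:, screened], b[:, screened])
        df = pd.DataFrame(
            {
                "cluster": cl,
                "gene": np.asarray(adata.var_names)[screened],
                "logFC": logfc[screened],
                "p": p,
            }
        )
        df["is_marker"] = (df["logFC"] > marker_logfc) & (df["p"] < marker_p)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["cluster", "gene", "logFC", "p", "is_marker"])
    return pd.concat(frames, ignore_index=True)


def pseudobulk_corr(sc_de: pd.DataFrame, protein_de: pd.DataFrame) -> dict[str, object]:
    """Pearson concordance of pseudobulk single-cell and protein fold changes.

    Inner-joins the two tables on identifier and correlates the logFC
    columns.  Fewer than 3 shared pairs yields NaN with a warning.
    """
    pairs = sc_de[["logFC"]].join(protein_de[["logFC"]], how="inner", lsuffix="_sc", rsuffix="_prot")
    pairs = pairs.dropna()
    if len(pairs) < 3:
        warnings.warn(f"pseudobulk_corr: only {len(pairs)} shared pairs")
        return {"r": float("nan"), "n_pairs": len(pairs), "pairs": pairs}
    r = float(np.corrcoef(pairs["logFC_sc"], pairs["logFC_prot"])[0, 1])
    return {"r": r, "n_pairs": len(pairs), "pairs": pairs}
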