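"""Microglial cell-state analysis: signature scoring, state assignment,
composition-shift testing, and pseudotime gene trends.

The module score of a gene set in a cell is the mean normalized expression of
the set minus the mean of expression-bin-matched control genes, the standard
guard against library-depth and expression-level confounding.  Cells are
assigned the state whose signature scores highest; condition-dependent shifts
in state composition are tested on the 2x2 state-vs-rest table with the
Pearson chi-squared statistic (1 df), optionally with a label-permutation p.
Pseudotime is an externally supplied scalar in [0, 1] per cell; trends are
sliding-window means on a shared grid so conditions can be overlaid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps

__all__ = [
    "module_score",
    "score_signatures",
    "assign_states",
    "composition_table",
    "composition_test",
    "pseudotime_trends",
]


def _dense(x) -> np.ndarray:
    return x.toarray() if sparse.issparse(x) else np.asarray(x)


def module_score(
    adata: ad.AnnData,
    signature: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    ctrl_pool: Sequence[str] | None = None,
) -> np.ndarray:
    """Binned-control module score of one gene set, per cell.

    Genes are ranked by mean normalized expression across cells and cut into
    ``n_bins`` equal-occupancy bins; for each signature gene, ``n_ctrl``
    control genes are sampled (with replacement when the bin is smaller) from
    its bin.  Score = mean over signature genes - mean over the control
    draw.  ``ctrl_pool`` overrides bin sampling with an explicit control set
    (e.g. the signature itself, which yields exactly zero).  Deterministic
    given ``seed``.
    """
    sig = [g for g in dict.fromkeys(signature) if g in adata.var_names]
    dropped = len(set(signature)) - len(sig)
    if dropped:
        warnings.warn(f"{dropped} signature genes absent from the data; dropped")
    if not sig:
        raise ValueError("signature empty after filtering to measured genes")
    X = _dense(adata.X)
    var_index = pd.Index(adata.var_names)
    sig_idx = var_index.get_indexer(sig)
    sig_mean = X[:, sig_idx].mean(axis=1)

    if ctrl_pool is not None:
        ctrl_idx = var_index.get_indexer([g for g in ctrl_pool if g in var_index])
        if len(ctrl_idx) == 0:
            raise ValueError("control pool empty after filtering")
        ctrl_mean = X[:, ctrl_idx].mean(axis=1)
        return sig_mean - ctrl_mean

    rng = np.random.default_rng(seed)
    gene_means = X.mean(axis=0)
    # Equal-occupancy bins on the rank of the mean (ties broken stably).
    order = np.argsort(gene_means, kind="stable")
    bin_of = np.empty(len(gene_means), dtype=int)
    bin_of[order] = np.minimum(
        (np.arange(len(gene_means)) * n_bins) // len(gene_means), n_bins - 1
    )
    members: dict[int, np.ndarray] = {
        b: np.where(bin_of == b)[0] for b in np.unique(bin_of)
    }
    ctrl_cols: list[np.ndarray] = []
    for gi in sig_idx:
        pool = members[bin_of[gi]]
        replace = len(pool) < n_ctrl
        ctrl_cols.append(rng.choice(pool, size=n_ctrl, replace=replace))
    ctrl_idx = np.concatenate(ctrl_cols)
    ctrl_mean = X[:, ctrl_idx].mean(axis=1)
    return sig_mean - ctrl_mean


def score_signatures(
    adata: ad.AnnData,
    signatures: Mapping[str, Sequence[str]],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every signature; returns a cells x signatures frame."""
    cols = {
        name: module_score(adata, genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
        for name, genes in signatures.items()
    }
    return pd.DataFrame(cols, index=adata.obs_names)


def assign_states(scores: pd.DataFrame) -> pd.DataFrame:
    """Assign each cell the argmax-scoring state.

    Ties are broken deterministically by lexicographic signature name and
    flagged.  Returns state, margin (top minus second score), and tie flag.
    """
    if scores.shape[1] < 1:
        raise ValueError("need at least one signature column")
    ordered = scores[sorted(scores.columns)]
    vals = ordered.to_numpy(dtype=float)
    top_idx = np.argmax(vals, axis=1)
    top = vals[np.arange(len(vals)), top_idx]
    tie = (vals == top[:, None]).sum(axis=1) > 1
    if vals.shape[1] > 1:
        part = np.partition(vals, -2, axis=1)
        margin = top - part[:, -2]
    else:
        margin = np.full(len(vals), np.nan)
    return pd.DataFrame(
        {
            "state": np.asarray(ordered.columns)[top_idx],
            "margin": margin,
            "tie": tie,
        },
        index=scores.index,
    )


def composition_table(
    assignments: Sequence[str], conditions: Sequence[str]
) -> pd.DataFrame:
    """Per condition x state raw counts and within-condition fractions."""
    df = pd.DataFrame({"state": list(assignments), "condition": list(conditions)})
    counts = df.groupby(["condition", "state"]).size().unstack(fill_value=0)
    fracs = counts.div(counts.sum(axis=1), axis=0)
    out = pd.concat({"count": counts, "fraction": fracs}, axis=1)
    return out


def composition_test(
    assignments: Sequence[str],
    conditions: Sequence[str],
    state: str,
    n_perm: int = 0,
    seed: int = 0,
) -> dict[str, object]:
    """Chi-squared test of a state's proportion shift between two conditions.

    Builds the 2x2 table (state vs all other states, by condition) and
    computes the Pearson chi-squared statistic N(ad-bc)^2 /
    ((a+b)(c+d)(a+c)(b+d)) with its 1-df asymptotic p (no continuity
    correction).  ``n_perm`` > 0 adds a permutation p from condition-label
    shuffles.  A zero margin yields NaN with a warning.
    """
    states = np.asarray(assignments, dtype=object)
    conds = np.asarray(conditions, dtype=object)
    cond_names = list(dict.fromkeys(conds))
    if len(cond_names) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {cond_names}")
    in_state = states == state

    def chi2_of(in_state_vec: np.ndarray) -> float:
        a = int(np.sum(in_state_vec & (conds == cond_names[0])))
        b = int(np.sum(~in_state_vec & (conds == cond_names[0])))
        c = int(np.sum(in_state_vec & (conds == cond_names[1])))
        d = int(np.sum(~in_state_vec & (conds == cond_names[1])))
        n = a + b + c + d
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        if denom == 0:
            return np.nan
        return n * (a * d - b * c) ** 2 / denom

    chi2 = chi2_of(in_state)
    if np.isnan(chi2):
        warnings.warn("composition_test: zero margin in the 2x2 table")
        p = np.nan
    else:
        p = float(sps.chi2.sf(chi2, df=1))
    result: dict[str, object] = {
        "state": state,
        "chi2": float(chi2) if not np.isnan(chi2) else np.nan,
        "p": p,
        "table": composition_table(assignments, conditions),
    }
    if n_perm > 0 and not np.isnan(chi2):
        rng = np.random.default_rng(seed)
        exceed = 0
        shuffled = in_state.copy()
        for _ in range(n_perm):
            rng.shuffle(shuffled)
            if chi2_of(shuffled) >= chi2 - 1e-12:
                exceed += 1
        result["p_perm"] = (exceed + 1) / (n_perm + 1)
    return result


def pseudotime_trends(
    adata: ad.AnnData,
    pseudotime: pd.Series,
    genes: Sequence[str],
    condition_key: str = "condition",
    n_windows: int = 50,
    min_cells_per_window: int = 5,
    min_cells_per_condition: int = 20,
) -> dict[str, object]:
    """Sliding-window gene-expression trends over pseudotime, per condition.

    ``pseudotime`` is an externally computed scalar in [0, 1] per cell.  On a
    shared grid of ``n_windows`` centers, each condition's curve is the mean
    normalized expression of cells whose pseudotime falls within the window
    (half-width one grid step, so windows overlap).  Windows with fewer than
    ``min_cells_per_window`` cells are linearly interpolated from their
    neighbors and flagged.  Genes absent from the data are skipped with a
    warning.
    """
    pt = pseudotime.reindex(adata.obs_names).to_numpy(dtype=float)
    if np.isnan(pt).any():
        raise ValueError("pseudotime missing for some cells")
    if pt.min() < 0 or pt.max() > 1:
        raise ValueError("pseudotime must lie in [0, 1]")
    present = [g for g in genes if g in adata.var_names]
    for g in genes:
        if g not in adata.var_names:
            warnings.warn(f"gene {g!r} absent; skipped")
    grid = (np.arange(n_windows) + 0.5) / n_windows
    half = 1.0 / n_windows
    X = _dense(adata[:, present].X)
    conds = adata.obs[condition_key].astype(str)

    curves: dict[tuple[str, str], np.ndarray] = {}
    flags: dict[str, np.ndarray] = {}
    for cond in dict.fromkeys(conds):
        in_cond = (conds == cond).to_numpy()
        if in_cond.sum() < min_cells_per_condition:
            raise ValueError(
                f"condition {cond!r} has {int(in_cond.sum())} cells; "
                f"need >= {min_cells_per_condition}"
            )
        tc = pt[in_cond]
        Xc = X[in_cond]
        means = np.full((n_windows, len(present)), np.nan)
        n_in = np.zeros(n_windows, dtype=int)
        for w, center in enumerate(grid):
            sel = np.abs(tc - center) <= half + 1e-12
            n_in[w] = int(sel.sum())
            if n_in[w] > 0:
                means[w] = Xc[sel].mean(axis=0)
        sparse_w = n_in < min_cells_per_window
        flags[cond] = sparse_w
        for j, g in enumerate(present):
            col = means[:, j]
            ok = ~sparse_w & ~np.isnan(col)
            if ok.sum() >= 2:
                col = np.interp(grid, grid[ok], col[ok])
            curves[(g, cond)] = col
    return {"grid": grid, "curves": curves, "sparse_windows": flags, "genes": present}
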