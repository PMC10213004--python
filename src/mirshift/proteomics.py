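"""Bulk proteome preprocessing and differential expression.

The workflow mirrors standard label-free DIA downstream analysis: proteins
quantified in at least 75% of the samples of every experimental group are
retained, sample columns are scaled to reads-per-million (non-missing sum =
1e6), intensities are log2(RPM+1)-transformed, and per-protein two-group
contrasts are tested either with Welch's t or with an empirical-Bayes
moderated t in which per-protein variances are shrunk toward a pooled prior.

The prior (d0, s0^2) is estimated by the method of moments on the log sample
variances: for s^2 ~ s0^2 * chi2_d / d scaled, log s^2 has variance
trigamma(d/2) + trigamma(d0/2), which is inverted numerically for d0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps

from .stats import bh_adjust

__all__ = ["AbundanceMatrix", "preprocess", "protein_de", "read_abundance_tsv", "write_abundance_tsv"]


@dataclass
class AbundanceMatrix:
    """Proteins x samples intensities with per-sample group/cohort labels.

    Missing quantifications are NaN (never zero: a zero is an observed value,
    a NaN is an absent one, and the presence filter counts only the latter
    as unobserved).
    """

    values: pd.DataFrame  # proteins x samples, NaN = missing
    groups: pd.Series  # sample -> group label, e.g. control/perturbed
    cohorts: pd.Series | None = None

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups).reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.values.columns[self.groups.isna()])
            raise ValueError(f"samples without group label: {missing}")

    def drop_samples(self, samples: Sequence[str]) -> "AbundanceMatrix":
        """Exclude samples (e.g. PCA outliers); exclusion is a caller decision."""
        keep = [c for c in self.values.columns if c not in set(samples)]
        return AbundanceMatrix(
            self.values[keep],
            self.groups[keep],
            None if self.cohorts is None else self.cohorts[keep],
        )


def preprocess(matrix: AbundanceMatrix, min_presence: float = 0.75) -> AbundanceMatrix:
    """Presence-filter proteins, then RPM-normalize each sample column.

    A protein is retained only if observed (non-NaN) in at least
    ``min_presence`` of the samples of EVERY group.  Each surviving column is
    then scaled so its non-NaN sum equals 1e6.
    """
    vals = matrix.values
    keep = pd.Series(True, index=vals.index)
    for group, cols in matrix.groups.groupby(matrix.groups).groups.items():
        sub = vals[list(cols)]
        if sub.shape[1] == 0:
            raise ValueError(f"group {group!r} has zero samples")
        keep &= sub.notna().mean(axis=1) >= min_presence
    vals = vals.loc[keep]
    colsum = vals.sum(axis=0, skipna=True)
    if (colsum <= 0).any():
        bad = list(colsum.index[colsum <= 0])
        raise ValueError(f"samples with non-positive total intensity: {bad}")
    vals = vals * (1e6 / colsum)
    return AbundanceMatrix(vals, matrix.groups, matrix.cohorts)


def _fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on log sample variances."""
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return np.inf, float(np.nanmean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    d = df[ok]
    e = z - special.digamma(d / 2) + np.log(d / 2)
    mean_e = float(np.mean(e))
    # Var(z) about its expectation, corrected for the per-protein chi2 part.
    excess = float(np.mean((e - mean_e) ** 2 * len(e) / (len(e) - 1) - special.polygamma(1, d / 2)))
    if excess <= 0:
        return np.inf, float(np.exp(mean_e))
    # Solve trigamma(d0/2) = excess for d0.
    f = lambda d0: special.polygamma(1, d0 / 2) - excess
    lo, hi = 1e-6, 1e6
    if f(lo) < 0:  # even tiny d0 cannot produce this much spread
        d0 = lo
    elif f(hi) > 0:
        return np.inf, float(np.exp(mean_e))
    else:
        d0 = float(optimize.brentq(f, lo, hi))
    s0_sq = float(np.exp(mean_e + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0_sq


def protein_de(
    matrix: AbundanceMatrix,
    method: str = "moderated",
    perturbed: str | None = None,
    log_offset: float = 1.0,
) -> pd.DataFrame:
    """Two-group differential abundance on log2(RPM + offset) values.

    Returns per protein: log2FC (perturbed minus control group mean,
    NA-aware), t statistic, raw p, and BH-adjusted p.  ``method`` is
    ``"moderated"`` (variance shrinkage toward a pooled prior, t with
    augmented degrees of freedom) or ``"welch"``.  Proteins with fewer than
    two observed values in either group get NaN statistics and are excluded
    from the BH multiplicity count.
    """
    if method not in {"moderated", "welch"}:
        raise ValueError(f"unknown method {method!r}")
    group_names = list(dict.fromkeys(matrix.groups))
    if len(group_names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {group_names}")
    if perturbed is None:
        # Convention: the non-"control"-like label is the perturbed side.
        lowered = [g.lower() for g in group_names]
        ctrl_idx = lowered.index("control") if "control" in lowered else 1
        perturbed = group_names[1 - ctrl_idx]
    control = next(g for g in group_names if g != perturbed)

    log_vals = np.log2(matrix.values + log_offset)
    a = log_vals[matrix.groups.index[matrix.groups == perturbed]].to_numpy()
    b = log_vals[matrix.groups.index[matrix.groups == control]].to_numpy()

    na_count = np.sum(~np.isnan(a), axis=1).astype(float)
    nb_count = np.sum(~np.isnan(b), axis=1).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma, mb = np.nanmean(a, axis=1), np.nanmean(b, axis=1)
        va = np.nanvar(a, axis=1, ddof=1)
        vb = np.nanvar(b, axis=1, ddof=1)
    logfc = ma - mb
    testable = (na_count >= 2) & (nb_count >= 2)

    t = np.full(len(logfc), np.nan)
    p = np.full(len(logfc), np.nan)
    if method == "welch":
        se2 = va / na_count + vb / nb_count
        with np.errstate(divide="ignore", invalid="ignore"):
            tt = logfc / np.sqrt(se2)
            dfw = se2**2 / (
                (va / na_count) ** 2 / (na_count - 1) + (vb / nb_count) ** 2 / (nb_count - 1)
            )
        t[testable] = tt[testable]
        p[testable] = 2 * sps.t.sf(np.abs(tt[testable]), dfw[testable])
    else:
        df_resid = na_count + nb_count - 2
        pooled = np.where(
            df_resid > 0,
            ((na_count - 1) * va + (nb_count - 1) * vb) / np.maximum(df_resid, 1),
            np.nan,
        )
        d0, s0_sq = _fit_variance_prior(pooled[testable], df_resid[testable])
        if np.isinf(d0):
            post = np.full_like(pooled, s0_sq)
            df_total = np.full_like(pooled, np.inf)
        else:
            post = (d0 * s0_sq + df_resid * pooled) / (d0 + df_resid)
            df_total = df_resid + d0
        with np.errstate(divide="ignore", invalid="ignore"):
            tt = logfc / np.sqrt(post * (1 / na_count + 1 / nb_count))
        t[testable] = tt[testable]
        p[testable] = 2 * sps.t.sf(np.abs(tt[testable]), df_total[testable])

    # Zero-variance degenerate case: identical values on both sides.
    both_zero = testable & (va == 0) & (vb == 0) & (logfc == 0)
    t[both_zero] = 0.0
    p[both_zero] = 1.0

    out = pd.DataFrame(
        {"logFC": logfc, "t": t, "p": np.clip(p, 0, 1)}, index=matrix.values.index
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out.attrs["contrast"] = f"{perturbed} - {control}"
    return out


def read_abundance_tsv(path) -> AbundanceMatrix:
    """Read a proteins x samples TSV with a two-row header (group, cohort)."""
    raw = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
    samples = [c[0] for c in raw.columns]
    groups = pd.Series([c[1].split("|")[0] for c in raw.columns], index=samples)
    cohorts = pd.Series(
        [c[1].split("|")[1] if "|" in c[1] else "" for c in raw.columns], index=samples
    )
    raw.columns = samples
    return AbundanceMatrix(raw, groups, cohorts)


def write_abundance_tsv(matrix: AbundanceMatrix, path) -> None:
    df = matrix.values.copy()
    cohorts = matrix.cohorts if matrix.cohorts is not None else pd.Series("", index=df.columns)
    df.columns = pd.MultiIndex.from_arrays(
        [df.columns, [f"{matrix.groups[c]}|{cohorts[c]}" for c in df.columns]]
    )
    df.to_csv(path, sep="\t")
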