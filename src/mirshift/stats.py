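"""Set-enrichment testing, multiplicity adjustment, and qPCR fold changes.

Enrichment follows the classic one-sided Fisher/hypergeometric scheme with an
FDR cut and a minimum overlap-fraction filter; relative qPCR quantification
uses the ddCt method (fold change = 2^-ddCt) with the arithmetic mean of
housekeeping Cts as the per-sample normalizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_gmt",
    "write_gmt",
    "bh_adjust",
    "fisher_enrichment",
    "ddct",
    "group_similar_sets",
]


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file into ``{set_name: [genes...]}`` (description dropped)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, NA-aware.

    NaN entries are excluded from the multiplicity count m and returned as
    NaN; adjusted values are clipped at 1 and monotone along the p-ranking.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class EnrichmentInput:
    """Query gene list, background universe, and named annotation sets."""

    query: Sequence[str]
    annotations: Mapping[str, Sequence[str]]
    universe: Sequence[str] | None = None

    def resolved_universe(self) -> set[str]:
        # Default background: all annotated genes plus the query itself.
        if self.universe is not None:
            return set(self.universe)
        uni: set[str] = set(self.query)
        for genes in self.annotations.values():
            uni.update(genes)
        return uni


def fisher_enrichment(
    inp: EnrichmentInput,
    alpha: float = 0.05,
    min_frac: float = 0.01,
    top_n: int = 20,
) -> pd.DataFrame:
    """One-sided enrichment of a query list against annotation sets.

    For each set the 2x2 table (in-set vs out, in-query vs out over the
    universe) is tested with the hypergeometric upper tail P(X >= overlap);
    p-values are BH-adjusted across sets.  A set passes when adjusted p <
    ``alpha`` and the overlap is at least ``min_frac`` of the query.  Results
    are ranked by raw p; the top ``top_n`` rows are returned.
    """
    universe = inp.resolved_universe()
    query = set(inp.query)
    if not query <= universe:
        missing = sorted(query - universe)[:5]
        raise ValueError(f"query genes missing from universe, e.g. {missing}")
    N, n = len(universe), len(query)
    rows = []
    for name, genes in inp.annotations.items():
        members = set(genes) & universe
        K = len(members)
        k = len(members & query)
        # Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append(
            {
                "set": name,
                "set_size": K,
                "overlap": k,
                "overlap_frac": k / n if n else 0.0,
                "p": min(p, 1.0),
            }
        )
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    res["p_adj"] = bh_adjust(res["p"].to_numpy())
    res["pass"] = (res["p_adj"] < alpha) & (res["overlap_frac"] >= min_frac)
    res = res.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    return res.head(top_n)


@dataclass
class CtTable:
    """Long-format qPCR table: one row per (sample, gene) with its Ct.

    ``groups`` maps each sample to its experimental group; ``housekeeping``
    lists the reference genes whose mean Ct normalizes each sample.
    """

    data: pd.DataFrame  # columns: sample, gene, ct
    housekeeping: Sequence[str]
    groups: Mapping[str, str] = field(default_factory=dict)


def ddct(
    ct: CtTable,
    gene: str,
    treated: str,
    calibrator: str,
) -> dict[str, object]:
    """ddCt relative quantification for one gene.

    Per sample, dCt = Ct(gene) - mean Ct(housekeeping); ddCt = mean
    dCt(treated) - mean dCt(calibrator); fold change = 2^-ddCt.  Samples
    missing the gene or any housekeeping measurement are dropped with a
    warning.  Per-sample folds (each sample's dCt against the calibrator mean
    dCt) are returned for dispersion estimates.
    """
    df = ct.data
    hk = list(ct.housekeeping)
    dct: dict[str, float] = {}
    for sample, sub in df.groupby("sample"):
        by_gene = sub.set_index("gene")["ct"]
        if gene not in by_gene.index or any(h not in by_gene.index for h in hk):
            warnings.warn(f"sample {sample!r} dropped: missing gene or housekeeping Ct")
            continue
        dct[sample] = float(by_gene[gene] - by_gene[hk].mean())
    t_samples = [s for s in dct if ct.groups.get(s) == treated]
    c_samples = [s for s in dct if ct.groups.get(s) == calibrator]
    if not t_samples or not c_samples:
        raise ValueError("treated or calibrator group has no usable samples")
    ddct_val = float(np.mean([dct[s] for s in t_samples]) - np.mean([dct[s] for s in c_samples]))
    cal_mean = float(np.mean([dct[s] for s in c_samples]))
    per_sample = {s: 2.0 ** (-(dct[s] - cal_mean)) for s in t_samples + c_samples}
    return {
        "gene": gene,
        "ddct": ddct_val,
        "fold_change": 2.0**-ddct_val,
        "per_sample_fold": per_sample,
        "n_treated": len(t_samples),
        "n_calibrator": len(c_samples),
    }


def group_similar_sets(
    sets: Mapping[str, Sequence[str]], threshold: float = 0.5
) -> list[list[str]]:
    """Convenience grouping of annotation sets by Jaccard similarity.

    Single-linkage groups of sets whose pairwise Jaccard index exceeds
    ``threshold``.  This is an automated stand-in for manual curation of
    redundant pathways and is labelled as such; it is not part of the core
    selection cascade.
    """
    names = list(sets)
    parent = {n: n for n in names}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(names):
        sa = set(sets[a])
        for b in names[i + 1 :]:
            sb = set(sets[b])
            denom = len(sa | sb)
            if denom and len(sa & sb) / denom > threshold:
                parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for n in names:
        groups.setdefault(find(n), []).append(n)
    return sorted(groups.values(), key=lambda g: g[0])
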