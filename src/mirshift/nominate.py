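"""Multi-omic miRNA target nomination.

The cascade: (1) predicted targets = genes flagged by at least
``min_predictors`` of seven prediction algorithms AND supported by at least
``min_clip`` AGO-CLIP experiments; (2) per perturbation dataset, the top
fraction of features anticorrelated with the miRNA change (top 5% upregulated
proteins under knockdown, top 5% downregulated under overexpression, or
significant anticorrelated single-cell DEGs); (3) putative targets = the
intersection of (1) and (2); (4) bookkeeping of per-dataset sets, their union
and cross-omic intersections; (5) cell-type expression summaries of the
nominated genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PREDICTOR_COLUMNS",
    "select_predicted",
    "top_fraction",
    "select_sc_anticorrelated",
    "nominate",
    "overlap_summary",
    "annotate_celltypes",
    "recovery_metrics",
]

PREDICTOR_COLUMNS = tuple(f"pred_{i}" for i in range(1, 8))


def select_predicted(
    evidence: pd.DataFrame,
    min_predictors: int = 2,
    min_clip: int = 3,
    predictor_columns: Sequence[str] = PREDICTOR_COLUMNS,
) -> set[str]:
    """Predicted-target selection: >= min_predictors algorithm hits AND
    >= min_clip supporting CLIP experiments.

    ``evidence`` is indexed by gene with boolean predictor columns and an
    integer ``clip_evidence`` column.
    """
    if not 1 <= min_predictors <= len(predictor_columns):
        raise ValueError("min_predictors out of range")
    missing = [c for c in [*predictor_columns, "clip_evidence"] if c not in evidence.columns]
    if missing:
        raise ValueError(f"evidence table missing columns: {missing}")
    n_hits = evidence[list(predictor_columns)].astype(bool).sum(axis=1)
    mask = (n_hits >= min_predictors) & (evidence["clip_evidence"] >= min_clip)
    return set(evidence.index[mask])


def top_fraction(
    ranked: pd.DataFrame,
    q: float = 0.05,
    direction: str = "up",
    metric: str = "logFC",
) -> set[str]:
    """Top-fraction selection: the ceil(q*N) most up/down features by logFC.

    Boundary ties are broken by smaller p, then lexicographic identifier, so
    the selected set is deterministic.  An empty table yields an empty set
    with a warning.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if direction not in {"up", "down"}:
        raise ValueError("direction must be 'up' or 'down'")
    if ranked.empty:
        warnings.warn("top_fraction: empty feature table")
        return set()
    if metric not in ranked.columns:
        raise ValueError(f"ranking metric column {metric!r} absent")
    k = math.ceil(q * len(ranked))
    df = ranked.copy()
    df["_id"] = df.index.astype(str)
    df["_p"] = df["p"] if "p" in df.columns else 0.0
    ascending = direction == "down"
    df = df.sort_values([metric, "_p", "_id"], ascending=[ascending, True, True], kind="mergesort")
    return set(df.index[:k])


def select_sc_anticorrelated(
    de: pd.DataFrame,
    perturbation: str,
    alpha: float = 0.05,
) -> set[str]:
    """Significant single-cell DEGs anticorrelated with the miRNA change.

    Under knockdown (miRNA down) anticorrelated targets go up (logFC > 0);
    under overexpression they go down.  Selection: adjusted p < alpha and the
    anticorrelated sign.
    """
    if perturbation not in {"KD", "OE"}:
        raise ValueError("perturbation must be 'KD' or 'OE'")
    sign = 1 if perturbation == "KD" else -1
    mask = (de["p_adj"] < alpha) & (np.sign(de["logFC"]) == sign)
    return set(de.index[mask])


def nominate(selected: set[str], predicted: set[str]) -> set[str]:
    """Putative targets: dataset-selected features that are also predicted."""
    return set(selected) & set(predicted)


@dataclass
class NominationResult:
    """Cross-dataset bookkeeping of putative-target sets."""

    per_dataset: dict[str, set[str]]
    union: set[str]
    membership: pd.DataFrame  # union genes x datasets, boolean
    pairwise: pd.DataFrame  # datasets x datasets intersection sizes
    proteomics_transcriptomics_common: set[str]


def overlap_summary(per_dataset: Mapping[str, set[str]]) -> NominationResult:
    """Union, membership matrix, pairwise intersections, and the cross-omic
    common set between the proteomic (prot_*) and transcriptomic (sc_*)
    dataset unions."""
    if len(per_dataset) < 2:
        raise ValueError("need at least two datasets")
    names = list(per_dataset)
    union = set().union(*per_dataset.values())
    genes = sorted(union)
    membership = pd.DataFrame(
        {n: [g in per_dataset[n] for g in genes] for n in names}, index=genes
    )
    pairwise = pd.DataFrame(
        [[len(per_dataset[a] & per_dataset[b]) for b in names] for a in names],
        index=names,
        columns=names,
    )
    prot = set().union(*(s for n, s in per_dataset.items() if n.startswith("prot")), set())
    sc = set().union(*(s for n, s in per_dataset.items() if n.startswith("sc")), set())
    return NominationResult(
        per_dataset={n: set(s) for n, s in per_dataset.items()},
        union=union,
        membership=membership,
        pairwise=pairwise,
        proteomics_transcriptomics_common=prot & sc,
    )


def annotate_celltypes(
    genes: Sequence[str],
    annotations: Mapping[str, Sequence[str]],
) -> pd.Series:
    """Cell-type expression percentages for a gene set.

    ``annotations`` maps gene -> list of cell-type labels (multi-label
    allowed); unannotated genes fall into an ``"unknown"`` bucket.  Each
    (gene, label) assignment contributes one unit; the returned percentages
    sum to 100.
    """
    counts: dict[str, int] = {}
    for g in genes:
        labels = list(annotations.get(g, [])) or ["unknown"]
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return pd.Series(dtype=float)
    return pd.Series({k: 100.0 * v / total for k, v in sorted(counts.items())})


def recovery_metrics(nominated: set[str], truth: set[str]) -> dict[str, float]:
    """Recall and precision of a nominated set against planted truth."""
    tp = len(nominated & truth)
    recall = tp / len(truth) if truth else math.nan
    precision = tp / len(nominated) if nominated else math.nan
    return {"recall": recall, "precision": precision, "tp": float(tp)}
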