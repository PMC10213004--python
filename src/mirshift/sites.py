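"""Canonical miRNA seed-match sites: pattern derivation, UTR scanning, census.

A mature miRNA's seed (nucleotides 2-7, extended to 2-8) defines four
canonical 3'UTR site classes on the target strand:

* ``6mer``    — Watson-Crick match to positions 2-7
* ``7mer-A1`` — 6mer followed by an A opposite miRNA position 1
* ``7mer-m8`` — match to positions 2-8
* ``8mer``   — 7mer-m8 followed by the A1 adenosine

All site strings are reported 5'→3' on the target (sense) strand in the RNA
alphabet.  Scanning classifies every locus by its most specific type: an 8mer
is reported once as an 8mer, never additionally as the 7mers and 6mer it
contains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SITE_TYPES",
    "MirnaSequence",
    "SiteHit",
    "seed_patterns",
    "scan_sequences",
    "summarize_census",
]

#: Site classes ordered by precedence, most specific first.
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}


@dataclass(frozen=True)
class MirnaSequence:
    """A mature miRNA, 5'→3', RNA alphabet.

    Raises ``ValueError`` if shorter than 8 nt (positions 1-8 are needed to
    derive the canonical site strings) or if the alphabet is not A/C/G/U.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 8:
            raise ValueError(
                f"miRNA {self.name!r} is {len(seq)} nt; at least 8 required"
            )
        bad = set(seq) - set("ACGU")
        if bad:
            raise ValueError(f"non-RNA characters in miRNA {self.name!r}: {sorted(bad)}")


@dataclass(frozen=True)
class SiteHit:
    """One classified seed-match occurrence: 1-based inclusive start on the UTR."""

    utr_id: str
    start: int
    site_type: str

    @property
    def length(self) -> int:
        return {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}[self.site_type]

    @property
    def end(self) -> int:
        """1-based inclusive end."""
        return self.start + self.length - 1


def _revcomp_rna(seq: str) -> str:
    return "".join(_RNA_COMPLEMENT[b] for b in reversed(seq))


def seed_patterns(mirna: MirnaSequence) -> dict[str, str]:
    """Derive the four canonical target-strand site strings for a miRNA.

    6mer = revcomp(positions 2-7); 7mer-m8 = revcomp(2-8);
    7mer-A1 = 6mer + "A"; 8mer = 7mer-m8 + "A".  Returned in RNA alphabet,
    5'→3' on the target strand, keyed by site type.
    """
    seq = mirna.sequence
    six = _revcomp_rna(seq[1:7])
    sevm8 = _revcomp_rna(seq[1:8])
    return {
        "8mer": sevm8 + "A",
        "7mer-m8": sevm8,
        "7mer-A1": six + "A",
        "6mer": six,
    }


def _normalize_utr(seq: str, utr_id: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGUN")
    if bad:
        raise ValueError(f"UTR {utr_id!r} contains non-nucleotide characters: {sorted(bad)}")
    return s


def scan_sequences(
    utrs: Iterable[tuple[str, str]] | Mapping[str, str],
    patterns: Mapping[str, str],
) -> list[SiteHit]:
    """Scan UTR sequences for canonical seed sites with precedence.

    ``utrs`` is a mapping or iterable of ``(utr_id, sequence)``; DNA input is
    mapped T→U before matching and N never matches.  Every maximal site is
    reported exactly once with its most specific type (8mer > 7mer-m8 >
    7mer-A1 > 6mer): a candidate whose interval is contained in an
    already-reported hit's interval is suppressed.  Distinct sites may still
    overlap partially.
    """
    if isinstance(utrs, Mapping):
        items = utrs.items()
    else:
        items = utrs
    pats = {t: patterns[t].upper().replace("T", "U") for t in SITE_TYPES if t in patterns}

    hits: list[SiteHit] = []
    for utr_id, raw in items:
        seq = _normalize_utr(raw, utr_id)
        accepted: list[tuple[int, int]] = []  # 0-based [start, end) intervals
        for site_type in SITE_TYPES:
            pat = pats.get(site_type)
            if pat is None:
                continue
            k = len(pat)
            pos = seq.find(pat)
            while pos != -1:
                iv = (pos, pos + k)
                if not any(a <= iv[0] and iv[1] <= b for a, b in accepted):
                    accepted.append(iv)
                    hits.append(SiteHit(utr_id=utr_id, start=pos + 1, site_type=site_type))
                pos = seq.find(pat, pos + 1)
    hits.sort(key=lambda h: (h.utr_id, h.start, SITE_TYPES.index(h.site_type)))
    return hits


def hits_to_frame(hits: Sequence[SiteHit]) -> pd.DataFrame:
    """Tabulate hits as a TSV-ready frame (utr_id, start, type)."""
    return pd.DataFrame(
        {
            "utr_id": [h.utr_id for h in hits],
            "start": [h.start for h in hits],
            "type": [h.site_type for h in hits],
        }
    )


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    n = len(values)
    if n == 0:
        return (math.nan, math.nan)
    mean = float(np.mean(values))
    sem = float(np.std(values, ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    return mean, sem


def summarize_census(
    hits: Sequence[SiteHit],
    target_groups: Mapping[str, str],
) -> pd.DataFrame:
    """Per-group binding-site census: total sites per target and type mix.

    Every target in ``target_groups`` contributes, including targets with no
    hits (they count as total 0 but are excluded from the type-proportion
    averages, which are undefined for them).  Returns one row per group with
    the group size, mean ± SEM of total sites per target, and mean ± SEM of
    the per-target proportion of each site type.  Empty groups yield NA.
    """
    per_target: dict[str, dict[str, int]] = {t: {s: 0 for s in SITE_TYPES} for t in target_groups}
    for h in hits:
        if h.utr_id in per_target:
            per_target[h.utr_id][h.site_type] += 1

    rows = []
    for group in dict.fromkeys(target_groups.values()):
        members = [t for t, g in target_groups.items() if g == group]
        totals = np.array([sum(per_target[t].values()) for t in members], dtype=float)
        mean_total, sem_total = _mean_sem(totals)
        row: dict[str, object] = {
            "group": group,
            "n_targets": len(members),
            "total_mean": mean_total,
            "total_sem": sem_total,
        }
        with_sites = [t for t in members if sum(per_target[t].values()) > 0]
        for s in SITE_TYPES:
            if with_sites:
                props = np.array(
                    [per_target[t][s] / sum(per_target[t].values()) for t in with_sites]
                )
                m, sem = _mean_sem(props)
            else:
                m, sem = math.nan, math.nan
            row[f"prop_{s}_mean"] = m
            row[f"prop_{s}_sem"] = sem
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
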