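"""Synthetic multi-omic data with planted ground truth.

Generates every input the nomination/census/cell-state pipeline consumes —
3'UTRs with planted seed-match sites, predictor/CLIP evidence tables,
perturbation proteomes, and negative-binomial single-cell counts over
discrete cell states — so each stage can be tested against a known truth
without any external download.

Randomness discipline: one integer seed drives an independent, counter-based
RNG stream per artifact type (targets, UTRs, evidence, proteome, cells), so
e.g. enlarging the UTR set does not perturb the cell simulation.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import io as sio
from scipy import sparse

from .sites import MirnaSequence, seed_patterns
from .stats import write_gmt

__all__ = [
    "MIR132_3P",
    "SimConfig",
    "TruthBundle",
    "gen_utrs",
    "gen_evidence",
    "gen_proteome",
    "gen_sc",
    "write_fixture_bundle",
]

#: mmu-miR-132-3p (MIMAT0000426), the default simulated miRNA.
MIR132_3P = MirnaSequence(name="mmu-miR-132-3p", sequence="UAACAGUCUACAGCCAUGGUCG")

_STREAMS = {"targets": 0, "utrs": 1, "evidence": 2, "proteome": 3, "sc": 4}


@dataclass
class SimConfig:
    """Study-scale simulation parameters.

    Defaults mirror the simulated study conditions: a 2,000-gene universe
    with 50 true targets repressed by one log2 unit, seven predictors at 0.9
    sensitivity / 0.95 specificity, CLIP support Poisson(6) for true targets
    vs Poisson(0.5) otherwise, 10 proteome samples per group at residual SD
    0.5, and 1,500 cells per condition across three microglial states whose
    DAM fraction doubles (10% -> 20%) under perturbation.
    """

    seed: int = 0
    # UTRs
    n_utrs: int = 100
    utr_len: int = 500
    gc: float = 0.45
    planted_sites: dict[str, int] = field(default_factory=lambda: {"8mer": 1, "7mer-m8": 1})
    # gene universe / evidence
    n_genes: int = 2000
    n_true_targets: int = 50
    predictor_sens: float = 0.9
    predictor_spec: float = 0.95
    n_predictors: int = 7
    clip_lambda_true: float = 6.0
    clip_lambda_false: float = 0.5
    # proteome
    n_samples_per_group: int = 10
    repression_log2: float = 1.0
    proteome_sd: float = 0.5
    # single cell
    n_cells_per_condition: int = 1500
    states: tuple[str, ...] = ("homeostatic", "DAM", "IRM")
    state_props: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "CTRL": (0.8, 0.1, 0.1),
            "KD": (0.7, 0.2, 0.1),
            "OE": (0.7, 0.2, 0.1),
        }
    )
    n_program_genes: int = 50
    program_strength: float = 2.0
    nb_dispersion: float = 0.3
    libsize_log_mean: float = 8.0
    libsize_log_sd: float = 0.3
    mito_frac_range: tuple[float, float] = (0.01, 0.10)

    def __post_init__(self) -> None:
        for name in (
            "n_utrs",
            "utr_len",
            "n_genes",
            "n_true_targets",
            "n_predictors",
            "n_samples_per_group",
            "n_cells_per_condition",
            "n_program_genes",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("gc", "predictor_sens", "predictor_spec"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_true_targets > self.n_utrs or self.n_utrs > self.n_genes:
            raise ValueError("need n_true_targets <= n_utrs <= n_genes")
        for cond, props in self.state_props.items():
            if len(props) != len(self.states):
                raise ValueError(f"state_props[{cond!r}] length != number of states")
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError(f"state_props[{cond!r}] must sum to 1")

    def rng(self, artifact: str, subkey: str | None = None) -> np.random.Generator:
        """Independent stream per artifact type (and optional sub-key)."""
        key = [_STREAMS[artifact]]
        if subkey is not None:
            key.append(zlib.crc32(subkey.encode()) % 2**31)
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=tuple(key))
        return np.random.default_rng(ss)

    @property
    def genes(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]


@dataclass
class TruthBundle:
    """Planted ground truth: what the pipeline should recover."""

    true_target_ids: set[str] = field(default_factory=set)
    planted_site_table: dict[str, dict[str, int]] = field(default_factory=dict)
    planted_site_positions: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)
    true_state_labels: dict[str, list[str]] = field(default_factory=dict)
    planted_effects: dict[str, float] = field(default_factory=dict)
    state_programs: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "true_target_ids": sorted(self.true_target_ids),
            "planted_site_table": self.planted_site_table,
            "planted_site_positions": {
                u: [[s, t, seq] for s, t, seq in v]
                for u, v in self.planted_site_positions.items()
            },
            "true_state_labels": self.true_state_labels,
            "planted_effects": self.planted_effects,
            "state_programs": self.state_programs,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthBundle":
        payload = json.loads(Path(path).read_text())
        return cls(
            true_target_ids=set(payload["true_target_ids"]),
            planted_site_table=payload["planted_site_table"],
            planted_site_positions={
                u: [(int(s), t, seq) for s, t, seq in v]
                for u, v in payload["planted_site_positions"].items()
            },
            true_state_labels=payload["true_state_labels"],
            planted_effects=payload["planted_effects"],
            state_programs=payload["state_programs"],
        )


def choose_targets(cfg: SimConfig) -> TruthBundle:
    """Draw the true-target set and its per-gene repression effects."""
    rng = cfg.rng("targets")
    genes = cfg.genes
    targets = sorted(rng.choice(genes, size=cfg.n_true_targets, replace=False))
    truth = TruthBundle(true_target_ids=set(targets))
    truth.planted_effects = {g: float(cfg.repression_log2) for g in targets}
    return truth


def gen_utrs(
    cfg: SimConfig,
    patterns: Mapping[str, str],
    truth: TruthBundle | None = None,
) -> tuple[list[tuple[str, str]], TruthBundle]:
    """Generate UTRs (DNA alphabet) with seed sites planted in true targets.

    UTR ids are gene ids: every true target gets a UTR, padded with
    non-target genes up to ``n_utrs``.  Each true-target UTR receives
    ``planted_sites[type]`` copies of each requested site string at
    non-overlapping positions (rejection placement); background bases are
    i.i.d. with the configured GC content.  Truth records exact 1-based
    positions, types, and planted strings.
    """
    if not patterns:
        raise ValueError("patterns must be nonempty")
    longest = max(len(p) for p in patterns.values())
    if cfg.utr_len <= longest:
        raise ValueError("utr_len must exceed the longest site pattern")
    need = sum(cfg.planted_sites.get(t, 0) * len(p) for t, p in patterns.items())
    if need > cfg.utr_len:
        raise ValueError(
            f"requested sites need {need} bases but utr_len is {cfg.utr_len}"
        )
    truth = truth if truth is not None else choose_targets(cfg)
    rng = cfg.rng("utrs")
    targets = sorted(truth.true_target_ids)
    non_targets = [g for g in cfg.genes if g not in truth.true_target_ids]
    utr_ids = targets + non_targets[: cfg.n_utrs - len(targets)]
    utr_ids = sorted(utr_ids)

    dna_patterns = {t: p.upper().replace("U", "T") for t, p in patterns.items()}
    p_base = np.array([(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2])
    alphabet = np.array(list("ACGT"))

    records: list[tuple[str, str]] = []
    for utr_id in utr_ids:
        seq = rng.choice(alphabet, size=cfg.utr_len, p=p_base)
        if utr_id in truth.true_target_ids:
            placed: list[tuple[int, int]] = []
            sites: list[tuple[int, str, str]] = []
            table: dict[str, int] = {}
            for site_type, count in cfg.planted_sites.items():
                if site_type not in dna_patterns:
                    raise ValueError(f"no pattern provided for site type {site_type!r}")
                pat = dna_patterns[site_type]
                for _ in range(count):
                    for _try in range(1000):
                        start = int(rng.integers(0, cfg.utr_len - len(pat) + 1))
                        iv = (start, start + len(pat))
                        if all(iv[1] <= a or iv[0] >= b for a, b in placed):
                            placed.append(iv)
                            seq[iv[0] : iv[1]] = list(pat)
                            sites.append((start + 1, site_type, pat))
                            table[site_type] = table.get(site_type, 0) + 1
                            break
                    else:
                        raise ValueError(
                            f"could not place {count} x {site_type} in {cfg.utr_len} nt"
                        )
            truth.planted_site_positions[utr_id] = sorted(sites)
            truth.planted_site_table[utr_id] = table
        records.append((utr_id, "".join(seq)))
    return records, truth


def gen_evidence(cfg: SimConfig, truth: TruthBundle) -> pd.DataFrame:
    """Predictor flags and CLIP counts correlated with planted truth.

    Each of the ``n_predictors`` algorithms flags a true target with
    probability ``predictor_sens`` and a non-target with
    ``1 - predictor_spec``; CLIP evidence counts are Poisson with the
    true/false means.
    """
    if not truth.true_target_ids:
        raise ValueError("truth has no true targets")
    rng = cfg.rng("evidence")
    genes = cfg.genes
    is_true = np.array([g in truth.true_target_ids for g in genes])
    p_hit = np.where(is_true, cfg.predictor_sens, 1 - cfg.predictor_spec)
    flags = rng.random((cfg.n_genes, cfg.n_predictors)) < p_hit[:, None]
    lam = np.where(is_true, cfg.clip_lambda_true, cfg.clip_lambda_false)
    clip = rng.poisson(lam)
    df = pd.DataFrame(
        flags, index=pd.Index(genes, name="gene"),
        columns=[f"pred_{i}" for i in range(1, cfg.n_predictors + 1)],
    )
    df["clip_evidence"] = clip
    return df


def gen_proteome(cfg: SimConfig, truth: TruthBundle, direction: str = "KD"):
    """Perturbation proteome with targets shifted in the anticorrelated sense.

    Log2 abundances are Normal(per-protein baseline, ``proteome_sd``); in the
    perturbed group, true targets shift by +``repression_log2`` under miRNA
    knockdown (derepression) and by the negative under overexpression.
    Low-abundance values are preferentially set missing (explicit NaN).
    Returns ``(values, groups)``: a linear-intensity proteins x samples frame
    and the sample -> group series.
    """
    if direction not in {"KD", "OE"}:
        raise ValueError("direction must be 'KD' or 'OE'")
    if cfg.n_samples_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    rng = cfg.rng("proteome", subkey=direction)
    genes = cfg.genes
    n = cfg.n_samples_per_group
    baseline = rng.normal(20.0, 2.0, size=cfg.n_genes)
    shift = np.array(
        [truth.planted_effects.get(g, 0.0) for g in genes]
    ) * (1.0 if direction == "KD" else -1.0)
    log2 = np.empty((cfg.n_genes, 2 * n))
    log2[:, :n] = baseline[:, None] + rng.normal(0, cfg.proteome_sd, (cfg.n_genes, n))
    log2[:, n:] = (baseline + shift)[:, None] + rng.normal(0, cfg.proteome_sd, (cfg.n_genes, n))
    # Missingness biased toward low abundance: logistic in the log2 value.
    q10 = np.quantile(baseline, 0.10)
    p_miss = 0.25 / (1.0 + np.exp(log2 - q10))
    missing = rng.random(log2.shape) < p_miss
    vals = np.power(2.0, log2)
    vals[missing] = np.nan
    samples = [f"CTRL-{i+1}" for i in range(n)] + [f"{direction}-{i+1}" for i in range(n)]
    values = pd.DataFrame(vals, index=pd.Index(genes, name="protein"), columns=samples)
    groups = pd.Series(["control"] * n + ["perturbed"] * n, index=samples)
    return values, groups


def gen_sc(
    cfg: SimConfig, truth: TruthBundle, condition: str
) -> tuple[sparse.csr_matrix, pd.DataFrame]:
    """Negative-binomial single-cell counts over discrete cell states.

    Cells are drawn from the condition's state proportions; per-cell gene
    means are ``libsize * softmax(base + program_strength * state_loading)``
    with gamma-Poisson (NB) sampling at the configured dispersion.  Perturbed
    conditions additionally scale true-target means by 2^(+r) under KD
    (derepression) or 2^(-r) under OE.  State gene programs are disjoint
    blocks of non-target genes, shared across conditions.  Returns
    ``(counts cells x genes CSR, metadata frame)`` and records true state
    labels in ``truth``.
    """
    if condition not in cfg.state_props:
        raise ValueError(f"no state_props for condition {condition!r}")
    genes = cfg.genes
    base_rng = cfg.rng("sc", subkey="base")
    base = base_rng.normal(0.0, 1.0, size=cfg.n_genes)
    non_targets = [g for g in genes if g not in truth.true_target_ids]
    if len(non_targets) < cfg.n_program_genes * len(cfg.states):
        raise ValueError("not enough non-target genes for the state programs")
    program_pool = base_rng.permutation(non_targets)
    gene_pos = {g: i for i, g in enumerate(genes)}
    loadings = np.zeros((len(cfg.states), cfg.n_genes))
    if not truth.state_programs:
        for si, state in enumerate(cfg.states):
            block = list(
                program_pool[si * cfg.n_program_genes : (si + 1) * cfg.n_program_genes]
            )
            truth.state_programs[state] = sorted(block)
    for si, state in enumerate(cfg.states):
        idx = [gene_pos[g] for g in truth.state_programs[state]]
        loadings[si, idx] = 1.0

    rng = cfg.rng("sc", subkey=f"cells:{condition}")
    n_cells = cfg.n_cells_per_condition
    props = np.asarray(cfg.state_props[condition], dtype=float)
    state_idx = rng.choice(len(cfg.states), size=n_cells, p=props)
    libsize = np.exp(rng.normal(cfg.libsize_log_mean, cfg.libsize_log_sd, size=n_cells))

    factor = {"KD": 2.0**cfg.repression_log2, "OE": 2.0**-cfg.repression_log2}.get(condition, 1.0)
    target_idx = np.array([gene_pos[g] for g in sorted(truth.true_target_ids)], dtype=int)

    logits = base[None, :] + cfg.program_strength * loadings[state_idx]
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    mean = libsize[:, None] * probs
    if factor != 1.0 and target_idx.size:
        mean[:, target_idx] *= factor
    shape = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(shape, mean * cfg.nb_dispersion)
    counts = rng.poisson(lam)

    barcodes = [f"{condition}-{i:05d}" for i in range(1, n_cells + 1)]
    meta = pd.DataFrame(
        {
            "condition": condition,
            "run": np.where(np.arange(n_cells) % 2 == 0, "run1", "run2"),
            "cell_type": "MG",
            "state": [cfg.states[i] for i in state_idx],
            "doublet_score": rng.beta(1.5, 15.0, size=n_cells),
            "mito_frac": rng.uniform(*cfg.mito_frac_range, size=n_cells),
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    truth.true_state_labels.update(dict(zip(barcodes, meta["state"])))
    return sparse.csr_matrix(counts, dtype=np.int64), meta


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(
    cfg: SimConfig,
    outdir,
    mirna: MirnaSequence = MIR132_3P,
    conditions: Sequence[str] = ("CTRL", "KD"),
) -> dict[str, object]:
    """Write the full fixture bundle and a hash manifest.

    Emits eight pipeline-input files (UTR FASTA, evidence TSV, proteome TSV,
    MTX + features/barcodes TSVs, cell metadata TSV, signature GMT) plus the
    planted-truth JSON and the manifest itself.  Identical configs produce
    byte-identical files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    patterns = seed_patterns(mirna)
    truth = choose_targets(cfg)

    records, truth = gen_utrs(cfg, patterns, truth)
    fasta = out / "utrs.fasta"
    SeqIO.write(
        [SeqRecord(Seq(s), id=u, description="") for u, s in records], str(fasta), "fasta"
    )

    evidence = gen_evidence(cfg, truth)
    evidence_path = out / "evidence.tsv"
    evidence.to_csv(evidence_path, sep="\t")

    values, groups = gen_proteome(cfg, truth, direction="KD")
    proteome_path = out / "proteome.tsv"
    labeled = values.copy()
    labeled.columns = pd.MultiIndex.from_arrays(
        [values.columns, [f"{groups[c]}|sim" for c in values.columns]]
    )
    labeled.to_csv(proteome_path, sep="\t")

    mats, metas = [], []
    for cond in conditions:
        m, meta = gen_sc(cfg, truth, cond)
        mats.append(m)
        metas.append(meta)
    counts = sparse.vstack(mats).tocsr()
    meta = pd.concat(metas)
    mtx_path = out / "counts.mtx"
    sio.mmwrite(str(mtx_path), counts.T.tocoo(), field="integer")
    features_path = out / "features.tsv"
    features_path.write_text("\n".join(cfg.genes) + "\n")
    barcodes_path = out / "barcodes.tsv"
    barcodes_path.write_text("\n".join(meta.index) + "\n")
    meta_path = out / "metadata.tsv"
    meta.to_csv(meta_path, sep="\t")

    gmt_path = out / "signatures.gmt"
    write_gmt(truth.state_programs, gmt_path, description="planted_program")

    truth_path = out / "truth.json"
    truth.to_json(truth_path)

    files = [
        fasta,
        evidence_path,
        proteome_path,
        mtx_path,
        features_path,
        barcodes_path,
        meta_path,
        gmt_path,
    ]
    manifest = {
        "config": asdict(cfg),
        "files": {p.name: _sha256(p) for p in files},
        "truth": {truth_path.name: _sha256(truth_path)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
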