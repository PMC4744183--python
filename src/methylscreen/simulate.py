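"""Synthetic methylome generator with known ground truth.

Generates everything the pipeline consumes: a reference chromosome carrying
gene models with planted intragenic CpG islands, per-CpG methylation
probability profiles for two conditions, RRBS-like per-site count tables, and
bisulfite clone reads — all deterministic under one seed so every downstream
stage can be tested against planted truth.

The emulated design: a set of screened genes each carrying a CpG-dense
segment in intron 1; one designated target gene whose island is methylated in
condition A but hypomethylated in condition B (an intron-1 island losing
methylation when the responsible de novo methyltransferase is absent), all
other genes identical between conditions.  RRBS libraries are emulated as an
MspI + TaqαI double digest with 100–350 bp size selection: only CpGs on
retained fragments receive coverage.  Per covered CpG, coverage is
zero-truncated Poisson and the methylated read count is binomial with success
probability p + (1−p)·failure, where failure is the bisulfite
conversion-failure rate (an unconverted unmethylated C reads as methylated).

Background (non-island) sequence is CpG-depleted, as vertebrate genomic
background is; planted islands are CpG-rich segments anchored by MspI sites
so they land on size-selectable fragments, as CpG islands do in real RRBS.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import bisulfite
from .bisulfite import MethylationState, RestrictionEnzyme, convert, cpg_positions, digest
from .counts import SITE_COLUMNS, write_site_counts
from .genes import GeneModel, write_gene_models
from .seqio import write_fasta

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "CloneSet",
    "generate_reference",
    "simulate_rrbs_counts",
    "simulate_clones",
    "stage_rng",
    "RRBS_ENZYMES",
]

#: Enzymes of the reduced-representation double digest.
RRBS_ENZYMES: tuple[RestrictionEnzyme, ...] = (
    RestrictionEnzyme("MspI", "CCGG", 1),
    RestrictionEnzyme("TaqaI", "TCGA", 1),
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Deterministic per-stage generator fanned out from one top-level seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic methylome.

    ``meth_prob_condition_a``/``_b`` give per-region-class CpG methylation
    probabilities ("island" and "background").  Only the designated target
    gene's island differs between conditions; every other CpG uses the
    condition-A probability in both conditions.
    """

    seed: int = 0
    n_genes: int = 20
    n_island_genes: int | None = None  # None -> every gene carries an island
    target_gene_index: int | None = 0  # None -> no differential gene
    island_length_bp: int = 300
    background_gc: float = 0.45
    meth_prob_condition_a: Mapping[str, float] = field(
        default_factory=lambda: {"island": 0.8, "background": 0.05})
    meth_prob_condition_b: Mapping[str, float] = field(
        default_factory=lambda: {"island": 0.2, "background": 0.05})
    conversion_failure_rate: float = 0.005
    mean_coverage: float = 15.0
    clone_count: int = 10
    clone_error_rate: float = 0.0
    size_select_min_bp: int = 100
    size_select_max_bp: int = 350
    chrom: str = "chrSim"

    def __post_init__(self) -> None:
        fracs = {"background_gc": self.background_gc,
                 "conversion_failure_rate": self.conversion_failure_rate,
                 "clone_error_rate": self.clone_error_rate}
        for cond in (self.meth_prob_condition_a, self.meth_prob_condition_b):
            for k, v in cond.items():
                fracs[f"meth_prob[{k}]"] = v
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.size_select_min_bp >= self.size_select_max_bp:
            raise ValueError("size_select_min_bp must be < size_select_max_bp")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.island_length_bp < 200:
            raise ValueError(
                f"island_length_bp={self.island_length_bp} is too short to satisfy "
                "the CpG-island criteria (minimum island length is 200 bp)")
        if self.target_gene_index is not None and not 0 <= self.target_gene_index < self.n_genes:
            raise ValueError("target_gene_index out of range")

    @property
    def island_gene_count(self) -> int:
        n = self.n_genes if self.n_island_genes is None else self.n_island_genes
        if not 0 <= n <= self.n_genes:
            raise ValueError("n_island_genes out of range")
        return n

    def to_dict(self) -> dict:
        d = asdict(self)
        d["meth_prob_condition_a"] = dict(self.meth_prob_condition_a)
        d["meth_prob_condition_b"] = dict(self.meth_prob_condition_b)
        return d


@dataclass
class SimulatedDataset:
    """Reference, gene models and true per-CpG methylation profiles."""

    config: SimulationConfig
    sequence: str
    genes: list[GeneModel]
    #: per-CpG truth: chrom, pos (0-based C of CpG), strand, gene_id, region, p_a, p_b
    profile: pd.DataFrame
    #: planted island spans [(start, end, gene_id)]
    planted_islands: list[tuple[int, int, str]]

    @property
    def chrom(self) -> str:
        return self.config.chrom

    def target_gene_id(self) -> str | None:
        idx = self.config.target_gene_index
        return None if idx is None else self.genes[idx].gene_id

    def write(self, out_dir: str | Path) -> dict[str, str]:
        """Write reference FASTA, gene models and the truth profile table."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"reference": str(out / "reference.fa"),
                 "genes": str(out / "genes.tsv"),
                 "truth_profile": str(out / "truth_profile.tsv")}
        write_fasta([(self.chrom, self.sequence)], paths["reference"])
        write_gene_models(self.genes, paths["genes"])
        prof = self.profile.copy()
        prof["pos"] = prof["pos"] + 1  # 1-based at the I/O boundary
        prof.to_csv(paths["truth_profile"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# Reference generation


def _random_background(rng: np.random.Generator, length: int, gc: float,
                       cpg_depletion: float = 0.8) -> np.ndarray:
    """IID bases at the given GC fraction with one-pass CpG depletion.

    Each CG dinucleotide of the draw is destroyed with probability
    ``cpg_depletion`` (the G is resampled from A/T/C), approximating the CpG
    depletion of vertebrate genomic background.
    """
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    arr = _BASES[rng.choice(4, size=length, p=p)]
    if length >= 2:
        cg = np.nonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))[0]
        kill = cg[rng.random(cg.size) < cpg_depletion]
        if kill.size:
            repl = np.frombuffer(b"ATC", dtype=np.uint8)
            arr[kill + 1] = repl[rng.integers(0, 3, size=kill.size)]
    return arr


def _cpg_rich_segment(rng: np.random.Generator, length: int,
                      cg_token_prob: float = 0.35) -> np.ndarray:
    """CpG-island-like sequence: a token stream emitting 'CG' with probability
    ``cg_token_prob``, else a single GC-rich base.  Comfortably satisfies the
    island criteria (GC ≈ 0.7, Obs/Exp ≈ 2)."""
    out = np.empty(length + 1, dtype=np.uint8)
    single = np.frombuffer(b"CGAT", dtype=np.uint8)
    p_single = np.array([0.2, 0.2, 0.3, 0.3])
    i = 0
    # draw in blocks for speed
    while i < length:
        k = max(64, (length - i) // 2 + 8)
        toks = rng.random(k) < cg_token_prob
        bases = single[rng.choice(4, size=k, p=p_single)]
        for t, b in zip(toks, bases):
            if t:
                out[i] = ord("C")
                if i + 1 <= length:
                    out[i + 1] = ord("G")
                i += 2
            else:
                out[i] = b
                i += 1
            if i >= length:
                break
    return out[:length]


def _planted_island(rng: np.random.Generator, length: int) -> np.ndarray:
    """Island segment anchored by MspI sites (CCGG) at both ends so the
    intervening fragment is recoverable by the reduced-representation digest.

    Internal MspI/TaqαI sites are scrubbed from the core (one base of each
    occurrence mutated) so every planted island maps to a single fragment of
    length ``length − 4`` between the two anchor cuts — keeping the planted
    truth's coverage unambiguous under size selection.
    """
    anchor = np.frombuffer(b"CCGG", dtype=np.uint8)
    core = _cpg_rich_segment(rng, length - 8)
    isl = np.concatenate([anchor, core, anchor])
    L = isl.size
    sites = (b"CCGG", b"TCGA")
    for _ in range(100):
        text = isl.tobytes()
        offending = []
        for site in sites:
            start = 0
            while (i := text.find(site, start)) != -1:
                if not (i == 0 and site == b"CCGG") and not (i == L - 4 and site == b"CCGG"):
                    offending.append(i)
                start = i + 1
        if not offending:
            break
        for i in offending:
            # mutate one match base inside the core region [4, L-4)
            j = min(max(i, 4), L - 5)
            isl[j] = ord("A") if isl[j] != ord("A") else ord("T")
    return isl


def generate_reference(config: SimulationConfig) -> SimulatedDataset:
    """Build the reference chromosome, gene models and true methylation profiles.

    Each gene is a three-exon model (5'UTR in exon 1, 3'UTR in exon 3); genes
    carrying an island have it planted mid-intron-1.  The designated target
    gene's island methylation differs between conditions; all other CpGs are
    identical between conditions.
    """
    rng = stage_rng(config.seed, 0)
    parts: list[np.ndarray] = []
    pos = 0
    genes: list[GeneModel] = []
    planted: list[tuple[int, int, str]] = []
    island_flags = [i < config.island_gene_count for i in range(config.n_genes)]

    def emit(seg: np.ndarray) -> tuple[int, int]:
        nonlocal pos
        parts.append(seg)
        start, pos = pos, pos + seg.size
        return start, pos

    spacer = 400
    for i in range(config.n_genes):
        emit(_random_background(rng, spacer, config.background_gc))
        gene_id = f"gene{i:04d}"
        tx_start = pos
        e1_start, e1_end = emit(_random_background(rng, 200, config.background_gc))
        if island_flags[i]:
            emit(_random_background(rng, 150, config.background_gc))
            isl_start, isl_end = emit(_planted_island(rng, config.island_length_bp))
            planted.append((isl_start, isl_end, gene_id))
            emit(_random_background(rng, 150, config.background_gc))
        else:
            emit(_random_background(rng, 300 + config.island_length_bp,
                                    config.background_gc))
        e2_start, e2_end = emit(_random_background(rng, 150, config.background_gc))
        emit(_random_background(rng, 300, config.background_gc))
        e3_start, e3_end = emit(_random_background(rng, 250, config.background_gc))
        tx_end = pos
        genes.append(GeneModel(
            gene_id=gene_id, chrom=config.chrom,
            strand="+" if i % 2 == 0 else "-",
            tx_start=tx_start, tx_end=tx_end,
            cds_start=tx_start + 100, cds_end=tx_end - 150,
            exon_starts=(e1_start, e2_start, e3_start),
            exon_ends=(e1_end, e2_end, e3_end)))
    emit(_random_background(rng, spacer, config.background_gc))
    sequence = np.concatenate(parts).tobytes().decode("ascii")

    profile = _build_profile(sequence, genes, planted, config)
    return SimulatedDataset(config=config, sequence=sequence, genes=genes,
                            profile=profile, planted_islands=planted)


def _build_profile(sequence: str, genes: Sequence[GeneModel],
                   planted: Sequence[tuple[int, int, str]],
                   config: SimulationConfig) -> pd.DataFrame:
    cpgs = cpg_positions(sequence)
    region = np.full(cpgs.size, "background", dtype=object)
    gene_of_island = np.full(cpgs.size, "", dtype=object)
    for s, e, gid in planted:
        mask = (cpgs >= s) & (cpgs < e)
        region[mask] = "island"
        gene_of_island[mask] = gid
    gene_id = np.full(cpgs.size, "", dtype=object)
    for gm in genes:
        mask = (cpgs >= gm.tx_start) & (cpgs < gm.tx_end)
        gene_id[mask] = gm.gene_id
    pa_map = config.meth_prob_condition_a
    p_a = np.where(region == "island", pa_map["island"], pa_map["background"]).astype(float)
    p_b = p_a.copy()
    target = None if config.target_gene_index is None else genes[config.target_gene_index].gene_id
    if target is not None:
        tmask = (region == "island") & (gene_of_island == target)
        p_b[tmask] = config.meth_prob_condition_b["island"]
    return pd.DataFrame({
        "chrom": config.chrom, "pos": cpgs, "strand": "+",
        "gene_id": gene_id, "region": region, "p_a": p_a, "p_b": p_b})


# ---------------------------------------------------------------------------
# RRBS count simulation


def _double_digest_fragments(sequence: str) -> list[tuple[int, int]]:
    """Fragments of the simultaneous MspI + TaqαI digest (union of cut sites)."""
    cuts: set[int] = set()
    for enz in RRBS_ENZYMES:
        cuts.update(digest(sequence, enz).cut_positions)
    bounds = [0, *sorted(cuts), len(sequence)]
    return [(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def _zero_truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    cov = rng.poisson(lam, size)
    while (cov == 0).any():
        zeros = cov == 0
        cov[zeros] = rng.poisson(lam, int(zeros.sum()))
    return cov


def simulate_rrbs_counts(
    dataset: SimulatedDataset,
    config: SimulationConfig | None = None,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Simulate per-condition RRBS site count tables plus a provenance log.

    The unconverted reference is double-digested in silico; fragments with
    length inside the size-selection window (inclusive) are retained, and
    only CpGs on retained fragments receive coverage.  Returns
    ``({"A": table, "B": table}, provenance)`` with 1-based positions.
    """
    config = config or dataset.config
    frags = _double_digest_fragments(dataset.sequence)
    lo, hi = config.size_select_min_bp, config.size_select_max_bp
    retained = [(a, b) for a, b in frags if lo <= b - a <= hi]
    provenance = {
        "config": config.to_dict(),
        "enzymes": [e.name for e in RRBS_ENZYMES],
        "n_fragments_total": len(frags),
        "retained_fragments": [list(f) for f in retained],
        "retained_fragment_lengths": [b - a for a, b in retained],
    }
    prof = dataset.profile
    if not retained:
        warnings.warn("size selection retained no fragments; emitting empty tables")
        empty = pd.DataFrame(columns=SITE_COLUMNS)
        return {"A": empty.copy(), "B": empty.copy()}, provenance

    starts = np.array([a for a, _ in retained])
    ends = np.array([b for _, b in retained])
    pos = prof["pos"].to_numpy()
    idx = np.searchsorted(starts, pos, side="right") - 1
    covered = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
    tables = {}
    for stage, (cond, pcol) in enumerate([("A", "p_a"), ("B", "p_b")], start=1):
        rng = stage_rng(config.seed, stage)
        p = prof.loc[covered, pcol].to_numpy()
        cov = _zero_truncated_poisson(rng, config.mean_coverage, p.size)
        p_eff = p + (1.0 - p) * config.conversion_failure_rate
        meth = rng.binomial(cov, p_eff)
        tables[cond] = pd.DataFrame({
            "chrom": prof.loc[covered, "chrom"].to_numpy(),
            "pos": pos[covered] + 1,
            "strand": "+",
            "meth_count": meth,
            "unmeth_count": cov - meth,
            "context": "CpG"})
    return tables, provenance


# ---------------------------------------------------------------------------
# Clone simulation


@dataclass
class CloneSet:
    """Simulated bisulfite clones for one region, with planted truth.

    ``truth`` is a clone × CpG-position boolean matrix (True = methylated);
    columns are 0-based CpG positions within the region.
    """

    region_label: str
    region_seq: str
    clones: list[tuple[str, str]]
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"clones": str(out / f"clones_{self.region_label}.fa"),
                 "truth": str(out / f"clone_truth_{self.region_label}.tsv")}
        write_fasta(self.clones, paths["clones"])
        self.truth.to_csv(paths["truth"], sep="\t")
        return paths


def simulate_clones(
    region_seq: str,
    cpg_probs: Sequence[float] | Mapping[int, float],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    *,
    region_label: str = "region",
    strand: str = "OT",
) -> CloneSet:
    """Simulate Sanger-style bisulfite clones of one PCR region.

    Per clone, each CpG's methylation state is Bernoulli(profile probability);
    the clone read is the bisulfite conversion of the region under that state,
    with conversion failures at rate ``conversion_failure_rate`` at non-CpG
    cytosines and uniform substitution errors at ``clone_error_rate``.
    ``cpg_probs`` is either a sequence aligned to the region's CpG positions
    or a {position: probability} mapping on 0-based region coordinates.
    """
    if config.clone_count < 1:
        raise ValueError("clone_count must be >= 1")
    rng = rng if rng is not None else stage_rng(config.seed, 3)
    cpgs = cpg_positions(region_seq)
    if isinstance(cpg_probs, Mapping):
        missing = [int(p) for p in cpgs if int(p) not in cpg_probs]
        if missing:
            raise ValueError(f"cpg_probs missing positions {missing[:5]}")
        probs = np.array([cpg_probs[int(p)] for p in cpgs], dtype=float)
    else:
        probs = np.asarray(cpg_probs, dtype=float)
        if probs.size != cpgs.size:
            raise ValueError(
                f"cpg_probs length {probs.size} != number of CpGs {cpgs.size}")
    clones = []
    truth_rows = []
    for c in range(config.clone_count):
        states = rng.random(cpgs.size) < probs
        state = MethylationState.from_positions(cpgs[states])
        read = convert(region_seq, state, strand,
                       failure_rate=config.conversion_failure_rate, rng=rng,
                       failure_at_cpg=False)
        if config.clone_error_rate > 0:
            arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8).copy()
            hits = np.nonzero(rng.random(arr.size) < config.clone_error_rate)[0]
            for h in hits:
                choices = _BASES[_BASES != arr[h]]
                arr[h] = rng.choice(choices)
            read = arr.tobytes().decode("ascii")
        clone_id = f"{region_label}_clone{c:03d}"
        clones.append((clone_id, read))
        truth_rows.append(states)
    truth = pd.DataFrame(
        np.array(truth_rows, dtype=bool),
        index=[cid for cid, _ in clones],
        columns=[int(p) for p in cpgs])
    truth.index.name = "clone_id"
    return CloneSet(region_label=region_label, region_seq=region_seq,
                    clones=clones, truth=truth)


def clone_region(dataset: SimulatedDataset, gene_id: str, condition: str = "A",
                 flank: int = 20) -> tuple[str, dict[int, float], int]:
    """Extract a gene's planted-island PCR region and its per-CpG truth
    probabilities for the given condition.  Returns (region sequence,
    {region-relative CpG position: probability}, region genomic start)."""
    spans = [(s, e) for s, e, gid in dataset.planted_islands if gid == gene_id]
    if not spans:
        raise ValueError(f"gene {gene_id!r} carries no planted island")
    s, e = spans[0]
    start = max(0, s - flank)
    end = min(len(dataset.sequence), e + flank)
    region = dataset.sequence[start:end]
    pcol = {"A": "p_a", "B": "p_b"}[condition]
    prof = dataset.profile
    inside = prof[(prof["pos"] >= start) & (prof["pos"] < end - 1)]
    probs = {int(row.pos) - start: float(getattr(row, pcol))
             for row in inside.itertuples()}
    return region, probs, start


def write_provenance(provenance: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(provenance, indent=2) + "\n")
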