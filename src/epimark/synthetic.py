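"""Synthetic two-species genomics world with known ground truth.

The generator emulates the structure the pipeline is built for: a gene
annotation on a small genome; root/stem FPKM expression with a log-normal
positive component; TSS-proximal mark peaks whose per-gene probability is a
function of the gene's expression decile (high deciles more often marked,
mirroring the observed coupling of H3K4me3 with active transcription) and
whose centres sit a configurable distance downstream of the TSS; uniform
intergenic noise peaks; hidden stranded "novel" genes that emit unstranded
transcript fragments, TSS-proximal peaks and stranded ESTs; co-expression
modules with exact planted composition; and reciprocal-best-hit tables with
a planted orthologue pairing plus decoy hits above the E-value cutoff.

Everything is drawn from a single seeded generator, and the writers are
deterministic, so a fixed seed reproduces every output file byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as emio
from .core import DensityTrack, GeneModel, GenomicInterval, Peak, merge_pairs, subtract_pairs
from .landscape import expression_groups
from .strand import EstAlignment, TranscriptCandidate

DECILE_ORDER = [f"L{i}" for i in range(1, 11)] + ["unexpressed"]


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic world; defaults are the study conditions.

    ``peak_prob_by_decile`` lists the marking probability for expression
    groups L1 (highest) .. L10 then unexpressed; the default decreases
    monotonically so mark density tracks expression level.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 300
    gene_length_range: Tuple[int, int] = (1000, 4000)
    min_gene_gap: int = 2400
    exons_per_gene: Tuple[int, int] = (1, 5)
    frac_expressed: float = 0.8
    frac_biased: float = 0.2
    bias_fold: float = 4.0
    peak_prob_by_decile: Tuple[float, ...] = (
        0.95, 0.90, 0.85, 0.80, 0.75, 0.70, 0.65, 0.60, 0.55, 0.50, 0.30,
    )
    peak_offset_mean: int = 200
    peak_offset_sd: float = 80.0
    peak_width: int = 500
    n_noise_peaks: int = 40
    n_novel_genes: int = 20
    novel_length_range: Tuple[int, int] = (1500, 3000)
    fragments_per_novel: Tuple[int, int] = (1, 1)
    novel_peak_offset_mean: int = 150
    novel_peak_offset_sd: float = 50.0
    novel_stem_prob: float = 0.7
    est_per_novel: float = 2.0
    n_ortholog_pairs: int = 60
    same_chrom_prob: float = 0.8
    n_decoy_hits: int = 120
    module_spec: Tuple[Tuple[int, int, int], ...] = ((43, 9, 21), (37, 37, 31))
    bin_size: int = 50
    active_cutoff: float = 0.0

    def __post_init__(self):
        if len(self.peak_prob_by_decile) != 11:
            raise ValueError("peak_prob_by_decile needs 11 entries (L1..L10, unexpressed)")
        if not all(0.0 <= p <= 1.0 for p in self.peak_prob_by_decile):
            raise ValueError("probabilities must be in [0, 1]")
        for name in ("n_chroms", "chrom_length", "n_genes", "peak_width", "bin_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.frac_expressed <= 1.0:
            raise ValueError("frac_expressed must be in [0, 1]")
        for size, n_exp, n_marked in self.module_spec:
            if n_exp > size or n_marked > size:
                raise ValueError(f"infeasible module spec {(size, n_exp, n_marked)}")


@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    chrom_lengths: Dict[str, int]
    genes: Dict[str, GeneModel]
    expression: pd.DataFrame  # samples: root, stem
    peaks: Dict[str, List[Peak]]
    tracks: Dict[str, DensityTrack]
    candidates: List[TranscriptCandidate]
    ests: List[EstAlignment]
    edges: pd.DataFrame
    hits_ab: pd.DataFrame
    hits_ba: pd.DataFrame
    truth: Dict


def _place_intervals(
    rng: np.random.Generator,
    n: int,
    length_range: Tuple[int, int],
    chrom_lengths: Mapping[str, int],
    occupied: Dict[str, List[Tuple[int, int]]],
    min_gap: int,
    what: str,
) -> List[GenomicInterval]:
    """Rejection-sample non-overlapping intervals with a minimum gap."""
    chroms = sorted(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out: List[GenomicInterval] = []
    tries = 0
    max_tries = 400 * max(1, n)
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} non-overlapping {what} after {max_tries} tries; "
                "reduce counts or enlarge the genome"
            )
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        limit = chrom_lengths[chrom] - length - min_gap
        if limit <= min_gap:
            continue
        start = int(rng.integers(min_gap, limit))
        end = start + length
        clash = any(s < end + min_gap and start - min_gap < e
                    for s, e in occupied.get(chrom, []))
        if clash:
            continue
        occupied.setdefault(chrom, []).append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(GenomicInterval(chrom, start, end, strand))
    return out


def _make_exons(rng: np.random.Generator, iv: GenomicInterval,
                n_range: Tuple[int, int]) -> List[GenomicInterval]:
    n = int(rng.integers(n_range[0], n_range[1] + 1))
    length = len(iv)
    n = max(1, min(n, length // 60))  # keep exons and introns non-trivial
    if n == 1:
        return [GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand)]
    cuts = np.sort(rng.choice(np.arange(1, 2 * n), size=2 * n - 2, replace=False))
    edges = iv.start + (np.concatenate([[0], cuts, [2 * n]]) * length) // (2 * n)
    exons = []
    for i in range(0, 2 * n, 2):  # alternate exon/intron slices; first+last exonic
        s, e = int(edges[i]), int(edges[i + 1])
        if e > s:
            exons.append(GenomicInterval(iv.chrom, s, e, iv.strand))
    # force exons to reach the gene ends so the span equals the exon union
    first, last = exons[0], exons[-1]
    exons[0] = GenomicInterval(iv.chrom, iv.start, first.end, iv.strand)
    exons[-1] = GenomicInterval(iv.chrom, last.start, iv.end, iv.strand)
    return exons


def generate_annotation(
    config: SyntheticConfig, rng: np.random.Generator
) -> Tuple[Dict[str, GeneModel], Dict[str, int], Dict[str, List[Tuple[int, int]]]]:
    chrom_lengths = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    mean_span = sum(config.gene_length_range) / 2 + config.min_gene_gap
    if config.n_genes * mean_span >= 0.85 * config.n_chroms * config.chrom_length:
        raise ValueError("genome too small for requested gene count")
    occupied: Dict[str, List[Tuple[int, int]]] = {}
    ivs = _place_intervals(rng, config.n_genes, config.gene_length_range,
                           chrom_lengths, occupied, config.min_gene_gap, "genes")
    genes: Dict[str, GeneModel] = {}
    for i, iv in enumerate(ivs):
        gid = f"gA{i:05d}"
        genes[gid] = GeneModel(gid, iv, _make_exons(rng, iv, config.exons_per_gene))
    return genes, chrom_lengths, occupied


def generate_expression(
    config: SyntheticConfig, genes: Mapping[str, GeneModel], rng: np.random.Generator
) -> pd.DataFrame:
    """Root/stem FPKM: an exact frac_expressed share of genes gets a
    log-normal positive value, a frac_biased share of those is root- or
    stem-biased by bias_fold; the rest are exactly zero."""
    gene_ids = sorted(genes)
    n = len(gene_ids)
    n_expr = int(round(config.frac_expressed * n))
    expressed = rng.choice(n, size=n_expr, replace=False)
    base = np.zeros(n)
    base[expressed] = rng.lognormal(mean=1.0, sigma=1.2, size=n_expr)
    root = base.copy()
    stem = base.copy()
    n_biased = int(round(config.frac_biased * n_expr))
    biased = rng.choice(expressed, size=n_biased, replace=False)
    half = n_biased // 2
    root[biased[:half]] *= config.bias_fold      # root-biased
    stem[biased[half:]] *= config.bias_fold      # stem-biased
    # round to the written precision so files and memory agree exactly
    root = np.array([float(f"{v:.6g}") for v in root])
    stem = np.array([float(f"{v:.6g}") for v in stem])
    return pd.DataFrame({"root": root, "stem": stem}, index=pd.Index(gene_ids, name="gene_id"))


def _decile_probs(config: SyntheticConfig) -> Dict[str, float]:
    return dict(zip(DECILE_ORDER, config.peak_prob_by_decile))


def generate_peaks(
    config: SyntheticConfig,
    genes: Mapping[str, GeneModel],
    expression: pd.DataFrame,
    rng: np.random.Generator,
) -> Tuple[Dict[str, List[Peak]], Dict[str, Dict[str, bool]], Dict[str, pd.Series]]:
    """Decile-conditional TSS-proximal gene peaks per sample.

    Returns (peaks per sample, marked-flag truth per sample, decile labels
    per sample).  Peak centres are clipped into the gene body so a marked
    gene always carries its own peak inside its mark-association window.
    """
    probs = _decile_probs(config)
    peaks: Dict[str, List[Peak]] = {}
    marked: Dict[str, Dict[str, bool]] = {}
    deciles: Dict[str, pd.Series] = {}
    w = config.peak_width
    for sample in ("root", "stem"):
        groups = expression_groups(expression, sample)
        deciles[sample] = groups
        sample_peaks: List[Peak] = []
        flags: Dict[str, bool] = {}
        for i, gid in enumerate(sorted(genes)):
            g = genes[gid]
            p = probs[groups[gid]]
            hit = bool(rng.random() < p)
            flags[gid] = hit
            if not hit:
                continue
            offset = int(np.clip(round(rng.normal(config.peak_offset_mean,
                                                  config.peak_offset_sd)),
                                 0, len(g.interval) - 1))
            centre = g.tss + offset if g.strand == "+" else g.tss - offset
            start = max(0, centre - w // 2)
            end = start + w
            score = round(5.0 + float(expression.loc[gid, sample]), 3)
            sample_peaks.append(
                Peak(f"{sample}_pk{i:05d}", GenomicInterval(g.chrom, start, end), score, sample)
            )
        peaks[sample] = sample_peaks
        marked[sample] = flags
    return peaks, marked, deciles


def _allowed_space(
    chrom_lengths: Mapping[str, int],
    forbidden: Mapping[str, Sequence[Tuple[int, int]]],
) -> Dict[str, List[Tuple[int, int]]]:
    return {
        c: subtract_pairs([(0, length)], forbidden.get(c, []))
        for c, length in chrom_lengths.items()
    }


def generate_noise_peaks(
    config: SyntheticConfig,
    chrom_lengths: Mapping[str, int],
    keepout: Mapping[str, Sequence[Tuple[int, int]]],
    rng: np.random.Generator,
    sample: str,
) -> List[Peak]:
    """Exactly n_noise_peaks with centres in intergenic space, clear of every
    gene/novel-gene association window."""
    allowed = _allowed_space(chrom_lengths, keepout)
    flat = [(c, s, e) for c in sorted(allowed) for s, e in allowed[c]]
    if not flat:
        raise RuntimeError("no intergenic space left for noise peaks")
    lens = np.array([e - s for _, s, e in flat], dtype=float)
    out = []
    w = config.peak_width
    for i in range(config.n_noise_peaks):
        j = int(rng.choice(len(flat), p=lens / lens.sum()))
        c, s, e = flat[j]
        centre = int(rng.integers(s, e))
        start = max(0, centre - w // 2)
        score = round(float(rng.uniform(1.0, 4.0)), 3)
        out.append(Peak(f"{sample}_noise{i:04d}",
                        GenomicInterval(c, start, start + w), score, sample))
    return out


def generate_novel_and_ests(
    config: SyntheticConfig,
    chrom_lengths: Mapping[str, int],
    occupied: Dict[str, List[Tuple[int, int]]],
    rng: np.random.Generator,
) -> Tuple[List[TranscriptCandidate], List[EstAlignment], Dict[str, Dict],
           Dict[str, List[Peak]]]:
    """Hidden stranded novel genes, their unstranded fragments, stranded
    ESTs and TSS-proximal peaks (root always; stem with novel_stem_prob)."""
    ivs = _place_intervals(rng, config.n_novel_genes, config.novel_length_range,
                           chrom_lengths, occupied, config.min_gene_gap, "novel genes")
    truth: Dict[str, Dict] = {}
    candidates: List[TranscriptCandidate] = []
    ests: List[EstAlignment] = []
    novel_peaks: Dict[str, List[Peak]] = {"root": [], "stem": []}
    w = config.peak_width
    ci = ei = 0
    for k, iv in enumerate(ivs):
        nid = f"novel{k:04d}"
        truth[nid] = {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                      "strand": iv.strand}
        # fragments: contiguous sub-spans separated by small gaps
        n_frag = int(rng.integers(config.fragments_per_novel[0],
                                  config.fragments_per_novel[1] + 1))
        length = len(iv)
        n_frag = max(1, min(n_frag, length // 400))
        bounds = [iv.start, iv.end]
        if n_frag > 1:
            inner = np.sort(rng.choice(np.arange(iv.start + 200, iv.end - 200),
                                       size=n_frag - 1, replace=False))
            bounds = [iv.start] + [int(b) for b in inner] + [iv.end]
        frags = []
        for f in range(n_frag):
            s = bounds[f] if f == 0 else bounds[f] + int(rng.integers(100, 300))
            e = bounds[f + 1]
            if e - s < 100:
                s = bounds[f]
            frags.append((s, e))
            candidates.append(
                TranscriptCandidate(f"cand{ci:05d}",
                                    GenomicInterval(iv.chrom, s, e, ".")))
            ci += 1
        truth[nid]["fragments"] = frags
        # peaks near the hidden TSS
        tss = iv.start if iv.strand == "+" else iv.end - 1
        for sample in ("root", "stem"):
            if sample == "stem" and rng.random() >= config.novel_stem_prob:
                continue
            offset = int(np.clip(round(rng.normal(config.novel_peak_offset_mean,
                                                  config.novel_peak_offset_sd)),
                                 0, length - 1))
            centre = tss + offset if iv.strand == "+" else tss - offset
            start = max(0, centre - w // 2)
            novel_peaks[sample].append(
                Peak(f"{sample}_nv{k:04d}", GenomicInterval(iv.chrom, start, start + w),
                     round(float(rng.uniform(8.0, 20.0)), 3), sample))
        # stranded ESTs; some span fragment gaps
        n_est = int(rng.poisson(config.est_per_novel))
        for _ in range(n_est):
            if n_frag > 1 and rng.random() < 0.7:
                f = int(rng.integers(0, n_frag - 1))
                s = int(rng.integers(max(iv.start, frags[f][1] - 300), frags[f][1] - 20))
                e = int(rng.integers(frags[f + 1][0] + 20,
                                     min(iv.end, frags[f + 1][0] + 300)))
            else:
                f = int(rng.integers(0, n_frag))
                fs, fe = frags[f]
                s = int(rng.integers(fs, fe - 50))
                e = int(rng.integers(s + 50, min(fe, s + 800) + 1))
            ests.append(EstAlignment(f"est{ei:05d}",
                                     GenomicInterval(iv.chrom, s, e, iv.strand)))
            ei += 1
    return candidates, ests, truth, novel_peaks


def generate_tracks(
    config: SyntheticConfig,
    chrom_lengths: Mapping[str, int],
    peaks: Mapping[str, Sequence[Peak]],
    rng: np.random.Generator,
) -> Dict[str, DensityTrack]:
    """Peak coverage (score per overlapped bin) plus low gamma background."""
    tracks = {}
    for sample in sorted(peaks):
        t = DensityTrack(config.bin_size, chrom_lengths)
        for c in sorted(t.data):
            t.data[c] += rng.gamma(shape=0.5, scale=0.1, size=len(t.data[c]))
        for p in peaks[sample]:
            t.add(p.chrom, p.interval.start, p.interval.end, p.score)
        for c in t.data:
            t.data[c] = np.round(t.data[c], 6)
        tracks[sample] = t
    return tracks


def generate_modules(
    config: SyntheticConfig,
    genes: Mapping[str, GeneModel],
    expression: pd.DataFrame,
    marked_root: Mapping[str, bool],
    rng: np.random.Generator,
) -> Tuple[pd.DataFrame, List[Dict]]:
    """Co-expression edge lists with exact planted (size, n_expressed,
    n_marked) composition per module, flags taken in the root sample."""
    gene_ids = sorted(genes)
    expressed = {g: bool(expression.loc[g, "root"] > config.active_cutoff)
                 for g in gene_ids}
    pools = {
        (True, True): [g for g in gene_ids if expressed[g] and marked_root[g]],
        (True, False): [g for g in gene_ids if expressed[g] and not marked_root[g]],
        (False, True): [g for g in gene_ids if not expressed[g] and marked_root[g]],
        (False, False): [g for g in gene_ids if not expressed[g] and not marked_root[g]],
    }
    for key in pools:
        pools[key] = list(pools[key])
    used: set = set()
    rows = []
    modules_truth = []
    for mi, (size, n_exp, n_marked) in enumerate(config.module_spec):
        n_unexp = size - n_exp
        avail = {k: [g for g in v if g not in used] for k, v in pools.items()}
        lo = max(0, n_marked - len(avail[(False, True)]),
                 n_marked - n_unexp)
        hi = min(n_exp, n_marked, len(avail[(True, True)]))
        em = hi  # marked correlates with expression: take as many as allowed
        feasible = (
            lo <= em <= hi
            and n_exp - em <= len(avail[(True, False)])
            and n_marked - em <= len(avail[(False, True)])
            and n_unexp - (n_marked - em) <= len(avail[(False, False)])
            and n_marked - em >= 0
            and n_marked - em <= n_unexp
        )
        if not feasible:
            raise ValueError(
                f"module spec {(size, n_exp, n_marked)} infeasible with current "
                "gene pools; adjust n_genes, frac_expressed or peak probabilities"
            )
        pick = lambda pool, k: [pool[j] for j in rng.choice(len(pool), size=k, replace=False)] if k else []
        members = (
            pick(avail[(True, True)], em)
            + pick(avail[(True, False)], n_exp - em)
            + pick(avail[(False, True)], n_marked - em)
            + pick(avail[(False, False)], n_unexp - (n_marked - em))
        )
        used.update(members)
        anchor_pool = [g for g in gene_ids if g not in used and g not in members]
        anchor = anchor_pool[int(rng.integers(0, len(anchor_pool)))]
        used.add(anchor)
        for m in sorted(members):
            sign = "positive" if rng.random() < 0.8 else "negative"
            rows.append({"gene_a": anchor, "gene_b": m, "sign": sign})
        modules_truth.append({
            "anchor": anchor, "size": size, "n_expressed": n_exp,
            "n_marked": n_marked, "members": sorted(members),
        })
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "sign"])
    return edges, modules_truth


def generate_hits(
    config: SyntheticConfig,
    genes: Mapping[str, GeneModel],
    rng: np.random.Generator,
) -> Tuple[pd.DataFrame, pd.DataFrame, List[Tuple[str, str]], Dict[str, str]]:
    """Bidirectional hit tables with a planted RBH pairing below the E-value
    cutoff and log-uniform decoy hits above it."""
    a_ids = sorted(genes)
    if config.n_ortholog_pairs > len(a_ids):
        raise ValueError("more orthologue pairs than genes")
    chroms = sorted({genes[g].chrom for g in a_ids})
    b_chrom_of = {c: f"B{j + 1:02d}" for j, c in enumerate(chroms)}
    chosen = sorted(rng.choice(len(a_ids), size=config.n_ortholog_pairs, replace=False))
    pairs: List[Tuple[str, str]] = []
    chrom_of_b: Dict[str, str] = {}
    rows_ab, rows_ba = [], []
    for j, idx in enumerate(chosen):
        a = a_ids[idx]
        if rng.random() < config.same_chrom_prob:
            bc = b_chrom_of[genes[a].chrom]
        else:
            bc = b_chrom_of[chroms[int(rng.integers(0, len(chroms)))]]
        b = f"gB{j:05d}"
        chrom_of_b[b] = bc
        pairs.append((a, b))
        e1 = 10.0 ** rng.uniform(-120, -60)
        e2 = 10.0 ** rng.uniform(-120, -60)
        bit = round(float(rng.uniform(300, 900)), 1)
        rows_ab.append({"qseqid": a, "sseqid": b, "evalue": e1, "bitscore": bit})
        rows_ba.append({"qseqid": b, "sseqid": a, "evalue": e2, "bitscore": bit})
    b_ids = [b for _, b in pairs]
    seen = {(r["qseqid"], r["sseqid"]) for r in rows_ab}
    n_dec = 0
    while n_dec < config.n_decoy_hits and a_ids and b_ids:
        q = a_ids[int(rng.integers(0, len(a_ids)))]
        s = b_ids[int(rng.integers(0, len(b_ids)))]
        ev = 10.0 ** rng.uniform(-54, -10)
        bit = round(float(rng.uniform(40, 200)), 1)
        if (q, s) in seen:
            continue
        seen.add((q, s))
        rows_ab.append({"qseqid": q, "sseqid": s, "evalue": ev, "bitscore": bit})
        rows_ba.append({"qseqid": s, "sseqid": q,
                        "evalue": 10.0 ** rng.uniform(-54, -10), "bitscore": bit})
        n_dec += 1
    cols = ["qseqid", "sseqid", "evalue", "bitscore"]
    hits_ab = pd.DataFrame(rows_ab, columns=cols).sort_values(cols[:2], kind="stable").reset_index(drop=True)
    hits_ba = pd.DataFrame(rows_ba, columns=cols).sort_values(cols[:2], kind="stable").reset_index(drop=True)
    return hits_ab, hits_ba, sorted(pairs), chrom_of_b


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Full deterministic world build from a single seeded generator."""
    rng = np.random.default_rng(config.seed)
    genes, chrom_lengths, occupied = generate_annotation(config, rng)
    expression = generate_expression(config, genes, rng)
    peaks, marked, deciles = generate_peaks(config, genes, expression, rng)
    candidates, ests, novel_truth, novel_peaks = generate_novel_and_ests(
        config, chrom_lengths, occupied, rng)
    # keep noise clear of every association window around known and novel genes
    keepout: Dict[str, List[Tuple[int, int]]] = {}
    for c, pairs_ in occupied.items():
        keepout[c] = merge_pairs([(max(0, s - 3000), e + 3000) for s, e in pairs_])
    for sample in ("root", "stem"):
        noise = generate_noise_peaks(config, chrom_lengths, keepout, rng, sample)
        peaks[sample] = sorted(
            peaks[sample] + novel_peaks[sample] + noise,
            key=lambda p: (p.chrom, p.interval.start, p.peak_id))
    tracks = generate_tracks(config, chrom_lengths, peaks, rng)
    edges, modules_truth = generate_modules(config, genes, expression,
                                            marked["root"], rng)
    hits_ab, hits_ba, pairs, chrom_of_b = generate_hits(config, genes, rng)
    truth = {
        "chrom_lengths": chrom_lengths,
        "genes": {
            g: {
                "decile_root": deciles["root"][g],
                "decile_stem": deciles["stem"][g],
                "marked_root": marked["root"][g],
                "marked_stem": marked["stem"][g],
                "expressed": bool(expression.loc[g, "root"] > 0
                                  or expression.loc[g, "stem"] > 0),
            }
            for g in sorted(genes)
        },
        "novel": novel_truth,
        "modules": modules_truth,
        "ortholog_pairs": [list(p) for p in pairs],
        "chrom_of_b": chrom_of_b,
    }
    return SyntheticWorld(config, chrom_lengths, genes, expression, peaks,
                          tracks, candidates, ests, edges, hits_ab, hits_ba, truth)


def write_world(world: SyntheticWorld, outdir: str) -> Dict[str, str]:
    """Write every world file; returns name -> path."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    emio.write_annotation(world.genes, p("annotation.gtf"))
    emio.write_expression(world.expression, p("expression.tsv"))
    for sample in sorted(world.peaks):
        emio.write_peaks(world.peaks[sample], p(f"peaks_{sample}.bed"))
        emio.write_bedgraph(world.tracks[sample], p(f"density_{sample}.bedgraph"))
    with open(p("candidates.gtf"), "w") as fh:
        for c in sorted(world.candidates, key=lambda c: (c.chrom, c.interval.start)):
            for e in c.exons:
                fh.write(
                    f"{c.chrom}\tepimark\texon\t{e.start + 1}\t{e.end}\t.\t.\t.\t"
                    f'gene_id "{c.candidate_id}"; transcript_id "{c.candidate_id}.1";\n')
    emio.write_bed6([(e.est_id, e.interval) for e in world.ests], p("ests.bed"))
    emio.write_table(world.edges, p("edges.tsv"))
    emio.write_table(world.hits_ab, p("hits_AB.tsv"))
    emio.write_table(world.hits_ba, p("hits_BA.tsv"))
    with open(p("truth.json"), "w") as fh:
        json.dump(world.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(p("config.json"), "w") as fh:
        json.dump(dataclasses.asdict(world.config), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def strand_recovery(world: SyntheticWorld, max_dist: int = 2000,
                    max_gap: int = 5000) -> float:
    """Fraction of hidden novel genes whose strand the annotation pipeline
    recovers; the evaluation half of the generator's ground truth."""
    from .strand import annotate_pipeline

    final, _ = annotate_pipeline(world.candidates, world.genes, world.peaks,
                                 world.ests, max_dist=max_dist, max_gap=max_gap)
    surviving = [c for c in final if c.status == "novel"]
    n_ok = 0
    novel = world.truth["novel"]
    for nid, info in novel.items():
        iv = GenomicInterval(info["chrom"], info["start"], info["end"], info["strand"])
        overlapping = [c for c in surviving
                       if c.chrom == iv.chrom
                       and c.interval.start < iv.end and iv.start < c.interval.end]
        if overlapping and all(c.strand == info["strand"] for c in overlapping):
            n_ok += 1
    return n_ok / max(1, len(novel))
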