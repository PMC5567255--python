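"""End-to-end orchestration: configuration, stage running, manifest.

Stages communicate only through files in the declared formats, so any stage
can also be run standalone from the CLI.  A run writes its effective
configuration and a manifest of output checksums into the output directory;
identical config + seed reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd
import yaml

from . import io as emio
from .core import gene_density
from .differential import (
    call_differential,
    candidate_regions_from_peaks,
    expression_consistency,
    tissue_specific_zscore,
)
from .landscape import (
    REGIONS,
    concurrence_stats,
    expression_groups,
    kmeans_rows,
    metagene_profile,
    region_breakdown,
    tss_matrix,
)
from .modules import build_module, fisher_exact_two_sided, module_contingency, module_report
from .orthology import chromosome_ratio_matrix, classify_conservation, rbh_orthologs
from .strand import annotate_pipeline, EstAlignment, TranscriptCandidate

log = logging.getLogger(__name__)

_PATH_KEYS = (
    "annotation", "expression", "peaks_root", "peaks_stem",
    "density_root", "density_stem", "candidates", "ests",
    "edges", "hits_ab", "hits_ba",
)


@dataclass
class RunConfig:
    """Validated inputs and thresholds for a full pipeline run."""

    annotation: str
    expression: str
    peaks_root: str
    peaks_stem: str
    density_root: str
    density_stem: str
    candidates: str
    ests: str
    edges: str
    hits_ab: str
    hits_ba: str
    out: str = "epimark_out"
    promoter_span: int = 3000
    strand_window: int = 2000
    est_max_gap: int = 5000
    window_up: int = 1000
    active_cutoff: float = 0.0
    alpha: float = 1e-5
    fold: float = 2.0
    e_cutoff: float = 1e-55
    conservation_threshold: float = 0.45
    kmeans_k: int = 4
    seed: int = 0

    def validate(self) -> None:
        for key in _PATH_KEYS:
            path = getattr(self, key)
            if not os.path.exists(path):
                raise FileNotFoundError(f"config key {key}: missing file {path}")
        for key in ("promoter_span", "strand_window", "est_max_gap", "window_up"):
            if getattr(self, key) < 0:
                raise ValueError(f"config key {key}: must be >= 0")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.e_cutoff <= 0:
            raise ValueError("e_cutoff must be positive")
        if self.kmeans_k < 1:
            raise ValueError("kmeans_k must be >= 1")


def validate_config(path: str) -> RunConfig:
    """Load and range-check a YAML run configuration; unknown keys rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    missing = [k for k in _PATH_KEYS if k not in raw]
    if missing:
        raise ValueError(f"{path}: missing required keys {missing}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _candidates_from_gtf(path: str) -> List[TranscriptCandidate]:
    from .core import GenomicInterval
    from .io import _gtf_db, _validate_gtf_lines

    _validate_gtf_lines(path)
    db = _gtf_db(path)
    exons: Dict[str, list] = {}
    for f in db.features_of_type("exon"):
        gid = f.attributes["gene_id"][0]
        exons.setdefault(gid, []).append(GenomicInterval(f.seqid, f.start - 1, f.end, "."))
    out = []
    for gid in sorted(exons):
        ivs = sorted(exons[gid], key=lambda e: e.start)
        span = GenomicInterval(ivs[0].chrom, ivs[0].start, max(e.end for e in ivs), ".")
        out.append(TranscriptCandidate(gid, span, ivs))
    return out


def run_all(config: RunConfig) -> Dict[str, str]:
    """Execute landscape -> strand -> diff -> orthology -> module stages.

    Returns the output manifest (relative path -> sha256).  A stage failure
    aborts the run naming the stage; files already written by the failing
    stage are kept with a ``.partial`` suffix.
    """
    config.validate()
    os.makedirs(config.out, exist_ok=True)
    with open(os.path.join(config.out, "run_config.json"), "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, sort_keys=True)
        fh.write("\n")

    genes = emio.parse_annotation(config.annotation)
    expr = emio.read_expression(config.expression)
    peaks = {"root": emio.parse_peaks(config.peaks_root, "root"),
             "stem": emio.parse_peaks(config.peaks_stem, "stem")}
    tracks = {"root": emio.read_bedgraph(config.density_root),
              "stem": emio.read_bedgraph(config.density_stem)}
    chrom_lengths = tracks["root"].chrom_lengths

    stage_files: List[str] = []

    def out_path(name: str) -> str:
        path = os.path.join(config.out, name)
        stage_files.append(path)
        return path

    def run_stage(name, fn):
        stage_files.clear()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - stage boundary
            for path in stage_files:
                if os.path.exists(path):
                    os.replace(path, path + ".partial")
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    # ---- landscape ----
    def _landscape():
        rows = []
        for sample in ("root", "stem"):
            bd = region_breakdown(genes, chrom_lengths, peaks[sample],
                                  config.promoter_span)
            for r in REGIONS:
                rows.append({"mode": f"peaks_{sample}", "region": r,
                             "count": bd.counts[r], "fraction": bd.fractions[r]})
        bg = region_breakdown(genes, chrom_lengths, None, config.promoter_span)
        for r in REGIONS:
            rows.append({"mode": "genome_background", "region": r,
                         "count": bg.counts[r], "fraction": bg.fractions[r]})
        emio.write_table(pd.DataFrame(rows), out_path("breakdown.tsv"))

        gd = gene_density(genes, chrom_lengths)
        emio.write_bedgraph(gd, out_path("gene_density.bedgraph"))

        prof_rows = []
        for sample in ("root", "stem"):
            groups = expression_groups(expr, sample)
            for label in sorted(groups.unique()):
                subset = [genes[g] for g in groups[groups == label].index if g in genes]
                if not subset:
                    continue
                prof = metagene_profile(tracks[sample], subset)
                prof_rows.append({"sample": sample, "group": label,
                                  **{f"bin{i}": v for i, v in enumerate(prof)}})
        emio.write_table(pd.DataFrame(prof_rows), out_path("metagene_profiles.tsv"))

        tm = tss_matrix(tracks["root"], genes)
        tm_out = tm.copy()
        if len(tm) >= config.kmeans_k:
            tm_out.insert(0, "cluster", kmeans_rows(tm, config.kmeans_k, config.seed))
        tm_out.index.name = "gene_id"
        tm_out.reset_index().pipe(emio.write_table, out_path("tss_matrix.tsv"))

        conc_rows = []
        for sample in ("root", "stem"):
            fa, fp = concurrence_stats(genes, expr, peaks[sample], sample,
                                       config.active_cutoff, config.window_up)
            conc_rows.append({"sample": sample, "frac_active_with_mark": fa,
                              "frac_peaks_near_active": fp})
        emio.write_table(pd.DataFrame(conc_rows), out_path("concurrence.tsv"))

    run_stage("landscape", _landscape)

    # ---- strand ----
    def _strand():
        cands = _candidates_from_gtf(config.candidates)
        ests = [EstAlignment(name, iv) for name, iv in emio.parse_bed6(config.ests)]
        final, counts = annotate_pipeline(cands, genes, peaks, ests,
                                          config.strand_window, config.est_max_gap)
        with open(out_path("novel.gtf"), "w") as fh:
            for c in sorted(final, key=lambda c: (c.chrom, c.interval.start)):
                if c.status != "novel":
                    continue
                strand = c.strand if c.strand in "+-" else "."
                ev = ",".join(sorted(c.evidence)) or "none"
                for e in c.exons:
                    fh.write(
                        f"{c.chrom}\tepimark\texon\t{e.start + 1}\t{e.end}\t.\t{strand}\t.\t"
                        f'gene_id "{c.candidate_id}"; transcript_id "{c.candidate_id}.1"; '
                        f'strand_evidence "{ev}"; ambiguous "{str(c.ambiguous).lower()}";\n')
        rep = pd.DataFrame(
            [{"candidate_id": c.candidate_id, "chrom": c.chrom,
              "start": c.interval.start, "end": c.interval.end,
              "status": c.status, "strand": c.strand,
              "ambiguous": c.ambiguous, "evidence": ",".join(sorted(c.evidence))}
             for c in final]).sort_values("candidate_id", kind="stable")
        emio.write_table(rep, out_path("strand_report.tsv"))
        with open(out_path("strand_support.json"), "w") as fh:
            json.dump(counts, fh, indent=1, sort_keys=True)
            fh.write("\n")

    run_stage("strand", _strand)

    # ---- differential ----
    def _diff():
        regions = candidate_regions_from_peaks(peaks["root"], peaks["stem"])
        calls = call_differential(tracks["root"], tracks["stem"], regions,
                                  config.alpha, "root", "stem")
        with open(out_path("diff_regions.bed"), "w") as fh:
            for r in sorted(calls, key=lambda r: (r.interval.chrom, r.interval.start)):
                score = -math.log10(max(r.p_value, 1e-300))
                fh.write(f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                         f"{r.direction}\t{score:.4g}\n")
        cons = expression_consistency(calls, genes, expr, "root", "stem",
                                      config.fold, config.active_cutoff,
                                      config.window_up)
        emio.write_table(
            pd.DataFrame([{"direction": d, "fraction": v} for d, v in sorted(cons.items())]),
            out_path("consistency.tsv"))
        specific = tissue_specific_zscore(expr)
        emio.write_table(
            pd.DataFrame([{"sample": s, "gene_id": g}
                          for s in sorted(specific) for g in specific[s]],
                         columns=["sample", "gene_id"]),
            out_path("specific_genes.tsv"))

    run_stage("diff", _diff)

    # ---- orthology ----
    def _orthology():
        hits_ab = emio.read_table(config.hits_ab)
        hits_ba = emio.read_table(config.hits_ba)
        pairs = rbh_orthologs(hits_ab, hits_ba, config.e_cutoff)
        emio.write_table(pd.DataFrame(pairs, columns=["gene_a", "gene_b"]),
                         out_path("pairs.tsv"))
        chrom_of_a = {g: genes[g].chrom for g in genes}
        truth_path = os.path.join(os.path.dirname(config.hits_ab), "truth.json")
        chrom_of_b: Dict[str, str] = {}
        if os.path.exists(truth_path):
            with open(truth_path) as fh:
                chrom_of_b = json.load(fh).get("chrom_of_b", {})
        usable = [p for p in pairs if p[0] in chrom_of_a and p[1] in chrom_of_b]
        if usable and chrom_of_b:
            matrix = chromosome_ratio_matrix(usable, chrom_of_a, chrom_of_b)
            matrix.ratios.round(6).reset_index(names="chrom_a").pipe(
                emio.write_table, out_path("ratio_matrix.tsv"))
            classify_conservation(matrix, config.conservation_threshold).reset_index(
                names="chrom_a").pipe(emio.write_table, out_path("conservation.tsv"))

    run_stage("orthology", _orthology)

    # ---- module ----
    def _module():
        edges = emio.read_table(config.edges)
        _, frac_marked = concurrence_stats(genes, expr, peaks["root"], "root",
                                           config.active_cutoff, config.window_up)
        # genome background: marked = genes with >=1 root peak in their window
        from intervaltree import IntervalTree

        trees: Dict[str, IntervalTree] = {}
        for g in genes.values():
            w = g.mark_window(config.window_up)
            trees.setdefault(g.chrom, IntervalTree()).addi(w.start, w.end, g.gene_id)
        marked_ids = set()
        for p in peaks["root"]:
            t = trees.get(p.chrom)
            if t is not None:
                marked_ids.update(h.data for h in t[p.centre])
        genome_marked = len(marked_ids)
        genome_unmarked = len(genes) - genome_marked
        rows = []
        for anchor in sorted(edges["gene_a"].unique()):
            module = build_module(anchor, edges, expr, peaks["root"], genes,
                                  "root", config.active_cutoff, config.window_up)
            report = module_report(module)
            row = {"anchor": anchor, "n_members": len(module.members), **report}
            for subset in ("expressed", "unexpressed"):
                if module.subset(subset):
                    table = module_contingency(module, subset, genome_marked,
                                               genome_unmarked)
                    row[f"fisher_p_{subset}"] = fisher_exact_two_sided(table)
                else:
                    row[f"fisher_p_{subset}"] = float("nan")
            rows.append(row)
        emio.write_table(pd.DataFrame(rows), out_path("module_report.tsv"))

    run_stage("module", _module)

    manifest = {}
    for root, _, files in os.walk(config.out):
        for name in sorted(files):
            if name == "manifest.json":
                continue
            path = os.path.join(root, name)
            manifest[os.path.relpath(path, config.out)] = _sha256(path)
    with open(os.path.join(config.out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
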