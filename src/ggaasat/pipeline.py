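"""Stage orchestration: scan, annotate, permutation test, associate.

Each stage reads its inputs from files, writes deterministic TSV/BED/JSON
outputs plus a run manifest (input checksums, configuration, seed, package
version), and draws all randomness from a single configured seed fanned out
per stage by name hashing, so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .association_stats import (
    QUADRANTS,
    annotate_associations,
    assign_bound_microsatellites,
    filter_for_length_analysis,
    peaks_per_mb,
    quadrant_correlations,
    stratify_quadrants,
)
from .gene_annotation import (
    annotate_nearest_genes,
    classify_feature,
    classify_range,
    distance_group_comparison,
)
from .io_formats import (
    read_de_table,
    read_fasta,
    read_gene_table,
    read_peaks,
    write_regions_bed,
)
from .overlap_permutation import (
    non_n_intervals,
    randomize_regions_test,
    resample_permutation_test,
    shifted_zscore_profile,
)
from .region_builder import filter_microsatellites, per_chromosome_profile, scan_genome

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline parameters with their standard defaults."""

    genome: Optional[str] = None
    peaks: Optional[str] = None
    peaks_dialect: str = "narrowpeak"
    genes: Optional[str] = None
    de: Optional[str] = None
    out_dir: str = "results"
    max_gap: int = 20
    min_consecutive: int = 3
    range_threshold: int = 5000
    fdr_cutoff: float = 0.05
    n_perm: int = 1000
    consecutive_cap: int = 20
    seed: int = 1
    motif: str = "GGAA"
    flip_lfc: bool = False
    signed_lfc: bool = False
    exclude_softmask: bool = False
    shift_offsets: List[int] = field(default_factory=lambda: [])

    def __post_init__(self) -> None:
        if len(self.motif) != 4:
            raise ValueError("motif must be a 4-mer")
        for name in ("max_gap", "min_consecutive", "range_threshold", "n_perm",
                     "consecutive_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived by hashing the
    stage name with the global seed."""
    digest = hashlib.blake2s(f"{seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(config: PipelineConfig, out_dir: Path, stage: str) -> None:
    inputs = {}
    for name in ("genome", "peaks", "genes", "de"):
        path = getattr(config, name)
        if path and Path(path).exists():
            inputs[name] = {"path": str(path), "sha256": _sha256(path)}
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": inputs,
    }
    with open(out_dir / "run_manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
        f.write("\n")


def run_scan(config: PipelineConfig) -> Dict[str, Path]:
    """Scan the genome, write regions and microsatellites BED plus summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(config.genome)
    scan = scan_genome(genome, max_gap=config.max_gap, motif=config.motif,
                       exclude_softmask=config.exclude_softmask)
    msats = filter_microsatellites(scan.final, config.min_consecutive)
    write_regions_bed(scan.final, out / "regions.bed")
    write_regions_bed(msats, out / "microsatellites.bed")
    profile = per_chromosome_profile(scan.final)
    profile.to_csv(out / "chromosome_profile.tsv", sep="\t", index=False,
                   float_format="%.6f")
    summary = {
        "n_regions_presplit": len(scan.presplit),
        "n_regions": len(scan.final),
        "n_microsatellites": len(msats),
        "n_mixed_presplit": sum(1 for r in scan.presplit if r.strand_class == "mixed"),
    }
    with open(out / "scan_summary.json", "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True)
        f.write("\n")
    write_manifest(config, out, "scan")
    return {"regions": out / "regions.bed", "microsatellites": out / "microsatellites.bed"}


def run_annotate(config: PipelineConfig, regions=None) -> Path:
    """Nearest-gene annotation TSV for the scanned regions."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if regions is None:
        from .io_formats import read_regions_bed

        regions = read_regions_bed(out / "regions.bed")
    genes = read_gene_table(config.genes)
    hits = annotate_nearest_genes(regions, genes)
    rows = []
    for hit in hits:
        rows.append(
            {
                "chrom": hit.region.chrom,
                "start": hit.region.start,
                "end": hit.region.end,
                "max_consecutive": hit.region.max_consecutive,
                "gene_id": hit.gene.gene_id if hit.gene else "",
                "distance": hit.distance,
                "signed_offset": hit.signed_offset if hit.signed_offset is not None else "",
                "range_class": classify_range(hit, config.range_threshold),
                "feature": classify_feature(hit),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "annotation.tsv", sep="\t", index=False, float_format="%.1f")
    comparison = distance_group_comparison(regions, genes)
    comparison.to_csv(out / "distance_comparison.tsv", sep="\t", index=False,
                      float_format="%.6g")
    write_manifest(config, out, "annotate")
    return out / "annotation.tsv"


def run_permtest(config: PipelineConfig, regions=None, msats=None) -> Path:
    """Resampling + randomization overlap tests and the shifted-z profile."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(config.genome)
    if regions is None:
        from .io_formats import read_regions_bed

        regions = read_regions_bed(out / "regions.bed")
    if msats is None:
        msats = filter_microsatellites(regions, config.min_consecutive)
    peaks = read_peaks(config.peaks, dialect=config.peaks_dialect)
    peak_ivs = [(p.chrom, p.start, p.end) for p in peaks]

    res = resample_permutation_test(
        msats, regions, peak_ivs, n_perm=config.n_perm,
        seed=stage_seed(config.seed, "resample"),
    )
    mappable = non_n_intervals(genome)
    rand = randomize_regions_test(
        msats, mappable, peak_ivs, n_perm=config.n_perm,
        seed=stage_seed(config.seed, "randomize"),
    )
    rows = []
    for strategy, r in (("resample", res), ("randomize", rand)):
        rows.append(
            {
                "strategy": strategy,
                "observed": r.observed,
                "perm_mean": r.perm_mean,
                "perm_sd": r.perm_sd,
                "z": r.z if r.z is not None else "",
                "p_empirical": r.p_empirical,
                "n_perm": r.n_perm,
                "seed": config.seed,
            }
        )
    pd.DataFrame(rows).to_csv(out / "permutation.tsv", sep="\t", index=False,
                              float_format="%.6g")

    offsets = config.shift_offsets or _default_offsets(msats)
    profile = shifted_zscore_profile(
        msats, regions, peak_ivs, offsets,
        n_perm=min(config.n_perm, 200),
        seed=stage_seed(config.seed, "shift"),
        chrom_lengths=genome.lengths,
    )
    pd.DataFrame(
        {
            "offset": profile.offsets,
            "z": [z if z is not None else "" for z in profile.z_scores],
            "n_dropped": profile.n_dropped,
        }
    ).to_csv(out / "shift_profile.tsv", sep="\t", index=False, float_format="%.6g")
    write_manifest(config, out, "permtest")
    return out / "permutation.tsv"


def _default_offsets(regions) -> List[int]:
    """Symmetric offset grid scaled to the data: out to ~25x the median
    region span in 10 steps each side."""
    if regions:
        spans = sorted(r.end - r.start for r in regions)
        span = spans[len(spans) // 2]
    else:
        span = 100
    step = max(5 * span, 50)
    return [i * step for i in range(-10, 11)]


def run_associate(config: PipelineConfig, msats=None) -> Path:
    """Bound-microsatellite association table and quadrant correlations."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if msats is None:
        from .io_formats import read_regions_bed

        msats = read_regions_bed(out / "microsatellites.bed")
    peaks = read_peaks(config.peaks, dialect=config.peaks_dialect)
    genes = read_gene_table(config.genes)
    de = read_de_table(config.de, flip_lfc=config.flip_lfc)

    records = assign_bound_microsatellites(peaks, msats)
    records = annotate_associations(records, genes, de,
                                    threshold=config.range_threshold,
                                    fdr_cutoff=config.fdr_cutoff)
    records = filter_for_length_analysis(records, config.consecutive_cap)
    rows = []
    for r in records:
        rows.append(
            {
                "chrom": r.microsatellite.chrom,
                "start": r.microsatellite.start,
                "end": r.microsatellite.end,
                "total_motifs": r.total_motifs,
                "max_consecutive": r.max_consecutive,
                "density": round(r.density, 4),
                "peak": r.peak.name if r.peak else "",
                "fold_enrichment": r.fold_enrichment,
                "dist_to_summit": r.dist_to_summit,
                "gene_id": r.gene.gene_id if r.gene else "",
                "dist_to_tss": r.dist_to_tss,
                "range_class": r.range_class,
                "regulation": r.regulation,
                "log2fc": r.log2fc,
            }
        )
    pd.DataFrame(rows).to_csv(out / "associations.tsv", sep="\t", index=False,
                              float_format="%.6g")

    quads, counts = stratify_quadrants(records, threshold=config.range_threshold)
    counts.to_csv(out / "quadrant_counts.tsv", sep="\t", index=False)
    corr_frames = []
    all_corr = quadrant_correlations(records, signed_lfc=config.signed_lfc)
    all_corr.insert(0, "quadrant", "all_bound")
    corr_frames.append(all_corr)
    for rc, reg in QUADRANTS:
        corr = quadrant_correlations(quads[(rc, reg)], signed_lfc=config.signed_lfc)
        corr.insert(0, "quadrant", f"{rc}:{reg}")
        corr_frames.append(corr)
    pd.concat(corr_frames, ignore_index=True).to_csv(
        out / "correlations.tsv", sep="\t", index=False, float_format="%.6g"
    )
    write_manifest(config, out, "associate")
    return out / "associations.tsv"


def run_all(config: PipelineConfig) -> Dict[str, Path]:
    """Scan, annotate, test overlaps and associate in one pass; emits all
    stage outputs under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(config.genome)
    scan = scan_genome(genome, max_gap=config.max_gap, motif=config.motif,
                       exclude_softmask=config.exclude_softmask)
    msats = filter_microsatellites(scan.final, config.min_consecutive)
    paths = run_scan(config)
    run_annotate(config, regions=scan.final)
    run_permtest(config, regions=scan.final, msats=msats)
    run_associate(config, msats=msats)
    peaks = read_peaks(config.peaks, dialect=config.peaks_dialect)
    ppm = peaks_per_mb(peaks, genome.lengths)
    ppm.to_csv(out / "peaks_per_mb.tsv", sep="\t", index=False, float_format="%.4f")
    write_manifest(config, out, "run_all")
    paths.update(
        {
            "annotation": out / "annotation.tsv",
            "permutation": out / "permutation.tsv",
            "shift_profile": out / "shift_profile.tsv",
            "associations": out / "associations.tsv",
            "correlations": out / "correlations.tsv",
            "peaks_per_mb": out / "peaks_per_mb.tsv",
        }
    )
    return paths
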