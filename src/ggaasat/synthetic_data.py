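"""Synthetic genomes, peak files and expression tables with planted truth.

The generator emulates the downstream products of a repeat-element binding
study: a genome carrying planted GGAA/TTCC repeat regions of controlled
consecutive-motif composition, a narrowPeak file whose fold-enrichment is a
noisy increasing (plateauing) function of motif count, and a
differential-expression table in which activated genes respond to
microsatellite length at close range while repression is length-independent.
Every planted element is recorded in a machine-readable truth table so each
pipeline stage can be tested without external data.

Background sequence is i.i.d. uniform A/C/G/T.  Incidental motifs are
destroyed only within a 24-bp buffer around planted regions (so planted
elements can never chain with clutter); elsewhere incidental motifs are kept
and recorded as unplanted truth, so the scanner is exercised on realistic
clutter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import (
    DERecord,
    GeneRecord,
    GenomeSequence,
    Peak,
    write_de_table,
    write_fasta,
    write_gene_table,
    write_peaks_narrowpeak,
)
from .region_builder import scan_genome

MOTIF = "GGAA"
MOTIF_RC = "TTCC"
_FILLER = "CT" * 16  # motif-free spacer alphabet; creates no GGAA/TTCC at junctions
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_class_counts() -> Dict[int, int]:
    """Planted regions per consecutive-motif class: heavy 1-2 clutter plus
    200 per microsatellite class 3..20."""
    counts = {1: 2000, 2: 1000}
    counts.update({c: 200 for c in range(3, 21)})
    return counts


@dataclass
class SimulationConfig:
    """All knobs of the synthetic scenario; defaults are the standard study
    conditions used throughout the tests."""

    n_chroms: int = 4
    chrom_length: int = 12_500_000
    regions_per_class: Mapping[int, int] = field(default_factory=default_class_counts)
    mixed_fraction: float = 0.15
    extra_motif_rate: float = 2.0  # Poisson mean of extra gapped motif runs
    max_gap: int = 20
    slot_margin: int = 24  # motif-free buffer kept on both sides of a planted region
    # genes
    n_genes: int = 700
    promoter_linked_fraction: float = 0.15
    promoter_offset_max: int = 4000
    pseudo_gene_fraction: float = 0.02
    # binding model: fold_enrichment = a + b * min(class, plateau) + N(0, sd)
    base_enrichment: float = 2.0
    enrichment_slope: float = 0.35
    plateau_class: int = 16
    enrichment_sd: float = 1.0
    summit_jitter_sd: float = 20.0
    peak_halfwidth: int = 150
    n_noise_peaks: int = 150
    # binding probability: logistic in consecutive-motif class
    binding_midpoint: float = 5.0
    binding_scale: float = 1.5
    binding_max: float = 0.98
    # expression model
    p_activated_promoter: float = 0.6
    p_repressed_promoter: float = 0.3
    p_activated_enhancer: float = 0.45
    p_repressed_enhancer: float = 0.45
    mu_activated: float = 2.0
    mu_repressed: float = 1.5
    lfc_sd: float = 0.6
    null_lfc_sd: float = 0.3
    enhancer_activation_scale: float = 0.5  # length-independent activated effect far away
    range_threshold: int = 5000
    seed: int = 1

    def binding_probability(self, max_consecutive: int) -> float:
        z = (max_consecutive - self.binding_midpoint) / self.binding_scale
        return self.binding_max / (1.0 + math.exp(-z))

    def enrichment_mean(self, max_consecutive: int) -> float:
        return self.base_enrichment + self.enrichment_slope * min(
            max_consecutive, self.plateau_class
        )

    def activation_ramp(self, max_consecutive: int) -> float:
        return min(max_consecutive, self.plateau_class) / self.plateau_class


# ---------------------------------------------------------------------------
# region layout construction

@dataclass
class _PlantedFragment:
    """One post-split region the pipeline should recover: a maximal group of
    same-strand runs within a planted layout."""

    offset_start: int
    offset_end: int
    strand: str
    total_motifs: int
    max_consecutive: int


@dataclass
class _RegionLayout:
    sequence: str
    fragments: List[_PlantedFragment]
    planted_class: int
    mixed: bool


def _build_layout(cls: int, strand: str, mixed: bool, rng: np.random.Generator,
                  cfg: SimulationConfig) -> _RegionLayout:
    """Compose a planted region from motif runs separated by 1..max_gap
    spacers, with the main run of ``cls`` adjacent motifs defining the
    region's consecutive-motif class."""
    runs: List[Tuple[int, str]] = [(cls, strand)]
    for _ in range(int(rng.poisson(cfg.extra_motif_rate))):
        run_len = 1 if cls == 1 else int(rng.integers(1, min(cls, 3) + 1))
        runs.append((run_len, strand))
    if cls == 1 and len(runs) == 1:
        runs.append((1, strand))  # chains need >= 2 motifs to survive
    if mixed:
        opp = "-" if strand == "+" else "+"
        runs.append((1, opp))
    rng.shuffle(runs)  # type: ignore[arg-type]

    parts: List[str] = []
    occs: List[Tuple[int, int, str]] = []  # (start, run_len, strand) per run
    cursor = 0
    for i, (run_len, run_strand) in enumerate(runs):
        if i > 0:
            gap = int(rng.integers(1, cfg.max_gap + 1))
            parts.append(_FILLER[:gap])
            cursor += gap
        motif = MOTIF if run_strand == "+" else MOTIF_RC
        parts.append(motif * run_len)
        occs.append((cursor, run_len, run_strand))
        cursor += 4 * run_len

    seq = "".join(parts)
    # group consecutive same-strand runs into post-split fragments
    fragments: List[_PlantedFragment] = []
    group: List[Tuple[int, int, str]] = [occs[0]]
    for occ in occs[1:]:
        if occ[2] == group[-1][2]:
            group.append(occ)
        else:
            fragments.append(_group_to_fragment(group))
            group = [occ]
    fragments.append(_group_to_fragment(group))
    return _RegionLayout(sequence=seq, fragments=fragments,
                         planted_class=cls, mixed=mixed)


def _group_to_fragment(group: List[Tuple[int, int, str]]) -> _PlantedFragment:
    start = group[0][0]
    end = group[-1][0] + 4 * group[-1][1]
    return _PlantedFragment(
        offset_start=start,
        offset_end=end,
        strand=group[0][2],
        total_motifs=sum(g[1] for g in group),
        max_consecutive=max(g[1] for g in group),
    )


# ---------------------------------------------------------------------------
# genome assembly

def _random_background(n: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _scrub_zone(buf: np.ndarray, lo: int, hi: int, rng: np.random.Generator) -> None:
    """Destroy GGAA/TTCC windows whose start lies in [lo, hi) of ``buf`` by
    resampling their bases until the zone is clean."""
    lo = max(lo, 0)
    hi = min(hi, len(buf) - 3)
    if hi <= lo:
        return
    for _ in range(1000):
        segment = buf[lo : hi + 3].tobytes().decode()
        found = -1
        for pat in (MOTIF, MOTIF_RC):
            i = segment.find(pat)
            if i != -1 and i < hi - lo:
                found = lo + i
                break
        if found == -1:
            return
        buf[found : found + 4] = _random_background(4, rng)
    raise RuntimeError("failed to scrub buffer zone of incidental motifs")


def generate_genome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[GenomeSequence, pd.DataFrame]:
    """Emit the FASTA-ready genome and the planted-fragment truth table.

    The truth table has one row per expected post-split region; incidental
    background regions are appended by :func:`annotate_background_truth`
    after a scan of the emitted sequence.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    specs: List[Tuple[int, str, bool]] = []
    for cls in sorted(config.regions_per_class):
        for _ in range(config.regions_per_class[cls]):
            strand = "+" if rng.random() < 0.5 else "-"
            mixed = bool(rng.random() < config.mixed_fraction)
            specs.append((cls, strand, mixed))
    order = rng.permutation(len(specs))
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    assigned: Dict[str, List[Tuple[int, str, bool]]] = {c: [] for c in chrom_names}
    for rank, idx in enumerate(order):
        assigned[chrom_names[rank % config.n_chroms]].append(specs[idx])

    sequences: Dict[str, str] = {}
    rows: List[dict] = []
    planted_id = 0
    margin = config.slot_margin
    for chrom in chrom_names:
        buf = _random_background(config.chrom_length, rng)
        placements: List[Tuple[int, int]] = []
        n_regions = len(assigned[chrom])
        # one slot per region spreads planted elements across the whole
        # chromosome; the jitter keeps adjacent regions > max_gap apart
        slot = config.chrom_length // max(n_regions, 1)
        for i, (cls, strand, mixed) in enumerate(assigned[chrom]):
            layout = _build_layout(cls, strand, mixed, rng, config)
            room = slot - len(layout.sequence) - 2 * margin
            if room < 0:
                raise ValueError(
                    f"planted content overflows {chrom}; increase chrom_length to "
                    f">= {int(1.3 * n_regions * (len(layout.sequence) + 2 * margin))}"
                )
            start = i * slot + margin + int(rng.integers(0, room + 1))
            end = start + len(layout.sequence)
            buf[start:end] = np.frombuffer(layout.sequence.encode(), dtype=np.uint8)
            placements.append((start, end))
            for frag in layout.fragments:
                fs, fe = start + frag.offset_start, start + frag.offset_end
                rows.append(
                    {
                        "chrom": chrom,
                        "start": fs,
                        "end": fe,
                        "strand": frag.strand,
                        "total_motifs": frag.total_motifs,
                        "max_consecutive": frag.max_consecutive,
                        "density": frag.total_motifs * 4 / (fe - fs) * 100.0,
                        "length": fe - fs,
                        "planted_id": f"pr{planted_id:06d}",
                        "planted_class": layout.planted_class,
                        "mixed_origin": layout.mixed,
                        "source": "planted",
                    }
                )
            planted_id += 1
            cursor = end
        for start, end in placements:
            _scrub_zone(buf, start - 24, start - 3, rng)
            _scrub_zone(buf, end, end + 21, rng)
        sequences[chrom] = buf.tobytes().decode()

    genome = GenomeSequence(chrom_names=chrom_names, sequences=sequences)
    truth = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    truth["is_microsatellite"] = truth["max_consecutive"] >= 3
    return genome, truth


def annotate_background_truth(
    genome: GenomeSequence, truth: pd.DataFrame, max_gap: int = 20
) -> pd.DataFrame:
    """Append incidental background regions, found by scanning the emitted
    sequence, to the planted truth table.

    Also asserts that every planted fragment is recovered verbatim by the
    scan — a generator-level consistency guarantee.
    """
    scan = scan_genome(genome, max_gap=max_gap)
    planted_keys = {
        (r.chrom, r.start, r.end) for r in truth.itertuples(index=False)
    }
    scanned_keys = {r.key() for r in scan.final}
    missing = planted_keys - scanned_keys
    if missing:
        raise AssertionError(f"planted fragments not recovered by scan: {sorted(missing)[:5]}")
    rows = []
    for region in scan.final:
        if region.key() in planted_keys:
            continue
        rows.append(
            {
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "strand": region.strand,
                "total_motifs": region.total_motifs,
                "max_consecutive": region.max_consecutive,
                "density": region.density,
                "length": region.length,
                "planted_id": "",
                "planted_class": 0,
                "mixed_origin": False,
                "source": "background",
                "is_microsatellite": region.max_consecutive >= 3,
            }
        )
    if rows:
        truth = pd.concat([truth, pd.DataFrame(rows)], ignore_index=True)
    return truth.sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# genes, peaks, expression

def generate_genes(
    config: SimulationConfig,
    truth: pd.DataFrame,
    genome: GenomeSequence,
    rng: np.random.Generator,
) -> Tuple[List[GeneRecord], set]:
    """Gene table: a configurable fraction of planted microsatellites get a
    dedicated promoter-linked gene (TSS within the range threshold of the
    fragment midpoint); remaining genes are placed uniformly.  Returns the
    genes and the set of pseudo-gene ids (pseudo genes are never the
    promoter-linked ones)."""
    lengths = genome.lengths
    msats = truth[(truth["source"] == "planted") & truth["is_microsatellite"]]
    placements: List[Tuple[str, int, bool]] = []  # chrom, tss, linked
    for row in msats.itertuples(index=False):
        if rng.random() < config.promoter_linked_fraction:
            mid = (row.start + row.end) // 2
            offset = int(rng.integers(-config.promoter_offset_max,
                                      config.promoter_offset_max + 1))
            tss = int(np.clip(mid + offset, 0, lengths[row.chrom] - 1))
            placements.append((row.chrom, tss, True))
    n_uniform = max(config.n_genes - len(placements), 0)
    chrom_names = genome.chrom_names
    probs = np.array([lengths[c] for c in chrom_names], dtype=float)
    probs /= probs.sum()
    for _ in range(n_uniform):
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=probs))]
        tss = int(rng.integers(0, lengths[chrom]))
        placements.append((chrom, tss, False))

    placements.sort(key=lambda p: (p[0], p[1]))
    genes: List[GeneRecord] = []
    pseudo_ids: set = set()
    for i, (chrom, tss, linked) in enumerate(placements):
        gene_id = f"G{i + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(gene_id=gene_id, name=gene_id, chrom=chrom,
                                strand=strand, tss=tss))
        if not linked and rng.random() < config.pseudo_gene_fraction:
            pseudo_ids.add(gene_id)
    return genes, pseudo_ids


def generate_peaks(
    config: SimulationConfig,
    truth: pd.DataFrame,
    genome: GenomeSequence,
    rng: np.random.Generator,
) -> Tuple[List[Peak], pd.DataFrame]:
    """Bind each planted microsatellite with probability pi(max_consecutive)
    and emit a summit-jittered peak whose fold-enrichment follows the noisy
    plateau ramp; adds uniform noise peaks.  Updates the truth table with
    bound/fold_enrichment/summit columns."""
    lengths = genome.lengths
    truth = truth.copy()
    truth["bound"] = False
    truth["fold_enrichment"] = np.nan
    truth["summit"] = -1
    peaks: List[Peak] = []
    specs: List[Tuple[str, int, float, int]] = []  # chrom, summit, fe, truth idx
    for idx, row in truth.iterrows():
        if row["source"] != "planted" or not row["is_microsatellite"]:
            continue
        c = int(row["max_consecutive"])
        if rng.random() >= config.binding_probability(c):
            continue
        mid = (int(row["start"]) + int(row["end"])) // 2
        summit = int(np.clip(round(mid + rng.normal(0, config.summit_jitter_sd)),
                             1, lengths[row["chrom"]] - 2))
        fe = max(config.enrichment_mean(c) + rng.normal(0, config.enrichment_sd), 0.1)
        specs.append((row["chrom"], summit, fe, idx))
    for _ in range(config.n_noise_peaks):
        chrom = genome.chrom_names[int(rng.integers(0, len(genome.chrom_names)))]
        summit = int(rng.integers(1, lengths[chrom] - 1))
        fe = max(config.base_enrichment + rng.normal(0, config.enrichment_sd), 0.1)
        specs.append((chrom, summit, fe, -1))

    specs.sort(key=lambda s: (s[0], s[1]))
    for i, (chrom, summit, fe, idx) in enumerate(specs):
        start = max(summit - config.peak_halfwidth, 0)
        end = min(summit + config.peak_halfwidth, lengths[chrom])
        name = f"peak{i + 1:05d}"
        peaks.append(Peak(chrom=chrom, start=start, end=end, summit=summit,
                          fold_enrichment=round(fe, 4), name=name, qvalue=0.01))
        if idx >= 0:
            truth.loc[idx, "bound"] = True
            truth.loc[idx, "fold_enrichment"] = round(fe, 4)
            truth.loc[idx, "summit"] = summit
    return peaks, truth


def generate_de_table(
    config: SimulationConfig,
    truth: pd.DataFrame,
    genes: Sequence[GeneRecord],
    pseudo_ids: set,
    rng: np.random.Generator,
) -> Tuple[List[DERecord], pd.DataFrame]:
    """Differential-expression table realizing the regulation structure.

    The nearest (non-pseudo) gene of each bound microsatellite is drawn
    activated or repressed with distance-class-specific probabilities.
    Activated genes at close range carry a log2 fold-change whose mean
    follows the same plateau ramp as binding (length-dependent activation);
    distal activated genes get a length-independent mean; repression is
    length-independent everywhere.  All remaining genes are null
    (fdr ~ U(0.05, 1), small centred log2 fold-change).
    """
    truth = truth.copy()
    truth["gene_id"] = ""
    truth["regulation"] = ""
    truth["log2fc"] = np.nan
    truth["distance_class"] = ""

    usable = [g for g in genes if g.gene_id not in pseudo_ids]
    by_chrom: Dict[str, List[GeneRecord]] = {}
    for g in usable:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gs in by_chrom.values():
        gs.sort(key=lambda g: (g.tss, g.gene_id))
    tss_arrays = {c: np.array([g.tss for g in gs]) for c, gs in by_chrom.items()}

    def nearest(chrom: str, pos: int) -> Optional[GeneRecord]:
        arr = tss_arrays.get(chrom)
        if arr is None or len(arr) == 0:
            return None
        i = int(np.searchsorted(arr, pos))
        best, best_d = None, None
        for j in (i - 1, i):
            if 0 <= j < len(arr):
                d = abs(pos - int(arr[j]))
                if best_d is None or d < best_d:
                    best, best_d = by_chrom[chrom][j], d
        return best

    bound = truth[truth["bound"] == True]  # noqa: E712
    order = bound.sort_values("fold_enrichment", ascending=False).index
    assignment: Dict[str, Tuple[str, float]] = {}  # gene_id -> (regulation, lfc)
    for idx in order:
        row = truth.loc[idx]
        mid = (int(row["start"]) + int(row["end"])) // 2
        gene = nearest(row["chrom"], mid)
        if gene is None:
            continue
        dist = abs(mid - gene.tss)
        promoter = dist <= config.range_threshold
        truth.loc[idx, "gene_id"] = gene.gene_id
        truth.loc[idx, "distance_class"] = "promoter" if promoter else "enhancer"
        if gene.gene_id in assignment:
            reg, lfc = assignment[gene.gene_id]
            truth.loc[idx, "regulation"] = reg
            truth.loc[idx, "log2fc"] = lfc
            continue
        u = rng.random()
        p_act = config.p_activated_promoter if promoter else config.p_activated_enhancer
        p_rep = config.p_repressed_promoter if promoter else config.p_repressed_enhancer
        c = int(row["max_consecutive"])
        if u < p_act:
            if promoter:
                mean = config.mu_activated * config.activation_ramp(c)
            else:
                mean = config.mu_activated * config.enhancer_activation_scale
            lfc = float(rng.normal(mean, config.lfc_sd))
            lfc = max(lfc, 0.05)  # keep the activated class sign-consistent
            reg = "activated"
        elif u < p_act + p_rep:
            lfc = float(rng.normal(-config.mu_repressed, config.lfc_sd))
            lfc = min(lfc, -0.05)
            reg = "repressed"
        else:
            reg = "unchanged"
            lfc = float(rng.normal(0, config.null_lfc_sd))
        assignment[gene.gene_id] = (reg, lfc)
        truth.loc[idx, "regulation"] = reg
        truth.loc[idx, "log2fc"] = lfc

    records: List[DERecord] = []
    for g in genes:
        if g.gene_id in assignment and assignment[g.gene_id][0] != "unchanged":
            reg, lfc = assignment[g.gene_id]
            fdr = float(10 ** -rng.uniform(1.5, 8.0))
        else:
            lfc = (assignment[g.gene_id][1] if g.gene_id in assignment
                   else float(rng.normal(0, config.null_lfc_sd)))
            fdr = float(rng.uniform(0.05, 1.0))
        records.append(DERecord(gene_id=g.gene_id, log2fc=lfc, fdr=fdr))
    return records, truth


# ---------------------------------------------------------------------------
# top level

@dataclass
class SimulationResult:
    genome: GenomeSequence
    truth: pd.DataFrame
    genes: List[GeneRecord]
    pseudo_ids: set
    peaks: List[Peak]
    de_records: List[DERecord]
    config: SimulationConfig


def simulate(config: Optional[SimulationConfig] = None,
             seed: Optional[int] = None) -> SimulationResult:
    """Run the full generator in memory.  ``seed`` overrides the config seed."""
    config = config if config is not None else SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    genome, truth = generate_genome(config, rng)
    truth = annotate_background_truth(genome, truth, max_gap=config.max_gap)
    genes, pseudo_ids = generate_genes(config, truth, genome, rng)
    peaks, truth = generate_peaks(config, truth, genome, rng)
    de_records, truth = generate_de_table(config, truth, genes, pseudo_ids, rng)
    return SimulationResult(genome=genome, truth=truth, genes=genes,
                            pseudo_ids=pseudo_ids, peaks=peaks,
                            de_records=de_records, config=config)


def write_simulation(result: SimulationResult, out_dir) -> Dict[str, Path]:
    """Write genome.fa, genes.tsv, peaks.narrowPeak, de.tsv and truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "genes": out / "genes.tsv",
        "peaks": out / "peaks.narrowPeak",
        "de": out / "de.tsv",
        "truth": out / "truth.tsv",
    }
    write_fasta(result.genome, paths["genome"])
    write_gene_table(result.genes, paths["genes"], pseudo_ids=result.pseudo_ids)
    write_peaks_narrowpeak(result.peaks, paths["peaks"])
    write_de_table(result.de_records, paths["de"])
    result.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.4f")
    return paths


def gaussian_copula_sample(
    rho_s: float, n: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Bivariate sample with a target Spearman correlation via a Gaussian
    copula: the Pearson correlation of the latent normals is
    2*sin(pi*rho_s/6).  Margins are made non-normal by monotone transforms
    (rank correlation is unaffected)."""
    rho_z = 2.0 * math.sin(math.pi * rho_s / 6.0)
    cov = np.array([[1.0, rho_z], [rho_z, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    return np.exp(z[:, 0]), z[:, 1] ** 3
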