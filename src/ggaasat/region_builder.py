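"""Chain motif occurrences into repeat regions and compute their statistics.

A repeat region is a maximal chain of GGAA/TTCC occurrences in which adjacent
motifs are separated by at most ``max_gap`` (default 20) non-motif
nucleotides; the region starts and ends exactly at motif boundaries.  Regions
whose motifs all lie on one strand are *pure*; regions containing both GGAA
and TTCC are *mixed* and are re-processed by splitting them into same-strand
clusters, discarding the degenerate case of exactly one motif on each strand.

A *microsatellite* is a repeat region whose longest run of directly adjacent
same-strand motifs (``max_consecutive``) is at least 3 — the operational
definition under which these elements behave as ETS-fusion response elements.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

import pandas as pd

from .motif_scan import MOTIF_LENGTH, MotifOccurrence, find_motif_occurrences

logger = logging.getLogger(__name__)

PURE_FORWARD = "pure_forward"
PURE_REVERSE = "pure_reverse"
MIXED = "mixed"

#: Consecutive-motif classes used for per-chromosome profiles: the value of
#: max_consecutive, with everything >= 6 pooled.
CONSECUTIVE_CLASSES = ("1", "2", "3", "4", "5", "6+")


class RegionStats(NamedTuple):
    total_motifs: int
    max_consecutive: int
    density: float
    length: int


@dataclass
class RepeatRegion:
    """A chained cluster of motif occurrences with summary statistics.

    ``occurrences`` may be None for regions re-read from a BED file, in which
    case only the precomputed statistics are available.
    """

    chrom: str
    start: int
    end: int
    occurrences: Optional[Tuple[MotifOccurrence, ...]]
    strand_class: str
    total_motifs: int
    max_consecutive: int
    density: float

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def strand(self) -> str:
        return {PURE_FORWARD: "+", PURE_REVERSE: "-"}.get(self.strand_class, ".")

    def key(self) -> Tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def classify_strand(occurrences: Sequence[MotifOccurrence]) -> str:
    strands = {o.strand for o in occurrences}
    if strands == {"+"}:
        return PURE_FORWARD
    if strands == {"-"}:
        return PURE_REVERSE
    return MIXED


def compute_region_stats(occurrences: Sequence[MotifOccurrence]) -> RegionStats:
    """Totals, longest zero-gap same-strand run, density and length.

    ``max_consecutive`` counts motifs that are directly adjacent
    (prev.end == next.start) *and* on the same strand; any insertion or
    strand switch breaks the run.  Density is the percent of region bases
    covered by motifs: total_motifs * 4 / length * 100.
    """
    if not occurrences:
        raise ValueError("region must contain at least one occurrence")
    total = len(occurrences)
    length = occurrences[-1].end - occurrences[0].start
    max_run = run = 1
    for prev, cur in zip(occurrences, occurrences[1:]):
        if cur.start == prev.end and cur.strand == prev.strand:
            run += 1
        else:
            run = 1
        max_run = max(max_run, run)
    density = total * MOTIF_LENGTH / length * 100.0
    return RegionStats(total, max_run, density, length)


def make_region(occurrences: Sequence[MotifOccurrence]) -> RepeatRegion:
    occs = tuple(occurrences)
    stats = compute_region_stats(occs)
    return RepeatRegion(
        chrom=occs[0].chrom,
        start=occs[0].start,
        end=occs[-1].end,
        occurrences=occs,
        strand_class=classify_strand(occs),
        total_motifs=stats.total_motifs,
        max_consecutive=stats.max_consecutive,
        density=stats.density,
    )


def build_repeat_regions(
    occurrences: Sequence[MotifOccurrence], max_gap: int = 20
) -> List[RepeatRegion]:
    """Chain sorted single-chromosome occurrences (both strands pooled).

    Adjacent occurrences with gap = next.start - prev.end <= ``max_gap`` fall
    in the same chain; chains of >= 2 motifs become regions, isolated single
    occurrences are discarded (singleton fragments may reappear later when
    mixed regions are split).
    """
    regions: List[RepeatRegion] = []
    if not occurrences:
        return regions
    chroms = {o.chrom for o in occurrences}
    if len(chroms) > 1:
        raise ValueError(f"occurrences span multiple chromosomes: {sorted(chroms)}")
    chain: List[MotifOccurrence] = [occurrences[0]]
    for prev, cur in zip(occurrences, occurrences[1:]):
        if cur.start < prev.start:
            raise ValueError("occurrences must be sorted by start")
        if cur.start - prev.end <= max_gap:
            chain.append(cur)
        else:
            if len(chain) >= 2:
                regions.append(make_region(chain))
            chain = [cur]
    if len(chain) >= 2:
        regions.append(make_region(chain))
    return regions


def split_mixed_region(region: RepeatRegion) -> List[RepeatRegion]:
    """Split a mixed region into maximal same-strand positional runs.

    Each run becomes a pure region with recomputed bounds and statistics.
    The degenerate mixed region of exactly one motif per strand is discarded
    entirely; single-occurrence runs from larger mixed regions are retained
    as 1-motif regions.
    """
    if region.strand_class != MIXED:
        raise ValueError("split_mixed_region requires a mixed region")
    occs = region.occurrences
    if occs is None:
        raise ValueError("region has no occurrence-level data")
    if len(occs) == 2:  # necessarily one "+" and one "-"
        return []
    runs: List[List[MotifOccurrence]] = [[occs[0]]]
    for cur in occs[1:]:
        if cur.strand == runs[-1][-1].strand:
            runs[-1].append(cur)
        else:
            runs.append([cur])
    return [make_region(run) for run in runs]


def split_regions(regions: Iterable[RepeatRegion]) -> List[RepeatRegion]:
    """Apply mixed-region splitting across a region list; pure regions pass
    through unchanged."""
    out: List[RepeatRegion] = []
    for region in regions:
        if region.strand_class == MIXED:
            out.extend(split_mixed_region(region))
        else:
            out.append(region)
    return out


def filter_microsatellites(
    regions: Sequence[RepeatRegion], min_consecutive: int = 3
) -> List[RepeatRegion]:
    """Regions with max_consecutive >= ``min_consecutive``, order preserved."""
    return [r for r in regions if r.max_consecutive >= min_consecutive]


@dataclass(frozen=True)
class StrandRunSummary:
    max_consecutive_forward: int
    max_consecutive_reverse: int
    motifs_forward: int
    motifs_reverse: int


def per_strand_runs(region: RepeatRegion) -> StrandRunSummary:
    """Longest zero-gap run and motif count computed separately per strand.

    Intended for pre-split mixed regions, to ask whether long consecutive
    runs ever co-occur on both strands of the same region.
    """
    if region.occurrences is None:
        raise ValueError("region has no occurrence-level data")
    result: Dict[str, Tuple[int, int]] = {}
    for strand in "+-":
        occs = [o for o in region.occurrences if o.strand == strand]
        count = len(occs)
        max_run = run = 1 if occs else 0
        for prev, cur in zip(occs, occs[1:]):
            run = run + 1 if cur.start == prev.end else 1
            max_run = max(max_run, run)
        result[strand] = (max_run, count)
    return StrandRunSummary(
        max_consecutive_forward=result["+"][0],
        max_consecutive_reverse=result["-"][0],
        motifs_forward=result["+"][1],
        motifs_reverse=result["-"][1],
    )


def consecutive_class(max_consecutive: int) -> str:
    return str(max_consecutive) if max_consecutive < 6 else "6+"


def per_chromosome_profile(regions: Sequence[RepeatRegion]) -> pd.DataFrame:
    """Counts and within-chromosome proportions of regions per
    consecutive-motif class {1, 2, 3, 4, 5, 6+}."""
    rows = [
        {"chrom": r.chrom, "consecutive_class": consecutive_class(r.max_consecutive)}
        for r in regions
    ]
    df = pd.DataFrame(rows, columns=["chrom", "consecutive_class"])
    counts = (
        df.groupby(["chrom", "consecutive_class"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby("chrom")["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts


@dataclass
class ScanResult:
    """Regions before and after mixed-region splitting, per genome scan."""

    presplit: List[RepeatRegion] = field(default_factory=list)
    final: List[RepeatRegion] = field(default_factory=list)


def _drop_masked(
    occs: List[MotifOccurrence], mask: Sequence[Tuple[int, int]]
) -> List[MotifOccurrence]:
    if not mask:
        return occs
    starts = [m[0] for m in mask]
    kept = []
    for o in occs:
        i = bisect.bisect_right(starts, o.end - 1) - 1
        if i >= 0 and mask[i][1] > o.start:
            continue
        kept.append(o)
    return kept


def scan_sequence(
    seq: str,
    chrom: str,
    max_gap: int = 20,
    motif: str = "GGAA",
    softmask_intervals: Optional[Sequence[Tuple[int, int]]] = None,
) -> ScanResult:
    """Full per-chromosome chain: scan -> chain -> split.

    By default soft-masked (lowercase) sequence is scanned like ordinary
    sequence; pass ``softmask_intervals`` to exclude occurrences overlapping
    repeat-masked intervals instead.
    """
    occs = find_motif_occurrences(seq, chrom, motif=motif)
    if softmask_intervals:
        occs = _drop_masked(occs, sorted(softmask_intervals))
    presplit = build_repeat_regions(occs, max_gap=max_gap)
    return ScanResult(presplit=presplit, final=split_regions(presplit))


def scan_genome(
    genome,
    max_gap: int = 20,
    motif: str = "GGAA",
    exclude_softmask: bool = False,
) -> ScanResult:
    """Scan every chromosome of a GenomeSequence; results are concatenated in
    chromosome order."""
    result = ScanResult()
    for chrom in genome.chrom_names:
        mask = genome.soft_mask.get(chrom) if exclude_softmask else None
        part = scan_sequence(
            genome.sequences[chrom], chrom, max_gap=max_gap, motif=motif,
            softmask_intervals=mask,
        )
        result.presplit.extend(part.presplit)
        result.final.extend(part.final)
    return result
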