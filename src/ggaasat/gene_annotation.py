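"""Nearest-gene annotation and distance stratification for repeat regions.

Distance is measured from the region midpoint to the gene transcription
start site, regardless of gene strand.  Regions within 5 kb of their nearest
TSS are classed promoter-like; the remainder enhancer-like.  Genomic-feature
labels additionally use the signed, strand-aware offset (upstream = before
the TSS in transcription direction).
"""

from __future__ import annotations

import bisect
import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneRecord
from .region_builder import RepeatRegion

logger = logging.getLogger(__name__)

PROMOTER_LIKE = "promoter_like"
ENHANCER_LIKE = "enhancer_like"

FEATURE_LABELS = (
    "promoter_le1kb",
    "promoter_1_2kb",
    "promoter_2_3kb",
    "gene_body",
    "downstream_le3kb",
    "distal_intergenic",
)


@dataclass(frozen=True)
class NearestGeneHit:
    """The gene whose TSS is closest to a region's midpoint.

    ``signed_offset`` is midpoint - TSS in genome coordinates; ``distance``
    its absolute value.  ``distance`` is +inf (and ``gene`` None) when the
    region's chromosome carries no gene.
    """

    region: RepeatRegion
    gene: Optional[GeneRecord]
    distance: float
    signed_offset: Optional[int]


class GeneIndex:
    """Per-chromosome TSS arrays sorted for binary-search nearest queries."""

    def __init__(self, genes: Sequence[GeneRecord]):
        by_chrom: Dict[str, List[GeneRecord]] = defaultdict(list)
        for g in genes:
            by_chrom[g.chrom].append(g)
        self._tss: Dict[str, List[int]] = {}
        self._genes: Dict[str, List[GeneRecord]] = {}
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: (g.tss, g.gene_id))
            self._tss[chrom] = [g.tss for g in gs]
            self._genes[chrom] = gs

    def nearest(self, chrom: str, pos: int) -> Tuple[Optional[GeneRecord], float]:
        """Gene with minimal |pos - tss|; ties broken by the lexicographically
        smaller gene_id."""
        tss = self._tss.get(chrom)
        if not tss:
            return None, math.inf
        genes = self._genes[chrom]
        i = bisect.bisect_left(tss, pos)
        best: Optional[GeneRecord] = None
        best_d = math.inf
        for j in (i - 1, i):
            if 0 <= j < len(tss):
                d = abs(pos - tss[j])
                if d < best_d:
                    best_d, best = d, genes[j]
        # Resolve ties among all genes at distance best_d (TSS = pos +/- best_d).
        candidates = []
        for target in {pos - int(best_d), pos + int(best_d)}:
            lo = bisect.bisect_left(tss, target)
            hi = bisect.bisect_right(tss, target)
            candidates.extend(genes[lo:hi])
        if candidates:
            best = min(candidates, key=lambda g: g.gene_id)
        return best, best_d


def nearest_gene(
    region: RepeatRegion, genes: Sequence[GeneRecord] | GeneIndex
) -> NearestGeneHit:
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    mid = region.midpoint
    gene, distance = index.nearest(region.chrom, mid)
    if gene is None:
        logger.warning("region %s:%d-%d: no gene on chromosome",
                       region.chrom, region.start, region.end)
        return NearestGeneHit(region, None, math.inf, None)
    return NearestGeneHit(region, gene, float(distance), mid - gene.tss)


def annotate_nearest_genes(
    regions: Sequence[RepeatRegion], genes: Sequence[GeneRecord]
) -> List[NearestGeneHit]:
    index = GeneIndex(genes)
    return [nearest_gene(r, index) for r in regions]


def classify_range(hit: NearestGeneHit, threshold: int = 5000) -> str:
    """Promoter-like iff distance <= threshold (inclusive: "within 5 kb")."""
    if math.isinf(hit.distance):
        logger.warning("infinite nearest-gene distance; classing enhancer-like")
        return ENHANCER_LIKE
    return PROMOTER_LIKE if hit.distance <= threshold else ENHANCER_LIKE


def classify_feature(
    hit: NearestGeneHit,
    gene_bodies: Optional[Dict[str, Tuple[str, int, int]]] = None,
) -> str:
    """Feature label for a region relative to its nearest gene.

    ``gene_bodies`` optionally maps gene_id -> (chrom, start, end); a region
    midpoint inside its nearest gene's body is labelled gene_body.  Upstream
    bins use the strand-aware offset: for a "+" gene, upstream positions are
    below the TSS.
    """
    if hit.gene is None or hit.signed_offset is None:
        return "distal_intergenic"
    mid = hit.region.midpoint
    if gene_bodies is not None:
        body = gene_bodies.get(hit.gene.gene_id)
        if body is not None and body[0] == hit.region.chrom and body[1] <= mid < body[2]:
            return "gene_body"
    upstream = -hit.signed_offset if hit.gene.strand == "+" else hit.signed_offset
    if upstream >= 0:
        if upstream <= 1000:
            return "promoter_le1kb"
        if upstream <= 2000:
            return "promoter_1_2kb"
        if upstream <= 3000:
            return "promoter_2_3kb"
        return "distal_intergenic"
    if -upstream <= 3000:
        return "downstream_le3kb"
    return "distal_intergenic"


def _comparison_class(max_consecutive: int) -> str:
    if max_consecutive <= 2:
        return "1-2"
    if max_consecutive >= 6:
        return "6+"
    return str(max_consecutive)


def distance_group_comparison(
    regions: Sequence[RepeatRegion],
    genes: Sequence[GeneRecord],
    log_scale: bool = True,
) -> pd.DataFrame:
    """Per consecutive-motif class: median nearest-gene distance and a Welch
    two-sample t-test against the pooled 1-2 class.

    Raw distances are heavy-tailed, so the test is run on log10(distance+1)
    by default (``log_scale=False`` switches to raw distances).  Classes with
    fewer than two observations are excluded with a warning.
    """
    hits = annotate_nearest_genes(regions, genes)
    groups: Dict[str, List[float]] = defaultdict(list)
    for hit in hits:
        if math.isinf(hit.distance):
            continue
        groups[_comparison_class(hit.region.max_consecutive)].append(hit.distance)
    reference = groups.get("1-2", [])
    if len(reference) < 2:
        raise ValueError("reference class 1-2 needs at least 2 observations")
    ref_values = np.log10(np.asarray(reference) + 1) if log_scale else np.asarray(reference)
    rows = []
    order = ["1-2", "3", "4", "5", "6+"]
    for label in order:
        values = groups.get(label, [])
        if label != "1-2" and len(values) < 2:
            if values:
                logger.warning("class %s has <2 observations; excluded", label)
            continue
        arr = np.asarray(values, dtype=float)
        test_values = np.log10(arr + 1) if log_scale else arr
        if label == "1-2":
            t, p = math.nan, math.nan
        else:
            t, p = stats.ttest_ind(test_values, ref_values, equal_var=False)
        rows.append(
            {
                "consecutive_class": label,
                "n": len(values),
                "median_distance": float(np.median(arr)),
                "welch_t": float(t) if not math.isnan(t) else math.nan,
                "p_value": float(p) if not math.isnan(p) else math.nan,
            }
        )
    return pd.DataFrame(rows)
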