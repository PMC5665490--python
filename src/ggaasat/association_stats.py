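"""Link binding peaks to microsatellites and genes; correlation and trend
statistics for the distance-stratified binding/expression analysis.

Each peak is assigned the microsatellite whose midpoint is closest to the
peak summit (the putative bound microsatellite); a microsatellite bound by
several peaks is represented once, by its strongest peak.  Records are then
stratified into four quadrants — {promoter-like, enhancer-like} x
{activated, repressed} — and Spearman correlations are computed between
binding enrichment, expression magnitude and microsatellite length measures.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .gene_annotation import (
    ENHANCER_LIKE,
    PROMOTER_LIKE,
    GeneIndex,
    classify_range,
    nearest_gene,
)
from .io_formats import DERecord, GeneRecord, Peak
from .region_builder import RepeatRegion

logger = logging.getLogger(__name__)

ACTIVATED = "activated"
REPRESSED = "repressed"
UNCHANGED = "unchanged"

QUADRANTS = (
    (PROMOTER_LIKE, ACTIVATED),
    (ENHANCER_LIKE, ACTIVATED),
    (PROMOTER_LIKE, REPRESSED),
    (ENHANCER_LIKE, REPRESSED),
)


@dataclass
class AssociationRecord:
    """One bound microsatellite with its strongest peak, nearest gene and
    regulation status."""

    microsatellite: RepeatRegion
    peak: Optional[Peak] = None
    dist_to_summit: Optional[int] = None
    gene: Optional[GeneRecord] = None
    dist_to_tss: float = math.inf
    range_class: Optional[str] = None
    regulation: str = UNCHANGED
    log2fc: float = math.nan
    fold_enrichment: float = math.nan

    @property
    def max_consecutive(self) -> int:
        return self.microsatellite.max_consecutive

    @property
    def total_motifs(self) -> int:
        return self.microsatellite.total_motifs

    @property
    def density(self) -> float:
        return self.microsatellite.density


def assign_bound_microsatellites(
    peaks: Sequence[Peak], microsatellites: Sequence[RepeatRegion]
) -> List[AssociationRecord]:
    """The microsatellite nearest each peak summit, deduplicated per
    microsatellite to its maximal-fold-enrichment peak.

    Distance is |microsatellite midpoint - peak summit|; midpoint ties go to
    the smaller start coordinate.  Peaks on chromosomes without any
    microsatellite are left unassigned and counted.
    """
    by_chrom: Dict[str, List[RepeatRegion]] = defaultdict(list)
    for m in microsatellites:
        by_chrom[m.chrom].append(m)
    mids: Dict[str, np.ndarray] = {}
    for chrom, ms in by_chrom.items():
        ms.sort(key=lambda m: (m.midpoint, m.start))
        mids[chrom] = np.array([m.midpoint for m in ms], dtype=np.int64)

    best: Dict[Tuple[str, int, int], Tuple[Peak, int]] = {}
    n_unassigned = 0
    for peak in peaks:
        ms = by_chrom.get(peak.chrom)
        if not ms:
            n_unassigned += 1
            continue
        arr = mids[peak.chrom]
        i = int(np.searchsorted(arr, peak.summit))
        cand: List[RepeatRegion] = []
        for j in (i - 1, i):
            if 0 <= j < len(ms):
                cand.append(ms[j])
        target = min(cand, key=lambda m: (abs(m.midpoint - peak.summit), m.start))
        dist = abs(target.midpoint - peak.summit)
        key = target.key()
        prev = best.get(key)
        if prev is None or peak.fold_enrichment > prev[0].fold_enrichment:
            best[key] = (peak, dist)
    if n_unassigned:
        logger.warning("%d peaks on chromosomes without microsatellites", n_unassigned)

    lookup = {m.key(): m for m in microsatellites}
    records = [
        AssociationRecord(
            microsatellite=lookup[key],
            peak=peak,
            dist_to_summit=dist,
            fold_enrichment=peak.fold_enrichment,
        )
        for key, (peak, dist) in best.items()
    ]
    records.sort(key=lambda r: (r.microsatellite.chrom, r.microsatellite.start))
    return records


def annotate_associations(
    records: Sequence[AssociationRecord],
    genes: Sequence[GeneRecord],
    de_records: Sequence[DERecord],
    threshold: int = 5000,
    fdr_cutoff: float = 0.05,
) -> List[AssociationRecord]:
    """Fill in nearest gene, range class and regulation for bound records.

    A gene is activated when fdr <= cutoff and its expression is higher with
    the fusion present (log2fc > 0), repressed when lower, and unchanged
    otherwise or when absent from the differential-expression table.
    """
    index = GeneIndex(genes)
    de_map = {d.gene_id: d for d in de_records}
    for rec in records:
        hit = nearest_gene(rec.microsatellite, index)
        rec.gene = hit.gene
        rec.dist_to_tss = hit.distance
        rec.range_class = classify_range(hit, threshold=threshold)
        de = de_map.get(hit.gene.gene_id) if hit.gene is not None else None
        if de is None:
            rec.regulation = UNCHANGED
            rec.log2fc = math.nan
        else:
            rec.log2fc = de.log2fc
            if de.fdr <= fdr_cutoff and de.log2fc > 0:
                rec.regulation = ACTIVATED
            elif de.fdr <= fdr_cutoff and de.log2fc < 0:
                rec.regulation = REPRESSED
            else:
                rec.regulation = UNCHANGED
    return list(records)


def filter_for_length_analysis(
    records: Sequence[AssociationRecord], max_consecutive_cap: int = 20
) -> List[AssociationRecord]:
    """Exclude microsatellites with more than ``max_consecutive_cap``
    consecutive motifs (too few exist for informative statistics)."""
    kept = [r for r in records if r.max_consecutive <= max_consecutive_cap]
    n_excluded = len(records) - len(kept)
    if n_excluded:
        logger.info("excluded %d records with > %d consecutive motifs",
                    n_excluded, max_consecutive_cap)
    return kept


@dataclass(frozen=True)
class CorrelationResult:
    r: Optional[float]
    p: Optional[float]
    n: int
    method: str = "spearman"


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with midrank ties; two-sided p by the
    t-approximation t = r*sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        return CorrelationResult(r=None, p=None, n=n)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=None, p=None, n=n)
    r, p = stats.spearmanr(x, y)
    if math.isnan(r):
        return CorrelationResult(r=None, p=None, n=n)
    return CorrelationResult(r=float(r), p=float(p), n=n)


@dataclass
class TrendFit:
    """Local-polynomial (tricube-weighted) trend with 95% bands."""

    x_grid: np.ndarray
    mean: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    span: float
    degree: int


def _loess_point(
    x0: float, x: np.ndarray, y: np.ndarray, k: int, degree: int
) -> Tuple[float, float]:
    d = np.abs(x - x0)
    idx = np.argsort(d, kind="stable")[:k]
    xs, ys, ds = x[idx], y[idx], d[idx]
    h = ds.max()
    if h == 0:
        return float(ys.mean()), float(ys.std(ddof=1) / math.sqrt(len(ys))) if len(ys) > 1 else 0.0
    w = (1 - (ds / h) ** 3) ** 3
    w = np.clip(w, 0, None)
    X = np.vander(xs - x0, degree + 1, increasing=True)
    W = w[:, None]
    XtWX = X.T @ (W * X)
    XtWy = X.T @ (w * ys)
    beta, *_ = np.linalg.lstsq(XtWX, XtWy, rcond=None)
    fitted_local = X @ beta
    resid = ys - fitted_local
    dof = max(w.sum() - (degree + 1), 1.0)
    sigma2 = float((w * resid**2).sum() / dof)
    # hat row for x0: e1^T (X'WX)^-1 X'W ; Var = sigma^2 * ||l||^2
    try:
        inv = np.linalg.pinv(XtWX)
        l = (inv @ (X.T * w))[0]
        se = math.sqrt(max(sigma2 * float((l**2).sum()), 0.0))
    except np.linalg.LinAlgError:
        se = math.sqrt(sigma2 / max(w.sum(), 1.0))
    return float(beta[0]), se


def loess_trend(
    x: Sequence[float],
    y: Sequence[float],
    span: float = 0.75,
    degree: int = 2,
    x_grid: Optional[Sequence[float]] = None,
    n_grid: int = 50,
) -> TrendFit:
    """Tricube-weighted local polynomial regression with pointwise 95% bands.

    Robust to outliers in the sense of local fitting; the band is fitted
    +/- 1.96 x the pointwise standard error of the local weighted
    least-squares estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("loess_trend needs at least 10 observations")
    k = max(int(math.ceil(span * n)), 2)
    if k < degree + 2:
        raise ValueError(
            f"span {span} gives local windows of {k} points, too few for a "
            f"degree-{degree} fit; increase span or lower the degree"
        )
    if x_grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    else:
        grid = np.asarray(x_grid, dtype=float)
    mean = np.empty(len(grid))
    se = np.empty(len(grid))
    for i, x0 in enumerate(grid):
        mean[i], se[i] = _loess_point(float(x0), x, y, k, degree)
    return TrendFit(
        x_grid=grid,
        mean=mean,
        band_low=mean - 1.96 * se,
        band_high=mean + 1.96 * se,
        span=span,
        degree=degree,
    )


def stratify_quadrants(
    records: Sequence[AssociationRecord], threshold: int = 5000
) -> Tuple[Dict[Tuple[str, str], List[AssociationRecord]], pd.DataFrame]:
    """Partition records into the four range x regulation quadrants.

    Records whose gene is unchanged are excluded; the partition over the
    remaining records is exhaustive and disjoint.  Returns the quadrant map
    and a count table.
    """
    quads: Dict[Tuple[str, str], List[AssociationRecord]] = {q: [] for q in QUADRANTS}
    for rec in records:
        if rec.regulation == UNCHANGED:
            continue
        range_class = (
            PROMOTER_LIKE if rec.dist_to_tss <= threshold else ENHANCER_LIKE
        )
        quads[(range_class, rec.regulation)].append(rec)
    counts = pd.DataFrame(
        [
            {"range_class": rc, "regulation": reg, "n": len(quads[(rc, reg)])}
            for rc, reg in QUADRANTS
        ]
    )
    return quads, counts


#: The six correlation pairs reported per quadrant: binding enrichment
#: (log2) against expression magnitude and microsatellite length measures,
#: and expression against length measures.
CORRELATION_PAIRS = (
    "enrichment_vs_expression",
    "enrichment_vs_max_consecutive",
    "enrichment_vs_total_motifs",
    "enrichment_vs_density",
    "expression_vs_max_consecutive",
    "expression_vs_total_motifs",
)


def _axes(records: Sequence[AssociationRecord], signed_lfc: bool) -> Dict[str, np.ndarray]:
    fe = np.array([max(r.fold_enrichment, 1e-9) for r in records])
    lfc = np.array([r.log2fc for r in records])
    return {
        "enrichment": np.log2(fe),
        "expression": lfc if signed_lfc else np.abs(lfc),
        "max_consecutive": np.array([r.max_consecutive for r in records], dtype=float),
        "total_motifs": np.array([r.total_motifs for r in records], dtype=float),
        "density": np.array([r.density for r in records]),
    }


def quadrant_correlations(
    records: Sequence[AssociationRecord], signed_lfc: bool = False
) -> pd.DataFrame:
    """Spearman results for the six standard pairs on one quadrant's records.

    The expression axis is |log2 fold-change| within a regulation class
    (magnitude of activation or repression) unless ``signed_lfc`` is set;
    the binding axis is log2 fold-enrichment.
    """
    rows = []
    if records:
        axes = _axes(records, signed_lfc)
    for pair in CORRELATION_PAIRS:
        a, b = pair.split("_vs_")
        if not records:
            rows.append({"pair": pair, "r": None, "p": None, "n": 0})
            continue
        res = spearman(axes[a], axes[b])
        rows.append({"pair": pair, "r": res.r, "p": res.p, "n": res.n})
    return pd.DataFrame(rows)


def group_summaries(
    records: Sequence[AssociationRecord], value: str = "enrichment",
    signed_lfc: bool = False,
) -> pd.DataFrame:
    """Per-consecutive-class median and quartiles of an axis, for
    boxplot-style reporting."""
    if not records:
        return pd.DataFrame(columns=["max_consecutive", "n", "q1", "median", "q3"])
    axes = _axes(records, signed_lfc)
    df = pd.DataFrame({
        "max_consecutive": axes["max_consecutive"].astype(int),
        "value": axes[value],
    })
    out = (
        df.groupby("max_consecutive")["value"]
        .agg(n="size", q1=lambda v: v.quantile(0.25), median="median",
             q3=lambda v: v.quantile(0.75))
        .reset_index()
    )
    return out


def peaks_per_mb(peaks: Sequence[Peak], lengths: Dict[str, int]) -> pd.DataFrame:
    """Peak counts normalized by chromosome length (peaks per Mb)."""
    for chrom, length in lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
    counts: Dict[str, int] = {chrom: 0 for chrom in lengths}
    for p in peaks:
        if p.chrom in counts:
            counts[p.chrom] += 1
    rows = [
        {"chrom": chrom, "n_peaks": counts[chrom],
         "peaks_per_mb": counts[chrom] / (lengths[chrom] / 1e6)}
        for chrom in sorted(lengths)
    ]
    return pd.DataFrame(rows)


def null_band(n: int, level: float = 0.95) -> float:
    """Half-width of the large-sample null band for a rank correlation of
    independent variables: z_crit / sqrt(n - 1)."""
    if n < 2:
        return math.inf
    z = stats.norm.ppf(0.5 + level / 2)
    return float(z / math.sqrt(n - 1))
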