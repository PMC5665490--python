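"""Permutation tests for the overlap between two genomic region sets.

The primary null model resamples query-sized sets from a fixed universe of
regions (preserving repeat-region internal structure); a second null
relocates each query region uniformly along the mappable genome.  Overlap is
defined as >= 1 bp shared under half-open interval semantics, and each query
region counts at most once however many subject regions it touches.

A shifted z-score profile translates the query by fixed offsets and
re-evaluates the resampling z at each shift, probing whether an association
is tied to the exact relative position of the two sets rather than to a
shared regional context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)


def _region_tuple(region) -> Tuple[str, int, int]:
    if isinstance(region, tuple):
        return region
    return (region.chrom, region.start, region.end)


def as_tuples(regions: Sequence) -> List[Tuple[str, int, int]]:
    return [_region_tuple(r) for r in regions]


class SubjectIndex:
    """Merged, sorted per-chromosome intervals supporting vectorized
    any-overlap queries."""

    def __init__(self, regions: Sequence):
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, start, end in as_tuples(regions):
            by_chrom.setdefault(chrom, []).append((start, end))
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: List[List[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)

    def overlaps_any(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Boolean mask: does each half-open [start, end) touch >= 1 bp of
        subject on this chromosome?"""
        s = self._starts.get(chrom)
        if s is None or len(s) == 0:
            return np.zeros(len(starts), dtype=bool)
        e = self._ends.get(chrom)
        idx = np.searchsorted(e, starts, side="right")
        mask = idx < len(s)
        out = np.zeros(len(starts), dtype=bool)
        out[mask] = s[idx[mask]] < ends[mask]
        return out

    def mask(self, regions: Sequence) -> np.ndarray:
        """Overlap indicator for an arbitrary region list, in input order."""
        tuples = as_tuples(regions)
        out = np.zeros(len(tuples), dtype=bool)
        by_chrom: Dict[str, List[int]] = {}
        for i, (chrom, _, _) in enumerate(tuples):
            by_chrom.setdefault(chrom, []).append(i)
        for chrom, indices in by_chrom.items():
            starts = np.array([tuples[i][1] for i in indices], dtype=np.int64)
            ends = np.array([tuples[i][2] for i in indices], dtype=np.int64)
            out[np.array(indices)] = self.overlaps_any(chrom, starts, ends)
        return out


def count_overlaps(query: Sequence, subject: Sequence) -> int:
    """Number of query regions overlapping >= 1 subject region by >= 1 bp."""
    if len(query) == 0:
        return 0
    index = subject if isinstance(subject, SubjectIndex) else SubjectIndex(subject)
    return int(index.mask(query).sum())


@dataclass
class PermutationResult:
    """Observed overlap against a permutation null.

    ``z`` is None (undefined sentinel) when the null has zero spread; the
    empirical p-value uses the +1 Monte-Carlo correction and is therefore
    never 0.
    """

    observed: int
    perm_mean: float
    perm_sd: float
    z: Optional[float]
    p_empirical: float
    n_perm: int
    alternative: str
    null: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))


def _summarize(observed: int, null: np.ndarray, alternative: str) -> PermutationResult:
    n_perm = len(null)
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    if alternative == "greater":
        extreme = int((null >= observed).sum())
    elif alternative == "less":
        extreme = int((null <= observed).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + extreme) / (n_perm + 1)
    z = (observed - mean) / sd if sd > 0 else None
    return PermutationResult(
        observed=observed, perm_mean=mean, perm_sd=sd, z=z,
        p_empirical=p, n_perm=n_perm, alternative=alternative, null=null,
    )


def _universe_setup(query: Sequence, universe: Sequence, subject) -> Tuple[np.ndarray, np.ndarray]:
    """Overlap indicator over the universe plus the query's indices in it.

    Query membership in the universe is by identity key (chrom, start, end);
    a query region absent from the universe is a contract violation.
    """
    u_tuples = as_tuples(universe)
    key_to_idx: Dict[Tuple[str, int, int], int] = {}
    for i, key in enumerate(u_tuples):
        key_to_idx.setdefault(key, i)
    q_idx = []
    for key in as_tuples(query):
        if key not in key_to_idx:
            raise ValueError(f"query region {key} is not a member of the universe")
        q_idx.append(key_to_idx[key])
    index = subject if isinstance(subject, SubjectIndex) else SubjectIndex(subject)
    u_hit = index.mask(u_tuples)
    return u_hit, np.array(q_idx, dtype=np.intp)


def resample_permutation_test(
    query: Sequence,
    universe: Sequence,
    subject: Sequence,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    alternative: str = "greater",
    rng: Optional[np.random.Generator] = None,
) -> PermutationResult:
    """Universe-resampling overlap test.

    Each permutation draws |query| regions from the universe uniformly
    without replacement and counts how many overlap the subject.  Because
    draws are subsets of a fixed universe, the per-region overlap indicator
    is precomputed once and each permutation reduces to a subset sum —
    identical in distribution to re-counting overlaps per draw.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(universe) < len(query):
        raise ValueError("universe smaller than query")
    subject_index = subject if isinstance(subject, SubjectIndex) else SubjectIndex(subject)
    u_hit, q_idx = _universe_setup(query, universe, subject_index)
    observed = int(u_hit[q_idx].sum())
    if rng is None:
        rng = np.random.default_rng(seed)
    k, n = len(q_idx), len(u_hit)
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        null[i] = u_hit[rng.choice(n, size=k, replace=False)].sum()
    return _summarize(observed, null, alternative)


def _chrom_offsets(spaces: Sequence[Tuple[str, int, int]], spacer: int = 1000) -> Dict[str, int]:
    offsets: Dict[str, int] = {}
    cursor = 0
    for chrom in sorted({s[0] for s in spaces}):
        offsets[chrom] = cursor
        extent = max(s[2] for s in spaces if s[0] == chrom)
        cursor += extent + spacer
    return offsets


def randomize_regions_test(
    query: Sequence,
    mappable_space: Sequence,
    subject: Sequence,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    alternative: str = "greater",
) -> PermutationResult:
    """Uniform-relocation overlap test.

    Each permutation independently relocates every query region —
    length-preserving, uniform over all valid placements in the mappable
    space (across chromosomes) — and recounts the overlap with the subject.
    """
    spaces = as_tuples(mappable_space)
    if not spaces:
        raise ValueError("mappable space is empty")
    q_tuples = as_tuples(query)
    subject_index = subject if isinstance(subject, SubjectIndex) else SubjectIndex(subject)
    observed = count_overlaps(q_tuples, subject_index)

    # Work in a concatenated coordinate axis so a single searchsorted covers
    # all chromosomes; chromosomes are padded apart so intervals never touch.
    offsets = _chrom_offsets(spaces)
    m_start = np.array([offsets[c] + s for c, s, _ in spaces], dtype=np.int64)
    m_len = np.array([e - s for _, s, e in spaces], dtype=np.int64)

    g_sub_starts: List[np.ndarray] = []
    g_sub_ends: List[np.ndarray] = []
    for chrom, off in offsets.items():
        s = subject_index._starts.get(chrom)
        if s is not None and len(s):
            g_sub_starts.append(s + off)
            g_sub_ends.append(subject_index._ends[chrom] + off)
    if g_sub_starts:
        sub_s = np.concatenate(g_sub_starts)
        sub_e = np.concatenate(g_sub_ends)
        order = np.argsort(sub_s)
        sub_s, sub_e = sub_s[order], sub_e[order]
    else:
        sub_s = sub_e = np.array([], dtype=np.int64)

    rng = np.random.default_rng(seed)
    lengths = np.array([e - s for _, s, e in q_tuples], dtype=np.int64)
    null = np.zeros(n_perm, dtype=np.int64)
    for length in np.unique(lengths):
        valid = np.maximum(m_len - length + 1, 0)
        total = int(valid.sum())
        if total == 0:
            bad = [i for i, L in enumerate(lengths) if L == length]
            raise ValueError(
                f"query region(s) {bad} of length {length} fit in no mappable interval"
            )
        cum = np.cumsum(valid)
        count = int((lengths == length).sum())
        draws = rng.integers(0, total, size=(n_perm, count))
        which = np.searchsorted(cum, draws, side="right")
        before = np.where(which > 0, cum[which - 1], 0)
        starts = m_start[which] + (draws - before)
        ends = starts + length
        if len(sub_s):
            idx = np.searchsorted(sub_e, starts, side="right")
            ok = idx < len(sub_s)
            hit = np.zeros_like(starts, dtype=bool)
            hit[ok] = sub_s[idx[ok]] < ends[ok]
            null += hit.sum(axis=1)
    return _summarize(observed, null, alternative)


@dataclass
class ShiftProfile:
    """z-score of the resampling test as a function of query translation."""

    offsets: List[int]
    z_scores: List[Optional[float]]
    n_dropped: List[int]


def shifted_zscore_profile(
    query: Sequence,
    universe: Sequence,
    subject: Sequence,
    offsets: Sequence[int],
    n_perm: int = 1000,
    seed: Optional[int] = None,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> ShiftProfile:
    """Resampling z recomputed after translating the query by each offset.

    The offset grid must include 0, whose entry reproduces the unshifted z
    (the same seed schedule is used at every offset).  Shifted regions are
    clipped to chromosome bounds; regions clipped away entirely are dropped
    from that offset's query and counted.
    """
    offsets = list(offsets)
    if 0 not in offsets:
        raise ValueError("offset grid must include 0")
    subject_index = SubjectIndex(subject)
    u_hit, _ = _universe_setup(query, universe, subject_index)
    n = len(u_hit)

    z_scores: List[Optional[float]] = []
    dropped: List[int] = []
    q_tuples = as_tuples(query)
    for d in offsets:
        shifted: List[Tuple[str, int, int]] = []
        n_drop = 0
        for chrom, s, e in q_tuples:
            ns, ne = s + d, e + d
            ns = max(ns, 0)
            if chrom_lengths is not None and chrom in chrom_lengths:
                ne = min(ne, chrom_lengths[chrom])
            if ns >= ne:
                n_drop += 1
                continue
            shifted.append((chrom, ns, ne))
        observed = count_overlaps(shifted, subject_index)
        rng = np.random.default_rng(seed)
        k = len(shifted)
        null = np.empty(n_perm, dtype=np.int64)
        for i in range(n_perm):
            null[i] = u_hit[rng.choice(n, size=k, replace=False)].sum()
        res = _summarize(observed, null, "greater")
        z_scores.append(res.z)
        dropped.append(n_drop)
    return ShiftProfile(offsets=offsets, z_scores=z_scores, n_dropped=dropped)


def non_n_intervals(genome) -> List[Tuple[str, int, int]]:
    """Mappable space default: maximal non-N intervals of a genome."""
    out: List[Tuple[str, int, int]] = []
    for chrom in genome.chrom_names:
        seq = genome.sequences[chrom]
        start = None
        for i, ch in enumerate(seq):
            if ch != "N":
                if start is None:
                    start = i
            elif start is not None:
                out.append((chrom, start, i))
                start = None
        if start is not None:
            out.append((chrom, start, len(seq)))
    return out
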