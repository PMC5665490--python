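"""Independent brute-force reference implementations used only by tests.

These are deliberately written in the most literal way possible — sliding
windows, transitive closures, all-pairs scans — and share no code with the
package, so agreement between the two routes is meaningful.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Sequence, Tuple

Occurrence = Tuple[int, str]  # (start, strand)
Region = dict


def oracle_find_occurrences(seq: str) -> List[Occurrence]:
    out = []
    for i in range(len(seq) - 3):
        window = seq[i : i + 4]
        if window == "GGAA":
            out.append((i, "+"))
        elif window == "TTCC":
            out.append((i, "-"))
    return out


def _closure_groups(occs: List[Occurrence], max_gap: int) -> List[List[Occurrence]]:
    """Group occurrences by the transitive closure of the gap relation."""
    n = len(occs)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            lo, hi = (i, j) if occs[i][0] <= occs[j][0] else (j, i)
            gap = occs[hi][0] - (occs[lo][0] + 4)
            if gap <= max_gap:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[rb] = ra
    groups: Dict[int, List[Occurrence]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(occs[i])
    out = [sorted(g) for g in groups.values()]
    out.sort(key=lambda g: g[0][0])
    return out


def _stats(occs: List[Occurrence]) -> Region:
    start = occs[0][0]
    end = occs[-1][0] + 4
    max_run = 0
    for strand in "+-":
        run = 0
        prev_end = None
        for s, st in occs:
            if st != strand:
                run = 0
                prev_end = None
                continue
            if prev_end is not None and s == prev_end:
                run += 1
            else:
                run = 1
            prev_end = s + 4
            max_run = max(max_run, run)
    strands = {st for _, st in occs}
    if strands == {"+"}:
        cls = "pure_forward"
    elif strands == {"-"}:
        cls = "pure_reverse"
    else:
        cls = "mixed"
    return {
        "start": start,
        "end": end,
        "total": len(occs),
        "max_consecutive": max_run,
        "density": len(occs) * 4 / (end - start) * 100.0,
        "class": cls,
        "occs": list(occs),
    }


def oracle_scan(seq: str, max_gap: int = 20) -> List[Region]:
    """Full reference chain: scan, chain by closure, split mixed regions,
    compute statistics.  Returns final regions sorted by start."""
    occs = oracle_find_occurrences(seq)
    final: List[Region] = []
    for group in _closure_groups(occs, max_gap):
        if len(group) < 2:
            continue
        region = _stats(group)
        if region["class"] != "mixed":
            final.append(region)
            continue
        # split into maximal same-strand stretches
        pieces: List[List[Occurrence]] = []
        for strand, run in itertools.groupby(group, key=lambda o: o[1]):
            pieces.append(list(run))
        if len(group) == 2:  # one motif per strand: discounted
            continue
        final.extend(_stats(piece) for piece in pieces)
    final.sort(key=lambda r: r["start"])
    return final


def oracle_count_overlaps(query: Sequence[Tuple[str, int, int]],
                          subject: Sequence[Tuple[str, int, int]]) -> int:
    count = 0
    for qc, qs, qe in query:
        for sc, ss, se in subject:
            if qc == sc and qs < se and ss < qe:
                count += 1
                break
    return count


def oracle_spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Midrank ties, then the Pearson correlation of the ranks."""

    def midranks(v: Sequence[float]) -> List[float]:
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mid = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = mid
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


def oracle_welch_t(a: Sequence[float], b: Sequence[float]) -> float:
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    return (ma - mb) / (va / na + vb / nb) ** 0.5


def random_motif_sequence(rng, length: int = 2000, n_inserts: int = 8) -> str:
    """Random background with planted GGAA/TTCC runs, so chained regions of
    varied composition actually occur at test scale."""
    seq = list("".join(rng.choice(["A", "C", "G", "T"], size=length)))
    for _ in range(int(rng.poisson(n_inserts))):
        run_len = int(rng.integers(1, 6))
        motif = "GGAA" if rng.random() < 0.5 else "TTCC"
        pos = int(rng.integers(0, length - 4 * run_len))
        block = motif * run_len
        seq[pos : pos + len(block)] = list(block)
    return "".join(seq)
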