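"""Regeneration-responsive element (RRE) calling.

Two peaks "match" when they lie on the same chromosome and their centers
are within `d` bp (default 100) of each other — the center-distance reading
of peak merging at distance 100. Emerging peaks are treated peaks with no
matching untreated peak; organ-level RRE sets are unioned with
center-distance dedup; Venn partitioning assigns connected components of
the cross-set proximity graph to cell-type combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Tuple

import numpy as np

from .core import Peak

DEFAULT_MERGE_DISTANCE = 100


@dataclass
class RRESet:
    """Deduplicated per-cell-type RRE collection."""

    cell_type: str
    peaks: List[Peak]
    provenance: List[str] = field(default_factory=list)


def _centers_by_chrom(peaks: Sequence[Peak]) -> Dict[str, Tuple[np.ndarray, List[int]]]:
    """chrom -> (sorted center array, original indices in the same order)."""
    by_chrom: Dict[str, List[int]] = {}
    for i, p in enumerate(peaks):
        by_chrom.setdefault(p.chrom, []).append(i)
    out = {}
    for chrom, idxs in by_chrom.items():
        centers = np.array([peaks[i].center for i in idxs])
        order = np.argsort(centers, kind="stable")
        out[chrom] = (centers[order], [idxs[k] for k in order])
    return out


def shared_peaks(
    set_a: Sequence[Peak], set_b: Sequence[Peak], d: int = DEFAULT_MERGE_DISTANCE
) -> List[Tuple[Peak, Peak]]:
    """All (peak_a, peak_b) pairs with same chromosome and |center_a-center_b| <= d."""
    if d < 0:
        raise ValueError(f"merge distance must be >= 0, got {d}")
    b_index = _centers_by_chrom(set_b)
    pairs: List[Tuple[Peak, Peak]] = []
    for pa in set_a:
        if pa.chrom not in b_index:
            continue
        centers, idxs = b_index[pa.chrom]
        lo = np.searchsorted(centers, pa.center - d, side="left")
        hi = np.searchsorted(centers, pa.center + d, side="right")
        for k in range(lo, hi):
            pairs.append((pa, set_b[idxs[k]]))
    return pairs


def emerging_peaks(
    treated: Sequence[Peak],
    untreated: Sequence[Peak],
    d: int = DEFAULT_MERGE_DISTANCE,
) -> RRESet:
    """Treated peaks with no untreated peak center within d bp on the same chromosome."""
    cell_types = {p.cell_type for p in treated} | {p.cell_type for p in untreated}
    cell_types.discard("")
    if len(cell_types) > 1:
        raise ValueError(f"cell-type mismatch between inputs: {sorted(cell_types)}")
    matched = {id(pa) for pa, _ in shared_peaks(treated, untreated, d)}
    emerging = [p for p in treated if id(p) not in matched]
    cell_type = next(iter(cell_types), "")
    return RRESet(cell_type=cell_type, peaks=emerging)


def combine_organs(
    rres_a: RRESet, rres_b: RRESet, d: int = DEFAULT_MERGE_DISTANCE
) -> RRESet:
    """Union two organ-level RRE sets, deduplicating center matches.

    When two peaks' centers are within d, the one with smaller p-value wins
    (missing p counts as 1; ties broken by smaller start, then organ order).
    """
    if rres_a.cell_type != rres_b.cell_type:
        raise ValueError(
            f"cell types differ: {rres_a.cell_type!r} vs {rres_b.cell_type!r}"
        )
    candidates = list(rres_a.peaks) + list(rres_b.peaks)

    def priority(p: Peak) -> Tuple[float, int]:
        return (p.p_value if p.p_value is not None else 1.0, p.start)

    # greedy selection in priority order; a peak is kept unless a
    # previously-kept peak matches it
    order = sorted(range(len(candidates)), key=lambda i: priority(candidates[i]))
    kept: List[Peak] = []
    for i in order:
        p = candidates[i]
        if not any(
            q.chrom == p.chrom and abs(q.center - p.center) <= d for q in kept
        ):
            kept.append(p)
    kept.sort(key=lambda p: (p.chrom, p.start, p.peak_id))
    return RRESet(
        cell_type=rres_a.cell_type,
        peaks=kept,
        provenance=list(dict.fromkeys(rres_a.provenance + rres_b.provenance)),
    )


def venn_partition(
    rre_sets: Dict[str, Sequence[Peak]], d: int = DEFAULT_MERGE_DISTANCE
) -> Dict[FrozenSet[str], int]:
    """Count proximity-graph connected components per cell-type combination.

    Every peak from every set is a node; nodes are connected when their
    centers are within d on the same chromosome (regardless of which set
    they come from). Each connected component contributes 1 to the count of
    the combination of cell types present in it.
    """
    if len(rre_sets) < 2:
        raise ValueError("need >=2 sets for a Venn partition")
    nodes: List[Tuple[str, Peak]] = [
        (ct, p) for ct, peaks in rre_sets.items() for p in peaks
    ]
    n = len(nodes)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_chrom: Dict[str, List[int]] = {}
    for i, (_, p) in enumerate(nodes):
        by_chrom.setdefault(p.chrom, []).append(i)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: nodes[i][1].center)
        for a_pos, i in enumerate(idxs):
            ci = nodes[i][1].center
            for j in idxs[a_pos + 1 :]:
                if nodes[j][1].center - ci > d:
                    break
                union(i, j)

    members: Dict[int, set] = {}
    for i, (ct, _) in enumerate(nodes):
        members.setdefault(find(i), set()).add(ct)
    counts: Dict[FrozenSet[str], int] = {}
    for cts in members.values():
        key = frozenset(cts)
        counts[key] = counts.get(key, 0) + 1
    return counts
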