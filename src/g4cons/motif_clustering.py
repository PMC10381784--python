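"""Clusters of G4 motifs with intersecting alignment-column coordinates.

Motif coordinates (promoter positions) are mapped through a block fragment's
gap structure into 1-based alignment columns.  Within one block and strand,
clusters are maximal sets of column intervals from two or more distinct
species that share a common column window of at least ``min_intersection``
columns.  Clustering is a deterministic greedy: the cluster maximising
(member count, common-window length, leftmost window) is emitted first and
its members are removed, so each interval joins at most one cluster and two
intervals of the same species never join the same cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from g4cons.block_alignment import AlignmentBlock, BlockFragment
from g4cons.g4_scanner import G4Motif

DEFAULT_MIN_INTERSECTION = 12  # four tracts x three guanines


@dataclass(frozen=True)
class ColumnInterval:
    """A motif's footprint in alignment columns of one block fragment."""

    block_name: str
    species_code: str
    first_col: int
    last_col: int
    strand: str
    motif_ref: G4Motif
    partial: bool = False  # motif extends past the fragment edge

    @property
    def n_columns(self) -> int:
        return self.last_col - self.first_col + 1

    def overlap(self, other: "ColumnInterval") -> int:
        return min(self.last_col, other.last_col) - max(self.first_col, other.first_col) + 1


@dataclass
class MotifCluster:
    block_name: str
    strand: str
    members: list[ColumnInterval]
    common: tuple[int, int]

    @property
    def low_confidence(self) -> bool:
        """True when every member is a partial-overlap interval."""
        return all(m.partial for m in self.members)

    def species(self) -> list[str]:
        return [m.species_code for m in self.members]


def map_motif_to_columns(m: G4Motif, f: BlockFragment, block_name: str = "") -> Optional[ColumnInterval]:
    """Column interval of the motif positions lying inside the fragment.

    Returns None when the motif does not overlap [f.start, f.end]; a motif
    that extends past either fragment edge is returned flagged ``partial``.
    """
    if m.species_code != f.species_code:
        raise ValueError(f"species mismatch: motif {m.species_code}, fragment {f.species_code}")
    lo = max(m.start, f.start)
    hi = min(m.end, f.end)
    if lo > hi:
        return None
    c0 = f.column_of(lo)
    c1 = f.column_of(hi)
    assert c0 is not None and c1 is not None
    return ColumnInterval(
        block_name=block_name,
        species_code=m.species_code,
        first_col=c0,
        last_col=c1,
        strand=m.strand,
        motif_ref=m,
        partial=(m.start < f.start or m.end > f.end),
    )


def map_block_motifs(
    block: AlignmentBlock, motifs: list[G4Motif]
) -> list[ColumnInterval]:
    """All column intervals of the given motifs within one block."""
    by_species: dict[str, BlockFragment] = {f.species_code: f for f in block.fragments}
    out = []
    for m in motifs:
        f = by_species.get(m.species_code)
        if f is None:
            continue
        ci = map_motif_to_columns(m, f, block.name)
        if ci is not None:
            out.append(ci)
    return out


def _best_cluster(
    intervals: list[ColumnInterval], min_intersection: int
) -> Optional[tuple[list[ColumnInterval], tuple[int, int]]]:
    """The single best cluster under the greedy objective, or None.

    Candidate windows run over every (interval start, interval end) pair of
    length >= min_intersection; an optimal common window is the intersection
    of its members, so its bounds are interval endpoints.  For a window,
    eligible intervals are those fully containing it; one interval per
    species is taken (the leftmost, then shortest).  The common window is
    the intersection of the chosen members, which by construction has at
    least ``min_intersection`` columns.
    """
    starts = sorted({iv.first_col for iv in intervals})
    ends = sorted({iv.last_col for iv in intervals})
    best: Optional[tuple[tuple[int, int, int], list[ColumnInterval], tuple[int, int]]] = None
    for a in starts:
        for b in ends:
            if b - a + 1 < min_intersection:
                continue
            covering = [iv for iv in intervals if iv.first_col <= a and iv.last_col >= b]
            by_species: dict[str, ColumnInterval] = {}
            for iv in sorted(covering, key=lambda v: (v.first_col, v.last_col, v.species_code)):
                by_species.setdefault(iv.species_code, iv)
            members = sorted(by_species.values(), key=lambda v: v.species_code)
            if len(members) < 2:
                continue
            common = (max(v.first_col for v in members), min(v.last_col for v in members))
            key = (len(members), common[1] - common[0] + 1, -common[0])
            if best is None or key > best[0]:
                best = (key, members, common)
    if best is None:
        return None
    return best[1], best[2]


def find_clusters(
    intervals: list[ColumnInterval], min_intersection: int = DEFAULT_MIN_INTERSECTION
) -> list[MotifCluster]:
    """Greedy extraction of motif clusters from one block and strand.

    Repeatedly emits the cluster maximising (member count, common-window
    length, leftmost common window) and removes its members; singletons are
    never emitted.  Every pair of members shares the cluster's common window
    and hence intersects by at least ``min_intersection`` columns.
    """
    if not intervals:
        return []
    strands = {iv.strand for iv in intervals}
    if len(strands) > 1:
        raise ValueError("find_clusters requires intervals from a single strand")
    blocks = {iv.block_name for iv in intervals}
    if len(blocks) > 1:
        raise ValueError("find_clusters requires intervals from a single block")
    pool = list(intervals)
    out: list[MotifCluster] = []
    while True:
        hit = _best_cluster(pool, min_intersection)
        if hit is None:
            break
        members, common = hit
        out.append(
            MotifCluster(
                block_name=members[0].block_name,
                strand=members[0].strand,
                members=members,
                common=common,
            )
        )
        chosen = set(id(m) for m in members)
        pool = [iv for iv in pool if id(iv) not in chosen]
    return out


def cluster_table(clusters: list[MotifCluster]) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    rows = []
    for i, c in enumerate(clusters, 1):
        for m in c.members:
            rows.append(
                {
                    "block_name": c.block_name,
                    "cluster_id": i,
                    "strand": c.strand,
                    "common_first": c.common[0],
                    "common_last": c.common[1],
                    "species_code": m.species_code,
                    "first_col": m.first_col,
                    "last_col": m.last_col,
                    "partial": m.partial,
                }
            )
    return pd.DataFrame(rows)
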