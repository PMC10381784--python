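"""Groups of conserved G4 motifs: shared G-tract alignment columns.

A cluster of intersecting motifs becomes a *conserved group* when a single
4-tuple of tract column intervals is feasible for two or more species, i.e.
on the motif-bearing strand every placed column holds G in each supporting
row (C on the coding strand for noncoding-strand motifs), with loop lengths
of 1–30 nt and an ungapped span of at most 45 nt in every supporting row.
Tract placements may shift locally inside longer G-runs (a GGGG run offers
the placements GGG., .GGG and GGGG), and the tuple realisable by the most
species wins — including species in which the scanner itself reported no
motif, as long as their block row supports the placement.

The search is exact: all placements per species are enumerated within the
cluster's common window extended by one motif span on each side.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from statistics import median
from typing import Optional

from g4cons.block_alignment import AlignmentBlock
from g4cons.g4_scanner import MAX_LOOP, MAX_SPAN, MIN_TRACT
from g4cons.motif_clustering import MotifCluster

Columns = tuple[int, int]
PlacementTuple = tuple[Columns, Columns, Columns, Columns]

_ZONE_ORDER = {"core": 0, "proximal": 1, "distal": 2}


@dataclass(frozen=True)
class TractPlacement:
    """Four feasible tract column intervals for one species' block row."""

    species_code: str
    columns: PlacementTuple  # ascending column order


@dataclass
class ConservedGroup:
    group_id: str
    block_name: str
    strand: str
    tract_columns: PlacementTuple
    loop_columns: tuple[Columns, Columns, Columns]
    members: list[str]
    non_members: list[str]
    zone: Optional[str] = None
    member_spans: dict[str, int] = field(default_factory=dict)
    low_confidence: bool = False
    order_code: str = ""

    @property
    def first_col(self) -> int:
        return self.tract_columns[0][0]

    @property
    def last_col(self) -> int:
        return self.tract_columns[3][1]

    @property
    def total_loop_columns(self) -> int:
        return sum(b - a + 1 for a, b in self.loop_columns)

    @property
    def length(self) -> float:
        """Median ungapped member span (used for length distributions)."""
        return median(self.member_spans.values()) if self.member_spans else 0.0


def _tract_symbol(strand: str) -> str:
    # noncoding-strand motifs appear as C-tracts on coding-strand rows
    return "G" if strand == "coding" else "C"


def _symbol_runs(row: str, symbol: str, lo: int, hi: int) -> list[tuple[int, int]]:
    """Maximal runs of ``symbol`` in columns [lo, hi] of a gapped row."""
    runs = []
    start = None
    for col in range(lo, hi + 1):
        if row[col - 1] == symbol:
            if start is None:
                start = col
        else:
            if start is not None and col - start >= MIN_TRACT:
                runs.append((start, col - 1))
            start = None
    if start is not None and hi - start + 1 >= MIN_TRACT:
        runs.append((start, hi))
    return runs


def enumerate_placements(
    cluster: MotifCluster, block: AlignmentBlock, flank: int = MAX_SPAN
) -> dict[str, list[TractPlacement]]:
    """All feasible tract placements per block species near the cluster window.

    Every sub-interval of length >= 3 of each G-run (C-run for noncoding
    clusters) is a tract option; 4-tuples are kept when, on the species' own
    ungapped sequence, consecutive tracts are separated by 1–30 nt loops and
    the full span is at most 45 nt.  All block rows are searched, not only
    cluster members: a species whose motif the scanner missed (e.g. a
    shortened terminal tract) can still support a group placement.
    """
    symbol = _tract_symbol(cluster.strand)
    lo = max(1, cluster.common[0] - flank)
    hi = min(block.width, cluster.common[1] + flank)
    out: dict[str, list[TractPlacement]] = {}
    for frag in block.fragments:
        row = frag.row
        # cumulative non-gap counts for ungapped loop/span arithmetic
        cum = [0] * (len(row) + 1)
        for i, ch in enumerate(row, 1):
            cum[i] = cum[i - 1] + (ch != "-")

        def ungapped(a: int, b: int) -> int:  # bases in columns [a, b]
            return cum[b] - cum[a - 1] if a <= b else 0

        options: list[Columns] = []
        for rs, re_ in _symbol_runs(row, symbol, lo, hi):
            for s in range(rs, re_ - MIN_TRACT + 2):
                for e in range(s + MIN_TRACT - 1, re_ + 1):
                    options.append((s, e))
        options.sort()
        placements: list[TractPlacement] = []

        def extend(chain: list[Columns]) -> None:
            if len(chain) == 4:
                if ungapped(chain[0][0], chain[3][1]) <= MAX_SPAN:
                    placements.append(TractPlacement(frag.species_code, tuple(chain)))
                return
            prev_end = chain[-1][1]
            for s, e in options:
                if s <= prev_end + 1:
                    continue
                loop = ungapped(prev_end + 1, s - 1)
                if not (1 <= loop <= MAX_LOOP):
                    continue
                if ungapped(chain[0][0], e) > MAX_SPAN:
                    continue
                chain.append((s, e))
                extend(chain)
                chain.pop()

        for first in options:
            extend([first])
        out[frag.species_code] = placements
    return out


def call_group(
    placements: dict[str, list[TractPlacement]],
    min_members: int = 2,
    *,
    cluster: MotifCluster | None = None,
    block: AlignmentBlock | None = None,
    group_id: str = "",
) -> Optional[ConservedGroup]:
    """Select the tract-column 4-tuple realisable by the most species.

    Ties are broken by more total tract columns, then smaller first column,
    then lexicographically on the tuple itself; returns None when the best
    tuple has fewer than ``min_members`` supporters.  The result is invariant
    to species input order.
    """
    support: dict[PlacementTuple, set[str]] = defaultdict(set)
    for code, plist in placements.items():
        for p in plist:
            support[p.columns].add(code)
    best: Optional[tuple[tuple[int, int, int], PlacementTuple]] = None
    for cols, codes in support.items():
        total = sum(e - s + 1 for s, e in cols)
        key = (len(codes), total, -cols[0][0])
        if best is None or key > best[0] or (key == best[0] and cols < best[1]):
            best = (key, cols)
    if best is None or len(support[best[1]]) < min_members:
        return None
    cols = best[1]
    members = sorted(support[cols])
    loop_columns = tuple((cols[i][1] + 1, cols[i + 1][0] - 1) for i in range(3))

    strand = cluster.strand if cluster else "coding"
    block_name = cluster.block_name if cluster else (block.name if block else "")
    non_members: list[str] = []
    spans: dict[str, int] = {}
    zone = None
    low_confidence = False
    if block is not None:
        non_members = sorted(set(block.species()) - set(members))
        for code in members:
            row = block.fragment(code).row
            spans[code] = sum(
                1 for ch in row[cols[0][0] - 1 : cols[3][1]] if ch != "-"
            )
    if cluster is not None:
        zones = [
            m.motif_ref.zone
            for m in cluster.members
            if m.species_code in members and m.motif_ref.zone is not None
        ]
        if zones:
            counts = Counter(zones)
            top = max(counts.values())
            zone = min(
                (z for z, c in counts.items() if c == top), key=lambda z: _ZONE_ORDER[z]
            )
        low_confidence = all(
            m.partial for m in cluster.members if m.species_code in members
        ) and any(m.species_code in members for m in cluster.members)
    return ConservedGroup(
        group_id=group_id or f"{block_name}:{strand}:{cols[0][0]}",
        block_name=block_name,
        strand=strand,
        tract_columns=cols,
        loop_columns=loop_columns,  # type: ignore[arg-type]
        members=members,
        non_members=non_members,
        zone=zone,
        member_spans=spans,
        low_confidence=low_confidence,
    )


def call_cluster_group(
    cluster: MotifCluster, block: AlignmentBlock, min_members: int = 2, group_id: str = ""
) -> Optional[ConservedGroup]:
    """Convenience: enumerate placements and call the group for one cluster."""
    placements = enumerate_placements(cluster, block)
    return call_group(
        placements, min_members, cluster=cluster, block=block, group_id=group_id
    )


def summarize_groups(groups: list[ConservedGroup]) -> dict[str, "pandas.DataFrame"]:  # noqa: F821
    """Per-order counts by strand and zone, plus a group-length table."""
    import pandas as pd

    zones = ["core", "proximal", "distal"]
    count_rows = []
    for order in sorted({g.order_code for g in groups} or {""}):
        row = {"order_code": order}
        for strand in ("coding", "noncoding"):
            for zone in zones:
                row[f"{strand}_{zone}"] = sum(
                    1
                    for g in groups
                    if g.order_code == order and g.strand == strand and g.zone == zone
                )
            row[f"{strand}_total"] = sum(
                1 for g in groups if g.order_code == order and g.strand == strand
            )
        count_rows.append(row)
    lengths = pd.DataFrame(
        {
            "group_id": [g.group_id for g in groups],
            "order_code": [g.order_code for g in groups],
            "strand": [g.strand for g in groups],
            "zone": [g.zone for g in groups],
            "n_members": [len(g.members) for g in groups],
            "length": [g.length for g in groups],
        }
    )
    return {"counts": pd.DataFrame(count_rows), "lengths": lengths}


def group_table(groups: list[ConservedGroup]) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    rows = []
    for g in groups:
        rows.append(
            {
                "group_id": g.group_id,
                "block_name": g.block_name,
                "strand": g.strand,
                "zone": g.zone,
                "n_members": len(g.members),
                "members": ",".join(g.members),
                "non_members": ",".join(g.non_members),
                "tracts": ";".join(f"{s}-{e}" for s, e in g.tract_columns),
                "loops": ";".join(f"{s}-{e}" for s, e in g.loop_columns),
                "median_length": g.length,
                "low_confidence": g.low_confidence,
            }
        )
    return pd.DataFrame(rows)


def write_group_slice(group: ConservedGroup, block: AlignmentBlock, path) -> None:
    """Aligned-FASTA slice of the group region with tract/loop annotation."""
    lo, hi = group.first_col, group.last_col
    marks = []
    for col in range(lo, hi + 1):
        if any(s <= col <= e for s, e in group.tract_columns):
            marks.append("T")
        elif any(s <= col <= e for s, e in group.loop_columns):
            marks.append("L")
        else:
            marks.append(".")
    with open(path, "w") as fh:
        fh.write(f"; group {group.group_id} strand={group.strand} columns {lo}-{hi}\n")
        fh.write("; " + "".join(marks) + "\n")
        for frag in block.fragments:
            role = "member" if frag.species_code in group.members else "non-member"
            sub = frag.row[lo - 1 : hi]
            fh.write(f">{frag.species_code}/{frag.start}-{frag.end} {role}\n{sub}\n")
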