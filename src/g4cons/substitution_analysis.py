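"""Substitution densities in conserved-group loops vs. matched controls.

Within a conserved group, member rows carry no substitutions in tract
columns by definition; loop columns are compared base-by-base against the
member consensus and every discordant non-gap base is one substitution
record.  Tract substitutions are counted on the *non-member* rows of the
block against the tract consensus symbol.  For each group a control
sub-alignment is selected with the same species and the same total column
length as the loops, free of predicted G4 motifs and of gap runs of three
or more; loop and control substitution densities form one pair, and the
per-order paired one-sided Wilcoxon signed-rank test (loops > control) with
a Holm–Bonferroni step-down across orders gives the family-wise inference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from g4cons.block_alignment import AlignmentBlock
from g4cons.conserved_groups import ConservedGroup
from g4cons.g4_scanner import G4Motif

GAP = "-"

#: maximum gap run allowed in a control row
MAX_CONTROL_GAP_RUN = 2


@dataclass(frozen=True)
class SubstitutionRecord:
    group_id: str
    column: int
    region: str  # loop1..loop3, tract1..tract4, control
    species_code: str
    observed: str
    consensus: str

    @property
    def type_label(self) -> str:
        """Unordered pair label in coding-strand orientation, e.g. ``C↔T``."""
        a, b = sorted((self.observed, self.consensus))
        return f"{a}↔{b}"


@dataclass(frozen=True)
class ControlAlignment:
    block_name: str
    segments: tuple[tuple[int, int], ...]  # 1-based inclusive column spans
    source: str  # same_block_upstream | same_block_downstream | same_block_split | other_block

    @property
    def n_columns(self) -> int:
        return sum(b - a + 1 for a, b in self.segments)


@dataclass(frozen=True)
class DensityPair:
    group_id: str
    loop_density: float
    control_density: float
    loop_total_length: int
    control_source: str


@dataclass
class OrderTestResult:
    order_code: str
    n_pairs: int
    p_raw: Optional[float]
    p_holm: Optional[float]
    n_loop_exceeds_control: int
    method: str = ""
    n_excluded: int = 0


def column_consensus(rows: Sequence[str], columns: Sequence[int]) -> str:
    """Most frequent non-gap base per column; ties go to the alphabetically
    smallest base; an all-gap column yields a gap."""
    if len(rows) < 2:
        raise ValueError("consensus needs at least two rows")
    out = []
    for col in columns:
        counts: dict[str, int] = {}
        for r in rows:
            ch = r[col - 1]
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            out.append(GAP)
        else:
            top = max(counts.values())
            out.append(min(ch for ch, c in counts.items() if c == top))
    return "".join(out)


def count_loop_substitutions(
    group: ConservedGroup, block: AlignmentBlock
) -> list[SubstitutionRecord]:
    """Consensus-discordant member bases in the group's loop columns.

    The consensus is taken over member rows only.  Gap positions are not
    substitutions (they enter the density through the fixed column-length
    denominator, not the count).
    """
    member_rows = [block.fragment(c).row for c in group.members]
    records = []
    for li, (a, b) in enumerate(group.loop_columns, 1):
        cols = list(range(a, b + 1))
        if not cols:
            continue
        cons = column_consensus(member_rows, cols)
        for code in group.members:
            row = block.fragment(code).row
            for c, cn in zip(cols, cons):
                ch = row[c - 1]
                if ch != GAP and cn != GAP and ch != cn and ch != "N":
                    records.append(
                        SubstitutionRecord(group.group_id, c, f"loop{li}", code, ch, cn)
                    )
    return records


def count_tract_substitutions(
    group: ConservedGroup, block: AlignmentBlock
) -> list[SubstitutionRecord]:
    """Non-member bases differing from the tract consensus symbol.

    Member rows are all-G (all-C on the coding strand for noncoding-strand
    groups) in tract columns by construction, so only the block rows that
    failed to join the group can contribute; this is the disruptive-position
    spectrum.  Labels are reported in coding-strand orientation.
    """
    symbol = "G" if group.strand == "coding" else "C"
    records = []
    for ti, (a, b) in enumerate(group.tract_columns, 1):
        for code in group.non_members:
            row = block.fragment(code).row
            for c in range(a, b + 1):
                ch = row[c - 1]
                if ch != GAP and ch != symbol and ch != "N":
                    records.append(
                        SubstitutionRecord(group.group_id, c, f"tract{ti}", code, ch, symbol)
                    )
    return records


# ---------------------------------------------------------------- controls


def _segment_eligible(
    block: AlignmentBlock,
    members: list[str],
    a: int,
    b: int,
    motifs_by_species: dict[str, list[tuple[int, int]]],
) -> bool:
    """A column segment is usable when no member row has a gap run of 3+
    inside it and no block row's promoter footprint intersects a predicted
    motif (the motif-free requirement covers every species, not only the
    group members)."""
    if a < 1 or b > block.width or a > b:
        return False
    member_set = set(members)
    for frag in block.fragments:
        if frag.species_code in member_set:
            seg = frag.row[a - 1 : b]
            run = 0
            for ch in seg:
                run = run + 1 if ch == GAP else 0
                if run > MAX_CONTROL_GAP_RUN:
                    return False
        # promoter footprint of the segment's non-gap positions
        positions = [frag.position_of(c) for c in range(a, b + 1)]
        positions = [p for p in positions if p is not None]
        if positions:
            lo, hi = positions[0], positions[-1]
            for ms, me in motifs_by_species.get(frag.species_code, ()):
                if ms <= hi and lo <= me:
                    return False
    return True


def select_control(
    group: ConservedGroup,
    blocks: list[AlignmentBlock],
    all_motifs: list[G4Motif],
) -> Optional[ControlAlignment]:
    """Motif-free control columns matching the group's species and loop length.

    Candidate windows of total length equal to the group's loop column count
    are scanned one column at a time outward from the group's edges: first
    upstream in the group's own block, then downstream, then split across
    both flanks, then left-to-right in any other block containing every
    member species.  The first eligible window wins.  Eligibility: no
    predicted G4 motif of any species intersects the window's promoter
    footprint and no member row has a gap run of 3 or more inside it.
    """
    L = group.total_loop_columns
    if L == 0:
        return None
    motifs_by_species: dict[str, list[tuple[int, int]]] = {}
    for m in all_motifs:
        motifs_by_species.setdefault(m.species_code, []).append((m.start, m.end))
    own = next(b for b in blocks if b.name == group.block_name)
    gs, ge = group.first_col, group.last_col

    # upstream, sliding away from the group edge
    for d in itertools.count(0):
        a, b = gs - L - d, gs - 1 - d
        if a < 1:
            break
        if _segment_eligible(own, group.members, a, b, motifs_by_species):
            return ControlAlignment(own.name, ((a, b),), "same_block_upstream")
    # downstream
    for d in itertools.count(0):
        a, b = ge + 1 + d, ge + L + d
        if b > own.width:
            break
        if _segment_eligible(own, group.members, a, b, motifs_by_species):
            return ControlAlignment(own.name, ((a, b),), "same_block_downstream")
    # split across the two flanks (at most two segments)
    for l1 in range(min(L - 1, gs - 1), 0, -1):
        up = (gs - l1, gs - 1)
        down = (ge + 1, ge + (L - l1))
        if down[1] <= own.width and _segment_eligible(
            own, group.members, *up, motifs_by_species
        ) and _segment_eligible(own, group.members, *down, motifs_by_species):
            return ControlAlignment(own.name, (up, down), "same_block_split")
    # any other block containing the same species
    member_set = set(group.members)
    for blk in blocks:
        if blk.name == group.block_name or not member_set <= set(blk.species()):
            continue
        for a in range(1, blk.width - L + 2):
            if _segment_eligible(blk, group.members, a, a + L - 1, motifs_by_species):
                return ControlAlignment(blk.name, ((a, a + L - 1),), "other_block")
    return None


def count_control_substitutions(
    group: ConservedGroup, control: ControlAlignment, blocks: list[AlignmentBlock]
) -> list[SubstitutionRecord]:
    """Consensus-discordant member bases in the control columns (same
    counting rule as for loops)."""
    blk = next(b for b in blocks if b.name == control.block_name)
    member_rows = [blk.fragment(c).row for c in group.members]
    records = []
    for a, b in control.segments:
        cols = list(range(a, b + 1))
        cons = column_consensus(member_rows, cols)
        for code in group.members:
            row = blk.fragment(code).row
            for c, cn in zip(cols, cons):
                ch = row[c - 1]
                if ch != GAP and cn != GAP and ch != cn and ch != "N":
                    records.append(
                        SubstitutionRecord(group.group_id, c, "control", code, ch, cn)
                    )
    return records


def density(records: Sequence, total_length: int) -> float:
    """Substitution count divided by total column length (may exceed 1)."""
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    n = len(records) if not isinstance(records, int) else records
    return n / total_length


def build_density_pairs(
    groups: list[ConservedGroup],
    blocks: list[AlignmentBlock],
    all_motifs: list[G4Motif],
) -> tuple[list[DensityPair], list[str]]:
    """One loop/control density pair per group; groups without an eligible
    control are returned separately as excluded."""
    pairs: list[DensityPair] = []
    excluded: list[str] = []
    for g in groups:
        control = select_control(g, blocks, all_motifs)
        if control is None:
            excluded.append(g.group_id)
            continue
        blk = next(b for b in blocks if b.name == g.block_name)
        loop_records = count_loop_substitutions(g, blk)
        ctrl_records = count_control_substitutions(g, control, blocks)
        L = g.total_loop_columns
        pairs.append(
            DensityPair(
                group_id=g.group_id,
                loop_density=density(loop_records, L),
                control_density=density(ctrl_records, control.n_columns),
                loop_total_length=L,
                control_source=control.source,
            )
        )
    return pairs, excluded


# ---------------------------------------------------------------- inference


def wilcoxon_paired_greater(
    pairs: Sequence[DensityPair] | Sequence[tuple[float, float]],
) -> tuple[Optional[float], str]:
    """One-sided paired Wilcoxon signed-rank p for loop > control.

    Zero differences are dropped.  The exact null distribution is used when
    n <= 25 and the absolute differences carry no tied ranks; otherwise the
    normal approximation with tie correction and continuity correction.
    Returns (p, method); p is None when every difference is zero.
    """
    diffs = []
    for p in pairs:
        if isinstance(p, DensityPair):
            diffs.append(p.loop_density - p.control_density)
        else:
            diffs.append(p[0] - p[1])
    d = np.asarray([x for x in diffs if x != 0.0])
    if d.size == 0:
        return None, "undefined"
    ranks = stats.rankdata(np.abs(d))
    has_ties = len(np.unique(ranks)) < len(ranks)
    if d.size <= 25 and not has_ties:
        res = stats.wilcoxon(d, alternative="greater", method="exact")
        return float(res.pvalue), "exact"
    res = stats.wilcoxon(d, alternative="greater", method="approx", correction=True)
    return float(res.pvalue), "normal_approx"


def holm_bonferroni(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment, returned in input order.

    The i-th smallest p is multiplied by (m − i), a running maximum enforces
    monotonicity, and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, min(1.0, p[idx] * (m - i)))
        adjusted[idx] = running
    return adjusted.tolist()


def run_order_test(
    groups: list[ConservedGroup],
    blocks: list[AlignmentBlock],
    all_motifs: list[G4Motif],
    order_code: str = "",
) -> OrderTestResult:
    """Density pairs and the raw one-sided Wilcoxon p for one order.

    ``p_holm`` is left unset here; it is filled in across the family of
    orders tested together (see :func:`adjust_family`).
    """
    pairs, excluded = build_density_pairs(groups, blocks, all_motifs)
    if not pairs:
        return OrderTestResult(order_code, 0, None, None, 0, "none", len(excluded))
    p_raw, method = wilcoxon_paired_greater(pairs)
    n_exceeds = sum(1 for p in pairs if p.loop_density > p.control_density)
    return OrderTestResult(
        order_code, len(pairs), p_raw, None, n_exceeds, method, len(excluded)
    )


def adjust_family(results: list[OrderTestResult]) -> list[OrderTestResult]:
    """Holm–Bonferroni across the orders tested in one run (in place)."""
    testable = [r for r in results if r.p_raw is not None]
    if testable:
        adj = holm_bonferroni([r.p_raw for r in testable])
        for r, a in zip(testable, adj):
            r.p_holm = a
    return results


def substitution_spectrum(records: list[SubstitutionRecord]) -> "pandas.DataFrame":  # noqa: F821
    """Counts of substitution-type labels (e.g. C↔T) by region class."""
    import pandas as pd

    rows: dict[tuple[str, str], int] = {}
    for r in records:
        region = "tract" if r.region.startswith("tract") else (
            "loop" if r.region.startswith("loop") else r.region
        )
        rows[(region, r.type_label)] = rows.get((region, r.type_label), 0) + 1
    return pd.DataFrame(
        [
            {"region": reg, "type": t, "count": c}
            for (reg, t), c in sorted(rows.items())
        ]
    )
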