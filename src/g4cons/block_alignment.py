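"""Reliable local multiple-alignment blocks over a promoter set.

A *reliable block* is a gapped multiple alignment of promoter fragments from
two or more distinct species with at least 100 columns and at least 80%
identical columns, where an identical column is one in which every row
carries the same non-gap symbol (a gap or N anywhere makes the column
non-identical).  Blocks are named ``h{n_fragments}x{width}`` with ``-1``,
``-2`` suffixes on collisions.

The builder is an anchor-and-extend stand-in for a full pangenome aligner:
shared k-mers across promoters are chained into diagonal bands per species
pair, species fragments are grouped by anchor connectivity, aligned by a
star strategy around a reference row (edlib global paths), and trimmed at
the ends until the identity criterion holds, dropping the most deviant rows
when the full set cannot qualify.  Removed rows and flanking column ranges
are re-searched, so one diverged region can yield several overlapping or
sibling blocks.  Externally built blocks can be imported via
:func:`read_block` instead.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from g4cons.dataset_io import Promoter, PromoterSet

MIN_IDENTITY = 0.8
MIN_WIDTH = 100
DEFAULT_K = 12

GAP = "-"


@dataclass(frozen=True)
class BlockFragment:
    """One gapped row of a block; ``start``/``end`` are 1-based inclusive
    promoter coordinates of the ungapped sequence on the coding strand."""

    species_code: str
    start: int
    end: int
    row: str

    @property
    def ungapped(self) -> str:
        return self.row.replace(GAP, "")

    def validate_against(self, promoter: Promoter) -> None:
        expect = promoter.sequence[self.start - 1 : self.end]
        if self.ungapped != expect:
            raise ValueError(
                f"{self.species_code}: row does not match promoter [{self.start},{self.end}]"
            )

    def column_of(self, pos: int) -> int | None:
        """1-based alignment column holding promoter position ``pos``."""
        if pos < self.start or pos > self.end:
            return None
        seen = self.start - 1
        for col, ch in enumerate(self.row, 1):
            if ch != GAP:
                seen += 1
                if seen == pos:
                    return col
        return None

    def position_of(self, col: int) -> int | None:
        """Promoter position in column ``col``; None on a gap."""
        if col < 1 or col > len(self.row):
            raise IndexError(col)
        if self.row[col - 1] == GAP:
            return None
        return self.start - 1 + len(self.row[:col].replace(GAP, ""))


@dataclass
class AlignmentBlock:
    name: str
    fragments: list[BlockFragment] = field(default_factory=list)

    def __post_init__(self) -> None:
        widths = {len(f.row) for f in self.fragments}
        if len(widths) > 1:
            raise ValueError(f"{self.name}: rows of unequal width {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(self.fragments[0].row) if self.fragments else 0

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def identity(self) -> float:
        return column_identity(self)

    def fragment(self, species_code: str) -> BlockFragment:
        for f in self.fragments:
            if f.species_code == species_code:
                return f
        raise KeyError(species_code)

    def species(self) -> list[str]:
        return [f.species_code for f in self.fragments]

    def column(self, col: int) -> list[str]:
        return [f.row[col - 1] for f in self.fragments]


def column_identity(block: AlignmentBlock) -> float:
    """Fraction of columns where all rows share one symbol in {A,C,G,T}."""
    if block.width == 0:
        raise ValueError("zero-width block")
    rows = [f.row for f in block.fragments]
    ident = 0
    for col in zip(*rows):
        first = col[0]
        if first in "ACGT" and all(c == first for c in col[1:]):
            ident += 1
    return ident / block.width


def validate_block(
    block: AlignmentBlock, min_identity: float = MIN_IDENTITY, min_width: int = MIN_WIDTH
) -> bool:
    """Reliability verdict: width and identity thresholds only (maximality is
    a property of the builder, not of the validator)."""
    return block.width >= min_width and column_identity(block) >= min_identity


def block_name(n_fragments: int, width: int) -> str:
    return f"h{n_fragments}x{width}"


# ---------------------------------------------------------------- builder


def _kmer_anchors(seqs: dict[str, str], k: int) -> dict[tuple[str, str], list[tuple[int, int]]]:
    """Shared k-mer matches per species pair as (pos_a, pos_b), 1-based."""
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for code, seq in seqs.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                index[kmer].append((code, i + 1))
    pairs: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for hits in index.values():
        if len(hits) < 2 or len(hits) > 200:  # drop hyper-repetitive k-mers
            continue
        for ai in range(len(hits)):
            for bi in range(ai + 1, len(hits)):
                (ca, pa), (cb, pb) = hits[ai], hits[bi]
                if ca == cb:
                    continue
                if ca > cb:
                    (ca, pa), (cb, pb) = (cb, pb), (ca, pa)
                pairs[(ca, cb)].append((pa, pb))
    return pairs


def _banded_intervals(
    matches: list[tuple[int, int]], k: int, band: int = 25, min_anchors: int = 2
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Group pair matches into diagonal bands; return interval pairs."""
    by_band: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for pa, pb in matches:
        by_band[(pa - pb) // band].append((pa, pb))
    out = []
    for hits in by_band.values():
        if len(hits) < min_anchors:
            continue
        pas = [h[0] for h in hits]
        pbs = [h[1] for h in hits]
        out.append(((min(pas), max(pas) + k - 1), (min(pbs), max(pbs) + k - 1)))
    return out


def _star_align(fragments: dict[str, str], ref_code: str) -> dict[str, str]:
    """Gapped rows from global alignments of every sequence to the reference.

    Standard star construction: per-reference-position insertion sizes are
    maximised over all pairwise paths, then every row is re-padded.
    """
    ref = fragments[ref_code]
    paths: dict[str, list[tuple[str, int]]] = {}
    for code, seq in fragments.items():
        if code == ref_code:
            continue
        res = edlib.align(seq, ref, mode="NW", task="path")
        ops = [(m[1], int(m[0])) for m in re.findall(r"(\d+)([=XIDS])", res["cigar"])]
        paths[code] = ops
    # insertion sizes relative to the reference: ins[i] = max gap opened
    # after reference position i (i = 0 allows leading insertions)
    ins = [0] * (len(ref) + 1)
    for ops in paths.values():
        rpos = 0
        for op, n in ops:
            if op in ("=", "X", "D"):
                rpos += n
            else:  # I: bases of the query not present in the reference
                ins[rpos] = max(ins[rpos], n)
    rows: dict[str, str] = {}
    # reference row
    parts = [GAP * ins[0]]
    for i, ch in enumerate(ref, 1):
        parts.append(ch)
        parts.append(GAP * ins[i])
    rows[ref_code] = "".join(parts)
    for code, ops in paths.items():
        seq = fragments[code]
        qpos = 0
        rpos = 0
        parts = []
        pending_ins = 0
        for op, n in ops:
            if op == "I":
                parts.append(seq[qpos : qpos + n])
                qpos += n
                pending_ins += n
            else:
                parts.append(GAP * (ins[rpos] - pending_ins))
                pending_ins = 0
                for _ in range(n):
                    if op == "D":
                        parts.append(GAP)
                    else:
                        parts.append(seq[qpos])
                        qpos += 1
                    rpos += 1
                    if _ < n - 1:
                        parts.append(GAP * ins[rpos])
        parts.append(GAP * (ins[rpos] - pending_ins))
        rows[code] = "".join(parts)
    width = len(rows[ref_code])
    assert all(len(r) == width for r in rows.values()), "star alignment width mismatch"
    return rows


def _trim_ends_to_identity(
    ident_flags: list[bool], min_identity: float, min_width: int, edge: int = 25
) -> tuple[int, int] | None:
    """Trim columns from the ends until the identity criterion holds.

    Ends are trimmed one column at a time — a non-identical end column
    first, otherwise the end whose outermost ``edge`` columns are less
    identical (ties go left) — until the retained stretch reaches the
    identity threshold or falls below ``min_width`` (then None).  Interior
    low-identity stretches are deliberately retained: the criterion is an
    average over the block, not a per-column filter, and trimming only the
    ends keeps the block's background columns an unbiased sample of the
    aligned region (control windows for the substitution test are drawn
    from them).
    """
    n = len(ident_flags)
    pre = [0] * (n + 1)
    for idx, f in enumerate(ident_flags):
        pre[idx + 1] = pre[idx] + (1 if f else 0)

    def ident(a: int, b: int) -> float:  # 0-based inclusive
        return (pre[b + 1] - pre[a]) / (b - a + 1)

    i, j = 0, n - 1
    while j - i + 1 >= min_width and ident(i, j) < min_identity:
        if not ident_flags[i]:
            i += 1
        elif not ident_flags[j]:
            j -= 1
        elif ident(i, min(i + edge - 1, j)) <= ident(max(j - edge + 1, i), j):
            i += 1
        else:
            j -= 1
    if j - i + 1 >= min_width and ident(i, j) >= min_identity:
        return (i + 1, j + 1)  # 1-based inclusive columns
    return None


def _identity_flags(mat: np.ndarray) -> np.ndarray:
    """Per-column all-rows-identical-and-ACGT flags for a codes matrix."""
    first = mat[0]
    same = (mat == first).all(axis=0)
    acgt = np.isin(first, np.frombuffer(b"ACGT", dtype=np.uint8))
    return same & acgt


def _subset_blocks(
    rows: dict[str, str],
    intervals: dict[str, tuple[int, int]],
    min_identity: float,
    min_width: int,
) -> list[tuple[dict[str, str], dict[str, tuple[int, int]], tuple[int, int]]]:
    """Extract qualifying row subsets from one aligned proto-block.

    A block need not contain every promoter: when the full row set has no
    qualifying window, the row deviating most from the column consensus is
    dropped and the search repeats; rows removed from one block are re-fed
    to the same procedure, so several sibling blocks over one region can be
    emitted (mirroring what pangenome aligners report for diverged sets).
    """
    codes = sorted(rows)
    mat = np.frombuffer(
        "".join(rows[c] for c in codes).encode(), dtype=np.uint8
    ).reshape(len(codes), -1)
    symbols = np.frombuffer(b"ACGTN-", dtype=np.uint8)
    out = []
    # work queue of (row indices, 0-based inclusive column range): after a
    # block is emitted, its flanking column ranges are re-searched with all
    # rows and its own window with the rows that were dropped, so diverged
    # sets yield several sibling/adjacent blocks instead of one fragmentary hit
    stack: list[tuple[list[int], int, int]] = [(list(range(len(codes))), 0, mat.shape[1] - 1)]
    while stack:
        idx, a, b = stack.pop()
        if len(idx) < 2 or b - a + 1 < min_width:
            continue
        cur = list(idx)
        window = None
        col_map = None
        while True:
            sub = mat[cur][:, a : b + 1]
            # drop all-gap columns (can appear after row removal)
            keep = ~(sub == ord("-")).all(axis=0)
            col_map = np.nonzero(keep)[0]
            if col_map.size < min_width:
                window = None
                break
            flags = _identity_flags(sub[:, keep])
            window = _trim_ends_to_identity(flags.tolist(), min_identity, min_width)
            if window is not None or len(cur) <= 2:
                break
            # remove the row deviating most from the per-column majority
            counts = (sub[None, :, :] == symbols[:, None, None]).sum(axis=1)
            consensus = symbols[counts.argmax(axis=0)]
            dev = (sub != consensus[None, :]).sum(axis=1)
            cur.pop(int(dev.argmax()))
        if window is None:
            continue
        c0 = a + int(col_map[window[0] - 1])  # 0-based absolute columns
        c1 = a + int(col_map[window[1] - 1])
        sub_rows = {codes[i]: rows[codes[i]] for i in cur}
        sub_ivals = {codes[i]: intervals[codes[i]] for i in cur}
        out.append((sub_rows, sub_ivals, (c0 + 1, c1 + 1)))
        removed = [i for i in idx if i not in cur]
        # flank ranges overlap the emitted window by more than one motif
        # span (45 nt) so a motif falling on a window edge is still wholly
        # contained in a neighbouring block; overlap stays below min_width,
        # so every subproblem strictly shrinks and recursion terminates
        margin = min(60, min_width - 1)
        stack.append((idx, a, c0 - 1 + margin))
        stack.append((idx, c1 + 1 - margin, b))
        stack.append((removed, c0, c1))
    return out


def _trim_to_window(rows: dict[str, str], intervals: dict[str, tuple[int, int]], c0: int, c1: int):
    """Slice alignment columns [c0, c1] (1-based), dropping columns that are
    gaps in every kept row, and fix fragment coordinates."""
    kept_rows = {code: row[c0 - 1 : c1] for code, row in rows.items()}
    width = c1 - c0 + 1
    keep_cols = [
        i for i in range(width) if any(r[i] != GAP for r in kept_rows.values())
    ]
    out_rows = {}
    out_intervals = {}
    for code, row in rows.items():
        left_removed = len(row[: c0 - 1].replace(GAP, ""))
        kept = "".join(kept_rows[code][i] for i in keep_cols)
        s0, _ = intervals[code]
        ungapped = kept.replace(GAP, "")
        ns = s0 + left_removed
        out_rows[code] = kept
        out_intervals[code] = (ns, ns + len(ungapped) - 1)
    return out_rows, out_intervals


def build_blocks(
    pset: PromoterSet,
    k: int = DEFAULT_K,
    min_identity: float = MIN_IDENTITY,
    min_width: int = MIN_WIDTH,
    allow_subthreshold: bool = False,
) -> list[AlignmentBlock]:
    """Anchor-and-extend block construction within one order.

    Shared k-mers are chained into diagonal bands per species pair; species
    sharing anchors form a proto-block whose per-species fragment is the
    union of its anchored intervals.  Fragments are star-aligned around the
    longest fragment and trimmed to the widest column window satisfying the
    identity criterion.  Deterministic given the input order and parameters.
    """
    if len(pset.promoters) < 2:
        return []
    seqs = {p.species_code: p.sequence for p in pset.promoters}
    pairs = _kmer_anchors(seqs, k)
    # per-species anchored interval union + connectivity
    parent: dict[str, str] = {c: c for c in seqs}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    spans: dict[str, tuple[int, int]] = {}
    for (ca, cb), matches in pairs.items():
        bands = _banded_intervals(matches, k)
        if not bands:
            continue
        ra, rb = find(ca), find(cb)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
        for (ia, ib) in bands:
            for code, (s, e) in ((ca, ia), (cb, ib)):
                if code in spans:
                    s0, e0 = spans[code]
                    spans[code] = (min(s0, s), max(e0, e))
                else:
                    spans[code] = (s, e)
    components: dict[str, list[str]] = defaultdict(list)
    for code in sorted(spans):
        components[find(code)].append(code)

    blocks: list[AlignmentBlock] = []
    eff_width = 1 if allow_subthreshold else min_width
    for members in components.values():
        if len(members) < 2:
            continue
        intervals = {c: spans[c] for c in members}
        fragments = {c: seqs[c][intervals[c][0] - 1 : intervals[c][1]] for c in members}
        ref = max(members, key=lambda c: (len(fragments[c]), c))
        rows = _star_align(fragments, ref)
        for sub_rows, sub_ivals, window in _subset_blocks(
            rows, intervals, min_identity, eff_width
        ):
            rows2, intervals2 = _trim_to_window(sub_rows, sub_ivals, *window)
            frags = [
                BlockFragment(code, intervals2[code][0], intervals2[code][1], rows2[code])
                for code in sorted(rows2)
            ]
            block = AlignmentBlock(block_name(len(frags), len(frags[0].row)), frags)
            if allow_subthreshold or validate_block(block, min_identity, min_width):
                blocks.append(block)
    # disambiguate name collisions deterministically
    seen: dict[str, int] = {}
    for b in blocks:
        n = seen.get(b.name, 0)
        seen[b.name] = n + 1
        if n:
            b.name = f"{b.name}-{n}"
    blocks.sort(key=lambda b: b.name)
    return blocks


# ---------------------------------------------------------------- file I/O

_HEADER_RE = re.compile(r"^([A-Za-z0-9]+)/(\d+)-(\d+)$")


def write_block(block: AlignmentBlock, path: str | Path) -> None:
    """Aligned FASTA with ``>SPECIESCODE/start-end`` headers."""
    with open(path, "w") as fh:
        for f in block.fragments:
            fh.write(f">{f.species_code}/{f.start}-{f.end}\n{f.row}\n")


def read_block(path: str | Path, promoters: PromoterSet | None = None) -> AlignmentBlock:
    """Read one block file; validates width and, when a promoter set is
    supplied, that each ungapped row matches its promoter coordinates."""
    path = Path(path)
    fragments: list[BlockFragment] = []
    code = None
    rows: list[tuple[str, int, int, list[str]]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                m = _HEADER_RE.match(line[1:])
                if not m:
                    raise ValueError(f"{path.name}: malformed header {line!r}")
                code, s, e = m.group(1), int(m.group(2)), int(m.group(3))
                rows.append((code, s, e, []))
            else:
                if not rows:
                    raise ValueError(f"{path.name}: sequence before header")
                rows[-1][3].append(line.upper())
    for code, s, e, chunks in rows:
        row = "".join(chunks)
        if len(row.replace(GAP, "")) != e - s + 1:
            raise ValueError(f"{path.name}: {code} ungapped length != {s}-{e}")
        fragments.append(BlockFragment(code, s, e, row))
    block = AlignmentBlock(path.stem, fragments)
    if promoters is not None:
        for f in fragments:
            f.validate_against(promoters.get(f.species_code))
    return block


def write_blocks(blocks: list[AlignmentBlock], out_dir: str | Path) -> Path:
    """One aligned-FASTA file per block plus an index TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "blocks_index.tsv", "w") as idx:
        idx.write("name\tn_fragments\twidth\tidentity\n")
        for b in blocks:
            write_block(b, out_dir / f"{b.name}.fasta")
            idx.write(f"{b.name}\t{b.n_fragments}\t{b.width}\t{column_identity(b):.4f}\n")
    return out_dir


def read_blocks(dir_path: str | Path, promoters: PromoterSet | None = None) -> list[AlignmentBlock]:
    dir_path = Path(dir_path)
    blocks = [
        read_block(p, promoters)
        for p in sorted(dir_path.glob("*.fasta"))
    ]
    return blocks
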