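"""Constrained G4 motif detection on both strands of a promoter.

A G4 motif is four G-tracts of at least three consecutive guanines separated
by three loops of 1–30 nt, with a total span of at most 45 nt (the pattern
``G3+ L1-30 G3+ L1-30 G3+ L1-30 G3+``).  Candidates are enumerated over all
tract placements, including length-3 (and longer) sub-placements inside
longer G-runs; a greedy scored selection then reports non-overlapping motifs
per strand.  Motifs on the noncoding strand are detected on the reverse
complement and reported back in coding-strand coordinates, where their
G-tracts appear as C-tracts.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass, replace
from typing import Optional

from g4cons.dataset_io import Promoter

MIN_TRACT = 3
MAX_LOOP = 30
MAX_SPAN = 45

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: TSS-distance zones, inclusive upper bounds (distal is open-ended)
ZONE_CORE_MAX = 180
ZONE_PROXIMAL_MAX = 500


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class G4Motif:
    """A G4 motif in 1-based inclusive coding-strand coordinates.

    ``tracts`` are the four tract intervals sorted by coding-strand position;
    for noncoding-strand motifs these are the C-tract intervals and the first
    tract of the motif (5' on the motif strand) is the *last* interval.
    ``loops`` are read 5'→3' on the motif-bearing strand.
    """

    species_code: str
    strand: str  # "coding" | "noncoding"
    start: int
    end: int
    tracts: tuple[tuple[int, int], ...]
    loops: tuple[str, str, str]
    score: float = 0.0
    tss_distance: Optional[int] = None
    zone: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("coding", "noncoding"):
            raise ValueError(f"bad strand {self.strand!r}")
        if len(self.tracts) != 4:
            raise ValueError("a G4 motif has exactly four tracts")

    @property
    def total_length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "G4Motif") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class Candidate:
    """A tract placement tuple on one strand, in local (scanned-strand) coords."""

    tracts: tuple[tuple[int, int], ...]  # ordered 5'->3' on the scanned strand

    @property
    def start(self) -> int:
        return self.tracts[0][0]

    @property
    def end(self) -> int:
        return self.tracts[3][1]

    @property
    def total_length(self) -> int:
        return self.end - self.start + 1

    def loop_intervals(self) -> list[tuple[int, int]]:
        return [
            (self.tracts[i][1] + 1, self.tracts[i + 1][0] - 1) for i in range(3)
        ]


def _g_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of G, 1-based inclusive. N never counts as G."""
    return [(m.start() + 1, m.end()) for m in re.finditer(r"G+", seq)]


def _tract_placements(runs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """All sub-intervals of length >= MIN_TRACT of the maximal G-runs."""
    out = []
    for rs, re_ in runs:
        for s in range(rs, re_ - MIN_TRACT + 2):
            for e in range(s + MIN_TRACT - 1, re_ + 1):
                out.append((s, e))
    out.sort()
    return out


def find_candidates(seq: str) -> list[Candidate]:
    """Enumerate every admissible four-tract placement in ``seq``.

    Tracts are all-G intervals of length >= 3 (any sub-interval of a longer
    run is admissible), strictly ordered without overlap, with loops of
    1–30 nt between consecutive tracts and every tract inside the 45-nt
    window anchored at the first tract's start.  Candidates may overlap one
    another; selection happens downstream.
    """
    seq = seq.upper()
    placements = _tract_placements(_g_runs(seq))
    if not placements:
        return []
    starts = [p[0] for p in placements]
    out: list[Candidate] = []

    def extend(chain: list[tuple[int, int]], window_end: int) -> None:
        if len(chain) == 4:
            out.append(Candidate(tuple(chain)))
            return
        prev_end = chain[-1][1]
        lo = bisect_left(starts, prev_end + 2)
        for i in range(lo, len(placements)):
            s, e = placements[i]
            if s > prev_end + MAX_LOOP + 1:
                break
            if e > window_end:
                continue
            chain.append((s, e))
            extend(chain, window_end)
            chain.pop()

    for first in placements:
        if first[1] > first[0] + MAX_SPAN - 1:
            continue
        extend([first], first[0] + MAX_SPAN - 1)
    return out


def candidate_score(c: Candidate) -> float:
    """Selection score: prefers long tracts, short equal loops, compact span."""
    tract_lens = [e - s + 1 for s, e in c.tracts]
    loop_lens = [b - a + 1 for a, b in c.loop_intervals()]
    mean = sum(loop_lens) / 3.0
    var = sum((x - mean) ** 2 for x in loop_lens) / 3.0
    return 10.0 * min(min(tract_lens), 5) - var - (c.total_length - 15) / 2.0


def _loop_seqs(c: Candidate, seq: str) -> tuple[str, str, str]:
    return tuple(seq[a - 1 : b] for a, b in c.loop_intervals())  # type: ignore[return-value]


def select_nonoverlapping(candidates: list[Candidate], seq: str) -> list[Candidate]:
    """Greedy selection of mutually non-overlapping candidates.

    Candidates are taken in order of descending score; ties are broken by
    smaller start, then shorter total length, then the lexicographically
    smallest loop concatenation.  A candidate is kept iff its [start, end]
    span is disjoint from every already-kept candidate.
    """
    # the tract tuple is a final key: candidates can tie on score, start,
    # length and even loop content (e.g. placements sliding inside one run)
    ordered = sorted(
        candidates,
        key=lambda c: (
            -candidate_score(c),
            c.start,
            c.total_length,
            "".join(_loop_seqs(c, seq)),
            c.tracts,
        ),
    )
    chosen: list[Candidate] = []
    for c in ordered:
        if all(c.end < k.start or k.end < c.start for k in chosen):
            chosen.append(c)
    chosen.sort(key=lambda c: c.start)
    return chosen


def _to_motif(c: Candidate, seq: str, strand: str, length: int, species_code: str) -> G4Motif:
    """Map a candidate on the scanned strand to coding-strand coordinates."""
    loops = _loop_seqs(c, seq)
    if strand == "coding":
        tracts = c.tracts
        start, end = c.start, c.end
    else:
        # position i on the reverse complement <-> coding position length-i+1
        tracts = tuple(sorted((length - e + 1, length - s + 1) for s, e in c.tracts))
        start, end = length - c.end + 1, length - c.start + 1
    return G4Motif(
        species_code=species_code,
        strand=strand,
        start=start,
        end=end,
        tracts=tracts,
        loops=loops,
        score=candidate_score(c),
    )


def assign_zone(m: G4Motif, promoter_length: int) -> G4Motif:
    """Attach TSS distance and zone. Distance is measured from the motif's
    TSS-proximal edge: ``promoter_length - end`` (the last promoter position
    abuts the TSS, so a motif ending there has distance 0, zone ``core``)."""
    if m.end > promoter_length or m.start < 1:
        raise ValueError(f"motif [{m.start},{m.end}] outside promoter of length {promoter_length}")
    d = promoter_length - m.end
    if d <= ZONE_CORE_MAX:
        zone = "core"
    elif d <= ZONE_PROXIMAL_MAX:
        zone = "proximal"
    else:
        zone = "distal"
    return replace(m, tss_distance=d, zone=zone)


def scan_promoter(p: Promoter) -> list[G4Motif]:
    """Non-overlapping G4 motifs on both strands, in coding coordinates.

    Each strand is scanned and selected independently: coding-strand motifs
    from the sequence itself, noncoding-strand motifs from its reverse
    complement (appearing as C-tracts on the coding strand).  Zones are
    assigned relative to the promoter's TSS-proximal end.
    """
    motifs: list[G4Motif] = []
    for strand, seq in (("coding", p.sequence), ("noncoding", reverse_complement(p.sequence))):
        selected = select_nonoverlapping(find_candidates(seq), seq)
        motifs.extend(_to_motif(c, seq, strand, p.length, p.species_code) for c in selected)
    motifs = [assign_zone(m, p.length) for m in motifs]
    motifs.sort(key=lambda m: (m.start, m.strand))
    return motifs


def motif_table(motifs: list[G4Motif]) -> "pandas.DataFrame":  # noqa: F821
    """Tabular view of a motif list (TSV-ready)."""
    import pandas as pd

    rows = []
    for m in motifs:
        row = {
            "species_code": m.species_code,
            "strand": m.strand,
            "start": m.start,
            "end": m.end,
            "total_length": m.total_length,
            "tss_distance": m.tss_distance,
            "zone": m.zone,
            "score": m.score,
        }
        for i, (s, e) in enumerate(m.tracts, 1):
            row[f"tract{i}"] = f"{s}-{e}"
        for i, lp in enumerate(m.loops, 1):
            row[f"loop{i}_len"] = len(lp)
        rows.append(row)
    return pd.DataFrame(rows)
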