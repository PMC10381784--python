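"""Promoter set I/O, species naming, and dataset filtration.

A promoter here is a 1000-nt (nominally) coding-strand sequence whose last
position abuts the transcription start site (TSS): position 1 is the distal
end and position ``length`` lies immediately upstream of the TSS.  Sets are
grouped by taxonomic order and filtered for sequencing gaps (long N runs)
and for lack of similarity to any relative in the set.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

#: discard reasons recognised in :class:`PromoterSet.discarded`
DISCARD_REASONS = ("n_run", "no_relative_match", "user")


class InvalidNameError(ValueError):
    """Raised when a species name component needed for coding is empty."""


@dataclass(frozen=True)
class Promoter:
    """One coding-strand promoter sequence, 5'→3', ending at the TSS."""

    species_code: str
    order_code: str
    sequence: str
    source_id: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 1:
            raise ValueError(f"{self.species_code}: empty sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(f"{self.species_code}: non-IUPAC characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PromoterSet:
    """Promoters of one taxonomic order plus a discard log."""

    order_code: str
    promoters: list[Promoter] = field(default_factory=list)
    discarded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        codes = [p.species_code for p in self.promoters]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate species codes in set")
        for p in self.promoters:
            if p.order_code != self.order_code:
                raise ValueError(f"{p.species_code}: order {p.order_code!r} != set order {self.order_code!r}")

    def __len__(self) -> int:
        return len(self.promoters)

    def get(self, species_code: str) -> Promoter:
        for p in self.promoters:
            if p.species_code == species_code:
                return p
        raise KeyError(species_code)


def make_species_code(order_name: str, genus: str, species_epithets: list[str]) -> str:
    """Build the 8–11 character species code.

    First three letters of the order (capitalised), first two of the genus
    (upper case), then the first three letters of each epithet (lower case):
    ("Primates", "Homo", ["sapiens"]) → ``PriHOsap``.
    """
    if not order_name or not genus:
        raise InvalidNameError("order name and genus must be non-empty")
    code = order_name[:3].capitalize() + genus[:2].upper()
    for ep in species_epithets:
        code += ep[:3].lower()
    return code


def _longest_n_run(seq: str) -> int:
    best = 0
    for m in re.finditer(r"N+", seq):
        best = max(best, m.end() - m.start())
    return best


def filter_n_runs(pset: PromoterSet, max_run: int = 100) -> PromoterSet:
    """Discard promoters containing a run of N strictly longer than ``max_run``.

    A sequence with exactly ``max_run`` consecutive N is retained; separate
    shorter runs are never concatenated.
    """
    if max_run < 1:
        raise ValueError("max_run must be >= 1")
    kept, dropped = [], list(pset.discarded)
    for p in pset.promoters:
        if _longest_n_run(p.sequence) > max_run:
            dropped.append((p.species_code, "n_run"))
        else:
            kept.append(p)
    return PromoterSet(pset.order_code, kept, dropped)


def _local_aligner(match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def best_local_match(a: str, b: str) -> tuple[int, float]:
    """Best local alignment of two sequences: (aligned columns, identity).

    Scoring is match +1 / mismatch −1 / gap −2.  Identity is the fraction of
    aligned (non-gap-paired) columns that are identical.
    """
    aligner = _local_aligner()
    try:
        aln = aligner.align(a, b)[0]
    except (IndexError, ValueError):
        return 0, 0.0
    matches = 0
    columns = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        columns += a1 - a0
        for x, y in zip(a[a0:a1], b[b0:b1]):
            if x == y:
                matches += 1
    if columns == 0:
        return 0, 0.0
    return columns, matches / columns


def filter_relative_similarity(
    pset: PromoterSet, min_len: int = 100, min_identity: float = 0.70
) -> PromoterSet:
    """Discard promoters with no adequate local match to any other set member.

    Each promoter is locally aligned against every other promoter of the same
    order; it is retained iff some alignment reaches ``min_len`` aligned
    columns at ``min_identity`` identity.  This is the reproducible stand-in
    for a "significant relative match" filter and supersets any single
    closest-relative comparison (a promoter passing against its closest
    relative always passes here).
    """
    if len(pset.promoters) <= 1:
        if len(pset.promoters) == 1:
            warnings.warn("single-promoter set: similarity filter is a no-op", stacklevel=2)
        return PromoterSet(pset.order_code, list(pset.promoters), list(pset.discarded))
    kept, dropped = [], list(pset.discarded)
    for p in pset.promoters:
        ok = False
        for q in pset.promoters:
            if q.species_code == p.species_code:
                continue
            cols, ident = best_local_match(p.sequence, q.sequence)
            if cols >= min_len and ident >= min_identity:
                ok = True
                break
        if ok:
            kept.append(p)
        else:
            dropped.append((p.species_code, "no_relative_match"))
    return PromoterSet(pset.order_code, kept, dropped)


def read_promoter_fasta(path: str | Path, order_code: str | None = None) -> PromoterSet:
    """Read a promoter set from FASTA (``>SPECIESCODE [free text]``).

    Lowercase letters are uppercased; non-IUPAC characters raise.  The order
    code defaults to the first three characters of the first species code.
    """
    promoters = []
    for rec in SeqIO.parse(str(path), "fasta"):
        code = rec.id
        oc = order_code if order_code is not None else code[:3]
        promoters.append(
            Promoter(species_code=code, order_code=oc, sequence=str(rec.seq), source_id=rec.description)
        )
    if not promoters:
        return PromoterSet(order_code or "UNK", [])
    oc = order_code if order_code is not None else promoters[0].species_code[:3]
    promoters = [replace(p, order_code=oc) for p in promoters]
    return PromoterSet(oc, promoters)


def write_promoter_fasta(pset: PromoterSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.species_code, description=p.source_id or "")
        for p in pset.promoters
    ]
    SeqIO.write(records, str(path), "fasta")


def write_discard_report(pset: PromoterSet, path: str | Path) -> None:
    """TSV of (species_code, reason) for every discarded promoter."""
    with open(path, "w") as fh:
        fh.write("species_code\treason\n")
        for code, reason in pset.discarded:
            fh.write(f"{code}\t{reason}\n")
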