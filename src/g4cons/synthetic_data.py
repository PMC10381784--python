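"""Promoter-evolution simulator with exact ground truth.

Each simulated order is a star phylogeny: one ancestral promoter carrying
planted G4 motifs, from which every species descends independently through
point substitutions (optionally elevated inside motif loops), occasional
G-tract-disrupting substitutions, short indels and runs of N.  Planted
motifs satisfy the scanner's own constraints (four G-tracts of 3–5, loops
1–30, span <= 45); the background is sampled with G- and C-runs capped at
two so that every scanner hit and every conserved group has a known planted
origin.  All events are recorded so that each species sequence can be
replayed exactly from the ancestor, and the expected conserved groups (the
planted motifs and the species whose tracts stayed intact) are available as
ground truth for every pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from g4cons.dataset_io import Promoter, PromoterSet, make_species_code
from g4cons.g4_scanner import MAX_SPAN, reverse_complement

_BASES = np.array(list("ACGT"))
_BASE_IDX = {b: i for i, b in enumerate("ACGT")}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated order.

    Defaults emulate a mammalian-order promoter set: 10–30 related species,
    1000-bp promoters, a handful of planted motifs biased to the noncoding
    strand, and ~5% background divergence from the common ancestor.
    """

    n_species: int = 10
    promoter_length: int = 1000
    n_planted_motifs: int = 5
    noncoding_fraction: float = 0.7
    tract_len_range: tuple[int, int] = (3, 5)
    loop_len_range: tuple[int, int] = (1, 10)
    background_rate: float = 0.05
    loop_rate_multiplier: float = 1.0
    tract_disruption_prob: float = 0.0
    transition_bias: float = 0.6
    indel_rate: float = 0.0  # expected events per site
    indel_max_len: int = 3
    n_run_prob: float = 0.0  # per species
    n_run_len_range: tuple[int, int] = (5, 20)
    min_spacing: int = 60
    order_code: str = "Syn"
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (
            self.background_rate,
            self.tract_disruption_prob,
            self.noncoding_fraction,
            self.n_run_prob,
            self.transition_bias,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates and probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedMotif:
    """One planted motif in 1-based ancestor (coding-strand) coordinates."""

    start: int
    end: int
    strand: str
    tracts: tuple[tuple[int, int], ...]  # ascending coding-strand order
    loop_intervals: tuple[tuple[int, int], ...]


@dataclass
class SpeciesEvents:
    substitutions: list[tuple[int, str, str, str]] = field(default_factory=list)
    # (ancestor position, from, to, region label)
    indels: list[tuple[int, str, str | int]] = field(default_factory=list)
    # (ancestor position, "ins"/"del", inserted seq or deleted length)
    n_runs: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class GroundTruth:
    ancestor: str
    motifs: list[PlantedMotif]
    events: dict[str, SpeciesEvents]
    region: list[str]  # per ancestor position: "background" | "tract:i" | "loop:i"
    config: SimConfig

    def replay(self, species_code: str) -> str:
        """Reconstruct one species sequence from the recorded events."""
        ev = self.events[species_code]
        seq = list(self.ancestor)
        for pos, src, dst, _ in ev.substitutions:
            assert seq[pos - 1] == src
            seq[pos - 1] = dst
        for pos, length in ev.n_runs:
            for i in range(length):
                seq[pos - 1 + i] = "N"
        for pos, kind, payload in sorted(ev.indels, reverse=True):
            if kind == "del":
                del seq[pos - 1 : pos - 1 + int(payload)]
            else:
                seq[pos - 1 : pos - 1] = list(payload)
        return "".join(seq)

    def expected_group_members(self, motif_index: int) -> list[str]:
        """Species whose tract positions of the given motif are untouched."""
        motif = self.motifs[motif_index]
        tract_positions = {
            p for s, e in motif.tracts for p in range(s, e + 1)
        }
        members = []
        for code, ev in self.events.items():
            if all(pos not in tract_positions for pos, *_ in ev.substitutions):
                members.append(code)
        return sorted(members)


def _species_codes(n: int) -> list[str]:
    codes = []
    for i in range(n):
        genus = chr(ord("A") + i // 26) + chr(ord("a") + i % 26)
        codes.append(make_species_code("Synthetic", genus, ["sim"]))
    return codes


def _sample_capped(rng: np.random.Generator, n: int, forbid_runs: str = "GC") -> str:
    """Random sequence with runs of G and of C capped at two."""
    out: list[str] = []
    while len(out) < n:
        b = _BASES[rng.integers(4)]
        if (
            b in forbid_runs
            and len(out) >= 2
            and out[-1] == b
            and out[-2] == b
        ):
            continue
        out.append(b)
    return "".join(out)


def _sample_loop(rng: np.random.Generator, n: int) -> str:
    """Loop on the motif strand: G runs capped at 2 and no terminal G, so a
    planted tract never extends into its loops."""
    while True:
        s = _sample_capped(rng, n)
        if "GGG" in s:
            continue
        if s[0] != "G" and s[-1] != "G":
            return s


def _sample_motif(rng: np.random.Generator, cfg: SimConfig) -> tuple[str, list[tuple[int, int]]]:
    """Motif-strand sequence and local tract intervals, span <= 45."""
    t_lo, t_hi = cfg.tract_len_range
    l_lo, l_hi = cfg.loop_len_range
    while True:
        tracts = [int(rng.integers(t_lo, t_hi + 1)) for _ in range(4)]
        loops = [int(rng.integers(l_lo, l_hi + 1)) for _ in range(3)]
        if sum(tracts) + sum(loops) <= MAX_SPAN:
            break
    parts: list[str] = []
    intervals: list[tuple[int, int]] = []
    pos = 1
    for i, t in enumerate(tracts):
        parts.append("G" * t)
        intervals.append((pos, pos + t - 1))
        pos += t
        if i < 3:
            lp = _sample_loop(rng, loops[i])
            parts.append(lp)
            pos += loops[i]
    return "".join(parts), intervals


def generate_order(config: SimConfig) -> tuple[PromoterSet, GroundTruth]:
    """Simulate one order: ancestor with planted motifs, then descendants.

    Raises when the requested motifs cannot be planted with the configured
    spacing.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    L = config.promoter_length

    # --- assemble the ancestor -------------------------------------------
    motif_seqs: list[tuple[str, list[tuple[int, int]], str]] = []
    for _ in range(config.n_planted_motifs):
        seq, tr, = _sample_motif(rng, config)
        strand = "noncoding" if rng.random() < config.noncoding_fraction else "coding"
        motif_seqs.append((seq, tr, strand))
    total_motif = sum(len(s) for s, _, _ in motif_seqs)
    n_gaps = config.n_planted_motifs + 1
    slack = L - total_motif - n_gaps * config.min_spacing
    if slack < 0:
        raise ValueError(
            f"infeasible planting: {config.n_planted_motifs} motifs of total "
            f"length {total_motif} with spacing {config.min_spacing} exceed {L} nt"
        )
    extra = rng.multinomial(slack, np.full(n_gaps, 1.0 / n_gaps))
    gaps = [config.min_spacing + int(e) for e in extra]

    ancestor: list[str] = []
    region: list[str] = []
    motifs: list[PlantedMotif] = []
    def _gap_seq(n: int, before_motif: bool, after_motif: bool) -> str:
        # A/T at motif junctions so planted tracts never extend into the
        # background and the planted coordinates are exact ground truth
        s = list(_sample_capped(rng, n))
        if after_motif and s:
            s[0] = "AT"[rng.integers(2)]
        if before_motif and s:
            s[-1] = "AT"[rng.integers(2)]
        return "".join(s)

    for i, (mseq, tr_local, strand) in enumerate(motif_seqs):
        bg = _gap_seq(gaps[i], before_motif=True, after_motif=i > 0)
        ancestor.append(bg)
        region.extend(["background"] * len(bg))
        start = sum(len(x) for x in ancestor) + 1
        coding_seq = mseq if strand == "coding" else reverse_complement(mseq)
        mlen = len(mseq)
        if strand == "coding":
            tracts = [(start + s - 1, start + e - 1) for s, e in tr_local]
        else:
            tracts = sorted(
                (start + mlen - e, start + mlen - s) for s, e in tr_local
            )
        labels = ["loop"] * mlen
        for s, e in tracts:
            for p in range(s, e + 1):
                labels[p - start] = "tract"
        region.extend(f"{lab}:{i}" for lab in labels)
        ancestor.append(coding_seq)
        loop_ivals = tuple(
            (tracts[j][1] + 1, tracts[j + 1][0] - 1) for j in range(3)
        )
        motifs.append(
            PlantedMotif(start, start + mlen - 1, strand, tuple(tracts), loop_ivals)
        )
    bg = _gap_seq(gaps[-1], before_motif=False, after_motif=config.n_planted_motifs > 0)
    ancestor.append(bg)
    region.extend(["background"] * len(bg))
    anc = "".join(ancestor)
    assert len(anc) == L and len(region) == L

    # per-position substitution rates (tracts mutate only via disruptions)
    rates = np.zeros(L)
    for i, lab in enumerate(region):
        if lab == "background":
            rates[i] = config.background_rate
        elif lab.startswith("loop"):
            rates[i] = config.background_rate * config.loop_rate_multiplier

    # --- descend each species --------------------------------------------
    codes = _species_codes(config.n_species)
    anc_arr = np.array(list(anc))
    events: dict[str, SpeciesEvents] = {}
    promoters: list[Promoter] = []
    for code in codes:
        ev = SpeciesEvents()
        hit = np.nonzero(rng.random(L) < rates)[0]
        seq = anc_arr.copy()
        for idx in map(int, hit):
            src = anc[idx]
            if rng.random() < config.transition_bias:
                dst = _TRANSITION[src]
            else:
                dst = _TRANSVERSIONS[src][rng.integers(2)]
            seq[idx] = dst
            ev.substitutions.append((idx + 1, src, dst, region[idx]))
        for mi, motif in enumerate(motifs):
            if config.tract_disruption_prob and rng.random() < config.tract_disruption_prob:
                ts, te = motif.tracts[rng.integers(4)]
                pos = int(rng.integers(ts, te + 1))
                src = anc[pos - 1]
                choices = [b for b in "ACGT" if b != src]
                dst = choices[rng.integers(3)]
                seq[pos - 1] = dst
                ev.substitutions.append((pos, src, dst, region[pos - 1]))
        ev.substitutions.sort()
        # N runs and indels confined to background, away from motifs
        bg_positions = [i + 1 for i in range(L) if region[i] == "background"]
        if config.n_run_prob and rng.random() < config.n_run_prob:
            nlen = int(rng.integers(*config.n_run_len_range, endpoint=True))
            anchor = int(rng.choice(bg_positions))
            run = [p for p in range(anchor, anchor + nlen) if p <= L and region[p - 1] == "background"]
            if run:
                ev.n_runs.append((run[0], len(run)))
                for p in run:
                    seq[p - 1] = "N"
        final = seq.tolist()
        if config.indel_rate:
            n_events = rng.poisson(config.indel_rate * L)
            taken: set[int] = set()
            for _ in range(n_events):
                pos = int(rng.choice(bg_positions))
                if pos in taken:
                    continue
                ilen = int(rng.integers(1, config.indel_max_len + 1))
                if rng.random() < 0.5:
                    span = range(pos, pos + ilen)
                    if any(p > L or region[p - 1] != "background" or p in taken for p in span):
                        continue
                    taken.update(span)
                    ev.indels.append((pos, "del", ilen))
                else:
                    taken.add(pos)
                    ev.indels.append((pos, "ins", _sample_capped(rng, ilen)))
            for pos, kind, payload in sorted(ev.indels, reverse=True):
                if kind == "del":
                    del final[pos - 1 : pos - 1 + int(payload)]
                else:
                    final[pos - 1 : pos - 1] = list(payload)
        events[code] = ev
        promoters.append(
            Promoter(code, config.order_code, "".join(final), source_id="synthetic")
        )
    pset = PromoterSet(config.order_code, promoters)
    truth = GroundTruth(anc, motifs, events, region, config)
    return pset, truth


def planted_group_recovery(
    truth: GroundTruth,
    groups,
    blocks,
) -> tuple[int, int]:
    """(recovered, planted): planted motifs whose conserved group was called
    with exactly the planted tract coordinates.

    A planted motif counts as recovered when some called group of the same
    strand has tract columns that map, through the block row of a member
    free of indels, onto the planted ancestor tract intervals.
    """
    planted = {
        (m.strand, m.tracts): False for m in truth.motifs
    }
    by_name = {b.name: b for b in blocks}
    for g in groups:
        block = by_name[g.block_name]
        for code in g.members:
            if truth.events[code].indels:
                continue
            frag = block.fragment(code)
            tracts = []
            for s, e in g.tract_columns:
                ps, pe = frag.position_of(s), frag.position_of(e)
                if ps is None or pe is None:
                    break
                tracts.append((ps, pe))
            else:
                key = (g.strand, tuple(tracts))
                if key in planted:
                    planted[key] = True
            break
    return sum(planted.values()), len(planted)


def generate_null_and_alt_batches(
    config: SimConfig,
    n_replicates: int,
    alt_multiplier: float = 2.0,
) -> dict[str, list[SimConfig]]:
    """Replicate configs for type-I-error (multiplier 1) and power
    (multiplier ``alt_multiplier``) batches, with a manifest.

    Replicate seeds are derived deterministically from ``config.seed``; each
    entry is materialised on demand with :func:`generate_order`.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(2 * n_replicates)]
    null_cfgs = [
        replace(config, loop_rate_multiplier=1.0, seed=seeds[i])
        for i in range(n_replicates)
    ]
    alt_cfgs = [
        replace(config, loop_rate_multiplier=alt_multiplier, seed=seeds[n_replicates + i])
        for i in range(n_replicates)
    ]
    manifest = [
        {"batch": "null", "replicate": i, "seed": c.seed, "loop_rate_multiplier": 1.0}
        for i, c in enumerate(null_cfgs)
    ] + [
        {"batch": "alt", "replicate": i, "seed": c.seed, "loop_rate_multiplier": alt_multiplier}
        for i, c in enumerate(alt_cfgs)
    ]
    return {"null": null_cfgs, "alt": alt_cfgs, "manifest": manifest}
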