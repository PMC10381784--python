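import itertools

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from g4cons.block_alignment import AlignmentBlock, BlockFragment
from g4cons.conserved_groups import ConservedGroup
from g4cons.reporting import analyze_order
from g4cons.substitution_analysis import (
    column_consensus,
    count_control_substitutions,
    count_loop_substitutions,
    count_tract_substitutions,
    density,
    holm_bonferroni,
    select_control,
    wilcoxon_paired_greater,
)
from g4cons.synthetic_data import SimConfig, generate_order

import oracles


def _block(rows, name="b"):
    frags = [
        BlockFragment(f"SynA{chr(97+i)}sim", 1, len(r.replace("-", "")), r)
        for i, r in enumerate(rows)
    ]
    return AlignmentBlock(name, frags)


def _group(members, tract_columns, strand="coding", non_members=(), block_name="b"):
    cols = tract_columns
    loops = tuple((cols[i][1] + 1, cols[i + 1][0] - 1) for i in range(3))
    return ConservedGroup(
        group_id="g1",
        block_name=block_name,
        strand=strand,
        tract_columns=cols,
        loop_columns=loops,
        members=list(members),
        non_members=list(non_members),
    )


class TestColumnConsensus:
    def test_majority(self):
        assert column_consensus(["A", "A", "G"], [1]) == "A"

    def test_tie_breaks_alphabetically(self):
        assert column_consensus(["A", "A", "G", "G"], [1]) == "A"
        assert column_consensus(["T", "C"], [1]) == "C"

    def test_all_gap_column(self):
        assert column_consensus(["-", "-"], [1]) == "-"

    def test_matches_counting_oracle(self, rng):
        for _ in range(30):
            n_rows, width = int(rng.integers(2, 7)), int(rng.integers(1, 20))
            rows = [
                "".join(rng.choice(list("ACGT-"), size=width)) for _ in range(n_rows)
            ]
            cons = column_consensus(rows, range(1, width + 1))
            for col in range(width):
                counts = {}
                for r in rows:
                    if r[col] != "-":
                        counts[r[col]] = counts.get(r[col], 0) + 1
                if not counts:
                    assert cons[col] == "-"
                else:
                    top = max(counts.values())
                    assert cons[col] == min(b for b, c in counts.items() if c == top)


# Block rows for substitution tests: motif at columns 3-19 (tracts 3-5, 8-10,
# 13-15, 17-19), loops at 6-7, 11-12, 16.
CLEAN = "AT" + "GGG" + "CA" + "GGG" + "TT" + "GGG" + "C" + "GGG" + "ATTATCTTCCAATT"


class TestSubstitutionCounting:
    TRACTS = ((3, 5), (8, 10), (13, 15), (17, 19))

    def test_identical_members_give_no_records(self):
        block = _block([CLEAN, CLEAN, CLEAN])
        g = _group(["SynAasim", "SynAbsim", "SynAcsim"], self.TRACTS)
        assert count_loop_substitutions(g, block) == []

    def test_loop_substitutions_counted_against_consensus(self):
        mutated = CLEAN[:5] + "TA" + CLEAN[7:]  # loop1 'CA' -> 'TA' in one row
        block = _block([CLEAN, CLEAN, mutated])
        g = _group(["SynAasim", "SynAbsim", "SynAcsim"], self.TRACTS)
        recs = count_loop_substitutions(g, block)
        assert len(recs) == 1
        r = recs[0]
        assert (r.species_code, r.column, r.region) == ("SynAcsim", 6, "loop1")
        assert (r.observed, r.consensus) == ("T", "C")
        assert r.type_label == "C↔T"

    def test_gap_positions_are_not_substitutions(self):
        gapped = CLEAN[:5] + "-" + CLEAN[6:]
        block = _block([CLEAN, CLEAN, gapped])
        g = _group(["SynAasim", "SynAbsim", "SynAcsim"], self.TRACTS)
        assert count_loop_substitutions(g, block) == []

    def test_matches_per_column_counting_oracle(self, rng):
        for _ in range(20):
            rows = []
            for _ in range(4):
                chars = list(CLEAN)
                for li, (a, b) in enumerate([(6, 7), (11, 12), (16, 16)]):
                    for col in range(a, b + 1):
                        if rng.random() < 0.4:
                            chars[col - 1] = str(rng.choice(list("ACGT")))
                rows.append("".join(chars))
            block = _block(rows)
            members = [f.species_code for f in block.fragments]
            g = _group(members, self.TRACTS)
            got = len(count_loop_substitutions(g, block))
            expect = 0
            loop_cols = [6, 7, 11, 12, 16]
            for col in loop_cols:
                column = [r[col - 1] for r in rows]
                counts = {}
                for ch in column:
                    if ch != "-":
                        counts[ch] = counts.get(ch, 0) + 1
                top = max(counts.values())
                cons = min(b for b, c in counts.items() if c == top)
                expect += sum(1 for ch in column if ch not in ("-", cons) and ch != "N")
            assert got == expect

    def test_tract_substitutions_from_non_members_only(self):
        broken = CLEAN[:4] + "A" + CLEAN[5:]  # GGG -> GGA at column 5
        block = _block([CLEAN, CLEAN, broken])
        g = _group(
            ["SynAasim", "SynAbsim"], self.TRACTS, non_members=["SynAcsim"]
        )
        recs = count_tract_substitutions(g, block)
        assert len(recs) == 1
        assert recs[0].type_label == "A↔G"
        assert recs[0].region == "tract1"
        # members-only block yields nothing
        g2 = _group(["SynAasim", "SynAbsim"], self.TRACTS)
        assert count_tract_substitutions(g2, block) == []

    def test_member_tract_columns_contribute_zero_records(self):
        """Definitional consistency on a full pipeline run."""
        pset, _ = generate_order(SimConfig(seed=23))
        res = analyze_order(pset)
        for g in res.groups:
            block = next(b for b in res.blocks if b.name == g.block_name)
            for r in count_loop_substitutions(g, block):
                assert not any(s <= r.column <= e for s, e in g.tract_columns)
            for r in count_tract_substitutions(g, block):
                assert r.species_code in g.non_members

    def test_strand_complement_type_labels(self):
        """Relabelling a group's strand swaps complementary pair labels:
        a C↔T record on a noncoding-strand C-tract corresponds to G↔A on
        the coding strand."""
        broken_c = CLEAN.replace("G", "C")[:4] + "T" + CLEAN.replace("G", "C")[5:]
        rows_c = [CLEAN.replace("G", "C"), CLEAN.replace("G", "C"), broken_c]
        g_c = _group(
            ["SynAasim", "SynAbsim"], self.TRACTS, strand="noncoding",
            non_members=["SynAcsim"],
        )
        recs_c = count_tract_substitutions(g_c, _block(rows_c))
        broken_g = CLEAN[:4] + "A" + CLEAN[5:]
        g_g = _group(["SynAasim", "SynAbsim"], self.TRACTS, non_members=["SynAcsim"])
        recs_g = count_tract_substitutions(g_g, _block([CLEAN, CLEAN, broken_g]))
        pair = {recs_c[0].type_label, recs_g[0].type_label}
        assert pair == {"C↔T", "A↔G"}


class TestSelectControl:
    def test_clean_upstream_flank_wins(self):
        width = 60
        rows = ["A" * 20 + CLEAN[:40]] * 3
        block = _block(rows)
        g = _group(
            ["SynAasim", "SynAbsim", "SynAcsim"],
            tuple((s + 20, e + 20) for s, e in TestSubstitutionCounting.TRACTS),
        )
        ctrl = select_control(g, [block], all_motifs=[])
        assert ctrl is not None
        assert ctrl.source == "same_block_upstream"
        L = g.total_loop_columns
        assert ctrl.segments == ((g.first_col - L, g.first_col - 1),)
        assert ctrl.n_columns == L

    def test_gap_runs_disqualify_windows(self):
        rows = ["A" * 8 + "---" + "A" * 9 + CLEAN[:40]] * 3
        block = _block(rows)
        g = _group(
            ["SynAasim", "SynAbsim", "SynAcsim"],
            tuple((s + 20, e + 20) for s, e in TestSubstitutionCounting.TRACTS),
        )
        ctrl = select_control(g, [block], all_motifs=[])
        assert ctrl is not None
        # the 3-gap run blocks part of the upstream flank; whatever window is
        # chosen must avoid it entirely
        for a, b in ctrl.segments:
            assert not (a <= 11 and b >= 9)

    def test_none_when_exhausted(self):
        rows = [CLEAN[:20]] * 2  # only motif columns, no flank of loop length
        block = _block(rows)
        g = _group(["SynAasim", "SynAbsim"], TestSubstitutionCounting.TRACTS)
        from g4cons.g4_scanner import G4Motif

        motif_everywhere = [
            G4Motif(
                species_code=c,
                strand="coding",
                start=1,
                end=20,
                tracts=((1, 3), (5, 7), (9, 11), (13, 15)),
                loops=("A", "A", "A"),
            )
            for c in ("SynAasim", "SynAbsim")
        ]
        assert select_control(g, [block], motif_everywhere) is None

    def test_fallback_to_other_block(self):
        rows_own = [CLEAN[:20]] * 2
        own = _block(rows_own, name="b")
        # a block over a distant promoter region, free of motifs
        other = AlignmentBlock(
            "c",
            [
                BlockFragment(c, 200, 223, "ATCTTACTATCATTACCTTACTAT")
                for c in ("SynAasim", "SynAbsim")
            ],
        )
        g = _group(["SynAasim", "SynAbsim"], TestSubstitutionCounting.TRACTS)
        from g4cons.g4_scanner import G4Motif

        motifs = [
            G4Motif(
                species_code=c,
                strand="coding",
                start=1,
                end=20,
                tracts=((1, 3), (5, 7), (9, 11), (13, 15)),
                loops=("A", "A", "A"),
            )
            for c in ("SynAasim", "SynAbsim")
        ]
        ctrl = select_control(g, [own, other], motifs)
        assert ctrl is not None and ctrl.source == "other_block"
        assert ctrl.block_name == "c"

    def test_control_density_counted_like_loops(self):
        # group loops total 5 columns, so the adjacent upstream control
        # window is columns 8-12; plant one difference inside it (col 9)
        rows = ["ATCTTACTAT" + CLEAN[:30]] * 2
        mutated = "ATCTTACTGT" + CLEAN[:30]
        block = _block([rows[0], mutated])
        g = _group(
            ["SynAasim", "SynAbsim"],
            tuple((s + 10, e + 10) for s, e in TestSubstitutionCounting.TRACTS),
        )
        ctrl = select_control(g, [block], all_motifs=[])
        recs = count_control_substitutions(g, ctrl, [block])
        assert len(recs) == 1 and recs[0].region == "control"


class TestDensity:
    def test_examples(self):
        assert density(4, 20) == 0.2
        assert density([], 10) == 0.0
        with pytest.raises(ValueError):
            density(3, 0)


class TestWilcoxon:
    def test_all_positive_five_pairs(self):
        pairs = [(0.5, 0.1), (0.4, 0.1), (0.3, 0.1), (0.25, 0.1), (0.2, 0.1)]
        p, method = wilcoxon_paired_greater(pairs)
        assert method == "exact"
        assert p == pytest.approx(1 / 32)

    def test_single_pair(self):
        p, _ = wilcoxon_paired_greater([(0.3, 0.1)])
        assert p == pytest.approx(0.5)

    def test_all_zero_differences_undefined(self):
        p, method = wilcoxon_paired_greater([(0.2, 0.2), (0.1, 0.1)])
        assert p is None and method == "undefined"

    def test_exact_branch_matches_enumeration(self, rng):
        for n in (2, 4, 6, 8, 10, 12):
            for _ in range(6):
                mags = rng.permutation(np.arange(1, n + 1)).astype(float)
                signs = rng.choice([-1.0, 1.0], size=n)
                diffs = mags * signs
                pairs = [(d, 0.0) for d in diffs]
                p, method = wilcoxon_paired_greater(pairs)
                assert method == "exact"
                assert p == pytest.approx(oracles.exact_signed_rank_p(diffs))

    def test_tied_ranks_fall_back_to_normal_approximation(self):
        pairs = [(0.3, 0.1), (0.4, 0.2), (0.1, 0.3), (0.6, 0.2)]  # |d| ties
        p, method = wilcoxon_paired_greater(pairs)
        assert method == "normal_approx"
        assert 0.0 < p < 1.0


class TestHolm:
    def test_published_family_adjustment(self):
        """Adjusting five raw order-level p-values: the smallest is scaled
        by the family size (0.003947 x 5 = 0.019735) and the running
        maximum propagates 0.6276 to the larger of the two middle values."""
        raw = [0.003947, 0.02381, 0.2648, 0.7797, 0.2092]
        adjusted = holm_bonferroni(raw)
        assert adjusted == pytest.approx(
            [0.019735, 0.09524, 0.6276, 0.7797, 0.6276]
        )

    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.3]) == [0.3]

    def test_cap_and_monotonicity(self):
        assert holm_bonferroni([0.6, 0.7]) == [1.0, 1.0]

    def test_elementwise_dominance_and_sorted_monotone(self, rng):
        for _ in range(20):
            ps = rng.uniform(size=int(rng.integers(1, 10)))
            adj = holm_bonferroni(ps)
            assert all(a >= p for a, p in zip(adj, ps))
            order = np.argsort(ps)
            assert list(np.array(adj)[order]) == sorted(np.array(adj)[order])

    def test_matches_statsmodels_and_oracle(self, rng):
        for _ in range(10):
            ps = list(rng.uniform(size=6))
            ours = holm_bonferroni(ps)
            sm = multipletests(ps, method="holm")[1]
            assert ours == pytest.approx(list(sm))
            assert ours == pytest.approx(oracles.holm_adjust(ps))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])
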