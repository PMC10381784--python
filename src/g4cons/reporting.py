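"""Summary tables and the end-to-end pipeline driver.

The driver runs, per order: motif scan → block construction (or import) →
column-interval clustering per block and strand → conserved-group calling →
substitution counting with matched controls → paired Wilcoxon, then one
Holm–Bonferroni step-down across all orders of the run.  Every intermediate
is written in the package's plain-text formats (TSV tables, aligned FASTA
blocks, JSON twins of each table).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from g4cons.block_alignment import AlignmentBlock, build_blocks, read_blocks, write_blocks
from g4cons.conserved_groups import (
    ConservedGroup,
    call_cluster_group,
    group_table,
    summarize_groups,
    write_group_slice,
)
from g4cons.dataset_io import PromoterSet, filter_n_runs, read_promoter_fasta
from g4cons.g4_scanner import G4Motif, motif_table, scan_promoter
from g4cons.motif_clustering import (
    DEFAULT_MIN_INTERSECTION,
    MotifCluster,
    cluster_table,
    find_clusters,
    map_block_motifs,
)
from g4cons.substitution_analysis import (
    DensityPair,
    OrderTestResult,
    adjust_family,
    build_density_pairs,
    count_loop_substitutions,
    count_tract_substitutions,
    run_order_test,
    substitution_spectrum,
)

logger = logging.getLogger("g4cons")

ZONES = ("core", "proximal", "distal")


def report_zone_table(
    motifs_by_order: dict[str, list[G4Motif]],
    psets: dict[str, PromoterSet],
) -> pd.DataFrame:
    """Per-order zone table: promoter counts, species without motifs, and
    coding/noncoding motif counts per TSS-distance zone.

    A species counts as "without motifs" when neither strand carries one.
    Zone partitions sum to the per-strand totals by construction; the mean
    motif count per species is appended for each order.
    """
    rows = []
    for order in sorted(psets):
        pset = psets[order]
        motifs = motifs_by_order.get(order, [])
        with_motifs = {m.species_code for m in motifs}
        row = {
            "order_code": order,
            "n_promoters": len(pset),
            "n_without_motifs": sum(
                1 for p in pset.promoters if p.species_code not in with_motifs
            ),
        }
        for strand in ("coding", "noncoding"):
            for zone in ZONES:
                row[f"{strand}_{zone}"] = sum(
                    1 for m in motifs if m.strand == strand and m.zone == zone
                )
            row[f"{strand}_total"] = sum(1 for m in motifs if m.strand == strand)
        row["mean_motifs_per_species"] = (
            len(motifs) / len(pset) if len(pset) else 0.0
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    # internal consistency: zones partition the strand totals
    for strand in ("coding", "noncoding"):
        zone_sum = sum(df[f"{strand}_{z}"] for z in ZONES)
        assert (zone_sum == df[f"{strand}_total"]).all()
    return df


def report_distance_histogram(motifs: list[G4Motif], bin_width: int = 50) -> pd.DataFrame:
    """Per-strand binned counts of motif TSS distances."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    rows: dict[tuple[int, str], int] = {}
    for m in motifs:
        b = m.tss_distance // bin_width
        rows[(b, m.strand)] = rows.get((b, m.strand), 0) + 1
    out = [
        {
            "bin_start": b * bin_width,
            "bin_end": (b + 1) * bin_width - 1,
            "strand": strand,
            "count": c,
        }
        for (b, strand), c in sorted(rows.items())
    ]
    return pd.DataFrame(out, columns=["bin_start", "bin_end", "strand", "count"])


def _dedupe_groups(
    candidates: list[ConservedGroup], blocks_by_name: dict[str, AlignmentBlock]
) -> list[ConservedGroup]:
    """One group per underlying promoter locus.

    Overlapping and sibling blocks can call the same conserved locus more
    than once; duplicates are recognised when two same-strand groups place a
    shared species' tracts on identical promoter coordinates.  The call with
    the most members wins (ties: earliest group id), so each locus enters
    the substitution test exactly once with its maximal membership.
    """
    item_to_component: dict[tuple, int] = {}
    parent = list(range(len(candidates)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, g in enumerate(candidates):
        block = blocks_by_name[g.block_name]
        for code in g.members:
            frag = block.fragment(code)
            coords = tuple(
                (frag.position_of(s), frag.position_of(e)) for s, e in g.tract_columns
            )
            item = (g.strand, code, coords)
            if item in item_to_component:
                ri, rj = find(item_to_component[item]), find(i)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
            else:
                item_to_component[item] = i
    best: dict[int, ConservedGroup] = {}
    for i, g in enumerate(candidates):
        root = find(i)
        cur = best.get(root)
        if cur is None or (len(g.members), cur.group_id) > (len(cur.members), g.group_id):
            best[root] = g
    return [best[r] for r in sorted(best, key=lambda r: candidates[r].group_id)]


@dataclass
class OrderAnalysis:
    """Everything the pipeline computes for one order."""

    order_code: str
    pset: PromoterSet
    motifs: list[G4Motif] = field(default_factory=list)
    blocks: list[AlignmentBlock] = field(default_factory=list)
    clusters: list[MotifCluster] = field(default_factory=list)
    groups: list[ConservedGroup] = field(default_factory=list)
    pairs: list[DensityPair] = field(default_factory=list)
    excluded_groups: list[str] = field(default_factory=list)
    test: OrderTestResult | None = None


def analyze_order(
    pset: PromoterSet,
    *,
    blocks: list[AlignmentBlock] | None = None,
    k: int = 12,
    min_identity: float = 0.8,
    min_width: int = 100,
    min_intersection: int = DEFAULT_MIN_INTERSECTION,
    min_members: int = 2,
) -> OrderAnalysis:
    """Run scan → blocks → clusters → groups → substitution test for one order."""
    res = OrderAnalysis(pset.order_code, pset)
    for p in pset.promoters:
        res.motifs.extend(scan_promoter(p))
    res.blocks = (
        blocks
        if blocks is not None
        else build_blocks(pset, k=k, min_identity=min_identity, min_width=min_width)
    )
    gid = 0
    candidates: list[ConservedGroup] = []
    by_name = {b.name: b for b in res.blocks}
    for block in res.blocks:
        intervals = map_block_motifs(block, res.motifs)
        for strand in ("coding", "noncoding"):
            sub = [iv for iv in intervals if iv.strand == strand]
            clusters = find_clusters(sub, min_intersection)
            res.clusters.extend(clusters)
            for cl in clusters:
                gid += 1
                g = call_cluster_group(
                    cl, block, min_members, group_id=f"{pset.order_code}_g{gid}"
                )
                if g is not None:
                    g.order_code = pset.order_code
                    candidates.append(g)
    res.groups = _dedupe_groups(candidates, by_name)
    res.pairs, res.excluded_groups = build_density_pairs(
        res.groups, res.blocks, res.motifs
    )
    res.test = run_order_test(res.groups, res.blocks, res.motifs, pset.order_code)
    return res


def order_results_table(results: list[OrderTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "order_code": r.order_code,
                "n_pairs": r.n_pairs,
                "p_raw": r.p_raw,
                "p_holm": r.p_holm,
                "n_loop_exceeds_control": r.n_loop_exceeds_control,
                "method": r.method,
                "n_excluded": r.n_excluded,
            }
            for r in results
        ]
    )


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)
    path.with_suffix(".json").write_text(df.to_json(orient="records", indent=1))


def run_all(config: dict, out_dir: str | Path) -> Path:
    """End-to-end run over one or more orders from a config mapping.

    Config keys: ``inputs`` (order_code → FASTA path or, alternatively,
    precomputed datasets), optional ``blocks_dir`` per order, and per-stage
    parameters (``k``, ``min_identity``, ``min_width``, ``min_intersection``,
    ``min_members``, ``max_n_run``).  Missing input paths fail before any
    stage runs.
    """
    out = Path(out_dir)
    inputs = config.get("inputs", {})
    if not inputs:
        raise ValueError("config.inputs is empty")
    for path in inputs.values():
        if not Path(path).exists():
            raise FileNotFoundError(path)
    out.mkdir(parents=True, exist_ok=True)
    params = {
        key: config[key]
        for key in ("k", "min_identity", "min_width", "min_intersection", "min_members")
        if key in config
    }
    analyses: list[OrderAnalysis] = []
    for order in sorted(inputs):
        pset = read_promoter_fasta(inputs[order], order_code=order)
        pset = filter_n_runs(pset, config.get("max_n_run", 100))
        blocks = None
        blocks_dir = config.get("blocks_dirs", {}).get(order)
        if blocks_dir:
            blocks = read_blocks(blocks_dir, pset)
        logger.info("order %s: %d promoters", order, len(pset))
        analyses.append(analyze_order(pset, blocks=blocks, **params))
    tests = adjust_family([a.test for a in analyses if a.test is not None])

    motifs_by_order = {a.order_code: a.motifs for a in analyses}
    psets = {a.order_code: a.pset for a in analyses}
    _write_table(report_zone_table(motifs_by_order, psets), out / "zone_table.tsv")
    all_motifs = [m for a in analyses for m in a.motifs]
    _write_table(report_distance_histogram(all_motifs), out / "distance_histogram.tsv")
    _write_table(
        motif_table(all_motifs) if all_motifs else pd.DataFrame(), out / "motifs.tsv"
    )
    for a in analyses:
        write_blocks(a.blocks, out / "blocks" / a.order_code)
    _write_table(
        pd.concat(
            [cluster_table(a.clusters) for a in analyses if a.clusters],
            ignore_index=True,
        )
        if any(a.clusters for a in analyses)
        else pd.DataFrame(),
        out / "clusters.tsv",
    )
    all_groups = [g for a in analyses for g in a.groups]
    _write_table(
        group_table(all_groups) if all_groups else pd.DataFrame(), out / "groups.tsv"
    )
    for a in analyses:
        if not a.groups:
            continue
        slice_dir = out / "groups" / a.order_code
        slice_dir.mkdir(parents=True, exist_ok=True)
        for g in a.groups:
            blk = next(b for b in a.blocks if b.name == g.block_name)
            write_group_slice(g, blk, slice_dir / f"{g.group_id}.fasta")
    if all_groups:
        summary = summarize_groups(all_groups)
        _write_table(summary["counts"], out / "group_counts.tsv")
        _write_table(summary["lengths"], out / "group_lengths.tsv")
    sub_records = []
    for a in analyses:
        for g in a.groups:
            blk = next(b for b in a.blocks if b.name == g.block_name)
            sub_records.extend(count_loop_substitutions(g, blk))
            sub_records.extend(count_tract_substitutions(g, blk))
    if sub_records:
        _write_table(
            pd.DataFrame(
                [
                    {
                        "group_id": r.group_id,
                        "column": r.column,
                        "region": r.region,
                        "species_code": r.species_code,
                        "observed": r.observed,
                        "consensus": r.consensus,
                        "type": r.type_label,
                    }
                    for r in sub_records
                ]
            ),
            out / "substitutions.tsv",
        )
        _write_table(substitution_spectrum(sub_records), out / "spectra.tsv")
    pairs_rows = [
        {
            "order_code": a.order_code,
            "group_id": p.group_id,
            "loop_density": p.loop_density,
            "control_density": p.control_density,
            "loop_total_length": p.loop_total_length,
            "control_source": p.control_source,
        }
        for a in analyses
        for p in a.pairs
    ]
    _write_table(pd.DataFrame(pairs_rows), out / "density_pairs.tsv")
    _write_table(order_results_table(tests), out / "order_tests.tsv")
    (out / "run_config.json").write_text(json.dumps(config, indent=1, default=str))
    return out
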