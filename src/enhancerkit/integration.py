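"""Dataset integrators: expression units, nearest-gene tables, co-occupancy.

FPKM_g = count_g * 1e9 / (exonic_length_g * library_total)
TPM_g  = (count_g / length_g) * 1e6 / sum_j (count_j / length_j)

so TPM always sums to 1e6 whenever any count is positive. The near-peak
table joins each peak to its nearest gene (unstranded edge distance, ties
broken deterministically) together with that gene's FPKM/TPM. Promoter
co-occupancy asks, for a strand-aware window of −250/+1000 bp around each
TSS, whether every supplied peak set overlaps the window by at least 1 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import Interval, nearest_feature
from .track_io import GeneAnnotation, PeakSet

log = logging.getLogger(__name__)


@dataclass
class ExpressionTable:
    """Per-gene raw counts with length- and depth-normalized units."""

    table: pd.DataFrame  # columns: gene, count, length, fpkm, tpm
    library_total: int

    def by_gene(self) -> pd.DataFrame:
        return self.table.set_index("gene")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def compute_expression(
    counts: Mapping[str, int],
    lengths: Mapping[str, int],
    library_total: int | None = None,
) -> ExpressionTable:
    """FPKM and TPM from raw gene counts and exonic lengths.

    ``library_total`` defaults to the sum of counts. All-zero counts yield
    an all-zero table; a gene missing a length raises.
    """
    genes = list(counts.keys())
    missing = [g for g in genes if g not in lengths]
    if missing:
        raise KeyError(f"gene {missing[0]!r} has no exonic length")
    cnt = np.array([counts[g] for g in genes], dtype=np.float64)
    lng = np.array([lengths[g] for g in genes], dtype=np.float64)
    if np.any(cnt < 0):
        raise ValueError("negative count")
    if np.any(lng <= 0):
        raise ValueError("non-positive gene length")
    if library_total is None:
        library_total = int(cnt.sum())
    rate = cnt / lng
    if library_total > 0:
        fpkm = cnt * 1e9 / (lng * library_total)
    else:
        fpkm = np.zeros_like(cnt)
    denom = rate.sum()
    tpm = rate * 1e6 / denom if denom > 0 else np.zeros_like(rate)
    df = pd.DataFrame(
        {"gene": genes, "count": cnt.astype(np.int64), "length": lng.astype(np.int64),
         "fpkm": fpkm, "tpm": tpm}
    )
    return ExpressionTable(df, library_total)


def gene_expression_near_peaks(
    peaks: Sequence[tuple[Interval, str]] | PeakSet,
    genes: GeneAnnotation,
    expr: ExpressionTable,
) -> pd.DataFrame:
    """One row per peak: nearest gene, signed distance, and its FPKM/TPM.

    Peaks with no gene on their chromosome are flagged unassigned.
    """
    if len(genes) == 0:
        raise ValueError("empty gene annotation")
    if isinstance(peaks, PeakSet):
        peak_list = [(p.interval, p.name) for p in peaks]
    else:
        peak_list = list(peaks)
    features = [(g.interval, g.gene_id) for g in genes]
    expr_by_gene = expr.by_gene()
    rows = []
    for iv, name in peak_list:
        hit = nearest_feature(iv, features)
        row = {
            "peak": name,
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "gene": hit.feature_id if not hit.unassigned else "",
            "distance": hit.distance if not hit.unassigned else np.nan,
            "unassigned": hit.unassigned,
            "fpkm": np.nan,
            "tpm": np.nan,
        }
        if not hit.unassigned and hit.feature_id in expr_by_gene.index:
            row["fpkm"] = float(expr_by_gene.loc[hit.feature_id, "fpkm"])
            row["tpm"] = float(expr_by_gene.loc[hit.feature_id, "tpm"])
        rows.append(row)
    return pd.DataFrame(rows)


def promoter_proximal_window(gene, upstream: int, downstream: int, chrom_length: int) -> Interval:
    """Strand-aware TSS window: upstream is 5' of the TSS along the gene.

    For a + strand gene with TSS t the window is ``[t - upstream,
    t + downstream)``; for a - strand gene upstream extends toward larger
    coordinates: ``[t - downstream + 1, t + upstream + 1)``. Clipped to the
    chromosome.
    """
    t = gene.tss
    if gene.interval.strand == "-":
        start, end = t - downstream + 1, t + upstream + 1
    else:
        start, end = t - upstream, t + downstream
    return Interval(gene.interval.chrom, max(0, start), min(chrom_length, end))


def promoter_cooccupancy(
    genes: GeneAnnotation,
    peak_sets: Mapping[str, PeakSet],
    upstream: int = 250,
    downstream: int = 1000,
) -> tuple[pd.DataFrame, int]:
    """Per-gene occupancy flags over all peak sets, plus the co-occupied count.

    A gene is co-occupied iff *every* peak set overlaps its
    promoter-proximal window by at least 1 bp. Genes sharing a gene id keep
    only their first record in genome order (logged).
    """
    if not peak_sets:
        raise ValueError("need at least one peak set")
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be >= 0")
    genome = genes.genome
    seen: dict[str, object] = {}
    ordered = sorted(genes, key=lambda g: genome.sort_key(g.interval))
    dupes = 0
    uniq = []
    for g in ordered:
        if g.gene_id in seen:
            dupes += 1
            continue
        seen[g.gene_id] = g
        uniq.append(g)
    if dupes:
        log.info("co-occupancy: kept first record for %d duplicated gene ids", dupes)

    trees: dict[str, dict[str, IntervalTree]] = {}
    for name, ps in peak_sets.items():
        trees[name] = {}
        for p in ps:
            trees[name].setdefault(p.interval.chrom, IntervalTree()).addi(
                p.interval.start, p.interval.end
            )

    rows = []
    co_count = 0
    for g in uniq:
        win = promoter_proximal_window(g, upstream, downstream, genome.length(g.interval.chrom))
        flags = {}
        for name in peak_sets:
            tree = trees[name].get(win.chrom)
            flags[name] = bool(tree is not None and tree.overlap(win.start, win.end))
        co = all(flags.values())
        co_count += co
        rows.append(
            {"gene": g.gene_id, "chrom": win.chrom, "window_start": win.start,
             "window_end": win.end, **{f"occupied_{n}": flags[n] for n in peak_sets},
             "co_occupied": co}
        )
    return pd.DataFrame(rows), co_count
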