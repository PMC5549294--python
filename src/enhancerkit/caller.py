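"""Genome-wide enhancer calling.

The trained classifier is applied to every 200-bp window of the genome;
enhancer-classed windows within 1 bp of each other are merged into
continuous elements (a merged call carries the maximum window probability);
calls must overlap a q-passing DNase hypersensitive peak by at least 1 bp
to be validated; validated calls are stratified into "active" and "primed"
states by their mean H3K27ac coverage; optional GRO-seq strand tracks give
per-call sense/antisense eRNA coverage; metagene matrices over call
midpoints ± 3 kb support heatmap/profile rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import Config, Genome, Interval, Window, make_windows, merge_intervals, overlap_bp
from .features import extract_features
from .model import EnhancerModel
from .track_io import CoverageTrack, PeakSet

log = logging.getLogger(__name__)

STATE_ACTIVE = "active"
STATE_PRIMED = "primed"
STATE_UNASSIGNED = "unassigned"


class ScoredWindow(NamedTuple):
    window: Window
    probability: float
    is_enhancer: bool


@dataclass
class EnhancerCall:
    """A merged (optionally DHS-validated, state-annotated) enhancer element."""

    interval: Interval
    probability: float
    validated: bool = False
    state: str = STATE_UNASSIGNED
    mark_means: dict[str, float] = field(default_factory=dict)
    erna: tuple[float, float] | None = None  # (sense, antisense) mean RPM


def scan_genome(
    model: EnhancerModel,
    genome: Genome,
    tracks: Mapping[str, CoverageTrack],
    config: Config,
) -> list[ScoredWindow]:
    """Score every scan window with the classifier.

    A window is classed "enhancer" iff its enhancer-class probability is at
    least ``config.prob_threshold``. The result is independent of
    chromosome processing order (windows are in genome order).
    """
    windows = make_windows(genome, config.window_size)
    ordered = {m: tracks[m] for m in model.markers}  # raises KeyError on a missing marker
    feats = extract_features([w.interval for w in windows], ordered, flank=model.flank)
    proba = model.predict_proba(feats)
    thr = config.prob_threshold
    return [ScoredWindow(w, float(p), bool(p >= thr)) for w, p in zip(windows, proba)]


def call_enhancers(scored: Sequence[ScoredWindow], config: Config, genome: Genome | None = None) -> list[EnhancerCall]:
    """Merge enhancer-classed windows within ``merge_gap`` bp into calls.

    A call's probability is the maximum over its member windows, preserving
    the strongest evidence through the merge.
    """
    hits = [(sw.window.interval, sw.probability) for sw in scored if sw.is_enhancer]
    if not hits:
        return []
    merged = merge_intervals([iv for iv, _ in hits], config.merge_gap, genome)
    calls = [EnhancerCall(iv, 0.0) for iv in merged]
    by_chrom: dict[str, list[EnhancerCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.interval.chrom, []).append(c)
    for iv, prob in hits:
        for call in by_chrom[iv.chrom]:
            if overlap_bp(call.interval, iv) > 0:
                call.probability = max(call.probability, prob)
                break
    return calls


def validate_with_dhs(calls: Sequence[EnhancerCall], dhs: PeakSet, config: Config) -> list[EnhancerCall]:
    """Keep calls overlapping a retained DHS peak by >= ``min_dhs_overlap`` bp.

    ``dhs`` is expected to be q-filtered already (on read). The discarded
    count is logged; an empty peak set yields an empty validated list with
    a warning.
    """
    if len(dhs) == 0:
        log.warning("empty DHS peak set: no call can be validated")
        return []
    trees: dict[str, IntervalTree] = {}
    for p in dhs:
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(p.interval.start, p.interval.end)
    validated = []
    for call in calls:
        iv = call.interval
        best = 0
        for hit in trees.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end):
            best = max(best, min(iv.end, hit.end) - max(iv.start, hit.begin))
        if best >= config.min_dhs_overlap:
            validated.append(replace(call, validated=True))
    log.info("DHS validation: %d of %d calls retained", len(validated), len(calls))
    return validated


def classify_states(
    calls: Sequence[EnhancerCall],
    h3k27ac: CoverageTrack,
    threshold: float | None = None,
) -> tuple[list[EnhancerCall], float]:
    """Stratify calls into active/primed by mean H3K27ac over the call.

    ``threshold`` defaults to the genome-wide mean of the H3K27ac track
    (above-background). Returns the annotated calls and the threshold used.
    """
    if threshold is None:
        threshold = h3k27ac.genome_wide_mean()
    out = []
    if calls:
        means = h3k27ac.means([c.interval for c in calls])
        for call, m in zip(calls, means):
            state = STATE_ACTIVE if m >= threshold else STATE_PRIMED
            marks = dict(call.mark_means)
            marks["H3K27ac"] = float(m)
            out.append(replace(call, state=state, mark_means=marks))
    return out, float(threshold)


def annotate_mark_means(
    calls: Sequence[EnhancerCall], tracks: Mapping[str, CoverageTrack]
) -> list[EnhancerCall]:
    """Attach the mean coverage of every supplied marker to each call."""
    out = [replace(c, mark_means=dict(c.mark_means)) for c in calls]
    if out:
        ivs = [c.interval for c in out]
        for marker, track in tracks.items():
            for call, m in zip(out, track.means(ivs)):
                call.mark_means[marker] = float(m)
    return out


def erna_coverage(
    calls: Sequence[EnhancerCall],
    gro_plus: CoverageTrack | None,
    gro_minus: CoverageTrack | None,
) -> list[EnhancerCall]:
    """Per-call (sense, antisense) mean GRO-seq coverage over the call span.

    Plus-strand coverage is reported as sense, minus-strand as antisense.
    With either track missing the fields are left empty with a warning.
    """
    if gro_plus is None or gro_minus is None:
        log.warning("missing GRO-seq strand track: eRNA coverage left empty")
        return [replace(c) for c in calls]
    out = [replace(c) for c in calls]
    if out:
        ivs = [c.interval for c in out]
        sense = gro_plus.means(ivs)
        anti = gro_minus.means(ivs)
        for call, s, a in zip(out, sense, anti):
            call.erna = (float(s), float(a))
    return out


@dataclass
class MetageneMatrix:
    """Signal matrix over call midpoints ± flank, binned, for heatmaps."""

    values: np.ndarray  # (n_calls, n_bins)
    bin_offsets: np.ndarray  # bin start offsets relative to the midpoint
    call_order: list[int]  # row -> index into the input call list
    bin_size: int
    flank: int

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=[str(int(o)) for o in self.bin_offsets])
        df.insert(0, "call", self.call_order)
        df.to_csv(path, sep="\t", index=False)


def metagene_matrix(
    calls: Sequence[EnhancerCall],
    track: CoverageTrack,
    flank: int = 3000,
    bin_size: int = 50,
    rank_track: CoverageTrack | None = None,
) -> MetageneMatrix:
    """Binned signal across midpoint ± ``flank`` for every call.

    Rows are ordered by decreasing mean of ``rank_track`` (default: the
    track itself) over the call, ties broken by genome order of the input.
    Bins clipped at chromosome edges contribute the mean of their clipped
    part; a fully out-of-range bin is 0.
    """
    if not calls:
        raise ValueError("no calls to profile")
    if (2 * flank) % bin_size:
        raise ValueError("bin_size must divide 2 * flank")
    n_bins = 2 * flank // bin_size
    offsets = np.arange(-flank, flank, bin_size)

    ranker = rank_track if rank_track is not None else track
    rank_vals = ranker.means([c.interval for c in calls])
    order = sorted(range(len(calls)), key=lambda i: (-rank_vals[i], i))

    genome = track.genome
    values = np.zeros((len(calls), n_bins), dtype=np.float64)
    for row, i in enumerate(order):
        iv = calls[i].interval
        mid = iv.midpoint
        L = genome.length(iv.chrom)
        starts = mid + offsets
        ends = starts + bin_size
        cs = np.clip(starts, 0, L)
        ce = np.clip(ends, 0, L)
        width = ce - cs
        sig = track.signal_integral(iv.chrom, ce) - track.signal_integral(iv.chrom, cs)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(width > 0, sig / np.maximum(width, 1), 0.0)
        values[row] = vals
    return MetageneMatrix(values, offsets, order, bin_size, flank)


_CALL_COLUMNS = [
    "chrom", "start", "end", "name", "probability", "validated", "state",
    "erna_sense", "erna_antisense",
]


def write_calls_tsv(calls: Sequence[EnhancerCall], path, genome: Genome) -> None:
    """Extended call table: BED-like coordinates plus probability, state,
    per-mark means and eRNA coverages."""
    order = sorted(range(len(calls)), key=lambda i: genome.sort_key(calls[i].interval))
    markers = sorted({m for c in calls for m in c.mark_means})
    cols = _CALL_COLUMNS + [f"mean_{m}" for m in markers]
    rows = []
    for out_i, i in enumerate(order):
        c = calls[i]
        row = {
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "name": f"enh_{out_i + 1}",
            "probability": repr(c.probability),
            "validated": int(c.validated),
            "state": c.state,
            "erna_sense": repr(c.erna[0]) if c.erna else "",
            "erna_antisense": repr(c.erna[1]) if c.erna else "",
        }
        for m in markers:
            row[f"mean_{m}"] = repr(c.mark_means[m]) if m in c.mark_means else ""
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path, genome: Genome) -> list[EnhancerCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    calls = []
    for _, r in df.iterrows():
        marks = {
            col[len("mean_"):]: float(r[col])
            for col in df.columns
            if col.startswith("mean_") and pd.notna(r[col])
        }
        erna = None
        if "erna_sense" in df.columns and pd.notna(r["erna_sense"]):
            erna = (float(r["erna_sense"]), float(r["erna_antisense"]))
        calls.append(
            EnhancerCall(
                Interval(r["chrom"], int(r["start"]), int(r["end"])).validate(genome),
                float(r["probability"]),
                bool(r["validated"]),
                str(r["state"]),
                marks,
                erna,
            )
        )
    return calls
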