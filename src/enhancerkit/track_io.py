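"""Readers and writers for bedGraph, BED, narrowPeak and GTF.

Coverage tracks are step functions: per-chromosome sorted, non-overlapping
``(start, end, value)`` segments in RPM units, with implicit value 0 over
uncovered bases. Readers reject malformed records (with line numbers) rather
than silently repairing them; records on chromosomes absent from the genome
are dropped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

from .genome import Genome, Interval

log = logging.getLogger(__name__)

_BEDGRAPH_HEADERS = ("track", "browser", "#")


@dataclass
class CoverageTrack:
    """Step-function coverage over a genome (bedGraph semantics).

    Internally each chromosome holds sorted ``starts``, ``ends`` and
    ``values`` arrays plus a cumulative signal integral, so interval means
    are O(log n) lookups of the antiderivative.
    """

    genome: Genome
    _chrom_data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)
    _cum: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @classmethod
    def from_segments(
        cls, genome: Genome, segments: Iterable[tuple[str, int, int, float]]
    ) -> "CoverageTrack":
        """Build a track from ``(chrom, start, end, value)`` records.

        Segments on a chromosome must not overlap; they need not be sorted.
        """
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in segments:
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        track = cls(genome)
        for chrom, segs in by_chrom.items():
            if chrom not in genome:
                raise ValueError(f"segment on unknown chromosome {chrom!r}")
            segs.sort()
            starts = np.array([s for s, _, _ in segs], dtype=np.int64)
            ends = np.array([e for _, e, _ in segs], dtype=np.int64)
            values = np.array([v for _, _, v in segs], dtype=np.float64)
            if np.any(starts >= ends):
                i = int(np.argmax(starts >= ends))
                raise ValueError(f"segment with start >= end at {chrom}:{starts[i]}-{ends[i]}")
            if np.any(ends[:-1] > starts[1:]):
                i = int(np.argmax(ends[:-1] > starts[1:]))
                raise ValueError(
                    f"overlapping segments on {chrom}: "
                    f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
                )
            if ends[-1] > genome.length(chrom):
                raise ValueError(f"segment past end of {chrom}: {ends[-1]} > {genome.length(chrom)}")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"non-finite coverage value on {chrom}")
            track._chrom_data[chrom] = (starts, ends, values)
        return track

    @classmethod
    def from_arrays(cls, genome: Genome, arrays: dict[str, np.ndarray], bin_size: int) -> "CoverageTrack":
        """Build a track from per-chromosome binned value arrays.

        ``arrays[chrom][i]`` is the value over ``[i*bin_size, (i+1)*bin_size)``
        clipped to the chromosome end; zero bins are dropped and runs of equal
        value are merged into single segments.
        """
        segments = []
        for chrom, vals in arrays.items():
            L = genome.length(chrom)
            vals = np.asarray(vals, dtype=np.float64)
            if len(vals):
                # boundaries of runs of equal value
                change = np.flatnonzero(vals[1:] != vals[:-1]) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(vals)]))
                for s, e in zip(starts, ends):
                    v = vals[s]
                    if v != 0.0:
                        segments.append((chrom, s * bin_size, min(e * bin_size, L), v))
        return cls.from_segments(genome, segments)

    def segments(self) -> Iterator[tuple[str, int, int, float]]:
        """Yield segments in genome order."""
        for chrom in self.genome.names:
            if chrom not in self._chrom_data:
                continue
            starts, ends, values = self._chrom_data[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def _cumulative(self, chrom: str) -> np.ndarray:
        if chrom not in self._cum:
            starts, ends, values = self._chrom_data[chrom]
            self._cum[chrom] = np.concatenate(([0.0], np.cumsum(values * (ends - starts))))
        return self._cum[chrom]

    def signal_integral(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Antiderivative of coverage evaluated at ``positions`` (vectorised)."""
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self._chrom_data:
            return np.zeros(positions.shape, dtype=np.float64)
        starts, ends, values = self._chrom_data[chrom]
        cum = self._cumulative(chrom)
        idx = np.searchsorted(starts, positions, side="right") - 1
        idx_c = np.clip(idx, 0, len(starts) - 1)
        inside = np.clip(positions - starts[idx_c], 0, ends[idx_c] - starts[idx_c])
        out = cum[idx_c] + values[idx_c] * inside
        return np.where(idx < 0, 0.0, out)

    def means(self, intervals: Sequence[Interval]) -> np.ndarray:
        """Mean coverage over each interval (uncovered bases count as 0)."""
        out = np.zeros(len(intervals), dtype=np.float64)
        by_chrom: dict[str, list[int]] = {}
        for i, iv in enumerate(intervals):
            by_chrom.setdefault(iv.chrom, []).append(i)
        for chrom, idxs in by_chrom.items():
            starts = np.array([intervals[i].start for i in idxs], dtype=np.int64)
            ends = np.array([intervals[i].end for i in idxs], dtype=np.int64)
            sig = self.signal_integral(chrom, ends) - self.signal_integral(chrom, starts)
            out[idxs] = sig / (ends - starts)
        return out

    def total_signal(self) -> float:
        """Integral of coverage over the whole genome (RPM·bp)."""
        return float(
            sum(self._cumulative(c)[-1] for c in self._chrom_data)
        )

    def genome_wide_mean(self) -> float:
        return self.total_signal() / self.genome.total_length()

    def scaled(self, factor: float) -> "CoverageTrack":
        track = CoverageTrack(self.genome)
        for chrom, (s, e, v) in self._chrom_data.items():
            track._chrom_data[chrom] = (s.copy(), e.copy(), v * factor)
        return track


class Peak(NamedTuple):
    """One ENCODE narrowPeak record."""

    interval: Interval
    name: str
    score: int
    signal_value: float
    p_value: float  # -log10; -1 when missing
    q_value: float  # -log10; -1 when missing
    summit: int  # offset from start; -1 when not called


@dataclass
class PeakSet:
    """A collection of narrowPeak calls tied to a genome."""

    genome: Genome
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def intervals(self) -> list[Interval]:
        return [p.interval for p in self.peaks]

    def q_filtered(self, q_max: float) -> "PeakSet":
        """Retain peaks with q-value below ``q_max`` (−log10 score ≥ threshold).

        A missing q-value (sentinel −1) fails the filter.
        """
        thr = -np.log10(q_max)
        kept = [p for p in self.peaks if p.q_value >= thr]
        dropped = len(self.peaks) - len(kept)
        if dropped:
            log.info("q-filter (q < %g): discarded %d of %d peaks", q_max, dropped, len(self.peaks))
        return PeakSet(self.genome, kept)


class Gene(NamedTuple):
    gene_id: str
    symbol: str
    interval: Interval  # stranded gene span
    tss: int  # 0-based TSS position (start for +, end-1 for -)
    exonic_length: int  # bp in the union of the gene's exons


@dataclass
class GeneAnnotation:
    genome: Genome
    genes: list[Gene] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def by_id(self) -> dict[str, Gene]:
        return {g.gene_id: g for g in self.genes}


def _data_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith(_BEDGRAPH_HEADERS):
                continue
            yield lineno, stripped.split()


def read_bedgraph(path, genome: Genome, rescale_rpm: bool = False) -> CoverageTrack:
    """Read a 4-column bedGraph into a :class:`CoverageTrack`.

    Values are taken as already RPM-normalized; with ``rescale_rpm`` raw
    values are rescaled to RPM units (value × 1e6 / total signal). Records on
    chromosomes missing from ``genome`` are dropped with a logged count;
    overlapping records, non-numeric values and inverted coordinates raise.
    """
    segments = []
    skipped = 0
    for lineno, fields in _data_lines(path):
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns, got {len(fields)}")
        chrom, s, e, v = fields
        try:
            start, end = int(s), int(e)
            value = float(v)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric bedGraph record") from None
        if start < 0:
            raise ValueError(f"{path}:{lineno}: negative coordinate")
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
        if chrom not in genome:
            skipped += 1
            continue
        segments.append((chrom, start, end, value))
    if skipped:
        log.info("%s: dropped %d records on chromosomes absent from genome", path, skipped)
    track = CoverageTrack.from_segments(genome, segments)
    if rescale_rpm:
        total = track.total_signal()
        if total > 0:
            track = track.scaled(1e6 / total)
    return track


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a track as bedGraph, merging adjacent runs of equal value."""
    with open(path, "w") as fh:
        prev = None  # (chrom, start, end, value) pending
        for chrom, start, end, value in track.segments():
            if prev is not None and prev[0] == chrom and prev[2] == start and prev[3] == value:
                prev = (chrom, prev[1], end, value)
                continue
            if prev is not None:
                fh.write(f"{prev[0]}\t{prev[1]}\t{prev[2]}\t{prev[3]!r}\n")
            prev = (chrom, start, end, value)
        if prev is not None:
            fh.write(f"{prev[0]}\t{prev[1]}\t{prev[2]}\t{prev[3]!r}\n")


def read_narrowpeak(path, genome: Genome, q_max: float | None = None) -> PeakSet:
    """Read an ENCODE narrowPeak (BED6+4) file.

    With ``q_max`` given, peaks whose −log10 q-value falls below
    ``−log10(q_max)`` are discarded (missing q-values fail the filter).
    """
    peaks = []
    skipped = 0
    for lineno, fields in _data_lines(path):
        if len(fields) != 10:
            raise ValueError(f"{path}:{lineno}: expected 10 narrowPeak columns, got {len(fields)}")
        chrom, s, e, name, score, strand, signal, p, q, summit = fields
        start, end = int(s), int(e)
        if start < 0:
            raise ValueError(f"{path}:{lineno}: negative coordinate")
        if chrom not in genome:
            skipped += 1
            continue
        strand = strand if strand in ("+", "-") else "."
        peaks.append(
            Peak(
                Interval(chrom, start, end, strand).validate(genome),
                name,
                int(float(score)),
                float(signal),
                float(p),
                float(q),
                int(summit),
            )
        )
    if skipped:
        log.info("%s: dropped %d peaks on chromosomes absent from genome", path, skipped)
    ps = PeakSet(genome, peaks)
    if q_max is not None:
        ps = ps.q_filtered(q_max)
    return ps


def write_narrowpeak(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.score}\t{iv.strand}"
                f"\t{p.signal_value!r}\t{p.p_value!r}\t{p.q_value!r}\t{p.summit}\n"
            )


def read_bed(path, genome: Genome) -> list[tuple[Interval, str]]:
    """Read a BED3+/BED6 file into ``(interval, name)`` pairs."""
    out = []
    skipped = 0
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
        chrom, s, e = fields[0], int(fields[1]), int(fields[2])
        if s < 0:
            raise ValueError(f"{path}:{lineno}: negative coordinate")
        if chrom not in genome:
            skipped += 1
            continue
        name = fields[3] if len(fields) > 3 else f"feature_{lineno}"
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
        out.append((Interval(chrom, s, e, strand).validate(genome), name))
    if skipped:
        log.info("%s: dropped %d features on chromosomes absent from genome", path, skipped)
    return out


def write_bed(
    elements: Sequence[Interval],
    path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
    genome: Genome | None = None,
) -> None:
    """Write BED6. Scores are probabilities mapped to the integer 0–1000 range."""
    rows = list(range(len(elements)))
    if genome is not None:
        rows.sort(key=lambda i: genome.sort_key(elements[i]))
    with open(path, "w") as fh:
        for out_i, i in enumerate(rows):
            iv = elements[i]
            name = names[i] if names is not None else f"enh_{out_i + 1}"
            score = int(np.clip(round(1000 * scores[i]), 0, 1000)) if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def _exon_union_length(exons: list[tuple[int, int]]) -> int:
    exons = sorted(exons)
    total = 0
    cur_s, cur_e = exons[0]
    for s, e in exons[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    return total + cur_e - cur_s


# fixed GTF 2.2 attribute dialect; gffutils' sniffer can mis-infer it from
# files whose sampled lines carry a single attribute each
_GTF_DIALECT = {
    "multival separator": ",",
    "trailing semicolon": True,
    "leading semicolon": False,
    "semicolon in quotes": False,
    "field separator": "; ",
    "fmt": "gtf",
    "keyval separator": " ",
    "repeated keys": False,
    "quoted GFF2 values": True,
    "order": ["gene_id", "gene_name", "transcript_id"],
}


def _read_gtf(path, genome: Genome) -> GeneAnnotation:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        dialect=_GTF_DIALECT,
    )
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    for ex in db.features_of_type("exon"):
        gid = ex.attributes.get("gene_id", [None])[0]
        if gid is not None:
            # gffutils keeps GTF 1-based inclusive coordinates
            exons_by_gene.setdefault(gid, []).append((ex.start - 1, ex.end))
    genes = []
    skipped = 0
    for g in db.features_of_type("gene"):
        if g.seqid not in genome:
            skipped += 1
            continue
        gid = g.attributes.get("gene_id", [g.id])[0]
        symbol = g.attributes.get("gene_name", [gid])[0]
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {gid} has no strand")
        iv = Interval(g.seqid, g.start - 1, g.end, g.strand).validate(genome)
        tss = iv.start if g.strand == "+" else iv.end - 1
        exons = exons_by_gene.get(gid, [(iv.start, iv.end)])
        genes.append(Gene(gid, symbol, iv, tss, _exon_union_length(exons)))
    if skipped:
        log.info("%s: skipped %d genes on chromosomes absent from genome", path, skipped)
    return GeneAnnotation(genome, genes)


def _read_gene_bed(path, genome: Genome) -> GeneAnnotation:
    genes = []
    skipped = 0
    for lineno, fields in _data_lines(path):
        if len(fields) < 6:
            raise ValueError(f"{path}:{lineno}: gene BED needs 6 columns (strand required)")
        chrom, s, e, name, _score, strand = fields[:6]
        if strand not in ("+", "-"):
            raise ValueError(f"{path}:{lineno}: gene {name} has no strand")
        if chrom not in genome:
            skipped += 1
            continue
        iv = Interval(chrom, int(s), int(e), strand).validate(genome)
        tss = iv.start if strand == "+" else iv.end - 1
        genes.append(Gene(name, name, iv, tss, iv.width))
    if skipped:
        log.info("%s: skipped %d genes on chromosomes absent from genome", path, skipped)
    return GeneAnnotation(genome, genes)


def read_gene_annotation(path, genome: Genome) -> GeneAnnotation:
    """Read gene models from GTF (gene/exon features) or 6-column BED.

    The format is chosen by extension (``.bed`` → BED, anything else → GTF).
    TSS follows the strand rule (start for ``+``, end − 1 for ``-``); exonic
    length is the length of the per-gene union of exons, falling back to the
    gene span when a gene has no exon records.
    """
    if str(path).endswith(".bed"):
        return _read_gene_bed(path, genome)
    return _read_gtf(path, genome)
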