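"""Coordinate system and interval algebra.

All coordinates are 0-based, half-open (BED convention). A :class:`Genome`
fixes the chromosome universe and a stable chromosome order that every
interval collection in the package is sorted by.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence


@dataclass(frozen=True)
class Genome:
    """Ordered chromosomes with lengths; the coordinate universe.

    Parameters
    ----------
    chroms
        Sequence of ``(name, length_bp)`` pairs. Names must be unique and
        lengths positive. The given order defines the sort order of every
        interval collection tied to this genome.
    """

    chroms: tuple[tuple[str, int], ...]

    def __init__(self, chroms: Iterable[tuple[str, int]]):
        chroms = tuple((str(n), int(l)) for n, l in chroms)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for n, l in chroms:
            if l <= 0:
                raise ValueError(f"chromosome {n!r} has non-positive length {l}")
        object.__setattr__(self, "chroms", chroms)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chroms)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chroms)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def order(self, chrom: str) -> int:
        """Rank of ``chrom`` in the genome's stable chromosome order."""
        try:
            return self.names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __len__(self) -> int:
        return len(self.chroms)

    def total_length(self) -> int:
        return sum(l for _, l in self.chroms)

    def sort_key(self, iv: "Interval") -> tuple[int, int, int]:
        return (self.order(iv.chrom), iv.start, iv.end)

    @classmethod
    def from_chrom_sizes(cls, path) -> "Genome":
        """Read a two-column ``name<TAB>length`` chromosome-sizes table."""
        chroms = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 'name length'")
                chroms.append((parts[0], int(parts[1])))
        return cls(chroms)

    def to_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for n, l in self.chroms:
                fh.write(f"{n}\t{l}\n")


@dataclass(frozen=True, order=False)
class Interval:
    """Half-open genomic interval ``[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # even-width intervals resolve to start + width // 2 for determinism
        return self.start + self.width // 2

    def expanded(self, flank: int, genome: Genome) -> "Interval":
        """Symmetric flank extension, clipped to chromosome bounds."""
        L = genome.length(self.chrom)
        return replace(self, start=max(0, self.start - flank), end=min(L, self.end + flank))

    def validate(self, genome: Genome) -> "Interval":
        if self.chrom not in genome:
            raise ValueError(f"interval on unknown chromosome {self.chrom!r}")
        if self.end > genome.length(self.chrom):
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {genome.length(self.chrom)}"
            )
        return self


class Window(NamedTuple):
    """One tile of the genome scan: an interval plus its scan ordinal."""

    interval: Interval
    index: int


@dataclass
class Config:
    """Tunable parameters of the enhancer-discovery pipeline.

    Defaults follow the published workflow conventions: 200-bp scan windows,
    merging of enhancer windows within 1 bp of each other, DHS validation at
    q < 0.01 with at least 1 bp of overlap, promoter negatives at TSS ± 1 kb,
    a one-third held-out test split, metagene profiles over ±3 kb, and
    promoter-proximal windows of −250/+1000 bp around the TSS.
    """

    window_size: int = 200
    merge_gap: int = 1
    dhs_q_max: float = 0.01
    min_dhs_overlap: int = 1
    promoter_flank: int = 1000
    test_fraction: float = 1 / 3
    metagene_flank: int = 3000
    metagene_bin: int = 50
    promoter_proximal: tuple[int, int] = (250, 1000)  # (upstream, downstream)
    h3k27ac_active_threshold: float | None = None  # None → genome-wide mean
    prob_threshold: float = 0.5
    feature_flank: int = 0
    n_trees: int = 500
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("window_size", "merge_gap", "min_dhs_overlap", "promoter_flank",
                     "metagene_flank", "metagene_bin"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if not 0 < self.dhs_q_max < 1:
            raise ValueError("dhs_q_max must be in (0, 1)")


def make_windows(genome: Genome, window_size: int) -> list[Window]:
    """Tile every chromosome into consecutive ``window_size``-bp windows.

    Windows within a chromosome are ``[0, w), [w, 2w), ...`` with a final
    truncated window covering the remainder, concatenated in genome order.
    Their union equals the genome and they are pairwise disjoint.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    windows: list[Window] = []
    idx = 0
    for chrom, length in genome.chroms:
        for start in range(0, length, window_size):
            windows.append(Window(Interval(chrom, start, min(start + window_size, length)), idx))
            idx += 1
    return windows


def merge_intervals(intervals: Sequence[Interval], max_gap: int, genome: Genome | None = None) -> list[Interval]:
    """Merge intervals separated by a gap of at most ``max_gap`` bp.

    Output is sorted (genome order when a genome is given, else lexicographic
    chromosome order), pairwise separated by gaps strictly greater than
    ``max_gap``, and idempotent under re-merging.
    """
    if not intervals:
        return []
    if genome is not None:
        key = lambda iv: (genome.order(iv.chrom), iv.start, iv.end)
    else:
        key = lambda iv: (iv.chrom, iv.start, iv.end)
    ivs = sorted(intervals, key=key)
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.chrom == last.chrom and iv.start - last.end <= max_gap:
            if iv.end > last.end:
                merged[-1] = replace(last, end=iv.end)
        else:
            merged.append(iv)
    return merged


def overlap_bp(a: Interval, b: Interval) -> int:
    """Number of shared bases between two half-open intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


class NearestHit(NamedTuple):
    feature_id: object
    distance: int | None  # signed; negative when the feature lies 5' of the query
    unassigned: bool


def _gap_and_sign(query: Interval, feature: Interval) -> tuple[int, int]:
    """Edge-to-edge gap (0 when overlapping) and sign on the forward axis."""
    if overlap_bp(query, feature) > 0:
        return 0, 0
    if feature.end <= query.start:
        return query.start - feature.end, -1
    return feature.start - query.end, +1


def nearest_feature(query: Interval, features: Sequence[tuple[Interval, object]]) -> NearestHit:
    """Closest feature to ``query`` by unstranded edge-to-edge distance.

    Distance is 0 for any overlap, else the gap between the closest edges,
    signed negative when the feature lies 5' of the query on the forward
    axis. Ties break on (lower feature start, then lexicographic id) for
    determinism. With no feature on the query's chromosome the hit is
    flagged ``unassigned`` rather than raising.
    """
    if not features:
        raise ValueError("feature list is empty")
    best: tuple[int, int, str] | None = None
    best_hit: NearestHit | None = None
    for iv, fid in features:
        if iv.chrom != query.chrom:
            continue
        gap, sign = _gap_and_sign(query, iv)
        key = (gap, iv.start, str(fid))
        if best is None or key < best:
            best = key
            best_hit = NearestHit(fid, sign * gap, False)
    if best_hit is None:
        return NearestHit(None, None, True)
    return best_hit
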