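"""Signal normalization math.

Covers interval mean coverage, 1x-depth (RPGC) scaling, effective genome
size, and fragment-length estimation by strand cross-correlation.

RPGC ("reads per genomic content") rescales raw coverage so the genome-wide
mean depth is 1x, where depth = mapped reads x fragment length / effective
genome size. The effective genome size is approximated as the number of
non-N bases of the assembly (overridable), which removes any dependence on
external mappability tooling while preserving the scaling formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Genome, Interval
from .track_io import CoverageTrack


@dataclass(frozen=True)
class RpgcParams:
    """Inputs of the 1x-normalization: library size, fragment length, EGS."""

    n_mapped: int
    fragment_length: int
    egs: int

    def __post_init__(self):
        if self.n_mapped <= 0 or self.fragment_length <= 0 or self.egs <= 0:
            raise ValueError("RPGC parameters must all be positive")


def mean_coverage(track: CoverageTrack, region: Interval) -> float:
    """Mean signal over ``region``; uncovered bases contribute 0."""
    return float(track.means([region])[0])


def rpgc_scale_factor(p: RpgcParams) -> float:
    """Scale factor bringing raw extended-read coverage to 1x genome-wide depth.

    Multiplying a raw fragment-pileup track by ``egs / (n_mapped *
    fragment_length)`` makes its mean over the effective genome exactly 1.
    """
    return p.egs / (p.n_mapped * p.fragment_length)


def effective_genome_size(fasta_path=None, genome: Genome | None = None) -> int:
    """Effective genome size: non-N bases of the FASTA, or the genome total.

    With a FASTA, counts every base that is not ``N``/``n``. Without one,
    falls back to the sum of chromosome lengths of ``genome``.
    """
    if fasta_path is None:
        if genome is None:
            raise ValueError("need a FASTA path or a Genome")
        return genome.total_length()
    from Bio import SeqIO

    total = 0
    n_records = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        n_records += 1
        seq = str(rec.seq).upper()
        total += len(seq) - seq.count("N")
    if n_records == 0:
        raise ValueError(f"{fasta_path}: no FASTA records found")
    return total


@dataclass
class FragmentLengthEstimate:
    """Cross-correlation profile and its (phantom-guarded) maximum."""

    best_shift: int
    correlation_profile: list[tuple[int, float]]
    read_length: int


def _binned_density(positions_by_chrom: dict[str, np.ndarray], n_bins_by_chrom: dict[str, int], bin_size: int) -> dict[str, np.ndarray]:
    out = {}
    for chrom, n_bins in n_bins_by_chrom.items():
        pos = positions_by_chrom.get(chrom)
        dens = np.zeros(n_bins, dtype=np.float64)
        if pos is not None and len(pos):
            idx = np.asarray(pos, dtype=np.int64) // bin_size
            idx = idx[(idx >= 0) & (idx < n_bins)]
            np.add.at(dens, idx, 1.0)
        out[chrom] = dens
    return out


def estimate_fragment_length(
    plus_starts: dict[str, np.ndarray],
    minus_ends: dict[str, np.ndarray],
    max_shift: int = 400,
    read_length: int = 36,
    bin_size: int = 10,
    phantom_guard: bool = True,
) -> FragmentLengthEstimate:
    """Estimate fragment length from strand-split read positions.

    For each candidate shift ``d`` in ``[0, max_shift]`` (stepped by
    ``bin_size``), the score is the Pearson correlation between the binned
    plus-strand 5' start density and the minus-strand 5' end density shifted
    left by ``d``; ``best_shift`` is the argmax. Shifts within
    ``read_length ± 10`` bp are excluded from the argmax (the phantom-peak
    guard) unless ``phantom_guard`` is off.
    """
    if not any(len(v) for v in plus_starts.values()) or not any(len(v) for v in minus_ends.values()):
        raise ValueError("cannot estimate fragment length: a strand has no reads")
    if max_shift < read_length:
        raise ValueError("max_shift must be >= read_length")

    n_bins = {}
    for chrom in set(plus_starts) | set(minus_ends):
        hi = 0
        for d in (plus_starts, minus_ends):
            pos = d.get(chrom)
            if pos is not None and len(pos):
                hi = max(hi, int(np.max(pos)))
        n_bins[chrom] = hi // bin_size + 1 + max_shift // bin_size
    plus = _binned_density(plus_starts, n_bins, bin_size)
    minus = _binned_density(minus_ends, n_bins, bin_size)

    shifts = list(range(0, max_shift + 1, bin_size))
    profile = []
    for shift in shifts:
        d = shift // bin_size
        xs, ys = [], []
        for chrom, nb in n_bins.items():
            if nb - d < 2:
                continue
            xs.append(plus[chrom][: nb - d])
            ys.append(minus[chrom][d:nb])
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        if x.std() == 0 or y.std() == 0:
            score = 0.0
        else:
            score = float(np.corrcoef(x, y)[0, 1])
        profile.append((shift, score))

    candidates = [
        (score, shift)
        for shift, score in profile
        if not (phantom_guard and abs(shift - read_length) <= 10)
    ]
    if not candidates:
        raise ValueError("phantom guard excluded every candidate shift")
    best_score = max(s for s, _ in candidates)
    best_shift = min(shift for s, shift in candidates if s == best_score)
    return FragmentLengthEstimate(best_shift, profile, read_length)


def read_read_starts(path, genome: Genome | None = None) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Read a 3-column TSV (chrom, 5' position, strand) of read starts.

    Returns plus-strand 5' starts and minus-strand 5' ends, keyed by
    chromosome, ready for :func:`estimate_fragment_length`.
    """
    plus: dict[str, list[int]] = {}
    minus: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'chrom pos strand'")
            chrom, pos, strand = fields
            if genome is not None and chrom not in genome:
                continue
            if strand == "+":
                plus.setdefault(chrom, []).append(int(pos))
            elif strand == "-":
                minus.setdefault(chrom, []).append(int(pos))
            else:
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
    return (
        {c: np.array(v, dtype=np.int64) for c, v in plus.items()},
        {c: np.array(v, dtype=np.int64) for c, v in minus.items()},
    )


def write_read_starts(path, plus: dict[str, np.ndarray], minus: dict[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        for strand, d in (("+", plus), ("-", minus)):
            for chrom in sorted(d):
                for pos in d[chrom]:
                    fh.write(f"{chrom}\t{int(pos)}\t{strand}\n")
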