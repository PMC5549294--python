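"""Deterministic simulator of a toy regulatory genome.

Emulates the input universe of the enhancer-discovery pipeline: a small
multi-chromosome genome carrying planted enhancers and genes, bedGraph
coverage tracks with the canonical chromatin signatures, DNase narrowPeak
calls, GRO-seq strand tracks, strand-split read-start lists, and gene-level
count tables.

Signal model
------------
Signal bumps are discretized Gaussian profiles on a 10-bp grid. A planted
enhancer carries a central DNase (open chromatin) bump and flanking
H3K4me1 — plus H3K27ac when active — bumps with a central dip, the
"peak-valley-peak" shape of marks around a nucleosome-free region. Active
enhancers transcribe divergent eRNAs (GRO plus bump 3' of center, minus
bump 5' of center) at a 6:1 sense and 5:1 antisense amplitude ratio over
primed ones. A gene promoter carries a strong H3K4me3 bump, a DNase bump
and only weak H3K4me1; expressed genes add low sense-strand GRO signal over
the start of the gene body. Background noise is exponential with mean
``0.05 * peak_amplitude / snr`` everywhere; every output is a pure function
of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome import Genome, Interval
from .track_io import CoverageTrack, CoverageTrack as _Track, Gene, GeneAnnotation, Peak, PeakSet

BIN = 10  # bp grid of all simulated signal

DEFAULT_GENOME_SPEC = (("chr1", 1_000_000), ("chr2", 1_000_000))
MIN_SPACING = 2_000  # bp between any two planted elements

# bump amplitudes (RPM-like units)
AMP_DNASE_ENH = 8.0
AMP_K4ME1_ENH = 6.0
AMP_K27AC_ACTIVE = 6.0
AMP_K4ME3_PROM = 6.0
AMP_DNASE_PROM = 5.0
AMP_K4ME1_PROM = 0.8
AMP_GRO_SENSE_ACTIVE = 6.0
AMP_GRO_ANTI_ACTIVE = 5.0
AMP_GRO_PRIMED = 1.0
GRO_GENE_BODY = 0.2

FLANK_OFFSET = 250  # bp from enhancer center to each histone-mark bump
GRO_OFFSET = 300  # bp from enhancer center to each eRNA bump

MARKERS = ("DNase", "H3K4me1", "H3K27ac", "H3K4me3")


@dataclass
class SyntheticTruth:
    """Planted ground truth: genome, enhancers with states, genes with
    planted expression means."""

    genome: Genome
    enhancers: list[tuple[Interval, str]]  # (interval, "active" | "primed")
    genes: GeneAnnotation
    expression_means: dict[str, float]
    seed: int

    def enhancer_intervals(self) -> list[Interval]:
        return [iv for iv, _ in self.enhancers]

    def states(self) -> list[str]:
        return [s for _, s in self.enhancers]


def _place_elements(
    rng: np.random.Generator,
    genome: Genome,
    widths: list[int],
    occupied: dict[str, list[tuple[int, int]]],
    max_attempts_per_element: int = 1_000,
) -> list[Interval]:
    """Uniform placement with rejection to keep >= MIN_SPACING bp between
    any two planted elements."""
    placed = []
    names = genome.names
    weights = np.array([genome.length(n) for n in names], dtype=float)
    weights /= weights.sum()
    for width in widths:
        for _ in range(max_attempts_per_element):
            chrom = names[rng.choice(len(names), p=weights)]
            L = genome.length(chrom)
            if L - width - MIN_SPACING <= MIN_SPACING:
                continue
            start = int(rng.integers(MIN_SPACING, L - width - MIN_SPACING))
            end = start + width
            clash = any(
                start - MIN_SPACING < oe and os < end + MIN_SPACING
                for os, oe in occupied.get(chrom, [])
            )
            if not clash:
                occupied.setdefault(chrom, []).append((start, end))
                placed.append(Interval(chrom, start, end))
                break
        else:
            raise ValueError(
                "element placement infeasible: density too high for the "
                f"{MIN_SPACING}-bp spacing constraint"
            )
    return placed


def simulate_truth(
    n_enhancers: int = 50,
    frac_active: float = 0.6,
    n_genes: int = 150,
    genome_spec: tuple[tuple[str, int], ...] | None = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Plant enhancers (active/primed) and genes on a toy genome.

    Elements are placed uniformly with rejection sampling so that any two
    planted elements are separated by at least 2 kb; in particular no
    enhancer overlaps a promoter. ``round(n_enhancers * frac_active)``
    enhancers are active. Identical seeds reproduce identical truths.
    """
    genome = Genome(genome_spec or DEFAULT_GENOME_SPEC)
    rng = np.random.default_rng(seed)
    occupied: dict[str, list[tuple[int, int]]] = {}

    gene_widths = [int(rng.integers(20, 41)) * 100 for _ in range(n_genes)]  # 2-4 kb
    gene_ivs = _place_elements(rng, genome, gene_widths, occupied)
    enh_widths = [int(rng.integers(30, 51)) * 10 for _ in range(n_enhancers)]  # 300-500 bp
    enh_ivs = _place_elements(rng, genome, enh_widths, occupied)

    n_active = int(math.floor(n_enhancers * frac_active + 0.5))
    states = np.array(["active"] * n_active + ["primed"] * (n_enhancers - n_active), dtype=object)
    rng.shuffle(states)
    enhancers = list(zip(enh_ivs, states.tolist()))

    genes = []
    means = {}
    for i, iv in enumerate(gene_ivs):
        strand = "+" if rng.random() < 0.5 else "-"
        iv = Interval(iv.chrom, iv.start, iv.end, strand)
        tss = iv.start if strand == "+" else iv.end - 1
        # two exons covering ~30% of the span each
        exon = max(100, int(0.3 * iv.width))
        exonic = min(2 * exon, iv.width)
        gid = f"g{i + 1}"
        genes.append(Gene(gid, gid, iv, tss, exonic))
        means[gid] = 0.0 if rng.random() < 0.1 else float(np.round(rng.lognormal(4.0, 1.0), 3))
    return SyntheticTruth(genome, enhancers, GeneAnnotation(genome, genes), means, seed)


def _add_bump(arr: np.ndarray, center_bp: float, sd_bp: float, amp: float) -> None:
    lo = max(0, int((center_bp - 4 * sd_bp) // BIN))
    hi = min(len(arr), int((center_bp + 4 * sd_bp) // BIN) + 1)
    if hi <= lo:
        return
    x = (np.arange(lo, hi) + 0.5) * BIN
    arr[lo:hi] += amp * np.exp(-((x - center_bp) ** 2) / (2 * sd_bp**2))


def simulate_tracks(
    truth: SyntheticTruth, snr: float = 10.0, seed: int = 0
) -> dict[str, CoverageTrack]:
    """Build the six coverage tracks implied by the planted truth.

    Returns a dict with keys ``DNase, H3K4me1, H3K27ac, H3K4me3, GRO_plus,
    GRO_minus``. ``snr`` scales the exponential background noise
    (``snr = inf`` turns noise off entirely).
    """
    if not snr > 0:
        raise ValueError("snr must be > 0")
    genome = truth.genome
    rng = np.random.default_rng(seed)
    track_names = list(MARKERS) + ["GRO_plus", "GRO_minus"]
    arrays = {
        t: {c: np.zeros(-(-L // BIN), dtype=np.float64) for c, L in genome.chroms}
        for t in track_names
    }

    for iv, state in truth.enhancers:
        c = iv.midpoint
        ch = iv.chrom
        _add_bump(arrays["DNase"][ch], c, 100, AMP_DNASE_ENH)
        for off in (-FLANK_OFFSET, FLANK_OFFSET):
            _add_bump(arrays["H3K4me1"][ch], c + off, 120, AMP_K4ME1_ENH)
            if state == "active":
                _add_bump(arrays["H3K27ac"][ch], c + off, 120, AMP_K27AC_ACTIVE)
        sense_amp = AMP_GRO_SENSE_ACTIVE if state == "active" else AMP_GRO_PRIMED
        anti_amp = AMP_GRO_ANTI_ACTIVE if state == "active" else AMP_GRO_PRIMED
        _add_bump(arrays["GRO_plus"][ch], c + GRO_OFFSET, 150, sense_amp)
        _add_bump(arrays["GRO_minus"][ch], c - GRO_OFFSET, 150, anti_amp)

    for gene in truth.genes:
        t = gene.tss
        ch = gene.interval.chrom
        _add_bump(arrays["H3K4me3"][ch], t, 250, AMP_K4ME3_PROM)
        _add_bump(arrays["DNase"][ch], t, 100, AMP_DNASE_PROM)
        _add_bump(arrays["H3K4me1"][ch], t, 250, AMP_K4ME1_PROM)
        if truth.expression_means.get(gene.gene_id, 0) > 0:
            body = min(2000, gene.interval.width)
            strand_track = "GRO_plus" if gene.interval.strand == "+" else "GRO_minus"
            if gene.interval.strand == "+":
                lo, hi = gene.interval.start, gene.interval.start + body
            else:
                lo, hi = gene.interval.end - body, gene.interval.end
            arrays[strand_track][ch][lo // BIN : -(-hi // BIN)] += GRO_GENE_BODY

    if np.isfinite(snr):
        noise_scale = 0.05 * AMP_DNASE_ENH / snr
        for t in track_names:
            for ch in arrays[t]:
                arrays[t][ch] += rng.exponential(noise_scale, len(arrays[t][ch]))

    return {t: _Track.from_arrays(genome, arrays[t], BIN) for t in track_names}


def simulate_dhs_peaks(
    truth: SyntheticTruth,
    seed: int = 0,
    n_decoys: int = 40,
    q_pass_range: tuple[float, float] = (2.5, 6.0),
    q_decoy_range: tuple[float, float] = (0.1, 1.9),
) -> PeakSet:
    """One q-passing DHS peak per planted enhancer plus q-failing decoys.

    Passing peaks carry −log10 q-values drawn from ``q_pass_range`` (all
    >= 2, i.e. q < 0.01); decoys are placed at random background sites with
    −log10 q below 2, so a q < 0.01 filter removes them all.
    """
    rng = np.random.default_rng(seed)
    genome = truth.genome
    peaks = []
    for i, (iv, _) in enumerate(truth.enhancers):
        center = iv.midpoint + int(rng.integers(-30, 31))
        half = 150
        L = genome.length(iv.chrom)
        start, end = max(0, center - half), min(L, center + half)
        q = float(rng.uniform(*q_pass_range))
        peaks.append(
            Peak(
                Interval(iv.chrom, start, end),
                f"dhs_{i + 1}",
                int(min(1000, q * 100)),
                float(rng.uniform(5, 15)),
                q + 1.0,
                q,
                (end - start) // 2,
            )
        )
    occupied: dict[str, list[tuple[int, int]]] = {}
    for iv, _ in truth.enhancers:
        occupied.setdefault(iv.chrom, []).append((iv.start, iv.end))
    decoys = _place_elements(rng, genome, [200] * n_decoys, occupied)
    for i, iv in enumerate(decoys):
        q = float(rng.uniform(*q_decoy_range))
        peaks.append(
            Peak(iv, f"decoy_{i + 1}", int(q * 100), float(rng.uniform(1, 4)), q + 1.0, q, 100)
        )
    return PeakSet(genome, peaks)


def simulate_reads_for_fraglen(
    fragment_length: int,
    n_fragments: int,
    read_length: int,
    seed: int = 0,
    genome_length: int = 100_000,
    chrom: str = "chrR",
    poisson_lengths: bool = False,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Strand-split read positions from uniformly placed fragments.

    The plus read's 5' start is the fragment start; the minus read's 5' end
    is the fragment end. With ``poisson_lengths`` fragment lengths are drawn
    Poisson around the target length instead of being exact.
    """
    rng = np.random.default_rng(seed)
    if poisson_lengths:
        lengths = rng.poisson(fragment_length, n_fragments)
        lengths = np.maximum(lengths, read_length)
    else:
        lengths = np.full(n_fragments, fragment_length, dtype=np.int64)
    hi = genome_length - int(lengths.max()) - 1
    starts = rng.integers(0, hi, n_fragments)
    return {chrom: np.sort(starts)}, {chrom: np.sort(starts + lengths)}


def simulate_expression(
    truth: SyntheticTruth, seed: int = 0, dispersion: float = 0.1
) -> tuple[dict[str, int], int]:
    """Overdispersed (gamma-Poisson) counts around the planted gene means.

    Returns the per-gene counts and the library total (their sum). A gene
    with planted mean 0 always counts 0.
    """
    rng = np.random.default_rng(seed)
    counts = {}
    for gene in truth.genes:
        mu = truth.expression_means[gene.gene_id]
        if mu <= 0:
            counts[gene.gene_id] = 0
        else:
            lam = rng.gamma(1.0 / dispersion, mu * dispersion)
            counts[gene.gene_id] = int(rng.poisson(lam))
    return counts, int(sum(counts.values()))


def write_fasta(genome: Genome, path, seed: int = 0, n_run_every: int | None = None) -> None:
    """Random ACGT FASTA for the genome, optionally with planted N runs.

    With ``n_run_every`` set, a 50-bp N run is planted every that many bases.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    records = []
    for chrom, L in genome.chroms:
        arr = bases[rng.integers(0, 4, L)]
        if n_run_every:
            for pos in range(n_run_every, L - 50, n_run_every):
                arr[pos : pos + 50] = ord("N")
        records.append(SeqRecord(Seq(arr.tobytes().decode()), id=chrom, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_gtf(genes: GeneAnnotation, path) -> None:
    """Gene and exon GTF records (1-based inclusive) for the annotation.

    Each gene gets two synthetic exons at its ends whose union length equals
    the recorded exonic length.
    """
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            fh.write(
                f"{iv.chrom}\tenhancerkit\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            half = g.exonic_length // 2
            exons = [
                (iv.start, iv.start + half),
                (iv.end - (g.exonic_length - half), iv.end),
            ]
            for es, ee in exons:
                fh.write(
                    f"{iv.chrom}\tenhancerkit\texon\t{es + 1}\t{ee}\t.\t{iv.strand}\t.\t{attrs}\n"
                )


def write_truth_bed(truth: SyntheticTruth, path) -> None:
    """Planted enhancers as BED6 plus a 7th state column."""
    genome = truth.genome
    order = sorted(range(len(truth.enhancers)), key=lambda i: genome.sort_key(truth.enhancers[i][0]))
    with open(path, "w") as fh:
        for out_i, i in enumerate(order):
            iv, state = truth.enhancers[i]
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\ttruth_{out_i + 1}\t0\t.\t{state}\n")


def write_counts_tsv(counts: dict[str, int], library_total: int, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# library_total\t{library_total}\n")
        for gene in counts:
            fh.write(f"{gene}\t{counts[gene]}\n")


def read_counts_tsv(path) -> tuple[dict[str, int], int | None]:
    counts: dict[str, int] = {}
    library_total = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line.lstrip("#").split()
                if parts and parts[0] == "library_total":
                    library_total = int(parts[1])
                continue
            gene, cnt = line.split("\t")
            counts[gene] = int(cnt)
    return counts, library_total
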