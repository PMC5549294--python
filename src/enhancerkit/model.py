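"""Random-forest enhancer classifier.

The model separates two classes of genomic elements from their chromatin
features: known enhancer elements (positives) against an equal number of
gene promoter regions, TSS ± 1 kb (negatives). One third of each class is
held out for testing and summarised in a confusion matrix.

Classical bagged-tree defaults are used: 500 trees, sqrt(#markers) features
per split, unbounded depth. The prediction surface exposes the probability
of the "enhancer" class; windows are classed enhancer at probability >= 0.5
unless configured otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .genome import Config, Genome, Interval, overlap_bp
from .features import FeatureMatrix, extract_features
from .track_io import CoverageTrack, GeneAnnotation

log = logging.getLogger(__name__)

POSITIVE = "enhancer"
NEGATIVE = "non-enhancer"

MODEL_FORMAT_VERSION = 1


@dataclass
class TrainingSet:
    """Features plus per-row labels and provenance."""

    features: FeatureMatrix
    labels: np.ndarray  # array of POSITIVE / NEGATIVE
    origin: list[str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != len(self.features) or len(self.origin) != len(self.features):
            raise ValueError("training-set row count mismatch")

    def __len__(self) -> int:
        return len(self.features)

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def subset(self, idx: Sequence[int]) -> "TrainingSet":
        idx = list(idx)
        return TrainingSet(self.features.subset(idx), self.labels[idx], [self.origin[i] for i in idx])


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("TP\tFP\tTN\tFN\taccuracy\n")
            fh.write(f"{self.tp}\t{self.fp}\t{self.tn}\t{self.fn}\t{self.accuracy!r}\n")


@dataclass
class EnhancerModel:
    """Trained tree ensemble plus the metadata needed to reapply it."""

    forest: RandomForestClassifier
    markers: tuple[str, ...]
    flank: int
    n_trees: int
    seed: int
    held_out: ConfusionMatrix | None = None

    def predict_proba(self, features: FeatureMatrix) -> np.ndarray:
        """Probability of the enhancer class per row; marker order enforced."""
        if features.markers != self.markers:
            missing = set(self.markers) - set(features.markers)
            extra = set(features.markers) - set(self.markers)
            raise ValueError(
                f"marker mismatch: model expects {list(self.markers)}; "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        proba = self.forest.predict_proba(features.values)
        pos_idx = list(self.forest.classes_).index(POSITIVE)
        return proba[:, pos_idx]

    def save(self, path) -> None:
        joblib.dump(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "markers": self.markers,
                "flank": self.flank,
                "n_trees": self.n_trees,
                "seed": self.seed,
                "held_out": self.held_out,
                "forest": self.forest,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "EnhancerModel":
        payload = joblib.load(path)
        version = payload.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model file format version {version!r} unsupported "
                f"(expected {MODEL_FORMAT_VERSION})"
            )
        return cls(
            payload["forest"],
            tuple(payload["markers"]),
            payload["flank"],
            payload["n_trees"],
            payload["seed"],
            payload["held_out"],
        )


def promoter_interval(tss: int, chrom: str, flank: int, genome: Genome) -> Interval:
    """TSS ± flank window, clipped to the chromosome."""
    L = genome.length(chrom)
    return Interval(chrom, max(0, tss - flank), min(L, tss + flank))


def build_training_set(
    enhancers: Sequence[Interval],
    genes: GeneAnnotation,
    tracks: Mapping[str, CoverageTrack],
    config: Config,
    seed: int,
) -> TrainingSet:
    """Positives = input enhancers; negatives = equally many sampled promoters.

    Promoters (TSS ± ``config.promoter_flank``) are drawn as a seed-
    deterministic uniform sample of genes; a sampled promoter overlapping
    any enhancer is resampled (logged). Errors out when genes are too few.
    """
    if len(genes) < len(enhancers):
        raise ValueError(
            f"need at least as many genes ({len(genes)}) as enhancers ({len(enhancers)})"
        )
    if not enhancers:
        raise ValueError("no enhancer elements supplied")
    genome = next(iter(tracks.values())).genome
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes.genes))
    promoters: list[Interval] = []
    prom_origin: list[str] = []
    resampled = 0
    enh_by_chrom: dict[str, list[Interval]] = {}
    for iv in enhancers:
        enh_by_chrom.setdefault(iv.chrom, []).append(iv)
    for gi in order:
        if len(promoters) == len(enhancers):
            break
        gene = genes.genes[gi]
        prom = promoter_interval(gene.tss, gene.interval.chrom, config.promoter_flank, genome)
        if any(overlap_bp(prom, e) > 0 for e in enh_by_chrom.get(prom.chrom, [])):
            resampled += 1
            continue
        promoters.append(prom)
        prom_origin.append(f"promoter:{gene.gene_id}")
    if len(promoters) < len(enhancers):
        raise ValueError("too few non-overlapping gene promoters to balance the classes")
    if resampled:
        log.info("resampled %d promoters that overlapped an enhancer", resampled)

    elements = list(enhancers) + promoters
    ids = [f"enh_{i}" for i in range(len(enhancers))] + [f"prom_{i}" for i in range(len(promoters))]
    feats = extract_features(elements, tracks, flank=config.feature_flank, ids=ids)
    labels = np.array([POSITIVE] * len(enhancers) + [NEGATIVE] * len(promoters), dtype=object)
    origin = [f"enhancer:{iv.chrom}:{iv.start}-{iv.end}" for iv in enhancers] + prom_origin
    return TrainingSet(feats, labels, origin)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_train_test(ts: TrainingSet, test_fraction: float, seed: int) -> tuple[TrainingSet, TrainingSet]:
    """Stratified split: per class, round(n x test_fraction) rows go to test."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    train_idx: list[int] = []
    for label in sorted(set(ts.labels.tolist())):
        rows = np.flatnonzero(ts.labels == label)
        if len(rows) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 rows")
        n_test = _round_half_up(len(rows) * test_fraction)
        n_test = min(max(n_test, 1), len(rows) - 1)
        perm = rng.permutation(rows)
        test_idx.extend(perm[:n_test].tolist())
        train_idx.extend(perm[n_test:].tolist())
    return ts.subset(sorted(train_idx)), ts.subset(sorted(test_idx))


def train_classifier(
    train: TrainingSet, n_trees: int = 500, seed: int = 0, n_jobs: int = 1
) -> EnhancerModel:
    """Fit a bagged decision-tree ensemble on the training rows.

    Each tree grows on a bootstrap sample with a random sqrt-sized feature
    subset per split and no depth cap. Constant features warn but do not
    fail.
    """
    classes = set(train.labels.tolist())
    if classes != {POSITIVE, NEGATIVE}:
        raise ValueError(f"training set must contain both classes, got {sorted(classes)}")
    constant = [
        m
        for j, m in enumerate(train.features.markers)
        if np.ptp(train.features.values[:, j]) == 0
    ]
    if constant:
        warnings.warn(f"constant features across all rows: {constant}", stacklevel=2)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        max_depth=None,
        random_state=seed,
        n_jobs=n_jobs,
    )
    forest.fit(train.features.values, train.labels.astype(str))
    return EnhancerModel(forest, train.features.markers, train.features.flank, n_trees, seed)


def evaluate(model: EnhancerModel, test: TrainingSet, prob_threshold: float = 0.5) -> ConfusionMatrix:
    """Confusion matrix on held-out rows with "enhancer" as the positive class."""
    proba = model.predict_proba(test.features)
    pred_pos = proba >= prob_threshold
    actual_pos = test.labels == POSITIVE
    tp = int(np.sum(pred_pos & actual_pos))
    fp = int(np.sum(pred_pos & ~actual_pos))
    tn = int(np.sum(~pred_pos & ~actual_pos))
    fn = int(np.sum(~pred_pos & actual_pos))
    cm = ConfusionMatrix(tp, fp, tn, fn)
    log.info("held-out confusion matrix: TP=%d FP=%d TN=%d FN=%d accuracy=%.4f", tp, fp, tn, fn, cm.accuracy)
    return cm
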