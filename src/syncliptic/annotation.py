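"""Peak-to-transcript-feature classification and motif-input extraction.

A peak is classified by the transcript feature overlapping its centre
(the lower median of the positions of maximum read coverage inside the
peak), with precedence 3'UTR > 5'UTR > exon > intron across overlapping
transcripts; peaks whose centre touches no gene are intergenic.  Motif
discovery inputs are fixed-width (41 nt) windows centred on peak centres,
paired with large background sets of equally sized windows drawn from
regions of the same feature class that carry no read coverage at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    GenomeAnnotation,
    GenomicInterval,
    PeakRecord,
    SequenceStore,
    reverse_complement,
)

log = logging.getLogger(__name__)

FEATURE_CLASSES = ("five_prime_utr", "exon", "three_prime_utr", "intron", "intergenic")

# precedence across overlapping transcripts (highest first)
_PRECEDENCE = ("three_prime_utr", "five_prime_utr", "exon", "intron")


@dataclass(frozen=True)
class PeakCenter:
    peak_id: str
    center: int
    max_coverage: int
    from_midpoint: bool = False  # set when coverage was absent


class FeatureIndex:
    """Flattened (chrom -> arrays of labelled feature intervals) view of an annotation."""

    def __init__(self, annotation: GenomeAnnotation):
        feats: dict[str, list[tuple[int, int, str, str, str]]] = {}
        spans: dict[str, list[tuple[int, int, str]]] = {}
        for gid, tx in annotation.transcripts():
            for s, e, cls in tx.feature_intervals():
                feats.setdefault(tx.chrom, []).append((s, e, cls, gid, tx.strand))
        for gid, gene in annotation.genes.items():
            s, e = gene.span
            spans.setdefault(gene.chrom, []).append((s, e, gid))
        self._feats = {
            c: {
                "start": np.array([f[0] for f in v]),
                "end": np.array([f[1] for f in v]),
                "cls": np.array([f[2] for f in v]),
                "gene": np.array([f[3] for f in v]),
                "strand": np.array([f[4] for f in v]),
            }
            for c, v in feats.items()
        }
        self._spans = {
            c: {
                "start": np.array([s[0] for s in v]),
                "end": np.array([s[1] for s in v]),
                "gene": np.array([s[2] for s in v]),
            }
            for c, v in spans.items()
        }

    def classes_at(self, chrom: str, pos: int) -> list[tuple[str, str]]:
        """(class, gene_id) of every feature overlapping a position."""
        f = self._feats.get(chrom)
        if f is None:
            return []
        hit = (f["start"] <= pos) & (pos < f["end"])
        return list(zip(f["cls"][hit], f["gene"][hit]))

    def genes_overlapping(self, iv: GenomicInterval) -> list[tuple[str, int]]:
        """(gene_id, overlap length) for genes whose span intersects the interval."""
        s = self._spans.get(iv.chrom)
        if s is None:
            return []
        ov = np.minimum(s["end"], iv.end) - np.maximum(s["start"], iv.start)
        hit = ov > 0
        return list(zip(s["gene"][hit], ov[hit].astype(int)))

    def class_intervals(self, feature_class: str) -> list[tuple[str, int, int, str]]:
        """Merged (chrom, start, end, strand) intervals of one feature class."""
        out: list[tuple[str, int, int, str]] = []
        for chrom, f in sorted(self._feats.items()):
            sel = f["cls"] == feature_class
            for strand in ("+", "-"):
                ssel = sel & (f["strand"] == strand)
                ivs = sorted(zip(f["start"][ssel], f["end"][ssel]))
                merged: list[list[int]] = []
                for s, e in ivs:
                    if merged and s <= merged[-1][1]:
                        merged[-1][1] = max(merged[-1][1], e)
                    else:
                        merged.append([int(s), int(e)])
                out.extend((chrom, s, e, strand) for s, e in merged)
        return out


def classify_peak(
    peak: PeakRecord,
    index: FeatureIndex,
    center: int | None = None,
) -> tuple[str, str | None]:
    """Feature class of the peak centre plus the assigned gene.

    Precedence across overlapping transcripts: 3'UTR > 5'UTR > exon > intron.
    The gene is the one with the largest overlap with the peak interval, ties
    broken lexicographically; no overlap at all gives ("intergenic", None).
    """
    iv = peak.interval
    if center is None:
        center = (iv.start + iv.end - 1) // 2
    hits = index.classes_at(iv.chrom, center)
    cls = "intergenic"
    for candidate in _PRECEDENCE:
        if any(c == candidate for c, _ in hits):
            cls = candidate
            break
    genes = index.genes_overlapping(iv)
    if not genes:
        return "intergenic", None
    gene = sorted(genes, key=lambda g: (-g[1], g[0]))[0][0]
    if cls == "intergenic":
        # centre outside any feature but the peak still touches a gene span
        return "intergenic", gene
    return cls, gene


def feature_distribution(classes: Iterable[str]) -> tuple[pd.Series, int]:
    """Percentage of peaks per genic feature class.

    Percentages are over the non-intergenic classes (they sum to 100);
    the intergenic count is returned separately.
    """
    classes = list(classes)
    if not classes:
        raise ValueError("no peaks to summarize")
    counts = pd.Series(classes).value_counts()
    n_intergenic = int(counts.get("intergenic", 0))
    genic = counts.reindex(
        ["five_prime_utr", "exon", "three_prime_utr", "intron"], fill_value=0
    )
    total = genic.sum()
    if total == 0:
        raise ValueError("no genic peaks to summarize")
    return 100.0 * genic / total, n_intergenic


def coverage_from_reads(
    reads: Sequence[GenomicInterval], chrom_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Per-base read coverage via difference arrays."""
    diff = {c: np.zeros(length + 1, dtype=np.int64) for c, length in chrom_lengths.items()}
    for r in reads:
        d = diff.get(r.chrom)
        if d is None:
            continue
        d[min(r.start, d.size - 1)] += 1
        d[min(r.end, d.size - 1)] -= 1
    return {c: np.cumsum(d[:-1]) for c, d in diff.items()}


def peak_coverage(peak: PeakRecord, reads: Sequence[GenomicInterval]) -> np.ndarray:
    """Read coverage across one peak interval."""
    iv = peak.interval
    cov = np.zeros(len(iv), dtype=np.int64)
    for r in reads:
        if r.chrom != iv.chrom:
            continue
        s = max(r.start, iv.start) - iv.start
        e = min(r.end, iv.end) - iv.start
        if e > s:
            cov[s:e] += 1
    return cov


def peak_center(peak: PeakRecord, coverage: np.ndarray) -> PeakCenter:
    """Lower median of the positions attaining maximum coverage in the peak."""
    iv = peak.interval
    coverage = np.asarray(coverage)
    if coverage.size != len(iv):
        raise ValueError("coverage array length must equal peak length")
    if coverage.max(initial=0) == 0:
        return PeakCenter(
            peak.peak_id, (iv.start + iv.end - 1) // 2, 0, from_midpoint=True
        )
    maxima = np.flatnonzero(coverage == coverage.max())
    center = iv.start + int(maxima[(maxima.size - 1) // 2])
    return PeakCenter(peak.peak_id, center, int(coverage.max()))


def window_bounds(center: int, size: int) -> tuple[int, int]:
    """[center - floor(size/2), center + ceil(size/2)); symmetric for odd size."""
    return center - size // 2, center + (size + 1) // 2


def extract_window(
    center: int,
    chrom: str,
    genome: SequenceStore,
    strand: str = "+",
    size: int = 41,
) -> str:
    """Genomic sequence of the fixed-size window centred on a position.

    Minus-strand windows are reverse-complemented.  Raises ValueError if the
    window crosses a chromosome boundary (callers typically skip and log).
    """
    start, end = window_bounds(center, size)
    seq = genome.fetch(chrom, start, end)
    return reverse_complement(seq) if strand == "-" else seq


def sample_background(
    index: FeatureIndex,
    coverage: Mapping[str, np.ndarray],
    genome: SequenceStore,
    feature_class: str,
    n: int = 200_000,
    size: int = 41,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Random class-matched zero-coverage windows for motif background sets.

    Candidate start positions lie fully inside a (merged) interval of the
    requested feature class and have zero read coverage across the whole
    window; ``n`` positions are drawn uniformly (with replacement) from the
    eligible set.  Minus-strand windows are reverse-complemented.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    eligible: list[tuple[str, int, str]] = []  # (chrom, start, strand)
    total_bases = 0
    for chrom, s, e, strand in index.class_intervals(feature_class):
        if e - s < size or chrom not in coverage:
            continue
        total_bases += e - s
        cov = np.asarray(coverage[chrom])
        csum = np.concatenate([[0], np.cumsum(cov)])
        starts = np.arange(s, e - size + 1)
        window_cov = csum[starts + size] - csum[starts]
        for p in starts[window_cov == 0]:
            eligible.append((chrom, int(p), strand))
    if not eligible:
        raise ValueError(f"no zero-coverage {feature_class} windows of size {size}")
    if total_bases < n * size:
        raise ValueError(
            f"eligible {feature_class} space ({total_bases} bases) smaller than "
            f"n*size; at most {total_bases // size} windows are supportable"
        )
    picks = rng.integers(0, len(eligible), size=n)
    out = []
    for i in picks:
        chrom, start, strand = eligible[i]
        seq = genome.fetch(chrom, start, start + size)
        out.append(reverse_complement(seq) if strand == "-" else seq)
    return out
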