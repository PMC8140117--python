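"""Genomic data model and readers/writers for the standard formats.

All coordinates are internally 0-based half-open (BED native); GTF is
converted on read and back-converted on write, so a GTF round-trip is the
identity.  Strand is one of ``+``, ``-``, ``.``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class PeakRecord:
    """A called peak with read counts in the compartment (x) and reference (y) samples."""

    interval: GenomicInterval
    peak_id: str
    gene_id: str | None = None
    count_x: int | None = None
    count_y: int | None = None

    def __post_init__(self) -> None:
        for c in (self.count_x, self.count_y):
            if c is not None and c < 0:
                raise ValueError(f"negative count for peak {self.peak_id}")

    def with_counts(self, count_x: int, count_y: int) -> "PeakRecord":
        return replace(self, count_x=int(count_x), count_y=int(count_y))


@dataclass
class Transcript:
    """Exon/CDS structure of one transcript; introns and UTRs are derived.

    ``exons`` and ``cds`` are sorted, non-overlapping lists of (start, end)
    tuples in genomic coordinates (0-based half-open).
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        self.cds = sorted((int(s), int(e)) for s, e in self.cds)
        for s, e in self.exons + self.cds:
            if s >= e:
                raise ValueError(f"empty feature in transcript {self.transcript_id}")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.transcript_id}")
        span = self.span
        for s, e in self.cds:
            if s < span[0] or e > span[1]:
                raise ValueError(
                    f"CDS outside transcript span in {self.transcript_id}"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 > e1
        ]

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def _utr_side(self, low: bool) -> list[tuple[int, int]]:
        if not self.cds:
            return []
        cds_lo = self.cds[0][0]
        cds_hi = self.cds[-1][1]
        out = []
        for s, e in self.exons:
            if low:
                if s < cds_lo:
                    out.append((s, min(e, cds_lo)))
            else:
                if e > cds_hi:
                    out.append((max(s, cds_hi), e))
        return out

    @property
    def five_prime_utr(self) -> list[tuple[int, int]]:
        """Exonic sequence upstream of the CDS in transcript orientation."""
        return self._utr_side(low=self.strand == "+")

    @property
    def three_prime_utr(self) -> list[tuple[int, int]]:
        return self._utr_side(low=self.strand == "-")

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def feature_intervals(self) -> list[tuple[int, int, str]]:
        """All (start, end, class) pieces of this transcript.

        Classes: five_prime_utr / three_prime_utr where derivable, remaining
        exonic sequence "exon" (this includes CDS), inter-exon gaps "intron".
        """
        pieces: list[tuple[int, int, str]] = []
        utr5 = self.five_prime_utr
        utr3 = self.three_prime_utr
        utr = sorted(utr5 + utr3)
        for s, e in self.exons:
            cursor = s
            for us, ue in utr:
                if ue <= s or us >= e:
                    continue
                cls = "five_prime_utr" if (us, ue) in utr5 else "three_prime_utr"
                if us > cursor:
                    pieces.append((cursor, us, "exon"))
                pieces.append((max(us, s), min(ue, e), cls))
                cursor = min(ue, e)
            if cursor < e:
                pieces.append((cursor, e, "exon"))
        pieces.extend((s, e, "intron") for s, e in self.introns)
        return sorted(pieces)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        starts, ends = zip(*(t.span for t in self.transcripts.values()))
        return min(starts), max(ends)


@dataclass
class GenomeAnnotation:
    """gene -> transcript -> feature hierarchy."""

    genes: dict[str, Gene] = field(default_factory=dict)

    def add_transcript(self, gene_id: str, tx: Transcript) -> None:
        gene = self.genes.setdefault(gene_id, Gene(gene_id, tx.chrom, tx.strand))
        if gene.chrom != tx.chrom:
            raise ValueError(f"transcript {tx.transcript_id} on wrong chromosome")
        gene.transcripts[tx.transcript_id] = tx

    def transcripts(self) -> Iterable[tuple[str, Transcript]]:
        for gid, gene in self.genes.items():
            for tx in gene.transcripts.values():
                yield gid, tx


class SequenceStore:
    """In-memory chromosome -> nucleotide string mapping."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seq = {c: str(s).upper() for c, s in sequences.items()}

    def chromosomes(self) -> list[str]:
        return list(self._seq)

    def length(self, chrom: str) -> int:
        return len(self._seq[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seq:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > len(self._seq[chrom]) or start >= end:
            raise ValueError(
                f"window {chrom}:{start}-{end} outside chromosome bounds"
            )
        return self._seq[chrom][start:end]


@dataclass
class CountMatrix:
    """Non-negative integer counts (rows = genes or peaks, columns = samples)."""

    counts: pd.DataFrame
    lib_size: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative entries in count matrix")
        if self.lib_size is None:
            self.lib_size = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_size = pd.Series(self.lib_size, index=self.counts.columns).astype(
                float
            )

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# readers / writers


def read_peaks_bed(path: str | Path) -> list[PeakRecord]:
    """Read peak intervals from a BED6 file (counts left unset)."""
    peaks: list[PeakRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 BED columns")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate peak_id {name!r}")
            seen.add(name)
            peaks.append(PeakRecord(iv, name))
    return peaks


def write_peaks_bed(peaks: Sequence[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.peak_id}\t0\t{iv.strand}\n"
            )


def read_intervals_bed(path: str | Path) -> list[GenomicInterval]:
    """Read plain intervals (e.g. read fragments); BED3+, strand optional."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                out.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_intervals_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tread{i}\t0\t{iv.strand}\n")


def read_gtf(path: str | Path) -> GenomeAnnotation:
    """Load exon/CDS rows of a GTF into a :class:`GenomeAnnotation`.

    pyranges performs the 1-based-inclusive -> 0-based-half-open conversion.
    """
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    required = {"Feature", "gene_id", "transcript_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"GTF {path} lacks required attributes {required}")
    ann = GenomeAnnotation()
    df = df[df["Feature"].isin(["exon", "CDS"])]
    for (gid, tid), sub in df.groupby(["gene_id", "transcript_id"], sort=True):
        strands = set(sub["Strand"].astype(str))
        if not strands.issubset({"+", "-"}):
            raise ValueError(f"unknown strand for transcript {tid}")
        exons = sub[sub["Feature"] == "exon"]
        cds = sub[sub["Feature"] == "CDS"]
        tx = Transcript(
            transcript_id=str(tid),
            chrom=str(sub["Chromosome"].iloc[0]),
            strand=strands.pop(),
            exons=list(zip(exons["Start"], exons["End"])),
            cds=list(zip(cds["Start"], cds["End"])),
        )
        ann.add_transcript(str(gid), tx)
    return ann


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Serialize exon and CDS rows (coordinates back-converted to 1-based)."""
    with open(path, "w") as fh:
        for gid in sorted(annotation.genes):
            gene = annotation.genes[gid]
            for tid in sorted(gene.transcripts):
                tx = gene.transcripts[tid]
                attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
                for feature, ivs in (("exon", tx.exons), ("CDS", tx.cds)):
                    for s, e in ivs:
                        fh.write(
                            f"{tx.chrom}\tsyncliptic\t{feature}\t{s + 1}\t{e}\t.\t"
                            f"{tx.strand}\t.\t{attrs}\n"
                        )


def read_fasta(path: str | Path) -> SequenceStore:
    from Bio import SeqIO

    return SequenceStore(
        {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    )


def write_fasta(
    sequences: Mapping[str, str] | SequenceStore, path: str | Path, width: int = 70
) -> None:
    if isinstance(sequences, SequenceStore):
        sequences = {c: sequences.fetch(c, 0, sequences.length(c)) for c in sequences.chromosomes()}
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# read counting


def count_reads_in_peaks(
    peaks: Sequence[PeakRecord],
    reads_x: Sequence[GenomicInterval],
    reads_y: Sequence[GenomicInterval],
    strand_matched: bool = False,
    min_overlap: int = 1,
) -> tuple[list[PeakRecord], int, int]:
    """Count reads overlapping each peak by >= ``min_overlap`` bases.

    A read overlapping several peaks increments each of them, but the
    per-sample library size (reads mapping to the peak universe) counts it
    once.  Returns (peaks with counts, lib_size_x, lib_size_y).
    """
    counts = []
    libs = []
    for reads in (reads_x, reads_y):
        c, lib = _count_one_sample(peaks, reads, strand_matched, min_overlap)
        counts.append(c)
        libs.append(lib)
    out = [
        p.with_counts(cx, cy) for p, cx, cy in zip(peaks, counts[0], counts[1])
    ]
    return out, libs[0], libs[1]


def _count_one_sample(
    peaks: Sequence[PeakRecord],
    reads: Sequence[GenomicInterval],
    strand_matched: bool,
    min_overlap: int,
) -> tuple[np.ndarray, int]:
    known_chroms = {p.interval.chrom for p in peaks}
    counts = np.zeros(len(peaks), dtype=np.int64)
    lib = 0
    skipped = 0
    strands = ("+", "-", ".") if strand_matched else (None,)
    for strand in strands:
        for chrom in known_chroms:
            idx = np.array(
                [
                    i
                    for i, p in enumerate(peaks)
                    if p.interval.chrom == chrom
                    and (strand is None or p.interval.strand == strand)
                ],
                dtype=int,
            )
            if idx.size == 0:
                continue
            r_sel = [
                r
                for r in reads
                if r.chrom == chrom and (strand is None or r.strand == strand)
            ]
            if not r_sel:
                continue
            r_start = np.sort(np.array([r.start for r in r_sel]))
            r_end = np.sort(np.array([r.end for r in r_sel]))
            p_start = np.array([peaks[i].interval.start for i in idx])
            p_end = np.array([peaks[i].interval.end for i in idx])
            # reads overlapping [ps, pe) by >= k bases: start <= pe - k and end >= ps + k
            n_started = np.searchsorted(r_start, p_end - min_overlap, side="right")
            n_ended = np.searchsorted(r_end, p_start + min_overlap, side="left")
            counts[idx] = n_started - n_ended
            # library size: reads touching any (merged) peak, counted once
            order = np.argsort(p_start)
            merged: list[list[int]] = []
            for s, e in zip(p_start[order], p_end[order]):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], int(e))
                else:
                    merged.append([int(s), int(e)])
            m_start = np.array([m[0] for m in merged])
            m_end = np.array([m[1] for m in merged])
            rs = np.array([r.start for r in r_sel])
            re = np.array([r.end for r in r_sel])
            # exact for min_overlap=1 (the default); for larger k a read
            # spanning a gap could satisfy k against the merged region only
            pos = np.searchsorted(m_start, re - min_overlap, side="right") - 1
            hit = (pos >= 0) & (m_end[np.clip(pos, 0, None)] >= rs + min_overlap)
            lib += int(hit.sum())
    skipped = sum(1 for r in reads if r.chrom not in known_chroms)
    if skipped:
        log.warning("skipped %d reads on unknown chromosomes", skipped)
    return counts, lib


# ---------------------------------------------------------------------------
# result tables


def write_results_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV; float columns in scientific notation."""
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.6e}"
            )
    out.to_csv(path, sep="\t", index=False)


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
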