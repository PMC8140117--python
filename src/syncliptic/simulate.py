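"""Synthetic fixtures with the statistical structure the analyses assume.

Three generators produce, with ground-truth labels and full seed
determinism: (i) a toy genome + annotation and a two-sample CLIP experiment
with NB counts, differing library scales, a smooth nonlinear M-vs-A trend
and a labelled minority of truly compartment-enriched peaks; (ii) a
4-time-point (0/8/12/24 h) transcription-shutoff decay time course with
genotype-dependent stabilization archetypes for a labelled gene subset;
(iii) a label-free proteomics intensity matrix with intensity-dependent
(missing-not-at-random) holes.  Every generator is a pure function of its
parameters and seed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _nb
from .io import (
    CountMatrix,
    GenomeAnnotation,
    GenomicInterval,
    PeakRecord,
    SequenceStore,
    Transcript,
    write_intervals_bed,
    write_peaks_bed,
)


def default_trend(a: np.ndarray) -> np.ndarray:
    """Smooth nonlinear M-vs-A distortion mimicking an off-centre raw MA cloud."""
    a = np.asarray(a, dtype=float)
    return 0.8 * np.sin(a / 2.0) - 0.5 * np.exp(-a)


# ---------------------------------------------------------------------------
# toy genome + annotation


def simulate_annotation(
    n_genes: int,
    seed: int = 0,
    chrom_length: int | None = None,
    coding_fraction: float = 0.8,
) -> tuple[GenomeAnnotation, SequenceStore]:
    """Random non-overlapping genes on a toy genome.

    Genes carry 1-3 transcripts of 2-8 exons; coding genes (default 80%)
    have a CDS flanked by non-empty 5'/3' UTRs on their longest transcript.
    Raises if ``chrom_length`` is given and cannot hold all genes.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    ann = GenomeAnnotation()
    chrom = "chr1"
    cursor = 500
    for g in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 9))
        exon_lens = rng.integers(100, 401, size=n_exons)
        intron_lens = rng.integers(80, 601, size=n_exons - 1)
        exons = []
        pos = cursor
        for i in range(n_exons):
            exons.append((pos, pos + int(exon_lens[i])))
            pos = exons[-1][1]
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        gene_end = exons[-1][1]
        if chrom_length is not None and gene_end > chrom_length:
            raise ValueError(
                f"gene {g + 1} of {n_genes} exceeds chromosome capacity "
                f"{chrom_length}"
            )
        gid = f"gene{g + 1:05d}"
        cds: list[tuple[int, int]] = []
        if rng.random() < coding_fraction:
            first_s, first_e = exons[0]
            last_s, last_e = exons[-1]
            cds_lo = int(rng.integers(first_s + 20, first_e - 10))
            cds_hi = int(rng.integers(last_s + 10, last_e - 20))
            cds = [
                (max(s, cds_lo), min(e, cds_hi))
                for s, e in exons
                if min(e, cds_hi) > max(s, cds_lo)
            ]
        ann.add_transcript(
            gid,
            Transcript(f"{gid}.t1", chrom, strand, exons, cds),
        )
        for t in range(int(rng.integers(0, 3))):
            lo = int(rng.integers(0, n_exons - 1))
            hi = int(rng.integers(lo + 1, n_exons)) + 1
            sub = exons[lo:hi]
            sub_cds = [
                (max(s, cds[0][0]), min(e, cds[-1][1]))
                for s, e in sub
                if cds and min(e, cds[-1][1]) > max(s, cds[0][0])
            ]
            ann.add_transcript(
                gid,
                Transcript(f"{gid}.t{t + 2}", chrom, strand, sub, sub_cds),
            )
        cursor = gene_end + int(rng.integers(300, 1501))
    total = cursor + 500
    if chrom_length is not None:
        total = chrom_length
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bytes(alphabet[rng.integers(0, 4, size=total)]).decode()
    return ann, SequenceStore({chrom: seq})


# ---------------------------------------------------------------------------
# CLIP experiment


@dataclass
class ClipSimulation:
    peaks: list[PeakRecord]
    truth: pd.DataFrame  # peak_id, enriched, effect_log2
    lib_x: int
    lib_y: int
    reads_x: list[GenomicInterval] | None = None
    reads_y: list[GenomicInterval] | None = None
    params: dict = field(default_factory=dict)

    def count_matrix(self) -> CountMatrix:
        df = pd.DataFrame(
            {
                "x": [p.count_x for p in self.peaks],
                "y": [p.count_y for p in self.peaks],
            },
            index=[p.peak_id for p in self.peaks],
        )
        return CountMatrix(df)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_peaks_bed(self.peaks, outdir / "peaks.bed")
        self.count_matrix().counts.rename_axis("peak_id").to_csv(
            outdir / "counts.tsv", sep="\t"
        )
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        if self.reads_x is not None:
            write_intervals_bed(self.reads_x, outdir / "reads_x.bed")
            write_intervals_bed(self.reads_y, outdir / "reads_y.bed")


def simulate_clip_experiment(
    annotation: GenomeAnnotation,
    n_peaks: int,
    frac_enriched: float = 0.05,
    effect_log2: float = 2.0,
    phi: float = 0.1,
    trend: Callable[[np.ndarray], np.ndarray] | None = None,
    lib_ratio: float = 0.5,
    seed: int = 0,
    mean_count: float = 30.0,
    frac_depleted: float = 0.0,
    realize_reads: bool = False,
    read_length: int = 40,
    min_gap: int = 40,
    genome: SequenceStore | None = None,
) -> ClipSimulation:
    """Two-sample CLIP peak counts with NB noise, a smooth MA trend and a
    labelled enriched minority.

    Per peak, the reference expectation is log-normal around ``mean_count``;
    the compartment expectation is scaled by ``lib_ratio`` and distorted by
    2**(trend(A) + e) where e = ``effect_log2`` for the enriched fraction
    (optionally -``effect_log2`` for a depleted fraction) and 0 otherwise.
    ``realize_reads`` additionally places fixed-length read fragments with a
    triangular density so within-peak coverage is unimodal.
    """
    if not (0 <= frac_enriched < 1) or not (0 <= frac_depleted < 1):
        raise ValueError("fractions must lie in [0, 1)")
    if phi < 0 or lib_ratio <= 0 or mean_count <= 0:
        raise ValueError("phi, lib_ratio and mean_count must be positive")
    trend = trend or default_trend
    rng = np.random.default_rng(seed)

    genes = sorted(annotation.genes)
    gene_spans = {g: annotation.genes[g].span for g in genes}
    chrom_of = {g: annotation.genes[g].chrom for g in genes}
    strand_of = {g: annotation.genes[g].strand for g in genes}

    # peaks are disjoint within the sample, as a peak caller would emit them
    peaks: list[PeakRecord] = []
    placed: dict[str, list[tuple[int, int]]] = {g: [] for g in genes}
    widths = rng.integers(50, 251, size=n_peaks)
    for i in range(n_peaks):
        w = int(widths[i])
        for _attempt in range(60):
            g = genes[int(rng.integers(0, len(genes)))]
            lo, hi = gene_spans[g]
            if hi - lo <= w + 1:
                continue
            start = int(rng.integers(lo, hi - w))
            occupied = placed[g]
            j = bisect.bisect_left(occupied, (start, start + w))
            # keep at least min_gap between peaks so realized reads, which
            # extend up to read_length/2 beyond a peak edge, stay exclusive
            if j > 0 and occupied[j - 1][1] + min_gap > start:
                continue
            if j < len(occupied) and occupied[j][0] < start + w + min_gap:
                continue
            occupied.insert(j, (start, start + w))
            peaks.append(
                PeakRecord(
                    GenomicInterval(chrom_of[g], start, start + w, strand_of[g]),
                    f"peak{i + 1:06d}",
                    gene_id=g,
                )
            )
            break
        else:
            raise ValueError(
                f"could not place {n_peaks} disjoint peaks in the annotation "
                f"(placed {len(peaks)}); simulate more or larger genes"
            )

    mu_y = rng.lognormal(mean=np.log(mean_count), sigma=1.0, size=n_peaks)
    mu_x0 = mu_y * lib_ratio
    a0 = 0.5 * (np.log2(mu_x0 + 1.0) + np.log2(mu_y + 1.0))
    t = np.asarray(trend(a0), dtype=float)
    if not np.isfinite(t).all():
        raise ValueError("trend function returned non-finite values")
    effect = np.zeros(n_peaks)
    n_enr = int(round(frac_enriched * n_peaks))
    n_dep = int(round(frac_depleted * n_peaks))
    special = rng.choice(n_peaks, size=n_enr + n_dep, replace=False)
    effect[special[:n_enr]] = effect_log2
    effect[special[n_enr:]] = -effect_log2
    mu_x = mu_x0 * 2.0 ** (t + effect)

    count_x = _nb.nb_rvs(rng, mu_x, phi)
    count_y = _nb.nb_rvs(rng, mu_y, phi)
    peaks = [
        p.with_counts(cx, cy) for p, cx, cy in zip(peaks, count_x, count_y)
    ]
    truth = pd.DataFrame(
        {
            "peak_id": [p.peak_id for p in peaks],
            "gene_id": [p.gene_id for p in peaks],
            "enriched": effect > 0,
            "depleted": effect < 0,
            "effect_log2": effect,
            "trend_log2": t,
            "mu_y": mu_y,
        }
    )
    sim = ClipSimulation(
        peaks=peaks,
        truth=truth,
        lib_x=int(count_x.sum()),
        lib_y=int(count_y.sum()),
        params={
            "n_peaks": n_peaks,
            "frac_enriched": frac_enriched,
            "effect_log2": effect_log2,
            "phi": phi,
            "lib_ratio": lib_ratio,
            "seed": seed,
            "mean_count": mean_count,
        },
    )
    if realize_reads:
        sim.reads_x = _place_reads(rng, peaks, count_x, read_length, genome)
        sim.reads_y = _place_reads(rng, peaks, count_y, read_length, genome)
    return sim


def _place_reads(
    rng: np.random.Generator,
    peaks: Sequence[PeakRecord],
    counts: np.ndarray,
    read_length: int,
    genome: SequenceStore | None,
) -> list[GenomicInterval]:
    """Fixed-length fragments with triangular centre density inside each peak."""
    reads: list[GenomicInterval] = []
    for p, c in zip(peaks, counts):
        iv = p.interval
        if c == 0:
            continue
        mode = (iv.start + iv.end) / 2.0
        centers = rng.triangular(iv.start, mode, iv.end, size=int(c))
        half = read_length // 2
        hi_cap = genome.length(iv.chrom) if genome is not None else None
        for ctr in centers:
            s = max(0, int(round(ctr)) - half)
            e = s + read_length
            if hi_cap is not None and e > hi_cap:
                e = hi_cap
                s = max(0, e - read_length)
            reads.append(GenomicInterval(iv.chrom, s, e, iv.strand))
    return reads


# ---------------------------------------------------------------------------
# stability time course

ARCHETYPES = ("stabilized_12h", "stabilized_24h", "early_transient")

# unit-amplitude mean log2FC (mutant/wild-type) at 0/8/12/24 h per archetype;
# shapes are chosen mutually distant under the (1 - R)/2 profile distance so
# the three decay behaviours are genuinely distinguishable
_ARCHETYPE_PROFILES = {
    "stabilized_12h": np.array([0.0, 0.4, 2.2, 2.4]),
    "stabilized_24h": np.array([0.0, 0.0, 0.2, 2.4]),
    "early_transient": np.array([0.0, 2.0, 1.0, 0.0]),
}


@dataclass
class StabilitySimulation:
    counts: dict[float, CountMatrix]  # per time point
    design: pd.DataFrame  # sample, genotype, replicate (per time point layout)
    truth: pd.DataFrame  # gene_id, stabilized, archetype, halflife_h
    params: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for t, cm in self.counts.items():
            cm.counts.rename_axis("gene_id").to_csv(
                outdir / f"counts_{t:g}h.tsv", sep="\t"
            )
        self.design.to_csv(outdir / "design.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def simulate_stability_timecourse(
    n_genes: int,
    frac_stabilized: float = 0.1,
    halflife_shift: float = 2.0,
    replicates: int = 6,
    timepoints: Sequence[float] = (0.0, 8.0, 12.0, 24.0),
    seed: int = 0,
    phi: float = 0.05,
    depth_per_gene: float = 1000.0,
) -> StabilitySimulation:
    """Transcription-shutoff decay counts for two genotypes.

    Expected wild-type abundance decays exponentially with a per-gene
    half-life (log-normal, median 8 h); for the stabilized fraction the
    mutant follows one of three archetype logFC-vs-time profiles
    (stabilized by 12 h, stabilized only at 24 h, early transient), scaled
    by log2(``halflife_shift``).  Sequencing depth is fixed per time point,
    so composition is renormalized as in a real library.  NB noise per
    replicate.
    """
    if halflife_shift <= 0:
        raise ValueError("half-life shift must be positive")
    if not (0 <= frac_stabilized < 1):
        raise ValueError("frac_stabilized must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
    base = rng.lognormal(mean=0.0, sigma=1.2, size=n_genes)
    base /= base.sum()
    halflife = rng.lognormal(mean=np.log(8.0), sigma=0.5, size=n_genes)

    n_stab = int(round(frac_stabilized * n_genes))
    # a transcript that has fully decayed by the late time points cannot carry
    # a late-stabilization signature, so labels go to genes whose half-life
    # leaves them quantifiable across the course
    eligible = np.flatnonzero(halflife >= 4.0)
    if eligible.size < n_stab:
        raise ValueError("too few genes with half-life >= 4 h to stabilize")
    stab_idx = rng.choice(eligible, size=n_stab, replace=False)
    archetype = np.array(["none"] * n_genes, dtype=object)
    archetype[stab_idx] = [ARCHETYPES[i % 3] for i in range(n_stab)]

    amp = np.log2(halflife_shift)
    timepoints = [float(t) for t in timepoints]
    depth = depth_per_gene * n_genes
    counts: dict[float, CountMatrix] = {}
    samples = [
        f"{g}_rep{r + 1}" for g in ("wt", "mut") for r in range(replicates)
    ]
    design = pd.DataFrame(
        {
            "sample": samples,
            "genotype": ["wt"] * replicates + ["mut"] * replicates,
            "replicate": list(range(1, replicates + 1)) * 2,
        }
    )
    t_index = {t: k for k, t in enumerate(timepoints)}
    for t in timepoints:
        decay = base * 2.0 ** (-t / halflife)
        logfc = np.zeros(n_genes)
        for i in stab_idx:
            logfc[i] = amp * _ARCHETYPE_PROFILES[archetype[i]][t_index[t]]
        mu_wt = decay / decay.sum() * depth
        shifted = decay * 2.0**logfc
        mu_mut = shifted / shifted.sum() * depth
        cols = {}
        for g, mu in (("wt", mu_wt), ("mut", mu_mut)):
            for r in range(replicates):
                cols[f"{g}_rep{r + 1}"] = _nb.nb_rvs(rng, mu, phi)
        counts[t] = CountMatrix(pd.DataFrame(cols, index=genes))
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "stabilized": archetype != "none",
            "archetype": archetype,
            "halflife_h": halflife,
        }
    )
    return StabilitySimulation(
        counts=counts,
        design=design,
        truth=truth,
        params={
            "n_genes": n_genes,
            "frac_stabilized": frac_stabilized,
            "halflife_shift": halflife_shift,
            "replicates": replicates,
            "timepoints": timepoints,
            "phi": phi,
            "seed": seed,
        },
    )


def archetype_profiles(
    n_per_archetype: int = 20,
    noise_sd: float = 0.1,
    amplitude: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Noisy archetype logFC profiles (for clustering recovery checks)."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for k, name in enumerate(ARCHETYPES):
        mean = amplitude * _ARCHETYPE_PROFILES[name]
        rows.append(mean + rng.normal(0.0, noise_sd, size=(n_per_archetype, 4)))
        labels.extend([k] * n_per_archetype)
    X = np.vstack(rows)
    idx = [f"gene{i + 1:04d}" for i in range(X.shape[0])]
    return (
        pd.DataFrame(X, index=idx, columns=["0h", "8h", "12h", "24h"]),
        np.asarray(labels),
    )


# ---------------------------------------------------------------------------
# proteomics


def simulate_proteomics(
    n_proteins: int,
    groups: Sequence[str] | None = None,
    frac_changed: float = 0.1,
    missing_rate: float = 0.1,
    seed: int = 0,
    effect: float = 1.0,
    noise_sd: float = 0.25,
):
    """Label-free intensity matrix with group effects and MNAR missingness.

    log2 intensities are normal around a per-protein baseline; a labelled
    fraction carries a +-``effect`` shift in the second group.  Missingness
    is concentrated in low intensities (probability decreasing with the
    intensity rank, mean ``missing_rate``).  Peptide counts (1-20) scale
    with abundance.  Returns (ProteinIntensityMatrix, truth table).
    """
    from .proteomics import ProteinIntensityMatrix

    if missing_rate >= 1 or missing_rate < 0:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if groups is None:
        groups = ["A"] * 6 + ["B"] * 6
    groups = pd.Series(groups, index=[f"s{i + 1}" for i in range(len(groups))])
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("exactly two groups required")

    prots = [f"prot{i + 1:05d}" for i in range(n_proteins)]
    base = rng.normal(25.0, 2.5, size=n_proteins)
    changed = np.zeros(n_proteins, dtype=bool)
    changed[rng.choice(n_proteins, int(round(frac_changed * n_proteins)), replace=False)] = True
    sign = rng.choice([-1.0, 1.0], size=n_proteins)
    delta = np.where(changed, sign * effect, 0.0)

    X = np.empty((n_proteins, len(groups)))
    for j, s in enumerate(groups.index):
        shift = delta if groups[s] == levels[1] else 0.0
        X[:, j] = base + shift + rng.normal(0.0, noise_sd, size=n_proteins)

    if missing_rate > 0:
        flat = X.ravel()
        ranks = np.argsort(np.argsort(flat)) / flat.size  # in [0, 1)
        p_miss = np.clip(missing_rate * 2.0 * (1.0 - ranks), 0.0, 1.0)
        holes = rng.random(flat.size) < p_miss
        flat[holes] = np.nan
        X = flat.reshape(X.shape)

    peptides = np.clip(
        1 + rng.poisson(np.exp((base - 20.0) / 2.5)), 1, 20
    )
    matrix = ProteinIntensityMatrix(
        pd.DataFrame(X, index=prots, columns=groups.index),
        pd.Series(peptides, index=prots),
        groups,
    )
    truth = pd.DataFrame(
        {"protein": prots, "changed": changed, "effect_log2": delta}
    )
    return matrix, truth
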