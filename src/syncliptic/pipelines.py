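"""End-to-end orchestration of the CLIP-enrichment and stability analyses.

Each pipeline reads standard-format inputs, runs the library stages in a
fixed order, writes every artifact as TSV/BED/FASTA plus a JSON manifest of
all parameter values, and logs one structured line per stage.  A single
global seed fans out to per-stage seeds through a stable hash, so stages
are individually reproducible and two runs with identical manifests produce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    FeatureIndex,
    classify_peak,
    coverage_from_reads,
    extract_window,
    feature_distribution,
    peak_center,
    peak_coverage,
    sample_background,
)
from .enrichment import (
    center_cloud_mask,
    enrichment_table,
    estimate_common_dispersion,
    matched_count_cutoff,
    peak_offsets,
    select_matched_count,
    select_peaks,
)
from .io import (
    CountMatrix,
    count_reads_in_peaks,
    read_fasta,
    read_gtf,
    read_intervals_bed,
    read_peaks_bed,
    write_fasta,
    write_peaks_bed,
    write_results_tsv,
)
from .manorm import adjust_m, make_ma_profile, tmm_factors
from .stability import (
    average_linkage_cut,
    correlation_distance,
    filter_expressed,
    nb_de_two_group,
)

log = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2**31)."""
    return (seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class ClipConfig:
    """Inputs and tunables of the CLIP compartment-enrichment pipeline."""

    peaks_bed: str
    out_dir: str
    reads_x_bed: str | None = None
    reads_y_bed: str | None = None
    counts_tsv: str | None = None  # alternative to read BEDs: peak_id, x, y
    gtf: str | None = None
    fasta: str | None = None
    offset_o: float = 1.0
    span: float = 0.25
    robust_iterations: int = 4
    mask_lo: float = -3.0
    mask_hi: float = 1.0
    cutoff: float = 1e-5
    window_size: int = 41
    n_background: int = 200_000
    strand_matched: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClipConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class ClipResult:
    enrichment_x: pd.DataFrame
    enrichment_y: pd.DataFrame
    selected_x: pd.DataFrame
    selected_y: pd.DataFrame
    dispersion: float
    reverse_cutoff: float
    classes: pd.DataFrame | None = None
    class_percentages: pd.Series | None = None
    manifest: dict = field(default_factory=dict)


def _manifest(config, out_dir: Path, extra: dict) -> dict:
    manifest = {
        "syncliptic_version": __version__,
        "parameters": dataclasses.asdict(config),
        **extra,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def run_clip_pipeline(config: ClipConfig) -> ClipResult:
    """count -> TMM -> MA -> LOESS -> dispersion -> LRT -> select ->
    reverse matched-count selection -> classify -> motif windows/background."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    peaks = read_peaks_bed(config.peaks_bed)
    log.info("stage=read_peaks n=%d", len(peaks))
    reads_x = reads_y = None
    if config.counts_tsv is not None:
        tbl = pd.read_csv(config.counts_tsv, sep="\t", index_col=0)
        order = {p.peak_id: p for p in peaks}
        missing = set(tbl.index) - set(order)
        if missing:
            raise ValueError(f"counts for unknown peaks: {sorted(missing)[:3]}...")
        peaks = [order[i].with_counts(r["x"], r["y"]) for i, r in tbl.iterrows()]
        lib_x, lib_y = int(tbl["x"].sum()), int(tbl["y"].sum())
    else:
        if config.reads_x_bed is None or config.reads_y_bed is None:
            raise ValueError("either counts_tsv or both read BEDs are required")
        reads_x = read_intervals_bed(config.reads_x_bed)
        reads_y = read_intervals_bed(config.reads_y_bed)
        peaks, lib_x, lib_y = count_reads_in_peaks(
            peaks, reads_x, reads_y, strand_matched=config.strand_matched
        )
    log.info("stage=count lib_x=%d lib_y=%d", lib_x, lib_y)

    x = np.array([p.count_x for p in peaks])
    y = np.array([p.count_y for p in peaks])
    ids = np.array([p.peak_id for p in peaks])
    cm = CountMatrix(
        pd.DataFrame({"x": x, "y": y}, index=ids),
        lib_size=pd.Series({"x": lib_x, "y": lib_y}),
    )
    norm = tmm_factors(cm)
    eff = norm.effective_lib_size
    log.info("stage=tmm factors=%s", norm.factors.round(4).to_dict())

    results = {}
    masks = {}
    profiles = {}
    for direction, (cx, cy, lx, ly) in {
        "x": (x, y, eff["x"], eff["y"]),
        "y": (y, x, eff["y"], eff["x"]),
    }.items():
        prof = make_ma_profile(ids, cx, cy, lx, ly, o=config.offset_o)
        prof = adjust_m(
            prof, span=config.span, robust_iterations=config.robust_iterations
        )
        profiles[direction] = prof
        masks[direction] = center_cloud_mask(prof, config.mask_lo, config.mask_hi)

    # common dispersion from the centre of the forward raw MA cloud
    mask = masks["x"]
    if mask.sum() < 50:
        raise ValueError("too few peaks in the central MA cloud for dispersion")
    prof_x = profiles["x"]
    ox, oy = peak_offsets(prof_x.lib_x, prof_x.lib_y, prof_x.fitted)
    disp = estimate_common_dispersion(x[mask], y[mask], ox[mask], oy[mask])
    log.info("stage=dispersion phi=%.4g n=%d", disp.phi, disp.n_peaks_used)

    for direction in ("x", "y"):
        results[direction] = enrichment_table(profiles[direction], disp.phi)

    selected_x = select_peaks(results["x"], cutoff=config.cutoff)
    n_sel = int(selected_x["selected"].sum())
    rev_cutoff = float("nan")
    if n_sel > 0:
        rev_cutoff = matched_count_cutoff(results["y"]["p"].to_numpy(), n_sel)
        selected_y = select_matched_count(results["y"], n_sel)
    else:
        selected_y = select_peaks(results["y"], cutoff=0.0)
    log.info(
        "stage=select n_forward=%d reverse_cutoff=%.6g", n_sel, rev_cutoff
    )

    write_results_tsv(selected_x, out / "enrichment_x.tsv")
    write_results_tsv(selected_y, out / "enrichment_y.tsv")
    by_id = {p.peak_id: p for p in peaks}
    sel_peaks = [by_id[i] for i in selected_x.loc[selected_x["selected"], "peak_id"]]
    write_peaks_bed(sel_peaks, out / "selected_x.bed")

    classes_df = None
    percentages = None
    if config.gtf is not None:
        index = FeatureIndex(read_gtf(config.gtf))
        rows = []
        for p in sel_peaks:
            cov = peak_coverage(p, reads_x) if reads_x is not None else np.zeros(0)
            center = (
                peak_center(p, cov)
                if cov.size
                else peak_center(p, np.zeros(len(p.interval)))
            )
            cls, gene = classify_peak(p, index, center.center)
            rows.append(
                {
                    "peak_id": p.peak_id,
                    "center": center.center,
                    "class": cls,
                    "gene_id": gene,
                }
            )
        classes_df = pd.DataFrame(
            rows, columns=["peak_id", "center", "class", "gene_id"]
        )
        classes_df.to_csv(out / "classes_x.tsv", sep="\t", index=False)
        if len(classes_df):
            percentages, n_intergenic = feature_distribution(classes_df["class"])
            log.info(
                "stage=classify pct=%s intergenic=%d",
                percentages.round(2).to_dict(),
                n_intergenic,
            )
        if config.fasta is not None and len(classes_df):
            _motif_inputs(config, classes_df, index, reads_x, out)

    manifest = _manifest(
        config,
        out,
        {"dispersion": disp.phi, "n_selected": n_sel, "reverse_cutoff": rev_cutoff},
    )
    return ClipResult(
        enrichment_x=results["x"],
        enrichment_y=results["y"],
        selected_x=selected_x,
        selected_y=selected_y,
        dispersion=disp.phi,
        reverse_cutoff=rev_cutoff,
        classes=classes_df,
        class_percentages=percentages,
        manifest=manifest,
    )


def _motif_inputs(config: ClipConfig, classes_df, index, reads_x, out: Path) -> None:
    genome = read_fasta(config.fasta)
    targets = {}
    skipped = 0
    for _, row in classes_df.iterrows():
        try:
            seq = extract_window(
                int(row["center"]),
                _chrom_of(classes_df, row, index),
                genome,
                size=config.window_size,
            )
        except (ValueError, KeyError):
            skipped += 1
            continue
        targets[row["peak_id"]] = seq
    write_fasta(targets, out / "targets_x.fa")
    if skipped:
        log.warning("stage=windows skipped=%d (chromosome boundary)", skipped)
    chrom_lengths = {c: genome.length(c) for c in genome.chromosomes()}
    coverage = (
        coverage_from_reads(reads_x, chrom_lengths)
        if reads_x is not None
        else {c: np.zeros(n, dtype=int) for c, n in chrom_lengths.items()}
    )
    for cls in sorted(set(classes_df["class"]) - {"intergenic"}):
        try:
            seqs = sample_background(
                index,
                coverage,
                genome,
                feature_class=cls,
                n=config.n_background,
                size=config.window_size,
                seed=stage_seed(config.seed, f"background_{cls}"),
            )
        except ValueError as exc:
            log.warning("stage=background class=%s skipped: %s", cls, exc)
            continue
        write_fasta(
            {f"{cls}_bg{i + 1}": s for i, s in enumerate(seqs)},
            out / f"background_{cls}.fa",
        )


def _chrom_of(classes_df, row, index) -> str:
    # peaks of one toy simulation live on one chromosome; fall back to the
    # first indexed chromosome when gene assignment is absent
    gene = row["gene_id"]
    for chrom, spans in index._spans.items():
        if gene is not None and gene in spans["gene"]:
            return chrom
    return next(iter(index._spans))


# ---------------------------------------------------------------------------
# stability pipeline


@dataclass
class StabilityConfig:
    counts_tsv: dict[str, str]  # time point label -> counts TSV (genes x samples)
    design_tsv: str  # columns: sample, genotype
    out_dir: str
    fdr: float = 0.05
    k: int = 3
    filter_rule: str = "count_fraction"
    filter_threshold: float = 10
    filter_fraction: float = 2 / 3
    reference_timepoint: str | None = None  # filter on this matrix (default first)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StabilityConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class StabilityResult:
    de: dict[str, pd.DataFrame]
    increased: pd.Index
    decreased: pd.Index
    clusters: dict[str, pd.Series]
    manifest: dict = field(default_factory=dict)


def run_stability_pipeline(config: StabilityConfig) -> StabilityResult:
    """Per-time-point two-group NB tests at the FDR threshold, sign-split
    gene sets, and (1-R)/2 average-linkage clustering of logFC profiles."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = pd.read_csv(config.design_tsv, sep="\t")
    timepoints = list(config.counts_tsv)
    matrices = {
        t: CountMatrix(pd.read_csv(p, sep="\t", index_col=0))
        for t, p in config.counts_tsv.items()
    }
    ref = config.reference_timepoint or timepoints[0]
    kept = filter_expressed(
        matrices[ref],
        rule=config.filter_rule,
        threshold=config.filter_threshold,
        fraction=config.filter_fraction,
    )
    log.info("stage=filter kept=%d of %d", len(kept), matrices[ref].counts.shape[0])

    de = {}
    for t in timepoints:
        cm = matrices[t]
        sub = CountMatrix(cm.counts.loc[kept], lib_size=cm.lib_size)
        groups = (
            design.set_index("sample").loc[sub.counts.columns, "genotype"].to_numpy()
        )
        de[t] = nb_de_two_group(sub, groups)
        write_results_tsv(
            de[t].reset_index(), out / f"de_{t}.tsv"
        )
        log.info(
            "stage=de t=%s significant=%d", t, int((de[t]["q"] < config.fdr).sum())
        )

    # a gene significant at any time point, direction by sign at its best q
    qs = pd.DataFrame({t: de[t]["q"] for t in timepoints})
    fcs = pd.DataFrame({t: de[t]["logFC"] for t in timepoints})
    sig = qs.min(axis=1) < config.fdr
    best_t = qs.idxmin(axis=1)
    sign = np.sign(
        [fcs.loc[g, best_t[g]] for g in fcs.index]
    )
    increased = fcs.index[sig & (sign > 0)]
    decreased = fcs.index[sig & (sign < 0)]

    clusters: dict[str, pd.Series] = {}
    for name, genes in (("increased", increased), ("decreased", decreased)):
        if len(genes) < config.k:
            log.info("stage=cluster set=%s skipped (only %d genes)", name, len(genes))
            continue
        profiles = fcs.loc[genes]
        D, _ = correlation_distance(profiles)
        labels = average_linkage_cut(D, k=config.k)
        clusters[name] = pd.Series(labels, index=genes, name="cluster")
        clusters[name].rename_axis("gene_id").to_frame().to_csv(
            out / f"clusters_{name}.tsv", sep="\t"
        )
        log.info(
            "stage=cluster set=%s sizes=%s",
            name,
            np.bincount(labels)[1:].tolist(),
        )

    manifest = _manifest(
        config,
        out,
        {
            "n_increased": int(len(increased)),
            "n_decreased": int(len(decreased)),
        },
    )
    pd.Series(increased).to_csv(out / "increased.tsv", sep="\t", index=False)
    pd.Series(decreased).to_csv(out / "decreased.tsv", sep="\t", index=False)
    return StabilityResult(
        de=de,
        increased=increased,
        decreased=decreased,
        clusters=clusters,
        manifest=manifest,
    )
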