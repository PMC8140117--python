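# syncliptic

Statistics for compartment-resolved RNA-binding-protein studies:
replicate-free CLIP-seq peak enrichment between a biochemically isolated
compartment (e.g. synaptoneurosomes) and total tissue, annotation and
sequence extraction for motif discovery, differential mRNA decay from
transcription-shutoff time courses, and label-free proteomics statistics —
plus seeded synthetic-data generators with ground-truth labels so every
stage can be exercised and validated without any sequencing download.

It is written for computational biologists who have peak calls and read
counts from a two-condition CLIP experiment without replicates (one library
per compartment), and for the downstream RNA-seq/proteomics comparisons
that typically accompany such a study.

## The model

For each peak with read counts *x* (compartment) and *y* (reference), the
log-ratio and average log-intensity are

    M = log2[(x + o)/(lib_x + o)] − log2[(y + o)/(lib_y + o)]
    A = [log2(x + o) + log2(y + o)] / 2,   o = 1,

where `lib` are effective library sizes: reads mapping to the peak
universe × TMM normalization factor. Because the raw cloud is off-centre
and bends with *A*, a robust LOESS (span 1/4, locally linear, bisquare
"symmetric" reweighting, 4 iterations) of *M* on *A* is subtracted:
adjusted M = M − fitted M. A single negative-binomial dispersion φ
(variance μ + φμ²) is estimated from the centre of the raw cloud
(−3 < M < 1) by Cox–Reid adjusted profile likelihood — with no replicates,
a common dispersion is the only estimable choice — and each peak is tested
by a likelihood-ratio test of a shared rate against the saturated model,
with the LOESS correction folded into the GLM offsets; the statistic is
referred to χ²(1) and peaks are ranked by unadjusted p (selection at
p < 1e−5; the reverse direction selected by a matched-count cutoff).

Downstream, decay time courses are tested per time point with a two-group
NB LRT (TMM offsets, common Cox–Reid dispersion, BH-FDR 0.05), and logFC
profiles are clustered with average linkage on the distance (1 − R)/2
(Pearson R), cut into three groups. Gene-set enrichment is the one-sided
hypergeometric tail; association tests are Pearson χ² with an
expected-count ≥ 5 rule. Proteomics intensities are filtered (≥2 peptides,
≤4 missing), normalized by a rescaled robust z-score, and tested with
pooled-variance t-tests, with a lowest-decile pseudo fold change for
proteins observed in only one condition.

See `docs/methods.md` for assumptions, defaults, numerical choices and
limitations.

## Worked example

`examples/clip_enrichment.py` simulates a 2,000-peak two-sample CLIP
experiment with 5% truly enriched peaks at 16-fold and runs the whole
chain; it prints:

```
effective library sizes: x=79032 y=112447
adjusted MA cloud (truly null peaks): intercept=+0.125 slope=-0.034
common dispersion phi=0.138 from 1679 central peaks
peaks with p < 1e-5: 53 (truly enriched among them: 100%)
matched-count reverse cutoff: 7.420e-06 (selects exactly 53 peaks)
```

The near-flat line through the null peaks shows the LOESS adjustment
removed the injected intensity-dependent trend; φ ≈ 0.14 is the common
overdispersion estimated from the central cloud; all 53 peaks passing the
stringent cutoff are truly compartment-enriched; and the reverse
(reference-specific) analysis is thresholded so it returns exactly as many
peaks.

The other example scripts cover the remaining capabilities, each printing
and explaining its numbers:

- `examples/motif_inputs.py` — feature classification, 41-nt target
  windows, zero-coverage class-matched backgrounds;
- `examples/stability_clustering.py` — per-time-point differential decay,
  archetype clustering (ARI vs truth), hypergeometric target enrichment;
- `examples/proteomics_abundance.py` — filtering, robust normalization,
  pooled t-tests, pseudo fold changes.

There is also a thin CLI (`syncliptic simulate|count|manorm|run-clip|
run-stability|proteomics`) over the same library functions; the pipeline
commands take a YAML config and write TSV/BED/FASTA artifacts with a JSON
manifest, byte-reproducibly for a given seed.

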