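# smaddyn

Quantification of SMAD signaling dynamics in micropatterned human embryonic stem
cell (hESC) colonies and dissociated single cells, from raw multi-channel
microscopy to interpretable dynamic features — plus the two companion analyses
such experiments lean on: Kolmogorov–Smirnov comparison of single-cell
immunofluorescence distributions across conditions, and classification of
time-course RNA-seq responses into transient, stable, and down-regulated gene
groups.

The package is aimed at quantitative biologists analyzing live reporter lines
(e.g. RFP–SMAD1, mCitrine–SMAD2, GFP–SMAD4) on micropatterned colonies: BMP/SMAD1
signaling is sustained (*stable*) while ACTIVIN/SMAD2 signaling is *adaptive* — a
pulse of nuclear translocation that relaxes to an elevated post-stimulation
baseline — and both responses are biased toward the colony edge. Every stage is
testable without any experimental download: a first-class synthetic-data module
renders colonies of packed nuclei with known per-cell ground truth, draws
log-normal endpoint IF intensities, and simulates negative-binomial count time
courses with planted gene classes.

## The pipeline

1. **Correction** (`smaddyn.correction`) — background removal by subtracting the
   per-channel *minimum intensity image* (pixel-wise minimum over all frames, with
   a tiled low-percentile fallback for single-frame endpoint images), then
   vignetting correction by dividing by the minimum image normalized to mean 1 —
   which corrects the intensity drop-off at the image border without changing the
   average image intensity.
2. **Segmentation** (`smaddyn.segmentation`) — threshold the nuclear-marker (H2B
   or DAPI) channel into a foreground mask; median + disk-mean filtering matched
   to the expected nucleus size; extended-maxima seeds, dilated; seeded watershed
   restricted to the foreground; removal of objects much larger or smaller than a
   nucleus; and a perinuclear *donut* cytoplasmic mask per cell (difference of two
   dilations of the nuclear mask, never overlapping any neighboring nuclear mask).
3. **Quantification** (`smaddyn.quantify`) — median per-cell nuclear intensity in
   each channel; the SMAD2-style readout N/C = median nuclear / median donut
   reporter intensity; the SMAD1-style readout nuclear reporter / nuclear H2B;
   least-squares colony circle fit; radial profiles binned by distance from the
   colony edge and averaged over colonies; population mean ± SD trajectories per
   time point (no single-cell tracking).
4. **Dynamics** (`smaddyn.dynamics`) — trajectory features: pre-stimulus baseline,
   peak, peak time, post-stimulation baseline (mean readout at T > 8 hr after
   ligand addition), and the adaptation index
   `(peak − post) / (peak − pre) ∈ [0, 1]`; stable-vs-adaptive classification;
   Hill fits `A·c^h / (K^h + c^h)` of dose-response series.
5. **Distribution comparison** (`smaddyn.ksdist`) — per-replicate KS distance of
   each marker/condition CDF to a reference condition's CDF (robust to
   replicate-to-replicate shifts in absolute intensity), with one-way ANOVA and
   Tukey HSD significance classes.
6. **Transcriptome** (`smaddyn.transcriptome`) — control-baseline interpolation
   (linear through the 0/6/12 hr untreated samples) and subtraction; the
   two-fold-change and >100-read-count gene filters; per-gene z-scoring;
   average-linkage hierarchical clustering with centered-correlation distance; and
   template-based assignment of clusters to transient-up / stable-up /
   down-regulated groups. Median-of-ratios normalization, hypergeometric gene-set
   enrichment (Benjamini–Hochberg corrected), and RT-PCR ΔΔCt-style relative
   quantification are included.

## Worked example

Simulate two adaptive-reporter colonies, run the full image pipeline, and
summarize the recovered population trajectory:

```python
from smaddyn import pipeline

config = pipeline.validate_config({
    "seed": 11,
    "outdir": "demo_run",
    "stages": ["simulate", "correct", "segment", "quantify",
               "trajectory", "dynamics"],
    "simulate": {"kind": "adaptive", "n_colonies": 2, "n_cells_per_colony": 40},
})
pipeline.run_pipeline(config)
```

`demo_run/dynamics_summary.json` then contains (values printed by this exact run):

```
      pre_baseline: 0.705
              peak: 3.107
            t_peak: 1.720
     post_baseline: 0.918
  adaptation_index: 0.911
    classification: adaptive
```

Reading: before ACTIVIN-like stimulation (t_stim = 1 hr) the reporter is
cytoplasm-enriched (N/C ≈ 0.7); the response peaks ~0.7 hr after stimulation at
N/C ≈ 3.1, then relaxes to a baseline (mean over T > 8 hr after stimulation)
of ≈ 0.92 — elevated above the pre-stimulus level but far below the peak, giving
an adaptation index of 0.91 and an *adaptive* classification. The programmed
ground truth for this run (`demo_run/ground_truth.csv`) lists each cell's true
nuclear fraction and N/C ratio per frame; the recovered trajectory
(`demo_run/trajectory.csv`) tracks it within a few percent RMS.

The same stages are available from the shell via the `smaddyn` CLI
(`simulate`, `correct`, `segment`, `quantify`, `profile`, `trajectory`,
`dynamics`, `ksdist`, `timecourse`, `run`); see `smaddyn --help`.

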