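# osteomsi

Spatial marker discovery and validation for MALDI mass spectrometry
imaging (MSI) of osteochondral tissue — cartilage, subchondral bone and
the junction between them — aimed at extracellular-matrix (ECM)
remodeling in osteoarthritis. The package is for proteomics and imaging
scientists who need a reproducible, scriptable version of the
candidate-discovery / cohort-validation workflow that commercial MSI
software performs interactively.

## What it computes

MALDI-MSI acquires one MS1 spectrum per laser position (pixel). On such
data the pipeline runs, in order:

1. **Normalization.** Each pixel's spectrum is rescaled so the spike-in
   reference peptide ([Glu1]-fibrinopeptide B, monoisotopic
   [M+H]⁺ = 1570.6768) has unit area in its window, cancelling
   pixel-to-pixel multiplicative gain. TIC and RMS normalization are
   available alternatives, and a TIC-preserving resampler puts ragged
   per-pixel axes onto one common mass axis.
2. **Feature selection.** Peaks of the tissue mean spectrum are picked
   and the top-500 most abundant m/z features form a pixels × features
   matrix; feature images are hotspot-clipped (99th percentile) for
   display only.
3. **Segmentation.** Bisecting K-means (repeated 2-means splits of the
   highest-variance leaf) partitions the pixels into tissue regions —
   typically 4–6 leaves separate cartilage, transitional layer, healthy
   and diseased bone, and marrow. Manual polygon ROIs are supported for
   guided segmentation.
4. **Screening.** Every feature is scored by the area under the ROC
   curve (midrank Mann–Whitney, AUROC = P(a > b) + ½P(a = b)) between
   two region masks; features with max(AUROC, 1 − AUROC) ≥ 0.85 become
   candidate markers.
5. **Validation.** Candidates are tested across the donor cohort on
   per-sample ROI mean intensities with one-sided Student's t-tests
   (paired within donors, pooled-variance between donors) at α = 0.05,
   with a descriptive PLS-DA score plot.
6. **Annotation.** Candidate m/z values are matched against a peptide
   spectral library (sequence + PTMs + theoretical monoisotopic [M+H]⁺)
   at ≤ 2 mDa, with explicit handling of hydroxyproline (HYP,
   +15.994915 Da) ladders on collagen peptides.

A ground-truthed synthetic cohort generator (`osteomsi.synthetic`)
produces osteochondral phantoms — cartilage band, trabecular bone
network, marrow, and a diseased wedge under the region of cartilage
loss — with log-normal biological noise, per-pixel gain, a spike-in
channel and planted collagen-peptide markers, so the whole pipeline is
testable end to end without any raw data.

## Worked example

```python
from osteomsi import peptide_mz, hyp_series
from osteomsi.pipeline import run_pipeline

print(f"{peptide_mz('EGVNDNEEGFFSAR'):.4f}")   # GluFib spike-in standard
print(hyp_series("GKPGEQGVPGDLGAP"))            # collagen HYP ladder

report = run_pipeline(raw={"run": {"mode": "simulate", "seed": 7}},
                      out_dir="run7")
print(report.counts)
```

prints

```
1570.6768
[(0, 1378.6961...), (1, 1394.6910...), (2, 1410.6859...), (3, 1426.6808...)]
{'pixels': 115200, 'flagged_pixels': 0, 'features': 501, 'samples': 12,
 'segments': 5, 'candidates': 6, 'validated': 4, 'trend': 0, 'annotated': 6}
```

The GluFib mass is the normalization target; the ladder shows the exact
+15.994915 spacing of 0–3 hydroxyprolines on a collagen α1(I) peptide.
The simulated run processes a 12-section cohort (4 OA donors with paired
medial/lateral sections plus 4 controls): 501 features are screened, 6
pass the AUROC ≥ 0.85 screen between diseased and healthy bone, the 4
planted diseased-elevated HYP peptides validate in the paired cohort
test (the 2 bone-marker candidates elevated in *healthy* bone correctly
fail the one-sided elevation test), and all candidates annotate uniquely
against the synthetic library within 2 mDa. Per-stage TSV outputs and a
JSON run report land in `run7/`.

The same stages are available from the shell:

```bash
osteomsi simulate --seed 7 --out section.imzML
osteomsi normalize section.imzML normed.imzML --method reference_peak
osteomsi segment normed.imzML labels.tsv --leaves 5 --seed 7
osteomsi run config.toml --out results/
```

## Layout

```
src/osteomsi/
  config.py        pipeline constants (reference m/z, thresholds, seeds)
  core_data.py     MSIDataset, imzML/TSV I/O, resampling, normalization
  features.py      peak picking, top-N selection, feature tables, images
  segmentation.py  bisecting K-means, polygon/leaf ROIs
  discriminant.py  AUROC screening
  cohort_stats.py  ROI means, one-sided t-tests, PLS-DA
  annotation.py    peptide masses, HYP series, library matching
  synthetic.py     phantom and cohort simulator with ground truth
  pipeline.py      end-to-end orchestration and run reports
  cli.py           `osteomsi` command-line entry point
```

See `docs/methods.md` for the statistical model, parameter choices and
known limitations.
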