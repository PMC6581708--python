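# mstates

EEG microstate analysis for resting-state studies: from multichannel
recordings to per-class temporal parameters and two-group statistics,
with a fully ground-truthed synthetic-EEG generator for validation.

## The problem

Resting-state EEG alternates between brief (~60–120 ms) periods during
which the scalp potential topography stays quasi-stable — *microstates*
— before switching to another configuration. Summarizing a recording by
its microstate dynamics gives a small set of physiologically
interpretable numbers per subject that can be compared between groups
(e.g. a clinical cohort vs controls). `mstates` is for researchers who
want that entire workflow as a tested, scriptable pipeline:

1. **Preprocess**: 1–50 Hz zero-phase Butterworth band-pass, decimation
   to 125 Hz, coordinate-based spatial smoothing, average reference,
   exclusion of ±0.5 s windows around >100 μV excursions.
2. **Segment**: maps at local maxima of the global field power
   `GFP(t) = √(Σᵢ(uᵢ−ū)²/N)` are clustered by a polarity-invariant
   modified k-means (assignment by squared spatial correlation,
   template update by the dominant eigenvector of the members' scatter);
   the number of classes is picked by a seven-criterion meta-criterion
   vote. Clustering runs per subject first, then on the pooled
   individual templates to get group-level classes.
3. **Back-fit**: every sample is labeled winner-takes-all by |spatial
   correlation| (floor 0.5), then temporally smoothed (Besag-style
   penalty, λ = 10, window half-size b = 3) to remove spurious
   single-sample interruptions.
4. **Parameters & statistics**: per class and subject — mean duration
   (ms), occurrence (1/s), coverage, and global explained variance
   `GEVᵤ = Σ_{t∈u}(GFPᵤ(t)·C_{u,t})² / Σ_t GFP(t)²`; groups compared per
   cell with two-tailed Mann–Whitney–Wilcoxon tests and
   Benjamini–Hochberg FDR correction within each parameter's family of
   classes (α = 0.05).

Because real study data of this kind are typically not redistributable,
the package ships a first-class synthetic generator: semi-Markov state
sequences over smooth dipolar template maps, rectified-alpha amplitude
modulation, spatially correlated pink + white noise, and injected
high-amplitude artifacts — all with exported ground truth (templates,
labels, dwell times, artifact times), so every stage is testable.

## Worked example

```python
import numpy as np
import mstates as ms

# one synthetic subject: 65 channels, 500 Hz, 4 latent classes, 40 s
cfg = ms.SimulationConfig(duration=40.0, seed=42)
rec, truth = ms.simulate_subject(cfg)

clean = ms.preprocess(rec)                      # 1-50 Hz, 125 Hz, smoothed, masked
templates, sel = ms.individual_clustering(clean, seed=0)
seq, segments = ms.backfit(clean, templates)

perm, r = ms.match_templates(templates.maps, truth.templates.maps)
print(f"chosen k            : {sel.chosen_k}")
print(f"template recovery |r|: {np.round(np.sort(r), 3)}")
print(f"total GEV           : {templates.gev_total:.3f}")
durations = [ms.mean_duration(segments, u) for u in range(sel.chosen_k)]
print(f"mean durations (ms) : {np.round(durations, 1)}")
coverages = [ms.coverage(seq, u) for u in range(sel.chosen_k)]
print(f"coverage            : {np.round(coverages, 3)}")
```

Output:

```
chosen k            : 4
template recovery |r|: [0.968 0.985 0.989 0.995]
total GEV           : 0.883
mean durations (ms) : [73.7 73.1 78.  72.4]
coverage            : [0.284 0.206 0.271 0.239]
```

The meta-criterion found the four latent classes; each estimated
template correlates ≥ 0.97 in magnitude with a true map (sign is
irrelevant — topographies are polarity invariant); the four classes
explain 88% of the GFP-weighted variance of this subject; dwell times
sit in the 70–80 ms range of the 80 ms generative mean, and each class
covers roughly a quarter of the analyzed time, as generated.

For a cohort, put one row per subject in a manifest CSV
(`subject_id,group,eeg_path[,montage_path]`, EDF or the TSV matrix
format) and run the end-to-end driver, which writes group templates,
per-subject label sequences, segment tables, parameters, and the
group-statistics table:

```bash
mstates simulate --channels 65 --classes 4 --rate 500 --duration 180 \
        --dwell-mean 80 --snr 4 --seed 7 --out subj01/
mstates run manifest.csv --seed 7 --out results/
```

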