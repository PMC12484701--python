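# seegkit

Analysis of intracranial stereo-EEG (SEEG) local field potentials recorded
while a subject views emotionally negative (Neg) versus positive (Pos)
pictures.  The package implements the full analysis chain used in
affective intracranial electrophysiology:

* **Preprocessing** — polyphase downsampling (2048 → 500 Hz), zero-phase
  0.1–195 Hz Butterworth bandpass, 50 Hz powerline notch with harmonics,
  adjacent-contact bipolar re-referencing, epoch segmentation around
  stimulus onsets, and automatic rejection of epochs containing sustained
  (> 250 ms) high-amplitude paroxysmal activity.
* **ERP contrast** — baseline-corrected, baseline-SD–normalized trial
  averages per condition; a per-sample paired *t*-test between Neg and Pos
  (paired across subjects, or across trials within one session); and a
  temporal-consistency rule that only accepts runs of sub-threshold
  *p*-values strictly longer than 30 ms.  Each channel's **divergence
  latency** is the start of its earliest surviving interval.
* **Band power** — Welch spectra (2-s Hann segments, 50 % overlap) per
  trial and lead, normalized band power in delta (0.5–4), theta (4–8),
  alpha (8–13), beta (13–30) and gamma (30–100 Hz) — each band's power
  divided by the total 0.5–100 Hz power, so the five fractions sum to 1 —
  and per-band paired *t* contrasts.
* **Connectivity** — the phase-locking value (PLV) between channel pairs:

  `PLV = | ⟨ exp{ i (φ_a(t) − φ_b(t)) } ⟩ |`

  with instantaneous phases φ from the Hilbert analytic signal of the
  band-limited trace; 0 means a completely random phase relation, 1 perfect
  locking.  Stimulus-window PLV is adjusted by subtracting the pre-stimulus
  baseline-window PLV, and channel-pair values are pooled into region-pair
  (ROI × ROI) matrices.
* **Synthetic sessions** — a generator that emulates the recording paradigm
  (2048 Hz multichannel sessions, 1/f background, 50 Hz line contamination,
  60 interleaved Neg/Pos presentations) and plants ground-truth effects:
  evoked transients at configurable latencies, condition-dependent band
  power scalings, and delta-band phase coupling calibrated to requested PLV
  targets.  It is the test bed for every stage of the pipeline.

The canonical (`headline`) scenario encodes a hierarchical limbic response
cascade: amygdala diverges at 520 ms (Neg up-regulated), anterior cingulate
at 550 ms (Neg down), orbitofrontal cortex at 1050 ms (Neg down) and
hippocampus at 1360 ms (Neg up); gamma power is suppressed under Neg in
Amy/ACC/Hip while OFC is spectrally silent; and delta-band phase locking
between the amygdala and ACC/Hip/OFC is stronger under Neg.

## Worked example

```bash
seegkit run --scenario headline --seed 1 --subjects 5 --out results/demo
```

generates five synthetic subjects, runs the full chain, and prints:

```
seegkit pipeline run — scenario 'headline', seed 1, 5 subjects

Earliest diverging ROI: Amy
Divergence latencies (s): Amy=0.544, ACC=0.576, OFC=1.090, Hip=1.388, MCC=1.760
Significant band contrasts (p<0.05): Amy/delta Neg>Pos (p=0.0105); Amy/beta Neg>Pos (p=0.00679); Amy/gamma Neg<Pos (p=0.000202); ACC/delta Neg>Pos (p=0.0334); ACC/alpha Neg>Pos (p=0.0281); ACC/gamma Neg<Pos (p=0.000195); Hip/delta Neg>Pos (p=0.0125); Hip/beta Neg>Pos (p=0.0092); Hip/gamma Neg<Pos (p=2.47e-07)
Amy-to-others adjusted PLV (delta): Neg=-0.097, Pos=-0.155
```

Reading the output: the recovered divergence ordering reproduces the
planted cascade (amygdala first, then ACC, OFC, hippocampus; at only five
subjects the onsets run 20–30 ms late, and MCC picks up a spurious late
interval at the uncorrected α = 0.05).  Gamma power is significantly lower
under negative pictures in Amy, ACC and Hip — the planted ×0.8
suppression — while the accompanying Neg>Pos shifts in other bands of the
same regions are the mechanical compensation of relative powers that sum
to one.  Delta-band amygdala phase locking is clearly higher under Neg
(−0.097 vs −0.155; both values are negative because the baseline window is
shorter than the stimulus window, which raises the finite-sample baseline
PLV level — the condition difference is the meaningful quantity).  The
same results are written as TSV tables
(`erp_latencies.tsv`, `band_contrasts.tsv`, `plv_region_pairs.tsv`) plus a
JSON manifest that fully determines a bit-exact rerun.

The library surface mirrors the CLI; see `seegkit.pipeline.run_pipeline`,
`seegkit.erp.erp_contrast`, `seegkit.spectral.band_power_table`,
`seegkit.connectivity.condition_plv` and `seegkit.synth.generate_session`.

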