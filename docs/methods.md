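# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package; nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and preprocessing

Recordings are multichannel depth-electrode (SEEG) voltage traces in
microvolts with per-contact metadata (shaft, contact index, optional MNI
coordinate, ROI label) and an event table of stimulus onsets labelled Neg
or Pos.  The conditioning chain is fixed in order:

1. **Downsampling** to 500 Hz by polyphase resampling (2048 → 500 Hz is the
   exact rational ratio 125/512).  The anti-alias FIR is a Kaiser design
   whose stopband starts at the new Nyquist (250 Hz) with ≥ 60 dB
   attenuation; the passband edge sits near 170 Hz.  The transition band
   therefore overlaps 170–250 Hz, far above the 100 Hz ceiling of every
   analysis band, trading a slice of unused bandwidth for firm alias
   protection at ordinary filter lengths.  Event onsets are rescaled and
   rounded to the nearest sample.
2. **Bandpass** 0.1–195 Hz: 4th-order Butterworth applied forward-backward
   (zero net phase, effective 8th order) as second-order sections for
   numerical stability at the 0.1 Hz edge.  Data are reflect-padded by 1 s
   before filtering and trimmed after, suppressing filter transients.
3. **Notch** at 50 Hz and harmonics up to min(195, Nyquist − 5) Hz:
   second-order IIR notches with a fixed 2 Hz −3 dB bandwidth, zero-phase.
   Tones ≥ 3 Hz away pass within 3 dB (single notch, after the
   forward-backward pass ≈ 1 dB); the line tones are suppressed far beyond
   20 dB.
4. **Bipolar montage**: adjacent contacts on each shaft, (lower index) −
   (higher index).  The sign convention is arbitrary in power and PLV but
   must be consistent for the ERP, so one global convention is enforced and
   a session records its montage state (re-application is an error).  A
   pair inherits an ROI only when both parents agree.
5. **Epoching** from 1 s before onset (the fixation-cross baseline) to 6 s
   after; events whose window leaves the recording are dropped and flagged.
6. **Artifact rejection**: clinical review of interictal discharges is
   replaced by an automated surrogate — per channel, amplitudes are
   robust-z-scored (median/MAD over the whole epoch set) and a trial is
   removed when any channel exceeds 6 robust z continuously for strictly
   longer than 250 ms.  The rule is monotone in the threshold and the
   duration gate makes brief sharp transients survivable, as intended.

Filtering is applied to the continuous data before epoching; the
alternative (epoch-wise filtering) differs only through edge handling,
which the reflect padding already addresses.

## ERP contrast

Per trial and channel the baseline-window mean is subtracted and the trace
is divided by the baseline-window SD, putting all leads in baseline-z
units.  Condition means are time-domain trial averages (an FFT plays no
role in averaging).  The Neg-vs-Pos statistic is a per-sample paired
*t*: with several subjects the pairs are per-subject condition means
(group inference); within a single session, trials paired by presentation
index.  Significance requires p < 0.05 **and** membership in a run of
consecutive sub-alpha samples strictly longer than 30 ms — at 500 Hz at
least 16 samples.  No further multiple-comparison correction is applied
across samples or channels; the duration gate is the temporal-consistency
control, and its effect is verified on null simulations (the gated
false-interval rate is strictly below the ungated rate; per-sample p
remains uniform).  A channel's divergence latency is the earliest
surviving interval start, with the sign of (Neg − Pos) over that interval
reported as up-/down-regulation of the negative condition.

With 1/f noise the null *t*-course is smooth, so gated false intervals
still occur at a low per-channel rate; latency estimates on real data
should always be read together with the interval list.

## Band power

Welch spectra use 2-s Hann segments with 50 % overlap over the 0–6 s
stimulus window (five segments), resolving the 0.5 Hz delta edge while
still averaging.  Band fractions are computed per trial and lead as the
trapezoidal band integral divided by the 0.5–100 Hz total (the union of
the five canonical bands), making them amplitude-scale free and summing to
1 by construction; normalization precedes any averaging.  Contrasts are
paired *t*-tests on condition-mean fractions, by default on ROI-pooled
per-subject means, reported per band with direction.

Because the five fractions sum to one, a genuine power change in one band
mechanically shifts the others in the opposite direction (e.g. a gamma
suppression slightly raises the delta/theta/alpha/beta fractions).  This
compensation is a property of relative power, not an artifact, and is
visible in low-noise synthetic data.

## Phase-locking connectivity

Epochs are band-limited (4th-order zero-phase Butterworth per band), the
instantaneous phase is the angle of the Hilbert analytic signal, and the
PLV of a pair is the modulus of the mean complex exponential of the phase
difference.  The default estimator averages over time within each trial
(robust at ~30 trials/condition) and then across trials; an across-trials
estimator (locking across trials at fixed time, averaged over the window)
is provided for larger designs and refuses fewer than 8 trials.  200 ms is
trimmed from each epoch edge before phase extraction; pairs are restricted
to cross-shaft channels to limit volume-conduction remnants surviving the
bipolar montage.

Finite windows inflate PLV above zero under the null: a 0.5–4 Hz signal
in a 2-s window carries only ~10–15 effective phase samples, giving a null
level near 0.35 for 1/f inputs.  The level decreases with window length
and depends on the band's effective bandwidth; consequently the
baseline-adjusted PLV (stimulus minus baseline window) is negatively
biased when the baseline window is shorter, a bias common to both
conditions that cancels in Neg-vs-Pos comparisons.  Region-pair summaries
are means of adjusted values over cross-region channel pairs, with pair
counts reported and empty region pairs flagged as missing rather than
zero.  Low-band edge effects can extend slightly beyond the 200 ms trim;
windows compared against each other should have equal length.

## Synthetic data

The generator's defaults are the study conditions: 12 subjects, 2048 Hz,
one shaft per ROI, 60 trials (30 per condition) with 1 s rest + 1 s
fixation before each 6-s picture and a cyclic 1–6 s inter-trial gap, 1/f
background at 20 µV RMS with a 5 µV 50 Hz line component.  Channel counts
are the desk-scale problem size: 3 contacts per shaft for the four
responsive ROIs (Amy, ACC, OFC, Hip), 2 for the silent ones
(Ins/MCC/PCC/Pcun) — real implantations carry tens of contacts per region,
so between-contact averaging is correspondingly weaker here.

Planted effects:

* **Evoked transients**: truncated Gaussians (SD = duration/4, support
  exactly [latency, latency + duration]) so the condition difference
  begins at the nominal latency, recoverable without onset bias.  The two
  conditions receive opposite half-amplitudes (Neg +A/2, Pos −A/2; polarity
  from the neg_up/neg_down direction), which makes the condition difference
  equal A while keeping evoked *power* identical across conditions — the
  time-domain/spectral dissociation the headline scenario requires (OFC
  diverges in the ERP yet stays spectrally silent).  Amplitude decays as
  1/contact along the shaft so the deflection survives bipolar
  differencing.  The headline amplitude (3 baseline-SD units of condition
  difference at the strongest contact) is a free parameter chosen for
  reliable group-level detection at 12 subjects and documented as such.
* **Band power scalings**: the brick-wall band component of the background
  is multiplied by √scale during Neg stimulation windows (100 ms cosine
  ramps), scaling Neg band power by exactly the requested factor.
* **Delta coupling**: every coupled region receives a shared 1/f-shaped
  band-limited source, injected with alternating sign across contacts (a
  local dipole pattern) together with a per-shaft common-mode compensator;
  coefficients are chosen so band power is preserved at both the contact
  and the bipolar level, with a final per-trial amplitude rescale (phases,
  hence PLV, are untouched) pinning the realized power exactly.  The
  mixing fraction is solved by bisection against a Monte-Carlo estimate of
  the connectivity module's own PLV with a fixed internal seed, so a
  "PLV target" is literally what the pipeline measures.  Targets outside
  the achievable range (null floor to full-sharing ceiling at the given
  window) raise a configuration error reporting that range; the headline
  targets are 0.55 (Neg) vs 0.40 (Pos), placing the prescribed 0.15 margin
  comfortably inside the feasible band.
* **Artifacts**: optional Tukey-windowed 20-z bursts of 300 ms planted in a
  configurable fraction of trials, with the affected trial indices recorded
  in the ground truth for rejection tests.

All randomness derives from one seed through per-subject, per-purpose
child streams; identical (seed, subject) inputs reproduce sessions
bit-exactly.  A fast path (`generate_epochs`) emits analysis-rate epochs
directly — same effect machinery with per-channel semantics, no continuous
plumbing — for calibration studies needing hundreds of replicates.

What the generator does **not** emulate: real evoked waveform morphology
(multi-component ERPs), non-stationary or state-dependent background,
spatially correlated noise across shafts, realistic epileptiform
discharge shapes, or volume conduction.  Passing recovery tests therefore
demonstrates that the estimators recover the planted statistical
structure at realistic sizes, not that real recordings would behave this
way.

## Verification studies and problem sizes

* **Null calibration**: 500 replicates of effect-free epochs (4 channels,
  20 trials/condition, 500 Hz).  Per-sample paired-t p-values are pooled
  for a uniformity KS test at a decimated stride (≈ 1/8 of the window) so
  the pooled values are approximately independent — serial correlation
  inside a 1/f epoch would otherwise invalidate the iid KS reference while
  the marginal distribution is exactly uniform.  The per-band rejection
  rate at α = 0.05 and the gated-vs-ungated false-interval rates come from
  the same run.
* **Headline recovery**: cohorts of 12 subjects at seeds 1–20 through the
  complete pipeline (generation at 2048 Hz onward).  Recorded per seed:
  ROI-pooled divergence latencies and their ordering (tolerance ± 40 ms
  against the planted values), gamma direction and significance in
  Amy/ACC/Hip, OFC spectral silence (all five bands at p ≥ 0.05), and the
  delta-band Amy-to-others adjusted-PLV condition difference.  Note that
  OFC silence requires five simultaneous true-negative tests at an
  uncorrected α = 0.05, so its expected per-seed success is ≈ 0.8 even
  with a perfectly clean generator — an inherent property of the
  uncorrected multi-band testing scheme, mirrored from the analysis it
  validates.

Runtimes are sized for a single CPU: roughly 3 s per synthetic subject
end-to-end, ~12 minutes for the 20-seed recovery study, ~1 minute for the
null calibration.

## Known limitations

* The paroxysm detector is an amplitude heuristic; it will miss
  low-amplitude epileptiform patterns an expert would reject.
* Welch parameters, the normalization denominator (0.5–100 Hz), the
  baseline-SD normalization of ERPs, and subtraction (rather than ratio)
  for PLV baseline adjustment are reasonable conventions, configurable
  where the analysis admits alternatives.
* PLV is undirected and phase-only; no correction for shared reference or
  field spread beyond the bipolar montage and cross-shaft pairing is
  attempted.
* The EDF writer covers plain EDF with integer sampling rates and 1-s
  records — sufficient for interchange and round-trip testing, not a
  general EDF+ implementation.
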