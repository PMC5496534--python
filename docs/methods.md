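# Methods

This note documents the models and procedures implemented in `songnoise`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate about real field
data.

## Level arithmetic

All sound pressure levels are dB re 20 μPa. Internally every operation
works in linear power units (`10^(L/10)`) and converts to dB only at the
boundary, so chained operations do not accumulate log/exp rounding.

* **Leq** (equivalent continuous level) is the energetic mean of the
  samples: `10·log10(mean 10^(L/10))`.
* **Lx exceedance levels** (L90 = level exceeded 90 % of the time) are
  computed as the (100 − x)th percentile of the sample distribution with
  linear interpolation between order statistics — the common numerical
  default; sound-level-meter firmware may use a histogram method, but
  the difference is far below the 0.1-dB export resolution for the
  600+-sample windows used here.
* **SEL** normalises an event's total energy to 1 s:
  `10·log10(Σ 10^(L_t/10)·Δt / 1 s)`, making levels of events with
  different durations comparable.
* **Energy subtraction** removes a background estimate in the power
  domain: `10·log10(10^(total/10) − 10^(noise/10))`. It is declared
  invalid when the total does not exceed the background by a
  signal-to-noise margin, 0.5 dB by default (configurable). Near-zero
  residual energy makes the subtraction numerically explosive, and a
  band that close to the noise floor carries no usable song energy;
  such bands are dropped and reported rather than floored, because
  flooring would bias band sums upward unpredictably.
* **A-weighting** is the standard closed-form response, applied as a
  per-frequency gain at 1/3-octave band centres when combining
  Z-weighted band levels into a broadband A-weighted level. A
  time-domain weighting filter is unnecessary because all
  sound-level-meter inputs are already per-band levels.
* **1/3-octave bands** use the nominal IEC centre labels for identity
  (matching how meter exports name their columns) with base-2 edges
  `centre·2^(±1/6)`.

## Noise metrics

Three per-song noise measures at increasing time scales:

* **instantaneous** — Leq of the broadband A-weighted samples in the
  10 s immediately before song onset (half-open window; samples at or
  after onset never contribute). Field recordings truncate, so the
  window may shrink to 5 s before the song is rejected; a hard 10-s
  requirement would silently drop usable data.
* **bout background** — L90 over the song bout (≥ 10 s), robust to
  transient events such as passing vehicles.
* **territory** — median of per-recording Leq values across a bird's
  recordings (midpoint convention for even counts). The median is taken
  over recordings, not pooled 100-ms samples, because the recording is
  the natural replication unit at this time scale; the pooled-sample
  alternative is available via `pool_samples=True`.

## Song amplitude (source SEL at 1 m)

Per song: (1) band Leq of a 3–15-s song-free noise segment as near the
song as possible; (2) band SEL over the song segment; (3) per band,
subtract the background energy expected over the song window — the noise
Leq scaled by `10·log10(duration/1 s)`, the physically consistent
reconciliation of the two windows' durations; (4) energetic sum over
surviving bands; (5) spherical-spreading correction
`+20·log10(distance/1 m)` to the 1-m reference. The band set defaults to
the seven nominal centres 2 000–8 000 Hz (where the study species sings)
and is configurable. The result is reported as dB(Z) — unweighted within
bands — because only bands the birds use enter the sum. No excess
attenuation beyond spherical spreading is applied (an optional dB/m hook
exists in the renderer's inverse but defaults to zero): recordist
distances are ≤ ~16 m, where atmospheric absorption at these frequencies
is a small fraction of a dB.

The final quantity is a sound exposure level (energy, duration-aware),
not a duration-normalised equivalent level; for the 1.5–2.5-s songs of
this species the two differ by a near-constant ~2–4 dB offset which
cancels in the regression stage.

## Minimum frequency

Spectrograms use a 256-point transform with a Hann window and
non-overlapping frames (at 25 kHz: 97.66-Hz bins, 10.24-ms frames — the
non-overlap is implied by a printed time resolution equal to the window
length). The measurement collapses the spectrogram over time into an
average power spectrum (robust to frame-level dropouts; a per-bin
maximum-envelope variant is one switch away), finds the peak bin at or
above a 500-Hz analysis floor (excluding rumble), and scans upward for
the lowest bin within the threshold (−36 dB, i.e. a power ratio of
10^−3.6) of the peak power. Because the threshold is relative, the
measurement is invariant to gain. With a Hann window a tone's own
mainlobe crosses −36 dB about one bin from its centre, so the
measurement carries an intrinsic ±1-bin (±97.7 Hz) resolution; all
accuracy contracts in the tests are stated at that resolution.

## Mixed-model selection

Candidate linear mixed models of a song trait are enumerated over the
three noise measures — optionally with quadratic terms (quadratic
without linear is allowed, since such models are part of the published
candidate set for this system), pairwise interactions among noise
measures, and a recordist-distance covariate — always including the
intercept-only null. Fits use `statsmodels` `MixedLM` by **maximum
likelihood** (never REML: REML likelihoods are not comparable across
different fixed-effect structures). Ranking uses

    AICc = −2 logL + 2k + 2k(k+1)/(n − k − 1)

with `n` the number of songs and `k` counting every estimated parameter:
fixed effects + random-effect (co)variances + residual variance. Under
this rule the intercept-only model with a by-bird random intercept has
k = 3 and each one-noise-term model k = 4, matching the published
rankings for this system; for that reason the random-intercept structure
is the default for both responses. A by-bird random slope on bout
background (random intercept + slope, unstructured covariance, three
(co)variance parameters) is available via `random="slope"` for the
min-freq set, where bird-specific noise responsiveness is plausible.

Akaike weights are `exp(−Δᵢ/2)` normalised over the candidate set;
evidence ratios are weight ratios against the null (equivalently
`exp(ΔAICc_null/2)` within one set); parameter importance is the total
weight of models containing a term. Non-converged fits and fits with a
boundary (singular) variance estimate are excluded from ranking with a
logged warning rather than silently kept — a boundary fit's likelihood
is not comparable at the stated k.

Residual diagnostics report a residual-vs-fitted trend slope, a
spread-ratio heteroscedasticity index (mean |residual| in the upper vs
lower half of fitted values), and the D'Agostino–Pearson normality
statistic, plus the raw arrays for plotting.

## Synthetic data

The generator produces data at three levels, all deterministic under a
fixed seed.

**Song waveforms** are stylised two-component songs: a whistle at the
target minimum frequency (−12 dB relative to the peak, so its
window-leakage sidelobes stay below the −36 dB criterion) and a louder
30-Hz-AM trill ~1.5 kHz higher carrying the spectral peak. The whistle
is snapped onto the analysis bin grid one bin above the target so the
measured −36 dB edge lands on the grid point nearest the request; the
trill is snapped to the nearest nominal band centre so the renderer's
band filters see it mid-band.

**Noise waveforms** shape white Gaussian noise in the frequency domain
so each 1/3-octave band carries a requested floor level (matched within
1.5 dB, a tolerance absorbing filter-edge leakage), with optional
Hann-enveloped amplitude bursts emulating passing traffic.

**The renderer** inverts the analysis chain: it scales a song to a known
source SEL at 1 m (waveform samples are interpreted as pascals,
SPL = 10·log10(mean x²/(20 μPa)²)), attenuates by 1/distance, mixes into
the noise bed, band-filters with zero-phase 4th-order Butterworth
filters, and integrates 100-ms per-band Leq plus an A-weighted broadband
series — exactly what the field meter would have stored.

**Whole studies** draw per-song amplitude from
`β₀ + β_N·N + β_N²·N² + β_D·D + bird + ε` with the field-estimated
coefficients as defaults (β_N = −1.6 dB/dB, β_N² = 0.022 dB/dB²,
β_D = 0.14 dB/m) over the field-observed ranges (instantaneous noise
30–54 dB(A), distances 2–16 m), and minimum frequency from per-bird
means with zero noise effect by default (the null world for that
response). Unstated scales were fixed once at field-realistic values:
bird-intercept SD 1.5 dB and residual SD 1.5 dB (songs then span roughly
the observed 77–86 dB(Z)), per-bird mean minimum frequency
N(4000, 250²) Hz with 100-Hz within-bird SD, and β₀ = 105 dB. Per-bird
song counts are drawn from the packaged per-male sampling table's
right-skewed distribution (1–16 songs) rather than balanced sampling, to
exercise unbalanced-data behaviour.

What the generator does **not** emulate: real song phonology and
syllable structure, reverberation and atmospheric absorption,
directional birds and microphones, correlated noise between bands, or
meter detector dynamics (Fast time constant). Passing the recovery
suites therefore shows the analysis chain is internally correct and
unbiased under its own assumptions — not that field estimates are free
of the biases those unmodelled effects can introduce.

## Problem sizes in the verification scripts

The acceptance script and the matching tests use 100 audio-rendered
recovery cases (source SEL 70–90 dB, distances 2–16 m, per-band SNR
≥ 10 dB), 200 model-selection replicates at 50 birds × 10 songs, 100
minimum-frequency loop-closure songs, and 200 null-world replicates at
the field design (17 birds, the packaged per-male counts, 77 songs) —
sizes at which the Monte-Carlo error of the reported rates is a few
percent while a full run stays comfortably interactive.

## Known limitations

* The exceedance-level and median conventions may differ in the last
  decimal from specific meter firmware.
* The amplitude chain assumes the song-free noise segment is
  statistically representative of the noise under the song; rapidly
  changing soundscapes violate this.
* Model enumeration caps simultaneous noise measures at two by default;
  three-way additive or interaction structures must be requested
  explicitly.
* `MixedLM` boundary fits (zero bird variance) are excluded from
  ranking; with very few birds this can prune most of a candidate set.
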