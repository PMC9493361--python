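# Methods

This note documents the models, numerical choices, and known limitations of
`neurocpm`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and feature extraction

### EEG amplitude modulation

The EEG-AM representation treats a band-limited signal's instantaneous
amplitude as a signal in its own right. For a carrier band *B* and
modulation band *M*:

1. zero-phase FIR band-pass to *B*;
2. envelope = magnitude of the analytic (Hilbert) signal;
3. zero-phase FIR band-pass of the envelope to *M*.

Band table: δ 0.1–4, θ 4–8, α 8–12, β 12–30, γ 30–50 Hz; modulation bands
m-δ … m-γ share the same edges. The envelope of a band-limited signal
cannot carry modulation beyond limits set by the carrier band (Bedrosian),
so only 14 carrier/modulator pairs are admissible. The set is hard-coded as
an enumeration rather than derived from a bandwidth formula, because the
admissible list is not a simple bandwidth rule (α-m-α is excluded while
β-m-β and γ-m-γ are included). Only β-m-α and γ-m-α are wired into the
default pipeline.

**Filtering.** All FIR filters are Hamming-window designs (~53 dB
stopband), order ≈ 3.3·fs/Δf with transition width Δf = 2 Hz for EEG bands
and 0.02 Hz for the fNIRS band. They are applied as a *centered convolution
with an odd-length symmetric kernel*: the group delay of such a kernel is
exactly (N−1)/2 samples, so centering gives an exactly zero-phase,
single-pass filter — no group delay between channels, and the designed
magnitude response (not its square, as forward–backward filtering would
give). Kernels longer than the record are capped with a logged warning.
The broadband 0.1–100 Hz filter is a 2nd-order Butterworth applied
forward–backward (`sosfiltfilt`), matching its acquisition-side role.

**Edge handling.** The first and last second of every AM series is flagged
as filter/Hilbert transient and excluded from connectivity. Over a 5-minute
record the Pearson estimate is insensitive to this 2 s trim.

### wICA artifact correction

Channels are unmixed with FastICA (all components kept; deterministic
seeded initialization, so the operation is reproducible). Each independent
component is wavelet-decomposed (`sym8`, level = ⌊log₂(fs/4)⌋, capped at
the maximum valid level). Per decomposition level, a robust universal
threshold u = σ·√(2 ln N) is computed with σ from that level's median
absolute deviation — the MAD makes σ insensitive to sparse artifact
outliers within the level. A component is flagged artifactual when any
coefficient exceeds `ic_artifact_threshold` (default 1.6) times its level's
u; in flagged components, coefficients beyond `cleaning_tolerance` (default
1.4) times u are clipped back to that bound. Sub-threshold (neural)
structure is retained everywhere — including neural content leaked into
artifactual components — and the record is rebuilt from all corrected
sources, so output shape equals input shape and no component is discarded.
The two dimensionless knobs are the interface; setting both to infinity
reduces the operation to an ICA round trip. Because the universal threshold
grows with record length, the correction is gentler (more specific) on long
records; the suite validates preservation on the full 5-minute condition.

### fNIRS

Fixed order: band-pass 0.01–0.2 Hz → linear detrend over the whole record
→ modified Beer–Lambert inversion → segmentation. The MBLL solves, per
channel and sample,

    ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR] · d · DPF(λ)

for (ΔHbO, ΔHbR), reported in µM. Defaults: d = 30 mm; DPF = 7.25 at
760 nm and 6.38 at 850 nm (the published pair is bound per wavelength,
following the acquisition-software convention for these wavelengths; both
are configurable). Extinction coefficients are shipped as an explicit 2×2
table (base-10 molar extinction from the standard compiled hemoglobin
spectra, in 1/(mM·cm)):

| λ | ε_HbO | ε_HbR |
|------|-------|-------|
| 760 nm | 0.586 | 1.549 |
| 850 nm | 1.058 | 0.691 |

Results are reproducible bit-for-bit from this configuration. A channel-
inclusion list restricts connectivity to a subset of channels (the
synthetic default generates the 25 analysis channels directly).

## Connectivity, prediction, coupling

Connectivity is the Pearson correlation over the resting block; edges are
the strict upper triangle in row-major order (self-correlations carry no
information). Constant channels raise an error naming the channel.

CPM follows the leave-one-subject-out protocol exactly: per fold, edge-wise
Pearson r and **two-tailed** p against the training performances (both
association signs are biologically admissible); inclusive selection
p ≤ α (default 0.05); one **signed** CSS per modality — the sum of the
selected edge values regardless of correlation sign, *not* the
positive/negative network split some CPM variants use; linear SVR with
C = 1 and ε = 0.1·sd(training performances). CSS features are z-scored with
training-fold statistics before the SVR (flag-reversible): the 300-edge
fNIRS and 28-edge EEG CSS scales differ by an order of magnitude and an
unscaled linear SVR at C = 1 is scale-sensitive. Predictions are raw
regressor outputs (clipping to [0, 100] available as a flag). MAE is the
mean of per-subject absolute errors; its sd is the sample sd (ddof = 1)
across subjects. No multiple-testing correction is applied at edge
selection (selection is internal to the cross-validated model).

Coupling uses edges selected in ≥ 1 fold (union mask with fold
provenance), CSS vectors over *all* subjects, a two-tailed permutation test
with the positively biased estimator p = (1 + #{|r_perm| ≥ |r_obs|})/(1 +
n_perm) (exact under exchangeability, never zero), and Benjamini–Hochberg
FDR over the six pairwise comparisons. 10⁶ permutations is the faithful
default; tests use 10³–10⁵.

## Synthetic cohort generator

The generator defines the study conditions; downstream stages never see
ground truth.

* **Performance** is a clipped-linear transform of a standard normal
  latent: P = clip(70 + 24·z, 0, 100) — bounded in [0, 100]% with a
  realistic central mass near 70% and occasional floor/ceiling subjects.
  The standardized performance variate uses the closed-form moments of the
  clipped normal, so planted correlations are exact in population.
* **Planted edges** (default: three per fNIRS modality, one per EEG
  modality) receive per-subject weights w = c + s·(effect_r·P̃ +
  √(1−effect_r²)·η) with unit-variance η; the linear map preserves the
  edge–performance Pearson correlation at `effect_r`. Default range
  c, s = 0.5, 0.15 (HbR: 0.3, 0.1 — see below). Unplanted edges have latent
  weight 0.
* **EEG**: each channel is a sum of two amplitude-modulated tones — β
  carrier at 21 Hz and γ carrier at 45 Hz, shared across channels with
  random per-channel phases — plus alpha-band background and white noise
  (both scaled by `noise_sd`, default 1). The 8–12 Hz modulators are
  band-passed correlated noise mixed through the Cholesky factor of the
  target matrix; mixing before filtering preserves cross-correlations
  exactly. Modulators are soft-clipped (2.2·tanh(m/2.2)) to keep amplitudes
  positive. Two placement constraints matter: the carrier frequency is
  *common to all channels* in a band, so the band-edge shaping of the AM
  sidebands is identical across channels and the recovered modulators of a
  planted pair stay correlated near the planted weight; and the two
  carriers are placed so that neither tone's sidebands beat against the
  other carrier inside the 8–12 Hz modulation band. With noise off, the
  measured AM correlation of a fully shared modulator exceeds 0.99; at the
  default noise it is attenuated by a factor that is constant across
  subjects and therefore does not bias edge–performance correlations.
* **fNIRS**: slow (0.01–0.2 Hz) unit-variance latents realize the HbO
  targets; HbR_i = −ρ·z_HbO,i + √(1−ρ²)·u_i gives every channel an
  HbO–HbR correlation of −ρ (default ρ = 0.6). The achievable HbR pair
  correlation is then ρ²·R_HbO + (1−ρ²)·R_u, i.e. capped near 1−ρ²; the
  generator solves for R_u, projects it to the nearest positive-definite
  correlation matrix, and records the *achieved* targets in the ground
  truth. HbR weights are planted on a compressed range (0.3 ± 0.1·v) to
  stay inside the cap. Amplitudes: ~1 µM (HbO) and ~0.33 µM (HbR). Output
  is either hemoglobin directly or a forward-MBLL projection to
  two-wavelength optical densities (the default, so the inversion is
  exercised round-trip), plus measurement noise scaled by `noise_sd`.
* **Cross-modality coupling**: `cross_modal_r` (default −0.5) loads a
  shared subject-level latent into the residuals of the HbO and γ-m-α edge
  weights with opposite signs, so the HbO/γ-m-α coupling in CSS space is
  negative — the direction observed for oxyhemoglobin vs EEG-gamma-AM
  connectivity. The pairwise weight correlation is effect_r² +
  (1−effect_r²)·cross_modal_r: coupling is visible when the performance
  effect does not dominate.
* **Artifacts** (off by default): ocular-like slow raised-cosine transients
  with a frontal-dominant cross-channel projection, and brief
  high-amplitude spikes — used to test wICA.
* `sample_cohort_table` draws measured connectivity matrices directly from
  the latent targets (sample correlation of `t_eff` multivariate-normal
  draws, default 150), i.e. the same ground truth observed through
  finite-sample estimation noise. Replicate-heavy calibration studies (100
  null cohorts, effect-size sweeps) use this sampler; single-seed
  end-to-end checks and the acceptance script use full waveform synthesis.

What the generator does **not** emulate: 1/f background spectra,
nonstationarity, volume conduction between EEG channels, systemic
physiology (cardiac/respiratory/Mayer waves) in fNIRS, optode geometry, or
real artifact morphology. Passing tests therefore demonstrate correctness
of the pipeline's mechanics and calibration of its inference under the
stated generative model — not performance on real recordings.

## Reproducibility and problem sizes

All randomness flows from named seeds (cohort seed, wICA ICA seed,
permutation seed); identical configuration and seeds give byte-identical
outputs, and each run writes its resolved configuration, a manifest with a
config hash, and per-stage timings. The packaged study sizes are chosen at
desk scale: the acceptance run uses the full default cohort (31 subjects ×
5 min); structural smoke tests use 5 subjects × 60 s; replicate suites use
the table sampler at n = 30–60 with 100 replicates. Determinism of the
permutation test is per (seed, n_perm).

## Known limitations

* The wICA thresholds (1.4/1.6) are dimensionless multiples of each
  level's universal threshold; other wICA implementations scale their
  thresholds differently, so numerical equivalence with any particular
  toolbox is not claimed.
* The MBLL ships one extinction table; studies using different compiled
  spectra will obtain proportionally different concentration scales (the
  connectivity and CPM stages are invariant to per-channel positive
  scaling).
* Whether EEG-AM series should be downsampled before correlation is an
  open choice; this implementation correlates at native rate.
* The permutation test permutes one vector only — valid for the
  exchangeable null of no association, not for time-series dependence
  (CSS values are one-per-subject scalars, so exchangeability holds).
* LOSO with edge selection inside the fold is leakage-free (audited
  bit-identically in the suite) but its MAE estimate has the usual high
  variance of leave-one-out schemes.
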