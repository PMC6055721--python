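# Methods

## The model

Each cardiac site *i* is assigned a stylized action potential built as the
product of two logistic functions — one for excitation, one for recovery:

    AP_i(t) = A · σ(β_AT (t − τ_AT,i)) · [1 − σ(β_RT (t − τ_RT,i))] − V_rest

`τ_AT,i` and `τ_RT,i` (ms from the pacing stimulus) are the local activation
and repolarization times and coincide with the AP's steepest upslope and
downslope. `β_AT` and `β_RT` (1/ms) set those slopes and are
position-independent, so all APs share one shape and differ only in timing.
The unipolar electrogram is the inverted, rescaled difference between the
local AP and the *remote component*, the plain average of all M APs:

    UEG_i(t) = −α (AP_i(t) − mean_j AP_j(t)),   α = g_i/(g_i + g_e)

with α fixed at 0.25 (conductivity balance, assumed homogeneous and
isotropic). Direct consequences, all tested: the UEGs sum to zero across
sites at every sample; uniform timing yields identically zero UEGs; with two
sites the UEGs are antisymmetric; sites activating before/after the bulk
show QS/R-wave complexes and sites repolarizing before/after show
positive/negative T-waves, so the signed QRS area rises with AT and the
signed T-wave area falls with RT.

Amplitude parameters default to A = 100 mV and V_rest = 80 mV (rest ≈ −80 mV,
plateau ≈ +20 mV). No published value is implied: every correlation,
polarity, and marker statistic the package reports is invariant to the
voltage scale, which the test suite asserts; the defaults only make plotted
traces physiologically familiar.

## Markers

AT is the time of the minimum first derivative within the QRS window; RT is
the time of the maximum first derivative within the T-wave window regardless
of T-wave polarity (the Wyatt convention); ARI = RT − AT. Derivatives use
central differences (one-sided at the ends) on the native 1 kHz grid; ties
take the earliest sample; no smoothing is applied by default so that
detection is exact on clean simulated signals. Detection is invariant to
per-trace gain and offset.

Window policy: the analysis windows are not part of the model, so two
policies are provided. With priors (synthetic ground truth or previously
measured maps), QRS = [min AT − 10, max AT + 30] ms and T-wave from
max(QRS end, min RT − 30) to 20 ms before the beat end. Blind, the split
point is the minimum of the spatial-mean absolute derivative between the two
activity bursts (QRS and T-wave) of the averaged beat, excluding the first
10 ms (pacing artifact) and last 20 ms; the chosen windows are logged.

### Accuracy of marker recovery, and what "round trip" means

The derivative markers on a simulated UEG equal the generating τ only where
the remote component changes much more slowly than the local AP. For the QRS
this holds easily (local peak slope A·β_AT/4 ≈ 10 mV/ms versus a remote
slope of ~1 mV/ms), and AT is recovered to the sample. For the T-wave it
does **not** hold under physiologic conditions: with repolarization
dispersion of 50–70 ms and β_RT = 0.035/ms the remote T-downslope is
comparable to the local one, and the detected RT is systematically stretched
away from the mean RT — up to ±20 ms at the dispersion extremes, with the
signed median near 0 and rank order preserved (cc ≥ 0.94 against the
generating field). This is a property of the model-plus-convention, not a
detection bug; the package therefore validates markers the way the original
sock-mapping comparison does: markers *measured* from electrograms are the
model's input, and markers re-measured from the resulting simulation are
compared against that input. That comparison is a near-fixed point: median
ΔAT = 0 ± 0 with correlation 1, median ΔRT within ±1 ms with correlation
≈ 0.999, across seeds and cycle lengths. Marker recovery against generating
truth is asserted only per-site where the slow-remote condition (<10% slope
ratio inside the window) is verified to hold.

## Quality control

Beats are cut stimulus-aligned to one cycle length; the first 5 beats of
each drive train are discarded to approximate steady state. Two per-site
criteria follow, with no cross-site leakage:

- **stability** — mean Pearson correlation between each beat and the
  per-sample median beat, threshold 0.98 (zero-variance beats count as 0 and
  are logged);
- **spectral SNR** — Welch PSD (Hann, 1 s segments, 50% overlap) of the
  signal-averaged beat; band powers are trapezoidal integrals over 1–40 Hz
  (signal) and 40–100 Hz (noise); threshold 10 dB. White noise gives
  10·log10(39/60) ≈ −1.9 dB, the band-width ratio, which the tests confirm
  by Monte Carlo. SNR is computed after averaging (a config flag moves it to
  the median beat instead).

Signal averaging is the per-sample mean of the retained beats; residual iid
noise falls as 1/√n.

## Steepness grid search

`{β_AT, β_RT}` is selected from {0.2, 0.4, 0.6} × {0.025, 0.035, 0.045,
0.055} ms⁻¹ by maximizing the median Pearson correlation between recorded
and simulated electrograms over the whole beat (the first 10 ms after the
stimulus are excluded everywhere, because paced recordings carry an artifact
the model does not produce). α stays 0.25. Ties break toward the smaller
β_AT, then the smaller β_RT; the search is a pure function of its inputs.
The search objective deliberately uses the whole-beat correlation, not the
QRS or T-wave sub-scores. When a noise-free recording is generated by the
model itself the search returns the generating pair with median correlation
1 exactly; under 5%-of-QRS-amplitude additive noise it still recovers the
generating pair (tested by majority vote over 10 seeds).

## Synthetic sock datasets

The generator emulates a paced epicardial-sock acquisition; its defaults are
the study conditions every test and the acceptance script run under.

- **Geometry**: 240 electrodes on a basally truncated ellipsoid (semi-axes
  35 × 35 × 55 mm, cut at 0.45·c) laid out on a Fibonacci spiral with 0.5 mm
  seeded jitter. Distances are Euclidean between surface points, not true
  geodesics — adequate for smooth monotone activation fields, and a
  documented simplification.
- **Timing fields**: τ_AT = 20 ms + distance from the pacing electrode
  (default: the apex-most site) / 1.0 mm·ms⁻¹, plus a spatially correlated
  noise field (sd 3 ms, correlation length 15 mm); APD = (120 + 0.22·CL) ms
  with a −30 ms apex-to-base gradient plus the same kind of field noise;
  τ_RT = τ_AT + APD. Defaults give an AT range of ~60–120 ms and an RT
  dispersion of ~40–100 ms over seeds, checked by test. Configurations whose
  τ_RT reaches the cycle length are rejected.
- **Pseudo-recordings**: each beat is a UEG from the same logistic-AP family
  but with per-site lognormally perturbed β values (fraction 0.15) and
  per-beat timing jitter (sd 0.5 ms — stimulus-locked pacing is highly
  stable), plus band-limited Gaussian noise (sd 0.3 mV, low-passed at
  100 Hz), 0.3 Hz baseline wander (1 mV), and a 2 ms biphasic pacing
  artifact (8 mV). The per-site shape perturbation is what makes "recorded"
  differ from "simulated", as real tissue does, while zeroing all nuisances
  collapses the generator onto the model exactly (tested). 8 channels are
  corrupted by construction: half alternate between two morphologies every
  other beat (violating the 0.98 stability criterion), half carry a strong
  stimulus-locked 60 Hz component (passing stability but violating the 10 dB
  SNR criterion).

What the generator does *not* emulate: ionic AP dynamics, anisotropic or
heterogeneous conduction, scar, far-field atrial activity, electrode motion,
or real contact-noise statistics. Passing tests therefore demonstrate the
internal consistency of the model and pipeline under controlled conditions,
not clinical performance. In particular the per-site β_RT perturbation makes
the synthetic "recorded" T-wave areas noisier than human data, so
recorded-side T-area correlations are weaker than their in-vivo analogues;
the model-side quantities are unaffected.

## Pipeline and determinism

The validation run per cycle length: generate/load → segment → QC → average
→ detect markers (blind windows by default) → grid-search β → simulate UEGs
from the measured markers → re-measure markers on the simulation →
morphology statistics → summary table (one column per cycle length, rows for
site counts, ΔAT/ΔRT/ΔARI median ± MAD, marker correlations, whole/QRS/T
morphology correlations, area cross-correlations, and the timing–area
correlations for both the recorded and the model side). Every random choice
derives from a single run seed (per-cycle-length sub-seeds via a seed
sequence), and all later stages are deterministic, so reruns are
byte-identical; each output directory carries a run log with the config and
its hash. A stage that leaves zero usable sites aborts with a stage-named
error (CLI exit code 3; config errors exit 2).

Problem sizes: tests use reduced socks (typically 60 sites × 10 beats) for
unit-level checks and the full 240-site sock for the headline statistics;
the acceptance script runs eight full 240-site analyses (one per cycle
length plus two extra fields) in a few seconds.

## Statistics conventions

Pearson correlation throughout; undefined (zero-variance) correlations are
reported as NaN and flagged rather than silently dropped. Distributions are
summarized by median, MAD = median(|X − median X|), linearly interpolated
("type 7") quartiles, and Tukey fences Q1 − 1.5·IQR / Q3 + 1.5·IQR. MAD is
implemented with the absolute value (dispersions are nonnegative). Signed
window areas are trapezoidal integrals of the baseline-corrected voltage;
the baseline is the median of the 20 ms preceding the stimulus when
pre-stimulus samples exist, otherwise the first sample of the beat.
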