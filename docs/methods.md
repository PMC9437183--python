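# Methods

## Model overview

The package couples three components:

1. **stimulus synthesis** — acoustic CI-simulating stimuli (SAM tones,
   transposed tones, Gaussian-envelope tone trains, band-pass filtered click
   trains) and electric biphasic pulse trains;
2. **periphery models** — a stochastic single-fiber model of the
   electrically stimulated auditory nerve, and a simplified acoustic
   periphery behind a pluggable interface;
3. **the EI neuron** — a deterministic coincidence-counting binaural neuron
   with rectangular excitatory/inhibitory windows.

All randomness lives in the periphery; the EI stage is fully deterministic,
so across-repetition variance reflects periphery noise only. Interaural
time differences are imposed on the contralateral *spike trains* (positive
ITD/IPD = contralateral-leading, implemented as an earlier shift), which is
equivalent to delaying the stimulus for a time-invariant periphery and far
cheaper.

## EI neuron

At each pooled excitatory spike time `t` (simultaneous spikes are one
evaluation) the neuron computes
`C(t) = N_exc(t − w_exc, t] − g · N_inh(t − w_inh, t]` and fires when
`C(t) ≥ θ`, with an absolute refractory period `t_ref` and no partial
recovery. Defaults: `w_exc = 1.1 ms`, `w_inh = 3.1 ms`, `θ = 3`, `g = 2`,
`t_ref = 1.6 ms`, 20 excitatory / 8 inhibitory inputs.

Numerical conventions:

* windows are trailing (causal) and half-open `(t − W, t]`: a spike counts
  toward its own evaluation, a spike exactly at `t − W` does not;
* an interval of exactly `t_ref` between output spikes is allowed;
* both boundaries carry a 1-ps guard against float roundoff so that the
  event-driven implementation and the 1-µs integer-grid oracle
  (`ei_oracle`, test-only) agree spike-for-spike on grid-aligned inputs.

Two structural consequences follow directly. Because `w_inh > w_exc`, the
minimum of the rate-ITD function is not at 0 but near the ITD that centres
the excitation inside the inhibition; the trough's width is governed by
`w_inh − w_exc`. And because a spike volley preceding the inhibition by
more than `t_ref` can trigger a second output within the same modulation
cycle, high-level rate-ITD functions develop plateaus at the modulation
frequency and at twice the modulation frequency.

`apply_itd` accepts shifts up to ±20 ms: the ±4 ms ITD grids, and full IPD
cycles (`±π`) down to a 25 s⁻¹ rate, both need to be representable.

## Electric periphery

Per pulse, the membrane voltage at the end of the first (cathodic) phase is
`u = I · gain · (1 − exp(−τ_phase/τ_m))`; a fresh zero-mean Gaussian noise
draw (sd = `relative_spread · v_threshold`) is added, and the fiber fires if
`u + noise ≥ v_threshold · R(Δt)`, where `Δt` is the time since the last
action potential and `R(Δt) = 1/(1 − exp(−(Δt − t_abs)/τ_rel))` (infinite
within the absolute refractory time `t_abs`). A firing pulse emits its
spike at `pulse onset + discharge time + latency + jitter`. There is no
adaptation and every fiber shares the same threshold.

Defaults: `τ_m = 100 µs`, `t_abs = 0.7 ms`, `τ_rel = 1.32 ms`, latency
`0.685 ± 0.1 ms`, jitter sd `0.12 ms`, discharge time `10 µs`; these follow
the feline single-fiber literature on electric stimulation.

**Relative spread and gain.** `relative_spread = 0.30` and
`gain = 2.99 × 10⁻³ µA⁻¹` were fixed together, once, by two constraints:
(i) the behavioural reference procedure (below) must land at ≈240 µA for
the 40-pps standard, and (ii) the single-fiber rate-level function must
flatten near 10 dB above that reference, as electric rate-level functions
do — which pins the width of the single-pulse firing-probability curve.
A relative spread of ~0.06, as sometimes quoted for single cat fibers,
makes the fiber go from threshold to complete entrainment within ~1.5 dB;
every fiber would then entrain at 5 dB re threshold, the EI count would
always be `20 − 2·8 = +4`, and the trough-type tuning observed at
intermediate levels could not exist. The larger spread is interpreted as
the per-pulse response variability of the modelled fiber population rather
than a literal single-node property.

**Reference thresholds (dB-thr scale).** `find_reference_threshold`
bisects the pulse current (1-µA resolution, ≥10 repetitions averaged, the
same repetition seeds reused at every probed current so the rate-current
function is monotone during the search) until the EI neuron driven only by
its 20 ipsilateral fibers first fires ≥1 sp/s. The 40-pps unmodulated
standard yields ≈240 µA. The reference for SAM pulse trains is *derived*
with the same fiber parameters from the 40-Hz SAM 1000-pps standard and
comes out at ≈165-180 µA — lower than the unmodulated reference, as
expected from the larger number of near-peak pulses per train, though not
as low as 130 µA; with per-pulse independent threshold noise, firing at
half the deterministic threshold voltage has vanishing probability, so a
two-fold threshold reduction cannot emerge from this model class. All SAM
levels are stated re the derived reference, which keeps every condition
self-consistent (tuning-curve shapes depend on level re own threshold).

## Acoustic periphery (stand-in)

The full biophysical periphery is intentionally not re-implemented; the
module presents a narrow interface (stimulus in → spike ensemble out) so a
published model can be dropped in. The default chain per fiber:

1. 4th-order gammatone at CF (FIR from the closed-form impulse response;
   bandwidth `24.7(4.37·CF/1000 + 1)` Hz, the standard ERB scale);
2. half-wave rectification + first-order low-pass at **400 Hz** (IHC /
   synapse stage). The cutoff removes carrier fine structure and, equally
   important, sets the decay rate of the drive after a transient: ~22
   dB/ms, which stretches a high-level click response into a
   multi-millisecond burst, as strong click responses in detailed AN models
   are;
3. logistic rate map on the drive in dB: `rate = spont + (rate_max −
   spont)/(1 + e^{−s(L − L₀)})` with `rate_max = 1000 sp/s`, `L₀ = 19.5 dB`,
   `s = 0.7 dB⁻¹`. `rate_max` is the *onset* (instantaneous) ceiling, of
   the order of the inverse dead time — not a sustained rate;
4. divisive feed-forward adaptation `rate/(1 + 3·LP₆₀ₘₛ(rate)/rate_max)`,
   which compresses sustained responses to physiological values (a 30-dB
   SAM tone yields ~180 sp/s sustained) while preserving onsets;
5. inhomogeneous Poisson sampling at 20 kHz with a 0.75-ms dead time;
   spontaneous rate 5 sp/s (medium-spontaneous-rate class).

The deterministic stages are computed once per stimulus and shared across
fibers and repetitions; only the Poisson draws differ.

The operating point was chosen once against four qualitative anchors and
then frozen: silence reproduces the spontaneous rate; SAM tones at
4 kHz/128 Hz/30 dB SPL yield envelope vector strength ≈ 0.5 with spikes
confined to half the modulation cycle; filtered clicks and GE tones
phase-lock better than SAM tones (mirroring their higher AC/DC ratios); and
the EI neuron's peak response to SAM tones occurs near 30 dB SPL, with
shallower tuning above. High-level click trains then evoke ~3-ms bursts,
which produce the plateau hierarchy (rate = f_m, then 2·f_m) in rate-ITD
functions at 70 dB SPL.

**What the stand-in does not model:** level-dependent filter broadening and
compression, two-tone suppression, power-law adaptation, high/low-spont
fiber classes, refractory interactions beyond a fixed dead time, and any
tonotopic array. Tests passing with this stand-in demonstrate that the EI
stage reproduces the electric-acoustic correspondence given *envelope-coding
spike input*; they do not validate the stand-in as a general periphery
model, and exact acoustic spike rates are not reproduction targets.

## Stimuli

* Acoustic stimuli: 1 s duration, 10-ms sin² gating; level = steady-state
  RMS re 20 µPa. Sample rate 100 kHz (200 kHz for clicks so the 10-µs
  click spans ≥2 samples). All carriers start at phase 0; the GE carrier
  is phase-locked to each pulse centre.
* Transposed tones: modulator = half-wave-rectified `sin(2π f_m t)`,
  low-passed by a zero-phase 4th-order Butterworth at 2 kHz, peak-normalised.
* GE trains: Gaussian σ chosen so the amplitude-convention equivalent
  rectangular bandwidth equals the Greenwood 1.5-mm span at the carrier
  place (`ERB·ERD = 1` for a Gaussian; at 8 kHz: ERB ≈ 1695 Hz,
  ERD ≈ 0.59 ms). Human map constants `A = 165.4 Hz`, `a = 0.06 mm⁻¹`,
  `k = 1`, 35 mm. Adjacent-pulse overlap above −40 dB logs a warning.
* Filtered clicks: 10-µs condensation clicks through a 2nd-order Butterworth
  band-pass (scipy order 2) with constant-Q corners
  `f_lo·f_hi = f_c²`, `f_hi − f_lo = f_c/Q`, `Q = 0.5`.
* Electric trains: 600 ms, 100-µs phases; sin² gating multiplies the pulse
  *amplitudes* (the pulse shape is not windowed); SAM envelope
  `[1 − cos(2π f_m t)]/2` sampled at pulse times; `f_m ≤ 0.4·rate`.

## Analysis protocols

* Analysis windows: acoustic 0.2-1.0 s (onset discarded); electric
  0.01-0.6 s (gating ramp excluded).
* Vector strength `|N⁻¹ Σ e^{iφ_k}|`; period histogram with 50 bins.
* `√r_max − √r_min` on the mean tuning curve (a Poisson-motivated best-case
  discrimination contrast); `R²` = squared Pearson correlation of two
  *mean* curves (undefined for constant curves).
* **Trough span:** contiguous ITD span around the worst point with mean
  rate below 20 % of the curve maximum. Note an intrinsic limitation of
  per-pulse binomial input statistics: with independent fiber responses at
  probability p, the trough-to-peak firing ratio
  `P(E − 2I ≥ 3)/P(E ≥ 3)` (E ~ B(20, p), I ~ B(8, p)) has a floor of
  ≈ 0.33 over all p, so unmodulated electric troughs at 5 dB re threshold
  are pronounced but never fall below ~20 % of maximum; the trough's
  *half-depth* width (~2.3 ms at 50 pps) reflects `w_inh − w_exc` as
  expected.
* **Second-plateau offset:** worst ITD minus the nearest ITD whose mean
  rate attains the 2·f_m plateau. Because the per-cycle double-spike
  probability saturates just below 1 and repetitions are stochastic, the
  plateau is considered attained at 95 % of its nominal level; with a
  strict threshold the crossing point is repetition-noise dominated.
  Measured at 100-pps clicks, 70 dB SPL: ≈ 2.8-3.0 ms.
* **Rate limit (operational cutoff):** the first tested rate above the
  contrast peak whose `√r_max − √r_min` falls below 50 % of the maximum
  over the rate list. The *highest surviving* rate is deliberately not
  used: rectangular windows make the contrast collapse where the period
  ≈ `w_inh` (at 320/250/500 s⁻¹ for `w_inh` = 3.1/4.1/2.1 ms — tracking
  `1/w_inh`) but then partially revive at higher rates, where the sharp
  window edge re-samples the pulse grid without restoring ordinary tuning.
  The contrast also declines toward very low rates at low levels; that
  branch is not the limit either.

## Reproducibility and problem sizes

Every stochastic element is seeded; populations derive per-fiber seeds from
the master seed by `numpy` `SeedSequence` spawning, repetitions by the same
rule, so any single condition can be re-run in isolation bit-identically.
Default repetition counts follow the experimental protocols: 10 for
acoustic rate-ITD functions, 20 for electric and cross-modal comparisons.
The sweep runner writes per-condition tuning-curve CSVs, a metrics table
and a provenance JSON (config, seeds, version). The rate-limit property
test sweeps 9 rates × 3 inhibitory windows at 10 repetitions, which keeps
the full test suite under a minute on one core.

## Known limitations

* The trough-depth floor and the SAM-reference discrepancy discussed above
  are intrinsic to per-pulse-independent threshold noise.
* No synaptic delay separates the excitatory and inhibitory pathways; both
  share the periphery latency. Trough positions would shift by any such
  delay.
* The rectangular windows make high-rate behaviour (revivals) sharper than
  smooth post-synaptic kernels would; conclusions near the rate limit
  should lean on the collapse location, not on the fine structure above it.
* The acoustic stand-in targets qualitative envelope-coding fidelity only.
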