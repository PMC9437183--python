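# eisim

Single-neuron simulation of binaural interaural-time-difference (ITD)
sensitivity under **electric** (cochlear-implant pulse-train) and
**amplitude-modulated acoustic** stimulation.

Bilateral cochlear-implant users lose ITD sensitivity above roughly 300-500
pulses per second — strikingly similar to the *envelope* ITD limit of
normal-hearing listeners. This package implements the hypothesis that a
single excitatory-inhibitory (EI, LSO-type) brainstem neuron accounts for
both: the same deterministic coincidence-counting neuron is driven either by
a stochastic model of the electrically stimulated auditory nerve or by a
simplified acoustic periphery, and its rate-ITD/IPD tuning is analysed with
standard spike-train metrics.

## The model

**EI neuron.** At every pooled excitatory (ipsilateral) spike time *t* the
neuron forms the signed count

```
C(t) = |{ exc spikes in (t − w_exc, t] }| − g · |{ inh spikes in (t − w_inh, t] }|
```

and emits a spike when `C(t) ≥ θ`, subject to an absolute refractory period
`t_ref`. Defaults: `w_exc = 1.1 ms`, `w_inh = 3.1 ms`, `θ = 3`, inhibitory
gain `g = 2`, `t_ref = 1.6 ms`, with 20 excitatory and 8 inhibitory
auditory-nerve (AN) fiber inputs. Because `w_inh > w_exc`, the worst
(minimum-rate) ITD is *not* at zero but where excitation sits centred in the
longer inhibition; because the inhibitory window smears over a full cycle
once the stimulation period falls below `w_inh`, the rate limit of ITD
sensitivity is approximately `1/w_inh ≈ 323 s⁻¹` at the default window.

**Electric periphery.** A four-stage stochastic AN fiber: leaky
integrate-and-fire membrane charged by the first pulse phase
(`u = I·gain·(1 − e^(−τ_phase/τ_m))`), zero-mean Gaussian membrane noise,
exponential relative refractoriness on top of an absolute dead time, and
latency + jitter on the emitted spike. Stimuli are biphasic pulse trains
(100-µs phases), unmodulated (25-800 pps) or sinusoidally amplitude
modulated (`[1 − cos 2π f_m t]/2` envelope on 1000/5000-pps carriers), with
levels in dB re a behavioural reference current found by bisection (the
current at which the ipsilaterally driven EI neuron first exceeds 1 sp/s).

**Acoustic periphery.** A deliberately simple, pluggable stand-in (gammatone
→ rectify + low-pass → saturating rate nonlinearity → adaptation →
inhomogeneous Poisson with dead time) for medium-spontaneous-rate AN
fibers. Four CI-simulating stimulus classes are synthesised: SAM tones
`sin(2π f_c t)(1 − cos 2π f_m t)`, transposed tones, Gaussian-envelope (GE)
tone trains whose bandwidth equals a 1.5-mm cochlear span on the Greenwood
map, and 10-µs click trains band-pass filtered at constant Q = 0.5.

**Analysis.** Vector strength `vs = |Σ e^{iφ_k}| / N`, PSTH and period
histograms, rate-ITD/IPD tuning curves over `[−4, 4] ms` or `[−π, π]`, the
best-worst contrast `√r_max − √r_min`, and the squared Pearson correlation
`R²` between tuning curves.

## Worked example

```python
import numpy as np
from eisim import (EIParams, ei_count, simulate_ei, find_reference_threshold)
from eisim.experiments import make_fixture_spikes, rate_curve, trough_span
from eisim.analysis import sqrt_contrast

# 20 coincident excitatory and 8 double-weighted inhibitory inputs: +4 >= 3
exc, inh = make_fixture_spikes("full_volley")
ei = EIParams()
t = exc.pooled()[-1]
print("net count at volley:", ei_count(t, exc.pooled(), inh.pooled(), ei))
print("EI output spikes:", len(simulate_ei(exc, inh, ei)))

# behavioural reference current for the dB-thr scale (40-pps standard)
print(f"reference threshold: {find_reference_threshold('unmodulated', seed=1):.0f} uA")

# rate-ITD tuning of a 100-pps train at 5 dB re threshold
grid = np.round(np.arange(-4, 4.001, 0.2), 3)
curve = rate_curve("electric", "itd", grid, f_m=100.0, carrier_rate=100.0,
                   level=5.0, n_reps=10, seed=1)
m = curve.mean_rate
print(f"peak rate {m.max():.1f} sp/s, trough {m.min():.1f} sp/s "
      f"at ITD {curve.grid[np.argmin(m)]:+.1f} ms")
print(f"sqrt-contrast {sqrt_contrast(curve):.2f}")
```

prints

```
net count at volley: 4.0
EI output spikes: 1
reference threshold: 241 uA
peak rate 92.7 sp/s, trough 35.4 sp/s at ITD +0.6 ms
sqrt-contrast 3.68
```

The net coincidence count of +4 just surpasses the threshold of 3, so even
full inhibition cannot silence a fully entrained input — which is why ITD
tuning flattens at high stimulation levels. The trough sits at a positive
(contralateral-leading) ITD because the inhibitory window outlasts the
excitatory one.

A command-line interface mirrors the library
(`eisim stimgen | simulate | tune | sweep | metrics`); sweeps are driven by
YAML configs, e.g.

```yaml
experiment:
  pathway: electric
  rates: [25, 50, 100, 200, 250, 320, 400, 500, 800]
  levels: [5.0]
  axis: ipd
  n_reps: 20
  w_inh_list: [0.0021, 0.0031, 0.0041]
```

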