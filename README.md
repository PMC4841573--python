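# modgate

Modularity-gated activity propagation in clustered neuronal networks:
a simulator of two coupled clusters of Morris–Lecar neurons with
depressing/facilitating (Tsodyks–Markram-type) synapses, together with
the multielectrode-array (MEA) analysis pipeline used to characterize
network bursts and their propagation.

## The scientific problem

Cultured neuronal networks grown as grids of dense clusters joined by
sparse bridges fire in *network bursts* (NBs): brief epochs of
synchronized population firing.  Whether a burst in one cluster recruits
its neighbor depends on the burst's intensity, on the sparseness of the
bridge, and on inhibition — blocking inhibition can fling the gate open.
`modgate` is for computational and systems neuroscientists who want to
(a) simulate this gating and sweep the network *modularity*
λ — the probability with which intra-cluster synapses are replaced by
inter-cluster ones, so ⟨N_inter⟩/⟨N_intra⟩ = λ/(1 − λ) — and
(b) run the complete burst-analysis stack on recorded or synthetic
multichannel data.

The model: each neuron obeys

    C_m V̇ = I_ext − g_Ca·M_ss(V)(V − V_Ca) − g_K·W(V − V_K) − g_L(V − V_L)
    Ẇ     = φ (W_ss(V) − W) cosh((V − V3)/(2 V4))

driven by i.i.d. Gaussian noise current (µ = 7.55, σ = 4 µA/cm², fresh
every 0.1 ms step), coupled through synapses whose resources cycle
through recovered/active/inactive pools with a tangent-saturated
recovery rate and, for inhibitory synapses, facilitating utilization.
The analysis stack: activity intensity (rectified mean voltage minus a
kurtosis-gated noise threshold), the W/T/G burst-detection cascade,
cross-covariance delays, baseline-corrected transfer probabilities,
long-term directional asymmetry, activation-pattern entropy
E = −Σ Pᵢ log Pᵢ, burst-similarity clustering, the bimodality
coefficient, and propagation vectors.  See `docs/methods.md` for every
equation, parameter and convention.

## Worked example

Generate a surrogate recording of a cluster pair in which cluster 0
initiates bursts that propagate to cluster 1 with a 30 ms hop delay
(80% of bursts; the rest stay local to cluster 1), then run the
analysis:

```python
import numpy as np
from modgate import (compute_ai, make_schedule, preset_geometry,
                     render_voltage, detect_bursts_channel,
                     BurstDetectionParams, burst_delay, longterm_asymmetry)

geom = preset_geometry("pair")
patterns = [(0, (0, 1)), (1, (1,))]
schedule = make_schedule(geom, patterns, [0.8, 0.2],
                         hop_delay_mean=30.0, duration_ms=120_000.0, seed=11)
rec = render_voltage(schedule, seed=12)          # 10 kHz voltage + noise
ai = compute_ai(rec)                             # activity intensity
print(f"noise thresholds (uV): {np.round(ai.nt, 2)}")

params = BurstDetectionParams.experiment_channel()
bursts = [detect_bursts_channel(ai.ai[c], ai.bin_ms, params, counts=False,
                                active_floor=ai.floor()[c]) for c in (0, 1)]
print(f"bursts detected: cluster 0 -> {len(bursts[0])}, cluster 1 -> {len(bursts[1])}")

lags = []
for b in bursts[0]:
    lo = max(0, int((b.start - 500) / ai.bin_ms))
    hi = min(ai.ai.shape[1], int((b.end + 500) / ai.bin_ms))
    lags.append(burst_delay(ai.ai[0, lo:hi], ai.ai[1, lo:hi], ai.bin_ms).lag_ms)
print(f"mean inter-cluster delay: {np.mean(lags):.1f} ms")
print(f"long-term asymmetry (0 vs 1): {longterm_asymmetry(ai.ai[0], ai.ai[1], ai.bin_ms):.3f}")
```

Output:

```
noise thresholds (uV): [4.05 4.07]
bursts detected: cluster 0 -> 17, cluster 1 -> 21
mean inter-cluster delay: 29.3 ms
long-term asymmetry (0 vs 1): 0.367
```

The noise thresholds sit at the half-normal mean of the 5 µV rendering
noise (5·√(2/π) ≈ 3.99 µV); every scheduled burst is recovered; the
mean cross-covariance delay matches the scheduled 30 ms hop; and the
positive asymmetry says cluster 0 tends to lead — exactly the
ground truth the schedule encodes.

On the model side, a modularity sweep of the two-cluster network
(low inhibitory strength, proportional wiring, 60 s per run, two
network realizations per λ):

```python
from modgate.sweep import sweep_modularity, aggregate_sweep
df = sweep_modularity([0, 0.02, 0.05, 0.1, 0.15], n_seeds=2,
                      duration_ms=60_000.0, base_seed=1)
print(aggregate_sweep(df))
```

```
    lam  transfer_prob    delay_ms  rate_corr  n_bursts_1
0  0.00       0.000000  115.066667   0.051658        44.0
1  0.02       0.591667   67.673913   0.229638        37.0
2  0.05       0.915882   29.573529   0.721367        33.5
3  0.10       0.681911   23.734066   0.817935        42.5
4  0.15       0.946286    4.866667   0.955249        31.5
```

Disconnected clusters (λ = 0) transfer nothing once chance coincidences
are subtracted; over a narrow λ range the gate opens toward full
transmission, inter-cluster delays shrink from >100 ms to a few ms, and
the burst-wise firing-rate correlation between the clusters rises —
the modularity of the wiring directly controls transmission.

The same functionality is scriptable from the shell:

```sh
modgate synth --preset pair --seed 3 --out rec.h5 --truth truth.json
modgate detect --input rec.h5 --preset network --min-active-clusters 0 --out bursts.csv
modgate analyze --input rec.h5 --what delays
modgate sweep --lambdas 0,0.02,0.05,0.1,0.15 --seeds 2 --out sweep.csv
```

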