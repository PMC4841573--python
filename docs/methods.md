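# Methods

`modgate` models how the modular layout of a neuronal culture — two (or
more) dense clusters joined by a sparse bridge — gates the propagation
of network bursts (NBs), and implements the multielectrode-array (MEA)
analysis used to quantify that gating.  This note records the model,
the analysis conventions, the synthetic-data generator, and the places
where a concrete numerical choice had to be made.

## Network model

### Neurons

Each neuron is a Morris–Lecar element (time in ms, voltages in mV,
conductances in mS/cm², currents in µA/cm²):

    C_m dV/dt = I_ext − g_Ca·M_ss(V)(V − V_Ca) − g_K·W(V − V_K) − g_L(V − V_L)
    dW/dt     = φ (W_ss(V) − W) cosh((V − V3)/(2 V4))
    M_ss(V)   = ½(1 + tanh((V − V1)/V2)),   W_ss(V) = ½(1 + tanh((V − V3)/V4))

with g_Ca = 1, g_K = 2, g_L = 0.5, V_Ca = 100, V_K = −70, V_L = −50,
V1 = −1, V2 = 15, V3 = 10, V4 = 14.5, φ = 1/3.  Excitatory neurons have
C_m = 1 µF/cm², inhibitory ones C_m = 2; all other parameters are
shared.  These constants place the cell in the class-I excitable regime:
with the default noise mean the resting state sits near −30 mV, and a
few-mV fluctuation triggers a regenerative Ca²⁺ upstroke.

`I_ext = I_n + I_syn`.  The noise current I_n is redrawn independently
for every neuron at every integration step from N(µ = 7.55, σ = 4)
µA/cm², with no `dt` scaling — the effective noise spectrum therefore
depends on the step size; we document rather than "correct" this, and
all results use the fixed step below.

### Synapses

Synapses follow a resource-cycling (Tsodyks–Markram-type) scheme with a
saturating recovery term.  Fractions x, y, z of resources are
recovered, active and inactive (x + y + z = 1):

    dx/dt = z·(−tan(1.2 z − 1.2))/τ_rec − u·x·δ(t − t_AP)
    dy/dt = −y/τ_d + u·x·δ(t − t_AP)
    dz/dt = y/τ_d − z·(−tan(1.2 z − 1.2))/τ_rec

The tangent factor vanishes at z = 1, so recovery stalls after deep
depletion instead of accelerating; this prevents run-away tonic firing
at high network rates.  Excitatory synapses use a constant utilization
u = U₀ = 0.2; inhibitory synapses facilitate: du/dt = −u/τ_facil with a
jump u ← u + U₀(1 − u), U₀ = 0.06, applied *before* the resource jump
on each presynaptic spike.  Parameters per class:

| class | A (mV) | τ_rec | τ_d | τ_facil |
|-------|--------|-------|-----|---------|
| E→E   | 6.25   | 100   | 6   | —       |
| E→I   | 10     | 100   | 6   | —       |
| I→E, I→I | −10 or −20 | 800 | 6 or 12 | 1000 |

The inhibitory strength/decay alternatives are exposed as one switch,
`InhibitionLevel ∈ {low (A=10, τ_d=6), high_A (A=20, τ_d=6),
high_tau (A=10, τ_d=12)}`.  Per-synapse strengths are drawn from
N(A_nom, A_nom/2) and redrawn until within [0.8, 1.2]·A_nom (magnitudes;
the inhibitory sign is applied afterwards), giving a symmetric truncated
Gaussian whose mean is A_nom.  The synaptic input to a neuron is
Σᵢ Aᵢ·yᵢ(t) over its afferent synapses.

### Connectivity and modularity

Two clusters of 50 neurons; directed Bernoulli wiring inside cluster 1
at p = 0.25 and cluster 2 at p = 0.2, none between clusters; ⌊n/5⌋
randomly chosen inhibitory neurons per cluster.  Each intra-cluster
edge is then independently *replaced* with probability λ (the
modularity) by an edge from the same presynaptic neuron to a uniformly
chosen target in the other cluster (no self-edges or duplicates; edge
count is conserved exactly).  Hence ⟨N_inter⟩/⟨N_intra⟩ = λ/(1 − λ):
λ = 0 gives isolated clusters and λ = 0.5 erases the modular structure.

Three wiring schemes shape the bridge: *proportional* (targets drawn
uniformly, so inter-cluster synapse classes mirror the intra mix),
*feed-forward* (after proportional rewiring, inter E→I edges are added
or removed until their realized count equals the realized inter E→E
count, per direction), and *targeting* (inhibitory neurons receiving
inter-cluster excitation redirect their I→I outputs to random excitatory
neurons of their own cluster).  Two manipulations emulate pharmacology:
*inhibition block* (all inhibitory strengths set to 0, the in-silico
Bicuculline) and *local inhibition* (only inter-cluster inhibitory
strengths zeroed).

### Integration

Forward Euler at dt = 0.1 ms, 300 s nominal duration (60 s in the
scaled-down sweeps, below).  Choices the source material leaves open,
fixed here:

- **Spike definition**: upward crossing of V = 10 mV with a 2 ms
  lockout.  Spikes under these parameters peak well above 10 mV, and
  the lockout prevents double counting on coarse Euler steps.
- **Transmission**: spike jumps are applied to efferent synapses at the
  step of threshold crossing, with no axonal delay — inter-cluster
  delays in this preparation reflect recruitment time, not conduction.
- **Initial conditions**: V ~ U(−50, −30) mV, W = W_ss(V), synapses
  fully recovered (x = 1), dynamic u at U₀.  A 5 s warm-up is simulated
  and discarded; burst statistics are insensitive to the start after it.
- **Simplex clamping**: after each Euler step x, y, z are clamped to
  [0, 1] and renormalized to x + y + z = 1 (the tangent recovery term is
  only defined on [0, 1]).
- A divergence guard aborts if |V| exceeds 200 mV; a buffer guard
  aborts if the mean firing rate exceeds a configurable bound.

The integrator core is numba-compiled; a 60 s network of 100 neurons
runs in ~25 s on one core.  Identical seeds give bit-identical rasters.

## Recording analysis

### Activity intensity (AI)

Per channel, AI on 2 ms bins is mean |V| minus a noise threshold NT,
clipped at 0.  NT is the mean absolute voltage over 20 ms segments
whose unbiased, non-excess kurtosis (Gaussian = 3) is ≤ 3.1 — segments
containing spikes are super-Gaussian and get rejected, so NT estimates
the noise floor alone (for pure Gaussian noise NT → σ√(2/π)).  One NT
per channel per recording.  Edge bins shorter than a full bin are
dropped.  Gaussian smoothing, where used, is a unit-area kernel with
reflect padding.

**Active-bin floor.**  Burst detection counts "active" AI bins.  Taken
literally (AI > 0), half of all silent bins are active, because the bin
mean of |noise| fluctuates symmetrically around NT; detection then
cannot work on any recording with continuous noise.  We therefore
classify a bin as active when AI exceeds k·NT·√((π/2 − 1)/M) — k times
the standard deviation of the noise bin-mean, with M samples per bin
and k = 3 by default.  AI *values* are untouched (intensities,
correlations and delays all use the raw AI), and k = 0 restores the
literal rule.  This is the one place the package adds a guard the
original description does not spell out.

### Burst detection (W/T/G cascade)

On an event series — active-bin indicators for recordings, per-bin
spike counts for model rasters — the cascade is: (1) count events in
moving windows of length W every `step` ms; (2) zero counts below T;
(3) convolve the thresholded counts with the same boxcar again and
binarize at 1, which re-attaches burst-edge activity; (4) merge
candidate runs closer than G ms; (5) refine on the AI grid: start/end
are the first/last active bins in the candidate window, the peak is the
earliest maximum of the σ = 50 ms smoothed trace.  Presets:
experiment-channel {W=100, step=10, T=10, G=100}; experiment-network
{G=1000, participants must be active ≥ 10 ms, optionally ≥ 5 active
clusters}; model {W=10, step=2, T=5, G=50} on spike counts (the model
preset's step is not stated in the source and is set to the 2 ms grid).
Network-level detection pools event counts over channels.  Recruitment
time is peak − start; burst intensity is the AI sum over [start, end],
optionally normalized by the per-channel intensity SD over bursts.

### Propagation statistics

- **Delays**: lag of the peak of the Pearson-normalized cross-covariance
  of σ = 10 ms smoothed AI snippets, positive when the first trace
  leads; max lag ±500 ms; exact ties resolve to the smallest |lag|.
  For the model, the inter-cluster delay is the lag between the two
  clusters' burst peaks.
- **Sender classification** keeps bursts whose sending cluster leads.
- **Conditional propagation**: column-normalized joint histogram of
  SD-normalized burst intensities plus their Pearson correlation.
- **Transfer probability** (recordings): fraction of bursts in one
  cluster followed by a burst onset in the other within 1 s.
- **Transfer probability** (model): a cluster-1 burst counts as
  transmitted when a cluster-2 burst peak falls within 200 ms of its
  onset.  Cluster-1 bursts preceded by a cluster-2 peak within the same
  window were initiated by the other cluster and are excluded from the
  pool.  Chance coincidences are removed with counts from a λ = 0 run
  of the same duration: P = (T − T₀)/(N − T₀), clamped to [0, 1].  (The
  alternative denominator N − N₀ is a switch on the function.)
- **Long-term asymmetry**: cross-covariance over ±2 s lags, negative
  values zeroed; (∫₊ − ∫₋)/(∫₊ + ∫₋) ∈ [−1, 1], positive when the
  first trace leads.  The estimate averages both evaluation orders so
  swapping arguments flips the sign bit-exactly.
- **Propagation vectors**: per cluster and burst, each active neighbor
  contributes (peak lag) × (unit vector toward it), σ = 50 ms
  smoothing; the mean vector's angle ϴ is measured against the positive
  x-axis (positions in µm, x rightward, y upward, origin at the grid
  corner).  Network propagation variability is the mean over clusters
  of the circular SD of ϴ across bursts.
- **Distance profiles**: per channel pair, long-run AI correlation,
  mean |per-burst delay| and 1 s transfer probability, averaged in
  250 µm distance bins (grid pitch 500 µm).
- **Rate correlation (model)**: Pearson correlation over bursts of the
  two clusters' spike counts within 500 ms of burst onset.

### Pattern statistics

Burst similarity R_ij is the lag-maximum of the channel-averaged
normalized cross-covariance of σ = 10 ms smoothed AI snippets in a 1 s
window around the burst peaks (flat channels contribute zero).  Rows of
R give a Euclidean distance matrix fed to *average-linkage* hierarchical
clustering; the leaf order reorders R for display and the group count
is a user parameter (the original grouping was by visual inspection).

Activation-pattern entropy is the Shannon entropy of the empirical
distribution of binary participation patterns, normalized by
log(2^N − 1) — the uniform entropy over non-empty patterns of N
clusters.  The log base is a parameter: the formula is conventionally
written in bits, but the worked five-group value of ≈ 1.006 is
reproduced by natural logarithms, so nats are used where that value is
cited.  (With `n_clusters` matching the entry length, a 0/1 vector is
read as a participation mask, not as index lists.)

The bimodality coefficient BC = (m₃² + 1)/(m₄ + 3(n−1)²/((n−2)(n−3)))
uses bias-corrected sample skewness m₃ and *excess* kurtosis m₄, so the
large-n uniform reference is (0 + 1)/(−1.2 + 3) = 5/9 ≈ 0.555, the
Gaussian 1/3, and a symmetric two-point distribution 1.  It is applied
to sender/receiver intensity pairs projected on the identity line,
(x + y)/√2.  Burst sizes are summarized by active-electrode counts and
axis-aligned bounding-rectangle areas, each normalized by its maximum
over the burst population.

## Synthetic recordings

The generator emulates the *statistics* of patterned-culture MEA data,
not its biophysics.  Geometry: a rows × cols grid of circular clusters
(default 6 × 10, pitch 500 µm, diameters 80–200 µm); the expected cell
count of an island of area S µm² is max(0.0079·S − 1.9, 0).

A burst schedule draws burst times as a Poisson process (default
0.25 Hz) with a 1.5 s dead time (cultured NBs do not overlap), assigns
each burst an activation pattern from a probability table
(initiator + participant set), and propagates onsets along grid edges
restricted to the participants: each hop adds an independent
N(30, 5) ms delay (truncated positive) and fails with a configurable
probability, dropping the unreached subtree.  Per-burst intensity
scales are lognormal (σ = 0.3).

The renderer emits 10 kHz voltage: each participating channel receives
~120 biphasic 1.2 ms spike waveforms (amplitude 60 µV) per burst, with
offsets following a gamma(shape 2) envelope peaking 40 ms after onset
(exercising recruitment-time statistics), sporadic out-of-burst spikes
at 0.5 Hz, and i.i.d. Gaussian noise (σ = 5 µV, i.e. SNR 12 on the
spike peak).  What this does *not* emulate: electrode filtering,
spatial correlation of noise, spike-waveform diversity and overlap
saturation, slow drifts.  Passing recovery tests therefore validates
the analysis algebra and its robustness at realistic SNR, not
instrument-specific artifacts.

Ground-truth recovery at these defaults (checked in the test suite):
burst detection sensitivity and precision ≥ 0.95; mean inter-cluster
delay within one AI bin (+ sampling error) of the scheduled hop delay;
empirical pattern entropy within ~3 SE of the table's entropy; transfer
probabilities and asymmetry signs consistent with the schedule.

## Scaled-down sweep sizes

The modularity sweep used by the acceptance checks runs
λ ∈ {0, 0.02, 0.05, 0.1, 0.15}, 60 s of simulated time per run and two
network realizations per λ (the full-scale experiment is 300 s × 20
realizations).  With these sizes the package reproduces the qualitative
findings: baseline-corrected transfer is 0 for disconnected clusters,
rises steeply over a narrow λ range under low inhibition, and the
burst-wise rate correlation increases with λ; seed-averaged maxima land
near (but, with two realizations, not exactly at) full transmission.

## Known limitations

- Euler integration at 0.1 ms with per-step noise: results are
  step-size-dependent by construction; use the default dt.
- The leaky integrate-and-fire variant of the network and
  Ornstein–Uhlenbeck noise are out of scope.
- Exactly two clusters in the model; the synthetic generator, not the
  simulator, covers larger grids.
- Similarity matrices are O(bursts² × channels × window) and meant for
  ~10³ bursts at most.
- Statistical hypothesis testing (group comparisons) is left to the
  user; the package computes the statistics only.
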