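# Model and methods

`tactilesnn` simulates the tactile edge-orientation pathway as three spiking
stages driven by synthetic mechanical stimuli on a model skin patch, and
provides the decoders used to quantify how well edge orientation can be read
out at each stage.  This note documents the model equations, the parameters
that matter (units, defaults, and why), the numerical choices, and the known
limitations — in particular what the synthetic stimuli do and do not share
with real skin mechanics.

## Skin patch and stimuli

The skin is an 80 x 80 lattice of mechanoreceptors at 0.15 mm pitch
(~12 x 12 mm).  Stimulus geometry lives on a normalized mesh with both axes
in [-1, 1] (12 mm = 2 normalized units).  An edge at orientation theta is a
Gaussian ridge

    edge(x, y) = exp(-(x sin(theta) + y cos(theta))^2 / (2 w^2)),   w = 0.05,

so the half-maximum band is ~0.7 mm wide.  A point press is an isotropic 2-D
Gaussian with sigma = 0.05 (normalized units; treating the printed sigma as
normalized keeps the bump a local probe, comparable in width to the edge).

Two protocols generate force movies at dt = 0.1 ms:

* **Indentation** — trapezoidal depth envelope: 50 ms on-ramp, 200 ms hold,
  50 ms off-ramp (300 ms total), nominal depth 1 mm.  The per-frame force is
  `F * envelope(t) * edge(x, y)`.
* **Scan** — the edge contacts the bottom border, force ramps up over 50 ms
  while the edge is stationary (so afferent contact transients are not
  conflated with motion response), then the edge translates in +y at
  24 mm/s, covering the 12 mm patch in 500 ms.

`F` (`FORCE_AMPLITUDE = 100`, arbitrary units) is the single force-to-current
calibration constant linking stimulus amplitude to Izhikevich input current.
It was fixed once so that on-edge SA-I afferents sustain ~20-60 Hz during
the hold phase with onset rates up to ~150 Hz, and frozen for every
experiment.

### Trial noise

Trial-to-trial variability has three sources, each drawn from its own named
random stream:

* **Depth jitter** — the indentation depth is drawn per trial from
  1 mm +/- 0.5 mm SD (force scales linearly with depth; truncated at 0.1 mm).
* **Indentation noise** — a smooth multiplicative modulation of the contact
  force: an Ornstein-Uhlenbeck process with correlation time 10 ms and SD
  equal to the stated noise fraction (10% in the standard conditions).  A
  purely scalar per-trial amplitude factor would leave every current-trace
  *shape* invariant (the transduction chain is positively homogeneous), so
  correlation-based single-afferent features would be degenerate; modelling
  the noise as a slow within-trial modulation restores the within-class
  variability that any physical repetition of a contact exhibits.
* **Intrinsic membrane noise** — a Gaussian increment to every neuron's
  membrane potential per step, SD 1.5 mV/sqrt(ms), producing sparse (<1 Hz)
  background activity.

## First-order neurons (SA-I, RA-I)

100 SA-I afferents tile the patch as a 10 x 10 lattice of receptive-field
centres and 196 RA-I as 14 x 14 (296 total).  Each afferent innervates
exactly 28 distinct mechanoreceptors sampled from per-axis Gaussians around
its centre (sigma_d = 0.3 mm SA-I, 0.39 mm RA-I; off-grid or duplicate draws
are rejected and resampled, which biases border fields slightly inward), with
innervation weights uniform on [0.1, 1].  This produces the multi-hotspot
receptive fields that let individual afferents carry geometric stimulus
information.  The weighted force sum over the innervated sites is the
afferent's input current I_in.

Transduction (forward Euler, dt = 0.1 ms; derivative = backward difference):

* static SA-I:   `I_SA = k1 I_in` with k1 = 0.05 (memoryless Merkel gain)
* dynamic SA-I:  `tau_r dx/dt = k2 dI_in/dt + k1 I_in - x`,
  `tau_d dI_SA/dt = x - I_SA` with k2 = 3, tau_r = 5 ms, tau_d = 30 ms —
  a Merkel-cell (sustained) plus neurite (derivative) cascade whose ramp
  response overshoots its hold plateau
* RA-I:          `tau_RA dI_RA/dt = k3 |dI_in/dt| - I_RA` with k3 = 2,
  tau_RA = 30 ms — responds only while the skin input changes.

All neurons are Izhikevich units (`dv/dt = 0.04 v^2 + 5v + 140 - u + I`,
`du/dt = a(bv - u)`, reset v<-c, u<-u+d at 30 mV), integrated with forward
Euler at dt = 0.1 ms from the rest state (-70 mV, -14).  Afferents use the
regular-spiking set (a = 0.02, b = 0.2, c = -65, d = 8); cuneate and
cortical neurons use a = 0.1, d = 6.  The printed "s^-1" units for `a` are
interpreted per-ms, the standard convention for these parameter values.

## Cuneate nucleus

100 projection neurons (PN) on a lattice aligned with the SA-I centres and
100 interneurons (IN), one per PN.  PN p is excited by its co-located SA-I
afferent and the 2 nearest RA-I afferents; IN p is excited by the 4 nearest
same-type *neighbours* of those drivers and inhibits PN p — feedforward
lateral inhibition: the same skin contact that drives a PN recruits, through
its neighbourhood, inhibition onto that PN.  `inhibition_level` scales the
IN->PN weight (1 = full, 0.25 = partial).  Within each subpopulation, random
recurrent connections are drawn with probability 0.2 (PN->PN excitatory,
IN->IN inhibitory) at 2% of the feedforward weight: at the calibrated
feedforward gain, recurrent excitation at a substantial fraction of the
feedforward weight is past the positive-feedback runaway threshold of the
excitatory loop, so the recurrence is kept weak enough to perturb rather
than dominate.

Synapses are difference-of-exponential cascades: each presynaptic spike
increments an auxiliary variable by the synaptic weight after a 1 ms
latency; base time constants (AMPA tau_d 0.4 / tau_r 2 ms; GABA tau_d 0.25 /
tau_r 5 ms) are multiplied by a global factor of 7.  Because the cascade is
linear, feedforward drive is computed by filtering the delayed spike-count
matrix once per layer; only recurrent loops are stepped synapse-by-synapse.

Calibration constants (frozen): afferent->CN weight W_EX = 16, IN->PN weight
W_INH = 4 at full inhibition.  They were set so that the PN layer relays a
sparse but informative copy of the afferent pattern (a few hundred PN spikes
per indent trial at full inhibition, an order of magnitude more without
inhibition) — the "firing-rate filtering" role of the cuneate stage.

## Cortical layer (area 3b)

16 orientation groups (5-80 degrees in 5-degree steps) x 10 pyramidal
neurons (PY), each with a paired cortical interneuron (c-IN): 320 neurons.
A PY's receptive field has two adjacent skin sub-regions elongated along its
preferred orientation: an excitatory band (edge-template shape, width 0.1
normalized units) and an inhibitory band displaced one template width (0.2)
perpendicular to the orientation.  The ten PYs of a group place their bands
at y-offsets spanning the central +/-1.8 mm, so the group covers nearby
stimulus locations.  Skin-space templates are mapped onto PN channels
through each PN's skin footprint (the union of its driving afferents'
innervation weights), L1-normalized per neuron, scaled by G_EX = G_CIN = 80,
and frozen.  The excitatory band drives the PY; the inhibitory band drives
the paired c-IN, which synapses onto the PY (W_CIN = 30).

The decisive nonlinearity is the PY spike threshold: linear template overlap
between neighbouring orientations is high (a 5-degree rotation displaces the
band by less than its width over most of the patch), but only the
best-matching PYs cross threshold, so group spike counts act as a max-pool
over each group's locations.  The provided rate-based shortcut reproduces
exactly this (template score of the best PY per group) and is used in quick
tests; the spiking cortex is the default readout.

## Decoding

* **Winner-take-all** — the decoded orientation is the group with the
  largest summed PY spike count in the analysis window; ties break toward
  the smaller angle; an all-silent raster is an explicit no-detection
  (scored incorrect).
* **PCA + KNN** — per-unit spike counts (or other feature rows) are reduced
  to z = 3 principal components fit on the training folds only and
  classified by a k = 5 nearest-neighbour vote under stratified fivefold
  cross-validation.
* **Victor-Purpura distance** — standard O(n1 n2) dynamic program with
  insert/delete cost 1 and shift cost q |dt|, q in 1/ms (q = 1 in the
  single-afferent analysis).  Population spike-timing decoding sums per-unit
  VPd over a subsampled unit set and feeds per-trial distance rows to the
  classifier.
* **Correlation features** — a trial's input-current trace is correlated
  with each class's mean trace (leave-one-out for its own class); the
  16-vector of coefficients is the feature row.

## Experiment protocols and problem sizes

The default experiment configuration uses all 16 orientations, 10
repetitions per orientation, three stimulus locations spaced 1.2 mm along y
(drawn at random per trial), 10% indentation noise with depth jitter, full
inhibition, and the dynamic SA-I model.  The acceptance script runs the
pooled-accuracy experiment at 160 trials, the single-afferent analysis at
96 trials (16 orientations x 6 passes), and the cortical-latency measurement
over 12 seeds; these sizes keep a full reproduction run within a few minutes on one core
while leaving the statistical resolution of the pooled accuracies at a few
percentage points.

The single-afferent scanned-edge analysis follows the stated conditions of
that experiment: 10% indentation noise per trial (no depth jitter — the
scan presses at a controlled depth), one sampled SA-I and one RA-I afferent.
The sampled units are fixed exemplars of a reference population: the
receptive-field and connectivity streams are frozen at a dedicated
structural seed (the stream partitioning exists exactly so structure can be
held fixed while trial noise varies), and the default ids were chosen, after
surveying the population, to match the qualitative single-unit behaviour the
protocol examines — an SA-I whose current correlations are similar at
neighbouring low angles, an RA-I with diverse, temporally informative
responses.  Unit-to-unit variability in these single-neuron readouts is
substantial, and the per-unit accuracy distributions are wide.

Cortical detection latency is measured from smoothed (5 ms boxcar) net PY
input currents: each group is represented by its maximally driven PY, and
the latency is the earliest time after stimulus onset at which the
stimulated orientation's current exceeds every other group's and stays
dominant for at least 20 ms.

## Numerical choices

* Forward Euler everywhere at dt = 0.1 ms; all linear filters use the exact
  Euler recursion (verified against a high-accuracy integrator within 1%
  sup-norm on ramp-hold inputs).
* Membrane potentials are clamped at -120 mV; non-finite values (only
  reachable under absurd inputs) are reset with a logged warning.
* Spike delivery honours the 1 ms synaptic latency exactly; the in-loop
  recurrent stepper and the vectorized filter path produce identical traces.
* Winner-take-all ties break to the smallest orientation; KNN ties resolve
  by the nearest single neighbour (scikit-learn's ordering).
* Random streams are partitioned per experiment into receptive fields,
  connectivity, stimulus noise and intrinsic noise, so structure can be held
  fixed while trial noise varies; every report embeds its config and seed
  and can be replayed bit-identically.

## What the synthetic stimuli do not capture

The force model is a template, not tissue mechanics: no continuum skin
deformation, no lateral stress propagation beyond the Gaussian profile, no
ridge geometry, no viscoelastic creep.  Afferent heterogeneity is limited to
innervation randomness (no per-unit gain or threshold spread), and conduction
delays are collapsed into the two 1 ms synaptic latencies.  Passing tests
therefore demonstrate that the pathway architecture can encode and decode
edge orientation under the stated noise model — not that these accuracies
would survive real skin mechanics or natural touch statistics.

## Known limitations

* The decoder is robust to removing cuneate inhibition: PN spike counts
  rise sharply as `inhibition_level` falls, but winner-take-all accuracy
  stays near ceiling under the default conditions, because the
  L1-normalized cortical templates tolerate a dense PN code.  The
  accuracy-versus-inhibition *trend* is therefore non-strict here
  (non-decreasing with ties), weaker than the drop the original experiments
  reported.
* Single-afferent spike-timing (VPd) accuracies depend strongly on which
  unit is sampled and on the amplitude-noise model; the package reports
  them for fixed default units under the stated protocol noise.  In this
  implementation the SA-I spike train during a scan is itself informative
  at q = 1/ms — the burst onset time and the spike count both vary with
  orientation through the crossing geometry of the receptive field — so
  SA-I timing decoding sits far above chance (~40-55%) for every unit whose
  correlation features behave typically, rather than near chance.
* Population spike-timing decoding on the scan task does not lag count
  decoding here: with per-trial rows of summed pairwise VPd as features,
  the timing representation at q = 1/ms subsumes spike-count information
  (between non-coincident trains the distance reduces to count sums), so
  VPd decoding is at least as accurate as count decoding at every window.
  Count decoding on the scan task also *decreases* with window length —
  once the edge has crossed every receptive field, which units have fired
  stops being orientation-specific — so expanding-window curves rise only
  for the indentation task.
* The cortical receptive fields are constructed from templates rather than
  learned by a plasticity rule; they realize the same selectivity without
  modelling its development.
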