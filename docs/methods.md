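# Methods

## Model

`glut4queue` simulates GLUT4 storage-vesicle traffic in a single adipocyte as
a closed queuing network with a fixed population of `N` vesicles and four
stations: an infinite-server endosome store (service rate `μ_S` per vesicle,
per minute), `M` parallel FIFO microtubules of capacity `L` each (transit
rate `μ_M`), `M` paired single-server zero-buffer fusion sites (rate `μ_F`),
and an infinite-server plasma membrane (rate `μ_P`). All service times are
exponential and all switch times are zero, so the time spent moving between
stations is folded into the service times. Insulin acts on exactly one thing:
each fusion site is active with probability `p(I)` at insulin level `I`
(nM). Inactive sites accept no vesicles; because each microtubule feeds one
site and preserves arrival order, a permanently inactive site fills its
microtubule to capacity and freezes it, sequestering those vesicles from the
recycling pathway. Expected sequestration at stationarity is therefore
`M·L·(1−p)`, which is the basis of the start-point calculator and several
oracle tests. Basal recycling that in reality bypasses microtubules is folded
into the always-active fraction of the microtubule route; no separate direct
store→membrane route is modelled.

### Event mechanics

The engine is event-driven with a binary-heap calendar. Microtubule
departures follow the blocking-after-service recursion: arrival `i` with
arrival time `A_i` and service `S_i ~ Exp(μ_M)` leaves at `A_i + S_i + B_i`
if its service outlasts the predecessor's departure `D_{i−1}`, and otherwise
at `D_{i−1} + I_i + B_i`, where the increment time `I_i ~ Exp(L·μ_M)` — the
manoeuvre into the unloading zone — is drawn lazily at the moment the
predecessor departs, and `B_i` is the (possibly infinite) wait for the paired
fusion site to be active and empty. A blocked vesicle occupies its
microtubule server while it waits; transfers into a freed or newly activated
fusion site are instantaneous. A vesicle blocked at the store (its chosen
microtubule full) re-enters store service with a fresh `Exp(μ_S)` draw and
chooses uniformly among all `M` tubes again on the next attempt.

Simultaneous events (possible in floating point) are ordered by fixed station
priority — fusion completions, microtubule head-ready events, membrane
completions, store completions — then by vesicle id, so each realisation is a
deterministic function of (parameters, seed).

### Site activation coupling

How fusion-site states relate across insulin levels is a genuine modelling
choice. The default couples them through a per-site latent value
`u_m ~ U(0,1)` fixed for the realisation, with site `m` active iff
`u_m ≤ p(I)`. This makes activation monotone in insulin for non-decreasing
`p` — raising insulin only ever activates additional sites, matching the
one-way experimental protocol, where insulin is never lowered. Independent
redrawing at each insulin change is available via `redraw_activation=True`.

### Random-number contract

Each realisation derives seven named substreams from its seed
(store services, routing, tube services, increments, fusion services,
membrane services, latent activations) via `numpy.random.SeedSequence`
spawning, with draws consumed in simulation order within each substream.
This gives bit-reproducible realisations and supports common random numbers
in fitting. Suite realisation seeds and per-insulin-level network seeds are
spawned from the master seed the same way.

## Assay protocols

The **transition** protocol equilibrates the network at basal insulin for
`warm_up` minutes (default 500), steps to the target insulin at protocol time
zero, and records the plasma-membrane count on the sample grid
0, 0.5, 1, 2, 5, 10, 15, 20, 25, 30, 45, 60 min at four insulin levels
(0.3, 3, 30, 100 nM). The t = 0 sample reads the basal steady state — the
assay's zero-minute wells are unexposed to the step. The **uptake** protocol
continues for a further `equilibration` period (default 500 min) after the
step, then tags every vesicle on its first membrane visit — vesicles already
on the membrane count as tagged at t = 0, since the assay's initial
measurement is the membrane amount itself — and records the cumulative tag
count at 0, 2, 5, 10, 20, 30, 60, 90, 120, 180, 240, 300 min for nine levels
(0–100 nM). One model "repeat" runs every experiment once; levels with both
experiments share a realisation, the uptake continuing from the transition
end-state (a standalone fresh-warm-up mode exists and is statistically
identical; the suite's chained default mirrors the sequential schedule).
Traces are normalised to the across-realisation mean at the final sample time
of the reference (100 nM) experiment of the same kind — pooled across
realisations by default, per-realisation optionally.

## Distance and fitting

The model–data discrepancy is hierarchical: Wasserstein-1 distance (area
between empirical CDFs, valid for unequal sample sizes) between the model
realisation values and the data replicates at each sample time; the
unweighted mean of those over an experiment's grid; and the L2 norm across
experiments. Because every evaluation simulates a finite batch of
realisations (default 100), the objective is noisy — repeated evaluations at
fixed parameters give a band of distances whose width shrinks roughly as the
inverse square root of the realisation count.

Fitting is cyclic coordinate descent over the service rates, `N`, and the
activation probabilities. Each coordinate is minimised by a pattern line
search: probe one step either side of the incumbent, march while the
objective improves, halve the step otherwise, and finish when the step drops
below the coordinate's tolerance. Default tolerances and bounds: step
tolerance 1e-6 for all parameters except the integer-valued `N` (minimum
step 1000); `p(I) ∈ [0.01, 1]` (a floor that keeps some basal recycling);
`N ∈ [25000, 100000]`; rates ≥ 1e-6 with no upper bound; no evaluation cap
unless configured. Fresh evaluation seeds per objective call reproduce the
banded behaviour of the noisy objective (optimisation termini are then
noise-limited, not exact); `common_random_numbers=True` freezes one seed for
a smoother, deterministic surface. `grid_refine` evaluates the distance
exhaustively on a ±50% (default) grid around a terminus to escape local
minima. The studies module provides one-at-a-time sensitivity sweeps
(defaults ±1, 5, 10%), distance-noise bands (defaults 500 repeats of 100 and
1000 realisations), and pairwise landscapes (default ±90%, with a 2%
relative-distance convention for the indistinguishable "optimal region").

## Synthetic observations

`generate_synthetic_observations` emulates the replicated plate-assay tables
the fitter consumes: independent simulator realisations supply the replicate
values per (kind, insulin, time) — defaults of 6 transition and 10 uptake
replicates, the usual assay minima — with optional additive Gaussian
measurement noise truncated at zero (default `noise_sd = 0`, i.e. pure
simulator variability, since real inter-well variance is biological and not
separately modelled). Provenance records the generating truth. What passing
recovery tests on such data shows is that the inference machinery works when
the model is well-specified; it says nothing about model misspecification,
assay chemistry (fluorescence is taken exactly proportional to counts), or
cell-to-cell heterogeneity, none of which the generator emulates.

The start-point calculator inverts the sequestration expectation: given
uptake steady-state fractions `f(I)` relative to maximal insulin (estimated,
when derived from data, as the mean of the last two uptake sample times), and
a ceiling `max_recycling` (default 0.9) on the recycling pool at maximal
insulin, it returns `p(I) = 1 − N·(1 − max_recycling·f(I))/(M·L)`, clipped
to the [0.01, 1] fitting bounds. For the reference architecture
(N=25000, M=450, L=50) this gives `p(100 nM) = 0.8889`.

## Problem sizes used by the test suite

Simulation-backed tests run on two architectures chosen by this package:

* the **full-scale** reference architecture (N=25000, M=450, L=50) for the
  recycling-fraction check (20 seeds × 500 simulated minutes) — at the
  start-point activation 0.8889 the mean non-sequestered share is 90% of N
  with per-seed spread set by the binomial inactive-site count;
* a **scaled-down** architecture (N=2000, M=45, L=10) with rates
  `μ_S=0.12, μ_M=2.0, μ_F=2.4, μ_P=0.25`, `p(0)=0.45`, `p(100)=0.9`, which
  keeps the fusion sites as the rate-limiting bottleneck (as at full scale)
  while each realisation costs a fraction of a second. `μ_P=0.25` puts
  roughly a fifth of the recycling pool on the membrane, so the uptake t=0
  point and the transition kinetics carry a clear `μ_P` signal that the
  normalisation would otherwise hide. The shortened protocol uses 20-minute
  warm-up and equilibration (the scaled network's relaxation times are a few
  minutes), one transition level (100 nM) and two uptake levels (0, 100 nM),
  with uptake sampled to 120 min so both levels reach their plateaus — the
  plateau pair is what separates the activation probabilities from the
  fusion rate.

On the scaled architecture, the distance-noise check compares the spread of
6 repeated evaluations at 4 versus 40 realisations, and the
parameter-recovery check runs 4 independent fits against synthetic
observations with 8 transition / 12 uptake replicates (6 realisations per
evaluation, common random numbers, ≤85 evaluations, coordinate order
most-sensitive-first, step tolerances 0.008–0.05 for the sensitive
coordinates and coarser for `μ_S`, `μ_M`) started from multiplicative
perturbations of ×[0.75, 1.33] on rates and ±0.12 on activation
probabilities — start points of this quality mirror the pre-sampling used to
seed the full-scale fit, since a coordinate line search is local and can
follow the `μ_F`–`p`–`μ_P` compensating valley from a poor start.
`μ_F` and `μ_P` are asserted to return within ±25% and each `p(I)` within
±0.1 on at least 3 of 4 repeats; `μ_S` and `μ_M` are excluded from the
assertion because in the blocked-fusion regime stations upstream of the
bottleneck barely move the distance — at this scale they are identified only
near the regime boundary (e.g. where the store becomes the bottleneck).
`N` is held fixed in the scaled-down fits: with `M·L` only 22% of `N`,
normalisation removes nearly all information about the absolute population.

## Known limitations

* Vesicles are homogeneous (identical GLUT4 loading, identical microtubule
  lengths); realisation-to-realisation variance is therefore narrower than
  inter-well biological variance, especially at high insulin.
* No flush of fusion events on insulin application when microtubules operate
  at capacity; the model reproduces steady-state levels and kinetics, not
  single-event fusion statistics.
* Service times are exponential only; no alternative distributions.
* The fitter is a local line search on a noisy objective: termini are
  reproducible only within the distance-noise band, and the grid refinement
  is the only safeguard against local minima.
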