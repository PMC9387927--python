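# Methods

## Model

`ktwsim` simulates an open, well-mixed community of `N` bacterial strains and
`M` virulent phage strains. All bacteria compete for one shared resource
(logistic competition with carrying capacity 1 and inter-strain competition
coefficients equal to 1), and phages prey on bacteria through a bipartite
infection network. Densities follow generalized Lotka–Volterra dynamics:

    dB_i/dt = k_i B_i (1 − Σ_j B_j) − α B_i − B_i Σ_q η_qi P_q
    dP_q/dt = P_q Σ_m β_q η_qm B_m − δ P_q

Rates are expressed in units of the maximal bacterial growth rate and
densities in units of the carrying capacity. Defaults: universal bacterial
death rate α = 0.1 (e.g. protist grazing), phage decay rate δ = 1 (ocean
phage decay is comparable to the maximal bacterial division rate). Strain
parameters are sampled at invasion time: growth rate k ~ U[0, 1], burst
size β ~ U[1, 50], and each realized infection link gets an independent
strength η ~ U(0, 1) fixed for the lifetime of the pair.

The model is deterministic between invasions; there is no demographic
noise and no phage latency. Extinction is a threshold rule: a strain whose
density falls below 10⁻²⁰ is removed outright.

## Assembly protocol

A run starts from a single viable bacterium (k rejection-sampled above α) at
its steady state B* = 1 − α/k. Each subsequent step one invader — bacterium
or phage with probability ½ each — is added at an inoculum density of 10⁻⁶:

* **Model N** (nested): invading bacteria are resistant to all resident
  phages. Invading phages attack the predator-free bacterium (a feasible
  community has at most one) with probability 1 and every other bacterium
  with probability `p`.
* **Model R** (random): invading bacteria are attacked by each resident
  phage independently with probability `p`; phages are wired as in Model N.

The two models coincide at p = 0 (diagonal, classical kill-the-winner
wiring) and differ increasingly as p → 1.

After each addition the community is driven to a feasible steady state:
the linear system obtained from the per-capita steady-state conditions is
solved; if it is non-degenerate with strictly positive densities the
invasion succeeds and the community jumps to that state. Otherwise the
dynamics are integrated from the perturbed state until the first strain
crosses the extinction threshold, the strain is removed (phages stranded
without hosts are removed directly, since their dynamics are exactly
dP/dt = −δP), and the solve is retried. Each round removes at least one
strain, so the loop terminates.

Two protocol details are not forced by the model and were decided here:
a phage invader that ends up with zero links (possible when no
predator-free bacterium exists and every probability-`p` draw fails) is
discarded, and the failed attempt still consumes a time step, keeping the
time axis equal to "invasion trials". If an infeasible community produces
no extinction within the integration horizon the attempt is logged as
non-convergent and the resident community is kept (this affects well under
1% of attempts at the default horizon).

## Numerics

**Steady states.** The (N+M)-dimensional linear system is solved with LAPACK
(`numpy.linalg.solve`). The system is treated as degenerate when its
condition number exceeds 10¹² or a solved density lies in [0, 10⁻¹²);
degenerate and non-positive solutions are infeasible. Feasible solutions are
fixed points of the dynamics to ≲10⁻⁹ in rate units (tested).

**Integration.** Extinction resolution uses the classical fourth-order
Runge–Kutta scheme (numba-compiled). The step is accuracy-limited by the
fastest per-capita rate (g·h ≤ 0.25, so the local error of the fastest mode
stays ~(g h)⁵/120 ≈ 10⁻⁵) and stability-limited by an adaptive cap: the cap
starts at h = 0.1, grows by 1.5× after every 32 accepted steps (up to 10³),
and collapses back whenever a step is rejected. Rejection triggers are
NaNs, densities below −10⁻¹², or (for steps above twice the base cap) any
strain changing by more than a factor ~2 in one step; a rejected step is
retried with h halved. Hidden stiff Jacobian modes blow up within a few
large steps and trip these guards, so the cap self-throttles. Densities in
(−10⁻¹², 0) after an accepted step are clipped to zero.

**Asymptotic extinction jumps.** The dominant cost of the protocol is
integrating exponential tails: an invader at 10⁻⁶ decaying to 10⁻²⁰ spends
tens of e-folds in a regime where it no longer influences anything. A strain
below its *influence gate* (bacteria: 10⁻⁴ when phages are present, since a
bacterium feeds phages at up to β η B ≈ 50 B per capita, and 0.05 in
phage-free communities where only its resource share matters; phages: 10⁻³,
since η < 1) is dynamically negligible. When every strain outside the gates
is quasi-static — fastest outside per-capita rate and the gated strains'
total influence both below 2% of the slowest gated rate — the gated strains
evolve exponentially at frozen per-capita rates, and the integrator jumps
directly to the first event: a decaying strain crossing the extinction
threshold, or a growing strain reaching its gate (where normal stepping
resumes). The handed-off state immediately feeds a fresh linear solve,
which corrects residual drift of the survivors; the approximation can at
most reorder near-simultaneous extinctions of already-negligible strains.
This is a performance device, not a model change: the same trajectories
integrated without jumps give the same survivor sets (spot-checked against
LSODA in the tests).

**Horizon.** Integration gives up after 10⁶ time units (non-convergence is
an explicit error). Genuinely neutral or near-neutral configurations —
e.g. two bacteria with growth rates equal to within ~10⁻⁶ — can exceed any
horizon; they are measure-zero under continuous sampling.

## Triplet classification

The minimal eliminate-the-winner motif is a fast grower S, a slower grower
R (k_R < k_S), and one shared phage. Its asymptotic outcome is classified
in closed form by invasibility analysis, with every branch validated
against an independent LSODA integration oracle (≥99% agreement on random
non-boundary systems is part of the acceptance suite):

* phage persistence on a host alone: β η (1 − α/k) > δ;
* the S+phage boundary state has B_S = δ/(β η_S),
  P = (k_S(1−B_S) − α)/η_S; R invades iff k_R(1−B_S) − α − η_R P > 0;
* the interior point follows from 1 − B_S − B_R =
  α(η_R − η_S)/(η_R k_S − η_S k_R) and the phage line
  β(η_S B_S + η_R B_R) = δ; coexistence requires all three components
  positive, which forces η_R/η_S < k_R/k_S (the slower grower must be
  *less* exposed to the shared phage).

Decision order: if the phage persists on S, then R-invasibility and
interior positivity decide between S_EXCLUDES_R, COEXIST and R_EXCLUDES_S;
if it cannot persist on S, the outcome is R_EXCLUDES_S when the R+phage
state exists and repels S, else PHAGE_LOST (S wins alone). The corner where
R displaces S but the phage cannot then persist on R alone is labelled
R_EXCLUDES_S (the winner was eliminated; the phage may starve afterwards) —
the oracle's survivor sets {R, P} and {R} both map there. Points exactly on
a boundary go to COEXIST when the interior solution is non-negative, else
to the surviving competitor; ties are measure-zero.

Elimination-event detection scans each invasion attempt for the pre-event
fastest resident bacterium S going extinct while at least one slower
resident survives *and* every surviving bacterium (invader included) is
slower than S — without the latter condition, a faster phage-free invader
winning plain resource competition would masquerade as an
eliminate-the-winner event. The common phage is the candidate (resident or
the invading phage itself) with the largest β η on its S link; among
slower survivors it infects, the fastest is taken as R.

## Statistics

* **Growth-rate occupancy** N_B(k): time-average over all invasion attempts
  of the resident bacteria count per k-bin (bin width Δk = 0.1), divided by
  Δk. **Entry distribution** p_entry(k): normalized histogram of growth
  rates of bacteria that successfully entered (Σ p_entry Δk = 1). The
  normalization reads p_entry as the distribution of successful entries,
  not a per-attempt success probability — both readings fit the quantity's
  name; this one is self-normalizing and is what the fits below consume.
* **Elimination factor** E: least-squares fit of log N_B(k) against k on
  bins inside [0.3, 0.9] with positive counts (≥3 required; zero bins are
  excluded rather than floored — unbiased for an exponential profile), with
  N_B(k) ∝ exp(k/E), i.e. E is the *inverse* log-slope. A larger E means a
  flatter profile and hence a weaker fast-grower advantage; E ≈ 0.2 is the
  steep diagonal kill-the-winner limit, and a few cross-links (p = 0.05)
  flatten it to ≈ 0.28. The inverse-slope convention is adopted because the
  direct-slope reading would make larger values *steeper*, contradicting
  the quantity's interpretation; the reported magnitudes confirm it.
* **Entry advantage** G_A = s / (p_entry(0.3)·Δk), with s the fitted
  log-slope of p_entry(k) on the same window and p_entry(0.3) the fitted
  value at k = 0.3. Normalizing the slope by the entry density at the
  window's lower edge makes G_A a relative advantage of fast over slow
  entrants: G_A = 0 for a flat entry distribution, and for
  p_entry ∝ exp(s·k) the fit recovers s/(p_entry(0.3)·Δk) exactly.
* **KtW pairing**: link weights are β_q η_qi. A community is fully paired
  when every phage's strongest prey link and that bacterium's strongest
  predator link coincide, the map is a perfect matching of all phages onto
  an equal number of bacteria, and at most one bacterium — necessarily
  predator-free — remains outside (so balanced-diversity states
  N_B = N_P + 1 count as paired). The reported fraction is over every
  logged post-event community with at least one phage and one bacterium.
* **R/B**: among successful bacterial invasions that increased total strain
  count, the fraction whose η-column was all-zero at entry.

## Problem sizes and reproducibility

All randomness flows from one seeded numpy Generator per run, consumed in a
fixed documented order, so histories are bit-reproducible from their
config. The acceptance script and test suite use scaled-down ensembles:
20 seeds × 2500 invasion attempts per p for the elimination factor and
10 seeds × 2000 attempts for the pairing fractions (the headline statistics
are stationary in run length; 10⁴-attempt runs give the same values within
the seed-to-seed spread, which is reported alongside each estimate in the
tests).

## What the generator does and does not emulate

The simulator *is* the study system: it generates the assembly histories
the statistics are computed from. It emulates an open patch receiving a
sparse stream of immigrant strains with random traits, reaching a
deterministic steady state between arrivals. It does not emulate finite
population noise (no stochastic extinction of rare strains), phage
latency, trait evolution within resident strains, spatial refuges, or
simultaneous arrivals — so passing tests demonstrate the self-organization
properties of the deterministic invasion-structured model, not agreement
with any particular ocean dataset.

## Known limitations

* Feasibility (positive solution of the linear steady state) is used as
  the invasion-success criterion without checking dynamical stability of
  that state, mirroring the protocol's definition; unstable feasible states
  are rare for these interaction structures (the relaxation test in the
  suite finds none in 100 random communities) but are not excluded in
  principle.
* The pairing fraction at p = 1 is dominated by single-pair communities
  (frequent total collapses), which are paired by definition; see the
  per-size breakdown in the tests before comparing against conventions
  that count only multi-phage networks.
* The asymptotic-jump accelerator freezes quasi-static environments over
  a decaying strain's final e-folds; in principle this can reorder two
  near-simultaneous extinctions of negligible strains.
* Exact parameter ties (equal growth rates, boundary triplet parameters)
  are resolved by documented tie rules; they have measure zero under the
  continuous samplers.
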