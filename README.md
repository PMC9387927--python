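# ktwsim — open phage–bacteria ecosystem assembly

`ktwsim` simulates how a community of bacteria and virulent phages assembles
in an open environment — a well-mixed patch (think of a parcel of surface
ocean) that is constantly probed by immigrant strains. It is aimed at
theoretical ecologists studying the "kill the winner" (KtW) hypothesis:
phages preferentially suppress the fastest-growing bacteria, letting slower
growers coexist on a single shared resource. The package reproduces a
stronger phenomenon, *eliminate the winner*: a phage shared between a fast
and a slow grower can drive the fast grower fully extinct through apparent
competition.

## Model

`N` bacterial strains and `M` phage strains follow generalized
Lotka–Volterra dynamics (rates in units of the maximal bacterial growth
rate, densities in units of the carrying capacity):

```
dB_i/dt = k_i B_i (1 − Σ_j B_j) − α B_i − B_i Σ_q η_qi P_q
dP_q/dt = P_q Σ_m β_q η_qm B_m − δ P_q
```

with growth rates k_i ~ U[0,1], burst sizes β_q ~ U[1,50], infection rates
η_qi ~ U(0,1) on realized links, bacterial death rate α = 0.1 and phage
decay rate δ = 1. Starting from a single bacterium, invaders (bacterium or
phage, equiprobably) arrive one per step at density 10⁻⁶. Wiring of new
links is controlled by a cross-link probability `p` under two rules: Model
N (invading bacteria resistant to all resident phages) and Model R (each
resident phage attacks the invader with probability `p`). After each
arrival the community is driven to a feasible steady state — solving the
linear steady-state system, and integrating (RK4) to remove strains that
cross a 10⁻²⁰ extinction threshold when no positive solution exists.

On top of the simulator the package computes the analysis statistics: the
outcome phase diagram of the fast/slow/shared-phage triplet motif,
detection of eliminate-the-winner events, mutual strongest-link (KtW)
pairing of evolved networks, growth-rate occupancy N_B(k) and entry
distribution p_entry(k), the elimination factor E (N_B(k) ∝ exp(k/E)), the
entry advantage G_A, diversity statistics and the resistant-invader
fraction R/B. See `docs/methods.md` for definitions and numerical details.

## Worked example

```python
import ktwsim as kw

cfg = kw.AssemblyConfig(model="R", p=0.05, n_steps=2500, seed=11)
history = kw.run_assembly(cfg)

profile = kw.growth_rate_profile(history)
fit = kw.elimination_factor(profile)
print(f"elimination factor E = {fit.E:.3f} (fit over {fit.bins_used} bins)")

events = kw.detect_elimination_events(history)
print(f"eliminate-the-winner events: {len(events)}")
print(f"fully-paired community fraction: {kw.ktw_fraction([history]):.3f}")
```

prints

```
elimination factor E = 0.244 (fit over 6 bins)
eliminate-the-winner events: 7
fully-paired community fraction: 0.958
```

E ≈ 0.24 says the time-averaged number of resident bacteria rises roughly
e-fold per 0.24 of growth rate across k ∈ [0.3, 0.9] — fast growers still
dominate, but less steeply than in the diagonal p = 0 limit (E ≈ 0.2),
because occasionally a shared phage eliminates the fastest grower (7 such
events in this run). 96% of the logged communities have every phage and its
main host mutually paired by their strongest β·η link — the self-organized
return to a KtW-like network.

The same run from the shell:

```
$ ktwsim run --model R --p 0.05 --steps 2500 --seed 11 --out run_R_p005
$ ktwsim metrics --run-dir run_R_p005
{"ktw_fraction": 0.9576..., "E": 0.2435..., "RB_fraction": 0.9896...,
 "n_elimination_events": 7}
```

`run` writes a config echo, a JSON-lines event log with full network
snapshots, and a per-step summary TSV; `metrics` adds pairing/E/R-over-B
summaries and the elimination-event table. `ktwsim sweep` aggregates these
statistics over a grid of `p` values and seeds, and
`ktwsim phase-diagram` exports the analytic triplet-outcome grid over
(η_R/η_S, k_R/k_S).

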