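"""Sequential invasion protocol: community assembly under Models N and R.

Starting from a single viable bacterium, each step one invader — a bacterium
or a phage, equiprobably — is sampled, wired into the resident infection
network and added at a small inoculum density to the resident steady state.
The perturbed community is then relaxed to a new feasible steady state
(possibly after extinctions), and the outcome is logged.

Wiring rules:

* Model N ("nested"): invading bacteria are resistant to all resident phages
  (all-zero eta column).
* Model R ("random"): each resident phage attacks the invading bacterium
  independently with probability p.
* Invading phages (both models): the predator-free bacterium — a feasible
  community has at most one — is attacked with probability 1, every other
  bacterium with probability p. Link strengths are fresh Uniform(0, 1) draws
  and are fixed for the lifetime of the pair.

RNG discipline: one seeded numpy Generator drives everything, in fixed order
per step (invader kind, strain parameters, wiring presence/strengths in
bacterium index order), so a run is exactly reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .glv_core import (BacteriumStrain, CommunityState, Ecosystem,
                       GlobalRates, NonConvergenceError, PhageStrain,
                       resolve_after_perturbation)

BACTERIUM = "bacterium"
PHAGE = "phage"


@dataclass(frozen=True)
class AssemblyConfig:
    model: str  # "N" or "R"
    p: float  # cross-link probability
    n_steps: int
    seed: int
    inoculum: float = 1e-6
    threshold: float = 1e-20
    rates: GlobalRates = field(default_factory=GlobalRates)
    h_max: float = 0.1
    t_max: float = 1e6

    def __post_init__(self):
        if self.model not in ("N", "R"):
            raise ValueError(f"model must be 'N' or 'R', got {self.model!r}")
        if not 0 <= self.p <= 1:
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.inoculum <= 0:
            raise ValueError("inoculum must be > 0")


@dataclass
class InvasionEvent:
    """One invasion attempt: who tried to enter, and what the dust settled to."""

    step: int
    invader_kind: str  # "bacterium" | "phage"
    invader_id: int
    invader_param: float  # growth rate k or burst size beta
    invader_links: np.ndarray  # eta column (bacterium) or row (phage) at entry
    success: bool
    extinct_ids: list[int]
    pre_state: CommunityState
    post_state: CommunityState
    post_eco: Ecosystem
    discarded: bool = False  # phage attempt with no host link, never added
    non_convergent: bool = False  # relaxation hit the time horizon; reverted


@dataclass
class AssemblyHistory:
    config: AssemblyConfig
    initial_eco: Ecosystem
    initial_state: CommunityState
    events: list[InvasionEvent] = field(default_factory=list)

    def iter_with_base(self) -> Iterator[tuple[Ecosystem, CommunityState, InvasionEvent]]:
        """Yield (resident ecosystem, resident state, event) per attempt."""
        eco, state = self.initial_eco, self.initial_state
        for ev in self.events:
            yield eco, state, ev
            eco, state = ev.post_eco, ev.post_state


def sample_bacterium(rng: np.random.Generator, strain_id: int = 0,
                     birth_step: int = 0) -> BacteriumStrain:
    """Growth rate k ~ Uniform[0, 1]."""
    k = rng.random()
    while k == 0.0:  # k must be strictly positive
        k = rng.random()
    return BacteriumStrain(strain_id, k, birth_step)


def sample_phage(rng: np.random.Generator, strain_id: int = 0,
                 birth_step: int = 0) -> PhageStrain:
    """Burst size beta ~ Uniform[1, 50]."""
    return PhageStrain(strain_id, rng.uniform(1.0, 50.0), birth_step)


def initialize_ecosystem(config: AssemblyConfig,
                         rng: np.random.Generator | None = None):
    """One bacterium with k > alpha (rejection-sampled) at B* = 1 - alpha/k."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    alpha = config.rates.alpha
    k = rng.random()
    while k <= alpha:
        k = rng.random()
    eco = Ecosystem([BacteriumStrain(0, k, 0)], [], np.zeros((0, 1)),
                    config.rates)
    state = CommunityState(np.array([1.0 - alpha / k]), np.zeros(0))
    return eco, state


def wire_invading_bacterium(eco: Ecosystem, model: str, p: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Eta column for a new bacterium (length = number of resident phages)."""
    M = eco.n_phages
    col = np.zeros(M)
    if model == "N":
        return col
    present = rng.random(M) < p
    for q in range(M):
        if present[q]:
            col[q] = rng.random()
    return col


def wire_invading_phage(eco: Ecosystem, p: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Eta row for a new phage (length = number of resident bacteria).

    The single predator-free bacterium, when it exists, is linked with
    probability 1; all other bacteria with probability p. An all-zero row
    means the attempt must be discarded (a phage needs a host).
    """
    N = eco.n_bacteria
    row = np.zeros(N)
    free = eco.predator_free_bacteria()
    target = free[0] if len(free) == 1 else None
    for i in range(N):
        if i == target:
            row[i] = rng.random()
        elif rng.random() < p:
            row[i] = rng.random()
    return row


def run_assembly(config: AssemblyConfig) -> AssemblyHistory:
    """Run the full sequential-invasion protocol; fully seed-reproducible."""
    rng = np.random.default_rng(config.seed)
    eco, state = initialize_ecosystem(config, rng)
    history = AssemblyHistory(config, eco, state)
    next_id = 1
    for step in range(1, config.n_steps + 1):
        kind = BACTERIUM if rng.random() < 0.5 else PHAGE
        invader_id = next_id
        next_id += 1
        pre_state = state.copy()
        if kind == BACTERIUM:
            strain = sample_bacterium(rng, invader_id, step)
            links = wire_invading_bacterium(eco, config.model, config.p, rng)
            cand = eco.with_bacterium(strain, links)
            init = CommunityState(np.append(state.B, config.inoculum), state.P)
            param = strain.k
        else:
            strain = sample_phage(rng, invader_id, step)
            links = wire_invading_phage(eco, config.p, rng)
            param = strain.beta
            if not np.any(links > 0):
                # no host: the attempt is discarded but still consumes a step
                history.events.append(InvasionEvent(
                    step, kind, invader_id, param, links, success=False,
                    extinct_ids=[invader_id], pre_state=pre_state,
                    post_state=state.copy(), post_eco=eco, discarded=True))
                continue
            cand = eco.with_phage(strain, links)
            init = CommunityState(state.B, np.append(state.P, config.inoculum))
        try:
            new_eco, new_state, extinct = resolve_after_perturbation(
                cand, init, threshold=config.threshold,
                h_max=config.h_max, t_max=config.t_max)
        except NonConvergenceError:
            history.events.append(InvasionEvent(
                step, kind, invader_id, param, links, success=False,
                extinct_ids=[invader_id], pre_state=pre_state,
                post_state=state.copy(), post_eco=eco, non_convergent=True))
            continue
        success = invader_id not in extinct
        history.events.append(InvasionEvent(
            step, kind, invader_id, param, links, success=success,
            extinct_ids=extinct, pre_state=pre_state,
            post_state=new_state.copy(), post_eco=new_eco))
        eco, state = new_eco, new_state
    return history


def run_ensemble(model: str, p: float, n_steps: int, seeds,
                 **kwargs) -> list[AssemblyHistory]:
    """Convenience: one assembly run per seed with shared settings."""
    return [run_assembly(AssemblyConfig(model=model, p=p, n_steps=n_steps,
                                        seed=int(s), **kwargs))
            for s in seeds]
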