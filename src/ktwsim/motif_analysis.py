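"""The eliminate-the-winner triplet: fast grower S, slow grower R, shared phage.

Two bacteria on one resource can only coexist with a phage's help (apparent
competition on top of resource competition). Restricted to {S, R, P} the
dynamics are

    dB_S/dt = B_S [k_S (1 - B_S - B_R) - alpha - eta_S P]
    dB_R/dt = B_R [k_R (1 - B_S - B_R) - alpha - eta_R P]
    dP/dt   = P  [beta (eta_S B_S + eta_R B_R) - delta]

with k_R < k_S. The asymptotic outcome is classified in closed form from the
boundary steady states and the interior solution:

* phage persistence on a host alone requires beta * eta * (1 - alpha/k) > delta;
* the S+phage state has B_S = delta/(beta eta_S), P = (k_S(1-B_S) - alpha)/eta_S,
  and R invades it iff k_R (1 - B_S) - alpha - eta_R P > 0;
* the interior point follows from equating the two bacterial equations:
  1 - B_S - B_R = alpha (eta_R - eta_S) / (eta_R k_S - eta_S k_R), the phage
  line beta (eta_S B_S + eta_R B_R) = delta then splits the bacteria.

Coexistence therefore needs the slower grower to be *less* exposed to the
shared phage (eta_R < eta_S), and in fact eta_R/eta_S < k_R/k_S.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import AssemblyHistory, PHAGE
from .glv_core import Ecosystem, GlobalRates


class TripletOutcome(str, enum.Enum):
    COEXIST = "COEXIST"
    S_EXCLUDES_R = "S_EXCLUDES_R"
    R_EXCLUDES_S = "R_EXCLUDES_S"  # eliminate the winner
    PHAGE_LOST = "PHAGE_LOST"  # phage cannot persist; fastest grower wins alone


@dataclass(frozen=True)
class TripletSystem:
    k_S: float
    k_R: float
    eta_S: float
    eta_R: float
    beta: float
    rates: GlobalRates = field(default_factory=GlobalRates)

    def __post_init__(self):
        if not 0 < self.k_R < self.k_S <= 1:
            raise ValueError("need 0 < k_R < k_S <= 1")
        if not (0 < self.eta_S < 1 and 0 < self.eta_R < 1):
            raise ValueError("eta_S, eta_R must be in (0, 1)")
        if not 1 <= self.beta <= 50:
            raise ValueError("beta must be in [1, 50]")
        if self.k_R <= self.rates.alpha:
            raise ValueError("both bacteria must be viable alone (k > alpha)")


def _interior(t: TripletSystem):
    """Interior (coexistence) fixed point (B_S, B_R, P), or None if singular."""
    a, d = t.rates.alpha, t.rates.delta
    den = t.eta_R * t.k_S - t.eta_S * t.k_R
    if den == 0 or t.eta_S == t.eta_R:
        return None
    x = a * (t.eta_R - t.eta_S) / den  # 1 - B_S - B_R
    P = (t.k_S * x - a) / t.eta_S
    stot = 1.0 - x
    BS = (d / t.beta - t.eta_R * stot) / (t.eta_S - t.eta_R)
    BR = stot - BS
    return BS, BR, P


def triplet_margins(t: TripletSystem) -> dict:
    """Signed decision quantities; their zero sets are the region boundaries.

    Used to measure how far a parameter point sits from any analytic
    boundary (points with a tiny minimum |margin| are boundary cases).
    """
    a, d = t.rates.alpha, t.rates.delta
    m = {}
    BS0 = 1.0 - a / t.k_S
    BR0 = 1.0 - a / t.k_R
    m["phage_on_S"] = t.beta * t.eta_S * BS0 - d
    m["phage_on_R"] = t.beta * t.eta_R * BR0 - d
    if m["phage_on_S"] > 0:
        BS1 = d / (t.beta * t.eta_S)
        PS1 = (t.k_S * (1.0 - BS1) - a) / t.eta_S
        m["R_invades_SP"] = t.k_R * (1.0 - BS1) - a - t.eta_R * PS1
    if m["phage_on_R"] > 0:
        BR1 = d / (t.beta * t.eta_R)
        PR1 = (t.k_R * (1.0 - BR1) - a) / t.eta_R
        m["S_invades_RP"] = t.k_S * (1.0 - BR1) - a - t.eta_S * PR1
    inter = _interior(t)
    if inter is not None:
        m["interior_B_S"], m["interior_B_R"], m["interior_P"] = inter
    return m


def boundary_distance(t: TripletSystem) -> float:
    """Minimum |margin| over the decision quantities of :func:`triplet_margins`."""
    return min(abs(v) for v in triplet_margins(t).values())


def classify_triplet(t: TripletSystem) -> TripletOutcome:
    """Closed-form asymptotic outcome of the S/R/shared-phage system.

    Boundary tie rule: points exactly on an analytic boundary go to COEXIST
    when the interior solution is non-negative, else to the surviving
    competitor's region (ties are measure-zero; this keeps the map total and
    deterministic).
    """
    m = triplet_margins(t)
    if m["phage_on_S"] > 0:
        if m["R_invades_SP"] < 0:
            return TripletOutcome.S_EXCLUDES_R
        inter = _interior(t)
        if inter is not None and all(v >= 0 for v in inter):
            return TripletOutcome.COEXIST
        if m["R_invades_SP"] == 0:
            return TripletOutcome.S_EXCLUDES_R
        return TripletOutcome.R_EXCLUDES_S
    # phage cannot persist on S alone
    if m["phage_on_R"] > 0 and m["S_invades_RP"] <= 0:
        return TripletOutcome.R_EXCLUDES_S
    return TripletOutcome.PHAGE_LOST


def triplet_phase_diagram(k_S: float, eta_S: float, beta: float,
                          rates: GlobalRates = GlobalRates(),
                          resolution: int = 100) -> pd.DataFrame:
    """Outcome grid over (eta_R/eta_S, k_R/k_S) in (0, 1) x (0, 1).

    Cells are evaluated at their centers. Cells whose implied k_R is not
    viable alone (k_R <= alpha) fall outside the triplet's domain and are
    labelled "INVALID".
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    centers = (np.arange(resolution) + 0.5) / resolution
    rows = []
    for k_ratio, eta_ratio in itertools.product(centers, centers):
        k_R = k_ratio * k_S
        eta_R = eta_ratio * eta_S
        try:
            t = TripletSystem(k_S=k_S, k_R=k_R, eta_S=eta_S, eta_R=eta_R,
                              beta=beta, rates=rates)
            outcome = classify_triplet(t).value
        except ValueError:
            outcome = "INVALID"
        rows.append((eta_ratio, k_ratio, outcome))
    return pd.DataFrame(rows, columns=["eta_ratio", "k_ratio", "outcome"])


@dataclass
class EliminationEvent:
    """A fastest-resident-grower extinction mediated by a shared phage."""

    step: int
    eliminated_id: int  # S, the pre-event fastest resident grower
    survivor_id: int  # R, a surviving slower grower sharing a phage with S
    common_phage_id: int
    ratio_k: float  # k_R / k_S
    ratio_eta: float  # eta_R / eta_S for the common phage
    trigger: str  # "phage_invasion" | "bacterium_invasion"
    k_S: float = np.nan
    k_R: float = np.nan
    eta_S: float = np.nan
    eta_R: float = np.nan
    common_phage_beta: float = np.nan


def detect_elimination_events(history: AssemblyHistory) -> list[EliminationEvent]:
    """Scan a history for eliminate-the-winner events.

    An event qualifies when the pre-event fastest resident bacterium S goes
    extinct while at least one slower resident bacterium survives and every
    surviving bacterium (including the invader, if it stayed) is slower than
    S — i.e. the winner was genuinely replaced by slower growers, not beaten
    by a faster invader. The common phage is a phage present during the
    event (resident, or the invader itself) infecting both S and a surviving
    slower resident R; among candidates the phage with the largest
    beta * eta on its S link is picked, then the fastest R it also infects.
    """
    out: list[EliminationEvent] = []
    for base_eco, _base_state, ev in history.iter_with_base():
        if ev.discarded or ev.non_convergent or base_eco.n_bacteria == 0:
            continue
        s_idx = int(np.argmax(base_eco.k_vec))
        s = base_eco.bacteria[s_idx]
        if s.id not in ev.extinct_ids:
            continue
        survivors = ev.post_eco.bacteria
        if not survivors or max(b.k for b in survivors) >= s.k:
            continue
        surviving_res = [b for b in survivors if b.id != ev.invader_id]
        if not surviving_res:
            continue
        # candidate phages: residents plus an invading phage with its wiring
        candidates = []  # (beta*eta_S, beta, eta_S, phage_id, eta_by_bact_id)
        for q in range(base_eco.n_phages):
            eta_S = base_eco.eta[q, s_idx]
            if eta_S <= 0:
                continue
            links = {base_eco.bacteria[i].id: base_eco.eta[q, i]
                     for i in range(base_eco.n_bacteria)}
            ph = base_eco.phages[q]
            candidates.append((ph.beta * eta_S, ph.beta, eta_S, ph.id, links))
        if ev.invader_kind == PHAGE and not ev.discarded:
            links = {base_eco.bacteria[i].id: ev.invader_links[i]
                     for i in range(base_eco.n_bacteria)}
            eta_S = links.get(s.id, 0.0)
            if eta_S > 0:
                candidates.append((ev.invader_param * eta_S, ev.invader_param,
                                   eta_S, ev.invader_id, links))
        best = None
        for weight, beta, eta_S, pid, links in sorted(
                candidates, key=lambda c: -c[0]):
            rs = [b for b in surviving_res if links.get(b.id, 0.0) > 0]
            if rs:
                r = max(rs, key=lambda b: b.k)
                best = (pid, beta, eta_S, links[r.id], r)
                break
        if best is None:
            continue
        pid, beta, eta_S, eta_R, r = best
        out.append(EliminationEvent(
            step=ev.step, eliminated_id=s.id, survivor_id=r.id,
            common_phage_id=pid, ratio_k=r.k / s.k, ratio_eta=eta_R / eta_S,
            trigger=("phage_invasion" if ev.invader_kind == PHAGE
                     else "bacterium_invasion"),
            k_S=s.k, k_R=r.k, eta_S=eta_S, eta_R=eta_R,
            common_phage_beta=beta))
    return out


def elimination_events_table(events: list[EliminationEvent]) -> pd.DataFrame:
    """TSV-ready scatter data: step, trigger and the two ratios."""
    return pd.DataFrame(
        [(e.step, e.trigger, e.ratio_k, e.ratio_eta) for e in events],
        columns=["step", "trigger", "k_R_over_k_S", "eta_R_over_eta_S"])


def count_shared_phage_triplets(eco: Ecosystem) -> int:
    """Number of (bacterium pair, phage) motifs with the phage linking both."""
    links_per_phage = (eco.eta > 0).sum(axis=1)
    return int(np.sum(links_per_phage * (links_per_phage - 1) // 2))
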