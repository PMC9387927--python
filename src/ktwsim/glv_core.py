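"""Generalized Lotka-Volterra core for well-mixed phage-bacteria communities.

The community model: N bacterial strains compete for a single shared resource
(carrying capacity 1, competition coefficients all 1) and are preyed on by M
virulent phage strains through an M x N infection-rate matrix eta:

    dB_i/dt = k_i B_i (1 - sum_j B_j) - alpha B_i - B_i sum_q eta_qi P_q
    dP_q/dt = P_q sum_m beta_q eta_qm B_m - delta P_q

All rates are in units of the maximal bacterial growth rate, all densities in
units of the carrying capacity. ``alpha`` is a universal bacterial death rate
(protist grazing etc.), ``delta`` the phage decay rate, ``beta_q`` the burst
size of phage q.

Steady states are found from the linear system obtained by dividing each
equation by its density; a community is *feasible* when that system is
non-degenerate and all solved densities are strictly positive. Infeasible
communities are relaxed by RK4 integration until a strain crosses a very
small extinction threshold (1e-20 by default), the strain is removed, and
the procedure repeats (``resolve_after_perturbation``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _rk4

#: default extinction threshold (densities below this count as extinct)
EXTINCTION_THRESHOLD = 1e-20

#: condition number above which the linear steady-state system is degenerate
CONDITION_LIMIT = 1e12

#: solved densities below this are treated as numerically zero (degenerate)
DENSITY_FLOOR = 1e-12


class NonConvergenceError(RuntimeError):
    """Integration hit the time horizon without any strain going extinct."""

    def __init__(self, message, state=None, t=None):
        super().__init__(message)
        self.state = state
        self.t = t


@dataclass(frozen=True)
class GlobalRates:
    """Universal bacterial death rate alpha and phage decay rate delta."""

    alpha: float = 0.1
    delta: float = 1.0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")


@dataclass(frozen=True)
class BacteriumStrain:
    id: int
    k: float  # maximal growth rate, in (0, 1]
    birth_step: int = 0

    def __post_init__(self):
        if not 0 < self.k <= 1:
            raise ValueError(f"growth rate k must be in (0, 1], got {self.k}")


@dataclass(frozen=True)
class PhageStrain:
    id: int
    beta: float  # burst size, in [1, 50]
    birth_step: int = 0

    def __post_init__(self):
        if not 1 <= self.beta <= 50:
            raise ValueError(f"burst size beta must be in [1, 50], got {self.beta}")


class Ecosystem:
    """A resident community: strains, infection matrix and global rates.

    ``eta`` is phage-major (M x N); entry ``eta[q, i]`` is the infection rate
    of bacterium i by phage q, 0 exactly where there is no link. Instances
    are treated as immutable; the ``with_*`` / ``drop_*`` helpers return new
    ecosystems sharing no mutable state.
    """

    __slots__ = ("bacteria", "phages", "eta", "rates", "k_vec", "beta_vec")

    def __init__(self, bacteria: Sequence[BacteriumStrain],
                 phages: Sequence[PhageStrain],
                 eta: np.ndarray, rates: GlobalRates = GlobalRates()):
        self.bacteria = tuple(bacteria)
        self.phages = tuple(phages)
        eta = np.ascontiguousarray(np.asarray(eta, dtype=float).reshape(
            len(self.phages), len(self.bacteria)))
        if np.any(eta < 0) or np.any(eta >= 1):
            raise ValueError("eta entries must lie in [0, 1)")
        self.eta = eta
        self.eta.setflags(write=False)
        self.rates = rates
        self.k_vec = np.array([b.k for b in self.bacteria], dtype=float)
        self.beta_vec = np.array([p.beta for p in self.phages], dtype=float)

    def validate(self) -> None:
        """Check the resident-community invariant: every phage has a host.

        Transient ecosystems inside the extinction-resolution loop may
        briefly hold orphaned phages (they are removed in the next round),
        so this is not enforced by the constructor.
        """
        if self.n_phages and not np.all((self.eta > 0).any(axis=1)):
            raise ValueError("every phage must infect at least one bacterium")

    # -- basic views ------------------------------------------------------
    @property
    def n_bacteria(self) -> int:
        return len(self.bacteria)

    @property
    def n_phages(self) -> int:
        return len(self.phages)

    @property
    def n_strains(self) -> int:
        return len(self.bacteria) + len(self.phages)

    def predator_free_bacteria(self) -> list[int]:
        """Indices of bacteria with no phage link."""
        if not self.phages:
            return list(range(self.n_bacteria))
        return [i for i in range(self.n_bacteria)
                if not np.any(self.eta[:, i] > 0)]

    def orphan_phages(self) -> list[int]:
        """Indices of phages left with no host link (they decay as -delta P)."""
        return [q for q in range(self.n_phages)
                if not np.any(self.eta[q, :] > 0)]

    # -- structural edits -------------------------------------------------
    def with_bacterium(self, strain: BacteriumStrain, eta_col: np.ndarray) -> "Ecosystem":
        eta_col = np.asarray(eta_col, dtype=float).reshape(self.n_phages)
        eta = np.hstack([self.eta, eta_col[:, None]]) if self.n_phages else \
            np.zeros((0, self.n_bacteria + 1))
        return Ecosystem(self.bacteria + (strain,), self.phages, eta, self.rates)

    def with_phage(self, strain: PhageStrain, eta_row: np.ndarray) -> "Ecosystem":
        eta_row = np.asarray(eta_row, dtype=float).reshape(self.n_bacteria)
        eta = np.vstack([self.eta, eta_row[None, :]])
        return Ecosystem(self.bacteria, self.phages + (strain,), eta, self.rates)

    def drop_bacterium(self, index: int) -> "Ecosystem":
        keep = [i for i in range(self.n_bacteria) if i != index]
        bacteria = tuple(self.bacteria[i] for i in keep)
        eta = self.eta[:, keep] if self.n_phages else np.zeros((0, len(keep)))
        return Ecosystem(bacteria, self.phages, eta, self.rates)

    def drop_phage(self, index: int) -> "Ecosystem":
        keep = [q for q in range(self.n_phages) if q != index]
        phages = tuple(self.phages[q] for q in keep)
        return Ecosystem(self.bacteria, phages, self.eta[keep, :], self.rates)

    def drop_phages(self, indices: Sequence[int]) -> "Ecosystem":
        drop = set(indices)
        keep = [q for q in range(self.n_phages) if q not in drop]
        return Ecosystem(self.bacteria, tuple(self.phages[q] for q in keep),
                         self.eta[keep, :], self.rates)

    def __repr__(self):
        return (f"Ecosystem(n_bacteria={self.n_bacteria}, "
                f"n_phages={self.n_phages})")


@dataclass
class CommunityState:
    """Population densities aligned with an Ecosystem's strain order."""

    B: np.ndarray
    P: np.ndarray

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float).ravel()
        self.P = np.asarray(self.P, dtype=float).ravel()
        if np.any(self.B < 0) or np.any(self.P < 0):
            raise ValueError("densities must be non-negative")

    def copy(self) -> "CommunityState":
        return CommunityState(self.B.copy(), self.P.copy())


@dataclass
class SteadyStateResult:
    feasible: bool
    state: CommunityState | None = None
    degenerate: bool = False


def derivatives(eco: Ecosystem, state: CommunityState):
    """Right-hand side of the community dynamics, (dB/dt, dP/dt)."""
    if state.B.shape[0] != eco.n_bacteria or state.P.shape[0] != eco.n_phages:
        raise ValueError("state dimensions do not match ecosystem")
    B, P = state.B, state.P
    tot = B.sum()
    dB = B * (eco.k_vec * (1.0 - tot) - eco.rates.alpha - eco.eta.T @ P)
    dP = P * (eco.beta_vec * (eco.eta @ B) - eco.rates.delta)
    return dB, dP


def solve_steady_state(eco: Ecosystem) -> SteadyStateResult:
    """Solve the linear steady-state system and test feasibility.

    Dividing each equation by its (assumed positive) density gives, per
    bacterium i: k_i (1 - sum_j B_j) - alpha - sum_q eta_qi P_q = 0 and per
    phage q: beta_q sum_m eta_qm B_m = delta, an (N+M) x (N+M) linear system
    in (B, P). Feasible iff non-degenerate with all densities positive.
    """
    N, M = eco.n_bacteria, eco.n_phages
    if N + M == 0:
        return SteadyStateResult(True, CommunityState(np.zeros(0), np.zeros(0)))
    A = np.zeros((N + M, N + M))
    b = np.zeros(N + M)
    for i in range(N):
        A[i, :N] = -eco.k_vec[i]
        if M:
            A[i, N:] = -eco.eta[:, i]
        b[i] = eco.rates.alpha - eco.k_vec[i]
    for q in range(M):
        A[N + q, :N] = eco.beta_vec[q] * eco.eta[q, :]
        b[N + q] = eco.rates.delta
    try:
        x = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return SteadyStateResult(False, None, degenerate=True)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        return SteadyStateResult(False, None, degenerate=True)
    near_zero = (x >= 0) & (x < DENSITY_FLOOR)
    if np.any(near_zero):
        return SteadyStateResult(False, None, degenerate=True)
    if np.any(x < 0):
        return SteadyStateResult(False, None, degenerate=False)
    return SteadyStateResult(True, CommunityState(x[:N], x[N:]))


def integrate_until_extinction(eco: Ecosystem, init: CommunityState,
                               threshold: float = EXTINCTION_THRESHOLD,
                               h_max: float = 0.1,
                               t_max: float = 1e6):
    """RK4-integrate from ``init`` until one strain drops below ``threshold``.

    Returns ``(kind, index, state, t)`` with kind "bacterium" or "phage".
    Raises NonConvergenceError if no strain goes extinct before ``t_max``
    (the diagnostic state is attached to the exception).
    """
    if init.B.shape[0] != eco.n_bacteria or init.P.shape[0] != eco.n_phages:
        raise ValueError("state dimensions do not match ecosystem")
    status, kind, idx, t, B, P = _rk4.rk4_until_extinction(
        eco.k_vec, eco.rates.alpha, eco.eta, eco.beta_vec, eco.rates.delta,
        init.B.astype(float), init.P.astype(float), threshold, h_max, t_max)
    if status == _rk4.EXTINCT:
        return ("bacterium" if kind == 0 else "phage", idx,
                CommunityState(B, P), t)
    state = CommunityState(B, P)
    if status == _rk4.NO_EXTINCTION:
        raise NonConvergenceError(
            f"no extinction within t_max={t_max}", state=state, t=t)
    raise NonConvergenceError(
        f"RK4 step could not be stabilized at t={t}", state=state, t=t)


def resolve_after_perturbation(eco: Ecosystem, init: CommunityState,
                               threshold: float = EXTINCTION_THRESHOLD,
                               h_max: float = 0.1,
                               t_max: float = 1e6):
    """Relax a perturbed community to a feasible steady state.

    Alternates steady-state solving with integration-to-extinction, removing
    one strain per round (phages stranded without hosts are removed directly:
    their dynamics are exactly dP/dt = -delta P). Terminates because every
    round removes at least one strain.

    Returns ``(ecosystem, state, extinct_ids)``.
    """
    extinct: list[int] = []
    state = init.copy()
    while True:
        orphans = eco.orphan_phages()
        if orphans:
            extinct.extend(eco.phages[q].id for q in orphans)
            keep = [q for q in range(eco.n_phages) if q not in set(orphans)]
            state = CommunityState(state.B, state.P[keep])
            eco = eco.drop_phages(orphans)
            continue
        res = solve_steady_state(eco)
        if res.feasible:
            return eco, res.state, extinct
        kind, idx, at_ext, _t = integrate_until_extinction(
            eco, state, threshold=threshold, h_max=h_max, t_max=t_max)
        if kind == "bacterium":
            extinct.append(eco.bacteria[idx].id)
            keep = [i for i in range(eco.n_bacteria) if i != idx]
            state = CommunityState(at_ext.B[keep], at_ext.P)
            eco = eco.drop_bacterium(idx)
        else:
            extinct.append(eco.phages[idx].id)
            keep = [q for q in range(eco.n_phages) if q != idx]
            state = CommunityState(at_ext.B, at_ext.P[keep])
            eco = eco.drop_phage(idx)


# -- serialization --------------------------------------------------------

def ecosystem_to_dict(eco: Ecosystem, state: CommunityState | None = None) -> dict:
    """JSON-ready snapshot: strains, eta (phage-major rows), rates, densities."""
    doc = {
        "bacteria": [{"id": b.id, "k": b.k, "birth_step": b.birth_step}
                     for b in eco.bacteria],
        "phages": [{"id": p.id, "beta": p.beta, "birth_step": p.birth_step}
                   for p in eco.phages],
        "eta": eco.eta.tolist(),
        "alpha": eco.rates.alpha,
        "delta": eco.rates.delta,
    }
    if state is not None:
        doc["B"] = state.B.tolist()
        doc["P"] = state.P.tolist()
    return doc


def ecosystem_from_dict(doc: dict):
    """Inverse of :func:`ecosystem_to_dict`; returns (eco, state or None)."""
    bacteria = [BacteriumStrain(d["id"], d["k"], d["birth_step"])
                for d in doc["bacteria"]]
    phages = [PhageStrain(d["id"], d["beta"], d["birth_step"])
              for d in doc["phages"]]
    eta = np.array(doc["eta"], dtype=float).reshape(len(phages), len(bacteria))
    eco = Ecosystem(bacteria, phages, eta,
                    GlobalRates(doc["alpha"], doc["delta"]))
    state = None
    if "B" in doc:
        state = CommunityState(np.array(doc["B"]), np.array(doc["P"]))
    return eco, state


def ecosystem_to_json(eco: Ecosystem, state: CommunityState | None = None) -> str:
    return json.dumps(ecosystem_to_dict(eco, state))


def ecosystem_from_json(text: str):
    return ecosystem_from_dict(json.loads(text))
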