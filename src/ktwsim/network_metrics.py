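"""Network and growth-rate statistics of assembled communities.

Covers the kill-the-winner pairing test (mutual strongest beta*eta links),
diversity statistics, the growth-rate occupancy N_B(k) and entry
distribution p_entry(k), the elimination factor E, the entry advantage G_A,
and the resistant-invader fraction R/B.

Conventions
-----------
The elimination factor is fitted as N_B(k) ~ exp(k / E) on k in [0.3, 0.9]:
E is the *inverse* log-slope, so a larger E means a flatter occupancy
profile, i.e. relatively less advantage for fast growers (a stronger
eliminate-the-winner effect). A steep classical kill-the-winner profile has
E around 0.2; a few cross-links flatten it to around 0.28.

The entry advantage is G_A = slope / (p_entry(0.3) * dk), with the slope and
p_entry(0.3) taken from the log-linear fit of p_entry(k) on the same window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .assembly import AssemblyHistory, BACTERIUM
from .glv_core import Ecosystem

FIT_WINDOW = (0.3, 0.9)


@dataclass
class GrowthRateProfile:
    """Binned growth-rate statistics of one assembly history.

    N_B[b] is the time-averaged number of resident bacteria per unit k in
    bin b (average count / dk); p_entry[b] is the probability density over k
    of growth rates of bacteria that successfully entered, normalized so
    that sum(p_entry) * dk = 1 when any entry occurred.
    """

    bin_edges: np.ndarray
    N_B: np.ndarray
    p_entry: np.ndarray
    n_events: int
    n_entries: int

    @property
    def delta_k(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class EliminationFit:
    E: float
    slope: float
    residual: float
    bins_used: int
    flat: bool = False


@dataclass
class PairingReport:
    fully_paired: bool
    pairs: list[tuple[int, int]]  # (phage id, bacterium id) mutual best links
    unpaired: list[int]  # strain ids outside the matching


def growth_rate_profile(history: AssemblyHistory,
                        delta_k: float = 0.1) -> GrowthRateProfile:
    """Accumulate N_B(k) and p_entry(k) over all logged invasion attempts."""
    if not history.events:
        raise ValueError("history has no events")
    nbins = int(round(1.0 / delta_k))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    occupancy = np.zeros(nbins)
    entries = np.zeros(nbins)
    n_entries = 0
    for ev in history.events:
        ks = [b.k for b in ev.post_eco.bacteria]
        if ks:
            occupancy += np.histogram(ks, bins=edges)[0]
        if ev.invader_kind == BACTERIUM and ev.success:
            entries += np.histogram([ev.invader_param], bins=edges)[0]
            n_entries += 1
    n_events = len(history.events)
    N_B = occupancy / n_events / delta_k
    p_entry = entries / (n_entries * delta_k) if n_entries else entries
    return GrowthRateProfile(edges, N_B, p_entry, n_events, n_entries)


def _window_fit(profile: GrowthRateProfile, values: np.ndarray,
                window=FIT_WINDOW, min_bins: int = 3):
    """Least-squares log-linear fit on bins fully inside the window.

    Zero-count bins are excluded (log undefined; exclusion is unbiased for
    an exponential profile). Returns (slope, intercept, residual, n_bins).
    """
    lo, hi = window
    edges = profile.bin_edges
    sel = (edges[:-1] >= lo - 1e-9) & (edges[1:] <= hi + 1e-9) & (values > 0)
    if sel.sum() < min_bins:
        raise ValueError(
            f"need >= {min_bins} positive bins in [{lo}, {hi}], "
            f"got {int(sel.sum())}")
    x = profile.centers[sel]
    y = np.log(values[sel])
    (slope, intercept), res, *_ = np.polyfit(x, y, 1, full=True)
    residual = float(res[0]) if len(res) else 0.0
    return float(slope), float(intercept), residual, int(sel.sum())


def elimination_factor(profile: GrowthRateProfile,
                       window=FIT_WINDOW) -> EliminationFit:
    """Fit N_B(k) ~ exp(k/E) on the window; E is the inverse log-slope."""
    slope, _intercept, residual, nbins = _window_fit(profile, profile.N_B,
                                                     window)
    if abs(slope) < 1e-12:
        return EliminationFit(math.inf, slope, residual, nbins, flat=True)
    return EliminationFit(1.0 / slope, slope, residual, nbins)


def entry_advantage(profile: GrowthRateProfile,
                    window=FIT_WINDOW) -> float:
    """G_A = fitted log-slope of p_entry normalized by p_entry(0.3) * dk."""
    slope, intercept, _res, _n = _window_fit(profile, profile.p_entry, window)
    p03 = math.exp(intercept + slope * window[0])
    return slope / (p03 * profile.delta_k)


# -- kill-the-winner pairing ----------------------------------------------

def is_kill_the_winner_paired(eco: Ecosystem) -> PairingReport:
    """Do mutual strongest beta*eta links pair every phage with a bacterium?

    Fully paired iff every phage's strongest prey link and that bacterium's
    strongest predator link coincide, the map is a perfect matching of all
    phages onto an equal number of bacteria, and at most one (predator-free)
    bacterium stays outside the matching — the balanced-diversity state
    N_bacteria = N_phages + 1 still counts as paired.
    """
    M, N = eco.n_phages, eco.n_bacteria
    if M == 0:
        unpaired = [b.id for b in eco.bacteria]
        return PairingReport(N <= 1, [], unpaired)
    W = eco.beta_vec[:, None] * eco.eta  # M x N link strengths
    best_prey = np.argmax(W, axis=1)  # per phage
    col_max = W.max(axis=0)
    pairs = []
    matched_bacteria = set()
    ok = True
    for q in range(M):
        i = int(best_prey[q])
        if W[q, i] <= 0 or W[q, i] < col_max[i] or i in matched_bacteria:
            ok = False
            break
        # W[q,i] == col_max[i]: phage q is also bacterium i's strongest enemy
        matched_bacteria.add(i)
        pairs.append((eco.phages[q].id, eco.bacteria[i].id))
    if not ok:
        ids = [s.id for s in eco.bacteria + eco.phages]
        return PairingReport(False, [], ids)
    outside = [i for i in range(N) if i not in matched_bacteria]
    predator_free = set(eco.predator_free_bacteria())
    fully = len(outside) <= 1 and all(i in predator_free for i in outside)
    unpaired = [eco.bacteria[i].id for i in outside]
    return PairingReport(fully, pairs, unpaired)


def ktw_fraction(histories: Iterable[AssemblyHistory]) -> float:
    """Fraction of logged stable communities that are fully KtW-paired.

    Counts every post-event community with at least one phage and one
    bacterium (pairing is undefined for phage-free states).
    """
    n_total = 0
    n_paired = 0
    for history in histories:
        for ev in history.events:
            eco = ev.post_eco
            if eco.n_phages >= 1 and eco.n_bacteria >= 1:
                n_total += 1
                if is_kill_the_winner_paired(eco).fully_paired:
                    n_paired += 1
    if n_total == 0:
        raise ValueError("no stable communities with phages were logged")
    return n_paired / n_total


# -- diversity and invader statistics -------------------------------------

def strain_counts(history: AssemblyHistory) -> pd.DataFrame:
    """Per-attempt community sizes (the diversity time series of a run)."""
    rows = [(ev.step, ev.post_eco.n_bacteria, ev.post_eco.n_phages,
             ev.invader_kind, ev.success, len(ev.extinct_ids))
            for ev in history.events]
    return pd.DataFrame(rows, columns=["step", "n_bacteria", "n_phages",
                                       "invader_kind", "success", "n_extinct"])


def diversity_stats(histories_by_p: dict[float, Sequence[AssemblyHistory]]
                    ) -> pd.DataFrame:
    """Mean time-averaged and mean maximal total strain count per p."""
    rows = []
    for p, histories in sorted(histories_by_p.items()):
        avgs, maxs = [], []
        for h in histories:
            totals = np.array([ev.post_eco.n_strains for ev in h.events])
            avgs.append(totals.mean())
            maxs.append(totals.max())
        rows.append((p, float(np.mean(avgs)), float(np.mean(maxs))))
    return pd.DataFrame(rows, columns=["p", "avg_diversity", "max_diversity"])


def resistant_invader_fraction(history: AssemblyHistory) -> float:
    """R/B: among successful diversity-increasing bacterial invasions, the
    fraction whose invader was resistant to all resident phages at entry."""
    n = 0
    resistant = 0
    for base_eco, _s, ev in history.iter_with_base():
        if ev.invader_kind != BACTERIUM or not ev.success:
            continue
        if ev.post_eco.n_strains <= base_eco.n_strains:
            continue
        n += 1
        if not np.any(ev.invader_links > 0):
            resistant += 1
    if n == 0:
        raise ValueError("no diversity-increasing bacterial invasions logged")
    return resistant / n
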