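"""Run-directory serialization: config echo, JSON-lines event log, TSVs.

A run directory contains

* ``config.json`` — the resolved AssemblyConfig,
* ``initial.json`` — snapshot of the starting one-bacterium community,
* ``events.jsonl`` — one record per invasion attempt, including the full
  post-event ecosystem snapshot (strains, eta, densities),
* ``summary.tsv`` — step, n_bacteria, n_phages, invader_kind, success,
  n_extinct.

Everything is plain text and round-trips losslessly at full float precision
(Python's JSON emits shortest-repr doubles).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .assembly import AssemblyConfig, AssemblyHistory, InvasionEvent
from .glv_core import (CommunityState, GlobalRates, ecosystem_from_dict,
                       ecosystem_to_dict)
from .network_metrics import strain_counts


def config_to_dict(config: AssemblyConfig) -> dict:
    return {
        "model": config.model, "p": config.p, "n_steps": config.n_steps,
        "seed": config.seed, "inoculum": config.inoculum,
        "threshold": config.threshold, "alpha": config.rates.alpha,
        "delta": config.rates.delta, "h_max": config.h_max,
        "t_max": config.t_max,
    }


def config_from_dict(doc: dict) -> AssemblyConfig:
    return AssemblyConfig(
        model=doc["model"], p=doc["p"], n_steps=doc["n_steps"],
        seed=doc["seed"], inoculum=doc.get("inoculum", 1e-6),
        threshold=doc.get("threshold", 1e-20),
        rates=GlobalRates(doc.get("alpha", 0.1), doc.get("delta", 1.0)),
        h_max=doc.get("h_max", 0.05), t_max=doc.get("t_max", 1e5))


def event_to_dict(ev: InvasionEvent) -> dict:
    return {
        "step": ev.step,
        "invader_kind": ev.invader_kind,
        "invader_id": ev.invader_id,
        "invader_param": ev.invader_param,
        "invader_links": np.asarray(ev.invader_links).tolist(),
        "success": ev.success,
        "discarded": ev.discarded,
        "non_convergent": ev.non_convergent,
        "extinct_ids": list(ev.extinct_ids),
        "pre_B": ev.pre_state.B.tolist(),
        "pre_P": ev.pre_state.P.tolist(),
        "post_eco": ecosystem_to_dict(ev.post_eco, ev.post_state),
    }


def event_from_dict(doc: dict) -> InvasionEvent:
    eco, state = ecosystem_from_dict(doc["post_eco"])
    return InvasionEvent(
        step=doc["step"], invader_kind=doc["invader_kind"],
        invader_id=doc["invader_id"], invader_param=doc["invader_param"],
        invader_links=np.array(doc["invader_links"], dtype=float),
        success=doc["success"], extinct_ids=list(doc["extinct_ids"]),
        pre_state=CommunityState(np.array(doc["pre_B"]),
                                 np.array(doc["pre_P"])),
        post_state=state, post_eco=eco,
        discarded=doc.get("discarded", False),
        non_convergent=doc.get("non_convergent", False))


def save_run(history: AssemblyHistory, outdir: str | Path) -> Path:
    """Write config.json, initial.json, events.jsonl and summary.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(
        json.dumps(config_to_dict(history.config), indent=2) + "\n")
    (outdir / "initial.json").write_text(
        json.dumps(ecosystem_to_dict(history.initial_eco,
                                     history.initial_state)) + "\n")
    with open(outdir / "events.jsonl", "w") as fh:
        for ev in history.events:
            fh.write(json.dumps(event_to_dict(ev)) + "\n")
    strain_counts(history).to_csv(outdir / "summary.tsv", sep="\t",
                                  index=False)
    return outdir


def load_run(rundir: str | Path) -> AssemblyHistory:
    """Reconstruct an AssemblyHistory from a run directory."""
    rundir = Path(rundir)
    config = config_from_dict(json.loads((rundir / "config.json").read_text()))
    eco, state = ecosystem_from_dict(
        json.loads((rundir / "initial.json").read_text()))
    events = []
    with open(rundir / "events.jsonl") as fh:
        for line in fh:
            if line.strip():
                events.append(event_from_dict(json.loads(line)))
    return AssemblyHistory(config, eco, state, events)
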