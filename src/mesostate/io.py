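"""Plain-text readers and writers for pipeline artifacts.

Recordings travel as a CSV sample matrix plus a JSON sidecar (channel
names, rate, device, events); chains, fits and reports are JSON.  All
writers are byte-deterministic for a given input so artifact hashes can
be used for caching.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .dynamics import SessionFit
from .types import (
    Annotation,
    EEGRecording,
    InvalidInputError,
    ObservationMatrix,
    ProcessNoise,
    SessionChain,
    TransitionMatrix,
)

# ---------------------------------------------------------------------------
# recordings: <prefix>.csv + <prefix>.json
# ---------------------------------------------------------------------------


def save_recording(rec: EEGRecording, prefix) -> tuple[Path, Path]:
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    meta_path = prefix.with_suffix(".json")
    header = ",".join(rec.channel_names)
    np.savetxt(csv_path, rec.data.T, delimiter=",", header=header, comments="")
    meta = {
        "channel_names": list(rec.channel_names),
        "sampling_rate": rec.sampling_rate,
        "device": rec.device,
        "annotations": [
            {"onset": a.onset, "duration": a.duration, "label": a.label, "valid": a.valid}
            for a in rec.annotations
        ],
    }
    meta_path.write_text(json.dumps(meta, sort_keys=True))
    return csv_path, meta_path


def load_recording(prefix) -> EEGRecording:
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    meta_path = prefix.with_suffix(".json")
    for p in (csv_path, meta_path):
        if not p.exists():
            raise InvalidInputError(f"missing recording file: {p}")
    meta = json.loads(meta_path.read_text())
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2).T
    return EEGRecording(
        data=data,
        channel_names=meta["channel_names"],
        sampling_rate=meta["sampling_rate"],
        device=meta.get("device", "synthetic"),
        annotations=[Annotation(**a) for a in meta.get("annotations", [])],
    )


# ---------------------------------------------------------------------------
# chains (network-level archives)
# ---------------------------------------------------------------------------


def chain_to_jsonable(chain: SessionChain) -> dict:
    return {
        "session_id": chain.session_id,
        "condition": chain.condition,
        "states": [x.to_jsonable() for x in chain.states],
        "noise": [w.to_jsonable() for w in chain.noise] if chain.noise else None,
    }


def chain_from_jsonable(obj: dict) -> SessionChain:
    return SessionChain(
        session_id=obj["session_id"],
        condition=obj["condition"],
        states=[ObservationMatrix.from_jsonable(x) for x in obj["states"]],
        noise=(
            [ProcessNoise.from_jsonable(w) for w in obj["noise"]]
            if obj.get("noise")
            else None
        ),
    )


def _wrap(items: list, meta: dict | None) -> str:
    if meta is None:
        return json.dumps(items)
    return json.dumps({"meta": meta, "items": items})


def _unwrap(path) -> tuple[list, dict]:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"missing archive: {path}")
    payload = json.loads(path.read_text())
    if isinstance(payload, dict) and "items" in payload:
        return payload["items"], payload.get("meta", {})
    return payload, {}


def save_chains(chains: list[SessionChain], path, meta: dict | None = None) -> None:
    Path(path).write_text(_wrap([chain_to_jsonable(c) for c in chains], meta))


def load_chains(path) -> list[SessionChain]:
    items, _ = _unwrap(path)
    return [chain_from_jsonable(o) for o in items]


def read_meta(path) -> dict:
    """Metadata block of an archive ({} for bare archives)."""
    _, meta = _unwrap(path)
    return meta


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------


def fit_to_jsonable(fit: SessionFit, include_chain: bool = True) -> dict:
    return {
        "session_id": fit.session_id,
        "condition": fit.condition,
        "consensus_A": fit.consensus_A.to_jsonable(),
        "per_iteration_f1": fit.per_iteration_f1,
        "final_noise": [w.to_jsonable() for w in fit.final_noise],
        "final_transitions": [a.to_jsonable() for a in fit.final_transitions],
        "b0_final": fit.b0_final.to_jsonable(),
        "iterations_used": fit.iterations_used,
        "converged": fit.converged,
        "chain": chain_to_jsonable(fit.chain) if include_chain and fit.chain else None,
    }


def fit_from_jsonable(obj: dict) -> SessionFit:
    return SessionFit(
        session_id=obj["session_id"],
        condition=obj["condition"],
        consensus_A=TransitionMatrix.from_jsonable(obj["consensus_A"]),
        per_iteration_f1=[float(v) for v in obj["per_iteration_f1"]],
        final_noise=[ProcessNoise.from_jsonable(w) for w in obj["final_noise"]],
        final_transitions=[
            TransitionMatrix.from_jsonable(a) for a in obj["final_transitions"]
        ],
        b0_final=ProcessNoise.from_jsonable(obj["b0_final"]),
        iterations_used=obj["iterations_used"],
        converged=obj["converged"],
        chain=chain_from_jsonable(obj["chain"]) if obj.get("chain") else None,
    )


def save_fits(fits: list[SessionFit], path, meta: dict | None = None) -> None:
    Path(path).write_text(_wrap([fit_to_jsonable(f) for f in fits], meta))


def load_fits(path) -> list[SessionFit]:
    items, _ = _unwrap(path)
    return [fit_from_jsonable(o) for o in items]
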