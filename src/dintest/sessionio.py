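"""Session logs and configuration files.

A session log is JSON lines: a ``meta`` record (seed, condition, config
snapshot, timestamp), one ``trial`` record per presentation, and a final
``result`` record with the SRT. The config snapshot suffices to re-run
the session bit-identically. Config files are plain ``key = value`` text
mirroring the staircase and timing parameters; dB values are serialized
to two decimals, internal computation keeps full precision.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path

from .staircase import SrtResult, TrackConfig, TrackState
from .triplets import TimingConfig


class SessionFormatError(ValueError):
    """Malformed session log or config file; message carries file and line."""


def _round_floats(obj):
    if isinstance(obj, float):
        return round(obj, 2)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def write_session(path: str | Path, result: SrtResult, state: TrackState,
                  seed: int, condition: str) -> None:
    meta = {
        "type": "meta", "seed": seed, "condition": condition,
        "config": dataclasses.asdict(state.cfg),
        "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    res = {
        "type": "result",
        "srt_db": None if result.srt_db is None else round(result.srt_db, 2),
        "n_trials": result.n_trials,
        "reversal_snrs": [round(r, 2) for r in result.reversal_snrs],
        "converged": result.converged,
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(_round_floats(meta)) + "\n")
        for tr in state.trials:
            fh.write(json.dumps({"type": "trial", **tr.to_json_dict()}) + "\n")
        fh.write(json.dumps(res) + "\n")


def read_session(path: str | Path) -> dict:
    """Parse a session log into {meta, trials, result}."""
    out = {"meta": None, "trials": [], "result": None}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as e:
                raise SessionFormatError(f"{path}:{i}: invalid JSON ({e.msg})") from e
            kind = rec.get("type")
            if kind == "meta":
                out["meta"] = rec
            elif kind == "trial":
                out["trials"].append(rec)
            elif kind == "result":
                out["result"] = rec
            else:
                raise SessionFormatError(f"{path}:{i}: unknown record type {kind!r}")
    if out["result"] is None:
        raise SessionFormatError(f"{path}: missing result record")
    return out


def read_config(path: str | Path) -> dict[str, float]:
    """Read a ``key = value`` config file into a flat dict of floats/ints."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            s = line.split("#")[0].strip()
            if not s:
                continue
            if "=" not in s:
                raise SessionFormatError(f"{path}:{i}: expected 'key = value'")
            k, v = (part.strip() for part in s.split("=", 1))
            try:
                out[k] = int(v) if v.lstrip("+-").isdigit() else float(v)
            except ValueError as e:
                raise SessionFormatError(f"{path}:{i}: non-numeric value {v!r}") from e
    return out


def track_config_from_dict(d: dict, condition: str = "0") -> TrackConfig:
    fields = {f.name for f in dataclasses.fields(TrackConfig)}
    kw = {k: v for k, v in d.items() if k in fields}
    return TrackConfig.for_condition(condition, **kw)


def timing_config_from_dict(d: dict) -> TimingConfig:
    fields = {f.name for f in dataclasses.fields(TimingConfig)}
    return TimingConfig(**{k: v for k, v in d.items() if k in fields})
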