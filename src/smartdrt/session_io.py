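"""Trial-log and result-file round-tripping, config files, and replay.

Trial logs are plain CSV with a version line, one row per presented
trial.  Reading back a written log reproduces the records field for
field, and replaying a log through the engine reproduces the logged
posterior exactly (the update rule is deterministic on fixed data and
exchangeable, so row order does not affect the final posterior).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .audiogram import Audiogram
from .engine import Posterior, TrialRecord, build_prior, map_fe, update_posterior
from .excitation import SignalSpec, Stimulus
from .scales import hz_from_cam

__all__ = [
    "LOG_VERSION",
    "write_log",
    "read_log",
    "replay_estimate",
    "ReplayResult",
    "RunConfigFile",
    "write_result_json",
    "export_posterior_csv",
    "export_marginal_csv",
]

LOG_VERSION = 1
_COLUMNS = [
    "index", "phase", "f_mask_hz", "l_mask_db_hl", "is_catch", "response",
    "mi_bits", "fe_map_cam", "posterior_entropy_bits", "rng_call_count",
]


def _fmt(x: Optional[float]) -> str:
    """Shortest exact round-trip representation (lossless re-parse)."""
    if x is None:
        return ""
    return repr(float(x))


def write_log(path, trials) -> None:
    """Write trial records to a versioned CSV."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# smartdrt_log_version={LOG_VERSION}\n")
        w = csv.writer(fh)
        w.writerow(_COLUMNS)
        for t in trials:
            w.writerow([
                t.index, t.phase, _fmt(t.x.f_mask_hz), _fmt(t.x.l_mask_db),
                t.is_catch, t.y, _fmt(t.mi_bits), _fmt(t.fe_map_cam),
                _fmt(t.posterior_entropy_bits), t.rng_call_count,
            ])


def _parse_bool(s: str, row: int, col: str) -> bool:
    if s == "True":
        return True
    if s == "False":
        return False
    raise ValueError(f"row {row}: column {col!r} must be True/False, got {s!r}")


def read_log(path) -> list[TrialRecord]:
    """Read a trial log written by :func:`write_log`; lossless round trip."""
    with open(path, newline="") as fh:
        first = fh.readline().strip()
        if not first.startswith("# smartdrt_log_version="):
            raise ValueError("not a trial log: missing version line")
        version = int(first.split("=", 1)[1])
        if version != LOG_VERSION:
            raise ValueError(
                f"log version {version} not supported (expected {LOG_VERSION})"
            )
        reader = csv.DictReader(fh)
        if reader.fieldnames != _COLUMNS:
            raise ValueError(f"unexpected log columns: {reader.fieldnames}")
        out = []
        for i, row in enumerate(reader, start=1):
            try:
                phase = row["phase"]
                rec = TrialRecord(
                    index=int(row["index"]),
                    x=Stimulus(float(row["f_mask_hz"]), float(row["l_mask_db_hl"])),
                    y=_parse_bool(row["response"], i, "response"),
                    is_catch=_parse_bool(row["is_catch"], i, "is_catch"),
                    is_practice=(phase == "practice"),
                    phase=phase,
                    mi_bits=float(row["mi_bits"]) if row["mi_bits"] else None,
                    fe_map_cam=float(row["fe_map_cam"]) if row["fe_map_cam"] else None,
                    posterior_entropy_bits=(
                        float(row["posterior_entropy_bits"])
                        if row["posterior_entropy_bits"] else None
                    ),
                    rng_call_count=int(row["rng_call_count"]),
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"malformed log row {i}: {exc}") from exc
            out.append(rec)
    return out


@dataclass
class ReplayResult:
    """Inference-only rerun of a logged session."""

    posterior: Posterior
    fe_map_trace: list[float]
    final_fe_cam: float
    final_fe_hz: float
    n_inference_trials: int


def replay_estimate(
    trials,
    a: Audiogram,
    sig: SignalSpec,
    sd_db: float = 3.0,
    lapse: float = 0.01,
) -> ReplayResult:
    """Recompute the posterior from logged trials only (no selection)."""
    posterior = build_prior(a, sig)
    trace = []
    n = 0
    for t in trials:
        if t.is_practice or t.is_catch:
            continue
        posterior = update_posterior(posterior, t, sig, a, sd_db=sd_db, lapse=lapse)
        trace.append(map_fe(posterior))
        n += 1
    fe_cam = map_fe(posterior)
    return ReplayResult(
        posterior=posterior, fe_map_trace=trace, final_fe_cam=fe_cam,
        final_fe_hz=hz_from_cam(fe_cam), n_inference_trials=n,
    )


# ---------------------------------------------------------------------------
# posterior exports
# ---------------------------------------------------------------------------

def export_posterior_csv(path, p: Posterior) -> None:
    """CSV snapshot (fe_cam, ohcl_db, probability) over admissible cells."""
    g = p.grid
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["fe_cam", "ohcl_db", "probability"])
        for cam, ohcl, pr in zip(g.cell_fe_cam, g.cell_ohcl_db, p.prob):
            w.writerow([_fmt(cam), _fmt(ohcl), _fmt(pr)])


def export_marginal_csv(path, p: Posterior) -> None:
    """CSV of the f_e marginal (fe_cam, probability)."""
    from .engine import marginal_fe

    m = marginal_fe(p)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["fe_cam", "probability"])
        for cam, pr in zip(p.grid.fe_cam, m):
            w.writerow([_fmt(cam), _fmt(pr)])


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_SESSION_KEYS = {
    "n_active_trials", "n_catch", "n_practice", "sd_db", "lapse",
    "weight_sigma_cam", "exclusion_radius_cam", "rng_seed", "adaptive_sd",
    "sd_floor_db", "sd_restart_db", "enable_early_stop",
    "stop_mi_threshold_bits", "background_ten_db",
}
_PATH_KEYS = {"audiogram", "profile", "log", "out"}


@dataclass
class RunConfigFile:
    """Parsed YAML run configuration (unknown keys rejected)."""

    session: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    mode: str = "simulate"

    @classmethod
    def load(cls, path) -> "RunConfigFile":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {"session", "paths", "mode"}
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        session = raw.get("session") or {}
        bad = set(session) - _SESSION_KEYS
        if bad:
            raise ValueError(f"unknown session keys: {sorted(bad)}")
        paths = raw.get("paths") or {}
        bad = set(paths) - _PATH_KEYS
        if bad:
            raise ValueError(f"unknown path keys: {sorted(bad)}")
        mode = raw.get("mode", "simulate")
        if mode not in ("simulate", "replay"):
            raise ValueError(f"mode must be 'simulate' or 'replay', got {mode!r}")
        return cls(session=session, paths=paths, mode=mode)

    def session_config(self, **overrides):
        from .active import SessionConfig

        kwargs = dict(self.session)
        kwargs.update(overrides)
        return SessionConfig(**kwargs)


def _round_floats(obj, sig_digits: int = 12):
    if isinstance(obj, float):
        return float(f"{obj:.{sig_digits}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig_digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig_digits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), sig_digits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig_digits)
    return obj


def write_result_json(path, result) -> None:
    """Serialise a session result (config echo, final estimate, traces,
    flags) with 12-significant-digit floats for cross-platform stability."""
    from dataclasses import asdict

    payload = {
        "config": asdict(result.config),
        "final_fe_cam": result.final_fe_cam,
        "final_fe_hz": result.final_fe_hz,
        "fe_map_trace_cam": list(result.fe_map_trace),
        "mi_trace_bits": list(result.mi_trace),
        "posterior_trace": result.posterior_trace,
        "sd_trace_db": list(result.sd_trace),
        "flags": list(result.flags),
        "n_trials_presented": len(result.trials),
    }
    with open(path, "w") as fh:
        json.dump(_round_floats(payload), fh, indent=1)
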