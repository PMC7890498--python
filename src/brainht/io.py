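"""Result serialization: delimited time-series tables and JSON summaries.

Every artefact embeds enough provenance (parameter values, their hash, the
seed, schedule and solver settings) to re-run it exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

from .scenarios import SimulationResult, SummaryMetrics

try:  # single source for the version string
    from importlib.metadata import version

    __version__ = version("brainht")
except Exception:  # pragma: no cover - not installed
    __version__ = "unknown"

__all__ = ["config_hash", "write_timeseries", "write_summary", "provenance"]

_FLOAT_FMT = "%.12g"  # >= 10 significant digits, round-trips float64 closely


def config_hash(params_dict: dict) -> str:
    """Stable short hash of a parameter mapping."""
    blob = json.dumps(params_dict, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance(result: SimulationResult) -> dict:
    params = result.params.asdict()
    return {
        "version": __version__,
        "parameters": params,
        "config_hash": config_hash(params),
        "seed": result.seed,
        "fluctuations_on": result.fluctuations_on,
        "schedule": dataclasses.asdict(result.schedule),
        "equilibrium": dataclasses.asdict(result.equilibrium),
    }


def write_timeseries(result: SimulationResult, path: str | Path) -> Path:
    """Write the aligned time series as a tab-separated table."""
    path = Path(path)
    try:
        result.to_frame().to_csv(path, sep="\t", index=False,
                                 float_format=_FLOAT_FMT)
    except OSError as exc:
        raise OSError(f"cannot write time series to {path}: {exc}") from exc
    return path


def write_summary(
    metrics: SummaryMetrics | dict,
    path: str | Path,
    result: SimulationResult | None = None,
    extra: dict | None = None,
) -> Path:
    """Write summary metrics (plus provenance when available) as JSON."""
    path = Path(path)
    payload: dict = {}
    payload["metrics"] = (
        metrics.asdict() if isinstance(metrics, SummaryMetrics) else dict(metrics)
    )
    if result is not None:
        payload["provenance"] = provenance(result)
    if extra:
        payload.update(extra)
    try:
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write summary to {path}: {exc}") from exc
    return path
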