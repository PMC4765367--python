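"""Result serialization: schema-stable CSV tables with JSON sidecars.

Every writer emits the data table as comma-separated UTF-8 CSV (header row
mandatory, ``.`` decimal) plus a JSON sidecar carrying units and a
provenance header (package version, config hash, seed), so any output file
can be traced back to the run that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .doseresponse import DoseResponseResult
from .kinetics import SPECIES, RateConstants, Trajectory
from .zonation import InjuryMap, ZonalProfile

__all__ = [
    "UNITS",
    "provenance",
    "write_trajectory",
    "read_trajectory",
    "write_injury_map",
    "write_dose_response",
    "write_results",
]

#: Units fixed by the kinetics module, documented in every sidecar.
UNITS = {
    "time": "h",
    "concentration": "mM",
    "first_order_rate": "1/h",
    "bimolecular_rate": "1/(mM*h)",
    "production_rate": "mM/h",
    "length": "mm",
    "flow": "mm^3/h",
}


def provenance(seed: int | None = None, config_hash: str | None = None) -> dict:
    """Provenance header for JSON sidecars."""
    header = {"package": "zonasim", "version": __version__}
    if seed is not None:
        header["seed"] = int(seed)
    if config_hash is not None:
        header["config_hash"] = config_hash
    return header


def _write_sidecar(csv_path: Path, payload: dict) -> Path:
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return sidecar


def write_trajectory(
    traj: Trajectory,
    path: str | Path,
    *,
    seed: int | None = None,
    config_hash: str | None = None,
) -> Path:
    """Write a trajectory as `time,P,S,N,G,T,E_sul,E_gluc,C_GSH` CSV + sidecar."""
    path = Path(path)
    traj.to_frame().to_csv(path, index=False, float_format="%.17g")
    _write_sidecar(path, {
        "provenance": provenance(seed, config_hash),
        "units": UNITS,
        "columns": ["time", *SPECIES],
        "params": traj.params.as_dict(),
        "solver": traj.solver_meta,
    })
    return path


def read_trajectory(path: str | Path, params: RateConstants | None = None) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory`.

    If ``params`` is omitted they are recovered from the JSON sidecar.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    expected = ["time", *SPECIES]
    if list(frame.columns) != expected:
        raise ValueError(f"unexpected columns {list(frame.columns)}; expected {expected}")
    if params is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"no params given and sidecar missing: {sidecar}")
        meta = json.loads(sidecar.read_text())
        params = RateConstants(**meta["params"])
    return Trajectory(
        times=frame["time"].to_numpy(),
        states=frame[list(SPECIES)].to_numpy(),
        params=params,
    )


def write_injury_map(
    injury: InjuryMap,
    profile: ZonalProfile,
    path: str | Path,
    *,
    pattern: str | None = None,
    threshold: float | None = None,
    seed: int | None = None,
    config_hash: str | None = None,
) -> Path:
    """Write per-zone results as `z,oxygen,k450,betaG,P0,terminal_T,zone_label`.

    The sidecar carries the injury pattern label and the anoxia flag.
    """
    path = Path(path)
    frame = pd.DataFrame({
        "z": injury.z,
        "oxygen": profile.oxygen,
        "k450": profile.k_450_field,
        "betaG": profile.beta_G_field,
        "P0": profile.P0_field,
        "terminal_T": injury.terminal_T,
        "zone_label": injury.zone_labels,
    })
    frame.to_csv(path, index=False, float_format="%.17g")
    _write_sidecar(path, {
        "provenance": provenance(seed, config_hash),
        "units": UNITS,
        "pattern": pattern if pattern is not None else injury.pattern,
        "anoxic": bool(injury.anoxic),
        "threshold": threshold,
        "monotone_mapping": bool(profile.monotone_mapping),
    })
    return path


def write_dose_response(
    result: DoseResponseResult,
    path: str | Path,
    *,
    seed: int | None = None,
    config_hash: str | None = None,
) -> Path:
    """Write a scan as `dose,metric,survival,fitted_survival` CSV + Hill sidecar."""
    path = Path(path)
    fitted = (result.fitted_survival if result.fitted_survival is not None
              else np.full_like(result.doses, np.nan))
    frame = pd.DataFrame({
        "dose": result.doses,
        "metric": result.metric_values,
        "survival": result.survival,
        "fitted_survival": fitted,
    })
    frame.to_csv(path, index=False, float_format="%.17g")
    fit_block = None
    if result.fit is not None:
        p = result.fit.params
        fit_block = {
            "bottom": p.bottom, "top": p.top, "ec50": p.ec50, "hill_n": p.hill_n,
            "residual_norm": result.fit.residual_norm,
            "success": result.fit.success,
            "identifiable": result.fit.identifiable,
            "increasing": result.fit.increasing,
        }
    _write_sidecar(path, {
        "provenance": provenance(seed, config_hash),
        "units": UNITS,
        "damage_metric": result.metric,
        "hill_fit": fit_block,
    })
    return path


def write_results(result, path: str | Path, format: str = "csv", **kwargs) -> Path:
    """Dispatch on result type; ``format`` must be "csv" (table + JSON sidecar).

    ``InjuryMap`` results additionally require ``profile=`` in ``kwargs``.
    """
    if format not in ("csv", "json"):
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")
    if format == "json":
        # JSON-only export: the sidecar payload with the table inlined.
        path = Path(path)
        if isinstance(result, Trajectory):
            payload = {
                "provenance": provenance(kwargs.get("seed"), kwargs.get("config_hash")),
                "units": UNITS,
                "times": result.times.tolist(),
                "states": {s: result.species(s).tolist() for s in SPECIES},
            }
            path.write_text(json.dumps(payload, indent=2) + "\n")
            return path
        raise ValueError(f"json export not supported for {type(result).__name__}")
    if isinstance(result, Trajectory):
        return write_trajectory(result, path, **kwargs)
    if isinstance(result, InjuryMap):
        profile = kwargs.pop("profile", None)
        if profile is None:
            raise ValueError("writing an InjuryMap requires profile=<ZonalProfile>")
        return write_injury_map(result, profile, path, **kwargs)
    if isinstance(result, DoseResponseResult):
        return write_dose_response(result, path, **kwargs)
    raise TypeError(f"do not know how to write {type(result).__name__}")
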