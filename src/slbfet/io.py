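"""File dialects: CSV sensor traces (+ injection sidecars), whitespace
reflectivity tables, 2/3-column density/potential profiles, FRAP CSVs and
YAML stack configs.

All numeric round-trips are lossless (17 significant digits).  Comment
lines start with ``#``.  Errors carry line numbers / column names.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .electrostatics import PotentialProfile
from .kinetics import InjectionEvent, TimeTrace
from .membrane import FRAPCurve
from .reflectometry import DensityProfile, Medium, ReflectivityCurve, Slab, SlabStack

__all__ = [
    "read_trace", "write_trace",
    "read_injections", "write_injections",
    "read_reflectivity", "write_reflectivity",
    "read_profile", "write_profile", "write_potential",
    "read_frap", "write_frap",
    "load_stack_yaml", "load_template_yaml",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"
PathLike = Union[str, Path]


def _require_columns(df: pd.DataFrame, required: list[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; "
                         f"found {list(df.columns)}")


def read_trace(path: PathLike, injections: Optional[PathLike] = None) -> TimeTrace:
    """Read a sensor trace CSV (``time_s,v_tg_mV`` + optional ``i_d_A``)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    _require_columns(df, ["time_s"], path)
    if "v_tg_mV" not in df.columns and "i_d_A" not in df.columns:
        raise ValueError(f"{path}: need a v_tg_mV or i_d_A column")
    t = df["time_s"].to_numpy(float)
    bad = np.where(np.diff(t) <= 0)[0]
    if len(bad):
        # +2: header line plus 1-based indexing of the first offending row
        raise ValueError(f"{path}: time not strictly increasing at line {bad[0] + 3}")
    events = read_injections(injections) if injections is not None else []
    return TimeTrace(
        t_s=t,
        v_tg_mV=df["v_tg_mV"].to_numpy(float) if "v_tg_mV" in df.columns else None,
        i_d_A=df["i_d_A"].to_numpy(float) if "i_d_A" in df.columns else None,
        injections=events,
    )


def write_trace(trace: TimeTrace, path: PathLike,
                injections: Optional[PathLike] = None) -> None:
    cols: dict[str, np.ndarray] = {"time_s": trace.t_s}
    if trace.v_tg_mV is not None:
        cols["v_tg_mV"] = trace.v_tg_mV
    if trace.i_d_A is not None:
        cols["i_d_A"] = trace.i_d_A
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)
    if injections is not None:
        write_injections(trace.injections, injections)


def read_injections(path: PathLike) -> list[InjectionEvent]:
    """Read an injection sidecar CSV ``time_s,conc_M,label``."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    _require_columns(df, ["time_s", "conc_M"], path)
    labels = df["label"] if "label" in df.columns else [""] * len(df)
    return [
        InjectionEvent(time_s=float(t), analyte_conc_M=float(c),
                       label="" if pd.isna(l) else str(l))
        for t, c, l in zip(df["time_s"], df["conc_M"], labels)
    ]


def write_injections(events: list[InjectionEvent], path: PathLike) -> None:
    pd.DataFrame(
        {"time_s": [e.time_s for e in events],
         "conc_M": [e.analyte_conc_M for e in events],
         "label": [e.label for e in events]}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_reflectivity(path: PathLike) -> ReflectivityCurve:
    """Read a 2- or 3-column whitespace reflectivity table ``q R [sigmaR]``.

    For 2-column files sigma_R is imputed as 2% relative (logged).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)   # empty file warning
        data = np.loadtxt(path, comments="#", ndmin=2)
    if data.size == 0:
        raise ValueError(f"{path}: empty reflectivity file")
    if data.shape[1] not in (2, 3):
        raise ValueError(f"{path}: expected 2 or 3 columns, got {data.shape[1]}")
    q, r = data[:, 0], data[:, 1]
    if np.any(r < 0):
        raise ValueError(f"{path}: negative reflectivity values")
    if data.shape[1] == 2:
        logger.warning("%s: no sigma_R column; imputing 2%% relative", path)
        sigma = 0.02 * r
    else:
        sigma = data[:, 2]
    return ReflectivityCurve(q=q, R=r, sigma_R=sigma)


def write_reflectivity(curve: ReflectivityCurve, path: PathLike,
                       header: str = "q[1/A] R sigmaR") -> None:
    sigma = curve.sigma_R if curve.sigma_R is not None else 0.02 * curve.R
    np.savetxt(path, np.column_stack([curve.q, curve.R, sigma]),
               fmt=_FLOAT_FMT, header=header)


def read_profile(path: PathLike) -> DensityProfile:
    """Read a 2-column ``z[A] rho_e`` profile."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.size == 0 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (z_A, rho_e)")
    return DensityProfile(z_A=data[:, 0], rho_e=data[:, 1])


def write_profile(profile: DensityProfile, path: PathLike,
                  header: str = "z[A] rho_e[e/A^3]") -> None:
    np.savetxt(path, np.column_stack([profile.z_A, profile.rho_e]),
               fmt=_FLOAT_FMT, header=header)


def write_potential(profile: PotentialProfile, path: PathLike) -> None:
    np.savetxt(path,
               np.column_stack([profile.z_A, profile.E_V_per_m, profile.psi_V]),
               fmt=_FLOAT_FMT, header="z[A] E[V/m] psi[V]")


def read_frap(path: PathLike) -> FRAPCurve:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    _require_columns(df, ["time_s", "intensity_norm"], path)
    return FRAPCurve(t_s=df["time_s"].to_numpy(float),
                     intensity=df["intensity_norm"].to_numpy(float))


def write_frap(curve: FRAPCurve, path: PathLike) -> None:
    pd.DataFrame({"time_s": curve.t_s, "intensity_norm": curve.intensity}
                 ).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# YAML stack configs
# ---------------------------------------------------------------------------

_MEDIUM_KEYS = {"rho_e"}
_SLAB_KEYS = {"thickness_A", "rho_e", "roughness_A"}
_STACK_KEYS = {"substrate", "slabs", "ambient", "beam_energy_keV",
               "substrate_roughness_A"}


def _reject_unknown(mapping: dict, allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"{context}: unknown key(s) {sorted(unknown)} "
                         f"(allowed: {sorted(allowed)})")


def load_stack_yaml(path: PathLike) -> SlabStack:
    """Load a fixed slab stack from YAML.

    Schema::

        substrate: {rho_e: 0.66}
        ambient:   {rho_e: 0.334}
        beam_energy_keV: 16.2
        substrate_roughness_A: 3
        slabs:
          - {thickness_A: 8, rho_e: 0.45, roughness_A: 3}
    """
    stack, free = _load_stack(path, allow_bounds=False)
    return stack


def load_template_yaml(path: PathLike) -> tuple[SlabStack, dict[str, tuple[float, float]]]:
    """Load a fit template: scalar entries are fixed, ``[low, high]`` pairs
    are free parameters.  Returns (template stack at bound midpoints, free
    bounds dict keyed by parameter path)."""
    return _load_stack(path, allow_bounds=True)


def _coerce(value, key: str, free: dict, context: str, allow_bounds: bool) -> float:
    if isinstance(value, (list, tuple)):
        if not allow_bounds:
            raise ValueError(f"{context}.{key}: bounds not allowed in a fixed stack")
        if len(value) != 2 or value[1] <= value[0]:
            raise ValueError(f"{context}.{key}: bounds must be [low, high]")
        free[f"{context}.{key}" if context else key] = (float(value[0]), float(value[1]))
        return 0.5 * (float(value[0]) + float(value[1]))
    return float(value)


def _load_stack(path: PathLike, allow_bounds: bool):
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    _reject_unknown(cfg, _STACK_KEYS, str(path))
    free: dict[str, tuple[float, float]] = {}

    def medium(name: str) -> Medium:
        block = cfg.get(name)
        if not isinstance(block, dict):
            raise ValueError(f"{path}: missing or malformed {name!r} block")
        _reject_unknown(block, _MEDIUM_KEYS, f"{path}:{name}")
        return Medium(rho_e=_coerce(block["rho_e"], "rho_e", free, name, allow_bounds))

    substrate, ambient = medium("substrate"), medium("ambient")
    slabs = []
    for i, block in enumerate(cfg.get("slabs", [])):
        _reject_unknown(block, _SLAB_KEYS, f"{path}:slabs[{i}]")
        slabs.append(Slab(
            thickness_A=_coerce(block["thickness_A"], "thickness_A", free,
                                f"slabs[{i}]", allow_bounds),
            rho_e=_coerce(block["rho_e"], "rho_e", free, f"slabs[{i}]", allow_bounds),
            roughness_A=_coerce(block.get("roughness_A", 3.0), "roughness_A",
                                free, f"slabs[{i}]", allow_bounds),
        ))
    stack = SlabStack(
        substrate=substrate, slabs=slabs, ambient=ambient,
        beam_energy_keV=float(cfg.get("beam_energy_keV", 16.2)),
        substrate_roughness_A=_coerce(cfg.get("substrate_roughness_A", 3.0),
                                      "substrate_roughness_A", free, "",
                                      allow_bounds),
    )
    return stack, free
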