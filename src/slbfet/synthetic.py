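"""Synthetic instrument emulation.

Generates every input the analysis pipeline consumes — real-time binding
traces, titration series, specular reflectivity curves, FRAP recovery
curves and FET transfer curves — with the statistical structure the
downstream fitters assume, so the whole chain is testable without an
instrument.

Noise model:
  * traces / titrations: additive Gaussian, sigma in mV (default 0.1 mV);
  * reflectivity: relative Gaussian (default 2%), a Gaussian stand-in for
    photon counting statistics, with the sigma_R column populated;
  * FRAP: additive Gaussian on the normalized intensity (default 0.02).

Every generator is a pure function of its parameters and of
``NoiseSpec.seed``; identical seeds give bit-identical output and there is
no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kinetics import (
    InjectionEvent,
    KineticParams,
    TimeTrace,
    TransferCurve,
    _check_schedule,
    langmuir_response,
    trace_model,
)
from .membrane import FRAPCurve, frap_model
from .reflectometry import ReflectivityCurve, SlabStack, reflectivity

__all__ = [
    "NoiseSpec",
    "gen_binding_trace",
    "gen_titration",
    "gen_reflectivity",
    "gen_frap_curve",
    "gen_transfer_curve",
]

#: FRAP bleach-spot radius default, um (stand-in; configure per experiment)
DEFAULT_BLEACH_RADIUS_UM = 25.0


@dataclass(frozen=True)
class NoiseSpec:
    """Noise amplitudes and the single RNG seed all generators draw from."""

    voltage_sigma_mV: float = 0.1
    reflectivity_relative_sigma: float = 0.02
    intensity_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("voltage_sigma_mV", "reflectivity_relative_sigma",
                     "intensity_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_binding_trace(
    params: KineticParams,
    schedule: Sequence[InjectionEvent],
    duration_s: float,
    dt_s: float,
    noise: NoiseSpec = NoiseSpec(),
    *,
    equilibrium_fraction: bool = True,
    continuous: bool = True,
) -> TimeTrace:
    """Simulate a multi-injection real-time sensor trace.

    Injections superpose: each event starts a fresh model segment
    referenced to its own injection time, whose observed rate uses the
    *cumulative* analyte concentration and whose binding amplitude is the
    increment of the equilibrium amplitude, so the summed plateau equals
    the isotherm value at the cumulative concentration and
    zero-concentration (control) injections add only the RC transient.
    """
    if dt_s <= 0:
        raise ValueError("dt must be > 0")
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    schedule = list(schedule)
    _check_schedule(schedule)
    late = [e for e in schedule if e.time_s > duration_s]
    if late:
        raise ValueError(
            f"injection at t={late[0].time_s}s lies beyond the trace "
            f"duration {duration_s}s"
        )

    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    v = np.zeros_like(t)
    c_cum = 0.0
    amp_prev = 0.0
    for ev in schedule:
        c_cum += ev.analyte_conc_M
        if equilibrium_fraction:
            amp_cum = _plateau(params, c_cum, True)
            amp_inc = amp_cum - amp_prev
            amp_prev = amp_cum
        else:
            # verbatim model: every effective injection contributes a full
            # V_max step, as the printed single-injection formula does
            amp_inc = params.V_max_mV if ev.analyte_conc_M > 0 else 0.0
        seg = KineticParams(
            k1=params.k1, k_minus1=params.k_minus1,
            V_max_mV=amp_inc, V_p_mV=params.V_p_mV,
            tau1_s=params.tau1_s, tau2_s=params.tau2_s, T_s=params.T_s,
        )
        mask = t >= ev.time_s
        # segment amplitude already holds the occupancy increment, so the
        # segment itself is evaluated verbatim
        v[mask] += trace_model(t[mask] - ev.time_s, seg, c_cum,
                               equilibrium_fraction=False,
                               continuous=continuous)
    if noise.voltage_sigma_mV > 0:
        v = v + noise.rng().normal(0.0, noise.voltage_sigma_mV, size=t.shape)
    return TimeTrace(t_s=t, v_tg_mV=v, injections=schedule)


def _plateau(params: KineticParams, conc_M: float, equilibrium_fraction: bool) -> float:
    k_obs = params.k1 * conc_M + params.k_minus1
    if k_obs <= 0:
        return 0.0
    if equilibrium_fraction:
        return params.V_max_mV * params.k1 * conc_M / k_obs
    return params.V_max_mV if conc_M > 0 else 0.0


def gen_titration(
    params: KineticParams,
    concentrations: Sequence[float],
    noise: NoiseSpec = NoiseSpec(),
) -> list[tuple[float, float]]:
    """Equilibrium response amplitudes at a series of concentrations."""
    concs = [float(c) for c in concentrations]
    if not concs:
        raise ValueError("empty concentration list")
    if any(c <= 0 for c in concs):
        raise ValueError("concentrations must be > 0")
    if len(set(concs)) != len(concs):
        raise ValueError("concentrations must be distinct")
    rng = noise.rng()
    out = []
    for c in concs:
        dv = langmuir_response(c, params.K_eq_M, params.V_max_mV)
        if noise.voltage_sigma_mV > 0:
            dv += rng.normal(0.0, noise.voltage_sigma_mV)
        out.append((c, float(dv)))
    return out


def gen_reflectivity(
    stack: SlabStack,
    q_grid,
    noise: NoiseSpec = NoiseSpec(),
) -> ReflectivityCurve:
    """Simulate a specular reflectivity measurement of ``stack``.

    Relative Gaussian noise approximates counting statistics; sigma_R is
    the applied noise level.  With zero noise sigma_R is still populated
    (at a nominal 1e-6 relative floor) so fits stay weighted.
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0) or np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be positive and strictly increasing")
    r_true = reflectivity(stack, q)
    rel = noise.reflectivity_relative_sigma
    if rel > 0:
        r = r_true * (1.0 + noise.rng().normal(0.0, rel, size=q.shape))
        r = np.maximum(r, 1e-15)
        sigma = rel * r_true
    else:
        r = r_true
        sigma = 1e-6 * r_true
    return ReflectivityCurve(q=q, R=r, sigma_R=sigma)


def gen_frap_curve(
    D_um2_per_s: float,
    bleach_radius_um: float = DEFAULT_BLEACH_RADIUS_UM,
    duration_s: float = 600.0,
    dt_s: float = 2.0,
    noise: NoiseSpec = NoiseSpec(),
) -> FRAPCurve:
    """Simulate a normalized FRAP recovery curve."""
    if D_um2_per_s <= 0 or bleach_radius_um <= 0:
        raise ValueError("D and bleach radius must be > 0")
    if dt_s <= 0:
        raise ValueError("dt must be > 0")
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    f = frap_model(t, D_um2_per_s, bleach_radius_um)
    if noise.intensity_sigma > 0:
        f = f + noise.rng().normal(0.0, noise.intensity_sigma, size=t.shape)
    f = np.clip(f, 0.0, 1.2)
    return FRAPCurve(t_s=t, intensity=f)


def gen_transfer_curve(
    gm_A_per_V: float,
    v_range_V: tuple[float, float] = (-0.1, 0.1),
    n_points: int = 201,
    I_offset_A: float = 1e-6,
    shape: str = "linear",
    sigmoid_width_V: float = 0.05,
) -> TransferCurve:
    """FET transfer-curve table I_D(V_TG) with peak transconductance ``gm``.

    ``shape="linear"`` gives I = I_off + gm (V - V_lo); ``"sigmoid"`` a
    logistic curve with maximum slope gm at the midpoint.
    """
    if gm_A_per_V <= 0:
        raise ValueError("gm must be > 0 (monotone transfer curve)")
    if n_points < 2:
        raise ValueError("transfer curve needs >= 2 grid points")
    lo, hi = v_range_V
    if hi <= lo:
        raise ValueError("v_range must be increasing")
    v = np.linspace(lo, hi, n_points)
    if shape == "linear":
        i = I_offset_A + gm_A_per_V * (v - lo)
    elif shape == "sigmoid":
        v0, w = 0.5 * (lo + hi), sigmoid_width_V
        i = I_offset_A + 4.0 * gm_A_per_V * w / (1.0 + np.exp(-(v - v0) / w))
    else:
        raise ValueError(f"unknown transfer-curve shape {shape!r}")
    return TransferCurve(v_tg_V=v, i_d_A=i)
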