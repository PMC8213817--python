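"""Membrane electrostatics: Poisson integration of charge-density
profiles, Debye screening lengths, and the capacitive divider that maps a
membrane dipole-potential change onto the FET top gate.

Binding-induced electron redistribution inside the bilayer, measured as an
electron-density difference profile drho_e(z), acts as a charge density
rho_q(z) = -e * drho_e(z).  Integrating Poisson's equation twice along z,

    E(z)   = (1/eps0) * integral rho_q dz' / eps_r(z)      (E = 0 at the boundary)
    psi(z) = - integral E dz'                              (psi = 0 at the reference)

gives the electric-field and chemical-potential changes across the
membrane.  A fixed capacitive divider (attenuation = dV_TG / dpsi,
calibrated once) then predicts the top-gate response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.constants import Avogadro, Boltzmann, elementary_charge, epsilon_0

__all__ = [
    "ChargeProfile",
    "PotentialProfile",
    "CircuitModel",
    "charge_from_electron_density",
    "field_and_potential",
    "debye_length",
    "gate_attenuation_from_pair",
    "predict_dvtg",
]

A_TO_M = 1e-10


@dataclass
class ChargeProfile:
    """Charge density rho_q(z) in C/m^3 on an Angstrom z-grid."""

    z_A: np.ndarray
    rho_q: np.ndarray

    def __post_init__(self) -> None:
        self.z_A = np.asarray(self.z_A, dtype=float)
        self.rho_q = np.asarray(self.rho_q, dtype=float)
        if self.z_A.ndim != 1 or len(self.z_A) < 2:
            raise ValueError("z grid needs >= 2 points")
        if np.any(np.diff(self.z_A) <= 0):
            raise ValueError("z grid must be strictly increasing")
        if self.rho_q.shape != self.z_A.shape or not np.all(np.isfinite(self.rho_q)):
            raise ValueError("rho_q must be finite and match z in length")


@dataclass
class PotentialProfile:
    """Electric field E(z) [V/m] and potential psi(z) [V] on a z-grid [A]."""

    z_A: np.ndarray
    E_V_per_m: np.ndarray
    psi_V: np.ndarray


@dataclass(frozen=True)
class CircuitModel:
    """Capacitive-divider model: the fraction of a membrane potential
    change that appears at the top gate."""

    attenuation: float

    def __post_init__(self) -> None:
        if not 0.0 < self.attenuation <= 1.0:
            raise ValueError("attenuation must be in (0, 1]")

    @classmethod
    def from_capacitances(cls, C_membrane_path_F: float, C_TG_F: float) -> "CircuitModel":
        """Divider ratio C_path / (C_path + C_TG) of a series pair."""
        if C_membrane_path_F <= 0 or C_TG_F <= 0:
            raise ValueError("capacitances must be > 0")
        return cls(C_membrane_path_F / (C_membrane_path_F + C_TG_F))


def charge_from_electron_density(
    z_A, delta_rho_e, *, sign: float = -1.0
) -> ChargeProfile:
    """Convert an electron-density difference (e/A^3) to charge density.

    An *excess* of electrons is negative charge, hence the default
    ``sign=-1``: rho_q = sign * e * drho_e * 1e30 C/m^3.
    """
    drho = np.asarray(delta_rho_e, dtype=float)
    return ChargeProfile(z_A=np.asarray(z_A, float),
                         rho_q=sign * elementary_charge * drho * 1e30)


def field_and_potential(
    charge: ChargeProfile,
    eps_r: Union[float, np.ndarray] = 78.5,
    bc: Union[str, float] = "substrate-zero",
) -> PotentialProfile:
    """Integrate Poisson's equation for E(z) and psi(z).

    The grid is resampled to uniform spacing (the minimum input spacing)
    and integrated with cumulative trapezoids.  ``eps_r`` may be a scalar
    or a per-sample profile on the input grid (the displacement field is
    integrated first, then divided by eps0*eps_r, so dielectric steps are
    handled).  ``bc`` selects where E = 0 and psi = 0 are anchored:
    ``"substrate-zero"`` (z_min), ``"ambient-zero"`` (z_max), or a z
    position (A) inside the grid.
    """
    z_in = charge.z_A
    dz = float(np.min(np.diff(z_in)))
    z = np.arange(z_in[0], z_in[-1] + dz / 2, dz)
    rho = np.interp(z, z_in, charge.rho_q)
    if np.isscalar(eps_r) or np.ndim(eps_r) == 0:
        eps = np.full_like(z, float(eps_r))
    else:
        eps_arr = np.asarray(eps_r, dtype=float)
        if eps_arr.shape != z_in.shape:
            raise ValueError("eps_r profile must match the input z grid")
        eps = np.interp(z, z_in, eps_arr)
    if np.any(eps <= 0):
        raise ValueError("eps_r must be > 0")

    if bc == "substrate-zero":
        z_ref = z[0]
    elif bc == "ambient-zero":
        z_ref = z[-1]
    else:
        z_ref = float(bc)
        if not z[0] <= z_ref <= z[-1]:
            raise ValueError(f"boundary position {z_ref} A outside grid "
                             f"[{z[0]}, {z[-1]}] A")
    i_ref = int(np.argmin(np.abs(z - z_ref)))

    dz_m = dz * A_TO_M
    # displacement field D(z) = cumulative integral of rho_q, anchored at z_ref
    D = _cumtrapz(rho, dz_m)
    D -= D[i_ref]
    E = D / (epsilon_0 * eps)
    psi = -_cumtrapz(E, dz_m)
    psi -= psi[i_ref]
    return PotentialProfile(z_A=z, E_V_per_m=E, psi_V=psi)


def _cumtrapz(y: np.ndarray, dx: float) -> np.ndarray:
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1])) * dx
    return out


def debye_length(
    ionic_strength_M: float, temperature_K: float = 298.0, eps_r: float = 78.5
) -> float:
    """Debye screening length in nm.

    lambda_D = sqrt(eps0 eps_r k_B T / (2 N_A e^2 I)); for monovalent
    electrolyte in water at 25 C this is ~0.304/sqrt(I[M]) nm.
    """
    if ionic_strength_M <= 0:
        raise ValueError("ionic strength must be > 0 (lambda_D diverges)")
    if temperature_K <= 0 or eps_r <= 0:
        raise ValueError("temperature and eps_r must be > 0")
    I = ionic_strength_M * 1e3 * Avogadro          # ions / m^3 per species
    lam = np.sqrt(epsilon_0 * eps_r * Boltzmann * temperature_K
                  / (2.0 * elementary_charge**2 * I))
    return float(lam * 1e9)


def gate_attenuation_from_pair(
    delta_psi_ref_mV: float, delta_vtg_ref_mV: float
) -> CircuitModel:
    """Calibrate the divider from one (membrane dpsi, top-gate dV) pair."""
    if delta_psi_ref_mV <= 0:
        raise ValueError("reference membrane potential must be > 0")
    if delta_vtg_ref_mV <= 0:
        raise ValueError("reference top-gate response must be > 0")
    return CircuitModel(attenuation=delta_vtg_ref_mV / delta_psi_ref_mV)


def predict_dvtg(delta_psi_mV: float, circuit: CircuitModel) -> float:
    """Top-gate potential change dV_TG = attenuation * dpsi, in mV."""
    return circuit.attenuation * delta_psi_mV
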