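"""Quantitative helpers around the supported lipid bilayer itself:
coverage mass, receptor (binding-site) counting from the lipid
composition, and lateral diffusion from FRAP recovery curves.

The FRAP model is the uniform-disk closed form for 2-D free diffusion
into a circularly bleached spot,

    f(t) = exp(-2 tau_D / t) [I0(2 tau_D/t) + I1(2 tau_D/t)],
    tau_D = w^2 / (4 D),

with bleach radius w and diffusion coefficient D; f rises monotonically
from 0 (full bleach) to 1 (full recovery).  An optional mobile fraction
scales the recovering part for membranes with immobile lipid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.constants import Avogadro
from scipy.special import i0e, i1e

__all__ = [
    "LipidComposition",
    "FRAPCurve",
    "FRAPFit",
    "coverage_mass",
    "binding_sites",
    "frap_model",
    "frap_fit",
]

#: fluid-phase area per lipid, A^2 (DOPC literature standard)
DEFAULT_AREA_PER_LIPID_A2 = 72.0

M2_TO_A2 = 1e20


@dataclass(frozen=True)
class LipidComposition:
    """Mole fractions and molecular weights of the membrane species.

    ``fractions`` and ``molecular_weights`` share keys; fractions must sum
    to 1.  ``area_per_lipid_A2`` is the in-plane area one lipid occupies.
    """

    fractions: Mapping[str, float]
    molecular_weights: Mapping[str, float]     # g/mol
    area_per_lipid_A2: float = DEFAULT_AREA_PER_LIPID_A2

    def __post_init__(self) -> None:
        if set(self.fractions) != set(self.molecular_weights):
            raise ValueError("fractions and molecular_weights must share keys")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("mole fractions must be >= 0")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mole fractions must sum to 1, got {total}")
        if any(mw <= 0 for mw in self.molecular_weights.values()):
            raise ValueError("molecular weights must be > 0")
        if self.area_per_lipid_A2 <= 0:
            raise ValueError("area per lipid must be > 0")

    @property
    def mean_molecular_weight(self) -> float:
        """Mole-fraction-weighted mean MW, g/mol."""
        return sum(f * self.molecular_weights[k] for k, f in self.fractions.items())

    def fraction_of(self, species: str) -> float:
        return float(self.fractions.get(species, 0.0))


@dataclass
class FRAPCurve:
    """Normalized fluorescence recovery (pre-bleach intensity = 1)."""

    t_s: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.intensity.shape != self.t_s.shape:
            raise ValueError("intensity must match t in length")
        if np.any(self.intensity < 0) or np.any(self.intensity > 1.2):
            raise ValueError("normalized intensity must lie in [0, 1.2]")

    def __len__(self) -> int:
        return len(self.t_s)


def coverage_mass(area_m2: float, composition: LipidComposition) -> float:
    """Lipid mass (ug) needed to cover ``area_m2`` with one bilayer.

    Two leaflets of area/APL lipids each, at the composition-averaged
    molecular weight: m = 2 (A/APL) <MW> / N_A.
    """
    if area_m2 < 0:
        raise ValueError("area must be >= 0")
    n_per_leaflet = area_m2 * M2_TO_A2 / composition.area_per_lipid_A2
    mass_g = 2.0 * n_per_leaflet * composition.mean_molecular_weight / Avogadro
    return mass_g * 1e6


def binding_sites(
    area_m2: float,
    composition: LipidComposition,
    biotins_per_avidin: float = 2.0,
    receptor_species: str = "B-PE",
) -> float:
    """Number of protein binding sites on the upper leaflet.

    Only the upper leaflet is accessible to the analyte; each bound
    protein occupies ``biotins_per_avidin`` receptor lipids (two for
    avidin, avoiding steric hindrance).
    """
    if area_m2 < 0:
        raise ValueError("area must be >= 0")
    if biotins_per_avidin <= 0:
        raise ValueError("biotins_per_avidin must be > 0")
    frac = composition.fraction_of(receptor_species)
    if frac <= 0:
        raise ValueError(f"composition has no {receptor_species!r} receptor lipid")
    n_upper = area_m2 * M2_TO_A2 / composition.area_per_lipid_A2
    return n_upper * frac / biotins_per_avidin


def frap_model(t_s, D_um2_per_s: float, bleach_radius_um: float):
    """Uniform-disk FRAP recovery f(t), dimensionless in [0, 1).

    Evaluated as i0e(x) + i1e(x) with x = 2 tau_D / t, which is the
    overflow-safe form of exp(-x)[I0(x) + I1(x)]; t = 0 is the full-bleach
    limit f = 0.
    """
    if D_um2_per_s <= 0 or bleach_radius_um <= 0:
        raise ValueError("D and bleach radius must be > 0")
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    tau_d = bleach_radius_um**2 / (4.0 * D_um2_per_s)
    with np.errstate(divide="ignore"):
        x = np.where(t > 0, 2.0 * tau_d / np.where(t > 0, t, 1.0), np.inf)
    f = np.where(np.isinf(x), 0.0, i0e(x) + i1e(x))
    return float(f) if np.isscalar(t_s) else f


@dataclass
class FRAPFit:
    """Diffusion coefficient estimated from a recovery curve."""

    D_um2_per_s: float
    D_stderr: float
    mobile_fraction: float
    success: bool
    message: str


def frap_fit(
    curve: FRAPCurve,
    bleach_radius_um: float,
    fit_mobile_fraction: bool = False,
) -> FRAPFit:
    """Least-squares fit of the uniform-disk recovery model.

    With ``fit_mobile_fraction`` the model is m * f(t) where m in (0, 1]
    is the mobile fraction; otherwise m = 1 (fully fluid membrane).
    Degenerate curves (no recovery dynamics) are flagged, not raised.
    """
    if len(curve) < 10:
        raise ValueError("need >= 10 points spanning the recovery")
    if bleach_radius_um <= 0:
        raise ValueError("bleach radius must be > 0")
    t, y = curve.t_s, curve.intensity
    if float(np.ptp(y)) < 1e-3:
        return FRAPFit(D_um2_per_s=np.nan, D_stderr=np.nan,
                       mobile_fraction=np.nan, success=False,
                       message="flat curve: no recovery dynamics to fit")

    # initial D from the half-recovery time: f(tau_D) ~ 0.38
    span = float(np.max(y))
    i_half = int(np.argmin(np.abs(y - 0.38 * span)))
    t_half = max(float(t[i_half]), float(t[t > 0][0]) if np.any(t > 0) else 1.0)
    D0 = bleach_radius_um**2 / (4.0 * t_half)

    if fit_mobile_fraction:
        def model(tt, D, m):
            return m * frap_model(tt, D, bleach_radius_um)
        p0, bounds = (D0, min(span, 1.0)), ([1e-6, 1e-3], [1e6, 1.0])
    else:
        def model(tt, D):
            return frap_model(tt, D, bleach_radius_um)
        p0, bounds = (D0,), ([1e-6], [1e6])

    try:
        popt, pcov = optimize.curve_fit(model, t, y, p0=p0, bounds=bounds,
                                        maxfev=20000)
        perr = np.sqrt(np.diag(pcov))
        ok, msg = True, "converged"
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        return FRAPFit(D_um2_per_s=np.nan, D_stderr=np.nan,
                       mobile_fraction=np.nan, success=False,
                       message=f"fit did not converge: {exc}")
    mobile = float(popt[1]) if fit_mobile_fraction else 1.0
    return FRAPFit(D_um2_per_s=float(popt[0]), D_stderr=float(perr[0]),
                   mobile_fraction=mobile, success=ok, message=msg)
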