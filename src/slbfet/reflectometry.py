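"""Specular X-ray reflectometry of slab electron-density stacks.

Forward model: Parratt's recursion over homogeneous slabs with
Nevot-Croce Gaussian roughness damping of the per-interface Fresnel
coefficients.  Electron density rho_e (e/A^3) maps to scattering length
density through the classical electron radius, SLD = r_e * rho_e, and the
beam is incident from the ambient (water) side:

    k_z,j = sqrt(k_z,0^2 - 4 pi (SLD_j - SLD_ambient)),   k_z,0 = q / 2.

Absorption is neglected (hard X-rays, thin organic films).

The inverse problem — recovering slab thicknesses and densities from a
measured R(q) curve — is non-convex with many local minima, so fitting
uses a genetic algorithm (tournament selection, uniform crossover,
Gaussian mutation, elitism) over box-bounded parameters, minimising a
sigma-weighted chi^2 on log10 R, followed by an optional local
trust-region polish of the GA winner.
"""

from __future__ import annotations

import copy
import logging
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.special import erf

__all__ = [
    "R_E_A",
    "Slab",
    "SlabStack",
    "ReflectivityCurve",
    "GAConfig",
    "DensityProfile",
    "ReflectivityFit",
    "energy_to_wavelength",
    "build_profile",
    "reflectivity",
    "fresnel_reflectivity",
    "critical_q",
    "fit_reflectivity",
    "density_difference",
]

logger = logging.getLogger(__name__)

#: classical electron radius in Angstrom
R_E_A = 2.8179403262e-5

#: hc in keV * Angstrom
HC_KEV_A = 12.39842


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Slab:
    """One homogeneous layer: thickness, electron density and the Gaussian
    roughness of its interface to the slab above (toward the ambient)."""

    thickness_A: float
    rho_e: float               # electrons / A^3
    roughness_A: float = 3.0

    def __post_init__(self) -> None:
        if self.thickness_A < 0:
            raise ValueError("slab thickness must be >= 0")
        if self.rho_e < 0:
            raise ValueError("electron density must be >= 0")
        if self.roughness_A < 0:
            raise ValueError("roughness must be >= 0")


@dataclass
class Medium:
    """Semi-infinite substrate or ambient."""

    rho_e: float

    def __post_init__(self) -> None:
        if self.rho_e < 0:
            raise ValueError("electron density must be >= 0")


@dataclass
class SlabStack:
    """Layered model: substrate | slabs (bottom -> top) | ambient.

    z = 0 sits at the substrate surface and grows toward the ambient.
    ``substrate_roughness_A`` is the substrate/first-slab (or
    substrate/ambient) interface roughness; each slab's own roughness
    belongs to the interface above it.
    """

    substrate: Medium
    slabs: list[Slab]
    ambient: Medium
    beam_energy_keV: float = 16.2
    substrate_roughness_A: float = 3.0

    def __post_init__(self) -> None:
        if self.beam_energy_keV <= 0:
            raise ValueError("beam energy must be > 0")
        if self.substrate_roughness_A < 0:
            raise ValueError("roughness must be >= 0")

    @property
    def total_thickness_A(self) -> float:
        return float(sum(s.thickness_A for s in self.slabs))

    def interface_positions_A(self) -> np.ndarray:
        """z of each interface, substrate surface first."""
        return np.concatenate(
            ([0.0], np.cumsum([s.thickness_A for s in self.slabs]))
        )


@dataclass
class ReflectivityCurve:
    """Measured or simulated specular reflectivity R(q)."""

    q: np.ndarray              # A^-1
    R: np.ndarray
    sigma_R: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.q.ndim != 1 or len(self.q) == 0:
            raise ValueError("q must be a non-empty 1-D array")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be positive and strictly increasing")
        if self.R.shape != self.q.shape:
            raise ValueError("R must match q in length")
        if np.any(self.R <= 0):
            raise ValueError("R must be > 0")
        if self.sigma_R is not None:
            self.sigma_R = np.asarray(self.sigma_R, dtype=float)
            if self.sigma_R.shape != self.q.shape:
                raise ValueError("sigma_R must match q in length")
            if np.any(self.R > 1.0 + 3.0 * self.sigma_R):
                raise ValueError("R exceeds 1 by more than 3 sigma")

    def __len__(self) -> int:
        return len(self.q)


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters for reflectivity fitting."""

    population: int = 128
    generations: int = 300
    crossover_prob: float = 0.7
    mutation_prob: float = 0.2
    mutation_sigma: float = 0.05      # fraction of each bound width, annealed
    mutation_anneal: float = 0.9      # fractional sigma reduction by the end
    immigrant_fraction: float = 0.1   # random individuals injected per generation
    tournament_size: int = 3
    elitism: int = 2
    seed: int = 0
    polish: bool = True
    polish_starts: int = 10           # distinct basins polished after the GA

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for name in ("crossover_prob", "mutation_prob", "mutation_anneal",
                     "immigrant_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class DensityProfile:
    """Laterally averaged electron density rho_e(z), z in Angstrom with
    z = 0 at the substrate surface, positive toward the outer buffer."""

    z_A: np.ndarray
    rho_e: np.ndarray

    def __post_init__(self) -> None:
        self.z_A = np.asarray(self.z_A, dtype=float)
        self.rho_e = np.asarray(self.rho_e, dtype=float)
        if self.z_A.ndim != 1 or len(self.z_A) < 2:
            raise ValueError("z grid needs >= 2 points")
        if np.any(np.diff(self.z_A) <= 0):
            raise ValueError("z grid must be strictly increasing")
        if self.rho_e.shape != self.z_A.shape:
            raise ValueError("rho_e must match z in length")


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def energy_to_wavelength(energy_keV: float) -> float:
    """X-ray wavelength in Angstrom, lambda = hc/E = 12.39842/E(keV)."""
    if energy_keV <= 0:
        raise ValueError("energy must be > 0")
    return HC_KEV_A / energy_keV


def build_profile(stack: SlabStack, z_grid_A) -> DensityProfile:
    """Roughness-smoothed electron-density profile of a stack.

    Each interface contributes an error-function step
    (rho_above - rho_below) * Phi((z - z_i)/sigma_i); zero roughness gives
    a sharp step.  The grid must cover the stack plus 5x the largest
    roughness on both sides so the profile has reached its plateaus.
    """
    z = np.asarray(z_grid_A, dtype=float)
    pos = stack.interface_positions_A()
    sig = [stack.substrate_roughness_A] + [s.roughness_A for s in stack.slabs]
    margin = 5.0 * max(sig) if max(sig) > 0 else 0.0
    if z[0] > pos[0] - margin or z[-1] < pos[-1] + margin:
        raise ValueError(
            f"z grid [{z[0]}, {z[-1]}] must cover the stack "
            f"[{pos[0] - margin}, {pos[-1] + margin}] (stack +/- 5 x max "
            "roughness)"
        )
    rhos = [stack.substrate.rho_e] + [s.rho_e for s in stack.slabs] + [stack.ambient.rho_e]
    rho = np.full_like(z, rhos[0])
    for z_i, s_i, below, above in zip(pos, sig, rhos[:-1], rhos[1:]):
        if s_i > 0:
            step = 0.5 * (1.0 + erf((z - z_i) / (s_i * np.sqrt(2.0))))
        else:
            step = (z >= z_i).astype(float)
        rho = rho + (above - below) * step
    return DensityProfile(z_A=z, rho_e=rho)


def _kz_layers(stack: SlabStack, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-layer vertical wavevectors, layers ordered beam-side first
    (ambient, top slab, ..., bottom slab, substrate).

    Returns (kz [n_layers, nq], d [n_layers], sigma [n_interfaces]).
    """
    rho = np.array(
        [stack.ambient.rho_e]
        + [s.rho_e for s in reversed(stack.slabs)]
        + [stack.substrate.rho_e]
    )
    d = np.array(
        [0.0] + [s.thickness_A for s in reversed(stack.slabs)] + [0.0]
    )
    # interface i sits between layer i and i+1; the roughness of the
    # interface below slab j (bottom->top index) is ...: in beam order the
    # interface above slab s is s.roughness_A, and the last interface (to
    # the substrate) is substrate_roughness_A.
    sigma = np.array(
        [s.roughness_A for s in reversed(stack.slabs)]
        + [stack.substrate_roughness_A]
    )
    kz0 = q / 2.0
    sld = R_E_A * rho
    kz = np.sqrt(kz0[None, :] ** 2 - 4.0 * np.pi * (sld[:, None] - sld[0]) + 0j)
    return kz, d, sigma


def reflectivity(stack: SlabStack, q) -> np.ndarray:
    """Specular reflectivity |r|^2 at momentum transfers ``q`` (A^-1).

    Parratt recursion from the substrate upward; Fresnel coefficients are
    damped by Nevot-Croce factors exp(-2 k_j k_{j+1} sigma^2).  For a
    non-absorbing substrate R = 1 below the critical edge.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be > 0")
    kz, d, sigma = _kz_layers(stack, q)
    n_int = kz.shape[0] - 1
    r_tot = np.zeros(len(q), dtype=complex)
    for i in range(n_int - 1, -1, -1):
        ki, kj = kz[i], kz[i + 1]
        r_i = (ki - kj) / (ki + kj) * np.exp(-2.0 * ki * kj * sigma[i] ** 2)
        if i == n_int - 1:
            r_tot = r_i
        else:
            phase = np.exp(2j * kj * d[i + 1])
            rp = r_tot * phase
            r_tot = (r_i + rp) / (1.0 + r_i * rp)
    return np.abs(r_tot) ** 2


def fresnel_reflectivity(rho_substrate: float, rho_ambient: float, q) -> np.ndarray:
    """Closed-form Fresnel reflectivity of a single sharp interface."""
    q = np.asarray(q, dtype=float)
    kz0 = q / 2.0
    contrast = 4.0 * np.pi * R_E_A * (rho_substrate - rho_ambient)
    kzs = np.sqrt(kz0**2 - contrast + 0j)
    r = (kz0 - kzs) / (kz0 + kzs)
    return np.abs(r) ** 2


def critical_q(rho_substrate: float, rho_ambient: float) -> float:
    """Critical momentum transfer q_c = 4 sqrt(pi r_e (rho_s - rho_a))."""
    contrast = rho_substrate - rho_ambient
    if contrast <= 0:
        return 0.0
    return 4.0 * np.sqrt(np.pi * R_E_A * contrast)


# ---------------------------------------------------------------------------
# Genetic-algorithm fitting
# ---------------------------------------------------------------------------

_PARAM_RE = re.compile(
    r"^(?:slabs\[(\d+)\]\.(thickness_A|rho_e|roughness_A)"
    r"|(substrate|ambient)\.rho_e|substrate_roughness_A$)"
)


def _get_param(stack: SlabStack, name: str) -> float:
    m = _PARAM_RE.match(name)
    if not m:
        raise ValueError(f"unknown stack parameter {name!r}")
    if m.group(1) is not None:
        return getattr(stack.slabs[int(m.group(1))], m.group(2))
    if m.group(3) is not None:
        return getattr(stack, m.group(3)).rho_e
    return stack.substrate_roughness_A


def _set_param(stack: SlabStack, name: str, value: float) -> None:
    m = _PARAM_RE.match(name)
    if not m:
        raise ValueError(f"unknown stack parameter {name!r}")
    if m.group(1) is not None:
        setattr(stack.slabs[int(m.group(1))], m.group(2), float(value))
    elif m.group(3) is not None:
        getattr(stack, m.group(3)).rho_e = float(value)
    else:
        stack.substrate_roughness_A = float(value)


@dataclass
class ReflectivityFit:
    """GA fit result: best stack, objective value and convergence log."""

    stack: SlabStack
    params: dict[str, float]
    chi2: float
    chi2_reduced: float
    n_points: int
    generations_log: list[float]
    polished: bool
    success: bool
    message: str


def fit_reflectivity(
    curve: ReflectivityCurve,
    template: SlabStack,
    free: dict[str, tuple[float, float]],
    ga: GAConfig = GAConfig(),
) -> ReflectivityFit:
    """Fit a slab stack to a reflectivity curve with a genetic algorithm.

    ``free`` maps parameter paths (``"slabs[0].thickness_A"``,
    ``"slabs[2].rho_e"``, ``"substrate.rho_e"``, ``"substrate_roughness_A"``
    ...) to finite (low, high) bounds; everything else in ``template`` is
    held fixed.  The objective is chi^2 on log10 R weighted by the
    propagated uncertainty sigma_logR = sigma_R / (R ln 10) (unit weights
    when the curve has no sigma_R).  Deterministic under a fixed
    ``ga.seed``.
    """
    if len(curve) == 0:
        raise ValueError("empty reflectivity curve")
    if not free:
        raise ValueError("no free parameters: nothing to fit")
    names = sorted(free)
    lo = np.array([free[n][0] for n in names], dtype=float)
    hi = np.array([free[n][1] for n in names], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)) and np.all(hi > lo)):
        raise ValueError("bounds must be finite with high > low")
    for n in names:
        _get_param(template, n)  # validates names early

    log_r = np.log10(curve.R)
    if curve.sigma_R is not None:
        w = curve.sigma_R / (curve.R * np.log(10.0))
        w = np.where(w > 0, w, np.nanmin(w[w > 0]) if np.any(w > 0) else 1.0)
    else:
        w = np.ones_like(log_r)

    work = copy.deepcopy(template)

    def objective(x: np.ndarray) -> float:
        for n, v in zip(names, x):
            _set_param(work, n, v)
        with np.errstate(divide="ignore"):
            model = np.log10(np.maximum(reflectivity(work, curve.q), 1e-300))
        return float(np.sum(((model - log_r) / w) ** 2))

    rng = np.random.default_rng(ga.seed)
    npar = len(names)
    width = hi - lo
    pop = lo + rng.random((ga.population, npar)) * width
    fit = np.array([objective(ind) for ind in pop])
    log: list[float] = [float(fit.min())]

    n_imm = int(ga.immigrant_fraction * ga.population)
    for gen in range(ga.generations):
        # annealed mutation width: broad exploration early, refinement late
        sigma = ga.mutation_sigma * (1.0 - ga.mutation_anneal * gen / ga.generations)
        order = np.argsort(fit)
        elite = pop[order[: ga.elitism]].copy()
        # tournament selection of parents
        idx = rng.integers(0, ga.population, size=(ga.population, ga.tournament_size))
        parents = pop[idx[np.arange(ga.population), np.argmin(fit[idx], axis=1)]]
        # uniform crossover of consecutive pairs
        children = parents.copy()
        for i in range(0, ga.population - 1, 2):
            if rng.random() < ga.crossover_prob:
                swap = rng.random(npar) < 0.5
                a, b = children[i].copy(), children[i + 1].copy()
                children[i, swap], children[i + 1, swap] = b[swap], a[swap]
        # per-gene Gaussian mutation
        mutate = rng.random((ga.population, npar)) < ga.mutation_prob
        children = children + mutate * rng.normal(
            0.0, sigma, (ga.population, npar)
        ) * width
        children = np.clip(children, lo, hi)
        # random immigrants keep the population from collapsing into one basin
        if n_imm:
            children[-n_imm:] = lo + rng.random((n_imm, npar)) * width
        children[: ga.elitism] = elite
        pop = children
        fit = np.array([objective(ind) for ind in pop])
        log.append(float(fit.min()))

    order = np.argsort(fit)
    best = pop[order[0]].copy()
    best_chi2 = float(fit[order[0]])
    polished = False
    if ga.polish:
        def res(x: np.ndarray) -> np.ndarray:
            for n, v in zip(names, x):
                _set_param(work, n, v)
            with np.errstate(divide="ignore"):
                model = np.log10(np.maximum(reflectivity(work, curve.q), 1e-300))
            return (model - log_r) / w

        # polish the best individual of each distinct basin, not just the
        # overall winner: the winner's basin need not contain the optimum
        starts: list[np.ndarray] = []
        for i in order:
            x = pop[i]
            if any(np.max(np.abs(x - s) / width) < 0.05 for s in starts):
                continue
            starts.append(x)
            sol = optimize.least_squares(res, x, bounds=(lo, hi), method="trf")
            if 2.0 * sol.cost <= best_chi2:
                best, best_chi2, polished = sol.x, float(2.0 * sol.cost), True
            if len(starts) >= ga.polish_starts:
                break

    fitted = copy.deepcopy(template)
    for n, v in zip(names, best):
        _set_param(fitted, n, v)
    dof = max(len(curve) - npar, 1)
    return ReflectivityFit(
        stack=fitted, params=dict(zip(names, (float(v) for v in best))),
        chi2=best_chi2, chi2_reduced=best_chi2 / dof, n_points=len(curve),
        generations_log=log, polished=polished, success=True,
        message=f"GA {ga.generations} generations, polish={polished}",
    )


# ---------------------------------------------------------------------------
# Profile arithmetic
# ---------------------------------------------------------------------------

def density_difference(
    profile_after: DensityProfile, profile_before: DensityProfile
) -> DensityProfile:
    """Pointwise electron-density difference after - before.

    Profiles are linearly interpolated onto the union of both z-grids
    restricted to the overlapping range; non-overlapping profiles are
    rejected.
    """
    z0 = max(profile_after.z_A[0], profile_before.z_A[0])
    z1 = min(profile_after.z_A[-1], profile_before.z_A[-1])
    if z1 <= z0:
        raise ValueError("profiles have no overlapping z-range")
    z = np.union1d(profile_after.z_A, profile_before.z_A)
    z = z[(z >= z0) & (z <= z1)]
    da = np.interp(z, profile_after.z_A, profile_after.rho_e)
    db = np.interp(z, profile_before.z_A, profile_before.rho_e)
    return DensityProfile(z_A=z, rho_e=da - db)
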