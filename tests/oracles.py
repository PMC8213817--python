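"""Independent numerical oracles used by the test suite.

These deliberately re-derive quantities by a different route than the
package (Abeles transfer matrices instead of Parratt recursion; analytic
error-function electrostatics instead of numerical quadrature) so that
agreement is evidence, not tautology.
"""

import numpy as np
from scipy.constants import epsilon_0
from scipy.special import erf

R_E_A = 2.8179403262e-5


def tm_reflectivity(stack, q):
    """Specular reflectivity via 2x2 Abeles transfer matrices.

    Same physics as the Parratt recursion (Nevot-Croce damped Fresnel
    coefficients, beam from the ambient side) but formulated as a product
    of interface and propagation matrices with r = M10/M00.
    """
    q = np.asarray(q, dtype=float)
    rho = np.array(
        [stack.ambient.rho_e]
        + [s.rho_e for s in reversed(stack.slabs)]
        + [stack.substrate.rho_e]
    )
    d = np.array([0.0] + [s.thickness_A for s in reversed(stack.slabs)] + [0.0])
    sig = np.array(
        [s.roughness_A for s in reversed(stack.slabs)]
        + [stack.substrate_roughness_A]
    )
    sld = R_E_A * rho
    out = np.empty_like(q)
    for iq, qv in enumerate(q):
        k0 = qv / 2.0
        kz = np.sqrt(k0**2 - 4.0 * np.pi * (sld - sld[0]) + 0j)
        M = np.eye(2, dtype=complex)
        for i in range(len(rho) - 1):
            r = (kz[i] - kz[i + 1]) / (kz[i] + kz[i + 1]) * np.exp(
                -2.0 * kz[i] * kz[i + 1] * sig[i] ** 2
            )
            I = np.array([[1.0, r], [r, 1.0]], dtype=complex)
            M = M @ I
            if i < len(rho) - 2:
                ph = 1j * kz[i + 1] * d[i + 1]
                M = M @ np.array([[np.exp(-ph), 0.0], [0.0, np.exp(ph)]],
                                 dtype=complex)
        out[iq] = abs(M[1, 0] / M[0, 0]) ** 2
    return out


def gaussian_dipole_charge(z_A, amp_C_per_m3, z1_A, z2_A, width_A):
    """rho_q(z) = A [exp(-(z-z1)^2/2s^2) - exp(-(z-z2)^2/2s^2)]."""
    z = np.asarray(z_A, dtype=float)
    return amp_C_per_m3 * (
        np.exp(-((z - z1_A) ** 2) / (2.0 * width_A**2))
        - np.exp(-((z - z2_A) ** 2) / (2.0 * width_A**2))
    )


def gaussian_dipole_closed_form(z_A, amp_C_per_m3, z1_A, z2_A, width_A, eps_r):
    """Analytic E(z), psi(z) of the Gaussian dipole with E(z_min)=psi(z_min)=0.

    The cumulative Gaussian integral is an erf; the potential needs
    int erf(u) du = u erf(u) + exp(-u^2)/sqrt(pi), all in closed form.
    """
    z = np.asarray(z_A, dtype=float) * 1e-10
    z1, z2, s = z1_A * 1e-10, z2_A * 1e-10, width_A * 1e-10
    rt2s = np.sqrt(2.0) * s

    def cum(zv, zc):
        # integral of the unit Gaussian from z_min to zv
        return s * np.sqrt(np.pi / 2.0) * (
            erf((zv - zc) / rt2s) - erf((z[0] - zc) / rt2s)
        )

    E = amp_C_per_m3 / (epsilon_0 * eps_r) * (cum(z, z1) - cum(z, z2))

    def ierf(u):
        return u * erf(u) + np.exp(-(u**2)) / np.sqrt(np.pi)

    def cum2(zv, zc):
        # integral of cum(., zc) from z_min to zv
        u, u0 = (zv - zc) / rt2s, (z[0] - zc) / rt2s
        inner = rt2s * (ierf(u) - ierf(u0)) - (zv - z[0]) * erf(u0)
        return s * np.sqrt(np.pi / 2.0) * inner

    psi = -amp_C_per_m3 / (epsilon_0 * eps_r) * (cum2(z, z1) - cum2(z, z2))
    return E, psi
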