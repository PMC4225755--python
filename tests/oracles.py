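"""Independent brute-force oracles used by the tests.

These deliberately re-derive quantities by enumeration or direct
summation, sharing no code path with the implementations they check.
"""

import numpy as np

from twostep_imrt.dose import blocked_rotation_dose, strip_rotation_dose


def grid_search_beta_omega(rho_oar: float, gamma: float,
                           omega_lo: float = 0.2, omega_hi: float = 3.0,
                           omega_step: float = 1e-3,
                           beta_lo: float = 0.005, beta_hi: float = 0.3,
                           beta_step: float = 1e-3):
    """Exhaustive (omega, beta) grid minimization of
    f^2 = E[(D_S1 + omega*D_S2 - 1)^2] over the target annulus.

    For each beta the integrand is quadratic in omega, so the grid values
    f^2(omega_i, beta_j) are evaluated exactly from three integrals per
    beta; the minimum over the full grid is returned.
    """
    rho = np.linspace(rho_oar + gamma, 1.0, 1501)
    w = rho / np.trapezoid(rho, rho)
    a = blocked_rotation_dose(rho, rho_oar) - 1.0
    omegas = np.arange(omega_lo, omega_hi + omega_step / 2, omega_step)
    best = (np.inf, None, None)
    for beta in np.arange(beta_lo, beta_hi + beta_step / 2, beta_step):
        b = strip_rotation_dose(rho, rho_oar, beta)
        c0 = np.trapezoid(w * a * a, rho)
        c1 = np.trapezoid(w * a * b, rho)
        c2 = np.trapezoid(w * b * b, rho)
        f2 = c0 + 2.0 * c1 * omegas + c2 * omegas ** 2
        i = int(np.argmin(f2))
        if f2[i] < best[0]:
            best = (float(f2[i]), float(omegas[i]), float(beta))
    return best  # (f2_min, omega, beta)


def indicator_dose_sum(points_xy, segments, iso=(0.0, 0.0)):
    """Per-point exposure by direct double loop over segments and leaf
    intervals (ignores z: intended for single-pair toy segments)."""
    out = np.zeros(len(points_xy))
    for i, (x, y) in enumerate(points_xy):
        for seg in segments:
            phi = np.radians(seg.gantry_angle)
            u = (x - iso[0]) * np.cos(phi) + (y - iso[1]) * np.sin(phi)
            for lo, hi in seg.leaves.values():
                if lo <= u <= hi:
                    out[i] += seg.mu
                    break
    return out


def double_loop_cov(soi_doses, objectives):
    """COV by explicit per-voxel loops (no vectorization)."""
    total = 0.0
    for obj in objectives:
        doses = soi_doses[obj.structure]
        n = len(doses)
        pens = []
        if obj.kind == "min_dose":
            pens = [max(0.0, obj.dose_gy - d) for d in doses]
        elif obj.kind == "max_dose":
            pens = [max(0.0, d - obj.dose_gy) for d in doses]
        elif obj.kind == "max_dvh":
            srt = sorted(doses, reverse=True)
            d_v = srt[min(int(np.floor(obj.volume_fraction * n)), n - 1)]
            for d in doses:
                if obj.dose_gy < d <= d_v:
                    pens.append(d - obj.dose_gy)
        total += obj.weight * sum(p * p for p in pens) / n
    return total
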