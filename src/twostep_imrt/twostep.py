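"""2-Step fluence-step generation and the beta*(gamma, rho_OAR) lookup.

The 2-Step decomposition delivers three aperture families per gantry
angle: S0 conformal to the target, S1 sparing the OAR (the target opening
with the OAR shadow removed), and narrow S2 strips adjacent to the OAR
shadow edges that compensate the target underdosage S1 introduces.

The S2 strip width is w = beta * R_PTV per leaf pair, where beta comes
from the optimum of the continuous-rotation model: minimizing

    f^2 = sigma_D^2 + (Dbar - D0)^2

over the target annulus rho in [rho_OAR + gamma, 1] (area weighting
2*pi*rho drho, D0 = mean dose of an unblocked rotation = 1) for the
radial dose D(rho) = D_S1(rho) + omega * D_S2(rho; beta).  The product
beta* = omega_opt * beta_opt depends only weakly on gamma; it is tabulated
over (gamma, rho_OAR) and parameterized by a fourth-order polynomial in
rho_OAR per gamma node (linear interpolation across gamma).  Two modes are
kept: the free joint (omega, beta) optimum used at generation time (the
strip is then emitted with omega = 1, i.e. width beta*), and the
fixed-omega optimum (omega = 1) used by MU-preserving adaptation, where
the segment weight cannot change.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .dose import Segment, blocked_rotation_dose, strip_rotation_dose
from .geometry import BEVProjection, NormalizedGeometry

logger = logging.getLogger(__name__)


class TwoStepError(ValueError):
    pass


# ---------------------------------------------------------------------------
# radial-model optimization
# ---------------------------------------------------------------------------

_N_RHO = 1501  # quadrature nodes over the target annulus


@dataclass(frozen=True)
class OptResult:
    omega_opt: float
    beta_opt: float
    f2_min: float
    f2_no_s2: float
    converged: bool = True

    @property
    def beta_star(self) -> float:
        return self.omega_opt * self.beta_opt


def _annulus_quadrature(rho_in: float):
    rho = np.linspace(rho_in, 1.0, _N_RHO)
    w = rho.copy()  # area weight 2*pi*rho drho; constants cancel
    w /= np.trapezoid(w, rho)
    return rho, w


def _f2_terms(rho, w, a, b, omega):
    """f^2 = E[(D - D0)^2] with D = a + omega*b and D0 = 1."""
    r = a + omega * b - 1.0
    return float(np.trapezoid(w * r * r, rho))


def optimize_beta_omega(rho_oar: float, gamma: float,
                        constraint: float | None = None,
                        omega_bounds: tuple[float, float] = (0.2, 3.0),
                        beta_bounds: tuple[float, float] | None = None,
                        ) -> OptResult:
    """Optimal S2 (weight, width) for one normalized geometry.

    Unconstrained mode searches (omega, beta) jointly over the bounded
    domain: for fixed beta the optimal omega is the closed-form
    least-squares weight (clipped to ``omega_bounds``), so only a 1D
    search over beta remains.  The bounds matter: in the idealized
    continuous model the narrow-strip dose profile scales with
    omega * beta only, so without a weight cap the joint optimum drifts
    to an arbitrarily narrow, arbitrarily heavy strip while the product
    beta* stays finite.  ``constraint`` fixes omega instead (the
    MU-preserving adaptation setting) and searches beta alone.  The beta
    search is a deterministic coarse scan refined by bounded minimization.
    """
    if not 0.0 < rho_oar < 1.0:
        raise TwoStepError("rho_oar must be in (0, 1)")
    if gamma < 0.0 or rho_oar + gamma > 1.0:
        raise TwoStepError("gamma must satisfy 0 <= gamma <= 1 - rho_oar")

    rho, w = _annulus_quadrature(rho_oar + gamma)
    a = blocked_rotation_dose(rho, rho_oar)
    f2_no_s2 = _f2_terms(rho, w, a, 0.0, 0.0)
    if beta_bounds is None:
        beta_bounds = (0.005, 1.0 - rho_oar - 1e-6)
    bmin, bmax = beta_bounds

    def f2_of_beta(beta: float) -> tuple[float, float]:
        b = strip_rotation_dose(rho, rho_oar, beta)
        if constraint is not None:
            return _f2_terms(rho, w, a, b, constraint), constraint
        num = float(np.trapezoid(w * b * (1.0 - a), rho))
        den = float(np.trapezoid(w * b * b, rho))
        omega = num / den if den > 0 else 0.0
        omega = float(np.clip(omega, *omega_bounds))
        return _f2_terms(rho, w, a, b, omega), omega

    betas = np.linspace(bmin, bmax, 200)
    vals = np.array([f2_of_beta(b)[0] for b in betas])
    i = int(np.argmin(vals))
    lo = betas[max(0, i - 1)]
    hi = betas[min(len(betas) - 1, i + 1)]
    res = minimize_scalar(lambda b: f2_of_beta(b)[0], bounds=(lo, hi),
                          method="bounded", options={"xatol": 1e-6})
    beta_opt = float(res.x)
    f2_min, omega_opt = f2_of_beta(beta_opt)
    converged = bool(res.success)
    if not converged:
        logger.warning("beta search did not converge at rho_oar=%.3f gamma=%.3f",
                       rho_oar, gamma)
    if vals[i] < f2_min:  # keep the scan point if the refinement backslid
        beta_opt = float(betas[i])
        f2_min, omega_opt = f2_of_beta(beta_opt)
    return OptResult(float(omega_opt), beta_opt, f2_min, f2_no_s2, converged)


# ---------------------------------------------------------------------------
# beta* table
# ---------------------------------------------------------------------------


@dataclass
class BetaStarTable:
    """beta* = omega_opt * beta_opt sampled over (gamma, rho_OAR).

    ``beta_star`` holds the free-optimum product; ``beta_star_fixed`` the
    fixed-omega (omega = 1) optimum used by adaptation.  ``coeffs`` /
    ``coeffs_fixed`` are degree-4 polynomial coefficients in rho_OAR
    (numpy ``polyfit`` order), one row per gamma node; evaluation
    interpolates linearly across gamma and clamps out-of-domain queries to
    the boundary with a warning.
    """

    rho_grid: np.ndarray
    gamma_grid: np.ndarray
    omega_opt: np.ndarray        # (n_gamma, n_rho)
    beta_opt: np.ndarray
    beta_star: np.ndarray
    beta_star_fixed: np.ndarray
    coeffs: np.ndarray           # (n_gamma, 5)
    coeffs_fixed: np.ndarray
    max_rel_residual: float
    settings: dict

    def _poly_eval(self, coeffs: np.ndarray, gamma: float, rho_oar: float) -> float:
        g = float(np.clip(gamma, self.gamma_grid[0], self.gamma_grid[-1]))
        r = float(np.clip(rho_oar, 0.0, self.rho_grid[-1]))
        if g != gamma or rho_oar > self.rho_grid[-1] or rho_oar < 0.0:
            # constant message so the default warning filter reports it once
            warnings.warn("beta* lookup outside the table domain; clamped to "
                          "the boundary", stacklevel=3)
            logger.debug("beta* clamp: gamma=%.3f rho_oar=%.3f", gamma, rho_oar)
        j = int(np.searchsorted(self.gamma_grid, g, side="right") - 1)
        j = min(max(j, 0), len(self.gamma_grid) - 2) if len(self.gamma_grid) > 1 else 0
        if len(self.gamma_grid) == 1:
            return max(0.0, float(np.polyval(coeffs[0], r)))
        g0, g1 = self.gamma_grid[j], self.gamma_grid[j + 1]
        t = 0.0 if g1 == g0 else (g - g0) / (g1 - g0)
        v0 = float(np.polyval(coeffs[j], r))
        v1 = float(np.polyval(coeffs[j + 1], r))
        return max(0.0, (1.0 - t) * v0 + t * v1)

    def lookup(self, gamma: float, rho_oar: float, mode: str = "free") -> float:
        """beta*(gamma, rho_OAR) from the polynomial parameterization."""
        if rho_oar <= 0.0:
            return 0.0
        if mode == "free":
            return self._poly_eval(self.coeffs, gamma, rho_oar)
        if mode == "fixed":
            return self._poly_eval(self.coeffs_fixed, gamma, rho_oar)
        raise TwoStepError(f"unknown beta* mode {mode!r}")

    def to_dict(self) -> dict:
        return {
            "rho_grid": self.rho_grid.tolist(),
            "gamma_grid": self.gamma_grid.tolist(),
            "omega_opt": self.omega_opt.tolist(),
            "beta_opt": self.beta_opt.tolist(),
            "beta_star": self.beta_star.tolist(),
            "beta_star_fixed": self.beta_star_fixed.tolist(),
            "coeffs": self.coeffs.tolist(),
            "coeffs_fixed": self.coeffs_fixed.tolist(),
            "max_rel_residual": self.max_rel_residual,
            "settings": self.settings,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BetaStarTable":
        return cls(
            np.asarray(d["rho_grid"]), np.asarray(d["gamma_grid"]),
            np.asarray(d["omega_opt"]), np.asarray(d["beta_opt"]),
            np.asarray(d["beta_star"]), np.asarray(d["beta_star_fixed"]),
            np.asarray(d["coeffs"]), np.asarray(d["coeffs_fixed"]),
            float(d["max_rel_residual"]), dict(d["settings"]))


def build_beta_star_table(
    rho_grid=None, gamma_grid=None, residual_tol: float = 0.05,
) -> BetaStarTable:
    """Tabulate and parameterize beta* over the default (gamma, rho_OAR)
    domain rho_OAR in [0.05, 0.6], gamma in [0, 0.3].

    Deterministic.  Each polynomial fit is anchored through the origin
    (beta*(gamma, 0) = 0).  If the maximum relative fit residual at the
    grid nodes exceeds ``residual_tol`` the table is still returned but
    flagged in the log.
    """
    rho_grid = np.asarray(rho_grid if rho_grid is not None
                          else np.linspace(0.05, 0.6, 12), dtype=float)
    gamma_grid = np.asarray(gamma_grid if gamma_grid is not None
                            else [0.0, 0.1, 0.2, 0.3], dtype=float)
    ng, nr = len(gamma_grid), len(rho_grid)
    omega = np.zeros((ng, nr))
    beta = np.zeros((ng, nr))
    bstar = np.zeros((ng, nr))
    bfix = np.zeros((ng, nr))
    for j, g in enumerate(gamma_grid):
        for i, r in enumerate(rho_grid):
            free = optimize_beta_omega(r, g)
            fixed = optimize_beta_omega(r, g, constraint=1.0)
            omega[j, i] = free.omega_opt
            beta[j, i] = free.beta_opt
            bstar[j, i] = free.beta_star
            bfix[j, i] = fixed.beta_star

    def fit(values: np.ndarray) -> np.ndarray:
        co = np.zeros((ng, 5))
        x = np.concatenate(([0.0], rho_grid))
        for j in range(ng):
            y = np.concatenate(([0.0], values[j]))
            # weight the origin anchor heavily so beta*(gamma, 0) ~ 0
            w = np.concatenate(([10.0], np.ones(nr)))
            co[j] = np.polyfit(x, y, 4, w=w)
        return co

    coeffs = fit(bstar)
    coeffs_fixed = fit(bfix)
    resid = 0.0
    for j in range(ng):
        pred = np.polyval(coeffs[j], rho_grid)
        resid = max(resid, float(np.max(np.abs(pred - bstar[j]) / bstar[j])))
        predf = np.polyval(coeffs_fixed[j], rho_grid)
        resid = max(resid, float(np.max(np.abs(predf - bfix[j]) / bfix[j])))
    if resid > residual_tol:
        logger.warning("beta* polynomial fit residual %.1f%% exceeds %.1f%%",
                       100 * resid, 100 * residual_tol)
    return BetaStarTable(
        rho_grid, gamma_grid, omega, beta, bstar, bfix, coeffs, coeffs_fixed,
        resid, settings={"n_rho_quadrature": _N_RHO, "d0": 1.0,
                         "dose_model": "exposure-fraction, parallel beam"})


# ---------------------------------------------------------------------------
# segment generation
# ---------------------------------------------------------------------------


def _target_pairs(bev: BEVProjection, target: str) -> list[int]:
    ks = [k for k in bev.pairs if bev.intervals(k, target)]
    if not ks:
        raise TwoStepError(
            f"empty {target} projection at gantry {bev.gantry_angle} deg")
    return sorted(ks)


def generate_s0(bev: BEVProjection, target: str) -> Segment:
    """Target-conformal aperture: per leaf pair the outer hull of the
    target projection; leaf pairs beyond the target extent stay closed."""
    leaves = {}
    for k in _target_pairs(bev, target):
        leaves[k] = bev.hull(k, target)
    return Segment(bev.gantry_angle, leaves, step_type="S0", target=target)


def _block_interval(bev: BEVProjection, k: int, oar: str,
                    block_margin: float) -> tuple[float, float] | None:
    hull = bev.hull(k, oar)
    if hull is None:
        return None
    return (hull[0] - block_margin, hull[1] + block_margin)


def generate_s1(bev: BEVProjection, target: str, oar: str,
                block_margin: float = 0.0) -> list[Segment]:
    """OAR-sparing apertures: the S0 opening with the OAR shadow removed.

    One MLC leaf pair carries one interval, so when the shadow splits the
    opening the left and right parts go to separate one-sided segments
    ("L" / "R", relative to the block).  Pairs without an OAR shadow keep
    the full S0 opening (carried on the "L" segment).  If no pair sees the
    OAR at all, the single S1 segment equals S0.
    """
    any_block = False
    left: dict[int, tuple[float, float]] = {}
    right: dict[int, tuple[float, float]] = {}
    for k in _target_pairs(bev, target):
        lo, hi = bev.hull(k, target)
        blk = _block_interval(bev, k, oar, block_margin)
        if blk is None or blk[1] <= lo or blk[0] >= hi:
            left[k] = (lo, hi)
            continue
        any_block = True
        if blk[0] > lo:
            left[k] = (lo, blk[0])
        if blk[1] < hi:
            right[k] = (blk[1], hi)
    if not any_block:
        return [Segment(bev.gantry_angle, left, step_type="S1", target=target)]
    out = []
    if left:
        out.append(Segment(bev.gantry_angle, left, step_type="S1",
                           target=target, side="L"))
    if right:
        out.append(Segment(bev.gantry_angle, right, step_type="S1",
                           target=target, side="R"))
    return out


def generate_s2(bev: BEVProjection, ngeo: dict[int, NormalizedGeometry],
                table: BetaStarTable, target: str, oar: str,
                block_margin: float = 0.0,
                mode: str = "free") -> list[Segment]:
    """Narrow compensation strips adjacent to each OAR-shadow edge.

    Per leaf pair the strip width is w = beta * R_PTV with
    beta = beta*(gamma, rho_OAR) / omega at the generation rule omega = 1,
    clipped to the target opening; sidedness matches the S1 split.  Pairs
    whose layer has no OAR (rho_OAR = 0) get no strip.
    """
    left: dict[int, tuple[float, float]] = {}
    right: dict[int, tuple[float, float]] = {}
    for k in _target_pairs(bev, target):
        geo = ngeo.get(k)
        if geo is None or not geo.oar_present or geo.rho_oar <= 0.0:
            continue
        blk = _block_interval(bev, k, oar, block_margin)
        if blk is None:
            continue
        lo, hi = bev.hull(k, target)
        gamma = geo.gamma if np.isfinite(geo.gamma) else 0.0
        beta = table.lookup(max(gamma, 0.0), geo.rho_oar, mode=mode)
        w = beta * geo.r_ptv
        if w <= 0.0:
            continue
        l_strip = (max(lo, blk[0] - w), min(blk[0], hi))
        if l_strip[1] > l_strip[0]:
            left[k] = l_strip
        r_strip = (max(blk[1], lo), min(hi, blk[1] + w))
        if r_strip[1] > r_strip[0]:
            right[k] = r_strip
    out = []
    if left:
        out.append(Segment(bev.gantry_angle, left, step_type="S2",
                           target=target, side="L"))
    if right:
        out.append(Segment(bev.gantry_angle, right, step_type="S2",
                           target=target, side="R"))
    return out


# ---------------------------------------------------------------------------
# whole-plan generation
# ---------------------------------------------------------------------------


def measure_geometry_map(ss, gantry_angle: float, pairs, target: str, oar: str,
                         mlc=None, iso=None) -> dict[int, NormalizedGeometry]:
    """(rho_OAR, gamma) per leaf pair for one gantry angle."""
    from .geometry import GeometryError, measure_normalized_geometry

    out: dict[int, NormalizedGeometry] = {}
    for k in pairs:
        try:
            out[k] = measure_normalized_geometry(
                ss, gantry_angle, k, target=target, oar=oar, mlc=mlc, iso=iso)
        except GeometryError:
            continue
    return out


def generate_plan(ss, table: BetaStarTable, prescriptions: dict[str, float],
                  targets: tuple[str, ...] = ("PTV",), oar: str = "Rectum",
                  beams: list[float] | None = None, mlc=None, iso=None,
                  fractions: int = 33, block_margin: float = 0.0):
    """Generate the full pre-fine-tune 2-Step segment set.

    Per gantry angle and per target SOI: one S0 segment, the S1 pair, and
    the S2 strips at generation-rule widths (omega = 1).  Initial MUs are
    uniform (1 MU per segment, S2 at omega = 1 relative to S1); the weight
    optimization stage assigns the actual values.
    """
    from .dose import Plan, default_beams
    from .geometry import project_to_bev

    beams = beams if beams is not None else default_beams()
    segments: list[Segment] = []
    for angle in beams:
        bev = project_to_bev(ss, angle, mlc=mlc, iso=iso)
        for target in targets:
            s0 = generate_s0(bev, target)
            s1s = generate_s1(bev, target, oar, block_margin)
            ngeo = measure_geometry_map(ss, angle, _target_pairs(bev, target),
                                        target, oar, mlc=mlc, iso=iso)
            s2s = generate_s2(bev, ngeo, table, target, oar, block_margin)
            for seg in [s0, *s1s, *s2s]:
                seg.mu = 1.0
                segments.append(seg)
    return Plan(segments, dict(prescriptions), fractions, list(beams))


__all__ = [
    "BetaStarTable", "OptResult", "TwoStepError", "build_beta_star_table",
    "generate_plan", "generate_s0", "generate_s1", "generate_s2",
    "measure_geometry_map", "optimize_beta_omega",
]
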