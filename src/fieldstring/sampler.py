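"""Restrained overdamped Langevin dynamics in order-parameter space.

The full molecular system is reduced to its two slow torsions, so a window's
umbrella sampling is an Euler-Maruyama integration of

    z <- z - dt * m * grad(F + U) + sqrt(2 RT m dt) * xi,
    U(z) = 1/2 kappa |z - center|^2   (torus-aware displacement)

whose stationary distribution is exp(-(F + U)/RT).  Only that stationary
distribution matters for the mean-force estimate, which is why no inertia or
thermostat is needed.  All dynamics are in radians; interfaces are degrees.

The mean force (free-energy gradient at the window center, to first order in
RT/kappa) is the average restraint force kappa * (center - <z>).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEG, RAD, rt_kj_mol
from .geometry import OPPoint, wrap_deg, wrap_rad

__all__ = ["SamplerConfig", "WindowSample", "SamplerError",
           "sample_window", "sample_windows", "mean_force", "metric_tensor"]


class SamplerError(RuntimeError):
    pass


@dataclass(frozen=True)
class SamplerConfig:
    """Settings for one umbrella window.

    time_step and mobility are reduced units (mobility in rad^2 per kJ/mol
    per time unit); spring is the restraint stiffness in kJ/mol/rad^2 per
    order parameter; n_steps counts total integration steps, of which the
    first burn_in_fraction are discarded.
    """

    time_step: float = 5e-4
    mobility: float = 1.0
    temperature: float = 298.15
    n_steps: int = 25000
    burn_in_fraction: float = 0.2
    seed: int = 0
    spring: float = 100.0

    def __post_init__(self):
        if self.time_step <= 0:
            raise ValueError("time_step must be > 0")
        if self.n_steps < 1000:
            raise ValueError("n_steps must be >= 1000")
        if not (0 <= self.burn_in_fraction < 1):
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if self.spring <= 0:
            raise ValueError("spring must be > 0")


@dataclass
class WindowSample:
    """Window statistics: first/second moments of the restrained OPs.

    covariance is in rad^2; mean_restraint_force in kJ/mol/rad.  n_effective
    is a conservative effective sample count from the analytic restraint
    relaxation time.  trajectory (degrees, retained steps only) is attached
    only when requested — it feeds the WHAM cross-check.
    """

    center: OPPoint
    mean_op: OPPoint
    covariance: np.ndarray
    mean_restraint_force: np.ndarray
    n_effective: int
    spring: float
    temperature: float
    trajectory: np.ndarray | None = None


def _resolve_gradient(landscape, field_spec):
    """Accept a Landscape (fast tabulated gradient) or a bare callable
    mapping (N, 2) degrees -> (N, 2) kJ/mol/deg."""
    if hasattr(landscape, "tabulated_gradient"):
        table = landscape.tabulated_gradient(field_spec)
        return table.grad, table.max_curvature_rad
    if callable(landscape):
        curvature = float(getattr(landscape, "max_curvature_rad", 0.0))
        return landscape, curvature
    raise TypeError("landscape must be a Landscape or a gradient callable")


def sample_windows(landscape, field_spec, centers_deg, config: SamplerConfig,
                   rng: np.random.Generator | None = None,
                   store_trajectory: bool = False) -> list[WindowSample]:
    """Sample all windows at once (states propagated as one array).

    centers_deg: (K, 2) window centers in degrees.  Returns one WindowSample
    per center.  With the same rng state the result is bit-reproducible.
    """
    grad_deg, curvature_rad = _resolve_gradient(landscape, field_spec)
    dt, mob, kappa = config.time_step, config.mobility, config.spring
    if dt * mob * (kappa + curvature_rad) >= 0.5:
        raise SamplerError(
            f"stability condition violated: dt*m*(spring + curvature) = "
            f"{dt * mob * (kappa + curvature_rad):.3f} >= 0.5")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    centers = np.atleast_2d(np.asarray(centers_deg, dtype=float))
    c_rad = centers * DEG
    z = c_rad.copy()
    rt = rt_kj_mol(config.temperature)
    noise_amp = np.sqrt(2.0 * rt * mob * dt)
    burn = int(config.burn_in_fraction * config.n_steps)
    retained = config.n_steps - burn

    k = len(centers)
    s1 = np.zeros((k, 2))
    s2 = np.zeros((k, 2, 2))
    traj = np.empty((retained, k, 2)) if store_trajectory else None

    for step in range(config.n_steps):
        g = grad_deg(wrap_deg(z * RAD)) * RAD          # kJ/mol/rad
        delta = wrap_rad(z - c_rad)
        force = g + kappa * delta
        z = z - dt * mob * force + noise_amp * rng.standard_normal((k, 2))
        if step >= burn:
            d = wrap_rad(z - c_rad)
            s1 += d
            s2 += d[:, :, None] * d[:, None, :]
            if store_trajectory:
                traj[step - burn] = wrap_deg(z * RAD)
        if step % 4096 == 0 and not np.all(np.isfinite(z)):
            raise SamplerError(f"non-finite state at step {step}")

    tau = 1.0 / (dt * mob * kappa)                     # restraint relaxation, steps
    n_eff = max(1, int(retained / (1.0 + 2.0 * tau)))
    out = []
    for i in range(k):
        dbar = s1[i] / retained
        cov = s2[i] / retained - np.outer(dbar, dbar)
        out.append(WindowSample(
            center=OPPoint(centers[i, 0], centers[i, 1]),
            mean_op=OPPoint(*(wrap_deg(c_rad[i] * RAD + dbar * RAD))),
            covariance=cov,
            mean_restraint_force=-kappa * dbar,
            n_effective=n_eff,
            spring=kappa,
            temperature=config.temperature,
            trajectory=traj[:, i, :].copy() if store_trajectory else None))
    return out


def sample_window(landscape, field_spec, center: OPPoint,
                  config: SamplerConfig,
                  store_trajectory: bool = False) -> WindowSample:
    """Umbrella-sample a single window (seeded from config.seed)."""
    arr = center.as_array() if isinstance(center, OPPoint) else np.asarray(center)
    return sample_windows(landscape, field_spec, arr[None, :], config,
                          store_trajectory=store_trajectory)[0]


def mean_force(window: WindowSample, estimator: str = "restraint") -> np.ndarray:
    """Estimate dF/dz at the window center, kJ/mol/rad.

    "restraint": kappa * (center - <z>) — exactly <grad F> over the biased
    ensemble (since <grad(F+U)> = 0), i.e. the free-energy gradient smoothed
    over the window width RT/kappa; first order in RT/kappa.

    "gaussian": RT * Sigma^-1 * (center - <z>) — the umbrella-integration
    refinement, which replaces the restraint stiffness by the locally
    observed stiffness RT*Sigma^-1.  Exact for locally quadratic free energy
    of any curvature, so it undoes the window-width smoothing that clips
    sharp profile features.
    """
    if estimator == "restraint":
        return np.asarray(window.mean_restraint_force, dtype=float)
    if estimator == "gaussian":
        delta = wrap_deg(window.center.as_array() - window.mean_op.as_array()) * DEG
        return rt_kj_mol(window.temperature) * np.linalg.solve(window.covariance, delta)
    raise ValueError(f"unknown estimator {estimator!r}")


def metric_tensor(window: WindowSample, mode: str = "identity") -> np.ndarray:
    """Preconditioning tensor for the string update.

    identity: the 2x2 identity (both OPs are plain torsions).
    covariance: RT * Sigma^-1 normalized to unit determinant — reweights
    directions by their sampled mobility.
    """
    if mode == "identity":
        return np.eye(2)
    if mode == "covariance":
        cov = np.asarray(window.covariance, dtype=float)
        det = np.linalg.det(cov)
        if not np.isfinite(det) or det <= 1e-18:
            raise SamplerError("singular covariance: window sampled too few states")
        m = rt_kj_mol(window.temperature) * np.linalg.inv(cov)
        return m / np.sqrt(np.linalg.det(m))
    raise ValueError(f"unknown tensor mode {mode!r}")
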