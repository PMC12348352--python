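"""Finite-temperature string method in the (phi, psi) order parameters.

A string of N images discretizes a candidate transition path between the two
conformer basins.  Each iteration umbrella-samples every image's window,
estimates mean forces, moves the interior images down the force component
perpendicular to the string,

    dz_i = -step * P_i M_i f_i,     P_i = I - t_i t_i^T,

smooths the string lightly to suppress sampling-noise zig-zag, and
redistributes the images to equal arc length.  Endpoints stay anchored at
the deterministic basin minima.  The fixed point of this iteration is the
minimum free-energy path: on it the perpendicular mean force vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEG, RAD
from .geometry import OPPoint, unwrap_chain, wrap_deg
from .landscape import FieldSpec, Landscape, locate_minima
from .sampler import SamplerConfig, WindowSample, mean_force, metric_tensor, sample_windows

__all__ = ["StringState", "FTSConfig", "FTSResult",
           "initialize_string", "update_images", "reparameterize",
           "smooth_string", "run_fts"]


@dataclass
class StringState:
    """Ordered images z_0 ... z_{N-1} on the uniform parameter grid alpha."""

    images: np.ndarray              # (N, 2) degrees, wrapped
    alpha: np.ndarray = None        # (N,) uniform grid on [0, 1]

    def __post_init__(self):
        self.images = wrap_deg(np.asarray(self.images, dtype=float))
        n = len(self.images)
        if n < 4:
            raise ValueError("a string needs at least 4 images")
        if self.alpha is None:
            self.alpha = np.linspace(0.0, 1.0, n)
        seg = np.linalg.norm(wrap_deg(np.diff(self.images, axis=0)), axis=1)
        if np.any(seg == 0.0):
            raise ValueError("consecutive images must be distinct")

    @property
    def n_images(self) -> int:
        return len(self.images)

    def points(self) -> list[OPPoint]:
        return [OPPoint(p[0], p[1]) for p in self.images]

    def arc_lengths(self) -> np.ndarray:
        """Cumulative chord arc length in degrees, starting at 0."""
        seg = np.linalg.norm(wrap_deg(np.diff(self.images, axis=0)), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class FTSConfig:
    n_images: int = 20
    max_iterations: int = 100
    string_step: float = 20.0        # deg^2 per (kJ/mol/deg)
    max_displacement: float = 3.0    # per-image cap, deg/iteration
    smoothing_lambda: float = 0.1
    convergence_tol: float = 0.3     # deg RMS displacement
    convergence_window: int = 5      # consecutive iterations below tol
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    tensor_mode: str = "identity"
    force_mode: str = "sampled"      # "sampled" | "exact" (analytic gradient)
    force_estimator: str = "gaussian"  # "gaussian" (umbrella integration) | "restraint"

    def __post_init__(self):
        if self.n_images < 4:
            raise ValueError("n_images must be >= 4")
        for name in ("max_iterations", "string_step", "smoothing_lambda",
                     "convergence_tol", "convergence_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FTSResult:
    string: StringState
    mean_forces: np.ndarray          # (N, 2) kJ/mol/rad, sampled on final string
    iterations_run: int
    converged: bool
    displacement_history: list       # per-iteration RMS image displacement, deg
    samples: list | None = None      # final-string WindowSamples, if kept


def initialize_string(a: OPPoint, b: OPPoint, n_images: int) -> StringState:
    """Shortest-arc linear interpolation between the two basins."""
    pa = a.as_array() if isinstance(a, OPPoint) else np.asarray(a, dtype=float)
    pb = b.as_array() if isinstance(b, OPPoint) else np.asarray(b, dtype=float)
    if np.all(wrap_deg(pb - pa) == 0.0):
        raise ValueError("string endpoints coincide")
    target = pa + wrap_deg(pb - pa)
    t = np.linspace(0.0, 1.0, n_images)[:, None]
    return StringState(images=pa[None, :] * (1 - t) + target[None, :] * t)


def _tangents(images_unwrapped: np.ndarray) -> np.ndarray:
    """Unit tangents: central differences interior, one-sided at the ends."""
    t = np.empty_like(images_unwrapped)
    t[1:-1] = images_unwrapped[2:] - images_unwrapped[:-2]
    t[0] = images_unwrapped[1] - images_unwrapped[0]
    t[-1] = images_unwrapped[-1] - images_unwrapped[-2]
    norms = np.linalg.norm(t, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("zero-length tangent: coincident neighboring images")
    return t / norms[:, None]


def update_images(string: StringState, forces_rad, tensors, step: float,
                  max_displacement: float = 3.0) -> StringState:
    """Move interior images against the perpendicular mean force.

    forces_rad: (N, 2) mean forces in kJ/mol/rad; tensors: list of 2x2
    preconditioners.  Endpoints are anchored.  Per-image displacement is
    capped at max_displacement degrees.
    """
    forces = np.asarray(forces_rad, dtype=float)
    if len(forces) != string.n_images:
        raise ValueError("forces not aligned with images")
    un = unwrap_chain(string.images)
    tang = _tangents(un)
    f_deg = forces * DEG                     # kJ/mol/rad -> kJ/mol/deg
    new = un.copy()
    for i in range(1, string.n_images - 1):
        mf = np.asarray(tensors[i], dtype=float) @ f_deg[i]
        perp = mf - tang[i] * (tang[i] @ mf)
        disp = -step * perp
        norm = np.linalg.norm(disp)
        if norm > max_displacement:
            disp *= max_displacement / norm
        new[i] = un[i] + disp
    return StringState(images=new, alpha=string.alpha.copy())


def reparameterize(string: StringState, tol: float = 1e-6,
                   max_passes: int = 12) -> StringState:
    """Redistribute images to equal arc length along the string.

    The images are resampled from an interpolating cubic spline of the
    current string (parameterized by cumulative chord length), iterated
    until consecutive chord lengths agree with their mean to within tol
    (relative).  Spline resampling preserves curvature — unlike repeated
    piecewise-linear redistribution it does not progressively cut corners.
    Endpoints are fixed.
    """
    from scipy.interpolate import CubicSpline

    un = unwrap_chain(string.images)
    for _ in range(max_passes):
        seg = np.linalg.norm(np.diff(un, axis=0), axis=1)
        if np.max(np.abs(seg - seg.mean())) <= tol * seg.mean():
            break
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        spline = CubicSpline(cum, un, axis=0)
        new = spline(np.linspace(0.0, cum[-1], len(un)))
        new[0], new[-1] = un[0], un[-1]
        un = new
    return StringState(images=un, alpha=string.alpha.copy())


def smooth_string(string: StringState, smoothing_lambda: float) -> StringState:
    """Local averaging z_i <- (1-l) z_i + l (z_{i-1}+z_{i+1})/2, ends fixed."""
    if not (0.0 <= smoothing_lambda < 1.0):
        raise ValueError("smoothing lambda must be in [0, 1)")
    if smoothing_lambda == 0.0:
        return StringState(images=string.images.copy(), alpha=string.alpha.copy())
    un = unwrap_chain(string.images)
    new = un.copy()
    lam = smoothing_lambda
    new[1:-1] = (1 - lam) * un[1:-1] + lam * 0.5 * (un[:-2] + un[2:])
    return StringState(images=new, alpha=string.alpha.copy())


def _string_forces(landscape, field_spec, string, config, rng,
                   store_trajectory=False):
    """Mean forces (kJ/mol/rad) for every image, plus samples if sampled."""
    if config.force_mode == "exact":
        g = landscape.gradient_deg(string.images, field_spec) * RAD
        samples = None
        tensors = [np.eye(2)] * string.n_images
        return g, tensors, samples
    samples = sample_windows(landscape, field_spec, string.images,
                             config.sampler, rng=rng,
                             store_trajectory=store_trajectory)
    forces = np.array([mean_force(w, config.force_estimator) for w in samples])
    tensors = [metric_tensor(w, config.tensor_mode) for w in samples]
    return forces, tensors, samples


def run_fts(landscape: Landscape, field_spec: FieldSpec | None,
            config: FTSConfig, seed: int,
            endpoints: tuple | None = None,
            keep_final_samples: bool = False,
            callback=None) -> FTSResult:
    """Drive the string to the minimum free-energy path.

    Endpoints are anchored at the deterministic basin minima (or at the
    supplied ``endpoints``).  Per-iteration randomness is drawn from a
    counter-based split of ``seed``.  Non-convergence within max_iterations
    is reported in the result, not raised.
    """
    if endpoints is None:
        (a, b), _ = locate_minima(landscape, field_spec)
    else:
        a, b = endpoints
    string = initialize_string(a, b, config.n_images)
    streams = np.random.SeedSequence(seed).spawn(config.max_iterations + 1)
    history = []
    converged = False
    iterations = 0
    for it in range(config.max_iterations):
        rng = np.random.default_rng(streams[it])
        forces, tensors, _ = _string_forces(landscape, field_spec, string,
                                            config, rng)
        moved = update_images(string, forces, tensors, config.string_step,
                              config.max_displacement)
        moved = smooth_string(moved, config.smoothing_lambda)
        moved = reparameterize(moved)
        disp = np.linalg.norm(wrap_deg(moved.images - string.images), axis=1)
        rms = float(np.sqrt(np.mean(disp ** 2)))
        history.append(rms)
        string = moved
        iterations = it + 1
        if callback is not None:
            callback(it, rms, float(np.max(np.abs(forces))))
        if (len(history) >= config.convergence_window
                and max(history[-config.convergence_window:]) < config.convergence_tol):
            converged = True
            break
    # final mean forces, aligned with the returned string (fresh stream)
    rng = np.random.default_rng(streams[config.max_iterations])
    forces, _, samples = _string_forces(landscape, field_spec, string, config,
                                        rng, store_trajectory=keep_final_samples)
    return FTSResult(string=string, mean_forces=forces,
                     iterations_run=iterations, converged=converged,
                     displacement_history=history,
                     samples=samples if keep_final_samples else None)
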