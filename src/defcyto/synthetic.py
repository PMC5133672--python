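"""Ground-truthed synthetic deformability-cytometry inputs.

Two levels of simulation are provided:

* **Rendered image sequences** — a cell is modelled as an incompressible
  viscoelastic ellipse.  While resident in the extensional-flow junction
  its strain follows a Kelvin–Voigt-type creep law
  ``eps(t) = eps_max * (1 - exp(-t/tau))`` with a microsecond-scale time
  constant; after exit it relaxes toward a residual strain.  Area is
  conserved throughout (the minor axis shrinks as the major axis grows),
  which ties strain to deformability analytically: D = (1 + eps)^2.
  Boundary texture is injected as low-order Fourier modes on the radial
  function, giving analytic control over the morphology metrics.  Frames
  are rasterized (dark cell, bright background), blurred with a Gaussian
  PSF and corrupted with additive noise; every event carries the profile
  computed from the noise-free continuous shape as ground truth.

* **Feature-space populations** — per-class truncated multivariate
  Gaussians over the 15 biophysical parameters, and spike-in mixtures
  with exact largest-remainder allocation so that mixing fractions are
  exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .features import (
    DEFAULT_WINDOW,
    PARAMETER_NAMES,
    BiophysicalProfile,
    morphology_metrics,
)

CELL_CONTRAST = 0.6  # brightfield-like: dark cell on background 1.0


class InvalidSpecError(ValueError):
    """Raised for simulation specs violating their invariants."""


class RenderError(RuntimeError):
    """Raised when a cell cannot be rendered inside the image bounds."""


@dataclass
class ViscoelasticCellSpec:
    """One simulated cell: geometry plus creep/recovery parameters.

    Parameters
    ----------
    initial_diameter : float
        Undeformed diameter (um).
    max_strain : float
        Asymptotic creep strain eps_max >= 0.
    creep_time : float
        Creep time constant tau (us), > 0; of order a few us.
    recovery_fraction : float
        Fraction of the attained strain that relaxes away after the
        junction (1 = full elastic recovery, 0 = fully plastic).
    recovery_time : float
        Recovery time constant (us), > 0.
    boundary_modes : list of (k, amplitude)
        Radial Fourier perturbation modes; k >= 2, amplitude < 0.3 so the
        boundary stays simple and star convex.
    """

    initial_diameter: float
    max_strain: float = 0.5
    creep_time: float = 2.0
    recovery_fraction: float = 0.8
    recovery_time: float = 2.0
    boundary_modes: list[tuple[int, float]] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_diameter <= 0:
            raise InvalidSpecError("initial_diameter must be positive")
        if self.max_strain < 0:
            raise InvalidSpecError("max_strain must be >= 0")
        if self.creep_time <= 0 or self.recovery_time <= 0:
            raise InvalidSpecError("time constants must be positive")
        if not 0 <= self.recovery_fraction <= 1:
            raise InvalidSpecError("recovery_fraction must be in [0, 1]")
        for k, amp in self.boundary_modes:
            if k < 2 or not np.isreal(k):
                raise InvalidSpecError("mode frequency k must be an integer >= 2")
            if abs(amp) >= 0.3:
                raise InvalidSpecError("mode amplitude must be < 0.3")


@dataclass
class RenderSpec:
    """Imaging model: optics, timing and frame layout of an event movie."""

    pixel_size: float = 0.5          # um / px
    frame_interval: float = 2.0      # us
    n_pre_frames: int = 2
    n_junction_frames: int = 5       # ~8 us residence, ~4 creep times
    n_post_frames: int = 2
    psf_sigma: float = 1.0           # px
    noise_sd: float = 0.02           # fraction of full intensity scale
    image_shape: tuple[int, int] = (96, 96)

    def __post_init__(self) -> None:
        if min(self.n_pre_frames, self.n_junction_frames, self.n_post_frames) < 1:
            raise InvalidSpecError("all frame counts must be >= 1")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise InvalidSpecError("pixel_size and frame_interval must be positive")


@dataclass
class FrameShape:
    """Analytic cell shape in one frame: area-conserving perturbed ellipse."""

    major_semi: float                 # um, along the flow (column) axis
    minor_semi: float                 # um
    strain: float
    modes: list[tuple[int, float]]

    def radius(self, theta: np.ndarray) -> np.ndarray:
        """Radial boundary function r(theta), theta from the major axis."""
        a, b = self.major_semi, self.minor_semi
        r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        for k, amp in self.modes:
            r = r * (1 + amp * np.cos(k * theta))
        return r


@dataclass
class CellEvent:
    """One cell's frame stack plus timing metadata and optional ground truth."""

    event_id: str
    frames: list[np.ndarray]
    frame_interval: float             # us
    pixel_size: float                 # um / px
    junction_arrival_index: int
    ground_truth: BiophysicalProfile | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise InvalidSpecError("frames must be nonempty")
        if not 0 <= self.junction_arrival_index < len(self.frames):
            raise InvalidSpecError("junction_arrival_index out of range")
        shapes = {f.shape for f in self.frames}
        if len(shapes) != 1:
            raise InvalidSpecError("all frames must have the same shape")


# ---------------------------------------------------------------------------
# trajectory and rendering


def creep_strain(t: np.ndarray | float, eps_max: float, tau: float) -> np.ndarray:
    """Creep law eps(t) = eps_max * (1 - exp(-t/tau)) for t >= 0."""
    return eps_max * (1.0 - np.exp(-np.asarray(t, float) / tau))


def simulate_trajectory(
    spec: ViscoelasticCellSpec, render: RenderSpec
) -> list[FrameShape]:
    """Per-frame shape states of one cell event.

    Pre-junction frames are undeformed; junction frames follow the creep
    law with time measured from arrival; post-junction frames relax toward
    the residual strain ``(1 - recovery_fraction) * eps_exit``.  The area
    of the unperturbed ellipse is conserved in every frame.
    """
    r0 = spec.initial_diameter / 2.0
    dt = render.frame_interval
    strains = [0.0] * render.n_pre_frames
    t_j = dt * np.arange(render.n_junction_frames)
    strains += list(creep_strain(t_j, spec.max_strain, spec.creep_time))
    eps_exit = strains[-1]
    t_p = dt * np.arange(1, render.n_post_frames + 1)
    rf = spec.recovery_fraction
    strains += list(eps_exit * ((1 - rf) + rf * np.exp(-t_p / spec.recovery_time)))

    shapes = []
    for eps in strains:
        a = r0 * (1 + eps)
        shapes.append(FrameShape(major_semi=a, minor_semi=r0**2 / a,
                                 strain=eps, modes=list(spec.boundary_modes)))
    return shapes


def _rasterize(shape: FrameShape, render: RenderSpec) -> np.ndarray:
    rows, cols = render.image_shape
    cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    px = render.pixel_size
    max_r = shape.radius(np.linspace(0, 2 * np.pi, 720, endpoint=False)).max()
    margin = max_r / px + 3 * render.psf_sigma
    if margin > min(cr, cc, rows - 1 - cr, cols - 1 - cc):
        raise RenderError("cell exceeds image bounds")
    dy = (np.arange(rows) - cr)[:, None] * px
    dx = (np.arange(cols) - cc)[None, :] * px
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    inside = rho <= shape.radius(theta)
    img = np.where(inside, 1.0 - CELL_CONTRAST, 1.0)
    if render.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, render.psf_sigma, mode="nearest")
    return img


def _shape_measures(shape: FrameShape, n: int = 1440
                    ) -> tuple[float, float, float, float]:
    """(area, perimeter, deformability, major axis length) of the continuous
    perturbed boundary, via dense polygon sampling."""
    from .features import _polygon_second_moments, polygon_perimeter

    theta = 2 * np.pi * np.arange(n + 1) / n
    r = shape.radius(theta)
    poly = np.column_stack([r * np.sin(theta), r * np.cos(theta)])
    area = 0.5 * float(np.sum(r[:-1] ** 2) * (2 * np.pi / n))
    perim = polygon_perimeter(poly)
    ev = np.linalg.eigvalsh(_polygon_second_moments(poly))
    d = float(np.sqrt(ev[1] / ev[0]))
    major = float(4.0 * np.sqrt(ev[1]))
    return area, perim, d, major


def _analytic_profile(
    shapes: list[FrameShape], spec: ViscoelasticCellSpec, render: RenderSpec,
    window: int = DEFAULT_WINDOW,
) -> BiophysicalProfile:
    """Profile of the noise-free continuous trajectory (extraction oracle).

    All quantities are measured on the perturbed analytic boundary exactly
    as the extractor measures them on pixels; without boundary modes the
    deformability reduces to the area-conserving identity D = (1+eps)^2.
    """
    arrival = render.n_pre_frames
    last_j = arrival + render.n_junction_frames - 1
    theta = 2 * np.pi * np.arange(360) / 360

    meas = [_shape_measures(s) for s in shapes]
    areas = np.array([m[0] for m in meas])
    deform = np.array([m[2] for m in meas])
    majors = np.array([m[3] for m in meas])

    area0, perim0, _, _ = meas[0]
    A = 2.0 * np.sqrt(area0 / np.pi)
    C1 = 4 * np.pi * area0 / perim0**2
    strains = (majors - A) / A

    j = slice(arrival, last_j + 1)
    d3_rel = int(np.argmax(deform[j]))
    dt = render.frame_interval
    js = strains[j]
    T2 = float(np.max(np.diff(js)) / dt) if js.size >= 2 else 0.0

    M1, M2 = morphology_metrics(shapes[0].radius(theta), window)
    M3, M4 = morphology_metrics(shapes[arrival + d3_rel].radius(theta), window)

    return BiophysicalProfile(
        A=float(A), C1=float(C1),
        D1=float(deform[arrival]), D2=float(deform[j].mean()),
        D3=float(deform[j][d3_rel]), D4=float(deform[-1]),
        T1=d3_rel * dt, T2=T2, S1=float(js.max()), S2=float(strains[-1]),
        M1=M1, M2=M2, M3=M3, M4=M4,
        AR1=float(areas[arrival + d3_rel] / area0),  # 1 by incompressibility
    )


def render_event(
    trajectory: list[FrameShape],
    render: RenderSpec,
    seed: int,
    spec: ViscoelasticCellSpec | None = None,
    event_id: str = "event-0",
    label: str | None = None,
) -> CellEvent:
    """Rasterize a trajectory into a noisy frame stack.

    Each frame is the filled perturbed ellipse blurred with the Gaussian
    PSF plus additive Gaussian noise.  When ``spec`` is given, the event's
    ``ground_truth`` is the profile of the noise-free continuous shape.
    """
    if not trajectory:
        raise InvalidSpecError("trajectory must be nonempty")
    rng = np.random.default_rng(seed)
    frames = []
    for shape in trajectory:
        img = _rasterize(shape, render)
        if render.noise_sd > 0:
            img = img + rng.normal(0, render.noise_sd, img.shape)
        frames.append(img)
    gt = _analytic_profile(trajectory, spec, render) if spec is not None else None
    return CellEvent(
        event_id=event_id, frames=frames,
        frame_interval=render.frame_interval, pixel_size=render.pixel_size,
        junction_arrival_index=render.n_pre_frames,
        ground_truth=gt, label=label,
    )


def simulate_event(
    spec: ViscoelasticCellSpec, render: RenderSpec,
    event_id: str = "event-0", label: str | None = None,
) -> CellEvent:
    """Convenience wrapper: trajectory + rendering, seeded from the spec."""
    traj = simulate_trajectory(spec, render)
    return render_event(traj, render, seed=spec.rng_seed, spec=spec,
                        event_id=event_id, label=label)


def sample_cell_specs(
    n: int,
    rng: np.random.Generator,
    diameter_mean: float = 15.0,
    diameter_sd: float = 1.5,
    max_strain_mean: float = 0.5,
    max_strain_sd: float = 0.05,
    creep_time: float = 2.0,
    recovery_fraction: float = 0.8,
    recovery_time: float = 2.0,
    mode_k: int = 6,
    mode_amp_mean: float = 0.02,
    mode_amp_sd: float = 0.005,
) -> list[ViscoelasticCellSpec]:
    """Draw a population of cell specs with Gaussian diameter/strain spread."""
    specs = []
    for _ in range(n):
        d = max(float(rng.normal(diameter_mean, diameter_sd)), 0.2 * diameter_mean)
        eps = max(float(rng.normal(max_strain_mean, max_strain_sd)), 0.0)
        amp = float(np.clip(rng.normal(mode_amp_mean, mode_amp_sd), 0.0, 0.29))
        specs.append(ViscoelasticCellSpec(
            initial_diameter=d, max_strain=eps, creep_time=creep_time,
            recovery_fraction=recovery_fraction, recovery_time=recovery_time,
            boundary_modes=[(mode_k, amp)] if amp > 0 else [],
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return specs


# ---------------------------------------------------------------------------
# feature-space populations


@dataclass
class PopulationSpec:
    """A feature-space cell population: truncated multivariate Gaussian."""

    class_name: str
    mean: np.ndarray
    covariance: np.ndarray
    n_cells: int = 1000
    rng_seed: int = 0
    feature_names: tuple[str, ...] = PARAMETER_NAMES
    truncation_bounds: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        p = len(self.feature_names)
        if self.mean.shape != (p,):
            raise InvalidSpecError("mean length must match feature_names")
        if self.covariance.shape != (p, p):
            raise InvalidSpecError("covariance must be p x p")
        if not np.allclose(self.covariance, self.covariance.T):
            raise InvalidSpecError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.covariance).min() < -1e-10:
            raise InvalidSpecError("covariance must be positive semi-definite")

    def bounds(self) -> dict[str, tuple[float, float]]:
        """Physical parameter ranges enforced by truncation."""
        b = {
            "A": (1e-9, np.inf), "AR1": (1e-9, np.inf),
            "D1": (1.0, np.inf), "D2": (1.0, np.inf),
            "D3": (1.0, np.inf), "D4": (1.0, np.inf),
            "T1": (0.0, np.inf), "M2": (0.0, np.inf), "M4": (0.0, np.inf),
        }
        if self.truncation_bounds:
            b.update(self.truncation_bounds)
        return {k: v for k, v in b.items() if k in self.feature_names}


def generate_feature_population(spec: PopulationSpec) -> pd.DataFrame:
    """Sample a feature table from a truncated multivariate Gaussian.

    Out-of-bounds draws are rejected and redrawn, so marginals are exact
    truncations; reproducible under ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    names = list(spec.feature_names)
    bounds = spec.bounds()
    lo = np.array([bounds.get(f, (-np.inf, np.inf))[0] for f in names])
    hi = np.array([bounds.get(f, (-np.inf, np.inf))[1] for f in names])

    out = np.empty((spec.n_cells, len(names)))
    got = 0
    attempts = 0
    while got < spec.n_cells:
        m = max(spec.n_cells - got, 256)
        draw = rng.multivariate_normal(spec.mean, spec.covariance, size=m,
                                       method="cholesky" if
                                       np.linalg.eigvalsh(spec.covariance).min() > 1e-12
                                       else "svd")
        ok = draw[np.all((draw >= lo) & (draw <= hi), axis=1)]
        take = min(len(ok), spec.n_cells - got)
        out[got:got + take] = ok[:take]
        got += take
        attempts += 1
        if attempts > 1000:
            raise InvalidSpecError(
                "truncation bounds reject nearly all probability mass")
    table = pd.DataFrame(out, columns=names)
    table["label"] = spec.class_name
    return table


def largest_remainder_allocation(fractions: Sequence[float], n_total: int) -> np.ndarray:
    """Integer counts summing to n_total, proportional to fractions.

    Floor allocation plus distribution of the leftover units to the
    largest fractional remainders (ties broken by lowest index).
    """
    f = np.asarray(fractions, dtype=float)
    if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise InvalidSpecError("fractions must be nonnegative and sum to 1")
    exact = f * n_total
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    short = n_total - counts.sum()
    # stable sort => ties go to the lowest index
    order = np.argsort(-remainder, kind="stable")
    counts[order[:short]] += 1
    return counts


def generate_spiked_mixture(
    specs: Sequence[PopulationSpec],
    fractions: Sequence[float],
    n_total: int,
    seed: int,
) -> pd.DataFrame:
    """Spike-in mixture with exact per-class counts and true labels.

    Emulates mixing experiments in which pure populations are combined at
    known ratios; counts follow the exact largest-remainder allocation so
    the true mixing fractions are exact by construction.
    """
    if len(specs) != len(fractions):
        raise InvalidSpecError("one fraction per population spec required")
    counts = largest_remainder_allocation(fractions, n_total)
    rng = np.random.default_rng(seed)
    parts = []
    for i, (spec, c) in enumerate(zip(specs, counts)):
        sub = PopulationSpec(
            class_name=spec.class_name, mean=spec.mean,
            covariance=spec.covariance, n_cells=int(c),
            rng_seed=int(rng.integers(0, 2**31 - 1)),
            feature_names=spec.feature_names,
            truncation_bounds=spec.truncation_bounds,
        )
        parts.append(generate_feature_population(sub))
    table = pd.concat(parts, ignore_index=True)
    perm = rng.permutation(len(table))
    return table.iloc[perm].reset_index(drop=True)
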