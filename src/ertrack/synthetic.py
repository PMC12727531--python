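"""Synthetic single-molecule data with known ground truth.

Monte Carlo Brownian and confined trajectories, diffusion mixtures with
known population fractions, ER-like tubule networks with known junction
coordinates, distance-dependent puncta intensities and FRAP / optogenetic
recruitment time series.  Every generator is deterministic given its seed, so
each analysis stage can be tested for parameter recovery without any
external data.

The random-walk model: at each time step a particle draws an independent
zero-mean Gaussian displacement along each Cartesian axis with standard
deviation sqrt(2 D Δt) — the 1D Brownian propagator for a free diffusion
coefficient D.  3D runs are projected to (x, y) for analysis, mimicking
near-TIRF imaging of a quasi-planar ER; localization error is additive
Gaussian noise per frame per axis (standard deviation σ), not cumulative,
which yields the familiar 4σ² MSD intercept in 2D.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .io_tracks import ImageStack, Localization, Trajectory, TrajectorySet
from .kinetics import KineticTrace


@dataclass
class SimulationConfig:
    """Parameters of a Brownian / confined mixture simulation.

    ``diffusion_coefficients`` and ``fractions`` define the mixture; a single
    population is the usual case.  ``confinement_radius`` (µm) only applies
    to :func:`simulate_confined`.
    """

    diffusion_coefficients: list[float] = field(default_factory=lambda: [0.01])
    fractions: list[float] = field(default_factory=lambda: [1.0])
    dimensionality: int = 2
    step_interval: float = 1.0  # s
    n_steps: int = 20
    n_particles: int = 100
    localization_sigma: float = 0.0  # µm
    confinement_radius: float | None = None  # µm
    seed: int = 0
    field_size: float = 20.0  # µm, start positions drawn uniformly in this box

    def __post_init__(self) -> None:
        if len(self.diffusion_coefficients) != len(self.fractions):
            raise ValueError("diffusion_coefficients and fractions must have equal length")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be >= 0")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if any(d < 0 for d in self.diffusion_coefficients):
            raise ValueError("diffusion coefficients must be >= 0")
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.step_interval <= 0:
            raise ValueError("step_interval must be > 0")
        if self.localization_sigma < 0:
            raise ValueError("localization_sigma must be >= 0")
        if self.confinement_radius is not None and self.confinement_radius <= 0:
            raise ValueError("confinement_radius must be > 0 when set")


@dataclass
class GroundTruth:
    """Per-trajectory truth emitted alongside synthetic data."""

    population_index: np.ndarray | None = None  # per trajectory
    fractions: list[float] | None = None
    diffusion_coefficients: list[float] | None = None
    confined: np.ndarray | None = None  # bool per trajectory
    junctions_um: np.ndarray | None = None  # (k, 2) x,y
    t_half: float | None = None

    def __post_init__(self) -> None:
        if self.population_index is not None and self.fractions is not None:
            if self.population_index.max(initial=-1) >= len(self.fractions):
                raise ValueError("population index out of range")


def _assign_populations(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(len(cfg.fractions), size=cfg.n_particles, p=np.asarray(cfg.fractions))


def _to_trajectory_set(positions: np.ndarray, cfg: SimulationConfig, condition: str) -> TrajectorySet:
    """positions: (n_particles, n_frames, ndim) µm; keeps only x, y."""
    dt = cfg.step_interval
    trajs = []
    for i in range(positions.shape[0]):
        pts = [
            Localization(t=j * dt, x=float(positions[i, j, 0]), y=float(positions[i, j, 1]), frame=j)
            for j in range(positions.shape[1])
        ]
        trajs.append(Trajectory(track_id=str(i), points=pts))
    return TrajectorySet(trajs, frame_interval=dt, pixel_size=0.1, condition=condition)


def simulate_brownian(config: SimulationConfig) -> tuple[TrajectorySet, GroundTruth]:
    """Free Brownian mixture; per-axis steps ~ N(0, 2 D Δt), noise N(0, σ²)."""
    rng = np.random.default_rng(config.seed)
    ndim = config.dimensionality
    n, m = config.n_particles, config.n_steps
    pop = _assign_populations(config, rng)
    d_per = np.asarray(config.diffusion_coefficients)[pop]  # (n,)
    scale = np.sqrt(2.0 * d_per * config.step_interval)[:, None, None]
    steps = rng.standard_normal((n, m, ndim)) * scale
    starts = rng.uniform(0, config.field_size, size=(n, 1, ndim))
    pos = np.concatenate([starts, starts + np.cumsum(steps, axis=1)], axis=1)
    if config.localization_sigma > 0:
        pos = pos + rng.standard_normal(pos.shape) * config.localization_sigma
    ts = _to_trajectory_set(pos, config, condition="brownian")
    gt = GroundTruth(
        population_index=pop,
        fractions=list(config.fractions),
        diffusion_coefficients=list(config.diffusion_coefficients),
        confined=np.zeros(n, dtype=bool),
    )
    return ts, gt


def _reflect_radial(pos: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Fold positions outside a disc/sphere of ``radius`` back inside.

    Radial multiple reflection: the radial coordinate is mapped through the
    triangle wave of period 2·radius, which is the exact result of repeated
    specular reflection along the radial direction — valid for steps of any
    size relative to the radius.
    """
    rel = pos - center
    r = np.linalg.norm(rel, axis=-1, keepdims=True)
    m = np.mod(r, 2 * radius)
    folded = radius - np.abs(m - radius)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(r > 0, rel * (folded / np.maximum(r, 1e-300)), rel)
    return center + rel


def simulate_confined(config: SimulationConfig) -> tuple[TrajectorySet, GroundTruth]:
    """Brownian steps reflected at a circular (2D) / spherical (3D) boundary.

    Populations with a finite ``confinement_radius`` are confined about each
    particle's start point; the long-time MSD then plateaus at a value set by
    the radius instead of growing linearly.
    """
    if config.confinement_radius is None:
        raise ValueError("confinement_radius must be set for simulate_confined")
    if config.localization_sigma >= config.confinement_radius:
        import warnings

        warnings.warn(
            "localization_sigma >= confinement_radius: confinement is unresolvable",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    ndim = config.dimensionality
    n, m = config.n_particles, config.n_steps
    pop = _assign_populations(config, rng)
    d_per = np.asarray(config.diffusion_coefficients)[pop]
    scale = np.sqrt(2.0 * d_per * config.step_interval)[:, None]
    starts = rng.uniform(0, config.field_size, size=(n, ndim))
    pos = np.empty((n, m + 1, ndim))
    pos[:, 0] = starts
    cur = starts.copy()
    for j in range(m):
        cur = cur + rng.standard_normal((n, ndim)) * scale
        cur = _reflect_radial(cur, starts, config.confinement_radius)
        pos[:, j + 1] = cur
    if config.localization_sigma > 0:
        pos = pos + rng.standard_normal(pos.shape) * config.localization_sigma
    ts = _to_trajectory_set(pos, config, condition="confined")
    gt = GroundTruth(
        population_index=pop,
        fractions=list(config.fractions),
        diffusion_coefficients=list(config.diffusion_coefficients),
        confined=np.ones(n, dtype=bool),
    )
    return ts, gt


def simulate_mixture(
    confined_fraction: float,
    free_d: float,
    confined_d: float,
    confinement_radius: float,
    n_particles: int,
    n_steps: int = 12,
    step_interval: float = 1.0,
    localization_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[TrajectorySet, GroundTruth]:
    """Mixture of confined and free particles with per-trajectory truth labels.

    The confined subpopulation models translating, ER-tethered mRNA; the free
    subpopulation models untethered mRNA.  Trajectory ids are remapped so the
    output ordering carries no population information.
    """
    rng = np.random.default_rng(seed)
    n_conf = int(round(confined_fraction * n_particles))
    base = dict(
        dimensionality=2,
        step_interval=step_interval,
        n_steps=n_steps,
        localization_sigma=localization_sigma,
    )
    parts: list[Trajectory] = []
    confined_flags: list[bool] = []
    if n_conf > 0:
        cfg_c = SimulationConfig(
            diffusion_coefficients=[confined_d],
            fractions=[1.0],
            n_particles=n_conf,
            confinement_radius=confinement_radius,
            seed=int(rng.integers(2**31)),
            **base,
        )
        ts_c, _ = simulate_confined(cfg_c)
        parts += ts_c.trajectories
        confined_flags += [True] * n_conf
    if n_particles - n_conf > 0:
        cfg_f = SimulationConfig(
            diffusion_coefficients=[free_d],
            fractions=[1.0],
            n_particles=n_particles - n_conf,
            seed=int(rng.integers(2**31)),
            **base,
        )
        ts_f, _ = simulate_brownian(cfg_f)
        parts += ts_f.trajectories
        confined_flags += [False] * (n_particles - n_conf)
    order = rng.permutation(len(parts))
    trajs = []
    flags = np.empty(len(parts), dtype=bool)
    for new_id, old in enumerate(order):
        tr = parts[old]
        trajs.append(Trajectory(track_id=str(new_id), points=tr.points, cell_id=tr.cell_id))
        flags[new_id] = confined_flags[old]
    ts = TrajectorySet(trajs, frame_interval=step_interval, pixel_size=0.1, condition="mixture")
    gt = GroundTruth(
        population_index=flags.astype(int),
        fractions=[1 - confined_fraction, confined_fraction],
        diffusion_coefficients=[free_d, confined_d],
        confined=flags,
    )
    return ts, gt


def sample_displacements_cdf(
    fractions: list[float],
    diffusion_coefficients: list[float],
    lag_t: float,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Draw 2D displacement magnitudes from a diffusion mixture.

    For a population with coefficient D the squared displacement over lag t
    is exponential with mean 4 D t, i.e. the displacement CDF is
    1 − exp(−r²/(4 D t)); this is the generative inverse of the mixture
    model fitted downstream.
    """
    if abs(sum(fractions) - 1) > 1e-9 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    pop = rng.choice(len(fractions), size=n, p=np.asarray(fractions))
    d = np.asarray(diffusion_coefficients)[pop]
    r2 = rng.exponential(scale=4.0 * d * lag_t)
    return np.sqrt(r2)


# ---------------------------------------------------------------------------
# ER tubule network fixture


def synth_er_network(
    n_junctions: int,
    field_size: float = 20.0,
    tubule_width: float = 0.2,
    pixel_size: float = 0.05,
    seed: int = 0,
    intensity: float = 1000.0,
) -> tuple[ImageStack, GroundTruth]:
    """Render a connected tubule network whose 3-way nodes are the junctions.

    Junction nodes are laid out on a jittered grid, connected by a
    boustrophedon backbone, and given outward spokes so that every junction
    has tubule degree exactly 3 and spokes never cross — the recorded
    coordinates are an exact ground truth for branch-point detection.
    """
    rng = np.random.default_rng(seed)
    npx = int(round(field_size / pixel_size))
    img = np.zeros((npx, npx), dtype=float)

    def draw_segment(p0: np.ndarray, p1: np.ndarray) -> None:
        from skimage.draw import line

        r0, c0 = int(p0[1] / pixel_size), int(p0[0] / pixel_size)
        r1, c1 = int(p1[1] / pixel_size), int(p1[0] / pixel_size)
        rr, cc = line(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < npx) & (cc >= 0) & (cc < npx)
        img[rr[ok], cc[ok]] = 1.0

    if n_junctions == 0:
        # single straight tubule across the field
        y = field_size * 0.5 + rng.uniform(-0.1, 0.1)
        draw_segment(np.array([field_size * 0.1, y]), np.array([field_size * 0.9, y]))
        junctions = np.empty((0, 2))
    else:
        # Junction nodes on a jittered grid, one row backbone per grid row;
        # rows are joined by degree-2 elbow paths outside the grid so every
        # junction sits on a locally straight backbone.  Spokes are then
        # added perpendicular-ish (greedy max angular separation from the
        # incident edges) until each junction has tubule degree exactly 3.
        side = int(np.ceil(np.sqrt(n_junctions)))
        cell = field_size * 0.8 / max(side, 2)
        margin = field_size * 0.1
        nodes: list[np.ndarray] = []
        rows: list[list[int]] = []
        k = 0
        for gy in range(side):
            row = []
            for gx in range(side):
                if k >= n_junctions:
                    break
                jitter = rng.uniform(-0.1, 0.1, size=2) * cell
                nodes.append(
                    np.array([margin + (gx + 0.5) * cell, margin + (gy + 0.5) * cell]) + jitter
                )
                row.append(k)
                k += 1
            if row:
                rows.append(row)
        junctions = np.array(nodes)
        incident: dict[int, list[np.ndarray]] = {i: [] for i in range(len(nodes))}

        def connect(i: int, j: int, via: list[np.ndarray] = ()) -> None:
            path = [nodes[i], *via, nodes[j]]
            for a, b in zip(path, path[1:]):
                draw_segment(a, b)
            incident[i].append((path[1] - nodes[i]) / np.linalg.norm(path[1] - nodes[i]))
            incident[j].append((path[-2] - nodes[j]) / np.linalg.norm(path[-2] - nodes[j]))

        for row in rows:
            for a, b in zip(row, row[1:]):
                connect(a, b)
        for r in range(len(rows) - 1):
            if r % 2 == 0:  # join on the right, then left, alternating
                a, b = rows[r][-1], rows[r + 1][-1]
                x_out = max(nodes[a][0], nodes[b][0]) + 0.5 * cell
            else:
                a, b = rows[r][0], rows[r + 1][0]
                x_out = min(nodes[a][0], nodes[b][0]) - 0.5 * cell
            connect(a, b, via=[np.array([x_out, nodes[a][1]]), np.array([x_out, nodes[b][1]])])

        spoke_len = 0.3 * cell
        angles = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        for i, p in enumerate(nodes):
            while len(incident[i]) < 3:
                dirs = np.array(incident[i])
                # pick the candidate direction farthest from all incident ones
                cand = np.column_stack([np.cos(angles), np.sin(angles)])
                score = np.min(np.arccos(np.clip(cand @ dirs.T, -1, 1)), axis=1) if len(dirs) else np.ones(len(cand))
                u = cand[int(np.argmax(score))]
                draw_segment(p, p + u * spoke_len)
                incident[i].append(u)

    from skimage.morphology import dilation, disk

    radius_px = max(1, int(round(tubule_width / 2 / pixel_size)))
    mask = dilation(img > 0, disk(radius_px))
    out = np.where(mask, intensity, 0.0) + rng.normal(0, intensity * 0.01, size=img.shape)
    stack = ImageStack(out, pixel_size=pixel_size)
    return stack, GroundTruth(junctions_um=junctions)


def synth_puncta_near_refs(
    refs_um: np.ndarray,
    n_puncta: int,
    field_size: float,
    near_intensity: float,
    far_intensity: float,
    near_cutoff_um: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random puncta whose intensity steps with distance to refs.

    Returns (positions (n,2) µm, intensities).  Intensity is
    ``near_intensity`` within ``near_cutoff_um`` of the nearest reference and
    ``far_intensity`` beyond — a minimal model of translation signal
    enrichment near organelles.
    """
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, field_size, size=(n_puncta, 2))
    d, _ = cKDTree(np.asarray(refs_um)).query(pts)
    inten = np.where(d < near_cutoff_um, near_intensity, far_intensity)
    return pts, inten


# ---------------------------------------------------------------------------
# kinetic traces


def synth_kinetic_trace(
    kind: Literal["frap", "recruitment"],
    plateau: float,
    rate: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = 1.0,
    n_pre: int = 10,
    duration: float = 120.0,
    bleach_fraction: float = 0.25,
    recovery_fraction: float = 1.0,
) -> KineticTrace:
    """Synthetic FRAP or optogenetic-recruitment time series.

    FRAP: ``n_pre`` pre-bleach frames at ``plateau``, instantaneous bleach to
    ``bleach_fraction * plateau``, then saturating-exponential recovery toward
    ``bleach + recovery_fraction * (plateau - bleach)`` with rate constant
    ``rate`` (1/s).  Recruitment: baseline 0 before activation, then
    ``I(t) = plateau * (1 - exp(-rate * t))``.  t = 0 at the event frame; the
    half-rise time of the noiseless curve is ln(2)/rate.
    """
    rng = np.random.default_rng(seed)
    n_post = int(round(duration / dt)) + 1
    times = np.concatenate([np.arange(-n_pre, 0) * dt, np.arange(n_post) * dt])
    tpost = np.arange(n_post) * dt
    if kind == "frap":
        bleach = bleach_fraction * plateau
        target = bleach + recovery_fraction * (plateau - bleach)
        post = target - (target - bleach) * np.exp(-rate * tpost) if rate > 0 else np.full(n_post, bleach)
        intensities = np.concatenate([np.full(n_pre, plateau), post])
    elif kind == "recruitment":
        post = plateau * (1.0 - np.exp(-rate * tpost)) if rate > 0 else np.zeros(n_post)
        intensities = np.concatenate([np.zeros(n_pre), post])
    else:
        raise ValueError(f"unknown trace kind {kind!r}")
    if noise_sd > 0:
        intensities = intensities + rng.normal(0, noise_sd, size=intensities.shape)
    return KineticTrace(times=times, intensities=intensities, event_index=n_pre)
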