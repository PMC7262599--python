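"""Synthetic time-lapse generator with known geometry and kinematics.

Emulates the imaging regime the pipeline targets: flat "fried egg" cells
with an elliptical nucleus, two diffraction-limited centrosome spots
(~3 px) moving at 0.1–0.5 μm/min, frames every 5 min, separation ending
near 10 μm inter-centrosome distance, optional radially moving EB3 comets
and a perinuclear actin annulus.  Every movie comes with a ground-truth
table so detection, segmentation, tracking and metrics are all verifiable
without microscopy data.

Conventions: image arrays are (row, col) = (y, x), 0-based; physical
coordinates are (x, y) in μm = (col, row) × pixel size.  The simulator is
2D — the geometry of these cells reduces to two dimensions — but a
constant z column is emitted so 3D-capable consumers run unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask

from .io import ImageStack

MODES = ("separation", "congression", "stall_at_NE", "stationary", "detach")


class SceneError(ValueError):
    """Invalid scene configuration (e.g. nucleus not inside cell)."""


@dataclass
class SceneConfig:
    """Static geometry and rendering parameters of one synthetic cell.

    Lengths are μm unless the name says px.  Defaults describe a U2OS-like
    cell at 0.2 μm/px: ~18 × 12 μm nucleus inside a ~44 × 36 μm cell,
    imaged every 5 min with peak spot SNR well above 5.
    """

    shape_px: tuple[int, int] = (256, 256)       # (Y, X)
    pixel_size_um: float = 0.2
    frame_interval_min: float = 5.0
    n_frames: int = 40
    nucleus_center_um: tuple[float, float] | None = None  # default: image center
    nucleus_semiaxes_um: tuple[float, float] = (9.0, 6.0)
    nucleus_orientation_deg: float = 0.0
    cell_semiaxes_um: tuple[float, float] = (22.0, 18.0)
    cell_polygon_um: np.ndarray | None = None    # (N, 2) x,y vertices; overrides ellipse
    background: float = 100.0
    read_noise: float = 5.0                      # Gaussian sigma, intensity units
    photon_scale: float = 1.0                    # Poisson scaling; 0 disables shot noise
    psf_sigma_px: float = 1.5                    # spot size ~3 px FWHM-ish
    channel_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"centrosome": 300.0, "dna": 150.0, "tubulin": 120.0}
    )
    comet_speed_um_min: float = 0.25
    comet_rate_per_frame: int = 5                # new comets per centrosome per frame
    comet_lifetime_frames: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise SceneError("pixel size must be positive")
        if self.frame_interval_min <= 0:
            raise SceneError("frame interval must be positive")
        if min(self.nucleus_semiaxes_um) <= 0 or min(self.cell_semiaxes_um) <= 0:
            raise SceneError("semi-axes must be positive")

    @property
    def center_um(self) -> tuple[float, float]:
        if self.nucleus_center_um is not None:
            return tuple(self.nucleus_center_um)
        ny, nx = self.shape_px
        return ((nx - 1) / 2 * self.pixel_size_um, (ny - 1) / 2 * self.pixel_size_um)


@dataclass
class TrajectoryProgram:
    """Programmed motion of the two centrosomes of one cell.

    modes: separation (engaged pair moves apart to target distance/angle),
    congression (separated pair moves to the nuclear centroid), stall_at_NE
    (approach from the cytoplasm, pause at the nuclear envelope, continue),
    stationary, detach (move radially away from the nucleus).
    """

    mode: str = "separation"
    speeds_um_min: tuple[float, float] = (0.3, 0.3)   # per-centrosome, may differ
    start_um: tuple[tuple[float, float], tuple[float, float]] | None = None
    target_distance_um: float = 10.0                  # separation endpoint
    target_angle_deg: float = 180.0                   # at the nuclear centroid
    axis_angle_deg: float = 0.0                       # orientation of the pair axis
    noise_sigma_um: float = 0.0                       # positional jitter per frame
    onset_frame: int = 3                              # pre-phase length (separation)
    dwell_min: float = 20.0                           # NE pause duration (stall mode)
    contact_threshold_um: float = 1.5

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; one of {MODES}")
        if min(self.speeds_um_min) < 0:
            raise ValueError("speeds must be >= 0")
        if not (0.0 < self.target_angle_deg <= 180.0):
            raise ValueError("target angle must be in (0, 180] degrees")
        if self.target_distance_um < 0:
            raise ValueError("target distance must be >= 0")


@dataclass
class Scene:
    """Rasterized geometry: masks plus analytic centroids (μm)."""

    config: SceneConfig
    nucleus_mask: np.ndarray
    cell_mask: np.ndarray
    nuclear_centroid_um: tuple[float, float]
    cellular_centroid_um: tuple[float, float]
    nucleus_boundary_um: np.ndarray  # (N, 2) x,y polygon


@dataclass
class GroundTruth:
    """Per-frame true positions and phase labels; the oracle for all tests."""

    table: pd.DataFrame   # cell_id, frame, t_min, centrosome_id, x_um, y_um, z_um, phase
    congressed: bool
    t_contact_min: float | None
    target_reached: bool
    program: TrajectoryProgram

    def positions(self, centrosome_id: int) -> np.ndarray:
        sub = self.table[self.table.centrosome_id == centrosome_id]
        return sub[["x_um", "y_um"]].to_numpy()


# ---------------------------------------------------------------------------
# scene construction

def _ellipse_mask(shape_px, center_um, semiaxes_um, orientation_deg, pixel_size):
    ny, nx = shape_px
    yy, xx = np.mgrid[0:ny, 0:nx]
    # work in pixel units so a symmetric center yields a symmetric mask
    # (μm-space arithmetic breaks ties differently left and right of center)
    x = (xx - center_um[0] / pixel_size) * pixel_size
    y = (yy - center_um[1] / pixel_size) * pixel_size
    th = math.radians(orientation_deg)
    xr = x * math.cos(th) + y * math.sin(th)
    yr = -x * math.sin(th) + y * math.cos(th)
    a, b = semiaxes_um
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def ellipse_boundary(center_um, semiaxes_um, orientation_deg=0.0, n=360):
    """Sampled (x, y) μm polygon of an ellipse boundary."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    a, b = semiaxes_um
    th = math.radians(orientation_deg)
    x = a * np.cos(t)
    y = b * np.sin(t)
    xr = x * math.cos(th) - y * math.sin(th) + center_um[0]
    yr = x * math.sin(th) + y * math.cos(th) + center_um[1]
    return np.column_stack([xr, yr])


def make_scene(config: SceneConfig) -> Scene:
    """Rasterize nucleus and cell masks; centroids match the analytic
    ellipse centers to within half a pixel."""
    px = config.pixel_size_um
    c = config.center_um
    nuc = _ellipse_mask(
        config.shape_px, c, config.nucleus_semiaxes_um,
        config.nucleus_orientation_deg, px,
    )
    if config.cell_polygon_um is not None:
        poly = np.asarray(config.cell_polygon_um, float)
        cell = polygon2mask(config.shape_px, poly[:, ::-1] / px)  # (x,y)μm -> (r,c)px
    else:
        cell = _ellipse_mask(config.shape_px, c, config.cell_semiaxes_um, 0.0, px)
    if not nuc.any():
        raise SceneError("nucleus does not intersect the image")
    if not (cell | ~nuc).all() or not (cell[nuc]).all():
        raise SceneError("nucleus mask is not contained in the cell mask")

    def mask_centroid(m):
        rr, cc = np.nonzero(m)
        return (cc.mean() * px, rr.mean() * px)

    return Scene(
        config=config,
        nucleus_mask=nuc,
        cell_mask=cell,
        nuclear_centroid_um=mask_centroid(nuc),
        cellular_centroid_um=mask_centroid(cell),
        nucleus_boundary_um=ellipse_boundary(
            c, config.nucleus_semiaxes_um, config.nucleus_orientation_deg
        ),
    )


# ---------------------------------------------------------------------------
# trajectories

def _pair_endpoints(center, distance, angle_deg, axis_deg):
    """Place two points about `center` so their angle at the center is
    `angle_deg` and their separation is `distance`.

    Both constraints hold with a symmetric radius r = D / sqrt(2(1-cosθ)).
    """
    th = math.radians(angle_deg)
    r = distance / math.sqrt(2.0 * (1.0 - math.cos(th))) if th > 0 else 0.0
    phi = math.radians(axis_deg)
    out = []
    for s in (+1, -1):
        ang = phi + s * th / 2.0
        out.append(
            (center[0] + r * math.cos(ang), center[1] + r * math.sin(ang))
        )
    return np.array(out)


def _walk_to(start, target, speed, dt, n_frames, hold=0):
    """Constant-speed straight-line path from start toward target; clamps at
    the target.  `hold` initial frames are stationary.  Returns (n_frames, 2)
    positions and a boolean 'moving' array."""
    pos = np.empty((n_frames, 2))
    moving = np.zeros(n_frames, bool)
    p = np.asarray(start, float)
    tgt = np.asarray(target, float)
    step = speed * dt
    for i in range(n_frames):
        pos[i] = p
        if i < hold:
            continue
        d = tgt - p
        dist = math.hypot(*d)
        if dist <= 1e-9:
            continue
        moving[i] = True
        p = tgt.copy() if dist <= step else p + d / dist * step
    return pos, moving


def simulate_pair(
    program: TrajectoryProgram,
    scene: Scene,
    n_frames: int | None = None,
    seed: int = 0,
    cell_id: int = 0,
) -> GroundTruth:
    """Generate the true centrosome-pair trajectory for one cell.

    Deterministic under (program, scene, seed).  If the programmed endpoint
    is not reachable within the movie, the result is flagged
    (`target_reached=False`), never silently truncated.
    """
    cfg = scene.config
    n = n_frames if n_frames is not None else cfg.n_frames
    dt = cfg.frame_interval_min
    nc = np.asarray(scene.nuclear_centroid_um)
    v1, v2 = program.speeds_um_min
    rng = np.random.default_rng(seed)
    mode = program.mode

    finals = _pair_endpoints(
        nc, program.target_distance_um, program.target_angle_deg,
        program.axis_angle_deg,
    )

    if mode == "stationary":
        starts = (
            np.asarray(program.start_um, float)
            if program.start_um is not None else finals
        )
        pos = np.repeat(starts[:, None, :], n, axis=1)
        moving = np.zeros((2, n), bool)
        phases = np.full((2, n), "pre", object)
    elif mode == "separation":
        if program.start_um is not None:
            starts = np.asarray(program.start_um, float)
        else:
            # engaged pair 1 μm apart near the nuclear centroid, each offset
            # toward its own endpoint
            starts = np.array([
                nc + 0.5 * _unit(finals[0] - nc),
                nc + 0.5 * _unit(finals[1] - nc),
            ])
        pos, moving, phases = _run_two(
            starts, finals, (v1, v2), dt, n, hold=program.onset_frame
        )
    elif mode == "congression":
        if program.start_um is not None:
            starts = np.asarray(program.start_um, float)
        else:
            starts = finals  # begin separated at the programmed geometry
        pos, moving, phases = _run_two(
            starts, np.array([nc, nc]), (v1, v2), dt, n, hold=0
        )
    elif mode == "detach":
        if program.start_um is not None:
            starts = np.asarray(program.start_um, float)
        else:
            starts = _boundary_points(scene, program.axis_angle_deg)
        away = np.array([
            starts[0] + 1e3 * _unit(starts[0] - nc),
            starts[1] + 1e3 * _unit(starts[1] - nc),
        ])
        pos, moving, phases = _run_two(starts, away, (v1, v2), dt, n, hold=0)
    elif mode == "stall_at_NE":
        pos, moving, phases = _run_stall(program, scene, n, dt)
    else:  # pragma: no cover - guarded by TrajectoryProgram
        raise ValueError(mode)

    if program.noise_sigma_um > 0:
        pos = pos + rng.normal(0.0, program.noise_sigma_um, pos.shape)

    d = np.hypot(*(pos[0] - pos[1]).T)
    target_reached = _target_reached(mode, pos, finals, nc, d, program)
    below = d < program.contact_threshold_um
    if mode in ("congression",) and below.any():
        t_contact = float(np.argmax(below) * dt)
        congressed = True
    else:
        t_contact, congressed = None, False

    rows = []
    for cid in (0, 1):
        for f in range(n):
            rows.append(
                (cell_id, f, f * dt, cid, pos[cid, f, 0], pos[cid, f, 1], 0.0,
                 phases[cid, f])
            )
    table = pd.DataFrame(
        rows,
        columns=["cell_id", "frame", "t_min", "centrosome_id",
                 "x_um", "y_um", "z_um", "phase"],
    )
    return GroundTruth(table, congressed, t_contact, target_reached, program)


def _unit(v):
    nrm = math.hypot(*v)
    return np.asarray(v, float) / nrm if nrm > 0 else np.array([1.0, 0.0])


def _run_two(starts, targets, speeds, dt, n, hold):
    pos = np.empty((2, n, 2))
    moving = np.empty((2, n), bool)
    phases = np.empty((2, n), object)
    for i in range(2):
        pos[i], moving[i] = _walk_to(starts[i], targets[i], speeds[i], dt, n, hold)
        started = np.cumsum(moving[i]) > 0
        phases[i] = np.where(~started, "pre", np.where(moving[i], "active", "post"))
    return pos, moving, phases


def _boundary_points(scene, axis_deg):
    nc = np.asarray(scene.nuclear_centroid_um)
    b = scene.nucleus_boundary_um
    phi = math.radians(axis_deg)
    u = np.array([math.cos(phi), math.sin(phi)])
    proj = (b - nc) @ u
    return np.array([b[np.argmax(proj)], b[np.argmin(proj)]])


def _run_stall(program, scene, n, dt):
    """Approach the nucleus from the cytoplasm, pause at the envelope for
    `dwell_min`, then continue toward the nuclear centroid."""
    cfg = scene.config
    nc = np.asarray(scene.nuclear_centroid_um)
    contacts = _boundary_points(scene, program.axis_angle_deg)
    if program.start_um is not None:
        starts = np.asarray(program.start_um, float)
    else:
        starts = np.array([
            contacts[i] + 5.0 * _unit(contacts[i] - nc) for i in range(2)
        ])
    dwell_frames = int(round(program.dwell_min / dt))
    pos = np.empty((2, n, 2))
    phases = np.empty((2, n), object)
    moving = np.zeros((2, n), bool)
    for i in range(2):
        v = program.speeds_um_min[i]
        # leg 1: to the NE contact point
        leg1, mv1 = _walk_to(starts[i], contacts[i], v, dt, n)
        arrived = np.isclose(leg1, contacts[i]).all(axis=1)
        t_hit = int(np.argmax(arrived)) if arrived.any() else n
        for f in range(n):
            if f < t_hit:
                pos[i, f] = leg1[f]
                phases[i, f] = "outside"
                moving[i, f] = mv1[f]
            elif f < t_hit + dwell_frames:
                pos[i, f] = contacts[i]
                phases[i, f] = "pause"
            else:
                k = f - (t_hit + dwell_frames)
                leg2, mv2 = _walk_to(contacts[i], nc, v, dt, n)
                pos[i, f] = leg2[min(k, n - 1)]
                phases[i, f] = "inside"
                moving[i, f] = True
    return pos, moving, phases


def _target_reached(mode, pos, finals, nc, d, program):
    if mode == "separation":
        return bool(
            np.allclose(pos[:, -1, :], finals, atol=1e-6)
        )
    if mode == "congression":
        return bool(d[-1] < program.contact_threshold_um)
    return True


# ---------------------------------------------------------------------------
# comets

def simulate_comets(
    scene: Scene,
    truth: GroundTruth | None = None,
    seed: int = 0,
    n_frames: int | None = None,
) -> pd.DataFrame:
    """EB3-like comets nucleated at the centrosomes, moving radially outward
    at the configured speed until their lifetime ends or they leave the cell.

    Returns a long-format table (comet_id, frame, x_um, y_um, angle_rad)
    usable both for rendering and as tracking ground truth.
    """
    cfg = scene.config
    n = n_frames if n_frames is not None else cfg.n_frames
    dt = cfg.frame_interval_min
    speed = cfg.comet_speed_um_min
    rng = np.random.default_rng(seed)
    if truth is not None:
        origins = {
            f: truth.table[truth.table.frame == f][["x_um", "y_um"]].to_numpy()
            for f in range(n)
        }
    else:
        origins = {f: np.array([scene.nuclear_centroid_um]) for f in range(n)}
    ny, nx = cfg.shape_px
    xmax, ymax = (nx - 1) * cfg.pixel_size_um, (ny - 1) * cfg.pixel_size_um
    rows = []
    comet_id = 0
    for f0 in range(n):
        for origin in origins[f0]:
            for _ in range(cfg.comet_rate_per_frame):
                ang = rng.uniform(0, 2 * np.pi)
                u = np.array([math.cos(ang), math.sin(ang)])
                # nucleate slightly off the centrosome so comets don't sit
                # on top of the spot
                p0 = origin + 1.0 * u
                for age in range(cfg.comet_lifetime_frames):
                    f = f0 + age
                    if f >= n:
                        break
                    p = p0 + speed * dt * age * u
                    if not (0 <= p[0] <= xmax and 0 <= p[1] <= ymax):
                        break
                    rows.append((comet_id, f, p[0], p[1], ang))
                comet_id += 1
    return pd.DataFrame(rows, columns=["comet_id", "frame", "x_um", "y_um", "angle_rad"])


# ---------------------------------------------------------------------------
# rendering

def _add_gaussian(frame, x_px, y_px, amp, sigma, aspect=1.0, angle=0.0):
    """Accumulate an (optionally elongated) Gaussian at sub-pixel position."""
    half = int(math.ceil(4 * sigma * max(1.0, aspect)))
    r0, c0 = int(round(y_px)), int(round(x_px))
    ny, nx = frame.shape
    rlo, rhi = max(0, r0 - half), min(ny, r0 + half + 1)
    clo, chi = max(0, c0 - half), min(nx, c0 + half + 1)
    if rlo >= rhi or clo >= chi:
        return
    yy, xx = np.mgrid[rlo:rhi, clo:chi]
    dx, dy = xx - x_px, yy - y_px
    ca, sa = math.cos(angle), math.sin(angle)
    along = dx * ca + dy * sa
    perp = -dx * sa + dy * ca
    s_along = sigma * aspect
    frame[rlo:rhi, clo:chi] += amp * np.exp(
        -(along**2 / (2 * s_along**2) + perp**2 / (2 * sigma**2))
    )


def render_movie(
    scene: Scene,
    truth: GroundTruth | None = None,
    comets: pd.DataFrame | None = None,
    seed: int | None = None,
) -> ImageStack:
    """Render the configured channels into a T,C,Y,X stack.

    centrosome: Gaussian spots at the true positions; dna: nucleus mask;
    tubulin: textured cell body (so Gabor-based segmentation has structure
    to find); eb3: anisotropic comets; actin: perinuclear annulus.  Noise is
    Poisson shot noise plus Gaussian read noise, deterministic under the
    seed.
    """
    cfg = scene.config
    n = cfg.n_frames
    px = cfg.pixel_size_um
    roles = list(cfg.channel_amplitudes)
    for role in roles:
        if role not in ("centrosome", "dna", "tubulin", "eb3", "actin"):
            raise ValueError(f"unknown channel role {role!r}")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ny, nx = cfg.shape_px
    data = np.empty((n, len(roles), ny, nx), np.float32)

    texture = _cell_texture(scene, rng)
    actin_ring = _annulus(scene, halfwidth_um=1.0)
    if "eb3" in roles and comets is None and truth is not None:
        comets = simulate_comets(scene, truth, seed=int(rng.integers(2**31)))

    for f in range(n):
        for ci, role in enumerate(roles):
            amp = cfg.channel_amplitudes[role]
            img = np.full((ny, nx), cfg.background, float)
            if role == "centrosome" and truth is not None:
                sub = truth.table[truth.table.frame == f]
                for _, row in sub.iterrows():
                    _add_gaussian(img, row.x_um / px, row.y_um / px, amp,
                                  cfg.psf_sigma_px)
            elif role == "dna":
                img += amp * scene.nucleus_mask
            elif role == "tubulin":
                img += amp * texture
            elif role == "eb3" and comets is not None:
                sub = comets[comets.frame == f]
                for _, row in sub.iterrows():
                    _add_gaussian(img, row.x_um / px, row.y_um / px, amp,
                                  cfg.psf_sigma_px, aspect=2.0,
                                  angle=row.angle_rad)
            elif role == "actin":
                img += amp * actin_ring
            data[f, ci] = _apply_noise(img, cfg, rng)

    channels = {role: i for i, role in enumerate(roles)}
    return ImageStack(data, px, cfg.frame_interval_min, channels)


def _apply_noise(img, cfg, rng):
    out = np.clip(img, 0, None)
    if cfg.photon_scale > 0:
        out = rng.poisson(out * cfg.photon_scale) / cfg.photon_scale
    if cfg.read_noise > 0:
        out = out + rng.normal(0.0, cfg.read_noise, out.shape)
    return out.astype(np.float32)


def _cell_texture(scene: Scene, rng) -> np.ndarray:
    """Band-pass random texture restricted to the cell body; flat outside."""
    from scipy.ndimage import gaussian_filter

    noise = rng.standard_normal(scene.cell_mask.shape)
    band = gaussian_filter(noise, 1.0) - gaussian_filter(noise, 4.0)
    band = band / (np.abs(band).max() + 1e-12)
    return scene.cell_mask * (0.7 + 0.3 * band)


def _annulus(scene: Scene, halfwidth_um: float) -> np.ndarray:
    from scipy.ndimage import distance_transform_edt

    px = scene.config.pixel_size_um
    inside = distance_transform_edt(scene.nucleus_mask) * px
    outside = distance_transform_edt(~scene.nucleus_mask) * px
    dist = np.where(scene.nucleus_mask, inside, -outside)  # signed, >0 inside
    return (np.abs(dist) <= halfwidth_um).astype(float)
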