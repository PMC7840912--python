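"""Synthetic ground-truthed movie simulator.

Encodes the observed life cycle of mutant-keratin granules: Poisson
nucleation restricted to the peripheral two thirds of an annular
granule-bearing zone at the cell margin, sigmoidal fluorescence growth
to a plateau followed by fast near-linear dissolution, inward radial
drift whose speed falls with granule size, pairwise fusion of granules
that come closer than a capture radius, and erratic (purely diffusive)
terminal motion.  Granules are rendered as Gaussian point-spread
blobs with Poisson shot noise and Gaussian read noise on a 16-bit
detector.

The same module provides bare-trajectory generators (Brownian,
drifting, box-confined) used to benchmark the MSD anomalous-exponent
analysis against motion of known class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import Calibration, TrackPath

# Fraction of the plateau fluorescence a granule holds at nucleation;
# fixes the logistic growth steepness together with growth_fraction.
F_BIRTH_FRACTION = 0.05


@dataclass
class SimulationConfig:
    """Parameters of the granule life-cycle and imaging model.

    All lengths are in micrometres, times in minutes unless noted.

    Attributes
    ----------
    cell_radius : float
        Radius of the disc-shaped cell.
    zone_outer_margin : float
        Distance of the granule-bearing zone from the cell edge.
    zone_width : float
        Radial width of the granule-bearing annulus (~10 µm: granules
        live within roughly 10 µm of the cell boundary).
    nucleation_rate : float
        Granule births per minute over the whole nucleation zone.
    mean_lifetime, lifetime_sd : float
        Mean and SD of the sampled granule lifetime (minutes).
    growth_fraction : float
        Fraction of the lifetime spent growing; the rest is a fast,
        linear dissolution phase.
    plateau_fluo : float
        Plateau fluorescence (arbitrary units) of the logistic growth.
    drift_speed0 : float
        Inward radial drift speed of a nascent granule (µm/min).
    size_speed_exponent : float
        Speed scales as (F / F_birth)**(-exponent): larger granules
        move slower.
    diffusion_coeff : float
        Isotropic diffusion coefficient (µm²/min); per frame the
        squared 2-D displacement has variance 4·D·Δt.
    fusion_radius : float
        Two granules closer than this fuse; the smaller one's
        fluorescence is added to the larger.
    psf_sigma : float
        Gaussian PSF sigma (µm).
    photon_scale : float
        Expected photons per fluorescence unit.
    read_noise_sd : float
        Additive Gaussian read noise SD (detector counts).
    background_level : float
        Constant background photon level.
    pixel_size : float
        µm per pixel (77 nm scan pixels by default).
    frame_interval : float
        Seconds per frame (20 s, i.e. 3 frames/min).
    n_frames : int
        Movie length in frames (recordings are 270–365 frames).
    rng_seed : int
        Seed of the single random generator driving every draw.
    """

    cell_radius: float = 20.0
    zone_outer_margin: float = 0.0
    zone_width: float = 10.0
    nucleation_rate: float = 6.0
    mean_lifetime: float = 26.0
    lifetime_sd: float = 6.0
    growth_fraction: float = 0.75
    plateau_fluo: float = 1000.0
    drift_speed0: float = 0.8
    size_speed_exponent: float = 0.2
    diffusion_coeff: float = 0.01
    fusion_radius: float = 0.5
    psf_sigma: float = 0.1
    photon_scale: float = 1.0
    read_noise_sd: float = 3.0
    background_level: float = 100.0
    pixel_size: float = 0.077
    frame_interval: float = 20.0
    n_frames: int = 300
    rng_seed: int = 0

    def __post_init__(self) -> None:
        nonneg = (
            "cell_radius zone_outer_margin zone_width nucleation_rate "
            "mean_lifetime lifetime_sd plateau_fluo drift_speed0 "
            "size_speed_exponent diffusion_coeff fusion_radius photon_scale "
            "read_noise_sd background_level"
        ).split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.growth_fraction < 1:
            raise ValueError("growth_fraction must lie in (0, 1)")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.fusion_radius >= self.cell_radius:
            raise ValueError("fusion_radius must be smaller than cell_radius")
        if self.zone_outer_margin + self.zone_width > self.cell_radius:
            raise ValueError("granule zone does not fit inside the cell")

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.pixel_size, self.frame_interval)

    @property
    def zone_outer_radius(self) -> float:
        return self.cell_radius - self.zone_outer_margin

    @property
    def zone_inner_radius(self) -> float:
        return self.zone_outer_radius - self.zone_width

    @property
    def nucleation_inner_radius(self) -> float:
        """Inner radius of the nucleation sub-zone (outer 2/3 of the zone)."""
        return self.zone_outer_radius - 2.0 / 3.0 * self.zone_width

    @property
    def terminus_radius(self) -> float:
        """Radius at which inward drift halts, mid-way into the inner
        third of the zone (the dissolution "transition zone")."""
        return self.zone_inner_radius + self.zone_width / 6.0


@dataclass
class GroundTruthGranule:
    """Truth record for one simulated granule.

    ``positions`` and ``fluorescence`` cover exactly the frames
    ``birth_frame..death_frame`` inclusive.  ``end_reason`` is one of
    ``dissolved`` (fluorescence reached zero), ``merged`` (fused into
    ``merged_into``) or ``censored`` (still alive at the last frame).
    """

    granule_id: int
    birth_frame: int
    death_frame: int
    positions: np.ndarray
    fluorescence: np.ndarray
    merged_into: int | None = None
    merge_frame: int | None = None
    end_reason: str = "dissolved"

    @property
    def lifetime_frames(self) -> int:
        return self.death_frame - self.birth_frame

    def as_track_path(self) -> TrackPath:
        frames = np.arange(self.birth_frame, self.death_frame + 1)
        return TrackPath(frames, self.positions, self.fluorescence,
                         track_id=self.granule_id)


@dataclass
class SyntheticMovie:
    """Rendered synthetic movie plus its ground truth."""

    stack: np.ndarray
    calibration: Calibration
    truth: list[GroundTruthGranule] = field(default_factory=list)
    config: SimulationConfig | None = None


class _Granule:
    __slots__ = ("gid", "birth_frame", "pos", "fluo", "lifetime_min",
                 "growth_min", "decay_min", "f_birth", "phase", "age_min",
                 "decay_slope", "positions", "fluos", "merged_into",
                 "merge_frame", "end_reason")

    def __init__(self, gid, birth_frame, pos, lifetime_min, growth_fraction,
                 f_birth):
        self.gid = gid
        self.birth_frame = birth_frame
        self.pos = np.array(pos, dtype=float)
        self.lifetime_min = lifetime_min
        self.growth_min = growth_fraction * lifetime_min
        self.decay_min = (1.0 - growth_fraction) * lifetime_min
        self.f_birth = f_birth
        self.fluo = f_birth
        self.phase = "growth"
        self.age_min = 0.0
        self.decay_slope = 0.0
        self.positions = []
        self.fluos = []
        self.merged_into = None
        self.merge_frame = None
        self.end_reason = "dissolved"


def _logistic_fluo(age_min: float, growth_min: float, plateau: float) -> float:
    # F(0) = F_BIRTH_FRACTION * plateau, F(growth_min) = (1 - F_BIRTH_FRACTION) * plateau
    if growth_min <= 0:
        return plateau
    k = 2.0 * math.log(1.0 / F_BIRTH_FRACTION - 1.0) / growth_min
    return plateau / (1.0 + math.exp(-k * (age_min - growth_min / 2.0)))


def simulate(config: SimulationConfig) -> SyntheticMovie:
    """Run the granule life-cycle simulation and render the movie.

    Granules nucleate as a Poisson process in time, uniformly by area
    in the peripheral two thirds of the granule zone.  During growth
    they drift radially inward at ``drift_speed0·(F/F_birth)^(-exp)``
    until they reach the drift terminus inside the inner third of the
    zone; dissolution (linear fluorescence decay, zero drift) starts
    once both the growth period has elapsed and the terminus has been
    reached, so granules are born peripherally and die centrally.
    Brownian jitter is superimposed throughout.  Granule pairs closer
    than ``fusion_radius`` fuse: total fluorescence is conserved and
    the smaller partner's record ends with ``merged_into`` set.
    """
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    dt_min = cfg.frame_interval / 60.0
    side_um = 2.0 * cfg.cell_radius + 2.0
    n_px = int(math.ceil(side_um / cfg.pixel_size))
    centre_um = (n_px - 1) / 2.0 * cfg.pixel_size

    sigma_step = math.sqrt(2.0 * cfg.diffusion_coeff * dt_min)
    r_nuc_in = cfg.nucleation_inner_radius
    r_nuc_out = cfg.zone_outer_radius
    r_term = cfg.terminus_radius

    alive: list[_Granule] = []
    done: list[_Granule] = []
    next_gid = 0

    def record(g: _Granule) -> None:
        g.positions.append(g.pos.copy())
        g.fluos.append(g.fluo)

    for frame in range(cfg.n_frames):
        if frame > 0:
            # ---- propagate everything alive from the previous frame
            for g in alive:
                g.age_min += dt_min
                if g.phase == "growth":
                    r = np.hypot(*g.pos)
                    law = _logistic_fluo(min(g.age_min, g.growth_min),
                                         g.growth_min, cfg.plateau_fluo)
                    gain = g.fluo - _logistic_fluo(
                        min(g.age_min - dt_min, g.growth_min), g.growth_min,
                        cfg.plateau_fluo)
                    g.fluo = law + max(gain, 0.0)
                    speed = cfg.drift_speed0 * (
                        max(g.fluo, 1e-12) / g.f_birth) ** (-cfg.size_speed_exponent)
                    if r > 1e-9:
                        new_r = max(r - speed * dt_min, r_term)
                        g.pos *= new_r / r
                    # dissolution waits for both the growth clock and
                    # arrival at the terminus zone
                    at_terminus = np.hypot(*g.pos) <= r_term + 1e-9
                    if g.age_min >= g.growth_min and (at_terminus
                                                      or cfg.drift_speed0 == 0):
                        g.phase = "decay"
                        g.decay_slope = (g.fluo / g.decay_min
                                         if g.decay_min > 0 else math.inf)
                else:
                    g.fluo -= g.decay_slope * dt_min
                if sigma_step > 0:
                    g.pos += rng.normal(0.0, sigma_step, size=2)

            # ---- deaths by dissolution
            still = []
            for g in alive:
                if g.phase == "decay" and g.fluo <= 0:
                    g.end_reason = "dissolved"
                    done.append(g)
                else:
                    still.append(g)
            alive = still

        # ---- nucleation (Poisson in time)
        if cfg.nucleation_rate > 0:
            n_births = rng.poisson(cfg.nucleation_rate * dt_min)
            for _ in range(n_births):
                u = rng.uniform()
                r = math.sqrt(u * (r_nuc_out**2 - r_nuc_in**2) + r_nuc_in**2)
                theta = rng.uniform(0.0, 2.0 * math.pi)
                lifetime = max(rng.normal(cfg.mean_lifetime, cfg.lifetime_sd),
                               2.0 * dt_min)
                g = _Granule(next_gid, frame,
                             (r * math.cos(theta), r * math.sin(theta)),
                             lifetime, cfg.growth_fraction,
                             F_BIRTH_FRACTION * cfg.plateau_fluo)
                next_gid += 1
                alive.append(g)

        # ---- fusion: greedy nearest pairs below the capture radius
        if cfg.fusion_radius > 0 and len(alive) > 1:
            pts = np.array([g.pos for g in alive])
            d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
            iu = np.triu_indices(len(alive), k=1)
            pairs = [(d[i, j], i, j) for i, j in zip(*iu)
                     if d[i, j] < cfg.fusion_radius]
            pairs.sort()
            dead = set()
            for _, i, j in pairs:
                if i in dead or j in dead:
                    continue
                gi, gj = alive[i], alive[j]
                big, small = (gi, gj) if gi.fluo >= gj.fluo else (gj, gi)
                big.fluo += small.fluo
                small.merged_into = big.gid
                small.merge_frame = frame
                small.end_reason = "merged"
                record(small)
                done.append(small)
                dead.add(i if small is gi else j)
            alive = [g for k, g in enumerate(alive) if k not in dead]

        for g in alive:
            record(g)

    for g in alive:
        g.end_reason = "censored"
        done.append(g)

    truth = []
    for g in sorted(done, key=lambda g: g.gid):
        positions = np.array(g.positions, dtype=float)
        if positions.size == 0:
            continue
        positions = positions + centre_um  # centred -> image coordinates
        truth.append(GroundTruthGranule(
            granule_id=g.gid,
            birth_frame=g.birth_frame,
            death_frame=g.birth_frame + len(g.positions) - 1,
            positions=positions,
            fluorescence=np.maximum(np.array(g.fluos, dtype=float), 0.0),
            merged_into=g.merged_into,
            merge_frame=g.merge_frame,
            end_reason=g.end_reason,
        ))

    stack = _render(truth, cfg, n_px, rng)
    return SyntheticMovie(stack=stack, calibration=cfg.calibration,
                          truth=truth, config=cfg)


def _render(truth: list[GroundTruthGranule], cfg: SimulationConfig,
            n_px: int, rng: np.random.Generator) -> np.ndarray:
    """Render granules as unit-integral Gaussians scaled by fluorescence,
    with Poisson shot noise and Gaussian read noise, on a 16-bit range."""
    sigma_px = cfg.psf_sigma / cfg.pixel_size
    half = max(int(math.ceil(4.0 * sigma_px)), 2)
    stack = np.zeros((cfg.n_frames, n_px, n_px), dtype=np.uint16)
    expected = np.empty((n_px, n_px), dtype=float)
    for frame in range(cfg.n_frames):
        expected.fill(cfg.background_level)
        for g in truth:
            if not g.birth_frame <= frame <= g.death_frame:
                continue
            x_um, y_um = g.positions[frame - g.birth_frame]
            amp = cfg.photon_scale * g.fluorescence[frame - g.birth_frame]
            if amp <= 0:
                continue
            cx = x_um / cfg.pixel_size
            cy = y_um / cfg.pixel_size
            ix, iy = int(round(cx)), int(round(cy))
            x0, x1 = max(ix - half, 0), min(ix + half + 1, n_px)
            y0, y1 = max(iy - half, 0), min(iy + half + 1, n_px)
            if x0 >= x1 or y0 >= y1:
                continue
            xs = np.arange(x0, x1) - cx
            ys = np.arange(y0, y1) - cy
            gx = np.exp(-0.5 * (xs / sigma_px) ** 2)
            gy = np.exp(-0.5 * (ys / sigma_px) ** 2)
            patch = np.outer(gy, gx) * (amp / (2.0 * math.pi * sigma_px**2))
            expected[y0:y1, x0:x1] += patch
        img = rng.poisson(expected).astype(float)
        if cfg.read_noise_sd > 0:
            img += rng.normal(0.0, cfg.read_noise_sd, size=img.shape)
        stack[frame] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return stack


# ---------------------------------------------------------------------------
# Bare-trajectory generators for motion-class benchmarks
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def brownian_tracks(n_tracks: int, n_frames: int, diffusion_um2_per_min: float,
                    frame_interval_s: float = 20.0, seed=0) -> list[TrackPath]:
    """Isotropic free 2-D diffusion: per-axis step SD = sqrt(2·D·Δt)."""
    rng = _as_rng(seed)
    dt_min = frame_interval_s / 60.0
    sd = math.sqrt(2.0 * diffusion_um2_per_min * dt_min)
    frames = np.arange(n_frames)
    out = []
    for i in range(n_tracks):
        steps = rng.normal(0.0, sd, size=(n_frames - 1, 2))
        pos = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        out.append(TrackPath(frames, pos, track_id=i))
    return out


def drift_tracks(n_tracks: int, n_frames: int, drift_um_per_min: float,
                 diffusion_um2_per_min: float, frame_interval_s: float = 20.0,
                 seed=0) -> list[TrackPath]:
    """Constant drift along a random direction plus Brownian noise."""
    rng = _as_rng(seed)
    dt_min = frame_interval_s / 60.0
    sd = math.sqrt(2.0 * diffusion_um2_per_min * dt_min)
    frames = np.arange(n_frames)
    out = []
    for i in range(n_tracks):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        v = drift_um_per_min * dt_min * np.array([math.cos(theta),
                                                  math.sin(theta)])
        steps = v + rng.normal(0.0, sd, size=(n_frames - 1, 2))
        pos = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        out.append(TrackPath(frames, pos, track_id=i))
    return out


def confined_tracks(n_tracks: int, n_frames: int, diffusion_um2_per_min: float,
                    box_um: float = 0.5, frame_interval_s: float = 20.0,
                    seed=0) -> list[TrackPath]:
    """Brownian motion inside a reflecting square box of side ``box_um``."""
    rng = _as_rng(seed)
    dt_min = frame_interval_s / 60.0
    sd = math.sqrt(2.0 * diffusion_um2_per_min * dt_min)
    frames = np.arange(n_frames)
    out = []
    for i in range(n_tracks):
        pos = np.empty((n_frames, 2))
        pos[0] = rng.uniform(0.0, box_um, size=2)
        for k in range(1, n_frames):
            p = pos[k - 1] + rng.normal(0.0, sd, size=2)
            # reflect into [0, box] (fold the infinite tiling)
            p = np.abs(p)
            p = box_um - np.abs(box_um - p % (2.0 * box_um))
            pos[k] = p
        out.append(TrackPath(frames, pos, track_id=i))
    return out


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
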