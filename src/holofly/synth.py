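"""Physics-based synthetic hologram generator.

No raw recordings ship with this package, so every downstream stage is
exercised against simulated ground truth: opaque fly silhouettes (ellipse
body plus thin leg elements) placed in a 3D arena, illuminated by a
collimated plane wave, and propagated to the sensor with the shared Fresnel
kernel.  The generator produces both the hologram frames and a per-frame
truth table (id, position, behavioral state), which is what validation of
the reconstruction chain is measured against.

Forward model
-------------
Flies are treated as binary transmission masks.  The incident unit plane
wave is multiplied by the farthest fly's mask, propagated to the next fly's
plane, multiplied again, and so on down to the sensor — so a near fly
correctly shadows a far one.  The recorded frame is
``|E|^2 * background_level`` (optionally times a smooth shading pattern)
plus zero-mean Gaussian sensor noise, clipped to ``[0, 1]``.

Motion model
------------
Each fly follows a three-state Markov chain (resting / walking / flying).
Per frame the state is resampled with a small switch probability, drawing
the new state from the target occupancy fractions, which makes those
fractions the exact stationary distribution.  Walkers are pinned to an
arena face and move in-plane at low speed; flyers move freely in the volume
at high speed; boundaries reflect.  A scripted free-fall segment can be
injected to exercise rapid-vertical-event detection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import HologramFrame, write_frames
from .optics import OpticsConfig, propagate

__all__ = [
    "SyntheticFly",
    "ArenaBox",
    "StateModel",
    "FallScript",
    "GroundTruthSession",
    "make_silhouette",
    "simulate_hologram",
    "simulate_session",
    "simulate_scripted",
    "polynomial_shading",
]

STATES = ("resting", "walking", "flying")

#: default leg elements: (width_px, length_px, angle_rad relative to body axis)
DEFAULT_APPENDAGES: tuple[tuple[float, float, float], ...] = (
    (3.0, 25.0, 0.9),
    (3.0, 28.0, 1.6),
    (3.0, 25.0, 2.3),
    (3.0, 25.0, -0.9),
    (3.0, 28.0, -1.6),
    (3.0, 25.0, -2.3),
)


class DegenerateObjectError(ValueError):
    """Raised when a fly rasterizes to fewer than 2 pixels across."""


@dataclass
class SyntheticFly:
    """Geometric model of one fly: opaque ellipse body plus leg elements."""

    body_length_m: float = 3e-3
    body_axis_ratio: float = 0.4
    appendages: tuple[tuple[float, float, float], ...] = DEFAULT_APPENDAGES
    position_m: tuple[float, float, float] = (0.0, 0.0, 0.14)
    orientation_rad: float = 0.0
    state: str = "resting"

    def __post_init__(self) -> None:
        if self.body_length_m <= 0:
            raise ValueError("body_length_m must be positive")
        if not 0 < self.body_axis_ratio <= 1:
            raise ValueError("body_axis_ratio must be in (0, 1]")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}")


@dataclass(frozen=True)
class ArenaBox:
    """Axis-aligned arena volume.

    ``x`` runs along sensor columns, ``y`` along rows (gravity points to
    +y), ``z`` along the optical axis away from the sensor.  The default
    70 x 35 x 55 mm box starts 140 mm from the sensor, the orientation in
    which the sensor field of view covers the 70 x 35 face.
    """

    x0_m: float = 0.0
    y0_m: float = 0.0
    z0_m: float = 0.140
    size_m: tuple[float, float, float] = (0.070, 0.035, 0.055)

    @property
    def lo(self) -> np.ndarray:
        return np.array([self.x0_m, self.y0_m, self.z0_m])

    @property
    def hi(self) -> np.ndarray:
        return self.lo + np.asarray(self.size_m)

    def contains(self, p, tol: float = 1e-9) -> bool:
        p = np.asarray(p)
        return bool(np.all(p >= self.lo - tol) and np.all(p <= self.hi + tol))


@dataclass(frozen=True)
class StateModel:
    """Three-state behavioral model driving synthetic trajectories.

    ``fractions`` is the exact stationary occupancy of (resting, walking,
    flying); ``switch_prob`` is the per-frame probability of redrawing the
    state from those fractions (mean dwell in state i is
    ``1 / (switch_prob * (1 - fractions[i]))`` frames).
    """

    fractions: tuple[float, float, float] = (0.6, 0.3, 0.1)
    switch_prob: float = 0.1
    walk_speed_mm_s: tuple[float, float] = (2.0, 15.0)
    fly_speed_mm_s: tuple[float, float] = (50.0, 300.0)

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("state fractions must sum to 1")
        if not 0 < self.switch_prob <= 1:
            raise ValueError("switch_prob must be in (0, 1]")


@dataclass(frozen=True)
class FallScript:
    """Inject a gravity free-fall for one fly over a frame span."""

    fly: int = 0
    start_frame: int = 0
    n_frames: int = 10
    g_m_s2: float = 9.81


@dataclass
class GroundTruthSession:
    """Simulated recording plus its per-frame truth table."""

    frames: list[HologramFrame] | None
    truth: list[list[tuple]]  # per frame: (fly_id, x_m, y_m, z_m, state)
    cfg: OpticsConfig
    arena: ArenaBox
    fps: float
    seed: int

    @property
    def n_frames(self) -> int:
        return len(self.truth)

    def truth_dataframe(self) -> pd.DataFrame:
        rows = [
            (f, fid, x, y, z, s)
            for f, recs in enumerate(self.truth)
            for (fid, x, y, z, s) in recs
        ]
        return pd.DataFrame(
            rows, columns=["frame", "fly", "x_m", "y_m", "z_m", "state"]
        )

    def save(self, out_dir: str | Path) -> Path:
        """Write frames (multi-page TIFF) and truth/config (JSON)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if self.frames is not None:
            write_frames(out_dir / "frames.tiff", self.frames)
        meta = {
            "seed": self.seed,
            "fps": self.fps,
            "optics": {
                "wavelength_m": self.cfg.wavelength_m,
                "pixel_pitch_m": self.cfg.pixel_pitch_m,
                "sensor_shape": list(self.cfg.sensor_shape),
                "z_min_m": self.cfg.z_min_m,
                "z_max_m": self.cfg.z_max_m,
                "z_step_m": self.cfg.z_step_m,
            },
            "arena": {
                "x0_m": self.arena.x0_m,
                "y0_m": self.arena.y0_m,
                "z0_m": self.arena.z0_m,
                "size_m": list(self.arena.size_m),
            },
            "truth": [
                [
                    {"fly": fid, "x_m": x, "y_m": y, "z_m": z, "state": s}
                    for (fid, x, y, z, s) in recs
                ]
                for recs in self.truth
            ],
        }
        (out_dir / "truth.json").write_text(json.dumps(meta, indent=1))
        return out_dir


# ---------------------------------------------------------------------------
# silhouette rasterization


def make_silhouette(
    fly: SyntheticFly,
    pitch_m: float,
    shape: tuple[int, int] | None = None,
    center_px: tuple[float, float] | None = None,
) -> np.ndarray:
    """Rasterize a fly into a binary transmission mask (0 opaque, 1 clear).

    With ``shape=None`` a tight window around the fly is returned with the
    body centered; otherwise the fly is drawn on a grid of the given shape
    centered at ``center_px`` (row, col), clipped at the borders.
    """
    if pitch_m <= 0:
        raise ValueError("pitch_m must be positive")
    major_px = fly.body_length_m / pitch_m
    if major_px < 2.0:
        raise DegenerateObjectError(
            f"body spans {major_px:.2f} px (< 2 px) at this pitch"
        )
    a = major_px / 2.0  # semi-major, px
    b = a * fly.body_axis_ratio

    max_leg = max((l for (_, l, _) in fly.appendages), default=0.0)
    reach = a + max_leg + 3.0

    if shape is None:
        n = int(np.ceil(2 * reach)) + 1
        shape = (n, n)
        center_px = ((n - 1) / 2.0, (n - 1) / 2.0)
    elif center_px is None:
        center_px = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)

    mask = np.ones(shape, dtype=np.float64)
    r0 = max(0, int(np.floor(center_px[0] - reach)))
    r1 = min(shape[0], int(np.ceil(center_px[0] + reach)) + 1)
    c0 = max(0, int(np.floor(center_px[1] - reach)))
    c1 = min(shape[1], int(np.ceil(center_px[1] + reach)) + 1)
    if r0 >= r1 or c0 >= c1:
        return mask  # fly entirely outside the grid

    rr = np.arange(r0, r1, dtype=float)[:, None] - center_px[0]
    cc = np.arange(c0, c1, dtype=float)[None, :] - center_px[1]
    cos_t, sin_t = np.cos(fly.orientation_rad), np.sin(fly.orientation_rad)
    # body-frame coordinates: u along major axis, v along minor
    u = cc * cos_t + rr * sin_t
    v = -cc * sin_t + rr * cos_t

    opaque = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    for width, length, angle in fly.appendages:
        ax, ay = np.cos(angle), np.sin(angle)
        # anchor on the ellipse boundary, extend outward along the ray
        p0 = np.array([a * ax, b * ay])
        p1 = p0 + length * np.array([ax, ay])
        d = p1 - p0
        dd = float(d @ d)
        t = ((u - p0[0]) * d[0] + (v - p0[1]) * d[1]) / dd
        t = np.clip(t, 0.0, 1.0)
        dist2 = (u - (p0[0] + t * d[0])) ** 2 + (v - (p0[1] + t * d[1])) ** 2
        opaque |= dist2 <= (width / 2.0) ** 2
    mask[r0:r1, c0:c1] = np.where(opaque, 0.0, 1.0)
    return mask


def polynomial_shading(
    shape: tuple[int, int], amplitude: float = 0.1, seed: int = 0
) -> np.ndarray:
    """Smooth multiplicative fixed-pattern background (quadratic surface).

    Emulates slow illumination nonuniformity from window aberrations; mean
    1.0, peak-to-peak roughly ``2 * amplitude``.
    """
    rng = np.random.default_rng(seed)
    ry = np.linspace(-1, 1, shape[0])[:, None]
    cx = np.linspace(-1, 1, shape[1])[None, :]
    coef = rng.uniform(-1, 1, size=5)
    surf = (
        coef[0] * cx
        + coef[1] * ry
        + coef[2] * cx * ry
        + coef[3] * cx**2
        + coef[4] * ry**2
    )
    surf -= surf.mean()
    peak = np.abs(surf).max()
    if peak > 0:
        surf *= amplitude / peak
    return 1.0 + surf


# ---------------------------------------------------------------------------
# forward hologram model


def _position_px(fly: SyntheticFly, cfg: OpticsConfig) -> tuple[float, float]:
    x, y, _ = fly.position_m
    return (y / cfg.pixel_pitch_m, x / cfg.pixel_pitch_m)


def simulate_hologram(
    flies: list[SyntheticFly],
    cfg: OpticsConfig,
    background_level: float = 0.5,
    noise_sd: float = 0.01,
    seed: int = 0,
    shading: np.ndarray | None = None,
    index: int = 0,
    t_s: float = 0.0,
) -> HologramFrame:
    """Record one synthetic inline hologram of the given flies.

    The plane wave traverses the flies' transmission planes farthest-first
    (multiplicative shadowing), is propagated to the sensor, and the
    intensity is scaled, shaded, noised, and clipped to ``[0, 1]``.
    Deterministic for a fixed ``seed``.
    """
    shape = cfg.sensor_shape
    if not flies:
        field_int = np.ones(shape)
    else:
        order = sorted(flies, key=lambda f: f.position_m[2], reverse=True)
        for f in order:
            z = f.position_m[2]
            if not (cfg.z_min_m <= z <= cfg.z_max_m):
                raise ValueError(
                    f"fly at z={z} m outside search range "
                    f"[{cfg.z_min_m}, {cfg.z_max_m}]"
                )
        e = make_silhouette(
            order[0], cfg.pixel_pitch_m, shape, _position_px(order[0], cfg)
        ).astype(np.complex128)
        z_prev = order[0].position_m[2]
        for f in order[1:]:
            z_next = f.position_m[2]
            if z_prev - z_next > 0:
                e = propagate(e, cfg, z_prev - z_next).values
            e = e * make_silhouette(
                f, cfg.pixel_pitch_m, shape, _position_px(f, cfg)
            )
            z_prev = z_next
        e = propagate(e, cfg, z_prev).values
        field_int = np.abs(e) ** 2

    intensity = field_int * background_level
    if shading is not None:
        intensity = intensity * shading
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=shape)
    return HologramFrame(np.clip(intensity, 0.0, 1.0), index=index, t_s=t_s)


# ---------------------------------------------------------------------------
# trajectory simulation


def _nearest_face(p: np.ndarray, arena: ArenaBox) -> tuple[int, float]:
    """Index of the pinned axis and the wall value of the nearest face."""
    lo, hi = arena.lo, arena.hi
    d_lo = p - lo
    d_hi = hi - p
    cands = [(d_lo[i], i, lo[i]) for i in range(3)] + [
        (d_hi[i], i, hi[i]) for i in range(3)
    ]
    _, axis, wall = min(cands, key=lambda t: t[0])
    return axis, wall


def _draw_velocity(
    state: str,
    p: np.ndarray,
    arena: ArenaBox,
    model: StateModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int | None]:
    """Velocity (m/s) for a fresh dwell; returns the pinned axis for walkers."""
    if state == "resting":
        return np.zeros(3), None
    if state == "walking":
        axis, wall = _nearest_face(p, arena)
        p[axis] = wall
        speed = rng.uniform(*model.walk_speed_mm_s) * 1e-3
        theta = rng.uniform(0, 2 * np.pi)
        tang = [i for i in range(3) if i != axis]
        v = np.zeros(3)
        v[tang[0]] = speed * np.cos(theta)
        v[tang[1]] = speed * np.sin(theta)
        return v, axis
    speed = rng.uniform(*model.fly_speed_mm_s) * 1e-3
    vec = rng.normal(size=3)
    vec /= np.linalg.norm(vec)
    return speed * vec, None


def _reflect(p: np.ndarray, v: np.ndarray, arena: ArenaBox) -> None:
    lo, hi = arena.lo, arena.hi
    for i in range(3):
        if p[i] < lo[i]:
            p[i] = 2 * lo[i] - p[i]
            v[i] = -v[i]
        elif p[i] > hi[i]:
            p[i] = 2 * hi[i] - p[i]
            v[i] = -v[i]
        p[i] = min(max(p[i], lo[i]), hi[i])


def simulate_session(
    n_flies: int,
    n_frames: int,
    fps: float = 100.0,
    state_model: StateModel | None = None,
    cfg: OpticsConfig | None = None,
    seed: int = 0,
    arena: ArenaBox | None = None,
    fly_template: SyntheticFly | None = None,
    fall: FallScript | None = None,
    render: bool = True,
    background_level: float = 0.5,
    noise_sd: float = 0.01,
    shading: np.ndarray | None = None,
) -> GroundTruthSession:
    """Simulate a multi-fly recording session with ground truth.

    With ``render=False`` only the truth table is produced (cheap; used for
    long statistical checks).  Deterministic for a fixed ``seed``.
    """
    if n_flies < 1 or n_frames < 2:
        raise ValueError("need n_flies >= 1 and n_frames >= 2")
    model = state_model or StateModel()
    cfg = cfg or OpticsConfig()
    template = fly_template or SyntheticFly()
    if arena is None:
        # default box, but never wider than the field of view
        fov_y, fov_x = cfg.fov_m
        base = ArenaBox()
        arena = ArenaBox(
            size_m=(
                min(base.size_m[0], fov_x),
                min(base.size_m[1], fov_y),
                base.size_m[2],
            )
        )
    rng = np.random.default_rng(seed)
    dt = 1.0 / fps
    fractions = np.asarray(model.fractions)

    pos = np.stack(
        [rng.uniform(arena.lo + 1e-4, arena.hi - 1e-4) for _ in range(n_flies)]
    )
    states = [STATES[rng.choice(3, p=fractions)] for _ in range(n_flies)]
    vels = np.zeros((n_flies, 3))
    pinned: list[int | None] = [None] * n_flies
    for i in range(n_flies):
        vels[i], pinned[i] = _draw_velocity(states[i], pos[i], arena, model, rng)
    orients = rng.uniform(0, 2 * np.pi, size=n_flies)
    fall_v = 0.0

    truth: list[list[tuple]] = []
    frame_seeds = np.random.default_rng(seed + 1).integers(
        0, 2**31 - 1, size=n_frames
    )
    frames: list[HologramFrame] | None = [] if render else None

    for k in range(n_frames):
        in_fall = (
            fall is not None
            and fall.start_frame <= k < fall.start_frame + fall.n_frames
        )
        recs = []
        flies_now = []
        for i in range(n_flies):
            if fall is not None and i == fall.fly and in_fall:
                st = "flying"
                if k == fall.start_frame:
                    fall_v = 0.0
            else:
                st = states[i]
            recs.append((i, pos[i, 0], pos[i, 1], pos[i, 2], st))
            if render:
                flies_now.append(
                    replace(
                        template,
                        position_m=tuple(pos[i]),
                        orientation_rad=float(orients[i]),
                        state=st,
                    )
                )
        truth.append(recs)
        if render:
            frames.append(
                simulate_hologram(
                    flies_now,
                    cfg,
                    background_level=background_level,
                    noise_sd=noise_sd,
                    seed=int(frame_seeds[k]),
                    shading=shading,
                    index=k,
                    t_s=k * dt,
                )
            )

        # advance dynamics to the next frame
        for i in range(n_flies):
            if fall is not None and i == fall.fly and in_fall:
                fall_v += fall.g_m_s2 * dt
                y_new = pos[i, 1] + fall_v * dt  # gravity along +y
                if y_new >= arena.hi[1]:
                    pos[i, 1] = arena.hi[1]  # landed on the floor
                    fall_v = 0.0
                else:
                    pos[i, 1] = y_new
                continue
            if rng.random() < model.switch_prob:
                new_state = STATES[rng.choice(3, p=fractions)]
                if new_state != states[i]:
                    states[i] = new_state
                    vels[i], pinned[i] = _draw_velocity(
                        new_state, pos[i], arena, model, rng
                    )
            pos[i] += vels[i] * dt
            _reflect(pos[i], vels[i], arena)
            if pinned[i] is not None:
                vels[i][pinned[i]] = 0.0

    return GroundTruthSession(
        frames=frames, truth=truth, cfg=cfg, arena=arena, fps=fps, seed=seed
    )


def simulate_scripted(
    paths_m: np.ndarray,
    cfg: OpticsConfig,
    fps: float = 100.0,
    states: list[list[str]] | None = None,
    fly_template: SyntheticFly | None = None,
    seed: int = 0,
    arena: ArenaBox | None = None,
    render: bool = True,
    background_level: float = 0.5,
    noise_sd: float = 0.01,
) -> GroundTruthSession:
    """Render a session from explicit trajectories.

    ``paths_m`` has shape ``(n_frames, n_flies, 3)``; used to build
    deterministic crossing/occlusion fixtures with exact ground truth.
    """
    paths_m = np.asarray(paths_m, dtype=float)
    n_frames, n_flies, _ = paths_m.shape
    template = fly_template or SyntheticFly()
    arena = arena or ArenaBox()
    frame_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, n_frames)
    truth = []
    frames: list[HologramFrame] | None = [] if render else None
    for k in range(n_frames):
        recs = []
        flies_now = []
        for i in range(n_flies):
            st = states[k][i] if states is not None else "flying"
            x, y, z = paths_m[k, i]
            recs.append((i, x, y, z, st))
            if render:
                flies_now.append(
                    replace(template, position_m=(x, y, z), state=st)
                )
        truth.append(recs)
        if render:
            frames.append(
                simulate_hologram(
                    flies_now,
                    cfg,
                    background_level=background_level,
                    noise_sd=noise_sd,
                    seed=int(frame_seeds[k]),
                    index=k,
                    t_s=k / fps,
                )
            )
    return GroundTruthSession(
        frames=frames, truth=truth, cfg=cfg, arena=arena, fps=fps, seed=seed
    )
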