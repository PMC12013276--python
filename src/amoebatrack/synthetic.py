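"""Synthetic microcosms with known ground truth.

Two generators back the pipeline's tests and examples:

* :func:`sample_curve` draws noisy cumulative-activity curves directly from
  known two-phase parameters (increment-level Gaussian noise, truncated at
  zero so the cumulative sum stays nondecreasing);
* :func:`render_stack` renders a time-lapse recording of a plate: static
  high-contrast cyst patches near the lawn edge, trophozoites that excyst
  after a delay and explore by random walks with exponentially distributed
  active durations, and a colonization cohort whose activation times follow a
  logistic law — so the aggregate cumulative activity follows the two-phase
  model by construction, with every event time recorded as ground truth.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .activity import CumulativeActivityCurve, ImageStack
from .model import TwoPhaseParams, ValidationError, eval_model

__all__ = [
    "NoiseSpec",
    "SceneSpec",
    "GroundTruth",
    "sample_curve",
    "render_stack",
    "scene_to_params",
    "disc_offsets",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise levels for the generators.

    ``increment_cv`` is the coefficient of variation applied to per-interval
    activity increments (curve generator); ``pixel_sigma`` is per-pixel
    Gaussian sensor noise in intensity levels (image generator).
    """

    increment_cv: float = 0.0
    pixel_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.increment_cv < 0 or self.pixel_sigma < 0:
            raise ValueError("noise levels must be nonnegative")


@dataclass(frozen=True)
class SceneSpec:
    """Configuration of a rendered microcosm scene.

    Defaults describe the reference scene used throughout the test suite:
    a 128x128 field recorded for 2,400 frames at 30 s (a 20 h window), with
    the two behavioral phases compressed so both complete inside the window.
    Time fields are in hours and map onto the model parameters:
    ``excystation_delay_mean`` -> tx, ``exploration_decay`` -> tp,
    ``colonization_half_time`` -> tc, ``colonization_growth_time`` -> tg.
    """

    frame_shape: tuple[int, int] = (128, 128)
    n_frames: int = 2400
    frame_interval: float = 30.0  #: seconds
    n_cysts: int = 30
    cyst_radius: int = 3
    trophozoite_radius: int = 3
    excystation_delay_mean: float = 2.0  #: h; the deterministic delay (tx)
    excystation_spread: float = 0.25  #: h; exponential tail beyond the delay
    exploration_decay: float = 1.0  #: h; mean active duration after excysting (tp)
    colonization_half_time: float = 10.0  #: h (tc)
    colonization_growth_time: float = 1.0  #: h (tg)
    n_colonizers: int = 80  #: colonization cohort size; 0 disables the phase
    colonizer_burst: float = 0.5  #: h each colonizer spends moving
    step_sigma: float = 2.0  #: px per frame random-walk step
    lawn_offset: float = 20.0  #: px between the cyst band and the lawn edge
    background_level: int = 120
    contrast: int = 80
    pixel_sigma: float = 2.0  #: sensor noise, intensity levels

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if min(self.frame_shape) < 4 * max(self.cyst_radius, self.trophozoite_radius):
            raise ValueError("frame too small for the requested object radii")
        for name in ("cyst_radius", "trophozoite_radius", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cysts < 0 or self.n_colonizers < 0:
            raise ValueError("object counts must be nonnegative")
        for name in (
            "excystation_delay_mean",
            "excystation_spread",
            "exploration_decay",
            "colonization_half_time",
            "colonization_growth_time",
            "colonizer_burst",
            "step_sigma",
            "pixel_sigma",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def window_hours(self) -> float:
        return (self.n_frames - 1) * self.frame_interval / 3600.0


@dataclass
class GroundTruth:
    """What the generator actually did: the answer key for recovery tests."""

    true_params: TwoPhaseParams
    event_times: np.ndarray  #: excystation times per amoeba, h
    per_frame_active: np.ndarray | None  #: moving objects per frame
    seed: int


def sample_curve(
    params: TwoPhaseParams,
    grid,
    noise: NoiseSpec | None = None,
) -> tuple[CumulativeActivityCurve, GroundTruth]:
    """Draw a cumulative-activity curve from known two-phase parameters.

    Per-interval increments are Normal(mu_i, (cv*mu_i)^2) truncated at zero,
    where mu_i is the exact model increment over the interval; the curve is
    their running sum.  With ``increment_cv = 0`` the output equals
    :func:`~amoebatrack.model.eval_model` on the grid exactly.
    """
    noise = noise or NoiseSpec()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("time grid is empty")
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValidationError("time grid must be 1-D and strictly increasing")

    model_vals = eval_model(params, grid)
    if noise.increment_cv > 0:
        mu = np.diff(model_vals)
        ca0 = float(model_vals[0])
        rng = np.random.default_rng(noise.seed)
        inc = np.maximum(0.0, rng.normal(mu, noise.increment_cv * mu))
        ca = np.concatenate([[ca0], ca0 + np.cumsum(inc)])
    else:
        ca = model_vals.copy()  # exact noise-off identity, no cumsum rounding
    curve = CumulativeActivityCurve(times=grid.copy(), ca=ca)
    gt = GroundTruth(
        true_params=params,
        event_times=np.empty(0),
        per_frame_active=None,
        seed=noise.seed,
    )
    return curve, gt


def disc_offsets(radius: int) -> np.ndarray:
    """(dy, dx) offsets of the pixels strictly inside a disc of given radius.

    The strict interior keeps the pixel count <= pi*r^2, which the amplitude
    predictions rely on.
    """
    r = int(radius)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    mask = dy**2 + dx**2 < r**2
    if not mask.any():  # radius 1: keep the center pixel
        mask = (dy == 0) & (dx == 0)
    return np.stack([dy[mask], dx[mask]], axis=1)


def _place_nonoverlapping(rng, n, x_range, y_range, min_dist, max_tries=500):
    """Rejection-sample n points with pairwise distance >= min_dist."""
    pts: list[tuple[float, float]] = []
    for _ in range(n):
        for _try in range(max_tries):
            x = rng.uniform(*x_range)
            y = rng.uniform(*y_range)
            if all((x - px) ** 2 + (y - py) ** 2 >= min_dist**2 for px, py in pts):
                pts.append((x, y))
                break
        else:
            raise ValueError("scene too small to place objects without overlap")
    return np.array(pts, dtype=float)


class _Canvas:
    """Static background + discs, rebuilt whenever the static content changes."""

    def __init__(self, shape, background, contrast):
        self.shape = shape
        self.background = background
        self.contrast = contrast
        self.discs: list[tuple[float, float, np.ndarray]] = []  # (y, x, offsets)
        self._img: np.ndarray | None = None

    def add(self, y, x, offsets):
        self.discs.append((y, x, offsets))
        self._img = None

    def remove(self, y, x, offsets):
        for i, (py, px, off) in enumerate(self.discs):
            if py == y and px == x and off is offsets:
                del self.discs[i]
                break
        self._img = None

    def image(self) -> np.ndarray:
        if self._img is None:
            img = np.full(self.shape, float(self.background))
            for y, x, off in self.discs:
                _paint(img, y, x, off, self.background + self.contrast)
            self._img = img
        return self._img


def _paint(img, y, x, offsets, value):
    h, w = img.shape
    ys = np.clip(np.round(y).astype(int) + offsets[:, 0], 0, h - 1)
    xs = np.clip(np.round(x).astype(int) + offsets[:, 1], 0, w - 1)
    img[ys, xs] = value


def render_stack(scene: SceneSpec, seed: int = 0) -> tuple[ImageStack, GroundTruth]:
    """Render a synthetic time-lapse recording of a colonizing microcosm.

    Cysts sit as static discs in a band near the lawn edge.  Each amoeba
    excysts at ``excystation_delay_mean + Exp(excystation_spread)`` hours,
    random-walks for an Exp(``exploration_decay``) active period, then
    re-encysts in place.  Colonizers activate at logistic(tc, tg) times on
    the lawn, move for ``colonizer_burst`` hours, and freeze.  Sensor noise
    is i.i.d. Gaussian per pixel.  Fully deterministic given (scene, seed).
    """
    rng = np.random.default_rng(seed)
    h, w = scene.frame_shape
    dt_h = scene.frame_interval / 3600.0
    window = scene.n_frames * dt_h

    cyst_off = disc_offsets(scene.cyst_radius)
    troph_off = disc_offsets(scene.trophozoite_radius)

    # cyst band to the left of the lawn edge (lawn occupies the right side)
    lawn_edge = w * 0.5
    margin = scene.cyst_radius + 1
    band_lo = max(margin, lawn_edge - scene.lawn_offset - 6 * scene.cyst_radius)
    band_hi = max(band_lo + 1, lawn_edge - scene.lawn_offset)
    cyst_pos = _place_nonoverlapping(
        rng, scene.n_cysts, (band_lo, band_hi), (margin, h - margin), 2 * scene.cyst_radius + 1
    )

    # excystation schedule and active durations of the inoculum
    t_ex = scene.excystation_delay_mean + rng.exponential(
        scene.excystation_spread or 0.0, size=scene.n_cysts
    )
    dur = rng.exponential(scene.exploration_decay or 0.0, size=scene.n_cysts)
    f_ex = np.round(t_ex / dt_h).astype(int)
    f_stop = np.round((t_ex + dur) / dt_h).astype(int)

    # colonization cohort: logistic activation times, short activity bursts
    if scene.n_colonizers > 0:
        t_act = rng.logistic(
            scene.colonization_half_time, scene.colonization_growth_time, size=scene.n_colonizers
        )
        col_pos = np.stack(  # (x, y), matching cyst_pos ordering
            [
                rng.uniform(lawn_edge + margin, w - margin, scene.n_colonizers),
                rng.uniform(margin, h - margin, scene.n_colonizers),
            ],
            axis=1,
        )
        f_act = np.round(t_act / dt_h).astype(int)
        f_frz = np.round((t_act + scene.colonizer_burst) / dt_h).astype(int)
    else:
        t_act = np.empty(0)
        col_pos = np.empty((0, 2))
        f_act = np.empty(0, dtype=int)
        f_frz = np.empty(0, dtype=int)

    canvas = _Canvas((h, w), scene.background_level, scene.contrast)
    cyst_discs = []
    for x, y in cyst_pos:
        canvas.add(y, x, cyst_off)
        cyst_discs.append((y, x))

    troph_xy = cyst_pos.copy()  # (x, y); movers start where their cyst sat
    col_xy = col_pos.copy()
    frames = np.empty((scene.n_frames, h, w), dtype=np.uint8)
    per_frame_active = np.zeros(scene.n_frames, dtype=np.int64)

    for f in range(scene.n_frames):
        # state transitions at this frame
        for i in range(scene.n_cysts):
            if f_ex[i] == f:
                y0, x0 = cyst_discs[i]
                canvas.remove(y0, x0, cyst_off)
            if f_stop[i] == f and f_ex[i] < f:  # re-encyst where it stopped
                canvas.add(troph_xy[i, 1], troph_xy[i, 0], cyst_off)
        for j in range(len(f_act)):
            if f_frz[j] == f and 0 <= f_act[j] < f:
                canvas.add(col_xy[j, 1], col_xy[j, 0], cyst_off)

        img = canvas.image().copy()

        inoc_active = (f_ex <= f) & (f < f_stop)
        col_active = (f_act <= f) & (f < f_frz) if len(f_act) else np.empty(0, dtype=bool)
        n_active = int(inoc_active.sum()) + int(col_active.sum() if len(f_act) else 0)
        per_frame_active[f] = n_active

        for i in np.nonzero(inoc_active)[0]:
            troph_xy[i] += rng.normal(0.0, scene.step_sigma, 2)
            troph_xy[i, 0] = np.clip(troph_xy[i, 0], margin, w - margin)
            troph_xy[i, 1] = np.clip(troph_xy[i, 1], margin, h - margin)
            _paint(img, troph_xy[i, 1], troph_xy[i, 0], troph_off,
                   scene.background_level + scene.contrast)
        if len(f_act):
            for j in np.nonzero(col_active)[0]:
                col_xy[j] += rng.normal(0.0, scene.step_sigma, 2)
                col_xy[j, 0] = np.clip(col_xy[j, 0], lawn_edge + margin, w - margin)
                col_xy[j, 1] = np.clip(col_xy[j, 1], margin, h - margin)
                _paint(img, col_xy[j, 1], col_xy[j, 0], troph_off,
                       scene.background_level + scene.contrast)

        if scene.pixel_sigma > 0:
            img = img + rng.normal(0.0, scene.pixel_sigma, img.shape)
        frames[f] = np.clip(np.round(img), 0, 255).astype(np.uint8)

    stack = ImageStack(
        frames=frames,
        frame_interval=scene.frame_interval,
        metadata={"generator": "amoebatrack.synthetic.render_stack", "seed": int(seed)},
    )
    gt = GroundTruth(
        true_params=scene_to_params(scene),
        event_times=t_ex,
        per_frame_active=per_frame_active,
        seed=int(seed),
    )
    return stack, gt


def scene_to_params(scene: SceneSpec) -> TwoPhaseParams:
    """Nominal two-phase parameters a scene should induce.

    Time parameters are exact field mappings; amplitudes are geometric
    predictions (objects x active frames x at most 2 disc areas of changed
    pixels per frame pair) and therefore upper-bound approximations.
    """
    dt_h = scene.frame_interval / 3600.0
    area = len(disc_offsets(scene.trophozoite_radius))
    cia = scene.n_cysts * (scene.exploration_decay / dt_h) * 2 * area
    if scene.n_colonizers > 0:
        cca = scene.n_colonizers * (scene.colonizer_burst / dt_h) * 2 * area
    else:
        cca = 0.0
    return TwoPhaseParams(
        cIA=float(cia),
        cCA=float(cca),
        tx=float(scene.excystation_delay_mean),
        tp=float(max(scene.exploration_decay, 1e-6)),
        tc=float(max(scene.colonization_half_time, 1e-6)),
        tg=float(max(scene.colonization_growth_time, 1e-6)),
    )
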