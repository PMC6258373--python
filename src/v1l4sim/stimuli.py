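"""Visual stimulus movies: drifting gratings, flashes, moving bars, gray screen.

Movies are grayscale (0-255) space-time arrays with a 1 ms frame step and
1.25 degrees per pixel on a 192x96 (x by y) frame.  Every stimulus starts
with 500 ms of mid-gray, which downstream analysis discards as an
equilibration period.  Grating conditions follow the g1-g240 naming scheme
(numbering increases first along temporal frequency, then spatial frequency,
then drift direction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GRAY_LEVEL = 127.0
PIXEL_DEG = 1.25
FRAME_NX = 192          # x (azimuth) pixels
FRAME_NY = 96           # y (elevation) pixels
GRAY_PREFIX_MS = 500

#: grating condition grids, in the order used by the g1-g240 numbering
GRATING_TFS = (1.0, 2.0, 4.0, 8.0, 15.0)          # Hz
GRATING_SFS = (0.025, 0.05, 0.1, 0.2, 0.4, 0.8)   # cycles per degree
GRATING_DIRECTIONS = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)

BAR_WIDTH_DEG = 4.0
BAR_SPEED_DEG_PER_S = 33.8


@dataclass
class StimulusMovie:
    """Grayscale movie with pixel-to-degree geometry and a stimulus name."""

    frames: np.ndarray          # (t, ny, nx) float32 in [0, 255]
    name: str
    dt_ms: float = 1.0
    pixel_deg: float = PIXEL_DEG

    @property
    def duration_ms(self) -> float:
        return self.frames.shape[0] * self.dt_ms

    def pixel_centers_deg(self):
        """(x_deg, y_deg) 1-D arrays of pixel-centre coordinates, centred."""
        nt, ny, nx = self.frames.shape
        x = (np.arange(nx) + 0.5 - nx / 2) * self.pixel_deg
        y = (np.arange(ny) + 0.5 - ny / 2) * self.pixel_deg
        return x, y


def _gray_frames(n_ms: int) -> np.ndarray:
    return np.full((n_ms, FRAME_NY, FRAME_NX), GRAY_LEVEL, dtype=np.float32)


def make_gray(duration_ms: int = 1000, name: str = "spont") -> StimulusMovie:
    """Uniform mid-gray screen (used to measure spontaneous activity)."""
    if duration_ms < GRAY_PREFIX_MS:
        raise ValueError("gray movie must be at least 500 ms")
    return StimulusMovie(_gray_frames(int(duration_ms)), name)


def make_grating(direction: float, sf: float, tf: float,
                 contrast: float = 80.0,
                 duration_ms: int = 2500,
                 name: str | None = None,
                 strict_nyquist: bool = True) -> StimulusMovie:
    """Square-wave drifting grating after a 500 ms gray prefix.

    ``direction`` (degrees) is the drift direction, perpendicular to the
    stripes; ``sf`` in cycles per degree, ``tf`` in Hz, ``contrast`` in
    percent (levels are 127 +/- 1.27 * contrast).  A square wave is rendered
    by thresholding the drifting sinusoidal phase at pixel centres.

    Spatial periods below 2 pixels alias on the 1.25 deg grid and raise by
    default; ``strict_nyquist=False`` renders them anyway (point-sampled,
    aliased), which is what the fixed pixel grid produces for the 0.8 cpd
    condition of the standard tuning battery.
    """
    if sf <= 0 or tf <= 0:
        raise ValueError("sf and tf must be positive")
    if sf > 0:
        period_px = 1.0 / sf / PIXEL_DEG
        if period_px < 2.0 and strict_nyquist:
            raise ValueError("spatial period below 2 pixels would alias")
    nt = int(duration_ms)
    x = (np.arange(FRAME_NX) + 0.5 - FRAME_NX / 2) * PIXEL_DEG
    y = (np.arange(FRAME_NY) + 0.5 - FRAME_NY / 2) * PIXEL_DEG
    th = np.deg2rad(direction)
    u = x[None, :] * np.cos(th) + y[:, None] * np.sin(th)   # (ny, nx) degrees
    t_s = np.arange(nt) / 1000.0                            # seconds
    phase = 2.0 * np.pi * (sf * u[None, :, :] - tf * t_s[:, None, None])
    if contrast == 0:
        drift = np.full((nt, FRAME_NY, FRAME_NX), GRAY_LEVEL, dtype=np.float32)
    else:
        amp = 1.27 * contrast
        drift = (GRAY_LEVEL
                 + amp * np.where(np.sin(phase) >= 0.0, 1.0, -1.0)
                 ).astype(np.float32)
    frames = np.concatenate([_gray_frames(GRAY_PREFIX_MS), drift])
    if name is None:
        try:
            name = grating_name(direction, sf, tf)
        except ValueError:
            name = f"grating_d{direction:g}_sf{sf:g}_tf{tf:g}"
    return StimulusMovie(frames, name)


def grating_name(direction: float, sf: float, tf: float) -> str:
    """The gN label of a grating condition on the standard grids."""
    try:
        ti = GRATING_TFS.index(tf)
        si = GRATING_SFS.index(sf)
        di = GRATING_DIRECTIONS.index(direction % 360.0)
    except ValueError:
        raise ValueError("condition not on the g1-g240 grids") from None
    return f"g{ti + len(GRATING_TFS) * si + len(GRATING_TFS) * len(GRATING_SFS) * di + 1}"


def parse_grating_name(name: str) -> tuple[float, float, float]:
    """Invert :func:`grating_name`: "g8" -> (direction, sf, tf)."""
    if not name.startswith("g"):
        raise ValueError(f"not a grating name: {name!r}")
    idx = int(name[1:]) - 1
    n_tf, n_sf = len(GRATING_TFS), len(GRATING_SFS)
    if not 0 <= idx < n_tf * n_sf * len(GRATING_DIRECTIONS):
        raise ValueError(f"grating index out of range: {name!r}")
    ti = idx % n_tf
    si = (idx // n_tf) % n_sf
    di = idx // (n_tf * n_sf)
    return GRATING_DIRECTIONS[di], GRATING_SFS[si], GRATING_TFS[ti]


def make_flash(kind: str = "flash_2") -> StimulusMovie:
    """Full-field flash; two fixed timing schemes.

    flash_1: gray 0-1000 ms, white 1000-2000 ms, gray 2000-3000 ms.
    flash_2: gray 0-600 ms, white 600-650 ms, gray 650-1500 ms.
    """
    if kind == "flash_1":
        spans = [(1000, GRAY_LEVEL), (1000, 255.0), (1000, GRAY_LEVEL)]
    elif kind == "flash_2":
        spans = [(600, GRAY_LEVEL), (50, 255.0), (850, GRAY_LEVEL)]
    else:
        raise ValueError(f"unknown flash kind {kind!r}")
    parts = [np.full((n, FRAME_NY, FRAME_NX), v, dtype=np.float32)
             for n, v in spans]
    return StimulusMovie(np.concatenate(parts), kind)


def flash_onset_ms(kind: str) -> int:
    return {"flash_1": 1000, "flash_2": 600}[kind]


def make_bar(color: str = "white", axis: str = "hor",
             width_deg: float = BAR_WIDTH_DEG,
             speed_deg_per_s: float = BAR_SPEED_DEG_PER_S) -> StimulusMovie:
    """Single moving bar on gray background, full-field traversal.

    ``axis="hor"`` is a vertical bar sweeping left to right; ``axis="vert"``
    a horizontal bar sweeping bottom to top.  Names follow the
    "Wbar_v50pixps_hor" convention.
    """
    if color not in ("white", "black"):
        raise ValueError("color must be 'white' or 'black'")
    if axis not in ("hor", "vert"):
        raise ValueError("axis must be 'hor' or 'vert'")
    level = 255.0 if color == "white" else 0.0
    extent = (FRAME_NX if axis == "hor" else FRAME_NY) * PIXEL_DEG
    # leading edge sweeps from just outside one side to past the other
    travel = extent + width_deg
    n_drift = int(np.ceil(travel / speed_deg_per_s * 1000.0))
    coord = (np.arange(FRAME_NX if axis == "hor" else FRAME_NY) + 0.5) \
        * PIXEL_DEG
    frames = _gray_frames(GRAY_PREFIX_MS + n_drift)
    v_per_ms = speed_deg_per_s / 1000.0
    for i in range(n_drift):
        lead = v_per_ms * i
        inside = (coord > lead - width_deg) & (coord <= lead)
        if axis == "hor":
            frames[GRAY_PREFIX_MS + i, :, inside] = level
        else:
            frames[GRAY_PREFIX_MS + i, inside, :] = level
    name = f"{'W' if color == 'white' else 'B'}bar_v50pixps_{axis}"
    return StimulusMovie(frames, name)
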