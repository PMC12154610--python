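"""Spatial scene machinery: rooms, source grids, and binaural rendering.

Rooms are shoebox-shaped with log-uniformly sampled dimensions; a listener
is placed uniformly at random subject to wall-distance and height
constraints.  For each listener environment a grid of candidate source
locations is built (72 azimuths x 11 elevations x 2 distances = 1584
locations).

Binaural rendering is parametric by default: a spherical-head model applies
the Woodworth interaural time difference and a frequency-dependent
head-shadow (first-order low-pass on the far ear plus a broadband level
difference).  Elevation does not alter the parametric cues (a documented
limitation); users wanting measured-room fidelity can supply a binaural
room impulse response (BRIR) pair instead, which is convolved per ear.

Azimuth convention: degrees clockwise from the listener's front, in
[0, 360).  Positive lateralization is toward the right ear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, fftconvolve, filtfilt

from .periphery import Waveform

__all__ = [
    "SPEED_OF_SOUND",
    "HEAD_RADIUS",
    "RoomSpec",
    "SourceLocation",
    "BinauralRender",
    "sample_room_and_listener",
    "build_location_grid",
    "default_elevations",
    "woodworth_itd",
    "render_binaural",
    "precedence_stimulus",
]

SPEED_OF_SOUND = 343.0  # m/s
HEAD_RADIUS = 0.0875  # m (spherical-head default)


# --------------------------------------------------------------------------
# Rooms and locations
# --------------------------------------------------------------------------

@dataclass
class RoomSpec:
    """Shoebox room with a listener pose.

    ``listener_position`` is (x, y, z) in meters with the origin at one
    corner; ``listener_heading`` is the facing direction in degrees
    (0 = +y axis, clockwise).
    """

    length: float  # x extent, m
    width: float  # y extent, m
    height: float  # z extent, m
    listener_position: tuple[float, float, float]
    listener_heading: float = 0.0

    MIN_WALL_DIST = 1.45
    MAX_LISTENER_HEIGHT = 2.0

    def __post_init__(self):
        if not (3.0 <= self.length <= 30.0 and 3.0 <= self.width <= 30.0):
            raise ValueError("length/width must be in [3, 30] m")
        if not (2.2 <= self.height <= 10.0):
            raise ValueError("height must be in [2.2, 10] m")
        x, y, z = self.listener_position
        if min(x, self.length - x, y, self.width - y) < self.MIN_WALL_DIST - 1e-9:
            raise ValueError("listener closer than 1.45 m to a wall")
        if not (0.0 <= z <= self.MAX_LISTENER_HEIGHT + 1e-9):
            raise ValueError("listener height must be <= 2 m")

    def wall_distance(self, azimuth_deg: float) -> float:
        """Horizontal distance from the listener to the nearest wall along
        the world-frame ray at ``listener_heading + azimuth``."""
        ang = np.deg2rad(self.listener_heading + azimuth_deg)
        dx, dy = np.sin(ang), np.cos(ang)  # clockwise-from-+y convention
        x, y, _ = self.listener_position
        dists = []
        if dx > 1e-12:
            dists.append((self.length - x) / dx)
        elif dx < -1e-12:
            dists.append(-x / dx)
        if dy > 1e-12:
            dists.append((self.width - y) / dy)
        elif dy < -1e-12:
            dists.append(-y / dy)
        return float(min(dists))


@dataclass
class SourceLocation:
    """Source position relative to the listener (polar)."""

    azimuth: float  # degrees clockwise from front, [0, 360)
    elevation: float  # degrees
    distance: float  # m

    def __post_init__(self):
        self.azimuth = float(self.azimuth) % 360.0
        if self.distance <= 0:
            raise ValueError("distance must be positive")


@dataclass
class BinauralRender:
    """A rendered stereo waveform with the interaural cues it encodes."""

    stereo: Waveform
    itd: float  # seconds, positive = right ear leads
    ild: float  # dB, positive = right ear louder
    source: SourceLocation


def sample_room_and_listener(rng: np.random.Generator) -> RoomSpec:
    """Sample a room (log-uniform dimensions) and a valid listener pose."""
    def logu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    length, width = logu(3.0, 30.0), logu(3.0, 30.0)
    height = logu(2.2, 10.0)
    m = RoomSpec.MIN_WALL_DIST
    x = rng.uniform(m, length - m) if length > 2 * m else length / 2.0
    y = rng.uniform(m, width - m) if width > 2 * m else width / 2.0
    z = rng.uniform(0.0, min(RoomSpec.MAX_LISTENER_HEIGHT, height))
    heading = rng.uniform(0.0, 360.0)
    return RoomSpec(length, width, height, (x, y, z), heading)


def default_elevations() -> np.ndarray:
    """11 elevations from -40 to +60 degrees in 10-degree steps."""
    return np.arange(-40.0, 61.0, 10.0)


def build_location_grid(
    room: RoomSpec,
    rng: np.random.Generator,
    n_azimuths: int = 72,
    elevations: np.ndarray | None = None,
    fixed_distance: float = 1.4,
) -> list[SourceLocation]:
    """Per-environment grid: n_azimuths x n_elevations x 2 distances.

    The first distance is fixed (1.4 m); the second is drawn uniformly
    between 1 m and 0.1 m less than the listener-to-wall distance along
    that azimuth.
    """
    if elevations is None:
        elevations = default_elevations()
    azimuths = np.arange(n_azimuths) * (360.0 / n_azimuths)
    grid: list[SourceLocation] = []
    for az in azimuths:
        wall = room.wall_distance(az)
        hi = wall - 0.1
        assert hi >= 1.0, "listener wall-distance constraint violated"
        for el in elevations:
            grid.append(SourceLocation(az, float(el), fixed_distance))
            grid.append(SourceLocation(az, float(el), float(rng.uniform(1.0, hi))))
    return grid


# --------------------------------------------------------------------------
# Parametric binaural rendering
# --------------------------------------------------------------------------

def woodworth_itd(azimuth_deg: float, head_radius: float = HEAD_RADIUS) -> float:
    """Spherical-head ITD in seconds; positive when the source is to the right."""
    lateral = np.sin(np.deg2rad(azimuth_deg))
    phi = float(np.arcsin(np.clip(lateral, -1.0, 1.0)))
    return head_radius / SPEED_OF_SOUND * (phi + np.sin(phi))


def _fractional_delay(x: np.ndarray, delay_s: float, rate: float) -> np.ndarray:
    """Delay by a (possibly fractional) number of samples, zero-filled."""
    d = delay_s * rate
    n = np.arange(x.shape[-1])
    return np.interp(n - d, n, x, left=0.0, right=0.0)


def render_binaural(
    mono: Waveform,
    loc: SourceLocation,
    mode: str = "parametric",
    brir: tuple[np.ndarray, np.ndarray] | Waveform | None = None,
    head_radius: float = HEAD_RADIUS,
    reference_distance: float = 1.4,
) -> Waveform:
    """Spatialize a mono waveform to a stereo (left, right) waveform.

    ``parametric`` mode applies the Woodworth ITD (split symmetrically
    across the ears), a broadband far-ear attenuation, and a first-order
    low-pass head-shadow on the far ear whose cutoff shrinks with
    lateralization.  Amplitude scales as reference_distance / distance.
    Elevation leaves the parametric cues unchanged.  ``brir`` mode
    convolves the signal with a supplied per-ear impulse-response pair.
    """
    if mono.n_channels != 1:
        raise ValueError("render_binaural expects a mono input")
    x = mono.samples[0]
    if mode == "brir":
        if brir is None:
            raise ValueError("brir mode requires a stereo impulse-response pair")
        if isinstance(brir, Waveform):
            if brir.n_channels != 2:
                raise ValueError("BRIR waveform must be stereo")
            h_l, h_r = brir.samples
        else:
            h_l, h_r = (np.asarray(h, dtype=float) for h in brir)
        left = fftconvolve(x, h_l)[: x.size]
        right = fftconvolve(x, h_r)[: x.size]
        return Waveform(np.vstack([left, right]), mono.sample_rate)
    if mode != "parametric":
        raise ValueError(f"unknown rendering mode {mode!r}")

    lateral = float(np.sin(np.deg2rad(loc.azimuth)))  # +1 = hard right
    itd = woodworth_itd(loc.azimuth, head_radius)
    gain = reference_distance / max(loc.distance, 0.1)
    near = _fractional_delay(x, 0.0, mono.sample_rate) * gain
    far = _fractional_delay(x, abs(itd), mono.sample_rate) * gain
    # head shadow on the far ear: broadband attenuation + low-pass
    shadow_db = 6.0 * abs(lateral)
    far = far * 10.0 ** (-shadow_db / 20.0)
    if abs(lateral) > 1e-9:
        nyq = mono.sample_rate / 2.0
        cos_az = np.cos(np.deg2rad(loc.azimuth))
        cutoff = 800.0 + (0.95 * nyq - 800.0) * max(cos_az, 0.0)
        b, a = butter(1, min(cutoff, 0.99 * nyq) / nyq)
        far = filtfilt(b, a, far)  # zero-phase so the shadow does not bias the ITD
    if abs(lateral) <= 1e-9:
        left = right = near
    elif lateral > 0:  # source on the right
        left, right = far, near
    else:
        left, right = near, far
    return Waveform(np.vstack([left, right]), mono.sample_rate)


def precedence_stimulus(
    signal: Waveform,
    lead_loc: SourceLocation,
    lag_loc: SourceLocation,
    delay: float,
    **render_kwargs,
) -> Waveform:
    """Lead/lag pair construction for precedence-effect stimuli.

    The signal is rendered at the lead location; a copy delayed by
    zero-padding (``floor(delay * rate)`` samples) is rendered at the lag
    location; the two binaural renders are summed channel-wise.  The output
    length is the input length plus the delay in samples.
    """
    if delay < 0:
        raise ValueError("delay must be nonnegative")
    n_delay = int(np.floor(delay * signal.sample_rate))
    pad_lead = Waveform(
        np.pad(signal.samples, ((0, 0), (0, n_delay))), signal.sample_rate
    )
    pad_lag = Waveform(
        np.pad(signal.samples, ((0, 0), (n_delay, 0))), signal.sample_rate
    )
    lead = render_binaural(pad_lead, lead_loc, **render_kwargs)
    lag = render_binaural(pad_lag, lag_loc, **render_kwargs)
    return Waveform(lead.samples + lag.samples, signal.sample_rate)
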