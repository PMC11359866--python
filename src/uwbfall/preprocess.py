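"""Three-map radar preprocessing.

A raw pulse matrix is converted into the three magnitude maps the
classifier consumes:

* **range–time** — three-pulse MTI canceller, then the analytic-signal
  envelope (Hilbert transform along slow time, per range bin);
* **time–Doppler** — the analytic signal is summed coherently across
  range bins and a magnitude STFT (default window 128, overlap 110) is
  taken along slow time;
* **range–Doppler** — magnitude FFT along slow time, per range bin.

The MTI filter is the second-difference canceller
``y(n) = x(n+1) - 2 x(n) + x(n-1)`` applied along slow time; it
annihilates constant and linearly-drifting returns (stationary clutter)
and has magnitude response 4 sin²(πf/prf).

The Hilbert transform is applied along slow time because that is the axis
carrying Doppler information; the resulting analytic signal makes the
single-sided Doppler line of a real carrier-phase echo recoverable by the
downstream FFT/STFT.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.fft import fft, fftfreq, fftshift
from scipy.signal import hilbert
from scipy.signal.windows import get_window
from skimage.transform import resize as _sk_resize

from .echo_sim import PulseMatrix
from .params import RadarParams

MAP_KINDS = ("range_time", "time_doppler", "range_doppler")
IMAGE_SIZE = 80


@dataclass(frozen=True)
class StftConfig:
    """Short-time Fourier transform parameters (slow-time axis)."""

    window_length: int = 128
    overlap: int = 110
    window_shape: str = "hann"

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.window_length:
            raise ValueError(
                f"need 0 <= overlap < window_length, got "
                f"{self.overlap} / {self.window_length}"
            )

    @property
    def hop(self) -> int:
        return self.window_length - self.overlap

    def n_frames(self, n_samples: int) -> int:
        if n_samples < self.window_length:
            raise ValueError(
                f"signal of {n_samples} samples shorter than window "
                f"{self.window_length}"
            )
        return (n_samples - self.window_length) // self.hop + 1


@dataclass
class RadarMap:
    """A 2-D magnitude map with physical axis coordinates.

    ``axis0``/``axis1`` give the physical coordinates of the grid rows
    and columns (range in m, time in s, or Doppler in Hz, depending on
    ``kind``).
    """

    values: np.ndarray
    kind: str
    axis0: np.ndarray
    axis1: np.ndarray
    params: RadarParams
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        if np.any(self.values < 0):
            raise ValueError("map values must be non-negative magnitudes")
        if self.values.shape != (len(self.axis0), len(self.axis1)):
            raise ValueError("axis lengths do not match grid shape")


@dataclass
class RadarImage:
    """A fixed-size normalized classifier input image."""

    pixels: np.ndarray
    kind: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError("image must be 2-D")
        if self.pixels.size and (
            self.pixels.min() < 0.0 or self.pixels.max() > 1.0 + 1e-6
        ):
            raise ValueError("pixels must lie in [0, 1]")


def mti_filter(pulses: PulseMatrix) -> PulseMatrix:
    """Three-pulse canceller along slow time.

    Output column n is x(n+1) - 2 x(n) + x(n-1); the slow-time axis
    shrinks by two samples.  Constant and linear slow-time components
    (stationary and uniformly drifting clutter) map exactly to zero.
    """
    x = pulses.samples
    if x.shape[1] < 3:
        raise ValueError(
            f"three-pulse canceller needs >= 3 pulses, got {x.shape[1]}"
        )
    y = x[:, 2:] - 2.0 * x[:, 1:-1] + x[:, :-2]
    return PulseMatrix(y, pulses.params, label=pulses.label)


def _analytic(x: np.ndarray) -> np.ndarray:
    """Analytic signal along slow time (axis 1)."""
    return hilbert(x, axis=1)


def analytic_envelope(pulses: PulseMatrix) -> RadarMap:
    """Range–time map: magnitude of the slow-time analytic signal.

    For each range bin the Hilbert transform converts the real echo
    sequence into its analytic signal; the magnitude is the envelope.
    """
    x = pulses.samples
    if x.size == 0:
        raise ValueError("empty pulse matrix")
    env = np.abs(_analytic(x))
    return RadarMap(
        values=env,
        kind="range_time",
        axis0=pulses.range_axis,
        axis1=pulses.slow_time,
        params=pulses.params,
        label=pulses.label,
    )


def time_doppler(
    pulses: PulseMatrix, cfg: StftConfig = StftConfig()
) -> RadarMap:
    """Time–Doppler map: magnitude STFT of the range-summed analytic signal.

    The analytic signal is summed coherently over range bins, collapsing
    the fast-time axis into a single complex slow-time series, and framed
    with ``cfg.window_length``/``cfg.overlap`` (defaults 128/110, hop 18).
    The Doppler axis is centered on 0 Hz and spans ±prf/2.
    """
    x = pulses.samples
    n = x.shape[1]
    n_frames = cfg.n_frames(n)  # raises if window longer than signal
    sig = _analytic(x).sum(axis=0)
    win = get_window(cfg.window_shape, cfg.window_length, fftbins=True)
    starts = np.arange(n_frames) * cfg.hop
    frames = np.stack([sig[s : s + cfg.window_length] for s in starts])
    spec = fftshift(fft(frames * win, axis=1), axes=1)
    mags = np.abs(spec).T  # (freq, frame)
    prf = pulses.params.prf
    freqs = fftshift(fftfreq(cfg.window_length, d=1.0 / prf))
    times = (starts + cfg.window_length / 2.0) / prf
    return RadarMap(
        values=mags,
        kind="time_doppler",
        axis0=freqs,
        axis1=times,
        params=pulses.params,
        label=pulses.label,
    )


def range_doppler(pulses: PulseMatrix) -> RadarMap:
    """Range–Doppler map: magnitude FFT along slow time per range bin.

    The input (typically MTI-filtered) is converted to its analytic
    signal first so a real carrier-phase echo yields a single Doppler
    line at +2|v|fc/c.  Unnormalized FFT convention: the squared
    magnitudes sum to n_pulses × the input energy (Parseval).
    """
    x = pulses.samples
    if x.shape[1] < 2:
        raise ValueError("need >= 2 slow-time samples")
    spec = fftshift(fft(_analytic(x), axis=1), axes=1)
    prf = pulses.params.prf
    freqs = fftshift(fftfreq(x.shape[1], d=1.0 / prf))
    return RadarMap(
        values=np.abs(spec),
        kind="range_doppler",
        axis0=pulses.range_axis,
        axis1=freqs,
        params=pulses.params,
        label=pulses.label,
    )


def to_image(
    radar_map: RadarMap, size: int = IMAGE_SIZE, floor_db: float = -60.0
) -> RadarImage:
    """Log-compress, normalize and resample a map to a size × size image.

    Magnitudes are converted to dB relative to the map maximum, floored
    at ``floor_db``, min–max normalized to [0, 1] and bilinearly
    resampled (with Gaussian anti-aliasing when downsampling, so narrow
    ridges are averaged into the coarse grid instead of aliased away).
    The output is invariant to a positive rescaling of the input map.
    An all-zero map yields an all-zero image.
    """
    v = np.asarray(radar_map.values, dtype=float)
    if v.size == 0:
        raise ValueError("empty map")
    vmax = v.max()
    if vmax <= 0.0:
        return RadarImage(
            np.zeros((size, size), dtype=np.float32),
            kind=radar_map.kind,
            label=radar_map.label,
        )
    db = 20.0 * np.log10(np.maximum(v / vmax, 1e-300))
    db = np.maximum(db, floor_db)
    img = (db - db.min()) / (db.max() - db.min()) if db.max() > db.min() else np.zeros_like(db)
    if img.shape != (size, size):
        img = _sk_resize(img, (size, size), order=1, mode="edge",
                         anti_aliasing=None, preserve_range=True)
        img = np.clip(img, 0.0, 1.0)
    return RadarImage(img, kind=radar_map.kind, label=radar_map.label)


def pulse_matrix_to_images(
    pulses: PulseMatrix,
    stft_cfg: StftConfig = StftConfig(),
    size: int = IMAGE_SIZE,
) -> dict:
    """Full pipeline: MTI → the three maps → normalized images.

    Returns a dict keyed by map kind.  Deterministic: the same pulse
    matrix always yields bit-identical images.
    """
    filtered = mti_filter(pulses)
    rt = analytic_envelope(filtered)
    td = time_doppler(filtered, stft_cfg)
    rd = range_doppler(filtered)
    return {m.kind: to_image(m, size=size) for m in (rt, td, rd)}
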