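"""Radar operating parameters.

The default configuration mirrors a PulsOn-440-class impulse UWB module:
4.3 GHz center frequency, 1.7 GHz bandwidth (3.1--4.8 GHz), 240 Hz pulse
repetition frequency, 5 s recordings.  The fast-time axis is represented as
an equivalent decimated range grid (default 256 bins over 5 m) rather than
the hardware ADC rate: the downstream pipeline consumes magnitude maps, and
the physical range resolution c/(2B) is preserved by the echo envelope
width, not by the grid pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import yaml

#: speed of light, m/s
C = 299_792_458.0


@dataclass(frozen=True)
class RadarParams:
    """Operating parameters of the simulated impulse UWB radar.

    Parameters
    ----------
    prf : float
        Pulse repetition frequency in Hz.  Sets the slow-time sampling
        rate; the unambiguous Doppler span is ±prf/2.
    fc : float
        Carrier (center) frequency in Hz.
    bandwidth : float
        Transmit bandwidth in Hz; the range envelope width is c/(2B).
    duration : float
        Recording length in seconds.
    n_range_bins : int
        Number of fast-time (range) bins on the decimated grid.
    max_range : float
        Maximum unambiguous range represented on the grid, in meters.
    """

    prf: float = 240.0
    fc: float = 4.3e9
    bandwidth: float = 1.7e9
    duration: float = 5.0
    n_range_bins: int = 256
    max_range: float = 5.0

    def __post_init__(self) -> None:
        if self.prf <= 0:
            raise ValueError(f"prf must be positive, got {self.prf}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.fc <= 0 or self.bandwidth <= 0:
            raise ValueError("fc and bandwidth must be positive")
        if self.n_range_bins < 1 or self.max_range <= 0:
            raise ValueError("n_range_bins and max_range must be positive")
        if self.n_pulses < 3:
            raise ValueError(
                "recording must contain at least 3 pulses for the "
                f"three-pulse canceller, got {self.n_pulses}"
            )

    @property
    def n_pulses(self) -> int:
        """Number of slow-time pulses, round(prf * duration)."""
        return int(round(self.prf * self.duration))

    @property
    def range_bin_width(self) -> float:
        """Grid pitch of the fast-time axis, m."""
        return self.max_range / self.n_range_bins

    @property
    def range_resolution(self) -> float:
        """Physical range resolution c/(2B), m."""
        return C / (2.0 * self.bandwidth)

    @property
    def max_unambiguous_speed(self) -> float:
        """Largest radial speed whose Doppler stays below prf/2, m/s."""
        return (self.prf / 2.0) * C / (2.0 * self.fc)

    def doppler_shift(self, v: float) -> float:
        """Doppler frequency 2 v fc / c for radial speed ``v`` (m/s)."""
        return 2.0 * v * self.fc / C

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "RadarParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        # YAML 1.1 reads exponents like "4.3e9" (no sign) as strings
        for key, val in data.items():
            if key == "n_range_bins":
                data[key] = int(val)
            else:
                data[key] = float(val)
        return cls(**data)
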