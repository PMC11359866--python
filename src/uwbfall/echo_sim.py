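"""Synthetic UWB echo generation for the ten-class fall/activity taxonomy.

Generates raw pulse matrices (fast time × slow time) containing a single
human-scale moving scatterer over static clutter and receiver noise.  Each
of the ten behavior classes is realized as a family of radial-motion
trajectories whose kinematics (peak radial speed, event duration, net
displacement, sign of motion) are drawn from class-specific seeded
distributions:

====  ============================  =========================================
id    behavior                      radial signature
====  ============================  =========================================
0     sitting down                  slow single transient, ~0.5 m/s
1     fall while sitting/standing   short burst, peak 1.5–1.7 m/s, in place
2     bending to pick something up  two slow opposite transients, ~0.7 m/s
3     fall sideways to the radar    burst 1.7–2.0 m/s, small radial travel
4     standing up                   very slow single transient, ~0.3 m/s
5     fall backwards (away)         burst 2.6–3.0 m/s moving away
6     walking towards the radar     sustained ~0.85 m/s, range decreasing
7     walking away from the radar   sustained ~0.85 m/s, range increasing
8     fall 45° right, towards       burst 2.0–2.3 m/s moving towards
9     fall 45° left, towards        burst 2.3–2.6 m/s moving towards
====  ============================  =========================================

A single real-valued receive channel is modeled: the echo at each pulse is
a Gaussian range envelope centered on the scatterer, modulated by the
carrier phase cos(4π fc R/c), so that the Doppler shift 2 v fc / c appears
after analytic-signal conversion and slow-time spectral analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import h5py
import numpy as np

from .params import C, RadarParams

N_CLASSES = 10

CLASS_NAMES = (
    "sitting_down",
    "fall_while_sitting_standing",
    "bending_to_pick_up",
    "fall_sideways",
    "standing_up",
    "fall_backwards_away",
    "walking_towards",
    "walking_away",
    "fall_45deg_right_towards",
    "fall_45deg_left_towards",
)

#: classes whose signature is a short high-speed fall burst
FALL_CLASSES = frozenset({1, 3, 5, 8, 9})
#: slow posture transitions
TRANSITION_CLASSES = frozenset({0, 2, 4})
#: sustained gait classes
WALK_CLASSES = frozenset({6, 7})


@dataclass
class MotionProfile:
    """Radial trajectory and reflectivity of a single scatterer.

    ``range_trajectory`` maps slow time (s, vectorized) to radial range
    R(t) in meters; ``rcs_envelope`` maps slow time to a dimensionless
    scatterer amplitude.
    """

    class_id: Optional[int]
    range_trajectory: Callable[[np.ndarray], np.ndarray]
    rcs_envelope: Callable[[np.ndarray], np.ndarray]


@dataclass
class PulseMatrix:
    """Raw or filtered radar echoes on a fast-time × slow-time grid.

    ``samples`` has shape (n_range_bins, n_pulses): axis 0 is fast time
    (range), axis 1 is slow time (pulse index).
    """

    samples: np.ndarray
    params: RadarParams
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D grid")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("pulse matrix contains non-finite values")

    @property
    def n_pulses(self) -> int:
        return self.samples.shape[1]

    @property
    def slow_time(self) -> np.ndarray:
        """Slow-time axis in seconds."""
        return np.arange(self.n_pulses) / self.params.prf

    @property
    def range_axis(self) -> np.ndarray:
        """Range-bin centers in meters."""
        p = self.params
        return (np.arange(self.samples.shape[0]) + 0.5) * p.range_bin_width


@dataclass
class LabeledEchoSet:
    """An ordered, labeled collection of simulated recordings."""

    items: List[PulseMatrix]
    seed: int
    class_counts: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts: Dict[int, int] = {}
        for pm in self.items:
            if pm.label is None or not 0 <= pm.label < N_CLASSES:
                raise ValueError(f"item has invalid label {pm.label}")
            counts[pm.label] = counts.get(pm.label, 0) + 1
        if self.class_counts:
            if self.class_counts != counts:
                raise ValueError("class_counts inconsistent with items")
        else:
            self.class_counts = counts

    def __len__(self) -> int:
        return len(self.items)

    @property
    def labels(self) -> np.ndarray:
        return np.array([pm.label for pm in self.items], dtype=int)

    def save(self, path) -> None:
        """Write to an HDF5 archive, one dataset per sample."""
        with h5py.File(path, "w") as fh:
            fh.attrs["seed"] = self.seed
            fh.attrs["n_items"] = len(self.items)
            for i, pm in enumerate(self.items):
                ds = fh.create_dataset(f"sample_{i:05d}", data=pm.samples)
                ds.attrs["label"] = pm.label
                for k, v in vars(pm.params).items():
                    ds.attrs[f"param_{k}"] = v

    @classmethod
    def load(cls, path) -> "LabeledEchoSet":
        items = []
        with h5py.File(path, "r") as fh:
            n = int(fh.attrs["n_items"])
            seed = int(fh.attrs["seed"])
            for i in range(n):
                ds = fh[f"sample_{i:05d}"]
                pkw = {
                    k[len("param_") :]: v
                    for k, v in ds.attrs.items()
                    if k.startswith("param_")
                }
                pkw["n_range_bins"] = int(pkw["n_range_bins"])
                params = RadarParams(**pkw)
                items.append(
                    PulseMatrix(ds[()], params, label=int(ds.attrs["label"]))
                )
        return cls(items=items, seed=seed)


# ---------------------------------------------------------------------------
# trajectory construction


def _hann_bump(t: np.ndarray, t0: float, dur: float) -> np.ndarray:
    """Raised-cosine velocity bump on [t0, t0+dur], unit peak."""
    u = (t - t0) / dur
    out = np.zeros_like(t, dtype=float)
    m = (u >= 0.0) & (u <= 1.0)
    out[m] = 0.5 * (1.0 - np.cos(2.0 * np.pi * u[m]))
    return out


def _profile_from_velocity(
    v_of_t: Callable[[np.ndarray], np.ndarray],
    r0: float,
    params: RadarParams,
) -> Callable[[np.ndarray], np.ndarray]:
    """Integrate a velocity law into R(t) on a dense grid, interpolate."""
    tg = np.linspace(0.0, params.duration, 4096)
    v = v_of_t(tg)
    r = r0 + np.concatenate(
        ([0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(tg)))
    )

    def R(t: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), tg, r)

    return R


# per-class kinematic bands: (peak radial speed m/s, burst duration s, sign)
# sign is the direction of radial motion (+away, -towards, None = random side)
_BURST_BANDS = {
    0: ((0.45, 0.60), (1.2, 1.8), +1.0),  # sit down: settle slightly away
    1: ((1.50, 1.70), (0.40, 0.60), -1.0),  # collapse roughly in place
    2: ((0.60, 0.75), (0.70, 0.95), None),  # bend down + straighten up
    3: ((1.70, 2.00), (0.50, 0.70), None),  # sideways: random side
    4: ((0.25, 0.38), (1.2, 1.8), -1.0),  # stand up: drift slightly towards
    5: ((2.60, 3.00), (0.50, 0.80), +1.0),  # backwards = away from radar
    8: ((2.00, 2.30), (0.45, 0.65), -1.0),  # 45° right, towards
    9: ((2.30, 2.60), (0.60, 0.80), -1.0),  # 45° left, towards
}


def make_profile(
    class_id: int, params: RadarParams, rng_seed: int
) -> MotionProfile:
    """Draw a seeded motion profile for one behavior class.

    Falls are short high-speed bursts followed by stillness (with a drop
    in reflectivity once the subject is on the floor); walking is a
    sustained signed velocity; posture transitions are slow transients.

    Raises
    ------
    ValueError
        If ``class_id`` is not in 0..9.
    """
    if not 0 <= class_id < N_CLASSES:
        raise ValueError(f"unknown class_id {class_id}, expected 0..9")
    rng = np.random.default_rng(rng_seed)
    dur_total = params.duration
    margin = 0.4

    if class_id in WALK_CLASSES:
        speed = rng.uniform(0.75, 0.95)
        sign = -1.0 if class_id == 6 else +1.0
        t_start = rng.uniform(0.02, 0.08) * dur_total
        if class_id == 6:
            r0 = rng.uniform(params.max_range - 0.8, params.max_range - margin)
            travel_max = r0 - margin
        else:
            r0 = rng.uniform(margin, margin + 0.5)
            travel_max = params.max_range - margin - r0
        # walk until the boundary margin is reached, then stand still
        t_stop = min(dur_total, t_start + travel_max / speed)

        def v_of_t(t, s=speed, sg=sign, a=t_start, b=t_stop):
            v = np.zeros_like(t, dtype=float)
            m = (t >= a) & (t <= b)
            v[m] = sg * s
            # short ramps at the ends to keep the trajectory smooth
            ramp = 0.15
            lead = (t >= a - ramp) & (t < a)
            v[lead] = sg * s * (t[lead] - (a - ramp)) / ramp
            return v

        R = _profile_from_velocity(v_of_t, r0, params)
        rcs = _make_rcs(rng, dur_total, fall_time=None)
        return MotionProfile(class_id, R, rcs)

    (p_lo, p_hi), (d_lo, d_hi), sign = _BURST_BANDS[class_id]
    peak = rng.uniform(p_lo, p_hi)
    # events scale with the recording: on short clips the burst is clipped
    # so the peak radial speed (the class signature) is preserved
    dur = min(rng.uniform(d_lo, d_hi), 0.5 * dur_total)
    if sign is None:
        sign = float(rng.choice([-1.0, 1.0]))
    # event onset: 16% of the recording in, leaving room for the aftermath
    t0_lo = 0.16 * dur_total
    t0_hi = max(t0_lo + 1e-6, dur_total - dur - 0.24 * dur_total)
    t0 = rng.uniform(t0_lo, t0_hi)
    # extreme radial excursion of a single hann bump is peak*dur/2
    disp = sign * peak * dur / 2.0
    lo = margin + max(-disp, 0.0)
    hi = params.max_range - margin - max(disp, 0.0)
    r0 = rng.uniform(lo, hi)

    if class_id == 2:
        # bend down then straighten back up: two nearly-cancelling bumps
        gap = rng.uniform(0.2, 0.5)
        dur2 = dur * rng.uniform(0.9, 1.1)

        def v_of_t(t, p=peak, s=sign, a=t0, d1=dur, g=gap, d2=dur2):
            return p * s * (
                _hann_bump(t, a, d1) - 0.92 * _hann_bump(t, a + d1 + g, d2)
            )
    else:

        def v_of_t(t, p=peak, s=sign, a=t0, d=dur):
            return p * s * _hann_bump(t, a, d)

    R = _profile_from_velocity(v_of_t, r0, params)
    fall_time = t0 + dur if class_id in FALL_CLASSES else None
    rcs = _make_rcs(rng, dur_total, fall_time=fall_time)
    return MotionProfile(class_id, R, rcs)


def _make_rcs(
    rng: np.random.Generator, duration: float, fall_time: Optional[float]
) -> Callable[[np.ndarray], np.ndarray]:
    """Slowly fluctuating reflectivity; drops after a fall (body prone)."""
    base = rng.uniform(0.9, 1.1)
    wobble_f = rng.uniform(0.3, 0.8)
    wobble_a = rng.uniform(0.02, 0.08)
    phase = rng.uniform(0.0, 2.0 * np.pi)

    def rcs(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        a = base * (1.0 + wobble_a * np.sin(2.0 * np.pi * wobble_f * t + phase))
        if fall_time is not None:
            # smooth 0.3 s transition down to 60% reflectivity on the floor
            w = np.clip((t - fall_time) / 0.3, 0.0, 1.0)
            a = a * (1.0 - 0.4 * w)
        return a

    return rcs


# ---------------------------------------------------------------------------
# echo synthesis


def synthesize_pulses(
    profile: MotionProfile,
    params: RadarParams,
    clutter_amp: float = 2.0,
    noise_sigma: float = 0.15,
    rng_seed: int = 0,
) -> PulseMatrix:
    """Render a motion profile into a raw real-valued pulse matrix.

    Each pulse is a Gaussian range envelope (std = c/2B, the physical
    range resolution) centered on R(t), modulated by the carrier phase
    cos(4π fc R/c); a time-constant clutter column and i.i.d. Gaussian
    noise are added.  Deterministic for a given seed.

    Raises
    ------
    ValueError
        If the trajectory leaves [0, max_range] or ``noise_sigma`` < 0.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    if clutter_amp < 0:
        raise ValueError("clutter_amp must be non-negative")
    rng = np.random.default_rng(rng_seed)
    t = np.arange(params.n_pulses) / params.prf
    R = np.asarray(profile.range_trajectory(t), dtype=float)
    if np.any(R <= 0.0) or np.any(R >= params.max_range):
        raise ValueError(
            "trajectory leaves (0, max_range): "
            f"[{R.min():.3f}, {R.max():.3f}] vs max_range {params.max_range}"
        )
    amp = np.asarray(profile.rcs_envelope(t), dtype=float)

    r_axis = (np.arange(params.n_range_bins) + 0.5) * params.range_bin_width
    sigma_r = params.range_resolution
    envelope = np.exp(
        -((r_axis[:, None] - R[None, :]) ** 2) / (2.0 * sigma_r**2)
    )
    phase = np.cos(4.0 * np.pi * params.fc * R / C)
    echo = envelope * (amp * phase)[None, :]

    if clutter_amp > 0:
        r_clutter = rng.uniform(0.2, 0.8) * params.max_range
        clutter_col = clutter_amp * np.exp(
            -((r_axis - r_clutter) ** 2) / (2.0 * sigma_r**2)
        )
        echo = echo + clutter_col[:, None]
    if noise_sigma > 0:
        echo = echo + rng.normal(0.0, noise_sigma, size=echo.shape)

    return PulseMatrix(echo, params, label=profile.class_id)


def generate_dataset(
    params: RadarParams,
    per_class: int,
    rng_seed: int,
    clutter_amp: float = 2.0,
    noise_sigma: float = 0.15,
    classes: Sequence[int] = tuple(range(N_CLASSES)),
) -> LabeledEchoSet:
    """Generate a balanced labeled set of ``10 * per_class`` recordings.

    Sample order interleaves classes (0,1,...,9,0,1,...); reproducible
    from ``rng_seed`` alone.
    """
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    ss = np.random.SeedSequence(rng_seed)
    seeds = ss.generate_state(2 * per_class * len(classes)).reshape(-1, 2)
    items = []
    k = 0
    for rep in range(per_class):
        for cid in classes:
            prof_seed, echo_seed = seeds[k]
            k += 1
            prof = make_profile(cid, params, int(prof_seed % (2**31)))
            items.append(
                synthesize_pulses(
                    prof,
                    params,
                    clutter_amp=clutter_amp,
                    noise_sigma=noise_sigma,
                    rng_seed=int(echo_seed % (2**31)),
                )
            )
    return LabeledEchoSet(items=items, seed=rng_seed)
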