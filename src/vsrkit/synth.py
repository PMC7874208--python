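"""Synthetic vestibulospinal-reflex (VSR) recordings.

The VSR assay rocks a head-embedded zebrafish larva about its yaw axis
(platform excursion ±75° at 0.53 Hz, filmed at 30 fps) and measures the
evoked tail deflection.  The camera records one deliberately unilluminated
("black") frame per stimulus cycle, which downstream code uses to segment
the trace into cycles.

This module generates tail-angle traces with the statistical structure the
analysis assumes, for three phenotype classes:

* **wild type** — sustained evoked bouts with mild adaptation;
* **mechanotransduction null** — no evoked response at all (platform sway
  and camera noise only), as in *pcdh15a* / *lhfpl5a* mutants;
* **depletion/recovery ("synj1-like")** — normal initial bouts, rapid
  decline, and recovery that requires tens of seconds of rest.

The fatigue phenotype is modelled phenomenologically with a scalar
releasable resource ``R ∈ [0, 1]``: each evoked bout consumes ``δ`` of the
pool, a bout requires ``R ≥ response_threshold`` and has amplitude
proportional to ``R``, and the pool relaxes back toward 1 with time
constant ``τ_rec`` — but only during rest periods, stimulation being
treated as continuously depleting.  No claim is made about the underlying
synaptic-vesicle biology; the model exists to give the estimators a ground
truth to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "StimulusProtocol",
    "PhenotypeParams",
    "EpochSpan",
    "TailTrace",
    "StimulusSchedule",
    "make_stimulus",
    "simulate_trace",
    "phenotype_preset",
    "PRESETS",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """Stimulus/recording geometry and epoch/rest schedule.

    Parameters
    ----------
    frequency
        Yaw-stimulus frequency in Hz.
    amplitude
        Platform excursion in degrees (75 means ±75°).
    fps
        Camera frame rate.
    frames_per_recording
        Frame count of one recording epoch when ``epochs`` is not given.
    black_pause_ms
        Duration of the illumination pause that produces each marker frame.
    epochs
        Ordered ``(stimulus_duration_s, following_rest_s)`` pairs.  Rest
        periods contain no frames.  ``None`` means a single epoch of
        ``frames_per_recording / fps`` seconds with no rest.
    """

    frequency: float = 0.53
    amplitude: float = 75.0
    fps: float = 30.0
    frames_per_recording: int = 1280
    black_pause_ms: float = 16.0
    epochs: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ValueError(f"frequency must be > 0, got {self.frequency}")
        if not self.fps > 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.frames_per_recording < 2 * self.frames_per_cycle:
            raise ValueError(
                "frames_per_recording must cover at least two stimulus cycles "
                f"({2 * self.frames_per_cycle} frames), got {self.frames_per_recording}"
            )
        if self.epochs is not None:
            eps = tuple((float(s), float(r)) for s, r in self.epochs)
            if any(s < 0 or r < 0 for s, r in eps):
                raise ValueError("epoch durations must be >= 0")
            object.__setattr__(self, "epochs", eps)

    @property
    def frames_per_cycle(self) -> int:
        """Frames in one stimulus cycle, ``floor(fps / frequency)``."""
        return int(math.floor(self.fps / self.frequency))

    @property
    def cycle_duration_s(self) -> float:
        return self.frames_per_cycle / self.fps

    def epoch_schedule(self) -> tuple[tuple[float, float], ...]:
        """The effective ``(stimulus_s, rest_s)`` schedule."""
        if self.epochs is not None:
            return self.epochs
        return ((self.frames_per_recording / self.fps, 0.0),)

    def rest_durations(self) -> list[float]:
        """Rest following each epoch (the last entry is usually 0)."""
        return [r for _, r in self.epoch_schedule()]

    def total_duration_s(self) -> float:
        """Total trial duration: stimulation plus all rest periods."""
        return float(sum(s + r for s, r in self.epoch_schedule()))

    @classmethod
    def prolonged(cls, n_epochs: int = 6, stimulus_s: float = 42.0, **kw) -> "StimulusProtocol":
        """Prolonged stimulation: consecutive stimuli with no rest (6 x 42 s = 252 s)."""
        return cls(epochs=tuple((stimulus_s, 0.0) for _ in range(n_epochs)), **kw)

    @classmethod
    def defined_interval(
        cls,
        rests: Sequence[float] = (20.0, 15.0, 10.0, 5.0, 0.0),
        stimulus_s: float = 42.0,
        **kw,
    ) -> "StimulusProtocol":
        """Defined-interval trial: stimuli separated by decreasing rests.

        The default reproduces the 302-s protocol: six 42-s stimuli with
        rests of 20/15/10/5/0 s between them.
        """
        epochs = [(stimulus_s, float(r)) for r in rests] + [(stimulus_s, 0.0)]
        return cls(epochs=tuple(epochs), **kw)


@dataclass(frozen=True)
class PhenotypeParams:
    """Generative parameters of one synthetic larva.

    ``bout_amplitude_deg`` is the peak evoked tail deflection at a full
    resource pool; ``depletion_per_cycle`` (δ) and ``recovery_tau_s``
    (τ_rec) govern the fatigue/recovery dynamics described in the module
    docstring.  ``adaptation_rate`` multiplies the bout amplitude by
    ``(1 - rate)`` each cycle, which is how the mild wild-type decline is
    produced without touching the resource pool.
    """

    bout_amplitude_deg: float = 25.0
    bout_prob: float = 0.95
    adaptation_rate: float = 0.0
    startle_rate: float = 0.0
    sway_amplitude_deg: float = 5.0
    noise_sd_deg: float = 0.8
    pool_init: float = 1.0
    depletion_per_cycle: float = 0.0
    recovery_tau_s: float = 5.0
    response_threshold: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bout_prob", "startle_rate", "adaptation_rate", "pool_init"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "bout_amplitude_deg",
            "sway_amplitude_deg",
            "noise_sd_deg",
            "depletion_per_cycle",
            "recovery_tau_s",
            "response_threshold",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: Study-condition presets for the three phenotype classes.
PRESETS: dict[str, PhenotypeParams] = {
    "wild_type": PhenotypeParams(
        bout_amplitude_deg=25.0,
        bout_prob=0.95,
        adaptation_rate=0.02,
        startle_rate=0.01,
        depletion_per_cycle=0.0,
        recovery_tau_s=5.0,
        response_threshold=0.1,
    ),
    "mechanotransduction_null": PhenotypeParams(
        bout_amplitude_deg=0.0,
        bout_prob=0.0,
        adaptation_rate=0.0,
        startle_rate=0.0,
        depletion_per_cycle=0.0,
    ),
    "synj1_like": PhenotypeParams(
        bout_amplitude_deg=25.0,
        bout_prob=0.95,
        adaptation_rate=0.0,
        startle_rate=0.01,
        depletion_per_cycle=0.25,
        recovery_tau_s=15.0,
        response_threshold=0.2,
    ),
}


def phenotype_preset(name: str, **overrides) -> PhenotypeParams:
    """Return a named preset, optionally with fields overridden."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown phenotype preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class EpochSpan:
    """Location of one stimulation epoch inside a concatenated recording."""

    start: int  # first frame index (inclusive)
    stop: int  # one past the last frame index
    t0_s: float  # wall-clock time of the first frame
    rest_after_s: float  # unrecorded rest following this epoch


@dataclass
class TailTrace:
    """Per-frame signed tail angle with black-frame markers.

    ``angles`` holds the tail angle α in degrees (positive toward one fixed
    lateral side).  ``valid`` is False for black marker frames and for
    frames whose angle had to be interpolated.  ``epochs`` locates each
    stimulation epoch; rest periods between epochs contain no frames and
    appear only as gaps in :meth:`times`.
    """

    angles: np.ndarray
    fps: float
    black_frames: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)
    epochs: list[EpochSpan] | None = None

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.black_frames = np.asarray(self.black_frames, dtype=int)
        n = len(self.angles)
        if len(self.valid) != n:
            raise ValueError("angles and valid must have equal length")
        if self.black_frames.size:
            if np.any(np.diff(self.black_frames) <= 0):
                raise ValueError("black_frames must be strictly increasing")
            if self.black_frames[0] < 0 or self.black_frames[-1] >= n:
                raise ValueError("black_frames out of range")
            if np.any(self.valid[self.black_frames]):
                raise ValueError("black frames must be marked invalid")

    @property
    def n_frames(self) -> int:
        return len(self.angles)

    def epoch_spans(self) -> list[EpochSpan]:
        if self.epochs:
            return self.epochs
        return [EpochSpan(0, self.n_frames, 0.0, 0.0)]

    def times(self) -> np.ndarray:
        """Wall-clock time of each frame in seconds (rest gaps included)."""
        t = np.empty(self.n_frames, dtype=float)
        for ep in self.epoch_spans():
            t[ep.start : ep.stop] = ep.t0_s + np.arange(ep.stop - ep.start) / self.fps
        return t


@dataclass
class StimulusSchedule:
    """Per-frame platform angle plus the black-frame marker schedule."""

    platform_deg: np.ndarray
    black_frames: np.ndarray
    epochs: list[EpochSpan]
    fps: float

    @property
    def n_frames(self) -> int:
        return len(self.platform_deg)


def make_stimulus(protocol: StimulusProtocol) -> StimulusSchedule:
    """Lay out the platform motion and marker-frame schedule of a trial.

    Within each epoch the platform angle is ``amplitude * sin(2π f t)`` and a
    black frame is recorded every ``frames_per_cycle`` frames starting with
    the epoch's first frame.  Rest periods contain no frames.
    """
    if not isinstance(protocol, StimulusProtocol):
        raise TypeError("protocol must be a StimulusProtocol")
    fpc = protocol.frames_per_cycle
    platform: list[np.ndarray] = []
    blacks: list[np.ndarray] = []
    epochs: list[EpochSpan] = []
    start, t0 = 0, 0.0
    for stim_s, rest_s in protocol.epoch_schedule():
        n = int(round(stim_s * protocol.fps))
        t_local = np.arange(n) / protocol.fps
        platform.append(
            protocol.amplitude * np.sin(2.0 * np.pi * protocol.frequency * t_local)
        )
        blacks.append(start + np.arange(0, n, fpc))
        epochs.append(EpochSpan(start, start + n, t0, rest_s))
        start += n
        t0 += n / protocol.fps + rest_s
    return StimulusSchedule(
        platform_deg=np.concatenate(platform) if platform else np.empty(0),
        black_frames=np.concatenate(blacks) if blacks else np.empty(0, dtype=int),
        epochs=epochs,
        fps=protocol.fps,
    )


# Tail-beat carrier inside each bout.  A bout is not a smooth hump: the tail
# oscillates at beat frequency under a half-sine envelope, which is what lets
# the evoked movement survive subtraction of the 5-frame rolling median.
_BEAT_HZ = 10.0

# Startle waveform: a fast C-bend with a counter-bend, a few frames wide.
_STARTLE_SHAPE = np.array([0.35, 1.0, -0.45])


def _bout_waveform(amp: float, n: int, phase: float, fps: float) -> np.ndarray:
    k = np.arange(n)
    envelope = np.sin(np.pi * (k + 1) / (n + 1))
    carrier = np.sin(2.0 * np.pi * _BEAT_HZ * k / fps + phase)
    return amp * envelope * carrier


def simulate_trace(params: PhenotypeParams, protocol: StimulusProtocol) -> TailTrace:
    """Simulate the tail-angle trace of one larva under a stimulus protocol.

    The trace is the sum of a slow platform-sway baseline (a sinusoid at the
    stimulus frequency), evoked bouts governed by the resource pool ``R``,
    rare startle excursions, and white frame noise.  Black marker frames are
    flagged invalid.  Identical ``(params, protocol)`` — the seed lives in
    ``params`` — produce bit-identical traces.

    Notes
    -----
    All per-cycle random draws are consumed whether or not a bout fires, so
    traces simulated with different depletion rates but the same seed share
    one random stream and differ only through the resource dynamics.
    """
    if not isinstance(params, PhenotypeParams):
        raise TypeError("params must be a PhenotypeParams")
    sched = make_stimulus(protocol)
    rng = np.random.default_rng(params.seed)
    n = sched.n_frames
    fpc = protocol.frames_per_cycle

    t_local = np.concatenate(
        [np.arange(ep.stop - ep.start) / protocol.fps for ep in sched.epochs]
    )
    angles = params.sway_amplitude_deg * np.sin(
        2.0 * np.pi * protocol.frequency * t_local
    )
    if params.noise_sd_deg > 0:
        angles = angles + rng.normal(0.0, params.noise_sd_deg, size=n)

    R = params.pool_init
    active_truth: list[bool] = []
    for ep in sched.epochs:
        # Adaptation is a within-recording effect: each new stimulus epoch
        # re-engages the reflex at full gain (only the resource pool carries
        # over), which is what keeps wild type active across long protocols.
        amp_factor = 1.0
        for cs in range(ep.start, ep.stop, fpc):
            ce = min(cs + fpc, ep.stop)
            # Unconditional draws keep streams aligned across parameter values.
            u_bout = rng.random()
            bout_len = int(rng.integers(6, 13))
            bout_frac = rng.random()
            beat_phase = rng.uniform(0.0, 2.0 * np.pi)
            u_startle = rng.random()
            startle_amp = rng.uniform(85.0, 110.0)
            startle_frac = rng.random()

            fired = False
            if (
                params.bout_amplitude_deg > 0
                and R >= params.response_threshold
                and u_bout < params.bout_prob
            ):
                amp = params.bout_amplitude_deg * R * amp_factor
                room = ce - cs - 1 - bout_len  # frame cs is the black marker
                if room > 0:
                    b0 = cs + 1 + int(bout_frac * room)
                    angles[b0 : b0 + bout_len] += _bout_waveform(
                        amp, bout_len, beat_phase, protocol.fps
                    )
                    fired = True
                    R = max(0.0, R - params.depletion_per_cycle)
            active_truth.append(fired)

            if u_startle < params.startle_rate:
                room = ce - cs - 1 - len(_STARTLE_SHAPE)
                if room > 0:
                    s0 = cs + 1 + int(startle_frac * room)
                    angles[s0 : s0 + len(_STARTLE_SHAPE)] += (
                        startle_amp * _STARTLE_SHAPE
                    )
            amp_factor *= 1.0 - params.adaptation_rate
        if ep.rest_after_s > 0 and params.recovery_tau_s > 0:
            R = 1.0 - (1.0 - R) * math.exp(-ep.rest_after_s / params.recovery_tau_s)

    valid = np.ones(n, dtype=bool)
    valid[sched.black_frames] = False
    return TailTrace(
        angles=angles,
        fps=protocol.fps,
        black_frames=sched.black_frames,
        valid=valid,
        meta={
            "seed": params.seed,
            "params": params,
            "protocol": protocol,
            "bouts_fired": active_truth,
        },
        epochs=sched.epochs,
    )
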