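"""Synthetic motion-onset VEP session generator.

Generates epoched multichannel EEG that mimics a six-button mVEP speller
paradigm: each trial sweeps a motion-onset stimulus across the six virtual
buttons (140 ms motion + 60 ms gap each, 300 ms inter-trial gap, 1.5 s per
trial), five trials form a 7.5 s block sharing one target button, and an
ordered list of blocks forms a session.

A target epoch carries the canonical mVEP waveform — a positive P1 near
130 ms, a prominent negative N2 near 160-200 ms and a positive P2 near
240 ms — modelled as a sum of three Gaussian bumps projected through a
fixed 8-channel posterior topography, plus 1/f-shaped Gaussian noise.
Non-target epochs contain noise only.  Slow nonstationarity of the
subject's state is emulated by a per-block drift process acting on the
component amplitudes (multiplicative gain), latencies (additive shift)
and the spatial topography (convex mixing towards a second pattern).

All randomness flows from explicit integer seeds through
``numpy.random.SeedSequence`` keyed by (seed, block, trial, button), so a
session is bit-reproducible and individual epochs can be regenerated in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ParadigmConfig",
    "WaveModel",
    "DriftModel",
    "Epoch",
    "Block",
    "SessionData",
    "drifted_wave",
    "simulate_epoch",
    "simulate_session",
]

#: Default 8-channel montage (O3, O4, P3, P4, CP1, CP2, CP3, CP4):
#: occipito-parietal emphasis typical of motion-onset responses.
DEFAULT_TOPOGRAPHY = (1.0, 1.0, 0.8, 0.8, 0.5, 0.5, 0.6, 0.6)

#: Alternate spatial pattern used as the endpoint of topography drift:
#: emphasis moved from occipital to centro-parietal sites with a polarity
#: change at P3/P4, i.e. a genuinely different spatial state rather than a
#: rescaling of the default pattern.
DEFAULT_ALT_TOPOGRAPHY = (0.2, 0.2, -0.4, -0.4, 1.0, 1.0, 0.8, 0.8)


@dataclass(frozen=True)
class ParadigmConfig:
    """Timing and layout of the six-button mVEP speller paradigm."""

    n_buttons: int = 6
    trials_per_block: int = 5
    n_blocks: int = 72
    sampling_rate: float = 1000.0  # Hz
    epoch_duration: float = 500.0  # ms
    motion_duration: float = 140.0  # ms
    inter_stimulus_gap: float = 60.0  # ms
    inter_trial_gap: float = 300.0  # ms
    n_channels: int = 8

    def __post_init__(self) -> None:
        for name in ("n_buttons", "trials_per_block", "n_blocks", "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.sampling_rate <= 0 or self.epoch_duration <= 0:
            raise ValueError("sampling_rate and epoch_duration must be positive")

    @property
    def trial_duration_ms(self) -> float:
        """One sweep over all buttons plus the inter-trial gap (1500 ms at defaults)."""
        return (
            self.n_buttons * (self.motion_duration + self.inter_stimulus_gap)
            + self.inter_trial_gap
        )

    @property
    def block_duration_ms(self) -> float:
        """Five trials at defaults: 7500 ms."""
        return self.trials_per_block * self.trial_duration_ms

    @property
    def block_duration_s(self) -> float:
        return self.block_duration_ms / 1000.0

    @property
    def epoch_samples(self) -> int:
        return int(round(self.sampling_rate * self.epoch_duration / 1000.0))


@dataclass(frozen=True)
class WaveModel:
    """Parametric mVEP waveform: three Gaussian components through a topography.

    Amplitudes are in microvolts; P1 and P2 must be positive and N2
    negative.  ``noise_sd`` is the per-channel standard deviation of the
    additive 1/f^alpha noise before any filtering.
    """

    latencies_ms: tuple[float, float, float] = (130.0, 180.0, 240.0)  # P1, N2, P2
    widths_ms: tuple[float, float, float] = (20.0, 25.0, 30.0)
    amplitudes_uv: tuple[float, float, float] = (3.0, -6.0, 4.0)
    topography: tuple[float, ...] = DEFAULT_TOPOGRAPHY
    noise_sd: float = 10.0
    noise_exponent: float = 1.0

    def __post_init__(self) -> None:
        p1, n2, p2 = self.amplitudes_uv
        if not (p1 > 0 and p2 > 0):
            raise ValueError("P1 and P2 amplitudes must be strictly positive")
        if not n2 < 0:
            raise ValueError("N2 amplitude must be strictly negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not np.all(np.isfinite(self.topography)):
            raise ValueError("topography weights must be finite")
        if any(w <= 0 for w in self.widths_ms):
            raise ValueError("component widths must be positive")


@dataclass(frozen=True)
class DriftModel:
    """Per-block nonstationarity of the subject's state.

    ``magnitude`` is a dimensionless fraction per block; the drift level at
    block *b* is ``d(b) = magnitude * g(b)`` where ``g`` depends on
    ``kind``: 0 for ``none``, ``b`` for ``linear``, a standard Gaussian
    random walk for ``random_walk`` and a unit step at ``changepoint`` for
    ``abrupt``.  The level is applied to the aspects in ``aspects``:

    - ``amplitude``: all component amplitudes scaled by ``1 - d``
      (floored at 0 so signs never flip): positive drift emulates the
      fading evoked response of a fatiguing subject,
    - ``latency``: all component latencies shifted by ``d * 50`` ms,
    - ``topography``: convex mixing ``(1 - w) * topo + w * alt`` with
      ``w = clip(d, 0, 1)``, rescaled to the original pattern norm.
    """

    kind: str = "none"
    magnitude: float = 0.0
    changepoint: int | None = None
    seed: int = 0
    aspects: tuple[str, ...] = ("amplitude", "latency", "topography")
    alt_topography: tuple[float, ...] = DEFAULT_ALT_TOPOGRAPHY

    #: ms of latency shift per unit of drift level
    LATENCY_SCALE_MS = 50.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "linear", "random_walk", "abrupt"):
            raise ValueError(f"unknown drift kind: {self.kind!r}")
        if self.kind == "abrupt" and self.changepoint is None:
            raise ValueError("abrupt drift requires a changepoint block index")
        bad = set(self.aspects) - {"amplitude", "latency", "topography"}
        if bad:
            raise ValueError(f"unknown drift aspects: {sorted(bad)}")

    def levels(self, n_blocks: int) -> np.ndarray:
        """Drift level d(b) for blocks 0..n_blocks-1."""
        b = np.arange(n_blocks, dtype=float)
        if self.kind == "none":
            g = np.zeros(n_blocks)
        elif self.kind == "linear":
            g = b
        elif self.kind == "abrupt":
            g = (b >= self.changepoint).astype(float)
        else:  # random_walk
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x5EED]))
            g = np.cumsum(rng.standard_normal(n_blocks))
        return self.magnitude * g


def drifted_wave(wave: WaveModel, drift: DriftModel, block_index: int,
                 levels: np.ndarray | None = None) -> WaveModel:
    """Waveform model for a given block under the drift process."""
    if levels is None:
        levels = drift.levels(block_index + 1)
    d = float(levels[block_index])
    if d == 0.0:
        return wave
    lat = wave.latencies_ms
    amp = wave.amplitudes_uv
    topo = np.asarray(wave.topography, dtype=float)
    if "amplitude" in drift.aspects:
        gain = max(1.0 - d, 0.0)
        amp = tuple(a * gain for a in amp)
        if amp[0] == 0.0:  # fully attenuated: keep signs valid with a tiny floor
            eps = 1e-12
            amp = (eps, -eps, eps)
    if "latency" in drift.aspects:
        shift = d * DriftModel.LATENCY_SCALE_MS
        lat = tuple(l + shift for l in lat)
    if "topography" in drift.aspects:
        w = min(max(d, 0.0), 1.0)
        alt = np.asarray(drift.alt_topography, dtype=float)
        mixed = (1.0 - w) * topo + w * alt
        norm = np.linalg.norm(mixed)
        if norm > 0:
            mixed = mixed * (np.linalg.norm(topo) / norm)
        topo = mixed
    return replace(wave, latencies_ms=lat, amplitudes_uv=amp,
                   topography=tuple(topo))


@dataclass(eq=False)
class Epoch:
    """One stimulus-locked recording: channels x samples, microvolts."""

    data: np.ndarray
    button: int
    is_target: bool
    block_index: int
    trial_index: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")


@dataclass
class Block:
    target_button: int
    epochs: list[Epoch]


@dataclass
class SessionData:
    """Ordered blocks of epochs plus the paradigm they were recorded under."""

    blocks: list[Block]
    paradigm: ParadigmConfig

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def target_buttons(self) -> list[int]:
        return [b.target_button for b in self.blocks]

    def all_epochs(self) -> list[Epoch]:
        return [e for b in self.blocks for e in b.epochs]


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                sd: float, exponent: float) -> np.ndarray:
    """1/f^alpha-shaped Gaussian noise, independent per channel, unit-free
    spectral shaping rescaled to standard deviation ``sd`` per channel."""
    if sd == 0.0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC offset
    shaped = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    std = shaped.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return shaped / std * sd


def _component_signal(wave: WaveModel, n_samples: int, rate: float) -> np.ndarray:
    t = np.arange(n_samples) / rate * 1000.0  # ms
    s = np.zeros(n_samples)
    for lat, width, amp in zip(wave.latencies_ms, wave.widths_ms,
                               wave.amplitudes_uv):
        s += amp * np.exp(-0.5 * ((t - lat) / width) ** 2)
    return s


def simulate_epoch(state: WaveModel, is_target: bool, seed,
                   paradigm: ParadigmConfig | None = None,
                   button: int = 0, block_index: int = 0,
                   trial_index: int = 0) -> Epoch:
    """Generate one epoch from a (possibly drifted) waveform model.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.  A target
    epoch is the component waveform projected through the topography plus
    noise; a non-target epoch is noise only.
    """
    paradigm = paradigm or ParadigmConfig()
    n = paradigm.epoch_samples
    for lat in state.latencies_ms:
        if not (0.0 <= lat < paradigm.epoch_duration):
            raise ValueError(
                f"component latency {lat} ms outside epoch [0, "
                f"{paradigm.epoch_duration}) ms"
            )
    topo = np.asarray(state.topography, dtype=float)
    if topo.shape != (paradigm.n_channels,):
        raise ValueError(
            f"topography has {topo.size} weights for {paradigm.n_channels} channels"
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    data = _pink_noise(rng, paradigm.n_channels, n, state.noise_sd,
                       state.noise_exponent)
    if is_target:
        data = data + np.outer(topo, _component_signal(state, n, paradigm.sampling_rate))
    return Epoch(data=data, button=button, is_target=is_target,
                 block_index=block_index, trial_index=trial_index)


def simulate_session(paradigm: ParadigmConfig, wave: WaveModel,
                     drift: DriftModel, seed: int) -> SessionData:
    """Simulate a full session: per block one uniformly random target
    button, per trial one target and ``n_buttons - 1`` non-target epochs,
    drift applied cumulatively per block."""
    levels = drift.levels(paradigm.n_blocks)
    target_rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A26E7]))
    targets = target_rng.integers(0, paradigm.n_buttons, size=paradigm.n_blocks)
    blocks: list[Block] = []
    for b in range(paradigm.n_blocks):
        state = drifted_wave(wave, drift, b, levels=levels)
        epochs: list[Epoch] = []
        for t in range(paradigm.trials_per_block):
            for btn in range(paradigm.n_buttons):
                ss = np.random.SeedSequence([seed, b, t, btn])
                epochs.append(
                    simulate_epoch(state, is_target=(btn == targets[b]), seed=ss,
                                   paradigm=paradigm, button=btn,
                                   block_index=b, trial_index=t)
                )
        blocks.append(Block(target_button=int(targets[b]), epochs=epochs))
    return SessionData(blocks=blocks, paradigm=paradigm)
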