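"""Synthetic auditory-ERP data: N100-like deflections in pink noise.

The generator emulates the morphology of the auditory N100: a negative
deflection peaking near 100 ms over fronto-central electrodes with polarity
reversal (positivity) over the temporal sites, embedded in 1/f background
noise.  The temporal waveform is deliberately a Gaussian bump — not a
Mexican hat — so the wavelet detector is not trivially matched to the
injected signal.

Frequency conditions differ by small latency shifts, amplitude gains and a
lateral tilt of the topography, all scaled by a single ``effect_scale``
knob; ``effect_scale = 0`` is an exact null (all 12 condition templates
identical), used for calibration tests.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import protocol as proto
from .montage import default_channels, montage_positions
from .preprocess import (EPOCH_START_MS, EPOCH_STOP_MS, FS_HZ,
                         ContinuousRecording, EpochSet)
from .protocol import StimulusProtocol, StimulusType

# base N100 morphology (vertex-negative, ~100 ms, ~15 ms Gaussian SD)
BASE_LATENCY_MS = 100.0
BASE_AMPLITUDE_UV = -8.0
BASE_WIDTH_MS = 15.0

# per-unit-effect_scale condition spreads (frequency conditions only)
LATENCY_SPREAD_MS = 10.0      # total latency spread across the 4 frequencies
AMPLITUDE_SPREAD = 0.25       # total relative gain spread
TOPOGRAPHY_TILT = 0.15        # lateral displacement (radians-ish) of the pole


@dataclasses.dataclass
class ERPTemplate:
    """Separable space x time evoked response: Gaussian bump x topography."""

    latency_ms: float
    amplitude_uv: float
    width_ms: float
    topography: np.ndarray          # one unitless weight per channel
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.topography = np.asarray(self.topography, dtype=float)
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        if len(self.topography) != len(self.channel_labels):
            raise ValueError("one topography weight per channel required")

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        """Temporal profile in uV at the reference (unit-weight) electrode."""
        return self.amplitude_uv * np.exp(
            -0.5 * ((np.asarray(t_ms, float) - self.latency_ms) / self.width_ms) ** 2)

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        """channels x time evoked field in uV."""
        return np.outer(self.topography, self.waveform(t_ms))


@dataclasses.dataclass
class SimConfig:
    """Ground-truth parameters of a simulated session."""

    n_channels: int = 63
    fs_hz: float = FS_HZ
    trials_per_condition: int = 200
    noise_sd_uv: float = 5.0
    effect_scale: float = 1.0
    latency_spread_ms: float = LATENCY_SPREAD_MS
    amplitude_spread: float = AMPLITUDE_SPREAD
    topography_tilt: float = TOPOGRAPHY_TILT
    modality_effects: bool = True
    # per-modality multiplier on the frequency effect (e.g. {"right": 0.0}
    # simulates a subject whose right-ear pathway carries no frequency
    # information); missing modalities default to 1.
    modality_effect_scales: dict | None = None
    spatial_noise_corr: float = 0.0   # 0 = independent channels
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class SyntheticDataset:
    """Simulated epochs plus the ground truth that generated them."""

    epochs: EpochSet
    config: SimConfig
    templates: dict[StimulusType, ERPTemplate]

    def ground_truth_json(self) -> str:
        gt = {
            "config": self.config.to_dict(),
            "templates": {
                str(k): {"latency_ms": t.latency_ms, "amplitude_uv": t.amplitude_uv,
                         "width_ms": t.width_ms, "topography": t.topography.tolist()}
                for k, t in self.templates.items()},
        }
        return json.dumps(gt, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# templates

def _gaussian_topography(channels: list[str], centers: list[tuple[np.ndarray, float]],
                         spatial_sd_rad: float = 0.7) -> np.ndarray:
    """Sum of spatial Gaussian kernels (in great-circle angle) over the scalp."""
    pos = montage_positions(channels).to_numpy(dtype=float)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    topo = np.zeros(len(channels))
    for center, weight in centers:
        c = np.asarray(center, float)
        c /= np.linalg.norm(c)
        ang = np.arccos(np.clip(pos @ c, -1.0, 1.0))
        topo += weight * np.exp(-0.5 * (ang / spatial_sd_rad) ** 2)
    return topo


def _pole_positions(tilt_x: float = 0.0):
    """Kernel centers: fronto-central negativity + temporal positivities.

    ``tilt_x`` slides the negative pole laterally (positive = rightward),
    used both for per-frequency topography perturbations and for the
    contralateral emphasis of monaural stimulation.
    """
    pos = montage_positions(["Cz", "FCz", "T7", "T8"]).to_numpy(dtype=float)
    neg = (pos[0] + pos[1]) / 2.0
    neg = neg + np.array([tilt_x, 0.0, 0.0])
    neg /= np.linalg.norm(neg)
    return [(neg, 1.0), (pos[2], -0.55), (pos[3], -0.55)]


def _build_topography(channels: list[str], tilt_x: float) -> np.ndarray:
    """Unit topography: +1 at the fronto-central pole, opposite sign temporally.

    The kernel weights are chosen so the fronto-central weight is positive
    and maximal; multiplying by a negative amplitude yields the N100's
    fronto-central negativity and temporal positivity.
    """
    topo = _gaussian_topography(channels, _pole_positions(tilt_x))
    ref = topo.max()
    if ref <= 0:
        raise RuntimeError("degenerate topography")
    return topo / ref


def default_templates(effect_scale: float,
                      channels: list[str] | None = None,
                      latency_spread_ms: float = LATENCY_SPREAD_MS,
                      amplitude_spread: float = AMPLITUDE_SPREAD,
                      topography_tilt: float = TOPOGRAPHY_TILT,
                      modality_effects: bool = True,
                      modality_effect_scales: dict | None = None
                      ) -> dict[StimulusType, ERPTemplate]:
    """Condition templates for all 12 stimulus types.

    The base response peaks at 100 ms, is most negative between Cz and FCz
    and positive at T7/T8.  Frequency conditions (index k = 0..3 over
    250..2000 Hz) are perturbed proportionally to ``effect_scale``:
    latency shift, amplitude gain, and a lateral tilt of the negative pole.
    Monaural modalities add a contralateral tilt, also scaled by
    ``effect_scale`` so that ``effect_scale = 0`` leaves all 12 templates
    exactly identical.  ``modality_effect_scales`` multiplies only the
    frequency-dependent components, letting one stimulation pathway be
    silenced while the others keep their frequency selectivity.
    """
    if effect_scale < 0:
        raise ValueError("effect_scale must be >= 0")
    channels = channels if channels is not None else default_channels(63)

    mod_scales = modality_effect_scales or {}
    templates: dict[StimulusType, ERPTemplate] = {}
    for stype in proto.enumerate_stimulus_types():
        k = proto.FREQUENCIES_HZ.index(stype.frequency_hz)
        centered = (k - 1.5) / 3.0        # -0.5 .. +0.5 across frequencies
        # frequency-dependent components scale per modality so a pathway can
        # be silenced (its templates then coincide across frequencies)
        eff = effect_scale * float(mod_scales.get(stype.modality, 1.0))
        latency = BASE_LATENCY_MS + eff * latency_spread_ms * centered
        gain = 1.0 + eff * amplitude_spread * centered
        tilt = eff * topography_tilt * centered
        if modality_effects:
            # contralateral emphasis for monaural stimulation; scaled by
            # effect_scale so the effect_scale = 0 null is exact across all
            # 12 conditions
            tilt += effect_scale * \
                {"left": 0.25, "right": -0.25, "binaural": 0.0}[stype.modality]
        templates[stype] = ERPTemplate(
            latency_ms=latency,
            amplitude_uv=BASE_AMPLITUDE_UV * gain,
            width_ms=BASE_WIDTH_MS,
            topography=_build_topography(channels, tilt),
            channel_labels=list(channels),
        )
    return templates


# ---------------------------------------------------------------------------
# noise

def pink_noise(n_samples: int, n_channels: int, sd_uv: float,
               seed: int | np.random.Generator = 0) -> np.ndarray:
    """1/f ("pink") Gaussian noise, one independent series per channel.

    Synthesized spectrally: white Gaussian Fourier coefficients scaled by
    1/sqrt(f), zero DC, then each channel rescaled to sample SD ``sd_uv``.
    The power spectral density consequently falls off as 1/f (slope -1 on
    log-log axes).
    """
    if n_samples <= 1:
        raise ValueError("n_samples must be > 1")
    if sd_uv < 0:
        raise ValueError("sd_uv must be >= 0")
    if sd_uv == 0:
        return np.zeros((n_channels, n_samples))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_freq = n_samples // 2 + 1
    spectrum = (rng.standard_normal((n_channels, n_freq))
                + 1j * rng.standard_normal((n_channels, n_freq)))
    f = np.arange(n_freq, dtype=float)
    f[0] = np.inf                        # kill DC
    spectrum /= np.sqrt(f)
    x = np.fft.irfft(spectrum, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * sd_uv


def _spatial_mixing(channels: list[str], corr_scale: float) -> np.ndarray:
    """Mixing matrix giving distance-decaying inter-channel noise correlation."""
    pos = montage_positions(channels).to_numpy(dtype=float)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    ang = np.arccos(np.clip(pos @ pos.T, -1.0, 1.0))
    cov = np.exp(-ang / corr_scale)
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(len(channels)))
    # normalize rows so per-channel variance is preserved
    return L / np.linalg.norm(L, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# epoch / recording synthesis

def _epoch_time_axis(fs_hz: float) -> np.ndarray:
    step = 1000.0 / fs_hz
    return np.arange(EPOCH_START_MS, EPOCH_STOP_MS, step)


def simulate_epochs(config: SimConfig,
                    protocol: StimulusProtocol) -> SyntheticDataset:
    """Directly synthesize epoched data (template + pink noise per trial).

    Epochs span [-50, 350) ms at the configured rate; labels follow the
    protocol's event order.  ``trials_per_condition`` in the config is
    informative only — the protocol dictates the actual counts.
    """
    if config.noise_sd_uv < 0:
        raise ValueError("noise_sd_uv must be >= 0")
    if config.noise_sd_uv == 0 and config.effect_scale == 0:
        raise ValueError("noise-free null dataset requested: every epoch would "
                         "be identical and featureless; choose one of "
                         "noise_sd_uv > 0 or effect_scale > 0")

    channels = default_channels(config.n_channels)
    templates = default_templates(
        config.effect_scale, channels,
        latency_spread_ms=config.latency_spread_ms,
        amplitude_spread=config.amplitude_spread,
        topography_tilt=config.topography_tilt,
        modality_effects=config.modality_effects,
        modality_effect_scales=config.modality_effect_scales)
    t_ms = _epoch_time_axis(config.fs_hz)
    known = set(templates)
    for ev in protocol.events:
        if ev.stype not in known:
            raise ValueError(f"protocol contains unknown stimulus type {ev.stype}")

    rng = np.random.default_rng(config.seed)
    mix = (_spatial_mixing(channels, config.spatial_noise_corr)
           if config.spatial_noise_corr > 0 else None)

    fields = {s: t.evaluate(t_ms) for s, t in templates.items()}
    n_trials = len(protocol.events)
    data = np.empty((n_trials, len(channels), len(t_ms)))
    for i, ev in enumerate(protocol.events):
        noise = pink_noise(len(t_ms), len(channels), config.noise_sd_uv, rng) \
            if config.noise_sd_uv > 0 else 0.0
        if mix is not None and config.noise_sd_uv > 0:
            noise = mix @ noise
        data[i] = fields[ev.stype] + noise

    epochs = EpochSet(data=data, time_axis_ms=t_ms, channel_labels=channels,
                      labels=[e.stype for e in protocol.events], fs_hz=config.fs_hz)
    return SyntheticDataset(epochs=epochs, config=config, templates=templates)


def simulate_recording(config: SimConfig,
                       protocol: StimulusProtocol,
                       tail_ms: float = 1000.0) -> ContinuousRecording:
    """Continuous synthetic recording: pink noise + evoked field at each onset.

    Useful for exercising the full preprocessing chain (epoch extraction,
    filtering, artifact screening) end to end.
    """
    if config.noise_sd_uv == 0 and config.effect_scale == 0:
        raise ValueError("noise-free null recording requested; see simulate_epochs")
    channels = default_channels(config.n_channels)
    templates = default_templates(
        config.effect_scale, channels,
        latency_spread_ms=config.latency_spread_ms,
        amplitude_spread=config.amplitude_spread,
        topography_tilt=config.topography_tilt,
        modality_effects=config.modality_effects,
        modality_effect_scales=config.modality_effect_scales)
    rng = np.random.default_rng(config.seed)

    duration_ms = protocol.onsets_ms[-1] + EPOCH_STOP_MS + tail_ms
    n_samples = int(round(duration_ms * config.fs_hz / 1000.0))
    data = pink_noise(n_samples, len(channels), config.noise_sd_uv, rng) \
        if config.noise_sd_uv > 0 else np.zeros((len(channels), n_samples))
    if config.spatial_noise_corr > 0 and config.noise_sd_uv > 0:
        data = _spatial_mixing(channels, config.spatial_noise_corr) @ data

    # add each evoked response over a finite support around its peak
    support_ms = 6.0 * BASE_WIDTH_MS
    for ev in protocol.events:
        tpl = templates[ev.stype]
        t0 = ev.onset_ms + tpl.latency_ms
        lo = max(0, int(round((t0 - support_ms) * config.fs_hz / 1000.0)))
        hi = min(n_samples, int(round((t0 + support_ms) * config.fs_hz / 1000.0)))
        t_rel = np.arange(lo, hi) * 1000.0 / config.fs_hz - ev.onset_ms
        data[:, lo:hi] += tpl.evaluate(t_rel)

    return ContinuousRecording(data=data, fs_hz=config.fs_hz,
                               channel_labels=channels,
                               events=list(protocol.events))


def save_dataset(ds: SyntheticDataset, directory: str | Path) -> None:
    """Write the epochs container plus a ground-truth JSON sidecar."""
    from .io import save_epochs
    directory = Path(directory)
    save_epochs(ds.epochs, directory)
    (directory / "ground_truth.json").write_text(ds.ground_truth_json())
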