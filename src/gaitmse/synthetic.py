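"""Seeded generator of insole-like plantar pressure recordings.

The generator emulates the statistical structure that the downstream analysis
assumes about treadmill walking recorded by an 8-sensor pressure insole at
100 Hz:

* each stride is a stance phase (fixed fraction of the stride, default 0.6)
  followed by a zero-pressure swing phase;
* within stance, hindfoot sensors load early, forefoot sensors late and the
  midfoot in between at lower amplitude, so the summed whole-foot trace shows
  the classic double-peaked vertical ground-reaction-force shape (loading
  peak, mid-stance valley, push-off peak);
* stride durations fluctuate around a nominal value with either white or
  AR(1)-autocorrelated jitter — the irregularity knob that walking speed
  turns: faster presets have shorter, noisier, less autocorrelated strides;
* per-region peak amplitudes scale with body weight and with speed-dependent
  multipliers, and additive Gaussian sensor noise (clipped at zero pressure)
  models the measurement chain.

Every recording is produced by a single seeded generator, so identical
configuration plus seed yields bit-identical output; the realized per-cycle
durations and cycle boundaries are stored in the recording metadata as
ground truth for event-detection tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .core import REGIONS, PressureRecording, SensorLayout
from .errors import InvalidParameterError

__all__ = [
    "GaitGeneratorConfig",
    "SensorLayout",
    "STANCE_FRACTION",
    "generate_cycle_waveform",
    "generate_recording",
    "generate_paired_plate_signal",
    "speed_preset",
]

#: Fraction of the stride spent in ground contact (standard gait value).
STANCE_FRACTION = 0.6

# Per-region raised-cosine bump parameters, as fractions of stance duration:
# (center, half-width, relative amplitude). Hindfoot loads early, forefoot
# late, midfoot in between at reduced amplitude — this is what produces the
# double-peaked total with a mid-stance valley.
_REGION_BUMP = {
    # hindfoot loading is a sharp impact transient; the narrow bump also
    # makes the discrete heel-peak location robust to sensor noise. The wide
    # midfoot and forefoot bumps overlap so the summed trace is genuinely
    # bimodal (loading peak, mid-stance valley, push-off peak).
    "hindfoot": (0.15, 0.12, 1.00),
    "midfoot": (0.45, 0.45, 1.00),
    "forefoot": (0.75, 0.32, 1.00),
}

# Site-specific timing/amplitude tweaks (center offset in stance fraction,
# amplitude factor) so the 8 channels are distinguishable but fuse to a
# stable regional mean. Unknown sites fall back to evenly spread offsets.
_SITE_TWEAKS = {
    # heel sensors share their timing so the fused hindfoot peak is a single
    # well-defined sample (heel strike is one impact event)
    "heel-medial": (0.000, 1.00),
    "heel-lateral": (0.000, 0.95),
    "arch-medial": (-0.015, 1.00),
    "arch-lateral": (+0.015, 0.90),
    "MTH1": (-0.030, 1.05),
    "MTH3": (0.000, 1.00),
    "MTH5": (+0.020, 0.80),
    "hallux": (+0.060, 0.90),
}


@dataclass(frozen=True)
class GaitGeneratorConfig:
    """Parameters of one synthetic walking trial.

    ``region_amplitude_scale`` multiplies the per-region peak pressure
    (pressure units are "kg-equivalents": a multiplier of 1.0 puts the
    regional mean peak near the subject's body weight).  ``jitter_sd_s`` is
    the stationary SD of the stride-duration fluctuation; with
    ``jitter_structure="autocorrelated"`` the fluctuation is an AR(1)
    process with coefficient ``jitter_ar1_phi`` (white noise otherwise).
    """

    speed_kmh: float
    weight_kg: float = 70.0
    fs_hz: float = 100.0
    n_cycles: int = 200
    mean_stride_s: float = 1.1
    jitter_sd_s: float = 0.02
    jitter_structure: str = "white"
    jitter_ar1_phi: float = 0.0
    region_amplitude_scale: dict[str, float] = field(
        default_factory=lambda: {"hindfoot": 1.0, "midfoot": 0.45, "forefoot": 1.0}
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise InvalidParameterError("fs_hz must be positive")
        if self.n_cycles < 1:
            raise InvalidParameterError("n_cycles must be >= 1")
        if self.mean_stride_s <= 0:
            raise InvalidParameterError("mean_stride_s must be positive")
        if self.jitter_sd_s < 0:
            raise InvalidParameterError("jitter_sd_s must be >= 0")
        if self.jitter_structure not in ("white", "autocorrelated"):
            raise InvalidParameterError(
                f"jitter_structure must be 'white' or 'autocorrelated', "
                f"got {self.jitter_structure!r}"
            )
        if not 0 <= self.jitter_ar1_phi < 1:
            raise InvalidParameterError("jitter_ar1_phi must be in [0, 1)")
        if self.weight_kg <= 0:
            raise InvalidParameterError("weight_kg must be positive")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        missing = set(REGIONS) - set(self.region_amplitude_scale)
        if missing:
            raise InvalidParameterError(f"region_amplitude_scale missing {sorted(missing)}")
        if any(v < 0 for v in self.region_amplitude_scale.values()):
            raise InvalidParameterError("amplitude multipliers must be >= 0")


def _raised_cosine(t: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    """Compact-support unimodal bump: 0 outside |t - center| >= halfwidth."""
    u = (t - center) / halfwidth
    out = np.zeros_like(t)
    inside = np.abs(u) < 1
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * u[inside]))
    return out


def _sensor_bump_params(layout: SensorLayout) -> list[tuple[float, float, float]]:
    """(center, halfwidth, amplitude-factor) per sensor, in stance fractions."""
    params = []
    # fallback offsets for unrecognized site names, spread within each region
    by_region: dict[str, list[int]] = {r: [] for r in REGIONS}
    for i, r in enumerate(layout.region_of):
        by_region[r].append(i)
    fallback_offset = {}
    for r, idxs in by_region.items():
        offs = np.linspace(-0.02, 0.02, len(idxs)) if len(idxs) > 1 else [0.0]
        for i, o in zip(idxs, offs):
            fallback_offset[i] = float(o)
    for i, (site, region) in enumerate(zip(layout.anatomical_site, layout.region_of)):
        center, halfwidth, _ = _REGION_BUMP[region]
        d_center, amp = _SITE_TWEAKS.get(site, (fallback_offset[i], 1.0))
        params.append((center + d_center, halfwidth, amp))
    return params


def generate_cycle_waveform(
    config: GaitGeneratorConfig, layout: SensorLayout, stride_s: float
) -> np.ndarray:
    """Noiseless per-sensor pressure curves for a single stride.

    Returns an ``(n_samples, 8)`` array covering one stride of duration
    ``stride_s``: a stance window (``STANCE_FRACTION`` of the stride) holding
    one raised-cosine bump per sensor, followed by an all-zero swing window.
    """
    if stride_s <= 0:
        raise InvalidParameterError(f"stride_s must be positive, got {stride_s}")
    n = int(round(stride_s * config.fs_hz))
    if n < 2:
        raise InvalidParameterError(
            f"stride_s={stride_s} too short for fs={config.fs_hz} Hz"
        )
    n_stance = max(int(round(STANCE_FRACTION * n)), 1)
    # Bump timing is anchored to the NOMINAL stride's stance duration, i.e.
    # the loading/push-off peaks sit at fixed times after heel strike rather
    # than stretching with each cycle's jitter. This keeps the peak-to-peak
    # stride intervals aligned with the programmed cycle durations to within
    # one sample, which is the generator's ground-truth contract.
    n_ref = max(
        int(round(STANCE_FRACTION * round(config.mean_stride_s * config.fs_hz))), 1
    )
    k = np.arange(n_stance, dtype=float)  # sample index within stance
    out = np.zeros((n, len(layout.sensor_ids)))
    for i, (center, halfwidth, amp_factor) in enumerate(_sensor_bump_params(layout)):
        region = layout.region_of[i]
        amplitude = (
            config.weight_kg * config.region_amplitude_scale[region] * amp_factor
        )
        # snap the bump center onto the sample grid so the per-sensor (and
        # fused) peak sample is unambiguous under additive noise
        center_samp = round(center * n_ref)
        halfwidth_samp = halfwidth * n_ref
        out[:n_stance, i] = amplitude * _raised_cosine(k, center_samp, halfwidth_samp)
    return out


def _stride_jitter(config: GaitGeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_cycles
    sd = config.jitter_sd_s
    if sd == 0:
        return np.zeros(n)
    if config.jitter_structure == "white" or config.jitter_ar1_phi == 0:
        jitter = rng.normal(0.0, sd, n)
    else:
        phi = config.jitter_ar1_phi
        innov_sd = sd * np.sqrt(1.0 - phi**2)
        jitter = np.empty(n)
        jitter[0] = rng.normal(0.0, sd)
        for k in range(1, n):
            jitter[k] = phi * jitter[k - 1] + rng.normal(0.0, innov_sd)
    # keep every stride duration positive
    return np.maximum(jitter, -0.5 * config.mean_stride_s)


def generate_recording(
    config: GaitGeneratorConfig, layout: SensorLayout | None = None
) -> PressureRecording:
    """Generate a full multi-cycle recording with jitter and sensor noise.

    The recording concatenates ``n_cycles`` stride waveforms whose durations
    are ``mean_stride_s`` plus jitter; Gaussian sensor noise with SD
    ``noise_sd`` is added to every channel and the result clipped at zero
    (pressure cannot be negative).  Metadata records the seed, the realized
    cycle boundaries/durations and the full configuration.
    """
    layout = layout or SensorLayout.default()
    if config.n_cycles < 3:
        warnings.warn(
            f"n_cycles={config.n_cycles} is too short for entropy analysis downstream",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    jitter = _stride_jitter(config, rng)
    durations = config.mean_stride_s + jitter
    # realize cycle boundaries on the sample grid from cumulative time, so
    # rounding errors do not accumulate across cycles
    edges_s = np.concatenate([[0.0], np.cumsum(durations)])
    boundaries = np.round(edges_s * config.fs_hz).astype(int)
    segments = []
    for k in range(config.n_cycles):
        n_k = boundaries[k + 1] - boundaries[k]
        segments.append(generate_cycle_waveform(config, layout, n_k / config.fs_hz))
    samples = np.concatenate(segments, axis=0)
    if config.noise_sd > 0:
        samples = samples + rng.normal(0.0, config.noise_sd, samples.shape)
        np.clip(samples, 0.0, None, out=samples)
    realized_durations = np.diff(boundaries) / config.fs_hz
    meta = {
        "seed": config.seed,
        "cycle_start_idx": boundaries[:-1].copy(),
        "cycle_duration_s": realized_durations,
        "programmed_duration_s": durations,
        "config": asdict(config),
    }
    return PressureRecording(
        samples=samples,
        fs_hz=config.fs_hz,
        weight_kg=config.weight_kg,
        speed_kmh=config.speed_kmh,
        layout=layout,
        meta=meta,
    )


def generate_paired_plate_signal(
    total: np.ndarray,
    bias: float = 0.0,
    noise_sd: float = 0.0,
    second_peak_attenuation: float = 1.0,
    seed: int = 0,
    contact_threshold_frac: float = 0.05,
) -> np.ndarray:
    """Surrogate force-plate trace paired with an insole total-pressure trace.

    Models the systematic differences one expects between an insole and a
    force plate: an additive ``bias``, Gaussian measurement noise, and a
    rescaled push-off (second stance) peak — real insoles under-read the
    push-off peak because few sensors sit under the rolling forefoot, so an
    attenuation > 1 makes the plate's second peak larger than the insole's.

    The second peak of each contact episode is scaled by
    ``second_peak_attenuation`` with a linear blend starting at the
    mid-stance valley (the first peak is untouched and the trace stays
    continuous).  Episodes without a clear double peak pass through
    unscaled.  With ``bias=0, noise_sd=0, second_peak_attenuation=1`` the
    output equals the input exactly.
    """
    from .errors import MorphologyError
    from .events import segment_stance, split_contacts

    total = np.asarray(total, dtype=float)
    if total.size and total.min() < 0:
        raise InvalidParameterError("total pressure trace must be nonnegative")
    out = total.astype(float).copy()
    if second_peak_attenuation != 1.0 and total.size:
        for start, end in split_contacts(total, contact_threshold_frac):
            segment = total[start:end]
            try:
                lm = segment_stance(segment)
            except MorphologyError:
                continue
            w = np.ones(end - start)
            v, p2 = lm.valley_idx, lm.second_peak_idx
            ramp = np.linspace(0.0, 1.0, p2 - v + 1)
            w[v : p2 + 1] = 1.0 + (second_peak_attenuation - 1.0) * ramp
            w[p2 + 1 :] = second_peak_attenuation
            out[start:end] = segment * w
    out += bias
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, out.shape)
    return out


# Speed presets: the study conditions. Faster walking has shorter strides,
# larger and less autocorrelated stride-time fluctuation (less regular gait),
# and higher hindfoot/forefoot loading. The forefoot multipliers are
# calibrated so the 6 km/h forefoot amplitude-pressure ratio exceeds the
# 2 km/h one by 26.7% (0.90 * 1.267 = 1.1403).
_PRESETS: dict[int, dict] = {
    2: dict(
        mean_stride_s=1.40,
        jitter_sd_s=0.010,
        jitter_structure="autocorrelated",
        jitter_ar1_phi=0.99,
        region_amplitude_scale={"hindfoot": 0.95, "midfoot": 0.45, "forefoot": 0.90},
    ),
    4: dict(
        mean_stride_s=1.10,
        jitter_sd_s=0.026,
        jitter_structure="autocorrelated",
        jitter_ar1_phi=0.92,
        region_amplitude_scale={"hindfoot": 1.05, "midfoot": 0.45, "forefoot": 1.02},
    ),
    6: dict(
        mean_stride_s=0.90,
        jitter_sd_s=0.032,
        jitter_structure="autocorrelated",
        jitter_ar1_phi=0.30,
        region_amplitude_scale={"hindfoot": 1.15, "midfoot": 0.45, "forefoot": 1.1403},
    ),
}

#: Default sensor-noise SD of the presets, in pressure units (~0.6% of a
#: 70 kg subject's regional peak).
PRESET_NOISE_SD = 0.4


def speed_preset(speed_kmh: int, **overrides) -> GaitGeneratorConfig:
    """Generator configuration for one of the study's treadmill speeds.

    Supported speeds are 2, 4 and 6 km/h.  Any :class:`GaitGeneratorConfig`
    field can be overridden by keyword (e.g. ``n_cycles``, ``seed``,
    ``noise_sd=0`` for noiseless runs).
    """
    try:
        base = _PRESETS[int(speed_kmh)]
    except (KeyError, TypeError, ValueError):
        raise InvalidParameterError(
            f"no preset for speed {speed_kmh!r}; supported speeds are 2, 4, 6 km/h"
        ) from None
    if int(speed_kmh) != speed_kmh:
        raise InvalidParameterError(f"no preset for speed {speed_kmh!r}")
    cfg = GaitGeneratorConfig(
        speed_kmh=float(speed_kmh), noise_sd=PRESET_NOISE_SD, **base
    )
    return replace(cfg, **overrides) if overrides else cfg
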