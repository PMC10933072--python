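"""Shared data containers: sensor layout, raw recordings, fused regional signals.

These types are re-exported by the modules that own them conceptually
(:mod:`gaitmse.synthetic` for :class:`SensorLayout`, :mod:`gaitmse.fusion`
for :class:`PressureRecording` / :class:`RegionalSignal`); they live here so
the generator and the fusion stage can share them without circular imports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .errors import ConfigurationError, InvalidParameterError

#: Canonical plantar regions, in proximal-to-distal order.
REGIONS = ("hindfoot", "midfoot", "forefoot")

#: Default anatomical sites for the 8-sensor insole. The real device's sensor
#: positions are not standardized, so this mapping is an explicit, overridable
#: assumption: two heel sensors (hindfoot), two arch sensors (midfoot), and
#: four sensors under the metatarsal heads and hallux (forefoot).
DEFAULT_SITES = (
    ("s1", "heel-medial", "hindfoot"),
    ("s2", "heel-lateral", "hindfoot"),
    ("s3", "arch-medial", "midfoot"),
    ("s4", "arch-lateral", "midfoot"),
    ("s5", "MTH1", "forefoot"),
    ("s6", "MTH3", "forefoot"),
    ("s7", "MTH5", "forefoot"),
    ("s8", "hallux", "forefoot"),
)


@dataclass(frozen=True)
class SensorLayout:
    """Assignment of the 8 insole sensors to anatomical sites and regions.

    Parameters
    ----------
    sensor_ids
        Ordered channel labels, matching the column order of recordings.
    anatomical_site
        Per-sensor site name (free text; recognized names get site-specific
        waveform timing in the generator).
    region_of
        Per-sensor region, each one of ``{"hindfoot", "midfoot", "forefoot"}``.
    """

    sensor_ids: tuple[str, ...]
    anatomical_site: tuple[str, ...]
    region_of: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.sensor_ids)
        if n != 8:
            raise ConfigurationError(f"layout must have exactly 8 sensors, got {n}")
        if len(self.anatomical_site) != n or len(self.region_of) != n:
            raise ConfigurationError("sensor_ids, anatomical_site, region_of must align")
        if len(set(self.sensor_ids)) != n:
            raise ConfigurationError("sensor ids must be unique")
        bad = set(self.region_of) - set(REGIONS)
        if bad:
            raise ConfigurationError(f"unknown region(s): {sorted(bad)}")
        for region in REGIONS:
            if region not in self.region_of:
                raise ConfigurationError(f"region {region!r} has no sensors")

    @classmethod
    def default(cls) -> "SensorLayout":
        ids, sites, regions = zip(*DEFAULT_SITES)
        return cls(ids, sites, regions)

    def sensors_in(self, region: str) -> tuple[int, ...]:
        """Channel indices belonging to ``region``."""
        if region not in REGIONS:
            raise ConfigurationError(f"unknown region {region!r}")
        return tuple(i for i, r in enumerate(self.region_of) if r == region)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            sid: {"site": site, "region": region}
            for sid, site, region in zip(self.sensor_ids, self.anatomical_site, self.region_of)
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SensorLayout":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"layout file {path} must map sensor id -> site/region")
        ids, sites, regions = [], [], []
        for sid, entry in data.items():
            ids.append(str(sid))
            sites.append(str(entry["site"]))
            regions.append(str(entry["region"]))
        return cls(tuple(ids), tuple(sites), tuple(regions))


@dataclass
class PressureRecording:
    """A multi-channel plantar pressure time series with subject metadata.

    ``samples`` is an ``(n_samples, 8)`` array in arbitrary but consistent
    pressure units; ``weight_kg`` is the subject's body mass, ``speed_kmh``
    the treadmill speed label of the trial.
    """

    samples: np.ndarray
    fs_hz: float
    weight_kg: float
    speed_kmh: float
    layout: SensorLayout = field(default_factory=SensorLayout.default)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise InvalidParameterError("samples must be 2-D (n_samples x n_sensors)")
        if self.samples.shape[0] < 1:
            raise InvalidParameterError("recording must contain at least one sample")
        if self.samples.shape[1] != len(self.layout.sensor_ids):
            raise InvalidParameterError(
                f"samples have {self.samples.shape[1]} channels, "
                f"layout has {len(self.layout.sensor_ids)}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("samples must be finite")
        if self.fs_hz <= 0:
            raise InvalidParameterError("fs_hz must be positive")
        if self.weight_kg <= 0:
            raise InvalidParameterError("weight_kg must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return np.arange(self.n_samples) / self.fs_hz


@dataclass
class RegionalSignal:
    """Fused hindfoot / midfoot / forefoot traces plus a whole-foot total."""

    hindfoot: np.ndarray
    midfoot: np.ndarray
    forefoot: np.ndarray
    total: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        for name in ("hindfoot", "midfoot", "forefoot", "total"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        lengths = {t.shape for t in (self.hindfoot, self.midfoot, self.forefoot, self.total)}
        if len(lengths) != 1:
            raise InvalidParameterError("all regional traces must have equal length")
        if self.fs_hz <= 0:
            raise InvalidParameterError("fs_hz must be positive")

    def region(self, name: str) -> np.ndarray:
        if name not in REGIONS:
            raise ConfigurationError(f"unknown region {name!r}")
        return getattr(self, name)

    @property
    def n_samples(self) -> int:
        return self.total.shape[0]
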