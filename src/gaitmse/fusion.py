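"""Regional fusion, trace normalization and recording CSV I/O.

The 8 insole channels are fused into three regional signals (hindfoot,
midfoot, forefoot) by pointwise averaging of the member channels, and the
whole-foot total is obtained by further fusing the three regional traces
(sum by default, mean selectable).  For cross-device and cross-subject
comparison a trace can be normalized to unit peak amplitude on a common
percent-of-stance grid.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .core import REGIONS, PressureRecording, RegionalSignal, SensorLayout
from .errors import (
    ConfigurationError,
    InvalidParameterError,
    RecordingParseError,
    UndefinedNormalizationError,
)

__all__ = [
    "PressureRecording",
    "RegionalSignal",
    "fuse_regions",
    "normalize_trace",
    "read_recording",
    "write_recording",
    "write_regional",
]


def fuse_regions(rec: PressureRecording, total_mode: str = "sum") -> RegionalSignal:
    """Fuse per-sensor channels into regional and total pressure traces.

    Each regional trace is the pointwise arithmetic mean of its member
    channels.  ``total_mode`` selects how the three regional traces combine
    into the whole-foot total: ``"sum"`` (default, mimics whole-foot load)
    or ``"mean"``.
    """
    if total_mode not in ("sum", "mean"):
        raise InvalidParameterError(f"total_mode must be 'sum' or 'mean', got {total_mode!r}")
    regional = {}
    for region in REGIONS:
        idx = rec.layout.sensors_in(region)
        if not idx:
            raise ConfigurationError(f"region {region!r} has no sensors in layout")
        regional[region] = rec.samples[:, idx].mean(axis=1)
    stacked = np.stack([regional[r] for r in REGIONS])
    total = stacked.sum(axis=0) if total_mode == "sum" else stacked.mean(axis=0)
    return RegionalSignal(
        hindfoot=regional["hindfoot"],
        midfoot=regional["midfoot"],
        forefoot=regional["forefoot"],
        total=total,
        fs_hz=rec.fs_hz,
    )


def normalize_trace(trace: np.ndarray, n_points: int = 101) -> np.ndarray:
    """Normalize a trace to unit peak on an ``n_points`` percent-style grid.

    The time axis is linearly resampled onto ``n_points`` evenly spaced
    points spanning the trace (default 101 = 0..100% in 1% steps, the gait
    convention) and the amplitude rescaled so the resampled peak is exactly
    1.0.  Idempotent to float tolerance.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size == 0:
        raise InvalidParameterError("normalize_trace expects a nonempty 1-D trace")
    if n_points < 2:
        raise InvalidParameterError("n_points must be >= 2")
    if np.max(trace) <= 0:
        raise UndefinedNormalizationError(
            "trace has no positive samples; amplitude normalization undefined"
        )
    grid = np.linspace(0.0, trace.size - 1.0, n_points)
    resampled = np.interp(grid, np.arange(trace.size), trace)
    return resampled / resampled.max()


_REQUIRED_HEADERS = ("weight_kg", "speed_kmh", "fs_hz")


def write_recording(rec: PressureRecording, path: str | Path) -> None:
    """Write a recording in the documented CSV dialect.

    Header comment lines carry the metadata (``# weight_kg=…`` etc.), then a
    ``time_s,s1,…,s8`` column header and one row per sample.  Values are
    written with 17 significant digits so a read round-trips to full float
    precision.
    """
    path = Path(path)
    cols = ",".join(rec.layout.sensor_ids)
    lines = [
        f"# weight_kg={rec.weight_kg!r}",
        f"# speed_kmh={rec.speed_kmh!r}",
        f"# fs_hz={rec.fs_hz!r}",
        f"# seed={rec.meta.get('seed', 0)}",
        f"time_s,{cols}",
    ]
    times = rec.times
    for i in range(rec.n_samples):
        row = ",".join(f"{v:.17g}" for v in rec.samples[i])
        lines.append(f"{times[i]:.17g},{row}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_recording(path: str | Path, layout: SensorLayout | None = None) -> PressureRecording:
    """Read a recording written by :func:`write_recording`.

    Raises :class:`RecordingParseError` naming the offending line for missing
    header metadata, non-numeric cells or wrong column counts.  Trailing
    blank lines are tolerated.
    """
    layout = layout or SensorLayout.default()
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    n_cols: int | None = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise RecordingParseError(f"malformed header {line!r}", lineno)
                key, _, value = body.partition("=")
                try:
                    header[key.strip()] = float(value)
                except ValueError:
                    raise RecordingParseError(
                        f"non-numeric header value {value!r} for {key.strip()!r}", lineno
                    ) from None
                continue
            if line.startswith("time_s"):
                n_cols = len(line.split(","))
                continue
            cells = line.split(",")
            if n_cols is None:
                raise RecordingParseError("data row before column header", lineno)
            if len(cells) != n_cols:
                raise RecordingParseError(
                    f"expected {n_cols} columns, got {len(cells)}", lineno
                )
            try:
                rows.append([float(c) for c in cells[1:]])
            except ValueError:
                raise RecordingParseError(f"non-numeric cell in row {line!r}", lineno) from None
    for key in _REQUIRED_HEADERS:
        if key not in header:
            raise RecordingParseError(f"missing required header '# {key}=...'")
    if not rows:
        raise RecordingParseError("recording contains no samples")
    meta = {"seed": int(header["seed"])} if "seed" in header else {}
    meta["source_file"] = str(path)
    return PressureRecording(
        samples=np.asarray(rows, dtype=float),
        fs_hz=header["fs_hz"],
        weight_kg=header["weight_kg"],
        speed_kmh=header["speed_kmh"],
        layout=layout,
        meta=meta,
    )


def write_regional(sig: RegionalSignal, path: str | Path) -> None:
    """Export a fused signal as ``time_s,hindfoot,midfoot,forefoot,total`` CSV."""
    path = Path(path)
    times = np.arange(sig.n_samples) / sig.fs_hz
    lines = ["time_s,hindfoot,midfoot,forefoot,total"]
    for i in range(sig.n_samples):
        lines.append(
            f"{times[i]:.17g},{sig.hindfoot[i]:.17g},{sig.midfoot[i]:.17g},"
            f"{sig.forefoot[i]:.17g},{sig.total[i]:.17g}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
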