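"""Multi-scale sample entropy of stride-interval series.

Sample entropy (SampEn) is the negative log of the conditional probability
that two subsequences of a series which match for ``m`` consecutive points
(Chebyshev distance strictly below a tolerance ``r``, self-matches excluded)
also match for ``m + 1`` points.  Multi-scale entropy (MSE) applies SampEn
to coarse-grained copies of the series: at scale ``s`` the series is replaced
by the means of consecutive non-overlapping windows of length ``s``, so the
entropy-vs-scale profile separates short-time irregularity from structure
that survives averaging.

Conventions
-----------
* Matching uses the strict inequality ``d < r``.
* Template counting follows the standard Richman–Moorman construction:
  both the length-``m`` and the length-``m+1`` template sets contain
  ``N' - m`` vectors (``N'`` = coarse-grained length), so the pair counts
  share a denominator and ``SampEn = -ln(A / B)`` with ``A <= B``
  guaranteed, hence SampEn >= 0 whenever defined.
* By default the tolerance is ``r = r_frac * SD`` of the ORIGINAL series and
  is held fixed across scales, the established MSE convention; computing a
  fresh SD per scale is selectable via ``r_convention="per_scale_SD"``.
* Zero matches at either length give an undefined entropy, reported as NaN
  (never +/-inf) so downstream aggregation stays well-defined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InvalidScaleError, SeriesLengthError, ToleranceError

__all__ = [
    "EntropyParams",
    "MSEProfile",
    "MSEReport",
    "coarse_grain",
    "sample_entropy",
    "mse",
    "mse_report",
]


@dataclass(frozen=True)
class EntropyParams:
    """Parameters of the multi-scale entropy computation.

    m : embedding dimension (template length); 2 is the field default for
        stride-interval series.
    r_frac : tolerance as a fraction of the series SD; 0.25 is the upper end
        of the customary 0.10-0.25 range and the default here.
    max_scale : largest coarse-graining scale; 6 covers the small (1-3) and
        large (4-6) scale bands summarized by :class:`MSEProfile`.
    r_convention : ``"fixed_from_original_SD"`` (default) computes r once
        from the original series; ``"per_scale_SD"`` recomputes it from each
        coarse-grained series.
    """

    m: int = 2
    r_frac: float = 0.25
    max_scale: int = 6
    r_convention: str = "fixed_from_original_SD"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ToleranceError(f"m must be >= 1, got {self.m}")
        if not 0 < self.r_frac <= 1:
            raise ToleranceError(f"r_frac must be in (0, 1], got {self.r_frac}")
        if self.max_scale < 1:
            raise InvalidScaleError(f"max_scale must be >= 1, got {self.max_scale}")
        if self.r_convention not in ("fixed_from_original_SD", "per_scale_SD"):
            raise ToleranceError(f"unknown r_convention {self.r_convention!r}")


@dataclass
class MSEProfile:
    """Entropy per scale plus the scale-band summaries.

    ``entropy_by_scale[s - 1]`` is the sample entropy at scale ``s`` (nats).
    ``samp_en`` is the scale-1 value, ``mse_s`` the mean over scales 1-3 and
    ``mse_l`` the mean over scales 4-6 (``None`` when max_scale is too small).
    Undefined scales are NaN and propagate to the band means as NaN.
    """

    entropy_by_scale: np.ndarray
    sd_original: float
    params: EntropyParams
    n_input: int
    samp_en: float = field(init=False)
    mse_s: float | None = field(init=False)
    mse_l: float | None = field(init=False)

    def __post_init__(self) -> None:
        self.entropy_by_scale = np.asarray(self.entropy_by_scale, dtype=float)
        self.samp_en = float(self.entropy_by_scale[0])
        self.mse_s = (
            float(np.mean(self.entropy_by_scale[0:3])) if self.params.max_scale >= 3 else None
        )
        self.mse_l = (
            float(np.mean(self.entropy_by_scale[3:6])) if self.params.max_scale >= 6 else None
        )

    def entropy_at(self, s: int) -> float:
        """Entropy at scale ``s`` (1-based)."""
        if not 1 <= s <= self.params.max_scale:
            raise InvalidScaleError(f"scale {s} outside 1..{self.params.max_scale}")
        return float(self.entropy_by_scale[s - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scale": np.arange(1, self.params.max_scale + 1),
                "entropy": self.entropy_by_scale,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def coarse_grain(x: Sequence[float], s: int) -> np.ndarray:
    """Coarse-grain ``x`` at scale ``s``.

    Output element ``j`` (1-based) is the mean of ``x[(j-1)*s : j*s]``; the
    output length is ``floor(N / s)`` and any trailing remainder shorter than
    ``s`` is dropped.  Scale 1 returns the series unchanged.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise InvalidScaleError("coarse_grain expects a 1-D series")
    if s < 1:
        raise InvalidScaleError(f"scale must be >= 1, got {s}")
    n = x.size
    if s > n:
        raise InvalidScaleError(f"scale {s} exceeds series length {n}")
    if s == 1:
        return x.copy()
    n_out = n // s
    return x[: n_out * s].reshape(n_out, s).mean(axis=1)


def _pair_match_count(x: np.ndarray, m: int, r: float, n_templates: int) -> int:
    """Ordered pairs (i != j) of length-``m`` templates with Chebyshev distance < r.

    Only the first ``n_templates`` templates participate, so the m and m+1
    counts can be formed over equally many vectors.
    """
    templates = sliding_window_view(x, m)[:n_templates]
    # Chebyshev distance matrix; n_templates is at most a few thousand here.
    dist = np.abs(templates[:, None, :] - templates[None, :, :]).max(axis=2)
    # The diagonal is zero and always < r; subtract the self-matches.
    return int(np.count_nonzero(dist < r)) - n_templates


def sample_entropy(x: Sequence[float], m: int = 2, r: float | None = None) -> float:
    """Sample entropy of ``x`` with embedding dimension ``m`` and absolute tolerance ``r``.

    Returns ``-ln(A / B)`` where ``B`` and ``A`` count template pairs matching
    at lengths ``m`` and ``m + 1`` (strict ``< r``, self-matches excluded,
    both sets containing ``N - m`` templates).  Returns NaN when either count
    is zero (entropy undefined), never raises for that case.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise SeriesLengthError("sample_entropy expects a 1-D series")
    if m < 1:
        raise ToleranceError(f"m must be >= 1, got {m}")
    n = x.size
    if n < m + 2:
        raise SeriesLengthError(f"series length {n} < m + 2 = {m + 2}")
    if r is None or r <= 0:
        raise ToleranceError(
            f"tolerance r must be positive, got {r!r}; for (near-)constant series "
            "pass an absolute r instead of a fraction of SD"
        )
    n_templates = n - m
    b_count = _pair_match_count(x, m, r, n_templates)
    a_count = _pair_match_count(x, m + 1, r, n_templates)
    if b_count == 0 or a_count == 0:
        warnings.warn(
            f"sample entropy undefined: {b_count} m-matches, {a_count} (m+1)-matches",
            stacklevel=2,
        )
        return float("nan")
    return -math.log(a_count / b_count)


def _min_length(params: EntropyParams) -> int:
    return params.max_scale * (params.m + 2)


def mse(x: Sequence[float], params: EntropyParams | None = None) -> MSEProfile:
    """Multi-scale entropy profile of ``x``.

    For each scale ``s`` from 1 to ``params.max_scale`` the series is
    coarse-grained and its sample entropy computed with tolerance
    ``r_frac * SD`` (SD of the original series by default, recomputed per
    scale under the ``per_scale_SD`` convention).
    """
    params = params or EntropyParams()
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < _min_length(params):
        raise SeriesLengthError(
            f"series length {n} too short for max_scale={params.max_scale} with "
            f"m={params.m}; need at least {_min_length(params)} points"
        )
    sd = float(np.std(x, ddof=1))
    if sd == 0 and params.r_convention == "fixed_from_original_SD":
        raise ToleranceError(
            "constant series has SD=0 so r = r_frac*SD = 0; use an absolute "
            "tolerance via sample_entropy directly"
        )
    values = np.empty(params.max_scale)
    for s in range(1, params.max_scale + 1):
        y = coarse_grain(x, s)
        if params.r_convention == "per_scale_SD":
            sd_s = float(np.std(y, ddof=1))
            if sd_s == 0:
                raise ToleranceError(f"coarse-grained series at scale {s} is constant")
            r = params.r_frac * sd_s
        else:
            r = params.r_frac * sd
        values[s - 1] = sample_entropy(y, params.m, r)
    return MSEProfile(entropy_by_scale=values, sd_original=sd, params=params, n_input=n)


@dataclass
class MSEReport:
    """Per-condition entropy summary table and pairwise small-scale contrasts.

    ``table`` has one row per condition with mean and SD (across replicate
    series) of SampEn, MSE_S and MSE_L plus the series lengths used;
    ``pairwise_mse_s`` lists the difference in mean MSE_S for every ordered
    condition pair (later condition minus earlier, in input order).
    """

    table: pd.DataFrame
    pairwise_mse_s: pd.DataFrame
    profiles: dict[str, list[MSEProfile]]


def _as_series(obj) -> np.ndarray:
    intervals = getattr(obj, "intervals", obj)
    return np.asarray(intervals, dtype=float)


def mse_report(
    series_by_condition: Mapping[str, Iterable],
    params: EntropyParams | None = None,
) -> MSEReport:
    """Summarize MSE across labeled conditions.

    ``series_by_condition`` maps a condition label (e.g. a walking speed) to
    one or more stride-interval series (arrays or ``StrideSeries``).  NaN
    entropies (undefined scales) propagate into the means as missing values
    with a warning.
    """
    params = params or EntropyParams()
    if not series_by_condition:
        raise SeriesLengthError("at least one condition is required")
    profiles: dict[str, list[MSEProfile]] = {}
    rows = []
    for label, series in series_by_condition.items():
        if hasattr(series, "intervals") or (
            isinstance(series, np.ndarray) and series.ndim == 1
        ):
            series = [series]
        else:
            series = list(series)
            if series and np.isscalar(series[0]):
                series = [np.asarray(series, dtype=float)]
        profs = [mse(_as_series(s), params) for s in series]
        profiles[label] = profs
        samp = np.array([p.samp_en for p in profs])
        mse_s = np.array([p.mse_s for p in profs], dtype=float)
        mse_l = np.array(
            [p.mse_l if p.mse_l is not None else np.nan for p in profs], dtype=float
        )
        n_undef = int(np.isnan(samp).sum() + np.isnan(mse_s).sum() + np.isnan(mse_l).sum())
        if n_undef:
            warnings.warn(
                f"condition {label!r}: {n_undef} undefined entropy cell(s) "
                "excluded from the condition means",
                stacklevel=2,
            )

        def _mean(a: np.ndarray) -> float:
            return float(np.nanmean(a)) if not np.isnan(a).all() else float("nan")

        def _sd(a: np.ndarray) -> float:
            a = a[~np.isnan(a)]
            return float(np.std(a, ddof=1)) if a.size > 1 else 0.0

        rows.append(
            {
                "condition": label,
                "n_series": len(profs),
                "series_lengths": [p.n_input for p in profs],
                "n_undefined_cells": n_undef,
                "sampen_mean": _mean(samp),
                "sampen_sd": _sd(samp),
                "mse_s_mean": _mean(mse_s),
                "mse_s_sd": _sd(mse_s),
                "mse_l_mean": _mean(mse_l),
                "mse_l_sd": _sd(mse_l),
            }
        )
    table = pd.DataFrame(rows)
    labels = list(series_by_condition)
    pair_rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            da = table.loc[table.condition == a, "mse_s_mean"].item()
            db = table.loc[table.condition == b, "mse_s_mean"].item()
            pair_rows.append({"condition_a": a, "condition_b": b, "mse_s_diff": db - da})
    pairwise = pd.DataFrame(pair_rows, columns=["condition_a", "condition_b", "mse_s_diff"])
    return MSEReport(table=table, pairwise_mse_s=pairwise, profiles=profiles)
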