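"""Bland–Altman agreement and correlation between paired pressure methods.

Used to check an insole total-pressure trace against a paired force-plate
measurement: limits of agreement are the classic Bland–Altman construction
``mean difference ± 1.96 × SD of differences`` (not a confidence interval of
the mean), alongside the Pearson correlation of the paired values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import InputError
from .events import segment_stance

__all__ = ["AgreementResult", "bland_altman", "validate_paired_traces", "bland_altman_plot"]


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman statistics and Pearson correlation for paired methods.

    ``pearson_r`` (and its ``p_value``) are NaN when either input has zero
    variance, where the correlation is undefined.
    """

    mean_diff: float
    loa_low: float
    loa_high: float
    coverage: float
    pearson_r: float
    p_value: float
    n_pairs: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n", encoding="utf-8")


def bland_altman(x: np.ndarray, y: np.ndarray) -> AgreementResult:
    """Agreement statistics for paired measurements ``x`` (method A) and ``y`` (method B).

    Differences are ``d = x - y``; limits of agreement are
    ``mean(d) ± 1.96 * SD(d)`` (sample SD) and ``coverage`` is the fraction
    of differences falling inside them (inclusive).  Pearson r is computed
    on the raw pairs and flagged NaN if either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise InputError("paired inputs must be 1-D")
    if x.size != y.size:
        raise InputError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise InputError(f"need at least 3 pairs, got {x.size}")
    d = x - y
    mean_diff = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_low = mean_diff - 1.96 * sd
    loa_high = mean_diff + 1.96 * sd
    coverage = float(np.mean((d >= loa_low) & (d <= loa_high)))
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant input: Pearson r undefined", stacklevel=2)
        r, p = float("nan"), float("nan")
    else:
        r, p = stats.pearsonr(x, y)
        r, p = float(r), float(p)
    return AgreementResult(
        mean_diff=mean_diff,
        loa_low=loa_low,
        loa_high=loa_high,
        coverage=coverage,
        pearson_r=r,
        p_value=p,
        n_pairs=int(x.size),
    )


def validate_paired_traces(
    insole_total: np.ndarray,
    plate_total: np.ndarray,
    mode: str = "trace",
) -> AgreementResult:
    """Agreement between normalized insole and force-plate total-pressure traces.

    Both traces must already be on a common grid (see
    :func:`gaitmse.fusion.normalize_trace`).  ``mode="trace"`` (default)
    compares every grid sample; ``mode="peaks"`` compares only the three
    stance landmarks (loading peak, valley, push-off peak) of each trace,
    for the case where agreement on peak values alone is of interest.
    """
    insole = np.asarray(insole_total, dtype=float)
    plate = np.asarray(plate_total, dtype=float)
    if insole.size != plate.size:
        raise InputError(
            f"traces must share a grid: lengths {insole.size} vs {plate.size}"
        )
    if mode == "trace":
        return bland_altman(insole, plate)
    if mode == "peaks":
        vals = []
        for trace in (insole, plate):
            lm = segment_stance(trace)
            vals.append(
                np.array([trace[lm.first_peak_idx], trace[lm.valley_idx], trace[lm.second_peak_idx]])
            )
        return bland_altman(vals[0], vals[1])
    raise InputError(f"mode must be 'trace' or 'peaks', got {mode!r}")


def bland_altman_plot(x: np.ndarray, y: np.ndarray, path: str | Path) -> AgreementResult:
    """Save a Bland–Altman scatter (mean vs. difference with limit lines)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = bland_altman(x, y)
    means = (x + y) / 2.0
    diffs = x - y
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=8, alpha=0.6)
    for level, style in ((res.mean_diff, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(level, color="k", linestyle=style, linewidth=0.8)
    ax.set_xlabel("mean of paired measurements")
    ax.set_ylabel("difference (A - B)")
    ax.set_title(f"Bland–Altman (r = {res.pearson_r:.3f}, n = {res.n_pairs})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return res
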