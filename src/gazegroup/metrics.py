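"""The 16 per-scanpath eye-tracking metrics and their per-participant table.

Three metric families are covered: movement measures (average fixation
duration, saccade amplitude and duration, the ambient/focal K coefficient),
numerosity measures (fixation/saccade counts and rates, scanpath length,
completion time), and spatial statistics of the fixation-position
distribution (standard deviation, skewness, excess kurtosis, per axis).

Units: durations and completion time in milliseconds, lengths in pixels,
rates per second, K coefficient and shape statistics unitless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .io import Dataset, Scanpath

#: Canonical metric names, in canonical column order.
METRIC_NAMES: tuple[str, ...] = (
    "AvgFix",
    "AvgSac",
    "AvgSacDur",
    "KCoef",
    "FixNum",
    "FixRate",
    "SacNum",
    "SacRate",
    "ScanLen",
    "CompTime",
    "StdX",
    "StdY",
    "SkewX",
    "SkewY",
    "KurtX",
    "KurtY",
)


@dataclass(frozen=True)
class SaccadeRecord:
    """Movement between fixations ``from_index`` and ``from_index + 1``."""

    from_index: int
    to_index: int
    length: float  # px, Euclidean distance between fixation centers
    duration: float  # ms, gap between fixation end and next start, >= 0


def compute_saccades(scanpath: Scanpath) -> list[SaccadeRecord]:
    """Derive the saccades implied by consecutive fixations.

    A scanpath with f fixations yields f − 1 saccades. Saccade duration is
    the gap between the end of one fixation and the start of the next,
    floored at zero (a repaired/abutting sequence may have zero gaps).
    """
    out: list[SaccadeRecord] = []
    fx = scanpath.fixations
    for i in range(len(fx) - 1):
        a, b = fx[i], fx[i + 1]
        length = float(np.hypot(b.x - a.x, b.y - a.y))
        duration = max(0.0, b.start - (a.start + a.duration))
        out.append(SaccadeRecord(i, i + 1, length, duration))
    return out


def duration_and_rate_metrics(
    scanpath: Scanpath, completion_time: float | None = None
) -> dict[str, float]:
    """Fixation/saccade counts, durations and per-second rates.

    Completion time defaults to the scanpath's temporal span (first start
    to last end); pass ``completion_time`` when the trial's true display
    time is known.
    """
    sacc = compute_saccades(scanpath)
    durs = scanpath.durations()
    fix_num = float(len(scanpath))
    sac_num = float(len(sacc))
    if completion_time is None:
        completion_time = scanpath.fixations[-1].end - scanpath.fixations[0].start
    if completion_time <= 0:
        raise ValueError("completion time is zero; rates are undefined")
    seconds = completion_time / 1000.0
    return {
        "AvgFix": float(np.mean(durs)),
        "AvgSacDur": float(np.mean([s.duration for s in sacc])) if sacc else 0.0,
        "FixNum": fix_num,
        "SacNum": sac_num,
        "FixRate": fix_num / seconds,
        "SacRate": sac_num / seconds,
        "CompTime": float(completion_time),
    }


def amplitude_metrics(scanpath: Scanpath) -> dict[str, float]:
    """Scanpath length (sum of saccade amplitudes) and mean amplitude."""
    sacc = compute_saccades(scanpath)
    if not sacc:
        return {"AvgSac": 0.0, "ScanLen": 0.0}
    scan_len = float(sum(s.length for s in sacc))
    return {"AvgSac": scan_len / len(sacc), "ScanLen": scan_len}


def spatial_moment_metrics(scanpath: Scanpath) -> tuple[dict[str, float], set[str]]:
    """Spread and shape of the fixation-position distribution, per axis.

    Std uses the n−1 sample estimator; skewness is the population-moment
    g1 = m3 / m2^{3/2} and kurtosis the excess g2 = m4 / m2² − 3 (zero for
    a normal distribution). Degenerate cases (too few fixations, or a
    zero-variance axis) yield 0 and are reported in the returned flag set.
    """
    xy = scanpath.xy()
    vals: dict[str, float] = {}
    flags: set[str] = set()
    for axis, name in ((0, "X"), (1, "Y")):
        v = xy[:, axis]
        if len(v) >= 2:
            vals[f"Std{name}"] = float(np.std(v, ddof=1))
        else:
            vals[f"Std{name}"] = 0.0
            flags.add(f"Std{name}")
        if len(v) >= 3 and np.ptp(v) > 0:
            vals[f"Skew{name}"] = float(stats.skew(v, bias=True))
            vals[f"Kurt{name}"] = float(stats.kurtosis(v, fisher=True, bias=True))
        else:
            vals[f"Skew{name}"] = 0.0
            vals[f"Kurt{name}"] = 0.0
            flags.add(f"Skew{name}")
            flags.add(f"Kurt{name}")
    return vals, flags


def k_coefficient(dataset: Dataset) -> tuple[dict[tuple[str, str], float], set[str]]:
    """Ambient/focal K coefficient for every scanpath of a dataset.

    Each fixation with an outgoing saccade contributes the pair
    (fixation duration d, following saccade amplitude a). Durations and
    amplitudes are z-scored with the POOLED dataset mean and standard
    deviation, and a scanpath's K is the mean of z(d) − z(a) over its
    pairs: positive K means long fixations with short saccades (focal
    attention), negative K the opposite (ambient attention).

    Returns a per-(participant, stimulus) K map plus degeneracy flags
    ("zero-variance" when a pooled channel is constant; scanpaths without
    any saccade get K = 0 and a "no-pairs:<key>" flag).
    """
    if not dataset.scanpaths:
        raise ValueError("empty dataset")
    pairs: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    all_d: list[np.ndarray] = []
    all_a: list[np.ndarray] = []
    for key, sp in sorted(dataset.scanpaths.items()):
        sacc = compute_saccades(sp)
        d = sp.durations()[:-1] if sacc else np.empty(0)
        a = np.array([s.length for s in sacc], dtype=float)
        pairs[key] = (d, a)
        all_d.append(d)
        all_a.append(a)
    pooled_d = np.concatenate(all_d) if all_d else np.empty(0)
    pooled_a = np.concatenate(all_a) if all_a else np.empty(0)
    flags: set[str] = set()
    if pooled_d.size < 2:
        raise ValueError("need at least two pooled fixation/saccade pairs")
    sd_d = float(np.std(pooled_d, ddof=1))
    sd_a = float(np.std(pooled_a, ddof=1))
    mu_d = float(np.mean(pooled_d))
    mu_a = float(np.mean(pooled_a))
    if sd_d == 0 or sd_a == 0:
        flags.add("zero-variance")
        return {k: 0.0 for k in pairs}, flags
    out: dict[tuple[str, str], float] = {}
    for key, (d, a) in pairs.items():
        if d.size == 0:
            out[key] = 0.0
            flags.add(f"no-pairs:{key}")
        else:
            out[key] = float(np.mean((d - mu_d) / sd_d - (a - mu_a) / sd_a))
    return out, flags


def metric_vector(scanpath: Scanpath, k_value: float) -> dict[str, float]:
    """All 16 metrics of one scanpath (K must be supplied: it is pooled)."""
    vals = duration_and_rate_metrics(scanpath)
    vals.update(amplitude_metrics(scanpath))
    spatial, _ = spatial_moment_metrics(scanpath)
    vals.update(spatial)
    vals["KCoef"] = k_value
    return {name: vals[name] for name in METRIC_NAMES}


def compute_metric_table(
    dataset: Dataset,
    aggregation: str | Callable = "mean",
    per_scanpath: bool = False,
) -> pd.DataFrame:
    """Compute the participants × 16 metric table.

    Per-scanpath metric vectors are aggregated across each participant's
    stimuli (default: unweighted mean). With ``per_scanpath=True`` the
    table keeps one row per (participant, stimulus) instead, indexed by a
    MultiIndex.
    """
    if not dataset.scanpaths:
        raise ValueError("empty dataset")
    k_map, _ = k_coefficient(dataset)
    rows = []
    index = []
    for key, sp in sorted(dataset.scanpaths.items()):
        rows.append(metric_vector(sp, k_map[key]))
        index.append(key)
    df = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["participant", "stimulus"]))
    df = df[list(METRIC_NAMES)]
    if per_scanpath:
        return df
    agg = df.groupby(level="participant", sort=True).agg(aggregation)
    bad = agg.index[~np.isfinite(agg.to_numpy()).all(axis=1)].tolist()
    if bad:
        raise ValueError(f"participants with invalid metric values: {bad}")
    return agg
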