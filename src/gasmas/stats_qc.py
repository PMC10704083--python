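"""Outlier filtering, replicate aggregation and comparability statistics.

Implements the protocol's QC chain: the pathlength outlier rule (0 m or
> 0.23 m), per-configuration mean/SD aggregation over 21 replicates, a
from-scratch two-sample Kolmogorov-Smirnov test used to decide whether two
pathlength samples are statistically indistinguishable (p > 0.05), and
box-plot statistics of estimated O2 concentrations per nominal gas batch.

The KS test computes the D statistic from pooled empirical CDFs. Its p-value
uses the exact permutation null distribution (integer lattice-path counting)
for small tie-free samples and the asymptotic Kolmogorov series with the
Stephens small-sample correction, lambda = (sqrt(ne) + 0.12 + 0.11/sqrt(ne))
* D, otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .inversion import GasEstimate

__all__ = [
    "ConfigSummary",
    "KsResult",
    "BoxSummary",
    "flag_outliers",
    "aggregate_replicates",
    "ks_two_sample",
    "compare_configurations",
    "concentration_boxes",
    "holm_adjust",
]

#: Protocol outlier bounds on the calculated pathlength, metres.
OUTLIER_LOW = 0.0
OUTLIER_HIGH = 0.23
#: Numerical tolerance for the "0 m" outlier class.
ZERO_TOL = 1e-12

#: Sample-size bound below which the exact permutation p-value is used.
EXACT_MAX_N = 16


@dataclass(frozen=True)
class ConfigSummary:
    """Aggregated pathlength/O2 statistics for one configuration."""

    config_id: str
    n_total: int
    n_outliers: int
    mean_pathlength: float | None  # m, outliers excluded; None if no data
    sd_pathlength: float | None
    mean_o2: float | None
    sd_o2: float | None


@dataclass(frozen=True)
class KsResult:
    """Two-sample Kolmogorov-Smirnov comparison outcome."""

    d_statistic: float
    p_value: float
    n1: int
    n2: int
    comparable: bool  # p > 0.05: samples statistically indistinguishable
    method: str = "asymp"

    def __post_init__(self) -> None:
        if not 0.0 <= self.d_statistic <= 1.0:
            raise ValueError("D must lie in [0, 1]")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p must lie in [0, 1]")


@dataclass(frozen=True)
class BoxSummary:
    """Box-plot statistics (median, quartiles, 1.5 IQR whiskers)."""

    label: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outlier_values: tuple[float, ...]


def flag_outliers(
    estimates: Iterable[GasEstimate],
    low: float = OUTLIER_LOW,
    high: float = OUTLIER_HIGH,
) -> list[GasEstimate]:
    """Apply the pathlength outlier rule: flag l <= low (+tol) or l > high.

    The upper bound is strict (0.230 m is retained, 0.231 m is flagged);
    the lower class catches exact zeros — i.e. failed 820 nm inversions —
    within a 1e-12 m numerical tolerance. Idempotent and order-independent.
    """
    if not low < high:
        raise ValueError("outlier bounds must satisfy low < high")
    flagged = []
    for est in estimates:
        is_outlier = (
            est.pathlength <= low + ZERO_TOL
            or est.pathlength > high
            or not est.valid
        )
        flagged.append(replace(est, outlier=is_outlier))
    return flagged


def aggregate_replicates(estimates: Sequence[GasEstimate]) -> ConfigSummary:
    """Mean/SD pathlength and O2 over the non-outlier, valid replicates.

    Sample standard deviation (n-1 denominator); a configuration whose
    replicates are all outliers yields an explicitly empty summary rather
    than propagating NaNs.
    """
    ids = {e.config_id for e in estimates}
    if len(ids) != 1:
        raise ValueError("all estimates must share one config_id")
    (config_id,) = ids
    kept = [e for e in estimates if not e.outlier and e.valid]
    n_total = len(estimates)
    n_outliers = n_total - len(kept)
    if not kept:
        return ConfigSummary(config_id, n_total, n_outliers, None, None, None, None)
    lengths = np.array([e.pathlength for e in kept])
    o2 = np.array([e.o2_fraction for e in kept])
    o2 = o2[np.isfinite(o2)]
    sd = float(np.std(lengths, ddof=1)) if len(lengths) > 1 else 0.0
    mean_o2 = float(np.mean(o2)) if len(o2) else None
    sd_o2 = float(np.std(o2, ddof=1)) if len(o2) > 1 else (0.0 if len(o2) else None)
    return ConfigSummary(
        config_id,
        n_total,
        n_outliers,
        float(np.mean(lengths)),
        sd,
        mean_o2,
        sd_o2,
    )


def _ks_statistic_numerator(x: np.ndarray, y: np.ndarray) -> int:
    """max over pooled points of |n2*F1 - n1*F2| * 1 (integer units).

    Returns the integer numerator h with D = h / (n1*n2); exact arithmetic
    avoids float ties in the exact-p path counting.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    labels = np.concatenate([np.ones(n1, dtype=np.int64), np.zeros(n2, dtype=np.int64)])
    order = np.argsort(pooled, kind="mergesort")
    pooled, labels = pooled[order], labels[order]
    # counts of x (resp. y) at or below each pooled point
    cx = np.cumsum(labels)
    cy = np.cumsum(1 - labels)
    # evaluate only at the last index of each tied block
    last = np.r_[pooled[1:] != pooled[:-1], True]
    dev = np.abs(cx * n2 - cy * n1)[last]
    return int(dev.max())


def _exact_p_value(h: int, n1: int, n2: int) -> float:
    """P(D >= h/(n1*n2)) under H0 by lattice-path counting (no ties).

    Counts orderings whose ECDF path always stays strictly inside the band
    |i*n2 - j*n1| < h; the complement probability is the exact two-sided p.
    """
    if h <= 0:
        return 1.0
    # paths[j] = number of admissible paths to (i, j), rolled over i
    paths = [0.0] * (n2 + 1)
    paths[0] = 1.0
    total = math.comb(n1 + n2, n1)
    for j in range(1, n2 + 1):
        paths[j] = paths[j - 1] if abs(0 * n2 - j * n1) < h else 0.0
    for i in range(1, n1 + 1):
        row = [0.0] * (n2 + 1)
        row[0] = paths[0] if abs(i * n2) < h else 0.0
        for j in range(1, n2 + 1):
            if abs(i * n2 - j * n1) < h:
                row[j] = row[j - 1] + paths[j]
        paths = row
    return min(1.0, max(0.0, 1.0 - paths[n2] / total))


def _asymptotic_p_value(d: float, n1: int, n2: int) -> float:
    """Kolmogorov series with the Stephens finite-sample correction."""
    if d <= 0.0:
        return 1.0
    n_e = n1 * n2 / (n1 + n2)
    lam = (math.sqrt(n_e) + 0.12 + 0.11 / math.sqrt(n_e)) * d
    total = 0.0
    for k in range(1, 101):
        term = (-1.0) ** (k - 1) * math.exp(-2.0 * k * k * lam * lam)
        total += term
        if abs(term) < 1e-10:
            break
    return min(1.0, max(0.0, 2.0 * total))


def ks_two_sample(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> KsResult:
    """Two-sample Kolmogorov-Smirnov test, implemented from scratch.

    D is the supremum distance between the two empirical CDFs, evaluated in
    exact integer arithmetic over the pooled sample. ``method``:

    - ``"exact"``: permutation-null p by lattice-path counting (requires
      tie-free data);
    - ``"asymp"``: Kolmogorov series with Stephens' correction;
    - ``"auto"`` (default): exact when both samples are small
      (max n <= 16) and tie-free, asymptotic otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    h = _ks_statistic_numerator(x, y)
    d = h / (n1 * n2)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    if method == "auto":
        method = "exact" if (max(n1, n2) <= EXACT_MAX_N and not has_ties) else "asymp"
    if method == "exact":
        if has_ties:
            raise ValueError("exact p-value requires tie-free data")
        p = _exact_p_value(h, n1, n2)
    elif method == "asymp":
        p = _asymptotic_p_value(d, n1, n2)
    else:
        raise ValueError(f"unknown method {method!r}")
    return KsResult(
        d_statistic=d, p_value=p, n1=n1, n2=n2, comparable=p > 0.05, method=method
    )


def compare_configurations(
    samples: Mapping[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]],
    method: str = "asymp",
) -> list[tuple[str, str, KsResult]]:
    """Run KS comparisons over a caller-specified pairing scheme.

    ``samples`` maps group keys (e.g. ``config_id`` or ``config_id@conc``)
    to pathlength samples; ``pairs`` names which groups to compare. No
    multiple-testing correction is applied by default (use
    :func:`holm_adjust` on the returned p-values if desired).
    """
    results = []
    for key1, key2 in pairs:
        if key1 not in samples or key2 not in samples:
            raise KeyError(f"unknown pairing key in ({key1!r}, {key2!r})")
        results.append((key1, key2, ks_two_sample(samples[key1], samples[key2], method)))
    return results


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional multiplicity control)."""
    m = len(p_values)
    order = np.argsort(p_values)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_values[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def concentration_boxes(
    estimates: Iterable[GasEstimate],
    use_percent: bool = True,
    include_outliers: bool = False,
) -> list[BoxSummary]:
    """Box statistics of estimated O2 concentration per nominal gas batch.

    Quartiles use linear interpolation between order statistics (the type-7
    convention); whiskers extend to the extreme data points within 1.5 IQR
    of the quartiles, and points beyond the fences are listed individually.
    """
    groups: dict[float, list[float]] = {}
    for est in estimates:
        if not est.valid or (est.outlier and not include_outliers):
            continue
        if not np.isfinite(est.o2_fraction):
            continue
        scale = 100.0 if use_percent else 1.0
        groups.setdefault(est.o2_nominal * scale, []).append(est.o2_fraction * scale)
    boxes = []
    for label in sorted(groups):
        values = np.asarray(groups[label])
        q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = values[(values >= lo_fence) & (values <= hi_fence)]
        fliers = values[(values < lo_fence) | (values > hi_fence)]
        boxes.append(
            BoxSummary(
                label=float(label),
                median=float(med),
                q1=float(q1),
                q3=float(q3),
                whisker_low=float(inside.min()),
                whisker_high=float(inside.max()),
                outlier_values=tuple(sorted(float(v) for v in fliers)),
            )
        )
    return boxes
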