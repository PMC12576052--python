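"""Region-level methylation summaries and interval plumbing.

Two trimming rules are provided:

* ``range_trim`` — average only values inside [median − v, median + v],
  where v is by default the sample variance of the values (a standard-
  deviation half-width is available via ``spread='std'``).  Used for
  CpG-island-style summaries.
* ``tail_trim``  — drop floor(tail_fraction · n) values from each end of the
  sorted list, then report mean and sample variance of the rest.  Used for
  imprinting-control-region-style summaries (default 5% per tail).
"""

from __future__ import annotations

import numpy as np

from .errors import NoDataError
from .records import MethylationRecord, Region, RegionSummary


def range_trimmed_mean(
    levels, spread: str = "variance"
) -> tuple[float, int]:
    """Mean of values within [median − v, median + v]; returns (mean, n_used).

    v is the sample variance of the values (``spread='variance'``) or their
    sample standard deviation (``spread='std'``).  A singleton is returned
    unchanged.  The band always contains the median, so at least one value
    survives.
    """
    vals = np.asarray(levels, dtype=float)
    if vals.size == 0:
        raise NoDataError("range_trimmed_mean of an empty collection")
    if vals.size == 1:
        return float(vals[0]), 1
    m = float(np.median(vals))
    v = float(np.var(vals, ddof=1))
    if spread == "std":
        v = float(np.sqrt(v))
    elif spread != "variance":
        raise ValueError(f"spread must be 'variance' or 'std', got {spread!r}")
    keep = vals[(vals >= m - v) & (vals <= m + v)]
    return float(keep.mean()), int(keep.size)


def tail_trimmed_stats(
    values, tail_fraction: float = 0.05
) -> tuple[float, float, int]:
    """Mean/variance after dropping floor(f·n) values from each sorted end.

    Returns (mean, sample variance, n_used); variance is 0.0 when fewer than
    two values remain.  Ties are broken by stable sort on value order.
    """
    if not (0.0 <= tail_fraction < 0.5):
        raise ValueError(
            f"tail_fraction must be in [0, 0.5), got {tail_fraction}"
        )
    vals = np.sort(np.asarray(values, dtype=float), kind="stable")
    if vals.size == 0:
        raise NoDataError("tail_trimmed_stats of an empty collection")
    k = int(np.floor(tail_fraction * vals.size))
    keep = vals[k: vals.size - k]
    var = float(np.var(keep, ddof=1)) if keep.size >= 2 else 0.0
    return float(keep.mean()), var, int(keep.size)


def summarize_regions(
    records: list[MethylationRecord],
    regions: list[Region],
    method: str = "range_trim",
    tail_fraction: float = 0.05,
    spread: str = "variance",
) -> list[RegionSummary]:
    """Trimmed-mean methylation per region.

    ``records`` should already be strand-averaged (one record per CpG site);
    a record belongs to a region when its C position falls in the half-open
    interval [start, end).
    """
    if method not in ("range_trim", "tail_trim"):
        raise ValueError(f"unknown trimming method {method!r}")
    out = []
    for region in regions:
        levels = [
            r.level
            for r in records
            if r.chrom == region.chrom and region.contains(r.start)
        ]
        n_total = len(levels)
        if n_total == 0:
            out.append(
                RegionSummary(region, 0, 0, float("nan"), method)
            )
            continue
        if method == "range_trim":
            mean, n_used = range_trimmed_mean(levels, spread=spread)
            var = float("nan")
        else:
            mean, var, n_used = tail_trimmed_stats(levels, tail_fraction)
        out.append(
            RegionSummary(region, n_total, n_used, mean, method, var)
        )
    return out


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent sorted half-open intervals."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def intersect_regions(
    a: list[Region], b: list[Region]
) -> list[Region]:
    """Pairwise interval intersections, merged per chromosome and sorted."""
    by_chrom_a: dict[str, list[tuple[int, int]]] = {}
    by_chrom_b: dict[str, list[tuple[int, int]]] = {}
    for reg in a:
        by_chrom_a.setdefault(reg.chrom, []).append((reg.start, reg.end))
    for reg in b:
        by_chrom_b.setdefault(reg.chrom, []).append((reg.start, reg.end))
    out: list[Region] = []
    for chrom in sorted(set(by_chrom_a) & set(by_chrom_b)):
        left = _merge(by_chrom_a[chrom])
        right = _merge(by_chrom_b[chrom])
        i = j = 0
        while i < len(left) and j < len(right):
            start = max(left[i][0], right[j][0])
            end = min(left[i][1], right[j][1])
            if start < end:
                out.append(Region(chrom, start, end))
            if left[i][1] <= right[j][1]:
                i += 1
            else:
                j += 1
    return out
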