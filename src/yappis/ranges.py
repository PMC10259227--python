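"""Outlier removal and decomposition of score distributions into domains.

Patch score distributions are cleaned with the Tukey interquartile-range
rule and then partitioned into contiguous bins ("domains") whose width is
set by Scott's rule, 3.49·s·n^(-1/3).  The resulting :class:`DomainSet`
tiles the retained score range; bins are half-open ``[lo, hi)`` with the
last bin closed at the top, so every retained value belongs to exactly one
domain.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np


def remove_outliers_iqr(values: Sequence[float], k: float = 1.5) -> list[float]:
    """Keep values within [Q1 - k·IQR, Q3 + k·IQR] (linear-interpolated
    quartiles, single pass).  Requires at least 4 observations."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 4:
        raise ValueError("too few observations (need >= 4)")
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return [float(v) for v in arr[(arr >= lo) & (arr <= hi)]]


def scott_bin_width(values: Sequence[float]) -> float:
    """Scott's-rule histogram width 3.49·s·n^(-1/3) (s = sample std)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 values")
    s = float(np.std(arr, ddof=1))
    if s == 0.0:
        raise ValueError("degenerate distribution (zero variance)")
    return 3.49 * s * arr.size ** (-1.0 / 3.0)


@dataclass(frozen=True)
class DomainSet:
    """Contiguous equal-width score bins spanning a retained score range."""

    scale_name: str
    bin_edges: tuple[float, ...]

    def __post_init__(self) -> None:
        edges = self.bin_edges
        if len(edges) < 2:
            raise ValueError("need at least 2 edges")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def bins(self) -> list[tuple[float, float]]:
        return list(zip(self.bin_edges, self.bin_edges[1:]))

    def bin_index(self, value: float) -> int | None:
        """Index of the domain containing *value*; None when outside the
        tiled range.  Bins are [lo, hi), last bin [lo, hi]."""
        edges = self.bin_edges
        if value < edges[0] or value > edges[-1]:
            return None
        if value == edges[-1]:
            return self.n_bins - 1
        return int(np.searchsorted(edges, value, side="right")) - 1

    def interval(self, index: int) -> tuple[float, float]:
        return (self.bin_edges[index], self.bin_edges[index + 1])

    def to_json(self) -> str:
        return json.dumps(
            {"scale_name": self.scale_name, "bin_edges": list(self.bin_edges)},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "DomainSet":
        obj = json.loads(text)
        return cls(obj["scale_name"], tuple(obj["bin_edges"]))


def make_domains(values: Sequence[float], scale_name: str = "") -> DomainSet:
    """Partition [min, max] of already outlier-filtered values into Scott-
    width bins; the final partial bin is extended past max if needed."""
    arr = np.asarray(list(values), dtype=float)
    width = scott_bin_width(arr)
    lo, hi = float(arr.min()), float(arr.max())
    n_bins = max(1, math.ceil((hi - lo) / width - 1e-12))
    edges = tuple(lo + width * i for i in range(n_bins)) + (max(lo + width * n_bins, hi),)
    return DomainSet(scale_name, edges)
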