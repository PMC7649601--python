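"""Brace-root contribution to anchorage from a whorl-removal series.

With slopes keyed by test label (``A`` = all whorls intact, the last
label = all soil-entering whorls excised):

* ``ratio = slope(last) / slope(A)`` — relative contribution; lower
  means brace roots contribute more.
* ``difference = slope(A) - slope(last)`` — absolute contribution (N/m);
  may legitimately be negative when technical variation puts a later
  measurement above ``A``.
* per-whorl ratios, Whorl 1 = closest to the soil: for labels A..D,
  ``whorl1 = D/C``, ``whorl2 = C/B``, ``whorl3 = B/A``. Their product
  telescopes to the overall ratio.

The beam-length correction addresses a competing explanation: excising
brace roots moves the effective anchorage point from the attachment
height ``a`` down to the soil, lengthening the cantilever from ``h - a``
to ``h``. For a tip-loaded cantilever the force-deflection slope scales
as 1/L^3, so if removal changed *only* the beam length the observed
ratio would equal ``((h - a)/h)^3``. Dividing the observed ratio by this
geometric null re-expresses it so that pure beam lengthening maps to 1;
values below 1 indicate anchorage loss beyond geometry.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ContiguityError, DomainError, GeometryError

__all__ = [
    "BeamGeometry",
    "ContributionResult",
    "contribution_ratio",
    "contribution_difference",
    "whorl_ratios",
    "beam_corrected_ratio",
    "contribution_result",
    "contribution_table",
]


@dataclass(frozen=True)
class BeamGeometry:
    """Cantilever geometry: load height ``h`` and whorl attachment height ``a``."""

    load_height_m: float
    attachment_height_m: float

    def __post_init__(self):
        if not self.load_height_m > 0:
            raise GeometryError(f"load height must be > 0, got {self.load_height_m}")
        if not 0 <= self.attachment_height_m < self.load_height_m:
            raise GeometryError(
                f"need 0 <= attachment height < load height, got "
                f"a={self.attachment_height_m}, h={self.load_height_m}"
            )

    @property
    def length_ratio_cubed(self) -> float:
        """((h - a)/h)^3, the pure-geometry slope ratio for whorl removal."""
        return ((self.load_height_m - self.attachment_height_m) / self.load_height_m) ** 3


@dataclass(frozen=True)
class ContributionResult:
    """Contribution statistics for one plant's removal series."""

    plant_id: str
    ratio: float
    difference: float
    whorl_ratios: tuple[float, ...]
    corrected_ratio: float | None = None


def _ordered_slopes(series: Mapping[str, float]) -> list[float]:
    """Slopes ordered A, B, C, ... after checking label contiguity."""
    labels = sorted(series)
    expected = list(string.ascii_uppercase[: len(labels)])
    if labels != expected:
        raise ContiguityError(f"labels {labels} are not contiguous from 'A'")
    if not labels:
        raise ContiguityError("empty series")
    return [float(series[lab]) for lab in labels]


def contribution_ratio(series: Mapping[str, float]) -> float:
    """slope(last)/slope(A); 1.0 for a single-label series (no whorls in soil)."""
    slopes = _ordered_slopes(series)
    if slopes[0] <= 0:
        raise DomainError(f"slope(A) must be > 0, got {slopes[0]}")
    return slopes[-1] / slopes[0]


def contribution_difference(series: Mapping[str, float]) -> float:
    """slope(A) - slope(last), in N/m; 0.0 for a single-label series."""
    slopes = _ordered_slopes(series)
    return slopes[0] - slopes[-1]


def whorl_ratios(series: Mapping[str, float]) -> tuple[float, ...]:
    """Adjacent-label ratios ordered from the soil-closest whorl upward.

    For labels A..D returns (D/C, C/B, B/A). Empty for a single label.
    """
    slopes = _ordered_slopes(series)
    if any(s <= 0 for s in slopes[:-1]):
        raise DomainError("intermediate slopes must be > 0 for whorl ratios")
    return tuple(slopes[i + 1] / slopes[i] for i in range(len(slopes) - 2, -1, -1))


def beam_corrected_ratio(
    ratio: float,
    geometry: BeamGeometry,
    direction: str = "divide",
) -> float:
    """Remove the pure beam-lengthening effect from a contribution ratio.

    With ``direction="divide"`` (default) the corrected ratio is
    ``ratio / ((h - a)/h)^3``: a removal that only lengthened the beam
    maps exactly to 1, and ``a = 0`` leaves the ratio unchanged. The
    alternative reading ``direction="multiply"`` is provided because the
    sign convention of such corrections is not universal; only the
    null-maps-to-1 property anchors the default.
    """
    if not ratio > 0:
        raise DomainError(f"ratio must be > 0, got {ratio}")
    if direction not in ("divide", "multiply"):
        raise ValueError("direction must be 'divide' or 'multiply'")
    g = geometry.length_ratio_cubed
    return ratio / g if direction == "divide" else ratio * g


def contribution_result(
    plant_id: str,
    series: Mapping[str, float],
    geometry: BeamGeometry | None = None,
    direction: str = "divide",
) -> ContributionResult:
    """Bundle ratio, difference, per-whorl ratios and optional correction."""
    ratio = contribution_ratio(series)
    corrected = None if geometry is None else beam_corrected_ratio(ratio, geometry, direction)
    wr = whorl_ratios(series) if len(series) >= 2 else ()
    return ContributionResult(plant_id, ratio, contribution_difference(series), wr, corrected)


def contribution_table(results, plants=None) -> pd.DataFrame:
    """Tabulate ContributionResults (one row per plant) for CSV export."""
    plants = {p.plant_id: p for p in plants} if plants else {}
    max_w = max((len(r.whorl_ratios) for r in results), default=0)
    rows = []
    for r in results:
        rec = plants.get(r.plant_id)
        row = {
            "plant_id": r.plant_id,
            "plot_id": rec.plot_id if rec else "",
            "whorls_in_soil": rec.whorls_in_soil if rec else len(r.whorl_ratios),
            "ratio": r.ratio,
            "difference": r.difference,
        }
        for k in range(max_w):
            row[f"whorl{k + 1}"] = r.whorl_ratios[k] if k < len(r.whorl_ratios) else math.nan
        row["corrected_ratio"] = math.nan if r.corrected_ratio is None else r.corrected_ratio
        rows.append(row)
    return pd.DataFrame(rows)
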