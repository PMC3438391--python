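"""Geographic clines and empirical outlier tests.

Serial founder effects during the out-of-Africa expansion leave allele
frequencies correlated with distance from East Africa.  This module computes
great-circle distances from Addis Ababa (9N, 38E), Pearson correlations of
locus frequencies with those distances, and empirical p-values that rank an
observed statistic within a genome-wide background distribution of the same
statistic -- the standard device for separating locus-specific signals from
shared demographic history, since the study populations are not independent
draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .kir_data import StudyPanel

#: Mean Earth radius, km (IUGG).
EARTH_RADIUS_KM = 6371.0088

#: The reference point for distance-from-Africa: Addis Ababa, Ethiopia.
ADDIS_ABABA: "GeoPoint"


@dataclass(frozen=True)
class GeoPoint:
    """Latitude/longitude in degrees; south and west negative."""

    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if abs(self.latitude) > 90 or abs(self.longitude) > 180:
            raise ValueError(f"invalid coordinates {self}")


ADDIS_ABABA = GeoPoint(9.0, 38.0)


@dataclass(frozen=True)
class BackgroundDistribution:
    """Per-marker background statistics (one value per genome-wide marker)."""

    statistics: tuple[float, ...]
    statistic_kind: str = "correlation"

    def __post_init__(self) -> None:
        if not self.statistics:
            raise ValueError("background distribution may not be empty")

    def __len__(self) -> int:
        return len(self.statistics)


@dataclass(frozen=True)
class ClineResult:
    """A frequency-vs-distance cline: Pearson r and its empirical p-value."""

    r: float
    p_emp: float | None
    n_populations: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| > 1")


def great_circle_km(a: GeoPoint, b: GeoPoint) -> float:
    """Haversine great-circle distance in kilometres."""
    la1, lo1 = math.radians(a.latitude), math.radians(a.longitude)
    la2, lo2 = math.radians(b.latitude), math.radians(b.longitude)
    h = (math.sin((la2 - la1) / 2.0) ** 2
         + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2.0) ** 2)
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def distance_from_africa(panel: StudyPanel) -> dict[str, float]:
    """Great-circle distance (km) from Addis Ababa to each population."""
    out = {}
    for pop in panel:
        if math.isnan(pop.latitude) or math.isnan(pop.longitude):
            raise ValueError(f"population {pop.name!r} has unresolved coordinates")
        out[pop.name] = great_circle_km(
            ADDIS_ABABA, GeoPoint(pop.latitude, pop.longitude))
    return out


def distances_from_africa(latitudes, longitudes) -> np.ndarray:
    """Vectorised distance-from-Addis-Ababa for coordinate arrays."""
    return np.array([
        great_circle_km(ADDIS_ABABA, GeoPoint(float(la), float(lo)))
        for la, lo in zip(latitudes, longitudes)])


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation; errors on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def empirical_p_abs(observed: float, bg: BackgroundDistribution) -> float:
    """Proportion of background statistics strictly greater in |.| than observed.

    Ties (|b| == |observed|) do not count as greater.  Monotone non-increasing
    in |observed|; 0 when the observed statistic exceeds the whole background.
    """
    b = np.abs(np.asarray(bg.statistics, dtype=float))
    return float((b > abs(observed)).sum() / len(bg))


def empirical_p_two_tailed(
    observed: float, bg: BackgroundDistribution, doubled: bool = True
) -> float:
    """Two-tailed empirical p of ``observed`` within the background.

    With the default doubling rule, ``p = 2 * min(#{b >= obs}, #{b <= obs}) / N``
    capped at 1.  ``doubled=False`` returns the one-sided smaller-tail
    proportion instead (the rule is stated ambiguously in the field; both are
    exposed).
    """
    b = np.asarray(bg.statistics, dtype=float)
    upper = int((b >= observed).sum())
    lower = int((b <= observed).sum())
    tail = min(upper, lower) / len(bg)
    return float(min(1.0, 2.0 * tail)) if doubled else float(tail)


def cline_correlation(
    frequencies: Mapping[str, float] | Sequence[float],
    distances_km: Mapping[str, float] | Sequence[float],
    background: BackgroundDistribution | None = None,
) -> ClineResult:
    """Correlate per-population frequencies with distance from Africa.

    Mappings are aligned by population name; sequences positionally.  If a
    ``background`` of per-marker correlations is given, the |r|-based
    empirical p-value is attached.
    """
    if isinstance(frequencies, Mapping):
        if not isinstance(distances_km, Mapping):
            raise TypeError("both or neither argument must be mappings")
        names = sorted(frequencies)
        if set(names) != set(distances_km):
            raise ValueError("population sets differ")
        x = [distances_km[k] for k in names]
        y = [frequencies[k] for k in names]
    else:
        x, y = list(distances_km), list(frequencies)
    r = pearson_r(x, y)
    p = empirical_p_abs(r, background) if background is not None else None
    return ClineResult(r=r, p_emp=p, n_populations=len(x))
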