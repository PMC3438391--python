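"""Synthetic panels with the statistical structure the analyses assume.

Three generators make every stage testable without external downloads:

* :func:`simulate_panel` -- Hardy-Weinberg diploid sampling from specified
  per-population haplotype frequencies (random union of gametes, the model
  the EM estimator inverts);
* :func:`simulate_background` -- hierarchically drifted biallelic marker
  frequencies in the Balding-Nichols style (a Beta distribution with mean
  ``p0`` and variance ``F p0 (1 - p0)`` at each level), standing in for a
  genome-wide SNP background;
* :func:`simulate_cline` -- a linear frequency gradient in distance from
  Africa with Gaussian noise, clamped to [0, 1].

All randomness flows through one seeded generator per call; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geography_selection import distances_from_africa
from .kir_data import (
    AprioriHaplotypeSet,
    PopulationSample,
    StudyPanel,
    genotype_from_pair,
)

__all__ = [
    "PopulationSpec", "DriftModelSpec",
    "simulate_panel", "simulate_background", "simulate_cline",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Blueprint for one simulated population."""

    name: str
    region: str
    latitude: float
    longitude: float
    n: int
    haplotype_frequencies: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        total = sum(self.haplotype_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")


@dataclass(frozen=True)
class DriftModelSpec:
    """Two-level Balding-Nichols drift model for background markers."""

    ancestral_frequency: float = 0.5
    region_divergence: float = 0.09
    population_divergence: float = 0.02
    n_markers: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.ancestral_frequency < 1.0:
            raise ValueError("ancestral_frequency must be in (0, 1)")
        for f in (self.region_divergence, self.population_divergence):
            if not 0.0 < f < 1.0:
                raise ValueError("divergence parameters must be in (0, 1)")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")


def simulate_panel(
    specs: Sequence[PopulationSpec],
    H: AprioriHaplotypeSet,
    seed: int = 0,
) -> StudyPanel:
    """Draw a diploid panel under HWE from per-population haplotype frequencies.

    Each individual receives two haplotypes i.i.d. from the population's
    frequency vector; the observable genotype is their marker-set union.
    Fully reproducible for a given seed.
    """
    He = H.expand()
    index = {h.name: h for h in He}
    rng = np.random.default_rng(seed)
    pops = []
    for spec in specs:
        names = list(spec.haplotype_frequencies)
        missing = [nm for nm in names if nm not in index]
        if missing:
            raise KeyError(f"haplotypes not in the a priori set: {missing}")
        probs = np.array([spec.haplotype_frequencies[nm] for nm in names])
        draws = rng.choice(len(names), size=(spec.n, 2), p=probs)
        genotypes = tuple(
            genotype_from_pair(
                index[names[i]], index[names[j]],
                individual_id=f"{spec.name}-{k:04d}")
            for k, (i, j) in enumerate(draws))
        pops.append(PopulationSample(
            spec.name, spec.region, spec.latitude, spec.longitude, genotypes))
    return StudyPanel(tuple(pops))


def _balding_nichols(rng, mean: float, F: float, size) -> np.ndarray:
    mean = np.clip(mean, 1e-9, 1 - 1e-9)
    a = mean * (1.0 - F) / F
    b = (1.0 - mean) * (1.0 - F) / F
    return rng.beta(a, b, size=size)


def simulate_background(
    spec: DriftModelSpec,
    regions: Sequence[str],
) -> pd.DataFrame:
    """Hierarchically drifted per-population marker frequency matrix.

    ``regions`` gives the region label of each population (one entry per
    population, repeated labels allowed).  Per marker, each region's
    frequency drifts from the ancestral value with divergence ``F_r``, and
    each population's from its region value with ``F_p``.  Returns a
    populations x markers DataFrame of frequencies from which callers compute
    per-marker statistics (correlations with distance, FST components, ...).
    """
    rng = np.random.default_rng(spec.seed)
    region_names = list(dict.fromkeys(regions))
    out = np.empty((len(regions), spec.n_markers))
    region_freqs = {
        r: _balding_nichols(
            rng, spec.ancestral_frequency, spec.region_divergence,
            spec.n_markers)
        for r in region_names}
    for i, r in enumerate(regions):
        out[i] = np.array([
            _balding_nichols(rng, m, spec.population_divergence, None)
            for m in region_freqs[r]])
    return pd.DataFrame(
        out, index=[f"pop{i:02d}" for i in range(len(regions))],
        columns=[f"m{j:04d}" for j in range(spec.n_markers)])


def simulate_cline(
    latitudes: Sequence[float],
    longitudes: Sequence[float],
    intercept: float = 0.1,
    slope: float = 3e-5,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Linear frequency-vs-distance cline with Gaussian noise, clamped to [0,1].

    ``slope`` is frequency per km of great-circle distance from Addis Ababa.
    """
    rng = np.random.default_rng(seed)
    d = distances_from_africa(latitudes, longitudes)
    f = intercept + slope * d + rng.normal(0.0, noise_sd, size=len(d))
    return np.clip(f, 0.0, 1.0)
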