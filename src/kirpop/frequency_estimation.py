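"""Carrier and gene (allelic) frequency estimation for presence/absence loci.

Most KIR markers behave like dominant markers: typing only reveals whether a
locus is present on at least one chromosome.  The carrier frequency is a
direct count, while the chromosome-level gene frequency must be inferred.
Under Hardy-Weinberg equilibrium the fraction of non-carriers equals the
squared frequency of the null (locus-absent) haplotype class, giving the
square-root estimator of Lynch and Milligan; their small-sample Taylor
correction is available as an option.

Two loci are effectively biallelic presence markers -- KIR2DL2L3 (alleles
KIR2DL2 / KIR2DL3) marks the centromeric motifs and KIR3DL1S1 (KIR3DL1 /
KIR3DS1) the telomeric ones -- and support direct genotype-level counting:
an individual carrying only allele A is scored AA, only B is BB, and both
is AB.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .kir_data import KIR_LOCI, PopulationSample, StudyPanel

logger = logging.getLogger(__name__)

#: The two biallelic presence loci: name -> (allele A marker, allele B marker).
BIALLELIC_LOCI: dict[str, tuple[str, str]] = {
    "2DL2L3": ("2DL2", "2DL3"),
    "3DL1S1": ("3DL1", "3DS1"),
}


class DoubleNegativeError(ValueError):
    """Individuals carrying neither allele of a biallelic presence locus."""

    def __init__(self, count: int):
        self.count = count
        super().__init__(
            f"{count} individual(s) carry neither allele; exclude or reassign "
            "them before direct counting")


@dataclass(frozen=True)
class BiallelicLocusSpec:
    """A locus whose two alleles are typed as separate presence markers."""

    locus_name: str
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError("alleles must differ")
        for a in (self.allele_a, self.allele_b):
            if a not in KIR_LOCI:
                raise ValueError(f"unknown marker {a!r}")


def carrier_frequency(pop: PopulationSample, locus: str) -> float:
    """Fraction k/n of individuals in whom ``locus`` is present."""
    k = sum(1 for g in pop.genotypes if g.has(locus))
    return k / pop.n


def gene_frequency_sqrt(k_carriers: int, n: int, bias_corrected: bool = False) -> float:
    """Gene frequency of a dominant presence marker from carrier counts.

    With ``x = (n - k)/n`` the fraction of null homozygotes, the estimator is
    ``p = 1 - sqrt(x)``.  ``bias_corrected`` applies the Lynch-Milligan
    small-sample correction to the null-allele estimate,
    ``q = sqrt(x) / (1 - Var(x) / (8 x^2))`` with ``Var(x) = x (1 - x) / n``,
    which counteracts the downward bias of the plain square root.  Computed
    from integer counts, never from rounded frequencies.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k_carriers <= n:
        raise ValueError(f"k={k_carriers} outside [0, {n}]")
    x = (n - k_carriers) / n
    if x == 0.0:
        return 1.0
    q = math.sqrt(x)
    if bias_corrected:
        var = x * (1.0 - x) / n
        q = q / (1.0 - var / (8.0 * x * x))
    return min(max(1.0 - q, 0.0), 1.0)


def biallelic_direct_frequency(kA: int, kB: int, n: int) -> tuple[float, float]:
    """Allele frequencies of a biallelic presence locus by direct counting.

    Assuming every chromosome carries one of the two alleles, the ``n - kB``
    A-only carriers are AA homozygotes, the ``n - kA`` B-only carriers BB, and
    the remaining ``kA + kB - n`` heterozygotes, so
    ``pA = (n + kA - kB) / 2n``.  Individuals carrying neither allele violate
    the assumption and raise :class:`DoubleNegativeError` with their count;
    the caller decides whether to exclude them (see
    :func:`biallelic_frequency_excluding_negatives`).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= kA <= n and 0 <= kB <= n):
        raise ValueError("allele carrier counts outside [0, n]")
    if kA + kB < n:
        raise DoubleNegativeError(n - kA - kB)
    pA = (n + kA - kB) / (2 * n)
    return pA, 1.0 - pA


def biallelic_frequency_excluding_negatives(
    kA: int, kB: int, n: int
) -> tuple[float, float]:
    """Direct counting with double-negative individuals excluded.

    The rare individuals carrying neither allele (deletion homozygotes at
    KIR3DL1S1) are dropped from the denominator with a logged warning; the
    remaining sample is counted as in :func:`biallelic_direct_frequency`.
    """
    excess = n - kA - kB
    if excess > 0:
        logger.warning(
            "excluding %d double-negative individual(s) from direct count", excess)
        n -= excess
    return biallelic_direct_frequency(kA, kB, n)


def _population_biallelic(pop: PopulationSample, allele_a: str, allele_b: str):
    kA = sum(1 for g in pop.genotypes if g.has(allele_a))
    kB = sum(1 for g in pop.genotypes if g.has(allele_b))
    return biallelic_frequency_excluding_negatives(kA, kB, pop.n)


def frequency_table(
    panel: StudyPanel,
    kind: str = "carrier",
    loci: Sequence[str] | None = None,
    bias_corrected: bool = False,
) -> pd.DataFrame:
    """Population x locus frequency table of the requested kind.

    ``kind="carrier"`` counts carriers directly; ``kind="gene"`` applies the
    square-root estimator to each locus's carrier count (with the
    Lynch-Milligan correction if ``bias_corrected``); ``kind="allele"``
    direct-counts the biallelic loci (``loci`` then names entries of
    :data:`BIALLELIC_LOCI`) and returns one column per allele, summing to 1
    per locus per population.  Values are unrounded; use
    :func:`present_3dp` for the 3-decimal presentation used in published
    tables.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    if kind in ("carrier", "gene"):
        loci = list(loci) if loci is not None else list(KIR_LOCI)
        rows = {}
        for pop in panel:
            vals = []
            for locus in loci:
                k = sum(1 for g in pop.genotypes if g.has(locus))
                if kind == "carrier":
                    vals.append(k / pop.n)
                else:
                    vals.append(gene_frequency_sqrt(k, pop.n, bias_corrected))
            rows[pop.name] = vals
        out = pd.DataFrame.from_dict(rows, orient="index", columns=loci)
    elif kind == "allele":
        names = list(loci) if loci is not None else list(BIALLELIC_LOCI)
        rows = {}
        cols = []
        for ln in names:
            a, b = BIALLELIC_LOCI[ln]
            cols += [f"{ln}:{a}", f"{ln}:{b}"]
        for pop in panel:
            vals = []
            for ln in names:
                a, b = BIALLELIC_LOCI[ln]
                pA, pB = _population_biallelic(pop, a, b)
                vals += [pA, pB]
            rows[pop.name] = vals
        out = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    out.index.name = "population"
    out.attrs["kind"] = kind
    out.attrs["n"] = {pop.name: pop.n for pop in panel}
    return out


def present_3dp(table: pd.DataFrame) -> pd.DataFrame:
    """Half-up rounding to 3 decimals, matching published presentation."""
    return table.map(lambda v: math.floor(v * 1000 + 0.5) / 1000)


def back_compute_count(frequency: float, n: int) -> int:
    """Recover an integer carrier count from a printed frequency, k = round(f*n)."""
    return int(round(frequency * n))


def sqrt_estimator_sweep(
    carriers: pd.DataFrame,
    genes: pd.DataFrame,
    n: pd.Series,
    decimals: int = 3,
    count_slack: int = 1,
) -> pd.DataFrame:
    """Check the square-root estimator against a published frequency table.

    For every population x locus cell the carrier count is back-computed as
    ``k = round(carrier * n)`` and the estimator's output compared with the
    printed gene frequency at ``decimals`` places.  Where the printed carrier
    frequency is consistent with more than one count (rounding ambiguity),
    counts within ``count_slack`` of k are also accepted.  Returns a boolean
    population x locus match matrix.
    """
    match = pd.DataFrame(False, index=carriers.index, columns=carriers.columns)
    for pop in carriers.index:
        npop = int(n[pop])
        for locus in carriers.columns:
            cf = float(carriers.at[pop, locus])
            printed = round(float(genes.at[pop, locus]), decimals)
            k = back_compute_count(cf, npop)
            ok = round(gene_frequency_sqrt(k, npop), decimals) == printed
            if not ok and count_slack:
                for kk in range(max(0, k - count_slack),
                                min(npop, k + count_slack) + 1):
                    if (round(kk / npop, decimals) == round(cf, decimals)
                            and round(gene_frequency_sqrt(kk, npop),
                                      decimals) == printed):
                        ok = True
                        break
            match.at[pop, locus] = ok
    return match


def allele_frequencies_from_carriers(
    carriers: pd.DataFrame,
    n: pd.Series,
    locus: str = "3DL1S1",
) -> pd.DataFrame:
    """Biallelic direct-count allele frequencies from a carrier-frequency table.

    Carrier counts for the locus's two allele markers are back-computed from
    the table (``k = round(cf * n)``) and direct-counted per population, with
    double-negative individuals excluded.  Returns a population x 2 DataFrame
    (columns = the allele marker names) whose rows sum to 1.
    """
    a, b = BIALLELIC_LOCI[locus]
    rows = {}
    for pop in carriers.index:
        npop = int(n[pop])
        kA = back_compute_count(float(carriers.at[pop, a]), npop)
        kB = back_compute_count(float(carriers.at[pop, b]), npop)
        rows[pop] = biallelic_frequency_excluding_negatives(kA, kB, npop)
    return pd.DataFrame.from_dict(rows, orient="index", columns=[a, b])
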