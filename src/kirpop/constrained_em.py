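"""Constrained EM estimation of gene-content haplotype frequencies.

Presence/absence genotypes are unphased: a profile is consistent with any
unordered pair of haplotypes whose marker-set union reproduces it.  An
unconstrained EM over all subsets would be hopeless at these sample sizes, so
the estimator restricts explanations to an *a priori* list of known/possible
haplotypes.  The list *spans* a genotype set when every observed genotype is
the union of at least one listed pair.  In ``sharp`` mode a non-spanning list
is an error (the list must be augmented); in ``lenient`` mode unspanned
individuals are set aside and reported as the unresolved fraction --
published estimates visibly tolerated up to ~15% unresolved haplotypes, so
both contracts are exposed.

The E-step weights each individual's compatible pairs by the Hardy-Weinberg
pair probability ``(2 - delta_ij) f_i f_j``; the M-step re-estimates each
haplotype frequency as its expected share of the 2N resolved chromosomes.
The observed-data log-likelihood is non-decreasing at every iteration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kir_data import (
    AprioriHaplotypeSet,
    GeneContentHaplotype,
    GenotypeProfile,
    PopulationSample,
    StudyPanel,
)

__all__ = [
    "CompatiblePairSet", "EMConfig", "HaplotypeFrequencyEstimate",
    "SpanningReport", "SpanningError",
    "compatible_pairs", "spanning_check", "em_fit", "augment_minimal",
    "default_candidates",
]


class SpanningError(ValueError):
    """Sharp-mode failure: the a priori haplotypes do not span the genotypes."""

    def __init__(self, unspanned: Sequence[frozenset[str]]):
        self.unspanned = list(unspanned)
        shown = [sorted(s) for s in self.unspanned[:5]]
        super().__init__(
            f"{len(self.unspanned)} observed genotype(s) cannot be generated "
            f"from any pair of a priori haplotypes (e.g. {shown}); "
            "the a priori set must be increased")


@dataclass(frozen=True)
class CompatiblePairSet:
    """Unordered haplotype index pairs (i <= j) explaining one genotype."""

    genotype_id: str
    pairs: tuple[tuple[int, int], ...]

    @property
    def spanned(self) -> bool:
        return bool(self.pairs)


@dataclass(frozen=True)
class EMConfig:
    tolerance: float = 1e-8
    max_iterations: int = 2000
    restarts: int = 1
    seed: int = 0
    mode: str = "sharp"

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.mode not in ("sharp", "lenient"):
            raise ValueError("mode must be 'sharp' or 'lenient'")


@dataclass(frozen=True)
class HaplotypeFrequencyEstimate:
    """EM output: haplotype frequencies, log-likelihood trace, diagnostics."""

    frequencies: dict[str, float]
    log_likelihood: float
    iterations: int
    unresolved_fraction: float
    log_likelihood_trace: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}")
        if not np.isfinite(self.log_likelihood):
            raise ValueError("log-likelihood not finite")
        if not 0.0 <= self.unresolved_fraction <= 1.0:
            raise ValueError("unresolved_fraction outside [0, 1]")

    def aggregated(self, hset: AprioriHaplotypeSet) -> dict[str, float]:
        """Sum variant frequencies back to their motif-level parent names."""
        out: dict[str, float] = {}
        for name, f in self.frequencies.items():
            parent = hset.parent_of(name)
            out[parent] = out.get(parent, 0.0) + f
        return out


def compatible_pairs(
    g: GenotypeProfile, H: AprioriHaplotypeSet
) -> CompatiblePairSet:
    """All pairs (i <= j, self-pairs included) whose marker union equals ``g``.

    Motif-level lists are expanded to marker level first; indices refer to the
    expanded set's order.  An empty pair list means the genotype is unspanned.
    """
    He = H.expand()
    target = g.present
    candidates = [i for i, h in enumerate(He) if h.markers <= target]
    pairs = tuple(
        (i, j)
        for i, j in itertools.combinations_with_replacement(candidates, 2)
        if He[i].markers | He[j].markers == target)
    return CompatiblePairSet(genotype_id=g.individual_id, pairs=pairs)


@dataclass(frozen=True)
class SpanningReport:
    """Per-distinct-genotype spanning status for one population."""

    population: str
    spanned: dict[frozenset[str], bool]
    counts: dict[frozenset[str], int]

    @property
    def all_spanned(self) -> bool:
        return all(self.spanned.values())

    @property
    def unspanned_genotypes(self) -> list[frozenset[str]]:
        return [g for g, ok in self.spanned.items() if not ok]

    @property
    def unresolved_fraction(self) -> float:
        total = sum(self.counts.values())
        bad = sum(c for g, c in self.counts.items() if not self.spanned[g])
        return bad / total


def spanning_check(
    pop: PopulationSample, H: AprioriHaplotypeSet, sharp: bool = False
) -> SpanningReport:
    """Report which distinct genotypes the a priori list spans.

    With ``sharp=True`` any unspanned genotype raises :class:`SpanningError`
    carrying the offending profiles.
    """
    He = H.expand()
    counts = pop.distinct_genotypes()
    spanned = {}
    for pattern in counts:
        probe = GenotypeProfile("probe", pattern)
        spanned[pattern] = compatible_pairs(probe, He).spanned
    report = SpanningReport(population=pop.name, spanned=spanned, counts=counts)
    if sharp and not report.all_spanned:
        raise SpanningError(report.unspanned_genotypes)
    return report


def _em_once(
    pair_sets: list[tuple[int, tuple[tuple[int, int], ...]]],
    n_hap: int,
    f0: np.ndarray,
    cfg: EMConfig,
) -> tuple[np.ndarray, float, int, list[float]]:
    """Run EM from one starting point.  ``pair_sets`` holds (count, pairs)."""
    f = f0.copy()
    total_chrom = 2.0 * sum(c for c, _ in pair_sets)
    trace: list[float] = []
    prev_ll = -np.inf
    iterations = 0
    for iterations in range(1, cfg.max_iterations + 1):
        new_f = np.zeros(n_hap)
        ll = 0.0
        for count, pairs in pair_sets:
            probs = np.array(
                [(1.0 if i == j else 2.0) * f[i] * f[j] for i, j in pairs])
            tot = probs.sum()
            if tot <= 0.0:
                # All mass withdrawn from this genotype's explanations;
                # resurrect with uniform weights over its pairs.
                probs = np.ones(len(pairs))
                tot = probs.sum()
                ll += count * -np.inf
            else:
                ll += count * np.log(tot)
            w = probs / tot
            for (i, j), wij in zip(pairs, w):
                new_f[i] += count * wij
                new_f[j] += count * wij
        f = new_f / total_chrom
        trace.append(ll)
        if ll - prev_ll < cfg.tolerance and np.isfinite(ll):
            prev_ll = ll
            break
        prev_ll = ll
    return f, prev_ll, iterations, trace


def em_fit(
    pop: PopulationSample,
    H: AprioriHaplotypeSet,
    cfg: EMConfig = EMConfig(),
) -> HaplotypeFrequencyEstimate:
    """Estimate haplotype frequencies for one population by constrained EM.

    Restart 0 initializes uniformly over the (expanded) a priori list for
    reproducibility; further restarts draw Dirichlet(1) starting points from
    a generator seeded with ``cfg.seed``.  The best-likelihood run is
    returned.  Frequencies below 1e-10 are truncated to zero and the vector
    renormalized on output only.
    """
    He = H.expand()
    n_hap = len(He)
    counts = pop.distinct_genotypes()
    pair_sets = []
    unresolved = 0
    unspanned = []
    for pattern, count in counts.items():
        cps = compatible_pairs(GenotypeProfile("g", pattern), He)
        if cps.spanned:
            pair_sets.append((count, cps.pairs))
        else:
            unresolved += count
            unspanned.append(pattern)
    if cfg.mode == "sharp" and unspanned:
        raise SpanningError(unspanned)
    if not pair_sets:
        raise ValueError("no resolvable individuals")

    rng = np.random.default_rng(cfg.seed)
    best = None
    for restart in range(max(1, cfg.restarts)):
        if restart == 0:
            f0 = np.full(n_hap, 1.0 / n_hap)
        else:
            f0 = rng.dirichlet(np.ones(n_hap))
        f, ll, iters, trace = _em_once(pair_sets, n_hap, f0, cfg)
        if best is None or ll > best[1]:
            best = (f, ll, iters, trace)

    f, ll, iters, trace = best
    f = np.where(f < 1e-10, 0.0, f)
    f = f / f.sum()
    return HaplotypeFrequencyEstimate(
        frequencies={h.name: float(x) for h, x in zip(He, f)},
        log_likelihood=float(ll),
        iterations=iters,
        unresolved_fraction=unresolved / pop.n,
        log_likelihood_trace=tuple(trace),
    )


def default_candidates(base: AprioriHaplotypeSet) -> AprioriHaplotypeSet:
    """Default augmentation candidate space.

    All Cen x Tel motif recombinants (including the 3DS1-deleted telomeric
    motif), expanded to marker level, plus every single-marker deletion
    variant of a base haplotype that keeps the framework intact.
    """
    from .kir_data import CEN_MOTIFS, TEL_MOTIFS, FRAMEWORK_LOCI, _make_haplotype

    haps: dict[str, GeneContentHaplotype] = {}
    for cen in CEN_MOTIFS:
        for tel in TEL_MOTIFS:
            for v in _make_haplotype(cen, tel).variants():
                haps.setdefault(v.name, v)
    for h in base.expand():
        for marker in sorted(h.markers - FRAMEWORK_LOCI):
            name = f"{h.name}-del{marker}"
            if name not in haps:
                haps[name] = GeneContentHaplotype(
                    name, h.cen_motif, h.tel_motif, h.markers - {marker})
    return AprioriHaplotypeSet(tuple(haps.values()))


def augment_minimal(
    panel: StudyPanel,
    base: AprioriHaplotypeSet,
    candidates: AprioriHaplotypeSet | None = None,
) -> list[GeneContentHaplotype]:
    """Greedy minimal augmentation of ``base`` to span a panel's genotypes.

    Repeatedly adds the candidate that newly spans the most currently
    unspanned distinct genotypes (ties: fewest markers, then lexicographic
    name) until everything is spanned or candidates are exhausted (a partial
    result is then returned; callers can detect it by re-running
    :func:`spanning_check`).  Returns added haplotypes in addition order.
    """
    if candidates is None:
        candidates = default_candidates(base)
    current = list(base.expand())
    cand = [c for c in candidates.expand()
            if c.name not in {h.name for h in current}]

    patterns: set[frozenset[str]] = set()
    for pop in panel:
        patterns.update(pop.distinct_genotypes())

    def unspanned_set(haps: list[GeneContentHaplotype]) -> set[frozenset[str]]:
        hs = AprioriHaplotypeSet(tuple(haps))
        out = set()
        for pat in patterns:
            if not compatible_pairs(GenotypeProfile("g", pat), hs).spanned:
                out.add(pat)
        return out

    added: list[GeneContentHaplotype] = []
    remaining = unspanned_set(current)
    while remaining and cand:
        best = None
        for c in cand:
            trial = unspanned_set(current + [c])
            gain = len(remaining) - len(trial)
            key = (-gain, len(c.markers), c.name)
            if gain > 0 and (best is None or key < best[0]):
                best = (key, c, trial)
        if best is None:
            break  # no candidate helps; partial result
        _, chosen, remaining = best
        current.append(chosen)
        cand.remove(chosen)
        added.append(chosen)
    return added
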