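"""Domain model for KIR gene-content data.

The KIR cluster on chromosome 19q13.4 varies between individuals in which
genes are present at all.  Presence/absence typing of 16 loci therefore yields
a binary *genotype profile* per individual, and chromosome-level variation is
described by *gene-content haplotypes*: combinations of a centromeric (Cen)
and a telomeric (Tel) motif flanked by four framework genes that are present
on essentially every haplotype.

This module defines the marker universe, the haplotype/genotype/panel
containers used throughout the package, the reference haplotype catalog
(the common Cen x Tel combinations plus the Cen-B3 haplotype and the
KIR3DS1-deletion haplotype), and plain-CSV readers/writers for genotype
tables and haplotype catalogs.
"""

from __future__ import annotations

import csv
import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

#: The 16 typed KIR presence/absence markers, in canonical (published) order.
KIR_LOCI: tuple[str, ...] = (
    "2DL1", "2DL2", "2DL3", "2DL4", "2DL5", "2DP1", "2DS1", "2DS2",
    "2DS3", "2DS4", "2DS5", "3DL1", "3DL2", "3DL3", "3DP1", "3DS1",
)

#: Framework genes flanking the Cen and Tel motifs; present on essentially
#: all haplotypes (KIR3DL3 / KIR3DP1 centromeric, KIR2DL4 / KIR3DL2 telomeric).
FRAMEWORK_LOCI: frozenset[str] = frozenset({"3DL3", "3DP1", "2DL4", "3DL2"})

#: The seven HGDP-CEPH world regions.
REGIONS: tuple[str, ...] = (
    "Africa", "Middle East", "Europe", "Central-South Asia",
    "East Asia", "Oceania", "America",
)

# Motif gene content.  KIR2DS3 and KIR2DS5 are alleles of one duplicated
# locus (2DS3S5) that can occupy a slot on some motifs; the slot is kept
# symbolic here and assigned to a concrete marker by expansion.
CEN_MOTIFS: dict[str, frozenset[str]] = {
    "Cen-A": frozenset({"2DL3", "2DP1", "2DL1"}),
    "Cen-B1": frozenset({"2DL2", "2DS2", "2DL5", "2DP1", "2DL1"}),
    "Cen-B2": frozenset({"2DL2", "2DS2"}),
    "Cen-B3": frozenset({"2DL3", "2DL5", "2DP1", "2DL1"}),
}
TEL_MOTIFS: dict[str, frozenset[str]] = {
    "Tel-A": frozenset({"3DL1", "2DS4"}),
    "Tel-B": frozenset({"3DS1", "2DL5", "2DS1"}),
    "Tel-B-del3DS1": frozenset({"2DL5", "2DS1"}),
}
#: Motifs carrying a 2DS3S5 slot (exactly one of KIR2DS3 / KIR2DS5 per slot).
S3S5_MOTIFS: frozenset[str] = frozenset(
    {"Cen-B1", "Cen-B3", "Tel-B", "Tel-B-del3DS1"}
)
S3S5_ALLELES: tuple[str, str] = ("2DS3", "2DS5")

_SHORT = {"Cen-A": "cA", "Cen-B1": "cB1", "Cen-B2": "cB2", "Cen-B3": "cB3",
          "Tel-A": "tA", "Tel-B": "tB", "Tel-B-del3DS1": "tBdel"}


class GenotypeTableError(ValueError):
    """Malformed genotype table (unknown column, bad header)."""


@dataclass(frozen=True)
class GeneContentHaplotype:
    """A chromosome-level gene-content pattern over the 16 KIR markers.

    ``markers`` holds the concretely assigned presence set.  A haplotype whose
    motifs carry unassigned 2DS3S5 slots lists those motifs in ``s3s5_slots``;
    such a haplotype is *motif-level* and must be expanded (one variant per
    allele assignment) before any set-union operation.
    """

    name: str
    cen_motif: str
    tel_motif: str
    markers: frozenset[str]
    s3s5_slots: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = self.markers - set(KIR_LOCI)
        if unknown:
            raise ValueError(f"unknown markers: {sorted(unknown)}")
        if not FRAMEWORK_LOCI <= self.markers:
            missing = FRAMEWORK_LOCI - self.markers
            raise ValueError(f"framework loci absent: {sorted(missing)}")
        if self.cen_motif not in CEN_MOTIFS:
            raise ValueError(f"unknown Cen motif {self.cen_motif!r}")
        if self.tel_motif not in TEL_MOTIFS:
            raise ValueError(f"unknown Tel motif {self.tel_motif!r}")

    @property
    def is_marker_level(self) -> bool:
        """True once every 2DS3S5 slot has a concrete allele."""
        return not self.s3s5_slots

    def variants(self) -> tuple["GeneContentHaplotype", ...]:
        """Expand 2DS3S5 slots into concrete marker-level haplotypes.

        One variant per Cartesian assignment of {2DS3, 2DS5} to each occupied
        motif slot (centromeric slot first in the name suffix).  A haplotype
        that is already marker-level expands to itself.
        """
        if self.is_marker_level:
            return (self,)
        out = []
        for alleles in itertools.product(S3S5_ALLELES, repeat=len(self.s3s5_slots)):
            name = self.name + "." + ".".join(alleles)
            out.append(GeneContentHaplotype(
                name=name,
                cen_motif=self.cen_motif,
                tel_motif=self.tel_motif,
                markers=self.markers | set(alleles),
            ))
        return tuple(out)


@dataclass(frozen=True)
class AprioriHaplotypeSet:
    """An ordered, uniquely named list of candidate haplotypes.

    This is the a-priori constraint set for haplotype inference: genotype
    explanations are restricted to unordered pairs drawn from this list.
    """

    haplotypes: tuple[GeneContentHaplotype, ...]

    def __post_init__(self) -> None:
        if not self.haplotypes:
            raise ValueError("a priori haplotype list may not be empty")
        names = [h.name for h in self.haplotypes]
        if len(set(names)) != len(names):
            raise ValueError("haplotype names must be unique")
        keys = {(h.name, h.markers, h.s3s5_slots) for h in self.haplotypes}
        if len(keys) != len(self.haplotypes):
            raise ValueError("duplicate haplotype entries")

    def __iter__(self) -> Iterator[GeneContentHaplotype]:
        return iter(self.haplotypes)

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __getitem__(self, i: int) -> GeneContentHaplotype:
        return self.haplotypes[i]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(h.name for h in self.haplotypes)

    @property
    def is_marker_level(self) -> bool:
        return all(h.is_marker_level for h in self.haplotypes)

    def expand(self) -> "AprioriHaplotypeSet":
        """Return the marker-level set (no-op if already marker-level)."""
        if self.is_marker_level:
            return self
        return AprioriHaplotypeSet(
            tuple(v for h in self.haplotypes for v in h.variants()))

    def parent_of(self, name: str) -> str:
        """Motif-level name a variant was expanded from (identity otherwise)."""
        for h in self.haplotypes:
            if h.name == name:
                return name
            if name.startswith(h.name + "."):
                return h.name
        return name


@dataclass(frozen=True)
class GenotypeProfile:
    """One individual's presence/absence calls over the 16 markers.

    Every marker has a definite call; rows with missing calls are rejected at
    read time rather than imputed.
    """

    individual_id: str
    present: frozenset[str]

    def __post_init__(self) -> None:
        unknown = self.present - set(KIR_LOCI)
        if unknown:
            raise ValueError(f"unknown markers: {sorted(unknown)}")

    @property
    def presence(self) -> Mapping[str, bool]:
        return {locus: locus in self.present for locus in KIR_LOCI}

    def has(self, locus: str) -> bool:
        if locus not in KIR_LOCI:
            raise KeyError(locus)
        return locus in self.present


@dataclass(frozen=True)
class PopulationSample:
    """A named population sample with coordinates and typed individuals."""

    name: str
    region: str
    latitude: float
    longitude: float
    genotypes: tuple[GenotypeProfile, ...]

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if len(self.genotypes) < 1:
            raise ValueError("population sample must contain >= 1 genotype")

    @property
    def n(self) -> int:
        return len(self.genotypes)

    def distinct_genotypes(self) -> dict[frozenset[str], int]:
        """Counts of distinct presence patterns, insertion-ordered."""
        counts: dict[frozenset[str], int] = {}
        for g in self.genotypes:
            counts[g.present] = counts.get(g.present, 0) + 1
        return counts


@dataclass(frozen=True)
class StudyPanel:
    """A collection of population samples with unique names."""

    populations: tuple[PopulationSample, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")

    def __iter__(self) -> Iterator[PopulationSample]:
        return iter(self.populations)

    def __len__(self) -> int:
        return len(self.populations)

    def __getitem__(self, name: str) -> PopulationSample:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.populations)


def _make_haplotype(cen: str, tel: str) -> GeneContentHaplotype:
    slots = tuple(m for m in (cen, tel) if m in S3S5_MOTIFS)
    return GeneContentHaplotype(
        name=f"{_SHORT[cen]}-{_SHORT[tel]}",
        cen_motif=cen,
        tel_motif=tel,
        markers=FRAMEWORK_LOCI | CEN_MOTIFS[cen] | TEL_MOTIFS[tel],
        s3s5_slots=slots,
    )


def build_reference_haplotypes(
    include_deletion: bool = True,
    expand_2DS3S5: bool = True,
) -> AprioriHaplotypeSet:
    """Build the reference gene-content haplotype catalog.

    The catalog holds the six common Cen x Tel combinations
    (Cen-A/B1/B2 x Tel-A/B), the seventh Cen-B3 ~ Tel-A haplotype, and, if
    ``include_deletion``, the Cen-B1 ~ Tel-B haplotype lacking KIR3DS1 -- the
    extra haplotype needed to span genotype panels in which the 3DS1 deletion
    segregates.

    With ``expand_2DS3S5`` every occupied 2DS3S5 slot is assigned concretely,
    one variant per allele per slot (the typing assay calls KIR2DS3 and
    KIR2DS5 separately, so marker-level analysis needs the expansion):
    7 motif-level haplotypes expand to 14, 8 to 18.
    """
    combos = [
        ("Cen-A", "Tel-A"), ("Cen-A", "Tel-B"),
        ("Cen-B1", "Tel-A"), ("Cen-B1", "Tel-B"),
        ("Cen-B2", "Tel-A"), ("Cen-B2", "Tel-B"),
        ("Cen-B3", "Tel-A"),
    ]
    haps = [_make_haplotype(c, t) for c, t in combos]
    if include_deletion:
        haps.append(_make_haplotype("Cen-B1", "Tel-B-del3DS1"))
    out = AprioriHaplotypeSet(tuple(haps))
    return out.expand() if expand_2DS3S5 else out


def genotype_from_pair(
    h1: GeneContentHaplotype,
    h2: GeneContentHaplotype,
    individual_id: str | None = None,
) -> GenotypeProfile:
    """Presence profile of a diploid carrying haplotypes ``h1`` and ``h2``.

    Presence/absence typing cannot see copy number, so the observable profile
    is the set union of the two haplotypes' marker sets (commutative and
    idempotent by construction).
    """
    for h in (h1, h2):
        if not h.is_marker_level:
            raise ValueError(
                f"haplotype {h.name!r} has unassigned 2DS3S5 slots; "
                "expand before forming genotypes")
    return GenotypeProfile(
        individual_id=individual_id or f"{h1.name}+{h2.name}",
        present=h1.markers | h2.markers,
    )


# ---------------------------------------------------------------------------
# Genotype table IO
#
# CSV layout: population, region, individual_id, then one column per marker
# in canonical order with values in {0, 1}.  Coordinates are carried in a
# separate population-metadata table (see kirpop.datasets).
# ---------------------------------------------------------------------------

def read_genotype_table(
    path,
    coordinates: Mapping[str, tuple[float, float]] | None = None,
) -> StudyPanel:
    """Read a genotype CSV into a :class:`StudyPanel`.

    Rows with a missing cell or a value outside {0, 1} are rejected with a
    logged diagnostic; an unknown marker column fails the whole file.
    ``coordinates`` optionally maps population name to (latitude, longitude);
    populations without an entry get NaN coordinates.
    """
    coordinates = coordinates or {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        meta_cols = {"population", "region", "individual_id"}
        if not meta_cols <= set(header):
            raise GenotypeTableError(
                f"missing required columns: {sorted(meta_cols - set(header))}")
        marker_cols = [c for c in header if c not in meta_cols]
        unknown = set(marker_cols) - set(KIR_LOCI)
        if unknown:
            raise GenotypeTableError(f"unknown marker columns: {sorted(unknown)}")
        missing = set(KIR_LOCI) - set(marker_cols)
        if missing:
            raise GenotypeTableError(f"missing marker columns: {sorted(missing)}")

        groups: dict[str, tuple[str, list[GenotypeProfile]]] = {}
        for lineno, row in enumerate(reader, start=2):
            present = set()
            bad = None
            for locus in KIR_LOCI:
                val = (row.get(locus) or "").strip()
                if val == "1":
                    present.add(locus)
                elif val != "0":
                    bad = (locus, val)
                    break
            if bad is not None:
                logger.warning(
                    "rejecting row %d (individual %r): %s=%r not in {0,1}",
                    lineno, row.get("individual_id"), bad[0], bad[1])
                continue
            pop = row["population"]
            groups.setdefault(pop, (row["region"], []))[1].append(
                GenotypeProfile(row["individual_id"], frozenset(present)))

    pops = []
    for name, (region, genos) in groups.items():
        lat, lon = coordinates.get(name, (float("nan"), float("nan")))
        pops.append(PopulationSample(name, region, lat, lon, tuple(genos)))
    return StudyPanel(tuple(pops))


def write_genotype_table(panel: StudyPanel, path) -> None:
    """Write a panel back to the canonical genotype CSV layout."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["population", "region", "individual_id", *KIR_LOCI])
        for pop in panel:
            for g in pop.genotypes:
                writer.writerow(
                    [pop.name, pop.region, g.individual_id]
                    + [int(locus in g.present) for locus in KIR_LOCI])


def write_haplotype_catalog(hset: AprioriHaplotypeSet, path) -> None:
    """Serialize a haplotype catalog (name, motifs, slots, 16 presence bits)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "cen_motif", "tel_motif", "s3s5_slots", *KIR_LOCI])
        for h in hset:
            writer.writerow(
                [h.name, h.cen_motif, h.tel_motif, ";".join(h.s3s5_slots)]
                + [int(locus in h.markers) for locus in KIR_LOCI])


def read_haplotype_catalog(path) -> AprioriHaplotypeSet:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        haps = []
        for row in reader:
            markers = frozenset(l for l in KIR_LOCI if row[l].strip() == "1")
            slots = tuple(s for s in row.get("s3s5_slots", "").split(";") if s)
            haps.append(GeneContentHaplotype(
                row["name"], row["cen_motif"], row["tel_motif"], markers, slots))
    return AprioriHaplotypeSet(tuple(haps))
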