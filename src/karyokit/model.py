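"""Domain model for mitotic karyotypes with rDNA FISH landmarks.

The objects here describe what a cytogeneticist measures on a metaphase
plate: somatic chromosomes with long/short arm lengths in micrometres,
optional satellites (secondary constrictions), and ribosomal DNA sites
(5S and 45S) located by arm and by fractional position along the arm,
measured from the centromere (0) toward the telomere (1).

Centromere position follows the Levan arm-ratio convention: a chromosome
with arm ratio r = L/S is metacentric (m) up to r = 1.7, submetacentric
(sm) up to 3.0, subtelocentric (st) up to 7.0 and telocentric (t) beyond.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum, IntEnum
from typing import Iterable


class RDNAFamily(str, Enum):
    """Ribosomal DNA probe family used as a FISH landmark."""

    FIVE_S = "5S"
    FORTYFIVE_S = "45S"


class Arm(str, Enum):
    SHORT = "SHORT"
    LONG = "LONG"

    @property
    def other(self) -> "Arm":
        return Arm.LONG if self is Arm.SHORT else Arm.SHORT


class PositionClass(str, Enum):
    """Qualitative band position along an arm, centromere -> telomere."""

    CENTROMERIC_PROXIMAL = "CENTROMERIC_PROXIMAL"
    INTERCALARY = "INTERCALARY"
    SUBTELOMERIC = "SUBTELOMERIC"
    TELOMERIC = "TELOMERIC"


#: Half-open bins on the arm fraction for each qualitative class; the last
#: bin is closed at 1.0.  These make the verbal vocabulary computable.
POSITION_BINS: dict[PositionClass, tuple[float, float]] = {
    PositionClass.CENTROMERIC_PROXIMAL: (0.0, 0.25),
    PositionClass.INTERCALARY: (0.25, 0.75),
    PositionClass.SUBTELOMERIC: (0.75, 0.95),
    PositionClass.TELOMERIC: (0.95, 1.0),
}


def classify_position(frac: float) -> PositionClass:
    """Map an arm fraction in [0, 1] to its qualitative position class."""
    if not 0.0 <= frac <= 1.0:
        raise ValueError(f"arm fraction {frac} outside [0, 1]")
    for cls, (lo, hi) in POSITION_BINS.items():
        if lo <= frac < hi:
            return cls
    return PositionClass.TELOMERIC


def position_midpoint(cls: PositionClass) -> float:
    lo, hi = POSITION_BINS[cls]
    return (lo + hi) / 2.0


class GenomeLabel(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    UNKNOWN = "UNKNOWN"


class MorphologyClass(IntEnum):
    """Levan centromere-position class, ordered by increasing asymmetry."""

    m = 1
    sm = 2
    st = 3
    t = 4

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: Upper arm-ratio bound of each Levan class (closed on the lower class).
LEVAN_THRESHOLDS: tuple[tuple[float, MorphologyClass], ...] = (
    (1.7, MorphologyClass.m),
    (3.0, MorphologyClass.sm),
    (7.0, MorphologyClass.st),
)


@dataclass(frozen=True)
class RDNASite:
    family: RDNAFamily
    arm: Arm
    position_class: PositionClass
    position_frac: float | None = None

    @property
    def resolved_frac(self) -> float:
        """Fractional arm position; falls back to the class midpoint."""
        if self.position_frac is not None:
            return self.position_frac
        return position_midpoint(self.position_class)

    def violations(self) -> list[str]:
        out = []
        if self.position_frac is not None:
            if not 0.0 <= self.position_frac <= 1.0:
                out.append(f"position_frac {self.position_frac} outside [0,1]")
            elif classify_position(self.position_frac) is not self.position_class:
                out.append(
                    f"position_frac {self.position_frac} outside the "
                    f"{self.position_class.value} bin"
                )
        return out


@dataclass(frozen=True)
class Satellite:
    """Secondary constriction; metadata only, contributes no arm length."""

    arm: Arm
    position_frac: float | None = None


@dataclass(frozen=True)
class Chromosome:
    """One somatic chromosome.

    Arms are named by length: construction normalizes so that
    ``long_arm_um >= short_arm_um``, relabelling site and satellite arms
    when the measured values arrive swapped.
    """

    label: str
    long_arm_um: float
    short_arm_um: float
    satellite: Satellite | None = None
    sites: tuple[RDNASite, ...] = ()
    genome: GenomeLabel | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        if self.short_arm_um > self.long_arm_um:
            long, short = self.short_arm_um, self.long_arm_um
            object.__setattr__(self, "long_arm_um", long)
            object.__setattr__(self, "short_arm_um", short)
            object.__setattr__(
                self,
                "sites",
                tuple(replace(s, arm=s.arm.other) for s in self.sites),
            )
            if self.satellite is not None:
                object.__setattr__(
                    self, "satellite", replace(self.satellite, arm=self.satellite.arm.other)
                )

    @property
    def total_length_um(self) -> float:
        return self.long_arm_um + self.short_arm_um

    def arm_length(self, arm: Arm) -> float:
        return self.long_arm_um if arm is Arm.LONG else self.short_arm_um

    def sites_on(self, arm: Arm) -> tuple[RDNASite, ...]:
        return tuple(s for s in self.sites if s.arm is arm)

    def violations(self) -> list[str]:
        out = []
        if self.total_length_um <= 0:
            out.append(f"{self.label}: total length must be positive")
        if self.long_arm_um < 0 or self.short_arm_um < 0:
            out.append(f"{self.label}: negative arm length")
        for site in self.sites:
            out.extend(f"{self.label}: {v}" for v in site.violations())
        return out


@dataclass
class Karyotype:
    """Full somatic complement: the unit statistics and events act on.

    ``ploidy`` times the basic number ``basic_number_x`` must equal the
    somatic count 2n unless the complement is flagged ``unbalanced``
    (a mid-scenario intermediate, e.g. after a fission whose acentric
    products have not yet been fused back).
    """

    species: str
    chromosomes: list[Chromosome]
    ploidy: int
    basic_number_x: int
    unbalanced: bool = False

    @property
    def somatic_number_2n(self) -> int:
        return len(self.chromosomes)

    def total_length_um(self) -> float:
        return sum(c.total_length_um for c in self.chromosomes)

    def copy(self) -> "Karyotype":
        return Karyotype(
            species=self.species,
            chromosomes=list(self.chromosomes),
            ploidy=self.ploidy,
            basic_number_x=self.basic_number_x,
            unbalanced=self.unbalanced,
        )


@dataclass(frozen=True)
class AcentricSegment:
    """Centromere-less chromosome fragment; a scenario intermediate only.

    ``position_frac`` of each carried site is re-expressed from the
    segment end that used to face the centromere.
    """

    origin_label: str
    origin_arm: Arm
    length_um: float
    sites: tuple[RDNASite, ...] = ()


def arm_ratio(chrom: Chromosome) -> float:
    """Levan arm ratio r = L/S; +inf for a telocentric (S = 0)."""
    if chrom.short_arm_um == 0:
        return math.inf
    return chrom.long_arm_um / chrom.short_arm_um


def classify_morphology(chrom: Chromosome) -> MorphologyClass:
    """Levan centromere-position class from the arm ratio.

    Boundaries are closed on the lower (more symmetric) class, so
    r = 1.7 is still metacentric.
    """
    r = arm_ratio(chrom)
    for upper, cls in LEVAN_THRESHOLDS:
        if r <= upper:
            return cls
    return MorphologyClass.t


def validate(karyotype: Karyotype) -> list[str]:
    """Collect every invariant violation; empty list means valid.

    Validation never raises: malformed data yields messages naming the
    offending chromosome and rule.
    """
    out: list[str] = []
    for chrom in karyotype.chromosomes:
        out.extend(chrom.violations())
    if karyotype.ploidy < 1:
        out.append(f"ploidy {karyotype.ploidy} < 1")
    if karyotype.basic_number_x < 1:
        out.append(f"basic number x {karyotype.basic_number_x} < 1")
    expected = karyotype.ploidy * karyotype.basic_number_x
    if not karyotype.unbalanced and karyotype.somatic_number_2n != expected:
        out.append(
            f"balance violation: 2n = {karyotype.somatic_number_2n} but "
            f"ploidy x basic number = {expected}"
        )
    return out


def _label_sort_key(label: str) -> tuple:
    """Natural sort: 'B2' < 'B10', genomes grouped alphabetically."""
    head = label.rstrip("0123456789")
    tail = label[len(head):]
    return (head, int(tail) if tail else -1)


def monoploid_complement(karyotype: Karyotype) -> list[Chromosome]:
    """One representative chromosome per homologue group.

    Homologues are grouped by label (idiograms present pairs under a
    shared label).  The representative's arm lengths are the group means;
    its rDNA sites are taken from the group member carrying the most
    sites, so a locus scored on any homologue is represented.  For a
    diploid this returns x chromosomes; for an allopolyploid, x per
    parental genome present.
    """
    if karyotype.unbalanced:
        raise ValueError("monoploid complement undefined for an unbalanced karyotype")
    groups: dict[str, list[Chromosome]] = {}
    for chrom in karyotype.chromosomes:
        groups.setdefault(chrom.label, []).append(chrom)
    sizes = {len(g) for g in groups.values()}
    if len(sizes) > 1:
        detail = ", ".join(f"{lab}:{len(g)}" for lab, g in sorted(groups.items()))
        raise ValueError(f"homologue groups of unequal size ({detail})")
    reps = []
    for label in sorted(groups, key=_label_sort_key):
        group = groups[label]
        donor = max(group, key=lambda c: len(c.sites))  # ties keep list order
        reps.append(
            Chromosome(
                label=label,
                long_arm_um=sum(c.long_arm_um for c in group) / len(group),
                short_arm_um=sum(c.short_arm_um for c in group) / len(group),
                satellite=donor.satellite,
                sites=donor.sites,
                genome=donor.genome,
            )
        )
    return reps


def homologue_groups(karyotype: Karyotype) -> dict[str, list[int]]:
    """Indices of the chromosomes sharing each label, in complement order."""
    groups: dict[str, list[int]] = {}
    for i, chrom in enumerate(karyotype.chromosomes):
        groups.setdefault(chrom.label, []).append(i)
    return groups
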