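"""Genome-signature matching and polyploidy-type inference.

Three recurrent monoploid genomes are recognizable in canary grass
karyotypes:

* genome A (x = 6): strongly asymmetric, with two submetacentric or
  subtelocentric chromosomes per monoploid set, one short-arm
  (sub)telomeric 45S site and a long-arm subtelomeric 5S "double band"
  (two sites on one chromosome);
* genome B (x = 7): more symmetric, one intercalary 45S site and a
  single 5S-bearing chromosome, typically (sub)telomeric;
* genome C (x = 7): symmetric, a centromere-proximal short-arm 45S site
  (absent where nucleolar dominance silenced it) and a conspicuous 5-6
  5S sites per monoploid set; known only from tetraploids.

A karyotype is scored by splitting it into monoploid sub-complements
(by parental genome label when recorded, else by the alphabetic prefix
of the chromosome labels), scoring each against all signatures (four
equally weighted rule families: basic number, morphology/symmetry, 45S
pattern, 5S pattern) and taking the best-scoring label, UNKNOWN below
threshold.  Ploidy plus the set of assigned labels then decides between
auto- and allopolyploidy.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .model import (
    Arm,
    Chromosome,
    GenomeLabel,
    Karyotype,
    MorphologyClass,
    PositionClass,
    RDNAFamily,
    RDNASite,
    Satellite,
    classify_morphology,
    classify_position,
    monoploid_complement,
)
from .stats import mca


class PolyploidyType(str, Enum):
    DIPLOID = "DIPLOID"
    AUTOPOLYPLOID = "AUTOPOLYPLOID"
    ALLOPOLYPLOID = "ALLOPOLYPLOID"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class RDNARule:
    """Declarative constraint on one rDNA family within a monoploid set.

    ``bearing`` and ``signals`` are inclusive (min, max) ranges on the
    number of site-bearing chromosomes and the total site count;
    ``position_mode`` states whether *all* sites or at least *any* one
    site must fall on the required arm/position classes;
    ``sites_per_bearing`` pins the per-chromosome site count (2 encodes
    a double band).
    """

    family: RDNAFamily
    bearing: tuple[int, int]
    signals: tuple[int, int] | None = None
    arm: Arm | None = None
    position_classes: tuple[PositionClass, ...] | None = None
    position_mode: str = "all"
    sites_per_bearing: int | None = None

    def check(self, complement: list[Chromosome]) -> bool:
        per_chrom = [
            [s for s in c.sites if s.family is self.family] for c in complement
        ]
        bearing = [sites for sites in per_chrom if sites]
        n_bearing = len(bearing)
        total = sum(len(sites) for sites in bearing)
        if not self.bearing[0] <= n_bearing <= self.bearing[1]:
            return False
        if self.signals is not None and not self.signals[0] <= total <= self.signals[1]:
            return False
        if self.sites_per_bearing is not None and any(
            len(sites) != self.sites_per_bearing for sites in bearing
        ):
            return False
        all_sites = [s for sites in bearing for s in sites]
        if all_sites and (self.arm is not None or self.position_classes is not None):
            ok = [self._site_ok(s) for s in all_sites]
            if self.position_mode == "any":
                if not any(ok):
                    return False
            elif not all(ok):
                return False
        return True

    def _site_ok(self, site: RDNASite) -> bool:
        if self.arm is not None and site.arm is not self.arm:
            return False
        if (
            self.position_classes is not None
            and site.position_class not in self.position_classes
        ):
            return False
        return True


@dataclass(frozen=True)
class GenomeSignature:
    """Rule set describing one monoploid genome; each rule family is
    individually testable against a monoploid complement."""

    label: GenomeLabel
    basic_number: int
    rdna_45s_rule: RDNARule
    rdna_5s_rule: RDNARule
    min_sm_st: int | None = None  # morphology composition requirement
    max_mca_pct: float | None = None  # karyotype-symmetry requirement

    def rule_results(self, complement: list[Chromosome]) -> dict[str, bool]:
        results = {
            "basic_number": len(complement) == self.basic_number,
            "morphology": self._morphology_ok(complement),
            "rdna_45s": self.rdna_45s_rule.check(complement),
            "rdna_5s": self.rdna_5s_rule.check(complement),
        }
        return results

    def _morphology_ok(self, complement: list[Chromosome]) -> bool:
        if not complement:
            return False
        if self.min_sm_st is not None:
            n = sum(
                1
                for c in complement
                if classify_morphology(c) >= MorphologyClass.sm
            )
            if n < self.min_sm_st:
                return False
        if self.max_mca_pct is not None:
            sub = Karyotype(
                species="_sub",
                chromosomes=list(complement),
                ploidy=1,
                basic_number_x=len(complement),
            )
            if mca(sub) >= self.max_mca_pct:
                return False
        return True


_SUBTELO = (PositionClass.SUBTELOMERIC, PositionClass.TELOMERIC)

_SIGNATURES = (
    GenomeSignature(
        label=GenomeLabel.A,
        basic_number=6,
        min_sm_st=2,
        rdna_45s_rule=RDNARule(
            family=RDNAFamily.FORTYFIVE_S,
            bearing=(1, 1),
            arm=Arm.SHORT,
            position_classes=_SUBTELO,
        ),
        rdna_5s_rule=RDNARule(
            family=RDNAFamily.FIVE_S,
            bearing=(1, 1),
            signals=(2, 2),
            arm=Arm.LONG,
            position_classes=_SUBTELO,
            sites_per_bearing=2,  # the diagnostic 5S double band
        ),
    ),
    GenomeSignature(
        label=GenomeLabel.B,
        basic_number=7,
        max_mca_pct=20.0,
        rdna_45s_rule=RDNARule(
            family=RDNAFamily.FORTYFIVE_S,
            bearing=(1, 1),
            position_classes=(PositionClass.INTERCALARY,),
        ),
        rdna_5s_rule=RDNARule(
            family=RDNAFamily.FIVE_S,
            bearing=(1, 2),
            signals=(1, 3),
            position_classes=_SUBTELO,
            position_mode="any",
        ),
    ),
    GenomeSignature(
        label=GenomeLabel.C,
        basic_number=7,
        max_mca_pct=20.0,
        rdna_45s_rule=RDNARule(
            family=RDNAFamily.FORTYFIVE_S,
            bearing=(0, 1),  # nucleolar dominance may have silenced it
            arm=Arm.SHORT,
            position_classes=(PositionClass.CENTROMERIC_PROXIMAL,),
        ),
        rdna_5s_rule=RDNARule(
            family=RDNAFamily.FIVE_S,
            bearing=(2, 7),
            signals=(5, 6),  # the conspicuous 5-6 sites per monoploid set
        ),
    ),
)


def builtin_signatures() -> list[GenomeSignature]:
    """The packaged A/B/C genome signatures."""
    return list(_SIGNATURES)


def score_signature(complement: list[Chromosome], sig: GenomeSignature) -> float:
    """Fraction of the signature's four rule families satisfied by a
    monoploid complement, in [0, 1]."""
    if not complement:
        return 0.0
    results = sig.rule_results(complement)
    return sum(results.values()) / len(results)


@dataclass(frozen=True)
class SubGenomeCall:
    partition_key: str
    label: GenomeLabel
    score: float
    copies: int  # monoploid copies of this sub-genome in the complement


@dataclass(frozen=True)
class GenomeAssignment:
    species: str
    sub_genomes: tuple[SubGenomeCall, ...]
    formula: str
    polyploidy_type: PolyploidyType


def _partition_key(chrom: Chromosome) -> str:
    if chrom.genome is not None:
        return chrom.genome.value
    head = chrom.label.rstrip("0123456789")
    return head or chrom.label


def assign(karyotype: Karyotype, threshold: float = 0.75) -> GenomeAssignment:
    """Assign a genome label to each monoploid sub-complement and infer
    the polyploidy type.

    Sub-complements are partitioned by recorded genome label (falling
    back to the label prefix), condensed to one representative per
    homologue group, and scored against every built-in signature; the
    best label wins, or UNKNOWN below the score threshold.  The genome
    formula follows karyotype-table style: one letter per diploid genome
    copy, distinct parental genomes separated by "/" (e.g. "A", "BB",
    "B/C").
    """
    parts: dict[str, list[Chromosome]] = {}
    for chrom in karyotype.chromosomes:
        parts.setdefault(_partition_key(chrom), []).append(chrom)

    calls = []
    for key in sorted(parts):
        sub = Karyotype(
            species=f"{karyotype.species}[{key}]",
            chromosomes=parts[key],
            ploidy=1,
            basic_number_x=len(parts[key]),
            unbalanced=False,
        )
        try:
            reps = monoploid_complement(sub)
        except ValueError:
            calls.append(SubGenomeCall(key, GenomeLabel.UNKNOWN, 0.0, 0))
            continue
        copies = len(parts[key]) // len(reps) if reps else 0
        best_label, best_score = GenomeLabel.UNKNOWN, -1.0
        for sig in builtin_signatures():
            score = score_signature(reps, sig)
            if score > best_score:
                best_label, best_score = sig.label, score
        if best_score < threshold:
            best_label = GenomeLabel.UNKNOWN
        calls.append(SubGenomeCall(key, best_label, max(best_score, 0.0), copies))

    formula_parts = []
    for call in calls:
        diploid_copies = max(call.copies // 2, 1)
        formula_parts.append(call.label.value * diploid_copies)
    formula = "/".join(formula_parts)

    labels = {c.label for c in calls}
    if karyotype.ploidy == 2:
        ptype = PolyploidyType.DIPLOID
    elif GenomeLabel.UNKNOWN in labels or not labels:
        ptype = PolyploidyType.UNKNOWN
    elif len(labels) == 1:
        ptype = PolyploidyType.AUTOPOLYPLOID
    else:
        ptype = PolyploidyType.ALLOPOLYPLOID
    return GenomeAssignment(
        species=karyotype.species,
        sub_genomes=tuple(calls),
        formula=formula,
        polyploidy_type=ptype,
    )


# ---------------------------------------------------------------------------
# diploid template karyotypes realizing each signature


def _chrom(
    label: str,
    genome: GenomeLabel,
    long_um: float,
    short_um: float,
    sites: tuple[RDNASite, ...] = (),
    satellite: Satellite | None = None,
) -> Chromosome:
    return Chromosome(
        label=label,
        long_arm_um=long_um,
        short_arm_um=short_um,
        satellite=satellite,
        sites=sites,
        genome=genome,
    )


def _site(family, arm, frac) -> RDNASite:
    return RDNASite(family, arm, classify_position(frac), frac)


def template_monoploid(label: GenomeLabel) -> list[Chromosome]:
    """A concrete monoploid complement scoring 1.0 against its own
    signature; arm lengths are illustrative (um)."""
    S5, S45 = RDNAFamily.FIVE_S, RDNAFamily.FORTYFIVE_S
    if label is GenomeLabel.A:
        return [
            _chrom("A1", label, 4.2, 3.8,
                   (_site(S45, Arm.SHORT, 0.85),), Satellite(Arm.SHORT, 0.8)),
            _chrom("A2", label, 5.0, 1.0,
                   (_site(S5, Arm.LONG, 0.82), _site(S5, Arm.LONG, 0.90))),
            _chrom("A3", label, 3.6, 3.2),
            _chrom("A4", label, 3.4, 3.0),
            _chrom("A5", label, 3.2, 2.8),
            _chrom("A6", label, 4.5, 1.5),
        ]
    if label is GenomeLabel.B:
        return [
            _chrom("B1", label, 3.4, 3.0, (_site(S45, Arm.LONG, 0.5),)),
            _chrom("B2", label, 3.2, 2.8, (_site(S5, Arm.LONG, 0.85),)),
            _chrom("B3", label, 3.0, 2.6),
            _chrom("B4", label, 2.8, 2.4),
            _chrom("B5", label, 2.6, 2.2),
            _chrom("B6", label, 2.4, 2.0),
            _chrom("B7", label, 2.2, 1.8),
        ]
    if label is GenomeLabel.C:
        return [
            _chrom("C1", label, 3.3, 2.9,
                   (_site(S45, Arm.SHORT, 0.10),), Satellite(Arm.SHORT, 0.15)),
            _chrom("C2", label, 3.1, 2.7,
                   (_site(S5, Arm.LONG, 0.40), _site(S5, Arm.LONG, 0.60))),
            _chrom("C3", label, 2.9, 2.5,
                   (_site(S5, Arm.LONG, 0.35), _site(S5, Arm.LONG, 0.65))),
            _chrom("C4", label, 2.7, 2.3, (_site(S5, Arm.SHORT, 0.15),)),
            _chrom("C5", label, 2.5, 2.1),
            _chrom("C6", label, 2.3, 1.9),
            _chrom("C7", label, 2.1, 1.7),
        ]
    raise ValueError(f"no template for {label}")


def template_karyotype(label: GenomeLabel, species: str | None = None) -> Karyotype:
    """Diploid karyotype built from two copies of the genome template."""
    mono = template_monoploid(label)
    return Karyotype(
        species=species or f"genome-{label.value} template",
        chromosomes=[c for c in mono for _ in range(2)],
        ploidy=2,
        basic_number_x=len(mono),
    )
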