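"""Chromosome rearrangement events and scenario replay.

Implements the event algebra behind descending dysploidy and
polyploidization in grasses: pericentromeric fission (producing acentric
whole-arm segments), telomere-to-telomere ("end-to-end") fusion of such a
segment onto another chromosome's arm, pericentric and paracentric
inversions, reciprocal translocation, whole-genome duplication
(autopolyploidy), amphidiploid merger (allopolyploidy), and gain/loss of
rDNA loci (e.g. nucleolar dominance in an allopolyploid).

Every structural event conserves total chromatin length (chromosomes plus
unfused acentric segments) exactly: dysploidy changes chromosome number,
not DNA content.  Chromosome geometry uses a signed coordinate along the
chromosome, negative on the short arm, positive on the long arm, with the
centromere at zero; an inversion reverses the marked segment in place and
the centromere moves with it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Any

from .model import (
    AcentricSegment,
    Arm,
    Chromosome,
    GenomeLabel,
    Karyotype,
    PositionClass,
    RDNAFamily,
    RDNASite,
    classify_position,
)


class EventKind(str, Enum):
    FISSION_PERICENTROMERIC = "FISSION_PERICENTROMERIC"
    END_TO_END_FUSION = "END_TO_END_FUSION"
    PERICENTRIC_INVERSION = "PERICENTRIC_INVERSION"
    PARACENTRIC_INVERSION = "PARACENTRIC_INVERSION"
    RECIPROCAL_TRANSLOCATION = "RECIPROCAL_TRANSLOCATION"
    AUTOPOLYPLOIDY = "AUTOPOLYPLOIDY"
    ALLOPOLYPLOID_MERGE = "ALLOPOLYPLOID_MERGE"
    RDNA_LOSS = "RDNA_LOSS"
    RDNA_GAIN = "RDNA_GAIN"


@dataclass(frozen=True)
class RearrangementEvent:
    kind: EventKind
    params: dict[str, Any] = field(default_factory=dict)


@dataclass
class Scenario:
    """Ordered list of events; by default each event acts on every
    chromosome sharing the target label (FISH observations are somatic,
    and rearrangements fixed in a lineage affect both homologues)."""

    name: str
    events: list[RearrangementEvent]
    apply_to_homologues: bool = True


@dataclass(frozen=True)
class EventRecord:
    kind: EventKind
    params: dict[str, Any]
    consumed: tuple[str, ...]
    produced: tuple[str, ...]
    length_before_um: float
    length_after_um: float
    sites_moved: int


EventLog = list


class RearrangementError(ValueError):
    pass


# ---------------------------------------------------------------------------
# coordinate helpers


def _site_coords(chrom: Chromosome) -> list[tuple[RDNASite, float]]:
    out = []
    for s in chrom.sites:
        f = s.resolved_frac
        x = f * chrom.long_arm_um if s.arm is Arm.LONG else -f * chrom.short_arm_um
        out.append((s, x))
    return out


def _rebuild(
    chrom: Chromosome,
    lo: float,
    hi: float,
    centromere: float,
    site_coords: list[tuple[RDNASite, float]],
) -> Chromosome:
    """Reassemble a chromosome from interval [lo, hi] with the centromere
    at ``centromere``; the right side goes in the long-arm slot and the
    constructor renormalizes arm names by length."""
    left = centromere - lo
    right = hi - centromere
    sites = []
    for s, x in site_coords:
        if x < centromere and left > 0:
            frac = min((centromere - x) / left, 1.0)
            arm = Arm.SHORT
        else:
            frac = min((x - centromere) / right, 1.0) if right > 0 else 0.0
            arm = Arm.LONG
        sites.append(
            replace(s, arm=arm, position_frac=frac, position_class=classify_position(frac))
        )
    return Chromosome(
        label=chrom.label,
        long_arm_um=right,
        short_arm_um=left,
        satellite=chrom.satellite,
        sites=tuple(sites),
        genome=chrom.genome,
    )


def _indices_for_label(karyotype: Karyotype, label: str, all_homologues: bool) -> list[int]:
    idx = [i for i, c in enumerate(karyotype.chromosomes) if c.label == label]
    if not idx:
        raise RearrangementError(f"no chromosome labelled {label!r}")
    if not all_homologues:
        if len(idx) > 1:
            raise RearrangementError(
                f"label {label!r} is ambiguous ({len(idx)} homologues); "
                "enable homologue application or disambiguate"
            )
    return idx


# ---------------------------------------------------------------------------
# structural events


def fission_pericentromeric(
    karyotype: Karyotype,
    chrom_label: str,
    break_frac: float = 0.0,
    apply_to_homologues: bool = True,
) -> tuple[Karyotype, list[AcentricSegment]]:
    """Break a chromosome in the centromeric region and delete the
    centromere, yielding two acentric whole-arm segments.

    Site positions on each segment are re-expressed from the end that
    used to face the centromere.  The karyotype is flagged unbalanced
    until the segments are fused elsewhere.  Only the exact centromeric
    break (``break_frac = 0``) is modelled; the centromere itself
    contributes no length, so chromatin is conserved.
    """
    if break_frac != 0.0:
        raise RearrangementError(
            "only a break at the centromere (break_frac = 0) is modelled"
        )
    idx = _indices_for_label(karyotype, chrom_label, apply_to_homologues)
    out = karyotype.copy()
    segments = []
    for i in idx:
        chrom = out.chromosomes[i]
        for arm in (Arm.LONG, Arm.SHORT):
            length = chrom.arm_length(arm)
            if length <= 0:
                continue
            segments.append(
                AcentricSegment(
                    origin_label=chrom.label,
                    origin_arm=arm,
                    length_um=length,
                    sites=chrom.sites_on(arm),
                )
            )
    out.chromosomes = [c for i, c in enumerate(out.chromosomes) if i not in set(idx)]
    out.unbalanced = True
    return out, segments


def end_to_end_fusion(
    karyotype: Karyotype,
    recipient_label: str,
    segment: AcentricSegment,
    recipient_arm: Arm,
    _index: int | None = None,
) -> Karyotype:
    """Fuse an acentric segment telomere-to-telomere onto the distal end
    of the recipient's chosen arm.

    The segment's former telomere joins the recipient telomere, so the
    segment's former centromeric end becomes the new arm terminus; a site
    at segment fraction p lands at arm-tip distance p x segment length.
    Arm names renormalize (the fused arm may become the long arm).
    """
    if _index is None:
        _index = _indices_for_label(karyotype, recipient_label, False)[0]
    out = karyotype.copy()
    chrom = out.chromosomes[_index]
    old = chrom.arm_length(recipient_arm)
    new = old + segment.length_um
    sites = []
    for s in chrom.sites:
        if s.arm is recipient_arm:
            frac = s.resolved_frac * old / new
            sites.append(
                replace(s, position_frac=frac, position_class=classify_position(frac))
            )
        else:
            sites.append(s)
    for s in segment.sites:
        frac = (old + segment.length_um * (1.0 - s.resolved_frac)) / new
        sites.append(
            replace(
                s,
                arm=recipient_arm,
                position_frac=frac,
                position_class=classify_position(frac),
            )
        )
    long_um = new if recipient_arm is Arm.LONG else chrom.long_arm_um
    short_um = new if recipient_arm is Arm.SHORT else chrom.short_arm_um
    out.chromosomes[_index] = Chromosome(
        label=chrom.label,
        long_arm_um=long_um,
        short_arm_um=short_um,
        satellite=chrom.satellite,
        sites=tuple(sites),
        genome=chrom.genome,
    )
    return out


def pericentric_inversion(
    karyotype: Karyotype,
    chrom_label: str,
    frac_short: float,
    frac_long: float,
    apply_to_homologues: bool = True,
) -> Karyotype:
    """Invert the segment spanning the centromere between a breakpoint at
    ``frac_short`` on the short arm and ``frac_long`` on the long arm.

    The marked segment reverses in place, carrying the centromere with
    it, so asymmetric breakpoints change the arm lengths (and possibly
    the Levan class) while conserving total length.  Inverting both
    whole arms reverses the entire chromosome, which is an orientation
    flip and leaves arm lengths unchanged.
    """
    if not (0.0 <= frac_short <= 1.0 and 0.0 <= frac_long <= 1.0):
        raise RearrangementError("inversion breakpoint fractions must lie in [0, 1]")
    idx = _indices_for_label(karyotype, chrom_label, apply_to_homologues)
    out = karyotype.copy()
    for i in idx:
        chrom = out.chromosomes[i]
        s_b = frac_short * chrom.short_arm_um
        l_b = frac_long * chrom.long_arm_um
        pivot = l_b - s_b  # segment [-s_b, l_b] maps x -> pivot - x
        coords = [
            (s, pivot - x if -s_b <= x <= l_b else x) for s, x in _site_coords(chrom)
        ]
        out.chromosomes[i] = _rebuild(
            chrom, -chrom.short_arm_um, chrom.long_arm_um, pivot, coords
        )
    return out


def paracentric_inversion(
    karyotype: Karyotype,
    chrom_label: str,
    arm: Arm,
    frac_a: float,
    frac_b: float,
    apply_to_homologues: bool = True,
) -> Karyotype:
    """Invert the within-arm interval [frac_a, frac_b]: site positions in
    the interval are mirrored (p -> frac_a + frac_b - p); arm lengths and
    the centromere are untouched.  Applying the same inversion twice is
    the identity."""
    if not (0.0 <= frac_a < frac_b <= 1.0):
        raise RearrangementError("need 0 <= frac_a < frac_b <= 1")
    idx = _indices_for_label(karyotype, chrom_label, apply_to_homologues)
    out = karyotype.copy()
    for i in idx:
        chrom = out.chromosomes[i]
        sites = []
        for s in chrom.sites:
            f = s.resolved_frac
            if s.arm is arm and frac_a <= f <= frac_b:
                f = frac_a + frac_b - f
                s = replace(s, position_frac=f, position_class=classify_position(f))
            sites.append(s)
        out.chromosomes[i] = replace(chrom, sites=tuple(sites))
    return out


def reciprocal_translocation(
    karyotype: Karyotype,
    label1: str,
    arm1: Arm,
    frac1: float,
    label2: str,
    arm2: Arm,
    frac2: float,
    apply_to_homologues: bool = True,
) -> Karyotype:
    """Exchange the terminal segments distal to the two breakpoints.

    Chromosome number is unchanged, total length is conserved, and sites
    travel with their segments, keeping their distance from the
    breakpoint (centromere-telomere polarity maintained).
    """
    if label1 == label2:
        raise RearrangementError("reciprocal translocation needs two distinct chromosomes")
    idx1 = _indices_for_label(karyotype, label1, apply_to_homologues)
    idx2 = _indices_for_label(karyotype, label2, apply_to_homologues)
    if len(idx1) != len(idx2):
        raise RearrangementError(
            f"homologue counts differ: {label1} x{len(idx1)} vs {label2} x{len(idx2)}"
        )
    out = karyotype.copy()
    for i1, i2 in zip(idx1, idx2):
        c1, c2 = out.chromosomes[i1], out.chromosomes[i2]
        new1, new2 = _translocate_pair(c1, arm1, frac1, c2, arm2, frac2)
        out.chromosomes[i1] = new1
        out.chromosomes[i2] = new2
    return out


def _split_arm(
    chrom: Chromosome, arm: Arm, frac: float
) -> tuple[float, list[RDNASite], list[tuple[RDNASite, float]]]:
    """Proximal retained length, retained sites (all arms), and distal
    sites with offsets from the breakpoint."""
    length = chrom.arm_length(arm)
    cut = frac * length
    retained, distal = [], []
    for s in chrom.sites:
        if s.arm is arm and s.resolved_frac * length > cut:
            distal.append((s, s.resolved_frac * length - cut))
        else:
            retained.append(s)
    return cut, retained, distal


def _graft(
    chrom: Chromosome,
    arm: Arm,
    retained_len: float,
    retained_sites: list[RDNASite],
    incoming_len: float,
    incoming: list[tuple[RDNASite, float]],
) -> Chromosome:
    new_len = retained_len + incoming_len
    sites = []
    for s in retained_sites:
        if s.arm is arm:
            f = s.resolved_frac * chrom.arm_length(arm) / new_len if new_len > 0 else 0.0
            s = replace(s, position_frac=f, position_class=classify_position(f))
        sites.append(s)
    for s, offset in incoming:
        f = (retained_len + offset) / new_len if new_len > 0 else 0.0
        sites.append(
            replace(s, arm=arm, position_frac=f, position_class=classify_position(f))
        )
    long_um = new_len if arm is Arm.LONG else chrom.long_arm_um
    short_um = new_len if arm is Arm.SHORT else chrom.short_arm_um
    return Chromosome(
        label=chrom.label,
        long_arm_um=long_um,
        short_arm_um=short_um,
        satellite=chrom.satellite,
        sites=tuple(sites),
        genome=chrom.genome,
    )


def _translocate_pair(
    c1: Chromosome, arm1: Arm, frac1: float, c2: Chromosome, arm2: Arm, frac2: float
) -> tuple[Chromosome, Chromosome]:
    keep1, sites1, distal1 = _split_arm(c1, arm1, frac1)
    keep2, sites2, distal2 = _split_arm(c2, arm2, frac2)
    give1 = c1.arm_length(arm1) - keep1
    give2 = c2.arm_length(arm2) - keep2
    # retained-site fractions must be rescaled against the OLD arm length,
    # so _graft receives the original chromosome for reference
    new1 = _graft(c1, arm1, keep1, sites1, give2, distal2)
    new2 = _graft(c2, arm2, keep2, sites2, give1, distal1)
    return new1, new2


# ---------------------------------------------------------------------------
# ploidy events


def autopolyploidize(karyotype: Karyotype, factor: int) -> Karyotype:
    """Whole-genome duplication within one genome: every chromosome is
    replicated so the ploidy level multiplies by ``factor``."""
    if factor < 2:
        raise RearrangementError("polyploidization factor must be >= 2")
    if karyotype.unbalanced:
        raise RearrangementError("cannot polyploidize an unbalanced karyotype")
    out = karyotype.copy()
    out.chromosomes = [c for c in karyotype.chromosomes for _ in range(factor)]
    out.ploidy = karyotype.ploidy * factor
    return out


def allopolyploid_merge(
    karyotype1: Karyotype, karyotype2: Karyotype, species: str | None = None
) -> Karyotype:
    """Amphidiploid union of two complements: chromosome sets join,
    ploidies add, and genome labels record parental provenance."""
    if not karyotype2.chromosomes:
        return karyotype1.copy()
    if not karyotype1.chromosomes:
        return karyotype2.copy()
    if karyotype1.unbalanced or karyotype2.unbalanced:
        raise RearrangementError("cannot merge unbalanced karyotypes")
    for parent in (karyotype1, karyotype2):
        if any(c.genome is None for c in parent.chromosomes):
            raise RearrangementError(
                f"{parent.species!r} has unlabelled chromosomes; genome "
                "provenance would be lost in the merger"
            )
    if karyotype1.basic_number_x != karyotype2.basic_number_x:
        raise RearrangementError(
            "amphidiploid parents must share a basic number "
            f"({karyotype1.basic_number_x} vs {karyotype2.basic_number_x})"
        )
    return Karyotype(
        species=species or f"{karyotype1.species} x {karyotype2.species}",
        chromosomes=list(karyotype1.chromosomes) + list(karyotype2.chromosomes),
        ploidy=karyotype1.ploidy + karyotype2.ploidy,
        basic_number_x=karyotype1.basic_number_x,
    )


# ---------------------------------------------------------------------------
# rDNA locus events


@dataclass(frozen=True)
class SiteSelector:
    """Matches rDNA sites by any combination of chromosome label, genome,
    family, arm and position class; unset fields match everything."""

    family: RDNAFamily
    label: str | None = None
    genome: GenomeLabel | None = None
    arm: Arm | None = None
    position_class: PositionClass | None = None

    def matches_chromosome(self, chrom: Chromosome) -> bool:
        if self.label is not None and chrom.label != self.label:
            return False
        if self.genome is not None and chrom.genome is not self.genome:
            return False
        return True

    def matches_site(self, site: RDNASite) -> bool:
        if site.family is not self.family:
            return False
        if self.arm is not None and site.arm is not self.arm:
            return False
        if self.position_class is not None and site.position_class is not self.position_class:
            return False
        return True


def rdna_loss(
    karyotype: Karyotype,
    selector: SiteSelector,
    strict: bool = True,
    limit: int | None = None,
) -> Karyotype:
    """Remove sites matched by the selector (e.g. nucleolar-dominance
    suppression of the 45S loci inherited from one parental genome).
    ``limit`` caps the number of sites removed, in complement order,
    which expresses dosage losses like "one pair of four homologous
    sites".  Chromosome lengths are untouched."""
    out = karyotype.copy()
    removed = 0
    for i, chrom in enumerate(out.chromosomes):
        if not selector.matches_chromosome(chrom):
            continue
        kept = []
        for s in chrom.sites:
            if selector.matches_site(s) and (limit is None or removed < limit):
                removed += 1
            else:
                kept.append(s)
        if len(kept) != len(chrom.sites):
            out.chromosomes[i] = replace(chrom, sites=tuple(kept))
    if removed == 0 and strict:
        raise RearrangementError(f"selector matched no site: {selector}")
    return out


def rdna_gain(
    karyotype: Karyotype,
    chrom_label: str,
    site: RDNASite,
    apply_to_homologues: bool = True,
) -> Karyotype:
    """Add an rDNA site (locus amplification/dispersal) to a chromosome."""
    idx = _indices_for_label(karyotype, chrom_label, apply_to_homologues)
    out = karyotype.copy()
    for i in idx:
        chrom = out.chromosomes[i]
        out.chromosomes[i] = replace(chrom, sites=chrom.sites + (site,))
    return out


# ---------------------------------------------------------------------------
# scenario replay


def _total_length(karyotype: Karyotype, pool: list[AcentricSegment]) -> float:
    return karyotype.total_length_um() + sum(s.length_um for s in pool)


def replay(
    karyotype: Karyotype,
    scenario: Scenario,
    partners: dict[str, Karyotype] | None = None,
) -> tuple[Karyotype, EventLog]:
    """Apply a scenario's events in order and record what happened.

    Acentric segments produced by fissions wait in a pool until a fusion
    event claims them by origin label and arm; when homologue application
    is on, a fusion consumes one matching segment per homologue of the
    recipient.  ``partners`` resolves the parent karyotypes referenced by
    ALLOPOLYPLOID_MERGE events.  After the last event the complement is
    re-balanced if possible: with an empty pool and 2n divisible by the
    ploidy, the basic number is recomputed (this is how a dysploid
    scenario turns x = 7 into x = 6).
    """
    state = karyotype.copy()
    pool: list[AcentricSegment] = []
    log: EventLog = []
    for event in scenario.events:
        before = _total_length(state, pool)
        p = dict(event.params)
        kind = event.kind
        consumed: tuple[str, ...] = ()
        produced: tuple[str, ...] = ()
        moved = 0
        if kind is EventKind.FISSION_PERICENTROMERIC:
            state, segments = fission_pericentromeric(
                state,
                p["chrom_label"],
                p.get("break_frac", 0.0),
                scenario.apply_to_homologues,
            )
            pool.extend(segments)
            consumed = (p["chrom_label"],)
            produced = tuple(f"{s.origin_label}:{s.origin_arm.value}" for s in segments)
            moved = sum(len(s.sites) for s in segments)
        elif kind is EventKind.END_TO_END_FUSION:
            origin = p["segment_origin"]
            seg_arm = Arm(p["segment_arm"])
            rec_arm = Arm(p["recipient_arm"])
            matches = [
                s for s in pool if s.origin_label == origin and s.origin_arm is seg_arm
            ]
            targets = _indices_for_label(
                state, p["recipient_label"], scenario.apply_to_homologues
            )
            if not scenario.apply_to_homologues:
                targets = targets[:1]
                matches = matches[:1]
            if len(matches) < len(targets):
                raise RearrangementError(
                    f"{len(targets)} recipients {p['recipient_label']!r} but only "
                    f"{len(matches)} unfused segments from {origin}:{seg_arm.value}"
                )
            for seg, i in zip(matches, targets):
                state = end_to_end_fusion(
                    state, p["recipient_label"], seg, rec_arm, _index=i
                )
                pool.remove(seg)
                moved += len(seg.sites)
            consumed = tuple(f"{origin}:{seg_arm.value}" for _ in targets)
            produced = (p["recipient_label"],)
        elif kind is EventKind.PERICENTRIC_INVERSION:
            state = pericentric_inversion(
                state,
                p["chrom_label"],
                p["frac_short"],
                p["frac_long"],
                scenario.apply_to_homologues,
            )
            consumed = produced = (p["chrom_label"],)
        elif kind is EventKind.PARACENTRIC_INVERSION:
            state = paracentric_inversion(
                state,
                p["chrom_label"],
                Arm(p["arm"]),
                p["frac_a"],
                p["frac_b"],
                scenario.apply_to_homologues,
            )
            consumed = produced = (p["chrom_label"],)
        elif kind is EventKind.RECIPROCAL_TRANSLOCATION:
            state = reciprocal_translocation(
                state,
                p["label1"],
                Arm(p["arm1"]),
                p["frac1"],
                p["label2"],
                Arm(p["arm2"]),
                p["frac2"],
                scenario.apply_to_homologues,
            )
            consumed = produced = (p["label1"], p["label2"])
        elif kind is EventKind.AUTOPOLYPLOIDY:
            state = autopolyploidize(state, p["factor"])
        elif kind is EventKind.ALLOPOLYPLOID_MERGE:
            partner_name = p["partner"]
            if partners is None or partner_name not in partners:
                raise RearrangementError(
                    f"merge partner {partner_name!r} not provided to replay()"
                )
            state = allopolyploid_merge(
                state, partners[partner_name], species=p.get("species")
            )
            consumed = (partner_name,)
        elif kind is EventKind.RDNA_LOSS:
            selector = SiteSelector(
                family=RDNAFamily(p["family"]),
                label=p.get("label"),
                genome=GenomeLabel(p["genome"]) if p.get("genome") else None,
                arm=Arm(p["arm"]) if p.get("arm") else None,
                position_class=(
                    PositionClass(p["position_class"]) if p.get("position_class") else None
                ),
            )
            state = rdna_loss(
                state, selector, strict=p.get("strict", True), limit=p.get("limit")
            )
        elif kind is EventKind.RDNA_GAIN:
            site = RDNASite(
                family=RDNAFamily(p["family"]),
                arm=Arm(p["arm"]),
                position_class=PositionClass(p["position_class"]),
                position_frac=p.get("position_frac"),
            )
            state = rdna_gain(state, p["chrom_label"], site, scenario.apply_to_homologues)
            produced = (p["chrom_label"],)
        else:  # pragma: no cover - exhaustive enum
            raise RearrangementError(f"unknown event kind {kind}")
        log.append(
            EventRecord(
                kind=kind,
                params=dict(event.params),
                consumed=consumed,
                produced=produced,
                length_before_um=before,
                length_after_um=_total_length(state, pool),
                sites_moved=moved,
            )
        )
    if not pool and state.somatic_number_2n % state.ploidy == 0:
        state.basic_number_x = state.somatic_number_2n // state.ploidy
        state.unbalanced = False
    return state, log


# ---------------------------------------------------------------------------
# scenario (de)serialization


def scenario_from_json(path: str | Path) -> Scenario:
    """Load a scenario from a JSON file: an object with ``name``,
    optional ``apply_to_homologues`` and an ``events`` array of
    ``{"kind": ..., <params>}`` objects (or a bare events array)."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if isinstance(doc, list):
        doc = {"name": Path(path).stem, "events": doc}
    events = []
    for obj in doc["events"]:
        obj = dict(obj)
        obj.pop("note", None)
        kind = EventKind(obj.pop("kind"))
        events.append(RearrangementEvent(kind=kind, params=obj))
    return Scenario(
        name=doc.get("name", Path(path).stem),
        events=events,
        apply_to_homologues=doc.get("apply_to_homologues", True),
    )


_BUILTIN_SCENARIOS = {
    "FIG4_DYSPLOIDY": "fig4_dysploidy.json",
    "P_PARADOXA": "p_paradoxa.json",
    "P_ARUNDINACEA": "p_arundinacea.json",
    "P_AQUATICA": "p_aquatica.json",
    "P_MINOR": "p_minor.json",
    "HYBRID_ARUN_X_AQUA": "hybrid_arun_x_aqua.json",
}


def builtin_scenario(name: str) -> Scenario:
    """Load one of the packaged scenarios by name (e.g. FIG4_DYSPLOIDY,
    the descending-dysploidy pathway from the all-metacentric x = 7
    ancestor to the extant x = 6 karyotype)."""
    try:
        fname = _BUILTIN_SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(_BUILTIN_SCENARIOS))}"
        ) from None
    from importlib import resources

    with resources.as_file(
        resources.files("karyokit").joinpath(f"data/scenarios/{fname}")
    ) as path:
        return scenario_from_json(path)
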