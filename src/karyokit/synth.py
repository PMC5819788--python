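"""Synthetic karyotypes: a parametric generator, a microscopy-style
noise model, and reconstructed fixtures for the eight canary grass
(*Phalaris*) karyotypes plus the hypothesized ancestral complements.

Published karyotype tables print summary statistics (2n, total monoploid
length, asymmetry indices) and rDNA signal counts, but not the underlying
per-chromosome arm lengths.  The fixtures therefore *reconstruct* arm
lengths by design: chromosome number, ploidy, genome labels and every
rDNA signal count match the published complement exactly, total
monoploid length is rescaled to the published value, and the qualitative
morphology composition (which chromosomes are metacentric versus
sub(meta/telo)centric, which arm carries which band) follows the
idiogram descriptions.  Absolute arm lengths beyond that are synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import (
    Arm,
    Chromosome,
    GenomeLabel,
    Karyotype,
    PositionClass,
    POSITION_BINS,
    RDNAFamily,
    RDNASite,
    Satellite,
    classify_position,
)

# ---------------------------------------------------------------------------
# generator


@dataclass(frozen=True)
class SitePlan:
    """Place ``pairs`` homologue pairs carrying ``sites_per_chromosome``
    sites of one family on the given arm/position class."""

    family: RDNAFamily
    pairs: int
    arm: Arm
    position_class: PositionClass
    sites_per_chromosome: int = 1


@dataclass(frozen=True)
class GeneratorParams:
    basic_number: int
    ploidy: int = 2
    mean_chrom_len_um: float = 5.0
    cv_target: float = 0.15
    # arm ratio r = 1 + lognormal(log_loc, log_scale), support [1, inf)
    arm_ratio_log_loc: float = -1.5
    arm_ratio_log_scale: float = 0.4
    rdna_plan: tuple[SitePlan, ...] = ()
    genome: GenomeLabel | None = None
    species: str = "synthetic"
    label_prefix: str = "S"
    seed: int = 0


@dataclass(frozen=True)
class NoiseParams:
    """Measurement-style noise: independent multiplicative log-normal
    error on each arm length, random loss of faint signals, and jitter
    of band positions along the arm."""

    length_noise_cv: float = 0.05
    site_dropout_prob: float = 0.02
    position_jitter_sd: float = 0.03


def generate(params: GeneratorParams) -> Karyotype:
    """Generate a balanced karyotype: 2n = ploidy x basic number,
    homologues identical before any noise, chromosome lengths rescaled so
    the empirical length CV equals the target, and rDNA sites placed
    uniformly within their class bin.  Deterministic given the seed.
    """
    x = params.basic_number
    site_pairs_needed = sum(p.pairs for p in params.rdna_plan)
    if site_pairs_needed > x:
        raise ValueError(
            f"rDNA plan needs {site_pairs_needed} bearing pairs but only "
            f"{x} chromosome pairs exist"
        )
    rng = np.random.default_rng(params.seed)
    lengths = np.full(x, float(params.mean_chrom_len_um))
    if params.cv_target > 0 and x > 1:
        z = rng.standard_normal(x)
        z = (z - z.mean()) / (z.std(ddof=1) or 1.0)
        lengths = params.mean_chrom_len_um * (1.0 + params.cv_target * z)
        floor = 0.05 * params.mean_chrom_len_um
        lengths = np.maximum(lengths, floor)
    lengths = np.sort(lengths)[::-1]
    ratios = 1.0 + rng.lognormal(params.arm_ratio_log_loc, params.arm_ratio_log_scale, x)

    monoploid: list[Chromosome] = []
    for i in range(x):
        total, r = float(lengths[i]), float(ratios[i])
        short = total / (1.0 + r)
        monoploid.append(
            Chromosome(
                label=f"{params.label_prefix}{i + 1}",
                long_arm_um=total - short,
                short_arm_um=short,
                genome=params.genome,
            )
        )
    cursor = 0
    for plan in params.rdna_plan:
        lo, hi = POSITION_BINS[plan.position_class]
        for _ in range(plan.pairs):
            chrom = monoploid[cursor]
            sites = tuple(
                RDNASite(
                    plan.family,
                    plan.arm,
                    plan.position_class,
                    float(rng.uniform(lo, hi)),
                )
                for _ in range(plan.sites_per_chromosome)
            )
            monoploid[cursor] = replace(chrom, sites=chrom.sites + sites)
            cursor += 1
    return Karyotype(
        species=params.species,
        chromosomes=[c for c in monoploid for _ in range(params.ploidy)],
        ploidy=params.ploidy,
        basic_number_x=x,
    )


def perturb(karyotype: Karyotype, noise: NoiseParams, seed: int) -> Karyotype:
    """Apply measurement noise; homologues are perturbed independently
    (each is a separate measurement on the metaphase plate)."""
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise.length_noise_cv**2)))
    out = karyotype.copy()
    for i, chrom in enumerate(out.chromosomes):
        long_um = chrom.long_arm_um * float(np.exp(rng.normal(0.0, sigma))) if sigma else chrom.long_arm_um
        short_um = chrom.short_arm_um * float(np.exp(rng.normal(0.0, sigma))) if sigma else chrom.short_arm_um
        sites = []
        for s in chrom.sites:
            if noise.site_dropout_prob and rng.random() < noise.site_dropout_prob:
                continue
            if noise.position_jitter_sd:
                frac = float(
                    np.clip(s.resolved_frac + rng.normal(0.0, noise.position_jitter_sd), 0.0, 1.0)
                )
                s = replace(s, position_frac=frac, position_class=classify_position(frac))
            sites.append(s)
        out.chromosomes[i] = Chromosome(
            label=chrom.label,
            long_arm_um=long_um,
            short_arm_um=short_um,
            satellite=chrom.satellite,
            sites=tuple(sites),
            genome=chrom.genome,
        )
    return out


# ---------------------------------------------------------------------------
# fixtures


_S5 = RDNAFamily.FIVE_S
_S45 = RDNAFamily.FORTYFIVE_S


def _site(family: RDNAFamily, arm: Arm, frac: float) -> RDNASite:
    return RDNASite(family, arm, classify_position(frac), frac)


def _pair(
    label: str,
    genome: GenomeLabel | None,
    long_um: float,
    short_um: float,
    sites: tuple[RDNASite, ...] = (),
    satellite: Satellite | None = None,
    copies: int = 2,
    per_copy_sites: dict[int, tuple[RDNASite, ...]] | None = None,
) -> list[Chromosome]:
    """Expand one homologue group; ``per_copy_sites`` overrides the site
    list of individual homologues (hemizygous or diverged loci)."""
    out = []
    for i in range(copies):
        copy_sites = sites
        if per_copy_sites is not None and i in per_copy_sites:
            copy_sites = per_copy_sites[i]
        out.append(
            Chromosome(
                label=label,
                long_arm_um=long_um,
                short_arm_um=short_um,
                satellite=satellite,
                sites=copy_sites,
                genome=genome,
            )
        )
    return out


def _scaled(chroms: list[Chromosome], factor: float) -> list[Chromosome]:
    return [
        replace(c, long_arm_um=c.long_arm_um * factor, short_arm_um=c.short_arm_um * factor)
        for c in chroms
    ]


def _scale_to_tml(chroms: list[Chromosome], ploidy: int, tml_target: float) -> list[Chromosome]:
    tml_now = sum(c.total_length_um for c in chroms) / ploidy
    return _scaled(chroms, tml_target / tml_now)


def _brachystachys() -> Karyotype:
    A = GenomeLabel.A
    chroms = (
        _pair("A1", A, 3.1, 2.4, (_site(_S45, Arm.SHORT, 0.85),), Satellite(Arm.SHORT, 0.80))
        + _pair("A2", A, 3.9, 1.2, (_site(_S5, Arm.LONG, 0.82), _site(_S5, Arm.LONG, 0.90)))
        + _pair("A3", A, 2.6, 2.2)
        + _pair("A4", A, 2.4, 2.0)
        + _pair("A5", A, 2.2, 1.9)
        + _pair("A6", A, 3.7, 1.5)
    )
    return Karyotype("P. brachystachys", _scale_to_tml(chroms, 2, 50.2), 2, 6)


def _canariensis() -> Karyotype:
    A = GenomeLabel.A
    chroms = (
        _pair("A1", A, 2.9, 2.2, (_site(_S45, Arm.SHORT, 0.88),), Satellite(Arm.SHORT, 0.82))
        + _pair("A2", A, 4.1, 1.0, (_site(_S5, Arm.LONG, 0.80), _site(_S5, Arm.LONG, 0.92)))
        + _pair("A3", A, 2.5, 2.0)
        + _pair("A4", A, 2.3, 1.9)
        + _pair("A5", A, 2.1, 1.7)
        + _pair("A6", A, 3.9, 1.1)
    )
    return Karyotype("P. canariensis", _scale_to_tml(chroms, 2, 35.0), 2, 6)


def _paradoxa() -> Karyotype:
    B = GenomeLabel.B
    chroms = (
        _pair("B1", B, 2.6, 2.2, (_site(_S45, Arm.LONG, 0.50),))
        + _pair("B2", B, 2.4, 2.1, (_site(_S5, Arm.SHORT, 0.45),))
        + _pair("B3", B, 2.3, 2.0)
        + _pair("B4", B, 2.2, 1.9)
        + _pair("B5", B, 2.1, 1.8)
        + _pair("B6", B, 2.0, 1.7)
        + _pair("B7", B, 1.9, 1.5)
    )
    return Karyotype("P. paradoxa", _scale_to_tml(chroms, 2, 30.3), 2, 7)


def _coerulescens() -> Karyotype:
    B = GenomeLabel.B
    chroms = (
        _pair("B1", B, 4.3, 3.0, (_site(_S45, Arm.LONG, 0.55),))
        + _pair("B2", B, 4.5, 2.8, (_site(_S5, Arm.LONG, 0.50),))
        # the third 5S locus is hemizygous: present on one B3 homologue only
        + _pair("B3", B, 4.0, 2.7, (), per_copy_sites={0: (_site(_S5, Arm.LONG, 0.85),)})
        + _pair("B4", B, 3.8, 2.6)
        + _pair("B5", B, 3.6, 2.5)
        + _pair("B6", B, 3.4, 2.4)
        + _pair("B7", B, 3.0, 2.5)
    )
    return Karyotype("P. coerulescens", _scale_to_tml(chroms, 2, 49.6), 2, 7)


def _caroliniana() -> Karyotype:
    B = GenomeLabel.B
    chroms = (
        _pair("B1", B, 3.9, 3.0, (_site(_S45, Arm.SHORT, 0.50),), copies=4)
        + _pair(
            "B2", B, 3.7, 2.9, (_site(_S5, Arm.LONG, 0.85),), copies=4,
            per_copy_sites={2: (_site(_S5, Arm.SHORT, 0.82),), 3: (_site(_S5, Arm.SHORT, 0.82),)},
        )
        + _pair("B3", B, 3.5, 2.8, copies=4)
        + _pair("B4", B, 3.3, 2.6, copies=4)
        + _pair("B5", B, 3.1, 2.4, copies=4)
        + _pair("B6", B, 2.9, 2.2, copies=4)
        + _pair("B7", B, 2.7, 2.0, copies=4)
    )
    return Karyotype("P. caroliniana", _scale_to_tml(chroms, 4, 47.6), 4, 7)


def _arundinacea() -> Karyotype:
    B = GenomeLabel.B
    chroms = (
        # two 45S pairs diverged by a pericentric inversion: two homologues
        # intercalary, two proximal beside the secondary constriction
        _pair(
            "B1", B, 3.8, 2.9, (_site(_S45, Arm.SHORT, 0.50),), copies=4,
            per_copy_sites={
                2: (_site(_S45, Arm.SHORT, 0.15),),
                3: (_site(_S45, Arm.SHORT, 0.15),),
            },
        )
        + _pair(
            "B2", B, 3.6, 2.8, (_site(_S5, Arm.LONG, 0.45),), copies=4,
            per_copy_sites={2: (), 3: ()},  # one 5S pair was lost
        )
        + _pair("B3", B, 3.4, 2.7, copies=4)
        + _pair("B4", B, 3.2, 2.5, copies=4)
        + _pair("B5", B, 3.0, 2.3, copies=4)
        + _pair("B6", B, 2.8, 2.1, copies=4)
        + _pair("B7", B, 2.6, 1.9, copies=4)
    )
    return Karyotype("P. arundinacea", _scale_to_tml(chroms, 4, 46.0), 4, 7)


def _aquatica() -> Karyotype:
    B, C = GenomeLabel.B, GenomeLabel.C
    b_chroms = (
        _pair("B1", B, 4.0, 3.1, (_site(_S45, Arm.SHORT, 0.50),))
        + _pair(
            "B2", B, 3.8, 3.0, (_site(_S5, Arm.LONG, 0.85),),
            per_copy_sites={1: (_site(_S5, Arm.LONG, 0.45),)},
        )
        + _pair("B3", B, 3.6, 2.9)
        + _pair("B4", B, 3.4, 2.7)
        + _pair("B5", B, 3.2, 2.5)
        + _pair("B6", B, 3.0, 2.3)
        + _pair("B7", B, 2.8, 2.1)
    )
    c_chroms = (
        _pair("C1", C, 3.9, 3.2, (_site(_S45, Arm.SHORT, 0.12),), Satellite(Arm.SHORT, 0.08))
        + _pair("C2", C, 3.7, 3.1, (_site(_S5, Arm.LONG, 0.40), _site(_S5, Arm.LONG, 0.62)))
        + _pair("C3", C, 3.5, 3.0, (_site(_S5, Arm.LONG, 0.35), _site(_S5, Arm.SHORT, 0.55)))
        + _pair(
            "C4", C, 3.3, 2.8,
            (_site(_S5, Arm.SHORT, 0.15), _site(_S5, Arm.LONG, 0.20)),
            per_copy_sites={1: ()},
        )
        + _pair("C5", C, 3.1, 2.6)
        + _pair("C6", C, 2.9, 2.4)
        + _pair("C7", C, 2.7, 2.2)
    )
    chroms = _scale_to_tml(b_chroms, 2, 49.3) + _scale_to_tml(c_chroms, 2, 49.9)
    return Karyotype("P. aquatica", chroms, 4, 7)


def _minor() -> Karyotype:
    B, C = GenomeLabel.B, GenomeLabel.C
    b_chroms = (
        _pair("B1", B, 3.1, 2.4, (_site(_S45, Arm.SHORT, 0.50),))
        + _pair("B2", B, 2.9, 2.3, (_site(_S5, Arm.LONG, 0.45),))
        + _pair("B3", B, 2.8, 2.2, (_site(_S5, Arm.LONG, 0.40),))
        + _pair("B4", B, 2.7, 2.1)
        + _pair("B5", B, 2.5, 2.0)
        + _pair("B6", B, 2.3, 1.9)
        + _pair("B7", B, 2.1, 1.7)
    )
    # the 45S locus inherited from the C parent was silenced and lost
    c_chroms = (
        _pair("C1", C, 3.0, 2.5)
        + _pair("C2", C, 2.9, 2.4, (_site(_S5, Arm.LONG, 0.38),))
        + _pair("C3", C, 2.8, 2.3, (_site(_S5, Arm.LONG, 0.55),))
        + _pair("C4", C, 2.6, 2.2, (_site(_S5, Arm.SHORT, 0.45),))
        + _pair("C5", C, 2.4, 2.1, (_site(_S5, Arm.SHORT, 0.20),))
        + _pair("C6", C, 2.3, 1.9, (_site(_S5, Arm.LONG, 0.85), _site(_S5, Arm.LONG, 0.45)))
        + _pair("C7", C, 2.1, 1.6)
    )
    chroms = _scale_to_tml(b_chroms, 2, 38.9) + _scale_to_tml(c_chroms, 2, 38.9)
    return Karyotype("P. minor", chroms, 4, 7)


def proto_a() -> Karyotype:
    """The hypothesized all-metacentric x = 7 ancestor of the A-genome
    lineage: proto-A7 carries a centromere-proximal 5S on its long arm
    (the chromosome that fissions), proto-A2 a subtelomeric 5S, and
    proto-A1 the subtelomeric short-arm 45S retained by extant A1."""
    A = GenomeLabel.A
    chroms = (
        _pair("A1", A, 4.0, 4.0, (_site(_S45, Arm.SHORT, 0.85),), Satellite(Arm.SHORT, 0.80))
        + _pair("A2", A, 3.0, 3.0, (_site(_S5, Arm.LONG, 0.85),))
        + _pair("A3", A, 3.5, 3.5)
        + _pair("A4", A, 3.25, 3.25)
        + _pair("A5", A, 3.0, 3.0)
        + _pair("A6", A, 2.8, 2.8)
        + _pair("A7", A, 3.0, 3.0, (_site(_S5, Arm.LONG, 0.10),))
    )
    return Karyotype("PROTO_A", chroms, 2, 7)


def ancestral_b() -> Karyotype:
    """Putative ancestral x = 7 B-genome diploid (close to the extant
    *P. coerulescens* pattern): intercalary 45S on B1, intercalary 5S on
    B2, subtelomeric 5S on B3."""
    B = GenomeLabel.B
    chroms = (
        _pair("B1", B, 3.5, 2.9, (_site(_S45, Arm.LONG, 0.55),))
        + _pair("B2", B, 3.3, 2.8, (_site(_S5, Arm.LONG, 0.50),))
        + _pair("B3", B, 3.1, 2.6, (_site(_S5, Arm.LONG, 0.85),))
        + _pair("B4", B, 2.9, 2.4)
        + _pair("B5", B, 2.7, 2.2)
        + _pair("B6", B, 2.5, 2.0)
        + _pair("B7", B, 2.3, 1.8)
    )
    return Karyotype("ANCESTRAL_B", chroms, 2, 7)


SPECIES_ORDER = (
    "P. brachystachys",
    "P. canariensis",
    "P. aquatica",
    "P. minor",
    "P. paradoxa",
    "P. caroliniana",
    "P. coerulescens",
    "P. arundinacea",
)


def fixtures() -> dict[str, Karyotype]:
    """All packaged karyotypes: the eight studied species plus the
    PROTO_A and ANCESTRAL_B reconstructions."""
    ks = [
        _brachystachys(),
        _canariensis(),
        _aquatica(),
        _minor(),
        _paradoxa(),
        _caroliniana(),
        _coerulescens(),
        _arundinacea(),
        proto_a(),
        ancestral_b(),
    ]
    return {k.species: k for k in ks}
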