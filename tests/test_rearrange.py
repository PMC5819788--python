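import io
import random

import pytest

from karyokit.io import write_karyotypes
from karyokit.model import (
    Arm,
    Chromosome,
    Karyotype,
    MorphologyClass,
    PositionClass,
    RDNAFamily,
    RDNASite,
    classify_morphology,
    classify_position,
)
from karyokit.rearrange import (
    RearrangementError,
    Scenario,
    SiteSelector,
    allopolyploid_merge,
    autopolyploidize,
    builtin_scenario,
    end_to_end_fusion,
    fission_pericentromeric,
    paracentric_inversion,
    pericentric_inversion,
    rdna_loss,
    reciprocal_translocation,
    replay,
)
from karyokit.stats import count_rdna, mca
from karyokit.synth import proto_a
from karyokit.genomes import template_karyotype
from karyokit.model import GenomeLabel


def site(fam, arm, frac):
    return RDNASite(fam, arm, classify_position(frac), frac)


def chrom(L, S, label="X1", sites=()):
    return Chromosome(label=label, long_arm_um=L, short_arm_um=S, sites=sites)


def diploid(pairs):
    chroms = [c for c in pairs for _ in (0, 1)]
    return Karyotype("t", list(chroms), ploidy=2, basic_number_x=len(pairs))


class TestFission:
    def test_ambiguous_label_without_homologue_mode_raises(self):
        k = diploid(
            [chrom(3.0, 3.0, "A7", sites=(site(RDNAFamily.FIVE_S, Arm.LONG, 0.1),))]
        )
        with pytest.raises(RearrangementError, match="ambiguous"):
            fission_pericentromeric(k, "A7", apply_to_homologues=False)

    def test_homologue_symmetry(self):
        k = diploid(
            [
                chrom(3.0, 3.0, "A7", sites=(site(RDNAFamily.FIVE_S, Arm.LONG, 0.1),)),
                chrom(2.0, 2.0, "A1"),
            ]
        )
        out, segments = fission_pericentromeric(k, "A7")
        assert out.somatic_number_2n == k.somatic_number_2n - 2
        assert out.unbalanced
        assert len(segments) == 4
        long_segs = [s for s in segments if s.origin_arm is Arm.LONG]
        assert all(s.length_um == pytest.approx(3.0) for s in segments)
        # the 5S travels with the long-arm segment, near its centromeric end
        assert all(s.sites and s.sites[0].resolved_frac == pytest.approx(0.1) for s in long_segs)
        # chromatin conserved: segments account for the removed chromosomes
        assert sum(s.length_um for s in segments) + out.total_length_um() == pytest.approx(
            k.total_length_um()
        )

    def test_unknown_label_raises(self):
        k = diploid([chrom(2.0, 2.0, "A1")])
        with pytest.raises(RearrangementError):
            fission_pericentromeric(k, "A9")

    def test_paracentromeric_offset_unsupported(self):
        k = diploid([chrom(2.0, 2.0, "A1")])
        with pytest.raises(RearrangementError):
            fission_pericentromeric(k, "A1", break_frac=0.1)


class TestFusion:
    def test_segment_extends_recipient_arm(self):
        k = diploid([chrom(2.0, 2.0, "A2"), chrom(3.0, 3.0, "A7")])
        k2, segments = fission_pericentromeric(k, "A7")
        seg = [s for s in segments if s.origin_arm is Arm.LONG][0]
        fused = end_to_end_fusion(k2, "A2", seg, Arm.LONG, _index=0)
        target = fused.chromosomes[0]
        assert (target.long_arm_um, target.short_arm_um) == (pytest.approx(5.0), pytest.approx(2.0))
        assert classify_morphology(target) is MorphologyClass.sm  # r = 2.5

    def test_site_lands_distal_after_telomere_join(self):
        seg_site = site(RDNAFamily.FIVE_S, Arm.LONG, 0.1)
        k = diploid([chrom(3.0, 3.0, "A2"), chrom(3.0, 3.0, "A7", sites=(seg_site,))])
        k2, segments = fission_pericentromeric(k, "A7")
        seg = [s for s in segments if s.origin_arm is Arm.LONG][0]
        fused = end_to_end_fusion(k2, "A2", seg, Arm.LONG, _index=0)
        (moved,) = fused.chromosomes[0].sites
        # former centromere-proximal position p=0.1 ends near the new terminus
        assert moved.resolved_frac == pytest.approx((3.0 + 3.0 * 0.9) / 6.0)
        assert moved.position_class is PositionClass.TELOMERIC

    def test_replay_rejects_segment_shortage(self):
        k = diploid([chrom(2.0, 2.0, "A2"), chrom(3.0, 3.0, "A7")])
        scenario = Scenario(
            "double-fuse",
            [
                builtin_scenario("FIG4_DYSPLOIDY").events[0],  # fission A7
                builtin_scenario("FIG4_DYSPLOIDY").events[1],  # fuse LONG onto A2
                builtin_scenario("FIG4_DYSPLOIDY").events[1],  # reuse: pool exhausted
            ],
        )
        with pytest.raises(RearrangementError, match="unfused segments"):
            replay(k, scenario)


class TestPericentricInversion:
    def test_zero_breakpoints_identity(self):
        k = diploid([chrom(5.0, 2.0, "B1", sites=(site(RDNAFamily.FIVE_S, Arm.LONG, 0.6),))])
        out = pericentric_inversion(k, "B1", 0.0, 0.0)
        assert out.chromosomes == k.chromosomes

    def test_whole_chromosome_inversion_is_orientation_flip(self):
        k = diploid([chrom(5.0, 2.0, "B1", sites=(site(RDNAFamily.FIVE_S, Arm.SHORT, 0.5),))])
        out = pericentric_inversion(k, "B1", 1.0, 1.0)
        c = out.chromosomes[0]
        assert (c.long_arm_um, c.short_arm_um) == (pytest.approx(5.0), pytest.approx(2.0))
        (s,) = c.sites
        assert s.arm is Arm.SHORT and s.resolved_frac == pytest.approx(0.5)

    def test_asymmetric_breakpoints_move_centromere(self):
        # arms (6, 3); invert whole short arm + 1.2 um of the long arm:
        # pivot lands 1.8 um into the old short arm -> arms become (7.8, 1.2)
        k = diploid([chrom(6.0, 3.0, "A2", sites=(site(RDNAFamily.FIVE_S, Arm.SHORT, 0.85),))])
        out = pericentric_inversion(k, "A2", 1.0, 0.2)
        c = out.chromosomes[0]
        assert c.long_arm_um == pytest.approx(7.8)
        assert c.short_arm_um == pytest.approx(1.2)
        (s,) = c.sites
        # old coordinate -2.55 reverses to +0.75, i.e. 2.55 um from the new
        # centromere on the long arm
        assert s.arm is Arm.LONG
        assert s.resolved_frac == pytest.approx(2.55 / 7.8)

    def test_total_length_conserved_on_random_cases(self):
        rng = random.Random(99)
        for _ in range(300):
            L, S = rng.uniform(1, 8), rng.uniform(0.5, 8)
            k = diploid([chrom(L, S, "B1")])
            out = pericentric_inversion(k, "B1", rng.random(), rng.random())
            assert out.total_length_um() == pytest.approx(k.total_length_um(), rel=1e-12)

    def test_out_of_range_rejected(self):
        k = diploid([chrom(5.0, 2.0, "B1")])
        with pytest.raises(RearrangementError):
            pericentric_inversion(k, "B1", 1.2, 0.0)


class TestParacentricInversion:
    def test_mirror_and_rebinning(self):
        k = diploid([chrom(5.0, 2.0, "B1", sites=(site(RDNAFamily.FIVE_S, Arm.LONG, 0.9),))])
        out = paracentric_inversion(k, "B1", Arm.LONG, 0.5, 1.0)
        (s,) = out.chromosomes[0].sites
        assert s.resolved_frac == pytest.approx(0.6)
        assert s.position_class is PositionClass.INTERCALARY

    def test_interval_without_sites_is_noop(self):
        k = diploid([chrom(5.0, 2.0, "B1", sites=(site(RDNAFamily.FIVE_S, Arm.LONG, 0.9),))])
        out = paracentric_inversion(k, "B1", Arm.LONG, 0.1, 0.4)
        assert out.chromosomes == k.chromosomes

    def test_involution(self):
        k = diploid([chrom(5.0, 2.0, "B1", sites=(site(RDNAFamily.FIVE_S, Arm.LONG, 0.9),))])
        once = paracentric_inversion(k, "B1", Arm.LONG, 0.5, 1.0)
        twice = paracentric_inversion(once, "B1", Arm.LONG, 0.5, 1.0)
        assert twice.chromosomes == k.chromosomes


class TestReciprocalTranslocation:
    def test_equal_segments_swap_sites_only(self):
        s1 = site(RDNAFamily.FIVE_S, Arm.LONG, 0.9)
        s2 = site(RDNAFamily.FORTYFIVE_S, Arm.LONG, 0.9)
        k = diploid([chrom(4.0, 2.0, "B1", sites=(s1,)), chrom(4.0, 3.0, "B2", sites=(s2,))])
        out = reciprocal_translocation(k, "B1", Arm.LONG, 0.8, "B2", Arm.LONG, 0.8)
        c1 = [c for c in out.chromosomes if c.label == "B1"][0]
        c2 = [c for c in out.chromosomes if c.label == "B2"][0]
        assert c1.long_arm_um == pytest.approx(4.0)
        assert c2.long_arm_um == pytest.approx(4.0)
        assert c1.sites[0].family is RDNAFamily.FORTYFIVE_S
        assert c2.sites[0].family is RDNAFamily.FIVE_S

    def test_full_retention_is_identity(self):
        k = diploid([chrom(4.0, 2.0, "B1"), chrom(4.0, 3.0, "B2")])
        out = reciprocal_translocation(k, "B1", Arm.LONG, 1.0, "B2", Arm.LONG, 1.0)
        assert out.chromosomes == k.chromosomes

    def test_total_length_conserved_on_random_cases(self):
        rng = random.Random(5)
        for _ in range(300):
            k = diploid(
                [
                    chrom(rng.uniform(1, 8), rng.uniform(0.5, 8), "B1"),
                    chrom(rng.uniform(1, 8), rng.uniform(0.5, 8), "B2"),
                ]
            )
            arm1 = Arm.LONG if rng.random() < 0.5 else Arm.SHORT
            arm2 = Arm.LONG if rng.random() < 0.5 else Arm.SHORT
            out = reciprocal_translocation(k, "B1", arm1, rng.random(), "B2", arm2, rng.random())
            assert out.total_length_um() == pytest.approx(k.total_length_um(), rel=1e-12)
            assert out.somatic_number_2n == k.somatic_number_2n

    def test_same_chromosome_rejected(self):
        k = diploid([chrom(4.0, 2.0, "B1")])
        with pytest.raises(RearrangementError):
            reciprocal_translocation(k, "B1", Arm.LONG, 0.5, "B1", Arm.SHORT, 0.5)


class TestPloidyEvents:
    def test_autopolyploid_doubling_and_tripling(self):
        b = template_karyotype(GenomeLabel.B)
        assert autopolyploidize(b, 2).somatic_number_2n == 28
        assert autopolyploidize(b, 3).somatic_number_2n == 42
        assert autopolyploidize(b, 2).ploidy == 4

    def test_factor_one_rejected(self):
        with pytest.raises(RearrangementError):
            autopolyploidize(template_karyotype(GenomeLabel.B), 1)

    def test_merge_of_diploids(self):
        merged = allopolyploid_merge(
            template_karyotype(GenomeLabel.B), template_karyotype(GenomeLabel.C), "BC"
        )
        assert merged.somatic_number_2n == 28
        assert merged.ploidy == 4
        assert merged.species == "BC"

    def test_merge_of_tetraploids_gives_octoploid(self, fx):
        merged = allopolyploid_merge(fx["P. arundinacea"], fx["P. aquatica"])
        assert merged.somatic_number_2n == 56
        assert merged.ploidy == 8

    def test_merge_with_empty_is_identity(self):
        b = template_karyotype(GenomeLabel.B)
        empty = Karyotype("none", [], ploidy=2, basic_number_x=7, unbalanced=True)
        assert allopolyploid_merge(b, empty).chromosomes == b.chromosomes

    def test_merge_rejects_unlabelled_parent(self):
        plain = diploid([chrom(2.0, 1.0, "Z1")])
        with pytest.raises(RearrangementError):
            allopolyploid_merge(template_karyotype(GenomeLabel.B), plain)


class TestRdnaEvents:
    def test_loss_by_genome_selector(self):
        merged = allopolyploid_merge(
            template_karyotype(GenomeLabel.B), template_karyotype(GenomeLabel.C), "BC"
        )
        out = rdna_loss(
            merged, SiteSelector(family=RDNAFamily.FORTYFIVE_S, genome=GenomeLabel.C)
        )
        assert count_rdna(out, RDNAFamily.FORTYFIVE_S) == (2, 2)
        assert out.total_length_um() == pytest.approx(merged.total_length_um())

    def test_strict_selector_without_match_raises(self):
        b = template_karyotype(GenomeLabel.B)
        sel = SiteSelector(family=RDNAFamily.FIVE_S, label="B5")
        with pytest.raises(RearrangementError):
            rdna_loss(b, sel)
        # lenient mode is a no-op
        assert rdna_loss(b, sel, strict=False).chromosomes == b.chromosomes

    def test_limit_caps_removed_sites(self):
        b4 = autopolyploidize(template_karyotype(GenomeLabel.B), 2)
        out = rdna_loss(b4, SiteSelector(family=RDNAFamily.FIVE_S, label="B2"), limit=2)
        assert count_rdna(out, RDNAFamily.FIVE_S) == (2, 2)


class TestReplay:
    def test_empty_scenario_is_identity(self):
        proto = proto_a()
        out, log = replay(proto, Scenario("empty", []))
        assert out.chromosomes == proto.chromosomes
        assert log == []

    def test_fig4_dysploidy_outcome(self):
        proto = proto_a()
        out, log = replay(proto, builtin_scenario("FIG4_DYSPLOIDY"))
        assert out.somatic_number_2n == 12
        assert out.basic_number_x == 6
        assert not out.unbalanced
        morphs = [classify_morphology(c) for c in out.chromosomes]
        assert sum(1 for m in morphs if m >= MorphologyClass.sm) == 4
        assert count_rdna(out, RDNAFamily.FIVE_S) == (4, 2)
        assert mca(out) > mca(proto)

    def test_fig4_conserves_chromatin_at_every_step(self):
        proto = proto_a()
        _, log = replay(proto, builtin_scenario("FIG4_DYSPLOIDY"))
        for record in log:
            assert record.length_after_um == pytest.approx(
                record.length_before_um, rel=1e-9
            )

    def test_p_minor_scenario_nucleolar_dominance(self):
        b = template_karyotype(GenomeLabel.B)
        out, _ = replay(
            b,
            builtin_scenario("P_MINOR"),
            partners={"GENOME_C_TEMPLATE": template_karyotype(GenomeLabel.C)},
        )
        assert out.somatic_number_2n == 28
        assert count_rdna(out, RDNAFamily.FORTYFIVE_S) == (2, 2)

    def test_replay_is_deterministic_through_tsv(self):
        proto = proto_a()
        outputs = []
        for _ in range(2):
            out, _ = replay(proto, builtin_scenario("FIG4_DYSPLOIDY"))
            buf = io.StringIO()
            write_karyotypes([out], buf)
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]
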