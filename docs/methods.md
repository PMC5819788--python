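# Methods

## The model

A karyotype is the somatic complement of a cell: a list of chromosomes,
each with a long and a short arm length in micrometres, an optional
satellite (secondary constriction, metadata only — it contributes no
length), and an ordered list of rDNA sites. A site is a (family, arm,
position) triple, with position expressed as a fraction of the arm
measured from the centromere (0) to the telomere (1). The qualitative
position vocabulary of FISH descriptions is made computable by fixed
bins on that fraction: centromere-proximal [0, 0.25), intercalary
[0.25, 0.75), subtelomeric [0.75, 0.95), telomeric [0.95, 1]. No
base-pair coordinate exists anywhere in the model; microscopy measures
lengths, not sequence.

Arms are named by length. Construction normalizes a chromosome so the
long arm is the longer one, relabelling site arms if the measurements
arrive swapped; when both arms are exactly equal the given naming is
kept. Levan arm-ratio classes use the standard intervals m [1, 1.7],
sm (1.7, 3], st (3, 7], t (> 7], with boundaries closed on the more
symmetric class; a zero-length short arm classifies as telocentric.

Karyotype-level bookkeeping: ploidy and basic number x, with the
balance invariant 2n = ploidy · x. Scenario intermediates (after a
fission, before the fusion that re-incorporates the acentric material)
are explicitly flagged unbalanced rather than silently tolerated.

## Karyological statistics

TML (total monoploid length) is the somatic chromatin total divided by
the ploidy; for allopolyploids a per-genome variant divides each
sub-genome's total by its own copy number. M_CA is the per-chromosome
mean of (L−S)/(L+S) × 100; the complement-wide arm-total variant is
available as an option because the two readings coexist in the
literature, but the per-chromosome mean is the defined Mean Centromeric
Asymmetry and is the default. CV_CL is the coefficient of variation of
chromosome total lengths × 100, with the sample SD (n−1) by default and
the population SD as an option.

Consequences used as test oracles: M_CA and CV_CL are invariant under
uniform scaling and chromosome reordering; autopolyploidization leaves
M_CA, TML and the population-SD CV_CL unchanged (the sample-SD CV_CL
shifts by the finite-sample factor √(2(n−1)/(2n−1)), which is why the
invariance is asserted on the population variant).

## The rearrangement algebra

Chromosome geometry during an event uses a signed coordinate: negative
on the short arm, positive on the long arm, centromere at 0. All
structural events conserve total chromatin length (chromosomes plus
unfused acentric segments) to machine precision; the centromere is
modelled as a zero-length feature, so "loss of the centromere" in a
fission costs no length.

- **Pericentromeric fission** deletes the centromere and releases both
  arms as acentric segments; site positions on a segment are measured
  from the end that faced the centromere. Only the exact centromeric
  break is modelled: a paracentromeric offset would leave the centromere
  on one product, contradicting the two-acentric-segments picture this
  operator exists to express.
- **End-to-end fusion** joins a segment's former telomere to the
  recipient arm's telomere, so the segment's former centromeric end
  becomes the new arm terminus: a site that was proximal in the donor
  ends up distal in the recipient. Arm names renormalize afterwards.
- **Pericentric inversion** reverses the segment between a breakpoint on
  each arm *in place*; the centromere travels with the reversed segment,
  so asymmetric breakpoints change arm lengths (and Levan class) while
  conserving total length. A degenerate corollary: inverting both whole
  arms reverses the entire chromosome, which is an orientation flip with
  no observable effect. For this reason the shipped dysploidy scenario
  asymmetrizes the fused chromosomes with inversions spanning the whole
  short arm plus a proximal slice of the long arm — a choice that also
  carries both 5S sites of the derived A2 onto its long arm, as observed
  in the extant species.
- **Paracentric inversion** mirrors site positions within a single-arm
  interval (p → a + b − p); arm lengths are untouched and the operation
  is an involution.
- **Reciprocal translocation** exchanges the terminal segments distal to
  one breakpoint on each of two chromosomes; sites keep their distance
  to the breakpoint (centromere–telomere polarity maintained).
- **Autopolyploidy** replicates every chromosome; **allopolyploid
  merge** unions two balanced complements, adding ploidies, and refuses
  parents with unlabelled chromosomes (genome provenance would be lost)
  or differing basic numbers.
- **rDNA gain/loss** edit site lists only. Loss selects by any
  combination of chromosome label, parental genome, family, arm and
  position class; an optional cap on the number of removed sites
  expresses dosage losses ("one pair of four homologous sites") that a
  label selector alone cannot, since homologues share labels.

Scenarios are ordered event lists in JSON; replay applies them
deterministically, pools acentric segments between fission and fusion,
logs per-event length and site movements, and re-balances the complement
at the end (an empty segment pool with 2n divisible by the ploidy
recomputes x — this is how the dysploidy scenario turns x = 7 into
x = 6). By default every event acts on all homologues of its target
label, because FISH observations are somatic and rearrangements fixed in
a lineage affect homologue pairs symmetrically.

### The packaged ancestor and dysploidy scenario

PROTO_A is the hypothesized all-metacentric 2n = 14 ancestor of the
x = 6 lineage: proto-A7 metacentric with a centromere-proximal 5S on one
arm, proto-A2 with a subtelomeric 5S, proto-A1 with the subtelomeric
short-arm 45S (and satellite) retained by the extant A1. Its arm lengths
are a design choice (documented in the fixture builder) picked so the
post-scenario TML (~45 µm) sits inside the range reported for the extant
x = 6 species. The FIG4_DYSPLOIDY scenario fissions proto-A7, fuses the
5S-bearing long arm onto proto-A2 and the short arm onto proto-A6, and
applies pericentric inversions to both products. The replayed outcome —
2n = 12, exactly four sm/st chromosomes, four 5S signals on two
chromosomes, M_CA rising from 0 to ~18 — reproduces the diagnostic
pattern of the extant x = 6 karyotypes.

## Genome signatures and assignment

Each of the three recurrent monoploid genomes is a rule set with four
equally weighted rule families: basic number, morphology/symmetry, 45S
pattern, 5S pattern.

- **A** (x = 6): ≥ 2 sm/st chromosomes per monoploid set; one 45S-bearing
  chromosome with short-arm (sub)telomeric sites; one 5S-bearing
  chromosome carrying exactly two long-arm (sub)telomeric sites (the
  double band).
- **B** (x = 7): monoploid M_CA < 20 ("more symmetrical"); one
  45S-bearing chromosome, intercalary; one or two 5S-bearing chromosomes
  (1–3 sites), at least one site (sub)telomeric.
- **C** (x = 7): monoploid M_CA < 20; at most one 45S-bearing chromosome
  with centromere-proximal short-arm sites (zero bearing is allowed —
  nucleolar dominance can have silenced the locus); 5–6 5S sites total.

The M_CA < 20 symmetry threshold encodes the observed split between the
x = 7 taxa (M_CA ≲ 19) and the x = 6 taxa (M_CA ≳ 25). The soft "at
least one (sub)telomeric" reading of the B 5S position rule reflects
that several B-genome taxa carry their 5S intercalary; those taxa score
3/4 = 0.75, which is exactly the assignment threshold, and still assign
to B because no other signature exceeds 0.5 for them. Scores are the
satisfied-rule fraction in [0, 1]; a sub-complement whose best score
falls below 0.75 is labelled UNKNOWN.

Assignment partitions a karyotype into monoploid sub-complements by
recorded parental genome label (falling back to the alphabetic label
prefix), condenses each homologue group to one representative (arm
lengths averaged; the site list taken from the homologue with the most
sites, so hemizygous loci are represented and single-homologue signal
dropout is harmless), scores every signature, and assembles the genome
formula in karyotype-table style: one letter per diploid genome copy,
distinct genomes joined by "/" ("A", "BB", "B/C"). Ploidy 2 is DIPLOID;
higher ploidy with one distinct label is AUTOPOLYPLOID, with several
ALLOPOLYPLOID, and any UNKNOWN sub-genome makes the type UNKNOWN.

## Synthetic data and fixtures

The generator draws chromosome total lengths as mean·(1 + cv·z) with the
z-sample standardized, so the realized monoploid length CV equals the
target exactly (the somatic sample CV differs only by the duplicated-
sample factor, within 4% for x ≥ 6); arm ratios come from a shifted
log-normal 1 + LogNormal(−1.5, 0.4), spanning metacentric to
subtelocentric with a metacentric-leaning median, matching the
composition of the studied grass karyotypes; planned rDNA sites are
placed uniformly within their class bin. Homologues are identical before
noise. The noise model perturbs each arm with independent log-normal
error (default CV 5% — a realistic squash-preparation measurement
spread), drops each signal with probability 0.02 (faint-band loss), and
jitters band positions with SD 0.03 of the arm, re-binning the class.
Homologues are perturbed independently because each is a separate
measurement.

The eight species fixtures reproduce, exactly: 2n, ploidy, basic number,
genome labels, and every 45S/5S signal/bearing-chromosome count of the
published complements, including the hemizygous third 5S locus of
*P. coerulescens*, the asymmetric 45S pair of *P. arundinacea* (two
intercalary, two proximal homologues), and the missing C-genome 45S of
*P. minor*. Per-chromosome arm lengths are *not* published; the fixtures
reconstruct them to match the published TML (per-genome TML for
*P. aquatica*, whose table prints sub-genome rows; *P. minor*'s
unprinted split is taken equal for both sub-genomes) and the qualitative
m/sm/st composition. The published asymmetry indices are therefore only
approximated (M_CA of the reconstruction is within a few points of
print), and no test asserts them — what passing tests show is that the
counting, scenario and assignment machinery reproduces every discretely
reported quantity, not that the microscope measurements were recovered. The double 5S site of *P. minor* producing 16 signals on 14
chromosomes is placed on the C6 pair (one subtelomeric, one intercalary
site per homologue), a choice the data constrain only to "some C pair".

## Parsimony mapping

The packaged topology transcribes the accepted subgenus/section
classification: (brachystachys, canariensis) — subgenus *Phalaris* —
sister to the rest; within subgenus *Phalaroides*, *coerulescens*
subtending (*paradoxa*, (*aquatica*, *minor*)), and (*caroliniana*,
*arundinacea*) as the remaining clade. Branch lengths are omitted.
Characters are mapped with unordered Fitch parsimony (no cost model is
defensible from qualitative descriptions); polytomies are folded child
by child. The implementation is validated in tests against an exhaustive
brute-force minimum over all internal labelings, feasible at 8 leaves.
One most-parsimonious reconstruction is reported for edge placement,
resolved top-down keeping the parent state where allowed (deterministic
tie-break); alternative placements of equal cost are not enumerated.
With the packaged fixtures the basic-number character needs exactly one
change (a single early dysploidy event), ploidy two (one per tetraploid
clade), and the genome formulas confine A to section *Phalaris* and C to
section *Bulbophalaris* with B present in every x = 7 species.

## File formats and determinism

Karyotypes serialize to a strict TSV (UTF-8, header, '.' decimals —
comma decimals are rejected with the offending line and column named):
one row per somatic chromosome with species, label, genome, arm lengths,
satellite, a compact site list, ploidy and x. Fractions are written at
six decimals, making one write/read cycle a fixed point of the
serialization; all pipelines (generator, replay, rendering) are
byte-deterministic given a seed. Idiograms render to plain SVG text with
fixed numeric formatting: homologue groups in columns, centromere-
aligned, 45S bands green and 5S red, genome labels colour-coding the
fill.

## Problem sizes and limitations

Default test and acceptance runs use the packaged 12–28-chromosome
karyotypes, 500-replicate noise experiments, 1000-karyotype statistical
oracle comparisons and the 8-leaf exhaustive parsimony check; all
complete in seconds.

Known limitations: no meiotic pairing or population dynamics of
rearrangements; no breakpoint sequence model; satellites do not
contribute length (their handling in published TML values is unstated);
the event algebra applies events to whole homologue groups, so
within-pair heterozygous rearrangements must be expressed via the
site-level operators or per-homologue input rows; signature scoring is
rule-based and calibrated to this genus — transferring it to other
groups means re-encoding the signatures, not retuning opaque weights.
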