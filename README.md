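# karyokit

Karyotype modelling for plant molecular cytogenetics, built around the
canary grasses (*Phalaris*, Poaceae) — a genus with two basic chromosome
numbers (x = 6 and x = 7), diploid and tetraploid species, and 5S/45S
rDNA FISH landmarks that make chromosome evolution traceable.

The package is for cytogeneticists and comparative genomicists who want
to go beyond describing karyotypes: it lets you *replay* hypothesized
chromosome-evolution scenarios (descending dysploidy, auto- and
allopolyploidy, nucleolar dominance) as explicit, length-conserving
event sequences and check their predictions against observed
complements.

## What it computes

**Karyological parameters.** For a complement of chromosomes with long
and short arm lengths L_i, S_i (µm):

- arm ratio r_i = L_i/S_i with Levan classes m (r ≤ 1.7), sm (≤ 3),
  st (≤ 7), t (> 7);
- TML, total monoploid length: Σ(L_i + S_i) over one monoploid set;
- M_CA, mean centromeric asymmetry: mean of (L_i − S_i)/(L_i + S_i) × 100;
- CV_CL, interchromosomal asymmetry: sCL/x̄CL × 100 (sample SD of
  chromosome lengths over their mean);
- rDNA signal counts per family, reported as "signals / bearing
  chromosomes" as in FISH karyotype tables.

**Rearrangement algebra.** Pericentromeric fission (centromere lost, two
acentric whole-arm segments), telomere–telomere ("end-to-end") fusion of
a segment onto another chromosome's arm, pericentric and paracentric
inversion, reciprocal translocation, whole-genome duplication,
amphidiploid merger, and rDNA site gain/loss. Every structural event
conserves total chromatin length exactly — dysploidy changes chromosome
number, not DNA content. Ordered event lists (scenarios) replay
deterministically with a full event log.

**Genome signatures.** Monoploid genomes A (x = 6, asymmetric, 5S double
band), B (x = 7, symmetric, intercalary 45S) and C (x = 7, 5–6 5S sites
per monoploid set) are encoded as testable rule sets; karyotypes are
split into monoploid sub-complements, scored, and classified as diploid,
autopolyploid or allopolyploid.

**Parsimony mapping.** Fitch small parsimony of karyotype characters
(basic number, ploidy, genome formula) on the packaged species topology.

**Synthetic data.** A seeded generator of realistic grass karyotypes
(2n = 12/14/28, arm-ratio distributions from metacentric to
subtelocentric, planned rDNA sites) plus a microscopy-style noise model
(multiplicative arm-length error, signal dropout, band-position jitter).
The eight species fixtures reproduce the published chromosome numbers,
genome formulas and all rDNA signal counts exactly; their arm lengths
are reconstructions scaled to the published TML values.

## Worked example

```python
import karyokit as kk

fx = kk.fixtures()
print(kk.stats_table([fx["P. aquatica"], fx["P. brachystachys"]]).round(1))

proto = kk.proto_a()                       # hypothesized 2n=14 ancestor
scenario = kk.builtin_scenario("FIG4_DYSPLOIDY")
derived, log = kk.replay(proto, scenario)
print(derived.somatic_number_2n, derived.basic_number_x, kk.mca(derived))
print(kk.count_rdna(derived, kk.RDNAFamily.FIVE_S))
print(kk.assign(fx["P. aquatica"]).formula)
```

prints

```
     species  2n  x  ploidy   TML  M_CA  CV_CL  45S    5S
 P. aquatica  28  7       4  49.6  10.7   12.5  4/4  12/7
P. brachystachys  12  6    2  50.2  22.1   10.3  2/2   4/2
12 6 17.648...
(4, 2)
B/C
```

Reading: the dysploidy scenario (fission of the proximal-5S metacentric
proto-A7, fusion of its two arms onto proto-A2 and proto-A6, pericentric
inversions) turns the symmetric 2n = 14 ancestor into a 2n = 12, x = 6
karyotype whose mean centromeric asymmetry rises from 0 to ~18 and whose
four 5S signals sit on just two chromosomes — the diagnostic pattern of
the extant x = 6 species. The B/C formula identifies *P. aquatica* as an
allotetraploid combining one B and one C monoploid genome pair.

The same functionality is available from the shell:

```
karyokit stats    --in karyotypes.tsv --out stats.tsv
karyokit replay   --in proto_a.tsv --scenario fig4_dysploidy.json --out derived.tsv
karyokit assign   --in karyotypes.tsv --out assignments.tsv
karyokit simulate --x 7 --ploidy 2 --seed 42 --plan plan.json --out sim.tsv
karyokit map-tree --in karyotypes.tsv --out report.json
karyokit idiogram --in karyotypes.tsv --species "P. minor" --out minor.svg
```

Packaged inputs (fixture TSVs, scenario JSONs, the species tree) live in
`src/karyokit/data/`.

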