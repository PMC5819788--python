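"""Karyological parameters: TML, M_CA, CV_CL and rDNA signal counts.

* TML (total monoploid length): summed chromosome length of one monoploid
  set, i.e. the somatic total divided by the ploidy level.
* M_CA (mean centromeric asymmetry): mean over chromosomes of
  (L - S) / (L + S) x 100; 0 for a fully metacentric complement.
* CV_CL (interchromosomal asymmetry): coefficient of variation of
  chromosome total lengths x 100 (sCL / xCL x 100).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Chromosome, Karyotype, RDNAFamily, validate


@dataclass(frozen=True)
class KaryotypeStats:
    species: str
    tml_um: float
    mca_pct: float
    cvcl_pct: float
    mean_chrom_len_um: float
    sd_chrom_len_um: float
    counts_45s: tuple[int, int]
    counts_5s: tuple[int, int]


def _lengths(karyotype: Karyotype) -> np.ndarray:
    return np.array([c.total_length_um for c in karyotype.chromosomes], dtype=float)


def tml(karyotype: Karyotype) -> float:
    """Total monoploid length in um: somatic chromatin total / ploidy."""
    problems = [v for v in validate(karyotype) if "balance" in v]
    if karyotype.unbalanced or problems:
        raise ValueError("TML requires a balanced karyotype")
    return float(_lengths(karyotype).sum()) / karyotype.ploidy


def tml_by_genome(karyotype: Karyotype) -> dict[str, float]:
    """TML of each parental sub-genome of an allopolyploid.

    Each genome's chromosomes form ``copies = count / x`` monoploid sets;
    the per-genome TML is that genome's chromatin total divided by its
    copy number.
    """
    totals: dict[str, float] = {}
    counts: dict[str, int] = {}
    for chrom in karyotype.chromosomes:
        key = chrom.genome.value if chrom.genome is not None else "UNKNOWN"
        totals[key] = totals.get(key, 0.0) + chrom.total_length_um
        counts[key] = counts.get(key, 0) + 1
    out = {}
    for key, total in totals.items():
        copies = counts[key] / karyotype.basic_number_x
        if copies <= 0 or copies != int(copies):
            raise ValueError(
                f"genome {key} has {counts[key]} chromosomes, not a multiple "
                f"of x = {karyotype.basic_number_x}"
            )
        out[key] = total / copies
    return out


def mca(karyotype: Karyotype, set_total: bool = False) -> float:
    """Mean centromeric asymmetry in percent.

    Default is the per-chromosome mean of (L - S)/(L + S) x 100
    (Peruzzi & Eroglu's M_CA).  ``set_total=True`` instead uses the
    complement-wide arm totals (sum L - sum S)/(sum L + sum S) x 100.
    """
    if not karyotype.chromosomes:
        raise ValueError("M_CA undefined for an empty karyotype")
    L = np.array([c.long_arm_um for c in karyotype.chromosomes])
    S = np.array([c.short_arm_um for c in karyotype.chromosomes])
    if np.any(L + S <= 0):
        raise ValueError("M_CA requires positive chromosome lengths")
    if set_total:
        return float((L.sum() - S.sum()) / (L.sum() + S.sum()) * 100.0)
    return float(np.mean((L - S) / (L + S)) * 100.0)


def cvcl(karyotype: Karyotype, sample_sd: bool = True) -> float:
    """Interchromosomal asymmetry: CV of chromosome lengths x 100.

    Sample SD (n - 1 denominator) by default; ``sample_sd=False``
    switches to the population SD.
    """
    lengths = _lengths(karyotype)
    if lengths.size < 2:
        raise ValueError("CV_CL requires at least 2 chromosomes")
    sd = float(np.std(lengths, ddof=1 if sample_sd else 0))
    return sd / float(np.mean(lengths)) * 100.0


def count_rdna(karyotype: Karyotype, family: RDNAFamily) -> tuple[int, int]:
    """(total signals, signal-bearing chromosomes) for one rDNA family.

    This mirrors the "signals / chromosomes with signals" notation of
    FISH karyotype tables.
    """
    signals = 0
    bearing = 0
    for chrom in karyotype.chromosomes:
        n = sum(1 for s in chrom.sites if s.family is family)
        signals += n
        bearing += 1 if n else 0
    return signals, bearing


def karyotype_stats(karyotype: Karyotype) -> KaryotypeStats:
    lengths = _lengths(karyotype)
    return KaryotypeStats(
        species=karyotype.species,
        tml_um=tml(karyotype),
        mca_pct=mca(karyotype),
        cvcl_pct=cvcl(karyotype),
        mean_chrom_len_um=float(lengths.mean()),
        sd_chrom_len_um=float(np.std(lengths, ddof=1)),
        counts_45s=count_rdna(karyotype, RDNAFamily.FORTYFIVE_S),
        counts_5s=count_rdna(karyotype, RDNAFamily.FIVE_S),
    )


def stats_table(
    karyotypes: list[Karyotype],
    sample_sd: bool = True,
    mca_set_total: bool = False,
) -> pd.DataFrame:
    """One row of karyological parameters per karyotype.

    Column order follows the conventional FISH-karyotype table layout:
    2n, TML, M_CA, CV_CL, then 45S and 5S as "signals/bearing".
    """
    rows = []
    for k in karyotypes:
        s45 = count_rdna(k, RDNAFamily.FORTYFIVE_S)
        s5 = count_rdna(k, RDNAFamily.FIVE_S)
        rows.append(
            {
                "species": k.species,
                "2n": k.somatic_number_2n,
                "x": k.basic_number_x,
                "ploidy": k.ploidy,
                "TML": tml(k),
                "M_CA": mca(k, set_total=mca_set_total),
                "CV_CL": cvcl(k, sample_sd=sample_sd),
                "45S": f"{s45[0]}/{s45[1]}",
                "5S": f"{s5[0]}/{s5[1]}",
            }
        )
    columns = ["species", "2n", "x", "ploidy", "TML", "M_CA", "CV_CL", "45S", "5S"]
    return pd.DataFrame(rows, columns=columns)
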