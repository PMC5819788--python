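"""Karyotype TSV reading and writing.

One row per somatic chromosome.  Columns::

    species  chrom_label  genome  long_um  short_um  satellite  sites  ploidy  x

* ``genome`` is A/B/C/UNKNOWN or empty.
* ``satellite`` is ``0`` (absent), or ``ARM[:frac]`` (e.g. ``SHORT:0.9``);
  a bare ``1`` is accepted and read as a short-arm satellite.
* ``sites`` is a semicolon-separated list of
  ``family:arm:position_class[:position_frac]``, e.g.
  ``5S:LONG:SUBTELOMERIC:0.850000``.
* ``ploidy`` and ``x`` repeat per row and must be constant per species.

The dialect is strict: UTF-8, tab separators, header required, and '.'
as the decimal separator — a comma decimal such as ``38,9`` is rejected
with the offending line and column named (typeset tables mix decimal
styles; the file format must not).  Fractions are written with six
decimals, which makes write -> read a lossless round trip.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, TextIO

from .model import (
    Arm,
    Chromosome,
    GenomeLabel,
    Karyotype,
    PositionClass,
    RDNAFamily,
    RDNASite,
    Satellite,
    validate,
)

COLUMNS = [
    "species",
    "chrom_label",
    "genome",
    "long_um",
    "short_um",
    "satellite",
    "sites",
    "ploidy",
    "x",
]

_FAMILY_TOKENS = {"5S": RDNAFamily.FIVE_S, "45S": RDNAFamily.FORTYFIVE_S}


class KaryotypeTSVError(ValueError):
    """Malformed karyotype TSV; message carries line and column."""


def _parse_float(token: str, line: int, column: str) -> float:
    if "," in token:
        raise KaryotypeTSVError(
            f"line {line}, column {column}: comma decimal {token!r} — use '.'"
        )
    try:
        return float(token)
    except ValueError:
        raise KaryotypeTSVError(
            f"line {line}, column {column}: non-numeric value {token!r}"
        ) from None


def _parse_site(token: str, line: int) -> RDNASite:
    parts = token.split(":")
    if len(parts) not in (3, 4):
        raise KaryotypeTSVError(
            f"line {line}, column sites: malformed site {token!r} "
            "(expected family:arm:class[:frac])"
        )
    fam, arm, cls = parts[0], parts[1], parts[2]
    if fam not in _FAMILY_TOKENS:
        raise KaryotypeTSVError(f"line {line}: unknown rDNA family {fam!r}")
    try:
        arm_e = Arm(arm)
        cls_e = PositionClass(cls)
    except ValueError as exc:
        raise KaryotypeTSVError(f"line {line}: {exc}") from None
    frac = _parse_float(parts[3], line, "sites") if len(parts) == 4 else None
    return RDNASite(_FAMILY_TOKENS[fam], arm_e, cls_e, frac)


def _parse_satellite(token: str, line: int) -> Satellite | None:
    if token in ("", "0"):
        return None
    if token == "1":
        return Satellite(Arm.SHORT)
    parts = token.split(":")
    try:
        arm = Arm(parts[0])
    except ValueError:
        raise KaryotypeTSVError(
            f"line {line}, column satellite: unknown token {token!r}"
        ) from None
    frac = _parse_float(parts[1], line, "satellite") if len(parts) > 1 else None
    return Satellite(arm, frac)


def _format_frac(frac: float | None) -> str:
    return "" if frac is None else f":{frac:.6f}"


def _site_token(site: RDNASite) -> str:
    return (
        f"{site.family.value}:{site.arm.value}:{site.position_class.value}"
        f"{_format_frac(site.position_frac)}"
    )


def _satellite_token(sat: Satellite | None) -> str:
    if sat is None:
        return "0"
    return f"{sat.arm.value}{_format_frac(sat.position_frac)}"


def write_karyotypes(karyotypes: Iterable[Karyotype], path: str | Path | TextIO) -> None:
    rows = []
    for k in karyotypes:
        for chrom in k.chromosomes:
            rows.append(
                [
                    k.species,
                    chrom.label,
                    chrom.genome.value if chrom.genome is not None else "",
                    f"{chrom.long_arm_um:.6f}",
                    f"{chrom.short_arm_um:.6f}",
                    _satellite_token(chrom.satellite),
                    ";".join(_site_token(s) for s in chrom.sites),
                    str(k.ploidy),
                    str(k.basic_number_x),
                ]
            )
    if hasattr(path, "write"):
        _write_rows(path, rows)
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            _write_rows(fh, rows)


def _write_rows(fh: TextIO, rows: list[list[str]]) -> None:
    writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
    writer.writerow(COLUMNS)
    writer.writerows(rows)


def read_karyotypes(path: str | Path | TextIO, strict: bool = True) -> list[Karyotype]:
    """Parse a karyotype TSV into one Karyotype per species (file order).

    With ``strict=True`` (default) the loaded karyotypes are validated
    and any invariant violation raises.
    """
    if hasattr(path, "read"):
        karyotypes = _read_fh(path)
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            karyotypes = _read_fh(fh)
    if strict:
        for k in karyotypes:
            problems = validate(k)
            if problems:
                raise KaryotypeTSVError(
                    f"karyotype {k.species!r} invalid: " + "; ".join(problems)
                )
    return karyotypes


def _read_fh(fh: TextIO) -> list[Karyotype]:
    reader = csv.reader(fh, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise KaryotypeTSVError("empty file: header row required") from None
    missing = [c for c in COLUMNS if c not in header]
    if missing:
        raise KaryotypeTSVError(f"missing columns: {', '.join(missing)}")
    idx = {c: header.index(c) for c in COLUMNS}

    order: list[str] = []
    chroms: dict[str, list[Chromosome]] = {}
    meta: dict[str, tuple[int, int]] = {}
    for line_no, row in enumerate(reader, start=2):
        if not row or all(not cell for cell in row):
            continue
        if len(row) < len(header):
            raise KaryotypeTSVError(f"line {line_no}: expected {len(header)} columns")
        species = row[idx["species"]]
        genome_token = row[idx["genome"]]
        genome = GenomeLabel(genome_token) if genome_token else None
        sites_token = row[idx["sites"]]
        sites = tuple(
            _parse_site(tok, line_no) for tok in sites_token.split(";") if tok
        )
        chrom = Chromosome(
            label=row[idx["chrom_label"]],
            long_arm_um=_parse_float(row[idx["long_um"]], line_no, "long_um"),
            short_arm_um=_parse_float(row[idx["short_um"]], line_no, "short_um"),
            satellite=_parse_satellite(row[idx["satellite"]], line_no),
            sites=sites,
            genome=genome,
        )
        ploidy = int(_parse_float(row[idx["ploidy"]], line_no, "ploidy"))
        x = int(_parse_float(row[idx["x"]], line_no, "x"))
        if species not in chroms:
            order.append(species)
            chroms[species] = []
            meta[species] = (ploidy, x)
        elif meta[species] != (ploidy, x):
            raise KaryotypeTSVError(
                f"line {line_no}: ploidy/x differ within species {species!r}"
            )
        chroms[species].append(chrom)
    return [
        Karyotype(
            species=sp,
            chromosomes=chroms[sp],
            ploidy=meta[sp][0],
            basic_number_x=meta[sp][1],
        )
        for sp in order
    ]
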