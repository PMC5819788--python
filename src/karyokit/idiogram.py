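"""Deterministic SVG idiograms: one column per homologue group,
chromosomes centromere-aligned, 45S bands green and 5S bands red (the
usual FISH pseudo-colours), genome label colour-coding the chromosome
fill.  Output is plain SVG text with fixed numeric formatting, so the
same karyotype always renders to identical bytes."""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import Arm, Karyotype, RDNAFamily, homologue_groups
from .model import _label_sort_key  # shared natural ordering of labels


@dataclass(frozen=True)
class IdiogramSpec:
    scale_px_per_um: float = 12.0
    chrom_width_px: float = 14.0
    gap_px: float = 8.0
    group_gap_px: float = 22.0
    band_height_px: float = 3.0
    margin_px: float = 30.0
    colors: dict = field(
        default_factory=lambda: {
            RDNAFamily.FORTYFIVE_S: "#2ca02c",  # green
            RDNAFamily.FIVE_S: "#d62728",  # red
            "satellite": "#555555",
            "outline": "#222222",
            "A": "#dce6f7",
            "B": "#ececec",
            "C": "#fbe3cd",
            "None": "#ffffff",
        }
    )


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def render_idiogram(karyotype: Karyotype, spec: IdiogramSpec | None = None) -> str:
    """Render the karyotype as an SVG document string."""
    spec = spec or IdiogramSpec()
    groups = homologue_groups(karyotype)
    labels = sorted(groups, key=_label_sort_key)
    max_short = max((c.short_arm_um for c in karyotype.chromosomes), default=1.0)
    max_long = max((c.long_arm_um for c in karyotype.chromosomes), default=1.0)
    cen_y = spec.margin_px + max_short * spec.scale_px_per_um
    height = cen_y + max_long * spec.scale_px_per_um + spec.margin_px

    parts: list[str] = []
    x = spec.margin_px
    for label in labels:
        for idx in groups[label]:
            chrom = karyotype.chromosomes[idx]
            fill = spec.colors.get(
                chrom.genome.value if chrom.genome is not None else "None", "#ffffff"
            )
            parts.append(_chromosome_glyph(chrom, x, cen_y, fill, spec))
            x += spec.chrom_width_px + spec.gap_px
        parts.append(
            f'<text x="{_fmt(x - spec.gap_px - len(groups[label]) * (spec.chrom_width_px + spec.gap_px) / 2)}" '
            f'y="{_fmt(height - spec.margin_px / 3)}" font-size="9" '
            f'text-anchor="middle" font-family="sans-serif">{label}</text>'
        )
        x += spec.group_gap_px - spec.gap_px
    width = x + spec.margin_px
    body = "\n".join(parts)
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(width)}" '
        f'height="{_fmt(height)}" viewBox="0 0 {_fmt(width)} {_fmt(height)}">\n'
        f"{body}\n</svg>\n"
    )


def _chromosome_glyph(chrom, x: float, cen_y: float, fill: str, spec: IdiogramSpec) -> str:
    s = spec.scale_px_per_um
    w = spec.chrom_width_px
    short_px = chrom.short_arm_um * s
    long_px = chrom.long_arm_um * s
    out = [
        f'<g class="chromosome" data-label="{chrom.label}">',
        f'<rect x="{_fmt(x)}" y="{_fmt(cen_y - short_px)}" width="{_fmt(w)}" '
        f'height="{_fmt(max(short_px, 0.5))}" rx="3" fill="{fill}" '
        f'stroke="{spec.colors["outline"]}" stroke-width="0.8"/>',
        f'<rect x="{_fmt(x)}" y="{_fmt(cen_y)}" width="{_fmt(w)}" '
        f'height="{_fmt(max(long_px, 0.5))}" rx="3" fill="{fill}" '
        f'stroke="{spec.colors["outline"]}" stroke-width="0.8"/>',
        # centromere: pinch marker
        f'<line x1="{_fmt(x - 1)}" y1="{_fmt(cen_y)}" x2="{_fmt(x + w + 1)}" '
        f'y2="{_fmt(cen_y)}" stroke="{spec.colors["outline"]}" stroke-width="1.5"/>',
    ]
    for site in chrom.sites:
        frac = site.resolved_frac
        if site.arm is Arm.SHORT:
            y = cen_y - frac * short_px
        else:
            y = cen_y + frac * long_px
        color = spec.colors[site.family]
        out.append(
            f'<rect class="band" x="{_fmt(x)}" '
            f'y="{_fmt(y - spec.band_height_px / 2)}" width="{_fmt(w)}" '
            f'height="{_fmt(spec.band_height_px)}" fill="{color}"/>'
        )
    if chrom.satellite is not None:
        frac = chrom.satellite.position_frac
        frac = 0.9 if frac is None else frac
        arm_px = short_px if chrom.satellite.arm is Arm.SHORT else long_px
        sign = -1.0 if chrom.satellite.arm is Arm.SHORT else 1.0
        y = cen_y + sign * frac * arm_px
        out.append(
            f'<circle cx="{_fmt(x + w / 2)}" cy="{_fmt(y)}" r="2.0" '
            f'fill="none" stroke="{spec.colors["satellite"]}" stroke-width="1"/>'
        )
    out.append("</g>")
    return "\n".join(out)
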