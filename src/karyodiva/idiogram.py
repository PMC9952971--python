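"""Deterministic SVG idiogram of a haploid chromosome complement.

Chromosomes are drawn as paired-arm bars ordered by rank (longest
first), short arm up, with all centromeres aligned on one horizontal
line, the Levan class lettered beneath each bar, and a micrometre scale
bar.  Rendering is fully deterministic (fixed float formatting, no
timestamps) so outputs can be diffed byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from xml.sax.saxutils import escape

from .karyomorphometry import Karyotype

__all__ = ["IdiogramStyle", "render_idiogram"]


@dataclass(frozen=True)
class IdiogramStyle:
    pixels_per_um: float = 30.0
    chromosome_gap: float = 18.0     # px between glyph centres' edges
    glyph_width: float = 12.0        # px
    centromere_marker: str = "notch"  # or "line"
    scale_bar_um: float = 5.0        # matches a 5 µm micrograph scale bar
    margin: float = 20.0             # px

    def validate(self) -> None:
        numeric = (self.pixels_per_um, self.chromosome_gap, self.glyph_width,
                   self.scale_bar_um, self.margin)
        if any(v <= 0 for v in numeric):
            raise ValueError("all idiogram style dimensions must be positive")
        if self.centromere_marker not in ("notch", "line"):
            raise ValueError(
                f"unknown centromere marker {self.centromere_marker!r}"
            )


def _f(value: float) -> str:
    return f"{value:.2f}"


def render_idiogram(karyotype: Karyotype,
                    style: IdiogramStyle | None = None) -> str:
    """Render a karyotype as an SVG 1.1 document string."""
    style = style or IdiogramStyle()
    style.validate()
    chroms = karyotype.chromosomes
    if not chroms:
        raise ValueError("empty karyotype")

    px = style.pixels_per_um
    max_short = max(c.mean_short_arm for c in chroms)
    max_long = max(c.mean_long_arm for c in chroms)
    centromere_y = style.margin + max_short * px
    label_y = centromere_y + max_long * px + 16.0
    scale_y = label_y + 18.0
    width = (style.margin * 2
             + len(chroms) * style.glyph_width
             + (len(chroms) - 1) * style.chromosome_gap)
    height = scale_y + style.margin

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_f(width)}" height="{_f(height)}" '
        f'viewBox="0 0 {_f(width)} {_f(height)}">',
        '<g font-family="sans-serif" font-size="11">',
    ]
    for i, chrom in enumerate(chroms):
        x = style.margin + i * (style.glyph_width + style.chromosome_gap)
        short_px = chrom.mean_short_arm * px
        long_px = chrom.mean_long_arm * px
        parts.append(
            f'<g class="chromosome" data-rank="{chrom.rank}">'
            f'<rect x="{_f(x)}" y="{_f(centromere_y - short_px)}" '
            f'width="{_f(style.glyph_width)}" height="{_f(short_px)}" '
            f'rx="3.00" fill="#7a7a7a" stroke="#222222"/>'
            f'<rect x="{_f(x)}" y="{_f(centromere_y)}" '
            f'width="{_f(style.glyph_width)}" height="{_f(long_px)}" '
            f'rx="3.00" fill="#9a9a9a" stroke="#222222"/>'
        )
        if style.centromere_marker == "notch":
            parts.append(
                f'<circle cx="{_f(x + style.glyph_width / 2)}" '
                f'cy="{_f(centromere_y)}" r="2.50" fill="#ffffff" '
                f'stroke="#222222"/>'
            )
        else:
            parts.append(
                f'<line x1="{_f(x - 2)}" y1="{_f(centromere_y)}" '
                f'x2="{_f(x + style.glyph_width + 2)}" '
                f'y2="{_f(centromere_y)}" stroke="#d33" stroke-width="1.50"/>'
            )
        parts.append(
            f'<text x="{_f(x + style.glyph_width / 2)}" y="{_f(label_y)}" '
            f'text-anchor="middle">{escape(chrom.levan_class)}</text>'
            '</g>'
        )
    bar_px = style.scale_bar_um * px
    bar_x = width - style.margin - bar_px
    parts.append(
        f'<line x1="{_f(bar_x)}" y1="{_f(scale_y)}" '
        f'x2="{_f(bar_x + bar_px)}" y2="{_f(scale_y)}" '
        f'stroke="#000000" stroke-width="2.00"/>'
        f'<text x="{_f(bar_x + bar_px / 2)}" y="{_f(scale_y - 5)}" '
        f'text-anchor="middle">{_f(style.scale_bar_um)} µm</text>'
    )
    parts.append('</g>')
    parts.append('</svg>')
    return "\n".join(parts) + "\n"
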