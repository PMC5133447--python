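"""Minimal deterministic SVG rendering of cluster architectures.

Genes are drawn as pointed boxes (the point marks the 3' end, i.e. the
transcription direction); non-marker genes inserted into a cluster are
grey; separate segments of a split arrangement are joined by a
double-slash glyph standing for intervening sequence of varying length.
"""

from __future__ import annotations

from pathlib import Path

from .synteny import ArchitectureCall, ClusterCall

BOX_W, BOX_H, TIP, GAP_X, SLASH_W, PAD = 46, 22, 9, 6, 26, 14
MARKER_FILL, INSERT_FILL, STROKE = "#e8524a", "#c8c8c8", "#333333"


def _pointed_box(x: float, y: float, strand: int, fill: str, label: str) -> str:
    if strand >= 0:
        pts = [
            (x, y), (x + BOX_W - TIP, y), (x + BOX_W, y + BOX_H / 2),
            (x + BOX_W - TIP, y + BOX_H), (x, y + BOX_H),
        ]
    else:
        pts = [
            (x + BOX_W, y), (x + TIP, y), (x, y + BOX_H / 2),
            (x + TIP, y + BOX_H), (x + BOX_W, y + BOX_H),
        ]
    points = " ".join(f"{px:.1f},{py:.1f}" for px, py in pts)
    svg = (
        f'<polygon points="{points}" fill="{fill}" stroke="{STROKE}" stroke-width="1"/>'
    )
    if label:
        svg += (
            f'<text x="{x + BOX_W / 2:.1f}" y="{y + BOX_H / 2 + 4:.1f}" '
            f'font-family="sans-serif" font-size="11" text-anchor="middle">{label}</text>'
        )
    return svg


def _double_slash(x: float, y: float) -> str:
    y0, y1 = y - 2, y + BOX_H + 2
    return (
        f'<line x1="{x + 6:.1f}" y1="{y1}" x2="{x + 14:.1f}" y2="{y0}" '
        f'stroke="{STROKE}" stroke-width="2"/>'
        f'<line x1="{x + 12:.1f}" y1="{y1}" x2="{x + 20:.1f}" y2="{y0}" '
        f'stroke="{STROKE}" stroke-width="2"/>'
    )


def _cluster_elements(cluster: ClusterCall, x: float, y: float) -> tuple[list[str], float]:
    parts: list[str] = []
    for i, member in enumerate(cluster.members):
        if i > 0:
            for _gid in cluster.intervening[i - 1]:
                parts.append(_pointed_box(x, y, 1, INSERT_FILL, ""))
                x += BOX_W + GAP_X
        parts.append(_pointed_box(x, y, member.strand, MARKER_FILL, member.family))
        x += BOX_W + GAP_X
    return parts, x


def architecture_svg(call: ArchitectureCall) -> str:
    """One SVG row per genome: clusters separated by double slashes."""
    y = PAD + 16
    x = float(PAD)
    parts: list[str] = [
        f'<text x="{PAD}" y="{PAD + 4}" font-family="sans-serif" font-size="12" '
        f'font-style="italic">{call.taxon} ({call.arch_class})</text>'
    ]
    for ci, cluster in enumerate(call.clusters):
        if ci > 0:
            parts.append(_double_slash(x, y))
            x += SLASH_W + GAP_X
        elems, x = _cluster_elements(cluster, x, y)
        parts.extend(elems)
    for fam, _gid in call.detached_paralogs:
        parts.append(_double_slash(x, y))
        x += SLASH_W + GAP_X
        parts.append(_pointed_box(x, y, 1, MARKER_FILL, fam))
        x += BOX_W + GAP_X
    width = max(x + PAD, 200)
    height = y + BOX_H + PAD
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
        f'height="{height:.0f}" viewBox="0 0 {width:.0f} {height:.0f}">'
        + "".join(parts)
        + "</svg>"
    )


def write_architecture_svg(call: ArchitectureCall, path: str | Path) -> None:
    Path(path).write_text(architecture_svg(call) + "\n")
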