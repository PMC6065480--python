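"""Multi-track fusion figures.

The default single-fusion layout stacks, top to bottom: a superTranscript
scale axis, a read coverage track, a gene boundary track, a protein domain
track, a transcript (exon-structure) track, and a sashimi plot whose arcs
are labeled with split-read support counts.  Expected breakpoints are drawn
as vertical lines spanning all tracks.  A multi-sample variant stacks one
coverage panel per sample above the shared annotation tracks, with
per-isoform breakpoint lines colored by isoform group.

Output is deterministic for a fixed bundle and spec (fixed fonts and DPI, no
timestamps in PDF metadata), so figures are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import PathPatch, Rectangle
from matplotlib.path import Path as MplPath

from fusionlens.alignment_analysis import CoverageTrack, Junction, displayed_junctions

KNOWN_TRACKS = ("axis", "coverage", "gene_boundary", "domains", "transcripts", "sashimi")

# colorblind-safe (Okabe-Ito) palette
PALETTE = ["#0072B2", "#D55E00", "#009E73", "#E69F00", "#CC79A7", "#56B4E9", "#F0E442"]

_RC = {
    "font.family": "DejaVu Sans",
    "font.size": 8,
    "svg.hashsalt": "fusionlens",
    "pdf.fonttype": 42,
}


@dataclass
class TrackBundle:
    """Everything needed to draw one fusion: coverage, annotation, junctions."""

    refname: str
    length: int
    coverage: list[CoverageTrack] = field(default_factory=list)
    gene_boundaries: list[tuple[int, int, str]] = field(default_factory=list)
    domains: list[tuple[int, int, str]] = field(default_factory=list)
    transcripts: list[tuple[str, list[tuple[int, int]]]] = field(default_factory=list)
    junctions: list[Junction] = field(default_factory=list)
    breakpoints: list[tuple[int, int]] = field(default_factory=list)  # (pos, isoform group)

    def validate(self) -> None:
        for s, e, _ in self.gene_boundaries + self.domains:
            if not (0 <= s < e <= self.length):
                raise ValueError(f"interval [{s},{e}) outside [0,{self.length})")


@dataclass
class FigureSpec:
    """Figure customization: track order/presence, colors, thresholds."""

    track_order: tuple[str, ...] = KNOWN_TRACKS
    colors: dict = field(default_factory=dict)
    min_display_support: int = 3
    output_format: str = "pdf"
    width: float = 8.0
    height_per_track: float = 0.9
    coverage_label: Optional[str] = None

    def validate(self) -> None:
        unknown = [t for t in self.track_order if t not in KNOWN_TRACKS]
        if unknown:
            raise ValueError(f"unknown track name(s) {unknown}; known: {list(KNOWN_TRACKS)}")

    def color(self, key: str, default: str) -> str:
        return self.colors.get(key, default)


# ---------------------------------------------------------------------------
# per-track renderers


def _draw_axis(ax, bundle: TrackBundle, spec: FigureSpec) -> None:
    ax.set_xlim(0, bundle.length)
    ax.set_ylim(0, 1)
    ax.spines[["left", "right", "top"]].set_visible(False)
    ax.yaxis.set_visible(False)
    ax.xaxis.set_ticks_position("bottom")
    ax.set_xlabel("superTranscript position (bp)", fontsize=7)


def _draw_coverage(ax, track: CoverageTrack, bundle: TrackBundle, spec: FigureSpec) -> None:
    x = np.arange(bundle.length)
    y = track.values if len(track.values) == bundle.length else np.zeros(bundle.length)
    ax.fill_between(x, 0, y, step="post", color=spec.color("coverage", PALETTE[0]), lw=0)
    ax.set_xlim(0, bundle.length)
    ax.set_ylim(bottom=0)
    label = spec.coverage_label or ("RPM" if track.scale == "rpm" else "depth")
    if track.sample:
        label = f"{track.sample}\n{label}"
    ax.set_ylabel(label, fontsize=7, rotation=0, ha="right", va="center")
    ax.spines[["right", "top"]].set_visible(False)
    ax.tick_params(labelbottom=False)


def _draw_gene_boundary(ax, bundle: TrackBundle, spec: FigureSpec) -> None:
    for i, (s, e, name) in enumerate(bundle.gene_boundaries):
        color = spec.color(f"gene_{name}", PALETTE[i % len(PALETTE)])
        ax.add_patch(Rectangle((s, 0.3), e - s, 0.4, facecolor=color, alpha=0.6, lw=0))
        ax.text((s + e) / 2, 0.5, name, ha="center", va="center", fontsize=7)
    ax.set_xlim(0, bundle.length)
    ax.set_ylim(0, 1)
    ax.axis("off")


def _draw_domains(ax, bundle: TrackBundle, spec: FigureSpec) -> None:
    for i, (s, e, name) in enumerate(bundle.domains):
        color = spec.color("domains", PALETTE[3])
        ax.add_patch(Rectangle((s, 0.35), e - s, 0.3, facecolor=color, lw=0.5, edgecolor="black"))
        ax.text((s + e) / 2, 0.8, name, ha="center", va="center", fontsize=6)
    ax.set_xlim(0, bundle.length)
    ax.set_ylim(0, 1)
    ax.axis("off")


def _draw_transcripts(ax, bundle: TrackBundle, spec: FigureSpec) -> None:
    n = max(len(bundle.transcripts), 1)
    for i, (tx_id, exons) in enumerate(bundle.transcripts):
        y = 1 - (i + 0.5) / n
        span = (min(s for s, _ in exons), max(e for _, e in exons))
        ax.plot(span, [y, y], color="black", lw=0.6, zorder=1)
        for s, e in exons:
            ax.add_patch(
                Rectangle(
                    (s, y - 0.3 / n),
                    e - s,
                    0.6 / n,
                    facecolor=spec.color("transcripts", PALETTE[2]),
                    lw=0,
                    zorder=2,
                )
            )
        ax.text(span[0], y + 0.32 / n, tx_id, fontsize=5, va="bottom")
    ax.set_xlim(0, bundle.length)
    ax.set_ylim(0, 1)
    ax.axis("off")


def _draw_sashimi(ax, bundle: TrackBundle, spec: FigureSpec) -> None:
    shown = displayed_junctions(bundle.junctions, spec.min_display_support)
    max_support = max((j.support for j in shown), default=1)
    for j in shown:
        color = (
            spec.color("sashimi_boundary", PALETTE[1])
            if j.crosses_boundary
            else spec.color("sashimi", PALETTE[0])
        )
        height = 0.3 + 0.6 * j.support / max_support
        mid = (j.start + j.end) / 2
        path = MplPath(
            [(j.start, 0), (mid, 2 * height), (j.end, 0)],
            [MplPath.MOVETO, MplPath.CURVE3, MplPath.CURVE3],
        )
        lw = 0.8 + 1.5 * j.support / max_support
        ax.add_patch(PathPatch(path, fill=False, edgecolor=color, lw=lw))
        ax.text(mid, height + 0.05, str(j.support), ha="center", fontsize=6, color=color)
    ax.set_xlim(0, bundle.length)
    ax.set_ylim(0, 1.25)
    ax.axis("off")


_TRACK_RENDERERS = {
    "axis": _draw_axis,
    "gene_boundary": _draw_gene_boundary,
    "domains": _draw_domains,
    "transcripts": _draw_transcripts,
    "sashimi": _draw_sashimi,
}

_HEIGHT_RATIOS = {
    "axis": 0.35,
    "coverage": 1.6,
    "gene_boundary": 0.45,
    "domains": 0.45,
    "transcripts": 1.0,
    "sashimi": 1.3,
}


def _breakpoint_lines(axes, bundle: TrackBundle, spec: FigureSpec) -> None:
    for pos, group in bundle.breakpoints:
        color = spec.color(f"breakpoint_{group}", PALETTE[group % len(PALETTE)])
        for ax in axes:
            ax.axvline(pos, color=color, lw=0.8, ls="-", alpha=0.85, zorder=5)


def build_fusion_figure(bundle: TrackBundle, spec: FigureSpec = FigureSpec()):
    """Assemble the single-fusion multi-track figure; returns (fig, axes by
    track name).  Coverage tracks beyond the first each get their own panel."""
    spec.validate()
    bundle.validate()
    if not bundle.coverage and "coverage" in spec.track_order:
        raise ValueError("bundle has no coverage track")

    rows: list[tuple[str, object]] = []
    for name in spec.track_order:
        if name == "coverage":
            for track in bundle.coverage:
                rows.append(("coverage", track))
        else:
            rows.append((name, None))
    ratios = [_HEIGHT_RATIOS[name] for name, _ in rows]
    with plt.rc_context(_RC):
        fig, axes = plt.subplots(
            len(rows),
            1,
            figsize=(spec.width, spec.height_per_track * sum(ratios)),
            gridspec_kw={"height_ratios": ratios, "hspace": 0.45},
            squeeze=False,
        )
        axes = axes[:, 0]
        axes_by_track: dict[str, list] = {}
        for ax, (name, payload) in zip(axes, rows):
            if name == "coverage":
                _draw_coverage(ax, payload, bundle, spec)
            else:
                _TRACK_RENDERERS[name](ax, bundle, spec)
            ax.set_label(name)
            axes_by_track.setdefault(name, []).append(ax)
        _breakpoint_lines(axes, bundle, spec)
        fig.suptitle(bundle.refname, fontsize=9)
    return fig, axes_by_track


def _save(fig, path: str | Path, spec: FigureSpec) -> Path:
    path = Path(path)
    metadata = {"CreationDate": None} if path.suffix == ".pdf" else {}
    fig.savefig(path, format=path.suffix.lstrip("."), dpi=150, metadata=metadata)
    plt.close(fig)
    return path


def render_fusion_figure(
    bundle: TrackBundle, spec: FigureSpec = FigureSpec(), path: str | Path = "fusion.pdf"
) -> Path:
    """Render the single-fusion figure to PDF (vector, default) or PNG."""
    fig, _ = build_fusion_figure(bundle, spec)
    return _save(fig, path, spec)


def build_multisample_figure(bundles: Sequence[TrackBundle], spec: FigureSpec = FigureSpec()):
    """Stack per-sample coverage panels over shared annotation tracks.

    All bundles must describe the same fusion sequence.  The first bundle
    supplies the shared annotation (boundaries, domains, transcripts) and the
    union of breakpoints is drawn across every panel, colored by isoform
    group.
    """
    if not bundles:
        raise ValueError("no bundles given")
    ref0, len0 = bundles[0].refname, bundles[0].length
    for b in bundles[1:]:
        if b.refname != ref0 or b.length != len0:
            raise ValueError(
                f"bundles disagree: {b.refname}({b.length}) vs {ref0}({len0})"
            )
    merged = replace_coverage(bundles)
    return build_fusion_figure(merged, spec)


def replace_coverage(bundles: Sequence[TrackBundle]) -> TrackBundle:
    """Merge per-sample bundles into one with stacked coverage tracks and the
    union of breakpoint markers."""
    base = bundles[0]
    coverage = [t for b in bundles for t in b.coverage]
    breakpoints = sorted({bp for b in bundles for bp in b.breakpoints})
    junctions = bundles[0].junctions if len(bundles) == 1 else []
    merged = TrackBundle(
        refname=base.refname,
        length=base.length,
        coverage=coverage,
        gene_boundaries=base.gene_boundaries,
        domains=base.domains,
        transcripts=base.transcripts,
        junctions=junctions,
        breakpoints=breakpoints,
    )
    return merged


def render_multisample_figure(
    bundles: Sequence[TrackBundle],
    spec: FigureSpec = FigureSpec(),
    path: str | Path = "fusion_multisample.pdf",
) -> Path:
    """Render the multi-sample overlay figure (one coverage panel per sample
    above shared annotation tracks)."""
    spec = replace(spec, track_order=tuple(t for t in spec.track_order if t != "sashimi"))
    fig, _ = build_multisample_figure(bundles, spec)
    return _save(fig, path, spec)
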