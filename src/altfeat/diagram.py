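"""Matplotlib rendering of the single-gene transcript/feature diagram.

Boxes are exons drawn to scale; thin boxes are UTR, tall filled boxes are
CDS; features are thick bars spanning the exons that encode them and their
intervening introns, labelled with the InterPro identifier or signature.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

from altfeat.alt_classifier import DiagramModel

_EXON_H = 0.22
_CDS_H = 0.38
_FEATURE_H = 0.10


def render_diagram(model: DiagramModel, path: str | Path, dpi: int = 150) -> None:
    """Draw one track per transcript (plus feature bars) and save to file."""
    n_rows = sum(1 + len(t.features) for t in model.tracks)
    fig_h = max(2.0, 0.5 * n_rows + 1.0)
    fig, ax = plt.subplots(figsize=(10, fig_h))
    cmap = plt.get_cmap("tab10")
    colors: dict[str, tuple] = {}

    y = 0.0
    yticks, ylabels = [], []
    for track in model.tracks:
        mid = y
        ax.hlines(mid, track.exons[0].start, track.exons[-1].end,
                  color="0.4", lw=1, zorder=1)
        for ex in track.exons:
            ax.add_patch(Rectangle((ex.start, mid - _EXON_H / 2), ex.length,
                                   _EXON_H, facecolor="white", edgecolor="0.2",
                                   zorder=2))
        for block in track.cds_blocks:
            ax.add_patch(Rectangle((block.start, mid - _CDS_H / 2), block.length,
                                   _CDS_H, facecolor="#4878a8", edgecolor="0.2",
                                   zorder=3))
        tag = "**" if track.appris_principal else ""
        yticks.append(mid)
        ylabels.append(f"{track.transcript_id}{tag}")
        y -= 1.0
        for label, span, _blocks in track.features:
            if label not in colors:
                colors[label] = cmap(len(colors) % 10)
            ax.add_patch(Rectangle((span.start, y - _FEATURE_H / 2), span.length,
                                   _FEATURE_H, facecolor=colors[label],
                                   edgecolor="none", zorder=2))
            ax.annotate(label, (span.start, y + 0.12), fontsize=7,
                        color=colors[label])
            y -= 0.6
        y -= 0.4

    ax.set_xlim(model.xmin - 200, model.xmax + 200)
    ax.set_ylim(y, 1.0)
    ax.set_yticks(yticks)
    ax.set_yticklabels(ylabels, fontsize=8)
    ax.set_xlabel(f"chr{model.chrom} ({model.strand}) position")
    title = model.gene_name or model.gene_id
    ax.set_title(f"{title} ({model.gene_id})", fontsize=10)
    ax.spines[["top", "right", "left"]].set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
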