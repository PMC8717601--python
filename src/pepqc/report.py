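"""Assembly of the portable per-cohort HTML QC report.

The report has three sections: (1) sample overview — length histograms,
a descriptive table (total peptides, in-range count, LF, BF) and, for
multi-sample runs, an UpSet panel of exclusive intersections; (2)
annotation results — aggregate binder bar plots and %rank heatmaps; (3)
sequence motifs — logos from the unsupervised and allele-specific
clustering routines.  All figures are embedded inline as SVG so the
document renders with no network access; editable PDF copies of every
figure and all underlying data files accompany the report.
"""

from __future__ import annotations

import html
import io
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap, Normalize

from .binding import THRESHOLDS, BinderCall, RankTable
from .logo import LogoMatrix, render_logo
from .metrics import IntersectionSummary, QcMetrics, length_histogram, round2
from .motif_cluster import TRASH, UNANNOTATED, ClusterSolution
from .peptide_io import Sample

plt.rcParams["svg.hashsalt"] = "pepqc"

CAP_VALUES = {"I": 2.5, "II": 12.0}
MAX_HEATMAP_ROWS = 5000  # display-only binning threshold


@dataclass
class HeatmapData:
    """Capped, lexicographically sorted %rank matrix ready for display."""

    peptide_order: list[str]
    capped_ranks: np.ndarray
    cap_value: float
    alleles: list[str]
    mhc_class: str


@dataclass
class ReportBundle:
    """Paths of everything a run writes: the HTML, figures, and data files."""

    html_path: Path
    figures: list[Path] = field(default_factory=list)
    data_files: list[Path] = field(default_factory=list)
    archive: Path | None = None
    metadata: dict = field(default_factory=dict)


def heatmap_order(rank_table: RankTable, mhc_class: str) -> HeatmapData:
    """Cap ranks, then sort rows lexicographically by allele columns.

    Values above 2.5 (class I) or 12 (class II) are set to the cap so
    poorly scoring peptides cannot convolute the ordering.  The sort is
    stable: ties preserve the input order.
    """
    if not rank_table.peptides:
        raise ValueError("heatmap_order requires a non-empty rank table")
    cap = CAP_VALUES[mhc_class]
    capped = np.minimum(rank_table.rank, cap)
    order = np.lexsort(capped[:, ::-1].T)  # leftmost column is primary key
    return HeatmapData(
        peptide_order=[rank_table.peptides[i] for i in order],
        capped_ranks=capped[order],
        cap_value=cap,
        alleles=list(rank_table.alleles),
        mhc_class=mhc_class,
    )


def binder_barplot_data(calls: list[BinderCall]) -> dict[str, int]:
    """Aggregate-call counts for the binding-strength bar plot."""
    return {
        "SB": sum(1 for c in calls if c == BinderCall.SB),
        "WB": sum(1 for c in calls if c == BinderCall.WB),
        "NB": sum(1 for c in calls if c == BinderCall.NB),
    }


def binding_colormap(mhc_class: str) -> tuple[LinearSegmentedColormap, Normalize]:
    """Red→blue→yellow colormap anchored at the SB/WB thresholds."""
    sb, wb = THRESHOLDS[mhc_class]
    cap = CAP_VALUES[mhc_class]
    cmap = LinearSegmentedColormap.from_list(
        "binding",
        [(0.0, "#c0171c"), (sb / cap, "#c0171c"),
         ((sb + wb) / 2 / cap, "#2d5f9e"),
         (wb / cap, "#4d7fc4"), (1.0, "#f5e642")],
    )
    return cmap, Normalize(vmin=0.0, vmax=cap)


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def _fig_to_svg(fig) -> str:
    buf = io.StringIO()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    return buf.getvalue()


def _save_pdf(fig, path: Path) -> Path:
    fig.savefig(path, format="pdf", metadata={"CreationDate": None})
    return path


def length_histogram_fig(sample: Sample, max_len: int = 30):
    hist = length_histogram(sample.peptides, max_len)
    fig, ax = plt.subplots(figsize=(4.5, 2.4))
    ax.bar(list(hist), list(hist.values()), color="#2d5f9e")
    ax.set_xlabel("peptide length")
    ax.set_ylabel("count")
    ax.set_title(f"{sample.name}: length distribution (≤{max_len}-mers)", fontsize=9)
    fig.tight_layout()
    return fig


def binder_bar_fig(sample_name: str, counts: dict[str, int]):
    fig, ax = plt.subplots(figsize=(3.0, 2.4))
    colors = {"SB": "#c0171c", "WB": "#4d7fc4", "NB": "#f5e642"}
    ax.bar(list(counts), list(counts.values()), color=[colors[k] for k in counts])
    ax.set_ylabel("peptides")
    ax.set_title(f"{sample_name}: aggregate binding strength", fontsize=9)
    fig.tight_layout()
    return fig


def heatmap_fig(data: HeatmapData, sample_name: str):
    matrix = data.capped_ranks
    if matrix.shape[0] > MAX_HEATMAP_ROWS:  # bin rows for display only
        edges = np.linspace(0, matrix.shape[0], MAX_HEATMAP_ROWS + 1).astype(int)
        matrix = np.vstack([
            matrix[a:b].mean(axis=0) for a, b in zip(edges[:-1], edges[1:]) if b > a
        ])
    cmap, norm = binding_colormap(data.mhc_class)
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(data.alleles), 3.2))
    im = ax.imshow(matrix, aspect="auto", cmap=cmap, norm=norm,
                   interpolation="nearest")
    ax.set_xticks(range(len(data.alleles)), data.alleles, rotation=45,
                  ha="right", fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel(f"{matrix.shape[0]} peptides")
    ax.set_title(f"{sample_name}: %rank EL", fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8, label="%rank (capped)")
    fig.tight_layout()
    return fig


def upset_fig(summary: IntersectionSummary, max_subsets: int = 15):
    order = summary.plot_order()[:max_subsets]
    names = summary.sample_names
    fig, (ax_bar, ax_dot) = plt.subplots(
        2, 1, figsize=(max(3.0, 0.5 * len(order)), 3.4),
        height_ratios=[2.2, 1.0], sharex=True,
    )
    counts = [c for _, c in order]
    ax_bar.bar(range(len(order)), counts, color="#444444")
    ax_bar.set_ylabel("exclusive peptides")
    for x, (subset, _) in enumerate(order):
        for y, name in enumerate(names):
            inside = name in subset
            ax_dot.plot(x, y, "o", color="#222222" if inside else "#dddddd",
                        markersize=5)
    ax_dot.set_yticks(range(len(names)), names, fontsize=7)
    ax_dot.set_xticks([])
    ax_dot.set_ylim(-0.5, len(names) - 0.5)
    ax_dot.invert_yaxis()
    fig.suptitle("Peptide set intersections", fontsize=9)
    fig.tight_layout()
    return fig


# ---------------------------------------------------------------------------
# HTML assembly
# ---------------------------------------------------------------------------

_PAGE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>Immunopeptidomics QC report</title>
<style>
body {{ font-family: sans-serif; margin: 2em auto; max-width: 1100px; color: #222; }}
h1 {{ font-size: 1.5em; }} h2 {{ border-bottom: 2px solid #2d5f9e; padding-bottom: 0.2em; }}
table {{ border-collapse: collapse; margin: 1em 0; }}
td, th {{ border: 1px solid #bbb; padding: 0.3em 0.7em; text-align: right; }}
th {{ background: #eef2f7; }}
.figrow {{ display: flex; flex-wrap: wrap; gap: 1em; align-items: flex-start; }}
.notice {{ color: #8a5a00; background: #fff6e0; padding: 0.5em; border-radius: 4px; }}
.meta {{ color: #555; font-size: 0.9em; }}
</style>
</head>
<body>
<h1>Immunopeptidomics QC report</h1>
<p class="meta">{metadata}</p>
<h2>1. Sample overview</h2>
{overview}
<h2>2. Annotation results and binding heatmaps</h2>
{annotation}
<h2>3. Sequence motifs</h2>
{motifs}
</body>
</html>
"""


def _metrics_table(metrics: list[QcMetrics]) -> str:
    rows = []
    for m in metrics:
        bf = f"{round2(m.bf_score):.2f}" if m.bf_score is not None else "&mdash;"
        rows.append(
            f"<tr><td>{html.escape(m.sample_name)}</td><td>{m.total_peptides}</td>"
            f"<td>{m.in_range_peptides}</td><td>{round2(m.lf_score):.2f}</td>"
            f"<td>{bf}</td><td>{m.sb_count}</td><td>{m.wb_count}</td>"
            f"<td>{m.nb_count}</td></tr>"
        )
    return (
        "<table><tr><th>sample</th><th>total peptides</th><th>in-range</th>"
        "<th>LF</th><th>BF</th><th>SB</th><th>WB</th><th>NB</th></tr>"
        + "".join(rows) + "</table>"
    )


def assemble_report(
    samples: list[Sample],
    metrics: list[QcMetrics],
    rank_tables: dict[str, RankTable],
    unsupervised: dict[str, ClusterSolution | None],
    allele_specific: dict[str, dict[str, ClusterSolution]],
    logos: dict[str, list[tuple[str, LogoMatrix]]],
    metadata: dict,
    out_dir: str | Path,
    upset: IntersectionSummary | None = None,
    make_archive: bool = True,
) -> ReportBundle:
    """Write report.html plus figures/ (PDF) and data/ under ``out_dir``.

    ``logos`` maps sample name to (label, LogoMatrix) pairs covering both
    clustering routines; sections for skipped routines render a notice.
    """
    out_dir = Path(out_dir)
    figures_dir = out_dir / "figures"
    data_dir = out_dir / "data"
    figures_dir.mkdir(parents=True, exist_ok=True)
    data_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(html_path=out_dir / "report.html", metadata=dict(metadata))

    def emit(fig, name: str) -> str:
        svg = _fig_to_svg(fig)
        bundle.figures.append(_save_pdf(fig, figures_dir / f"{name}.pdf"))
        plt.close(fig)
        return f'<div class="fig">{svg}</div>'

    # --- section 1: overview -------------------------------------------------
    overview_parts = [_metrics_table(metrics)]
    overview_parts.append('<div class="figrow">')
    for sample in samples:
        overview_parts.append(emit(length_histogram_fig(sample),
                                   f"{sample.name}_lengths"))
    overview_parts.append("</div>")
    if upset is not None and len(samples) >= 2:
        overview_parts.append(emit(upset_fig(upset), "upset"))

    # --- section 2: annotation ----------------------------------------------
    annotation_parts = ['<div class="figrow">']
    for sample in samples:
        table = rank_tables.get(sample.name)
        if table is None or not table.peptides:
            annotation_parts.append(
                f'<p class="notice">{html.escape(sample.name)}: no in-range '
                "peptides; binding annotation skipped.</p>")
            continue
        counts = binder_barplot_data(table.aggregate_calls(sample.mhc_class))
        annotation_parts.append(emit(binder_bar_fig(sample.name, counts),
                                     f"{sample.name}_binders"))
        hm = heatmap_order(table, sample.mhc_class)
        annotation_parts.append(emit(heatmap_fig(hm, sample.name),
                                     f"{sample.name}_heatmap"))
        table.to_tsv(data_dir / f"{sample.name}_ranks.tsv")
        bundle.data_files.append(data_dir / f"{sample.name}_ranks.tsv")
    annotation_parts.append("</div>")

    # --- section 3: motifs ---------------------------------------------------
    motif_parts = []
    for sample in samples:
        motif_parts.append(f"<h3>{html.escape(sample.name)}</h3>")
        best = unsupervised.get(sample.name)
        motif_parts.append("<h4>Unsupervised</h4>")
        if best is None:
            motif_parts.append(
                '<p class="notice">Fewer than 20 in-range peptides; '
                "clustering skipped.</p>")
        else:
            n_trash = int((best.assignment == TRASH).sum())
            motif_parts.append(
                f"<p>Best grouping: {best.n_groups} group(s), total KLD "
                f"{best.total_kld:.2f} bits/peptide, {n_trash} peptide(s) "
                "in trash.</p>")
            if best.allele_association:
                for g, assoc in best.allele_association.items():
                    text = ", ".join(f"{a}: {pct:.0f}%" for a, pct in
                                     sorted(assoc.items(), key=lambda kv: -kv[1]))
                    motif_parts.append(
                        f"<p class='meta'>group {g + 1} allele association "
                        f"&mdash; {text}</p>")
            best.write_files(data_dir, prefix=f"{sample.name}_unsupervised")
        motif_parts.append("<h4>Allele-specific</h4>")
        per_allele = allele_specific.get(sample.name, {})
        if not per_allele:
            motif_parts.append(
                '<p class="notice">No allele subset reached 20 peptides; '
                "allele-specific clustering skipped.</p>")
        for key, solution in per_allele.items():
            label = "non-binders" if key == UNANNOTATED else key
            motif_parts.append(
                f"<p>{html.escape(label)}: {solution.n_groups} group(s), "
                f"KLD {solution.total_kld:.2f} bits/peptide.</p>")
            solution.write_files(
                data_dir, prefix=f"{sample.name}_{key.replace('*', '').replace(':', '')}")
        motif_parts.append('<div class="figrow">')
        for label, logo_matrix in logos.get(sample.name, []):
            safe = label.replace("*", "").replace(":", "").replace(" ", "_")
            paths = render_logo(logo_matrix, figures_dir / f"{sample.name}_{safe}",
                                title=f"{sample.name} {label}",
                                formats=("svg", "pdf"))
            svg_text = paths[0].read_text()
            bundle.figures.append(paths[1])
            motif_parts.append(f'<div class="fig">{svg_text}</div>')
        motif_parts.append("</div>")

    meta_text = " | ".join(
        f"{html.escape(str(k))}: {html.escape(str(v))}" for k, v in metadata.items()
    )
    page = _PAGE.format(
        metadata=meta_text,
        overview="\n".join(overview_parts),
        annotation="\n".join(annotation_parts),
        motifs="\n".join(motif_parts),
    )
    bundle.html_path.write_text(page)

    # collect cluster/data files written above
    bundle.data_files = sorted(set(bundle.data_files) | set(data_dir.glob("*")))
    if make_archive:
        archive = out_dir / "report_bundle.zip"
        with zipfile.ZipFile(archive, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.write(bundle.html_path, "report.html")
            for p in bundle.figures:
                zf.write(p, f"figures/{p.name}")
            for p in bundle.data_files:
                zf.write(p, f"data/{p.name}")
        bundle.archive = archive
    return bundle
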