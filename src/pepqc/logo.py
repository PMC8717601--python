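"""Sequence-logo matrices and rendering from aligned peptide cores.

Probability matrices are built from an alignment in three steps: Hobohm-1
greedy redundancy clustering assigns each sequence a weight 1/(cluster
size); weighted residue frequencies are pseudocount-corrected toward
BLOSUM62-derived expected frequencies, blended by the effective sequence
number (alpha = n_clusters - 1) against the pseudocount weight beta; and
letter heights are computed either as Shannon information content
(height = p * (log2 20 - H), non-negative) or as Kullback-Leibler
log-odds against a background (signed: depleted residues hang below the
axis).  Alignments may contain ``-`` gap characters, which contribute no
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .matrices import AA_INDEX, background_frequencies, blosum62_conditional
from .peptide_io import CANONICAL_AA

LOG2_20 = float(np.log2(20))
GAP = "-"


@dataclass
class Alignment:
    """Equal-length sequences over the canonical alphabet (plus ``-`` gaps)."""

    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment must contain at least one sequence")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValueError("all sequences must have equal length")
        for s in self.sequences:
            bad = set(s) - set(CANONICAL_AA) - {GAP}
            if bad:
                raise ValueError(f"non-canonical characters {bad} in {s!r}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @classmethod
    def from_file(cls, path: str | Path) -> "Alignment":
        seqs = [line.strip().upper() for line in open(path) if line.strip()]
        return cls(seqs)


@dataclass
class WeightedCounts:
    """Hobohm-weighted observed frequencies and the clustering that made them."""

    weights: np.ndarray  # per-sequence, in (0, 1]
    n_clusters: int
    p_obs: np.ndarray  # 20 x L, columns sum to 1


@dataclass
class LogoMatrix:
    """Per-position letter heights in bits; signed for KLD logos."""

    kind: str  # "shannon" | "kld"
    heights: np.ndarray  # 20 x L
    column_total: np.ndarray  # length L

    def __post_init__(self) -> None:
        if self.kind not in ("shannon", "kld"):
            raise ValueError(f"unknown logo kind {self.kind!r}")


def sequence_identity(a: str, b: str) -> float:
    """Fraction of positions with identical non-gap residues."""
    matches = sum(1 for x, y in zip(a, b) if x == y and x != GAP)
    return matches / len(a)


def hobohm1(alignment: Alignment, identity_threshold: float = 0.63) -> WeightedCounts:
    """Greedy Hobohm-1 clustering and weighted frequency estimation.

    Sequences are scanned in input order; each joins the first existing
    cluster whose representative (its founding sequence) shares at least
    ``identity_threshold`` identical positions, else founds a new cluster.
    Weight = 1 / cluster size, so each cluster contributes total weight 1.
    """
    reps: list[str] = []
    cluster_of = np.empty(len(alignment.sequences), dtype=int)
    for i, seq in enumerate(alignment.sequences):
        for c, rep in enumerate(reps):
            if sequence_identity(seq, rep) >= identity_threshold:
                cluster_of[i] = c
                break
        else:
            cluster_of[i] = len(reps)
            reps.append(seq)
    sizes = np.bincount(cluster_of)
    weights = 1.0 / sizes[cluster_of]

    L = alignment.length
    counts = np.zeros((20, L))
    for seq, w in zip(alignment.sequences, weights):
        for pos, aa in enumerate(seq):
            if aa != GAP:
                counts[AA_INDEX[aa], pos] += w
    totals = counts.sum(axis=0)
    p_obs = np.where(totals > 0, counts / np.where(totals > 0, totals, 1.0), 1.0 / 20)
    return WeightedCounts(weights=weights, n_clusters=len(reps), p_obs=p_obs)


def pseudocount_correct(
    p_obs: np.ndarray,
    n_clusters: int,
    beta: float = 200.0,
    blosum_conditional: np.ndarray | None = None,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Blend observed frequencies with BLOSUM-derived expectations.

    Per column: g(b) = sum_a p_obs(a) q(b|a); p' = (alpha p_obs + beta g)
    / (alpha + beta) with alpha = n_clusters - 1.  beta = 0 returns the
    observed frequencies exactly; a single-cluster alignment with beta > 0
    returns g exactly.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    alpha = n_clusters - 1
    if alpha + beta == 0:
        raise ValueError("alpha + beta = 0: one cluster and no pseudocounts")
    cond = blosum62_conditional() if blosum_conditional is None else blosum_conditional
    g = cond.T @ p_obs
    p = (alpha * p_obs + beta * g) / (alpha + beta)
    return p / p.sum(axis=0, keepdims=True)


def shannon_heights(p: np.ndarray) -> LogoMatrix:
    """Shannon logo: information R = log2(20) - H per column, height = p*R."""
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    H = -plogp.sum(axis=0)
    R = LOG2_20 - H
    return LogoMatrix(kind="shannon", heights=p * R, column_total=R)


def kld_heights(p: np.ndarray, q: np.ndarray | None = None) -> LogoMatrix:
    """Kullback-Leibler logo: signed per-letter log-odds contributions.

    Column total D = sum_b p log2(p/q).  Enriched residues (p >= q) are
    drawn above the axis with height p*D scaled among themselves; depleted
    residues carry their signed contribution p*log2(p/q) below the axis.
    Heights stored here are the signed contributions; the renderer splits
    them about the axis.
    """
    q = background_frequencies() if q is None else np.asarray(q)
    if (q <= 0).any():
        raise ValueError("background must be strictly positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(p > 0, p * np.log2(p / q[:, None]), 0.0)
    D = contrib.sum(axis=0)
    return LogoMatrix(kind="kld", heights=contrib, column_total=D)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

#: Standard amino-acid color classes (hydrophobic black, polar green,
#: basic blue, acidic red, neutral purple).
LETTER_COLORS = {
    **{aa: "#000000" for aa in "AVLIPWFM"},
    **{aa: "#109648" for aa in "GSTYC"},
    **{aa: "#255c99" for aa in "KRH"},
    **{aa: "#d62839" for aa in "DE"},
    **{aa: "#7b4b94" for aa in "NQ"},
}


def render_logo(
    matrix: LogoMatrix,
    path: str | Path,
    title: str | None = None,
    formats: tuple[str, ...] = ("svg",),
) -> list[Path]:
    """Render a logo to vector files; returns the written paths.

    Letters are stacked per position by ascending magnitude, enriched
    letters above the axis and (for KLD logos) depleted letters below.
    Output is deterministic: repeated renders are byte-identical.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    plt.rcParams["svg.hashsalt"] = "pepqc"
    font = FontProperties(family="DejaVu Sans", weight="bold")

    n_pos = matrix.heights.shape[1]
    fig, ax = plt.subplots(figsize=(max(n_pos * 0.55, 2.0), 2.6))
    y_min, y_max = 0.0, 0.0
    for pos in range(n_pos):
        col = matrix.heights[:, pos]
        up = [(CANONICAL_AA[r], h) for r, h in enumerate(col) if h > 1e-12]
        down = [(CANONICAL_AA[r], h) for r, h in enumerate(col) if h < -1e-12]
        y = 0.0
        for aa, h in sorted(up, key=lambda t: t[1]):
            _draw_letter(ax, aa, pos, y, h, font, PathPatch, TextPath, Affine2D)
            y += h
        y_max = max(y_max, y)
        y = 0.0
        for aa, h in sorted(down, key=lambda t: -t[1]):
            _draw_letter(ax, aa, pos, y + h, -h, font, PathPatch, TextPath, Affine2D)
            y += h
        y_min = min(y_min, y)
    ax.set_xlim(-0.5, n_pos - 0.5)
    span = max(y_max - y_min, 1e-6)
    ax.set_ylim(y_min - 0.05 * span, max(y_max, 1e-6) + 0.05 * span)
    ax.set_xticks(range(n_pos), [str(i + 1) for i in range(n_pos)])
    ax.set_ylabel("bits")
    ax.axhline(0.0, color="0.3", lw=0.8)
    ax.spines[["top", "right"]].set_visible(False)
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()

    path = Path(path)
    written = []
    for fmt in formats:
        out = path.with_suffix(f".{fmt}")
        fig.savefig(out, format=fmt, metadata=_clean_metadata(fmt))
        written.append(out)
    plt.close(fig)
    return written


def _clean_metadata(fmt: str) -> dict:
    # strip timestamps so repeated renders are byte-identical
    if fmt == "svg":
        return {"Date": None}
    if fmt == "pdf":
        return {"CreationDate": None}
    return {}


def _draw_letter(ax, aa, pos, y0, height, font, PathPatch, TextPath, Affine2D):
    tp = TextPath((0, 0), aa, size=1.0, prop=font)
    bbox = tp.get_extents()
    scale_x = 0.9 / bbox.width
    scale_y = height / bbox.height
    transform = (
        Affine2D()
        .translate(-bbox.x0, -bbox.y0)
        .scale(scale_x, scale_y)
        .translate(pos - 0.45, y0)
    )
    ax.add_patch(PathPatch(
        transform.transform_path(tp),
        facecolor=LETTER_COLORS.get(aa, "#555555"),
        edgecolor="none",
    ))


def logo_from_cores(
    cores: list[str],
    kind: str = "kld",
    identity_threshold: float = 0.63,
    beta: float = 200.0,
    background: np.ndarray | None = None,
) -> LogoMatrix:
    """Full path from aligned cores to a logo matrix."""
    wc = hobohm1(Alignment(cores), identity_threshold)
    if wc.n_clusters == 1 and beta == 0:
        p = wc.p_obs
    else:
        p = pseudocount_correct(wc.p_obs, wc.n_clusters, beta)
    if kind == "shannon":
        return shannon_heights(p)
    return kld_heights(p, background)
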