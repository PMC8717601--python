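"""Per-sample QC numbers and multi-sample set intersections.

Two scalar scores summarize a sample:

* **LF (length fraction)** — the fraction of all peptides whose length lies
  in the class-appropriate range (8–12 for class I, 9–22 for class II).
  A proxy for MHC-ligand enrichment: proteolytic contaminants are often
  longer than genuine ligands.
* **BF (binding fraction)** — the fraction of in-range peptides whose
  aggregate call is SB or WB.  A proxy for allele specificity of the
  isolation.

Both are displayed rounded to two decimals but kept at full precision
internally.  Set intersections between samples are exclusive membership
counts (UpSet-style): every peptide in the union is counted in exactly one
subset.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .binding import BinderCall, subset_by_length
from .peptide_io import Sample


@dataclass
class QcMetrics:
    """QC summary for one sample."""

    sample_name: str
    total_peptides: int
    in_range_peptides: int
    lf_score: float
    bf_score: float | None  # None when no in-range peptides (rendered as em dash)
    sb_count: int = 0
    wb_count: int = 0
    nb_count: int = 0

    def __post_init__(self) -> None:
        if self.in_range_peptides > self.total_peptides:
            raise ValueError("in_range_peptides cannot exceed total_peptides")


def round2(x: float) -> float:
    """Round half away from zero to 2 decimals (display convention)."""
    from decimal import ROUND_HALF_UP, Decimal

    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def length_histogram(peptides: set[str], max_len: int = 30) -> dict[int, int]:
    """Counts per length 1..max_len; longer peptides are excluded here only.

    Peptides above ``max_len`` still count toward totals and LF denominators;
    the truncation is display-only.
    """
    hist = {length: 0 for length in range(1, max_len + 1)}
    for p in peptides:
        if len(p) <= max_len:
            hist[len(p)] += 1
    return hist


def lf_score(peptides: set[str], mhc_class: str) -> float:
    """Fraction of all peptides within the class-appropriate length range."""
    if not peptides:
        raise ValueError("lf_score requires a non-empty peptide set")
    in_range = subset_by_length(peptides, mhc_class)
    return len(in_range) / len(peptides)


def bf_score(calls: list[BinderCall]) -> float:
    """Fraction of in-range peptides called SB or WB (aggregate over alleles)."""
    if not calls:
        raise ValueError("bf_score requires at least one in-range peptide")
    bound = sum(1 for c in calls if c in (BinderCall.SB, BinderCall.WB))
    return bound / len(calls)


def compute_metrics(sample: Sample, aggregate_calls: list[BinderCall]) -> QcMetrics:
    """Assemble QcMetrics from a sample and its per-in-range-peptide calls."""
    total = len(sample.peptides)
    in_range = len(subset_by_length(sample.peptides, sample.mhc_class))
    if len(aggregate_calls) != in_range:
        raise ValueError(
            f"expected {in_range} aggregate calls for in-range peptides, "
            f"got {len(aggregate_calls)}"
        )
    counts = Counter(aggregate_calls)
    return QcMetrics(
        sample_name=sample.name,
        total_peptides=total,
        in_range_peptides=in_range,
        lf_score=lf_score(sample.peptides, sample.mhc_class) if total else 0.0,
        bf_score=bf_score(aggregate_calls) if aggregate_calls else None,
        sb_count=counts.get(BinderCall.SB, 0),
        wb_count=counts.get(BinderCall.WB, 0),
        nb_count=counts.get(BinderCall.NB, 0),
    )


@dataclass
class IntersectionSummary:
    """Exclusive intersection counts over every non-empty subset of samples.

    Keys of ``exclusive_counts`` are frozensets of sample names; each
    peptide in the union is counted under exactly the subset of samples
    containing it, so the counts sum to the union size.
    """

    sample_names: list[str]
    exclusive_counts: dict[frozenset[str], int]

    def plot_order(self) -> list[tuple[frozenset[str], int]]:
        """Subsets ordered by descending count, then by subset size."""
        return sorted(
            self.exclusive_counts.items(), key=lambda kv: (-kv[1], len(kv[0]))
        )


def upset_summary(samples: list[Sample]) -> IntersectionSummary:
    """Exclusive membership counts over all non-empty sample subsets."""
    names = [s.name for s in samples]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sample names")
    if len(samples) < 2:
        raise ValueError("upset_summary requires at least 2 samples")
    membership: Counter[frozenset[str]] = Counter()
    universe = set().union(*(s.peptides for s in samples))
    for peptide in universe:
        key = frozenset(s.name for s in samples if peptide in s.peptides)
        membership[key] += 1
    return IntersectionSummary(sample_names=names, exclusive_counts=dict(membership))


def write_sample_metrics(metrics: list[QcMetrics], path: str | Path) -> None:
    """Write the batch metrics file (tab-delimited, one row per sample)."""
    with open(path, "w") as fh:
        fh.write("sample\ttotal_peptides\tlf_score\tbf_score\n")
        for m in metrics:
            bf = f"{round2(m.bf_score):.2f}" if m.bf_score is not None else "—"
            fh.write(
                f"{m.sample_name}\t{m.total_peptides}\t{round2(m.lf_score):.2f}\t{bf}\n"
            )


def read_sample_metrics(path: str | Path) -> list[dict]:
    """Re-parse a metrics file written by :func:`write_sample_metrics`."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            row = dict(zip(header, cells))
            row["total_peptides"] = int(row["total_peptides"])
            row["lf_score"] = float(row["lf_score"])
            row["bf_score"] = None if row["bf_score"] == "—" else float(row["bf_score"])
            rows.append(row)
    return rows
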