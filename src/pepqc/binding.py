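"""Per-peptide, per-allele eluted-ligand percent-rank scores and binder calls.

Peptides are first restricted to the class-specific length subset (8–12-mers
for MHC class I, 9–22-mers for class II), then scored against each allele to
yield an eluted-ligand percent rank (%rank EL; lower is stronger).  Ranks are
annotated categorically with class-specific thresholds:

====== ========== ===========
call   class I    class II
====== ========== ===========
SB     ≤ 0.5      ≤ 2.0
WB     ≤ 2.0      ≤ 10
NB     > 2.0      > 10
====== ========== ===========

A peptide's *aggregate* call over several alleles is its best call — a
peptide that is a weak binder for one allele and a strong binder for
another counts as an SB.

Two predictors are provided: a mock PSSM-based predictor (deterministic,
self-contained, used for testing and synthetic cohorts) and a text adapter
for externally produced NetMHCpan-4.0/4.1 / NetMHCIIpan-4.0 output.
"""

from __future__ import annotations

import re
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np

from .matrices import AA_INDEX, background_frequencies, encode
from .peptide_io import CANONICAL_AA

CLASS_I_LENGTHS = range(8, 13)
CLASS_II_LENGTHS = range(9, 23)

#: %rank thresholds (SB, WB) per MHC class; ranks above WB are NB.
THRESHOLDS = {"I": (0.5, 2.0), "II": (2.0, 10.0)}


class BinderCall(IntEnum):
    """Categorical binder call; ordering SB < WB < NB follows rank thresholds."""

    SB = 0
    WB = 1
    NB = 2


@dataclass
class RankTable:
    """%rank EL matrix over an ordered peptide list and allele list."""

    peptides: list[str]
    alleles: list[str]
    rank: np.ndarray  # shape (len(peptides), len(alleles))

    def __post_init__(self) -> None:
        self.rank = np.asarray(self.rank, dtype=float)
        if self.rank.shape != (len(self.peptides), len(self.alleles)):
            raise ValueError(
                f"rank matrix shape {self.rank.shape} does not match "
                f"{len(self.peptides)} peptides x {len(self.alleles)} alleles"
            )
        if self.rank.size and not (self.rank > 0).all():
            raise ValueError("%rank values must be positive")

    def calls(self, mhc_class: str) -> np.ndarray:
        """Per-cell BinderCall matrix."""
        out = np.empty(self.rank.shape, dtype=np.int8)
        for (i, j), r in np.ndenumerate(self.rank):
            out[i, j] = annotate_rank(r, mhc_class)
        return out

    def aggregate_calls(self, mhc_class: str) -> list[BinderCall]:
        """Best call per peptide across alleles."""
        cells = self.calls(mhc_class)
        return [BinderCall(int(row.min())) for row in cells]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("peptide\t" + "\t".join(self.alleles) + "\n")
            for pep, row in zip(self.peptides, self.rank):
                fh.write(pep + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")


def normalize_allele(name: str) -> str:
    """Canonicalize HLA allele spellings to the starred-colon form.

    Accepts ``HLA-A*02:01``, ``HLA-A02:01`` and ``HLA-A0201``; other names
    (e.g. mouse H-2 or synthetic alleles) pass through unchanged.
    """
    m = re.fullmatch(r"(HLA-)?([A-Z]+[0-9]*)\*?(\d{2}):?(\d{2,3})", name.strip())
    if m:
        return f"HLA-{m.group(2)}*{m.group(3)}:{m.group(4)}"
    return name.strip()


def subset_by_length(peptides: set[str], mhc_class: str) -> set[str]:
    """Class-specific length subset: 8–12-mers (I) or 9–22-mers (II)."""
    lengths = CLASS_I_LENGTHS if mhc_class == "I" else CLASS_II_LENGTHS
    return {p for p in peptides if len(p) in lengths}


def annotate_rank(rank: float, mhc_class: str) -> BinderCall:
    """Call a single %rank value SB, WB or NB with class-specific thresholds."""
    if rank <= 0:
        raise ValueError(f"%rank must be positive, got {rank}")
    sb, wb = THRESHOLDS[mhc_class]
    if rank <= sb:
        return BinderCall.SB
    if rank <= wb:
        return BinderCall.WB
    return BinderCall.NB


def aggregate_call(calls: list[BinderCall]) -> BinderCall:
    """Best (lowest-threshold) call across alleles: any SB wins, then WB, else NB."""
    if not calls:
        raise ValueError("aggregate_call requires at least one call")
    return BinderCall(min(int(c) for c in calls))


# ---------------------------------------------------------------------------
# Mock PSSM predictor
# ---------------------------------------------------------------------------

CORE_LENGTH = 9


@dataclass
class PredictorSpec:
    """Configuration of the rank predictor.

    ``kind`` is ``"mock_pssm"`` (PSSM-scored, empirically calibrated %ranks)
    or ``"external_adapter"`` (parse NetMHCpan/NetMHCIIpan output files).
    The mock predictor requires one 20x9 probability matrix per allele in
    ``pssms``; ranks are percentiles of the peptide's log-odds score within
    a seeded background of uniform-random peptides.
    """

    kind: str = "mock_pssm"
    pssms: dict[str, np.ndarray] = field(default_factory=dict)
    background_size: int = 10_000
    seed: int = 0
    external_paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("mock_pssm", "external_adapter"):
            raise ValueError(f"unknown predictor kind {self.kind!r}")
        for allele, pssm in self.pssms.items():
            pssm = np.asarray(pssm, dtype=float)
            if pssm.shape != (len(CANONICAL_AA), CORE_LENGTH):
                raise ValueError(f"PSSM for {allele} must be 20x{CORE_LENGTH}")
            if not np.allclose(pssm.sum(axis=0), 1.0, atol=1e-6):
                raise ValueError(f"PSSM columns for {allele} must sum to 1")
            self.pssms[allele] = pssm


def _log_odds(pssm: np.ndarray) -> np.ndarray:
    q = background_frequencies()
    return np.log2(pssm / q[:, None])


def score_peptide(peptide: str, pssm: np.ndarray) -> float:
    """Best log-odds score of a peptide against a 9-column PSSM.

    Peptides longer than the core are scored over every contiguous 9-mer
    window; the best window wins.  Peptides one residue short of the core
    are scored with a single matrix-column gap tried at every position,
    the gapped column contributing 0 bits (background vs background).
    """
    lo = _log_odds(pssm)
    idx = encode(peptide)
    n = len(idx)
    if n >= CORE_LENGTH:
        best = -np.inf
        for off in range(n - CORE_LENGTH + 1):
            s = lo[idx[off : off + CORE_LENGTH], np.arange(CORE_LENGTH)].sum()
            best = max(best, float(s))
        return best
    if n == CORE_LENGTH - 1:
        best = -np.inf
        for gap in range(CORE_LENGTH):
            cols = np.delete(np.arange(CORE_LENGTH), gap)
            s = lo[idx, cols].sum()
            best = max(best, float(s))
        return best
    raise ValueError(
        f"peptide {peptide!r} too short for mock scoring (min {CORE_LENGTH - 1})"
    )


def _random_peptides(rng: np.random.Generator, n: int, lengths: range) -> list[str]:
    lens = rng.integers(lengths.start, lengths.stop, size=n)
    return [
        "".join(CANONICAL_AA[i] for i in rng.integers(0, 20, size=ln)) for ln in lens
    ]


class MockPredictor:
    """Deterministic PSSM-based %rank predictor.

    Each allele's %rank of a peptide is 100 x (1 - empirical percentile of
    its log-odds score) within a seeded background of uniform-random
    peptides of the class's length range, mirroring the percent-rank
    semantics of eluted-ligand predictors without their neural networks.
    Ranks are clipped below at 100/background_size so they remain positive.
    """

    def __init__(self, spec: PredictorSpec, mhc_class: str):
        if spec.kind != "mock_pssm":
            raise ValueError("MockPredictor requires a mock_pssm spec")
        self.spec = spec
        self.mhc_class = mhc_class
        self._background_scores: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(spec.seed)
        lengths = CLASS_I_LENGTHS if mhc_class == "I" else CLASS_II_LENGTHS
        background = _random_peptides(rng, spec.background_size, lengths)
        for allele, pssm in spec.pssms.items():
            scores = np.array([score_peptide(p, pssm) for p in background])
            self._background_scores[allele] = np.sort(scores)

    def rank(self, peptide: str, allele: str) -> float:
        if allele not in self.spec.pssms:
            raise KeyError(f"mock predictor has no PSSM for allele {allele!r}")
        bg = self._background_scores[allele]
        score = score_peptide(peptide, self.spec.pssms[allele])
        # fraction of background scoring >= this peptide (higher score = lower rank)
        n_better = len(bg) - np.searchsorted(bg, score, side="left")
        return max(100.0 * n_better / len(bg), 100.0 / len(bg))


_predictor_cache: dict[tuple, "MockPredictor"] = {}


def _cached_predictor(spec: PredictorSpec, mhc_class: str) -> "MockPredictor":
    """Reuse predictors with identical matrices/backgrounds across calls.

    Scoring the random background dominates predictor construction, so a
    batch over many samples with the same alleles pays for it once.
    """
    key = (
        mhc_class, spec.background_size, spec.seed,
        tuple(sorted((a, p.tobytes()) for a, p in spec.pssms.items())),
    )
    if key not in _predictor_cache:
        if len(_predictor_cache) > 8:
            _predictor_cache.clear()
        _predictor_cache[key] = MockPredictor(spec, mhc_class)
    return _predictor_cache[key]


def predict_ranks(
    peptides: list[str] | set[str],
    alleles: list[str],
    spec: PredictorSpec,
    mhc_class: str = "I",
    chunk_size: int = 100,
    workers: int = 1,
) -> RankTable:
    """Score all peptides against all alleles, chunked for concurrency.

    Chunking and worker count are pure scheduling concerns: the result is
    bit-identical for any ``chunk_size``/``workers``.  Work units are
    (chunk, allele) pairs merged back in stable input order.
    """
    if not alleles:
        raise ValueError("at least one allele required")
    ordered = sorted(peptides) if isinstance(peptides, (set, frozenset)) else list(peptides)
    if not ordered:
        return RankTable(peptides=[], alleles=list(alleles), rank=np.empty((0, len(alleles))))

    predictor = _cached_predictor(spec, mhc_class)
    chunks = [ordered[i : i + chunk_size] for i in range(0, len(ordered), chunk_size)]
    jobs = [(ci, aj, chunk, allele)
            for ci, chunk in enumerate(chunks)
            for aj, allele in enumerate(alleles)]

    def run(job):
        ci, aj, chunk, allele = job
        return ci, aj, [predictor.rank(p, allele) for p in chunk]

    if workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(run, jobs))
    else:
        results = [run(j) for j in jobs]

    rank = np.empty((len(ordered), len(alleles)))
    offsets = np.cumsum([0] + [len(c) for c in chunks])
    for ci, aj, values in results:
        rank[offsets[ci] : offsets[ci] + len(values), aj] = values
    return RankTable(peptides=ordered, alleles=list(alleles), rank=rank)


# ---------------------------------------------------------------------------
# External predictor output adapter (NetMHCpan-4.0/4.1, NetMHCIIpan-4.0)
# ---------------------------------------------------------------------------

def parse_external_rank_output(text: str) -> RankTable:
    """Parse whitespace-formatted NetMHCpan-4.x / NetMHCIIpan-4.0 output.

    Extracts the peptide, allele and EL %rank columns from one or more
    per-allele runs concatenated in ``text`` and merges them into a single
    RankTable.  All allele runs must cover the same peptide set.
    """
    per_allele: dict[str, dict[str, float]] = {}
    header_cols: list[str] | None = None
    current_rank_idx = None
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", "-")):
            continue
        fields = stripped.split()
        if fields[0] == "Pos":  # header row of a result block
            header_cols = fields
            # NetMHCpan-4.1 calls it %Rank_EL; 4.0 calls it %Rank; IIpan Rank
            for name in ("%Rank_EL", "%Rank", "Rank"):
                if name in header_cols:
                    current_rank_idx = header_cols.index(name)
                    break
            else:
                raise ValueError("unrecognized layout: no %rank column in header")
            continue
        if header_cols is None or not fields[0].isdigit():
            continue
        if len(fields) < len(header_cols) - 2:
            raise ValueError(f"unrecognized layout: short data row {stripped!r}")
        allele = normalize_allele(fields[1])
        peptide = fields[header_cols.index("Peptide")]
        rank = float(fields[current_rank_idx])
        per_allele.setdefault(allele, {})[peptide] = rank
    if not per_allele:
        raise ValueError("unrecognized layout: no data rows found")

    alleles = list(per_allele)
    peptide_sets = [set(d) for d in per_allele.values()]
    if any(s != peptide_sets[0] for s in peptide_sets[1:]):
        raise ValueError("peptide set mismatch between allele runs")
    first_allele_order = list(per_allele[alleles[0]])
    rank = np.array([[per_allele[a][p] for a in alleles] for p in first_allele_order])
    return RankTable(peptides=first_allele_order, alleles=alleles, rank=rank)
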