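"""Synthetic peptide cohorts with known ground truth.

Real immunopeptidomics samples mix genuine MHC ligands (drawn from
allele-specific motifs, mostly 9-mers for class I) with co-isolated
proteolytic contaminants (length-dispersed, motif-free).  The generator
emulates exactly that: binders are drawn column-independently from a
motif's position-specific scoring matrix and length-varied by terminal
trimming/padding; contaminants are uniform-random residue strings with a
configurable length distribution (placing mass above 12-mers depresses
the LF score, as real contamination does).  Every peptide's origin is
recorded in a manifest so LF/BF and cluster-recovery assertions have
ground truth to compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .binding import CORE_LENGTH
from .matrices import background_frequencies
from .peptide_io import CANONICAL_AA

#: Default binder length distribution (class I eluted-ligand-like).
BINDER_LENGTHS = {8: 0.10, 9: 0.60, 10: 0.15, 11: 0.10, 12: 0.05}

#: Default contaminant length distribution: long, tryptic-fragment-like.
CONTAMINANT_LENGTHS = {13: 0.2, 14: 0.2, 15: 0.15, 16: 0.15, 18: 0.1,
                       20: 0.1, 25: 0.05, 30: 0.05}


@dataclass
class MotifSpec:
    """A synthetic allele motif: a 20x9 PSSM with designated anchors."""

    allele_name: str
    pssm: np.ndarray
    anchor_positions: list[int]  # 1-based
    anchor_residues: dict[int, str]

    def __post_init__(self) -> None:
        self.pssm = np.asarray(self.pssm, dtype=float)
        if self.pssm.shape != (20, CORE_LENGTH):
            raise ValueError("PSSM must be 20x9")
        if not np.allclose(self.pssm.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PSSM columns must sum to 1")
        if any(not 1 <= p <= CORE_LENGTH for p in self.anchor_positions):
            raise ValueError("anchor positions must lie in 1..9")


def make_motif(
    allele_name: str,
    anchor_residues: dict[int, str],
    anchor_strength: float = 0.85,
) -> MotifSpec:
    """Build a motif with near-background columns except at the anchors.

    Anchor columns put ``anchor_strength`` probability on the anchor
    residue and spread the remainder over the other 19 residues by
    background proportion.
    """
    q = background_frequencies()
    pssm = np.tile(q[:, None], (1, CORE_LENGTH))
    if any(not 1 <= p <= CORE_LENGTH for p in anchor_residues):
        raise ValueError("anchor positions must lie in 1..9")
    for pos, residue in anchor_residues.items():
        r = CANONICAL_AA.index(residue)
        col = q.copy()
        col[r] = 0.0
        col = (1.0 - anchor_strength) * col / col.sum()
        col[r] = anchor_strength
        pssm[:, pos - 1] = col
    return MotifSpec(
        allele_name=allele_name,
        pssm=pssm,
        anchor_positions=sorted(anchor_residues),
        anchor_residues=dict(anchor_residues),
    )


def builtin_motifs() -> dict[str, MotifSpec]:
    """Two example motifs with fully disjoint anchor residues.

    Each carries primary anchors at P2/P9 and auxiliary anchors at P3/P7,
    mirroring the primary-plus-auxiliary anchor architecture of real
    class I motifs; no residue is shared between the two motifs' anchors,
    so ground-truth group membership is unambiguous.
    """
    return {
        "SYN-A": make_motif("SYN-A", {2: "L", 3: "W", 7: "Y", 9: "V"}),
        "SYN-B": make_motif("SYN-B", {2: "D", 3: "G", 7: "K", 9: "R"}),
    }


def mock_pssm_for_allele(allele: str, seed: int = 0) -> np.ndarray:
    """Deterministic stand-in PSSM for an arbitrary allele name.

    Known synthetic motifs are returned as-is; other names get a motif
    with P2/P9 anchors drawn from a generator seeded by the allele name,
    so any allele string yields a stable, distinct mock motif.
    """
    builtin = builtin_motifs()
    if allele in builtin:
        return builtin[allele].pssm
    digest = sum(ord(c) * 31**i for i, c in enumerate(allele)) % (2**31)
    rng = np.random.default_rng([seed, digest])
    anchors = {2: CANONICAL_AA[rng.integers(20)], 9: CANONICAL_AA[rng.integers(20)]}
    return make_motif(allele, anchors).pssm


def _draw_lengths(rng: np.random.Generator, n: int, dist: dict[int, float]) -> np.ndarray:
    lengths = np.array(sorted(dist))
    probs = np.array([dist[l] for l in lengths], dtype=float)
    probs /= probs.sum()
    return rng.choice(lengths, size=n, p=probs)


def sample_binders(
    motif: MotifSpec,
    n: int,
    seed: int | np.random.Generator = 0,
    length_distribution: dict[int, float] | None = None,
) -> list[str]:
    """Draw n motif-true peptides, length-varied around the 9-mer core.

    9-mers are drawn column-independently from the PSSM; shorter peptides
    trim the C terminus, longer ones append background-frequency residues.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dist = BINDER_LENGTHS if length_distribution is None else length_distribution
    q = background_frequencies()
    lengths = _draw_lengths(rng, n, dist)
    peptides = []
    for ln in lengths:
        core = "".join(
            CANONICAL_AA[rng.choice(20, p=motif.pssm[:, c])] for c in range(CORE_LENGTH)
        )
        if ln < CORE_LENGTH:
            pep = core[:ln]
        elif ln > CORE_LENGTH:
            tail = "".join(CANONICAL_AA[i] for i in rng.choice(20, size=ln - CORE_LENGTH, p=q))
            pep = core + tail
        else:
            pep = core
        peptides.append(pep)
    return peptides


def sample_contaminants(
    n: int,
    length_distribution: dict[int, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Draw n uniform-random peptides with the given length distribution."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dist = CONTAMINANT_LENGTHS if length_distribution is None else length_distribution
    lengths = _draw_lengths(rng, n, dist)
    return [
        "".join(CANONICAL_AA[i] for i in rng.integers(0, 20, size=ln)) for ln in lengths
    ]


@dataclass
class SampleSpec:
    """Ground-truth recipe for one synthetic sample."""

    name: str
    motifs: list[MotifSpec]
    n_binders_per_allele: int = 500
    contaminant_fraction: float = 0.0
    contaminant_lengths: dict[int, float] = field(
        default_factory=lambda: dict(CONTAMINANT_LENGTHS))
    binder_lengths: dict[int, float] = field(
        default_factory=lambda: dict(BINDER_LENGTHS))

    def __post_init__(self) -> None:
        if not 0.0 <= self.contaminant_fraction <= 1.0:
            raise ValueError("contaminant_fraction must lie in [0, 1]")
        if not 1 <= len(self.motifs) <= 6:
            raise ValueError("between 1 and 6 motifs per sample")


@dataclass
class CohortSpec:
    """Recipe for a multi-sample synthetic cohort."""

    samples: list[SampleSpec]
    shared_peptide_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_peptide_fraction <= 1.0:
            raise ValueError("shared_peptide_fraction must lie in [0, 1]")


def generate_sample(spec: SampleSpec, rng: np.random.Generator) -> list[tuple[str, str]]:
    """Generate (peptide, origin) pairs for one sample spec."""
    n_binders_total = spec.n_binders_per_allele * len(spec.motifs)
    if spec.contaminant_fraction >= 1.0:
        n_binders_total = 0
    pairs: list[tuple[str, str]] = []
    if n_binders_total:
        for motif in spec.motifs:
            for pep in sample_binders(
                motif, spec.n_binders_per_allele, rng, spec.binder_lengths
            ):
                pairs.append((pep, motif.allele_name))
    n_total = (
        int(round(n_binders_total / (1.0 - spec.contaminant_fraction)))
        if spec.contaminant_fraction < 1.0
        else spec.n_binders_per_allele * max(len(spec.motifs), 1)
    )
    n_contaminants = n_total - n_binders_total
    for pep in sample_contaminants(n_contaminants, spec.contaminant_lengths, rng):
        pairs.append((pep, "contaminant"))
    return pairs


def build_cohort(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Write per-sample peptide lists, a config file and a manifest.

    Returns the manifest path.  The manifest records each peptide's
    origin (generating allele, ``contaminant``, or ``shared``), enabling
    LF/BF and cluster-recovery assertions downstream.  Deterministic
    given ``spec.rng_seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.rng_seed)
    manifest_rows: list[tuple[str, str, str]] = []
    first_sample_peptides: list[str] = []
    for si, sample_spec in enumerate(spec.samples):
        pairs = generate_sample(sample_spec, rng)
        if si > 0 and spec.shared_peptide_fraction > 0 and first_sample_peptides:
            n_shared = int(round(len(pairs) * spec.shared_peptide_fraction))
            shared = rng.choice(first_sample_peptides, size=n_shared, replace=False)
            pairs = pairs[: len(pairs) - n_shared] + [(p, "shared") for p in shared]
        if si == 0:
            first_sample_peptides = [p for p, _ in pairs]
        with open(out_dir / f"{sample_spec.name}.txt", "w") as fh:
            for pep, _ in pairs:
                fh.write(pep + "\n")
        manifest_rows += [(pep, sample_spec.name, origin) for pep, origin in pairs]

    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("peptide\tsample\torigin\n")
        for pep, name, origin in manifest_rows:
            fh.write(f"{pep}\t{name}\t{origin}\n")
    with open(out_dir / "cohort_config.txt", "w") as fh:
        fh.write(f"rng_seed\t{spec.rng_seed}\n")
        fh.write(f"shared_peptide_fraction\t{spec.shared_peptide_fraction}\n")
        for s in spec.samples:
            alleles = ",".join(m.allele_name for m in s.motifs)
            fh.write(
                f"sample\t{s.name}\talleles={alleles}\t"
                f"n_binders={s.n_binders_per_allele}\t"
                f"contaminant_fraction={s.contaminant_fraction}\n"
            )
    return manifest
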