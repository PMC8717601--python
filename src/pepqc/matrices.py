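"""Substitution-matrix data: background frequencies and BLOSUM62 conditionals.

The pseudocount correction used for logo probability matrices and Gibbs
clustering needs the conditional substitution probabilities q(b|a).  The
BLOSUM62 log-odds scores s(a,b) = 2·log2(p(a,b)/(q(a)q(b))) are shipped
with biopython; the conditionals are reconstructed from them as

    q(b|a) ∝ q(b) · 2^(s(a,b)/2),   normalized over b,

which inverts the log-odds up to the integer rounding of the published
matrix.  Background frequencies q(b) are the standard natural
amino-acid composition shipped in ``data/background_frequencies.txt``.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices

from .peptide_io import CANONICAL_AA

AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}


@lru_cache(maxsize=1)
def background_frequencies() -> np.ndarray:
    """Background frequency vector q(b), ordered as ``CANONICAL_AA``."""
    freqs = {}
    text = resources.files("pepqc.data").joinpath("background_frequencies.txt").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, val = line.split()
        freqs[aa] = float(val)
    q = np.array([freqs[aa] for aa in CANONICAL_AA])
    return q / q.sum()


@lru_cache(maxsize=1)
def blosum62_conditional() -> np.ndarray:
    """Conditional substitution matrix Q with Q[a, b] = q(b|a); rows sum to 1."""
    blosum = substitution_matrices.load("BLOSUM62")
    q = background_frequencies()
    n = len(CANONICAL_AA)
    cond = np.empty((n, n))
    for i, a in enumerate(CANONICAL_AA):
        for j, b in enumerate(CANONICAL_AA):
            cond[i, j] = q[j] * 2.0 ** (blosum[a, b] / 2.0)
    cond /= cond.sum(axis=1, keepdims=True)
    return cond


def encode(peptide: str) -> np.ndarray:
    """Integer-encode a peptide over the canonical alphabet."""
    return np.array([AA_INDEX[c] for c in peptide], dtype=np.intp)
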