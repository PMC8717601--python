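"""Reading and normalizing peptide lists.

Search-engine exports arrive as plain text (one peptide per line) or as
delimited tables from which a sequence column is selected.  Before any
analysis, sequences are stripped of flanking residues (``P.KAPDNRETL.V`` →
``KAPDNRETL``), stripped of chemical-modification annotations (e.g.
oxidation of methionine, carbamidomethylation), and filtered to the
20-letter canonical amino-acid alphabet.  Peptide lists are treated as
sets: duplicates are collapsed before all downstream analysis.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

#: Residue-string symbols removed by modification stripping (outside brackets).
_INLINE_JUNK = re.compile(r"[0-9+\-.*]")


class PeptideError(ValueError):
    """Raised for malformed peptide records (e.g. unbalanced brackets)."""


@dataclass(frozen=True)
class RawPeptideRecord:
    """One non-empty data row as read from a peptide list file."""

    text: str
    source_line: int

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise PeptideError(f"empty record at line {self.source_line}")
        if self.source_line < 1:
            raise PeptideError("source_line must be >= 1")


@dataclass
class Sample:
    """A named peptide sample with its MHC class and allele list.

    ``peptides`` is a deduplicated set of canonical sequences;
    ``dropped_count`` records how many input rows were removed by
    preprocessing (non-canonical residues plus collapsed duplicates).
    """

    name: str
    mhc_class: str  # "I" or "II"
    alleles: list[str]
    peptides: set[str] = field(default_factory=set)
    dropped_count: int = 0

    def __post_init__(self) -> None:
        if self.mhc_class not in ("I", "II"):
            raise ValueError(f"mhc_class must be 'I' or 'II', got {self.mhc_class!r}")
        if not 1 <= len(self.alleles) <= 6:
            raise ValueError(
                f"sample {self.name!r}: between 1 and 6 alleles required, "
                f"got {len(self.alleles)}"
            )


def _sniff_delimiter(path: Path) -> str:
    if path.suffix.lower() == ".csv":
        return ","
    if path.suffix.lower() == ".tsv":
        return "\t"
    # plain .txt may still be delimited; sniff the first line
    with open(path, newline="") as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return "\n"  # single column, one peptide per line


def _looks_like_header(cells: list[str], multi_column: bool) -> bool:
    """Heuristic header detection.

    A row is a header if, in a multi-column file, any cell fails to parse
    as a peptide-ish token or is a lowercase-containing word (column
    titles like "Peptide" or "Intensity" are made of canonical letters);
    or if a single-column first row contains lowercase/space characters.
    """
    if multi_column:
        return any(
            not _peptide_like(c) or re.search(r"[a-z]", c)
            for c in cells if c.strip()
        )
    cell = cells[0]
    return bool(re.search(r"[a-z ]", cell)) and not _peptide_like(cell)


def _peptide_like(text: str) -> bool:
    """True if ``text`` could plausibly be a (possibly modified) peptide."""
    stripped = re.sub(r"\(.*?\)|\[.*?\]", "", text)
    stripped = _INLINE_JUNK.sub("", stripped)
    return bool(stripped) and all(c.upper() in _CANONICAL_SET or c == "." for c in stripped)


def read_peptide_table(path: str | Path, column: str | None = None) -> list[RawPeptideRecord]:
    """Read one peptide record per non-empty data row.

    Parameters
    ----------
    path:
        A ``.txt`` (one peptide per line), ``.csv`` or ``.tsv`` file.
    column:
        Header name of the sequence column.  Required when the file has
        more than one column; ignored for single-column files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = _sniff_delimiter(path)

    records: list[RawPeptideRecord] = []
    with open(path, newline="") as fh:
        if delim == "\n":
            rows = [[line.rstrip("\r\n")] for line in fh]
        else:
            rows = list(csv.reader(fh, delimiter=delim))
    rows = [(i + 1, r) for i, r in enumerate(rows)]
    rows = [(ln, r) for ln, r in rows if any(c.strip() for c in r)]
    if not rows:
        return []

    first_cells = rows[0][1]
    multi_column = max(len(r) for _, r in rows) > 1
    has_header = _looks_like_header([c.strip() for c in first_cells], multi_column)

    col_idx = 0
    if multi_column:
        if column is None:
            raise ValueError(
                f"{path}: column selection required for multi-column files"
            )
        if not has_header:
            raise ValueError(f"{path}: multi-column file has no detectable header row")
        header = [c.strip() for c in first_cells]
        if column not in header:
            raise ValueError(f"{path}: column {column!r} not found in header {header}")
        col_idx = header.index(column)
    elif column is not None and has_header and first_cells[0].strip() != column:
        raise ValueError(f"{path}: column {column!r} not found")

    data_rows = rows[1:] if has_header else rows
    for line_no, cells in data_rows:
        if col_idx >= len(cells):
            continue
        text = cells[col_idx].strip()
        if text:
            records.append(RawPeptideRecord(text=text, source_line=line_no))
    return records


def strip_flanks(text: str) -> str:
    """Remove flanking residues written as ``X.PEPTIDE.Y``.

    The pattern must split on ``.`` into exactly three parts with
    single-character outer parts (a residue or ``-`` for a terminus);
    anything else passes through unchanged.
    """
    parts = text.split(".")
    if len(parts) == 3 and parts[1]:
        left, middle, right = parts
        if len(left) == 1 and len(right) == 1:
            lc, rc = left.upper(), right.upper()
            if (lc in _CANONICAL_SET or lc == "-") and (rc in _CANONICAL_SET or rc == "-"):
                return middle
    return text


def strip_modifications(text: str) -> str:
    """Remove chemical-modification annotations from a residue string.

    Removes every parenthesized ``(...)`` and bracketed ``[...]``
    substring (including nested content), then removes digits and the
    symbols ``+ - . *`` from what remains, and uppercases the result.

    Raises
    ------
    PeptideError
        If brackets or parentheses are unbalanced.
    """
    out: list[str] = []
    depth = 0
    for ch in text:
        if ch in "([":
            depth += 1
        elif ch in ")]":
            depth -= 1
            if depth < 0:
                raise PeptideError(f"unbalanced bracket in record {text!r}")
        elif depth == 0:
            out.append(ch)
    if depth != 0:
        raise PeptideError(f"unbalanced bracket in record {text!r}")
    return _INLINE_JUNK.sub("", "".join(out)).upper()


def is_canonical(sequence: str) -> bool:
    """True if ``sequence`` is non-empty and uses only the 20 canonical residues."""
    return bool(sequence) and all(c in _CANONICAL_SET for c in sequence)


def filter_canonical(sequences: list[str]) -> tuple[set[str], int]:
    """Keep canonical sequences, deduplicated.

    Returns the set of retained peptides and the number of input strings
    dropped (non-canonical rejects plus duplicates collapsed).
    """
    kept: set[str] = set()
    dropped = 0
    for seq in sequences:
        if not is_canonical(seq):
            dropped += 1
        elif seq in kept:
            dropped += 1
        else:
            kept.add(seq)
    return kept, dropped


def clean_records(records: list[RawPeptideRecord]) -> tuple[set[str], int]:
    """Full preprocessing: flank strip, modification strip, canonical filter."""
    cleaned = [strip_modifications(strip_flanks(r.text)) for r in records]
    return filter_canonical(cleaned)


def load_sample(
    path: str | Path,
    name: str,
    mhc_class: str,
    alleles: list[str],
    column: str | None = None,
) -> Sample:
    """Read, preprocess and package one sample's peptide list."""
    records = read_peptide_table(path, column=column)
    peptides, dropped = clean_records(records)
    logger.info(
        "sample %s: %d records read, %d peptides kept, %d dropped",
        name, len(records), len(peptides), dropped,
    )
    return Sample(
        name=name, mhc_class=mhc_class, alleles=list(alleles),
        peptides=peptides, dropped_count=dropped,
    )
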