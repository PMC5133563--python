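"""Protein I/O and lysine-centered peptide window extraction.

A candidate malonylation site is represented as a fixed-length peptide window
centered on a lysine (K): ``xi`` residues upstream, the K itself, and ``eta``
residues downstream.  Positions that fall outside the protein are padded with
the dummy residue ``X``.  With the default ``xi=6, eta=9`` every window is a
16-mer, the geometry chosen to cover the flanking context observed in
proteomics-derived malonyl-peptides.

Site positions are 1-based in all I/O (UniProt convention); indices are
0-based internally.  Window positions are labeled -xi..-1, 0, +1..+eta with
the candidate K at 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

log = logging.getLogger("malsite")

#: The 20 native amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Dummy residue used for terminal padding and substituted unknowns.
PAD_CHAR = "X"
#: Full 21-symbol encoding alphabet.
ALPHABET = AMINO_ACIDS + PAD_CHAR

_NONSTANDARD = set("BJOUZ*")


class ParseError(ValueError):
    """Raised for malformed FASTA or tabular inputs."""


class AnnotationError(ValueError):
    """Raised when site annotations are inconsistent with the sequences."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("protein record with empty id")
        if not self.sequence:
            raise ParseError(f"protein {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class SiteAnnotation:
    """A labeled candidate site: 1-based lysine position in a protein."""

    protein_id: str
    position: int
    label: int  # 1 = malonylated (positive), 0 = non-malonylated (negative)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise AnnotationError(
                f"{self.protein_id}: site position must be 1-based, got {self.position}"
            )
        if self.label not in (0, 1):
            raise AnnotationError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class WindowConfig:
    """Window geometry: ``xi`` upstream, center K, ``eta`` downstream."""

    xi: int = 6
    eta: int = 9
    pad_char: str = PAD_CHAR

    def __post_init__(self) -> None:
        if self.xi < 0 or self.eta < 0:
            raise ValueError("xi and eta must be non-negative")
        if len(self.pad_char) != 1:
            raise ValueError("pad_char must be a single symbol")

    @property
    def length(self) -> int:
        return self.xi + 1 + self.eta

    @property
    def center_index(self) -> int:
        return self.xi


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-length window over the 21-letter alphabet.

    ``label`` is 1/0 for benchmark windows and None for query windows.
    """

    residues: str
    protein_id: str | None = None
    position: int | None = None  # 1-based position of the center in the protein
    label: int | None = None

    def __post_init__(self) -> None:
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"window contains symbols outside the 21-letter alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def center_residue(self, config: WindowConfig) -> str:
        return self.residues[config.center_index]


def sanitize_sequence(seq: str, record_id: str = "?") -> str:
    """Uppercase and map non-standard residues (B, J, O, U, Z, *, ...) to X.

    The encoding alphabet is fixed at 21 symbols, so anything outside the 20
    native amino acids becomes the dummy residue, with a logged warning.
    """
    seq = seq.upper()
    out = []
    replaced: set[str] = set()
    for ch in seq:
        if ch in AMINO_ACIDS or ch == PAD_CHAR:
            out.append(ch)
        else:
            replaced.add(ch)
            out.append(PAD_CHAR)
    if replaced:
        log.warning(
            "protein %s: mapped non-standard residues %s to %s",
            record_id, sorted(replaced), PAD_CHAR,
        )
    return "".join(out)


# ---------------------------------------------------------------------------
# FASTA and tabular I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords, preserving order.

    Sequences are uppercased and sanitized; duplicate ids are an error.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: FASTA entry with empty header")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq)
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(rec.id, sanitize_sequence(seq, rec.id)))
        seen.add(rec.id)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_LABEL_MAP = {"1": 1, "0": 0, "positive": 1, "negative": 0}


def read_site_table(path: str | Path) -> list[SiteAnnotation]:
    """Read a TSV with columns protein_id, position, label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "position", "label"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: site table must have columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        label = _LABEL_MAP.get(str(row.label).strip().lower())
        if label is None:
            raise ParseError(f"{path}: unrecognized label {row.label!r}")
        out.append(SiteAnnotation(str(row.protein_id), int(row.position), label))
    return out


def write_site_table(annotations: Iterable[SiteAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [(a.protein_id, a.position, a.label) for a in annotations],
        columns=["protein_id", "position", "label"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_peptides(path: str | Path) -> list[PeptideWindow]:
    """Read a labeled peptide TSV (columns: peptide, label [, protein_id, position])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "peptide" not in df.columns or "label" not in df.columns:
        raise ParseError(f"{path}: peptide table must have columns peptide, label")
    has_src = {"protein_id", "position"}.issubset(df.columns)
    out = []
    for row in df.itertuples(index=False):
        label = _LABEL_MAP.get(str(row.label).strip().lower())
        if label is None:
            raise ParseError(f"{path}: unrecognized label {row.label!r}")
        out.append(
            PeptideWindow(
                str(row.peptide).upper(),
                protein_id=str(row.protein_id) if has_src and not pd.isna(row.protein_id) else None,
                position=int(row.position) if has_src and not pd.isna(row.position) else None,
                label=label,
            )
        )
    return out


def write_peptides(windows: Iterable[PeptideWindow], path: str | Path) -> None:
    rows = [(w.residues, w.label, w.protein_id or "", w.position if w.position is not None else "")
            for w in windows]
    df = pd.DataFrame(rows, columns=["peptide", "label", "protein_id", "position"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Window extraction and benchmark assembly
# ---------------------------------------------------------------------------

def extract_window(
    protein: ProteinRecord,
    position: int,
    config: WindowConfig = WindowConfig(),
    require_center_lysine: bool = False,
) -> PeptideWindow:
    """Extract the xi+1+eta window centered at a 1-based ``position``.

    Residues falling outside the protein are replaced by ``config.pad_char``.
    """
    seq = protein.sequence
    if not 1 <= position <= len(seq):
        raise AnnotationError(
            f"{protein.id}: position {position} out of range 1..{len(seq)}"
        )
    center = position - 1
    if require_center_lysine and seq[center] != "K":
        raise AnnotationError(
            f"{protein.id}: residue at position {position} is {seq[center]!r}, not K"
        )
    parts = []
    for i in range(center - config.xi, center + config.eta + 1):
        parts.append(seq[i] if 0 <= i < len(seq) else config.pad_char)
    return PeptideWindow("".join(parts), protein_id=protein.id, position=position)


def build_benchmark(
    proteins: Sequence[ProteinRecord],
    annotations: Sequence[SiteAnnotation],
    config: WindowConfig = WindowConfig(),
    auto_negative: bool | None = None,
) -> list[PeptideWindow]:
    """Assemble labeled windows from proteins and site annotations.

    If ``auto_negative`` is True (default: enabled automatically when the
    annotation list contains no explicit negatives), every lysine in the
    annotated proteins that is not annotated positive becomes a negative
    window — the standard construction for PTM benchmarks where experiments
    report modified sites only.
    """
    by_id = {p.id: p for p in proteins}
    if len(by_id) != len(proteins):
        raise ParseError("duplicate protein ids in input collection")
    missing = sorted({a.protein_id for a in annotations} - set(by_id))
    if missing:
        raise AnnotationError(f"annotations refer to unknown proteins: {missing}")

    offenders = [
        f"{a.protein_id}:{a.position}({by_id[a.protein_id].sequence[a.position - 1]})"
        for a in annotations
        if not (1 <= a.position <= len(by_id[a.protein_id].sequence))
        or by_id[a.protein_id].sequence[a.position - 1] != "K"
    ]
    if offenders:
        raise AnnotationError(f"annotated sites are not lysine residues: {offenders}")

    if auto_negative is None:
        auto_negative = not any(a.label == 0 for a in annotations)

    windows: list[PeptideWindow] = []
    for a in annotations:
        w = extract_window(by_id[a.protein_id], a.position, config)
        windows.append(replace(w, label=a.label))

    if auto_negative:
        positive_keys = {(a.protein_id, a.position) for a in annotations if a.label == 1}
        annotated_ids = {a.protein_id for a in annotations}
        explicit = {(a.protein_id, a.position) for a in annotations}
        for pid in sorted(annotated_ids):
            seq = by_id[pid].sequence
            for i, ch in enumerate(seq):
                key = (pid, i + 1)
                if ch == "K" and key not in positive_keys and key not in explicit:
                    w = extract_window(by_id[pid], i + 1, config)
                    windows.append(replace(w, label=0))
    return windows


# ---------------------------------------------------------------------------
# Redundancy filtering
# ---------------------------------------------------------------------------

def hamming_identity(a: str, b: str) -> float:
    """Fraction of positions at which two equal-length windows agree.

    The dummy residue X counts as an ordinary symbol.
    """
    if len(a) != len(b):
        raise ValueError("identity requires equal-length windows")
    return sum(x == y for x, y in zip(a, b)) / len(a)


@dataclass(frozen=True)
class RemovalRecord:
    removed: PeptideWindow
    closest_retained: PeptideWindow
    identity: float


def redundancy_filter(
    windows: Sequence[PeptideWindow],
    threshold: float = 0.4,
    scope: str = "all",
) -> tuple[list[PeptideWindow], list[RemovalRecord]]:
    """Greedy single-pass redundancy removal at a pairwise-identity threshold.

    Windows are scanned in input order; a window is removed if its Hamming
    identity to any *previously retained* window is >= ``threshold``.  The
    earlier window always wins a conflict, making the result deterministic.
    ``scope='within-class'`` restricts comparisons to windows with the same
    label; ``scope='all'`` (default) compares across the whole set.

    Returns the retained windows and a removal log recording, for each removed
    window, its closest retained match and their identity.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if scope not in ("all", "within-class"):
        raise ValueError(f"unknown scope {scope!r}")
    lengths = {len(w) for w in windows}
    if len(lengths) > 1:
        raise ValueError(f"mixed window lengths: {sorted(lengths)}")

    kept: list[PeptideWindow] = []
    removed: list[RemovalRecord] = []
    for w in windows:
        best_id, best_match = -1.0, None
        for k in kept:
            if scope == "within-class" and k.label != w.label:
                continue
            ident = hamming_identity(w.residues, k.residues)
            if ident > best_id:
                best_id, best_match = ident, k
        if best_match is not None and best_id >= threshold:
            removed.append(RemovalRecord(w, best_match, best_id))
        else:
            kept.append(w)
    return kept, removed
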