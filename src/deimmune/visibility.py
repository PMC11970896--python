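"""MHC-I immune-visibility of protein sequences.

The *absolute visibility* of a sequence is the number of its 8-, 9- and
10-mers that a presentation predictor calls presented, counting overlapping
windows separately and counting a k-mer once regardless of how many MHC-I
alleles would display it (the predictor interface is already allele-pooled).
*Relative visibility* divides a design's visibility by its template's: a
design with visibility 9 against a template with 36 scores 0.25.

Windows containing unknown residues (``X``) are "unclear": they never add to
visibility but are counted so that low-confidence reports can be flagged.
Residues can be annotated as epitope (inside a presented window), anchor
(second or last position of a presented window), unclear, or none.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from .alphabet import UNCLEAR, PEPTIDE_LENGTHS
from .presentation import PresentationCall, PresentationPredictor

__all__ = [
    "KmerCall",
    "VisibilityReport",
    "ResidueCategory",
    "enumerate_kmers",
    "absolute_visibility",
    "relative_visibility",
    "annotate_residues",
    "multi_chain_visibility",
    "render_annotation",
]


class KmerCall(NamedTuple):
    """One scanned window: 0-based half-open ``[start, start+length)``."""

    start: int
    length: int
    presented: PresentationCall


def enumerate_kmers(
    sequence: str, lengths: Iterable[int] = PEPTIDE_LENGTHS
) -> list[tuple[int, int, str]]:
    """All contiguous windows of each requested length, left to right.

    Returns ``(start, length, peptide)`` triples with 0-based half-open
    coordinates.  An 11-residue sequence yields four 8-mers, three 9-mers
    and two 10-mers.  Sequences shorter than every requested length yield
    an empty list.
    """
    out: list[tuple[int, int, str]] = []
    for L in sorted(set(int(x) for x in lengths)):
        for s in range(0, len(sequence) - L + 1):
            out.append((s, L, sequence[s : s + L]))
    return out


@dataclass
class VisibilityReport:
    """Per-window presentation calls and the visibility counts they imply."""

    sequence: str
    kmer_calls: list[KmerCall]
    predictor_name: str
    lengths: tuple[int, ...] = PEPTIDE_LENGTHS
    coordinate_convention: str = "0-based, half-open"

    absolute_visibility: int = field(init=False)
    unclear_count: int = field(init=False)

    def __post_init__(self) -> None:
        self.absolute_visibility = sum(
            1 for c in self.kmer_calls if c.presented is True
        )
        self.unclear_count = sum(
            1 for c in self.kmer_calls if c.presented is UNCLEAR
        )

    @property
    def total_kmers(self) -> int:
        return len(self.kmer_calls)

    def expected_kmer_count(self) -> int:
        """Closed-form window count Σ_L max(0, len - L + 1)."""
        n = len(self.sequence)
        return sum(max(0, n - L + 1) for L in self.lengths)

    def presented_windows(self) -> list[KmerCall]:
        return [c for c in self.kmer_calls if c.presented is True]

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "predictor": self.predictor_name,
            "coordinate_convention": self.coordinate_convention,
            "absolute_visibility": self.absolute_visibility,
            "unclear_count": self.unclear_count,
            "total_kmers": self.total_kmers,
            "kmer_calls": [
                {
                    "start": c.start,
                    "length": c.length,
                    "presented": None if c.presented is UNCLEAR else bool(c.presented),
                }
                for c in self.kmer_calls
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))


def absolute_visibility(
    sequence: str,
    predictor: PresentationPredictor,
    lengths: Iterable[int] = PEPTIDE_LENGTHS,
) -> VisibilityReport:
    """Scan *sequence* with *predictor* and count presented windows.

    Each enumerated window is assessed exactly once; duplicate peptide
    strings at different positions are counted separately, while repeated
    strings are evaluated through a small cache so the predictor sees each
    distinct peptide once.
    """
    cache: dict[str, PresentationCall] = {}
    calls: list[KmerCall] = []
    for start, L, pep in enumerate_kmers(sequence, lengths):
        if pep not in cache:
            cache[pep] = predictor(pep)
        calls.append(KmerCall(start, L, cache[pep]))
    return VisibilityReport(
        sequence=sequence,
        kmer_calls=calls,
        predictor_name=getattr(predictor, "name", type(predictor).__name__),
        lengths=tuple(sorted(set(int(x) for x in lengths))),
    )


def relative_visibility(design_visibility: float, template_visibility: float) -> float:
    """Design visibility divided by template visibility.

    Returns ``nan`` (the "undefined" marker) when the template visibility is
    zero; raises on negative inputs.
    """
    if design_visibility < 0 or template_visibility < 0:
        raise ValueError("visibilities must be non-negative")
    if template_visibility == 0:
        return math.nan
    return design_visibility / template_visibility


def multi_chain_visibility(
    chains: Sequence[str],
    predictor: PresentationPredictor,
    lengths: Iterable[int] = PEPTIDE_LENGTHS,
) -> tuple[int, list[VisibilityReport]]:
    """Visibility of a multi-chain protein: per-chain scans, summed.

    No window spans a chain break (the proteasome does not splice chains).
    """
    reports = [absolute_visibility(c, predictor, lengths) for c in chains]
    return sum(r.absolute_visibility for r in reports), reports


class ResidueCategory(str, Enum):
    """Per-residue annotation, mirroring the black/yellow/red/gray rendering."""

    NONE = "none"
    EPITOPE = "epitope"
    ANCHOR = "anchor"
    UNCLEAR = "unclear"


def annotate_residues(
    sequence: str,
    predictor: PresentationPredictor,
    lengths: Iterable[int] = PEPTIDE_LENGTHS,
    report: VisibilityReport | None = None,
) -> list[ResidueCategory]:
    """Categorize every residue by its role in presented windows.

    Precedence: anchor (second or terminal residue of at least one presented
    window) > epitope (inside at least one presented window) > unclear
    (inside at least one 'X'-containing window and no presented one) > none.
    """
    if report is None:
        report = absolute_visibility(sequence, predictor, lengths)
    cats = [ResidueCategory.NONE] * len(sequence)
    # Mark unclear coverage first; epitope/anchor overwrite it.
    for c in report.kmer_calls:
        if c.presented is UNCLEAR:
            for i in range(c.start, c.start + c.length):
                cats[i] = ResidueCategory.UNCLEAR
    for c in report.kmer_calls:
        if c.presented is True:
            for i in range(c.start, c.start + c.length):
                if cats[i] is not ResidueCategory.ANCHOR:
                    cats[i] = ResidueCategory.EPITOPE
    for c in report.kmer_calls:
        if c.presented is True:
            cats[c.start + 1] = ResidueCategory.ANCHOR
            cats[c.start + c.length - 1] = ResidueCategory.ANCHOR
    return cats


_ANSI = {
    ResidueCategory.NONE: "\x1b[0m",
    ResidueCategory.EPITOPE: "\x1b[33m",  # yellow
    ResidueCategory.ANCHOR: "\x1b[31m",  # red
    ResidueCategory.UNCLEAR: "\x1b[90m",  # gray
}
_HTML = {
    ResidueCategory.NONE: "black",
    ResidueCategory.EPITOPE: "goldenrod",
    ResidueCategory.ANCHOR: "red",
    ResidueCategory.UNCLEAR: "gray",
}


def render_annotation(
    sequence: str, categories: Sequence[ResidueCategory], mode: str = "ansi"
) -> str:
    """Render a sequence with epitope/anchor/unclear coloring.

    ``mode='ansi'`` emits terminal escape codes; ``mode='html'`` emits
    ``<span>`` elements.  Black = outside every predicted epitope, yellow =
    epitope, red = anchor, gray = unclear.
    """
    if len(sequence) != len(categories):
        raise ValueError("sequence and categories differ in length")
    if mode == "ansi":
        parts = [f"{_ANSI[c]}{ch}" for ch, c in zip(sequence, categories)]
        return "".join(parts) + "\x1b[0m"
    if mode == "html":
        parts = [
            f'<span style="color:{_HTML[c]}">{ch}</span>'
            for ch, c in zip(sequence, categories)
        ]
        return "".join(parts)
    raise ValueError(f"unknown render mode {mode!r}")
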