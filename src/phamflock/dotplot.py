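"""Exact-word dot plots of concatenated genomes or proteomes.

A dot plot places a point at (i, j) whenever the word of length ``word``
starting at position i of the x sequence equals the word starting at
position j of the y sequence (for nucleotide plots, reverse-complement
matches are reported too, flagged with their orientation).  Concatenating
per-phage segments along each axis, with a sentinel between segments that
can never participate in a match, turns the plot into an all-vs-all
population comparison: on-diagonal blocks are self/intracluster similarity,
off-diagonal blocks are cross-phage similarity.  Defaults follow common
practice for genome/proteome word plots: word 15 for nucleotide, 5 for
amino-acid sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio.Seq import Seq

from .io_formats import AnnotatedGenome

__all__ = [
    "AxisSegment",
    "DotplotMatchSet",
    "word_matches",
    "concatenated_dotplot",
]

SENTINEL = "#"  # outside both the nucleotide and amino-acid alphabets

DEFAULT_WORD = {"nucleotide": 15, "protein": 5}


@dataclass(frozen=True)
class AxisSegment:
    """One phage's extent on a dot-plot axis (0-based, end-exclusive)."""

    phage: str
    offset: int
    length: int

    @property
    def end(self) -> int:
        return self.offset + self.length


@dataclass
class DotplotMatchSet:
    """All exact word matches between two (possibly concatenated) sequences."""

    word: int
    alphabet: str  # "nucleotide" or "protein"
    x_segments: list[AxisSegment]
    y_segments: list[AxisSegment]
    matches: list[tuple[int, int, str]] = field(default_factory=list)  # (x, y, orientation)

    def segment_of(self, axis: str, position: int) -> AxisSegment:
        segments = self.x_segments if axis == "x" else self.y_segments
        for seg in segments:
            if seg.offset <= position < seg.end:
                return seg
        raise ValueError(f"position {position} outside {axis} axis")

    def matches_between(self, phage_x: str, phage_y: str) -> list[tuple[int, int, str]]:
        seg_x = next(s for s in self.x_segments if s.phage == phage_x)
        seg_y = next(s for s in self.y_segments if s.phage == phage_y)
        return [
            (x, y, o)
            for x, y, o in self.matches
            if seg_x.offset <= x < seg_x.end and seg_y.offset <= y < seg_y.end
        ]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matches, columns=["x", "y", "orientation"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def boundaries_dataframe(self) -> pd.DataFrame:
        rows = [
            {"axis": axis, "phage": s.phage, "start": s.offset, "end": s.end}
            for axis, segs in (("x", self.x_segments), ("y", self.y_segments))
            for s in segs
        ]
        return pd.DataFrame(rows)

    def text_raster(self, bins: int = 60) -> str:
        """Coarse character raster of the match set (rows are y, top down)."""
        nx = max(s.end for s in self.x_segments)
        ny = max(s.end for s in self.y_segments)
        grid = [[" "] * bins for _ in range(bins)]
        for x, y, orientation in self.matches:
            bx = min(int(x * bins / nx), bins - 1)
            by = min(int(y * bins / ny), bins - 1)
            ch = "." if orientation == "forward" else ","
            if grid[by][bx] == " " or ch == ".":
                grid[by][bx] = ch
        return "\n".join("".join(row) for row in reversed(grid))


def _validate_alphabet(alphabet: str) -> None:
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"alphabet must be 'nucleotide' or 'protein', got {alphabet!r}")


def word_matches(
    seq_x: str,
    seq_y: str,
    word: int,
    alphabet: str = "nucleotide",
    *,
    revcomp: bool = True,
    x_segments: list[AxisSegment] | None = None,
    y_segments: list[AxisSegment] | None = None,
) -> DotplotMatchSet:
    """Exhaustive exact word matching between two sequences.

    Returns every (i, j) with ``seq_x[i:i+word] == seq_y[j:j+word]``; for
    the nucleotide alphabet, positions where the x word equals the reverse
    complement of the y word are reported with orientation ``revcomp``.
    Words containing the concatenation sentinel never match.
    """
    _validate_alphabet(alphabet)
    if word < 1:
        raise ValueError("word must be >= 1")
    if len(seq_x) < word or len(seq_y) < word:
        raise ValueError(f"both sequences must be at least word size ({word}) long")

    index: dict[str, list[int]] = {}
    for j in range(len(seq_y) - word + 1):
        w = seq_y[j : j + word]
        if SENTINEL in w:
            continue
        index.setdefault(w, []).append(j)

    matches: list[tuple[int, int, str]] = []
    do_rc = revcomp and alphabet == "nucleotide"
    for i in range(len(seq_x) - word + 1):
        w = seq_x[i : i + word]
        if SENTINEL in w:
            continue
        for j in index.get(w, ()):
            matches.append((i, j, "forward"))
        if do_rc:
            wrc = str(Seq(w).reverse_complement())
            for j in index.get(wrc, ()):
                matches.append((i, j, "revcomp"))

    if x_segments is None:
        x_segments = [AxisSegment("x", 0, len(seq_x))]
    if y_segments is None:
        y_segments = [AxisSegment("y", 0, len(seq_y))]
    return DotplotMatchSet(
        word=word,
        alphabet=alphabet,
        x_segments=x_segments,
        y_segments=y_segments,
        matches=matches,
    )


def _concatenate(
    genomes: Sequence[AnnotatedGenome], level: str, word: int
) -> tuple[str, list[AxisSegment]]:
    parts: list[str] = []
    segments: list[AxisSegment] = []
    offset = 0
    sentinel = SENTINEL * word
    for k, genome in enumerate(genomes):
        if level == "genome":
            seq = genome.sequence
        else:
            if not genome.genes:
                raise ValueError(f"genome {genome.name} has no annotated genes")
            seq = "".join(g.protein_seq for g in genome.genes)
        if k > 0:
            parts.append(sentinel)
            offset += word
        parts.append(seq)
        segments.append(AxisSegment(genome.name, offset, len(seq)))
        offset += len(seq)
    return "".join(parts), segments


def concatenated_dotplot(
    genomes: Sequence[AnnotatedGenome],
    level: str = "genome",
    word: int | None = None,
    *,
    revcomp: bool = True,
) -> DotplotMatchSet:
    """Self dot plot of a population's concatenated genomes or proteomes.

    Per-phage segments are joined with a word-length sentinel run, so no
    match can cross a phage boundary; the axis segment table attributes
    every block to a phage pair.
    """
    if not genomes:
        raise ValueError("at least one genome is required")
    if level not in ("genome", "proteome"):
        raise ValueError("level must be 'genome' or 'proteome'")
    alphabet = "nucleotide" if level == "genome" else "protein"
    if word is None:
        word = DEFAULT_WORD[alphabet]
    seq, segments = _concatenate(genomes, level, word)
    return word_matches(
        seq,
        seq,
        word,
        alphabet,
        revcomp=revcomp,
        x_segments=segments,
        y_segments=segments,
    )
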