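"""Sliding-window nucleotide diversity (π) and divergence-hotspot calling.

π is the average pairwise proportion of nucleotide differences per site.
Windows use site-complete deletion: a column where any sequence carries a
gap or N is excluded from both the difference and site counts (DnaSP-style
windowed behaviour, and the convention its 400 bp / 200 bp plastome scans
assume).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

from .genome import GeneFeature, QuadripartitePartition

__all__ = [
    "AlignedSet",
    "WindowDiversity",
    "Hotspot",
    "read_alignment",
    "window_pi",
    "call_hotspots",
    "per_region_pi",
]

_ALPHABET = frozenset("ACGTN-")


@dataclass
class AlignedSet:
    """A gap-aware multiple alignment of n >= 2 equal-length sequences."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        if len(self.labels) != len(self.rows):
            raise ValueError("labels/rows length mismatch")
        self.rows = [r.upper() for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        bad = set().union(*(set(r) for r in self.rows)) - _ALPHABET
        if bad:
            raise ValueError(f"unsupported alignment characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n(self) -> int:
        return len(self.rows)

    def _matrix(self) -> np.ndarray:
        return np.frombuffer(
            "".join(self.rows).encode(), dtype="S1"
        ).reshape(self.n, self.length)


@dataclass(frozen=True)
class WindowDiversity:
    start: int  # 0-based half-open columns
    end: int
    valid_sites: int
    pi: float | None  # None when no valid sites


@dataclass(frozen=True)
class Hotspot:
    start: int
    end: int
    peak_pi: float
    peak_start: int
    peak_end: int
    label: str = ""


def read_alignment(path: str | Path) -> AlignedSet:
    """Read an aligned FASTA file (equal-length rows) into an AlignedSet."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return AlignedSet(
        labels=[r.id for r in records], rows=[str(r.seq) for r in records]
    )


def _column_stats(aln: AlignedSet) -> tuple[np.ndarray, np.ndarray]:
    """(valid, diff_count) per column: validity mask and pairwise-diff sums."""
    m = aln._matrix()
    valid = np.ones(aln.length, dtype=bool)
    for b in (b"-", b"N"):
        valid &= ~(m == b).any(axis=0)
    n = aln.n
    diff = np.zeros(aln.length, dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            diff += m[i] != m[j]
    return valid, diff


def _pi_over(valid: np.ndarray, diff: np.ndarray, n: int) -> tuple[int, float | None]:
    v = int(valid.sum())
    if v == 0:
        return 0, None
    npairs = n * (n - 1) // 2
    return v, float(diff[valid].sum()) / (npairs * v)


def window_pi(
    aln: AlignedSet,
    window: int = 400,
    step: int = 200,
    min_terminal_sites: int = 50,
) -> list[WindowDiversity]:
    """Sliding-window π across the alignment.

    The terminal partial window is kept only when it retains at least
    ``min_terminal_sites`` valid sites.  A window longer than the alignment
    degrades, with a warning, to a single whole-alignment window.
    """
    if not 1 <= step <= window:
        raise ValueError("require window >= step >= 1")
    if window > aln.length:
        warnings.warn(
            f"window ({window}) exceeds alignment length ({aln.length}); "
            "computing a single whole-alignment window"
        )
        window = step = aln.length
    valid, diff = _column_stats(aln)
    out: list[WindowDiversity] = []
    start = 0
    while start < aln.length:
        end = min(start + window, aln.length)
        v, pi = _pi_over(valid[start:end], diff[start:end], aln.n)
        if end - start < window:  # terminal partial window
            if v >= min_terminal_sites:
                out.append(WindowDiversity(start, end, v, pi))
            break
        out.append(WindowDiversity(start, end, v, pi))
        if end == aln.length:
            break
        start += step
    return out


def _label_for(
    peak: WindowDiversity, annotation: Sequence[GeneFeature]
) -> str:
    overlapping = [
        f.gene_name
        for f in annotation
        if f.span[0] < peak.end and f.span[1] > peak.start
    ]
    if overlapping:
        return "-".join(dict.fromkeys(overlapping))
    left = [f for f in annotation if f.span[1] <= peak.start]
    right = [f for f in annotation if f.span[0] >= peak.end]
    lname = max(left, key=lambda f: f.span[1]).gene_name if left else ""
    rname = min(right, key=lambda f: f.span[0]).gene_name if right else ""
    if lname and rname:
        return f"{lname}-{rname}"
    return lname or rname


def call_hotspots(
    windows: Sequence[WindowDiversity],
    threshold: float = 0.10,
    annotation: Sequence[GeneFeature] | None = None,
) -> list[Hotspot]:
    """Merge runs of overlapping windows with π above ``threshold``.

    Each merged region carries its peak window's π; with annotation, the
    region is labelled by the gene(s) overlapping the peak window, or by
    its flanking genes as an intergenic-spacer name ("trnH-psbA" style).
    """
    hot = [w for w in windows if w.pi is not None and w.pi > threshold]
    if not hot:
        return []
    hot.sort(key=lambda w: w.start)
    groups: list[list[WindowDiversity]] = [[hot[0]]]
    for w in hot[1:]:
        if w.start < groups[-1][-1].end:
            groups[-1].append(w)
        else:
            groups.append([w])
    out = []
    for g in groups:
        peak = max(g, key=lambda w: w.pi)
        label = _label_for(peak, annotation) if annotation else ""
        out.append(
            Hotspot(
                start=g[0].start,
                end=max(w.end for w in g),
                peak_pi=peak.pi,
                peak_start=peak.start,
                peak_end=peak.end,
                label=label,
            )
        )
    return out


def per_region_pi(
    aln: AlignedSet, partition: QuadripartitePartition
) -> tuple[float | None, float | None, float | None]:
    """(π_LSC, π_IR, π_SSC) with the partition projected onto columns.

    The alignment must be in genome coordinates (the indel-free synthetic
    alignments are; for real aligned data, project the partition through
    the alignment first).  IR pools IRb and IRa columns.
    """
    valid, diff = _column_stats(aln)
    L = aln.length

    def region(cols: list[int]) -> float | None:
        if not cols:
            return None
        idx = np.array(cols)
        _, pi = _pi_over(valid[idx], diff[idx], aln.n)
        return pi

    pi_lsc = region(partition.lsc.columns(L))
    pi_ir = region(partition.irb.columns(L) + partition.ira.columns(L))
    pi_ssc = region(partition.ssc.columns(L))
    return pi_lsc, pi_ir, pi_ssc
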