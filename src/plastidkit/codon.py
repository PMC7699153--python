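"""Codon-usage statistics: counts, RSCU, positional GC, ENc and CAI.

All statistics operate on a :class:`CodonCountTable`, so per-gene and
per-genome (pooled) values come from the same code path.  Conventions:

* RSCU within a synonymous family of size k: ``RSCU_j = x_j * k / sum(x)``;
  a uniform family has RSCU 1 everywhere.
* ENc is Wright's effective number of codons, estimated from per-family
  codon homozygosity and clamped to [20, 61].
* Synonymous third-position contents (A3s/T3s/C3s/G3s, GC3s) are computed
  over codons of amino acids with at least two synonymous codons —
  everything except Met, Trp and stops.
* CAI follows Sharp & Li: relative-adaptiveness weights from a reference
  gene set, geometric mean over a gene's scorable codons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from ._genetics import (
    AA_OF,
    ALL_CODONS,
    DEGENERACY_CLASSES,
    FAMILIES,
    SENSE_CODONS,
    STOP_CODONS,
    SYNONYMOUS_CODONS,
)
from .genome import CodingSequence

__all__ = [
    "CodonCountTable",
    "RSCUTable",
    "CAIWeights",
    "CodonUsageSummary",
    "count_codons",
    "compute_rscu",
    "gc_by_position",
    "synonymous_third_position",
    "compute_enc",
    "enc_expected",
    "build_cai_weights",
    "compute_cai",
    "summarize_usage",
]

ENC_MIN, ENC_MAX = 20.0, 61.0


@dataclass(frozen=True)
class CodonCountTable:
    """Counts over the 64 DNA triplets."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = set(ALL_CODONS) - set(self.counts)
        extra = set(self.counts) - set(ALL_CODONS)
        if missing or extra:
            raise ValueError(f"count table keys must be the 64 codons "
                             f"(missing {len(missing)}, extra {sorted(extra)[:3]})")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative codon count")

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        return CodonCountTable(
            {c: self.counts[c] + other.counts[c] for c in ALL_CODONS}
        )


@dataclass(frozen=True)
class RSCUTable:
    rscu: Mapping[str, float]
    include_stops: bool
    empty_families: tuple[str, ...] = ()  # families with zero occurrences


@dataclass(frozen=True)
class CAIWeights:
    """Relative adaptiveness w in (0, 1] per codon; max-w codon per family is 1."""

    w: Mapping[str, float]
    reference: str = ""


@dataclass(frozen=True)
class CodonUsageSummary:
    """One species/gene row of codon-usage indices (Table-2 style)."""

    label: str
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3s: float | None
    a3s: float | None
    t3s: float | None
    c3s: float | None
    g3s: float | None
    cai: float | None
    enc: float | None
    n_codons: int = 0


def count_codons(
    cds_list: Iterable[CodingSequence], include_terminal_stops: bool = True
) -> CodonCountTable:
    """Aggregate codon counts over a set of validated coding sequences."""
    cds_list = list(cds_list)
    if not cds_list:
        raise ValueError("count_codons: empty CDS list")
    counts = {c: 0 for c in ALL_CODONS}
    for cds in cds_list:
        cods = cds.codons if include_terminal_stops else cds.sense_codons
        for c in cods:
            if c in counts:  # codons containing N are skipped
                counts[c] += 1
    return CodonCountTable(counts)


def _families(include_stops: bool) -> dict[str, tuple[str, ...]]:
    fams = dict(FAMILIES)
    if include_stops:
        fams["*"] = tuple(sorted(STOP_CODONS))
    return fams


def compute_rscu(table: CodonCountTable, include_stops: bool = True) -> RSCUTable:
    """Relative synonymous codon usage per codon.

    Stop codons form a 3-codon family by default (so e.g. TGA receives an
    RSCU like any synonymous codon); single-codon families (Met, Trp) have
    RSCU fixed at 1 when used, 0 when absent.
    """
    if table.n_codons == 0:
        raise ValueError("compute_rscu: empty count table")
    rscu: dict[str, float] = {}
    empty: list[str] = []
    for aa, codons in _families(include_stops).items():
        total = sum(table.counts[c] for c in codons)
        if total == 0:
            empty.append(aa)
            for c in codons:
                rscu[c] = 0.0
        else:
            k = len(codons)
            for c in codons:
                rscu[c] = table.counts[c] * k / total
    if not include_stops:
        for c in STOP_CODONS:
            rscu.setdefault(c, 0.0)
    return RSCUTable(rscu=rscu, include_stops=include_stops,
                     empty_families=tuple(empty))


def gc_by_position(
    table: CodonCountTable,
) -> tuple[float, float, float, float, float]:
    """(gc1, gc2, gc3, gc12, gc): GC fraction at each codon position.

    ``gc`` is the mean over the three positions, ``gc12`` the mean of the
    first two (the neutrality-plot ordinate).
    """
    n = table.n_codons
    if n == 0:
        raise ValueError("gc_by_position: empty count table")
    gc_pos = [0, 0, 0]
    for codon, x in table.counts.items():
        for p in range(3):
            if codon[p] in "GC":
                gc_pos[p] += x
    gc1, gc2, gc3 = (g / n for g in gc_pos)
    return gc1, gc2, gc3, (gc1 + gc2) / 2, (gc1 + gc2 + gc3) / 3


def synonymous_third_position(
    table: CodonCountTable,
) -> tuple[float, float, float, float, float] | None:
    """(a3s, t3s, c3s, g3s, gc3s) over synonymously-variable codons.

    Returns ``None`` when the table contains only Met/Trp/stop codons.
    """
    totals = {b: 0 for b in "ACGT"}
    n = 0
    for codon in SYNONYMOUS_CODONS:
        x = table.counts[codon]
        totals[codon[2]] += x
        n += x
    if n == 0:
        return None
    a3s, t3s, c3s, g3s = (totals[b] / n for b in "ATCG")
    return a3s, t3s, c3s, g3s, c3s + g3s


class EncUndefinedError(ValueError):
    """Raised when a degeneracy class has no estimable homozygosity."""


def _family_homozygosity(table: CodonCountTable, codons: tuple[str, ...]) -> float | None:
    """Wright's F̂ = (n·Σp̂² − 1)/(n − 1) for one synonymous family."""
    xs = [table.counts[c] for c in codons]
    n = sum(xs)
    if n < 2:
        return None
    s = sum((x / n) ** 2 for x in xs)
    return (n * s - 1) / (n - 1)


def compute_enc(table: CodonCountTable, clamp: bool = True) -> float:
    """Wright's effective number of codons.

    ENc = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6, with F̄k the mean estimated
    homozygosity of the synonymous families with degeneracy k.  Families
    with fewer than 2 codons observed, or with F̂ = 0, are dropped from
    their class mean; a missing 3-fold class (Ile) is imputed as
    (F̄2 + F̄4)/2.  The result is clamped to [20, 61].
    """
    if table.n_codons == 0:
        raise ValueError("compute_enc: empty count table")
    class_means: dict[int, float] = {}
    for k, aas in DEGENERACY_CLASSES.items():
        if k == 1:
            continue
        fs = []
        for aa in aas:
            f = _family_homozygosity(table, FAMILIES[aa])
            if f is not None and f > 0:
                fs.append(f)
        if fs:
            class_means[k] = sum(fs) / len(fs)
    if 3 not in class_means and 2 in class_means and 4 in class_means:
        class_means[3] = (class_means[2] + class_means[4]) / 2
    weights = {2: 9.0, 3: 1.0, 4: 5.0, 6: 3.0}
    for k in weights:
        if k not in class_means:
            raise EncUndefinedError(
                f"ENc undefined: no estimable {k}-fold family homozygosity"
            )
    enc = 2.0 + sum(w / class_means[k] for k, w in weights.items())
    if clamp:
        enc = min(ENC_MAX, max(ENC_MIN, enc))
    return enc


def enc_expected(gc3s: float) -> float:
    """Wright's expected ENc under mutation–drift alone at a given GC3s.

    ENc* = 2 + s + 29 / (s² + (1 − s)²) with s = GC3s.
    """
    s = gc3s
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"gc3s must be in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


_CAI_EXCLUDED = frozenset({"ATG", "TGG"}) | STOP_CODONS


def build_cai_weights(
    reference: Iterable[CodingSequence],
    zero_count_floor: float = 0.01,
    description: str = "",
) -> CAIWeights:
    """Sharp & Li relative-adaptiveness weights from a reference gene set.

    ``w_j = x_j / max_family(x)`` on the pooled reference counts (identical
    to RSCU/RSCUmax).  Codons unseen in the reference receive a small floor
    weight rather than 0 so gene CAI never collapses to zero on a single
    rare codon; families entirely absent from the reference get w = 1 with
    a warning.
    """
    refs = list(reference)
    if not refs:
        raise ValueError("build_cai_weights: empty reference set")
    table = count_codons(refs, include_terminal_stops=False)
    w: dict[str, float] = {}
    for aa, codons in FAMILIES.items():
        if len(codons) < 2 or aa in ("M", "W"):
            continue
        xmax = max(table.counts[c] for c in codons)
        if xmax == 0:
            warnings.warn(f"CAI reference has no codons for {aa}; weights set to 1")
            for c in codons:
                w[c] = 1.0
            continue
        for c in codons:
            x = table.counts[c]
            w[c] = x / xmax if x > 0 else zero_count_floor
    for c in _CAI_EXCLUDED:
        w[c] = 1.0  # never scored, kept for completeness
    return CAIWeights(w=w, reference=description or f"{len(refs)} reference genes")


def compute_cai(gene: CodingSequence, weights: CAIWeights) -> float | None:
    """Codon adaptation index: geometric mean of w over scorable codons.

    Met, Trp and stop codons are excluded.  ``None`` when nothing scorable.
    """
    log_sum = 0.0
    n = 0
    for c in gene.codons:
        if c in _CAI_EXCLUDED or c not in weights.w:
            continue
        log_sum += math.log(weights.w[c])
        n += 1
    if n == 0:
        return None
    return math.exp(log_sum / n)


def summarize_usage(
    cds_list: Iterable[CodingSequence],
    weights: CAIWeights | None = None,
    label: str = "",
    include_terminal_stops: bool = True,
) -> CodonUsageSummary:
    """One pooled codon-usage row over a gene set (the per-species summary).

    Codons are pooled across genes (CodonW "concatenated" style).  When no
    CAI reference is supplied, the photosynthesis genes of the input
    (psa/psb/rbcL sets, a proxy for highly expressed plastid genes) are
    used; if none are present the whole input is the reference.
    """
    cds_list = list(cds_list)
    if not cds_list:
        raise ValueError("summarize_usage: empty CDS list")
    table = count_codons(cds_list, include_terminal_stops=include_terminal_stops)
    gc1, gc2, gc3, gc12, gc = gc_by_position(table)
    syn = synonymous_third_position(table)
    a3s = t3s = c3s = g3s = gc3s = None
    if syn is not None:
        a3s, t3s, c3s, g3s, gc3s = syn
    try:
        enc = compute_enc(table)
    except EncUndefinedError:
        enc = None
    if weights is None:
        from .rates import assign_gene_sets  # local import: avoid cycle at load

        sets = assign_gene_sets([c.gene_name for c in cds_list])
        photo = [c for c in cds_list if sets[c.gene_name] in ("psa", "psb", "rbcL")]
        weights = build_cai_weights(
            photo or cds_list,
            description="photosynthesis genes" if photo else "all input genes",
        )
    pooled_nt = "".join(c for cds in cds_list for c in cds.sense_codons)
    cai = None
    if len(pooled_nt) >= 3:
        pooled = CodingSequence(gene_name=label or "pooled", nt=pooled_nt)
        cai = compute_cai(pooled, weights)
    return CodonUsageSummary(
        label=label, gc=gc, gc1=gc1, gc2=gc2, gc3=gc3, gc12=gc12,
        gc3s=gc3s, a3s=a3s, t3s=t3s, c3s=c3s, g3s=g3s,
        cai=cai, enc=enc, n_codons=table.n_codons,
    )
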