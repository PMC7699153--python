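"""Annotated plastome I/O, CDS extraction, and quadripartite structure.

A chloroplast genome is a circular molecule of ~120–170 kb with a
characteristic four-part layout: a large single-copy region (LSC), one arm
of an inverted repeat (IRb), a small single-copy region (SSC), and the
second, reverse-complementary arm (IRa).  This module reads annotated
plastomes from GenBank flat files, extracts and validates spliced coding
sequences under translation table 11, detects the IR pair from sequence
alone, and reports genes overlapping the four region junctions.

Coordinates are 0-based half-open internally; GenBank's 1-based inclusive
convention applies only at the file boundary (handled by Biopython).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ._genetics import codons_of, revcomp, translate

__all__ = [
    "GenomeFormatError",
    "CdsValidationError",
    "Interval",
    "GeneFeature",
    "QuadripartitePartition",
    "CodingSequence",
    "GenomeRecord",
    "JunctionGene",
    "RegionGC",
    "read_genbank",
    "write_genbank",
    "extract_cds",
    "detect_inverted_repeats",
    "junction_report",
    "region_gc",
    "unique_cds_features",
]

_VALID_BASES = frozenset("ACGTN")


class GenomeFormatError(ValueError):
    """Raised for malformed input files or inconsistent coordinates."""


class CdsValidationError(ValueError):
    """Raised when a coding sequence fails frame or stop-codon validation."""


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on the linearized circle.

    ``start > end`` denotes an interval wrapping the origin; its span is
    ``[start, L) + [0, end)``.
    """

    start: int
    end: int

    def length(self, genome_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start
        return genome_length - self.start + self.end

    def extract(self, seq: str) -> str:
        if self.start <= self.end:
            return seq[self.start : self.end]
        return seq[self.start :] + seq[: self.end]

    def columns(self, genome_length: int) -> list[int]:
        if self.start <= self.end:
            return list(range(self.start, self.end))
        return list(range(self.start, genome_length)) + list(range(self.end))

    def contains(self, pos: int, genome_length: int) -> bool:
        if self.start <= self.end:
            return self.start <= pos < self.end
        return pos >= self.start or pos < self.end


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene: exon structure, strand and reading-frame offset."""

    gene_name: str
    kind: str  # CDS | tRNA | rRNA
    exons: tuple[tuple[int, int], ...]  # transcription order, 0-based half-open
    strand: str  # "+" | "-"
    codon_start_offset: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("CDS", "tRNA", "rRNA"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_name}: empty exon list")
        for s, e in self.exons:
            if not s < e:
                raise ValueError(f"{self.gene_name}: bad exon ({s}, {e})")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_name}: strand must be '+' or '-'")
        if self.codon_start_offset not in (0, 1, 2):
            raise ValueError(f"{self.gene_name}: codon_start_offset must be 0/1/2")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint (min start, max end) over all exons."""
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)


@dataclass(frozen=True)
class QuadripartitePartition:
    """The LSC / IRb / SSC / IRa tiling of a plastome."""

    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval

    def region_of(self, pos: int, genome_length: int) -> str:
        for name in ("lsc", "irb", "ssc", "ira"):
            if getattr(self, name).contains(pos, genome_length):
                return name
        raise ValueError(f"position {pos} not covered by partition")


@dataclass(frozen=True)
class CodingSequence:
    """A spliced, strand-resolved, in-frame CDS.

    ``nt`` is the mRNA-sense DNA string; a terminal stop codon is retained
    and flagged.  Internal stops are rejected at construction.
    """

    gene_name: str
    nt: str
    gene_set: str = "unassigned"
    has_terminal_stop: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.nt) < 3 or len(self.nt) % 3:
            raise CdsValidationError(
                f"{self.gene_name}: CDS length {len(self.nt)} not a positive "
                "multiple of 3"
            )
        aa = translate(self.nt)
        internal = aa[:-1]
        if "*" in internal:
            raise CdsValidationError(
                f"{self.gene_name}: internal stop codon at codon index "
                f"{internal.index('*')}"
            )
        object.__setattr__(self, "has_terminal_stop", aa.endswith("*"))

    @property
    def codons(self) -> list[str]:
        return codons_of(self.nt)

    @property
    def sense_codons(self) -> list[str]:
        """Codons with the terminal stop (if any) removed."""
        cods = self.codons
        if self.has_terminal_stop:
            return cods[:-1]
        return cods


@dataclass
class GenomeRecord:
    """One annotated plastome."""

    id: str
    seq: str
    features: list[GeneFeature] = field(default_factory=list)
    partition: QuadripartitePartition | None = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise GenomeFormatError(f"{self.id}: empty sequence")
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise GenomeFormatError(
                f"{self.id}: ambiguity codes other than N are not supported: "
                f"{sorted(bad)}"
            )
        for f in self.features:
            for s, e in f.exons:
                if not (0 <= s < e <= len(self.seq)):
                    raise GenomeFormatError(
                        f"{self.id}/{f.gene_name}: exon ({s}, {e}) outside "
                        f"[0, {len(self.seq)})"
                    )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class JunctionGene:
    """One gene at (or near) a region junction."""

    junction: str  # e.g. "LSC/IRb"
    gene_name: str
    bases_in_ir: int  # overlap length on the IR side; 0 if no overlap
    distance: int  # 0 when overlapping, else distance to the junction (bp)


@dataclass(frozen=True)
class RegionGC:
    total: float
    lsc: float | None = None
    ir: float | None = None
    ssc: float | None = None


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------

_KINDS = ("CDS", "tRNA", "rRNA")


def read_genbank(path) -> GenomeRecord:
    """Read a single-record GenBank flat file into a :class:`GenomeRecord`.

    Captures CDS/tRNA/rRNA features with exon structure (``join`` parts in
    transcription order), strand, and ``codon_start``.  Features crossing
    the origin of a circular record appear as two exons.
    """
    try:
        record = SeqIO.read(path, "genbank")
    except ValueError as exc:
        raise GenomeFormatError(f"{path}: {exc}") from exc
    seq = str(record.seq).upper()
    if not seq or set(seq) == {"N"}:
        raise GenomeFormatError(f"{path}: record has no ORIGIN sequence")
    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in _KINDS:
            continue
        name = (
            feat.qualifiers.get("gene", [None])[0]
            or feat.qualifiers.get("locus_tag", [None])[0]
            or feat.type
        )
        strand = "-" if feat.location.strand == -1 else "+"
        exons = []
        for part in feat.location.parts:
            s, e = int(part.start), int(part.end)
            if not (0 <= s < e <= len(seq)):
                raise GenomeFormatError(
                    f"{path}/{name}: feature coordinates ({s}, {e}) exceed "
                    f"sequence length {len(seq)} without a circular join"
                )
            exons.append((s, e))
        offset = int(feat.qualifiers.get("codon_start", ["1"])[0]) - 1
        features.append(
            GeneFeature(
                gene_name=name,
                kind=feat.type,
                exons=tuple(exons),
                strand=strand,
                codon_start_offset=offset if feat.type == "CDS" else 0,
            )
        )
    return GenomeRecord(id=record.id or record.name, seq=seq, features=features)


def write_genbank(genome: GenomeRecord, path) -> None:
    """Write a :class:`GenomeRecord` as a circular GenBank flat file."""
    record = SeqRecord(
        Seq(genome.seq),
        id=genome.id,
        name=genome.id[:16].replace(" ", "_"),
        description="synthetic plastome",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        parts = [SimpleLocation(s, e, strand=strand) for s, e in f.exons]
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        qualifiers = {"gene": [f.gene_name]}
        if f.kind == "CDS":
            qualifiers["codon_start"] = [str(f.codon_start_offset + 1)]
        record.features.append(SeqFeature(loc, type=f.kind, qualifiers=qualifiers))
    SeqIO.write(record, path, "genbank")


# ---------------------------------------------------------------------------
# CDS extraction
# ---------------------------------------------------------------------------


def extract_cds(
    genome: GenomeRecord, feature: GeneFeature, gene_set: str = "unassigned"
) -> CodingSequence:
    """Splice, strand-resolve and frame-trim one CDS feature.

    Exons are concatenated in the order annotated; minus-strand genes are
    reverse-complemented; the first ``codon_start_offset`` bases are dropped.
    """
    if feature.kind != "CDS":
        raise ValueError(f"{feature.gene_name}: not a CDS feature")
    nt = "".join(genome.seq[s:e] for s, e in feature.exons)
    if feature.strand == "-":
        nt = revcomp(nt)
    nt = nt[feature.codon_start_offset :]
    if len(nt) % 3:
        raise CdsValidationError(
            f"{feature.gene_name}: spliced length {len(nt)} not divisible by 3 "
            "after codon_start trimming"
        )
    return CodingSequence(gene_name=feature.gene_name, nt=nt, gene_set=gene_set)


def unique_cds_features(genome: GenomeRecord) -> list[GeneFeature]:
    """CDS features deduplicated by (gene name, extracted sequence).

    Genes annotated twice because they sit inside both IR arms collapse to a
    single representative, matching how plastome gene counts are reported.
    """
    seen: set[tuple[str, str]] = set()
    out = []
    for f in genome.features:
        if f.kind != "CDS":
            continue
        nt = "".join(genome.seq[s:e] for s, e in f.exons)
        if f.strand == "-":
            nt = revcomp(nt)
        key = (f.gene_name, nt)
        if key in seen:
            continue
        seen.add(key)
        out.append(f)
    return out


# ---------------------------------------------------------------------------
# Inverted-repeat detection
# ---------------------------------------------------------------------------


def _maximal_extension(
    seq: str, a0: int, a1: int, b0: int, b1: int
) -> tuple[int, int, int, int]:
    """Extend an exact reverse-complement match [a0,a1) ~ rc([b0,b1))."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "?"}
    # left of A pairs with right of B
    while a0 > 0 and b1 < len(seq) and comp[seq[a0 - 1]] == seq[b1]:
        a0 -= 1
        b1 += 1
    # right of A pairs with left of B
    while a1 < b0 and comp[seq[a1]] == seq[b0 - 1]:
        a1 += 1
        b0 -= 1
    return a0, a1, b0, b1


def detect_inverted_repeats(
    genome: GenomeRecord, min_len: int = 10_000
) -> QuadripartitePartition | None:
    """Locate the plastome IR pair and derive the quadripartite partition.

    Finds the longest pair of disjoint, exactly reverse-complementary
    repeats of length >= ``min_len`` (k-mer seeded, maximally extended by
    direct comparison).  The two gaps between the arms become LSC (larger)
    and SSC (smaller).  Returns ``None`` when no such repeat exists — the
    genome is still usable, just without regional statistics.

    Real plastome IR arms are effectively identical, so exact matching is
    appropriate; near-identical repeats with internal mismatches yield the
    longer exactly-matching arm.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = genome.seq
    L = len(seq)
    if L < 2 * min_len:
        return None
    k = min(min_len, 1000)
    index: dict[str, list[int]] = {}
    for i in range(0, L - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    rc = revcomp(seq)
    best: tuple[int, int, int, int] | None = None
    covered: list[tuple[int, int, int, int]] = []
    step = max(1, (min_len - k) // 2 + 1)
    positions = list(range(0, L - k + 1, step)) + [L - k]
    for j in positions:
        kmer = rc[j : j + k]
        hits = index.get(kmer)
        if not hits:
            continue
        # rc[j:j+k] corresponds to forward interval [L-j-k, L-j)
        b0f, b1f = L - j - k, L - j
        for p in hits:
            a0, a1, b0, b1 = (p, p + k, b0f, b1f)
            if a0 > b0:
                a0, a1, b0, b1 = b0, b1, a0, a1
            if a1 > b0:  # overlapping (palindromic) match: not an IR pair
                continue
            if any(c[0] <= a0 and a1 <= c[1] and c[2] <= b0 and b1 <= c[3]
                   for c in covered):
                continue
            a0, a1, b0, b1 = _maximal_extension(seq, a0, a1, b0, b1)
            covered.append((a0, a1, b0, b1))
            if a1 - a0 >= min_len and (best is None or a1 - a0 > best[1] - best[0]):
                best = (a0, a1, b0, b1)
    if best is None:
        return None
    a0, a1, b0, b1 = best
    arm1 = Interval(a0, a1)
    arm2 = Interval(b0, b1)
    between = Interval(a1, b0)
    around = Interval(b1 % L, a0)  # wraps the origin unless b1 == L and a0 == 0
    len_between = between.length(L)
    len_around = around.length(L)
    if len_between >= len_around:
        lsc, ssc = between, around
        irb, ira = arm2, arm1
    else:
        lsc, ssc = around, between
        irb, ira = arm1, arm2
    return QuadripartitePartition(lsc=lsc, irb=irb, ssc=ssc, ira=ira)


# ---------------------------------------------------------------------------
# Junction report and regional GC
# ---------------------------------------------------------------------------


def _overlap(span: tuple[int, int], iv: Interval, L: int) -> int:
    s, e = span
    cols = 0
    if iv.start <= iv.end:
        cols = max(0, min(e, iv.end) - max(s, iv.start))
    else:
        cols = max(0, min(e, L) - max(s, iv.start)) + max(0, min(e, iv.end) - s)
    return cols


def junction_report(
    genome: GenomeRecord, near: int = 100
) -> list[JunctionGene]:
    """Report genes overlapping (or within ``near`` bp of) the 4 junctions.

    For an overlapping gene the reported number is the exact count of its
    bases lying on the IR side of the junction; a nearby non-overlapping
    gene is reported with its distance to the junction instead.
    """
    part = genome.partition
    if part is None:
        raise ValueError(f"{genome.id}: no quadripartite partition")
    L = genome.length
    junctions = [
        ("LSC/IRb", part.irb.start, part.irb),
        ("IRb/SSC", part.irb.end % L, part.irb),
        ("SSC/IRa", part.ira.start, part.ira),
        ("IRa/LSC", part.ira.end % L, part.ira),
    ]
    report: list[JunctionGene] = []
    for label, pos, ir_iv in junctions:
        for f in genome.features:
            s, e = f.span
            if s < pos < e:
                report.append(
                    JunctionGene(label, f.gene_name, _overlap((s, e), ir_iv, L), 0)
                )
            else:
                d = min(abs(s - pos), abs(e - pos), abs(s - pos + L) % L,
                        abs(e - pos + L) % L)
                if 0 < d <= near:
                    report.append(JunctionGene(label, f.gene_name, 0, d))
    return report


def _gc_fraction(seq: str) -> float | None:
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return None
    return (counts["G"] + counts["C"]) / denom


def region_gc(genome: GenomeRecord) -> RegionGC:
    """GC fraction overall and per region (IR computed over IRb ∪ IRa)."""
    total = _gc_fraction(genome.seq)
    if total is None:
        raise GenomeFormatError(f"{genome.id}: sequence contains no A/C/G/T")
    part = genome.partition
    if part is None:
        return RegionGC(total=total)
    return RegionGC(
        total=total,
        lsc=_gc_fraction(part.lsc.extract(genome.seq)),
        ir=_gc_fraction(
            part.irb.extract(genome.seq) + part.ira.extract(genome.seq)
        ),
        ssc=_gc_fraction(part.ssc.extract(genome.seq)),
    )
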