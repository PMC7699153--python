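"""Synthetic plastome generator for testing and demonstration.

Emulates the salient features of a real comparative plastome study without
any external data: ~160 kb circular genomes with an LSC + IRb + SSC + IRa
layout, AT-rich protein-coding genes (GC3s ≈ 0.29 by default), IR regions
both more GC-rich and more conserved than the single-copy regions,
divergence between species concentrated in intergenic hotspot windows, and
coding sequences evolved under controlled per-gene-set dN/dS (ω).

Simplifications, chosen deliberately so every downstream statistic has an
exact oracle: no indels (alignments are column-true by construction), a
star tree rather than a resolved topology, and concerted IR evolution (the
two arms stay exactly reverse-complementary, as real plastome IRs
effectively do).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from ._genetics import AA_OF, FAMILIES, STOP_CODONS, revcomp
from .diversity import AlignedSet
from .genome import (
    CodingSequence,
    GeneFeature,
    GenomeRecord,
    Interval,
    QuadripartitePartition,
    write_genbank,
)

__all__ = [
    "SyntheticSpec",
    "gen_biased_cds",
    "gen_genome",
    "evolve_alignment",
    "evolve_cds_pair",
    "gen_species_set",
    "write_fixture_set",
]

# ordered so the first 14 names cover one gene per functional set
_GENE_CATALOG = (
    "accD atpA ccsA cemA clpP matK ndhA petA psaA psbA rbcL rpoA rpl2 rps2 "
    "psbB psbC psbD psbE psbF psbH psbI psbJ psbK psbL psbM psbN psbT psbZ "
    "psaB psaC psaI psaJ atpB atpE atpF atpH atpI ndhB ndhC ndhD ndhE ndhG "
    "ndhH ndhI ndhJ ndhK petB petD petG petL petN rpoB rpoC1 rpoC2 rpl14 "
    "rpl16 rpl20 rpl23 rpl32 rpl33 rpl36 rps3 rps4 rps7 rps8 rps11 rps12 "
    "rps14 rps15 rps18 rps19 ycf2 ycf3 ycf4 ndhF"
).split()


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults mirror the observed scale of a five-species plastome
    comparison: ~160 kb genomes, ~80 genes, GC3s ≈ 0.29, IR mutation rate
    one fifth of the single-copy rate, seven elevated-rate intergenic
    hotspots, and per-set ω spanning strong purifying selection (psb ≈
    0.06) to relaxed/near-neutral (clpP ≈ 1.06).
    """

    seed: int = 0
    n_genes: int = 74
    codons_per_gene: int = 240
    gc3s_target: float = 0.29
    bias_strength: float = 0.0
    region_lengths: tuple[int, int, int] = (87_000, 26_500, 18_300)  # lsc, ir, ssc
    region_gc: tuple[float, float, float] = (0.34, 0.43, 0.31)  # intergenic bg
    mutation_rates: tuple[float, float, float] = (0.02, 0.004, 0.02)
    hotspots: tuple[tuple[int, int, float], ...] | None = None  # (start, end, rate)
    n_hotspots: int = 7
    hotspot_rate: float = 0.08
    hotspot_width: int = 600
    omega_by_set: tuple[tuple[str, float], ...] = (
        ("accD", 0.45), ("atp", 0.09), ("ccsA", 0.35), ("cemA", 0.30),
        ("clpP", 1.06), ("matK", 0.50), ("ndh", 0.30), ("pet", 0.08),
        ("psa", 0.10), ("psb", 0.06), ("rbcL", 0.20), ("rpo", 0.25),
        ("rpl", 0.30), ("rps", 0.30),
    )
    divergence_t: float = 0.10
    irb_overlap: int = 60    # bases of the LSC/IRb junction gene inside IRb
    ira_overlap: int = 1300  # bases of the SSC/IRa junction gene inside IRa

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.region_lengths):
            raise ValueError("region lengths must be positive")
        probs = list(self.mutation_rates) + [self.hotspot_rate]
        if self.hotspots:
            probs += [h[2] for h in self.hotspots]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("mutation rates must be probabilities")
        if not 0.0 <= self.gc3s_target <= 1.0:
            raise ValueError("gc3s_target must be in [0, 1]")
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be >= 0")


# ---------------------------------------------------------------------------
# Biased coding sequences
# ---------------------------------------------------------------------------


def _codon_probs(gc3s_target: float, bias_strength: float) -> dict[str, np.ndarray]:
    """Per-amino-acid codon sampling probabilities.

    Within each synonymous family, G/C-ending codons share probability mass
    ``gc3s_target`` and A/T-ending codons share ``1 - gc3s_target``, so the
    pooled GC3s expectation equals the target.  ``bias_strength`` then
    multiplies the first A/T-ending codon's weight by exp(bias), skewing
    usage toward a single codon (ENc → 20 as bias → ∞).
    """
    out: dict[str, np.ndarray] = {}
    for aa, codons in FAMILIES.items():
        gc_enders = [c for c in codons if c[2] in "GC"]
        at_enders = [c for c in codons if c[2] in "AT"]
        p = {}
        if gc_enders and at_enders:
            for c in gc_enders:
                p[c] = gc3s_target / len(gc_enders)
            for c in at_enders:
                p[c] = (1.0 - gc3s_target) / len(at_enders)
        else:
            for c in codons:
                p[c] = 1.0 / len(codons)
        if bias_strength > 0 and len(codons) > 1:
            preferred = (at_enders or list(codons))[0]
            p[preferred] *= float(np.exp(bias_strength))
        v = np.array([p[c] for c in codons])
        out[aa] = v / v.sum()
    return out


def gen_biased_cds(
    spec: SyntheticSpec,
    names: list[str] | None = None,
    codon_counts: list[int] | None = None,
) -> list[CodingSequence]:
    """Generate validated CDSs with codon usage tuned to ``spec``.

    Each gene starts with ATG, ends with a TAA stop, and draws amino acids
    uniformly with codons sampled from the family distributions described
    in :func:`_codon_probs`.  Deterministic under ``spec.seed``.
    """
    if names is None:
        names = _GENE_CATALOG[: spec.n_genes]
    if codon_counts is None:
        codon_counts = [spec.codons_per_gene] * len(names)
    if spec.gc3s_target in (0.0, 1.0) and spec.bias_strength == 0:
        # reachable, but warn that single-base-class targets interact with
        # families lacking that ending
        pass
    rng = np.random.default_rng(spec.seed)
    probs = _codon_probs(spec.gc3s_target, spec.bias_strength)
    aas = sorted(FAMILIES)
    out = []
    for name, n_codons in zip(names, codon_counts):
        if n_codons < 2:
            raise ValueError(f"{name}: need at least 2 codons")
        picks = rng.choice(len(aas), size=n_codons - 1)
        codons = ["ATG"]
        for k in np.asarray(picks):
            aa = aas[int(k)]
            fam = FAMILIES[aa]
            codons.append(fam[int(rng.choice(len(fam), p=probs[aa]))])
        codons.append("TAA")
        out.append(CodingSequence(gene_name=name, nt="".join(codons)))
    return out


# ---------------------------------------------------------------------------
# Whole-genome construction
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return np.frombuffer(b"ACGT", dtype="S1")[rng.choice(4, size=n, p=p)]


def _place(genes: list[CodingSequence], space: int, offset: int,
           region: str) -> list[tuple[int, CodingSequence]]:
    """Evenly space genes inside a region; error if they do not fit."""
    total = sum(len(g.nt) for g in genes)
    if total >= space:
        raise ValueError(
            f"genes ({total} bp) do not fit in the {region} region ({space} bp)"
        )
    gap = (space - total) // (len(genes) + 1) if genes else 0
    placed = []
    pos = offset + gap
    for g in genes:
        placed.append((pos, g))
        pos += len(g.nt) + gap
    return placed


def gen_genome(spec: SyntheticSpec, genome_id: str = "synthetic") -> GenomeRecord:
    """Assemble an annotated plastome: LSC + IRb + SSC + revcomp(IRb).

    Protein-coding genes are placed in the LSC (ndh-family and ccsA genes
    in the SSC), an rRNA gene inside the IR (annotated once per arm), and
    two junction-spanning genes are planted with known overlaps: an
    rpl22-like gene reaching ``spec.irb_overlap`` bases into IRb and a
    ycf1-like gene reaching ``spec.ira_overlap`` bases into IRa.  The
    returned record carries the true partition.
    """
    lsc_len, ir_len, ssc_len = spec.region_lengths
    rng = np.random.default_rng(spec.seed)
    gc_lsc, gc_ir, gc_ssc = spec.region_gc
    lsc = _random_bases(rng, lsc_len, gc_lsc).copy()
    irb = _random_bases(rng, ir_len, gc_ir).copy()
    ssc = _random_bases(rng, ssc_len, gc_ssc).copy()

    names = list(_GENE_CATALOG[: spec.n_genes])
    cds_spec = replace(spec, seed=spec.seed + 1)
    junction_codons = [
        max(2, spec.irb_overlap // 3 + 40),                 # rpl22-like
        max(2, (spec.ira_overlap + max(300, ssc_len // 6)) // 3 + 1),  # ycf1-like
    ]
    all_cds = gen_biased_cds(
        cds_spec,
        names=names + ["rpl22", "ycf1"],
        codon_counts=[spec.codons_per_gene] * len(names) + junction_codons,
    )
    cds_by_name = {c.gene_name: c for c in all_cds}
    rpl22, ycf1 = cds_by_name.pop("rpl22"), cds_by_name.pop("ycf1")
    ssc_genes = [cds_by_name[n] for n in names
                 if n.startswith("ndh") or n == "ccsA"]
    lsc_genes = [cds_by_name[n] for n in names
                 if not (n.startswith("ndh") or n == "ccsA")]

    features: list[GeneFeature] = []

    # rpl22-like gene ending spec.irb_overlap bases past the LSC/IRb boundary
    jlen = len(rpl22.nt)
    if spec.irb_overlap >= jlen or spec.irb_overlap >= ir_len:
        raise ValueError("irb_overlap too large for the junction gene or IR")
    start = lsc_len - (jlen - spec.irb_overlap)
    arr = np.frombuffer(rpl22.nt.encode(), dtype="S1")
    lsc[start:] = arr[: jlen - spec.irb_overlap]
    irb[: spec.irb_overlap] = arr[jlen - spec.irb_overlap :]
    features.append(GeneFeature("rpl22", "CDS", ((start, start + jlen),), "+"))

    # ycf1-like gene ending spec.ira_overlap bases past the SSC/IRa boundary;
    # its IRa portion is stored as the reverse complement of the IRb tail
    ylen = len(ycf1.nt)
    if spec.ira_overlap >= ylen:
        raise ValueError("ira_overlap must be smaller than the ycf1-like gene")
    if spec.ira_overlap >= ir_len or (ylen - spec.ira_overlap) >= ssc_len // 2:
        raise ValueError("ycf1-like junction gene does not fit its regions")
    yarr = np.frombuffer(ycf1.nt.encode(), dtype="S1")
    ssc_part = ylen - spec.ira_overlap
    ssc[ssc_len - ssc_part :] = yarr[:ssc_part]
    tail = ycf1.nt[ssc_part:]
    irb[ir_len - spec.ira_overlap :] = np.frombuffer(
        revcomp(tail).encode(), dtype="S1"
    )
    y_start = lsc_len + ir_len + ssc_len - ssc_part
    features.append(GeneFeature("ycf1", "CDS", ((y_start, y_start + ylen),), "+"))

    # interior genes, evenly spaced; SSC keeps its head clear for the IR
    # boundary-mismatch guard and its tail for the ycf1-like gene
    for pos, g in _place(lsc_genes, start - 100, 50, "LSC"):
        lsc[pos : pos + len(g.nt)] = np.frombuffer(g.nt.encode(), dtype="S1")
        features.append(
            GeneFeature(g.gene_name, "CDS", ((pos, pos + len(g.nt)),), "+")
        )
    for pos, g in _place(ssc_genes, ssc_len - ssc_part - 100, 50, "SSC"):
        abs_pos = lsc_len + ir_len + pos
        ssc[pos : pos + len(g.nt)] = np.frombuffer(g.nt.encode(), dtype="S1")
        features.append(
            GeneFeature(g.gene_name, "CDS", ((abs_pos, abs_pos + len(g.nt)),), "+")
        )

    # one rRNA gene inside the IR, annotated on both arms
    rrn_len = min(2000, ir_len // 4)
    rrn_off = ir_len // 2
    if spec.irb_overlap < rrn_off and rrn_off + rrn_len < ir_len - spec.ira_overlap:
        s_b = lsc_len + rrn_off
        features.append(GeneFeature("rrn23", "rRNA", ((s_b, s_b + rrn_len),), "+"))
        s_a = lsc_len + ir_len + ssc_len + (ir_len - rrn_off - rrn_len)
        features.append(GeneFeature("rrn23", "rRNA", ((s_a, s_a + rrn_len),), "-"))

    # guard against chance maximal extension of the IR arms into the SSC:
    # the base after IRb must not pair with the base before IRa
    comp = {b"A": b"T", b"C": b"G", b"G": b"C", b"T": b"A"}
    if comp[bytes(ssc[0])] == bytes(ssc[-1]):
        for bb in (b"A", b"C", b"G", b"T"):
            if comp[bb] != bytes(ssc[-1]):
                ssc[0] = bb
                break

    seq = (
        lsc.tobytes() + irb.tobytes() + ssc.tobytes()
        + revcomp(irb.tobytes().decode()).encode()
    ).decode()
    L = len(seq)
    partition = QuadripartitePartition(
        lsc=Interval(0, lsc_len),
        irb=Interval(lsc_len, lsc_len + ir_len),
        ssc=Interval(lsc_len + ir_len, lsc_len + ir_len + ssc_len),
        ira=Interval(lsc_len + ir_len + ssc_len, L),
    )
    features.sort(key=lambda f: f.span)
    return GenomeRecord(id=genome_id, seq=seq, features=features,
                        partition=partition)


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _site_rates(genome: GenomeRecord,
                spec: SyntheticSpec) -> np.ndarray:
    L = genome.length
    rates = np.full(L, spec.mutation_rates[0])
    part = genome.partition
    if part is not None:
        r_lsc, r_ir, r_ssc = spec.mutation_rates
        for iv, r in ((part.lsc, r_lsc), (part.irb, r_ir),
                      (part.ssc, r_ssc), (part.ira, r_ir)):
            cols = iv.columns(L)
            if cols:
                rates[np.array(cols)] = r
    for start, end, rate in spec.hotspots or ():
        rates[start:end] = rate
    if rates.max() > 0.75:
        raise ValueError("per-site substitution probability > 0.75 "
                         "(Jukes–Cantor saturation)")
    return rates


def _mutate_sites(seq_arr: np.ndarray, rates: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    out = seq_arr.copy()
    hit = np.nonzero(rng.random(len(out)) < rates)[0]
    for i in hit:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def evolve_alignment(
    ancestor: GenomeRecord, n_taxa: int, spec: SyntheticSpec
) -> AlignedSet:
    """Star-tree, site-independent substitution process over the genome.

    Each taxon derives independently from the ancestor; per-site
    substitution probability comes from the region rates, overridden
    inside hotspot intervals.  No indels, so rows are columns-true.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(spec.seed)
    rates = _site_rates(ancestor, spec)
    anc = np.frombuffer(ancestor.seq.encode(), dtype="S1")
    rows = [
        _mutate_sites(anc, rates, rng).tobytes().decode()
        for _ in range(n_taxa)
    ]
    labels = [f"sp{i + 1}" for i in range(n_taxa)]
    return AlignedSet(labels=labels, rows=rows)


def _evolve_codons(
    codons: list[str], omega: float, t_lineage: float, rng: np.random.Generator
) -> list[str]:
    """Stop-avoiding codon substitution process on one lineage.

    Proposals are uniform single-base changes; synonymous proposals are
    accepted with probability 1, nonsynonymous with probability ``omega``,
    stop-producing ones always rejected.  The proposal count is calibrated
    so the realized synonymous divergence per synonymous site ≈
    ``t_lineage``.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    cods = list(codons)
    n = len(cods)
    n_prop = rng.poisson(3.0 * n * t_lineage)
    for _ in range(n_prop):
        ci = int(rng.integers(n))
        pos = int(rng.integers(3))
        cur = cods[ci]
        if cur in STOP_CODONS or "N" in cur:
            continue
        alts = [b for b in "ACGT" if b != cur[pos]]
        new = cur[:pos] + alts[int(rng.integers(3))] + cur[pos + 1 :]
        if new in STOP_CODONS:
            continue
        if AA_OF[new] == AA_OF[cur] or rng.random() < omega:
            cods[ci] = new
    return cods


def evolve_cds_pair(
    gene: CodingSequence, omega: float, t: float, seed: int
) -> tuple[CodingSequence, CodingSequence]:
    """Evolve two descendants of one CDS to pairwise synonymous depth ≈ t."""
    if t < 0:
        raise ValueError("t must be >= 0")
    rng = np.random.default_rng(seed)
    sense = gene.sense_codons
    stop = gene.codons[-1:] if gene.has_terminal_stop else []
    pair = []
    for _ in range(2):
        evolved = _evolve_codons(sense, omega, t / 2.0, rng)
        pair.append(
            CodingSequence(gene_name=gene.gene_name, nt="".join(evolved + stop),
                           gene_set=gene.gene_set)
        )
    return pair[0], pair[1]


# ---------------------------------------------------------------------------
# Full multi-species data set
# ---------------------------------------------------------------------------


def _auto_hotspots(genome: GenomeRecord, spec: SyntheticSpec
                   ) -> tuple[tuple[int, int, float], ...]:
    """Place hotspot intervals in the largest intergenic gaps (LSC + SSC)."""
    part = genome.partition
    bounds = []
    if part is not None:
        bounds = [(part.lsc.start, part.lsc.end), (part.ssc.start, part.ssc.end)]
    else:
        bounds = [(0, genome.length)]
    spans = sorted(f.span for f in genome.features)
    gaps = []
    for lo, hi in bounds:
        prev = lo
        for s, e in spans:
            if e <= lo or s >= hi:
                continue
            if s - prev >= 100:
                gaps.append((prev, s))
            prev = max(prev, e)
        if hi - prev >= 100:
            gaps.append((prev, hi))
    gaps.sort(key=lambda g: g[1] - g[0], reverse=True)
    chosen = []
    for lo, hi in gaps[: spec.n_hotspots]:
        width = min(spec.hotspot_width, hi - lo)
        mid = (lo + hi) // 2
        chosen.append((mid - width // 2, mid - width // 2 + width,
                       spec.hotspot_rate))
    chosen.sort()
    return tuple(chosen)


def gen_species_set(
    spec: SyntheticSpec, n_taxa: int = 5
) -> tuple[list[GenomeRecord], AlignedSet]:
    """Generate an ancestor and ``n_taxa`` descendant species genomes.

    Coding regions evolve codon-wise under each gene set's ω (pairwise
    synonymous depth ≈ ``spec.divergence_t``); intergenic sites evolve
    under the region rates with hotspot elevation; the IR arms evolve in
    concert (IRa is rebuilt as revcomp(IRb) per species), so the
    descendants keep a detectable quadripartite structure.  Rows of the
    returned alignment are the species genomes (no indels).
    """
    from .rates import assign_gene_sets

    ancestor = gen_genome(spec)
    part = ancestor.partition
    assert part is not None
    hotspots = spec.hotspots or _auto_hotspots(ancestor, spec)
    spec_h = replace(spec, hotspots=hotspots)
    lsc_len, ir_len, ssc_len = spec.region_lengths
    unique_len = lsc_len + ir_len + ssc_len

    # unique-part site rates; CDS positions are masked out of the site
    # process and evolved codon-wise instead
    rates = _site_rates(ancestor, spec_h)[:unique_len]
    omega_map = dict(spec.omega_by_set)
    cds_feats = [f for f in ancestor.features if f.kind == "CDS"]
    sets = assign_gene_sets([f.gene_name for f in cds_feats])
    for f in cds_feats:
        s, e = f.span
        rates[s : min(e, unique_len)] = 0.0
    # the IRb tail mirrors the ycf1-like gene's IRa portion: freeze it too
    ycf1 = next((f for f in ancestor.features if f.gene_name == "ycf1"), None)
    if ycf1 is not None:
        overlap = ycf1.span[1] - (unique_len)
        if overlap > 0:
            rates[lsc_len + ir_len - overlap : lsc_len + ir_len] = 0.0

    rng = np.random.default_rng(spec.seed + 10_000)
    anc_unique = np.frombuffer(ancestor.seq[:unique_len].encode(), dtype="S1")
    genomes = []
    rows = []
    for i in range(n_taxa):
        u = _mutate_sites(anc_unique, rates, rng)
        for f in cds_feats:
            s, e = f.span
            nt = ancestor.seq[s:e]
            cds = CodingSequence(f.gene_name, nt)
            evolved = _evolve_codons(
                cds.sense_codons, omega_map.get(sets[f.gene_name], 0.3),
                spec.divergence_t / 2.0, rng,
            )
            if cds.has_terminal_stop:
                evolved = evolved + [cds.codons[-1]]
            enc = "".join(evolved).encode()
            if e <= unique_len:
                u[s:e] = np.frombuffer(enc, dtype="S1")
            else:  # ycf1-like gene: SSC part direct, IRa part via the IRb tail
                cut = unique_len - s
                u[s:unique_len] = np.frombuffer(enc[:cut], dtype="S1")
                tail = enc[cut:].decode()
                u[lsc_len + ir_len - len(tail) : lsc_len + ir_len] = (
                    np.frombuffer(revcomp(tail).encode(), dtype="S1")
                )
        irb_new = u[lsc_len : lsc_len + ir_len].tobytes().decode()
        full = u.tobytes().decode() + revcomp(irb_new)
        genomes.append(
            GenomeRecord(
                id=f"sp{i + 1}", seq=full,
                features=list(ancestor.features), partition=part,
            )
        )
        rows.append(full)
    aln = AlignedSet(labels=[g.id for g in genomes], rows=rows)
    return genomes, aln


def write_fixture_set(
    outdir: str | Path, spec: SyntheticSpec, n_taxa: int = 5
) -> dict[str, Path]:
    """Materialize a demo data set: GenBank files + aligned FASTA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes, aln = gen_species_set(spec, n_taxa=n_taxa)
    paths: dict[str, Path] = {}
    for g in genomes:
        p = outdir / f"{g.id}.gb"
        write_genbank(g, p)
        paths[g.id] = p
    aln_path = outdir / "alignment.fasta"
    with open(aln_path, "w") as fh:
        for label, row in zip(aln.labels, aln.rows):
            fh.write(f">{label}\n")
            for i in range(0, len(row), 70):
                fh.write(row[i : i + 70] + "\n")
    paths["alignment"] = aln_path
    return paths
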