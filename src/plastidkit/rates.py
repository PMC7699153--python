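"""Nei–Gojobori (1986) dN/dS estimation by functional gene set.

The NG86 method counts, per codon, the expected numbers of synonymous (S)
and nonsynonymous (N) sites from the 9 single-base neighbours, resolves
observed codon differences by averaging over all minimal substitution
pathways (excluding pathways through stop codons), and corrects the
proportions pS, pN with the one-parameter Jukes–Cantor formula
d = −(3/4)·ln(1 − 4p/3).

Gene sets follow the standard functional grouping of plastid genes
(photosystems psa/psb, ATP synthase atp, NADH dehydrogenase ndh, ... plus
the single-gene sets accD, ccsA, cemA, clpP, matK, rbcL): 14 sets in all.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from ._genetics import AA_OF, STOP_CODONS, codons_of
from .genome import CodingSequence, GenomeRecord, extract_cds, unique_cds_features

__all__ = [
    "SubstRates",
    "GENE_SETS",
    "assign_gene_sets",
    "ng86_sites",
    "ng86_pair",
    "geneset_rates",
]

#: the 14 functional gene sets: exact single-gene names and name prefixes
GENE_SET_EXACT = ("accD", "ccsA", "cemA", "clpP", "matK", "rbcL")
GENE_SET_PREFIXES = ("atp", "ndh", "pet", "psa", "psb", "rpo", "rpl", "rps")
GENE_SETS = tuple(sorted(GENE_SET_EXACT + GENE_SET_PREFIXES))


@dataclass(frozen=True)
class SubstRates:
    """dN, dS and site counts for one sequence pair or gene-set aggregate."""

    dn: float | None
    ds: float | None
    omega: float | None  # dn/ds; None when ds == 0 or either rate undefined
    n_sites: float
    s_sites: float
    pairs_used: int = 1
    codons_compared: int = 0


def assign_gene_sets(gene_names: Iterable[str]) -> dict[str, str]:
    """Map each gene name to its functional set ("unassigned" if none).

    Exact names (accD, ccsA, cemA, clpP, matK, rbcL) are matched first,
    then the three-letter prefixes (psbA → psb, rps19 → rps, ...).
    """
    out: dict[str, str] = {}
    for name in gene_names:
        if name in GENE_SET_EXACT:
            out[name] = name
            continue
        for prefix in GENE_SET_PREFIXES:
            if name.startswith(prefix):
                out[name] = prefix
                break
        else:
            out[name] = "unassigned"
    return out


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes the fraction of its 3 possible single-base
    changes that are synonymous; changes to stop codons count as
    nonsynonymous.  s + n == 3 for every codon.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"ng86_sites: stop codon {codon}")
    aa = AA_OF[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in STOP_CODONS and AA_OF[mut] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _pathway_differences(c1: str, c2: str) -> tuple[float, float] | None:
    """Average (synonymous, nonsynonymous) differences between two codons.

    Enumerates every ordering of the differing positions; pathways passing
    through a stop codon are excluded.  ``None`` when no stop-free pathway
    exists (the codon pair is then dropped from the comparison).
    """
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    if not diff_pos:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        ok = True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if AA_OF[cur] == AA_OF[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        return None
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    """JC correction d = −(3/4)·ln(1 − 4p/3); None at/beyond saturation."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


_GOOD = frozenset("ACGT")


def ng86_pair(cds_a: CodingSequence, cds_b: CodingSequence) -> SubstRates:
    """NG86 dN/dS between two equal-length coding sequences.

    Codon pairs containing N (or a stop codon in either sequence, e.g. the
    terminal stop) are dropped, as are pairs whose every minimal pathway
    passes through a stop.  Site counts are averaged over the two
    sequences.
    """
    ca, cb = cds_a.codons, cds_b.codons
    if len(ca) != len(cb):
        raise ValueError(
            f"{cds_a.gene_name}: sequences differ in length "
            f"({3 * len(ca)} vs {3 * len(cb)} nt)"
        )
    s_sites = n_sites = 0.0
    sd = nd = 0.0
    used = 0
    for x, y in zip(ca, cb):
        if (set(x) | set(y)) - _GOOD:
            continue
        if x in STOP_CODONS or y in STOP_CODONS:
            continue
        path = _pathway_differences(x, y)
        if path is None:
            continue
        sx, nx = ng86_sites(x)
        sy, ny = ng86_sites(y)
        s_sites += (sx + sy) / 2.0
        n_sites += (nx + ny) / 2.0
        sd += path[0]
        nd += path[1]
        used += 1
    if used == 0:
        raise ValueError(
            f"{cds_a.gene_name}/{cds_b.gene_name}: no comparable codons"
        )
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)
    omega = None
    if dn is not None and ds is not None and ds > 0:
        omega = dn / ds
    return SubstRates(
        dn=dn, ds=ds, omega=omega,
        n_sites=n_sites, s_sites=s_sites,
        pairs_used=1, codons_compared=used,
    )


def _shared_cds(
    genomes: Sequence[GenomeRecord],
) -> dict[str, list[CodingSequence]]:
    """Gene name -> one CDS per genome, for genes shared by all genomes.

    Genes whose extracted CDS lengths differ between genomes are skipped
    (the estimator requires positional homology; the synthetic generator
    is indel-free so nothing is skipped there).
    """
    per_genome: list[dict[str, CodingSequence]] = []
    for g in genomes:
        d: dict[str, CodingSequence] = {}
        for f in unique_cds_features(g):
            if f.gene_name not in d:
                d[f.gene_name] = extract_cds(g, f)
        per_genome.append(d)
    shared = set(per_genome[0])
    for d in per_genome[1:]:
        shared &= set(d)
    out = {}
    for name in sorted(shared):
        cdss = [d[name] for d in per_genome]
        if len({len(c.nt) for c in cdss}) == 1:
            out[name] = cdss
    return out


def geneset_rates(
    genomes: Sequence[GenomeRecord],
    assignment: Mapping[str, str] | None = None,
) -> dict[str, SubstRates]:
    """Mean pairwise NG86 rates per functional gene set across genomes.

    Shared genes are concatenated per genome in fixed (sorted) name order;
    every genome pair is compared and dN, dS are averaged arithmetically
    over the C(n,2) pairs; ω = mean dN / mean dS.  Sets with no shared
    genes are absent from the result.
    """
    if len(genomes) < 2:
        raise ValueError("geneset_rates needs at least 2 genomes")
    shared = _shared_cds(genomes)
    if assignment is None:
        assignment = assign_gene_sets(shared.keys())
    by_set: dict[str, list[str]] = {}
    for name in shared:
        gs = assignment.get(name, "unassigned")
        if gs != "unassigned":
            by_set.setdefault(gs, []).append(name)
    out: dict[str, SubstRates] = {}
    for gs, names in sorted(by_set.items()):
        names.sort()
        concats = []
        for i in range(len(genomes)):
            nt = "".join("".join(shared[n][i].sense_codons) for n in names)
            concats.append(CodingSequence(gene_name=f"{gs}:{genomes[i].id}", nt=nt))
        pair_rates = [
            ng86_pair(a, b) for a, b in itertools.combinations(concats, 2)
        ]
        dns = [r.dn for r in pair_rates if r.dn is not None]
        dss = [r.ds for r in pair_rates if r.ds is not None]
        dn = sum(dns) / len(dns) if dns else None
        ds = sum(dss) / len(dss) if dss else None
        omega = dn / ds if dn is not None and ds not in (None, 0.0) else None
        out[gs] = SubstRates(
            dn=dn, ds=ds, omega=omega,
            n_sites=sum(r.n_sites for r in pair_rates) / len(pair_rates),
            s_sites=sum(r.s_sites for r in pair_rates) / len(pair_rates),
            pairs_used=len(pair_rates),
            codons_compared=pair_rates[0].codons_compared,
        )
    return out


def pairwise_rates_table(
    genomes: Sequence[GenomeRecord],
    assignment: Mapping[str, str] | None = None,
) -> list[tuple[str, str, str, SubstRates]]:
    """Long-format (gene_set, genome_a, genome_b, rates) table."""
    if len(genomes) < 2:
        raise ValueError("needs at least 2 genomes")
    shared = _shared_cds(genomes)
    if assignment is None:
        assignment = assign_gene_sets(shared.keys())
    by_set: dict[str, list[str]] = {}
    for name in shared:
        gs = assignment.get(name, "unassigned")
        if gs != "unassigned":
            by_set.setdefault(gs, []).append(name)
    rows = []
    for gs, names in sorted(by_set.items()):
        names.sort()
        for i, j in itertools.combinations(range(len(genomes)), 2):
            a = CodingSequence(
                gene_name=f"{gs}:{genomes[i].id}",
                nt="".join("".join(shared[n][i].sense_codons) for n in names),
            )
            b = CodingSequence(
                gene_name=f"{gs}:{genomes[j].id}",
                nt="".join("".join(shared[n][j].sense_codons) for n in names),
            )
            rows.append((gs, genomes[i].id, genomes[j].id, ng86_pair(a, b)))
    return rows
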