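"""Diagnostics of the forces shaping codon usage.

Three classic plots, as data tables:

* ENc–GC3s ("Wright") plot: observed effective number of codons per gene
  against its expected value under mutation–drift alone; genes below the
  curve suggest selection on codon choice.
* PR2 (parity rule 2) plot: AT-bias A3s/(A3s+T3s) against GC-bias
  G3s/(G3s+C3s) at synonymous third positions; (0.5, 0.5) means no
  strand-asymmetric mutation/selection.
* Neutrality plot: per-gene GC12 regressed on GC3; a slope near 1 points
  to mutation pressure, near 0 to selective constraint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .codon import CodonUsageSummary, enc_expected

__all__ = [
    "PR2Point",
    "NeutralityFit",
    "EncCurvePoint",
    "pr2_coordinates",
    "pr2_from_contents",
    "neutrality_fit",
    "enc_curve_table",
]


@dataclass(frozen=True)
class PR2Point:
    label: str
    at_bias: float  # A3s / (A3s + T3s)
    gc_bias: float  # G3s / (G3s + C3s)


@dataclass(frozen=True)
class NeutralityFit:
    slope: float
    intercept: float
    r2: float
    n_genes: int


@dataclass(frozen=True)
class EncCurvePoint:
    label: str
    gc3s: float
    enc_observed: float
    enc_expected: float
    deviation: float  # (expected - observed) / expected; > 0 means below curve


def pr2_from_contents(
    a3s: float, t3s: float, c3s: float, g3s: float, label: str = ""
) -> PR2Point | None:
    """PR2 coordinates from synonymous third-position base contents.

    Returns ``None`` (undefined point) when either denominator is zero.
    """
    if a3s + t3s <= 0 or g3s + c3s <= 0:
        return None
    return PR2Point(label=label, at_bias=a3s / (a3s + t3s),
                    gc_bias=g3s / (g3s + c3s))


def pr2_coordinates(summary: CodonUsageSummary, label: str | None = None) -> PR2Point | None:
    """PR2 coordinates of a codon-usage summary row."""
    if summary.a3s is None:
        return None
    return pr2_from_contents(
        summary.a3s, summary.t3s, summary.c3s, summary.g3s,
        label=summary.label if label is None else label,
    )


def neutrality_fit(points: Sequence[tuple[float, float]]) -> NeutralityFit:
    """OLS regression of GC12 on GC3 over per-gene points (gc12, gc3)."""
    if len(points) < 3:
        raise ValueError("neutrality_fit needs at least 3 genes")
    gc12 = [p[0] for p in points]
    gc3 = [p[1] for p in points]
    if len(set(gc3)) == 1:
        raise ValueError("no GC3 variation among genes")
    res = stats.linregress(gc3, gc12)
    return NeutralityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        n_genes=len(points),
    )


def enc_curve_table(
    per_gene: Iterable[CodonUsageSummary],
) -> list[EncCurvePoint]:
    """ENc–GC3s plot data with deviation from Wright's expected curve."""
    out = []
    for s in per_gene:
        if s.gc3s is None or s.enc is None:
            continue
        exp = enc_expected(s.gc3s)
        out.append(
            EncCurvePoint(
                label=s.label,
                gc3s=s.gc3s,
                enc_observed=s.enc,
                enc_expected=exp,
                deviation=(exp - s.enc) / exp,
            )
        )
    return out
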