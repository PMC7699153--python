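"""Codon-usage bias of a synthetic AT-rich plastid gene set.

Generates 40 coding sequences with GC3s tuned to 0.29 (typical of
chloroplast genes), then prints the pooled usage summary, the most and
least preferred leucine codons by RSCU, and where the pool sits relative
to Wright's mutation-drift ENc curve.
"""

from plastidkit import (
    compute_rscu,
    count_codons,
    enc_expected,
    summarize_usage,
)
from plastidkit.simulate import SyntheticSpec, gen_biased_cds

spec = SyntheticSpec(seed=3, n_genes=40, codons_per_gene=250, gc3s_target=0.29)
genes = gen_biased_cds(spec)

summary = summarize_usage(genes, label="synthetic pool")
print(f"pooled over {summary.n_codons} codons from {len(genes)} genes")
print(f"  GC1 {summary.gc1:.3f}  GC2 {summary.gc2:.3f}  GC3 {summary.gc3:.3f}")
print(f"  GC3s {summary.gc3s:.3f}  ENc {summary.enc:.2f}  CAI {summary.cai:.3f}")

expected = enc_expected(summary.gc3s)
print(f"  expected ENc at this GC3s (mutation-drift only): {expected:.2f}")
print(f"  deviation from the curve: {(expected - summary.enc) / expected:+.3f}")

rscu = compute_rscu(count_codons(genes)).rscu
leu = {c: rscu[c] for c in ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG")}
top = max(leu, key=leu.get)
bottom = min(leu, key=leu.get)
print(f"  leucine RSCU: highest {top} ({leu[top]:.2f}), "
      f"lowest {bottom} ({leu[bottom]:.2f})")
print("An ENc near its expectation and RSCU favouring A/T-ending codons "
      "are the signature of mutation-driven, AT-biased codon usage.")
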