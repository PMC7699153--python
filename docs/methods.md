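# Methods

This note documents the models and procedures plastidkit implements, the
numerical conventions chosen where the literature leaves room, what the
synthetic-data generator does and does not emulate, and the package's
known limitations.

## Genome model and coordinates

A plastome is modelled as a circular DNA molecule with CDS/tRNA/rRNA
features carrying exon structure (`join` parts in transcription order),
strand, and a `codon_start` reading-frame offset. Coordinates are 0-based
half-open internally; GenBank's 1-based inclusive convention exists only
at the file boundary (handled by Biopython). Features crossing the origin
appear as two exons. Ambiguity codes other than N are rejected at read
time: downstream statistics have no defined semantics for them, and a
loud failure beats silent miscounting.

CDS validation uses NCBI translation table 11 (plastid/bacterial): exons
are spliced, minus-strand genes reverse-complemented, `codon_start` bases
trimmed; any internal stop aborts with the gene name and codon index,
while a terminal stop is retained and flagged. Genes annotated twice
because they lie inside both IR arms are deduplicated by (name, extracted
sequence), matching how plastome gene counts are conventionally reported.

## Inverted-repeat detection

The IR pair is found as the longest pair of disjoint, exactly
reverse-complementary repeats of length ≥ `min_len` (default 10 kb),
seeded with 1 kb k-mer matches between the sequence and its reverse
complement and extended maximally by direct base comparison. Exact
matching is deliberate: real plastome IR arms are kept effectively
identical by copy correction, and near-identical repeat detection would
complicate the contract without a use case. When the arms differ at an
internal base, the longer exactly-matching arm is returned. The two gaps
between the arms become LSC (larger) and SSC (smaller); the partition
tiles the genome exactly, and LSC intervals may wrap the origin.

Junction reports give, for each of the four region boundaries, every
feature overlapping it with the exact number of its bases on the IR side,
plus features within 100 bp reported with their distance instead.

## Codon-usage statistics

All indices are computed from a 64-entry codon count table, so per-gene
and pooled per-species values share one code path. Per-species rows pool
codons across genes (CodonW's "concatenated" style); a per-gene averaging
mode was considered and rejected for the summary row because a pooled row
is what a single-species table reports.

Conventions under table 11:

* Synonymous family structure: nine 2-fold families, one 3-fold (Ile),
  five 4-fold, three 6-fold (Leu, Ser, Arg); Met and Trp are single-codon
  families.
* RSCU treats the three stop codons as a synonymous family by default
  (configurable), so a stop codon can meaningfully have RSCU below 1;
  single-codon families have RSCU 1 when present.
* Synonymous third-position contents (A3s/T3s/C3s/G3s, GC3s) are computed
  over codons of amino acids with ≥ 2 synonymous codons — everything
  except Met, Trp and stops.
* ENc follows Wright's estimator. Small-sample rules: families with fewer
  than 2 observed codons are dropped from their degeneracy-class mean;
  families with estimated homozygosity F̂ = 0 are also dropped (an
  estimate of 0 is uninformative and would let a single two-codon family
  zero a class divisor); an absent 3-fold class is imputed as
  F̄₃ = (F̄₂ + F̄₄)/2; any other empty class makes ENc undefined for that
  gene. The result is clamped to [20, 61], as CodonW does.
* CAI weights are Sharp & Li relative adaptiveness on pooled reference
  counts; codons unseen in the reference receive a floor weight of 0.01
  (configurable) so one rare codon cannot zero a gene's geometric mean.
  The default reference set is the photosynthesis genes (psa, psb, rbcL
  sets) of the analysed genomes, a standard proxy for highly expressed
  plastid genes; because CAI is reference-relative, absolute CAI values
  are comparable only within one reference choice.

PR2 coordinates use the synonymous third-position contents (the CodonW
definitions) rather than fourfold-degenerate-family-only counts; the
former reproduces published per-species biases exactly from published
content tables. The neutrality fit is ordinary least squares of per-gene
GC12 on GC3 (scipy's linregress), reporting slope, intercept and R²; R²
rather than r is reported because the quantity is used as a proportion of
variance explained.

## Nucleotide diversity

π is the mean pairwise proportion of differing sites. Windows (default
400 bp / 200 bp step, the standard plastome scan) use site-complete
deletion: any column with a gap or N in any row is excluded from both
numerator and denominator, matching DnaSP's windowed behaviour and making
the brute-force oracle unambiguous. A terminal partial window is kept
only if it retains ≥ 50 valid sites. Output files use 1-based inclusive
coordinates (DnaSP convention) for the window table and 0-based half-open
for the BED hotspot track.

Hotspots are maximal runs of strictly overlapping windows with π above
the threshold (default 0.10); each region carries its peak window's π and
is labelled by the genes overlapping the peak window, or by its flanking
genes as an intergenic-spacer name ("trnH-psbA" style).

The pipeline consumes a pre-built aligned FASTA and never shells out to
an aligner: determinism and testability outweigh convenience here.

## Substitution rates

dN/dS uses the Nei–Gojobori (1986) counting method with Jukes–Cantor
correction. Maximum-likelihood codon models (codeml-style) are out of
scope by design: NG86 is fully specifiable, has an exact desk-scale
oracle, and suffices for the comparative ordering of gene sets. Absolute
rate values from ML studies are therefore comparable only qualitatively.

Per codon, synonymous site counts come from the 9 single-base neighbours
(changes to stops count as nonsynonymous), so S + N = 3 exactly. Observed
differences are averaged with equal weight over all minimal substitution
pathways; pathways through stop codons are excluded, and codon pairs with
no stop-free pathway are dropped entirely (the MEGA convention). Codons
containing N or a stop in either sequence are dropped pairwise. pS or pN
at or beyond the 3/4 saturation point leaves the corrected rate missing.

Gene sets follow the 14 standard functional groups (atp, ndh, pet, psa,
psb, rpo, rpl, rps prefixes; accD, ccsA, cemA, clpP, matK, rbcL
singletons). Shared genes are concatenated per genome in sorted name
order; dN and dS are averaged without weighting over all C(n,2) genome
pairs and ω = mean dN / mean dS. Genes whose extracted CDS lengths differ
between genomes are skipped for the set: the estimator requires
positional homology, and codon-aware alignment is outside the package's
scope.

## Synthetic data

The generator exists so that every statistic above has a ground truth. It
emulates: a ~160 kb LSC + IRb + SSC + IRa layout (defaults 87 kb / 26.5
kb / 18.3 kb); ~74 protein-coding genes with AT-rich usage (GC3s target
0.29); intergenic background GC of 0.34 / 0.43 / 0.31 for LSC / IR / SSC;
junction-spanning genes with known IR overlaps (an rpl22-like gene 60 bp
into IRb, a ycf1-like gene 1300 bp into IRa); IR mutation rate one fifth
of the single-copy rate (0.004 vs 0.02 per site); seven 600 bp intergenic
hotspots at rate 0.08, placed in the largest intergenic gaps; per-set ω
from 0.06 (psb) to 1.06 (clpP); and pairwise synonymous depth t = 0.1.
These defaults are the study conditions the tests run under; desk-scale
tests shrink the genome (20 kb / 6 kb / 4 kb, 20 genes) to keep the suite
fast, which changes problem size, not conditions.

Within each synonymous family, G/C-ending codons share probability mass
equal to the GC3s target, so the pooled GC3s expectation equals the
target exactly; `bias_strength` multiplies one codon's weight by
exp(bias), driving ENc toward 20 at the extreme. CDS evolution proposes
uniform single-base changes, accepts synonymous ones always and
nonsynonymous ones with probability ω, rejects stop-producing ones, and
calibrates the proposal count so realized dS ≈ t — the estimator being
tested plays no role in the simulation. Intergenic sites evolve by
per-site Bernoulli substitution under the region/hotspot rates, and the
IR arms evolve in concert (IRa is rebuilt as the reverse complement of
the evolved IRb), preserving detectable structure.

Deliberate non-realism, and what it implies: there is **no indel
process**, so alignments are column-true by construction and window-π and
NG86 oracles are exact — passing tests say nothing about alignment-error
robustness on real data. Species derive from a **star tree**, so there is
no topology signal and no rate variation along branches. Codon usage is
drawn i.i.d. per site with uniform amino-acid frequencies, so
context effects and amino-acid composition bias are absent.

## Numerical choices and degenerate inputs

Fractions are reported to 3 decimals and ENc to 2 in the summary tables
(the conventional printed precision); full precision is available from
the API. Undefined quantities (zero denominators, saturated distances,
unestimable ENc classes) are reported as missing (`None`/`NA`), never as
0. Region GC over an all-N region is missing. A window with zero valid
sites is missing. ω is missing exactly when dS = 0. All randomness flows
through explicit integer seeds (numpy `default_rng`); no hash-order or
platform dependence.

## Limitations

* Real-data dN/dS requires pre-aligned, equal-length CDSs per gene;
  the package skips length-discordant genes rather than aligning them.
* IR detection assumes exact arm identity and does not search across the
  sequence origin for the arms themselves.
* The CAI reference set is a package default, not a universal constant;
  absolute CAI values depend on it.
* The hotspot labeller names regions by flanking/overlapping genes of the
  first genome's annotation; with sparse annotation, labels may be empty.
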