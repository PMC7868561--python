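# Methods

## Coordinates and formats

All intervals are 0-based half-open (BED-native). circBase-style catalog
tables are treated as BED-like on ingest; a `one_based` flag on the
catalog readers shifts 1-based inclusive tables instead, since exports of
such catalogs exist in both conventions. Chromosome names are never
normalised ("chr1" ≠ "1"); a naming mismatch between inputs surfaces as
zero overlaps rather than being silently repaired. Coverage is
interchanged as bedGraph; the library size N is not part of that format
and must be supplied (the synthetic writer emits a `.total` sidecar).

## Expression and activity scores

* `rpm_backsplice(j, n) = j/n × 10⁶` — back-splice junction reads per
  million raw reads.
* `rpkm_backsplice(rpm) = rpm/112 × 1000`. The 112 bp constant is the
  effective junction-detection length (a 75 bp read needs a 20 bp anchor
  on each side of the junction, so 112 bp of junction-adjacent sequence
  is detectable). It is treated as an opaque, configurable normalisation
  parameter, not re-derived.
* `rpkm_body(m, n, L) = 10⁹·m/(n·L)` — plain read-density RPKM.
* `rpkm_ss(track, tss) = 10⁹·C/(2000·N)` with C the H3K27ac read count in
  `[tss−1000, tss+1000)`. C is computed as coverage-sum / read length so
  the score is derivable from a bedGraph alone; the read length is a
  stated convention (default 75 bp, 50 bp in the worked example).
  When the window is clipped at a chromosome edge the numerator shrinks
  but the denominator stays 2000 — the 2 kb constant is part of the
  score's definition, and keeping it fixed keeps the score monotone in
  the observed coverage.

The TAH rule uses strict inequalities on both axes (expression and
promoter activity); a tie is not "higher". This is conservative and
makes the call deterministic under exact arithmetic.

Host linear expression is scored as `rpkm_body` over the host gene span.
An alternative reading scores the linear reads over the circRNA's own
span; the primitive accepts any region, but the pipeline compares the
circle against its host gene as a unit, which is the cleaner statement of
"expressed above its host".

## Promoter windows

Two window conventions coexist deliberately:

* `expression_window` (±1 kb): the RPKM_ss activity window — it matches
  the fixed 2000 bp denominator of that score;
* `tf_window` (−2 kb/+1 kb, strand-aware): TF occupancy, promoter
  methylation and ChIA-PET TSS anchoring.

Both are named, and every consumer takes the convention as a parameter.
The circRNA TSS is defined as the 5′ end of the back-splice span by
strand; promoter-mark pileups upstream of circle spans support this
choice, and nothing else in the pipeline depends on it once fixed.

## TF network

Edge rule: a TF occupies a target when ≥ 1 bp of one of its peaks
intersects the target's `tf_window`. No overlap fraction is imposed (the
occupancy notion is "has at least one peak"), which makes edge presence
monotone in window size — a property the tests assert. Edges are
deduplicated per (TF, target, cell line), so ChIP replicates collapse.
The degree distribution is fitted by least squares on log(frequency)
vs log(degree) over nonzero bins — adequate for the visual power-law
claim it supports; a discrete maximum-likelihood fit is deliberately out
of scope. "Hub" targets are reported as the top decile by TF in-degree,
since no printed cutoff exists for that notion.

## Super-enhancers

ROSE-style: constituents fully contained within ±2 kb of a TSS are
removed, survivors on a chromosome are stitched while the end-to-start
gap is < 12.5 kb. Region signal is Σ over constituents of
max(sample − input coverage sum, 0). For the super/typical cutoff, both
the rank and signal axes are min–max scaled to [0, 1] and the cutoff is
the signal where a slope-1 line slid up from below touches the ranked
curve. This tangency is computed in the support-line form
`argmin(y − x)` rather than by scanning discrete slopes: the two agree on
a convex hockey-stick, but discrete forward differences are unstable when
many high-signal regions have near-equal loads, whereas the support-line
form is exact and deterministic (ties resolve to the lowest index, i.e.
the more inclusive cutoff). Regions *strictly above* the cutoff are
super-enhancers, so a flat curve yields none.

CircRNA assignment: a circle joins an enhancer when its span overlaps the
region or its TSS is within 50 kb (the conventional enhancer-to-gene
mapping window; no value is printed for circRNAs anywhere, so it is
configurable); the nearest region wins, ties break toward the higher
signal.

## Methylation

Promoter methylation is the mean beta of CpGs in the `tf_window`. In
WGBS mode CpGs with coverage < 4 are excluded; array mode carries no
coverage and uses all probes in the window. Stratification uses five
equal-width beta bins over [0, 1] (granularity configurable). Group
contrasts use the one-sided Wilcoxon rank-sum test (TAH < other for
beta; SE > TE for expression), matching the direction of the planted
effects.

## ChIA-PET contacts

A circRNA TSS has a distal regulatory contact when one anchor of a pair
overlaps its `tf_window`, the partner anchor overlaps a regulatory region
(the H3K27ac peak set by default; the stitched-enhancer set is a valid
substitute), and the anchor midpoints are ≥ 10 kb apart. Pairs are
unordered; 3C/5C/Hi-C pairs are treated identically to ChIA-PET pairs.
The regulatory anchor is *not* required to be non-promoter — promoter–
promoter loops count, and excluding them would need an extra annotation
judgment the data do not force.

## Probe re-annotation

The junction library concatenates up to 45 nt from the 3′ end ("tail")
and 45 nt from the 5′ end ("head") of each circle in transcript
orientation (reverse-complemented for minus-strand circles); circles
shorter than 90 nt contribute ⌊L/2⌋ per flank so the junction stays
centred. When host exon blocks are available the spliced sequence is
used; a flag falls back to the contiguous genomic span. Matching is
exact full-length substring search in either orientation — at zero
mismatches over 90-mers, alignment heuristics add nothing. A match must
cross the junction midpoint: a probe wholly inside one flank also occurs
in the linear transcript and is not junction-specific (this is stricter
than a plain alignment-based re-annotation). Probes hitting more than
one circle are discarded; circles retained need ≥ 1 exact probe; per-circle
expression is the mean of its retained probes' intensities.

## Enrichment statistics

* Hypergeometric overlap: exact upper-tail P(X ≥ k), enrichment
  convention.
* Permutation overlap: 20,000 draws by default, sampling the test-set
  size without replacement from a caller-chosen universe (full catalog,
  or a restricted subset such as the TF-bound circles — the two null
  models of interest differ only in that universe). Empirical p uses the
  add-one correction, (#null ≥ observed + 1)/(draws + 1), so p > 0 always.
* Preranked GSEA: features ranked by the Welch t statistic (descending,
  ties broken by id for determinism); hits weighted by |score|^p
  (default p = 1) normalised to one, misses by 1/(N − set size); ES is
  the running-sum extremum; significance by permuting set membership,
  compared two-sided among same-sign null ES values. Normalised ES and
  multi-set FDR are out of scope (single-set questions only). If every
  hit has score exactly 0 the weights degenerate and hits fall back to
  uniform weighting.
* Knockdown filter: FC = mean(control)/mean(knockdown); down-regulated
  ⇔ FC ≥ 1.4. The threshold and direction are parameters; the
  convention "bigger FC = stronger down-regulation in the knockdown" is
  fixed here because the commonly quoted alternative ("FC < 1.4") is
  ambiguous about which ratio is meant, and worked numbers in the
  literature (e.g. a 0.831 knockdown/control ratio called "decreased")
  are consistent with the control/knockdown reading.

## Synthetic data generator

The generator emulates the full input suite with planted truth. Defaults
are the study conditions:

| parameter | default | rationale |
|---|---|---|
| fraction planted TAH | 0.25 | middle of the reported 20–30% range |
| TAH circ/host expression factor | 4× (non-TAH 0.25×) | clear two-sided separation at realistic depth |
| TAH promoter H3K27ac factor | 2× host (non-TAH 0.5×) | same contrast on the activity axis |
| counts model | negative binomial, dispersion 20 | RNA-seq-realistic overdispersion; noise=0 ⇒ rounded means |
| library sizes | 10⁷ reads (RNA and ChIP) | desk-scale depth with non-trivial counting noise |
| read length | 75 bp | typical ENCODE RNA/ChIP read length; fixes all coverage→count conversions |
| contact rates | 0.5 TAH / 0.1 non-TAH | inside the reported 23–52% vs 11–46% ranges |
| methylation anticorrelation | ρ = 0.6 (Gaussian copula) | strong but noisy promoter beta–activity coupling |
| knockdown factor | 2× on bound TAH circles, hosts unchanged | the host-independence contrast |
| SE geometry | 4–6 × 800 bp constituents, 1.5 kb gaps, 8× background height | stitches into one region, clearly above the typical-enhancer load |

Geometry is engineered for identifiability: circles start at internal
exons so their TSS sits ≥ 3.3 kb (one exon+intron pitch) from the host
TSS, which keeps all ±1 kb activity windows disjoint; TF peaks are 300 bp
rectangles centred on the target TSS and therefore fall in exactly one
promoter window; enhancer constituents live in intergenic zones > 2 kb
from every TSS; ChIA-PET anchors pair a TSS window with a gene-promoter
or enhancer peak ≥ 12 kb away. Consequently, at noise = 0 every planted
structure is recovered exactly (the tests assert precision = recall = 1
for TAH status, TF edges, contacts and probes), and the noisy regime
degrades gracefully (TAH F1 ≈ 0.98 at default noise).

Ambiguous probes are planted by giving two single-exon circles an
identical junction context ("twins") so any probe targeting either hits
both; decoys are random 60-mers. Probe intensities copy the planted
per-circle values exactly, so intensity collapsing is checked for exact
recovery.

What the generator does **not** emulate: read-level sequencing (no
FASTQ/alignment), mappability and GC structure, overlapping genes and
nested windows, isoform complexity, batch effects in arrays, and
replicate structure beyond i.i.d. noise. Passing recovery tests
therefore demonstrates correctness of the interval arithmetic, score
formulas and statistical machinery under the planted model — not
robustness to the full messiness of real ENCODE data.

## Problem sizes

The default configuration yields ~420 circRNAs over 200 genes on four
chromosomes (~9 Mb); recovery checks run at ~2,100 circRNAs (1,050
genes). The permutation test uses its full 20,000 draws; GSEA uses 1,000
set permutations. These sizes keep every quantity statistically
meaningful while the whole suite plus the acceptance script completes in
well under a minute.

## Known limitations

* The TSS-exclusion list for stitching is caller-supplied; excluding
  circRNA promoter peaks (as the pipelines here do) is a choice, and
  supplying only gene TSSs would leave circle-promoter peaks in the
  enhancer universe.
* The log–log least-squares power-law fit is biased for heavy-tailed
  data at small n; it is reported with R² and a degeneracy flag rather
  than being treated as inference.
* Wilcoxon contrasts assume exchangeability within groups; planted
  per-gene effects mildly violate independence across circles sharing a
  host.
* The null-calibration tests for the permutation machinery are
  stochastic with fixed seeds; they verify calibration at the tested
  seeds, not uniformly.
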