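# Methods

This note documents the models, conventions and numerical choices behind
`intronlab`, in the order data flows through the package.

## Library design (`intronlab.design`)

**Geometry.** Coordinates are 1-based closed intervals counted from the
barcode's first base.  The barcode occupies positions 1–12 and the variable
region 13–170 (158 nt).  Synthetic introns start at position 18 (5 nt into
the region): the 5'SS occupies 18–23, the intron spans `18 … 18+L−1`, the
3'SS is the last 3 intron bases, the U element sits immediately upstream of
the 3'SS, and the branch motif ends D nt before the intron end, where the
branch-to-3'SS distance D counts from the first base after the 7-nt motif
through the final intron base (the 3'SS triplet included).  This makes
"branch end removed from the 3'SS by D nt" literal.  Natural-style introns
are inserted with 5-nt exonic flanks at the region's 5' end, capping intron
length at 148 nt.

**Site catalog.** Defaults: five 5'SS hexamers (`GTATGT` consensus plus
four genome-plausible variants), branch sites `TACTAAC` plus the degenerate
templates `NNCTAAC`, `NNCTAAT`, `NNTTAAC` (instantiated by seeded uniform
draws over the two N positions, a configurable number of times per
template), 3'SS `TAG`/`CAG`/`AAG`, U elements `ATTTTTAA`/`TTTAA`/`TAA`.
Mock (negative-control) sites are drawn once per library from the seed,
avoiding the canonical dinucleotides.  The bundled background regions are
seeded random ATG-free sequences — synthetic stand-ins for gene-derived
backgrounds, with the same statistical role (a fixed sequence context).

**No-start-codon rule.** The library is transcribed as non-coding RNA, so
every `ATG` at any offset is removed by a single deterministic substitution
(preferring the G, then A, then T; never creating a new ATG), except inside
protected splice-site motifs: a 5'SS such as `GTATGT` keeps its ATG, and a
stop codon (TAA/TAG/TGA) is planted starting 6 nt downstream of that ATG in
its frame.  Consequence: synthetic introns need ≥ 5 nt between the 5'SS and
the branch motif to host the stop, which the generators enforce.

**Two-intron designs.** Layout `exon1(5) – intronA – exon2 – intronB –
exon3(20)`, middle exon filled from the background and varying with the
intron lengths; all ordered pairs of the intron pool are built (n² variants
from n introns, self-pairs included).  The 20-nt 3' tail is a deliberate
geometry choice: a 5-nt tail would leave the intron2–exon3 junction
reference with only 5 discriminative exonic bases, putting unspliced reads
exactly at the positive-call boundary (100/125 = 0.80) and making the
five-way classification unsound.  Self-pairs (the same intron twice) are
kept, but their intron1-only and intron2-only isoforms are intrinsically
ambiguous to junction classification (the intron2–exon3 reference equals
the intron1 tail); the classifier abstains (`unclassified`) on such reads
rather than guessing.

**Structure mutants.** Random mutations around a chosen site (never inside
any site motif) are screened in-silico until the whole site is base-paired
in the predicted structure of a ±16-nt window.  Half the proposals seed a
complementary patch (the site's reverse complement at a random nearby
offset, ≥ 3 nt away for the hairpin loop) before adding noise mutations;
acceptance is purely by the fold predicate, and accepted variants record
their mutation positions.

## Read simulation (`intronlab.simulate`)

Reads emulate merged, adapter-trimmed amplicons covering barcode +
(possibly spliced) variable region, with sample (RNA/DNA), two biological
repeats and four control indexes assigned uniformly.  Per variant, a copy
number is drawn log-normal (ln-scale μ=0, σ=1) and an isoform mixture is
drawn as: negative controls never splice; other single-intron designs
splice with probability 0.4, with efficiency ~ Beta(2.0, 1.8) (a bimodal
mostly-on/mostly-off population, median SE of spliced designs ≈ 0.5);
two-intron designs draw Dirichlet(2, 1, 1, 0.5, 1) over (unspliced,
intron1, intron2, exon-skipping, both).  Sequencing error is i.i.d.
substitution at rate 0.001 by default (no indels).  DNA-sample reads are
always unspliced.  The truth table records realized multinomial counts, so
estimates are compared to per-draw truth, not asymptotic fractions.

Cryptic isoforms are injected explicitly (`inject_cryptic`): designed 5'
end, 3' end shifted onto a downstream HAG (overridable), at least 10 nt of
3' exon retained — an isoform that splices away the entire 3' exon leaves
nothing to amplify or align and is invisible to any read-based method.

What the generator does **not** emulate: PCR and amplification bias, UMI
duplicates, quality-score structure, indel errors, intron-lariat
intermediates, NMD-coupled abundance effects (copy number and splicing are
drawn independently, so SE–abundance correlations are null readouts here).
Passing tests therefore certify the computational pipeline — decoding,
classification, aggregation, statistics — not any biological claim about
real libraries.

## Alignment (`intronlab.align`)

Pairwise alignment uses Biopython's `PairwiseAligner` (affine gaps; gap of
length n costs open + (n−1)·extend; `N` matches nothing).  Junction scoring
uses match +5 / mismatch −4 / gap open 8 / gap extend 8 — the classic
nucleotide defaults of the Smith–Waterman implementations this assay family
uses — with threshold 0.8 on the self-normalized score.  Junctions
truncated at oligo ends are used at natural length; the self-score
denominator renormalizes them.

The cryptic ("gapped") mode aligns the read **end-to-end** against the full
design under gap open 100 / extend 1.  A purely local alignment under
these costs never bridges a spliced-out intron when one flanking exon is
short (dropping a 17-nt exon is cheaper than a 100+L gap), so the long
uninterrupted gap only appears when the read is consumed entirely — which
our amplicons always permit.  Under this reading the printed call rule is
used literally: normalized score (design self-score denominator) < 0.7 and
mismatches < 6.  The comparison direction and denominator are config
switches (`cryptic_score_cmp`, thresholds in `QuantifyConfig`).

**Coordinate wobble.** When the base before an intron equals its last base,
intervals `(a, b)` and `(a−1, b−1)` excise identical sequences and no read
can distinguish them.  All interval reporting (detection, designed-end
comparison, injected truth keys) therefore uses the 5'-most equivalent
interval (`canonical_gap`).

**Resolution limit.** An alternative 3'SS within ~4 nt of the designed end
is not resolvable by the junction rule: the designed exon–exon junction
still scores > 0.8 on such reads (e.g. a 4-nt gap costs 32, leaving
168/200 = 0.84), so they count as designed spliced.  The simulator's
cryptic injections use offsets ≥ 6 nt accordingly.

## Quantification (`intronlab.quantify`)

Barcode decoding: exact 12-nt prefix lookup, else semi-global edit distance
of each barcode against the read's first 11–13 nt (tolerating one indel
shift); assign iff a unique barcode attains the minimum and it is < 3.
Classification is memoized per unique (variant, sequence) pair after exact
dereplication, so cost scales with unique reads.  SE per (index, repeat) is
isoform count over total variant reads in the group, undetermined reads
included in the denominator (a config switch excludes them); aggregation is
the read-count-weighted mean between repeats within each index, then the
median over indexes with data (even count → mean of the central pair).
Filters exactly as printed: < 10 reads per sample → dropped; DNA-sample
SE > 0.05 (strict) → RNA SE zeroed and flagged; cryptic clusters reported
only at SE > 0.01 (strict); a cryptic cluster at the canonical designed
ends is reassigned to the designed isoform.

Two-intron reads are classified by the five positive/negative junction
rule-sets, checked in the order (both, exon-skipping, intron1, intron2,
unspliced).  The order matters: a doubly-spliced read also satisfies the
single-intron rule-sets, so the stricter patterns must be tested first; no
match → `unclassified`.

## Statistics (`intronlab.stats`, `intronlab.genomes`)

The avoidance test registers intron 3' ends as position 0 (motif anchored
at its first base, negative offsets intronic, strand-resolved), computes
mean motif frequency in the upstream window −32…−3 and downstream window
+1…+30, and compares with control sets of N random coding-region anchors
(same strand orientation, sampled with replacement from the precomputed
per-position window counts): p = fraction of control sets whose window mean
is **below** the introns', in increments of 1/n_controls.  Synthetic
genomes provide the three calibration regimes: null placement (p ~
Uniform), planted depletion (motifs hard-masked in −40…+30; p → 0), and
planted enrichment for profile tests.

Cramer's V uses SE classes [SE = 0], (0, 0.5], (0.5, 1] (configurable
edges), χ² without continuity correction, φC = √(χ²/(n·(k−1))) with k = 3;
empty classes are reduced away and φC is undefined (flagged) when fewer
than two classes remain on either side.  The mock SE–abundance control
draws spliced and unspliced levels i.i.d. log-normal(0, 1): by symmetry
E[SE | total] = 1/2, so the true correlation is exactly zero and the
observed p-values are Uniform — the construction, not a tuned parameter,
guarantees the control behaves.

## Predictive model (`intronlab.features`, `intronlab.model`)

39 features per single-intron variant, frozen in `FEATURE_SCHEMA`:
5 categorical (site sequences, U element, background id) and 34 numeric
(geometry, composition, U/Y-tract content in the 20-nt window upstream of
the 3'SS, Nussinov ΔG proxies and site-pairing fractions in local windows,
HAG-motif context).  The structure engine is a Nussinov maximum
base-pairing DP (Watson–Crick + G:U, minimum hairpin loop 3, score =
−pairs); ViennaRNA's `RNAfold` is pluggable for true MFE but no default or
test depends on it.

LightGBM regression with 50 leaves, learning rate 0.1, feature and bagging
fraction 0.8, bagging frequency 5, ≤ 500 rounds with 5-round early
stopping; 75/25 train/test split (test = round(0.25·N), so N = 12,667 →
3,167) and 5-fold averaging CV: five models, each early-stopped on its
held-out fold, test prediction = their mean.  Shapley values are LightGBM's
exact TreeSHAP (`pred_contrib=True`), averaged over the five fold models
and ranked by mean |value|; local accuracy (attributions + base =
prediction) holds to 1e-6 per fold model.  Confidence intervals are
percentile bootstrap (1000 resamples): over test pairs for the test r, and
over attribution rows for the per-feature mean |Shapley| — resampling
without retraining, which measures attribution stability at fixed models
rather than full training variance.

## Problem sizes and seeds

The bundled analyses and the acceptance script run at desk scale chosen
once for this package: libraries of 200–600 variants, ~2,000 reads per
variant at error 0.001 for recovery checks, 10⁴ control sets (10⁵ is the
method default) and 100–200 replicate genomes for calibration, 100
replicates for the mock control.  One global seed fans out to per-stage
sub-seeds via `numpy.random.SeedSequence.spawn` in a fixed stage order, so
every stage is independently reproducible and reruns are byte-identical.

## Known limitations

* Junction classification cannot resolve alternative 3'SS within ~4 nt of
  the designed end, nor distinguish intron1 from intron2 isoforms of
  self-paired two-intron designs (it abstains).
* Alternative **5'** splice sites are outside the assay's read layout and
  are not modeled.
* The Nussinov proxy counts pairs; it is not a free-energy model (no
  stacking, no loop penalties beyond the minimum hairpin).
* The avoidance test's control anchors are sampled with replacement;
  with candidate pools ≫ N this is indistinguishable from without
  replacement but keeps the resampling fully vectorized.
* `splicing_efficiency` reports per-isoform aggregates; because the median
  across indexes is nonlinear, the sum of aggregated isoform SEs can in
  adversarial configurations exceed 1 even though every per-group SE vector
  sums to ≤ 1; in multinomially sampled data it does not.
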