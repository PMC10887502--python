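# Methods

## Problem and model

A mixed mtDNA sample contains reads from a small number of contributors,
each carrying one mitochondrial haplotype. Haplotypes are organized in a
rooted phylogeny whose branches carry diagnostic SNPs; the cumulative set of
variants on the root-to-node path defines the expected haplotype of each
haplogroup (back-mutation tokens remove the variant at their position, and a
later assignment at a position overrides an earlier one).

Reads are reduced to observations at diagnostic positions only. For fragment
*i* covering position *p* with base *b_ip* and quality *Q*, the error
probability is ε_ip = 10^(−Q/10) (clipped to [1e−6, 0.75]). Under candidate
haplogroup *h*, the expected allele at *p* is the derived allele if *p* lies
on *h*'s cumulative path and the reference base otherwise; the fragment
log-likelihood is Σ_p log(1−ε) for matches and Σ_p log(ε/3) for mismatches —
the standard independent-error read model with uniform error spectrum. Only
substitutions participate; indel variants are parsed and carried through the
tree machinery but leave the reference base in the expectation, because
diagnostic evidence in this pipeline is SNP-based.

The mixture model is p(read i) = Σ_h π_h exp(ℓ_ih) with π on the simplex. EM
starts from the uniform distribution (deterministic by design — results must
be bit-reproducible), iterates the standard E/M steps in log space, asserts
a non-decreasing log-likelihood at every iteration, and stops when
max|Δπ| < 1e−4 (max 500 iterations). Candidates whose likelihood is never
within a factor of 1000 of any fragment's best candidate are pruned before
EM; grafted knowns are never pruned. Candidates with identical expected
alleles across all diagnostic positions are collapsed before fitting
(preferring a known haplotype's label), since EM provably preserves their
initial uniform split and would report a meaningless tie.

## Contributor selection

Selection runs in two phases, refitting EM on the survivors after every
change until stable:

1. **Support filter**: drop candidates with fewer than `min_unique_frags`
   (default 10) fragments whose responsibility exceeds 0.5. This removes
   "passive" candidates that only ride likelihood ties (ancestors, the
   reference-equal root) — such candidates can hold non-trivial π yet never
   dominate a single fragment.
2. **Proportion floor**: drop candidates below `min_prop` (default 0.01,
   chosen because 1–2% minors are the recognized hard regime for this kind
   of data).

Support is filtered first deliberately: evaluating the proportion floor
while phantom candidates still hold tie mass can push a genuine 5% minor to
the floor. If every candidate fails, the top-π candidate is reported with a
low-support warning. Survivors are ranked by π (ties lexicographic) with
renormalized proportions; per-contributor reports list each expected
diagnostic SNP covered by the data with its observed derived-allele
fraction, and the observed subset forms the partial haplotype.

Grafted known haplotypes are held to relaxed floors (`min_prop_known` =
0.001, `min_unique_frags_known` = 3): a known haplotype is an investigator
query whose estimated proportion should be reported even when small. This is
what recovers ~1% trace contributors; spurious-haplogroup resolution needs
no special casing — the known carries the private mutations and wins the
tied reads outright. Observations are rebuilt on the augmented tree when
knowns are grafted, because private mutations become diagnostic for the
grafted leaf.

Heteroplasmy is not modeled explicitly; a minor allele at one position
behaves as low-proportion signal and can, when it coincides with another
clade's diagnostic SNP, produce a spurious low-proportion call — which the
diagnostic-SNP report exposes via its observed fraction.

## Preprocessing

- **Pair correction**: the reverse read is reverse-complemented and the best
  ungapped relative placement of the two mates is found (seeded substring
  search with exhaustive fallback; minimum overlap 20 bases, minimum
  identity 0.75; the offset may be negative, since asymmetric primer
  trimming can leave the reverse mate starting before read 1). With ≤ 2
  disagreements inside the overlap, both mates receive the higher-quality
  base (quality ties keep read 1 — deterministic, and at realistic error
  rates negligible); with more, the pair passes through unchanged and is
  counted, preserving reads for the EM which models error anyway.
- **Primer trimming**: primers (IUPAC-expanded, with reverse complements at
  the opposite terminus) are matched at read termini with ≤ 1 mismatch via
  split-half exact lookup; the longest match per terminus is removed.
  Interior occurrences are never touched.
- **Merging**: mates are merged into one fragment per amplicon molecule;
  within the overlap the higher-quality base wins, agreements keep the
  larger quality.
- **NUMT removal** operates on merged fragments (the truth conditions are
  fragment-level distances): candidates are unclipped fragments mapping to
  the nuclear reference with Levenshtein distance < 3; a candidate is
  removed iff its nuclear distance is strictly smaller than its distance to
  the circularized mitochondrial reference (ties keep the fragment;
  unmapped-to-mito counts as +inf).
- **Built-in aligner**: exact 15-mer seeding with ungapped evaluation and
  edlib verification, circular wrap by modulo-L coordinates (pad logic
  guarantees control-region amplicons align contiguously). A fragment is
  soft-clipped when more than 2 contiguous terminal bases mismatch at the
  best placement. This aligner targets mini references bundled with the
  package; production data can supply external SAM/BAM instead, in which
  case distances are recomputed from the read sequence against the spanned
  reference window rather than trusting aligner tags.

Stage order is correction → trimming → NUMT removal: correction needs raw
mate geometry, trimming changes read termini that the NUMT distance would
otherwise count as mismatch, and filtering last keeps the metrics
interpretable (input = output + removed, per stage).

## Synthetic data

The generator emulates whole-mitogenome multiplex amplicon sequencing:

- a deterministic 16,569-base synthetic circular reference and a
  23-haplogroup mini-tree with three deep clades (L; U/K; J/T/B2 under R)
  and a deliberately shallow H-like clade whose one-SNP branches make
  spurious-call fixtures constructible. Reference bases at diagnostic
  positions are forced to differ from the derived alleles;
- a fixed scheme of 166 overlapping amplicons (stride 100, lengths 157–177,
  mean ≈ 167 bp as in whole-mito amplicon kits) with 20-base primers whose
  binding sites avoid the tree's diagnostic positions — mirroring how
  commercial panels design primers away from known polymorphic sites. Primer
  footprints carry reference alleles (a primer is a synthesized oligo,
  blind to the template), which is exactly the primer-directed error that
  trimming exists to remove; with probability 0.1 per end a one-base primer
  synthesis mismatch is injected;
- paired 150-base reads from both molecule ends with independent per-base
  errors at a constant Phred quality (default Q30; per spec a constant-Q
  profile keeps the ε-model exercised without platform-specific detail);
  heteroplasmy is sampled binomially per molecule, so both mates agree, with
  MAF validated to (0, 0.5];
- NUMT implantation: a 400-base mito-derived segment with an edit every 25
  bases (every read-sized window is ≥ 3 edits from the mitogenome) embedded
  in random nuclear flanks; implanted fragments carry exactly 0–2
  molecule-level substitutions and no additional read error, pinning their
  nuclear distance inside the filter's candidate band;
- mixing by without-replacement subsetting at integer ratios with
  largest-remainder rounding to an exact total, seeded-shuffled interleaving
  so no downstream step can exploit file order, and sole sources generated
  with a ~10% surplus so subsets are genuine draws; random reduction
  recomputes achieved per-source counts from read ids.

What the generator does **not** emulate: platform-specific error spectra and
quality decay, PCR chimeras/amplicon concatenation, indel sequencing errors,
alignment ambiguity from repeats, and real population haplotype diversity
(the mini-tree has 23 nodes, not thousands). Passing validation therefore
demonstrates the correctness of the pipeline's logic and estimator under the
stated noise model — not calibrated performance on a particular instrument
or on the full phylogeny.

## Validation scenarios and problem sizes

The canned panels in `mtdemix.scenarios` pin the study conditions: 20,000
fragments per mixture (~200x mitogenome coverage), two-person mixtures with
minors of 5/10/25/50% for detection and proportion recovery, the six
standard ratios (1:1, 1:3, 3:1; 1:1:1, 1:3:3, 3:3:1) for multi-person
detection, contributor pairs from distinct clades differing at ≥ 5
diagnostic SNPs. The mixture-arithmetic check uses the full 720,000-fragment
two-person construction. Fixtures for the spurious-call and trace-contributor
phenomena use private mutations placed on isolated positions (1018, 16093 —
coinciding with the shallow H-clade branch SNPs — and 8700, 15300).

## Numerical choices and degenerate inputs

- log-space E-step with logsumexp; π floored at 1e−300 before taking logs;
  EM monotonicity asserted with 1e−6 slack.
- ε clipped to [1e−6, 0.75]; N or non-ACGT calls skip the position for that
  fragment; fragments covering no diagnostic position are excluded from N
  and counted as uninformative; zero informative fragments is an error
  ("nothing to deconvolute").
- Equal-π ties in ranking break lexicographically; equal-quality correction
  ties keep read 1; equal nuclear/mito distance keeps the read.
- Circular coordinates are 1-based rCRS-style throughout; wrapping occurs
  only at alignment.
- All randomness flows through numpy Generators seeded from a single user
  seed; derived seeds stay below 2^31.

## Known limitations

- Observation mapping is ungapped after seeding; indel-containing fragments
  rely on the edlib verification step only for acceptance, and a true indel
  over a diagnostic position would be misread (no indel evidence is used).
- The number of contributors is not hypothesis-tested; it emerges from the
  support/proportion filters.
- No likelihood-ratio or weight-of-evidence statistics are produced.
- Proportions for trace contributors recovered via knowns are supported by
  few fragments and are reported with correspondingly few significant
  digits; interpretation belongs to the analyst.
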