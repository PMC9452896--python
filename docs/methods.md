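# Methods

`mirpair` analyses small-RNA sequencing of paired biological
compartments: an engineered human skeletal-muscle tissue ("myobundle",
MB) and the extracellular vesicles (EV) it secretes into culture
medium, under three electrical-stimulation treatments (CTL — no
stimulation, CLFS — chronic low-frequency, IHFS — intermittent
high-frequency). The design is fully crossed: every subject contributes
one MB and one EV sample per treatment, so every MB↔EV comparison can
be paired within subject.

## Quantification

Input is coordinate-level alignments (SAM) of adapter-trimmed reads
whose names carry a UMI (by default the last `_`-delimited token;
overridable by regex), plus a miRBase-style GFF3 of mature miRNAs.
Counting applies three rules:

1. **Multimap cap.** A read is kept only if it maps to at most 13
   genomic locations (`NH` tag; when absent, the per-read-id record
   count). The bound is inclusive: `NH:i:13` is kept, `NH:i:14` dropped.
2. **Seed-anchored assignment.** A kept alignment is assigned to a
   mature miR when strands match, the read's 5′ genomic terminus equals
   the annotated mature 5′ terminus, and the 3′ termini differ by at
   most 2 nt (trimming or extension). Anchoring the 5′ end pins read
   positions 2–8 onto the annotated seed coordinates exactly; it is the
   stricter of the two readings of "seed matching" and reflects the
   biology of miRNA 5′-end homogeneity. The looser reading — the read
   merely covers the seed interval — is available as
   `seed_mode="cover"` but is not the default. Because only one mature
   record can share a 5′ terminus, no fractional assignment is needed.
3. **UMI deduplication.** Molecules are distinct
   (chrom, strand, start, end, UMI) tuples per miR. This is exact-match
   deduplication; directional/edit-distance UMI clustering is a noted
   extension point, not implemented.

Coordinates are 1-based inclusive throughout; 5′/3′ termini swap roles
on the minus strand. The seed is mature positions 2–8 (the canonical
definition).

## Filtering and normalization

Low expressors are removed before any factor computation: a miR is kept
iff its CPM (computed on raw library sizes) reaches 0.5 in at least two
samples. The dropped identifiers are retained — they feed the
preferential-expression stage, where absence in one compartment is
signal, not noise ("informative missingness").

Three normalization strategies are provided:

* **TMM** (default): per sample against an automatically chosen
  reference (upper quartile of scaled counts closest to the mean),
  gene-wise M (log2 ratio of proportions) and A (mean log2 abundance)
  over genes positive in both, doubly trimmed (30% of M and 5% of A
  from each tail, by average ranks), combined by a weighted mean with
  inverse asymptotic-variance weights; factors are rescaled to
  geometric mean 1. The factor multiplies the raw library size.
* **Median-of-ratios** size factors (DESeq-style): the median, over
  genes positive in all samples, of counts divided by the per-gene
  geometric mean; rescaled to geometric mean 1. A size factor absorbs
  depth, so its effective library size is the factor times the
  geometric-mean library size.
* **TPM**: counts divided by annotated mature length, columns rescaled
  to sum 1e6. Mature miRs span a narrow 15–30 nt range, so with equal
  lengths TPM reduces to CPM.

## Differential expression

Counts are modelled per miR as negative binomial with a log link:
`log mu = offset + X beta`, offsets being log effective library sizes.
The design is intercept + subject indicators + group indicator(s); the
subject blocks encode the within-subject pairing. Contrasts are tested
by dropping the group column(s) and comparing deviances.

Dispersion is estimated by Cox–Reid adjusted profile likelihood (APL):
the NB log-likelihood at the per-gene IRLS fit minus half the log
determinant of the weighted information. A common dispersion maximizes
the summed APL over a log-spaced grid on [1e-6, 20] refined by golden
section; per-miR maximizers are then shrunk toward the common value on
the log scale, weighting the per-miR value by its residual df against a
prior weight of 10 (`prior_df`). As `prior_df → ∞` the tagwise values
collapse to the common one.

The quasi-likelihood F-test scales the per-contrast deviance drop by a
moderated quasi-dispersion: per-miR residual deviance over residual df,
squeezed toward the mean quasi-dispersion with the same prior df, and
the p-value comes from F(contrast df, residual df + prior df). This is
a deliberately simplified form of the quasi-likelihood NB framework:
no trended dispersion, no robust weighting, and the squeeze target is
the plain mean rather than an F-moment fit. Exact numerical agreement
with any reference package is a non-goal; the contract is calibration,
verified by simulation (null rejection ≈ 0.05, near-uniform null
p-values, high power at planted log2FC = 2).

p-values are reported unadjusted — the intended use is small-n
discovery profiling — with a Benjamini–Hochberg column available behind
a flag.

**Numerical choices.** IRLS starts from `log max(y, 0.125)`, converges
at relative coefficient change < 1e-8 (cap 50 iterations;
non-converged miRs are excluded from test tables). A relative ridge of
1e-10 on the weighted information keeps miRs with an all-zero group
solvable; linear predictors are clipped to ±30. Deviance drops below
the IRLS noise floor (1e-8 relative) are treated as zero, and the
moderated quasi-dispersion is floored at 1e-6 — both guards only bind
on degenerate (zero-residual) data.

## The dual-normalization contrast plan

`run_all_contrasts` mirrors the study's scheme:

* **Within treatment, between compartments** (MB vs EV in CTL, CLFS,
  IHFS): filtering and TMM on the *joint* matrix of all 18 samples.
* **Between treatments, within compartment** (CLFS vs CTL, IHFS vs CTL,
  IHFS vs CLFS, separately for MB and EV): filtering and TMM *per
  compartment*. An across-all-treatments F-test per compartment is
  optional.

Each contrast subsets its samples, re-estimates dispersion on the
subset and tests the group coefficient. Normalizing MB and EV
separately for treatment contrasts avoids the compartment composition
difference leaking into treatment factors; the joint normalization is
what makes the MB-vs-EV contrast meaningful. The three kept-miR sets
(joint, MB-only, EV-only) are returned for downstream use.

## Paired-compartment analyses

**Correlation.** For each miR (by default those significant in the
corresponding MB-vs-EV contrast) and each treatment, the Pearson
correlation of TMM-normalized counts across subject pairs, with a
two-sided p from `t = r sqrt((n-2)/(1-r^2))` on n−2 df. With n = 3
pairs the test has a single degree of freedom and is fragile — values
are reported but should be read as descriptive. At |r| = 1 the t
statistic diverges; the p-value is reported as the smallest positive
float and the row flagged `boundary` rather than emulating rounded
finite values. Zero-variance vectors yield an explicit `undefined`
flag, never a silent NaN.

**Preferential expression.** A miR is MB-preferential when it passes
the low-expressor filter in the MB-only matrix but not the EV-only one
(and symmetrically) — precisely the expression a joint filter would
discard. Flagged miRs are confirmed on raw counts: a repeated-measures
comparison of compartments across all subject × treatment units (two
within-subject levels, which reduces exactly to a paired t-test on the
9 units and is implemented as such), followed, when p < 0.05, by
paired t-tests within each treatment. Zero-variance differences flag
the test undefined.

**Set overlaps.** Venn regions of 2–4 named DE sets, as exclusive
regions partitioning the union (counts only; no graphics).

## Over-representation analysis

One-sided hypergeometric ORA of a significant-miR set against
user-supplied pathway→miR sets (GMT-like TSV). The universe is the
pre-filtering miR catalogue; pathway sets are intersected with it
before testing. `observed = |hits ∩ pathway|`,
`expected = |hits||pathway|/|universe|`, `p = P(X ≥ observed)`.
Pathways are ranked by observed count (ties by ascending p), matching
the convention of reporting top pathways by hit count; p-values are
unadjusted by default.

## Normalization-method comparison

The same QL engine is run three times on one contrast, differing only
in normalization: TMM factors, median-of-ratios factors, and a TPM arm
in which TPM values are rescaled to each sample's original depth and
rounded to integer pseudo-counts. The rounding trick keeps all three
arms inside one count-based engine at the cost of diverging from
package-level TPM pipelines whose test statistic is a separate choice;
with equal mature lengths the pseudo-counts equal the raw counts, so
the TPM arm isolates the effect of dropping composition correction.
DE-set sizes and Venn overlaps are reported at p < 0.05 and, for the
TPM arm, additionally at p < 0.01.

## Synthetic data

The generator produces every input the pipeline consumes, so all
stages are testable without external downloads.

`simulate_counts` draws NB counts under the study design (default 3
subjects × 2 compartments × 3 treatments, 991 miRs — the size of the
study's pre-filter catalogue). Per-miR baselines are log-normal
(default median 30, log-sd 1.5 — a heavy-tailed abundance profile
typical of miRNA-seq); per-sample depth multipliers are uniform in
`lib_size_range`. Planted truth classes are disjoint: treatment
effects (one random non-CTL treatment × compartment cell each),
compartment effects (MB-vs-EV, random direction, all treatments),
and compartment-exclusive miRs whose other-compartment mean is zeroed
(hard informative missingness; a leaky variant is available). MB–EV
correlation is induced by a shared per-subject log-normal effect:
with biological log-sd `bio_sd` and shared fraction `planted_corr`,
the log-scale MB–EV correlation is `planted_corr`. The default
`bio_sd = 0` makes the NB dispersion parameter the sole
variance source, so dispersion-recovery simulations are interpretable;
planting correlation requires `bio_sd > 0` and is validated as such.
Counts are gamma–Poisson draws from a seeded PCG64 generator; a seed
fully determines the output.

What the generator does **not** emulate: sequence content (coordinates
suffice for the counting rules), isomiR 5′ heterogeneity beyond the
corruption shifts, GC/length biases, and between-subject dispersion
heterogeneity. Passing calibration on these simulations therefore
shows the machinery is correct under the stated model, not that real
libraries satisfy the model.

`simulate_alignments` emits toy SAM + GFF3 text whose reads exercise
every assignment outcome (multimap beyond the cap, 5′ shifts, 3′
variation inside and outside tolerance, strand flips, duplicate UMIs),
bundled with truth counts computed by a separately coded naive
application of the rules — the oracle for exact quantifier tests.

`calibration_experiment` runs type-I, power, fold-change-recovery and
correlation-recovery studies through the real pipeline stages. The
calibration layout is 3 subjects × 2 compartments (6 samples), the
smallest unit of the study design; type-I uses 2000 null miRs at
dispersion 0.1, power uses 500 planted miRs (log2FC = 2, mean count
100, dispersion 0.05). These sizes give Monte-Carlo standard errors
of ~0.5 and ~2 percentage points respectively.

## Known limitations

* Exact-match UMI deduplication overcounts molecules whose UMIs carry
  sequencing errors; clustering-based dedup is an extension point.
* No trended (abundance-dependent) dispersion; the common+tagwise
  scheme can under-shrink at the extremes of the abundance range.
* The DESeq2-style arm of the normalization comparison is
  median-of-ratios size factors feeding the common NB engine, not the
  full VST/Wald machinery.
* Pearson p-values at n = 3 pairs rest on one degree of freedom and
  normality; treat them as descriptive.
* The pipeline consumes alignments; aligner choice and adapter
  trimming are upstream concerns.
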