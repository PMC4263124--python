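# Methods

This note documents the models behind `popomics`, the parameters that
matter, the design choices made where several reasonable options
existed, and what the synthetic-data tests do and do not demonstrate
about real community data.

## Contig signatures and binning

**Signature.** A contig's signature is the vector of canonical
pentanucleotide counts: a 5-mer and its reverse complement are counted
together (the canonical form is the lexicographic minimum of the pair),
giving 4⁵/2 = 512 dimensions — for odd k no k-mer is its own reverse
complement, so the count is exact. Windows containing any non-ACGT
symbol are skipped rather than imputed.

**CLR transform.** Signature counts are compositional; Euclidean
distances on raw proportions are misleading. Counts are therefore
shifted by a pseudocount (default 1, configurable), closed to
proportions, and mapped through the centred log-ratio transform
`clr(p) = log p − mean(log p)`. The pseudocount handles the zeros that
short contigs inevitably have; its exact value has little influence at
the default ≥ 1 kb contig lengths because most of the 512 cells are
populated.

**Embedding.** The CLR matrix is projected to 2-D with Barnes–Hut
t-SNE (perplexity 30, PCA initialisation, 1,000 iterations, fixed seed,
single-threaded for reproducibility). Perplexity 30 requires at least
90 contigs; within-bin refinement passes on small groups therefore use
smaller perplexities or pass the group through unchanged with a logged
warning. t-SNE preserves neighbourhoods, not global geometry, so all
quantitative statements downstream are made on cluster memberships,
never on embedded distances.

**Mixture clustering.** Clustering is EM on a 2-D Gaussian mixture.
Means can be supplied by the user (the interactive workflow, one
component per visually identified cluster) or seeded automatically —
k-means++ for a given K, or a BIC scan over 2..K_max when K is unknown.
Covariances are initialised as σ²I with small positive σ² (default 1)
and floored at 1e-6 on the diagonal to prevent singular components; EM
stops when the relative log-likelihood change drops below 1e-6 or after
500 iterations. The log-likelihood trace is retained and is
non-decreasing — a useful invariant check. Contigs whose maximal
posterior falls below 0.5 are labelled *unbinned* rather than forced
into a bin; the cutoff is configurable.

**Iterative refinement.** A second pass re-profiles each first-round
bin using only its contigs ≥ 1,000 bp (short contigs carry the noisiest
signatures) and splits the bin if a BIC scan prefers more than one
component; sub-1 kb contigs inherit their group's label so the final
labelling covers every contig.

**Coverage splitting.** Two populations with near-identical
oligonucleotide composition can land in one signature bin yet differ
strongly in abundance. A bin is therefore tested for depth bimodality:
1- and 2-component Gaussian mixtures are fitted to log₁₀ per-contig
depth and the bin is split iff (a) BIC(2) + 10 < BIC(1), (b) the
components are bimodally separated — Ashman's
D = |μ₁−μ₂| / √((σ₁²+σ₂²)/2) ≥ 2 — and (c) both mixture weights are at
least 0.05. Guards (b) and (c) matter in practice: contig depth noise
is length-dependent, so single-population log-depths are leptokurtic
and a 2-component fit can beat the 1-component fit on tails alone, or
collapse one component onto a single outlier contig; neither situation
is a population split. Sub-bins are labelled `a` (lower mean depth) and
`b` (higher).

## Population metrics

**Relative population size.** For composite genome *i*,
`N_i = (c_i/l_i) / Σ_j (c_j/l_j)` with c_i its mapped metagenomic reads
and l_i its length. This is the default, dimensionless reading (Σ N_i
= 1); it is the only scale on which the expression threshold below
produces FPKM-magnitude cutoffs. A conventional `rpkm_like` scale
(10⁹·c_i/(C·l_i)) is provided for sensitivity analysis; the two are
proportional within a sample, and every output table records the mode
used.

**Expression calls.** FPKM = count·10⁹/(length·total_mapped), with the
denominator the total metatranscriptomic fragments mapped in the sample
(a global rather than per-bin denominator — the N_i factor in the
threshold already corrects for population size). A gene is *expressed*
iff metaT FPKM ≥ factor × N_i, factor 50 by default; boundary equality
counts as expressed, and raising the factor can only shrink the
expressed set.

**Functional profile, completeness, AAI.** COG category counts per bin
are normalized by the bin's gene total; genes with several categories
collapse to `Multi+I` when lipid metabolism (I) is among them, else
`Multi-I`, and uncategorized genes to `No`. Completeness is the
percentage of a 40-marker universal single-copy gene panel detected at
least once. AAI between two proteomes uses reciprocal best hits under
global alignment (BLOSUM62, gap open −11 / extend −1) and reports
median ± s.d. identity (matches over alignment columns) with the pair
count.

## Variants

Variant identity is the exact (contig, 1-based position, ref, alt)
tuple; multiallelic records are decomposed per ALT allele and non-SNP
alleles skipped with a counter. The consensus is the intersection over
all callers, with per-library depths resolved to the cross-caller
minimum (conservative). The depth filter keeps a variant only when
*both* the metagenomic and metatranscriptomic depths are ≥ 10
(inclusive, per-site). Population-level summaries report SNPs per kb
and that density divided by N_i, which makes densities comparable
between abundant and rare populations. Per-gene counts use inclusive
interval containment; a variant inside two overlapping genes increments
both.

## Proteomics (NSI)

The spectral index of a protein sums the per-spectrum fragment-ion
intensities over all its peptides, so peptide and spectral counts enter
as summation multiplicities. NSI divides by protein length and by the
run's total spectral index, fixing the closure identity
Σ NSI_p·length_p = 1, which every run is tested against. Normalization
is per run. Undetected proteins are *absent*, not zero — detection is
sparse and absence of evidence is not evidence of zero abundance. log₂
NSI (negative, since NSI is a fraction) supports ratio comparisons; no
pseudo-offset is added.

## Ecology

Rarefaction is classical subsampling without replacement
(multivariate hypergeometric draws), 10 replicates of 6,359 reads per
sample by default; replicate totals equal the depth exactly and indices
are reported as mean ± s.d. over replicates. Simpson diversity defaults
to the Gini–Simpson form 1 − Σp² (the dominance Σp² and inverse 1/Σp²
forms are available by flag, and the form in use is written into the
output header). Pielou evenness is (−Σp ln p)/ln S over taxa with
non-zero proportion and is *undefined* (NaN), not 0, for a single-taxon
sample. Spearman correlations use average ranks for ties and are
undefined for constant vectors.

## The synthetic community generator

The generator produces the inputs the analysis consumes, with known
ground truth. What it emulates, and how:

- **Distinct composition per population.** Genomes come from an
  order-2 Markov chain — the minimal order with non-trivial pentamer
  structure. Per step, P(G)+P(C) equals the population's `gc_fraction`
  in every di-nucleotide context, so G+C is controlled exactly; the
  split of the G+C mass between G and C (and A+T between A and T) is
  logistic-skewed per context with scale `signature_bias` (default 1),
  giving each population its own expected pentamer profile.
- **Contigs.** Genomes are tiled into non-overlapping fragments, by
  default log-uniform on [1,000, 20,000] bp (draft-assembly-like sizes;
  terminal remainders merge into the last contig so lengths conserve
  the genome exactly).
- **Counts.** MetaG counts are multinomial with contig probability
  ∝ abundance × length; metaT counts are multinomial over genes with
  weight abundance × level × gamma noise (negative-binomial-like
  overdispersion, dispersion 0.3 by default) for expressed genes and
  exactly 0 otherwise. Library totals are conserved exactly. Transcript
  levels are lognormal (σ = 0.75) plus a floor of 0.25, so a gene that
  is "on" in the ground truth is clearly detectable rather than
  borderline — the regime in which threshold-recovery statements are
  meaningful.
- **Variants.** round(snp_per_kb × genome_length/1000) true SNPs placed
  uniformly without collision; each synthetic caller reports truth
  minus Bernoulli dropouts (2 %) plus uniform false positives (2 %),
  three callers by default, with per-record Poisson depths around
  configurable means (50×).
- **Spectra.** A `proteome_detect_fraction` subset of expressed genes
  receives 1+Poisson peptides × 1+Poisson spectra with positive
  lognormal intensities scaled by transcript level.
- **Default community.** Five populations, 2 Mb genomes, G+C 0.35–0.65,
  abundances (0.40, 0.25, 0.15, 0.12, 0.08), expressed fractions
  (0.45, 0.93, 0.85, 0.90, 0.95) — a dominant generalist against
  high-expression populations — and SNP densities spanning an order of
  magnitude. Library sizes are 2×10⁶ reads each for metaG and metaT:
  large enough that recovery statements are sampling-noise-limited,
  small enough to run in seconds.

All randomness flows from a single root seed through named
`SeedSequence` substreams, so identical specifications reproduce
byte-identical bundles.

**What passing tests do not show.** The generator has no sequencing
errors, no assembly chimerism or strain mosaicism, no shared/horizontal
sequence between populations, no GC-dependent coverage bias, and gene
models never span contig ends. Binning recovery on these conditions
demonstrates the correctness of the implementation chain, not expected
performance on real assemblies, where inter-population signature
overlap and assembly artefacts dominate the error budget.

## Numerical and interface choices

- EM: tolerance 1e-6 (relative log-likelihood), max 500 iterations,
  covariance floor 1e-6; degenerate components raise an error naming
  the component.
- Intervals are 1-based inclusive in GFF3/VCF on disk, converted at the
  I/O boundary.
- TSVs are tab-separated UTF-8 with '.' decimals; each table carries a
  `#` header naming units and the mode/form used (N_i mode, Simpson
  form, rarefaction depth).
- The pipeline writes a resolved-config copy and a manifest with
  SHA-256 digests per output, which is how end-to-end determinism is
  asserted.
- Scales used in the shipped tests (five 2-Mb genomes, ~1,600 contigs,
  2×10⁶-read libraries; smaller two-population communities for variant
  and splitting studies) were chosen so the full suite and the
  acceptance script each complete in well under a minute of compute on
  one core while leaving every recovery statement dominated by model
  behaviour rather than sampling noise.

## Known limitations

- The BH-SNE + mixture chain replaces the interactive,
  visually-initialised clustering a human would perform; the automatic
  K/BIC mode can under- or over-split communities whose populations are
  compositionally close.
- Per-site depth filtering is implemented; windowed "regional" depth
  filtering is not.
- AAI uses exact global alignment of all-vs-all candidates, which is
  quadratic in proteome size — appropriate for the bin-sized proteomes
  it is applied to here, not for large databases.
- The NSI formula follows the published spectral-index construction
  (intensity sum, length and total-signal normalization); other
  normalization orders exist and per-fraction (rather than per-run)
  normalization is not implemented.
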