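# Methods

## Fetal genotype model

Plasma cfDNA at a biallelic SNP is modelled as a two-component mixture:
a maternal component with alt-allele dosage m/2 (m ∈ {0, 1, 2} maternal
alt copies) at weight 1 − f, and a fetal component with dosage k/2 at
weight f, the fetal fraction. A symmetric per-read miscall probability ε
maps the mixture dosage p to the observed alt probability
p′ = p(1 − ε) + (1 − p)ε, and alt counts are Binomial(depth, p′).
The construction assumes read counts are independent given the
genotypes (plain binomial, no overdispersion), that sites are biallelic
(multiallelic records are split upstream), and that the placental
genotype equals the fetal genotype (no mosaicism modelling).

Posteriors over k are computed in log space with log-sum-exp
normalization, so depths up to 10⁵ cannot underflow; ties in the
maximum-posterior call break to the smallest k. The default prior is
uniform over {0, 1, 2}; a Mendelian prior built from the parental
genotypes (transmission probability copies/2 per parent) is available
when both are known. ε defaults to 0.01, a typical short-read
substitution-error scale; at f = 0 the likelihood is flat in k and the
posterior returns the prior, which the caller treats as the
identifiability limit rather than an error.

## Fetal-fraction estimation

The estimator uses sites where the mother is homozygous reference and
the father homozygous alternate: the fetus is then an obligate
heterozygote and the plasma alt-read fraction has expectation
f/2 · (1 − 2ε) + ε. The moment estimate inverts the ε term, doubles the
mean, and clamps to [0, 1]; the standard error follows from the delta
method on the site mean. Restricting to homozygous-alt fathers (rather
than any alt-carrying father) removes the transmission uncertainty of
heterozygous fathers, which would otherwise halve the expected signal
at half the sites and bias the plain 2×-mean formula downward by ~f/4;
an `include_het_fathers` option widens the site set and rescales by the
Mendelian expectation E[k | father] = copies/2 instead. At the default
study conditions (2000 sites, 200× depth, alt frequencies uniform on
0.05–0.95) about 70 sites qualify and the estimator's RMSE is ~0.004,
comfortably inside the ±0.01 recovery target the tests enforce across
f ∈ {0.05, 0.10, 0.20}.

## Fragment tagging and size distributions

At sites where an allele is absent from the maternal genotype
(mother hom-ref or hom-alt), fragments carrying that allele can only be
fetal, up to read error; fragments carrying the maternal-only allele
are labelled maternal (a deliberate simplification: roughly a fraction
f of them are fetal fragments carrying the shared allele, which is why
tag-vs-truth agreement plateaus near 1 − f rather than 1). Size
distributions are normalized histograms on fixed global edges
(50–400 bp in 5 bp bins) so samples are directly comparable; kernel
estimates were rejected to keep distributions exactly reproducible and
summable. Out-of-range lengths clip into the terminal bins. The
per-fragment fetal-origin probability combines the two histograms with
the fetal fraction by Bayes' rule and returns the prior f where both
densities vanish.

## CNV model

Per-bin fragment counts are normalized median-to-median against
presumed-diploid reference control bins
(ratioᵢ = (cᵢ/median c) / (rᵢ/median r)); bins with a zero reference
count are masked. A heterozygous fetal event scales only the fetal
share of the mixture, so the expected ratio is 1 + f(c − 2)/2 for fetal
copy number c ∈ {1, 2, 3} — the three-state space {fetal_del, diploid,
fetal_dup}. Maternal-origin events (ratio shifts of ±0.5) are outside
this space by design; a gross-deviation guard flags |log₂ ratio| > 0.75
for manual review. log₂ ratios are Gaussian with a pooled standard
deviation estimated from the reference controls.

The optional size channel models each bin's fraction of sub-threshold
(< 150 bp) fragments as Gaussian around its state expectation: with S_f
and S_m the short-fragment probabilities of the fetal and maternal
length laws, a state with fetal weight w = f·c/2 expects
((1 − f)S_m + wS_f)/((1 − f) + w). The two channels are independent
given the state and combine additively in log space with weight 1.

Segmentation scans every contiguous run of 3–25 bins per chromosome,
computes the log-likelihood ratio of the best non-diploid state against
diploid, and greedily accepts non-overlapping segments above the
threshold (10 nats by default, ~4.5σ for a single Gaussian channel) in
decreasing-LR order, which is deterministic and exactly testable.
Ratios are floored at 10⁻³ before the log. At f = 0 the states
coincide; the caller warns and returns no calls.

Under the default validation conditions (50 bins, σ = 0.05 diploid /
σ = 0.03 event runs, f = 0.10) the measured false-positive rate is
0/100 seeds and 10-bin-deletion power 100/100 with ≥ 50% reciprocal
overlap. An 800 kb duplication on 100 kb bins needs the deep-coverage
regime targeted panels operate in: at ~8000 fragments per bin the
Poisson log₂ noise is ≈ 0.016, putting the ±f/2 shift at ≈ 4.3σ per bin
and making the event decisive over its 8 bins; the detection scenario
is simulated at that coverage.

## Artifact filters and trio classification

The child-side filters run in a fixed order — allele-fraction band,
blacklist, depth — with removals attributed to the first failing stage;
since each is a pure predicate, the three commute as set intersections
(property-tested). The AF band is literal: AF ≤ 0.20 excluded,
AF ≤ 0.80 kept, AF > 0.80 excluded. The upper cut also removes true
homozygous variants; an `exempt_hom_alt` switch restores them, off by
default to match the band's stated semantics. Blacklist intervals are
BED (0-based half-open), variants are VCF (1-based): interval
[100, 200) removes positions 101–200, and the boundary sentinels are
unit-tested. Classification uses called genotypes only (alt presence =
called copies ≥ 1, raw read evidence is not consulted): proband alt
with mother 0 and father ≥ 1 is paternally inherited, with both
parents 0 de novo, with mother ≥ 1 maternal-or-shared; any required
genotype missing makes the variant unclassifiable.

## Concordance statistics

For one sample and inheritance category, the child/fetus callset
defines the total; variants also present in plasma are common and the
remainder uncommon, with the mean plasma coverage at uncommon sites as
the companion diagnostic. Percentages are rounded half-up to integers,
with one reporting convention: 100% is only printed when the overlap is
complete, so 488/490 (99.6%) reports as 99. The coverage refilter drops
uncommon variants at plasma coverage ≤ threshold (default 5 reads) from
the denominator — the reading under which refiltering is provably
monotone non-decreasing in the percentage, which the tests enforce.
Correlations are squared Pearson coefficients; because the pooling of
published scatter summaries is often ambiguous, the analysis emits the
pooled (both categories), per-category, and coverage-vs-fetal-fraction
pairings side by side.

The bundled validation tables are treated as ground-truth data. Two
internal inconsistencies of those tables surface in the acceptance
suite and are left visible rather than papered over: five of the 72
printed percentage cells follow no deterministic rounding of their own
counts (four print the truncated value, one is arithmetically off by
~2), and the overlap-vs-fetal-fraction r² recomputed from the tables is
0.12–0.17 under every documented pooling, far from the published
0.0167 — while the coverage-vs-fetal-fraction pairing gives 0.061,
suggesting the published figure may pair coverage, not overlap, with
fetal fraction. Both pairings are reported.

## Synthetic cohort generator

The generator is the package's test substrate and mirrors the model's
assumptions deliberately: parents drawn from Hardy-Weinberg at
per-site alt frequencies (uniform 0.05–0.95 by default), Mendelian
transmission, de novo injection at 10⁻³ per site restricted to
sites where neither parent carries the alt (so labels are unambiguous),
Poisson(200) plasma depth and binomial alt counts from the same
error-adjusted mixture the caller inverts, Gaussian fragment lengths
(fetal mode 143 bp, maternal 166 bp, sd 20 — conventional cfDNA
values), Poisson per-bin fragment counts with the fetal rate scaled by
c/2 inside injected events, and diploid control samples for the
reference. Defaults (2000 sites, 50 × 100 kb bins, 500 fragments/bin,
f = 0.10 with the 0.05–0.20 range swept in tests) keep any single
cohort under a few seconds. All randomness flows from one seeded
generator in a fixed draw order, so cohorts are byte-reproducible.

Because generator and model share the mixture formula, passing tests
demonstrate internal consistency and correct inference under the
stated model — not robustness to what real cfDNA adds: GC and
mappability bias (a correction hook exists in normalization but the
generator produces unbiased counts), overdispersed counts, placental
mosaicism, maternal CNVs, multi-nucleotide variants, and alignment
artifacts are all outside the simulation.

## Numerical and interface choices

Positions are 1-based in VCF-derived tables, 0-based half-open in
BED/bin tables; conversions are boundary-tested. Floats print with 6
significant digits in TSV outputs. Posteriors normalize in log space;
percentages round half-up; the CNV scan floors ratios at 10⁻³; filter
boundaries are closed/open exactly as documented. The scikit-learn
estimator shape was chosen for the model components so they compose
with pipelines and grid search; stage functions remain the primary API
for scripting, and the CLI is a thin layer over them.
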