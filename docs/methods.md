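# Methods

## Assay model

The assay quantifies the fraction of Alu elements whose internal HpaII/MspI
site (C^CGG, embedded in the Alu consensus context AACC^CGG) is unmethylated.
Two parallel digestions are modelled: MspI cuts every CCGG; HpaII cuts only
where the site's internal CpG is unmethylated. Methylation of either strand's
cytosine is treated as blocking HpaII; modification of the outer cytosine
(CpA context) is ignored. Adaptor ligation is implicit: every cut end is
assumed ligated with probability 1, since no ligation-efficiency term enters
the quantification.

A product is predicted at a cut site when all of the following hold:

1. the site lies in AACCCGG context (on either strand) inside an annotated
   Alu element;
2. the chosen enzyme cuts the site under the supplied methylation state;
3. the Alu primer matches the element sequence on the side of the cut it
   points toward, within `max_mismatches` (default 1) and with an exact
   3'-terminal clamp (default 5 nt) — N bases never match;
4. the product length, genomic span plus adaptor, lies within
   [`amplicon_min`, `amplicon_max`] (default 40–200 bp, ordinary qPCR
   feasibility bounds).

One product is emitted per (site, orientation, element), at the valid primer
placement closest to the cut; emitting every placement would double-count a
single molecular species. The set of elements owning at least one product
under MspI with everything unmethylated is the maximal amplifiable set (the
QUAluome). For a methylation state, the expected PUMA ground truth is
100 × (HpaII-amplifiable products) / (MspI-amplifiable products).

Coordinates are 0-based half-open everywhere; RepeatMasker `.out` rows
(1-based inclusive) are converted on load and each annotation row counts as
one element — fragmented elements are not merged. The AACCCGG anchor is
scanned on both strands by default (a reverse-strand anchor appears as
CCGGGTT on the forward strand); single-strand counting is available via
`scan_motif(..., both_strands=False)` and `qualu census --strands one`,
since double-stranded DNA is what the enzymes see but published per-strand
hit counts may use either convention.

## Census conventions

A CpG, CCGG or AACCCGG occurrence is attributed to a class (Alu, LINE, CpG
island) when its interval shares at least one base with at least one feature
of the class, mirroring independent per-class interval intersections.
Classes are deliberately not exclusive: an occurrence inside an Alu that sits
in a CpG island counts in both rows. CpG is strand-symmetric and counted
once, on the forward strand. CCGG is palindromic and counted once per
position. N runs match nothing and contribute no CpGs. FLAM/FRAM free
monomers are excluded from the Alu element count by case-insensitive
rep-name prefix.

## Quantification

PUMA is the efficiency-corrected ratio of ratios

PUMA = [E_AluH^(−Cq_AluH) / E_L1H^(−Cq_L1H)] /
[E_AluM^(−Cq_AluM) / E_L1M^(−Cq_L1M)] × 100.

The L1PA normalizer must not contain a CCGG site, otherwise its copy number
would depend on the digestion and the normalization would not cancel; schemes
violating this produce a warning. Efficiencies are fitted per assay from
dilution series (E = 10^(−1/slope), with r² reported and warnings below
0.98 or outside [1.6, 2.1]); when no standards are available a global default
of E = 2 is used with a logged notice.

Estimates above 105% are reported raw with a warning, never clamped:
an inflated ratio flags assay failure and clamping would hide it. A missing
Cq yields an undetermined (NaN) result carrying a `not_detected` flag.

Uncertainty is propagated by bootstrap over technical replicates: each of
`n_resamples` (default 1000) draws picks one Cq per assay uniformly with
replacement and recomputes PUMA; the reported estimate and SD are the mean
and SD of that distribution, which converge to the exhaustive enumeration
over all replicate combinations. The seed is mandatory. Replicate outliers
are never dropped by default; `drop_replicate_outliers` (>1 cycle from the
assay median) is available but opt-in, so data are not silently altered.
Permutation-style resampling of amplification-model residuals is a
recognised alternative; bootstrap over replicates was chosen because it
requires no access to raw fluorescence data and is fully reproducible.

Hypomethylation is called when PUMA strictly exceeds the cutoff (default
12%). The cutoff helper takes the empirical 99th percentile of normal-tissue
values using linear interpolation (numpy's default, type-7), requiring at
least 10 values; the convention is fixed so a published cutoff can be
reproduced exactly.

## Biomarker statistics

Tumors are fixed as the positive, higher-PUMA class. AUC is computed from
the Mann-Whitney rank statistic with mid-ranks for ties, which equals the
trapezoidal area under the empirical ROC curve (both routes are implemented
and cross-checked). The operating cutoff maximizes Youden's J; ties are
broken toward higher specificity; the reported threshold is the midpoint
between the two observed values bracketing the optimum. Two-group
comparisons use Mann-Whitney U (exact when both groups have ≤8 values and no
ties), paired comparisons the Wilcoxon signed-rank test, and >2 groups
Kruskal-Wallis.

## Synthetic data

The mini-genome generator plants non-overlapping elements on a random
background (40% GC): copies of a bundled 288 bp AluY-like consensus carrying
one AACCCGG anchor and the default primer site; 600 bp LINE-1-like copies of
a CCGG-free synthetic sequence (so the normalizer is digestion-independent
by construction); and 400 bp CpG-rich islands (~66% GC). Each Alu copy gets
an i.i.d. per-base substitution rate drawn from `alu_divergence_range`
(default U(0, 0.2), spanning young-to-old subfamily divergence) and a
subfamily label by band (<5% AluYsim, <15% AluSsim, else AluJsim). Under the
default range roughly 15–25% of planted copies remain amplifiable, with
young bands strongly over-represented — the same age bias the assay shows on
a real genome. Placement draws random gaps partitioning the free space, so
any density below 100% packs. Substitution is the only mutation process (no
indels); this suffices to create motif/primer loss with age while keeping
the amplicon geometry fixed, but it means real-world indel-driven length
variation and truncated elements are not represented, and amplifiable
fractions on real genomes will differ.

Methylation states are i.i.d. Bernoulli per CCGG site with a given
unmethylated probability. Cq values follow
Cq = intercept − log_E(template count) + N(0, noise_sd) per replicate, with
defaults E = 2, intercepts 34 (Alu assays) and 31 (L1 assays), noise 0.15
cycles and triplicate wells — typical bench values. A zero template count
produces a non-detected well. With zero noise and matched H/M intercepts the
round trip simulate → quantify returns the planted fraction exactly.

## Validation experiment sizes

The end-to-end recovery experiment uses a 100 kb mini-genome with 200
planted Alus and 50 simulated samples per planted fraction
(2, 6, 12 and 40% unmethylated). For this experiment the Alu divergence is
drawn from U(0, 0.02) — young copies — so that ~180 of 200 elements are
amplifiable: the real assay integrates over ~10^5 sites, and a scaled-down
genome must keep enough reporters that binomial sampling noise stays below
the Cq noise being tested. Non-detected samples (possible at the 2% fraction,
where the expected HpaII template count is ~4) are excluded from medians, as
they would be in reporting practice. Census oracle checks run the same
quadratic brute-force interval scans as the unit tests on 100 kb genomes,
where exact equality is asserted cell by cell.

## Limitations

- Primer thermodynamics (melting temperature, dimers, PCR plateau and bias)
  are out of scope; matching is purely sequence-based.
- The bundled primer scheme is a reasonable default built from the bundled
  consensus; reproducing a specific published assay requires supplying that
  assay's primer and adaptor sequences via a scheme file.
- The whole-genome-scale census numbers (millions of Alu elements, ~10^5
  amplifiable sites) require a real genome FASTA plus RepeatMasker
  annotations; the synthetic tests validate the machinery, not those counts.
- Site-vs-element concordance uses an absolute beta difference (default
  0.25) between the anchor CpG and the mean of the element's other covered
  CpGs (≥3 required); other concordance definitions are possible and the
  delta is a parameter, so sensitivity analysis across delta is recommended
  on real bisulfite tracks.
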