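# Methods

## Segregation model

Oocytes carry 19 autosomes plus one X (the Y enters only with a male
pronucleus at fertilisation). Each chromosome is tracked as dyads (two
sister chromatids under cohesion) and free single chromatids, the two
currencies that matter for DNA mass and hence for read share.

Per chromosome, independently:

1. **Prophase/metaphase I.** A crossover-linked bivalent forms with
   probability `p_bivalent`; otherwise the pair is two univalents, each of
   which undergoes premature sister separation (PSSC) with probability
   `p_pssc`. `p_bivalent = 1` models a recombination-proficient control;
   `p_bivalent = 0` a fully achiasmate oocyte in which every chromosome is
   a univalent pair.
2. **Anaphase I.** A bivalent partitions reductionally: one dyad to the
   egg, one to the first polar body. An intact univalent goes whole to a
   uniformly random pole. A separated univalent's two chromatids segregate
   independently, each to a random pole. Conservation: egg + PB1 always
   hold 4 chromatid units per chromosome.
3. **Anaphase II and fertilisation.** Every maternal dyad splits 1 + 1
   between zygote and second polar body, except with probability
   `p_mii_ndj` both sisters nondisjoin to one product (either, with equal
   probability). Maternal singles partition uniformly. The sperm adds one
   chromatid per autosome plus one X or Y (equal probability).
   Conservation: maternal zygote + PB2 units equal the egg's complement.

Assumptions and simplifications: univalents retain sister cohesion unless
PSSC fires; chromosomes behave independently (no interchromosomal effect);
anaphase is always bipolar — tripolar spindles, polar-body extrusion
failure and congression timing are imaging phenomenology outside the
model's scope; the first polar body is simulated (it anchors the MI
conservation law) but not sequenced by default, since the reciprocity
argument concerns the MII partition and therefore the second polar body.
All draws come from a single seeded generator threaded through every stage,
so cohorts are bit-reproducible.

## Read-count model

A sample's expected read share per chromosome is proportional to
`length_bp × chromatid_units` — sequencing measures DNA mass, so a retained
single chromatid produces a graded (half-step) copy-number signal. Counts
are multinomial at fixed depth (default 200,000 mapped reads, the design
point of the assay being emulated). Amplification noise is modelled as
Dirichlet-multinomial overdispersion with a single knob `rho` in [0, 1):
the Dirichlet concentration is `alpha_0 = ((1-rho)/rho) ·
((1-p_min)/p_min)`, calibrated to the sample's smallest nonzero expected
proportion `p_min`, so the most weakly represented chromosome has relative
proportion standard deviation `sqrt(rho/(1-rho))` (≈ 4.5% at the default
`rho = 0.002`) and every better-represented chromosome less. `rho = 0` is
pure multinomial. This keeps per-chromosome coefficients of variation a few
percent — well clear of the 20% call threshold — while inflating count
variance roughly eightfold over multinomial at defaults, i.e. plainly
detectable overdispersion. Mappability and GC bias are not modelled; the
empirical reference absorbs any fixed per-chromosome bias by construction.

What the generator does **not** emulate about real libraries: segmental
events, amplification dropout and chimera artefacts, mappability structure
within chromosomes, and batch effects between runs. Passing tests
demonstrate the correctness of the procedure on whole-chromosome dosage
signals, not robustness to those artefacts.

## Copy-number procedure

Reference proportions are per-chromosome means over karyotypically normal
samples, kept per sex (`sex_matched`, default) or averaged across sexes
(`pooled`). The pooled mode is provided for completeness but is biased on
sex chromosomes (a half-male pool puts the female X ratio at ≈ 4/3 before
doubling); autosomal calls agree between modes. Samples of unknown sex are
sexed by Y read share: male iff the sample's Y proportion is at least half
the male reference's. Copy number is the proportion ratio doubled for
autosomes and the female X, and taken raw for male X/Y; the female Y has
zero reference proportion and is reported absent. Copy numbers are kept
unrounded; calls threshold the relative deviation from baseline (2, or 1
for male X/Y) at `delta_rel = 0.2`, chosen so single-chromatid imbalances
(CN 2.5 / 1.5, deviation 0.25) are called while sampling noise (CV ≈ 1–5%)
is not. Complexity classes: euploid (0 aneuploid chromosomes), simple
(1–2), complex (≥ 3).

Polar bodies are haploid, but the statistic uses only relative proportions:
a euploid polar body (one chromatid per autosome and per X) has exactly the
female reference pattern, so polar bodies are analysed against the female
reference with the standard baselines and no special casing.

## Reciprocity

Relations per chromosome of a matched pair (Y excluded — polar bodies carry
none): *reciprocal* when one call is a gain and the other a loss,
*concordant* when both deviate the same way, *unmatched* when only one
deviates, *neutral* otherwise. The reciprocity fraction is computed over
chromosomes aneuploid in the polar body — the fraction whose zygote call is
opposite — and is left undefined (never divided) when the polar body is
fully euploid. Strict sign opposition is required, not magnitude matching:
magnitudes are half-integer valued and noisy. Cohort summaries report the
fraction of complex zygotes, the mean defined reciprocity fraction,
per-chromosome aneuploidy frequencies and a chi-square uniformity statistic
across autosomes; the statistic is reported, not turned into a decision.

## Numerical choices and degenerate inputs

- Proportions sum to 1 within 1e-12; an all-zero karyotype, empty
  reference, zero depth or an out-of-range probability is rejected at
  construction with a named error.
- Counts on zero-proportion chromosomes are exactly zero, and totals equal
  the requested depth exactly (no rounding drift).
- Call thresholds are inclusive (`deviation ≥ delta_rel` calls), making
  behaviour at exact boundaries deterministic.
- Gain/loss calls are invariant to uniform scaling of counts and
  monotone in `delta_rel`.
- Input chromosome names are normalised (`chr1` → `1`, `chrM` → `MT`);
  lengths are cross-checked against the genome model within 1%; duplicate
  rows and negative counts are parse errors naming the line.
- Output files carry version/seed/config-hash headers and no timestamps,
  so identical runs are byte-identical.

## Known limitations

The statistic is a *relative* measure: proportions are renormalised within
each sample, so a heavily skewed karyotype shifts the effective baseline of
its unaffected chromosomes. Quantitatively, a chromosome with `u` chromatid
units in a sample whose length-weighted mean dosage is `S` reads
`CN = 2u/S`; once enough imbalance accumulates (e.g. dyad losses of the
three largest chromosomes, or five same-direction nondisjunctions), normal
chromosomes drift past the 20% threshold and are miscalled. Exact recovery
of integer dosage is therefore guaranteed only for modest aneuploidy loads
(the test suite demonstrates it for up to three single-chromatid
imbalances), and per-chromosome calls in chaotic samples are best read
through the complexity class, which is robust. This is a property of any
proportion-normalised low-coverage method, not of this implementation.

Problem sizes used by the test and acceptance suites — cohorts of 9–200
oocytes, 1,000–20,000 replicate simulations, reference sets of 10 + 10 —
were chosen to pin each stochastic check to ~3 standard errors while
keeping any run to seconds on a single core.
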