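# zygocall

Whole-chromosome aneuploidy analysis for **low-coverage single-cell
sequencing of zygotes and their matched polar bodies**, together with a
chromatid-resolution simulator of meiotic chromosome segregation in
**crossover-deficient mouse oocytes**.

When meiotic recombination fails, homologous chromosomes persist as unpaired
univalents at metaphase I. Univalents segregate at random and frequently
undergo premature sister-chromatid separation (PSSC), so the resulting eggs
carry chaotic mixtures of whole chromosomes and single chromatids. Because
the second polar body receives exactly the chromatids the egg does not keep
at anaphase II, an error that enriches the zygote for a chromosome should
deplete the matched polar body — a *reciprocal* aneuploidy. `zygocall`
implements the read-count analysis that detects these events, and a
generative model that reproduces them in silico, so the whole pipeline is
testable without any sequencing data.

## The copy-number statistic

For sample *s* with per-chromosome mapped-read counts \(n_c\), the read
proportion is \(p_c = n_c / \sum_j n_j\). Against a reference set of
karyotypically normal samples with mean proportions \(\bar r_c\) (kept
per sex, or pooled), the predicted copy number is

```
CN_c = 2 · p_c / r̄_c      autosomes (both sexes) and the female X
CN_c =     p_c / r̄_c      male X and Y (single-copy in euploid cells)
```

so a euploid chromosome reads CN = 2 (CN = 1 for male X/Y). Expected
proportions scale with chromosome length × chromatid content, which makes a
single retained chromatid a graded, detectable signal. A chromosome is
called a **gain** when CN/baseline − 1 ≥ δ and a **loss** when
1 − CN/baseline ≥ δ (default δ = 0.2); a sample with ≥ 3 aneuploid
chromosomes is **complex**, 1–2 **simple**, 0 **euploid**. Polar bodies are
haploid but self-normalising: they are analysed identically against the
female reference.

The simulator draws, per chromosome: bivalent formation with probability
`p_bivalent`, PSSC per univalent with probability `p_pssc`, and anaphase-II
nondisjunction per dyad with probability `p_mii_ndj`; `(1, 0, 0)` is a
control oocyte, `(0, 0.5, 0)` an achiasmate mutant. Counts are multinomial
at ~200,000 reads per sample with optional Dirichlet overdispersion.

## Worked example

```
$ zygocall demo --seed 7 --out demo
control: 9 pairs | zygotes euploid 1.00 | zygotes complex 0.00 | mean reciprocity n/a
mutant: 20 pairs | zygotes euploid 0.00 | zygotes complex 1.00 | mean reciprocity 0.18889900948724478
```

The control cohort (all bivalents) yields 9/9 zygotes and polar bodies
called euploid, so the mean reciprocity fraction is undefined (`n/a` — no
aneuploid polar-body chromosomes exist to be reciprocated). Every
crossover-deficient zygote is complex-aneuploid, and among chromosomes
aneuploid in a mutant polar body, ~19% show the strictly opposite call in
the matched zygote under the default mutant parameters. Each cohort
directory contains the idxstats-style count tables, the manifest, the
reference profile, a per-chromosome `calls.tsv`, and a `pair_report/` with
the pair relations, a heatmap-ready CN-deviation matrix and a JSON summary.

The same analysis runs stepwise on real or simulated count tables:

```
zygocall simulate --n 10 --p-bivalent 0 --p-pssc 0.5 --seed 3 --out run
zygocall build-ref --manifest run/manifest.tsv --out run/ref.tsv
zygocall call --manifest run/manifest.tsv --ref run/ref.tsv --out run/calls.tsv
zygocall pair-report --manifest run/manifest.tsv --calls run/calls.tsv --out run/report
```

Input count tables follow the samtools-idxstats dialect (chrom, length,
mapped, unmapped); `chr`-prefixed names are normalised automatically.

## Layout

- `zygocall.meiosim` — genome model; prophase, MI, MII + fertilisation.
- `zygocall.readsim` — expected read proportions and count simulation.
- `zygocall.cnvcall` — reference building, sexing, copy number, calls.
- `zygocall.pairs` — pair reciprocity and cohort summaries.
- `zygocall.io` / `zygocall.cli` — file formats, configuration, CLI.

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
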