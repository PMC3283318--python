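# utrlen

Which genomic composition features determine the length of a 5'
untranslated region?  `utrlen` is a reusable pipeline for asking that
question of any per-species set of 5'UTR sequences: it computes
per-sequence composition features, cleans the data, fits a multiple linear
regression of log-length on the features, and decomposes the explained
variance into per-feature importances.  A synthetic-data module generates
5'UTR sets with known planted structure, so the whole pipeline is testable
without downloading anything.

## The model

For each 5'UTR of length *L* with per-sequence base fractions
*f*<sub>A</sub>, *f*<sub>C</sub>, *f*<sub>G</sub>, *f*<sub>U</sub>, the
observed-to-expected (OE) ratio of a motif *m* = *b*<sub>1</sub>…*b*<sub>k</sub> is

    OE(m) = observed(m) / (L · f_b1 · … · f_bk)

with overlapping occurrences counted and OE defined as 0 when a required
base is absent.  Values near 1 are compatible with chance; depletion
(OE < 1) of a deleterious motif suggests selection.  The regression is

    Y = β0 + β1·X1 + … + βp·Xp + ε

where *Y* is log10 *L* and the candidate predictors are G+C content, the
OE ratios of the start trinucleotide AUG and of the stop trinucleotides
UGA, UAA, UAG (together the raw material of upstream ORFs), and the OE
ratios of the CG, UG, UU, UA dinucleotides (methylation, CG-mutation and
mRNA-stability proxies).  A 0/1 upstream-ORF presence flag is available as
a tenth covariate.

Around the fit the pipeline provides:

* a **zero-OE filter** — UTRs with more than one zero among the four
  trinucleotide OE ratios are removed as uninformative (short sequences
  cannot display selection on motifs they are not even expected to
  contain once; the companion *minimal length* statistic
  1/(*f*<sub>b1</sub>·…·*f*<sub>b3</sub>) makes this threshold explicit);
* **backward elimination** of predictors by largest t-test p-value at a
  configurable α (default 0.05);
* **VIF** collinearity screening (flagging VIF > 10);
* **partial correlations** between log-length and each retained predictor,
  controlling for the others;
* **RCVE**, the relative contribution to variability explained:
  (R²_full − R²_reduced)/R²_full when one predictor is dropped.

## Worked example

Analyse a synthetic "species" of 3,000 genes in which longer 5'UTRs were
planted to follow G+C content (β = +1.5) and suppression of the UGA/UAG
stop trinucleotides (β = −0.15 and −0.20):

```python
from utrlen import RunConfig, SyntheticSpec, run_pipeline

spec = SyntheticSpec(
    n_genes=3000,
    motif_modifiers={"UGA": (0.4, 1.6), "UAG": (0.4, 1.6)},
    planted_beta={"gc": 1.5, "UGA": -0.15, "UAG": -0.20},
    seed=42,
)
summary = run_pipeline(RunConfig(synthetic=spec, seed=42))
```

which prints/returns (abridged):

```
n featurized: 3000   retained after zero-OE filter: 2261
selected: ['gc', 'oe_aug', 'oe_uga', 'oe_uaa', 'oe_uag', 'oe_uu', 'oe_ua']
adjusted R2: 0.411
coefficients: {'intercept': 1.691, 'gc': 1.604, 'oe_aug': -0.075,
               'oe_uga': -0.079, 'oe_uaa': -0.032, 'oe_uag': -0.083,
               'oe_uu': 0.046, 'oe_ua': -0.053}
RCVE top 3: gc 0.74, oe_uga 0.061, oe_uag 0.054
max VIF: 1.9
```

Reading the output: about a quarter of the UTRs were dropped by the
zero-OE rule (they are too short to carry trinucleotide information); the
planted G+C effect is recovered with the right sign and magnitude
(coefficients on measured OE features are attenuated relative to the
planted generative factors — see `docs/methods.md`); no collinearity is
flagged; and RCVE correctly identifies G+C as the dominant determinant
followed by the two suppressed stop trinucleotides.  The same analysis
runs on a real FASTA file via `RunConfig(fasta=...)` or the CLI:

```sh
utrlen simulate --n-genes 3000 --seed 42 --out utrs.fasta
utrlen run --fasta utrs.fasta --outdir results/
```

`run` writes the feature table, the filter report, coefficient /
partial-correlation tables (with `ns` entries for eliminated predictors),
VIF and RCVE tables, and a `summary.json` that fully reproduces the run.

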