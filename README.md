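# ousiometrics

Tools for measuring the *essence of meaning* carried by words and texts.

Large crowd-sourced affect lexicons score every word on three survey
dimensions — valence (**Va**), arousal (**Ar**), and dominance (**Dm**) —
but the three VAD axes turn out to be strongly intercorrelated
(r<sub>Va,Ar</sub> ≈ −0.27, r<sub>Ar,Dm</sub> ≈ 0.30, r<sub>Va,Dm</sub> ≈ 0.49),
so VAD is not the orthogonal frame it is assumed to be. This package
re-derives orthogonal frames directly from the data and provides the
instruments to work with them:

- **Frameworks.** Center the N×3 score matrix A (subtract the best-worst
  design mean of ½ from each dimension) and take its SVD, A = UΣVᵀ. The
  right-singular directions, sign-fixed and ordered by singular value,
  define the **goodness–aggression–structure (GAS)** basis; rotating the
  primary Gd–Ag plane clockwise by −π/4 gives **power–danger–structure
  (PDS)**: Pw = (Gd+Ag)/√2, Dg = (Ag−Gd)/√2. Together the primary-plane
  axes form the **GPADS** circumplex.
- **Ousiograms.** Annotated weighted 2D histograms of any two dimensions
  (bin width 1/30 on [−1,1]²), with marginals, weighted medians, the
  plane's SVD ellipse, convex-hull boundary word labels, and internal
  labels along the eight cardinal/intercardinal rays.
- **Corpus statistics.** Frequency-rank distributions are restricted to
  the scored lexicon (the *lexical lens*) and summarized by
  probability-weighted means, medians, and skewness — the statistics
  behind the token-level **safety bias**, the skew of danger scores
  toward safe words seen across large corpora.
- **Ousiometer.** A windowed instrument scoring a text's sliding 1-gram
  windows (default 10,000-token windows stepping by 100) by the
  probability-weighted mean M<sub>avg</sub> = Σ<sub>τ</sub> p<sub>τ</sub> M<sub>τ</sub>,
  yielding per-dimension time series and a power–danger trajectory over
  equal narrative epochs.

A seeded synthetic-lexicon generator (trivariate Gaussian with the
reference correlation structure, ~20,000 terms) makes the entire
pipeline runnable and testable without any external data.

## Worked example

```sh
ousio synth --n-terms 20000 --seed 1 -o lexicon.tsv \
    --corpus-out corpus.tsv --corpus-tokens 500000
ousio derive -l lexicon.tsv -o derived
```

prints (synthetic lexicon, so values vary slightly with the seed):

```
terms: 20000
VAD pairwise correlations:
        Va      Ar      Dm
Va  1.0000 -0.2777  0.4917
Ar -0.2777  1.0000  0.2887
Dm  0.4917  0.2887  1.0000
singular values: (29.8, 23.6, 12.0)
explained variances (%): 55.8, 35.1, 9.1
GAS basis rows (Va, Ar, Dm weights):
  Gd: +0.86  -0.16  +0.48
  Ag: -0.15  +0.82  +0.55
  St: +0.49  +0.54  -0.68
PDS basis rows (Va, Ar, Dm weights):
  Pw: +0.50  +0.47  +0.73
  Dg: -0.72  +0.70  +0.05
  St: +0.49  +0.54  -0.68
```

The correlation matrix shows the built-in VAD non-orthogonality; the
first two SVD dimensions explain ~91% of variance, and the basis rows
give each new dimension's weights on (Va, Ar, Dm). Token-weighted
statistics through the lexical lens:

```sh
ousio corpus-stats -l lexicon.tsv -f PDS --freq corpus.tsv -o bias.json
# Pw: mean=+0.0073 median=+0.0070 skew=-0.396
# Dg: mean=+0.0185 median=+0.0313 skew=-0.239
# St: mean=+0.0040 median=+0.0084 skew=+0.200
```

Other subcommands: `ousio score` (term score tables in any framework),
`ousio ousiogram` (figure + machine-readable sidecar JSON), and
`ousio meter` (time series + trajectory CSVs for a plain-text file).
Everything is also importable as a library (`import ousiometrics`).

Analyses that require the reference ~20k-term crowd-sourced VAD lexicon
(it is not redistributable here) run once the TSV is placed at
`data/NRC-VAD-Lexicon.txt`.

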