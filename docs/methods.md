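# Methods

## Model and procedure

The package operates on term-scored affect lexicons: each term carries
three best-worst-scaling scores — valence (Va), arousal (Ar), dominance
(Dm) — in [0, 1]. Because best-worst scaling is symmetric by design, its
population mean on every dimension is exactly ½; centering therefore
subtracts the constant 0.5, never the empirical column mean. This
matters: the derived bases reproduce the published two-decimal weight
matrices only under the design-mean convention, and it keeps centering
an exact affine map (raw = centered + ½ to machine precision).

Framework derivation is plain SVD of the centered N×3 matrix A = UΣVᵀ.
The rows of Vᵀ, ordered by descending singular value, are the
uncorrelated axes of the score cloud. SVD leaves each axis's sign free,
so signs are pinned by a fixed convention — the goodness weight on Va
positive, the aggression weight on Ar positive, the structure weight on
Dm negative — which makes derivation deterministic and idempotent (the
convention is recorded in every exported basis). The power–danger frame
is the −π/4 rotation of the primary plane:

    Pw = (Gd + Ag)/√2,    Dg = (Ag − Gd)/√2,    St unchanged.

Because the GAS coordinates are uncorrelated over the deriving data with
variances σ₁² ≥ σ₂², the rotation redistributes the primary plane's
variance evenly — each rotated axis carries (σ₁²+σ₂²)/2 — and
reintroduces a correlation (σ₂²−σ₁²)/(σ₁²+σ₂²) between power and danger
(≈ −0.22 at the reference variance shares 55.6/35.3). Both facts are
closed forms and are tested against the matrix pipeline.

Frameworks are always derived at the type level (each term weighted
equally). Token frequencies enter only downstream — in weighted
correlations, histograms, bias summaries, and the meter — never in the
SVD. The SVD core accepts any entities×dimensions matrix (only the
3-dimension case gets the named GAS/PDS treatment).

## Token-level statistics

A frequency distribution maps terms to nonnegative weights. Sub-corpora
(years, days) merge with equal weight by normalizing each to
probabilities before averaging — the only reading under which unequal-
sized sub-corpora contribute equally. The lexical lens keeps only terms
with scores, preserving weights and reporting type and token coverage;
coverage below 0.25 warns but never errors. The core statistic is the
probability-weighted mean Σ p_τ M_τ.

Numerical conventions, chosen where the procedure is underdetermined:

- **Weighted median**: the smallest score whose cumulative probability
  reaches ½ (lower convention, no interpolation) — deterministic on
  discrete atoms and identical to the order-statistic median under
  uniform weights. A 1e−9 slack absorbs floating accumulation at an
  exact-half boundary. The convention is recorded in every BiasSummary.
- **Weighted skewness**: probability-weighted g₁ = m₃/m₂^{3/2}; NaN for
  a zero-variance dimension.
- **Tie-averaged ranks**: rank 1 is most frequent; tied frequencies
  share the arithmetic mean of the ranks they span (scipy's
  `rankdata(method="average")`), so ranks always sum to N(N+1)/2.
- **Undefined correlations** (zero-variance dimension, e.g. all weight
  on one term) are reported as NaN, never coerced to zero.

## Ousiograms

Histograms use half-open bins [lo, hi) with the final bin closed, index
floor((v−lo)/w), default width 1/30 on a fixed [−1,1]² extent; values
exactly at the upper edge stay in the last bin, values outside the
extent are clipped inward and counted. Mass is conserved exactly and
marginals are row/column sums by construction.

The plane ellipse is centered on the (weighted) mean with axes from the
principal directions of the weighted covariance and radii equal to the
standard deviations along them (a one-σ contour; the scaling is a
rendering choice and is recorded in the ellipse metadata).

Boundary annotation computes the convex hull of occupied-*bin centers*
(not raw points), cuts the perimeter into arcs of roughly the requested
spacing starting at the first hull vertex, takes the outward normal of
the hull edge under each arc midpoint, and greedily assigns the unused
term with the largest scalar projection onto that normal (an alternative
nearest-to-midpoint mode is available). Internal annotation places
evenly spaced targets on the eight rays k·π/4 between an origin-
exclusion radius (default 0.1) and each ray's data extent, assigning the
nearest unused term. No term is ever used twice across both sets, and
annotation is deterministic given identical inputs. Defaults — spacing
0.15 plot units, 4 targets per ray — are this package's choices for
legible figures; both are tunable. Rendering writes a sidecar JSON
carrying every plotted element so that checks never parse pixels.

## The ousiometer

The tokenizer (version 1, frozen) splits text into maximal runs of word
characters and apostrophes plus single punctuation characters, and
case-folds all tokens; narrative time counts every token. Multi-word
lexicon entries cannot match a single 1-gram and are thus ignored by the
meter. Windows start at token 1 and advance by s; window k is plotted at
its center W/2 + (k−1)s, giving floor((T−W)/s)+1 points. A window with
no matched tokens is a missing value (NaN) — zero is a meaningful score,
never a stand-in. Per-window coverage is the matched fraction. With
non-overlapping windows the coverage-weighted mean of window values
telescopes exactly to the whole-text average (prefix-sum
implementation, O(T) per dimension). Defaults W = 10,000 and s = 100
with 10 trajectory epochs are the instrument's standard smoothing.
Epochs partition the window sequence into contiguous blocks whose sizes
differ by at most one.

## Synthetic data

The generator draws n terms from a zero-mean trivariate Gaussian with a
target correlation matrix and per-dimension standard deviations, then
clips to [−½, ½]. Defaults emulate the reference lexicon's conditions:
20,000 terms and correlations (r_VaAr, r_ArDm, r_VaDm) =
(−0.27, 0.30, 0.49). Standard deviations default to (0.19, 0.15, 0.15):
the generator validates that >99% of draws fall inside the bounds
(capping sd at 0.5/2.576 ≈ 0.194), so the defaults sit just under that
cap while mirroring the real ordering of dispersions (valence widest);
clipping then touches <1% of draws and distorts correlations
negligibly, which is why clipping is preferred over rejection
resampling. The synthetic corpus generator emits multinomial token
counts over a 1/rank^α Zipf law (α = 1 by default) and reports its own
emitted-token total for bookkeeping checks.

What the synthetic data does *not* emulate: real lexicons are not
Gaussian (they are platykurtic with asymmetric tails, which is exactly
what the safety-bias medians measure), contain n-grams, and have
heavy-tailed usage unevenly correlated with meaning. Passing tests on
synthetic data therefore validate the machinery — centering, SVD
recovery, rotation algebra, weighting, windowing — not empirical claims
about English; reproduction of the published lexicon-dependent numbers
additionally requires the reference ~20k-term VAD lexicon placed at
`data/NRC-VAD-Lexicon.txt` (it is not redistributable with the
package).

## Degenerate inputs and tie-breaks

A zero singular value flags the basis degenerate but still returns it.
Duplicate lexicon terms keep the first occurrence; terms are
NFC-normalized, matched byte-exactly, with internal single spaces of
n-grams preserved (case handling belongs to the tokenizer, not the
lexicon). Ties in greedy annotation fall to the earlier term in score
order (stable, seedless). Single-point histograms carry a degenerate
zero-radius ellipse. Fewer candidate terms than annotation targets
annotates as many as possible.

## Problem sizes

Default test and acceptance runs use synthetic lexicons of 20,000 terms
(50,000 where a tighter Monte-Carlo tolerance is asserted), annotation
clouds of a few hundred points, and texts of order 10⁴ tokens — sizes at
which the Monte-Carlo tolerances quoted in the tests (Fisher-z 3σ for
correlations, 0.02 entry error for basis recovery) hold with margin
while the whole suite stays fast.
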