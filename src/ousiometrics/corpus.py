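"""Token-level corpus machinery: frequency distributions and bias statistics.

Lexicon analysis treats every word equally (types); real language use
weights words by frequency (tokens). This module ingests frequency-rank
files (term<TAB>count), merges sub-corpora with equal weight (each
year's or day's distribution normalized to probabilities before
averaging, so unequal-sized sub-corpora still contribute equally),
restricts a distribution to the scored lexicon ("lexical lens"), and
computes probability-weighted means, medians and skewness per framework
dimension -- the statistics behind the linguistic safety bias, the
token-level skew of danger scores toward the safe side.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ContractError, InputError
from .frameworks import ScoreMatrix
from .lexicon import CenteredLexicon

#: Token-coverage fraction below which lensing warns (never errors).
MIN_TOKEN_COVERAGE = 0.25


@dataclass
class FrequencyDistribution:
    """Nonnegative weight per term (raw counts or merged probabilities)."""

    weights: dict[str, float]
    n_subcorpora: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ContractError("weights must be nonnegative")

    @property
    def total(self) -> float:
        return float(sum(self.weights.values()))

    def probabilities(self) -> dict[str, float]:
        total = self.total
        if total <= 0:
            raise ContractError("cannot normalize a zero-total distribution")
        return {t: w / total for t, w in self.weights.items()}

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class CoverageReport:
    """How much of a distribution survived the lexical lens."""

    tokens_total: float
    tokens_matched: float
    types_total: int
    types_matched: int

    @property
    def token_coverage(self) -> float:
        return self.tokens_matched / self.tokens_total if self.tokens_total > 0 else 0.0

    @property
    def type_coverage(self) -> float:
        return self.types_matched / self.types_total if self.types_total > 0 else 0.0

    def to_dict(self) -> dict:
        return {
            "tokens_total": self.tokens_total,
            "tokens_matched": self.tokens_matched,
            "types_total": self.types_total,
            "types_matched": self.types_matched,
            "token_coverage": self.token_coverage,
            "type_coverage": self.type_coverage,
        }


def read_frequency_tsv(path: str | Path, label: str = "") -> FrequencyDistribution:
    """Read a term<TAB>count file; duplicate terms have counts summed.

    Rows with negative or non-numeric counts are rejected and counted; a
    file yielding no valid rows is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"frequency file not found: {path}")
    weights: dict[str, float] = {}
    rejected = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                rejected += 1
                continue
            term = fields[0]
            try:
                count = float(fields[1])
            except ValueError:
                rejected += 1
                continue
            if not np.isfinite(count) or count < 0:
                rejected += 1
                continue
            weights[term] = weights.get(term, 0.0) + count
    if not weights:
        raise InputError(f"no valid rows in frequency file: {path} ({rejected} rejected)")
    return FrequencyDistribution(weights=weights, n_subcorpora=1, label=label or path.stem)


def merge_equal_weight(dists: Sequence[FrequencyDistribution]) -> FrequencyDistribution:
    """Average sub-corpus distributions with equal weight.

    Each input is first normalized to probabilities, then the k
    probability vectors are averaged with weight 1/k; the merged total
    is exactly 1 regardless of sub-corpus sizes.
    """
    if len(dists) == 0:
        raise ContractError("need at least one distribution to merge")
    k = len(dists)
    merged: dict[str, float] = {}
    for dist in dists:
        if dist.total <= 0:
            raise InputError(f"sub-corpus {dist.label!r} has zero total weight")
        for term, p in dist.probabilities().items():
            merged[term] = merged.get(term, 0.0) + p / k
    label = "+".join(d.label for d in dists if d.label)
    return FrequencyDistribution(weights=merged, n_subcorpora=k, label=label)


def rank_with_tie_averaging(dist: FrequencyDistribution) -> dict[str, float]:
    """Frequency ranks, 1 = most frequent, ties sharing averaged ranks."""
    if dist.total <= 0:
        raise ContractError("cannot rank a zero-total distribution")
    terms = list(dist.weights)
    counts = np.array([dist.weights[t] for t in terms])
    ranks = rankdata(-counts, method="average")
    return {t: float(r) for t, r in zip(terms, ranks)}


def lexical_lens(
    dist: FrequencyDistribution, lex: CenteredLexicon | ScoreMatrix | frozenset
) -> tuple[FrequencyDistribution, CoverageReport]:
    """Restrict a distribution to terms present in the scored lexicon.

    Weights of surviving terms are preserved; everything else is dropped
    but counted in the coverage report. An empty intersection is valid
    output (coverage 0) -- downstream statistics refuse it. Token
    coverage below MIN_TOKEN_COVERAGE draws a warning.
    """
    if isinstance(lex, CenteredLexicon):
        term_set = lex.term_set
    elif isinstance(lex, ScoreMatrix):
        term_set = frozenset(lex.terms)
    else:
        term_set = frozenset(lex)
    kept = {t: w for t, w in dist.weights.items() if t in term_set}
    report = CoverageReport(
        tokens_total=dist.total,
        tokens_matched=float(sum(kept.values())),
        types_total=len(dist.weights),
        types_matched=len(kept),
    )
    if 0 < report.token_coverage < MIN_TOKEN_COVERAGE or (
        report.tokens_total > 0 and report.tokens_matched == 0
    ):
        warnings.warn(
            f"lexical lens kept only {report.token_coverage:.1%} of tokens "
            f"({report.types_matched}/{report.types_total} types)",
            stacklevel=2,
        )
    lensed = FrequencyDistribution(
        weights=kept, n_subcorpora=dist.n_subcorpora, label=dist.label
    )
    return lensed, report


def _aligned(dist: FrequencyDistribution, scores: ScoreMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(probabilities, row indices) for the distribution's terms."""
    if dist.total <= 0:
        raise ContractError("distribution has zero total weight")
    index = {t: i for i, t in enumerate(scores.terms)}
    missing = [t for t in dist.weights if t not in index]
    if missing:
        raise ContractError(
            f"{len(missing)} terms lack scores (e.g. {missing[0]!r}); "
            "apply lexical_lens first"
        )
    terms = list(dist.weights)
    p = np.array([dist.weights[t] for t in terms])
    p = p / p.sum()
    rows = np.array([index[t] for t in terms])
    return p, rows


def ousiometric_average(
    dist: FrequencyDistribution, scores: ScoreMatrix, dimension: str
) -> float:
    """Probability-weighted mean score of one dimension.

    This is the ousiometer's core statistic: with normalized frequencies
    p_tau, the average meaning is sum_tau p_tau * M_tau. Invariant under
    positive rescaling of all weights.
    """
    p, rows = _aligned(dist, scores)
    return float(p @ scores.column(dimension)[rows])


def weighted_median(values: np.ndarray, probs: np.ndarray) -> float:
    """Smallest value whose cumulative probability reaches 1/2.

    Lower-interpolation convention on discrete atoms: deterministic, and
    identical to the order-statistic median under uniform weights.
    """
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(probs[order])
    cum /= cum[-1]
    # 1e-9 slack absorbs accumulation error at an exact-half boundary
    i = int(np.searchsorted(cum, 0.5 - 1e-9, side="left"))
    return float(values[order][min(i, len(values) - 1)])


@dataclass
class BiasSummary:
    """Weighted mean / median / skewness per framework dimension."""

    framework: str
    dims: tuple[str, ...]
    means: dict[str, float]
    medians: dict[str, float]
    skewnesses: dict[str, float]
    median_convention: str = "lower (first cumulative probability >= 1/2)"
    coverage: CoverageReport | None = None

    def to_dict(self) -> dict:
        doc = {
            "framework": self.framework,
            "dims": list(self.dims),
            "means": self.means,
            "medians": self.medians,
            "skewnesses": self.skewnesses,
            "median_convention": self.median_convention,
        }
        if self.coverage is not None:
            doc["coverage"] = self.coverage.to_dict()
        return doc

    def to_json(self, path: str | Path) -> None:
        try:
            Path(path).write_text(
                json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8"
            )
        except OSError as exc:
            raise InputError(f"cannot write bias summary to {path}: {exc}") from exc


def bias_summary(
    dist: FrequencyDistribution | None,
    scores: ScoreMatrix,
    coverage: CoverageReport | None = None,
) -> BiasSummary:
    """Per-dimension weighted mean, median, and skewness.

    Passing ``dist=None`` uses uniform weights (type-level summary).
    Skewness is the probability-weighted g1 = m3 / m2^{3/2}; a
    zero-variance dimension has undefined skewness (NaN).
    """
    if dist is None:
        dist = FrequencyDistribution(
            weights={t: 1.0 for t in scores.terms}, label="uniform"
        )
    p, rows = _aligned(dist, scores)
    means, medians, skews = {}, {}, {}
    for dim in scores.dims:
        x = scores.column(dim)[rows]
        m = float(p @ x)
        xc = x - m
        m2 = float(p @ xc**2)
        m3 = float(p @ xc**3)
        means[dim] = m
        medians[dim] = weighted_median(x, p)
        skews[dim] = m3 / m2**1.5 if m2 > 0 else float("nan")
    return BiasSummary(
        framework=scores.framework,
        dims=scores.dims,
        means=means,
        medians=medians,
        skewnesses=skews,
        coverage=coverage,
    )


def read_frequency_directory(directory: str | Path) -> FrequencyDistribution:
    """Merge every ``*.tsv`` in a directory as equally weighted sub-corpora."""
    directory = Path(directory)
    if not directory.is_dir():
        raise InputError(f"not a directory: {directory}")
    files = sorted(directory.glob("*.tsv"))
    if not files:
        raise InputError(f"no .tsv files in {directory}")
    return merge_equal_weight([read_frequency_tsv(f) for f in files])
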