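"""Term-scored affect lexicons: reading, centering, synthesis, writing.

A VAD lexicon assigns every term three best-worst-scaling scores --
valence (Va), arousal (Ar), and dominance (Dm) -- each in [0, 1]. Because
best-worst scaling is symmetric, the design mean of every dimension is
exactly 1/2, so centering subtracts 1/2 (never the empirical column mean)
and moves scores onto the [-1/2, 1/2] scale on which all downstream
factor analysis operates.

The synthetic generator draws terms from a zero-mean trivariate Gaussian
with a configurable correlation structure, emulating the size and the
pairwise correlations of a real crowd-sourced lexicon so that the whole
pipeline is testable without any external data.
"""

from __future__ import annotations

import itertools
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError, InputError, ValidationError

VAD_DIMS = ("Va", "Ar", "Dm")

#: Largest per-dimension standard deviation for which >99% of Gaussian
#: draws land inside [-1/2, 1/2] (0.5 / z_{0.995}).
MAX_SYNTHETIC_SD = 0.5 / 2.5758293035489004


@dataclass
class ParseReport:
    """Bookkeeping from a lexicon read: what was kept and what was not."""

    rows_read: int = 0
    rows_rejected: int = 0
    reasons: Counter = field(default_factory=Counter)

    def reject(self, reason: str) -> None:
        self.rows_rejected += 1
        self.reasons[reason] += 1


@dataclass
class RawLexicon:
    """Terms with (Va, Ar, Dm) scores on the survey scale [0, 1].

    ``scores`` is a DataFrame indexed by term with columns Va/Ar/Dm, rows
    in file order. The index carries no duplicates.
    """

    scores: pd.DataFrame
    report: ParseReport = field(default_factory=ParseReport)

    def __post_init__(self) -> None:
        if len(self.scores) < 1:
            raise ValidationError("lexicon must contain at least one entry")
        if self.scores.index.has_duplicates:
            raise ValidationError("duplicate terms in lexicon")
        vals = self.scores[list(VAD_DIMS)].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite score in lexicon")
        if vals.min() < 0.0 or vals.max() > 1.0:
            raise ValidationError("raw scores must lie in [0, 1]")

    @property
    def terms(self) -> list[str]:
        return list(self.scores.index)

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class CenteredLexicon:
    """Terms with scores on the centered [-1/2, 1/2] scale."""

    scores: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.scores) < 1:
            raise ValidationError("lexicon must contain at least one entry")
        vals = self.scores.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite score in centered lexicon")
        if vals.min() < -0.5 - 1e-12 or vals.max() > 0.5 + 1e-12:
            raise ValidationError("centered scores must lie in [-1/2, 1/2]")

    @property
    def terms(self) -> list[str]:
        return list(self.scores.index)

    @property
    def term_set(self) -> frozenset[str]:
        return frozenset(self.scores.index)

    def __len__(self) -> int:
        return len(self.scores)


# Default correlation structure of the reference crowd-sourced lexicon:
# r(Va,Ar) = -0.27, r(Ar,Dm) = 0.30, r(Va,Dm) = 0.49.
DEFAULT_CORRELATIONS = np.array(
    [
        [1.00, -0.27, 0.49],
        [-0.27, 1.00, 0.30],
        [0.49, 0.30, 1.00],
    ]
)


@dataclass
class SyntheticLexiconSpec:
    """Recipe for a synthetic centered lexicon.

    Defaults emulate the reference lexicon: ~20,000 terms with the
    pairwise correlations above. Standard deviations mirror the real
    ordering (valence most dispersed) while keeping >99% of Gaussian
    draws inside [-1/2, 1/2] so that boundary clipping is negligible.
    """

    n_terms: int = 20_000
    target_correlations: np.ndarray = field(
        default_factory=lambda: DEFAULT_CORRELATIONS.copy()
    )
    standard_deviations: tuple[float, ...] = (0.19, 0.15, 0.15)
    seed: int = 0

    def validate(self) -> None:
        if self.n_terms < 1:
            raise ValidationError("n_terms must be positive")
        corr = np.asarray(self.target_correlations, dtype=float)
        if corr.shape != (3, 3):
            raise ValidationError("correlation matrix must be 3x3")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValidationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValidationError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValidationError("correlation matrix is not positive semidefinite")
        sds = np.asarray(self.standard_deviations, dtype=float)
        if sds.shape != (3,) or (sds <= 0).any():
            raise ValidationError("need 3 positive standard deviations")
        if (sds > MAX_SYNTHETIC_SD + 1e-12).any():
            raise ValidationError(
                f"standard deviations must be <= {MAX_SYNTHETIC_SD:.4f} so that "
                ">99% of draws fall inside [-1/2, 1/2]"
            )

    def covariance(self) -> np.ndarray:
        sds = np.asarray(self.standard_deviations, dtype=float)
        return np.asarray(self.target_correlations, float) * np.outer(sds, sds)


@dataclass
class Dialect:
    """Column layout of a lexicon TSV.

    ``columns`` names each tab-separated field; it must contain "term"
    and the three dimension names. ``header`` controls the first line:
    True (skip it), False (data from line one), or "auto" (skip a first
    line whose score fields do not parse as numbers).
    """

    columns: tuple[str, ...] = ("term", "Va", "Ar", "Dm")
    header: bool | str = "auto"

    def indices(self) -> tuple[int, int, int, int]:
        try:
            return tuple(self.columns.index(c) for c in ("term",) + VAD_DIMS)
        except ValueError as exc:
            raise ValidationError(f"dialect must name term/Va/Ar/Dm columns: {exc}")


def read_vad_lexicon(path: str | Path, dialect: Dialect | None = None) -> RawLexicon:
    """Read a tab-separated VAD lexicon, validating row by row.

    Invalid rows (too few fields, non-numeric or out-of-range scores,
    duplicate terms) are rejected and counted in the parse report rather
    than aborting the read; the read is fatal only if no valid row
    remains. Terms are NFC-normalized and matched byte-exactly -- no
    case folding or stemming happens at this layer. Internal single
    spaces in n-gram terms are preserved.
    """
    dialect = dialect or Dialect()
    i_term, i_va, i_ar, i_dm = dialect.indices()
    path = Path(path)
    if not path.exists():
        raise InputError(f"lexicon file not found: {path}")

    report = ParseReport()
    terms: list[str] = []
    rows: list[tuple[float, float, float]] = []
    seen: set[str] = set()

    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    start = 0
    if lines and dialect.header is True:
        start = 1
    elif lines and dialect.header == "auto":
        fields = lines[0].split("\t")
        try:
            [float(fields[i]) for i in (i_va, i_ar, i_dm)]
        except (ValueError, IndexError):
            start = 1

    for line in lines[start:]:
        if not line.strip():
            continue
        report.rows_read += 1
        fields = line.split("\t")
        if len(fields) <= max(i_term, i_va, i_ar, i_dm):
            report.reject("too_few_fields")
            continue
        term = unicodedata.normalize("NFC", fields[i_term].strip())
        if not term:
            report.reject("empty_term")
            continue
        try:
            scores = tuple(float(fields[i]) for i in (i_va, i_ar, i_dm))
        except ValueError:
            report.reject("non_numeric_score")
            continue
        if not all(np.isfinite(s) and 0.0 <= s <= 1.0 for s in scores):
            report.reject("score_out_of_range")
            continue
        if term in seen:
            report.reject("duplicate_term")  # keep-first policy
            continue
        seen.add(term)
        terms.append(term)
        rows.append(scores)

    if not rows:
        raise InputError(f"no valid rows in lexicon file: {path}")
    frame = pd.DataFrame(rows, index=pd.Index(terms, name="term"), columns=list(VAD_DIMS))
    return RawLexicon(scores=frame, report=report)


def center_scores(lex: RawLexicon, provenance: str = "") -> CenteredLexicon:
    """Shift scores from [0, 1] to [-1/2, 1/2] by subtracting exactly 1/2.

    Best-worst scaling has a design mean of one half, so the shift is the
    constant 0.5 in every dimension -- not the empirical column mean.
    """
    return CenteredLexicon(scores=lex.scores - 0.5, provenance=provenance)


def _term_names(n: int) -> list[str]:
    """Deterministic pronounceable-ish distinct term strings w0, w1, ..."""
    return [f"w{i:06d}" for i in range(n)]


def generate_synthetic_lexicon(spec: SyntheticLexiconSpec) -> CenteredLexicon:
    """Draw a centered lexicon from the spec's trivariate Gaussian.

    Draws are clipped (not resampled) to [-1/2, 1/2]; with the default
    standard deviations fewer than 1% of draws touch the boundary, so
    the distortion of the correlation structure is negligible. Identical
    spec (including seed) yields identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    draws = rng.multivariate_normal(
        mean=np.zeros(3), cov=spec.covariance(), size=spec.n_terms,
        method="cholesky" if _is_pd(spec) else "eigh",
    )
    np.clip(draws, -0.5, 0.5, out=draws)
    frame = pd.DataFrame(
        draws,
        index=pd.Index(_term_names(spec.n_terms), name="term"),
        columns=list(VAD_DIMS),
    )
    return CenteredLexicon(scores=frame, provenance=f"synthetic(seed={spec.seed})")


def _is_pd(spec: SyntheticLexiconSpec) -> bool:
    return np.linalg.eigvalsh(np.asarray(spec.target_correlations, float)).min() > 1e-10


def write_scores(scores: CenteredLexicon | pd.DataFrame, path: str | Path) -> None:
    """Write a term/score table as UTF-8 TSV with 6-decimal fixed point.

    Accepts either a lexicon or any term-indexed score DataFrame (e.g.
    PDS scores with columns Pw/Dg/St). A header row names the dimensions.
    An empty table yields a header-only file.
    """
    frame = scores.scores if isinstance(scores, CenteredLexicon) else scores
    path = Path(path)
    try:
        frame.to_csv(path, sep="\t", float_format="%.6f", encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot write scores to {path}: {exc}") from exc


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_scores`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"score table not found: {path}")
    return pd.read_csv(path, sep="\t", index_col="term", encoding="utf-8")


def zipf_corpus_weights(
    n_types: int,
    n_tokens: int,
    terms: list[str] | None = None,
    exponent: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, int], int]:
    """Sample a synthetic corpus with frequency roughly proportional to 1/rank.

    Draws ``n_tokens`` tokens from a discrete power-law over ``n_types``
    types (probability of rank k proportional to k**-exponent) and
    returns (term -> count, tokens emitted). The token total is returned
    so that readers of the serialized corpus can be checked against the
    generator's own bookkeeping.
    """
    if n_types < 1 or n_tokens < 1:
        raise ContractError("need at least one type and one token")
    if terms is None:
        terms = _term_names(n_types)
    elif len(terms) != n_types:
        raise ContractError("terms list length must equal n_types")
    rng = np.random.default_rng(seed)
    probs = np.arange(1, n_types + 1, dtype=float) ** -exponent
    probs /= probs.sum()
    counts = rng.multinomial(n_tokens, probs)
    weights = {t: int(c) for t, c in zip(terms, counts) if c > 0}
    return weights, n_tokens
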