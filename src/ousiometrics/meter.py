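"""The ousiometer: windowed essential-meaning time series for texts.

A text is read as an ordered stream of 1-grams (narrative time T counts
every token -- words, numbers, punctuation). Sliding windows of W tokens
advancing by s tokens are each scored by the probability-weighted mean
of the lensed tokens' framework scores; pairing two dimensions (power
and danger by default) over equal narrative epochs gives the text's
trajectory through the meaning plane. Defaults follow the instrument's
standard smoothing: W = 10,000 1-grams, s = 100, 10 epochs.

Tokenizer rules (version 1, deliberately simple and frozen for
reproducibility): the text is split into maximal runs of word characters
and apostrophes, plus single punctuation characters as their own tokens;
all tokens are case-folded. Multi-word lexicon entries never match a
single 1-gram and are therefore ignored by the meter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError, InputError
from .frameworks import ScoreMatrix

TOKENIZER_VERSION = 1
DEFAULT_WINDOW = 10_000
DEFAULT_STEP = 100
DEFAULT_EPOCHS = 10

_TOKEN_RE = re.compile(r"[\w']+|[^\w\s]")


@dataclass
class TokenStream:
    """An ordered list of 1-grams; narrative time is the token index."""

    tokens: list[str]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.tokens) < 1:
            raise ContractError("token stream must contain at least one token")

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize_1grams(text: str, label: str = "") -> TokenStream:
    """Split text into case-folded 1-grams, punctuation as own tokens.

    All tokens are retained in the stream -- narrative time counts
    everything -- whether or not they carry a lexicon score. The rules
    are stable (versioned) so that runs are reproducible.
    """
    if not text or not text.strip():
        raise InputError("cannot tokenize empty or whitespace-only text")
    tokens = [t.casefold() for t in _TOKEN_RE.findall(text)]
    return TokenStream(tokens=tokens, label=label)


@dataclass
class OusioTimeSeries:
    """Per-dimension windowed averages over a token stream."""

    window_size: int
    step: int
    centers: np.ndarray  # narrative-time abscissa of each window
    series: dict[str, np.ndarray]  # dim -> values (NaN where no coverage)
    coverage: np.ndarray  # matched-token fraction per window
    framework: str = ""
    label: str = ""

    @property
    def n_points(self) -> int:
        return len(self.centers)

    @property
    def dims(self) -> tuple[str, ...]:
        return tuple(self.series)


def n_windows(t_total: int, window: int, step: int) -> int:
    """Number of full windows: floor((T - W)/s) + 1 for T >= W, else 0."""
    if t_total < window:
        return 0
    return (t_total - window) // step + 1


def windowed_scores(
    stream: TokenStream,
    scores: ScoreMatrix,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    dims: tuple[str, ...] | None = None,
) -> OusioTimeSeries:
    """Score sliding windows through the lexical lens.

    Window k (k = 1, 2, ...) covers tokens [1 + (k-1)s, W + (k-1)s] of
    narrative time and is plotted at its center W/2 + (k-1)s. Within a
    window, the matched tokens form a frequency distribution whose
    probability-weighted mean score is the window's value for each
    dimension; a window with zero matched tokens yields NaN (a missing
    value, never zero). Per-window coverage is the matched fraction.
    """
    if window < 1 or step < 1:
        raise ContractError("window and step must be >= 1")
    t_total = len(stream)
    if t_total < window:
        raise ContractError(
            f"text has {t_total} 1-grams but the window is {window}; "
            "lower the window size to at most the text length"
        )
    dims = tuple(dims) if dims is not None else scores.dims
    index = {t: i for i, t in enumerate(scores.terms)}
    rows = np.array([index.get(tok, -1) for tok in stream.tokens], dtype=int)
    matched = rows >= 0

    # prefix sums over narrative time -> O(T) per dimension
    cum_match = np.concatenate([[0], np.cumsum(matched)])
    k = n_windows(t_total, window, step)
    starts = np.arange(k) * step
    ends = starts + window
    m = cum_match[ends] - cum_match[starts]

    series: dict[str, np.ndarray] = {}
    for dim in dims:
        col = scores.column(dim)
        vals = np.where(matched, col[np.clip(rows, 0, None)], 0.0)
        cum_val = np.concatenate([[0.0], np.cumsum(vals)])
        sums = cum_val[ends] - cum_val[starts]
        with np.errstate(invalid="ignore", divide="ignore"):
            series[dim] = np.where(m > 0, sums / np.maximum(m, 1), np.nan)

    centers = window / 2.0 + starts
    return OusioTimeSeries(
        window_size=window,
        step=step,
        centers=centers.astype(float),
        series=series,
        coverage=m / float(window),
        framework=scores.framework,
        label=stream.label,
    )


@dataclass
class Trajectory:
    """Paired-dimension path through the meaning plane, in epochs."""

    dim_pair: tuple[str, str]
    centers: np.ndarray
    x: np.ndarray
    y: np.ndarray
    epochs: np.ndarray  # 0-based epoch label per window
    n_epochs: int

    @property
    def n_points(self) -> int:
        return len(self.centers)


def build_trajectory(
    series: OusioTimeSeries,
    dim_pair: tuple[str, str] = ("Pw", "Dg"),
    n_epochs: int = DEFAULT_EPOCHS,
) -> Trajectory:
    """Pair two dimensions and partition narrative time into equal epochs.

    Epochs partition the window sequence into n contiguous blocks whose
    sizes differ by at most one; the label of a window is the block
    containing it.
    """
    for dim in dim_pair:
        if dim not in series.series:
            raise ContractError(f"dimension {dim!r} missing from the series")
    n = series.n_points
    if n < n_epochs:
        raise ContractError(
            f"{n} windows cannot fill {n_epochs} epochs; reduce the epoch "
            "count or the window/step sizes"
        )
    epochs = (np.arange(n) * n_epochs) // n
    return Trajectory(
        dim_pair=(dim_pair[0], dim_pair[1]),
        centers=series.centers.copy(),
        x=series.series[dim_pair[0]].copy(),
        y=series.series[dim_pair[1]].copy(),
        epochs=epochs,
        n_epochs=n_epochs,
    )


def _series_frame(obj: OusioTimeSeries | Trajectory) -> pd.DataFrame:
    if isinstance(obj, OusioTimeSeries):
        data = {"center": obj.centers}
        data.update({dim: obj.series[dim] for dim in obj.series})
        data["coverage"] = obj.coverage
        return pd.DataFrame(data)
    return pd.DataFrame(
        {
            "center": obj.centers,
            obj.dim_pair[0]: obj.x,
            obj.dim_pair[1]: obj.y,
            "epoch": obj.epochs,
        }
    )


def export_series(obj: OusioTimeSeries | Trajectory, path: str | Path) -> None:
    """Write a series or trajectory as CSV (6 decimals, NaN as empty)."""
    frame = _series_frame(obj)
    try:
        frame.to_csv(path, index=False, float_format="%.6f", na_rep="")
    except OSError as exc:
        raise InputError(f"cannot write series to {path}: {exc}") from exc


def read_series(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`export_series` (empty -> NaN)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"series file not found: {path}")
    return pd.read_csv(path)
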