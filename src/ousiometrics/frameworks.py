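"""Essential-meaning frameworks: SVD derivation, rotation, statistics.

Centered VAD scores form an N x 3 matrix A (rows are terms). Its SVD
A = U S V^T yields right-singular directions -- the uncorrelated axes of
the score cloud -- which, ordered by descending singular value and
sign-fixed by convention, define the goodness-aggression-structure (GAS)
basis. Rotating the primary Gd-Ag plane clockwise by -pi/4 gives the
power-danger-structure (PDS) basis:

    Pw = (Gd + Ag) / sqrt(2),    Dg = (Ag - Gd) / sqrt(2).

Both bases are orthonormal 3 x 3 changes of coordinates from VAD. The
GAS/PDS primary axes together form the GPADS circumplex. Frameworks are
always derived at the type level (every term weighted equally); token
weights enter only in statistics and histograms, never in the SVD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, InputError, ValidationError
from .lexicon import VAD_DIMS, CenteredLexicon

GAS_DIMS = ("Gd", "Ag", "St")
PDS_DIMS = ("Pw", "Dg", "St")
GPADS_DIMS = ("Gd", "Pw", "Ag", "Dg", "St")

#: Default cone half-angle for axis word rankings: (1/2) arccos(2/sqrt(6)),
#: about 17.6 degrees. Cones of this half-angle around the 13 axes of the
#: 3x3x3 meaning cube (faces, edges, corners) do not overlap.
DEFAULT_CONE_HALF_ANGLE = 0.5 * float(np.arccos(2.0 / np.sqrt(6.0)))


@dataclass
class ScoreMatrix:
    """Term scores expressed in a named framework (rows = terms)."""

    terms: list[str]
    values: np.ndarray
    dims: tuple[str, ...]
    framework: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.terms):
            raise ValidationError("values must be N x d with N == len(terms)")
        if self.values.shape[1] != len(self.dims):
            raise ValidationError("one column per dimension name required")
        if not np.isfinite(self.values).all():
            raise ValidationError("scores must be finite")

    @classmethod
    def from_lexicon(cls, lex: CenteredLexicon) -> "ScoreMatrix":
        return cls(
            terms=list(lex.scores.index),
            values=lex.scores.to_numpy(dtype=float),
            dims=tuple(lex.scores.columns),
            framework="VAD",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.terms, name="term"), columns=list(self.dims)
        )

    def column(self, dim: str) -> np.ndarray:
        try:
            return self.values[:, self.dims.index(dim)]
        except ValueError as exc:
            raise ContractError(f"dimension {dim!r} not in {self.dims}") from exc

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class FrameworkBasis:
    """An orthonormal change of basis from a source framework.

    Row i of ``matrix`` gives the weights expressing target dimension i
    as a linear combination of the source dimensions. ``singular_values``
    are defined only for SVD-derived bases (None after rotation).
    """

    source_dims: tuple[str, ...]
    target_dims: tuple[str, ...]
    matrix: np.ndarray
    singular_values: np.ndarray | None
    explained_variance: np.ndarray
    sign_convention: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        k = len(self.target_dims)
        if self.matrix.shape != (k, len(self.source_dims)):
            raise ValidationError("basis matrix shape mismatch")
        gram = self.matrix @ self.matrix.T
        if not np.allclose(gram, np.eye(k), atol=1e-9):
            raise ValidationError("basis rows must be orthonormal within 1e-9")
        if abs(self.explained_variance.sum() - 1.0) > 1e-9:
            raise ValidationError("explained variances must sum to 1")
        if self.singular_values is not None:
            self.singular_values = np.asarray(self.singular_values, dtype=float)
            if (np.diff(self.singular_values) > 1e-12).any():
                raise ValidationError("singular values must be nonincreasing")

    @property
    def name(self) -> str:
        return "".join(d[0] for d in self.target_dims)

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "source_dims": list(self.source_dims),
            "target_dims": list(self.target_dims),
            "matrix": [[float(x) for x in row] for row in self.matrix],
            "singular_values": (
                None if self.singular_values is None
                else [float(s) for s in self.singular_values]
            ),
            "explained_variance": [float(v) for v in self.explained_variance],
            "sign_convention": self.sign_convention,
            "degenerate": self.degenerate,
        }
        if path is not None:
            try:
                Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
            except OSError as exc:
                raise InputError(f"cannot write basis to {path}: {exc}") from exc
        return doc

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "FrameworkBasis":
        if not isinstance(source, dict):
            path = Path(source)
            if not path.exists():
                raise InputError(f"basis file not found: {path}")
            source = json.loads(path.read_text(encoding="utf-8"))
        sv = source.get("singular_values")
        return cls(
            source_dims=tuple(source["source_dims"]),
            target_dims=tuple(source["target_dims"]),
            matrix=np.asarray(source["matrix"], dtype=float),
            singular_values=None if sv is None else np.asarray(sv, dtype=float),
            explained_variance=np.asarray(source["explained_variance"], dtype=float),
            sign_convention=source.get("sign_convention", ""),
            degenerate=bool(source.get("degenerate", False)),
        )


def explained_variances(singular_values: Sequence[float]) -> np.ndarray:
    """Fractions of total variance: sigma_i^2 / sum_j sigma_j^2."""
    sv = np.asarray(singular_values, dtype=float)
    total = float((sv**2).sum())
    if total == 0.0:
        raise ContractError("all singular values are zero")
    return sv**2 / total


# Sign convention for GAS: (anchor source dim, required sign) per target row.
_GAS_SIGNS = ((0, +1.0), (1, +1.0), (2, -1.0))  # Gd.Va>0, Ag.Ar>0, St.Dm<0


def derive_gas_basis(scores: ScoreMatrix) -> FrameworkBasis:
    """SVD the centered score matrix into the GAS orthonormal basis.

    Rows are the right-singular directions ordered by descending singular
    value. The SVD leaves each row's sign free; it is fixed so that the
    goodness weight on Va is positive, the aggression weight on Ar is
    positive, and the structure weight on Dm is negative -- deriving
    twice from the same data therefore yields the identical basis.
    A zero singular value marks the basis degenerate but still returns it.
    """
    n, d = scores.values.shape
    if n < d:
        raise ContractError(f"need at least {d} terms to derive a {d}-dim basis")
    if np.allclose(scores.values.std(axis=0), 0.0):
        raise ContractError("all score columns are constant")

    _, sv, vt = np.linalg.svd(scores.values, full_matrices=False)
    rows = vt.copy()
    if d == 3:
        target_dims = GAS_DIMS
        for i, (src, want) in enumerate(_GAS_SIGNS):
            if rows[i, src] * want < 0:
                rows[i] *= -1.0
        convention = "Gd.Va>0, Ag.Ar>0, St.Dm<0"
    else:
        # Generic entities x dimensions matrix: anchor each row's sign on
        # its largest-magnitude weight being positive.
        target_dims = tuple(f"S{i + 1}" for i in range(d))
        for i in range(d):
            j = int(np.argmax(np.abs(rows[i])))
            if rows[i, j] < 0:
                rows[i] *= -1.0
        convention = "largest-|weight| positive"

    degenerate = bool(sv.min() <= sv.max() * 1e-12)
    return FrameworkBasis(
        source_dims=scores.dims,
        target_dims=target_dims,
        matrix=rows,
        singular_values=sv,
        explained_variance=explained_variances(sv),
        sign_convention=convention,
        degenerate=degenerate,
    )


def rotate_primary_plane(matrix: np.ndarray) -> np.ndarray:
    """The -pi/4 rotation of the first two rows, third row untouched.

    Works on any 3-row weight matrix (e.g. one printed to limited
    precision); :func:`rotate_gas_to_pds` applies it to a validated
    basis.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != 3:
        raise ContractError("expected a 3-row weight matrix")
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    return np.vstack(
        [
            (matrix[0] + matrix[1]) * inv_sqrt2,
            (-matrix[0] + matrix[1]) * inv_sqrt2,
            matrix[2],
        ]
    )


def rotate_gas_to_pds(gas: FrameworkBasis) -> FrameworkBasis:
    """Rotate the primary Gd-Ag plane by -pi/4 into the PDS basis.

    Pw = (Gd + Ag)/sqrt(2), Dg = (Ag - Gd)/sqrt(2); St is untouched.
    Because the GAS dimensions are uncorrelated over the deriving score
    set, the rotated plane splits their combined variance evenly:
    explained variance becomes ((e1+e2)/2, (e1+e2)/2, e3). Singular
    values are not defined for the rotated basis.
    """
    if gas.target_dims != GAS_DIMS:
        raise ContractError(f"expected a GAS basis, got dims {gas.target_dims}")
    matrix = rotate_primary_plane(gas.matrix)
    e1, e2, e3 = gas.explained_variance
    ev = np.array([(e1 + e2) / 2.0, (e1 + e2) / 2.0, e3])
    return FrameworkBasis(
        source_dims=gas.source_dims,
        target_dims=PDS_DIMS,
        matrix=matrix,
        singular_values=None,
        explained_variance=ev,
        sign_convention=gas.sign_convention + "; -pi/4 primary-plane rotation",
        degenerate=gas.degenerate,
    )


def apply_basis(scores: ScoreMatrix, basis: FrameworkBasis) -> ScoreMatrix:
    """Express scores in the basis' target framework (term order kept)."""
    if scores.dims != basis.source_dims:
        raise ContractError(
            f"score dims {scores.dims} do not match basis source {basis.source_dims}"
        )
    return ScoreMatrix(
        terms=list(scores.terms),
        values=scores.values @ basis.matrix.T,
        dims=basis.target_dims,
        framework=basis.name,
    )


def gpads_scores(scores_vad: ScoreMatrix, gas: FrameworkBasis, pds: FrameworkBasis) -> ScoreMatrix:
    """Composite five-dimension circumplex view: Gd, Pw, Ag, Dg, St."""
    g = apply_basis(scores_vad, gas)
    p = apply_basis(scores_vad, pds)
    cols = {
        "Gd": g.column("Gd"),
        "Pw": p.column("Pw"),
        "Ag": g.column("Ag"),
        "Dg": p.column("Dg"),
        "St": g.column("St"),
    }
    return ScoreMatrix(
        terms=list(scores_vad.terms),
        values=np.column_stack([cols[d] for d in GPADS_DIMS]),
        dims=GPADS_DIMS,
        framework="GPADS",
    )


def _weight_vector(scores: ScoreMatrix, weights) -> np.ndarray:
    """Normalized probability weights aligned with the score rows."""
    if weights is None:
        return np.full(len(scores), 1.0 / len(scores))
    mapping: Mapping[str, float] = getattr(weights, "weights", weights)
    missing = [t for t in mapping if t not in set(scores.terms)]
    if missing:
        raise ContractError(
            f"{len(missing)} weighted terms absent from scores (e.g. {missing[0]!r})"
        )
    w = np.array([float(mapping.get(t, 0.0)) for t in scores.terms])
    total = w.sum()
    if total <= 0:
        raise ContractError("weights must have positive total")
    return w / total


def pairwise_correlations(scores: ScoreMatrix, weights=None) -> pd.DataFrame:
    """(Weighted) Pearson correlation matrix of the framework dimensions.

    Token weights, when given, are normalized to probabilities and enter
    the means and covariances. A zero-variance dimension has no defined
    correlation; its off-diagonal entries are reported as NaN (flagged
    missing), never as zero.
    """
    if len(scores) < 2:
        raise ContractError("need at least 2 terms for correlations")
    p = _weight_vector(scores, weights)
    x = scores.values
    mean = p @ x
    xc = x - mean
    cov = xc.T @ (xc * p[:, None])
    sd = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[~np.isfinite(corr)] = np.nan
    np.fill_diagonal(corr, 1.0)
    # zero-variance dims: off-diagonals undefined
    zero = sd <= max(sd.max(), 1.0) * 1e-12 if sd.max() > 0 else sd >= 0
    for i in np.flatnonzero(zero):
        corr[i, :] = np.nan
        corr[:, i] = np.nan
        corr[i, i] = 1.0
    return pd.DataFrame(corr, index=list(scores.dims), columns=list(scores.dims))


@dataclass
class PlaneEllipse:
    """One-sigma ellipse of a weighted 2D score cloud (SVD axes)."""

    center: tuple[float, float]
    axes: np.ndarray  # 2x2, rows = unit axis directions, major first
    radii: tuple[float, float]
    dim_pair: tuple[str, str]
    degenerate: bool = False
    scaling: str = "one-sigma"

    def to_dict(self) -> dict:
        return {
            "center": [float(c) for c in self.center],
            "axes": [[float(v) for v in row] for row in self.axes],
            "radii": [float(r) for r in self.radii],
            "dim_pair": list(self.dim_pair),
            "degenerate": self.degenerate,
            "scaling": self.scaling,
        }


def plane_svd_ellipse(
    scores: ScoreMatrix, dim_pair: tuple[str, str], weights=None
) -> PlaneEllipse:
    """SVD axes of a coordinate plane, as a one-sigma ellipse.

    The center is the (weighted) mean of the two coordinates; the axes
    are the principal directions of the centered pair and the radii the
    standard deviations along them (singular values of the centered data
    scaled by 1/sqrt(N)). The radius scaling is recorded in the output.
    """
    if len(scores) < 2:
        raise ContractError("need at least 2 terms for an ellipse")
    p = _weight_vector(scores, weights)
    xy = np.column_stack([scores.column(dim_pair[0]), scores.column(dim_pair[1])])
    center = p @ xy
    xc = xy - center
    cov = xc.T @ (xc * p[:, None])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = [1, 0]
    evals = np.clip(evals[order], 0.0, None)
    axes = evecs[:, order].T
    # deterministic orientation: first nonzero component positive
    for i in range(2):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] *= -1.0
    degenerate = bool(evals[0] <= 0.0)
    return PlaneEllipse(
        center=(float(center[0]), float(center[1])),
        axes=axes,
        radii=(float(np.sqrt(evals[0])), float(np.sqrt(evals[1]))),
        dim_pair=(dim_pair[0], dim_pair[1]),
        degenerate=degenerate,
    )


@dataclass
class ConeRanking:
    """Terms inside a cone around an axis, ranked by scalar projection."""

    axis: np.ndarray
    half_angle: float
    ranked: list[tuple[str, float]]

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.ranked, columns=["term", "component"])
        frame.index = pd.RangeIndex(1, len(frame) + 1, name="rank")
        try:
            frame.to_csv(path, sep="\t", float_format="%.6f", encoding="utf-8")
        except OSError as exc:
            raise InputError(f"cannot write cone ranking to {path}: {exc}") from exc


def rank_terms_in_cone(
    scores: ScoreMatrix,
    axis: Iterable[float],
    half_angle: float = DEFAULT_CONE_HALF_ANGLE,
    top_n: int = 20,
) -> ConeRanking:
    """Rank terms by component size along an axis, restricted to a cone.

    A term qualifies when its score vector makes an angle at most
    ``half_angle`` with the axis (full-vector angle, so the cone lives in
    score space, not a projection). Qualifying terms are ordered by
    descending scalar projection onto the unit axis and truncated to
    ``top_n``. Zero vectors have no direction and are excluded.
    """
    axis = np.asarray(list(axis), dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0.0:
        raise ContractError("cone axis must be nonzero")
    if axis.shape != (scores.values.shape[1],):
        raise ContractError("axis dimensionality must match the framework")
    unit = axis / norm
    mags = np.linalg.norm(scores.values, axis=1)
    proj = scores.values @ unit
    with np.errstate(divide="ignore", invalid="ignore"):
        cosang = np.where(mags > 0, proj / mags, -np.inf)
    keep = cosang >= np.cos(half_angle) - 1e-12
    order = np.argsort(-proj[keep], kind="stable")
    idx = np.flatnonzero(keep)[order][:top_n]
    ranked = [(scores.terms[i], float(proj[i])) for i in idx]
    return ConeRanking(axis=unit, half_angle=half_angle, ranked=ranked)


#: The 13 axes of the 3x3x3 meaning cube in (Pw, Dg, St) coordinates:
#: 3 face axes, 6 edge axes, 4 corner axes (each listed once; negate for
#: the opposite end).
CUBE_AXES: dict[str, tuple[float, float, float]] = {
    "Pw": (1, 0, 0),
    "Dg": (0, 1, 0),
    "St": (0, 0, 1),
    "Pw+Dg": (1, 1, 0),
    "Pw-Dg": (1, -1, 0),
    "Pw+St": (1, 0, 1),
    "Pw-St": (1, 0, -1),
    "Dg+St": (0, 1, 1),
    "Dg-St": (0, 1, -1),
    "Pw+Dg+St": (1, 1, 1),
    "Pw+Dg-St": (1, 1, -1),
    "Pw-Dg+St": (1, -1, 1),
    "Pw-Dg-St": (1, -1, -1),
}
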