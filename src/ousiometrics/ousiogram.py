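"""Ousiograms: annotated weighted 2D histograms of two meaning dimensions.

An ousiogram arranges a collection of scored terms (types, or tokens
weighted by frequency) on a plane of two essential dimensions, with
marginal distributions, weighted medians, the plane's SVD ellipse, and
two kinds of automatic word annotations: boundary words placed along
outward normals of the histogram's convex hull, and internal words
nearest to evenly spaced targets on the eight cardinal/intercardinal
rays. Bins are half-open [lo, hi) with the final bin closed; the default
bin width is 1/30 on a fixed [-1, 1] x [-1, 1] extent so that plots are
comparable across corpora.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .corpus import FrequencyDistribution, weighted_median
from .errors import ContractError, InputError
from .frameworks import PlaneEllipse, ScoreMatrix, plane_svd_ellipse

SCHEMA_VERSION = 1

DEFAULT_BIN_WIDTH = 1.0 / 30.0
DEFAULT_EXTENT = ((-1.0, 1.0), (-1.0, 1.0))
DEFAULT_SPACING = 0.15
DEFAULT_N_PER_RAY = 4
DEFAULT_EXCLUSION_RADIUS = 0.1


@dataclass
class OusiogramGrid:
    """Weighted 2D histogram with marginals, medians and ellipse."""

    dim_pair: tuple[str, str]
    bin_width: float
    extent: tuple[tuple[float, float], tuple[float, float]]
    counts: np.ndarray  # shape (nx, ny), counts[ix, iy]
    marginal_x: np.ndarray
    marginal_y: np.ndarray
    median_x: float
    median_y: float
    ellipse: PlaneEllipse
    max_bin: float
    total_weight: float
    n_clipped: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        (x0, _), (y0, _) = self.extent
        nx, ny = self.counts.shape
        cx = x0 + (np.arange(nx) + 0.5) * self.bin_width
        cy = y0 + (np.arange(ny) + 0.5) * self.bin_width
        return cx, cy


def _bin_index(v: np.ndarray, lo: float, n_bins: int, bin_width: float) -> np.ndarray:
    """Half-open binning: floor((v-lo)/w), the upper edge mapped inward."""
    idx = np.floor((v - lo) / bin_width).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def _points_and_weights(
    scores: ScoreMatrix,
    dim_pair: tuple[str, str],
    weights: FrequencyDistribution | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = scores.column(dim_pair[0])
    y = scores.column(dim_pair[1])
    if weights is None:
        return x, y, np.ones(len(scores))
    index = {t: i for i, t in enumerate(scores.terms)}
    missing = [t for t in weights.weights if t not in index]
    if missing:
        raise ContractError(
            f"{len(missing)} weighted terms lack scores (e.g. {missing[0]!r}); "
            "apply lexical_lens first"
        )
    rows = np.array([index[t] for t in weights.weights], dtype=int)
    w = np.array(list(weights.weights.values()), dtype=float)
    return x[rows], y[rows], w


def build_ousiogram(
    scores: ScoreMatrix,
    dim_pair: tuple[str, str],
    weights: FrequencyDistribution | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    extent: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_EXTENT,
) -> OusiogramGrid:
    """Accumulate weighted scores into the histogram grid.

    With no weights every term counts once (type level). Values outside
    the extent are clipped into the boundary bins and counted; values
    exactly on the upper edge stay in the last bin. Total bin mass
    always equals total input weight.
    """
    if len(scores) < 1:
        raise ContractError("cannot build an ousiogram from an empty score set")
    x, y, w = _points_and_weights(scores, dim_pair, weights)
    if w.sum() <= 0:
        raise ContractError("total weight must be positive")
    (x0, x1), (y0, y1) = extent
    nx = int(np.ceil((x1 - x0) / bin_width - 1e-9))
    ny = int(np.ceil((y1 - y0) / bin_width - 1e-9))

    outside = (x < x0) | (x > x1) | (y < y0) | (y > y1)
    n_clipped = int(outside.sum())
    if n_clipped:
        warnings.warn(f"{n_clipped} points outside extent were clipped", stacklevel=2)
    xc = np.clip(x, x0, x1)
    yc = np.clip(y, y0, y1)

    ix = _bin_index(xc, x0, nx, bin_width)
    iy = _bin_index(yc, y0, ny, bin_width)
    counts = np.zeros((nx, ny))
    np.add.at(counts, (ix, iy), w)

    p = w / w.sum()
    if len(scores) >= 2:
        ellipse = plane_svd_ellipse(scores, dim_pair, weights)
    else:  # a single point has no spread: degenerate ellipse at the point
        ellipse = PlaneEllipse(
            center=(float(x[0]), float(y[0])),
            axes=np.eye(2),
            radii=(0.0, 0.0),
            dim_pair=(dim_pair[0], dim_pair[1]),
            degenerate=True,
        )
    return OusiogramGrid(
        dim_pair=(dim_pair[0], dim_pair[1]),
        bin_width=bin_width,
        extent=extent,
        counts=counts,
        marginal_x=counts.sum(axis=1),
        marginal_y=counts.sum(axis=0),
        median_x=weighted_median(xc, p),
        median_y=weighted_median(yc, p),
        ellipse=ellipse,
        max_bin=float(counts.max()),
        total_weight=float(w.sum()),
        n_clipped=n_clipped,
    )


@dataclass
class BoundaryLabel:
    term: str
    anchor: tuple[float, float]  # segment midpoint on the hull
    normal_angle: float  # radians, outward

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "anchor": [float(self.anchor[0]), float(self.anchor[1])],
            "normal_angle": float(self.normal_angle),
        }


@dataclass
class InternalLabel:
    term: str
    ray_angle: float  # radians, one of k*pi/4
    target: tuple[float, float]
    position: tuple[float, float]  # the term's own coordinates

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "ray_angle": float(self.ray_angle),
            "target": [float(self.target[0]), float(self.target[1])],
            "position": [float(self.position[0]), float(self.position[1])],
        }


@dataclass
class AnnotationSet:
    """Boundary and internal labels; no term appears twice overall."""

    boundary: list[BoundaryLabel] = field(default_factory=list)
    internal: list[InternalLabel] = field(default_factory=list)

    def used_terms(self) -> set[str]:
        return {b.term for b in self.boundary} | {i.term for i in self.internal}

    def to_dict(self) -> dict:
        return {
            "boundary": [b.to_dict() for b in self.boundary],
            "internal": [i.to_dict() for i in self.internal],
        }


def _hull_of_occupied_bins(grid: OusiogramGrid) -> np.ndarray | None:
    cx, cy = grid.bin_centers()
    ix, iy = np.nonzero(grid.counts)
    pts = np.column_stack([cx[ix], cy[iy]])
    if len(pts) < 3:
        return None
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return None  # collinear
    return pts[hull.vertices]  # counterclockwise


def annotate_boundary(
    grid: OusiogramGrid,
    scores: ScoreMatrix,
    labels: list[str] | None = None,
    spacing: float = DEFAULT_SPACING,
    used: set[str] | None = None,
    mode: str = "projection",
) -> AnnotationSet:
    """Label the histogram's convex-hull boundary with extremal words.

    The hull of occupied-bin centers is subdivided into arcs of length
    approximately ``spacing``; at each arc midpoint the outward normal of
    the underlying hull edge is taken, and the annotation is the
    not-yet-used candidate term maximizing scalar projection onto that
    normal (``mode="midpoint"`` instead picks the term nearest the arc
    midpoint). Each term is used at most once.
    """
    if mode not in ("projection", "midpoint"):
        raise ContractError(f"unknown boundary annotation mode {mode!r}")
    used = set() if used is None else set(used)
    vertices = _hull_of_occupied_bins(grid)
    out = AnnotationSet()
    if vertices is None:
        warnings.warn("fewer than 3 non-collinear occupied bins; no boundary labels",
                      stacklevel=2)
        return out

    candidates = labels if labels is not None else list(scores.terms)
    cand_set = set(candidates)
    pts = np.column_stack(
        [scores.column(grid.dim_pair[0]), scores.column(grid.dim_pair[1])]
    )
    cand_idx = [i for i, t in enumerate(scores.terms) if t in cand_set]

    # walk the closed hull polygon; cut the perimeter into equal arcs
    edges = np.roll(vertices, -1, axis=0) - vertices
    lengths = np.linalg.norm(edges, axis=1)
    perimeter = float(lengths.sum())
    if perimeter == 0.0:
        return out
    n_segments = max(1, int(round(perimeter / spacing)))
    arc = perimeter / n_segments
    cumlen = np.concatenate([[0.0], np.cumsum(lengths)])

    for k in range(n_segments):
        mid_s = (k + 0.5) * arc
        e = int(np.searchsorted(cumlen, mid_s, side="right")) - 1
        e = min(e, len(vertices) - 1)
        t_on_edge = (mid_s - cumlen[e]) / lengths[e] if lengths[e] > 0 else 0.0
        midpoint = vertices[e] + t_on_edge * edges[e]
        direction = edges[e] / lengths[e] if lengths[e] > 0 else np.array([1.0, 0.0])
        normal = np.array([direction[1], -direction[0]])  # outward for CCW hull

        best_term, best_score = None, -np.inf
        for i in cand_idx:
            term = scores.terms[i]
            if term in used:
                continue
            if mode == "projection":
                value = float(pts[i] @ normal)
            else:
                value = -float(np.linalg.norm(pts[i] - midpoint))
            if value > best_score:
                best_term, best_score = term, value
        if best_term is None:
            break
        used.add(best_term)
        out.boundary.append(
            BoundaryLabel(
                term=best_term,
                anchor=(float(midpoint[0]), float(midpoint[1])),
                normal_angle=float(np.arctan2(normal[1], normal[0])),
            )
        )
    return out


RAY_ANGLES = tuple(k * np.pi / 4.0 for k in range(8))


def annotate_internal(
    scores: ScoreMatrix,
    dim_pair: tuple[str, str],
    n_per_ray: int = DEFAULT_N_PER_RAY,
    exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS,
    used: set[str] | None = None,
) -> AnnotationSet:
    """Label interior example words along the 8 cardinal/intercardinal rays.

    Each ray from the origin gets ``n_per_ray`` target points evenly
    spaced between the origin-exclusion radius and the ray's data extent
    (the largest scalar projection of any point onto the ray); each
    target is annotated with the nearest unused term in Euclidean plane
    distance. Fewer available terms than targets is not an error.
    """
    if len(scores) < 1:
        raise ContractError("cannot annotate an empty score set")
    used = set() if used is None else set(used)
    out = AnnotationSet()
    if n_per_ray <= 0:
        return out
    pts = np.column_stack([scores.column(dim_pair[0]), scores.column(dim_pair[1])])

    for angle in RAY_ANGLES:
        u = np.array([np.cos(angle), np.sin(angle)])
        extent = float((pts @ u).max())
        if extent <= exclusion_radius:
            continue
        targets = np.linspace(exclusion_radius, extent, n_per_ray)
        for r in targets:
            target = r * u
            dists = np.linalg.norm(pts - target, axis=1)
            order = np.argsort(dists, kind="stable")
            chosen = None
            for i in order:
                if scores.terms[i] not in used:
                    chosen = int(i)
                    break
            if chosen is None:
                return out  # every term used up
            used.add(scores.terms[chosen])
            out.internal.append(
                InternalLabel(
                    term=scores.terms[chosen],
                    ray_angle=float(angle),
                    target=(float(target[0]), float(target[1])),
                    position=(float(pts[chosen, 0]), float(pts[chosen, 1])),
                )
            )
    return out


def annotate(
    grid: OusiogramGrid,
    scores: ScoreMatrix,
    spacing: float = DEFAULT_SPACING,
    n_per_ray: int = DEFAULT_N_PER_RAY,
) -> AnnotationSet:
    """Boundary then internal annotation with a shared no-reuse set."""
    result = annotate_boundary(grid, scores, spacing=spacing)
    inner = annotate_internal(
        scores, grid.dim_pair, n_per_ray=n_per_ray, used=result.used_terms()
    )
    result.internal = inner.internal
    return result


def sidecar_dict(grid: OusiogramGrid, annotations: AnnotationSet | None) -> dict:
    """Everything a rendered figure shows, as plain JSON-ready data."""
    return {
        "schema_version": SCHEMA_VERSION,
        "dim_pair": list(grid.dim_pair),
        "bin_width": grid.bin_width,
        "extent": [list(grid.extent[0]), list(grid.extent[1])],
        "counts": [[float(v) for v in row] for row in grid.counts],
        "marginal_x": [float(v) for v in grid.marginal_x],
        "marginal_y": [float(v) for v in grid.marginal_y],
        "median_x": grid.median_x,
        "median_y": grid.median_y,
        "ellipse": grid.ellipse.to_dict(),
        "max_bin": grid.max_bin,
        "total_weight": grid.total_weight,
        "n_clipped": grid.n_clipped,
        "annotations": annotations.to_dict() if annotations is not None else None,
    }


def render_ousiogram(
    grid: OusiogramGrid,
    annotations: AnnotationSet | None,
    path: str | Path,
    cmap: str = "magma_r",
    title: str = "",
) -> Path:
    """Render the figure (PNG/SVG by extension) plus a sidecar JSON.

    The sidecar carries every plotted element -- bins, marginals,
    medians, ellipse, annotation coordinates -- so downstream checks
    never parse pixels. The color map is linearly normalized to the
    highest-count bin. Returns the sidecar path.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse as MplEllipse

    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    doc = sidecar_dict(grid, annotations)
    try:
        sidecar.write_text(
            json.dumps(doc, sort_keys=True, separators=(",", ":")) + "\n",
            encoding="utf-8",
        )
    except OSError as exc:
        raise InputError(f"cannot write sidecar to {sidecar}: {exc}") from exc

    (x0, x1), (y0, y1) = grid.extent
    fig = plt.figure(figsize=(7.2, 7.2))
    gs = fig.add_gridspec(
        2, 2, width_ratios=(5, 1), height_ratios=(1, 5), hspace=0.04, wspace=0.04
    )
    ax = fig.add_subplot(gs[1, 0])
    ax_top = fig.add_subplot(gs[0, 0], sharex=ax)
    ax_right = fig.add_subplot(gs[1, 1], sharey=ax)

    masked = np.ma.masked_equal(grid.counts.T, 0.0)
    mesh = ax.imshow(
        masked,
        origin="lower",
        extent=(x0, x1, y0, y1),
        cmap=cmap,
        vmin=0.0,
        vmax=grid.max_bin if grid.max_bin > 0 else 1.0,
        interpolation="nearest",
        aspect="equal",
    )
    fig.colorbar(mesh, ax=ax_right, fraction=0.3, pad=0.02, label="bin weight")

    cx, cy = grid.bin_centers()
    ax_top.bar(cx, grid.marginal_x, width=grid.bin_width, color="0.45")
    ax_top.plot(
        [grid.median_x], [0], marker="v", color="0.1", markersize=9, clip_on=False
    )
    ax_right.barh(cy, grid.marginal_y, height=grid.bin_width, color="0.45")
    ax_right.plot(
        [0], [grid.median_y], marker="<", color="0.1", markersize=9, clip_on=False
    )
    for a in (ax_top, ax_right):
        a.tick_params(labelbottom=False, labelleft=False)

    ell = grid.ellipse
    angle_deg = float(np.degrees(np.arctan2(ell.axes[0, 1], ell.axes[0, 0])))
    ax.add_patch(
        MplEllipse(
            ell.center,
            width=2 * ell.radii[0],
            height=2 * ell.radii[1],
            angle=angle_deg,
            fill=False,
            color="k",
            lw=1.2,
        )
    )

    if annotations is not None:
        for b in annotations.boundary:
            dx, dy = np.cos(b.normal_angle), np.sin(b.normal_angle)
            ax.annotate(
                b.term,
                xy=b.anchor,
                xytext=(b.anchor[0] + 0.1 * dx, b.anchor[1] + 0.1 * dy),
                fontsize=7,
                ha="center",
                va="center",
                rotation=0,
            )
        for lab in annotations.internal:
            ax.text(
                lab.position[0], lab.position[1], lab.term, fontsize=6,
                ha="center", va="center", color="0.2",
            )

    ax.axhline(0.0, color="0.7", lw=0.6)
    ax.axvline(0.0, color="0.7", lw=0.6)
    ax.set_xlabel(grid.dim_pair[0])
    ax.set_ylabel(grid.dim_pair[1])
    if title:
        ax_top.set_title(title)
    try:
        fig.savefig(path, dpi=150)
    except OSError as exc:
        raise InputError(f"cannot write figure to {path}: {exc}") from exc
    finally:
        plt.close(fig)
    return sidecar
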