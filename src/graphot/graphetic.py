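"""Graphetic dissimilarity metrics between letter shapes, and model RDMs.

Implements the shape metrics used to model sub-letter (graphetic)
processing:

* fuzzy **Jaccard distance** — one minus intersection over union, computed
  on intensities with elementwise min/max;
* **Wasserstein-1 distance** (earth mover's distance) — the minimal total
  cost of transporting one glyph's pixel mass onto another's, with
  Euclidean pixel-grid ground cost, solved exactly as a linear program;
* **Gromov-Wasserstein distance** — square-loss comparison of the two
  glyphs' internal distance structures, invariant to rigid transformations,
  solved by conditional gradient with exact inner transport steps;
* transformation-invariant variants of Jaccard/Wasserstein, minimising the
  metric over translation, scale and/or rotation of one glyph via
  multi-start Nelder-Mead (translation for Jaccard is resolved by the
  cross-correlation peak instead).

Pairs of glyphs are aligned to maximal overlap via the peak of their 2-D
linear cross-correlation before metric evaluation.  A representational
dissimilarity matrix (RDM) collects the metric over all unordered letter
pairs; rank-transformed RDMs (ranks 1..435 over the lower triangle of a
30-letter RDM) feed the rank-correlation RSA downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal, sparse, stats
from scipy.optimize import linprog, minimize

from .glyphs import IntensityImage, MassDistribution, to_mass_distribution

__all__ = [
    "RDM",
    "RankRDM",
    "TransformBounds",
    "TransportPlan",
    "align_by_crosscorr",
    "jaccard_distance",
    "wasserstein_distance",
    "gromov_wasserstein_distance",
    "invariant_distance",
    "build_model_rdm",
    "rank_transform_rdm",
    "rdm_to_csv",
    "rdm_from_csv",
    "rdm_to_hdf5",
    "rdm_from_hdf5",
]

MARGINAL_TOL = 1e-8
#: combined support size beyond which the dense transport LP is refused
MAX_COMBINED_SUPPORT = 20_000
#: intensity threshold applied before Gromov-Wasserstein support extraction
GW_MIN_INTENSITY = 0.05
#: finite objective penalty for degenerate transforms in the optimiser
_PENALTY = 1e12


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RDM:
    """Symmetric dissimilarity matrix over an ordered letter set."""

    labels: tuple[str, ...]
    values: np.ndarray
    metric_id: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if vals.shape != (n, n):
            raise ValueError("values must be square and match labels")
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(vals), 0, atol=1e-12):
            raise ValueError("RDM diagonal must be zero")
        if np.any(vals < -1e-12):
            raise ValueError("RDM values must be non-negative")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return len(self.labels)

    def lower_triangle(self) -> np.ndarray:
        """The informative pairwise values, row-major over i > j."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]


@dataclass(frozen=True)
class RankRDM:
    """RDM whose lower-triangle values are (average-tie) ranks 1..n_pairs."""

    labels: tuple[str, ...]
    ranks: np.ndarray
    metric_id: str = ""

    def __post_init__(self) -> None:
        ranks = np.asarray(self.ranks, dtype=float)
        n = len(self.labels)
        if ranks.shape != (n, n):
            raise ValueError("ranks must be square and match labels")
        if not np.allclose(ranks, ranks.T, atol=1e-12):
            raise ValueError("rank matrix must be symmetric")
        n_pairs = n * (n - 1) // 2
        i, j = np.tril_indices(n, k=-1)
        if not np.isclose(ranks[i, j].sum(), n_pairs * (n_pairs + 1) / 2):
            raise ValueError("lower-triangle rank sum is inconsistent")
        object.__setattr__(self, "ranks", ranks)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return len(self.labels)

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(self.n, k=-1)
        return self.ranks[i, j]


@dataclass(frozen=True)
class TransformBounds:
    """Search bounds for the geometric-invariance optimisation.

    Translation is bounded between ``-x`` and ``2x`` where ``x`` is the
    transformed letter's width (horizontal) or height (vertical), with zero
    at the top-left origin.  Scale is optimised on a log scale between
    log(0.5) and log(2).  Rotation is unbounded, with starting values
    spaced over [-180, 180] degrees.  ``starts_per_dim`` equidistant
    starting values are placed along each optimised dimension.
    """

    log_scale_range: tuple[float, float] = (float(np.log(0.5)), float(np.log(2.0)))
    rotation_start_range: tuple[float, float] = (-180.0, 180.0)
    translation_factor: tuple[float, float] = (-1.0, 2.0)
    starts_per_dim: int = 5

    def __post_init__(self) -> None:
        if self.starts_per_dim < 1:
            raise ValueError("starts_per_dim must be >= 1")
        if not (self.log_scale_range[0] <= 0.0 <= self.log_scale_range[1]):
            raise ValueError("identity (log-scale 0) must lie inside scale bounds")
        if not (self.translation_factor[0] <= 0.0 <= self.translation_factor[1]):
            raise ValueError("identity (zero shift) must lie inside translation bounds")


@dataclass(frozen=True)
class TransportPlan:
    """Optimal coupling between two mass distributions."""

    source: MassDistribution
    target: MassDistribution
    couplings: np.ndarray  # (k, 3): source index, target index, mass
    cost: float

    def __post_init__(self) -> None:
        coup = np.asarray(self.couplings, dtype=float)
        if coup.ndim != 2 or coup.shape[1] != 3:
            raise ValueError("couplings must have shape (k, 3)")
        row = np.zeros(len(self.source))
        col = np.zeros(len(self.target))
        np.add.at(row, coup[:, 0].astype(int), coup[:, 2])
        np.add.at(col, coup[:, 1].astype(int), coup[:, 2])
        if (np.abs(row - self.source.masses).max() > MARGINAL_TOL
                or np.abs(col - self.target.masses).max() > MARGINAL_TOL):
            raise ValueError("coupling marginals do not match the distributions")
        object.__setattr__(self, "couplings", coup)


# --------------------------------------------------------------------------
# alignment
# --------------------------------------------------------------------------

def align_by_crosscorr(
    a: IntensityImage, b: IntensityImage
) -> tuple[tuple[int, int], IntensityImage, IntensityImage]:
    """Overlap-align two glyph images via their 2-D linear cross-correlation.

    Returns the integer offset ``(dr, dc)`` (position of ``b``'s origin
    relative to ``a``'s that maximises the cross-correlation, i.e. maximal
    ink overlap) together with both images zero-padded onto a common canvas
    at that relative placement.  Ties at the correlation peak are broken by
    first occurrence in row-major scan order.
    """
    pa, pb = a.pixels, b.pixels
    if not pa.any() or not pb.any():
        raise ValueError("cannot align empty images")
    cc = signal.correlate(pa, pb, mode="full", method="auto")
    peak = np.unravel_index(int(np.argmax(cc)), cc.shape)
    # full cross-correlation index (i, j) corresponds to shifting b by
    # (i - (Hb - 1), j - (Wb - 1)) relative to a
    dr = int(peak[0]) - (pb.shape[0] - 1)
    dc = int(peak[1]) - (pb.shape[1] - 1)

    # common canvas: place a at (Hb, Wb) so any admissible shift of b fits
    ha, wa = pa.shape
    hb, wb = pb.shape
    canvas_shape = (ha + 2 * hb, wa + 2 * wb)
    a_pad = np.zeros(canvas_shape)
    b_pad = np.zeros(canvas_shape)
    a_pad[hb : hb + ha, wb : wb + wa] = pa
    b_pad[hb + dr : hb + dr + hb, wb + dc : wb + dc + wb] = pb

    # crop jointly to the union ink bounding box (placement preserved)
    union = (a_pad > 0) | (b_pad > 0)
    rows = np.flatnonzero(union.any(axis=1))
    cols = np.flatnonzero(union.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    return (
        (dr, dc),
        IntensityImage(a_pad[sl], a.glyph_id, a.font_id),
        IntensityImage(b_pad[sl], b.glyph_id, b.font_id),
    )


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def jaccard_distance(a: IntensityImage, b: IntensityImage) -> float:
    """Fuzzy Jaccard distance: 1 - sum(min(a, b)) / sum(max(a, b)).

    Both images must live on a common (aligned, padded) canvas.  With
    binary images this reduces to one minus shape overlap over shape union.
    """
    pa, pb = a.pixels, b.pixels
    if pa.shape != pb.shape:
        raise ValueError("images must share a common canvas; align them first")
    union = np.maximum(pa, pb).sum()
    if union == 0:
        raise ValueError("Jaccard distance undefined for two empty images")
    return float(1.0 - np.minimum(pa, pb).sum() / union)


def _solve_ot(cost: np.ndarray, p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact discrete optimal transport by linear programming (HiGHS).

    Returns the optimal coupling matrix and its cost.  The LP is the
    classical transportation problem; the simplex solver returns an exact
    vertex of the transport polytope.
    """
    n, m = cost.shape
    row = sparse.kron(sparse.eye(n), np.ones((1, m)), format="csr")
    col = sparse.kron(np.ones((1, n)), sparse.eye(m), format="csr")
    # one marginal constraint is redundant; dropping it keeps A full rank
    a_eq = sparse.vstack([row, col]).tocsc()[:-1]
    b_eq = np.concatenate([p, q])[:-1]
    res = linprog(cost.ravel(), A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if res.status != 0:  # pragma: no cover - polytope is never empty here
        raise RuntimeError(f"transport LP failed: {res.message}")
    plan = res.x.reshape(n, m)
    return plan, float(res.fun)


def wasserstein_distance(
    p: MassDistribution, q: MassDistribution
) -> tuple[float, TransportPlan]:
    """Exact Wasserstein-1 distance between two unit-mass pixel distributions.

    The ground cost between support points is the Euclidean distance on
    the pixel grid; the reported distance is the sum over the optimal plan
    of transported mass times ground distance.

    Raises
    ------
    ValueError
        If total masses differ beyond tolerance (scale masses to one
        first), or if the combined support exceeds
        :data:`MAX_COMBINED_SUPPORT` (threshold or downscale the images).
    """
    if abs(p.masses.sum() - q.masses.sum()) > 1e-9:
        raise ValueError(
            "total masses differ; scale each distribution's mass to sum to 1 first"
        )
    if len(p) + len(q) > MAX_COMBINED_SUPPORT:
        raise ValueError(
            f"combined support {len(p) + len(q)} exceeds {MAX_COMBINED_SUPPORT}; "
            "raise min_intensity or downscale the images"
        )
    cost = np.linalg.norm(
        p.coords[:, None, :].astype(float) - q.coords[None, :, :].astype(float),
        axis=-1,
    )
    plan, total = _solve_ot(cost, p.masses, q.masses)
    i, j = np.nonzero(plan > 1e-15)
    couplings = np.column_stack([i, j, plan[i, j]])
    return total, TransportPlan(source=p, target=q, couplings=couplings, cost=total)


def _ipf_coupling(
    rng: np.random.Generator, p: np.ndarray, q: np.ndarray, iters: int = 100
) -> np.ndarray:
    """Random feasible coupling via iterative proportional fitting."""
    t = rng.random((p.size, q.size)) + 1e-3
    for _ in range(iters):
        t *= (p / t.sum(axis=1))[:, None]
        t *= (q / t.sum(axis=0))[None, :]
    return t


def _gw_objective(c1: np.ndarray, c2: np.ndarray, t: np.ndarray, const: float) -> float:
    return const - 2.0 * float(np.sum((c1 @ t @ c2) * t))


def gromov_wasserstein_distance(
    p: MassDistribution,
    q: MassDistribution,
    max_support: int = 1500,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-9,
    n_starts: int = 4,
) -> float:
    """Square-loss Gromov-Wasserstein objective between two distributions.

    Each distribution is described by the pairwise Euclidean distances
    among its own support points, making the comparison invariant to rigid
    transformations (translation, rotation, reflection) of either glyph.
    The non-convex objective is minimised by conditional gradient (each
    descent direction is an exact transport LP with the current gradient
    as cost, followed by an exact quadratic line search), run from the
    product coupling plus ``n_starts - 1`` seeded random feasible
    couplings; the best converged objective is returned.  Tiny supports
    with equal masses on both sides (n = m <= 8) are additionally solved
    exactly by enumerating all assignment couplings.

    If a support exceeds ``max_support`` points, it is reduced by
    intensity-weighted subsampling with the given seed before solving.
    """
    if max_support < 2:
        raise ValueError("max_support must be >= 2")
    rng = np.random.default_rng(seed)
    p = _subsample(p, max_support, rng)
    q = _subsample(q, max_support, rng)
    xs = p.coords.astype(float)
    xt = q.coords.astype(float)
    c1 = np.linalg.norm(xs[:, None] - xs[None, :], axis=-1)
    c2 = np.linalg.norm(xt[:, None] - xt[None, :], axis=-1)
    a, b = p.masses, q.masses
    const = float(a @ (c1**2) @ a + b @ (c2**2) @ b)

    starts: list[np.ndarray] = [np.outer(a, b)]
    for s in range(max(0, n_starts - 1)):
        if s % 2 == 0:
            # a random vertex of the transport polytope: optimal coupling
            # for a random cost matrix
            t0, _ = _solve_ot(rng.random((a.size, b.size)), a, b)
            starts.append(t0)
        else:
            starts.append(_ipf_coupling(rng, a, b))

    best = np.inf
    for t0 in starts:
        t = t0
        obj = _gw_objective(c1, c2, t, const)
        for _ in range(max_iter):
            grad = -4.0 * (c1 @ t @ c2)  # constant-marginal terms dropped
            direction, _ = _solve_ot(grad - grad.min(), a, b)
            delta = direction - t
            slope = -4.0 * float(np.sum((c1 @ t @ c2) * delta))
            curv = -2.0 * float(np.sum((c1 @ delta @ c2) * delta))
            if curv > 0:
                step = float(np.clip(-slope / (2 * curv), 0.0, 1.0))
            else:
                step = 1.0 if slope + curv < 0 else 0.0
            if step == 0.0:
                break
            t = t + step * delta
            new_obj = _gw_objective(c1, c2, t, const)
            if abs(obj - new_obj) < tol:
                obj = new_obj
                break
            obj = new_obj
        best = min(best, obj)
    # Conditional gradient only guarantees a local optimum of this
    # non-convex objective.  For tiny equal-mass supports the assignment
    # couplings can be enumerated exactly; take the best of both.
    if (
        len(a) == len(b) <= 8
        and np.allclose(a, 1 / len(a), atol=1e-12)
        and np.allclose(b, 1 / len(b), atol=1e-12)
    ):
        n = len(a)
        for perm in itertools.permutations(range(n)):
            pidx = np.asarray(perm)
            val = float(np.sum((c1 - c2[np.ix_(pidx, pidx)]) ** 2)) / n**2
            best = min(best, val)
    # tiny negative values are round-off of an exactly-zero objective
    return float(max(best, 0.0))


def _subsample(
    dist: MassDistribution, max_support: int, rng: np.random.Generator
) -> MassDistribution:
    if len(dist) <= max_support:
        return dist
    idx = rng.choice(len(dist), size=max_support, replace=False, p=dist.masses)
    idx.sort()
    masses = dist.masses[idx]
    return MassDistribution(coords=dist.coords[idx], masses=masses / masses.sum())


# --------------------------------------------------------------------------
# geometric-invariance optimisation
# --------------------------------------------------------------------------

def _resize_to_height(img: IntensityImage, height: int) -> IntensityImage:
    if img.shape[0] <= height:
        return img
    from PIL import Image as PILImage

    scale = height / img.shape[0]
    w = max(1, round(img.shape[1] * scale))
    im = PILImage.fromarray(np.round(img.pixels * 255).astype(np.uint8), mode="L")
    arr = np.asarray(im.resize((w, height), PILImage.BILINEAR), dtype=float) / 255.0
    if not arr.any():  # pragma: no cover - only for pathological inputs
        raise ValueError("downscaling erased all ink")
    return IntensityImage(arr, img.glyph_id, img.font_id)


def _transform_image(
    pixels: np.ndarray, rotation_deg: float, log_scale: float,
    shift_rc: tuple[float, float],
) -> np.ndarray:
    """Rotate/scale about the image centre then translate, bilinear."""
    theta = np.deg2rad(rotation_deg)
    s = np.exp(log_scale)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    # output->input map for ndimage: x_in = M @ (x_out - c - shift) + c
    m = rot.T / s
    centre = (np.asarray(pixels.shape, dtype=float) - 1) / 2
    offset = centre - m @ (centre + np.asarray(shift_rc, dtype=float))
    out = ndimage.affine_transform(
        pixels, m, offset=offset, order=1, mode="constant", cval=0.0
    )
    return np.clip(out, 0.0, 1.0)


def invariant_distance(
    a: IntensityImage,
    b: IntensityImage,
    metric: str = "wasserstein",
    transforms: frozenset[str] | set[str] = frozenset(),
    bounds: TransformBounds | None = None,
    work_height_px: int = 75,
    min_intensity: float = 0.0,
    extra_starts: list[dict[str, float]] | None = None,
) -> tuple[float, dict[str, float]]:
    """Minimum metric value over geometric transformations of ``b``.

    ``b``'s parameters (any subset of translation, scale, rotation) are
    varied while ``a`` is held constant.  Images are downscaled to
    ``work_height_px`` before optimisation.  The search runs Nelder-Mead
    from the full factorial grid of ``starts_per_dim`` equidistant
    starting values per optimised dimension (plus the identity transform,
    and any ``extra_starts``, e.g. warm starts from a smaller transform
    set); the minimum over all runs is returned together with the best
    transform parameters.

    For the Jaccard metric, translation is not given to the optimiser:
    each evaluation instead re-aligns the transformed image by the peak of
    the 2-D cross-correlation, which maximises overlap directly.
    """
    transforms = frozenset(transforms)
    valid = {"translation", "scale", "rotation"}
    if not transforms <= valid:
        raise ValueError(f"unknown transforms: {sorted(transforms - valid)}")
    if metric not in ("jaccard", "wasserstein"):
        raise ValueError(f"metric must be jaccard or wasserstein, got {metric!r}")
    bounds = bounds or TransformBounds()

    a = _resize_to_height(a, work_height_px)
    b = _resize_to_height(b, work_height_px)
    _, a_pad, b_pad = align_by_crosscorr(a, b)

    def plain(ai: IntensityImage, bi: IntensityImage) -> float:
        if metric == "jaccard":
            return jaccard_distance(ai, bi)
        d, _ = wasserstein_distance(
            to_mass_distribution(ai, min_intensity),
            to_mass_distribution(bi, min_intensity),
        )
        return d

    if not transforms:
        return plain(a_pad, b_pad), {}

    xcorr_translation = metric == "jaccard" and "translation" in transforms
    dims: list[str] = []
    if "rotation" in transforms:
        dims.append("rotation")
    if "scale" in transforms:
        dims.append("scale")
    if "translation" in transforms and not xcorr_translation:
        dims.extend(["shift_row", "shift_col"])

    hb, wb = b.shape  # translation bounds scale with the letter's own size
    lo_f, hi_f = bounds.translation_factor
    bound_map = {
        "rotation": (-np.inf, np.inf),
        "scale": bounds.log_scale_range,
        "shift_row": (lo_f * hb, hi_f * hb),
        "shift_col": (lo_f * wb, hi_f * wb),
    }
    start_map = {
        "rotation": np.linspace(*bounds.rotation_start_range, bounds.starts_per_dim),
        "scale": np.linspace(*bounds.log_scale_range, bounds.starts_per_dim),
        "shift_row": np.linspace(lo_f * hb, hi_f * hb, bounds.starts_per_dim),
        "shift_col": np.linspace(lo_f * wb, hi_f * wb, bounds.starts_per_dim),
    }

    def objective(x: np.ndarray) -> float:
        params = dict(zip(dims, x))
        rot = params.get("rotation", 0.0)
        ls = params.get("scale", 0.0)
        shift = (params.get("shift_row", 0.0), params.get("shift_col", 0.0))
        tb = _transform_image(b_pad.pixels, rot, ls, shift)
        if not tb.any():
            return _PENALTY  # transform pushed all ink off the canvas
        bi = IntensityImage(tb, b.glyph_id, b.font_id)
        ai = a_pad
        if xcorr_translation:
            _, ai, bi = align_by_crosscorr(a_pad, bi)
        try:
            return plain(ai, bi)
        except ValueError:
            return _PENALTY

    identity = np.zeros(len(dims))
    if not dims:
        # translation-only Jaccard: fully resolved by the alignment peak
        return objective(identity), {"translation": float("nan")}
    starts = [identity]
    for combo in itertools.product(*(start_map[d] for d in dims)):
        starts.append(np.asarray(combo, dtype=float))
    for es in extra_starts or []:
        starts.append(np.asarray([es.get(d, 0.0) for d in dims], dtype=float))

    nm_bounds = [bound_map[d] for d in dims]
    best_val = objective(identity)  # aligned/identity evaluation always counted
    best_x = identity
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=nm_bounds,
            options={"xatol": 1e-3, "fatol": 1e-7, "maxiter": 200 * len(dims)},
        )
        if res.fun < best_val:
            best_val, best_x = float(res.fun), res.x
    params = dict(zip(dims, (float(v) for v in best_x)))
    if xcorr_translation:
        params["translation"] = float("nan")  # resolved by cross-correlation peak
    return float(best_val), params


# --------------------------------------------------------------------------
# RDM assembly
# --------------------------------------------------------------------------

def build_model_rdm(
    images: dict[str, IntensityImage],
    metric: str = "wasserstein",
    invariance: frozenset[str] | set[str] = frozenset(),
    bounds: TransformBounds | None = None,
    work_height_px: int = 75,
    min_intensity: float = 0.0,
    gw_max_support: int = 1500,
    seed: int = 0,
) -> RDM:
    """Pairwise graphetic dissimilarity matrix over a letter set.

    For each unordered pair the two glyphs are overlap-aligned by
    cross-correlation and the configured metric is evaluated (with
    geometric-invariance optimisation when ``invariance`` is non-empty).
    Gromov-Wasserstein needs no alignment (it is rigid-invariant); its
    support is thresholded at :data:`GW_MIN_INTENSITY` for tractability.
    """
    if len(images) < 2:
        raise ValueError("need at least 2 letters")
    labels = tuple(images.keys())
    n = len(labels)
    vals = np.zeros((n, n))
    inv_tag = "".join(sorted(t[0].upper() for t in invariance)) or "none"
    for i, j in itertools.combinations(range(n), 2):
        a, b = images[labels[i]], images[labels[j]]
        if metric == "gw":
            d = gromov_wasserstein_distance(
                to_mass_distribution(_resize_to_height(a, work_height_px),
                                     GW_MIN_INTENSITY),
                to_mass_distribution(_resize_to_height(b, work_height_px),
                                     GW_MIN_INTENSITY),
                max_support=gw_max_support,
                seed=seed,
            )
        elif invariance:
            d, _ = invariant_distance(
                a, b, metric=metric, transforms=invariance, bounds=bounds,
                work_height_px=work_height_px, min_intensity=min_intensity,
            )
        else:
            _, a_pad, b_pad = align_by_crosscorr(a, b)
            if metric == "jaccard":
                d = jaccard_distance(a_pad, b_pad)
            elif metric == "wasserstein":
                d, _ = wasserstein_distance(
                    to_mass_distribution(a_pad, min_intensity),
                    to_mass_distribution(b_pad, min_intensity),
                )
            else:
                raise ValueError(f"unknown metric: {metric!r}")
        vals[i, j] = vals[j, i] = d
    return RDM(labels=labels, values=vals, metric_id=f"{metric}:{inv_tag}")


def rank_transform_rdm(rdm: RDM) -> RankRDM:
    """Replace lower-triangle values by their ranks (average ranks on ties)."""
    n = rdm.n
    i, j = np.tril_indices(n, k=-1)
    ranks = stats.rankdata(rdm.values[i, j], method="average")
    mat = np.zeros((n, n))
    mat[i, j] = ranks
    mat[j, i] = ranks
    return RankRDM(labels=rdm.labels, ranks=mat, metric_id=rdm.metric_id)


# --------------------------------------------------------------------------
# serialisation
# --------------------------------------------------------------------------

def rdm_to_csv(rdm: RDM | RankRDM, path: str) -> None:
    vals = rdm.values if isinstance(rdm, RDM) else rdm.ranks
    pd.DataFrame(vals, index=list(rdm.labels), columns=list(rdm.labels)).to_csv(path)


def rdm_from_csv(path: str, metric_id: str = "") -> RDM:
    df = pd.read_csv(path, index_col=0)
    return RDM(labels=tuple(str(c) for c in df.columns),
               values=df.to_numpy(dtype=float), metric_id=metric_id)


def rdm_to_hdf5(rdm: RDM | RankRDM, path: str) -> None:
    import h5py

    vals = rdm.values if isinstance(rdm, RDM) else rdm.ranks
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=[s.encode("utf-8") for s in rdm.labels])
        f.create_dataset("values", data=vals)
        f.create_dataset("metric_id", data=rdm.metric_id.encode("utf-8"))


def rdm_from_hdf5(path: str) -> RDM:
    import h5py

    with h5py.File(path, "r") as f:
        labels = tuple(s.decode("utf-8") for s in f["labels"][()])
        values = f["values"][()]
        metric_id = f["metric_id"][()].decode("utf-8")
    return RDM(labels=labels, values=values, metric_id=metric_id)
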