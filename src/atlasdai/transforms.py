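"""Coordinate transformations between brain spatial reference systems.

Supports least-squares affine fits, thin-plate-spline (TPS) landmark
interpolation, exact/approximate inversion, composition, and seeded
inverse-consistency scoring.  Transformations operate on
:class:`PointSet` objects (coordinates tagged with a mandatory SRS name) or
raw ``(n, dim)`` arrays.

Thin-plate splines
------------------
Given landmark pairs :math:`(p_i, q_i)` the TPS is the minimum-bending-energy
interpolant

.. math:: f(x) = A [1, x]^T + \\sum_i w_i U(\\lVert x - p_i \\rVert)

with radial kernel :math:`U(r) = r^2 \\log r` in 2D (``U(0)=0``) and
:math:`U(r) = -r` in 3D, subject to the side conditions
:math:`\\sum_i w_i = 0` and :math:`\\sum_i w_i p_i = 0` per output dimension,
which remove the kernel's affine null space.  A regularization scalar
``lam`` >= 0 relaxes exact interpolation (``lam = 0`` interpolates exactly).

A TPS has no closed-form inverse; :func:`invert_transform` refits a TPS on the
swapped (target, source) pairs and tags it approximate.  The quality of such
an inverse is measured by :func:`inverse_consistency`, which reports the
round-trip error ``inv(fwd(p)) - p`` over a seeded uniform sample, mirroring
the practice of returning consistency statistics alongside coordinate
transformation responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import (
    ComplexAxisError,
    ChainMismatch,
    DegenerateConfiguration,
    DimensionMismatch,
    InvalidLambda,
    InvalidSampleCount,
    SingularMatrix,
    SingularSystem,
    SRSMismatch,
    Underdetermined,
)

__all__ = [
    "PointSet",
    "AffineTransform",
    "TPSTransform",
    "CompositeTransform",
    "LiftedPlanarTransform",
    "TransformationRecord",
    "ConsistencyStats",
    "fit_affine",
    "fit_tps",
    "apply_transform",
    "invert_transform",
    "inverse_consistency",
    "compose",
    "load_tie_points",
    "save_tie_points",
]

ATOL = 1e-9  # package-wide absolute comparison tolerance


# ---------------------------------------------------------------------------
# point sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PointSet:
    """One or more points with a mandatory SRS name.

    ``points`` is an ``(n, dim)`` float array (dim 2 or 3).  The optional
    ``out_of_validity_flags`` mark points that fell outside the axis extents
    of the SRS they were expressed in at some step of a transformation.
    """

    srs_name: str
    points: np.ndarray
    out_of_validity_flags: np.ndarray | None = None

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] not in (2, 3):
            raise DimensionMismatch(
                f"points must be (n, 2) or (n, 3), got {pts.shape}")
        if not self.srs_name:
            raise SRSMismatch("PointSet requires a non-empty srs_name")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)
        if self.out_of_validity_flags is not None:
            flags = np.asarray(self.out_of_validity_flags, dtype=bool)
            if flags.shape != (len(pts),):
                raise DimensionMismatch("one flag per point required")
            flags.setflags(write=False)
            object.__setattr__(self, "out_of_validity_flags", flags)

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    def __len__(self) -> int:
        return len(self.points)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PointSet):
            return NotImplemented
        if self.srs_name != other.srs_name:
            return False
        if not np.array_equal(self.points, other.points):
            return False
        a = (np.zeros(len(self), bool) if self.out_of_validity_flags is None
             else self.out_of_validity_flags)
        b = (np.zeros(len(other), bool) if other.out_of_validity_flags is None
             else other.out_of_validity_flags)
        return np.array_equal(a, b)


# ---------------------------------------------------------------------------
# transform classes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffineTransform:
    """Homogeneous affine map; ``matrix`` is ``(dim+1, dim+1)``."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] not in (3, 4):
            raise DimensionMismatch(
                f"affine matrix must be 3x3 or 4x4, got {m.shape}")
        last = np.zeros(m.shape[1])
        last[-1] = 1.0
        if not np.allclose(m[-1], last, atol=ATOL):
            raise SingularMatrix("last row of a homogeneous affine must be "
                                 "(0, ..., 0, 1)")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    @property
    def dim(self) -> int:
        return self.matrix.shape[0] - 1

    @classmethod
    def identity(cls, dim: int) -> "AffineTransform":
        return cls(np.eye(dim + 1))

    @classmethod
    def translation(cls, offset: Sequence[float]) -> "AffineTransform":
        off = np.asarray(offset, dtype=float)
        m = np.eye(len(off) + 1)
        m[:-1, -1] = off
        return cls(m)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        _check_dim(self, pts)
        d = self.dim
        return pts @ self.matrix[:d, :d].T + self.matrix[:d, d]

    def inverse(self) -> "AffineTransform":
        d = self.dim
        lin = self.matrix[:d, :d]
        if abs(np.linalg.det(lin)) < 1e-300:
            raise SingularMatrix("linear block is singular")
        return AffineTransform(np.linalg.inv(self.matrix))

    @property
    def is_approximate(self) -> bool:
        return False

    def to_payload(self) -> dict:
        return {"type": "affine", "dim": self.dim,
                "matrix": self.matrix.tolist()}


def _tps_kernel(r: np.ndarray, dim: int) -> np.ndarray:
    """Polyharmonic radial kernel: r^2 log r in 2D (U(0)=0), -r in 3D."""
    if dim == 2:
        out = np.zeros_like(r)
        pos = r > 0
        out[pos] = r[pos] ** 2 * np.log(r[pos])
        return out
    return -r


@dataclass(frozen=True)
class TPSTransform:
    """Thin-plate-spline landmark interpolant.

    Attributes
    ----------
    control_points : (n, dim) source landmarks
    weights : (n, dim) kernel coefficients, one column per output dimension
    affine_part : (dim+1, dim) coefficients of the affine term, rows ordered
        (constant, x, y[, z])
    lam : regularization scalar used at fit time (0 = exact interpolation)
    approximate : True when the spline was produced by a swapped refit
        (e.g. as the inverse of another TPS)
    """

    control_points: np.ndarray
    weights: np.ndarray
    affine_part: np.ndarray
    lam: float = 0.0
    approximate: bool = False

    def __post_init__(self):
        cp = np.asarray(self.control_points, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        a = np.asarray(self.affine_part, dtype=float)
        d = cp.shape[1]
        if w.shape != cp.shape:
            raise DimensionMismatch("one weight row per control point, one "
                                    "column per output dimension")
        if a.shape != (d + 1, d):
            raise DimensionMismatch(
                f"affine_part must be ({d + 1}, {d}), got {a.shape}")
        for arr, name in ((cp, "control_points"), (w, "weights"),
                          (a, "affine_part")):
            arr.setflags(write=False)
        object.__setattr__(self, "control_points", cp)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "affine_part", a)

    @property
    def dim(self) -> int:
        return self.control_points.shape[1]

    @property
    def is_approximate(self) -> bool:
        return self.approximate

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        _check_dim(self, pts)
        r = np.linalg.norm(pts[:, None, :] - self.control_points[None],
                           axis=2)
        k = _tps_kernel(r, self.dim)
        ones = np.ones((len(pts), 1))
        p = np.hstack([ones, pts])
        return k @ self.weights + p @ self.affine_part

    def side_condition_residual(self) -> float:
        """Max violation of sum(w)=0 and sum(w * p)=0 per output dim."""
        s0 = np.abs(self.weights.sum(axis=0)).max()
        s1 = np.abs(self.control_points.T @ self.weights).max()
        return float(max(s0, s1))

    def inverse(self) -> "TPSTransform":
        targets = self(self.control_points)
        return fit_tps(list(zip(targets, self.control_points)),
                       dim=self.dim, lam=self.lam, _approximate=True)

    def to_payload(self) -> dict:
        return {"type": "tps", "dim": self.dim,
                "control_points": self.control_points.tolist(),
                "weights": self.weights.tolist(),
                "affine_part": self.affine_part.tolist(),
                "lambda": self.lam, "approximate": self.approximate}


@dataclass(frozen=True)
class CompositeTransform:
    """Ordered composition; applying it equals applying each step in order."""

    steps: tuple

    def __post_init__(self):
        object.__setattr__(self, "steps", tuple(self.steps))
        dims = {s.dim for s in self.steps}
        if len(dims) > 1:
            raise DimensionMismatch(f"mixed dimensionalities: {dims}")

    @property
    def dim(self) -> int:
        return self.steps[0].dim

    @property
    def is_approximate(self) -> bool:
        return any(s.is_approximate for s in self.steps)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        out = np.atleast_2d(np.asarray(points, dtype=float))
        for s in self.steps:
            out = s(out)
        return out

    def inverse(self) -> "CompositeTransform":
        return CompositeTransform(tuple(s.inverse()
                                        for s in reversed(self.steps)))

    def to_payload(self) -> dict:
        return {"type": "composite",
                "steps": [s.to_payload() for s in self.steps]}


@dataclass(frozen=True)
class LiftedPlanarTransform:
    """A 2D in-plane transform lifted to 3D with an affine slice-axis map.

    Acts on (x, y, z) as ``(T(x, y), z * z_scale + z_offset)``.  Used to embed
    per-slice 2D registrations of an image stack into the 3D transformation
    graph.
    """

    planar: object  # any 2D transform
    z_scale: float = 1.0
    z_offset: float = 0.0

    @property
    def dim(self) -> int:
        return 3

    @property
    def is_approximate(self) -> bool:
        return getattr(self.planar, "is_approximate", False)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        _check_dim(self, pts)
        xy = self.planar(pts[:, :2])
        z = pts[:, 2] * self.z_scale + self.z_offset
        return np.column_stack([xy, z])

    def inverse(self) -> "LiftedPlanarTransform":
        if self.z_scale == 0:
            raise SingularMatrix("slice-axis map is not invertible")
        return LiftedPlanarTransform(
            self.planar.inverse(), z_scale=1.0 / self.z_scale,
            z_offset=-self.z_offset / self.z_scale)

    def to_payload(self) -> dict:
        return {"type": "lifted_planar", "planar": self.planar.to_payload(),
                "z_scale": self.z_scale, "z_offset": self.z_offset}


def transform_from_payload(d: dict):
    """Rebuild a transform from its JSON-style payload."""
    kind = d["type"]
    if kind == "affine":
        return AffineTransform(np.asarray(d["matrix"]))
    if kind == "tps":
        return TPSTransform(np.asarray(d["control_points"]),
                            np.asarray(d["weights"]),
                            np.asarray(d["affine_part"]),
                            lam=d.get("lambda", 0.0),
                            approximate=d.get("approximate", False))
    if kind == "composite":
        return CompositeTransform(tuple(transform_from_payload(s)
                                        for s in d["steps"]))
    if kind == "lifted_planar":
        return LiftedPlanarTransform(transform_from_payload(d["planar"]),
                                     z_scale=d["z_scale"],
                                     z_offset=d["z_offset"])
    raise ValueError(f"unknown transform payload type {kind!r}")


# ---------------------------------------------------------------------------
# quality metadata and registry records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsistencyStats:
    """Round-trip error statistics of a forward/inverse transform pair."""

    n_samples: int
    seed: int
    mean_error: float
    max_error: float
    rms_error: float

    def __post_init__(self):
        if self.n_samples < 1:
            raise InvalidSampleCount("n_samples must be >= 1")
        if not (0.0 <= self.mean_error <= self.max_error + ATOL):
            raise ValueError("require 0 <= mean_error <= max_error")


@dataclass(frozen=True)
class TransformationRecord:
    """A registered forward mapping between two SRSs.

    ``method`` carries the executable transform payload; ``hub`` names the
    atlas hub serving the transformation; ``inverse_code`` links the record
    registered for the opposite direction, if any.
    """

    code: str
    source_srs: str
    target_srs: str
    hub: str
    method: object
    version: str = "1.0"
    inverse_code: str | None = None
    consistency: ConsistencyStats | None = None

    def __post_init__(self):
        if self.source_srs == self.target_srs:
            raise SRSMismatch("source and target SRS must differ")

    @property
    def dim(self) -> int:
        return self.method.dim

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.method(points)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _split_pairs(pairs, dim: int):
    src = np.asarray([p[0] for p in pairs], dtype=float)
    dst = np.asarray([p[1] for p in pairs], dtype=float)
    if src.ndim != 2 or src.shape[1] != dim or dst.shape != src.shape:
        raise DimensionMismatch(
            f"pairs must be ({len(pairs)}, {dim}) on both sides")
    return src, dst


def _check_not_complex(*srs_descs):
    for d in srs_descs:
        if d is not None and getattr(d, "has_complex_axis", False):
            raise ComplexAxisError(
                f"SRS {d.name!r} has a free-text 'complex' axis; "
                "transformation fitting over it is refused")


def fit_affine(pairs, dim: int, *, source_srs=None,
               target_srs=None) -> AffineTransform:
    """Least-squares affine fit from landmark pairs.

    Requires at least ``dim + 1`` pairs with affinely independent source
    points (non-collinear in 2D, non-coplanar in 3D).  The fit is exact
    (to round-off) when the pairs are consistent with a single affine map.
    """
    _check_not_complex(source_srs, target_srs)
    src, dst = _split_pairs(pairs, dim)
    n = len(src)
    if n < dim + 1:
        raise Underdetermined(
            f"affine fit in {dim}D needs >= {dim + 1} pairs, got {n}")
    design = np.hstack([src, np.ones((n, 1))])
    if np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, np.abs(src).max())) \
            < dim + 1:
        raise DegenerateConfiguration(
            "source points are affinely dependent "
            "(collinear/coplanar or duplicated)")
    sol, *_ = np.linalg.lstsq(design, dst, rcond=None)
    m = np.eye(dim + 1)
    m[:dim, :dim] = sol[:dim].T
    m[:dim, dim] = sol[dim]
    return AffineTransform(m)


def fit_tps(pairs, dim: int, lam: float = 0.0, *, source_srs=None,
            target_srs=None, _approximate: bool = False) -> TPSTransform:
    """Fit a thin-plate spline from landmark pairs.

    At ``lam = 0`` the spline interpolates every landmark exactly; ``lam > 0``
    trades interpolation for smoothness by adding ``lam`` to the kernel
    matrix diagonal.  Duplicate source landmarks make the kernel system
    singular and are rejected.
    """
    if lam < 0:
        raise InvalidLambda(f"lambda must be >= 0, got {lam}")
    _check_not_complex(source_srs, target_srs)
    src, dst = _split_pairs(pairs, dim)
    n = len(src)
    if n < dim + 1:
        raise Underdetermined(
            f"TPS fit in {dim}D needs >= {dim + 1} pairs, got {n}")
    # duplicate source landmarks => zero rows/cols difference => singular
    diff = src[:, None, :] - src[None, :, :]
    r = np.linalg.norm(diff, axis=2)
    off_diag = r[~np.eye(n, dtype=bool)]
    if off_diag.size and off_diag.min() < 1e-12:
        raise SingularSystem("duplicate source landmarks")
    k = _tps_kernel(r, dim) + lam * np.eye(n)
    p = np.hstack([np.ones((n, 1)), src])
    sys_mat = np.zeros((n + dim + 1, n + dim + 1))
    sys_mat[:n, :n] = k
    sys_mat[:n, n:] = p
    sys_mat[n:, :n] = p.T
    rhs = np.zeros((n + dim + 1, dim))
    rhs[:n] = dst
    try:
        sol = np.linalg.solve(sys_mat, rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularSystem(f"TPS system is singular: {exc}") from exc
    w = sol[:n]
    a = sol[n:]
    tps = TPSTransform(src, w, a, lam=lam, approximate=_approximate)
    if tps.side_condition_residual() > 1e-6:
        raise SingularSystem("TPS side conditions violated; source "
                             "configuration is degenerate")
    return tps


# ---------------------------------------------------------------------------
# application / inversion / scoring / composition
# ---------------------------------------------------------------------------

def _check_dim(t, pts: np.ndarray) -> None:
    if pts.shape[1] != t.dim:
        raise DimensionMismatch(
            f"transform is {t.dim}D but points are {pts.shape[1]}D")


def apply_transform(t, ps: PointSet, registry=None) -> PointSet:
    """Apply a transform (or TransformationRecord) to a PointSet.

    When ``t`` is a :class:`TransformationRecord`, ``ps.srs_name`` must match
    its source SRS (by code or name if a registry is supplied) and the output
    is re-tagged with the target SRS.  With a registry available, points
    falling outside the source SRS's axis extents are flagged
    ``out_of_validity`` rather than refused, so near-boundary queries still
    transform.  The input PointSet is never mutated.
    """
    if isinstance(t, TransformationRecord):
        src_id, dst_id = t.source_srs, t.target_srs
        if registry is not None:
            if registry.resolve_code(ps.srs_name) != \
                    registry.resolve_code(src_id):
                raise SRSMismatch(
                    f"PointSet is in {ps.srs_name!r}, transformation expects "
                    f"{src_id!r}")
            dst_id = registry.get_srs(dst_id).name
        elif ps.srs_name not in (src_id,):
            raise SRSMismatch(
                f"PointSet is in {ps.srs_name!r}, transformation expects "
                f"{src_id!r}")
        method = t.method
    else:
        src_id, dst_id, method = ps.srs_name, ps.srs_name, t
    pts = np.array(ps.points, dtype=float)  # defensive copy
    _check_dim(method, pts)
    flags = (np.array(ps.out_of_validity_flags)
             if ps.out_of_validity_flags is not None
             else np.zeros(len(pts), dtype=bool))
    if registry is not None and ps.srs_name in registry:
        ext = registry.get_srs(ps.srs_name).extents()[:pts.shape[1]]
        outside = np.any((pts < ext[:, 0]) | (pts > ext[:, 1]), axis=1)
        flags |= outside
    out = method(pts)
    return PointSet(srs_name=dst_id, points=out, out_of_validity_flags=flags)


def invert_transform(t):
    """Invert a transform: exact for affines, swapped refit for TPS.

    The TPS inverse interpolates the swapped (target, source) landmark pairs
    and is tagged approximate; quantify its quality with
    :func:`inverse_consistency`.
    """
    if isinstance(t, TransformationRecord):
        return replace(
            t, code=t.inverse_code or f"{t.code}-inv",
            source_srs=t.target_srs, target_srs=t.source_srs,
            inverse_code=t.code, method=invert_transform(t.method))
    return t.inverse()


def inverse_consistency(fwd, inv, region, n: int = 1000,
                        seed: int = 0) -> ConsistencyStats:
    """Round-trip error statistics of a forward/inverse pair.

    Draws ``n`` uniform points from ``region`` (a ``(dim, 2)`` array of
    per-axis (min, max) bounds) with a seeded generator and reports the mean,
    max and RMS of ``||inv(fwd(p)) - p||``.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise InvalidSampleCount(f"n must be >= 1, got {n}")
    region = np.asarray(region, dtype=float)
    dim = fwd.dim
    if region.shape != (dim, 2):
        raise DimensionMismatch(
            f"region must be ({dim}, 2) for a {dim}D transform")
    rng = np.random.default_rng(seed)
    pts = rng.uniform(region[:, 0], region[:, 1], size=(n, dim))
    err = np.linalg.norm(inv(fwd(pts)) - pts, axis=1)
    return ConsistencyStats(
        n_samples=n, seed=seed, mean_error=float(err.mean()),
        max_error=float(err.max()),
        rms_error=float(np.sqrt((err ** 2).mean())))


def compose(ts: Sequence):
    """Compose transforms in application order (first applied first).

    Adjacent :class:`TransformationRecord` steps must chain (each target SRS
    equal to the next source SRS) or :class:`ChainMismatch` is raised.  A run
    of pure affines collapses into a single matrix product; anything else
    yields a :class:`CompositeTransform` applying the steps in order.
    """
    ts = list(ts)
    if not ts:
        raise ChainMismatch("cannot compose an empty sequence")
    records = [t for t in ts if isinstance(t, TransformationRecord)]
    if records:
        if len(records) != len(ts):
            raise ChainMismatch("mix of records and bare transforms")
        for a, b in zip(records, records[1:]):
            if a.target_srs != b.source_srs:
                raise ChainMismatch(
                    f"step targets {a.target_srs!r} but next step expects "
                    f"{b.source_srs!r}")
        methods = [r.method for r in records]
    else:
        methods = ts
    dims = {m.dim for m in methods}
    if len(dims) > 1:
        raise DimensionMismatch(f"mixed dimensionalities: {dims}")
    if all(isinstance(m, AffineTransform) for m in methods):
        m = np.eye(methods[0].dim + 1)
        for step in methods:
            m = step.matrix @ m
        return AffineTransform(m)
    return CompositeTransform(tuple(methods))


# ---------------------------------------------------------------------------
# tie-point I/O
# ---------------------------------------------------------------------------

def load_tie_points(path, dim: int | None = None):
    """Read tie-point pairs from CSV columns sx,sy[,sz],tx,ty[,tz]."""
    import csv as _csv
    with open(path, newline="") as fh:
        rows = [r for r in _csv.reader(fh) if r and not r[0].startswith("#")]
    if rows and not _is_number(rows[0][0]):
        rows = rows[1:]  # header
    pairs = []
    for r in rows:
        vals = [float(x) for x in r if x.strip() != ""]
        d = len(vals) // 2
        if len(vals) != 2 * d or d not in (2, 3):
            raise DimensionMismatch(f"bad tie-point row: {r}")
        if dim is not None and d != dim:
            raise DimensionMismatch(
                f"expected {dim}D tie-points, row has {d}D")
        pairs.append((tuple(vals[:d]), tuple(vals[d:])))
    return pairs


def save_tie_points(path, pairs) -> None:
    import csv as _csv
    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        d = len(pairs[0][0]) if pairs else 2
        header = (["sx", "sy", "sz"][:d]) + (["tx", "ty", "tz"][:d])
        w.writerow(header)
        for s, t in pairs:
            w.writerow([repr(float(v)) for v in (*s, *t)])


def _is_number(s: str) -> bool:
    try:
        float(s)
    except ValueError:
        return False
    return True
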