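"""Synthetic phantom atlases, warps and fixtures.

Everything the infrastructure needs to be exercised without downloading real
atlas volumes is generated here, deterministically from seeds: phantom label
volumes built from pairwise-disjoint ellipsoids (so structure membership has
a closed-form point-in-ellipsoid oracle independent of the voxel data),
slice stacks with smooth intensity texture for registration, known smooth
warps with ground-truth tie-points, seeded object stores, and the seven-SRS
mouse registry fixture with its star-topology transformation graph around
Waxholm Space 0.9.

The registry fixture's axis extents and inter-atlas affines are synthetic
placeholders — the published record gives codes, names, families, versions
and prose descriptions, not numeric geometry — and are marked as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .chain_resolver import TransformationGraph
from .errors import TooManyStructures
from .objects import ObjectRecord
from .registration import warp_image
from .srs_registry import (
    AxisSpec,
    Registry,
    SRSDescription,
    StructureRecord,
)
from .transforms import (
    AffineTransform,
    TransformationRecord,
    fit_tps,
    inverse_consistency,
    invert_transform,
)

__all__ = [
    "PhantomStructure", "PhantomAtlas", "WarpSpec",
    "make_phantom_atlas", "make_warped_copy", "make_table1_registry",
    "make_object_store", "register_phantom",
]


# ---------------------------------------------------------------------------
# phantom atlases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomStructure:
    name: str
    label: int
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def contains(self, point) -> bool:
        """Closed-form point-in-ellipsoid membership test."""
        p = np.asarray(point, dtype=float)
        c = np.asarray(self.center)
        r = np.asarray(self.radii)
        return bool(np.sum(((p - c) / r) ** 2) <= 1.0)


@dataclass(frozen=True)
class PhantomAtlas:
    """A synthetic label volume standing in for a real reference atlas.

    The volume is indexed ``labels[x, y, z]`` (0 = background, 1..n =
    structures); coordinates are in voxel units so world and index space
    coincide.  ``slice_index`` runs along Z.
    """

    seed: int
    shape: tuple[int, int, int]
    voxel_size_mm: float
    labels: np.ndarray
    structures: tuple[PhantomStructure, ...]
    srs_code: str
    srs_name: str

    def label_slice(self, k: int) -> np.ndarray:
        """2D label plate for slice k, image-indexed (row=y, col=x)."""
        return self.labels[:, :, k].T.copy()

    def intensity_slice(self, k: int) -> np.ndarray:
        """Smooth intensity plate for slice k, suitable for registration."""
        base = self.labels[:, :, k].T.astype(float) * 60.0
        smooth = ndimage.gaussian_filter(base, sigma=2.0)
        ny, nx = smooth.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        gradient = 20.0 * (xx / max(nx - 1, 1) + yy / max(ny - 1, 1))
        return smooth + gradient

    def structure_at(self, point) -> PhantomStructure | None:
        """Analytic structure lookup (independent of the label volume)."""
        for s in self.structures:
            if s.contains(point):
                return s
        return None

    def srs_description(self) -> SRSDescription:
        nx, ny, nz = self.shape
        axes = (
            AxisSpec("X", "left-to-right", "voxel", 0.0, float(nx),
                     voxel_size_mm=self.voxel_size_mm),
            AxisSpec("Y", "dorsal-to-ventral", "voxel", 0.0, float(ny),
                     voxel_size_mm=self.voxel_size_mm),
            AxisSpec("Z", "posterior-to-anterior", "voxel", 0.0, float(nz),
                     voxel_size_mm=self.voxel_size_mm),
        )
        return SRSDescription(
            code=self.srs_code, name=self.srs_name,
            srs_family="Phantom", version="1.0", species="Mouse",
            description=f"synthetic phantom atlas (seed={self.seed})",
            origin_description="corner voxel (0, 0, 0)", axes=axes,
            region_of_validity="whole phantom", author="synthetic")

    def save_nifti(self, path) -> None:
        import nibabel as nib
        affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine),
                 str(path))


def make_phantom_atlas(seed: int, shape=(48, 48, 32), n_structures: int = 3,
                       srs_code: str = "LOCAL:0900",
                       srs_name: str | None = None,
                       voxel_size_mm: float = 0.1,
                       min_radius: float = 4.0,
                       max_radius: float | None = None) -> PhantomAtlas:
    """Generate a phantom label volume of pairwise-disjoint ellipsoids.

    Placement is by seeded rejection sampling on bounding boxes, so disjoint
    structures are guaranteed by construction; labels 1..n are all present.
    Raises :class:`TooManyStructures` when the requested count cannot be
    placed in the given shape.
    """
    if n_structures < 1:
        raise TooManyStructures("n_structures must be >= 1")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    if max_radius is None:
        max_radius = max(min_radius + 1.0, min(shape) / 5.0)
    placed: list[tuple[np.ndarray, np.ndarray]] = []
    attempts, max_attempts = 0, 2000 * n_structures
    while len(placed) < n_structures:
        attempts += 1
        if attempts > max_attempts:
            raise TooManyStructures(
                f"could not place {n_structures} disjoint ellipsoids in "
                f"shape {shape}")
        radii = rng.uniform(min_radius, max_radius, size=3)
        lo = radii + 1.0
        hi = np.asarray(shape) - radii - 1.0
        if np.any(hi <= lo):
            raise TooManyStructures(
                f"shape {shape} too small for radius {max_radius}")
        center = rng.uniform(lo, hi)
        box_lo, box_hi = center - radii - 0.5, center + radii + 0.5
        if any(np.all(box_lo < phi) and np.all(plo < box_hi)
               for plo, phi in placed):
            continue
        placed.append((box_lo, box_hi))
        if len(placed) == 1:
            centers, radiis = [center], [radii]
        else:
            centers.append(center)
            radiis.append(radii)
    labels = np.zeros(shape, dtype=np.int16)
    xs, ys, zs = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
    structures = []
    for i, (c, r) in enumerate(zip(centers, radiis), start=1):
        mask = (((xs - c[0]) / r[0]) ** 2 + ((ys - c[1]) / r[1]) ** 2
                + ((zs - c[2]) / r[2]) ** 2) <= 1.0
        labels[mask] = i
        structures.append(PhantomStructure(
            name=f"structure_{i:02d}", label=i,
            center=tuple(float(v) for v in c),
            radii=tuple(float(v) for v in r)))
    return PhantomAtlas(
        seed=seed, shape=shape, voxel_size_mm=voxel_size_mm, labels=labels,
        structures=tuple(structures), srs_code=srs_code,
        srs_name=srs_name or f"Phantom_{srs_code.replace(':', '_')}")


def register_phantom(registry: Registry, phantom: PhantomAtlas
                     ) -> SRSDescription:
    """Register a phantom's SRS and structure table in a registry."""
    desc = phantom.srs_description()
    registry.register_srs(desc)
    for s in phantom.structures:
        registry.add_structure(StructureRecord(
            srs_code=desc.code, structure_name=s.name,
            vocabulary_ref="phantom-vocabulary", geometry_ref=s.label))
    return desc


# ---------------------------------------------------------------------------
# known warps with ground-truth tie-points
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WarpSpec:
    """Specification of a synthetic 2D warp with known ground truth."""

    seed: int
    family: str = "sinusoidal-tps"  # or "affine"
    magnitude: float = 2.0  # peak displacement, in pixels
    n_tiepoints: int = 25

    def __post_init__(self):
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.family not in ("affine", "sinusoidal-tps"):
            raise ValueError(f"unknown warp family {self.family!r}")


def _tiepoint_grid(shape, n: int) -> np.ndarray:
    """Roughly square interior grid of about n points, (x, y) order."""
    h, w = shape
    g = max(2, int(round(np.sqrt(n))))
    xs = np.linspace(0.1 * (w - 1), 0.9 * (w - 1), g)
    ys = np.linspace(0.1 * (h - 1), 0.9 * (h - 1), g)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def make_warped_copy(slice_image: np.ndarray, warp: WarpSpec):
    """Produce a warped copy of a plate with its ground-truth transform.

    Returns ``(warped_image, true_transform, tie_points)`` where the true
    transform maps warped-image pixel coordinates to plate coordinates and
    each tie-point pair ``(source, target)`` satisfies
    ``true_transform(source) == target`` exactly.  The warped image is
    produced by :func:`~atlasdai.registration.warp_image` using the true
    transform as the pull-back map, so ``warped(p) = plate(T(p))``.
    Magnitude zero yields a pixel-identical copy and an identity transform.
    """
    img = np.asarray(slice_image, dtype=float)
    rng = np.random.default_rng(warp.seed)
    h, w = img.shape
    grid = _tiepoint_grid((h, w), warp.n_tiepoints)
    m = warp.magnitude
    if warp.family == "affine":
        theta = 0.01 * m * rng.uniform(-1, 1)
        scale = 1.0 + 0.002 * m * rng.uniform(-1, 1)
        shift = m * rng.uniform(-1, 1, size=2)
        c, s = np.cos(theta), np.sin(theta)
        mat = np.eye(3)
        mat[:2, :2] = scale * np.array([[c, -s], [s, c]])
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        mat[:2, 2] = center - mat[:2, :2] @ center + shift
        true_t = AffineTransform(mat)
    else:
        phases = rng.uniform(0, 2 * np.pi, size=4)
        dx = m * np.sin(2 * np.pi * grid[:, 0] / w + phases[0]) \
            * np.cos(2 * np.pi * grid[:, 1] / h + phases[1])
        dy = m * np.sin(2 * np.pi * grid[:, 1] / h + phases[2]) \
            * np.cos(2 * np.pi * grid[:, 0] / w + phases[3])
        targets = grid + np.column_stack([dx, dy])
        if m == 0:
            true_t = AffineTransform.identity(2)
        else:
            true_t = fit_tps(list(zip(grid, targets)), dim=2)
    tie_points = [(tuple(p), tuple(q))
                  for p, q in zip(grid, true_t(grid))]
    warped = warp_image(img, inverse=true_t, output_shape=(h, w))
    return warped, true_t, tie_points


# ---------------------------------------------------------------------------
# the seven-SRS mouse registry fixture
# ---------------------------------------------------------------------------

_TABLE1_ROWS = [
    # code, name, family, version, description
    ("INCF:0001", "Mouse_WHS_0.9", "WHS", "0.9",
     "WHS initial version, with origin in the back-left-bottom corner"),
    ("INCF:0002", "Mouse_WHS_1.0", "WHS", "1.0",
     "WHS with origin shifted to the intersection of midline and the center"
     " of anterior commissure"),
    ("INCF:0100", "Mouse_ABAvoxel_1.0", "ABAvoxel", "1.0",
     "SRS used in the Allen Mouse Brain Atlas 3D model (circa 2005)"),
    ("INCF:0101", "Mouse_ABAreference_1.0", "ABAreference", "1.0",
     "SRS in the Allen Mouse Brain Atlas reference atlas"),
    ("INCF:0102", "Mouse_AGEA_1.0", "AGEA", "1.0",
     "SRS used in the Allen Mouse Brain Atlas gene expression module, a"
     " derivative of ABAvoxel"),
    ("INCF:0200", "Mouse_Paxinos_1.0", "Paxinos", "1.0",
     "SRS in the Paxinos and Franklin stereotaxic atlas of the mouse brain"),
    ("INCF:0300", "Mouse_EMAP-T23_1.0", "EMAP-T23", "1.0",
     "A T23 model of EMAP developing mouse atlas"),
]

#: hub hosting the star edge of each non-hub SRS (to/from Mouse_WHS_0.9)
_EDGE_HUBS = {
    "INCF:0002": "WHS",
    "INCF:0100": "ABA",
    "INCF:0101": "ABA",
    "INCF:0102": "ABA",   # the direct AGEA<->WHS_0.9 edge is served by ABA
    "INCF:0200": "UCSD",  # WHS_0.9<->Paxinos is served by UCSD
    "INCF:0300": "WHS",
}

_WHS09 = "INCF:0001"


def _placeholder_axes(lo: float, hi: float):
    """Synthetic, non-anatomical placeholder extents in mm."""
    return (AxisSpec("X", "left-to-right", "mm", lo, hi),
            AxisSpec("Y", "posterior-to-anterior", "mm", lo, hi),
            AxisSpec("Z", "ventral-to-dorsal", "mm", lo, hi))


def make_table1_registry(seed: int = 20140912,
                         consistency_n: int = 100
                         ) -> tuple[Registry, TransformationGraph]:
    """The seven registered mouse SRSs with a star transformation graph.

    Every SRS other than Mouse_WHS_0.9 is linked to it by a seeded synthetic
    affine (forward and inverse registered as independent edges), so any
    chain between two non-WHS_0.9 systems takes exactly two steps through
    the common go-between space.  The AGEA edge is served by the ABA hub and
    the Paxinos edge by the UCSD hub; extents and affines are synthetic
    placeholders, deterministic for a fixed seed.
    """
    reg = Registry()
    for i, (code, name, family, version, desc) in enumerate(_TABLE1_ROWS):
        lo, hi = (-5.0, 5.0) if family == "Paxinos" else (0.0, 10.0)
        origin = ("back-left-bottom corner" if code == _WHS09
                  else "synthetic placeholder origin")
        reg.register_srs(SRSDescription(
            code=code, name=name, srs_family=family, version=version,
            species="Mouse", description=desc, origin_description=origin,
            axes=_placeholder_axes(lo, hi),
            region_of_validity="whole brain", author="registry fixture"))
    graph = TransformationGraph(registry=reg)
    rng = np.random.default_rng(seed)
    region = reg.get_srs(_WHS09).extents()
    for code, hub in sorted(_EDGE_HUBS.items()):
        # small seeded affine: near-identity rotation+scale plus offset
        angle = rng.uniform(-0.2, 0.2)
        scale = rng.uniform(0.8, 1.2)
        shift = rng.uniform(-1.0, 1.0, size=3)
        c, s = np.cos(angle), np.sin(angle)
        mat = np.eye(4)
        mat[0, 0] = scale * c
        mat[0, 1] = -scale * s
        mat[1, 0] = scale * s
        mat[1, 1] = scale * c
        mat[2, 2] = scale
        mat[:3, 3] = shift
        fwd = AffineTransform(mat)
        inv = invert_transform(fwd)
        short = code.split(":")[1]
        fwd_code = f"TX:{short}-0001"
        inv_code = f"TX:0001-{short}"
        stats = inverse_consistency(fwd, inv, region, n=consistency_n,
                                    seed=seed)
        graph.add_transformation(TransformationRecord(
            code=fwd_code, source_srs=code, target_srs=_WHS09, hub=hub,
            method=fwd, version="1.0", inverse_code=inv_code,
            consistency=stats))
        graph.add_transformation(TransformationRecord(
            code=inv_code, source_srs=_WHS09, target_srs=code, hub=hub,
            method=inv, version="1.0", inverse_code=fwd_code,
            consistency=stats))
    return reg, graph


# ---------------------------------------------------------------------------
# object stores
# ---------------------------------------------------------------------------

_MODALITIES = ("histology", "MRI", "immunofluorescence", "Nissl")


def make_object_store(seed: int, n_images: int, srs_name: str,
                      extents) -> list[ObjectRecord]:
    """Seeded random 2D-image records with boxes inside the given extents.

    ``extents`` is a (dim, 2) array of per-axis (min, max) bounds; all
    generated boxes lie within it.  Deterministic for a fixed seed.
    """
    if n_images < 0:
        raise ValueError("n_images must be >= 0")
    rng = np.random.default_rng(seed)
    extents = np.asarray(extents, dtype=float)
    span = extents[:, 1] - extents[:, 0]
    out = []
    for i in range(n_images):
        center = rng.uniform(extents[:, 0] + 0.1 * span,
                             extents[:, 1] - 0.1 * span)
        half = rng.uniform(0.02, 0.25, size=len(span)) * span
        lo = np.maximum(center - half, extents[:, 0])
        hi = np.minimum(center + half, extents[:, 1])
        out.append(ObjectRecord(
            object_kind="image2d", srs_name=srs_name,
            extent=tuple((float(a), float(b)) for a, b in zip(lo, hi)),
            title=f"image_{i:03d}",
            modality=_MODALITIES[int(rng.integers(len(_MODALITIES)))],
            provenance=f"synthetic object store (seed={seed})"))
    return out
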