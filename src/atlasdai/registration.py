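"""Data-publication workflow: registering 2D image collections to an atlas.

The workflow mirrors how user-supplied slice images enter the atlasing
infrastructure: a *manifest* captures the uploaded collection with checksums,
thumbnails and provenance; each image is aligned to a target atlas plate from
user-supplied *tie-points* (corresponding point pairs) by an affine
least-squares stage followed by a thin-plate-spline correction; the fitted
transform warps the image onto the plate grid; finally a new spatial
reference system is derived for the collection, with forward and inverse
transformations to the target atlas registered in the chain graph so the
user's coordinates become queryable across hubs.

Image coordinate convention: pixel centers, origin at the top-left pixel,
x rightward (columns), y downward (rows), 0-based.  Plate coordinates are in
the plate SRS's units.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .chain_resolver import TransformationGraph
from .errors import (
    DegenerateConfiguration,
    EmptyCollection,
    NonInvertibleOverGrid,
    SingularMatrix,
    Underdetermined,
    UnknownTargetSRS,
    UnreadableImage,
)
from .srs_registry import AxisSpec, Registry, SliceRecord, SRSDescription
from .transforms import (
    AffineTransform,
    ConsistencyStats,
    LiftedPlanarTransform,
    TPSTransform,
    compose,
    fit_affine,
    fit_tps,
    inverse_consistency,
    invert_transform,
    TransformationRecord,
)

__all__ = [
    "ManifestEntry", "Manifest", "TiePointSet", "RegistrationResult",
    "build_manifest", "align_image", "warp_image", "derive_srs",
]


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestEntry:
    filename: str
    checksum: str  # sha256 hex digest of the file bytes
    width: int
    height: int
    pixel_size: float
    thumbnail_path: str | None = None


@dataclass
class Manifest:
    """Provenance record of an uploaded image collection."""

    collection_name: str
    entries: list[ManifestEntry] = field(default_factory=list)
    #: ordered processing-step records: (step name, iso timestamp, params)
    provenance: list[tuple[str, str, dict]] = field(default_factory=list)

    def add_step(self, name: str, **params) -> None:
        ts = time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())
        self.provenance.append((name, ts, params))

    def to_dict(self) -> dict:
        return {
            "collection_name": self.collection_name,
            "entries": [vars(e) | {} for e in self.entries],
            "provenance": [{"step": s, "timestamp": t, "params": p}
                           for s, t, p in self.provenance],
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load_json(cls, path) -> "Manifest":
        with open(path) as fh:
            d = json.load(fh)
        m = cls(collection_name=d["collection_name"])
        m.entries = [ManifestEntry(**e) for e in d["entries"]]
        m.provenance = [(p["step"], p["timestamp"], p["params"])
                        for p in d["provenance"]]
        return m

    def verify_checksums(self, base_dir=".") -> list[str]:
        """Names of entries whose file bytes no longer match the manifest."""
        bad = []
        for e in self.entries:
            p = Path(base_dir) / e.filename
            if not p.exists() or _sha256(p) != e.checksum:
                bad.append(e.filename)
        return bad


def load_manifest_files(directory) -> list[Path]:
    """Image files (png/tif/tiff) in a directory, lexicographic order."""
    d = Path(directory)
    exts = {".png", ".tif", ".tiff"}
    return sorted(p for p in d.iterdir() if p.suffix.lower() in exts)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def build_manifest(files, collection_name: str = "collection",
                   pixel_size: float = 1.0,
                   thumbnail_dir=None, thumbnail_max: int = 128) -> Manifest:
    """Manifest an image collection: checksums, sizes, thumbnails.

    Entry order is deterministic (lexicographic by filename).  Thumbnails are
    sub-sampled copies written to ``thumbnail_dir`` when given.  Unreadable
    files raise :class:`UnreadableImage` naming the file.
    """
    manifest = Manifest(collection_name=collection_name)
    for f in sorted(Path(f) for f in files):
        try:
            with Image.open(f) as im:
                w, h = im.size
                thumb_path = None
                if thumbnail_dir is not None:
                    scale = max(1, max(w, h) // thumbnail_max)
                    thumb = im.resize((max(1, w // scale),
                                       max(1, h // scale)))
                    thumb_path = str(Path(thumbnail_dir)
                                     / f"{f.stem}_thumb.png")
                    thumb.save(thumb_path)
        except (OSError, ValueError) as exc:
            raise UnreadableImage(f"cannot read image {f}: {exc}") from exc
        manifest.entries.append(ManifestEntry(
            filename=f.name, checksum=_sha256(f), width=w, height=h,
            pixel_size=pixel_size, thumbnail_path=thumb_path))
    manifest.add_step("build_manifest", n_files=len(manifest.entries),
                      pixel_size=pixel_size)
    return manifest


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TiePointSet:
    """User-defined correspondence pairs linking an image to an atlas plate.

    ``pairs`` holds (image pixel coordinate, plate coordinate) tuples; at
    least 3 non-collinear pairs are required for a 2D alignment, and image-
    side points must be distinct.
    """

    image_id: str
    target_srs: str
    slice_index: int
    pairs: tuple

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple(
            (tuple(map(float, s)), tuple(map(float, t)))
            for s, t in self.pairs))

    def source_points(self) -> np.ndarray:
        return np.array([s for s, _ in self.pairs])

    def target_points(self) -> np.ndarray:
        return np.array([t for _, t in self.pairs])


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of aligning one image to an atlas plate."""

    image_id: str
    target_srs: str
    slice_index: int
    affine_stage: AffineTransform
    tps_stage: TPSTransform
    consistency: ConsistencyStats
    warped_image_path: str | None = None

    @property
    def forward(self):
        """Composite image-to-plate transform (affine then TPS)."""
        return compose([self.affine_stage, self.tps_stage])

    @property
    def inverse(self):
        """Approximate plate-to-image transform (swapped-refit TPS inverse
        followed by the exact affine inverse)."""
        return compose([invert_transform(self.tps_stage),
                        invert_transform(self.affine_stage)])


def align_image(image: np.ndarray, tie_points: TiePointSet,
                lam: float = 0.0,
                consistency_n: int = 1000,
                consistency_seed: int = 0) -> RegistrationResult:
    """Align an image to its target plate from tie-points.

    Stage 1 fits an affine map by least squares over all pairs; stage 2 fits
    a thin-plate spline on the affine-mapped image points so the composite
    maps every image tie-point exactly onto its plate tie-point (at
    ``lam = 0``).  Inverse-consistency statistics of the composite against
    its swapped-refit inverse are computed over the plate-side landmark
    bounding box with a seeded sample.
    """
    pairs = tie_points.pairs
    if len(pairs) < 3:
        raise Underdetermined(
            f"2D alignment needs >= 3 tie-points, got {len(pairs)}")
    src = tie_points.source_points()
    dst = tie_points.target_points()
    affine = fit_affine(list(zip(src, dst)), dim=2)
    mid = affine(src)
    tps = fit_tps(list(zip(mid, dst)), dim=2, lam=lam)
    forward = compose([affine, tps])
    inverse = compose([invert_transform(tps), invert_transform(affine)])
    lo, hi = src.min(axis=0), src.max(axis=0)
    span = np.maximum(hi - lo, 1e-6)
    region = np.column_stack([lo, lo + span])
    stats = inverse_consistency(forward, inverse, region,
                                n=consistency_n, seed=consistency_seed)
    return RegistrationResult(
        image_id=tie_points.image_id, target_srs=tie_points.target_srs,
        slice_index=tie_points.slice_index, affine_stage=affine,
        tps_stage=tps, consistency=stats)


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------

def warp_image(image: np.ndarray, transform=None, output_shape=None,
               background: float = 0.0, inverse=None) -> np.ndarray:
    """Resample an image through a coordinate transform.

    ``transform`` maps source image coordinates (x, y) to output-grid
    coordinates.  Resampling is by inverse mapping: each output pixel center
    is pulled back through the transform's inverse and the source is sampled
    with bilinear interpolation; pixels that land outside the source are
    filled with ``background``.  For a TPS the inverse is the swapped-refit
    approximation; pass a better ``inverse`` explicitly if one is known.
    """
    image = np.asarray(image, dtype=float)
    if output_shape is None:
        output_shape = image.shape[:2]
    if inverse is None:
        if transform is None:
            raise NonInvertibleOverGrid(
                "warp_image needs a transform or an explicit inverse")
        try:
            inverse = invert_transform(transform)
        except (SingularMatrix, DegenerateConfiguration) as exc:
            raise NonInvertibleOverGrid(str(exc)) from exc
    h, w = output_shape
    ys, xs = np.mgrid[0:h, 0:w]
    out_pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    src_pts = inverse(out_pts)
    if not np.all(np.isfinite(src_pts)):
        raise NonInvertibleOverGrid(
            "inverse transform is not finite over the output grid")
    # map_coordinates expects (row, col) = (y, x)
    coords = np.vstack([src_pts[:, 1], src_pts[:, 0]])
    warped = ndimage.map_coordinates(image, coords, order=1,
                                     mode="constant", cval=background)
    return warped.reshape(h, w)


# ---------------------------------------------------------------------------
# deriving a new SRS
# ---------------------------------------------------------------------------

def _slice_record(code: str, r: RegistrationResult) -> SliceRecord:
    """Per-slice placement row: the affine stage as a 2D-to-plate map."""
    m = np.zeros((3, 3))
    m[:2, :2] = r.affine_stage.matrix[:2, :2]
    m[:2, 2] = r.affine_stage.matrix[:2, 2]
    m[2, 2] = 1.0
    return SliceRecord(srs_code=code, slice_index=r.slice_index,
                       plane="coronal", in_plane_to_3d=tuple(m.ravel()))

def derive_srs(collection_name: str, results, target_srs: str,
               registry: Registry, graph: TransformationGraph,
               hub: str = "local", author: str = "",
               pixel_size_mm: float = 0.02) -> SRSDescription:
    """Derive a registered SRS for an aligned image collection.

    Creates (or updates in place, when re-invoked with more registered
    slices) an SRS in the user namespace ``LOCAL:``, named after the
    collection, whose X/Y extents are the union of the registered images'
    tie-point extents in image pixels and whose Z axis is the slice index.
    Per-slice placements are stored as Slice table rows; a representative
    forward/inverse transformation pair to ``target_srs`` (the 2D composite
    of the first slice, lifted to 3D with an identity slice-index map) is
    registered in the chain graph so the new SRS becomes chain-reachable.
    """
    results = list(results)
    if not results:
        raise EmptyCollection("derive_srs requires at least one "
                              "registration result")
    if target_srs not in registry:
        raise UnknownTargetSRS(f"target SRS {target_srs!r} is not registered")
    target_code = registry.resolve_code(target_srs)

    # union of per-image tie-point source extents, in pixels
    boxes = np.array([
        [r.tps_stage.control_points.min(axis=0),
         r.tps_stage.control_points.max(axis=0)] for r in results])
    lo = boxes[:, 0, :].min(axis=0)
    hi = boxes[:, 1, :].max(axis=0)
    z_indices = [r.slice_index for r in results]
    z_lo, z_hi = float(min(z_indices)), float(max(z_indices) + 1)

    axes = (
        AxisSpec("X", "left-to-right", "voxel", float(lo[0]), float(hi[0]),
                 voxel_size_mm=pixel_size_mm),
        AxisSpec("Y", "dorsal-to-ventral", "voxel", float(lo[1]),
                 float(hi[1]), voxel_size_mm=pixel_size_mm),
        AxisSpec("Z", "posterior-to-anterior", "voxel", z_lo, z_hi,
                 voxel_size_mm=pixel_size_mm),
    )
    existing = None
    try:
        existing = registry.get_srs(collection_name)
    except Exception:
        pass
    if existing is not None and existing.code.startswith("LOCAL:"):
        desc = replace(existing, axes=axes,
                       region_of_validity=f"registered slices "
                                          f"{sorted(set(z_indices))}")
        registry.update_srs(desc)
        present = {s.slice_index for s in registry.slices
                   if s.srs_code == desc.code}
        for r in sorted(results, key=lambda r: r.slice_index):
            if r.slice_index not in present:
                registry.add_slice(_slice_record(desc.code, r))
        return desc

    code = registry.next_local_code()
    desc = SRSDescription(
        code=code, name=collection_name, srs_family=collection_name,
        version="1.0", species=registry.get_srs(target_code).species,
        description=f"user collection {collection_name!r} registered to "
                    f"{registry.get_srs(target_code).name}",
        origin_description="top-left pixel of the registered images",
        axes=axes,
        region_of_validity=f"registered slices {sorted(set(z_indices))}",
        author=author, derived_from=target_code)
    registry.register_srs(desc)

    for r in sorted(results, key=lambda r: r.slice_index):
        registry.add_slice(_slice_record(code, r))

    rep = results[0]
    fwd3 = LiftedPlanarTransform(rep.forward)
    inv3 = LiftedPlanarTransform(rep.inverse)
    fwd_code = f"{code}-to-{target_code}"
    inv_code = f"{target_code}-to-{code}"
    graph.add_transformation(TransformationRecord(
        code=fwd_code, source_srs=code, target_srs=target_code, hub=hub,
        method=fwd3, inverse_code=inv_code, consistency=rep.consistency))
    graph.add_transformation(TransformationRecord(
        code=inv_code, source_srs=target_code, target_srs=code, hub=hub,
        method=inv3, inverse_code=fwd_code, consistency=rep.consistency))
    return desc
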