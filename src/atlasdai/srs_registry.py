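"""Registry of brain spatial reference systems (SRSs).

A spatial reference system (SRS) for the rodent brain is a named coordinate
system: an origin description, three oriented axes with measurement units and
valid extents, a region of validity (an anatomical structure set or the whole
brain), and provenance (author, derivation).  Mirroring geodetic practice
(EPSG-style registries), each SRS carries a unique code such as ``INCF:0001``
and a unique name such as ``Mouse_WHS_0.9``; software references systems by
either.

The registry also keeps the optional per-SRS tables: *Structure* (delineated
anatomical structures with label values), *Fiducial* (recognizable landmark
points), and *Slice* (per-plate 2D-to-3D placements for atlases defined as
stacks of 2D plates).
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DuplicateCode,
    DuplicateName,
    NotFound,
    ValidationError,
)

__all__ = [
    "AxisSpec",
    "SRSDescription",
    "StructureRecord",
    "FiducialRecord",
    "SliceRecord",
    "Registry",
    "Violation",
    "validate_srs",
    "DIRECTION_VECTORS",
    "COMPLEX_DIRECTION",
]

#: Controlled anatomical direction terms, mapped to signed unit vectors in the
#: canonical interior frame (left-to-right = +x, posterior-to-anterior = +y,
#: ventral-to-dorsal = +z).  Orthogonality of an SRS's three axes is checked
#: in this frame.
DIRECTION_VECTORS: dict[str, tuple[int, int, int]] = {
    "left-to-right": (1, 0, 0),
    "right-to-left": (-1, 0, 0),
    "posterior-to-anterior": (0, 1, 0),
    "anterior-to-posterior": (0, -1, 0),
    "ventral-to-dorsal": (0, 0, 1),
    "dorsal-to-ventral": (0, 0, -1),
}

#: Free-text marker for curved/derived axes (e.g. developing-brain axes) that
#: cannot be expressed as a straight anatomical direction.  Such axes are
#: storable but refuse transformation fitting.
COMPLEX_DIRECTION = "complex"

_UNITS = ("mm", "um", "voxel")

# arrows and unicode micro signs are normalised to the ASCII vocabulary
_DIRECTION_ALIASES = {
    "left→right": "left-to-right",
    "right→left": "right-to-left",
    "posterior→anterior": "posterior-to-anterior",
    "anterior→posterior": "anterior-to-posterior",
    "dorsal→ventral": "dorsal-to-ventral",
    "ventral→dorsal": "ventral-to-dorsal",
}
_UNIT_ALIASES = {"µm": "um", "μm": "um", "micron": "um", "millimeter": "mm"}


def normalize_direction(term: str) -> str:
    return _DIRECTION_ALIASES.get(term, term)


def normalize_unit(unit: str) -> str:
    return _UNIT_ALIASES.get(unit, unit)


@dataclass(frozen=True)
class AxisSpec:
    """One coordinate axis of an SRS.

    Parameters
    ----------
    axis_label
        ``"X"``, ``"Y"`` or ``"Z"``.
    anatomical_direction
        Controlled term (see :data:`DIRECTION_VECTORS`) or ``"complex"``.
    unit
        ``"mm"``, ``"um"`` or ``"voxel"``.
    extent_min, extent_max
        Valid coordinate bounds along the axis, in ``unit``.
    voxel_size_mm
        Physical voxel pitch; required for cross-SRS use when ``unit`` is
        ``"voxel"``.
    """

    axis_label: str
    anatomical_direction: str
    unit: str
    extent_min: float
    extent_max: float
    voxel_size_mm: float | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "anatomical_direction",
            normalize_direction(self.anatomical_direction))
        object.__setattr__(self, "unit", normalize_unit(self.unit))

    @property
    def is_complex(self) -> bool:
        return self.anatomical_direction == COMPLEX_DIRECTION

    def direction_vector(self) -> tuple[int, int, int] | None:
        return DIRECTION_VECTORS.get(self.anatomical_direction)


@dataclass(frozen=True)
class SRSDescription:
    """A named brain spatial reference system."""

    code: str
    name: str
    srs_family: str
    version: str
    species: str
    description: str = ""
    origin_description: str = ""
    axes: tuple[AxisSpec, ...] = ()
    region_of_validity: str = "whole brain"
    author: str = ""
    derived_from: str | None = None
    reference_implementation: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "axes", tuple(self.axes))

    @property
    def has_complex_axis(self) -> bool:
        return any(a.is_complex for a in self.axes)

    def axis(self, label: str) -> AxisSpec:
        for a in self.axes:
            if a.axis_label == label:
                return a
        raise KeyError(label)

    def extents(self) -> np.ndarray:
        """(3, 2) array of per-axis (min, max) bounds, in axis order X,Y,Z."""
        return np.array(
            [[a.extent_min, a.extent_max] for a in self.axes], dtype=float)


@dataclass(frozen=True)
class StructureRecord:
    """A delineated anatomical structure of an SRS."""

    srs_code: str
    structure_name: str
    vocabulary_ref: str | None = None
    #: label value in a label volume (positive integer), or a per-slice
    #: polygon reference string
    geometry_ref: int | str | None = None


@dataclass(frozen=True)
class FiducialRecord:
    """A recognizable landmark point of an SRS, usable for alignment."""

    srs_code: str
    fiducial_name: str
    point: tuple[float, float, float]


@dataclass(frozen=True)
class SliceRecord:
    """Placement of one 2D plate of a plate-stack SRS into its 3D frame.

    ``in_plane_to_3d`` is a flattened 3x3 affine taking plate coordinates
    (u, v, 1) to 3D SRS coordinates; row-major, 9 values mapping to a
    (3, 3) matrix whose columns act on (u, v, 1).
    """

    srs_code: str
    slice_index: int
    plane: str  # coronal | sagittal | horizontal
    in_plane_to_3d: tuple[float, ...]

    def mapping_matrix(self) -> np.ndarray:
        return np.asarray(self.in_plane_to_3d, dtype=float).reshape(3, 3)


@dataclass(frozen=True)
class Violation:
    """One validation failure, locating the offending field."""

    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.field}: {self.message}"


_CODE_PREFIXES = ("INCF:", "LOCAL:")


def validate_srs(desc: SRSDescription) -> list[Violation]:
    """Validate an SRS description; an empty report means registrable.

    Checks the code pattern, presence of exactly three distinctly-labelled
    axes, controlled direction vocabulary, unit vocabulary (voxel axes must
    declare a physical voxel size), extent ordering, and mutual orthogonality
    of the three anatomical directions (skipped if any axis is "complex").
    """
    v: list[Violation] = []
    code = desc.code
    ok_prefix = any(code.startswith(p) for p in _CODE_PREFIXES)
    if not (ok_prefix and code.split(":", 1)[1].isdigit()):
        v.append(Violation("code", f"code {code!r} does not match 'INCF:NNNN'"
                                   " or 'LOCAL:NNNN'"))
    if not desc.name:
        v.append(Violation("name", "name must be non-empty"))
    if len(desc.axes) != 3:
        v.append(Violation("axes", f"expected exactly 3 axes, got "
                                   f"{len(desc.axes)}"))
    labels = [a.axis_label for a in desc.axes]
    if len(set(labels)) != len(labels):
        v.append(Violation("axes", f"axis labels not distinct: {labels}"))
    for a in desc.axes:
        fld = f"axes[{a.axis_label}]"
        if a.axis_label not in ("X", "Y", "Z"):
            v.append(Violation(fld, f"axis_label {a.axis_label!r} not in "
                                    "{'X','Y','Z'}"))
        if (a.anatomical_direction not in DIRECTION_VECTORS
                and not a.is_complex):
            v.append(Violation(
                fld, f"anatomical_direction {a.anatomical_direction!r} is "
                     f"not a controlled term or 'complex'"))
        if a.unit not in _UNITS:
            v.append(Violation(fld, f"unit {a.unit!r} not in {_UNITS}"))
        if a.unit == "voxel" and a.voxel_size_mm is None:
            v.append(Violation(fld, "voxel axes require voxel_size_mm"))
        if not a.extent_min < a.extent_max:
            v.append(Violation(
                fld, f"extent_min ({a.extent_min}) must be < extent_max "
                     f"({a.extent_max})"))
    if len(desc.axes) == 3 and not desc.has_complex_axis:
        vecs = [a.direction_vector() for a in desc.axes]
        if all(x is not None for x in vecs):
            m = np.array(vecs)
            gram = m @ m.T
            if not np.array_equal(gram, np.eye(3, dtype=int)):
                v.append(Violation(
                    "axes", "anatomical directions are not mutually "
                            "orthogonal: "
                    + ", ".join(a.anatomical_direction for a in desc.axes)))
    return v


@dataclass
class Registry:
    """In-memory registry of SRS descriptions and their optional tables.

    SRS records are keyed by code; names form a secondary unique index.
    Structure/fiducial/slice rows reference their SRS by code and are checked
    for referential integrity when added and when a registry is loaded.
    """

    _srs: dict[str, SRSDescription] = field(default_factory=dict)
    structures: list[StructureRecord] = field(default_factory=list)
    fiducials: list[FiducialRecord] = field(default_factory=list)
    slices: list[SliceRecord] = field(default_factory=list)

    # -- core operations -----------------------------------------------------

    def register_srs(self, desc: SRSDescription) -> str:
        violations = validate_srs(desc)
        if violations:
            raise ValidationError(violations)
        if desc.code in self._srs:
            raise DuplicateCode(desc.code)
        if any(d.name == desc.name for d in self._srs.values()):
            raise DuplicateName(desc.name)
        if desc.derived_from is not None and desc.derived_from not in self._srs:
            raise ValidationError([Violation(
                "derived_from", f"unknown SRS code {desc.derived_from!r}")])
        self._srs[desc.code] = desc
        return desc.code

    def get_srs(self, identifier: str) -> SRSDescription:
        """Resolve an SRS by code or by name."""
        if identifier in self._srs:
            return self._srs[identifier]
        for d in self._srs.values():
            if d.name == identifier:
                return d
        raise NotFound(f"no SRS with code or name {identifier!r}")

    def resolve_code(self, identifier: str) -> str:
        return self.get_srs(identifier).code

    def __contains__(self, identifier: str) -> bool:
        try:
            self.get_srs(identifier)
        except NotFound:
            return False
        return True

    def __len__(self) -> int:
        return len(self._srs)

    def list_srs(self, species: str | None = None,
                 family: str | None = None) -> list[SRSDescription]:
        """List registered SRSs, sorted by code; filters are conjunctive."""
        out = [d for d in self._srs.values()
               if (species is None or d.species == species)
               and (family is None or d.srs_family == family)]
        return sorted(out, key=lambda d: d.code)

    def remove_srs(self, identifier: str) -> None:
        code = self.resolve_code(identifier)
        del self._srs[code]
        self.structures = [s for s in self.structures if s.srs_code != code]
        self.fiducials = [f for f in self.fiducials if f.srs_code != code]
        self.slices = [s for s in self.slices if s.srs_code != code]

    def update_srs(self, desc: SRSDescription) -> None:
        """Replace an existing record (same code) after re-validation."""
        if desc.code not in self._srs:
            raise NotFound(desc.code)
        violations = validate_srs(desc)
        if violations:
            raise ValidationError(violations)
        other = [d for c, d in self._srs.items() if c != desc.code]
        if any(d.name == desc.name for d in other):
            raise DuplicateName(desc.name)
        self._srs[desc.code] = desc

    def next_local_code(self) -> str:
        """Allocate the next unused code in the user namespace ``LOCAL:``."""
        used = {int(c.split(":")[1]) for c in self._srs if
                c.startswith("LOCAL:")}
        n = 1
        while n in used:
            n += 1
        return f"LOCAL:{n:04d}"

    # -- auxiliary tables ----------------------------------------------------

    def _require(self, srs_code: str) -> None:
        if srs_code not in self._srs:
            raise NotFound(f"unknown SRS code {srs_code!r}")

    def add_structure(self, rec: StructureRecord) -> None:
        self._require(rec.srs_code)
        if isinstance(rec.geometry_ref, int) and rec.geometry_ref <= 0:
            raise ValidationError([Violation(
                "geometry_ref", "label values must be positive integers")])
        self.structures.append(rec)

    def add_fiducial(self, rec: FiducialRecord) -> None:
        self._require(rec.srs_code)
        ext = self.get_srs(rec.srs_code).extents()
        p = np.asarray(rec.point, dtype=float)
        if not (np.all(ext[:, 0] <= p) and np.all(p <= ext[:, 1])):
            raise ValidationError([Violation(
                "point", f"fiducial {rec.fiducial_name!r} lies outside the "
                         f"axis extents of {rec.srs_code}")])
        self.fiducials.append(rec)

    def add_slice(self, rec: SliceRecord) -> None:
        self._require(rec.srs_code)
        if any(s.srs_code == rec.srs_code and s.slice_index == rec.slice_index
               for s in self.slices):
            raise ValidationError([Violation(
                "slice_index", f"slice {rec.slice_index} already present for "
                               f"{rec.srs_code}")])
        self.slices.append(rec)

    def structures_for(self, identifier: str) -> list[StructureRecord]:
        code = self.resolve_code(identifier)
        return [s for s in self.structures if s.srs_code == code]

    # -- persistence ---------------------------------------------------------

    def to_dict(self) -> dict:
        def axis_d(a: AxisSpec) -> dict:
            d = {"axis_label": a.axis_label,
                 "anatomical_direction": a.anatomical_direction,
                 "unit": a.unit, "extent_min": a.extent_min,
                 "extent_max": a.extent_max}
            if a.voxel_size_mm is not None:
                d["voxel_size_mm"] = a.voxel_size_mm
            return d

        def srs_d(s: SRSDescription) -> dict:
            return {"code": s.code, "name": s.name,
                    "srs_family": s.srs_family, "version": s.version,
                    "species": s.species, "description": s.description,
                    "origin_description": s.origin_description,
                    "axes": [axis_d(a) for a in s.axes],
                    "region_of_validity": s.region_of_validity,
                    "author": s.author, "derived_from": s.derived_from,
                    "reference_implementation": s.reference_implementation}

        return {
            "srs": [srs_d(s) for s in self.list_srs()],
            "structures": [{"srs_code": s.srs_code,
                            "structure_name": s.structure_name,
                            "vocabulary_ref": s.vocabulary_ref,
                            "geometry_ref": s.geometry_ref}
                           for s in self.structures],
            "fiducials": [{"srs_code": f.srs_code,
                           "fiducial_name": f.fiducial_name,
                           "point": list(f.point)} for f in self.fiducials],
            "slices": [{"srs_code": s.srs_code, "slice_index": s.slice_index,
                        "plane": s.plane,
                        "in_plane_to_3d": list(s.in_plane_to_3d)}
                       for s in self.slices],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Registry":
        reg = cls()
        for s in d.get("srs", []):
            axes = tuple(AxisSpec(**a) for a in s["axes"])
            reg.register_srs(SRSDescription(
                code=s["code"], name=s["name"], srs_family=s["srs_family"],
                version=s["version"], species=s["species"],
                description=s.get("description", ""),
                origin_description=s.get("origin_description", ""),
                axes=axes,
                region_of_validity=s.get("region_of_validity", "whole brain"),
                author=s.get("author", ""),
                derived_from=s.get("derived_from"),
                reference_implementation=s.get("reference_implementation")))
        for s in d.get("structures", []):
            reg.add_structure(StructureRecord(**s))
        for f in d.get("fiducials", []):
            reg.add_fiducial(FiducialRecord(
                srs_code=f["srs_code"], fiducial_name=f["fiducial_name"],
                point=tuple(f["point"])))
        for s in d.get("slices", []):
            reg.add_slice(SliceRecord(
                srs_code=s["srs_code"], slice_index=s["slice_index"],
                plane=s["plane"], in_plane_to_3d=tuple(s["in_plane_to_3d"])))
        return reg

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load_json(cls, path) -> "Registry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    # CSV convenience dump: registry-table columns plus flattened axis columns
    _CSV_FIELDS = ["Code", "Name", "SRS family", "Version", "Species",
                   "SRS description", "Origin", "Region of validity",
                   "Author", "Derived from", "Reference implementation"]

    def to_csv(self) -> str:
        buf = io.StringIO()
        axis_cols = []
        for lbl in ("X", "Y", "Z"):
            axis_cols += [f"{lbl} direction", f"{lbl} unit", f"{lbl} min",
                          f"{lbl} max"]
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(self._CSV_FIELDS + axis_cols)
        for s in self.list_srs():
            row = [s.code, s.name, s.srs_family, s.version, s.species,
                   s.description, s.origin_description, s.region_of_validity,
                   s.author, s.derived_from or "",
                   s.reference_implementation or ""]
            for lbl in ("X", "Y", "Z"):
                try:
                    a = s.axis(lbl)
                    row += [a.anatomical_direction, a.unit,
                            repr(a.extent_min), repr(a.extent_max)]
                except KeyError:
                    row += ["", "", "", ""]
            w.writerow(row)
        return buf.getvalue()

    def save_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_csv())

    def copy(self) -> "Registry":
        return Registry.from_dict(self.to_dict())
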