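"""Shared service-layer datatypes: object store records, structure hits,
process descriptions.

Kept separate so both the XML encoding layer and the hub service layer can
use them without circular imports.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ObjectRecord:
    """A spatially referenced object published by an atlas hub.

    ``extent`` is a per-axis ((min, max), ...) box in the SRS's units; point
    objects use a degenerate box.  ``metadata`` carries title, modality and
    provenance strings.
    """

    object_kind: str  # image2d | annotation | structure | volume
    srs_name: str
    extent: tuple[tuple[float, float], ...]
    title: str = ""
    modality: str = ""
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(
            self, "extent",
            tuple((float(lo), float(hi)) for lo, hi in self.extent))


@dataclass(frozen=True)
class StructureHit:
    """One structure found at (or near) a point of interest."""

    structure_name: str
    label: int
    vocabulary_ref: str | None = None


@dataclass(frozen=True)
class ProcessInput:
    """One input parameter of a WPS process."""

    name: str
    semantic_type: str  # e.g. srs-name | coordinate | radius | poi
    required: bool = True


@dataclass(frozen=True)
class ProcessDescription:
    """Self-description of a hub process: inputs and output document kind."""

    identifier: str
    inputs: tuple[ProcessInput, ...] = ()
    output_kind: str = "WaxML"

    def __post_init__(self):
        object.__setattr__(self, "inputs", tuple(self.inputs))
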