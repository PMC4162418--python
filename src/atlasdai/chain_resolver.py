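"""Transformation graph and multi-hub chain resolution.

Registered transformations form a directed multigraph over SRS codes
(forward and inverse mappings are independent edges; an edge lacking a
registered inverse is never auto-inverted).  Resolving a chain between two
SRSs finds a path with the fewest steps — fewer steps in a composite
transformation means less accumulated mapping error — and breaks ties
deterministically, preferring routes through the Waxholm Space (WHS) family,
which serves as the community's go-between reference space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import DuplicateCode, NoPathFound, UnknownSRS, SRSMismatch
from .srs_registry import Registry
from .transforms import PointSet, TransformationRecord, apply_transform

__all__ = ["ChainStep", "Chain", "TransformationGraph"]


@dataclass(frozen=True)
class ChainStep:
    """One step of a resolved chain: which hub runs which transformation."""

    order: int
    hub: str
    transformation_code: str
    source_srs: str
    target_srs: str


@dataclass(frozen=True)
class Chain:
    """An ordered sequence of transformation steps between two SRSs."""

    input_srs: str
    output_srs: str
    steps: tuple[ChainStep, ...]

    def __post_init__(self):
        object.__setattr__(self, "steps", tuple(self.steps))
        prev = self.input_srs
        for i, s in enumerate(self.steps, start=1):
            if s.order != i:
                raise SRSMismatch("step order indices must be 1..k")
            if s.source_srs != prev:
                raise SRSMismatch(
                    f"step {i} starts at {s.source_srs!r}, expected {prev!r}")
            prev = s.target_srs
        if self.steps and prev != self.output_srs:
            raise SRSMismatch("chain does not end at output_srs")

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def hubs(self) -> tuple[str, ...]:
        return tuple(s.hub for s in self.steps)

    @property
    def intermediate_srs(self) -> tuple[str, ...]:
        return tuple(s.target_srs for s in self.steps[:-1])


def _version_key(version: str) -> tuple:
    """Order version strings numerically where possible ('0.9' < '1.0')."""
    parts = []
    for tok in str(version).split("."):
        parts.append((0, int(tok)) if tok.isdigit() else (1, tok))
    return tuple(parts)


@dataclass
class TransformationGraph:
    """Directed multigraph of registered transformations over SRS codes."""

    registry: Registry
    _g: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)
    _by_code: dict[str, TransformationRecord] = field(default_factory=dict)

    def add_transformation(self, rec: TransformationRecord) -> str:
        """Register a transformation edge; endpoints must resolve."""
        if rec.code in self._by_code:
            raise DuplicateCode(rec.code)
        for srs in (rec.source_srs, rec.target_srs):
            if srs not in self.registry:
                raise UnknownSRS(f"SRS {srs!r} is not registered")
        src = self.registry.resolve_code(rec.source_srs)
        dst = self.registry.resolve_code(rec.target_srs)
        self._g.add_edge(src, dst, key=rec.code, record=rec)
        self._by_code[rec.code] = rec
        return rec.code

    def get_transformation(self, code: str) -> TransformationRecord:
        try:
            return self._by_code[code]
        except KeyError:
            raise NoPathFound(f"no transformation with code {code!r}")

    def list_transformations(self, hub: str | None = None
                             ) -> list[TransformationRecord]:
        out = [r for r in self._by_code.values()
               if hub is None or r.hub == hub]
        return sorted(out, key=lambda r: r.code)

    def direct_records(self, source: str, target: str
                       ) -> list[TransformationRecord]:
        src = self.registry.resolve_code(source)
        dst = self.registry.resolve_code(target)
        if not self._g.has_edge(src, dst):
            return []
        return sorted((d["record"] for d in self._g[src][dst].values()),
                      key=lambda r: r.code)

    # -- resolution ----------------------------------------------------------

    def _best_edge(self, src: str, dst: str) -> TransformationRecord:
        # among parallel edges: highest version wins; at equal version the
        # lexicographically smallest code (direct_records is code-sorted)
        recs = self.direct_records(src, dst)
        best = recs[0]
        for r in recs[1:]:
            if _version_key(r.version) > _version_key(best.version):
                best = r
        return best

    def _whs_version(self, node_path: list[str]):
        """Highest WHS version among a path's interior SRSs (None if none)."""
        versions = []
        for code in node_path[1:-1]:
            desc = self.registry.get_srs(code)
            if desc.srs_family == "WHS":
                versions.append(_version_key(desc.version))
        return max(versions) if versions else None

    def resolve_chain(self, input_srs: str, output_srs: str) -> Chain:
        """Resolve a fewest-steps transformation chain between two SRSs.

        Deterministic: identical graphs yield identical chains regardless of
        edge insertion order.  ``input == output`` resolves to an empty
        chain; unreachable targets raise :class:`NoPathFound`.
        """
        src = self.registry.resolve_code(input_srs)
        dst = self.registry.resolve_code(output_srs)
        if src == dst:
            return Chain(input_srs=src, output_srs=dst, steps=())
        try:
            paths = list(nx.all_shortest_paths(self._g, src, dst))
        except (nx.NetworkXNoPath, nx.NodeNotFound):
            raise NoPathFound(f"no transformation path {src!r} -> {dst!r}")
        candidates = []
        for node_path in paths:
            recs = [self._best_edge(a, b)
                    for a, b in zip(node_path, node_path[1:])]
            codes = tuple(r.code for r in recs)
            candidates.append((self._whs_version(node_path), codes, recs))
        # tie-break among fewest-step paths: interior-WHS paths first, then
        # highest interior WHS version, then smallest code sequence
        whs = [c for c in candidates if c[0] is not None]
        if whs:
            top = max(v for v, _, _ in whs)
            pool = [c for c in whs if c[0] == top]
        else:
            pool = candidates
        recs = min(pool, key=lambda c: c[1])[2]
        steps = tuple(
            ChainStep(order=i, hub=r.hub, transformation_code=r.code,
                      source_srs=self.registry.resolve_code(r.source_srs),
                      target_srs=self.registry.resolve_code(r.target_srs))
            for i, r in enumerate(recs, start=1))
        return Chain(input_srs=src, output_srs=dst, steps=steps)

    def execute_chain(self, chain: Chain, ps: PointSet) -> PointSet:
        """Run a resolved chain as sequential TransformPOI applications."""
        if self.registry.resolve_code(ps.srs_name) != chain.input_srs:
            raise SRSMismatch(
                f"PointSet is in {ps.srs_name!r} but the chain starts at "
                f"{chain.input_srs!r}")
        cur = PointSet(srs_name=chain.input_srs, points=ps.points,
                       out_of_validity_flags=ps.out_of_validity_flags)
        for step in chain.steps:
            rec = self.get_transformation(step.transformation_code)
            cur = apply_transform(rec, cur, registry=self.registry)
            # normalize tagging to codes so the next step's SRS check holds
            cur = PointSet(
                srs_name=self.registry.resolve_code(cur.srs_name),
                points=cur.points,
                out_of_validity_flags=cur.out_of_validity_flags)
        if not chain.steps:
            cur = PointSet(srs_name=chain.output_srs, points=ps.points,
                           out_of_validity_flags=ps.out_of_validity_flags)
        return cur

    def chain_consistency(self, chain: Chain):
        """Per-step consistency metadata, in step order (None when absent)."""
        return [self.get_transformation(s.transformation_code).consistency
                for s in chain.steps]
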