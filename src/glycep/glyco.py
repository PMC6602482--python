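"""N-glycosylation sequons, surface residue triangles, and pattern statistics.

A *glycosylation triangle* is a triangle of three mutually proximal surface
residues that contains the Asn of an N-glycosylation sequon; during training
each triangle pattern accumulates an epitope-enrichment ratio
``n_epi / n_total`` over the corpus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .structure_io import AntigenStructure, EpitopeLabeling

__all__ = [
    "SequonMap",
    "SubgroupTable",
    "SurfaceTriangle",
    "PatternRatioTable",
    "find_sequons",
    "enumerate_triangles",
    "all_surface_triangles",
    "mark_glyco",
    "compute_ratio_table",
    "NoGlycoTrianglesError",
    "TRIANGLE_MAX_DIST",
]

TRIANGLE_MAX_DIST = 15.0


class NoGlycoTrianglesError(ValueError):
    pass


@dataclass(frozen=True)
class SequonMap:
    """0-based indices of Asn residues opening an Asn-X-Ser/Thr sequon (X != Pro)."""

    asn_positions: frozenset[int]

    def __contains__(self, idx: int) -> bool:
        return idx in self.asn_positions

    def __len__(self) -> int:
        return len(self.asn_positions)


def find_sequons(sequence: str) -> SequonMap:
    """All positions i with sequence[i]=='N', sequence[i+1]!='P', sequence[i+2] in 'ST'.

    Overlapping sequons are all reported. 'X' is allowed in the middle slot
    (any residue but proline) but does not satisfy the Ser/Thr slot.
    """
    hits = {
        i
        for i in range(len(sequence) - 2)
        if sequence[i] == "N" and sequence[i + 1] != "P" and sequence[i + 2] in ("S", "T")
    }
    return SequonMap(frozenset(hits))


class SubgroupTable:
    """Amino acid -> functional subgroup mapping (13 groups over 20 residues)."""

    def __init__(self, mapping: dict[str, str], unknown_group: str = "UNK"):
        self.mapping = dict(mapping)
        self.unknown_group = unknown_group
        groups = {g for aa, g in self.mapping.items() if aa != "X"}
        if len(groups) != 13:
            raise ValueError(f"expected 13 subgroups over the 20 standard residues, got {len(groups)}")
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.mapping)
        if missing:
            raise ValueError(f"unmapped residues: {sorted(missing)}")

    @classmethod
    def default(cls) -> "SubgroupTable":
        raw = json.loads(resources.files("glycep.data").joinpath("subgroups.json").read_text())
        mapping = {aa: gid for gid, members in raw["groups"].items() for aa in members}
        return cls(mapping, unknown_group=raw.get("unknown_group", "UNK"))

    def group(self, aa: str) -> str:
        return self.mapping.get(aa, self.unknown_group)

    @property
    def n_groups(self) -> int:
        return len({g for aa, g in self.mapping.items() if aa != "X"})

    def pattern_key(self, aas: tuple[str, str, str]) -> str | None:
        """Canonical unordered pattern key; None when any member is unknown."""
        groups = [self.group(a) for a in aas]
        if self.unknown_group in groups:
            return None
        return "|".join(sorted(groups))


@dataclass
class SurfaceTriangle:
    members: frozenset[int]
    pattern: str | None
    is_glytri: bool = False
    is_epi_glytri: bool = False


def _triangle(structure: AntigenStructure, members: frozenset[int], table: SubgroupTable) -> SurfaceTriangle:
    aas = tuple(structure.residues[i].aa for i in sorted(members))
    return SurfaceTriangle(members=members, pattern=table.pattern_key(aas))


def enumerate_triangles(
    structure: AntigenStructure,
    center: int,
    max_dist: float = TRIANGLE_MAX_DIST,
    subgroups: SubgroupTable | None = None,
) -> list[SurfaceTriangle]:
    """Every surface triangle {center, a, b} with all pairwise distances <= max_dist."""
    if not structure.residues[center].is_surface:
        return []
    subgroups = subgroups or SubgroupTable.default()
    dist = structure.distance_matrix()
    surf = structure.surface_indices
    neigh = [j for j in surf if j != center and dist[center, j] <= max_dist]
    out = []
    for ia, a in enumerate(neigh):
        for b in neigh[ia + 1 :]:
            if dist[a, b] <= max_dist:
                out.append(_triangle(structure, frozenset((center, a, b)), subgroups))
    return out


def all_surface_triangles(
    structure: AntigenStructure,
    max_dist: float = TRIANGLE_MAX_DIST,
    subgroups: SubgroupTable | None = None,
) -> list[SurfaceTriangle]:
    """Unique surface triangles of the structure (each counted once)."""
    subgroups = subgroups or SubgroupTable.default()
    dist = structure.distance_matrix()
    surf = structure.surface_indices
    out = []
    for ii, i in enumerate(surf):
        for jj, j in enumerate(surf[ii + 1 :], start=ii + 1):
            if dist[i, j] > max_dist:
                continue
            for k in surf[jj + 1 :]:
                if dist[i, k] <= max_dist and dist[j, k] <= max_dist:
                    out.append(_triangle(structure, frozenset((i, j, k)), subgroups))
    return out


def mark_glyco(
    triangles: list[SurfaceTriangle],
    sequons: SequonMap,
    labels: EpitopeLabeling | None = None,
) -> list[SurfaceTriangle]:
    """Flag glycosylation triangles (and, with labels, epitope glycosylation triangles)."""
    for tri in triangles:
        tri.is_glytri = any(m in sequons for m in tri.members)
        if labels is not None:
            n_epi = sum(1 for m in tri.members if labels.labels[m])
            tri.is_epi_glytri = tri.is_glytri and n_epi >= 2
        else:
            tri.is_epi_glytri = False
    return triangles


@dataclass
class PatternRatioTable:
    """Per-pattern glycosylation-triangle counts and epitope-enrichment ratios."""

    entries: dict[str, tuple[int, int, float]] = field(default_factory=dict)
    schema_version: int = 1

    @property
    def n_patterns(self) -> int:
        return len(self.entries)

    def ratio(self, pattern: str | None) -> float:
        if pattern is None or pattern not in self.entries:
            return 0.0
        return self.entries[pattern][2]

    @property
    def vocabulary(self) -> list[str]:
        return sorted(self.entries)

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "entries": {
                p: {"n_epi_glytri": e, "n_glytri": g, "ratio": r}
                for p, (e, g, r) in sorted(self.entries.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatternRatioTable":
        entries = {
            p: (v["n_epi_glytri"], v["n_glytri"], v["ratio"]) for p, v in d["entries"].items()
        }
        return cls(entries=entries, schema_version=d.get("schema_version", 1))


def compute_ratio_table(
    training: list[tuple[AntigenStructure, EpitopeLabeling, SequonMap]],
    max_dist: float = TRIANGLE_MAX_DIST,
    subgroups: SubgroupTable | None = None,
) -> PatternRatioTable:
    """Corpus-wide pattern -> (n_epi_glytri, n_glytri, ratio) census.

    Each unique triangle is counted once per structure; triangles containing
    unknown residues carry no pattern and are skipped.
    """
    subgroups = subgroups or SubgroupTable.default()
    n_epi: dict[str, int] = {}
    n_gly: dict[str, int] = {}
    for structure, labeling, sequons in training:
        tris = all_surface_triangles(structure, max_dist=max_dist, subgroups=subgroups)
        mark_glyco(tris, sequons, labeling)
        for tri in tris:
            if not tri.is_glytri or tri.pattern is None:
                continue
            n_gly[tri.pattern] = n_gly.get(tri.pattern, 0) + 1
            if tri.is_epi_glytri:
                n_epi[tri.pattern] = n_epi.get(tri.pattern, 0) + 1
    if not n_gly:
        raise NoGlycoTrianglesError("no glycosylation triangles in corpus")
    entries = {p: (n_epi.get(p, 0), g, n_epi.get(p, 0) / g) for p, g in n_gly.items()}
    return PatternRatioTable(entries=entries)
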