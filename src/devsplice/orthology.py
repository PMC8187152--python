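"""Cross-species 1:1 exon orthology from coordinate mappings.

Exons from every species are mapped (by an external liftover; mappings are
an *input* here) onto every other species' coordinates.  Exons whose
mapped coordinates poorly match any exon of some species (intersect:union
ratio below a threshold) are discarded; the survivors form a graph with
edges between exons whose mapped coordinates agree in *all* species, and
connected components containing exactly one exon per species become
orthology groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "ExonMapping",
    "OrthoGroup",
    "build_ortho_groups",
    "iou",
    "read_mappings_tsv",
    "write_ortho_groups_tsv",
]

Interval = tuple[int, int]


def iou(a: Interval, b: Interval) -> float:
    """Intersection-over-union of two 0-based half-open intervals."""
    if a[1] <= a[0] or b[1] <= b[0]:
        raise ValueError("intervals must be non-empty")
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union


@dataclass
class ExonMapping:
    """One exon with its native and lifted coordinates in every species.

    ``coords`` maps species name -> interval; absence of a species key
    means the exon failed to map there.  The native species' entry holds
    the exon's own coordinates.
    """

    exon_id: str
    species: str
    coords: dict[str, Interval] = field(default_factory=dict)

    def validate(self) -> None:
        if self.species not in self.coords:
            raise ValueError(f"{self.exon_id}: missing native coordinates")
        for sp, (s, e) in self.coords.items():
            if e <= s:
                raise ValueError(f"{self.exon_id}: negative-length interval in {sp}")


@dataclass(frozen=True)
class OrthoGroup:
    group_id: str
    members: tuple[tuple[str, str], ...]  # (species, exon_id), one per species

    def exon_for(self, species: str) -> str:
        return dict(self.members)[species]


def _min_cross_iou(x: ExonMapping, y: ExonMapping, species: Sequence[str]) -> float:
    """Smallest per-species IoU of the two exons' mapped coordinates.

    Returns 0 when either exon lacks coordinates in some species.
    """
    worst = 1.0
    for sp in species:
        ca = x.coords.get(sp)
        cb = y.coords.get(sp)
        if ca is None or cb is None:
            return 0.0
        worst = min(worst, iou(ca, cb))
        if worst == 0.0:
            return 0.0
    return worst


def build_ortho_groups(
    mappings: Iterable[ExonMapping],
    species: Sequence[str],
    node_min_iou: float = 0.6,
    edge_min_iou: float = 0.6,
) -> list[OrthoGroup]:
    """Build 1:1 orthologous exon groups.

    Node filter: an exon is kept iff in every species its mapped interval
    reaches IoU >= ``node_min_iou`` against at least one exon of that
    species (its own native coordinates trivially qualify).  Edges connect
    exon pairs whose mapped coordinates have IoU strictly greater than
    ``edge_min_iou`` in all species.  Connected components with exactly
    one exon per species (covering all species) are returned as groups,
    ordered deterministically; all other components are discarded.
    """
    exons = [m for m in mappings]
    for m in exons:
        m.validate()
    by_species: dict[str, list[ExonMapping]] = {sp: [] for sp in species}
    for m in exons:
        if m.species not in by_species:
            raise ValueError(f"unknown species {m.species!r} for exon {m.exon_id}")
        by_species[m.species].append(m)

    def node_ok(m: ExonMapping) -> bool:
        for sp in species:
            c = m.coords.get(sp)
            if c is None:
                return False
            if sp == m.species:
                continue
            best = 0.0
            for other in by_species[sp]:
                native = other.coords.get(sp)
                if native is not None:
                    best = max(best, iou(c, native))
            if best < node_min_iou:
                return False
        return True

    kept = [m for m in exons if node_ok(m)]
    graph = nx.Graph()
    for m in kept:
        graph.add_node((m.species, m.exon_id))
    for i, x in enumerate(kept):
        for y in kept[i + 1 :]:
            if x.species == y.species:
                continue
            if _min_cross_iou(x, y, species) > edge_min_iou:
                graph.add_edge((x.species, x.exon_id), (y.species, y.exon_id))

    groups: list[OrthoGroup] = []
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for comp in components:
        sp_counts: dict[str, int] = {}
        for sp, _ in comp:
            sp_counts[sp] = sp_counts.get(sp, 0) + 1
        if set(sp_counts) == set(species) and all(v == 1 for v in sp_counts.values()):
            members = tuple(sorted(comp, key=lambda t: list(species).index(t[0])))
            groups.append(OrthoGroup(group_id=f"og{len(groups) + 1}", members=members))
    return groups


def read_mappings_tsv(path: str) -> list[ExonMapping]:
    """Read a mappings table (exon_id, species, target_species, start, end)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[tuple[str, str], ExonMapping] = {}
    for row in df.itertuples(index=False):
        key = (row.species, row.exon_id)
        if key not in out:
            out[key] = ExonMapping(exon_id=row.exon_id, species=row.species)
        out[key].coords[row.target_species] = (int(row.start), int(row.end))
    return list(out.values())


def write_ortho_groups_tsv(groups: Sequence[OrthoGroup], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tspecies\texon_id\n")
        for g in groups:
            for sp, ex in g.members:
                fh.write(f"{g.group_id}\t{sp}\t{ex}\n")
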