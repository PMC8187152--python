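"""Evolution of cassette exons: gain/loss detection and parsimony dating.

New exon candidates are exons interspaced between a pair of consecutive
1:1 orthologous "border" exons in only a subset of species.  Candidates
pass three filters (no similarity to the inter-border region of species
lacking the exon; mutual similarity among species carrying it; length
< 500 nt), and the presence/absence pattern over the species tree is
explained by a single gain or a single loss event found by parsimony;
patterns with no or several single-event explanations are discarded.

"Alternification" applies the same parsimony dating to the
cassette/constitutive status of exons orthologous across all species: an
exon is a cassette exon in a species when at least four organ-stage pairs
have PSI < 0.9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy

__all__ = [
    "DEFAULT_SPECIES",
    "DEFAULT_TREE_NEWICK",
    "Candidate",
    "EvoEvent",
    "InterspacedExon",
    "SpeciesTree",
    "apply_birth_filters",
    "cassette_status",
    "detect_alternification",
    "find_interspaced_candidates",
    "interval_overlap_flag",
    "parsimony_age",
    "similar",
]

DEFAULT_SPECIES = (
    "human",
    "macaque",
    "mouse",
    "rat",
    "rabbit",
    "opossum",
    "chicken",
)

DEFAULT_TREE_NEWICK = "((((human,macaque),((mouse,rat),rabbit)),opossum),chicken);"

#: Human-readable labels for clades of the default tree.
AGE_CLASS_LABELS = {
    frozenset({"human", "macaque"}): "primate",
    frozenset({"mouse", "rat"}): "rodent",
    frozenset({"mouse", "rat", "rabbit"}): "glires",
    frozenset({"human", "macaque", "mouse", "rat", "rabbit"}): "eutherian",
    frozenset(
        {"human", "macaque", "mouse", "rat", "rabbit", "opossum"}
    ): "mammalian",
}


class SpeciesTree:
    """Rooted species tree exposing the clade below every branch."""

    def __init__(self, newick: str = DEFAULT_TREE_NEWICK):
        tree = dendropy.Tree.get(data=newick, schema="newick")
        self.leaves: frozenset[str] = frozenset(
            t.label.replace(" ", "_") for t in tree.taxon_namespace
        )
        self.clades: list[frozenset[str]] = []
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            below = frozenset(
                lf.taxon.label.replace(" ", "_") for lf in node.leaf_iter()
            )
            self.clades.append(below)

    def age_class(self, clade: frozenset[str]) -> str:
        if len(clade) == 1:
            return f"{next(iter(clade))}-specific"
        return AGE_CLASS_LABELS.get(clade, "+".join(sorted(clade)))


@dataclass(frozen=True)
class EvoEvent:
    event: str  # gain | loss | alternification_gain | alternification_loss
    branch: frozenset[str]  # species below the event's branch
    age_class: str


def parsimony_age(
    presence: Mapping[str, bool], tree: Optional[SpeciesTree] = None, kind: str = ""
) -> Optional[EvoEvent]:
    """Date a presence/absence pattern by single-event parsimony.

    Enumerates every single-gain scenario (gain on a branch whose clade
    equals the present set) and single-loss scenario (loss on a branch
    whose clade equals the absent set).  Returns the event when exactly
    one scenario reproduces the pattern; returns None for constant
    patterns and for ambiguous or unexplainable ones (e.g. root-split
    patterns, where one gain and one loss are equally parsimonious).
    """
    tree = tree if tree is not None else SpeciesTree()
    if set(presence) != set(tree.leaves):
        raise ValueError("presence vector must cover every tree leaf exactly")
    present = frozenset(sp for sp, v in presence.items() if v)
    absent = tree.leaves - present
    if not present or not absent:
        return None
    prefix = f"{kind}_" if kind else ""
    scenarios: list[EvoEvent] = []
    for clade in tree.clades:
        if clade == present:
            scenarios.append(
                EvoEvent(prefix + "gain", clade, tree.age_class(clade))
            )
        if clade == absent:
            scenarios.append(EvoEvent(prefix + "loss", clade, tree.age_class(clade)))
    if len(scenarios) == 1:
        return scenarios[0]
    return None


# ---------------------------------------------------------------------------
# Candidate detection and filtering
# ---------------------------------------------------------------------------

@dataclass
class InterspacedExon:
    exon_id: str
    sequence: str
    flank5: str = ""  # up to 4 nt on each side, used for the query
    flank3: str = ""

    @property
    def query(self) -> str:
        return (self.flank5[-4:] + self.sequence + self.flank3[:4]).upper()


@dataclass
class Candidate:
    pair_id: str
    useg_id: str
    dseg_id: str
    presence: dict[str, bool]
    exons: dict[str, InterspacedExon]
    excluded: Optional[str] = None  # reason, if any


def find_interspaced_candidates(
    border_pairs: Iterable[dict],
    species: Sequence[str] = DEFAULT_SPECIES,
) -> list[Candidate]:
    """Collect candidate gained/lost exons from border-exon pairs.

    Each ``border_pairs`` record carries ``pair_id``, ``useg_id``,
    ``dseg_id``, ``interspaced`` (species -> list of
    :class:`InterspacedExon` found between the borders) and optionally
    ``non_consecutive`` (species where the borders are not consecutive;
    such pairs are skipped).  Pairs where no species has an interspaced
    exon yield no candidate; pairs where some species holds more than one
    are excluded with reason ``multi_exon``.
    """
    out: list[Candidate] = []
    for rec in border_pairs:
        if rec.get("non_consecutive"):
            continue
        inter: Mapping[str, list[InterspacedExon]] = rec.get("interspaced", {})
        presence = {sp: len(inter.get(sp, [])) > 0 for sp in species}
        if not any(presence.values()):
            continue
        cand = Candidate(
            pair_id=rec["pair_id"],
            useg_id=rec.get("useg_id", ""),
            dseg_id=rec.get("dseg_id", ""),
            presence=presence,
            exons={sp: lst[0] for sp, lst in inter.items() if lst},
        )
        if any(len(lst) > 1 for lst in inter.values()):
            cand.excluded = "multi_exon"
        out.append(cand)
    return out


def similar(
    query: str,
    target: str,
    word_size: int = 8,
    match: int = 1,
    mismatch: int = -2,
    x_drop: int = 10,
    min_score: int = 14,
) -> bool:
    """Permissive seed-and-extend local similarity test.

    Finds exact ``word_size``-mer seeds shared between query and target
    and extends them ungapped in both directions with an X-drop rule;
    returns True when any extension reaches ``min_score``.  With the
    defaults, any exact shared block of >= ``min_score`` nt is guaranteed
    to be detected (mirroring a highly permissive E-value cut-off).
    """
    q = query.upper()
    t = target.upper()
    if len(q) < word_size or len(t) < word_size:
        return False
    index: dict[str, list[int]] = {}
    for j in range(len(t) - word_size + 1):
        word = t[j : j + word_size]
        if "N" in word:
            continue
        index.setdefault(word, []).append(j)

    def score(a: str, b: str) -> int:
        return match if a == b and a != "N" else mismatch

    seen_diag: set[tuple[int, int]] = set()
    for i in range(len(q) - word_size + 1):
        word = q[i : i + word_size]
        if "N" in word:
            continue
        for j in index.get(word, ()):
            diag = (i - j, j // 50)  # one extension per diagonal stretch
            if diag in seen_diag:
                continue
            seen_diag.add(diag)
            base = word_size * match
            # extend right
            best_r = 0
            cur = 0
            qi, tj = i + word_size, j + word_size
            while qi < len(q) and tj < len(t):
                cur += score(q[qi], t[tj])
                if cur > best_r:
                    best_r = cur
                if best_r - cur > x_drop:
                    break
                qi += 1
                tj += 1
            # extend left
            best_l = 0
            cur = 0
            qi, tj = i - 1, j - 1
            while qi >= 0 and tj >= 0:
                cur += score(q[qi], t[tj])
                if cur > best_l:
                    best_l = cur
                if best_l - cur > x_drop:
                    break
                qi -= 1
                tj -= 1
            if base + best_r + best_l >= min_score:
                return True
    return False


def apply_birth_filters(
    candidate: Candidate,
    target_regions: Mapping[str, str],
    max_length: int = 500,
    similarity=similar,
) -> bool:
    """Return True when a candidate passes all three birth/loss filters.

    1. No presence-species exon may align to the border+inter-border
       region (``target_regions``) of any species lacking the exon.
    2. When the exon is present in several species, all of their exon
       sequences must align to each other.
    3. Every candidate exon must be shorter than ``max_length`` nt.
    """
    if candidate.excluded:
        return False
    exons = list(candidate.exons.values())
    if any(len(ex.sequence) >= max_length for ex in exons):
        return False
    absent = [sp for sp, present in candidate.presence.items() if not present]
    for sp in absent:
        region = target_regions.get(sp, "")
        if not region:
            continue
        if any(similarity(ex.query, region) for ex in exons):
            return False
    for a in range(len(exons)):
        for b in range(a + 1, len(exons)):
            if not similarity(exons[a].query, exons[b].sequence):
                return False
    return True


# ---------------------------------------------------------------------------
# Alternification
# ---------------------------------------------------------------------------

def cassette_status(
    organ_stage_psi: Sequence[float], min_pairs: int = 4, psi_cutoff: float = 0.9
) -> Optional[bool]:
    """True = cassette, False = constitutive, None = unknown (no defined PSI).

    Cassette iff at least ``min_pairs`` organ-stage mean PSI values are
    strictly below ``psi_cutoff``.
    """
    vals = [v for v in organ_stage_psi if v is not None and not math.isnan(v)]
    if not vals:
        return None
    return bool(sum(v < psi_cutoff for v in vals) >= min_pairs)


def detect_alternification(
    psi_by_species: Mapping[str, Sequence[float]],
    tree: Optional[SpeciesTree] = None,
    min_pairs: int = 4,
    psi_cutoff: float = 0.9,
) -> tuple[dict[str, Optional[bool]], Optional[EvoEvent]]:
    """Per-species cassette status of an ortho exon plus its dated event.

    ``psi_by_species`` maps species -> organ-stage mean PSI values.
    Species with no defined PSI get status None and the whole vector is
    discarded (event None).  Otherwise the cassette/constitutive vector is
    dated by single-event parsimony.
    """
    tree = tree if tree is not None else SpeciesTree()
    status = {
        sp: cassette_status(psi_by_species.get(sp, ()), min_pairs, psi_cutoff)
        for sp in sorted(tree.leaves)
    }
    if any(v is None for v in status.values()):
        return status, None
    event = parsimony_age(
        {sp: bool(v) for sp, v in status.items()}, tree, kind="alternification"
    )
    return status, event


# ---------------------------------------------------------------------------
# Feature overlap
# ---------------------------------------------------------------------------

def interval_overlap_flag(
    exon: tuple[int, int],
    features: Iterable[tuple[int, int]],
    min_overlap: int = 1,
) -> bool:
    """True iff the exon overlaps any single feature by >= ``min_overlap`` nt."""
    s, e = exon
    if e <= s:
        raise ValueError("empty exon interval")
    for fs, fe in features:
        if fe <= fs:
            raise ValueError("empty feature interval")
        if min(e, fe) - max(s, fs) >= min_overlap:
            return True
    return False
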