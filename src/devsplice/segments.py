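"""Gene segmentation and alternative-splicing classification.

A *segment* is the sequence between two adjacent splice sites of a gene.
Segments are classified as constitutive (present in all isoforms) or
alternative, and alternative segments fall into four classes depending on
the kinds of splice sites at their boundaries (in transcription
orientation):

====  =========  ========
AS    start      end
====  =========  ========
CE    acceptor   donor
AA    acceptor   acceptor
AD    donor      donor
RI    donor      acceptor
====  =========  ========

All coordinates are 0-based half-open genomic intervals; GTF I/O converts
from/to the 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "GeneModel",
    "Segment",
    "StructuralInputError",
    "classify_as_class",
    "is_frame_preserving",
    "is_microexon",
    "read_gtf_genes",
    "segment_gene",
    "segments_to_rows",
    "write_segments_tsv",
]

AS_CLASSES = ("CE", "AA", "AD", "RI")

#: Microexon length bounds in nucleotides (inclusive).
MICROEXON_MIN = 3
MICROEXON_MAX = 27


class StructuralInputError(ValueError):
    """Raised when annotation input violates structural invariants."""


Interval = tuple[int, int]


@dataclass
class GeneModel:
    """A gene as a set of transcripts, each an ordered list of exon intervals."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[list[Interval]]
    transcript_ids: Optional[list[str]] = None

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise StructuralInputError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if not self.transcripts:
            raise StructuralInputError(f"{self.gene_id}: no transcripts")
        for t, exons in enumerate(self.transcripts):
            if not exons:
                raise StructuralInputError(f"{self.gene_id}: empty transcript {t}")
            prev_end = None
            for start, end in exons:
                if end <= start:
                    raise StructuralInputError(
                        f"{self.gene_id}: empty/inverted exon ({start},{end})"
                    )
                if prev_end is not None and start <= prev_end:
                    # start == prev_end would be a zero-length intron
                    raise StructuralInputError(
                        f"{self.gene_id}: unsorted or overlapping exons in transcript {t}"
                    )
                prev_end = end

    def introns(self) -> set[Interval]:
        out: set[Interval] = set()
        for exons in self.transcripts:
            for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
                out.add((e0, s1))
        return out

    def span(self) -> Interval:
        starts = [exons[0][0] for exons in self.transcripts]
        ends = [exons[-1][1] for exons in self.transcripts]
        return min(starts), max(ends)


@dataclass
class Segment:
    """A between-splice-site unit of a gene with its AS status."""

    segment_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    start_kind: Optional[str]  # donor/acceptor in transcription orientation
    end_kind: Optional[str]
    status: str  # constitutive | alternative
    as_class: str  # CE | AA | AD | RI | NA

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Interval:
        return self.start, self.end


def classify_as_class(start_kind: str, end_kind: str) -> str:
    """Map boundary splice-site kinds (transcription orientation) to AS class."""
    table = {
        ("acceptor", "donor"): "CE",
        ("acceptor", "acceptor"): "AA",
        ("donor", "donor"): "AD",
        ("donor", "acceptor"): "RI",
    }
    try:
        return table[(start_kind, end_kind)]
    except KeyError:
        raise ValueError(f"invalid splice-site kinds ({start_kind!r}, {end_kind!r})")


def is_microexon(ls: int) -> bool:
    """True for cassette-exon lengths of 3-27 nt."""
    if ls < 1:
        raise ValueError("segment length must be >= 1")
    return MICROEXON_MIN <= ls <= MICROEXON_MAX


def is_frame_preserving(ls: int) -> bool:
    """True when the segment length is divisible by three."""
    if ls < 1:
        raise ValueError("segment length must be >= 1")
    return ls % 3 == 0


def _covering_exon(exons: list[Interval], start: int, end: int) -> bool:
    return any(s <= start and end <= e for s, e in exons)


def _covering_intron(exons: list[Interval], start: int, end: int) -> bool:
    return any(e0 <= start and end <= s1 for (_, e0), (s1, _) in zip(exons, exons[1:]))


def segment_gene(gene: GeneModel) -> list[Segment]:
    """Split a gene into segments between adjacent splice sites.

    A segment is *alternative* when at least one transcript includes it
    (inside an exon) and at least one excludes it (inside an intron).
    Terminal segments — bounded by a gene end rather than a splice site —
    are always reported constitutive with class NA; alternative first/last
    exons are out of analysis scope.
    """
    gene.validate()
    introns = gene.introns()
    intron_starts = {s for s, _ in introns}
    intron_ends = {e for _, e in introns}
    gstart, gend = gene.span()

    sites = sorted(p for p in (intron_starts | intron_ends) if gstart < p < gend)
    bounds = [gstart] + sites + [gend]

    minus = gene.strand == "-"

    def left_kind(p: int) -> Optional[str]:
        # site kind as seen by the segment to the right of p
        if minus:
            if p in intron_ends:
                return "donor"
            if p in intron_starts:
                return "acceptor"
        else:
            if p in intron_ends:
                return "acceptor"
            if p in intron_starts:
                return "donor"
        return None

    def right_kind(q: int) -> Optional[str]:
        if minus:
            if q in intron_starts:
                return "acceptor"
            if q in intron_ends:
                return "donor"
        else:
            if q in intron_starts:
                return "donor"
            if q in intron_ends:
                return "acceptor"
        return None

    segments: list[Segment] = []
    n = 0
    for p, q in zip(bounds, bounds[1:]):
        lk, rk = left_kind(p), right_kind(q)
        # transcription orientation: minus strand reads right-to-left
        start_kind, end_kind = (rk, lk) if minus else (lk, rk)
        included = any(_covering_exon(t, p, q) for t in gene.transcripts)
        excluded = any(_covering_intron(t, p, q) for t in gene.transcripts)
        terminal = start_kind is None or end_kind is None
        alternative = included and excluded and not terminal
        status = "alternative" if alternative else "constitutive"
        as_class = classify_as_class(start_kind, end_kind) if alternative else "NA"
        n += 1
        segments.append(
            Segment(
                segment_id=f"{gene.gene_id}.s{n}",
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                start=p,
                end=q,
                strand=gene.strand,
                start_kind=start_kind,
                end_kind=end_kind,
                status=status,
                as_class=as_class,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def _parse_gtf_attrs(field8: str) -> dict[str, str]:
    attrs = {}
    for chunk in field8.rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def _shared_site_groups(
    transcripts: dict[str, list[Interval]]
) -> list[list[str]]:
    """Group transcripts that share at least one splice site (transitively)."""
    tids = list(transcripts)
    site_sets = {}
    for tid in tids:
        exons = transcripts[tid]
        sites = set()
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            sites.add(e0)
            sites.add(s1)
        site_sets[tid] = sites
    parent = {tid: tid for tid in tids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(tids):
        for b in tids[i + 1 :]:
            if site_sets[a] & site_sets[b]:
                parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for tid in tids:
        groups.setdefault(find(tid), []).append(tid)
    return sorted(groups.values(), key=lambda g: g[0])


def read_gtf_genes(path: str, regroup_by_splice_sites: bool = True) -> list[GeneModel]:
    """Read exon features from a GTF file into :class:`GeneModel` objects.

    Transcripts annotated under one ``gene_id`` but sharing no splice site
    are split into separate genes when ``regroup_by_splice_sites`` is set
    (suffixes ``.g1``, ``.g2``, ... are appended).
    """
    per_tx: dict[tuple[str, str, str, str], dict[str, list[Interval]]] = {}
    for line in open(path):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 9 or f[2] != "exon":
            continue
        attrs = _parse_gtf_attrs(f[8])
        gid, tid = attrs["gene_id"], attrs["transcript_id"]
        key = (gid, f[0], f[6], "")
        start, end = int(f[3]) - 1, int(f[4])  # GTF is 1-based inclusive
        per_tx.setdefault(key, {}).setdefault(tid, []).append((start, end))

    genes: list[GeneModel] = []
    for (gid, chrom, strand, _), txs in per_tx.items():
        for tid in txs:
            txs[tid].sort()
        if regroup_by_splice_sites and len(txs) > 1:
            groups = _shared_site_groups(txs)
        else:
            groups = [sorted(txs)]
        multi = len(groups) > 1
        for g, tids in enumerate(groups, start=1):
            name = f"{gid}.g{g}" if multi else gid
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    transcripts=[txs[t] for t in tids],
                    transcript_ids=list(tids),
                )
            )
    return genes


SEGMENT_COLUMNS = (
    "segment_id",
    "gene_id",
    "chrom",
    "start",
    "end",
    "strand",
    "status",
    "as_class",
    "length",
)


def segments_to_rows(segments: Iterable[Segment]) -> Iterator[tuple]:
    for s in segments:
        yield (
            s.segment_id,
            s.gene_id,
            s.chrom,
            s.start,
            s.end,
            s.strand,
            s.status,
            s.as_class,
            s.length,
        )


def write_segments_tsv(segments: Iterable[Segment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for row in segments_to_rows(segments):
            fh.write("\t".join(str(x) for x in row) + "\n")
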