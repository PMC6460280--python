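"""End-TAG deconvolution: map Sanger insert-end reads onto pooled contigs.

Each clone contributes up to two TAGS (vector-anchored Sanger reads into
the two insert ends).  Mapping both TAGS of a clone uniquely onto one
contig, in head-to-head orientation, identifies that contig as the clone's
fully reconstructed insert (FULL); a single uniquely placed end marks a
partial reconstruction (PARTIAL); tied best placements leave the clone
AMBIGUOUS, and anything else is NONE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import build_kmer_index, find_local_hits
from .core import SeqRecord
from .poolasm import Contig


@dataclass(frozen=True)
class TagMapParams:
    """TAG-to-contig mapping thresholds.

    Sanger end reads are high quality but may run past the insert end, so
    only half the tag is required to align by default.  A best hit counts
    as unique when its score beats the runner-up by ≥ ``tie_margin`` of the
    best score.
    """

    min_identity: float = 0.95
    min_tag_coverage: float = 0.50
    tie_margin: float = 0.05
    k: int = 15
    match: int = 1
    mismatch: int = -2
    xdrop: int = 30


@dataclass(frozen=True)
class TagPair:
    clone_id: str
    fwd_tag: SeqRecord | None = None
    rev_tag: SeqRecord | None = None

    def __post_init__(self) -> None:
        if self.fwd_tag is None and self.rev_tag is None:
            raise ValueError(f"clone {self.clone_id}: at least one TAG required")


def pair_tags(tags: list[SeqRecord]) -> list[TagPair]:
    """Group TAG records named ``<clone>__FWD`` / ``<clone>__REV`` into pairs."""
    by_clone: dict[str, dict[str, SeqRecord]] = {}
    for t in tags:
        if "__" not in t.id:
            raise ValueError(f"TAG id {t.id!r} does not follow '<clone>__FWD/REV'")
        clone, end = t.id.rsplit("__", 1)
        if end not in ("FWD", "REV"):
            raise ValueError(f"TAG id {t.id!r}: end must be FWD or REV")
        by_clone.setdefault(clone, {})[end] = t
    return [
        TagPair(clone, d.get("FWD"), d.get("REV")) for clone, d in sorted(by_clone.items())
    ]


@dataclass(frozen=True)
class TagHit:
    tag_id: str
    contig_id: str
    identity: float
    tag_coverage: float
    contig_start: int
    contig_end: int
    strand: str
    score: int


@dataclass(frozen=True)
class TagAssignment:
    clone_id: str
    status: str  # FULL | PARTIAL | AMBIGUOUS | NONE
    contig_id: str | None = None
    ends_matched: tuple[str, ...] = ()
    orientation_consistent: bool | None = None
    span_start: int | None = None
    span_end: int | None = None


def map_tags(
    tag_pairs: list[TagPair],
    contigs: list[Contig],
    params: TagMapParams = TagMapParams(),
) -> list[TagHit]:
    """All acceptable TAG placements, best-first per tag.

    A placement qualifies when identity ≥ ``min_identity`` over the aligned
    span and the span covers ≥ ``min_tag_coverage`` of the tag.  Hits are
    ordered (tag_id, score desc, contig_id asc); tags with no acceptable
    placement are simply absent.
    """
    if not contigs:
        raise ValueError("map_tags requires at least one contig")
    refs = [SeqRecord(c.contig_id, c.residues) for c in contigs]
    index = build_kmer_index(refs, params.k)
    hits: list[TagHit] = []
    for pair in tag_pairs:
        for tag in (pair.fwd_tag, pair.rev_tag):
            if tag is None:
                continue
            for h in find_local_hits(
                tag, refs, index,
                k=params.k, match=params.match, mismatch=params.mismatch, xdrop=params.xdrop,
            ):
                coverage = h.query_span / len(tag)
                if h.identity >= params.min_identity and coverage >= params.min_tag_coverage:
                    hits.append(
                        TagHit(
                            tag_id=tag.id,
                            contig_id=h.ref_id,
                            identity=round(h.identity, 4),
                            tag_coverage=round(coverage, 4),
                            contig_start=h.ref_start,
                            contig_end=h.ref_end,
                            strand=h.strand,
                            score=h.score,
                        )
                    )
    hits.sort(key=lambda h: (h.tag_id, -h.score, h.contig_id))
    return hits


def _best_unique(hits: list[TagHit], tie_margin: float) -> tuple[TagHit | None, bool]:
    """(unique best hit or None, tied-on-different-contigs flag)."""
    if not hits:
        return None, False
    best = hits[0]
    for other in hits[1:]:
        if other.contig_id == best.contig_id:
            continue
        if best.score - other.score < tie_margin * best.score:
            return None, True  # tie across contigs
        break
    return best, False


def assign_clones(
    tag_hits: list[TagHit],
    tag_pairs: list[TagPair],
    params: TagMapParams = TagMapParams(),
) -> list[TagAssignment]:
    """Collapse TAG placements to one status per clone.

    Rules, applied in order: FULL when both ends' unique best hits land on
    one contig on opposite strands; PARTIAL when exactly one end is
    uniquely placed; AMBIGUOUS when an end has tied best placements on
    different contigs; NONE otherwise (including clones with no TAGs,
    which are reported with a warning by the CLI layer).
    """
    by_tag: dict[str, list[TagHit]] = {}
    for h in tag_hits:
        by_tag.setdefault(h.tag_id, []).append(h)
    out: list[TagAssignment] = []
    for pair in sorted(tag_pairs, key=lambda p: p.clone_id):
        ends: dict[str, tuple[TagHit | None, bool]] = {}
        for label, tag in (("FWD", pair.fwd_tag), ("REV", pair.rev_tag)):
            if tag is None:
                ends[label] = (None, False)
            else:
                ends[label] = _best_unique(by_tag.get(tag.id, []), params.tie_margin)
        fwd, fwd_tied = ends["FWD"]
        rev, rev_tied = ends["REV"]
        unique = [(lbl, h) for lbl, h in (("FWD", fwd), ("REV", rev)) if h is not None]
        if (
            len(unique) == 2
            and fwd.contig_id == rev.contig_id
            and fwd.strand != rev.strand
        ):
            span = (min(fwd.contig_start, rev.contig_start), max(fwd.contig_end, rev.contig_end))
            out.append(
                TagAssignment(
                    clone_id=pair.clone_id,
                    status="FULL",
                    contig_id=fwd.contig_id,
                    ends_matched=("FWD", "REV"),
                    orientation_consistent=True,
                    span_start=span[0],
                    span_end=span[1],
                )
            )
        elif len(unique) == 1:
            lbl, h = unique[0]
            out.append(
                TagAssignment(
                    clone_id=pair.clone_id,
                    status="PARTIAL",
                    contig_id=h.contig_id,
                    ends_matched=(lbl,),
                    orientation_consistent=None,
                    span_start=h.contig_start,
                    span_end=h.contig_end,
                )
            )
        elif fwd_tied or rev_tied:
            out.append(TagAssignment(clone_id=pair.clone_id, status="AMBIGUOUS"))
        else:
            out.append(TagAssignment(clone_id=pair.clone_id, status="NONE"))
    return out


@dataclass(frozen=True)
class TaggingSummary:
    n_clones: int
    n_full: int
    n_partial: int
    n_ambiguous: int
    n_none: int
    full_pct: float  # 100 × FULL / n_clones, one decimal


def tagging_report(assignments: list[TagAssignment]) -> TaggingSummary | None:
    """Status counts plus the full-assembly percentage (one decimal).

    Returns None for an empty assignment list (nothing to summarize).
    """
    if not assignments:
        return None
    counts = {"FULL": 0, "PARTIAL": 0, "AMBIGUOUS": 0, "NONE": 0}
    for a in assignments:
        counts[a.status] += 1
    n = len(assignments)
    return TaggingSummary(
        n_clones=n,
        n_full=counts["FULL"],
        n_partial=counts["PARTIAL"],
        n_ambiguous=counts["AMBIGUOUS"],
        n_none=counts["NONE"],
        full_pct=full_percentage(counts["FULL"], n),
    )


def full_percentage(n_full: int, n_clones: int) -> float:
    """100 × FULL / clones, rounded to one decimal (18 of 40 → 45.0)."""
    if n_clones <= 0:
        raise ValueError("n_clones must be positive")
    return round(100.0 * n_full / n_clones, 1)
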