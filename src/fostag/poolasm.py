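"""Pool-level read screening, desk-scale greedy assembly, assembly stats.

Screening removes reads that align to the vector/host references with
expect ≤ 1e-5 over ≥ 70% of the read (both thresholds configurable);
removed reads are discarded whole, and the report records every read's
best hit.  The assembler is a deterministic greedy overlap-layout merger
intended for simulated pools and small real datasets — an externally
assembled contig FASTA can be used instead anywhere contigs are consumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .align import LocalHit, build_kmer_index, edit_distance, find_local_hits
from .core import SeqRecord, revcomp


@dataclass(frozen=True)
class ScreenParams:
    """Vector/host screening thresholds and alignment scoring."""

    evalue_max: float = 1e-5
    min_read_coverage: float = 0.70
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5    # kept for interface compatibility; the default
    gap_extend: int = -2  # engine extends gap-free (substitution-only data)
    k: int = 11
    xdrop: int = 20
    karlin_K: float = 0.621

    def __post_init__(self) -> None:
        if not (0 < self.min_read_coverage <= 1):
            raise ValueError("min_read_coverage must be in (0, 1]")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")


@dataclass(frozen=True)
class ScreenRecord:
    read_id: str
    ref_id: str | None
    evalue: float | None
    read_coverage: float
    verdict: str  # "kept" or "removed"


@dataclass(frozen=True)
class Contig:
    contig_id: str
    residues: str
    mean_depth: float = 0.0

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_nt: int
    longest_nt: int
    n_gt_1kb: int
    n_gt_10kb: int
    mean_nt: int
    n50_nt: int
    l50_count: int

    TSV_LABELS = (
        ("Number of contigs", "n_contigs"),
        ("Total size of contigs (nt)", "total_nt"),
        ("Size of longest contig (nt)", "longest_nt"),
        ("Number of contigs > 1 kb", "n_gt_1kb"),
        ("Number of contigs > 10 kb", "n_gt_10kb"),
        ("Mean contig size (nt)", "mean_nt"),
        ("N50 contig size (nt)", "n50_nt"),
        ("L50 contig count (nt)", "l50_count"),
    )

    def rows(self) -> list[tuple[str, int]]:
        return [(label, getattr(self, attr)) for label, attr in self.TSV_LABELS]


def screen_reads(
    reads: list[SeqRecord],
    screen_refs: list[SeqRecord],
    params: ScreenParams = ScreenParams(),
) -> tuple[list[SeqRecord], list[SeqRecord], list[ScreenRecord]]:
    """Partition reads into (kept, removed) against vector/host references.

    A read is removed iff its gap-free local alignments to one reference,
    all with E ≤ ``evalue_max``, jointly cover ≥ ``min_read_coverage`` of
    the read (joint coverage lets reads spanning a circular reference's
    origin screen correctly).  The report lists each read's best-scoring
    hit and verdict; kept and removed always partition the input.
    """
    if not screen_refs:
        raise ValueError("screening requires at least one reference sequence")
    if not reads:
        return [], [], []
    index = build_kmer_index(screen_refs, params.k)
    kept: list[SeqRecord] = []
    removed: list[SeqRecord] = []
    report: list[ScreenRecord] = []
    for read in reads:
        hits = find_local_hits(
            read, screen_refs, index,
            k=params.k, match=params.match, mismatch=params.mismatch,
            xdrop=params.xdrop, K=params.karlin_K,
        )
        # combined query coverage per reference over significant hits, so a
        # read spanning the circular vector's origin (two HSPs) still screens
        by_ref: dict[str, list[tuple[int, int]]] = {}
        for h in hits:
            if h.evalue <= params.evalue_max:
                by_ref.setdefault(h.ref_id, []).append((h.query_start, h.query_end))
        qualifying = any(
            _union_length(spans) / len(read) >= params.min_read_coverage
            for spans in by_ref.values()
        )
        best: LocalHit | None = hits[0] if hits else None
        verdict = "removed" if qualifying else "kept"
        (removed if qualifying else kept).append(read)
        report.append(
            ScreenRecord(
                read_id=read.id,
                ref_id=best.ref_id if best else None,
                evalue=best.evalue if best else None,
                read_coverage=(best.query_span / len(read)) if best else 0.0,
                verdict=verdict,
            )
        )
    return kept, removed, report


def _union_length(spans: list[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for s, e in sorted(spans):
        s = max(s, last_end)
        if e > s:
            total += e - s
            last_end = e
        last_end = max(last_end, e)
    return total


class _Draft:
    """Mutable contig under construction (internal to the assembler)."""

    __slots__ = ("seq", "offset", "depth_bases", "alive")

    def __init__(self, seq: str):
        self.seq = seq
        self.offset = 0  # actual_pos = stored_pos - offset
        self.depth_bases = len(seq)
        self.alive = True


def _try_place(
    draft: _Draft, q: str, diag: int, min_overlap: int, min_identity: float
) -> tuple[int, int] | None:
    """Check whether q placed at contig coordinate ``diag`` overlaps acceptably.

    Returns (overlap_start, overlap_end) in contig coordinates, or None.
    """
    L = len(draft.seq)
    ov_s, ov_e = max(0, diag), min(L, diag + len(q))
    ov = ov_e - ov_s
    if ov < min_overlap:
        return None
    c_part = draft.seq[ov_s:ov_e]
    q_part = q[ov_s - diag : ov_e - diag]
    allowed = int(math.floor((1 - min_identity) * ov + 1e-9))
    if edit_distance(q_part, c_part, limit=allowed) == -1:
        return None
    return ov_s, ov_e


def greedy_assemble(
    reads: list[SeqRecord],
    min_overlap: int = 40,
    min_identity: float = 0.95,
    k: int = 21,
) -> list[Contig]:
    """Deterministic greedy overlap assembly of (cleaned) reads.

    Reads are taken longest-first (id tie-break) and merged into the draft
    contig sharing the most k-mers on a consistent diagonal, provided the
    implied overlap is ≥ ``min_overlap`` nt at ≥ ``min_identity``; both read
    orientations are tried.  A final pass merges draft contigs against each
    other and drops contained duplicates.  Identical inputs give identical
    contig output, with contigs named by descending length.
    """
    order = sorted(reads, key=lambda r: (-len(r), r.id))
    drafts: list[_Draft] = []
    index: dict[str, list[tuple[int, int]]] = {}

    def index_region(di: int, lo: int, hi: int) -> None:
        d = drafts[di]
        s = d.seq
        for pos in range(max(0, lo), min(len(s) - k + 1, hi)):
            index.setdefault(s[pos : pos + k], []).append((di, pos + d.offset))

    def candidates(q: str) -> list[tuple[int, int, int]]:
        votes: dict[tuple[int, int], int] = {}
        for qpos in range(0, len(q) - k + 1):
            for di, stored in index.get(q[qpos : qpos + k], ()):
                if not drafts[di].alive:
                    continue
                diag = (stored - drafts[di].offset) - qpos
                key = (di, diag)
                votes[key] = votes.get(key, 0) + 1
        return sorted(
            ((v, di, diag) for (di, diag), v in votes.items()),
            key=lambda t: (-t[0], t[1], t[2]),
        )[:4]

    def merge(di: int, q: str, diag: int) -> None:
        d = drafts[di]
        d.depth_bases += len(q)
        if diag < 0:  # read sticks out to the left
            prefix = q[: -diag]
            d.seq = prefix + d.seq
            d.offset -= len(prefix)
            index_region(di, 0, len(prefix) + k - 1)
            diag = 0
        if diag + len(q) > len(d.seq):  # sticks out to the right
            tail_start = len(d.seq)
            d.seq = d.seq + q[len(d.seq) - diag :]
            index_region(di, tail_start - k + 1, len(d.seq))

    for read in order:
        placed = False
        for q in (read.residues, revcomp(read.residues)):
            for _votes, di, diag in candidates(q):
                span = _try_place(drafts[di], q, diag, min_overlap, min_identity)
                if span is not None:
                    merge(di, q, diag)
                    placed = True
                    break
            if placed:
                break
        if not placed:
            di = len(drafts)
            drafts.append(_Draft(read.residues))
            index_region(di, 0, len(read.residues))

    _merge_drafts(drafts, min_overlap, min_identity, k)

    final = sorted(
        (d for d in drafts if d.alive), key=lambda d: (-len(d.seq), d.seq)
    )
    width = max(5, len(str(len(final))))
    return [
        Contig(f"contig_{i + 1:0{width}d}", d.seq, round(d.depth_bases / len(d.seq), 2))
        for i, d in enumerate(final)
    ]


def _merge_drafts(drafts: list[_Draft], min_overlap: int, min_identity: float, k: int) -> None:
    """Repeatedly merge draft contigs that overlap or contain one another."""
    changed = True
    while changed:
        changed = False
        alive = sorted(
            (i for i, d in enumerate(drafts) if d.alive),
            key=lambda i: (-len(drafts[i].seq), i),
        )
        for ai in range(len(alive)):
            a = drafts[alive[ai]]
            if not a.alive:
                continue
            a_index = {}
            for pos in range(len(a.seq) - k + 1):
                a_index.setdefault(a.seq[pos : pos + k], []).append(pos)
            for bi in range(ai + 1, len(alive)):
                b = drafts[alive[bi]]
                if not b.alive:
                    continue
                for q in (b.seq, revcomp(b.seq)):
                    votes: dict[int, int] = {}
                    for qpos in range(0, len(q) - k + 1, max(1, k // 2)):
                        for pos in a_index.get(q[qpos : qpos + k], ()):
                            d = pos - qpos
                            votes[d] = votes.get(d, 0) + 1
                    merged = False
                    for diag, _v in sorted(votes.items(), key=lambda t: (-t[1], t[0]))[:3]:
                        span = _try_place(a, q, diag, min_overlap, min_identity)
                        if span is None:
                            continue
                        if diag >= 0 and diag + len(q) <= len(a.seq):
                            pass  # contained duplicate: fold into a
                        else:
                            new = (q[:-diag] if diag < 0 else "") + a.seq
                            if diag + len(q) > len(a.seq):
                                new = new + q[len(a.seq) - diag :]
                            a.seq = new
                            a_index = {}
                            for pos in range(len(a.seq) - k + 1):
                                a_index.setdefault(a.seq[pos : pos + k], []).append(pos)
                        a.depth_bases += b.depth_bases
                        b.alive = False
                        changed = True
                        merged = True
                        break
                    if merged:
                        break


def mean_contig_size(total_nt: int, n_contigs: int) -> int:
    """Mean contig size rounded half away from zero to an integer."""
    if n_contigs <= 0:
        raise ValueError("n_contigs must be positive")
    return int(math.floor(total_nt / n_contigs + 0.5))


def assembly_stats(contigs: list[Contig]) -> AssemblyStats:
    """Descending-length summary: totals, >1 kb / >10 kb counts, mean, N50/L50.

    N50 is the smallest length in the descending-length prefix whose
    cumulative sum reaches half the total (inclusive when the sum lands
    exactly on total/2); L50 is the number of contigs in that prefix.
    """
    if not contigs:
        raise ValueError("assembly_stats requires at least one contig")
    lengths = sorted((len(c) for c in contigs), reverse=True)
    total = sum(lengths)
    half = total / 2
    cum = 0
    n50 = lengths[-1]
    l50 = len(lengths)
    for i, L in enumerate(lengths):
        cum += L
        if cum >= half:
            n50, l50 = L, i + 1
            break
    return AssemblyStats(
        n_contigs=len(lengths),
        total_nt=total,
        longest_nt=lengths[0],
        n_gt_1kb=sum(1 for L in lengths if L > 1000),
        n_gt_10kb=sum(1 for L in lengths if L > 10000),
        mean_nt=mean_contig_size(total, len(lengths)),
        n50_nt=n50,
        l50_count=l50,
    )


def theoretical_coverage(n_reads: int, mean_read_len: float, n_clones: int, clone_len: float = 44000.0) -> float:
    """Fold coverage per clone: ``n_reads × mean_read_len / (n_clones × clone_len)``.

    The default clone length of 44 kb corresponds to a ~36 kb insert plus an
    ~8 kb vector; all four terms are explicit so callers can substitute the
    read count and fosmid length convention they prefer.
    """
    if n_reads <= 0 or mean_read_len <= 0 or n_clones <= 0 or clone_len <= 0:
        raise ValueError("all inputs to theoretical_coverage must be positive")
    return n_reads * mean_read_len / (n_clones * clone_len)
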