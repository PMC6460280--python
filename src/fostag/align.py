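"""Seed-and-extend local alignment and identity helpers.

A deliberately small alignment engine for desk-scale screening and TAG
mapping: exact k-mer seeds grouped by diagonal, gap-free X-drop extension
(maximal-scoring span, not the drop point), and ungapped Karlin–Altschul
E-values for the configured match/mismatch scores.  N never matches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import edlib
from scipy.optimize import brentq

from .core import SeqRecord, revcomp


@dataclass(frozen=True)
class LocalHit:
    """One gap-free local alignment of a query against a reference."""

    query_id: str
    ref_id: str
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    matches: int
    score: int
    strand: str  # orientation of the query relative to the reference
    evalue: float = math.inf

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def identity(self) -> float:
        return self.matches / self.query_span


@lru_cache(maxsize=None)
def karlin_lambda(match: int, mismatch: int) -> float:
    """λ for an ungapped match/mismatch score pair at uniform base composition.

    Solves ``0.25 e^{λ·match} + 0.75 e^{λ·mismatch} = 1`` for λ > 0.
    """
    if match <= 0 or mismatch >= 0:
        raise ValueError("need match > 0 and mismatch < 0")

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-6, 10.0))


def evalue(score: int, m: int, n: int, match: int, mismatch: int, K: float) -> float:
    """Ungapped Karlin–Altschul expect: ``K·m·n·e^{−λS}``."""
    lam = karlin_lambda(match, mismatch)
    return K * m * n * math.exp(-lam * score)


def build_kmer_index(refs: list[SeqRecord], k: int) -> dict[str, list[tuple[int, int]]]:
    """Map every reference k-mer to its (ref index, position) occurrences."""
    index: dict[str, list[tuple[int, int]]] = {}
    for ri, ref in enumerate(refs):
        s = ref.residues
        for pos in range(len(s) - k + 1):
            kmer = s[pos : pos + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((ri, pos))
    return index


def _extend_ungapped(
    q: str, r: str, qpos: int, rpos: int, k: int, match: int, mismatch: int, xdrop: int
) -> tuple[int, int, int, int, int, int]:
    """Extend an exact k-mer anchor gap-free in both directions.

    Returns (query_start, query_end, ref_start, ref_end, matches, score) of
    the maximal-scoring span containing the anchor.
    """
    score = k * match
    matches = k
    # right of the anchor
    best = score
    best_i = 0
    best_m = 0
    run_m = 0
    i = 0
    qi, ri_ = qpos + k, rpos + k
    run = score
    while qi + i < len(q) and ri_ + i < len(r):
        a, b = q[qi + i], r[ri_ + i]
        if a == b and a != "N":
            run += match
            run_m += 1
        else:
            run += mismatch
        i += 1
        if run > best:
            best, best_i, best_m = run, i, run_m
        elif best - run > xdrop:
            break
    q_end, r_end = qi + best_i, ri_ + best_i
    score, matches = best, matches + best_m
    # left of the anchor
    best = score
    best_i = 0
    best_m = 0
    run_m = 0
    i = 0
    run = score
    while qpos - i > 0 and rpos - i > 0:
        a, b = q[qpos - i - 1], r[rpos - i - 1]
        if a == b and a != "N":
            run += match
            run_m += 1
        else:
            run += mismatch
        i += 1
        if run > best:
            best, best_i, best_m = run, i, run_m
        elif best - run > xdrop:
            break
    return qpos - best_i, q_end, rpos - best_i, r_end, matches + best_m, best


def find_local_hits(
    query: SeqRecord,
    refs: list[SeqRecord],
    index: dict[str, list[tuple[int, int]]],
    *,
    k: int = 11,
    match: int = 1,
    mismatch: int = -2,
    xdrop: int = 20,
    max_diagonals: int = 12,
    K: float = 0.621,
    search_revcomp: bool = True,
) -> list[LocalHit]:
    """Best gap-free local hits of a query against an indexed reference set.

    Seeds are binned by (reference, diagonal); the most seed-rich diagonals
    are extended and overlapping extensions on the same reference are
    deduplicated, keeping the higher score.  Hits come back sorted by
    (score desc, ref_id asc, ref_start asc) with E-values attached.
    """
    n_total = sum(len(r) for r in refs)
    orientations = [("+", query.residues)]
    if search_revcomp:
        orientations.append(("-", revcomp(query.residues)))
    hits: list[LocalHit] = []
    for strand, q in orientations:
        diags: dict[tuple[int, int], list[int]] = {}
        for qpos in range(0, len(q) - k + 1):
            kmer = q[qpos : qpos + k]
            for ri, rpos in index.get(kmer, ()):
                diags.setdefault((ri, rpos - qpos), []).append(qpos)
        if not diags:
            continue
        ranked = sorted(diags.items(), key=lambda kv: (-len(kv[1]), kv[0]))[:max_diagonals]
        seen_spans: dict[int, list[tuple[int, int, int]]] = {}
        for (ri, diag), qlist in ranked:
            qpos = qlist[0]
            rpos = qpos + diag
            qs, qe, rs, re_, m, s = _extend_ungapped(
                q, refs[ri].residues, qpos, rpos, k, match, mismatch, xdrop
            )
            spans = seen_spans.setdefault(ri, [])
            if any(rs < e and b < re_ and sc >= s for b, e, sc in spans):
                continue  # contained in / worse than an existing extension
            spans.append((rs, re_, s))
            if strand == "-":  # report query coords on the original read
                qs, qe = len(q) - qe, len(q) - qs
            hits.append(
                LocalHit(
                    query_id=query.id,
                    ref_id=refs[ri].id,
                    query_start=qs,
                    query_end=qe,
                    ref_start=rs,
                    ref_end=re_,
                    matches=m,
                    score=s,
                    strand=strand,
                    evalue=evalue(s, len(query), n_total, match, mismatch, K),
                )
            )
    hits.sort(key=lambda h: (-h.score, h.ref_id, h.ref_start))
    return hits


def edit_distance(a: str, b: str, limit: int = -1) -> int:
    """Levenshtein distance (edlib); -1 if a limit is given and exceeded."""
    return edlib.align(a, b, mode="NW", task="distance", k=limit)["editDistance"]


def edit_identity(a: str, b: str) -> float:
    """Normalized edit similarity: ``1 − d(a, b) / max(|a|, |b|)``."""
    d = edit_distance(a, b)
    return 1.0 - d / max(len(a), len(b))


def meets_identity(a: str, b: str, threshold: float) -> bool:
    """True iff edit identity ≥ threshold, using a banded early-exit search."""
    longest = max(len(a), len(b))
    allowed = int(math.floor((1.0 - threshold) * longest + 1e-9))
    if abs(len(a) - len(b)) > allowed:
        return False
    return edit_distance(a, b, limit=allowed) != -1
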