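"""ORF prediction, redundancy clustering, enzyme categorization, GO-slim.

This module carries the annotation half of the pipeline:

* six-frame ORF calling with the prokaryotic start/stop convention and a
  longest-ORF-per-stop rule (one gene per locus);
* greedy incremental peptide clustering at an identity threshold, the
  longest member seeding each cluster;
* domain evidence, either parsed from a HMMER per-domain table produced by
  an external profile search, or from the built-in position-weight-matrix
  motif scanner (used with simulated data, where planted genes carry known
  marker peptides);
* collapse of domain hits to one enzyme class per protein by most
  significant E-value, against a user-supplied domain→category table;
* rollup of domain→GO annotations to their nearest GO-slim ancestors.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import GeneticCode, Interval, SeqRecord, TABLE11, revcomp, translate
from .poolasm import Contig
from .tagmap import TagAssignment
from . import simlib

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


# ---------------------------------------------------------------------------
# ORF prediction

@dataclass(frozen=True)
class OrfParams:
    code: GeneticCode = TABLE11
    min_protein_aa: int = 30

    def __post_init__(self) -> None:
        if self.min_protein_aa < 1:
            raise ValueError("min_protein_aa must be >= 1")


@dataclass(frozen=True)
class OrfPrediction:
    orf_id: str
    contig_id: str
    interval: Interval  # forward-strand coordinates
    strand: str
    frame: int  # 0-2 on the scanned strand
    nt_length: int  # includes the stop codon
    aa_length: int  # nt_length / 3 - 1
    protein: str
    partial: bool = False  # runs off a contig edge (no stop seen)


def orf_scan(
    contig: Contig | SeqRecord,
    params: OrfParams = OrfParams(),
    include_partial: bool = False,
) -> list[OrfPrediction]:
    """All maximal complete ORFs on six frames of a contig.

    An ORF begins at a start codon (ATG/GTG/TTG), ends at the first
    in-frame stop, and encodes at least ``min_protein_aa`` residues.
    Within a frame, later starts sharing the same stop are suppressed
    (longest-per-stop).  ORFs that run off the contig edge are flagged
    partial and only reported when ``include_partial`` is set.  Output is
    ordered by forward-strand start coordinate.
    """
    seq = contig.residues
    cid = contig.contig_id if isinstance(contig, Contig) else contig.id
    code = params.code
    min_nt = (params.min_protein_aa + 1) * 3
    n = len(seq)
    found: list[tuple[int, int, str, int, bool]] = []  # fwd_start, fwd_end, strand, frame, partial
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            pending: int | None = None
            pos = frame
            while pos + 3 <= n:
                codon = s[pos : pos + 3]
                if code.is_stop(codon):
                    if pending is not None:
                        length = pos + 3 - pending
                        if length >= min_nt:
                            found.append(_orient(pending, pos + 3, strand, frame, n, False))
                        pending = None
                elif pending is None and code.is_start(codon):
                    pending = pos
                pos += 3
            if pending is not None and include_partial:
                end = pos  # last complete codon boundary
                if end - pending >= min_nt:
                    found.append(_orient(pending, end, strand, frame, n, True))
    found.sort(key=lambda t: (t[0], t[1], t[2]))
    out: list[OrfPrediction] = []
    for i, (fs, fe, strand, frame, partial) in enumerate(found):
        if strand == "+":
            cds = seq[fs:fe]
        else:
            cds = revcomp(seq[fs:fe])
        nt = fe - fs
        if partial:
            protein = "".join(
                code.aa(cds[p : p + 3]) for p in range(0, nt, 3)
            )
            aa = nt // 3
        else:
            protein = translate(cds, code)
            aa = nt // 3 - 1
        out.append(
            OrfPrediction(
                orf_id=f"{cid}_orf{i + 1:05d}",
                contig_id=cid,
                interval=Interval(cid, fs, fe, strand),
                strand=strand,
                frame=frame,
                nt_length=nt,
                aa_length=aa,
                protein=protein,
                partial=partial,
            )
        )
    return out


def _orient(start: int, end: int, strand: str, frame: int, n: int, partial: bool):
    if strand == "+":
        return (start, end, strand, frame, partial)
    return (n - end, n - start, strand, frame, partial)


# ---------------------------------------------------------------------------
# Redundancy clustering

@dataclass(frozen=True)
class ClusterParams:
    """Greedy clustering settings.

    ``identity_threshold`` is the normalized edit similarity
    ``1 − d/max(|a|, |b|)`` required between a peptide and a cluster seed,
    i.e. near-identity along the entire protein, both sequences end to end.
    """

    identity_threshold: float = 0.90

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError("identity_threshold must be in (0, 1]")


@dataclass(frozen=True)
class Cluster:
    seed_id: str
    seed_length: int
    member_ids: tuple[str, ...]


def cluster_peptides(
    proteins: list[SeqRecord], params: ClusterParams = ClusterParams()
) -> list[Cluster]:
    """Greedy incremental clustering, longest peptides first.

    Peptides are visited by (length desc, id asc); each joins the earliest
    existing cluster whose seed reaches the identity threshold, else founds
    a new cluster with itself as seed.  Every peptide lands in exactly one
    cluster.  A shared-5-mer prefilter prunes seed comparisons; it is exact
    for thresholds ≥ 0.9 on peptides of ≥ 11 residues and is bypassed below
    that, so the partition never depends on it.
    """
    if not proteins:
        return []
    from .align import meets_identity

    order = sorted(proteins, key=lambda p: (-len(p), p.id))
    t = params.identity_threshold
    use_prefilter = t >= 0.9 and all(len(p) >= 11 for p in proteins)
    seeds: list[SeqRecord] = []
    members: list[list[str]] = []
    kmer_to_clusters: dict[str, set[int]] = {}

    def seed_kmers(s: str) -> set[str]:
        return {s[i : i + 5] for i in range(len(s) - 4)}

    for pep in order:
        L = len(pep)
        if use_prefilter:
            cand: set[int] = set()
            for kmer in seed_kmers(pep.residues):
                cand |= kmer_to_clusters.get(kmer, set())
            candidates = sorted(cand)
        else:
            candidates = range(len(seeds))
        joined = False
        for ci in candidates:
            seed = seeds[ci]
            if min(L, len(seed)) + 1e-9 < t * max(L, len(seed)):
                continue
            if meets_identity(pep.residues, seed.residues, t):
                members[ci].append(pep.id)
                joined = True
                break
        if not joined:
            ci = len(seeds)
            seeds.append(pep)
            members.append([pep.id])
            if use_prefilter:
                for kmer in seed_kmers(pep.residues):
                    kmer_to_clusters.setdefault(kmer, set()).add(ci)
    return [
        Cluster(seed_id=s.id, seed_length=len(s), member_ids=tuple(m))
        for s, m in zip(seeds, members)
    ]


@dataclass(frozen=True)
class SeedStats:
    n_clusters: int
    mean_aa: float
    sd_aa: float  # population standard deviation
    max_aa: int


def seed_stats(clusters: list[Cluster]) -> SeedStats:
    """Mean, population SD and max of cluster-seed lengths."""
    if not clusters:
        raise ValueError("seed_stats requires at least one cluster")
    lengths = np.array([c.seed_length for c in clusters], dtype=float)
    return SeedStats(
        n_clusters=len(clusters),
        mean_aa=float(lengths.mean()),
        sd_aa=float(lengths.std()),  # ddof=0
        max_aa=int(lengths.max()),
    )


# ---------------------------------------------------------------------------
# Domain evidence

@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    domain_accession: str
    domain_name: str
    evalue: float  # per-domain independent E-value
    env_start: int  # 0-based half-open on the protein
    env_end: int

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("E-value must be positive")


class DomainTableError(ValueError):
    """Malformed HMMER per-domain tabular file."""


def parse_domain_hits(path: str | Path, evalue_cutoff: float = 1e-10) -> list[DomainHit]:
    """Parse a HMMER ``--domtblout`` per-domain table, keeping E ≤ cutoff.

    Expects the hmmscan orientation (target = domain profile, query =
    protein); the independent (i-Evalue) column is used.  Malformed data
    lines raise :class:`DomainTableError` with their line number, as does
    a file with no parsable lines at all.
    """
    path = Path(path)
    if not path.exists():
        raise DomainTableError(f"no such domain table: {path}")
    hits: list[DomainHit] = []
    parsable = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise DomainTableError(
                    f"{path}:{lineno}: expected >= 22 whitespace-separated fields, got {len(fields)}"
                )
            try:
                evalue = float(fields[12])
                env_from, env_to = int(fields[19]), int(fields[20])
            except ValueError as exc:
                raise DomainTableError(f"{path}:{lineno}: {exc}") from exc
            parsable += 1
            if evalue > evalue_cutoff:
                continue
            accession = fields[1] if fields[1] != "-" else fields[0]
            hits.append(
                DomainHit(
                    protein_id=fields[3],
                    domain_accession=accession,
                    domain_name=fields[0],
                    evalue=evalue,
                    env_start=env_from - 1,
                    env_end=env_to,
                )
            )
    if parsable == 0:
        raise DomainTableError(f"{path}: no parsable domain lines")
    return hits


class MotifModelError(ValueError):
    pass


@dataclass
class MotifModel:
    """Position-weight-matrix motif with exact score calibration.

    The log-odds matrix is scored against a uniform 20-letter background;
    the null score distribution is computed exactly by convolution over
    columns (discretized to ``step``), so a window score converts to a
    p-value and then to a database-level E-value analytically.
    """

    name: str
    accession: str
    pwm: np.ndarray  # (w, 20) natural-log odds
    step: float = 0.01
    _grid: np.ndarray = field(init=False, repr=False)
    _sf: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.pwm.ndim != 2 or self.pwm.shape[1] != len(AA_ALPHABET):
            raise MotifModelError("PWM must have one column per standard amino acid")
        dist: dict[int, float] = {0: 1.0}
        for col in self.pwm:
            ints, counts = np.unique(np.round(col / self.step).astype(int), return_counts=True)
            nxt: dict[int, float] = {}
            for v, c in zip(ints, counts):
                p = c / len(AA_ALPHABET)
                for s, q in dist.items():
                    nxt[s + v] = nxt.get(s + v, 0.0) + q * p
            dist = nxt
        grid = np.array(sorted(dist), dtype=np.int64)
        probs = np.array([dist[g] for g in grid])
        self._grid = grid
        self._sf = probs[::-1].cumsum()[::-1]  # survival function over grid

    @property
    def width(self) -> int:
        return len(self.pwm)

    @classmethod
    def from_peptide(
        cls, peptide: str, accession: str, name: str, consensus_prob: float = 0.9
    ) -> "MotifModel":
        """Degenerate-consensus model: one dominant residue per column."""
        bad = set(peptide) - set(AA_ALPHABET)
        if bad:
            raise MotifModelError(f"motif peptide has non-standard residues {sorted(bad)}")
        w = len(peptide)
        other = (1.0 - consensus_prob) / (len(AA_ALPHABET) - 1)
        bg = 1.0 / len(AA_ALPHABET)
        pwm = np.full((w, len(AA_ALPHABET)), math.log(other / bg))
        for i, aa in enumerate(peptide):
            pwm[i, _AA_INDEX[aa]] = math.log(consensus_prob / bg)
        return cls(name=name, accession=accession, pwm=pwm)

    def pvalue(self, score: float) -> float:
        """P(null window score ≥ score); conservative at grid boundaries."""
        key = int(math.floor(score / self.step + 1e-9))
        i = np.searchsorted(self._grid, key, side="left")
        if i >= len(self._grid):
            return float(self._sf[-1]) if key <= self._grid[-1] else 0.0
        return float(self._sf[i])

    def best_window(self, protein: str) -> tuple[float, int] | None:
        """(best score, window start) over all windows, None if too short."""
        w = self.width
        if len(protein) < w:
            return None
        enc = np.array([_AA_INDEX.get(aa, -1) for aa in protein], dtype=np.int64)
        windows = np.lib.stride_tricks.sliding_window_view(enc, w)
        # non-standard residues (X, *) score as the worst column entry
        col_min = self.pwm.min(axis=1)
        scores = np.where(
            windows >= 0,
            self.pwm[np.arange(w)[None, :], np.clip(windows, 0, None)],
            col_min[None, :],
        ).sum(axis=1)
        best = int(np.argmax(scores))
        return float(scores[best]), best


def default_motif_models(consensus_prob: float = 0.9) -> list[MotifModel]:
    """Models matching the simulator's planted marker peptides."""
    return [
        MotifModel.from_peptide(
            simlib.MARKER_PEPTIDES[cat],
            accession=simlib.MARKER_ACCESSIONS[cat],
            name=f"{cat}_marker",
            consensus_prob=consensus_prob,
        )
        for cat in simlib.CATEGORIES
    ]


def fallback_motif_scan(
    proteins: list[SeqRecord],
    motif_models: list[MotifModel],
    evalue_cutoff: float = 1e-10,
) -> list[DomainHit]:
    """PWM scan producing :class:`DomainHit` rows, HMMER-table compatible.

    E-value of a protein's best window = exact null p-value × total number
    of windows scanned for that motif across the whole protein set, so
    thresholds behave like database-wide expects.
    """
    hits: list[DomainHit] = []
    for model in motif_models:
        n_windows = sum(max(0, len(p) - model.width + 1) for p in proteins)
        if n_windows == 0:
            continue
        for p in proteins:
            bw = model.best_window(p.residues)
            if bw is None:
                continue
            score, start = bw
            evalue = model.pvalue(score) * n_windows
            if 0 < evalue <= evalue_cutoff:
                hits.append(
                    DomainHit(
                        protein_id=p.id,
                        domain_accession=model.accession,
                        domain_name=model.name,
                        evalue=evalue,
                        env_start=start,
                        env_end=start + model.width,
                    )
                )
    hits.sort(key=lambda h: (h.protein_id, h.evalue, h.domain_accession))
    return hits


# ---------------------------------------------------------------------------
# Enzyme-category calls

@dataclass(frozen=True)
class CategoryCall:
    protein_id: str
    category: str  # lipase_esterase | protease | other
    best_evalue_per_category: tuple[tuple[str, float], ...] = ()


def load_category_table(path: str | Path) -> dict[str, str]:
    """Load a domain→category TSV (accession, category); '#' comments allowed."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or parts[1] not in ("lipase_esterase", "protease"):
                if parts[0].lower() == "accession":  # header row
                    continue
                raise ValueError(f"{path}:{lineno}: expected 'accession<TAB>lipase_esterase|protease'")
            table[parts[0]] = parts[1]
    if not table:
        raise ValueError(f"{path}: empty category table")
    return table


def categorize(hits: list[DomainHit], category_table: dict[str, str]) -> list[CategoryCall]:
    """One enzyme class per protein, by most significant listed-domain hit.

    A protein whose hits include both lipase/esterase and protease domains
    is resolved to the class of its best (smallest) E-value; proteins with
    no table-listed hits are 'other'.  Exactly one call per protein that
    has any hit.
    """
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    calls: list[CategoryCall] = []
    for pid in sorted(by_protein):
        listed = [h for h in by_protein[pid] if h.domain_accession in category_table]
        best_per_cat: dict[str, float] = {}
        for h in listed:
            cat = category_table[h.domain_accession]
            best_per_cat[cat] = min(best_per_cat.get(cat, math.inf), h.evalue)
        if listed:
            best = min(listed, key=lambda h: (h.evalue, h.domain_accession))
            category = category_table[best.domain_accession]
        else:
            category = "other"
        calls.append(
            CategoryCall(
                protein_id=pid,
                category=category,
                best_evalue_per_category=tuple(sorted(best_per_cat.items())),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# GO-slim rollup

@dataclass(frozen=True)
class GoMaps:
    """Domain→GO mapping, GO parent edges, and the slim term set."""

    domain_to_go: dict[str, tuple[str, ...]]
    parents: dict[str, tuple[str, ...]]
    slim_terms: frozenset[str]

    def __post_init__(self) -> None:
        _check_acyclic(self.parents)


def _check_acyclic(parents: dict[str, tuple[str, ...]]) -> None:
    state: dict[str, int] = {}  # 1 = on stack, 2 = done

    def visit(node: str) -> None:
        state[node] = 1
        for p in parents.get(node, ()):
            s = state.get(p)
            if s == 1:
                raise ValueError(f"GO parent edges contain a cycle through {node!r}")
            if s is None:
                visit(p)
        state[node] = 2

    for n in list(parents):
        if state.get(n) is None:
            visit(n)


def load_domain_to_go(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a pfam2go-style mapping.

    Accepts either the classic ``Pfam:PF00012 HSP70 > GO:... ; GO:0006457``
    lines or a plain two-column TSV (accession, GO id).
    """
    mapping: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("!", "#")):
                continue
            if ">" in line and ";" in line:
                left, _, right = line.partition(">")
                acc = left.split()[0].split(":", 1)[-1]
                go_id = right.rsplit(";", 1)[1].strip()
            else:
                parts = line.split("\t")
                if len(parts) < 2:
                    continue
                acc, go_id = parts[0], parts[1]
            mapping.setdefault(acc, []).append(go_id)
    return {k: tuple(v) for k, v in mapping.items()}


def load_edges(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a (child, parent) TSV edge list into a child→parents map."""
    parents: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            child, parent = line.split("\t")[:2]
            parents.setdefault(child, []).append(parent)
    return {k: tuple(v) for k, v in parents.items()}


def load_term_list(path: str | Path) -> frozenset[str]:
    with open(path) as fh:
        return frozenset(
            line.strip() for line in fh if line.strip() and not line.startswith("#")
        )


def nearest_slim_ancestors(term: str, maps: GoMaps) -> tuple[int, tuple[str, ...]]:
    """BFS climb to the nearest slim ancestor(s) of a GO term.

    Returns (distance, terms); a slim term maps to itself at distance 0;
    (−1, ()) when no slim ancestor is reachable.
    """
    if term in maps.slim_terms:
        return 0, (term,)
    seen = {term}
    frontier = [term]
    dist = 0
    while frontier:
        dist += 1
        nxt: list[str] = []
        for t in frontier:
            for p in maps.parents.get(t, ()):
                if p not in seen:
                    seen.add(p)
                    nxt.append(p)
        hits = sorted(p for p in nxt if p in maps.slim_terms)
        if hits:
            return dist, tuple(hits)
        frontier = nxt
    return -1, ()


@dataclass(frozen=True)
class SlimRollup:
    counts: dict[str, int]  # slim term → annotation count (ties counted at each)
    n_annotations: int  # domain→GO annotations considered
    n_mapped: int  # annotations with >= 1 slim ancestor
    n_unmapped: int

    def fractions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        if total == 0:
            return {}
        return {t: c / total for t, c in sorted(self.counts.items())}


def goslim_rollup(hits: list[DomainHit], maps: GoMaps) -> SlimRollup:
    """Climb every domain hit's GO annotations to GO-slim terms.

    Each (hit, GO term) annotation contributes one count at every nearest
    slim ancestor (ties kept), so multi-domain proteins and tied ancestors
    can make the total exceed the protein count.  Annotations whose term is
    absent from the ontology, or has no slim ancestor, are tallied as
    unmapped (with a warning for absent terms).  Every annotation is
    either mapped (≥ 1 slim ancestor) or unmapped.
    """
    counts: dict[str, int] = {}
    n_annotations = n_mapped = n_unmapped = 0
    for h in hits:
        for term in maps.domain_to_go.get(h.domain_accession, ()):
            n_annotations += 1
            if term not in maps.parents and term not in maps.slim_terms:
                warnings.warn(f"GO term {term} absent from the parent edge list", stacklevel=2)
                n_unmapped += 1
                continue
            _, ancestors = nearest_slim_ancestors(term, maps)
            if not ancestors:
                n_unmapped += 1
                continue
            n_mapped += 1
            for a in ancestors:
                counts[a] = counts.get(a, 0) + 1
    return SlimRollup(counts=counts, n_annotations=n_annotations, n_mapped=n_mapped, n_unmapped=n_unmapped)


# ---------------------------------------------------------------------------
# Per-fosmid enzyme report

@dataclass(frozen=True)
class EnzymeReportRow:
    enzyme_class: str
    fosmid_id: str
    contig_id: str
    gene_id: str
    nt_length: int
    aa_length: int


@dataclass(frozen=True)
class EnzymeReport:
    rows: tuple[EnzymeReportRow, ...]
    total_predictions: int  # all ORFs on TAG-assigned contigs
    class_counts: tuple[tuple[str, int], ...]
    class_pct: tuple[tuple[str, float], ...]  # 100 × count / total, one decimal


def category_percentage(count: int, total: int) -> float:
    """100 × count / total, one decimal (14 of 451 → 3.1)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 1)


def fosmid_enzyme_report(
    assignments: list[TagAssignment],
    predictions: list[OrfPrediction],
    calls: list[CategoryCall],
) -> EnzymeReport:
    """Enzyme-class table over TAG-assigned fosmids.

    Rows list every lipase/esterase or protease gene on a contig that was
    deconvolved to a clone (FULL or PARTIAL); the summary gives per-class
    counts and percentages of all ORF predictions on those contigs.
    """
    contig_to_clone = {
        a.contig_id: a.clone_id
        for a in assignments
        if a.status in ("FULL", "PARTIAL") and a.contig_id
    }
    call_by_protein = {c.protein_id: c for c in calls}
    assigned_predictions = [p for p in predictions if p.contig_id in contig_to_clone]
    rows: list[EnzymeReportRow] = []
    counts = {"lipase_esterase": 0, "protease": 0}
    for p in assigned_predictions:
        call = call_by_protein.get(p.orf_id)
        if call is None or call.category not in counts:
            continue
        counts[call.category] += 1
        rows.append(
            EnzymeReportRow(
                enzyme_class=call.category,
                fosmid_id=contig_to_clone[p.contig_id],
                contig_id=p.contig_id,
                gene_id=p.orf_id,
                nt_length=p.nt_length,
                aa_length=p.aa_length,
            )
        )
    rows.sort(key=lambda r: (r.enzyme_class, r.fosmid_id, r.gene_id))
    total = len(assigned_predictions)
    pct = tuple(
        (cls, category_percentage(c, total) if total else 0.0)
        for cls, c in sorted(counts.items())
    )
    return EnzymeReport(
        rows=tuple(rows),
        total_predictions=total,
        class_counts=tuple(sorted(counts.items())),
        class_pct=pct,
    )
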