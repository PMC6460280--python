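"""Synthetic pooled fosmid library generator with ground truth.

Emulates the wet-lab design this toolkit targets: ~30–40 kb environmental
inserts ligated into an ~8 kb fosmid vector, tens of clones pooled for
shotgun sequencing (reads of mean length 369 nt), and two vector-anchored
Sanger end reads (TAGS) per clone reading inward from the two primer sites.
Every read, TAG and planted gene is traceable through a
:class:`TruthManifest`, so each downstream stage (screening, assembly, TAG
deconvolution, ORF calling, categorization) can be tested for parameter
recovery without external data.

Clones are circular (vector + insert), so shotgun reads may span the
vector–insert junctions; the manifest records each read's vector-derived
fraction.  The default error model is substitution-only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core import Interval, SeqRecord, TABLE11, revcomp, translate, write_fasta, write_tsv

# pCC2FOS sequencing primer pair, reading into the insert from either flank.
PCC2FOS_FWD_PRIMER = "GTACAACGACACCTAGAC"
PCC2FOS_REV_PRIMER = "CAGGAAACAGCCTAGGAA"

CATEGORIES = ("lipase_esterase", "protease", "other")

# 16-aa marker peptides planted inside simulated CDSs; the fallback motif
# scanner in genecat carries matching position-weight models.  The lipase
# marker embeds a GXSXG-like serine-hydrolase flavor, the protease marker a
# HEXXH-like metalloprotease flavor; the third is deliberately neutral.
MARKER_PEPTIDES = {
    "lipase_esterase": "WVVGHSMGGGGTLRYA",
    "protease": "YTAVHELGHALGLWHE",
    "other": "QNDKWESTPRAYMFCI",
}

MARKER_ACCESSIONS = {
    "lipase_esterase": "MK0001",
    "protease": "MK0002",
    "other": "MK0003",
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# synonymous codon choices per amino acid, for embedding marker peptides;
# codons are drawn at random per planting so two planted genes of the same
# category never share long identical DNA stretches (which would otherwise
# create spurious assembly overlaps between clones)
_SYN_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(TABLE11.codon_table.items()):
    if _aa != "*":
        _SYN_CODONS[_aa] = _SYN_CODONS.get(_aa, ()) + (_codon,)

_NONSTOP_CODONS = sorted(c for c, a in TABLE11.codon_table.items() if a != "*")


class SimConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


def random_dna(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=n)]).decode()


@dataclass(frozen=True)
class VectorSpec:
    """Fosmid vector backbone with its cloning site and sequencing primers.

    The forward primer ends exactly at the cloning site; the reverse primer
    sits immediately after it on the minus strand, so both read into the
    insert from opposite flanks.
    """

    backbone: str
    cloning_site: int
    fwd_primer_site: Interval
    rev_primer_site: Interval

    def __post_init__(self) -> None:
        cs = self.cloning_site
        if not (0 < cs <= len(self.backbone)):
            raise ValueError("cloning site outside backbone")
        f, r = self.fwd_primer_site, self.rev_primer_site
        if f.end > cs or r.start < cs:
            raise ValueError("primer sites must flank the cloning site")
        if f.strand != "+" or r.strand != "-":
            raise ValueError("fwd primer must be on '+', rev primer on '-'")

    @property
    def fwd_primer(self) -> str:
        return self.backbone[self.fwd_primer_site.start : self.fwd_primer_site.end]

    @property
    def rev_primer(self) -> str:
        return revcomp(self.backbone[self.rev_primer_site.start : self.rev_primer_site.end])


def default_vector(seed: int = 80421, length: int = 8000) -> VectorSpec:
    """Synthetic ~8 kb backbone embedding the pCC2FOS primer pair.

    The real vector sequence is not bundled; callers may substitute their
    own backbone FASTA, as long as the primer sites are annotated.
    """
    rng = np.random.default_rng(seed)
    backbone = random_dna(rng, length)
    cs = length // 2
    p = len(PCC2FOS_FWD_PRIMER)
    backbone = (
        backbone[: cs - p]
        + PCC2FOS_FWD_PRIMER
        + revcomp(PCC2FOS_REV_PRIMER)
        + backbone[cs + p :]
    )
    return VectorSpec(
        backbone=backbone,
        cloning_site=cs,
        fwd_primer_site=Interval("vector", cs - p, cs, "+"),
        rev_primer_site=Interval("vector", cs, cs + p, "-"),
    )


@dataclass(frozen=True)
class Clone:
    """A simulated fosmid: environmental insert ligated into the vector."""

    clone_id: str
    insert: str
    vector: VectorSpec
    planted_genes: tuple[tuple[Interval, str], ...] = ()

    @property
    def circular_sequence(self) -> str:
        """Vector with the insert at the cloning site (linearized circle)."""
        cs = self.vector.cloning_site
        return self.vector.backbone[:cs] + self.insert + self.vector.backbone[cs:]

    @property
    def insert_span(self) -> tuple[int, int]:
        """Insert coordinates on :attr:`circular_sequence`."""
        cs = self.vector.cloning_site
        return cs, cs + len(self.insert)

    def __len__(self) -> int:
        return len(self.insert) + len(self.vector.backbone)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the pool simulator.

    Defaults mirror the screening design this toolkit emulates: 40 pooled
    clones, shotgun reads of mean length 369 nt, ~36 kb inserts (truncated
    normal within 25–45 kb), ~30× theoretical coverage per fosmid, and
    700 nt Sanger end-TAGS.  ``seed`` is mandatory: identical configs give
    byte-identical outputs.
    """

    seed: int
    n_clones: int = 40
    coverage: float = 30.0
    read_mean_len: float = 369.0
    read_len_sd: float = 120.0
    read_min_len: int = 50
    read_error_rate: float = 0.0
    tag_read_len: int = 700
    tag_error_rate: float = 0.0
    insert_mean: float = 36000.0
    insert_sd: float = 3000.0
    insert_min: int = 25000
    insert_max: int = 45000
    # (category, CDS length in nt) planted per clone, in insert order
    genes_per_clone: tuple[tuple[str, int], ...] = (
        ("lipase_esterase", 1116),
        ("protease", 1101),
        ("other", 903),
    )

    def __post_init__(self) -> None:
        positive = {
            "n_clones": self.n_clones,
            "coverage": self.coverage,
            "read_mean_len": self.read_mean_len,
            "read_len_sd": self.read_len_sd,
            "read_min_len": self.read_min_len,
            "tag_read_len": self.tag_read_len,
            "insert_mean": self.insert_mean,
            "insert_sd": self.insert_sd,
            "insert_min": self.insert_min,
            "insert_max": self.insert_max,
        }
        for name, v in positive.items():
            if v <= 0:
                raise SimConfigError(f"{name} must be positive, got {v}")
        if self.insert_min > self.insert_max:
            raise SimConfigError("insert_min exceeds insert_max")
        if not (self.insert_min <= self.insert_mean <= self.insert_max):
            raise SimConfigError("insert_mean outside [insert_min, insert_max]")
        if not (0 <= self.read_error_rate < 1 and 0 <= self.tag_error_rate < 1):
            raise SimConfigError("error rates must be in [0, 1)")
        if self.tag_read_len >= self.insert_min:
            raise SimConfigError("tag_read_len must be shorter than the smallest insert")
        for cat, nt in self.genes_per_clone:
            if cat not in CATEGORIES:
                raise SimConfigError(f"unknown gene category {cat!r}")
            if nt % 3 != 0 or nt < 93:
                raise SimConfigError(f"planted gene length {nt} must be a multiple of 3 and >= 93")


@dataclass
class ReadOrigin:
    read_id: str
    clone_id: str
    start: int  # on the circular clone sequence
    length: int
    strand: str
    vector_fraction: float


@dataclass
class PlantedGene:
    clone_id: str
    gene_id: str
    interval: Interval  # on the clone's insert, forward strand
    category: str
    nt_length: int
    aa_length: int
    protein: str


@dataclass
class TruthManifest:
    """Ground-truth bookkeeping: every read, TAG and planted gene."""

    reads: dict[str, ReadOrigin] = field(default_factory=dict)
    tags: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)
    genes: list[PlantedGene] = field(default_factory=list)

    def vector_read_ids(self, min_fraction: float = 0.70) -> set[str]:
        """Reads whose vector-derived fraction reaches ``min_fraction``."""
        return {r.read_id for r in self.reads.values() if r.vector_fraction >= min_fraction}

    def write_tsv(self, path: str | Path) -> None:
        rows = [
            (r.read_id, r.clone_id, r.start, r.length, r.strand, f"{r.vector_fraction:.4f}")
            for r in self.reads.values()
        ]
        write_tsv(path, ("read_id", "clone_id", "start", "length", "strand", "vector_fraction"), rows)

    def write_genes_tsv(self, path: str | Path) -> None:
        rows = [
            (g.clone_id, g.gene_id, g.interval.start, g.interval.end, g.interval.strand,
             g.category, g.nt_length, g.aa_length)
            for g in self.genes
        ]
        write_tsv(
            path,
            ("clone_id", "gene_id", "start", "end", "strand", "category", "nt_length", "aa_length"),
            rows,
        )


class GenePlantingError(ValueError):
    """Requested CDS placement is out of bounds or overlaps an existing gene."""


def make_cds(rng: np.random.Generator, category: str, length_nt: int) -> str:
    """Build a valid CDS of ``length_nt`` nt carrying the category marker.

    ATG start, random non-stop codons, the category's 16-aa marker peptide
    embedded mid-CDS, and a TAA stop.  Passes :func:`fostag.core.translate`.
    """
    n_codons = length_nt // 3
    marker = MARKER_PEPTIDES[category]
    n_body = n_codons - 2  # minus start and stop
    if n_body < len(marker):
        raise GenePlantingError(f"CDS of {length_nt} nt too short for a {len(marker)}-aa marker")
    body = [
        _NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_body)
    ]
    mid = (n_body - len(marker)) // 2
    for i, aa in enumerate(marker):
        options = _SYN_CODONS[aa]
        body[mid + i] = options[rng.integers(0, len(options))]
    return "ATG" + "".join(body) + "TAA"


def plant_gene(
    insert: str,
    category: str,
    length_nt: int,
    position: int,
    rng: np.random.Generator,
    existing: tuple[tuple[Interval, str], ...] = (),
    seq_id: str = "insert",
) -> tuple[str, Interval]:
    """Write a marker-carrying CDS into ``insert`` at ``position``.

    The modified window is ``[position - 3, position + length_nt)``: an
    in-frame TAA is placed immediately upstream so the planted start codon
    is the first start after a stop, and the planted CDS is therefore
    recovered at its exact coordinates by a longest-ORF-per-stop scanner.
    Everything outside that window is unchanged.

    Raises :class:`GenePlantingError` when the window leaves no flanking
    sequence on either side, or overlaps a previously planted gene.
    """
    if length_nt % 3 != 0 or length_nt < 93:
        raise GenePlantingError(f"CDS length {length_nt} must be a multiple of 3 and >= 93")
    if category not in CATEGORIES:
        raise GenePlantingError(f"unknown category {category!r}")
    if position < 3 or position + length_nt > len(insert) - 1:
        raise GenePlantingError(
            f"planted gene [{position}, {position + length_nt}) leaves no flank "
            f"within insert of length {len(insert)}"
        )
    window = Interval(seq_id, position - 3, position + length_nt, "+")
    for iv, _ in existing:
        if window.overlaps(Interval(seq_id, iv.start - 3, iv.end, iv.strand)):
            raise GenePlantingError(f"planted gene window {window} overlaps existing gene {iv}")
    cds = make_cds(rng, category, length_nt)
    new_insert = insert[: position - 3] + "TAA" + cds + insert[position + length_nt :]
    assert len(new_insert) == len(insert)
    return new_insert, Interval(seq_id, position, position + length_nt, "+")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


def _apply_substitutions(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n_err = rng.binomial(len(arr), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(arr), size=n_err, replace=False)
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = choices[rng.integers(0, len(choices))]
    return bytes(arr).decode()


def _vector_overlap(start: int, length: int, insert_span: tuple[int, int], total: int) -> float:
    """Fraction of a (possibly wrapping) read drawn from vector sequence."""
    ins_s, ins_e = insert_span
    segs = [(start, min(start + length, total))]
    if start + length > total:
        segs.append((0, start + length - total))
    vec = 0
    for s, e in segs:
        vec += max(0, min(e, ins_s) - s)  # vector before the insert
        vec += max(0, e - max(s, ins_e))  # vector after the insert
    return vec / length


def build_clone(
    rng: np.random.Generator, clone_id: str, config: SimConfig, vector: VectorSpec
) -> tuple[Clone, list[PlantedGene]]:
    """One clone: random insert with the configured genes planted evenly."""
    ins_len = int(
        _truncated_normal(rng, config.insert_mean, config.insert_sd, config.insert_min, config.insert_max)
    )
    insert = random_dna(rng, ins_len)
    genes: tuple[tuple[Interval, str], ...] = ()
    records: list[PlantedGene] = []
    k = len(config.genes_per_clone)
    for gi, (category, nt) in enumerate(config.genes_per_clone):
        zone_lo = max(3, gi * ins_len // max(k, 1) + 50)
        zone_hi = (gi + 1) * ins_len // max(k, 1) - nt - 50
        if zone_hi <= zone_lo:
            raise SimConfigError(
                f"insert of {ins_len} nt cannot host gene {gi} of {nt} nt without overlap"
            )
        position = int(rng.integers(zone_lo, zone_hi))
        insert, iv = plant_gene(insert, category, nt, position, rng, existing=genes, seq_id=clone_id)
        genes = genes + ((iv, category),)
        cds = insert[iv.start : iv.end]
        records.append(
            PlantedGene(
                clone_id=clone_id,
                gene_id=f"{clone_id}_g{gi + 1}",
                interval=iv,
                category=category,
                nt_length=nt,
                aa_length=nt // 3 - 1,
                protein=translate(cds),
            )
        )
    return Clone(clone_id, insert, vector, genes), records


@dataclass
class SimResult:
    clones: list[Clone]
    reads: list[SeqRecord]
    tags: list[SeqRecord]
    manifest: TruthManifest
    config: SimConfig


def simulate_pool(config: SimConfig, vector: VectorSpec | None = None) -> SimResult:
    """Simulate a pooled fosmid sequencing experiment with ground truth.

    Shotgun reads are drawn uniformly from each clone's circular sequence
    (so a vector-length/clone-length fraction of reads is vector-derived);
    per clone, the two TAGS are the ``tag_read_len`` stretches immediately
    downstream of the forward and reverse primer sites, reading inward.
    """
    vector = vector or default_vector()
    rng = np.random.default_rng(config.seed)
    clones: list[Clone] = []
    manifest = TruthManifest()
    reads: list[SeqRecord] = []
    tags: list[SeqRecord] = []
    read_no = 0
    for ci in range(config.n_clones):
        clone_id = f"clone{ci + 1:03d}"
        clone, gene_records = build_clone(rng, clone_id, config, vector)
        clones.append(clone)
        manifest.genes.extend(gene_records)
        circ = clone.circular_sequence
        doubled = circ + circ
        total = len(circ)
        n_reads = math.ceil(config.coverage * total / config.read_mean_len)
        for _ in range(n_reads):
            length = int(
                _truncated_normal(
                    rng, config.read_mean_len, config.read_len_sd, config.read_min_len, total
                )
            )
            start = int(rng.integers(0, total))
            seq = doubled[start : start + length]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                seq = revcomp(seq)
            seq = _apply_substitutions(rng, seq, config.read_error_rate)
            read_id = f"read_{read_no:06d}"
            read_no += 1
            reads.append(SeqRecord(read_id, seq))
            manifest.reads[read_id] = ReadOrigin(
                read_id, clone_id, start, length, strand,
                _vector_overlap(start, length, clone.insert_span, total),
            )
        # Sanger end-TAGS: pure insert sequence, reading inward
        t = config.tag_read_len
        fwd = _apply_substitutions(rng, clone.insert[:t], config.tag_error_rate)
        rev = _apply_substitutions(rng, revcomp(clone.insert[-t:]), config.tag_error_rate)
        fwd_id, rev_id = f"{clone_id}__FWD", f"{clone_id}__REV"
        tags.append(SeqRecord(fwd_id, fwd))
        tags.append(SeqRecord(rev_id, rev))
        manifest.tags[clone_id] = (fwd_id, rev_id)
    return SimResult(clones, reads, tags, manifest, config)


def write_pool(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write reads.fasta, tags.fasta, clones.fasta and truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": outdir / "reads.fasta",
        "tags": outdir / "tags.fasta",
        "clones": outdir / "clones.fasta",
        "truth_reads": outdir / "truth.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "vector": outdir / "vector.fasta",
    }
    write_fasta(result.reads, paths["reads"])
    write_fasta(result.tags, paths["tags"])
    write_fasta(
        [SeqRecord(c.clone_id, c.circular_sequence) for c in result.clones], paths["clones"]
    )
    vec = result.clones[0].vector if result.clones else default_vector()
    write_fasta([SeqRecord("vector", vec.backbone)], paths["vector"])
    result.manifest.write_tsv(paths["truth_reads"])
    result.manifest.write_genes_tsv(paths["truth_genes"])
    return paths
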