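"""End-to-end orchestration: screen → assemble → stats → tag → orfscan →
cluster → annotate → report, with a provenance manifest.

External-tool escape hatches: a user-supplied contigs FASTA replaces the
internal screening/assembly stages, and a user-supplied HMMER per-domain
table replaces the built-in motif scanner, so the toolkit interoperates
with production assemblers and profile searches without reimplementing
them at scale.  Outputs are deterministic: rerunning with the same config
and inputs is byte-identical (logging goes to stderr, never into files).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from . import __version__
from .core import SeqRecord, read_fasta, write_fasta, write_tsv
from .genecat import (
    CategoryCall,
    ClusterParams,
    OrfParams,
    categorize,
    cluster_peptides,
    default_motif_models,
    fallback_motif_scan,
    fosmid_enzyme_report,
    goslim_rollup,
    GoMaps,
    load_category_table,
    load_domain_to_go,
    load_edges,
    load_term_list,
    orf_scan,
    parse_domain_hits,
    seed_stats,
)
from .poolasm import Contig, ScreenParams, assembly_stats, greedy_assemble, screen_reads
from .tagmap import TagMapParams, assign_clones, map_tags, pair_tags, tagging_report


class ConfigError(ValueError):
    """Invalid pipeline configuration (unknown keys, missing inputs)."""


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All stage parameters and file paths for one pipeline run.

    The config is serialized verbatim into the run manifest; unknown keys
    are rejected rather than ignored.
    """

    tags: str | None = None
    reads: str | None = None
    screen_refs: tuple[str, ...] = ()
    contigs: str | None = None        # external assembly escape hatch
    domain_table: str | None = None   # external HMMER domtbl escape hatch
    category_table: str | None = None  # defaults to the bundled example
    domain_to_go: str | None = None
    go_edges: str | None = None
    slim_terms: str | None = None
    seed: int = 0
    screen: ScreenParams = field(default_factory=ScreenParams)
    assemble_min_overlap: int = 40
    assemble_min_identity: float = 0.95
    tagmap: TagMapParams = field(default_factory=TagMapParams)
    orf: OrfParams = field(default_factory=OrfParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    annotate_evalue_cutoff: float = 1e-10

    _NESTED = {"screen": ScreenParams, "tagmap": TagMapParams, "orf": OrfParams, "cluster": ClusterParams}

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key, typ in cls._NESTED.items():
            if key in kwargs and isinstance(kwargs[key], dict):
                block = kwargs[key]
                block_known = {f.name for f in dataclasses.fields(typ)}
                bad = set(block) - block_known
                if bad:
                    raise ConfigError(f"unknown keys in {key!r} block: {sorted(bad)}")
                try:
                    kwargs[key] = typ(**block)
                except ValueError as exc:
                    raise ConfigError(f"invalid {key!r} block: {exc}") from exc
        if "screen_refs" in kwargs:
            kwargs["screen_refs"] = tuple(kwargs["screen_refs"])
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _json_default(o):
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o).__name__}")


def bundled_category_table() -> Path:
    """Path to the shipped example domain→category table (synthetic)."""
    return Path(resources.files("fostag") / "data" / "example_category_table.tsv")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(stage: str, message: str, quiet: bool) -> None:
    if not quiet:
        ts = time.strftime("%H:%M:%S")
        print(f"[{ts}] [{stage}] {message}", file=sys.stderr)


def run_pipeline(config: PipelineConfig, outdir: str | Path, quiet: bool = False) -> Path:
    """Execute the full pipeline into ``outdir``; returns the run directory.

    Any stage failure raises :class:`StageFailure` naming the stage; files
    written before the failure are retained for inspection.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "fostag",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {},
        "counts": {},
    }
    for label in ("reads", "tags", "contigs", "domain_table", "category_table",
                  "domain_to_go", "go_edges", "slim_terms"):
        p = getattr(config, label)
        if p:
            if not Path(p).exists():
                raise ConfigError(f"{label} file not found: {p}")
            manifest["inputs"][label] = {"path": str(p), "sha256": _sha256(p)}
    for i, ref in enumerate(config.screen_refs):
        if not Path(ref).exists():
            raise ConfigError(f"screen_refs file not found: {ref}")
        manifest["inputs"][f"screen_ref_{i}"] = {"path": str(ref), "sha256": _sha256(ref)}

    counts = manifest["counts"]

    # --- screen + assemble (or external contigs) ---
    if config.contigs:
        _log("assemble", f"using external contigs from {config.contigs}", quiet)
        contigs = [Contig(r.id, r.residues) for r in read_fasta(config.contigs)]
        counts["contigs"] = len(contigs)
    else:
        if not config.reads:
            raise StageFailure("screen", "no reads file configured and no external contigs given")
        try:
            reads = read_fasta(config.reads)
            refs = [r for ref in config.screen_refs for r in read_fasta(ref)]
            if not refs:
                raise ValueError("screening requires at least one reference FASTA")
            kept, removed, report = screen_reads(reads, refs, config.screen)
        except StageFailure:
            raise
        except Exception as exc:
            raise StageFailure("screen", str(exc)) from exc
        counts["reads_in"] = len(reads)
        counts["reads_removed"] = len(removed)
        counts["reads_kept"] = len(kept)
        _log("screen", f"{len(removed)} of {len(reads)} reads removed as vector/host", quiet)
        write_fasta(kept, out / "reads.cleaned.fasta")
        write_tsv(
            out / "screen_report.tsv",
            ("read_id", "ref_id", "evalue", "read_coverage", "verdict"),
            (
                (r.read_id, r.ref_id or "-",
                 f"{r.evalue:.3g}" if r.evalue is not None else "-",
                 f"{r.read_coverage:.3f}", r.verdict)
                for r in report
            ),
        )
        try:
            contigs = greedy_assemble(
                kept, min_overlap=config.assemble_min_overlap,
                min_identity=config.assemble_min_identity,
            )
        except Exception as exc:
            raise StageFailure("assemble", str(exc)) from exc
        counts["contigs"] = len(contigs)
        _log("assemble", f"{len(contigs)} contigs", quiet)
    write_fasta([SeqRecord(c.contig_id, c.residues) for c in contigs], out / "contigs.fasta")

    # --- stats ---
    try:
        stats = assembly_stats(contigs)
    except Exception as exc:
        raise StageFailure("stats", str(exc)) from exc
    write_tsv(out / "assembly_stats.tsv", ("statistic", "value"), stats.rows())

    # --- tag ---
    if not config.tags:
        raise StageFailure("tag", "no TAGS file configured (set 'tags' in the config)")
    try:
        tag_records = read_fasta(config.tags)
        pairs = pair_tags(tag_records)
        hits = map_tags(pairs, contigs, config.tagmap)
        assignments = assign_clones(hits, pairs, config.tagmap)
    except StageFailure:
        raise
    except Exception as exc:
        raise StageFailure("tag", str(exc)) from exc
    summary = tagging_report(assignments)
    counts["clones"] = len(assignments)
    counts["clones_full"] = summary.n_full if summary else 0
    _log("tag", f"{summary.n_full}/{summary.n_clones} clones FULL "
         f"({summary.full_pct}%)" if summary else "no clones", quiet)
    write_tsv(
        out / "tag_assignments.tsv",
        ("clone_id", "contig_id", "status", "ends_matched", "span_start", "span_end"),
        (
            (a.clone_id, a.contig_id or "-", a.status, ",".join(a.ends_matched) or "-",
             a.span_start if a.span_start is not None else "-",
             a.span_end if a.span_end is not None else "-")
            for a in assignments
        ),
        comments=(
            f"min_identity={config.tagmap.min_identity} "
            f"min_tag_coverage={config.tagmap.min_tag_coverage} "
            f"tie_margin={config.tagmap.tie_margin}",
        ),
    )

    # --- orfscan ---
    try:
        predictions = [p for c in contigs for p in orf_scan(c, config.orf)]
    except Exception as exc:
        raise StageFailure("orfscan", str(exc)) from exc
    counts["orfs"] = len(predictions)
    _log("orfscan", f"{len(predictions)} complete ORFs >= {config.orf.min_protein_aa} aa", quiet)
    proteins = [SeqRecord(p.orf_id, p.protein) for p in predictions]
    if proteins:
        write_fasta(proteins, out / "orfs.faa")
    write_tsv(
        out / "orfs.tsv",
        ("orf_id", "contig_id", "start", "end", "strand", "frame", "nt_length", "aa_length"),
        (
            (p.orf_id, p.contig_id, p.interval.start, p.interval.end, p.strand,
             p.frame, p.nt_length, p.aa_length)
            for p in predictions
        ),
    )

    # --- cluster ---
    try:
        clusters = cluster_peptides(proteins, config.cluster)
    except Exception as exc:
        raise StageFailure("cluster", str(exc)) from exc
    counts["clusters"] = len(clusters)
    if clusters:
        ss = seed_stats(clusters)
        _log("cluster", f"{ss.n_clusters} clusters; seeds {ss.mean_aa:.0f}±{ss.sd_aa:.0f} aa", quiet)
    write_tsv(
        out / "clusters.tsv",
        ("seed_id", "seed_length", "n_members", "member_ids"),
        ((c.seed_id, c.seed_length, len(c.member_ids), ",".join(c.member_ids)) for c in clusters),
        comments=(f"identity_threshold={config.cluster.identity_threshold} "
                  "identity=1-d/max_len (Levenshtein d, end-to-end)",),
    )

    # --- annotate ---
    try:
        if config.domain_table:
            hits_dom = parse_domain_hits(config.domain_table, config.annotate_evalue_cutoff)
            _log("annotate", f"{len(hits_dom)} domain hits from external table", quiet)
        else:
            hits_dom = fallback_motif_scan(
                proteins, default_motif_models(), config.annotate_evalue_cutoff
            )
            _log("annotate", f"{len(hits_dom)} motif-scan hits at E<="
                 f"{config.annotate_evalue_cutoff:g}", quiet)
        table_path = config.category_table or bundled_category_table()
        table = load_category_table(table_path)
        calls = categorize(hits_dom, table)
    except Exception as exc:
        raise StageFailure("annotate", str(exc)) from exc
    counts["domain_hits"] = len(hits_dom)
    counts["category_calls"] = len(calls)
    write_tsv(
        out / "category_calls.tsv",
        ("protein_id", "category", "best_evalues"),
        (
            (c.protein_id, c.category,
             ";".join(f"{k}={v:.3g}" for k, v in c.best_evalue_per_category) or "-")
            for c in calls
        ),
    )
    if config.domain_to_go and config.go_edges and config.slim_terms:
        try:
            maps = GoMaps(
                domain_to_go=load_domain_to_go(config.domain_to_go),
                parents=load_edges(config.go_edges),
                slim_terms=load_term_list(config.slim_terms),
            )
            rollup = goslim_rollup(hits_dom, maps)
        except Exception as exc:
            raise StageFailure("annotate", f"GO rollup: {exc}") from exc
        fractions = rollup.fractions()
        write_tsv(
            out / "goslim.tsv",
            ("slim_term", "count", "fraction"),
            ((t, c, f"{fractions[t]:.4f}") for t, c in sorted(rollup.counts.items())),
            comments=(f"annotations={rollup.n_annotations} mapped={rollup.n_mapped} "
                      f"unmapped={rollup.n_unmapped}",),
        )

    # --- report ---
    try:
        report = fosmid_enzyme_report(assignments, predictions, calls)
    except Exception as exc:
        raise StageFailure("report", str(exc)) from exc
    counts["enzyme_genes"] = len(report.rows)
    write_tsv(
        out / "enzyme_report.tsv",
        ("enzyme_class", "fosmid_id", "contig_id", "gene_id", "nt_length", "aa_length"),
        (dataclasses.astuple(r) for r in report.rows),
        comments=(
            f"total_predictions_on_assigned_fosmids={report.total_predictions}",
            " ".join(f"{cls}={pct}%" for cls, pct in report.class_pct),
        ),
    )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    _log("done", f"run directory: {out}", quiet)
    return out
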