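"""ORF calling, clustering, domain evidence, categorization, GO-slim."""

import numpy as np
import pytest

from fostag import simlib
from fostag.core import SeqRecord, TABLE11, revcomp
from fostag.genecat import (
    Cluster,
    ClusterParams,
    DomainHit,
    DomainTableError,
    GoMaps,
    MotifModel,
    OrfParams,
    categorize,
    category_percentage,
    cluster_peptides,
    default_motif_models,
    fallback_motif_scan,
    fosmid_enzyme_report,
    goslim_rollup,
    load_category_table,
    nearest_slim_ancestors,
    orf_scan,
    parse_domain_hits,
    seed_stats,
)
from fostag.poolasm import Contig
from fostag.simlib import make_cds, plant_gene, random_dna
from fostag.tagmap import TagAssignment

# --- ORF scanning ----------------------------------------------------------

def orf_oracle(seq: str, min_aa: int = 30) -> set[tuple[int, int, str]]:
    """Exhaustive six-frame enumeration: for every start codon, walk to the
    first in-frame stop; keep the earliest start per stop."""
    n = len(seq)
    best: dict[tuple[str, int], int] = {}
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for i in range(n - 2):
            if s[i : i + 3] not in TABLE11.start_codons:
                continue
            j = i + 3
            while j + 3 <= n and s[j : j + 3] not in TABLE11.stop_codons:
                j += 3
            if j + 3 > n:
                continue
            if (j + 3 - i) // 3 - 1 < min_aa:
                continue
            key = (strand, j + 3)
            if key not in best or i < best[key]:
                best[key] = i
    out = set()
    for (strand, e), i in best.items():
        fs, fe = (i, e) if strand == "+" else (n - e, n - i)
        out.add((fs, fe, strand))
    return out


def test_orf_scan_equals_bruteforce_on_random_contigs(rng):
    for _ in range(60):
        seq = random_dna(rng, 2000)
        got = {
            (p.interval.start, p.interval.end, p.strand)
            for p in orf_scan(Contig("c", seq))
        }
        assert got == orf_oracle(seq)


def test_orf_predictions_are_consistent(rng):
    seq = random_dna(rng, 3000)
    for p in orf_scan(Contig("c", seq)):
        assert p.aa_length == p.nt_length // 3 - 1
        assert p.nt_length == len(p.interval)
        assert "*" not in p.protein
        assert p.protein[0] == "M"


def test_planted_2115_nt_gene_recovered_as_704_aa(rng):
    insert = random_dna(rng, 6000)
    insert, iv = plant_gene(insert, "lipase_esterase", 2115, 2000, rng)
    preds = orf_scan(Contig("c", insert))
    match = [p for p in preds if p.interval.start == iv.start and p.interval.end == iv.end]
    assert len(match) == 1
    assert match[0].aa_length == 704
    assert match[0].strand == "+"


def test_29_aa_orf_suppressed():
    # 90-nt CDS encodes 29 aa (incl. the initiator M), below the 30-aa minimum
    cds = "ATG" + "GCT" * 28 + "TAA"
    assert orf_scan(Contig("c", cds + "ACGT")) == []
    cds_ok = "ATG" + "GCT" * 29 + "TAA"  # 93 nt -> 30 aa
    preds = orf_scan(Contig("c", cds_ok + "ACGT"))
    assert len(preds) == 1 and preds[0].aa_length == 30


def test_orf_scan_min_length_parameter(rng):
    cds = make_cds(rng, "other", 150)  # 49 aa
    preds = orf_scan(Contig("c", "CCC" + cds + "CCC"), OrfParams(min_protein_aa=50))
    assert preds == []


# --- clustering ------------------------------------------------------------

def _levenshtein(a: str, b: str) -> int:
    prev = np.arange(len(b) + 1)
    idx = np.arange(len(b) + 1)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    for i, ca in enumerate(a, 1):
        cost = (bb != ord(ca)).astype(int)
        base = np.empty(len(b) + 1, dtype=int)
        base[0] = i
        base[1:] = np.minimum(prev[1:] + 1, prev[:-1] + cost)
        prev = np.minimum.accumulate(base - idx) + idx
    return int(prev[-1])


def greedy_cluster_oracle(proteins, threshold):
    """Quadratic reference with the same ordering rule, own edit distance."""
    order = sorted(proteins, key=lambda p: (-len(p), p.id))
    clusters: list[list] = []
    for p in order:
        for c in clusters:
            seed = c[0]
            d = _levenshtein(p.residues, seed.residues)
            if 1 - d / max(len(p), len(seed)) >= threshold:
                c.append(p)
                break
        else:
            clusters.append([p])
    return [tuple(x.id for x in c) for c in clusters]


def _mutate(rng, seq, n_sub):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    s = list(seq)
    for pos in rng.choice(len(s), size=n_sub, replace=False):
        s[pos] = aas[rng.integers(0, 20)]
    return "".join(s)


def test_identical_peptides_collapse():
    prots = [SeqRecord("b", "MKLVAW" * 10), SeqRecord("a", "MKLVAW" * 10)]
    clusters = cluster_peptides(prots)
    assert len(clusters) == 1
    assert clusters[0].seed_id == "a"  # id tie-break at equal length
    assert set(clusters[0].member_ids) == {"a", "b"}


def test_85_percent_identity_splits():
    rng = np.random.default_rng(5)
    base = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 100))
    variant = _mutate(rng, base, 15)  # 85% identity < 0.90
    clusters = cluster_peptides([SeqRecord("a", base), SeqRecord("b", variant)])
    assert len(clusters) == 2


def test_clustering_matches_quadratic_oracle_with_planted_families(rng):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    prots = []
    pid = 0
    for fam in range(20):  # families at ~95% identity
        L = int(rng.integers(40, 81))
        base = "".join(aas[i] for i in rng.integers(0, 20, L))
        for _ in range(int(rng.integers(2, 6))):
            n_sub = int(rng.integers(0, max(1, L // 20) + 1))
            prots.append(SeqRecord(f"p{pid:04d}", _mutate(rng, base, n_sub)))
            pid += 1
    while pid < 200:  # singletons
        L = int(rng.integers(40, 81))
        prots.append(SeqRecord(f"p{pid:04d}", "".join(aas[i] for i in rng.integers(0, 20, L))))
        pid += 1
    got = [c.member_ids for c in cluster_peptides(prots)]
    assert got == greedy_cluster_oracle(prots, 0.90)
    # partition property
    all_ids = [m for c in got for m in c]
    assert sorted(all_ids) == sorted(p.id for p in prots)


def test_seed_stats():
    clusters = [
        Cluster("a", 100, ("a",)),
        Cluster("b", 172, ("b", "c")),
    ]
    ss = seed_stats(clusters)
    assert ss.mean_aa == pytest.approx(136.0)
    assert ss.max_aa == 172
    single = seed_stats([Cluster("x", 50, ("x",))])
    assert single.sd_aa == 0.0
    lengths = np.array([100, 172], dtype=float)
    assert ss.sd_aa == pytest.approx(float(lengths.std()))
    with pytest.raises(ValueError):
        seed_stats([])


# --- domain evidence -------------------------------------------------------

DOMTBL = """\
#                                                                            --- full sequence --- -------------- this domain -------------  hmm coord   ali coord   env coord
# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target
Peptidase_S8         PF00082.29   281 prot_A               -            420   2.1e-40  135.2   0.0   1   1   1.2e-43   3.2e-40  134.6   0.0     2   280    31   311    30   312 0.95 Subtilase family
Abhydrolase_1        PF00561.27   245 prot_B               -            310   5.0e-22   74.8   0.1   1   2   4.1e-25   1.1e-21   73.9   0.1     5   240    18   255    17   256 0.91 alpha/beta hydrolase fold
Abhydrolase_1        PF00561.27   245 prot_B               -            310   5.0e-22   74.8   0.1   2   2   3.3e-06   8.8e-03    9.1   0.0    40    90   270   300   268   302 0.70 alpha/beta hydrolase fold
Peptidase_M48        PF01435.25   195 prot_C               -            255   7.7e-15   51.5   0.0   1   1   6.0e-18   1.6e-14   50.4   0.0     1   190    40   230    40   231 0.88 Peptidase family M48
DUF1234              PF91234.1    120 prot_D               -            180   3.0e-08   29.0   0.0   1   1   2.2e-11   6.0e-08   28.1   0.0     1   115    10   128     9   130 0.80 Domain of unknown function
"""


def test_parse_domain_hits_applies_cutoff(tmp_path):
    p = tmp_path / "hits.domtbl"
    p.write_text(DOMTBL)
    hits = parse_domain_hits(p, evalue_cutoff=1e-10)
    # the 8.8e-03 secondary domain and the 6.0e-08 hit fall above the cutoff
    assert [(h.protein_id, h.domain_accession) for h in hits] == [
        ("prot_A", "PF00082.29"),
        ("prot_B", "PF00561.27"),
        ("prot_C", "PF01435.25"),
    ]
    h = hits[0]
    assert h.evalue == pytest.approx(3.2e-40)
    assert (h.env_start, h.env_end) == (29, 312)  # 1-based 30..312


def test_parse_domain_hits_errors(tmp_path):
    missing = tmp_path / "nope.domtbl"
    with pytest.raises(DomainTableError, match="no such"):
        parse_domain_hits(missing)
    bad = tmp_path / "bad.domtbl"
    bad.write_text("only three fields here\n")
    with pytest.raises(DomainTableError, match=":1:"):
        parse_domain_hits(bad)
    empty = tmp_path / "empty.domtbl"
    empty.write_text("# nothing but comments\n")
    with pytest.raises(DomainTableError, match="no parsable"):
        parse_domain_hits(empty)


def test_motif_scan_finds_planted_marker(rng):
    cds = make_cds(rng, "lipase_esterase", 1116)
    from fostag.core import translate

    protein = SeqRecord("p1", translate(cds))
    decoys = [
        SeqRecord(f"d{i}", "".join("ACDEFGHIKLMNPQRSTVWY"[j] for j in rng.integers(0, 20, 300)))
        for i in range(50)
    ]
    hits = fallback_motif_scan([protein] + decoys, default_motif_models())
    assert [(h.protein_id, h.domain_accession) for h in hits] == [("p1", "MK0001")]
    assert hits[0].evalue <= 1e-10


def test_motif_scan_false_positive_rate(rng):
    """No random protein reaches E ≤ 1e-10 over 1,000 trials."""
    aas = "ACDEFGHIKLMNPQRSTVWY"
    decoys = [
        SeqRecord(f"d{i:04d}", "".join(aas[j] for j in rng.integers(0, 20, 120)))
        for i in range(1000)
    ]
    assert fallback_motif_scan(decoys, default_motif_models()) == []


def test_motif_scan_empty_input():
    assert fallback_motif_scan([], default_motif_models()) == []


def test_motif_model_pvalue_is_exact_binomial():
    """For a two-valued PWM the null distribution is binomial in the number
    of consensus matches; the DP convolution must reproduce it."""
    from scipy import stats

    model = MotifModel.from_peptide("WVVGHSMGGGGTLRYA", "X1", "m")
    w = model.width
    hi = float(model.pwm.max(axis=1).sum())  # all-consensus score
    lo_col = float(model.pwm[0].min())
    hi_col = float(model.pwm[0].max())
    for k in (w, w - 1, w - 3):
        score = k * hi_col + (w - k) * lo_col
        expected = float(stats.binom.sf(k - 1, w, 1 / 20))
        assert model.pvalue(score) == pytest.approx(expected, rel=1e-6)
    assert model.pvalue(hi + 1) == 0.0


# --- categorization --------------------------------------------------------

TABLE = {"L1": "lipase_esterase", "P1": "protease"}


def _hit(pid, acc, e):
    return DomainHit(pid, acc, acc, e, 0, 10)


def test_categorize_best_evalue_wins():
    hits = [_hit("g", "L1", 1e-30), _hit("g", "P1", 1e-12)]
    calls = categorize(hits, TABLE)
    assert len(calls) == 1
    assert calls[0].category == "lipase_esterase"
    assert dict(calls[0].best_evalue_per_category) == {
        "lipase_esterase": 1e-30,
        "protease": 1e-12,
    }


def test_categorize_unlisted_domains_are_other():
    calls = categorize([_hit("g", "ZZZ", 1e-40)], TABLE)
    assert calls[0].category == "other"


def test_categorize_one_call_per_protein():
    hits = [
        _hit("a", "L1", 1e-20), _hit("a", "P1", 1e-15), _hit("a", "ZZZ", 1e-50),
        _hit("b", "P1", 1e-11),
    ]
    calls = categorize(hits, TABLE)
    assert [c.protein_id for c in calls] == ["a", "b"]
    assert [c.category for c in calls] == ["lipase_esterase", "protease"]


def test_stricter_cutoff_never_adds_calls(tmp_path):
    p = tmp_path / "hits.domtbl"
    p.write_text(DOMTBL)
    loose = {c.protein_id for c in categorize(parse_domain_hits(p, 1e-5), TABLE)}
    strict = {c.protein_id for c in categorize(parse_domain_hits(p, 1e-20), TABLE)}
    assert strict <= loose


def test_bundled_category_table_loads():
    from fostag.pipeline import bundled_category_table

    table = load_category_table(bundled_category_table())
    assert table["MK0001"] == "lipase_esterase"
    assert table["MK0002"] == "protease"
    assert "MK0003" not in table  # neutral marker is deliberately unlisted


# --- GO-slim rollup --------------------------------------------------------

EDGES = {
    "GO:t_deep": ("GO:t_mid",),
    "GO:t_mid": ("GO:slimA",),
    "GO:t_tie": ("GO:a", "GO:b"),
    "GO:a": ("GO:slimA",),
    "GO:b": ("GO:slimB",),
    "GO:slimA": ("GO:root",),
    "GO:slimB": ("GO:root",),
    "GO:orphan": ("GO:root",),
}
MAPS = GoMaps(
    domain_to_go={
        "D_direct": ("GO:slimA",),
        "D_deep": ("GO:t_deep",),
        "D_tie": ("GO:t_tie",),
        "D_orphan": ("GO:orphan",),
    },
    parents=EDGES,
    slim_terms=frozenset({"GO:slimA", "GO:slimB"}),
)


def ancestors_oracle(term, maps):
    """All ancestors with exact minimum distances, by exhaustive recursion."""
    dist = {}

    def walk(t, d):
        for p in maps.parents.get(t, ()):
            if p not in dist or d + 1 < dist[p]:
                dist[p] = d + 1
                walk(p, d + 1)

    walk(term, 0)
    dist[term] = 0
    slim = {t: d for t, d in dist.items() if t in maps.slim_terms}
    if not slim:
        return -1, ()
    m = min(slim.values())
    return m, tuple(sorted(t for t, d in slim.items() if d == m))


@pytest.mark.parametrize("term", ["GO:slimA", "GO:t_deep", "GO:t_mid", "GO:t_tie", "GO:orphan"])
def test_nearest_slim_matches_exhaustive_search(term):
    assert nearest_slim_ancestors(term, MAPS) == ancestors_oracle(term, MAPS)


def test_rollup_counts_and_conservation():
    hits = [
        _hit("p1", "D_direct", 1e-20),
        _hit("p1", "D_deep", 1e-15),  # second domain on the same protein
        _hit("p2", "D_tie", 1e-12),
        _hit("p3", "D_orphan", 1e-12),
    ]
    rollup = goslim_rollup(hits, MAPS)
    assert rollup.n_annotations == 4
    assert rollup.n_unmapped == 1  # orphan has no slim ancestor
    assert rollup.n_mapped + rollup.n_unmapped == rollup.n_annotations
    # tie counted at both slim terms; multi-domain protein counts twice
    assert rollup.counts == {"GO:slimA": 3, "GO:slimB": 1}


def test_rollup_warns_on_unknown_term():
    maps = GoMaps(domain_to_go={"D": ("GO:unknown",)}, parents=EDGES, slim_terms=MAPS.slim_terms)
    with pytest.warns(UserWarning, match="absent"):
        rollup = goslim_rollup([_hit("p", "D", 1e-12)], maps)
    assert rollup.n_unmapped == 1


def test_cyclic_edges_rejected():
    with pytest.raises(ValueError, match="cycle"):
        GoMaps(domain_to_go={}, parents={"a": ("b",), "b": ("a",)}, slim_terms=frozenset())


# --- enzyme report ---------------------------------------------------------

def test_category_percentage_one_decimal():
    assert category_percentage(14, 451) == 3.1
    assert category_percentage(12, 451) == 2.7
    with pytest.raises(ValueError):
        category_percentage(1, 0)


def test_fosmid_enzyme_report_counts(rng):
    from fostag.genecat import OrfPrediction
    from fostag.core import Interval

    asg = [
        TagAssignment("cl1", "FULL", "c1", ("FWD", "REV"), True, 0, 5000),
        TagAssignment("cl2", "NONE"),
    ]
    preds = [
        OrfPrediction("g1", "c1", Interval("c1", 0, 303, "+"), "+", 0, 303, 100, "M" * 100),
        OrfPrediction("g2", "c1", Interval("c1", 400, 703, "+"), "+", 1, 303, 100, "M" * 100),
        OrfPrediction("g3", "c9", Interval("c9", 0, 303, "+"), "+", 0, 303, 100, "M" * 100),
    ]
    from fostag.genecat import CategoryCall

    calls = [
        CategoryCall("g1", "lipase_esterase"),
        CategoryCall("g2", "other"),
        CategoryCall("g3", "protease"),  # on an unassigned contig: excluded
    ]
    report = fosmid_enzyme_report(asg, preds, calls)
    assert report.total_predictions == 2
    assert dict(report.class_counts) == {"lipase_esterase": 1, "protease": 0}
    assert dict(report.class_pct)["lipase_esterase"] == 50.0
    assert report.rows[0].fosmid_id == "cl1"
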