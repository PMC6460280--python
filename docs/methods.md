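# Methods

This note records the models, conventions and design choices behind
`fostag`, in the order data flows through the toolkit.

## Sequence conventions

Coordinates are 0-based half-open everywhere; features on the minus
strand report their span on the forward strand. Translation uses the
bacterial/archaeal code (table 11) with starts restricted to ATG, GTG and
TTG and stops TAA, TGA and TAG. Alternative starts render as M at CDS
position 1 only, the standard prokaryotic convention; reported gene sizes
are unaffected by this choice and always satisfy `aa = nt/3 − 1` because
the stop codon is counted in the nucleotide length but not the protein.
Codons containing N translate to X, and N never scores as a match in any
alignment.

## The pool simulator (`simlib`)

The simulator emulates the screening design the toolkit targets:

| parameter | default | rationale |
| --- | --- | --- |
| clones per pool | 40 | pool size of the screening design |
| insert length | N(36 kb, 3 kb) truncated to [25, 45] kb | ~30 kb size-selected environmental fragments; the exact distribution is a modeling choice, configurable |
| vector | synthetic 8,000 nt backbone | carries the real pCC2FOS sequencing-primer pair flanking the cloning site; the true backbone is not bundled and can be substituted |
| read length | truncated N(369, 120), min 50 nt | mean matches long-read pyrosequencing output; the spread is a modeling choice |
| per-fosmid coverage | 30× | matches the theoretical per-fosmid depth of the screening design (~135k reads × 369 nt / 40 clones / ~44 kb) |
| TAG length | 700 nt | typical high-quality Sanger read |
| error model | substitution-only, default 0 | keeps alignment ground truth exact; an error rate can be configured, indel/homopolymer errors are out of scope |

Clones are circular (vector + insert), reads are drawn uniformly from the
circle, so reads may span the vector–insert junctions and a
vector-length/clone-length fraction of reads is vector-derived; the truth
manifest stores each read's exact vector-derived fraction.

Planted genes are valid CDSs carrying a category-specific 16-aa marker
peptide mid-protein (a GXSXG-flavored serine-hydrolase marker for
lipases/esterases, a HEXXH-flavored one for proteases, and a neutral
marker for the `other` class). Marker peptides are encoded with randomly
drawn synonymous codons at each planting so two planted genes never share
long identical DNA stretches that could create spurious assembly
overlaps. `plant_gene` also writes an in-frame TAA immediately upstream
of the planted start (the documented modified window is
`[position − 3, position + length)`): without that guard, a chance
upstream in-frame start would make the longest-ORF-per-stop rule report a
longer gene than planted, and exact-size recovery could not be asserted.

What the simulator does **not** emulate: base-quality profiles, indels
and homopolymer artifacts, chimeric molecules, host-genome contamination
reads, community abundance structure, and real domain content (markers
stand in for profile hits). Passing recovery tests therefore demonstrate
the correctness of the pipeline's logic on clean data, not its
sensitivity on real 454/Illumina output.

## Screening (`poolasm.screen_reads`)

A read is discarded when its local alignments to one reference, each with
expect ≤ 1e-5, jointly cover ≥ 70 % of the read. The aligner is
deliberately small: exact 11-mer seeds binned by diagonal, gap-free
X-drop extension reporting the maximal-scoring span, scores +1/−2, and
ungapped Karlin–Altschul statistics (λ solved for the score pair at
uniform composition, K = 0.621, both exposed in `ScreenParams`). Gap
penalties are accepted in the parameter block for interface compatibility
but the default engine never opens gaps, consistent with the
substitution-only simulator. Joint (union) coverage per reference is what
lets a read spanning the circular vector's origin — two separate HSPs on
the linear reference — screen correctly. Removed reads are discarded
whole rather than trimmed; the report records every read's best hit,
E-value, coverage and verdict.

One quantization effect is worth knowing: for a junction read whose true
vector fraction is within a few nucleotides of the 70 % cutoff, the local
alignment can extend one or two chance-matching bases past the
vector–insert junction, so the decision can differ from the
generative-truth label inside a ±5 nt band around the threshold. Tests
treat that band as quantization; outside it, screening decisions equal
the truth labels exactly on error-free data, and no majority-insert read
is ever removed.

## Greedy assembly (`poolasm.greedy_assemble`)

Reads are visited longest-first (id tie-break) and merged into the draft
contig sharing the most 21-mers on a consistent diagonal when the implied
overlap is ≥ 40 nt at ≥ 95 % identity (banded edit distance over the full
overlap, both read orientations tried); otherwise the read founds a new
draft. A final pass merges drafts against each other and folds contained
duplicates. Identity over the *entire* implied overlap is what prevents
vector-stub chimeras between clones. The assembler is deterministic:
identical input yields byte-identical contig FASTA, with contigs named in
descending length order. It is a desk-scale tool — an external assembly
can be supplied to the pipeline instead (`contigs:` in the config).

Assembly statistics follow the usual definitions: N50 is the smallest
length in the descending-length prefix whose cumulative sum reaches half
the total (inclusive when the sum lands exactly on half); L50 is that
prefix's size; the mean rounds half away from zero to an integer
(2,853,727 nt / 3,811 contigs → 749). `theoretical_coverage` exposes all
four terms (reads × mean length / clones / fosmid length) with a 44 kb
default fosmid length (~36 kb insert + 8 kb vector), since conventions
differ on which read total and clone length to use.

## TAG deconvolution (`tagmap`)

TAGS map to contigs with the same seed-and-extend engine (15-mer seeds);
a placement qualifies at ≥ 95 % identity over the aligned span covering
≥ 50 % of the tag — Sanger ends are accurate but may run past the insert,
hence the permissive coverage. A best hit is *unique* when it beats the
best hit on any other contig by ≥ 5 % of its score. Clone status is a
cascade: FULL when both ends place uniquely on one contig on opposite
strands (the head-to-head geometry implied by primers reading inward from
opposite vector flanks); else PARTIAL when exactly one end places
uniquely; else AMBIGUOUS when an end is tied across contigs; else NONE —
so two ends placing uniquely on *different* contigs fall through to NONE.
All thresholds are recorded in the output header. The summary reports
counts per status and the full-assembly percentage to one decimal
(18 of 40 → 45.0 %).

## ORF calling and clustering (`genecat`)

The ORF scanner emits all maximal complete ORFs on six frames: first
start codon after the previous in-frame stop through the first stop, at
least 30 aa of protein. Later starts sharing a stop are suppressed
(longest-per-stop, one gene per locus); ORFs running off a contig edge
are flagged partial and excluded from standard output, since all reported
gene sizes assume a terminal stop codon.

Redundancy clustering is greedy and incremental: peptides sorted by
(length desc, id asc); each joins the earliest cluster whose *seed* (the
longest member) is near-identical end to end, else founds a new cluster.
"90 % identity along the entire protein" is implemented as normalized
edit similarity `1 − d/max(|a|, |b|)` with Levenshtein distance `d`: this
is alignment-invariant (no dependence on which co-optimal alignment a
tool reports), enforces end-to-end comparison through the length
normalization, and makes the implementation provably equal to the
quadratic reference used in tests. A shared-5-mer prefilter prunes seed
comparisons; it is mathematically exact for thresholds ≥ 0.9 on peptides
of ≥ 11 residues and bypassed otherwise, so it can never change the
partition.

## Domain evidence and enzyme categories

Domain hits come from either a HMMER `--domtblout` per-domain table
(hmmscan orientation; the independent i-Evalue is used; E ≤ 1e-10) or the
built-in motif scanner. The scanner models each marker as a
position-weight matrix against a uniform 20-letter background, computes
the null score distribution *exactly* by discretized convolution over
columns, and converts a protein's best window score to a p-value and then
a database-wide E-value (p × total windows scanned). With the default
16-column models a planted marker scores far below the 1e-10 cutoff while
a single substitution inside the marker still passes; random proteins
essentially never do. This gives simulated data the same downstream
interface as real profile searches without shipping any profile database.

Enzyme class is assigned per protein by the most significant E-value
among hits listed in the user-supplied domain→category table
(lipase/esterase vs protease; equal E-values break by accession); listed
domains absent → `other`. A protein carrying both domain classes is thus
resolved to exactly one class. The bundled
`data/example_category_table.tsv` is a synthetic example (marker
accessions plus a few illustrative family accessions), not a curated
list.

GO-slim rollup climbs each domain's GO annotations to their *nearest*
slim ancestors by breadth-first search over the (acyclic) parent edge
list; a slim term maps to itself, ties at equal depth are all kept, and
annotations whose term is missing from the ontology or has no slim
ancestor are tallied as unmapped. Every annotation is therefore mapped to
≥ 1 slim term or unmapped; when nearest ancestors are unique the slim
counts sum exactly to the mapped annotations, and with ties the total can
exceed it — the same reason multi-domain proteins make total annotations
exceed the protein count.

## Wet-lab support (`wetlab`)

Directional-TOPO forward primers are `CACC` + the 5′ gene-specific
segment; restriction-mode primers are `AA` + recognition site +
gene-specific segment on both sides, with the amplicon scanned for
internal occurrences of the site (conflict flag). Output is uppercase
with the adaptor span reported as an interval. Melting temperatures use
the Wallace 2/4 rule with a configurable acceptance window — a
deliberately simple screen, not a nearest-neighbor model. Protease
activity is `µmol tyrosine / (min × ml)`; the tyrosine standard curve is
a least-squares line over ≥ 3 calibration points (0.110–1.5 µmol in the
assay this mirrors), inverted analytically, with absorbances outside the
calibrated range returned with an extrapolation flag. Lipolytic readouts
are raw absorbance at 410 nm with no unit definition, so no lipase unit
conversion is exposed. Temperature/pH/ion response curves are treated as
data to tabulate, not modeled.

## Determinism and problem sizes

Every stochastic component draws from a single seeded generator; the
pipeline writes no timestamps into output files, so a rerun with the same
config and inputs is byte-identical, and the run manifest records
parameters and input checksums. The test suite exercises parameter
recovery on a 5-clone pool with ~12 kb inserts (shared fixture) and a
20-clone pool at the full default geometry (~36 kb inserts, 30×
coverage, ~71k reads); oracle suites use 1,000 random 2-kb contigs for
ORF calling, 1,000 random length multisets for N50/L50, and 200-peptide
sets with planted 95 %-identity families for clustering. These sizes keep
the whole suite around two minutes while leaving no stage untested at its
default geometry.

## Known limitations

* The greedy assembler has no consensus polishing or scaffolding; with
  nonzero read error rates contigs carry the first-seen base at each
  position. At realistic pyrosequencing error rates the recovery
  guarantees above weaken accordingly.
* The screening aligner is gap-free; indel-rich contaminants would need
  the thresholds revisited or an external screen.
* The motif scanner is a stand-in interface for profile searches: it
  detects the simulator's planted markers, not real Pfam domains.
* Clone status uses a fixed 5 % score margin for uniqueness; repetitive
  inserts in real libraries may need a stricter margin.
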