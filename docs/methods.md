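# Methods

## The multi-layer graph model

karyograph reconciles *n* ≥ 3 draft ("preliminary") assemblies of one genome.
Each draft is a layer; each contig is a node; each surviving pairwise
alignment between contigs of different layers is an inter-layer edge. All
*n*(*n*−1) directed layer pairs are ingested separately because aligner
output is not symmetric under query/target exchange, especially for contigs
with multiple hits. Intra-layer edges encode external same-chromosome
evidence: Hi-C contact links aggregated per contig pair, or genetic-map /
reference chromosome assignments expanded to a clique among same-chromosome
contigs (reachability is all the clustering step consumes, so the clique is
the minimal faithful encoding).

Coordinates are 0-based half-open on the forward strand everywhere (the PAF
convention); SAM input is converted on ingestion, with query intervals
recovered from CIGAR clipping. Alignment coordinates on an edge always refer
to the *original* contig. When a node is split, no alignment is rewritten:
edge endpoints move to the fragment holding the majority of the aligned
interval, and classification clips the alignment to the current node
intervals on the fly, rescaling the partner interval linearly. Base-level
correspondence is not tracked across a clip; for geometry classification the
linear approximation is exact on the synthetic data and adequate on real
alignments at the tolerance below.

### Alignment filtering

Four criteria, all tunable: mapping quality, sequence length, alignment
block length, sequence identity. Defaults: mapq ≥ 20, contig length ≥ 50 kb
(0 for reads), block ≥ 5 kb (2 kb for reads), identity ≥ 0.90. These are
conservative for noisy long reads; with ultra-long reads or high-accuracy
drafts the mapq and block thresholds should be raised. Identity is taken
from a `de:f`/`dv:f` divergence tag when the aligner provides one, else
`n_match / block_len`.

### Merge geometry

For one alignment, each of its two termini is *internal* iff the unaligned
overhang beyond it exceeds a tolerance on **both** sequences
(strand-mirrored, so internality is geometry- not orientation-dependent).
Labels: `contained` (query covered within tolerance), `containing`,
`dovetail` (end-to-end mergeable), `internal_conflict` (≥ 1 internal
terminus, with the target-side breakpoint coordinates retained). The
tolerance defaults to max(500 bp, 2 % of the shorter sequence): a fixed
floor absorbs aligner end-trimming, the relative term scales with sequence
size. Supplementary/split alignments of one contig are classified
independently, not merged into one logical alignment first.

## Mis-assembly detection

Internal-conflict breakpoints on a node (from assembly-layer partners only;
reads join the graph after this stage) are clustered by single linkage at
≤ `cluster_window` (default 10 kb, the scale of long-read end noise); each
cluster defines a region M = [min breakpoint − flank, max + flank] clipped
to the node (flank default 500 bp). Support counts use **distinct partner
contigs**, not alignment records:

- *N_A*: partners contributing a breakpoint inside M;
- *N_B*: partners whose clipped alignment spans M plus flank on both sides;
- *N_S*: partners with an alignment terminus inside M that coincides with
  the partner's own sequence end (overhang ≤ tolerance).

The four-condition decision rule is in the README. Two edge cases are
resolved conservatively: condition 4 requires *N_A* ≥ 1 (the ratio is
otherwise undefined, and a locus with no partial mapping has no discordance
to evaluate), and a negative *N_B* − *N_S* satisfies the ≤ 0.6 inequality
literally. Flagged nodes are split at the lower median of the supporting
breakpoints — robust, deterministic, and exact when all partners agree.
Nodes are scanned in descending length (ties by layer then name) so the
long, chimera-prone contigs are handled first and the split log is
reproducible; the scan iterates to a fixpoint (cap 50 passes) and the suite
re-scans the fixpoint graph to assert no region still decides true. Node
splits conserve bases by construction: the two fragments tile the original
interval.

## Clustering, rescue, read partitioning

Scaffolding groups are the connected components over the union of inter- and
intra-layer edges (networkx), numbered by descending total contig bases for
stable diffable output. The reachability shortcut (inferred intra-layer
edges chaining same-layer nodes of one component) is provided and proven
partition-invariant by property test. Orphans — one contig from one layer —
are flagged for contamination triage, not classified. Short contigs excluded
from the graph are rescued into the group receiving ≥ 60 % of their filtered
aligned bases; ties or sub-majority winners stay unassigned, preventing
repetitive short contigs from landing arbitrarily.

Reads are assigned by summed aligned bases per group; the winner must lead
the runner-up by a margin (default 20 %), otherwise the read is AMBIGUOUS.
Read-only components smaller than 10 reads are reported as unplaced strays
rather than as groups. Export is strict (ambiguous dropped) or
`duplicate_ambiguous` (written to every near-tied group — helps shared
repeats, inflates coverage; explicitly opt-in). Exported records are
byte-identical to the input FASTQ/FASTA.

## Group assembly support

The overlap merger accepts only dovetail edges with ≥ 10 kb overlap
(config), retires contained contigs, and merges a component only if it is an
unbranched path: branches and cycles are reported, never resolved
heuristically — a wrong join is worse than no join, and repeat collapse is
the known failure mode of any such splice. Contigs are spliced at the
overlap midpoint (left contig keeps its bases up to it), so the merged
length is exactly Σ|contigs| − Σ overlaps, and on error-free input the
reconstruction is byte-exact. Orientation is resolved from edge end labels
(opposite ends for same-strand overlaps, same ends for reverse).

Telomere scanning counts non-overlapping copies of the motif and its reverse
complement in a terminal window (default 5 kb, ≥ 25 copies to report — loose
enough for degenerate arrays, strict enough that chance hits in random
sequence score zero). The motif itself is a required input: it differs
between clades, so no default is safe. Arm-pairing proposals enumerate all
pairings of groups lacking a telomere at one or both ends (4 arms ⇒ 3
combinations), rank them by fewest unpaired telomere-free ends, and filter
by the expected chromosome number when known; accepting a proposal is the
user's decision. Competing assemblies of one group are ranked
lexicographically by (internal zero-depth positions, collapsed bases, gap
count).

## Depth QC

Depth is accumulated from alignment blocks by difference array, so total
depth equals total aligned block length. Collapsed regions are maximal runs
with depth > multiplier × mean (multiplier 2.0, i.e. double the average
depth; mean computed over all positions including zeros, genome-wide mean
optional via parameter), kept at ≥ 1 kb. By default every reported position
satisfies the threshold pointwise; a `merge_gap` parameter can join nearby
runs for users who prefer consolidated calls, at the cost of that guarantee.
Window means use non-overlapping 5 kb windows with the trailing partial
window averaged over its true length.

## Synthetic data

The generator emulates the study conditions end to end: GC-biased i.i.d.
chromosomes (default GC 0.36 and telomere motif TTAGGC — a nematode-like
genome) with 300-copy telomere arrays, optional interspersed repeat families
with per-copy point divergence placed disjointly so annotations stay exact,
per-layer fragmentation with ±30 % length spread around an N50 target and
20 kb adjacent-fragment overlaps (the assemblable redundancy end-merging
needs), chimeras spliced at stated coordinates with junctions recorded,
reads drawn uniformly with exponential length spread (mean 15 kb, floor
1 kb), and Hi-C contact pairs with cis enrichment.

Alignments are **computed from truth coordinates**, not produced by an
aligner: any two origin segments sharing a chromosome interval yield one
exact record (mapq 0 inside annotated repeats). This makes unit tests exact
and removes every external-tool dependency, at the price of realism: no
spurious homology hits, no alignment jitter, no error-model artifacts.
Passing tests therefore demonstrate the graph algorithms' correctness under
the stated geometry, not robustness to aligner noise — the filtering
thresholds exist for the latter and are exercised only logically.

The integration scenario fixes the scale at 6 chromosomes of 0.5–2 Mb, 5
layers (N50 targets 400–800 kb), 3 chimeras in 3 different layers joining
disjoint chromosome pairs, and 20× error-free reads anchored to the
coarsest (chimera-free) layer. This runs the whole pipeline in seconds on
one CPU while exercising every code path; the acceptance tests assert 100 %
junction recall within 10 kb, zero false splits, exactly 6 groups matching
the true chromosomes, 100 % read-partition purity among placed reads, and
byte-exact chromosome reconstruction by the overlap merger.

## Known limitations

- No base-level breakpoint refinement: split coordinates inherit the
  breakpoint cluster's resolution (≤ cluster_window).
- The proportional rescale in alignment clipping is approximate on real
  (indel-containing) alignments.
- Orphan groups are flagged, not taxonomically classified.
- External assembler invocation per group is a rendered-command hook only.
- The read error model is uniform point error; homopolymer and chimeric-read
  artifacts of real long reads are not simulated.
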