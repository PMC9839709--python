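# karyograph

Chromosome-by-chromosome reconciliation of draft long-read genome assemblies
through a multi-layer graph.

## The problem

De novo assemblers applied to long-read data (PacBio, Nanopore) produce
hundreds of contigs per genome, and different assemblers fail differently:
each draft has its own chimeric joins and its own fragmentation. karyograph
exploits that disagreement. Several draft assemblies of the *same* genome
become layers of one graph; contigs are nodes; reciprocal alignments between
layers become inter-layer edges; optional Hi-C contacts or genetic-map /
reference chromosome assignments become intra-layer edges. From there:

1. **Mis-assembly detection** — a chimeric contig forces partner contigs'
   alignments to stop dead in its interior ("partial mappings"). Breakpoints
   of such internal conflicts are clustered into a candidate region *M*,
   scored by the number of partner contigs partially mapped to it (*N_A*),
   spanning it completely (*N_B*), or starting/ending at it (*N_S*). With
   *n* assembly layers, *M* is called a genuine mis-assembly if any of

   - *N_A* ≥ *n*/2
   - *N_B* = 0 and *N_A* ≥ 2
   - *N_A* ≥ 2 and *N_B*/*N_A* ≤ 0.5
   - *N_S* > 0 and (*N_B* − *N_S*)/*N_A* ≤ 0.6

   holds; the node is then split at the median supporting breakpoint, edges
   are re-assigned, and the scan iterates until the graph is conflict-free.
2. **Contig clustering** — connected components of the conflict-free graph
   form scaffolding groups, ideally one per chromosome (or arm). Single-contig
   single-layer groups are flagged as orphans (typical contaminant /
   organelle signatures); contigs below the graph's length threshold are
   rescued into the group absorbing the majority of their aligned bases.
3. **Read partitioning** — raw reads join the graph as an extra layer via
   alignment to an anchor assembly and are exported per group, so each
   chromosome can be re-assembled independently by any external assembler.
4. **Group assembly support** — a deliberately conservative overlap-graph
   merger (dovetail edges only, containments retired, branched components
   reported rather than resolved), telomere-motif scans of contig termini,
   enumeration of arm-pairing proposals, and a depth-of-coverage referee to
   choose between competing assemblies of one group.
5. **Depth QC** — per-base depth, 5 kb window means, and collapsed-region
   calls (depth above double the average), flagging repeat copies merged
   into one locus.

A synthetic-data generator (`karyograph.simulate`) produces multi-chromosome
genomes, fragmented assembly layers with injected chimeras, reads, Hi-C links
and all implied alignments with exact truth, so the entire pipeline is
testable without external tools.

## Worked example

```bash
karyograph simulate --seed 2 --outdir fx
karyograph detect fx/L1.fasta fx/L2.fasta fx/L3.fasta fx/L4.fasta fx/L5.fasta \
    --alignments fx/alignments --out splits.tsv
karyograph cluster --graph splits.tsv.graph --out groups.tsv
karyograph partition-reads --graph splits.tsv.graph \
    --alignments fx/reads_vs_anchor.paf --reads fx/truth/reads.fastq \
    --outdir parts
```

prints

```
fixture written to fx (anchor layer L5)
3 splits; graph bundle at splits.tsv.graph
6 groups (0 orphan)
{"1": {"reads": 2583, "bases": 38182239}, "2": {"reads": 2197, "bases": 33936120},
 "5": {"reads": 1061, "bases": 15913273}, "3": {"reads": 1753, "bases": 27336358},
 "4": {"reads": 1296, "bases": 19630744}, "6": {"reads": 602, "bases": 9002213}}
```

The simulated genome has 6 chromosomes and 3 injected chimeric contigs in 3
of the 5 layers. `detect` finds exactly the 3 injected junctions — the split
log shows each chimera cut with N_A = 8 partial partners and N_B = 0 spanning
partners (nothing spans a chimeric junction):

```
original_node                 contig       cut     iteration  ...  N_A  N_B  N_S
1:L2_chimera1:0-510074        L2_chimera1  248209  0          ...  8    0    0
2:L3_chimera1:0-492275        L3_chimera1  242275  0          ...  8    0    0
0:L1_chimera1:0-485433        L1_chimera1  233713  0          ...  8    0    0
```

`cluster` then recovers one scaffolding group per chromosome, and
`partition-reads` writes one FASTQ per chromosome plus the summary above
(group 1 = the 2 Mb chromosome at ~19x placed coverage, and so on).

The same steps are available as library calls (`build_graph`, `run_mdm`,
`cluster`, `assign_reads`, `merge_group`, `telomere_scan`,
`depth_from_alignments`); see `docs/methods.md` for the model and parameter
details.

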