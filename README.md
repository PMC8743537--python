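# levitax

Taxonomic classification of bacteria-infecting positive-sense single-stranded
RNA viruses (class *Leviviricetes*), for virologists and metagenomicists who
need to place MS2-like phage contigs into the 2021 ICTV framework — and for
anyone extending that framework with new metatranscriptomic sequences.

## The classification ladder

A genome is classified by a cascade of quantitative demarcation criteria:

1. **Class** — the genome must encode the three leviviricete core proteins:
   maturation protein (MP), coat protein (CP) and RNA-directed RNA polymerase
   (RdRP), found by six-frame ORF calling and profile-HMM scanning.
   Coding-completeness requires MP ≥ 350 aa and RdRP ≥ 500 aa.
2. **Order** — membership of the RdRP profile-HMM cluster:
   RdRP_A → *Norzivirales*, RdRP_B → *Timlovirales*.
3. **Family** — membership of one of nine CP clusters, each mapped to one of
   six families (e.g. CP_A/CP_B/CP_H → *Fiersviridae*, CP_C →
   *Atkinsviridae*, AP205-like → *Duinviridae*). If the CP cluster's family
   belongs to a different order than the RdRP cluster implies, the
   combination is *incongruent* and both order and family stay Unassigned.
4. **Genus / species** — single-linkage clustering of pairwise amino-acid
   identity (PAAI) of the RdRP: PAAI ≥ 50 % joins a genus, PAAI ≥ 80 % joins
   a species; species clusters always nest inside genus clusters. Each
   cluster gets an exemplar (ICTV-archived > GenBank-deposited > longest
   contig).

The toolkit implements every stage: FASTA/GFF3/TSV/Newick I/O, ORF calling,
Plan7-style profile HMMs (build, Viterbi/forward scoring, HMMER3 ASCII
read/write), Markov clustering of all-vs-all Smith–Waterman similarity
graphs, Needleman–Wunsch PAAI, neighbor-joining trees with clade-concordance
checks, and a synthetic-genome generator with planted taxonomy for testing
the whole chain without downloads.

## Worked example

```python
from levitax.classify import DemarcationConfig, classify_genomes, calls_to_frame
from levitax.hmm import build_library
from levitax.simulate import simulate_reference_set

ds = simulate_reference_set(n_orders=2, families_per_order=1,
                            genera_per_family=2, species_per_genus=2,
                            members_per_species=2, seed=42)
library = build_library(ds.msas)
cfg = DemarcationConfig(cluster_taxon_map=ds.taxon_map)
calls = classify_genomes(ds.genomes, library,
                         reference=ds.rdrp_reference(), cfg=cfg)
print(calls_to_frame(calls).head(2).to_string(index=False))
```

prints (abridged):

```
         genome_id  complete        order       family             genus_id                     species_id
syn_o1_f1_g1_s1_m1      True Norzivirales Fiersviridae Fiersviridae_genus_1 Fiersviridae_genus_1_species_1
syn_o1_f1_g1_s1_m2      True Norzivirales Fiersviridae Fiersviridae_genus_1 Fiersviridae_genus_1_species_1
```

Each row is one genome: `complete` is the coding-completeness filter,
order/family come from the RdRP/CP profile-HMM clusters, and genus/species
from RdRP PAAI against the demarcated reference set. On this 16-genome
corpus all 16 calls match the planted taxonomy exactly (see
`examples/classify_synthetic.py`; the other scripts under `examples/`
demonstrate demarcation, profile scoring and tree concordance).

The same pipeline is available from the shell:

```bash
levitax simulate --seed 42 --orders 2 --families 1 --genera 2 --species 2 --members 2 --out work/
levitax build-hmms --proteins work/proteins.faa --out work/lib.hmm
levitax classify --genomes work/genomes.fasta --hmms work/lib.hmm \
    --map work/cluster_taxon_map.tsv --out work/calls.tsv
```

## Using real data

The classifier reads any HMMER3 ASCII profile library (e.g. the published
*Leviviricetes* CP/MP/RdRP profiles) via `--hmms`, a cluster→taxon TSV via
`--map` (a packaged copy of the 2021 scheme is the default), and reference
RdRPs with known genus/species via `--reference/--reference-taxa`. See
`docs/methods.md` for the model details and the choices made where the
original pipeline parameters are unpublished.
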