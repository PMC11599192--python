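# cd28fam

Classification of vertebrate **CD28/CTLA4-family co-stimulatory and
co-inhibitory receptors** (CD28, CTLA4, ICOS, CD28H, CD28HL1-3, CD28X, PD-1)
from three independent lines of evidence:

1. **degenerate consensus motifs** — the diagnostic CDR3-loop, G-strand,
   E-strand, transmembrane and cytoplasmic signaling motifs of each family
   (e.g. the CTLA4 `[M/L/I]-[Y/F]-P-P-P-Y` + `GxG` signature, the CD28
   cytoplasmic `[D/E/V/I]-Y-M-[N/D]-[M/I/V/T]` with its PI3K `YxxM` and
   GRB2/GADS `YxNx` sites, the PD-1 ITIM `[I/V]xYxxL` and ITSM `TxYxx[V/I]`);
2. **domain architecture** — the shared leader / single IgV ectodomain /
   stalk / TM / cytoplasmic-tail layout of a type-I membrane receptor, with
   the IgV framework cysteine pair and tryptophan (canonical C23/W41
   numbering) located explicitly, and divergent V domains (bony-fish PD-1)
   flagged rather than rejected;
3. **conserved synteny** — marker genes of each receptor locus (e.g. *fsd1*
   and *stap2* around *cd28h*), the ancestral three-gene CD28/CTLA4/ICOS
   cassette, and counts of paralogous region copies surviving teleost- and
   salmonid-type whole-genome duplications (WGD).

The package is aimed at comparative immunogenetics: given receptor protein
sequences and (optionally) gene-order tables of their loci, it reproduces
the decision rule "member of the CD28 family iff (1) IgV-TM-IC architecture
with the conserved motifs and (2) conserved synteny markers", including the
unresolved **CD28/CTLA4 co-ortholog** outcome for chondrichthyan cassette
genes that cannot be assigned to CD28, CTLA4 or ICOS. A synthetic-data
module generates receptors and genomes with known truth, so every stage is
testable without genome downloads.

## The decision rule

For a protein record, the architecture module segments the sequence
(Kyte–Doolittle hydropathy for TM and leader; C/W/C spacing windows
C→W ∈ [10,25], C→C ∈ [50,85] for the IgV framework) and derives motif
windows. Each of the ten catalog profiles is then scored:

    score = Σ 2·[REQUIRED motif matched in its region]
          + Σ 1·[SUPPORTING motif matched]
          + 2·[≥2 shared synteny markers]  (1 point for exactly 1)

The top profile wins if `score ≥ 4` and it leads the runner-up by `≥ 2`;
two cassette-locus profiles within the margin of each other yield
`CD28_CTLA4_CO_ORTHOLOG`; anything else is `UNCLASSIFIED`. When a genomic
context is supplied, a canonical label additionally requires synteny
evidence.

Phylogenetic support uses pairwise global alignment (BLOSUM62, affine gaps
−11/−1), Poisson-corrected distances d = −ln(1−p), neighbor-joining trees
with column-bootstrap supports, and clade-membership tests on unrooted
bipartitions.

## Worked example

```python
from cd28fam import load_catalog, classify
from cd28fam.simulate import (SimProteinConfig, simulate_family_protein,
                              marker_context_table)

catalog = load_catalog()
record, truth = simulate_family_protein(
    SimProteinConfig(family="CD28X", seed=42), profiles=catalog)
table = marker_context_table("CD28X", record.id, profiles=catalog)

a = classify(record, genome_context=(table, record.id), profiles=catalog)
print(a.label, a.score, a.runner_up_label, a.runner_up_score)
for e in a.evidence:
    print(" ", e.source, e.detail, e.region, e.weight_points)
```

prints

```
CD28X 7 CD28 3
  MOTIF YxCx_6_PPPx_4/5_GxG CDR3_NEIGHBORHOOD 2
  MOTIF YxxxxT TM 1
  MOTIF EYEDM CYTOPLASMIC 2
  SYNTENY anos1,nlgn4x,pnpla4,pudp,sts  2
```

— the CD28X CDR3+G-strand signature (a CTLA4-like `PPP…GxG`), the
transmembrane dimerization motif, the conserved cytoplasmic `EYEDM`, and
five shared locus markers give score 7; the runner-up (CD28, score 3, from
the embedded `PPP` and `YxxxxT`) trails by 4, so the label is accepted.

The same pipeline from the shell:

```sh
cd28fam simulate proteins --family CD28X --n 2 --divergence 0.1 --seed 42 \
    --out-prefix cd28x
cd28fam classify --fasta cd28x.fasta --out run
# -> "2 sequences classified (CD28X: 2) -> run/assignments.tsv"
```

Other subcommands: `cd28fam scan` (motif occurrences as TSV),
`cd28fam synteny` (marker support and cassette detection),
`cd28fam tree` (NJ + bootstrap Newick), `cd28fam simulate genomes`
(WGD/loss gene-order tables).

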