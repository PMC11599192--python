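# Methods

This note records the models, parameter choices and known limitations of
`cd28fam` — what each stage assumes, which knobs matter, and what the
synthetic benchmarks do and do not demonstrate about real genome data.

## Motif model

Family-diagnostic motifs are degenerate consensus patterns over the 20
standard residues: fixed residues, residue classes (`[M/L/I]`), fixed-length
wildcard runs (`x`, `x_6`), bounded spacers (`x_4/5`) and unbounded spacers
(`(X)_n`). Matching is exact (no scoring, no mismatch tolerance): a motif
either occurs in a window or it does not. This mirrors how these motifs are
used in the comparative literature — presence/absence calls on curated
consensus strings — and keeps every call auditable. Position-specific
scoring and HMMs are deliberately out of scope.

Choices that needed fixing:

* **Unbounded spacers** are bounded at 60 residues for matching. The only
  unbounded pattern in the catalog joins an ITIM to an ITSM within one
  cytoplasmic tail; 60 residues covers any plausible spacing there.
* **The ambiguity code X** (gap-filled gene models) satisfies wildcard and
  spacer positions but never fixed/class positions. This is conservative:
  an assembly gap can never *create* a diagnostic residue.
* **All overlapping matches are reported**; for unbounded-spacer patterns
  only the shortest match per start (longer spacer extensions add no
  information). Coordinates are 1-based inclusive throughout, matching
  residue-numbering conventions like C23/W41.
* The polar residue class written `[E/K/Q/N-polar]` in the source
  literature is encoded as the explicit set `{E,K,Q,N,S,T}`; the affected
  catalog entries carry a note flagging the interpretation.

## Evidence catalog

`data/catalog.yaml` holds the ten profiles (nine canonical families plus
the chondrichthyan CD28/CTLA4 co-ortholog class). REQUIRED motifs are those
conserved across a family's full species range; lineage-restricted variants
(e.g. the chondrichthyan/reptile `E-I-P-P-P`) are SUPPORTING so that
classification works across the whole range. The chondrichthyan cassette
position (first/second/third gene) is an optional attribute on evidence
(`cassette_position: 3` for the third-position `EYxNM`), not a separate
profile.

The cassette families (CD28, CTLA4, ICOS, co-ortholog) share one locus and
hence one marker panel. The curated panels for the non-cassette families
come straight from the locus descriptions (*fsd1*/*stap2*;
*man2b*/*kiaa0232*/*tcb1d14*; *slbp*/*tacc3*/*tmem129*;
*prkab1b*/*pla2g1b*/*tmem233*; *pudp*/*sts*/*anos1*/*nlgn4x*/*pnpla4*;
*pcyt1a*/*tctexd2*/*rtp* + *muc4*/*tnk2*/*tfrx*/*zdhhcl9*). For the
cassette locus itself no explicit marker list was available, so the panel
uses the human 2q33 neighborhood (*raph1*, *abi2*, *wdr12*, *cyp20a1*) as a
curated stand-in; any user catalog can replace it.

ICOS's CDR3 `P-[P/A/L]-P` is weighted REQUIRED: it is reported across the
ICOS range, and treating it as supporting evidence leaves ICOS
indistinguishable from the co-ortholog class under the margin rule. ICOS's
lineage-restricted G-strand `GxG` (turtle/gar/sterlet only) is recorded as
a note, not evidence.

## Architecture inference

A stand-in for profile-based domain annotation, built from standard
first-principles surrogates so that tests are pinned to explicit numbers:

* **TM segments**: mean Kyte–Doolittle hydropathy over a 19-residue window
  ≥ 1.6; overlapping qualifying windows merged; interval ends then trimmed
  back to residues with hydropathy ≥ 1.0 (window overhang otherwise
  overshoots each boundary by up to half a window); intervals ≥ 15 residues
  reported. The membrane anchor is the last TM with ≥ 8 downstream
  residues.
* **Leader**: mean hydropathy of residues 2–16 ≥ 1.0 calls a leader of 18
  residues (a typical signal-peptide length).
* **IgV framework**: a C…W…C triple with C→W spacing in [10, 25] and C→C
  spacing in [50, 85], bracketing the canonical C23/W41/C104-style
  framework. The leftmost, then tightest triple wins. The IgV interval is
  [cys1 − 22, cys2 + 13] (C23 numbering puts 22 residues before the first
  framework cysteine; the G strand ends ~13 residues after the second). A
  pre-TM span ≥ 55 residues without a triple sets the *divergent IgV* flag
  (the bony-fish PD-1 situation) instead of failing.
* **Motif windows**: CDR3 neighborhood = [cys2 − 5, cys2 + 30] (the CDR3
  loop follows the second framework cysteine); G strand = last 15 residues
  of the IgV; E strand = [cys1 + 30, cys1 + 50]; C-terminal window = last
  20 residues. These localize the "CDR3 loop" / "G strand" / "E strand"
  vocabulary without a structural alignment; they are generous on purpose
  since motif matching, not the window, carries the specificity.

## Classification

Scoring: REQUIRED motif matched in its window = 2 points, SUPPORTING = 1,
synteny hit sharing ≥ 2 profile markers = 2 (exactly one = 1). The 2/1
weights are an artifact convention (the literature ranks motif evidence
only qualitatively). Acceptance threshold 4 and margin 2 are the smallest
values that accept every zero-divergence exemplar while forcing the
chondrichthyan hybrid pattern (CTLA4-like CDR3/G-strand plus CD28-like TM
and cytoplasmic motifs) into the co-ortholog outcome; both are exposed as
parameters. When the top two profiles are cassette-locus families within
the margin, the outcome is `CD28_CTLA4_CO_ORTHOLOG`; otherwise sub-margin
or sub-threshold results are `UNCLASSIFIED`.

Genomic context is optional: when present, a canonical label requires
synteny evidence (mirroring the two-criterion membership rule); when
absent, the synteny criterion is waived rather than failed, since
transcript-only evidence is still classifiable. Exact ties between
profiles are broken by fixed catalog order; permuting the catalog changes
no label except on such exact ties.

## Synteny

Windows are measured in gene ranks, not base pairs, because curated synteny
panels list only conserved markers (default half-width k = 10 genes).
Gene-symbol matching is case-insensitive, strips `.N`/`-N` lineage
suffixes, and tolerates a short trailing `[0-9ab]` ohnolog tag (so `tacc3`
matches `TACC3` and `tacc3.2`, and `prkab1` matches `prkab1b`). This
tolerance can over-match contrived families of names that differ only by a
trailing digit; curated marker panels do not collide this way. Cassette
detection reports maximal runs of ≥ 2 family genes separated by at most
`max_gap` (default 1) interleaving genes. Paralogous-region counting
accepts ≥ `min_shared` (default 2) distinct markers per window and counts
at most one region per chromosome unless two windows are > 50 gene ranks
apart (the post-rearrangement fusion case).

## Phylogenetic support

Maximum-likelihood inference is out of scope; the clustering layer is
distance-based and is used for topology/recovery questions only (never
likelihoods). Pairwise global alignment uses BLOSUM62 with affine gaps
−11/−1 (a gap of length k costs −11 − (k − 1)); percent identity is
computed over non-terminal-gap columns. Multiple alignments for
bootstrapping come from center-star progressive alignment over the same
pairwise aligner — a deliberate simplification of full progressive MSA
that is adequate at the scale of a per-species receptor repertoire
(tens of sequences), not for deep phylogenomics.

Neighbor joining is the canonical agglomeration with two pinned details:
Q-criterion ties break on the lexicographically lowest label pair, and
negative branch lengths are clamped to zero with the deficit moved to the
sibling edge (preserving the joined pair's path length). On additive
matrices NJ reproduces all path lengths to < 1e-9 (branch lengths are
serialized at 17 significant digits for this reason). Distances are
Poisson-corrected, d = −ln(1 − p) with p the mismatch fraction over shared
non-gap columns; saturated pairs (p ≥ 1, or no shared columns) are capped
at d = 10 with a warning. Bootstrap resampling draws one index vector per
replicate from a single seeded generator over taxa sorted by label, so
supports are reproducible and invariant to input taxon order. Clade
membership asks whether the candidate lies inside the smallest non-trivial
bipartition side containing all references; a star tree therefore yields
False for any proper subset.

## Synthetic data

The generators define the conditions every test runs under.

**Proteins.** The backbone is: 18-residue hydrophobic leader (M +
Leu/Val/Ala/Phe), IgV scaffold with the C/W/C framework at canonical
spacings (cys1 at domain position 23, W at +18, second C at +65), a stalk
of 10–14 residues, a 21-residue Leu/Ile/Val/Phe TM, and a cytoplasmic tail
of 36–44 residues. The family's REQUIRED and SUPPORTING motifs are planted
in their regions: motifs whose third element is the framework cysteine
(`YxC…`) are anchored on cys2, other CDR3 motifs follow it, the G-strand
motif sits in the last 15 IgV residues, the E-strand motif at cys1 + 35,
the TM motif (`YxxxxT`) inside the TM, cytoplasmic motifs from TM + 10, and
C-terminal motifs 8 residues from the end. PD-1 exemplars omit the
framework triple (the divergent bony-fish V domain).

Scaffold residues are drawn from the hydrophilic alphabet `{S,T,N,Q,D,E,A}`
— no G (scaffold glycines would create chance `GxG` matches in the G-strand
window at a rate that corrupts cassette-family assignment), no Y/C/W (no
chance tyrosine motifs or framework triples), nothing hydrophobic enough to
fake a TM. The stalk and the first 9 cytoplasmic residues additionally
exclude A so the planted TM boundaries stay sharp (biologically: a
Ser/Thr-rich stalk and a charged juxtamembrane). Class positions in
planted motifs take the alphabetically first member, wildcards take S (L
inside the TM), unbounded spacers take 8 residues: a zero-divergence
exemplar is the family's canonical consensus representative, and recovery
at divergence 0 is exact by construction.

Divergence applies independent per-site substitutions at the given rate,
drawing the replacement uniformly from the 19 alternatives — a stress
parameter, not an evolutionary model (no rate matrix, no among-site
variation, no indels). With `protect_motifs` the planted motif positions
*and* the three framework residues are exempt; at 10% divergence the mean
identity to the unmutated exemplar is ~90–92% (the protected ~10–18% of
sites never change). An optional `mutation_seed` separates the
substitution stream from the scaffold seed so several descendants of one
ancestor can be simulated.

**Genomes.** An ancestral chromosome carries the three-gene cassette
between its markers plus one block per placed family (markers flanking the
receptor gene), blocks separated by filler genes. Each WGD duplicates
every chromosome; loss removes genes per-copy with a given probability
(optionally restricted to receptor genes and/or specific copies);
rearrangement applies adjacent transpositions. The truth table records
block ancestry, marker-copy survival (≥ 2 markers retained) and
receptor-copy survival per block; with zero loss, surviving copies equal
2^WGD and match the detector exactly.

**What passing means.** The synthetic benchmarks show that the decision
rule, the scanner, the segmenter and the synteny detectors are correct and
well-calibrated *under the generator's assumptions*: motifs intact up to
protected substitution, a single clean TM, no indels, no paralogy within a
window, marker names used consistently. Real gene models bring truncated
N-termini, mispredicted exons, lineage-specific motif erosion (e.g.
cyprinid CD28 tails) and assembly gaps; the X-handling and divergent-IgV
paths address some of this, but recovery percentages measured here do not
transfer to real annotation pipelines.

## Problem sizes

Default test and acceptance runs use 200 exemplars per family at 10%
divergence (plus 50 at zero), 50 seeds per profile for catalog/generator
consistency, 1000 random motif oracle cases, 100 random additive matrices
(≤ 8 taxa) and 100 bootstrap replicates — sizes chosen to exercise every
code path with comfortable statistical margins at desk scale.

## Known limitations

* Exact motif matching cannot score partially degenerate motifs; a single
  substitution in a REQUIRED motif silently removes 2 points.
* Hydropathy-based TM detection fails for marginal TMs and multi-pass
  proteins (out of scope: all targets are single-pass type I).
* The IgV test keys on the C/W/C framework only; other IgSF folds with
  compatible spacing would pass architecture (classification still
  requires family motifs and synteny).
* Center-star MSA degrades for deep divergences; bootstrap supports from
  it are indicative, not publication-grade phylogenetics.
* The ohnolog-tolerant gene-name matcher can conflate symbols that differ
  only by a trailing digit (`tmem1` vs `tmem12`).
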