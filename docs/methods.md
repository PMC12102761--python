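# Methods

## Scope and data model

The package analyzes annotated mitochondrial genomes: per-genome
structural summaries, the codon-usage bias battery for the 13
protein-coding genes (PCGs), per-gene divergence statistics across taxa,
and concatenated datasets for downstream phylogenetics. Coordinates are
1-based inclusive (GenBank convention); circular features may wrap the
origin and are stitched on extraction. Light-strand features are stored
with forward-strand coordinates and a coding-orientation sequence.

Gene names are normalized to a controlled vocabulary (ATP6/8, COX1–3,
CYTB, NAD1–6, NAD4L; tRNA-Xxx; srRNA/lrRNA; CR; OL) via a synonym table
shipped as package data. Unmappable names warn and are retained verbatim,
never dropped.

## Genetic code handling

All indices derive their synonymous-family partition from the active NCBI
translation table (default 2, vertebrate mitochondrial). This matters:
under table 2 Arg collapses to the fourfold CGN box, Met (ATA/ATG) and
Trp (TGA/TGG) become twofold families, and no amino acid is
single-synonym, so the standard-code habit of "excluding Met, Trp" from
synonymous statistics has no direct analogue. The default excludes
exactly the single-synonym families of the active code (none under table
2) plus stops; a `legacy_exclude` option reproduces the standard-code
exclusion for comparability with CodonW-lineage outputs.

Start-codon policy: the permissive default accepts {ATG, GTG} plus the
table's own initiators (table 2 also lists ATT/ATC/ATA); `strict=True`
limits validation to the explicit set. GTG initiation is common for COX1
in clupeiform fishes. Truncated stops (a trailing T or TA) are completed
to TAA, modelling post-transcriptional polyadenylation; any other frame
remainder is an error.

## Index definitions and numerical choices

- **RSCU**: observed × degeneracy / family total. Families with zero
  observations are flagged undefined rather than zero-filled.
- **ENC**: Wright's estimator by degeneracy class. Families with n ≤ 1 or
  F̂ ≤ 0 are omitted from their class mean; a wholly absent class is
  imputed at F̄ = 1/k. The estimate is clamped to [20, 61]; note the
  finite-sample estimator approaches its asymptote from above (uniform
  usage of the 60 table-2 sense codons gives 60 + O(1/n)).
- **X3s**: per-base denominators restricted to codons whose family
  permits that base synonymously at position 3 (CodonW convention), so
  A3s + T3s + G3s + C3s generally exceeds 1. GC3s uses the common
  denominator of all multi-synonym-family codons.
- **CAI**: weights w = RSCU/RSCU_max per family from a reference set.
  The analysis of a self-contained genome set has no external
  high-expression reference, so the default reference is the pooled
  13-PCG usage of all taxa in the run; any weight table may be supplied.
  Reference codons with w = 0 receive a configurable floor (0.01).
- **CBI/FOP**: optimal set defaults to the highest-RSCU codon per family
  in the pooled reference (alphabetical tie-break for determinism);
  N_rand is the expected optimal count under uniform synonym usage.
- **GRAVY/AROMO**: Kyte–Doolittle means and aromatic fraction of the
  translation, terminal stop excluded (cross-checked against Biopython's
  ProtParam in the tests).
- Initiation codons are counted as written (no forced-Met recoding);
  the effect is at most one codon per gene.

## Bias diagnostics

The neutrality fit is an ordinary least-squares regression of GC12 on GC3
across genes with a two-sided t-test on the slope; with only seven
independent per-species fits no multiple-testing correction is applied.
The expected-ENC curve is 2 + s + 29/(s² + (1 − s)²); it is symmetric in
s ↔ 1 − s only up to its linear term (f(s) − f(1 − s) = 2s − 1) and peaks
marginally above s = 0.5. PR2 coordinates default to the classical
fourfold-degenerate stratum; an `all_synonymous` mode exists for
tool-lineage comparability. Quadrants follow the mathematical convention
(II = upper-left, the A- and C-preferring corner); points exactly on an
axis are reported as boundary.

ΔRSCU codon classification needs high- and low-bias gene groups; no
universal definition exists for mitochondrial data. The default ranks the
13 genes by ENC and takes the three lowest-ENC genes as the high-bias
(high-expression proxy) group and the three highest as the low-bias
group; the ranking key (ENC or CAI) and group size are configuration
options recorded in the output metadata. Optimal codons are by
construction the intersection of the high-frequency (RSCU > 1) and
high-expression (ΔRSCU > 0.08) sets.

## Divergence estimators

π uses complete deletion by default (columns with any gap/ambiguity
dropped globally — the DnaSP convention); K2P and Ka/Ks use pairwise
deletion. The Nei–Gojobori implementation is the original proportional
method: per-codon potential synonymous sites are the synonymous fraction
of the nine single-nucleotide changes, with changes into stop codons
counted as nonsynonymous so S + N = 3 × codons holds exactly; observed
differences are averaged over all shortest substitution pathways,
excluding pathways through stops (if every pathway is blocked, all are
used with stop-traversing steps counted as nonsynonymous). Jukes–Cantor
correction is applied to both proportions; pS or pN ≥ 3/4 and saturated
K2P log arguments yield NaN, flagged rather than raised. The per-gene
"average Ka/Ks" is the arithmetic mean of defined per-pair ratios;
a ratio-of-means alternative is a configuration switch. The
implementation agrees with Biopython's independent NG86 routine to 1e-9
on simulated data.

## Synthetic-data generator

Each codon site evolves independently under a continuous-time chain over
sense codons with rate ∝ κ^[transition] × ω^[nonsynonymous] for
single-nucleotide changes; stop codons are unreachable. Rates are
normalized by the root sequence's mean per-codon rate so a branch of
length b accumulates b expected substitutions per nucleotide site (exact
at the root, approximate under composition drift). The default tree is a
star with each tip at d/2 from the root, making d the expected pairwise
divergence and keeping closed-form expectations simple. Root codons draw
position-3 bases exactly from the target GC3/skew distribution (stop
avoidance resamples only positions 1–2) and positions 1–2 uniformly.

Defaults represent a small radiation of congeneric fish mitogenomes:
7 taxa, the 13 PCGs at their approximate true codon counts (56–612),
GC3 = 0.405 with AT3 skew +0.31 and GC3 skew −0.47 (third-position A > C
> T > G), κ = 2, ω = 0.03 (strong purifying selection, within the range
mitochondrial PCGs show), d = 0.2.

What the generator emulates: family structure of the vertebrate
mitochondrial code, controlled third-position composition, purifying
selection, truncated stops, GTG initiation, a light-strand gene, variable
control-region length. What it does not: indels (alignments are gap-free
by construction), rate heterogeneity across sites beyond the syn/nonsyn
dichotomy, realistic tRNA/rRNA evolution, strand-asymmetric mutation.
Passing recovery tests therefore demonstrate estimator correctness under
the model's assumptions, not robustness to alignment error or
among-site rate variation. Two consequences worth noting: with ω ≪ 1 the
substitution process is strongly site-heterogeneous, so K2P (which
assumes homogeneity) underestimates the nominal d — the K2P recovery
experiment accordingly runs at ω = 1; and with ω = 0 the NG86 pathway
average can still ascribe a tiny nonsynonymous share to multi-hit codons
(e.g. TTA vs CTC inside the sixfold Leu box), so Ka is asserted ≈ 0, not
exactly 0.

## Problem sizes

The test suite runs a reduced 13-gene panel (~2,790 codons) for
end-to-end fixtures and 5,000-codon two-taxon replicates for recovery
(10 replicates for K2P, 20 per ω for Ka/Ks); the acceptance script uses
the full default gene panel for the synthetic study and the same
recovery sizes. These sizes put Monte-Carlo error well inside the
asserted tolerances (3 standard errors for K2P; 15% relative for mean
Ka/Ks).

## Known limitations

- Real-data reproduction requires user-supplied GenBank files and an
  accession-to-species table; no network fetching is performed.
- The "Mt" whole-genome dataset is approximated as PCGsRNA plus
  control-region/OL partitions; true whole-genome alignment is external.
- Alignment itself (MAFFT etc.) and alignment trimming as published
  (Gblocks/trimAl) are external; `gap_trim` is a simple gap-fraction
  surrogate whose site counts will not be bit-identical to those tools.
- No ML codon models (the Ka/Ks here is counting-based NG86), no
  correspondence analysis, no tree inference.
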