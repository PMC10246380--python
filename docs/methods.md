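# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic data do and do not emulate, and the numerical
choices made where the design was genuinely open.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Roles and coordinates

Every analysis is driven by a species-role map: exactly one **focal**
parasite, ≥ 1 **donor-clade** species (the host's family, the expected
source of transfers), ≥ 1 **relative-clade** species (the parasite's true
phylogenetic relatives), and ≥ 1 **outgroup** for rooting; other species
are tolerated and ignored by the clade tests.  All genomic coordinates are
1-based closed intervals end to end; conversions (e.g. BED) happen only at
format boundaries, so intron length is always `end − start + 1`.

Gene records carry the CDS-defining exons; gene length is the span of
those exons (UTRs are outside the input convention).  When a gene has
several transcripts the longest CDS is kept, matching the primary-
transcript convention of orthology inputs.  A CDS whose length is not a
multiple of 3 is flagged partial and excluded from codon-level analyses;
codons containing N are masked there as well.

## Orthogroup copy-number categories

The classifier applies a fixed precedence order (all-zero → unclassified;
focal-only → focal-specific; 0:1 exact; 0:n with some n > 1; 1:1; 2:1
exact; ≥ 2n:n; else unclassified).  The "at least 2n:n (n > 1)" reading is
ambiguous in the field's usage; here it means every non-focal species has
≥ 2 copies and the focal count is at least twice each, with a strict mode
(`strict_2n_n`) additionally requiring equal non-focal counts for
sensitivity analysis.  The headline loss fraction is reported with two
denominators — orthogroups present in *all* non-focal species (primary)
and in *at least one* — because "conserved among the other species" can
mean either.  Enrichment uses the two-sided Fisher exact test with
Benjamini–Hochberg q-values across categories; raw p-values are always
kept alongside.

## Alignment engine

The progressive aligner is deliberately simple and deterministic: pairwise
global Needleman–Wunsch (BLOSUM62; a gap of length k costs 10 + k), UPGMA
guide tree on pairwise identity distances, profile–profile merges with
sum-of-pairs scoring and the same affine penalties (ties in the dynamic
program resolved in a fixed state order).  Externally computed alignments
are accepted unchanged.  Trimming keeps a column iff its non-gap occupancy
is ≥ the threshold (default 0.6); the boundary uses ≥ because the external
tool the convention comes from leaves its boundary behavior unspecified.
The trimmed result retains an explicit kept-column map so intron positions
can still be projected after trimming.  Back-translation maps each residue
to its codon and `-` to `---`, trims a terminal stop with a log line, and
fails loudly on any other discordance.

## Tree engine

The built-in engine is canonical Saitou–Nei neighbor joining on
Poisson-corrected protein distances (d = −ln(1 − p) on pairwise-complete
columns, capped at 10), with the classic Felsenstein bootstrap (resample
columns, rebuild, count splits; default 100 replicates at desk scale).
Q-matrix ties break on the lexicographic order of cluster representative
labels; negative branch lengths are clamped to 0 with the deficit moved to
the sister branch.  Maximum-likelihood inference is intentionally out of
scope: the transfer criterion is purely topological, so externally
computed trees with support labels are first-class inputs and the internal
engine is just the self-contained default.  Rooting places the root on
the edge separating the outgroup; a non-monophyletic multi-leaf outgroup
falls back to the single outgroup leaf farthest from the focal gene, with
a warning.

## Transfer classification

For each focal gene on the rooted tree, let C be the smallest clade
containing the gene and ≥ 1 donor-clade leaf.  The gene is a transfer iff
C contains no relative-clade leaf, C's stem support is ≥ the gate
(default 50; 70 is a reasonable choice for NJ trees), and the protein
exceeds 150 aa (≤ 150 aa is excluded outright).  The symmetric condition
on the smallest relative-containing clade gives a vertical call under the
same gate; everything else is unresolved.  Two deliberate choices: a tree
lacking donor-clade homologs yields *unresolved*, never vertical (absence
of evidence is not placement), and leaves from "other" taxa inside the
defining clade do not disqualify it (only relative-clade leaves do) but
are logged.  Support is read from the stem edge only; resolution inside
the donor clade is irrelevant.  Focal paralogs are classified
independently, so post-transfer duplications yield several transfer calls
in one orthogroup.  The mitochondrial screen is the same classifier with a
mitochondrial taxon panel and a compartment tag.

Functionality is expression-based: expressed = max FPKM across tissues
strictly > 1; functional = expressed transfer call.  Genes absent from the
expression matrix count as unexpressed (logged).

## Introns

Introns are the gaps between consecutive CDS exons, reverse-complemented
and reordered 5'→3' for minus-strand genes; canonical means GT..AG on the
transcript strand.  Phase is cumulative CDS length before the intron mod
3; the host codon is the codon completed (phase 0) or interrupted (phase
1/2) at the boundary.  Two introns are **analogous** iff they project to
the same protein-alignment column with the same phase — the only precise
reading consistent with position-conservation figures in this literature;
a host codon whose column was trimmed leaves the position undefined and
the pair is skipped with a log line.  Identity of analogous introns uses
global nucleotide alignment (match +1, mismatch −1, gap of length k costs
2 + 0.5k) with identity = matches / alignment columns, gaps included —
stated explicitly because "identity" is convention-dependent.  Pairs under
100 bp are skipped, mirroring the ≥ 100 bp intron filter.  Origin is the
group of the best-identity subject; exact ties are "uncertain".  The
candidate set is the supplied donor- and relative-clade introns, a
self-contained replacement for a remote-database best-hit search.
Long-intron genes have at least one intron strictly over 1 kb.

The intron/expression association is a 1-df Pearson chi-square; the Yates
correction is applied automatically when any expected cell is below 5 (and
can be forced on or off).  Type-I calibration of this default is part of
the acceptance suite.

## Selection

NG86 counting with equal-weight stop-avoiding pathway averaging (if every
pathway passes through a stop — possible only for rare multi-difference
pairs — all pathways are used) and Jukes–Cantor correction; pS ≥ 0.75
saturates dS and leaves ω undefined, as do dS = 0 and fewer than 10
comparable codons (configurable).  The foreground/background contrast is a
desk-scale surrogate for branch-model likelihood tests: foreground pairs
are each transferred gene with its closest donor-clade homolog (smallest
raw nucleotide p-distance), background pairs are all pairs among the
vertically inherited genes; set-level dN and dS are pairwise estimates
weighted by compared-codon counts and ω_set = mean(dN)/mean(dS).  Because
a pairwise path mixes the post-transfer (foreground) segment with
donor-side (background) evolution, the recovered foreground ω is a
path-length-weighted blend — it detects the planted contrast but
underestimates extreme foreground values.  Regimes use a ±0.1 neutral
band around 1, since a point estimate is never exactly 1.  Likelihood
branch models and relaxation tests are out of scope; their ω tables can be
supplied via `read_external_omega` and reuse the same regime logic.

## The synthetic-data generator

The generator is the package's study system.  Defaults (the fixed
conditions, chosen for biological plausibility and recoverability, not
per-run):

| parameter | default | meaning |
|---|---|---|
| species tree | 6 taxa, see `DEFAULT_SPECIES_TREE` | focal terminal 0.25 (parasite rate acceleration), donor clade with 0.06 terminals on a 0.21 stem, relatives 0.10/0.12, outgroup 0.35; substitutions/site |
| `n_families` / `n_codons` | 200 / 350 | 350 codons ≈ the 1 kb mean CDS typical of these genomes |
| `rate_dup`, `rate_loss` | 0.1 each | events per gene lineage per unit branch length (Gillespie within branch; duplicates copy the branch-start state) |
| `rate_transfer` / `n_transfer_families` | 0 / unset | Poisson transfers on donor terminal branches, or exactly-k planting for deterministic recovery experiments |
| `post_transfer_branch` | 0.4 | divergence the transferred copy accrues inside the parasite after the transfer point; comparable to the focal terminal branch and what makes the foreground ω contrast visible to the pairwise surrogate |
| `kappa` / `omega_by_class` | 2.0 / 0.2, 0.2 | HKY transition bias; per-class ω for vertical and transferred genes |
| intron model | Poisson(3) count, length 60 + Geometric(mean 140), GT..AG | phase-0 junctions fixed per family at the root; intron sequences evolve neutrally along the tree (termini preserved), so transferred genes carry donor-derived intron sequence |
| `focal_vertical_length_factor` | 3.0 | intron elongation in the focal species' vertical genes (repeat expansion in the bloated parasite genome); transferred genes keep compact donor-like introns |
| expression | log-normal(μ=1, σ=1) FPKM, 30% silent | replicate-averaged values per tissue (bract, sepal, petal, disk) |

Codon evolution is an HKY-biased proposal process with ω-weighted
acceptance: proposals at rate `branch_length` per nucleotide site,
proposals creating stops rejected, synonymous proposals accepted,
nonsynonymous accepted with probability ω (for ω > 1 the synonymous
acceptance is scaled by 1/ω instead).  Realized substitutions/site are
therefore ≈ t·(fS + ω·fN), and the NG86 estimate of a planted ω carries a
small downward bias from the transition bias the counting method ignores —
both visible in, and bounded by, the recovery tests.  Branch lengths are
exact for topology purposes, approximate as molecular clocks.

What the generator does **not** emulate: coding-sequence indels (families
are alignment-free, so the aligner is exercised on its own fixtures),
recombination, codon-usage bias, intron gain/loss except the configured
focal-vertical loss, assembly/annotation error, and orthology-inference
noise (true family membership is the orthogroup table).  Passing recovery
tests therefore demonstrate correctness of the decision logic under clean
inputs, not robustness to annotation artifacts.

One bookkeeping subtlety: in fixed-number planting mode the primary gene
lineage is exempt from loss so every planted transfer has a live donor
source and a focal vertical counterpart; the event log remains exactly
consistent with the realized gene counts (per-species count = 1 + dups +
transfers − losses along the root-to-tip path, replayed by the tests).
Transfers are recorded on the recipient branch with the donor branch as an
annotation.  In "replace" mode the displaced vertical copy is recorded as
a loss on the focal branch.

## Problem sizes and determinism

The shipped experiments are desk-scale by design: 200 families × 30
planted transfers with 100 bootstrap replicates for transfer recovery;
10 seeds per point on the ω grid; 2,000 tables for chi-square calibration;
50 random 5–8-taxon trees for NJ recovery (with exhaustive least-squares
confirmation at 5–6 taxa).  All randomness flows from explicit seeds
(numpy `default_rng` with composite seed sequences; per-family streams),
and identical config + seed reproduces byte-identical outputs.

## Known limitations

* NJ + classic bootstrap understate support relative to ML ultrafast
  bootstrap; the 50% gate is a display-convention default and should be
  re-examined (e.g. 70) when the internal engine is used on real data.
* The pairwise ω surrogate blends foreground and background segments
  (above); use the external-ω adapter for publication-grade branch tests.
* Intron origin assignment is only as good as the candidate intron set;
  it does not search databases.
* The Fisher/chi-square helpers assume replicate-averaged, independent
  gene-level observations.
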