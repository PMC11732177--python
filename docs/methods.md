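# Methods

This note documents the models, conventions and design choices behind
`cyslys`, in the spirit of a statistics package's model documentation: what
each stage computes, which knobs matter, and what the synthetic benchmark does
and does not establish.

## Structure model and functional atoms

Each protein is a single-chain monomeric model in PDBx/mmCIF, with 1-based
UniProt residue numbering and per-residue pLDDT carried in the per-atom
B-factor column (the AlphaFold DB convention; pLDDT is constant across a
residue's atoms and we read the first). The geometric reduction is
deliberately minimal: a cysteine is represented by its thiol sulfur (SG), a
lysine by its ε-amine nitrogen (NZ) — the donor and acceptor atoms of the
S → N acetyl-transfer chemistry. There is no Cβ or centroid fallback:
residues missing the functional atom are excluded and logged rather than
approximated, and multi-chain files are rejected rather than guessed at,
because inter-chain pairs in multimeric proteoforms are a different analysis.

PAE matrices follow the AlphaFold DB v4 JSON dialect. PAE is asymmetric as
emitted; all pair-level uses go through a symmetrized accessor
(mean of the (i,j) and (j,i) entries). A PAE file whose dimension disagrees
with the paired model is a hard error — silent index misalignment would
corrupt every downstream lookup.

## Significance model for PTM sites

Peptide rows (possibly multi-site) are stratified to single residues: a
site's log2FC is the plain arithmetic mean of the signed log2 fold changes of
all peptides covering it, and its corrected p is their minimum. The mean is
applied to signed values with no special rule for conflicting directions; the
minimum-p rule makes a site as significant as its best-supported peptide.
Significance is the dual threshold p(corr) ≤ 0.05 **and** |log2FC| ≥ 0.58
(≈1.5-fold), both comparisons inclusive. Fold changes are assumed log2-scaled
on input; a `linear_fc` switch converts signed linear ratios
(sign(x)·log2|x|) for tables exported on the linear scale.

## Pair geometry and confidence filtering

Pair enumeration is all-vs-all within a protein — chains at these sizes
(hundreds of residues, tens of Cys/Lys) do not warrant a spatial index, and a
naive double loop is the reference implementation the tests compare against.
Thresholds, all configurable via `ProximityConfig`:

| parameter | default | meaning |
|---|---|---|
| `distance_threshold` | 15.0 Å | SG–NZ separation for proximity (inclusive ≤) |
| `plddt_min` | 70 | both residues must have pLDDT ≥ 70 (strictly-below excluded) |
| `pae_max` | 15.0 Å | symmetrized PAE of the pair must be ≤ 15 |
| `pae_mode` | `pair` | `residue` filters on each residue's whole-chain mean PAE instead |
| `distance_bin_edges` | 0, 5, 7.5, 10, 12.5, 15 | nearest-counterpart histogram bins |

The PAE cutoff is phrased per-residue in parts of the literature, but PAE is
intrinsically pairwise; we filter the pair's symmetrized PAE by default and
expose the per-residue interpretation (row-mean PAE of each member) behind
`pae_mode="residue"`. The histogram bins step by 2.5 Å from 5 Å because the
5–7.5 Å stratum is where the Lys-proximity effect on Cys redox is reported to
concentrate; distances beyond the last edge, and significant sites with no
quality-passing counterpart at all, land in an overflow bin (the latter also
logged). Nearest-counterpart searches consider **all** quality-passing
counterpart residues, not only modified ones.

## Motif classification

Proximal pairs of one protein form a bipartite graph (Cys nodes, Lys nodes,
one edge per proximal pair). Its connected components are the motif units,
classified purely by residue counts: (1,1) → Cys₁:Lys₁, (>1,1) → Cysₓ:Lys₁,
(1,>1) → Cys₁:Lysₓ, (>1,>1) → Cysₓ:Lysₓ. Components were chosen over
per-residue ego networks because they make the four classes mutually
exclusive and exhaustive over the proximal-pair set — with overlapping
neighborhoods, any ego-centric convention counts some pairs in two motifs.
The ego view (per-residue proximal degree) remains available as an
informational report. Motif statistics are reported both over all components
and restricted to components containing at least one significantly modified
residue; the restricted view is the headline one.

## Crosstalk statistics

Both analyses are 2×2 Fisher's exact tests with the sample (cross-product)
odds ratio ad/bc:

* **Protein level** — the analyzed universe (all proteins with ≥ 1 quantified
  site in either dataset) is partitioned into both / acetyl-only / redox-only
  / neither by significant-site content; the 2×2 tests co-occurrence of the
  two modification types on the same protein. Different conditioning universes
  give different ORs; the universe used is always echoed in the report.
* **Pair level** — restricted to proximal pairs, rows split by significant
  redox Cys, columns by significant acetyl Lys, each proximal pair counted
  once.

The two-sided p sums hypergeometric probabilities (margins fixed) of all
tables no more probable than the observed one; ties are included to ~1e-7
relative tolerance for platform stability. With any zero cell the
Haldane–Anscombe corrected OR ((a+½)(d+½))/((b+½)(c+½)) is reported and
flagged. Conditional-MLE odds ratios and confidence intervals are out of
scope.

## Normalization cascade

Acetyl-peptide abundances are corrected in a fixed three-stage order, each
stage multiplicative:

1. **Retention-time standards** (run-to-run instrument variability):
   factor_s = mean over samples of the standard sum / standard sum of s,
   applied to every feature of s. The cross-sample-mean anchor only sets the
   absolute scale — any positive anchor cancels in downstream ratios — so the
   corrected table is invariant up to one global scalar under rescaling of
   any single sample's raw data.
2. **Acetyl-BSA** (sample-prep/IP variability): the same factor construction
   using the BSA peptide set, computed on the already standard-corrected
   table.
3. **GPQ** (protein loading): factor(p, s) = GPQ(p, reference)/GPQ(p, s) from
   a standard-corrected label-free protein table, applied per acetyl feature
   mapped to protein p. Features whose protein lacks GPQ in a sample are left
   unadjusted and logged; a zero GPQ against nonzero acetyl signal excludes
   the feature from statistics.

Differential testing is an unpaired two-sample t-test — pooled variance by
default, Welch behind a flag, since the generic "unpaired t-test" does not
specify — with Benjamini–Hochberg step-up correction (via statsmodels).
Missing abundances stay missing (no imputation); features with fewer than two
values in either group are skipped and logged; two zero-variance groups with
equal means get p = 1 by convention.

## Synthetic study conditions

The generator reproduces the statistical structure of the study inputs at
desk scale; its defaults are the fixed study conditions of the test suite and
acceptance script.

* **Geometry.** Cys/Lys residues sit on a jittered 3D lattice with 32 Å
  spacing (> 2× the proximity threshold), so non-planted pairs are never
  proximal; planted pairs place the Lys NZ at an axis-aligned offset from the
  Cys SG at the requested distance, with coordinates pre-rounded to the
  3-decimal mmCIF precision so the planted distance survives the file
  round-trip exactly. Each lysine is planted at most once; by default half of
  the lysines are planted at distances uniform on [4, 14.5] Å.
* **Composition.** 2.5 % Cys and 6.5 % Lys per chain — typical proteome
  composition; 80-residue chains by default, scaled up in end-to-end checks.
* **Confidence.** pLDDT mixes N(88, 6) clipped to [70, 100] with a 15 %
  low-confidence tail uniform on [40, 69.9], straddling the 70 cutoff; PAE
  rises with sequence separation from 4 Å near the diagonal to 18 Å at the
  far corner (σ = 1 noise), straddling the 15 Å cutoff. Both are rounded to
  the precision of the file formats at generation time so the cutoffs are
  applied to exactly the values the parsers see.
* **Crosstalk.** Each Cys is redox-modified with rate 0.5; a Lys with ≥ 1
  quality-passing proximal modified Cys is acetylated with probability p1
  where odds(p1) = OR·odds(p0), else with p0 = 0.3; the default planted
  OR is 1.9. Group sizes for abundance simulation are 5 + 5. Modified sites
  draw log2FC ~ sign·max(0.6, N(2.0, 0.6)) and p ~ U(0.0005, 0.045); null
  sites N(0, 0.2) and U(0.06, 0.95); a `label_noise` rate can flip the drawn
  statistics.
* **Quantitation.** Lognormal abundances with planted per-sample injection
  and prep scalars and per-(protein, sample) loading scalars constructed so
  the cascade removes them exactly (up to per-protein constants that cancel
  in group comparisons); 20 of 200 peptides carry a planted log2FC of 1.5.

Everything derives from one integer seed; runs are byte-reproducible.

What passing the synthetic benchmark shows: the geometry, filtering, graph,
normalization and exact-test code paths are correct against independent
oracles, and the pair-level OR estimator recovers a planted effect at
realistic scale. What it does not show: anything about real protein folds
(structures here are lattices, not folds), about search-engine or
quantitation artifacts upstream of the site tables, or about the biological
magnitude of crosstalk in real tissue — real AlphaFold models enter only
through the literature-anchored accession checks, which require the model
files.

## Numerical and degenerate-input conventions

* Distances are plain double-precision Euclidean norms; thresholds inclusive
  (≤ 15.0 Å proximity), pLDDT exclusion strict (< 70 excluded).
* mmCIF coordinates round-trip at 3 decimals, B-factors at 2; the synthetic
  generator pre-rounds to these grids.
* Empty Cys or Lys partitions, empty site tables and proteins with no
  counterpart residues are all legal inputs that flow through with logged,
  accounted exclusions; an empty *proximal pair set* makes the pair-level
  contingency a recorded degenerate-table error rather than an abort.
* Pipeline outputs are sorted on stable keys and written with fixed float
  formatting; reruns on identical inputs are byte-identical.
* Stage failures abort with the stage name and offending record; partial
  artifacts go to a quarantine directory.

## Problem sizes used in checks

Oracle-equivalence checks use 200 random 60-residue proteins (~1,600 pairs);
Fisher's exact is enumerated for 1,000 random tables with total ≤ 60; OR
recovery uses 50 seeds × 30,000 pairs; motif classification is checked on 500
random bipartite graphs of up to 40 nodes; end-to-end pipeline checks pool
five simulated 150-protein cohorts (~2,000 proximal pairs). These sizes give
sub-percent Monte-Carlo error on the recovery medians while keeping the whole
suite and the acceptance script in the seconds-to-a-minute range.

## Known limitations

* Monomers only; no inter-chain pairs, no proteoform assemblies.
* The sample OR, not the conditional-MLE OR; no interval estimates.
* Site stratification has no conflict rule for sites observed in opposite
  directions across peptides (the signed mean stands).
* The ortholog cross-reference is a plain offline table join; no sequence
  alignment or orthology inference is performed.
* PAE filtering interpretations (per-pair vs per-residue) can disagree near
  the cutoff; the default is per-pair and the alternative is a switch, but
  results near the boundary depend on the choice.
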