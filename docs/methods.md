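# Methods

This note documents the models, defaults and numerical choices behind
`toxbarcode`, and what the synthetic world does and does not establish.

## The synthetic world (`syndata`)

The generator produces a self-consistent venom-gland dataset with known
("planted") regulatory truth. It is a stated world, not a fit to data: its
defaults are fixed once and all recovery tests are scored against it.

**Gene family.** `n_genes` (default 24; recovery studies use 80) toxin
paralogs in `n_groups` (default 2) functional groups — neurotoxin-like "A"
and cytotoxin-like "B". Each group is a clean clade: one pure-birth (Yule,
rate 1.0) ultrametric subtree per group, joined at the root by stems
(length 1.0 plus whatever keeps the tree ultrametric). Making groups exact
clades is a deliberate simplification of the real paralog tree; it gives
every downstream group-contrast test an unambiguous truth.

**Sequences.** One tree underlies both promoter (500 bp) and CDS (420 nt =
140-aa precursor) evolution. Substitution is Jukes–Cantor-style: Poisson
(rate × branch length × sites) events, uniform site, uniform different
base. Default rates are 0.1 substitutions/site/unit for both regions —
equal rates make the expected promoter and peptide distance matrices
proportional. At much lower divergence (e.g. 0.05/site with a 210-nt CDS)
the patristic promoter–peptide correlation drops to ≈0.4 purely from
estimation noise on short sequences, which is why these defaults were
chosen.

**Barcodes.** Each TF gets a random strongly-informative motif (length
8–12, consensus count 91/100 per column) and one non-overlapping promoter
slot, inherited down the tree. Shared TFs (4) are present at the root;
group TFs (6 for A, 3 for B, echoing the richer neurotoxin repertoire) can
be gained only on branches inside their group's clade (gain 0.9/branch) and
any present motif can be lost (0.05/branch). At the leaves the consensus of
every present TF is stamped into its slot, so the planted truth is
scanner-detectable by construction; a lost motif simply leaves drifted
background. `TruthRegulome` records the planted (gene, TF) pairs, offsets
and groups.

**Genome layout.** Leaves are laid out in depth-first tree order, in tandem
with 1 kb intergenic gaps, across `n_scaffolds` (default 2) scaffolds with
random cut points — so physical distance correlates with phylogenetic
distance, scaffold breaks need not align with groups, and cross-scaffold
pairs exist (they are "not measured" downstream). TF genes sit on a filler
scaffold; only their identity matters.

**Cells.** Populations default to secretory-A (30%), secretory-B (20%) and
non-secretory (50%); both secretory types carry the epithelial markers
LAMA3/EPCAM. Latent TF activity per cell = population base level ×
log-normal noise (σ = 0.5, mean 1). A toxin's relative level is the
weighted mean of its planted TFs' activities plus a leak (0.02), with
group-specific TFs weighted 3:1 over shared TFs — the calibration that
makes within-group toxin correlation ≈0.5: recoverable but not trivial.
TF transcripts are 0.5 × (activity + leak); markers 2.0 in their
populations; 200 background genes at 0.05. Per-cell depth is log-normal
(mean 5000, σ_log 0.3); counts are negative-binomial with dispersion 0.3
(variance μ + 0.3μ²). `expected_mean_count` exposes the closed-form mean
used as the test oracle.

**Sections.** A 40×60 grid with an elliptical gland mask. Each toxin's
image is a Gaussian profile along the anterior–posterior axis centred at
its group position (A: 0.2, B: 0.8; sd 0.15) plus pixel noise (sd 0.05),
clipped at zero and zeroed outside the mask. Within a group, noise is the
only difference between toxin images.

**Determinism.** All randomness flows from one seed through named
substreams (CRC-keyed `SeedSequence` spawn keys), so adding a component
never perturbs another's draws, and identical parameters reproduce
byte-identical fixtures.

**What a green test does not establish.** The world has no doublets,
ambient RNA, batch effects, isoform structure, chromatin state, alignment
gaps (alignments are identity by construction), unbalanced clades, or
motif degeneracy beyond the PFM's 91/3 columns; real-data performance on
those axes is untested.

## Expression

- QC keeps cells with ≥ 1000 total counts **and** ≥ 100 distinct genes
  (inclusive thresholds); the filter is idempotent.
- TMM follows the edgeR definition exactly — reference column by
  75th-percentile rule, two-sided 30% trim on M and 5% on A, inverse-
  variance-weighted mean of retained M, factors rescaled to geometric mean
  1 — and matches `edgeR::calcNormFactors` to 1e-7 on a frozen fixture.
- The divergence statistic is the signed orthogonal residual from a
  total-least-squares line (first principal axis) fitted through the
  non-toxin (clr bulk, clr pseudo-bulk) points. The interval is two-sided:
  percentiles [(100−p)/2, 100−(100−p)/2] of non-toxin residuals, p = 99 by
  default. Zeros are lifted by half the smallest nonzero value before clr.
- Clustering is log1p-CPM → PCA (30 components) → kNN (k = 20) → Leiden
  modularity at resolution 1.0 with a derived seed; labels are ordered by
  community size. Identical cells short-circuit to one community.
- Toxin-cell calls are cluster-level: mean toxin count fraction ≥ 0.2 and
  marker detection rate ≥ 0.5 (defaults chosen for the synthetic world;
  tune for real data).
- Spearman co-expression uses average ranks on log1p-CPM; constancy is
  judged with a relative tolerance (1e-10) because CPM introduces
  float-eps jitter.

## Co-expression modules (`coexpr`)

Unsigned adjacency |cor|^β by default (signed ((1+cor)/2)^β behind a flag).
The soft power is the smallest β whose scale-free fit R² ≥ 0.8, where the
fit regresses log₁₀ p(k) on log₁₀ k over **10 equal-width bins** of
connectivity (empty bins dropped, R² reported as 0 for positive slopes).
Equal-width binning is the standard choice; equal-occupancy bins would make
p(k) constant by construction and the index meaningless. TOM is the usual
(Σ a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij); modules come from average
linkage on 1−TOM cut at height 0.99 with a ≥ 30 size floor, then iterative
eigengene merging below dissimilarity 0.2 (the conventional reading of a
"correlation threshold of 0.2": merge when eigengene correlation > 0.8).
Eigengenes are first principal components of standardized module
expression, sign-oriented to the module mean and scaled to unit variance.

A modelling caveat the tests make explicit: with two **anti-correlated**
planted groups (as arises in toxin cells, where expressing one group's
toxins suppresses the other's CPM share), unsigned TOM folds the groups
into one module — a known property of unsigned networks, not a bug. The
synthetic module-recovery test therefore runs the signed variant; the
planted-block tests (uncorrelated blocks) run the unsigned default.

## Regulatory network (`regnet`)

Promoters are the 500 bp upstream of the TSS (1-based inclusive; minus
strand takes the reverse complement of [tss+1, tss+500]; scaffold edges
clamp with a warning). PWM entries are
log₂((count + pseudocount·bg)/(column total + pseudocount)/bg) with
pseudocount 1.0 distributed by a uniform background; N scores 0. A window
is a hit at ≥ score_fraction × maximum attainable score, default 0.85
(deficit 0.15, the scanning tool's documented default; the effective
threshold of the original analysis is unreported). Overlapping hits all
count. Candidates require membership in the module TF set **and** ≥ 1 site
in the toxin's promoter.

Importances are per-target random forests (default 1000 trees, √#TFs
features per split, derived per-target seeds); sklearn's impurity
importances are exactly the normalized total variance reduction, summing to
1 whenever any split occurs. The pipeline fits them on **all** QC-passing
cells: in the synthetic world the toxin-cell subset leaves the secretory
A-vs-B contrast as the dominant signal, making opposite-group TFs strong
(anti-correlated) predictors; the non-secretory cells anchor the shared-TF
signal and recover planted-pair AUROC ≈ 0.9.

## Evolutionary distances (`evodist`)

p-distance with pairwise gap deletion; JC69 d = −¾ ln(1 − 4p/3), undefined
(missing, with warning) at p ≥ ¾. Neighbor joining uses the Q criterion
with deterministic tie-breaking by the lexicographically smallest label
pair (internal nodes carry their smallest descendant leaf label); negative
branch lengths clamp to 0 with a warning; additive matrices are recovered
exactly and patristic(NJ(D)) = D. The NJ tree is a deterministic stand-in
for the original likelihood trees — patristic correlation, not topology
inference, is the analysis-critical quantity — and externally supplied
Newick trees can be fed straight to `patristic`.

## Spatial (`spatial`)

Co-occurrence is Pearson correlation over masked pixels (cosine similarity
behind a flag; optional per-pixel TIC normalization). The underlying
commercial-software statistic is unspecified in the source analysis, so
sign structure rather than magnitude is treated as reproducible. Centroids
are intensity-weighted means of the normalized axis coordinate (anterior 0,
posterior 1); group location differences use one-way ANOVA (F = t² for two
groups).

## Integration (`integrate`)

Jaccard over barcode sets (empty-vs-empty pairs missing); genomic distance
between gene midpoints within a scaffold only; matrix correlation by
Pearson over complete upper-triangle pairs (pairwise deletion, n reported).
Because pairwise entries are not independent, a Mantel permutation p
(joint row/column permutation, p = (1+hits)/(1+perms)) is available; it is
off by default to mirror the parametric analysis. The GRN keeps all
candidate edges (no importance cutoff — none is reported upstream), with
protein links only between candidate TFs; betweenness is unnormalized
Brandes counting with directed regulation edges and bidirectional protein
links.

## Pipeline

`run_pipeline` executes expression → coexpr → regnet → evodist → spatial →
integrate from a fixture directory, writes every table as TSV plus a JSON
report (config echo, summary statistics, step timings), rejects unknown
config keys, and is bit-reproducible given (config, seed). Steps are
individually skippable; partial runs compose to the one-shot result.

## Known limitations

- The synthetic world's group-clade structure and stamped consensus motifs
  make barcode recall near-ceiling; real promoters with degenerate sites
  will be harder.
- Unsigned module detection cannot split anti-correlated programs (above).
- JC69/p distances ignore rate heterogeneity and alignment uncertainty.
- The divergence test assumes one pseudo-bulk vs one bulk library; no
  replicate-aware variance model.
- Betweenness on the default GRN (no protein links) is identically zero;
  it becomes informative only with TF–TF links.
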