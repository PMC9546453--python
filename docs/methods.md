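# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the design choices made where the procedure was
genuinely open, and what the synthetic data can and cannot demonstrate.

## Homology search and the internal aligner

The pipeline's homology semantics are those of a BLASTP tabular workflow:
above-threshold hits (E ≤ `max_evalue`, identity ≥ `min_identity_pct`),
best hits by bitscore, and reciprocal best hits (RBH) as the orthology
proxy. Two interchangeable backends satisfy the same contract: ingestion
of a precomputed 12-column hit table, or the internal aligner.

The internal aligner is an affine-gap Smith–Waterman (Gotoh) over BLOSUM62
with NCBI-style gap costs (open 11, extend 1; a gap of length L costs
11 + L). Scores are integers, so ties are exact; the traceback is
deterministic (optimal cell with smallest row-major index; diagonal
preferred over gap-in-subject over gap-in-query), making the whole search
reproducible bit-for-bit. Identity % is identical columns over all columns
of the local alignment (gap columns count in the denominator; a local
alignment has no end gaps). The e-value is Karlin–Altschul-style:
bit = (λS − ln K)/ln 2 with the standard gapped BLOSUM62 constants
λ = 0.267, K = 0.041, and E = m·n·2^(−bit) over a declared effective
search space m·n = (summed query lengths) × (summed subject lengths),
fixed once per search. The point of this construction is not to reproduce
NCBI numbers exactly but to give desk-scale tests a deterministic scorer
with the same thresholding semantics; its raw scores are verified exactly
against an independent exhaustive dynamic-programming implementation in
the test suite.

Isoforms are not collapsed: every sequence record is treated
independently. A configurable gene-id prefix-strip rule (off by default)
reconciles mixed id forms.

## Consensus targeting

Predictor labels are inputs; the predictors are never run. Consensus:
plastid iff ASAFind or HECTAR says plastid; mitochondrial iff HECTAR says
mitochondrion or the MitoFates presequence probability ≥ `mitofates_cut`
(0.35); both together mark dual targeting. WolfPSort is only a fallback
label when the three primary tools are silent. Transporter selection
requires a transport-associated functional term (configurable term list)
AND a consensus plastid call.

## Composite evidence score

Seven independent indicators per (transporter, gene) pair, each worth +1;
correlations count only when strictly greater than `corr_threshold` (0.5),
and undefined correlations (gene missing, < 3 shared observations, zero
variance) count 0. Association requires a total ≥ `assoc_min_score` (3,
inclusive). Pathway linkage requires ≥ `pathway_min_genes` associated
genes (default 4 — the strict reading of "more than three"; set 3 to get
the inclusive alternative). Loss-pattern agreement is set equality by
default (`loss_match_mode="subset"` relaxes it). The cross-species
condition uses the RBH-mapped homologue's expression; transporters without
a mapped homologue score 0 on that condition. The plastid-targeting
condition is evaluated on the candidate gene, not the transporter — every
query transporter is plastid-targeted by selection, so the condition only
discriminates on that side. Module co-membership accepts any shared label;
correlations are computed across all condition values rather than
per-condition means unless grouping is configured.

## Organelle co-regulation

Pearson correlations between each transporter and a panel of
mitochondria-encoded genes are computed across condition-group values — by
default the per-group means of the expression matrix (emulating 17
light:dark acclimation processing groups), switchable to per-array values
(`group_reduce="none"`). Pairwise-complete observations only; pairs with
fewer than 3 shared points or zero variance are excluded from the means
and `n_mito_genes_used` reports how many contributed, so a silent NaN can
never poison a mean. Crosstalk candidates must exceed `crosstalk_cut`
(±0.5) on both the biogenesis and the respiratory axis.

## Taxonomic conservation

Presence profiles count species (not hits) per taxonomic group; the
grouped taxonomy is data, not code (species → group → lineage class, with
lineage classes diatom / other ochrophyte / aplastidic stramenopile /
other secondary red). The uniqueness rule is exactly: count > 1 in every
diatom group, total non-diatom species < 4, and no single non-diatom group
above 2. Aplastidic groups count toward the non-diatom total — they are
non-diatom categories. Group tallies count transporters with ≥ 2 species
in the group.

## Environmental meta-omics

Meta-gene filtering is a two-stage best-hit intersection: the best hit
among labelled cultured references must be diatom plastid-targeted, and
the best hit in the query proteome must be the queried gene itself. The
clade stage builds a neighbour-joining guide tree (scikit-bio) from
1 − fractional-identity distances on pairwise local alignments; sequences
covering < 50 % of the query are dropped first (emulating manual removal
of poorly aligned sequences), as are sequences with undefined distances
(worst offender first). Because an NJ tree is unrooted, the "diatom
plastid clade" is defined by bipartitions: the smallest edge-side
containing every diatom plastid reference and no other cultured reference.
If no such side exists the filter-stage set is kept, with a warning —
extraction never adds a meta-gene the filter did not retain.

Per station, retained meta-gene MetaT and MetaG abundances are summed;
stations without records are omitted, never zero-filled, and a family may
lack MetaG entirely. For each family × parameter × combo, r_T and r_G are
Pearson correlations over pairwise-complete stations (< 3 stations →
undefined, not significant). The tested statistic is r_T, with two-tailed
p from t = r√((n−2)/(1−r²)), df = n−2; the printed sign rule is
implemented as positive iff r_T² > r_G² (ties take the sign of r_T;
families without MetaG take the sign of r_T). An alternative mode
(`env_stat_mode="difference"`) instead correlates the per-station
difference sum_T − sum_G and signs by that correlation; the default was
chosen because the R²-comparison sign rule is only meaningful when two
correlations are compared. No multiple-testing correction is applied per
combo — the aggregation rule across combos (≥ `env_min_combos` = 3 of the
ten depth × size combinations) is itself the robustness device; a
Benjamini–Hochberg option exists in principle through the configurable
alpha but is deliberately not the default. The combo list follows the
procedural ten (including the < 0.8 µm fraction). The merged
primary-production panel is ten covariates (six accessory pigments, net
primary production, particulate inorganic/organic carbon, total carbon);
the family flag requires ≥ `pp_min_params` = 8 of them strong in the same
direction (set `pp_same_direction: false` to count directions jointly).

## Synthetic data: what it emulates, what it does not

Generators derive independent streams from one root seed
(`SeedSequence(seed, spawn_key=(stream,))`, streams 0–4), so outputs are
byte-identical under a fixed seed and adding a generator never perturbs
another.

* **Proteomes** — planted orthologs are point-mutated copies of a common
  ancestor with mutations spread evenly (so local alignments measure near
  the target identity); decoys are random-composition sequences. Default
  length 80 aa: long enough that the weakest default ortholog (40–50 %
  identity) still clears the e-value threshold at desk-scale search
  spaces. No indels, domain structure, or compositional bias.
* **Expression** — block-correlated condition profiles: block members
  share a latent factor with loading ℓ and independent noise
  (default sd √(1−ℓ²), planted pairwise r = ℓ²). When the latent count
  permits, latents are orthogonalized, making the zero-noise regime free
  of chance correlation — recovery there is exact by construction. Real
  expression data has heavier tails, batch structure and missingness the
  generator does not model.
* **Presence profiles** — planted uniques satisfy the uniqueness rule by
  construction; backgrounds that accidentally satisfy it are perturbed; a
  forced profile contradicting the planted truth is refused.
* **Environment** — station covariates drawn over realistic ranges
  (temperature −2…31 °C, pH 7.9…8.3, pigments mg/m³, …); the ten
  primary-production covariates share a latent productivity factor
  (loading 0.9). A planted effect couples a family's MetaT station sums to
  a parameter (or to the productivity latent) at the stated r; MetaG
  couples weakly (0.3×) for a positive planted sign or more tightly
  (1.2×, capped at 0.99) for a negative one. Abundances are affine-shifted
  positive, which leaves Pearson r untouched. Real survey abundances are
  zero-inflated and log-skewed; only rank/positivity realism is attempted.
* **Meta pools** — diatom references are light mutations of the query;
  outgroup references descend from their own common ancestor (so they form
  a coherent sister clade, as real homologues would); in-clade and
  out-of-clade meta-genes descend from the respective references.

Consequently, passing tests demonstrate correctness of the rules,
statistics and plumbing under the planted statistical structure — not
performance on real proteomes, arrays or survey data.

## Numerical choices and calibration

TSV floats carry 6 significant digits; all iteration orders are sorted;
reports serialize with sorted keys — the bundled atlas run is
byte-identical across reruns. Empirically the per-combo null significance
rate sits slightly above nominal (≈ 0.055–0.06 at α = 0.05 over 2000
draws): the correlation t-test assumes bivariate normality while the
simulated covariates are uniform, and the five size fractions of a depth
share covariate draws. This small liberality is inherent to the raw
per-combo test; the ≥ 3-combo aggregation absorbs it.

## Problem sizes

The bundled atlas bundle is ~1/10 study scale — 7 transporters with 15
candidate genes and 10 decoys per proteome, an 8-gene mitochondrial panel,
17 condition groups, 2 diatom + 2 non-diatom taxonomic groups of 4 species,
30 stations × 10 depth × size combinations, and a 13-sequence homologue
pool — chosen so a complete run takes seconds while every rule operates at
its designed thresholds. Monte-Carlo checks use 200 seeds (recovery rates)
and 2000 draws (calibration).

## Known limitations

* The internal e-value is a calibrated surrogate, not an NCBI
  reproduction; absolute e-values differ from BLAST output although the
  thresholding behaviour matches.
* Cross-species condition (iv) requires a third-species expression matrix
  and RBH map; when absent it scores 0 for all pairs (the bundled fixture
  omits it, mirroring the absence of such microarray data in practice).
* NJ clade extraction depends on distance quality; highly diverged pools
  with < 50 % query coverage fall back to the filter-stage set rather than
  guessing.
* WGCNA modules, origin/loss annotations and pathway assignments are
  consumed as inputs; the package never infers them.
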