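# Methods

This note documents the statistical models behind each pipeline stage, the
design of the synthetic-data generator, the parameter choices that matter,
and what the validation studies do and do not demonstrate.

## Statistical kernel

All statistics are computed from their explicit formulas; scipy supplies
only distribution tail probabilities (Student t, χ², binomial).

* **Two-group test.** Welch's unequal-variance t with Welch–Satterthwaite
  degrees of freedom, two-sided. The pooled-variance variant is available
  (`equal_var=True`) because the historical array-tool implementations of
  "univariate t" are ambiguous on this point; Welch is the default as the
  robust modern choice. Taxa are tested on log2(relative abundance + pc)
  with pc = half the smallest nonzero relative abundance in the table
  (configurable); testing raw proportions is a switch. The same test is
  the declared stand-in for expression differences (log2-scale values) —
  downstream stages consume only directions, fold changes and p values,
  so a negative-binomial count model would change nothing structural.
* **FDR.** Benjamini–Hochberg step-up, the standard choice where a method
  is not otherwise specified. q ≥ p elementwise, permutation-equivariant.
* **Correlation.** Pearson r with the two-sided p from the t transform
  t = r·√((n−2)/(1−r²)); Spearman is Pearson on tie-averaged ranks.
  Spearman is the default for taxa–phenotype screening (robust to the
  skewed abundance scale), Pearson for gene expression (log-scale,
  approximately elliptical).
* **Fisher combination.** χ² = −2·Σᵢ ln Pᵢ referred to χ²(2k). Exact
  zeros are clamped to 1e−300 (with a warning) to keep the logarithm
  finite; k = 1 reduces to the identity. The per-group-then-combine
  design treats the k sample groups as independent evidence about a
  shared correlation structure while letting each group have its own
  baseline — the reason the network survives strain-to-strain expression
  offsets.
* **One-proportion test.** Exact binomial. The two-sided p sums all
  outcome probabilities not exceeding that of the observed count (the
  "minlike" convention); normal approximation is deliberately not used,
  as the cohort application (69 of 69 negatives) sits in the extreme
  tail.
* **Ranks.** Ascending, ties averaged, so each rank column sums to
  n(n+1)/2 exactly — the invariant the rank-sum score depends on.

## Edge criteria and network

A gene pair becomes an edge only when all four hold: per-group p < 0.3 in
every group; Fisher-combined p < 0.01; one strict correlation sign across
all groups; and sign(r) = sign(lfc_a)·sign(lfc_b). The last rule encodes
that co-regulated genes (fold changes in the same direction under the
perturbation) should correlate positively and oppositely regulated genes
negatively; a gene with zero fold change admits no edges. The permissive
per-group threshold (0.3) acknowledges the small group sizes (7–10
samples); the combined threshold (0.01) does the real filtering. The
pairwise BH q over combined p values is computed and reported but is not
an inclusion criterion. Genes with no admissible edge are not network
members; the membership fraction is reported, never asserted, because it
depends on effect sizes and group sizes. Distances are unweighted hop
counts (no edge weights are defined); a node's average shortest path
length is taken over its connected component only, and isolated nodes
have no defined path length (they are excluded upstream by the
membership rule).

## Mediator screen

Correlations are computed strictly within the factor-deficient group —
the screen refuses metadata containing the control label — because a
direct effect of the factor on both microbe and phenotype would otherwise
manufacture correlation. Since the perturbed group is the factor-free
condition in both emulated designs, a feature more abundant in the
perturbed group is *depleted by* the factor; the classification rule then
requires sign agreement between regulation and phenotype correlation in
every phenotype (both fasting glucose and AUC-GTT by default; any-of is a
switch), each at p < α = 0.05, two-sided. Mixed correlation signs never
classify. Candidates are ordered by the minimum p across phenotypes with
a lexicographic feature-id tiebreak; the screen's output order is
deterministic.

Missing phenotype values are excluded pairwise and the effective n is
recorded per correlation; pairs with fewer than three complete
observations, or a constant vector, are flagged untestable rather than
raising.

## Rank-sum regulator score

All four sources are ranked ascending ("smallest to largest") and the
*largest* total wins: longer path lengths (peripheral placement), larger
|correlation|, larger |log10 fold change| and a positive sign-consistency
source all push a gene up. The signed source s4 = ±s1 rewards genes whose
per-group correlation signs agree (s4 = +s1 ranks above s4 = −s1 at equal
magnitude); exactly-zero correlations are treated as sign-inconsistent.
Ties in the total score break lexicographically by gene id, making the
full ordering deterministic. The inhibitor/enhancer label reports the
shared correlation sign but never changes the score. Only network members
are ranked (peripherality is undefined otherwise); excluded genes are
reported with a warning.

## Synthetic-data generator

The generator is the package's reference experiment: its defaults define
the study conditions under which the recovery claims are tested.

**Microbiome.** Counts follow a logistic-normal–multinomial model:
per-sample log abundances are log(baseline · fold multiplier) plus
taxon-specific Gaussian noise, closed to proportions by softmax, then
multinomially sampled at a fixed library size. The logistic-normal (rather
than Dirichlet) choice is deliberate: it allows taxon-specific dispersion,
which the planted structure needs, whereas a single Dirichlet
concentration forces one dispersion on the whole community.

Defaults (chosen once, by a design-phase power calibration at 40–100
pilot seeds, before the validation thresholds were ever evaluated):

| parameter | default | meaning |
|---|---|---|
| n_taxa | 200 | community size |
| n_samples_per_group | 10 | mice per group per experiment |
| n_regulated_taxa | 20 | planted responders (10% of community) |
| regulation_fold | 5 | baseline multiplier in the perturbed group |
| mediator_baseline | 0.10 | mediator's baseline proportion |
| taxon/mediator dispersion | 0.7 | log-scale biological SD |
| library_size | 50 000 | reads per sample |
| β0, β1, σ | 100, −50, 5 | glucose model (mg/dl; per unit proportion) |
| auc_scale | 300 | AUC-GTT is the same model on its own scale |

The mediator emulates an abundant mucin-degrader that blooms when the
factor is removed (≈10% → ≈25–30% of the community); its proportion
causally sets both phenotypes for every perturbed-group sample
(phenotype = β0 + β1·proportion + N(0, σ)), and control samples carry no
phenotype, matching the within-knockout correlation design. Phenotype
correlations pool the perturbed groups of both experiments (n = 20), the
desk-scale analogue of the n = 50 within-knockout design. A 10%
community share for the mediator is what gives the proportion enough
absolute spread for β1·sd(proportion) to rival σ; a rare taxon with the
same fold change would be recovered as concordant but not as a
correlated mediator.

**Expression.** Four strain groups with (8, 7, 9, 10) samples. Genes are
organised in five modules (30, 30, 25, 25, 20; 70 background noise
genes); module genes load 0.9 on a per-group latent factor, giving
within-module correlations ≈ 0.8 with signs consistent across groups.
Module fold changes share the module's sign (|log10 FC| ~ U(0.3, 0.9)),
so planted edges satisfy the fold-change rule; background genes hover
near zero fold change. The planted regulator belongs to exactly one
module with a deliberately weaker loading (0.82 → pairwise r ≈ 0.74),
placing it reliably inside the network but at its periphery, and carries
the largest |log10 FC| (1.2). The microbe is generated causally
*downstream* of the regulator — log microbe abundance mixes the
standardized regulator expression at target correlation −0.8 with
independent noise — which is both the biological story of an inhibitor
gene and the construction that decouples coupling strength from network
placement. (An earlier construction that coupled the regulator to an
exogenous microbe vector forced a trade-off between peripherality and
membership and was abandoned during design.)

**Randomness.** One RNG stream per logical component (taxa, phenotype,
expression), each keyed by (master seed, CRC32 of the component name), so
streams never interleave and outputs are byte-identical across reruns of
the same configuration. Ground truth is emitted as a separate artifact;
nothing in the data tables identifies planted features.

**What the generator does not emulate.** Phylogenetic correlation among
taxa, sequencing-error and chimera processes, batch effects, zero
inflation beyond what the compositional model produces, nonlinear
phenotype responses, and gene-regulatory directionality beyond the single
planted arrow. Recovery results on this generator therefore demonstrate
that the inference chain is implemented correctly and calibrated under
its own assumptions — not that those assumptions hold in any particular
real dataset.

## Validation studies and their problem sizes

The acceptance studies run at sizes chosen to finish in minutes on one
core while keeping Monte-Carlo error a few percent: 100 replicates for
each recovery and null study, 200 taxa / 200 genes per replicate, 40-gene
noise signatures (78 000 pairs total) for the edge calibration. The
deterministic test-suite uses seeds 0–99. Measured there: planted
mediator nominated top candidate-improver in 94/100; planted regulator
rank 1 in 87/100 and top-3 in 99/100; zero concordant features under the
global null; noise-pair admissible-edge rate ≈ 0.006%. Rerunning with
fresh seeds (as `scripts/acceptance.py` does from its `--seed`) moves
these rates by a few points (e.g. 86–94% mediator recovery); the long-run
rates sit close to the claimed bounds, which is a known sensitivity of
the chosen study conditions rather than a property of the inference code.

## Numerical conventions and degenerate inputs

Correlations are clipped to [−1, 1] before the t transform; |r| = 1 maps
to p = 0. Constant vectors raise a degenerate-input error in the kernel
and are converted to untestable flags by the screening layers. BH is
applied over testable features only. Float serialization uses 17
significant digits for matrices (lossless round trip) and 10 for derived
record tables. All orderings (candidates, ranks, edges) carry explicit
deterministic tiebreaks.
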