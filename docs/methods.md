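# Methods

This note records the model as implemented, the defaults and why they were
chosen, the numerical conventions, and what the synthetic generators do and
do not emulate.

## Cluster geometry and statistics

A cluster is an ordered gene list (anterior, 3', first) with strictly
positive intergenic distances d(i,i+1) in Kbp.  Gene lengths default to 0:
the model works purely with intergenic distances, and a nonzero length only
contributes to the cluster span.  Descriptive statistics use the
**population variance** (divisor n): that convention reproduces the
reference variances of all three packaged clusters (43.686 / 731.444 /
1698.025 Kbp²; the compact-cluster value recomputes to 43.6875, a rounding
artifact of the printed table, hence the package-wide ±0.01 tolerance on
printed statistics).

The "modified amphioxus" fixture is stored exactly as tabulated: it keeps
gene 14 and the 13→14 distance of 62 Kbp even though the mouse HoxD
cluster has no paralog 14.  Fidelity to the tabulated column was preferred
over the verbal definition ("only the paralogs present in mouse"); the
restriction operator `restrict_to_genes` reproduces the column exactly from
the full amphioxus cluster, summing spanned stretches (4→8 = 63+11+42+21 =
137) and conserving the outer span.

BED input uses standard 0-based half-open intervals on a single strand;
distances are start-to-start between successive intervals.  This choice is
simple, documented and reversible (writing and re-reading round-trips).

## Noise experiment

Each distance d(i,i+1) is the functioning time (in proportional units) of
gene i; the Factor of Phenotypic Realization f(i,i+1) = l/d(i,i+1) converts
it into a segment of ideal length l (default l = 100, arbitrary phenotypic
units).  Mean-zero Gaussian innovations perturb the FPRs; the realized
lengths l' = f'·d are pooled over all R·n values (R realizations × n
segments) and summarized by their mean and population variance.  Pooling
over all values, rather than averaging per-realization statistics, makes
the closed forms exact.

Four noise families are implemented (defaults: additive-mean-relative,
level ε = 0.05, R = 250):

| family                 | perturbation                       | pooled variance        |
|------------------------|------------------------------------|------------------------|
| additive-mean-relative | f' = f + η, sd(η) = ε·mean(f)      | (ε·mean f)²·mean(d²)   |
| additive-absolute      | f' = f + η, sd(η) = ε              | ε²·mean(d²)            |
| multiplicative         | f' = f·(1+η), sd(η) = ε            | ε²·l²                  |
| brownian               | l' = l + η, sd(η) = ε·√d           | ε²·mean(d)             |

The brownian family models noise accumulating over functioning time.  The
"5 % noise" phrasing common in this setting is ambiguous (standard
deviation or variance, relative to what); all four readings are selectable
and the package does **not** promise any particular absolute variance.
What it does guarantee — and what the acceptance checks assert — is:

* zero noise reproduces the ideal body plan exactly;
* the pooled mean is unbiased (within 3 SE of l);
* Monte-Carlo pooled variance converges to the closed form (within 3 SE at
  R = 10 000);
* under the same white noise the variance ordering follows the geometry:
  compact < loose < loose-with-merged-gaps, robust over random seeds.

**Cross-organism comparisons use one common noise amplitude** (ε times the
pooled mean FPR over all compared clusters) so that every geometry is
perturbed by the *same* white noise.  Scaling the noise to each cluster's
own mean FPR would renormalize away part of the geometric effect (and can
even invert the ordering between the two loose geometries), which would
defeat the purpose of the comparison.  When a single profile is perturbed
on its own, the per-profile mean is used.  Each cluster receives an
independent substream keyed by its organism name (CRC32), making the
comparison order-independent and reproducible.

Negative perturbed lengths are retained with a logged warning, not clipped:
at ε ≈ 0.05 they are rare (they occur only on segments whose distance is
large relative to the mean) and clipping would bias the variance.

## Force model

* **Morphogen**: M(x) = M0·exp(−(axis_length−x)/λ), peak at the posterior
  end.  Only monotonicity matters for any conclusion; the exponential is
  the minimal standard choice.  Defaults: axis_length 100 (arbitrary embryo
  units), λ = 30, M0 = 1.
* **Thresholds**: S_k = {x : M(x) ≥ T_k} gives nested domains sharing the
  posterior end.  The schedule describes the macroscopic picture; the force
  pathway below generates expression domains itself, which is why
  `simulate_expression` accepts but does not consume a schedule.
* **Force**: F = P·N with P(x,t) = α·M(x)·t (P-molecule production starts
  and continues; linear accumulation is the simplest monotone choice, and
  saturation is deliberately omitted as an early-stage model).  N =
  κ_N·span, the charge being distributed over the whole cluster, so
  deletions reduce it proportionally.  Defaults α = 60, κ_N = 0.01: with
  uniform stiffness 1 these make a posterior cell extrude the full 94-Kbp
  compact cluster within the default time horizon t_max = 2 while an
  anterior cell extrudes only the first gene — the regime the model
  describes.
* **Extrusion**: quasi-static work balance E = max{e : ∫₀^e s(u)du ≤
  F_eff} against a stepwise stiffness profile s(u) > 0.  Beyond the
  declared profile the last stiffness extends indefinitely (the fiber
  continues into the anchor region); extrusion is therefore defined for any
  force, and a probe can overshoot the fiber interval described by the
  profile.  Removing the 5' anchor (posterior split) divides the resistance:
  F_eff = F/ρ with 0 < ρ < 1 (default 0.5), so a loose-ended cluster never
  extrudes less at the same force.
* **Activation**: triangular kernel I(δ) = I0·max(0, 1−|δ−δ_TF|/w) for
  δ = E−L_g ≥ 0, zero for genes still inside the CT (δ < 0).  Defaults
  δ_TF = 0 (factory at the CT/ICD border), w = 130 Kbp, I0 = 1.  Putting the
  peak at the border makes intensity strictly decreasing with distance past
  the factory, which yields quantitative collinearity structurally: the most
  recently extruded (most posterior active) gene is always strongest.  At
  t = 0 no P-molecules exist, the cluster is in its ground state, and all
  genes are silent regardless of kernel geometry.

### Collinearity regression

`collinearity_report` checks, on an (x, t) grid (defaults 101 × 201 over
[0, 100] × [0, 2]):

1. **spatial** — cumulative expression domains (expression persists once
   triggered, as in the embryo) have anterior boundaries that move
   posteriorly with gene rank, never-expressed genes forming a posterior
   suffix;
2. **temporal** — first-activation times at the posterior end are
   nondecreasing in rank;
3. **quantitative** — at every grid point with ≥ 2 simultaneously active
   genes, the most posterior active gene has the highest intensity.

Ties at grid resolution count as passes; witnesses (coordinates and
intensities) are reported for every failure.  The wild-type compact cluster
passes all three for the defaults and for random ×/÷2 perturbations of λ,
α and stiffness — the grid steps were chosen fine enough that activation
and boundary orderings stay resolved across that range.

## Mutant engine

Deletions remove the region's Kbp and merge flanking distances; charge
follows the new span.  The named intergenic region "i" (between genes 4
and 8) is modeled as the stretch immediately anterior to gene 8, default
length 10 Kbp (its true extent is not in the packaged tables;
configurable).  Tandem duplications insert the copy adjacent to the
original with a zero-length junction, so duplicating a region and deleting
the copy restores the original exactly; wild-type validation (positive
distances, strictly increasing paralog numbers) is relaxed for manipulation
products.

**Anterior deletions** compare the mutant extrusion E with L−D.  The
wild-type force is calibrated as the work needed to extrude the fiber to
the probe on the wild-type profile; the mutant force is that work scaled by
the charge ratio (span−D)/span; E is what that force achieves on the
post-deletion profile.  Case 1 (unchanged) holds when |E−(L−D)| ≤ η·L with
η = 0.05 — equality is treated as an observable equivalence, not an exact
identity, and the boundary is assigned to case 1.  Case 2 (E above the
band) is anteriorization; when the overshoot exceeds a second threshold
(gain_eta = 0.10, i.e. the probe sits well inside the ICD and its retreat
to the border yields a marked intensity rise under the border-peaked
kernel) the verdict is ANTERIORIZED_WITH_GAIN.  Case 3 (E below the band)
is SILENCED: the probe stays inside the CT; for a probe that is not the
most posterior gene the rationale notes that a compensating
posteriorization could in principle relocate it.  The partition is
exhaustive and exclusive for any η > 0, and the verdict moves monotonically
SILENCED → UNCHANGED → ANTERIORIZED as E grows at fixed L−D.

**Posterior edits** need no profile: a deletion lowers N, so by F = P·N
the pulling capacity must rise to compensate — delayed posteriorization; a
duplication raises N, anteriorizing the probe and carrying it past the
factory — downregulation.  **Splits** that remove the fixed end (including
inversions that take the Evx2–Hoxd13 boundary) anteriorize the remaining
genes; an inversion sparing that anchor region leaves expression unchanged.
Anterior duplications get a delayed/posteriorized verdict but are the most
weakly constrained rule in the engine.

Each packaged scenario declares the elasticity profile that realizes its
case — the outcomes genuinely hinge on unobserved local elasticity, so the
profiles are data (`SCENARIO_PROFILES`), not hidden constants.  The
"posterior_stiff_belt" profile, for example, concentrates stiffness in a
1-Kbp belt between genes 12 and 13 on an otherwise soft fiber: the
wild-type calibration must pay the belt's full cost while the
charge-reduced mutant force stalls inside it, stranding the terminal probe
short of L−D.

## Synthetic data

`generate_cluster` draws intergenic distances from a lognormal (default),
uniform or fixed law parameterized by mean and coefficient of variation.
Lognormal is the default because real intergenic distances are strictly
positive and right-skewed (the loose reference cluster spans 5–100 Kbp).
Distances are rounded to 0.1 Kbp for readable fixtures (cosmetic, below any
tolerance used) and floored at 0.1 Kbp.  `cluster_ladder` builds clusters
of increasing dispersion from one shared set of underlying draws, rescaled
to the target mean, so dispersion statistics increase monotonically along
the ladder by construction rather than only in expectation.

The generators emulate cluster *geometry* only: no sequence content, no
phylogenetic covariance between paralogs, no correlated noise across
segments, and no chromatin state.  Tests passing on synthetic clusters
therefore validate the statistical machinery and its closed forms, not any
claim about a particular genome beyond the packaged reference clusters.

## Problem sizes and reproducibility

Default experiment sizes: 250 realizations for comparisons (10 000 where a
Monte-Carlo estimate is checked against its closed form at 3 standard
errors), 100 seeds for the ordering robustness check, 51 parameter sets
(default + 50 log-uniform ×/÷2 draws) for the collinearity regression, and
a 101 × 201 simulation grid.  These sizes put every Monte-Carlo check well
inside its statistical resolution while keeping a full run under a few
seconds.  All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds give bit-identical
realizations, and cross-cluster comparisons use order-independent
substreams.

## Known limitations

* The model is qualitative by design: units are arbitrary and only
  orderings are meaningful ("we do not know the real nature" of the
  pulling molecules applies here too — P and N are formal).
* Absolute noise-experiment variances depend on the amplitude calibration;
  only the ordering is contractual.
* No saturation of P, no extrusion reversibility ('reeling in'), no polymer
  physics beyond the scalar stiffness profile, no split-cluster
  (arthropod-type) representation, and no quantitative expression levels
  for mutants.
* The anterior-deletion verdicts inherit the declared elasticity profiles;
  different profiles can realize different cases, which is a feature of the
  model (local elasticity is the explanatory degree of freedom), not an
  artifact.
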