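# Methods

## Scope and data model

The package mines compilations of uniaxial brain-tissue stress–strain
records. A record carries eight input parameters — donor age (months),
strain rate (s⁻¹), specimen diameter and thickness (m), white/gray/mixed
composition, storage and testing temperature (°C), post-mortem
preservation time (s) — and two outputs, true strain and true stress
(Pa). The reference compilation structure is a fixed 15-study table
(`brainmech.studies.default_study_table`): 903 tension and 4,676
compression points, 5,579 in total, each study tension-only or
compression-only at one or two of three strain-rate regimes
(quasi-static, intermediate, high).

Two transcription caveats are carried knowingly. First, the published
per-subset counts sum to one fewer compression record (4,675) than the
per-study totals (4,676); the package follows the per-study totals, so
the high-rate compression subset holds 2,235 records where the published
subset table prints 2,234. Second, the source table's two temperature
columns are transcribed in its printed header order (testing, storage),
although parts of the source's narrative suggest the opposite
assignment; the pipeline treats both as opaque ranked inputs, so only
the column labels — not any computation — depend on this reading.

## Synthetic generator

No raw data are deposited for the reference compilation (its records
were digitized from published plots), so the generator emulates it: per
study and regime it emits monotone curves

σ(ε) = k · (exp(α·ε) − 1),  α = 2,

with the stiffness scale k a product of monotone modifiers of the
testing conditions, times multiplicative lognormal noise (CV 0.05 by
default). Defaults encode the directions the experimental literature
reports, with magnitudes chosen once as plausible for soft neural
tissue:

| modifier | form | default | emulates |
|---|---|---|---|
| rate | rate^q | q = 0.15 | stiffening over ~6 decades of rate |
| age | (age/6 mo)^a | a = 0.3 | adult stiffer than infant |
| testing temp | exp(c·(T−22)) | c = 0.01/°C | stiffer at physiological T |
| storage temp | exp(c·(T−22)) | c = 0.01/°C | warm storage stiffens |
| post-mortem | 1 + p·hours | p = 0.01/h | slow stiffening with delay |
| composition | factor | white 0.8, gray 1.0, mixed 0.9 | gray ≳ white, unresolved in the literature |
| geometry | (d/t)^g | g = 0.1 | squat specimens respond stiffer |

Strain rates are sampled log-uniformly within regime bands —
quasi-static 0.0064–0.64 s⁻¹ (the range quoted for quasi-static
tension), intermediate 0.64–90 s⁻¹, high 90–3000 s⁻¹ — but regime
labels always come from the study table, never from the sampled value.
Strains are evenly spaced over (0, 0.5] true strain. Studies listing
several ages, thicknesses, compositions or temperatures have one value
sampled per curve (default 30 points per curve), so within-study
diversity appears at the curve level.

Within two-regime studies the split of the study's record count across
regimes is a free choice; the packaged default
(`data/regime_allocation.json`) is fixed so the five state×regime
subsets land on 370 / 533 / 1,686 / 755 / 2,235 points. Identical seed
and parameters give a bit-identical table (per-study seeds are spawned
from one root sequence).

What the generator does **not** emulate — and hence what passing tests
cannot show about real data: viscoelastic hysteresis, preconditioning
and relaxation; heterogeneity within a specimen; digitization error
structure; any quantitatively calibrated constitutive response. The
generator's role is to give the pipeline recoverable structure with the
right metadata shape, not biofidelity.

## Compilation and normalization

Engineering measures convert to true measures as ε = ln(1+e),
σ = s·(1+e) (compression handled as positive magnitudes, the sign
convention recorded in metadata). Units convert to SI except
temperatures, which stay in °C as the source tables print them.
Composition encodes as white 0.33, gray 0.66, mixed 1.00; this encoded
column is already in [0,1] and is not rescaled further. Every other
column is divided by its maximum absolute value *within the rows being
normalized* — normalization is per subset, since each subset is
analyzed and plotted self-normalized; whole-dataset normalization is
available by compiling the full table. Peaks are stored, making the
transform invertible and idempotent. All-zero columns are left unscaled
with a warning.

The seven subsets drop inputs that do not discriminate there: the
tension-side subsets carry no age or testing-temperature column, and
high-rate compression no post-mortem column. Stress-state/regime pairs
outside the schema (e.g. high-rate tension) are rejected at compile
time rather than silently pooled.

## SOM sensitivity ranking

Training is the classical online scheme on a 10×10 lattice: per sample
the best-matching unit minimizes Euclidean distance, and the update
Δw = lr · h · (x − w) applies a Gaussian lattice neighborhood h around
the winner. Learning rate (0.5 → 0.05) and radius (5 → 1.5 lattice
units) decay exponentially over epochs (default 10). The fairly wide
final radius is deliberate: trained maps stay smooth, which stabilizes
component planes — the quantity the ranking consumes — at the price of
a higher quantization error than a sharply annealed map would reach.
Weight initialization (uniform in [0,1], matching the normalized data)
and the per-epoch shuffle draw from two independent seed-derived
streams, so retraining with one feature removed under the same seed
visits samples in an identical order: leave-one-feature-out becomes a
matched-pairs comparison rather than a comparison across diverged
random trajectories.

A component plane maps each neuron to the mean of a chosen variable
over the samples it wins (empty neurons fall back to their own weight
coordinate). The importance of input feature f for a subset is

score(f) = 1 − corr(aᵣ, bᵣ) averaged over seeded restarts r,

where aᵣ and bᵣ are the true-strain plane values looked up at each
sample's BMU under the reference map and under the map retrained
without f. Features are ranked by descending score; scores within 0.05
of the head of their group are reported as tied — mirroring the fact
that rankings of this kind genuinely tie often. Spatial coherence of a
single plane is quantified by Moran's I under rook adjacency, clipped
to [−1, 1], with a constant plane defined as 0.

Two properties of this quantification are worth stating honestly.
A feature strongly coupled to the outputs is partly *redundant* with
them inside the map, so its removal changes the strain plane less than
naive intuition suggests (an exact duplicate column scores ≈ 0); and
the per-restart noise of the change score is of the same order as
typical feature separations, so tie groups are wide at moderate restart
counts (default 10 restarts; the orchestrated pipeline subsamples
ranking inputs to 1,500 rows per subset to keep a full seven-subset run
in minutes on one core). The score *ordering* between an
output-coupled feature and an independent noise feature is nonetheless
stable, which is what the test suite pins down.

## PCA

Columns are centered; the sample covariance (divisor N−1) is
eigendecomposed (`eigh`); components sort by descending eigenvalue with
the sign convention that each component's largest-magnitude loading is
positive. The retained dimension k is the smallest with cumulative
explained variance ≥ 85%; for the clustering stage k is capped at 3
(clusters are fitted and visualized in at most three dimensions), and a
cap that leaves the threshold unmet is logged, not hidden. PCA runs on
the peak-normalized columns (covariance, not correlation — the
normalization already puts columns on comparable scales), and by
default includes the two output columns alongside the inputs; a caller
can pass an input-only matrix to exclude them.

## Gustafson–Kessel fuzzy C-means

Memberships u_ik ∈ [0,1] with Σᵢ u_ik = 1 minimize
J = ΣᵢΣₖ u_ik^Q d²(x_k, vᵢ) by alternating the closed-form updates of
memberships, prototypes vᵢ (weighted means with weights u^Q) and fuzzy
covariances Fᵢ (weighted scatter). The GK distance
d² = (x−v)ᵀ (ρᵢ det Fᵢ)^{1/n} Fᵢ⁻¹ (x−v) fixes each cluster's
hypervolume to ρᵢ (1 by default) while leaving shape and orientation
free. Q defaults to 2, the conventional midpoint between crisp and
soft partitioning.

Numerical policy: covariances are symmetrized and nudged by
γ = 10⁻⁶·trace(F)/n (absolute floor 10⁻⁶) on the diagonal until the
condition number is ≤ 10¹⁰; a point at zero distance from one or more
prototypes takes full membership split evenly among them; clusters
whose total membership mass collapses are re-seeded from a random data
point with a logged warning. Initialization is a random valid
membership matrix; fits restart from several seeds (default 10) and
keep the lowest final cost. Convergence is max |ΔU| < 10⁻⁵ or 200
iterations; J is recorded every iteration (with identity covariances —
plain fuzzy C-means — the recorded sequence is provably non-increasing;
with adaptive covariances the final cost is checked against the
initial one instead, as the hypervolume normalization re-scales the
objective between iterations).

The cluster count is selected by a membership-confidence rule: the
largest C in the searched range (default 2–6) whose best-restart fit
keeps ≥ 50% of points above 0.5 maximum membership, falling back to
the smallest C with a warning if none qualify. "Largest qualifying"
is chosen because the smallest always qualifies trivially; note the
rule is deliberately permissive — even a single isotropic blob sliced
into wedges keeps confident cores, so it bounds softness rather than
detecting "true" cluster number. Clustering runs on the PCA scores
(distance computation is the reason the reduction exists); cluster
characterization tables report per-cluster means of the *denormalized*
original variables under hard (argmax) assignment.

## Orchestration and reproducibility

`pipeline.run` derives every stage-and-subset seed deterministically
from one global seed, writes per-subset artifacts (ranking CSV, PCA
JSON, partition JSON, cluster characterization CSV), a cross-subset
rank table with explicit tie groups, and a manifest (parameters, seeds,
package version, per-stage outcomes) sufficient to re-run any stage in
isolation. Reruns under the same config are byte-identical. Problem
sizes used by the test suite are scaled to desk hardware: ranking
checks use subsets of 400–700 rows with 2–3 restarts, clustering
recovery uses 600-point planted-blob datasets over 10 seeds, and the
convergence sweep uses 100 random instances of 20–80 points.

## Known limitations

- The ranking quantification has limited resolution (wide ties) at
  desk-scale restart counts; it orders clearly coupled vs. irrelevant
  features reliably but should not be over-read for adjacent ranks.
- The generator's modifier magnitudes are plausible, not calibrated;
  absolute stresses and cluster positions carry no biological meaning.
- The temperature-column labelling ambiguity of the source table (see
  above) swaps two column names if resolved the other way.
- Species differences are out of scope (single-species behaviour is
  assumed), as is any viscoelastic time-dependence.
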