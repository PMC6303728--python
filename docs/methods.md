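# Methods

This note records the models, numerical choices, and open design decisions
behind `seascapegen`, in the spirit of the methods documentation of mature
simulation/statistics packages. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Surface-current construction (`ocean_fields`)

**Geostrophy.** Surface geostrophic velocity is computed from sea-surface
height η on a regular lon/lat grid via the f-plane balance

    u = −(g/f) ∂η/∂y,    v = +(g/f) ∂η/∂x,    f = 2Ω sin(lat),

with g = 9.81 m s⁻², Ω = 7.292115×10⁻⁵ rad s⁻¹ and a spherical Earth of
radius 6 371 km for the degree→metre conversion (Δx = R cos(lat) Δλ,
Δy = R Δφ). Derivatives are centered second-order differences in the
interior and first-order one-sided next to domain edges and land cells; this
keeps the stencil usable along coastlines at the cost of one order of
accuracy there. Because f → 0 at the equator, a configurable band
(default |lat| < 5°, standard altimetry practice) is masked. The operator is
linear in η; the test suite asserts this as a property.

**Ekman response.** The wind-driven component treats the stress vector as a
complex number and applies `v_ek(z) = β(z)·τ·e^{iθ(z)}` per depth level
(0 and 15 m). The β and θ coefficients are fitted to drifter/float data in
the literature that defines the merged current products; no printed values
are available here, so they are *required configuration* with placeholder
defaults (β = 0.3 m s⁻¹ per N m⁻², θ = π/4) and a warning whenever the
defaults are used. The rotation preserves speed (|v_ek| = β|τ|), which is
asserted as a property.

**Synthetic presets.** Four analytic fields serve as advection oracles:
`uniform_flow`; `solid_body_rotation`, defined so that trajectories are exact
circles *in lon/lat coordinate space* (the m/s components carry a cos(lat)
factor that cancels the spherical conversion) with period 2π/ω — this gives a
closed-form orbit against which integrator error is measured;
`double_gyre`, whose u/v are obtained by applying the *same centered
difference* to a streamfunction that the divergence diagnostic uses, making
the discrete divergence vanish identically at interior nodes; and
`boundary_current_with_eddies`, an alongshore jet with Gaussian eddies and a
configurable cross-shore fraction (qualitative stand-in for a western
boundary current system).

## 2. Lagrangian dispersal (`lagrangian`)

Particles are advected in 2-D at one depth level. Although larvae occupy a
three-dimensional ocean, the drifting stages of the target taxa are confined
to the upper mixed layer (< 15 m) and the forcing products are surface/15 m
currents, so horizontal advection is the experiment actually informative
here. Velocity at off-grid points is bilinear in space and linear in time;
land-masked nodes contribute zero velocity with their interpolation weight
retained, so currents decay smoothly toward the coast (free-slip-like).
Integration is Euler or classical RK4 (default RK4, dt = 3 h, matching the
finest temporal resolution of merged current products).

Two error floors matter when measuring integrator accuracy: RK4 truncation
(O(dt⁴)) and the bilinear-interpolation error of the sampled field
(O(Δgrid²), independent of dt). The convergence-order check therefore uses a
fine grid (0.05°) and a coarse dt ladder so truncation dominates; the orbit
closes to ~10⁻⁶ of its radius at dt = period/200.

**Settlement rule.** "Reaching the coast" is not a standard physical event,
so it is defined explicitly: a particle settles at its first entry into a
*coastal cell* (an ocean cell 4-adjacent to land) at drift age ≥ `min_age`
(default 0; set it to emulate a pre-competency period). Settlement is
cumulative within the release duration. A step that would land on a land
cell settles the particle at its previous (coastal) position; pre-competent
particles hold position instead. Particles leaving the domain are flagged
and excluded from further recording. Initial positions are scattered
uniformly on a disc of 0.1° radius (seeded); default 1 000 particles per
release, 120-day duration.

Arrival fractions are settled/released per release, optionally broken down by
destination site (coastal cells assigned to the nearest site within a
radius). Density grids count recorded (particle, time) samples on a 1°×1°
grid, so cell counts are proportional to residence time.

## 3. Population genetics (`popgen`)

**Diversity.** He is Nei's unbiased estimator (2n/(2n−1))(1−Σp²); allelic
richness is hypergeometric rarefaction to a common number of gene copies
(default: twice the smallest per-population genotyped count at the locus);
PIC = 1 − Σp² − Σ_{i<j} 2p_i²p_j². Missing calls are dropped per locus
(pairwise-complete).

**HWE and linkage.** The HWE test is the Monte-Carlo exact test: gene copies
are shuffled and re-paired, and the p-value is the fraction of arrangements
whose conditional probability given the allele counts is ≤ the observed
one. An exhaustive-enumeration version (recursive pairing of allele counts)
is included for small samples and used as the oracle. The linkage test
permutes one locus's genotypes across individuals *within populations* and
uses the summed G (log-likelihood-ratio) statistic of the per-population
genotype×genotype tables. All permutation p-values use (#extreme + 1)/(n+1).

**Null alleles.** The EM estimator assumes HWE over visible alleles plus one
null allele: null heterozygotes appear as visible homozygotes, null
homozygotes as missing. Gene counting iterates expected genotype counts and
frequency updates to a 10⁻⁸ tolerance. Whether observed missing genotypes
enter the likelihood as putative null homozygotes is a genuine ambiguity in
the published EM implementations; both variants are available
(`missing_as_null`, default True) and the default is documented, not claimed
to replicate any specific tool.

**FST.** θ is the Weir & Cockerham (1984) variance-components estimator
(a/(a+b+c)), multi-locus by ratio of sums, with percentile bootstrap CIs over
loci (default 1 000 replicates; published studies often use 10⁵ — the default
is desk-scale and configurable). The estimator choice is worth stating
because field studies often cite software rather than estimators; the
widely used FST tools are WC-type. The ENA ("excluding null alleles")
correction recomputes the components from EM-adjusted visible-allele
frequencies with the null class excluded and renormalized, keeping observed
heterozygote proportions. When estimated null frequencies are ~0 the ENA θ
coincides with the uncorrected θ. Corrected and uncorrected matrices are
compared with a paired t-test over population pairs; a zero-variance nonzero
difference is reported as p = 0 (deterministic difference), identical
matrices as (t = 0, p = 1).

**AMOVA.** Three levels (among groups / among populations within groups /
within populations) on gene copies with allele-identity distances (d² = 1
between different alleles). With missing data, sums of squares are computed
per locus and summed; variance components are estimated per locus with that
locus's gene-copy counts (coefficients n1, n2, n3) and summed over loci;
fixation indices are ratios of summed components. Reported df follow the
full-sample convention (G−1, P−G, 2N−P). Permutation schemes per index:
F_CT permutes whole populations among groups; F_SC permutes individuals
among populations within groups; F_ST permutes individuals across all
populations. For complete toy data the components equal a brute-force nested
ANOVA on one-hot gene-copy vectors to 10⁻¹⁰ (tested).

**Isolation by distance.** Mantel correlation of FST/(1−FST) (negative θ
clamped to 0 for the transform only; matrices retain negatives elsewhere)
against great-circle km (haversine; a stand-in for coastal-path distance,
which is out of scope). One-sided permutation of population labels.

## 4. dbRDA (`seascape_rda`)

The response dissimilarity matrix (typically pairwise FST, used directly as a
dissimilarity with negatives clamped; a √FST switch is available) is Gower
double-centered and eigen-decomposed. Positive-eigenvalue site coordinates
are regressed on column-standardized predictors; constrained axes come from
the eigen-analysis of the fitted values (capscale-style). Negative PCoA
eigenvalues are excluded from the regression and reported separately rather
than corrected (Lingoes/Cailliez would change total inertia); this matches
the behaviour of the standard constrained-ordination implementation, against
which the constrained eigenvalues are cross-checked in the test suite
(identical up to the variance-vs-SS scaling of 1/(n−1)).

PCNM axes: the inter-site distance matrix is truncated at the longest
minimum-spanning-tree edge, distances beyond the threshold are replaced by
4× the threshold, and the truncated matrix is double-centered and
eigen-decomposed; positive-eigenvalue eigenvectors are the spatial
predictors (on a regular transect they are sinusoid-like with increasing
sign changes).

Marginal tests condition each term on all others: F = (added inertia/df) /
(residual inertia/df_res), with p by permutation of reduced-model residuals.
Forward selection adds the candidate with the smallest marginal p (ties by
larger F) while p < α_add = 0.05; forward-only is deliberate — with ≤ ~6
candidates and ~15 sites a bidirectional search adds instability without
information. Variance partitioning uses Ezekiel-adjusted R² and Möbius
inversion over subset unions; adjusted fractions may be slightly negative,
and fractions plus residual sum to 1.

## 5. Synthetic data (`synthetic_data`) — what it does and does not emulate

Genotypes follow a hierarchical Balding–Nichols model: ancestral frequencies
~ flat Dirichlet; group frequencies ~ Dirichlet(p(1−F)/F) with F the design
between-group differentiation (default 0.05, chosen to sit in the
weak-but-detectable regime the motivating system occupies); populations nest
within groups the same way (default F = 0.01). Defaults mirror the study
system's shape: 3 groups, 21 loci with 2–14 alleles per locus, tens of
individuals per population, and one admixed contact-zone population whose
gene copies are drawn from two donor groups with probability α. Null
alleles are injected per gene copy and masked exactly as the EM model
assumes; extra missingness is applied afterwards. The generator gives a
closed-form F target for parameter-recovery tests — which is why
Balding–Nichols was chosen over coalescent simulation.

What a green test therefore establishes: estimator correctness under HWE,
hierarchical island structure, and the stated null-allele mechanism. What it
does not: mutation-model realism (no stepwise mutation), linkage, demographic
history, or selection — real microsatellite data can violate all of these.

The fixture world places a meridional coastline, an alongshore boundary
current with eddies, and 15 sites whose offshore distance cycles between
0.5° and 2.5° (variable shelf width), which produces site-to-site variation
in settlement for the recruit predictor. Environmental covariates follow a
linear poleward-cooling gradient in minimum SST (0.35 °C per degree
latitude, ~tropical-to-subtropical range) with Gaussian noise; chl a and
KD490 are independent positive noise.

## 6. Degenerate inputs and tie-breaks

Monomorphic loci: HWE and linkage tests are signalled as undefined (not
p = 1). Pairs of populations with no shared polymorphic locus are an error
for θ. AMOVA with completely fixed groups yields F_SC = 0/0 → NaN, reported
as such. Forward selection with all-noise candidates returns an empty set;
the pipeline then falls back to an unselected two-column model for
reporting. Permutation p-values can never be 0 by construction.

## 7. Known limitations

- Dispersal is passive and 2-D: no larval behaviour (vertical migration,
  directed swimming), mortality, or sub-grid diffusion.
- The ENA correction is one defensible reading of the published EM-based
  procedure, not a bit-for-bit replication of any closed-source tool.
- Multi-locus AMOVA weighting with missing data follows the per-locus
  component-sum convention described above; other tools make other choices.
- Geographic distance is great-circle, not coastal-path.
- The accession-based tier of the analysis (re-running on the deposited
  271-individual dataset) requires an external download and is not exercised
  by the test suite.
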