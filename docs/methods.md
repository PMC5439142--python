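# Methods

## Model

The package fits the univariate animal model

    y = X1 β1 + X2 β2 + Z u + e,
    u ~ N(0, σ²_g K),    e ~ N(0, σ²_e I),

where X1 is the 0/1 incidence of contemporary group (CG) with the intercept
absorbed (no reference level dropped), X2 holds all other fixed effects,
Z maps records to animals over the full ordered pedigree, and K is the
relationship matrix actually fitted: pedigree A, or the single-step H
combining A with a genomic G for a genotyped subset. Variance components are
supplied, not estimated: the package deliberately excludes REML — its scope
begins after a variance-component analysis has been run.

Assumptions that matter for exactness of the PEVMean recovery:

* one random (animal) effect, homogeneous residual variance R = σ²_e I;
* the intercept is absorbed into CG, so X1 is a pure incidence matrix and
  (X1'X1)⁻¹X1'Z is the record-weighted CG averaging operator;
* [X1 X2] has full column rank (checked; violations raise an error naming
  the confounded columns).

Under these, the identity Var(X'Xβ̂) − σ²_e X'X = Var(X'Z(û−u)) turns the
top-left block of the record-space variance equation into function 2 (X2
empty) or function 3 (general), both implemented literally and both exact:
the test suite asserts max|function3 − direct PEVMean| < 1e-8·(1+max|·|)
across herds of 200–2000 animals, 5–40 CGs, 1–3 extra effects, under A and
H, and the observed deviations are at machine precision (~1e-15).

## Averaging convention

A CG's mean breeding value is averaged over *records*, because the operator
(X1'X1)⁻¹X1'Z is defined through the record-level design; an animal with two
records would be counted twice. The simulator emits one record per animal,
so this distinction is untested by default and documented here.

## Pedigree machinery

`order_pedigree` topologically sorts animal/sire/dam triples (stable,
input-order tie-break), promotes parent-only ids to founders with a logged
notice, and rejects duplicate ids and ancestry cycles (reporting the id
chain). Unknown parents are the sentinel `0` and are treated as unrelated,
non-inbred base animals — there is no phantom-parent/genetic-group
modelling.

`build_A` is the dense tabular recursion (diagonal 1 + F), capped at 5000
animals; it exists mainly as the in-repo oracle. `build_A_inverse` uses the
Meuwissen–Luo recursion: inbreeding coefficients from per-animal ancestor
traces (O(n·depth), never forming A), then sparse assembly of per-animal
contributions 1/d_i with d_i = 0.5 − 0.25(F_s + F_d), an unknown parent
counting as F = −1. Agreement with the dense inverse is asserted to 1e-8 on
50 random pedigrees up to 500 animals including inbred loops.

## Genomic machinery

G is VanRaden's first method, G = MM'/(2Σp_j(1−p_j)) with M centred by 2p.
Allele frequencies default to the observed sample when reading genotype
files, with an explicit override; the simulator attaches the true
base-population frequencies to its panels, since E[G] = A22 holds under
base frequencies while sample frequencies re-centre G toward zero on small
family panels. Monomorphic markers are dropped with a logged count; an
error is raised only when nothing polymorphic remains.

H⁻¹ is the single-step form A⁻¹ + (G⁻¹ − A22⁻¹) scattered into the
genotyped block, with the τ = ω = 1 scaling of the plain method. G is
blended as 0.95·G + 0.05·A22 by default to guarantee invertibility (weight
1 disables blending and is used in the null tests, where forcing G = A22
makes H⁻¹ collapse to A⁻¹ exactly). Near-singular G or A22 (condition
number above 1e12) raises an error advising blending.

## Solver

Direct sparse LU factorisation of the MME coefficient matrix, assembled on
the λ = σ²_e/σ²_g scale; all variance blocks are the corresponding blocks
of the inverse times σ²_e. Iterative solvers are deliberately out of scope:
the package's claim is exactness, not approximation. Var(β̂) comes from
solving against the first p identity columns; the PEV block is only
extractable below a configurable dense limit (default 5000 animals) and
exists to cross-check, not to compute. For systems of dimension ≤ 2000 a
dense condition estimate above 1e12 triggers a rank error, distinguishing
confounded designs from ill-scaled covariates.

## Statistics and guards

PEVD, flock correlation, VED, corrected VED (VED − σ²_e(1/n_i + 1/n_j)),
CR, and CD of the CG mean-difference contrast with prior variance read from
K̄ = (X1'X1)⁻¹X1'Z·σ²_g K·Z'X1(X1'X1)⁻¹ (computed uniformly through the
fitted K, whether A or H). Correlation denominators hitting the guard
ε = 1e-12 yield NaN and a `flagged` mark in the report rather than a silent
number. Function-3 outputs are symmetrised as (M+M')/2; asymmetry beyond
1e-8 raises instead of being absorbed. The report emits both function-3 and
(when PEV was extractable) direct-based values with a max-deviation column,
so the exactness claim is visible in routine output.

One boundary worth knowing: cross-flock CD is exactly zero in disconnected
designs only when each flock's recorded members are mutually unrelated (or
symmetrically related) — then the flock mean is fully confounded with the
CG effect. With multi-generation within-flock families, prior relationships
make flock means slightly predictable and CD is small but positive even
with zero connectedness; flock correlations remain exactly zero. The test
suite pins the exact-zero case and verified the small-positive case against
the dense GLS oracle.

## Diagnostics

* **Correction trace**: 2Tr(Var(β̂₂,β̂₁)W) + Tr(Var(β̂₂)W'W), the cheap
  rearrangement; the full-matrix trace is the test oracle. Far-from-zero
  values mean function 2 is a poor substitute for function 3.
* **Covariance ratio** det(Var(β̂₁)_full·Var(β̂₁)_reduced⁻¹), via
  log-determinants; 1 when added effects leave the CG block untouched.
* **Marginal r²** = Var(ŷ)/(Var(ŷ)+σ²_e+σ²_g) with the population
  (divide-by-n) variance of Xβ̂.
* **r²_β** from the Wald statistic β̂'Var(β̂)⁻¹β̂ with ν = n − p and the
  statistic's dimension q taken equal to p (the total number of estimated
  fixed effects) — the construction leaves q undefined otherwise; whether ν
  should also subtract random-effect degrees of freedom is left open and
  not guessed. These r² statistics are reported for model comparison; they
  carry no information about the correction factor.
* **Operation count** 2p₁ + 6p₁² + p₁p₂(2p₁+p₂): predicted post-solve cost.

## Synthetic herds

The simulator emulates a multi-flock scheme: per-CG founder rams and ewes,
a global link-ram pool siring a configurable fraction of matings
(`link_sire_fraction`; 0 = fully disconnected flocks, the off-diagonal
PEVMean blocks are then exactly zero), discrete generations, one record per
animal, and gene-dropped SNP genotypes for the youngest
`genotyped_fraction` of the pedigree. Breeding values use the exact
recursion u_i = (u_s+u_d)/2 + m_i with Var(m_i) = σ²_g(0.5 − 0.25(F_s+F_d))
using exact parental inbreeding, so the Monte-Carlo covariance target is
σ²_g A exactly (verified at 500 replicates on a trio, tolerance 0.1σ²_g).

Default parameters and why:

* σ²_g = 1.81, σ²_e = 7.43 (λ ≈ 4.105, h² = 0.20): working values for a
  sheep live-weight trait, in kg².
* CG effect SD 2.0 kg around a mean of 10: environmental spread between
  flock-sex classes of the order of the phenotypic SD.
* covariates N(20, 4²) by default — an *uncentred* weaning-weight-like
  covariate, chosen deliberately so the absorbed-intercept sensitivity
  (large correction factor, inflated CR) is visible out of the box; the
  `balanced` flag repeats identical covariate values and factor patterns in
  every CG to exercise the balanced-design identities.
* link_sire_fraction 0.3, 4 link rams, 3 private sires and 15 dams per CG,
  2 generations: modest, realistic connectedness so flock correlations fall
  in the 0.1–0.3 range rather than degenerating to 0 or 1.

Test problem sizes (up to ~2000 animals, 40 CGs) were chosen so every exact
claim is also checkable against dense brute-force oracles; the method
itself only ever needs the p-column solve and scales far beyond that.

What the simulator does not emulate: selection and non-random mating,
missing or repeated records, genotype-by-environment structure,
heterogeneous residual variances, genetic groups. Passing tests certify the
algebraic identities and estimator implementations, not robustness of
connectedness assessment to those real-data features.

## Known limitations

Single trait, single random effect only — the exact recovery does not
extend as-is to multi-trait or maternal-effect models. PEV extraction (the
cross-check path) is dense and capped. The pedigree inbreeding trace is
exact but quadratic in pathological deep-loop pedigrees. CD between groups
with identical prior genetic means is undefined and reported as NaN.
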