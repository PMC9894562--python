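# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates.

## Connectivity model and generators

Networks have two populations in a fixed contiguous ordering (E block first).
The reference composition is the standard cortical 80/20 split (N_E = 4 N_I);
dense reference experiments use N = 1500 and sparse ones N = 1000, with a
smaller N = 900 (2:1 split) network for the pure-bulk measurement.

**Dense Gaussian.** Means depend only on the presynaptic population
(J̄·E = J_E/N_E > 0, J̄·I = −J_I/N_I < 0; Dale's law is enforced on the mean
only, individual Gaussian weights may violate it). Element variances are
g²_pq/N; g is a 2×2 table, row = postsynaptic type. Reciprocal motifs are
imprinted by mixing an i.i.d. standard-normal matrix Y′ with its transpose,
y_ij = γ_pq y′_ij + √(1−γ²_pq) y′_ji with
γ = sign(η)·√((1−√(1−η²))/2), which preserves unit marginal variance and
gives corr(y_ij, y_ji) = 2γ√(1−γ²) = η exactly. γ is evaluated in the
algebraically equivalent form |η|/√(2(1+√(1−η²))) to stay accurate for
small η. The mixing couples off-diagonal pairs only; diagonal entries are
sampled independently with the within-population variance and carry no
self-motif (an O(1/N) choice). Cross-population (EI/IE) pairs are mixed
jointly with the common γ_EI = γ_IE and each directed entry is scaled by its
own g_pq.

**Sparse Bernoulli.** Homogeneous connection probability c, weights A_E > 0
and A_I < 0 set by the presynaptic type. Reciprocity is generated by a
*compensated pairwise scheme*: for each unordered pair, the forward edge is
present with probability c; given presence the mirror is present with
probability ρ_pq, given absence with probability c(1−ρ_pq)/(1−c). Both
directed edges then have marginal density exactly c, and the presence
correlation is (ρ_pq − c)/(1 − c), so the implied weight correlation is
η_pq = sign(A_pA_q)(ρ_pq − c)/(1 − c). A direct upper-triangle rewrite of
the mirror edges would not preserve the marginal density; the compensated
scheme is the construction consistent with both the density and the target
correlation. Feasibility requires c(1−ρ)/(1−c) ≤ 1, i.e. ρ ≥ (2c−1)/c for
c > 1/2; the constructor rejects infeasible combinations. Diagonal entries
are independent Bernoulli(c).

Moment matching maps sparse to Gaussian parameters: J_E = N_E c A_E,
J_I = −N_I c A_I, g²_pq/N = A_q² c(1−c), η from the formula above. All
analytic predictions agree exactly under this map, and the two generators
produce statistically indistinguishable outlier ensembles at the reference
sizes (checked by a two-sample comparison).

Each generator consumes a single integer seed through one
`numpy.random.default_rng` stream in a fixed draw order, so realizations are
bit-reproducible.

## Spectral predictions

The outlier condition from the matrix determinant lemma is expanded in
powers of Z/λ and truncated at second order, giving the cubic
λ³ = λ₀λ² + [θ₁]λ + [θ₂] with [θ₁] = 0 on average. Only this truncated
(k = 2) form is implemented; the untruncated solution is out of scope, and
the truncation error is visible as a systematic offset between the cubic
root and the empirical ensemble mean at strong motifs (the offset stays
inside the finite-size ensemble band at the reference parameters, which is
what the acceptance tests assert). The finite-size standard deviation of the
outlier is the first-order expression, O(1/√N).

**Bulk radius.** For homogeneous variances r_g = g. For cell-type-dependent
variances we use r_g = √(largest eigenvalue of the 2×2 matrix
M_pq = α_q g²_pq). This formula reduces to g in the homogeneous case and is
validated *empirically* against sampled fluctuation spectra (agreement
within 5% at N = 1500); its status is an empirically supported choice, not a
derivation.

**Outlier/bulk separation.** With motifs the bulk is non-circular. The
classifier uses an elliptical boundary with semi-axes r_g(1 ± τ), where
τ = Σ α_pα_q g_pq g_qp η_pq / Σ α_pα_q g_pq g_qp is the variance-weighted
effective correlation (equal to η in the homogeneous case, where the
elliptic law is exact), floored at the finite-size scale 2r_g/√N and
multiplied by the margin 1 + 2/√N (bulk-edge fluctuations scale as N^(−1/2)).
Block-structured mixed-sign correlations deform the bulk beyond any ellipse;
for those cases the classifier can additionally be given the realization's
own fluctuation matrix Z, and flags only eigenvalues of J that are far
(10× the median displacement) from the spectrum of Z — the bulk of the same
realization. This is how the complex-conjugate outlier pairs of the
heterogeneous-motif regime are detected. The dominant-outlier extraction
used in ensembles takes the largest-modulus eigenpair by ARPACK with the
all-ones start vector (the outlier eigenvector has O(1) overlap with it),
which is ~50× faster than a full eigendecomposition and agrees with it to
1e-8.

## Rank-one approximation

Truncated eigendecomposition (not SVD) defines the rank-R approximation,
because it preserves the dominant eigenvalues that control autonomous
dynamics; SVD truncation preserves singular values but generically not the
top eigenvalue (asserted in tests). Rank-R is implemented generically; only
R = 1 is exercised. A real rank-one truncation does not exist when the
dominant eigenvalue is a complex pair; this raises rather than silently
returning a complex matrix.

Perturbation vectors use Δm = Z m̄/λ₀ and Δn = Zᵀn̄/λ₀. Predicted
Gaussian-mixture statistics use λ₀² in the variance denominators and the
dominant cubic root λ² in the covariance denominators — the λ substitution
absorbs part of the nonlinearity of the outlier shift and makes the
population-averaged covariance equal λ − λ₀ by construction. Two
consequences are worth recording:

* The prescription is *not* jointly realizable in extreme regimes: when
  |λ| < λ₀ (strong negative reciprocity) the covariance can exceed the
  Cauchy–Schwarz bound of the λ₀-scaled variances. The code warns and
  proceeds, since the mean-field equations only consume the numbers
  separately.
* Perturbation theory is a lower bound on the eigenvector entry variances;
  numerical eigenvectors exceed it by an amount that grows with g and with
  the proximity of the outlier to the bulk. The 15%-level quantitative
  agreement of all five vector statistics is asserted where the validity
  condition (outlier several bulk radii out, λ₀ = 1.4, g = 0.3) holds; in
  the marginal regime λ₀ = 0.8 the variances inflate by ~20% and only the
  covariance–shift identity σ_nm ≈ λ − λ₀ is asserted.

Sign conventions: numerical right eigenvectors are fixed by a positive
overlap with the all-ones direction; left vectors by L̂ᵀR̂ = 1 with
nearest-eigenvalue pairing (1e-8 relative) against the transpose
decomposition. The comparison normalization R = (L̂ᵀR̄ / L̄ᵀR̂)^{1/2} R̂ is
idempotent and warns when R̂ is nearly orthogonal to R̄.

## Dynamics and mean-field theory

The rate network ẋ = −x + Jφ(x), φ(x) = 1 + tanh(x − θ) with θ = 1.5
throughout the reference experiments, is integrated with fixed-step explicit
Euler: dt = 0.05 (time constant 1), T = 200, convergence when max|ẋ| < 1e-8,
divergence guard at ‖x‖_∞ > 1e6. The dynamics are smooth and saturating
(φ ∈ (0,2)), so there is no stiffness; steady states move by < 1e-5 under
dt halving. Branch probing initializes x₀ = κ₀m with κ₀ ∈ {0, 2(J_E+J_I)},
bracketing the reachable range since φ < 2 bounds the recurrent drive.

Gaussian averages ⟨f(μ, Δ)⟩ = E[f(μ + √Δ z)] use fixed-order Gauss–Hermite
quadrature, order 301 (the highest order the double-precision weight
recurrence supports), accurate to ~1e-9 against adaptive quadrature over the
operational range (|μ| ≤ 4, Δ ≤ 3). Δ enters as a *variance*: the integrand
is evaluated at μ + √Δ·z. φ′ = sech² is analytic, computed in an
overflow-safe exponential form.

Latent fixed points are roots of κ − F_mean(κ) − F_cov(κ) bracketed on a
2001-point grid over κ ∈ ±(2(J_E+J_I)+1) and refined by bisection to 1e-10;
the solver raises when the edge values prove a root outside the window.
Stability uses the one-dimensional criterion dRHS/dκ < 1 (equivalently a
negative κ̇ slope), with the derivative from central differences (h = 1e-6)
of the quadrature RHS. Generic fixed-point counts are 1 or 3; the
bifurcation sweep reports the first grid value with three roots as the
bistability onset.

The superposition mean-field route (independent connectivity only) iterates
μ_x = J_E⟨φ⟩_E − J_I⟨φ⟩_I and Δ_x,p = Σ_q α_q g²_pq⟨φ²⟩_q with damping 0.5,
tolerance 1e-10, up to 10⁴ iterations, from a near-zero and a high-activity
init to expose bistability. Its mean agrees with the rank-one κ* to a few
percent at the reference parameters. Its variance dominates the rank-one
prediction κ²σ²_m exactly (Jensen) when g is homogeneous — there the
comparison is a theorem; with cell-type-dependent g the cross-population
weighting makes the inequality only approximate (violations of ~2% occur at
the low fixed point), so the dominance assertion is made in the homogeneous
case.

## What the synthetic data does and does not show

All validation data are generated by the package's own samplers under the
reference conditions (N = 1500/1000/900, 10–50 seeds, the coupling,
variance-ratio and motif values of the reference experiments). They exercise
exactly the model class the theory addresses: block-structured first and
second moments with reciprocal pairwise motifs. They do not contain
heavy-tailed weights, hubs, higher-order motifs (chain/convergent/
divergent), distance- or plasticity-structured connectivity, or external
input — so passing tests certify the local-to-global mapping within its
stated assumptions (central limit theorem for the vector entries, outlier
outside the bulk, g below unity), not robustness of real cortical data to
those violations. Ensemble sizes follow the reference experiments
(30 realizations for spectra, 50 for vector statistics); sweep-level
attractor checks simulate the two branch initializations at the endpoints of
each sweep with one realization per point, which suffices for the discrete
count comparison.

## Known limitations

* The cubic (k = 2) outlier equation degrades for |θ₂| large or λ₀ → 0; the
  predicted complex pair can be quantitatively off even when a conjugate
  pair is correctly detected empirically.
* The heterogeneous bulk-radius formula and the elliptical separation
  boundary are empirical commitments, validated at the parameters used here.
* DMFT is restricted to independent connectivity (its decorrelation
  assumption fails with motifs); no chaotic-regime or time-dependent
  mean-field analysis is included.
* Rank-R statistics formulas for R > 1 are not implemented; the truncation
  machinery alone is generic in R.
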