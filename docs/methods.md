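# Methods

This note documents the models implemented in `connharm`, the choices made
where the design was genuinely open, and what the synthetic-fixture tests
do and do not demonstrate.

## Graph model of the connectome

The connectome is an undirected, unweighted graph on the vertices of a
cortical surface mesh.  Local edges are exactly the triangle edges of the
mesh (deduplicated); on a regular triangulation this gives six neighbours
per interior vertex.  Long-range edges are added one per fibre tract by
snapping each endpoint to its Euclidean-nearest mesh vertex (ties broken
toward the lower vertex index, a fixed deterministic rule).  Fibres whose
two endpoints snap to the same vertex are dropped — the adjacency has zero
diagonal by definition — with a logged count.  Duplicate and reversed
pairs collapse to one edge; a pair that coincides with a mesh edge is
classed local.  Tractography parameters (FA threshold, minimum length,
maximum turning angle, seeds per vertex) are carried as provenance metadata
only and never enter any computation; tractography itself is out of scope —
the package consumes endpoint tables.

If a graph is disconnected the eigenproblem is restricted to the largest
connected component and the retained-vertex mask is recorded, rather than
computing per-component bases whose constant vectors would interleave.
Coordinates are used in the mesh's native millimetre frame; no registration
is performed.

**Randomized controls.**  `randomize_long_range` redraws the long-range
edges uniformly at random (without replacement) over all non-local,
non-self vertex pairs, preserving the local edge set and the long-range
edge count.  This is the minimal reading of "randomize the long-range
connections while preserving local structure"; a degree-preserving
double-edge-swap mode is also provided for users who want to additionally
hold each vertex's long-range degree fixed.

## Laplacian and harmonics

Both symmetric Laplacians are implemented: the combinatorial form
`D − A` (zero row sums, constant kernel) and the symmetric normalized form
`D^{−1/2}(D − A)D^{−1/2}` (unit diagonal).  Which form a given analysis
intends is ambiguous in general — both are "the symmetric graph
Laplacian" — so every basis records its normalization, and the default is
`symmetric_normalized`.  Note one practical difference exploited below:
only the combinatorial form annihilates constants exactly on irregular
graphs, which matters for the uniform fixed point of the neural field
model.

Eigenpairs are computed with a dense symmetric solver up to n = 2500 and
shift-invert Lanczos beyond; postconditions (per-pair residual and
orthonormality, both ≤ 1e−8) are asserted on every call.  Eigenvector sign
is fixed by making the largest-magnitude entry positive (ties to the lower
vertex index).  Within a degenerate eigenvalue cluster individual vectors
are only defined up to rotation, so validation compares subspaces
(principal angles) rather than vectors; `HarmonicBasis.degenerate_groups`
exposes the clustering.  Harmonic indexing is 0-based internally; the
conventional 1-based "wavenumber" count, in which the constant λ = 0 mode
is harmonic #1, is presentation-level (`wavenumber(j) = j + 1`).

## Spectral transform

Projection uses the plain inner products `c_j = ⟨x, ψ_j⟩`; binary maps are
projected as 0/1 vectors (a demeaning option exists but is off by default —
demeaning only moves energy out of the constant mode).  The normalized
reconstruction error is `e(k) = ‖x − x̂_k‖₂/‖x‖₂`, which is dimensionless,
starts at e(0) = 1 and is non-increasing; it is computed from tail sums of
squared coefficients plus a directly-evaluated final residual, avoiding the
catastrophic cancellation of the naive `‖x‖² − Σc²` form.  The
percent-of-spectrum helper maps a fraction f to k = round(f·n) modes.

## Matching and the Monte-Carlo null

MI between a continuous harmonic and a binary map requires discretizing
the harmonic; the default is the sign indicator (consistent with the
F-measure's binarization), with equal-frequency quantization into b bins as
an option.  MI is the plug-in estimate from the joint vertex-count table,
reported in bits.  The F-measure uses vertex-level precision/recall of the
sign-binarized harmonic and takes the maximum over the two polarities,
since an eigenvector's sign is arbitrary.

The null model rewires only the long-range edges and recomputes the k
lowest harmonics with identical settings per simulation.  Empirical
p-values use the add-one estimator `p = (1 + #{null ≥ obs}) / (1 + N)`,
which never returns zero.  Null samples can be compared per harmonic index
(default) or pooled across all k indices per network
(`pool_harmonics=True`).  Pooling rests on approximate exchangeability of
null scores across harmonic indices and buys p-value granularity
1/(1 + k·N) at fixed simulation cost; at desk scale (hundreds rather than
hundreds of thousands of simulations) it is the only way an
FDR-corrected q-value can clear conventional thresholds, because with
per-harmonic nulls the smallest achievable q is k/(1 + N).  q-values are
Benjamini–Hochberg across all (harmonic, network) tests, separately per
metric.  With 199 or more null draws the p-value grid is fine enough that
the estimator's discreteness no longer distorts uniformity tests of null
p-values.

## Neural field model

Per node, excitatory and inhibitory activity follow

    τₛ dE/dt = −d_E E + S(α_EE 𝒟_EE E − α_IE 𝒟_IE I)
    τₛ dI/dt = −d_I I + S(α_EI 𝒟_EI E − α_II 𝒟_II I)

with S(x) = 1/(1 + e^{−a(x−θ)}).  Defaults: d_E = d_I = 2, all α = 150,
τₛ = 1 (time unit), a = 1, θ = 0 (the canonical sigmoid placement; gain
and threshold are exposed in the config).  Named diffusion presets cover
the studied regimes, all with short-range excitation and broad inhibition
("Mexican hat"):

| preset | σ_EE | σ_EI | σ_IE | σ_II |
|---|---|---|---|---|
| fast_excitation | 20 | 4 | 4 | 50 |
| slow_excitation | 6 | 4 | 4 | 50 |
| slow_excitation_fast_ie | 6 | 4 | 10 | 50 |
| slow_excitation_strong_ii | 6 | 4 | 10 | 90 |

**Diffusion operator.**  Spatial propagation is iterated application of the
Laplacian, `𝒟_σ = (I − (σ/s)Δ)^s`, the explicit-Euler approximation of the
heat kernel e^{−σΔ}; σ is the diffusion extent and s is chosen so that
(σ/s)·λ_max ≤ 1/2 (λ_max from a cheap spectral bound: 2·max degree for the
combinatorial form, 2 for the normalized form), keeping every spectral
factor in (½, 1] per substep and the operator both stable and close to the
heat kernel.  Passing an explicit s that violates (σ/s)λ_max < 1 is an
error that reports the smallest stable s.  Because 𝒟_σ is a polynomial in
Δ, harmonics are its eigenvectors with gain g_σ(λ) = (1 − (σ/s)λ)^s — this
exact gain (not the e^{−σλ} limit) is used everywhere in the linear
analysis so that predictions match the simulated operator to machine
precision.  For n ≤ 1500 the powered operator is precomputed densely via
binary exponentiation; beyond that it is applied as s sparse
matrix-vector products.

**Integration.**  Explicit Euler with dt = 0.01·τₛ by default (RK4
optional); with S ∈ (0,1) and d > 0 trajectories are confined to
[0, 1/d], which is asserted as a boundedness test.  Initial conditions are
i.i.d. uniform noise in [0, 0.1] per node (seed-deterministic) — the
noise-driven self-organization setting — or a constant state, or a given
state.  A dt-halving smoke test bounds the discretization error in smooth
regimes; in oscillatory regimes individual trajectories are
phase-sensitive, so convergence-order checks are run over short horizons
or with RK4.

**Spectra and correlation.**  Temporal power spectra are node-averaged
periodograms of E after discarding a configurable transient (default: the
first 20% of samples), without detrending (a constant signal then has all
its power exactly in the zero-frequency bin); frequencies are in cycles
per τₛ, and the dominant frequency is the largest nonzero-frequency peak.
Seed-based maps are Pearson correlations of each seed's E series with
every node's; zero-variance nodes yield NaN (an explicit undefined marker)
rather than a fabricated zero.

## Linear (Hopf) stability

The spatially uniform fixed point solves d_E E = S(α_EE E − α_IE I) and
d_I I = S(α_EI E − α_II I) (diffusion gains are 1 at λ = 0); it is found
by multi-start root finding with Newton polishing to residual < 1e−10.
The uniform state is exactly invariant under diffusion only for the
combinatorial Laplacian, so the stability analyses default to that form;
with the normalized form on an irregular graph the "uniform fixed point"
is an approximation and the per-harmonic linearization is heuristic.

Restricted to harmonic λ, the linearization is the 2×2 matrix

    J(λ) = (1/τₛ) [ −d_E + α_EE g_EE(λ) S′(u_E)    −α_IE g_IE(λ) S′(u_E) ]
                  [  α_EI g_EI(λ) S′(u_I)          −d_I − α_II g_II(λ) S′(u_I) ]

with u_E, u_I the sigmoid arguments at the fixed point.  Cells of a
(swept σ, λ) grid are classified from trace τ and determinant δ:
saddle (δ < 0) → unstable_monotonic; |τ·τₛ| < 1e−3 with δ > 0 →
hopf_critical (the tolerance is resolution-appropriate for typical grids
and configurable); τ > 0 with τ² < 4δ → unstable_oscillatory; τ > 0
otherwise → unstable_monotonic; else stable.  Any of the four σ's can be
swept; which one is informative depends on where the graph's spectrum
lies — on the 162-vertex fixture the σ_EE sweep is the one that crosses
the oscillatory boundary within the available eigenvalues.

Predictions are cross-validated by `perturbation_growth_rate`: the full
nonlinear model is integrated from the fixed point plus a small multiple
(1e−5) of one harmonic seeded along the leading Jacobian eigendirection,
and the log amplitude of the (E, I) projection onto that harmonic is
regressed against time within the linear-regime window (amplitude capped
at min(10³·ε, 0.05) before nonlinear saturation or cross-mode seeding can
contaminate the fit).  The fitted rate's sign is compared with the
predicted leading real part.

## Lyapunov analysis

The integrated (typically limit-cycle) trajectory is perturbed at time t*
by i.i.d. symmetric uniform noise on E and I, independently n_perturb = 10
times (default amplitude: 1% of the reference E range).  L(t) is the
worst case over copies and nodes of |perturbed − unperturbed| across both
populations; it is identically zero before t* by construction.  A stable
limit cycle re-attracts perturbed copies only up to a small permanent
phase shift, so raw L(t) plateaus at a phase-offset floor; the verdict
therefore uses, by default, a phase-aligned tail distance (each tail
sample compared to the best-matching reference sample within a small
time-shift window) over the last 20% of post-perturbation samples, and
requires sup L finite and tail mean < ε with ε defaulting to the noise
amplitude — i.e. the perturbation must not have grown.  Raw and aligned
tail means are both reported.

## Synthetic fixtures: what they do and do not show

The fixture module generates (i) cycle-graph "meshes", whose Laplacian
eigenbasis is the discrete Fourier basis in closed form — the analytic
oracle for eigensolvers, transforms and reconstruction; (ii) icospheres
(12·4^s vertex closed triangulations) as the curved-surface stand-in, with
uniformly random planted long-range edges standing in for fibre tracts;
and (iii) binary maps thresholded from a chosen harmonic at a quantile
(ties broken by vertex index), giving a matching problem whose answer is
known by construction.  Generation is a pure function of (spec, seed).

Fixture scale was chosen to exercise every pipeline within interactive
runtimes: 42-vertex graphs for matching/null statistics (40 harmonics, 200
rewirings), 162 vertices for basis completeness, dynamics and stability.
Because diffusion extents multiply Laplacian eigenvalues, graph scale
shifts which harmonics a given σ can destabilize: the studied σ presets
place their oscillatory bands over small λ, so the 162-vertex dynamics
runs use the symmetric normalized Laplacian (low spectrum ~0.075–0.2,
inside both presets' bands), while the stability cross-validation uses the
combinatorial form (exact uniform fixed point) and sweeps σ_EE.

These fixtures share none of the statistics of real cortical geometry or
DTI fibre anatomy — no folding, no distance-dependent fibre probability,
no hemispheric structure.  Passing tests therefore demonstrate
correctness of the machinery (exact linear algebra, calibrated null
statistics, dynamics faithful to the stated equations, reproducibility),
not the empirical claim that any particular brain network matches any
particular harmonic of a real connectome; reproducing subject-level
results requires subject data and cluster-scale null ensembles that are
out of scope here.

## Numerical conventions

All on-disk vertex indexing is 0-based; vertex order is the single source
of alignment across artifacts.  Floating-point text output uses `%.17g`
(exact float64 round trip), manifests contain no timestamps, and every
random draw flows from an explicit seed, so identical configurations
produce byte-identical outputs.  Label 0 in network label maps is the
unassigned/medial-wall class and produces no map.  Degenerate inputs fail
loudly: constant maps cannot be binarized, the zero pattern has no
normalized error curve, zero-variance nodes give NaN correlations, and
eigensolver postcondition violations raise rather than warn.
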