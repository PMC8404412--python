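# Methods

## Model

`fedgtf` fits a rank-R canonical polyadic (CP) model to an order-D sparse
tensor under a generalized element-wise loss:

    minimize  F(A, X) = Σ_{i∈I} f(A(i), X(i)) + Σ_d r_d(A^(d)),
    subject to  A = Σ_{r=1..R} A^(1)(:,r) ∘ … ∘ A^(D)(:,r),

where `I` is the set of **all** I_Π = Π_d I_d entries.  Entries absent from
the COO input are data zeros, not missing values — the generalized-CP
convention for sparse count/binary tensors.  Two losses are built in:

* `least_squares`: f(m, x) = ½(m − x)², derivative m − x, for nonnegative
  count data;
* `bernoulli_logit`: f(m, x) = log(1 + e^m) − x·m, derivative σ(m) − x,
  for binary data.  Both are computed overflow-safely (`logaddexp`, `expit`).

Regularizers are per-factor: `frobenius_sq` (λ‖A‖_F², smooth, gradient 2λA)
and `l1` (λ‖A‖₁, nonsmooth, handled by a soft-threshold proximal step with
threshold γ[t]·λ — the standard proximal-gradient scaling).

## Federated setting

The tensor is horizontally partitioned: client k holds a slab of I₁ᵏ
patient rows over the full feature modes, Σ_k I₁ᵏ = I₁.  The patient factor
block of each client is private: it is updated purely locally and the
engine's single serialization path refuses mode-1 matrices outright, so no
patient factor rows or patient-mode gradients ever enter a message.  When
the sampled block is mode 1, the round is communication-free.

## Stochastic gradients

The partial gradient w.r.t. A^(d) is ∇F = Y_<d> H_d with Y(i) = ∂f/∂m at
entry i and H_d the Khatri-Rao product of the other factors.  The engine
samples |S| fibers (columns of the mode-d unfolding) uniformly without
replacement and forms

    G^(d) = (I_Π/I_d)/|S| · Y_<d>(:,S) H_d(S,:).

The leading factor makes the estimator unbiased for the full-entry sum; the
bare sampled product (the literal unscaled form) is available via
`rescale=False` / `--no-gradient-rescale`.  Rows of H_d are assembled from
the inverse of the unfolding index map — the full Khatri-Rao product is
never materialized and no intermediate exceeds I_d × |S|.  Per-client
samples are drawn from the client's own local fiber space, independently
across clients and iterations, from per-client RNG streams spawned off the
master seed.  |S| is clamped to the local fiber count when a slab is
smaller than the requested budget.

## Algorithms

**FedGTF-EF** (per-round compression).  Each iteration the server samples a
block d (uniformly; cyclic and cyclic-shared orders are available).  For a
shared block each client sends Δ = Compress(γ[t]·G + E), the server
broadcasts the K-client mean, the factor is updated (gradient step, or prox
for `l1`), and the error memory becomes E ← P − Δ.  The 1/K in the server
average is as printed in the algorithm; users comparing against a
centralized run on the pooled tensor should scale γ by K.

**FedGTF-EF-PC** (periodic communication).  Clients step local copies of
the sampled block; every τ-th iteration they compress the accumulated
displacement from the server copy (plus error memory), the server applies
the mean and broadcasts, and clients adopt the server copy.  Error memories
are untouched at non-communication rounds.  Only the sampled block is
synchronized at a communication round; other blocks keep their drift until
they coincide with one — the literal reading of the update rule.  The
periodic variant is restricted to smooth regularizers (the algorithm has no
proximal branch).  At τ = 1 it coincides with FedGTF-EF up to one floating
rounding per update (the displacement is computed as (A_g − (A_g − γG)) + E
rather than γG + E); trajectories agree to ~1e-15 per iteration and the
equivalence test asserts 1e-12.

The ablation baselines are the same loop under configuration: DistBrasCPD
(identity compressor), DistBrasCPD-comp (sign), DistSGD-EF /
DistSGD-EF-comp (all blocks every iteration, gradients evaluated jointly at
the iteration's starting point).  Runs are deterministic given the config:
a master `SeedSequence` spawns the block sequence, the initialization, the
partition shuffle and one stream per client.  Factors start i.i.d.
uniform(0,1)/√R, drawn once globally so shared modes are identical
everywhere and a client's patient rows do not depend on K.  The run length
is exactly T iterations (t = 0..T−1), keeping bit totals clean multiples of
the cycle lengths; there is no convergence test, matching the fixed-budget
formulation and keeping accounting deterministic.  Non-finite factors abort
the run with a diagnostic.

## Compression and the bit model

The sign compressor sends sign(P) (1 bit per element, sign(0) encoded as a
zero that still occupies its bit) plus one 32-bit scale ‖vec(P)‖₁/n.  It is
a δ-approximate compressor with δ = ‖P‖₁²/(n‖P‖₂²) ∈ [1/n, 1], tight.  The
identity compressor is the 32-bit full-precision baseline.  Arithmetic runs
in float64 throughout; the bit model deliberately prices messages at the
32-bit word the reduction ratios presuppose.

Uplink accounting: every (iteration, client, block) row records payload and
scale bits.  Reductions are reported payload-only by default (the scale
scalar is asymptotically negligible and excluded from the closed-form
ratios); `include_scale=True` counts it.  The closed form is

    reduction = 1 − (1/D if block-level)(1/32 if element-level)(1/τ if round-level),

i.e. 99.22% for D=4 single-block sign, 99.90% adding τ=8.  The all-block
baseline is priced at all D blocks per client per round at full size (a
dense gradient all-reduce, including the patient block) — this is the
baseline the closed-form ratios describe, and with equal mode sizes and
cyclic shared-mode sampling the measured ratio reproduces them *exactly*,
in integer arithmetic.  Block-randomized runs log 0 bits on patient rounds,
which is why a random-order run measures slightly *more* reduction than the
closed form (it skips mode-1 entirely about 1/D of the time);
`measured_reduction(..., shared_only=True)` drops patient-block rows from
both sides for a shared-modes-only comparison.  Percentages print at two
decimals, round-half-even.

## Synthetic data

`generate_instance` draws ground-truth factors i.i.d. uniform(0,1), samples
`round(density · I_Π)` nonzero positions uniformly without replacement
(default density 1e-4, the sparsity regime of diagnosis × procedure ×
medication co-occurrence tensors), and fills values by loss type:
least-squares values are the model values plus optional truncated Gaussian
noise (level expressed relative to the mean absolute model value, default
1%); logit values are Bernoulli draws through σ(m − offset) with the offset
at the median model value so the success rate at sampled positions is near
½, storing the drawn 1s only.  Instances are bit-reproducible from the spec
and seed.

An important consequence of the zero-as-data semantics: at density p < 1 a
"noiseless" instance is the low-rank tensor M masked to p of its entries,
and the full-entry least-squares minimizer concentrates near p·M, not M.
Parameter recovery against the generating factors is therefore only a
meaningful target for dense (density = 1) instances, where the pipeline
reaches relative reconstruction errors of ~1e-3 under 1-bit compression;
at p = 0.05 any optimizer lands at relative error ≈ 0.95 by construction.
`recovery_error` compares the two CP reconstructions directly, which is
exactly invariant to the permutation/scale-redistribution ambiguity;
`match_components` provides a greedy cosine component matching as a
diagnostic heuristic.

What the generator does not emulate: real coding vocabularies, longitudinal
visit structure, correlated missingness, inter-client distribution shift.
Green tests on these instances validate optimization, compression and
accounting — not clinical phenotype quality.

## Defaults and problem sizes

Defaults: R = 5, |S| = 128, constant γ = 0.05 (chosen for the sparse worked
example below; dense instances need γ ≈ 0.005 since gradient magnitudes
scale with the active entry count), γ/√(T+1) schedule available, τ = 8 for
the periodic variant, K = 2–4.  The test suite and the reproduction script
use desk-scale tensors (8⁴ to 20×15³, T ≤ a few thousand) — communication
ratios are size-independent by construction, and the equivalence and oracle
properties they verify are exact, so small shapes lose no generality.

## Known limitations

* Simulation only: no transport, stragglers, dropout, secure aggregation or
  differential privacy.
* The objective evaluation streams over all I_Π entries; it is exact but
  meant for desk-scale monitoring (a sampled unbiased estimate is available
  for larger shapes).
* Greedy component matching can mispair near-collinear components; the
  headline recovery metric does not depend on it.
* Wall-clock/memory profiling is out of scope; cost claims are structural
  (no intermediate beyond I_d × |S|).
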