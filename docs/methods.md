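# Methods

## Problem

Experimentally confirmed miRNA–disease associations form a sparse binary
matrix `Y ∈ {0,1}^{p×q}` (p diseases × q miRNAs).  Link prediction scores
the unknown entries so that true-but-unobserved associations rank above
true negatives.  Two side kernels inform the prediction: a disease
semantic similarity `Sd` (p×p) computed from MeSH-style ancestor DAGs, and
a miRNA functional similarity `Sm` (q×q) computed by best-match-averaging
disease similarities over the miRNAs' association profiles.

## Disease semantic similarity

Each disease term d has an ancestor DAG.  Its contribution to its own
semantic value is 1; an ancestor t contributes
`D_d(t) = Δ · max{ D_d(t′) : t′ a child of t within the DAG }`, so
contributions decay geometrically with distance from d and multiple paths
take the maximum, not the sum.  The semantic value is `DV(d) = Σ_t D_d(t)`
and the similarity of two diseases is

    S(d_i, d_j) = Σ_{t ∈ T_i ∩ T_j} (D_i(t) + D_j(t)) / (DV(i) + DV(j)).

Δ defaults to 0.5, the conventional value for this similarity family; it is
exposed in the config.  "Children of t" means children within the
disease's own DAG, because the node and edge sets are defined per disease.

miRNA functional similarity is the best-match average: for association
profiles D1, D2,

    sim = [Σ_{d∈D1} max_{d′∈D2} Sd(d,d′) + Σ_{d∈D2} max_{d′∈D1} Sd(d,d′)]
          / (|D1| + |D2|).

A miRNA with no training associations gets a zero row/column (warned); a
precomputed similarity matrix can be supplied instead and takes precedence.

## Submodels

All three submodels score every pair; their outputs are min–max normalized
to [0,1] per matrix before any fusion, because they live on incompatible
scales (least-squares fits vs probabilities).

**CMF** — collaborative matrix factorization.  Minimizes

    ‖Y − ABᵀ‖²_F + λl(‖A‖²_F + ‖B‖²_F) + λm‖Sm − AAᵀ‖²_F + λd‖Sd − BBᵀ‖²_F

over miRNA factors A (q×k) and disease factors B (p×k), by alternating
closed-form ridge block updates with the similarity Gram terms lagged one
half-iteration.  Because the lagged update alone does not guarantee
descent, each block update is damped (step halving toward the previous
iterate) until the objective does not increase, making the objective trace
monotone by construction.  Initialization is the truncated SVD of Y, so
the fit is deterministic.  Defaults: k=50, λl=0.5, λm=λd=0.125,
100 iterations, tolerance 1e−6 on the relative objective change.

**NRLMF** — neighborhood-regularized logistic matrix factorization.  Link
probability `P_ij = σ(u_i v_jᵀ)`; observed positives are up-weighted by
c ≥ 1; the loss is

    Σ_ij (1 + c·y_ij − y_ij)·softplus(u_i v_jᵀ) − c·y_ij·u_i v_jᵀ
      + ½tr[Uᵀ(λd I + α L_d)U] + ½tr[Vᵀ(λt I + β L_t)V],

where L_d, L_t are unnormalized Laplacians (D − W) of k-NN–sparsified,
symmetrized similarity graphs.  Optimized by full-batch AdaGrad from a
seeded Gaussian init (s.d. 1/√r); the iterate with the lowest objective is
returned.  The softplus form avoids overflow.  Defaults: r=50, c=5,
λd=λt=0.625, α=β=0.1, k=5 neighbors, learning rate 0.1, 100 iterations.
An optional flag replaces the factors of entities with no training
positives by the similarity-weighted mean of their neighbors' factors
(off by default).

**LapRLS** — Laplacian regularized least squares.  One closed form per
side with the *normalized* Laplacian `L = I − D^{−1/2} W D^{−1/2}`:

    F_d* = W_d (W_d + β_d L_d W_d + ε I)⁻¹ Y,
    F_m* = W_m (W_m + β_m L_m W_m + ε I)⁻¹ Yᵀ,
    F*   = (F_d* + F_m*ᵀ)/2.

The printed stationarity condition of this functional is typo-ridden in
parts of the literature; the implementation follows the standard
derivation (∂/∂α of ‖Y − Wα‖² + β tr(αᵀWLWα) = 0 ⇒ α* = (W + βLW)⁻¹Y),
which the tests verify against direct numerical minimization.  Kernels are
the two similarity matrices.  Defaults β_d=β_m=0.3, jitter ε=1e−6.

## Q-learning fusion

The final score is the convex combination `F* = a·F1 + b·F2 + c·F3` of the
normalized submodel scores.  The weight triple lives on a discretized
3-simplex with resolution h (stored as integer grid units, so a+b+c=1
holds exactly).  Actions are the six directed one-step weight transfers
plus STAY; an episode starts from the grid-rounded equal-weight state.
Each step fuses with the candidate weights, computes the AUC on a held-out
validation slice (validation positives plus an equal number of sampled
unknown pairs), and rewards the *sign* of the AUC change: +1 if it
strictly improved, −1 otherwise (a tie counts as −1).  The Q-table is
updated off-policy:

    Q(s,a) ← Q(s,a) + α_q [ r + γ max_{a′} Q(s′,a′) − Q(s,a) ].

Exploration is ε-greedy with multiplicative per-episode decay; greedy ties
break to the first action index, so training is deterministic given the
seed.  The returned weights are the *visited state with the highest
validation AUC* — the deterministic reading of "approach the optimal
solution" — which guarantees the result never validates below the
equal-weight start.  Defaults: h=0.01 (5151 grid states), α_q=0.1, γ=0.9,
ε=0.2 decaying ×0.99, 200 episodes × 50 steps.  An optional post-hoc line
search (`refine=True`) sweeps weight pairs continuously around the best
grid state to emit 4-decimal weights; it is separate from, and never
feeds back into, the Q-learning.

Validation AUCs are cached per state, so the cost of a run is dominated by
the number of *distinct* states visited, not the step count.

## Evaluation protocol

The cross-validation unit is the known association (pair-level masking).
Positives are shuffled (seeded) and partitioned into k=5 test sets; each
fold's remaining positives are split 8:1 into submodel training and
weight validation.  Reported AUC/AUPR for a fold score the fold's test
positives against *all* unknown pairs of the matrix (no sampling, hence
deterministic given folds); negative sampling is confined to the RL loop.
Per-method results are averaged over folds by default (`auc_mode=mean`);
`pooled` concatenates scores across folds first.  AUC is the Mann–Whitney
statistic (ties half-credit); AUPR is the step-wise, non-interpolated
area.  Both are delegated to scikit-learn and cross-checked in the tests
against an O(n²) pair-counting oracle and an exhaustive threshold sweep.
The equal-weight (⅓,⅓,⅓) fusion is always evaluated alongside as the
control for the learned weights.

Candidate ranking for one disease sorts its non-training miRNAs by score,
ties broken lexicographically by miRNA label for determinism.

## Synthetic data

The generator plants the structure all three submodels assume: latent
factors G_d (p×rank), G_m (q×rank) with standard-normal entries; true
scores σ(G_d G_mᵀ); Y = the top `density` fraction of entries;
similarities are row-cosine kernels of the same factors (clipped to [0,1],
unit diagonal).  `flip_noise` flips a fraction of labels after
thresholding; `sim_noise` adds symmetric Gaussian noise to the kernels,
dialing down how informative similarity is about association.  Everything
is deterministic per seed.

Default study conditions are p=q=60, rank 4, density 0.1, no noise —
small enough that the full 5-fold comparison runs in seconds, large
enough that chance-level AUC is distinguishable from recovery.  What
passing on this generator shows is that the pipeline recovers a planted
low-rank structure when similarity is informative; it does *not* show
performance on real association data, where similarity kernels are
noisier, the positive rate is far lower, and name matching between
resources is itself a source of error.

`desk_scale_config()` provides the parameter block used at this scale:
latent ranks 10 (CMF) and 5 (NRLMF), NRLMF with learning rate 0.5,
300 iterations and α=β=0.5 (stronger Laplacian smoothing suits the highly
informative synthetic kernels), Q-learning 100 episodes × 40 steps.  The
library-wide defaults above target matrices with hundreds of rows.

## Numerical choices

- Similarity readers symmetrize `(M+Mᵀ)/2` only below asymmetry 1e−8 and
  force the diagonal to 1, logging changes; anything worse is an error.
- Singular normal equations in CMF fall back to a 1e−8 ridge jitter.
- `laprls_solve` reports the condition number when a system stays singular
  after the jitter.
- NRLMF aborts with diagnostics if the objective goes non-finite.
- Reward ties (ΔAUC = 0 exactly) score −1, the literal "otherwise" rule.
- Zero-degree nodes in the normalized Laplacian are kept isolated
  (unit diagonal, zero off-diagonal).
- Q-table greedy ties break to the lowest action index.

## Limitations

- The Q-learning state space is a coarse grid; the optional refinement is
  a local search and inherits whatever the grid search found.
- Fusion weights are learned per fold from a small validation slice; with
  few positives the argmax-AUC state can overfit that slice.
- No Gaussian interaction-profile kernels, no kernel fusion, no
  neighborhood smoothing by default — the submodels are deliberately the
  plain variants.
- Disease/miRNA name reconciliation across resources is the caller's
  responsibility; readers only trim and case-fold.
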