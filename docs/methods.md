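# Methods

## Model

`normgame` solves a two-stage game between `n ≥ 2` women and their male
partners. Stage 1: every woman `i` simultaneously chooses a nonnegative
effort `e_ki` toward every man `k` (the effort matrix is stored with
`E[k, i]` = effort of woman `i` on man `k`; a man's attitude depends only on
his own row). Stage 2: every man chooses a violence level. Because the
stage-2 payoff is strictly concave quadratic in `v_i`, men's behaviour
collapses to the linear best response `v_i = (1/c_i) Σ_k n_ik a_k`, and the
subgame-perfect equilibrium reduces to a simultaneous-move game among women
whose payoff gradients (`foc_residual`) incorporate that best response.

Modelling assumptions worth keeping in view:

- **Attitudes and violence are unbounded reals.** Attitudes `a_j` and
  violence `v_i` may go negative; negative `v_i` can be read as actively
  protective behaviour. No clipping is applied anywhere, and equilibrium
  quantities are reported unmodified even when negative.
- **Attitude functions are decreasing; strict convexity is advisory.** The
  contract asks for strictly decreasing, strictly convex attitude functions.
  The linear model used by all scenario presets is only weakly convex; it is
  accepted, and `LinearAttitudeModel.validate()` flags the weak convexity as
  a `UserWarning` rather than an error. `ExponentialAttitudeModel`
  (`a_j = a0_j exp(−Σ f_ji e_ji)`) is a strictly convex alternative that
  also exercises the solver's general path.
- **Welfare is zero-tolerance utility.** All normative comparisons use
  `W_i = −s_i v_i − ½ Σ_k d_ki e_ki²`, i.e. the baseline utility with the
  tolerance `t_i` forced to zero and all altruism terms removed. Tolerance
  affects behaviour, never welfare accounting.
- **Effort-cost subscripts.** The cost rate `d_ki` is read as the rate for
  *woman i's* effort on man `k` — each woman pays for her own efforts. This
  reading is the one under which the first-order conditions reproduce the
  homogeneous-community equilibrium (`e = 0.05` in the baseline preset).

## Parameters

| symbol | meaning | domain | preset default |
|---|---|---|---|
| `n` | couples in the community | `≥ 2` | 10 (20 in Scenario 2) |
| `s_i` | suffering per unit violence | `> 0` | 1 (1.5 in Scenario 2) |
| `t_i` | tolerance of own violence | `[0, 1)` | 0.5 |
| `c_i` | marginal cost of violence | `> 0` | 1 (0.4 in Scenario 2) |
| `n_ij` | norm payoff rate | `> 0` | 1 (5 in Scenario 2) |
| `d_ki` | effort-cost rate | `> 0` | 1 |
| `a0_j`, `f_ji` | attitude intercept / slope | —, `≥ 0` | 2, 0.1 |
| `b, η, ρ` | altruism weights | `≥ 0` | 0 (swept) |

All quantities are in the model's abstract effort/violence/utility units.
Block scale factors (`ScaleFactors`) multiply whole parameter groups:
`σ→s, τ→t, γ→D, κ→c, ν→N, α→slopes`. `τ` and `α` may be zero (zero
tolerance and zero effectiveness are legal parameter values, and the
percent-change sweeps reach them); `σ, γ, κ, ν` must stay strictly positive
to preserve the sign constraints of the underlying parameters.

## Solvers and numerical choices

**Closed form (linear attitudes).** Entrywise
`e_ki = s_i(1−t_i) n_ik f_ki / (d_ki c_i)`, with the process weight added to
the numerator (`+b`), the empathy term adding other women's marginal
suffering (`+η Σ_{j≠i} s_j n_jk f_ki / c_j`), and reciprocity solved per man
as the linear system `(diag(d_k·) − ρ·11ᵀ) e_k· = base`. Negative candidates
are projected to zero with an active-set re-solve (with all-positive
parameters they do not arise; zero slopes produce exact boundary entries).
Reciprocity existence is decided by a positive-definiteness test of each
per-man system matrix, with relative eigenvalue tolerance `1e−9`; in the
symmetric unit-cost case this reproduces the `ρ < 1/n` threshold exactly.

**Damped best-response iteration (any attitude model).** Each sweep replaces
every effort entry with the woman's exact best response given all other
entries (a linear formula when the model's partials are effort-independent,
otherwise bracketed Brent root-finding on the scalar first-order condition),
then blends old and new with damping 0.5. Defaults: tolerance `1e−10` on the
max entry change, 10 000 iterations, divergence bound `max|e| > 1e8`.
Baseline/process/empathetic best responses are constant under linear
attitudes, so the damped iteration converges geometrically at rate 0.5
(~35 sweeps); reciprocity slows it near the existence boundary, which is why
the boundary itself is detected by the positive-definiteness pre-check
rather than by waiting for the iterates to escape the magnitude bound (at
exactly `ρ = 1/n` the best-response map drifts linearly and would escape
only after ~10⁹ sweeps).

**Uniqueness probe.** `check_uniqueness` re-solves from seeded uniform
random starting matrices and reports the maximum pairwise distance between
converged profiles (`unique` below `1e−6`); any non-convergent run makes the
verdict `inconclusive`.

**Welfare-marginal conditions.** Equilibrium sensitivities to the altruism
weights are central finite differences of the *solved* equilibrium with
relative step `1e−4`; at weight 0, where the admissible range ends, the
second-order one-sided stencil `(−3f(x) + 4f(x+h) − f(x+2h))/(2h)` is used
instead — exact for the quadratic-in-weight welfare paths of the linear
model. Each mechanism's printed welfare-improvement inequality is evaluated
per woman with the tolerance weights `τ_ji` (`t_i` on own-dyad terms, 1 on
cross-dyad terms); the conditions are local (derivative at a point), which
is how the monotonicity claims are operationalised. Two printing ambiguities
in the process-benefit condition were resolved by consistency with the
structurally identical empathy condition and verified against the sign of
the numerically computed welfare gradient at every tested point.

**Social-dilemma certificate.** At a converged interior equilibrium, the
certificate search raises two women's efforts on the designated men by a
common increment δ (men re-best-respond, everything else fixed), scanning 50
log-spaced points in `[1e−4, 1]` and refining once by a factor-3 window
around the best point. The certificate reports the increment and both
welfare gains; the theory guarantees only existence of such a deviation, not
its size.

## Scenario presets and the heterogeneity generator

Scenarios 1–3 are homogeneous communities (parameters above); their sweep
axes are percent-change grids on tolerance (−100 %..+90 %), effectiveness
(±100 %), effort cost (−95 %..+100 %, since zero cost is inadmissible) and
violence cost (0..+300 %), and altruism grids `b, η ∈ [0, 1]`,
`ρ ∈ [0, 0.095]` (the equilibrium ceases to exist at 0.1).

Scenario 4 perturbs the homogeneous community couple by couple: each
targeted parameter of couple `i` is multiplied by an independent factor
drawn log-uniformly from `[1/3, 3]` — the symmetric distribution on the
multiplicative scale implied by "threefold reduction to threefold increase",
with median factor 1. The default targets are the per-couple scalars
`s_i` and `c_i`. The targets are a configurable switch (`d` and `n` columns
and attitude slopes `f` can be added), but the default is deliberate:
community-level outcomes involve sums over couples of these factors, and
sums of `n` independent log-uniform factors concentrate at the factor
*mean* (≈1.21), not its median (1). Perturbing the effort-cost or
norm-payoff matrices therefore inflates the community's median violence
response by ~20–50 % relative to the homogeneous baseline, destroying the
defining feature of the heterogeneous experiment — that median outcomes
mirror the homogeneous community (violence drop ≈10 units and welfare gain
≈5 per unit of intrinsic benefit) while the spread across women widens.
Tolerance is never perturbed: a factor of up to 3 could push `t_i` past 1.
The default seed is 20210301 and is recorded in every scenario-4 output.

The Scenario-4 summary tables report min/median/max across women of
*changes from the zero-altruism baseline* (not outcome levels): the
worst-off woman in the change distribution is the one with the least to
gain, and her welfare gain peaks at a much smaller altruism weight than the
median woman's — at intrinsic benefit +1.0 she is typically worse off than
with no altruism at all, while the median and best-off women still gain.

What the generator does *not* emulate: correlated risk factors across
couples (each factor is independent), heavy-tailed or bimodal parameter
distributions, network structure in who can persuade whom, and any change
over time. Passing tests show the solver and the comparative conclusions are
correct *under the model's assumptions*; they are not evidence about any
real community.

## Problem sizes

All computations run on desk scale: communities of 10–20 couples, sweeps of
20–40 grid points, 100 random communities for the heterogeneous medians and
solver cross-checks, a 3 000-point grid (step 5×10⁻⁵) for the reciprocity
existence boundary. The full test suite runs in a few seconds; the
acceptance script in about two.

## Known limitations

- The violence-cost comparative static in the strong-norms community is
  non-monotone with an analytic interior peak at `c = 0.75`
  (`v(c) = 200/c − 75/c²`), an 87.5 % increase over the preset `c = 0.4`;
  qualitative descriptions of this sweep as peaking after the cost "more
  than doubled" depend on the axis convention and are not reproduced
  pixel-for-pixel — the tables report the analytic peak.
- Men are not strategic effort-exerters, there is no belief updating or
  misperception of norms (pluralistic ignorance), and no dynamics; the
  equilibrium is a statics comparison device.
- Existence under reciprocity is decided by the positive-definiteness test;
  for non-linear attitude models far from the linear regime this is a
  necessary-condition heuristic inherited from the linearised system, and
  the divergence bound of the iterative solver is the backstop.
- The boundedness condition under which equilibrium uniqueness is guaranteed
  is assumed, not verified, for user-supplied attitude models.
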