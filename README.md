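# normgame

A game-theoretic model of women's collective action to change the social
norms that sustain domestic violence.

## The problem

In many communities, men's use of violence against female partners is
rewarded or sanctioned by other men through social norms. Women can push
back — by persuading men directly, enlisting relatives, involving local
authorities — but each woman's effort mainly benefits *other* women's
relationships, because the men she influences also stop encouraging each
other's violence. Those positive externalities make abstention individually
rational even though every woman would gain if all acted: collective action
against domestic violence is a **social dilemma**. `normgame` lets public
health modellers and community-mobilisation researchers explore this
mechanism quantitatively, and evaluate altruism-based interventions that can
dissolve the dilemma.

## The model

A community holds `n` couples. The game has two stages:

1. each woman `i` picks persuasion efforts `e_ji ≥ 0` toward every man `j`;
2. each man `i` picks a violence level `v_i`.

Man `i`'s attitude `a_i(e_i1, …, e_in)` is strictly decreasing in the effort
aimed at him. His payoff and best response are

    U_hi = (Σ_j n_ij a_j) v_i − ½ c_i v_i²   ⇒   v_i* = (1/c_i) Σ_j n_ij a_j,

where `n_ij > 0` are norm payoff rates (`n_ii` his intrinsic rate) and `c_i`
his marginal cost of violence. Woman `i`'s baseline utility is

    U_wi = −s_i (1 − t_i) v_i − ½ Σ_k d_ki e_ki²,

with suffering rate `s_i`, tolerance `t_i ∈ [0,1)` and effort-cost rates
`d_ki`. Her welfare `W_i` is the same expression with `t_i` set to zero
(tolerance shaped by long-term abuse is not credited normatively). With
linear attitudes `a_j = a0_j − Σ_i f_ji e_ji` the unique subgame-perfect
equilibrium is available in closed form, entrywise

    e_ki* = s_i (1 − t_i) n_ik f_ki / (d_ki c_i),

and a damped best-response iteration handles general attitude models. Three
altruism mechanisms extend `U_wi`: an intrinsic per-unit benefit of acting
(`b`, process-based), a weight on other women's suffering (`η`, empathetic),
and a motive to match other women's efforts (`ρ`, reciprocal). Reciprocity
couples women's first-order conditions; the equilibrium exists only while
`diag(d_k·) − ρ·11ᵀ` stays positive definite (`ρ < 1/n` in the symmetric
unit-cost case).

## Worked example

The bundled Scenario 1 community (`n=10`, `s=c=n_ij=d_ij=1`, `t=0.5`,
`a_j = 2 − 0.1 Σ e_ji`) models widespread, influential pro-violence norms
and weak persuasive power:

```text
$ normgame solve --scenario 1
 woman  violence  effort  utility  welfare
     1      19.5    0.05  -9.7625 -19.5125
     ...
method=closed_form converged=True iterations=0 max_foc_residual=0.000e+00
```

Each woman exerts a token 0.05 units per dyad and endures violence 19.5 —
yet the equilibrium is a dilemma, certified by exhibiting a joint deviation
that pays for both deviators:

```text
$ normgame certify-dilemma --scenario 1
social dilemma certified: joint deviation delta=0.149258 raises welfare by
0.0112497 (woman 1) and 0.0112497 (woman 2)
```

Intrinsic motivation mobilises the community: at `b = 1` per-dyad effort
rises to 1.05, violence halves to 9.5 and welfare improves from −19.5125 to
−15.0125 per woman:

```text
$ normgame solve --scenario 3 --variant process --weight 1.0
 woman  violence  effort  utility  welfare
     1       9.5    1.05   0.2375 -15.0125
     ...
```

The welfare-marginal condition shows where to stop — at `b = 1` the marginal
effort cost already exceeds the returned benefit (welfare peaks at
`b = 0.95`):

```text
$ normgame check-propositions --scenario 3 --variant process --weight 1.0
...
welfare-improvement condition fails for all women
```

`normgame run-scenario {1|2|3|4}` writes the full sweep tables (CSV) behind
the four scenarios, including the heterogeneous-community min/median/max
summary of Scenario 4; `examples/scenario*.json` document the config-file
schema.

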