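# pl2design

Optimal experimental design for ODE models via two-dimensional profile
likelihoods.

Dynamic models in systems biology — reaction networks written as ordinary
differential equations — are routinely fit to sparse, noisy measurements,
and the resulting parameter estimates can be so uncertain that the profile
likelihood never crosses its confidence threshold: the parameter is
*practically non-identifiable*. `pl2design` answers the follow-up question
an experimenter actually has: **which single measurement (which observable,
at which time, under which perturbation) will best reduce the uncertainty
of the parameter I care about?**

## The method

For a model with parameters θ and data Y, the profile likelihood of a
target parameter β with nuisance parameters ω is

    PL(β | Y) = −2 ln [ L(β, ω̂(β) | Y) / L(θ̂ | Y) ],

and `{β : PL(β) < icdf(χ²₁, α)}` is an α-level confidence interval (Wilks).
The uncertainty in β is summarized across *all* confidence levels by the
average confidence-interval width

    w̄(β | Y) = ∫₀^0.95 w(CI_α) dα,

with bounds-clipped widths so that non-identifiability is penalized rather
than ignored.

A candidate measurement D = {g, t, u} has an unknown outcome z. The
validation (prediction) profile likelihood VPL(z | Y) — obtained by
refitting all parameters on Y ∪ {z} — says which outcomes are plausible
given today's data. Combining both gives the two-dimensional profile

    PL2D(z, β) = PL(β | Y ∪ {z}) + VPL(z | Y),

whose horizontal cross-sections are the post-measurement profiles of β for
each hypothetical outcome. Sampling outcome rows at equidistant predictive
confidence quantiles (capped at the 95% predictive level) turns the
predictive-density-weighted expectation into a plain mean:

    W(β | Y, D) = mean over rows z of w̄(β | Y ∪ {z}),

the **expected average profile width** — the design criterion. The best
next experiment is `D* = argmin_D W(β | Y, D)`, and a sequential loop
(fit → profile → rank candidates → measure D* → repeat) drives all
resolvable non-identifiabilities out of the model.

Everything is plain frequentist machinery: no parameter priors are needed,
and the non-linearity of the model enters through actual re-optimization
rather than a quadratic (Fisher-matrix) approximation.

## Worked example: the ABC chain

The built-in fixture is the conversion chain A → B → C with rates p1, p2
and unknown initial amount A0 (log10 scale, bounds [−5, 3]). Only B and C
are observed — twice each, early in the dynamics, with log-normal noise
σ_log = 0.2:

```
$ pl2design make-fixture abc --seed 1 --out demo/
$ cat demo/data.csv
observable,time,perturbation,value,sigma
B,3.0,default,-0.8521010861963828,
B,6.0,default,-0.5523602488406685,
C,3.0,default,-1.646060089411026,
C,6.0,default,-1.4334225122607216,

$ pl2design fit abc demo/data.csv --starts 20 --seed 0 --out demo/fit.json
fit: objective=1.33078 (20 local optimizations)

$ pl2design profile abc demo/data.csv --parameter p1 --out demo/prof_p1
profile of p1: practically_non_identifiable (12 optimizations)
```

The four data points pin down p2 but not p1: its 95% interval,
[−3.53, 3.0] on the log10 axis, runs into the upper parameter bound
(`upper_open: true`), and its average CI width is 3.62 decades. Which of
the three possible measurements at t = 40 — A, B or C — would fix that?

```
$ pl2design design2d abc demo/data.csv --target p1 --candidates demo/candidates.csv --out demo/design
selected: A@t=40/default
```

with the ranking (from `demo/design.json`):

```
A @ t=40   W = 0.122   budget 434
B @ t=40   W = 1.564   budget 432
C @ t=40   W = 1.862   budget 425
```

Measuring the so-far unobserved state A is an order of magnitude more
informative than measuring B or C again: every sampled outcome row of the
A@40 two-dimensional profile yields a closed 95% interval for p1 (expected
width 0.12 decades), whereas B and C leave p1 one-sided for most outcomes.
Each candidate's two-dimensional profile costs ~430 warm-started local
optimizations. The sequential loop

```
$ pl2design sequential abc demo/data.csv --candidates demo/candidates.csv \
      --target p1 --oracle simulate --max-iter 1 --seed 0 --out demo/seq.json
```

therefore measures A at t = 40 first, after which p1 classifies as
identifiable.

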