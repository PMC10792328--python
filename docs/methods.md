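# Methods

## The life-table model

A `LifeTable` holds a cohort on a contiguous integer age grid $0..\omega$:
survivors $l_x$ (persons, radix $l_0 = 100\,000$ by default), deaths $d_x$,
the age-specific mortality rate $m_x$ and the remaining life expectancy
$e_x$ (years).  Two conventions are load-bearing:

* **$m_x \equiv d_x/l_x$.**  The mortality-space estimator divides and sums
  exactly this quantity, so after construction the $m_x$ column always
  equals $d_x/l_x$ — it is the per-interval death probability given
  survival to exact age $x$, not the central rate $d_x/L_x$.  Input files
  carrying central rates are accepted; their rate column is treated as a
  hazard for survivorship reconstruction ($l_{x+1} = l_x e^{-m_x}$) and the
  stored $m_x$ is then re-derived.  The distinction is below the
  estimators' sensitivity at ordinary mortality levels.
* **Closure.**  Trailing ages with $l_x = 0$ are truncated; $\omega$ is the
  last age with survivors.  A *closed* cohort has $d_\omega = l_\omega$ and
  $\sum_x d_x = l_0$.  Tables may also be *open* (survivors beyond
  $\omega$, $0 \le d_\omega \le l_\omega$), which some toy and period
  inputs require; a supplied deaths column is kept verbatim so open tables
  round-trip through files.

Life expectancy uses trapezoidal person-years, $L_x = (l_x + l_{x+1})/2$,
with $a_x = 1/2$ in the terminal interval as well ($L_\omega = l_\omega/2$),
so $e_\omega \le 1$ and a cohort dying entirely in its first year has
$e_0 = 1/2$.  When an input file supplies $e_x$ it is preferred; otherwise
$e_x = T_x/l_x$ is computed, and recomputation is idempotent.

## The direct estimator

$b_x = x\,m_x / M_x$ with $M_x = \sum_{a=0}^{x} m_a$ (inclusive sums).
Conventions at the boundaries: $b_0 = 0$ (the age factor annihilates the
numerator) and $M_x/x$ is undefined at $x = 0$; if mortality is
identically zero up to some age, $b_x$ there is set to 0 with a logged
warning.  The identity $x\,m_x = b_x M_x$ holds at every age by
construction and is tested to $10^{-12}$; so are invariance under
rate-scaling (the constant cancels) and under radix rescaling.

The person-life-years-lost column is $\mathrm{PLYL}_x = x\,d_x/M_x$, the
unique reading under which both $b_x = \mathrm{PLYL}_x / l_x$ and the
ratio definition of $b_x$ hold simultaneously.

**Scalar summary.**  The default scalar HLYL is the peak of the $b_x$
curve, the smallest age winning exact ties; a fixed-age read-out is
exposed (`summary="at-age"`).  On *closed* cohorts the peak search stops
at $\omega - 1$: the terminal row has $d_\omega/l_\omega \equiv 1$ by
closure, an artifact carrying no mortality information (archival tables
are open at 110+, where the distinction does not arise).

**Known limitation.**  The estimator presumes mortality accumulates from
birth.  On a law with essentially zero pre-senescent mortality (the pure
Gumbel death-age model) the cumulative $M_x$ in the thin left tail equals
its own last increment, so $b_x \approx x$ there and the raw peak lands in
the tail rather than near the senescent shape; reading the curve at the
modal death age recovers the expected magnitude.  Real schedules, with
their infant and background components, do not trigger this regime.

## Parametric models and fitting

Three two-parameter laws, all evaluated in log space
(`log1p`/`expm1`/`logaddexp`) because $x^l$ overflows double precision
near $l > 14$ on human age grids:

* log-logistic: $S = 1/(1+\lambda x^l)$, $h = \lambda l x^{l-1}/(1+\lambda
  x^l)$, $\Lambda = \ln(1+\lambda x^l)$.  The scale $\lambda$ is kept as a
  free parameter: with $\lambda = 1$ and ages in years the hazard cannot
  reach human mortality levels; $l$ alone remains the HLYL carrier.
* Weibull: $S = e^{-(bx)^l}$, $h = b l (bx)^{l-1}$.
* Gompertz in Gumbel death-age form: $F = e^{-e^{-(l+bx)}}$, location
  $-l/b$ (the modal death age), scale $1/b$.  The ratio $f/F =
  b\,e^{-(l+bx)}$ is a *reversed* hazard — it decreases with age — and is
  deliberately exposed as `gompertz_ratio`, never as a hazard, to prevent
  silent misuse.  The Carriere aliases $B = b e^{-l}$, $c = e^{-b}$ are
  provided on the parameter object.

**What is fitted to what.**  The empirical `mx` series is the interval
probability $d_x/l_x$, so the model's prediction for it is its own
interval probability $1 - S(x+1)/S(x)$ (computed as
$-\mathrm{expm1}(\Lambda(x) - \Lambda(x+1))$), not the instantaneous
hazard: comparing a hazard against interval data carries an $O(\mu)$ bias
(~10% where $\mu \approx 0.25$) that would contaminate the shape.  With
this choice a table generated from the family is recovered to solver
tolerance.  The Gompertz family is fitted to the death-age CDF
$1 - l_x/l_0$ instead, matched by $F(x)$: its printed ratio decreases with
age and cannot track adult mortality, while its CDF fits the death
distribution directly and yields $|l| = b \times$ (modal age), the
magnitude reported for this estimator.  Both series choices are
overridable in `FitConfig`.

**Protocol.**  Unweighted least squares on the natural scale, ages
$1..\omega-1$ by default: age 0 is excluded because none of the monotone
laws can represent the infant spike (standard in parametric mortality
fitting), and the closed-cohort terminal row is excluded because its
$d/l \equiv 1$ is a closure artifact.  Optimization is multi-start
Levenberg–Marquardt in log-parameter space: the base start anchors the
scale at the modal death age with shape 7 (Gompertz: $b_0 = 0.1$,
$l_0 = -b_0 \times$ mode), plus 7 seeded jittered starts (±50% uniform),
best SSE kept — deterministic given the seed.  The goodness-of-fit surface
is $R^2$, SSE and the residual standard error
$\sqrt{\mathrm{SSE}/(n-p)}$ with $p = 2$; $R^2$ is NaN when the observed
series has zero variance, and an identically-constant series raises an
error (a lifetime law is not identifiable from it).

Fitting rates unweighted means the oldest ages — rates estimated from a
handful of survivors — carry full weight.  Under binomial sampling at
radix $10^5$ this puts ~7% sampling SD on a single Weibull shape estimate
(bias ~1%): recovery under noise is therefore assessed on the replicate
average, which is the quantity the generator's unbiasedness guarantees.

## The synthetic generator

`make_life_table` turns a continuous hazard into a closed cohort table.
Survival is computed from the family's *closed-form* cumulative hazard,
$S(x) = e^{-\Lambda(x)}$ — all five families have one (Gompertz–Makeham:
$Ax + \tfrac{B}{\theta}(e^{\theta x}-1)$) — so the interval probabilities
$q_x = 1 - S(x+1)/S(x)$ are exact under the generating law rather than
carrying quadrature bias; the parameter-recovery tolerances (1% noiseless)
leave no room for such bias.  Noiseless mode uses $l_x = l_0 S(x)$
unrounded, so $\sum d_x = l_0$ holds to the last bit.  Binomial mode draws
deaths sequentially, $d_x \sim \mathrm{Binomial}(l_x, q_x)$, keeping
$l_{x+1} = l_x - d_x$ exact under noise; expectations match the noiseless
deaths (tested over 200 replicates).  A warning is emitted when
$S(\omega) > 0.05$ (the closed terminal row then carries real mass).

Defaults emulate a contemporary high-LE schedule: Gompertz–Makeham with
$A = 5\times10^{-4}$, $B = 3\times10^{-5}$, $\theta = 0.1$ (background
mortality plus a ~7-year senescent doubling time, $e_0 \approx 74$),
radix $10^5$, $\omega = 110$.  What the generator does *not* emulate:
infant and young-adult excess mortality, old-age deceleration/plateaus,
period effects and heterogeneity (frailty).  Passing recovery tests
therefore demonstrate estimator correctness under the stated laws, not
robustness to the shape mis-specification real data always carries — the
cross-family fits in `examples/fit_models.py` show how strongly model
choice matters when the law is wrong.

The fixed recovery grid (`scenario_suite`) spans shapes 6–9 with scales
anchored near modal age 70–80, ×{noiseless, binomial}, 18 scenarios.

## Pipeline and reference comparison

`run_estimation` produces one record per table × method with
$\mathrm{HLE} = e_0 - \mathrm{HLYL}$ (negative HLE allowed but logged);
a failed fit yields NaN markers, never aborts a batch.  The packaged
reference (India 2000–2019: direct, log-logistic, Gompertz, Weibull and
the WHO HALE anchors for 2000/2010/2015/2019, plus a WHO HLE row for
2005) satisfies the subtraction identity on all 240 non-WHO cells within
0.002 — the printed 3-decimal rounding.  WHO values are anchors only:
they derive from Sullivan-type morbidity data and are never recomputed
here.  Comparison flags, per year × sex, the method minimizing
$|\mathrm{HLYL} - \mathrm{HLYL}_{\mathrm{WHO}}|$.

On the reference fixture the log-logistic HLYL rises monotonically
2000→2019 for all three populations, exceeds the other methods', is higher
for women than men in every year, and is the closest to the WHO anchor —
the orderings that motivate preferring the log-logistic form.  One noted
source discrepancy: the 2019 female log-logistic HLYL circulates as 9.38,
9.35 and 9.345 in different renditions; the fixture stores the
highest-precision value, 9.345.

## Numerical and testing notes

* Identities ($f = hS$, $F + S = 1$, $x m_x = b_x M_x$, invariances) are
  asserted at rtol $10^{-12}$ with an atol floor of $10^{-12}$: quantities
  of magnitude $\lesssim 1$ reconstructed through different rounding paths
  (e.g. survivorship at another radix) differ at the $10^{-12}$ absolute
  level.
* The closed form $\ln(1+x^l)$ is validated against adaptive quadrature of
  the hazard to $10^{-8}$ over a grid of $(x, l)$.
* Deaths on the rate-derived construction path are $l_x q_x$ directly;
  survivor differences would lose up to 5 decimal digits at $q \sim
  10^{-6}$.
* Problem sizes in the default suite: $\omega = 110$ tables, 20-replicate
  noise studies, 200-replicate unbiasedness checks — chosen so the whole
  suite runs in a few seconds while keeping Monte-Carlo standard errors
  well inside the asserted tolerances.
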