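# lifeyears

Estimation of **healthy life years lost (HLYL)** and **healthy life
expectancy (HLE)** from complete (single-year-of-age) life tables, for
demographers and population-health researchers who have mortality data but
no direct morbidity surveys.

The idea is to read the health state of a population out of the shape of
its mortality schedule alone.  Two routes are implemented:

**Direct ("mortality space") estimator.**  The life table is extended with
the cumulative mortality $M_x = \sum_{a=0}^{x} m_a$ (with $m_a = d_a/l_a$),
the average mortality $M_x/x$, the person life years lost
$\mathrm{PLYL}_x = x\,d_x / M_x$, and the ratio

$$b_x \;=\; \frac{x\,m_x}{\sum_{a=0}^{x} m_a},$$

the "total space over mortality space" fraction.  $b_x$ rises with age to a
peak and then declines; the peak is the direct HLYL estimate, and it is
invariant to rescaling all rates by a constant and to the choice of radix.

**Parametric estimators.**  Three lifetime laws are fitted to the table,
and in each the shape/location parameter $l$ carries the HLYL:

| model        | survival / CDF                          | fitted to            | HLYL  |
|--------------|-----------------------------------------|----------------------|-------|
| log-logistic | $S(x) = 1/(1+\lambda x^{l})$            | mortality rates $m_x$| $l$   |
| Weibull      | $S(x) = e^{-(bx)^{l}}$                  | mortality rates $m_x$| $l$   |
| Gompertz     | $F(x) = e^{-e^{-(l+bx)}}$ (Gumbel form) | death CDF $1-l_x/l_0$| $|l|$ |

For the unit-scale log-logistic law the cumulative hazard has the closed
form $\int_0^x \frac{l s^{l-1}}{1+s^{l}}\,ds = \ln(1+x^{l})$, which ties
$b_x$ analytically to the hazard:
$b_x = l x^{l} / \big[(1+x^{l})\ln(1+x^{l})\big] \to l$ as $x \to 0^+$.

HLE then follows by subtraction, $\mathrm{HLE} = \mathrm{LE} -
\mathrm{HLYL}$, with LE the life expectancy at birth $e_0$ of the same
table.  A packaged reference table (India 2000–2019, all four methods plus
the WHO HALE anchors) supports comparison; a synthetic life-table generator
(closed-form survival from Gompertz–Makeham, Weibull, log-logistic, Gumbel
or constant hazards, with optional binomial sampling noise) makes every
estimator testable against known truth.

## Worked example

```python
from lifeyears import FitConfig, SimConfig, direct_hlyl, fit_model, make_life_table

lt = make_life_table(SimConfig())          # synthetic cohort, radix 100 000
est = direct_hlyl(lt)
print(lt.e0, est.hlyl, est.age)
fr = fit_model(lt, FitConfig(family="gompertz"))
print(fr.hlyl, fr.r2)
```

Running `python examples/direct_estimator.py` prints:

```
life expectancy at birth : 73.93 years
direct HLYL (peak of bx) : 8.130 years at age 97
bx at ages 50/70/90      : 3.478 / 6.107 / 7.943
survival / mortality area: 73.9 / 37.1 person-years per person
```

so of the 73.9 years this cohort expects at birth, about 8.1 are lost to
ill health by the direct criterion, the loss peaking at age 97.  And
`python examples/india_reference.py` prints:

```
2019 total population, distance of each method's HLYL from WHO (10.490 y):
  loglogistic  HLYL  8.786  |diff| 1.704  <- closest
  direct       HLYL  7.262  |diff| 3.228
  weibull      HLYL  6.664  |diff| 3.826
  gompertz     HLYL  6.641  |diff| 3.849
```

i.e. on the 2019 reference row the log-logistic estimate lands closest to
the WHO healthy-life-years figure.  The other examples cover model fitting
(`fit_models.py`) and noisy parameter recovery (`simulate_and_recover.py`).

## Command line

A thin CLI wraps the same functions:

```sh
lifeyears simulate --family weibull --params '{"b": 0.0125, "l": 7}' --out t.csv
lifeyears direct   --lifetable t.csv
lifeyears fit      --lifetable t.csv --model loglogistic
lifeyears estimate --input-dir tables/ --out results.csv
lifeyears compare  --results results.csv --reference builtin:india_2000_2019 --out diffs.csv
lifeyears check-reference
```

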