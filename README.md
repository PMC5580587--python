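# tmcgm

Grey GM(1,1) forecasting with Markov residual-state correction and
Gauss–Newton-optimized whitening coefficients — the composite model often
written **T-MCGM(1,1)** — for very short, positive-valued annual time
series.

## The problem

Health planners need demand forecasts for specific diseases, but the
underlying indicators — here urban **two-week hospitalization rates**
(‰, one number per year per disease) — come as series of barely ten
points. Regression and ARMA-style models are data-hungry at that length;
grey-system models are built for it. The package bundles such a dataset
(diabetes `DD`, heart disease `HD`, cerebrovascular disease `CD`,
2006–2015) and works on any CSV/JSON file with a `year` column and
positive series columns.

## The model

**GM(1,1).** The raw series x⁽⁰⁾ is smoothed by the accumulated
generating operation x⁽¹⁾(j) = Σᵢ≤ⱼ x⁽⁰⁾(i) and modelled through the grey
difference equation

```
x⁽⁰⁾(j) + a·z⁽¹⁾(j) = b ,   z⁽¹⁾(j) = ½[x⁽¹⁾(j−1) + x⁽¹⁾(j)] ,  j = 2..n,
```

with the developing coefficient *a* and grey action *b* estimated by
least squares. Fitted and forecast values are restored with
x̂⁽⁰⁾(i+1) = (x⁽⁰⁾(1) − b/a)(1 − eᵃ)e^(−a·i), the first point anchored at
the observation.

**Markov residual correction.** The signed residuals e(i) = x⁽⁰⁾(i) −
x̂⁽⁰⁾(i) of points 2..n are binned into r equal-width states spanning
[min e, max e]; a one-step Markov chain over the state labels gives the
transition matrix P. Each state interval [Lⱼ, Uⱼ] is a grey number
whitened to a point correction vⱼ = αⱼLⱼ + (1−αⱼ)Uⱼ, and the corrected
value adds the probability-weighted correction:

```
x̃⁽⁰⁾(t+1) = x̂⁽⁰⁾(t+1) + Σᵢ aᵢ(t)·vᵢ ,   a(t) = a(t−1)·P.
```

**Whitening optimization.** The coefficients α ∈ [0,1]^r are chosen to
minimize ‖x⁽⁰⁾ − x̃⁽⁰⁾(α)‖² by a Gauss–Newton iteration from α = 0.5
with a forward finite-difference Jacobian (step αᵢ/R, R = 200, floored at
1e−4) and clamping into the unit box. Because x̃⁽⁰⁾ is affine in α, the
iteration normally converges in two steps and its fixed point coincides
with the box-constrained linear least-squares solution.

## Worked example

```sh
tmcgm run --input src/tmcgm/data/twoweek_hospitalization_rates.csv \
          --column HD -r 3 --horizon 7 --output report.json
```

The JSON report for the heart-disease series contains (abridged, values
as actually computed):

```
gm11:        a = -0.0815, b = 9.0489
metrics:     GM11    mape 3.59 %   rmse 0.562
             TMCGM11 mape 3.11 %   rmse 0.528
alpha:       [1.0, 0.944, 0.0]
forecast (2016–2022, ‰):
             GM11    21.80 23.65 25.66 27.84 30.21 32.77 35.56
             TMCGM11 21.72 23.54 25.52 27.70 30.06 32.63 35.42
```

Reading: the plain grey model already tracks this fairly smooth series
(3.59 % mean absolute percentage error over points 2..10; the anchored
first point is excluded as its error is structurally zero). The Markov
correction shaves the in-sample MAPE to 3.11 % and shifts each forecast
by the expected whitened residual of the state the chain predicts. The
negative developing coefficient corresponds to ~8.5 % annual growth in
demand.

`tmcgm fit` runs the plain grey model only; `tmcgm simulate` generates
synthetic series with known parameters and optional Markov-switching
noise (see `tmcgm --help`).

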