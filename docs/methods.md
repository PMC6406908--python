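# Methods

## The model

The pipeline quantifies the momentum of keyword-defined research fields
from a publication-count panel: a non-negative integer `N(f, j, y)` for
every field `f`, journal `j` and calendar year `y`, together with one
impact factor `IF(j)` per journal.

**Annual impact.** `AI(f, j, y) = N(f, j, y) × IF(j)`. The impact factor
acts as a per-article weight, so an article in a high-impact journal
contributes more mass than one in a low-impact journal. A single
impact-factor snapshot is applied to all years; there is no per-year IF
table, and no per-article citation data enters the index.

**Annual impact index.** `AII(f, y) = Σ_j AI(f, j, y)` — the field's
impact-weighted publication mass in year `y`. It is linear in the counts
and homogeneous of degree 1 in the impact factors, and additive over any
partition of the journal set (both properties are tested).

**Fold change.** Fields differ enormously in absolute mass, so trends are
compared on `Δ-AII(f, y) = AII(f, y) / AII(f, y−1)`. A zero AII would
make the ratio undefined (or degenerate), so any zero — numerator or
denominator — is first replaced by the substitution constant, default
**1.081**. That value is the AI of a single article in the
lowest-impact-factor tracked journal, i.e. the smallest nonzero mass the
panel can express; a helper (`derive_sub_constant`) recovers it as
`min(IF)` from any journal table. Substituting on both sides (not just
the denominator) keeps every Δ-AII finite and positive and makes a 0 → 0
transition read as "no change" (Δ = 1); each substitution is recorded
per (field, year, position) so the denominator-only variant remains
auditable from the output.

**Forecasting.** For each field, the Δ-AII values of a trailing window
(default 5 years) are fitted by ordinary least squares with a polynomial
of degree 1, 2 or 3 on integer time indices 1..w, and the fitted curve is
evaluated at index `w + h` to predict the fold change `h ∈ {1, 2, 3}`
years past the window. Calendar years map affinely onto the index axis,
which leaves polynomial predictions unchanged. Fields are ranked by
predicted Δ-AII descending (ties broken lexicographically by field name,
so the ranking is independent of input order) and the top-*k* (default
20) form the predicted hot set. Degree 1 is the recommended default:
degrees 2–3 interpolate 5-point windows aggressively and extrapolate
erratically, which the backtests on the synthetic corpus reproduce.
Extrapolations ≤ 0 are kept and ranked (they are an ordering signal) but
flagged, since a true fold change is positive.

**Backtesting.** Every window whose target year still has actual data is
forecast and scored:

- *Accuracy A* — the fraction of (field, window) point predictions within
  a tolerance of the actual Δ-AII, pooled over fields and windows. The
  tolerance is an absolute difference in fold units, default 1.0; the
  multiplicative reading (ratio within [1/2, 2]) was rejected because
  Δ-AII is already a fold value. The headline figure is the horizon-1
  value; per-horizon values are also reported.
- *Accuracies B, C, D* — top-*k* set overlap (rank-agnostic intersection)
  between predicted and actual top-*k* lists at horizons 1, 2, 3, pooled
  across windows (*k* slots per window).

Each pooled overlap is tested against the coincidence baseline
`p0 = k / n_fields` — the expected overlap rate of two independent random
top-*k* picks — with a one-sided exact binomial test (alternative:
"greater", significance 0.05). Per-window p-values are emitted alongside
the pooled ones for transparency. With the defaults, `p0 = 20/79`, and 23
pooled matches in 60 slots (three pooled windows) gives p = 0.018.

## A calibration caveat the backtest exposes

The coincidence baseline assumes the predicted and actual top-*k* sets
are independent. At **horizon 1 they are not**: the actual target ratio
`AII(e+1)/AII(e)` shares the window-end year `e` with the fitted data. A
field that fluctuated upward at `e` looks hot to the forecaster *and* is
pushed down in the very next ratio by mean reversion. On an
all-stationary null corpus this drives the horizon-1 overlap far *below*
`p0` (about 8% observed against a 25.3% baseline — a z-score near −13),
while horizons 2 and 3, whose target ratios share no year with the
window, sit squarely on `p0` (|z| < 2 across seeds). Consequently the
null-calibration check is run at horizon 2, and the horizon-1 suppression
is asserted as a property in its own right. For real-data use this means
horizon-1 overlap accuracies should be read against an empirical null,
not against `k / n_fields`.

## The synthetic corpus

The generator emulates the panel the pipeline is designed for: **79
fields × 30 journals × 10 contiguous years** of small counts, impact
factors spanning **1.081–44.405** with a right-skewed (lognormal,
clipped) spread whose endpoints are always included — so the derived
substitution constant is 1.081 at the defaults.

Counts are independent Poisson draws per (field, journal, year) around a
rate `λ(f, y)` set by the field's regime:

| regime | default share | rate model | expected Δ-AII |
|---|---|---|---|
| stationary | 0.45 | constant `λ₀` | 1 |
| emerging | 0.25 | `λ₀ · g^t`, `g ~ U(1.2, 2.0)` per field | `g` |
| burst | 0.15 | constant with one year × 25 | 25 at the burst year, 1/25 after |
| declining | 0.15 | `λ₀ · d^t`, `d ~ U(0.7, 0.9)` per field | `d` |

`λ₀` (base_rate) defaults to 0.5 expected articles per
(field, journal, year), giving mostly-zero cells with occasional small
counts, the texture of per-journal-per-year keyword hits. The burst
multiplier 25 and the growth range bracket the extremes seen in real
panels of this kind (one-year jumps of ~5× to ~25×). Burst years are
randomized per field so spikes do not coincide; emerging and declining
trajectories start at the first simulated year, so their expected Δ-AII
is constant over all fold-change years. Every field carries its regime
label and exact generative parameters as ground truth. Counts are small
Poisson tallies with no overdispersion, no correlation between fields or
journals, and no secular drift in journal impact — passing tests on this
corpus therefore validate the *mechanics* of the pipeline (index algebra,
fitting, ranking, pooling, significance), not the predictability of real
literature dynamics, which are burstier and cross-correlated.

Setting `base_rate = 0` is allowed as a degenerate all-zero panel; it
drives every AII to zero and exercises the substitution path end to end
(all Δ-AII become 1 with two substitutions each). `noiseless=True`
replaces the Poisson draw with rounded expected counts, which together
with a large base rate (50–100) makes the planted trends exact — the
regression then recovers every planted growth field in the predicted
top-*k* and backtests at accuracy 1.0, the parameter-recovery check.

## Numerical choices

- Least squares is solved via numpy's SVD-based `lstsq` on a Vandermonde
  design — stable for the short, small-index windows used here. The
  explicit normal-equations solve `(VᵀV)c = Vᵀy` is kept solely as an
  independent test oracle (agreement to 1e−8 over 1000 random windows).
- The binomial tail is `scipy.stats.binomtest(..., alternative="greater")`,
  cross-checked in the tests against an exact rational tail sum.
- AII and Δ-AII are carried at full float precision; 3-decimal values in
  displays are rounding only.
- Windows must contain strictly increasing time indices and at least
  degree + 1 points; violations raise rather than silently degrade.
- Apportioning the regime mix uses largest-remainder rounding, so the
  realized regime counts match the requested proportions to ±1 field.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
native corpus size (79 × 30 × 10) for the noisy backtest, a 30-field
noiseless corpus for parameter recovery, and a 79-field, 60-year
all-stationary corpus (53 pooled horizon-2 windows) for null calibration
— a few seconds end to end on one CPU.

## Known limitations

- The index inherits the impact factor's weaknesses: journal-level, not
  article-level, prestige, and a static snapshot applied retroactively.
- Point extrapolation only; no prediction intervals, no model averaging
  across degrees, and no correction for testing three degrees.
- One-year bursts are poison for polynomial extrapolation: the spike
  enters the window and is extrapolated forward just as the real series
  reverts (visible in `examples/forecast_and_rank.py`). Detecting bursts
  rather than extrapolating through them is future work.
- Keyword-level counts conflate homonymous fields; the directed-query
  mechanism (AND-ing a disambiguation term) mitigates but does not solve
  this.
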