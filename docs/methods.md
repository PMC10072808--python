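# Methods

## The estimation problem

A diary-based contact survey records, for each participant, every two-way
conversation in physical presence (or skin-to-skin contact) over a 24-hour
window, with the contactee's age (exact or as a range), the setting(s), a
duration band, physicality, frequency of meeting, and a distance-from-home
band. Because diaries under-capture casual contacts, participants are also
asked afterwards for counts of omitted ("supplementary") contacts in four
coarse age bands (0–4, 5–15, 16–64, 65+) split by physical/non-physical.
Supplementary counts enter degree summaries and degree regressions; they
never enter mixing matrices, since their settings and exact ages are unknown.

The pipeline estimates, for age bands *i*, *j* on a 14-band scheme (5-year
bands to 64, then 65+):

```
c_ij = Σ_{p∈i} w_p n_pj / Σ_{p∈i} w_p
```

the weighted mean number of daily contacts of a band-*i* participant with
band-*j* contactees, then symmetrises it against band population sizes `N_i`:

```
c'_ij = (c_ij N_i + c_ji N_j) / (2 N_i)
```

This is the minimal correction that makes directed contact totals balance
(`c'_ij N_i = c'_ji N_j`) while conserving the overall number of contact
events (`Σ_ij c'_ij N_i = Σ_ij c_ij N_i`). It is exact, idempotent, and a
no-op on already-balanced input — properties the test suite asserts on random
matrices.

Assumptions: each diary line is one contact (repeat encounters with the same
person are not deduplicated — the survey instrument cannot distinguish them);
participants are exchangeable within band after weighting; the population
table refers to the same stratum as the matrix being adjusted (urban and
rural matrices are adjusted against their own stratum populations, the
combined matrix against the combined population).

## Age band schemes and conventions

Three band schemes coexist: the 14-band matrix scheme, the 7-band
quota-sampling scheme (0–5, 6–12, 13–19, 20–29, 30–39, 40–59, 60+), and the
8-band regression scheme (0–4, 5–14, …, 55–64, 65+). Bands are half-open
`[lower, next_lower)` on integer ages; a printed label "0–5" therefore has
next lower bound 6, so both endpoints are inside the band.

Contactee ages reported as a range resolve to `floor((min+max)/2)` before
banding; a seeded uniform-draw mode is available as a sensitivity check.
Contacts with no reported age are excluded from matrices and counted on the
matrix object (`n_dropped_missing_age`) — exclusion is conservative and
visible, rather than imputed.

Duration bands map to midpoints 2.5, 9.5, 37, 150 and 240 minutes; the open
top band is right-truncated at 4 h, so "more than 4 hours" contributes 240
minutes to contact-hour totals. A *high-intensity* contact is physical OR at
least 15 minutes long (duration band 15–59 min or above — the band edges
align exactly with the cutpoint).

Multi-setting contacts (e.g. home and school) contribute once to **each**
reported setting's matrix by default, while the all-settings matrix counts
every contact exactly once; an "exclusive" mode instead diverts them to a
separate `multiple` matrix. Descriptive setting-proportion displays always
use the exclusive `multiple` bucket — the two conventions serve different
outputs and both are tested. Transport, leisure and unspecified settings are
merged into one `other_transport_leisure` analysis setting, since each alone
carries a fraction of a percent of contacts.

## Raking

Weights are fitted by iterative proportional fitting over the margin
variables residence, age group (8-band scheme), diary day type and
employment status, with user-supplied population shares (margins are always
external inputs — census-style sources, not the survey itself). Controls:
relative margin tolerance 1e-8, at most 1000 passes; non-convergence is
returned flagged rather than raised. Weights are normalised to mean 1.
Optional trimming clips weights to multiples of the mean (default bounds
[0.2, 5]) with up to 5 trim/re-rake cycles; bounds win over margins on the
final pass, guarding against extreme weights that inflate design effects.
Where employment status is absent it can be derived from age and occupation:
under 15 or 65+ → non-working age; working-age adults in paid occupation
categories → employed; otherwise unemployed. The mapping is a documented
default, overridable in data preparation.

## Weighted quantiles

Weighted medians/IQRs use the inverse of the weighted ECDF with an *upper*
tie-break: the reported quantile is the smallest observed value whose
cumulative weight share strictly exceeds q. With equal weights and odd n
this equals the ordinary sample median; when a cumulative share lands
exactly on q the next observed value is returned.

## Chi-squared machinery

Independence tests are plain Pearson X² (no continuity correction — the
intended use is large tables at survey scale), delegated to
`scipy.stats.chi2_contingency`; the test suite checks it against an
independent textbook implementation on random tables. The trend test for a
binary outcome over ordered categories is Cochran–Armitage with integer
scores 1..k (configurable), written in-house since no installed dependency
exposes it; the statistic is invariant to reversing the level order. The
diary-vs-supplementary reporting comparison coarsens diary contact ages to
the four supplementary bands and tests the age distribution (4×2, df 3) and
the physical proportion (2×2, df 1) across methods.

## Negative-binomial regression

Degree (diary + supplementary) and total contact hours are modelled as NB2
counts with log link. Contact hours are a sum of band midpoints, so the
response is total minutes rounded to the nearest integer — NB machinery on
the minutes scale leaves relative rates unaffected (the intercept is in
minutes). Fitting alternates a GLM step for the coefficients at fixed
dispersion (statsmodels IRLS, raking weights as frequency-style likelihood
weights) with a bounded one-dimensional ML step for the dispersion given the
fitted means, to joint convergence (relative tolerance 1e-8 on α, up to 50
outer iterations; failure raises with diagnostics). Wald 95% intervals are
conditional on the fitted dispersion, the standard practice for this
alternation. Per-term ANOVA refits the model without each term by the same
joint ML and reports the likelihood-ratio statistic on levels−1 degrees of
freedom; a reduced fit that fails to converge is flagged, never fabricated.
Degenerate categorical levels (empty, or a single level) are rejected with
the level named before fitting.

## The synthetic generator

The generator produces surveys with the same statistical skeleton as the
field design, and — crucially — an exactly known ground truth.

* **Quota recruitment** fills every age-band × sex × residence cell exactly
  (n must divide evenly over the 28 strata; an infeasible quota against the
  stratum population is an error). Ages are uniform within sampling bands
  (60+ capped at 84).
* **Population** per stratum follows an exponential-decay age pyramid
  (default 0.025 per year of band midpoint — a young population), integerised
  by largest remainder.
* **Ground-truth matrices** are built per setting from a Gaussian
  age-assortative kernel (bandwidth 6 years) plus intergenerational ridges
  offset by 28 years for home contacts (parent/grandparent–child mixing),
  band-level support masks confining school mixing to ages ~3–24 and work to
  15–64, then symmetrised in totals against the population and scaled so the
  population-mean total degree is 31 contacts/day split across settings
  roughly as home-household 29%, home-non-household 28%, work 5%, school 10%,
  other 28%. The per-setting and total matrices satisfy the reciprocity
  identity by construction, so the estimation pipeline has a fixed target.
  Household structure is *not* simulated explicitly; the ridge amplitude is
  the (configurable) stand-in for multigenerational co-residence, which keeps
  the ground truth in closed form.
* **Degrees** are negative binomial with mean equal to the participant's
  band row sum times covariate multipliers (defaults: rural ×1.23, weekend
  ×0.81; dispersion size k = 1.2). Multipliers are renormalised to mean 1
  within each matrix band, so covariate effects never bias the band-level
  ground truth; relative rates within bands are preserved for regression
  recovery.
* **Contact attributes**: contactee band from the truth's row distribution,
  age uniform within band; setting from the per-setting truth at (i, j);
  duration and physicality from per-setting tables in which longer contacts
  are more often physical, and home/school contacts are longest and most
  physical; distance shares 88/10/2% across <1 km / 1–9 km / >9 km; a 5%
  chance a home contact also reports a second setting; 15% of ages arrive as
  a (within-band) range.
* **Reporting**: each contact is relegated from the diary to supplementary
  coarse-band counts with probability 0.40 if physical and 0.62 if not —
  diary contacts end up roughly twice as likely to be physical, the diary
  share of all contacts lands near half, and a participant with any
  relegated contact self-reports an incomplete diary.

All randomness flows from one seed through named sub-model streams, so
regenerating with the same config is byte-identical.

What the generator does **not** emulate: explicit household rosters and
within-household contact saturation, repeat contacts with the same person,
day-of-week activity structure beyond a weekend rate multiplier, spatial or
network clustering, and any individual-level coupling between a participant's
own employment and their work contacts (support masks act at band level).
Passing recovery tests therefore demonstrate the *estimators* are correct
under the stated sampling model, not that real diaries satisfy that model.

## Test and verification sizes

Property tests run on matrices up to 14 bands (hundreds to a thousand random
cases), raking instances up to 3 variables × 5 levels against a brute-force
alternating-proportions oracle, and brute-force per-contact tallies on
surveys of ≤ 20 participants. Ground-truth matrix recovery is asserted at
10,080 participants (every adjusted cell within 3 delta-method Monte-Carlo
standard errors of the truth), and NB interval coverage at 2,016
participants × 100 replicates (≥ 93 of 100 Wald CIs covering the generating
rate ratio). These sizes make the full suite and the acceptance script run
in minutes on a single CPU while keeping the Monte-Carlo error small
relative to the tolerances.

## Known limitations

* Matrix cells come with no interval estimates (no bootstrap); the SE
  machinery used in verification is delta-method, for testing only.
* Reciprocity adjustment of a cell observed in only one direction keeps the
  observed value and mirrors it; total-event conservation then holds only on
  fully observed matrices.
* The hours regression inherits the coarseness of duration bands; midpoint
  truncation at 4 h compresses the right tail.
* Raking supports marginal targets only (no joint-cell calibration, no
  GREG), matching the method's standard use.
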