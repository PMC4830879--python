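# Methods

## Scope and data model

`ovistage` estimates the age of *Calliphora vicina* eggs from embryonic
morphology. Its calibration is a staging table: 15 morphological landmarks
(homogeneous yolk mass through fully developed tracheal system) scored
over the eleven 10 % intervals of total egg development (0 % = oviposition,
100 % = hatching) at two constant rearing temperatures, 7.3 °C (120 h total
egg stage) and 25 °C (16 h). Each cell is an ordinal visibility category:
blank = not visible, `+` = visible in <25 % of examined individuals,
`++` = 25–75 %, `+++` = >75 %. Blank cells are genuine absences, not
missing data: the scoring scheme defines only the three plus symbols, so
absence of a symbol encodes absence of the character.

The calibration ships as a human-editable TSV (one row per
landmark × temperature, eleven category columns) so that observation files
remain stable across versions; landmark ids are fixed snake-case tokens
(`bright_peripheral_ring`, `cephalic_furrow`, …). Cells whose transcription
from degraded renderings of the source table required resolution against
the per-interval narrative carry provenance comments in the fixture header
rather than silent guesses.

Each interval also maps to the *Drosophila melanogaster* embryonic stages
of Campos-Ortega & Hartenstein (1–17). Stages only partly contained in an
interval (stage 16 split across 80 % and 90 %; stage 6 partly in 20 %) are
carried as an explicit `partial` flag, not fractional weights — the
calibration gives no finer quantitation.

## Thermal model

Development is driven by accumulated degree hours (ADH) above a lower
developmental threshold of 1 °C (default; overridable in the fixture for
other populations):

* **Accumulation** integrates `max(0, T(t) − 1)` over a temperature
  profile under piecewise-constant (left-hold) interpolation. Left-hold
  matches data-logger semantics and makes every integral exact, so
  additivity over sub-intervals holds to machine precision, not
  approximately.
* **Requirement.** The total ADH requirement is temperature dependent
  (756 at 7.3 °C vs 384 at 25 °C — higher ADH demand in the cold), so a
  single fixed total would be wrong at one of the two calibrations. The
  requirement at proportion p and temperature T is
  `p × (T − 1) × duration(T)`, with `duration` linearly interpolated in
  temperature between the two calibrated points. Only two calibration
  temperatures exist, so any richer interpolation would be invention;
  outside [7.3, 25] °C the requirement clamps to the nearest calibrated
  temperature and every downstream report carries an
  `ExtrapolationWarning`.
* **Fluctuating profiles** use rate summation: each left-hold step at
  temperature T contributes `(T − 1)Δt / ADH_total(T)` of development,
  capped at 1.0 (hatching). At constant calibrated temperatures this
  reduces exactly to the printed chronology.
* **Inversion** (age from a development-proportion range) is deterministic
  bisection on the monotone accumulation, tolerance 0.01 h, no randomness.
  Targets unreachable within the logged span return a censored flag on the
  affected bound instead of raising: a too-short logger trace is a result
  the report must carry, not a crash.

## Likelihood and posterior

The ordinal categories are mapped to representative presence probabilities:
ABSENT → 0.01, RARE → 0.125, COMMON → 0.5, PREVALENT → 0.875. The
calibration reports only ranges, so these point values are configuration,
validated to lie inside their category's range; RARE/COMMON/PREVALENT
defaults are the range midpoints, and the ABSENT floor (0.01) models
occasional mis-scoring rather than literal impossibility, which also keeps
every log-likelihood finite. Sensitivity to these choices is bounded in
practice because adjacent intervals are separated by category *changes*,
not by the exact point values; any admissible choice preserves the
likelihood ordering that drives the MAP interval.

For one egg, assessed landmarks contribute `log q` (PRESENT) or
`log(1 − q)` (ABSENT); NOT_ASSESSED contributes nothing and is the explicit
don't-know state. ABSENT scores are deliberately informative — a blank
calibration cell is a real absence. Landmarks are treated as independent
given the interval: the calibration provides no joint frequencies, so any
dependence structure would be invention; the practical consequence is that
the posterior can be overconfident when landmarks are biologically coupled
(e.g. spine bands and posterior spiracles both reflect cuticle secretion).

Category lookup at non-calibrated temperatures uses the *nearest*
calibrated temperature (ties to 7.3 °C, the slower and therefore
PMI-conservative regime) because visibility frequencies exist only at the
two calibrations, whereas the thermal model interpolates continuously —
the two resolutions are intentionally different and both are recorded in
the report warnings.

The posterior is `prior × exp(log L)` normalised (uniform prior by
default). MAP ties break toward the earlier interval — a younger egg gives
a shorter, safer minimum-interval claim. The 95 % credible set is built by
posterior-mass ordering, then extended to be contiguous: development is
monotone, and a disjoint age set is not forensically actionable. The
credible set quantifies observation uncertainty under the calibration's
frequencies only; it does not include inter-individual developmental
asynchrony, for which the calibration provides no variance estimate.

### Preservation semantics

* `LIVING`: all 15 landmarks scorable.
* `HWK_ETHANOL` (hot-water killed, then 80 % ethanol): the four fragile
  landmarks (homogeneous yolk mass, clear gaps, dorsal folds, fully
  developed tracheal system) are forced to NOT_ASSESSED regardless of what
  was recorded, so the posterior is invariant to their scoring — vitelline
  collapse and protein coagulation make any such score unreliable.
* `ETHANOL_DIRECT`: decomposition removes all landmark information below
  the 90 % interval → fully censored estimate over [0, 1] with a strong
  warning. If first-instar larval morphology is recorded PRESENT the
  estimate is censored to the 90–100 % window (proportion range
  [0.9, 1.0]), the only statement such material supports.

Censored estimates exit the CLI with status 0: an uninformative sample is a
finding, distinct from broken input (exit 2) or an internal invariant
violation (exit 3).

## Synthetic cohorts

The simulator emulates the calibration study's design — cohorts of eggs at
a known true interval under a constant calibrated temperature, each
landmark drawn PRESENT independently with its cell's frequency — and is the
package's validation surface, since the underlying study reports ordinal
frequencies rather than per-egg numeric outcomes. Two sampling policies:

* `REPRESENTATIVE` (default): the same point probabilities the estimator
  assumes. Passing recovery tests under this policy shows the inference
  machinery is correct *under the model*, i.e. it is a well-specified
  self-consistency check.
* `UNIFORM_IN_RANGE`: per run, each cell's frequency is drawn uniformly
  inside its ordinal range while the estimator still assumes the
  representative values — a mis-specification stress test.

What the simulator does **not** emulate about real casework: biological
developmental asynchrony between eggs (an optional Gaussian jitter on
proportion exists for robustness studies, default 0 and not part of the
calibration), correlated landmark visibility, scorer error beyond the
ABSENT floor, fluctuating-temperature rearing of the calibration cohorts,
and precocious (larviposited) offspring. Passing recovery tests therefore
demonstrates internal consistency and resolution, not field accuracy.

Determinism: each egg's random stream is seeded from (seed, egg index), so
cohorts are bit-for-bit reproducible and order-independent (a longer cohort
extends a shorter one with the same seed); the UNIFORM_IN_RANGE frequency
draws use a separate stream keyed on (seed, interval).

Interval assignment from a continuous proportion uses half-open bins
[i/10, (i+1)/10), with 1.0 assigned to the 100 % interval; eggs whose
uncapped development exceeds 1.0 strictly before collection are flagged
hatched.

## Validation problem sizes

The recovery check runs 200 eggs per true interval at 25 °C (2 200 eggs
total, fixed seed) and requires the modal MAP interval to be the truth or
an adjacent interval with ≥ 90 % credible-set coverage of the truth —
matching the 10–20 % resolution the landmark chronology supports.
Frequency-recovery checks use 10 000-egg cohorts (±3 binomial standard
errors around the representative value; inside the ordinal range for
uniform sampling). Both finish in seconds.

## Known limitations

* Two calibration temperatures only; between them everything is linear
  interpolation, outside them clamping-with-warning. The temperature
  dependence of the ADH requirement deserves denser calibration than two
  points, and the reports label interpolated/extrapolated regimes for this
  reason.
* The intervals are specific to *C. vicina*; landmark chronologies differ
  even among Calliphoridae, so the calibration must not be reused across
  species.
* The 20 % interval genuinely differs between the two temperatures (the
  bright peripheral ring is prevalent at 25 °C but rare at 7.3 °C, where
  early gastrulation dominates); the estimator simply uses the
  per-temperature cells and takes no position on whether this is sampling
  or biology.
* No humidity effects, no nonlinear development-rate models, no
  post-hatching (larval) aging, and no image analysis — landmark scoring is
  a human input.
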