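# Methods

## The black-box energy balance

Growth over a complete batch culture is treated as a small set of lumped
reactions. Catabolism of nutrient D releases Gibbs energy in proportion to
the amount degraded; anabolism consumes energy in proportion to the biomass
formed; the balance per unit biomass defines the overall biomass yield.
All dissipation terms are stored as non-negative magnitudes (kJ/g), and the
balance always reads *catabolic supply = overall dissipation + anabolic
costs*:

    N·g_cat = ΔB·(g_X + g_an)        →        Y = ΔB/N = g_cat/(g_X + g_an)

Because every secreted byproduct is assumed to be re-consumed before
stationary phase (the batch runs to exhaustion), byproduct free energy does
not appear. In the signed notation often used for such balances the
energy-releasing terms (overall dissipation, catabolism) map to −g_X,
−g_cat and the energy-consuming ones (anabolism, biosynthesis) to +g_an,
+g_bsyn; the magnitude convention is used throughout because it makes every
qualitative statement ("precursor supplementation raises the yield",
"a positive catabolic coupling raises ΔB") hold with positive parameters.

Units: nutrient and precursor amounts in µg per well, biomass in µg dry
weight per well, energies in kJ/g, per-amount coupling coefficients in
µg⁻¹.

## Two degradable nutrients with mutual effects

Each catabolic term and the anabolic term acquire a linear "mutual effect"
factor in the other nutrient's initial amount: f_cat1 = 1 + m_cat_1·N₂,
f_cat2 = 1 + m_cat_2·N₁, f_an = 1 + m_an_1·N₁ + m_an_2·N₂. Solving the
balance for ΔB gives

    ΔB = (g₁N₁ + g₂N₂ + Δm_CAT·N₁N₂) / (g_X + g_an·f_an),
    Δm_CAT = g₁·m_cat_1 + g₂·m_cat_2.

Only the combination Δm_CAT enters ΔB, so the individual catabolic
coefficients are not identifiable from endpoint data; the fitting layer
exposes the reduced parameterization

    ΔB = (Y₁N₁ + Y₂N₂ + δ·N₁N₂) / (1 + α₁N₁ + α₂N₂)

with Y_i = g_i/(g_X+g_an), δ = Δm_CAT/(g_X+g_an), α_i = g_an·m_an_i/(g_X+g_an),
and refuses designs with a single base amount (δ would be confounded with
the yields). A useful analytic consequence, used as a cross-check
throughout: with α = 0 the yield of nutrient 1 at fixed N₂ is exactly
(g₁ + Δm_CAT·N₂)/(g_X+g_an) — linear in the base amount with slope δ.

## Degradable nutrient plus a non-degradable biomass precursor

The anabolic reaction is split into biosynthesis of the precursor
(magnitude g_bsyn) and the remainder (g_an_excl). The utilization ratio

    M_utl = min(1, M / (q_req·ΔB))

is the fraction of the precursor requirement covered externally; q_req
(µg precursor per µg biomass, default 0.02 for a methionine-like amino
acid — about 1.7 µg per ~80 µg of dry biomass) is a required model
constant. Couplings: f_cat = 1 + m_cat·M_utl, f_an = 1 + m_an_N·N +
m_an_M·M_utl, f_bsyn = 1 + m_bsyn·N; the biosynthesis cost is scaled by
(1 − M_utl). Because M_utl contains ΔB, the balance closes into a quadratic
in ΔB on the unsaturated branch (M′ = M/q_req):

    G_A·ΔB² − ΔB·[N·g_cat − g_an_excl·m_an_M·M′ + g_bsyn·(1+m_bsyn·N)·M′]
            − N·g_cat·m_cat·M′ = 0,
    G_A = g_X + g_an_excl·(1 + m_an_N·N) + g_bsyn·(1 + m_bsyn·N).

The physical root is the one continuous with the M → 0 limit (the larger
root; at M = 0 the roots are 0 and N·g_cat/G_A). Branching: the
unsaturated solution is accepted iff its implied M_utl ≤ 1; otherwise the
saturated branch applies (M_utl = 1, biosynthesis term gone, ΔB linear in
N). Validity violations — G_A ≤ 0, a negative discriminant with no
consistent saturated solution, no positive root — raise structured errors
rather than returning clamped values.

An independent numeric solver (`solve_energy_balance_numeric`) solves the
original implicit balance by bracketing and bisection on ΔB with
M_utl = min(1, M′/ΔB), deliberately avoiding the quadratic; the two routes
agree to better than 1e−6 relative across randomized valid draws (measured
~1e−13). When the residual crosses zero more than once (possible for
m_cat < 0) the solver takes the largest root — the branch continuous with
the no-precursor limit.

### Two closures, and where the non-monotone regime lives

With the capped M_utl above, ΔB(M) at fixed N is **provably monotone** up
to a flat saturated tail: the larger quadratic root has an interior
critical point only on a measure-zero parameter locus, the saturated
branch is constant in M, and the branch transition steps downward. The
characteristic *dip-then-linear-rise* dose response seen in precursor
titrations therefore cannot occur under the capped closure.

The package exposes a second, *supply-limited* closure
(`closure="supply_limited"`): M′ = M/q_req at every dose, i.e. the supplied
precursor is treated as fully incorporated even beyond the point where it
covers the requirement (the biosynthesis relief term then overshoots). On
this closure the quadratic's solution set has a fold — a window of doses
with no real root — flanked by a decreasing low-dose branch and an
increasing high-dose branch: exactly the dip-then-recovery shape. Solution
-space exploration (`map_solution_space`) uses this closure for precursor
sweeps and treats fold-gap doses as missing; a curve that strictly
decreases before the gap and strictly increases after it is labelled
non-monotone. The capped closure remains the default everywhere else
(fitting, simulation, the numeric oracle) because it is the
self-consistent reading of the utilization cap.

## Curve processing

* OD600 → linearized OD via a monotone piecewise-linear calibration map
  (identity by default; out-of-range readings are extrapolated with the
  terminal slopes and logged), then → µg dry weight per well with
  0.396 g DW·L⁻¹·OD⁻¹ and a 200 µl well volume.
* ΔB = B(t_peak + 4 h) − B(t₀), the sample nearest the target time; 4 h is
  the midpoint of a 3–5 h stationary window and is configurable. The peak
  is anchored at the first sample reaching 99.9% of the maximum so
  asymptotically plateauing curves anchor at stationary-phase onset.
* Growth rate: best sliding-window log-linear fit (7 points ≈ 1 h at
  10-min sampling), window chosen by maximal R², ties to the earliest;
  flagged unreliable below R² = 0.95 or at rates ≤ 1e−3 h⁻¹.
* Diauxic segmentation: the derivative of 5-point-smoothed log biomass
  defines growth phases (rate ≥ 20% of its peak); the two changepoints
  flanking the inter-phase plateau are refined by exhaustively minimising
  within-segment rate variance. Phase-1 gain is B(plateau start) − B(0);
  phase-2 gain runs to the end of the trajectory (the stationary tail is
  flat), while its rate is fitted on the active growth interval only. A
  missing second phase yields a single-phase flag, not an error.

## Yield pipeline

Replicate ΔB values are averaged per condition (mean ± SE, deterministic
ordering). The linear region is the longest contiguous window of at least
4 points whose OLS fit reaches R² ≥ 0.9 (ties → higher R², then leftmost);
if none qualifies the caller must supply a range. Yields are unweighted
OLS slopes on replicate means. Segmented fits enumerate every admissible
breakpoint (≥ 3 points per segment) and keep the SSE-minimising pair of
per-segment OLS lines; SSE ties (continuous piecewise data) resolve to the
larger breakpoint so the junction sample stays in phase 1; each segment is
also tested against a constant model with a nested F-test at α = 0.05, and
the two-slope fit is flagged effectively-linear when the slopes agree
within 2 joint SEs. The yield-vs-base trend is an OLS line through the
per-base yields whose slope SE combines the residual-based estimate in
quadrature with the per-yield errors propagated through the slope
estimator (the residual SE alone understates the uncertainty with few base
amounts). The acetate secretion rate is the acetate-vs-OD slope times the
growth rate, also expressed per gram dry weight via the OD calibration.

## Fitting mutual effects

Both reduced models are fitted by trust-region nonlinear least squares
(scipy `least_squares`) with a 5-start seeded multistart (±50% log-uniform
perturbations). Residuals are weighted by 1/ΔB by default, matching the
multiplicative error structure of plate-reader endpoints (floored at 5% of
the largest ΔB to keep near-zero endpoints from dominating). Standard
errors come from the Gauss–Newton covariance s²(JᵀJ)⁻¹. Effects are
classified qualitatively by a 2-SE rule: positive/negative only when the
estimate is more than two standard errors from zero.

Identifiability is reported honestly: for the precursor model the pair
(b = g_bsyn/G_A0, m_bsyn) is an intercept/slope decomposition of the
biosynthesis gain profile b_eff(N) = b(1 + m_bsyn·N) whose intercept sits
at N = 0, far outside any realistic design; at 2% endpoint noise the two
trade off almost perfectly while b_eff at sampled base amounts is
recovered to a few percent. `PrecursorFitResult.biosynthesis_gain_at`
exposes the identifiable combination.

## Synthetic data

The generator realises the models as data under the study's conditions:
triplicate wells, 10-minute sampling, multiplicative Gaussian endpoint and
OD noise (default CV 2%, truncated at −90% to preserve positivity),
measured amounts up to 240 µg/well, base amounts up to 160–240 µg/well,
inoculum ≈ 4 µg dry weight (OD ≈ 0.05 in 200 µl). Diauxic trajectories are
a phenomenological two-exponential construction — growth at µ₁ (0.9 h⁻¹)
to a fraction (70%) of the target ΔB, a 3 h plateau, growth at µ₂
(0.3 h⁻¹) to the target, then flat — because the endpoint, not the
trajectory, is the object of the model; Monod-style kinetics, evaporation,
plate-edge effects and time-resolved byproduct dynamics are deliberately
not emulated, so passing round-trip tests demonstrate correctness of the
endpoint analysis, not robustness to every real-plate artifact. All
generators are bit-reproducible under a fixed seed.

Parameter-recovery studies use dose grids dense in the informative region
(for the precursor model, the low-dose window below saturation where the
dip lives — mirroring real titrations that sample the low end densely) and
6 base amounts spanning 20–240 µg.

## Numerical choices and limitations

* Bisection tolerance 1e−12 relative, 1024-point bracketing grid for the
  energy-balance oracle; quadratic solved in closed form.
* Changepoint and breakpoint searches are exhaustive on the observed
  grids — deterministic, no randomness anywhere outside the generators.
* The model family is an endpoint description: it cannot represent
  dual-role nutrients that are simultaneously degradable and biomass
  precursors (e.g. aspartate); for such data only the descriptive
  two-phase segmented fit applies.
* Raw Gibbs-energy magnitudes are never estimated from ΔB data alone —
  only reduced (scaled) combinations are; helpers accept user-supplied
  energy values for conversion.
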