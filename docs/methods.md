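# Methods

## Model structure

Two cell-type parameterizations (human erythrocyte; resting anaerobic
skeletal muscle) share one model skeleton: the three upper-glycolysis
reactions (HK, GPI, PFK), a lumped ATP-consuming load, and an adenylate pool
A = [ATP] + [ADP] + [AMP] that is conserved on the time scales of interest.
Glucose and orthophosphate are held constant.  The pentose-phosphate
pathway, the 2,3-bisphosphoglycerate shunt, oxidative phosphorylation and
the creatine-kinase system are outside the model's scope; in cells where
those routes carry significant flux the quantitative conclusions do not
transfer.

Upper glycolysis determines the steady-state flux; the lower-glycolysis
kinases are represented by the stoichiometric identity V_PGK = V_PK =
2 V_PFK.  The ATP balance of the whole pathway is therefore
−V_HK + 3 V_PFK − V_ATPase (HK and PFK each consume one ATP; PGK and PK
together produce four per PFK turnover), and net glycolytic production is
3 V_PFK − V_HK, equal to 2 V_PFK at any steady state.

### Rate laws

* **HK** (irreversible, G6P product inhibition):
  `V = A_HK (ATP/K_HK1) / (1 + ATP/K_HK1 + G6P/K_HK2)`.
* **GPI** (reversible isomerization, equilibrium ratio [G6P]/[F6P] = K_GPI1):
  `V = A_GPI ((G6P − K_GPI1 F6P)/K_GPI2) / (1 + G6P/K_GPI2 + F6P/K_GPI3)`.
  K_GPI1 = 3 is treated as dimensionless; the alternative reading
  (G6P − F6P/K_GPI1 with K_GPI1 in mM) predicts a flux of ~56 mM/h at the
  erythrocyte operating point instead of the ~1.17 mM/h that balances HK,
  and is rejected on that numerical anchor.
* **PFK**: with r = AMP/K_PFK3,

      V = A_PFK (1 + Pi/K_PFK6) · F6P/(F6P+K_PFK1) · ATP/(ATP+K_PFK2)
          · (1 + 2r)/(1 + r)
          · 1 / (1 + L0 [ (1 + ATP_i/K_PFK4) / ((1 + r)(1 + F6P/K_PFK5)) ]^4)

  with L0 = 10⁸.  The factor grouping was fixed by two anchors: the rate at
  the erythrocyte operating point (ATP 1.5 mM, F6P 23.1 µM, AMP 41 µM,
  Pi 1 mM) must equal ≈1.17 mM/h (computed: 1.169), and the rate must fall
  monotonically with ATP above ~1 mM at fixed substrate.  "Removing" ATP
  inhibition means freezing ATP_i at 1.5 mM inside the inhibitory factor
  while every other ATP occurrence varies; freezing rather than deleting
  leaves the normal operating point exactly unchanged.
* **ATPase**: linear `a·ATP` or hyperbolic `V_max ATP/(ATP + K_ATP)` with
  K_ATP = 10 µM ≪ physiological ATP.  The linear activity is stored in h⁻¹
  (erythrocyte 1.57, muscle 5.16) so that a·[ATP] is a flux in mM/h; with
  ATP = 1.5 mM this balances the 2.34 mM/h net production of the erythrocyte
  model, which fixes the unit interpretation.

### Units and parameters

Internally everything is mM and hours.  Configuration files may carry
per-entry units (µM values are converted on load); dumps always include a
units field.  The two built-in sets differ in the three enzyme activities,
Pi (1 vs 2 mM), pool size (1.79 vs 5.4 mM), ATPase parameters, and the
clamped AMP used in AK-free mode (40 vs 30 µM); the Michaelis/allosteric
constants are shared.  The AK equilibrium constant defaults to K = 1
exactly, which reproduces ADP ≈ 250 µM and AMP ≈ 41 µM at ATP = 1.5 mM for
the 1.79 mM pool.  K = 0.25 is rejected at validation (the closed-form
split divides by 4K − 1).

## Adenylate algebra

With AK equilibrated, E = 2[ATP] + [ADP] is the single adenylate degree of
freedom and its balance contains no AK flux.  The split of E uses
Q = √(A² − 2AE + E² + 8AEK − 4E²K), ATP = ½[E + (A−Q)/(4K−1)],
ADP = (Q−A)/(4K−1), AMP = A − ATP − ADP; of the two quadratic roots this is
the unique one with all three concentrations non-negative for 0 ≤ E ≤ 2A
(asserted against an independent bisection solver in the tests).
Concentrations within −10⁻¹² of zero are clamped to zero to absorb round-off
at the E = 0 and E = 2A boundaries; anything more negative raises an
infeasibility error.  For clamped-ATP scans the complementary pair is
ADP = [√(ATP(4KA + ATP − 4K·ATP)) − ATP]/(2K), AMP = A − ATP − ADP.  The
quadratic approximation AMP ≈ A(1 − ATP/A)² is provided for illustration
only and never used inside the dynamics (it overestimates the exact AMP by
~14% at the erythrocyte operating point).

The AK rate is reconstructed along trajectories as
V_AK = d[AMP]/dt = (E − A − Q)/(2Q) · dE/dt; positive values mean AK is
producing ATP (and AMP) from ADP.

## Numerics

* **Integration**: LSODA with rtol 10⁻⁸ / atol 10⁻¹⁰ mM; a terminal state
  counts as converged when every |d/dt| < 10⁻⁶ mM/h.  The unreduced
  five-variable model with explicit mass-action AK (forward constant chosen
  as a stated multiple of the glycolytic flux scale) is stiff and uses
  Radau; it serves purely as the independent oracle for the equilibrium
  reduction (agreement: <1% of the state at 10³× flux-scale AK activity,
  <0.1% at 10⁴×).
* **Characteristic curves**: for each clamped ATP the two-variable steady
  state (G6P, F6P) is solved in log-concentration space (Powell hybrid,
  retried from shifted guesses) to a flux-balance residual below 10⁻⁸ mM/h;
  non-converged points are flagged, never dropped.  The default grid is 400
  points on (0.02A, 0.995A), swept outward from the physiological point by
  natural-parameter continuation.
* **Steady states**: characteristic/ATPase intersections are bracketed on
  the grid, refined by scalar root-finding, then polished by a full
  three-variable solve on the dynamic system.  Stability comes from the
  eigenvalues of a central finite-difference Jacobian; real parts within
  ±10⁻⁹ h⁻¹ of zero are flagged "marginal" rather than silently classified
  (fold points sit at zero).  Branch labels follow the local slope of the
  characteristic.  When no nonzero state exists the ATP-depleted state is
  reported as the sole attractor; its Jacobian is degenerate (a zero
  eigenvalue along the GPI-equilibrium line), so no eigenvalues are attached
  to it.
* **Bifurcation diagrams**: the characteristic is ATPase-independent, so it
  is computed once and intersected per activity; the saddle-node activity is
  bracketed by bisection to 0.1% between the last activity with a nonzero
  state and the first without.  For the erythrocyte hyperbolic load it lands
  within ~1% above the characteristic maximum (the K_ATP = 10 µM offset).
* **Stabilization metrics**: C = d ln[ATP]_ST / d ln a by central difference
  with a ±2% activity step on the stable branch; Q = −1/C.  The linear toy
  model provides the closed-form reference (Q = 1 − b/a).
* **Pool-sweep overlay**: each curve is normalized by its maximum point on
  both axes and compared on a fixed window of 0.1–1.9 in peak-normalized ATP
  units (ascending branch through the descending branch down to near-zero
  flux); the extreme tails outside the window, where the grids end at
  different relative positions, are excluded.  The reported statistic is the
  largest pairwise pointwise difference in units of the (unit) peak.

## Scenario generator

Scenarios are the package's synthetic experiments: serializable
(base cell type, overrides, AK mode, ATP-inhibition flag, seed) records that
reproduce bit-identically at fixed solver settings.  The built-in factories
cover the HK-inhibition-constant sweep with co-adjusted HK activity, the
regulation knockouts (frozen ATP inhibition; clamped AMP), pool variants,
and log-uniform random perturbations of the three enzyme activities drawn
from numpy's PCG64 generator (algorithm name recorded in the file).  The
ensembles emulate enzyme-activity variability between cells; they do not
emulate measurement noise, pool drift, or correlated enzyme expression, so
ensemble results speak to parametric robustness of the curve shape, not to
inference from noisy data.

## Observed behaviour and known limitations

All quantities below are computed by the test suite or the acceptance
script.

* The erythrocyte model's normal steady state reproduces the published
  operating point to well under 1% (ATP 1.499 mM, V_PFK 1.176 mM/h, net
  production 2.353 mM/h, G6P 70.3 µM, F6P 23.0 µM); the muscle model gives
  V_PFK 12.85 mM/h and production 25.70 mM/h.
* ATP stabilization is asymmetric around the default load: a twofold load
  step from half-normal to normal moves steady ATP by ≈9%, while a step
  from normal to double moves it by ≈17.5% (the descending branch steepens
  below the operating point).  The stabilization coefficient at the default
  load is Q ≈ 5.4.
* The maximal transient AK share after the twofold load steps is 18.5%
  (linear) and 17.5% (hyperbolic) with the share defined as
  100·V_AK⁺/((3V_PFK − V_HK) + V_AK⁺).  Counting gross lower-glycolysis
  production (4 V_PFK) in the denominator instead roughly halves these
  numbers (~10%); the net convention is the default and the sensitivity is
  asserted in the tests.
* Normalized pool-sweep curves (pools 0.9/1.79/3.58 mM) agree to within 2%
  of peak through the peak and physiological region; the worst-case
  deviation over the full overlay window is ≈6% of peak, on the deep
  ascending branch where absolute Michaelis constants break the exact
  ATP/A scaling of the adenylate ratios.
* The characteristic's peak height grows monotonically but sub-proportionally
  with HK activity (ratio 1.73 at 2× A_HK, 0.56 at 0.5×).
* Weakening AMP activation of PFK by raising K_PFK3 100× flattens the bell
  to a vestigial bump (<5% of peak above the high-ATP endpoint); at 1000×
  the curve is strictly monotone increasing.
* Energy charge exceeds relative ATP by ~7 percentage points at the
  operating point and by ≤12 over the descending branch, so the
  characteristic plotted against φ is a slightly shifted copy of the curve
  against ATP/A.

SBML export is not implemented; the YAML parameter/scenario files plus the
equations above are the portable model description.
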