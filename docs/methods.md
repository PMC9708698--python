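# Methods

## Kinetic model

Imino-proton exchange is modelled as the two-state scheme
closed ⇌ open → exchanged, with opening rate k_open (s⁻¹), closing rate
k_close (s⁻¹) and open-state exchange rate k_ex,open (s⁻¹), giving the
overall rate k_ex = k_open·k_ex,open/(k_close + k_ex,open). The model
assumes (i) the open state is sparsely populated (k_close ≫ k_open), so
opening events are rare and uncorrelated, and (ii) exchange from the
closed state is negligible. Two consequences are used throughout:
k_ex ≤ k_open always, and k_ex → k_open as the catalyst saturates (EX1).

Open-state exchange is taken proportional to the base-catalyst
concentration, k_ex,open = k_B·[B], the standard base-catalysis
assumption; k_B (mM⁻¹s⁻¹) is not separately identifiable from titration
data (only K_half = k_close/k_B is), and defaults to 1.

## Transfer equation and its oracle

The water-magnetization-transfer curve is
I(t)/I0 = 1 − 2·k_ex/(R1w − R1a)·(e^(−R1a·t) − e^(−R1w·t)). The R1a
entering this equation is the *apparent* imino relaxation rate, as
measured by selective inversion recovery — it already contains the
exchange contribution. Under that reading the equation is the exact
dilute-limit solution of the coupled two-pool longitudinal exchange
system, which `core_model.mcconnell_two_pool` integrates numerically
(LSODA, rtol 1e-10) with detailed-balance back-exchange
(k_water→imino = k_ex/pool_ratio). The equivalence is asserted to
≤1e-4 relative over a grid of rates for pool ratios ≥1e5, with the
closed form evaluated at R1a = R1a_intrinsic + k_ex. When
|R1w − R1a| < 1e-9 s⁻¹ the implementation switches to the analytic
limit 1 − 2·k_ex·t·e^(−R1a·t); the branch is continuous to ≤1e-8.
Perfect water inversion (the factor 2) is assumed; an
inversion-efficiency scalar (default 1.0) is available.

## Fitting

* **Recovery fits.** I(t) = I∞·(1 − a·e^(−R1·t)) with a = 2 (inversion)
  or 1 (saturation), via Levenberg–Marquardt (`scipy.optimize.curve_fit`)
  with the rate initialised from the earliest point; standard errors are
  asymptotic. Vanishing-amplitude or non-positive-rate solutions raise a
  fit failure rather than returning a number.
* **Exchange fit.** The transfer model I0·(1 − k_ex·h(t)) is linear in
  (I0, I0·k_ex), so the least-squares optimum is computed exactly by
  linear algebra on the design [1, −h(t)] — no iterative optimiser, no
  convergence failures, and exact invariance to intensity scaling. The
  physical bound k_ex ≥ 0 (and a cap at 10⁴ s⁻¹) is enforced by
  projection, refitting the amplitude at the bound. R1a/R1w are held
  fixed at their recovery-fit values; their uncertainties are not
  propagated into the Monte Carlo (the error model attributes the error
  bars to intensity noise alone).
* **Monte Carlo.** 50 replicates (default) perturb the *observed*
  intensities with independent Gaussian noise of the spectral noise sd;
  the reported k_ex is the replicate mean ± sd next to the unperturbed
  point estimate. Replicate failures are counted and >20% flags the
  result. All randomness derives from one seed via numpy Generators.
* **Leakage correction.** If a fraction L of the signal is lost linearly
  over the n spectra, the spectrum recorded k-th is multiplied by
  1/(1 − L·(k−1)/(n−1)) — in acquisition order, which matters because
  the delays are recorded scrambled (0.1, 0.001, 0.01, 0.06, 0.03 s).
  For L = 0.16, n = 5 this gives {1, 1/0.96, 1/0.92, 1/0.88, 1/0.84}.
* **Averaging modes.** For overlapped peaks, per-series curves are
  normalised to the shortest-delay point, averaged per delay, and fit
  once; per-residue summaries use the unweighted mean of MC means with
  the sample sd across residues.

## Catalyst speciation

[B] = c0·10^(−pKa)/(10^(−pH) + 10^(−pKa)), concentrations in mM. The
Tris pKa defaults to 8.256 at the experiments' 18 °C (8.06 at 25 °C,
temperature coefficient −0.028 K⁻¹) and is a config field, not a
constant; this default reproduces the correspondence of ~100 mM base
form with ~300 mM total Tris at pH 8.0. Activity corrections and
ionic-strength pKa shifts are out of scope. The two-sample exchange
titration (equal-volume swaps keeping pH and crowders constant) is
modelled by `titration_mixing_schedule`, which conserves total mass.

## Titration inference and the in-cell verdict

k_open (in vitro) is the maximum k_ex over the titration (plateau rule),
carrying that point's MC sd; a non-plateau flag is raised when the two
highest-concentration points still differ by >2 combined sd. A
saturation fit k_ex([B]) = k_open·[B]/(K_half+[B]) is provided as a
clearly labelled model-based extension. The in-cell verdict is
`increased_in_cell` iff k_ex(in-cell) − m·sd > k_open(in vitro) + m·sd
with m = 1 by default (configurable); the underlying bound is one-sided,
so the only alternative is `indeterminate` — the ±1-sd separation rule
is this package's explicit formalisation of an error-bar comparison that
is otherwise only made visually.

## Synthetic data

The generator emulates the hairpin study design: five imino residues,
per-residue (k_open, k_close) solved in closed form so the two-state
model passes through the published exchange rates at 10 and 300 mM total
catalyst (pH 8.0, pKa 8.256); the five delays in their scrambled
recording order; homoscedastic additive Gaussian intensity noise with
sd 0.01·I0 in vitro and 0.05·I0 in cells (the ~5× factor emulates the
broader, noisier in-cell lines; the true in-cell noise magnitude is not
published, so only plausible emulation is possible). The in-cell
condition is generated directly from the published in-cell k_ex — the
intracellular catalyst content is unknown by construction — with the
generating in-cell opening rate placed at mid-saturation
(k_open = 2·k_ex) unless declared explicitly. Recovery curves use 11
log-spaced delays (2 ms–4 s) covering apparent rates from ~0.3 to
~40 s⁻¹.

What passing tests show: the estimation chain is unbiased (<5% median
relative bias over k_ex ∈ [0.5, 40] s⁻¹ at these noise levels), its MC
error bars have roughly nominal 1-sd coverage, and the end-to-end
pipeline reproduces the published verdict pattern when fed data with the
published rates. What they do not show: robustness to baseline
distortion, peak overlap, lineshape changes, heteroscedastic or
correlated noise, or catalyst-dependent relaxation not captured by the
apparent-R1a convention — real spectra are outside the input boundary.

## Structure screen

`structure_contacts` loads a multi-model PDB/mmCIF ensemble (gemmi),
requires hydrogens and a common atom roster, normalises atom-name
dialects (H4' / H4′ / H4*), and reports every (imino proton, H3'/H4')
pair strictly closer than 5 Å in ≥7 models — "more than six of twelve"
is read as ≥7, with both the cutoff comparison and min_models
configurable for sensitivity checks. Inter- and intra-residue pairs are
both counted (self-pairs excluded); donors default to guanine H1 and
thymine/uracil H3.

## Problem sizes and numerical choices

Default study: 5 residues × 3 conditions × 5 delays for transfer, 11
delays for recovery; MC 50 replicates; the bound property is checked
over 1000 seeded in-cell runs (seconds, thanks to the exact linear
exchange fit). Duplicate titration concentrations collapse to their mean
with a warning; degenerate recovery data (flat series) fail loudly;
k_ex fits of all-equal ratios return exactly 0.

## Known limitations

Only a single monoprotic base catalyst is modelled; k_close and the
open-state lifetime are not estimated in absolute terms (not
identifiable from plateau data); NOE/spin-diffusion magnetization
transfer pathways are addressed only via the geometric screen, not
simulated; the deposited telomere-quadruplex ensemble itself is not
bundled, so the screen's published-structure control requires the user
to supply the PDB file.
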