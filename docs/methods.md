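# Methods

## The equilibration model

A unilamellar vesicle is a spherical shell: aqueous core of diameter
`d − 2t` inside a bilayer of thickness `t`, outer diameter `d` (the
quantity DLS reports — every diameter in this package is an outer
diameter). Per vesicle:

- core volume `(π/6)(d − 2t)³`
- membrane volume `(π/6)(d³ − (d − 2t)³)`
- lipid count `π(d² + (d − 2t)²)/a`, both leaflets, with `a` the area one
  lipid occupies in one leaflet.

A suspension with countable-lipid molarity `C_L` contains
`C_L·N_A / E[N_lipids]` vesicles per litre; multiplying by the expected
per-vesicle core (or membrane) volume gives the excluded-volume fraction

    α = C_L · N_A · E[V_phase] / E[N_lipids] · 10⁻²⁴ L/nm³ .

The model's central assumption is equal chemical activity across the
membrane at equilibrium: the local concentration inside the excluded
phase equals `C_T` (hydrophilic) or `K·C_T` (lipophilic, membrane:water
partition coefficient `K`). Hence `C_max = α·C_E` in bulk units, capped at
the supplied drug `C_T`; when the cap binds the result is flagged
`drug_limited`. Encapsulated plus free drug always equals `C_T` (mole
conservation). Co-loading treats each compound independently in its own
phase — a dilute-solute assumption that ignores competition and any
dye–dye interaction.

Two corollaries follow from the geometry and are enforced by tests: at
fixed `C_L`, the hydrophilic D:L is nearly linear in diameter
(`core volume per lipid ∝ a·(d−2t)³ / (d² + (d−2t)²) ≈ a·d/12` for
`d ≫ t`; R² > 0.999 over 60–200 nm at t = 5 nm), and the lipophilic D:L
is nearly independent of diameter (< 1% spread over the same range),
because membrane volume per lipid is fixed by `t` and `a` alone.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| bilayer thickness `t` | 5.0 | nm | typical DSPC bilayer; never a hidden constant, every entry point takes it |
| area per lipid `a` | 0.45 | nm² | typical DSPC head-group area |
| partition coefficient `K` | 1 | — | membrane concentration equals external at equilibrium unless the user knows better |
| PDI | interpreted as CV² of diameter | — | standard DLS cumulant convention |
| burst-pool rate `k_a` | 4 | 1/h | ≈10-min half-life; unidentifiable from two printed release points, so fixed, exposed as a flag |
| loading rate `k` (generator) | 3 | 1/h | puts the 1-h value at 95% of plateau, i.e. loading that visibly saturates within an hour |
| Avogadro constant | 6.02214076×10²³ | 1/mol | CODATA exact value; all unit conversions centralized in `_units.py` |

"Lipid concentration" means countable lipid (DSPC) only; cholesterol
shapes the membrane geometry but is excluded from D:L mole ratios. The
20 mM figure for the concentrated protocol suspension is only
self-consistent on that basis. Callers who want cholesterol counted can
simply pass total lipid molarity.

Temperature and incubation time are metadata: the model predicts the
equilibrium endpoint, and the observed temperature dependence of loading
efficiency is an empirical matter for fitting. Sub-transition adsorption
(the substantial D:L seen at 4 °C) is represented only in the synthetic
data as a condition mean, not mechanistically — there is no quantitative
model of the membrane-surface binding behind it, and none is attempted.

## Polydispersity

Lognormal diameters with `σ_ln² = ln(1 + PDI)` and mean fixed at the
nominal diameter. Expectations are computed by deterministic quadrature
(`scipy.integrate.quad`) over the distribution truncated at `2t + 1 nm`
(the smallest geometrically valid vesicle), renormalized; truncated mass
above 10⁻⁹ triggers a warning. The seeded Monte-Carlo sampler
(`sample_diameters`, rejection below the same floor) exists as an
independent cross-check and is what the oracle-equivalence tests use:
quadrature and Monte-Carlo agree within 0.5% both at PDI → 0 (against the
monodisperse closed form) and at PDI 0.13.

## Kinetics

Loading: `dl(t) = dl_max(1 − e^{−kt})`, a lumped empirical rate — no
permeability × area / volume decomposition is attempted since no
permeability value is available. Fitting uses `scipy.optimize.curve_fit`
with fixed start `(k = 1/h, dl_max = max observed)` and tight fixed
tolerances for determinism; an all-zero series returns `k = 0` flagged
non-converged.

Release: `released(t) = f_a(1 − e^{−k_a t}) + (1 − f_a)(1 − e^{−k_e t})`,
retained = 1 − released; fractions, not absolute concentrations, are the
state variable, matching percent-retained reporting.
`calibrate_release` solves the two-point system exactly: `f_a` is
eliminated via the first observation and `k_e` found by Brent's method on
`[0, k_a]`; the bracket endpoints diagnose the two failure modes (later
release below the burst-only floor; slow rate that would have to exceed
the fast rate). The solution reproduces both observations to 1e−9 and is
verified by forward simulation before being returned. `fit_release` is
bounded least squares with fixed start `(f_a = 0.2, k_e = 0.01/h)` and
`k_a` held fixed.

## Quantification

Standard curves are linear only (ordinary least squares via
`scipy.stats.linregress`), with exact inverse prediction and a warning on
below-blank signals. Two calibration points are accepted (exact
interpolation); a design with a single distinct concentration is rejected.

Peak detection smooths the spectrum with a quadratic Savitzky–Golay
filter (window ≈ one third of the minimum separation) before
`scipy.signal.find_peaks`, then refines each maximum to the vertex of a
local parabola — on a 1-nm grid with realistic noise this keeps reported
positions within ±2 nm of the true band centers, where the raw noisy
argmax wanders ±4 nm. The prominence threshold is a fraction of the
spectrum's dynamic range (max − min), not of the raw maximum, so constant
baseline offsets cannot change the result. Defaults (10% prominence,
30 nm separation) suit fluorophore pairs ~100 nm apart in emission.

## Synthetic data

Each generator is the statistical inverse of exactly one analysis
operation and ships a `*.truth.json` sidecar with its ground-truth
parameters. Defaults encode the study conditions: ~80 nm populations with
PDI 0.13; condition-mean D:L of 2.39×10⁻⁴ (passive baseline), 0.011
(4 °C adsorption), 0.041 (equilibration at 55 °C); loading that reaches
95% of plateau at 1 h; release calibrated to 20% by 2 h / 25% by 48 h;
emission peaks at 512 and 625 nm. Noise defaults are 10% relative for
D:L-type measurements (the scale of replicate bench SEMs) and 0.03
absolute for retained fractions. What the generators do **not** emulate:
instrument-specific artifacts (DLS autocorrelation, plate-reader
nonlinearity), spectral overlap between fluorophores, serum-interaction
or temperature-dependent mechanisms. Passing recovery tests therefore
demonstrates statistical identifiability under idealized noise, not
robustness to real-instrument systematics.

All randomness is `numpy.random.default_rng` seeded explicitly; a master
seed fans out to per-generator seeds via SHA-256 (`derive_seed`), kept
below 2³¹.

## Design choices and limitations

- The model is an upper-bound volume argument; it contains no pH/ion
  gradient (active loading), no in-core precipitation, no
  membrane-permeability prediction, and no mechanistic temperature
  dependence. Observed loading below the predicted maximum is expected
  and is what the empirical efficiency/kinetics layer describes.
- Problem sizes in the test suite (quadrature tolerances, 50k–200k
  Monte-Carlo samples, 200 fit replicates) were chosen as the smallest
  that make the statistical assertions stable across seeds.
- The drug-limited cap uses `min(C_max, C_T)`; exactly at the boundary
  the result is reported as not drug-limited (the cap is inactive).
- Degenerate inputs are defined, not errors, where a limit exists: zero
  bilayer thickness (no membrane phase), `d = 2t` (no core), zero lipid
  (empty suspension, α = 0), zero drug (D:L = 0).
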