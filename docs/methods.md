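# Methods

## The circuit model

The model is a deliberately small delay-differential system for a
transcription factor that represses its own gene and activates a target,
while a diffusible modifier (sulfane sulfur, tracked in nM
"sulfane-sulfur equivalents") converts it into a weakly DNA-binding
persulfidated form. Species: apo regulator A, persulfidated regulator As,
modifier pool S, target protein G (all nM; time in minutes).

Assumptions worth stating explicitly:

- Transcription and translation of the regulator are collapsed into a
  single discrete delay τ with first-order turnover d_A shared by both
  regulator forms. A pure (un-delayed) negative-feedback ODE of this form
  is monotone and can only relax to its fixed point; the delay is what
  lets the loop oscillate at all.
- Promoter occupancy is quasi-static: Hill functions of the *effective
  repressor* R = A + As/α_K, i.e. the persulfidated form still binds,
  α_K-fold more weakly. Both promoters feel the same α_K (whether the
  modified form activates the target promoter differently is unknown;
  one shift factor is the parsimonious choice).
- Persulfidation is mass-action (k_mod·A·S, consuming one S equivalent),
  reversible through an unspecified cellular reductant at rate k_red; S
  is additionally drained by other sinks (d_S). Donor stoichiometry
  (HS_nH vs S₈) is a config-level conversion factor, default 1.
- Impulse doses are added to S at the nearest grid point; the pre-run
  history (t < 0) is the initial state held constant.

### Default parameters

| parameter | value | units | role |
|---|---|---|---|
| β_A | 20 | nM/min | max regulator synthesis |
| K_rep, n_rep | 100, 2 | nM, – | self-repression half-max, cooperativity |
| τ | 80 | min | expression delay |
| d_A | 0.05 | 1/min | regulator turnover (~14 min half-life) |
| k_mod | 1e-3 | 1/(nM·min) | persulfidation rate constant |
| k_red | 0.01 | 1/min | back-reduction of the persulfide |
| d_S | 0.02 | 1/min | modifier loss to other sinks |
| β_G, K_act, n_act, d_G | 10, 200, 2, 0.05 | | target synthesis/activation/turnover |
| α_K | 20 | – | K_D fold-shift of the persulfidated form |

These give a fixed point A* ≈ 138 nM, delayed loop gain b ≈ −0.066/min
and critical delay τ_c ≈ 58 min, so the default τ = 80 min puts the loop
past its Hopf point: sustained waves with a ~196 min period. The set was
chosen once so that every qualitative regime of interest (waves, pulse
derepression, dominance switch, sensing-dead null) is reachable at
physiological concentration scales (tens of nM regulator, intracellular
sulfane sulfur reported from ~10 μM up to ~500 μM — hence the 0.4–20 μM
doses used in the bundled protocols). Every constant is overridable via
config.

### Linear stability

Linearizing dA/dt = β_A·f(A(t−τ)) − d_A·A about A\* gives
b = β_A·f′(A\*). For b < 0 the delayed scalar equation has a Hopf
bifurcation iff |b| > d_A, at

    τ_c = arccos(−d_A/|b|) / sqrt(b² − d_A²),

else the fixed point is stable at every delay (τ_c = ∞). This closed form
is used both as an analysis output and as the oracle that the simulated
onset of sustained waves must respect.

### Integration

Fixed-step classical RK4 with the method of steps. The delayed term is
read from stored history by cubic Hermite interpolation using stored
left/right derivative limits — impulse doses kink the derivative, and
one-sided limits keep the interpolation (and hence the integration)
4th-order away from the propagated breakpoints at t_event + kτ, where the
solution itself only has higher-derivative discontinuities. Large doses
make the modification flux stiff (rate ≈ k_mod·S per minute), so each
output step is internally subdivided adaptively (bounded by 1000
substeps) based on the current fastest rate; the output grid is
unaffected. States are floored at zero; an excursion below −1e-9 nM
raises instead of being silently clamped. Step-halving agreement is ~1e-5
relative for smooth runs and < 0.1% at dt = 0.5 min across pulse
breakpoints.

### Oscillation and pulse metrics

Peaks are strict local maxima of A above the midrange of the retained
window (default: discard the first 30%); "sustained" requires the last
two peak amplitudes to agree within 20%. Pulse runs are compared with an
identically initialized baseline from the first dose onward:
peak-A ratio, total time with As > A, the lag between A and G first
exceeding their baseline maxima, and the ratio of time-integrated G.
Ties/absences: if neither trace exceeds baseline (e.g. an empty
schedule), the lag is reported as 0.

## Equilibrium binding

Single-species fraction bound solves the 1:1 quadratic with probe
depletion treated exactly (probe and protein are comparable, ~20 nM, in
gel-shift conditions), evaluated on the numerically stable branch
2TD/(s + √(s²−4TD)). The apo/persulfidated mixture solves a strictly
monotone scalar equation for free probe by Brent's method (machine
tolerance), with Kd_As = α_K·Kd_A. Anisotropy is the linear mix
r_free + (r_bound − r_free)·f. K_D fitting is nonlinear least squares
(lmfit Levenberg–Marquardt) in log10 K_D, started at the concentration of
half-maximal observed anisotropy; a curve whose dynamic range is below 3×
a stated noise floor is rejected as unidentifiable rather than fitted.

## Expression quantification

Relative expression is 2^(−(CT_target − CT_ref)) with the amplification
efficiency fixed at 2; replicates are quantified individually and then
averaged (mean ± sample SD), not by averaging CTs. Prevalence percentages
are truncated (not rounded) at the second decimal in exact integer
arithmetic, matching the convention of the genus survey the number comes
from (2,752/3,033 → 90.73%).

## Persulfide mass spectrometry

Digestion follows the conventional tryptic rule (cleave after K/R, not
before P) with configurable missed cleavages, over the 20 canonical
residues. Masses are neutral monoisotopic sums from an embedded 5-decimal
residue table plus water (18.010565 Da); iodoacetamide blocking adds
57.02146 Da (AM) and a persulfidated-then-blocked cysteine adds
89.00353 Da (S-AM), so the S-AM − AM difference is exactly one sulfur,
31.97207 Da — the "+32" MS1 signature. Matching enumerates per-cysteine
modification assignments from a menu, reports everything within a ppm
tolerance ordered by |error| then position, and a charge helper converts
neutral ↔ m/z ((M + z·1.007276)/z) since printed masses in the field are
sometimes [M] and sometimes [M+H]⁺.

The bundled protein is a labelled **synthetic stand-in** (143 aa, Cys at
62/89/113/137 like the real regulator) used wherever the pipeline needs a
sequence; the real AdpA sequence (GenBank CAB87229.1) is an optional
external input (`data/external/CAB87229_adpa.faa`) that enables the
printed-peptide-mass checks but is not redistributed.

## Synthetic data

Generators are seeded (`numpy` Generator; identical seed ⇒ identical
output) and, at zero noise, exactly invert through their analysis stages.
Noise models are assumptions, not measurements — the experiments they
emulate report only mean ± SD of three repeats: Gaussian additive noise
on anisotropy (default sd 0.005) and on CT values (default 0.2 cycles),
lognormal multiplicative noise on reporter signals and MS1 intensities
(default log-sd 0.05 ≈ 5% CV). The generators reproduce the *designs*
(12-point log-spaced titrations over 10 nM–22.5 μM, triplicate CT tables
against a reference gene, AM/S-AM mass pairs at a 17% intensity ratio
with ppm-scale jitter), not instrument-level artifacts: no melt curves,
efficiency drift, gel smearing, chromatography or isotope envelopes.
Passing tests therefore demonstrate correctness of the arithmetic and
the statistical protocols under the assumed noise, not robustness to
every failure mode of real instruments.

## Parameter inference

Bounded nonlinear least squares (scipy trf) of the simulated reporter
against observations, multi-start (the nominal start plus seeded
multiplicative jitters, optionally augmented by a deterministic coarse
log-grid screen), deterministic given data and seed. Residuals are taken
on log G by default — the maximum-likelihood choice under the
multiplicative noise model; the linear scale remains available.

Identifiability drove the default design: during a single strong dose,
essentially the whole regulator pool is persulfidated and the data
constrain only the combination k_red/(k_mod·S) + 1/α_K that scales the
effective repressor, leaving {k_mod, α_K} on a long curved ridge (fits
then scatter along it even though the local Fisher information looks
adequate). The default protocol therefore uses two doses — 400 nM, where
the k_mod-dependent apo residue dominates, and 20 μM, where the 1/α_K
term dominates — with 28 sampling times over 100–1500 min and triplicate
5% noise. Under this protocol both constants come back within 20% of
truth in ≥ 80% of seeded datasets (100% in the bundled 50-seed study);
profile-likelihood curves are available via `profile_loss`.

## Pipeline

Stages run in a fixed dependency order from a schema-validated config
(unknown keys rejected); each stage writes plain CSV/JSON plus a manifest
with the global seed, per-stage child seeds (SeedSequence spawns) and the
config digest. Reruns of the same config are byte-identical except for
the manifest timestamp. Units are nM/min internally; configs may declare
μM and are converted on read.

## Known limitations

- The delay concretization and its parameter values are the package's own
  defaults; they reproduce the qualitative regimes, not fitted in-vivo
  kinetics.
- Single-site binding only: multi-complex stoichiometries visible in some
  gel shifts (e.g. of the C62S variant) are out of scope.
- The C62S analog is modelled as k_mod = 0 (sensing-dead) only; any
  direct effect of the mutation on DNA binding is not represented.
- No stochastic (molecule-count) simulation; no mRNA-level regulation,
  and no spatial/colony-scale patterning.
- Prevalence/identifiability statements are conditional on the stated
  noise models and designs.
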