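# Methods

## Photophysics

Distances derive from the Förster relations `E = 1 − τ_DA/τ_D` and
`R = R₀(E⁻¹ − 1)^(1/6)`. The Förster radii are taken as given constants
of the dye pairs (Tb³⁺/Bodipy FL 44.9 Å, Tb³⁺/Cy3 61.2 Å); spectral
overlap, orientation factor and quantum-yield corrections are outside
scope. The registry is overridable from a YAML file for other dye
pairs.

Donor-only lifetimes vary with the local environment of each labelled
cysteine and are fit per probe position (two exponentials, the longer
lifetime kept; a warning fires if it carries < 85% of the amplitude).
The synthetic default is τ_D = 2.0 ms, a typical Tb³⁺-chelate scale,
configurable per residue.

Distances are computed per replicate and aggregated as sample
mean ± SD (ddof = 1), not by analytic error propagation: the replicate
spread already contains the lifetime-fit uncertainty, and the
nonlinearity of the sixth-root map makes first-order propagation
unreliable near the ends of the efficiency curve. Distances with
E < 0.02 (≈ 1.9 R₀) sit on the flat tail of the transfer curve and are
flagged low-confidence.

## Decay fitting

Model: `I(t) = Σ aᵢ exp(−t/τᵢ) + b` with 1–3 components, `aᵢ, b ≥ 0`,
sampled after a 0.2 ms acquisition delay (default grid 0.2–10 ms at
10 µs). Fitting uses variable projection — the outer optimizer moves
log-lifetimes, amplitudes are solved linearly at each step — with a
deterministic multistart (log-spaced grids plus, for the 3-component
fit, splits of the 2-component optimum). Variable projection makes the
fit exactly invariant to uniform intensity rescaling.

Residuals are weighted by counting statistics (w = 1/√I with a floor at
1/√(10⁻³·I_max)), the standard choice for photon-counting emission
decays. This matters for model selection: the 2-vs-3 component choice
uses AICc with a two-unit preference threshold, and AICc is only
calibrated when the residuals are homoscedastic — on √I-noise data the
unweighted criterion overfits roughly a quarter of two-component
traces, the weighted one ≲ 5%.

Post-processing applies three rules, in order:

1. **Merge** components whose lifetime ratio is below 1.6: adjacent
   conformer lifetimes in this system differ by at least a factor of
   ~2, so closer pairs are one physical component split by the
   optimizer (when the two-component fit is already at numerical noise,
   i.e. a noiseless trace, the three-component model is not considered
   at all).
2. **Floor**: components contributing less than 5% of the largest
   observable amplitude at the window start (`a·exp(−t₀/τ)`; the t = 0
   amplitude is meaningless for ultra-short components extrapolated
   through the delay) are noise artifacts and are dropped. This assumes
   roughly comparable state populations; both knobs are exposed.
3. **Strip** lifetimes below 0.1 ms as instrument response.

These thresholds are defaults chosen once against the generator's study
conditions (counting noise at 1% of peak intensity); they are
parameters of `fit_decay`, not constants.

## State assignment

Each acceptor channel resolves a window of the distance range. The
assignment uses the channel overlap — the longer Bodipy distance
matching the shorter Cy3 distance identifies the partially open state —
and routes the remaining components: short Bodipy → closed, long Cy3 →
open. Four cases cover the observed channel patterns (two per channel;
one Bodipy + two Cy3 with/without overlap; Cy3 only); patterns without
an overlap anchor keep generic short/long labels rather than guessing
state identities, with an explicit user mapping possible.

The channel match tolerance defaults to `max(3 Å, 2 × pooled SD)`;
matched pairs up to ~5.7 Å apart occur in practice, so the tolerance is
configurable and the raw channel difference is always reported
alongside.

Two physically motivated guards keep boundary artifacts out of the
routing: Bodipy distances above 73 Å (E < 0.05 at the short R₀) and Cy3
distances below 42 Å (E > 0.9 at the long R₀, i.e. sensitized lifetimes
at the instrument-response boundary) are flagged, never assigned. The
second guard is the mirror of the first: the closed-state separation is
only measurable in the Bodipy channel, and without the guard an
instrument component fitted just above the 0.1 ms stripping cutoff
masquerades as a spurious short Cy3 "distance".

## Restraints and model validation

State-resolved distances become unambiguous Cβ–Cβ restraints between
the two Rad50 protomer chains (A/B, 1-based author numbering; Cα
fallback for glycine with a warning). Bounds are ±5 Å for targets up to
75 Å inclusive and ±7 Å above, reflecting the flatter, more error-prone
region of the long-R₀ efficiency curve; the boundary convention
(exactly 75 → ±5) follows the rule's wording "greater than 75". Mixed
pairs are emitted in both directions (donor and acceptor labels are
interchangeable between protomers); identity pairs are their own
mirror. For the partially open state either the mean of the two channel
values (default) or both values may be emitted — the choice is exposed
because either is defensible.

Export uses the CNS/HADDOCK `assign` dialect with stable ordering and a
round-trip parser. Ambiguous interface restraints are accepted only as
a verbatim pass-through file; this package never derives them.
Leave-one-probe-out subsets support dropout robustness runs. Validation
computes Euclidean Cβ–Cβ distances per restraint with a configurable
satisfaction threshold, and cluster consistency reports the SD of each
pair distance across cluster-representative models.

## SAXS population fitting

Theoretical profiles use the orientationally averaged Debye sum with
uniform unit bead form factors (one bead per residue or the synthetic
bead geometry). No hydration layer or excluded-volume term is modelled,
so χ² values against real beamline data are **not** comparable with
atomistic calculators (FoXS-class); the machinery targets relative
model ranking and population deconvolution, which depend on profile
*shape* differences between conformers rather than absolute scale.

Single-state comparison: scale-optimized, σ-weighted χ² with the scale
in closed form; normalization 1/M by default with a 1/(M−1) option
(conventions differ between pipelines). Multi-state fitting minimizes
the χ² of `c·Σ wₖIₖ` under `wₖ ≥ 0, Σwₖ = 1`. Because the global scale
c is free, the simplex constraint is absorbed exactly: unconstrained
nonnegative coefficients are solved by NNLS on σ-whitened profiles and
normalized (`c = Σβ, w = β/c`), which is deterministic and globally
optimal. When fewer states than candidate profiles are requested, all
subsets of that size are fit and the best kept. Proportional profiles
are detected (cosine similarity > 1 − 10⁻¹²) and flagged
non-identifiable.

## Kinetics

ATPase titrations are fit to `v₀ = V_max[S]ⁿ/(K_Mⁿ + [S]ⁿ)` by
least squares (initial guesses: V_max from the maximal rate, K_M from
the concentration nearest half-max, n = 1; n can be fixed at 1 for
plain Michaelis–Menten). At least five distinct concentrations are
required. Ligand depletion is ignored (free ≈ total), valid when the
substrate exceeds the enzyme concentration by orders of magnitude, as
in these assays. Single-site saturation is `L/(L + K_D)`.

## Synthetic data generator

The generator emulates the study conditions so that every stage is
testable round-trip:

- **Decays**: each conformer distance in the bundled reference table is
  mapped to a sensitized lifetime through the inverse Förster relation
  and summed with an instrument component (τ = 0.05 ms, 20% of the
  amplitude) on the 0.2–10 ms grid. Visible states share the remaining
  amplitude equally (true per-state amplitudes are unknown;
  configurable). Noise is Gaussian with σ = max(floor, k·√I) (Poisson
  counting as an option), with every draw flowing through one recorded
  seed; reruns are byte-identical.
- **Channel visibility** is an efficiency window [0.08, 0.93] per
  acceptor: below 0.08 there is no measurable sensitized decay (the
  practical ceiling of ~85–90 Å for the long-R₀ acceptor), above 0.93
  the sensitized lifetime (< 0.15 ms at τ_D = 2 ms) merges with the
  instrument response. This window routes every row of the bundled
  table into the observed channel pattern — closed via Bodipy,
  partially open via both, open via Cy3 — which is what the assignment
  stage relies on.
- **Toy conformers**: two C2-symmetric protomer bead clouds. Probe
  beads are solved (least squares over the protomer-A coordinates, with
  protomer B the C2 image) so that every inter-protomer probe distance
  matches its target to < 10⁻⁶ Å; infeasible target sets raise an error
  naming the worst-violated pair. A deterministic filler cloud gives
  each model a molecular-envelope-like shape for scattering. These are
  *synthetic stand-ins* for docked atomistic models: they reproduce the
  probe network geometry and gross inter-protomer separation, nothing
  else.
- **Scattering mixtures** are population-weighted Debye profiles with a
  σ column (1% of I when noiseless, so χ² stays defined) and optional
  seeded Gaussian noise. **Titrations** are forward Hill kinetics.

What passing tests do and do not show: round-trip recovery on this
generator validates the *inference machinery* — fitting, selection,
assignment, deconvolution — under the stated noise model. It does not
validate the photophysical assumptions themselves (κ², labelling
stoichiometry, donor photobleaching are not simulated), nor
hydration-sensitive scattering features of real beamline data.

## Problem sizes and numerical choices

Default study: 5 probe pairs × 5 conditions × 2 acceptor channels × 3
replicates (150 traces of 981 points) plus donor-only traces; the suite
exercises subsets and a 1000-trace recovery sweep. Optimizer tolerances
are 10⁻¹⁵ (decay fits must resolve distances to ≲ 0.1 Å, i.e. lifetimes
to ~10⁻⁴ relative). Lifetime search bounds are [10⁻³, 4·t_max] ms in
log space. Ties and degeneracies: equal AICc prefers the smaller model;
NNLS zeros drop components exactly.

## Known limitations

- At most two resolvable components per channel are routed; a third
  surviving component raises an over-fit error rather than guessing.
- The partially open state's two channel estimates are averaged for
  restraints by default; if the two dyes perturb the separation
  differently this hides a real discrepancy (the raw difference is
  always reported).
- Population weights below ~1–2% are not recoverable at 1% profile
  noise (degenerate with the noise floor).
- The generator's equal-amplitude default means the amplitude floor in
  decay fitting (5%) is generous; strongly skewed state populations
  would require lowering it.
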