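# Methods

## The generative model

`tcmodel` implements two conductance-based neural mass models of a cortical
column and fits them to amplitude spectra of electrophysiological recordings
(4–80 Hz, the range typically reconstructed from MEG virtual sensors).

The **thalamo-cortical model (TCM)** couples eight populations: layer 4 spiny
stellates (SS), layer 2/3 pyramidal cells (SP) and interneurons (SI), layer 5
pyramidal cells (DP) and interneurons (DI), layer 6 thalamic-projection
pyramidal cells (TP), thalamic reticular neurons (RT) and thalamic relay
neurons (RL). The **cortical comparator (CMC)** keeps SS, SP, SI and DP only.

Each population `i` carries a mean membrane potential `V_i` and one
conductance state per channel. Channels are AMPA, NMDA, GABA_A and GABA_B on
every population, plus M-currents (non-inactivating potassium) and H-currents
(hyperpolarisation-activated) on TP and RL only, giving 8 × 7 = 56 states for
the TCM and 4 × 5 = 20 for the CMC. The equations of motion are

    C_i dV_i/dt = g_L (V_L − V_i) + Σ_n g_n,i (V_n − V_i) + u_i
    dg_n,i/dt   = κ_n (ς_n,i − g_n,i)

with channel reversal potentials `V_n`, decay rates `κ_n`, a fixed leak
(`g_L = 1`, `V_L = −70 mV`, so the membrane time constant is `C/g_L`), and a
constant direct-current input `u` entering RL (TCM) or SS (CMC). Synaptic
drives are `ς_n,i = Σ_j γ_n[i,j] σ(V_j)`, where `σ` is the expected proportion
of source cells firing — the Gaussian CDF of the population potential about a
fixed threshold of −40 mV with per-population dispersion `Σ_j` — and
`γ_n` is the sparse intrinsic connectivity for channel `n`. NMDA currents are
gated by the magnesium-block switch `f(V) = 1/(1 + 0.2 exp(−α V))`
(`α = 0.06 /mV`). M/H drives are logistic functions of the population's own
voltage (M: half-activation −35 mV, slope 10 mV, increasing; H: −75 mV,
slope 5.5 mV, decreasing), giving TP and RL their characteristic intrinsic
dynamics.

All free quantities are **log-scaling coefficients** on prior means
(`value = mean · exp(θ)`), so positivity is structural and `θ = 0` is the
prior mean. A TCM parameter vector has 67 coefficients: 41 connectivity
weights, 6 channel rates, 8 capacitances, 8 firing dispersions, 2 conduction
delays, the input gain and an observation scale.

### Default connectivity and kinetics

The intrinsic pathway list (13 AMPA, 15 NMDA including SP→SP and DP→DP
recurrent self-gains, 13 GABA_A including self-gain diagonals; GABA_B rides on
the GABA_A mask at a fixed ratio) gives exactly 41 free connectivity
parameters and includes the feed-forward SS→SP→DP→TP spine, PING-style
SP↔SI and DP↔DI loops, and the TP→RT/RL→cortex thalamo-cortical loop.
Kinetics follow the conductance-model lineage this family of models descends
from: `κ` prior means 1/2.2 (AMPA), 1/100 (NMDA), 1/5 (GABA_A), 1/300
(GABA_B), 1/160 (M), 1/100 (H) ms⁻¹; reversal potentials +60 mV (AMPA, NMDA),
−90 mV (GABA_A), −100 mV (GABA_B), −70 mV (M), −30 mV (H).

The default coupling strengths (AMPA 1.5, NMDA 0.5, GABA_A 1.5 between
populations; 0.5 on recurrent self-gains; GABA_B at 0.3 of GABA_A; input gain
80) were selected by forward screening for three joint properties:

1. the default TCM holds a stable, bounded limit cycle (sustained
   oscillations with both low-frequency and gamma content);
2. up-scaling the four drug-sensitive pathways (AMPA/NMDA SP→SI, NMDA and
   GABA_A DP→DP) lowers theta/alpha amplitude and raises gamma amplitude —
   the qualitative ketamine signature;
3. the four pathway effects remain *jointly* identifiable: at the fully
   shifted point, removing any single one changes the spectrum by more than
   the measurement-noise scale. This is not automatic — with larger self-gain
   weights an 11-fold GABA_A DP→DP increase silences DP outright, after which
   the spectrum is blind to the other three pathways.

Keeping the self-gain diagonals weaker than the between-population weights is
what keeps ten-fold modulations of the recurrent gains in a graded rather
than saturating regime.

## Numerical integration

Trajectories are integrated with a delayed-Euler scheme,
`y(t+dt) = y(t) + dt · Q f(y(t))`, at `dt = 1/1200 s` over 2 s with the first
300 ms discarded as burn-in (2040 retained samples). The delay operator

    Q = inv(I + D ∘ J)

folds the conduction delays `D` (state-by-state, ms) into the update through
the system Jacobian `J` (central finite differences): first-order Taylor
expansion of `f_i(y_j(t − D_ij))` gives exactly this form for non-negative
delays, and a method-of-steps oracle on a two-state linear delay system
confirms the sign (the opposite sign tracks the true delayed system worse
than ignoring the delay altogether). Defaults place 8 ms on cortex→thalamus
(TP onto RT/RL) and 3 ms on thalamus→cortex (RL onto cortical populations),
an 11 ms loop; both delays are free parameters in fitting.

`Q` is evaluated once at the start of integration — but at the operating
point of the *driven* circuit (the resting state found with the input
current applied). At the zero-input rest the network is silent, all firing
gradients vanish, and `Q` would be indistinguishable from the identity.
The initial state of integration is the deterministic zero-input resting
state, found by damped fixed-point iteration on the voltage balance;
the input transient is absorbed by the burn-in. Integration aborts with a
diagnostic error (carrying the offending parameters) if any membrane
potential leaves ±200 mV. The inner loop is compiled (numba); a pure-Python
reference loop (also used when `Q` is periodically re-evaluated) agrees with
it to ~1e-11 over half a second.

## Observation model

The observed quantity is an amplitude spectrum on a 4–80 Hz, 1 Hz grid. The
voltages of the contributing populations (SS, SP, DP, TP in the TCM; SS, SP,
DP in the CMC) are demeaned and factored by exact dynamic mode decomposition
at rank equal to the number of contributing channels. Per-mode amplitude
spectra (magnitude FFT of the real part of each mode time series) are
combined with energy weights, smoothed with a Gaussian kernel (2 native
frequency bins by default), interpolated onto the analysis grid and scaled by
the observation-scale parameter. DMD rather than a plain channel sum avoids
entangling overlapping rhythms from different populations in a single
channel-weighted residual. A leading-mode-only option exists; energy
weighting is the default so secondary rhythms are not discarded.

## Inversion: variational Laplace

Fitting maximises the Laplace free energy of a Gaussian observation model
(iid noise precision `τ = exp(λ)` across frequency bins) with Gaussian priors
on the coefficients and a Gaussian hyperprior on `λ`:

    F = −τ/2 (e'e + tr(J Σ J')) + m/2 (log τ − log 2π) − KL(q(θ) ‖ p(θ)) − KL(q(λ) ‖ p(λ))

For a linear forward model this equals the log evidence exactly, which the
test suite checks against the conjugate closed form to 1e-6. Optimisation is
regularised Gauss–Newton ascent: sensitivities by central finite differences
on the coefficients (step 1e-3 by default; 0.05 recommended for the
oscillatory circuit, where a broader secant averages over limit-cycle
raggedness), Levenberg–Marquardt damping doubled on rejection and halved on
acceptance, steps accepted only if F increases, and the noise hyperparameter
updated by 1-D Newton ascent within each evaluation. Convergence is declared
after three consecutive accepted steps improving F by less than 0.01 nats.
Unstable candidate parameters (integration divergence) count as rejected
steps. The hyperprior centre defaults to a data-derived value giving a prior
noise SD of about a tenth of the data RMS.

### Global search for oscillatory forward models

The limit-cycle forward model produces a multi-basin, locally rough free
energy surface: plain Gauss–Newton from the prior mean reliably stalls, and
near-degenerate parameter explanations of the same spectrum compete. Two
deterministic aids are built in, both screened by a cheap one-evaluation free
energy and both leaving the prior untouched:

* **branched greedy coordinate search** (`probe_sweeps`, `probe_branches`,
  `probe_steps`): single-coefficient offsets (±1, ±2 by default) are
  screened; the best-scoring first moves on distinct coordinates each root a
  greedy chain; the best endpoint seeds the ascent. After the ascent, up to
  two further greedy-plus-ascent cycles run, accepted only on an F increase.
* **prior-draw multistart** (`n_starts`): additional ascents from the most
  promising of a pool of prior draws.

These are disabled by default (plain VL) and enabled for circuit fits.

### Two-stage group fitting

Group fits first invert the across-dataset mean spectrum from the base
priors, then invert every dataset with priors re-centred on that group
posterior mean (variances unchanged). This shrinks all datasets toward a
common starting basin so that between-condition differences express as
coefficient differences rather than basin lottery.

Connectivity coefficients in group fits use prior variance 1.0 (the package
default of 1/16 applies to kinetics and scale parameters): the drug effects
this pipeline is designed to detect are order-log(10) excursions, which a
1/16-variance prior would place 7–9 SDs away and effectively forbid.

## Model comparison

Fixed-effects selection is the softmax of summed free energies (max-shifted
for overflow safety). Random-effects selection implements the variational
Dirichlet-multinomial scheme (`α₀ = 1`): dataset-wise model responsibilities
and Dirichlet pseudo-counts are iterated to convergence; exceedance
probabilities are Monte-Carlo estimates (10⁶ seeded Dirichlet draws — stable
to about three decimals); the Bayesian omnibus risk (BOR) compares the
evidence of the equal-frequency null against the RFX model's ELBO, and
protected exceedance probabilities blend exceedance with the null according
to BOR. Fit quality is additionally summarised by the across-dataset
correlation between observed and predicted amplitude at each frequency.

## Group statistics

Between-condition differences use paired t statistics with a sign-flip
permutation null (5000 permutations by default, seeded) and family-wise
correction by the permutation distribution of the maximum |t| across
variables (frequencies or parameters). The +1-smoothed p estimate bounds the
attainable p at `1/(n_perm+1)`. Tests run on log-scaling coefficients (the
symmetric scale); effects are reported as percent change of the physical
parameter, `100·(exp(Δθ̄) − 1)`. Variables with zero within-pair variance
are flagged and reported as t = 0, p = 1 rather than silently dropped.

## Synthetic study generator

The generator emulates a 16-subject, two-condition (placebo/ketamine)
crossover: per subject, coefficient offsets shared between conditions
(paired design); in the drug condition four pathway coefficients are shifted
up — AMPA SP→SI and NMDA SP→SI by log 5.7, NMDA DP→DP by log 10, GABA_A
DP→DP by log 11, the reporting scale of the effects this model family is
used to quantify; amplitude noise is additive Gaussian truncated at zero.
All draws are keyed by (seed, subject, condition) so regeneration is
order-independent.

Scale anchors, chosen once for the default regime: measurement noise SD 0.02
(about a tenth of the default spectrum's RMS — trial-averaged spectra are
high-SNR) and subject-level coefficient SD 0.05, which makes between-subject
spectral variability comparable to measurement noise. In this near-critical
oscillatory regime the spectrum responds strongly to small coefficient
changes, so subject variability much larger than this would swamp both the
noise and the injected effects and make the generator's own study design
unidentifiable.

What the generator does **not** emulate: raw MEG time series, beamforming,
trial structure, frequency-correlated (1/f) noise, or between-subject
differences in quantities other than connectivity. Passing tests therefore
demonstrate internal consistency of the modelling pipeline under its own
assumptions, not performance on real MEG spectra.

## The reduced end-to-end study

The full pipeline is exercised on a scaled-down study: 8 subjects × 2
conditions, subject variability restricted to the four injected pathways,
free parameters = the 4 injected connectivity coefficients + the 6 receptor
rates + the observation scale. This mirrors the parameter sets the statistical analysis
is designed around (connectivity and rate constants), keeps every fit's
search space identifiable, and holds the whole study (17 fits plus
permutation statistics) to about ten minutes on one CPU. Problem sizes for all
other analyses: permutation calibration 2000 null replicates at 500
permutations; RFX exceedance 10⁶ Dirichlet draws; recovery checks on 2-free-
parameter fits against a 0.05-spaced grid-search oracle.

## Known limitations

* Per-dataset posteriors over strongly shifted connectivity are direction-
  reliable but magnitude-soft: several pathway effects saturate the spectrum
  (e.g. GABA_A DP→DP beyond ~e¹), so the likelihood pins "up a lot" much
  more sharply than "up exactly eleven-fold". Group statistics on paired
  differences are the intended readout.
* The Laplace posterior covariance is a local curvature estimate; in
  multi-basin regions it understates true uncertainty. The grid-search
  oracle in the tests quantifies this on a 2-parameter plane.
* The delay operator is a first-order treatment of conduction delays,
  adequate for the 11 ms loop against the circuit's slower kinetics; it is
  frozen at the start of integration (a refresh option exists).
* Amplitude spectra discard phase; parameter combinations with matching
  amplitude spectra are inherently indistinguishable.
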