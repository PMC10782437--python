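# Methods

## The selectivity objective

A candidate molecule is scored by the fraction of molecules bound to the
*target* pocket in a canonical ensemble whose states are the target pocket,
a panel of structurally homologous off-target pockets, and an artificial
"anybind" sink:

    P = exp(-β ε_target) / Z,
    Z = exp(-β ε_target) + Σ_j exp(-β ε_offtarget_j) + exp(-β ε_anybind),

with β = 1/(kT), k = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and T = 310 K (so
kT = 0.61603 kcal/mol). Energies are predicted binding free energies in
kcal/mol; all Boltzmann terms are equally weighted (a per-pocket weight
vector is exposed for abundance weighting but defaults to 1 and is
untested against any reference). The sum is evaluated through a
log-sum-exp shift, so arbitrarily deep energies cannot overflow.

The anybind sink energy is calibrated as the mean target-pocket energy of
random latent samples minus 1 kcal/mol (−6.0 kcal/mol for the FLT3 panel).
It encodes the expectation that any molecule finds *some* environment that
binds it at that energy: a molecule whose target binding is not clearly
stronger than the sink cannot score highly, which removes weak binders
from consideration regardless of their off-target profile.

A *hit* is a score strictly greater than 0.5.

When experimental dissociation constants are available, ε = kT·ln(Kd)
(1 M standard state) turns the same objective into a ratio of inverse Kd
values over the pockets with reported measurements:
P ≈ (1/Kd_target) / Σ_i (1/Kd_i). The anybind term and unreported pockets
are omitted, not imputed; for potent binders (nM constants) their Boltzmann
weights are negligible next to exp(−β ε) of a reported nanomolar pocket.
Only energy *differences* enter either form, so the standard-state choice
cannot affect any score.

## Latent space and optimization domain

The generative decoder's latent space has independent standard-normal
coordinates (56 for the pretrained junction-tree VAE; the dimensionality
is a run parameter so the synthetic test landscape can use 4). The
optimizer works in the unit hypercube: u = Φ(z) per coordinate, inverted
by the normal quantile function. Coordinates are clamped to
[10⁻¹⁰, 1−10⁻¹⁰], which keeps the probit finite while leaving the round
trip exact to 10⁻⁹ for |z| ≤ 4 and to 10⁻⁵ for |z| ≤ 6.

## Surrogate model

The surrogate over the hypercube is a GP with an ARD Matérn 5/2 kernel
and a **fixed** observation-noise variance, default 0.2 on the score
scale. The noise is deliberately never re-estimated: duplicate proposals
return cached scores, and a maximum-likelihood noise estimate would
collapse toward zero on those exact repeats. The description of the noise
as "0.2" is interpreted as a variance; an implementation treating it as a
standard deviation can pass `noise_variance=0.04`.

Kernel lengthscales (one per dimension, bounded to [10⁻³, 10] hypercube
units) and the signal variance are fitted by maximizing the log marginal
likelihood with L-BFGS-B using analytic gradients, from one moderate
default start plus ≥4 log-uniform restarts; the prior mean is the constant
mean of the observations (scores live in [0, 1], so a zero mean would bias
expected improvement far from data). Cholesky factorization escalates
jitter 10⁻¹⁰ → 10⁻⁶ on failure. Hyperparameters are refit after every new
observation; at a few hundred training points one fit costs well under a
second.

## Acquisition

Expected improvement, EI = (μ−best)Φ(z) + σφ(z) with z = (μ−best)/σ,
maximization form, zero at σ = 0 when μ ≤ best. Because cached repeats
teach the GP long lengthscales, most of the hypercube is stationary and
naive random multistart ascent fails; the acquisition optima must lie
near the best known points. Each proposal therefore runs 10 independent
rounds of seeding and refinement: 1024 uniform seeds plus 1024 seeds
formed by Gaussian perturbation (sd 0.1 per dimension, in *hypercube*
coordinates — the coordinate system of the optimization; whether the
original perturbation was applied in latent coordinates is not
determinable, so it is exposed as configuration) around history points
with score > 0.4, sampled uniformly with replacement. All seeds are ranked
by EI; the top 64 are refined by bounded L-BFGS-B ascent with analytic EI
gradients, and the best refined point across rounds is proposed. The
refinement never returns less than the seed's own EI (the seed is kept on
the rare optimizer failure). With no above-threshold history points all
seeds are uniform. If a proposal lands within 10⁻⁹ of an existing training
input three times in a row, the next proposal is replaced by a uniform
draw to avoid stalls.

The "ten iterations of seeding and optimization" are implemented as ten
independent seed-and-refine rounds per proposal with the best point taken
across rounds; a shared growing candidate pool is an alternative reading
with no observable difference in the proposal contract (the maximum over
all refined points is returned either way).

## Oracle contract, invalid decodes, duplicate caching

An oracle maps a latent point to a molecule identity plus per-pocket
energies. Decoding is deterministic and many-to-one; identity is the cache
key. About 1% of decodes produce molecules that cannot be embedded in 3-D
and therefore cannot be docked: these are *invalid*, and every pocket is
assigned a fixed placeholder energy of −5.0 kcal/mol (equivalently,
anybind + 1 kcal/mol, selectable for panels with a different anybind
calibration). For a six-pocket panel at the default anybind this yields a
constant score of 0.0903 — low enough to discourage re-exploration and
never a hit. Invalid status and placeholder scores are cached per identity
like any other result.

Duplicate proposals return the previously computed energies and score, and
the repeated (x, y) pair *is* appended to the GP training data at its new
hypercube location: exact repeats at nearby inputs are what teach the
process its long lengthscales. Repeats are excluded from unique-molecule
hit statistics.

## Synthetic landscape

The synthetic oracle emulates the structure of decode + dock without any
chemistry, so the full loop can be exercised in seconds:

- each pocket's energy surface is a baseline (−4.5 kcal/mol) plus 3
  Gaussian wells, centers drawn from the latent prior truncated to
  |z| ≤ 2, depths uniform in [−10, −6] kcal/mol, width 0.45;
- the target pocket receives one designated *selective* well (depth −10)
  whose center is kept ≥ 3 widths from every off-target well center, so a
  high-score region exists by construction (asserted at build time:
  noise-free score > 0.5 at the selective center, < 0.2 far from all
  wells);
- decode identity is the index string of the latent cell of side 0.25
  containing the point; energies are evaluated at the *cell center*, so
  they are a property of the molecule, not of the exact latent point;
- a salted hash of the identity marks ≈1% of cells invalid — invalidity is
  a property of the molecule, as in a real decoder;
- docking noise is Gaussian, sd 0.3 kcal/mol during search and 0.075 at
  validation (mirroring low- vs high-effort docking; a 4× noise reduction
  stands in for the 8 → 64 exhaustiveness increase), seeded per identity
  and fidelity so results are reproducible across processes.

The well width (0.45) was chosen so that random latent sampling yields a
unique-molecule hit rate of a few percent (mean ≈ 4% over ten seeds),
matching the qualitative behavior of the real system, where random
sampling hits ≈ 4.5% of the time. The landscape does **not** emulate the
real system's structure-activity relationships, decoder validity
correlations, or docking-score biases (e.g. the rotatable-bond–dependent
error of empirical scoring functions); passing tests demonstrate that the
optimization machinery works on a landscape with the stated geometry, not
that any particular chemistry will be found.

## Run structure and problem sizes

A full-scale run is 150 random initialization evaluations followed by 200
BO iterations, with hits rescored at validation fidelity and the top 20
reported. The packaged comparison study uses 50 + 100 iterations in 4
dimensions over 10 paired seeds, with the acquisition search scaled to
2 rounds of 128 + 128 seeds and 8 refinement starts and 2 GP restarts —
sizes chosen so the whole study runs in a couple of minutes while leaving
the BO-vs-random contrast unambiguous (BO wins all 10 pairs; one-sided
paired sign test p = 2⁻¹⁰ ≈ 0.001). Hit rates are computed over unique
identities per phase. The real-system hit rates (~4.5% random, ~10% BO)
require the actual decoder and docking engine and are treated as
qualitative anchors only.

## Numerical choices

- Gas constant 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ (kT = 0.61603 kcal/mol at 310 K).
- Score comparisons against published tables use ±0.002: printed energies
  are rounded to 2 d.p. and scores to 3 d.p.
- Hit and seeding thresholds are strict inequalities.
- EI at σ = 0 is the hinge max(μ−best, 0); posterior variance is clipped
  at 0 (and at 10⁻¹⁴ inside gradient computations).
- All run-level randomness derives from one integer seed through spawned
  seed sequences (initialization, per-iteration GP restarts, acquisition,
  stall fallbacks), making histories byte-identical across repeat runs.

## Known limitations

- The real decoder and docking adapters are interface contracts only; no
  weights or binaries ship with the package, and nothing here validates
  docking accuracy.
- The GP is dense; beyond a few thousand observations the cubic cost
  would dominate and a sparse approximation would be needed.
- The Kd-based score ignores unreported off-targets entirely; for a
  molecule with strong unmeasured off-target binding it overestimates
  selectivity.
- Pointwise posterior-mean shrinkage toward each training target holds
  exactly only for a single observation; with correlated training points
  individual residuals can exceed the prior-mean residual (the aggregate
  contraction is what the tests assert).
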