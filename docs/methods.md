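# Methods

## The biological model

Weibel-Palade body (WPB) length is treated as an integer number of VWF
quanta, each molded by one Golgi mini-stack (quantum length l, default
0.576 μm, the median measured in HUVECs). Mini-stacks are occupied by a
quantum independently with probability p — a proxy for cellular VWF
expression — and quanta in laterally linked, adjacent mini-stacks
co-package into a single granule. Every distributional model in
`wpbribbon.models` is a statement about which mini-stacks count as
"adjacent":

* an infinite linear chain (geometric run lengths),
* a population mixture of such chains with cell-specific p,
* finite independent segments of L mini-stacks,
* a long chain plus a fraction q of free stable dimers,
* an infinite chain whose 1Q products are selectively depleted after
  biogenesis (relative abundance factor α = β′/β ≤ 1).

The models are deliberately minimal: no spatial geometry of cisternae, no
lateral diffusion of quanta within the TGN lumen, no kinetics of VWF
arrival or granule budding. Runs are counted at a single steady state.

## Quantization

Measured lengths are divided by l and rounded. The default policy is
round-to-nearest with ties at exact half-multiples rounded away from zero;
a "ceil" policy (round up) is provided as a configurable variant since
both conventions are in circulation for this assay. Ratios within 1e-9 of
an integer are snapped to it first so that exact multiples of l survive
float round-off under either policy. Objects shorter than half a quantum
are clamped to class 1 by default — under the biogenesis model every
segmented WPB contains at least one quantum — with "drop" as the
alternative; neither choice is observable in data generated at the default
noise level.

## Mixtures and quadrature

Occupancy mixtures are represented on discrete p-grids rather than by
symbolic integration, so arbitrary empirical cell populations can be
plugged in. The canonical uniform grid (`uniform_p_grid`) places n equal
weights at the midpoints of n equal cells of [0, 1]: the equal-weight sum
is then a midpoint quadrature rule with O(n⁻²) error (~1e-7 at the default
n = 1001 against the exact 1/(n(n+1)) law), whereas an endpoint-inclusive
grid would be ~1e-4 off at the same size. A p = 1 grid point contributes
only tail mass (its granules are effectively infinite) and is handled
exactly through the explicit tail.

## Truncation and tails

Theoretical distributions are computed to a truncation class n_max
(default 100) together with the analytically exact tail mass beyond it
(e.g. p^n_max for the geometric model, 1/(n_max+1) for the uniform
mixture). All normalization checks and KS comparisons use this
truncated-plus-tail representation; nothing is silently renormalized. For
CDF comparisons the tail acts as a shared final open class, so KS
distances are insensitive to n_max once the tail is small (for p < 0.99
the tail at n_max = 100 is < 1e-40; a doubling test confirms
insensitivity).

## Fitting

The only fit criterion is the Kolmogorov–Smirnov distance (maximal
absolute CDF difference), minimized over parameter grids:

* **p** is fit to the observed distribution conditioned on n ≥ 2,
  renormalized to a proper conditional distribution and compared with the
  geometric conditional tail P(n | n ≥ 2) = p^(n-2)(1-p). This step is
  exactly invariant to the observed 1Q frequency. The grid is uniform
  with step 1e-4 on [0, 0.9999] (matching the four decimals at which p
  is conventionally reported); ties break toward smaller p.
* **α** is then fixed algebraically, α = p·f1/[(1-p)(1-f1)], reproducing
  the observed 1Q frequency exactly. Data whose 1Q class is
  *over*-represented yield α > 1; this is reported with a warning flag
  rather than clamped, as a diagnosis that the data fall outside the
  instability regime.
* **Shared-α series**: each condition keeps its own p; the common α is
  the WPB-count-weighted mean of the per-condition inversions, and
  per-condition predictions use (p_i, shared α). Because the free-α fits
  are a superset, the shared-α weighted KS can never be smaller — the
  test suite asserts this.

No likelihoods, standard errors or goodness-of-fit p-values are produced;
the procedure is a transparent grid search by design.

## The breathing ribbon

Mini-stack monomers and stable dimers link end-to-end at a
size-independent rate r and unlink per bond: d1 for weak bonds
(monomer–dimer or dimer–dimer contacts), d2 for the internal bond of a
dimer, with d2 < d1 the physically expected regime. Two adjacent free
monomers fuse instantly into a dimer, and pieces longer than five
mini-stacks are excluded to keep the state space finite. That yields seven
species (monomer, dimer, trimer, two tetramer isomers, two pentamer
isomers) and 22 reaction channels; ambiguous end-attachments (monomer or
dimer joining a trimer) split 1/2 : 1/2 between the two product isomers,
there being no basis for an end preference. A config toggle
(`dimer_split_in_pieces`) disables d2 splits inside pieces larger than a
free dimer, covering the alternative reading in which only isolated dimers
can dissociate; the default allows them. The test suite re-derives the
entire channel set from explicit monomer/bond layouts of the seven species
with an independent symbolic enumerator.

Stochastic dynamics uses Gillespie's direct method with standard
combinatorial mass action (x(x-1)/2 for identical pairs). A specialized
scalar kernel (numba-compiled when available) is the production path; a
generic channel-table loop is the reference implementation, and the two
are cross-checked statistically in the tests. Every channel conserves the
length-weighted mini-stack count, so conservation is exact at every event
by construction (integer stoichiometry). Simulations require an explicit
seed; replicate streams are derived with `numpy.random.SeedSequence`.

Mean-field ODEs are generated mechanically from the same channel list
(identical-pair propensity x²/2 in the mean-field limit) and integrated
with LSODA to t = 5000 — the operational definition of steady state,
inherited from the assay convention — followed by a residual check
‖dx/dt‖∞ < 1e-8·M. Only the dimensionless groups rM/d1 and d1/d2 affect
steady-state length frequencies; fits therefore fix r = 0.001 and
M = 100,000 (a cell-population scale) and grid-search (d1, d2), with
observed lengths 4 and 5 pooling their indistinguishable isomers. Grid
boundary hits are flagged as a signal to widen the search. In
unbinding-dominated regimes d1 is only weakly identified (steady-state
frequencies flatten in rM/d1), while d1/d2 — the dimer-stability ratio —
is strongly identified; recovery tests reflect this asymmetry.

## Synthetic data

Generators emulate the high-throughput morphometry output the analysis
consumes: ~100,000 WPB lengths per condition (the assay's per-condition
sample size), quanta drawn exactly from the chosen model, lengths n·l plus
Gaussian measurement noise truncated positive. The default noise SD is
0.05 μm — a declared convention, not a measured value; it is set well
below half a quantum (0.288 μm) so that quantization is noise-robust at
default settings, and the tests sweep it. Cell-to-cell occupancy
variability is modeled as Beta(a, b) — a flexible [0,1] family whose
uniform special case reproduces the 1/(n(n+1)) law; no particular family
is implied by the data. Per-cell WPB counts default to ∝ p(1-p), the
expected WPB density of the infinite-ribbon model (cells with occupancy
near 0.5 make the most granules), with equal counts as an option. Golgi
fragment tables are multinomial draws over lengths 1–5. Every generator is
deterministic given its seed and returns a ground-truth manifest.

What the generators do *not* emulate: segmentation artifacts (merged or
truncated organelles), non-Gaussian length error, spatial correlations
between neighboring mini-stacks, or condition-dependent noise. Passing
recovery tests therefore demonstrate correctness of the inference chain
under the stated statistical assumptions, not robustness to imaging
pathology.

## Problem sizes in the test suite

Stochastic consistency checks run at M = 10⁴ mini-stacks (steady-state
frequencies depend only on rM/d1 and d1/d2, so results transfer to the
M = 10⁵ population scale by the tested rescaling invariance), with 20
replicates for SSA-vs-mean-field comparisons at 3 Monte-Carlo standard
errors. Rate-recovery fits use t = 50 (relaxation times are ~1/d2, orders
of magnitude shorter). Parameter-recovery runs use 100 replicates of 10⁵
WPBs. Exhaustive-enumeration cross-checks cover segments up to L = 12.

## Known limitations

* The five-piece cap truncates the aggregation hierarchy; regimes with
  strong binding (large rM/d1) pile mass into the capped classes and the
  model stops being a faithful fragmentation description there.
* The reaction scheme fixes 1/2:1/2 end-attachment splits and instant
  monomer fusion; both are modeling conventions exposed as configuration,
  not measured quantities.
* α > 1 outputs are diagnostic only; the instability model's derivation
  assumes α ≤ 1.
* KS grid fitting gives point estimates without uncertainty; replicate
  synthetic datasets (the `synthetic` module) are the intended way to
  gauge estimator spread.
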