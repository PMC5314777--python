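# Methods

## Assembly model

The cap-binding complex is modelled as a random-order assembly over two
scaffolds — eIF4G (`G`) and the mRNA 5′ end (`R`) — and four ligands —
eIF4A (`A`), eIF4E (`E`), Ded1 (`D`) and Pab1 (`P`). Each scaffold carries
one dedicated site per ligand; each ligand carries one G-facing and one
R-facing site, so within a complex a ligand is bound to G, to R, or bridges
both. Three structural rules define the grammar:

1. at most one copy of each molecule per complex (single-copy rule);
2. no direct G–R bond — the scaffolds communicate only through bridging
   ligands;
3. every complex is connected.

These rules are the unique simple constraints under which the expansion
reproduces the published network size (211 species, 872 reversible binding
reactions with four ligands), and they fix the closed forms

* species(n) = n + 2^(n+1) + 4^n − 3^n,
* reversible pairs(n) = n·(2^n + 4^n − 2·3^(n−1)),

which the test suite verifies against an independent brute-force
graph-growing enumeration for n = 0–4. Binding reactions come in four
forward classes (free ligand onto a G-containing complex, free ligand onto
an R-containing complex, bimolecular bridging of a G-only and an R-only
complex with disjoint ligand content, intramolecular ring closure of a
singly tethered ligand), each paired with exactly one reverse
(terminal unbinding, fission, in-ring bond opening). At four ligands the
forward tally is 180/180/216/296.

Two reactions stand in for the rest of translation: the unique fully
bridged species (all four ligands doubly bound — 8 bonds) associates with a
buffered 43S pool to form an elongating ribosome, releasing the free
factors; the elongating ribosome resolves into a free 40S subunit, a
peptide and the free mRNA. The choice of the all-bridged species as the
initiation substrate is a design decision: it is the only reading under
which exactly two reactions and four new species complete the model
(215 species, 1746 reactions).

## Kinetics

Mass action throughout, in molecule numbers per cell (bimolecular constants
in (molecules/cell)⁻¹ s⁻¹; no volume conversion). The 43S and free-40S
pools are boundary species, leaving 213 time-dependent states. Without
cooperativity, parameters group per ligand as kon/koff to each scaffold,
two intramolecular closure rates and one in-ring bond dissociation rate
(7 × 4), plus the initiation and elongation constants — 30 in total.
Bridging association shares the kon of the bond being formed; fission
shares the corresponding koff.

The peptide count grows linearly once the cycling subsystem is stationary,
so the quasi-steady state is computed as: stiff integration (BDF, analytic
Jacobian, rtol 1e−8 / atol 1e−10) in expanding decades until every
non-peptide rate of change falls below 1e−9 of the largest pool per second,
then a damped Newton polish. The dynamic subsystem conserves the six
molecule totals, which makes the raw Jacobian singular; six residual rows
(the free monomers) are replaced by the conservation equations. A `coarse`
mode (single loose integration + Newton) accelerates fitting loops; the
Newton step restores full accuracy. At convergence the two flux readouts
k_elong·[EL] and k_init·[full]·[43S] agree to ≤1e−6 relative, and the six
conservation laws hold to 1e−6 relative — both asserted in the tests.

Abundance scans recompute the steady state per grid point with one total
rescaled, normalize flux to the 100% point (always inserted), and report
rate-control coefficients as central finite differences of normalized flux
versus normalized abundance.

### Default parameters and totals

The study's fitted rate constants live in supplementary model files that
are not part of the printed record, so the shipped defaults are an
illustrative, clearly non-published set chosen once to express the
qualitative behaviour the printed results establish, with the eIF4G total
fixed at the measured ~22,000 molecules per cell:

| parameter | value | rationale |
|---|---|---|
| kon_G (all ligands) | 1e−4 /molec/s | Kd to the scaffold = 10⁴ molecules, i.e. partners mostly scaffold-bound at nominal abundance |
| kon_R (all ligands) | 1e−8 /molec/s | direct ligand–mRNA binding is weak; partners reach the mRNA through eIF4G |
| koff_G, koff_R | 1 s⁻¹ | sub-second bond lifetimes, fast pre-equilibrium |
| kc_G, kc_R | 10 s⁻¹ | intramolecular closure; closed/open weight kc/koff_bridge = 10 |
| koff_bridge | 1 s⁻¹ | in-ring bond opening |
| k_init | 5e−6 /molec/s | slow initiation drain, keeps assembly near equilibrium |
| k_elong | 2 s⁻¹ | ribosome recycling faster than initiation |
| totals | G 22k, mRNA 60k, A 25k, E 22k, D 22k, P 25k; 43S 10k (fixed), 40S 0 (fixed) | partner factors of the same order as the scaffold; mRNA 5′ ends not limiting |

Two of these choices carry the biology. Weak *direct* ligand–mRNA binding
is what produces the asymmetry the data show: overexpressing a ligand then
cannot saturate the mRNA's sites with ligand copies foreign to the
scaffold's, so eIF4E/eIF4A scans rise to a plateau instead of exhibiting
their own prozone. And partner totals comparable to the scaffold's place
the combinatorial dilution point — where extra eIF4G copies start stealing
partners from each other — right above the physiological abundance, putting
the flux maximum at ~100%. Under these defaults the eIF4G scan is unimodal
(flux 38% at one-fifth and 11% at five-fold the wild-type abundance), and
the summed amount of mRNA-free eIF4G complexes triples between 100% and
500% — the mechanistic signature of prozone inhibition.

## Fitting

Weighted least squares on flux percentages, optimized in log10 parameter
space over a fixed 10-stage schedule alternating Hooke–Jeeves pattern
search (exploratory ± step per coordinate, pattern acceleration, step
halving; default step 0.5 → 1e−4 decades) with global-best particle swarm
(inertia 0.7, cognitive/social 1.5/1.5, positions clamped to bounds,
seeded and reproducible). Every stage warm-starts from the incumbent, so
the best objective is non-increasing. Steady-state failures are charged a
finite penalty (1e6) rather than raised, letting the search cross bad
regions. Because flux is normalized, overall-scale parameters (e.g. the
initiation constant) are structurally non-identifiable from a single scan;
recovery is therefore assessed at the curve level. In the shipped
experiments (one-ligand model, two free constants perturbed by 0.8 and 0.6
decades, scans of the scaffold and the ligand) the schedule returns the
generating curve to ≤5% RMS and the objective below 1e−4 on noiseless
data, with individual constants free to drift along flat directions.
Problem sizes for these experiments (10-species model, 9 grid points,
~120-evaluation pattern-search stages, 6-particle swarms) were chosen to
make the recovery claim at desk scale.

## Cytometry noise pipeline

Stages, in order: (1) drop the first 1.0 s and last 0.2 s of acquisition
(unstable flow); (2) keep events with FSC in 40,000–100,000 and SSC in
10,000–90,000; (3) locate the highest-density centre of the FSC–SSC
scatterplot as the modal bin of a 2-D histogram (default bin 2,500 a.u.;
ties broken by 3×3-smoothed neighbourhood mass, then lowest indices);
(4) gate radially, distanceᵢ = √((FSCᵢ−centre)² + (SSCᵢ−centre)²); (5)
CV = σ/μ with the sample (n−1) standard deviation. The pipeline is a pure
function of (events, config).

The CV-versus-radius curve decreases toward an intrinsic floor as the gate
shrinks. The plateau estimate is the mean CV over the three smallest radii
retaining ≥200 events (default radius grid geometric, 1,000–30,000 a.u.),
with a stability flag if those CVs spread more than 15% — the plateau rule
is one defensible reading of "approach to a minimum CV" and is
configurable.

The dual-reporter statistic Noise² = ⟨(G − M)²⟩/(2⟨G⟩⟨M⟩) is applied after
scaling both channels to a common mean (the two fusions differ in absolute
brightness; the normalization is switchable). It is symmetric and invariant
to common rescaling. For two reporters with intrinsic CV c and a shared
extrinsic factor of CV e, its expectation is c²(1+e²), so √Noise² reads out
the per-reporter intrinsic CV up to the small (1+e²)^½ inflation — 4% at
e = 0.3.

## Synthetic data

The generators emulate the measurement settings, not the instruments. Per
cell: a shared log-normal extrinsic factor s (unit mean, configurable CV);
channel intensity = mean · s · (1 + intrinsic normal deviate, clipped at
0); scatter = mean · s^(2/3) · (1 + 3% measurement noise) — the sublinear
exponent reflects that scatter tracks cell diameter/cross-section while
expression capacity scales with volume; debris (default 5%) is placed
uniformly outside the scatter windows with low fluorescence; timestamps are
uniform. mRNA counts are negative binomial in (mean, CV) parameterization,
exactly Poisson at the dispersion floor CV² = 1/mean, with sub-Poisson
targets rejected. Competition assays are Poisson colony counts split by the
final population fraction r/(1+r). Every generator is a deterministic
function of (config, seed).

What the generators do **not** model: spectral overlap and compensation,
autofluorescence, doublets, instrument saturation or carry-over, cell-cycle
substructure beyond the single size factor, and transcription-level noise
dynamics. Passing the recovery tests therefore shows the estimators are
correct for the stated noise decomposition, not that real cytometry obeys
that decomposition.

## Numerical choices and edge cases

* Integrator BDF with analytic sparse-assembled Jacobian; rel/abs
  tolerances 1e−8/1e−10 (1e−4/1e−6 in coarse mode, Newton-polished).
* Newton: max 50 iterations, backtracking line search with non-negativity
  guard, residual tolerance 1e−10 relative to the largest pool.
* Zero-mRNA or zero-initiation models short-circuit to zero flux; empty
  gates, sub-100-event density estimation, unsorted radii, non-positive
  means and sub-Poisson count targets raise informative errors.
* CVs are reported at full precision and rounded to 2 decimals only for
  display, matching the field's reporting convention.

## Known limitations

* The published fitted parameter values are unavailable, so curve-level
  identity with the published abundance–response data cannot be asserted;
  the defaults reproduce the qualitative (prozone/plateau) behaviour only.
* Which of the 65 six-component species served as the published initiation
  substrate is inferred (the all-bridged one), as is the boundary-species
  choice behind the 213-ODE count.
* The grammar is one counts-consistent reconstruction of the published
  rule set; alternative context restrictions could yield the same counts.
* No stochastic (SSA) simulation, no thermodynamic-cycle constraints on
  rate constants, no eIF4B or repressed-complex extensions.
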