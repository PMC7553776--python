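# Methods

## Competition equilibrium

The model is two receptors, one ligand, 1:1 stoichiometry everywhere and a
well-mixed compartment: free ligand R satisfies

    f(R) = R + A_tot·R/(Kd_A+R) + I_tot·R/(Kd_I+R) − R_tot = 0.

f is strictly increasing on [0, R_tot] (its derivative is ≥ 1), so the
physical root is unique. It is found by 80 rounds of bracketed bisection on
[0, R_tot] followed by Newton polishing to 1e-12 relative on R; Newton is
well conditioned here because f′ ≥ 1. Free receptor concentrations are
evaluated as `total·Kd/(Kd+R)` rather than `total − complex`, which would
cancel catastrophically near saturation and break the mass-action identity
at the 1e-9 relative tolerance the tests enforce.

The linearized mode holds the abundant receptor constant (valid when
A_tot ≫ R_tot and R ≪ Kd_A, both satisfied by the defaults A_tot = 1000 µM,
Kd_A = 125 µM, R_tot = 15 µM): the A-complex becomes exactly linear in free
ligand, A_tot·R/Kd_A, while the I-complex keeps its hyperbolic form
I_tot·R/(Kd_I+R) with the scarce receptor's pool conserved at I_tot. This
is what makes the abundant receptor a buffer: adding ligand loads it
linearly while the tight receptor saturates.

Buffering curves support both a free-ligand axis (grid used directly) and a
total-ligand axis (each grid point solved exactly first); free is the
default since the distinction only matters when ligand depletion by the
receptors is appreciable. Whether "receptor concentration" means free or
total is immaterial in the linearized regime, where the two coincide.

Internal unit is µM throughout the equilibrium module; the nM-scale
affinity of the tight receptor enters as 0.0016 µM. This one-unit policy
avoids silent nM/µM/mM mixing in a system that genuinely spans six orders
of magnitude.

## CSP analysis

CSP_i = sqrt(ΔδH_i² + (α·ΔδN_i)²) with α = 0.14 for every residue type,
configurable. Published weighting schemes differ (a factor ½ inside the
root, glycine-specific α); since both the significance call and the Kd fit
are invariant to a global rescaling of all CSPs, the variant choice cannot
change which residues are called or the fitted constant, so the simplest
form is used. Residues assigned in the reference but missing at a
titration point (broadened or prolines) are reported as absent and excluded
from statistics and fits — never imputed as zero.

Significance: threshold = k·SD with k = 2 by default, SD the population
standard deviation over all assigned residues, strict inequality at the
threshold. An optional iterative mode re-estimates the SD after excluding
values beyond 3 SD until stable; it is off by default because the plain
2-SD rule is the method actually exercised by the tests.

Kd fitting assumes fast exchange: the observed CSP of residue i at molar
ratio r is CSP_max,i · fb(r·P₀, P₀, Kd) with the exact ligand-depletion
fraction bound. For fixed Kd the amplitudes CSP_max,i have a closed-form
non-negative least-squares solution, so the fit reduces to a 1-D profile
optimization over log Kd: a 120-point log-spaced grid scan over
[1e-3, 1e6] µM followed by bounded scalar minimization between the
bracketing grid points (xatol 1e-12 on log10 Kd). Two uncertainties are
reported because they answer different questions: a curvature-based SD
(2s²/∂²SSR/∂Kd² at the optimum — how sharply the data pin the shared
constant) and a leave-one-residue-out jackknife SD (how much any single
residue steers it).

With only one non-zero ratio the shared Kd and the amplitudes are
degenerate; the fit still runs (the contract requires ≥ 1 point) but the
uncertainty fields are the place that degeneracy shows up. All-zero CSPs
raise "no binding signal" rather than returning a boundary value.

## BLI kinetics

Closed-form 1:1 model, association then dissociation, continuous at the
phase boundary. No mass-transport limitation term and no heterogeneous-
ligand model: the analysis chain is the plain Langmuir scheme. Inputs are
assumed double-referenced (blank and bare-sensor subtracted).

The global fit shares kon and koff across all analyte concentrations of an
injection series; Rmax is shared by default (same sensor, same ligand load
within a series) with a per-curve option for capacity drift between
regeneration cycles. Rates are optimized as log10 parameters (kon in
[1e1, 1e10] M⁻¹s⁻¹, koff in [1e-8, 10] s⁻¹) via Levenberg–Marquardt least
squares on the concatenated residuals of both phases of every trace.
Initialization is deterministic: koff from the log-linear slope of the
dissociation tail, kon from the regression of per-curve kobs estimates
(time to reach 1−1/e of the association plateau) against concentration,
Rmax from the plateau back-corrected by C/(C+KD). KD = koff/kon is reported
in nM and the identity holds exactly by construction. Replicate series are
fitted independently and their KDs averaged (arithmetic mean, sample SD),
matching how replicate biosensor experiments are normally summarized.

## Concentration census and blot calibration

conc = copies / (N_A · V_cell · f_compartment) with N_A the CODATA
Avogadro constant, V_cell = 1e-15 L (a cell idealized as a 1 µm cube) and
f = 0.30 for the periplasm. These defaults give 1.107 mM for 200,000
copies, 16.6 µM for 3,000 and 1.107 µM for 200. Note that an often-quoted
intermediate of 3.448e-4 M for 200,000 copies per 1e-15 L implies a
non-standard Avogadro constant; this package uses the standard constant
(3.32e-4 M cellular, 1.107 mM periplasmic) and reports rounded values
("~1 mM") only through an explicit one-significant-figure helper, with the
raw value always retained.

Blot calibration: a tagged protein detected by both antibodies fixes the
sensitivity factor (probe intensity / reference intensity on the same
band); an unknown probed with the probe antibody is then converted to a
concentration by deflating its band by that factor and scaling by a
reference protein of known concentration. Processing order is per-lane
background subtraction (clipped at zero) then per-lane normalization by the
designated non-specific loading band.

## Synthetic data

All generators are deterministic functions of (config, seed) through one
named `numpy` Generator each; no global random state.

**Titration** (defaults: true Kd 125 µM, P₀ 50 µM, ratios 0/2/10,
120 residues, 9 binders): each binding residue gets a fixed random
direction in the (ΔδH, α·ΔδN) plane of unit weighted length, scaled by
CSP_max,i·fb(r·P₀,P₀,Kd); every residue at every point receives Gaussian
shift noise (¹H 0.004 ppm, ¹⁵N 0.02 ppm — typical peak-position
reproducibility on a well-resolved 2D spectrum). CSP_max is drawn from
0.2–0.5 ppm: the generator's binding set models the strongly perturbed
interface residues, with weaker shifters subsumed in the non-binding
background. What the generator deliberately omits: residue-to-residue
variation in the apparent constant (exchange-regime differences, secondary
sites, local dynamics). Real titrations have it, and it — not peak-position
noise — is what dominates the uncertainty of a shared-Kd fit on real data.
Consequently the jackknife spread on synthetic fits (a few µM) is much
smaller than the tens-of-µM spread a real three-point titration produces;
recovery tests on this generator validate the estimator, not the field
error bar of a real experiment.

**BLI** (defaults: kon 1e6 M⁻¹s⁻¹, koff 1.6e-3 s⁻¹, hence KD 1.6 nM;
concentrations 5.9/8.9/13.3/20/30 nM; 1000 s + 1000 s at 1 s sampling;
4 series): closed-form traces plus i.i.d. Gaussian noise of 0.005 nm
(0.5% of the 1 nm Rmax, a typical amplitude for a ~10–15 kDa analyte on a
streptavidin tip at low-nM ligand load). No drift or regeneration
artifacts are simulated, so replicate-to-replicate KD scatter is far
smaller than between real injection series; the 4-series average exercises
the averaging contract, not instrument variability.

**Blot** (defaults: 1 mM reference, 40 µM target, factor 25, 10%
multiplicative lognormal noise per band): three lanes — dual-detected
calibration band, reference band, target band — each with a background and
a non-specific loading band, intensity = sensitivity × concentration ×
lognormal(CV) + background. The lognormal is mean-one so noise does not
bias intensities upward.

## Problem sizes in tests and the acceptance script

Property tests run the solver oracle on 200–1000 random systems
(log-uniform concentrations 1e-3–1e4 µM, Kds 1e-4–1e4 µM), the titration
recovery on 50–200 seeds, and the blot round trip on 100 draws; the
acceptance script fits one titration, four sensorgram series and 8
replicate blots per induction level. These sizes make every check a
few seconds at most while keeping Monte-Carlo medians stable.

## Known limitations

- The competition model has no membrane anchoring, no peptidoglycan
  binding and no phosphorelay kinetics; it describes soluble domains in a
  well-mixed compartment.
- The CSP fit assumes pure fast exchange; intermediate-exchange broadening
  is neither modeled nor detected beyond residues dropping out of a peak
  list.
- The BLI fit has no mass-transport term, so transport-limited data will
  bias kon downward with no warning beyond residual structure.
- Census arithmetic treats copy numbers and geometry as exact; its error
  is entirely the error of those inputs.
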