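# Methods

## The two-site occupancy model

CYP3A4 metabolizes midazolam (MDZ) at two positions: C1 (major product,
1OH-MDZ) and C4 (minor product, 4OH-MDZ). The ratio of the two formation
rates — the site-of-metabolism (SOM) ratio, v_1OH / v_4OH — is sensitive to
occupancy of a peripheral allosteric site between the F-F' and G-G' loops
and the membrane interface: the singly-bound enzyme makes C1 product
exclusively, while a second ligand at the allosteric site (another MDZ
molecule, or a heterotropic effector such as progesterone) switches on 4OH
formation.

`cypsom.model` implements this as a rapid-equilibrium partition function
over the grid {productive site ∈ {empty, S, X}} × {allosteric site ∈
{empty, S, X}} with *strictly stepwise* binding: the allosteric site
carries ligand only when the productive site is occupied, so states with an
occupied allosteric site and empty productive site have zero statistical
weight. For the homotropic case this collapses to the classical stepwise
scheme

    Z = 1 + [S]/K1 + [S]²/(K1·K2)

with stepwise dissociation constants K1 (productive) and K2 (allosteric).
The stepwise form was chosen over independent-site binding because the
binding constants this package defaults to (K1 = 5.1 µM, K2 = 14.7 µM for
MDZ) are stepwise constants: they describe adding the second ligand to the
already-singly-bound enzyme. An independent-site parameterization would
double-count the allosteric-only species that the stepwise constants never
observed.

Each productive state (substrate at the productive site; allosteric site
empty, substrate-occupied, or effector-occupied) turns over with its own
kcat and splits product by its own 4OH fraction `f4oh`. Defaults: all
kcat equal (SOM-focused analysis), `f4oh_s = 0` (exclusive C1 when singly
bound), `f4oh_ss = f4oh_sx = 0.35` (the homotropic ceiling; the 4OH share
of total product approaches but never exceeds 35% in a substrate sweep).
States with effector at the productive site, and the doubly-effector state,
are catalytically silent — only MDZ products are observable.

Sentinels: `kd_allo_x = None` ("disabled") removes effector binding at the
allosteric site; `kd_prod_x = None` ("nobind") removes competitive binding
at the productive site. SOM at zero 4OH rate is NaN, never infinity, so
tables stay serializable.

Units throughout: concentrations µM, rates min⁻¹ per enzyme, distances Å.

## Fitting

`fit_rate_data` minimizes the weighted sum of squared residuals over
(v_1OH, v_4OH) jointly, via `lmfit`/`least_squares`. Dissociation
constants are fitted as log10 values (bounds 10⁻⁴–10⁵ µM), 4OH fractions
box-bounded to [0, 1], kcats non-negative. Ten restarts (configurable)
start from seeded Gaussian perturbations of the initial guess (sd 0.5 on
log10-Kd, 0.15 on fractions, 30% on kcats); ties break by lowest residual,
then lowest parameter norm. After the fit, each free parameter is
perturbed by 5% and a parameter whose perturbation leaves every residual
unchanged (max |Δ| ≤ 1e-10) is flagged non-identifiable — this catches,
e.g., effector constants fitted against effector-free data.

`fit_titration` is an ordinary `curve_fit` of the non-cooperative Langmuir
isotherm B(L) = Bmax·L/(Ks + L) modelling the fractional high-spin shift
of the heme iron; standard errors come from the fit covariance. A flat
response raises an identifiability error rather than returning a
meaningless Ks.

## Effector-mode classification

`classify_effector_mode` compares observed effector-present rates against
the baseline model evaluated at matched substrate concentrations and
returns one of: `no-effect`, `competitive-inhibition`,
`allosteric-4OH-favoring`, `allosteric-4OH-suppressing`, `mixed`.

The SOM comparison is restricted to matched concentrations where the
baseline 4OH share of total product is at least `min_4oh_share` (default
5%). This floor matters: at very low substrate the baseline forms almost
no 4OH, so *any* allosteric occupancy — even by an effector whose own
4OH fraction is low — registers as a large relative SOM drop. The
suppressing direction (effector displacing the second substrate molecule
with a lower 4OH fraction) is only visible where the homotropic minor
product is quantifiable. Among admissible concentrations, the
largest-magnitude relative SOM shift decides the direction (default
threshold ±20%); the total-rate shift is the median over matched
concentrations (default threshold −20% for inhibition). If the baseline
never reaches the floor but the effector data do, the verdict is
4OH-favoring. SOM shifted *and* rates down is `mixed`.

## Trajectory geometry

The reactive oxidant (Compound I, the ferryl Fe=O intermediate) is
represented by a virtual oxygen placed `fe_o_distance` (default 1.65 Å, a
typical ferryl bond length) from the iron along the unit normal of the
least-squares plane through the four pyrrole nitrogens, oriented away from
the proximal cysteine thiolate sulfur (i.e. toward the distal, substrate
face). The construction is rigid-motion equivariant; collinear nitrogens
or an in-plane sulfur raise geometry errors.

Frame classification measures Euclidean distances from the substrate
carbons to the virtual oxygen:

* productive: d(C1, O) ≤ 4.5 Å (inclusive — "within");
* selective: productive and d(C4, O) > 5.5 Å (strict — "more than");
* non-selective: productive but C4 also within 5.5 Å of the oxidant, so
  the minor 4OH product is geometrically accessible.

A known ambiguity: the 5.5 Å criterion could be measured to the virtual
oxygen or to the iron ("further away from heme"); this package fixes the
former, consistent with measuring the productive criterion to the same
point. Both cutoffs are parameters of `ClassificationThresholds`.

Contacts: a residue is in contact with the ligand in a frame iff any
heavy-atom pair distance is ≤ 4.0 Å (hydrogens excluded). No standard
cutoff exists for "close contact"; 4.0 Å is a common heavy-atom choice and
is a parameter. Contact counts are tallied over productive frames only
(via the mask argument), mirroring the analysis the classification feeds.
The between-condition differential reports per-residue relative frequency
change (f_b − f_a)/f_a, flags |change| ≥ 50% as major (the criterion
separating major from minor contact changes), and reports residues with
zero baseline frequency as a "new-contact" category instead of dividing by
zero.

Frame indexing is 0-based over the trajectory as read; stride applies
after reading. MDAnalysis handles all topology/trajectory I/O, so
nm-based formats (XTC) arrive in Å automatically.

## Synthetic data

The generators stand in for unreleased experimental and simulation data;
they reproduce the *statistical structure* the analysis assumes, not the
physics.

* Kinetic datasets evaluate the occupancy model on a design grid (default
  12 log-spaced substrate points, 0.5–100 µM) and add either additive or
  proportional Gaussian noise; noiseless output equals the model exactly.
  Replicates are separate rows, never averaged.
* Titrations evaluate the Langmuir isotherm plus additive noise, clipped
  to [0, 1].
* Toy trajectories write a minimal PDB/DCD system: an idealized planar
  heme pseudo-residue (Fe at the origin, four pyrrole N at ±2 Å on the
  axes, axial S at −2.3 Å), a two-atom ligand (C1, C4), and one CA
  pseudo-atom per CYP3A4 residue of interest (B-C loop 106/108, F-F' loop
  213–221, active site 304/309). Per frame, productive/selective labels
  are Bernoulli draws; C1 and C4 distances to the analytically known
  virtual oxygen come from truncated normals (means 3.8/5.2 Å for C1
  in/out of productive range, 4.8/6.3 Å for C4 near/far, sd 0.3 Å)
  truncated 0.05 Å clear of the 4.5/5.5 Å thresholds, so every label is
  recoverable exactly — no boundary frame exists. Residue atoms are
  placed 3.2 Å from C1 (contact) or parked ~65 Å away (no contact) per
  Bernoulli contact indicators.

What the toy system does *not* emulate: ligand internal geometry (C1 and
C4 are placed independently), protein sterics, membrane, correlated frame
dynamics (frames are i.i.d.), and any energetics. Passing tests therefore
demonstrate correctness of the geometric classification and counting
machinery against known ground truth, not fidelity of MD itself.

Scenario presets pin the concentration designs used throughout: PGS at
15 µM, steroids at 20/50 µM, medroxyprogesterone at 2/8 µM (a tighter
binder, probed lower to avoid complete inhibition), an ANF/Gefitinib-like
preset with `f4oh_sx = 0.05 < 0.35` (SOM shifts opposite to steroids), and
a Schisandrin-like weak effector with a large (70%) spin-shift amplitude.
PGS's allosteric Kd is not established in this system; the preset sets it
to 14.7 µM so that MDZ outcompetes 15 µM effector above ~15 µM substrate,
matching the observed crossover. The two-condition trajectory pair uses
productive probability 0.52 ("slightly more than 50%" of frames) in both
conditions, selective probability 0.8 without effector versus 0.6 with,
and contact probabilities designed so the designated major-loss residues
(106, 108, 215, 218, 220) drop by ≥ 58% while the minor changes (217, 309
down, 304 up) stay under 35%: with 2000 frames per condition every
designed category is ≥ 3 standard errors from the 50% flag threshold, so
the differential recovers the designed classification across seeds.

## Problem sizes and numerics

Default analysis sizes — 12-point saturation curves, 2000-frame toy
trajectories, 20-replicate recovery studies — run in seconds on one CPU
and give comfortable statistical margins for every check performed; they
are the package's validation scale, not a physical claim. Occupancy
normalization holds to 1e-12 by construction (weights divided by their
sum). The noiseless generate-then-refit round trip recovers binding
constants to better than 1e-4 relative; at 5% proportional noise the
median Kd error across 20 seeded replicates stays under 15%.

## Known limitations

* Two sites only: the third, lower-affinity steroid interaction site is
  outside the default model.
* Rapid-equilibrium only; no kinetic binding schemes, no NADPH coupling.
* Free ligand concentration is identified with total (ligand-excess
  regime).
* The effector-mode classifier is threshold-based on point estimates; it
  does not propagate fit uncertainty into the verdict.
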