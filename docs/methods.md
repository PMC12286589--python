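# Methods

## Problem and model overview

`marrowdose` estimates the absorbed dose to the perivascular haematopoietic
stem-cell (HSC) layer of red bone marrow — the 10 µm shell around the
sinusoidal capillary endothelium — after inhalation of alpha emitters, beta
emitters or radioactive noble gases. The pipeline has four coupled stages:
an idealised trabecular-bone/marrow geometry, a simplified Monte Carlo
energy-deposition engine, a first-order biokinetic compartment solver, and a
dose-assembly step that also produces ratio comparisons against SAF-style
(specific-absorbed-fraction) reference estimates.

## Geometry

The cervical-vertebra spongiosa is idealised as a periodic tiling of cubic
cells. Each cell has a marrow cavity of inner dimension 600 µm inside an
outer cell dimension of 630 µm, i.e. 15 µm bone half-walls forming a 30 µm
trabecular plate between neighbouring cavities. Each cavity contains a
square grid of parallel circular cylinders (sinusoids) of radius 20 µm,
axes along z, spanning the cavity; with the default 5×5 grid the axis
spacing is 120 µm. A 3×3 block of cells (225 vessels) is modeled
explicitly; the full site is taken to be 1600 cells / 40 000 vessels, and
the ratio 40 000/225 is carried on the model as `vessel_scale`.

Region definitions, with *r* the distance to the nearest vessel axis:
`BLOOD` (*r* < 20 µm), `PERIVASCULAR_HSC` (20 ≤ *r* < 30 µm),
`RED_BONE_MARROW` (rest of the cavity), `TRABECULAR_SURFACE` (bone within
10 µm Euclidean depth of a bone–marrow interface, including the rounded
edge/corner pieces of that offset surface) and `TRABECULAR_VOLUME` (deeper
bone). Densities: 1.765 g/cm³ bone, 1.0 g/cm³ everything else.

Design choices that were genuinely open:

* **Vessel arrangement.** Only counts and radii are constrained by the
  source material; the square grid was chosen because it makes
  25 × 1600 = 40 000 exact, keeps the 10 µm shells non-overlapping
  (60 µm clearance at 120 µm spacing), and admits closed-form region
  volumes. The modeled block is taken 3×3 rather than 9×1; nothing
  downstream is sensitive to this because the cells are identical and
  periodic.
* **"Inner 30 µm" of bone.** A 30 µm plate with two 10 µm surface layers
  leaves only 10 µm of interior, so a literal reading ("surface = outer
  10 µm, volume = inner 30 µm") is geometrically impossible. The package
  defines `TRABECULAR_VOLUME` as the complement of the surface layer within
  the bone.
* **Bone mass.** The lattice's bone mass (~0.1 g for 1600 cells) is far
  below the tabulated 12.2 g of cervical trabecular bone; the cell
  dimensions are used as stated and no attempt is made to force mass
  agreement. Doses are per-region energy over per-region mass, so this
  affects only absolute whole-site bookkeeping, which is not a supported
  output.
* **Ties.** Boundary ties resolve to the inner region (half-open shells),
  a measure-zero choice made for determinism.
* **Marrow as a source.** `RED_BONE_MARROW` *as a source* includes the HSC
  shell by default (whole-marrow convention, `marrow_includes_shell=True`),
  since the shell is marrow tissue; classification labels are unaffected.

Ray tracing collects exact intersections with every boundary surface
(planes, vessel/shell cylinders, and the quarter-cylinder/octant-sphere
pieces of the bone-surface offset) and classifies interval midpoints, so
segment lengths are exact to float precision and labels agree with a fine
stepping oracle everywhere except within one step of a boundary.

## Transport

The engine replaces a general-purpose code with the minimum physics needed
for geometry-driven conclusions:

* **Alphas**: straight tracks under the continuous-slowing-down
  approximation. Energy deposited in a segment of length *s* and density ρ
  is E(R) − E(R − ρs), with R the residual mass range. Lateral straggling
  over tens of µm is negligible against the model's idealisations.
* **Electrons**: condensed history. Each step covers a fixed fraction
  (default 5%) of the residual CSDA range, deposits energy along a straight
  sub-path (crossing region boundaries exactly), then deflects by a
  Highland-formula Gaussian polar angle (X₀ = 36.08 g/cm²).
* **Cutoff**: particles below 5 keV (configurable) deposit locally.
  Emissions sampled below the cutoff deposit at the emission point.
* **Termination**: particles leaving the 3×3 block are scored as escaped;
  energy is conserved per history to float precision (asserted at 10⁻⁹
  relative per run).
* **Stopping powers**: a packaged *synthetic* table for unit-density tissue
  (`data/stopping_power_tissue_synthetic.csv`), generated by
  `make_tissue_stopping_table` from the Berger–Seltzer electron
  collision-stopping formula and an effective-charge-scaled proton Bethe
  formula for alphas (I = 75 eV, Z/A = 0.5551; the Bethe logarithm is
  floored at very low energy, affecting ≲2 µm of range). Spot checks:
  electron 100 keV → 4.12 MeV cm²/g, CSDA range 143 µm; alpha 5 MeV →
  885 MeV cm²/g, range ≈43 µm. Bone uses density scaling of the tissue
  mass stopping power; composition corrections are second order here.
* **Not modeled**: bremsstrahlung (small radiative yield for ≤2 MeV
  electrons in soft tissue, and no photon targets exist in the model),
  delta rays, progeny in-growth during transport.

Runs stop when the relative standard error of the target-region (HSC shell)
tally drops below `target_rel_se` (default 0.05) after `min_histories`, or
at `max_histories` with `converged=False`. For bone-source alphas the tally
mean is near zero and the SE never converges — mirroring the practical need
for looser stopping criteria (0.5, even 0.9) in the reference workflow —
so history caps bound those runs.

Dose conversion is D = Ē·(1.602 176 634×10⁻¹³ J/MeV)/(m kg) per source
particle. The 40 000/225 vessel scale converts modeled-subsystem *totals*
to whole-site totals; for dose itself (an intensive quantity over identical
repeating units) the factor cancels, so both scaled and unscaled values are
reported and the unscaled one is the physically meaningful per-unit dose.

## Nuclide data and beta spectra

Eleven nuclides are packaged (Cs-137, I-131, Sr-90; Ra-223, Pu-239, U-238,
Th-232, Rn-222; Xe-133, Xe-135, Kr-85) as JSON files flagged *synthetic
approximations*: half-lives, alpha lines, beta branches and major
conversion-electron lines at commonly quoted energies and yields, parent
only (no Y-90, radon-progeny or actinide chains by default). Because the
supported outputs are ratios and mechanisms rather than absolute doses, the
exactness of these fixtures is not load-bearing; users can supply evaluated
data in the same schema. Noble gases are transported as electron emitters.

Beta energies follow the allowed-transition shape
N(E) ∝ p·W·(Q − E)²·F(Z, W) with the non-relativistic Fermi function
F = 2πη/(1 − e^(−2πη)), η = αZW/(pc), sampled by rejection under a gridded
envelope. Spectrum means are validated against quadrature of the same
density; no forbidden-transition shape factors are included.

## Biokinetics

Transfer networks are first-order: dN/dt = (M − λI)N with M in day⁻¹,
column-conserving (diagonal = −Σ outflows; explicit excreta compartments
act as sinks *inside* the state, so total decays obey
N₀(1 − e^(−λT)) exactly). A 1 Bq intake is N₀ = 1/λₛ atoms in the intake
compartment. Decays per compartment are λ∫₀ᵀ N dt, evaluated through the
augmented matrix exponential
exp([[A, I], [0, 0]]T) = [[e^(AT), ∫e^(As)ds], [0, I]]; a stiff LSODA
quadrature is the fallback for non-finite exponentials. An independent
eigendecomposition route (`synthetic.analytic_decays`) and an adaptive-ODE
oracle in the tests pin the solver to <10⁻⁶ relative error on random
fixtures.

Horizons: 15 800 000 min for long-lived nuclides, 10 000 min for
short-lived, with "long-lived" defined as half-life ≥ 30 days. (The two
stated horizon labels — 15.8 M minutes and "10 years" — are mutually
inconsistent by ~3×; the minute count is authoritative here.) The 30-day
threshold puts I-131 (8 d) on the short horizon; a per-nuclide override
exists because the original assignment for borderline nuclides is unstated.

Noble gases reuse the radon-like system with the lung→blood rate scaled by
relative blood solubility (×½ Xe, ×¼ Kr) and the gas's own decay constant.
The packaged radon-like system is schematic (synthetic rates, plausible
ordering only); real analyses should supply reference transfer
coefficients, which are licensed external data and not redistributed here.
The cervical RBM-blood pool is apportioned 0.18 % of whole-body-blood
decays (6.1 g/3410 g, blood-volume proportionality).

## Dose assembly and comparisons

Total dose is the bilinear sum Σₛ (Gy/source)ₛ × decaysₛ over source
regions, with missing coefficients raising named errors. The inhalation
scenario (1 Bq/m³, 1 L inhaled) fixes the intake at 10⁻³ Bq; the 1 h
exposure duration is provenance metadata only, since concentration × volume
already determines the intake. SAF-style reference doses use
Σₛ decaysₛ·E(J)·SAF(s→target), with the classical alpha convention
(absorbed fraction 0.5 from trabecular surface, 0.05 from volume, over
target mass) as a helper. Published summary doses for the eleven nuclides
are packaged solely to reproduce the reference/model *ratio* columns
(e.g. Ra-223: 3.92×10⁻⁹/1.88×10⁻¹⁰ = 20.9); two printed beta-row ratios
(I-131, Sr-90 vs the older reference) are inconsistent with their own dose
pairs and are not asserted. Report rounding is half-away-from-zero: ratios
to 1 decimal, doses to 3 significant figures.

## Synthetic data

The generators emulate exactly the statistical structure the pipeline
assumes and nothing more: Metzler-structured random transfer matrices with
an intake compartment, an excreta sink and an eigendecomposition solution
record; schema-valid toy nuclides; toy SAF tables; and reduced geometry
specs (same cell dimensions, smaller vessel grids and blocks, all
invariants preserved). Fixtures are byte-reproducible under a seed and
hashed into a manifest. Passing tests on these fixtures demonstrates the
*solvers and samplers* are correct; they say nothing about the fidelity of
any particular reference coefficient set, which users must supply.

## Problem sizes and numerical choices

The test suite and acceptance script run reduced configurations chosen as
the smallest that still exhibit each mechanism: a one-cell/one-vessel
lattice (bone-to-shell separation 270 µm, far beyond any alpha range) for
the short-range test at ~10⁴ histories, a one-cell/4-vessel lattice for
source-comparison runs at ~1.2–1.5×10³ histories per source, electron runs
at a few hundred histories, and 100 random 5-compartment fixtures for the
solver checks. Boundary tolerances are 10⁻⁹ µm in tracing; the rejection
samplers draw in vectorised blocks; all randomness flows through
`numpy.random.Generator` seeded explicitly.

## Known limitations

Absolute Gy/source values are indicative only (synthetic decay and
stopping-power data; no bremsstrahlung; no progeny; idealised geometry with
a bone mass far below the tabulated site mass). Supported conclusions are
the relative, geometry-driven ones: which source regions can physically
irradiate the perivascular shell, and how reference-convention estimates
compare once decay counts are fixed. The lattice models one skeletal site;
marrow/blood proportions vary strongly across the skeleton, so whole-body
extrapolation is out of scope.
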