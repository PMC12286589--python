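# marrowdose

Absorbed dose to the **perivascular haematopoietic stem-cell (HSC) layer** of
red bone marrow from inhaled alpha/beta emitters and noble gases.

Classical skeletal dosimetry treats haematopoietic stem cells as uniformly
spread through the marrow cavities. Imaging studies instead place most HSCs
within ~10 µm of the sinusoidal capillary endothelium. For short-range alpha
particles this matters enormously: whether the target shell sits next to the
trabecular bone surfaces (the classical source of bone-seeking nuclides) or
next to the blood vessels changes the dose by orders of magnitude.

`marrowdose` is a small research pipeline for exploring that question. It is
aimed at internal-dosimetry and radiation-protection researchers who want a
transparent, fully scriptable model rather than a production transport code.

## The model

* **Geometry** (`marrowdose.geometry`) — cervical-vertebra spongiosa idealised
  as a periodic lattice of cubic cells: a 600 µm marrow cavity inside 630 µm
  cells (15 µm bone half-walls), each cavity holding a square grid of parallel
  sinusoid cylinders of radius *r*ᵥ = 20 µm. Regions: `BLOOD` (*r* < 20 µm
  from a vessel axis), `PERIVASCULAR_HSC` (20 ≤ *r* < 30 µm, the target),
  `RED_BONE_MARROW`, `TRABECULAR_SURFACE` (bone within 10 µm of the marrow
  interface) and `TRABECULAR_VOLUME`. A 3×3 block of 25-vessel cells (225
  vessels) stands in for the full 1600-cell, 40 000-vessel site; the ratio
  40 000/225 is carried as `vessel_scale`.
* **Transport** (`marrowdose.transport`) — simplified Monte Carlo:
  straight-track CSDA alphas and condensed-history electrons (Highland
  small-angle scattering, 5 keV cutoff), with exact ray tracing through the
  lattice and per-region energy tallies with relative standard errors.
  Absorbed dose per source particle is *D* = Ē·(1.602×10⁻¹³ J/MeV)/*m*.
* **Biokinetics** (`marrowdose.biokinetics`) — first-order compartment models
  d**N**/dt = (**M** − λ**I**)**N**; decays per compartment λ∫**N** dt via the
  augmented matrix exponential. Noble-gas systems derive from a radon-like
  system by scaling the lung→blood transfer (×½ Xe, ×¼ Kr). The cervical
  RBM-blood pool receives 0.18 % of whole-body-blood decays (6.1 g/3410 g).
* **Dose assembly** (`marrowdose.dose`) — *D* = Σₛ (Gy/source)ₛ × (decays)ₛ
  over source regions, with SAF-style reference estimates
  (*D* = Σₛ decaysₛ·E·SAF(s→target)) and reference/model ratio columns.

Everything the pipeline consumes — mass tables, vessel morphometry, nuclide
decay files, compartment matrices, stopping powers — is either packaged as a
small text table or generated by `marrowdose.synthetic`. The packaged decay
and stopping-power data are clearly flagged synthetic approximations; see
`docs/methods.md` for what that does and does not imply.

## Worked example

Dose to the HSC shell per emitted alpha for a Ra-223 source in blood versus
on the trabecular surface (reduced one-cell lattice, 2×2 vessels):

```python
import numpy as np
from marrowdose import (RegionLabel, build_lattice, TransportConfig,
                        transport_alpha, tally_to_dose, load_packaged_nuclide)
from marrowdose.synthetic import gen_reduced_geometry

model = build_lattice(gen_reduced_geometry(1/3))
ra = load_packaged_nuclide("ra223")
cfg = TransportConfig(max_histories=2000, min_histories=500, seed=0)
for src in (RegionLabel.BLOOD, RegionLabel.TRABECULAR_SURFACE):
    t = transport_alpha(model, src, ra, cfg, np.random.default_rng(0))
    d = tally_to_dose(t, RegionLabel.PERIVASCULAR_HSC,
                      model.region_mass_g(RegionLabel.PERIVASCULAR_HSC))
    print(f"{src.name:<20} n={t.n_histories:<6} rel_se={t.rel_se():.3f}  "
          f"dose={d:.3e} Gy/source")
```

```
BLOOD                n=500    rel_se=0.024  dose=5.782e-05 Gy/source
TRABECULAR_SURFACE   n=2000   rel_se=0.365  dose=3.518e-07 Gy/source
```

The blood source delivers ~160× more dose per particle to the shell than the
bone-surface source: the ~44 µm alpha range rarely bridges the ≥30 µm
marrow gap between bone and the nearest vessel shell, while particles born in
a vessel are already adjacent to the target. (The bone-source run stops at
its history cap with a large standard error — few histories score at all —
which is itself the physical point.)

A CLI mirrors the stages:

```bash
marrowdose tables                 # printed-table fraction arithmetic
marrowdose geometry --scale 0.2   # region volume/mass report
marrowdose transport --nuclide rn222 --source BLOOD --histories 2000 --seed 1
marrowdose compare                # reference/model ratio columns
marrowdose fixtures --outdir fx --seed 0
```

## Limitations

The transport engine is not a production code (PHITS, EGSnrc, Geant4 and
kin do far more): no bremsstrahlung, delta rays or
photon transport, and the packaged stopping powers and decay data are
synthetic approximations. Absolute Gy/source values are therefore indicative
only; the geometry-driven *comparisons* between source regions are the
supported output. See `docs/methods.md` for the full discussion.
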