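# flexsome

Ensemble analysis of flexible multi-enzyme assemblies: conformer pools,
small-angle X-ray scattering (SAXS), genetic-algorithm ensemble selection,
tomographic radial density profiles, and sequence charge patterning.

## The scientific problem

Large bacterial RNA-decay machines such as the RNA degradosome are built
from a rigid catalytic core (a ribonuclease tetramer) carrying long
intrinsically disordered scaffold tails that recruit partner enzymes and
tether the assembly to the inner membrane.  No single structure describes
such an object — in solution it is an *ensemble* of conformations.  The
standard way to characterize it combines:

1. **Conformer-pool generation** — rigid crystal-structure domains joined
   by sampled random-coil linkers, partner enzymes docked as rigid ligands,
   four protomers combined onto a shared tetramer core, clash-filtered.
2. **SAXS analysis** — Debye-formula curves for every pool member
   (`I(q) = Σᵢⱼ wᵢwⱼ sinc(q·rᵢⱼ)`), Guinier fits
   (`ln I ≈ ln I₀ − q²Rg²/3`), pair-distance distributions P(r),
   dimensionless Kratky transforms `(qRg)²·I(q)/I(0)`, and
   concentration-series merging.
3. **Ensemble optimization** — a genetic algorithm selects sub-ensembles of
   pool models whose average curve fits the measured curve (reduced χ²
   after an analytic scale factor), and entropy-based metrics quantify
   flexibility: `Rflex = 100·H(Rg histogram)/H_max` and
   `Rσ = sd(Rg, ensemble)/sd(Rg, pool)`.
4. **Radial density profiles (1D-RDP)** — for the membrane-bound assembly,
   tomographic subvolumes of protein-coated vesicles are symmetrized and
   reduced to ρ(r) from the vesicle centre outwards; the membrane peak,
   the membrane–protein gap and the radial extension of the protein shell
   are read off the profile.
5. **Charge analysis** — isoelectric points (Henderson–Hasselbalch with the
   Bjellqvist pKa set), charged-residue fractions (FCR, NCPR) and the
   Das–Pappu κ patterning parameter (δ/δ_max over 5–6-residue blobs)
   localize the electrostatics that drive membrane association.

A synthetic-data module generates every input with planted ground truth
(domain templates, mixture curves with counting noise, liposome volumes,
charge-patterned sequences), so the full pipeline is testable end-to-end
without any external data.

## Worked example

`examples/03_ensemble_selection.py` plants a 50/50 compact/extended mixture
in a size-graded pool of 150 globules and lets the genetic algorithm
recover it:

```
best chi^2          : 0.947  (true mixture would give ~1)
recovered weights   : compact 0.50 / extended 0.50  (planted 0.50/0.50)
Rflex(pool)         : 97.59 %
Rflex(ensembles)    : 47.17 %
Rsigma              : 1.473  (1 = ensembles as broad as the pool)
```

The fit reaches the noise floor (χ² ≈ 1), the planted 50/50 weights are
recovered exactly, and the selected ensembles occupy a much narrower slice
of size space than the random pool (Rflex drops from ~98% to ~47%) — the
signature of a target generated by a *specific* two-state mixture rather
than the whole pool.

`examples/04_radial_profile.py` does the same for the tomography stage: a
synthetic vesicle built with membrane radius 100 Å, gap 30 Å and protein
extension 140 Å at unit signal-to-noise is symmetrized and profiled:

```
membrane peak radius :   99.4 A  (truth 100)
membrane-protein gap :   24.6 A  (truth 30)
protein extension    :  147.3 A  (truth 140)
```

All three metrics land within one voxel (8.8 Å) of the planted geometry.

The other examples cover pool generation (`01`), curve-level SAXS analysis
(`02`) and the charge report for the bundled scaffold sequences (`05`).
Each is a short script that builds its own input, runs one capability and
prints what the numbers mean.

There is also a thin command-line interface (`flexsome --help`) with
subcommands `simulate`, `generate-pool`, `compute-curves`, `guinier`,
`pofr`, `kratky`, `merge`, `fit-ensemble`, `rdp` and `charge`; every run
writes a manifest (seeds, config, input checksums) sufficient to reproduce
it.

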