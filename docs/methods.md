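# Methods

`flexsome` implements the computational arm of a hybrid structural-biology
workflow for large assemblies built from rigid enzymatic cores connected by
intrinsically disordered scaffolds — the situation exemplified by the
bacterial RNA degradosome, where a tetrameric ribonuclease core carries a
long disordered C-terminal tail that recruits a helicase, enolase and a
second exonuclease, and tethers the whole assembly to the inner membrane.
This note records the models, the defaults and the reasoning behind every
numerically consequential choice.

## Coarse-grained conformer model

A protomer is a chain of rigid bead bodies (one bead per residue at the
Cα position, unit scattering weight) joined by random-coil linkers.  The
coil model uses fixed 3.8 Å virtual bonds, bond angles sampled uniformly in
[75°, 155°], dihedrals uniform in [−180°, 180°), and a hard excluded-volume
radius of 4.0 Å against all non-bonded beads (linker and context).  These
are standard coarse virtual-bond statistics for polypeptides; nothing in
the downstream analysis depends on the torsion library beyond its producing
realistic coil dimensions.  Dead ends restart the linker (500 restarts
before a `LinkerSamplingError` carrying the attempt count).  The bonded
neighbourhood of a linker anchor (context beads within 4.0 Å of the anchor
point) is exempt from the excluded-volume check, because those contacts are
covalent context rather than clashes.

Partner enzymes are attached as rigid *ligands* with a fixed dock transform
expressed relative to their attachment residue; their orientation is not
re-sampled per model.  Non-core domains that continue the chain are
oriented anchor-to-centre along the chain direction with a uniformly random
spin, so a domain extends away from the chain it continues instead of
sweeping back through it.

**Clash score.** A bead-overlap count per 1000 beads with a 3.0 Å
threshold stands in for an all-atom clash score; consecutive beads of the
same chain are bonded and excluded.  The default pool cutoff of 60 mirrors
standard practice for coarse model filtering.  Tetramer pools are built by
drawing four protomers with replacement, docking each core with one of four
rigid transforms (an idealized D2 set by default — identity plus the three
180° rotations — with the protomer core displaced off-axis), and rejecting
combinations whose *inter-protomer* clash score exceeds the cutoff.

**Pool sizes.** Tests and examples use desk-scale pools (60–1000 models).
The command line exposes the production-scale preset (4 × 20,000 protomers
combined into 10⁶ tetramers) but nothing in the algorithms depends on pool
size beyond sampling density.

## Scattering

Theoretical curves use the Debye sum `I(q) = Σᵢⱼ wᵢwⱼ sinc(q·rᵢⱼ)`, so
`I(0) = (Σw)²` identically.  The accelerated path histograms pair distances
at ≤ 0.5 Å and evaluates each occupied bin at its *weighted mean* distance
(exact for isolated distances, second-order accurate otherwise); agreement
with the exact double sum is well under 0.5% for q ≤ 0.3 Å⁻¹.  No atomic
form factors or hydration shell are modelled: pool curves and synthetic
"experimental" curves share one forward model, which is what ensemble
selection requires, and absolute calibration is out of scope.

**Guinier fit.** Weighted linear regression of ln I on q² over the largest
low-q window with q·Rg ≤ 1.3, grown from the lowest q and iterated to a
stable window (≤ 20 rounds).  When noise makes the smallest 5-point window
non-decaying, the initial window is widened until the slope is negative;
a curve with no decaying window raises an error.  Note the classical
caveat: for a compact globule the qRg ≤ 1.3 window carries an inherent
upward bias of ≈ 1.8% in Rg — the 2% agreement checked in the tests is the
sum of this bias and sampling scatter, which is why closed-form fixtures
use ≥ 5000 beads.

**P(r).**  From a model: weighted pair-distance histogram, unit area.
From a curve: regularized indirect transform minimizing
`Σ[(I_model−I)/σ]² + α‖p″‖²` subject to `p ≥ 0`, `p(0)=p(dmax)=0`, with
`I_model(q) = 4π∫p(r) sinc(qr) dr + c`.  The non-negative constant `c`
absorbs the self-scattering floor `Σw²` of discrete bead models, which pair
distances do not describe and which dominates the high-q tail of
coarse-grained curves; it fits to ≈ 0 for continuum-like input.  The
smoothing weight α (default 1.0) acts on a normalized scale: the data and
curvature blocks are balanced by their matrix norms before α is applied.
No automatic L-curve search is performed.  Round-trip accuracy is assessed
against the model histogram at a comparison bin of 3.8 Å (the bead
spacing): finer bins resolve the discrete-distance structure of bead
models, which no band-limited curve can carry.

**Merging.**  Curves of a concentration series are least-squares scaled
onto the lowest-concentration reference over the shared q-window.  Below a
crossover (the first 20% of the shared window, where inter-particle
interference distorts concentrated samples) the merged curve is the
reference alone; above it all scaled curves are combined by
inverse-variance weighting, which propagates σ and gains averaging
precision.

## Ensemble selection

The selector is a genetic algorithm over chromosomes of L = 20 pool
indices with repetition (multiplicity encodes weight).  Fitness is the
reduced χ² after the analytic scale μ; each generation applies elitism
(2 copies), rank selection of parents from the top half, one-point
crossover (rate 0.5) and per-slot mutation to a uniform random index
(default rate 0.1).  The run is repeated independently (default 10×); the
best-of-repeats is reported as "the best fitting ensemble" and the pooled
per-repeat winners feed the size-distribution comparisons.  Ties in
fitness resolve by stable sort order, and the winning chromosome is
reported sorted, so results are bit-reproducible from the seed.  In the
planted-recovery tests a lower mutation rate (0.03) is used: with near-
duplicate pool members the end game is a hill climb, and fewer simultaneous
mutations per child speed convergence without changing the operators.

Recovery checks compare the fit against the attainable optimum: the
reduced χ² of a perfect model fluctuates with standard deviation
√(2/K) ≈ 0.14 at K = 101 grid points, so a fixed bound of 1.05 is met *or*
the fit must be at least as good as the planted truth's own χ² for that
noise realization.  Mixture weights are scored after classifying selected
members by Rg proximity to the planted components, because pools contain
near-duplicate curves and per-index identifiability is not a property of
the method.

**Flexibility metrics.**  Rflex is the Shannon entropy of the Rg histogram
relative to uniform occupancy, as a percentage (0% = degenerate,
100% = every bin equally occupied; 100 bins over the pool range by
default).  Uniform occupancy is detected exactly from the integer counts so
the endpoint is exact.  Rσ is the ratio of ensemble to pool Rg standard
deviations.

## Radial density profiles

Volumes are cubic-voxel scalar grids (z, y, x).  Symmetrization applies
the 60 icosahedral rotations about the volume centre (trilinear
interpolation) followed by fine rotational averaging about chosen axes
(10° steps).  Trilinear resampling blurs features narrower than ~3 voxels;
equivalence and invariance tests therefore use shells at least that wide,
and mass conservation is asserted inside the inscribed sphere (corners
rotate out of the box).

The 1-D profile samples each sphere of radius r = 0, voxel, 2·voxel, …
(up to half the box) at max(100, 4πr²/voxel²) Fibonacci points with
trilinear interpolation.  The automatic centre is the density-weighted
centroid of the thresholded high-density shell.

**Profile metrics.**  Baseline = median of the outer 20% of the r-range
(solvent; the synthetic-volume default box of 80 voxels at 8.8 Å leaves a
clean solvent margin beyond the protein shell).  The membrane peak is the
first local maximum exceeding baseline + ½·(global max − baseline), refined
to sub-voxel precision by parabolic interpolation.  Beyond the peak-side
valley, the protein shell is the contiguous region above baseline +
frac·(protein peak − baseline) with frac = 0.1 (configurable); both edges
are refined by interpolating the local half-rise crossing, which localizes
a sharp shell edge to a fraction of the grid step and keeps the recovered
(membrane radius, gap, extension) within one voxel of a planted geometry.
The **gap** is measured from the membrane *peak* to the shell's inner edge
— the convention under which the generator's (radius, gap, extent)
parameters are recovered identically; the **extension** is the shell
width.  The shell is bimodal when it carries ≥ 2 local maxima separated by
a ≥ 10% dip.  Profiles from different vesicles are aligned on their
membrane peaks before pointwise mean ± sd (vesicle radii differ, peak
alignment is the only registration the profiles support).

## Charge analysis

Net charge follows the Henderson–Hasselbalch model with the Bjellqvist pKa
set (the set behind the ProtParam tool), including residue-specific
N-terminal pKas; the isoelectric point is found by bisection on pH ∈
[0, 14] to |charge| < 10⁻⁴.  The bisection is deliberately unclamped:
strongly basic peptides have pI above 12, outside the search range of some
common implementations.

Charge fractions and κ follow the polyampholyte-patterning convention:
K/R positive, D/E negative, histidine excluded (it is ionizable for pI).
δ is the variance of the blob charge asymmetry σ = (f⁺−f⁻)²/(f⁺+f⁻) over
sliding windows of 5 and 6 residues (zero-charge windows contribute σ = 0);
κ = δ/δ_max.  δ_max is exact by enumeration of multiset permutations for
compositions with ≤ 20,000 arrangements — at short lengths window edge
effects can beat the segregated arrangement — and otherwise uses the
deterministic block construction (both orders of the charge blocks with
all placements of the neutral residues among the three gaps).  Region
reports classify sequences on the (FCR, |NCPR|) diagram of states
(weak < 0.25 ≤ boundary ≤ 0.35 < strong polyampholyte; |NCPR| > 0.35
polyelectrolyte).

**Reference sequences.**  The two scaffold-protein sequences bundled under
`flexsome/data/` are offline reconstructions of the corresponding public
database entries, not verbatim downloads; the FASTA header of each entry
records which published segment values the reconstruction reproduces
(helicase: all three segment pIs exactly; endoribonuclease: full-protein
pI, acidic-segment pI, FCR and the basic-segment κ) and which it misses
(two values, from residual errors in the low-complexity scaffold region —
the corresponding checks in the acceptance suite fail and are expected
to).  Conclusions drawn from these sequences inherit that caveat.

## Synthetic data

Every generator is a pure function of its parameters and seed.  The
liposome generator builds a membrane shell with Gaussian radial
cross-section (default radius 100 Å, FWHM 20 Å) and a protein shell
spanning the planted gap (30 Å) and extension (140 Å) — the geometry the
radial-profile stage is designed to measure — with optional partial
angular occupancy and white noise.  The planted-ensemble generator mixes
pool curves with stated weights and adds Gaussian noise with
σ(q) = noise·√(I(q)·I(0)) (counting-statistics shape, 1% at the forward
point by default), storing the ground truth beside the target.  Patterned
sequences realize an exact charge composition as segregated (the
δ-maximizing arrangement, κ = 1 by construction), alternating (minimal δ)
or shuffled arrangements.

What the generators do *not* emulate: real lipid scattering contrast,
detector effects, buffer mismatch, CTF and missing-wedge artefacts of
tomography, and conformer-curve families outside the package's own forward
model.  Passing the planted-recovery suites therefore demonstrates the
correctness and calibration of the algorithms, not instrument-level
realism.

## Problem sizes

Default test and acceptance runs use pools of 100–200 models with 101-point
q-grids, 80³-voxel volumes, and 10 GA repeats of 300–500 generations —
sizes chosen so the full suite exercises every stage end-to-end at desk
scale while remaining statistically meaningful (e.g. 10–20 seeds for
fraction-of-seeds checks, 100 replicates for χ² calibration).
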