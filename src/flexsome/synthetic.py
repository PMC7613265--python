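"""Synthetic inputs with planted ground truth for every pipeline stage.

The experimental inputs this pipeline was designed around (SEC-SAXS curves
of a tetrameric multi-enzyme assembly, tomographic subvolumes of
protein-coated liposomes) are not publicly deposited, so this module
generates stand-ins whose ground truth is known by construction: rigid
domain templates with blueprints, mixture scattering curves from a planted
ensemble with counting-statistics noise, spherical-shell liposome volumes
with a protein shell separated by a gap, and amino-acid sequences with
controlled charge fraction and patterning.  Every generator is a pure
function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .charge import ProteinSequence, delta_max, _charge_vector
from .conformers import (ChainBlueprint, ConformerModel, Pool, RigidDomain,
                         TetramerBlueprint)
from .radial import DensityVolume, ProfileMetrics
from .scattering import ScatteringCurve

__all__ = [
    "PlantedExperiment",
    "SyntheticLiposomeSpec",
    "make_domain_templates",
    "make_planted_experiment",
    "make_liposome_volume",
    "make_patterned_sequence",
    "d2_tetramer_blueprint",
]


@dataclass
class PlantedExperiment:
    """A noisy target curve with its generating mixture recorded."""

    pool: Pool
    true_indices: np.ndarray
    true_weights: np.ndarray
    target: ScatteringCurve
    noise_scale: float
    seed: int


@dataclass
class SyntheticLiposomeSpec:
    """Geometry of a synthetic protein-coated vesicle volume.

    Defaults mirror the measured geometry of the study system: a membrane
    shell at 100 A radius, a ~30 A low-density gap, and a protein shell
    extending 140 A beyond the gap, on an 8.8 A/voxel grid.
    """

    box: int = 80  # leaves a solvent margin beyond the protein shell for baselining
    voxel: float = 8.8
    membrane_radius: float = 100.0
    membrane_thickness: float = 20.0
    gap: float = 30.0
    protein_extent: float = 140.0
    amplitudes: tuple[float, float] = (1.0, 0.45)
    occupancy: float = 1.0        # angular fraction of the protein shell filled
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.membrane_radius + self.gap + self.protein_extent >= self.box * self.voxel / 2:
            raise ValueError("geometry exceeds the box half-width")


def sphere_bead_cloud(radius: float, n_beads: int, rng,
                      min_spacing: float = 3.8) -> np.ndarray:
    """Quasi-uniform bead cloud filling a sphere without steric overlap.

    Beads sit on a jittered cubic lattice whose spacing is chosen from the
    target count (never below ``min_spacing``, the virtual bond length, so
    the cloud is clash-free at the 3.0 A overlap threshold).  The returned
    count is the number of lattice sites inside the sphere, close to but
    not exactly ``n_beads``.
    """
    vol = 4.0 / 3.0 * np.pi * radius ** 3
    a = max(min_spacing, (vol / n_beads) ** (1.0 / 3.0))
    jitter = max(0.0, (a - 3.1) / (2.0 * np.sqrt(3.0)))
    half = int(np.ceil(radius / a))
    ax = np.arange(-half, half + 1) * a
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= radius]
    pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
    return pts - pts.mean(axis=0)


def d2_tetramer_blueprint(spacing: float = 40.0) -> TetramerBlueprint:
    """Idealized D2 core: identity plus the three 180-degree rotations,
    with protomer cores displaced off-axis so the four copies do not overlap."""
    t0 = np.array([spacing, spacing, 0.0])
    rots = [np.eye(3),
            np.diag([1.0, -1.0, -1.0]),
            np.diag([-1.0, 1.0, -1.0]),
            np.diag([-1.0, -1.0, 1.0])]
    return TetramerBlueprint(core_transforms=[(r, r @ t0 - t0 * 0) for r in rots])


def make_domain_templates(kind: str, *, radius: float = 15.0,
                          n_beads: int = 120, linker_length: int = 40,
                          rng=None):
    """Generate rigid-domain templates plus a matching chain blueprint.

    ``sphere``: one spherical domain, no linkers.  ``dumbbell``: two spheres
    joined by one linker.  ``core_tetramer``: a D2-symmetric core domain
    followed by an alternating series of linkers and satellite domains,
    whose total linker length (~320 residues split by the microdomains)
    matches the scale of the disordered scaffold half of the study protein.
    """
    rng = np.random.default_rng(rng)

    def _dom(name, rad, nb):
        beads = sphere_bead_cloud(rad, nb, rng)
        # chain anchors sit on opposite surface beads so linkers grow outward
        return RigidDomain(id=name, beads=beads,
                           anchor_in=int(np.argmin(beads[:, 0])),
                           anchor_out=int(np.argmax(beads[:, 0])))

    if kind == "sphere":
        dom = _dom("sphere", radius, n_beads)
        bp = ChainBlueprint(segments=[("rigid", "sphere")], core_id="sphere")
        return {"sphere": dom}, bp
    if kind == "dumbbell":
        a = _dom("lobe_a", radius, n_beads)
        b = _dom("lobe_b", radius, n_beads)
        bp = ChainBlueprint(segments=[("rigid", "lobe_a"),
                                      ("linker", linker_length),
                                      ("rigid", "lobe_b")], core_id="lobe_a")
        return {"lobe_a": a, "lobe_b": b}, bp
    if kind == "core_tetramer":
        core = _dom("core", radius * 1.6, n_beads * 2)
        sat1 = _dom("helicase", radius, n_beads)
        sat2 = _dom("enolase", radius, n_beads)
        sat3 = _dom("cap", radius * 0.7, n_beads // 2)
        # ~320 disordered residues split by the recruitment microdomains
        bp = ChainBlueprint(
            segments=[("rigid", "core"), ("linker", 110), ("rigid", "helicase"),
                      ("linker", 110), ("rigid", "enolase"), ("linker", 100),
                      ("rigid", "cap")],
            core_id="core")
        domains = {"core": core, "helicase": sat1, "enolase": sat2, "cap": sat3}
        return domains, bp
    raise ValueError(f"unknown template kind {kind!r}")


def make_planted_experiment(pool: Pool, true_weights, noise: float = 0.01,
                            rng=None, seed: int | None = None) -> PlantedExperiment:
    """Mix pool curves with ``true_weights`` and add counting-like noise.

    ``true_weights`` is a sparse mapping {pool index: weight} or a dense
    vector; weights must sum to 1.  The noise model is sigma(q) =
    noise * sqrt(I(q) * I(0)), i.e. proportional to sqrt(I) and equal to
    ``noise`` relative at the forward-scattering point.
    """
    if pool.curves is None:
        raise ValueError("pool curves not computed")
    rng = np.random.default_rng(rng if rng is not None else seed)
    if isinstance(true_weights, dict):
        idx = np.array(sorted(true_weights), dtype=int)
        w = np.array([true_weights[i] for i in idx], dtype=float)
    else:
        w = np.asarray(true_weights, dtype=float)
        idx = np.nonzero(w)[0]
        w = w[idx]
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("true weights must sum to 1")
    ideal = w @ pool.curves[idx]
    sigma = noise * np.sqrt(np.clip(ideal, 0, None) * ideal.max())
    sigma = np.clip(sigma, 1e-12 * ideal.max(), None)
    target = ScatteringCurve(q=pool.curve_q.copy(),
                             I=ideal + rng.normal(0.0, sigma),
                             sigma=sigma)
    return PlantedExperiment(pool=pool, true_indices=idx, true_weights=w,
                             target=target, noise_scale=noise,
                             seed=seed if seed is not None else -1)


def make_liposome_volume(spec: SyntheticLiposomeSpec):
    """Build a synthetic protein-coated vesicle volume.

    Density = membrane spherical shell with a Gaussian radial cross-section
    centred on ``membrane_radius`` + a protein shell from
    ``membrane_radius + gap`` to ``membrane_radius + gap + protein_extent``
    (optionally with angular occupancy < 1 to mimic discrete particles)
    + white Gaussian noise.  Returns (DensityVolume, ProfileMetrics ground
    truth).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.box
    ax = (np.arange(n) - (n - 1) / 2.0) * spec.voxel
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(x * x + y * y + z * z)
    sd = spec.membrane_thickness / 2.355  # FWHM -> Gaussian sigma
    mem = spec.amplitudes[0] * np.exp(-0.5 * ((r - spec.membrane_radius) / sd) ** 2)
    r_in = spec.membrane_radius + spec.gap
    r_out = r_in + spec.protein_extent
    prot = np.where((r >= r_in) & (r <= r_out), spec.amplitudes[1], 0.0)
    if spec.occupancy < 1.0:
        # carve pseudo-particles: keep voxels whose angular hash falls below
        # the occupancy fraction, using smooth random plane waves
        u = np.stack([x, y, z]) / np.maximum(r, 1e-9)
        phase = np.zeros_like(r)
        for _ in range(6):
            k = rng.standard_normal(3) * 3.0
            phase += np.cos(k[0] * u[0] + k[1] * u[1] + k[2] * u[2]
                            + rng.uniform(0, 2 * np.pi))
        thr = np.quantile(phase, 1.0 - spec.occupancy)
        prot = np.where(phase >= thr, prot, 0.0)
    grid = mem + prot + rng.normal(0.0, spec.noise_sd, size=r.shape)
    truth = ProfileMetrics(membrane_peak_r=spec.membrane_radius,
                           gap=spec.gap, extension=spec.protein_extent,
                           protein_region=(r_in, r_out), bimodal=False,
                           baseline=0.0)
    return DensityVolume(grid=grid, voxel=spec.voxel), truth


def make_patterned_sequence(n: int, fplus: float, fminus: float,
                            arrangement: str = "random", rng=None,
                            positive: str = "K", negative: str = "E",
                            neutral: str = "G") -> ProteinSequence:
    """A sequence with exact charge composition and chosen patterning.

    ``segregated`` realizes the delta-maximizing block arrangement (kappa =
    1 by construction), ``alternating`` spreads charges as evenly as
    possible (minimal delta for the composition), ``random`` shuffles.
    """
    n_plus = round(n * fplus)
    n_minus = round(n * fminus)
    if n_plus + n_minus > n:
        raise ValueError("fplus + fminus exceeds 1")
    if abs(n_plus - n * fplus) > 1e-9 or abs(n_minus - n * fminus) > 1e-9:
        raise ValueError("fractions must be integral counts at this length")
    n_zero = n - n_plus - n_minus
    if arrangement == "segregated":
        charges = np.concatenate([np.ones(n_plus, int), -np.ones(n_minus, int),
                                  np.zeros(n_zero, int)])
        if n_plus + n_minus >= 2:
            _best, pattern = delta_max(charges.astype(np.int8),
                                       return_pattern=True)
            charges = pattern
    elif arrangement == "alternating":
        charges = np.zeros(n, dtype=int)
        n_charged = n_plus + n_minus
        if n_charged:
            slots = np.floor(np.arange(n_charged) * n / n_charged).astype(int)
            signs, p, m = [], n_plus, n_minus
            take_plus = n_plus >= n_minus
            while p + m:
                if take_plus and p:
                    signs.append(1); p -= 1
                elif m:
                    signs.append(-1); m -= 1
                else:
                    signs.append(1); p -= 1
                take_plus = not take_plus
            charges[slots] = signs
    elif arrangement == "random":
        rng = np.random.default_rng(rng)
        charges = np.concatenate([np.ones(n_plus, int), -np.ones(n_minus, int),
                                  np.zeros(n_zero, int)])
        rng.shuffle(charges)
    else:
        raise ValueError(f"unknown arrangement {arrangement!r}")
    residues = "".join(positive if c > 0 else (negative if c < 0 else neutral)
                       for c in charges)
    return ProteinSequence(id=f"synthetic_{arrangement}", residues=residues)
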