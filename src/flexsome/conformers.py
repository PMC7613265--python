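"""Conformer-pool generation for rigid-domain / flexible-linker assemblies.

A protomer is described by a :class:`ChainBlueprint`: an ordered list of rigid
domains (crystal-structure-derived bead bodies) and random-coil linkers, with
optional partner enzymes attached as rigid ligands.  Pools of protomers are
generated by sampling linker conformations, filtered by a coarse clash score,
and four protomer pools are combined into a tetramer pool by rigid docking of
each protomer core onto a shared oligomerization core.

Coordinates are in Angstrom, one bead per residue at the C-alpha position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "RigidDomain",
    "ChainBlueprint",
    "ConformerModel",
    "Pool",
    "TetramerBlueprint",
    "LinkerSamplingError",
    "BlueprintError",
    "EmptyPoolError",
    "CombinationError",
    "sample_linker",
    "build_protomer",
    "clash_score",
    "filter_pool",
    "combine_tetramers",
    "model_rg",
    "model_dmax",
]

BOND_LENGTH = 3.8  # Angstrom, virtual C-alpha - C-alpha bond
EXCLUDED_VOLUME = 4.0  # Angstrom, minimum non-bonded bead separation
ANGLE_RANGE_DEG = (75.0, 155.0)  # sampled virtual bond angle


class LinkerSamplingError(RuntimeError):
    """Raised when a self-avoiding linker cannot be placed.

    Carries the number of restarts attempted in :attr:`attempts`.
    """

    def __init__(self, attempts: int):
        super().__init__(
            f"failed to place a self-avoiding linker after {attempts} restarts"
        )
        self.attempts = attempts


class BlueprintError(ValueError):
    """A blueprint references a missing domain or is otherwise malformed."""


class EmptyPoolError(RuntimeError):
    """All models were removed by a filter."""


class CombinationError(RuntimeError):
    """Tetramer combination rejected too many random draws."""


@dataclass
class RigidDomain:
    """A rigid bead body with optional chain-anchor bead indices."""

    id: str
    beads: np.ndarray  # (n, 3) C-alpha coordinates, Angstrom
    anchor_in: int | None = None
    anchor_out: int | None = None
    dock_transform: tuple[np.ndarray, np.ndarray] | None = None  # (R, t)

    def __post_init__(self):
        self.beads = np.asarray(self.beads, dtype=float)
        if self.beads.ndim != 2 or self.beads.shape[1] != 3 or len(self.beads) < 1:
            raise ValueError("beads must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(self.beads)):
            raise ValueError("bead coordinates must be finite")
        for a in (self.anchor_in, self.anchor_out):
            if a is not None and not (0 <= a < len(self.beads)):
                raise ValueError(f"anchor index {a} out of range")


@dataclass
class ChainBlueprint:
    """Ordered description of one protomer chain.

    ``segments`` is a list of ``("rigid", domain_id)`` or
    ``("linker", n_residues)`` entries; ``ligands`` is a list of
    ``(domain_id, attachment_segment, attachment_offset)`` triples that attach
    partner enzymes as rigid bodies; ``core_id`` names the rigid domain that
    is the oligomerization core.
    """

    segments: list[tuple[str, object]]
    ligands: list[tuple[str, int, int]] = field(default_factory=list)
    core_id: str | None = None

    def validate(self, domains: dict[str, RigidDomain]) -> None:
        if not self.segments:
            raise BlueprintError("blueprint has no segments")
        prev_kind = None
        for kind, arg in self.segments:
            if kind not in ("rigid", "linker"):
                raise BlueprintError(f"unknown segment kind {kind!r}")
            if kind == "linker":
                if prev_kind == "linker":
                    raise BlueprintError("two adjacent linker segments")
                if int(arg) < 1:
                    raise BlueprintError("linker length must be >= 1")
            else:
                if arg not in domains:
                    raise BlueprintError(f"blueprint references missing domain {arg!r}")
            prev_kind = kind
        for dom_id, seg, _off in self.ligands:
            if dom_id not in domains:
                raise BlueprintError(f"ligand references missing domain {dom_id!r}")
            if not (0 <= seg < len(self.segments)):
                raise BlueprintError(f"ligand attachment segment {seg} out of range")
        if self.core_id is not None and self.core_id not in domains:
            raise BlueprintError(f"core domain {self.core_id!r} missing")


@dataclass
class ConformerModel:
    """Bead-level model of one protomer or tetramer.

    ``chain`` holds a chain index per bead (1..4 for tetramers), ``segment``
    a segment identifier per bead, ``flexible`` marks linker beads.
    """

    beads: np.ndarray
    weights: np.ndarray | None = None
    chain: np.ndarray | None = None
    segment: np.ndarray | None = None
    flexible: np.ndarray | None = None

    def __post_init__(self):
        self.beads = np.asarray(self.beads, dtype=float).reshape(-1, 3)
        n = len(self.beads)
        if n < 1:
            raise ValueError("a model needs at least one bead")
        if self.weights is None:
            self.weights = np.ones(n)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != n:
            raise ValueError("len(weights) != len(beads)")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be > 0")
        if self.chain is None:
            self.chain = np.ones(n, dtype=int)
        self.chain = np.asarray(self.chain)
        if self.segment is None:
            self.segment = np.zeros(n, dtype=int)
        self.segment = np.asarray(self.segment)
        if self.flexible is None:
            self.flexible = np.zeros(n, dtype=bool)
        self.flexible = np.asarray(self.flexible, dtype=bool)

    def __len__(self) -> int:
        return len(self.beads)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ConformerModel":
        """Return a rigidly transformed copy (beads' = R beads + t)."""
        return replace(self, beads=self.beads @ np.asarray(rotation).T + translation)


@dataclass
class Pool:
    """A pool of conformer models with per-model size metrics.

    ``curves`` is filled by the scattering module (one intensity array per
    model on a shared q-grid).  ``provenance`` records source indices for
    combined tetramer models.
    """

    models: list[ConformerModel]
    rg: np.ndarray
    dmax: np.ndarray
    curves: np.ndarray | None = None   # (n_models, K) intensities
    curve_q: np.ndarray | None = None  # shared q-grid of `curves`
    seed: int | None = None
    provenance: np.ndarray | None = None

    def __post_init__(self):
        self.rg = np.asarray(self.rg, dtype=float)
        self.dmax = np.asarray(self.dmax, dtype=float)
        if not (len(self.models) == len(self.rg) == len(self.dmax)):
            raise ValueError("models/rg/dmax must be parallel")

    def __len__(self) -> int:
        return len(self.models)

    @classmethod
    def from_models(cls, models, seed=None, provenance=None) -> "Pool":
        rg = np.array([model_rg(m) for m in models])
        dmax = np.array([model_dmax(m) for m in models])
        return cls(models=list(models), rg=rg, dmax=dmax, seed=seed,
                   provenance=provenance)


@dataclass
class TetramerBlueprint:
    """Four rigid transforms mapping a protomer core onto the tetramer core."""

    core_transforms: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self):
        if len(self.core_transforms) != 4:
            raise ValueError("exactly 4 core transforms required")
        checked = []
        for rot, t in self.core_transforms:
            rot = np.asarray(rot, dtype=float)
            t = np.asarray(t, dtype=float).reshape(3)
            if rot.shape != (3, 3) or not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8):
                raise ValueError("rotation must be orthonormal 3x3")
            checked.append((rot, t))
        self.core_transforms = checked


# ---------------------------------------------------------------------------
# linker sampling
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction")
    return v / n


def _perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, ref))


def _next_bead(prev2: np.ndarray, prev1: np.ndarray, theta: float, phi: float) -> np.ndarray:
    """Place a bead at BOND_LENGTH from prev1 with bond angle theta at prev1
    (angle between prev1->prev2 and prev1->new) and dihedral phi about the
    prev2->prev1 axis."""
    b = _unit(prev1 - prev2)
    p = _perpendicular(b)
    q = np.cross(b, p)
    # direction at angle (pi - theta) from the incoming bond, rotated by phi
    d = (np.cos(np.pi - theta) * b
         + np.sin(np.pi - theta) * (np.cos(phi) * p + np.sin(phi) * q))
    return prev1 + BOND_LENGTH * d


def sample_linker(n_residues, start_point, start_direction, context_beads=None,
                  rng=None, excluded_volume=EXCLUDED_VOLUME,
                  max_attempts=500):
    """Sample a self-avoiding random-coil linker of ``n_residues`` beads.

    The chain grows from ``start_point`` with the first virtual bond along
    ``start_direction``, fixed 3.8 A bonds, bond angles uniform in
    [75 deg, 155 deg] and dihedrals uniform in [-180 deg, 180 deg).  Every
    bead must clear ``excluded_volume`` from every non-adjacent linker bead
    and from every bead of ``context_beads``.  Deterministic given ``rng``.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(rng)
    start_point = np.asarray(start_point, dtype=float)
    direction = _unit(np.asarray(start_direction, dtype=float))
    context = (np.asarray(context_beads, dtype=float).reshape(-1, 3)
               if context_beads is not None and len(context_beads) else None)
    ctx_tree = cKDTree(context) if context is not None else None
    lo, hi = np.deg2rad(ANGLE_RANGE_DEG)

    for attempt in range(max_attempts):
        beads = np.empty((n_residues, 3))
        ok = False
        for _try in range(30):
            if attempt == 0 and _try == 0:
                d0 = direction
            else:  # jittered restart direction
                d0 = rng.standard_normal(3)
                d0 = _unit(d0 + 2.0 * direction * np.linalg.norm(d0))
            cand0 = start_point + BOND_LENGTH * d0
            if ctx_tree is None or ctx_tree.query(cand0)[0] >= excluded_volume:
                beads[0] = cand0
                ok = True
                break
        if not ok:
            continue
        for i in range(1, n_residues):
            placed = False
            for _try in range(30):
                theta = rng.uniform(lo, hi)
                phi = rng.uniform(-np.pi, np.pi)
                prev2 = beads[i - 2] if i >= 2 else start_point
                cand = _next_bead(prev2, beads[i - 1], theta, phi)
                if i >= 2 and np.min(np.linalg.norm(beads[: i - 1] - cand, axis=1)) < excluded_volume:
                    continue
                if ctx_tree is not None and ctx_tree.query(cand)[0] < excluded_volume:
                    continue
                beads[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return beads
    raise LinkerSamplingError(max_attempts)


# ---------------------------------------------------------------------------
# protomer assembly
# ---------------------------------------------------------------------------

def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation (QR of a Gaussian matrix, det corrected)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _align_with_spin(v_from: np.ndarray, v_to: np.ndarray, rng) -> np.ndarray:
    """Rotation taking v_from to v_to, composed with a random spin about v_to."""
    a, b = _unit(v_from), _unit(v_to)
    cross = np.cross(a, b)
    s, c = np.linalg.norm(cross), float(np.dot(a, b))
    if s < 1e-12:
        base = np.eye(3) if c > 0 else _rotvec_matrix(_perpendicular(a), np.pi)
    else:
        base = _rotvec_matrix(cross / s, np.arctan2(s, c))
    return _rotvec_matrix(b, rng.uniform(0.0, 2.0 * np.pi)) @ base


def _rotvec_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = _unit(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def build_protomer(blueprint: ChainBlueprint, domains: dict[str, RigidDomain],
                   rng=None) -> ConformerModel:
    """Assemble one protomer model from a blueprint.

    Rigid domains keep their internal geometry; the domain named
    ``blueprint.core_id`` (or the first rigid segment) is placed at its
    native coordinates and anchors the chain.  Non-core domains receive a
    random orientation per model.  Ligand domains are placed rigidly by
    their ``dock_transform`` expressed relative to the attachment bead.
    """
    blueprint.validate(domains)
    rng = np.random.default_rng(rng)

    beads_parts, seg_parts, flex_parts = [], [], []
    seg_start_index: list[int] = []  # first global bead index of each segment
    n_total = 0
    cur_point = None  # chain growth point
    cur_dir = np.array([1.0, 0.0, 0.0])
    core_id = blueprint.core_id
    if core_id is None:
        for kind, arg in blueprint.segments:
            if kind == "rigid":
                core_id = arg
                break

    for seg_idx, (kind, arg) in enumerate(blueprint.segments):
        seg_start_index.append(n_total)
        if kind == "linker":
            n_res = int(arg)
            if cur_point is None:
                start, direction = np.zeros(3), cur_dir
            else:
                start, direction = cur_point, cur_dir
            if beads_parts:
                context = np.concatenate(beads_parts)
                # the anchor's bonded neighbourhood is exempt from the
                # excluded-volume check (it is covalent context)
                near = np.linalg.norm(context - start, axis=1) < EXCLUDED_VOLUME
                context = context[~near]
            else:
                context = None
            coil = sample_linker(n_res, start, direction, context, rng)
            beads_parts.append(coil)
            seg_parts.append(np.full(n_res, seg_idx))
            flex_parts.append(np.ones(n_res, dtype=bool))
            cur_point = coil[-1]
            cur_dir = _unit(coil[-1] - (coil[-2] if n_res > 1 else start))
        else:
            dom = domains[arg]
            placed = dom.beads.copy()
            if cur_point is None:
                pass  # first (core) domain stays at native coordinates
            else:
                a_in = dom.anchor_in if dom.anchor_in is not None else 0
                if arg != core_id:
                    # orient the body forward (anchor-to-centre along the
                    # chain direction) with a random spin, so the domain
                    # extends away from the chain it continues
                    centre = placed.mean(axis=0)
                    fwd = centre - placed[a_in]
                    rot = _align_with_spin(fwd, cur_dir, rng)
                    placed = (placed - placed[a_in]) @ rot.T + placed[a_in]
                target = cur_point + BOND_LENGTH * cur_dir
                placed += target - placed[a_in]
            beads_parts.append(placed)
            seg_parts.append(np.full(len(placed), seg_idx))
            flex_parts.append(np.zeros(len(placed), dtype=bool))
            a_out = dom.anchor_out if dom.anchor_out is not None else len(placed) - 1
            cur_point = placed[a_out]
            if len(placed) > 1:
                cur_dir = _unit(placed[a_out] - placed.mean(axis=0))
        n_total += len(beads_parts[-1])

    # rigid ligand attachment
    max_seg = len(blueprint.segments)
    for lig_idx, (dom_id, seg, off) in enumerate(blueprint.ligands):
        dom = domains[dom_id]
        anchor_global = seg_start_index[seg] + off
        all_beads = np.concatenate(beads_parts)
        if not (0 <= anchor_global < len(all_beads)):
            raise BlueprintError(f"ligand attachment offset {off} out of segment")
        anchor_pos = all_beads[anchor_global]
        if dom.dock_transform is not None:
            rot, t = dom.dock_transform
            placed = dom.beads @ np.asarray(rot).T + np.asarray(t) + anchor_pos
        else:
            placed = dom.beads - dom.beads.mean(axis=0) + anchor_pos \
                + np.array([0.0, 0.0, BOND_LENGTH + EXCLUDED_VOLUME])
        beads_parts.append(placed)
        seg_parts.append(np.full(len(placed), max_seg + lig_idx))
        flex_parts.append(np.zeros(len(placed), dtype=bool))

    beads = np.concatenate(beads_parts)
    return ConformerModel(
        beads=beads,
        chain=np.ones(len(beads), dtype=int),
        segment=np.concatenate(seg_parts),
        flexible=np.concatenate(flex_parts),
    )


# ---------------------------------------------------------------------------
# clash scoring and filtering
# ---------------------------------------------------------------------------

def clash_score(model: ConformerModel, overlap_threshold: float = 3.0) -> float:
    """Bead-overlap count per 1000 beads.

    Counts pairs of non-adjacent beads closer than ``overlap_threshold``
    (adjacent = consecutive indices on the same chain) and scales by
    1000 / bead count.  Zero for clash-free models.
    """
    beads = model.beads
    n = len(beads)
    if n < 2:
        return 0.0
    tree = cKDTree(beads)
    pairs = tree.query_pairs(overlap_threshold, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    i, j = pairs[:, 0], pairs[:, 1]
    d = np.linalg.norm(beads[i] - beads[j], axis=1)
    strict = d < overlap_threshold
    adjacent = (np.abs(i - j) == 1) & (model.chain[i] == model.chain[j])
    return float(np.sum(strict & ~adjacent) * 1000.0 / n)


def _inter_protomer_clash(beads_list, overlap_threshold=3.0) -> float:
    """Clash score counting only pairs across different protomers."""
    all_beads = np.concatenate(beads_list)
    owner = np.concatenate([np.full(len(b), k) for k, b in enumerate(beads_list)])
    tree = cKDTree(all_beads)
    pairs = tree.query_pairs(overlap_threshold, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    i, j = pairs[:, 0], pairs[:, 1]
    d = np.linalg.norm(all_beads[i] - all_beads[j], axis=1)
    inter = (owner[i] != owner[j]) & (d < overlap_threshold)
    return float(np.sum(inter) * 1000.0 / len(all_beads))


def filter_pool(pool: Pool, max_clash: float = 60.0,
                overlap_threshold: float = 3.0) -> Pool:
    """Retain models with ``clash_score <= max_clash``, order preserved."""
    if len(pool) == 0:
        raise EmptyPoolError("cannot filter an empty pool")
    keep = [k for k, m in enumerate(pool.models)
            if clash_score(m, overlap_threshold) <= max_clash]
    if not keep:
        raise EmptyPoolError(f"no model passed clash filter <= {max_clash}")
    return Pool(
        models=[pool.models[k] for k in keep],
        rg=pool.rg[keep],
        dmax=pool.dmax[keep],
        curves=pool.curves[keep] if pool.curves is not None else None,
        curve_q=pool.curve_q,
        seed=pool.seed,
        provenance=pool.provenance[keep] if pool.provenance is not None else None,
    )


# ---------------------------------------------------------------------------
# tetramer combination
# ---------------------------------------------------------------------------

def combine_tetramers(protomer_pools, blueprint: TetramerBlueprint, n: int,
                      rng=None, max_clash: float = 60.0,
                      overlap_threshold: float = 3.0,
                      rejection_window: int = 1000) -> Pool:
    """Combine four protomer pools into ``n`` tetramer models.

    Each tetramer draws one protomer per pool uniformly at random (with
    replacement), rigidly superposes each protomer core onto the tetramer
    reference via ``blueprint.core_transforms`` and is accepted if the
    inter-protomer clash score is at most ``max_clash``.  Rejected draws are
    resampled; an acceptance rate below 1% over ``rejection_window``
    consecutive draws raises :class:`CombinationError`.  Source indices are
    recorded in ``provenance``.
    """
    if len(protomer_pools) != 4:
        raise ValueError("four protomer pools required")
    for p in protomer_pools:
        if len(p) == 0:
            raise EmptyPoolError("empty protomer pool")
    rng = np.random.default_rng(rng)

    out_models, out_prov = [], []
    recent = []  # rolling accept/reject record
    while len(out_models) < n:
        idx = [int(rng.integers(len(p))) for p in protomer_pools]
        parts = []
        for k in range(4):
            rot, t = blueprint.core_transforms[k]
            m = protomer_pools[k].models[idx[k]]
            parts.append(m.beads @ rot.T + t)
        score = _inter_protomer_clash(parts, overlap_threshold)
        accepted = score <= max_clash
        recent.append(accepted)
        if len(recent) > rejection_window:
            recent.pop(0)
        if accepted:
            beads = np.concatenate(parts)
            chain = np.concatenate([np.full(len(p), k + 1) for k, p in enumerate(parts)])
            segment = np.concatenate(
                [protomer_pools[k].models[idx[k]].segment for k in range(4)])
            flexible = np.concatenate(
                [protomer_pools[k].models[idx[k]].flexible for k in range(4)])
            out_models.append(ConformerModel(beads=beads, chain=chain,
                                             segment=segment, flexible=flexible))
            out_prov.append(idx)
        elif len(recent) == rejection_window and sum(recent) < 0.01 * rejection_window:
            raise CombinationError(
                f"acceptance rate below 1% over the last {rejection_window} draws")
    pool = Pool.from_models(out_models, provenance=np.array(out_prov))
    return pool


# ---------------------------------------------------------------------------
# size metrics
# ---------------------------------------------------------------------------

def model_rg(model: ConformerModel) -> float:
    """Weighted radius of gyration, sqrt(sum w |r - rbar|^2 / sum w)."""
    w = model.weights
    centre = np.average(model.beads, axis=0, weights=w)
    sq = np.sum((model.beads - centre) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=w)))


def model_dmax(model: ConformerModel, chunk: int = 2048) -> float:
    """Maximum pairwise bead distance (Angstrom)."""
    beads = model.beads
    n = len(beads)
    if n < 2:
        return 0.0
    # all-pairs in chunks; desk-scale models stay O(n^2) but memory-bounded
    best = 0.0
    for a in range(0, n, chunk):
        block = beads[a:a + chunk]
        d2 = np.sum((block[:, None, :] - beads[None, :, :]) ** 2, axis=-1)
        best = max(best, float(d2.max()))
    return float(np.sqrt(best))
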