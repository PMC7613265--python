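"""Conformer-pool generation: linker statistics, rigidity, clash filtering,
tetramer combination and size metrics."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import flexsome as fx
from flexsome.conformers import (BOND_LENGTH, EXCLUDED_VOLUME,
                                 BlueprintError, EmptyPoolError,
                                 LinkerSamplingError)
from flexsome.synthetic import make_domain_templates, d2_tetramer_blueprint


# ---------------------------------------------------------------------- linkers

def test_single_residue_linker_sits_one_bond_from_start():
    beads = fx.sample_linker(1, [1.0, 2.0, 3.0], [0, 0, 1],
                             rng=np.random.default_rng(0))
    assert np.isclose(np.linalg.norm(beads[0] - [1, 2, 3]), BOND_LENGTH)


def test_linker_geometry_contract():
    """Fixed bond length, contour bound and self-avoidance."""
    rng = np.random.default_rng(1)
    beads = fx.sample_linker(10, [0, 0, 0], [1, 0, 0], rng=rng)
    bonds = np.linalg.norm(np.diff(beads, axis=0), axis=1)
    assert np.allclose(bonds, BOND_LENGTH, atol=1e-9)
    assert np.linalg.norm(beads[-1]) <= 10 * BOND_LENGTH
    d = squareform(pdist(beads))
    np.fill_diagonal(d, np.inf)
    off_bond = d + np.diag(np.full(9, np.inf), 1) + np.diag(np.full(9, np.inf), -1)
    assert off_bond.min() >= EXCLUDED_VOLUME - 1e-9


def test_linker_deterministic_given_seed():
    a = fx.sample_linker(25, [0, 0, 0], [0, 1, 0], rng=np.random.default_rng(9))
    b = fx.sample_linker(25, [0, 0, 0], [0, 1, 0], rng=np.random.default_rng(9))
    assert np.array_equal(a, b)


def test_linker_respects_context_and_reports_failure():
    # enclose the start point in a tight cage: no placement can succeed
    cage = np.array([[x, y, z] for x in (-5, 0, 5) for y in (-5, 0, 5)
                     for z in (-5, 0, 5) if (x, y, z) != (0, 0, 0)])
    with pytest.raises(LinkerSamplingError) as err:
        fx.sample_linker(5, [0, 0, 0], [1, 0, 0], context_beads=cage,
                         rng=np.random.default_rng(2), max_attempts=20)
    assert err.value.attempts <= 20


def _oracle_linker(n, rng):
    """Independent re-implementation of the sampling rules: fixed 3.8 A
    bonds, bond angle uniform in [75, 155] deg, dihedral uniform, 4.0 A
    self-avoidance, restart on dead ends."""
    while True:
        pts = [np.zeros(3), np.array([BOND_LENGTH, 0.0, 0.0])]
        dead = False
        for _ in range(n - 1):
            placed = False
            for _t in range(30):
                theta = np.deg2rad(rng.uniform(75, 155))
                phi = rng.uniform(-np.pi, np.pi)
                b = pts[-1] - pts[-2]
                b /= np.linalg.norm(b)
                ref = np.array([0.0, 0.0, 1.0]) if abs(b[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
                u = np.cross(b, ref); u /= np.linalg.norm(u)
                v = np.cross(b, u)
                d = (np.cos(np.pi - theta) * b
                     + np.sin(np.pi - theta) * (np.cos(phi) * u + np.sin(phi) * v))
                cand = pts[-1] + BOND_LENGTH * d
                if len(pts) < 2 or np.min(np.linalg.norm(np.array(pts[:-1]) - cand,
                                                         axis=1)) >= EXCLUDED_VOLUME:
                    pts.append(cand); placed = True; break
            if not placed:
                dead = True; break
        if not dead:
            return np.array(pts[1:]) - pts[0]


def test_linker_end_to_end_statistics_match_independent_oracle():
    """Mean squared end-to-end distance agrees with a from-scratch
    implementation of the same coil rules within 15%."""
    n, reps = 20, 1500
    rng = np.random.default_rng(11)
    mine = np.mean([np.linalg.norm(fx.sample_linker(n, [0, 0, 0], [1, 0, 0],
                                                    rng=rng)[-1]) ** 2
                    for _ in range(reps)])
    oracle_rng = np.random.default_rng(13)
    theirs = np.mean([np.linalg.norm(_oracle_linker(n, oracle_rng)[-1]) ** 2
                      for _ in range(reps)])
    assert abs(mine - theirs) / theirs < 0.15


# ------------------------------------------------------------------- protomers

def test_single_rigid_domain_blueprint_is_identity(rng):
    dom = fx.RigidDomain(id="d", beads=rng.uniform(-10, 10, (30, 3)))
    bp = fx.ChainBlueprint(segments=[("rigid", "d")], core_id="d")
    model = fx.build_protomer(bp, {"d": dom}, np.random.default_rng(0))
    assert np.allclose(model.beads, dom.beads)


def test_rigid_domains_are_internally_preserved():
    r = np.random.default_rng(5)
    domains, bp = make_domain_templates("dumbbell", rng=r)
    ref = {k: squareform(pdist(d.beads)) for k, d in domains.items()}
    inter = []
    for seed in range(4):
        model = fx.build_protomer(bp, domains, np.random.default_rng(seed))
        for seg_idx, (kind, arg) in enumerate(bp.segments):
            if kind != "rigid":
                continue
            sub = model.beads[model.segment == seg_idx]
            assert np.allclose(squareform(pdist(sub)), ref[arg], atol=1e-6)
        com = [model.beads[model.segment == s].mean(axis=0) for s in (0, 2)]
        inter.append(np.linalg.norm(com[1] - com[0]))
    assert np.std(inter) > 1.0  # inter-domain geometry varies over seeds


def test_protomer_bead_count_bookkeeping():
    r = np.random.default_rng(5)
    domains, bp = make_domain_templates("dumbbell", rng=r)
    lig = fx.RigidDomain(id="lig", beads=r.uniform(-5, 5, (17, 3)))
    domains["lig"] = lig
    bp.ligands = [("lig", 1, 3)]  # attached to the linker segment
    model = fx.build_protomer(bp, domains, np.random.default_rng(1))
    expected = sum(len(domains[a].beads) if k == "rigid" else a
                   for k, a in bp.segments) + 17
    assert len(model) == expected


def test_blueprint_referencing_missing_domain_raises():
    bp = fx.ChainBlueprint(segments=[("rigid", "ghost")])
    with pytest.raises(BlueprintError):
        fx.build_protomer(bp, {}, np.random.default_rng(0))


# ----------------------------------------------------------------- clash score

def test_clash_score_examples(rng):
    two = fx.ConformerModel(beads=[[0, 0, 0], [10, 0, 0]], chain=[1, 2])
    assert fx.clash_score(two) == 0.0
    coincident = fx.ConformerModel(beads=np.zeros((10, 3)),
                                   chain=np.arange(1, 11))
    assert fx.clash_score(coincident) == pytest.approx(4500.0)


def test_clash_score_matches_brute_force(rng):
    beads = rng.uniform(0, 15, (100, 3))
    chain = np.ones(100, dtype=int)
    model = fx.ConformerModel(beads=beads, chain=chain)
    count = 0
    for i in range(100):
        for j in range(i + 1, 100):
            if j - i == 1:
                continue
            if np.linalg.norm(beads[i] - beads[j]) < 3.0:
                count += 1
    assert fx.clash_score(model) == pytest.approx(count * 1000 / 100)


def test_filter_pool_matches_per_model_oracle_and_is_idempotent(rng):
    models = [fx.ConformerModel(beads=rng.uniform(0, s, (40, 3)))
              for s in np.linspace(5, 40, 30)]
    pool = fx.Pool.from_models(models)
    kept = fx.filter_pool(pool, max_clash=60)
    expected = [m for m in models if fx.clash_score(m) <= 60]
    assert len(kept) == len(expected)
    again = fx.filter_pool(kept, max_clash=60)
    assert len(again) == len(kept)
    assert all(np.array_equal(a.beads, b.beads)
               for a, b in zip(again.models, kept.models))
    with pytest.raises(EmptyPoolError):
        fx.filter_pool(pool, max_clash=-1.0)


# ------------------------------------------------------------------- tetramers

def test_combine_tetramers_from_singleton_pools(rng):
    domains, bp = make_domain_templates("sphere", rng=np.random.default_rng(0))
    protomer = fx.build_protomer(bp, domains, np.random.default_rng(0))
    protomer.beads += 100.0  # move off-centre so D2 copies are disjoint
    pools = [fx.Pool.from_models([protomer]) for _ in range(4)]
    tbp = d2_tetramer_blueprint()
    tet = fx.combine_tetramers(pools, tbp, n=5, rng=np.random.default_rng(1))
    assert len(tet) == 5
    assert tet.provenance.shape == (5, 4)
    assert np.all(tet.provenance == 0)
    first = tet.models[0].beads
    for other in tet.models[1:]:
        assert np.allclose(other.beads, first)
    # rigid docking: each protomer equals its core transform of the source
    for k in range(4):
        rot, t = tbp.core_transforms[k]
        placed = tet.models[0].beads[tet.models[0].chain == k + 1]
        assert np.allclose(placed, protomer.beads @ rot.T + t, atol=1e-6)


def test_combine_tetramers_seed_determinism(dumbbell_pool):
    tbp = d2_tetramer_blueprint(spacing=60.0)
    pools = [dumbbell_pool] * 4
    a = fx.combine_tetramers(pools, tbp, 8, np.random.default_rng(4), max_clash=200)
    b = fx.combine_tetramers(pools, tbp, 8, np.random.default_rng(4), max_clash=200)
    assert np.array_equal(a.provenance, b.provenance)
    assert all(np.array_equal(x.beads, y.beads)
               for x, y in zip(a.models, b.models))


# --------------------------------------------------------------- size metrics

def test_rg_and_dmax_examples():
    two = fx.ConformerModel(beads=[[0, 0, 0], [10, 0, 0]])
    assert fx.model_rg(two) == pytest.approx(5.0)
    assert fx.model_dmax(two) == pytest.approx(10.0)
    one = fx.ConformerModel(beads=[[1, 1, 1]])
    assert fx.model_rg(one) == 0.0 and fx.model_dmax(one) == 0.0


def test_rg_of_uniform_sphere_approaches_closed_form():
    from conftest import random_cloud
    cloud = random_cloud(50.0, 5000, np.random.default_rng(8))
    rg = fx.model_rg(fx.ConformerModel(beads=cloud))
    assert rg == pytest.approx(np.sqrt(3 / 5) * 50, rel=0.02)


def test_dmax_matches_brute_force(rng):
    beads = rng.uniform(-30, 30, (100, 3))
    model = fx.ConformerModel(beads=beads)
    brute = max(np.linalg.norm(beads[i] - beads[j])
                for i in range(100) for j in range(i + 1, 100))
    assert fx.model_dmax(model) == pytest.approx(brute, abs=1e-9)
    assert fx.model_dmax(model) >= fx.model_rg(model)


def test_pool_contour_bound(dumbbell_pool):
    """Dmax never exceeds chain contour plus domain diameters."""
    from flexsome.synthetic import make_domain_templates
    domains, bp = make_domain_templates("dumbbell", rng=np.random.default_rng(7))
    diam = sum(fx.model_dmax(fx.ConformerModel(beads=d.beads))
               for d in domains.values())
    contour = 3.8 * sum(a for k, a in bp.segments if k == "linker")
    assert np.all(dumbbell_pool.dmax <= contour + diam + 2 * 3.8)
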