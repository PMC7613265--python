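"""Readers and writers for the standard formats the pipeline touches.

PDB (C-alpha bead models, occupancy column carries the bead weight), 3-column
whitespace-delimited scattering curves (q I sigma, '#' comments), MRC/CCP4
density volumes (mode-2 float, isotropic voxels enforced) and FASTA.  Every
CLI invocation records a :class:`RunManifest` sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import gemmi
import numpy as np
from Bio import SeqIO

from .charge import ProteinSequence
from .conformers import ConformerModel, RigidDomain
from .radial import DensityVolume, RadialProfile
from .scattering import PairDistribution, ScatteringCurve

__all__ = [
    "read_pdb", "write_pdb", "read_domain",
    "read_curve", "write_curve", "write_pair_distribution",
    "read_mrc", "write_mrc",
    "read_fasta",
    "RunManifest", "write_manifest",
    "reference_scaffold_sequences",
]

_CHAIN_NAMES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def read_pdb(path) -> ConformerModel:
    """Read a C-alpha bead model from a PDB file.

    Only CA atoms are kept; chain identity and residue numbering are
    preserved, and the occupancy column is interpreted as the bead weight.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    beads, weights, chains = [], [], []
    chain_ids: dict[str, int] = {}
    for model in st:
        for chain in model:
            cid = chain_ids.setdefault(chain.name, len(chain_ids) + 1)
            for res in chain:
                for atom in res:
                    if atom.name == "CA":
                        beads.append([atom.pos.x, atom.pos.y, atom.pos.z])
                        weights.append(atom.occ if atom.occ > 0 else 1.0)
                        chains.append(cid)
        break  # first MODEL only
    if not beads:
        raise ValueError(f"no CA ATOM records in {path}")
    return ConformerModel(beads=np.array(beads), weights=np.array(weights),
                          chain=np.array(chains))


def read_domain(path, domain_id: str | None = None, **anchors) -> RigidDomain:
    """Read a PDB file as a rigid domain (convenience wrapper)."""
    model = read_pdb(path)
    return RigidDomain(id=domain_id or Path(path).stem, beads=model.beads,
                       **anchors)


def write_pdb(model: ConformerModel, path) -> None:
    """Write a bead model as C-alpha-only ATOM records (chains A..D for
    tetramers; occupancy column carries the bead weight)."""
    st = gemmi.Structure()
    st.name = "flexsome bead model"
    md = gemmi.Model("1")
    for cid in sorted(set(model.chain.tolist())):
        chain = gemmi.Chain(_CHAIN_NAMES[(int(cid) - 1) % len(_CHAIN_NAMES)])
        sel = np.nonzero(model.chain == cid)[0]
        for serial, k in enumerate(sel, start=1):
            res = gemmi.Residue()
            res.name = "GLY"
            res.seqid = gemmi.SeqId(serial, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            x, y, z = model.beads[k]
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = float(model.weights[k])
            atom.b_iso = 0.0
            res.add_atom(atom)
            chain.add_residue(res)
        md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


def read_curve(path) -> ScatteringCurve:
    """Read a 2- or 3-column scattering curve (q I [sigma])."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 columns (q, I)")
    q, intensity = data[:, 0], data[:, 1]
    if np.any(np.diff(q) <= 0):
        raise ValueError(f"{path}: q not strictly increasing")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return ScatteringCurve(q=q, I=intensity, sigma=sigma)


def write_curve(curve: ScatteringCurve, path, header: str = "") -> None:
    cols = [curve.q, curve.I] + ([curve.sigma] if curve.sigma is not None else [])
    head = (header + "\n" if header else "") + \
        ("q(1/A) I sigma" if curve.sigma is not None else "q(1/A) I")
    np.savetxt(path, np.column_stack(cols), header=head, fmt="%.8e")


def write_pair_distribution(pd_: PairDistribution, path) -> None:
    np.savetxt(path, np.column_stack([pd_.r, pd_.p]),
               header=f"dmax = {pd_.dmax:.3f} A\nr(A) p(r)", fmt="%.8e")


def write_profile(profile: RadialProfile, path) -> None:
    cols = [profile.r, profile.rho]
    head = "r(A) rho"
    if profile.n_samples is not None:
        cols.append(profile.n_samples)
        head += " n"
    if profile.sd is not None:
        cols.append(profile.sd)
        head += " sd"
    np.savetxt(path, np.column_stack(cols), header=head, fmt="%.8e")


def write_mrc(vol: DensityVolume, path) -> None:
    """Write a mode-2 (float32) MRC/CCP4 map with isotropic voxel size."""
    ccp4 = gemmi.Ccp4Map()
    grid = gemmi.FloatGrid(np.ascontiguousarray(vol.grid, dtype=np.float32))
    nz, ny, nx = vol.grid.shape
    grid.set_unit_cell(gemmi.UnitCell(nx * vol.voxel, ny * vol.voxel,
                                      nz * vol.voxel, 90, 90, 90))
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def read_mrc(path, rtol: float = 1e-3) -> DensityVolume:
    """Read an MRC/CCP4 map; anisotropic voxels are an error."""
    ccp4 = gemmi.read_ccp4_map(str(path))
    arr = np.array(ccp4.grid, copy=True)
    sp = ccp4.grid.spacing
    if max(sp) - min(sp) > rtol * max(sp):
        raise ValueError(f"{path}: anisotropic voxels {sp}")
    return DensityVolume(grid=arr.astype(float), voxel=float(np.mean(sp)))


def read_fasta(path) -> list[ProteinSequence]:
    """Read protein sequences; lowercase letters are uppercased with a warning."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"{rec.id}: lowercase residues uppercased")
        out.append(ProteinSequence(id=rec.id, residues=seq.upper()))
    if not out:
        raise ValueError(f"no sequences in {path}")
    return out


def reference_scaffold_sequences() -> dict[str, ProteinSequence]:
    """The bundled scaffold-protein sequences, keyed by accession label.

    These are offline reconstructions of the two public database entries
    the charge analysis targets (see the FASTA header for validation
    status); they are NOT verbatim downloads.
    """
    from importlib.resources import files
    path = files("flexsome").joinpath("data/degradosome_scaffold_reconstructed.fasta")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seqs = read_fasta(str(path))
    return {s.id.split("|")[0]: s for s in seqs}


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Everything needed to reproduce a CLI run bit-exactly."""

    command: list[str]
    config: dict
    seeds: dict
    input_checksums: dict
    tool_version: str
    timestamp: str


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(out_path, config: dict, seeds: dict, inputs=()) -> RunManifest:
    from . import __version__
    manifest = RunManifest(
        command=list(sys.argv),
        config=config,
        seeds=seeds,
        input_checksums={str(p): _sha256(p) for p in inputs if Path(p).is_file()},
        tool_version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    Path(out_path).write_text(json.dumps(asdict(manifest), indent=2))
    return manifest
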