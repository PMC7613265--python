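"""Radial density profiling of vesicle-bound assemblies from 3-D volumes.

A tomographic subvolume of a protein-coated liposome is symmetrized
(icosahedral averaging followed by fine rotational averaging about chosen
axes), reduced to a 1-D radial density profile from the vesicle centre
outwards, and the profile is summarized by the membrane peak radius, the
membrane-to-protein gap and the radial extension of the protein shell.
Profiles from different vesicles can be aligned on their membrane peaks and
averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = [
    "DensityVolume",
    "RadialProfile",
    "ProfileMetrics",
    "FlatProfileError",
    "icosahedral_average",
    "axis_rotational_average",
    "radial_profile",
    "profile_metrics",
    "average_profiles",
]


class FlatProfileError(RuntimeError):
    """Profile has no peak above baseline."""


@dataclass
class DensityVolume:
    """A cubic-voxel scalar volume.  ``grid`` is indexed (z, y, x), ``voxel``
    is the edge length in Angstrom, ``origin`` an offset in Angstrom."""

    grid: np.ndarray
    voxel: float
    origin: np.ndarray | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-D")
        if min(self.grid.shape) < 16:
            raise ValueError("volume must be at least 16^3 voxels")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid must be finite")
        if self.voxel <= 0:
            raise ValueError("voxel size must be positive")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def is_cubic(self) -> bool:
        return len(set(self.grid.shape)) == 1

    def centre_voxel(self) -> np.ndarray:
        return (np.array(self.grid.shape, dtype=float) - 1.0) / 2.0


def _rotate_grid(grid: np.ndarray, rot: np.ndarray) -> np.ndarray:
    """Rotate a volume about its geometric centre, trilinear interpolation."""
    centre = (np.array(grid.shape, dtype=float) - 1.0) / 2.0
    # affine_transform maps output coords to input: in = M @ out + offset.
    # Sampling the rotated volume at x requires input coord R^-1 (x - c) + c.
    m = rot.T
    offset = centre - m @ centre
    return ndimage.affine_transform(grid, m, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def icosahedral_average(vol: DensityVolume) -> DensityVolume:
    """Mean of the volume over the 60 rotations of the icosahedral group.

    Uses trilinear interpolation about the volume centre; density inside the
    inscribed sphere is conserved to interpolation accuracy.
    """
    if not vol.is_cubic:
        raise ValueError("icosahedral averaging requires a cubic volume")
    rots = Rotation.create_group("I").as_matrix()
    acc = np.zeros_like(vol.grid)
    for rot in rots:
        acc += _rotate_grid(vol.grid, rot)
    return DensityVolume(grid=acc / len(rots), voxel=vol.voxel,
                         origin=vol.origin.copy())


def axis_rotational_average(vol: DensityVolume, axes=("X", "Y"),
                            step_deg: float = 10.0) -> DensityVolume:
    """Sequential rotational averaging about the listed axes.

    ``step_deg`` must divide 360.  Axes are the volume's X/Y/Z directions
    through its centre.
    """
    if not vol.is_cubic:
        raise ValueError("rotational averaging requires a cubic volume")
    if abs(360.0 / step_deg - round(360.0 / step_deg)) > 1e-9:
        raise ValueError("step_deg must divide 360")
    n_steps = int(round(360.0 / step_deg))
    grid = vol.grid
    # grid axes are (z, y, x); a named axis maps to a rotation-matrix axis
    axis_vec = {"X": [1.0, 0.0, 0.0], "Y": [0.0, 1.0, 0.0], "Z": [0.0, 0.0, 1.0]}
    for axis in axes:
        if axis.upper() not in axis_vec:
            raise ValueError(f"unknown axis {axis!r}")
        acc = np.zeros_like(grid)
        for k in range(n_steps):
            ang = np.deg2rad(k * step_deg)
            rot = Rotation.from_rotvec(np.array(axis_vec[axis.upper()]) * ang).as_matrix()
            # matrices act on (z, y, x) index vectors; axis order is symmetric
            acc += _rotate_grid(grid, rot)
        grid = acc / n_steps
    return DensityVolume(grid=grid, voxel=vol.voxel, origin=vol.origin.copy())


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


@dataclass
class RadialProfile:
    """Shell-averaged density versus radius (r in Angstrom, step = voxel)."""

    r: np.ndarray
    rho: np.ndarray
    n_samples: np.ndarray | None = None
    sd: np.ndarray | None = None  # filled by average_profiles

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.r[0] != 0 and self.sd is None:
            raise ValueError("r must start at 0")
        if self.r.shape != self.rho.shape:
            raise ValueError("r and rho must match")


def auto_centre(vol: DensityVolume) -> np.ndarray:
    """Density-weighted centroid of the thresholded high-density shell, in
    voxel coordinates (z, y, x)."""
    thr = np.median(vol.grid) + 0.5 * (vol.grid.max() - np.median(vol.grid))
    mask = vol.grid >= thr
    if not mask.any():
        return vol.centre_voxel()
    w = vol.grid[mask]
    coords = np.argwhere(mask)
    return (coords * w[:, None]).sum(axis=0) / w.sum()


def radial_profile(vol: DensityVolume, center="auto") -> RadialProfile:
    """1-D radial density profile from the centre outwards.

    For each radius r = 0, voxel, 2*voxel, ... up to half the box, the
    density is averaged over at least max(100, 4*pi*r^2/voxel^2)
    quasi-uniform (Fibonacci) points on the sphere of radius r, sampled by
    trilinear interpolation.
    """
    if isinstance(center, str) and center == "auto":
        centre = auto_centre(vol)
    else:
        centre = np.asarray(center, dtype=float) / vol.voxel  # Angstrom -> voxel
    if np.any(centre < 0) or np.any(centre > np.array(vol.grid.shape) - 1):
        raise ValueError("center outside volume")
    half_box = min(vol.grid.shape) * vol.voxel / 2.0
    radii = np.arange(0.0, half_box + 1e-9, vol.voxel)
    rho = np.empty(len(radii))
    counts = np.empty(len(radii), dtype=int)
    for k, r in enumerate(radii):
        if r == 0:
            rho[k] = float(ndimage.map_coordinates(
                vol.grid, centre.reshape(3, 1), order=1, mode="nearest")[0])
            counts[k] = 1
            continue
        n = max(100, int(np.ceil(4.0 * np.pi * r ** 2 / vol.voxel ** 2)))
        pts = centre[None, :] + _fibonacci_sphere(n) * (r / vol.voxel)
        vals = ndimage.map_coordinates(vol.grid, pts.T, order=1, mode="nearest")
        rho[k] = float(vals.mean())
        counts[k] = n
    return RadialProfile(r=radii, rho=rho, n_samples=counts)


@dataclass
class ProfileMetrics:
    """Geometry of a membrane-plus-protein radial profile (Angstrom).

    ``gap`` is measured from the membrane peak to the inner edge of the
    protein shell; ``extension`` is the radial width of the protein shell.
    """

    membrane_peak_r: float
    gap: float | None
    extension: float | None
    protein_region: tuple[float, float] | None
    bimodal: bool
    baseline: float


def _parabolic_peak(r: np.ndarray, rho: np.ndarray, i: int) -> float:
    """Sub-grid peak position from a parabola through three points."""
    if not (0 < i < len(r) - 1):
        return float(r[i])
    denom = rho[i - 1] - 2 * rho[i] + rho[i + 1]
    if denom >= 0:
        return float(r[i])
    shift = 0.5 * (rho[i - 1] - rho[i + 1]) / denom
    return float(r[i] + np.clip(shift, -1.0, 1.0) * (r[1] - r[0]))


def _half_rise_edge(r, rho, i_edge, direction, baseline, floor) -> float:
    """Interpolated edge position: the crossing of the local half-rise level
    between the boundary sample and its interior neighbour.  ``direction``
    is +1 for a left (rising) edge, -1 for a right (falling) edge."""
    i_int = i_edge + direction
    if not (0 <= i_int < len(r)):
        return float(r[i_edge])
    half = baseline + 0.5 * (rho[i_int] - baseline)
    lo_v, hi_v = rho[i_edge], rho[i_int]
    if hi_v <= lo_v or not (lo_v <= half <= hi_v):
        return float(r[i_edge])
    t = (half - lo_v) / (hi_v - lo_v)
    return float(r[i_edge] + t * (r[i_int] - r[i_edge]))


def _local_maxima(y: np.ndarray) -> np.ndarray:
    idx = []
    for i in range(1, len(y) - 1):
        if y[i] >= y[i - 1] and y[i] >= y[i + 1] and (y[i] > y[i - 1] or y[i] > y[i + 1]):
            idx.append(i)
    return np.array(idx, dtype=int)


def profile_metrics(profile: RadialProfile, frac: float = 0.1) -> ProfileMetrics:
    """Extract membrane peak, gap and protein-shell extension from a profile.

    Baseline is the median over the outer 20% of the r-range (solvent).  The
    membrane peak is the first local maximum exceeding baseline plus half
    the global contrast.  Beyond the peak-side valley, the protein shell is
    the contiguous region where the density stays above baseline +
    ``frac`` * (protein peak - baseline); the gap is the distance from the
    membrane peak to the shell's inner edge and the extension is the shell
    width.  The shell is flagged bimodal when it carries two or more local
    maxima separated by a >= 10% dip.
    """
    r, rho = profile.r, profile.rho
    outer = rho[int(np.floor(0.8 * len(r))):]
    baseline = float(np.median(outer))
    gmax = float(rho.max())
    if gmax <= baseline:
        raise FlatProfileError("no density above baseline")
    peak_thr = baseline + 0.5 * (gmax - baseline)
    maxima = _local_maxima(rho)
    mem_candidates = maxima[rho[maxima] >= peak_thr] if len(maxima) else np.array([], int)
    if len(mem_candidates) == 0:
        raise FlatProfileError("no membrane peak above threshold")
    i_peak = int(mem_candidates[0])

    # valley between membrane and protein shell: minimum after the peak
    # before the density rises again (or the profile end)
    i = i_peak
    while i + 1 < len(rho) and rho[i + 1] <= rho[i]:
        i += 1
    i_valley = i
    if i_valley >= len(rho) - 1:
        return ProfileMetrics(membrane_peak_r=float(r[i_peak]), gap=None,
                              extension=None, protein_region=None,
                              bimodal=False, baseline=baseline)

    after = rho[i_valley:]
    prot_peak = float(after.max())
    if prot_peak - baseline <= frac * (rho[i_peak] - baseline):
        return ProfileMetrics(membrane_peak_r=float(r[i_peak]), gap=None,
                              extension=None, protein_region=None,
                              bimodal=False, baseline=baseline)
    thr = baseline + frac * (prot_peak - baseline)
    i_prot_peak = i_valley + int(np.argmax(after))
    lo = i_prot_peak
    while lo > i_valley and rho[lo - 1] >= thr:
        lo -= 1
    hi = i_prot_peak
    while hi + 1 < len(rho) and rho[hi + 1] >= thr:
        hi += 1
    # sub-voxel edge refinement: interpolate the local half-rise crossing,
    # which localizes a sharp shell edge to a fraction of the grid step
    r_in = _half_rise_edge(r, rho, lo, direction=+1, baseline=baseline,
                           floor=i_valley)
    r_out = _half_rise_edge(r, rho, hi, direction=-1, baseline=baseline,
                            floor=len(rho) - 1)
    region = (r_in, r_out)

    seg_max = _local_maxima(rho[lo:hi + 1])
    bimodal = False
    if len(seg_max) >= 2:
        seg = rho[lo:hi + 1]
        for a, b in zip(seg_max[:-1], seg_max[1:]):
            dip = seg[a:b + 1].min()
            lower_peak = min(seg[a], seg[b])
            if lower_peak - dip >= 0.1 * (lower_peak - baseline):
                bimodal = True
                break
    peak_r = _parabolic_peak(r, rho, i_peak)
    return ProfileMetrics(
        membrane_peak_r=peak_r,
        gap=float(r_in - peak_r),
        extension=float(r_out - r_in),
        protein_region=region,
        bimodal=bimodal,
        baseline=baseline,
    )


def average_profiles(profiles, align: str = "membrane_peak") -> RadialProfile:
    """Align profiles on their membrane peaks and average pointwise.

    Returns the mean profile on the first profile's grid (restricted to the
    radii where every shifted profile is defined) with the pointwise
    standard deviation in ``sd``.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    if align != "membrane_peak":
        raise ValueError("only membrane_peak alignment is supported")
    peaks, offenders = [], []
    for k, p in enumerate(profiles):
        try:
            peaks.append(profile_metrics(p).membrane_peak_r)
        except FlatProfileError:
            offenders.append(k)
    if offenders:
        raise FlatProfileError(f"profiles without a membrane peak: {offenders}")
    ref = profiles[0]
    ref_peak = peaks[0]
    # shifted profile k is defined on [r_k0 + shift, r_k-1 + shift]
    lo = max(p.r[0] + (ref_peak - pk) for p, pk in zip(profiles, peaks))
    hi = min(p.r[-1] + (ref_peak - pk) for p, pk in zip(profiles, peaks))
    sel = (ref.r >= lo - 1e-9) & (ref.r <= hi + 1e-9)
    if not sel.any():
        raise ValueError("aligned profiles share no support")
    r_out = ref.r[sel]
    stack = np.empty((len(profiles), len(r_out)))
    for k, (p, pk) in enumerate(zip(profiles, peaks)):
        stack[k] = np.interp(r_out - (ref_peak - pk), p.r, p.rho)
    return RadialProfile(r=r_out, rho=stack.mean(axis=0),
                         n_samples=np.full(len(r_out), len(profiles)),
                         sd=stack.std(axis=0))
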