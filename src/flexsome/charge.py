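"""Sequence-level electrostatics: isoelectric point, charged-residue
fractions and the kappa charge-patterning parameter.

The isoelectric point follows the Henderson-Hasselbalch model with the
Bjellqvist pKa set (the set used by the ProtParam web tool), solved by
bisection on the net charge.  Charge patterning follows the Das-Pappu
polyampholyte framework: lysine/arginine count as positive and
aspartate/glutamate as negative (histidine is excluded from the charge
fractions, the convention of the CIDER tool), local charge asymmetry
``sigma = (f+ - f-)^2 / (f+ + f-)`` is averaged over sliding blobs of 5 and
6 residues, and kappa is the blob-asymmetry variance delta normalized by
the delta of the most segregated rearrangement of the same composition.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProteinSequence",
    "ChargeMetrics",
    "UnknownResidueError",
    "UndefinedPIError",
    "UndefinedKappaError",
    "net_charge",
    "isoelectric_point",
    "charge_fractions",
    "kappa",
    "delta_patterning",
    "delta_max",
    "region_report",
]

CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")

# Bjellqvist pKa values (as used by ProtParam): side chains, and
# residue-specific N-terminal pKas.
PKA_POSITIVE = {"K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_NTERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82,
             "V": 7.44, "E": 7.7}
PKA_NTERM_DEFAULT = 7.5
PKA_CTERM = 3.55

POSITIVE_SET = "KR"   # charge-fraction convention (H excluded)
NEGATIVE_SET = "DE"


class UnknownResidueError(ValueError):
    pass


class UndefinedPIError(ValueError):
    pass


class UndefinedKappaError(ValueError):
    pass


@dataclass
class ProteinSequence:
    """A protein sequence with an optional 1-based inclusive region."""

    id: str
    residues: str
    region: tuple[int, int] | None = None

    def __post_init__(self):
        self.residues = self.residues.upper()
        if self.region is not None:
            start, end = self.region
            if not (1 <= start <= end):
                raise ValueError("region must satisfy 1 <= start <= end")
            if end > len(self.residues):
                warnings.warn(
                    f"{self.id}: region end {end} beyond sequence length "
                    f"{len(self.residues)}; clamping")
                self.region = (start, len(self.residues))

    def subsequence(self) -> str:
        if self.region is None:
            return self.residues
        start, end = self.region
        return self.residues[start - 1:end]


@dataclass
class ChargeMetrics:
    pi: float
    fplus: float
    fminus: float
    fcr: float
    ncpr: float
    kappa: float | None = None
    delta: float | None = None
    delta_max: float | None = None

    def __post_init__(self):
        if self.fcr > 1 + 1e-12 or abs(self.ncpr) > self.fcr + 1e-12:
            raise ValueError("inconsistent charge fractions")


def _check(seq: str, strict: bool = True) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    if strict:
        for k, aa in enumerate(seq):
            if aa not in CANONICAL:
                raise UnknownResidueError(
                    f"non-canonical residue {aa!r} at position {k + 1}")
    return seq


def net_charge(seq: str, pH: float, strict: bool = True) -> float:
    """Henderson-Hasselbalch net charge at a given pH (elementary charges).

    Sums D, E, C, Y side chains, H, K, R side chains and both termini with
    the Bjellqvist pKa set; monotone non-increasing in pH.
    """
    seq = _check(seq, strict)
    q = 1.0 / (1.0 + 10.0 ** (pH - PKA_NTERM.get(seq[0], PKA_NTERM_DEFAULT)))
    for aa, pk in PKA_POSITIVE.items():
        q += seq.count(aa) / (1.0 + 10.0 ** (pH - pk))
    q -= 1.0 / (1.0 + 10.0 ** (PKA_CTERM - pH))
    for aa, pk in PKA_NEGATIVE.items():
        q -= seq.count(aa) / (1.0 + 10.0 ** (pk - pH))
    return q


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH of zero net charge, by bisection on [0, 14]."""
    seq = _check(seq)
    lo, hi = 0.0, 14.0
    if net_charge(seq, lo) <= 0 or net_charge(seq, hi) >= 0:
        raise UndefinedPIError("net charge does not change sign on [0, 14]")
    while True:
        mid = 0.5 * (lo + hi)
        q = net_charge(seq, mid)
        if abs(q) < tol or hi - lo < 1e-12:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid


def charge_fractions(seq: str) -> tuple[float, float, float, float]:
    """(f+, f-, FCR, NCPR) with K/R positive and D/E negative."""
    seq = _check(seq)
    n = len(seq)
    fplus = sum(seq.count(aa) for aa in POSITIVE_SET) / n
    fminus = sum(seq.count(aa) for aa in NEGATIVE_SET) / n
    return fplus, fminus, fplus + fminus, fplus - fminus


# ---------------------------------------------------------------------------
# kappa
# ---------------------------------------------------------------------------

def _charge_vector(seq: str) -> np.ndarray:
    return np.array([1 if aa in POSITIVE_SET else (-1 if aa in NEGATIVE_SET else 0)
                     for aa in seq], dtype=np.int8)


def _sigma(fp: float, fm: float) -> float:
    tot = fp + fm
    return 0.0 if tot == 0 else (fp - fm) ** 2 / tot


def _delta_g(charges: np.ndarray, g: int) -> float:
    """Mean squared deviation of blob charge asymmetry from the sequence's."""
    n = len(charges)
    fp_seq = float(np.count_nonzero(charges > 0)) / n
    fm_seq = float(np.count_nonzero(charges < 0)) / n
    sig_seq = _sigma(fp_seq, fm_seq)
    if n < g:
        return 0.0
    kernel = np.ones(g)
    pos = np.convolve((charges > 0).astype(float), kernel, mode="valid") / g
    neg = np.convolve((charges < 0).astype(float), kernel, mode="valid") / g
    tot = pos + neg
    with np.errstate(divide="ignore", invalid="ignore"):
        sig = np.where(tot > 0, (pos - neg) ** 2 / tot, 0.0)
    return float(np.mean((sig - sig_seq) ** 2))


def delta_patterning(seq_or_charges, blob_sizes=(5, 6)) -> float:
    """delta: blob charge-asymmetry variance averaged over blob sizes."""
    charges = (seq_or_charges if isinstance(seq_or_charges, np.ndarray)
               else _charge_vector(_check(seq_or_charges)))
    return float(np.mean([_delta_g(charges, g) for g in blob_sizes]))


def _block_patterns(n_plus: int, n_minus: int, n_zero: int):
    """Candidate maximally segregated arrangements: the charge blocks in both
    orders, with the neutral residues split among the three gaps."""
    plus = np.ones(n_plus, dtype=np.int8)
    minus = -np.ones(n_minus, dtype=np.int8)
    for z1 in range(n_zero + 1):
        for z2 in range(n_zero - z1 + 1):
            z3 = n_zero - z1 - z2
            zeros = (np.zeros(z1, dtype=np.int8), np.zeros(z2, dtype=np.int8),
                     np.zeros(z3, dtype=np.int8))
            yield np.concatenate([zeros[0], plus, zeros[1], minus, zeros[2]])
            if n_plus and n_minus:
                yield np.concatenate([zeros[0], minus, zeros[1], plus, zeros[2]])


def delta_max(seq_or_charges, blob_sizes=(5, 6), return_pattern=False,
              exhaustive_limit: int = 20000):
    """Maximum delta over rearrangements of the composition.

    For small compositions (at most ``exhaustive_limit`` distinct
    arrangements) the maximum is exact, by enumeration of the multiset
    permutations; block edge effects at short lengths can beat the
    segregated arrangement, so enumeration is required for exactness.
    Longer sequences use the deterministic block-segregated search of the
    published kappa algorithm: both orders of the contiguous positive and
    negative blocks with every placement of the neutral residues among the
    three gaps.
    """
    from math import comb

    charges = (seq_or_charges if isinstance(seq_or_charges, np.ndarray)
               else _charge_vector(_check(seq_or_charges)))
    n = len(charges)
    n_plus = int(np.count_nonzero(charges > 0))
    n_minus = int(np.count_nonzero(charges < 0))
    n_zero = n - n_plus - n_minus
    n_arrangements = comb(n, n_plus) * comb(n - n_plus, n_minus)
    if n_arrangements <= exhaustive_limit:
        from sympy.utilities.iterables import multiset_permutations
        candidates = (np.array(p, dtype=np.int8) for p in multiset_permutations(
            [1] * n_plus + [-1] * n_minus + [0] * n_zero))
    else:
        candidates = _block_patterns(n_plus, n_minus, n_zero)
    best, best_pat = -1.0, None
    for pat in candidates:
        d = delta_patterning(pat, blob_sizes)
        if d > best + 1e-15:
            best, best_pat = d, pat
    return (best, best_pat) if return_pattern else best


def kappa(seq: str, blob_sizes=(5, 6)) -> ChargeMetrics:
    """Full charge metrics for a sequence, including kappa = delta/delta_max."""
    seq = _check(seq)
    fplus, fminus, fcr, ncpr = charge_fractions(seq)
    charges = _charge_vector(seq)
    n_charged = int(np.count_nonzero(charges))
    if fcr == 0 or n_charged < 2:
        raise UndefinedKappaError("kappa needs >= 2 charged residues")
    d = delta_patterning(charges, blob_sizes)
    dmax = delta_max(charges, blob_sizes)
    if dmax <= 0:
        raise UndefinedKappaError("delta_max is zero for this composition")
    return ChargeMetrics(pi=isoelectric_point(seq), fplus=fplus, fminus=fminus,
                         fcr=fcr, ncpr=ncpr, kappa=d / dmax, delta=d,
                         delta_max=dmax)


def kappa_exhaustive(seq: str, blob_sizes=(5, 6)) -> float:
    """Brute-force kappa: delta_max over ALL distinct arrangements of the
    composition.  Exponential; intended for sequences of ~10 residues as an
    independent oracle."""
    charges = _charge_vector(_check(seq))
    best = 0.0
    for perm in set(itertools.permutations(charges.tolist())):
        best = max(best, delta_patterning(np.array(perm, dtype=np.int8), blob_sizes))
    return delta_patterning(charges, blob_sizes) / best


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def classify_polyampholyte(fcr: float, ncpr: float) -> str:
    """Diagram-of-states class from (FCR, |NCPR|)."""
    if abs(ncpr) > 0.35:
        return "strong polyelectrolyte"
    if fcr > 0.35:
        return "strong polyampholyte"
    if fcr >= 0.25:
        return "boundary (Janus) polyampholyte"
    return "weak polyampholyte"


def region_report(sequence: ProteinSequence | str, regions=None) -> pd.DataFrame:
    """Tabulate charge metrics for a list of 1-based inclusive regions.

    ``regions=None`` reports the whole sequence.  Overlapping regions only
    warn.  Regions with fewer than two charged residues report kappa as NaN.
    """
    if isinstance(sequence, str):
        sequence = ProteinSequence(id="seq", residues=sequence)
    seq = sequence.residues
    if regions is None:
        regions = [(1, len(seq))]
    spans = sorted(regions)
    for (a1, b1), (a2, _b2) in zip(spans, spans[1:]):
        if a2 <= b1:
            warnings.warn(f"regions {(a1, b1)} and {(a2, _b2)} overlap")
    rows = []
    for start, end in regions:
        sub = ProteinSequence(sequence.id, seq, region=(start, end)).subsequence()
        fplus, fminus, fcr, ncpr = charge_fractions(sub)
        try:
            cm = kappa(sub)
            kap, dlt, dmx = cm.kappa, cm.delta, cm.delta_max
        except UndefinedKappaError:
            kap = dlt = dmx = float("nan")
        rows.append({
            "id": sequence.id, "start": start, "end": min(end, len(seq)),
            "length": len(sub), "pI": round(isoelectric_point(sub), 2),
            "fplus": fplus, "fminus": fminus, "FCR": fcr, "NCPR": ncpr,
            "kappa": kap, "delta": dlt, "delta_max": dmx,
            "class": classify_polyampholyte(fcr, ncpr),
        })
    return pd.DataFrame(rows)
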