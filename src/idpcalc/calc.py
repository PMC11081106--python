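"""Back-calculators for the four internally computed observables.

Per conformer the four observables are pure functions of the coordinates:

* PRE       — the Euclidean distance between the two template atoms (A).
* NOE       — a power-mean distance over the N assignment combinations of an
              ambiguous proton pair. Default mode averages d^6
              (``d = ((1/N) sum d_k^6)^(1/6)``); mode ``"rminus6"`` gives the
              conventional NMR r^-6 average (``((1/N) sum d_k^-6)^(-1/6)``).
* 3J-HNHA   — the Karplus curve J = A cos^2(phi - pi/3) + B cos(phi - pi/3) + C
              evaluated at the backbone phi torsion (Hz).
* smFRET    — E = 1 / (1 + (D'/S)^6) with D' the CA-CA distance scaled by
              (n + 7)/n to account for dye-linker size, n the sequence
              separation and S the experiment-derived scale factor.

No ensemble averaging happens here: one value per conformer per template row,
leaving reweighting and summary statistics downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np

from .ensemble import Conformer, expand_atom_names, select_atom
from .errors import ComputationError, UndefinedTorsionError

#: Residue offset added to the sequence separation to absorb dye-linker size.
DYE_LINKER_OFFSET = 7.0


@dataclass(frozen=True)
class KarplusCoefficients:
    """Coefficients of J(theta) = A cos^2 theta + B cos theta + C, in Hz."""

    A: float = 6.51
    B: float = -1.76
    C: float = 1.60

    def __post_init__(self):
        if not self.A > 0:
            raise ValueError("Karplus A must be positive")


DEFAULT_KARPLUS = KarplusCoefficients()


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

def euclidean_distance(p1, p2) -> float:
    """Scalar distance sqrt(dx^2 + dy^2 + dz^2) between two points (A)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return float(np.sqrt(np.sum((p1 - p2) ** 2)))


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in radians, range (-pi, pi].

    IUPAC sign convention: viewed from p2 toward p3, a clockwise rotation of
    the far bond is positive. Invariant under rigid motion; negates under
    reflection. Collinear geometry raises :class:`UndefinedTorsionError`.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise UndefinedTorsionError("collinear atoms: torsion undefined")
    b2n = b2 / np.linalg.norm(b2)
    m1 = np.cross(n1, b2n)
    angle = math.atan2(float(np.dot(m1, n2)), float(np.dot(n1, n2)))
    if angle <= -math.pi + 1e-15:
        angle = math.pi
    return angle


def compute_phi(conformer: Conformer, resseq: int) -> float:
    """Backbone phi torsion C(i-1)-N(i)-CA(i)-C(i) in radians.

    Undefined at the first residue (no preceding carbonyl carbon).
    """
    numbers = conformer.residue_numbers()
    if resseq not in numbers:
        raise UndefinedTorsionError(f"residue {resseq} absent")
    pos = numbers.index(resseq)
    if pos == 0:
        raise UndefinedTorsionError(f"phi undefined at first residue {resseq}")
    prev = numbers[pos - 1]
    c_prev = select_atom(conformer, prev, "C")
    n = select_atom(conformer, resseq, "N")
    ca = select_atom(conformer, resseq, "CA")
    c = select_atom(conformer, resseq, "C")
    return dihedral(c_prev.coord, n.coord, ca.coord, c.coord)


# ---------------------------------------------------------------------------
# Observable back-calculators
# ---------------------------------------------------------------------------

def _guard(fn, missing: str):
    """Run ``fn``; under the "null" policy a computation error yields None."""
    if missing == "fail":
        return fn()
    try:
        return fn()
    except ComputationError:
        return None


def backcalc_pre(conformer: Conformer, pairs, missing: str = "fail") -> list[float | None]:
    """PRE distances: one atom-pair Euclidean distance per template row (A)."""
    out = []
    for pair in pairs:
        def one(pair=pair):
            a1 = select_atom(conformer, pair.res1, pair.atom1)
            a2 = select_atom(conformer, pair.res2, pair.atom2)
            return euclidean_distance(a1.coord, a2.coord)
        out.append(_guard(one, missing))
    return out


def noe_average(distances, mode: str = "r6") -> float:
    """Power-mean of assignment-combination distances.

    ``"r6"``: ((1/N) sum d^6)^(1/6) — the literal template-averaging form.
    ``"rminus6"``: ((1/N) sum d^-6)^(-1/6) — conventional NOE r^-6 averaging.
    Both reduce to the single distance when N = 1 and are bounded by
    [min d, max d].
    """
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0:
        raise ValueError("no distances to average")
    if d.size == 1:
        return float(d[0])  # exact reduction to the plain distance
    if mode == "r6":
        return float(np.mean(d ** 6) ** (1.0 / 6.0))
    if mode == "rminus6":
        return float(np.mean(d ** -6.0) ** (-1.0 / 6.0))
    raise ValueError(f"unknown NOE averaging mode: {mode!r}")


def backcalc_noe(
    conformer: Conformer,
    pairs,
    averaging: str = "r6",
    missing: str = "fail",
) -> list[float | None]:
    """NOE distances with multi-assignment averaging (A).

    For each template row every assignment combination — the Cartesian product
    of {primary + alternatives} on each side, with pseudoatom group names
    expanded to their member protons — contributes a distance d_k; the row
    value is their power mean under ``averaging``. With no alternatives the
    result equals :func:`backcalc_pre` exactly.
    """
    out = []
    for pair in pairs:
        def one(pair=pair):
            side1, side2 = [], []
            for name in [pair.atom1, *pair.atom1_alts]:
                side1.extend(expand_atom_names(conformer, pair.res1, name))
            for name in [pair.atom2, *pair.atom2_alts]:
                side2.extend(expand_atom_names(conformer, pair.res2, name))
            # De-duplicate while preserving order (aliases may coincide).
            side1 = list(dict.fromkeys(side1))
            side2 = list(dict.fromkeys(side2))
            dists = [
                euclidean_distance(a.coord, b.coord) for a, b in product(side1, side2)
            ]
            return noe_average(dists, averaging)
        out.append(_guard(one, missing))
    return out


def karplus(phi: float, k: KarplusCoefficients = DEFAULT_KARPLUS) -> float:
    """3J-HNHA coupling from phi: J = A cos^2(phi - pi/3) + B cos(phi - pi/3) + C."""
    c = math.cos(phi - math.pi / 3.0)
    return k.A * c * c + k.B * c + k.C


def backcalc_jc(
    conformer: Conformer,
    records,
    k: KarplusCoefficients = DEFAULT_KARPLUS,
    missing: str = "fail",
) -> list[float | None]:
    """3J-HNHA couplings (Hz), one per template residue, via the Karplus curve."""
    out = []
    for rec in records:
        def one(rec=rec):
            return karplus(compute_phi(conformer, rec.resnum), k)
        out.append(_guard(one, missing))
    return out


def fret_efficiency(distance: float, separation: int, scale: float,
                    linker_offset: float = DYE_LINKER_OFFSET) -> float:
    """smFRET efficiency from a CA-CA distance.

    The distance is stretched by (n + linker_offset)/n, n = sequence
    separation, to approximate the dye attachment points, then passed through
    the Foerster sigmoid with scale factor S: E = 1/(1 + (D'/S)^6).
    """
    n = abs(int(separation))
    if n == 0:
        raise ValueError("smFRET residues must differ")
    d_corr = distance * (n + linker_offset) / n
    return 1.0 / (1.0 + (d_corr / scale) ** 6)


def backcalc_smfret(
    conformer: Conformer,
    pairs,
    linker_offset: float = DYE_LINKER_OFFSET,
    missing: str = "fail",
) -> list[float | None]:
    """smFRET efficiencies (unitless, in (0, 1]) from CA-CA distances."""
    out = []
    for pair in pairs:
        def one(pair=pair):
            ca1 = select_atom(conformer, pair.res1, "CA")
            ca2 = select_atom(conformer, pair.res2, "CA")
            d = euclidean_distance(ca1.coord, ca2.coord)
            return fret_efficiency(d, pair.res2 - pair.res1, pair.scale, linker_offset)
        out.append(_guard(one, missing))
    return out
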