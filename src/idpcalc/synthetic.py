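"""Synthetic peptide conformer ensembles with prescribed backbone torsions.

Disordered-ensemble back-calculation needs all-atom structures whose internal
coordinates are known exactly, so every calculator can be checked against the
torsions that built the structure. This module places backbone atoms
sequentially (natural-extension reference frame: each atom from a bond
length, bond angle and torsion relative to three placed atoms) using
idealized peptide geometry, then adds the amide proton, HA and a CB stub —
the atoms the four templates can name. Physical realism (side-chain packing,
clash avoidance) is deliberately out of scope: the calculators only read the
atoms the templates reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.SeqUtils import seq3

from .ensemble import AtomRecord, Conformer, Ensemble, write_pdb
from .errors import InputError
from .templates import RestraintTemplate, write_template
from . import templates as _templates

# Idealized peptide-backbone geometry (Angstrom / degrees).
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
         "N-H": 1.010, "CA-CB": 1.530, "CA-HA": 1.090}
_ANGLE = {"N-CA-C": 111.0, "CA-C-N": 116.2, "C-N-CA": 121.7,
          "CA-C-O": 120.8, "C-N-H": 119.3, "N-CA-CB": 110.5, "N-CA-HA": 109.5}

_AA1 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class TorsionSpec:
    """Backbone torsions for one peptide conformer, radians.

    ``phi[0]`` is unused (phi is undefined at the first residue); ``psi[-1]``
    only orients the final carbonyl oxygen. Omega defaults to pi (trans).
    """

    sequence: str
    phi: list[float]
    psi: list[float]
    omega: list[float] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.sequence)
        if n < 2:
            raise InputError("sequence must have at least 2 residues")
        bad = set(self.sequence.upper()) - _AA1
        if bad:
            raise InputError(f"invalid residue letter(s): {sorted(bad)}")
        if len(self.phi) != n or len(self.psi) != n:
            raise InputError("phi/psi lists must match sequence length")
        if not self.omega:
            self.omega = [math.pi] * n
        if len(self.omega) != n:
            raise InputError("omega list must match sequence length")
        for series in (self.phi, self.psi, self.omega):
            if not all(math.isfinite(v) for v in series):
                raise InputError("torsions must be finite")


def place_atom(a, b, c, bond: float, angle_deg: float, torsion: float) -> np.ndarray:
    """Place atom D bonded to C given the frame A-B-C.

    D lies at distance ``bond`` from C, with angle(B, C, D) = ``angle_deg``
    and dihedral(A, B, C, D) = ``torsion`` (radians).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = math.radians(angle_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(torsion),
        -bond * math.sin(theta) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_peptide(spec: TorsionSpec, label: str = "peptide", chain: str = "A") -> Conformer:
    """Build an all-atom conformer whose backbone torsions equal ``spec``.

    Recomputing phi on the result recovers ``spec.phi`` to ~1e-6 rad.
    """
    seq = spec.sequence.upper()
    coords: dict[tuple[int, str], np.ndarray] = {}

    # First residue seeds the frame: N at origin, CA on +x, C in the xy-plane.
    coords[(1, "N")] = np.zeros(3)
    coords[(1, "CA")] = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = math.radians(_ANGLE["N-CA-C"])
    coords[(1, "C")] = coords[(1, "CA")] + _BOND["CA-C"] * np.array(
        [math.cos(ang), math.sin(ang), 0.0]
    )

    for i in range(1, len(seq) + 1):
        n_i, ca_i, c_i = coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")]
        if i < len(seq):
            coords[(i + 1, "N")] = place_atom(
                n_i, ca_i, c_i, _BOND["C-N"], _ANGLE["CA-C-N"], spec.psi[i - 1]
            )
            coords[(i + 1, "CA")] = place_atom(
                ca_i, c_i, coords[(i + 1, "N")],
                _BOND["N-CA"], _ANGLE["C-N-CA"], spec.omega[i]
            )
            coords[(i + 1, "C")] = place_atom(
                c_i, coords[(i + 1, "N")], coords[(i + 1, "CA")],
                _BOND["CA-C"], _ANGLE["N-CA-C"], spec.phi[i]
            )
        # Carbonyl O, trans to the next N (psi + pi).
        coords[(i, "O")] = place_atom(
            n_i, ca_i, c_i, _BOND["C-O"], _ANGLE["CA-C-O"], spec.psi[i - 1] + math.pi
        )
        # Amide H (residues > 1, not proline): trans to CA across the peptide bond.
        if i > 1 and seq[i - 1] != "P":
            coords[(i, "H")] = place_atom(
                coords[(i - 1, "CA")], coords[(i - 1, "C")], n_i,
                _BOND["N-H"], _ANGLE["C-N-H"], spec.omega[i - 1] + math.pi
            )
        # HA and a CB stub off CA (no CB for glycine).
        coords[(i, "HA")] = place_atom(
            c_i, n_i, ca_i, _BOND["CA-HA"], _ANGLE["N-CA-HA"], math.radians(119.0)
        )
        if seq[i - 1] != "G":
            coords[(i, "CB")] = place_atom(
                c_i, n_i, ca_i, _BOND["CA-CB"], _ANGLE["N-CA-CB"], math.radians(-122.0)
            )

    atom_order = ("N", "CA", "C", "O", "H", "HA", "CB")
    atoms: list[AtomRecord] = []
    serial = 0
    for i in range(1, len(seq) + 1):
        resname = seq3(seq[i - 1]).upper()
        for name in atom_order:
            if (i, name) not in coords:
                continue
            serial += 1
            x, y, z = (float(v) for v in coords[(i, name)])
            atoms.append(AtomRecord(
                serial=serial, name=name, altloc=" ", resname=resname,
                chain=chain, resseq=i, icode="", x=x, y=y, z=z,
                element=name[0],
            ))
    return Conformer(label=label, chain=chain, atoms=atoms)


#: Default 12-residue generic coil sequence (no proline: every amide has an H).
DEFAULT_SEQUENCE = "ASDGKLNEQTVR"
#: Default uniform torsion-sampling windows (radians): a broad coil-like
#: region for phi, unrestricted psi.
PHI_RANGE = (math.radians(-170.0), math.radians(-50.0))
PSI_RANGE = (-math.pi, math.pi)


def sample_torsions(rng, sequence: str,
                    phi_range=PHI_RANGE, psi_range=PSI_RANGE) -> TorsionSpec:
    """Draw one conformer's torsions uniformly from the given windows."""
    n = len(sequence)
    phi = rng.uniform(*phi_range, size=n).tolist()
    psi = rng.uniform(*psi_range, size=n).tolist()
    return TorsionSpec(sequence=sequence, phi=phi, psi=psi)


def generate_ensemble(out_dir, n_conformers: int, seed: int,
                      sequence: str = DEFAULT_SEQUENCE,
                      phi_range=PHI_RANGE, psi_range=PSI_RANGE) -> Ensemble:
    """Write ``n_conformers`` torsion-sampled PDB files and return the ensemble.

    Deterministic for a fixed seed; filenames are zero-padded so lexicographic
    and numeric order coincide.
    """
    if n_conformers < 1:
        raise InputError("n_conformers must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_conformers - 1)))
    conformers = []
    for k in range(n_conformers):
        spec = sample_torsions(rng, sequence, phi_range, psi_range)
        label = f"conf_{k:0{width}d}"
        conformer = build_peptide(spec, label=label)
        write_pdb(conformer, out_dir / f"{label}.pdb")
        conformers.append(conformer)
    return Ensemble(conformers=conformers)


def generate_template(ensemble: Ensemble, datatype: str, n_rows: int,
                      seed: int, path) -> RestraintTemplate:
    """Write a template whose rows reference only atoms the ensemble has."""
    rng = np.random.default_rng(seed)
    conf = ensemble.conformers[0]
    residues = conf.residue_numbers()
    has_h = sorted(r for r in residues if (r, "H") in conf.index)

    rows = []
    if datatype == "pre":
        seen = set()
        while len(rows) < n_rows:
            r1, r2 = (int(v) for v in rng.choice(has_h, size=2, replace=False))
            if (r1, r2) in seen:
                continue
            seen.add((r1, r2))
            rows.append(_templates.PrePair(r1, "H", r2, "H"))
    elif datatype == "noe":
        while len(rows) < n_rows:
            r1, r2 = (int(v) for v in rng.choice(has_h, size=2, replace=False))
            alts1 = ("HA",) if rng.random() < 0.5 else ()
            alts2 = ("HA",) if rng.random() < 0.5 else ()
            rows.append(_templates.NoePair(r1, "H", alts1, r2, "H", alts2))
    elif datatype == "jc":
        eligible = [r for r in residues[1:]]
        pick = rng.choice(eligible, size=min(n_rows, len(eligible)), replace=False)
        rows = [_templates.JcRecord(int(r)) for r in sorted(pick)]
    elif datatype == "smfret":
        while len(rows) < n_rows:
            r1, r2 = sorted(int(v) for v in rng.choice(residues, size=2, replace=False))
            if r2 - r1 < 2:
                continue
            scale = round(float(rng.uniform(40.0, 60.0)), 1)
            rows.append(_templates.SmfretPair(r1, r2, scale))
    else:
        raise InputError(f"unknown datatype {datatype!r}")

    template = RestraintTemplate(datatype=datatype, rows=rows, source=str(path))
    write_template(template, path)
    return template
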