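"""Conformer-ensemble I/O.

An ensemble is a set of single-conformer all-atom PDB files, one structure
per file — the convention used by torsion-sampling generators of disordered
protein pools. This module reads and indexes those files, resolves atom
lookups (including common proton-name dialects such as H vs HN), and writes
conformers back out as PDB text.

Parsing is delegated to Biopython's ``Bio.PDB.PDBParser``; this module adds
the single-conformer semantics: first MODEL only, blank/'A' altlocs only,
one chain selected, and an index that maps ``(resseq, name)`` to exactly one
atom.
"""

from __future__ import annotations

import io
import logging
import tarfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio.PDB import PDBParser

from .errors import AmbiguousAtomError, InputError, MissingAtomError, MissingResidueError

logger = logging.getLogger(__name__)

_PARSER = PDBParser(QUIET=True)


@dataclass(frozen=True)
class AtomRecord:
    """One retained ATOM record, author numbering, coordinates in Angstrom."""

    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    x: float
    y: float
    z: float
    element: str

    @property
    def coord(self):
        import numpy as np

        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Conformer:
    """A single all-atom structure with an atom index on the selected chain.

    ``index`` maps ``(resseq, name)`` to the unique retained atom; building it
    raises :class:`AmbiguousAtomError` if two retained atoms collide.
    """

    label: str
    chain: str
    atoms: list[AtomRecord]
    index: dict[tuple[int, str], AtomRecord] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            for atom in self.atoms:
                key = (atom.resseq, atom.name)
                if key in self.index:
                    raise AmbiguousAtomError(key)
                self.index[key] = atom

    @property
    def sequence(self) -> dict[int, str]:
        """Author residue number -> 3-letter residue code."""
        seq: dict[int, str] = {}
        for atom in self.atoms:
            seq.setdefault(atom.resseq, atom.resname)
        return seq

    def residue_numbers(self) -> list[int]:
        return sorted(self.sequence)


@dataclass
class Ensemble:
    """Ordered list of conformers, lexicographic by source filename."""

    conformers: list[Conformer]

    def __post_init__(self):
        if not self.conformers:
            raise InputError("ensemble is empty")

    def __len__(self):
        return len(self.conformers)

    def __iter__(self) -> Iterator[Conformer]:
        return iter(self.conformers)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.conformers]


def _structure_to_conformer(structure, label: str, chain_id: str | None) -> Conformer:
    models = list(structure)
    if not models:
        raise InputError(f"{label}: no ATOM records")
    if len(models) > 1:
        logger.warning("%s: %d MODELs present, retaining MODEL 1 only", label, len(models))
    model = models[0]

    chains = list(model)
    if not chains:
        raise InputError(f"{label}: no ATOM records")
    if chain_id is None:
        if len(chains) > 1:
            logger.warning(
                "%s: multiple chains (%s) and no chain selected; using %r",
                label, ",".join(c.id for c in chains), chains[0].id,
            )
        chain = chains[0]
    else:
        matches = [c for c in chains if c.id == chain_id]
        if not matches:
            raise InputError(f"{label}: chain {chain_id!r} not present")
        chain = matches[0]

    atoms: list[AtomRecord] = []
    for residue in chain:
        hetflag, resseq, icode = residue.id
        if hetflag.strip():
            continue  # HETATM: out of scope
        for atom in residue.get_unpacked_list():
            altloc = atom.get_altloc()
            if altloc not in (" ", "A"):
                logger.info("%s: dropping altloc %r of %s/%d", label, altloc, atom.get_name(), resseq)
                continue
            x, y, z = (float(v) for v in atom.coord)
            atoms.append(
                AtomRecord(
                    serial=int(atom.get_serial_number() or 0),
                    name=atom.get_name(),
                    altloc=altloc,
                    resname=residue.get_resname().strip(),
                    chain=chain.id,
                    resseq=int(resseq),
                    icode=icode.strip(),
                    x=x, y=y, z=z,
                    element=(atom.element or "").strip(),
                )
            )
    if not atoms:
        raise InputError(f"{label}: no ATOM records retained")
    return Conformer(label=label, chain=chain.id, atoms=atoms)


def parse_pdb(path, chain: str | None = None) -> Conformer:
    """Parse one PDB file into a :class:`Conformer`.

    Multi-MODEL files contribute MODEL 1 only (a warning is logged); altlocs
    other than blank/'A' are dropped; one chain is retained (the first, or
    ``chain`` if given).
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"cannot read PDB file: {path}")
    label = path.stem
    try:
        structure = _PARSER.get_structure(label, str(path))
    except Exception as exc:  # Bio.PDB raises assorted types on mangled input
        raise InputError(f"{path}: unparseable PDB ({exc})") from exc
    return _structure_to_conformer(structure, label, chain)


def _iter_pdb_sources(source: Path):
    """Yield (label, open-text-handle) pairs sorted by filename."""
    if source.is_dir():
        paths = sorted(source.glob("*.pdb"), key=lambda p: p.name)
        for p in paths:
            yield p.stem, p.open("r")
    elif source.is_file() and (source.suffix in (".tar", ".tgz") or source.name.endswith(".tar.gz")):
        with tarfile.open(source) as tar:
            members = sorted(
                (m for m in tar.getmembers() if m.isfile() and m.name.endswith(".pdb")),
                key=lambda m: Path(m.name).name,
            )
            for m in members:
                raw = tar.extractfile(m)
                yield Path(m.name).stem, io.TextIOWrapper(raw)
    else:
        raise InputError(f"not a directory or PDB tar archive: {source}")


def load_ensemble(source, chain: str | None = None, strict_sequence: bool = False) -> Ensemble:
    """Load every ``*.pdb`` under a directory (or tar archive) as an ensemble.

    Conformers are ordered lexicographically by filename regardless of how the
    filesystem enumerates them. All conformers are checked for a consistent
    residue sequence on the selected chain; mismatches warn by default or
    raise when ``strict_sequence`` is set.
    """
    source = Path(source)
    conformers = []
    for label, handle in _iter_pdb_sources(source):
        with handle:
            try:
                structure = _PARSER.get_structure(label, handle)
            except Exception as exc:
                raise InputError(f"{label}: unparseable PDB ({exc})") from exc
        conformers.append(_structure_to_conformer(structure, label, chain))
    if not conformers:
        raise InputError(f"no PDB files found in {source}")

    reference = conformers[0].sequence
    offenders = [c.label for c in conformers[1:] if c.sequence != reference]
    if offenders:
        msg = f"sequence mismatch vs {conformers[0].label}: {', '.join(offenders)}"
        if strict_sequence:
            raise InputError(msg)
        logger.warning(msg)
    return Ensemble(conformers=conformers)


# ---------------------------------------------------------------------------
# Atom lookup with proton-name dialect fallback
# ---------------------------------------------------------------------------

# Amide proton: "H" (PDB v3) vs "HN" (older/CNS dialect), both directions.
_AMIDE_ALIASES = {"H": ("HN",), "HN": ("H",)}


def _fallback_names(name: str):
    """Candidate alternative spellings for a proton name, most specific first."""
    yield from _AMIDE_ALIASES.get(name, ())
    # Methylene/methyl numbering-shift dialects, e.g. HB2/HB3 vs HB1/HB2.
    if len(name) >= 2 and name[0] == "H" and name[-1].isdigit():
        stem, digit = name[:-1], int(name[-1])
        for alt in (digit - 1, digit + 1):
            if 1 <= alt <= 3:
                yield f"{stem}{alt}"


def select_atom(conformer: Conformer, resseq: int, name: str) -> AtomRecord:
    """Resolve one atom by residue number and name.

    An exact match wins; otherwise the proton-dialect fallback table is
    consulted (H<->HN, +-1 numbering shifts) and any substitution is logged.
    Pseudoatom names (e.g. "HB" for the HB* group) are *not* expanded here —
    that is NOE multi-assignment semantics, see :func:`expand_atom_names`.
    """
    if resseq not in conformer.sequence:
        raise MissingResidueError(resseq)
    record = conformer.index.get((resseq, name))
    if record is not None:
        return record
    for alt in _fallback_names(name):
        record = conformer.index.get((resseq, alt))
        if record is not None:
            logger.info("%s: atom %s/%d resolved via dialect fallback %s", conformer.label, name, resseq, alt)
            return record
    raise MissingAtomError(resseq, name)


def expand_atom_names(conformer: Conformer, resseq: int, name: str) -> list[AtomRecord]:
    """Resolve a (possibly pseudo) proton name to one or more atoms.

    Used for NOE multi-assignment: an unnumbered group name like "HB" expands
    to whichever of HB1/HB2/HB3 exist. A name that resolves directly (or via
    the single-atom fallback) yields exactly one atom.
    """
    try:
        return [select_atom(conformer, resseq, name)]
    except MissingAtomError:
        pass
    expanded = [
        conformer.index[(resseq, f"{name}{i}")]
        for i in (1, 2, 3)
        if (resseq, f"{name}{i}") in conformer.index
    ]
    if not expanded:
        raise MissingAtomError(resseq, name)
    logger.info("%s: pseudoatom %s/%d expanded to %d protons", conformer.label, name, resseq, len(expanded))
    return expanded


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _pdb_atom_name(name: str) -> str:
    # Columns 13-16: names shorter than 4 chars start at column 14 unless the
    # first character is a digit.
    if len(name) >= 4 or (name and name[0].isdigit()):
        return f"{name:<4.4s}"
    return f" {name:<3s}"


def write_pdb(conformer: Conformer, path) -> Path:
    """Serialize a conformer as fixed-column PDB ATOM records."""
    path = Path(path)
    lines = []
    for a in conformer.atoms:
        lines.append(
            f"ATOM  {a.serial:5d} {_pdb_atom_name(a.name)}{a.altloc or ' '}"
            f"{a.resname:>3s} {a.chain}{a.resseq:4d}{a.icode or ' '}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {a.element:>2s}\n"
        )
    lines.append("END\n")
    path.write_text("".join(lines))
    return path
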