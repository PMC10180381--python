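"""Cluster geometries: XYZ I/O, water-monomer partitioning, compactness ordering.

Structures are ordered lists of atoms with Cartesian coordinates in Å.
Clusters are sequenced by radius of gyration, the compactness proxy used to
order configurations from compressed to extended.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np

from .constants import ATOMIC_MASSES, RECOGNIZED_ELEMENTS
from .exceptions import CompositionError, MalformedFileError, PartitionError

__all__ = [
    "Atom",
    "Structure",
    "MonomerPartition",
    "read_xyz",
    "write_xyz",
    "partition_monomers",
    "extract_monomer",
    "radius_of_gyration",
    "sort_by_gyration",
]

DEFAULT_OH_CUTOFF = 1.3  # Å; covers distorted covalent O-H (~0.96) but not H-bonds (>=1.6)


@dataclass(frozen=True)
class Atom:
    """One atom: chemical symbol plus Cartesian position in Å."""

    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if self.element not in RECOGNIZED_ELEMENTS:
            raise MalformedFileError(f"unknown element symbol {self.element!r}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES[self.element]


@dataclass
class Structure:
    """One cluster configuration: an id, ordered atoms, and a free-text comment."""

    id: str
    atoms: list[Atom]
    comment: str = ""

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("a Structure needs at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) coordinate array in Å."""
        return np.array([a.position for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])


@dataclass(frozen=True)
class MonomerPartition:
    """Disjoint assignment of atom indices to water monomers.

    Each group is an (O, H, H) index triplet; groups jointly cover the
    structure's atoms.
    """

    groups: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        flat = [i for g in self.groups for i in g]
        if len(flat) != len(set(flat)):
            raise PartitionError("monomer groups are not disjoint")

    def __len__(self) -> int:
        return len(self.groups)


_KEYVAL_RE = re.compile(r"(\w+)=(\S+)")


def _parse_comment_tokens(comment: str) -> dict[str, str]:
    """Lenient key=value tokens on the comment line; unknown tokens are ignored."""
    return dict(_KEYVAL_RE.findall(comment))


def read_xyz(source: str | Path | TextIO) -> list[Structure]:
    """Read a plain or multi-frame XYZ file into a list of structures.

    The id of each frame defaults to ``frame_<k>`` (0-based) unless the
    comment line carries an ``id=<label>`` token.

    Raises
    ------
    MalformedFileError
        If an atom-count line is not an integer, a frame is truncated, an
        atom record does not have 4 fields, or an element is unknown.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        with open(source) as fh:
            lines = fh.read().splitlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = source.read().splitlines()

    structures: list[Structure] = []
    pos = 0
    frame = 0
    while pos < len(lines):
        if lines[pos].strip() == "" and all(l.strip() == "" for l in lines[pos:]):
            break  # trailing blank lines
        try:
            natoms = int(lines[pos].strip())
        except ValueError:
            raise MalformedFileError(
                f"frame {frame}: expected an atom count, got {lines[pos]!r}"
            ) from None
        if pos + 1 >= len(lines):
            raise MalformedFileError(f"frame {frame}: missing comment line")
        comment = lines[pos + 1]
        records = lines[pos + 2 : pos + 2 + natoms]
        if len(records) < natoms or any(r.strip() == "" for r in records):
            raise MalformedFileError(
                f"frame {frame}: atom count {natoms} does not match the records present"
            )
        atoms = []
        for rec in records:
            fields = rec.split()
            if len(fields) < 4:
                raise MalformedFileError(f"frame {frame}: bad atom record {rec!r}")
            sym = fields[0]
            if sym not in RECOGNIZED_ELEMENTS:
                raise MalformedFileError(f"frame {frame}: unknown element symbol {sym!r}")
            try:
                xyz = np.array([float(v) for v in fields[1:4]])
            except ValueError:
                raise MalformedFileError(
                    f"frame {frame}: non-numeric coordinate in {rec!r}"
                ) from None
            atoms.append(Atom(sym, xyz))
        tokens = _parse_comment_tokens(comment)
        structures.append(Structure(tokens.get("id", f"frame_{frame}"), atoms, comment))
        pos += 2 + natoms
        frame += 1
    return structures


def write_xyz(structures: Sequence[Structure] | Structure, dest: str | Path | TextIO) -> None:
    """Write structures as multi-frame XYZ, embedding ``id=`` on the comment line."""
    if isinstance(structures, Structure):
        structures = [structures]
    buf = io.StringIO()
    for s in structures:
        comment = s.comment
        if f"id={s.id}" not in comment:
            comment = (f"id={s.id} " + comment).strip()
        buf.write(f"{len(s)}\n{comment}\n")
        for a in s.atoms:
            x, y, z = a.position
            buf.write(f"{a.element} {x:.8f} {y:.8f} {z:.8f}\n")
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(buf.getvalue())
    else:
        dest.write(buf.getvalue())


def partition_monomers(s: Structure, oh_cutoff: float = DEFAULT_OH_CUTOFF) -> MonomerPartition:
    """Assign each hydrogen to its nearest oxygen, forming (O, H, H) monomers.

    Raises
    ------
    CompositionError
        If the structure contains elements other than O/H or the H:O ratio
        is not exactly 2.
    PartitionError
        If any oxygen does not receive exactly two hydrogens, or an assigned
        O-H distance exceeds ``oh_cutoff``.
    """
    elements = s.elements
    o_idx = [i for i, e in enumerate(elements) if e == "O"]
    h_idx = [i for i, e in enumerate(elements) if e == "H"]
    if len(o_idx) + len(h_idx) != len(elements):
        bad = sorted(set(elements) - {"O", "H"})
        raise CompositionError(f"non-water elements present: {bad}")
    if len(h_idx) != 2 * len(o_idx) or not o_idx:
        raise CompositionError(
            f"water stoichiometry requires 2 H per O, got {len(o_idx)} O / {len(h_idx)} H"
        )
    pos = s.positions
    # nearest-O assignment for every H
    assigned: dict[int, list[int]] = {o: [] for o in o_idx}
    offending: list[str] = []
    for h in h_idx:
        d = np.linalg.norm(pos[o_idx] - pos[h], axis=1)
        k = int(np.argmin(d))
        if d[k] > oh_cutoff:
            offending.append(f"H atom {h} is {d[k]:.3f} Å from its nearest O (cutoff {oh_cutoff})")
        assigned[o_idx[k]].append(h)
    for o, hs in assigned.items():
        if len(hs) != 2:
            offending.append(f"O atom {o} received {len(hs)} hydrogens")
    if offending:
        raise PartitionError("monomer partition failed: " + "; ".join(offending))
    groups = tuple((o, *sorted(assigned[o])) for o in o_idx)
    return MonomerPartition(groups)


def extract_monomer(s: Structure, group: tuple[int, int, int]) -> Structure:
    """Pull one (O, H, H) monomer out of a cluster as a standalone structure."""
    return Structure(f"{s.id}_mono_{group[0]}", [s.atoms[i] for i in group])


def radius_of_gyration(s: Structure, weighting: str = "mass") -> float:
    """RMS distance of atoms from the (weighted) centroid, in Å.

    ``weighting`` is ``"mass"`` (default), ``"uniform"``, or ``"oxygen"``
    (oxygen positions only, unit weights) — the convention used is recorded
    by callers so orderings remain comparable.
    """
    pos = s.positions
    if weighting == "mass":
        w = s.masses
    elif weighting == "uniform":
        w = np.ones(len(s))
    elif weighting == "oxygen":
        sel = [i for i, e in enumerate(s.elements) if e == "O"]
        if not sel:
            raise ValueError("oxygen weighting requires at least one O atom")
        pos = pos[sel]
        w = np.ones(len(sel))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    w = w / w.sum()
    centroid = w @ pos
    return float(np.sqrt(np.sum(w * np.sum((pos - centroid) ** 2, axis=1))))


def sort_by_gyration(
    structures: Iterable[Structure], weighting: str = "mass"
) -> list[Structure]:
    """Stable ascending sort by radius of gyration (compressed first)."""
    return sorted(structures, key=lambda s: radius_of_gyration(s, weighting))
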