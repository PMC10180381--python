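"""One-body-subtracted interaction-energy deviations.

For each cluster the quantity of interest is

    deviation = ΔE_total − ΔE_1-body

where ΔE_total is the method-minus-benchmark difference of total interaction
energies (each total referenced to n times the isolated monomer at the
reference gas-phase geometry), and ΔE_1-body is the same difference for the
sum of monomer distortion energies. Subtracting the one-body part isolates
the intermolecular interaction, which is the piece a dispersion correction
can actually improve.

The reference monomer geometry is OH = 0.95865 Å and HOH = 104.348°.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Protocol, Sequence, TextIO

import numpy as np
import pandas as pd

from .constants import HARTREE_TO_KCAL_PER_MOL
from .exceptions import DataError, MalformedFileError
from .geometry import Atom, MonomerPartition, Structure, extract_monomer, partition_monomers
from .dispersion import DispersionComponents, ScalingFactors, dispersion_energy

__all__ = [
    "ReferenceGeometry",
    "EnergyRecord",
    "DeviationRecord",
    "MonomerPotentialBackend",
    "HarmonicBackend",
    "monomer_internal_coordinates",
    "one_body_sum",
    "interaction_deviation",
    "apply_dispersion",
    "read_energy_table",
    "write_energy_table",
    "assemble_deviations",
]


@dataclass(frozen=True)
class ReferenceGeometry:
    """Gas-phase reference water monomer: O-H length (Å) and H-O-H angle (deg)."""

    r_oh: float = 0.95865
    theta_hoh: float = 104.348

    def __post_init__(self) -> None:
        if not self.r_oh > 0 or not 0 < self.theta_hoh < 180:
            raise ValueError("reference geometry out of range")

    def to_structure(self, structure_id: str = "ref_monomer") -> Structure:
        """Canonical Cartesian realization (O at origin, molecule in the xy plane)."""
        t = math.radians(self.theta_hoh)
        atoms = [
            Atom("O", np.zeros(3)),
            Atom("H", np.array([self.r_oh, 0.0, 0.0])),
            Atom("H", np.array([self.r_oh * math.cos(t), self.r_oh * math.sin(t), 0.0])),
        ]
        return Structure(structure_id, atoms)


@dataclass
class EnergyRecord:
    """Per-structure total (and optionally per-monomer) energies by method, kcal/mol."""

    structure_id: str
    n_monomers: int
    e_total: dict[str, float]
    e_ref_monomer: dict[str, float] = field(default_factory=dict)
    e_monomers: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_monomers < 1:
            raise DataError(f"{self.structure_id}: n_monomers must be >= 1")
        for method, energies in self.e_monomers.items():
            if len(energies) != self.n_monomers:
                raise DataError(
                    f"{self.structure_id}: {method} carries {len(energies)} monomer "
                    f"energies for n_monomers={self.n_monomers}"
                )


@dataclass(frozen=True)
class DeviationRecord:
    """Eq.-style bookkeeping for one cluster, all energies in kcal/mol."""

    structure_id: str
    n_monomers: int
    delta_total: float
    delta_onebody: float

    @property
    def deviation(self) -> float:
        return self.delta_total - self.delta_onebody


class MonomerPotentialBackend(Protocol):
    """Intramolecular potential of one water monomer, relative to its minimum."""

    def evaluate(self, monomer: Structure) -> float: ...


def monomer_internal_coordinates(monomer: Structure) -> tuple[float, float, float]:
    """(r_OH1, r_OH2 in Å, H-O-H angle in degrees) of an (O, H, H) structure."""
    elements = monomer.elements
    if sorted(elements) != ["H", "H", "O"]:
        raise DataError(f"not a water monomer: {elements}")
    o = elements.index("O")
    hs = [i for i in range(3) if i != o]
    pos = monomer.positions
    v1, v2 = pos[hs[0]] - pos[o], pos[hs[1]] - pos[o]
    r1, r2 = float(np.linalg.norm(v1)), float(np.linalg.norm(v2))
    cos_t = float(np.clip(np.dot(v1, v2) / (r1 * r2), -1.0, 1.0))
    return r1, r2, math.degrees(math.acos(cos_t))


@dataclass(frozen=True)
class HarmonicBackend:
    """Two-stretch/one-bend harmonic monomer potential about the reference geometry.

    Force constants default to values representative of the water molecule
    (stretch ~8.4 mdyn/Å ≈ 1200 kcal·mol⁻¹·Å⁻², bend ≈ 100 kcal·mol⁻¹·rad⁻²);
    the potential is zero, by construction, at the reference geometry.
    """

    reference: ReferenceGeometry = ReferenceGeometry()
    k_r: float = 1200.0  # kcal/mol/Å² per O-H stretch
    k_theta: float = 100.0  # kcal/mol/rad²

    def evaluate(self, monomer: Structure) -> float:
        r1, r2, theta = monomer_internal_coordinates(monomer)
        dr1 = r1 - self.reference.r_oh
        dr2 = r2 - self.reference.r_oh
        dth = math.radians(theta - self.reference.theta_hoh)
        return 0.5 * self.k_r * (dr1**2 + dr2**2) + 0.5 * self.k_theta * dth**2


def one_body_sum(
    s: Structure,
    p: MonomerPartition,
    backend: MonomerPotentialBackend,
    ref: ReferenceGeometry = ReferenceGeometry(),
) -> float:
    """Σ_i [E(monomer_i) − E(reference monomer)] under the backend, kcal/mol."""
    e_ref = backend.evaluate(ref.to_structure())
    total = 0.0
    for group in p.groups:
        try:
            total += backend.evaluate(extract_monomer(s, group)) - e_ref
        except Exception as exc:
            raise DataError(
                f"{s.id}: one-body backend failed on monomer {group}: {exc}"
            ) from exc
    return total


def interaction_deviation(
    rec: EnergyRecord,
    method: str,
    reference_method: str,
    onebody_method: float = 0.0,
    onebody_reference: float = 0.0,
) -> DeviationRecord:
    """Method-minus-benchmark deviation with the one-body part split out.

    delta_total = [E_m^n − n·E_m^ref] − [E_r^n − n·E_r^ref];
    delta_onebody = onebody_method − onebody_reference;
    the deviation property is their difference, exactly.
    """
    for m in (method, reference_method):
        if m not in rec.e_total:
            raise DataError(f"{rec.structure_id}: no total energy for method {m!r}")
    n = rec.n_monomers
    d_m = rec.e_total[method] - n * rec.e_ref_monomer.get(method, 0.0)
    d_r = rec.e_total[reference_method] - n * rec.e_ref_monomer.get(reference_method, 0.0)
    return DeviationRecord(
        structure_id=rec.structure_id,
        n_monomers=n,
        delta_total=d_m - d_r,
        delta_onebody=onebody_method - onebody_reference,
    )


def apply_dispersion(
    rec: DeviationRecord, comp: DispersionComponents, s: ScalingFactors
) -> DeviationRecord:
    """Shift the method total by −E_dis (the correction stabilizes the method side)."""
    if comp.structure_id != rec.structure_id:
        raise DataError(
            f"component table id {comp.structure_id!r} does not match record "
            f"{rec.structure_id!r}"
        )
    return replace(rec, delta_total=rec.delta_total - dispersion_energy(comp, s))


# ---------------------------------------------------------------- tables ---

_UNIT_FACTORS = {"kcal/mol": 1.0, "hartree": HARTREE_TO_KCAL_PER_MOL}


def _parse_units_header(text: str) -> float:
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("#") and "units:" in stripped:
            unit = stripped.split("units:", 1)[1].strip()
            if unit not in _UNIT_FACTORS:
                raise MalformedFileError(f"unknown energy unit {unit!r}")
            return _UNIT_FACTORS[unit]
        if stripped and not stripped.startswith("#"):
            break
    return 1.0  # kcal/mol by default


def read_energy_table(source: str | Path | TextIO) -> list[EnergyRecord]:
    """Parse a TSV energy table.

    Expected columns: ``structure_id``, ``n_monomers``, ``<method>__total``,
    optional ``<method>__ref_monomer`` and ``<method>__monomer_<i>`` columns.
    A leading ``# units: kcal/mol|hartree`` comment declares the energy unit;
    conversion happens here, once, at the boundary.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    factor = _parse_units_header(text)
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#")
    for col in ("structure_id", "n_monomers"):
        if col not in df.columns:
            raise MalformedFileError(f"energy table missing column {col!r}")
    total_methods = [c[: -len("__total")] for c in df.columns if c.endswith("__total")]
    if not total_methods:
        raise MalformedFileError("energy table carries no <method>__total column")
    mono_cols: dict[str, list[tuple[int, str]]] = {}
    for c in df.columns:
        if "__monomer_" in c:
            method, idx = c.rsplit("__monomer_", 1)
            mono_cols.setdefault(method, []).append((int(idx), c))
    for cols in mono_cols.values():
        cols.sort()

    records = []
    for row in df.itertuples(index=False):
        row_d = row._asdict()
        n = int(row_d["n_monomers"])
        e_total = {m: float(row_d[f"{m}__total"]) * factor for m in total_methods}
        e_ref = {
            m: float(row_d[f"{m}__ref_monomer"]) * factor
            for m in total_methods
            if f"{m}__ref_monomer" in row_d and pd.notna(row_d[f"{m}__ref_monomer"])
        }
        e_mono = {}
        for method, cols in mono_cols.items():
            vals = [row_d[c] for _, c in cols if pd.notna(row_d[c])]
            if vals:
                if len(vals) != n:
                    raise MalformedFileError(
                        f"{row_d['structure_id']}: {method} has {len(vals)} per-monomer "
                        f"energies but n_monomers={n}"
                    )
                e_mono[method] = [float(v) * factor for v in vals]
        records.append(
            EnergyRecord(str(row_d["structure_id"]), n, e_total, e_ref, e_mono)
        )
    return records


def write_energy_table(
    records: Sequence[EnergyRecord], dest: str | Path | TextIO, units: str = "kcal/mol"
) -> None:
    if units not in _UNIT_FACTORS:
        raise MalformedFileError(f"unknown energy unit {units!r}")
    inv = 1.0 / _UNIT_FACTORS[units]
    methods = sorted({m for r in records for m in r.e_total})
    max_mono = {
        m: max((r.n_monomers for r in records if m in r.e_monomers), default=0)
        for m in methods
    }
    rows = []
    for r in records:
        row: dict[str, object] = {"structure_id": r.structure_id, "n_monomers": r.n_monomers}
        for m in methods:
            if m in r.e_total:
                row[f"{m}__total"] = repr(r.e_total[m] * inv)
            if m in r.e_ref_monomer:
                row[f"{m}__ref_monomer"] = repr(r.e_ref_monomer[m] * inv)
            for i, v in enumerate(r.e_monomers.get(m, [])):
                row[f"{m}__monomer_{i}"] = repr(v * inv)
        rows.append(row)
    cols = ["structure_id", "n_monomers"]
    for m in methods:
        cols.append(f"{m}__total")
        if any(m in r.e_ref_monomer for r in records):
            cols.append(f"{m}__ref_monomer")
        cols.extend(f"{m}__monomer_{i}" for i in range(max_mono[m]))
    df = pd.DataFrame(rows).reindex(columns=cols)
    text = f"# units: {units}\n" + df.to_csv(sep="\t", index=False)
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)


def assemble_deviations(
    records: Sequence[EnergyRecord],
    method: str,
    reference_method: str,
    structures: Mapping[str, Structure] | None = None,
    backend: MonomerPotentialBackend | None = None,
    ref: ReferenceGeometry = ReferenceGeometry(),
    oh_cutoff: float = 1.3,
) -> list[DeviationRecord]:
    """Build one DeviationRecord per energy record.

    One-body sums are taken from per-monomer table columns when present for a
    method; otherwise they are evaluated with ``backend`` on the cluster
    geometry (which must then be supplied). The same backend may serve both
    methods — mirroring a benchmark-side one-body treatment computed from a
    shared intramolecular potential.
    """
    out = []
    for rec in records:
        onebody = {}
        for m in (method, reference_method):
            if m in rec.e_monomers:
                e_ref = rec.e_ref_monomer.get(m, 0.0)
                onebody[m] = sum(e - e_ref for e in rec.e_monomers[m])
            elif backend is not None:
                if structures is None or rec.structure_id not in structures:
                    raise DataError(
                        f"{rec.structure_id}: one-body backend needs the cluster geometry"
                    )
                s = structures[rec.structure_id]
                onebody[m] = one_body_sum(s, partition_monomers(s, oh_cutoff), backend, ref)
            else:
                onebody[m] = 0.0
        out.append(
            interaction_deviation(
                rec, method, reference_method, onebody[method], onebody[reference_method]
            )
        )
    return out
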