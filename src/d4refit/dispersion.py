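"""Two-body multipole dispersion energy with rational (Becke-Johnson) damping.

The dispersion correction is the damped pairwise sum

    E_dis = sum_{a<b} [ S6 * C6_ab / r^6 * f6(r) + S8 * C8_ab / r^8 * f8(r) ]

with f_n(r) = r^n / (r^n + (sr_n * R0_ab)^n) and R0_ab = a1*sqrt(C8/C6) + a2.
E_dis is stored positive and SUBTRACTED from the electronic energy; both
retained orders enter linearly in their scaling factors, so a structure's
dispersion energy at any (S6, S8) is the dot product of the factors with the
raw per-order sums evaluated once at unit scaling. That exact linearity is
what makes the scaling-factor refit a convex piecewise-linear problem.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
import yaml

from .constants import BOHR_TO_ANGSTROM, HARTREE_TO_KCAL_PER_MOL
from .exceptions import DataError, ParameterError, ValidationWarning
from .geometry import Structure

__all__ = [
    "ElementParams",
    "PairTable",
    "DampingParams",
    "ScalingFactors",
    "DispersionComponents",
    "FunctionalParams",
    "ParameterSet",
    "c8_from_c6",
    "damping_radius",
    "bj_damping",
    "cluster_components",
    "dispersion_energy",
    "read_component_table",
    "write_component_table",
    "load_parameters",
]


@dataclass(frozen=True)
class ElementParams:
    """Per-element multipole ratio Q_a (Å²) for the C8 recursion."""

    symbol: str
    q_factor: float

    def __post_init__(self) -> None:
        if not self.q_factor > 0:
            raise ParameterError(f"q_factor for {self.symbol} must be > 0")


@dataclass
class PairTable:
    """Symmetric C6 lookup, kcal·mol⁻¹·Å⁶, keyed by unordered element pair."""

    c6: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        norm: dict[tuple[str, str], float] = {}
        for (a, b), v in self.c6.items():
            if v < 0:
                raise ParameterError(f"C6({a},{b}) must be non-negative")
            norm[tuple(sorted((a, b)))] = float(v)
        self.c6 = norm

    def get(self, a: str, b: str) -> float:
        key = tuple(sorted((a, b)))
        if key not in self.c6:
            raise ParameterError(f"no C6 coefficient for element pair {key[0]}-{key[1]}")
        return self.c6[key]


@dataclass(frozen=True)
class DampingParams:
    """BJ damping constants: a1 (dimensionless), a2 (Å), sr8 (radius scaling)."""

    a1: float
    a2: float
    sr8: float = 1.0

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0 or not self.sr8 > 0:
            raise ParameterError("damping parameters require a1 >= 0, a2 >= 0, sr8 > 0")


@dataclass(frozen=True)
class ScalingFactors:
    """Dimensionless multipliers of the n=6 and n=8 dispersion orders."""

    s6: float
    s8: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.s6) and math.isfinite(self.s8)):
            raise ValueError("scaling factors must be finite")


@dataclass(frozen=True)
class DispersionComponents:
    """Raw per-order damped sums of one structure, evaluated at unit scaling."""

    structure_id: str
    e6_raw: float  # kcal/mol
    e8_raw: float  # kcal/mol


@dataclass(frozen=True)
class FunctionalParams:
    scaling: ScalingFactors
    damping: DampingParams


@dataclass
class ParameterSet:
    """Everything the evaluator needs: Q factors, C6 pairs, per-functional knobs."""

    elements: dict[str, ElementParams]
    pairs: PairTable
    functionals: dict[str, FunctionalParams]

    def functional(self, name: str) -> FunctionalParams:
        key = name.lower()
        if key not in self.functionals:
            raise ParameterError(
                f"functional {name!r} not in parameter file (have {sorted(self.functionals)})"
            )
        return self.functionals[key]


def c8_from_c6(c6: float, qa: float, qb: float) -> float:
    """Recursion for the n=8 coefficient: C8 = 3 · C6 · √(Q_a·Q_b)."""
    if c6 < 0:
        raise ValueError("C6 must be non-negative")
    if qa <= 0 or qb <= 0:
        raise ValueError("Q factors must be positive")
    return 3.0 * c6 * math.sqrt(qa * qb)


def damping_radius(c6: float, c8: float, d: DampingParams) -> float:
    """Pair critical radius R0 = a1·√(C8/C6) + a2 (Å)."""
    if c6 > 0:
        return d.a1 * math.sqrt(c8 / c6) + d.a2
    return d.a2


def bj_damping(r: float, order: int, c6: float, c8: float, d: DampingParams) -> float:
    """Rational damping f_n(r) = r^n / (r^n + (sr_n·R0)^n), in [0, 1]."""
    if r <= 0:
        raise ValueError("interatomic distance must be positive")
    if order not in (6, 8):
        raise ValueError("only orders 6 and 8 are retained")
    sr = 1.0 if order == 6 else d.sr8
    r0 = sr * damping_radius(c6, c8, d)
    rn = r**order
    return rn / (rn + r0**order)


def cluster_components(
    s: Structure,
    pt: PairTable,
    ep: Mapping[str, ElementParams],
    d: DampingParams,
) -> DispersionComponents:
    """Damped pairwise sums over distinct atom pairs (a<b) at unit scaling.

    Raises :class:`ParameterError` when an element or pair coefficient is
    missing, naming the offender.
    """
    elements = s.elements
    for e in set(elements):
        if e not in ep:
            raise ParameterError(f"no element parameters for {e}")
    pos = s.positions
    n = len(s)
    e6 = 0.0
    e8 = 0.0
    for a in range(n):
        for b in range(a + 1, n):
            r = float(np.linalg.norm(pos[a] - pos[b]))
            c6 = pt.get(elements[a], elements[b])
            c8 = c8_from_c6(c6, ep[elements[a]].q_factor, ep[elements[b]].q_factor)
            e6 += c6 / r**6 * bj_damping(r, 6, c6, c8, d)
            e8 += c8 / r**8 * bj_damping(r, 8, c6, c8, d)
    return DispersionComponents(s.id, e6, e8)


def dispersion_energy(comp: DispersionComponents, s: ScalingFactors) -> float:
    """E_dis(S6, S8) = S6·e6_raw + S8·e8_raw — exactly linear in the factors."""
    return s.s6 * comp.e6_raw + s.s8 * comp.e8_raw


# ---------------------------------------------------------------- tables ---

_COMPONENT_COLUMNS = ["structure_id", "e6_raw", "e8_raw"]


def write_component_table(
    components: Sequence[DispersionComponents], dest: str | Path | TextIO
) -> None:
    df = pd.DataFrame(
        {
            "structure_id": [c.structure_id for c in components],
            "e6_raw": [repr(c.e6_raw) for c in components],
            "e8_raw": [repr(c.e8_raw) for c in components],
        }
    )
    text = "# units: kcal/mol\n" + df.to_csv(sep="\t", index=False)
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)


def read_component_table(source: str | Path | TextIO) -> list[DispersionComponents]:
    """Parse a TSV of per-structure raw components (columns structure_id, e6_raw, e8_raw).

    Negative raw components are physically impossible for damped sums of
    positive terms and trigger a :class:`ValidationWarning`, not a failure,
    since external codes may apply different sign conventions.
    """
    if isinstance(source, (str, Path)):
        buf: TextIO = io.StringIO(Path(source).read_text())
    else:
        buf = source
    try:
        df = pd.read_csv(buf, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"unreadable component table: {exc}") from exc
    missing = [c for c in _COMPONENT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"component table missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        e6, e8 = float(row.e6_raw), float(row.e8_raw)
        if e6 < 0 or e8 < 0:
            warnings.warn(
                f"structure {row.structure_id}: negative raw component", ValidationWarning
            )
        out.append(DispersionComponents(str(row.structure_id), e6, e8))
    return out


# ------------------------------------------------------------ parameters ---

_C6_AU_TO_KCAL_A6 = HARTREE_TO_KCAL_PER_MOL * BOHR_TO_ANGSTROM**6


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    """Load a parameter file, converting declared units to kcal/mol and Å.

    Without ``path`` the packaged water (H/O) parameter set is used.
    """
    if path is None:
        text = resources.files("d4refit.data").joinpath("d4_params.yaml").read_text()
    else:
        text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ParameterError(f"unparsable parameter file: {exc}") from exc
    for section in ("units", "elements", "pairs", "functionals"):
        if section not in raw:
            raise ParameterError(f"parameter file missing section {section!r}")
    units = raw["units"]
    c6_scale = {"hartree_bohr6": _C6_AU_TO_KCAL_A6, "kcalmol_angstrom6": 1.0}
    q_scale = {"bohr2": BOHR_TO_ANGSTROM**2, "angstrom2": 1.0}
    a2_scale = {"bohr": BOHR_TO_ANGSTROM, "angstrom": 1.0}
    try:
        fc6 = c6_scale[units.get("c6", "kcalmol_angstrom6")]
        fq = q_scale[units.get("q_factor", "angstrom2")]
        fa2 = a2_scale[units.get("a2", "angstrom")]
    except KeyError as exc:
        raise ParameterError(f"unknown unit declaration {exc}") from None

    elements = {
        sym: ElementParams(sym, float(entry["q_factor"]) * fq)
        for sym, entry in raw["elements"].items()
    }
    pairs = {}
    for key, val in raw["pairs"].items():
        parts = key.split("-")
        if len(parts) != 2:
            raise ParameterError(f"bad pair key {key!r} (expected 'A-B')")
        pairs[(parts[0], parts[1])] = float(val) * fc6
    functionals = {}
    for name, entry in raw["functionals"].items():
        try:
            functionals[name.lower()] = FunctionalParams(
                ScalingFactors(float(entry["s6"]), float(entry["s8"])),
                DampingParams(float(entry["a1"]), float(entry["a2"]) * fa2,
                              float(entry.get("sr8", 1.0))),
            )
        except KeyError as exc:
            raise ParameterError(f"functional {name!r} missing key {exc}") from None
    return ParameterSet(elements, PairTable(pairs), functionals)
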