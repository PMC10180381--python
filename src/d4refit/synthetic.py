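"""Synthetic water-cluster ensembles with known ground-truth scaling factors.

The generator emulates ensembles of non-equilibrium (H2O)n clusters of
variable size and compactness: oxygens placed by rejection sampling with a
minimum O-O separation, rigid monomers built at the gas-phase reference
geometry, randomly oriented, then distorted by Gaussian perturbations of the
two O-H lengths and the bend angle. The mock energy tables are constructed
so that the benchmark-minus-method gap, after one-body subtraction, is a
known linear function of the dispersion components plus optional noise —
which makes every downstream stage (deviation assembly, statistics, the
scaling-factor refit) testable against an exact answer.

Nothing here attempts thermodynamically realistic sampling; the base
interaction model cancels exactly in the deviation construction and only
sets realistic magnitudes (tens of kcal/mol per cluster).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .dispersion import (
    DampingParams,
    DispersionComponents,
    ElementParams,
    PairTable,
    ParameterSet,
    cluster_components,
    write_component_table,
)
from .exceptions import GenerationError
from .geometry import Atom, MonomerPartition, Structure, partition_monomers, write_xyz
from .interaction import EnergyRecord, HarmonicBackend, ReferenceGeometry, write_energy_table

__all__ = [
    "ClusterGenSpec",
    "MockEnergySpec",
    "SyntheticDataset",
    "gen_cluster",
    "gen_dataset",
    "ladder_specs",
    "mock_base_energy",
    "write_dataset",
]

#: Per-monomer noise scale emulating the benchmark's stochastic error
#: (~0.1 kcal/mol per monomer).
DEFAULT_NOISE_PER_MONOMER = 0.1


@dataclass(frozen=True)
class ClusterGenSpec:
    """Recipe for one (H2O)n configuration.

    Distortion defaults (σ_r = 0.02 Å, σ_θ = 2°) produce visibly
    non-equilibrium monomers with one-body energies of a few tenths of
    kcal/mol — the scale at which one-body subtraction matters.
    """

    n_monomers: int
    box_side: float  # Å
    min_oo: float = 2.5  # Å
    distort_sigma_r: float = 0.02  # Å
    distort_sigma_theta: float = 2.0  # degrees
    seed: int = 0
    structure_id: str = ""

    def __post_init__(self) -> None:
        if self.n_monomers < 1 or self.min_oo <= 0 or self.box_side <= 0:
            raise GenerationError("invalid cluster generation spec")


@dataclass(frozen=True)
class MockEnergySpec:
    """Ground truth for the mock energy tables.

    ``noise_sigma`` is the per-cluster Gaussian noise; with
    ``noise_per_monomer`` set (the default) the actual σ for an n-mer is
    ``noise_sigma * n``, mirroring a stochastic benchmark whose error grows
    with system size.
    """

    s6_true: float
    s8_true: float
    base_model: str = "lj"
    noise_sigma: float = DEFAULT_NOISE_PER_MONOMER
    noise_per_monomer: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise GenerationError("noise_sigma must be non-negative")

    def sigma_for(self, n_monomers: int) -> float:
        return self.noise_sigma * (n_monomers if self.noise_per_monomer else 1.0)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _monomer_atoms(
    center: np.ndarray,
    rotation: np.ndarray,
    r1: float,
    r2: float,
    theta_deg: float,
) -> list[Atom]:
    t = math.radians(theta_deg)
    local = np.array(
        [
            [0.0, 0.0, 0.0],
            [r1, 0.0, 0.0],
            [r2 * math.cos(t), r2 * math.sin(t), 0.0],
        ]
    )
    placed = local @ rotation.T + center
    return [Atom("O", placed[0]), Atom("H", placed[1]), Atom("H", placed[2])]


def gen_cluster(spec: ClusterGenSpec, ref: ReferenceGeometry = ReferenceGeometry()) -> Structure:
    """Generate one cluster; a pure function of the spec (seed included).

    Oxygen sites are drawn uniformly in the box and rejected until all O-O
    distances are at least ``min_oo``; a bounded number of restarts guards
    against infeasible (too dense) specs.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_monomers
    centers: list[np.ndarray] | None = None
    for _ in range(200):  # whole-configuration restarts
        trial: list[np.ndarray] = []
        ok = True
        for _ in range(n):
            for _ in range(2000):
                cand = rng.uniform(0.0, spec.box_side, size=3)
                if all(np.linalg.norm(cand - c) >= spec.min_oo for c in trial):
                    trial.append(cand)
                    break
            else:
                ok = False
                break
        if ok:
            centers = trial
            break
    if centers is None:
        raise GenerationError(
            f"could not place {n} oxygens with min O-O {spec.min_oo} Å in a "
            f"{spec.box_side} Å box; increase box_side"
        )
    atoms: list[Atom] = []
    for c in centers:
        rot = _random_rotation(rng)
        r1 = ref.r_oh + rng.normal(0.0, spec.distort_sigma_r) if spec.distort_sigma_r else ref.r_oh
        r2 = ref.r_oh + rng.normal(0.0, spec.distort_sigma_r) if spec.distort_sigma_r else ref.r_oh
        th = (
            ref.theta_hoh + rng.normal(0.0, spec.distort_sigma_theta)
            if spec.distort_sigma_theta
            else ref.theta_hoh
        )
        atoms.extend(_monomer_atoms(c, rot, r1, r2, th))
    sid = spec.structure_id or f"w{n}_seed{spec.seed}"
    return Structure(sid, atoms, comment=f"id={sid} n={n}")


def mock_base_energy(s: Structure, p: MonomerPartition) -> float:
    """Additive O-O pair interaction standing in for hydrogen bonding.

    Lennard-Jones-like well (ε = 5 kcal/mol, r_min = 2.9 Å) summed over
    oxygen pairs. The exact form is irrelevant to the refit protocol — it
    cancels in the method-minus-benchmark deviation — and only sets cluster
    binding energies of realistic magnitude.
    """
    eps, rmin = 5.0, 2.9
    o_pos = s.positions[[g[0] for g in p.groups]]
    e = 0.0
    for i in range(len(o_pos)):
        for j in range(i + 1, len(o_pos)):
            x = rmin / float(np.linalg.norm(o_pos[i] - o_pos[j]))
            e += eps * (x**12 - 2 * x**6)
    return e


@dataclass
class SyntheticDataset:
    """Everything a pipeline run needs, plus the ground truth that made it."""

    structures: list[Structure]
    partitions: list[MonomerPartition]
    energy_records: list[EnergyRecord]
    components: list[DispersionComponents]
    ground_truth: dict

    method: str = "dft"
    reference_method: str = "mc"


def gen_dataset(
    specs: Sequence[ClusterGenSpec],
    mock: MockEnergySpec,
    params: ParameterSet,
    functional: str = "b3lyp",
    ref: ReferenceGeometry = ReferenceGeometry(),
    method: str = "dft",
    reference_method: str = "mc",
) -> SyntheticDataset:
    """Generate structures plus mock energy and component tables.

    The benchmark total is constructed as
    ``base + Σ onebody − (s6_true·e6_raw + s8_true·e8_raw) + noise`` and the
    uncorrected method total as ``base + Σ onebody``, so the pre-dispersion
    deviation of every cluster is exactly
    ``s6_true·e6_raw + s8_true·e8_raw − noise``: the refit must recover the
    true factors, exactly at zero noise.
    """
    damping = params.functional(functional).damping
    backend = HarmonicBackend(ref)
    noise_rng = np.random.default_rng(mock.seed)
    structures, partitions, records, comps = [], [], [], []
    truth_rows = []
    for spec in specs:
        s = gen_cluster(spec, ref)
        p = partition_monomers(s)
        comp = cluster_components(s, params.pairs, params.elements, damping)
        onebody = [
            backend.evaluate(Structure("m", [s.atoms[i] for i in g])) for g in p.groups
        ]
        base = mock_base_energy(s, p)
        disp_true = mock.s6_true * comp.e6_raw + mock.s8_true * comp.e8_raw
        noise = float(noise_rng.normal(0.0, mock.sigma_for(spec.n_monomers)))
        e_method = base + sum(onebody)
        e_reference = base + sum(onebody) - disp_true + noise
        records.append(
            EnergyRecord(
                structure_id=s.id,
                n_monomers=spec.n_monomers,
                e_total={method: e_method, reference_method: e_reference},
                e_ref_monomer={method: 0.0, reference_method: 0.0},
                e_monomers={method: list(onebody), reference_method: list(onebody)},
            )
        )
        structures.append(s)
        partitions.append(p)
        comps.append(comp)
        truth_rows.append(
            {
                "structure_id": s.id,
                "n_monomers": spec.n_monomers,
                "e6_raw": comp.e6_raw,
                "e8_raw": comp.e8_raw,
                "noise": noise,
                "deviation_pre_dispersion": disp_true - noise,
            }
        )
    ground_truth = {
        "s6_true": mock.s6_true,
        "s8_true": mock.s8_true,
        "noise_sigma": mock.noise_sigma,
        "noise_per_monomer": mock.noise_per_monomer,
        "seed": mock.seed,
        "functional": functional,
        "per_structure": truth_rows,
    }
    return SyntheticDataset(structures, partitions, records, comps, ground_truth,
                            method, reference_method)


def ladder_specs(
    sizes: Sequence[int],
    n_per_size: int,
    seed: int,
    min_oo: float = 2.5,
    distort_sigma_r: float = 0.02,
    distort_sigma_theta: float = 2.0,
) -> list[ClusterGenSpec]:
    """Specs spanning the requested sizes with a compressed-to-extended spread.

    The box side scales as n^(1/3) (constant monomer density at fixed packing
    factor) while the packing factor sweeps from dense to loose across the
    configurations of each size, so every size yields a gyration ladder.
    """
    if not sizes:
        raise GenerationError("sizes must be non-empty")
    packing = np.linspace(2.9, 3.9, n_per_size) if n_per_size > 1 else np.array([3.4])
    specs = []
    k = 0
    for n in sizes:
        for j in range(n_per_size):
            spec_seed = (seed * 1000003 + k) % 2**31  # distinct, deterministic
            specs.append(
                ClusterGenSpec(
                    n_monomers=n,
                    box_side=float(packing[j] * n ** (1.0 / 3.0)),
                    min_oo=min_oo,
                    distort_sigma_r=distort_sigma_r,
                    distort_sigma_theta=distort_sigma_theta,
                    seed=spec_seed,
                    structure_id=f"w{n}_{j:03d}",
                )
            )
            k += 1
    return specs


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit the XYZ/TSV/JSON dialects consumed by the rest of the pipeline."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "structures": out / "clusters.xyz",
        "energies": out / "energies.tsv",
        "components": out / "components.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_xyz(ds.structures, paths["structures"])
    write_energy_table(ds.energy_records, paths["energies"])
    write_component_table(ds.components, paths["components"])
    paths["ground_truth"].write_text(json.dumps(ds.ground_truth, indent=2) + "\n")
    return paths
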