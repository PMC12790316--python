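"""Steric and electronic molecular descriptors and their ensemble aggregation.

The three descriptors of the final affinity model are

* ``epsilon_homo`` -- energy of the highest occupied molecular orbital
  (Hartree); a higher (less negative) value indicates a more easily
  donated electron pair, favoring bond formation with CO2,
* ``site_dipole`` -- magnitude of the Hirshfeld atomic dipole at the
  carbanionic site CA (atomic units); a larger value indicates stronger
  electrostatic attraction of the incoming CO2,
* ``buried_b1`` -- buried Sterimol B1 at CA averaged over the two
  C1/C2 axes (Angstrom); local steric bulk shielding the adduct.

Each descriptor is collected per conformer and aggregated four ways
over the ensemble: minimum, maximum, Boltzmann-weighted average, and
the value of the lowest-energy conformer.

Sterimol parameters (Verloop's L, B1, B5) are computed from scratch:
van der Waals spheres projected onto the attachment axis (L) and onto
directions in the perpendicular plane (B1 = minimal width, B5 = maximal
width).  The perpendicular direction search uses a coarse angular grid
with golden-section refinement around every local optimum; a fine-grid
brute-force scan serves as the test oracle elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import json

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    DegenerateGeometryError,
    GeometryError,
    InputError,
)
from .qm_interface import QMResult
from .structures import ConformerEnsemble, NucleophileRecord
from .units import HARTREE_TO_KCAL, KB_HARTREE, ROOM_TEMPERATURE

__all__ = [
    "BONDI_RADII",
    "radii_for",
    "SterimolValues",
    "SiteB1",
    "EnsembleDescriptor",
    "DescriptorTable",
    "boltzmann_weights",
    "sterimol",
    "buried_sterimol",
    "site_b1",
    "aggregate",
    "co2_affinity",
    "build_descriptor_table",
    "GUARANTEED_DESCRIPTORS",
    "AGGREGATIONS",
    "DEFAULT_BURIED_RADIUS",
]

# Bondi (1964) van der Waals radii, Angstrom.  Configurable via `radii_for`.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "He": 1.40,
    "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "Ne": 1.54,
    "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Ar": 1.88,
    "As": 1.85, "Se": 1.90, "Br": 1.85, "Kr": 2.02,
    "Te": 2.06, "I": 1.98, "Xe": 2.16,
    "Li": 1.82, "Na": 2.27, "K": 2.75,
}

#: Sphere radius for the buried-Sterimol exclusion, Angstrom.
DEFAULT_BURIED_RADIUS = 5.5
#: Coarse direction-search step, degrees.
DEFAULT_ANGULAR_STEP = 1.0

AGGREGATIONS = ("min", "max", "boltz", "lowE")
GUARANTEED_DESCRIPTORS = ("epsilon_homo", "site_dipole", "buried_b1")


def radii_for(elements: Sequence[str], table: Mapping[str, float] | None = None) -> np.ndarray:
    """Van der Waals radii for an element list (Bondi set by default)."""
    table = BONDI_RADII if table is None else table
    try:
        return np.array([table[e] for e in elements], float)
    except KeyError as exc:
        raise InputError(f"no van der Waals radius tabulated for {exc}") from exc


@dataclass(frozen=True)
class SterimolValues:
    """Verloop steric parameters about one attachment axis, Angstrom."""

    L: float
    B1: float
    B5: float
    axis: tuple[int, int]  # (attach_index, axis_index)
    buried_radius: float | None = None

    def __post_init__(self):
        if self.B1 > self.B5 + 1e-12:
            raise GeometryError("B1 must not exceed B5")


@dataclass(frozen=True)
class SiteB1:
    """Buried B1 at CA, averaged over the CA->C1 and CA->C2 axes."""

    value: float
    b1_c1: float
    b1_c2: float


@dataclass(frozen=True)
class EnsembleDescriptor:
    """Four ensemble aggregations of one per-conformer descriptor."""

    name: str
    min: float
    max: float
    boltz: float
    lowE: float
    units: str = ""

    def __post_init__(self):
        eps = 1e-9 * max(1.0, abs(self.min), abs(self.max))
        if not (self.min - eps <= self.boltz <= self.max + eps):
            raise ValueError("Boltzmann average outside [min, max]")
        if not (self.min - eps <= self.lowE <= self.max + eps):
            raise ValueError("lowE value outside [min, max]")


def boltzmann_weights(
    energies: Sequence[float], temperature: float = ROOM_TEMPERATURE
) -> np.ndarray:
    """Boltzmann weights of conformer energies (Hartree) at ``temperature``.

    w_i = exp(-(E_i - E_min)/kT) / sum_j exp(-(E_j - E_min)/kT); the
    shift by the minimum is applied for numerical stability.  Weights
    sum to 1 within 1e-12.
    """
    energies = np.asarray(energies, float)
    if energies.size == 0:
        raise InputError("empty energy list")
    if temperature <= 0:
        raise InputError("temperature must be > 0 K")
    shifted = energies - energies.min()
    w = np.exp(-shifted / (KB_HARTREE * temperature))
    return w / w.sum()


# --------------------------------------------------------------------------
# Sterimol


def _golden_refine(f: Callable[[float], float], lo: float, hi: float, tol: float = 1e-10) -> float:
    """Golden-section minimum of ``f`` on [lo, hi]; returns f at the optimum."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return min(fc, fd)


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis of the plane perpendicular to u."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, helper)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return v, w


def _sterimol_core(
    origin: np.ndarray,
    u: np.ndarray,
    points: np.ndarray,
    radii: np.ndarray,
    angular_step: float,
) -> tuple[float, float, float]:
    """L, B1, B5 of van der Waals spheres about axis ``u`` through ``origin``."""
    rel = points - origin
    proj = rel @ u
    length = float((proj + radii).max())

    v, w = _perp_basis(u)
    a = rel @ v  # perpendicular components
    b = rel @ w

    def width(theta: float) -> float:
        return float((a * np.cos(theta) + b * np.sin(theta) + radii).max())

    n_grid = max(int(round(360.0 / angular_step)), 8)
    thetas = np.linspace(0.0, 2.0 * np.pi, n_grid, endpoint=False)
    # vectorized coarse scan
    widths = (
        a[None, :] * np.cos(thetas)[:, None]
        + b[None, :] * np.sin(thetas)[:, None]
        + radii[None, :]
    ).max(axis=1)

    step = 2.0 * np.pi / n_grid
    # refine every local optimum of the periodic coarse profile
    left = np.roll(widths, 1)
    right = np.roll(widths, -1)
    b1 = np.inf
    for i in np.nonzero((widths <= left) & (widths <= right))[0]:
        b1 = min(b1, _golden_refine(width, thetas[i] - step, thetas[i] + step))
    b5 = -np.inf
    neg = lambda t: -width(t)
    for i in np.nonzero((widths >= left) & (widths >= right))[0]:
        b5 = max(b5, -_golden_refine(neg, thetas[i] - step, thetas[i] + step))
    return length, float(b1), float(b5)


def sterimol(
    coordinates: np.ndarray,
    radii: Sequence[float],
    attach_index: int,
    axis_index: int,
    angular_step: float = DEFAULT_ANGULAR_STEP,
    l_correction: float = 0.0,
) -> SterimolValues:
    """Sterimol L, B1, B5 about the attach -> axis direction.

    All atoms except the attachment atom contribute their van der Waals
    spheres.  ``l_correction`` adds the historical +0.40 Angstrom CPK
    offset to L when requested; the default omits it, as modern
    implementations do.  The result is invariant under rigid motion.
    """
    coords = np.asarray(coordinates, float)
    radii = np.asarray(radii, float)
    if attach_index == axis_index:
        raise GeometryError("attach and axis atoms must differ")
    origin = coords[attach_index]
    direction = coords[axis_index] - origin
    norm = np.linalg.norm(direction)
    if norm < 1e-8:
        raise GeometryError("attach and axis atoms are coincident")
    u = direction / norm

    mask = np.arange(len(coords)) != attach_index
    length, b1, b5 = _sterimol_core(
        origin, u, coords[mask], radii[mask], angular_step
    )
    return SterimolValues(
        L=length + l_correction, B1=b1, B5=b5, axis=(attach_index, axis_index)
    )


def buried_sterimol(
    coordinates: np.ndarray,
    radii: Sequence[float],
    attach_index: int,
    axis_index: int,
    buried_radius: float = DEFAULT_BURIED_RADIUS,
    angular_step: float = DEFAULT_ANGULAR_STEP,
) -> SterimolValues:
    """Sterimol restricted to atoms within ``buried_radius`` of the attach atom.

    Atoms whose center lies farther than the sphere radius contribute
    nothing (whole-atom exclusion); when every atom fits inside the
    sphere the result equals the plain Sterimol.  The axis direction is
    always taken from the original axis atom, inside the sphere or not.
    """
    if buried_radius <= 0:
        raise GeometryError("buried_radius must be > 0")
    coords = np.asarray(coordinates, float)
    radii = np.asarray(radii, float)
    if attach_index == axis_index:
        raise GeometryError("attach and axis atoms must differ")
    origin = coords[attach_index]
    direction = coords[axis_index] - origin
    norm = np.linalg.norm(direction)
    if norm < 1e-8:
        raise GeometryError("attach and axis atoms are coincident")
    u = direction / norm

    dist = np.linalg.norm(coords - origin, axis=1)
    mask = (np.arange(len(coords)) != attach_index) & (dist <= buried_radius)
    if not mask.any():
        raise DegenerateGeometryError(
            f"no atoms within {buried_radius} A of the attach atom"
        )
    length, b1, b5 = _sterimol_core(
        origin, u, coords[mask], radii[mask], angular_step
    )
    return SterimolValues(
        L=length,
        B1=b1,
        B5=b5,
        axis=(attach_index, axis_index),
        buried_radius=buried_radius,
    )


def site_b1(
    coordinates: np.ndarray,
    radii: Sequence[float],
    record: NucleophileRecord,
    buried_radius: float = DEFAULT_BURIED_RADIUS,
    angular_step: float = DEFAULT_ANGULAR_STEP,
) -> SiteB1:
    """Buried B1 at the carbanionic site, averaged over both C-neighbor axes.

    The pattern defines two equally valid attachment axes (CA -> C1 and
    CA -> C2); the site descriptor is their arithmetic mean, with both
    per-axis values retained.
    """
    b1_c1 = buried_sterimol(
        coordinates, radii, record.ca_index, record.c1_index,
        buried_radius=buried_radius, angular_step=angular_step,
    ).B1
    b1_c2 = buried_sterimol(
        coordinates, radii, record.ca_index, record.c2_index,
        buried_radius=buried_radius, angular_step=angular_step,
    ).B1
    return SiteB1(value=0.5 * (b1_c1 + b1_c2), b1_c1=b1_c1, b1_c2=b1_c2)


# --------------------------------------------------------------------------
# Ensemble aggregation and the response


def aggregate(
    values: Sequence[float],
    energies: Sequence[float],
    temperature: float = ROOM_TEMPERATURE,
    name: str = "",
    units: str = "",
) -> EnsembleDescriptor:
    """Aggregate per-conformer values into min/max/Boltz/lowE.

    ``lowE`` is the value of the conformer with minimal energy (ties
    resolved to the lowest index); ``boltz`` the Boltzmann-weighted
    average at ``temperature``.
    """
    values = np.asarray(values, float)
    energies = np.asarray(energies, float)
    if values.shape != energies.shape:
        raise InputError(
            f"values ({values.shape}) and energies ({energies.shape}) differ in length"
        )
    w = boltzmann_weights(energies, temperature)
    return EnsembleDescriptor(
        name=name,
        min=float(values.min()),
        max=float(values.max()),
        boltz=float(w @ values),
        lowE=float(values[int(np.argmin(energies))]),
        units=units,
    )


def co2_affinity(
    g_adduct: float,
    g_nucleophile: float,
    g_co2: float,
    settings_hashes: Sequence[str] | None = None,
) -> float:
    """CO2 affinity: negative Gibbs free reaction energy, kcal/mol.

    CO2A = -(G_adduct - G_nucleophile - G_CO2) * 627.509474.  Positive
    values indicate a thermodynamically stable carboxylate adduct.  All
    three free energies must come from the same settings preset; pass
    their hashes to enforce it.
    """
    if settings_hashes is not None:
        distinct = {h for h in settings_hashes if h}
        if len(distinct) > 1:
            raise ConsistencyError(
                f"free energies mix settings presets: {sorted(distinct)}"
            )
    return -(g_adduct - g_nucleophile - g_co2) * HARTREE_TO_KCAL


# --------------------------------------------------------------------------
# Descriptor table


@dataclass
class DescriptorTable:
    """Per-nucleophile descriptor matrix with provenance metadata.

    ``data`` holds one row per nucleophile id; columns are
    ``<descriptor>_<aggregation>`` pairs plus the optional response
    column ``co2a`` (kcal/mol).  ``complete`` flags rows with a full
    set of conformer results; incomplete rows are never imputed.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    response: str | None = None

    def __post_init__(self):
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise InputError(f"duplicate descriptor columns: {dupes}")

    @property
    def feature_names(self) -> list[str]:
        drop = {self.response, "complete"}
        return [c for c in self.data.columns if c not in drop]

    @property
    def complete(self) -> pd.DataFrame:
        if "complete" in self.data.columns:
            return self.data[self.data["complete"]].drop(columns="complete")
        return self.data

    def to_csv(self, path: str | Path) -> None:
        """Write the table plus a JSON metadata sidecar (units, provenance)."""
        path = Path(path)
        self.data.to_csv(path, index_label="id")
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(self.metadata, indent=2, default=str))

    @classmethod
    def from_csv(cls, path: str | Path, response: str | None = None) -> "DescriptorTable":
        path = Path(path)
        data = pd.read_csv(path, index_col="id")
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        if response is None and "co2a" in data.columns:
            response = "co2a"
        return cls(data=data, metadata=metadata, response=response)


_DESCRIPTOR_UNITS = {
    "epsilon_homo": "Hartree",
    "site_dipole": "au",
    "buried_b1": "Angstrom",
}


def build_descriptor_table(
    records: Sequence[NucleophileRecord],
    ensembles: Mapping[str, ConformerEnsemble],
    qm_results: Mapping[str, Sequence[QMResult]],
    buried_radius: float = DEFAULT_BURIED_RADIUS,
    angular_step: float = DEFAULT_ANGULAR_STEP,
    temperature: float = ROOM_TEMPERATURE,
    radii_table: Mapping[str, float] | None = None,
    extra_descriptors: Mapping[str, Callable[[NucleophileRecord, QMResult], float]] | None = None,
    response: Mapping[str, float] | None = None,
    provenance: dict | None = None,
) -> DescriptorTable:
    """Assemble the per-nucleophile descriptor table.

    Guaranteed columns: ``epsilon_homo``, ``site_dipole`` and
    ``buried_b1``, each under all four aggregations (12 feature
    columns).  ``extra_descriptors`` maps extra names to callables
    ``f(record, qm_result) -> float`` evaluated per conformer and
    aggregated the same way.  Records with missing or mismatched
    conformer results are flagged incomplete, never imputed.

    Boltzmann weighting uses the per-conformer Gibbs free energies when
    every conformer carries one, falling back to electronic energies.
    """
    extra_descriptors = dict(extra_descriptors or {})
    rows: dict[str, dict[str, float]] = {}
    complete_flags: dict[str, bool] = {}

    for record in records:
        row: dict[str, float] = {}
        ensemble = ensembles.get(record.id)
        results = qm_results.get(record.id)
        if ensemble is None or results is None or len(results) != len(ensemble):
            rows[record.id] = row
            complete_flags[record.id] = False
            continue
        radii = radii_for(record.elements, radii_table)
        try:
            per_conf: dict[str, list[float]] = {
                name: [] for name in GUARANTEED_DESCRIPTORS
            }
            per_conf.update({name: [] for name in extra_descriptors})
            for result in results:
                per_conf["epsilon_homo"].append(result.homo_energy)
                per_conf["site_dipole"].append(result.site_dipole(record.ca_index))
                per_conf["buried_b1"].append(
                    site_b1(
                        result.optimized_coordinates,
                        radii,
                        record,
                        buried_radius=buried_radius,
                        angular_step=angular_step,
                    ).value
                )
                for name, fn in extra_descriptors.items():
                    per_conf[name].append(float(fn(record, result)))
            gibbs = [r.gibbs_free_energy for r in results]
            energies = (
                gibbs
                if all(g is not None for g in gibbs)
                else [r.electronic_energy for r in results]
            )
            for name, values in per_conf.items():
                agg = aggregate(
                    values, energies, temperature=temperature, name=name
                )
                row[f"{name}_min"] = agg.min
                row[f"{name}_max"] = agg.max
                row[f"{name}_boltz"] = agg.boltz
                row[f"{name}_lowE"] = agg.lowE
            complete_flags[record.id] = True
        except Exception:
            complete_flags[record.id] = False
        rows[record.id] = row

    data = pd.DataFrame.from_dict(rows, orient="index")
    data = data.reindex([r.id for r in records])  # keep empty rows too
    data["complete"] = pd.Series(complete_flags)
    resp_col = None
    if response is not None:
        data["co2a"] = pd.Series(dict(response))
        resp_col = "co2a"

    metadata = {
        "units": {
            **_DESCRIPTOR_UNITS,
            **{name: "" for name in extra_descriptors},
            "co2a": "kcal/mol",
        },
        "aggregations": list(AGGREGATIONS),
        "buried_radius": buried_radius,
        "angular_step": angular_step,
        "temperature": temperature,
        **(provenance or {}),
    }
    return DescriptorTable(data=data, metadata=metadata, response=resp_col)
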