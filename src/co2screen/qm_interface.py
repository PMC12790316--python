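"""Electronic-structure backend contract, output parsing and caching.

The workflow needs, per conformer: an optimized geometry, the
electronic and Gibbs free energies, orbital energies (to locate the
HOMO), and Hirshfeld charges/atomic dipoles.  Where those numbers come
from is behind the :class:`Backend` protocol:

* :class:`MockBackend` -- deterministic pseudo-properties computed from
  geometry and composition alone.  NON-PHYSICAL; exists so that the
  plumbing (caching, filtering, descriptor extraction, reporting) can
  be exercised without an engine.
* :func:`parse_engine_output` -- reads structured engine log files
  (dialects registered by name), the backend-free input path for users
  who ran their own calculations.
* External engines are adapted by implementing :class:`Backend`.

Two settings presets mirror the two-round screening economy: a cheap
level for geometry + screening properties and a refined level for the
affinity energies.  Both are just strings passed through; the package
never interprets method names.

Results are cached content-addressed by (structure hash, settings
hash), so identical reruns never touch the engine.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from rdkit import Chem

from .errors import (
    CapabilityError,
    ConvergenceError,
    MissingPropertyError,
    ParseError,
    RegistryError,
)
from .structures import Conformer
from .units import ROOM_TEMPERATURE

__all__ = [
    "QMSettings",
    "QMResult",
    "Backend",
    "MockBackend",
    "QMCache",
    "run_backend",
    "parse_engine_output",
    "register_dialect",
    "SCREENING_PRESET",
    "AFFINITY_PRESET",
    "CAPABILITIES",
]

CAPABILITIES = frozenset({"optimize", "single_point", "thermochemistry", "hirshfeld"})


@dataclass(frozen=True)
class QMSettings:
    """Level-of-theory settings; strings are passed to engines verbatim."""

    method: str = "PBE-D3(BJ)/def2-TZVPD"
    solvent_model: str = "SMD"
    solvent: str = "DMSO"
    temperature: float = ROOM_TEMPERATURE  # K
    charge: int = -1
    multiplicity: int = 1

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")

    def hash(self) -> str:
        payload = json.dumps(
            {
                "method": self.method,
                "solvent_model": self.solvent_model,
                "solvent": self.solvent,
                "temperature": round(self.temperature, 6),
                "charge": self.charge,
                "multiplicity": self.multiplicity,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


#: Round-1 preset: geometries and screening properties at the cheap level.
SCREENING_PRESET = QMSettings(method="PBE-D3(BJ)/def2-TZVPD")
#: Round-2 preset: affinity energies at the refined level.
AFFINITY_PRESET = QMSettings(method="B3LYP-D3(BJ)/def2-TZVPD")


@dataclass
class QMResult:
    """Per-conformer electronic-structure properties (Hartree / Angstrom / au)."""

    optimized_coordinates: np.ndarray
    electronic_energy: float
    orbital_energies: np.ndarray
    homo_index: int
    gibbs_free_energy: float | None = None
    hirshfeld_charges: np.ndarray | None = None
    hirshfeld_atomic_dipoles: np.ndarray | None = None  # (N, 3) au
    settings_hash: str = ""
    provenance: str = ""

    def __post_init__(self):
        self.optimized_coordinates = np.asarray(self.optimized_coordinates, float)
        self.orbital_energies = np.asarray(self.orbital_energies, float)
        n = self.optimized_coordinates.shape[0]
        if not (0 <= self.homo_index < len(self.orbital_energies)):
            raise ValueError("homo_index outside orbital_energies")
        if self.homo_index + 1 < len(self.orbital_energies):
            if self.homo_energy >= self.orbital_energies[self.homo_index + 1]:
                raise ValueError("HOMO energy must lie below the LUMO energy")
        for name in ("hirshfeld_charges", "hirshfeld_atomic_dipoles"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, float)
                setattr(self, name, arr)
                if arr.shape[0] != n:
                    raise ValueError(f"{name} length does not match atom count")

    @property
    def homo_energy(self) -> float:
        """Energy of the highest occupied molecular orbital, Hartree."""
        return float(self.orbital_energies[self.homo_index])

    def site_dipole(self, atom_index: int) -> float:
        """Magnitude of the Hirshfeld atomic dipole at one atom, au.

        The magnitude is the only rotation-invariant scalar of the
        atomic dipole vector, hence the reported site descriptor.
        """
        if self.hirshfeld_atomic_dipoles is None:
            raise MissingPropertyError("result carries no Hirshfeld atomic dipoles")
        return float(np.linalg.norm(self.hirshfeld_atomic_dipoles[atom_index]))

    # -- JSON round trip for the on-disk cache ---------------------------
    def to_dict(self) -> dict:
        return {
            "optimized_coordinates": self.optimized_coordinates.tolist(),
            "electronic_energy": self.electronic_energy,
            "orbital_energies": self.orbital_energies.tolist(),
            "homo_index": self.homo_index,
            "gibbs_free_energy": self.gibbs_free_energy,
            "hirshfeld_charges": None
            if self.hirshfeld_charges is None
            else self.hirshfeld_charges.tolist(),
            "hirshfeld_atomic_dipoles": None
            if self.hirshfeld_atomic_dipoles is None
            else self.hirshfeld_atomic_dipoles.tolist(),
            "settings_hash": self.settings_hash,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QMResult":
        return cls(
            optimized_coordinates=np.array(d["optimized_coordinates"]),
            electronic_energy=d["electronic_energy"],
            orbital_energies=np.array(d["orbital_energies"]),
            homo_index=d["homo_index"],
            gibbs_free_energy=d["gibbs_free_energy"],
            hirshfeld_charges=None
            if d["hirshfeld_charges"] is None
            else np.array(d["hirshfeld_charges"]),
            hirshfeld_atomic_dipoles=None
            if d["hirshfeld_atomic_dipoles"] is None
            else np.array(d["hirshfeld_atomic_dipoles"]),
            settings_hash=d.get("settings_hash", ""),
            provenance=d.get("provenance", ""),
        )


@runtime_checkable
class Backend(Protocol):
    """Contract every electronic-structure backend fulfils.

    A backend declaring a capability must populate the corresponding
    :class:`QMResult` fields or raise.
    """

    name: str
    capabilities: frozenset[str]

    def compute(
        self, elements: Sequence[str], coordinates: np.ndarray, settings: QMSettings
    ) -> QMResult:
        ...


def structure_hash(elements: Sequence[str], coordinates: np.ndarray, charge: int) -> str:
    """Content hash of a structure; coordinates rounded to 1e-6 Angstrom."""
    coords = np.round(np.asarray(coordinates, float), 6)
    payload = json.dumps(
        {"elements": list(elements), "coords": coords.tolist(), "charge": charge}
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:20]


_PT = Chem.GetPeriodicTable()


class MockBackend:
    """Deterministic pseudo-property backend for plumbing tests.

    All quantities are smooth functions of interatomic distances and
    composition only, so they are exactly invariant under rigid rotation
    and translation and bit-stable across reruns.  The numbers are
    NON-PHYSICAL: they exist to exercise caching, filtering, descriptor
    extraction and reporting without an engine.

    HOMO energies land in the interval (-0.19, -0.10) Hartree so a
    -0.140 Hartree screen partitions realistic batches both ways.
    """

    name = "mock"
    capabilities = CAPABILITIES

    def __init__(self):
        self.n_calls = 0

    def compute(
        self, elements: Sequence[str], coordinates: np.ndarray, settings: QMSettings
    ) -> QMResult:
        self.n_calls += 1
        coords = np.asarray(coordinates, float)
        n = len(elements)
        z = np.array([_PT.GetAtomicNumber(str(s)) for s in elements], float)

        if n > 1:
            diff = coords[:, None] - coords[None, :]
            dist = np.sqrt((diff**2).sum(-1))
            iu = np.triu_indices(n, k=1)
            pair_d = dist[iu]
            bonded = np.exp(-pair_d / 2.0)
            e_elec = -0.5 * z.sum() - 0.05 * float(bonded.sum())
            dbar = float(pair_d.mean())
        else:
            dist = np.zeros((1, 1))
            e_elec = -0.5 * z.sum()
            dbar = 0.0

        n_electrons = int(z.sum()) - settings.charge
        n_occ = max(n_electrons // 2, 1)
        homo_index = n_occ - 1
        # smooth, bounded map of mean pair distance into a HOMO window
        homo = -0.19 + 0.09 / (1.0 + np.exp(-(dbar - 3.0)))
        occupied = homo - 0.03 * np.arange(n_occ - 1, -1, -1)
        virtuals = homo + 0.05 * np.array([1.0, 2.0])
        orbital_energies = np.concatenate([occupied, virtuals])

        # charges: even split of the total charge plus a zero-sum smooth term
        if n > 1:
            coord_term = np.exp(-dist).sum(axis=1) - 1.0  # self-term removed
            deviation = 0.05 * np.tanh(coord_term - coord_term.mean())
            deviation -= deviation.mean()
        else:
            deviation = np.zeros(1)
        charges = settings.charge / n + deviation

        # atomic dipoles: covariant pair sum -> invariant magnitudes
        dipoles = np.zeros((n, 3))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                rij = coords[j] - coords[i]
                d = dist[i, j]
                dipoles[i] += 0.1 * np.exp(-d) * rij / d

        gibbs = e_elec + 0.05 + 0.001 * n + 1e-5 * settings.temperature
        return QMResult(
            optimized_coordinates=coords,
            electronic_energy=float(e_elec),
            orbital_energies=orbital_energies,
            homo_index=homo_index,
            gibbs_free_energy=float(gibbs),
            hirshfeld_charges=charges,
            hirshfeld_atomic_dipoles=dipoles,
            settings_hash=settings.hash(),
            provenance=self.name,
        )


class QMCache:
    """Content-addressed result cache, optionally persisted to disk.

    Keys are ``(structure hash, settings hash)``; on disk each entry is
    one JSON file named ``<structure>_<settings>.json``.
    """

    def __init__(self, directory: str | Path | None = None):
        self.directory = Path(directory) if directory is not None else None
        if self.directory is not None:
            self.directory.mkdir(parents=True, exist_ok=True)
        self._memory: dict[str, QMResult] = {}

    @staticmethod
    def key(struct_hash: str, settings_hash: str) -> str:
        return f"{struct_hash}_{settings_hash}"

    def get(self, key: str) -> QMResult | None:
        if key in self._memory:
            return self._memory[key]
        if self.directory is not None:
            path = self.directory / f"{key}.json"
            if path.exists():
                result = QMResult.from_dict(json.loads(path.read_text()))
                self._memory[key] = result
                return result
        return None

    def put(self, key: str, result: QMResult) -> None:
        self._memory[key] = result
        if self.directory is not None:
            (self.directory / f"{key}.json").write_text(
                json.dumps(result.to_dict())
            )


def run_backend(
    conformer: Conformer,
    elements: Sequence[str],
    settings: QMSettings,
    backend: Backend,
    cache: QMCache | None = None,
    require: Sequence[str] = ("single_point",),
) -> QMResult:
    """Run (or fetch from cache) one conformer through a backend.

    ``require`` lists the capabilities the caller depends on; a backend
    not declaring them raises :class:`CapabilityError` before any
    compute.  Cache hits never invoke the engine.
    """
    missing = set(require) - set(backend.capabilities)
    if missing:
        raise CapabilityError(
            f"backend {backend.name!r} lacks capabilities: {sorted(missing)}"
        )
    key = QMCache.key(
        structure_hash(elements, conformer.coordinates, settings.charge),
        settings.hash(),
    )
    if cache is not None:
        hit = cache.get(key)
        if hit is not None:
            return hit
    result = backend.compute(elements, conformer.coordinates, settings)
    if cache is not None:
        cache.put(key, result)
    return result


# --------------------------------------------------------------------------
# Engine output parsing

_DIALECTS: dict[str, callable] = {}


def register_dialect(name: str):
    """Register a parser for an engine-output dialect under ``name``."""

    def deco(fn):
        _DIALECTS[name] = fn
        return fn

    return deco


def parse_engine_output(
    path: str | Path,
    dialect: str = "plainlog",
    require: Sequence[str] = (),
) -> QMResult:
    """Parse an engine output file into a :class:`QMResult`.

    ``require`` may list ``"thermochemistry"`` and/or ``"hirshfeld"``;
    a file missing a required section raises
    :class:`MissingPropertyError` naming it.  Truncated files raise
    :class:`ParseError` naming the incomplete section.  Units are
    normalized to Hartree / Angstrom / atomic units.
    """
    if dialect not in _DIALECTS:
        raise RegistryError(
            f"unknown output dialect {dialect!r}; known: {sorted(_DIALECTS)}"
        )
    result = _DIALECTS[dialect](Path(path))
    if "thermochemistry" in require and result.gibbs_free_energy is None:
        raise MissingPropertyError("no thermochemistry section in output")
    if "hirshfeld" in require and result.hirshfeld_atomic_dipoles is None:
        raise MissingPropertyError("no Hirshfeld section in output")
    return result


@register_dialect("plainlog")
def _parse_plainlog(path: Path) -> QMResult:
    """Parse the bracket-sectioned key/value log format.

    Sections: ``[GEOMETRY]`` (element x y z, Angstrom), ``[SCF]``
    (``energy_hartree``, ``converged``), ``[ORBITALS]`` (energy
    occupancy pairs; HOMO = highest orbital with occupancy > 0),
    optional ``[HIRSHFELD]`` (charge dx dy dz per atom, au) and
    ``[THERMO]`` (``gibbs_hartree``).  ``[END]`` marks a complete file;
    its absence means the run was truncated.
    """
    try:
        text = path.read_text()
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc

    sections: dict[str, list[str]] = {}
    current: str | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].upper()
            sections[current] = []
            continue
        if current is not None:
            sections[current].append(line)

    if "END" not in sections:
        missing = "GEOMETRY"
        for name in ("GEOMETRY", "SCF", "ORBITALS", "HIRSHFELD", "THERMO"):
            if name not in sections:
                missing = name
                break
        else:
            missing = "END marker"
        raise ParseError(f"truncated output: missing {missing} section")

    for name in ("GEOMETRY", "SCF", "ORBITALS"):
        if name not in sections or not sections[name]:
            raise ParseError(f"truncated output: missing {name} section")

    elements: list[str] = []
    coords: list[list[float]] = []
    for line in sections["GEOMETRY"]:
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(f"malformed GEOMETRY line: {line!r}")
        elements.append(parts[0])
        try:
            coords.append([float(p) for p in parts[1:]])
        except ValueError:
            raise ParseError(f"malformed GEOMETRY line: {line!r}")

    kv = {}
    for line in sections["SCF"]:
        if "=" in line:
            k, v = (s.strip() for s in line.split("=", 1))
            kv[k] = v
    if "energy_hartree" not in kv:
        raise ParseError("SCF section lacks energy_hartree")
    if kv.get("converged", "true").lower() not in ("true", "yes", "1"):
        raise ConvergenceError(f"SCF did not converge in {path.name}")
    e_elec = float(kv["energy_hartree"])

    energies, occupancies = [], []
    for line in sections["ORBITALS"]:
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"malformed ORBITALS line: {line!r}")
        energies.append(float(parts[0]))
        occupancies.append(float(parts[1]))
    occ_idx = [i for i, o in enumerate(occupancies) if o > 0]
    if not occ_idx:
        raise ParseError("ORBITALS section has no occupied orbital")
    homo_index = max(occ_idx)

    charges = dipoles = None
    if "HIRSHFELD" in sections and sections["HIRSHFELD"]:
        charges, dipoles = [], []
        for line in sections["HIRSHFELD"]:
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"malformed HIRSHFELD line: {line!r}")
            charges.append(float(parts[0]))
            dipoles.append([float(p) for p in parts[1:]])
        if len(charges) != len(elements):
            raise ParseError("HIRSHFELD atom count differs from GEOMETRY")
        charges = np.array(charges)
        dipoles = np.array(dipoles)

    gibbs = None
    if "THERMO" in sections:
        tkv = {}
        for line in sections["THERMO"]:
            if "=" in line:
                k, v = (s.strip() for s in line.split("=", 1))
                tkv[k] = v
        if "gibbs_hartree" in tkv:
            gibbs = float(tkv["gibbs_hartree"])

    return QMResult(
        optimized_coordinates=np.array(coords),
        electronic_energy=e_elec,
        orbital_energies=np.array(energies),
        homo_index=homo_index,
        gibbs_free_energy=gibbs,
        hirshfeld_charges=charges,
        hirshfeld_atomic_dipoles=dipoles,
        provenance=f"plainlog:{path.name}",
    )
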