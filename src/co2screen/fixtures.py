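"""Synthetic inputs for building and testing the pipeline without downloads.

Three generator families:

* toy geometries with known Sterimol values -- analytic for the
  symmetric cases, otherwise computed at generation time by an
  independent brute-force direction scan (0.01 degree grid) that never
  shares code with the production grid+refinement search,
* descriptor tables with planted linear structure, for model-recovery
  tests,
* fake engine output files in a registered dialect, for parser
  round-trip tests.

Every fixture embeds its own expected values and every generator is a
pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import RegistryError, SpecError

__all__ = [
    "SyntheticSpec",
    "ToyGeometry",
    "TOY_CASES",
    "sterimol_brute_force",
    "make_toy_geometries",
    "random_geometry",
    "make_descriptor_table",
    "make_fake_engine_output",
    "random_rotation",
]


# --------------------------------------------------------------------------
# Independent Sterimol oracle


def sterimol_brute_force(
    coordinates: np.ndarray,
    radii: Sequence[float],
    attach_index: int,
    axis_index: int,
    step_degrees: float = 0.01,
    buried_radius: float | None = None,
) -> tuple[float, float, float]:
    """(L, B1, B5) by exhaustive direction scan at ``step_degrees``.

    Deliberately naive: enumerates the full circle of perpendicular
    directions on a fine grid with no refinement, so it is independent
    of the production search strategy and usable as its oracle.
    """
    coords = np.asarray(coordinates, float)
    radii = np.asarray(radii, float)
    origin = coords[attach_index]
    u = coords[axis_index] - origin
    u = u / np.linalg.norm(u)

    mask = np.arange(len(coords)) != attach_index
    if buried_radius is not None:
        mask &= np.linalg.norm(coords - origin, axis=1) <= buried_radius
    rel = coords[mask] - origin
    r = radii[mask]

    length = float((rel @ u + r).max())

    # orthonormal in-plane basis (any choice; results are basis-free)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, helper)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)

    a = rel @ v
    b = rel @ w
    thetas = np.deg2rad(np.arange(0.0, 360.0, step_degrees))
    widths = (
        a[None, :] * np.cos(thetas)[:, None]
        + b[None, :] * np.sin(thetas)[:, None]
        + r[None, :]
    ).max(axis=1)
    return length, float(widths.min()), float(widths.max())


# --------------------------------------------------------------------------
# Toy geometries


@dataclass(frozen=True)
class ToyGeometry:
    """A small geometry bundled with its expected Sterimol values."""

    case: str
    coordinates: np.ndarray
    radii: np.ndarray
    attach_index: int
    axis_index: int
    expected_L: float
    expected_B1: float
    expected_B5: float
    expected_source: str  # "analytic" | "brute-force"


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_geometry(
    rng: np.random.Generator, n_atoms: int = 8, spread: float = 2.5
) -> tuple[np.ndarray, np.ndarray]:
    """Random non-degenerate point cloud + radii for oracle comparisons.

    Atom 0 is the attachment, atom 1 the axis atom; a minimum pair
    separation keeps the axis well-defined.
    """
    while True:
        coords = rng.uniform(-spread, spread, size=(n_atoms, 3))
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > 0.7:
            break
    radii = rng.uniform(1.1, 2.0, size=n_atoms)
    return coords, radii


def _case_collinear() -> ToyGeometry:
    # attach at origin, one substituent atom on the axis at 1.09 A, r = 1.20
    coords = np.array([[0.0, 0.0, 0.0], [1.09, 0.0, 0.0]])
    radii = np.array([1.70, 1.20])
    return ToyGeometry(
        case="collinear",
        coordinates=coords,
        radii=radii,
        attach_index=0,
        axis_index=1,
        expected_L=1.09 + 1.20,
        expected_B1=1.20,
        expected_B5=1.20,
        expected_source="analytic",
    )


def _case_planar_t() -> ToyGeometry:
    # axis along +x; two equal atoms straddling the axis along +-y.
    # Widths: along y the sphere edge reaches dy + r; along z only r.
    # With dy + r > r the thin direction is z: B1 = r, B5 = dy + r.
    r = 1.5
    dy = 1.2
    coords = np.array(
        [
            [0.0, 0.0, 0.0],  # attach
            [1.4, 0.0, 0.0],  # axis atom, radius r
            [1.4, dy, 0.0],
            [1.4, -dy, 0.0],
        ]
    )
    radii = np.array([1.70, r, r, r])
    return ToyGeometry(
        case="planar-T",
        coordinates=coords,
        radii=radii,
        attach_index=0,
        axis_index=1,
        expected_L=1.4 + r,
        expected_B1=r,
        expected_B5=dy + r,
        expected_source="analytic",
    )


def _case_tetrahedral() -> ToyGeometry:
    # methyl-like: three equivalent atoms around the axis -> brute-force values
    bond = 1.09
    ang = np.deg2rad(109.471)
    coords = [[0.0, 0.0, 0.0], [0.0, 0.0, 1.54]]
    for k in range(3):
        phi = 2.0 * np.pi * k / 3.0
        coords.append(
            [
                bond * np.sin(ang) * np.cos(phi),
                bond * np.sin(ang) * np.sin(phi),
                1.54 + bond * np.cos(ang) + bond,  # displaced along axis
            ]
        )
    coords = np.array(coords)
    radii = np.array([1.70, 1.70, 1.20, 1.20, 1.20])
    length, b1, b5 = sterimol_brute_force(coords, radii, 0, 1)
    return ToyGeometry(
        case="tetrahedral",
        coordinates=coords,
        radii=radii,
        attach_index=0,
        axis_index=1,
        expected_L=length,
        expected_B1=b1,
        expected_B5=b5,
        expected_source="brute-force",
    )


def _case_distal_atom() -> ToyGeometry:
    # one far-out atom perpendicular to the axis sets B5; removing it
    # (buried sphere) must lower B5 but leave B1 untouched.
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0],
            [2.0, 1.0, 0.0],
            [2.0, -1.0, 0.0],
            [2.5, 6.5, 0.0],  # distal: beyond a 5.5 A sphere
        ]
    )
    radii = np.array([1.70, 1.70, 1.20, 1.20, 1.52])
    length, b1, b5 = sterimol_brute_force(coords, radii, 0, 1)
    return ToyGeometry(
        case="distal-atom",
        coordinates=coords,
        radii=radii,
        attach_index=0,
        axis_index=1,
        expected_L=length,
        expected_B1=b1,
        expected_B5=b5,
        expected_source="brute-force",
    )


def _case_random_seeded(seed: int = 2024) -> ToyGeometry:
    rng = np.random.default_rng(seed)
    coords, radii = random_geometry(rng, n_atoms=8)
    length, b1, b5 = sterimol_brute_force(coords, radii, 0, 1)
    return ToyGeometry(
        case="random-seeded",
        coordinates=coords,
        radii=radii,
        attach_index=0,
        axis_index=1,
        expected_L=length,
        expected_B1=b1,
        expected_B5=b5,
        expected_source="brute-force",
    )


TOY_CASES = {
    "collinear": _case_collinear,
    "planar-T": _case_planar_t,
    "tetrahedral": _case_tetrahedral,
    "distal-atom": _case_distal_atom,
    "random-seeded": _case_random_seeded,
}


def make_toy_geometries(case: str) -> ToyGeometry:
    """Fetch a registered toy geometry with its expected Sterimol values."""
    if case not in TOY_CASES:
        raise RegistryError(f"unknown toy case {case!r}; known: {sorted(TOY_CASES)}")
    return TOY_CASES[case]()


# --------------------------------------------------------------------------
# Synthetic descriptor tables


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a descriptor table with planted linear structure.

    ``true_features`` maps feature names to their raw-space
    coefficients; decoys are drawn correlated (``decoy_correlation``)
    to the true features in round-robin order.  The response is the
    linear combination plus Gaussian noise of ``noise_sigma`` kcal/mol.
    """

    n_samples: int = 31
    true_features: Mapping[str, float] = field(
        default_factory=lambda: {"x1": 2.0, "x2": -1.0, "x3": 0.5}
    )
    noise_sigma: float = 0.5257  # kcal/mol; matches R2 ~ 0.95 for the defaults
    n_decoys: int = 9
    decoy_correlation: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be >= 0")
        if not self.true_features:
            raise SpecError("need at least one true feature")
        if not -1.0 < self.decoy_correlation < 1.0:
            raise SpecError("decoy correlation must lie in (-1, 1)")
        names = list(self.true_features)
        if len(set(names)) != len(names):
            raise SpecError("feature names must be unique")


def make_descriptor_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Build the synthetic table; generating parameters live in ``.attrs``.

    True features are iid standard normal; decoy j is
    ``rho * true_(j mod k) + sqrt(1 - rho^2) * noise``, so each decoy
    carries the configured marginal correlation to one true feature.
    With the default coefficients (2, -1, 0.5) the signal variance is
    5.25, and the default noise sigma keeps the true-model R2 near
    0.95.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.true_features)
    coefs = np.array([spec.true_features[n] for n in names])
    x_true = rng.normal(size=(spec.n_samples, len(names)))

    data = {n: x_true[:, j] for j, n in enumerate(names)}
    rho = spec.decoy_correlation
    for d in range(spec.n_decoys):
        partner = d % len(names)
        noise = rng.normal(size=spec.n_samples)
        data[f"decoy{d + 1}"] = rho * x_true[:, partner] + np.sqrt(1 - rho**2) * noise

    y = x_true @ coefs + rng.normal(scale=spec.noise_sigma, size=spec.n_samples)
    frame = pd.DataFrame(data)
    frame["co2a"] = y
    frame.index = [f"syn{i + 1}" for i in range(spec.n_samples)]
    frame.attrs["spec"] = {
        "true_features": dict(spec.true_features),
        "noise_sigma": spec.noise_sigma,
        "n_decoys": spec.n_decoys,
        "decoy_correlation": spec.decoy_correlation,
        "seed": spec.seed,
    }
    return frame


# --------------------------------------------------------------------------
# Fake engine output


def make_fake_engine_output(
    path: str | Path,
    elements: Sequence[str],
    coordinates: np.ndarray,
    electronic_energy: float,
    orbital_energies: Sequence[float],
    occupancies: Sequence[float],
    hirshfeld_charges: Sequence[float] | None = None,
    hirshfeld_dipoles: np.ndarray | None = None,
    gibbs: float | None = None,
    dialect: str = "plainlog",
    truncate_after: str | None = None,
) -> Path:
    """Emit a parseable engine log embedding the given values verbatim.

    ``truncate_after`` cuts the file after the named section (and drops
    the end marker), producing the truncated-file fixtures for negative
    parser tests.
    """
    if dialect != "plainlog":
        raise RegistryError(f"unsupported fake-output dialect {dialect!r}")
    coords = np.asarray(coordinates, float)
    lines = ["# synthetic engine output (plainlog dialect)"]
    lines.append("[GEOMETRY]")
    for sym, (x, y, z) in zip(elements, coords):
        lines.append(f"{sym} {x:.10f} {y:.10f} {z:.10f}")
    sections = ["GEOMETRY"]

    lines.append("[SCF]")
    lines.append(f"energy_hartree = {electronic_energy:.10f}")
    lines.append("converged = true")
    sections.append("SCF")

    lines.append("[ORBITALS]")
    for e, occ in zip(orbital_energies, occupancies):
        lines.append(f"{e:.10f} {occ:g}")
    sections.append("ORBITALS")

    if hirshfeld_charges is not None and hirshfeld_dipoles is not None:
        lines.append("[HIRSHFELD]")
        for q, (dx, dy, dz) in zip(hirshfeld_charges, np.asarray(hirshfeld_dipoles)):
            lines.append(f"{q:.10f} {dx:.10f} {dy:.10f} {dz:.10f}")
        sections.append("HIRSHFELD")

    if gibbs is not None:
        lines.append("[THERMO]")
        lines.append(f"gibbs_hartree = {gibbs:.10f}")
        sections.append("THERMO")

    lines.append("[END]")
    lines.append("normal termination")

    if truncate_after is not None:
        if truncate_after not in sections:
            raise RegistryError(f"cannot truncate after unknown section {truncate_after!r}")
        # keep everything up to the end of the named section
        keep: list[str] = []
        current = None
        for line in lines:
            if line.startswith("[") and line.endswith("]"):
                if current == truncate_after:
                    break
                current = line[1:-1]
            keep.append(line)
        lines = keep

    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
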