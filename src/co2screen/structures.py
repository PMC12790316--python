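"""Molecular input handling: SMILES parsing, nucleophilic-pattern detection,
conformer-ensemble generation and structure file I/O.

The screening target is a carbon-centered nucleophile: a carbanionic
site CA (carbon, formal charge -1) flanked by exactly two carbon
neighbors C1 and C2.  Pattern detection is structural, so it does not
depend on the atom ordering of the input SMILES.

Conformer ensembles are produced with RDKit distance-geometry embedding
(ETKDGv3) followed by force-field ranking.  This is a desk-scale
stand-in for a metadynamics conformer search; the ensemble contract
(energy window, RMSD deduplication, ascending energy order) is the same
either way, so downstream code is agnostic to the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import (
    AmbiguousPatternError,
    EmptyInputError,
    FormatError,
    GeometryError,
    InputError,
    PatternAbsentError,
    PatternError,
    PatternMismatchError,
)
from .units import kcal_to_hartree

__all__ = [
    "NucleophileRecord",
    "Conformer",
    "ConformerEnsemble",
    "Reject",
    "ParseResult",
    "parse_smiles_input",
    "parse_smiles",
    "detect_pattern",
    "deprotonate",
    "embed_ensemble",
    "prune_ensemble",
    "read_xyz",
    "write_xyz",
    "read_sdf",
    "write_rejects",
]

# Default ensemble retention settings (configurable everywhere).
DEFAULT_ENERGY_WINDOW = 6.0  # kcal/mol above the minimum
DEFAULT_RMSD_THRESHOLD = 0.25  # Angstrom, heavy atoms
DEFAULT_N_CONFS = 50
DEFAULT_SEED = 42


@dataclass(frozen=True)
class NucleophileRecord:
    """A candidate nucleophile with its carbanionic site identified.

    Atom indices refer to the explicit-hydrogen molecule (hydrogens are
    appended after the heavy atoms, so heavy-atom indices match the
    SMILES parse order).
    """

    id: str
    smiles: str
    total_charge: int
    atoms: tuple[tuple[str, int], ...]  # (element symbol, formal charge)
    ca_index: int
    c1_index: int
    c2_index: int
    mol: Chem.Mol | None = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        if len({self.ca_index, self.c1_index, self.c2_index}) != 3:
            raise PatternError("CA/C1/C2 indices must be pairwise distinct")
        sym, charge = self.atoms[self.ca_index]
        if sym != "C" or charge != -1:
            raise PatternError("atom at ca_index must be a carbon with charge -1")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [sym for sym, _ in self.atoms]


@dataclass(frozen=True)
class Conformer:
    """One geometry of a nucleophile with its (relative) energy."""

    coordinates: np.ndarray  # (N, 3) Angstrom
    energy: float  # Hartree
    provenance: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise GeometryError(f"coordinates must be (N, 3), got {coords.shape}")
        if coords.shape[0] > 1:
            d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() <= 0.5:
                raise GeometryError(
                    f"minimum interatomic distance {d.min():.3f} A <= 0.5 A"
                )


@dataclass
class ConformerEnsemble:
    """Ordered conformers of one record, lowest energy first."""

    record: NucleophileRecord
    conformers: list[Conformer]
    energy_window: float = DEFAULT_ENERGY_WINDOW  # kcal/mol
    rmsd_threshold: float = DEFAULT_RMSD_THRESHOLD  # Angstrom

    def __post_init__(self):
        if not self.conformers:
            raise GeometryError("ensemble must contain at least one conformer")
        for c in self.conformers:
            if c.coordinates.shape[0] != self.record.n_atoms:
                raise GeometryError(
                    "conformer atom count does not match parent record"
                )

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def energies(self) -> np.ndarray:
        return np.array([c.energy for c in self.conformers])


@dataclass(frozen=True)
class Reject:
    """One input line that could not be turned into a record."""

    id: str
    line: int
    reason: str


@dataclass
class ParseResult:
    records: list[NucleophileRecord]
    rejects: list[Reject]

    @property
    def n_input_lines(self) -> int:
        return len(self.records) + len(self.rejects)


def detect_pattern(mol: Chem.Mol) -> tuple[int, int, int]:
    """Locate the unique carbanionic site CA and its carbon neighbors.

    Returns ``(ca_index, c1_index, c2_index)`` with C1/C2 ordered by
    ascending atom index.  Raises a typed error when the pattern is
    absent, mismatched (CA without exactly two carbon neighbors) or
    ambiguous (several candidate sites) -- an ambiguous site is never
    auto-picked.
    """
    candidates = [
        a for a in mol.GetAtoms() if a.GetSymbol() == "C" and a.GetFormalCharge() == -1
    ]
    if not candidates:
        raise PatternAbsentError("no carbanionic site")
    if len(candidates) > 1:
        raise AmbiguousPatternError(
            f"{len(candidates)} candidate carbanionic sites; pattern is ambiguous"
        )
    ca = candidates[0]
    carbon_neighbors = sorted(
        n.GetIdx() for n in ca.GetNeighbors() if n.GetSymbol() == "C"
    )
    if len(carbon_neighbors) != 2:
        raise PatternMismatchError(
            f"carbanionic site has {len(carbon_neighbors)} carbon neighbors, need 2"
        )
    return ca.GetIdx(), carbon_neighbors[0], carbon_neighbors[1]


def _record_from_mol(mol: Chem.Mol, record_id: str, smiles: str) -> NucleophileRecord:
    total_charge = Chem.GetFormalCharge(mol)
    if total_charge != -1:
        raise PatternAbsentError(
            f"total charge {total_charge:+d}, expected -1 for a carbanion"
        )
    ca, c1, c2 = detect_pattern(mol)
    molh = Chem.AddHs(mol)  # hydrogens appended; heavy indices preserved
    atoms = tuple((a.GetSymbol(), a.GetFormalCharge()) for a in molh.GetAtoms())
    return NucleophileRecord(
        id=record_id,
        smiles=Chem.MolToSmiles(mol),
        total_charge=total_charge,
        atoms=atoms,
        ca_index=ca,
        c1_index=c1,
        c2_index=c2,
        mol=molh,
    )


def parse_smiles(smiles: str, record_id: str = "mol") -> NucleophileRecord:
    """Parse a single SMILES string into a pattern-checked record."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparseable SMILES: {smiles!r}")
    return _record_from_mol(mol, record_id, smiles)


def parse_smiles_input(path: str | Path) -> ParseResult:
    """Read a ``.smi`` file (``SMILES [id]`` per line) into records.

    Every input line is accounted for: lines that fail SMILES parsing
    or the nucleophilic-pattern check end up in the rejects list with a
    reason, never silently dropped.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise InputError(f"cannot read input file {path}: {exc}") from exc

    records: list[NucleophileRecord] = []
    rejects: list[Reject] = []
    n_line = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        n_line += 1
        parts = line.split()
        smiles = parts[0]
        record_id = parts[1] if len(parts) > 1 else f"line{lineno}"
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            rejects.append(Reject(record_id, lineno, "unparseable SMILES"))
            continue
        try:
            records.append(_record_from_mol(mol, record_id, smiles))
        except PatternAbsentError as exc:
            rejects.append(Reject(record_id, lineno, f"no carbanionic site ({exc})"))
        except PatternError as exc:
            rejects.append(Reject(record_id, lineno, str(exc)))
    if n_line == 0 or (not records and not rejects):
        raise EmptyInputError(f"no input lines in {path}")
    if not records:
        raise EmptyInputError(
            f"zero valid records in {path} ({len(rejects)} rejects)"
        )
    return ParseResult(records, rejects)


def deprotonate(smiles: str, atom_index: int, record_id: str = "mol") -> NucleophileRecord:
    """Deprotonate a neutral C-H acid at ``atom_index`` and pattern-check.

    Convenience for users starting from the neutral precursor; the
    modeled carboxylation step itself starts from the carbanion.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparseable SMILES: {smiles!r}")
    if not (0 <= atom_index < mol.GetNumAtoms()):
        raise InputError(f"atom index {atom_index} out of range")
    atom = mol.GetAtomWithIdx(atom_index)
    if atom.GetTotalNumHs() < 1:
        raise InputError(f"atom {atom_index} carries no hydrogen to remove")
    rw = Chem.RWMol(mol)
    a = rw.GetAtomWithIdx(atom_index)
    a.SetNumExplicitHs(atom.GetTotalNumHs() - 1)
    a.SetNoImplicit(True)
    a.SetFormalCharge(atom.GetFormalCharge() - 1)
    product = rw.GetMol()
    Chem.SanitizeMol(product)
    return _record_from_mol(product, record_id, Chem.MolToSmiles(product))


# --------------------------------------------------------------------------
# Conformer generation


def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD of two equally indexed point sets after optimal superposition."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = a @ rot.T - b
    return float(np.sqrt((diff**2).sum() / len(a)))


def heavy_atom_rmsd(
    record: NucleophileRecord, x: np.ndarray, y: np.ndarray
) -> float:
    heavy = [i for i, (sym, _) in enumerate(record.atoms) if sym != "H"]
    return _kabsch_rmsd(x[heavy], y[heavy])


def prune_ensemble(ensemble: ConformerEnsemble) -> ConformerEnsemble:
    """Apply energy-window and RMSD deduplication; idempotent.

    Conformers are sorted ascending by energy; a conformer is kept only
    if it lies within the window of the minimum and is at least
    ``rmsd_threshold`` (heavy-atom RMSD, optimal superposition) away
    from every already-kept conformer.
    """
    confs = sorted(ensemble.conformers, key=lambda c: c.energy)
    e_min = confs[0].energy
    window_h = kcal_to_hartree(ensemble.energy_window)
    kept: list[Conformer] = []
    for c in confs:
        if c.energy - e_min > window_h:
            continue
        if any(
            heavy_atom_rmsd(ensemble.record, c.coordinates, k.coordinates)
            < ensemble.rmsd_threshold
            for k in kept
        ):
            continue
        kept.append(c)
    return ConformerEnsemble(
        record=ensemble.record,
        conformers=kept,
        energy_window=ensemble.energy_window,
        rmsd_threshold=ensemble.rmsd_threshold,
    )


def embed_ensemble(
    record: NucleophileRecord,
    n_confs: int = DEFAULT_N_CONFS,
    seed: int = DEFAULT_SEED,
    energy_window: float = DEFAULT_ENERGY_WINDOW,
    rmsd_threshold: float = DEFAULT_RMSD_THRESHOLD,
) -> ConformerEnsemble:
    """Generate a deduplicated conformer ensemble for a record.

    Distance-geometry embedding (ETKDGv3, seeded, hence deterministic)
    followed by MMFF94 optimization (UFF fallback when MMFF lacks
    parameters).  Force-field energies are converted to Hartree so the
    ensemble speaks the same units as electronic-structure output;
    only energy differences within an ensemble are meaningful.
    """
    if n_confs < 1:
        raise InputError("n_confs must be >= 1")
    if record.mol is None:
        mol = Chem.AddHs(Chem.MolFromSmiles(record.smiles))
    else:
        mol = Chem.Mol(record.mol)

    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.useRandomCoords = False
    cids = AllChem.EmbedMultipleConfs(mol, numConfs=int(n_confs), params=params)
    if len(cids) == 0:
        # retry with random-coordinate initialisation before giving up
        params.useRandomCoords = True
        cids = AllChem.EmbedMultipleConfs(mol, numConfs=int(n_confs), params=params)
    if len(cids) == 0:
        raise GeometryError(f"embedding failed for {record.id} ({record.smiles})")

    try:
        results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=1000)
        ff = "ETKDGv3+MMFF94"
        if any(code != 0 for code, _ in results):
            raise ValueError
    except Exception:
        results = AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=1000)
        ff = "ETKDGv3+UFF"

    conformers = []
    for cid, (code, energy_kcal) in zip(cids, results):
        if code != 0:
            continue
        coords = np.array(mol.GetConformer(cid).GetPositions(), dtype=float)
        conformers.append(
            Conformer(
                coordinates=coords,
                energy=kcal_to_hartree(energy_kcal),
                provenance=f"{ff} seed={seed}",
            )
        )
    if not conformers:
        raise GeometryError(f"force-field optimization failed for {record.id}")
    ensemble = ConformerEnsemble(
        record=record,
        conformers=conformers,
        energy_window=energy_window,
        rmsd_threshold=rmsd_threshold,
    )
    return prune_ensemble(ensemble)


# --------------------------------------------------------------------------
# Structure file I/O

XYZFrame = tuple[list[str], np.ndarray, str]


def read_xyz(path: str | Path) -> list[XYZFrame]:
    """Read a (multi-frame) XYZ file into ``(elements, coords, comment)``.

    Standard XYZ: atom-count line, comment line, then ``element x y z``
    records in Angstrom.  Malformed counts, element symbols or
    coordinates raise :class:`FormatError` with the offending line
    number.
    """
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc

    frames: list[XYZFrame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"malformed atom-count line {lines[i]!r}", line=i + 1)
        if natoms < 1:
            raise FormatError(f"non-positive atom count {natoms}", line=i + 1)
        if i + 1 >= len(lines):
            raise FormatError("missing comment line", line=i + 2)
        comment = lines[i + 1]
        elements: list[str] = []
        coords = np.empty((natoms, 3))
        for j in range(natoms):
            lineno = i + 2 + j
            if lineno >= len(lines):
                raise FormatError(
                    f"expected {natoms} atom lines, file ends after {j}",
                    line=lineno + 1,
                )
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise FormatError(f"malformed atom line {lines[lineno]!r}", line=lineno + 1)
            sym = parts[0]
            if not sym.isalpha() or len(sym) > 3:
                raise FormatError(f"bad element symbol {sym!r}", line=lineno + 1)
            try:
                coords[j] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise FormatError(
                    f"bad coordinate in {lines[lineno]!r}", line=lineno + 1
                )
            elements.append(sym)
        frames.append((elements, coords, comment))
        i += 2 + natoms
    if not frames:
        raise FormatError("no frames in XYZ file", line=1)
    return frames


def write_xyz(path: str | Path, frames: Iterable[XYZFrame]) -> None:
    """Write frames as multi-frame XYZ with 6-decimal coordinates."""
    out: list[str] = []
    for elements, coords, comment in frames:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(elements), 3):
            raise InputError("elements/coordinates shape mismatch")
        out.append(str(len(elements)))
        out.append(comment.replace("\n", " "))
        for sym, (x, y, z) in zip(elements, coords):
            out.append(f"{sym:<3s} {x:15.6f} {y:15.6f} {z:15.6f}")
    Path(path).write_text("\n".join(out) + "\n")


def ensemble_to_frames(ensemble: ConformerEnsemble) -> list[XYZFrame]:
    elements = ensemble.record.elements
    return [
        (elements, c.coordinates, f"{ensemble.record.id} E={c.energy:.10f} Eh")
        for c in ensemble.conformers
    ]


def read_sdf(path: str | Path) -> list[Chem.Mol]:
    """Read an SDF (V2000) file into RDKit molecules with coordinates."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"cannot read {path}: no such file")
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    mols = [m for m in supplier if m is not None]
    if not mols:
        raise FormatError(f"no valid molecules in {path}", line=1)
    return mols


def write_rejects(path: str | Path, rejects: Sequence[Reject]) -> None:
    """Write the rejects report as tab-delimited text (id, line, reason)."""
    lines = ["id\tline\treason"]
    lines += [f"{r.id}\t{r.line}\t{r.reason}" for r in rejects]
    Path(path).write_text("\n".join(lines) + "\n")
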