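"""Structure input: PDB parsing, solvent accessibility, surface flags, contacts.

Single-chain antigen structures are represented by light dataclasses rather
than wrapping a full ``Bio.PDB`` entity tree: downstream feature code only
needs per-residue heavy-atom coordinates, SASA, and surface flags.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

log = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "AntigenStructure",
    "EpitopeLabeling",
    "StructureError",
    "ChainNotFoundError",
    "EmptyChainError",
    "parse_structure",
    "compute_sasa",
    "flag_surface",
    "residue_distance",
    "label_epitopes",
    "MIN_TRAINING_RESIDUES",
    "DEFAULT_SURFACE_RASA",
    "DEFAULT_CONTACT_CUTOFF",
]

#: structures at or below this residue count are rejected for training/prediction
MIN_TRAINING_RESIDUES = 50
DEFAULT_SURFACE_RASA = 0.15
DEFAULT_CONTACT_CUTOFF = 4.0
DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_SASA_POINTS = 960

# van der Waals radii (A) for heavy elements; fallback covers rare elements
_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}
_VDW_DEFAULT = 1.70


class StructureError(ValueError):
    """Base class for structure input errors."""


class ChainNotFoundError(StructureError):
    pass


class EmptyChainError(StructureError):
    pass


@dataclass
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")


@dataclass
class ResidueRecord:
    chain_id: str
    seq_id: str  # author residue number + insertion code
    aa: str  # one-letter, 'X' for unmapped
    atoms: list[AtomRecord] = field(default_factory=list)
    sasa: float | None = None
    rasa: float | None = None
    is_surface: bool | None = None

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class AntigenStructure:
    pdb_id: str
    chain_id: str
    residues: list[ResidueRecord]

    # lazily built caches, invalidated by _invalidate()
    _distmat: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def surface_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.residues) if r.is_surface]

    def qualifies_for_training(self) -> bool:
        return len(self.residues) > MIN_TRAINING_RESIDUES

    def _invalidate(self) -> None:
        self._distmat = None

    def distance_matrix(self) -> np.ndarray:
        """Pairwise minimum heavy-atom distance between residues (cached)."""
        if self._distmat is None:
            n = len(self.residues)
            counts = [len(r.atoms) for r in self.residues]
            if any(c == 0 for c in counts):
                raise StructureError("residue with no atoms in distance computation")
            coords = np.concatenate([r.coords() for r in self.residues])
            owner = np.repeat(np.arange(n), counts)
            d = cdist(coords, coords)
            out = np.full((n, n), np.inf)
            np.minimum.at(out, (owner[:, None], owner[None, :]), d)
            self._distmat = out
        return self._distmat


@dataclass
class EpitopeLabeling:
    structure_key: tuple[str, str]
    labels: list[bool]
    n_positive: int
    n_negative_surface: int

    @classmethod
    def from_labels(cls, structure: AntigenStructure, labels: list[bool]) -> "EpitopeLabeling":
        n_pos = sum(labels)
        n_neg = sum(
            1 for r, lab in zip(structure.residues, labels) if r.is_surface and not lab
        )
        return cls((structure.pdb_id, structure.chain_id), list(labels), n_pos, n_neg)


# ---------------------------------------------------------------------------
# parsing

def _three_to_one() -> dict[str, str]:
    try:
        from Bio.Data.PDBData import protein_letters_3to1_extended as table
    except ImportError:  # older biopython layouts
        from Bio.PDB.Polypeptide import protein_letters_3to1_extended as table
    return {k.upper(): v for k, v in table.items() if len(v) == 1 and v.isupper()}


_AA3TO1 = None
_WATERS = {"HOH", "WAT", "DOD", "H2O"}
_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def parse_structure(pdb_text: str, chain_id: str, model_index: int = 0) -> AntigenStructure:
    """Parse one chain of a PDB-format string into an :class:`AntigenStructure`.

    Hydrogens and waters are dropped; HETATM residues are kept only when they
    map onto a standard amino acid (e.g. MSE -> M); unmapped polymer residues
    become ``'X'``. For alternate locations the highest-occupancy conformer of
    each atom is retained.
    """
    global _AA3TO1
    if _AA3TO1 is None:
        _AA3TO1 = _three_to_one()

    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parser = PDBParser(QUIET=True)
        bio_struct = parser.get_structure("antigen", io.StringIO(pdb_text))

    models = list(bio_struct)
    if not models:
        raise EmptyChainError("empty chain")
    model = models[min(model_index, len(models) - 1)]
    chain_ids = [c.id for c in model]
    if chain_id not in chain_ids:
        raise ChainNotFoundError(f"chain not found: {chain_id!r} (have {chain_ids})")
    chain = model[chain_id]

    residues: list[ResidueRecord] = []
    for res in chain:
        hetflag, resseq, icode = res.id
        resname = res.get_resname().strip().upper()
        if resname in _WATERS:
            continue
        one = _AA3TO1.get(resname)
        if one not in _STANDARD_AA:
            if hetflag.strip():  # ligand HETATM with no amino-acid mapping
                continue
            one = "X"
        atoms: dict[str, AtomRecord] = {}
        for atom in res.get_unpacked_list():
            element = (atom.element or "").strip().upper()
            if element in ("H", "D", ""):
                continue
            occ = atom.get_occupancy()
            occ = 1.0 if occ is None else float(occ)
            rec = AtomRecord(
                name=atom.get_name(),
                element=element,
                coords=atom.get_coord(),
                altloc=atom.get_altloc().strip(),
                occupancy=occ,
            )
            prev = atoms.get(rec.name)
            if prev is None or rec.occupancy > prev.occupancy:
                atoms[rec.name] = rec
        if not atoms:
            continue
        seq_id = f"{resseq}{icode.strip()}"
        residues.append(
            ResidueRecord(chain_id=chain_id, seq_id=seq_id, aa=one, atoms=list(atoms.values()))
        )
    if not residues:
        raise EmptyChainError("empty chain")
    return AntigenStructure(pdb_id="query", chain_id=chain_id, residues=residues)


# ---------------------------------------------------------------------------
# solvent accessibility (Shrake-Rupley with a deterministic spiral)

def _spiral_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _load_max_sasa() -> dict[str, float]:
    text = resources.files("glycep.data").joinpath("max_sasa.json").read_text()
    return json.loads(text)["values"]


_MAX_SASA: dict[str, float] | None = None


def compute_sasa(
    structure: AntigenStructure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
) -> AntigenStructure:
    """Populate per-residue ``sasa`` and ``rasa`` via Shrake-Rupley sampling.

    The sampling sphere is a fixed golden spiral, so results are bit-identical
    across runs for the same coordinates and ``n_points``.
    """
    global _MAX_SASA
    if _MAX_SASA is None:
        _MAX_SASA = _load_max_sasa()

    kept: list[ResidueRecord] = []
    for res in structure.residues:
        if not res.atoms:
            log.warning("residue %s has no atoms; excluded from SASA", res.seq_id)
            continue
        kept.append(res)
    structure.residues = kept
    structure._invalidate()

    coords = np.concatenate([r.coords() for r in kept])
    radii = np.array(
        [_VDW_RADII.get(a.element, _VDW_DEFAULT) for r in kept for a in r.atoms]
    )
    ext = radii + probe_radius
    sphere = _spiral_points(n_points)

    tree = cKDTree(coords)
    max_reach = 2.0 * ext.max()
    atom_areas = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        if neigh:
            nb = np.asarray(neigh)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (ext[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        atom_areas[i] = 4.0 * np.pi * ext[i] ** 2 * frac

    offset = 0
    for res in kept:
        n_at = len(res.atoms)
        res.sasa = float(atom_areas[offset : offset + n_at].sum())
        ref = _MAX_SASA.get(res.aa, _MAX_SASA["G"])
        res.rasa = res.sasa / ref
        offset += n_at
    return structure


def flag_surface(
    structure: AntigenStructure, rasa_threshold: float = DEFAULT_SURFACE_RASA
) -> AntigenStructure:
    """Set ``is_surface`` from relative SASA; returns the structure."""
    if any(r.rasa is None for r in structure.residues):
        raise StructureError("SASA not computed; call compute_sasa first")
    n_surface = 0
    for res in structure.residues:
        res.is_surface = res.rasa >= rasa_threshold
        n_surface += res.is_surface
    log.info("%d/%d surface residues (rasa >= %.3g)", n_surface, len(structure), rasa_threshold)
    return structure


def residue_distance(r1: ResidueRecord, r2: ResidueRecord) -> float:
    """Minimum heavy-atom to heavy-atom Euclidean distance."""
    if not r1.atoms or not r2.atoms:
        raise StructureError("residue with empty atom list")
    return float(cdist(r1.coords(), r2.coords()).min())


def label_epitopes(
    antigen: AntigenStructure,
    antibody_chains: list[AntigenStructure],
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> EpitopeLabeling:
    """Label surface residues contacting any binder heavy atom within cutoff."""
    if not antibody_chains:
        raise StructureError("no binder provided")
    if any(r.is_surface is None for r in antigen.residues):
        raise StructureError("surface flags not computed; call flag_surface first")
    ab_coords = np.concatenate([r.coords() for ch in antibody_chains for r in ch.residues])
    tree = cKDTree(ab_coords)
    labels = []
    for res in antigen.residues:
        if not res.is_surface:
            labels.append(False)
            continue
        d, _ = tree.query(res.coords(), k=1)
        labels.append(bool(np.min(d) <= contact_cutoff))
    return EpitopeLabeling.from_labels(antigen, labels)
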