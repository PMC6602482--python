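"""Seeded toy antigen generator.

Residues are placed on a jittered spherical lattice (one pseudo C-alpha plus
1-3 inward dummy side atoms), a contiguous surface cap is planted as the
epitope patch, and Asn-X-Ser/Thr sequons are written into the sequence with a
configurable enrichment inside the patch. Everything is deterministic in the
spec seed and round-trips through the PDB parser.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .glyco import SequonMap, find_sequons
from .structure_io import (
    AntigenStructure,
    AtomRecord,
    EpitopeLabeling,
    ResidueRecord,
    compute_sasa,
    flag_surface,
    parse_structure,
)

__all__ = ["SynthSpec", "SyntheticAntigen", "generate_antigen", "generate_complex", "generate_corpus"]

_AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_AAS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SynthSpec:
    n_residues: int = 80
    epitope_patch_fraction: float = 0.22
    epitope_patch_radius: float | None = None  # Angstrom along the sphere; overrides fraction
    n_sequons: int = 6
    sequon_epitope_enrichment: float = 1.0
    composition_bias: dict[str, float] = field(
        default_factory=lambda: {"Y": 3.0, "W": 3.0, "K": 2.0, "R": 2.0}
    )
    noise_sd: float = 0.3
    lattice_spacing: float = 7.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues <= 50:
            raise ValueError("n_residues must exceed 50")
        if self.sequon_epitope_enrichment < 1.0:
            raise ValueError("enrichment must be >= 1")


@dataclass
class SyntheticAntigen:
    pdb_id: str
    pdb_text: str
    sequence: str
    planted_epitope: list[bool]
    planted_sequons: list[int]
    spec: SynthSpec

    def to_structure(
        self, surface_threshold: float = 0.15, sasa_points: int = 240
    ) -> AntigenStructure:
        s = parse_structure(self.pdb_text, chain_id="A")
        s.pdb_id = self.pdb_id
        compute_sasa(s, n_points=sasa_points)
        flag_surface(s, surface_threshold)
        return s

    def labeling(self, structure: AntigenStructure) -> EpitopeLabeling:
        # epitope membership is a surface property: buried lattice residues
        # inside the planted cap are not labeled positive
        labels = [
            planted and bool(res.is_surface)
            for planted, res in zip(self.planted_epitope, structure.residues)
        ]
        return EpitopeLabeling.from_labels(structure, labels)

    def sequons(self) -> SequonMap:
        return find_sequons(self.sequence)


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _format_atom(serial, name, resname, chain, resseq, xyz, element) -> str:
    return (
        f"ATOM  {serial:5d} {name:<4s}{'':1s}{resname:3s} {chain:1s}{resseq:4d}{'':1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def _sample_sequence(rng, n, in_patch, bias) -> list[str]:
    base = np.ones(len(_AAS))
    boosted = base.copy()
    for aa, w in bias.items():
        boosted[_AAS.index(aa)] = w
    seq = []
    for i in range(n):
        p = boosted if in_patch[i] else base
        seq.append(_AAS[rng.choice(len(_AAS), p=p / p.sum())])
    return seq


def _plant_sequons(rng, seq, in_patch, spec) -> list[int]:
    n = len(seq)
    candidates = list(range(0, n - 2))
    weights = np.array(
        [spec.sequon_epitope_enrichment if in_patch[i] else 1.0 for i in candidates]
    )
    planted: list[int] = []
    attempts = 0
    while len(planted) < spec.n_sequons:
        attempts += 1
        if attempts > 10000 or not candidates:
            raise ValueError("infeasible spec: cannot place requested sequons")
        j = rng.choice(len(candidates), p=weights / weights.sum())
        i = candidates[j]
        if any(abs(i - q) < 3 for q in planted):
            continue
        planted.append(i)
        seq[i] = "N"
        x = _AAS[rng.integers(len(_AAS))]
        while x == "P":
            x = _AAS[rng.integers(len(_AAS))]
        seq[i + 1] = x
        seq[i + 2] = "S" if rng.random() < 0.5 else "T"
    return sorted(planted)


def benchmark_spec() -> SynthSpec:
    """Template for the planted-signal benchmark corpus.

    A dense lattice (so the 5 A calibration neighborhood is populated), strong
    sequon enrichment inside the patch, and a mild composition bias, so signal
    flows through both the glycosylation features and the general ones.
    """
    return SynthSpec(
        lattice_spacing=5.0,
        sequon_epitope_enrichment=8.0,
        n_sequons=10,
        composition_bias={"Y": 2.0, "W": 2.0},
    )


def generate_antigen(spec: SynthSpec) -> SyntheticAntigen:
    """Deterministically build one toy antigen from the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    radius = spec.lattice_spacing * np.sqrt(np.sqrt(3.0) * n / (8.0 * np.pi))
    units = _fibonacci_sphere(n)
    coords = units * radius + rng.normal(0.0, spec.noise_sd, size=(n, 3))

    if spec.epitope_patch_radius is not None:
        theta_max = spec.epitope_patch_radius / radius
    else:
        theta_max = np.arccos(1.0 - 2.0 * spec.epitope_patch_fraction)
    theta = np.arccos(np.clip(units[:, 2], -1.0, 1.0))
    in_patch = (theta <= theta_max).tolist()

    seq = _sample_sequence(rng, n, in_patch, spec.composition_bias)
    planted = _plant_sequons(rng, seq, in_patch, spec)

    lines = []
    serial = 1
    side_names = ["CB", "CG", "CD"]
    side_elements = ["C", "N", "O"]
    for i in range(n):
        resname = _AA1TO3[seq[i]]
        lines.append(_format_atom(serial, "CA", resname, "A", i + 1, coords[i], "C"))
        serial += 1
        unit = units[i]
        for si in range(int(rng.integers(1, 4))):
            depth = rng.uniform(0.8, 1.4)
            tangent = rng.normal(0.0, 0.3, size=3)
            tangent -= tangent.dot(unit) * unit
            pos = coords[i] - unit * depth + tangent
            el = side_elements[int(rng.integers(len(side_elements)))]
            lines.append(_format_atom(serial, side_names[si], resname, "A", i + 1, pos, el))
            serial += 1
    lines.append("TER")
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    return SyntheticAntigen(
        pdb_id=f"SYN{spec.seed:04d}",
        pdb_text=pdb_text,
        sequence="".join(seq),
        planted_epitope=in_patch,
        planted_sequons=planted,
        spec=spec,
    )


def generate_complex(spec: SynthSpec) -> tuple[SyntheticAntigen, AntigenStructure]:
    """Antigen plus a pseudo-binder chain hugging the planted patch.

    One binder atom sits 3.6-3.9 A radially above each patch residue's
    C-alpha (whose side atoms point inward), so a 4 A contact cutoff recovers
    the patch exactly while non-patch residues stay well out of range.
    """
    antigen = generate_antigen(spec)
    rng = np.random.default_rng(spec.seed + 1_000_003)
    structure = parse_structure(antigen.pdb_text, chain_id="A")
    n = len(structure)
    units = _fibonacci_sphere(n)
    binder_residues = []
    for i, flagged in enumerate(antigen.planted_epitope):
        if not flagged:
            continue
        ca = structure.residues[i].atoms[0].coords
        d = rng.uniform(3.6, 3.9)
        pos = ca + units[i] * d
        binder_residues.append(
            ResidueRecord(
                chain_id="B",
                seq_id=str(len(binder_residues) + 1),
                aa="G",
                atoms=[AtomRecord(name="CA", element="C", coords=pos)],
            )
        )
    binder = AntigenStructure(pdb_id=antigen.pdb_id, chain_id="B", residues=binder_residues)
    return antigen, binder


def generate_corpus(
    n_structures: int,
    spec_template: SynthSpec | None = None,
    seed: int = 0,
    sasa_points: int = 240,
) -> tuple[list[tuple[AntigenStructure, EpitopeLabeling, SequonMap]], dict]:
    """Independent antigens with derived per-structure seeds, plus a manifest."""
    if n_structures < 2:
        raise ValueError("corpus needs at least 2 structures")
    template = spec_template or SynthSpec()
    corpus = []
    entries = []
    children = np.random.SeedSequence(seed).spawn(n_structures)
    for k in range(n_structures):
        child_seed = int(children[k].generate_state(1)[0] % (2**31))
        spec = SynthSpec(
            n_residues=template.n_residues,
            epitope_patch_fraction=template.epitope_patch_fraction,
            epitope_patch_radius=template.epitope_patch_radius,
            n_sequons=template.n_sequons,
            sequon_epitope_enrichment=template.sequon_epitope_enrichment,
            composition_bias=dict(template.composition_bias),
            noise_sd=template.noise_sd,
            lattice_spacing=template.lattice_spacing,
            seed=child_seed,
        )
        antigen = generate_antigen(spec)
        structure = antigen.to_structure(sasa_points=sasa_points)
        structure.pdb_id = f"SYN{k:03d}"
        labeling = antigen.labeling(structure)
        sequons = antigen.sequons()
        corpus.append((structure, labeling, sequons))
        entries.append(
            {
                "pdb_id": structure.pdb_id,
                "seed": child_seed,
                "n_residues": len(structure),
                "n_epitope": labeling.n_positive,
                "n_sequons": len(sequons),
                "pdb_sha256": hashlib.sha256(antigen.pdb_text.encode()).hexdigest(),
            }
        )
    manifest = {
        "seed": seed,
        "n_structures": n_structures,
        "structures": entries,
    }
    manifest["manifest_sha256"] = hashlib.sha256(
        json.dumps(entries, sort_keys=True).encode()
    ).hexdigest()
    return corpus, manifest
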