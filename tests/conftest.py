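import numpy as np
import pytest

from glycep import model as M
from glycep import structure_io as sio
from glycep.structure_io import AntigenStructure, AtomRecord, ResidueRecord
from glycep.synthetic import SynthSpec, benchmark_spec, generate_antigen, generate_corpus


def _atom_line(serial, name, alt, resname, chain, resseq, x, y, z, occ, element):
    return (
        f"ATOM  {serial:5d} {name:<4s}{alt:1s}{resname:3s} {chain:1s}{resseq:4d}{'':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}"
    )


@pytest.fixture
def tri_pdb_text():
    """Minimal 3-residue chain A plus one chain B residue and a water."""
    lines = [
        _atom_line(1, "N", " ", "ALA", "A", 1, 0.0, 0.0, 0.0, 1.0, "N"),
        _atom_line(2, "CA", " ", "ALA", "A", 1, 1.5, 0.0, 0.0, 1.0, "C"),
        _atom_line(3, "CA", " ", "GLY", "A", 2, 5.0, 0.0, 0.0, 1.0, "C"),
        _atom_line(4, "CA", " ", "SER", "A", 3, 10.0, 0.0, 0.0, 1.0, "C"),
        _atom_line(5, "CA", " ", "GLY", "B", 1, 30.0, 0.0, 0.0, 1.0, "C"),
        "HETATM    6  O   HOH A 401      20.000  20.000  20.000  1.00  0.00           O",
        "TER",
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def altloc_pdb_text():
    lines = [
        _atom_line(1, "CA", "A", "ALA", "A", 1, 0.0, 0.0, 0.0, 0.6, "C"),
        _atom_line(2, "CA", "B", "ALA", "A", 1, 0.5, 0.0, 0.0, 0.4, "C"),
        _atom_line(3, "CB", "A", "ALA", "A", 1, 1.5, 0.0, 0.0, 0.6, "C"),
        _atom_line(4, "CB", "B", "ALA", "A", 1, 2.0, 0.0, 0.0, 0.4, "C"),
        _atom_line(5, "CA", " ", "GLY", "A", 2, 5.0, 0.0, 0.0, 1.0, "C"),
        "END",
    ]
    return "\n".join(lines) + "\n"


def make_point_structure(coords, aas=None, surface=None, rasa=None, pdb_id="TEST"):
    """Build a bare structure from single-atom residues at given coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    aas = aas or "A" * n
    residues = []
    for i in range(n):
        residues.append(
            ResidueRecord(
                chain_id="A",
                seq_id=str(i + 1),
                aa=aas[i],
                atoms=[AtomRecord(name="CA", element="C", coords=coords[i])],
                sasa=100.0,
                rasa=0.5 if rasa is None else rasa[i],
                is_surface=True if surface is None else bool(surface[i]),
            )
        )
    return AntigenStructure(pdb_id=pdb_id, chain_id="A", residues=residues)


def quick_structure(spec):
    """Synthetic antigen as a structure without the SASA pass (all surface)."""
    antigen = generate_antigen(spec)
    s = sio.parse_structure(antigen.pdb_text, chain_id="A")
    s.pdb_id = antigen.pdb_id
    for r in s.residues:
        r.sasa, r.rasa, r.is_surface = 100.0, 0.5, True
    return antigen, s


def hand_corpus():
    """Five 4-residue structures on a 10 A grid with hand-counted triangle census.

    Geometry: residues at (0,0),(10,0),(0,10),(10,10) -- every triple is a
    triangle (max pairwise distance 14.14 A). Expected ratio table derived by
    hand from the sequences/labels below:
      AG|NQ|ST  -> (3, 4, 0.75)
      AG|AG|NQ  -> (2, 2, 1.0)
      NQ|ST|ST  -> (2, 3, 2/3)
      NQ|ST|Y   -> (0, 2, 0.0)
      NQ|NQ|ST  -> (2, 2, 1.0)
    """
    from glycep.glyco import find_sequons
    from glycep.structure_io import EpitopeLabeling

    grid = [[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 10.0, 0.0], [10.0, 10.0, 0.0]]
    cases = [
        ("NASA", [True, True, False, False]),
        ("NTSY", [False, False, False, False]),
        ("ANAS", [True, False, True, True]),
        ("AYWK", [False, True, False, False]),
        ("NNSS", [True, True, True, False]),
    ]
    corpus = []
    for k, (seq, labels) in enumerate(cases):
        s = make_point_structure(grid, aas=seq, pdb_id=f"HAND{k}")
        corpus.append((s, EpitopeLabeling.from_labels(s, labels), find_sequons(seq)))
    expected = {
        "AG|NQ|ST": (3, 4, 0.75),
        "AG|AG|NQ": (2, 2, 1.0),
        "NQ|ST|ST": (2, 3, 2.0 / 3.0),
        "NQ|ST|Y": (0, 2, 0.0),
        "NQ|NQ|ST": (2, 2, 1.0),
    }
    return corpus, expected


@pytest.fixture(scope="session")
def default_antigen():
    return generate_antigen(SynthSpec(seed=1))


@pytest.fixture(scope="session")
def default_structure(default_antigen):
    return default_antigen.to_structure()


@pytest.fixture(scope="session")
def small_corpus():
    """8-structure labeled training corpus (tuned benchmark template)."""
    corpus, _ = generate_corpus(8, benchmark_spec(), seed=11)
    return corpus


@pytest.fixture(scope="session")
def trained_model(small_corpus):
    return M.train(small_corpus, seed=0)


@pytest.fixture(scope="session")
def bench_corpus():
    """20-structure planted-signal corpus for the end-to-end benchmark."""
    corpus, manifest = generate_corpus(20, benchmark_spec(), seed=1)
    return corpus, manifest


@pytest.fixture(scope="session")
def bench_ingredients(bench_corpus):
    corpus, _ = bench_corpus
    return M.corpus_ingredients(corpus)


@pytest.fixture(scope="session")
def bench_cv(bench_corpus, bench_ingredients):
    corpus, _ = bench_corpus
    return M.cross_validate(corpus, folds=10, seed=0, _ingredients=bench_ingredients)


@pytest.fixture(scope="session")
def bench_cv_ablated(bench_corpus, bench_ingredients):
    corpus, _ = bench_corpus
    return M.cross_validate(
        corpus, folds=10, seed=0, ablate_glyco=True, _ingredients=bench_ingredients
    )
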