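"""Per-residue micro-environment classifiers.

Six values feed the final regression for every surface residue: triangle
propensity (avg), patch relative-ASA (apref), clustering coefficient (cc),
neighborhood amino-acid-index mean (index), consolidated glycosylation-
triangle score (glytri), and consolidated shell-model glycosylation index
(glyindex).

The triangle-propensity, patch-ASA and neighborhood-index formulas of the
earlier tool generations are not published; the versions here are documented
reconstructions (corpus-frequency log-odds, patch-mean rasa, neighborhood-
mean index) with configuration hooks.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .glyco import (
    SequonMap,
    SubgroupTable,
    PatternRatioTable,
    all_surface_triangles,
    mark_glyco,
    TRIANGLE_MAX_DIST,
)
from .structure_io import AntigenStructure, EpitopeLabeling

__all__ = [
    "AAIndexTable",
    "ShellProfile",
    "FeatureVector",
    "ANNConsolidator",
    "TrianglePropensityTable",
    "StructureIngredients",
    "load_default_aaindex_tables",
    "DEFAULT_AAINDEX_ACCESSIONS",
    "SHELL_RADIUS",
    "SHELL_STEP",
    "N_SHELL_LAYERS",
    "PROPENSITY_EPS",
    "build_propensity_table",
    "propensity_avg",
    "relative_asa_pref",
    "clustering_coeff",
    "consolidated_aaindex",
    "glytri_weights",
    "consolidate_glytri",
    "shell_profile",
    "consolidate_glyindex",
    "extract_ingredients",
    "featurize",
    "FEATURE_NAMES",
]

DEFAULT_AAINDEX_ACCESSIONS = ("KIMC930101", "LAWE840101", "RICJ880102", "ROBB760113")
SHELL_RADIUS = 10.0
SHELL_STEP = 2.0
N_SHELL_LAYERS = int(SHELL_RADIUS / SHELL_STEP)
PROPENSITY_EPS = 1e-6
FEATURE_NAMES = ("avg", "apref", "cc", "index", "glytri", "glyindex")


class AAIndexTable:
    """One amino-acid index, z-scored over the 20 standard residues at load."""

    def __init__(self, accession: str, values: dict[str, float]):
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(values)
        if missing:
            raise ValueError(f"{accession}: missing residues {sorted(missing)}")
        self.accession = accession
        arr = np.array([values[a] for a in "ACDEFGHIKLMNPQRSTVWY"], dtype=float)
        std = arr.std()
        if std == 0:
            raise ValueError(f"{accession}: constant index")
        zs = (arr - arr.mean()) / std
        self.values = dict(zip("ACDEFGHIKLMNPQRSTVWY", zs.tolist()))

    def value(self, aa: str) -> float:
        # unknown residues sit at the standardized mean
        return self.values.get(aa, 0.0)

    @classmethod
    def from_text(cls, accession: str, text: str) -> "AAIndexTable":
        values: dict[str, float] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            m = re.match(r"^([A-Z])\s+(-?\d+(?:\.\d+)?)$", line)
            if not m:
                raise ValueError(f"{accession}: malformed line {line!r}")
            values[m.group(1)] = float(m.group(2))
        return cls(accession, values)


def load_default_aaindex_tables() -> list[AAIndexTable]:
    tables = []
    for acc in DEFAULT_AAINDEX_ACCESSIONS:
        text = resources.files("glycep.data.aaindex").joinpath(f"{acc}.txt").read_text()
        tables.append(AAIndexTable.from_text(acc, text))
    return tables


@dataclass
class ShellProfile:
    """Layered neighbor-index means around one residue (center excluded)."""

    residue_index: int
    layer_means: np.ndarray  # (n_layers, n_tables)
    layer_counts: np.ndarray  # (n_layers,)


@dataclass
class FeatureVector:
    avg: float
    apref: float
    cc: float
    index: float
    glytri: float
    glyindex: float

    def as_array(self) -> np.ndarray:
        return np.array([self.avg, self.apref, self.cc, self.index, self.glytri, self.glyindex])


class DimensionMismatchError(ValueError):
    pass


class ANNConsolidator:
    """One-hidden-layer (10 logistic units) scalar consolidator.

    Trained via scikit-learn's MLP against binary labels; scoring is an
    explicit forward pass over the stored weights so serialized models do not
    depend on estimator internals.
    """

    def __init__(self, weights: list[np.ndarray], biases: list[np.ndarray], n_inputs: int):
        self.weights = weights
        self.biases = biases
        self.n_inputs = n_inputs

    @classmethod
    def train(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        seed: int = 0,
        hidden_units: int = 10,
        max_iter: int = 300,
    ) -> "ANNConsolidator":
        from sklearn.neural_network import MLPClassifier

        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate labels: single class")
        early = bool(min(np.bincount(y)) >= 10)
        clf = MLPClassifier(
            hidden_layer_sizes=(hidden_units,),
            activation="logistic",
            solver="adam",
            max_iter=max_iter,
            random_state=seed,
            early_stopping=early,
            n_iter_no_change=10,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, y)
        return cls(
            weights=[w.copy() for w in clf.coefs_],
            biases=[b.copy() for b in clf.intercepts_],
            n_inputs=X.shape[1],
        )

    @staticmethod
    def _sigmoid(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))

    def score(self, vec: np.ndarray) -> float:
        return float(self.score_many(np.asarray(vec, dtype=float)[None, :])[0])

    def score_many(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise DimensionMismatchError(
                f"pattern dimension mismatch: got {X.shape[1]}, expected {self.n_inputs}"
            )
        h = self._sigmoid(X @ self.weights[0] + self.biases[0])
        out = self._sigmoid(h @ self.weights[1] + self.biases[1])
        return out.ravel()


@dataclass
class TrianglePropensityTable:
    """Pattern -> log((f_epi+eps)/(f_surf+eps)) over the training corpus."""

    scores: dict[str, float] = field(default_factory=dict)

    def score(self, pattern: str | None) -> float:
        if pattern is None:
            return 0.0
        return self.scores.get(pattern, 0.0)


def build_propensity_table(
    training: list[tuple[AntigenStructure, EpitopeLabeling, SequonMap]],
    max_dist: float = TRIANGLE_MAX_DIST,
    subgroups: SubgroupTable | None = None,
    eps: float = PROPENSITY_EPS,
) -> TrianglePropensityTable:
    """Corpus log-odds of each triangle pattern among epitope vs all surface triangles.

    An epitope triangle has >= 2 epitope-labeled members.
    """
    subgroups = subgroups or SubgroupTable.default()
    surf_counts: Counter[str] = Counter()
    epi_counts: Counter[str] = Counter()
    for structure, labeling, _ in training:
        for tri in all_surface_triangles(structure, max_dist=max_dist, subgroups=subgroups):
            if tri.pattern is None:
                continue
            surf_counts[tri.pattern] += 1
            if sum(1 for m in tri.members if labeling.labels[m]) >= 2:
                epi_counts[tri.pattern] += 1
    n_surf = sum(surf_counts.values())
    n_epi = sum(epi_counts.values())
    if n_surf == 0:
        raise ValueError("no surface triangles in corpus")
    scores = {}
    for p, c in surf_counts.items():
        f_surf = c / n_surf
        f_epi = (epi_counts.get(p, 0) / n_epi) if n_epi else 0.0
        scores[p] = float(np.log((f_epi + eps) / (f_surf + eps)))
    return TrianglePropensityTable(scores=scores)


# ---------------------------------------------------------------------------
# per-structure geometric ingredients (label-free, reusable across CV folds)


@dataclass
class StructureIngredients:
    """Label-free geometry/composition summaries feeding every classifier."""

    structure: AntigenStructure
    sequons: SequonMap
    surface: list[int]
    triangles: list  # unique SurfaceTriangle list, glytri-marked
    tri_patterns: dict[int, list[str | None]]  # residue -> patterns of its triangles
    tri_members: dict[int, set[int]]  # residue -> union of member indices
    glytri_census: dict[int, Counter]  # residue -> Counter(pattern -> N_occur)
    cc: dict[int, float]
    index: dict[int, float]
    shell: dict[int, np.ndarray]  # residue -> flattened (n_tables * n_layers)


def clustering_coeff(
    structure: AntigenStructure, center: int, contact_dist: float = TRIANGLE_MAX_DIST
) -> float:
    """Local clustering coefficient of the surface contact graph at ``center``."""
    dist = structure.distance_matrix()
    surf = structure.surface_indices
    neigh = [j for j in surf if j != center and dist[center, j] <= contact_dist]
    k = len(neigh)
    if k < 2:
        return 0.0
    links = sum(
        1
        for ia, a in enumerate(neigh)
        for b in neigh[ia + 1 :]
        if dist[a, b] <= contact_dist
    )
    return links / (k * (k - 1) / 2)


def consolidated_aaindex(
    structure: AntigenStructure,
    center: int,
    tables: list[AAIndexTable],
    contact_dist: float = TRIANGLE_MAX_DIST,
) -> float:
    """Mean (over tables) of the mean index over the contact neighborhood, center included."""
    dist = structure.distance_matrix()
    surf = structure.surface_indices
    members = [j for j in surf if dist[center, j] <= contact_dist and j != center] + [center]
    aas = [structure.residues[j].aa for j in members]
    return float(np.mean([np.mean([t.value(a) for a in aas]) for t in tables]))


def shell_profile(
    structure: AntigenStructure,
    center: int,
    tables: list[AAIndexTable],
    radius: float = SHELL_RADIUS,
    step: float = SHELL_STEP,
) -> ShellProfile:
    """Mean index per distance layer [0,2),[2,4),... around ``center`` (center excluded)."""
    n_layers = int(round(radius / step))
    dist = structure.distance_matrix()
    means = np.zeros((n_layers, len(tables)))
    counts = np.zeros(n_layers, dtype=int)
    binned: list[list[int]] = [[] for _ in range(n_layers)]
    for j in range(len(structure.residues)):
        if j == center:
            continue
        d = dist[center, j]
        if d < radius:
            binned[int(d // step)].append(j)
    for li, idxs in enumerate(binned):
        counts[li] = len(idxs)
        if idxs:
            aas = [structure.residues[j].aa for j in idxs]
            for ti, t in enumerate(tables):
                means[li, ti] = np.mean([t.value(a) for a in aas])
    return ShellProfile(residue_index=center, layer_means=means, layer_counts=counts)


def extract_ingredients(
    structure: AntigenStructure,
    sequons: SequonMap,
    tables: list[AAIndexTable] | None = None,
    subgroups: SubgroupTable | None = None,
    max_dist: float = TRIANGLE_MAX_DIST,
) -> StructureIngredients:
    tables = tables if tables is not None else load_default_aaindex_tables()
    subgroups = subgroups or SubgroupTable.default()
    surf = structure.surface_indices
    tris = all_surface_triangles(structure, max_dist=max_dist, subgroups=subgroups)
    mark_glyco(tris, sequons)

    tri_patterns: dict[int, list[str | None]] = {i: [] for i in surf}
    tri_members: dict[int, set[int]] = {i: set() for i in surf}
    glytri_census: dict[int, Counter] = {i: Counter() for i in surf}
    for tri in tris:
        for m in tri.members:
            tri_patterns[m].append(tri.pattern)
            tri_members[m].update(tri.members)
            if tri.is_glytri and tri.pattern is not None:
                glytri_census[m][tri.pattern] += 1

    cc = {i: clustering_coeff(structure, i, contact_dist=max_dist) for i in surf}
    index = {i: consolidated_aaindex(structure, i, tables, contact_dist=max_dist) for i in surf}
    shell = {
        i: shell_profile(structure, i, tables).layer_means.T.ravel().copy() for i in surf
    }
    return StructureIngredients(
        structure=structure,
        sequons=sequons,
        surface=surf,
        triangles=tris,
        tri_patterns=tri_patterns,
        tri_members=tri_members,
        glytri_census=glytri_census,
        cc=cc,
        index=index,
        shell=shell,
    )


# ---------------------------------------------------------------------------
# spec-level single-residue operations


def propensity_avg(
    structure: AntigenStructure,
    center: int,
    propensity_table: TrianglePropensityTable,
    subgroups: SubgroupTable | None = None,
    max_dist: float = TRIANGLE_MAX_DIST,
) -> float:
    """Mean pattern log-odds over all unit triangles containing ``center``; 0 if none."""
    from .glyco import enumerate_triangles

    tris = enumerate_triangles(structure, center, max_dist=max_dist, subgroups=subgroups)
    if not tris:
        return 0.0
    return float(np.mean([propensity_table.score(t.pattern) for t in tris]))


def relative_asa_pref(
    structure: AntigenStructure,
    center: int,
    max_dist: float = TRIANGLE_MAX_DIST,
) -> float:
    """Mean relative SASA over the residues of the center's unit triangles (center included)."""
    from .glyco import enumerate_triangles

    members: set[int] = {center}
    for tri in enumerate_triangles(structure, center, max_dist=max_dist):
        members.update(tri.members)
    return float(np.mean([structure.residues[j].rasa for j in sorted(members)]))


def glytri_weights(
    structure: AntigenStructure,
    center: int,
    sequons: SequonMap,
    ratio_table: PatternRatioTable,
    max_dist: float = TRIANGLE_MAX_DIST,
) -> dict[str, float]:
    """Sparse pattern -> ratio * N_occur map over glytri containing ``center``."""
    from .glyco import enumerate_triangles

    tris = mark_glyco(enumerate_triangles(structure, center, max_dist=max_dist), sequons)
    census: Counter[str] = Counter(
        t.pattern for t in tris if t.is_glytri and t.pattern is not None
    )
    out = {}
    for pattern, n_occur in census.items():
        if pattern in ratio_table.entries:
            out[pattern] = ratio_table.ratio(pattern) * n_occur
    return out


def _dense_weights(weights: dict[str, float], vocabulary: list[str]) -> np.ndarray:
    return np.array([weights.get(p, 0.0) for p in vocabulary])


def consolidate_glytri(
    weights: dict[str, float], consolidator: ANNConsolidator, vocabulary: list[str]
) -> float:
    extra = set(weights) - set(vocabulary)
    if extra:
        raise DimensionMismatchError(f"pattern dimension mismatch: unknown patterns {sorted(extra)}")
    return consolidator.score(_dense_weights(weights, vocabulary))


def consolidate_glyindex(
    profile: ShellProfile,
    selected_features: list[tuple[int, int]],
    consolidator: ANNConsolidator,
) -> float:
    """ANN output on the selected (table, layer) subset of the shell profile."""
    vec = np.array([profile.layer_means[layer, table] for table, layer in selected_features])
    return consolidator.score(vec)


def featurize(structure: AntigenStructure, model) -> pd.DataFrame:
    """Six-column feature table over the structure's surface residues.

    ``model`` is a trained :class:`glycep.model.EpitopeModel` carrying the
    ratio table, propensity table, consolidators and feature selection.
    """
    sequons = find_sequons_for(structure)
    ing = extract_ingredients(
        structure, sequons, tables=model.aaindex_tables, subgroups=model.subgroups
    )
    return assemble_features(ing, model)


def find_sequons_for(structure: AntigenStructure) -> SequonMap:
    from .glyco import find_sequons

    return find_sequons(structure.sequence)


def assemble_features(ing: StructureIngredients, model) -> pd.DataFrame:
    """Map precomputed ingredients + trained tables to the six feature columns."""
    structure = ing.structure
    rows = []
    vocab = model.glytri_vocabulary
    n_selected = len(model.glyindex_selection)
    sel_cols = [t * N_SHELL_LAYERS + l for t, l in model.glyindex_selection]

    w_mat = np.zeros((len(ing.surface), len(vocab)))
    g_mat = np.zeros((len(ing.surface), n_selected))
    for ri, i in enumerate(ing.surface):
        census = ing.glytri_census[i]
        for pi, p in enumerate(vocab):
            if p in census:
                w_mat[ri, pi] = model.ratio_table.ratio(p) * census[p]
        g_mat[ri] = ing.shell[i][sel_cols]

    glytri_scores = model.glytri_consolidator.score_many(w_mat)
    glyindex_scores = model.glyindex_consolidator.score_many(g_mat)

    for ri, i in enumerate(ing.surface):
        pats = ing.tri_patterns[i]
        avg = float(np.mean([model.propensity_table.score(p) for p in pats])) if pats else 0.0
        members = sorted(ing.tri_members[i] | {i})
        apref = float(np.mean([structure.residues[j].rasa for j in members]))
        res = structure.residues[i]
        rows.append(
            {
                "residue_index": i,
                "chain": res.chain_id,
                "seq_id": res.seq_id,
                "aa": res.aa,
                "avg": avg,
                "apref": apref,
                "cc": ing.cc[i],
                "index": ing.index[i],
                "glytri": float(glytri_scores[ri]),
                "glyindex": float(glyindex_scores[ri]),
            }
        )
    return pd.DataFrame(rows).set_index("residue_index")
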