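"""Training and scoring: feature selection, consolidators, logistic scorer,
neighborhood calibration, thresholding, and sub-model recommendation."""

from __future__ import annotations

import base64
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as F
from .features import (
    ANNConsolidator,
    StructureIngredients,
    TrianglePropensityTable,
    assemble_features,
    build_propensity_table,
    extract_ingredients,
    load_default_aaindex_tables,
)
from .glyco import (
    PatternRatioTable,
    SequonMap,
    SubgroupTable,
    compute_ratio_table,
)
from .structure_io import AntigenStructure, EpitopeLabeling

__all__ = [
    "EpitopeModel",
    "PredictionResult",
    "iterative_filter",
    "train",
    "predict_raw",
    "calibrate",
    "classify",
    "recommend_submodel",
    "cross_validate",
    "DEFAULT_THRESHOLD",
    "CALIBRATION_DIST",
]

DEFAULT_THRESHOLD = 0.089
CALIBRATION_DIST = 5.0
MODEL_SCHEMA_VERSION = 1

Corpus = list[tuple[AntigenStructure, EpitopeLabeling, SequonMap]]


def _b64(arr: np.ndarray) -> dict:
    a = np.ascontiguousarray(arr, dtype=np.float64)
    return {"shape": list(a.shape), "data": base64.b64encode(a.tobytes()).decode()}


def _unb64(d: dict) -> np.ndarray:
    return np.frombuffer(base64.b64decode(d["data"]), dtype=np.float64).reshape(d["shape"]).copy()


@dataclass
class EpitopeModel:
    """Trained scorer artifact; serializes to a versioned JSON document."""

    ratio_table: PatternRatioTable
    propensity_table: TrianglePropensityTable
    glytri_consolidator: ANNConsolidator
    glytri_vocabulary: list[str]
    glyindex_selection: list[tuple[int, int]]  # (table idx, layer idx)
    glyindex_consolidator: ANNConsolidator
    coef: np.ndarray  # 6 logistic coefficients (on z-scored features)
    intercept: float
    feature_mean: np.ndarray
    feature_std: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    submodel_key: tuple[str, str] | str = "general"
    provenance: dict = field(default_factory=dict)
    subgroups: SubgroupTable = field(default_factory=SubgroupTable.default)
    aaindex_tables: list = field(default_factory=load_default_aaindex_tables)

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.shape != (6,):
            raise ValueError("logistic model must have exactly 6 coefficients")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0,1)")

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "ratio_table": self.ratio_table.to_dict(),
            "propensity_table": self.propensity_table.scores,
            "glytri_vocabulary": self.glytri_vocabulary,
            "glytri_consolidator": {
                "weights": [_b64(w) for w in self.glytri_consolidator.weights],
                "biases": [_b64(b) for b in self.glytri_consolidator.biases],
                "n_inputs": self.glytri_consolidator.n_inputs,
            },
            "glyindex_selection": [list(t) for t in self.glyindex_selection],
            "glyindex_consolidator": {
                "weights": [_b64(w) for w in self.glyindex_consolidator.weights],
                "biases": [_b64(b) for b in self.glyindex_consolidator.biases],
                "n_inputs": self.glyindex_consolidator.n_inputs,
            },
            "logistic": {
                "coef": _b64(self.coef),
                "intercept": self.intercept,
                "feature_mean": _b64(self.feature_mean),
                "feature_std": _b64(self.feature_std),
            },
            "threshold": self.threshold,
            "submodel_key": list(self.submodel_key)
            if isinstance(self.submodel_key, tuple)
            else self.submodel_key,
            "provenance": self.provenance,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EpitopeModel":
        doc = json.loads(text)
        if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema: {doc.get('schema_version')}")

        def consolidator(d: dict) -> ANNConsolidator:
            return ANNConsolidator(
                weights=[_unb64(w) for w in d["weights"]],
                biases=[_unb64(b) for b in d["biases"]],
                n_inputs=d["n_inputs"],
            )

        key = doc["submodel_key"]
        return cls(
            ratio_table=PatternRatioTable.from_dict(doc["ratio_table"]),
            propensity_table=TrianglePropensityTable(scores=doc["propensity_table"]),
            glytri_consolidator=consolidator(doc["glytri_consolidator"]),
            glytri_vocabulary=doc["glytri_vocabulary"],
            glyindex_selection=[tuple(t) for t in doc["glyindex_selection"]],
            glyindex_consolidator=consolidator(doc["glyindex_consolidator"]),
            coef=_unb64(doc["logistic"]["coef"]),
            intercept=doc["logistic"]["intercept"],
            feature_mean=_unb64(doc["logistic"]["feature_mean"]),
            feature_std=_unb64(doc["logistic"]["feature_std"]),
            threshold=doc["threshold"],
            submodel_key=tuple(key) if isinstance(key, list) else key,
            provenance=doc.get("provenance", {}),
        )


@dataclass
class PredictionResult:
    structure_key: tuple[str, str]
    rows: pd.DataFrame  # residue_index-indexed: chain, seq_id, aa, is_surface, raw, adjusted, call
    threshold: float

    def to_tsv(self) -> str:
        return self.rows.to_csv(sep="\t", float_format="%.6f")


# ---------------------------------------------------------------------------
# feature selection


def _probe_auc(X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> tuple[float, float]:
    """Cross-validated probe AUC of a logistic model: (mean, standard error)."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold

    from .evaluation import roc_auc

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            continue
        clf = LogisticRegression(max_iter=500)
        clf.fit(X[tr], y[tr])
        aucs.append(roc_auc(clf.decision_function(X[te]), y[te]))
    return float(np.mean(aucs)), float(np.std(aucs) / np.sqrt(max(len(aucs), 1)))


def iterative_filter(
    candidates: np.ndarray,
    labels: np.ndarray,
    folds: int = 3,
    min_improvement: float = 1e-3,
    seed: int = 0,
) -> list[int]:
    """Greedy forward selection of candidate columns by cross-validated probe AUC.

    Stops when the best addition improves CV AUC by less than
    ``min_improvement`` or by less than one standard error of the candidate's
    fold AUCs (guards against chance improvements when maximizing over many
    noise candidates); always returns at least one column. Ties break by
    candidate order.
    """
    X = np.asarray(candidates, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate labels: single class")
    n_cand = X.shape[1]
    selected: list[int] = []
    best_auc = -np.inf
    while len(selected) < n_cand:
        scores, ses = [], []
        for j in range(n_cand):
            if j in selected:
                scores.append(-np.inf)
                ses.append(0.0)
                continue
            cols = selected + [j]
            mean, se = _probe_auc(X[:, cols], y, folds, seed)
            scores.append(mean)
            ses.append(se)
        j_best = int(np.argmax(scores))
        if not selected:
            selected.append(j_best)
            best_auc = scores[j_best]
            continue
        if scores[j_best] - best_auc < max(min_improvement, ses[j_best]):
            break
        selected.append(j_best)
        best_auc = scores[j_best]
    return selected


# ---------------------------------------------------------------------------
# training


def _corpus_ingredients(corpus: Corpus, subgroups, tables) -> list[StructureIngredients]:
    return [
        extract_ingredients(s, q, tables=tables, subgroups=subgroups)
        for s, _, q in corpus
    ]


def _fit_logistic(X: np.ndarray, y: np.ndarray, seed: int):
    from sklearn.linear_model import LogisticRegression

    # L2 with lambda = 1e-4 -> C = 1 / (lambda * n)
    C = 1.0 / (1e-4 * len(y))
    clf = LogisticRegression(C=C, class_weight="balanced", max_iter=2000, random_state=seed)
    clf.fit(X, y)
    return clf


def train(
    corpus: Corpus,
    config: dict | None = None,
    seed: int = 0,
    _ingredients: list[StructureIngredients] | None = None,
) -> EpitopeModel:
    """Full training pipeline on a labeled corpus.

    Ratio/propensity tables, the two consolidators, shell-feature selection
    and the six-feature logistic scorer are fit in sequence; the result is
    deterministic for a fixed corpus and seed.
    """
    config = config or {}
    if not corpus:
        raise ValueError("empty corpus")
    for s, _, _ in corpus:
        if not s.qualifies_for_training():
            raise ValueError(f"structure {s.pdb_id} has <= 50 residues")
    subgroups = config.get("subgroups") or SubgroupTable.default()
    tables = config.get("aaindex_tables") or load_default_aaindex_tables()

    all_labels = np.concatenate(
        [[lab.labels[i] for i in s.surface_indices] for s, lab, _ in corpus]
    ).astype(int)
    if all_labels.sum() == 0:
        raise ValueError("zero epitope residues in corpus")
    if len(all_labels) == 0:
        raise ValueError("zero surface residues in corpus")

    ratio_table = compute_ratio_table(corpus, subgroups=subgroups)
    propensity_table = build_propensity_table(corpus, subgroups=subgroups)
    vocab = ratio_table.vocabulary

    ings = _ingredients
    if ings is None:
        ings = _corpus_ingredients(corpus, subgroups, tables)

    # per-residue raw matrices over all surface residues of the corpus
    w_rows, shell_rows = [], []
    for ing, (s, lab, _) in zip(ings, corpus):
        for i in ing.surface:
            census = ing.glytri_census[i]
            w_rows.append([ratio_table.ratio(p) * census.get(p, 0) for p in vocab])
            shell_rows.append(ing.shell[i])
    W = np.asarray(w_rows, dtype=float)
    S = np.asarray(shell_rows, dtype=float)
    y = all_labels

    glytri_ann = ANNConsolidator.train(W, y, seed=seed)
    sel_cols = iterative_filter(S, y, folds=3, seed=seed)
    selection = [(c // F.N_SHELL_LAYERS, c % F.N_SHELL_LAYERS) for c in sel_cols]
    glyindex_ann = ANNConsolidator.train(S[:, sel_cols], y, seed=seed)

    # assemble six features with a lightweight carrier, then fit the scorer
    model = EpitopeModel(
        ratio_table=ratio_table,
        propensity_table=propensity_table,
        glytri_consolidator=glytri_ann,
        glytri_vocabulary=vocab,
        glyindex_selection=selection,
        glyindex_consolidator=glyindex_ann,
        coef=np.zeros(6),
        intercept=0.0,
        feature_mean=np.zeros(6),
        feature_std=np.ones(6),
        threshold=0.5,
        subgroups=subgroups,
        aaindex_tables=tables,
    )
    feats = [assemble_features(ing, model) for ing in ings]
    X = np.concatenate([f[list(F.FEATURE_NAMES)].to_numpy() for f in feats])
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xz = (X - mean) / std
    clf = _fit_logistic(Xz, y, seed)
    model.coef = clf.coef_.ravel()
    model.intercept = float(clf.intercept_[0])
    model.feature_mean = mean
    model.feature_std = std

    # default threshold: maximize balanced accuracy of calibrated training scores
    from .evaluation import confusion_metrics

    adj_all, lab_all = [], []
    for (s, lab, _), f in zip(corpus, feats):
        raw = _raw_from_features(f, model)
        adj = calibrate(s, raw)
        adj_all.append(adj.to_numpy())
        lab_all.append(np.array([lab.labels[i] for i in f.index]))
    adj_cat = np.concatenate(adj_all)
    lab_cat = np.concatenate(lab_all).astype(int)
    grid = np.unique(np.round(adj_cat, 4))
    best_t, best_ba = 0.5, -np.inf
    for t in grid:
        if not (0.0 < t < 1.0):
            continue
        m = confusion_metrics(adj_cat, lab_cat, t)
        if m.ba > best_ba:
            best_ba, best_t = m.ba, float(t)
    model.threshold = best_t

    fingerprint = hashlib.sha256(
        (";".join(f"{s.pdb_id}_{s.chain_id}" for s, _, _ in corpus) + f"|seed={seed}").encode()
    ).hexdigest()
    model.provenance = {"corpus_fingerprint": fingerprint, "seed": seed, "n_structures": len(corpus)}
    return model


def _raw_from_features(feats: pd.DataFrame, model: EpitopeModel) -> pd.Series:
    X = feats[list(F.FEATURE_NAMES)].to_numpy()
    Xz = (X - model.feature_mean) / model.feature_std
    z = Xz @ model.coef + model.intercept
    return pd.Series(1.0 / (1.0 + np.exp(-z)), index=feats.index, name="raw_score")


def predict_raw(structure: AntigenStructure, model: EpitopeModel) -> pd.Series:
    """Logistic raw antigenicity score per surface residue."""
    feats = F.featurize(structure, model)
    return _raw_from_features(feats, model)


def calibrate(
    structure: AntigenStructure,
    raw_scores: pd.Series,
    neighbor_dist: float = CALIBRATION_DIST,
    include_self: bool = True,
) -> pd.Series:
    """Neighborhood-mean score adjustment.

    Each surface residue's score becomes the mean raw score over surface
    residues within ``neighbor_dist`` (minimum heavy-atom distance). With
    ``include_self`` the residue itself is always in the average, so isolated
    residues keep their raw score.
    """
    dist = structure.distance_matrix()
    idx = list(raw_scores.index)
    adjusted = {}
    for i in idx:
        neigh = [j for j in idx if j != i and dist[i, j] <= neighbor_dist]
        if include_self:
            neigh.append(i)
        if not neigh:
            adjusted[i] = float(raw_scores[i])
        else:
            adjusted[i] = float(np.mean([raw_scores[j] for j in neigh]))
    return pd.Series(adjusted, name="adjusted_score").reindex(idx)


def classify(
    structure: AntigenStructure,
    raw_scores: pd.Series,
    adjusted_scores: pd.Series,
    threshold: float = DEFAULT_THRESHOLD,
) -> PredictionResult:
    """Boolean epitope call per surface residue at the given threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0,1]")
    rows = []
    for i, res in enumerate(structure.residues):
        surface = bool(res.is_surface)
        raw = float(raw_scores[i]) if surface and i in raw_scores.index else np.nan
        adj = float(adjusted_scores[i]) if surface and i in adjusted_scores.index else np.nan
        rows.append(
            {
                "residue_index": i,
                "chain": res.chain_id,
                "seq_id": res.seq_id,
                "aa": res.aa,
                "is_surface": surface,
                "raw_score": raw,
                "adjusted_score": adj,
                "predicted_epitope": bool(surface and not np.isnan(adj) and adj >= threshold),
            }
        )
    df = pd.DataFrame(rows).set_index("residue_index")
    return PredictionResult(
        structure_key=(structure.pdb_id, structure.chain_id), rows=df, threshold=threshold
    )


def predict(structure: AntigenStructure, model: EpitopeModel, threshold: float | None = None) -> PredictionResult:
    """Full scoring pipeline: featurize, score, calibrate, threshold."""
    raw = predict_raw(structure, model)
    adj = calibrate(structure, raw)
    return classify(structure, raw, adj, threshold if threshold is not None else model.threshold)


def recommend_submodel(
    registry: dict[tuple[str, str] | str, EpitopeModel],
    host: str | None = None,
    localization: str | None = None,
) -> EpitopeModel:
    """Exact (host, localization) match, else host-only, else the general model."""
    if not registry:
        raise ValueError("empty model registry")
    if host and localization and (host, localization) in registry:
        return registry[(host, localization)]
    if host:
        for key, m in registry.items():
            if isinstance(key, tuple) and key[0] == host and (key[1] in (None, "", "any")):
                return m
        host_only = [m for k, m in registry.items() if isinstance(k, tuple) and k[0] == host]
        if host_only:
            return host_only[0]
    if "general" not in registry:
        raise ValueError("registry has no general model")
    return registry["general"]


# ---------------------------------------------------------------------------
# cross-validation


def corpus_ingredients(corpus: Corpus) -> list[StructureIngredients]:
    """Label-free per-structure feature ingredients (shareable across CV runs)."""
    return _corpus_ingredients(corpus, SubgroupTable.default(), load_default_aaindex_tables())


def cross_validate(
    corpus: Corpus,
    folds: int = 10,
    seed: int = 0,
    ablate_glyco: bool = False,
    _ingredients: list[StructureIngredients] | None = None,
) -> dict:
    """Structure-level k-fold CV of the full pipeline; returns pooled + per-fold AUC.

    With ``ablate_glyco`` the glytri/glyindex columns are zeroed before the
    logistic fit and at prediction, leaving a four-feature model.
    """
    from .evaluation import roc_auc

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    fold_of = {int(order[i]): i % folds for i in range(len(corpus))}

    ings = _ingredients
    if ings is None:
        ings = corpus_ingredients(corpus)

    pooled_scores, pooled_labels, fold_rows = [], [], []
    for k in range(folds):
        tr_idx = [i for i in range(len(corpus)) if fold_of[i] != k]
        te_idx = [i for i in range(len(corpus)) if fold_of[i] == k]
        if not te_idx or not tr_idx:
            fold_rows.append({"fold": k, "auc": float("nan")})
            continue
        sub = [corpus[i] for i in tr_idx]
        model = train(sub, seed=seed, _ingredients=[ings[i] for i in tr_idx])
        if ablate_glyco:
            model = _ablated(model, sub, [ings[i] for i in tr_idx], seed)
        scores_k, labels_k = [], []
        for i in te_idx:
            s, lab, _ = corpus[i]
            feats = assemble_features(ings[i], model)
            if ablate_glyco:
                feats = feats.copy()
                feats["glytri"] = 0.0
                feats["glyindex"] = 0.0
            raw = _raw_from_features(feats, model)
            adj = calibrate(s, raw)
            scores_k.extend(adj.to_numpy())
            labels_k.extend(lab.labels[j] for j in adj.index)
        pooled_scores.extend(scores_k)
        pooled_labels.extend(labels_k)
        if len(set(labels_k)) == 2:
            fold_rows.append({"fold": k, "auc": roc_auc(np.array(scores_k), np.array(labels_k))})
        else:
            fold_rows.append({"fold": k, "auc": float("nan")})

    pooled_auc = roc_auc(np.array(pooled_scores), np.array(pooled_labels, dtype=int))
    return {"pooled_auc": pooled_auc, "folds": fold_rows, "n_folds": folds}


def _ablated(model: EpitopeModel, corpus: Corpus, ings, seed: int) -> EpitopeModel:
    """Refit the logistic scorer with glyco features zeroed (four-feature model)."""
    feats = [assemble_features(ing, model) for ing in ings]
    X = np.concatenate([f[list(F.FEATURE_NAMES)].to_numpy() for f in feats])
    X[:, 4] = 0.0
    X[:, 5] = 0.0
    y = np.concatenate(
        [[lab.labels[i] for i in f.index] for (s, lab, _), f in zip(corpus, feats)]
    ).astype(int)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    clf = _fit_logistic((X - mean) / std, y, seed)
    import copy

    m2 = copy.copy(model)
    m2.coef = clf.coef_.ravel()
    m2.intercept = float(clf.intercept_[0])
    m2.feature_mean = mean
    m2.feature_std = std
    return m2
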