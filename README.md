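# glycep

Glycosylation-aware conformational B-cell epitope prediction on protein 3D
structures.

Given a single antigen chain in PDB format, `glycep` flags surface residues,
computes six micro-environment classifiers per surface residue — triangle
propensity, patch relative-ASA, clustering coefficient, neighborhood
amino-acid-index mean, and two glycosylation-specific scores built from
N-glycosylation sequon (Asn-X-Ser/Thr, X ≠ Pro) triangles and a layered
"shell" profile of glycosylation-related amino-acid indexes — integrates them
with a logistic scorer, and calibrates each raw score by averaging over its
≤5 Å surface neighborhood before thresholding (default cutoff 0.089).

The full training pipeline is included (pattern ratio table, two 10-unit ANN
consolidators, greedy shell-feature selection, class-balanced logistic fit,
structure-level cross-validation), together with a deterministic synthetic
structure generator so every stage is testable offline.

## Layout

| module                 | role                                                              |
|------------------------|-------------------------------------------------------------------|
| `glycep.structure_io`  | PDB parsing, Shrake–Rupley SASA, surface flags, contact labeling  |
| `glycep.glyco`         | sequon detection, surface triangles, pattern ratio table          |
| `glycep.features`      | the six per-residue classifiers and ANN consolidators             |
| `glycep.model`         | training, raw scoring, calibration, thresholding, serialization   |
| `glycep.evaluation`    | ROC AUC (rank statistic), balanced accuracy, FPR, corpus reports  |
| `glycep.synthetic`     | seeded toy antigens/complexes/corpora with planted signal         |
| `glycep.cli`           | `glycep predict / train / evaluate / synth`                       |

Bundled data (`src/glycep/data/`): the amino-acid→subgroup consolidation
table (13 groups), the max-SASA normalization table, and four
glycosylation-related index files keyed by their AAindex accessions. The
index files ship offline stand-in scales — replace them with the official
AAindex entries (same one-letter/value format) for production use.

## CLI

```bash
# generate a labeled synthetic corpus
glycep synth --n 20 --seed 1 --out corpus/

# train (writes model JSON + 10-fold CV report)
glycep train --manifest corpus/manifest.tsv --seed 1 --out model.json

# predict (scores TSV, B-factor-annotated PDB, sequence summary)
glycep predict --in antigen.pdb --chain A --model model.json --out results/

# compare predictions against ground truth
glycep evaluate --pred results/antigen_scores.tsv \
                --truth corpus/SYN000_labels.tsv --out report/
```

Exit codes: 0 success, 1 usage error, 2 data error. All commands are
deterministic for a fixed `--seed`.

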