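"""Benchmark protocol: top-k site accuracy, atom-level ROC/AUC, metabolite
recall/precision/F1 and false-positive counts, and the exact-match depth sweep.

Top-k accuracy is the fraction of molecules for which at least one of the k
highest-ranked sites is a true SOM; credit is symmetry-aware, i.e. a
predicted atom counts if it lies in the same graph-automorphism class as a
true SOM.  Site prediction is also treated as atom-level binary
classification, scored by the area under the ROC curve — pooled over all
atoms of all molecules, and as the mean/median of per-molecule AUCs
(molecules whose atoms are all positive or all negative carry no ranking
information and are excluded from the per-molecule statistics).

Metabolite metrics are micro-averaged over molecules:
recall = (true metabolites recovered in the top-k list) / (all experimental
metabolites); precision = the same numerator over all predicted metabolites
in the top-k list; F1 is their harmonic mean; FP is the total count of
predicted-but-not-experimental structures.  Structure identity is canonical
SMILES equality with stereochemistry stripped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem
from sklearn.metrics import roc_auc_score

from .chem_io import PatternRecord
from .database import FingerprintDatabasePair
from .predictor import SitePrediction, predict_sites
from .similarity import SimilarityParams

logger = logging.getLogger(__name__)


@dataclass
class EvalMetrics:
    top_k_accuracy: dict[int, float] = field(default_factory=dict)
    auc_overall: float = float("nan")
    auc_mean: float = float("nan")
    auc_median: float = float("nan")
    recall_k: dict[int, float] = field(default_factory=dict)
    precision_k: dict[int, float] = field(default_factory=dict)
    f1_k: dict[int, float] = field(default_factory=dict)
    fp_count_k: dict[int, int] = field(default_factory=dict)


def symmetry_classes(mol: Chem.Mol) -> list[int]:
    """Graph-automorphism class label per atom (canonical ranks, ties kept)."""
    return list(Chem.CanonicalRankAtoms(mol, breakTies=False))


def _symmetry_hit(mol: Chem.Mol, predicted_atom: int,
                  truth: set[int]) -> bool:
    classes = symmetry_classes(mol)
    truth_classes = {classes[t] for t in truth}
    return classes[predicted_atom] in truth_classes


def topk_som_accuracy(predictions: Mapping[str, Sequence[SitePrediction]],
                      truth: Mapping[str, set[int]],
                      molecules: Mapping[str, Chem.Mol],
                      k: int) -> float:
    """Fraction of molecules with a true SOM among the k top-ranked sites."""
    hits = 0
    total = 0
    for mol_id, som_set in truth.items():
        if not som_set:
            raise ValueError(f"molecule {mol_id}: empty truth SOM set")
        total += 1
        sites = predictions.get(mol_id)
        if not sites:
            logger.warning("molecule %s: no predictions, counted as miss", mol_id)
            continue
        mol = molecules[mol_id]
        top = sorted(sites, key=lambda s: s.rank)[:k]
        if any(_symmetry_hit(mol, s.atom_index, som_set) for s in top):
            hits += 1
    return hits / total if total else 0.0


def auc_metrics(predictions: Mapping[str, Sequence[SitePrediction]],
                truth: Mapping[str, set[int]]
                ) -> tuple[float, float, float]:
    """(pooled AUC, mean per-molecule AUC, median per-molecule AUC)."""
    all_labels: list[int] = []
    all_scores: list[float] = []
    per_mol: list[float] = []
    for mol_id, sites in predictions.items():
        som_set = truth.get(mol_id, set())
        labels = [1 if s.atom_index in som_set else 0 for s in sites]
        scores = [s.p for s in sites]
        all_labels.extend(labels)
        all_scores.extend(scores)
        if 0 < sum(labels) < len(labels):
            per_mol.append(float(roc_auc_score(labels, scores)))
        else:
            logger.debug("molecule %s: single-class labels, excluded from "
                         "per-molecule AUC", mol_id)
    if len(set(all_labels)) < 2:
        raise ValueError("pooled labels are single-class; AUC undefined")
    overall = float(roc_auc_score(all_labels, all_scores))
    if not per_mol:
        return overall, float("nan"), float("nan")
    return overall, float(np.mean(per_mol)), float(np.median(per_mol))


def _stereo_stripped_canonical(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def metabolite_prf(predicted: Mapping[str, Sequence[str]],
                   truth: Mapping[str, Sequence[str]],
                   k: int) -> tuple[float, float, float, int]:
    """Micro-averaged (recall, precision, F1, FP count) for top-k metabolites.

    ``predicted`` maps molecule id to its ranked product SMILES; only the
    first k are scored.  Molecules with no experimental metabolites are
    excluded from the recall denominator.
    """
    n_true_total = 0
    n_hit = 0
    n_pred = 0
    n_fp = 0
    for mol_id, pred_list in predicted.items():
        true_set = {s for s in (_stereo_stripped_canonical(t)
                                for t in truth.get(mol_id, ())) if s}
        top = [s for s in (_stereo_stripped_canonical(p)
                           for p in pred_list[:k]) if s]
        if not true_set:
            logger.warning("molecule %s: no experimental metabolites, "
                           "excluded from recall", mol_id)
        else:
            n_true_total += len(true_set)
            n_hit += len(true_set & set(top))
        n_pred += len(top)
        n_fp += len([p for p in top if p not in true_set])
    recall = n_hit / n_true_total if n_true_total else 0.0
    precision = n_hit / n_pred if n_pred else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return recall, precision, f1, n_fp


def evaluate_sites(predictions: Mapping[str, Sequence[SitePrediction]],
                   truth: Mapping[str, set[int]],
                   molecules: Mapping[str, Chem.Mol],
                   ks: Sequence[int] = (1, 2, 3)) -> EvalMetrics:
    """Convenience wrapper computing the standard site-level metric set."""
    metrics = EvalMetrics()
    for k in ks:
        metrics.top_k_accuracy[k] = topk_som_accuracy(
            predictions, truth, molecules, k)
    metrics.auc_overall, metrics.auc_mean, metrics.auc_median = \
        auc_metrics(predictions, truth)
    return metrics


def depth_sweep(benchmark: Mapping[str, Chem.Mol],
                truth: Mapping[str, set[int]],
                db: FingerprintDatabasePair,
                patterns: Sequence[PatternRecord],
                depths: Sequence[int] = (1, 2, 3, 4, 5, 6),
                threshold: float = 3.5
                ) -> list[tuple[int, str, float, int]]:
    """Re-run site prediction per exact-match depth.

    Returns rows ``(depth, molecule_id, per-molecule AUC or nan, n_hit_atoms)``
    where ``n_hit_atoms`` counts atoms with any substrate-db hit — deep exact
    matching returns few or no similar fingerprints.
    """
    if any(d < 1 or d > db.n_layers for d in depths):
        raise ValueError(f"depths must lie in 1..{db.n_layers}")
    rows: list[tuple[int, str, float, int]] = []
    for depth in depths:
        params = SimilarityParams(exact_depth=depth, threshold=threshold,
                                  n_layers=db.n_layers)
        for mol_id, mol in benchmark.items():
            sites = predict_sites(mol, db, patterns, params, molecule_id=mol_id)
            som_set = truth.get(mol_id, set())
            labels = [1 if s.atom_index in som_set else 0 for s in sites]
            scores = [s.p for s in sites]
            auc = (float(roc_auc_score(labels, scores))
                   if 0 < sum(labels) < len(labels) else float("nan"))
            n_hit_atoms = sum(1 for s in sites if s.m > 0)
            rows.append((depth, mol_id, auc, n_hit_atoms))
    return rows


def write_depth_sweep(rows: Sequence[tuple[int, str, float, int]], path) -> None:
    from pathlib import Path
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("depth\tmolecule_id\tauc\tn_hit_atoms\n")
        for depth, mol_id, auc, n_hit in rows:
            fh.write(f"{depth}\t{mol_id}\t{auc:.6f}\t{n_hit}\n")
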