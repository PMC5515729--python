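"""Benchmark metrics: top-k accuracy, AUC, metabolite recall/precision/F1."""

import itertools
import random

import pytest
from rdkit import Chem

from somrx.evaluation import (auc_metrics, depth_sweep, evaluate_sites,
                              metabolite_prf, topk_som_accuracy,
                              write_depth_sweep)
from somrx.predictor import SitePrediction, predict_sites


def _sites(mol_id, scored):
    """scored: list of (atom_index, p); ranks assigned by descending p."""
    sites = [SitePrediction(mol_id, a, "C", 0, 0, 0, 0.0, p=p)
             for a, p in scored]
    for rank, s in enumerate(sorted(sites, key=lambda s: (-s.p, s.atom_index)),
                             1):
        s.rank = rank
    return sites


class TestTopK:
    def test_truth_at_rank_one_everywhere(self):
        mols = {"m1": Chem.MolFromSmiles("CCO"),
                "m2": Chem.MolFromSmiles("CCN")}
        preds = {"m1": _sites("m1", [(2, 1.0), (0, 0.2), (1, 0.1)]),
                 "m2": _sites("m2", [(2, 1.0), (1, 0.3), (0, 0.1)])}
        truth = {"m1": {2}, "m2": {2}}
        for k in (1, 2, 3):
            assert topk_som_accuracy(preds, truth, mols, k) == 1.0

    def test_truth_at_rank_three(self):
        mols = {"m1": Chem.MolFromSmiles("CCCO")}
        preds = {"m1": _sites("m1", [(0, 1.0), (1, 0.5), (3, 0.2), (2, 0.1)])}
        truth = {"m1": {3}}
        assert topk_som_accuracy(preds, truth, mols, 1) == 0.0
        assert topk_som_accuracy(preds, truth, mols, 2) == 0.0
        assert topk_som_accuracy(preds, truth, mols, 3) == 1.0

    def test_symmetry_aware_credit(self):
        # para-substituted ring: the two ortho CH positions are automorphic
        mol = Chem.MolFromSmiles("COc1ccc(C)cc1")
        classes = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
        pairs = [(i, j) for i, j in itertools.combinations(range(len(classes)), 2)
                 if classes[i] == classes[j]]
        i, j = pairs[0]
        preds = {"m1": _sites("m1", [(i, 1.0)])}
        assert topk_som_accuracy(preds, {"m1": {j}}, {"m1": mol}, 1) == 1.0

    def test_missing_predictions_count_as_miss(self):
        mols = {"m1": Chem.MolFromSmiles("CC"), "m2": Chem.MolFromSmiles("CO")}
        preds = {"m1": _sites("m1", [(0, 1.0)])}
        truth = {"m1": {0}, "m2": {1}}
        assert topk_som_accuracy(preds, truth, mols, 1) == 0.5

    def test_nondecreasing_in_k(self, fixture_db, manifest, holdout):
        mols, truth = holdout
        preds = {mid: predict_sites(m, fixture_db, manifest.patterns,
                                    molecule_id=mid)
                 for mid, m in mols.items()}
        accs = [topk_som_accuracy(preds, truth, mols, k) for k in (1, 2, 3, 4)]
        assert all(a <= b + 1e-12 for a, b in zip(accs, accs[1:]))

    def test_recount_from_written_tsv(self, tmp_path, fixture_db, manifest,
                                      holdout):
        """Accuracy recomputed from the sites TSV equals the in-memory value."""
        from somrx.chem_io import write_predictions
        mols, truth = holdout
        preds = {mid: predict_sites(m, fixture_db, manifest.patterns,
                                    molecule_id=mid)
                 for mid, m in mols.items()}
        all_sites = [s for sites in preds.values() for s in sites]
        tsv, _ = write_predictions(all_sites, [], tmp_path / "out")
        reread: dict[str, list] = {}
        for line in tsv.read_text().splitlines()[1:]:
            f = line.split("\t")
            s = SitePrediction(f[0], int(f[1]), f[2], int(f[3]), int(f[4]),
                               int(f[5]), float(f[6]), float(f[7]), f[8],
                               int(f[9]))
            reread.setdefault(f[0], []).append(s)
        for k in (1, 2, 3):
            assert topk_som_accuracy(reread, truth, mols, k) == \
                topk_som_accuracy(preds, truth, mols, k)


def _pair_count_auc(labels, scores):
    """Mann-Whitney oracle: P(score_pos > score_neg) + 0.5 P(equal)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        preds = {"m1": _sites("m1", [(0, 0.9), (1, 0.8), (2, 0.1), (3, 0.0)])}
        truth = {"m1": {0, 1}}
        overall, mean, median = auc_metrics(preds, truth)
        assert overall == mean == median == 1.0

    def test_random_scores_near_half(self):
        rng = random.Random(123)
        scored = [(i, rng.random()) for i in range(2000)]
        truth = {"m1": set(rng.sample(range(2000), 800))}
        overall, _, _ = auc_metrics({"m1": _sites("m1", scored)}, truth)
        assert overall == pytest.approx(0.5, abs=0.05)

    def test_toy_set_matches_pair_count_oracle(self):
        labels = [1, 0, 1, 0, 0, 1]
        scores = [0.9, 0.8, 0.7, 0.7, 0.2, 0.1]
        preds = {"m1": _sites("m1", list(enumerate(scores)))}
        truth = {"m1": {i for i, l in enumerate(labels) if l}}
        overall, _, _ = auc_metrics(preds, truth)
        assert overall == pytest.approx(_pair_count_auc(labels, scores))

    def test_invariant_under_monotone_rescaling(self):
        scores = [0.9, 0.5, 0.4, 0.3, 0.1, 0.0]
        truth = {"m1": {0, 2}}
        base, _, _ = auc_metrics({"m1": _sites("m1", list(enumerate(scores)))},
                                 truth)
        rescaled = [s ** 3 for s in scores]
        after, _, _ = auc_metrics(
            {"m1": _sites("m1", list(enumerate(rescaled)))}, truth)
        assert base == pytest.approx(after)

    def test_single_class_overall_raises(self):
        preds = {"m1": _sites("m1", [(0, 1.0), (1, 0.5)])}
        with pytest.raises(ValueError):
            auc_metrics(preds, {"m1": {0, 1}})

    def test_single_class_molecules_excluded_from_per_molecule(self):
        preds = {"m1": _sites("m1", [(0, 1.0), (1, 0.5)]),   # all positive
                 "m2": _sites("m2", [(0, 0.9), (1, 0.2)])}
        truth = {"m1": {0, 1}, "m2": {0}}
        overall, mean, median = auc_metrics(preds, truth)
        assert mean == 1.0  # only m2 contributes


class TestMetabolitePrf:
    def test_hand_example(self):
        predicted = {"m1": ["CC=O", "CCO", "OCC=O"]}  # 1 of 3 is real
        truth = {"m1": ["CC=O", "CC(=O)O"]}           # 2 experimental
        recall, precision, f1, fp = metabolite_prf(predicted, truth, k=3)
        assert recall == pytest.approx(0.5)
        assert precision == pytest.approx(1 / 3)
        assert f1 == pytest.approx(0.4)
        assert fp == 2

    def test_case_study_shape(self):
        """One molecule, 2 experimental, 3 predicted, 1 correct:
        top-3 precision 33.3%, recall 50%."""
        predicted = {"drug": ["Oc1ccccc1", "CCO", "CCN"]}
        truth = {"drug": ["Oc1ccccc1", "NCCO"]}
        recall, precision, _, _ = metabolite_prf(predicted, truth, k=3)
        assert precision * 100 == pytest.approx(33.3, abs=0.05)
        assert recall * 100 == pytest.approx(50.0, abs=1e-9)

    def test_empty_predictions(self):
        recall, precision, f1, fp = metabolite_prf(
            {"m1": []}, {"m1": ["CCO"]}, k=3)
        assert (recall, precision, f1, fp) == (0.0, 0.0, 0.0, 0)

    def test_stereo_stripped_identity(self):
        predicted = {"m1": ["C[C@H](O)CC"]}
        truth = {"m1": ["C[C@@H](O)CC"]}
        recall, precision, _, fp = metabolite_prf(predicted, truth, k=1)
        assert recall == precision == 1.0 and fp == 0

    def test_no_experimental_metabolites_excluded_from_recall(self):
        predicted = {"m1": ["CCO"], "m2": ["CC=O"]}
        truth = {"m1": ["CCO"], "m2": []}
        recall, precision, _, fp = metabolite_prf(predicted, truth, k=1)
        assert recall == 1.0          # denominator counts only m1
        assert precision == 0.5       # m2's prediction is a false positive
        assert fp == 1


class TestDepthSweep:
    def test_row_count(self, fixture_db, manifest, holdout):
        mols, truth = holdout
        sub = dict(list(mols.items())[:4])
        rows = depth_sweep(sub, truth, fixture_db, manifest.patterns,
                           depths=(3, 6))
        assert len(rows) == 2 * len(sub)

    def test_depth_three_consistent_with_default(self, fixture_db, manifest,
                                                 holdout):
        mols, truth = holdout
        mid, mol = next(iter(mols.items()))
        rows = depth_sweep({mid: mol}, truth, fixture_db, manifest.patterns,
                           depths=(3,))
        default_sites = predict_sites(mol, fixture_db, manifest.patterns,
                                      molecule_id=mid)
        assert rows[0][3] == sum(1 for s in default_sites if s.m > 0)

    def test_deeper_matching_returns_fewer_hits(self, fixture_db, manifest,
                                                holdout):
        """Exact match over all six layers finds fewer similar environments."""
        mols, truth = holdout
        rows = depth_sweep(mols, truth, fixture_db, manifest.patterns,
                           depths=(3, 6))
        hits3 = sum(r[3] for r in rows if r[0] == 3)
        hits6 = sum(r[3] for r in rows if r[0] == 6)
        assert hits6 < hits3

    def test_bad_depth_rejected(self, fixture_db, manifest, holdout):
        mols, truth = holdout
        with pytest.raises(ValueError):
            depth_sweep(mols, truth, fixture_db, manifest.patterns, depths=(0,))

    def test_tsv_output(self, tmp_path, fixture_db, manifest, holdout):
        mols, truth = holdout
        sub = dict(list(mols.items())[:2])
        rows = depth_sweep(sub, truth, fixture_db, manifest.patterns,
                           depths=(3,))
        out = tmp_path / "sweep.tsv"
        write_depth_sweep(rows, out)
        assert len(out.read_text().splitlines()) == len(rows) + 1


def test_evaluate_sites_wrapper(fixture_db, manifest, holdout):
    mols, truth = holdout
    preds = {mid: predict_sites(m, fixture_db, manifest.patterns,
                                molecule_id=mid)
             for mid, m in mols.items()}
    metrics = evaluate_sites(preds, truth, mols, ks=(1, 2, 3))
    assert set(metrics.top_k_accuracy) == {1, 2, 3}
    assert 0.0 <= metrics.auc_overall <= 1.0
    assert all(0.0 <= v <= 1.0 for v in metrics.top_k_accuracy.values())
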