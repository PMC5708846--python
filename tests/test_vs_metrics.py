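"""Screening metrics: ROC, NSQ_AUC, enrichment factors, chemotypes."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pocketforge.errors import ClassError, DataError, IdError
from pocketforge.vs_metrics import (
    ScreenTable,
    best_of_repeats,
    cluster_chemotypes,
    enrichment_factors,
    nsq_auc,
    prepare_racemic_library,
    ranked_ids,
    refinement_ligand_rank,
    roc_auc,
    roc_recovery,
    roc_selectivity,
)


def _table(scores_by_id, roles=None, pharm=None, chemo=None):
    ids = list(scores_by_id)
    df = pd.DataFrame({
        "id": ids,
        "role": [roles[i] if roles else "active" for i in ids],
        "pharmacology": [pharm[i] if pharm else
                         ("agonist" if (roles is None or
                                        roles[i] == "active") else "none")
                         for i in ids],
        "chemotype": [chemo.get(i, "") if chemo else "" for i in ids],
    })
    n_rep = len(next(iter(scores_by_id.values())))
    for k in range(n_rep):
        df[f"score_{k + 1}"] = [scores_by_id[i][k] for i in ids]
    return ScreenTable(df)


def _ranked_table(order):
    """Table whose ranking follows ``order`` ('A' = active, 'D' = decoy)."""
    scores, roles, pharm = {}, {}, {}
    for pos, cls in enumerate(order):
        cid = f"c{pos:03d}"
        scores[cid] = [float(pos)]
        roles[cid] = "active" if cls == "A" else "decoy"
        pharm[cid] = "agonist" if cls == "A" else "none"
    return _table(scores, roles, pharm)


class TestBestOfRepeats:
    def test_most_favorable_of_three(self):
        t = _table({"x": [-32.1, -30.5, -33.4]})
        assert best_of_repeats(t).df["best_score"].iloc[0] == -33.4

    def test_single_and_degenerate_repeats(self):
        t = _table({"x": [-10.0], "y": [-5.0]})
        assert best_of_repeats(t).df["best_score"].tolist() == [-10.0, -5.0]
        t = _table({"x": [-5, -5, -5]})
        assert best_of_repeats(t).df["best_score"].iloc[0] == -5

    def test_permutation_invariance_over_repeat_order(self):
        rng = np.random.default_rng(0)
        scores = list(rng.normal(size=4))
        results = set()
        for perm in itertools.permutations(scores):
            t = _table({"x": list(perm)})
            results.add(best_of_repeats(t).df["best_score"].iloc[0])
        assert len(results) == 1

    def test_missing_scores_raise(self):
        df = pd.DataFrame({
            "id": ["x"], "role": ["active"], "pharmacology": ["agonist"],
            "score_1": [np.nan],
        })
        with pytest.raises(DataError):
            best_of_repeats(ScreenTable(df))

    def test_higher_better_flag_flips_aggregation(self):
        t = ScreenTable(_table({"x": [1.0, 3.0, 2.0]}).df, higher_better=True)
        assert best_of_repeats(t).df["best_score"].iloc[0] == 3.0


class TestRocRecovery:
    def test_perfect_ranking_has_auc_one(self):
        roc = roc_recovery(_ranked_table("AAADDD"))
        assert roc_auc(roc) == pytest.approx(1.0)
        assert 1.0 in roc.tpr[roc.fpr == 0]

    def test_interleaved_ranking_matches_brute_force(self):
        roc = roc_recovery(_ranked_table("ADADAD"))
        # brute-force confusion counts at every threshold
        order = "ADADAD"
        pts = [(0.0, 0.0)]
        tp = fp = 0
        for cls in order:
            if cls == "A":
                tp += 1
            else:
                fp += 1
            pts.append((fp / 3, tp / 3))
        assert list(zip(roc.fpr, roc.tpr)) == pytest.approx(pts)

    def test_single_class_raises(self):
        with pytest.raises(ClassError):
            roc_recovery(_ranked_table("AAA"))

    def test_auc_equals_mann_whitney_u_exhaustively(self):
        # all labelings with both classes for n <= 10 compounds with
        # distinct scores; AUC must equal U / (n_pos * n_neg)
        for n in range(2, 11):
            for bits in range(1, 2 ** n - 1):
                order = ["A" if bits & (1 << i) else "D" for i in range(n)]
                table = _ranked_table(order)
                auc = roc_auc(roc_recovery(table))
                pos = [i for i, c in enumerate(order) if c == "A"]
                neg = [i for i, c in enumerate(order) if c == "D"]
                u = sum(1 for p in pos for q in neg if p < q)
                assert auc == pytest.approx(u / (len(pos) * len(neg)))


class TestRocSelectivity:
    def test_perfect_separation(self):
        pharm = {"a1": "agonist", "a2": "agonist",
                 "i1": "inhibitor", "i2": "inhibitor"}
        roles = {k: "active" for k in pharm}
        t = _table({"a1": [-9], "a2": [-8], "i1": [-2], "i2": [-1]},
                   roles, pharm)
        roc = roc_selectivity(t, positive="agonist")
        assert roc_auc(roc) == pytest.approx(1.0)

    def test_absent_class_is_na(self):
        pharm = {"i1": "inhibitor", "i2": "inhibitor", "d": "none"}
        roles = {"i1": "active", "i2": "active", "d": "decoy"}
        t = _table({"i1": [-3], "i2": [-2], "d": [-1]}, roles, pharm)
        with pytest.raises(ClassError):
            roc_selectivity(t, positive="agonist")

    def test_mixed_ordering_matches_oracle(self):
        order = "AIIAIAAI"  # agonists vs inhibitors, ranked best first
        pharm, roles, scores = {}, {}, {}
        for pos, cls in enumerate(order):
            cid = f"c{pos}"
            pharm[cid] = "agonist" if cls == "A" else "inhibitor"
            roles[cid] = "active"
            scores[cid] = [float(pos)]
        t = _table(scores, roles, pharm)
        auc = roc_auc(roc_selectivity(t, positive="agonist"))
        pos = [i for i, c in enumerate(order) if c == "A"]
        neg = [i for i, c in enumerate(order) if c == "I"]
        u = sum(1 for p in pos for q in neg if p < q)
        assert auc == pytest.approx(u / (len(pos) * len(neg)))


class TestNsqAuc:
    def test_perfect_ranking_scores_100(self):
        assert nsq_auc(roc_recovery(_ranked_table("AAADDDDD"))) \
            == pytest.approx(100.0)

    def test_reversed_ranking_scores_minus_50(self):
        assert nsq_auc(roc_recovery(_ranked_table("DDDDDAAA"))) \
            == pytest.approx(-50.0)

    def test_diagonal_ranking_scores_near_zero(self):
        # one active centered in every block of 100 decoys: the ROC
        # staircase straddles the diagonal
        order = ("D" * 50 + "A" + "D" * 50) * 50
        val = nsq_auc(roc_recovery(_ranked_table(order)))
        assert abs(val) < 0.5

    def test_invariant_under_strictly_monotone_score_transforms(self):
        rng = np.random.default_rng(4)
        ids = [f"c{i}" for i in range(40)]
        roles = {c: ("active" if i % 5 == 0 else "decoy")
                 for i, c in enumerate(ids)}
        pharm = {c: ("agonist" if roles[c] == "active" else "none")
                 for c in ids}
        base = {c: list(rng.normal(-30, 3, 3)) for c in ids}
        ref = nsq_auc(roc_recovery(_table(base, roles, pharm)))
        for f in (lambda x: 2 * x + 7, lambda x: x ** 3,
                  lambda x: np.expm1(x / 50)):
            transformed = {c: [float(f(s)) for s in v]
                           for c, v in base.items()}
            val = nsq_auc(roc_recovery(_table(transformed, roles, pharm)))
            assert val == pytest.approx(ref, abs=1e-9)


class TestEnrichmentFactors:
    def _big_table(self, in_top):
        """1000 compounds; cluster of 50 actives, ``in_top`` in the top 10."""
        rows = []
        cluster_positions = list(range(in_top)) + list(
            range(900, 900 + 50 - in_top))
        members = set(cluster_positions)
        for pos in range(1000):
            rows.append({
                "id": f"c{pos:04d}",
                "role": "active" if pos in members else "decoy",
                "pharmacology": "agonist" if pos in members else "none",
                "chemotype": "ct1" if pos in members else "",
                "score_1": float(pos),
            })
        return ScreenTable(pd.DataFrame(rows))

    def test_closed_form_ef_of_10(self):
        report = enrichment_factors(self._big_table(in_top=5))
        assert report.ef("ct1", 0.01) == pytest.approx(10.0)

    def test_upper_bound_ef_equals_inverse_fraction(self):
        report = enrichment_factors(self._big_table(in_top=10))
        assert report.ef("ct1", 0.01) == pytest.approx(20.0)

    def test_union_of_all_compounds_is_exactly_one(self):
        table = self._big_table(in_top=7)
        df = table.df.copy()
        df["chemotype"] = "all"
        for f in (0.01, 0.05, 0.10, 0.37):
            report = enrichment_factors(ScreenTable(df), fractions=[f])
            assert report.ef("all", f) == 1.0

    def test_uniformly_spread_cluster_is_near_one(self):
        rows = []
        for pos in range(1000):
            member = pos % 20 == 10  # every 20th compound, centered blocks
            rows.append({
                "id": f"c{pos:04d}",
                "role": "active" if member else "decoy",
                "pharmacology": "agonist" if member else "none",
                "chemotype": "ct1" if member else "",
                "score_1": float(pos),
            })
        report = enrichment_factors(ScreenTable(pd.DataFrame(rows)))
        for f in (0.05, 0.10):
            assert report.ef("ct1", f) == pytest.approx(1.0, abs=0.25)

    def test_empty_cluster_flagged_not_error(self):
        table = self._big_table(in_top=5)
        report = enrichment_factors(table, chemotypes=["ct1", "ghost"])
        row = report.table[(report.table["chemotype"] == "ghost")]
        assert not row["defined"].any()


class TestRefinementLigandRank:
    def test_top_ranked_and_percentile(self):
        t = _ranked_table("AD" * 100)
        rank, pct = refinement_ligand_rank(t, "c000")
        assert rank == 1
        rank, pct = refinement_ligand_rank(t, "c100")
        assert rank == 101
        assert pct == pytest.approx(0.505)

    def test_absent_id_raises(self):
        with pytest.raises(IdError):
            refinement_ligand_rank(_ranked_table("AD"), "nope")


class TestChemotypes:
    smiles = {
        "benz1": "NC(=N)c1ccccc1",          # benzamidine
        "benz2": "NC(=N)c1ccc(C)cc1",       # methylbenzamidine
        "acid1": "OC(=O)c1ccccc1",          # benzoic acid
        "acid2": "OC(=O)c1ccc(O)cc1",       # hydroxybenzoic acid
        "alk1": "CCCCCC",                   # hexane
        "dup": "NC(=N)c1ccccc1",            # duplicate of benz1
    }

    def _mols(self, names):
        from rdkit import Chem

        return {n: Chem.MolFromSmiles(self.smiles[n]) for n in names}

    def test_duplicates_share_a_label(self):
        labels = cluster_chemotypes(self._mols(["benz1", "dup", "alk1"]))
        assert labels["benz1"] == labels["dup"]

    def test_no_shared_pharmacophores_separate(self):
        labels = cluster_chemotypes(self._mols(["benz1", "alk1"]), cutoff=0.5)
        assert labels["benz1"] != labels["alk1"]

    def test_matches_brute_force_complete_linkage(self):
        from rdkit import DataStructs
        from rdkit.Chem.Pharm2D import Generate, Gobbi_Pharm2D

        names = ["acid1", "acid2", "alk1", "benz1", "benz2", "dup"]
        mols = self._mols(names)
        fps = {n: Generate.Gen2DFingerprint(mols[n], Gobbi_Pharm2D.factory)
               for n in names}
        cutoff = 0.5
        # naive agglomeration oracle
        clusters = [{n} for n in names]

        def complete(a, b):
            return max(
                1 - DataStructs.TanimotoSimilarity(fps[x], fps[y])
                for x in a for y in b
            )

        while True:
            best, pair = None, None
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    d = complete(clusters[i], clusters[j])
                    if best is None or d < best:
                        best, pair = d, (i, j)
            if best is None or best >= cutoff:
                break
            i, j = pair
            clusters[i] |= clusters[j]
            del clusters[j]
        oracle = {frozenset(c) for c in clusters}

        labels = cluster_chemotypes(mols, cutoff=cutoff)
        mine = {}
        for n, lb in labels.items():
            mine.setdefault(lb, set()).add(n)
        assert {frozenset(c) for c in mine.values()} == oracle

    def test_label_stability_under_input_order(self):
        names = ["benz1", "acid1", "alk1", "benz2"]
        a = cluster_chemotypes(self._mols(names))
        b = cluster_chemotypes(self._mols(list(reversed(names))))
        assert a == b


class TestRacemicLibrary:
    def _mol(self, smi):
        from rdkit import Chem

        return Chem.MolFromSmiles(smi)

    def test_one_unassigned_stereocenter_gives_two_records(self):
        out, warns = prepare_racemic_library({"m": self._mol("CC(N)C(=O)O")})
        assert len(out) == 2 and not warns

    def test_assigned_centers_untouched(self):
        out, _ = prepare_racemic_library({"m": self._mol("C[C@H](N)C(=O)O")})
        assert list(out) == ["m"]

    def test_duplicates_collapse(self):
        out, _ = prepare_racemic_library({
            "a": self._mol("c1ccccc1O"),
            "b": self._mol("Oc1ccccc1"),
        })
        assert list(out) == ["a"]

    def test_enumeration_overflow_passes_through_with_warning(self):
        smi = "CC(O)C(O)C(O)C(O)C(O)C(O)CO"  # 6 unassigned centers
        with pytest.warns(UserWarning):
            out, warns = prepare_racemic_library(
                {"m": self._mol(smi)}, max_isomers=4
            )
        assert list(out) == ["m"] and warns
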