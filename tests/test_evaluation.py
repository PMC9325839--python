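"""Evaluation analyses: batch reduction, similarity, scaffolds, classifier."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import DataStructs

from promgen.chem import bm_scaffold, canonicalize, ecfp6, ecfp6_rdkit, tanimoto
from promgen.curation import CuratedSets
from promgen.evaluation import (
    PromiscuityClassifier,
    classify_generated,
    neighbors,
    nll_summary,
    reduce_batch,
    retrieval,
    scaffold_analysis,
    train_classifier,
)


def _sets(multi_train, multi_test=(), single_test=(), none_test=()):
    def as_map(items, prefix):
        return {f"{prefix}{i}": canonicalize(s) for i, s in enumerate(items)}

    return CuratedSets(
        as_map(multi_train, "MT"), as_map(multi_test, "MU"),
        as_map(single_test, "ST"), as_map(none_test, "NT"),
    )


class TestReduceBatch:
    def test_duplicates_collapse_and_invalid_counted(self):
        batch = reduce_batch(["CCO", "OCC", "C1CC"], {})
        assert batch.n_raw == 3
        assert batch.n_valid == 2
        assert batch.unique == {"CCO"}

    def test_all_invalid_gives_empty_unique(self):
        batch = reduce_batch(["C1CC", "xyz", ""], {})
        assert batch.n_valid == 0 and batch.unique == frozenset()

    def test_planted_known_members_flagged_as_reproduced(self):
        known = {"set_a": [canonicalize(f"{'C'*i}O") for i in range(1, 8)]}
        raw = known["set_a"] + ["c1ccccc1", "C1CC"]
        batch = reduce_batch(raw, known)
        assert len(batch.reproduced["set_a"]) == 7
        assert batch.novel == {"c1ccccc1"}

    def test_reproduced_plus_novel_conserves_unique(self, universe_smiles):
        known = {"a": universe_smiles[:40], "b": universe_smiles[30:80]}
        raw = universe_smiles[:100] + ["C1CC", "CCO", "CCO"]
        batch = reduce_batch(raw, known, epoch=3)
        all_reproduced = set().union(*batch.reproduced.values())
        assert all_reproduced | set(batch.novel) == set(batch.unique)
        assert len(batch.unique) <= batch.n_valid <= batch.n_raw


class TestFingerprints:
    def test_spelling_invariance(self):
        assert np.array_equal(ecfp6("CCO"), ecfp6("OCC"))

    def test_different_molecules_differ(self):
        assert not np.array_equal(ecfp6("C"), ecfp6("CCO"))

    def test_larger_molecule_sets_more_bits(self, universe_smiles):
        big = max(universe_smiles, key=len)
        assert ecfp6(big).sum() > ecfp6("C").sum()

    def test_tanimoto_identities(self):
        a = np.zeros(2048, dtype=bool)
        a[[1, 2, 3]] = True
        b = np.zeros(2048, dtype=bool)
        b[[2, 3, 4]] = True
        assert tanimoto(a, a) == 1.0
        assert tanimoto(a, ~a & False) == 0.0  # disjoint (empty) sets
        assert tanimoto(a, b) == 0.5
        assert tanimoto(np.zeros(8, bool), np.zeros(8, bool)) == 0.0

    def test_tanimoto_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto(np.zeros(8, bool), np.zeros(9, bool))

    def test_tanimoto_matches_set_arithmetic_on_random_vectors(self):
        rng = np.random.default_rng(0)
        A = rng.random((50, 256)) < 0.2
        B = rng.random((50, 256)) < 0.2
        for a, b in zip(A, B):
            sa, sb = set(np.flatnonzero(a)), set(np.flatnonzero(b))
            union = len(sa | sb)
            expected = (len(sa & sb) / union) if union else 0.0
            assert tanimoto(a, b) == pytest.approx(expected, abs=1e-12)

    def test_numpy_tanimoto_agrees_with_rdkit_bulk(self, universe_smiles):
        probes = universe_smiles[:20]
        ref = universe_smiles[20:40]
        for p in probes[:5]:
            sims = DataStructs.BulkTanimotoSimilarity(
                ecfp6_rdkit(p), [ecfp6_rdkit(r) for r in ref]
            )
            mine = [tanimoto(ecfp6(p), ecfp6(r)) for r in ref]
            assert np.allclose(sims, mine, atol=1e-12)


class TestNeighbors:
    def test_pair_enumeration_on_small_grid(self):
        gen = ["c1ccccc1CCO", "c1ccccc1CCN", "c1ccccc1CC"]
        known = ["c1ccccc1CCOC", "c1ccccc1CCON"]
        sets = _sets(multi_train=known)
        batch = reduce_batch(gen, {"multi_train": sets.smiles("multi_train")})
        df = neighbors(batch, sets, threshold=0.0)
        row = df[df.set == "multi_train"].iloc[0]
        assert row.pairs == 6  # all 3x2 pairs at threshold 0
        assert row.pairs_per_known == pytest.approx(3.0)

    def test_exact_reproductions_excluded(self):
        member = canonicalize("c1ccccc1CCO")
        sets = _sets(multi_train=[member])
        batch = reduce_batch([member], {"multi_train": [member]})
        df = neighbors(batch, sets, threshold=0.0)
        assert df[df.set == "multi_train"].iloc[0].pairs == 0

    def test_threshold_is_inclusive(self):
        a, b = "c1ccccc1CCO", "c1ccccc1CCOC"
        tc = tanimoto(ecfp6(a), ecfp6(b))
        sets = _sets(multi_train=[b])
        batch = reduce_batch([a], {"multi_train": sets.smiles("multi_train")})
        at_tc = neighbors(batch, sets, threshold=tc)
        assert at_tc[at_tc.set == "multi_train"].iloc[0].pairs == 1

    def test_raising_threshold_never_increases_counts(self, universe_smiles):
        sets = _sets(multi_train=universe_smiles[:25])
        batch = reduce_batch(universe_smiles[100:140], {"multi_train": sets.smiles("multi_train")})
        counts = [
            neighbors(batch, sets, threshold=t)[lambda d: d.set == "multi_train"].iloc[0].pairs
            for t in (0.2, 0.4, 0.6, 0.8)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_counts_match_exhaustive_enumeration(self, universe_smiles):
        gen_smiles = universe_smiles[200:250]
        known = universe_smiles[:50]
        sets = _sets(multi_train=known)
        batch = reduce_batch(gen_smiles, {"multi_train": sets.smiles("multi_train")})
        df = neighbors(batch, sets, threshold=0.6)
        brute = sum(
            tanimoto(ecfp6(g), ecfp6(k)) >= 0.6
            for g in sorted(batch.novel)
            for k in sets.smiles("multi_train")
        )
        assert df[df.set == "multi_train"].iloc[0].pairs == brute


class TestRetrieval:
    def test_sample_equal_to_training_set(self, universe_smiles):
        sets = _sets(multi_train=universe_smiles[:10], single_test=universe_smiles[10:20])
        batch = reduce_batch(
            universe_smiles[:10], {n: sets.smiles(n) for n in sets.set_items()}
        )
        df = retrieval(batch, sets)
        assert df[df.set == "multi_train"].iloc[0].pct == 100.0
        assert df[df.set == "single_test"].iloc[0].pct == 0.0

    def test_empty_sample_retrieves_nothing(self, universe_smiles):
        sets = _sets(multi_train=universe_smiles[:10])
        batch = reduce_batch([], {})
        df = retrieval(batch, sets)
        assert (df.retrieved == 0).all()


class TestScaffolds:
    # hand-checked panel: molecule -> Bemis-Murcko scaffold
    PANEL = [
        ("CCc1ccccc1", "c1ccccc1"),                  # side chain pruned
        ("CCO", ""),                                  # acyclic: no scaffold
        ("CC(C)CC(=O)O", ""),                         # acyclic with branches
        ("c1ccc2ccccc2c1", "c1ccc2ccccc2c1"),         # fused rings kept whole
        ("CCc1ccc2ccccc2c1", "c1ccc2ccccc2c1"),       # substituted naphthalene
        ("OCC1CCCCC1", "C1CCCCC1"),                   # hydroxymethyl pruned
        ("C1CCCCC1c1ccccc1", "C1CCCCC1c1ccccc1"),     # linker-joined rings kept
        ("CC(=O)Nc1ccccc1", "c1ccccc1"),              # amide side chain pruned
        ("O=C(c1ccccc1)N1CCCCC1", "O=C(c1ccccc1)N1CCCCC1"),  # carbonyl linker kept
        ("CCCCCCCC", ""),                             # plain chain
    ]

    @pytest.mark.parametrize("smiles, expected", PANEL)
    def test_hand_checked_panel(self, smiles, expected):
        want = canonicalize(expected) if expected else ""
        assert bm_scaffold(smiles) == want

    def test_idempotent_on_universe(self, universe_smiles):
        for smi in universe_smiles[::10]:
            sc = bm_scaffold(smi)
            if sc:
                assert bm_scaffold(sc) == sc

    def test_generated_equal_to_training_gives_full_retrieval(self, universe_smiles):
        sets = _sets(multi_train=universe_smiles[:30], multi_test=universe_smiles[30:60])
        batch = reduce_batch(universe_smiles[:30], {n: sets.smiles(n) for n in sets.set_items()})
        df = scaffold_analysis({0: batch}, sets)
        assert df[df.set == "multi_train"].iloc[0].fraction == 1.0

    def test_empty_generated_set_retrieves_nothing(self, universe_smiles):
        sets = _sets(multi_train=universe_smiles[:30])
        batch = reduce_batch([], {})
        df = scaffold_analysis({0: batch}, sets)
        assert (df.retrieved == 0).all()


class TestNllSummary:
    def test_identical_members_collapse_quartiles(self, trained_generator):
        smi = canonicalize("c1ccccc1CCO")
        sets = CuratedSets({f"M{i}": smi for i in range(9)}, {}, {}, {})
        df = nll_summary({0: trained_generator}, sets)
        row = df[(df.set == "multi_train")].iloc[0]
        assert row.q25 == row["median"] == row.q75

    def test_quartiles_match_direct_percentiles(self, trained_generator, universe_smiles):
        members = universe_smiles[:40]
        sets = _sets(multi_train=members)
        df = nll_summary({0: trained_generator}, sets)
        row = df[df.set == "multi_train"].iloc[0]
        raw = trained_generator.sequence_nll(sets.smiles("multi_train"))
        q25, med, q75 = np.percentile(raw, [25, 50, 75])
        assert (row.q25, row["median"], row.q75) == pytest.approx((q25, med, q75))
        assert row.q25 <= row["median"] <= row.q75


class TestClassifier:
    def test_perfect_separation_on_single_motif_toy(self):
        """A single ring swap (furan vs benzene) separates the classes by one
        fingerprint bit pattern: held-out AUC and MCC are exactly 1."""
        pos = [f"c1ccoc1{'C' * i}" for i in range(1, 21)]
        neg = [f"c1ccccc1{'C' * i}" for i in range(1, 21)]
        clf = PromiscuityClassifier(random_state=0).fit(
            pos[:12] + neg[:12], [1] * 12 + [0] * 12
        )
        X_held, y_held = pos[12:] + neg[12:], np.array([1] * 8 + [0] * 8)
        proba = clf.predict_proba(X_held)[:, 1]
        from sklearn.metrics import matthews_corrcoef, roc_auc_score

        assert roc_auc_score(y_held, proba) == 1.0
        assert matthews_corrcoef(y_held, proba >= 0.5) == 1.0

    def test_permuted_labels_give_chance_auc(self, small_universe):
        rng = np.random.default_rng(0)
        smiles = [c.smiles for c in small_universe.compounds[:300]]
        y = rng.permutation([1] * 150 + [0] * 150)
        clf = PromiscuityClassifier(n_estimators=50, random_state=1).fit(
            smiles[:200], y[:200]
        )
        from sklearn.metrics import roc_auc_score

        auc = roc_auc_score(y[200:], clf.predict_proba(smiles[200:])[:, 1])
        assert 0.3 < auc < 0.7

    def test_single_class_input_rejected(self):
        with pytest.raises(ValueError):
            PromiscuityClassifier().fit(["CCO", "CCN"], [1, 1])

    def test_bundle_metrics_on_held_out_universe(self, small_universe):
        from promgen.curation import curate

        smiles_by_id = {c.compound_id: c.smiles for c in small_universe.compounds}
        sets = curate(
            small_universe.records, smiles_by_id, max_hit_rate=0.05, n_train=30, seed=5
        )
        bundle = train_classifier(sets, n_negative_per_class=60, seed=8)
        assert bundle.metrics["roc_auc"] > 0.7

    def test_classify_generated_conventions(self, small_universe):
        from promgen.curation import curate

        smiles_by_id = {c.compound_id: c.smiles for c in small_universe.compounds}
        sets = curate(
            small_universe.records, smiles_by_id, max_hit_rate=0.05, n_train=30, seed=5
        )
        bundle = train_classifier(sets, n_negative_per_class=60, seed=8)
        known = {n: sets.smiles(n) for n in sets.set_items()}
        full = reduce_batch(sets.smiles("multi_train"), known, epoch=1)
        empty = reduce_batch([], known, epoch=0)
        df = classify_generated(bundle, {0: empty, 1: full})
        assert np.isnan(df[df.epoch == 0].fraction_multi.iloc[0])
        frac = df[df.epoch == 1].fraction_multi.iloc[0]
        recall_on_train = np.mean(bundle.classifier.predict(sets.smiles("multi_train")))
        assert frac >= recall_on_train - 1e-9
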