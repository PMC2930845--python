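"""Subsequence-profile feature space: extraction, clustering, mapping, SVM."""

import numpy as np
import pytest

from gofunc.errors import FitError, ValidationError
from gofunc.spmap import (
    SpmapMethod,
    build_feature_space,
    build_profiles,
    cluster_subsequences,
    extract_subsequences,
    map_sequence,
    ungapped_score,
)
from gofunc.synthetic import SignalSpec, generate_term_family


class TestExtract:
    @pytest.mark.parametrize(
        "length,l,expected", [(10, 5, 6), (5, 5, 1), (4, 5, 0)]
    )
    def test_window_counts(self, length, l, expected):
        assert len(extract_subsequences(["A" * length], l)) == expected

    def test_l_below_two_rejected(self):
        with pytest.raises(ValueError):
            extract_subsequences(["AAAA"], 1)


class TestClustering:
    def test_identical_subsequences_merge(self):
        clusters = cluster_subsequences(["ACD", "ACD"], threshold=8.0)
        assert len(clusters) == 1 and len(clusters[0].members) == 2

    def test_threshold_above_self_score_gives_singletons(self):
        subs = ["ACD", "WFY", "KRE"]
        clusters = cluster_subsequences(subs, threshold=1000.0)
        assert len(clusters) == len(subs)

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValidationError):
            cluster_subsequences(["AC", "ACD"])

    def test_greedy_trace_matches_hand_replay(self):
        """Replay the greedy rule with independently computed scores."""
        subs = ["AAA", "AAS", "WWW", "WWF", "KKK"]
        threshold = 10.0
        ordered = sorted(subs)
        reps, assign = [], []
        for s in ordered:
            placed = False
            for ci, r in enumerate(reps):
                if ungapped_score(s, r) >= threshold:
                    assign.append(ci)
                    placed = True
                    break
            if not placed:
                reps.append(s)
                assign.append(len(reps) - 1)
        clusters = cluster_subsequences(subs, threshold=threshold)
        assert [c.representative for c in clusters] == reps
        got = {c.representative: sorted(c.members) for c in clusters}
        want = {}
        for s, ci in zip(ordered, assign):
            want.setdefault(reps[ci], []).append(s)
        assert got == {k: sorted(v) for k, v in want.items()}


class TestProfiles:
    def test_single_member_pseudocount(self):
        pm = build_profiles(cluster_subsequences(["AAA"]), pseudocount=1.0)
        prof = pm.clusters[0].profile
        a = "ACDEFGHIKLMNPQRSTVWY".index("A")
        assert prof[:, a] == pytest.approx([2 / 21] * 3)
        assert prof.sum(axis=1) == pytest.approx([1.0] * 3)

    def test_small_pseudocount_limit(self):
        pm = build_profiles(cluster_subsequences(["AC", "AC"]), pseudocount=1e-9)
        a = "ACDEFGHIKLMNPQRSTVWY".index("A")
        assert pm.clusters[0].profile[0, a] == pytest.approx(1.0, abs=1e-6)

    def test_two_member_counts(self):
        clusters = cluster_subsequences(["AC", "AD"], threshold=-100.0)
        assert len(clusters) == 1
        pm = build_profiles(clusters, pseudocount=1.0)
        prof = pm.clusters[0].profile
        order = "ACDEFGHIKLMNPQRSTVWY"
        assert prof[1, order.index("C")] == pytest.approx(2 / 22)
        assert prof[1, order.index("D")] == pytest.approx(2 / 22)
        assert prof[1, order.index("A")] == pytest.approx(1 / 22)

    def test_bad_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            build_profiles(cluster_subsequences(["AAA"]), pseudocount=0.0)


class TestMapping:
    def brute_force_vector(self, seq, pm):
        out = []
        for c in pm.clusters:
            best = -np.inf
            l = pm.subsequence_length
            for i in range(len(seq) - l + 1):
                w = seq[i : i + l]
                logp = sum(
                    np.log(c.profile[j, "ACDEFGHIKLMNPQRSTVWY".index(a)])
                    for j, a in enumerate(w)
                )
                best = max(best, logp)
            out.append(np.exp(best / l))
        return np.array(out)

    def test_matches_exhaustive_enumeration(self):
        pm = build_feature_space(["WWPDYWAC", "KKRKEKRK"], l=4, threshold=8.0)
        seq = "AWWPDYKK"
        assert map_sequence(seq, pm) == pytest.approx(self.brute_force_vector(seq, pm))

    def test_dimension_equals_cluster_count(self):
        pm = build_feature_space(["WWPDYWAC", "KKRKEKRK"], l=4)
        assert len(map_sequence("AAAAWWKK", pm)) == pm.dimension

    def test_representative_window_attains_max(self):
        pm = build_feature_space(["WWPDY"], l=5, threshold=1000.0)
        rep = pm.clusters[0].representative
        seq = "ACACA" + rep + "GGGGG"
        v = map_sequence(seq, pm)
        # appending the representative can only raise that dimension
        base = map_sequence("ACACAGGGGG", pm)
        assert v[0] >= base[0]

    def test_values_in_unit_interval(self):
        pm = build_feature_space(["WWPDYWAC", "KKRKEKRK"], l=4)
        v = map_sequence("MKTAYIAKQRQISFVK", pm)
        assert np.all(v >= 0.0) and np.all(v <= 1.0)

    def test_short_sequence_rejected(self):
        pm = build_feature_space(["WWPDY"], l=5)
        with pytest.raises(ValidationError):
            map_sequence("ACD", pm)

    def test_roundtrip_json(self, tmp_path):
        pm = build_feature_space(["WWPDYWAC"], l=4)
        pm.to_json(tmp_path / "pm.json")
        from gofunc.spmap import ProfileMap

        back = ProfileMap.from_json(tmp_path / "pm.json")
        assert back.dimension == pm.dimension
        for a, b in zip(pm.clusters, back.clusters):
            assert a.representative == b.representative
            assert a.profile == pytest.approx(b.profile)


class TestMarginClassifier:
    def _family(self, seed=7, n=40):
        pos, _ = generate_term_family(
            "GO:1", n, SignalSpec(kind="motif", motif="WWPDYW", fraction=1.0),
            seed=seed,
        )
        neg, _ = generate_term_family(
            "GO:2", n, SignalSpec(kind="motif", fraction=0.0), seed=seed + 1,
        )
        seqs = list(pos.values()) + list(neg.values())
        labels = np.array([True] * n + [False] * n)
        return seqs, labels

    def test_planted_motif_family_separable(self):
        seqs, labels = self._family(seed=7)
        rng = np.random.default_rng(7)
        idx = rng.permutation(len(seqs))
        train, test = idx[:60], idx[60:]
        m = SpmapMethod(random_state=0)
        m.fit([f"s{i}" for i in train], [seqs[i] for i in train], labels[train])
        pred = m.decision_values([seqs[i] for i in test]) > 0
        assert (pred == labels[test]).mean() > 0.9

    def test_separable_toy_set_perfect_training_accuracy(self):
        from gofunc.margin import fit_margin_classifier

        X = np.array([[0.0, 0.0], [0.1, 0.2], [1.0, 1.0], [0.9, 1.1]])
        y = np.array([False, False, True, True])
        model = fit_margin_classifier(X, y)
        assert ((model.decision_values(X) > 0) == y).all()

    def test_label_flip_negates_decision(self):
        from gofunc.margin import fit_margin_classifier

        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(3, 1, (10, 3))])
        y = np.arange(20) >= 10
        d1 = fit_margin_classifier(X, y).decision_values(X)
        d2 = fit_margin_classifier(X, ~y).decision_values(X)
        # numerically negated up to solver tolerance; signs must flip exactly
        assert d1 == pytest.approx(-d2, abs=1e-2)
        assert (np.sign(d1) == -np.sign(d2)).all()

    def test_single_class_rejected(self):
        seqs, _ = self._family(seed=5, n=6)
        with pytest.raises(FitError):
            SpmapMethod().fit(None, seqs, np.ones(len(seqs), dtype=bool))
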