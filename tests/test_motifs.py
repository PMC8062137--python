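"""PWM scanning, exact DP p-values, and differential binding scores."""

import itertools

import numpy as np
import pandas as pd
import pytest

from paleompra.errors import InputError
from paleompra.motifs import (
    PWM,
    background_model,
    diff_binding,
    log_odds,
    random_pwms,
    scan_batch,
    scan_sequence,
    score_distribution,
    tf_analyses,
    trim_to_variant,
)


def sharp_pwm(consensus: str, p: float = 0.85) -> PWM:
    rows = []
    for ch in consensus:
        row = np.full(4, (1 - p) / 3)
        row["ACGT".index(ch)] = p
        rows.append(row)
    return PWM("M_test", "TF_test", np.array(rows))


class TestBackground:
    def test_strand_symmetric(self):
        bg = background_model(["AAAA"])
        assert bg[0] == pytest.approx(0.5) and bg[3] == pytest.approx(0.5)
        assert bg.sum() == pytest.approx(1.0)

    def test_uniform_sequences(self, rng):
        seqs = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
                for _ in range(20)]
        bg = background_model(seqs)
        assert np.allclose(bg, 0.25, atol=0.02)

    def test_non_acgt_skipped(self):
        bg = background_model(["ACGTNNN"])
        assert bg.sum() == pytest.approx(1.0)
        with pytest.raises(InputError):
            background_model(["NNN"])


class TestScan:
    def test_consensus_is_the_maximizer(self, rng):
        pwm = sharp_pwm("ACGTAC")
        flank = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)])
        seq = flank + pwm.consensus + flank
        hits = scan_sequence(seq, pwm, np.full(4, 0.25))
        best = hits.loc[hits["score"].idxmax()]
        assert best["start"] == 30 and best["strand"] == "+"

    def test_reverse_complement_symmetry(self, rng):
        pwm = sharp_pwm("ACGGTA")
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        fwd = scan_sequence(seq, pwm, np.full(4, 0.25))
        rev = scan_sequence(rc, pwm, np.full(4, 0.25))
        a = fwd.sort_values(["start", "strand"], ignore_index=True)
        b = rev.sort_values(["start", "strand"], ignore_index=True)
        # same multiset of scores; strands swap
        assert np.allclose(np.sort(a["score"]), np.sort(b["score"]))
        assert (a.groupby("strand").size()["+"]
                == b.groupby("strand").size()["-"])

    def test_motif_longer_than_sequence_is_empty(self):
        pwm = sharp_pwm("ACGTACGT")
        assert len(scan_sequence("ACG", pwm, np.full(4, 0.25))) == 0


class TestExactPValues:
    @pytest.mark.parametrize("length", [4, 6, 8])
    def test_dp_equals_exhaustive_enumeration(self, length, rng):
        """DP tail probabilities match brute-force enumeration over all 4^L words."""
        pwm = PWM("M", "TF", rng.dirichlet(np.full(4, 0.7), size=length))
        bg = background_model(
            ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])])
        lo = log_odds(pwm, bg)
        q, delta, offset, tail = score_distribution(lo, bg)

        words = np.array(list(itertools.product(range(4), repeat=length)))
        word_scores = q[np.arange(length), words].sum(axis=1)
        word_probs = np.prod(bg[words], axis=1)
        for s in np.unique(word_scores)[::7]:
            exact = word_probs[word_scores >= s].sum()
            dp = tail[s - offset]
            assert dp == pytest.approx(exact, rel=1e-9, abs=1e-15)

    def test_p_values_in_unit_interval_and_tail_sums_to_one(self, rng):
        pwm = PWM("M", "TF", rng.dirichlet(np.full(4, 0.5), size=10))
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        _, _, _, tail = score_distribution(log_odds(pwm, bg), bg)
        assert tail[0] == pytest.approx(1.0)
        assert (np.diff(tail) <= 1e-12).all()


class TestTrim:
    def test_central_variant(self):
        mod = "A" * 100 + "G" + "A" * 99
        arc = "A" * 100 + "C" + "A" * 99
        m, a, start = trim_to_variant(mod, arc, (100,))
        assert len(m) == 61 and start == 70
        assert m[30] == "G" and a[30] == "C"

    def test_multi_variant_untouched(self):
        mod = "A" * 200
        m, a, start = trim_to_variant(mod, mod, (50, 120))
        assert len(m) == 200 and start == 0

    def test_edge_clipping(self):
        mod = "A" * 200
        m, _, start = trim_to_variant(mod, mod, (10,))
        assert start == 0 and len(m) == 41


class TestDiffBinding:
    def _hits(self, rows):
        return pd.DataFrame(rows, columns=[
            "pair_id", "allele", "motif_id", "strand", "start", "score", "p", "q"])

    def test_identical_alleles_zero_diff(self):
        rows = [("p1", al, "M1", "+", 5, 10.0, 1e-6, 0.01) for al in ("modern", "archaic")]
        db = diff_binding(self._hits(rows), pd.DataFrame({"motif_id": ["M1"], "tf": ["T"]}))
        assert db["score_diff"].iloc[0] == 0.0 and db["filled"].iloc[0] == "none"

    def test_conservative_fill_uses_batch_minimum(self):
        rows = [
            ("p1", "modern", "M1", "+", 5, 12.0, 1e-6, 0.01),
            ("p2", "modern", "M1", "+", 3, 6.1, 1e-5, 0.02),   # batch minimum 6.1
            ("p2", "archaic", "M1", "+", 3, 6.5, 1e-5, 0.02),
        ]
        db = diff_binding(self._hits(rows), pd.DataFrame({"motif_id": ["M1"], "tf": ["T"]}))
        row = db[db["pair_id"] == "p1"].iloc[0]
        assert row["filled"] == "archaic"
        assert row["score_archaic"] == pytest.approx(6.1)
        assert row["score_diff"] == pytest.approx(12.0 - 6.1)

    def test_q_gate_and_largest_diff_per_tf(self):
        rows = [
            ("p1", "modern", "M1", "+", 5, 10.0, 1e-6, 0.2),
            ("p1", "archaic", "M1", "+", 5, 8.0, 1e-5, 0.3),   # neither q <= 0.05: drop
            ("p1", "modern", "M2", "+", 7, 9.0, 1e-6, 0.01),
            ("p1", "archaic", "M2", "+", 7, 7.8, 1e-5, 0.3),   # +1.2
            ("p1", "modern", "M3", "-", 2, 5.0, 1e-6, 0.01),
            ("p1", "archaic", "M3", "-", 2, 8.0, 1e-5, 0.01),  # -3.0 wins for the TF
        ]
        meta = pd.DataFrame({"motif_id": ["M1", "M2", "M3"], "tf": ["T", "T", "T"]})
        db = diff_binding(self._hits(rows), meta)
        assert len(db) == 1
        assert db["score_diff"].iloc[0] == pytest.approx(-3.0)
        assert db["motif_id"].iloc[0] == "M3"

    def test_antisymmetry_under_allele_swap(self):
        rows = [
            ("p1", "modern", "M1", "+", 5, 11.0, 1e-6, 0.01),
            ("p1", "archaic", "M1", "+", 5, 9.0, 1e-5, 0.02),
            ("p2", "modern", "M1", "-", 1, 7.0, 1e-5, 0.01),
        ]
        meta = pd.DataFrame({"motif_id": ["M1"], "tf": ["T"]})
        hits = self._hits(rows)
        db = diff_binding(hits, meta)
        swapped = hits.copy()
        swapped["allele"] = swapped["allele"].map({"modern": "archaic",
                                                   "archaic": "modern"})
        db2 = diff_binding(swapped, meta)
        a = db.set_index("pair_id")["score_diff"]
        b = db2.set_index("pair_id")["score_diff"]
        assert np.allclose(a, -b.reindex(a.index))


class TestTfAnalyses:
    def _setup(self, rng, n_pairs=60, planted=True):
        pairs = [f"p{i}" for i in range(n_pairs)]
        lfc = rng.normal(0, 0.4, n_pairs)
        diff = pd.DataFrame({
            "pair_id": pairs, "lfc": lfc, "p": 0.001,
            "fdr": np.where(np.arange(n_pairs) < 30, 0.01, 0.5),
        })
        rows = []
        for i, p in enumerate(pairs[:30]):  # planted TF sites on differential pairs
            score = lfc[i] + rng.normal(0, 0.1) if planted else rng.normal(0, 1)
            rows.append({"pair_id": p, "tf": "TF_PLANT", "motif_id": "M0",
                         "score_modern": 1.0, "score_archaic": 1.0 - score,
                         "score_diff": score, "filled": "none"})
        for p in rng.choice(pairs, 15, replace=False):  # background TF everywhere
            rows.append({"pair_id": p, "tf": "TF_BG", "motif_id": "M1",
                         "score_modern": 1.0, "score_archaic": 0.5,
                         "score_diff": rng.normal(0, 1), "filled": "none"})
        return pd.DataFrame(rows), diff, pairs

    def test_planted_tf_correlation_recovered(self, rng):
        db, diff, pairs = self._setup(rng)
        res = tf_analyses(db, diff, pairs, min_sites=10)
        corr = res["correlation"].set_index("tf")
        assert corr.loc["TF_PLANT", "r"] > 0.8
        assert corr.loc["TF_PLANT", "fdr"] <= 0.05

    def test_min_sites_excludes_small_tfs(self, rng):
        db, diff, pairs = self._setup(rng)
        db_small = db[db["tf"] != "TF_BG"].iloc[:9]
        res = tf_analyses(db_small, diff, pairs, min_sites=10)
        assert len(res["enrichment"]) == 0

    def test_fpkm_filter(self, rng):
        db, diff, pairs = self._setup(rng)
        expr = pd.DataFrame({"tf": ["TF_PLANT", "TF_BG"], "fpkm": [0.5, 5.0]})
        res = tf_analyses(db, diff, pairs, tf_expression=expr, min_sites=10)
        assert "TF_PLANT" not in set(res["enrichment"].get("tf", []))

    def test_directionality_binomial(self, rng):
        db, diff, pairs = self._setup(rng)
        res = tf_analyses(db, diff, pairs, min_sites=10)
        d = res["directionality"]
        from scipy.stats import binom
        assert d["p"] == pytest.approx(float(binom.sf(d["k"] - 1, d["n"], 0.5)))
        assert d["p"] < 0.05  # planted signs agree


def test_scan_batch_q_family_and_reporting(rng):
    pwm = sharp_pwm("ACGTACGT", p=0.95)
    flank = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 40)])
    seqs = {"with": flank + pwm.consensus + flank, "without": flank + flank}
    hits = scan_batch(seqs, pwm, np.full(4, 0.25))
    assert (hits["p"] <= 1e-4).all()
    assert set(hits["seq_id"]) <= {"with", "without"}
    assert "with" in set(hits["seq_id"])
    assert (hits["q"] >= hits["p"] - 1e-15).all()


def test_random_pwms_valid_and_deterministic():
    a = random_pwms(10, ["T1", "T2"], seed=5)
    b = random_pwms(10, ["T1", "T2"], seed=5)
    assert all(np.allclose(x.matrix, y.matrix) for x, y in zip(a, b))
    assert all(np.allclose(p.matrix.sum(axis=1), 1.0) for p in a)
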