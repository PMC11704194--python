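"""Gene/arm copy scores against per-base oracles; contexts, NMF, Fisher tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from protegrate import cnv_genomics as cg


def _seg(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "nmark", "log2"])


def _per_base_mean(segments, chrom, start, end, sample):
    """Brute-force oracle: enumerate every base of [start, end] and average the
    log2 ratio of the segment covering it (bases covered by no segment skipped)."""
    vals = []
    sub = segments[(segments["sample"] == sample) & (segments["chrom"] == chrom)]
    for base in range(start, end + 1):
        hit = sub[(sub["start"] <= base) & (sub["end"] >= base)]
        if len(hit):
            vals.append(hit["log2"].iloc[0])
    return float(np.mean(vals)) if vals else np.nan


class TestGeneCopyNumber:
    GENES = pd.DataFrame({
        "gene": ["GA", "GB"], "chrom": ["1", "1"],
        "start": [100, 300], "end": [199, 399], "arm": ["1p", "1p"],
    })

    def test_gene_inside_single_segment(self):
        segs = _seg([("S1", "1", 1, 1000, 10, -1.0)])
        cn = cg.gene_copy_number(segs, self.GENES)
        assert cn.data.loc["GA", "S1"] == pytest.approx(-1.0)

    def test_equal_half_coverage_averages(self):
        segs = _seg([("S1", "1", 100, 149, 5, 0.0), ("S1", "1", 150, 199, 5, -1.0)])
        cn = cg.gene_copy_number(segs, self.GENES)
        assert cn.data.loc["GA", "S1"] == pytest.approx(-0.5)
        assert np.isnan(cn.data.loc["GB", "S1"])

    def test_unknown_chromosome_listed(self):
        segs = _seg([("S1", "chrX", 1, 10, 5, 0.0)])
        with pytest.raises(ValueError, match="chrX"):
            cg.gene_copy_number(segs, self.GENES)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instance_equals_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = pd.DataFrame({
            "gene": [f"G{i}" for i in range(5)],
            "chrom": ["1", "2", "1", "2", "1"],
            "start": rng.integers(1, 400, 5),
        })
        genes["end"] = genes["start"] + rng.integers(10, 200, 5)
        genes["arm"] = genes["chrom"] + "p"
        seg_rows = []
        for _ in range(8):
            chrom = rng.choice(["1", "2"])
            # keep per-sample/chrom segments non-overlapping by gridding
            slot = rng.integers(0, 6) * 100 + 1
            seg_rows.append(("S1", chrom, slot, slot + rng.integers(20, 99),
                             5, float(rng.normal())))
        segs = _seg(seg_rows).drop_duplicates(["chrom", "start"])
        cn = cg.gene_copy_number(segs, genes)
        for _, g in genes.iterrows():
            expected = _per_base_mean(segs, g["chrom"], g["start"], g["end"], "S1")
            got = cn.data.loc[g["gene"], "S1"]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-9)


class TestArmScore:
    GENES = pd.DataFrame({
        "gene": ["GA", "GB"], "chrom": ["1", "1"],
        "start": [1, 901], "end": [500, 1000], "arm": ["1p", "1p"],
    })

    def test_single_segment_whole_arm(self):
        segs = _seg([("S1", "1", 1, 1000, 10, -1.0)])
        arms = cg.arm_score(segs, self.GENES)
        assert arms.loc["1p", "S1"] == pytest.approx(-1.0)

    def test_equal_segments_cancel(self):
        segs = _seg([("S1", "1", 1, 500, 5, 1.0), ("S1", "1", 501, 1000, 5, -1.0)])
        arms = cg.arm_score(segs, self.GENES)
        assert arms.loc["1p", "S1"] == pytest.approx(0.0)

    def test_random_instance_equals_per_base_oracle(self):
        rng = np.random.default_rng(7)
        rows, pos = [], 1
        for _ in range(6):
            length = int(rng.integers(20, 150))
            rows.append(("S1", "1", pos, pos + length, 5, float(rng.normal())))
            pos += length + int(rng.integers(1, 50))
        segs = _seg(rows)
        arms = cg.arm_score(segs, self.GENES)
        expected = _per_base_mean(segs, "1", 1, 1000, "S1")
        assert arms.loc["1p", "S1"] == pytest.approx(expected, abs=1e-9)

    def test_empty_segments_warns_all_missing(self):
        with pytest.warns(UserWarning, match="empty"):
            arms = cg.arm_score(_seg([]), self.GENES)
        assert arms.shape[1] == 0


class TestAmpDelCalls:
    def test_boundary_inclusive_and_neutral(self):
        vals = pd.DataFrame({"S1": [1.0, -0.99, 0.0, -1.0]}, index=list("abcd"))
        calls = cg.call_amp_del(vals, cutoff=1.0)
        assert list(calls["S1"]) == ["amplified", "neutral", "neutral", "deleted"]

    def test_bad_cutoff(self):
        with pytest.raises(ValueError):
            cg.call_amp_del(pd.DataFrame([[0.0]]), cutoff=0.0)


class TestTMB:
    def test_direct_ratio(self):
        muts = pd.DataFrame({"sample": ["S1"] * 30})
        assert cg.tmb(muts, 30.0)["S1"] == pytest.approx(1.0)

    def test_zero_mutations(self):
        muts = pd.DataFrame({"sample": []})
        assert cg.tmb(muts, 30.0, samples=["S1"])["S1"] == 0

    def test_bad_coding_size(self):
        with pytest.raises(ValueError):
            cg.tmb(pd.DataFrame({"sample": ["S1"]}), 0.0)

    def test_poisson_cohort_mean_near_ten(self):
        """Poisson(316) mutations over 31.6 Mb -> mean TMB ~= 10 within 3 SE."""
        rng = np.random.default_rng(0)
        counts = rng.poisson(316, size=50)
        muts = pd.DataFrame({
            "sample": np.repeat([f"S{i}" for i in range(50)], counts)})
        t = cg.tmb(muts, 31.6)
        se = np.sqrt(316) / 31.6 / np.sqrt(50)
        assert abs(t.mean() - 10.0) < 3 * se


class TestContextMatrix:
    def test_purine_strand_collapses(self):
        # ref A with context C-A-T is the purine-strand form of A[T>C]G
        muts = pd.DataFrame([{
            "sample": "S1", "gene": "G", "chrom": "1", "pos": 5,
            "ref": "A", "alt": "G", "variant_class": "Missense_Mutation",
            "context": "CAT",
        }])
        mat = cg.context_matrix(muts)
        assert mat.loc["A[T>C]G", "S1"] == 1
        assert mat["S1"].sum() == 1

    def test_strand_invariance_full_enumeration(self):
        """All 192 strand representations map onto the canonical 96 rows."""
        comp = str.maketrans("ACGT", "TGCA")
        rows = []
        for label in cg.CONTEXTS_96:
            five, rest = label.split("[")
            sub, three = rest.split("]")
            ref, alt = sub.split(">")
            ctx = five + ref + three
            rows.append(dict(sample="P", ref=ref, alt=alt, context=ctx))
            rc = ctx.translate(comp)[::-1]
            rows.append(dict(sample="R", ref=rc[1], alt=alt.translate(comp), context=rc))
        muts = pd.DataFrame(rows).assign(gene="G", chrom="1", pos=1,
                                         variant_class="Silent")
        mat = cg.context_matrix(muts)
        assert (mat["P"] == 1).all() and (mat["R"] == 1).all()

    def test_empty_table_zero_matrix(self):
        mat = cg.context_matrix(pd.DataFrame(columns=["sample", "ref", "alt", "context"]))
        assert mat.shape == (96, 0) or (mat.to_numpy() == 0).all()

    def test_unknown_base_errors_with_row(self):
        muts = pd.DataFrame([{"sample": "S1", "gene": "G", "chrom": "1", "pos": 1,
                              "ref": "C", "alt": "N", "variant_class": "x",
                              "context": "ACA"}])
        with pytest.raises(ValueError, match="row 0"):
            cg.context_matrix(muts)


class TestSignatureNMF:
    def test_rank_one_exact_recovery(self):
        rng = np.random.default_rng(0)
        profile = rng.dirichlet(np.ones(96))
        exposure = np.array([500.0, 1000.0, 250.0])
        V = pd.DataFrame(np.outer(profile, exposure), index=cg.CONTEXTS_96,
                         columns=["a", "b", "c"])
        ref = pd.DataFrame({"R1": profile}, index=cg.CONTEXTS_96)
        fit = cg.extract_signatures(V, k=1, reference=ref, n_restarts=3, seed=0)
        assert fit.objective_trace[-1] < 1e-6 * np.linalg.norm(V.to_numpy())
        assert fit.cosine.loc["Sig1", "R1"] > 0.9999

    def test_objective_trace_monotone_nonincreasing(self):
        rng = np.random.default_rng(1)
        V = pd.DataFrame(rng.poisson(5.0, size=(96, 8)).astype(float),
                         index=cg.CONTEXTS_96, columns=[f"s{i}" for i in range(8)])
        ref = pd.DataFrame({"R1": np.full(96, 1 / 96)}, index=cg.CONTEXTS_96)
        fit = cg.extract_signatures(V, k=2, reference=ref, n_restarts=2, seed=0)
        trace = np.array(fit.objective_trace)
        assert np.all(np.diff(trace) <= 1e-8)
        assert (fit.exposures.to_numpy() >= 0).all()
        assert np.allclose(fit.profiles.sum(axis=0), 1.0, atol=1e-9)

    def test_k_too_large_errors(self):
        V = pd.DataFrame(np.ones((96, 3)), index=cg.CONTEXTS_96, columns=list("abc"))
        ref = pd.DataFrame({"R1": np.full(96, 1 / 96)}, index=cg.CONTEXTS_96)
        with pytest.raises(ValueError, match="k=5"):
            cg.extract_signatures(V, k=5, reference=ref)

    def test_matches_sklearn_reconstruction_quality(self):
        """Independent cross-check: our best-of-restarts MU NMF reaches a
        Frobenius error comparable to sklearn's NMF on the same matrix."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(2)
        W = rng.dirichlet(np.ones(96), size=2).T
        H = rng.uniform(50, 500, size=(2, 12))
        V = rng.poisson(W @ H).astype(float)
        Vdf = pd.DataFrame(V, index=cg.CONTEXTS_96, columns=[f"s{i}" for i in range(12)])
        ref = pd.DataFrame(W, index=cg.CONTEXTS_96, columns=["R1", "R2"])
        fit = cg.extract_signatures(Vdf, k=2, reference=ref, n_restarts=5, seed=0)
        sk = NMF(n_components=2, solver="mu", max_iter=2000, init="random",
                 random_state=0).fit(V)
        sk_err = np.linalg.norm(V - sk.transform(V) @ sk.components_)
        assert fit.objective_trace[-1] <= sk_err * 1.05


class TestCooccurrence:
    def _events(self, a, b):
        return pd.DataFrame([a, b], index=["fa", "fb"],
                            columns=[f"s{i}" for i in range(len(a))])

    def test_perfect_cooccurrence_matches_hypergeometric_tail(self):
        ev = self._events([1] * 10 + [0] * 10, [1] * 10 + [0] * 10)
        res = cg.cooccurrence(ev).iloc[0]
        # two-sided Fisher p by exact hypergeometric enumeration: sum the
        # probabilities of all tables at most as likely as the observed one
        pmf_obs = stats.hypergeom.pmf(10, 20, 10, 10)
        expected = sum(
            stats.hypergeom.pmf(k, 20, 10, 10)
            for k in range(11)
            if stats.hypergeom.pmf(k, 20, 10, 10) <= pmf_obs * (1 + 1e-9)
        )
        assert res["p"] == pytest.approx(expected, rel=1e-9)
        assert res["direction"] == "co-occurring"
        assert np.isinf(res["odds_ratio"]) or res["odds_ratio"] > 100

    def test_degenerate_margin_flagged(self):
        ev = self._events([1] * 6, [1, 0, 1, 0, 1, 0])
        res = cg.cooccurrence(ev).iloc[0]
        assert res["degenerate"] and res["p"] == 1.0

    def test_independent_events_calibrated(self):
        """~5% of raw Fisher p fall below 0.05 for independent plantings
        (discreteness makes the test conservative)."""
        rng = np.random.default_rng(0)
        frac = []
        for _ in range(5):
            ev = pd.DataFrame(rng.random((40, 60)) < 0.4,
                              index=[f"f{i}" for i in range(40)]).astype(int)
            res = cg.cooccurrence(ev)
            frac.append((res["p"] < 0.05).mean())
        assert np.mean(frac) <= 0.07
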