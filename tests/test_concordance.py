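import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from probelift import concordance as cc
from probelift import filters as fl
from probelift.io_formats import BetaMatrix, MethylationCall


def _pairs(betas, ratios, sample="S1", **extra):
    rows = []
    for i, (b, r) in enumerate(zip(betas, ratios)):
        rows.append(
            {
                "probe_id": f"cg{i}",
                "sample_id": sample,
                "beta": b,
                "seq_ratio": r,
                "coverage": 30,
                "mean_meth": (b + r) / 2,
                "diff": r - b,
                "bitscore": 91.0,
                "bitscore_bin": ">80",
                "unique": True,
                "mismatch_category": "clean",
                "probe_type": "I",
                "meth_tier": cc.meth_tier((b + r) / 2),
                "pass_all": True,
                **extra,
            }
        )
    return pd.DataFrame(rows)


class TestSummarize:
    def test_identical_vectors_give_perfect_agreement(self):
        s = cc.summarize(_pairs([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]), strata=[])
        row = s.iloc[0]
        assert row["pearson_r"] == pytest.approx(1.0)
        assert row["pct_within_20"] == row["pct_within_10"] == row["pct_within_5"] == 100

    def test_hand_computed_pearson_and_error_bins(self):
        # r = 0.28 / sqrt(0.2 * 0.44); |diffs| = .1, .1, .1, .3
        s = cc.summarize(_pairs([0, 0.2, 0.4, 0.6], [0.1, 0.1, 0.5, 0.9]), strata=[])
        row = s.iloc[0]
        assert row["pearson_r"] == pytest.approx(0.28 / math.sqrt(0.088), abs=1e-9)
        assert row["pct_within_20"] == pytest.approx(75.0)
        assert row["pct_within_10"] == pytest.approx(75.0)
        assert row["pct_within_5"] == pytest.approx(0.0)

    def test_zero_variance_marks_correlation_undefined(self):
        s = cc.summarize(_pairs([0.5, 0.5], [0.1, 0.9]), strata=[])
        assert math.isnan(s.iloc[0]["pearson_r"])

    def test_noise_degrades_concordance_monotonically(self):
        rng = np.random.default_rng(23)
        truth = rng.random(500)
        rows = []
        for sd, label in ((0.02, "low"), (0.2, "high")):
            b = np.clip(truth + rng.normal(0, sd, 500), 0, 1)
            p = _pairs(b, truth, mismatch_category=label)
            rows.append(p)
        pairs = pd.concat(rows, ignore_index=True)
        s = cc.summarize(pairs, strata=["mismatch_category"]).set_index("level")
        assert s.loc["low", "pearson_r"] > s.loc["high", "pearson_r"]
        assert s.loc["low", "pct_within_10"] > s.loc["high", "pct_within_10"]

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
            ),
            min_size=1,
            max_size=40,
        )
    )
    def test_error_bins_are_nested(self, pts):
        pairs = _pairs([b for b, _ in pts], [r for _, r in pts])
        row = cc.summarize(pairs, strata=[]).iloc[0]
        assert 0 <= row["pct_within_5"] <= row["pct_within_10"] <= row["pct_within_20"] <= 100

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
            ),
            min_size=3,
            max_size=30,
        )
    )
    def test_pearson_matches_two_pass_formula(self, pts):
        x = np.array([a for a, _ in pts])
        y = np.array([b for _, b in pts])
        if np.std(x) == 0 or np.std(y) == 0:
            return
        row = cc.summarize(_pairs(x, y), strata=[]).iloc[0]
        mx, my = x.mean(), y.mean()
        r = float(np.sum((x - mx) * (y - my)) / math.sqrt(
            np.sum((x - mx) ** 2) * np.sum((y - my) ** 2)
        ))
        assert row["pearson_r"] == pytest.approx(r, abs=1e-12)


class TestMethTier:
    @pytest.mark.parametrize(
        "m,tier",
        [(0.0, "low"), (0.29, "low"), (0.3, "mid"), (0.5, "mid"), (0.7, "mid"),
         (0.71, "high"), (1.0, "high")],
    )
    def test_boundaries(self, m, tier):
        assert cc.meth_tier(m) == tier


class TestBlandAltman:
    def test_single_pair_definition(self):
        table, stats = cc.bland_altman(_pairs([0.2], [0.4]))
        assert table.iloc[0]["mean_meth"] == pytest.approx(0.3)
        assert table.iloc[0]["diff"] == pytest.approx(0.2)  # sequencing minus array

    def test_identical_vectors_zero_limits(self):
        _, stats = cc.bland_altman(_pairs([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]))
        assert stats["mean_diff"] == 0 and stats["loa_lower"] == 0 == stats["loa_upper"]

    def test_mean_diff_identity(self):
        rng = np.random.default_rng(3)
        b, r = rng.random(100), rng.random(100)
        _, stats = cc.bland_altman(_pairs(b, r))
        assert stats["mean_diff"] == pytest.approx(float(np.mean(r) - np.mean(b)), abs=1e-12)

    def test_heteroscedastic_mid_range_spread(self):
        rng = np.random.default_rng(9)
        truth = np.concatenate([rng.uniform(0, 0.05, 300), rng.uniform(0.45, 0.55, 300)])
        sd = np.where((truth > 0.3) & (truth < 0.7), 0.15, 0.02)
        betas = np.clip(truth + rng.normal(0, 1, 600) * sd, 0, 1)
        table, _ = cc.bland_altman(_pairs(betas, truth))
        mid = table[(table["mean_meth"] > 0.3) & (table["mean_meth"] < 0.7)]["diff"].abs()
        ext = table[(table["mean_meth"] <= 0.3) | (table["mean_meth"] >= 0.7)]["diff"].abs()
        assert mid.mean() > ext.mean()


class TestDeltaConcordance:
    def _two_sample_pairs(self, b1, r1, b2, r2):
        p1 = _pairs(b1, r1, sample="S1")
        p2 = _pairs(b2, r2, sample="S2")
        return pd.concat([p1, p2], ignore_index=True)

    def test_identical_offsets_fully_concordant(self):
        pairs = self._two_sample_pairs([0.2, 0.4], [0.3, 0.5], [0.4, 0.6], [0.5, 0.7])
        d = cc.delta_concordance(pairs)
        assert d["pct_within_20"] == d["pct_within_10"] == d["pct_within_5"] == 100

    def test_hand_computed_deviation_lands_in_20_bin_only(self):
        # one probe, two samples: delta_array = -0.4, delta_seq = -0.2
        pairs = self._two_sample_pairs([0.2], [0.3], [0.6], [0.5])
        d = cc.delta_concordance(pairs)
        assert d["n_observations"] == 1
        assert d["pct_within_20"] == 100 and d["pct_within_10"] == 0

    def test_bins_nested_on_random_input(self):
        rng = np.random.default_rng(5)
        pairs = pd.concat(
            [
                _pairs(rng.random(50), rng.random(50), sample=f"S{k}")
                for k in range(4)
            ],
            ignore_index=True,
        )
        d = cc.delta_concordance(pairs)
        assert d["pct_within_5"] <= d["pct_within_10"] <= d["pct_within_20"]


class TestJoin:
    def _annot(self, pid, pos, contig="c1", **kw):
        base = dict(
            probe_id=pid, contig=contig, start=pos - 49, end=pos + 1, strand="+",
            raw_score=100, bitscore=91.0, evalue=1e-20, percent_identity=100.0,
            n_mismatch=0, n_gaps=0, cpg_present=True, cpg_mismatch=False,
            near_cpg_mismatch=False, mismatch_category="clean", n_hits=1,
            unique=True, gene_match_class="exact", probe_type="I",
            target_cpg_pos=pos,
        )
        base.update(kw)
        return fl.ProbeAnnotationRecord(**base)

    def _betas(self, pids, vals):
        return BetaMatrix(beta=pd.DataFrame({"S1": vals}, index=pd.Index(pids)))

    def test_exact_coordinate_pairs(self):
        annot = [self._annot("cg1", 148)]  # 0-based C -> 1-based 149
        meth = {"S1": [MethylationCall("c1", 149, 7, 10)]}
        pairs = cc.join_shared(annot, self._betas(["cg1"], [0.5]), meth)
        assert len(pairs) == 1
        assert pairs.iloc[0]["seq_ratio"] == pytest.approx(0.7)
        assert pairs.iloc[0]["diff"] == pytest.approx(0.2)

    def test_g_strand_call_folds_onto_c(self):
        annot = [self._annot("cg1", 148)]
        meth = {"S1": [MethylationCall("c1", 150, 5, 10)]}  # call on the G
        pairs = cc.join_shared(annot, self._betas(["cg1"], [0.5]), meth)
        assert len(pairs) == 1 and pairs.iloc[0]["seq_ratio"] == pytest.approx(0.5)

    def test_missing_beta_dropped(self):
        annot = [self._annot("cg1", 148)]
        meth = {"S1": [MethylationCall("c1", 149, 5, 10)]}
        pairs = cc.join_shared(annot, self._betas(["cg1"], [np.nan]), meth)
        assert pairs.empty

    def test_cohort_pair_count_matches_generator_truth(
        self, cohort, annotated, covered_meth
    ):
        pairs = cc.join_shared(annotated, cohort.betas, covered_meth)
        truth = cohort.truth.set_index("probe_id")
        conserved = truth[
            truth["cls"].isin(["clean", "mm_far", "mm_near", "duplicated"])
            | ((truth["cls"] == "mm_cpg") & (truth["probe_type"] == "I"))
        ].index
        expected = 0
        for s, calls in covered_meth.items():
            covered = {(c.chrom, c.pos) for c in calls}
            for pid in conserved:
                row = truth.loc[pid]
                if (row["contig"], row["cpg_pos0"] + 1) in covered and np.isfinite(
                    cohort.betas.beta.at[pid, s]
                ):
                    expected += 1
        assert len(pairs) == expected


class TestDetectionCorrelation:
    def _bm(self, pids, det):
        idx = pd.Index(pids)
        return BetaMatrix(
            beta=pd.DataFrame({"S1": [0.5] * len(pids)}, index=idx),
            detection_p=pd.DataFrame({"S1": det}, index=idx),
        )

    def _annots(self, bitscores):
        return [
            fl.ProbeAnnotationRecord(
                probe_id=f"cg{i}", contig="c1", start=0, end=50, strand="+",
                raw_score=100, bitscore=b, evalue=2.0 ** -b, percent_identity=100.0,
                n_mismatch=0, n_gaps=0, cpg_present=True, cpg_mismatch=False,
                near_cpg_mismatch=False, mismatch_category="clean", n_hits=1,
                unique=True, gene_match_class="exact", probe_type="I",
                target_cpg_pos=49,
            )
            for i, b in enumerate(bitscores)
        ]

    def test_constant_detection_p_is_undefined(self):
        annot = self._annots([80, 85, 90])
        det = cc.detection_alignment_correlation(annot, self._bm([a.probe_id for a in annot], [0.01] * 3))
        assert math.isnan(det.iloc[0]["rho_bitscore"])

    def test_perfectly_antiranked_gives_minus_one(self):
        bits = list(range(70, 80))
        annot = self._annots(bits)
        det = cc.detection_alignment_correlation(
            annot, self._bm([a.probe_id for a in annot], sorted(np.linspace(0, 0.1, 10), reverse=True))
        )
        assert det.iloc[0]["rho_bitscore"] == pytest.approx(-1.0)
        assert det.iloc[0]["rho_evalue"] == pytest.approx(1.0)
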