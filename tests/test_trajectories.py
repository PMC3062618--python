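"""Standardization, CI-based peak calling, correlations and clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stageloop import (
    correlation_summary,
    critical_r,
    dedup_by_annotation,
    detect_peaks,
    hcluster,
    peak_profiles,
    peak_summary,
    standardize,
)


class TestStandardize:
    def test_hand_example(self):
        z, const = standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])
        assert not const

    def test_constant_flagged(self):
        z, const = standardize([4.0] * 10)
        assert const
        np.testing.assert_allclose(z, 0.0)

    def test_mean_zero_sd_one(self, rng):
        z, _ = standardize(rng.normal(5, 3, size=40))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_too_short(self):
        with pytest.raises(ValueError):
            standardize([1.0])


class TestDetectPeaks:
    def test_monotone_increasing_peaks_at_last_stage(self):
        x = np.arange(40, dtype=float)
        assert detect_peaks(x, np.full(40, 0.1)) == [40]

    def test_two_equal_maxima_too_close_give_one_peak(self):
        """Equal maxima at stages 16 and 18 are within 3 stages: one peak,
        and the tie goes to the earlier stage."""
        x = np.zeros(40)
        x[15] = x[17] = 5.0
        assert detect_peaks(x, np.full(40, 0.1)) == [16]

    def test_secondary_peak_inside_ci_and_separated(self):
        """A second local maximum within the CI of the maximum and >= 3
        stages away is called as a second peak."""
        x = np.zeros(40)
        x[4] = 4.9
        x[15] = 5.0
        assert detect_peaks(x, np.full(40, 0.5)) == [5, 16]

    def test_secondary_peak_below_ci_rejected(self):
        x = np.zeros(40)
        x[4] = 3.0
        x[15] = 5.0
        # CI lower bound is 5 - 1.645*0.5 = 4.18 > 3
        assert detect_peaks(x, np.full(40, 0.5)) == [16]

    def test_min_sep_boundary(self):
        """|delta stage| = min_sep is allowed; min_sep - 1 is not."""
        x = np.zeros(40)
        x[10] = 5.0
        x[13] = 4.99
        assert detect_peaks(x, np.full(40, 0.5), min_sep=3) == [11, 14]
        assert detect_peaks(x, np.full(40, 0.5), min_sep=4) == [11]


def _planted_profiles(n_per_class=30, se=0.05, seed=0):
    """Genes with 1, 2 or 3 well-separated planted peaks plus tiny noise.

    Later peaks are made marginally shorter (within the CI of the maximum)
    so the primary peak is always the first planted one.
    """
    rng = np.random.default_rng(seed)
    peak_sets = {1: [(10,)], 2: [(8, 25)], 3: [(5, 20, 35)]}
    rows, truth = [], []
    for n_peaks, sets in peak_sets.items():
        for peaks in sets:
            for g in range(n_per_class):
                x = np.zeros(40)
                for j, p in enumerate(peaks):
                    stages = np.arange(40)
                    amp = 3.0 * (1.0 - 0.01 * j)
                    x += amp * np.exp(-0.5 * ((stages - (p - 1)) / 1.2) ** 2)
                x += rng.normal(0, se / 30, size=40)
                rows.append(x)
                truth.append((n_peaks, peaks))
    genes = pd.Index([f"g{i}" for i in range(len(rows))], name="gene_id")
    ls = pd.DataFrame(rows, index=genes)
    ses = pd.DataFrame(np.full_like(ls, se), index=genes)
    return ls, ses, truth


class TestPeakProfiles:
    def test_planted_peak_counts_recovered(self):
        ls, se, truth = _planted_profiles()
        profiles = peak_profiles(ls, se)
        for prof, (n_peaks, peaks) in zip(profiles, truth):
            assert prof.n_peaks == n_peaks
            assert tuple(prof.peaks) == peaks

    def test_single_peak_recovery_rate(self):
        """Strong single peaks (amplitude >> SE) recovered >= 99% exactly."""
        rng = np.random.default_rng(1)
        n = 500
        se_val = 0.2
        stages = np.arange(40)
        rows, truth = [], []
        for _ in range(n):
            p = int(rng.integers(4, 37))
            x = 10 * se_val * np.exp(-0.5 * ((stages - p) / 2.0) ** 2)
            x += rng.normal(0, se_val / 10, size=40)
            rows.append(x)
            truth.append(p + 1)
        ls = pd.DataFrame(rows, index=[f"g{i}" for i in range(n)])
        se = pd.DataFrame(np.full_like(ls, se_val), index=ls.index)
        profiles = peak_profiles(ls, se)
        hits = sum(p.primary == t for p, t in zip(profiles, truth))
        assert hits / n >= 0.99

    def test_peak_rule_invariants(self, rng):
        """On arbitrary noisy profiles every call obeys the rule: peaks are
        >= the CI lower bound of the maximum and pairwise >= 3 apart."""
        z90 = stats.norm.ppf(0.95)
        for _ in range(200):
            x = rng.normal(0, 1, size=40)
            se = rng.uniform(0.05, 0.5, size=40)
            peaks = detect_peaks(x, se)
            k_star = int(np.argmax(x))
            lower = x[k_star] - z90 * se[k_star]
            assert (k_star + 1) in peaks
            for p in peaks:
                assert x[p - 1] >= lower - 1e-12
            for i, p in enumerate(peaks):
                for q in peaks[i + 1 :]:
                    assert abs(p - q) >= 3


class TestPeakSummary:
    def test_ordering_and_histograms(self):
        ls, se, truth = _planted_profiles(n_per_class=10)
        summary = peak_summary(peak_profiles(ls, se))
        table = summary["table"]
        assert list(table["primary_peak"]) == sorted(table["primary_peak"])
        assert summary["n_peak_counts"].to_dict() == {1: 10, 2: 10, 3: 10}
        # primary peak of the multi-peak classes is the tallest (equal
        # heights resolve to the earlier stage)
        assert set(summary["stage_counts"].index) == {10, 8, 5}

    def test_permutation_invariance(self):
        ls, se, _ = _planted_profiles(n_per_class=8, seed=3)
        perm = np.random.default_rng(4).permutation(len(ls))
        s1 = peak_summary(peak_profiles(ls, se))
        s2 = peak_summary(peak_profiles(ls.iloc[perm], se.iloc[perm]))
        pd.testing.assert_frame_equal(s1["table"], s2["table"])


class TestCriticalR:
    def test_study_value(self):
        """With 40 stages at alpha = 0.01 the threshold rounds to 0.4."""
        assert critical_r(40, 0.01) == pytest.approx(0.4027, abs=5e-4)
        assert round(critical_r(40, 0.01), 1) == 0.4

    def test_monotone_in_n_and_alpha(self):
        assert critical_r(100, 0.01) < critical_r(40, 0.01) < critical_r(10, 0.01)
        assert critical_r(40, 0.05) < critical_r(40, 0.01)

    def test_permutation_oracle_small_n(self, rng):
        """Empirical null |r| quantile at n = 10 matches the formula."""
        n, alpha, reps = 10, 0.05, 20000
        x = rng.normal(size=n)
        rs = np.empty(reps)
        for i in range(reps):
            rs[i] = np.corrcoef(x, rng.permutation(x))[0, 1]
        emp = np.quantile(np.abs(rs), 1 - alpha)
        assert emp == pytest.approx(critical_r(n, alpha), abs=0.03)


class TestCorrelationSummary:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, index=pd.Index([f"g{i}" for i in range(len(rows))], name="gene_id")
        )

    def test_identical_and_flipped(self):
        base = np.sin(np.linspace(0, 3, 40))
        ls = self._frame([base, base + 0.0, -base])
        cs = correlation_summary(ls)
        R = cs.r_matrix.to_numpy()
        assert R[0, 1] == pytest.approx(1.0)
        assert R[0, 2] == pytest.approx(-1.0)
        assert cs.frac_significant == pytest.approx(1.0)

    def test_null_fraction_near_alpha(self, rng):
        ls = self._frame(rng.normal(size=(120, 40)))
        cs = correlation_summary(ls, alpha=0.01)
        n_pairs = 120 * 119 // 2
        se = np.sqrt(0.01 * 0.99 / n_pairs)
        # pairs sharing a gene are dependent; allow a wide band
        assert abs(cs.frac_significant - 0.01) < 6 * se

    def test_coregulated_block_dominates(self, rng):
        base = np.cos(np.linspace(0, 4, 40))
        block = [base + rng.normal(0, 0.1, 40) for _ in range(30)]
        noise = [rng.normal(0, 1, 40) for _ in range(30)]
        cs = correlation_summary(self._frame(block + noise))
        assert cs.frac_pos > cs.frac_neg
        cut = cs.cut_fractions.set_index("cut")
        assert cut.loc[0.8, "frac_pos"] >= 30 * 29 / 2 / (60 * 59 / 2)

    def test_constant_gene_excluded_with_warning(self, caplog, rng):
        rows = list(rng.normal(size=(3, 40))) + [np.zeros(40)]
        with caplog.at_level("WARNING"):
            cs = correlation_summary(self._frame(rows))
        assert cs.r_matrix.shape == (3, 3)
        assert "constant-profile" in caplog.text


class TestDedup:
    def test_first_unique_name_kept(self):
        genes = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "name": ["rpl3", "rpl3", "rps7"]}
        )
        out = dedup_by_annotation(genes)
        assert list(out["gene_id"]) == ["a", "c"]

    def test_all_unique_identity(self):
        genes = pd.DataFrame({"gene_id": list("abc"), "name": ["x", "y", "z"]})
        pd.testing.assert_frame_equal(dedup_by_annotation(genes), genes)

    def test_case_policy(self):
        genes = pd.DataFrame({"gene_id": ["a", "b"], "name": ["Rpl3", "rpl3"]})
        assert len(dedup_by_annotation(genes)) == 2
        assert len(dedup_by_annotation(genes, case_sensitive=False)) == 1


class TestHCluster:
    def test_anticorrelated_groups_split(self, rng):
        up = np.linspace(-1, 1, 40)
        rows = [up + rng.normal(0, 0.05, 40) for _ in range(6)]
        rows += [-up + rng.normal(0, 0.05, 40) for _ in range(6)]
        ls = pd.DataFrame(rows, index=[f"g{i}" for i in range(12)])
        dend = hcluster(ls, axis="genes")
        cut = dend.cut(2)
        assert len(set(cut.iloc[:6])) == 1
        assert len(set(cut.iloc[6:])) == 1
        assert cut.iloc[0] != cut.iloc[-1]

    def test_stage_blocks_recovered(self, rng):
        """Genes active in early/mid/late blocks cluster the stages into
        three contiguous temporal groups."""
        n_genes = 60
        X = rng.normal(0, 0.1, size=(n_genes, 40))
        bounds = [(0, 13), (13, 26), (26, 40)]
        for g in range(n_genes):
            lo, hi = bounds[g % 3]
            X[g, lo:hi] += 2.0
        ls = pd.DataFrame(
            X,
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"stage_{s}" for s in range(1, 41)],
        )
        dend = hcluster(ls, axis="stages")
        cut = dend.cut(3)
        assert len(set(cut.iloc[:13])) == 1
        assert len(set(cut.iloc[13:26])) == 1
        assert len(set(cut.iloc[26:])) == 1
        assert len(set(cut)) == 3

    def test_permutation_invariant_cophenetic(self, rng):
        X = rng.normal(size=(10, 15))
        ls = pd.DataFrame(X, index=[f"g{i}" for i in range(10)])
        perm = rng.permutation(10)
        c1 = hcluster(ls).cophenetic()
        c2 = hcluster(ls.iloc[perm]).cophenetic()
        c2 = c2.loc[c1.index, c1.columns]
        np.testing.assert_allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-10)

    def test_newick_well_formed(self, rng):
        ls = pd.DataFrame(rng.normal(size=(5, 12)), index=list("abcde"))
        nwk = hcluster(ls).to_newick()
        assert nwk.endswith(";")
        assert nwk.count("(") == nwk.count(")") == 4
        for label in "abcde":
            assert label in nwk

    def test_bad_axis(self, rng):
        ls = pd.DataFrame(rng.normal(size=(4, 6)))
        with pytest.raises(ValueError):
            hcluster(ls, axis="rows")
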