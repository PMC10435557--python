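"""Index tests against independent brute-force oracles."""

import statistics

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from careless_screen import (IndexConfig, ScaleDesign, assemble_cohort,
                             compute_index_table, even_odd, find_item_pairs,
                             irv, longstring_stats, mahalanobis_distances,
                             psych_score)
from careless_screen.indices import ItemPairSet


# --- naive oracles (kept deliberately dumb and loop-based) -----------------

def naive_runs(row):
    runs, count = [], 1
    for prev, cur in zip(row, row[1:]):
        if cur == prev:
            count += 1
        else:
            runs.append(count)
            count = 1
    runs.append(count)
    return runs


def naive_pairs(frame, threshold, mode):
    cols = [c for c in frame.columns if frame[c].nunique() > 1]
    out = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = pearsonr(frame[a], frame[b]).statistic
            if (mode == "synonym" and r >= threshold) or \
               (mode == "antonym" and r <= threshold):
                out.append((a, b))
    return out


def naive_mahad(X):
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    inv = np.linalg.pinv(np.cov(X, rowvar=False, ddof=1))
    return np.array([np.sqrt((r - mu) @ inv @ (r - mu)) for r in X])


def naive_even_odd(row, design):
    odd, even = [], []
    for sl in design.section_slices():
        items = [float(v) for v in row[sl]]  # statistics.mean truncates np ints
        odd.append(statistics.mean(items[0::2]))
        even.append(statistics.mean(items[1::2]))
    if len(set(odd)) == 1 or len(set(even)) == 1:
        return float("nan")
    return pearsonr(odd, even).statistic


class TestLongstring:
    def test_run_decomposition_example(self):
        assert longstring_stats([1, 1, 1, 2, 2, 1]) == (3, 2.0)

    def test_constant_row(self):
        assert longstring_stats([4] * 60) == (60, 60.0)

    def test_matches_naive_scanner_on_random_rows(self, rng):
        for _ in range(1000):
            row = rng.integers(1, 6, size=rng.integers(1, 40))
            runs = naive_runs(list(row))
            assert longstring_stats(row) == (max(runs), statistics.mean(runs))

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            longstring_stats([])


class TestIrv:
    def test_constant_row_is_zero(self):
        assert irv([3] * 10) == 0.0

    def test_two_point_closed_form(self):
        assert irv([1, 5]) == pytest.approx(statistics.stdev([1, 5]))
        assert irv([1, 5]) == pytest.approx(2 * np.sqrt(2))

    def test_total_equals_pooled_recomputation(self, rng):
        row = rng.integers(1, 6, size=60)
        sections = [row[k * 10:(k + 1) * 10] for k in range(6)]
        pooled = np.concatenate(sections)
        assert irv(row) == pytest.approx(irv(pooled), abs=1e-12)

    def test_subset_too_small_rejected(self):
        with pytest.raises(ValueError):
            irv([1, 2, 3], item_subset=slice(0, 1))


class TestFindItemPairs:
    def test_duplicate_columns_always_selected(self, rng):
        base = rng.integers(1, 6, size=50)
        frame = pd.DataFrame({"a": base, "b": base,
                              "c": rng.integers(1, 6, size=50)})
        pairs = find_item_pairs(frame, 0.9, "synonym")
        assert ("a", "b") in pairs.pairs

    def test_invalid_threshold_raises(self, rng):
        frame = pd.DataFrame(rng.integers(1, 6, size=(10, 4)))
        with pytest.raises(ValueError):
            find_item_pairs(frame, 1.01, "synonym")
        with pytest.raises(ValueError):
            find_item_pairs(frame, 0.5, "antonym")

    @pytest.mark.parametrize("mode,threshold", [("synonym", 0.6),
                                                ("antonym", -0.6)])
    def test_matches_exhaustive_scan(self, rng, mode, threshold):
        frame = pd.DataFrame(rng.integers(1, 6, size=(200, 20)),
                             columns=[f"i{k}" for k in range(20)])
        frame["i1"] = frame["i0"] + rng.integers(0, 2, size=200)  # near-dup
        frame["i2"] = 6 - frame["i0"]                             # antonym
        got = find_item_pairs(frame, threshold, mode)
        assert sorted(got.pairs) == sorted(naive_pairs(frame, threshold, mode))

    def test_constant_columns_excluded(self, rng, caplog):
        frame = pd.DataFrame({"a": rng.integers(1, 6, size=30),
                              "const": np.full(30, 3)})
        frame["b"] = frame["a"]
        with caplog.at_level("WARNING"):
            pairs = find_item_pairs(frame, 0.9, "synonym")
        assert all("const" not in p for p in pairs.pairs)
        assert any("constant" in r.message for r in caplog.records)

    def test_self_pairs_rejected(self):
        with pytest.raises(ValueError):
            ItemPairSet(mode="synonym", pairs=(("a", "a"),), threshold=0.6)


class TestPsychScore:
    def _pairs(self, n):
        return ItemPairSet(mode="synonym",
                           pairs=tuple((f"x{k}", f"y{k}") for k in range(n)),
                           threshold=0.6)

    def test_identical_pair_answers_give_one(self):
        row = pd.Series({"x0": 1, "y0": 1, "x1": 4, "y1": 4, "x2": 2, "y2": 2})
        assert psych_score(row, self._pairs(3)) == pytest.approx(1.0)

    def test_mirrored_answers_give_minus_one(self):
        row = pd.Series({"x0": 1, "y0": 5, "x1": 4, "y1": 2, "x2": 2, "y2": 4})
        assert psych_score(row, self._pairs(3)) == pytest.approx(-1.0)

    def test_matches_direct_correlation(self, rng):
        pairs = self._pairs(8)
        names = [p for ab in pairs.pairs for p in ab]
        for _ in range(50):
            row = pd.Series(dict(zip(names, rng.integers(1, 6, size=16))))
            x = [row[a] for a, _ in pairs.pairs]
            y = [row[b] for _, b in pairs.pairs]
            expected = (pearsonr(x, y).statistic
                        if len(set(x)) > 1 and len(set(y)) > 1 else np.nan)
            got = psych_score(row, pairs)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_too_few_pairs_flagged_undefined(self):
        row = pd.Series({"x0": 1, "y0": 2})
        assert np.isnan(psych_score(row, self._pairs(1)))


class TestMahalanobis:
    def test_row_at_mean_has_zero_distance(self, rng):
        X = rng.normal(size=(20, 3))
        # a row equal to the mean of the others also equals the full mean
        X[0] = X[1:].mean(axis=0)
        d = mahalanobis_distances(X)
        assert d[0] == pytest.approx(0.0, abs=1e-8)

    def test_identity_covariance_reduces_to_z_scores(self, rng):
        X = rng.normal(size=(5000, 2))
        d = mahalanobis_distances(X)
        X_std = (X - X.mean(0)) / X.std(0, ddof=1)
        approx = np.sqrt((X_std ** 2).sum(axis=1))
        # covariance is only approximately identity at finite n
        assert np.abs(d - approx).max() < 0.1

    def test_translation_invariance(self, rng):
        X = rng.integers(1, 6, size=(40, 6)).astype(float)
        shifted = X.copy()
        shifted[:, 2] += 7.0
        np.testing.assert_allclose(mahalanobis_distances(X),
                                   mahalanobis_distances(shifted), atol=1e-8)

    def test_matches_naive_quadratic_form(self, rng):
        X = rng.integers(1, 6, size=(50, 8))
        np.testing.assert_allclose(mahalanobis_distances(X), naive_mahad(X),
                                   atol=1e-8)

    def test_singular_covariance_uses_pseudoinverse(self, rng, caplog):
        X = rng.integers(1, 6, size=(5, 10))  # p > n
        with caplog.at_level("WARNING"):
            d = mahalanobis_distances(X)
        assert np.isfinite(d).all()
        assert any("pseudo-inverse" in r.message for r in caplog.records)

    def test_single_respondent_rejected(self):
        with pytest.raises(ValueError):
            mahalanobis_distances(np.ones((1, 4)))


class TestEvenOdd:
    def test_identical_half_means_give_one(self):
        design = ScaleDesign(n_scales=3, items_per_scale=2,
                             item_ids=tuple("abcdef"), reverse_coded=frozenset())
        # halves equal within scale, varying across scales
        frame = pd.DataFrame([[1, 1, 3, 3, 5, 5]], columns=list("abcdef"))
        assert even_odd(frame, design)[0] == pytest.approx(1.0)

    def test_two_scales_degenerate_and_flagged(self, rng, caplog):
        design = ScaleDesign(n_scales=2, items_per_scale=4,
                             item_ids=tuple("abcdefgh"),
                             reverse_coded=frozenset())
        frame = pd.DataFrame(rng.integers(1, 6, size=(20, 8)),
                             columns=list("abcdefgh"))
        with caplog.at_level("WARNING"):
            scores = even_odd(frame, design)
        assert any("degenerate" in r.message for r in caplog.records)
        finite = scores[np.isfinite(scores)]
        np.testing.assert_allclose(np.abs(finite), 1.0)

    def test_matches_first_principles_recomputation(self, default_design, rng):
        frame = pd.DataFrame(rng.integers(1, 6, size=(30, 60)),
                             columns=list(default_design.item_ids))
        got = even_odd(frame, default_design)
        for i in range(30):
            expected = naive_even_odd(frame.to_numpy()[i], default_design)
            if np.isnan(expected):
                assert np.isnan(got[i])
            else:
                assert got[i] == pytest.approx(expected, abs=1e-12)

    def test_spearman_brown_step_up(self, default_design, rng):
        frame = pd.DataFrame(rng.integers(1, 6, size=(10, 60)),
                             columns=list(default_design.item_ids))
        plain = even_odd(frame, default_design, spearman_brown=False)
        stepped = even_odd(frame, default_design, spearman_brown=True)
        mask = np.isfinite(plain)
        np.testing.assert_allclose(stepped[mask],
                                   2 * plain[mask] / (1 + plain[mask]))


class TestIndexTable:
    def test_default_table_has_thirteen_columns(self, default_index_table):
        assert default_index_table.shape[1] == 13
        assert list(default_index_table.columns[:7]) == [
            "res_psycsyn", "res_psychant", "str", "avgstr", "res_mahad",
            "res_evenodd", "irvTotal"]

    def test_derived_columns_appended_on_request(self, default_cohort):
        table = compute_index_table(default_cohort,
                                    IndexConfig(include_derived=True))
        assert table.shape[1] == 15
        assert {"irvDiff", "longDiff"} <= set(table.columns)

    def test_constant_responder(self, default_cohort):
        i = np.flatnonzero(
            default_cohort.careless_style.to_numpy() == "pattern")[0]
        table = compute_index_table(default_cohort)
        assert table["str"].iloc[i] == 60
        assert table["irvTotal"].iloc[i] == 0.0
        assert np.isnan(table["res_psycsyn"].iloc[i])

    def test_columns_match_rowwise_operations(self, default_cohort,
                                              default_index_table):
        X = default_cohort.responses.to_numpy()
        for i in range(0, default_cohort.n, 97):
            mx, avg = longstring_stats(X[i])
            assert default_index_table["str"].iloc[i] == mx
            assert default_index_table["avgstr"].iloc[i] == pytest.approx(avg)
            assert default_index_table["irvTotal"].iloc[i] == \
                pytest.approx(irv(X[i]))
            for k in range(1, 7):
                sl = slice((k - 1) * 10, k * 10)
                assert default_index_table[f"irv{k}"].iloc[i] == \
                    pytest.approx(irv(X[i], sl))
        np.testing.assert_allclose(default_index_table["res_mahad"],
                                   mahalanobis_distances(X), atol=1e-8)

    def test_respondent_permutation_permutes_rows(self, rng):
        # keep n > p so the covariance is nonsingular and the Mahalanobis
        # quadratic form is numerically stable under row reordering
        cohort = assemble_cohort(n_regular=140, n_careless=60, seed=6)
        table = compute_index_table(cohort)
        perm = rng.permutation(cohort.n)
        import careless_screen as cs
        shuffled = cs.SurveyCohort(
            responses=cohort.responses.iloc[perm].reset_index(drop=True),
            times=cohort.times.iloc[perm].reset_index(drop=True),
            demographics=cohort.demographics.iloc[perm].reset_index(drop=True),
            labels=cohort.labels[perm],
            careless_style=cohort.careless_style.iloc[perm]
                .reset_index(drop=True),
            design=cohort.design)
        table2 = compute_index_table(shuffled)
        np.testing.assert_allclose(
            table.iloc[perm].reset_index(drop=True).to_numpy(dtype=float),
            table2.to_numpy(dtype=float), atol=1e-6, equal_nan=True)


class TestDetectionOrderings:
    def test_style_signatures_on_synthetic_cohort(self):
        cohort = assemble_cohort(n_regular=600, n_careless=400, seed=2)
        table = compute_index_table(cohort)
        style = cohort.careless_style.to_numpy()
        regular = cohort.labels == 0
        assert table["str"][style == "pattern"].mean() > \
            table["str"][regular].mean()
        assert table["res_mahad"][style == "random"].mean() > \
            table["res_mahad"][regular].mean()
        assert table["irvTotal"][style == "random"].mean() > \
            table["irvTotal"][regular].mean()
        assert table["res_psycsyn"][regular].mean() > \
            table["res_psycsyn"][style == "random"].mean()
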