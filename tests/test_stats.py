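import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats

from molcomplexity.errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidArgumentError,
)
from molcomplexity.stats import (
    ResultsTable,
    correlation_matrix,
    pearson_one_tailed,
    run_pipeline,
    separation,
)
from oracles import auc_bruteforce, pearson_closed_form


class TestPearson:
    def test_perfect_positive(self):
        r, p = pearson_one_tailed([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == 1.0
        assert 0 < p <= 1e-12

    def test_perfect_negative(self):
        r, p = pearson_one_tailed([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r == -1.0
        assert p > 0.99

    def test_hand_computed_case(self):
        x, y = [1, 2, 3], [1, 2, 4]
        r, p = pearson_one_tailed(x, y)
        assert math.isclose(r, pearson_closed_form(x, y), abs_tol=1e-12)
        ref = scipy_stats.pearsonr(x, y, alternative="greater")
        assert math.isclose(r, ref.statistic, abs_tol=1e-12)
        assert math.isclose(p, ref.pvalue, abs_tol=1e-12)

    def test_constant_vector_raises(self):
        with pytest.raises(DegenerateInputError):
            pearson_one_tailed([1, 1, 1], [1, 2, 3])

    def test_short_input_raises(self):
        with pytest.raises(InsufficientDataError):
            pearson_one_tailed([1, 2], [1, 2])

    def test_matches_oracles_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r, p = pearson_one_tailed(x, y)
            assert math.isclose(r, pearson_closed_form(list(x), list(y)), abs_tol=1e-12)
            ref = scipy_stats.pearsonr(x, y, alternative="greater")
            assert math.isclose(r, ref.statistic, abs_tol=1e-12)
            assert math.isclose(p, ref.pvalue, abs_tol=1e-10)


class TestSeparation:
    def test_perfect(self):
        e = separation([1, 2, 9, 10], ["a", "a", "b", "b"])
        assert e.auc == 1.0
        assert e.cliffs_delta == 1.0

    def test_identical_multisets(self):
        e = separation([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert e.auc == 0.5
        assert e.cliffs_delta == 0.0

    def test_interleaved_matches_enumeration(self):
        values = [1, 3, 5, 2, 4, 6]
        labels = ["a", "a", "a", "b", "b", "b"]
        e = separation(values, labels)
        assert e.auc == auc_bruteforce([1, 3, 5], [2, 4, 6])

    def test_relabelling_flips(self):
        rng = np.random.default_rng(1)
        values = rng.integers(0, 10, size=30).astype(float)
        labels = np.array(["a"] * 15 + ["b"] * 15)
        e1 = separation(values, labels)
        flipped = np.where(labels == "a", "z", "a")  # swaps sort order
        e2 = separation(values, flipped)
        assert math.isclose(e1.auc, 1.0 - e2.auc, abs_tol=1e-12)

    def test_matches_bruteforce_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n1, n2 = int(rng.integers(1, 20)), int(rng.integers(1, 20))
            a = rng.integers(0, 6, size=n1).astype(float)
            b = rng.integers(0, 6, size=n2).astype(float)
            e = separation(
                np.concatenate([a, b]), np.array(["a"] * n1 + ["b"] * n2)
            )
            assert math.isclose(e.auc, auc_bruteforce(a, b), abs_tol=1e-12)
            assert math.isclose(e.auc, (e.cliffs_delta + 1) / 2, abs_tol=1e-12)

    def test_one_group_rejected(self):
        with pytest.raises(InvalidArgumentError):
            separation([1, 2, 3], ["a", "a", "a"])


class TestResultsTable:
    def test_duplicate_rejected(self):
        t = ResultsTable()
        t.add("x", "g", "raw-text", "rle", 1.0)
        with pytest.raises(InvalidArgumentError):
            t.add("x", "g", "raw-text", "rle", 2.0)

    def test_non_finite_rejected(self):
        t = ResultsTable()
        with pytest.raises(InvalidArgumentError):
            t.add("x", "g", "raw-text", "rle", float("nan"))


class TestCorrelationMatrix:
    def _table(self, columns: dict) -> ResultsTable:
        t = ResultsTable()
        n = len(next(iter(columns.values())))
        for i in range(n):
            for m, vals in columns.items():
                if vals[i] is not None:
                    t.add(f"obj{i}", "g", "raw-text", m, vals[i])
        return t

    def test_identical_columns(self):
        t = self._table({"m1": [1, 2, 3, 4], "m2": [1, 2, 3, 4]})
        report = correlation_matrix(t, "raw-text")
        r, p, n = report.lookup("m1", "m2")
        assert r == 1.0 and n == 4

    def test_negated_column(self):
        t = self._table({"m1": [1, 2, 3, 4], "m2": [-1, -2, -3, -4]})
        assert correlation_matrix(t, "raw-text").lookup("m1", "m2")[0] == -1.0

    def test_all_pairs_present(self):
        t = self._table({"a": [1, 2, 3, 5], "b": [2, 1, 4, 4], "c": [5, 3, 2, 1]})
        report = correlation_matrix(t, "raw-text")
        assert len(report.pairs) == 3

    def test_pairwise_complete_drops(self):
        t = self._table({"a": [1, 2, 3, 5], "b": [2, 1, 4, None]})
        report = correlation_matrix(t, "raw-text")
        assert report.lookup("a", "b")[2] == 3

    def test_insufficient_objects(self):
        t = self._table({"a": [1, 2], "b": [2, 1]})
        with pytest.raises(InsufficientDataError):
            correlation_matrix(t, "raw-text")


@pytest.fixture(scope="module")
def small_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    result = run_pipeline({"n_per_class": 12, "seed": 7}, out_dir=out)
    return result, out


class TestPipeline:
    def test_outputs_written(self, small_run):
        _, out = small_run
        for name in ("results.csv", "correlations.csv", "separation.csv", "manifest.json"):
            assert (out / name).exists()

    def test_deterministic_rerun(self, small_run, tmp_path):
        _, out = small_run
        again = tmp_path / "again"
        run_pipeline({"n_per_class": 12, "seed": 7}, out_dir=again)
        for name in ("results.csv", "correlations.csv", "separation.csv", "manifest.json"):
            assert (out / name).read_bytes() == (again / name).read_bytes()

    def test_manifest_embeds_seed(self, small_run):
        result, _ = small_run
        assert result.manifest["seed"] == 7
        assert result.manifest["config"]["n_per_class"] == 12

    def test_results_shape(self, small_run):
        result, _ = small_run
        df = result.results.to_frame()
        assert set(df["group"]) == {"modular", "random"}
        assert len(df) == 24 * len(result.manifest["measures"])

    def test_external_ma_column(self, tmp_path):
        from molcomplexity.synthetic import gen_string_corpus

        records = gen_string_corpus(n_per_class=5, seed=3)
        ma = pd.DataFrame(
            {"object_id": [r[0] for r in records], "ma": [float(i + len(r[2])) for i, r in enumerate(records)]}
        )
        ma_path = tmp_path / "ma.csv"
        ma.to_csv(ma_path, index=False)
        result = run_pipeline(
            {"n_per_class": 5, "seed": 3, "external_ma": str(ma_path)}
        )
        measures = {m for pair in result.correlations.pairs for m in pair[:2]}
        assert "MA" in measures

    def test_unknown_ma_ids_reported(self, tmp_path):
        ma_path = tmp_path / "ma.csv"
        pd.DataFrame({"object_id": ["nope1"], "ma": [1.0]}).to_csv(ma_path, index=False)
        with pytest.raises(InvalidArgumentError, match="nope1"):
            run_pipeline({"n_per_class": 4, "seed": 3, "external_ma": str(ma_path)})

    def test_bdm_measure_runs(self, ctm22, tmp_path):
        from molcomplexity.ctm_bdm import save_ctm_table

        table_path = tmp_path / "ctm.csv"
        save_ctm_table(ctm22, table_path)
        result = run_pipeline(
            {
                "n_per_class": 5,
                "seed": 11,
                "measures": ["lz78", "bdm"],
                "ctm_table": str(table_path),
                "bdm_block": 2,
            }
        )
        df = result.results.to_frame()
        assert (df[df["measure"] == "bdm"]["value"] > 0).all()
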