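import json
import math

import numpy as np
import pytest
from click.testing import CliRunner

from plascompare import (
    batch_summary,
    compare_report,
    generate_binset,
    pearson,
    perturb,
    write_bins,
)
from plascompare.cli import main
from plascompare.report import read_manifest, write_batch_tsv, write_json


def fixture_pair(tmp_path, seed, **edits):
    truth = generate_binset(seed, n_bins=3)
    pred, _ = perturb(truth, seed + 1, **edits)
    left = tmp_path / f"pred{seed}.tsv"
    right = tmp_path / f"truth{seed}.tsv"
    write_bins(pred, left)
    write_bins(truth, right)
    return left, right


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = [1.0, 2.0, 3.0]
        assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_three_point_example(self):
        assert pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson([1], [2])
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2, 3])


class TestCompareReport:
    def test_report_numbers_survive_json_round_trip(self, tmp_path):
        left, right = fixture_pair(tmp_path, 4, n_splits=1, n_extra=1)
        report = compare_report(left, right, alpha=0.5)
        out = tmp_path / "report.json"
        write_json(report, out)
        back = json.loads(out.read_text())
        assert back["normalized"] == report["normalized"]
        assert back["raw"] == report["raw"]

    def test_components_sum_to_total(self, tmp_path):
        left, right = fixture_pair(tmp_path, 5, n_splits=1, n_missing=1, n_duplicate=1)
        report = compare_report(left, right, alpha=0.5)
        raw = report["raw"]
        assert raw["splits"] + raw["joins"] + raw["extra"] + raw["missing"] == pytest.approx(
            raw["total"], rel=1e-9
        )
        norm = report["normalized"]
        assert norm["splits"] + norm["joins"] + norm["extra"] + norm["missing"] == pytest.approx(
            norm["total"], rel=1e-9
        )

    def test_identical_files_score_zero(self, tmp_path):
        truth = generate_binset(6)
        path = tmp_path / "t.tsv"
        write_bins(truth, path)
        report = compare_report(path, path)
        assert report["normalized"]["total"] == 0.0


class TestBatch:
    def manifest(self, tmp_path, rows):
        path = tmp_path / "manifest.tsv"
        path.write_text(
            "sample\tleft\tright\n"
            + "\n".join(f"{s}\t{l.name}\t{r.name}" for s, l, r in rows)
            + "\n"
        )
        return path

    def test_identical_pairs_aggregate_to_zero(self, tmp_path):
        truth = generate_binset(1)
        path = tmp_path / "t.tsv"
        write_bins(truth, path)
        manifest = self.manifest(tmp_path, [("s1", path, path), ("s2", path, path)])
        summary = batch_summary(read_manifest(manifest))
        agg = summary["aggregates"]["d"]
        assert agg == {"mean": 0.0, "std": 0.0, "n": 2}

    def test_sample_standard_deviation_over_rows(self, tmp_path):
        pairs = [fixture_pair(tmp_path, seed, n_splits=1, n_missing=1) for seed in (2, 9)]
        manifest = self.manifest(
            tmp_path, [(f"s{i}", l, r) for i, (l, r) in enumerate(pairs)]
        )
        summary = batch_summary(read_manifest(manifest))
        ds = [row["d"] for row in summary["rows"]]
        mean = sum(ds) / 2
        expected_std = math.sqrt(sum((v - mean) ** 2 for v in ds))  # n−1 = 1
        assert summary["aggregates"]["d"]["std"] == pytest.approx(expected_std)
        assert summary["aggregates"]["d"]["mean"] == pytest.approx(mean)

    def test_rows_sum_to_their_d(self, tmp_path):
        pairs = [fixture_pair(tmp_path, s, n_splits=1, n_extra=1, n_duplicate=1) for s in (3, 4, 5)]
        manifest = self.manifest(tmp_path, [(f"s{i}", l, r) for i, (l, r) in enumerate(pairs)])
        summary = batch_summary(read_manifest(manifest), with_f1=True)
        for row in summary["rows"]:
            total = row["splits"] + row["joins"] + row["extra"] + row["missing"]
            assert total == pytest.approx(row["d"], rel=1e-9)
            assert row["f1"] is not None

    def test_single_row_flagged(self, tmp_path):
        left, right = fixture_pair(tmp_path, 7, n_splits=1)
        manifest = self.manifest(tmp_path, [("only", left, right)])
        summary = batch_summary(read_manifest(manifest))
        agg = summary["aggregates"]["d"]
        assert agg["n"] == 1 and agg["std"] == 0.0 and agg.get("single_row")

    def test_broken_row_excluded_with_note(self, tmp_path):
        left, right = fixture_pair(tmp_path, 8, n_splits=1)
        manifest = self.manifest(tmp_path, [("ok", left, right), ("gone", left, tmp_path / "no.tsv")])
        summary = batch_summary(read_manifest(manifest))
        assert [r["sample"] for r in summary["rows"]] == ["ok"]
        assert summary["excluded"][0]["sample"] == "gone"

    def test_tsv_table_written(self, tmp_path):
        left, right = fixture_pair(tmp_path, 9, n_splits=1)
        manifest = self.manifest(tmp_path, [("s", left, right)])
        summary = batch_summary(read_manifest(manifest))
        out = tmp_path / "batch.tsv"
        write_batch_tsv(summary, out)
        lines = out.read_text().strip().splitlines()
        assert lines[0].startswith("sample\t")
        assert lines[-2].startswith("mean\t") and lines[-1].startswith("std\t")


class TestCli:
    def test_compare_command(self, tmp_path):
        left, right = fixture_pair(tmp_path, 11, n_splits=1)
        out = tmp_path / "report.json"
        result = CliRunner().invoke(
            main, ["compare", "--left", str(left), "--right", str(right), "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        assert json.loads(out.read_text())["alpha"] == 0.5

    def test_compare_repeat_fixture_value(self, tmp_path):
        for name, rows in {
            "left.tsv": [("P", "r", 4), ("P", "a", 9)],
            "right.tsv": [("Q1", "r", 4), ("Q2", "r", 4), ("Q2", "a", 9)],
        }.items():
            (tmp_path / name).write_text(
                "plasmid\tcontig\tcontig_len\n"
                + "\n".join("\t".join(map(str, r)) for r in rows)
                + "\n"
            )
        out = tmp_path / "report.json"
        result = CliRunner().invoke(
            main,
            ["compare", "--left", str(tmp_path / "left.tsv"),
             "--right", str(tmp_path / "right.tsv"), "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        assert json.loads(out.read_text())["normalized"]["total"] == pytest.approx(2 / 12)

    def test_alpha_out_of_range_is_usage_error(self, tmp_path):
        left, right = fixture_pair(tmp_path, 12)
        result = CliRunner().invoke(
            main,
            ["compare", "--left", str(left), "--right", str(right),
             "--alpha", "2", "--out", str(tmp_path / "o.json")],
        )
        assert result.exit_code != 0

    def test_simulate_then_batch_and_score(self, tmp_path):
        runner = CliRunner()
        sim = runner.invoke(
            main,
            ["simulate", "--seed", "5", "--splits", "1", "--missing", "1",
             "--out-dir", str(tmp_path / "fx")],
        )
        assert sim.exit_code == 0, sim.output
        (tmp_path / "m.tsv").write_text(
            "sample\tleft\tright\ns1\tfx/predicted.tsv\tfx/truth.tsv\n"
        )
        batch = runner.invoke(
            main,
            ["batch", "--manifest", str(tmp_path / "m.tsv"), "--ground-truth",
             "--out", str(tmp_path / "b.json")],
        )
        assert batch.exit_code == 0, batch.output
        assert (tmp_path / "b.tsv").exists()
        score = runner.invoke(
            main,
            ["score", "--left", str(tmp_path / "fx/predicted.tsv"),
             "--right", str(tmp_path / "fx/truth.tsv")],
        )
        assert score.exit_code == 0, score.output
        assert "F1 =" in score.output

    def test_truth_command(self, tmp_path):
        (tmp_path / "hits.tsv").write_text(
            "q1\tH1\t99.0\t900\t1\t0\t1\t900\t1\t900\t0.0\t900\n"
            "q2\tH1\t80.0\t900\t1\t0\t1\t900\t1\t900\t0.0\t900\n"
        )
        (tmp_path / "q.fa").write_text(">q1\n" + "A" * 1000 + "\n>q2\n" + "A" * 1000 + "\n")
        (tmp_path / "meta.tsv").write_text("id\tlength\tcircular\nH1\t60000\ttrue\n")
        result = CliRunner().invoke(
            main,
            ["truth", "--blast", str(tmp_path / "hits.tsv"),
             "--query-fasta", str(tmp_path / "q.fa"),
             "--hybrid-meta", str(tmp_path / "meta.tsv"),
             "--out", str(tmp_path / "truth_bins.tsv")],
        )
        assert result.exit_code == 0, result.output
        text = (tmp_path / "truth_bins.tsv").read_text()
        assert "q1" in text and "q2" not in text
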