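"""Comparison grid construction, pipeline runs, and Tukey HSD layer."""

import numpy as np
import pandas as pd
import pytest

from sulaniche.comparison_pipeline import (
    GroupKey,
    build_default_grid,
    per_isotope_pairwise,
    run,
    run_comparisons,
)
from sulaniche.io_tables import RunConfig, write_isotope_table, write_report
from sulaniche.synthetic_data import (
    SyntheticGroupSpec,
    generate_isotopes,
    paper_like_preset,
)


class TestBuildDefaultGrid:
    def test_full_dataset_yields_eight_comparisons(self, paper_like_samples):
        grid = build_default_grid(paper_like_samples)
        assert len(grid) == 8
        assert not any(spec.skip for spec in grid)
        names = [spec.name for spec in grid]
        assert sum("inter_specific" in n for n in names) == 2
        assert sum("female_vs_male" in n for n in names) == 4
        assert sum("breeding_vs_non_breeding" in n for n in names) == 2

    def test_missing_feathers_flags_feather_and_cross_period(self, paper_like_samples):
        blood_only = [s for s in paper_like_samples if s.tissue == "whole_blood"]
        grid = build_default_grid(blood_only)
        skipped = {spec.name for spec in grid if spec.skip}
        assert "inter_specific_body_feather" in skipped
        assert "masked_breeding_vs_non_breeding" in skipped
        assert "red_footed_breeding_vs_non_breeding" in skipped
        assert "inter_specific_whole_blood" not in skipped

    def test_undersized_sex_cell_is_skipped_not_fatal(self):
        specs = paper_like_preset()
        shrunk = [
            SyntheticGroupSpec(s.key, s.mean, s.covariance,
                               2 if s.key == GroupKey("red_footed", "female", "whole_blood") else s.n)
            for s in specs
        ]
        grid = build_default_grid(generate_isotopes(shrunk, seed=1))
        by_name = {spec.name: spec for spec in grid}
        assert by_name["red_footed_female_vs_male_whole_blood"].skip
        assert "n < 3" in by_name["red_footed_female_vs_male_whole_blood"].skip_reason
        assert not by_name["inter_specific_whole_blood"].skip

    def test_single_species_dataset_skips_interspecific_only(self, paper_like_samples):
        masked_only = [s for s in paper_like_samples if s.species == "masked"]
        grid = build_default_grid(masked_only)
        by_name = {spec.name: spec for spec in grid}
        assert by_name["inter_specific_whole_blood"].skip
        assert not by_name["masked_female_vs_male_whole_blood"].skip


class TestRunComparisons:
    CFG = RunConfig(seed=11, n_perm=199)

    def test_report_contains_every_comparison_once(self, paper_like_samples):
        report = run_comparisons(paper_like_samples, self.CFG)
        names = [r.spec.name for r in report.comparisons]
        assert len(names) == len(set(names)) == 8

    def test_rerun_is_identical(self, paper_like_samples):
        r1 = run_comparisons(paper_like_samples, self.CFG)
        r2 = run_comparisons(paper_like_samples, self.CFG)
        assert r1.summary() == r2.summary()

    def test_row_order_does_not_change_results(self, paper_like_samples):
        shuffled = list(paper_like_samples)
        np.random.default_rng(0).shuffle(shuffled)
        r1 = run_comparisons(paper_like_samples, self.CFG)
        r2 = run_comparisons(shuffled, self.CFG)
        assert r1.summary() == r2.summary()

    def test_minimum_p_value_under_small_permutation_count(self, paper_like_samples):
        report = run_comparisons(paper_like_samples, RunConfig(seed=3, n_perm=99))
        for r in report.comparisons:
            for test in (r.dispersion, r.centroid):
                if test is not None:
                    assert test.p_value >= 0.01

    def test_cross_period_comparison_standardizes_blood_side(self, paper_like_samples):
        report = run_comparisons(paper_like_samples, self.CFG)
        by_name = {r.spec.name: r for r in report.comparisons}
        cross = by_name["masked_breeding_vs_non_breeding"]
        blood = [s for s in paper_like_samples
                 if s.species == "masked" and s.tissue == "whole_blood"]
        raw_mean = np.mean([s.d13c for s in blood])
        assert cross.ellipse_a.centroid[0] == pytest.approx(0.972 * raw_mean + 0.962, rel=1e-9)

    def test_written_report_is_byte_identical_across_reruns(self, paper_like_samples, tmp_path):
        report = run_comparisons(paper_like_samples, self.CFG)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        write_report(report, d1)
        write_report(run_comparisons(paper_like_samples, self.CFG), d2)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()

    def test_run_accepts_paths_and_writes_report(self, paper_like_samples, tmp_path):
        iso = tmp_path / "iso.csv"
        write_isotope_table(paper_like_samples, iso)
        out = tmp_path / "report"
        report = run(iso, config=self.CFG, out_dir=out)
        assert (out / "comparisons.csv").exists()
        assert (out / "summary.yaml").exists()
        frame = pd.read_csv(out / "comparisons.csv")
        assert len(frame) == len(report.comparisons)


class TestPerIsotopePairwise:
    def test_two_identical_groups_adjusted_p_near_one(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=30)
        res = per_isotope_pairwise({"a": vals, "b": vals})
        assert res["p_adj"].iloc[0] > 0.9

    def test_shifted_group_rejected_against_all_others(self):
        rng = np.random.default_rng(2)
        groups = {name: rng.normal(0, 1, 15) for name in ("a", "b", "c")}
        groups["d"] = rng.normal(10, 1, 15)  # 10 pooled-sd shift
        res = per_isotope_pairwise(groups)
        involving_d = res[(res["group1"] == "d") | (res["group2"] == "d")]
        assert len(involving_d) == 3
        assert (involving_d["p_adj"] < 0.001).all()
        others = res[~((res["group1"] == "d") | (res["group2"] == "d"))]
        assert not others.empty

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            per_isotope_pairwise({"a": [1.0, 2.0, 3.0]})

    def test_constant_identical_groups_degenerate(self):
        with pytest.raises(ValueError):
            per_isotope_pairwise({"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0, 2.0]})
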