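"""Combinatorial perturbation enumeration, scoring and ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from monolignol.screen import (
    ExtrapolationWarning,
    PerturbationConfig,
    ScreenRow,
    enumerate_configs,
    predict_for_config,
    proportional_score,
    rank_configs,
)

FAMILIES10 = ["PAL", "C4H", "C3H", "4CL", "HCT",
              "CCoAOMT", "CCR", "CAld5H", "AldOMT", "CAD"]


def closed_form_count(f: int, levels: int, m: int) -> int:
    return sum(math.comb(f, k) * levels**k for k in range(m + 1))


class TestEnumeration:
    def test_study_screen_has_1161_configs(self):
        configs = enumerate_configs(FAMILIES10, (0.05, 10.0), 3)
        assert len(configs) == 1161

    def test_single_family_three_configs(self):
        configs = enumerate_configs(["PAL"], (0.05, 10.0), 1)
        ids = {c.config_id for c in configs}
        assert ids == {"WT", "PALx0.05", "PALx10"}

    def test_four_families_two_modified(self):
        configs = enumerate_configs(["A", "B", "C", "D"], (0.05, 10.0), 2)
        assert len(configs) == 33  # 1 + 4*2 + 6*4

    def test_no_duplicates_and_wildtype_included(self):
        configs = enumerate_configs(FAMILIES10, (0.05, 10.0), 2)
        ids = [c.config_id for c in configs]
        assert len(ids) == len(set(ids))
        assert "WT" in ids

    @settings(deadline=None, max_examples=30)
    @given(f=st.integers(1, 6), l=st.integers(1, 3), m=st.integers(0, 3))
    def test_count_matches_closed_form(self, f, l, m):
        m = min(m, f)
        levels = tuple(0.1 * (i + 1) for i in range(l))
        fams = [f"F{i}" for i in range(f)]
        assert len(enumerate_configs(fams, levels, m)) == \
            closed_form_count(f, l, m)

    def test_rejects_wildtype_level(self):
        with pytest.raises(ValueError, match="1.0"):
            enumerate_configs(FAMILIES10, (0.05, 1.0), 2)


class TestProportionalScore:
    def test_perfect_match_scores_zero(self):
        assert proportional_score({"a": 2.0, "b": 3.0}, {"a": 2.0, "b": 3.0}) == 0.0

    def test_printed_formula(self):
        assert proportional_score({"a": 2.0, "b": 3.0}, {"a": 0.0, "b": 0.0}) == 13.0

    def test_reorder_invariant(self):
        p = {"a": 1.0, "b": 5.0, "c": -2.0}
        d = {"c": 1.0, "a": 0.5, "b": 4.0}
        assert proportional_score(p, d) == proportional_score(dict(reversed(list(p.items()))), d)

    def test_mismatched_traits_listed(self):
        with pytest.raises(ValueError, match="only-desired.*'b'"):
            proportional_score({"a": 1.0}, {"b": 1.0})

    @settings(deadline=None, max_examples=30)
    @given(st.dictionaries(st.sampled_from("abcdef"),
                           st.floats(-50, 50), min_size=1))
    def test_nonnegative_zero_iff_equal(self, d):
        assert proportional_score(d, d) == 0.0
        shifted = {k: v + 1.0 for k, v in d.items()}
        assert proportional_score(shifted, d) > 0.0


def _row(config_id_mults, traits, converged=True):
    mult = {f: 1.0 for f in FAMILIES10}
    mult.update(config_id_mults)
    return ScreenRow(PerturbationConfig(tuple(mult.items())), traits,
                     {t: 0.0 for t in traits}, converged)


class TestRanking:
    def test_ascending_score_order(self):
        rows = [_row({"PAL": 0.05}, {"x": 5.0}), _row({"C4H": 0.05}, {"x": 2.0})]
        ranked = rank_configs(rows, {"x": 0.0})
        assert [r.score for r in ranked] == [4.0, 25.0]
        assert [r.rank for r in ranked] == [1, 2]

    def test_wildtype_first_for_wildtype_targets(self):
        wt = _row({}, {"x": 3.0})
        other = _row({"PAL": 0.05}, {"x": 3.5})
        ranked = rank_configs([other, wt], {"x": 3.0})
        assert ranked[0].config.config_id == "WT"
        assert ranked[0].score == 0.0

    def test_single_trait_direction(self):
        rows = [_row({"PAL": 0.05}, {"x": 1.0}), _row({"C4H": 0.05}, {"x": 9.0})]
        up = rank_configs(rows, ("x", "max"))
        assert up[0].traits["x"] == 9.0
        down = rank_configs(rows, ("x", "min"))
        assert down[0].traits["x"] == 1.0

    def test_matches_sort_oracle_on_random_rows(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(100):
            fam = FAMILIES10[i % 10]
            rows.append(_row({fam: 0.05} if i else {}, {"x": float(rng.normal())}))
        ranked = rank_configs(rows, {"x": 0.0})
        oracle = sorted(rows, key=lambda r: (r.traits["x"] ** 2,
                                             r.config.n_modified,
                                             r.config.config_id))
        assert [r.config.config_id for r in ranked] == \
            [r.config.config_id for r in oracle]

    def test_nonconverged_rows_excluded(self):
        good = _row({"PAL": 0.05}, {"x": 1.0})
        bad = _row({"C4H": 0.05}, {"x": 0.0}, converged=False)
        ranked = rank_configs([bad, good], {"x": 0.0})
        assert [r.config.config_id for r in ranked] == ["PALx0.05"]

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError, match="no converged"):
            rank_configs([], {"x": 0.0})


class TestPredictForConfig:
    def test_wildtype_config_has_zero_percent_change(self, small_noisefree):
        _, pipe = small_noisefree
        wt = enumerate_configs(list(pipe.pathway.families))[0]
        assert wt.config_id == "WT"
        row = predict_for_config(wt, pipe)
        assert row.converged
        for t, pct in row.percent_change.items():
            if np.isfinite(pct):
                assert pct == pytest.approx(0.0, abs=1e-6)

    def test_null_influence_family_leaves_trait_unchanged(self, small_noisefree):
        # intercept-only trait model: no family can move the prediction
        import copy
        _, pipe = small_noisefree
        pipe = copy.deepcopy(pipe)
        trait = next(iter(pipe.trait_models.models))
        m = pipe.trait_models.models[trait]
        m.predictors = ()
        m.coefficients = ()
        m.intercept = 42.0
        pipe.wt_traits[trait] = 42.0
        cfg_id = {"CAD": 10.0}
        mult = {f: 1.0 for f in pipe.pathway.families}
        mult.update(cfg_id)
        with pytest.warns(ExtrapolationWarning):
            row = predict_for_config(PerturbationConfig(tuple(mult.items())), pipe)
        assert row.percent_change[trait] == pytest.approx(0.0, abs=1e-9)

    def test_knockdown_scales_member_gene_transcripts(self, small_noisefree):
        _, pipe = small_noisefree
        mult = {f: 1.0 for f in pipe.pathway.families}
        mult["PAL"] = 0.05
        row = predict_for_config(PerturbationConfig(tuple(mult.items())), pipe)
        assert row.converged
        # strong PAL knockdown must move at least one trait
        assert any(abs(p) > 1.0 for p in row.percent_change.values()
                   if np.isfinite(p))
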