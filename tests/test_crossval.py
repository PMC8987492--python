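import numpy as np
import pandas as pd
import pytest

from boablup import (OriginMap, make_cv_plan, run_cv, scenario_design,
                     summarize, grid_search_correlation)
from boablup.crossval import _pearson

from conftest import make_map, make_panel


def _family_panel(n, n_sires, m=40, seed=0, breed="AN"):
    rng = np.random.default_rng(seed)
    fam = n // n_sires
    return make_panel(rng.integers(0, 2, (n, 2, m)), breed=breed,
                      sires=[f"S{j // fam}" for j in range(n)],
                      dams=[f"D{j}" for j in range(n)])


class TestCvPlan:
    def test_fifty_sires_five_folds(self):
        panel = _family_panel(750, 50)
        plan = make_cv_plan(panel, 5, seed=1)
        per_fold = pd.Series(plan.sire_folds).value_counts()
        assert (per_fold == 10).all()
        sizes = plan.fold_of.value_counts()
        assert (sizes == 150).all()

    def test_partition_and_sire_disjointness(self):
        panel = _family_panel(120, 12)
        plan = make_cv_plan(panel, 4, seed=2)
        assert set(plan.fold_of.index) == set(panel.ids)
        fold_by_sire = panel.individuals.groupby("sire_id")["id"].apply(
            lambda ids: {plan.fold_of[i] for i in ids})
        assert all(len(s) == 1 for s in fold_by_sire)

    def test_single_fold_and_missing_sires_rejected(self):
        panel = _family_panel(20, 4)
        with pytest.raises(ValueError, match="2 folds"):
            make_cv_plan(panel, 1)
        orphan = make_panel(np.zeros((4, 2, 3)))
        with pytest.raises(ValueError, match="sire"):
            make_cv_plan(orphan, 2)


class TestScenarioDesign:
    @pytest.mark.parametrize("n_an,val,ref1,ref2,pct", [
        (750, 150, 600, 6600, 9.09),
        (1500, 300, 1200, 7200, 16.67),
        (3000, 600, 2400, 8400, 28.57),
    ])
    def test_breed_size_table(self, n_an, val, ref1, ref2, pct):
        d = scenario_design(n_an)
        assert d["validation"] == val
        assert d["reference_within"] == ref1
        assert d["reference_multi"] == ref2
        assert d["pct_an_multi"] == pct
        assert d["sires_per_fold"] == 10
        assert d["fold_sizes"] == [val] * 5


class TestSummarize:
    def test_identical_accuracies_have_zero_spread(self):
        df = pd.DataFrame({"model": "boa", "replicate": [0, 0, 1, 1],
                           "fold": [0, 1, 0, 1], "accuracy": 0.5})
        out = summarize(df)
        assert out.loc[0, "sd"] == 0.0 and out.loc[0, "se"] == 0.0

    def test_two_replicate_hand_example(self):
        df = pd.DataFrame({"model": "boa", "replicate": [0, 1],
                           "fold": [0, 0], "accuracy": [0.4, 0.6]})
        out = summarize(df).iloc[0]
        assert out["mean"] == pytest.approx(0.5)
        assert out["sd"] == pytest.approx(0.14142, abs=1e-4)
        assert out["se"] == pytest.approx(0.1, abs=1e-5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame(columns=["model", "accuracy"]))


class TestAccuracy:
    def test_perfect_prediction_scores_one(self):
        v = np.array([0.3, -0.2, 1.4, 0.0])
        assert _pearson(v, v) == pytest.approx(1.0)

    def test_constant_vector_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            out = _pearson(np.ones(5), np.arange(5.0))
        assert np.isnan(out)


@pytest.fixture(scope="module")
def tiny_cv_setting():
    """Small two-breed CV problem with random origins."""
    rng = np.random.default_rng(30)
    m = 60
    gmap = make_map(np.sort(rng.choice(10_000_000, m, replace=False) + 1))
    an = _family_panel(60, 10, m=m, seed=31)
    an = make_panel(an.haplotypes, breed="AN", marker_map=gmap,
                    sires=an.individuals["sire_id"], dams=an.individuals["dam_id"])
    hf = make_panel(rng.integers(0, 2, (40, 2, m)), breed="HF", marker_map=gmap,
                    prefix="H")
    codes = (rng.random((60, 2, m)) < 0.2).astype(np.uint8)
    origins = OriginMap(codes, ("AN", "HF"))
    tbv_an = rng.normal(0, 0.5, 60)
    tbv_hf = rng.normal(0, 0.5, 40)
    an_ph = pd.DataFrame({"individual_id": an.ids,
                          "y": tbv_an + rng.normal(0, 0.8, 60), "tbv": tbv_an})
    hf_ph = pd.DataFrame({"individual_id": hf.ids,
                          "y": tbv_hf + rng.normal(0, 0.8, 40), "tbv": tbv_hf})
    mask = np.ones(m, bool)
    plan = make_cv_plan(an, 5, seed=32)
    return an, an_ph, hf, hf_ph, origins, mask, plan


class TestRunCv:
    def test_structure_and_reference_sizes(self, tiny_cv_setting):
        an, an_ph, hf, hf_ph, origins, mask, plan = tiny_cv_setting
        res = run_cv(an, an_ph, hf, hf_ph, origins, mask, plan, r=0.75)
        assert len(res) == 5 * 3
        assert set(res["model"]) == {"boa", "snp_blup_multi", "snp_blup_within"}
        within = res[res["model"] == "snp_blup_within"]
        assert (within["n_reference"] == 48).all()
        multi = res[res["model"] != "snp_blup_within"]
        assert (multi["n_reference"] == 48 + 40).all()
        assert res["accuracy"].notna().all()

    def test_no_leakage_from_validation_phenotypes(self, tiny_cv_setting):
        """Perturbing held-out phenotypes leaves that fold's accuracy unchanged."""
        an, an_ph, hf, hf_ph, origins, mask, plan = tiny_cv_setting
        base = run_cv(an, an_ph, hf, hf_ph, origins, mask, plan, r=0.5)
        mutated = an_ph.copy()
        fold0 = set(plan.fold_ids(0))
        mutated.loc[mutated["individual_id"].isin(fold0), "y"] += 1000.0
        res = run_cv(an, mutated, hf, hf_ph, origins, mask, plan, r=0.5)
        f0 = base["fold"] == 0
        pd.testing.assert_frame_equal(base[f0].reset_index(drop=True),
                                      res[f0].reset_index(drop=True))

    def test_unknown_model_rejected(self, tiny_cv_setting):
        an, an_ph, hf, hf_ph, origins, mask, plan = tiny_cv_setting
        with pytest.raises(ValueError, match="unknown models"):
            run_cv(an, an_ph, hf, hf_ph, origins, mask, plan, models=("gblup",))


class TestGridSearch:
    def test_single_element_grid_returned(self, tiny_cv_setting):
        an, an_ph, hf, hf_ph, origins, mask, plan = tiny_cv_setting
        best, prof = grid_search_correlation(an, an_ph, hf, hf_ph, origins,
                                             mask, plan, grid=(0.75,))
        assert best == 0.75 and len(prof) == 1

    def test_empty_or_invalid_grid_rejected(self, tiny_cv_setting):
        an, an_ph, hf, hf_ph, origins, mask, plan = tiny_cv_setting
        with pytest.raises(ValueError, match="empty"):
            grid_search_correlation(an, an_ph, hf, hf_ph, origins, mask, plan,
                                    grid=())
        with pytest.raises(ValueError, match="grid values"):
            grid_search_correlation(an, an_ph, hf, hf_ph, origins, mask, plan,
                                    grid=(1.5,))

    def test_ties_break_toward_larger_r(self, tiny_cv_setting, monkeypatch):
        import boablup.crossval as cv
        an, an_ph, hf, hf_ph, origins, mask, plan = tiny_cv_setting

        def fake_run_cv(*args, **kwargs):
            return pd.DataFrame({"fold": [0], "model": ["boa"],
                                 "accuracy": [0.3]})

        monkeypatch.setattr(cv, "run_cv", fake_run_cv)
        best, prof = cv.grid_search_correlation(
            an, an_ph, hf, hf_ph, origins, mask, plan, grid=(0.4, 0.8, 0.6))
        assert best == 0.8
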