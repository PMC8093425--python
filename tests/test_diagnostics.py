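"""Life-history models, dominance classification and scale-dependence screens."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from precipdiv.diagnostics_lifehistory import (
    dominant_species,
    fit_lifehistory_model,
    lifehistory_group_test,
    spake_codependence,
    weighted_refit,
)
from precipdiv.inference import ModelSpec, fit_lmm, prepare_effects
from precipdiv.synthetic_data import (
    ScenarioConfig,
    generate_effectsize_table,
    generate_synthesis_dataset,
)


def _community(rows):
    return pd.DataFrame(
        rows,
        columns=["is_control", "block_id", "plot_id", "species_id", "abundance"],
    )


class TestDominance:
    def test_argmax(self):
        df = _community(
            [(True, "b1", "p1", "A", 60.0), (True, "b1", "p1", "B", 40.0)]
        )
        rec = dominant_species(df, site_id="s1")
        assert rec.dominant_species == "A"
        assert rec.basis == pytest.approx(60.0)
        assert not rec.tied

    def test_tie_broken_lexicographically(self):
        df = _community(
            [(True, "b1", "p1", "B", 50.0), (True, "b1", "p1", "A", 50.0)]
        )
        rec = dominant_species(df, site_id="s1")
        assert rec.dominant_species == "A"
        assert rec.tied

    def test_empty_control_rejected(self):
        df = _community([(False, "b1", "p1", "A", 10.0)])
        with pytest.raises(ValueError):
            dominant_species(df)

    def test_matches_generator_truth(self):
        """The generator's SAD puts sp000 on top; dominance must recover it."""
        cfg = ScenarioConfig(
            n_studies=3, n_experiments_total=6, species_pool_size=15,
            sad_shape=1.5, individuals_per_plot_control=300, seed=31,
        )
        community, meta, truth = generate_synthesis_dataset(cfg)
        hits = 0
        for exp_id, grp in community.groupby("experiment_id"):
            rec = dominant_species(grp, site_id=exp_id)
            if not rec.tied:
                assert rec.dominant_species == truth[exp_id]["dominant_species"]
                hits += 1
        assert hits >= 4


class TestLifehistoryLogistic:
    def test_balanced_null_intercept_near_logit_fraction(self, rng):
        n = 200
        meta = pd.DataFrame(
            {
                "study_id": np.repeat([f"s{i}" for i in range(20)], n // 20),
                "experiment_id": [f"e{i}" for i in range(n)],
                "PET": rng.normal(1000, 200, n),
                "dominant_life_history": np.where(
                    rng.uniform(size=n) < 0.3, "monocarpic", "polycarpic"
                ),
            }
        )
        fit = fit_lifehistory_model(meta, climate="PET")
        frac = (meta["dominant_life_history"] == "monocarpic").mean()
        assert fit.coefficients["Intercept"] == pytest.approx(logit(frac), abs=0.35)
        assert abs(fit.coefficients["PET"]) < 1.0

    def test_strong_association_detected_with_correct_sign(self, rng):
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            n = 120
            pet = r.normal(0, 0.5, n)
            y = r.uniform(size=n) < expit(2.5 * pet)
            meta = pd.DataFrame(
                {
                    "study_id": np.repeat([f"s{i}" for i in range(12)], n // 12),
                    "experiment_id": [f"e{i}" for i in range(n)],
                    "PET": pet,
                    "dominant_life_history": np.where(y, "monocarpic", "polycarpic"),
                }
            )
            fit = fit_lifehistory_model(meta, climate="PET", standardize=False)
            if fit.coefficients["PET"] > 0 and fit.p_value < 0.05:
                hits += 1
        assert hits >= 19

    def test_single_class_rejected(self):
        meta = pd.DataFrame(
            {
                "study_id": ["s1", "s2"],
                "experiment_id": ["e1", "e2"],
                "PET": [1.0, 2.0],
                "dominant_life_history": ["monocarpic", "monocarpic"],
            }
        )
        with pytest.raises(ValueError):
            fit_lifehistory_model(meta, climate="PET")


def _effects_with_groups(rng, offset=0.0, n_studies=16):
    tab, _ = generate_effectsize_table([0.0], (0.1, 0.1, 0.1, 0.2), n_studies, 2, 4, rng)
    study_num = tab["study_id"].str[-2:].astype(int)
    tab["dominant_life_history"] = np.where(
        study_num % 2 == 0, "monocarpic", "polycarpic"
    )
    tab.loc[tab["dominant_life_history"] == "monocarpic", "lrr"] += offset
    tab["plot_size"] = 1.0
    return tab


class TestGroupTest:
    def test_swapping_labels_negates_difference(self, rng):
        tab = _effects_with_groups(rng, offset=0.2)
        res1 = lifehistory_group_test(tab, n_boot=30, rng=np.random.default_rng(0))
        swapped = tab.copy()
        swapped["dominant_life_history"] = swapped["dominant_life_history"].map(
            {"monocarpic": "polycarpic", "polycarpic": "monocarpic"}
        )
        res2 = lifehistory_group_test(swapped, n_boot=30, rng=np.random.default_rng(0))
        assert res1["difference"].iloc[0] == pytest.approx(
            -res2["difference"].iloc[0], abs=1e-6
        )

    def test_injected_offset_detected(self, rng):
        tab = _effects_with_groups(rng, offset=0.5, n_studies=20)
        res = lifehistory_group_test(tab, n_boot=60, rng=np.random.default_rng(1))
        assert res["significant"].iloc[0]
        assert res["difference"].iloc[0] > 0

    def test_missing_group_rejected(self, rng):
        tab = _effects_with_groups(rng)
        tab["dominant_life_history"] = "monocarpic"
        with pytest.raises(ValueError):
            lifehistory_group_test(tab, n_boot=10, rng=rng)


class TestCodependence:
    def test_homogeneous_studies_unflagged(self, rng):
        tab = _effects_with_groups(rng)
        tab["plot_size"] = rng.uniform(0.5, 1.5, len(tab))
        meta = (
            tab.drop_duplicates("experiment_id")[["study_id", "experiment_id"]]
            .assign(delta_P=rng.uniform(-50, 50, 32), MAP=rng.uniform(300, 900, 32),
                    duration=rng.integers(1, 10, 32))
        )
        rep = spake_codependence(tab, meta, leave_one_out=False)
        assert (rep.effect_design_correlations["r"].abs().dropna() <= 1).all()

    def test_inflated_study_flagged(self, rng):
        """A study with 10x plot size and inflated LRR variance draws a flag."""
        tab = _effects_with_groups(rng, n_studies=10)
        tab["plot_size"] = 1.0
        big = tab["study_id"] == "study01"
        tab.loc[big, "plot_size"] = 10.0
        tab.loc[big, "lrr"] *= 8.0
        meta = tab.drop_duplicates("experiment_id")[["study_id", "experiment_id"]].assign(
            delta_P=-40.0, MAP=500.0, duration=5
        )
        rep = spake_codependence(tab, meta, leave_one_out=False)
        assert any("var_lrr" in f and "plot_size" in f for f in rep.flagged_correlations)

    def test_needs_three_studies(self, rng):
        tab = _effects_with_groups(rng)
        small = tab[tab["study_id"].isin(["study01", "study02"])]
        with pytest.raises(ValueError):
            spake_codependence(small, pd.DataFrame({"study_id": []}))

    def test_leave_one_out_order_invariant(self, rng):
        tab, _ = generate_effectsize_table([0.0, 0.3], (0.1, 0.1, 0.1, 0.2), 8, 2, 3, rng)
        tab["plot_size"] = 1.0
        tab["delta_P"] = tab["delta_P_s"] * 100
        tab["MAP"] = 500.0
        tab["duration"] = 5
        meta = tab.drop_duplicates("experiment_id")[
            ["study_id", "experiment_id", "delta_P", "MAP", "duration"]
        ]
        rep1 = spake_codependence(tab, meta)
        rep2 = spake_codependence(tab.sample(frac=1.0, random_state=2), meta)
        assert rep1.influential_studies == rep2.influential_studies


class TestWeightedRefit:
    def test_equal_weights_match_unweighted(self, rng):
        tab, _ = generate_effectsize_table([0.05, 0.25], (0.1, 0.1, 0.1, 0.2), 10, 2, 4, rng)
        df, _ = prepare_effects(tab, "S", "local", standardize=False)
        df["n_plots_treatment"] = 4
        spec = ModelSpec(fixed_terms=("delta_P_s",), scale="local")
        weighted, cmp = weighted_refit(df, spec)
        for k, v in cmp["unweighted"].coefficients.items():
            assert weighted["coefficients"][k] == pytest.approx(v, abs=1e-3)
        assert all(cmp["sign_agreement"].values())
        assert weighted["weights_column"] == "n_plots_treatment"

    def test_unequal_weights_shift_towards_heavy_rows(self, rng):
        tab, _ = generate_effectsize_table([0.0, 0.3], (0, 0, 0, 0.3), 12, 2, 4, rng)
        df, _ = prepare_effects(tab, "S", "local", standardize=False)
        df["n_plots_treatment"] = np.where(df["study_id"] == "study01", 100, 1)
        spec = ModelSpec(fixed_terms=("delta_P_s",), scale="local")
        weighted, cmp = weighted_refit(df, spec)
        assert weighted["converged"]
        # weighted and unweighted must genuinely differ
        assert weighted["coefficients"]["delta_P_s"] != pytest.approx(
            cmp["unweighted"].coefficients["delta_P_s"], abs=1e-6
        )

    def test_nonpositive_sample_size_rejected(self, rng):
        tab, _ = generate_effectsize_table([0.0], (0, 0, 0, 0.1), 5, 2, 2, rng)
        df, _ = prepare_effects(tab, "S", "local", standardize=False)
        df["n_plots_treatment"] = 0
        with pytest.raises(ValueError):
            weighted_refit(df, ModelSpec(fixed_terms=(), scale="local"))
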