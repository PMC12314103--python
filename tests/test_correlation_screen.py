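import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microskill import (
    CohortTable,
    DegenerateInputError,
    InputError,
    ParameterKey,
    screen_parameters,
    screen_to_frame,
    select_model_features,
    spearman_rho_p,
)
from microskill.rubric_scoring import SurgeonScore
from microskill.io_formats import RUBRIC_CATEGORIES

from reference_screen import reference_screen_frame


def brute_force_permutation_p(x, y):
    """Exhaustive two-sided permutation p-value for Spearman rho, with rho
    computed by scipy (independent of the package's rank path)."""
    obs = abs(stats.spearmanr(x, y).statistic)
    count = total = 0
    for perm in itertools.permutations(y):
        r = stats.spearmanr(x, perm).statistic
        count += abs(r) >= obs - 1e-12
        total += 1
    return count / total


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([0.1, 0.7, 1.3, 2.0, 3.5])
        rho, _ = spearman_rho_p(x, np.exp(x))
        assert rho == 1.0

    def test_antitone_gives_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rho, _ = spearman_rho_p(x, -x)
        assert rho == -1.0

    def test_known_example_rho(self):
        rho, _ = spearman_rho_p([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_permutation_p_matches_exhaustive_enumeration(self, rng):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        _, p = spearman_rho_p(x, y, method="permutation")
        assert p == pytest.approx(brute_force_permutation_p(x, y))

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_permutation_oracle_random_fixtures(self, n, rng):
        for _ in range(5):
            x = rng.normal(size=n)
            y = rng.choice([0.0, 1.0, 2.0], size=n)  # forces ties
            if len(set(y)) == 1:
                continue
            _, p = spearman_rho_p(x, y, method="permutation")
            assert p == pytest.approx(brute_force_permutation_p(x, y))

    def test_rank_invariance_under_increasing_transform(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        rho1, _ = spearman_rho_p(x, y)
        rho2, _ = spearman_rho_p(np.exp(x), y**3 + 5 * y)
        assert rho1 == pytest.approx(rho2)

    def test_constant_input_flagged(self):
        with pytest.raises(DegenerateInputError):
            spearman_rho_p([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_pairs(self):
        with pytest.raises(InputError):
            spearman_rho_p([1, 2, 3], [1, 2, 3])

    def test_missing_pairs_dropped_listwise(self):
        rho, _ = spearman_rho_p([1, 2, np.nan, 3, 4, 5], [1, 2, 9, 3, 4, np.nan])
        assert rho == 1.0


def toy_cohort_and_scores(n=10, seed=3):
    rng = np.random.default_rng(seed)
    total = np.linspace(10, 44, n) + rng.normal(0, 0.1, n)
    surgeons = [f"s{i}" for i in range(n)]
    values = pd.DataFrame(
        {
            "n_tde:All": -total + rng.normal(0, 0.5, n),  # tracks skill
            "cv_va:All": rng.normal(size=n),  # noise
        },
        index=surgeons,
    )
    scores = [
        SurgeonScore(s, {c: t / 9 for c in RUBRIC_CATEGORIES})
        for s, t in zip(surgeons, total)
    ]
    return CohortTable(values=values), scores


class TestScreenParameters:
    def test_informative_parameter_significant_everywhere(self):
        cohort, scores = toy_cohort_and_scores()
        screen = screen_parameters(cohort, scores)
        df = screen_to_frame(screen)
        tde = df[df["parameter"] == "n_tde"]
        assert tde["significant"].all()
        assert (tde["rho"] < 0).all()

    def test_missing_cell_uses_fewer_pairs(self):
        cohort, scores = toy_cohort_and_scores()
        cohort.values.loc["s0", "n_tde:All"] = np.nan
        df = screen_to_frame(screen_parameters(cohort, scores))
        assert (df[df["parameter"] == "n_tde"]["n"] == 9).all()
        assert (df[df["parameter"] == "cv_va"]["n"] == 10).all()

    def test_type_one_error_calibration(self):
        # pure-noise parameter at alpha 0.05: about 5% of cells significant
        rng = np.random.default_rng(11)
        n = 20
        surgeons = [f"s{i}" for i in range(n)]
        total = np.linspace(9, 45, n)
        scores = [
            SurgeonScore(s, {c: (t + rng.normal(0, 0.3)) / 9
                             for c in RUBRIC_CATEGORIES})
            for s, t in zip(surgeons, total)
        ]
        hits = trials = 0
        for _ in range(60):
            values = pd.DataFrame(
                {"cv_va:All": rng.normal(size=n)}, index=surgeons
            )
            df = screen_to_frame(
                screen_parameters(CohortTable(values=values), scores)
            )
            hits += df["significant"].sum()
            trials += len(df)
        rate = hits / trials
        assert 0.01 < rate < 0.10

    def test_too_few_shared_surgeons(self):
        cohort, scores = toy_cohort_and_scores(n=4)
        with pytest.raises(InputError):
            screen_parameters(cohort, scores[:3])


class TestSelectModelFeatures:
    def test_reference_table_selection(self):
        m1, m2, m3 = select_model_features(reference_screen_frame())
        assert set(m1) == {
            ParameterKey("n_tde", phase="C"),
            ParameterKey("max_dva", phase="B"),
        }
        assert set(m2) == {
            ParameterKey("pd", hand="right", phase="All"),
            ParameterKey("pd", hand="left", phase="All"),
            ParameterKey("nji", hand="left", phase="All"),
            ParameterKey("nji", hand="right", phase="C"),
        }
        assert set(m3) == set(m1) | set(m2)
        assert len(m3) == 6

    def test_nothing_significant_gives_empty_models(self):
        df = reference_screen_frame()
        df["p"] = 1.0
        df["significant"] = False
        with pytest.warns(UserWarning):
            m1, m2, m3 = select_model_features(df)
        assert m1 == [] and m2 == [] and m3 == []

    def test_single_significant_cell_selected(self):
        df = reference_screen_frame()
        df["significant"] = False
        df["p"] = 1.0
        pick = (df["parameter"] == "cv_va") & (df["phase"] == "D") & (
            df["category"] == "efficiency"
        )
        df.loc[pick, ["p", "significant"]] = [0.01, True]
        with pytest.warns(UserWarning):  # motion family stays empty
            m1, m2, m3 = select_model_features(df)
        assert m1 == [ParameterKey("cv_va", phase="D")]
        assert m2 == []
        assert m3 == m1

    def test_model3_is_union(self, rng):
        df = reference_screen_frame()
        # randomly rescale p-values; union property must always hold
        df["p"] = rng.uniform(0, 0.2, len(df))
        df["significant"] = df["p"] < 0.05
        m1, m2, m3 = select_model_features(df)
        assert set(m3) == set(m1) | set(m2)
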