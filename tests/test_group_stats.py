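"""Mixed ANOVA, follow-up t-tests, and a priori power."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.power import TTestIndPower

from stressmmn import (
    DataError,
    independent_t,
    mixed_anova,
    one_sample_t,
    paired_contrast,
    required_sample_size,
    two_sample_power,
)
from stressmmn.group_stats import (
    anova_ss_total,
    groupwise_position_test,
    position_difference_weights,
    subject_contrast_values,
)

CUES = ["pitch", "intensity", "duration"]
POSITIONS = ["syll1", "syll2"]


def random_table(rng, n_per_group=(4, 4), effects=None):
    """Balanced long table with optional injected effects."""
    effects = effects or {}
    rows = []
    for gi, n in enumerate(n_per_group):
        group = f"g{gi}"
        for s in range(n):
            subject = f"{group}_s{s}"
            subj_offset = rng.normal(scale=1.0)
            for cue in CUES:
                for pos in POSITIONS:
                    value = (
                        rng.normal()
                        + subj_offset
                        + effects.get((group, cue, pos), 0.0)
                    )
                    rows.append(
                        {
                            "subject": subject,
                            "group": group,
                            "cue": cue,
                            "position": pos,
                            "mean_amplitude_uv": value,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# brute-force oracle: classical marginal-mean formulas with explicit loops
# ---------------------------------------------------------------------------

def anova_oracle(table):
    data = {
        (r.subject, r.cue, r.position): r.mean_amplitude_uv for r in table.itertuples()
    }
    group_of = {r.subject: r.group for r in table.itertuples()}
    subjects = sorted({k[0] for k in data})
    cues = sorted({k[1] for k in data})
    poss = sorted({k[2] for k in data})
    groups = sorted(set(group_of.values()))
    N, a, b, g = len(subjects), len(cues), len(poss), len(groups)
    n_g = {gr: sum(1 for s in subjects if group_of[s] == gr) for gr in groups}

    def mean(vals):
        vals = list(vals)
        return sum(vals) / len(vals)

    grand = mean(data.values())
    m_s = {s: mean(data[(s, c, p)] for c in cues for p in poss) for s in subjects}
    m_g = {gr: mean(m_s[s] for s in subjects if group_of[s] == gr) for gr in groups}
    m_c = {c: mean(data[(s, c, p)] for s in subjects for p in poss) for c in cues}
    m_p = {p: mean(data[(s, c, p)] for s in subjects for c in cues) for p in poss}
    m_gc = {
        (gr, c): mean(
            data[(s, c, p)] for s in subjects if group_of[s] == gr for p in poss
        )
        for gr in groups for c in cues
    }
    m_gp = {
        (gr, p): mean(
            data[(s, c, p)] for s in subjects if group_of[s] == gr for c in cues
        )
        for gr in groups for p in poss
    }
    m_cp = {(c, p): mean(data[(s, c, p)] for s in subjects) for c in cues for p in poss}
    m_gcp = {
        (gr, c, p): mean(data[(s, c, p)] for s in subjects if group_of[s] == gr)
        for gr in groups for c in cues for p in poss
    }
    m_sc = {(s, c): mean(data[(s, c, p)] for p in poss) for s in subjects for c in cues}
    m_sp = {(s, p): mean(data[(s, c, p)] for c in cues) for s in subjects for p in poss}

    ss = {}
    ss["group"] = a * b * sum(n_g[gr] * (m_g[gr] - grand) ** 2 for gr in groups)
    ss_sg = a * b * sum((m_s[s] - m_g[group_of[s]]) ** 2 for s in subjects)
    ss["cue"] = N * b * sum((m_c[c] - grand) ** 2 for c in cues)
    ss["group:cue"] = b * sum(
        n_g[gr] * (m_gc[(gr, c)] - m_g[gr] - m_c[c] + grand) ** 2
        for gr in groups for c in cues
    )
    ss_csg = b * sum(
        (m_sc[(s, c)] - m_s[s] - m_gc[(group_of[s], c)] + m_g[group_of[s]]) ** 2
        for s in subjects for c in cues
    )
    ss["position"] = N * a * sum((m_p[p] - grand) ** 2 for p in poss)
    ss["group:position"] = a * sum(
        n_g[gr] * (m_gp[(gr, p)] - m_g[gr] - m_p[p] + grand) ** 2
        for gr in groups for p in poss
    )
    ss_psg = a * sum(
        (m_sp[(s, p)] - m_s[s] - m_gp[(group_of[s], p)] + m_g[group_of[s]]) ** 2
        for s in subjects for p in poss
    )
    ss["cue:position"] = N * sum(
        (m_cp[(c, p)] - m_c[c] - m_p[p] + grand) ** 2 for c in cues for p in poss
    )
    ss["group:cue:position"] = sum(
        n_g[gr]
        * (
            m_gcp[(gr, c, p)] - m_gc[(gr, c)] - m_gp[(gr, p)] + m_g[gr]
            - (m_cp[(c, p)] - m_c[c] - m_p[p] + grand)
        ) ** 2
        for gr in groups for c in cues for p in poss
    )
    ss_cpsg = sum(
        (
            data[(s, c, p)] - m_sc[(s, c)] - m_sp[(s, p)] + m_s[s]
            - (
                m_gcp[(group_of[s], c, p)]
                - m_gc[(group_of[s], c)]
                - m_gp[(group_of[s], p)]
                + m_g[group_of[s]]
            )
        ) ** 2
        for s in subjects for c in cues for p in poss
    )
    errors = {"s(g)": ss_sg, "cs(g)": ss_csg, "ps(g)": ss_psg, "cps(g)": ss_cpsg}
    return ss, errors


class TestMixedAnova:
    @pytest.mark.parametrize("n_per_group", [(4, 4), (3, 5), (2, 4, 3)])
    def test_matches_brute_force_oracle(self, n_per_group):
        rng = np.random.default_rng(sum(n_per_group))
        table = random_table(rng, n_per_group)
        result = mixed_anova(table).set_index("effect")
        ss, errors = anova_oracle(table)
        for effect, expected in ss.items():
            assert result.loc[effect, "ss_effect"] == pytest.approx(expected, rel=1e-8)
        assert result.loc["group", "ss_error"] == pytest.approx(errors["s(g)"], rel=1e-8)
        assert result.loc["cue", "ss_error"] == pytest.approx(errors["cs(g)"], rel=1e-8)
        assert result.loc["position", "ss_error"] == pytest.approx(errors["ps(g)"], rel=1e-8)
        assert result.loc["cue:position", "ss_error"] == pytest.approx(
            errors["cps(g)"], rel=1e-8
        )
        # generalized eta squared against the same oracle quantities
        denom_err = sum(errors.values())
        for effect, expected in ss.items():
            assert result.loc[effect, "ges"] == pytest.approx(
                expected / (expected + denom_err), rel=1e-8
            )

    def test_ss_conservation(self):
        rng = np.random.default_rng(42)
        table = random_table(rng, (5, 5))
        result = mixed_anova(table)
        _, errors = anova_oracle(table)
        total = result["ss_effect"].sum() + sum(errors.values())
        assert total == pytest.approx(anova_ss_total(table), rel=1e-8)

    def test_degrees_of_freedom_study_design(self):
        rng = np.random.default_rng(0)
        table = random_table(rng, (16, 16))
        result = mixed_anova(table).set_index("effect")
        assert tuple(result.loc["position", ["df_effect", "df_error"]]) == (1, 30)
        assert tuple(result.loc["cue", ["df_effect", "df_error"]]) == (2, 60)
        assert tuple(result.loc["group:cue:position", ["df_effect", "df_error"]]) == (2, 60)

    def test_constant_table_all_zero_ss(self):
        rng = np.random.default_rng(1)
        table = random_table(rng, (3, 3))
        table["mean_amplitude_uv"] = 2.5
        result = mixed_anova(table)
        assert np.allclose(result["ss_effect"], 0.0)
        assert result["F"].isna().all()  # flagged undefined, not a crash

    def test_ges_bounded_and_monotone_in_position_effect(self):
        previous = -1.0
        for magnitude in (0.0, 1.0, 2.5):
            rng = np.random.default_rng(7)  # same noise, growing effect
            effects = {
                (g, c, "syll2"): -magnitude for g in ("g0", "g1") for c in CUES
            }
            table = random_table(rng, (6, 6), effects)
            result = mixed_anova(table).set_index("effect")
            ges = result.loc["position", "ges"]
            assert 0.0 <= ges <= 1.0
            assert ges >= previous
            previous = ges

    def test_four_level_between_factor_supported(self):
        rng = np.random.default_rng(3)
        table = random_table(rng, (2, 4, 3, 5))
        result = mixed_anova(table).set_index("effect")
        assert result.loc["group", "df_effect"] == 3
        assert result.loc["group", "df_error"] == 10

    def test_missing_cell_rejected(self):
        rng = np.random.default_rng(4)
        table = random_table(rng, (3, 3)).iloc[:-1]
        with pytest.raises(DataError, match="unbalanced"):
            mixed_anova(table)


class TestTTests:
    def test_paired_hand_computed_example(self):
        table = random_table(np.random.default_rng(5), (4,))
        # overwrite so that the pitch syll1-syll2 difference is 1,2,3,4
        table["mean_amplitude_uv"] = 0.0
        for i, s in enumerate(sorted(table["subject"].unique())):
            mask = (
                (table["subject"] == s)
                & (table["cue"] == "pitch")
                & (table["position"] == "syll1")
            )
            table.loc[mask, "mean_amplitude_uv"] = float(i + 1)
        table.loc[table["group"] == "g0", "group"] = "g0"
        res = paired_contrast(table, position_difference_weights("pitch"))
        assert res.t == pytest.approx(3.873, abs=0.001)
        assert res.df == 3
        assert res.cohen_d == pytest.approx(2.5 / np.std([1, 2, 3, 4], ddof=1))

    def test_paired_identical_values_no_effect(self):
        table = random_table(np.random.default_rng(6), (4,))
        table["mean_amplitude_uv"] = 1.5
        res = paired_contrast(table, position_difference_weights("pitch"))
        assert res.t == 0.0 and res.p == 1.0

    def test_paired_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(7)
        table = random_table(rng, (6,))
        w = position_difference_weights("duration")
        res = paired_contrast(table, w)
        flipped = paired_contrast(table, {k: -v for k, v in w.items()})
        assert flipped.t == pytest.approx(-res.t)
        assert flipped.p == pytest.approx(res.p)

    def test_independent_hand_computed_example(self):
        res = independent_t(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
        assert res.t == pytest.approx(-3.674, abs=0.001)
        assert res.df == 4
        assert res.cohen_d == pytest.approx(-3.0)

    def test_independent_swap_antisymmetry(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=5), rng.normal(size=7)
        r1, r2 = independent_t(a, b), independent_t(b, a)
        assert r2.t == pytest.approx(-r1.t)
        assert r2.cohen_d == pytest.approx(-r1.cohen_d)

    def test_independent_equal_means_zero_t(self):
        res = independent_t(np.array([1.0, 2.0, 3.0]), np.array([3.0, 2.0, 1.0]))
        assert res.t == pytest.approx(0.0)

    def test_independent_zero_pooled_variance_rejected(self):
        with pytest.raises(DataError):
            independent_t(np.array([1.0, 1.0]), np.array([1.0, 1.0]))

    def test_groupwise_position_dfs(self):
        rng = np.random.default_rng(9)
        effects = {("g0", c, "syll2"): -2.0 for c in CUES}
        table = random_table(rng, (16, 16), effects)
        paired = groupwise_position_test(table, "g0", "paired")
        pooled = groupwise_position_test(table, "g0", "pooled")
        assert paired.df == 15
        assert pooled.df == 30
        assert paired.t > 0 and pooled.t > 0


class TestPower:
    def test_published_effect_size_gives_32_total(self):
        res = required_sample_size(1.033, alpha=0.05, power=0.80)
        assert res.n_per_group == 16
        assert res.n_total == 32
        assert res.achieved_power >= 0.80
        assert two_sample_power(1.033, 15) < 0.80  # minimality

    def test_medium_effect_gives_64_per_group(self):
        assert required_sample_size(0.5).n_per_group == 64

    def test_required_n_monotone_in_effect_size(self):
        sizes = [required_sample_size(d).n_per_group for d in (0.4, 0.6, 0.9, 1.3)]
        assert sizes == sorted(sizes, reverse=True)

    @pytest.mark.parametrize("d", [0.3, 0.8, 1.2])
    def test_matches_statsmodels_solver(self, d):
        """Independent oracle: continuous statsmodels solution, ceiled."""
        continuous = TTestIndPower().solve_power(
            effect_size=d, alpha=0.05, power=0.80, alternative="two-sided"
        )
        assert required_sample_size(d).n_per_group == int(np.ceil(continuous))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DataError):
            required_sample_size(0.0)
        with pytest.raises(DataError):
            required_sample_size(0.5, alpha=1.5)
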