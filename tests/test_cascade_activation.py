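import itertools

import numpy as np
import pytest

from tmeomix import synthetic_data as sd
from tmeomix.cascade_activation import (
    CascadeParams,
    categorize_expression,
    cross_condition_check,
    find_cascades,
    last_activated,
)
from tmeomix.io_formats import UsageError

from conftest import make_design, make_table

ALL_SEQUENCES = tuple(itertools.permutations(("E", "I", "K")))
SIX_GROUPS = {"EC": 2, "ET": 2, "IC": 2, "IT": 2, "KC": 2, "KT": 2}


def cascade_world(group_means, rng_seed=71, sd=0.0):
    rng = np.random.default_rng(rng_seed)
    design = make_design(SIX_GROUPS)
    molecules = sorted({m for m, _ in group_means}) or ["g0"]
    table = make_table(rng, molecules, design, sd=sd, group_means=group_means)
    return table, design


class TestFindCascades:
    def test_boundary_inclusive_step(self):
        # group means (1, 3, 5): both steps exactly 2 → up member
        table, design = cascade_world({("g", "ET"): 1, ("g", "IT"): 3, ("g", "KT"): 5})
        res = find_cascades(table, design, CascadeParams(step=2))
        assert res.transcripts(("E", "I", "K"), "up") == ["g"]

    def test_sub_threshold_first_step_excluded(self):
        table, design = cascade_world({("g", "ET"): 1, ("g", "IT"): 2, ("g", "KT"): 5})
        res = find_cascades(table, design, CascadeParams(step=2))
        assert res.transcripts(("E", "I", "K"), "up") == []

    def test_planted_cascades_recovered_exactly(self):
        cfg = sd.SimulationConfig(
            n_genes=150, n_mirnas=10, n_proteins=10, noise_sd=0.1,
            planted_cascades=[
                sd.PlantedCascade("Gene0100", ("E", "I", "K"), 3.0),
                sd.PlantedCascade("Gene0101", ("E", "K", "I"), 3.0),
            ],
            seed=73,
        )
        ds = sd.simulate(cfg)
        res = find_cascades(ds.mrna, ds.design, CascadeParams(step=2))
        assert res.transcripts(("E", "I", "K"), "up") == ["Gene0100"]
        assert res.transcripts(("E", "K", "I"), "up") == ["Gene0101"]
        assert res.transcripts(("I", "E", "K"), "up") == []
        for seq in ((("E", "I", "K")), ("E", "K", "I"), ("I", "E", "K")):
            assert res.transcripts(seq, "down") == []

    def test_reversal_duality(self):
        rng = np.random.default_rng(79)
        design = make_design(SIX_GROUPS)
        table = make_table(
            rng, [f"g{i}" for i in range(60)], design, sd=3.0  # wide spread
        )
        params = CascadeParams(step=1.0, sequences=ALL_SEQUENCES)
        res = find_cascades(table, design, params)
        for seq in ALL_SEQUENCES:
            rev = tuple(reversed(seq))
            assert res.transcripts(seq, "up") == res.transcripts(rev, "down")

    def test_zero_step_lists_are_supersets_of_positive_step(self):
        rng = np.random.default_rng(83)
        design = make_design(SIX_GROUPS)
        table = make_table(rng, [f"g{i}" for i in range(60)], design, sd=3.0)
        loose = find_cascades(table, design, CascadeParams(step=0.0))
        strict = find_cascades(table, design, CascadeParams(step=1.5))
        for key, members in strict.lists.items():
            assert set(members) <= set(loose.lists[key])

    def test_missing_group_is_named_in_error(self):
        design = make_design({"EC": 2, "ET": 2, "IC": 2, "IT": 2, "KC": 2})
        table = make_table(np.random.default_rng(0), ["g"], design)
        with pytest.raises(UsageError, match="KT"):
            find_cascades(table, design, CascadeParams())


class TestCrossConditionCheck:
    def test_planted_tme_cascades_flagged_true(self):
        cfg = sd.SimulationConfig(
            n_genes=100, n_mirnas=10, n_proteins=10, noise_sd=0.1,
            planted_cascades=[sd.PlantedCascade("Gene0050", ("E", "I", "K"), 3.0)],
            seed=89,
        )
        ds = sd.simulate(cfg)
        res = find_cascades(ds.mrna, ds.design, CascadeParams(step=2))
        flags = cross_condition_check(res, ds.mrna, ds.design)
        assert flags.loc["Gene0050"]

    def test_equal_conditions_fail_strict_inequality(self):
        design = make_design(SIX_GROUPS)
        import pandas as pd

        from tmeomix.io_formats import ExpressionTable

        frame = pd.DataFrame(
            [[5.0] * len(design.sample_ids)], index=["g"], columns=design.sample_ids
        )
        table = ExpressionTable(frame, "mrna")
        res = find_cascades(table, design, CascadeParams(step=0.0))
        flags = cross_condition_check(res, table, design)
        assert not flags.loc["g"]

    def test_flags_equal_brute_force_mean_comparison(self):
        rng = np.random.default_rng(97)
        design = make_design(SIX_GROUPS)
        table = make_table(rng, [f"g{i}" for i in range(40)], design, sd=3.0)
        res = find_cascades(table, design, CascadeParams(step=0.5))
        flags = cross_condition_check(res, table, design)
        t_cols = [s for s in table.sample_ids if design.group(s).endswith("T")]
        c_cols = [s for s in table.sample_ids if design.group(s).endswith("C")]
        for mol, flag in flags.items():
            expected = table.data.loc[mol, t_cols].mean() > table.data.loc[mol, c_cols].mean()
            assert flag == expected


class TestCategorizeExpression:
    def test_gene_at_matrix_maximum_is_high_everywhere(self):
        rng = np.random.default_rng(101)
        design = make_design(SIX_GROUPS)
        table = make_table(
            rng, ["top", "g1", "g2"], design, sd=0.1,
            group_means={("top", g): 50.0 for g in SIX_GROUPS},
        )
        profile = categorize_expression(table, design, {"top"}, "s")
        assert (profile.categories.loc["top"] == "high").all()

    def test_quantile_cutpoints_give_balanced_occupancy(self):
        rng = np.random.default_rng(103)
        design = make_design({g: 1 for g in SIX_GROUPS})  # group mean = value
        n = 2000
        import pandas as pd

        from tmeomix.io_formats import ExpressionTable

        vals = rng.uniform(0, 1, (n, len(design.sample_ids)))
        table = ExpressionTable(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(n)],
                         columns=design.sample_ids),
            "mrna",
        )
        profile = categorize_expression(table, design, {f"g{i}" for i in range(n)}, "all")
        frac = (profile.categories == "high").to_numpy().mean()
        assert abs(frac - 1 / 3) < 0.05

    def test_explicit_cutpoints_override_quantiles(self):
        rng = np.random.default_rng(107)
        design = make_design(SIX_GROUPS)
        table = make_table(rng, ["g"], design, baseline=8.0, sd=0.01)
        profile = categorize_expression(table, design, {"g"}, "s", cutpoints=(100.0, 200.0))
        assert (profile.categories.loc["g"] == "low").all()

    def test_absent_genes_reported_not_fatal(self):
        rng = np.random.default_rng(109)
        design = make_design(SIX_GROUPS)
        table = make_table(rng, ["g"], design)
        profile = categorize_expression(table, design, {"g", "ghost"}, "s")
        assert profile.absent == ["ghost"]


class TestLastActivated:
    def _profile(self, rng_seed, set_genes, group_means):
        rng = np.random.default_rng(rng_seed)
        design = make_design(SIX_GROUPS)
        filler = {(f"f{i}", g): v for i in range(20)
                  for g, v in zip(SIX_GROUPS, (2, 5, 8, 11, 14, 17))}
        table = make_table(
            rng, sorted(set_genes) + [f"f{i}" for i in range(20)], design, sd=0.05,
            group_means={**filler, **group_means},
        )
        return categorize_expression(table, design, set_genes, "s")

    def test_single_planted_switch_gene_detected(self):
        genes = {f"h{i}" for i in range(6)} | {"switch"}
        means = {(f"h{i}", g): 16.0 for i in range(6) for g in SIX_GROUPS}
        means.update({("switch", g): (3.0 if g.endswith("C") else 16.0) for g in SIX_GROUPS})
        profile = self._profile(113, genes, means)
        assert last_activated(profile) == ["switch"]

    def test_no_switch_when_all_genes_high_everywhere(self):
        genes = {f"h{i}" for i in range(5)}
        means = {(f"h{i}", g): 16.0 for i in range(5) for g in SIX_GROUPS}
        assert last_activated(self._profile(127, genes, means)) == []

    def test_mid_in_tme_is_not_a_switch(self):
        genes = {f"h{i}" for i in range(6)} | {"half"}
        means = {(f"h{i}", g): 16.0 for i in range(6) for g in SIX_GROUPS}
        means.update({("half", g): (3.0 if g.endswith("C") else 9.0) for g in SIX_GROUPS})
        assert last_activated(self._profile(131, genes, means)) == []

    def test_switch_suppressed_without_active_background(self):
        # fewer than half of the set high in both conditions → nothing reported
        genes = {"switch", "low1", "low2"}
        means = {("switch", g): (3.0 if g.endswith("C") else 16.0) for g in SIX_GROUPS}
        means.update({(l, g): 3.0 for l in ("low1", "low2") for g in SIX_GROUPS})
        assert last_activated(self._profile(137, genes, means)) == []

    def test_study_config_activation_set_recovers_focal_switch(self, study_ds):
        from tmeomix.io_formats import GeneSetCollection

        act = study_ds.truth.activation
        members = set(act.always_high) | set(act.switch)
        profile = categorize_expression(
            study_ds.mrna, study_ds.design, members, act.set_name
        )
        assert last_activated(profile) == sorted(act.switch)
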