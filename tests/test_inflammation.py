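import numpy as np
import pandas as pd
import pytest

from conftest import fisher_greater_oracle
from txaging.inflammation import (
    SignatureSet,
    adjust_signature_counts,
    aggregate_category_display,
    compute_signature_counts,
    derive_signature_set,
    profile_populations,
    signature_age_trajectory,
)
from txaging.simulate import (
    SimulationConfig,
    simulate_mixture_aging_study,
    simulate_reference_compendium,
)
from txaging.aging import compute_aging_profile


def profile_from_fc(fc_by_gene: dict, p: float = 0.01) -> pd.DataFrame:
    genes = list(fc_by_gene)
    fc = np.array([fc_by_gene[g] for g in genes], dtype=float)
    return pd.DataFrame({"fc": fc, "p": p, "slope": np.log2(fc)}, index=genes)


class TestDeriveSignature:
    def test_planted_signature_recovery(self):
        cfg = SimulationConfig(seed=6, n_genes=2000, signature_size=500, signature_delta=2.0, noise_sd=0.3)
        panel = simulate_reference_compendium(cfg)
        for pop in panel.populations:
            derived = derive_signature_set(panel, pop, n=500)
            planted = set(panel.truth_signatures[pop])
            assert len(set(derived.members) & planted) / len(planted) >= 0.95

    def test_no_signal_gives_empty_flagged_set(self, small_config):
        panel = simulate_reference_compendium(small_config)
        # zero noise, population columns identical to the baseline
        flat = panel.values.copy()
        exact = np.round(panel.baseline)  # exactly representable values
        for cols in panel.populations.values():
            for c in cols:
                flat[c] = exact
        for c in panel.reference_cols:
            flat[c] = exact
        panel.values = flat
        derived = derive_signature_set(panel, next(iter(panel.populations)))
        assert derived.members == [] and derived.truncated

    def test_default_size_is_500(self):
        import inspect

        sig = inspect.signature(derive_signature_set)
        assert sig.parameters["n"].default == 500

    def test_duplicate_members_rejected(self):
        with pytest.raises(ValueError):
            SignatureSet("p", "c", members=["g1", "g1"])


class TestSignatureCounts:
    def test_counting_rule(self):
        fc = {f"g{i}": (1.5 if i < 400 else 0.5) for i in range(500)}
        counts = compute_signature_counts(list(fc), profile_from_fc(fc))
        assert (counts.n1, counts.n2) == (400, 100)
        assert counts.p_hat == pytest.approx(0.8)

    def test_all_increased(self):
        fc = {f"g{i}": 1.2 for i in range(50)}
        counts = compute_signature_counts(list(fc), profile_from_fc(fc))
        assert counts.p_hat == 1.0

    def test_ties_excluded_and_missing_reported(self):
        fc = {"g1": 1.5, "g2": 1.0, "g3": 0.5}
        counts = compute_signature_counts(["g1", "g2", "g3", "g9"], profile_from_fc(fc))
        assert (counts.n1, counts.n2, counts.n_tied, counts.n_missing) == (1, 1, 1, 1)

    def test_mean_percent_change_recovers_planted_shift(self):
        # +10% planted shift on members, 5+5 samples, noise sd 0.2
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(seed=100 + seed, n_genes=600, signature_size=150, noise_sd=0.2)
            panel = simulate_reference_compendium(cfg)
            study, _ = simulate_mixture_aging_study(cfg, panel, targets={"cd4_t_cell": 0.10})
            prof = compute_aging_profile(study)
            counts = compute_signature_counts(panel.truth_signatures["cd4_t_cell"], prof)
            if 6 <= counts.mean_percent_change <= 14:
                hits += 1
        assert hits >= 18  # >= 90% of seeds


class TestExclusionAdjustment:
    def two_pop_fixture(self):
        # A's members all increased (p-hat 0.8 overall), B balanced
        fc = {}
        a_members = [f"a{i}" for i in range(100)]
        shared = [f"s{i}" for i in range(50)]
        b_only = [f"b{i}" for i in range(450)]
        for i, g in enumerate(a_members):
            fc[g] = 1.5 if i < 80 else 0.5
        for g in shared:
            fc[g] = 1.5
        for i, g in enumerate(b_only):
            fc[g] = 1.5 if i < 225 else 0.5
        sigs = [
            SignatureSet("A", "catA", a_members + shared),
            SignatureSet("B", "catB", b_only + shared),
        ]
        return sigs, profile_from_fc(fc)

    def test_dominated_population_loses_shared_members(self):
        sigs, profile = self.two_pop_fixture()
        out = adjust_signature_counts(sigs, profile)
        raw_a, adj_a, _ = out["A"]
        raw_b, adj_b, survivors_b = out["B"]
        assert raw_a.p_hat > raw_b.p_hat
        # A (larger ratio) untouched; B loses the 50 shared members
        assert (adj_a.n1, adj_a.n2) == (raw_a.n1, raw_a.n2)
        assert len(survivors_b) == 450
        assert (adj_b.n1, adj_b.n2) == (225, 225)

    def test_single_population_unchanged(self, toy_profile):
        sigs = [SignatureSet("A", "c", list(toy_profile.index[:5]))]
        raw, adj, _ = adjust_signature_counts(sigs, toy_profile)["A"]
        assert (raw.n1, raw.n2) == (adj.n1, adj.n2)

    def test_disjoint_signatures_unchanged(self, toy_profile):
        sigs = [
            SignatureSet("A", "c", list(toy_profile.index[:5])),
            SignatureSet("B", "c", list(toy_profile.index[5:])),
        ]
        out = adjust_signature_counts(sigs, toy_profile)
        for raw, adj, _ in out.values():
            assert (raw.n1, raw.n2) == (adj.n1, adj.n2)

    def test_exclusion_monotonicity_property(self, rng):
        genes = [f"g{i}" for i in range(400)]
        fc = dict(zip(genes, np.exp2(rng.normal(0, 0.5, 400))))
        profile = profile_from_fc(fc)
        sigs = [
            SignatureSet(f"P{k}", "c", list(rng.choice(genes, size=120, replace=False)))
            for k in range(4)
        ]
        out = adjust_signature_counts(sigs, profile)
        raws = {k: v[0] for k, v in out.items()}
        top = max(raws, key=lambda k: raws[k].p_hat)
        for k, (raw, adj, _) in out.items():
            assert adj.n1 + adj.n2 <= raw.n1 + raw.n2
            assert adj.n1 <= raw.n1 and adj.n2 <= raw.n2
        assert (out[top][1].n1, out[top][1].n2) == (raws[top].n1, raws[top].n2)


class TestAbundanceShiftScreen:
    def test_strong_bias_is_extreme_vs_hypergeometric_oracle(self, toy_profile):
        # n1 = 400 of 500 against a balanced 5000/5000 background
        p_oracle = fisher_greater_oracle(400, 100, 5000 - 400, 5000 - 100)
        assert p_oracle < 1e-10

    def test_balanced_counts_not_significant(self):
        genes = [f"g{i}" for i in range(2000)]
        fc = {g: (1.5 if i % 2 == 0 else 0.5) for i, g in enumerate(genes)}
        profile = profile_from_fc(fc)
        members = genes[:200]  # alternating -> 100 up, 100 down
        sigs = [SignatureSet("A", "c", members)]
        res = profile_populations(sigs, profile)
        assert res.loc["A", "p_raw"] >= 0.5
        assert not res.loc["A", "significant"]

    def test_exclusion_can_veto_raw_significance(self):
        # A dominates; B's bias comes only from members shared with A
        fc = {}
        a_only = [f"a{i}" for i in range(200)]
        shared = [f"s{i}" for i in range(120)]
        b_only = [f"b{i}" for i in range(200)]
        bg = [f"x{i}" for i in range(3000)]
        for g in a_only + shared:
            fc[g] = 1.5  # all up
        for i, g in enumerate(b_only):
            fc[g] = 1.5 if i < 100 else 0.5  # balanced
        for i, g in enumerate(bg):
            fc[g] = 1.5 if i < 1500 else 0.5
        profile = profile_from_fc(fc)
        sigs = [SignatureSet("A", "c", a_only + shared), SignatureSet("B", "c", b_only + shared)]
        res = profile_populations(sigs, profile)
        assert res.loc["A", "significant"] and res.loc["A", "direction"] == "increase"
        assert res.loc["B", "p_raw"] < 0.05  # raw counts look biased
        assert res.loc["B", "p_star"] > 0.05  # exclusion removes the shared bias
        assert not res.loc["B", "significant"]

    def test_inconsistent_background_rejected(self):
        from txaging.inflammation import _fisher_one_sided

        with pytest.raises(ValueError):
            _fisher_one_sided(10, 2, 5, 100, "greater")


class TestCategoryDisplay:
    @pytest.mark.parametrize(
        "p_hats,expected",
        [((0.6, 0.7, 0.4), 0.7), ((0.3, 0.45, 0.55), 0.3), ((0.8,), 0.8)],
    )
    def test_median_rule(self, p_hats, expected):
        frame = pd.DataFrame(
            {
                "p_hat": p_hats,
                "significant": [False] * len(p_hats),
                "direction": ["none"] * len(p_hats),
            },
            index=[f"P{i}" for i in range(len(p_hats))],
        )
        cell = aggregate_category_display(frame)
        assert cell["displayed_proportion"] == pytest.approx(expected)
        assert cell["marker"] == "none"

    def test_marker_follows_displayed_population(self):
        frame = pd.DataFrame(
            {"p_hat": [0.9, 0.6], "significant": [True, False], "direction": ["increase", "none"]},
            index=["P0", "P1"],
        )
        assert aggregate_category_display(frame)["marker"] == "increase"


class TestTrajectory:
    def test_youngest_group_ratio_is_one(self, small_config):
        panel = simulate_reference_compendium(small_config)
        study, _ = simulate_mixture_aging_study(small_config, panel)
        traj = signature_age_trajectory(panel.truth_signatures["cd4_t_cell"], study, n_bins=2)
        assert traj["median_ratio"].iloc[0] == pytest.approx(1.0)

    def test_null_medians_near_unity(self):
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=300 + seed, n_genes=400, signature_size=100, noise_sd=0.1, n_per_group=5)
            panel = simulate_reference_compendium(cfg)
            study, _ = simulate_mixture_aging_study(cfg, panel, targets={"cd4_t_cell": 0.0})
            traj = signature_age_trajectory(panel.truth_signatures["cd4_t_cell"], study, n_bins=2)
            if traj["median_ratio"].between(0.95, 1.05).all():
                hits += 1
        assert hits >= 9

    def test_planted_increase_gives_nondecreasing_medians(self):
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=400 + seed, n_genes=400, signature_size=100, noise_sd=0.2)
            panel = simulate_reference_compendium(cfg)
            study, _ = simulate_mixture_aging_study(cfg, panel, targets={"cd4_t_cell": 0.5})
            traj = signature_age_trajectory(panel.truth_signatures["cd4_t_cell"], study, n_bins=2)
            if traj["median_ratio"].is_monotonic_increasing:
                hits += 1
        assert hits >= 9
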