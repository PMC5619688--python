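import numpy as np
import pandas as pd
import pytest
from types import SimpleNamespace

from mixt import (
    background_distribution,
    mixt_statistic,
    module_overlap,
    run_ssmixt,
)
from mixt.network import ModuleSet
from mixt.ranksum import compute_ranksum
from mixt.synthetic import interaction_power_config, generate


def module_set(tissue, mapping):
    genes, labels = [], []
    for label, gs in mapping.items():
        genes += list(gs)
        labels += [label] * len(gs)
    return ModuleSet(tissue=tissue,
                     assignment=pd.Series(labels, index=pd.Index(genes, name="gene")))


def rs(vals, name="rs"):
    return pd.Series(np.asarray(vals, dtype=float),
                     index=[f"P{i}" for i in range(len(vals))], name=name)


class TestModuleOverlap:
    def test_disjoint_modules_p_one(self):
        universe = [f"G{i}" for i in range(20)]
        mt = module_set("tumor", {"m1": universe[:5]})
        mb = module_set("blood", {"m1": universe[5:10]})
        out = module_overlap(mt, mb, universe)
        assert out.iloc[0].p == pytest.approx(1.0)
        assert out.iloc[0].n_overlap == 0

    def test_identical_modules_exact_tail(self):
        universe = [f"G{i}" for i in range(10)]
        mt = module_set("tumor", {"m1": universe[:3]})
        mb = module_set("blood", {"m1": universe[:3]})
        out = module_overlap(mt, mb, universe)
        assert out.iloc[0].p == pytest.approx(1 / 120)  # 1 / C(10,3)

    def test_grey_excluded_and_universe_restriction(self):
        universe = [f"G{i}" for i in range(10)]
        mt = module_set("tumor", {"m1": universe[:3], "grey": universe[3:6]})
        mb = module_set("blood", {"m1": universe[:3] + ["OFF_UNIVERSE"]})
        out = module_overlap(mt, mb, universe)
        assert len(out) == 1  # grey never tested
        assert out.iloc[0].n_b == 3  # off-universe gene discarded

    def test_empty_universe_error(self):
        mt = module_set("tumor", {"m1": ["a"]})
        with pytest.raises(ValueError, match="universe"):
            module_overlap(mt, mt, [])

    def test_mirrored_worked_example_significant(self):
        """Modules of 86 and 97 genes sharing 50 in a 16,782-gene universe
        are far beyond the fdr<0.01 overlap bound."""
        universe = [f"G{i}" for i in range(16_782)]
        shared = universe[:50]
        mt = module_set("tumor", {"darkturquoise": shared + universe[50:97]})
        mb = module_set("blood", {"darkturquoise": shared + universe[100:136]})
        out = module_overlap(mt, mb, universe)
        assert out.iloc[0].n_a == 97 and out.iloc[0].n_b == 86
        assert out.iloc[0].p <= 0.01
        assert bool(out.iloc[0].significant)


class TestMixtStatistic:
    def test_identical_ranksums_floor_p(self):
        x = rs(np.arange(30.0))
        r, p, direction = mixt_statistic(x, x, B=500, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 501)
        assert direction == "positive"

    def test_tissue_swap_symmetry(self, rng):
        a, b = rs(rng.normal(size=40)), rs(rng.normal(size=40))
        r_ab, _, _ = mixt_statistic(a, b, B=200, seed=1)
        r_ba, _, _ = mixt_statistic(b, a, B=200, seed=1)
        assert abs(r_ab) == pytest.approx(abs(r_ba), abs=1e-12)

    def test_fixed_seed_reproducible_and_B_stable(self, rng):
        a, b = rs(rng.normal(size=50)), rs(rng.normal(size=50))
        p1 = mixt_statistic(a, b, B=2000, seed=3)[1]
        assert mixt_statistic(a, b, B=2000, seed=3)[1] == p1
        p2 = mixt_statistic(a, b, B=4000, seed=4)[1]
        assert abs(p1 - p2) < 2 / 2000 + 2 / 4000 + 0.01

    def test_null_calibration_at_5pct(self, rng):
        hits = 0
        n_reps = 2000
        for i in range(n_reps):
            a, b = rs(rng.normal(size=30)), rs(rng.normal(size=30))
            if mixt_statistic(a, b, B=199, seed=i)[1] < 0.05:
                hits += 1
        assert 0.03 <= hits / n_reps <= 0.07

    def test_constant_ranksum_error(self):
        with pytest.raises(ValueError, match="constant"):
            mixt_statistic(rs(np.ones(10)), rs(np.arange(10.0)), B=100)

    def test_negative_direction(self):
        x = rs(np.arange(30.0))
        r, p, direction = mixt_statistic(x, rs(-np.arange(30.0)), B=500, seed=0)
        assert r == pytest.approx(-1.0)
        assert direction == "negative"


def true_profiles(cohort, truth):
    out = {}
    for tissue in ("tumor", "blood"):
        mem = truth.membership[tissue]
        expr = cohort.expr(tissue)
        out[tissue] = {
            m: SimpleNamespace(ranksum=compute_ranksum(
                expr, list(mem.index[mem == m]), cohort.patients))
            for m in sorted(set(mem.values) - {"grey"})
        }
    return out


class TestRunSsmixt:
    def test_planted_interaction_found_only_in_its_stratum(self):
        cfg = interaction_power_config(seed=123)
        cohort, truth = generate(cfg)
        profiles = true_profiles(cohort, truth)
        table, _ = run_ssmixt(profiles["tumor"], profiles["blood"],
                              cohort.clinical, ["pam50"], B=1999, master_seed=9)
        planted = table[(table.tumor_module == "turquoise")
                        & (table.blood_module == "blue")]
        by_stratum = planted.set_index("stratum")
        assert by_stratum.loc["basal"].p_emp < 0.005
        assert by_stratum.loc["lumA"].p_emp >= 0.005
        assert by_stratum.loc["lumB"].p_emp >= 0.005

    def test_small_stratum_skipped_and_logged(self):
        cfg = interaction_power_config(seed=5)
        cfg.schemes["pam50"] = {"basal": 40, "lumA": 75, "tiny": 5}
        cfg.interactions = []
        cohort, truth = generate(cfg)
        profiles = true_profiles(cohort, truth)
        table, skipped = run_ssmixt(profiles["tumor"], profiles["blood"],
                                    cohort.clinical, ["pam50"], B=199, master_seed=1)
        assert "tiny" not in set(table.stratum)
        assert any("tiny" in msg for msg in skipped)

    def test_no_schemes_error(self):
        with pytest.raises(ValueError, match="scheme"):
            run_ssmixt({}, {}, None, [])

    def test_interaction_table_schema(self):
        cfg = interaction_power_config(seed=77)
        cohort, truth = generate(cfg)
        profiles = true_profiles(cohort, truth)
        table, _ = run_ssmixt(profiles["tumor"], profiles["blood"],
                              cohort.clinical, ["pam50"], B=199, master_seed=2)
        assert {"scheme", "stratum", "tumor_module", "blood_module", "n", "r",
                "p_emp", "direction", "significant", "B", "seed"} <= set(table.columns)
        assert (table.p_emp >= 1 / 200).all() and (table.p_emp <= 1).all()
        assert table.r.between(-1, 1).all()


class TestBackgroundDistribution:
    def _profiles(self, rng, n_mod=4, n=50):
        return {f"m{i}": SimpleNamespace(ranksum=rs(rng.normal(size=n)))
                for i in range(n_mod)}

    def test_all_pairs_returned(self, rng):
        pt = self._profiles(rng, 2)
        pb = self._profiles(rng, 2)
        bg = background_distribution(pt, pb)
        assert len(bg["pairs"]) == 4
        assert bg["lower"] <= bg["upper"]

    def test_identical_modules_degenerate_flagged(self):
        x = rs(np.arange(20.0))
        pt = {"a": SimpleNamespace(ranksum=x), "b": SimpleNamespace(ranksum=x)}
        bg = background_distribution(pt, pt)
        assert bg["degenerate"]
        assert np.allclose(bg["pairs"].r, 1.0)

    def test_null_bounds_roughly_symmetric(self, rng):
        pt = self._profiles(rng, 8, n=100)
        pb = self._profiles(rng, 8, n=100)
        bg = background_distribution(pt, pb)
        assert abs(bg["lower"] + bg["upper"]) < 0.25
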