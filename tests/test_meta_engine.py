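import math
import shutil
import subprocess

import numpy as np
import pytest

from metameta import (
    DomainError,
    GroupSummary,
    effect_from_p_n,
    forest_data,
    meta_meta,
    pool_fixed,
    pool_random_dl,
)
from metameta.effects import EffectEstimate


def _dl_oracle(y, se):
    """Step-by-step DerSimonian-Laird arithmetic, independent of the engine."""
    y, se = np.asarray(y, float), np.asarray(se, float)
    w = 1 / se**2
    ybar = (w * y).sum() / w.sum()
    Q = (w * (y - ybar) ** 2).sum()
    df = len(y) - 1
    C = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (Q - df) / C) if len(y) > 1 else 0.0
    ws = 1 / (se**2 + tau2)
    pooled = (ws * y).sum() / ws.sum()
    return pooled, 1 / math.sqrt(ws.sum()), Q, tau2


def _random_instances(rng, n_instances, k_max=6):
    for _ in range(n_instances):
        k = int(rng.integers(1, k_max + 1))
        y = rng.normal(0.02, 0.05, k)
        se = rng.uniform(0.005, 0.2, k)
        yield [EffectEstimate(fisher_z=float(a), se=float(b)) for a, b in zip(y, se)]


class TestPoolFixed:
    def test_single_estimate_identity(self):
        e = effect_from_p_n(1e-9, 5000)
        r = pool_fixed([e])
        assert r.pooled_z == pytest.approx(e.fisher_z, abs=1e-15)
        assert r.se == pytest.approx(e.se, abs=1e-15)

    def test_three_identical_units(self):
        es = [EffectEstimate(fisher_z=0.1, se=0.1)] * 3
        r = pool_fixed(es)
        assert r.pooled_z == pytest.approx(0.1)
        assert r.se == pytest.approx(0.1 / math.sqrt(3))

    def test_matches_closed_form_oracle(self, rng):
        for es in _random_instances(rng, 50):
            r = pool_fixed(es)
            w = np.array([1 / e.se**2 for e in es])
            y = np.array([e.fisher_z for e in es])
            assert r.pooled_z == pytest.approx((w * y).sum() / w.sum(), abs=1e-12)
            assert r.se == pytest.approx(1 / math.sqrt(w.sum()), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            pool_fixed([])


class TestPoolRandomDL:
    def test_single_study_returns_unit(self):
        r = pool_random_dl([effect_from_p_n(2e-8, 14_754, "Meta3")])
        assert r.pooled_z == pytest.approx(0.046, abs=5e-4)
        assert r.ci_lower == pytest.approx(0.030, abs=5e-4)
        assert r.ci_upper == pytest.approx(0.062, abs=5e-4)
        assert r.tau2 == 0.0 and r.K == 1 and r.df == 0 and r.I2 == 0.0

    def test_homogeneous_truncates_to_fixed(self, rng):
        es = [EffectEstimate(fisher_z=0.05, se=float(s)) for s in rng.uniform(0.01, 0.1, 5)]
        fixed, random = pool_fixed(es), pool_random_dl(es)
        assert random.tau2 == 0.0
        assert random.pooled_z == fixed.pooled_z  # bit-for-bit
        assert random.se == fixed.se

    def test_matches_stepwise_oracle(self, rng):
        for es in _random_instances(rng, 100):
            r = pool_random_dl(es)
            pooled, se, Q, tau2 = _dl_oracle([e.fisher_z for e in es], [e.se for e in es])
            assert r.pooled_z == pytest.approx(pooled, abs=1e-10)
            assert r.se == pytest.approx(se, abs=1e-10)
            assert r.Q == pytest.approx(Q, abs=1e-10)
            assert r.tau2 == pytest.approx(tau2, abs=1e-10)

    def test_pooled_in_convex_hull_and_weights_sum(self, rng):
        for es in _random_instances(rng, 30):
            r = pool_random_dl(es)
            ys = [e.fisher_z for e in es]
            assert min(ys) - 1e-12 <= r.pooled_z <= max(ys) + 1e-12
            assert sum(w for _, w in r.weights) == pytest.approx(100.0, abs=1e-6)

    def test_permutation_invariance(self, rng):
        es = list(_random_instances(rng, 1, k_max=6))[0]
        es = [EffectEstimate(fisher_z=e.fisher_z, se=e.se, source_id=f"s{i}") for i, e in enumerate(es)]
        base = pool_random_dl(es)
        shuffled = pool_random_dl(es[::-1])
        assert shuffled.pooled_z == pytest.approx(base.pooled_z, abs=1e-14)
        assert dict(shuffled.weights) == pytest.approx(dict(base.weights), abs=1e-10)

    def test_duplicating_pooled_summary_is_a_fixed_point(self, rng):
        es = [EffectEstimate(fisher_z=0.05, se=0.05), EffectEstimate(fisher_z=0.05, se=0.08)]
        r = pool_random_dl(es)
        assert r.tau2 == 0.0
        r2 = pool_random_dl(es + [EffectEstimate(fisher_z=r.pooled_z, se=r.se)])
        assert abs(r2.pooled_z - r.pooled_z) < 1e-12

    def test_agrees_with_metafor(self, pseudo_studies):
        """Independent R oracle (metafor rma, method=DL) on the printed groups."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        yi = ",".join(f"{e.fisher_z:.10f}" for e in pseudo_studies)
        sei = ",".join(f"{e.se:.10f}" for e in pseudo_studies)
        script = (
            'suppressMessages(library(metafor));'
            f'f<-rma(yi=c({yi}),sei=c({sei}),method="DL");'
            'cat(sprintf("%.10f %.10f %.10f", coef(f), f$se, f$tau2))'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        pooled, se, tau2 = map(float, out.stdout.split())
        r = pool_random_dl(pseudo_studies)
        assert r.pooled_z == pytest.approx(pooled, abs=1e-8)
        assert r.se == pytest.approx(se, abs=1e-8)
        assert r.tau2 == pytest.approx(tau2, abs=1e-10)


class TestMetaMeta:
    def test_printed_second_level_summary(self, printed_groups):
        r = meta_meta(printed_groups)
        assert r.pooled_z == pytest.approx(0.012, abs=0.002)
        assert round(r.ci_lower, 3) == 0.004
        assert r.mode == "pseudo_study"

    def test_single_group_equals_conversion(self):
        g = GroupSummary(label="only", p_value=1e-6, total_n=10_000)
        r = meta_meta([g])
        e = effect_from_p_n(1e-6, 10_000)
        assert r.pooled_z == pytest.approx(e.fisher_z, abs=1e-15)

    def test_two_identical_groups_shrink_se(self):
        g = GroupSummary(label="a", p_value=1e-6, total_n=10_000)
        h = GroupSummary(label="b", p_value=1e-6, total_n=10_000)
        r = meta_meta([g, h])
        e = effect_from_p_n(1e-6, 10_000)
        assert r.tau2 == 0.0
        assert r.pooled_z == pytest.approx(e.fisher_z, abs=1e-14)
        assert r.se == pytest.approx(e.se / math.sqrt(2), abs=1e-14)

    def test_pooled_estimates_mode_is_the_rejected_alternative(self, printed_groups):
        """Pooling the printed group (z, se) pairs directly gives ~0.031, not 0.012."""
        groups = [
            GroupSummary(label="Meta1", p_value=6.5e-8, total_n=1_190_454, pooled_z=0.028, se=(0.039 - 0.018) / (2 * 1.959964)),
            GroupSummary(label="Meta2", p_value=1.48e-5, total_n=568_944, pooled_z=0.023, se=(0.034 - 0.013) / (2 * 1.959964)),
            GroupSummary(label="Meta3", p_value=2e-8, total_n=14_754, pooled_z=0.046, se=(0.062 - 0.030) / (2 * 1.959964)),
        ]
        r = meta_meta(groups, mode="pooled_estimates")
        assert r.pooled_z == pytest.approx(0.031, abs=0.004)
        assert abs(r.pooled_z - 0.012) > 0.01

    def test_missing_total_n_rejected(self):
        with pytest.raises(DomainError):
            meta_meta([GroupSummary(label="g", p_value=0.01)])


class TestForestData:
    def test_printed_three_group_weights(self, printed_groups, pseudo_studies):
        r = meta_meta(printed_groups)
        table = forest_data(r, pseudo_studies)
        w = dict(zip(table.label, table.weight_pct))
        assert abs(w["Meta1"] - w["Meta2"]) < 5.0
        assert w["Meta3"] == min(w["Meta1"], w["Meta2"], w["Meta3"])
        units = table[~table.is_summary]
        assert units.weight_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_single_unit_full_weight(self):
        e = effect_from_p_n(1e-9, 5000, "only")
        table = forest_data(pool_random_dl([e]), [e])
        assert table.weight_pct.iloc[0] == pytest.approx(100.0)

    def test_equal_se_triple_equal_weights(self):
        es = [EffectEstimate(fisher_z=0.1, se=0.1, source_id=s) for s in "abc"]
        table = forest_data(pool_random_dl(es), es)
        units = table[~table.is_summary]
        assert list(units.weight_pct.round(2)) == [33.33, 33.33, 33.33]
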