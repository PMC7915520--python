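import numpy as np
import pandas as pd
import pytest

from plastiqtl import qtl
from plastiqtl.linkage import ril_r_from_cm
from plastiqtl.model import P1, P2
from plastiqtl.simulate import (SimConfig, simulate_map_and_genotypes,
                                dosage_matrix)


@pytest.fixture(scope="module")
def scan_setup():
    """One 100 cM chromosome, 200 lines, markers every 5 cM."""
    cfg = SimConfig(n_lines=200, n_chromosomes=1, chrom_lengths_cM=[100.0],
                    chrom_names=["1A"], marker_spacing_cM=5.0, seed=31)
    mp, geno = simulate_map_and_genotypes(cfg)
    probs = qtl.genotype_probabilities(mp, geno, step_cM=1.0)
    return mp, geno, probs


def _trait_from_marker(geno, marker, effect, noise_sd, seed=0):
    rng = np.random.default_rng(seed)
    d = dosage_matrix(geno)[marker]
    return pd.Series(effect * d + rng.normal(0, noise_sd, len(d)),
                     index=geno.index)


class TestGenotypeProbabilities:
    def test_dosage_at_marker_equals_call(self, scan_setup):
        mp, geno, probs = scan_setup
        d = dosage_matrix(geno)
        for marker, cm in zip(mp["marker"][:5], mp["cM"][:5]):
            col = np.flatnonzero(np.isclose(probs.positions["cM"], cm))[0]
            assert np.allclose(probs.dosage[:, col], d[marker])

    def test_midpoint_between_equal_flanks_closed_form(self):
        geno = pd.DataFrame({"m1": ["B"] * 4, "m2": ["B"] * 4},
                            index=list("abcd"))
        mp = pd.DataFrame({"marker": ["m1", "m2"], "chrom": "1A",
                           "cM": [0.0, 10.0]})
        probs = qtl.genotype_probabilities(mp, geno, step_cM=5.0)
        col = np.flatnonzero(np.isclose(probs.positions["cM"], 5.0))[0]
        R = ril_r_from_cm(5.0)
        expected = 2 * (1 - R) ** 2 / ((1 - R) ** 2 + R ** 2) - 1
        assert np.allclose(probs.dosage[:, col], expected)
        assert expected > 0.9

    def test_opposite_flanks_cross_zero(self):
        geno = pd.DataFrame({"m1": ["B"], "m2": ["A"]}, index=["a"])
        mp = pd.DataFrame({"marker": ["m1", "m2"], "chrom": "1A",
                           "cM": [0.0, 20.0]})
        probs = qtl.genotype_probabilities(mp, geno, step_cM=1.0)
        dos = probs.dosage[0]
        cm = probs.positions["cM"].to_numpy()
        assert dos[np.isclose(cm, 0.0)][0] == 1.0
        assert dos[np.isclose(cm, 20.0)][0] == -1.0
        # symmetric interval: sign change at the midpoint
        assert np.isclose(dos[np.isclose(cm, 10.0)][0], 0.0, atol=1e-12)
        assert (np.diff(dos) < 0).all()

    def test_missing_line_uninformative(self):
        geno = pd.DataFrame({"m1": [np.nan], "m2": [np.nan]}, index=["a"])
        mp = pd.DataFrame({"marker": ["m1", "m2"], "chrom": "1A",
                           "cM": [0.0, 20.0]})
        probs = qtl.genotype_probabilities(mp, geno, step_cM=5.0)
        assert np.allclose(probs.dosage, 0.0)

    def test_bounded(self, scan_setup):
        _, _, probs = scan_setup
        assert probs.dosage.min() >= -1.0 and probs.dosage.max() <= 1.0


class TestScanSingle:
    def test_lod_matches_regression_oracle_everywhere(self, scan_setup):
        mp, geno, probs = scan_setup
        y = _trait_from_marker(geno, "1A_M0011", 1.0, 2.0, seed=1)
        prof = qtl.scan_single(probs, y, trait="T")
        n = prof.n
        for j in range(0, probs.dosage.shape[1], 7):
            x = probs.dosage[:, j]
            X = np.column_stack([np.ones(n), x])
            beta, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
            sse1 = float(((y.to_numpy() - X @ beta) ** 2).sum())
            sse0 = float(((y - y.mean()) ** 2).sum())
            lod = (n / 2) * np.log10(sse0 / sse1)
            assert np.isclose(prof.table["lod"].iloc[j], lod, atol=1e-8)

    def test_perfect_signal_capped(self, scan_setup):
        mp, geno, probs = scan_setup
        y = _trait_from_marker(geno, "1A_M0011", 1.0, 0.0)
        prof = qtl.scan_single(probs, y, trait="T")
        effs = qtl.effect_summary(prof, threshold=3.0)
        assert len(effs) == 1
        assert effs[0].lod == qtl.DEFAULT_LOD_CEILING
        assert np.isclose(effs[0].pev, 1.0)
        assert np.isclose(effs[0].pos_cM, 50.0)   # marker 11 sits at 50 cM
        assert np.isclose(effs[0].additive, 1.0)

    def test_constant_trait_no_effect(self, scan_setup):
        *_, probs = scan_setup
        y = pd.Series(5.0, index=probs.lines)
        prof = qtl.scan_single(probs, y)
        assert prof.max_lod == 0.0
        assert qtl.effect_summary(prof, threshold=0.0) == []

    def test_expected_lod_magnitude(self, scan_setup):
        # PEV ~= 0.2 -> LOD at the true position ~ -(n/2) log10(0.8)
        mp, geno, probs = scan_setup
        y = _trait_from_marker(geno, "1A_M0011", 1.0, 2.0, seed=2)
        prof = qtl.scan_single(probs, y)
        col = np.flatnonzero(np.isclose(probs.positions["cM"], 50.0))[0]
        expected = -(prof.n / 2) * np.log10(1 - 0.2)
        assert abs(prof.table["lod"].iloc[col] - expected) < 0.5 * expected


class TestEffectSummary:
    def _profile(self, lod, cm=None):
        cm = np.arange(len(lod), dtype=float) if cm is None else cm
        table = pd.DataFrame({"chrom": "1A", "cM": cm, "lod": lod,
                              "r2": 0.1, "additive": 0.5})
        return qtl.ScanProfile("T", "obs", "WW", "single", table, 100)

    def test_symmetric_profile_symmetric_interval(self):
        # floor is peak - 1.5 = 3.5: the flanking 4.0 points are included
        lod = np.array([1.0, 4.0, 5.0, 4.0, 1.0])
        effs = qtl.effect_summary(self._profile(lod), threshold=2.0)
        assert effs[0].support == (1.0, 3.0)
        assert effs[0].pos_cM == 2.0

    def test_monotone_profile_clipped_at_end(self):
        lod = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        effs = qtl.effect_summary(self._profile(lod), threshold=2.0)
        assert effs[0].support == (3.0, 4.0)   # clipped at the chromosome end
        assert effs[0].pos_cM == 4.0

    def test_itv_parent_from_sign(self):
        lod = np.array([0.0, 5.0, 0.0])
        prof = self._profile(lod)
        prof.table["additive"] = -0.4
        effs = qtl.effect_summary(prof, threshold=2.0)
        assert effs[0].itv == P1
        prof.table["additive"] = 0.4
        assert qtl.effect_summary(prof, threshold=2.0)[0].itv == P2


class TestPermutationThreshold:
    def test_deterministic_under_seed(self, scan_setup):
        *_, probs = scan_setup
        rng = np.random.default_rng(3)
        y = pd.Series(rng.normal(0, 1, len(probs.lines)), index=probs.lines)
        t1 = qtl.permutation_threshold(probs, y, n_perm=100, seed=7)
        t2 = qtl.permutation_threshold(probs, y, n_perm=100, seed=7)
        assert t1.lod_threshold == t2.lod_threshold
        assert np.array_equal(t1.sample, t2.sample)

    def test_alpha_one_gives_minimum(self, scan_setup):
        *_, probs = scan_setup
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(0, 1, len(probs.lines)), index=probs.lines)
        thr = qtl.permutation_threshold(probs, y, n_perm=100, alpha=1.0,
                                        seed=1)
        assert np.isclose(thr.lod_threshold, thr.sample.min())

    def test_null_trait_rarely_exceeds_threshold(self, scan_setup):
        *_, probs = scan_setup
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(0, 1, len(probs.lines)), index=probs.lines)
        thr = qtl.permutation_threshold(probs, y, n_perm=300, alpha=0.05,
                                        seed=2)
        hits = 0
        for _ in range(60):
            ynull = pd.Series(rng.normal(0, 1, len(probs.lines)),
                              index=probs.lines)
            prof = qtl.scan_single(probs, ynull)
            hits += prof.max_lod > thr.lod_threshold
        # 95% binomial interval around 0.05 at n=60 is ~[0, 9]
        assert hits <= 9


class TestTwoLinked:
    def test_two_qtls_recovered(self):
        cfg = SimConfig(n_lines=500, n_chromosomes=1, chrom_lengths_cM=[80.0],
                        chrom_names=["1A"], marker_spacing_cM=5.0, seed=32)
        mp, geno = simulate_map_and_genotypes(cfg)
        probs = qtl.genotype_probabilities(mp, geno, step_cM=1.0)
        d = dosage_matrix(geno)
        rng = np.random.default_rng(0)
        # opposite-sign QTLs at 20 and 60 cM
        y = pd.Series(1.0 * d["1A_M0005"] - 1.0 * d["1A_M0013"]
                      + rng.normal(0, 1, len(d)), index=geno.index)
        res = qtl.scan_two_linked(probs, y, "1A")
        assert res.retained
        assert abs(res.positions[0] - 20.0) <= 5.0
        assert abs(res.positions[1] - 60.0) <= 5.0
        assert res.additive[0] > 0 and res.additive[1] < 0

    def test_single_qtl_not_retained(self, scan_setup):
        mp, geno, probs = scan_setup
        y = _trait_from_marker(geno, "1A_M0011", 1.0, 1.0, seed=6)
        res = qtl.scan_two_linked(probs, y, "1A")
        assert not res.retained

    def test_null_not_retained(self, scan_setup):
        *_, probs = scan_setup
        rng = np.random.default_rng(7)
        y = pd.Series(rng.normal(0, 1, len(probs.lines)), index=probs.lines)
        assert not qtl.scan_two_linked(probs, y, "1A").retained

    def test_short_chromosome_falls_back(self):
        geno = pd.DataFrame({"m1": ["A", "B"] * 10, "m2": ["A", "B"] * 10},
                            index=[f"L{i}" for i in range(20)])
        mp = pd.DataFrame({"marker": ["m1", "m2"], "chrom": "1A",
                           "cM": [0.0, 5.0]})
        probs = qtl.genotype_probabilities(mp, geno, step_cM=1.0)
        y = pd.Series(np.arange(20.0), index=geno.index)
        assert not qtl.scan_two_linked(probs, y, "1A").retained


class TestJointEnvironments:
    def test_equal_effects_lod_additivity(self, scan_setup):
        mp, geno, probs = scan_setup
        y_ww = _trait_from_marker(geno, "1A_M0011", 1.0, 1.5, seed=8)
        y_wl = _trait_from_marker(geno, "1A_M0011", 1.0, 1.5, seed=9)
        res = qtl.scan_joint_environments(probs, y_ww, y_wl, trait="T")
        peak = int(res.profile.table["lod"].idxmax())
        joint = res.profile.table["lod"].iloc[peak]
        per_env_sum = sum(p.table["lod"].iloc[peak]
                          for p in res.per_env.values())
        assert np.isclose(joint, per_env_sum, atol=1e-9)
        assert res.specificity == "both"

    def test_wl_only_effect_tagged(self, scan_setup):
        mp, geno, probs = scan_setup
        rng = np.random.default_rng(10)
        y_ww = pd.Series(rng.normal(0, 1, len(probs.lines)),
                         index=probs.lines)
        y_wl = _trait_from_marker(geno, "1A_M0011", 1.0, 1.0, seed=11)
        res = qtl.scan_joint_environments(probs, y_ww, y_wl, trait="T")
        assert res.specificity == "WL-specific"

    def test_missing_environment_degrades(self, scan_setup):
        mp, geno, probs = scan_setup
        y_wl = _trait_from_marker(geno, "1A_M0011", 1.0, 1.0, seed=12)
        res = qtl.scan_joint_environments(probs, None, y_wl, trait="T")
        assert res.profile.model == "joint-env-degraded"


class TestMIM:
    def _two_chrom_setup(self, seed=33):
        cfg = SimConfig(n_lines=300, n_chromosomes=2,
                        chrom_lengths_cM=[80.0, 80.0],
                        chrom_names=["1A", "2A"], marker_spacing_cM=5.0,
                        seed=seed)
        mp, geno = simulate_map_and_genotypes(cfg)
        probs = qtl.genotype_probabilities(mp, geno, step_cM=1.0)
        d = dosage_matrix(geno)
        rng = np.random.default_rng(0)
        y = pd.Series(0.8 * d["1A_M0009"] + 0.8 * d["2A_M0009"]
                      + rng.normal(0, 1.3, len(d)), index=geno.index)
        return probs, y

    def test_refinement_raises_lod_for_unlinked_qtls(self):
        probs, y = self._two_chrom_setup()
        prof = qtl.scan_single(probs, y)
        effs = qtl.effect_summary(prof, threshold=3.0)
        assert len(effs) == 2
        refined = qtl.mim_refine(effs, probs, y)
        for old, new in zip(effs, refined):
            assert new.model == "MIM-adjusted"
            assert new.lod > old.lod   # residual variance reduced

    def test_single_qtl_noop(self, scan_setup):
        mp, geno, probs = scan_setup
        y = _trait_from_marker(geno, "1A_M0011", 1.0, 1.0, seed=13)
        prof = qtl.scan_single(probs, y)
        effs = qtl.effect_summary(prof, threshold=3.0)
        refined = qtl.mim_refine(effs, probs, y)
        # single-chromosome genome: no background covariates, same result
        assert np.isclose(refined[0].lod, effs[0].lod, atol=1e-9)
        assert refined[0].pos_cM == effs[0].pos_cM


class TestBootstrap:
    def test_deterministic(self, scan_setup):
        mp, geno, probs = scan_setup
        y = _trait_from_marker(geno, "1A_M0011", 1.0, 1.0, seed=14)
        b1 = qtl.bootstrap_ci(probs, y, "1A", n_boot=50, seed=5)
        b2 = qtl.bootstrap_ci(probs, y, "1A", n_boot=50, seed=5)
        assert b1 == b2

    def test_strong_qtl_tighter_than_weak(self):
        # position uncertainty shrinks with effect size; compared on
        # average over replicate noise draws to keep the check statistical
        cfg = SimConfig(n_lines=500, n_chromosomes=1, chrom_lengths_cM=[100.0],
                        chrom_names=["1A"], marker_spacing_cM=5.0, seed=34)
        mp, geno = simulate_map_and_genotypes(cfg)
        probs = qtl.genotype_probabilities(mp, geno, step_cM=1.0)
        sds = {"strong": [], "weak": []}
        for rep in range(6):
            strong = _trait_from_marker(geno, "1A_M0011", 1.0, 1.0,
                                        seed=100 + rep)
            weak = _trait_from_marker(geno, "1A_M0011", 0.25, 1.0,
                                      seed=100 + rep)
            sds["strong"].append(
                qtl.bootstrap_ci(probs, strong, "1A", n_boot=60,
                                 seed=rep).pos_sd)
            sds["weak"].append(
                qtl.bootstrap_ci(probs, weak, "1A", n_boot=60,
                                 seed=rep).pos_sd)
        assert np.mean(sds["strong"]) < 3.0
        assert np.mean(sds["weak"]) > np.mean(sds["strong"])
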