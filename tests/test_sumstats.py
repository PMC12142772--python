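"""Summary-statistics I/O, instrument selection, clumping and harmonisation."""

import numpy as np
import pandas as pd
import pytest

from mrmediate import (LdMatrix, SumStats, clump, f_statistic, harmonize,
                       ivw, read_sumstats, select_instruments, write_sumstats)
from mrmediate.simulate import SimConfig, simulate_chain

from conftest import make_sumstats


class TestReadWrite:
    def test_roundtrip_identity(self, tmp_path):
        s = make_sumstats(beta=[0.1, -0.2, 0.05], eaf=[0.3, np.nan, 0.7])
        path = tmp_path / "t.tsv"
        write_sumstats(s, path)
        back = read_sumstats(path, trait_name="trait")
        pd.testing.assert_frame_equal(back.data, s.data)

    def test_invalid_rows_dropped(self, tmp_path):
        s = make_sumstats()
        df = s.data.copy()
        df.loc[1, "se"] = 0.0                       # invariant violation
        df.loc[2, "other_allele"] = "AT"            # indel
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = read_sumstats(path)
        assert back.data["snp"].tolist() == ["rs1"]

    def test_lowercase_alleles_uppercased(self, tmp_path):
        s = make_sumstats()
        df = s.data.copy()
        df["effect_allele"] = "a"
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = read_sumstats(path)
        assert (back.data["effect_allele"] == "A").all()

    def test_missing_column_is_hard_error(self, tmp_path):
        df = make_sumstats().data.drop(columns=["se"])
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="se"):
            read_sumstats(path)

    def test_all_rows_invalid_is_hard_error(self, tmp_path):
        df = make_sumstats().data
        df["se"] = -1.0
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="no valid rows"):
            read_sumstats(path)

    def test_column_map(self, tmp_path):
        df = make_sumstats().data.rename(columns={"snp": "rsid", "pval": "p"})
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = read_sumstats(path, column_map={"snp": "rsid", "pval": "p"})
        assert back.n_snp == 3


class TestSelectInstruments:
    @pytest.mark.parametrize("threshold,expected", [(5e-8, 1), (5e-6, 2)])
    def test_threshold_filter(self, threshold, expected):
        s = make_sumstats(pval=[1e-9, 1e-7, 1e-5])
        assert select_instruments(s, threshold).n_snp == expected

    def test_exclusion_list_overrides_pvalue(self):
        s = make_sumstats(snp=["rs9490847", "rs2", "rs3"], pval=[1e-20, 1e-9, 1e-9])
        kept = select_instruments(s, 5e-8, exclusion_list={"rs9490847"})
        assert "rs9490847" not in kept.data["snp"].tolist()
        assert kept.n_snp == 2

    def test_empty_result_names_threshold(self):
        s = make_sumstats(pval=[0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="5e-08"):
            select_instruments(s, 5e-8)


def _brute_force_clump(df, r2_lookup, r2_max, window_bp):
    """Independent restatement of the greedy definition over the sorted list."""
    order = df.sort_values(["pval", "snp"]).index.tolist()
    kept = []
    for i in order:
        ok = True
        for j in kept:
            same_chr = df.at[i, "chr"] == df.at[j, "chr"]
            close = abs(df.at[i, "pos"] - df.at[j, "pos"]) <= window_bp
            if same_chr and close:
                r2 = r2_lookup(df.at[i, "snp"], df.at[j, "snp"])
                if r2 is not None and r2 >= r2_max:
                    ok = False
        if ok:
            kept.append(i)
    return sorted(df.loc[kept, "snp"])


class TestClump:
    def test_correlated_pair_keeps_smaller_p(self):
        s = make_sumstats(snp=["a", "b"], pval=[1e-10, 1e-8],
                          pos=[1_000_000, 1_001_000])
        ld = LdMatrix(["a", "b"], [[1.0, 0.9], [0.9, 1.0]])
        out = clump(s, ld, r2_max=0.001, window_kb=10_000)
        assert out.data["snp"].tolist() == ["a"]

    def test_independent_all_kept(self):
        s = make_sumstats(pos=[1, 2, 3])
        ld = LdMatrix(["rs1", "rs2", "rs3"], np.eye(3))
        assert clump(s, ld, 0.001, 10_000).n_snp == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_block(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        ids = [f"rs{i}" for i in range(n)]
        a = rng.uniform(0, 1, (n, n))
        r2 = np.clip((a + a.T) / 2, 0, 1)
        np.fill_diagonal(r2, 1.0)
        s = make_sumstats(snp=ids, pval=rng.uniform(1e-12, 1e-4, n).tolist(),
                          pos=(1_000_000 + 1000 * np.arange(n)).tolist())
        ld = LdMatrix(ids, r2)
        got = clump(s, ld, r2_max=0.3, window_kb=10_000)
        expect = _brute_force_clump(s.data, ld.lookup, 0.3, 10_000 * 1000)
        assert sorted(got.data["snp"]) == expect
        # greedy maximality: clumping its own output changes nothing
        again = clump(got, ld, r2_max=0.3, window_kb=10_000)
        assert again.data["snp"].tolist() == got.data["snp"].tolist()

    def test_snp_missing_from_ld_treated_independent(self):
        s = make_sumstats(snp=["a", "b"], pos=[1_000_000, 1_001_000])
        ld = LdMatrix(["a"], [[1.0]])
        assert clump(s, ld, 0.001, 10_000).n_snp == 2


class TestHarmonize:
    def test_identical_coding_is_identity(self):
        exp = make_sumstats("exp", beta=[0.1, 0.2, 0.3])
        out = make_sumstats("out", beta=[0.05, 0.1, 0.15])
        h = harmonize(exp, out)
        np.testing.assert_allclose(np.sort(h.Gamma), [0.05, 0.1, 0.15])

    def test_swapped_alleles_flip_sign_and_eaf(self):
        exp = make_sumstats("exp", snp=["rs1"], beta=[0.1])
        out = make_sumstats("out", snp=["rs1"], beta=[0.2],
                            effect_allele=["G"], other_allele=["A"], eaf=[0.7])
        h = harmonize(exp, out)
        assert h.Gamma[0] == pytest.approx(-0.2)

    def test_strand_complement_resolved(self):
        exp = make_sumstats("exp", snp=["rs1"], effect_allele=["A"],
                            other_allele=["G"], beta=[0.1])
        out = make_sumstats("out", snp=["rs1"], effect_allele=["T"],
                            other_allele=["C"], beta=[0.2])
        h = harmonize(exp, out)
        assert h.Gamma[0] == pytest.approx(0.2)

    @pytest.mark.parametrize("eaf_exp,eaf_out,kept", [
        (0.50, 0.50, False),   # dead-centre frequency: ambiguous
        (0.45, 0.45, False),   # inside the default +-0.08 window
        (0.30, 0.35, True),    # both clear, same side
        (0.30, 0.70, False),   # opposite sides of 0.5
        (0.30, np.nan, False),  # missing frequency
    ])
    def test_palindromic_frequency_rule(self, eaf_exp, eaf_out, kept):
        exp = make_sumstats("exp", snp=["rs1"], effect_allele=["A"],
                            other_allele=["T"], eaf=[eaf_exp])
        out = make_sumstats("out", snp=["rs1"], effect_allele=["A"],
                            other_allele=["T"], eaf=[eaf_out])
        if kept:
            assert harmonize(exp, out).n_snp == 1
        else:
            with pytest.raises(ValueError, match="no SNPs survived"):
                harmonize(exp, out)

    def test_irreconcilable_alleles_dropped(self):
        exp = make_sumstats("exp", snp=["rs1", "rs2"])
        out = make_sumstats("out", snp=["rs1", "rs2"],
                            effect_allele=["A", "C"], other_allele=["G", "G"])
        h = harmonize(exp, out)  # rs2 C/G cannot be reconciled with A/G
        assert list(h.snp_ids) == ["rs1"]

    def test_involution(self):
        rng = np.random.default_rng(1)
        exp = make_sumstats("exp", beta=rng.normal(0.1, 0.02, 3).tolist())
        out = make_sumstats("out", beta=rng.normal(0, 0.05, 3).tolist(),
                            effect_allele=["G", "A", "G"],
                            other_allele=["A", "G", "A"], eaf=[0.7, 0.3, 0.6])
        h1 = harmonize(exp, out)
        # rebuild the outcome with the harmonised (exposure-referenced) coding
        aligned = dict(zip(h1.snp_ids, h1.Gamma))
        out2 = SumStats("out", "continuous", out.data.assign(
            effect_allele="A", other_allele="G",
            beta=[aligned[s] for s in out.data["snp"]], eaf=0.3))
        h2 = harmonize(exp, out2)
        np.testing.assert_allclose(np.sort(h1.Gamma), np.sort(h2.Gamma))

    def test_flip_invariance_of_downstream_estimate(self, chain_sim):
        exp = chain_sim.sumstats["exposure"]
        out = chain_sim.sumstats["outcome"]
        theta = ivw(harmonize(exp, out)).theta_hat
        flipped = SumStats("out", out.trait_type, out.data.assign(
            effect_allele=out.data["other_allele"],
            other_allele=out.data["effect_allele"],
            beta=-out.data["beta"], eaf=1 - out.data["eaf"]))
        theta_f = ivw(harmonize(exp, flipped)).theta_hat
        assert theta_f == pytest.approx(theta, rel=1e-12)


class TestFStatistic:
    def test_square_of_ratio(self):
        from conftest import make_hset
        h = make_hset(np.array([0.1, 0.0]), np.zeros(2), sigma_x=0.02)
        f, mean_f, weak = f_statistic(h)
        np.testing.assert_allclose(f, [25.0, 0.0])
        assert mean_f == pytest.approx(12.5)
        assert not weak

    def test_weak_flag(self):
        from conftest import make_hset
        h = make_hset(np.array([0.01, 0.01]), np.zeros(2), sigma_x=0.02)
        _, mean_f, weak = f_statistic(h)
        assert weak and mean_f <= 10

    def test_mean_f_matches_noncentral_expectation(self):
        # 40 SNPs jointly explaining 4% of variance (0.1% each on average) at
        # n = 50,000.  Conditional on the realised effects, F_j is a
        # noncentral chi-square(1, ncp_j) ratio with ncp_j = n v_j/(1 - v_j),
        # v_j the variance explained; mean F should match 1 + mean(ncp).
        cfg = SimConfig(seed=11, n_exposure_snps=40, h2_exposure=0.04,
                        mediators=(), theta_xy_direct=0.0,
                        n_exp=50_000, n_out=100, n_med=100)
        sim = simulate_chain(cfg)
        exp = sim.sumstats["exposure"]
        f = (exp.data["beta"] / exp.data["se"]) ** 2
        maf, gamma = sim.truth["maf"], sim.truth["gamma"]
        v = 2 * maf * (1 - maf) * gamma**2
        ncp = 50_000 * v / (1 - v)
        mc_se = np.sqrt(np.sum(2 * (1 + 2 * ncp))) / 40
        assert abs(f.mean() - (1 + ncp.mean())) < 3 * mc_se
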