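import subprocess

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_permanova, exact_permutation_p
from ampliscreen import simulate as sim
from ampliscreen.community import bray_curtis
from ampliscreen.permanova import permanova


def random_distance(n, seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    return d


def test_two_group_hand_example():
    """Within-group distance 0, between-group 1: the factor explains everything."""
    d = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], float)
    meta = pd.DataFrame({"g": ["a", "a", "b", "b"]})
    res = permanova(d, meta, ["g"], n_perm=99, seed=0)
    assert res.total_ss == pytest.approx(1.0)
    assert res.factors[0].r2 == pytest.approx(1.0)
    assert res.factors[0].df == 1


def test_single_level_factor_degenerate():
    d = random_distance(8, 0)
    meta = pd.DataFrame({"g": ["x"] * 8, "h": ["a", "b"] * 4})
    res = permanova(d, meta, ["g", "h"], n_perm=49, seed=0)
    g = res.factors[0]
    assert g.df == 0 and g.ss == pytest.approx(0.0, abs=1e-12) and np.isnan(g.p_value)
    assert res.factors[1].df == 1


@pytest.mark.parametrize("n,seed", [(6, 1), (7, 2)])
def test_sequential_partition_matches_brute_force(n, seed):
    """SS, R2 and pseudo-F agree with explicit hat-matrix algebra."""
    d = random_distance(n, seed)
    rng = np.random.default_rng(seed)
    meta = pd.DataFrame({
        "f1": rng.choice(["a", "b"], n),
        "f2": rng.choice(["u", "v"], n),
    })
    if meta["f1"].nunique() < 2 or meta["f2"].nunique() < 2:
        meta.iloc[0] = ["a", "u"]
        meta.iloc[1] = ["b", "v"]
    res = permanova(d, meta, ["f1", "f2"], n_perm=9, seed=0)
    expected, ss_res, df_res, ss_total = brute_permanova(d, meta, ["f1", "f2"])
    assert res.total_ss == pytest.approx(ss_total)
    assert res.residual_ss == pytest.approx(ss_res)
    assert res.residual_df == df_res
    for mine, ref in zip(res.factors, expected):
        assert mine.df == ref["df"]
        assert mine.ss == pytest.approx(ref["ss"], abs=1e-10)
        assert mine.r2 == pytest.approx(ref["r2"], abs=1e-10)
        if ref["df"]:
            assert mine.pseudo_f == pytest.approx(ref["pseudo_f"], abs=1e-10)


def test_sampled_p_matches_full_enumeration():
    """Sampled permutation p sits within Monte-Carlo error of the exact p."""
    n = 6
    d = random_distance(n, 3)
    meta = pd.DataFrame({"g": ["a", "a", "a", "b", "b", "b"]})
    p_exact = exact_permutation_p(d, meta, "g")
    res = permanova(d, meta, ["g"], n_perm=999, seed=11)
    p_sampled = res.factors[0].p_value
    mc_err = 3.5 * np.sqrt(p_exact * (1 - p_exact) / 999) + 2 / 999
    assert abs(p_sampled - p_exact) <= mc_err


def test_additivity_for_any_factor_order():
    truth = sim.simulate_cohort(40, n_sites=4, site_effect_size=0.1, seed=21)
    counts = sim.community_counts(truth, depth=2000, seed=21)
    meta = sim.metadata_frame(truth)
    dm = bray_curtis(counts)
    orders = (
        ["location", "species", "blood_meal"],
        ["blood_meal", "species", "location"],
    )
    for order in orders:
        res = permanova(dm, meta, order, n_perm=0, seed=0)
        total = sum(f.ss for f in res.factors) + res.residual_ss
        assert total == pytest.approx(res.total_ss, rel=1e-9)
        assert sum(f.r2 for f in res.factors) + res.residual_ss / res.total_ss == pytest.approx(1.0)


def test_p_value_floor_is_one_over_nperm_plus_one():
    # strong, jittered group separation with unequal group sizes, so no
    # non-identity permutation reproduces the observed partition
    rng = np.random.default_rng(8)
    pts = np.concatenate([rng.normal(0, 0.1, (9, 2)), rng.normal(10, 0.1, (11, 2))])
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    meta = pd.DataFrame({"g": ["a"] * 9 + ["b"] * 11})
    res = permanova(d, meta, ["g"], n_perm=999, seed=0)
    assert res.factors[0].p_value == pytest.approx(1 / 1000)


def test_missing_factor_rejected():
    d = random_distance(5, 4)
    meta = pd.DataFrame({"g": ["a", "b", "a", "b", "a"]})
    with pytest.raises(ValueError):
        permanova(d, meta, ["nope"], n_perm=9)


def test_agrees_with_vegan_adonis2(tmp_path):
    """Cross-check df/SS/R2/F against the R ecology stack's sequential fit."""
    truth = sim.simulate_cohort(30, n_sites=3, site_effect_size=0.2, seed=5)
    counts = sim.community_counts(truth, depth=2000, seed=5)
    meta = sim.metadata_frame(truth)
    dm = bray_curtis(counts)
    factors = ["location", "species", "kdr_genotype", "blood_meal", "infection"]
    res = permanova(dm, meta, factors, n_perm=99, seed=1)

    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(tmp_path / "dm.tsv", sep="\t")
    meta.loc[list(dm.ids)].to_csv(tmp_path / "meta.tsv", sep="\t")
    script = f"""
    suppressMessages(library(vegan))
    d <- as.dist(as.matrix(read.table("{tmp_path}/dm.tsv", sep="\\t", header=TRUE,
                                      row.names=1, check.names=FALSE)))
    m <- read.table("{tmp_path}/meta.tsv", sep="\\t", header=TRUE, row.names=1)
    a <- adonis2(d ~ location + species + kdr_genotype + blood_meal + infection,
                 data=m, by="terms", permutations=99)
    write.csv(as.data.frame(a), "{tmp_path}/adonis.csv")
    """
    (tmp_path / "s.R").write_text(script)
    subprocess.run(["Rscript", str(tmp_path / "s.R")], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "adonis.csv", index_col=0)
    for f in res.factors:
        row = ref.loc[f.name]
        assert f.df == row["Df"]
        assert f.ss == pytest.approx(row["SumOfSqs"], abs=1e-8)
        assert f.r2 == pytest.approx(row["R2"], abs=1e-8)
        assert f.pseudo_f == pytest.approx(row["F"], abs=1e-8)
    assert res.residual_ss == pytest.approx(ref.loc["Residual", "SumOfSqs"], abs=1e-8)
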