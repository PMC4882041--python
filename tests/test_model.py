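"""Sampler correctness: degenerate inputs, determinism, exchangeability,
pooling behaviour and convergence diagnostics."""

import numpy as np
import pandas as pd
import pytest

from phytomacro.model import (ModelSpec, PosteriorDraws, SamplerConfig,
                              diagnose, fit_hierarchical, shrinkage_check)


def _labels(groups):
    """Expand {(species, phylum): n} into (y-placeholder, species, phylum)."""
    sp, ph = [], []
    for (s, p), n in groups.items():
        sp += [s] * n
        ph += [p] * n
    return np.array(sp), np.array(ph)


def test_constant_data_recovers_the_constant(fast_config):
    sp, ph = _labels({("s1", "A"): 5, ("s2", "A"): 5, ("s3", "B"): 5})
    y = np.full(15, 7.5)
    draws, _ = fit_hierarchical((y, sp, ph), config=fast_config)
    med = np.median(draws.flat_phylum_means(), axis=0)
    assert np.allclose(med, 7.5, atol=0.05)
    assert np.median(draws.flat("sigma_e")) < 0.05


def test_seed_determinism_and_row_order_invariance(tiny_table, fast_config):
    table, _ = tiny_table
    sub = table.df.loc[table.df["pool"] == "lipid"]
    a, _ = fit_hierarchical(sub, ModelSpec(), fast_config)
    b, _ = fit_hierarchical(sub, ModelSpec(), fast_config)
    assert np.array_equal(a.phylum_mean, b.phylum_mean)
    assert np.array_equal(a.sigma_e, b.sigma_e)

    shuffled = sub.sample(frac=1.0, random_state=3)
    c, _ = fit_hierarchical(shuffled, ModelSpec(), fast_config)
    assert np.array_equal(a.phylum_mean, c.phylum_mean)


def test_different_seeds_give_different_draws(tiny_table, fast_config):
    table, _ = tiny_table
    sub = table.df.loc[table.df["pool"] == "lipid"]
    a, _ = fit_hierarchical(sub, ModelSpec(), fast_config)
    import dataclasses
    b, _ = fit_hierarchical(sub, ModelSpec(),
                            dataclasses.replace(fast_config, seed=99))
    assert not np.array_equal(a.phylum_mean, b.phylum_mean)


def test_empty_input_raises():
    with pytest.raises(ValueError, match="empty"):
        fit_hierarchical((np.array([]), np.array([]), np.array([])))


def test_species_in_two_phyla_rejected():
    y = np.array([1.0, 2.0])
    with pytest.raises(ValueError, match="exactly one phylum"):
        fit_hierarchical((y, np.array(["s", "s"]), np.array(["A", "B"])))


def test_degenerate_design_flagged_weakly_identified(fast_config):
    draws, report = fit_hierarchical(
        (np.array([5.0]), np.array(["s"]), np.array(["A"])), config=fast_config)
    assert report.weakly_identified
    assert draws.mu.shape == (fast_config.n_chains, fast_config.kept_per_chain)


def test_conjugate_oracle_fixed_variance(fast_config):
    """With all scales fixed and mu fixed, the phylum-mean posterior has a
    closed normal-normal conjugate form (species level integrated out)."""
    rng = np.random.default_rng(1)
    mu0, s_p, s_s, s_e, n_per = 10.0, 3.0, 2.0, 1.5, 6
    rows = []
    for j in range(3):
        for s in range(4):
            for v in rng.normal(10 + j, 2.0, n_per):
                rows.append((v, f"p{j}s{s}", f"P{j}"))
    y, sp, ph = map(np.array, zip(*rows))
    y = y.astype(float)

    config = SamplerConfig(n_chains=2, n_iterations=10_000, thin=2, seed=4)
    draws, _ = fit_hierarchical(
        (y, sp, ph), config=config,
        fixed={"mu": mu0, "sigma_p": s_p, "sigma_s": s_s, "sigma_e": s_e})

    df = pd.DataFrame({"y": y, "s": sp, "p": ph})
    flat = draws.flat_phylum_means()
    for j, name in enumerate(draws.phylum_names):
        ybars = df.loc[df["p"] == name].groupby("s")["y"].mean()
        v = s_s**2 + s_e**2 / n_per
        prec = 1.0 / s_p**2 + len(ybars) / v
        oracle_mean = (mu0 / s_p**2 + ybars.sum() / v) / prec
        oracle_sd = prec**-0.5
        mc_se = flat[:, j].std() / np.sqrt(flat.shape[0] / 10)  # conservative ESS
        assert abs(flat[:, j].mean() - oracle_mean) < 3 * mc_se + 1e-9
        assert abs(flat[:, j].std() - oracle_sd) < 0.05 * oracle_sd + 3 * mc_se


def test_shrinkage_direction_and_sample_size_dependence(fast_config):
    """Sparse species shrink strongly toward the phylum mean; well-sampled
    species stay near their raw mean; shrinkage decreases with n."""
    rng = np.random.default_rng(2)
    rows = []
    # enough species to pin down the among-species scale (~2), so the
    # singleton outlier cannot inflate it and evade pooling
    for s in range(30):
        m = rng.normal(20.0, 2.0)
        for v in rng.normal(m, 2.0, 6):
            rows.append((v, f"a{s}", "A"))
    rows.append((28.0, "lone", "A"))              # singleton ~4 SD from its phylum
    for s in range(10):
        m = rng.normal(10.0, 2.0)
        for v in rng.normal(m, 2.0, 6):
            rows.append((v, f"b{s}", "B"))
    big = rng.normal(16.0, 2.0, 50)               # well-sampled outlying species
    for v in big:
        rows.append((v, "big", "B"))
    y, sp, ph = map(np.array, zip(*rows))

    draws, _ = fit_hierarchical((y.astype(float), sp, ph), config=fast_config)
    # Monte-Carlo tolerance: species sitting essentially on their phylum
    # median can flip the comparison by sampling noise alone
    diag = shrinkage_check(draws, (y.astype(float), sp, ph), tol=0.2)
    assert diag["shrunk"].all()

    lone = diag.set_index("species_key").loc["lone"]
    assert lone["posterior_distance"] < 0.75 * lone["raw_distance"]

    big_row = diag.set_index("species_key").loc["big"]
    assert abs(big_row["posterior_median"] - big.mean()) < 1.0
    # relative shrinkage is milder for the well-sampled species
    assert (big_row["posterior_distance"] / big_row["raw_distance"]
            > lone["posterior_distance"] / lone["raw_distance"])


def _draws_from(arrs):
    C, K = arrs["mu"].shape
    J = arrs["phylum_mean"].shape[2]
    return PosteriorDraws(
        mu=arrs["mu"], phylum_mean=arrs["phylum_mean"],
        species_mean=np.zeros((C, K, 1)),
        sigma_p=arrs.get("sigma_p", np.ones((C, K))),
        sigma_s=np.ones((C, K)), sigma_e=np.ones((C, K)),
        phylum_names=[f"P{j}" for j in range(J)],
        species_names=["s0"], species_phylum=np.zeros(1, dtype=np.intp),
    )


def test_diagnose_flags_disjoint_chains():
    rng = np.random.default_rng(0)
    K = 500
    good = _draws_from({
        "mu": rng.standard_normal((2, K)),
        "phylum_mean": rng.standard_normal((2, K, 2)),
    })
    rep = diagnose(good)
    assert rep.table["rhat"].max() < 1.01 and rep.passed

    bad_mu = np.concatenate([rng.standard_normal((1, K)) - 10,
                             rng.standard_normal((1, K)) + 10])
    bad = _draws_from({"mu": bad_mu,
                       "phylum_mean": rng.standard_normal((2, K, 2))})
    rep = diagnose(bad)
    assert rep.table.set_index("parameter").loc["mu", "rhat"] > 1.5
    assert not rep.passed


def test_diagnose_single_chain_flagged():
    rng = np.random.default_rng(0)
    d = _draws_from({"mu": rng.standard_normal((1, 200)),
                     "phylum_mean": rng.standard_normal((1, 200, 2))})
    rep = diagnose(d)
    assert not rep.passed
    assert any("single chain" in n for n in rep.notes)
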