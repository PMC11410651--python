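"""Methylome simulation: analytic moments, limits, determinism, pooling."""

import numpy as np
import pytest

import epicenmap as em
from epicenmap.errors import InputError
from epicenmap.haplotypes import EpiHaplotype


def _params(tiny_scenario, **over):
    base = em.MethylationParams.from_scenario(tiny_scenario)
    from dataclasses import replace

    return replace(base, **over)


def weighted(profile, context):
    sub = profile[profile["context"] == context]
    total = sub["meth"].sum() + sub["unmeth"].sum()
    return sub["meth"].sum() / total


def analytic_se(p, rho, lam, n_sites):
    """Standard error of the genome-wide weighted level.

    Per-site methylated counts have mean lam*p and variance
    lam*p(1-p)(1 + lam*rho) under Poisson coverage with a beta-binomial
    read law, so the count-weighted mean over n sites has this s.e.
    """
    return np.sqrt(p * (1 - p) * (1 + lam * rho) / (n_sites * lam))


def test_recovers_configured_level(tiny_genome, tiny_scenario):
    """HYPO CG at p=0.05, coverage 30: the weighted level lands within 3 s.e."""
    params = _params(tiny_scenario, coverage=30.0)
    params = _params(tiny_scenario, coverage=30.0,
                     probabilities={**params.probabilities, ("HYPO", "CG"): 0.05})
    hap = EpiHaplotype.uniform(tiny_genome.chromosomes, "HYPO")
    profile = em.simulate_methylome(tiny_genome, hap, params, seed=11,
                                    contexts=("CG",))
    n_sites = len(profile)
    assert n_sites >= 10_000
    se = analytic_se(0.05, params.overdispersion, 30.0, n_sites)
    assert abs(weighted(profile, "CG") - 0.05) < 3 * se


@pytest.mark.parametrize("state", ["METH", "HYPO", "HYPER"])
def test_recovers_all_contexts(tiny_genome, tiny_scenario, state):
    params = _params(tiny_scenario)
    hap = EpiHaplotype.uniform(tiny_genome.chromosomes, state)
    profile = em.simulate_methylome(tiny_genome, hap, params, seed=23)
    for context in em.CONTEXTS:
        p = params.probability(state, context)
        n = int((profile["context"] == context).sum())
        se = analytic_se(p, params.overdispersion, params.coverage, n)
        assert abs(weighted(profile, context) - p) < 3 * max(se, 1e-12)


def test_binomial_limit_variance(tiny_genome, tiny_scenario):
    """rho -> 0: per-site fractions have binomial variance p(1-p)/m."""
    p = 0.4
    probs = {(s, c): p for s in em.STATES for c in em.CONTEXTS}
    params = _params(tiny_scenario, coverage=30.0, overdispersion=0.0,
                     probabilities=probs)
    hap = EpiHaplotype.uniform(tiny_genome.chromosomes, "METH")
    profile = em.simulate_methylome(tiny_genome, hap, params, seed=2)
    cov = (profile["meth"] + profile["unmeth"]).to_numpy()
    keep = cov > 0
    frac = profile["meth"].to_numpy()[keep] / cov[keep]
    observed = frac.var()
    expected = np.mean(p * (1 - p) / cov[keep])
    assert observed == pytest.approx(expected, rel=0.05)

    # overdispersion inflates the variance beyond the binomial limit
    over = _params(tiny_scenario, coverage=30.0, overdispersion=0.2,
                   probabilities=probs)
    profile2 = em.simulate_methylome(tiny_genome, hap, over, seed=2)
    cov2 = (profile2["meth"] + profile2["unmeth"]).to_numpy()
    frac2 = profile2["meth"].to_numpy()[cov2 > 0] / cov2[cov2 > 0]
    assert frac2.var() > 1.5 * observed


def test_deterministic_and_emits_all_sites(tiny_genome, tiny_scenario):
    params = _params(tiny_scenario, coverage=0.5)  # sparse: zero-coverage sites
    hap = EpiHaplotype.uniform(tiny_genome.chromosomes, "METH")
    a = em.simulate_methylome(tiny_genome, hap, params, seed=5)
    b = em.simulate_methylome(tiny_genome, hap, params, seed=5)
    assert a.equals(b)
    c = em.simulate_methylome(tiny_genome, hap, params, seed=6)
    assert not a.equals(c)
    n_expected = sum(
        tiny_genome.cytosine_sites(ch)[0].size for ch in tiny_genome.chromosome_names
    )
    assert len(a) == n_expected
    assert ((a["meth"] + a["unmeth"]) == 0).any()  # zero-coverage sites emitted


def test_diploid_coverage_split(tiny_genome, tiny_scenario):
    params = _params(tiny_scenario, coverage=12.0)
    meth_hap = EpiHaplotype.uniform(tiny_genome.chromosomes, "METH")
    hypo_hap = EpiHaplotype.uniform(tiny_genome.chromosomes, "HYPO")
    profile = em.simulate_methylome(
        tiny_genome, (meth_hap, hypo_hap), params, seed=8, contexts=("CG",)
    )
    cov = (profile["meth"] + profile["unmeth"]).to_numpy()
    assert cov.mean() == pytest.approx(12.0, rel=0.02)
    # heterozygote CG level sits midway between the haplotype levels
    mid = (params.probability("METH", "CG") + params.probability("HYPO", "CG")) / 2
    assert weighted(profile, "CG") == pytest.approx(mid, abs=0.01)


def test_rejects_mismatched_haplotype(tiny_genome, tiny_scenario):
    params = _params(tiny_scenario)
    hap = EpiHaplotype.uniform({"ChrX": 1000}, "METH")
    with pytest.raises(InputError):
        em.simulate_methylome(tiny_genome, hap, params, seed=0)


def test_pool_sampler_matches_summed_individuals(tiny_genome, tiny_scenario):
    """The pooled-count sampler agrees in moments with explicit pooling."""
    params = _params(tiny_scenario, coverage=8.0)
    members = []
    for i in range(6):
        hap1 = EpiHaplotype.uniform(tiny_genome.chromosomes,
                                    "HYPO" if i % 2 else "METH")
        hap2 = EpiHaplotype.uniform(tiny_genome.chromosomes, "METH")
        members.append((hap1, hap2))
    pooled = em.simulate_pool_methylome(
        tiny_genome, members, params, seed=3, contexts=("CG",)
    )
    profiles = [
        em.simulate_methylome(tiny_genome, m, params, seed=100 + i,
                              contexts=("CG",))
        for i, m in enumerate(members)
    ]
    summed = em.pool_profiles(profiles)
    assert (pooled["pos"].to_numpy() == summed["pos"].to_numpy()).all()
    cov_a = (pooled["meth"] + pooled["unmeth"]).to_numpy()
    cov_b = (summed["meth"] + summed["unmeth"]).to_numpy()
    # identical coverage law: Poisson(6 * 8)
    assert cov_a.mean() == pytest.approx(48.0, rel=0.02)
    assert cov_b.mean() == pytest.approx(48.0, rel=0.02)
    assert cov_a.var() == pytest.approx(cov_b.var(), rel=0.05)
    # identical weighted level (3 haplotype-level s.e.)
    lvl_a = pooled["meth"].sum() / cov_a.sum()
    lvl_b = summed["meth"].sum() / cov_b.sum()
    assert lvl_a == pytest.approx(lvl_b, abs=0.01)
    # and matching per-site methylated-count dispersion
    assert pooled["meth"].var() == pytest.approx(summed["meth"].var(), rel=0.05)

    again = em.simulate_pool_methylome(
        tiny_genome, members, params, seed=3, contexts=("CG",)
    )
    assert pooled.equals(again)


def test_hairpin_rescue_is_context_specific(tiny_genome, tiny_scenario):
    """Rescue lifts CHG/CHH to METH levels over targets; CG and non-targets
    are byte-identical to the unrescued simulation at the same seed."""
    params = _params(tiny_scenario)
    base = EpiHaplotype.uniform(tiny_genome.chromosomes, "HYPO")
    rescued = em.apply_hairpin_rescue(base, tiny_genome, "ATHILA5")
    chrom = tiny_scenario.element_chromosome
    p0 = em.simulate_methylome(tiny_genome, base, params, 17, chromosomes=[chrom])
    p1 = em.simulate_methylome(tiny_genome, rescued, params, 17,
                               chromosomes=[chrom])
    pos0 = p0["pos"].to_numpy() - 1
    targets = tiny_genome.elements_of("ATHILA5")
    in_target = np.zeros(len(p0), dtype=bool)
    for row in targets.itertuples():
        in_target |= (pos0 >= row.start) & (pos0 < row.end)
    changed = (
        (p0["meth"].to_numpy() != p1["meth"].to_numpy())
        | (p0["unmeth"].to_numpy() != p1["unmeth"].to_numpy())
    )
    is_cg = (p0["context"] == "CG").to_numpy()
    assert not (changed & ~in_target).any()
    assert not (changed & in_target & is_cg).any()

    def level(profile, mask, context):
        sub = profile[mask & (profile["context"] == context).to_numpy()]
        return sub["meth"].sum() / (sub["meth"].sum() + sub["unmeth"].sum())

    # analytic means: CHG at METH level, CG still at HYPO level
    assert level(p1, in_target, "CHG") == pytest.approx(
        params.probability("METH", "CHG"), abs=0.03
    )
    assert level(p1, in_target, "CHH") == pytest.approx(
        params.probability("METH", "CHH"), abs=0.03
    )
    assert level(p1, in_target, "CG") == pytest.approx(
        params.probability("HYPO", "CG"), abs=0.02
    )
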