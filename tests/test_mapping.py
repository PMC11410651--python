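"""Pooled contrast mapping, marker epigenotyping and fine mapping."""

import numpy as np
import pandas as pd
import pytest

import epicenmap as em
from epicenmap.config import CONTEXTS
from epicenmap.errors import InputError
from epicenmap.haplotypes import EpiHaplotype
from epicenmap.mapping import ABSENT, PRESENT, UNDETERMINED


def contrast_frame(deltas, chrom="Chr1", width=100):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(len(deltas)) * width,
            "end": (np.arange(len(deltas)) + 1) * width,
            "fertile": np.nan,
            "sterile": np.nan,
            "delta": deltas,
        }
    )


def brute_linked_regions(deltas, threshold, chrom="Chr1", width=100):
    """Independent scan: collect qualifying runs, then rank."""
    regions = []
    run = []
    for i, d in enumerate(list(deltas) + [np.nan]):
        if not np.isnan(d) and d >= threshold:
            run.append(i)
        elif run:
            regions.append(
                (
                    -len(run),
                    -float(np.mean([deltas[j] for j in run])),
                    run[0] * width,
                    run[-1] * width + width,
                )
            )
            run = []
    regions.sort()
    return [
        (chrom, start, end, -neg_n, -neg_mean)
        for neg_n, neg_mean, start, end in regions
    ]


def window_tables_from_levels(levels_by_context, chrom="Chr1", width=100):
    n = len(next(iter(levels_by_context.values())))
    table = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * width,
            "end": (np.arange(n) + 1) * width,
            "partial": False,
        }
    )
    for ctx in CONTEXTS:
        level = np.asarray(levels_by_context.get(ctx, [np.nan] * n), dtype=float)
        table[f"{ctx}_meth"] = 0
        table[f"{ctx}_total"] = np.where(np.isnan(level), 0, 100)
        table[f"{ctx}_sites"] = np.where(np.isnan(level), 0, 10)
        table[f"{ctx}_level"] = level
    return table


def test_pool_contrast_examples():
    fertile = window_tables_from_levels({"CG": [0.8, 0.5, np.nan]})
    sterile = window_tables_from_levels({"CG": [0.1, 0.5, 0.4]})
    contrast = em.pool_contrast(fertile, sterile, "CG")
    assert contrast["delta"].to_numpy()[:2] == pytest.approx([0.7, 0.0])
    assert np.isnan(contrast["delta"].iloc[2])
    identical = em.pool_contrast(fertile, fertile, "CG")
    assert np.nansum(np.abs(identical["delta"].to_numpy())) == 0
    other_grid = window_tables_from_levels({"CG": [0.8, 0.5]})
    with pytest.raises(InputError):
        em.pool_contrast(fertile, other_grid, "CG")


def test_call_linked_region_examples():
    deltas = [0.0, 0.05, 0.45, 0.50, 0.48, 0.02]
    regions = em.call_linked_region(contrast_frame(deltas), threshold=0.3)
    assert len(regions) == 1
    assert (regions[0].start, regions[0].end) == (200, 500)
    assert regions[0].n_windows == 3
    assert em.call_linked_region(contrast_frame([0.1, 0.2]), 0.3) == []
    # equal-length runs rank by mean delta
    deltas = [0.4, 0.4, np.nan, 0.6, 0.6]
    regions = em.call_linked_region(contrast_frame(deltas), 0.3)
    assert regions[0].start == 300 and regions[1].start == 0


def test_call_linked_region_matches_brute_force():
    rng = np.random.default_rng(33)
    for _ in range(200):
        n = int(rng.integers(1, 40))
        deltas = rng.uniform(-0.5, 0.8, size=n)
        deltas[rng.random(n) < 0.2] = np.nan
        threshold = float(rng.uniform(0.05, 0.6))
        got = em.call_linked_region(contrast_frame(deltas), threshold)
        expected = brute_linked_regions(deltas, threshold)
        assert [(r.chrom, r.start, r.end, r.n_windows) for r in got] == [
            e[:4] for e in expected
        ]
        for r, e in zip(got, expected):
            assert r.mean_delta == pytest.approx(e[4])


def test_mcrbc_marker_haplotype_mode(tiny_genome, tiny_scenario):
    meth = EpiHaplotype.uniform(tiny_genome.chromosomes, "METH")
    hypo = EpiHaplotype.uniform(tiny_genome.chromosomes, "HYPO")
    amplicon = ("Chr1", 1_000, 1_500)
    hetero = em.SimIndividual("x", (hypo, meth), "sterile")
    homo = em.SimIndividual("y", (meth, meth), "fertile")
    # one undigested (hypomethylated) template suffices: dominant marker
    assert em.mcrbc_marker(hetero, amplicon) == PRESENT
    assert em.mcrbc_marker(homo, amplicon) == ABSENT


def test_mcrbc_marker_profile_mode():
    def profile(level):
        meth = int(level * 100)
        frame = pd.DataFrame(
            {
                "chrom": ["Chr1"],
                "pos": [1_010],
                "strand": ["+"],
                "meth": [meth],
                "unmeth": [100 - meth],
                "context": pd.Categorical(["CG"], categories=list(CONTEXTS)),
            }
        )
        return frame

    amplicon = ("Chr1", 1_000, 1_100)
    assert em.mcrbc_marker(profile(0.03), amplicon) == PRESENT
    assert em.mcrbc_marker(profile(0.85), amplicon) == ABSENT
    assert em.mcrbc_marker(profile(0.5), ("Chr1", 5_000, 5_100)) == UNDETERMINED


def marker_table(calls):
    """calls: {individual: {marker: call}}; markers named m1..mk left to right."""
    rows = []
    for ind, per_marker in calls.items():
        for marker, call in per_marker.items():
            k = int(marker[1:])
            rows.append((ind, marker, "Chr1", k * 1_000, k * 1_000 + 100, call))
    return pd.DataFrame(
        rows, columns=["individual", "marker", "chrom", "start", "end", "call"]
    )


def test_fine_map_example():
    """Steriles present at m2, m3 only; contradictions at m1 and m4 bound
    the interval exclusively."""
    calls = {
        "s1": {"m1": ABSENT, "m2": PRESENT, "m3": PRESENT, "m4": ABSENT},
        "s2": {"m1": ABSENT, "m2": PRESENT, "m3": PRESENT, "m4": ABSENT},
        "f1": {"m1": PRESENT, "m2": ABSENT, "m3": ABSENT, "m4": ABSENT},
        "f2": {"m1": ABSENT, "m2": ABSENT, "m3": ABSENT, "m4": ABSENT},
    }
    # m4: sterile s1/s2 absent -> contradicting; m1: fertile f1 present
    phenotypes = {"s1": "sterile", "s2": "sterile",
                  "f1": "fertile", "f2": "fertile"}
    result = em.fine_map(marker_table(calls), phenotypes)
    assert result.chrom == "Chr1"
    assert result.consistent_markers == ("m2", "m3")
    assert result.interval == (1_100, 4_000)  # (m1 end, m4 start), exclusive

    # brute-force maximality: no marker outside [m2, m3] is consistent
    table = marker_table(calls)
    for marker, sub in table.groupby("marker"):
        consistent = all(
            (phenotypes[r.individual] == "sterile") == (r.call == PRESENT)
            for r in sub.itertuples()
        )
        assert consistent == (marker in result.consistent_markers)


def test_fine_map_contradiction_and_single_marker():
    phenotypes = {"a": "sterile", "b": "fertile"}
    # identical calls with mixed phenotypes: contradiction everywhere
    calls = {"a": {"m1": PRESENT}, "b": {"m1": PRESENT}}
    result = em.fine_map(marker_table(calls), phenotypes)
    assert result.interval is None
    assert any(ind == "b" for _m, ind, _p, _c in result.contradictions)

    # one perfectly co-segregating marker spans the chromosome
    calls = {"a": {"m1": PRESENT}, "b": {"m1": ABSENT}}
    result = em.fine_map(marker_table(calls), phenotypes,
                         chrom_lengths={"Chr1": 50_000})
    assert result.interval == (0, 50_000)
    # undetermined calls are ignored
    calls = {"a": {"m1": PRESENT, "m2": UNDETERMINED},
             "b": {"m1": ABSENT, "m2": UNDETERMINED}}
    result = em.fine_map(marker_table(calls), phenotypes,
                         chrom_lengths={"Chr1": 50_000})
    assert result.consistent_markers == ("m1",)


def test_fine_map_contains_causal_locus_on_simulated_cohorts(
    tiny_genome, tiny_scenario
):
    """With one marker per 10 kb (plus one over the locus itself), the
    fine-mapped interval always contains the causal locus."""
    scenario = tiny_scenario.replace(population_size=80)
    chrom = scenario.causal_chrom
    length = dict(tiny_genome.chromosomes)[chrom]
    amplicons = [
        (f"m{k}", chrom, start, start + 500)
        for k, start in enumerate(range(0, length - 500, 10_000))
    ]
    amplicons.append(("mC", chrom, scenario.causal_start, scenario.causal_end))
    for seed in range(20):
        individuals = em.simulate_cross(tiny_genome, scenario, seed=seed)
        rows = []
        for ind in individuals:
            for name, c, s, e in amplicons:
                rows.append(
                    (ind.identifier, name, c, s, e, em.mcrbc_marker(ind, (c, s, e)))
                )
        markers = pd.DataFrame(
            rows, columns=["individual", "marker", "chrom", "start", "end", "call"]
        )
        phenotypes = {i.identifier: i.phenotype for i in individuals}
        result = em.fine_map(markers, phenotypes,
                             chrom_lengths=dict(tiny_genome.chromosomes))
        assert result.chrom == chrom
        lo, hi = result.interval
        assert lo <= scenario.causal_start and hi >= scenario.causal_end
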