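"""Private/common classification laws, diagnostic filters, group contrast."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from radpop import (
    GenotypeMatrix,
    PopulationMap,
    classify_alleles,
    count_private,
    diagnostic_filter,
    group_contrast,
    universal_locus_filter,
)
from radpop.genotype_model import MISSING, GenotypeModelError, SNPSite
from radpop.synthetic_data import SimConfig, simulate

from conftest import SITE_ROWS, single_site


def _matrix(genotypes_by_ind: dict[str, str], ref: str = "C") -> GenotypeMatrix:
    return GenotypeMatrix.from_site_genotypes(
        list(genotypes_by_ind.values()), ref=ref,
        individuals=list(genotypes_by_ind))


# -- classification definitions -----------------------------------------------


def test_private_allele_single_carrier_population():
    gm = _matrix({"x1": "TT", "x2": "CC", "y1": "CC", "y2": "CC"})
    pmap = PopulationMap({"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"})
    (call,) = classify_alleles(gm, pmap)
    assert call.allele == "T"
    assert call.category == "private"
    assert call.carrier_populations == ("X",)


def test_common_allele_two_carrier_populations():
    """An alternative allele seen in two varieties and absent elsewhere is
    common with exactly those carriers (the shared-T pattern of the
    published common-allele table)."""
    assignments = {"a1": "Allahverdi", "a2": "Allahverdi",
                   "s1": "Sarıfındık", "s2": "Sarıfındık", "s3": "Sarıfındık",
                   "t1": "Tombul", "t2": "Tombul"}
    gm = _matrix({"a1": "TT", "a2": "TT", "s1": "AT", "s2": "AA", "s3": "AA",
                  "t1": "AA", "t2": "AA"}, ref="A")
    pmap = PopulationMap(assignments)
    (call,) = classify_alleles(gm, pmap)
    assert call.category == "common"
    assert call.carrier_populations == ("Allahverdi", "Sarıfındık")


def test_partition_every_observed_alt_classified_once():
    """|private| + |common| equals the number of distinct (site, alt allele)
    pairs with at least one copy."""
    gm, pmap, _ = simulate(SimConfig(
        seed=31, populations=[("A", 3), ("B", 3), ("C", 2)], n_loci=150,
        beta_a=0.5, beta_b=2.0, locus_dropout_rate=0.1))
    calls = classify_alleles(gm, pmap)
    keys = [(c.site_index, c.allele) for c in calls]
    assert len(keys) == len(set(keys))
    idx = gm.individual_index(pmap.assignments.keys())
    observed = sum(
        int(gm.allele_counts(j, idx)[k] > 0)
        for j in range(gm.n_sites)
        for k in range(1, len(gm.sites[j].alleles))
    )
    assert len(calls) == observed
    n_private = sum(c.category == "private" for c in calls)
    n_common = sum(c.category == "common" for c in calls)
    assert n_private + n_common == len(calls)


def test_merging_populations_monotone_on_private_set():
    """Coarsening the map (merging two populations) never destroys a private
    allele: a private allele stays private (its carrier set stays a single
    population) and the only new private alleles are those previously shared
    by exactly the two merged populations."""
    gm, pmap, _ = simulate(SimConfig(
        seed=37, populations=[("A", 3), ("B", 3), ("C", 3)], n_loci=120))
    before = classify_alleles(gm, pmap)
    base = {(c.site_index, c.allele)
            for c in before if c.category == "private"}
    shared_ab = {(c.site_index, c.allele) for c in before
                 if set(c.carrier_populations) == {"A", "B"}}
    merged_assign = {ind: ("AB" if pop in ("A", "B") else pop)
                     for ind, pop in pmap.assignments.items()}
    merged = PopulationMap(merged_assign)
    after = {(c.site_index, c.allele)
             for c in classify_alleles(gm, merged) if c.category == "private"}
    assert after == base | shared_ab


def test_removing_individual_never_erases_common_allele_entirely():
    """Dropping one individual leaves every common allele still observed."""
    gm, pmap, _ = simulate(SimConfig(
        seed=41, populations=[("A", 4), ("B", 4)], n_loci=80,
        beta_a=5.0, beta_b=5.0))
    common = [c for c in classify_alleles(gm, pmap) if c.category == "common"]
    assert common  # the symmetric prior guarantees shared polymorphism
    victim = gm.individuals[0]
    keep = [i for i, ind in enumerate(gm.individuals) if ind != victim]
    gm2 = GenotypeMatrix(
        [gm.individuals[i] for i in keep], gm.sites, gm.calls[:, keep, :])
    pmap2 = PopulationMap({ind: pop for ind, pop in pmap.assignments.items()
                           if ind != victim})
    remaining = {(c.site_index, c.allele) for c in classify_alleles(gm2, pmap2)}
    for c in common:
        assert (c.site_index, c.allele) in remaining


def test_brute_force_oracle_small_catalogs():
    """On tiny catalogs, classification matches exhaustive enumeration of
    allele occurrences per population."""
    rng = np.random.default_rng(5)
    pops = {"i1": "P1", "i2": "P1", "i3": "P2", "i4": "P2", "i5": "P3", "i6": "P3"}
    pmap = PopulationMap(pops)
    for trial in range(20):
        sites, rows = [], []
        for j in range(rng.integers(1, 5)):
            sites.append(SNPSite(locus_id=j + 1, chromosome="1",
                                 position_bp=1000 * (j + 1), column=0,
                                 ref_allele="A", alt_alleles=("C", "T")))
            calls = rng.integers(0, 3, size=(6, 2)).astype(np.int8)
            drop = rng.random(6) < 0.2
            calls[drop] = MISSING
            rows.append(calls)
        gm = GenotypeMatrix(list(pops), sites, np.stack(rows))
        calls_out = {(c.site_index, c.allele): set(c.carrier_populations)
                     for c in classify_alleles(gm, pmap)}
        # brute force: walk every genotype of every individual
        expected: dict[tuple[int, str], set[str]] = {}
        for j, site in enumerate(sites):
            for i, ind in enumerate(gm.individuals):
                for a in gm.calls[j, i]:
                    if a > 0:
                        expected.setdefault(
                            (j, site.alleles[a]), set()).add(pops[ind])
        assert calls_out == expected


# -- diagnostic filter ---------------------------------------------------------


@pytest.mark.parametrize(
    "carrier_genotypes,expected_class",
    [
        (("TT", "TT"), "fixed_homozygous"),
        (("CT", "CT", "CT"), "all_heterozygous"),
        (("TT", "CT"), None),
    ],
    ids=["uniform-hom", "uniform-het", "mixed-dropped"],
)
def test_diagnostic_filter_uniformity(carrier_genotypes, expected_class):
    genotypes = {f"x{i}": g for i, g in enumerate(carrier_genotypes)}
    genotypes |= {"y1": "CC", "y2": "CC"}
    gm = _matrix(genotypes, ref="C")
    pmap = PopulationMap({ind: ("X" if ind.startswith("x") else "Y")
                          for ind in genotypes})
    calls = classify_alleles(gm, pmap)
    kept = diagnostic_filter(calls, gm, pmap)
    if expected_class is None:
        assert kept == []
    else:
        (call,) = kept
        assert call.diagnostic_class == expected_class


def test_diagnostic_filter_ignores_missing_members():
    """Uniformity is judged over genotyped members only."""
    gm = _matrix({"x1": "TT", "x2": "./.", "y1": "CC"}, ref="C")
    pmap = PopulationMap({"x1": "X", "x2": "X", "y1": "Y"})
    kept = diagnostic_filter(classify_alleles(gm, pmap), gm, pmap)
    (call,) = kept
    assert call.diagnostic_class == "fixed_homozygous"


def test_universal_locus_filter_thresholds():
    gm = _matrix({"x1": "TT", "x2": "CC", "y1": "CC", "y2": "./."}, ref="C")
    pmap = PopulationMap({"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"})
    calls = classify_alleles(gm, pmap)
    assert calls[0].locus_universality == pytest.approx(0.75)
    assert universal_locus_filter(calls, min_fraction=1.0) == []
    assert universal_locus_filter(calls, min_fraction=0.75) == calls
    with pytest.raises(ValueError):
        universal_locus_filter(calls, min_fraction=0.0)


def test_count_private_zero_when_no_alternatives():
    gm = GenotypeMatrix.from_site_genotypes(["CC", "CC"], ref="C", alts=["T"])
    pmap = PopulationMap({"ind1": "X", "ind2": "Y"})
    assert count_private(classify_alleles(gm, pmap), pmap) == {"X": 0, "Y": 0}


# -- planted-allele recovery ---------------------------------------------------


def _recovery_config(seed: int, dropout: float) -> SimConfig:
    # symmetric mid-frequency prior: background polymorphism is shared by
    # all populations, so planted alleles are the only private ones
    return SimConfig(
        seed=seed,
        populations=[("A", 3), ("B", 4), ("C", 5)],
        n_loci=120,
        beta_a=5.0,
        beta_b=5.0,
        n_private_per_population=4,
        private_carrier_profile="fixed_homozygous",
        locus_dropout_rate=dropout,
    )


def _recall_precision(dropout: float, seed: int = 43) -> tuple[float, float]:
    gm, pmap, truth = simulate(_recovery_config(seed, dropout))
    kept = diagnostic_filter(classify_alleles(gm, pmap), gm, pmap)
    found = {(c.site.locus_id, c.site.column, c.allele, c.carrier_populations[0])
             for c in kept}
    planted = {(r.locus_id, r.column, r.allele, r.population)
               for r in truth.planted.itertuples()}
    recall = len(found & planted) / len(planted)
    precision = len(found & planted) / len(found) if found else 1.0
    return recall, precision


def test_planted_private_alleles_fully_recovered_without_dropout():
    recall, precision = _recall_precision(dropout=0.0)
    assert recall == 1.0 and precision == 1.0


def test_recall_degrades_monotonically_with_dropout():
    recalls = [_recall_precision(d)[0] for d in (0.0, 0.35, 0.7)]
    assert recalls[0] == 1.0
    assert recalls[0] >= recalls[1] >= recalls[2]


def test_all_heterozygous_profile_recovered():
    cfg = _recovery_config(47, 0.0)
    cfg.private_carrier_profile = "all_heterozygous"
    gm, pmap, truth = simulate(cfg)
    kept = diagnostic_filter(classify_alleles(gm, pmap), gm, pmap)
    assert len(kept) == len(truth.planted)
    assert all(c.diagnostic_class == "all_heterozygous" for c in kept)


# -- group contrast ------------------------------------------------------------


def _contrast_fixture(res_genotypes, sus_genotypes, ref):
    genotypes = {f"R{i}": g for i, g in enumerate(res_genotypes)}
    genotypes |= {f"S{i}": g for i, g in enumerate(sus_genotypes)}
    gm = _matrix(genotypes, ref=ref)
    pmap = PopulationMap(
        {ind: ("Resistant" if ind.startswith("R") else "Susceptible")
         for ind in genotypes},
        role="phenotype-contrast")
    return gm, pmap


CONTRAST_ROWS = {
    # locus label -> (focal genotypes incl. dropout, carriers, carrier_fraction
    # over genotyped members, alt-copy frequency)
    "locus781": (("TT", "TT", "TT", "CT", "./.", "./.", "./.", "./."), 4, 1.0, 7 / 8),
    "locus22018": (("AA", "AA", "AA", "TT", "TT", "./.", "./.", "./."), 3, 3 / 5, 6 / 10),
    "locus9218": (("CC", "CC", "CT", "TT", "TT", "TT", "TT", "./."), 5, 5 / 7, 9 / 14),
    "locus18249": (("TC", "TC", "CC", "CC", "./.", "./.", "./.", "./."), 4, 1.0, 6 / 8),
}


@pytest.mark.parametrize("label", list(CONTRAST_ROWS))
def test_group_contrast_recovers_published_resistant_hits(label):
    """Each published resistant-group row yields a hit at the default
    inclusive >= 0.5 carrier threshold over genotyped members."""
    genotypes, carriers, fraction, alt_freq = CONTRAST_ROWS[label]
    ref = "T" if label in ("locus22018", "locus18249") else "C"
    gm, pmap = _contrast_fixture(genotypes, ["CC" if ref == "C" else ref * 2] * 13, ref)
    (hit,) = group_contrast(gm, pmap)
    assert hit.focal_group == "Resistant"
    assert hit.carrier_count == carriers
    assert hit.carrier_fraction == pytest.approx(fraction)
    assert hit.alt_freq == pytest.approx(alt_freq)
    assert hit.absent_in_other


def test_group_contrast_susceptible_hit():
    """The susceptible-private row: 6 homozygous carriers among 9 genotyped
    of 13 members, absent in the resistant group."""
    sus = ("CC", "CC", "CC", "TT", "TT", "TT", "TT", "TT", "TT",
           "./.", "./.", "./.", "./.")
    gm, pmap = _contrast_fixture(["CC"] * 8, sus, "C")
    (hit,) = group_contrast(gm, pmap)
    assert hit.focal_group == "Susceptible"
    assert hit.carrier_count == 6
    assert hit.carrier_fraction == pytest.approx(6 / 9)
    assert hit.homozygote_fraction == 1.0
    # with the nominal-size denominator this row falls below the threshold
    assert group_contrast(gm, pmap, denominator="nominal") == []


def test_group_contrast_requires_absence_in_other_group():
    gm, pmap = _contrast_fixture(["CT", "CC"], ["CT", "CC", "CC"], "C")
    assert group_contrast(gm, pmap) == []


def test_group_contrast_rejects_more_than_two_groups():
    gm = _matrix({"a": "CT", "b": "CC", "c": "CC"})
    pmap = PopulationMap({"a": "X", "b": "Y", "c": "Z"})
    with pytest.raises(GenotypeModelError):
        group_contrast(gm, pmap)
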