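"""Shared fixtures: published per-site genotype configurations.

The per-site rows of the study's common-allele and group-contrast tables
fully determine the underlying genotype configuration (N, the reference
allele frequency and the observed-heterozygote fraction pin down the counts
of each diploid genotype), so each row doubles as an exact oracle for the
per-site statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from radpop import GenotypeMatrix, PopulationMap


@dataclass(frozen=True)
class SiteRow:
    """One published per-site table row and the genotypes it determines."""

    label: str
    population: str
    ref: str
    genotypes: tuple[str, ...]
    p: float
    h_obs: float
    h_exp: float
    pi: float
    f_is: float
    digits: int  # printed precision of pi/f_is in the source table


# rows from the common-allele table (4-decimal pi) and the
# resistant/susceptible contrast table (3-decimal pi)
SITE_ROWS: list[SiteRow] = [
    SiteRow("locus46-Sarıfındık", "Sarıfındık", "A",
            ("AA", "AA", "AA", "TT", "TT"), 0.6, 0.0, 0.48, 0.5333, 1.0, 4),
    SiteRow("locus46-Allahverdi", "Allahverdi", "A",
            ("TT", "TT"), 0.0, 0.0, 0.0, 0.0, 0.0, 4),
    SiteRow("locus4404-Mincane", "Mincane", "C",
            ("CC", "TT"), 0.5, 0.0, 0.5, 0.6667, 1.0, 4),
    SiteRow("locus4404-Tombul_2", "Tombul_2", "C",
            ("CC", "CC", "CC", "TT"), 0.75, 0.0, 0.375, 0.4286, 1.0, 4),
    SiteRow("locus6415-Allahverdi", "Allahverdi", "C",
            ("CT", "CT"), 0.5, 1.0, 0.5, 0.6667, -0.5, 4),
    SiteRow("locus8388-Karafındık", "Karafındık", "G",
            ("GG", "AA"), 0.5, 0.0, 0.5, 0.6667, 1.0, 4),
    SiteRow("locus14093-Sarıfındık", "Sarıfındık", "T",
            ("TT", "TT", "TT", "TT", "CC"), 0.8, 0.0, 0.32, 0.3556, 1.0, 4),
    SiteRow("locus781-Resistant", "Resistant", "C",
            ("TT", "TT", "TT", "CT"), 0.125, 0.25, 0.219, 0.25, 0.0, 3),
    SiteRow("locus22018-Resistant", "Resistant", "T",
            ("AA", "AA", "AA", "TT", "TT"), 0.4, 0.0, 0.48, 0.533, 1.0, 3),
    SiteRow("locus9218-Resistant", "Resistant", "C",
            ("CC", "CC", "CT", "TT", "TT", "TT", "TT"), 0.357, 0.143, 0.459,
            0.495, 0.711, 3),
    SiteRow("locus18249-Resistant", "Resistant", "T",
            ("TC", "TC", "CC", "CC"), 0.25, 0.5, 0.375, 0.429, -0.167, 3),
    SiteRow("locus21961-Susceptible", "Susceptible", "C",
            ("CC", "CC", "CC", "TT", "TT", "TT", "TT", "TT", "TT"), 0.333,
            0.0, 0.444, 0.471, 1.0, 3),
]


def single_site(row: SiteRow) -> tuple[GenotypeMatrix, PopulationMap]:
    gm = GenotypeMatrix.from_site_genotypes(list(row.genotypes), ref=row.ref)
    pmap = PopulationMap({ind: row.population for ind in gm.individuals})
    return gm, pmap


@pytest.fixture(params=SITE_ROWS, ids=lambda r: r.label)
def site_row(request) -> SiteRow:
    return request.param
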