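"""Per-site and per-population summary statistics for genotype catalogs.

Definitions (at one SNP site, within one population, over the N individuals
whose locus was genotyped, i.e. n = 2N called alleles):

* allele frequencies     p_i = count_i / n
* expected heterozygosity  H_exp = 1 - sum_i p_i^2
* nucleotide diversity     pi = (n / (n - 1)) * H_exp
  (the unbiased small-sample correction; equal to the average pairwise
  difference over all n*(n-1)/2 allele pairs)
* observed heterozygosity  H_obs = (# heterozygous individuals) / N
* inbreeding coefficient   F_IS = (pi - H_obs) / pi, defined as 0 when pi = 0

The reported "P" column follows the convention of Stacks-style summary
tables: it is the frequency of the designated P nucleotide, which is the
reference-genome allele whenever the reference allele is present in the
population (it may therefore be the *minor* allele); when the reference
allele is absent P = 0 and no P nucleotide is reported. The within-population
major-allele frequency is additionally exposed as ``p_major``.

Population-level summaries average these per-site statistics over a chosen
site set (polymorphic-in-metapopulation by default) and attach a chi-squared
statistic for the deviation of mean observed from mean expected
heterozygosity/homozygosity:

    chi2 = N * [ (Ho - He)^2 / He + (HOMo - HOMe)^2 / HOMe ],  1 df

with N the number of individuals in the population. p-values are bucketed
as ">0.9", ">0.5" or "<=0.5" for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from radpop.genotype_model import (
    MISSING,
    GenotypeMatrix,
    PopulationMap,
    SNPSite,
)


class SiteAbsentError(ValueError):
    """The site has no called individuals in the requested population."""


class EmptySiteSetError(ValueError):
    """No sites available to summarize."""


@dataclass(frozen=True)
class SiteStats:
    """Per-site, per-population summary statistics (one table row)."""

    population: str
    n_ind: int
    p: float
    p_nuc: str | None
    q_nuc: str | None
    p_major: float
    h_obs: float
    h_exp: float
    pi: float
    f_is: float

    @property
    def hom_obs(self) -> float:
        return 1.0 - self.h_obs

    @property
    def hom_exp(self) -> float:
        return 1.0 - self.h_exp


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    p_value: float
    p_bucket: str
    degenerate: bool = False


@dataclass(frozen=True)
class PopSummary:
    """Population-level means of site statistics plus the chi-squared test."""

    population: str
    n_ind: int
    n_sites: int
    n_private_alleles: int
    mean_p: float
    mean_h_obs: float
    mean_h_exp: float
    mean_pi: float
    mean_f_is: float
    chi2: float
    chi2_p_value: float
    p_bucket: str

    @property
    def mean_hom_obs(self) -> float:
        return 1.0 - self.mean_h_obs

    @property
    def mean_hom_exp(self) -> float:
        return 1.0 - self.mean_h_exp


def _site_index(gm: GenotypeMatrix, site: SNPSite | int) -> int:
    if isinstance(site, int):
        return site
    return gm.sites.index(site)


def site_stats(
    gm: GenotypeMatrix,
    site: SNPSite | int,
    population: str,
    pmap: PopulationMap,
) -> SiteStats:
    """Compute the per-site statistics row for one population.

    N counts individuals of the population with a non-missing call at the
    site; raises :class:`SiteAbsentError` when no member is called.
    """
    j = _site_index(gm, site)
    snp = gm.sites[j]
    idx = gm.individual_index(pmap.members(population))
    calls = gm.calls[j, idx]
    called = calls[:, 0] != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        raise SiteAbsentError(
            f"site {snp.chromosome}:{snp.position_bp} absent in population "
            f"{population!r}"
        )
    calls = calls[called]
    counts = np.bincount(calls.reshape(-1), minlength=len(snp.alleles)).astype(float)
    n_alleles = 2 * n_called
    freqs = counts / n_alleles

    h_exp = 1.0 - float(np.sum(freqs**2))
    pi = h_exp * n_alleles / (n_alleles - 1) if n_alleles > 1 else 0.0
    h_obs = float(np.mean(calls[:, 0] != calls[:, 1]))
    f_is = (pi - h_obs) / pi if pi > 0 else 0.0

    # P nucleotide: the reference allele when present; Q: the most frequent
    # observed alternative (ties broken alphabetically).
    ref_present = counts[0] > 0
    p_nuc = snp.ref_allele if ref_present else None
    alt_observed = [
        (snp.alleles[k], float(freqs[k]))
        for k in range(1, len(snp.alleles))
        if counts[k] > 0
    ]
    q_nuc = None
    if alt_observed:
        top = max(f for _, f in alt_observed)
        # ties broken alphabetically by nucleotide
        q_nuc = min(a for a, f in alt_observed if f == top)
    p = float(freqs[0])
    max_f = float(freqs.max())
    return SiteStats(
        population=population,
        n_ind=n_called,
        p=p,
        p_nuc=p_nuc,
        q_nuc=q_nuc,
        p_major=max_f,
        h_obs=h_obs,
        h_exp=h_exp,
        pi=pi,
        f_is=f_is,
    )


def chi2_het_deviation(
    n_ind: int,
    mean_h_obs: float,
    mean_h_exp: float,
    mean_hom_obs: float | None = None,
    mean_hom_exp: float | None = None,
) -> Chi2Result:
    """Chi-squared deviation of mean observed from mean expected zygosity.

    chi2 = N * [(Ho-He)^2/He + (HOMo-HOMe)^2/HOMe], compared against a
    chi-squared distribution with 1 degree of freedom. Homozygosity means
    default to the complements of the heterozygosity means. A degenerate
    expected heterozygosity of exactly 0 or 1 leaves the statistic
    undefined; 0 is returned with ``degenerate=True``.
    """
    if mean_hom_obs is None:
        mean_hom_obs = 1.0 - mean_h_obs
    if mean_hom_exp is None:
        mean_hom_exp = 1.0 - mean_h_exp
    if mean_h_exp <= 0.0 or mean_h_exp >= 1.0:
        return Chi2Result(chi2=0.0, p_value=1.0, p_bucket=">0.9", degenerate=True)
    chi2 = n_ind * (
        (mean_h_obs - mean_h_exp) ** 2 / mean_h_exp
        + (mean_hom_obs - mean_hom_exp) ** 2 / mean_hom_exp
    )
    p = float(sps.chi2.sf(chi2, df=1))
    if p > 0.9:
        bucket = ">0.9"
    elif p > 0.5:
        bucket = ">0.5"
    else:
        bucket = "<=0.5"
    return Chi2Result(chi2=float(chi2), p_value=p, p_bucket=bucket)


def variant_site_indices(gm: GenotypeMatrix, pmap: PopulationMap) -> list[int]:
    """Sites polymorphic in the metapopulation (>= 2 alleles observed)."""
    idx = gm.individual_index(pmap.assignments.keys())
    out = []
    for j in range(gm.n_sites):
        counts = gm.allele_counts(j, idx)
        if np.count_nonzero(counts) >= 2:
            out.append(j)
    return out


def population_summary(
    gm: GenotypeMatrix,
    pmap: PopulationMap,
    site_set: str = "variant",
    n_fixed_sites: int | None = None,
    site_indices: Sequence[int] | None = None,
) -> list[PopSummary]:
    """Per-population means of site statistics over a chosen site set.

    ``site_set="variant"`` (default) averages over sites polymorphic in the
    metapopulation; ``"all"`` additionally dilutes the means with
    ``n_fixed_sites`` invariant sites (P = 1, all other statistics 0), which
    must then be supplied because invariant RAD columns are typically not
    exported to the genotype matrix. Private-allele counts are attached from
    the allele classifier, and the chi-squared deviation statistic is
    computed from the population means with N = the nominal population size.
    """
    from radpop.allele_discovery import classify_alleles, count_private

    pmap.validate_against(gm)
    if site_set not in ("variant", "all"):
        raise ValueError(f"unknown site_set {site_set!r}")
    if site_set == "all" and n_fixed_sites is None:
        raise ValueError('site_set="all" requires n_fixed_sites')

    if site_indices is None:
        site_indices = variant_site_indices(gm, pmap)
    if not site_indices and not (site_set == "all" and n_fixed_sites):
        raise EmptySiteSetError("no sites to summarize")

    private_counts = count_private(classify_alleles(gm, pmap), pmap)
    sizes = pmap.sizes

    out: list[PopSummary] = []
    for pop in pmap.populations:
        rows: list[SiteStats] = []
        for j in site_indices:
            try:
                rows.append(site_stats(gm, j, pop, pmap))
            except SiteAbsentError:
                continue
        n_var = len(rows)
        n_fixed = n_fixed_sites if site_set == "all" else 0
        n_tot = n_var + (n_fixed or 0)
        if n_tot == 0:
            raise EmptySiteSetError(f"population {pop!r} has no summarizable sites")

        def _mean(values: list[float], fixed_value: float = 0.0) -> float:
            return (sum(values) + (n_fixed or 0) * fixed_value) / n_tot

        mean_p = _mean([r.p for r in rows], fixed_value=1.0)
        mean_h_obs = _mean([r.h_obs for r in rows])
        mean_h_exp = _mean([r.h_exp for r in rows])
        mean_pi = _mean([r.pi for r in rows])
        mean_f_is = _mean([r.f_is for r in rows])
        chi = chi2_het_deviation(sizes[pop], mean_h_obs, mean_h_exp)
        out.append(
            PopSummary(
                population=pop,
                n_ind=sizes[pop],
                n_sites=n_tot,
                n_private_alleles=private_counts.get(pop, 0),
                mean_p=mean_p,
                mean_h_obs=mean_h_obs,
                mean_h_exp=mean_h_exp,
                mean_pi=mean_pi,
                mean_f_is=mean_f_is,
                chi2=chi.chi2,
                chi2_p_value=chi.p_value,
                p_bucket=chi.p_bucket,
            )
        )
    return out


__all__ = [
    "SiteStats",
    "PopSummary",
    "Chi2Result",
    "SiteAbsentError",
    "EmptySiteSetError",
    "site_stats",
    "chi2_het_deviation",
    "population_summary",
    "variant_site_indices",
]
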