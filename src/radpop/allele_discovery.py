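"""Private/common allele classification, diagnostic filters, group contrast.

A *private* allele is a non-reference allele observed (>= 1 copy) in exactly
one sub-population; a *common* allele is a non-reference allele observed in
two or more sub-populations. Classification is by presence, not frequency,
and is always relative to the designated reference genome allele at each
site.

Two filters narrow private alleles to usable diagnostic markers:

* the *diagnostic* filter keeps private alleles whose carrier population is
  uniform — every genotyped member homozygous for the alternative allele
  (``fixed_homozygous``: plausibly fixed in the variety) or every genotyped
  member a heterozygous carrier (``all_heterozygous``: diagnostic but not
  yet fixed);
* the *universal-locus* filter keeps alleles whose RAD locus was genotyped
  in (a configurable fraction of, by default all) individuals across all
  populations, since a marker assayable in every variety is the useful kind.

The *group-contrast* scan specialises classification to a two-group
phenotype map (e.g. disease Resistant vs Susceptible): it reports alleles
present in one group, absent (zero copies) in the other, and carried by at
least ``min_carrier_fraction`` of the focal group (inclusive threshold,
default 0.5). The carrier fraction is computed over the genotyped members of
the group by default; counting over the nominal group size is available via
``denominator="nominal"``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np

from radpop.genotype_model import (
    MISSING,
    GenotypeMatrix,
    GenotypeModelError,
    PopulationMap,
    SNPSite,
)

Category = Literal["private", "common"]
DiagnosticClass = Literal["fixed_homozygous", "all_heterozygous", "none"]


@dataclass(frozen=True)
class AlleleCall:
    """A classified non-reference allele at one SNP site."""

    site: SNPSite
    site_index: int
    allele: str
    category: Category
    carrier_populations: tuple[str, ...]
    locus_universality: float
    diagnostic_class: DiagnosticClass = "none"


@dataclass(frozen=True)
class GroupContrastHit:
    """A non-reference allele frequent in one phenotype group, absent in the other."""

    site: SNPSite
    site_index: int
    allele: str
    focal_group: str
    carrier_count: int
    carrier_fraction: float
    homozygote_fraction: float
    alt_freq: float
    n_called: int
    absent_in_other: bool = True


def _population_indices(
    gm: GenotypeMatrix, pmap: PopulationMap
) -> dict[str, np.ndarray]:
    return {pop: gm.individual_index(pmap.members(pop)) for pop in pmap.populations}


def _locus_universality(gm: GenotypeMatrix, idx_all: np.ndarray) -> dict[int, float]:
    """Fraction of all mapped individuals with each locus genotyped.

    Missingness is locus-level (allele dropout): an individual has the locus
    iff at least one of its SNP columns is called.
    """
    out: dict[int, float] = {}
    for locus_id, site_idx in gm.loci.items():
        has = (gm.calls[np.ix_(site_idx, idx_all)][:, :, 0] != MISSING).any(axis=0)
        out[locus_id] = float(has.mean())
    return out


def classify_alleles(gm: GenotypeMatrix, pmap: PopulationMap) -> list[AlleleCall]:
    """Classify every observed non-reference allele as private or common.

    Each (site, alternative allele) pair with at least one copy among the
    mapped individuals yields exactly one :class:`AlleleCall`; the carrier
    set is the populations holding >= 1 copy. ``diagnostic_class`` is left
    ``"none"``; apply :func:`diagnostic_filter` to assign it.
    """
    pmap.validate_against(gm)
    pop_idx = _population_indices(gm, pmap)
    idx_all = gm.individual_index(pmap.assignments.keys())
    universality = _locus_universality(gm, idx_all)

    calls: list[AlleleCall] = []
    for j, site in enumerate(gm.sites):
        if not site.alt_alleles:
            continue
        counts_by_pop = {
            pop: gm.allele_counts(j, idx) for pop, idx in pop_idx.items()
        }
        for k, allele in enumerate(site.alleles):
            if k == 0:
                continue  # reference allele is never private/common
            carriers = tuple(
                pop for pop in pmap.populations if counts_by_pop[pop][k] > 0
            )
            if not carriers:
                continue
            calls.append(
                AlleleCall(
                    site=site,
                    site_index=j,
                    allele=allele,
                    category="private" if len(carriers) == 1 else "common",
                    carrier_populations=carriers,
                    locus_universality=universality[site.locus_id],
                )
            )
    return calls


def diagnostic_filter(
    calls: Iterable[AlleleCall],
    gm: GenotypeMatrix,
    pmap: PopulationMap,
) -> list[AlleleCall]:
    """Keep private alleles uniform within their carrier population.

    Uniformity is judged over genotyped members only (individuals missing
    the locus are ignored): all homozygous for the alternative allele ->
    ``fixed_homozygous``; all heterozygous carriers of it ->
    ``all_heterozygous``; anything mixed is dropped. Common alleles are
    dropped.
    """
    kept: list[AlleleCall] = []
    for call in calls:
        if call.category != "private":
            continue
        (pop,) = call.carrier_populations
        idx = gm.individual_index(pmap.members(pop))
        site_calls = gm.calls[call.site_index, idx]
        site_calls = site_calls[site_calls[:, 0] != MISSING]
        code = call.site.alleles.index(call.allele)
        hom = (site_calls == code).all(axis=1)
        het = ((site_calls == code).sum(axis=1) == 1)
        if hom.all():
            kept.append(replace(call, diagnostic_class="fixed_homozygous"))
        elif het.all():
            kept.append(replace(call, diagnostic_class="all_heterozygous"))
    return kept


def universal_locus_filter(
    calls: Iterable[AlleleCall],
    min_fraction: float = 1.0,
) -> list[AlleleCall]:
    """Keep calls whose locus was genotyped in >= min_fraction of individuals."""
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    return [c for c in calls if c.locus_universality >= min_fraction]


def count_private(
    calls: Iterable[AlleleCall], pmap: PopulationMap
) -> dict[str, int]:
    """Number of private alleles per carrier population (zeros included)."""
    out = {pop: 0 for pop in pmap.populations}
    for call in calls:
        if call.category == "private":
            out[call.carrier_populations[0]] += 1
    return out


def group_contrast(
    gm: GenotypeMatrix,
    pmap: PopulationMap,
    min_carrier_fraction: float = 0.5,
    denominator: Literal["called", "nominal"] = "called",
) -> list[GroupContrastHit]:
    """Scan a two-group map for alleles private to one group and frequent in it.

    For every non-reference allele with >= 1 copy in exactly one group, the
    carrier fraction is the number of individuals carrying >= 1 copy divided
    by either the genotyped members of the group at that site (default) or
    the nominal group size. Hits require carrier_fraction >=
    ``min_carrier_fraction`` (inclusive). The per-copy alternative-allele
    frequency among called alleles is reported alongside.
    """
    if len(pmap.populations) != 2:
        raise GenotypeModelError(
            "group_contrast requires exactly two populations; use "
            "classify_alleles for varietal maps"
        )
    pmap.validate_against(gm)
    pop_idx = _population_indices(gm, pmap)
    sizes = pmap.sizes

    hits: list[GroupContrastHit] = []
    for j, site in enumerate(gm.sites):
        if not site.alt_alleles:
            continue
        counts = {pop: gm.allele_counts(j, idx) for pop, idx in pop_idx.items()}
        for k, allele in enumerate(site.alleles):
            if k == 0:
                continue
            present = [pop for pop in pmap.populations if counts[pop][k] > 0]
            if len(present) != 1:
                continue
            focal = present[0]
            idx = pop_idx[focal]
            site_calls = gm.calls[j, idx]
            called = site_calls[site_calls[:, 0] != MISSING]
            n_called = len(called)
            copies = (called == k).sum(axis=1)
            carrier_count = int((copies > 0).sum())
            n_hom = int((copies == 2).sum())
            denom = n_called if denominator == "called" else sizes[focal]
            carrier_fraction = carrier_count / denom
            if carrier_fraction < min_carrier_fraction:
                continue
            hits.append(
                GroupContrastHit(
                    site=site,
                    site_index=j,
                    allele=allele,
                    focal_group=focal,
                    carrier_count=carrier_count,
                    carrier_fraction=carrier_fraction,
                    homozygote_fraction=n_hom / carrier_count,
                    alt_freq=float(copies.sum() / (2 * n_called)),
                    n_called=n_called,
                )
            )
    return hits


__all__ = [
    "AlleleCall",
    "GroupContrastHit",
    "classify_alleles",
    "diagnostic_filter",
    "universal_locus_filter",
    "group_contrast",
    "count_private",
]
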