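"""Pairwise F_ST between sub-populations.

Two multi-site estimators are provided, both as ratios of sums over sites
(and over alleles at multi-allelic sites):

* Weir & Cockerham's theta (default): per-allele variance components
  a (among populations), b (among individuals within populations) and
  c (within individuals), with theta = sum(a) / sum(a + b + c);
* Hudson's estimator in the ratio-of-averages form
  sum[(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)] / sum[p1(1-p2) + p2(1-p1)]
  with n the called allele counts.

Sites where either population of a pair has fewer than ``min_called`` (2)
genotyped individuals are excluded from that pair; a pair with no usable
polymorphic site gets a missing (NaN) entry, never a silent 0. Small
negative estimates are a normal property of both estimators and are kept;
clipping to 0 is offered only at serialization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from radpop.genotype_model import (
    MISSING,
    GenotypeMatrix,
    GenotypeModelError,
    PopulationMap,
)

ESTIMATORS = ("weir-cockerham", "hudson")


@dataclass
class FstMatrix:
    """Symmetric pairwise F_ST matrix with per-pair usable-site counts."""

    populations: list[str]
    values: np.ndarray
    per_site_counts: np.ndarray
    estimator: str

    def to_dataframe(self, clip_negative: bool = False) -> pd.DataFrame:
        vals = self.values.copy()
        if clip_negative:
            vals = np.where(np.isnan(vals), np.nan, np.clip(vals, 0.0, None))
        return pd.DataFrame(vals, index=self.populations, columns=self.populations)

    def to_tsv(self, path: str | Path, clip_negative: bool = False) -> None:
        df = self.to_dataframe(clip_negative=clip_negative)
        df.index.name = "population"
        df.to_csv(path, sep="\t", na_rep="NA")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.populations.index(pair[0])
        j = self.populations.index(pair[1])
        return float(self.values[i, j])


def _pair_site_freqs(
    gm: GenotypeMatrix,
    j: int,
    idx1: np.ndarray,
    idx2: np.ndarray,
    min_called: int,
):
    """Called counts, allele frequencies and observed het for one site/pair.

    Returns None when the site is unusable for the pair (too few called
    individuals in either population, or monomorphic across both).
    """
    site = gm.sites[j]
    out = []
    for idx in (idx1, idx2):
        calls = gm.calls[j, idx]
        calls = calls[calls[:, 0] != MISSING]
        if len(calls) < min_called:
            return None
        counts = np.bincount(
            calls.reshape(-1), minlength=len(site.alleles)
        ).astype(float)
        freqs = counts / counts.sum()
        h_obs = float(np.mean(calls[:, 0] != calls[:, 1]))
        out.append((len(calls), freqs, h_obs))
    (n1, f1, h1), (n2, f2, h2) = out
    pooled = f1 * n1 + f2 * n2
    if np.count_nonzero(pooled) < 2:
        return None  # monomorphic in the pair
    return (n1, f1, h1), (n2, f2, h2)


def _wc_components(n1, f1, h1, n2, f2, h2):
    """Weir-Cockerham a, b, c summed over alleles for a two-population pair."""
    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
    a_sum = b_sum = c_sum = 0.0
    for k in range(len(f1)):
        p1, p2 = f1[k], f2[k]
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        # per-allele observed-het fraction: individuals heterozygous *for
        # allele k*; for biallelic sites this equals the plain het fraction
        # for both alleles.
        h_bar = (n1 * h1[k] + n2 * h2[k]) / (r * n_bar)
        pq = p_bar * (1.0 - p_bar)
        a = (n_bar / n_c) * (
            s2 - (pq - s2 * (r - 1.0) / r - h_bar / 4.0) / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            pq - s2 * (r - 1.0) / r - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def _per_allele_het(gm: GenotypeMatrix, j: int, idx: np.ndarray, n_alleles: int):
    """Fraction of called individuals heterozygous for each allele."""
    calls = gm.calls[j, idx]
    calls = calls[calls[:, 0] != MISSING]
    het = calls[:, 0] != calls[:, 1]
    out = np.zeros(n_alleles)
    for k in range(n_alleles):
        carries = (calls == k).sum(axis=1) == 1
        out[k] = np.mean(het & carries)
    return out


def pairwise_fst(
    gm: GenotypeMatrix,
    pmap: PopulationMap,
    estimator: str = "weir-cockerham",
    min_called: int = 2,
) -> FstMatrix:
    """Multi-site pairwise F_ST via ratio of sums of variance components.

    Requires >= 2 populations. Each pair uses the sites where both
    populations have >= ``min_called`` genotyped individuals and the pair is
    jointly polymorphic; the number of such sites is reported per pair.
    Pairs with no usable site get NaN.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    if len(pmap.populations) < 2:
        raise GenotypeModelError("pairwise_fst requires >= 2 populations")
    pmap.validate_against(gm)

    pops = list(pmap.populations)
    idx = {p: gm.individual_index(pmap.members(p)) for p in pops}
    n = len(pops)
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)

    for i1 in range(n):
        for i2 in range(i1 + 1, n):
            num = den = 0.0
            used = 0
            for j in range(gm.n_sites):
                pair = _pair_site_freqs(
                    gm, j, idx[pops[i1]], idx[pops[i2]], min_called
                )
                if pair is None:
                    continue
                (n1, f1, h1), (n2, f2, h2) = pair
                used += 1
                if estimator == "weir-cockerham":
                    ha1 = _per_allele_het(gm, j, idx[pops[i1]], len(f1))
                    ha2 = _per_allele_het(gm, j, idx[pops[i2]], len(f2))
                    a, b, c = _wc_components(n1, f1, ha1, n2, f2, ha2)
                    num += a
                    den += a + b + c
                else:  # hudson
                    an1, an2 = 2.0 * n1, 2.0 * n2
                    for k in range(len(f1)):
                        p1, p2 = f1[k], f2[k]
                        num += (
                            (p1 - p2) ** 2
                            - p1 * (1 - p1) / (an1 - 1.0)
                            - p2 * (1 - p2) / (an2 - 1.0)
                        )
                        den += p1 * (1 - p2) + p2 * (1 - p1)
            counts[i1, i2] = counts[i2, i1] = used
            if used == 0 or den == 0.0:
                values[i1, i2] = values[i2, i1] = np.nan
            else:
                values[i1, i2] = values[i2, i1] = num / den

    return FstMatrix(
        populations=pops, values=values, per_site_counts=counts, estimator=estimator
    )


__all__ = ["FstMatrix", "pairwise_fst", "ESTIMATORS"]
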