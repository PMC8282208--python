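"""Synthetic RAD-seq genotype catalogs with ground-truth bookkeeping.

The generator emulates the downstream product of a reference-aligned ddRAD
pipeline, not the reads: fixed-length (150 bp) loci placed on a small
chromosome layout, each carrying 0-10 SNP columns; per-population
alternative-allele frequencies drawn from a Beta prior; genotypes sampled
with a per-population inbreeding coefficient F via the standard
full-sib-style mixture

    P(hom ref) = p^2 + F p q,  P(het) = 2 p q (1 - F),  P(hom alt) = q^2 + F p q

(negative F truncated to max(F, -p/q, -q/p) so all probabilities stay
non-negative); planted population-private alternative alleles at sites
otherwise monomorphic-reference everywhere else; and locus-level allele
dropout (a dropped locus is missing at *all* its SNP columns for that
individual).

Every random draw for locus ``i`` comes from its own generator seeded by
``(seed, i)``, so growing ``n_loci`` extends a catalog without reshuffling
earlier loci, and the same seed reproduces the catalog byte-for-byte.

A :class:`TruthTable` records what was planted and drawn, so recovery of
private/diagnostic alleles and of F and expected heterozygosity can be
checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from radpop.genotype_model import (
    MISSING,
    DEFAULT_LOCUS_LENGTH,
    GenotypeMatrix,
    PopulationMap,
    SNPSite,
)

NUCS = np.array(list("ACGT"))

#: Sub-population sizes of the hazelnut varietal study this generator
#: emulates (32 individuals, nine named varieties).
STUDY_VARIETY_SIZES: dict[str, int] = {
    "Allahverdi": 2,
    "Çakıldak": 3,
    "Karafındık": 2,
    "Mincane": 2,
    "Palaz": 5,
    "Sarıfındık": 5,
    "Sivri": 4,
    "Tombul": 8,
    "Yomra": 2,
}

#: Powdery-mildew phenotype contrast groups of the same study.
STUDY_CONTRAST_SIZES: dict[str, int] = {"Resistant": 8, "Susceptible": 13}


class SimConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimConfig:
    """Configuration for one synthetic catalog.

    Parameters
    ----------
    seed : int
        Master seed; all randomness derives from it.
    populations : sequence of (name, size)
        Sub-populations and their (diploid) sample sizes.
    n_loci : int
        Number of RAD loci to generate (including SNP-free loci).
    snp_mean, snp_max : float, int
        SNPs per locus ~ min(Poisson(snp_mean), snp_max); loci may carry 0.
    beta_a, beta_b : float
        Beta prior for the per-population alternative-allele frequency at
        each regular SNP column. The default (0.5, 2.0) keeps the reference
        allele major at most sites, as expected for samples aligned to a
        conspecific reference genome.
    fixed_q : float, optional
        When set, every regular SNP column uses this alternative-allele
        frequency in every population instead of drawing from the Beta
        prior (useful for parameter-recovery checks at a known frequency).
    f_is : float or mapping
        Within-population inbreeding coefficient in [-0.5, 1], global or
        per population.
    n_private_per_population : int
        Planted private alternative alleles per population, each on its own
        dedicated locus, monomorphic-reference in all other populations.
    private_carrier_profile : str
        ``fixed_homozygous`` | ``all_heterozygous`` | ``mixed``.
    locus_dropout_rate : float
        Per-(locus, individual) probability the locus is unsequenced.
    chromosomes : sequence of (name, length_bp)
        Layout for coordinate assignment; loci placed proportionally to
        length, uniformly within a chromosome.
    locus_length : int
        Length of each RAD tag in bp (fixes the valid SNP column range).
    role : str
        Role recorded on the emitted population map.
    """

    seed: int
    populations: Sequence[tuple[str, int]] = field(
        default_factory=lambda: tuple(STUDY_VARIETY_SIZES.items())
    )
    n_loci: int = 500
    snp_mean: float = 2.0
    snp_max: int = 10
    beta_a: float = 0.5
    beta_b: float = 2.0
    fixed_q: float | None = None
    f_is: float | Mapping[str, float] = 0.0
    n_private_per_population: int = 0
    private_carrier_profile: str = "fixed_homozygous"
    locus_dropout_rate: float = 0.0
    chromosomes: Sequence[tuple[str, int]] = (
        ("1", 5_000_000),
        ("2", 4_000_000),
        ("3", 3_000_000),
    )
    locus_length: int = DEFAULT_LOCUS_LENGTH
    role: str = "varietal"

    def f_for(self, pop: str) -> float:
        if isinstance(self.f_is, Mapping):
            return float(self.f_is[pop])
        return float(self.f_is)

    def validate(self) -> None:
        if not self.populations:
            raise SimConfigError("at least one population required")
        if any(size < 1 for _, size in self.populations):
            raise SimConfigError("population sizes must be >= 1")
        for pop, _ in self.populations:
            f = self.f_for(pop)
            if not -0.5 <= f <= 1.0:
                raise SimConfigError(f"f_is for {pop!r} outside [-0.5, 1]")
        if self.fixed_q is not None and not 0.0 < self.fixed_q < 1.0:
            raise SimConfigError("fixed_q must be in (0, 1)")
        if not 0.0 <= self.locus_dropout_rate < 1.0:
            raise SimConfigError("locus_dropout_rate must be in [0, 1)")
        if self.private_carrier_profile not in (
            "fixed_homozygous",
            "all_heterozygous",
            "mixed",
        ):
            raise SimConfigError(
                f"unknown private_carrier_profile {self.private_carrier_profile!r}"
            )
        n_private_loci = self.n_private_per_population * len(self.populations)
        if n_private_loci > self.n_loci:
            raise SimConfigError(
                f"{n_private_loci} private loci requested but only "
                f"{self.n_loci} loci configured"
            )
        if self.snp_max < 1 and (self.n_private_per_population > 0):
            raise SimConfigError("planted alleles require snp_max >= 1")
        if any(length <= self.locus_length for _, length in self.chromosomes):
            raise SimConfigError("chromosome shorter than one locus")


@dataclass
class TruthTable:
    """Ground truth emitted alongside a simulated catalog.

    ``planted``: one row per planted private allele (locus, column, allele,
    carrier population, intended diagnostic class). ``loci``: chromosome
    placement and SNP count per locus. ``population_truth``: configured F
    and the mean expected heterozygosity implied by the drawn frequencies.
    ``site_freqs``: the drawn per-population alternative-allele frequency
    for every regular SNP column (NaN for planted columns, which are not
    frequency-driven).
    """

    planted: pd.DataFrame
    loci: pd.DataFrame
    population_truth: pd.DataFrame
    site_freqs: pd.DataFrame


class SimResult(NamedTuple):
    genotypes: GenotypeMatrix
    popmap: PopulationMap
    truth: TruthTable


def _locus_rng(seed: int, locus_index: int) -> np.random.Generator:
    # keyed per locus so earlier loci are invariant to n_loci
    return np.random.default_rng([seed, locus_index])


def _sample_pop_genotypes(
    rng: np.random.Generator, size: int, q: float, f: float
) -> np.ndarray:
    """Diploid genotypes (codes 0=ref,1=alt per chromosome) for one population."""
    p = 1.0 - q
    if q in (0.0, 1.0):
        f_eff = f
    else:
        f_eff = max(f, -p / q, -q / p)
    probs = np.array(
        [
            p * p + f_eff * p * q,
            2.0 * p * q * (1.0 - f_eff),
            q * q + f_eff * p * q,
        ]
    )
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    dosage = rng.choice(3, size=size, p=probs)
    out = np.zeros((size, 2), dtype=np.int8)
    out[dosage == 1, 1] = 1
    out[dosage == 2] = 1
    return out


def simulate(config: SimConfig) -> SimResult:
    """Generate a genotype catalog, population map and truth table."""
    config.validate()
    pops = [name for name, _ in config.populations]
    sizes = dict(config.populations)
    individuals: list[str] = []
    assignments: dict[str, str] = {}
    for pop, size in config.populations:
        for i in range(1, size + 1):
            name = f"{pop}_{i}"
            individuals.append(name)
            assignments[name] = pop
    pop_slices: dict[str, np.ndarray] = {}
    offset = 0
    for pop, size in config.populations:
        pop_slices[pop] = np.arange(offset, offset + size)
        offset += size
    n_ind = offset

    chrom_names = [c for c, _ in config.chromosomes]
    chrom_lengths = np.array([l for _, l in config.chromosomes], dtype=float)
    chrom_probs = chrom_lengths / chrom_lengths.sum()

    # plan planted private alleles: one dedicated locus each, spread across
    # the locus index range so placement stays representative
    n_planted = config.n_private_per_population * len(pops)
    planted_locus_pop: dict[int, str] = {}
    if n_planted:
        planted_idx = np.linspace(0, config.n_loci - 1, n_planted).astype(int)
        for m, locus_index in enumerate(planted_idx):
            planted_locus_pop[int(locus_index)] = pops[m % len(pops)]

    sites: list[SNPSite] = []
    rows: list[np.ndarray] = []
    planted_rows: list[dict] = []
    locus_rows: list[dict] = []
    freq_rows: list[dict] = []

    for locus_index in range(config.n_loci):
        rng = _locus_rng(config.seed, locus_index)
        locus_id = locus_index + 1
        ci = rng.choice(len(chrom_names), p=chrom_probs)
        chrom = chrom_names[ci]
        start = int(rng.integers(1, int(chrom_lengths[ci]) - config.locus_length + 1))

        planted_pop = planted_locus_pop.get(locus_index)
        n_snps = int(min(rng.poisson(config.snp_mean), config.snp_max))
        if planted_pop is not None:
            n_snps = max(n_snps, 1)
        locus_rows.append(
            {
                "locus_id": locus_id,
                "chromosome": chrom,
                "locus_start_bp": start,
                "n_snps": n_snps,
            }
        )
        if n_snps == 0:
            continue

        columns = np.sort(
            rng.choice(config.locus_length, size=n_snps, replace=False)
        )
        planted_col = int(rng.choice(columns)) if planted_pop is not None else None

        dropout = (
            rng.random(n_ind) < config.locus_dropout_rate
            if config.locus_dropout_rate > 0
            else np.zeros(n_ind, dtype=bool)
        )

        for col in columns:
            ref, alt = rng.choice(NUCS, size=2, replace=False)
            calls = np.zeros((n_ind, 2), dtype=np.int8)
            is_planted = planted_pop is not None and col == planted_col
            if is_planted:
                idx = pop_slices[planted_pop]
                profile = config.private_carrier_profile
                if profile == "fixed_homozygous":
                    calls[idx] = 1
                elif profile == "all_heterozygous":
                    calls[idx, 1] = 1
                else:  # mixed: every member carries, zygosity random
                    hom = rng.random(len(idx)) < 0.5
                    calls[idx, 1] = 1
                    calls[idx[hom], 0] = 1
                planted_rows.append(
                    {
                        "locus_id": locus_id,
                        "chromosome": chrom,
                        "position_bp": start + int(col),
                        "column": int(col),
                        "ref_allele": ref,
                        "allele": alt,
                        "population": planted_pop,
                        "profile": profile,
                    }
                )
            else:
                freqs = {}
                for pop in pops:
                    q = (
                        float(config.fixed_q)
                        if config.fixed_q is not None
                        else float(rng.beta(config.beta_a, config.beta_b))
                    )
                    freqs[pop] = q
                    calls[pop_slices[pop]] = _sample_pop_genotypes(
                        rng, sizes[pop], q, config.f_for(pop)
                    )
                freq_rows.append(
                    {
                        "locus_id": locus_id,
                        "column": int(col),
                        **{f"q_{pop}": freqs[pop] for pop in pops},
                    }
                )
            calls[dropout] = MISSING
            # the drawn alternative stays declared even when unobserved in
            # the sample, mirroring a catalog built against a larger panel
            sites.append(
                SNPSite(
                    locus_id=locus_id,
                    chromosome=chrom,
                    position_bp=start + int(col),
                    column=int(col),
                    ref_allele=str(ref),
                    alt_alleles=(str(alt),),
                    locus_start_bp=start,
                )
            )
            rows.append(calls)

    calls_arr = (
        np.stack(rows) if rows else np.empty((0, n_ind, 2), dtype=np.int8)
    )
    gm = GenotypeMatrix(individuals, sites, calls_arr)
    pmap = PopulationMap(assignments=assignments, role=config.role)

    # population-level truth: configured F and mean expected heterozygosity
    # implied by the drawn frequencies, E[2q(1-q)] over regular SNP columns
    freq_df = pd.DataFrame(freq_rows)
    pop_truth_rows = []
    for pop in pops:
        qcol = f"q_{pop}"
        qs = freq_df[qcol].to_numpy() if len(freq_df) else np.array([])
        pop_truth_rows.append(
            {
                "population": pop,
                "n_ind": sizes[pop],
                "true_f": config.f_for(pop),
                "mean_h_exp": float(np.mean(2 * qs * (1 - qs))) if len(qs) else np.nan,
            }
        )

    truth = TruthTable(
        planted=pd.DataFrame(
            planted_rows,
            columns=[
                "locus_id",
                "chromosome",
                "position_bp",
                "column",
                "ref_allele",
                "allele",
                "population",
                "profile",
            ],
        ),
        loci=pd.DataFrame(locus_rows),
        population_truth=pd.DataFrame(pop_truth_rows),
        site_freqs=freq_df,
    )
    return SimResult(genotypes=gm, popmap=pmap, truth=truth)


def study_variety_config(seed: int, **overrides) -> SimConfig:
    """A study-shaped varietal config: nine populations, 32 individuals."""
    params = dict(
        seed=seed,
        populations=tuple(STUDY_VARIETY_SIZES.items()),
        role="varietal",
    )
    params.update(overrides)
    return SimConfig(**params)


def study_contrast_config(seed: int, **overrides) -> SimConfig:
    """A study-shaped phenotype contrast config: 8 vs 13 individuals."""
    params = dict(
        seed=seed,
        populations=tuple(STUDY_CONTRAST_SIZES.items()),
        role="phenotype-contrast",
    )
    params.update(overrides)
    return SimConfig(**params)


__all__ = [
    "SimConfig",
    "SimConfigError",
    "TruthTable",
    "SimResult",
    "simulate",
    "study_variety_config",
    "study_contrast_config",
    "STUDY_VARIETY_SIZES",
    "STUDY_CONTRAST_SIZES",
]
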