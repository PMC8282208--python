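"""Domain types and I/O for RAD-seq genotype catalogs.

The in-memory model mirrors what a reference-aligned RAD pipeline produces:
fixed-length loci (150 bp tags in the hazelnut study this package was built
around), each carrying zero or more SNP columns, genotyped as unordered
diploid allele pairs across named individuals, with locus-level missingness
(allele dropout: a restriction-site mutation removes the whole tag for an
individual, not single SNPs).

Coordinate conventions
----------------------
* ``position_bp`` and ``locus_start_bp`` are 1-based genome coordinates.
* ``column`` is the 0-based offset of the SNP within the locus sequence,
  so ``position_bp == locus_start_bp + column``.

The reference allele is authoritative from input (the VCF REF field keyed to
the reference genome assembly); it is never re-inferred from sample
frequencies, because private/common allele classification is defined
relative to the reference genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")
MISSING = -1
DEFAULT_LOCUS_LENGTH = 150


class GenotypeModelError(ValueError):
    """Raised for malformed genotype inputs (ploidy, alleles, duplicates)."""


@dataclass(frozen=True)
class SNPSite:
    """One polymorphic column within a RAD locus.

    Parameters
    ----------
    locus_id : int
        Integer identifier of the RAD locus the SNP belongs to.
    chromosome : str
        Chromosome (pseudomolecule) label, or ``"NA"`` for unplaced loci.
    position_bp : int
        1-based genome position of the SNP.
    column : int
        0-based offset of the SNP within the locus sequence.
    ref_allele : str
        Nucleotide of the reference genome at this position.
    alt_alleles : tuple of str
        Observed non-reference nucleotides (order as given in input).
    locus_start_bp : int, optional
        1-based genome position of the first base of the locus. When given,
        ``position_bp == locus_start_bp + column`` must hold.
    """

    locus_id: int
    chromosome: str
    position_bp: int
    column: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    locus_start_bp: int | None = None

    def __post_init__(self) -> None:
        if self.ref_allele not in NUCLEOTIDES:
            raise GenotypeModelError(
                f"reference allele {self.ref_allele!r} at "
                f"{self.chromosome}:{self.position_bp} is not one of A,C,G,T"
            )
        for a in self.alt_alleles:
            if a not in NUCLEOTIDES:
                raise GenotypeModelError(
                    f"alternative allele {a!r} at "
                    f"{self.chromosome}:{self.position_bp} is not one of A,C,G,T"
                )
        if self.ref_allele in self.alt_alleles:
            raise GenotypeModelError(
                f"reference allele {self.ref_allele} repeated among alternatives "
                f"at {self.chromosome}:{self.position_bp}"
            )
        if len(set(self.alt_alleles)) != len(self.alt_alleles):
            raise GenotypeModelError(
                f"duplicate alternative alleles at {self.chromosome}:{self.position_bp}"
            )
        if self.column < 0:
            raise GenotypeModelError("column offsets are 0-based and non-negative")
        if (
            self.locus_start_bp is not None
            and self.position_bp != self.locus_start_bp + self.column
        ):
            raise GenotypeModelError(
                f"site {self.chromosome}:{self.position_bp}: position does not equal "
                f"locus_start_bp + column ({self.locus_start_bp} + {self.column})"
            )

    @property
    def alleles(self) -> tuple[str, ...]:
        """Reference allele followed by alternatives; call codes index this."""
        return (self.ref_allele, *self.alt_alleles)

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alt_alleles) > 1


class GenotypeMatrix:
    """Diploid genotype calls for individuals at SNP sites, grouped by locus.

    Calls are stored as an ``(n_sites, n_individuals, 2)`` int8 array of
    allele codes indexing :attr:`SNPSite.alleles` (0 = reference); both
    entries are ``-1`` for a missing call. Allele pairs are unordered; the
    stored order is normalised (sorted) so equality is well defined.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        sites: Sequence[SNPSite],
        calls: np.ndarray,
    ) -> None:
        self.individuals: list[str] = list(individuals)
        if len(set(self.individuals)) != len(self.individuals):
            raise GenotypeModelError("duplicate individual identifiers")
        self.sites: list[SNPSite] = list(sites)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.sites), len(self.individuals), 2):
            raise GenotypeModelError(
                f"calls shape {calls.shape} does not match "
                f"({len(self.sites)} sites, {len(self.individuals)} individuals, 2)"
            )
        # normalise unordered pairs and validate codes
        calls = np.sort(calls, axis=2)
        half_missing = (calls == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise GenotypeModelError("half-missing diploid calls are not allowed")
        for j, site in enumerate(self.sites):
            if calls[j].max(initial=MISSING) >= len(site.alleles):
                raise GenotypeModelError(
                    f"call at site {site.chromosome}:{site.position_bp} indexes an "
                    f"allele beyond the site's allele list"
                )
        self.calls = calls
        self._index = {name: i for i, name in enumerate(self.individuals)}

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_site_genotypes(
        cls,
        genotype_strings: Sequence[str],
        ref: str,
        alts: Sequence[str] | None = None,
        individuals: Sequence[str] | None = None,
        chromosome: str = "1",
        locus_id: int = 1,
        column: int = 0,
        position_bp: int = 1,
        locus_start_bp: int | None = None,
    ) -> "GenotypeMatrix":
        """Build a single-site matrix from genotype strings like ``"CT"``.

        ``"./."`` (or ``"--"``) denotes a missing call. Alternative alleles
        default to every non-reference nucleotide observed in the genotypes.
        Convenient for reconstructing the small per-site configurations that
        published summary tables fully determine.
        """
        observed: list[str] = []
        for g in genotype_strings:
            if g not in ("./.", "--"):
                if len(g) != 2:
                    raise GenotypeModelError(f"genotype string {g!r} is not diploid")
                observed.extend(g)
        if alts is None:
            alts = sorted(set(observed) - {ref})
        site = SNPSite(
            locus_id=locus_id,
            chromosome=chromosome,
            position_bp=position_bp,
            column=column,
            ref_allele=ref,
            alt_alleles=tuple(alts),
            locus_start_bp=locus_start_bp,
        )
        code = {a: i for i, a in enumerate(site.alleles)}
        if individuals is None:
            individuals = [f"ind{i + 1}" for i in range(len(genotype_strings))]
        calls = np.full((1, len(genotype_strings), 2), MISSING, dtype=np.int8)
        for i, g in enumerate(genotype_strings):
            if g in ("./.", "--"):
                continue
            calls[0, i] = [code[g[0]], code[g[1]]]
        return cls(individuals, [site], calls)

    # -- basic queries ---------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def loci(self) -> dict[int, list[int]]:
        """Mapping locus_id -> site indices, in site order."""
        out: dict[int, list[int]] = {}
        for j, site in enumerate(self.sites):
            out.setdefault(site.locus_id, []).append(j)
        return out

    def individual_index(self, names: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._index[n] for n in names], dtype=int)
        except KeyError as exc:
            raise GenotypeModelError(f"unknown individual {exc.args[0]!r}") from exc

    def is_called(self, site_index: int) -> np.ndarray:
        """Boolean vector over individuals: non-missing at this site."""
        return self.calls[site_index, :, 0] != MISSING

    def has_locus(self, locus_id: int) -> np.ndarray:
        """An individual has a locus iff >= 1 of its sites is called for it."""
        site_idx = self.loci[locus_id]
        return (self.calls[site_idx, :, 0] != MISSING).any(axis=0)

    def allele_counts(
        self, site_index: int, individual_idx: np.ndarray | None = None
    ) -> np.ndarray:
        """Counts of each allele code (length = n alleles at the site)."""
        site = self.sites[site_index]
        calls = self.calls[site_index]
        if individual_idx is not None:
            calls = calls[individual_idx]
        flat = calls.reshape(-1)
        flat = flat[flat != MISSING]
        return np.bincount(flat, minlength=len(site.alleles))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.sites == other.sites
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_individuals} individuals, "
            f"{self.n_sites} sites, {len(self.loci)} loci)"
        )


@dataclass
class PopulationMap:
    """Assignment of individuals to named sub-populations.

    ``role`` distinguishes a varietal map (many named varieties) from a
    two-group phenotype contrast (e.g. Resistant vs Susceptible); the
    group-contrast scan requires the latter shape.
    """

    assignments: dict[str, str]
    role: str = "varietal"
    populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.assignments:
            raise GenotypeModelError("population map is empty")
        if self.role not in ("varietal", "phenotype-contrast"):
            raise GenotypeModelError(f"unknown population-map role {self.role!r}")
        if not self.populations:
            seen: list[str] = []
            for pop in self.assignments.values():
                if pop not in seen:
                    seen.append(pop)
            self.populations = seen
        if set(self.populations) != set(self.assignments.values()):
            raise GenotypeModelError("populations list inconsistent with assignments")

    @property
    def sizes(self) -> dict[str, int]:
        out = {p: 0 for p in self.populations}
        for pop in self.assignments.values():
            out[pop] += 1
        return out

    def members(self, population: str) -> list[str]:
        if population not in self.populations:
            raise GenotypeModelError(f"unknown population {population!r}")
        return [ind for ind, pop in self.assignments.items() if pop == population]

    def validate_against(self, gm: GenotypeMatrix) -> None:
        """Every individual in the matrix must appear exactly once in the map."""
        missing = set(gm.individuals) - set(self.assignments)
        if missing:
            raise GenotypeModelError(
                f"individuals absent from the population map: {sorted(missing)}"
            )


@dataclass
class ChromosomeTable:
    """Per-chromosome locus/SNP counts and densities, plus an unplaced bucket.

    ``table`` has columns ``chrom, length_bp, n_snps, n_loci, loci_per_mb``
    (density rounded to integer for reporting, as in published per-chromosome
    summaries). Unplaced ("NA") sites contribute only a SNP count.
    """

    table: pd.DataFrame
    na_snps: int
    total_snps: int
    total_loci: int

    @property
    def mean_density(self) -> float:
        """Mean of per-chromosome densities (loci per Mb)."""
        return float(self.table["loci_per_mb"].mean())

    @property
    def overall_density(self) -> float:
        """Total placed loci divided by total assembly length in Mb."""
        return float(
            self.table["n_loci"].sum() / (self.table["length_bp"].sum() / 1e6)
        )

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# -- population map I/O --------------------------------------------------------


def read_population_map(path: str | Path, role: str = "varietal") -> PopulationMap:
    """Read a two-column (individual, population) delimited text file.

    Tab- or whitespace-delimited; population order is first-appearance order.
    Duplicated individuals and empty files are errors.
    """
    assignments: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise GenotypeModelError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            ind, pop = parts
            if ind in assignments:
                raise GenotypeModelError(
                    f"{path}:{lineno}: individual {ind!r} assigned twice"
                )
            assignments[ind] = pop
    if not assignments:
        raise GenotypeModelError(f"population map {path} is empty")
    return PopulationMap(assignments=assignments, role=role)


def write_population_map(pmap: PopulationMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ind, pop in pmap.assignments.items():
            fh.write(f"{ind}\t{pop}\n")


# -- VCF I/O -------------------------------------------------------------------


def read_vcf(
    path: str | Path,
    locus_window: int = DEFAULT_LOCUS_LENGTH,
) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF into a :class:`GenotypeMatrix`.

    The reference allele is taken from the REF column. Locus membership is
    taken from the ``LOCUS`` INFO key when present (with optional ``LSTART``
    for the locus start and ``COL`` for the intra-locus column); otherwise
    sites are grouped greedily per chromosome: a site within ``locus_window``
    bp of the first site of the current group joins it. Sites whose REF or
    ALT contain characters outside A,C,G,T (indels, symbolic alleles) are
    skipped with a warning. Missing genotypes (``./.``) map to MISSING;
    non-diploid GT entries are a hard error naming individual and site.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    sites: list[SNPSite] = []
    rows: list[np.ndarray] = []

    auto_locus = 0
    group_chrom: str | None = None
    group_start: int | None = None

    for variant in vcf:
        ref = variant.REF
        alts = tuple(variant.ALT)
        if ref not in NUCLEOTIDES or any(a not in NUCLEOTIDES for a in alts):
            logger.warning(
                "skipping site %s:%d: alleles outside {A,C,G,T} (REF=%s ALT=%s)",
                variant.CHROM,
                variant.POS,
                ref,
                ",".join(alts) or ".",
            )
            continue

        info_locus = variant.INFO.get("LOCUS")
        if info_locus is not None:
            locus_id = int(info_locus)
            lstart = variant.INFO.get("LSTART")
            locus_start = int(lstart) if lstart is not None else None
            col = variant.INFO.get("COL")
            if col is not None:
                column = int(col)
            elif locus_start is not None:
                column = variant.POS - locus_start
            else:
                column = 0
        else:
            if group_chrom != variant.CHROM or variant.POS >= group_start + locus_window:
                auto_locus += 1
                group_chrom = variant.CHROM
                group_start = variant.POS
            locus_id = auto_locus
            locus_start = group_start
            column = variant.POS - group_start

        site = SNPSite(
            locus_id=locus_id,
            chromosome=variant.CHROM,
            position_bp=variant.POS,
            column=column,
            ref_allele=ref,
            alt_alleles=alts,
            locus_start_bp=locus_start,
        )

        row = np.full((len(individuals), 2), MISSING, dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]  # last element is the phased flag
            if len(alleles) != 2:
                raise GenotypeModelError(
                    f"non-diploid genotype for individual {individuals[i]!r} at "
                    f"{variant.CHROM}:{variant.POS}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                continue
            row[i] = alleles
        sites.append(site)
        rows.append(row)

    calls = (
        np.stack(rows)
        if rows
        else np.empty((0, len(individuals), 2), dtype=np.int8)
    )
    return GenotypeMatrix(individuals, sites, calls)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF 4.2 with locus bookkeeping in INFO.

    Emits ``LOCUS``, ``COL`` and (when known) ``LSTART`` INFO keys so a
    round trip through :func:`read_vcf` reconstructs the same matrix.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=radpop\n")
        fh.write('##INFO=<ID=LOCUS,Number=1,Type=Integer,Description="RAD locus ID">\n')
        fh.write(
            '##INFO=<ID=COL,Number=1,Type=Integer,'
            'Description="0-based SNP column within the locus">\n'
        )
        fh.write(
            '##INFO=<ID=LSTART,Number=1,Type=Integer,'
            'Description="1-based genome position of the locus start">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chromosome for s in gm.sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individuals)
            + "\n"
        )
        for j, site in enumerate(gm.sites):
            info = f"LOCUS={site.locus_id};COL={site.column}"
            if site.locus_start_bp is not None:
                info += f";LSTART={site.locus_start_bp}"
            alt = ",".join(site.alt_alleles) if site.alt_alleles else "."
            gts = []
            for i in range(gm.n_individuals):
                a, b = gm.calls[j, i]
                gts.append("./." if a == MISSING else f"{a}/{b}")
            fh.write(
                f"{site.chromosome}\t{site.position_bp}\t.\t{site.ref_allele}\t"
                f"{alt}\t.\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )


# -- catalog density summary ---------------------------------------------------


def chromosome_table_from_counts(
    snp_counts: Mapping[str, int],
    locus_counts: Mapping[str, int],
    chrom_lengths: Mapping[str, int],
    na_snps: int = 0,
) -> ChromosomeTable:
    """Build a :class:`ChromosomeTable` from per-chromosome counts.

    Useful both internally (from a genotype matrix) and for published
    per-chromosome count tables where the genotype data themselves are not
    at hand. Densities are reported rounded to integer loci per Mb.
    """
    records = []
    for chrom in snp_counts:
        if chrom not in chrom_lengths:
            raise GenotypeModelError(f"no length supplied for chromosome {chrom!r}")
        length = int(chrom_lengths[chrom])
        if length <= 0:
            raise GenotypeModelError(f"chromosome {chrom!r} has non-positive length")
        n_loci = int(locus_counts[chrom])
        records.append(
            {
                "chrom": chrom,
                "length_bp": length,
                "n_snps": int(snp_counts[chrom]),
                "n_loci": n_loci,
                "loci_per_mb": int(round(n_loci / (length / 1e6))),
            }
        )
    table = pd.DataFrame(
        records, columns=["chrom", "length_bp", "n_snps", "n_loci", "loci_per_mb"]
    )
    return ChromosomeTable(
        table=table,
        na_snps=int(na_snps),
        total_snps=int(sum(snp_counts.values())) + int(na_snps),
        total_loci=int(sum(locus_counts.values())),
    )


def catalog_summary(
    gm: GenotypeMatrix, chrom_lengths: Mapping[str, int]
) -> ChromosomeTable:
    """Per-chromosome SNP counts, distinct-locus counts and loci/Mb density.

    Every chromosome appearing in the catalog must have a length in
    ``chrom_lengths``, except the literal label ``"NA"`` which collects
    unplaced sites into a SNP-count-only bucket.
    """
    snps: dict[str, int] = {}
    loci: dict[str, set[int]] = {}
    na_snps = 0
    na_loci: set[int] = set()
    for site in gm.sites:
        if site.chromosome == "NA":
            na_snps += 1
            na_loci.add(site.locus_id)
            continue
        snps[site.chromosome] = snps.get(site.chromosome, 0) + 1
        loci.setdefault(site.chromosome, set()).add(site.locus_id)

    table = chromosome_table_from_counts(
        snps,
        {c: len(s) for c, s in loci.items()},
        chrom_lengths,
        na_snps=na_snps,
    )
    table.total_loci = len(gm.loci)
    return table


__all__ = [
    "MISSING",
    "NUCLEOTIDES",
    "GenotypeModelError",
    "SNPSite",
    "GenotypeMatrix",
    "PopulationMap",
    "ChromosomeTable",
    "read_vcf",
    "write_vcf",
    "read_population_map",
    "write_population_map",
    "catalog_summary",
    "chromosome_table_from_counts",
]
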