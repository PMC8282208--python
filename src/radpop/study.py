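"""Published summary constants of the hazelnut ddRAD catalog.

The Turkish hazelnut varietal study this package was built around genotyped
a catalog of 472,140 consensus 150 bp RAD loci carrying 1,048,575 SNPs,
aligned to the 11 pseudochromosomes of the 'Tombul' reference genome
assembly (GCA_901000735.1). The per-chromosome SNP and locus counts below
are that study's published distribution; unplaced sites form the ``NA``
bucket (SNP count only).

The chromosome lengths that yielded the published loci/Mb densities were
not published. ``RECONSTRUCTED_CHROM_LENGTHS`` are synthetic stand-ins,
back-calculated as ``n_loci / density`` (in Mb, rounded to bp) from the
published counts and densities; they are self-consistent with the published
density column but are NOT the true assembly lengths.
"""

from __future__ import annotations

import pandas as pd

#: Per-chromosome (n_snps, n_loci, loci_per_mb) of the published catalog.
CHROMOSOME_CATALOG: dict[str, tuple[int, int, int]] = {
    "1": (134502, 61813, 1213),
    "2": (126956, 60694, 1193),
    "3": (99283, 49135, 1235),
    "4": (103804, 46402, 1259),
    "5": (97803, 45901, 1252),
    "6": (85327, 36265, 1198),
    "7": (85690, 40451, 1338),
    "8": (68405, 31939, 1239),
    "9": (68374, 30931, 1329),
    "10": (61963, 29783, 1310),
    "11": (63297, 27213, 1293),
}

#: SNPs on unplaced scaffolds.
NA_SNPS: int = 53171

TOTAL_SNPS: int = 1_048_575
TOTAL_LOCI: int = 472_140

#: Synthetic chromosome lengths back-calculated from published counts and
#: densities (see module docstring); bp.
RECONSTRUCTED_CHROM_LENGTHS: dict[str, int] = {
    chrom: round(n_loci / density * 1e6)
    for chrom, (_, n_loci, density) in CHROMOSOME_CATALOG.items()
}


def published_snp_counts() -> dict[str, int]:
    return {c: v[0] for c, v in CHROMOSOME_CATALOG.items()}


def published_locus_counts() -> dict[str, int]:
    return {c: v[1] for c, v in CHROMOSOME_CATALOG.items()}


def published_density_table() -> pd.DataFrame:
    """The published per-chromosome table with reconstructed lengths attached."""
    rows = [
        {
            "chrom": chrom,
            "length_bp": RECONSTRUCTED_CHROM_LENGTHS[chrom],
            "n_snps": n_snps,
            "n_loci": n_loci,
            "loci_per_mb": density,
        }
        for chrom, (n_snps, n_loci, density) in CHROMOSOME_CATALOG.items()
    ]
    return pd.DataFrame(rows)


__all__ = [
    "CHROMOSOME_CATALOG",
    "NA_SNPS",
    "TOTAL_SNPS",
    "TOTAL_LOCI",
    "RECONSTRUCTED_CHROM_LENGTHS",
    "published_snp_counts",
    "published_locus_counts",
    "published_density_table",
]
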