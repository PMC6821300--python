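"""Site extraction, outgroup polarization, pattern classification, windowing.

Coordinates are 0-based half-open throughout.  Heterozygous/ambiguity
codes and gaps are treated as missing; missingness is assessed listwise
within the taxa under consideration (typically the active quartet), so a
column unusable for one quartet may still serve another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class BiallelicSite:
    """One polarizable alignment column or genomic SNP."""

    block_id: str
    position: int
    allele_by_taxon: tuple[tuple[str, str], ...]  # (taxon, base) pairs

    def base(self, taxon: str) -> str:
        for t, b in self.allele_by_taxon:
            if t == taxon:
                return b
        raise KeyError(taxon)


@dataclass
class SiteExtractionStats:
    n_columns: int = 0
    n_biallelic: int = 0
    n_monomorphic: int = 0
    n_multiallelic: int = 0
    n_missing: int = 0


def extract_biallelic_sites(
    alignment: dict[str, str],
    taxa,
    block_id: str = "",
    stats: SiteExtractionStats | None = None,
) -> list[BiallelicSite]:
    """Columns with exactly two bases among ``taxa`` and no gap/N in any of them.

    ``alignment`` maps taxon label to an aligned sequence; all rows must
    have equal length.  Columns with >= 3 alleles, a single allele, or any
    missing call among ``taxa`` are excluded (and tallied in ``stats``).
    """
    taxa = list(taxa)
    seqs = [alignment[t].upper() for t in taxa]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: unequal row lengths")
    (length,) = lengths
    sites = []
    for col in range(length):
        bases = [s[col] for s in seqs]
        if stats is not None:
            stats.n_columns += 1
        if any(b not in _VALID for b in bases):
            if stats is not None:
                stats.n_missing += 1
            continue
        alleles = set(bases)
        if len(alleles) == 1:
            if stats is not None:
                stats.n_monomorphic += 1
            continue
        if len(alleles) > 2:
            if stats is not None:
                stats.n_multiallelic += 1
            continue
        if stats is not None:
            stats.n_biallelic += 1
        sites.append(BiallelicSite(block_id, col, tuple(zip(taxa, bases))))
    return sites


def polarize_site(site: BiallelicSite, outgroup: str) -> np.ndarray | None:
    """0/1 derived-state vector over the site's taxa, outgroup base ancestral.

    Polarization always follows the outgroup, even when the outgroup
    carries the globally rarer allele.  Returns None when the outgroup
    call is missing or ambiguous (caller counts the drop).
    """
    anc = site.base(outgroup)
    if anc not in _VALID:
        return None
    return np.array([0 if b == anc else 1 for _, b in site.allele_by_taxon], dtype=np.int8)


def classify_pattern(derived: np.ndarray) -> str:
    """ABBA/BABA/BBAA label of a (P1,P2,P3,O) derived-state vector.

    Only the 0/1 vector matters; the outgroup slot is 0 by construction.
    """
    if len(derived) != 4:
        raise ValueError("pattern classification requires a 4-taxon derived vector")
    key = tuple(int(x) for x in derived)
    return {(0, 1, 1, 0): "ABBA", (1, 0, 1, 0): "BABA", (1, 1, 0, 0): "BBAA"}.get(
        key, "uninformative"
    )


@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int
    end: int
    snp_positions: tuple[int, ...]


def assign_windows(table: pd.DataFrame, window_size: int) -> list[GenomicWindow]:
    """Tile SNPs into non-overlapping half-open windows [k*w, (k+1)*w).

    A SNP at position p belongs to window floor(p / w); empty windows are
    omitted.  ``table`` needs columns chrom and pos.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if (table["pos"] < 0).any():
        raise ValueError("negative SNP positions")
    positions = table[["chrom", "pos"]].drop_duplicates()
    windows = []
    idx = positions["pos"] // window_size
    for (chrom, k), grp in positions.groupby(["chrom", idx], sort=True):
        windows.append(
            GenomicWindow(
                chrom=chrom,
                start=int(k) * window_size,
                end=(int(k) + 1) * window_size,
                snp_positions=tuple(sorted(grp["pos"])),
            )
        )
    return windows


def read_frequency_table(path) -> pd.DataFrame:
    """Read the SNP frequency TSV (chrom, pos, pop, derived_freq, n_chrom)."""
    table = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "pop", "derived_freq", "n_chrom"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"frequency table missing columns: {sorted(missing)}")
    bad = ~table["derived_freq"].between(0.0, 1.0)
    if bad.any():
        raise ValueError("derived_freq outside [0, 1]")
    return table
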