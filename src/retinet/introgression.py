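"""Patterson's D-statistic in count and allele-frequency form.

The count form tallies ABBA/BABA site patterns per block (ortholog
cluster in transcriptome mode, 50-kb window in genome mode):

    D(P1,P2,P3,O) = (sum_i C_ABBA(i) - C_BABA(i)) / (sum_i C_ABBA(i) + C_BABA(i))

a ratio of sums over blocks, never a mean of per-block ratios.  The
frequency form replaces indicator counts with per-population derived
allele frequencies p_ij:

    abba_i = (1-p_i1) p_i2 p_i3 (1-p_i4),  baba_i = p_i1 (1-p_i2) p_i3 (1-p_i4)

and reduces exactly to the count form when every frequency is 0 or 1.
Standard errors come from a leave-one-out (delete-one) jackknife over
blocks; significance is a two-tailed z-test, z = D/SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from retinet.variation import (
    assign_windows,
    classify_pattern,
    extract_biallelic_sites,
    polarize_site,
)


@dataclass(frozen=True)
class QuartetAssignment:
    p1: str
    p2: str
    p3: str
    outgroup: str

    def __post_init__(self) -> None:
        if len({self.p1, self.p2, self.p3, self.outgroup}) != 4:
            raise ValueError("quartet labels must be distinct")

    @property
    def labels(self) -> tuple[str, str, str, str]:
        return (self.p1, self.p2, self.p3, self.outgroup)

    def __str__(self) -> str:
        return f"({self.p1},{self.p2},{self.p3},{self.outgroup})"


@dataclass
class PatternCounts:
    """ABBA/BABA/BBAA tallies (or frequency-weighted sums) for one block."""

    block_id: str
    c_abba: float = 0.0
    c_baba: float = 0.0
    c_bbaa: float = 0.0
    n_sites: int = 0


@dataclass
class DResult:
    quartet: QuartetAssignment
    mode: str  # "counts" | "frequencies"
    d: float
    se: float
    z: float
    p_two_tailed: float
    n_blocks: int
    numerator: float
    denominator: float
    flags: tuple[str, ...] = ()

    @property
    def stars(self) -> str:
        return significance_stars(self.p_two_tailed)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def count_patterns(sites, quartet: QuartetAssignment, block_id: str = "") -> PatternCounts:
    """Tally ABBA/BABA/BBAA over a block's polarized biallelic sites.

    Sites whose outgroup call is missing are dropped (not counted in
    n_sites).  An empty block yields all-zero counts.
    """
    counts = PatternCounts(block_id=block_id or (sites[0].block_id if sites else ""))
    for site in sites:
        derived_full = polarize_site(site, quartet.outgroup)
        if derived_full is None:
            continue
        order = [t for t, _ in site.allele_by_taxon]
        idx = [order.index(lab) for lab in quartet.labels]
        label = classify_pattern(derived_full[idx])
        counts.n_sites += 1
        if label == "ABBA":
            counts.c_abba += 1
        elif label == "BABA":
            counts.c_baba += 1
        elif label == "BBAA":
            counts.c_bbaa += 1
    return counts


def _totals(blocks) -> tuple[np.ndarray, np.ndarray]:
    num = np.array([b.c_abba - b.c_baba for b in blocks], dtype=float)
    den = np.array([b.c_abba + b.c_baba for b in blocks], dtype=float)
    return num, den


def d_from_counts(blocks) -> tuple[float, float, float]:
    """(numerator, denominator, d) of Patterson's D, ratio of sums over blocks.

    Raises ZeroDivisionError when no ABBA or BABA sites exist anywhere.
    """
    if not len(blocks):
        raise ValueError("at least one block required")
    num, den = _totals(blocks)
    total_num, total_den = num.sum(), den.sum()
    if total_den == 0:
        raise ZeroDivisionError("undefined: no ABBA/BABA-informative sites")
    return float(total_num), float(total_den), float(total_num / total_den)


def abba_baba_weights(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP frequency weights; ``freqs`` is (n_snps, 4) for (P1,P2,P3,O)."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 2 or freqs.shape[1] != 4:
        raise ValueError("expected an (n_snps, 4) frequency matrix")
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    p1, p2, p3, p4 = freqs.T
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba


def d_from_frequencies(freqs: np.ndarray) -> tuple[float, float, float]:
    """(numerator, denominator, d) from per-SNP derived-allele frequencies."""
    abba, baba = abba_baba_weights(freqs)
    num = float((abba - baba).sum())
    den = float((abba + baba).sum())
    if den == 0:
        raise ZeroDivisionError("undefined: zero ABBA+BABA weight")
    return num, den, num / den


def jackknife_se(num: np.ndarray, den: np.ndarray) -> tuple[float, int]:
    """Delete-one jackknife SE of the ratio-of-sums num/den over blocks.

    Recomputes theta_(i) with block i removed and returns
    sqrt(((n-1)/n) * sum_i (theta_(i) - mean(theta))^2) together with the
    number of usable deletions (deletions with a zero denominator are
    skipped with a warning and n adjusted).
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    if len(num) < 2:
        raise ValueError("insufficient_blocks: jackknife requires >= 2 blocks")
    loo_den = den.sum() - den
    ok = loo_den != 0
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} jackknife deletion(s) undefined (zero denominator); skipped",
            stacklevel=2,
        )
    n = int(ok.sum())
    if n < 2:
        raise ValueError("insufficient_blocks: fewer than 2 usable deletions")
    loo = (num.sum() - num[ok]) / loo_den[ok]
    se = np.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum())
    return float(se), n


def d_test(blocks, quartet: QuartetAssignment, mode: str = "counts") -> DResult:
    """Full D-statistic test over blocks: D, jackknife SE, z, two-tailed p."""
    num, den = _totals(blocks)
    total_num, total_den = num.sum(), den.sum()
    if total_den == 0:
        raise ZeroDivisionError("undefined: no ABBA/BABA-informative sites")
    d = float(total_num / total_den)
    se, n_used = jackknife_se(num, den)
    flags: list[str] = []
    if se == 0.0:
        if d == 0.0:
            flags.append("untestable")
            z, p = 0.0, 1.0
        else:
            flags.append("degenerate")
            z, p = np.inf if d > 0 else -np.inf, 0.0
    else:
        z = d / se
        p = float(2.0 * norm.sf(abs(z)))
    return DResult(
        quartet=quartet,
        mode=mode,
        d=d,
        se=se,
        z=float(z),
        p_two_tailed=p,
        n_blocks=n_used,
        numerator=float(total_num),
        denominator=float(total_den),
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# frequency / window mode


def _freq_matrix(table: pd.DataFrame, pops) -> pd.DataFrame:
    """Wide per-SNP frequency frame indexed by (chrom, pos), one column per pop."""
    missing = set(pops) - set(table["pop"].unique())
    if missing:
        raise KeyError(f"populations absent from table: {sorted(missing)}")
    wide = table.pivot_table(
        index=["chrom", "pos"], columns="pop", values="derived_freq", aggfunc="first"
    )
    wide = wide[list(pops)].dropna()
    return wide


def windowed_d(
    table: pd.DataFrame, quartet: QuartetAssignment, window_size: int = 50_000
):
    """Per-window D plus a chromosome-level D jackknifed over windows.

    Per-window SE/z comes from a delete-one jackknife over that window's
    SNPs; the chromosome-level statistic treats whole windows as
    jackknife blocks.  Windows with zero ABBA+BABA weight are excluded
    from the chromosome jackknife (flagged in the result).
    """
    wide = _freq_matrix(table, quartet.labels)
    per_window: list[dict] = []
    window_blocks: list[PatternCounts] = []
    n_undefined = 0
    for window in assign_windows(table, window_size):
        sub = wide.loc[(window.chrom, list(window.snp_positions)), :]
        abba, baba = abba_baba_weights(sub.to_numpy())
        den = float((abba + baba).sum())
        num = float((abba - baba).sum())
        row = {
            "chrom": window.chrom,
            "start": window.start,
            "end": window.end,
            "n_snps": len(window.snp_positions),
        }
        if den == 0:
            n_undefined += 1
            row.update(d=np.nan, se=np.nan, z=np.nan, defined=False)
        else:
            row["d"] = num / den
            try:
                se, _ = jackknife_se(abba - baba, abba + baba)
            except ValueError:
                se = np.nan
            row["se"] = se
            row["z"] = num / den / se if se and se > 0 else np.nan
            row["defined"] = True
            window_blocks.append(
                PatternCounts(
                    block_id=f"{window.chrom}:{window.start}-{window.end}",
                    c_abba=float(abba.sum()),
                    c_baba=float(baba.sum()),
                    n_sites=len(window.snp_positions),
                )
            )
        per_window.append(row)
    windows_df = pd.DataFrame(per_window)
    if len(window_blocks) >= 2:
        chrom_result = d_test(window_blocks, quartet, mode="frequencies")
        if n_undefined:
            chrom_result.flags = chrom_result.flags + (f"undefined_windows={n_undefined}",)
    elif len(window_blocks) == 1:
        b = window_blocks[0]
        chrom_result = DResult(
            quartet=quartet,
            mode="frequencies",
            d=(b.c_abba - b.c_baba) / (b.c_abba + b.c_baba),
            se=np.nan,
            z=np.nan,
            p_two_tailed=np.nan,
            n_blocks=1,
            numerator=b.c_abba - b.c_baba,
            denominator=b.c_abba + b.c_baba,
            flags=("se_undefined_single_window",),
        )
    else:
        raise ZeroDivisionError("no window with ABBA/BABA weight")
    return windows_df, chrom_result


# ---------------------------------------------------------------------------
# suites over cluster alignments


def cluster_pattern_counts(clusters, quartet: QuartetAssignment) -> list[PatternCounts]:
    """Per-cluster pattern tallies; ``clusters`` is an iterable of
    (cluster_id, alignment-dict) pairs."""
    blocks = []
    for cluster_id, alignment in clusters:
        sites = extract_biallelic_sites(alignment, quartet.labels, block_id=cluster_id)
        blocks.append(count_patterns(sites, quartet, block_id=cluster_id))
    return blocks


def run_d_suite(clusters, quartets) -> pd.DataFrame:
    """One D-test row per quartet over the same clusters, config order kept.

    ``clusters`` may be a list (reused across quartets); unknown quartet
    labels raise a KeyError naming the offending quartet.
    """
    clusters = list(clusters)
    if clusters:
        available = set(clusters[0][1])
        for q in quartets:
            unknown = set(q.labels) - available
            if unknown:
                raise KeyError(f"quartet {q}: unknown labels {sorted(unknown)}")
    rows = []
    for q in quartets:
        res = d_test(cluster_pattern_counts(clusters, q), q, mode="counts")
        rows.append(
            {
                "quartet": str(q),
                "mode": res.mode,
                "n_blocks": res.n_blocks,
                "numerator": res.numerator,
                "denominator": res.denominator,
                "d": res.d,
                "se": res.se,
                "z": res.z,
                "p": res.p_two_tailed,
                "stars": res.stars,
            }
        )
    return pd.DataFrame(rows)


def quartet_concordance(clusters, quartet: QuartetAssignment) -> pd.DataFrame:
    """Per-cluster (c_bbaa, c_abba, c_baba) tallies and the majority topology.

    Majority is the argmax of the three counts; ties (including all-zero
    clusters) are labelled "unresolved".
    """
    rows = []
    for counts in cluster_pattern_counts(clusters, quartet):
        tallies = {"BBAA": counts.c_bbaa, "ABBA": counts.c_abba, "BABA": counts.c_baba}
        best = max(tallies.values())
        winners = [k for k, v in tallies.items() if v == best]
        majority = winners[0] if best > 0 and len(winners) == 1 else "unresolved"
        rows.append(
            {
                "cluster_id": counts.block_id,
                "c_bbaa": counts.c_bbaa,
                "c_abba": counts.c_abba,
                "c_baba": counts.c_baba,
                "majority": majority,
            }
        )
    return pd.DataFrame(rows)
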