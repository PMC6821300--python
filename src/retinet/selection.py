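"""Pairwise Ka/Ks screening (NG86), candidate filters, branch-test planning.

The counting method is Nei–Gojobori (1986): degeneracy-weighted
synonymous/nonsynonymous site counts per codon, path-averaged
substitution counting between diverged codons, and a Jukes–Cantor
multiple-hit correction, d = -(3/4) ln(1 - (4/3) p).  Single-base
changes to stop codons are excluded from both the numerator and the
denominator of the site fractions, and mutational paths passing through
stop codons are excluded from the path average; codons whose every path
is blocked are skipped and flagged.

Ratios > 1 suggest positive selection; the screen retains pairs with
ratio > 1, an ungapped aligned fragment of at least 100 bp and Ks below
a saturation cap.  Candidate clusters then feed a branch-site test plan
(one planned test per cluster x foreground branch) exported for an
external likelihood engine.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import dendropy
import numpy as np
import pandas as pd

from retinet.codon import AMINO_ACID, STOP_CODONS

_BASES = "ACGT"

# fixed ingroup topology used for branch-test planning, outgroup first
DEFAULT_TOPOLOGY = (
    "(iulia,((erato,(sara,hortense)),(doris,(hecale,(cydno,melpomene)))));"
)

# eight terminal branches plus the four internal nodes of interest
DEFAULT_FOREGROUNDS: tuple = (
    "sara",
    "hortense",
    "erato",
    "doris",
    "hecale",
    "cydno",
    "melpomene",
    "iulia",
    ("sara", "hortense"),
    ("erato", "sara", "hortense"),
    ("cydno", "melpomene"),
    ("hecale", "cydno", "melpomene"),
)


@dataclass
class KaKsResult:
    pair: tuple[str, str]
    n_codons: int
    s_sites: float  # expected synonymous sites (mean of the two sequences)
    n_sites: float
    sd: float  # observed synonymous differences (path-averaged)
    nd: float
    ka: float
    ks: float
    ratio: float  # nan when undefined
    flags: tuple[str, ...] = ()
    method: str = "NG86"


# ---------------------------------------------------------------------------
# NG86 site counting


@lru_cache(maxsize=None)
def _codon_site_fraction(codon: str) -> float:
    """Synonymous-site contribution of one codon (sum of per-position
    fractions syn/(non-stop single-base changes))."""
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site contribution")
    aa = AMINO_ACID[codon]
    total = 0.0
    for pos in range(3):
        syn = counted = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            counted += 1
            if AMINO_ACID[mutant] == aa:
                syn += 1
        if counted:
            total += syn / counted
    return total


def ng86_sites(seq: str) -> tuple[float, float]:
    """(S, N): expected synonymous and nonsynonymous sites of one CDS.

    N is the stop-adjusted complement, 3*codons - S.  Raises on internal
    stop codons, naming the codon index.
    """
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    s = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon at codon index {i // 3}")
        s += _codon_site_fraction(codon)
    n_codons = len(seq) // 3
    return s, 3.0 * n_codons - s


# ---------------------------------------------------------------------------
# NG86 substitution counting


@lru_cache(maxsize=None)
def _codon_pair_differences(a: str, b: str) -> tuple[float, float] | None:
    """Path-averaged (sd, nd) between two sense codons.

    Averages synonymous/nonsynonymous step assignments over all k!
    orderings of the k differing positions, excluding paths through stop
    codons.  Returns None when every path is blocked.
    """
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    valid = 0
    sd = nd = 0.0
    for order in itertools.permutations(diff):
        current = a
        steps: list[bool] = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            steps.append(AMINO_ACID[nxt] == AMINO_ACID[current])
            current = nxt
        if blocked:
            continue
        valid += 1
        sd += sum(steps)
        nd += len(steps) - sum(steps)
    if valid == 0:
        return None
    return sd / valid, nd / valid


def ng86_substitutions(seq_a: str, seq_b: str) -> tuple[float, float, int]:
    """(sd, nd, n_skipped) between two aligned, gap-free, stop-free CDS."""
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    if len(seq_a) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    sd = nd = 0.0
    skipped = 0
    for i in range(0, len(seq_a), 3):
        counts = _codon_pair_differences(seq_a[i : i + 3], seq_b[i : i + 3])
        if counts is None:
            skipped += 1
            continue
        sd += counts[0]
        nd += counts[1]
    return sd, nd, skipped


def jc_correct(p: float) -> float:
    """Jukes–Cantor distance -(3/4) ln(1 - (4/3) p); saturated at p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        raise ValueError("saturated: proportion >= 3/4")
    return -0.75 * math.log(1.0 - p * 4.0 / 3.0) + 0.0


_MISSING = set("-Nn.")


def _strip_gapped_codons(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Drop codon columns containing a gap or missing base in either sequence."""
    kept_a, kept_b = [], []
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if any(ch in _MISSING for ch in ca + cb):
            continue
        kept_a.append(ca)
        kept_b.append(cb)
    return "".join(kept_a), "".join(kept_b)


def kaks(
    seq_a: str,
    seq_b: str,
    id_a: str = "a",
    id_b: str = "b",
    max_ks: float = 2.0,
) -> KaKsResult:
    """NG86 Ka/Ks for one aligned sequence pair.

    Gap-containing codon columns are removed pairwise first.  The ratio
    is defined only when Ks > 0 and neither rate is saturated; flags
    record ks_zero, saturated and skipped-codon conditions.  Symmetric in
    its arguments.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    if len(seq_a) % 3:
        raise ValueError("alignment length must be a multiple of 3")
    seq_a, seq_b = _strip_gapped_codons(seq_a, seq_b)
    n_codons = len(seq_a) // 3
    flags: list[str] = []
    if n_codons == 0:
        return KaKsResult(
            (id_a, id_b), 0, 0.0, 0.0, 0.0, 0.0, math.nan, math.nan, math.nan, ("too_short",)
        )
    s_a, n_a = ng86_sites(seq_a)
    s_b, n_b = ng86_sites(seq_b)
    s_sites, n_sites = (s_a + s_b) / 2.0, (n_a + n_b) / 2.0
    sd, nd, skipped = ng86_substitutions(seq_a, seq_b)
    if skipped:
        flags.append(f"codons_skipped={skipped}")
    ka = ks = ratio = math.nan
    if s_sites > 0 and n_sites > 0:
        ps, pn = sd / s_sites, nd / n_sites
        saturated = False
        try:
            ks = jc_correct(ps)
        except ValueError:
            saturated = True
        try:
            ka = jc_correct(pn)
        except ValueError:
            saturated = True
        if saturated:
            flags.append("saturated")
        elif ks > max_ks:
            flags.append("saturated")
        elif ks == 0.0:
            flags.append("ks_zero")
        else:
            ratio = ka / ks
    else:
        flags.append("no_sites")
    return KaKsResult(
        (id_a, id_b), n_codons, s_sites, n_sites, sd, nd, ka, ks, ratio, tuple(flags)
    )


# ---------------------------------------------------------------------------
# screening


def species_pairs(taxa) -> list[tuple[str, str]]:
    """All unordered species pairs, in deterministic taxa order (28 for 8)."""
    return list(itertools.combinations(taxa, 2))


def pairwise_plan(cluster_ids, taxa) -> pd.DataFrame:
    """The full screening plan: one row per (cluster, species pair)."""
    pairs = species_pairs(taxa)
    rows = [
        {"cluster_id": cid, "species_a": a, "species_b": b}
        for cid in cluster_ids
        for a, b in pairs
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "species_a", "species_b"])


def kaks_all_pairs(clusters, max_ks: float = 2.0) -> pd.DataFrame:
    """NG86 results for every species pair of every cluster.

    ``clusters`` is an iterable of (cluster_id, alignment-dict).  Returns
    one row per (cluster, pair) with counts, rates, ratio and flags.
    """
    rows = []
    for cluster_id, alignment in clusters:
        for a, b in species_pairs(list(alignment)):
            res = kaks(alignment[a], alignment[b], a, b, max_ks=max_ks)
            rows.append(
                {
                    "cluster_id": cluster_id,
                    "species_a": a,
                    "species_b": b,
                    "n_codons": res.n_codons,
                    "s_sites": res.s_sites,
                    "n_sites": res.n_sites,
                    "sd": res.sd,
                    "nd": res.nd,
                    "ka": res.ka,
                    "ks": res.ks,
                    "ratio": res.ratio,
                    "flags": ";".join(res.flags),
                    "method": res.method,
                }
            )
    return pd.DataFrame(rows)


def screen_candidates(
    kaks_table: pd.DataFrame, min_fragment: int = 100, max_ks: float = 2.0
) -> pd.DataFrame:
    """Mark (cluster, pair) rows passing the positive-selection screen.

    Retained rows have ratio > 1, an ungapped aligned fragment of at
    least ``min_fragment`` bp and a defined, unsaturated Ks below
    ``max_ks``.  Adds a boolean ``retained`` column; the distinct
    candidate clusters are ``table.loc[table.retained, "cluster_id"].unique()``.
    """
    table = kaks_table.copy()
    if table.empty:
        table["retained"] = pd.Series(dtype=bool)
        return table
    fragment_bp = table["n_codons"] * 3
    saturated = table["flags"].str.contains("saturated", na=False)
    table["retained"] = (
        (table["ratio"] > 1.0)
        & (fragment_bp >= min_fragment)
        & (table["ks"] > 0)
        & (table["ks"] <= max_ks)
        & ~saturated
    )
    return table


# ---------------------------------------------------------------------------
# branch-site test planning


def _tag_foreground(newick: str, foreground) -> str:
    """Newick with the foreground branch tagged '#1' (codeml convention)."""
    # fresh parse per foreground: dendropy taxa are shared across clones
    work = dendropy.Tree.get(data=newick, schema="newick")
    work.is_rooted = True
    labels = {t.label for t in work.taxon_namespace}
    if isinstance(foreground, str):
        if foreground not in labels:
            raise KeyError(f"foreground taxon {foreground!r} not on topology")
        for leaf in work.leaf_node_iter():
            if leaf.taxon.label == foreground:
                leaf.taxon.label = f"{foreground}#1"
    else:
        wanted = set(foreground)
        if not wanted <= labels:
            raise KeyError(f"foreground clade {sorted(wanted)} not on topology")
        mrca = work.mrca(taxon_labels=sorted(wanted))
        spanned = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        if spanned != wanted:
            raise KeyError(
                f"foreground {sorted(wanted)} is not a clade on the topology "
                f"(MRCA spans {sorted(spanned)})"
            )
        mrca.label = "#1"
    return work.as_string(schema="newick", suppress_rooting=True).strip()


def foreground_name(foreground) -> str:
    return foreground if isinstance(foreground, str) else "(" + "+".join(foreground) + ")"


def enumerate_branch_tests(
    candidate_clusters,
    tree: str | dendropy.Tree = DEFAULT_TOPOLOGY,
    foregrounds=DEFAULT_FOREGROUNDS,
) -> pd.DataFrame:
    """One planned branch-site test per (candidate cluster, foreground).

    Foregrounds are terminal taxon labels or tuples of labels naming an
    internal clade; each must resolve on the topology.  Rows appear in
    deterministic (cluster, foreground) order with the foreground-tagged
    newick ready for an external likelihood engine.
    """
    newick = (
        tree.as_string(schema="newick") if isinstance(tree, dendropy.Tree) else tree
    )
    dendropy.Tree.get(data=newick, schema="newick")  # validate once up front
    tagged = [(foreground_name(f), _tag_foreground(newick, f)) for f in foregrounds]
    rows = [
        {"cluster_id": cid, "foreground": name, "tree": newick}
        for cid in candidate_clusters
        for name, newick in tagged
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "foreground", "tree"])


def bh_fdr(p_values, q: float = 0.01) -> tuple[np.ndarray, float]:
    """Benjamini–Hochberg step-up at FDR level q.

    Returns (rejected boolean mask aligned with the input order, adjusted
    p threshold).  The threshold is the largest p_(k) with
    p_(k) <= k*q/m; all p-values at or below it are rejected.  An empty
    input rejects nothing (threshold 0).
    """
    p = np.asarray(list(p_values), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool), 0.0
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) * q / m)
    if not below.any():
        return np.zeros(m, dtype=bool), 0.0
    threshold = float(ranked[np.nonzero(below)[0][-1]])
    return p <= threshold, threshold
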