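"""Synthetic data with known introgression and selection ground truth.

The generator realises a three-class gene-tree mixture over a quartet
(P1, P2, P3, O) embedded in an eight-taxon tree.  Each locus follows

* the species topology ((P1,P2),P3,O)            w.p. 1 - g - 3q
* one of three incomplete-lineage-sorting (ILS)
  resolutions (ABBA-, BABA- or BBAA-like)        each w.p. q
* the introgression topology ((P2,P3),P1,O)      w.p. g

with q = (1/3) exp(-t_internal) the per-resolution ILS probability of a
coalescent internal branch of length ``t_internal``, and
g = gamma * (1 - 3q) the excess of (P2,P3) gene trees attributable to
gene flow at admixture proportion ``gamma``.  Under this mixture the
ABBA/BABA D-statistic has the closed form E[D] = g / (g + 2q), which
serves as the oracle for parameter-recovery tests downstream.

Three output modes share one config and one seed:

* per-locus informative-site pattern counts (transcriptome-style),
* gap-free eight-taxon codon alignments evolved down the drawn gene
  tree, with a per-locus omega scaling nonsynonymous acceptance, and
* a windowed SNP derived-allele-frequency table (genome-resequencing
  style) with introgressed tracts planted in known windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from retinet.codon import AMINO_ACID, SENSE_CODONS, STOP_CODONS

GENEALOGY_CLASSES = ("introgressed", "ils_abba", "ils_baba", "ils_bbaa", "concordant")

# pattern written by each genealogy class at its informative sites
CLASS_PATTERN = {
    "introgressed": "ABBA",
    "ils_abba": "ABBA",
    "ils_baba": "BABA",
    "ils_bbaa": "BBAA",
    "concordant": "BBAA",
}

DEFAULT_TAXA = ("sara", "hortense", "erato", "doris", "hecale", "cydno", "melpomene", "iulia")
DEFAULT_QUARTET = ("sara", "hortense", "erato", "iulia")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model; defaults are the study conditions.

    ``taxa`` is ordered with the outgroup last; ``quartet`` is
    (P1, P2, P3, O) with O the outgroup taxon.  ``mut_rate`` is the
    expected informative-site fraction per locus in pattern mode and the
    expected substitutions per site per branch in alignment mode.
    """

    n_loci: int = 1000
    sites_per_locus: int = 900
    taxa: tuple[str, ...] = DEFAULT_TAXA
    quartet: tuple[str, str, str, str] = DEFAULT_QUARTET
    gamma: float = 0.1
    t_internal: float = math.log(2.0)
    mut_rate: float = 0.02
    omega_selected: float = 5.0
    frac_selected: float = 0.05
    n_chrom_per_pop: int = 10
    window_size: int = 50_000
    n_windows: int = 100
    snps_per_window: int = 40
    tract_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.taxa) != 8 or len(set(self.taxa)) != 8:
            raise ValueError("taxa must be 8 distinct labels (outgroup last)")
        if len(set(self.quartet)) != 4 or not set(self.quartet) <= set(self.taxa):
            raise ValueError("quartet must be 4 distinct labels drawn from taxa")
        if self.quartet[3] != self.taxa[-1]:
            raise ValueError("quartet outgroup must be the last taxon in taxa")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.t_internal < 0:
            raise ValueError("t_internal must be nonnegative")
        if not 0.0 <= self.frac_selected <= 1.0:
            raise ValueError("frac_selected must lie in [0, 1]")
        if self.omega_selected <= 0:
            raise ValueError("omega_selected must be positive")
        if self.n_chrom_per_pop < 1:
            raise ValueError("n_chrom_per_pop must be >= 1")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        g, q = self.class_rates()
        if 1.0 - g - 3.0 * q < -1e-12:
            raise ValueError("gamma and t_internal imply negative concordant probability")

    def class_rates(self) -> tuple[float, float]:
        """(g, q): introgression excess and per-resolution ILS probability."""
        q = math.exp(-self.t_internal) / 3.0
        g = self.gamma * (1.0 - 3.0 * q)
        return g, q

    def class_probabilities(self) -> np.ndarray:
        """Probabilities over GENEALOGY_CLASSES order; sums to 1."""
        g, q = self.class_rates()
        p = np.array([g, q, q, q, max(0.0, 1.0 - g - 3.0 * q)])
        return p / p.sum()

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class LocusTruth:
    locus_id: str
    genealogy_class: str
    omega: float
    n_informative_sites: int


def expected_d(gamma: float, t_internal: float) -> float:
    """Closed-form E[D] of the mixture: g/(g+2q), g = gamma(1-3q), q = exp(-t)/3.

    Diverges only when no informative sites are possible (g + 2q = 0).
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    if t_internal < 0:
        raise ValueError("t_internal must be nonnegative")
    q = math.exp(-t_internal) / 3.0
    g = gamma * (1.0 - 3.0 * q)
    denom = g + 2.0 * q
    if denom == 0.0:
        raise ZeroDivisionError("g + 2q = 0: no informative sites possible")
    return g / denom


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent substream per output mode, all derived from config.seed
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _draw_classes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(len(GENEALOGY_CLASSES), size=config.n_loci, p=config.class_probabilities())


def _draw_omegas(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    selected = rng.random(config.n_loci) < config.frac_selected
    return np.where(selected, config.omega_selected, 1.0)


def simulate_locus_patterns(config: SimulationConfig):
    """Per-locus (LocusTruth, PatternCounts): all informative sites of a locus
    carry the pattern of its genealogy class; site counts are Poisson with
    mean ``mut_rate * sites_per_locus``."""
    from retinet.introgression import PatternCounts

    rng = _rng(config, stream=1)
    classes = _draw_classes(config, rng)
    n_sites = rng.poisson(config.mut_rate * config.sites_per_locus, size=config.n_loci)
    out = []
    for i in range(config.n_loci):
        cls = GENEALOGY_CLASSES[classes[i]]
        pattern = CLASS_PATTERN[cls]
        k = int(n_sites[i])
        truth = LocusTruth(f"locus{i:05d}", cls, 1.0, k)
        counts = PatternCounts(
            block_id=truth.locus_id,
            c_abba=k if pattern == "ABBA" else 0,
            c_baba=k if pattern == "BABA" else 0,
            c_bbaa=k if pattern == "BBAA" else 0,
            n_sites=k,
        )
        out.append((truth, counts))
    return out


# ---------------------------------------------------------------------------
# codon alignments


def _gene_tree(config: SimulationConfig, genealogy_class: str):
    """Nested (subtree, branch_length) representation of the locus gene tree.

    The trio grouping of (P1,P2,P3) follows the genealogy class; the four
    remaining ingroup taxa form a pectinate clade sister to the trio.
    """
    p1, p2, p3, og = config.quartet
    rest = [t for t in config.taxa if t not in set(config.quartet)]
    b = config.mut_rate
    if genealogy_class in ("concordant", "ils_bbaa"):
        trio = [([(p1, b), (p2, b)], b), (p3, b)]
    elif genealogy_class in ("ils_abba", "introgressed"):
        trio = [([(p2, b), (p3, b)], b), (p1, b)]
    else:  # ils_baba
        trio = [([(p1, b), (p3, b)], b), (p2, b)]
    ladder = [(rest[2], b), (rest[3], b)]
    ladder = [(rest[1], b), (ladder, b)]
    ladder = [(rest[0], b), (ladder, b)]
    ingroup = [(trio, b), (ladder, b)]
    return [(ingroup, b), (og, 2.0 * b)]


_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}


def _evolve_branch(codons: list[str], blen: float, omega: float,
                   rng: np.random.Generator) -> list[str]:
    """Evolve a codon list along one branch.

    Attempted single-base mutations arrive as Poisson(blen * n_sites);
    mutations creating stop codons are resampled.  Acceptance probability
    is min(1, omega) for nonsynonymous and min(1, 1/omega) for synonymous
    changes, so the realised nonsynonymous/synonymous rate ratio is omega.
    """
    n_codons = len(codons)
    n_attempts = rng.poisson(blen * 3 * n_codons)
    if n_attempts == 0:
        return codons
    codons = list(codons)
    p_ns = min(1.0, omega)
    p_s = min(1.0, 1.0 / omega)
    for _ in range(n_attempts):
        while True:
            i = int(rng.integers(n_codons))
            pos = int(rng.integers(3))
            old = codons[i]
            base = _OTHER[old[pos]][int(rng.integers(3))]
            new = old[:pos] + base + old[pos + 1:]
            if new not in STOP_CODONS:
                break
        synonymous = AMINO_ACID[new] == AMINO_ACID[old]
        if rng.random() < (p_s if synonymous else p_ns):
            codons[i] = new
    return codons


def _evolve_tree(codons, tree, omega, rng, out):
    for subtree, blen in tree:
        child = _evolve_branch(codons, blen, omega, rng)
        if isinstance(subtree, str):
            out[subtree] = "".join(child)
        else:
            _evolve_tree(child, subtree, omega, rng, out)


def simulate_cluster_alignments(config: SimulationConfig):
    """Gap-free eight-taxon codon alignments, one per locus.

    Returns a list of (LocusTruth, alignment) where alignment maps taxon
    label to an aligned CDS string.  ``n_informative_sites`` in the truth
    is filled with the number of biallelic quartet-informative columns of
    the realised alignment.
    """
    if config.sites_per_locus % 3 != 0:
        raise ValueError("sites_per_locus must be divisible by 3")
    from retinet.variation import extract_biallelic_sites

    rng = _rng(config, stream=2)
    classes = _draw_classes(config, rng)
    omegas = _draw_omegas(config, rng)
    n_codons = config.sites_per_locus // 3
    sense = list(SENSE_CODONS)
    out = []
    for i in range(config.n_loci):
        cls = GENEALOGY_CLASSES[classes[i]]
        root = [sense[j] for j in rng.integers(len(sense), size=n_codons)]
        alignment: dict[str, str] = {}
        _evolve_tree(root, _gene_tree(config, cls), float(omegas[i]), rng, alignment)
        alignment = {t: alignment[t] for t in config.taxa}
        sites = extract_biallelic_sites(alignment, config.quartet, block_id=f"cluster{i:05d}")
        truth = LocusTruth(f"cluster{i:05d}", cls, float(omegas[i]), len(sites))
        out.append((truth, alignment))
    return out


# ---------------------------------------------------------------------------
# windowed SNP frequencies

# base derived-allele configuration (P1, P2, P3, O) per genealogy class
_CLASS_FREQ = {
    "introgressed": (0.0, 1.0, 1.0, 0.0),
    "ils_abba": (0.0, 1.0, 1.0, 0.0),
    "ils_baba": (1.0, 0.0, 1.0, 0.0),
    "ils_bbaa": (1.0, 1.0, 0.0, 0.0),
    "concordant": (1.0, 1.0, 0.0, 0.0),
}

_FREQ_CONCENTRATION = 20.0  # Beta concentration of within-population drift noise


def simulate_window_frequencies(config: SimulationConfig):
    """SNP derived-allele-frequency table along one synthetic chromosome.

    Returns (table, tract_windows): a DataFrame with columns
    (chrom, pos, pop, derived_freq, n_chrom) — one row per (pos, pop),
    pops being the quartet labels — and the sorted window indices where
    introgressed tracts were planted.  Inside tract windows loci follow
    the full mixture at the configured gamma; outside, gamma = 0.
    """
    rng = _rng(config, stream=3)
    n_tract = int(round(config.tract_fraction * config.n_windows))
    tract = np.sort(rng.choice(config.n_windows, size=n_tract, replace=False))
    tract_set = set(int(w) for w in tract)

    null_probs = replace(config, gamma=0.0).class_probabilities()
    alt_probs = config.class_probabilities()

    pops = list(config.quartet)
    rows_pos: list[int] = []
    rows_class: list[int] = []
    for w in range(config.n_windows):
        offsets = np.sort(rng.choice(config.window_size, size=config.snps_per_window, replace=False))
        probs = alt_probs if w in tract_set else null_probs
        cls = rng.choice(len(GENEALOGY_CLASSES), size=config.snps_per_window, p=probs)
        rows_pos.extend(int(w) * config.window_size + offsets)
        rows_class.extend(cls)

    n_snps = len(rows_pos)
    base = np.array([_CLASS_FREQ[GENEALOGY_CLASSES[c]] for c in rows_class])  # (n_snps, 4)
    # drift noise: true frequency ~ Beta centred near the class configuration
    m = base * 0.9 + 0.05
    p_true = rng.beta(_FREQ_CONCENTRATION * m, _FREQ_CONCENTRATION * (1.0 - m))
    counts = rng.binomial(config.n_chrom_per_pop, p_true)
    freqs = counts / config.n_chrom_per_pop

    table = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.repeat(rows_pos, len(pops)),
            "pop": np.tile(pops, n_snps),
            "derived_freq": freqs.reshape(-1),
            "n_chrom": config.n_chrom_per_pop,
        }
    )
    return table, [int(w) for w in tract]


# ---------------------------------------------------------------------------
# writers


def write_cluster_fastas(clusters, out_dir) -> None:
    """One aligned FASTA per cluster plus a locus truth table (TSV)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for truth, alignment in clusters:
        with open(out / f"{truth.locus_id}.fasta", "w") as fh:
            for taxon, seq in alignment.items():
                fh.write(f">{taxon}\n{seq}\n")
        rows.append((truth.locus_id, truth.genealogy_class, truth.omega, truth.n_informative_sites))
    pd.DataFrame(rows, columns=["locus_id", "class", "omega", "n_sites"]).to_csv(
        out / "truth.tsv", sep="\t", index=False
    )


def write_frequency_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
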