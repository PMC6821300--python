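"""End-to-end orchestration: simulate -> cluster -> dstat -> kaks -> plan.

One YAML config drives every stage; a single master seed derives
per-stage substreams so any subset of stages is reproducible.  Each
stage writes plain-text artifacts (FASTA / TSV / newick / JSON) and the
run finishes with a machine-readable report whose counters reconcile
across stages.  A stage failure renames that stage's outputs with a
``.partial`` suffix and aborts, naming the failing stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from retinet import introgression, orthology, selection, simulate
from retinet.introgression import QuartetAssignment
from retinet.orthology import ScoringParams, SequenceRecord
from retinet.simulate import SimulationConfig

STAGES = ("simulate", "cluster", "dstat", "kaks", "plan")

_SIM_KEYS = {
    "n_loci", "sites_per_locus", "gamma", "t_internal", "mut_rate",
    "omega_selected", "frac_selected", "n_chrom_per_pop", "window_size",
    "n_windows", "snps_per_window", "tract_fraction",
}
_KNOWN_KEYS = _SIM_KEYS | {
    "stages", "taxa", "outgroup", "quartets", "min_score_significance",
    "min_fragment", "max_ks", "alpha", "q", "seed",
}


@dataclass
class PipelineConfig:
    stages: tuple[str, ...] = STAGES
    taxa: tuple[str, ...] = simulate.DEFAULT_TAXA
    outgroup: str = simulate.DEFAULT_TAXA[-1]
    quartets: tuple[tuple[str, str, str, str], ...] = (simulate.DEFAULT_QUARTET,)
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides
    min_score_significance: float = 1e-6
    min_fragment: int = 100
    max_ks: float = 2.0
    alpha: float = 0.05
    q: float = 0.01
    seed: int = 0

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            taxa=self.taxa,
            quartet=self.quartets[0],
            seed=self.seed,
            **self.sim,
        )

    def scoring_params(self) -> ScoringParams:
        return ScoringParams(max_significance=self.min_score_significance)

    def echo(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["taxa"] = list(self.taxa)
        d["quartets"] = [list(q) for q in self.quartets]
        return d


def validate_config(raw: str | dict) -> PipelineConfig:
    """Parse and validate a YAML pipeline config; unknown keys rejected."""
    data = yaml.safe_load(raw) if isinstance(raw, str) else dict(raw)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config must be a key-value document")
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    taxa = tuple(data.get("taxa", simulate.DEFAULT_TAXA))
    if len(taxa) != 8 or len(set(taxa)) != 8:
        raise ValueError("taxa must be 8 distinct labels")
    outgroup = data.get("outgroup", taxa[-1])
    if isinstance(outgroup, (list, tuple)):
        raise ValueError("exactly one outgroup required")
    if outgroup not in taxa:
        raise ValueError(f"outgroup {outgroup!r} not among taxa")
    if outgroup != taxa[-1]:
        raise ValueError("outgroup must be the last taxon in taxa order")

    stages = tuple(data.get("stages", STAGES))
    bad = set(stages) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")

    quartets_raw = data.get("quartets")
    if quartets_raw is None:
        ingroup = [t for t in taxa if t != outgroup]
        quartets = ((ingroup[0], ingroup[1], ingroup[2], outgroup),)
    else:
        quartets = tuple(tuple(q) for q in quartets_raw)
        for q in quartets:
            if len(q) != 4 or len(set(q)) != 4:
                raise ValueError(f"quartet {q} must be 4 distinct labels")
            if set(q) - set(taxa):
                raise ValueError(f"quartet {q} uses labels outside taxa")

    sim = {k: data[k] for k in _SIM_KEYS if k in data}
    if "window_size" in sim and sim["window_size"] <= 0:
        raise ValueError("window_size must be positive")

    return PipelineConfig(
        stages=stages,
        taxa=taxa,
        outgroup=outgroup,
        quartets=quartets,
        sim=sim,
        min_score_significance=float(data.get("min_score_significance", 1e-6)),
        min_fragment=int(data.get("min_fragment", 100)),
        max_ks=float(data.get("max_ks", 2.0)),
        alpha=float(data.get("alpha", 0.05)),
        q=float(data.get("q", 0.01)),
        seed=int(data.get("seed", 0)),
    )


def default_foregrounds(taxa, quartet) -> tuple:
    """8 terminal branches + 4 internal clades on the simulated topology."""
    if tuple(taxa) == simulate.DEFAULT_TAXA:
        return selection.DEFAULT_FOREGROUNDS
    p1, p2, p3, _ = quartet
    rest = [t for t in taxa if t not in set(quartet)]
    return tuple(taxa) + (
        (p1, p2),
        (p1, p2, p3),
        (rest[2], rest[3]),
        (rest[1], rest[2], rest[3]),
    )


def topology_newick(taxa, quartet) -> str:
    """Species topology matching the simulator's concordant gene tree."""
    if tuple(taxa) == simulate.DEFAULT_TAXA:
        return selection.DEFAULT_TOPOLOGY
    p1, p2, p3, og = quartet
    rest = [t for t in taxa if t not in set(quartet)]
    return (
        f"({og},((({p1},{p2}),{p3}),"
        f"({rest[0]},({rest[1]},({rest[2]},{rest[3]})))));"
    )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the enabled stages in dependency order; returns the report.

    Artifacts land under ``out_dir``; the report itself is written there
    as ``report.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_config = config.simulation_config()
    report: dict = {"config": config.echo(), "stages": {}, "files": {}}
    started = time.time()

    clusters: list | None = None  # [(cluster_id, alignment)]
    truths: list | None = None
    snp_table: pd.DataFrame | None = None
    candidates: list[str] = []
    stage_files: list[Path] = []

    def record(stage: str, **counts) -> None:
        report["stages"][stage] = counts
        for f in stage_files:
            report["files"][str(f.relative_to(out))] = _digest(f)
        stage_files.clear()

    def _ensure_simulated():
        nonlocal clusters, truths, snp_table
        if clusters is None:
            sim = simulate.simulate_cluster_alignments(sim_config)
            truths = [t for t, _ in sim]
            clusters = [(t.locus_id, aln) for t, aln in sim]
        if snp_table is None:
            snp_table, _ = simulate.simulate_window_frequencies(sim_config)

    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            if stage == "simulate":
                _ensure_simulated()
                cluster_dir = out / "clusters"
                simulate.write_cluster_fastas(
                    [(t, dict(a)) for (t, a) in zip(truths, (a for _, a in clusters))],
                    cluster_dir,
                )
                stage_files.append(cluster_dir / "truth.tsv")
                snp_path = out / "snps.tsv"
                simulate.write_frequency_table(snp_table, snp_path)
                stage_files.append(snp_path)
                record(
                    stage,
                    n_clusters=len(clusters),
                    n_snp_rows=len(snp_table),
                    n_snps=snp_table["pos"].nunique(),
                )

            elif stage == "cluster":
                _ensure_simulated()
                species_sets = {
                    sp: [
                        SequenceRecord(sp, cid, "iso1", aln[sp].replace("-", ""))
                        for cid, aln in clusters
                    ]
                    for sp in config.taxa
                }
                built = orthology.build_clusters(species_sets, config.scoring_params())
                members = orthology.membership_table(built, config.scoring_params())
                path = out / "clusters.tsv"
                members.to_csv(path, sep="\t", index=False)
                stage_files.append(path)
                truth_ids = {cid for cid, _ in clusters}
                recovered = sum(
                    1
                    for c in built
                    if len({r.gene_id for r in c.members.values()}) == 1
                    and next(iter(c.members.values())).gene_id in truth_ids
                )
                record(
                    stage,
                    n_clusters_built=len(built),
                    n_true_clusters=len(clusters),
                    n_recovered=recovered,
                )

            elif stage == "dstat":
                _ensure_simulated()
                quartets = [QuartetAssignment(*q) for q in config.quartets]
                suite = introgression.run_d_suite(clusters, quartets)
                path = out / "dstat_loci.tsv"
                suite.to_csv(path, sep="\t", index=False)
                stage_files.append(path)
                windows, chrom = introgression.windowed_d(
                    snp_table, quartets[0], sim_config.window_size
                )
                wpath = out / "dstat_windows.tsv"
                windows.to_csv(wpath, sep="\t", index=False)
                stage_files.append(wpath)
                record(
                    stage,
                    n_quartets=len(quartets),
                    n_windows=len(windows),
                    n_windows_defined=int(windows["defined"].sum()),
                    chromosome_d=chrom.d,
                    chromosome_z=chrom.z,
                )

            elif stage == "kaks":
                _ensure_simulated()
                table = selection.kaks_all_pairs(clusters, max_ks=config.max_ks)
                screened = selection.screen_candidates(
                    table, min_fragment=config.min_fragment, max_ks=config.max_ks
                )
                path = out / "kaks.tsv"
                screened.to_csv(path, sep="\t", index=False)
                stage_files.append(path)
                candidates = sorted(
                    screened.loc[screened["retained"], "cluster_id"].unique()
                )
                cpath = out / "candidates.tsv"
                pd.DataFrame({"cluster_id": candidates}).to_csv(
                    cpath, sep="\t", index=False
                )
                stage_files.append(cpath)
                record(
                    stage,
                    n_pairwise=len(screened),
                    n_retained_pairs=int(screened["retained"].sum()),
                    n_candidate_clusters=len(candidates),
                )

            elif stage == "plan":
                tree = topology_newick(config.taxa, config.quartets[0])
                foregrounds = default_foregrounds(config.taxa, config.quartets[0])
                plan = selection.enumerate_branch_tests(candidates, tree, foregrounds)
                path = out / "branch_tests.tsv"
                plan.to_csv(path, sep="\t", index=False)
                stage_files.append(path)
                record(
                    stage,
                    n_candidates=len(candidates),
                    n_foregrounds=len(foregrounds),
                    n_planned_tests=len(plan),
                )
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            for f in stage_files:
                if f.exists():
                    f.rename(f.with_suffix(f.suffix + ".partial"))
            raise StageError(stage, exc) from exc

    report["elapsed_s"] = round(time.time() - started, 3)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
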