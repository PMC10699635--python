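"""Umbrella pipeline: discover -> classify -> freq -> network -> tmrca -> amova -> mca.

Each stage is independently skippable; a stage failure aborts only its
downstream dependents. Every output carries a provenance header and the
run writes a JSON manifest (versions, seed, parameters, per-stage status).
"""

from __future__ import annotations

import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from . import io as yio
from .dating import date_sublineage, tmrca_table
from .discovery import FilterConfig, filter_candidate_snps
from .haplogroup import carrier_frequency_table, classify_haplogroup, default_tree, load_tree
from .network import build_mj_network, compute_str_weights, export_network
from .structure import amova_two_level, mca

logger = logging.getLogger("ylineage.pipeline")

STAGES = ("discover", "classify", "freq", "network", "tmrca", "amova", "mca")


@dataclass
class PipelineConfig:
    out_dir: Path
    str_path: Path | None = None
    genotypes_path: Path | None = None
    tree_path: Path | None = None
    vcf_path: Path | None = None
    mask_path: Path | None = None
    known_path: Path | None = None
    rates_path: Path | None = None
    stages: tuple[str, ...] = STAGES
    window_nt: int = 3000
    epsilon: float = 0.0
    weight_scheme: str = "muzzio"
    metric: str = "pairwise_difference"
    n_permutations: int = 999
    policy: str = "strict"
    mca_supplementary: str | None = "population"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass
class PipelineReport:
    outputs: dict[str, list[str]] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport()
    profiles = yio.read_str_table(config.str_path) if config.str_path else None
    genotypes = yio.read_snp_table(config.genotypes_path) if config.genotypes_path else None
    tree = load_tree(config.tree_path) if config.tree_path else default_tree()
    rates = yio.read_rates(config.rates_path) if config.rates_path else None

    def run_stage(name, requires, fn):
        if name not in config.stages:
            report.skipped.append(name)
            return
        missing = [r for r in requires if r is None]
        if missing:
            report.failures[name] = "missing required inputs"
            logger.error("[%s] missing required inputs", name)
            return
        try:
            report.outputs[name] = [str(p) for p in fn()]
            logger.info("[%s] done", name)
        except Exception as exc:  # pragma: no cover - defensive
            report.failures[name] = f"{type(exc).__name__}: {exc}"
            logger.error("[%s] failed: %s", name, traceback.format_exc())

    def stage_discover():
        variants = yio.read_vcf_variants(config.vcf_path)
        known = yio.read_known_catalog(config.known_path) if config.known_path else set()
        mask = yio.read_bed_mask(config.mask_path) if config.mask_path else {}
        result = filter_candidate_snps(
            variants, known, mask, FilterConfig(window_nt=config.window_nt)
        )
        vcf_out = out / "candidates.vcf"
        audit_out = out / "discovery_audit.json"
        yio.write_vcf_variants(result.kept, vcf_out)
        yio.write_json(
            [
                {"chrom": e["variant"].chrom, "pos": e["variant"].pos, "reason": e["reason"]}
                for e in result.audit
            ],
            audit_out,
            stage="discover",
            seed=config.seed,
            window_nt=config.window_nt,
        )
        return [vcf_out, audit_out]

    def stage_classify():
        results = classify_haplogroup(genotypes, tree, policy=config.policy)
        import pandas as pd

        df = pd.DataFrame(
            [
                (r.sample_id, r.haplogroup, ">".join(r.path), len(r.conflicts))
                for r in results
            ],
            columns=["sample_id", "haplogroup", "path", "n_conflicts"],
        )
        table_out = out / "classifications.tsv"
        conflicts_out = out / "conflicts.json"
        yio.write_tsv(df, table_out, stage="classify", seed=config.seed, policy=config.policy)
        yio.write_json(
            {r.sample_id: r.conflicts for r in results if r.conflicts},
            conflicts_out,
            stage="classify",
            seed=config.seed,
        )
        return [table_out, conflicts_out]

    def stage_freq():
        grouping = "population" if genotypes.populations is not None else None
        df = carrier_frequency_table(genotypes, grouping=grouping)
        path = out / "carrier_frequencies.tsv"
        yio.write_tsv(df, path, stage="freq", seed=config.seed)
        return [path]

    def stage_network():
        weights = compute_str_weights(profiles, scheme=config.weight_scheme)
        net = build_mj_network(profiles, weights=weights, epsilon=config.epsilon)
        gml = out / "network.graphml"
        edges = out / "network_edges.tsv"
        export_network(net, gml, fmt="graphml")
        export_network(net, edges, fmt="tsv")
        return [gml, edges]

    def stage_tmrca():
        from .dating import EMR

        used = rates or [EMR]
        results = date_sublineage(profiles, genotypes, used)
        df = tmrca_table(results)
        path = out / "tmrca.tsv"
        yio.write_tsv(
            df, path, stage="tmrca", seed=config.seed,
            rates=",".join(r.name for r in used),
        )
        return [path]

    def stage_amova():
        result = amova_two_level(
            profiles,
            metric=config.metric,
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        path = out / "amova.tsv"
        yio.write_tsv(
            result.to_frame(), path, stage="amova", seed=config.seed,
            metric=config.metric, permutations=config.n_permutations,
            **{k: f"{v:.5f}" for k, v in result.phi.items()},
            **{f"p_{k}": v for k, v in result.p_values.items()},
        )
        return [path]

    def stage_mca():
        supp = config.mca_supplementary if genotypes.populations is not None else None
        result = mca(genotypes, supplementary=supp)
        coords = out / "mca_coords.csv"
        with open(coords, "w") as fh:
            for line in yio.provenance_lines("mca", seed=config.seed):
                fh.write(line + "\n")
            result.col_coords.to_csv(fh)
        summary = out / "mca_summary.json"
        yio.write_json(
            {
                "eigenvalues": list(map(float, result.eigenvalues)),
                "percent_inertia": list(map(float, result.percent_inertia)),
                "cumulative_percent_dims12": result.cumulative_percent_dims12,
            },
            summary,
            stage="mca",
            seed=config.seed,
        )
        return [coords, summary]

    run_stage("discover", [config.vcf_path], stage_discover)
    run_stage("classify", [genotypes], stage_classify)
    run_stage("freq", [genotypes], stage_freq)
    run_stage("network", [profiles], stage_network)
    run_stage("tmrca", [profiles, genotypes], stage_tmrca)
    run_stage("amova", [profiles], stage_amova)
    run_stage("mca", [genotypes], stage_mca)

    yio.write_json(
        {
            "version": __version__,
            "seed": config.seed,
            "stages_requested": list(config.stages),
            "outputs": {k: v for k, v in report.outputs.items()},
            "failures": report.failures,
            "skipped": report.skipped,
            "parameters": {
                "window_nt": config.window_nt,
                "epsilon": config.epsilon,
                "weight_scheme": config.weight_scheme,
                "metric": config.metric,
                "n_permutations": config.n_permutations,
                "policy": config.policy,
            },
        },
        out / "manifest.json",
        stage="pipeline",
        seed=config.seed,
    )
    return report
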