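"""End-to-end orchestration: simulate/load -> DE -> cluster -> discover ->
compare -> scan -> co-localize -> operon statistics.

``run_all`` chains the stages in memory, writes every table as a plain-text
artifact under one run directory, and records a manifest of per-stage outputs
with content hashes; identical configuration and seed give identical hashes.
Stage seeds are derived deterministically from the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from ._util import derive_seed
from .annotation import GenomeAnnotation
from . import cluster as clustering
from . import colocalization as coloc
from . import diffexpr
from . import operon_stats
from .discovery import DiscoveredMotif, compare_motifs, discover_zoops
from .motifs import (extract_upstream, fixk_reference_pwm, hits_to_bed,
                     read_meme, scan, write_meme)
from .simulate import (SYNTHESIS_STRAINS, SimulationConfig, read_sequences,
                       simulate_dataset, write_dataset)

STAGES = ["simulate", "de", "cluster", "upstream", "discover", "compare",
          "scan", "colocalize", "operon_stats"]

_PARAM_BOUNDS = {
    "window": (1, 10_000), "bandwidth": (1.0, 1e7), "grid_step": (1, 1_000_000),
    "e_threshold": (0.0, np.inf), "compare_p": (0.0, 1.0), "scan_p": (0.0, 1.0),
    "min_count": (0, 1_000_000), "alpha": (0.0, 1.0), "top_k": (1, 10_000),
    "sub_threshold": (0.0, np.inf), "n_motifs": (1, 50), "restarts": (1, 10_000),
    "max_order": (1, 10), "min_fraction": (0.0, 1.0), "max_gap": (0, 1000),
    "min_genes": (1, 100_000),
}


class ConfigError(ValueError):
    """Raised with an itemized report of configuration problems."""


@dataclass
class PipelineConfig:
    """All stage parameters plus optional input paths.

    When no input paths are given, a synthetic dataset is generated from
    ``simulation`` (a :class:`SimulationConfig`).
    """

    genome_fasta: str | None = None
    annotation_gff: str | None = None
    counts_tsv: str | None = None
    regulator_flags_tsv: str | None = None
    reference_motifs_meme: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    parent_strain: str = "parent"
    effect_condition: str = "limited"
    composite_strains: tuple[str, ...] = SYNTHESIS_STRAINS
    window: int = 200
    bandwidth: float = 30000.0
    grid_step: int = 1000
    e_threshold: float = 1e-15
    compare_p: float = 0.001
    scan_p: float = 1e-4
    min_count: int = 10
    alpha: float = 0.05
    moderated: bool = True
    top_k: int = 2
    sub_threshold: float = 7.0
    target_cluster: str | None = None
    width_range: tuple[int, int] = (8, 18)
    n_motifs: int = 3
    restarts: int = 20
    max_order: int = 3
    min_fraction: float = 0.5
    max_gap: int = 3
    min_genes: int = 5
    seed: int = 0
    out_dir: str = "regulocate_run"


def validate_config(source: str | os.PathLike | dict | None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file or dict.

    Unknown keys and out-of-range values are collected into one itemized
    :class:`ConfigError`.  Normalization is idempotent.
    """
    if isinstance(source, PipelineConfig):
        return source
    if source is None:
        raw: dict[str, Any] = {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key in raw:
        if key not in known:
            errors.append(f"unknown key: {key}")
    for key, (lo, hi) in _PARAM_BOUNDS.items():
        if key in raw and raw[key] is not None:
            try:
                v = float(raw[key])
            except (TypeError, ValueError):
                errors.append(f"{key}: not a number ({raw[key]!r})")
                continue
            if not (lo <= v <= hi):
                errors.append(f"{key}: value {raw[key]!r} outside [{lo}, {hi}]")
    for key in ("genome_fasta", "annotation_gff", "counts_tsv",
                "regulator_flags_tsv", "reference_motifs_meme"):
        p = raw.get(key)
        if p is not None and not os.path.exists(p):
            errors.append(f"{key}: file not found ({p})")
    if "width_range" in raw and raw["width_range"] is not None:
        wr = tuple(raw["width_range"])
        if len(wr) != 2 or wr[0] < 2 or wr[1] < wr[0]:
            errors.append(f"width_range: invalid {raw['width_range']!r}")
        raw["width_range"] = wr
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    sim = raw.pop("simulation", None)
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    if isinstance(sim, SimulationConfig):
        cfg.simulation = sim
    elif isinstance(sim, dict):
        sim = dict(sim)
        for tup_key in ("replicon_names", "replicon_lengths", "n_genes",
                        "hot_region", "conditions"):
            if tup_key in sim and sim[tup_key] is not None:
                sim[tup_key] = tuple(sim[tup_key])
        if "strains" in sim and sim["strains"] is not None:
            sim["strains"] = tuple((s, bool(a)) for s, a in sim["strains"])
        if "operon_size_distribution" in sim and sim["operon_size_distribution"]:
            sim["operon_size_distribution"] = {
                int(k): float(v) for k, v in sim["operon_size_distribution"].items()}
        try:
            cfg.simulation = SimulationConfig(**sim)
            cfg.simulation.validate()
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid configuration:\n  simulation: {exc}") from exc
    return cfg


@dataclass
class RunResult:
    """In-memory results of one pipeline run (files listed in the manifest)."""

    config: PipelineConfig
    manifest: pd.DataFrame
    annotation: GenomeAnnotation | None = None
    de_results: dict[str, pd.DataFrame] | None = None
    matrix: pd.DataFrame | None = None
    cluster_labels: pd.Series | None = None
    target_cluster: str | None = None
    discovered: list[DiscoveredMotif] | None = None
    motif_matches: list | None = None
    hits: pd.DataFrame | None = None
    intergenic_hits: pd.DataFrame | None = None
    composite: pd.Series | None = None
    tracks: dict | None = None
    correlations: dict | None = None
    regions: list | None = None
    five_groups: pd.DataFrame | None = None
    group_test: Any = None
    decay: pd.DataFrame | None = None
    enrichment: Any = None
    truth: Any = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out: Path):
        self.out = out
        self.rows: list[tuple[str, str, str, str]] = []

    def add(self, stage: str, key: str, path: Path):
        self.rows.append((stage, key, str(path.relative_to(self.out)),
                          _sha256(path)))

    def note(self, stage: str, key: str, value: str):
        self.rows.append((stage, key, value, ""))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["stage", "key", "path", "sha256"])


def run_all(config: PipelineConfig | dict | str | None = None) -> RunResult:
    """Execute every stage and write all artifacts plus ``manifest.tsv``.

    A stage failure raises with the stage name; artifacts written before the
    failure are retained.
    """
    config = validate_config(config) if not isinstance(config, PipelineConfig) \
        else config
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    result = RunResult(config=config, manifest=pd.DataFrame())
    stage = "setup"
    try:
        # -- stage 1: simulate or load ------------------------------------
        stage = "simulate"
        sim_seed = derive_seed(config.seed, "simulate")
        if config.counts_tsv is None:
            sim_cfg = dataclasses.replace(config.simulation, seed=sim_seed)
            dataset = simulate_dataset(sim_cfg, seed=sim_seed)
            paths = write_dataset(dataset, out / "data")
            for key, p in paths.items():
                manifest.add(stage, key, Path(p))
            sequences = dataset.sequences
            annotation = dataset.annotation
            table = diffexpr.AbundanceTable(dataset.counts, dataset.gene_lengths)
            result.truth = dataset.truth
            parent = sim_cfg.parent_strain
            affected = sim_cfg.affected_strains()
        else:
            if config.genome_fasta is None or config.annotation_gff is None:
                raise ValueError("counts without genome_fasta/annotation_gff")
            sequences = read_sequences(config.genome_fasta)
            annotation = GenomeAnnotation.from_gff3(config.annotation_gff)
            table = diffexpr.AbundanceTable.from_tsv(config.counts_tsv)
            manifest.note(stage, "loaded_counts", str(config.counts_tsv))
            parent = config.parent_strain
            affected = [s for s in table.samples["strain"].unique()
                        if s != parent]
        result.annotation = annotation
        manifest.note(stage, "seed", str(sim_seed))

        # -- stage 2: differential expression ------------------------------
        stage = "de"
        contrasts = diffexpr.between_strain_contrasts(table, parent)
        de_results = {c.label: diffexpr.de_test(
            table, c, min_count=config.min_count, alpha=config.alpha,
            moderated=config.moderated) for c in contrasts}
        de_paths = diffexpr.write_de_results(de_results, out / "de")
        for label, p in de_paths.items():
            manifest.add(stage, label, Path(p))
        result.de_results = de_results

        # -- stage 3: clustering -------------------------------------------
        stage = "cluster"
        matrix = clustering.build_expression_matrix(de_results)
        if len(matrix) < 2:
            raise ValueError("fewer than 2 significant genes; nothing to cluster")
        dendro = clustering.complete_linkage(matrix)
        labels = clustering.cut_clusters(dendro, clustering.ClusterCutParams(
            top_k=config.top_k, sub_threshold=config.sub_threshold))
        heat = out / "cluster" / "heatmap_matrix.tsv"
        heat.parent.mkdir(exist_ok=True)
        clustering.heatmap_export(matrix, dendro, labels, heat)
        labels.rename("cluster").to_csv(out / "cluster" / "clusters.tsv", sep="\t")
        manifest.add(stage, "heatmap_matrix", heat)
        manifest.add(stage, "clusters", out / "cluster" / "clusters.tsv")
        effect_cols = [f"{s}.{config.effect_condition}" for s in affected
                       if f"{s}.{config.effect_condition}" in matrix.columns]
        profiles = clustering.cluster_mean_profiles(
            matrix[effect_cols] if effect_cols else matrix, labels)
        target = (config.target_cluster if config.target_cluster is not None
                  else profiles.mean(axis=1).idxmin())
        result.matrix, result.cluster_labels = matrix, labels
        result.target_cluster = str(target)
        manifest.note(stage, "target_cluster", str(target))

        # -- stage 4: upstream extraction ----------------------------------
        stage = "upstream"
        upstream, truncated = extract_upstream(annotation, sequences,
                                               window=config.window)
        target_genes = [g for g in labels.index[labels == target]
                        if g in upstream and len(upstream[g]) >= config.width_range[0]]
        target_seqs = {g: upstream[g] for g in target_genes}
        up_path = out / "upstream_target_cluster.fasta"
        with open(up_path, "w") as fh:
            for g, s in target_seqs.items():
                fh.write(f">{g}\n{s}\n")
        manifest.add(stage, "upstream_fasta", up_path)

        # -- stage 5: motif discovery --------------------------------------
        stage = "discover"
        found = discover_zoops(target_seqs, width_range=config.width_range,
                               n_motifs=config.n_motifs, restarts=config.restarts,
                               seed=derive_seed(config.seed, "discover"))
        if not found:
            raise ValueError("no motif discovered in the target cluster")
        reported = [m for m in found if m.e_value <= config.e_threshold] or found[:1]
        meme_path = out / "discovered_motifs.meme"
        write_meme({f"motif_{i + 1}": m.pwm for i, m in enumerate(reported)},
                   meme_path,
                   nsites={f"motif_{i + 1}": len(m.sites)
                           for i, m in enumerate(reported)},
                   e_values={f"motif_{i + 1}": m.e_value
                             for i, m in enumerate(reported)})
        manifest.add(stage, "motifs_meme", meme_path)
        result.discovered = found

        # -- stage 6: compare to reference motifs --------------------------
        stage = "compare"
        if config.reference_motifs_meme:
            refs = read_meme(config.reference_motifs_meme)
        else:
            refs = {"FixK_consensus": fixk_reference_pwm()}
        matches = compare_motifs(found[0].pwm, refs,
                                 permutations=1000,
                                 seed=derive_seed(config.seed, "compare"),
                                 p_threshold=config.compare_p,
                                 query_name="discovered_top")
        cmp_df = pd.DataFrame([m.__dict__ for m in matches])
        cmp_df.to_csv(out / "motif_matches.tsv", sep="\t", index=False)
        manifest.add(stage, "motif_matches", out / "motif_matches.tsv")
        result.motif_matches = matches

        # -- stage 7: genome scan ------------------------------------------
        stage = "scan"
        hits = scan(found[0].pwm, sequences, p_threshold=config.scan_p)
        hits_to_bed(hits, out / "motif_hits.bed", name="discovered_top")
        manifest.add(stage, "hits_bed", out / "motif_hits.bed")
        result.hits = hits

        # -- stage 8: co-localization --------------------------------------
        stage = "colocalize"
        intergenic = coloc.filter_orf_hits(hits, annotation)
        result.intergenic_hits = intergenic
        comp_strains = [s for s in config.composite_strains if s in affected] \
            or affected
        composite = coloc.composite_effect(de_results, comp_strains,
                                           config.effect_condition)
        result.composite = composite
        tracks, correlations = {}, {}
        track_rows = []
        for rep, length in annotation.replicon_lengths.items():
            track = coloc.motif_density(hits[hits["replicon"] == rep], length,
                                        bandwidth=config.bandwidth,
                                        grid_step=config.grid_step, replicon=rep)
            tracks[rep] = track
            track_rows.append(track.to_frame())
            if (annotation.genes["replicon"] == rep).sum() >= 3:
                try:
                    correlations[rep] = coloc.density_effect_correlation(
                        track, composite, annotation)
                except ValueError:
                    correlations[rep] = (float("nan"), float("nan"))
        pd.concat(track_rows).to_csv(out / "density_tracks.tsv", sep="\t",
                                     index=False)
        manifest.add(stage, "density_tracks", out / "density_tracks.tsv")
        flags = coloc.de_flags(
            de_results, [f"{s}.{config.effect_condition}" for s in affected
                         if f"{s}.{config.effect_condition}" in de_results])
        regions = coloc.detect_de_regions(annotation, flags,
                                          min_fraction=config.min_fraction,
                                          max_gap=config.max_gap,
                                          min_genes=config.min_genes)
        pd.DataFrame([{"replicon": r.replicon, "start": r.start, "end": r.end,
                       "n_genes": r.n_genes, "fraction_de": r.fraction_de}
                      for r in regions]).to_csv(out / "de_regions.tsv",
                                                sep="\t", index=False)
        manifest.add(stage, "de_regions", out / "de_regions.tsv")
        distances = {}
        for row in annotation.first_genes().itertuples(index=False):
            d = coloc.upstream_distance(row, intergenic, max_window=config.window)
            if d is not None:
                distances[row.gene_id] = d
        pd.Series(distances, name="distance_bp").to_csv(
            out / "upstream_distances.tsv", sep="\t")
        manifest.add(stage, "upstream_distances", out / "upstream_distances.tsv")
        result.tracks, result.correlations, result.regions = (tracks,
                                                              correlations,
                                                              regions)

        # -- stage 9: operon-position statistics ---------------------------
        stage = "operon_stats"
        five = operon_stats.classify_five_groups(annotation, intergenic,
                                                 window=config.window,
                                                 max_order=config.max_order)
        four = operon_stats.classify_four_groups(annotation, intergenic,
                                                 window=config.window)
        # the group analysis is confined to the detected DE regions, where a
        # shared regulatory signal is plausible; genome-wide groups dilute A
        # with unaffected genes
        if regions:
            region_genes = set().union(*(r.gene_ids for r in regions))
            in_regions = five.index.isin(region_genes)
            five = five.copy()
            five.loc[~in_regions, "five_group"] = None
        labels_out = five.copy()
        labels_out.insert(0, "four_group", four)
        labels_out.to_csv(out / "gene_groups.tsv", sep="\t")
        manifest.add(stage, "gene_groups", out / "gene_groups.tsv")
        group_test = operon_stats.group_anova_tukey(composite,
                                                    five["five_group"])
        stats_path = out / "group_stats.tsv"
        with open(stats_path, "w") as fh:
            fh.write(f"# one-way ANOVA F={group_test.f_statistic:.6g} "
                     f"p={group_test.p_value:.6g}\n")
            group_test.tukey.to_csv(fh, sep="\t", index=False)
        manifest.add(stage, "group_stats", stats_path)
        decay = operon_stats.operon_decay_profile(composite, five, annotation,
                                                  max_order=config.max_order)
        decay.to_csv(out / "operon_decay.tsv", sep="\t", index=False)
        manifest.add(stage, "operon_decay", out / "operon_decay.tsv")
        result.five_groups, result.group_test, result.decay = (five, group_test,
                                                               decay)
        if config.regulator_flags_tsv:
            flags_df = pd.read_csv(config.regulator_flags_tsv, sep="\t")
            flagged = set(flags_df.loc[flags_df.iloc[:, 1].astype(bool),
                                       flags_df.columns[0]])
            genome_bp = int(sum(annotation.replicon_lengths.values()))
            if regions:
                region = max(regions, key=lambda r: r.n_genes)
                k = len(flagged & set(region.gene_ids))
                enr = operon_stats.region_enrichment(
                    k, len(flagged), region.length, genome_bp,
                    region_genes=region.n_genes, genome_genes=len(annotation))
                result.enrichment = enr
                pd.DataFrame([enr.__dict__]).to_csv(out / "enrichment.tsv",
                                                    sep="\t", index=False)
                manifest.add(stage, "enrichment", out / "enrichment.tsv")
    except Exception as exc:
        mf = manifest.frame()
        mf.to_csv(out / "manifest.tsv", sep="\t", index=False)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    mf = manifest.frame()
    mf.to_csv(out / "manifest.tsv", sep="\t", index=False)
    result.manifest = mf
    return result
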