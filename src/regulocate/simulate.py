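"""Synthetic multi-replicon transcriptome datasets with planted regulation.

The generator emulates the structure the downstream analysis assumes for a
rhizobial genome: three replicons (chromosome-, megaplasmid- and chromid-
sized), genes packed into operons of 1-7 members, a contiguous "hot region"
on the megaplasmid-like replicon whose operons carry an upstream palindromic
binding site (default consensus TTGAT-N4-ATCAA), and a panel of strains in
which the motif-bearing operons are downregulated under one growth condition
only.  The first gene of a regulated operon takes the full effect and each
further gene is attenuated geometrically; one strain (the glgA1-like control)
and the parent never respond.  Counts are negative-binomial around
length-scaled abundances so that a two-replicate design has realistic
variance.

Every product is deterministic given (config, seed), and a TruthTable records
the planted sites and per-gene true effects for parameter-recovery tests.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import decode, derive_seed, revcomp
from .annotation import Gene, GenomeAnnotation
from .motifs import HIT_COLUMNS, PWM

DEFAULT_REPLICONS = ("chromosome", "pSymA", "pSymB")
DEFAULT_STRAINS: tuple[tuple[str, bool], ...] = (
    ("parent", False),
    ("phbA", True), ("phbB", True), ("phbAB", True), ("phbC", True),
    ("phaZ", True), ("bdhA", True), ("acsA2", True), ("acsA1", True),
    ("glgA1", False),
)
SYNTHESIS_STRAINS = ("phbA", "phbB", "phbAB", "phbC")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    The defaults are the study conditions the package is validated under:
    replicon proportions mimicking the Rm1021 chromosome/pSymA/pSymB, a
    120-kb hot region on the pSymA-like replicon, a first-order effect of
    -3 log2 units halving with each step into the operon, and two replicates
    per strain and condition.
    """

    seed: int = 0
    replicon_names: tuple[str, ...] = DEFAULT_REPLICONS
    replicon_lengths: tuple[int, ...] = (3_650_000, 1_350_000, 1_680_000)
    n_genes: tuple[int, ...] = (1550, 580, 720)
    operon_size_distribution: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.45, 2: 0.20, 3: 0.12, 4: 0.09,
                                 5: 0.06, 6: 0.05, 7: 0.03})
    gene_length_range: tuple[int, int] = (300, 3000)
    intergenic_min: int = 250
    hot_region: tuple[int, int, int] = (1, 600_000, 120_000)  # replicon, start, length
    motif: str = "TTGATNNNNATCAA"
    motif_fixed_prob: float = 0.97
    planted_fraction: float = 0.9
    decoy_rate: float = 2.0  # background placements per Mb outside the hot region
    upstream_window: int = 200
    strains: tuple[tuple[str, bool], ...] = DEFAULT_STRAINS
    parent_strain: str = "parent"
    conditions: tuple[str, str] = ("limited", "balanced")
    effect_condition: str = "limited"
    replicates: int = 2
    effect_beta: float = 3.0
    decay_delta: float = 0.5
    noise_sd: float = 0.5
    baseline_mu_log: float = math.log(500.0)
    baseline_sigma_log: float = 1.0
    dispersion: float = 0.1

    def motif_pwm(self) -> PWM:
        return PWM.from_consensus(self.motif, fixed=self.motif_fixed_prob)

    def affected_strains(self) -> list[str]:
        return [s for s, a in self.strains if a]

    def validate(self) -> None:
        if len(self.replicon_names) != len(self.replicon_lengths) or \
                len(self.n_genes) != len(self.replicon_lengths):
            raise ValueError("replicon_names, replicon_lengths and n_genes must align")
        if any(l <= 0 for l in self.replicon_lengths):
            raise ValueError("replicon lengths must be positive")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must be in [0, 1]")
        if not 0 < self.decay_delta <= 1:
            raise ValueError("decay_delta must be in (0, 1]")
        if self.gene_length_range[0] < 1 or \
                self.gene_length_range[1] < self.gene_length_range[0]:
            raise ValueError("invalid gene_length_range")
        if self.intergenic_min < 0:
            raise ValueError("intergenic_min must be >= 0")
        sizes = self.operon_size_distribution
        if not sizes or any(k < 1 for k in sizes) or \
                not math.isclose(sum(sizes.values()), 1.0, abs_tol=1e-6):
            raise ValueError("operon_size_distribution must sum to 1 over sizes >= 1")
        ridx, start, length = self.hot_region
        if not (0 <= ridx < len(self.replicon_lengths)):
            raise ValueError("hot_region replicon index out of range")
        if start < 0 or start + length > self.replicon_lengths[ridx]:
            raise ValueError("hot_region outside its replicon")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.dispersion < 0 or self.noise_sd < 0:
            raise ValueError("dispersion and noise_sd must be >= 0")
        names = [s for s, _ in self.strains]
        if len(set(names)) != len(names):
            raise ValueError("duplicate strain names")
        if self.parent_strain not in names:
            raise ValueError("parent strain missing from strain list")


@dataclass
class TruthTable:
    """Ground truth of one synthetic dataset."""

    planted_hits: pd.DataFrame  # replicon/start/end/strand/kind ('hot'|'decoy') + operon_id
    true_lfc: pd.DataFrame      # gene_id/strain/condition/log2fc (nonzero rows only)
    regulated_genes: pd.DataFrame  # gene_id/operon_id/operon_order
    skipped_operons: list[str] = field(default_factory=list)

    def lfc_lookup(self) -> dict[tuple[str, str, str], float]:
        return {(r.gene_id, r.strain, r.condition): r.log2fc
                for r in self.true_lfc.itertuples(index=False)}


@dataclass
class SyntheticDataset:
    sequences: dict[str, str]
    annotation: GenomeAnnotation
    truth: TruthTable
    counts: pd.DataFrame          # genes x samples, raw counts
    gene_lengths: pd.Series
    config: SimulationConfig


# -- genome ------------------------------------------------------------------

def generate_genome(config: SimulationConfig, seed: int | None = None
                    ) -> tuple[dict[str, str], GenomeAnnotation]:
    """Random replicon sequences plus a packed gene/operon annotation.

    Genes are laid out left to right; operon members are contiguous on a
    shared strand and all gaps respect ``intergenic_min``.  Within an operon,
    order 1 is the promoter-proximal gene (leftmost on '+', rightmost on '-').
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sizes = sorted(config.operon_size_distribution)
    size_p = np.array([config.operon_size_distribution[s] for s in sizes], dtype=float)
    size_p = size_p / size_p.sum()
    sequences: dict[str, str] = {}
    genes: list[Gene] = []
    for ridx, (rep, length, n) in enumerate(zip(config.replicon_names,
                                                config.replicon_lengths,
                                                config.n_genes)):
        seq = rng.integers(0, 4, size=length, dtype=np.int8)
        sequences[rep] = decode(seq)
        if n == 0:
            continue
        # operon structure: draw sizes until n genes are covered
        op_sizes: list[int] = []
        while sum(op_sizes) < n:
            op_sizes.append(int(rng.choice(sizes, p=size_p)))
        op_sizes[-1] -= sum(op_sizes) - n
        if op_sizes[-1] == 0:
            op_sizes.pop()
        gene_lengths = rng.integers(config.gene_length_range[0],
                                    config.gene_length_range[1] + 1, size=n)
        occupied = int(gene_lengths.sum()) + (n + 1) * config.intergenic_min
        slack = length - occupied
        if slack < 0:
            raise ValueError(
                f"cannot pack {n} genes into replicon {rep!r} "
                f"({occupied} bp needed, {length} available)")
        extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        gaps = config.intergenic_min + extra
        strands = rng.choice(["+", "-"], size=len(op_sizes))
        pos = 0
        gi = 0
        for oi, (osize, strand) in enumerate(zip(op_sizes, strands)):
            op_id = f"{rep}_op{oi + 1:04d}"
            member_coords = []
            for k in range(osize):
                pos += gaps[gi]
                start = pos + 1
                end = pos + int(gene_lengths[gi])
                pos = end
                member_coords.append((start, end))
                gi += 1
            orders = range(1, osize + 1) if strand == "+" else range(osize, 0, -1)
            for (start, end), order in zip(member_coords, orders):
                genes.append(Gene(
                    gene_id=f"{rep}_g{len(genes) + 1:05d}", replicon=rep,
                    start=start, end=end, strand=strand,
                    operon_id=op_id, operon_order=order))
    annotation = GenomeAnnotation(genes, dict(zip(config.replicon_names,
                                                  config.replicon_lengths)))
    return sequences, annotation


# -- motif planting ----------------------------------------------------------

def _first_gene_upstream_interval(row, window: int, replicon_length: int):
    """Forward-strand interval (0-based, half-open) of a gene's 5' window."""
    if row.strand == "+":
        lo, hi = row.start - 1 - window, row.start - 1
    else:
        lo, hi = row.end, row.end + window
    return max(0, lo), min(replicon_length, hi)


def plant_motifs(sequences: Mapping[str, str], annotation: GenomeAnnotation,
                 config: SimulationConfig, seed: int | None = None
                 ) -> tuple[dict[str, str], TruthTable]:
    """Write sampled motif instances upstream of hot-region operons, plus
    intergenic decoys elsewhere, and record every placement.

    Returns mutated sequences and a TruthTable whose ``true_lfc`` is filled
    later by :func:`simulate_expression`.
    """
    config.validate()
    rng = np.random.default_rng(derive_seed(config.seed if seed is None else seed,
                                            "plant"))
    pwm = config.motif_pwm()
    w = pwm.width
    window = config.upstream_window
    ridx, hstart, hlen = config.hot_region
    hot_rep = config.replicon_names[ridx]
    buffers = {rep: bytearray(seq, "ascii") for rep, seq in sequences.items()}
    hits: list[tuple] = []
    skipped: list[str] = []

    first = annotation.first_genes()
    eligible = []
    for row in first.itertuples(index=False):
        if row.replicon != hot_rep:
            continue
        members = annotation.genes[annotation.genes["operon_id"] == row.operon_id]
        lo, hi = int(members["start"].min()), int(members["end"].max())
        if not (hstart < lo and hi <= hstart + hlen):
            continue
        wlo, whi = _first_gene_upstream_interval(row, window,
                                                 config.replicon_lengths[ridx])
        if whi - wlo < w:
            skipped.append(row.operon_id)
            continue
        eligible.append((row, wlo, whi))
    n_plant = int(round(config.planted_fraction * len(eligible)))
    chosen = rng.choice(len(eligible), size=n_plant, replace=False) if n_plant else []
    for ci in sorted(chosen):
        row, wlo, whi = eligible[ci]
        site = pwm.sample(rng)
        strand = rng.choice(["+", "-"])
        if strand == "-":
            site = revcomp(site)
        off = int(rng.integers(wlo, whi - w + 1))
        buffers[hot_rep][off:off + w] = site.encode("ascii")
        hits.append((hot_rep, off + 1, off + w, strand, "hot", row.operon_id))

    # decoys: intergenic-only placements outside the hot region
    gene_iv = {rep: sub[["start", "end"]].to_numpy()
               for rep, sub in annotation.genes.groupby("replicon", sort=False)}
    for rep, length in zip(config.replicon_names, config.replicon_lengths):
        mb = length / 1e6
        if rep == hot_rep:
            mb -= hlen / 1e6
        n_decoys = rng.poisson(config.decoy_rate * max(mb, 0.0))
        placed = 0
        attempts = 0
        iv = gene_iv.get(rep, np.empty((0, 2), int))
        while placed < n_decoys and attempts < 200 * max(n_decoys, 1):
            attempts += 1
            off = int(rng.integers(0, length - w + 1))
            s, e = off + 1, off + w  # 1-based inclusive
            if rep == hot_rep and not (e < hstart or s > hstart + hlen):
                continue
            if iv.size and ((s <= iv[:, 1]) & (e >= iv[:, 0])).any():
                continue
            if any(h[0] == rep and not (e < h[1] or s > h[2]) for h in hits):
                continue
            site = pwm.sample(rng)
            strand = rng.choice(["+", "-"])
            if strand == "-":
                site = revcomp(site)
            buffers[rep][off:off + w] = site.encode("ascii")
            hits.append((rep, s, e, strand, "decoy", ""))
            placed += 1
    if skipped:
        warnings.warn(f"skipped {len(skipped)} operons with no room for an "
                      f"upstream motif", stacklevel=2)
    planted = pd.DataFrame(hits, columns=["replicon", "start", "end", "strand",
                                          "kind", "operon_id"])
    planted = planted.sort_values(["replicon", "start"]).reset_index(drop=True)
    regulated = _regulated_genes(annotation, planted)
    truth = TruthTable(planted_hits=planted,
                       true_lfc=pd.DataFrame(columns=["gene_id", "strain",
                                                      "condition", "log2fc"]),
                       regulated_genes=regulated, skipped_operons=skipped)
    return {rep: buf.decode("ascii") for rep, buf in buffers.items()}, truth


def _regulated_genes(annotation: GenomeAnnotation, planted: pd.DataFrame) -> pd.DataFrame:
    hot_ops = set(planted.loc[planted["kind"] == "hot", "operon_id"])
    sel = annotation.genes[annotation.genes["operon_id"].isin(hot_ops)]
    return sel[["gene_id", "operon_id", "operon_order"]].reset_index(drop=True)


# -- expression --------------------------------------------------------------

def sample_label(strain: str, condition: str, rep: int) -> str:
    return f"{strain}.{condition}.{rep}"


def simulate_expression(annotation: GenomeAnnotation, truth: TruthTable,
                        config: SimulationConfig, seed: int | None = None
                        ) -> tuple[pd.DataFrame, pd.Series, TruthTable]:
    """Negative-binomial counts for every strain x condition x replicate.

    A gene at within-operon order k of a motif-bearing operon has true
    log2 fold change ``-beta * delta**(k-1) + Normal(0, sigma)`` in affected
    strains under the effect condition, and exactly 0 everywhere else.
    Returns (counts, gene_lengths, truth-with-true_lfc).
    """
    config.validate()
    rng = np.random.default_rng(derive_seed(config.seed if seed is None else seed,
                                            "expression"))
    genes = annotation.genes
    n = len(genes)
    lengths = pd.Series(genes["end"].to_numpy() - genes["start"].to_numpy() + 1,
                        index=genes["gene_id"], name="length")
    base = rng.lognormal(config.baseline_mu_log, config.baseline_sigma_log, size=n)
    reg = truth.regulated_genes.set_index("gene_id")["operon_order"]
    reg_idx = genes["gene_id"].isin(reg.index).to_numpy()
    orders = reg.reindex(genes["gene_id"]).to_numpy()

    lfc_rows = []
    columns: dict[str, np.ndarray] = {}
    for strain, affected in config.strains:
        for condition in config.conditions:
            lfc = np.zeros(n)
            if affected and condition == config.effect_condition:
                k = orders[reg_idx]
                lfc[reg_idx] = (-config.effect_beta * config.decay_delta ** (k - 1)
                                + rng.normal(0.0, config.noise_sd, size=reg_idx.sum()))
                for g, v in zip(genes.loc[reg_idx, "gene_id"], lfc[reg_idx]):
                    lfc_rows.append((g, strain, condition, float(v)))
            mean = base * (lengths.to_numpy() / 1000.0) * np.power(2.0, lfc)
            for r in range(1, config.replicates + 1):
                if config.dispersion > 0:
                    shape = 1.0 / config.dispersion
                    counts = rng.poisson(rng.gamma(shape, mean / shape))
                else:
                    counts = rng.poisson(mean)
                columns[sample_label(strain, condition, r)] = counts
    counts = pd.DataFrame(columns, index=genes["gene_id"])
    counts.index.name = "gene_id"
    truth = replace(truth, true_lfc=pd.DataFrame(
        lfc_rows, columns=["gene_id", "strain", "condition", "log2fc"]))
    return counts, lengths, truth


def simulate_dataset(config: SimulationConfig, seed: int | None = None) -> SyntheticDataset:
    """Convenience: genome -> planted motifs -> expression, one seed."""
    seed = config.seed if seed is None else seed
    sequences, annotation = generate_genome(config, seed)
    sequences, truth = plant_motifs(sequences, annotation, config, seed)
    counts, lengths, truth = simulate_expression(annotation, truth, config, seed)
    return SyntheticDataset(sequences=sequences, annotation=annotation,
                            truth=truth, counts=counts, gene_lengths=lengths,
                            config=config)


# -- persistence -------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write FASTA + GFF3 + counts TSV + truth TSVs; all plain text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fasta",
        "gff3": out / "annotation.gff3",
        "counts": out / "counts.tsv",
        "truth_hits": out / "truth_hits.tsv",
        "truth_lfc": out / "truth_lfc.tsv",
        "truth_regulated": out / "truth_regulated.tsv",
    }
    records = [SeqRecord(Seq(seq), id=rep, description="")
               for rep, seq in dataset.sequences.items()]
    SeqIO.write(records, paths["fasta"], "fasta")
    dataset.annotation.to_gff3(paths["gff3"])
    table = dataset.counts.copy()
    table.insert(0, "length", dataset.gene_lengths)
    table.to_csv(paths["counts"], sep="\t")
    dataset.truth.planted_hits.to_csv(paths["truth_hits"], sep="\t", index=False)
    dataset.truth.true_lfc.to_csv(paths["truth_lfc"], sep="\t", index=False)
    dataset.truth.regulated_genes.to_csv(paths["truth_regulated"], sep="\t", index=False)
    return paths


def read_sequences(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
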