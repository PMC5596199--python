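"""Motif/operon-position gene groups and their effect-size statistics.

Genes are classified by whether a binding-site hit lies within a fixed window
5' of their transcription unit (either hit orientation counts; multiple hits
are no different from one; in-ORF hits must be pre-filtered) and by their
position within the operon:

four groups  - A: single transcription unit with motif upstream; B: singleton
without; C: member of an operon with a motif upstream of its first gene;
D: member of an operon without.

five groups  - A: first-order gene with motif upstream (singletons are
first-order); B/C: second/third-order genes of a motif-bearing operon;
E: member of a motif-less operon; Z: first-order gene without a motif.
Members beyond the maximum order of a motif-bearing operon are excluded from
testing but reported with their order.

Group differences are tested with one-way ANOVA plus Tukey HSD, the
within-operon decay is summarized by per-order means, and regulator-gene
enrichment in a region is the length-normalized fold (k/K)/(region/genome).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .colocalization import upstream_distance


@dataclass
class GroupTestResult:
    group_means: pd.Series
    group_sizes: pd.Series
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # columns group1, group2, meandiff, p_adj
    dropped_groups: list[str] = field(default_factory=list)

    def tukey_p(self, g1: str, g2: str) -> float:
        t = self.tukey
        sel = t[((t["group1"] == g1) & (t["group2"] == g2)) |
                ((t["group1"] == g2) & (t["group2"] == g1))]
        if sel.empty:
            raise KeyError((g1, g2))
        return float(sel["p_adj"].iloc[0])


@dataclass
class EnrichmentResult:
    k: int
    K: int
    region_bp: int
    genome_bp: int
    fold: float
    p_hypergeom: float | None = None


def _operon_motif_table(annotation, hits: pd.DataFrame, window: int) -> pd.DataFrame:
    """Per-operon: size and whether a hit sits within `window` bp 5' of the
    first gene (hits assumed pre-filtered of in-ORF occurrences)."""
    first = annotation.first_genes()
    sizes = annotation.operon_sizes()
    recs = []
    for row in first.itertuples(index=False):
        d = upstream_distance(row, hits, max_window=window)
        recs.append((row.operon_id, int(sizes[row.operon_id]), d is not None,
                     d if d is not None else np.nan))
    return pd.DataFrame(recs, columns=["operon_id", "size", "motif_upstream",
                                       "upstream_distance"]).set_index("operon_id")


def classify_four_groups(annotation, hits: pd.DataFrame,
                         window: int = 200) -> pd.Series:
    """Gene -> A/B/C/D by singleton-vs-operon and operon motif status."""
    ops = _operon_motif_table(annotation, hits, window)
    labels = {}
    for row in annotation.genes.itertuples(index=False):
        op = ops.loc[row.operon_id]
        if op["size"] == 1:
            labels[row.gene_id] = "A" if op["motif_upstream"] else "B"
        else:
            labels[row.gene_id] = "C" if op["motif_upstream"] else "D"
    return pd.Series(labels, name="four_group")


def classify_five_groups(annotation, hits: pd.DataFrame, window: int = 200,
                         max_order: int = 3) -> pd.DataFrame:
    """Gene -> A/B/C/E/Z plus operon order; order > max_order in motif-bearing
    operons gets a null label (excluded from testing, still reported)."""
    ops = _operon_motif_table(annotation, hits, window)
    order_names = {1: "A", 2: "B", 3: "C"}
    recs = []
    for row in annotation.genes.itertuples(index=False):
        op = ops.loc[row.operon_id]
        order = int(row.operon_order)
        if op["motif_upstream"]:
            label = order_names.get(order) if order <= max_order else None
        else:
            label = "Z" if op["size"] == 1 else "E"
        recs.append((row.gene_id, label, order,
                     op["upstream_distance"] if order == 1 else np.nan))
    return pd.DataFrame(recs, columns=["gene_id", "five_group", "order",
                                       "upstream_distance"]).set_index("gene_id")


def group_anova_tukey(log2fc: pd.Series, labels: pd.Series,
                      min_group_size: int = 2) -> GroupTestResult:
    """One-way fixed-effects ANOVA over groups plus Tukey HSD adjusted
    pairwise p-values (studentized-range distribution)."""
    df = pd.DataFrame({"y": log2fc, "g": labels}).dropna()
    sizes = df.groupby("g")["y"].count()
    dropped = list(sizes.index[sizes < min_group_size])
    if dropped:
        warnings.warn(f"dropping groups with <{min_group_size} members: "
                      f"{dropped}", stacklevel=2)
        df = df[~df["g"].isin(dropped)]
        sizes = sizes.drop(dropped)
    if len(sizes) < 2:
        raise ValueError("need at least two groups with enough members")
    groups = [df.loc[df["g"] == g, "y"].to_numpy() for g in sizes.index]
    if np.ptp(np.concatenate(groups)) < 1e-15:
        f_stat, p = 0.0, 1.0  # all observations identical
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_stat, p = stats.f_oneway(*groups)
        if not np.isfinite(f_stat):
            f_stat, p = 0.0, 1.0
    tk = pairwise_tukeyhsd(df["y"].to_numpy(), df["g"].to_numpy())
    pairs = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    tukey = pairs[["group1", "group2"]].copy()
    tukey["meandiff"] = np.asarray(tk.meandiffs, dtype=float)
    tukey["p_adj"] = np.asarray(tk.pvalues, dtype=float)  # unrounded
    return GroupTestResult(group_means=df.groupby("g")["y"].mean(),
                           group_sizes=sizes, f_statistic=float(f_stat),
                           p_value=float(p), tukey=tukey,
                           dropped_groups=dropped)


def operon_decay_profile(log2fc: pd.Series, five_groups: pd.DataFrame,
                         annotation, max_order: int = 3) -> pd.DataFrame:
    """Mean/SE of log2fc by within-operon order, separately for operons with
    and without an upstream motif, plus a monotone-attenuation flag.

    The flag is True when the motif-bearing means increase strictly toward 0
    across orders 1..max_order; None when fewer than two orders have data.
    """
    joined = five_groups.join(log2fc.rename("log2fc"))
    motif_labels = {"A", "B", "C"}
    rows = []
    for with_motif in (True, False):
        if with_motif:
            sel = joined[joined["five_group"].isin(motif_labels)]
        else:
            sel = joined[joined["five_group"] == "E"]
        for order in range(1, max_order + 1):
            vals = sel.loc[sel["order"] == order, "log2fc"].dropna()
            rows.append(("motif" if with_motif else "no_motif", order,
                         float(vals.mean()) if len(vals) else np.nan,
                         float(vals.std(ddof=1) / np.sqrt(len(vals)))
                         if len(vals) > 1 else np.nan,
                         int(len(vals))))
    out = pd.DataFrame(rows, columns=["operon_class", "order", "mean_log2fc",
                                      "se", "n"])
    motif_means = out.loc[out["operon_class"] == "motif", "mean_log2fc"]
    defined = motif_means.dropna()
    monotone = bool(np.all(np.diff(defined) > 0)) if len(defined) >= 2 else None
    out.attrs["monotone_attenuation"] = monotone
    return out


def region_enrichment(k: int, K: int, region_bp: int, genome_bp: int,
                      region_genes: int | None = None,
                      genome_genes: int | None = None) -> EnrichmentResult:
    """Length-normalized overrepresentation of flagged genes in a region.

    fold = (k/K) / (region_bp/genome_bp).  When gene counts are supplied, an
    auxiliary hypergeometric tail p (>= k flagged in the region) is added.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if not (0 <= k <= K):
        raise ValueError("need 0 <= k <= K")
    if region_bp <= 0 or genome_bp < region_bp:
        raise ValueError("need genome_bp >= region_bp > 0")
    fold = (k / K) / (region_bp / genome_bp)
    p = None
    if region_genes is not None and genome_genes is not None:
        p = float(stats.hypergeom.sf(k - 1, genome_genes, K, region_genes))
    return EnrichmentResult(k=k, K=K, region_bp=region_bp, genome_bp=genome_bp,
                            fold=float(fold), p_hypergeom=p)
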