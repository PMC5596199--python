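"""Overlaying motif occurrence and expression effect along the genome.

Four views are provided: a Gaussian kernel-density track of motif hits per
replicon (one unit of mass per hit, so the track integrates to the hit count);
a composite per-gene effect profile (mean log2 fold change over a strain
panel); contiguous differentially-expressed gene regions found by a
run/gap/fraction rule; and motif-to-ORF distance distributions.  The
headline statistic is the correlation between per-gene motif density and the
composite effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DensityTrack:
    """Kernel density of point features along one replicon."""

    replicon: str
    positions: np.ndarray  # bp grid
    density: np.ndarray
    bandwidth: float

    def value_at(self, pos) -> np.ndarray:
        return np.interp(pos, self.positions, self.density)

    @property
    def argmax_position(self) -> float:
        return float(self.positions[int(np.argmax(self.density))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"replicon": self.replicon, "pos": self.positions,
                             "density": self.density})


@dataclass
class Region:
    """A contiguous run of genes with a high differential-expression fraction."""

    replicon: str
    start: int
    end: int
    gene_ids: list[str]
    fraction_de: float

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _gaussian_sum(points: np.ndarray, grid: np.ndarray, bandwidth: float,
                  normalize: bool) -> np.ndarray:
    """Sum of unit-mass Gaussian kernels evaluated on a grid."""
    if points.size == 0:
        return np.zeros_like(grid, dtype=float)
    z = (grid[:, None] - points[None, :]) / bandwidth
    dens = np.exp(-0.5 * z ** 2).sum(axis=1) / (bandwidth * np.sqrt(2 * np.pi))
    if normalize:
        dens /= points.size
    return dens


def motif_density(hits: pd.DataFrame, replicon_length: int,
                  bandwidth: float = 30000, grid_step: int = 1000,
                  replicon: str | None = None) -> DensityTrack:
    """Gaussian kernel density of hit midpoints along one replicon.

    Each hit contributes one unit of mass, so co-located hits add linearly.
    """
    if replicon is None:
        reps = hits["replicon"].unique()
        if len(reps) > 1:
            raise ValueError("hits span multiple replicons; pass `replicon`")
        replicon = reps[0] if len(reps) else "?"
    sel = hits[hits["replicon"] == replicon] if len(hits) else hits
    mid = ((sel["start"].to_numpy() + sel["end"].to_numpy()) / 2.0
           if len(sel) else np.empty(0))
    grid = np.arange(0, replicon_length + 1, grid_step, dtype=float)
    dens = _gaussian_sum(np.asarray(mid, dtype=float), grid, bandwidth,
                         normalize=False)
    return DensityTrack(replicon=replicon, positions=grid, density=dens,
                        bandwidth=bandwidth)


def composite_effect(de_results: dict[str, pd.DataFrame], strains: list[str],
                     condition: str) -> pd.Series:
    """Per-gene mean log2fc over ``<strain>.<condition>`` contrasts, NA-skipping."""
    if not strains:
        raise ValueError("empty strain set")
    cols = []
    for strain in strains:
        label = f"{strain}.{condition}"
        if label not in de_results:
            raise KeyError(f"contrast {label!r} missing from DE results")
        cols.append(de_results[label]["log2fc"].rename(label))
    mat = pd.concat(cols, axis=1)
    out = mat.mean(axis=1, skipna=True)
    out.name = "composite_log2fc"
    return out


def de_flags(de_results: dict[str, pd.DataFrame],
             labels: list[str] | None = None) -> pd.Series:
    """Gene -> significant in at least one of the given contrasts."""
    use = labels if labels is not None else list(de_results)
    flags = None
    for label in use:
        s = de_results[label]["significant"].astype(bool)
        flags = s if flags is None else (flags | s)
    flags.name = "de_any"
    return flags


def detect_de_regions(annotation, flags: pd.Series, min_fraction: float = 0.5,
                      max_gap: int = 3, min_genes: int = 5) -> list[Region]:
    """Maximal runs of genes (annotation order) whose flagged fraction is high.

    Flagged genes separated by at most ``max_gap`` consecutive unflagged genes
    are merged into one candidate region; the region spans its first to last
    flagged gene and is kept when it has >= ``min_genes`` members and a
    flagged fraction >= ``min_fraction``.
    """
    regions: list[Region] = []
    for rep, sub in annotation.genes.groupby("replicon", sort=False):
        sub = sub.sort_values("start")
        f = flags.reindex(sub["gene_id"]).fillna(False).to_numpy(dtype=bool)
        idx = np.nonzero(f)[0]
        if idx.size == 0:
            continue
        runs: list[list[int]] = [[idx[0]]]
        for i in idx[1:]:
            if i - runs[-1][-1] - 1 <= max_gap:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            lo, hi = run[0], run[-1]
            members = sub.iloc[lo:hi + 1]
            frac = f[lo:hi + 1].mean()
            if len(members) >= min_genes and frac >= min_fraction:
                regions.append(Region(
                    replicon=rep, start=int(members["start"].min()),
                    end=int(members["end"].max()),
                    gene_ids=list(members["gene_id"]),
                    fraction_de=float(frac)))
    return regions


def filter_orf_hits(hits: pd.DataFrame, annotation) -> pd.DataFrame:
    """Drop hits overlapping any annotated ORF (in-gene motifs are ignored)."""
    keep = np.ones(len(hits), dtype=bool)
    for rep, sub in annotation.genes.groupby("replicon", sort=False):
        iv = sub[["start", "end"]].to_numpy()
        sel = hits["replicon"] == rep
        if not sel.any():
            continue
        s = hits.loc[sel, "start"].to_numpy()[:, None]
        e = hits.loc[sel, "end"].to_numpy()[:, None]
        overlap = ((s <= iv[None, :, 1]) & (e >= iv[None, :, 0])).any(axis=1)
        keep[np.nonzero(sel.to_numpy())[0][overlap]] = False
    return hits[keep].reset_index(drop=True)


def upstream_distance(gene, hits: pd.DataFrame, max_window: int = 200) -> int | None:
    """Strand-aware distance from an ORF start to its nearest 5' motif hit.

    For a '+' gene the distance is ``gene_start - hit_end`` and for a '-'
    gene ``hit_start - gene_end`` (1 means immediately adjacent).  Hits must
    already be filtered of in-ORF occurrences; returns None beyond
    ``max_window``.
    """
    sel = hits[hits["replicon"] == gene.replicon]
    if sel.empty:
        return None
    if gene.strand == "+":
        d = gene.start - sel["end"].to_numpy()
    else:
        d = sel["start"].to_numpy() - gene.end
    d = d[(d >= 1) & (d <= max_window)]
    return int(d.min()) if d.size else None


def distance_density(distances, bandwidth: float = 10.0,
                     max_window: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """1-D Gaussian KDE of motif-to-ORF distances on a 0..max_window grid."""
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0:
        raise ValueError("no distances to estimate a density from")
    if (d < 1).any():
        raise ValueError("distances must be >= 1")
    grid = np.arange(0, max_window + 1, dtype=float)
    dens = _gaussian_sum(d, grid, bandwidth, normalize=True)
    return grid, dens


def density_effect_correlation(track: DensityTrack, composite: pd.Series,
                               annotation) -> tuple[float, float]:
    """Pearson and Spearman correlation of per-gene motif density with the
    composite effect, over genes of the track's replicon.

    Each gene's density is the track value at its midpoint.
    """
    genes = annotation.genes
    sub = genes[genes["replicon"] == track.replicon]
    vals = composite.reindex(sub["gene_id"])
    ok = vals.notna().to_numpy()
    if ok.sum() < 3:
        raise ValueError("need at least 3 genes with a defined composite effect")
    mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0)[ok]
    dens = track.value_at(mids)
    eff = vals.to_numpy(dtype=float)[ok]
    if np.std(eff) < 1e-15 or np.std(dens) < 1e-15:
        warnings.warn("constant input; correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r = float(stats.pearsonr(dens, eff).statistic)
    rho = float(stats.spearmanr(dens, eff).statistic)
    return r, rho
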