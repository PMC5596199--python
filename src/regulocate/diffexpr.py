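"""FPKM normalization, fold changes and per-contrast significance testing.

The contract mirrors a Cuffdiff-style stage: counts are FPKM-normalized
(``1e9 * count / (length * total mapped)``, the total being the column sum of
the count table), the log2 fold change is taken between group mean FPKMs, and
genes are tested only when their summed raw count across the contrast reaches
a minimum threshold.  p-values get Benjamini-Hochberg correction over the
tested genes and a gene is significant when q <= alpha.

Two test flavours are provided.  ``moderated=True`` (default) shrinks the
per-gene pooled variance toward an F-distributed prior fitted across genes
(the limma construction), which is what makes two-replicate designs usable:
a plain per-gene Welch t with n=2 has ~2 degrees of freedom and cannot reach
BH-surviving p-values over thousands of genes.  ``moderated=False`` gives the
plain Welch t with the documented zero-variance conventions.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests

DE_COLUMNS = ["gene_id", "mean_fpkm_a", "mean_fpkm_b", "log2fc", "p", "q",
              "tested", "significant"]


class AbundanceTable:
    """Per-gene raw counts with gene lengths and structured sample labels.

    Sample labels follow ``<strain>.<condition>.<replicate>``.
    """

    def __init__(self, counts: pd.DataFrame, gene_lengths: pd.Series):
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        lengths = gene_lengths.reindex(counts.index)
        if lengths.isna().any() or (lengths <= 0).any():
            raise ValueError("every gene needs a positive length")
        if counts.columns.duplicated().any():
            raise ValueError("duplicate sample labels")
        self.counts = counts.astype(float)
        self.gene_lengths = lengths.astype(float)
        self._fpkm: pd.DataFrame | None = None

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.DataFrame:
        recs = []
        for label in self.counts.columns:
            m = re.match(r"(.+)\.([^.]+)\.([^.]+)$", label)
            if not m:
                raise ValueError(f"sample label {label!r} is not strain.condition.rep")
            recs.append((label, m.group(1), m.group(2), m.group(3)))
        return pd.DataFrame(recs, columns=["label", "strain", "condition",
                                           "replicate"]).set_index("label")

    @property
    def fpkm(self) -> pd.DataFrame:
        if self._fpkm is None:
            totals = self.counts.sum(axis=0)
            if (totals <= 0).any():
                raise ValueError("a sample has zero total counts")
            self._fpkm = 1e9 * self.counts / np.outer(self.gene_lengths, totals)
        return self._fpkm

    def samples_for(self, strain: str, condition: str) -> list[str]:
        s = self.samples
        sel = s[(s["strain"] == strain) & (s["condition"] == condition)]
        return list(sel.index)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.drop(columns=["length"]), df["length"])

    def to_tsv(self, path: str | os.PathLike) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.gene_lengths)
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class Contrast:
    """Two disjoint sample groups; log2fc is b relative to a."""

    label: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    kind: str = "between-strain"

    def __post_init__(self):
        if not self.group_a or not self.group_b:
            raise ValueError("both contrast groups must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("contrast groups overlap")


def fpkm(count: float, gene_length_bp: float, total_mapped_in_sample: float) -> float:
    """Fragments per kilobase of gene per million mapped fragments."""
    if gene_length_bp <= 0 or total_mapped_in_sample <= 0:
        raise ValueError("gene length and total mapped count must be positive")
    return 1e9 * count / (gene_length_bp * total_mapped_in_sample)


def log2_fold_change(mean_fpkm_a: float, mean_fpkm_b: float) -> float:
    """log2(b/a); NaN when either mean is zero."""
    if mean_fpkm_a < 0 or mean_fpkm_b < 0:
        raise ValueError("mean FPKM must be >= 0")
    if mean_fpkm_a == 0 or mean_fpkm_b == 0:
        return float("nan")
    return float(np.log2(mean_fpkm_b / mean_fpkm_a))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN inputs propagate as NaN and
    are excluded from the number of tests."""
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of s2 ~ s0^2 F(df, d0) on the log scale.

    Returns (s0^2, d0); d0 = inf when the observed spread of log s2 is no
    wider than the sampling spread, i.e. a common variance fits.
    """
    z = np.log(s2)
    e_z = z.mean() - (polygamma(0, df / 2) - np.log(df / 2))
    v = z.var(ddof=1) - polygamma(1, df / 2)
    if v <= 1e-12:
        return float(np.exp(e_z)), float("inf")
    lo, hi = 1e-2, 1e6
    for _ in range(200):
        mid = (lo + hi) / 2
        if polygamma(1, mid / 2) > v:
            lo = mid
        else:
            hi = mid
    d0 = (lo + hi) / 2
    s0 = np.exp(e_z + polygamma(0, d0 / 2) - np.log(d0 / 2))
    return float(s0), float(d0)


def de_test(table: AbundanceTable, contrast: Contrast, min_count: int = 10,
            alpha: float = 0.05, moderated: bool = True) -> pd.DataFrame:
    """Per-gene differential expression for one contrast.

    A gene is tested iff its total raw count over the contrast's samples is
    at least ``min_count``.  The test operates on log2(FPKM + 1).
    """
    for s in contrast.group_a + contrast.group_b:
        if s not in table.counts.columns:
            raise ValueError(f"sample {s!r} missing from table")
    counts_a = table.counts[list(contrast.group_a)]
    counts_b = table.counts[list(contrast.group_b)]
    fpkm_all = table.fpkm
    fa = fpkm_all[list(contrast.group_a)]
    fb = fpkm_all[list(contrast.group_b)]
    mean_a = fa.mean(axis=1).to_numpy()
    mean_b = fb.mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.where((mean_a > 0) & (mean_b > 0), np.log2(mean_b / mean_a), np.nan)
    total = counts_a.sum(axis=1).to_numpy() + counts_b.sum(axis=1).to_numpy()
    tested = total >= min_count

    na, nb = len(contrast.group_a), len(contrast.group_b)
    p = np.full(len(table.gene_ids), np.nan)
    if na < 2 or nb < 2:
        warnings.warn(f"contrast {contrast.label!r} has a group with <2 "
                      f"replicates; tests skipped", stacklevel=2)
        tested = np.zeros_like(tested)
    else:
        xa = np.log2(fa.to_numpy() + 1.0)
        xb = np.log2(fb.to_numpy() + 1.0)
        va = xa.var(axis=1, ddof=1)
        vb = xb.var(axis=1, ddof=1)
        diff = xb.mean(axis=1) - xa.mean(axis=1)
        if moderated:
            df_res = na + nb - 2
            pooled = ((na - 1) * va + (nb - 1) * vb) / df_res
            pos = tested & (pooled > 0)
            if pos.sum() >= 10:
                s0, d0 = _fit_f_dist(pooled[pos], df_res)
            else:
                s0, d0 = max(float(np.mean(pooled[tested])) if tested.any() else 1e-4,
                             1e-8), 10.0
            if np.isinf(d0):
                mod_var = np.full_like(pooled, s0)
                df_total = np.inf
            else:
                mod_var = (d0 * s0 + df_res * pooled) / (d0 + df_res)
                df_total = d0 + df_res
            se = np.sqrt(mod_var * (1.0 / na + 1.0 / nb))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = diff / se
            if np.isinf(df_total):
                p_all = 2 * stats.norm.sf(np.abs(t))
            else:
                p_all = 2 * stats.t.sf(np.abs(t), df_total)
            p = np.where(tested, p_all, np.nan)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                se2 = va / na + vb / nb
                t = diff / np.sqrt(se2)
                df_w = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            p_all = 2 * stats.t.sf(np.abs(t), df_w)
            zero_var = se2 == 0
            if zero_var.any():
                eq = zero_var & (np.abs(diff) < 1e-12)
                ne = zero_var & ~eq
                p_all[eq] = 1.0
                if ne.any():
                    warnings.warn("zero-variance genes with unequal means set "
                                  "to p=0", stacklevel=2)
                p_all[ne] = 0.0
            p = np.where(tested, p_all, np.nan)
    q = bh_fdr(p)
    significant = tested & (q <= alpha)
    return pd.DataFrame({
        "gene_id": table.gene_ids, "mean_fpkm_a": mean_a, "mean_fpkm_b": mean_b,
        "log2fc": lfc, "p": p, "q": q, "tested": tested,
        "significant": significant,
    }).set_index("gene_id")


def between_strain_contrasts(table: AbundanceTable, parent: str) -> list[Contrast]:
    """Mutant-vs-parent contrasts for every non-parent strain and condition."""
    s = table.samples
    out = []
    for strain in s["strain"].unique():
        if strain == parent:
            continue
        for condition in s["condition"].unique():
            ga = tuple(table.samples_for(parent, condition))
            gb = tuple(table.samples_for(strain, condition))
            if ga and gb:
                out.append(Contrast(label=f"{strain}.{condition}", group_a=ga,
                                    group_b=gb, kind="between-strain"))
    return out


def within_strain_contrast(table: AbundanceTable, strain: str,
                           condition_a: str, condition_b: str) -> Contrast:
    """Same strain, two growth conditions (b relative to a)."""
    return Contrast(label=f"{strain}.{condition_b}_vs_{condition_a}",
                    group_a=tuple(table.samples_for(strain, condition_a)),
                    group_b=tuple(table.samples_for(strain, condition_b)),
                    kind="within-strain")


def write_de_results(results: dict[str, pd.DataFrame], out_dir: str | os.PathLike) -> dict:
    paths = {}
    os.makedirs(out_dir, exist_ok=True)
    for label, df in results.items():
        path = os.path.join(out_dir, f"de_{label}.tsv")
        df.to_csv(path, sep="\t")
        paths[label] = path
    return paths


def read_de_results(paths: dict[str, str | os.PathLike]) -> dict[str, pd.DataFrame]:
    return {label: pd.read_csv(p, sep="\t", index_col=0)
            for label, p in paths.items()}
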