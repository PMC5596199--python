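"""Gene and operon annotation for multi-replicon bacterial genomes.

The central container is :class:`GenomeAnnotation`: a table of genes with
1-based inclusive coordinates, a strand, and operon membership expressed as an
``operon_id`` plus a transcription-order index (``operon_order``; 1 is the
promoter-proximal gene).  Genes of one operon are contiguous on the same
strand; for a minus-strand operon the order-1 gene is the rightmost one.

GFF3 is the on-disk format: ``gene`` features carrying ``ID``, ``operon_id``
and ``operon_order`` attributes, with ``##sequence-region`` pragmas recording
replicon lengths.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import gffutils
import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "replicon", "start", "end", "strand", "operon_id", "operon_order"]


@dataclass(frozen=True)
class Gene:
    """A single gene: 1-based inclusive coordinates on a named replicon."""

    gene_id: str
    replicon: str
    start: int
    end: int
    strand: str
    operon_id: str
    operon_order: int


class GenomeAnnotation:
    """Genes with coordinates, strand and operon structure.

    Parameters
    ----------
    genes
        Iterable of :class:`Gene` or a DataFrame with :data:`GENE_COLUMNS`.
    replicon_lengths
        Mapping replicon name -> length in bp.
    """

    def __init__(self, genes, replicon_lengths: Mapping[str, int]):
        if isinstance(genes, pd.DataFrame):
            df = genes.loc[:, GENE_COLUMNS].copy()
        else:
            df = pd.DataFrame([g.__dict__ for g in genes], columns=GENE_COLUMNS)
        df = df.sort_values(["replicon", "start"], kind="mergesort").reset_index(drop=True)
        self.genes = df
        self.replicon_lengths = dict(replicon_lengths)
        self._validate()

    def _validate(self) -> None:
        df = self.genes
        if df.empty:
            return
        if df["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")
        if (df["start"] < 1).any() or (df["end"] < df["start"]).any():
            raise ValueError("invalid gene coordinates")
        for rep, sub in df.groupby("replicon", sort=False):
            if rep not in self.replicon_lengths:
                raise ValueError(f"gene on unknown replicon {rep!r}")
            if (sub["end"] > self.replicon_lengths[rep]).any():
                raise ValueError(f"gene beyond end of replicon {rep!r}")
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (starts[1:] <= ends[:-1]).any():
                raise ValueError(f"overlapping genes on replicon {rep!r}")
        for op, sub in df.groupby("operon_id", sort=False):
            if sub["strand"].nunique() != 1:
                raise ValueError(f"operon {op!r} mixes strands")
            orders = np.sort(sub["operon_order"].to_numpy())
            if not np.array_equal(orders, np.arange(1, len(sub) + 1)):
                raise ValueError(f"operon {op!r} has non-consecutive orders")

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def replicons(self) -> list[str]:
        return list(self.replicon_lengths)

    def operons(self) -> Iterator[tuple[str, pd.DataFrame]]:
        """Yield (operon_id, members ordered by operon_order)."""
        for op, sub in self.genes.groupby("operon_id", sort=False):
            yield op, sub.sort_values("operon_order")

    def first_genes(self) -> pd.DataFrame:
        """The order-1 (promoter-proximal) gene of every transcription unit."""
        return self.genes[self.genes["operon_order"] == 1]

    def operon_sizes(self) -> pd.Series:
        return self.genes.groupby("operon_id")["gene_id"].count()

    def gene(self, gene_id: str) -> pd.Series:
        row = self.genes[self.genes["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        return row.iloc[0]

    def min_intergenic_gap(self) -> int | None:
        gaps = []
        for _, sub in self.genes.groupby("replicon", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            gaps.extend(starts[1:] - ends[:-1] - 1)
        return int(min(gaps)) if gaps else None

    # -- GFF3 round trip ---------------------------------------------------

    def to_gff3(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for rep, length in self.replicon_lengths.items():
                fh.write(f"##sequence-region {rep} 1 {length}\n")
            for row in self.genes.itertuples(index=False):
                attrs = (
                    f"ID={row.gene_id};operon_id={row.operon_id};"
                    f"operon_order={row.operon_order}"
                )
                fh.write(
                    f"{row.replicon}\tregulocate\tgene\t{row.start}\t{row.end}"
                    f"\t.\t{row.strand}\t.\t{attrs}\n"
                )

    @classmethod
    def from_gff3(cls, path: str | os.PathLike) -> "GenomeAnnotation":
        lengths: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, rep, _, end = line.split()
                    lengths[rep] = int(end)
                elif not line.startswith("#"):
                    break
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        genes = []
        for feat in db.features_of_type("gene"):
            genes.append(
                Gene(
                    gene_id=feat.attributes["ID"][0],
                    replicon=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                    operon_id=feat.attributes["operon_id"][0],
                    operon_order=int(feat.attributes["operon_order"][0]),
                )
            )
        for g in genes:
            lengths.setdefault(g.replicon, max(g.end for x in genes if x.replicon == g.replicon))
        return cls(genes, lengths)
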