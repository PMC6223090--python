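"""Gene tables: intervals, TSS, strand, and a summary expression value."""

from __future__ import annotations

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "expression"]


class GeneTable:
    """Genes with 0-based half-open body intervals and non-negative expression.

    The expression column is a per-gene summary (e.g. the median normalized
    expression across a tumor cohort). TSS is derived from strand: start for
    '+', end - 1 for '-'.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in GENE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"GeneTable missing columns: {missing}")
        if df["gene_id"].duplicated().any():
            raise ValueError("gene_id values must be unique")
        if (df["expression"] < 0).any():
            raise ValueError("expression must be non-negative")
        df = df.reset_index(drop=True)
        tss = np.where(df["strand"] == "-", df["end"] - 1, df["start"])
        self.df = df.assign(tss=tss)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def read_tsv(cls, path) -> "GeneTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
        return cls(df)

    def write_tsv(self, path) -> None:
        self.df[GENE_COLUMNS].to_csv(path, sep="\t", index=False)

    def expression_of(self, gene_ids) -> np.ndarray:
        sub = self.df.set_index("gene_id").loc[list(gene_ids), "expression"]
        return sub.to_numpy(dtype=float)

    def interval_tree(self):
        """chrom -> IntervalTree of gene bodies (payload gene_id), cached."""
        if not hasattr(self, "_trees"):
            from intervaltree import IntervalTree

            trees = {}
            for row in self.df.itertuples(index=False):
                trees.setdefault(row.chrom, IntervalTree()).addi(
                    row.start, row.end, row.gene_id
                )
            self._trees = trees
        return self._trees

    def row_by_id(self, gene_id):
        if not hasattr(self, "_by_id"):
            self._by_id = {
                row.gene_id: row for row in self.df.itertuples(index=False)
            }
        return self._by_id[gene_id]
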