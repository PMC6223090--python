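"""Somatic mutation records and the tab-separated catalog reader.

Positions are 1-based (ICGC/VCF convention). Single-base substitutions, and
insertions/deletions up to 200 bp, are retained; multi-base substitutions and
longer indels are dropped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

MAX_INDEL_LEN = 200

REQUIRED_COLUMNS = ("chrom", "pos", "ref", "alt", "donor_id")

_CONTROL_TISSUES = {"blood", "adjacent", "unknown"}


@dataclass
class MutationRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    donor_id: str
    mut_type: str  # SNV | INS | DEL
    control_tissue: str = "unknown"


def infer_mut_type(ref: str, alt: str) -> str | None:
    """SNV if both alleles are single differing bases; INS/DEL by length;
    None for multi-base substitutions (dropped upstream)."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNV" if ref != alt else None
    if len(alt) > len(ref):
        return "INS"
    if len(ref) > len(alt):
        return "DEL"
    return None  # equal-length multi-base substitution


class MutationTable:
    """Column-oriented somatic mutation catalog.

    Wraps a DataFrame with columns chrom, pos, ref, alt, donor_id, mut_type,
    control_tissue.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in ("chrom", "pos", "ref", "alt", "donor_id", "mut_type") if c not in df.columns]
        if missing:
            raise ValueError(f"MutationTable missing columns: {missing}")
        if "control_tissue" not in df.columns:
            df = df.assign(control_tissue="unknown")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def of_type(self, *mut_types: str) -> "MutationTable":
        return MutationTable(self.df[self.df["mut_type"].isin(mut_types)].copy())

    @property
    def snvs(self) -> "MutationTable":
        return self.of_type("SNV")

    def subset_donors(self, donor_ids) -> "MutationTable":
        return MutationTable(self.df[self.df["donor_id"].isin(set(donor_ids))].copy())

    def by_control_tissue(self, tissue: str) -> "MutationTable":
        return MutationTable(self.df[self.df["control_tissue"] == tissue].copy())

    def records(self):
        for row in self.df.itertuples(index=False):
            yield MutationRecord(
                chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt,
                donor_id=str(row.donor_id), mut_type=row.mut_type,
                control_tissue=getattr(row, "control_tissue", "unknown"),
            )


def read_mutation_table(path) -> MutationTable:
    """Read a tab-separated mutation catalog with a header line.

    Required columns: chrom, pos (1-based), ref, alt, donor_id. Optional:
    mutation_type, control_tissue. mut_type is inferred from allele lengths
    when absent; indels > 200 bp and multi-base substitutions are dropped and
    the counts logged.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    try:
        df["pos"] = df["pos"].astype("int64")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-integer value in 'pos' column") from exc
    if (df["pos"] < 1).any():
        raise ValueError(f"{path}: positions must be >= 1")

    if "mutation_type" in df.columns:
        df = df.rename(columns={"mutation_type": "mut_type"})
    if "mut_type" not in df.columns:
        df["mut_type"] = [infer_mut_type(r, a) for r, a in zip(df["ref"], df["alt"])]

    n0 = len(df)
    df = df[df["mut_type"].isin(["SNV", "INS", "DEL"])]
    n_multi = n0 - len(df)
    indel_len = (df["ref"].str.len() - df["alt"].str.len()).abs()
    too_long = (df["mut_type"] != "SNV") & (indel_len > MAX_INDEL_LEN)
    n_long = int(too_long.sum())
    df = df[~too_long].copy()
    if n_multi:
        logger.info("dropped %d multi-base substitution(s)", n_multi)
    if n_long:
        logger.info("dropped %d indel(s) longer than %d bp", n_long, MAX_INDEL_LEN)

    if "control_tissue" in df.columns:
        bad = ~df["control_tissue"].isin(_CONTROL_TISSUES)
        df.loc[bad, "control_tissue"] = "unknown"
    return MutationTable(df)


def write_mutation_table(table: MutationTable, path) -> None:
    cols = ["chrom", "pos", "ref", "alt", "donor_id", "mut_type", "control_tissue"]
    table.df[cols].to_csv(path, sep="\t", index=False)
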