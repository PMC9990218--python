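"""Panel coordinate frame: gene intervals, SNP loci and chromosome arms.

Everything downstream (depth tables, BAF profiles, segment calls) is expressed
in this frame. Coordinates are 0-based half-open throughout; VCF input/output
converts at the boundary. CNA-bearing content is restricted to the autosomes
(chr1..chr22); optional chrX/chrY genes are carried solely for sex inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
SEX_CHROMS = ("chrX", "chrY")

# Approximate GRCh38 chromosome lengths and centromere midpoints (Mb). These
# anchor the synthetic genome; only ratios of arm lengths matter downstream.
_CHROM_MB = {
    "chr1": (249, 123), "chr2": (242, 93), "chr3": (198, 91), "chr4": (190, 50),
    "chr5": (182, 48), "chr6": (171, 60), "chr7": (159, 60), "chr8": (145, 45),
    "chr9": (138, 43), "chr10": (134, 40), "chr11": (135, 53), "chr12": (133, 36),
    "chr13": (114, 18), "chr14": (107, 17), "chr15": (102, 19), "chr16": (90, 37),
    "chr17": (83, 25), "chr18": (80, 18), "chr19": (59, 26), "chr20": (64, 28),
    "chr21": (47, 12), "chr22": (51, 15), "chrX": (156, 61), "chrY": (57, 10),
}
_MB = 1_000_000


def default_arm_table(include_sex: bool = True) -> pd.DataFrame:
    """Chromosome-arm boundary table: chrom, arm (p/q), start, end."""
    rows = []
    for chrom, (length, cen) in _CHROM_MB.items():
        if not include_sex and chrom in SEX_CHROMS:
            continue
        rows.append((chrom, "p", 0, cen * _MB))
        rows.append((chrom, "q", cen * _MB, length * _MB))
    return pd.DataFrame(rows, columns=["chrom", "arm", "start", "end"])


@dataclass
class PanelDesign:
    """A targeted sequencing panel: gene intervals, SNP loci, arm boundaries.

    Attributes
    ----------
    genes : DataFrame with columns gene_id, chrom, start, end, arm
    snp_loci : DataFrame with columns chrom, pos, ref, alt, arm, gene_id
        ``gene_id`` is the gene whose footprint (or nearest flank) contains
        the locus; used to attach BAF evidence to genes.
    arms : DataFrame with columns chrom, arm, start, end
    """

    genes: pd.DataFrame
    snp_loci: pd.DataFrame
    arms: pd.DataFrame = field(default_factory=default_arm_table)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def autosomal_genes(self) -> pd.DataFrame:
        return self.genes[self.genes["chrom"].isin(AUTOSOMES)]

    @property
    def n_genes(self) -> int:
        return int(len(self.autosomal_genes))

    @property
    def n_snp_loci(self) -> int:
        return int(len(self.snp_loci))

    def arm_bounds(self, chrom: str, arm: str) -> tuple[int, int]:
        row = self.arms[(self.arms["chrom"] == chrom) & (self.arms["arm"] == arm)]
        if row.empty:
            raise KeyError(f"no arm definition for {chrom}{arm}")
        return int(row["start"].iloc[0]), int(row["end"].iloc[0])

    def validate(self) -> None:
        g = self.genes
        required = {"gene_id", "chrom", "start", "end", "arm"}
        missing = required - set(g.columns)
        if missing:
            raise ValueError(f"panel genes missing columns: {sorted(missing)}")
        if (g["end"] <= g["start"]).any():
            raise ValueError("gene intervals must be half-open with end > start")
        if g["gene_id"].duplicated().any():
            dup = g.loc[g["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        # non-overlap within each chromosome
        for chrom, sub in g.groupby("chrom", sort=False):
            s = sub.sort_values("start")
            if (s["start"].values[1:] < s["end"].values[:-1]).any():
                raise ValueError(f"overlapping gene intervals on {chrom}")
        if not self.snp_loci.empty:
            bad = ~self.snp_loci["chrom"].isin(AUTOSOMES)
            if bad.any():
                raise ValueError("SNP loci must be autosomal")
        # every autosomal gene/locus inside exactly one arm
        for _, row in self.autosomal_genes.iterrows():
            a0, a1 = self.arm_bounds(row["chrom"], row["arm"])
            if not (a0 <= row["start"] and row["end"] <= a1):
                raise ValueError(f"gene {row['gene_id']} outside its arm span")

    def gene_order(self) -> pd.DataFrame:
        """Autosomal genes in genomic order (chrom rank, then start)."""
        g = self.autosomal_genes.copy()
        g["_rank"] = g["chrom"].map({c: i for i, c in enumerate(AUTOSOMES)})
        return g.sort_values(["_rank", "start"]).drop(columns="_rank").reset_index(drop=True)
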