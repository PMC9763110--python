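"""Genomic annotation bundle consumed by QC and burden encoding.

Tracks are BED-convention DataFrames (0-based half-open). Gene models are
isoform-collapsed: a gene's span runs from the minimum start to the maximum
end over its isoforms, and only protein-coding genes (RefSeq ``NM_``
accessions) enter burden calculations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io

__all__ = ["AnnotationBundle", "collapse_isoforms", "load_annotation"]


def collapse_isoforms(isoforms: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-isoform rows to one span per gene symbol.

    Uses the minimum start and maximum end position across a gene's
    isoforms. ``protein_coding`` is derived from the accession prefix
    (``NM_`` = protein coding) when an ``accession`` column is present.
    """
    grouped = isoforms.groupby("symbol", sort=True)
    genes = grouped.agg(
        chrom=("chrom", "first"),
        start=("start", "min"),
        end=("end", "max"),
    ).reset_index()
    if "accession" in isoforms.columns:
        coding = grouped["accession"].agg(
            lambda a: bool(a.str.startswith("NM_").any())
        )
        genes["protein_coding"] = genes["symbol"].map(coding)
    else:
        genes["protein_coding"] = True
    return genes


@dataclass
class AnnotationBundle:
    """All annotation inputs of the pipeline.

    Attributes
    ----------
    chrom_lengths : dict
        Chromosome name -> length in bp.
    probes : dict
        Chromosome name -> sorted array of probe positions.
    special : DataFrame
        Centromere / telomere / immunoglobulin / T-cell-receptor intervals
        (columns chrom, start, end, name).
    segdups : DataFrame
        Segmental-duplication intervals (chrom, start, end).
    ndd_regions : DataFrame
        Neurodevelopmental CNV regions (label, chrom, start, end, cnv_type).
    isoforms : DataFrame
        Per-isoform gene rows (symbol, chrom, start, end, accession).
    genesets : dict
        Set name -> (category, list of member gene symbols).
    """

    chrom_lengths: dict[str, int]
    probes: dict[str, np.ndarray]
    special: pd.DataFrame
    segdups: pd.DataFrame
    ndd_regions: pd.DataFrame
    isoforms: pd.DataFrame
    genesets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for df, what in [
            (self.special, "special region"),
            (self.segdups, "segmental duplication"),
            (self.ndd_regions, "NDD region"),
            (self.isoforms, "gene isoform"),
        ]:
            if not len(df):
                continue
            for _, row in df.iterrows():
                if row["chrom"] not in self.chrom_lengths:
                    raise ValueError(f"{what} on unknown chromosome {row['chrom']!r}")
                if row["end"] > self.chrom_lengths[row["chrom"]] or row["start"] < 0:
                    label = row.get("label", f"{row['chrom']}:{row['start']}-{row['end']}")
                    raise ValueError(
                        f"{what} {label!r} exceeds chromosome bounds "
                        f"({row['chrom']} length {self.chrom_lengths[row['chrom']]})"
                    )

    @property
    def genes(self) -> pd.DataFrame:
        """Isoform-collapsed protein-coding gene spans."""
        genes = collapse_isoforms(self.isoforms)
        return genes[genes["protein_coding"]].reset_index(drop=True)

    def chrom_codes(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(sorted(self.chrom_lengths))}

    # -- persistence -------------------------------------------------------

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_json(
            {c: int(n) for c, n in self.chrom_lengths.items()},
            outdir / "chromosomes.json",
        )
        pd.DataFrame(
            [(c, int(p)) for c, pos in self.probes.items() for p in pos],
            columns=["chrom", "position"],
        ).to_csv(outdir / "probes.tsv", sep="\t", index=False)
        io.write_bed(self.special, outdir / "special_regions.bed", extra=["name"])
        io.write_bed(self.segdups, outdir / "segdups.bed")
        ndd = self.ndd_regions[["chrom", "start", "end", "label", "cnv_type"]]
        ndd.to_csv(outdir / "ndd_regions.bed", sep="\t", index=False, header=False)
        self.isoforms[["chrom", "start", "end", "symbol", "accession"]].to_csv(
            outdir / "gene_isoforms.bed", sep="\t", index=False, header=False
        )
        rows = [
            (name, cat, g)
            for name, (cat, members) in self.genesets.items()
            for g in members
        ]
        pd.DataFrame(rows, columns=["set", "category", "symbol"]).to_csv(
            outdir / "genesets.tsv", sep="\t", index=False
        )


def load_annotation(indir: str | Path) -> AnnotationBundle:
    """Load an annotation bundle written by :meth:`AnnotationBundle.write`."""
    indir = Path(indir)
    chrom_lengths = {k: int(v) for k, v in io.read_json(indir / "chromosomes.json").items()}
    probe_df = pd.read_csv(indir / "probes.tsv", sep="\t")
    probes = {
        c: np.sort(g["position"].to_numpy(dtype=np.int64))
        for c, g in probe_df.groupby("chrom")
    }
    special = io.read_bed(indir / "special_regions.bed", names=["name"])
    segdups = io.read_bed(indir / "segdups.bed")
    ndd = io.read_bed(indir / "ndd_regions.bed", names=["label", "cnv_type"])
    isoforms = io.read_bed(indir / "gene_isoforms.bed", names=["symbol", "accession"])
    gs = pd.read_csv(indir / "genesets.tsv", sep="\t")
    genesets: dict[str, tuple[str, list[str]]] = {}
    for name, g in gs.groupby("set"):
        genesets[name] = (g["category"].iloc[0], g["symbol"].tolist())
    return AnnotationBundle(
        chrom_lengths=chrom_lengths,
        probes=probes,
        special=special,
        segdups=segdups,
        ndd_regions=ndd[["label", "chrom", "start", "end", "cnv_type"]],
        isoforms=isoforms,
        genesets=genesets,
    )
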