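"""Containers for per-well amplicon read tables and OTU tables.

A sequencing library (one PCR plate) holds 60 sample replicates plus control
wells: blanks (estimate tag switching), extraction and PCR-negative controls
(catch contamination), and positive controls (a 10-taxon assembly with
increasing concentrations). Wells are identified by ``well_id`` and carry
either a ``sample_id`` or a ``control_type``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

SAMPLE = "sample"
CONTROL_TYPES = ("blank", "extraction", "negative", "positive")
#: Controls used for contaminant detection (positive controls deliberately
#: contain real plant DNA and are excluded).
NEGATIVE_CONTROLS = ("blank", "extraction", "negative")

WELL_COLUMNS = (
    "well_id",
    "sample_id",
    "species",
    "year",
    "subarea",
    "control_type",
    "library_id",
)


@dataclass
class ReplicateReadTable:
    """Read counts of amplicon sequences per PCR well.

    Attributes
    ----------
    counts : DataFrame with columns (sequence_id, well_id, read_count); only
        non-zero cells are stored.
    wells : DataFrame indexed by well_id with sample/control metadata.
    sequences : mapping sequence_id -> nucleotide string.
    """

    counts: pd.DataFrame
    wells: pd.DataFrame
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = self.counts.reset_index(drop=True)
        if "well_id" in self.wells.columns:
            self.wells = self.wells.set_index("well_id")
        unknown_wells = set(self.counts["well_id"]) - set(self.wells.index)
        if unknown_wells:
            raise ValueError(f"wells without metadata: {sorted(unknown_wells)[:5]}")
        unknown_seqs = set(self.counts["sequence_id"]) - set(self.sequences)
        if unknown_seqs:
            raise ValueError(f"unregistered sequences: {sorted(unknown_seqs)[:5]}")
        if (self.counts["read_count"] < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def total_reads(self) -> int:
        return int(self.counts["read_count"].sum())

    def sequence_totals(self) -> pd.Series:
        """Total reads per sequence across all wells, descending."""
        return (
            self.counts.groupby("sequence_id")["read_count"]
            .sum()
            .sort_values(ascending=False)
        )

    def drop_sequences(self, sequence_ids) -> "ReplicateReadTable":
        drop = set(sequence_ids)
        counts = self.counts[~self.counts["sequence_id"].isin(drop)]
        seqs = {k: v for k, v in self.sequences.items() if k not in drop}
        return ReplicateReadTable(counts, self.wells.reset_index(), seqs)

    # ---- IO -------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the long-format table with well metadata joined in."""
        out = self.counts.merge(
            self.wells.reset_index(), on="well_id", how="left"
        )[
            [
                "sequence_id",
                "well_id",
                "sample_id",
                "species",
                "year",
                "subarea",
                "control_type",
                "library_id",
                "read_count",
            ]
        ]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, fasta: str | Path) -> "ReplicateReadTable":
        df = pd.read_csv(path, sep="\t", dtype={"subarea": "object"})
        wells = (
            df[list(WELL_COLUMNS)]
            .drop_duplicates(subset="well_id")
            .reset_index(drop=True)
        )
        counts = df[["sequence_id", "well_id", "read_count"]]
        sequences = read_fasta(fasta)
        return cls(counts, wells, sequences)


@dataclass
class OTUTable:
    """Read counts per OTU per well, after clustering.

    ``otus`` is indexed by otu_id with columns ``centroid`` (sequence),
    ``taxon`` (assigned label or NA) and ``identity`` (best reference
    identity in [0, 1], NaN before assignment).
    """

    counts: pd.DataFrame  # otu_id, well_id, read_count
    wells: pd.DataFrame
    otus: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.reset_index(drop=True)
        if "well_id" in self.wells.columns:
            self.wells = self.wells.set_index("well_id")
        if "otu_id" in self.otus.columns:
            self.otus = self.otus.set_index("otu_id")

    @property
    def total_reads(self) -> int:
        return int(self.counts["read_count"].sum())

    def relative_abundance(self) -> pd.DataFrame:
        """Within-well relative abundance per (otu, well) cell."""
        out = self.counts.copy()
        well_tot = out.groupby("well_id")["read_count"].transform("sum")
        out["rel_abundance"] = out["read_count"] / well_tot
        return out

    def drop_otus(self, otu_ids) -> "OTUTable":
        drop = set(otu_ids)
        counts = self.counts[~self.counts["otu_id"].isin(drop)]
        otus = self.otus[~self.otus.index.isin(drop)]
        return OTUTable(counts, self.wells.reset_index(), otus.reset_index())

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.merge(self.wells.reset_index(), on="well_id", how="left")
        out = out.merge(
            self.otus.reset_index()[["otu_id", "taxon", "identity"]],
            on="otu_id",
            how="left",
        )
        out.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {record id: uppercase sequence}."""
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except FileNotFoundError:
        raise IOError(f"cannot read FASTA file: {path}")
    if not records:
        raise IOError(f"no FASTA records found in: {path}")
    return {rec.id: str(rec.seq).upper() for rec in records}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
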