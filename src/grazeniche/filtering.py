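"""Metabarcode read filtering: raw replicate table -> per-individual diets.

The cascade, in order: length filter, per-cell minimum read filter,
single-mismatch denoising, greedy 97% centroid clustering, taxonomic
assignment against a reference FASTA, contaminant removal (control vs sample
relative abundance), per-library tag-leak removal calibrated on blanks,
low-depth replicate removal, and finally merging of PCR replicates into
per-individual P/A, FOO and RRA profiles.

Contaminant removal runs before tag-leak removal: a contaminant inflates
blank wells and would otherwise distort the leak-rate estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .align import edit_distance, global_identity
from .readtable import (
    NEGATIVE_CONTROLS,
    OTUTable,
    ReplicateReadTable,
    read_fasta,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Sequence-level filters
# ---------------------------------------------------------------------------


def length_filter(
    table: ReplicateReadTable, min_len: int = 10, max_len: int = 220
) -> ReplicateReadTable:
    """Drop sequences whose length lies outside the closed [min_len, max_len]."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    bad = [
        sid for sid, seq in table.sequences.items() if not min_len <= len(seq) <= max_len
    ]
    if bad:
        logger.info("length_filter: removing %d sequences", len(bad))
    return table.drop_sequences(bad)


def min_read_filter(table: ReplicateReadTable, threshold: int = 10) -> ReplicateReadTable:
    """Zero out (sequence, well) cells with fewer than ``threshold`` reads.

    'Fewer than' is strict: a cell with exactly ``threshold`` reads survives.
    """
    counts = table.counts[table.counts["read_count"] >= threshold]
    return ReplicateReadTable(counts, table.wells.reset_index(), dict(table.sequences))


def denoise_single_mismatch(table: ReplicateReadTable) -> ReplicateReadTable:
    """Merge each sequence into its most abundant single-mismatch neighbour.

    A sequence within edit distance 1 of a strictly more abundant sequence
    (by global read total) has its counts added to that neighbour; among
    several candidates the most abundant wins, ties broken by lexicographic
    sequence order. Chains (A <- B <- C) are resolved by processing sequences
    in descending abundance, so counts flow to the chain head.
    """
    totals = table.sequence_totals()
    order = sorted(totals.index, key=lambda sid: (-totals[sid], table.sequences[sid]))
    parent: dict[str, str] = {}

    def root(sid: str) -> str:
        while sid in parent:
            sid = parent[sid]
        return sid

    for i, sid in enumerate(order):
        seq = table.sequences[sid]
        best = None
        for other in order[:i]:  # strictly more abundant, or equal-total earlier
            if totals[other] <= totals[sid]:
                continue
            if edit_distance(seq, table.sequences[other], k=1) == 1:
                if best is None or (
                    (-totals[other], table.sequences[other])
                    < (-totals[best], table.sequences[best])
                ):
                    best = other
        if best is not None:
            parent[sid] = root(best)
    if not parent:
        return table
    mapping = {sid: root(sid) for sid in order}
    counts = table.counts.copy()
    counts["sequence_id"] = counts["sequence_id"].map(mapping)
    counts = (
        counts.groupby(["sequence_id", "well_id"], as_index=False)["read_count"].sum()
    )
    keep = set(counts["sequence_id"])
    seqs = {k: v for k, v in table.sequences.items() if k in keep}
    logger.info("denoise: merged %d sequences", len(parent))
    return ReplicateReadTable(counts, table.wells.reset_index(), seqs)


def greedy_centroid_cluster(
    table: ReplicateReadTable, identity_threshold: float = 0.97
) -> OTUTable:
    """Greedy abundance-ordered centroid clustering (Sumaclust/UCLUST style).

    Sequences are visited in descending global abundance (ties by sequence
    string); each joins the first existing centroid with global-alignment
    identity >= threshold, else founds a new OTU named after its centroid.
    """
    totals = table.sequence_totals()
    order = sorted(totals.index, key=lambda sid: (-totals[sid], table.sequences[sid]))
    centroids: list[str] = []
    assignment: dict[str, str] = {}
    for sid in order:
        seq = table.sequences[sid]
        for cid in centroids:
            if global_identity(seq, table.sequences[cid]) >= identity_threshold:
                assignment[sid] = cid
                break
        else:
            centroids.append(sid)
            assignment[sid] = sid
    counts = table.counts.copy()
    counts["otu_id"] = counts["sequence_id"].map(assignment)
    counts = counts.groupby(["otu_id", "well_id"], as_index=False)["read_count"].sum()
    otus = pd.DataFrame(
        {
            "otu_id": centroids,
            "centroid": [table.sequences[c] for c in centroids],
            "taxon": pd.NA,
            "identity": np.nan,
        }
    )
    return OTUTable(counts, table.wells.reset_index(), otus)


# ---------------------------------------------------------------------------
# OTU-level filters
# ---------------------------------------------------------------------------


def assign_taxa(
    otus: OTUTable, reference: dict[str, str] | str, min_identity: float = 0.97
) -> OTUTable:
    """Label OTUs with their best-identity reference taxon; drop poor hits.

    ``reference`` is a taxon->sequence mapping or a FASTA path whose record
    ids are taxon labels. OTUs whose best identity falls below
    ``min_identity`` are removed from the dataset.
    """
    if isinstance(reference, str):
        reference = read_fasta(reference)
    if not reference:
        raise ValueError("reference set is empty")
    otu_meta = otus.otus.copy()
    labels, idents = [], []
    for _, row in otu_meta.iterrows():
        best_taxon, best_id = None, -1.0
        for taxon, seq in reference.items():
            ident = global_identity(row["centroid"], seq)
            if ident > best_id:
                best_taxon, best_id = taxon, ident
        labels.append(best_taxon)
        idents.append(best_id)
    otu_meta["taxon"] = labels
    otu_meta["identity"] = idents
    keep = otu_meta["identity"] >= min_identity
    dropped = otu_meta.index[~keep]
    if len(dropped):
        logger.info("assign_taxa: removed %d OTUs below %.2f identity",
                    len(dropped), min_identity)
    out = OTUTable(otus.counts, otus.wells.reset_index(), otu_meta.reset_index())
    return out.drop_otus(dropped)


def remove_contaminants(otus: OTUTable) -> OTUTable:
    """Remove OTUs more abundant in negative controls than in any sample.

    Comparison uses within-well *relative* abundance (control wells are much
    shallower than sample wells): an OTU is removed everywhere iff its
    maximum relative abundance over blank/extraction/negative wells exceeds
    its maximum over sample wells. Positive controls, which contain real
    plant DNA by design, are excluded from the comparison.
    """
    wells = otus.wells
    ctrl_wells = wells.index[wells["control_type"].isin(NEGATIVE_CONTROLS)]
    if len(ctrl_wells) == 0:
        logger.warning("remove_contaminants: no control wells, table unchanged")
        return otus
    rel = otus.relative_abundance()
    is_ctrl = rel["well_id"].isin(set(ctrl_wells))
    is_sample = rel["well_id"].map(wells["control_type"].isna())
    ctrl_max = rel[is_ctrl].groupby("otu_id")["rel_abundance"].max()
    samp_max = rel[is_sample].groupby("otu_id")["rel_abundance"].max()
    all_otus = otus.otus.index
    ctrl_max = ctrl_max.reindex(all_otus, fill_value=0.0)
    samp_max = samp_max.reindex(all_otus, fill_value=0.0)
    drop = all_otus[ctrl_max > samp_max]
    if len(drop):
        logger.info("remove_contaminants: removed %d OTUs: %s",
                    len(drop), list(drop))
    return otus.drop_otus(drop)


def remove_tag_leaks(otus: OTUTable) -> OTUTable:
    """Per-library removal of tag-switched signal, calibrated on blanks.

    Blanks receive reads only through tag switching, so the fraction of an
    OTU's library-wide reads that lands in a blank estimates its leak rate.
    Within each library, tau is the maximum such per-OTU blank share; every
    (OTU, well) cell of the library holding <= tau of that OTU's library
    total is then zeroed — discarding single OTU cells rather than whole PCR
    replicates. Libraries without blank reads get tau = 0 (no removal,
    logged).
    """
    wells = otus.wells
    rel = otus.counts.merge(
        wells[["library_id", "control_type"]], left_on="well_id", right_index=True
    )
    otu_lib_total = rel.groupby(["library_id", "otu_id"])["read_count"].transform(
        "sum"
    )
    rel["otu_share"] = rel["read_count"] / otu_lib_total
    taus = (
        rel[rel["control_type"] == "blank"]
        .groupby("library_id")["otu_share"]
        .max()
    )
    libraries = wells["library_id"].unique()
    taus = taus.reindex(libraries, fill_value=0.0).fillna(0.0)
    for lib, tau in taus.items():
        if tau == 0.0:
            logger.info("remove_tag_leaks: library %s has empty blanks, tau=0", lib)
    rel["tau"] = rel["library_id"].map(taus)
    keep = rel["otu_share"] > rel["tau"]
    counts = otus.counts[keep.to_numpy()]
    n_zeroed = int((~keep).sum())
    if n_zeroed:
        logger.info("remove_tag_leaks: zeroed %d cells", n_zeroed)
    return OTUTable(counts, wells.reset_index(), otus.otus.reset_index())


def discard_low_count_replicates(otus: OTUTable, min_total_reads: int = 100) -> OTUTable:
    """Drop wells whose total retained reads fall below ``min_total_reads``."""
    if min_total_reads < 0:
        raise ValueError("min_total_reads must be >= 0")
    well_tot = (
        otus.counts.groupby("well_id")["read_count"]
        .sum()
        .reindex(otus.wells.index, fill_value=0)
    )
    drop = well_tot.index[well_tot < min_total_reads]
    if len(drop):
        logger.info("discard_low_count_replicates: dropped %d wells", len(drop))
    counts = otus.counts[~otus.counts["well_id"].isin(set(drop))]
    wells = otus.wells.drop(index=drop)
    return OTUTable(counts, wells.reset_index(), otus.otus.reset_index())


# ---------------------------------------------------------------------------
# Replicate merging and dissimilarity
# ---------------------------------------------------------------------------


@dataclass
class DietProfiles:
    """Per-individual diet quantification on three bases.

    ``pa``, ``foo`` and ``rra`` are sample x taxon matrices: presence/absence
    (0/1), frequency of occurrence (fraction of retained PCR replicates
    detecting the taxon) and mean relative read abundance (mean over retained
    replicates of the within-replicate read proportion; rows sum to 1).
    ``meta`` maps sample_id to species, year, subarea and the number of
    retained replicates.
    """

    pa: pd.DataFrame
    foo: pd.DataFrame
    rra: pd.DataFrame
    meta: pd.DataFrame

    def basis(self, name: str) -> pd.DataFrame:
        if name not in ("pa", "foo", "rra"):
            raise ValueError(f"unknown basis {name!r}")
        return getattr(self, name)

    def to_csv(self, path) -> None:
        tidy = (
            pd.concat(
                {
                    "pa": self.pa.stack(),
                    "foo": self.foo.stack(),
                    "rra": self.rra.stack(),
                },
                axis=1,
            )
            .rename_axis(["sample_id", "taxon"])
            .reset_index()
        )
        tidy = tidy.merge(self.meta, on="sample_id")
        tidy.to_csv(path, index=False)


def merge_replicates(otus: OTUTable, by: str = "taxon") -> DietProfiles:
    """Merge retained PCR replicates into per-individual diet profiles.

    OTU counts are first aggregated by assigned taxon (``by="otu"`` keeps
    OTU resolution). Individuals with zero retained replicates are dropped
    with a log entry.
    """
    wells = otus.wells
    sample_wells = wells[wells["control_type"].isna()]
    counts = otus.counts.merge(
        otus.otus[["taxon"]], left_on="otu_id", right_index=True
    )
    key = "taxon" if by == "taxon" else "otu_id"
    if by == "taxon" and counts["taxon"].isna().any():
        raise ValueError("merge_replicates by taxon requires assigned OTUs")
    counts = counts[counts["well_id"].isin(set(sample_wells.index))]
    counts = counts.groupby([key, "well_id"], as_index=False)["read_count"].sum()
    # within-replicate proportions
    counts["prop"] = counts["read_count"] / counts.groupby("well_id")[
        "read_count"
    ].transform("sum")
    counts = counts.merge(
        sample_wells[["sample_id"]], left_on="well_id", right_index=True
    )

    retained = (
        counts.groupby("sample_id")["well_id"].nunique().rename("n_replicates_retained")
    )
    all_samples = sample_wells["sample_id"].unique()
    lost = set(all_samples) - set(retained.index)
    if lost:
        logger.info("merge_replicates: dropped %d individuals with no retained "
                    "replicates: %s", len(lost), sorted(lost)[:5])

    prop = counts.pivot_table(
        index="sample_id", columns=key, values="prop", aggfunc="sum", fill_value=0.0
    )
    det = counts.pivot_table(
        index="sample_id", columns=key, values="well_id", aggfunc="nunique",
        fill_value=0,
    )
    foo = det.div(retained.loc[det.index], axis=0)
    rra = prop.div(retained.loc[prop.index], axis=0)
    pa = (foo > 0).astype(int)

    meta = (
        sample_wells[["sample_id", "species", "year", "subarea"]]
        .drop_duplicates()
        .set_index("sample_id")
        .loc[pa.index]
        .join(retained)
        .reset_index()
    )
    return DietProfiles(pa=pa, foo=foo, rra=rra, meta=meta)


def bray_curtis_matrix(profiles: DietProfiles, basis: str = "rra") -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity between individuals.

    BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i); a pair of all-zero vectors
    is defined as 0 (logged).
    """
    mat = profiles.basis(basis)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    d = squareform(pdist(mat.to_numpy(float), metric="braycurtis"))
    if np.isnan(d).any():
        logger.info("bray_curtis_matrix: all-zero vector pair(s), distance set to 0")
        d = np.nan_to_num(d, nan=0.0)
    return pd.DataFrame(d, index=mat.index, columns=mat.index)


# ---------------------------------------------------------------------------
# The full cascade
# ---------------------------------------------------------------------------


@dataclass
class FilterSettings:
    """Thresholds of the filtering cascade (defaults as used in the study)."""

    min_len: int = 10
    max_len: int = 220
    min_reads_per_cell: int = 10
    cluster_identity: float = 0.97
    reference_identity: float = 0.97
    min_replicate_reads: int = 100
    merge_by: str = "taxon"


def run_filter_cascade(
    table: ReplicateReadTable,
    reference: dict[str, str] | str,
    settings: FilterSettings | None = None,
) -> tuple[OTUTable, DietProfiles]:
    """Raw replicate reads -> (final OTU table, per-individual diet profiles)."""
    s = settings or FilterSettings()
    table = length_filter(table, s.min_len, s.max_len)
    table = min_read_filter(table, s.min_reads_per_cell)
    table = denoise_single_mismatch(table)
    otus = greedy_centroid_cluster(table, s.cluster_identity)
    otus = assign_taxa(otus, reference, s.reference_identity)
    otus = remove_contaminants(otus)
    otus = remove_tag_leaks(otus)
    otus = discard_low_count_replicates(otus, s.min_replicate_reads)
    profiles = merge_replicates(otus, by=s.merge_by)
    return otus, profiles
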