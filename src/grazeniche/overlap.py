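"""Pianka's niche overlap between individual diets.

    O_jk = sum_i p_ij p_ik / sqrt(sum_i p_ij^2 * sum_i p_ik^2)

a cosine-type similarity of two resource-use vectors: 0 = disjoint niches,
1 = identical. Overlap is computed for every unordered pair of distinct
individuals sampled in the same year (cross-year comparisons are
meaningless here and discarded) and labelled by the unordered species pair
(10 interaction types for 4 diet species), on the FOO basis by default.
"""

from __future__ import annotations

import logging
from itertools import combinations, combinations_with_replacement

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def interaction_label(species_a: str, species_b: str) -> str:
    """Order-independent species-pair label, alphabetical."""
    return "-".join(sorted((species_a, species_b)))


def interaction_levels(species) -> list[str]:
    """All unordered species-pair labels (n*(n+1)/2 for n species)."""
    return sorted(
        interaction_label(a, b) for a, b in combinations_with_replacement(sorted(set(species)), 2)
    )


def pianka(p_j, p_k) -> float:
    """Pianka overlap of two non-negative resource-use vectors.

    Per-vector scale invariant, symmetric, bounded by 1 (Cauchy-Schwarz).
    Returns NaN (logged) if either vector is all-zero.
    """
    p_j = np.asarray(p_j, dtype=float)
    p_k = np.asarray(p_k, dtype=float)
    if p_j.shape != p_k.shape:
        raise ValueError("vectors must have the same length")
    if (p_j < 0).any() or (p_k < 0).any():
        raise ValueError("resource-use vectors must be non-negative")
    if p_j.max() == 0 or p_k.max() == 0:
        logger.warning("pianka: all-zero resource vector, overlap undefined")
        return float("nan")
    # the index is scale invariant per vector; rescale to avoid underflow
    p_j = p_j / p_j.max()
    p_k = p_k / p_k.max()
    nj = np.sqrt((p_j**2).sum())
    nk = np.sqrt((p_k**2).sum())
    return float((p_j * p_k).sum() / (nj * nk))


def pairwise_overlap(profiles, basis: str = "foo") -> pd.DataFrame:
    """Overlap records for every unordered within-year pair of individuals.

    Returns a DataFrame with columns (year, individual_j, individual_k,
    species_j, species_k, interaction, overlap). The taxon set of each year
    is the union over its individuals; absent taxa contribute zeros and the
    index is per-vector scale invariant, so the FOO rows need no
    renormalization.
    """
    mat = profiles.basis(basis)
    meta = profiles.meta.set_index("sample_id")
    records = []
    for year, idx in meta.groupby("year").groups.items():
        ids = [i for i in mat.index if i in set(idx)]
        if len(ids) < 2:
            continue
        sub = mat.loc[ids].to_numpy(float)
        norms = np.sqrt((sub**2).sum(axis=1))
        ok = norms > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(ok[:, None], sub / np.where(norms == 0, 1, norms)[:, None], 0)
        gram = unit @ unit.T
        for a, b in combinations(range(len(ids)), 2):
            ov = gram[a, b] if (ok[a] and ok[b]) else float("nan")
            sp_a, sp_b = meta.loc[ids[a], "species"], meta.loc[ids[b], "species"]
            records.append(
                {
                    "year": year,
                    "individual_j": ids[a],
                    "individual_k": ids[b],
                    "species_j": sp_a,
                    "species_k": sp_b,
                    "interaction": interaction_label(sp_a, sp_b),
                    "overlap": float(np.clip(ov, 0.0, 1.0)),
                }
            )
    return pd.DataFrame.from_records(records)
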