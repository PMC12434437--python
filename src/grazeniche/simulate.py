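"""Synthetic community generator.

Emulates the field study end to end so the whole pipeline is testable without
sequencing data: long-term herbivore census trajectories (logistic growth to
carrying capacity, then a culling-era fluctuation), a quadrat vegetation
survey on the Braun-Blanquet scale, per-individual "true" diet proportion
vectors whose scatter is density dependent, and per-PCR-replicate read tables
complete with control wells, contamination, sequencing-error variants and
tag switching.

The density-dependence mechanism: each species' individuals draw their diet
from a Dirichlet around the species preference vector. For the affected
species (red deer by default) the Dirichlet concentration is scaled by
``exp(-density_breadth_coefficient * z)`` where ``z`` is the standardized
October red deer count, so high deer density means more dispersed individual
diets and hence lower pairwise niche overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .readtable import ReplicateReadTable
from .species import (
    DEFAULT_SPECIES,
    DIET_SPECIES,
    GOOSE_POOL_LABEL,
    HerbivoreSpecies,
    validate_census,
)

NUCLEOTIDES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantTaxon:
    """A plant taxon: identifier, marker sequence, environmental abundance."""

    taxon_id: str
    sequence: str
    env_abundance: float

    def __post_init__(self) -> None:
        if not 10 <= len(self.sequence) <= 220:
            raise ValueError(
                f"{self.taxon_id}: sequence length {len(self.sequence)} outside 10-220"
            )
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"{self.taxon_id}: non-ACGT characters in sequence")
        if self.env_abundance < 0:
            raise ValueError("env_abundance must be >= 0")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the field design: 15 dung samples per species and year
    (5 per sub-area), 4 PCR replicates per sample, and per 96-well library
    12 blanks plus 8 extraction, 8 PCR-negative and 8 positive controls,
    the latter a 10-taxon assembly with strictly increasing concentrations.
    """

    n_samples_per_species_year: int = 15
    n_subareas: int = 3
    n_replicates: int = 4
    reads_per_replicate: int = 5000
    diet_concentration: float = 40.0
    density_breadth_coefficient: float = 0.7
    contamination_rate: float = 0.02
    tag_switch_rate: float = 0.002
    junk_rate: float = 0.005
    n_blanks: int = 12
    n_extraction: int = 8
    n_negative: int = 8
    n_positive: int = 8
    positive_control_taxa: dict[str, float] | None = None
    affected_species: tuple[str, ...] = ("red_deer",)
    driver_species: str = "red_deer"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("contamination_rate", "tag_switch_rate", "junk_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        for name in (
            "n_samples_per_species_year",
            "n_subareas",
            "n_replicates",
            "reads_per_replicate",
            "n_blanks",
            "n_extraction",
            "n_negative",
            "n_positive",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.diet_concentration <= 0:
            raise ValueError("diet_concentration must be positive")
        if self.positive_control_taxa is not None:
            concs = list(self.positive_control_taxa.values())
            if len(concs) != 10:
                raise ValueError("positive_control_taxa must have exactly 10 entries")
            if not all(a < b for a, b in zip(concs, concs[1:])):
                raise ValueError(
                    "positive control concentrations must be strictly increasing"
                )


@dataclass
class PlantCommunity:
    """The simulated flora: diet taxa, dedicated contaminants, junk amplicons.

    Contaminant taxa never occur in true diets or the vegetation survey;
    junk sequences fall outside the 10-220 bp marker length range so the
    length filter has real work to do.
    """

    taxa: list[PlantTaxon]
    contaminants: list[PlantTaxon]
    junk_sequences: dict[str, str] = field(default_factory=dict)

    @property
    def taxon_ids(self) -> list[str]:
        return [t.taxon_id for t in self.taxa]

    @property
    def env_abundance(self) -> pd.Series:
        s = pd.Series({t.taxon_id: t.env_abundance for t in self.taxa})
        return s / s.sum()

    def reference_sequences(self) -> dict[str, str]:
        """Reference FASTA content: all diet + contaminant taxa, labelled."""
        ref = {t.taxon_id: t.sequence for t in self.taxa}
        ref.update({t.taxon_id: t.sequence for t in self.contaminants})
        return ref


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(NUCLEOTIDES, size=length))


def generate_community(
    n_taxa: int = 25,
    seed: int = 0,
    min_len: int = 40,
    max_len: int = 140,
    max_pairwise_identity: float = 0.90,
) -> PlantCommunity:
    """Draw a plant community with well-separated marker sequences.

    Sequences are random and re-drawn until all pairwise identities stay
    below ``max_pairwise_identity``, so 97% clustering can never merge two
    distinct taxa by chance. Environmental abundances are lognormal,
    sorted decreasing (a few dominant graminoid-like taxa, many rare ones).
    """
    from .align import global_identity

    rng = np.random.default_rng(seed)
    sequences: list[str] = []
    while len(sequences) < n_taxa + 2:  # +2 dedicated contaminants
        cand = _random_sequence(rng, int(rng.integers(min_len, max_len + 1)))
        if all(global_identity(cand, s) < max_pairwise_identity for s in sequences):
            sequences.append(cand)
    abundance = np.sort(rng.lognormal(mean=0.0, sigma=1.2, size=n_taxa))[::-1]
    abundance = abundance / abundance.sum()
    taxa = [
        PlantTaxon(f"taxon_{i:02d}", sequences[i], float(abundance[i]))
        for i in range(n_taxa)
    ]
    contaminants = [
        PlantTaxon(f"contaminant_{j + 1}", sequences[n_taxa + j], 0.0)
        for j in range(2)
    ]
    junk = {
        "junk_short": _random_sequence(rng, 8),
        "junk_long": _random_sequence(rng, 260),
    }
    return PlantCommunity(taxa, contaminants, junk)


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogisticParams:
    """Discrete logistic growth parameters for one species."""

    initial: float
    growth_rate: float
    carrying_capacity: float
    intro_year: int | None = None

    def __post_init__(self) -> None:
        if self.carrying_capacity <= 0:
            raise ValueError("carrying capacity must be > 0")
        if self.initial < 0 or self.growth_rate < 0:
            raise ValueError("growth parameters must be non-negative")


def simulate_census(
    species_params: dict[str, LogisticParams],
    years,
    seed: int = 0,
    noise_sd: float = 0.2,
    winter_mortality: float = 0.1,
) -> pd.DataFrame:
    """Simulate October and May censuses under noisy discrete logistic growth.

    ``N[t+1] = N[t] + r*eps[t]*N[t]*(1 - N[t]/K)`` with lognormal noise
    ``eps`` on the growth increment, so ``r = 0`` gives an exactly constant
    population. May counts apply winter mortality to the previous October.
    """
    years = sorted(years)
    if not years:
        raise ValueError("years must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for name, par in species_params.items():
        first = par.intro_year if par.intro_year is not None else years[0]
        n = float(par.initial)
        prev_oct = None
        for year in range(first, years[-1] + 1):
            if year in years:
                rows.append((name, year, "October", int(round(n))))
                if prev_oct is not None:
                    may = int(round(prev_oct * (1 - winter_mortality)))
                    rows.append((name, year, "May", may))
            prev_oct = n
            eps = math.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
            n = max(
                0.0,
                n + par.growth_rate * eps * n * (1 - n / par.carrying_capacity),
            )
    census = pd.DataFrame(rows, columns=["species", "year", "season", "count"])
    return validate_census(census)


#: October counts for the management (culling) era, emulating the documented
#: dynamics: red deer fluctuating high-low from culling with high reproduction,
#: horses steadily reduced, cattle initially below target and rising, geese
#: wintering numbers roughly stable.
MANAGEMENT_ERA_OCTOBER: dict[str, dict[int, int]] = {
    "cattle": {2018: 200, 2019: 260, 2020: 300, 2021: 330},
    "horse": {2018: 800, 2019: 650, 2020: 530, 2021: 450},
    "red_deer": {2018: 2800, 2019: 1900, 2020: 2600, 2021: 1700},
    "greylag_goose": {2018: 8800, 2019: 9000, 2020: 8700, 2021: 9100},
    "barnacle_goose": {2018: 22000, 2019: 21500, 2020: 22500, 2021: 21800},
}

RESERVE_PARAMS: dict[str, LogisticParams] = {
    "cattle": LogisticParams(32, 0.25, 320, intro_year=1983),
    "horse": LogisticParams(18, 0.33, 1100, intro_year=1984),
    "red_deer": LogisticParams(44, 0.32, 3300, intro_year=1992),
    "greylag_goose": LogisticParams(400, 0.25, 9000, intro_year=1983),
    "barnacle_goose": LogisticParams(800, 0.25, 22000, intro_year=1983),
}


def reserve_census(seed: int = 0, noise_sd: float = 0.08) -> pd.DataFrame:
    """Long-term census of the reserve, 1983-2021.

    Free-running logistic growth from the historical introductions (32 cattle
    in 1983, 18 horses in 1984, 44 red deer in 1992) up to 2017, then the
    culling-era October counts from :data:`MANAGEMENT_ERA_OCTOBER`. Geese
    also get a December-April ``winter_average`` entry.
    """
    years = range(1983, 2022)
    census = simulate_census(RESERVE_PARAMS, years, seed=seed, noise_sd=noise_sd)
    for sp, by_year in MANAGEMENT_ERA_OCTOBER.items():
        for year, count in by_year.items():
            mask = (
                (census["species"] == sp)
                & (census["year"] == year)
                & (census["season"] == "October")
            )
            census.loc[mask, "count"] = count
    winter = census[
        (census["species"].isin(["greylag_goose", "barnacle_goose"]))
        & (census["season"] == "October")
    ].copy()
    winter["season"] = "winter_average"
    winter["count"] = (winter["count"] * 0.9).round().astype(int)
    return validate_census(
        pd.concat([census, winter], ignore_index=True).reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Plant survey
# ---------------------------------------------------------------------------


def simulate_plant_survey(
    taxa: list[PlantTaxon],
    n_quadrats: int = 45,
    seed: int = 0,
    noise_sd: float = 0.35,
    scale=None,
) -> pd.DataFrame:
    """Quadrat x taxon Braun-Blanquet category table.

    Each quadrat's percent cover of a taxon is a lognormal perturbation of
    ``100 * env_abundance``, then binned into the 9-category scale. Taxa with
    zero abundance are absent (empty category) everywhere.
    """
    from .selectivity import DEFAULT_BB_SCALE

    if n_quadrats < 1:
        raise ValueError("n_quadrats must be >= 1")
    scale = scale or DEFAULT_BB_SCALE
    rng = np.random.default_rng(seed)
    data = {}
    for taxon in taxa:
        cover = 100.0 * taxon.env_abundance
        if cover == 0:
            data[taxon.taxon_id] = [""] * n_quadrats
            continue
        draws = cover * rng.lognormal(0.0, noise_sd, size=n_quadrats)
        data[taxon.taxon_id] = [scale.category_for_cover(x) for x in draws]
    return pd.DataFrame(
        data, index=[f"quadrat_{i + 1:02d}" for i in range(n_quadrats)]
    )


# ---------------------------------------------------------------------------
# Diets
# ---------------------------------------------------------------------------


def species_preferences(
    community: PlantCommunity,
    seed: int = 0,
    tilt_sd: float = 0.8,
    goose_tilt_sd: float = 1.6,
) -> pd.DataFrame:
    """Species preference vectors (rows: diet species, columns: taxa).

    Preference is availability^0.7 times a species-specific lognormal tilt,
    renormalized, so herbivores broadly track the vegetation but each selects
    its own subset; geese get a stronger tilt (most distinct diet).
    """
    avail = community.env_abundance.to_numpy()
    prefs = {}
    for i, sp in enumerate(DIET_SPECIES):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1000 + i]))
        sd = goose_tilt_sd if sp == GOOSE_POOL_LABEL else tilt_sd
        w = avail**0.7 * rng.lognormal(0.0, sd, size=avail.size)
        prefs[sp] = w / w.sum()
    return pd.DataFrame(prefs, index=community.taxon_ids).T


def _october_count(census: pd.DataFrame, species: str, year: int) -> float:
    sub = census[
        (census["species"] == species)
        & (census["year"] == year)
        & (census["season"] == "October")
    ]
    if sub.empty:
        raise ValueError(f"no October census entry for {species} in {year}")
    return float(sub["count"].iloc[0])


def simulate_diets(
    census: pd.DataFrame,
    community: PlantCommunity,
    config: SimulationConfig,
    years=(2018, 2019, 2020, 2021),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual true diet proportion vectors.

    Returns ``(meta, diets)``: sample metadata (sample_id, species, year,
    subarea) and the matching matrix of diet proportions (rows sum to 1).
    Individuals are Dirichlet draws around the species preference; for
    species in ``config.affected_species`` the concentration shrinks as
    ``exp(-density_breadth_coefficient * z(deer count))``, dispersing
    individual diets at high deer density.
    """
    prefs = species_preferences(community, seed=config.seed)
    deer = np.array([_october_count(census, config.driver_species, y) for y in years])
    z = (deer - deer.mean()) / deer.std() if deer.std() > 0 else np.zeros_like(deer)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    meta_rows, diet_rows, ids = [], [], []
    for sp in DIET_SPECIES:
        if sp == GOOSE_POOL_LABEL:
            for gs in ("greylag_goose", "barnacle_goose"):
                for y in years:
                    _october_count(census, gs, y)  # precondition check
        pref = prefs.loc[sp].to_numpy()
        for yi, year in enumerate(years):
            if sp != GOOSE_POOL_LABEL:
                _october_count(census, sp, year)
            conc = config.diet_concentration
            if sp in config.affected_species:
                conc *= math.exp(-config.density_breadth_coefficient * z[yi])
            alpha = np.maximum(conc * pref, 1e-8)
            for i in range(config.n_samples_per_species_year):
                subarea = i % config.n_subareas + 1
                sample_id = f"{sp}_{year}_s{i + 1:02d}"
                ids.append(sample_id)
                meta_rows.append((sample_id, sp, year, subarea))
                diet_rows.append(rng.dirichlet(alpha))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "species", "year", "subarea"]
    )
    diets = pd.DataFrame(diet_rows, index=ids, columns=community.taxon_ids)
    return meta, diets


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def _variant_sequences(sequence: str) -> tuple[str, str]:
    """Two deterministic single-substitution error variants of a sequence."""

    def sub(seq: str, pos: int) -> str:
        order = "ACGT"
        repl = order[(order.index(seq[pos]) + 1) % 4]
        return seq[:pos] + repl + seq[pos + 1 :]

    third = len(sequence) // 3
    return sub(sequence, third), sub(sequence, min(2 * third, len(sequence) - 1))


def simulate_reads(
    meta: pd.DataFrame,
    diets: pd.DataFrame,
    community: PlantCommunity,
    config: SimulationConfig,
) -> ReplicateReadTable:
    """Per-replicate multinomial read counts with controls and noise.

    One library per (species, year): 4 replicates of each sample plus 12
    blanks, 8 extraction, 8 negative and 8 positive control wells.
    Contaminant reads enter every sample well at ``contamination_rate`` and
    make up the entirety of blank/extraction/negative wells (whose depth is
    proportionally low); 10% of each plant taxon's reads land on two fixed
    single-mismatch error variants; finally a fraction ``tag_switch_rate`` of
    every well's reads is reassigned uniformly across its library's wells.
    """
    if config.reads_per_replicate <= 0:
        raise ValueError("reads_per_replicate must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))

    taxa_ids = list(diets.columns)
    seq_registry: dict[str, str] = {}
    variant_of: dict[str, list[str]] = {}
    for t in community.taxa + community.contaminants:
        if t.taxon_id not in taxa_ids and t.env_abundance == 0.0:
            pass  # contaminants handled below regardless
        seq_registry[t.taxon_id] = t.sequence
        v1, v2 = _variant_sequences(t.sequence)
        seq_registry[f"{t.taxon_id}_v1"] = v1
        seq_registry[f"{t.taxon_id}_v2"] = v2
        variant_of[t.taxon_id] = [f"{t.taxon_id}_v1", f"{t.taxon_id}_v2"]
    seq_registry.update(community.junk_sequences)
    junk_ids = list(community.junk_sequences)
    contam_ids = [t.taxon_id for t in community.contaminants]

    pos_mix = config.positive_control_taxa
    if pos_mix is None:
        if len(taxa_ids) < 10:
            raise ValueError(
                "the 10-taxon positive control needs a community of >= 10 taxa"
            )
        pos_mix = {taxa_ids[i]: 1.5**i for i in range(10)}
    pos_taxa = list(pos_mix)
    pos_p = np.array(list(pos_mix.values()), dtype=float)
    pos_p = pos_p / pos_p.sum()

    # column order of the per-library count matrix
    all_source_ids = taxa_ids + contam_ids + junk_ids
    src_index = {s: i for i, s in enumerate(all_source_ids)}
    n_src = len(all_source_ids)

    counts_frames = []
    well_rows = []
    c_rate, j_rate = config.contamination_rate, config.junk_rate
    contam_p = np.zeros(n_src)
    for cid in contam_ids:
        contam_p[src_index[cid]] = 1.0 / len(contam_ids)
    junk_p = np.zeros(n_src)
    for jid in junk_ids:
        junk_p[src_index[jid]] = 1.0 / len(junk_ids)

    for (sp, year), group in meta.groupby(["species", "year"], sort=True):
        lib = f"{sp}_{year}"
        well_ids: list[str] = []
        comps: list[np.ndarray] = []
        depths: list[int] = []
        # sample replicate wells
        for _, row in group.iterrows():
            diet = np.zeros(n_src)
            diet[: len(taxa_ids)] = diets.loc[row.sample_id].to_numpy()
            comp = (1 - c_rate - j_rate) * diet + c_rate * contam_p + j_rate * junk_p
            for rep in range(1, config.n_replicates + 1):
                wid = f"{row.sample_id}_r{rep}"
                well_ids.append(wid)
                comps.append(comp)
                depths.append(int(rng.poisson(config.reads_per_replicate)))
                well_rows.append(
                    (wid, row.sample_id, sp, year, row.subarea, None, lib)
                )
        # control wells
        control_depth = c_rate * config.reads_per_replicate
        for ctype, n_wells in (
            ("blank", config.n_blanks),
            ("extraction", config.n_extraction),
            ("negative", config.n_negative),
        ):
            for i in range(1, n_wells + 1):
                wid = f"{lib}_{ctype}{i:02d}"
                well_ids.append(wid)
                comps.append(contam_p)
                depths.append(int(rng.poisson(control_depth)))
                well_rows.append((wid, None, sp, year, None, ctype, lib))
        pos_comp = np.zeros(n_src)
        for t, p in zip(pos_taxa, pos_p):
            pos_comp[src_index[t]] = p
        pos_comp = (1 - c_rate) * pos_comp + c_rate * contam_p
        for i in range(1, config.n_positive + 1):
            wid = f"{lib}_positive{i:02d}"
            well_ids.append(wid)
            comps.append(pos_comp)
            depths.append(int(rng.poisson(config.reads_per_replicate)))
            well_rows.append((wid, None, sp, year, None, "positive", lib))

        # source-taxon counts per well
        mat = np.zeros((n_src, len(well_ids)), dtype=np.int64)
        for w, (comp, depth) in enumerate(zip(comps, depths)):
            if depth > 0:
                mat[:, w] = rng.multinomial(depth, comp)
        # tag switching: uniform reassignment across the library's wells
        if config.tag_switch_rate > 0:
            switched = rng.binomial(mat, config.tag_switch_rate)
            mat -= switched
            totals = switched.sum(axis=1)
            for s in np.nonzero(totals)[0]:
                mat[s] += rng.multinomial(
                    totals[s], np.full(len(well_ids), 1.0 / len(well_ids))
                )
        # split plant-taxon reads into centroid + two error variants
        seq_ids: list[str] = []
        seq_mat_rows: list[np.ndarray] = []
        for s, src in enumerate(all_source_ids):
            row_counts = mat[s]
            if src in variant_of:
                split = rng.multinomial(row_counts, [0.90, 0.05, 0.05]).T
                for sid, cnts in zip([src] + variant_of[src], split):
                    seq_ids.append(sid)
                    seq_mat_rows.append(cnts)
            else:
                seq_ids.append(src)
                seq_mat_rows.append(row_counts)
        seq_mat = np.asarray(seq_mat_rows)
        nz = np.nonzero(seq_mat)
        counts_frames.append(
            pd.DataFrame(
                {
                    "sequence_id": np.asarray(seq_ids)[nz[0]],
                    "well_id": np.asarray(well_ids)[nz[1]],
                    "read_count": seq_mat[nz],
                }
            )
        )

    counts = pd.concat(counts_frames, ignore_index=True)
    wells = pd.DataFrame(
        well_rows,
        columns=[
            "well_id",
            "sample_id",
            "species",
            "year",
            "subarea",
            "control_type",
            "library_id",
        ],
    )
    used = set(counts["sequence_id"])
    registry = {k: v for k, v in seq_registry.items() if k in used}
    return ReplicateReadTable(counts, wells, registry)


# ---------------------------------------------------------------------------
# One-call bundle
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    """Everything one simulated field season set produces, truth included."""

    config: SimulationConfig
    community: PlantCommunity
    census: pd.DataFrame
    survey: pd.DataFrame
    meta: pd.DataFrame
    true_diets: pd.DataFrame
    reads: ReplicateReadTable
    species_registry: dict[str, HerbivoreSpecies] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES)
    )


def simulate_study(
    config: SimulationConfig | None = None,
    n_taxa: int = 25,
    years=(2018, 2019, 2020, 2021),
) -> SyntheticStudy:
    """Generate a full synthetic study under one configuration seed."""
    config = config or SimulationConfig()
    community = generate_community(n_taxa=n_taxa, seed=config.seed)
    census = reserve_census(seed=config.seed)
    survey = simulate_plant_survey(
        community.taxa, seed=config.seed + 1 if config.seed < 2**31 - 1 else 0
    )
    meta, diets = simulate_diets(census, community, config, years=years)
    reads = simulate_reads(meta, diets, community, config)
    return SyntheticStudy(config, community, census, survey, meta, diets, reads)
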