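"""Density-dependence models of niche overlap.

Two model families, both beta regressions on pairwise overlap records:

* Model 1: ``overlap ~ interaction / year`` — interaction main effects plus
  interaction-nested year effects (all fixed, treatment contrasts,
  alphabetical reference level).
* Model 2: ``overlap ~ interaction / energy + (1 | year)`` — interaction-
  specific slopes on a (z-standardized) population energy-expenditure
  covariate, with a year random intercept absorbing year-to-year
  fluctuations.

The AIC race refits Model 2 with the energy covariate taken from each
herbivore species separately and from all species summed, and reports AIC
differences against the total-energy reference. Overlap records share
individuals and are therefore pseudo-replicated; as in the source analyses
they are fit as independent observations (a documented caveat).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .betareg import BetaFit, boundary_transform, fit_beta_glm, fit_beta_glmm

logger = logging.getLogger(__name__)


def build_design(
    records: pd.DataFrame,
    predictor: str = "year",
    energy: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Design matrix for ``overlap ~ interaction / nested-term``.

    The "/" nesting expands to interaction main effects (treatment contrasts,
    alphabetical reference) plus interaction-specific effects of the nested
    term: one dummy per (interaction, non-reference year) for the
    categorical year model, or one slope per interaction for a continuous
    energy covariate (z-standardized, scaling stored in the metadata).
    """
    inter_levels = sorted(records["interaction"].unique())
    n = len(records)
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(n)}
    for lev in inter_levels[1:]:
        cols[f"interaction[{lev}]"] = (records["interaction"] == lev).to_numpy(float)
    meta: dict = {"predictor": predictor, "interaction_levels": inter_levels}
    if predictor == "year":
        year_levels = sorted(records["year"].unique())
        meta["year_levels"] = year_levels
        for lev in inter_levels:
            in_lev = (records["interaction"] == lev).to_numpy(float)
            for yr in year_levels[1:]:
                cols[f"interaction[{lev}]:year[{yr}]"] = in_lev * (
                    records["year"] == yr
                ).to_numpy(float)
    else:
        if energy is None:
            raise ValueError("continuous predictor requires an energy series")
        missing = set(records["year"].unique()) - set(energy.index)
        if missing:
            raise ValueError(f"energy series lacks years {sorted(missing)}")
        x = records["year"].map(energy).to_numpy(float)
        center, scale = float(x.mean()), float(x.std())
        if scale == 0:
            raise ValueError("energy covariate has zero variance")
        z = (x - center) / scale
        meta["energy_center"], meta["energy_scale"] = center, scale
        meta["energy_by_year"] = {int(k): float(v) for k, v in energy.items()}
        for lev in inter_levels:
            cols[f"interaction[{lev}]:energy"] = (
                records["interaction"] == lev
            ).to_numpy(float) * z
    X = pd.DataFrame(cols, index=records.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns by QR pivoting
        _, r = np.linalg.qr(X.to_numpy())
        aliased = [X.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8]
        raise ValueError(f"design matrix rank deficient; aliased columns: {aliased}")
    return X, meta


def fit_year_model(records: pd.DataFrame) -> BetaFit:
    """Model 1: fixed-effects beta regression, interaction-nested years."""
    X, meta = build_design(records, predictor="year")
    y = boundary_transform(records["overlap"].to_numpy())
    fit = fit_beta_glm(X, y)
    fit.meta.update(meta)
    fit.meta["boundary_transformed"] = bool(
        ((records["overlap"] == 0) | (records["overlap"] == 1)).any()
    )
    return fit


def fit_energy_model(records: pd.DataFrame, energy: pd.Series) -> BetaFit:
    """Model 2: interaction-nested energy slopes + year random intercept."""
    X, meta = build_design(records, predictor="energy", energy=energy)
    y = boundary_transform(records["overlap"].to_numpy())
    fit = fit_beta_glmm(X, y, groups=records["year"].to_numpy())
    fit.meta.update(meta)
    return fit


def interaction_slopes(fit: BetaFit) -> pd.Series:
    """Per-interaction energy slope estimates from a Model-2 fit."""
    slopes = {
        name.split("[", 1)[1].split("]")[0]: val
        for name, val in fit.params.items()
        if name.endswith(":energy")
    }
    return pd.Series(slopes, name="slope")


def aic_race(
    records: pd.DataFrame,
    energy_table: pd.DataFrame,
    reference: str = "total",
) -> pd.DataFrame:
    """Fit Model 2 under each energy-predictor variant and compare AIC.

    ``energy_table`` is year x variant (columns like total, red_deer, cattle,
    horse, geese). Returns one row per variant with AIC and the difference
    to the reference variant (lower = better support). Non-converged
    variants are excluded from the comparison and flagged.
    """
    if reference not in energy_table.columns:
        raise ValueError(f"reference variant {reference!r} not in energy table")
    rows = []
    fits: dict[str, BetaFit] = {}
    for variant in energy_table.columns:
        fit = fit_energy_model(records, energy_table[variant])
        fits[variant] = fit
        rows.append(
            {
                "variant": variant,
                "aic": fit.aic,
                "loglik": fit.loglik,
                "converged": fit.converged,
                "sigma_year": fit.sigma_group,
            }
        )
    out = pd.DataFrame(rows).set_index("variant")
    ref_aic = out.loc[reference, "aic"]
    out["delta_aic"] = np.where(out["converged"], out["aic"] - ref_aic, np.nan)
    if not out["converged"].all():
        logger.warning("aic_race: non-converged variants excluded: %s",
                       list(out.index[~out["converged"]]))
    out.attrs["fits"] = fits
    return out


def predict_overlap(fit: BetaFit, newdata: pd.DataFrame) -> pd.Series:
    """Predicted mean overlap for rows of (interaction, year).

    The random intercept (if any) is set to 0 for population-level
    predictions. Levels unseen during fitting raise a descriptive error.
    """
    meta = fit.meta
    inter_levels = meta["interaction_levels"]
    unseen = set(newdata["interaction"]) - set(inter_levels)
    if unseen:
        raise ValueError(f"unseen interaction level(s): {sorted(unseen)}")
    n = len(newdata)
    cols = {"Intercept": np.ones(n)}
    for lev in inter_levels[1:]:
        cols[f"interaction[{lev}]"] = (newdata["interaction"] == lev).to_numpy(float)
    if meta["predictor"] == "year":
        unseen_y = set(newdata["year"]) - set(meta["year_levels"])
        if unseen_y:
            raise ValueError(f"unseen year level(s): {sorted(unseen_y)}")
        for lev in inter_levels:
            in_lev = (newdata["interaction"] == lev).to_numpy(float)
            for yr in meta["year_levels"][1:]:
                cols[f"interaction[{lev}]:year[{yr}]"] = in_lev * (
                    newdata["year"] == yr
                ).to_numpy(float)
    else:
        energy = meta["energy_by_year"]
        unseen_y = {int(y) for y in newdata["year"]} - set(energy)
        if unseen_y:
            raise ValueError(f"no energy value for year(s): {sorted(unseen_y)}")
        z = (
            newdata["year"].astype(int).map(energy).to_numpy(float)
            - meta["energy_center"]
        ) / meta["energy_scale"]
        for lev in inter_levels:
            cols[f"interaction[{lev}]:energy"] = (
                newdata["interaction"] == lev
            ).to_numpy(float) * z
    X = pd.DataFrame(cols, index=newdata.index)[list(fit.params.index)]
    return pd.Series(fit.predict(X), index=newdata.index, name="predicted_overlap")


def predicted_overlap_grid(fit: BetaFit) -> pd.DataFrame:
    """Predictions for every (interaction, year) cell seen in training."""
    meta = fit.meta
    years = meta.get("year_levels") or sorted(meta["energy_by_year"])
    grid = pd.DataFrame(
        [(i, y) for i in meta["interaction_levels"] for y in years],
        columns=["interaction", "year"],
    )
    grid["predicted_overlap"] = predict_overlap(fit, grid)
    return grid


def correlate_with_counts(
    predictions: pd.DataFrame, counts: pd.Series
) -> pd.DataFrame:
    """Pearson correlation and OLS of predicted overlap vs herbivore counts.

    One row per interaction, with Holm-adjusted p-values reported alongside
    the raw ones. Zero-variance predictions yield NaN (flagged in the log).
    Requires >= 3 years.
    """
    rows = []
    for inter, grp in predictions.groupby("interaction"):
        x = grp["year"].map(counts).to_numpy(float)
        y = grp["predicted_overlap"].to_numpy(float)
        if len(x) < 3:
            raise ValueError("correlation requires at least 3 years")
        if np.std(y) == 0 or np.std(x) == 0:
            logger.warning("correlate_with_counts: zero variance for %s", inter)
            rows.append({"interaction": inter, "r": np.nan, "slope": np.nan,
                         "p_value": np.nan})
            continue
        fit = stats.linregress(x, y)
        rows.append(
            {
                "interaction": inter,
                "r": fit.rvalue,
                "slope": fit.slope,
                "p_value": fit.pvalue,
            }
        )
    out = pd.DataFrame(rows).set_index("interaction")
    valid = out["p_value"].notna()
    adjusted = np.full(len(out), np.nan)
    if valid.any():
        adjusted[valid.to_numpy()] = multipletests(
            out.loc[valid, "p_value"].to_numpy(), method="holm"
        )[1]
    out["p_holm"] = adjusted
    return out
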