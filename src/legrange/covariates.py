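"""Species- and region-level design variables.

Binary life traits (woody, annual) with missing entries are filled by
taxonomic mean imputation: a missing species takes the mean of observed
members of its genus, falling back to its tribe when the genus has no
observed member.  Imputed values therefore live in [0, 1] and read as the
probability that the species is woody/annual given its taxonomic group.

Continuous covariates (absolute native-range centroid latitude, total
native area, region area) are mean-centred and scaled by the sample
standard deviation before model fitting.  The human-use count stays on
its raw 0-11 scale because zero uses is the biologically meaningful
reference point at which the symbiosis main effect is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: the 11 recognised human-use categories
USE_CATEGORIES = frozenset(
    {
        "Chemical products",
        "Domestic",
        "Environmental",
        "Fibre",
        "Food and Drink",
        "Forage",
        "Medicine",
        "Miscellaneous",
        "Toxins",
        "Weed",
        "Wood",
    }
)

IMPUTABLE_TRAITS = ("woody", "annual")


class ImputationError(ValueError):
    pass


class ScalingError(ValueError):
    pass


def impute_taxonomic(traits: pd.DataFrame, columns=IMPUTABLE_TRAITS) -> pd.DataFrame:
    """Fill missing binary trait values by genus then tribe means.

    Requires ``genus`` and ``tribe`` columns.  Observed values are never
    altered; donors are only observed (never previously imputed) values.
    A ``<trait>_source`` column records provenance per species, one of
    ``observed`` / ``genus-mean`` / ``tribe-mean``.

    Raises :class:`ImputationError` if a species' tribe has no observed
    donor either.
    """
    out = traits.copy()
    for col in columns:
        vals = out[col].astype(float)
        observed = vals.notna()
        genus_mean = vals[observed].groupby(out.loc[observed, "genus"]).mean()
        tribe_mean = vals[observed].groupby(out.loc[observed, "tribe"]).mean()
        source = np.where(observed, "observed", "").astype(object)
        filled = vals.copy()
        for idx in out.index[~observed]:
            g, t = out.at[idx, "genus"], out.at[idx, "tribe"]
            if g in genus_mean.index:
                filled.at[idx] = genus_mean[g]
                source[out.index.get_loc(idx)] = "genus-mean"
            elif t in tribe_mean.index:
                filled.at[idx] = tribe_mean[t]
                source[out.index.get_loc(idx)] = "tribe-mean"
            else:
                sid = out.at[idx, "species_id"] if "species_id" in out else idx
                raise ImputationError(
                    f"no observed {col!r} donor in genus {g!r} or tribe {t!r} "
                    f"for species {sid!r}"
                )
        out[col] = filled
        out[f"{col}_source"] = source
    return out


def count_uses(categories) -> int:
    """Number of distinct recognised human-use categories; absence of any
    category means zero known uses."""
    cats = set(categories)
    unknown = cats - USE_CATEGORIES
    if unknown:
        raise ValueError(f"unrecognised use categories: {sorted(unknown)}")
    return len(cats)


@dataclass
class DesignMatrix:
    """Model design variables with scaling metadata.

    ``species`` columns: abs_latitude, native_area (both standardised),
    annual, woody (natural 0-1 scale), n_uses (raw count).
    ``region`` column: region_area (standardised).
    """

    species: pd.DataFrame
    region: pd.DataFrame
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    SCALED_SPECIES_COLS = ("abs_latitude", "native_area")
    SCALED_REGION_COLS = ("region_area",)

    def inverse_scale(self, column: str, values):
        mean, sd = self.scaling[column]
        return np.asarray(values) * sd + mean


def _standardise(col: pd.Series) -> tuple[pd.Series, tuple[float, float]]:
    mean = float(col.mean())
    sd = float(col.std(ddof=1))
    if not np.isfinite(sd) or sd == 0:
        raise ScalingError(f"zero-variance column {col.name!r} cannot be scaled")
    return (col - mean) / sd, (mean, sd)


def build_design(
    traits: pd.DataFrame,
    range_cov: pd.DataFrame,
    region_areas: pd.Series,
) -> DesignMatrix:
    """Assemble the design variables from traits and geographic covariates.

    ``traits`` indexed by species id with columns symbiotic, woody,
    annual, n_uses; ``range_cov`` indexed by species id with columns
    abs_native_centroid_lat, total_native_area_km2; ``region_areas``
    indexed by region id (km^2).
    """
    sp = pd.DataFrame(index=traits.index)
    sp["symbiosis"] = traits["symbiotic"].astype(float)
    scaling: dict[str, tuple[float, float]] = {}
    lat = range_cov.loc[traits.index, "abs_native_centroid_lat"].rename("abs_latitude")
    area = range_cov.loc[traits.index, "total_native_area_km2"].rename("native_area")
    sp["abs_latitude"], scaling["abs_latitude"] = _standardise(lat)
    sp["native_area"], scaling["native_area"] = _standardise(area)
    sp["annual"] = traits["annual"].astype(float)
    sp["woody"] = traits["woody"].astype(float)
    sp["n_uses"] = traits["n_uses"].astype(float)
    sp["symbiosis_x_uses"] = sp["symbiosis"] * sp["n_uses"]

    rg = pd.DataFrame(index=region_areas.index)
    scaled, scaling["region_area"] = _standardise(region_areas.rename("region_area"))
    rg["region_area"] = scaled
    return DesignMatrix(species=sp, region=rg, scaling=scaling)


def predictor_correlations(design: DesignMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among species-level predictors.

    Constant columns yield NaN entries (flagged, not raised), except on
    the diagonal which is always 1.
    """
    df = design.species if isinstance(design, DesignMatrix) else design
    if len(df) < 2:
        raise ValueError("need at least two species")
    corr = df.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr
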