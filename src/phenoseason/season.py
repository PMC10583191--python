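"""Season length assembly and the phenology -> season-length regression.

Season length is the number of days between the season start (the day the
fitted logistic growth curve reaches 25 % of final size) and the season
end (the day the averaged decline profile falls back to 25 % of maximum).
Days run continuously past day 365 for measurements taken the following
January; species that never drop below 25 % overwinter and are assigned a
season length of 365 d.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InputError, InsufficientDataError

PHENO_VARS = ["peak_day", "log_b", "sen_date", "sen_pace", "sen_shape"]

#: season length assigned to overwintering species (days)
OVERWINTER_LENGTH = 365.0


def assemble(
    growth_params: pd.DataFrame, senescence_params: pd.DataFrame
) -> pd.DataFrame:
    """Join the spring and autumn parameter tables into phenology records.

    Expects ``growth_params`` with columns species_id, peak_day, log_b,
    season_start and ``senescence_params`` with species_id, sen_date,
    sen_pace, sen_shape, season_end, overwinters.  Species missing either
    endpoint keep a missing season_length (and are excluded downstream
    from analyses that need it); exclusion reasons are recorded.
    """
    for name, df in (("growth", growth_params), ("senescence", senescence_params)):
        if df["species_id"].duplicated().any():
            dups = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
            raise InputError(f"duplicate species ids in {name} table: {dups}")
    records = growth_params.merge(
        senescence_params, on="species_id", how="outer", validate="1:1"
    ).sort_values("species_id")
    if "overwinters" not in records:
        records["overwinters"] = False
    records["overwinters"] = records["overwinters"].fillna(False).astype(bool)

    length = records["season_end"] - records["season_start"]
    length = length.where(~records["overwinters"], OVERWINTER_LENGTH)
    records["season_length"] = length.clip(upper=OVERWINTER_LENGTH)

    # overwintering species are kept (length 365); only species with a
    # missing endpoint or a degenerate length are excluded downstream
    reasons = []
    for _, row in records.iterrows():
        if row["overwinters"]:
            reasons.append("")
        elif pd.isna(row.get("season_start")):
            reasons.append("missing_season_start")
        elif pd.isna(row.get("season_end")):
            reasons.append("missing_season_end")
        elif row["season_length"] <= 0:
            reasons.append("nonpositive_length")
        else:
            reasons.append("")
    records["exclusion_reason"] = reasons
    bad = (records["season_length"] <= 0) & records["season_length"].notna()
    records.loc[bad, "season_length"] = np.nan
    return records.reset_index(drop=True)


class PhenologyRegressionResults:
    """Standardized OLS of season length on the five phenological variables."""

    def __init__(self, table: pd.DataFrame, r_squared: float, n: int, warning=None):
        self.table = table
        self.r_squared = r_squared
        self.n = n
        self.collinearity_warning = warning

    def summary(self) -> str:
        lines = [
            f"Season length ~ phenology (standardized OLS), "
            f"N = {self.n}, R^2 = {self.r_squared:.3f}",
            self.table.to_string(
                float_format=lambda v: f"{v: .3f}", index=False
            ),
        ]
        if self.collinearity_warning:
            lines.append(f"warning: {self.collinearity_warning}")
        return "\n".join(lines)


def regress_length_on_phenology(
    records: pd.DataFrame,
    condition_threshold: float = 1e8,
) -> PhenologyRegressionResults:
    """Multiple regression of z-scored season length on z-scored phenology.

    Returns standardized estimates with 95 % t-based confidence intervals
    and the model R^2.  Highly collinear predictor sets trigger a warning
    and a pseudo-inverse fit instead of a hard failure.
    """
    cols = PHENO_VARS + ["season_length"]
    data = records[cols].dropna()
    n = len(data)
    if n < 10:
        raise InsufficientDataError(
            f"need >= 10 complete records, have {n}"
        )
    z = (data - data.mean()) / data.std(ddof=1)
    X = sm.add_constant(z[PHENO_VARS].to_numpy())
    y = z["season_length"].to_numpy()
    warning = None
    cond = np.linalg.cond(X)
    if cond > condition_threshold:
        warning = f"collinear predictors (condition number {cond:.3g}); pinv fit"
        beta = np.linalg.pinv(X) @ y
        fitted = X @ beta
        resid = y - fitted
        df_resid = n - X.shape[1]
        s2 = resid @ resid / df_resid
        cov = s2 * np.linalg.pinv(X.T @ X)
        bse = np.sqrt(np.diag(cov))
        from scipy.stats import t as t_dist

        tcrit = t_dist.ppf(0.975, df_resid)
        ci_low = beta - tcrit * bse
        ci_high = beta + tcrit * bse
        r2 = 1.0 - (resid @ resid) / (y @ y)
    else:
        fit = sm.OLS(y, X).fit()
        beta, bse = fit.params, fit.bse
        ci = fit.conf_int(alpha=0.05)
        ci_low, ci_high = ci[:, 0], ci[:, 1]
        r2 = fit.rsquared
    table = pd.DataFrame(
        {
            "predictor": PHENO_VARS,
            "estimate": beta[1:],
            "ci_low": ci_low[1:],
            "ci_high": ci_high[1:],
        }
    )
    return PhenologyRegressionResults(table, float(r2), n, warning)
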