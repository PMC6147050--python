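"""Relative body mass: residuals from a sex-specific log-log mixed model.

An individual's "relative mass" is how much heavier or lighter it is than
expected for its sex, age and group: the conditional residual

    log(mass) - (intercept + slope * log(age) + group_effect)

from a linear mixed model of log mass on log age with a random intercept for
group identity, fitted separately per sex. Positive values mean heavier than
expected. The covariate is z-scored downstream together with the other
continuous covariates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning


@dataclass
class RelativeMassFit:
    """Fitted sex-specific log-log growth regression with group intercepts.

    group_effects are the conditional modes (BLUPs) of the group random
    intercepts, shrunken toward zero; sigma_group / sigma_resid are the
    between-group and residual SDs on the log-gram scale.
    """

    sex: str
    intercept: float
    slope: float
    group_effects: dict = field(default_factory=dict)
    sigma_group: float = 0.0
    sigma_resid: float = 1.0
    method: str = "reml"
    slope_se: float = float("nan")

    def expected_log_mass(self, age: float, group_id=None) -> float:
        if age <= 0:
            raise ValueError("age must be positive")
        g = 0.0
        if group_id is not None:
            if group_id in self.group_effects:
                g = self.group_effects[group_id]
            else:
                warnings.warn(
                    f"group {group_id!r} unseen during fitting; using group effect 0",
                    stacklevel=2,
                )
        return self.intercept + self.slope * np.log(age) + g

    def residual(self, mass: float, age: float, group_id=None) -> float:
        """Conditional residual log(mass) - fitted log mass."""
        if mass <= 0:
            raise ValueError("mass must be positive")
        return float(np.log(mass) - self.expected_log_mass(age, group_id))

    def to_json(self) -> str:
        return json.dumps(
            {
                "sex": self.sex,
                "intercept": self.intercept,
                "slope": self.slope,
                "group_effects": self.group_effects,
                "sigma_group": self.sigma_group,
                "sigma_resid": self.sigma_resid,
                "method": self.method,
                "slope_se": self.slope_se,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RelativeMassFit":
        return cls(**json.loads(text))


def relative_mass(fit: RelativeMassFit, individual_id, group_id, mass, age) -> float:
    """Relative mass of one individual at one observation (see module docs)."""
    del individual_id  # identity is not used; residuals are conditional on group
    return fit.residual(mass, age, group_id)


def fit_relative_mass(
    mass_records: pd.DataFrame,
    individuals: pd.DataFrame,
    sex: str,
    method: str = "reml",
) -> RelativeMassFit:
    """Fit the sex-specific log(mass) ~ log(age) + (1 | group) mixed model.

    Parameters
    ----------
    mass_records : DataFrame with individual_id, date, mass_g.
    individuals : DataFrame with individual_id, sex, birth_date, group_id.
    sex : which sex to fit ("F" or "M").
    method : "reml" (default) or "ml" variance estimation.

    With a single group the model degenerates: an OLS fit is returned with
    ``sigma_group = 0`` and a warning.
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    ind = individuals[individuals["sex"] == sex]
    if "is_breeder" in individuals.columns:
        ind = ind[~ind["is_breeder"].astype(bool)]
    df = mass_records.merge(
        ind[["individual_id", "birth_date", "group_id"]],
        on="individual_id",
        how="inner",
    )
    if len(df) < 3:
        raise ValueError(f"need at least 3 mass records for sex {sex!r}, got {len(df)}")
    age = (pd.to_datetime(df["date"]) - pd.to_datetime(df["birth_date"])).dt.days.to_numpy(float)
    if (age <= 0).any():
        raise ValueError("all mass-record ages must be positive")
    y = np.log(df["mass_g"].to_numpy(float))
    x = np.log(age)
    groups = df["group_id"].to_numpy()

    if len(np.unique(groups)) < 2:
        warnings.warn(
            "only one group in the mass data; falling back to OLS with sigma_group = 0",
            stacklevel=2,
        )
        X = sm.add_constant(x)
        ols = sm.OLS(y, X).fit()
        resid_sd = float(np.sqrt(ols.scale)) if len(y) > 2 else 0.0
        return RelativeMassFit(
            sex=sex,
            intercept=float(ols.params[0]),
            slope=float(ols.params[1]),
            group_effects={},
            sigma_group=0.0,
            sigma_resid=resid_sd,
            method="ols",
            slope_se=float(ols.bse[1]),
        )

    X = sm.add_constant(x)
    model = sm.MixedLM(y, X, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        res = model.fit(reml=(method == "reml"))
    group_effects = {g: float(np.asarray(re).ravel()[0]) for g, re in res.random_effects.items()}
    cov_re = float(np.asarray(res.cov_re).ravel()[0])
    return RelativeMassFit(
        sex=sex,
        intercept=float(np.asarray(res.fe_params)[0]),
        slope=float(np.asarray(res.fe_params)[1]),
        group_effects=group_effects,
        sigma_group=float(np.sqrt(max(cov_re, 0.0))),
        sigma_resid=float(np.sqrt(res.scale)),
        method=method,
        slope_se=float(np.asarray(res.bse_fe)[1]),
    )


def fit_relative_mass_by_sex(
    mass_records: pd.DataFrame, individuals: pd.DataFrame, method: str = "reml"
) -> dict[str, RelativeMassFit]:
    """Fit :func:`fit_relative_mass` for every sex present."""
    return {
        sex: fit_relative_mass(mass_records, individuals, sex, method=method)
        for sex in sorted(individuals["sex"].unique())
    }
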