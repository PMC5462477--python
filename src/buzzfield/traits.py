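"""Mixed-effects models linking buzz frequency to pollinator functional traits.

Characteristic (wingbeat) frequency falls with body size: bigger bees beat
their wings more slowly. Because tongue length and body size covary, two
complementary analyses are provided:

* a linear mixed model of per-buzz frequency on a single trait (wing
  length or tongue length), with a per-bee random intercept absorbing the
  repeated buzzes of each individual, reported with the marginal r²
  (Nakagawa–Schielzeth: fixed-effect variance over total variance);
* an ANCOVA of frequency on tongue length with wing length as covariate
  (type III marginal tests), asking whether the tongue signal is merely a
  body-size artifact;
* a cross-species log-linear model on literature records, collapsing
  replicate published values by sample-size-weighted means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "BeeRecord",
    "TraitModelFit",
    "MixedTraitModel",
    "LiteratureFrequencyModel",
    "fit_mixed_freq_trait",
    "ancova_tongue_with_wing",
    "weighted_mean",
    "fit_literature_model",
    "predict_trait_from_frequency",
    "bees_to_frame",
]


@dataclass
class BeeRecord:
    """One individual bee with its repeated buzz measurements."""

    bee_id: str
    species: str
    caste: str  # "queen" | "worker"
    wing_length: float  # mm
    tongue_length: float  # mm, prementum + glossa
    char_freqs: list  # Hz, one per buzz

    def __post_init__(self) -> None:
        if self.wing_length <= 0 or self.tongue_length <= 0:
            raise ValueError("trait lengths must be positive")
        if len(self.char_freqs) < 1:
            raise ValueError("at least one characteristic frequency is required")


@dataclass
class TraitModelFit:
    """Fitted frequency-on-trait mixed model."""

    trait: str
    intercept: float  # Hz
    slope: float  # Hz per mm
    random_intercept_var: float  # Hz^2, between-bee
    residual_var: float  # Hz^2, within-bee
    marginal_r2: float
    F: float
    df: tuple
    p: float
    trait_range: tuple = (np.nan, np.nan)

    def predict(self, trait_value) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(trait_value, dtype=float)


def bees_to_frame(bees) -> pd.DataFrame:
    """Long-format buzz table: one row per (bee, buzz)."""
    rows = [
        {
            "bee_id": b.bee_id,
            "species": b.species,
            "caste": b.caste,
            "wing_length": b.wing_length,
            "tongue_length": b.tongue_length,
            "freq": f,
        }
        for b in bees
        for f in b.char_freqs
    ]
    return pd.DataFrame(rows)


class MixedTraitModel(BaseEstimator, RegressorMixin):
    """Mixed-model regression of buzz frequency on one functional trait.

    freq_ij = b0 + b1 * trait_i + u_i + e_ij, with u_i a per-bee random
    intercept and repeated buzzes j within bee i. Fitted by REML. The
    marginal r² is var(b1*trait) / (var(b1*trait) + var(u) + var(e)).

    Parameters
    ----------
    trait : which trait column to use ("wing_length" or "tongue_length").
    per_bee_mean : collapse each bee's buzzes to its mean first (sensitivity
        mode; the default keeps buzzes as repeated measures).
    reml : estimation criterion (REML by default, the conventional choice
        for reporting variance components).
    """

    def __init__(self, trait: str = "wing_length", per_bee_mean: bool = False, reml: bool = True):
        self.trait = trait
        self.per_bee_mean = per_bee_mean
        self.reml = reml

    def fit(self, bees, y=None):
        df = bees if isinstance(bees, pd.DataFrame) else bees_to_frame(bees)
        if self.trait not in df.columns:
            raise ValueError(f"unknown trait {self.trait!r}")
        if df["bee_id"].nunique() < 3:
            raise ValueError("need at least 3 bees")
        if df[self.trait].nunique() < 2:
            raise ValueError(f"no trait variance: {self.trait} is constant")
        if self.per_bee_mean:
            df = (
                df.groupby("bee_id", as_index=False)
                .agg(freq=("freq", "mean"), **{self.trait: (self.trait, "first")})
            )
            ols = sm.OLS(df["freq"], sm.add_constant(df[self.trait])).fit()
            self._store_ols(df, ols)
            return self
        model = smf.mixedlm(f"freq ~ {self.trait}", df, groups=df["bee_id"])
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            # boundary fits (variance component ~ 0) emit convergence noise
            warnings.simplefilter("ignore")
            res = model.fit(reml=self.reml)
        b0, b1 = res.params["Intercept"], res.params[self.trait]
        var_u = float(res.cov_re.iloc[0, 0])
        var_e = float(res.scale)
        var_fix = float(np.var(b1 * df[self.trait].to_numpy()))
        denom = var_fix + var_u + var_e
        r2m = var_fix / denom if denom > 0 else 1.0
        n_bees = df["bee_id"].nunique()
        t_stat = float(res.tvalues[self.trait])
        df_den = n_bees - 2  # containment: trait varies between bees
        F = t_stat ** 2
        p = float(stats.f.sf(F, 1, df_den))
        self.fit_ = TraitModelFit(
            trait=self.trait,
            intercept=float(b0),
            slope=float(b1),
            random_intercept_var=max(var_u, 0.0),
            residual_var=var_e,
            marginal_r2=min(max(r2m, 0.0), 1.0),
            F=F,
            df=(1, df_den),
            p=p,
            trait_range=(float(df[self.trait].min()), float(df[self.trait].max())),
        )
        self.intercept_, self.slope_ = self.fit_.intercept, self.fit_.slope
        self.marginal_r2_ = self.fit_.marginal_r2
        return self

    def _store_ols(self, df, ols):
        b0, b1 = ols.params.iloc[0], ols.params.iloc[1]
        var_fix = float(np.var(b1 * df[self.trait].to_numpy()))
        var_e = float(ols.mse_resid)
        self.fit_ = TraitModelFit(
            trait=self.trait,
            intercept=float(b0),
            slope=float(b1),
            random_intercept_var=0.0,
            residual_var=var_e,
            marginal_r2=min(max(var_fix / (var_fix + var_e) if var_fix + var_e > 0 else 1.0, 0.0), 1.0),
            F=float(ols.fvalue),
            df=(1, int(ols.df_resid)),
            p=float(ols.f_pvalue),
            trait_range=(float(df[self.trait].min()), float(df[self.trait].max())),
        )
        self.intercept_, self.slope_ = self.fit_.intercept, self.fit_.slope
        self.marginal_r2_ = self.fit_.marginal_r2

    def predict(self, trait_values) -> np.ndarray:
        self._check_fitted()
        return self.fit_.predict(trait_values)

    def invert(self, f0: float) -> tuple:
        """Trait value implied by a characteristic frequency.

        Returns ``(trait_mm, extrapolated)``; the flag marks frequencies
        mapping outside the fitted trait range.
        """
        self._check_fitted()
        if self.fit_.slope == 0:
            raise ZeroDivisionError("zero slope: trait is not identifiable from frequency")
        trait = (f0 - self.fit_.intercept) / self.fit_.slope
        lo, hi = self.fit_.trait_range
        extrapolated = not (lo <= trait <= hi) if np.isfinite(lo) else True
        return float(trait), bool(extrapolated)

    def _check_fitted(self):
        if not hasattr(self, "fit_"):
            raise RuntimeError("model is not fitted")


def fit_mixed_freq_trait(bees, trait: str = "wing_length", **kw) -> TraitModelFit:
    """Fit the frequency-on-trait mixed model; returns the fit summary."""
    return MixedTraitModel(trait=trait, **kw).fit(bees).fit_


def ancova_tongue_with_wing(bees) -> pd.DataFrame:
    """Mixed-model ANCOVA: freq ~ tongue_length + wing_length (+ bee random
    intercept), with type III marginal tests per term.

    With continuous covariates only, the type III test of each term is the
    Wald test of its coefficient adjusting for the other. Returns a
    DataFrame indexed by term with columns F, df_num, df_den, p.
    """
    df = bees if isinstance(bees, pd.DataFrame) else bees_to_frame(bees)
    for col in ("tongue_length", "wing_length"):
        if df[col].nunique() < 2:
            raise ValueError(f"no variance in {col}")
    corr = np.corrcoef(df["tongue_length"], df["wing_length"])[0, 1]
    if abs(corr) > 1 - 1e-12:
        raise ValueError("tongue and wing length are exactly collinear; rank-deficient design")
    model = smf.mixedlm("freq ~ tongue_length + wing_length", df, groups=df["bee_id"])
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    n_bees = df["bee_id"].nunique()
    df_den = n_bees - 3  # containment df: two between-bee covariates + intercept
    rows = {}
    for term in ("tongue_length", "wing_length"):
        F = float(res.tvalues[term]) ** 2
        rows[term] = {"F": F, "df_num": 1, "df_den": df_den, "p": float(stats.f.sf(F, 1, df_den))}
    return pd.DataFrame.from_dict(rows, orient="index")


def weighted_mean(values, weights) -> float:
    """Sample-size-weighted mean of published measurements."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return float(np.sum(w * v) / np.sum(w))


class LiteratureFrequencyModel(BaseEstimator, RegressorMixin):
    """Cross-species log-linear model of buzz frequency on tongue length.

    Replicate published values per species x caste are first collapsed by
    sample-size-weighted means; then ``log(freq) = a + b * tongue`` is fit
    by OLS (the log transform accommodates the right tail of high-frequency
    small-bodied species). ``predict`` returns frequency in Hz via the
    back-transform exp(a + b * tongue).
    """

    def fit(self, entries: pd.DataFrame, y=None):
        df = entries.copy()
        required = {"species", "caste", "freq_hz", "tongue_mm"}
        if not required.issubset(df.columns):
            raise ValueError(f"entries need columns {sorted(required)}")
        for wcol in ("freq_n", "tongue_n"):
            if wcol not in df.columns:
                df[wcol] = 1.0
        collapsed = (
            df.groupby(["species", "caste"])
            .apply(
                lambda g: pd.Series(
                    {
                        "freq_hz": weighted_mean(g["freq_hz"], g["freq_n"]),
                        "tongue_mm": weighted_mean(g["tongue_mm"], g["tongue_n"]),
                    }
                ),
                include_groups=False,
            )
            .reset_index()
        )
        if len(collapsed) < 3:
            raise ValueError("need at least 3 species x caste entries")
        if np.any(collapsed["freq_hz"] <= 0):
            raise ValueError("frequencies must be positive for the log transform")
        if collapsed["tongue_mm"].nunique() < 2:
            raise ValueError("no tongue-length variance; rank-deficient design")
        ols = sm.OLS(
            np.log(collapsed["freq_hz"].to_numpy()),
            sm.add_constant(collapsed["tongue_mm"].to_numpy()),
        ).fit()
        self.intercept_ = float(ols.params[0])  # a, log-Hz
        self.rate_ = float(ols.params[1])  # b, per mm
        self.r2_ = float(ols.rsquared)
        self.F_ = float(ols.fvalue)
        self.p_ = float(ols.f_pvalue)
        self.df_ = (1, int(ols.df_resid))
        self.collapsed_ = collapsed
        return self

    def predict(self, tongue_mm) -> np.ndarray:
        if not hasattr(self, "rate_"):
            raise RuntimeError("model is not fitted")
        return np.exp(self.intercept_ + self.rate_ * np.asarray(tongue_mm, dtype=float))


def fit_literature_model(entries: pd.DataFrame) -> LiteratureFrequencyModel:
    """Fit the cross-species log-linear literature model."""
    return LiteratureFrequencyModel().fit(entries)


def predict_trait_from_frequency(fit: TraitModelFit, f0: float) -> tuple:
    """Invert a fitted trait line: trait = (f0 - intercept)/slope.

    Returns ``(trait_mm, extrapolated)``; monitoring use of the regression
    lines, flagged when the implied trait leaves the fitted range.
    """
    if fit.slope == 0:
        raise ZeroDivisionError("zero slope: inverse undefined")
    trait = (f0 - fit.intercept) / fit.slope
    lo, hi = fit.trait_range
    extrapolated = True if not np.isfinite(lo) else not (lo <= trait <= hi)
    return float(trait), bool(extrapolated)
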