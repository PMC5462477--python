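"""Plot-level survey statistics: acoustic vs visual counts and seed set.

Three analyses, all on plot means as is standard for small-n field designs:

* Pearson correlation between acoustic buzz counts and manual or visual
  bee counts (one-tailed for the directional "acoustics track bees"
  hypothesis);
* pollinator-exclusion contrast: open minus caged seed set per
  plot x species cell, one-sample one-tailed t against zero;
* ANCOVA of mean seed set on buzz density with plant species as covariate
  (type III tests), optionally with a density x species interaction to
  compare accrual curves between species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

__all__ = [
    "PlotSurvey",
    "SeedSetRecord",
    "correlate_counts",
    "exclusion_ttest",
    "seedset_ancova",
]


@dataclass
class PlotSurvey:
    """Per-plot survey effort and counts."""

    plot_id: str
    acoustic_buzzes: int
    visual_bees: int
    recording_hours: float
    observation_hours: float
    manual_buzzes: int | None = None  # annotation subsample
    elevation: float = np.nan  # m

    def __post_init__(self) -> None:
        if self.acoustic_buzzes < 0 or self.visual_bees < 0:
            raise ValueError("counts must be nonnegative")
        if self.recording_hours <= 0 or self.observation_hours <= 0:
            raise ValueError("survey hours must be positive")

    @property
    def buzz_density(self) -> float:
        """Buzzes per hour of recording."""
        return self.acoustic_buzzes / self.recording_hours


@dataclass
class SeedSetRecord:
    """Mean seed set for one plot x species x treatment cell."""

    plot_id: str
    plant_species: str  # e.g. "T. dasyphyllum" | "T. parryi"
    treatment: str  # "open" | "caged"
    mean_seeds_per_plant: float

    def __post_init__(self) -> None:
        if self.treatment not in ("open", "caged"):
            raise ValueError("treatment must be 'open' or 'caged'")
        if self.mean_seeds_per_plant < 0:
            raise ValueError("seed set must be nonnegative")


def correlate_counts(x, y, tail: str = "one"):
    """Pearson correlation between two per-plot count vectors.

    p comes from t = r * sqrt(df / (1 - r^2)) with df = n - 2; the
    one-tailed variant tests for a positive relationship. Returns
    ``(r, p, df)``. Small plot counts mean low power — interpret p with the
    sample size in mind.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 plots")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance in a count vector")
    alternative = {"one": "greater", "two": "two-sided"}.get(tail)
    if alternative is None:
        raise ValueError("tail must be 'one' or 'two'")
    res = stats.pearsonr(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue), len(x) - 2


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame(
        {
            "plot_id": [r.plot_id for r in records],
            "plant_species": [r.plant_species for r in records],
            "treatment": [r.treatment for r in records],
            "mean_seeds_per_plant": [r.mean_seeds_per_plant for r in records],
        }
    )


def exclusion_ttest(records):
    """Did bees add seeds? One-tailed t on open-minus-caged differences.

    Every plot x species cell must appear with both treatments; the
    per-cell differences (open − caged) are tested against zero with a
    one-sample t, df = cells − 1, one-tailed for difference > 0. Returns
    ``(mean_difference, t, df, p)``.
    """
    df = _records_frame(records)
    wide = df.pivot_table(
        index=["plot_id", "plant_species"],
        columns="treatment",
        values="mean_seeds_per_plant",
        aggfunc="mean",
    )
    if "open" not in wide.columns or "caged" not in wide.columns or wide.isna().any().any():
        missing = wide.index[wide.isna().any(axis=1)].tolist() if not wide.empty else "all"
        raise ValueError(f"open/caged pairing incomplete for cells: {missing}")
    diffs = (wide["open"] - wide["caged"]).to_numpy()
    n = len(diffs)
    mean_diff = float(diffs.mean())
    if np.allclose(diffs, diffs[0]) and np.isclose(diffs.std(ddof=1) if n > 1 else 0.0, 0.0):
        # degenerate: all differences identical
        t = 0.0 if mean_diff == 0 else np.inf * np.sign(mean_diff)
        p = 0.5 if mean_diff == 0 else (0.0 if mean_diff > 0 else 1.0)
        return mean_diff, float(t), n - 1, float(p)
    t, p = stats.ttest_1samp(diffs, 0.0, alternative="greater")
    return mean_diff, float(t), n - 1, float(p)


def seedset_ancova(
    records,
    density,
    treatment: str = "open",
    interaction: bool = False,
) -> pd.DataFrame:
    """ANCOVA of plot-mean seed set on buzz density with species covariate.

    ``density`` maps plot_id -> buzzes per hour. Fits
    ``mean_seeds ~ density + C(species)`` (plus ``density:species`` when
    ``interaction``) on the cells of the requested treatment, with
    sum-to-zero species coding and type III tests. Returns a DataFrame of
    per-term F, df and p plus a ``coef`` column for the density slope.
    """
    df = _records_frame(records)
    df = df[df["treatment"] == treatment].copy()
    if isinstance(density, dict):
        df["density"] = df["plot_id"].map(density)
    else:
        dser = pd.Series(density)
        df["density"] = df["plot_id"].map(dser)
    if df["density"].isna().any():
        raise ValueError("buzz density missing for some plots")
    formula = "mean_seeds_per_plant ~ density + C(plant_species, Sum)"
    if interaction:
        formula += " + density:C(plant_species, Sum)"
    n_params = 3 + (1 if interaction else 0)  # 2 species assumed; +1 per extra level
    n_params += max(df["plant_species"].nunique() - 2, 0)
    if len(df) <= n_params:
        raise ValueError("fewer plot-mean observations than model parameters")
    fit = smf.ols(formula, data=df).fit()
    table = anova_lm(fit, typ=3)
    out = table.rename(
        columns={"sum_sq": "ss", "df": "df_num", "PR(>F)": "p"}
    ).drop(index="Intercept", errors="ignore")
    out["df_den"] = fit.df_resid
    out.loc["density", "coef"] = fit.params["density"]
    # noiseless designs: a term explaining (numerically) nothing over an
    # (numerically) exact fit is 0/0 — report it as no evidence, not garbage
    total_ss = float(np.sum((df["mean_seeds_per_plant"] - df["mean_seeds_per_plant"].mean()) ** 2))
    negligible = out["ss"] < 1e-12 * max(total_ss, 1e-30)
    out.loc[negligible & out.index.str.contains("density|species"), ["F", "p"]] = [0.0, 1.0]
    return out
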