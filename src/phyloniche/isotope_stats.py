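"""Stable-isotope δ-notation, group summaries, and one-way ANOVA + Tukey.

Isotope ratios are expressed in the standard delta notation,

    δX = (R_sample / R_standard - 1) x 10^3   [per mil],

where R is the heavy-to-light isotope ratio (13C/12C or 15N/14N) and the
standard is the international reference (VPDB for C, atmospheric N2 for N).
δ15N tracks diet humification / trophic level; δ13C tracks C3 vs C4 plant
carbon sources.

Measurements are grouped by site, feeding group, or family and summarized
as n / mean / sample SD; between-group differences use one-way
fixed-effects ANOVA with all-pairs Tukey HSD (Tukey-Kramer for unequal n)
rendered as a compact letter display: groups sharing a letter are not
significantly different at the stated alpha.

NRI-environment relationships use Pearson correlations (two-sided t test,
df = n - 2) plus an OLS fit of NRI on the standardized covariates with a
site fixed factor — a documented fixed-effects stand-in for a site random
effect whose variance is negligible in this design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multicomp import pairwise_tukeyhsd
import statsmodels.formula.api as smf

__all__ = [
    "delta_value",
    "IsotopeTable",
    "summarize",
    "anova_tukey",
    "compact_letter_display",
    "correlate_nri_environment",
]

# instrument precision carried as metadata (per mil), not error-propagated
MEASUREMENT_PRECISION = {"d13C": 0.1, "d15N": 0.2}

SAMPLE_TYPES = ("termite", "litter", "soil")


def delta_value(r_sample: float, r_standard: float) -> float:
    """Delta notation: ((r_sample / r_standard) - 1) x 10^3, in per mil.

    Raises
    ------
    ValueError
        If ``r_standard <= 0`` or ``r_sample < 0``.
    """
    if r_standard <= 0:
        raise ValueError("r_standard must be positive")
    if r_sample < 0:
        raise ValueError("r_sample must be non-negative")
    return (r_sample / r_standard - 1.0) * 1e3


@dataclass
class IsotopeTable:
    """Per-sample δ15N/δ13C with type/site/plot/species metadata.

    Columns: sample_id, type (termite|litter|soil), site, plot, species
    (termite rows only), d15N, d13C.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"sample_id", "type", "site", "d15N", "d13C"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"isotope table missing columns: {sorted(missing)}")
        bad = set(df["type"]) - set(SAMPLE_TYPES)
        if bad:
            raise ValueError(f"unknown sample types: {sorted(bad)}")
        termites = df[df["type"] == "termite"]
        if "species" not in df.columns or termites["species"].isna().any():
            raise ValueError("termite rows must carry a species label")
        for col in ("d15N", "d13C"):
            if not np.isfinite(df[col].to_numpy(dtype=float)).all():
                raise ValueError(f"non-finite {col} values")

    @classmethod
    def read_csv(cls, path) -> "IsotopeTable":
        return cls(pd.read_csv(path))


def _grouped(table: IsotopeTable, grouping: str, traits: pd.DataFrame | None):
    """Rows of the relevant sample type with a 'group' column attached."""
    df = table.data
    if grouping == "site":
        sub = df.copy()
        sub["group"] = sub["site"]
        return sub
    if grouping not in ("feeding_group", "family"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if traits is None:
        raise ValueError(f"grouping by {grouping} requires a trait table")
    if grouping == "family" and "family" not in traits.columns:
        raise ValueError("trait table has no 'family' column")
    sub = df[df["type"] == "termite"].copy()
    lookup = traits.set_index("species")[grouping]
    unknown = sorted(set(sub["species"]) - set(lookup.index))
    if unknown:
        raise KeyError(f"species missing from trait table: {unknown}")
    sub["group"] = sub["species"].map(lookup)
    return sub


def summarize(
    table: IsotopeTable,
    grouping: str = "site",
    element: str = "d15N",
    traits: pd.DataFrame | None = None,
    sample_type: str | None = None,
) -> pd.DataFrame:
    """n / mean / sample SD of one element per group.

    ``grouping`` is "site", "feeding_group" or "family" (the latter two
    join the trait table on species and implicitly restrict to termite
    rows).  ``sample_type`` optionally restricts site summaries to one of
    termite/litter/soil.  The SD uses the n-1 denominator; a singleton
    group reports SD as NA rather than 0.  Groups are sorted by key.
    """
    if element not in ("d15N", "d13C"):
        raise ValueError(f"unknown element {element!r}")
    sub = _grouped(table, grouping, traits)
    if sample_type is not None:
        sub = sub[sub["type"] == sample_type]
    rows = []
    for key in sorted(sub["group"].dropna().unique()):
        vals = sub.loc[sub["group"] == key, element].to_numpy(dtype=float)
        rows.append(
            {
                "group": key,
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def compact_letter_display(
    groups: list, significant_pairs: set[frozenset]
) -> dict:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; the letter
    partition depends only on the set of significant pairs, not on group
    input order (groups are processed sorted).
    """
    groups = sorted(groups)
    # insert-absorb: start with one set of all groups; split every set
    # containing a significant pair, then drop sets nested in another
    letter_sets: list[frozenset] = [frozenset(groups)]
    for pair in sorted(significant_pairs, key=sorted):
        a, b = sorted(pair)
        new_sets: list[frozenset] = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        letter_sets = [
            s
            for i, s in enumerate(new_sets)
            if s
            and not any(
                (s < t) or (s == t and i > j)
                for j, t in enumerate(new_sets)
            )
        ]
    letter_sets.sort(key=lambda s: sorted(s))
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for k, s in enumerate(letter_sets):
        for g in sorted(s):
            out[g] += letters[k]
    return out


@dataclass
class AnovaTukeyResult:
    F: float
    df_between: int
    df_within: int
    p: float
    letters: dict
    tukey: pd.DataFrame
    excluded_groups: list


def anova_tukey(
    table: IsotopeTable,
    grouping: str = "site",
    element: str = "d15N",
    alpha: float = 0.05,
    traits: pd.DataFrame | None = None,
    sample_type: str | None = None,
) -> AnovaTukeyResult:
    """One-way fixed-effects ANOVA with Tukey HSD letters.

    Groups with fewer than two observations are excluded from the omnibus
    test with a warning (listed in ``excluded_groups``).  Tukey HSD uses
    the studentized-range distribution with the Tukey-Kramer unequal-n
    correction; the compact letter display assigns shared letters to
    non-significant pairs.
    """
    sub = _grouped(table, grouping, traits)
    if sample_type is not None:
        sub = sub[sub["type"] == sample_type]
    sizes = sub.groupby("group")[element].count()
    excluded = sorted(sizes[sizes < 2].index)
    keep = sub[~sub["group"].isin(excluded)]
    groups = sorted(keep["group"].unique())
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups with n >= 2")
    samples = [
        keep.loc[keep["group"] == g, element].to_numpy(dtype=float)
        for g in groups
    ]
    F, p = st.f_oneway(*samples)
    df_between = len(groups) - 1
    df_within = sum(len(s) for s in samples) - len(groups)
    tk = pairwise_tukeyhsd(
        keep[element].to_numpy(dtype=float),
        keep["group"].to_numpy(),
        alpha=alpha,
    )
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )
    sig_pairs = {
        frozenset((row["group1"], row["group2"]))
        for _, row in tukey.iterrows()
        if row["reject"]
    }
    letters = compact_letter_display(groups, sig_pairs)
    return AnovaTukeyResult(
        F=float(F),
        df_between=df_between,
        df_within=df_within,
        p=float(p),
        letters=letters,
        tukey=tukey,
        excluded_groups=excluded,
    )


def correlate_nri_environment(
    nri_frame: pd.DataFrame, env: pd.DataFrame
) -> dict:
    """Pearson correlations of plot NRI with environmental covariates.

    ``nri_frame`` needs columns ``plot_id`` and ``nri``; ``env`` needs
    ``plot`` plus ``rainfall_mm``, ``elevation_m``, ``temperature_C`` (and
    a ``site`` column for the adjusted fit).  For each covariate the
    Pearson r with its two-sided t test (df = n - 2) is returned; a
    zero-variance covariate is flagged with r = NaN.  An OLS fit of NRI on
    all three standardized covariates with a site fixed factor is attached
    under ``"ols"`` (a fixed-effects stand-in for a site random effect,
    flagged via ``"ols_site_factor": True``).
    """
    merged = nri_frame.merge(
        env, left_on="plot_id", right_on="plot", how="inner"
    )
    merged = merged[np.isfinite(merged["nri"])]
    if len(merged) < 3:
        raise ValueError("need >=3 plots with defined NRI")
    out: dict = {}
    for var in ("rainfall_mm", "elevation_m", "temperature_C"):
        x = merged[var].to_numpy(dtype=float)
        y = merged["nri"].to_numpy(dtype=float)
        if np.std(x) == 0:
            out[var] = {"r": np.nan, "t": np.nan, "p": np.nan,
                        "flag": "zero-variance covariate"}
            continue
        r, p = st.pearsonr(x, y)
        n = len(x)
        with np.errstate(divide="ignore"):
            t = r * np.sqrt((n - 2) / max(1 - r * r, 1e-300))
        out[var] = {"r": float(r), "t": float(t), "p": float(p), "n": n}
    model_df = merged.copy()
    for var in ("rainfall_mm", "elevation_m", "temperature_C"):
        s = model_df[var].std(ddof=1)
        model_df[var + "_z"] = (
            (model_df[var] - model_df[var].mean()) / s if s > 0 else 0.0
        )
    if "site" in model_df.columns and model_df["site"].nunique() > 1:
        formula = "nri ~ rainfall_mm_z + elevation_m_z + temperature_C_z + C(site)"
    else:
        formula = "nri ~ rainfall_mm_z + elevation_m_z + temperature_C_z"
    fit = smf.ols(formula, data=model_df).fit()
    out["ols"] = {
        "params": fit.params.to_dict(),
        "pvalues": fit.pvalues.to_dict(),
        "r_squared": float(fit.rsquared),
    }
    out["ols_site_factor"] = "C(site)" in formula
    return out
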