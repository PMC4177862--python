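"""Group statistics for callosal area tables.

The battery mirrors a classical ROI morphometry analysis: per-region
ANCOVA (group, or group x sex with interaction, plus age as a linear
covariate; Type III sums of squares under sum-to-zero factor coding),
Scheffe post-hoc contrasts among the four group-by-sex cells, a fixed
Bonferroni gate at p <= 0.01 for the five sub-regions (0.05 / 5, applied
inclusively), and a one-way ANOVA across acquisition sites on native-space
total callosal area.

Model fits go through :mod:`statsmodels` OLS on explicitly built design
matrices; Type III effect F values are obtained by full-vs-reduced model
comparison, which is equivalent to Type III under sum-to-zero coding (and
is cross-checked against ``statsmodels.stats.anova.anova_lm`` in the test
suite).  No Welch-type corrections are applied anywhere: the ANCOVA is
classical.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ValidationError
from .io import REGION_NAMES

DEFAULT_VALUE = "stereotaxic_area_mm2"
BONFERRONI_ALPHA = 0.01  # 0.05 / 5 sub-regions, inclusive
SCHEFFE_ALPHA = 0.05


@dataclass(frozen=True)
class AncovaResult:
    effect: str
    f: float
    df1: int
    df2: int
    p: float
    adjusted_means: dict | None = None

    def __post_init__(self) -> None:
        if self.f < 0 or not (0.0 <= self.p <= 1.0):
            raise ValidationError(f"invalid ANCOVA result: F={self.f}, p={self.p}")


@dataclass(frozen=True)
class PosthocResult:
    """All pairwise Scheffe contrasts among group-by-sex cells."""

    contrasts: tuple[dict, ...]
    alpha: float = SCHEFFE_ALPHA

    def significant_pairs(self) -> list[tuple]:
        return [
            tuple(sorted((c["cell_a"], c["cell_b"])))
            for c in self.contrasts
            if c["significant"]
        ]


def subject_frame(
    table: pd.DataFrame, region: str | None, value: str = DEFAULT_VALUE
) -> pd.DataFrame:
    """One row per subject with the analysis value for ``region``
    (``None`` or ``'total'`` sums the five sub-regions)."""
    keys = ["subject_id", "group", "sex", "age", "site"]
    if region in (None, "total"):
        sub = table[table["region"].isin(REGION_NAMES)]
        agg = sub.groupby(keys, as_index=False)[value].sum()
        return agg.rename(columns={value: "y"})
    sub = table[table["region"] == region]
    if sub.empty:
        raise ValidationError(f"no rows for region {region!r}")
    out = sub[keys + [value]].rename(columns={value: "y"}).reset_index(drop=True)
    if out["subject_id"].duplicated().any():
        raise ValidationError(f"duplicate subjects for region {region!r}")
    return out


def _sum_code(series: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(series.unique())
    if len(levels) != 2:
        raise ValidationError(
            f"factor {series.name!r} must have exactly 2 levels, got {levels}"
        )
    return np.where(series == levels[0], 1.0, -1.0), levels


def _check_cells(df: pd.DataFrame, factors: tuple[str, ...]) -> None:
    counts = df.groupby(list(factors)).size()
    full = 1
    for f in factors:
        full *= df[f].nunique()
    if len(counts) < full:
        seen = set(counts.index if len(factors) > 1 else [(i,) for i in counts.index])
        raise ValidationError(f"empty factor cell; populated cells: {sorted(seen)}")
    small = counts[counts < 2]
    if not small.empty:
        raise ValidationError(f"factor cells with < 2 subjects: {dict(small)}")


def _design(
    df: pd.DataFrame, factors: tuple[str, ...], covariates: tuple[str, ...]
) -> tuple[np.ndarray, dict[str, list[int]]]:
    """Sum-to-zero coded design matrix and column indices per effect."""
    cols = [np.ones(len(df))]
    blocks: dict[str, list[int]] = {}
    codes = {}
    for f in factors:
        x, _ = _sum_code(df[f])
        codes[f] = x
        blocks[f] = [len(cols)]
        cols.append(x)
    if len(factors) == 2:
        name = ":".join(factors)
        blocks[name] = [len(cols)]
        cols.append(codes[factors[0]] * codes[factors[1]])
    for c in covariates:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            raise ValidationError(f"missing or unparsable covariate {c!r}")
        blocks[c] = [len(cols)]
        cols.append(vals.to_numpy(dtype=float))
    return np.column_stack(cols), blocks


def _fit(y: np.ndarray, x: np.ndarray):
    fit = sm.OLS(y, x).fit()
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValidationError("rank-deficient design matrix")
    return fit


def ancova(
    table: pd.DataFrame,
    region: str | None,
    covariates: tuple[str, ...] = ("age",),
    factors: tuple[str, ...] = ("group",),
    value: str = DEFAULT_VALUE,
) -> dict[str, AncovaResult]:
    """Type III ANCOVA of one region; returns F/df/p per effect.

    ``factors`` is ``('group',)`` or ``('group', 'sex')``; with two factors
    the interaction is included.
    """
    if not 1 <= len(factors) <= 2:
        raise ValidationError("one or two factors supported")
    df = subject_frame(table, region, value)
    _check_cells(df, factors)
    x, blocks = _design(df, tuple(factors), tuple(covariates))
    y = df["y"].to_numpy(dtype=float)
    full = _fit(y, x)
    mse = full.ssr / full.df_resid
    results: dict[str, AncovaResult] = {}
    for effect, idx in blocks.items():
        keep = [j for j in range(x.shape[1]) if j not in idx]
        reduced = sm.OLS(y, x[:, keep]).fit()
        q = len(idx)
        f = float((reduced.ssr - full.ssr) / q / mse)
        f = max(f, 0.0)
        p = float(sps.f.sf(f, q, int(full.df_resid)))
        results[effect] = AncovaResult(
            effect=effect,
            f=f,
            df1=q,
            df2=int(full.df_resid),
            p=p,
            adjusted_means=_adjusted_group_means(df, full, blocks, effect)
            if effect == "group"
            else None,
        )
    return results


def _adjusted_group_means(df, full, blocks, effect) -> dict:
    """Least-squares group means at the mean covariate value (other
    sum-coded terms average to zero)."""
    params = full.params
    base = params[0]
    for name, idx in blocks.items():
        if name in ("group", "sex") or ":" in name:
            continue
        base += params[idx[0]] * float(pd.to_numeric(df[name]).mean())
    levels = sorted(df["group"].unique())
    coef = params[blocks["group"][0]]
    return {levels[0]: float(base + coef), levels[1]: float(base - coef)}


def ancova_group(
    table: pd.DataFrame,
    region: str | None,
    covariates: tuple[str, ...] = ("age",),
    factors: tuple[str, ...] = ("group",),
    value: str = DEFAULT_VALUE,
) -> AncovaResult:
    """The group main-effect F of the ANCOVA (see :func:`ancova`)."""
    return ancova(table, region, covariates, factors, value)["group"]


def interaction_f(
    table: pd.DataFrame,
    region: str,
    covariates: tuple[str, ...] = ("age",),
    value: str = DEFAULT_VALUE,
) -> AncovaResult:
    """Group-by-sex interaction F from the two-factor ANCOVA."""
    return ancova(table, region, covariates, ("group", "sex"), value)["group:sex"]


def scheffe_posthoc(
    table: pd.DataFrame,
    region: str,
    covariates: tuple[str, ...] = ("age",),
    value: str = DEFAULT_VALUE,
    alpha: float = SCHEFFE_ALPHA,
) -> PosthocResult:
    """Scheffe contrasts among the four group-by-sex cell means.

    Uses the error variance and residual df of the fitted interaction
    ANCOVA; the Scheffe p for a pairwise contrast with F_c =
    diff^2 / (MSE (1/n_i + 1/n_j)) is ``sf(F_c / (k-1); k-1, dfe)``.
    """
    df = subject_frame(table, region, value)
    _check_cells(df, ("group", "sex"))
    x, _ = _design(df, ("group", "sex"), tuple(covariates))
    y = df["y"].to_numpy(dtype=float)
    full = _fit(y, x)
    mse = full.ssr / full.df_resid
    dfe = int(full.df_resid)

    # age-adjusted cell means: observed mean shifted to the grand mean age
    beta_age = float(full.params[-1]) if covariates else 0.0
    grand_age = float(pd.to_numeric(df["age"]).mean()) if covariates else 0.0
    cells = {}
    for (g, s), cell in df.groupby(["group", "sex"]):
        adj = float(cell["y"].mean())
        if covariates:
            adj -= beta_age * (float(cell["age"].mean()) - grand_age)
        cells[(g, s)] = (adj, len(cell))
    k = len(cells)
    if k < 2:
        raise ValidationError("need at least 2 cells for post-hoc contrasts")
    contrasts = []
    for (a, (ma, na)), (b, (mb, nb)) in combinations(sorted(cells.items()), 2):
        fc = (ma - mb) ** 2 / (mse * (1.0 / na + 1.0 / nb))
        p = float(sps.f.sf(fc / (k - 1), k - 1, dfe))
        contrasts.append(
            {
                "cell_a": a,
                "cell_b": b,
                "mean_a": ma,
                "mean_b": mb,
                "diff": ma - mb,
                "f_contrast": float(fc),
                "p_scheffe": p,
                "significant": p < alpha,
            }
        )
    return PosthocResult(contrasts=tuple(contrasts), alpha=alpha)


def site_anova(table: pd.DataFrame, value: str = "native_area_mm2") -> AncovaResult:
    """One-way ANOVA of native-space total CC area across sites."""
    df = subject_frame(table, "total", value)
    sites = sorted(df["site"].unique())
    if len(sites) < 2:
        raise ValidationError("site ANOVA needs at least 2 sites")
    samples = [df.loc[df["site"] == s, "y"].to_numpy() for s in sites]
    f, p = sps.f_oneway(*samples)
    return AncovaResult(
        effect="site",
        f=float(f),
        df1=len(sites) - 1,
        df2=len(df) - len(sites),
        p=float(p),
    )


def bonferroni_gate(results, alpha: float = BONFERRONI_ALPHA) -> dict[str, bool]:
    """Fixed-threshold multiple-comparison gate over the five sub-regions:
    significant iff p <= 0.01 (inclusive)."""
    if len(results) != 5:
        raise ValidationError(f"expected exactly 5 region results, got {len(results)}")
    flags = {}
    for name, res in zip(REGION_NAMES, results):
        p = res.p if isinstance(res, AncovaResult) else float(res)
        flags[name] = bool(p <= alpha)
    return flags


def stats_battery(
    table: pd.DataFrame, value: str = DEFAULT_VALUE
) -> tuple[pd.DataFrame, dict]:
    """Full statistical battery on an area table.

    Per region (five sub-regions + total): two-factor (group x sex)
    ANCOVA with age covariate.  Bending angle gets the same model.  The
    Bonferroni gate is applied to the five sub-region group effects; a
    Scheffe post-hoc is run for every region whose interaction is
    significant at 0.05.  Site differences are checked by one-way ANOVA on
    native total area.  Returns a tidy effects table and a dict of extras.
    """
    def _fit_region(region, val):
        # two-factor model when every group-by-sex cell has >= 2 subjects,
        # else fall back to the one-factor group model
        try:
            return ancova(table, region, ("age",), ("group", "sex"), val)
        except ValidationError:
            return ancova(table, region, ("age",), ("group",), val)

    rows = []
    region_group_results = []
    posthocs = {}
    for region in list(REGION_NAMES) + ["total"]:
        effects = _fit_region(region, value)
        for name, r in effects.items():
            rows.append(
                {
                    "region": region,
                    "effect": name,
                    "F": r.f,
                    "df1": r.df1,
                    "df2": r.df2,
                    "p": r.p,
                }
            )
        if region != "total":
            region_group_results.append(effects["group"])
            if "group:sex" in effects and effects["group:sex"].p < SCHEFFE_ALPHA:
                posthocs[region] = scheffe_posthoc(table, region, ("age",), value)
    if "bending_deg" in table.columns:
        effects = _fit_region(REGION_NAMES[0], "bending_deg")
        for name, r in effects.items():
            rows.append(
                {
                    "region": "bending_angle",
                    "effect": name,
                    "F": r.f,
                    "df1": r.df1,
                    "df2": r.df2,
                    "p": r.p,
                }
            )
    gate = bonferroni_gate(region_group_results)
    site = None
    if table["site"].nunique() >= 2:
        site = site_anova(table)
        rows.append(
            {
                "region": "total_native",
                "effect": "site",
                "F": site.f,
                "df1": site.df1,
                "df2": site.df2,
                "p": site.p,
            }
        )
    tidy = pd.DataFrame(rows)
    tidy["significant"] = [
        (r.region in gate and r.effect == "group" and gate[r.region])
        if r.effect == "group" and r.region in gate
        else r.p < SCHEFFE_ALPHA
        for r in tidy.itertuples()
    ]
    extras = {"bonferroni": gate, "posthoc": posthocs, "site": site}
    return tidy, extras


def render_report(tidy: pd.DataFrame, extras: dict) -> str:
    """Human-readable text report of :func:`stats_battery` output."""
    lines = [
        "Callosal morphometry statistics",
        f"Sub-region gate: Bonferroni, significant iff p <= {BONFERRONI_ALPHA}",
        f"Post-hoc: Scheffe at alpha = {SCHEFFE_ALPHA}",
        "",
    ]
    for row in tidy.itertuples():
        lines.append(
            f"{row.region:>16s} {row.effect:>10s}: "
            f"F({row.df1},{row.df2}) = {row.F:7.2f}, p = {row.p:.4f}"
            + ("  *" if row.significant else "")
        )
    lines.append("")
    lines.append("Bonferroni-gated sub-region group effects:")
    for region, flag in extras["bonferroni"].items():
        lines.append(f"  {region:>16s}: {'significant' if flag else 'n.s.'}")
    for region, ph in extras["posthoc"].items():
        lines.append(f"Scheffe contrasts for {region}:")
        for c in ph.contrasts:
            lines.append(
                f"  {c['cell_a']} vs {c['cell_b']}: diff = {c['diff']:7.2f}, "
                f"p = {c['p_scheffe']:.4f}"
                + ("  *" if c["significant"] else "")
            )
    return "\n".join(lines) + "\n"
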