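"""Group comparisons and tabular reports across age x genotype.

The experimental unit is the NMJ; muscles are reported as nesting counts but
are not modeled (the comparisons are fixed-effects, matching common practice
for endplate data).  Electrophysiological measures are summarized as
mean ± SEM and compared by two-way ANOVA (age x genotype) with per-age
genotype post-tests under Bonferroni correction; morphometric measures are
typically non-normal and are summarized as median ± IQR and compared by the
Ansari-Bradley dispersion test followed by Mann-Whitney U for location.
Variance inflation (a hallmark of heterogeneous disease progression) is
tested per age with the variance-ratio F test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "ComparisonResult",
    "percent_change",
    "two_way_anova_bonferroni",
    "nonparametric_compare",
    "variance_f_test",
    "build_report",
]

MIN_GROUP_N = 3  # below this a comparison is flagged underpowered, no p reported


@dataclass
class ComparisonResult:
    """One statistical comparison (or one ANOVA effect)."""

    test: str
    measure: str
    age_weeks: Optional[int]
    statistic: float
    p_value: float
    adjusted_p: Optional[float] = None
    group_summary: dict = field(default_factory=dict)
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "measure": self.measure,
            "age_weeks": self.age_weeks,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "adjusted_p": self.adjusted_p,
            "note": self.note,
            **{f"summary_{k}": v for k, v in self.group_summary.items()},
        }


def percent_change(reference: float, observed: float) -> float:
    """Percent reduction of ``observed`` relative to ``reference``.

    ``100 * (reference - observed) / reference``; positive values are
    reductions, negative values increases.
    """
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return 100.0 * (reference - observed) / reference


def _check_table(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    df = table[table["measure"] == measure].dropna(subset=["value"]) if "measure" in table \
        else table.dropna(subset=["value"])
    cells = df.groupby(["age_weeks", "genotype"])["value"].size()
    ages = df["age_weeks"].unique()
    genos = df["genotype"].unique()
    for a in ages:
        for g in genos:
            if (a, g) not in cells.index:
                raise ValueError(f"empty cell: age={a}, genotype={g} for measure {measure!r}")
    return df


def two_way_anova_bonferroni(table: pd.DataFrame, measure: str) -> list[ComparisonResult]:
    """Age x genotype ANOVA plus Bonferroni-corrected per-age genotype post-tests.

    ``table`` columns: ``age_weeks``, ``genotype``, ``measure``, ``value``
    (``unit_id``/``muscle_id`` are carried but not modeled).  The Bonferroni
    family is the number of per-age post-tests within this measure.
    """
    df = _check_table(table, measure)
    if df["age_weeks"].nunique() < 2 or df["genotype"].nunique() < 2:
        raise ValueError("need >= 2 levels of age and genotype for a two-way ANOVA")

    model = ols("value ~ C(age_weeks) * C(genotype)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    out = []
    for effect, row in anova.iterrows():
        if effect == "Residual":
            continue
        out.append(ComparisonResult(
            test="two_way_anova",
            measure=measure,
            age_weeks=None,
            statistic=float(row["F"]),
            p_value=float(row["PR(>F)"]),
            note=f"effect={effect.strip()}",
        ))

    ages = sorted(df["age_weeks"].unique())
    genos = sorted(df["genotype"].unique())
    n_tests = len(ages)
    for a in ages:
        sub = df[df["age_weeks"] == a]
        x = sub[sub["genotype"] == genos[0]]["value"].to_numpy()
        y = sub[sub["genotype"] == genos[1]]["value"].to_numpy()
        summary = {}
        for g in genos:
            vals = sub[sub["genotype"] == g]["value"].to_numpy()
            summary[f"{g}_mean"] = float(np.mean(vals))
            summary[f"{g}_sem"] = float(stats.sem(vals)) if len(vals) > 1 else np.nan
            summary[f"{g}_n"] = int(len(vals))
        if min(len(x), len(y)) < MIN_GROUP_N:
            out.append(ComparisonResult("t_posttest", measure, int(a), np.nan, np.nan,
                                        group_summary=summary, note="underpowered: n < 3"))
            continue
        t, p = stats.ttest_ind(x, y)
        out.append(ComparisonResult(
            test="t_posttest",
            measure=measure,
            age_weeks=int(a),
            statistic=float(t),
            p_value=float(p),
            adjusted_p=float(min(1.0, p * n_tests)),
            group_summary=summary,
        ))
    return out


def nonparametric_compare(table: pd.DataFrame, measure: str) -> list[ComparisonResult]:
    """Per-age Ansari-Bradley (dispersion) then Mann-Whitney U (location).

    Medians and IQRs are reported per group; groups with n < 3 are flagged
    underpowered and no p is reported.
    """
    df = _check_table(table, measure)
    genos = sorted(df["genotype"].unique())
    if len(genos) != 2:
        raise ValueError("nonparametric_compare requires exactly two genotypes")
    out = []
    for a in sorted(df["age_weeks"].unique()):
        sub = df[df["age_weeks"] == a]
        x = sub[sub["genotype"] == genos[0]]["value"].to_numpy()
        y = sub[sub["genotype"] == genos[1]]["value"].to_numpy()
        summary = {}
        for g, vals in zip(genos, (x, y)):
            summary[f"{g}_median"] = float(np.median(vals)) if len(vals) else np.nan
            summary[f"{g}_iqr"] = float(np.subtract(*np.percentile(vals, [75, 25]))) \
                if len(vals) > 1 else np.nan
            summary[f"{g}_n"] = int(len(vals))
        if min(len(x), len(y)) < MIN_GROUP_N:
            for name in ("ansari_bradley", "mann_whitney_u"):
                out.append(ComparisonResult(name, measure, int(a), np.nan, np.nan,
                                            group_summary=summary,
                                            note="underpowered: n < 3"))
            continue
        ab_stat, ab_p = stats.ansari(x, y)
        out.append(ComparisonResult("ansari_bradley", measure, int(a),
                                    float(ab_stat), float(ab_p), group_summary=summary))
        u_stat, u_p = stats.mannwhitneyu(x, y, alternative="two-sided")
        out.append(ComparisonResult("mann_whitney_u", measure, int(a),
                                    float(u_stat), float(u_p), group_summary=summary))
    return out


def variance_f_test(table: pd.DataFrame, measure: str) -> list[ComparisonResult]:
    """Per-age two-sided variance-ratio F test between genotypes."""
    df = _check_table(table, measure)
    genos = sorted(df["genotype"].unique())
    if len(genos) != 2:
        raise ValueError("variance_f_test requires exactly two genotypes")
    out = []
    for a in sorted(df["age_weeks"].unique()):
        sub = df[df["age_weeks"] == a]
        x = sub[sub["genotype"] == genos[0]]["value"].to_numpy()
        y = sub[sub["genotype"] == genos[1]]["value"].to_numpy()
        if min(len(x), len(y)) < MIN_GROUP_N:
            out.append(ComparisonResult("f_test", measure, int(a), np.nan, np.nan,
                                        note="underpowered: n < 3"))
            continue
        vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
        if vx == 0 or vy == 0:
            raise ValueError(f"zero variance in a group at age {a}")
        F = vx / vy
        dfx, dfy = len(x) - 1, len(y) - 1
        p_one = stats.f.sf(F, dfx, dfy) if F >= 1 else stats.f.cdf(F, dfx, dfy)
        out.append(ComparisonResult(
            "f_test", measure, int(a), float(F), float(min(1.0, 2.0 * p_one)),
            group_summary={
                f"{genos[0]}_var": float(vx), f"{genos[1]}_var": float(vy),
                f"{genos[0]}_n": len(x), f"{genos[1]}_n": len(y),
            },
        ))
    return out


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _results_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def build_report(
    ephys: Optional[pd.DataFrame],
    morpho: Optional[pd.DataFrame],
    outdir,
) -> dict:
    """Write the full report bundle and return the tables.

    ``ephys``: one row per NMJ with columns ``age_weeks``, ``genotype`` and
    the per-NMJ summary measures.  ``morpho``: one row per NMJ image with the
    morphometry record fields.  Empty inputs produce empty sections.

    Files written: ``ephys_summary.csv`` (mean ± SEM per group x measure),
    ``ephys_comparisons.csv``; ``morpho_summary.csv`` (median ± IQR),
    ``morpho_comparisons.csv`` (Ansari-Bradley + Mann-Whitney + F tests);
    ``incidence.csv`` (floccular categories and extrajunctional clusters).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}

    if ephys is not None and len(ephys):
        measures = [c for c in ephys.columns
                    if c not in ("unit_id", "age_weeks", "genotype", "muscle_id", "notes")
                    and ephys[c].dtype.kind in "fi"]
        long = ephys.melt(id_vars=["age_weeks", "genotype"], value_vars=measures,
                          var_name="measure", value_name="value").dropna()
        summary = (long.groupby(["measure", "age_weeks", "genotype"])["value"]
                   .agg(mean="mean", sem=lambda v: stats.sem(v) if len(v) > 1 else np.nan,
                        n="size").reset_index())
        tables["ephys_summary"] = summary
        comps = []
        for m in measures:
            try:
                comps.extend(two_way_anova_bonferroni(long, m))
            except ValueError:
                continue
        tables["ephys_comparisons"] = _results_frame(comps) if comps else pd.DataFrame()

    if morpho is not None and len(morpho):
        measures = [c for c in morpho.columns
                    if c.startswith(("a_", "b_", "c_", "d_", "e_", "f_", "g_", "h_",
                                     "i_", "j_"))
                    or c in ("fractal_dimension", "dim_area_fraction", "valley_peak_ratio")]
        long = morpho.melt(id_vars=["age_weeks", "genotype"], value_vars=measures,
                           var_name="measure", value_name="value").dropna()
        summary = (long.groupby(["measure", "age_weeks", "genotype"])["value"]
                   .agg(median="median",
                        iqr=lambda v: np.subtract(*np.percentile(v, [75, 25])),
                        n="size").reset_index())
        tables["morpho_summary"] = summary
        comps = []
        for m in measures:
            try:
                comps.extend(nonparametric_compare(long, m))
                comps.extend(variance_f_test(long, m))
            except ValueError:
                continue
        tables["morpho_comparisons"] = _results_frame(comps) if comps else pd.DataFrame()

        if "floccular_category" in morpho.columns:
            inc = (morpho.groupby(["age_weeks", "genotype", "floccular_category"])
                   .size().rename("n_nmjs").reset_index())
            extra = (morpho.groupby(["age_weeks", "genotype"])["has_extrajunctional"]
                     .agg(n_extrajunctional="sum", n_total="size").reset_index())
            tables["incidence"] = inc
            tables["incidence_extrajunctional"] = extra

    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    return tables
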