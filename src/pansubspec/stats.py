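"""Cohort summary statistics.

Covers the subspecies-core HGT summary (how many core genes of each
subspecies are of foreign origin), defense-feature prevalence
(e.g. complete CRISPR-Cas loci per subspecies), a from-first-principles
one-way fixed-effects ANOVA (between/within sums of squares, F upper
tail), and the t-test of the Pearson correlation coefficient used for
the defense-vs-HGT relation.

Percentages are reported at full precision together with a display
rounding: one-decimal values use round-half-away-from-zero, integer
displays use nearest integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsInputError(ValueError):
    pass


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed percentages)."""
    factor = 10 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


# ---------------------------------------------------------------- fixtures

def load_table1() -> pd.DataFrame:
    """Packaged transcription of the printed subspecies-core gene table.

    Columns: subspecies, core_gene_id, prevalence_pct, hgt_status.
    """
    ref = resources.files("pansubspec.data") / "table1_subspecies_core.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_defense_annotation() -> pd.DataFrame:
    """Packaged synthetic defense-annotation table (42 representative strains).

    A synthetic stand-in reconstructed from printed cohort summaries:
    per-subspecies strain counts and complete-CRISPR counts are exact;
    R-M counts match the printed means/SDs at printed precision; the
    per-genome HGT percentages scatter around the printed subspecies
    means with a planted negative dependence on R-M count.
    """
    ref = resources.files("pansubspec.data") / "defense_annotation_synthetic.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


# ------------------------------------------------------------- operations

def summarize_core_hgt(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subspecies core-gene counts and foreign (HGT) fractions.

    ``table`` needs columns subspecies, core_gene_id, hgt_status
    (Native/Foreign).  Returns per subspecies: n_core, n_foreign,
    foreign_pct (full precision) and foreign_pct_display (one decimal,
    half-away).
    """
    if table.empty:
        raise StatsInputError("empty core-gene table")
    bad = set(table["hgt_status"]) - {"Native", "Foreign"}
    if bad:
        raise StatsInputError(f"unknown hgt_status values: {sorted(bad)}")
    rows = []
    for s, grp in table.groupby("subspecies", sort=True):
        n_core = len(grp)
        n_foreign = int((grp["hgt_status"] == "Foreign").sum())
        pct = 100.0 * n_foreign / n_core
        rows.append({"subspecies": s, "n_core": n_core,
                     "n_foreign": n_foreign, "foreign_pct": pct,
                     "foreign_pct_display": round_half_away(pct, 1)})
    return pd.DataFrame(rows)


def prevalence_summary(table: pd.DataFrame, feature: str) -> pd.DataFrame:
    """Per-subspecies prevalence (%) of a boolean feature column."""
    if feature not in table.columns:
        raise StatsInputError(f"no column {feature!r}")
    rows = []
    for s, grp in table.groupby("subspecies", sort=True):
        n = len(grp)
        if n == 0:
            rows.append({"subspecies": s, "n": 0, "n_with": 0,
                         "prevalence_pct": float("nan"),
                         "prevalence_display": float("nan")})
            continue
        n_with = int(grp[feature].astype(bool).sum())
        pct = 100.0 * n_with / n
        display = (round_half_away(pct, 1) if pct != round(pct)
                   else float(round(pct)))
        rows.append({"subspecies": s, "n": n, "n_with": n_with,
                     "prevalence_pct": pct, "prevalence_display": display})
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int


def anova_one_way(values, groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA from sums of squares."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise StatsInputError("values and groups must have equal length")
    levels = np.unique(groups)
    if len(levels) < 2:
        raise StatsInputError("ANOVA requires >= 2 groups")
    split = [values[groups == g] for g in levels]
    if any(len(v) < 2 for v in split):
        raise StatsInputError("each group needs >= 2 values")
    grand = values.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in split)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in split)
    dfb = len(levels) - 1
    dfw = len(values) - len(levels)
    if ssw == 0:
        f = 0.0 if ssb == 0 else float("inf")
    else:
        f = (ssb / dfb) / (ssw / dfw)
    p = 1.0 if f == 0 else float(sps.f.sf(f, dfb, dfw))
    return AnovaResult(f_statistic=float(f), p_value=p,
                       df_between=dfb, df_within=dfw)


@dataclass
class CorrelationResult:
    r: float
    t_statistic: float
    p_value: float
    n: int
    degenerate: bool = False


def pearson_correlation_test(x, y) -> CorrelationResult:
    """Pearson r with the two-sided t-test of the correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatsInputError("need n >= 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise StatsInputError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(r=float("nan"), t_statistic=float("nan"),
                                 p_value=float("nan"), n=x.size,
                                 degenerate=True)
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    if abs(r) >= 1.0 - 1e-12:
        r = math.copysign(1.0, r)
        # perfect correlation: t diverges, p -> 0; flagged boundary case
        return CorrelationResult(r=r, t_statistic=math.copysign(math.inf, r),
                                 p_value=0.0, n=n, degenerate=True)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, t_statistic=t, p_value=p, n=n)


def welch_group_ttest(values, groups, group_a, group_b):
    """Welch two-sample t-test between two subspecies groups.

    Provided as the group-comparison alternative reading of the
    defense-vs-HGT test; the primary reading is the correlation t-test.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    a = values[groups == group_a]
    b = values[groups == group_b]
    if len(a) < 2 or len(b) < 2:
        raise StatsInputError("each group needs >= 2 values")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
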