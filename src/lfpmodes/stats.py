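"""Diurnal statistics: per-period summaries, ANOVAs and Tukey post hocs.

The unit of analysis is the recording period: each electrode (or electrode
pair, for coherence) contributes one averaged value per measure and
condition.  Time-of-day effects at baseline are tested with a one-way ANOVA
over zeitgeber time with units as observations; drug-by-time effects with a
mixed two-way ANOVA (ZT between units, pre/post within units).  Post-hoc
pairwise comparisons use Tukey's HSD.  Significance is two-sided at
α = 0.05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "AnovaResult",
    "TwoWayResult",
    "build_summary",
    "summarize_session",
    "oneway_anova_zt",
    "twoway_rm_anova",
    "tukey_hsd",
]

SUMMARY_COLUMNS = ["animal", "zt", "condition", "unit", "measure", "value"]
VALID_ZT = (1, 7, 13, 19)


@dataclass
class AnovaResult:
    """One tested effect: F statistic, degrees of freedom, p value, and the
    Tukey-adjusted pairwise comparisons of its levels."""

    effect: str
    df_num: int
    df_den: int
    F: float
    p: float
    posthoc: list[tuple[str, str, float]] = field(default_factory=list)


@dataclass
class TwoWayResult:
    """Mixed two-way ANOVA output: the three effects plus Tukey comparisons
    of the ZT × condition cell means."""

    zt: AnovaResult
    condition: AnovaResult
    interaction: AnovaResult
    cell_tukey: pd.DataFrame


# ---------------------------------------------------------------------------
# summary assembly
# ---------------------------------------------------------------------------

def build_summary(*tables: pd.DataFrame, require_balanced: bool = True) -> pd.DataFrame:
    """Concatenate tidy per-period tables into one SessionSummary.

    Each input must carry at least the columns
    ``animal, zt, condition, unit, measure, value`` (extra columns such as
    ``region``, ``relation`` or ``band`` are preserved).  Validates the ZT
    vocabulary, rejects duplicate (animal, zt, condition, unit, measure,
    band) rows, and — when ``require_balanced`` — requires every unit to
    appear in both conditions, naming the offending animals otherwise.
    """
    if not tables:
        raise ValueError("no tables given")
    frames = []
    for t in tables:
        missing = [c for c in SUMMARY_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"table missing columns: {missing}")
        frames.append(t)
    df = pd.concat(frames, ignore_index=True, sort=False)

    bad_zt = set(df["zt"].unique()) - set(VALID_ZT)
    if bad_zt:
        raise ValueError(f"invalid zt values: {sorted(bad_zt)}")

    key_cols = ["animal", "zt", "condition", "unit", "measure"]
    if "band" in df.columns:
        key_cols.append("band")
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        raise ValueError(
            f"duplicate summary rows:\n{df.loc[dup, key_cols].to_string(index=False)}"
        )

    if require_balanced and df["condition"].nunique() > 1:
        conds = set(df["condition"].unique())
        per_unit = df.groupby(["animal", "unit"])["condition"].agg(lambda s: set(s))
        incomplete = per_unit[per_unit.apply(lambda s: s != conds)]
        if len(incomplete):
            animals = sorted({a for a, _ in incomplete.index})
            raise ValueError(f"missing condition data for animals: {animals}")
    return df


def summarize_session(
    session,
    config=None,
    thresholds=None,
    spindle_params=None,
    include_spindles: bool = True,
    include_coherence: bool = True,
) -> pd.DataFrame:
    """Run the full per-period analysis on one session → tidy summary rows.

    Produces ``band_percent`` (period-mean percent per channel and band),
    ``pct_slow``/``pct_theta`` from the dominance classifier, pooled-band
    ``coherence`` per channel pair, and raw/normalized spindle rates per
    channel.
    """
    from .modes import classify_session
    from .preprocess import AnalysisConfig
    from .spectral import session_band_power, session_coherence
    from .spindles import SpindleParams, detect_spindles, normalized_spindle_rate, spindle_rate

    config = config or AnalysisConfig()
    rows = []
    base = {"animal": session.animal, "zt": session.zt, "condition": session.condition}

    bp = session_band_power(session, config)
    for (channel, band), grp in bp.groupby(["channel", "band"]):
        rows.append(
            base | {
                "unit": channel,
                "measure": "band_percent",
                "band": band,
                "value": grp["percent"].mean(),
            }
        )

    classifications = classify_session(session, config, thresholds)
    for channel, cls in classifications.items():
        rows.append(base | {"unit": channel, "measure": "pct_slow", "band": "", "value": cls.pct_slow})
        rows.append(base | {"unit": channel, "measure": "pct_theta", "band": "", "value": cls.pct_theta})

    if include_coherence:
        coh = session_coherence(session, config)
        for (pair, relation, band), grp in coh.groupby(["pair", "relation", "band"]):
            rows.append(
                base | {
                    "unit": pair,
                    "measure": "coherence",
                    "relation": relation,
                    "band": band,
                    "value": grp["value"].mean(),
                }
            )

    if include_spindles:
        params = spindle_params or SpindleParams()
        for ch in session.channels:
            events = detect_spindles(ch.data, session.fs, params, channel=ch.name)
            rate = spindle_rate(events, session.duration)
            rows.append(base | {"unit": ch.name, "measure": "spindle_rate", "band": "", "value": rate})
            pct_slow = classifications[ch.name].pct_slow
            if pct_slow > 0:
                rows.append(
                    base | {
                        "unit": ch.name,
                        "measure": "normalized_rate",
                        "band": "",
                        "value": normalized_spindle_rate(rate, pct_slow),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVAs
# ---------------------------------------------------------------------------

def _filter_measure(summary: pd.DataFrame, measure: str, band: str | None) -> pd.DataFrame:
    df = summary[summary["measure"] == measure]
    if band is not None:
        df = df[df["band"] == band]
    if df.empty:
        raise ValueError(f"no rows for measure {measure!r}" + (f", band {band!r}" if band else ""))
    return df


def _oneway_f(groups: Sequence[np.ndarray]) -> tuple[float, int, int, float]:
    """Explicit between/within sums-of-squares one-way ANOVA."""
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    N = int(ns.sum())
    grand = np.concatenate(groups).mean()
    ss_between = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, groups)))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_num, df_den = k - 1, N - k
    if ss_within == 0:
        F = 0.0 if ss_between == 0 else np.inf
    else:
        F = (ss_between / df_num) / (ss_within / df_den)
    p = float(spstats.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
    return F, df_num, df_den, p


def oneway_anova_zt(
    summary: pd.DataFrame,
    measure: str,
    band: str | None = None,
    baseline_only: bool = True,
) -> AnovaResult:
    """One-way ANOVA of a measure over zeitgeber time at baseline.

    Units (electrodes or pairs) are the observations, grouped by ZT.  Every
    sampled ZT cell must be non-empty with at least two units.  Tukey HSD
    pairwise ZT comparisons are appended.
    """
    df = _filter_measure(summary, measure, band)
    if baseline_only:
        df = df[df["condition"] == "pre"]
        if df.empty:
            raise ValueError("no baseline ('pre') rows")
    levels = sorted(df["zt"].unique())
    if len(levels) < 2:
        raise ValueError("need at least two ZT levels")
    groups = []
    for zt in levels:
        vals = df.loc[df["zt"] == zt, "value"].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"ZT{zt} has fewer than 2 observations")
        groups.append(vals)
    F, df_num, df_den, p = _oneway_f(groups)
    posthoc = tukey_hsd({f"ZT{zt}": g for zt, g in zip(levels, groups)})
    return AnovaResult(
        effect="zt",
        df_num=df_num,
        df_den=df_den,
        F=F,
        p=p,
        posthoc=[tuple(r) for r in posthoc[["group_i", "group_j", "p_adj"]].itertuples(index=False)],
    )


def twoway_rm_anova(summary: pd.DataFrame, measure: str, band: str | None = None) -> TwoWayResult:
    """Mixed two-way ANOVA: ZT between units, condition (pre/post) within.

    Every unit must have exactly one value per condition.  Reports the two
    main effects and the interaction, plus Tukey HSD on the eight
    ZT × condition cell means.
    """
    import pingouin as pg

    df = _filter_measure(summary, measure, band).copy()
    df["unit_id"] = df["animal"].astype(str) + "/" + df["unit"].astype(str)
    counts = df.groupby(["unit_id", "condition"]).size().unstack(fill_value=0)
    if set(counts.columns) != {"pre", "post"} or not (counts == 1).all().all():
        raise ValueError("unbalanced design: every unit needs exactly one pre and one post value")

    aov = pg.mixed_anova(
        data=df, dv="value", within="condition", subject="unit_id", between="zt"
    )

    def _extract(source: str, name: str) -> AnovaResult:
        row = aov[aov["Source"] == source].iloc[0]
        F = row["F"]
        p = row["p_unc"] if "p_unc" in row.index else row["p-unc"]
        # a literally zero effect (e.g. identical pre/post values) yields 0/0
        if not np.isfinite(F):
            F, p = 0.0, 1.0
        return AnovaResult(
            effect=name,
            df_num=int(row["DF1"]),
            df_den=int(row["DF2"]),
            F=float(F),
            p=float(p),
        )

    cells = {
        f"ZT{zt}:{cond}": grp["value"].to_numpy(dtype=float)
        for (zt, cond), grp in df.groupby(["zt", "condition"])
    }
    cell_tukey = tukey_hsd(cells) if all(len(v) >= 2 for v in cells.values()) else pd.DataFrame()

    return TwoWayResult(
        zt=_extract("zt", "zt"),
        condition=_extract("condition", "condition"),
        interaction=_extract("Interaction", "zt:condition"),
        cell_tukey=cell_tukey,
    )


def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Tukey HSD over labelled groups → tidy pairwise table.

    Columns: group_i, group_j, diff, p_adj; p_adj is based on the
    studentized-range distribution and symmetric in pair order.
    """
    labels = list(groups.keys())
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for lab, s in zip(labels, samples):
        if len(s) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 values")
    res = spstats.tukey_hsd(*samples)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {
                    "group_i": labels[i],
                    "group_j": labels[j],
                    "diff": float(samples[i].mean() - samples[j].mean()),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)
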