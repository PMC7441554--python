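"""Stall scores and kinetics of polymerase stall resolution.

The stall score sigma(t) of a library entry is the fraction of its
library-size-normalized reads (CPM) found in the stalled product at
time t:

    sigma(t) = stalled_CPM(t) / (stalled_CPM(t) + extended_CPM(t))

so sigma = 1 means an entry seen only in the stalled fraction. Entries
absent from a fraction receive a substitute raw count of one before
normalization, keeping sigma defined and strictly inside (0, 1).

The change of sigma over the time course follows an exponential
growth/decay model sigma(t) = sigma0 * exp(lam * t), reflecting
association/dissociation kinetics of a single polymerase at a template;
lam > 0 marks persistent stalling (G-quadruplex-like), lam < 0 marks
transient, resolving stalling (hairpin-like). The fit is log-linear
least squares, which is exact for the model and needs no
initialization.

Significance of stalling is assessed per time point with a one-sided
Mann-Whitney U test of an entry's replicate scores against the pooled
random-GC negative controls, and combined across time points with
Fisher's method into a single Q value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class NormalizationError(ValueError):
    pass


def cpm_normalize(
    counts: pd.DataFrame, all_entries: list[str] | None = None
) -> pd.DataFrame:
    """Counts-per-million normalization per (fraction, time, replicate).

    Input is long-format with columns entry_id/time_min/replicate/
    stalled_reads/extended_reads. Entries listed in *all_entries* but
    absent (zero reads) in a library get a substitute raw count of 1 so
    their CPM, and hence sigma, stays defined.
    """
    df = counts.copy()
    if all_entries is not None:
        full = pd.MultiIndex.from_product(
            [all_entries, sorted(df["time_min"].unique()), sorted(df["replicate"].unique())],
            names=["entry_id", "time_min", "replicate"],
        )
        df = (
            df.set_index(["entry_id", "time_min", "replicate"])
            .reindex(full, fill_value=0)
            .reset_index()
        )
    for col in ("stalled_reads", "extended_reads"):
        df[col] = df[col].where(df[col] > 0, 1)
        totals = df.groupby(["time_min", "replicate"])[col].transform("sum")
        if (totals == 0).any():
            raise NormalizationError("library with zero total reads")
        df[col.replace("_reads", "_cpm")] = df[col] * 1e6 / totals
    return df


def stall_score(stalled_cpm: float, extended_cpm: float) -> float:
    """sigma = stalled / (stalled + extended), both in CPM."""
    total = stalled_cpm + extended_cpm
    if stalled_cpm < 0 or extended_cpm < 0 or total == 0:
        raise ValueError("stall score undefined for non-positive CPM totals")
    return stalled_cpm / total


def score_table(cpm: pd.DataFrame) -> pd.DataFrame:
    """Per (entry, time, replicate) sigma from a CPM-normalized table."""
    out = cpm.copy()
    out["sigma"] = out["stalled_cpm"] / (out["stalled_cpm"] + out["extended_cpm"])
    return out[["entry_id", "time_min", "replicate", "sigma"]]


def aggregate_replicates(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-entry per-time mean/sd of sigma plus a 95th-percentile outlier flag.

    An entry is flagged as an outlier when its mean replicate sd across
    time points exceeds the 95th percentile of that statistic over all
    entries; flagged entries are excluded downstream.
    """
    n_reps = scores["replicate"].nunique()
    agg = (
        scores.groupby(["entry_id", "time_min"])["sigma"]
        .agg(sigma_mean="mean", sigma_sd=lambda x: x.std(ddof=1))
        .reset_index()
    )
    if n_reps < 2:
        agg["sigma_sd"] = np.nan
        agg["outlier"] = False
        return agg
    per_entry_sd = agg.groupby("entry_id")["sigma_sd"].mean()
    cutoff = per_entry_sd.quantile(0.95)
    flagged = set(per_entry_sd.index[per_entry_sd > cutoff])
    agg["outlier"] = agg["entry_id"].isin(flagged)
    return agg


def fit_kinetics(
    sigma_by_time: np.ndarray | list[float], times: np.ndarray | list[float]
) -> tuple[float, float, float]:
    """Log-linear least-squares fit of sigma(t) = sigma0 * exp(lam * t).

    Returns (sigma0, lam, R^2 of the fit in log space, clipped to [0,1]).
    """
    sigma = np.asarray(sigma_by_time, dtype=float)
    t = np.asarray(times, dtype=float)
    mask = np.isfinite(sigma) & (sigma > 0)
    if mask.sum() < 3:
        raise ValueError("need at least 3 positive sigma values to fit kinetics")
    res = stats.linregress(t[mask], np.log(sigma[mask]))
    r2 = float(np.clip(res.rvalue**2, 0.0, 1.0))
    return float(np.exp(res.intercept)), float(res.slope), r2


def significance_vs_controls(
    entry_sigmas: dict[float, np.ndarray],
    control_sigmas: dict[float, np.ndarray],
) -> tuple[dict[float, float], float]:
    """Per-time Mann-Whitney P (one-sided, greater) and Fisher-combined Q.

    Control sigmas are pooled across control entries and replicates per
    time point. Q is the survival of chi2 with 2k degrees of freedom at
    -2 * sum(ln P_i).
    """
    if not control_sigmas or any(len(v) == 0 for v in control_sigmas.values()):
        raise ValueError("control sigma set is empty")
    p_by_time: dict[float, float] = {}
    for t, values in entry_sigmas.items():
        p = stats.mannwhitneyu(
            values, control_sigmas[t], alternative="greater"
        ).pvalue
        p_by_time[t] = float(p)
    q = fisher_combine(list(p_by_time.values()))
    return p_by_time, q


def fisher_combine(p_values: list[float]) -> float:
    """Fisher's method: chi2 = -2 sum(ln P_i), df = 2k."""
    p = np.clip(np.asarray(p_values, dtype=float), 1e-300, 1.0)
    chi2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(chi2, df=2 * len(p)))


@dataclass
class StallProfile:
    entry_id: str
    sigma_by_time: dict[float, np.ndarray]
    sigma_mean: dict[float, float]
    sigma_sd: dict[float, float]
    sigma0_fit: float
    lam_fit: float
    r2: float
    p_by_time: dict[float, float]
    q_combined: float
    outlier: bool


def build_stall_profiles(
    counts: pd.DataFrame,
    control_entries: list[str],
    all_entries: list[str] | None = None,
) -> dict[str, StallProfile]:
    """Full scoring stage: CPM, sigma, replicate aggregation, kinetic fit
    and significance against the negative controls, per entry."""
    cpm = cpm_normalize(counts, all_entries)
    scores = score_table(cpm)
    agg = aggregate_replicates(scores)
    times = sorted(scores["time_min"].unique())

    control_mask = scores["entry_id"].isin(set(control_entries))
    control_pool = {
        t: scores.loc[control_mask & (scores["time_min"] == t), "sigma"].to_numpy()
        for t in times
    }

    by_entry_rep = {
        (e, t): g["sigma"].to_numpy()
        for (e, t), g in scores.groupby(["entry_id", "time_min"])
    }
    agg_idx = agg.set_index(["entry_id", "time_min"])
    outliers = set(agg.loc[agg["outlier"], "entry_id"])

    profiles: dict[str, StallProfile] = {}
    for entry_id in scores["entry_id"].unique():
        sbt = {t: by_entry_rep[(entry_id, t)] for t in times}
        means = {t: float(agg_idx.loc[(entry_id, t), "sigma_mean"]) for t in times}
        sds = {t: float(agg_idx.loc[(entry_id, t), "sigma_sd"]) for t in times}
        try:
            sigma0, lam, r2 = fit_kinetics([means[t] for t in times], times)
        except ValueError:
            sigma0, lam, r2 = np.nan, np.nan, np.nan
        p_by_time, q = significance_vs_controls(sbt, control_pool)
        profiles[entry_id] = StallProfile(
            entry_id=entry_id,
            sigma_by_time=sbt,
            sigma_mean=means,
            sigma_sd=sds,
            sigma0_fit=sigma0,
            lam_fit=lam,
            r2=r2,
            p_by_time=p_by_time,
            q_combined=q,
            outlier=entry_id in outliers,
        )
    return profiles


def profiles_dataframe(profiles: dict[str, StallProfile]) -> pd.DataFrame:
    """Flat per-entry table (sigma per time point, kinetics, Q)."""
    rows = []
    for p in profiles.values():
        row = {"entry_id": p.entry_id}
        for t, m in p.sigma_mean.items():
            row[f"sigma_{t}"] = m
        row.update(
            sigma0=p.sigma0_fit,
            lam=p.lam_fit,
            r2=p.r2,
            q=p.q_combined,
            outlier=p.outlier,
        )
        rows.append(row)
    return pd.DataFrame(rows)
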