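"""Univariate statistics on log-transformed metabolite concentrations.

Covers the study's univariate layer: one-way ANOVA across intervention
groups, signed paired fold changes between time points with
Benjamini-Hochberg q-values, Pearson correlations of baseline variables
(including the TSP linewidth) with the physiological endpoints, and
survivor vs non-survivor comparisons.

Fold-change sign convention: the geometric-mean ratio ``exp(mean log
difference)`` is reported as-is when >= 1 and as its negative reciprocal
when < 1, so an FC of -2 means a halving.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ratio_to_signed_fc
from .conctable import ConcentrationTable

__all__ = [
    "log_transform",
    "group_anova",
    "pairwise_group_ttests",
    "paired_fold_change",
    "endpoint_correlation",
    "survival_comparison",
    "back_transformed_summary",
]


def log_transform(table: ConcentrationTable | pd.DataFrame):
    """Natural log of a concentration table.

    Zeros are replaced by half the smallest positive value of that
    metabolite before the log (replacements recorded per column);
    all-zero columns are dropped with a warning.  Returns
    ``(log_frame, replacements)``.
    """
    values = table.values if isinstance(table, ConcentrationTable) else table
    if (values.to_numpy(dtype=float) < 0).any():
        raise ValueError("concentrations must be non-negative")
    out = {}
    replacements: dict[str, float] = {}
    for col in values.columns:
        v = values[col].to_numpy(dtype=float).copy()
        pos = v[v > 0]
        if pos.size == 0:
            warnings.warn(f"dropping all-zero column {col!r}")
            continue
        if (v == 0).any():
            repl = 0.5 * pos.min()
            v[v == 0] = repl
            replacements[col] = float(repl)
        out[col] = np.log(v)
    return pd.DataFrame(out, index=values.index), replacements


def back_transformed_summary(logconc: pd.DataFrame) -> pd.DataFrame:
    """Back-transformed median and IQR per metabolite (exp of log-scale
    quantiles), the form in which concentrations are reported."""
    q = logconc.quantile([0.25, 0.5, 0.75])
    return pd.DataFrame({
        "median": np.exp(q.loc[0.5]),
        "q1": np.exp(q.loc[0.25]),
        "q3": np.exp(q.loc[0.75]),
    })


def group_anova(logconc: pd.DataFrame, groups) -> pd.DataFrame:
    """One-way ANOVA per metabolite across intervention groups."""
    groups = pd.Series(np.asarray(groups), index=logconc.index)
    labels = [g for g in groups.unique()
              if (groups == g).sum() >= 2]
    skipped = [g for g in groups.unique() if g not in labels]
    if skipped:
        warnings.warn(f"excluding group(s) with < 2 samples: {skipped}")
    if len(labels) < 2:
        raise ValueError("need at least two groups with >= 2 samples")
    rows = {}
    for col in logconc.columns:
        arrays = [logconc.loc[groups == g, col].dropna().to_numpy()
                  for g in labels]
        f, p = stats.f_oneway(*arrays)
        rows[col] = {"F": float(f), "p": float(p)}
    return pd.DataFrame(rows).T


def pairwise_group_ttests(logconc: pd.DataFrame, groups) -> pd.DataFrame:
    """Welch t-tests for every pair of groups, per metabolite."""
    groups = pd.Series(np.asarray(groups), index=logconc.index)
    labels = list(groups.unique())
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            for col in logconc.columns:
                va = logconc.loc[groups == a, col].dropna()
                vb = logconc.loc[groups == b, col].dropna()
                if len(va) < 2 or len(vb) < 2:
                    continue
                t, p = stats.ttest_ind(va, vb, equal_var=False)
                rows.append({"group_a": a, "group_b": b, "metabolite": col,
                             "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


def paired_fold_change(
    logconc_a: pd.DataFrame,
    logconc_b: pd.DataFrame,
    pairing_a,
    pairing_b,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Signed fold changes from paired within-animal log differences.

    For each metabolite present in both frames: pair samples on animal id,
    compute ``d = mean(log b - log a)``, report ``FC = exp(d)`` if >= 1
    else ``-exp(-d)``, a paired t-test p-value, and Benjamini-Hochberg
    q-values across the metabolites of the table.  Metabolites with fewer
    than ``min_pairs`` complete pairs are skipped with a warning.
    """
    a = logconc_a.copy()
    b = logconc_b.copy()
    a.index = pd.Index(np.asarray(pairing_a), name="animal_id")
    b.index = pd.Index(np.asarray(pairing_b), name="animal_id")
    common = a.index.intersection(b.index)
    rows = {}
    for col in [c for c in a.columns if c in b.columns]:
        da = a.loc[common, col]
        db = b.loc[common, col]
        ok = da.notna() & db.notna()
        n = int(ok.sum())
        if n < min_pairs:
            warnings.warn(f"skipping {col!r}: only {n} complete pairs")
            continue
        d = (db[ok] - da[ok]).to_numpy()
        ratio = float(np.exp(d.mean()))
        if np.allclose(d, 0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(db[ok], da[ok])
        rows[col] = {"fc": ratio_to_signed_fc(ratio), "ratio": ratio,
                     "t": float(t), "p": float(p), "n_pairs": n}
    result = pd.DataFrame(rows).T
    if len(result):
        result["q"] = multipletests(result["p"].to_numpy(), method="fdr_bh")[1]
        result["n_pairs"] = result["n_pairs"].astype(int)
    return result


def endpoint_correlation(
    variables: pd.DataFrame, endpoint, min_cases: int = 5
) -> pd.DataFrame:
    """Pearson r (and two-sided p) of each variable with an endpoint.

    ``variables`` typically holds log concentrations plus QC columns such
    as the TSP FWHM.  Zero-variance variables are reported with missing r.
    """
    endpoint = pd.Series(np.asarray(endpoint, dtype=float),
                         index=variables.index)
    rows = {}
    for col in variables.columns:
        v = variables[col].astype(float)
        ok = v.notna() & endpoint.notna()
        n = int(ok.sum())
        if n < min_cases:
            raise ValueError(
                f"{col!r}: only {n} complete cases (need >= {min_cases})")
        if v[ok].std(ddof=0) == 0 or endpoint[ok].std(ddof=0) == 0:
            rows[col] = {"r": np.nan, "p": np.nan, "n": n}
            continue
        r, p = stats.pearsonr(v[ok], endpoint[ok])
        rows[col] = {"r": float(r), "p": float(p), "n": n}
    out = pd.DataFrame(rows).T
    out["n"] = out["n"].astype(int)
    return out


def survival_comparison(logconc: pd.DataFrame, survived) -> pd.DataFrame:
    """Welch unpaired t-tests of baseline values, survivors vs
    non-survivors.  Returns an empty frame (with a warning) when either
    outcome group has fewer than 2 animals."""
    survived = pd.Series(np.asarray(survived, dtype=bool), index=logconc.index)
    g1 = logconc[survived]
    g0 = logconc[~survived]
    if len(g1) < 2 or len(g0) < 2:
        warnings.warn(
            f"survivor comparison skipped: {len(g1)} survivors vs "
            f"{len(g0)} non-survivors")
        return pd.DataFrame(columns=["t", "p"])
    rows = {}
    for col in logconc.columns:
        t, p = stats.ttest_ind(g1[col].dropna(), g0[col].dropna(),
                               equal_var=False)
        rows[col] = {"t": float(t), "p": float(p)}
    return pd.DataFrame(rows).T
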