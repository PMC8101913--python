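"""Nonparametric longitudinal statistics for the feature table.

The study design is a complete repeated-measures block: every subject is
measured at each follow-up time (T0, T1, T2) on both specimen sides. The
analysis layer mirrors that design:

* descriptives (mean, SD, median, IQR) per variable / side / time,
* Friedman's rank test across the follow-up times,
* pairwise Wilcoxon signed-rank tests between times,
* Mann-Whitney U between the upper and lower specimen side at each time.

All tests are rank-based (invariant to strictly monotone transformations of
the data). Friedman and the signed-rank test are implemented here because
the degenerate and tied cases the pipeline produces (all-tied blocks,
mid-rank ties in exact mode) are not covered by the scipy routines;
Mann-Whitney delegates to :func:`scipy.stats.mannwhitneyu`.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError

FEATURE_COLUMNS = ("uniformity", "contrast", "homogeneity", "entropy", "voh")
KEY_COLUMNS = ("subject", "time", "side", "replicate")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    p_value: float
    n: int
    method: str


def descriptives(values) -> dict[str, float]:
    """Mean, sample SD, median and interquartile range of a sample.

    SD uses the n-1 denominator (NaN for a single observation); the IQR is
    Q3 - Q1 with linear-interpolation quantiles.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("descriptives of an empty sample")
    q1, q3 = np.percentile(x, [25, 75])
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else float("nan"),
        "median": float(np.median(x)),
        "iqr": float(q3 - q1),
    }


def _friedman_statistic(rank_sums: np.ndarray, n: int, k: int, denom: float) -> float:
    dev = rank_sums - n * (k + 1) / 2.0
    return float((k - 1) * (dev**2).sum() / denom)


def friedman(blocks, method: str = "chisq") -> TestResult:
    """Friedman rank test over an ``(n_subjects, k_times)`` block matrix.

    Mid-ranks handle ties within a block; the tie-corrected chi-square
    statistic with ``k - 1`` degrees of freedom is the default reference
    distribution. ``method="exact"`` enumerates the permutation null
    (independent within-block permutations) by dynamic programming over
    column rank-sum vectors — feasible for k <= 4 and n <= 30 — and returns
    ``P(T >= T_obs)``. If every block is fully tied the statistic is 0 and
    p = 1.

    Raises
    ------
    ValueError
        On fewer than 2 subjects or 2 times, or incomplete blocks (NaNs).
    """
    x = np.asarray(blocks, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a (subjects >= 2) x (times >= 2) matrix")
    if np.isnan(x).any():
        bad = [(int(r), int(c)) for r, c in np.argwhere(np.isnan(x))]
        raise ValueError(f"incomplete blocks at (subject, time) cells: {bad}")
    n, k = x.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    rank_sums = ranks.sum(axis=0)
    denom = float((ranks**2).sum() - n * k * (k + 1) ** 2 / 4.0)
    if denom <= 0:  # all blocks fully tied: no information
        return TestResult(0.0, 1.0, n, "friedman-degenerate")
    obs = _friedman_statistic(rank_sums, n, k, denom)

    if method == "chisq":
        p = float(stats.chi2.sf(obs, k - 1))
        return TestResult(obs, p, n, "friedman-chisq")
    if method == "exact":
        if k > 4 or n > 30:
            raise ValueError("exact Friedman limited to k <= 4, n <= 30")
        # distribution of the column rank-sum vector under independent
        # within-block permutations, as {vector: count}
        dist: Counter[tuple[float, ...]] = Counter({(0.0,) * k: 1})
        for row in ranks:
            rows = list(itertools.permutations(row))
            new: Counter[tuple[float, ...]] = Counter()
            for vec, cnt in dist.items():
                for perm in rows:
                    key = tuple(v + r for v, r in zip(vec, perm))
                    new[key] += cnt
            dist = new
        total = sum(dist.values())
        hits = sum(
            cnt
            for vec, cnt in dist.items()
            if _friedman_statistic(np.array(vec), n, k, denom) >= obs - 1e-9
        )
        return TestResult(obs, hits / total, n, "friedman-exact")
    raise ValueError(f"unknown method {method!r}")


def wilcoxon_signed_rank(differences, exact_max_n: int = 25) -> TestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zeros are dropped; ties in |difference| get mid-ranks. For
    ``n <= exact_max_n`` the two-sided p-value is exact, computed from the
    full sign-flip distribution of W+ (a convolution over doubled mid-ranks,
    which are integers); above that, a normal approximation with tie-
    corrected variance ``sum(r_i^2) / 4`` is used, without continuity
    correction.

    Raises
    ------
    DegenerateInputError
        If every difference is zero.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        r2 = np.round(2 * ranks).astype(int)  # doubled mid-ranks: integers
        pmf = np.zeros(r2.sum() + 1)
        pmf[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(pmf)
            shifted[r:] = pmf[: pmf.size - r]
            pmf = 0.5 * (pmf + shifted)
        w2 = int(round(2 * w_plus))
        lo = pmf[: w2 + 1].sum()
        hi = pmf[w2:].sum()
        p = min(1.0, 2.0 * min(lo, hi))
        return TestResult(w_plus, float(p), n, "wilcoxon-exact")

    mu = ranks.sum() / 2.0
    sigma = np.sqrt((ranks**2).sum() / 4.0)
    z = (w_plus - mu) / sigma
    return TestResult(w_plus, float(2 * stats.norm.sf(abs(z))), n, "wilcoxon-normal")


def mann_whitney(a, b, exact_max_n: int = 25) -> TestResult:
    """Two-sided Mann-Whitney U test between two independent samples.

    Exact when both samples are small and the pooled data are tie-free;
    otherwise the tie-corrected normal approximation with continuity
    correction. The statistic is U of the first sample.

    Raises
    ------
    ValueError
        If either group is empty.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    use_exact = tie_free and max(a.size, b.size) <= exact_max_n
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if use_exact else "asymptotic"
    )
    return TestResult(
        float(res.statistic),
        float(res.pvalue),
        int(a.size + b.size),
        "mannwhitney-exact" if use_exact else "mannwhitney-normal",
    )


def load_feature_table(path, features: tuple[str, ...] = FEATURE_COLUMNS) -> pd.DataFrame:
    """Read and validate a feature CSV into a StudyTable DataFrame."""
    table = pd.read_csv(path)
    return validate_table(table, features)


def validate_table(table: pd.DataFrame, features: tuple[str, ...] = FEATURE_COLUMNS) -> pd.DataFrame:
    missing = [c for c in (*KEY_COLUMNS, *features) if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    dup = table.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        raise ValueError(
            f"duplicate (subject, time, side, replicate) rows: {table.loc[dup, list(KEY_COLUMNS)].values.tolist()}"
        )
    return table


def _subject_means(table: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Average replicates: one value per (subject, time, side)."""
    return (
        table.groupby(["subject", "time", "side"], sort=False)[variable]
        .mean()
        .reset_index()
    )


def build_report(
    table: pd.DataFrame,
    alpha: float = 0.05,
    times: tuple[str, ...] | None = None,
    features: tuple[str, ...] = FEATURE_COLUMNS,
    friedman_method: str = "chisq",
    replicate_policy: str = "mean",
) -> dict:
    """Full statistical report over a StudyTable.

    Per variable and side: descriptives at each time (replicates kept as
    separate rows), the Friedman test across times, pairwise Wilcoxon
    signed-rank tests between times, and a Mann-Whitney comparison of the
    upper vs lower side at each time. The upper/lower comparison uses an
    unpaired test even though the sides come from the same specimen,
    matching the convention of the clinical analysis it mirrors.

    ``replicate_policy`` controls how a subject's replicate samples enter
    the tests: "mean" (default) averages them so each subject contributes
    one value per time and side; "rows" keeps them as pseudo-replicates.

    Returns a JSON-serializable dict; see :func:`report_tables` for the
    two flat CSV views.
    """
    table = validate_table(table, features)
    if replicate_policy not in ("mean", "rows"):
        raise ValueError('replicate_policy must be "mean" or "rows"')
    if times is None:
        times = tuple(dict.fromkeys(table["time"]))
    sides = tuple(dict.fromkeys(table["side"]))
    if table["subject"].nunique() < 2:
        raise ValueError("Friedman test needs at least 2 subjects")

    report: dict = {"alpha": alpha, "times": list(times), "sides": list(sides), "variables": {}}
    for var in features:
        var_entry: dict = {}
        for side in sides:
            sub = table[table["side"] == side]
            entry: dict = {"descriptives": {}}
            for t in times:
                entry["descriptives"][t] = descriptives(sub.loc[sub["time"] == t, var])

            if replicate_policy == "mean":
                per_subject = _subject_means(sub, var)
            else:
                per_subject = sub.rename(columns={var: var})[["subject", "time", var]]
                per_subject = per_subject.groupby(["subject", "time"], sort=False)[var].mean().reset_index()
            wide = per_subject.pivot(index="subject", columns="time", values=var)
            missing_cells = wide[list(times)].isna()
            if missing_cells.any().any():
                cells = [
                    (s, t)
                    for s in wide.index
                    for t in times
                    if missing_cells.loc[s, t]
                ]
                raise ValueError(f"incomplete blocks for {var}/{side}: {cells}")
            blocks = wide[list(times)].to_numpy()
            fr = friedman(blocks, method=friedman_method)
            entry["friedman"] = fr.__dict__

            entry["pairwise_wilcoxon"] = {}
            for t1, t2 in itertools.combinations(times, 2):
                diffs = blocks[:, list(times).index(t2)] - blocks[:, list(times).index(t1)]
                try:
                    wr = wilcoxon_signed_rank(diffs)
                    entry["pairwise_wilcoxon"][f"{t1}-{t2}"] = wr.__dict__
                except DegenerateInputError:
                    entry["pairwise_wilcoxon"][f"{t1}-{t2}"] = {
                        "statistic": 0.0,
                        "p_value": 1.0,
                        "n": 0,
                        "method": "wilcoxon-degenerate",
                    }
            var_entry[side] = entry

        if len(sides) == 2:
            side_cmp = {}
            for t in times:
                groups = []
                for side in sides:
                    sel = table[(table["side"] == side) & (table["time"] == t)]
                    if replicate_policy == "mean":
                        vals = sel.groupby("subject", sort=False)[var].mean().to_numpy()
                    else:
                        vals = sel[var].to_numpy()
                    groups.append(vals)
                mw = mann_whitney(groups[0], groups[1])
                side_cmp[t] = mw.__dict__
            var_entry["side_comparison"] = side_cmp
        report["variables"][var] = var_entry
    return report


def report_tables(report: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a report into descriptive and pairwise-comparison tables.

    The first table carries, per variable / side / time, the descriptives
    with the Friedman p (across times) and the Mann-Whitney p (between
    sides); the second the pairwise Wilcoxon p-values between times.
    """
    desc_rows, pair_rows = [], []
    for var, var_entry in report["variables"].items():
        side_cmp = var_entry.get("side_comparison", {})
        for side in report["sides"]:
            entry = var_entry[side]
            for t, d in entry["descriptives"].items():
                desc_rows.append(
                    {
                        "variable": var,
                        "side": side,
                        "time": t,
                        **d,
                        "friedman_p": entry["friedman"]["p_value"],
                        "side_comparison_p": side_cmp.get(t, {}).get("p_value"),
                    }
                )
            for pair, w in entry["pairwise_wilcoxon"].items():
                pair_rows.append(
                    {
                        "variable": var,
                        "side": side,
                        "comparison": pair,
                        "statistic": w["statistic"],
                        "p_value": w["p_value"],
                        "method": w["method"],
                    }
                )
    return pd.DataFrame(desc_rows), pd.DataFrame(pair_rows)
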