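"""Inference layer for escape-response comparisons.

The centrepiece is a one-factor distance-based PERMANOVA: species differences
in the multivariate "overall performance" residuals are tested with a
pseudo-F computed from pairwise Euclidean distances and a null built by
permuting species labels. Sums of squares follow the pairwise-distance
identities

    SS_total  = sum_{i<j} d_ij^2 / n
    SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
    pseudo-F  = (SS_between / (k-1)) / (SS_within / (n-k))

and the permutation p-value uses the (+1)/(n_perm+1) convention, counting the
observed statistic among the permutations so p can never be zero.

Univariate comparisons (reaction time, take-off time) use classical one-way
ANOVA with Tukey HSD pairwise tests; unequal group sizes get the
Tukey-Kramer standard error. Pairwise outcomes are condensed into a compact
letter display (groups sharing no letter differ significantly) via the
insert-and-absorb algorithm. A logistic regression links reaction time to
the probability of jumping rather than scrambling.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

__all__ = [
    "PermanovaResult",
    "OnewayResult",
    "TukeyResult",
    "LogisticResult",
    "ModeComparison",
    "permanova",
    "oneway_lm",
    "tukey_hsd",
    "compact_letter_display",
    "logistic_jump",
    "scramble_vs_jump",
    "summarize",
]


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    df_between: int
    df_within: int
    n_permutations: int
    seed: int


def _as_matrix(matrix) -> np.ndarray:
    if hasattr(matrix, "values") and callable(matrix.values):  # PerformanceMatrix
        return matrix.values()
    arr = np.asarray(matrix, dtype=float)
    return arr.reshape(-1, 1) if arr.ndim == 1 else arr


def _ss_within(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    ss = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        # each within-group pair appears twice in the square matrix
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def permanova(
    matrix, groups, n_perm: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-factor PERMANOVA on Euclidean distances with a label-permutation null.

    ``matrix`` is a PerformanceMatrix, DataFrame or array (rows =
    individuals); ``groups`` are the species labels. Every group needs at
    least two members. Deterministic for a fixed seed and row order; the
    p-value is invariant to a joint permutation of rows and labels.
    """
    x = _as_matrix(matrix)
    labels = np.asarray(groups)
    if len(labels) != x.shape[0]:
        raise ValueError("groups length must match the number of rows")
    uniq, codes = np.unique(labels, return_inverse=True)
    k = len(uniq)
    n = len(labels)
    if k < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = uniq[counts < 2].tolist()
        raise ValueError(f"every group needs >= 2 members; too small: {small}")

    d2 = squareform(pdist(x, metric="euclidean")) ** 2
    ss_total = d2.sum() / (2.0 * n)
    df_b, df_w = k - 1, n - k

    def pseudo_f(c: np.ndarray) -> float:
        ss_w = _ss_within(d2, c, k)
        ss_b = ss_total - ss_w
        if ss_w == 0.0:
            # all points coincident within groups: F is 0 when nothing
            # separates the groups either, else infinite separation
            return 0.0 if ss_b <= 1e-12 else np.inf
        return (ss_b / df_b) / (ss_w / df_w)

    f_obs = pseudo_f(codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(codes)) >= f_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        df_between=df_b,
        df_within=df_w,
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Univariate linear models


@dataclass(frozen=True)
class OnewayResult:
    f: float
    p_value: float
    df_between: int
    df_within: int
    group_means: dict


def _split_by_group(values, groups):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    if len(values) != len(labels):
        raise ValueError("values and groups must have equal length")
    uniq = sorted(pd.unique(labels).tolist())
    return values, labels, uniq, [values[labels == g] for g in uniq]


def oneway_lm(values, groups) -> OnewayResult:
    """One-way ANOVA (linear model with a single categorical factor)."""
    values, labels, uniq, samples = _split_by_group(values, groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if len(values) <= len(uniq):
        raise ValueError("need more observations than groups")
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("zero within-group variance in every group; F undefined")
    f, p = sps.f_oneway(*samples)
    return OnewayResult(
        f=float(f),
        p_value=float(p),
        df_between=len(uniq) - 1,
        df_within=len(values) - len(uniq),
        group_means={g: float(s.mean()) for g, s in zip(uniq, samples)},
    )


@dataclass(frozen=True)
class TukeyResult:
    table: pd.DataFrame  # columns: group1, group2, mean_diff, p_adj, reject
    letters: dict
    alpha: float


def tukey_hsd(values, groups, alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD pairwise comparisons with a compact letter display.

    Adjusted p-values come from the studentized-range distribution; with
    unequal group sizes the Tukey-Kramer standard error
    ``sqrt(MSE/2 * (1/n_i + 1/n_j))`` is used.
    """
    values, labels, uniq, samples = _split_by_group(values, groups)
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = len(values)
    df_w = n - k
    if df_w < 1:
        raise ValueError("need more observations than groups")
    sse = sum(((s - s.mean()) ** 2).sum() for s in samples)
    mse = sse / df_w
    if mse == 0.0:
        raise ValueError("zero pooled within-group variance; HSD undefined")
    means = {g: s.mean() for g, s in zip(uniq, samples)}
    sizes = {g: len(s) for g, s in zip(uniq, samples)}
    rows = []
    for g1, g2 in itertools.combinations(uniq, 2):
        diff = means[g2] - means[g1]
        se = np.sqrt(mse / 2.0 * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        q = abs(diff) / se
        p_adj = float(sps.studentized_range.sf(q, k, df_w))
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "mean_diff": float(diff),
                "p_adj": p_adj,
                "reject": p_adj < alpha,
            }
        )
    table = pd.DataFrame(rows)
    sig_pairs = [
        (r["group1"], r["group2"]) for r in rows if r["reject"]
    ]
    letters = compact_letter_display(uniq, means, sig_pairs)
    return TukeyResult(table=table, letters=letters, alpha=alpha)


def compact_letter_display(groups, means, significant_pairs) -> dict:
    """Assign letters so that groups sharing no letter differ significantly.

    Insert-and-absorb: start with one letter covering all groups; for each
    significant pair, split every letter set containing both members, then
    drop sets absorbed by (subset of) another. Letter order follows group
    means (descending, ties broken by label).
    """
    order = sorted(groups, key=lambda g: (-means[g], str(g)))
    rank = {g: i for i, g in enumerate(order)}
    columns: list[set] = [set(groups)]
    for g1, g2 in significant_pairs:
        new_cols = []
        for col in columns:
            if g1 in col and g2 in col:
                new_cols.extend([col - {g1}, col - {g2}])
            else:
                new_cols.append(col)
        # absorb proper subsets (and duplicates)
        columns = [
            c
            for i, c in enumerate(new_cols)
            if c
            and not any(
                c < other or (c == other and i > j)
                for j, other in enumerate(new_cols)
            )
        ]
    columns.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, col in zip(alphabet, columns):
        for g in col:
            out[g] += letter
    return {g: "".join(sorted(s)) for g, s in out.items()}


# ---------------------------------------------------------------------------
# Logistic regression and mode comparison


@dataclass(frozen=True)
class LogisticResult:
    odds_ratio: float
    p_value: float
    slope: float
    intercept: float
    n: int


def logistic_jump(reaction_ms, jumped) -> LogisticResult:
    """Logistic regression of jump probability on reaction time.

    The odds ratio is per millisecond of reaction time. Single-class
    outcomes and complete separation are rejected explicitly rather than
    allowed to diverge.
    """
    x = np.asarray(reaction_ms, dtype=float)
    y = np.asarray(jumped, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("jumped must contain both outcome classes (0 and 1)")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, sm.add_constant(x)).fit(disp=False)
    except (Exception, PerfectSeparationWarning) as exc:
        raise ValueError(
            f"logistic fit failed (separation or non-convergence): {exc}"
        ) from exc
    if not np.all(np.isfinite(fit.bse)):
        raise ValueError("complete or quasi-complete separation: unstable fit")
    slope = float(fit.params[1])
    return LogisticResult(
        odds_ratio=float(np.exp(slope)),
        p_value=float(fit.pvalues[1]),
        slope=slope,
        intercept=float(fit.params[0]),
        n=len(y),
    )


@dataclass(frozen=True)
class ModeComparison:
    f: float
    p_value: float
    df_between: int
    df_within: int
    mean_jump: float
    mean_scramble: float


def scramble_vs_jump(takeoff_ms, mode) -> ModeComparison:
    """Compare take-off times between jump and scramble maneuvers.

    One-way linear model with escape mode as the factor; on two groups the
    F statistic equals the squared pooled-variance t statistic.
    """
    x = np.asarray(takeoff_ms, dtype=float)
    m = np.asarray(mode)
    present = set(np.unique(m))
    if present != {"jump", "scramble"}:
        raise ValueError(f"need both 'jump' and 'scramble' modes, got {present}")
    res = oneway_lm(x, m)
    return ModeComparison(
        f=res.f,
        p_value=res.p_value,
        df_between=res.df_between,
        df_within=res.df_within,
        mean_jump=res.group_means["jump"],
        mean_scramble=res.group_means["scramble"],
    )


# ---------------------------------------------------------------------------
# Group summaries


def summarize(trials: pd.DataFrame, metrics: list[str] | None = None) -> pd.DataFrame:
    """Per-species mean, standard error (SD/sqrt(n)) and n for each metric.

    Operates on non-null values only; a metric with a single observation
    gets a null SE, and an empty cell yields null mean and n = 0. Returns a
    tidy frame with columns species, metric, mean, se, n.
    """
    if metrics is None:
        skip = {
            "species",
            "individual_id",
            "fps",
            "mode",
            "hit_by_cork",
            "premature",
            "offscreen",
            "poor_video",
        }
        metrics = [
            c
            for c in trials.columns
            if c not in skip and pd.api.types.is_numeric_dtype(trials[c])
        ]
    rows = []
    for species, sub in trials.groupby("species", sort=True):
        for metric in metrics:
            vals = pd.to_numeric(sub[metric], errors="coerce").dropna()
            n = len(vals)
            rows.append(
                {
                    "species": species,
                    "metric": metric,
                    "mean": float(vals.mean()) if n else None,
                    "se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else None,
                    "n": n,
                }
            )
    return pd.DataFrame(rows, columns=["species", "metric", "mean", "se", "n"])
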