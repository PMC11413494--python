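"""End-to-end orchestration: I/O, exclusion rules, and the full analysis.

The pipeline mirrors the field study's workflow. Trials arrive as a CSV
(one row per individual, since animals are tested only once), censored
fields are dropped by the study's exclusion rules, jump kinematics are
reconstructed from displacement and airborne time, performance metrics are
size-corrected against body mass, and the inference layer compares species:

* jump frequency per species (how often each species jumps rather than
  scrambles when "attacked");
* a PERMANOVA on the multivariate size-corrected performance residuals;
* one-way linear models with Tukey HSD letters for reaction time and
  take-off time (raw values, both escape modes retained);
* per-species logistic (jump probability vs reaction time) and
  jump-vs-scramble take-off comparisons where both modes are well sampled.

Species in which too few animals jump (here the woodrat and ground
squirrel) are excluded from the performance branch, exactly as small jump
samples force in the field.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import stats as ek_stats
from .allometry import build_performance_matrix, standardize_columns
from .kinematics import JumpObservation, compute_kinematics
from .synthetic_data import TRIAL_COLUMNS

__all__ = [
    "METRIC_COLUMNS",
    "AnalysisConfig",
    "FilterResult",
    "read_trials",
    "write_trials",
    "derive_kinematics",
    "filter_for_reaction",
    "filter_for_performance",
    "jump_frequency",
    "run_full_analysis",
    "write_report",
]

log = logging.getLogger(__name__)

#: Config metric names -> derived trial-table columns.
METRIC_COLUMNS = {
    "takeoff_time": "takeoff_ms",
    "takeoff_angle": "takeoff_angle_deg",
    "jump_height": "jump_height_cm",
    "takeoff_velocity": "takeoff_speed_ms1",
}

_FLAG_COLUMNS = ["hit_by_cork", "premature", "offscreen", "poor_video"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the full analysis.

    ``metrics`` names the size-corrected variables entering the PERMANOVA.
    The default set is take-off time, take-off angle and jump height; the
    alternative velocity-based set (takeoff_velocity, jump_height,
    takeoff_angle) is equally runnable. ``min_jump_rows`` is the smallest
    per-species count of complete jump records admitted to the performance
    branch; ``min_mode_n`` is the per-mode minimum for the within-species
    jump-vs-scramble analyses.
    """

    metrics: tuple = ("takeoff_time", "takeoff_angle", "jump_height")
    n_perm: int = 999
    seed: int = 0
    alpha: float = 0.05
    min_jump_rows: int = 3
    min_mode_n: int = 5

    def __post_init__(self) -> None:
        unknown = [m for m in self.metrics if m not in METRIC_COLUMNS]
        if unknown:
            raise ValueError(
                f"unknown metric(s) {unknown}; choose from {sorted(METRIC_COLUMNS)}"
            )

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# I/O


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Enforces the fixed header, one record per individual, and legal mode
    tokens; malformed rows are reported with their line numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    df = df[TRIAL_COLUMNS]
    if df.empty:
        return df
    bad_mode = df.index[~df["mode"].isin(["jump", "scramble"])].tolist()
    if bad_mode:
        lines = [i + 2 for i in bad_mode]  # +1 header, +1 one-based
        raise ValueError(
            f"invalid mode token(s) on line(s) {lines}: expected 'jump' or 'scramble'"
        )
    dupes = df["individual_id"][df["individual_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(
            f"duplicate individual_id(s) {dupes}: each animal is tested once"
        )
    for col in _FLAG_COLUMNS:
        df[col] = df[col].astype(bool)
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table with the canonical header."""
    trials.to_csv(path, index=False, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# Derived kinematics


def derive_kinematics(trials: pd.DataFrame) -> pd.DataFrame:
    """Add reconstructed jump metrics and overall response time as columns.

    Rows with complete (displacement, airborne time) get takeoff_speed_ms1,
    takeoff_angle_deg and jump_height_cm from the ballistic reconstruction;
    overall_ms is reaction + take-off where both are present.
    """
    out = trials.copy()
    speed = np.full(len(out), np.nan)
    angle = np.full(len(out), np.nan)
    height = np.full(len(out), np.nan)
    have = (
        out["displacement_m"].notna()
        & out["airborne_s"].notna()
        & (out["airborne_s"] > 0)
    )
    for i in np.flatnonzero(have.to_numpy()):
        row = out.iloc[i]
        kin = compute_kinematics(
            JumpObservation(
                horizontal_displacement_m=float(row["displacement_m"]),
                airborne_time_s=float(row["airborne_s"]),
            )
        )
        speed[i] = kin.takeoff_speed
        angle[i] = kin.takeoff_angle_deg
        height[i] = kin.jump_height_m * 100.0  # report in cm
    out["takeoff_speed_ms1"] = speed
    out["takeoff_angle_deg"] = angle
    out["jump_height_cm"] = height
    out["overall_ms"] = out["reaction_ms"] + out["takeoff_ms"]
    return out


# ---------------------------------------------------------------------------
# Exclusion rules


@dataclass(frozen=True)
class FilterResult:
    """A filtered trial table plus per-rule exclusion accounting."""

    table: pd.DataFrame
    excluded: dict = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return sum(self.excluded.values())


def _apply_rules(trials: pd.DataFrame, rules) -> FilterResult:
    keep = trials
    excluded = {}
    for name, predicate in rules:
        drop = predicate(keep)
        excluded[name] = int(drop.sum())
        if excluded[name]:
            log.info("excluding %d trial(s): %s", excluded[name], name)
        keep = keep[~drop]
    return FilterResult(table=keep, excluded=excluded)


def filter_for_reaction(trials: pd.DataFrame) -> FilterResult:
    """Timing-analysis subset: drop hit-by-cork, premature and poor-video trials.

    Both escape modes are retained — jump probability is unrelated to
    reaction time, so scrambles and jumps are pooled.
    """
    return _apply_rules(
        trials,
        [
            ("hit_by_cork", lambda df: df["hit_by_cork"]),
            ("premature_reaction", lambda df: df["premature"]),
            ("poor_video", lambda df: df["poor_video"]),
        ],
    )


def filter_for_performance(trials: pd.DataFrame) -> FilterResult:
    """Jump-performance subset: jumps only, on-screen, usable video, complete
    displacement and airborne time."""
    return _apply_rules(
        trials,
        [
            ("scrambled", lambda df: df["mode"] != "jump"),
            ("offscreen", lambda df: df["offscreen"]),
            ("poor_video", lambda df: df["poor_video"]),
            (
                "incomplete_measurement",
                lambda df: df["displacement_m"].isna() | df["airborne_s"].isna(),
            ),
        ],
    )


def jump_frequency(trials: pd.DataFrame) -> pd.DataFrame:
    """Jumps, trials and integer jump percentage per species.

    Percentages round to the nearest integer with ties away from zero
    (30/48 -> 63%); a species with zero trials gets a null percent.
    """
    rows = []
    for species, sub in trials.groupby("species", sort=True):
        n = len(sub)
        jumps = int((sub["mode"] == "jump").sum())
        pct = int(np.floor(100.0 * jumps / n + 0.5)) if n else None
        rows.append({"species": species, "jumps": jumps, "trials": n, "percent": pct})
    return pd.DataFrame(rows, columns=["species", "jumps", "trials", "percent"])


# ---------------------------------------------------------------------------
# Full analysis


def _tukey_dict(res: ek_stats.TukeyResult) -> dict:
    return {
        "pairs": res.table.to_dict(orient="records"),
        "letters": dict(sorted(res.letters.items())),
        "alpha": res.alpha,
    }


def _timing_branch(subset: pd.DataFrame, column: str, alpha: float) -> dict:
    """One-way species model + Tukey letters for one raw timing variable."""
    data = subset.dropna(subset=[column])
    counts = data.groupby("species").size()
    usable = counts[counts >= 2].index
    data = data[data["species"].isin(usable)]
    if data["species"].nunique() < 2:
        return {"skipped": "fewer than 2 species with usable data"}
    res = ek_stats.oneway_lm(data[column], data["species"])
    tukey = ek_stats.tukey_hsd(data[column], data["species"], alpha=alpha)
    return {
        "n": int(len(data)),
        "anova": {
            "f": res.f,
            "p_value": res.p_value,
            "df_between": res.df_between,
            "df_within": res.df_within,
        },
        "group_means": res.group_means,
        "tukey": _tukey_dict(tukey),
    }


def _performance_branch(derived: pd.DataFrame, config: AnalysisConfig) -> dict:
    perf = filter_for_performance(derived)
    columns = [METRIC_COLUMNS[m] for m in config.metrics]
    complete = perf.table.dropna(subset=["mass_g", *columns])
    perf.excluded["missing_mass_or_metric"] = len(perf.table) - len(complete)
    # log-log size correction needs strictly positive metrics and mass
    positive = (complete[["mass_g", *columns]] > 0).all(axis=1)
    perf.excluded["nonpositive_metric"] = int((~positive).sum())
    complete = complete[positive]
    counts = complete.groupby("species").size()
    included = sorted(counts[counts >= config.min_jump_rows].index)
    excluded = {
        sp: int(n) for sp, n in counts.items() if n < config.min_jump_rows
    }
    section: dict = {
        "exclusions": perf.excluded,
        "included_species": included,
        "excluded_species": excluded,
        "metrics": list(config.metrics),
    }
    if len(included) < 2:
        section["skipped"] = "fewer than 2 species with enough complete jumps"
        return section
    data = complete[complete["species"].isin(included)]
    pm = standardize_columns(build_performance_matrix(data, columns))
    res = ek_stats.permanova(
        pm, data["species"].to_numpy(), n_perm=config.n_perm, seed=config.seed
    )
    section["n_rows"] = int(len(data))
    section["permanova"] = {
        "pseudo_f": res.pseudo_f,
        "p_value": res.p_value,
        "df_between": res.df_between,
        "df_within": res.df_within,
        "n_permutations": res.n_permutations,
    }
    return section


def _mode_branches(reaction_subset: pd.DataFrame, config: AnalysisConfig) -> dict:
    """Within-species jump-vs-scramble analyses for adequately sampled species."""
    out = {}
    for species, sub in reaction_subset.groupby("species", sort=True):
        timing = sub.dropna(subset=["reaction_ms", "takeoff_ms"])
        n_jump = int((timing["mode"] == "jump").sum())
        n_scramble = int((timing["mode"] == "scramble").sum())
        if min(n_jump, n_scramble) < config.min_mode_n:
            continue
        jumped = (timing["mode"] == "jump").astype(int)
        entry: dict = {"n_jump": n_jump, "n_scramble": n_scramble}
        try:
            logi = ek_stats.logistic_jump(timing["reaction_ms"], jumped)
            entry["logistic"] = {
                "odds_ratio": logi.odds_ratio,
                "p_value": logi.p_value,
                "slope": logi.slope,
            }
        except ValueError as exc:
            entry["logistic"] = {"skipped": str(exc)}
        cmp = ek_stats.scramble_vs_jump(timing["takeoff_ms"], timing["mode"])
        entry["takeoff_by_mode"] = {
            "f": cmp.f,
            "p_value": cmp.p_value,
            "df_between": cmp.df_between,
            "df_within": cmp.df_within,
            "mean_jump_ms": cmp.mean_jump,
            "mean_scramble_ms": cmp.mean_scramble,
        }
        out[species] = entry
    return out


def run_full_analysis(trials: pd.DataFrame, config: AnalysisConfig | None = None) -> dict:
    """Run every analysis branch and return a JSON-serializable report.

    Deterministic: the same trials, config and seed give a byte-identical
    serialized report. Sections appear only when their preconditions hold
    (e.g. the PERMANOVA is skipped unless at least two species have enough
    complete jump records).
    """
    config = config or AnalysisConfig()
    derived = derive_kinematics(trials)
    reaction = filter_for_reaction(derived)

    summary = ek_stats.summarize(
        derived,
        metrics=[
            "mass_g",
            "reaction_ms",
            "takeoff_ms",
            "overall_ms",
            "takeoff_speed_ms1",
            "jump_height_cm",
            "takeoff_angle_deg",
        ],
    )
    summary_nested: dict = {}
    for row in summary.to_dict(orient="records"):
        summary_nested.setdefault(row["species"], {})[row["metric"]] = {
            "mean": row["mean"],
            "se": row["se"],
            "n": row["n"],
        }

    report = {
        "jump_frequency": {
            r["species"]: {k: r[k] for k in ("jumps", "trials", "percent")}
            for r in jump_frequency(trials).to_dict(orient="records")
        },
        "summary": summary_nested,
        "performance": _performance_branch(derived, config),
        "reaction_time": {
            "exclusions": reaction.excluded,
            **_timing_branch(reaction.table, "reaction_ms", config.alpha),
        },
        "takeoff_time": {
            "exclusions": reaction.excluded,
            **_timing_branch(reaction.table, "takeoff_ms", config.alpha),
        },
        "mode_analyses": _mode_branches(reaction.table, config),
        "provenance": {
            "n_input_trials": int(len(trials)),
            "seed": config.seed,
            "config": asdict(config),
            "config_hash": config.hash(),
        },
    }
    return report


def report_to_json(report: dict) -> str:
    """Canonical (sorted-key) JSON serialization of a report."""

    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        if isinstance(obj, tuple):
            return list(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    return json.dumps(report, sort_keys=True, indent=2, default=_default)


def write_report(report: dict, path) -> None:
    """Write a report as canonical JSON."""
    with open(path, "w") as fh:
        fh.write(report_to_json(report))
        fh.write("\n")
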