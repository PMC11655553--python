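"""Orchestration: configuration, study simulation, filters, end-to-end analyses.

Ties the pieces together into the two study analyses:

* the *low-mood contrast* — first-session-sham data of the low-mood sample
  against the healthy baseline sample, per-half adjustment measures, mixed
  ANOVAs with Sample/Valence/Time/Block Order factors;
* the *stimulation analyses* — real vs sham within the during-task (or
  before-task) group on the blocks-2-3 window, paired contrasts with the
  real-minus-sham outlier rule, a Wilcoxon robustness check, and the
  one-sided between-group contrast of the two stimulation-timing groups.

Every run is reproducible from its config: all randomness flows from the
master seed, and a manifest records the resolved config plus the subject
counts at every filter step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitSettings, fit_cohort
from .measures import measures_table, rates_table
from .model import COMPARATOR_FAMILY, WINNING_MODEL
from .stats import (
    StatsResult,
    correlation_test,
    iqr_outliers,
    one_sample_t,
    paired_t,
    welch_t,
    wilcoxon_signed_rank,
)
from .anova import rm_anova
from .task import Cohort, CohortSpec, ParamDistribution, simulate_cohort

__all__ = [
    "AnalysisConfig",
    "simulate_study",
    "fit_study",
    "filter_cohort",
    "analyze_tdcs",
    "analyze_low_mood",
    "analyze_during_vs_before",
    "run_analysis",
    "write_table",
    "read_table",
]

log = logging.getLogger(__name__)

ANALYSES = ("low-mood-contrast", "tdcs-during", "tdcs-before", "during-vs-before")
SCHEMA_VERSION = 1


@dataclass(frozen=True)
class AnalysisConfig:
    """Resolved configuration of one reproduction run (YAML round-trippable)."""

    analysis: str = "tdcs-during"
    seed: int = 0
    model: str = WINNING_MODEL.name
    out_dir: str = "results"
    outliers: str = "both"  # with | without | both
    n_during: int = 41
    n_before: int = 44
    n_healthy: int = 40
    # injected ground-truth effects (natural-scale shifts of the volatile-
    # condition learning rate): the low-mood sample adjusts loss rates less
    # and win rates slightly more; real during-task stimulation undoes both.
    sample_shift_win: float = 0.10
    sample_shift_loss: float = -0.10
    stim_shift_win: float = -0.10
    stim_shift_loss: float = 0.10
    n_restarts: int = 3

    def __post_init__(self) -> None:
        if self.analysis not in ANALYSES:
            raise ValueError(f"analysis must be one of {ANALYSES}")
        if self.outliers not in ("with", "without", "both"):
            raise ValueError("outliers must be with/without/both")
        if self.model not in {m.name for m in COMPARATOR_FAMILY}:
            raise ValueError(f"unknown model {self.model!r}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# schema-versioned CSV I/O


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# iblt {kind} v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_table(path, kind: str) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        expected = f"# iblt {kind} v{SCHEMA_VERSION}"
        if header != expected:
            raise ValueError(f"{path}: expected schema header {expected!r}, found {header!r}")
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# study simulation


def simulate_study(config: AnalysisConfig) -> Cohort:
    """Simulate the full three-group study implied by the config.

    Two low-mood groups (stimulation during vs before the task, two sessions
    each, counterbalanced real/sham) plus the healthy baseline sample.  The
    injected effects define the ground truth the analyses should recover.
    """
    rng_seeds = np.random.SeedSequence(config.seed).generate_state(3)
    parts = []
    for group, n, s in (
        ("during-task", config.n_during, rng_seeds[0]),
        ("before-task", config.n_before, rng_seeds[1]),
        ("healthy-baseline", config.n_healthy, rng_seeds[2]),
    ):
        low_mood = group != "healthy-baseline"
        spec = CohortSpec(
            n_subjects=n,
            group=group,
            params=ParamDistribution(),
            sample_shift_win=config.sample_shift_win if low_mood else 0.0,
            sample_shift_loss=config.sample_shift_loss if low_mood else 0.0,
            stim_shift_win=config.stim_shift_win,
            stim_shift_loss=config.stim_shift_loss,
            seed=int(s % 2**31),
        )
        parts.append(simulate_cohort(spec))
    return Cohort(
        trials=pd.concat([p.trials for p in parts], ignore_index=True),
        truth=pd.concat([p.truth for p in parts], ignore_index=True),
        metadata=pd.concat([p.metadata for p in parts], ignore_index=True),
    )


def fit_study(
    trials: pd.DataFrame, model: str = WINNING_MODEL.name, settings: FitSettings | None = None
) -> pd.DataFrame:
    """Fit every subject-session and attach condition/stim labels per block."""
    spec = next(m for m in COMPARATOR_FAMILY if m.name == model)
    settings = settings or FitSettings()
    fits, _ = fit_cohort(trials, spec, settings)
    labels = trials.drop_duplicates(["subject_id", "session", "block_index"])[
        ["subject_id", "session", "block_index", "condition", "stim", "group"]
    ]
    return fits.merge(labels, on=["subject_id", "session", "block_index"], validate="one_to_one")


# ---------------------------------------------------------------------------
# cohort filters


def filter_cohort(metadata: pd.DataFrame, analysis: str) -> pd.DataFrame:
    """Subjects entering each analysis, with n logged before/after.

    The group-contrast analysis keeps only subjects (from either sample) who
    received sham in their first session, to avoid task-repetition confounds;
    the stimulation analyses keep both sessions of the relevant group.
    """
    if "first_session_stim" not in metadata.columns:
        raise ValueError("metadata must carry first_session_stim (session order)")
    n0 = len(metadata)
    if analysis == "low-mood-contrast":
        kept = metadata[metadata["first_session_stim"] == "sham"]
    elif analysis == "tdcs-during":
        kept = metadata[metadata["group"] == "during-task"]
    elif analysis == "tdcs-before":
        kept = metadata[metadata["group"] == "before-task"]
    elif analysis == "during-vs-before":
        kept = metadata[metadata["group"].isin(["during-task", "before-task"])]
    else:
        raise ValueError(f"unknown analysis {analysis!r}")
    if kept.empty:
        raise ValueError(f"no subjects left after the {analysis} filter")
    log.info("filter %s: %d -> %d subjects", analysis, n0, len(kept))
    return kept


# ---------------------------------------------------------------------------
# analyses


def _result_row(name: str, res: StatsResult, variant: str) -> dict:
    return {
        "contrast": name,
        "outlier_handling": variant,
        "test": res.test,
        "statistic": res.statistic,
        "df": res.df,
        "p": res.p,
        "effect_size": res.effect_size,
        "effect_size_type": res.effect_size_type,
        "n": res.n,
        "outliers_removed": res.outliers_removed,
    }


def analyze_tdcs(fits: pd.DataFrame, metadata: pd.DataFrame, group: str) -> dict:
    """Real-vs-sham contrasts on the blocks-2-3 measures for one group."""
    analysis = {"during-task": "tdcs-during", "before-task": "tdcs-before"}[group]
    meta = filter_cohort(metadata, analysis)
    sub = fits[fits["subject_id"].isin(meta["subject_id"])]
    meas = measures_table(sub, "tdcs")
    stim = sub.drop_duplicates(["subject_id", "session"])[["subject_id", "session", "stim"]]
    meas = meas.merge(stim, on=["subject_id", "session"], validate="one_to_one")
    meas = meas.merge(meta[["subject_id", "block_order"]], on="subject_id")

    wide = meas.pivot(index="subject_id", columns="stim", values="bias")
    diffs = (wide["real"] - wide["sham"]).dropna()
    mask = iqr_outliers(diffs.to_numpy(), variant="paired-difference")
    kept_ids = diffs.index[mask.keep]

    rows = []
    variants = {"without": diffs.index, "with": kept_ids}
    for variant, ids in variants.items():
        w = wide.loc[ids]
        removed = len(diffs) - len(ids)
        rows.append(
            _result_row(
                "bias: real vs sham", paired_t(w["real"], w["sham"], removed), variant
            )
        )
        rows.append(
            _result_row("bias vs 0, sham", one_sample_t(w["sham"], 0.0), variant)
        )
        rows.append(
            _result_row("bias vs 0, real", one_sample_t(w["real"], 0.0), variant)
        )
    # robustness check on all data points
    rows.append(
        _result_row(
            "bias: real vs sham", wilcoxon_signed_rank(wide["real"], wide["sham"]), "without"
        )
    )

    anovas = {}
    for variant, ids in variants.items():
        m = meas[meas["subject_id"].isin(ids)]
        anovas[f"bias_{variant}"] = rm_anova(
            m, dv="bias", subject="subject_id", within=["stim"], between=["block_order"]
        )
        long = m.melt(
            id_vars=["subject_id", "stim", "block_order"],
            value_vars=["win_adjustment", "loss_adjustment"],
            var_name="valence",
            value_name="adjustment",
        )
        anovas[f"adjustment_{variant}"] = rm_anova(
            long,
            dv="adjustment",
            subject="subject_id",
            within=["stim", "valence"],
            between=["block_order"],
        )
    # learning rates per se: tDCS Condition x Valence x Volatility x Block Order
    rates = rates_table(sub, "tdcs").merge(stim, on=["subject_id", "session"])
    rates = rates.merge(meta[["subject_id", "block_order"]], on="subject_id")
    anovas["rates"] = rm_anova(
        rates,
        dv="learning_rate",
        subject="subject_id",
        within=["stim", "valence", "volatility"],
        between=["block_order"],
    )
    return {
        "measures": meas,
        "diffs": diffs,
        "outlier_mask": mask,
        "contrasts": pd.DataFrame(rows),
        "anovas": anovas,
    }


def analyze_low_mood(fits: pd.DataFrame, metadata: pd.DataFrame) -> dict:
    """Low-mood vs healthy baseline on first-session-sham per-half measures."""
    meta = filter_cohort(metadata, "low-mood-contrast").copy()
    meta["sample"] = np.where(meta["group"] == "healthy-baseline", "healthy", "low-mood")
    sub = fits[
        fits["subject_id"].isin(meta["subject_id"])
        & (fits["session"] == 1)
        & (fits["stim"] == "sham")
    ]
    meas = measures_table(sub, "low-mood")
    meas = meas.merge(meta[["subject_id", "sample", "block_order", "bdi"]], on="subject_id")

    # subject-level means over halves feed the simple contrasts and the
    # per-factor-level outlier rule
    subj = meas.groupby(["subject_id", "sample", "bdi"], as_index=False)[
        ["win_adjustment", "loss_adjustment", "bias"]
    ].mean()
    mask = iqr_outliers(subj["bias"].to_numpy(), subj["sample"].to_numpy(), "raw-values")
    kept_ids = subj["subject_id"][mask.keep]

    rows = []
    variants = {"without": subj["subject_id"], "with": kept_ids}
    for variant, ids in variants.items():
        s = subj[subj["subject_id"].isin(ids)]
        removed = len(subj) - len(s)
        lo = s[s["sample"] == "low-mood"]
        he = s[s["sample"] == "healthy"]
        rows.append(
            _result_row(
                "bias: low-mood vs healthy",
                welch_t(lo["bias"], he["bias"], outliers_removed=removed),
                variant,
            )
        )
        rows.append(_result_row("bias vs 0, low-mood", one_sample_t(lo["bias"]), variant))
        rows.append(_result_row("bias vs 0, healthy", one_sample_t(he["bias"]), variant))
        rows.append(
            _result_row("BDI ~ bias", correlation_test(s["bdi"], s["bias"]), variant)
        )

    anovas = {}
    for variant, ids in variants.items():
        m = meas[meas["subject_id"].isin(ids)].copy()
        m["half"] = m["half"].astype(str)
        anovas[f"bias_{variant}"] = rm_anova(
            m,
            dv="bias",
            subject="subject_id",
            within=["half"],
            between=["sample", "block_order"],
        )
        long = m.melt(
            id_vars=["subject_id", "half", "sample", "block_order"],
            value_vars=["win_adjustment", "loss_adjustment"],
            var_name="valence",
            value_name="adjustment",
        )
        anovas[f"adjustment_{variant}"] = rm_anova(
            long,
            dv="adjustment",
            subject="subject_id",
            within=["half", "valence"],
            between=["sample", "block_order"],
        )
    # learning rates per se: Sample x Valence x Volatility x Time x Block Order
    # (3-level Volatility; GG-corrected p reported alongside uncorrected)
    rates = rates_table(sub, "low-mood").merge(
        meta[["subject_id", "sample", "block_order"]], on="subject_id"
    )
    rates["half"] = rates["half"].astype(str)
    anovas["rates"] = rm_anova(
        rates,
        dv="learning_rate",
        subject="subject_id",
        within=["valence", "volatility", "half"],
        between=["sample", "block_order"],
    )
    return {
        "measures": meas,
        "subject_means": subj,
        "outlier_mask": mask,
        "contrasts": pd.DataFrame(rows),
        "anovas": anovas,
    }


def analyze_during_vs_before(fits: pd.DataFrame, metadata: pd.DataFrame) -> dict:
    """One-sided between-group contrast of the paired stimulation effects."""
    effects = {}
    for group in ("during-task", "before-task"):
        res = analyze_tdcs(fits, metadata, group)
        effects[group] = res["diffs"]
    contrast = welch_t(
        effects["during-task"].to_numpy(),
        effects["before-task"].to_numpy(),
        alternative="greater",  # during-task effect predicted larger
    )
    return {
        "effects": effects,
        "contrasts": pd.DataFrame([_result_row("tDCS effect: during vs before", contrast, "without")]),
    }


# ---------------------------------------------------------------------------
# driver


def run_analysis(config: AnalysisConfig) -> dict:
    """Simulate, fit, analyse and write the report bundle for one config."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_study(config)
    settings = FitSettings(n_restarts=config.n_restarts, seed=config.seed + 1)
    fits = fit_study(cohort.trials, config.model, settings)

    if config.analysis in ("tdcs-during", "tdcs-before"):
        group = "during-task" if config.analysis == "tdcs-during" else "before-task"
        result = analyze_tdcs(fits, cohort.metadata, group)
    elif config.analysis == "low-mood-contrast":
        result = analyze_low_mood(fits, cohort.metadata)
    else:
        result = analyze_during_vs_before(fits, cohort.metadata)

    config.to_yaml(out / "config.yaml")
    write_table(fits, out / "fitted_parameters.csv", "parameters")
    write_table(cohort.metadata, out / "metadata.csv", "metadata")
    if "measures" in result:
        write_table(result["measures"], out / "measures.csv", "measures")
    write_table(result["contrasts"], out / "contrasts.csv", "results")
    for name, table in result.get("anovas", {}).items():
        write_table(table, out / f"anova_{name}.csv", "results")
    manifest = {
        "config": asdict(config),
        "n_subjects_simulated": int(cohort.metadata["subject_id"].nunique()),
        "n_sessions_fitted": int(fits.drop_duplicates(["subject_id", "session"]).shape[0]),
        "outliers_removed": int(result["outlier_mask"].n_removed) if "outlier_mask" in result else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    report_lines = [f"analysis: {config.analysis}", f"seed: {config.seed}", ""]
    for _, r in result["contrasts"].iterrows():
        report_lines.append(
            f"[{r['outlier_handling']:>7s}] {r['contrast']}: {r['test']} = "
            f"{r['statistic']:.3g} (df={r['df']:.4g}), p={r['p']:.4g}, "
            f"{r['effect_size_type']}={r['effect_size']:.3g}, n={r['n']}"
        )
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")
    return result
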