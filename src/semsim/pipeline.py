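"""Study orchestration: cohort loading, scoring, and the analysis battery.

The pipeline mirrors a two-group longitudinal design: baseline group
comparisons of demographic/clinical/cognitive/linguistic variables
(independent-sample Bayes factors; contingency Bayes factors for categorical
variables), paired baseline-to-follow-up comparisons per group, linear and
standardized change scores, correlational analyses in configurable scopes,
medication-dose correlations, and stratified robustness checks. Every output
row records the test family, prior settings, sample sizes and data scope.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .bayes import (
    BayesError,
    BayesResult,
    bf_anova_oneway,
    bf_contingency,
    bf_correlation,
    bf_ttest_independent,
    bf_ttest_paired,
)
from .cogscores import StroopRecord, dsst_total, golden_interference
from .embeddings import EmbeddingTable, load_embedding_table
from .simcore import SimConfig, aggregate_subject, profile_transcript, profiles_to_frame
from .textprep import annotate, default_stoplist, load_stoplist, parse_transcript_filename, read_chat_transcript, read_plain_transcript, tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "Cohort",
    "SchemaError",
    "load_cohort",
    "build_cohort",
    "baseline_tables",
    "longitudinal_tables",
    "change_scores",
    "correlation_tables",
    "dose_tables",
    "stratified_checks",
    "write_tables",
]

REQUIRED_COLUMNS = [
    "subject_id", "group", "timepoint", "age", "gender",
    "stroop_word", "stroop_colour", "stroop_colour_word",
    "dsst_oral", "dsst_written",
]

LINGUISTIC_VARS = ["NW_mean", "ASW_F_mean", "ASW_10_mean"]

CONTINUOUS_BASELINE_VARS = [
    "age", "SOFAS", "PANSS8_pos", "PANSS8_neg", "PANSS8_total",
    "TLI_total", "TLI_disorganization", "TLI_impoverishment", "TLI_dysregulation",
    "CDS", "CGI_S", "DSST_total", "fluency_count",
    "stroop_total_correct", "stroop_total_time", "stroop_IG",
] + LINGUISTIC_VARS

CATEGORICAL_BASELINE_VARS = [
    "gender", "education_band", "parental_SES_band", "immigrant",
    "first_language_english",
]


class SchemaError(ValueError):
    """Cohort metadata does not match the documented schema."""


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    stoplist_path: Optional[str] = None
    cauchy_width: float = 0.707
    beta_width: float = 1.0
    g_prior_scale: float = 0.5
    concentration: float = 1.0
    variance_rule: str = "pooled"

    def stoplist(self):
        if self.stoplist_path:
            return load_stoplist(self.stoplist_path)
        return default_stoplist()


@dataclass
class Cohort:
    """One row per subject x timepoint, with per-transcript profiles kept."""

    data: pd.DataFrame
    profiles: pd.DataFrame
    config: PipelineConfig
    oov_report: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["subject", "picture", "timepoint", "surface_form"]
        )
    )

    def scope(self, name: str) -> pd.DataFrame:
        """Named analysis scope: 'all', 'HC', 'FES' (baseline rows) or
        'followup_FES' (FES subjects with both timepoints)."""
        base = self.data[self.data.timepoint == "baseline"]
        if name == "all":
            return base
        if name in ("HC", "FES"):
            return base[base.group == name]
        if name == "followup_FES":
            followed = set(self.data.loc[self.data.timepoint == "followup", "subject_id"])
            return base[(base.group == "FES") & base.subject_id.isin(followed)]
        raise ValueError(f"unknown scope {name!r}")


def _compute_cognitive(meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.copy()
    ig, total = [], []
    for _, row in meta.iterrows():
        try:
            rec = StroopRecord(
                word_score=row["stroop_word"],
                colour_score=row["stroop_colour"],
                colour_word_score=row["stroop_colour_word"],
            )
            ig.append(golden_interference(rec))
        except (ValueError, TypeError):
            ig.append(np.nan)
        try:
            total.append(dsst_total(row["dsst_oral"], row["dsst_written"]))
        except (ValueError, TypeError):
            total.append(np.nan)
    meta["stroop_IG"] = ig
    meta["DSST_total"] = total
    return meta


def build_cohort(
    metadata: pd.DataFrame,
    transcripts: Dict[Tuple[str, str, str], str],
    table: EmbeddingTable,
    config: Optional[PipelineConfig] = None,
) -> Cohort:
    """Assemble a cohort from an in-memory metadata frame and transcript texts
    keyed (subject_id, timepoint, picture_id).

    Computes Stroop IG and the DSST total from the raw count columns and
    attaches subject-level linguistic aggregates from the scored transcripts.
    Subjects in ``transcripts`` that are absent from the metadata are an
    error; metadata rows without transcripts get missing linguistic fields
    with a warning.
    """
    config = config or PipelineConfig()
    missing = [c for c in REQUIRED_COLUMNS if c not in metadata.columns]
    if missing:
        raise SchemaError(f"metadata is missing required columns: {missing}")
    known = set(metadata.subject_id.astype(str))
    unknown = sorted({k[0] for k in transcripts} - known)
    if unknown:
        raise SchemaError(f"transcripts reference unknown subjects: {unknown[:5]}")

    stoplist = config.stoplist()
    profile_objs = []
    oov_rows = []
    per_subject: Dict[Tuple[str, str], list] = {}
    for (subject, timepoint, picture), text in sorted(transcripts.items()):
        t = annotate(
            tokenize(text), stoplist, table,
            subject_id=subject, picture_id=picture, timepoint=timepoint,
        )
        for surface in t.oov_report:
            oov_rows.append(
                {"subject": subject, "picture": picture, "timepoint": timepoint,
                 "surface_form": surface}
            )
        prof = profile_transcript(t, table, config.sim)
        profile_objs.append(prof)
        per_subject.setdefault((subject, timepoint), []).append(prof)

    meta = _compute_cognitive(metadata)
    ling_rows = []
    for (subject, timepoint), profs in per_subject.items():
        agg = aggregate_subject(profs)
        ling_rows.append(
            {
                "subject_id": subject, "timepoint": timepoint,
                "NW_mean": agg.NW_mean,
                "ASW_F_mean": np.nan if agg.ASW_F_mean is None else agg.ASW_F_mean,
                "ASW_10_mean": np.nan if agg.ASW_10_mean is None else agg.ASW_10_mean,
                "n_pictures": agg.n_pictures,
            }
        )
    ling = pd.DataFrame(
        ling_rows,
        columns=["subject_id", "timepoint", "NW_mean", "ASW_F_mean", "ASW_10_mean", "n_pictures"],
    )
    data = meta.merge(ling, on=["subject_id", "timepoint"], how="left")
    n_missing = int(data.ASW_F_mean.isna().sum()) if "ASW_F_mean" in data else len(data)
    if n_missing:
        logger.warning("%d subject x timepoint rows lack transcripts", n_missing)
    profiles = profiles_to_frame(
        profile_objs,
        stoplist_id=config.sim.stoplist_id,
        embedding_label=table.source_label,
    )
    oov = pd.DataFrame(oov_rows, columns=["subject", "picture", "timepoint", "surface_form"])
    return Cohort(data=data, profiles=profiles, config=config, oov_report=oov)


def load_cohort(
    metadata_csv: str | Path,
    transcript_dir: str | Path,
    embeddings: EmbeddingTable | str | Path,
    config: Optional[PipelineConfig] = None,
) -> Cohort:
    """File-system entry point: read the metadata CSV and every transcript in
    ``transcript_dir`` (``<subject>_<timepoint>_<picture>.txt`` or ``.cha``)."""
    if not isinstance(embeddings, EmbeddingTable):
        embeddings = load_embedding_table(embeddings)
    meta = pd.read_csv(metadata_csv)
    transcripts: Dict[Tuple[str, str, str], str] = {}
    for path in sorted(Path(transcript_dir).glob("*")):
        if path.suffix not in (".txt", ".cha"):
            continue
        subject, timepoint, picture = parse_transcript_filename(path.name)
        if path.suffix == ".cha":
            text = read_chat_transcript(path)
        else:
            text = read_plain_transcript(path)
        transcripts[(subject, timepoint, picture)] = text
    return build_cohort(meta, transcripts, embeddings, config)


# ---------------------------------------------------------------------------
# Analysis tables
# ---------------------------------------------------------------------------

def _result_row(res: BayesResult, **extra) -> Dict:
    row = {
        "BF10": res.bf10,
        "effect_size": res.effect_size,
        "ci_low": res.ci95[0],
        "ci_high": res.ci95[1],
        "family": res.family,
        "prior": json.dumps(res.prior, sort_keys=True),
        "n": json.dumps(res.n_info, sort_keys=True),
    }
    row.update(extra)
    return row


def baseline_tables(cohort: Cohort) -> pd.DataFrame:
    """Group comparison of every demographic/clinical/cognitive/linguistic
    variable at baseline: means +/- SD per group with the matching Bayes
    factor (independent t for continuous, contingency for categorical).
    Variables recorded in only one group are reported without a test."""
    cfg = cohort.config
    base = cohort.data[cohort.data.timepoint == "baseline"]
    hc = base[base.group == "HC"]
    fes = base[base.group == "FES"]
    if hc.empty or fes.empty:
        raise ValueError("baseline comparison needs both groups present")

    rows = []
    for var in CONTINUOUS_BASELINE_VARS:
        if var not in base.columns:
            continue
        x = hc[var].dropna().to_numpy(dtype=float)
        y = fes[var].dropna().to_numpy(dtype=float)
        if x.size == 0 and y.size == 0:
            logger.warning("variable %s all-missing; row omitted", var)
            continue
        row = {
            "variable": var, "kind": "continuous",
            "HC_mean": np.mean(x) if x.size else np.nan,
            "HC_sd": np.std(x, ddof=1) if x.size > 1 else np.nan,
            "FES_mean": np.mean(y) if y.size else np.nan,
            "FES_sd": np.std(y, ddof=1) if y.size > 1 else np.nan,
            "n_HC": int(x.size), "n_FES": int(y.size),
        }
        if x.size >= 2 and y.size >= 2:
            try:
                res = bf_ttest_independent(
                    x, y, cauchy_width=cfg.cauchy_width, variance_rule=cfg.variance_rule
                )
                row.update(_result_row(res))
            except BayesError as exc:
                logger.warning("t-test failed for %s: %s", var, exc)
        rows.append(row)

    for var in CATEGORICAL_BASELINE_VARS:
        if var not in base.columns:
            continue
        sub = base.dropna(subset=[var])
        counts = pd.crosstab(sub.group, sub[var])
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            logger.warning("categorical %s lacks two levels per margin; omitted", var)
            continue
        res = bf_contingency(counts.to_numpy(), concentration=cfg.concentration)
        rows.append(
            _result_row(
                res, variable=var, kind="categorical",
                n_HC=int(counts.loc["HC"].sum()) if "HC" in counts.index else 0,
                n_FES=int(counts.loc["FES"].sum()) if "FES" in counts.index else 0,
            )
        )
    return pd.DataFrame(rows)


def change_scores(cohort: Cohort, variable: str) -> pd.DataFrame:
    """Per-subject linear (follow-up - baseline) and standardized
    (linear / baseline) change for one variable. A zero baseline makes the
    standardized change missing, with a warning."""
    wide = (
        cohort.data.pivot_table(
            index=["subject_id", "group"], columns="timepoint", values=variable,
            aggfunc="first",
        )
        .reset_index()
    )
    if "followup" not in wide.columns:
        return pd.DataFrame(
            columns=["subject_id", "group", "variable", "linear_change", "standardized_change"]
        )
    wide = wide.dropna(subset=["baseline", "followup"])
    linear = wide["followup"] - wide["baseline"]
    zero_base = wide["baseline"] == 0
    if zero_base.any():
        logger.warning(
            "%d subjects have zero baseline %s; standardized change set missing",
            int(zero_base.sum()), variable,
        )
    standardized = np.where(zero_base, np.nan, linear / wide["baseline"])
    return pd.DataFrame(
        {
            "subject_id": wide["subject_id"],
            "group": wide["group"],
            "variable": variable,
            "linear_change": linear,
            "standardized_change": standardized,
        }
    )


def longitudinal_tables(cohort: Cohort, variables: Sequence[str] = tuple(LINGUISTIC_VARS)) -> pd.DataFrame:
    """Baseline vs follow-up comparison per group (paired Bayes factor on
    subjects observed twice) plus the between-group test on linear change."""
    cfg = cohort.config
    rows = []
    for var in variables:
        changes = change_scores(cohort, var)
        if changes.empty:
            logger.warning("no follow-up data for %s", var)
            continue
        per_group = {}
        for group, sub in changes.groupby("group"):
            d = sub.linear_change.dropna().to_numpy(dtype=float)
            per_group[group] = d
            both = cohort.data[
                (cohort.data.group == group)
                & cohort.data.subject_id.isin(sub.subject_id)
            ]
            b = both[both.timepoint == "baseline"][var].to_numpy(dtype=float)
            f = both[both.timepoint == "followup"][var].to_numpy(dtype=float)
            row = {
                "variable": var, "group": group, "analysis": "paired",
                "baseline_mean": np.nanmean(b), "baseline_sd": np.nanstd(b, ddof=1),
                "followup_mean": np.nanmean(f), "followup_sd": np.nanstd(f, ddof=1),
                "change_mean": np.mean(d), "change_sd": np.std(d, ddof=1),
                "n_pairs": int(d.size),
            }
            if d.size >= 2 and np.std(d, ddof=1) > 0:
                res = bf_ttest_paired(
                    summary=(float(np.mean(d)), float(np.std(d, ddof=1)), int(d.size)),
                    cauchy_width=cfg.cauchy_width,
                )
                row.update(_result_row(res))
            rows.append(row)
        if {"HC", "FES"} <= set(per_group) and all(
            v.size >= 2 for v in per_group.values()
        ):
            res = bf_ttest_independent(
                per_group["HC"], per_group["FES"],
                cauchy_width=cfg.cauchy_width, variance_rule=cfg.variance_rule,
            )
            rows.append(
                _result_row(
                    res, variable=var, group="HC vs FES",
                    analysis="linear_change_between_groups",
                    n_pairs=int(sum(v.size for v in per_group.values())),
                )
            )
    return pd.DataFrame(rows)


DEFAULT_CORRELATION_PAIRS = [
    ("ASW_F_mean", "stroop_total_correct"),
    ("ASW_F_mean", "stroop_IG"),
    ("ASW_F_mean", "stroop_incongruent_time"),
    ("ASW_F_mean", "DSST_total"),
    ("ASW_F_mean", "PANSS8_pos"),
    ("ASW_F_mean", "PANSS8_neg"),
    ("ASW_F_mean", "SOFAS"),
    ("ASW_F_mean", "TLI_total"),
    ("ASW_F_mean", "TLI_disorganization"),
    ("ASW_F_mean", "TLI_impoverishment"),
    ("ASW_F_mean", "TLI_dysregulation"),
]


def correlation_tables(
    cohort: Cohort,
    pairs: Sequence[Tuple[str, str]] = tuple(DEFAULT_CORRELATION_PAIRS),
    scope: str = "all",
) -> pd.DataFrame:
    """Bayesian Pearson correlations for variable pairs within a scope."""
    cfg = cohort.config
    frame = cohort.scope(scope)
    rows = []
    for a, b in pairs:
        if a not in frame.columns or b not in frame.columns:
            continue
        sub = frame[[a, b]].dropna()
        row = {"scope": scope, "var_a": a, "var_b": b, "n_obs": int(len(sub))}
        if len(sub) < 3:
            row["status"] = "not_computable"
            rows.append(row)
            continue
        x = sub[a].to_numpy(dtype=float)
        y = sub[b].to_numpy(dtype=float)
        try:
            res = bf_correlation(x=x, y=y, beta_width=cfg.beta_width)
            row.update(_result_row(res))
            row["r"] = float(np.corrcoef(x, y)[0, 1])
            row["status"] = "ok"
        except BayesError as exc:
            row["status"] = f"error: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def dose_tables(cohort: Cohort, standardized: bool = True) -> pd.DataFrame:
    """Medication-dose correlations with the change in linguistic variables
    among followed-up patients (standardized change by default)."""
    cfg = cohort.config
    col = "standardized_change" if standardized else "linear_change"
    fes_base = cohort.scope("followup_FES")
    doses = fes_base.set_index("subject_id")[["daily_dose_DDD", "total_dose"]]
    rows = []
    for var in ("NW_mean", "ASW_F_mean"):
        ch = change_scores(cohort, var)
        ch = ch[ch.group == "FES"].set_index("subject_id")
        joined = ch.join(doses, how="inner")
        for dose_var in ("daily_dose_DDD", "total_dose"):
            sub = joined[[col, dose_var]].dropna()
            row = {
                "dose_variable": dose_var, "change_variable": var,
                "change_type": col, "n_obs": int(len(sub)),
            }
            if len(sub) < 3 or sub[dose_var].std() == 0 or sub[col].std() == 0:
                row["status"] = "not_computable"
                rows.append(row)
                continue
            res = bf_correlation(
                x=sub[dose_var].to_numpy(float), y=sub[col].to_numpy(float),
                beta_width=cfg.beta_width,
            )
            row.update(_result_row(res))
            row["r"] = float(np.corrcoef(sub[dose_var], sub[col])[0, 1])
            row["status"] = "ok"
            rows.append(row)
    return pd.DataFrame(rows)


def stratified_checks(cohort: Cohort) -> pd.DataFrame:
    """Robustness analyses: (i) the ASW-F group test after removing
    immigrant / non-English-first-language subjects; (ii) within-FES
    education and socio-economic band comparisons; (iii) medication-class
    ANOVA at baseline and low-vs-high occupancy t-test at follow-up."""
    cfg = cohort.config
    base = cohort.data[cohort.data.timepoint == "baseline"]
    rows: List[Dict] = []

    def _ttest_row(x, y, **labels):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x = x[~np.isnan(x)]
        y = y[~np.isnan(y)]
        if x.size < 2 or y.size < 2:
            logger.warning("stratum too small for %s; skipped", labels)
            return
        res = bf_ttest_independent(
            x, y, cauchy_width=cfg.cauchy_width, variance_rule=cfg.variance_rule
        )
        rows.append(_result_row(res, **labels))

    if {"immigrant", "first_language_english"} <= set(base.columns):
        kept = base[(~base.immigrant.astype(bool)) & base.first_language_english.astype(bool)]
        _ttest_row(
            kept[kept.group == "HC"].ASW_F_mean, kept[kept.group == "FES"].ASW_F_mean,
            analysis="social_factors_removed", variable="ASW_F_mean",
            detail="native-born, English-first subjects only",
        )

    fes = base[base.group == "FES"]
    for band_var in ("education_band", "parental_SES_band"):
        if band_var not in fes.columns:
            continue
        levels = sorted(fes[band_var].dropna().unique())
        if len(levels) == 2:
            for var in ("ASW_F_mean", "NW_mean"):
                _ttest_row(
                    fes[fes[band_var] == levels[0]][var],
                    fes[fes[band_var] == levels[1]][var],
                    analysis=f"FES_{band_var}", variable=var,
                    detail=f"{levels[0]} vs {levels[1]}",
                )
        else:
            logger.warning("%s does not have two levels; skipped", band_var)

    if "medication_class" in fes.columns:
        groups = []
        for cls in ("naive", "low_D2_occupancy", "high_D2_occupancy"):
            vals = fes[fes.medication_class == cls].ASW_F_mean.dropna().to_numpy(float)
            if vals.size >= 2:
                groups.append(vals)
            else:
                logger.warning("medication stratum %s too small; skipped", cls)
        if len(groups) >= 2:
            res = bf_anova_oneway(groups, g_prior_scale=cfg.g_prior_scale)
            rows.append(
                _result_row(
                    res, analysis="medication_anova_baseline", variable="ASW_F_mean",
                    detail="naive vs low vs high D2 occupancy",
                )
            )
        follow = cohort.data[
            (cohort.data.timepoint == "followup") & (cohort.data.group == "FES")
        ]
        lo = follow[follow.medication_class == "low_D2_occupancy"].ASW_F_mean
        hi = follow[follow.medication_class == "high_D2_occupancy"].ASW_F_mean
        _ttest_row(
            lo, hi, analysis="medication_ttest_followup", variable="ASW_F_mean",
            detail="low vs high D2 occupancy at follow-up",
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + sig - 1)


def write_tables(cohort: Cohort, out_dir: str | Path, seed: Optional[int] = None) -> Dict[str, Path]:
    """Run the full battery and write the study tables plus a run manifest.

    Emits both presentation tables (Bayes factors to 3 significant figures,
    moments to 3 decimals) and raw-precision CSVs. Reruns on identical inputs
    produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "table1_baseline": baseline_tables(cohort),
        "table3_longitudinal": longitudinal_tables(cohort),
        "correlations": pd.concat(
            [
                correlation_tables(cohort, scope=s)
                for s in ("all", "FES", "HC")
            ],
            ignore_index=True,
        ),
        "table4_dose": dose_tables(cohort),
        "stratified": stratified_checks(cohort),
    }
    tables["table2_linguistic"] = tables["table1_baseline"][
        tables["table1_baseline"].variable.isin(LINGUISTIC_VARS)
    ]
    paths = {}
    for name, frame in tables.items():
        raw_path = out / f"{name}_raw.csv"
        frame.to_csv(raw_path, index=False)
        disp = frame.copy()
        for col in disp.columns:
            if disp[col].dtype.kind == "f":
                if col == "BF10":
                    disp[col] = disp[col].map(lambda v: _round_sig(v, 3))
                else:
                    disp[col] = disp[col].round(3)
        disp_path = out / f"{name}.csv"
        disp.to_csv(disp_path, index=False)
        paths[name] = disp_path
    cohort.profiles.to_csv(out / "similarity_profiles.csv", index=False)
    cohort.oov_report.to_csv(out / "oov_report.csv", index=False)

    manifest = {
        "semsim_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "sim_config": {
            "window": cohort.config.sim.window,
            "pair_mode": cohort.config.sim.pair_mode,
            "include_stops": cohort.config.sim.include_stops,
            "stoplist_id": cohort.config.sim.stoplist_id,
        },
        "priors": {
            "cauchy_width": cohort.config.cauchy_width,
            "beta_width": cohort.config.beta_width,
            "g_prior_scale": cohort.config.g_prior_scale,
            "concentration": cohort.config.concentration,
        },
        "variance_rule": cohort.config.variance_rule,
        "n_rows": int(len(cohort.data)),
        "n_profiles": int(len(cohort.profiles)),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True), "utf-8")
    return paths
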