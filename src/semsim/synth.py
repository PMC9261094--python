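"""Synthetic embedding tables and cohorts for end-to-end testing.

The generator emulates the structure of a two-group (first-episode
schizophrenia vs healthy control) longitudinal picture-description study:

* a clustered word-embedding space — K cluster centres sharing a common
  baseline similarity, each with a small vocabulary of noisy members;
* 1-minute descriptions as Markov cluster walks: each successive content
  word stays in the current semantic cluster with probability ``p_stay``
  (higher ``p_stay`` -> higher average word similarity), with stop words and
  out-of-vocabulary surfaces interleaved at fixed rates;
* a cohort of subjects x 3 pictures x up to two timepoints, with clinical,
  cognitive, demographic and medication covariates drawn from a Gaussian
  copula so that targeted cross-correlations (e.g. similarity vs processing
  speed) hold at the latent level.

``p_stay`` is calibrated against target mean similarity values by monotone
bisection / curve inversion, so group differences in ASW are expressed in
the generator's own units. A single integer seed fans out to per-subject,
per-transcript substreams keyed by (subject, picture, timepoint), making
output independent of generation order.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .embeddings import EmbeddingTable
from .simcore import SimConfig, asw_full, eligible_sequence, profile_transcript
from .textprep import annotate, default_stoplist, tokenize

__all__ = [
    "SynthConfig",
    "SyntheticEmbedding",
    "CalibrationError",
    "CalibrationCurve",
    "CohortData",
    "make_synthetic_embedding",
    "sample_transcript",
    "calibrate_p_stay",
    "build_calibration_curve",
    "SynthModel",
    "generate_cohort",
]

GROUPS = ("HC", "FES")
TIMEPOINTS = ("baseline", "followup")


class CalibrationError(ValueError):
    """Target similarity outside the achievable range of the embedding."""


# -- study-shaped default parameters ----------------------------------------

def _default_words() -> Dict[Tuple[str, str], Tuple[float, float]]:
    return {
        ("HC", "baseline"): (70.6, 14.9),
        ("FES", "baseline"): (68.4, 30.3),
        ("HC", "followup"): (70.0, 12.4),
        ("FES", "followup"): (52.1, 19.8),
    }


def _default_asw_targets() -> Dict[str, float]:
    return {"HC": 0.334, "FES": 0.352}


def _default_asw_sd() -> Dict[str, float]:
    return {"HC": 0.025, "FES": 0.034}


def _default_asw_change() -> Dict[str, Tuple[float, float]]:
    # (mean, sd) of the follow-up minus baseline change in subject ASW-F
    return {"HC": (-0.008, 0.028), "FES": (0.020, 0.033)}


@dataclass
class SynthConfig:
    # embedding space
    n_clusters: int = 20
    dim: int = 50
    within_cluster_noise: float = 1.6
    vocab_per_cluster: int = 25
    base_similarity: float = 0.30   # shared cosine floor between all words
    n_stopwords: int = 40
    n_oov: int = 30
    # transcripts
    stopword_rate: float = 0.35
    oov_rate: float = 0.02
    n_pictures: int = 3
    words_per_transcript: Dict[Tuple[str, str], Tuple[float, float]] = field(
        default_factory=_default_words
    )
    # cohort shape
    n_FES: int = 46
    n_HC: int = 36
    n_followup_FES: int = 20
    n_followup_HC: int = 13
    # similarity targets (subject-level means and between-subject SDs)
    asw_targets: Dict[str, float] = field(default_factory=_default_asw_targets)
    asw_sd: Dict[str, float] = field(default_factory=_default_asw_sd)
    asw_change: Dict[str, Tuple[float, float]] = field(default_factory=_default_asw_change)
    # calibration
    calibration_points: int = 21
    calibration_sims: int = 200
    refine_sims: int = 2500
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 2 or self.dim < 2:
            raise ValueError("need n_clusters >= 2 and dim >= 2")
        for rate in (self.stopword_rate, self.oov_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.stopword_rate + self.oov_rate >= 1.0:
            raise ValueError("stopword_rate + oov_rate must leave room for content words")
        if min(self.n_FES, self.n_HC) < 1:
            raise ValueError("sample sizes must be >= 1")


@dataclass
class SyntheticEmbedding:
    """An :class:`EmbeddingTable` plus the generator's lexicon bookkeeping."""

    table: EmbeddingTable
    cluster_tokens: List[List[str]]
    stop_tokens: List[str]
    oov_tokens: List[str]
    centers: np.ndarray


def _child_rng(seed: int, *key: str) -> np.random.Generator:
    """Substream keyed by strings; independent of generation order."""
    crc = zlib.crc32("/".join(key).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), crc]))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_synthetic_embedding(
    cfg: SynthConfig,
    rng: Optional[np.random.Generator] = None,
    orthogonalize: bool = False,
) -> SyntheticEmbedding:
    """Clustered random embedding: K unit centres (sharing ``base_similarity``
    pairwise cosine in expectation), each with ``vocab_per_cluster`` noisy
    members renormalized to unit length. Stop-list tokens get their own
    vectors; designated OOV surfaces are part of the lexicon but withheld
    from the table."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    k, d = cfg.n_clusters, cfg.dim
    if d < k and orthogonalize:
        raise ValueError(f"dim={d} too small to orthogonalize {k} centres")

    raw = rng.standard_normal((k, d))
    if orthogonalize:
        raw, _ = np.linalg.qr(raw.T)
        raw = raw.T[:k]
    axes = np.array([_unit(v) for v in raw])
    common = _unit(rng.standard_normal(d))
    b = cfg.base_similarity
    centers = np.array([_unit(np.sqrt(b) * common + np.sqrt(1 - b) * ax) for ax in axes])
    if orthogonalize and b == 0:
        centers = axes

    sigma = cfg.within_cluster_noise
    vectors: Dict[str, np.ndarray] = {}
    cluster_tokens: List[List[str]] = []
    for c in range(k):
        toks = []
        for i in range(cfg.vocab_per_cluster):
            tok = f"w{c:02d}x{i:02d}"
            if sigma > 0:
                noisy_axis = _unit(axes[c] + rng.standard_normal(d) * (sigma / np.sqrt(d)))
                vectors[tok] = _unit(np.sqrt(b) * common + np.sqrt(1 - b) * noisy_axis)
            else:
                vectors[tok] = centers[c].copy()
            toks.append(tok)
        cluster_tokens.append(toks)

    stop_tokens = sorted(default_stoplist())[: cfg.n_stopwords]
    for tok in stop_tokens:
        vectors[tok] = _unit(rng.standard_normal(d))
    oov_tokens = [f"imagword{i:02d}" for i in range(cfg.n_oov)]

    table = EmbeddingTable(
        dimension=d,
        vectors=vectors,
        source_label=f"synthetic K={k} d={d} noise={sigma}",
    )
    return SyntheticEmbedding(
        table=table,
        cluster_tokens=cluster_tokens,
        stop_tokens=stop_tokens,
        oov_tokens=oov_tokens,
        centers=centers,
    )


def sample_transcript(
    cfg: SynthConfig,
    embedding: SyntheticEmbedding,
    group: str,
    timepoint: str,
    rng: np.random.Generator,
    p_stay: float,
    n_words: Optional[int] = None,
) -> str:
    """One raw description: a Markov cluster walk over content words with
    stop words and OOV surfaces interleaved. Length is drawn from the
    (group, timepoint) word-count distribution, truncated at >= 5."""
    if not 0.0 <= p_stay <= 1.0:
        raise ValueError("p_stay must lie in [0, 1]")
    if n_words is None:
        mu, sd = cfg.words_per_transcript[(group, timepoint)]
        n_words = max(5, int(round(rng.normal(mu, sd))))
    k = cfg.n_clusters
    cluster = int(rng.integers(k))
    started = False
    words: List[str] = []
    for i in range(n_words):
        u = rng.random()
        if u < cfg.stopword_rate and embedding.stop_tokens:
            words.append(embedding.stop_tokens[int(rng.integers(len(embedding.stop_tokens)))])
            continue
        if u < cfg.stopword_rate + cfg.oov_rate and embedding.oov_tokens:
            words.append(embedding.oov_tokens[int(rng.integers(len(embedding.oov_tokens)))])
            continue
        if started and rng.random() > p_stay:
            cluster = (cluster + 1 + int(rng.integers(k - 1))) % k
        started = True
        toks = embedding.cluster_tokens[cluster]
        words.append(toks[int(rng.integers(len(toks)))])
    # light punctuation so the tokenizer has something to strip
    pieces = []
    for i, w in enumerate(words, start=1):
        pieces.append(w + ("." if i % 12 == 0 or i == len(words) else ""))
    return " ".join(pieces)


def _transcript_asw(
    cfg: SynthConfig,
    embedding: SyntheticEmbedding,
    text: str,
    stoplist: frozenset,
    sim: SimConfig,
) -> Optional[float]:
    t = annotate(tokenize(text), stoplist, embedding.table)
    seq = eligible_sequence(t, embedding.table, include_stops=sim.include_stops)
    return asw_full(seq, pair_mode=sim.pair_mode)


@dataclass
class CalibrationCurve:
    """Simulated mean ASW-F (and its transcript-level SD) on a p_stay grid."""

    p_grid: np.ndarray
    mean_asw: np.ndarray      # isotonically adjusted, strictly usable for inversion
    sd_asw: np.ndarray

    def invert(self, target: float, tol: float = 0.005) -> float:
        lo, hi = self.mean_asw[0], self.mean_asw[-1]
        if target < lo - tol or target > hi + tol:
            raise CalibrationError(
                f"target ASW {target:.4f} outside achievable [{lo:.4f}, {hi:.4f}]"
            )
        return float(np.interp(target, self.mean_asw, self.p_grid))

    def sd_at(self, p: float) -> float:
        return float(np.interp(p, self.p_grid, self.sd_asw))


def _simulated_asw(
    cfg: SynthConfig,
    embedding: SyntheticEmbedding,
    p_stay: float,
    n_sim: int,
    rng: np.random.Generator,
    group: str = "HC",
    timepoint: str = "baseline",
    stoplist: Optional[frozenset] = None,
    sim: SimConfig = SimConfig(),
) -> Tuple[float, float]:
    """Mean and SD of transcript-level ASW-F at a fixed p_stay."""
    stoplist = stoplist if stoplist is not None else default_stoplist()
    vals = []
    for _ in range(n_sim):
        text = sample_transcript(cfg, embedding, group, timepoint, rng, p_stay=p_stay)
        v = _transcript_asw(cfg, embedding, text, stoplist, sim)
        if v is not None:
            vals.append(v)
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


def build_calibration_curve(
    cfg: SynthConfig,
    embedding: SyntheticEmbedding,
    group: str = "HC",
    timepoint: str = "baseline",
    n_sim: Optional[int] = None,
    seed: Optional[int] = None,
) -> CalibrationCurve:
    """Simulate mean ASW-F at ``calibration_points`` levels of p_stay under
    the (group, timepoint) word-count distribution. Each level uses its own
    substream; a final isotonic pass enforces monotone means so inversion is
    well defined."""
    n_sim = n_sim if n_sim is not None else cfg.calibration_sims
    seed = seed if seed is not None else cfg.seed
    stoplist = default_stoplist()
    # geometric spacing in (1 - p): the similarity response is steepest as
    # p_stay approaches 1, so that is where grid resolution is needed
    p_grid = 1.0 - np.geomspace(1.0, 0.003, cfg.calibration_points)
    means, sds = [], []
    for i, p in enumerate(p_grid):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCA11B, i]))
        m, s = _simulated_asw(
            cfg, embedding, p, n_sim, rng, group=group, timepoint=timepoint,
            stoplist=stoplist,
        )
        means.append(m)
        sds.append(s)
    means = np.maximum.accumulate(np.asarray(means))
    # break exact ties so np.interp inversion stays single valued
    means += np.arange(len(means)) * 1e-12
    return CalibrationCurve(p_grid=p_grid, mean_asw=means, sd_asw=np.asarray(sds))


def calibrate_p_stay(
    embedding: SyntheticEmbedding,
    target_asw: float,
    cfg: SynthConfig,
    n_sim: int = 500,
    seed: Optional[int] = None,
    tol: float = 0.005,
    group: str = "HC",
    timepoint: str = "baseline",
) -> float:
    """Monotone bisection on p_stay until the simulated mean ASW-F is within
    ``tol`` of ``target_asw``. Common random numbers (one fixed substream per
    evaluation) make the simulated mean monotone in p_stay up to noise.
    Raises :class:`CalibrationError` (reporting the achievable interval) when
    the target lies outside [ASW(0), ASW(1)]."""
    seed = seed if seed is not None else cfg.seed
    stoplist = default_stoplist()

    def mean_at(p: float) -> float:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB15EC7]))
        return _simulated_asw(
            cfg, embedding, p, n_sim, rng, group=group, timepoint=timepoint,
            stoplist=stoplist,
        )[0]

    lo, hi = 0.0, 1.0
    f_lo, f_hi = mean_at(lo), mean_at(hi)
    if not (f_lo - tol <= target_asw <= f_hi + tol):
        raise CalibrationError(
            f"target ASW {target_asw:.4f} outside achievable "
            f"[{f_lo:.4f}, {f_hi:.4f}] for this embedding"
        )
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        f_mid = mean_at(mid)
        if abs(f_mid - target_asw) <= tol:
            return mid
        if f_mid < target_asw:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Covariate model
# ---------------------------------------------------------------------------

# marginal (mean, sd, clip_lo, clip_hi) per group; None = variable absent
_CLINICAL = {
    "age":                  {"HC": (21.4, 3.2, 16, 60), "FES": (22.0, 3.6, 16, 60)},
    "SOFAS":                {"HC": (80.2, 10.0, 0, 100), "FES": (39.3, 13.3, 0, 100)},
    "PANSS8_pos":           {"HC": None, "FES": (12.1, 3.0, 4, 28)},
    "PANSS8_neg":           {"HC": None, "FES": (7.4, 4.3, 4, 28)},
    "PANSS8_general":       {"HC": None, "FES": (6.1, 2.5, 2, 14)},
    "CDS":                  {"HC": None, "FES": (3.5, 3.3, 0, 27)},
    "CGI_S":                {"HC": None, "FES": (5.2, 0.9, 1, 7)},
    "TLI_disorganization":  {"HC": (0.153, 0.2, 0, 24), "FES": (1.01, 1.1, 0, 24)},
    "TLI_impoverishment":   {"HC": (0.13, 0.2, 0, 24), "FES": (0.58, 0.74, 0, 24)},
    "TLI_dysregulation":    {"HC": (0.06, 0.16, 0, 24), "FES": (0.17, 0.29, 0, 24)},
    "DSST_total":           {"HC": (68.6, 11.3, 0, 133), "FES": (52.8, 13.9, 0, 133)},
    "fluency_count":        {"HC": (26.6, 6.9, 0, 60), "FES": (19.8, 6.2, 0, 60)},
    "stroop_total_correct": {"HC": (78.2, 3.1, 0, 84), "FES": (70.8, 13.1, 0, 84)},
    "stroop_total_time":    {"HC": (74.6, 11.3, 20, 300), "FES": (84.8, 17.0, 20, 300)},
    "stroop_incongruent_time": {"HC": (55.0, 10.0, 10, 200), "FES": (65.0, 15.0, 10, 200)},
    "stroop_IG":            {"HC": (8.89, 1.5, -30, 40), "FES": (7.09, 3.5, -30, 40)},
}

# copula edges: latent correlations with the subject's ASW-F level and among
# covariates; FES values follow the baseline correlational results, HC the
# within-HC values.
_COPULA_EDGES = {
    "FES": {
        ("asw", "DSST_total"): -0.41,
        ("asw", "SOFAS"): -0.41,
        ("asw", "PANSS8_pos"): 0.39,
        ("asw", "PANSS8_neg"): 0.08,
        ("asw", "stroop_total_correct"): -0.22,
        ("asw", "stroop_IG"): -0.20,
        ("asw", "stroop_incongruent_time"): 0.28,
        ("asw", "TLI_disorganization"): 0.14,
        ("asw", "TLI_impoverishment"): 0.21,
        ("asw", "TLI_dysregulation"): -0.06,
        ("DSST_total", "stroop_total_correct"): 0.30,
        ("DSST_total", "stroop_incongruent_time"): -0.30,
        ("SOFAS", "PANSS8_pos"): -0.30,
        ("PANSS8_pos", "TLI_disorganization"): 0.30,
    },
    "HC": {
        ("asw", "DSST_total"): -0.03,
        ("asw", "stroop_total_correct"): -0.29,
        ("asw", "stroop_IG"): -0.25,
        ("asw", "stroop_incongruent_time"): 0.06,
        ("DSST_total", "stroop_total_correct"): 0.30,
        ("DSST_total", "stroop_incongruent_time"): -0.30,
    },
}

# follow-up FES change-score copula (standardized latent changes)
_CHANGE_EDGES = {
    ("asw_change", "PANSS8_neg_change"): 0.592,
    ("asw_change", "PANSS8_pos_change"): -0.125,
    ("asw_change", "SOFAS_change"): -0.04,
}
_CHANGE_MARGINALS = {  # (mean, sd) of FES follow-up changes
    "PANSS8_neg_change": (-0.3, 2.0),
    "PANSS8_pos_change": (-7.3, 2.6),
    "SOFAS_change": (19.5, 14.3),
}

_CATEGORICAL = {
    # P(value) per group
    "gender": {"HC": ("male", 0.67), "FES": ("male", 0.77)},
    "education_band": {"HC": (">12", 0.73), "FES": (">12", 0.63)},
    "parental_SES_band": {"HC": (">3", 0.58), "FES": (">3", 0.67)},
    "immigrant": {"HC": (True, 0.30), "FES": (True, 0.20)},
    "first_language_english": {"HC": (True, 0.88), "FES": (True, 0.82)},
}


def _nearest_psd_corr(R: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(R)
    vals = np.clip(vals, 1e-6, None)
    R2 = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(R2))
    return R2 / np.outer(d, d)


def _copula_draw(rng: np.random.Generator, names: List[str], edges: Dict[Tuple[str, str], float]) -> Dict[str, float]:
    idx = {n: i for i, n in enumerate(names)}
    R = np.eye(len(names))
    for (a, b), rho in edges.items():
        if a in idx and b in idx:
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = rho
    R = _nearest_psd_corr(R)
    z = np.linalg.cholesky(R) @ rng.standard_normal(len(names))
    return dict(zip(names, z))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

METADATA_COLUMNS = [
    "subject_id", "group", "timepoint", "age", "gender", "education_band",
    "parental_SES_band", "immigrant", "first_language_english",
    "PANSS8_pos", "PANSS8_neg", "PANSS8_total", "SOFAS",
    "TLI_total", "TLI_disorganization", "TLI_impoverishment", "TLI_dysregulation",
    "CDS", "CGI_S", "medication_class", "daily_dose_DDD", "total_dose",
    "stroop_word", "stroop_colour", "stroop_colour_word",
    "stroop_total_correct", "stroop_total_time", "stroop_incongruent_time",
    "dsst_oral", "dsst_written", "fluency_count",
]


@dataclass
class CohortData:
    """In-memory cohort: transcript texts keyed (subject, timepoint, picture),
    the metadata table, and the generating truth."""

    transcripts: Dict[Tuple[str, str, str], str]
    metadata: pd.DataFrame
    truth: Dict

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        tdir = out / "transcripts"
        tdir.mkdir(parents=True, exist_ok=True)
        for (subject, timepoint, picture), text in sorted(self.transcripts.items()):
            (tdir / f"{subject}_{timepoint}_{picture}.txt").write_text(text, "utf-8")
        self.metadata.to_csv(out / "metadata.csv", index=False)
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True), "utf-8")
        return out


class SynthModel:
    """Embedding + calibrated p_stay anchors, reusable across cohort draws.

    Building the model is the expensive step (calibration simulations); each
    :meth:`generate` call is then cheap, so replicate studies reuse one model.
    A matched-null variant (both groups at the HC similarity level, i.e.
    equal p_stay) can share the embedding and calibration of an existing
    model via ``share_from``.
    """

    def __init__(
        self,
        cfg: SynthConfig,
        curve_sims: Optional[int] = None,
        null: bool = False,
        share_from: Optional["SynthModel"] = None,
    ):
        self.cfg = cfg
        self.null = null
        if share_from is not None:
            self.embedding = share_from.embedding
            self.curves = share_from.curves
            self._anchor_cache = share_from._anchor_cache
        else:
            self.embedding = make_synthetic_embedding(cfg, rng=_child_rng(cfg.seed, "embedding"))
            self.curves = {
                (g, tp): build_calibration_curve(cfg, self.embedding, group=g,
                                                 timepoint=tp, n_sim=curve_sims)
                for g in GROUPS
                for tp in TIMEPOINTS
            }
            self._anchor_cache: Dict[Tuple[str, str, float], float] = {}

        # anchor targets: baseline from the group means, follow-up shifted by
        # the group's mean change; a matched-null cohort puts every group at
        # the HC similarity level (each still calibrated under its own
        # word-count distribution, so the null has no similarity difference)
        self.anchor_target = {}
        for g in GROUPS:
            src = "HC" if null else g
            self.anchor_target[(g, "baseline")] = cfg.asw_targets[src]
            self.anchor_target[(g, "followup")] = (
                cfg.asw_targets[src] + cfg.asw_change[src][0]
            )

        # refine each anchor's p_stay: invert the coarse curve, then Newton
        # steps against large independent simulations using the curve's slope
        self.p_anchor = {}
        for key, target in self.anchor_target.items():
            ck = (key[0], key[1], round(target, 6))
            if ck not in self._anchor_cache:
                self._anchor_cache[ck] = self._refine_anchor(key)
            self.p_anchor[key] = self._anchor_cache[ck]
        self.p_group = {g: self.p_anchor[(g, "baseline")] for g in GROUPS}

        # between-subject spread: remove the share of the table SD explained
        # by averaging n_pictures noisy transcripts per subject
        self.sd_between: Dict[str, float] = {}
        for g in GROUPS:
            curve = self.curves[(g, "baseline")]
            sd_w = curve.sd_at(self.p_group[g])
            tot = cfg.asw_sd[g]
            self.sd_between[g] = float(
                np.sqrt(max(tot ** 2 - sd_w ** 2 / cfg.n_pictures, (0.15 * tot) ** 2))
            )

    # -- subjects ----------------------------------------------------------

    def _subject_ids(self) -> List[Tuple[str, str, bool]]:
        rows = []
        for g, n, nf in (("HC", self.cfg.n_HC, self.cfg.n_followup_HC),
                         ("FES", self.cfg.n_FES, self.cfg.n_followup_FES)):
            for i in range(n):
                rows.append((f"{g}{i + 1:03d}", g, i < nf))
        return rows

    def _refine_anchor(self, key: Tuple[str, str], n_iter: int = 2) -> float:
        g, tp = key
        cfg = self.cfg
        curve = self.curves[key]
        target = self.anchor_target[key]
        lo, hi = curve.mean_asw[0], curve.mean_asw[-1]
        if not (lo - 0.005 <= target <= hi + 0.005):
            raise CalibrationError(
                f"anchor target {target:.4f} for {key} outside achievable "
                f"[{lo:.4f}, {hi:.4f}]"
            )
        slope_grid = np.gradient(curve.mean_asw, curve.p_grid)
        p = curve.invert(float(np.clip(target, lo, hi)))
        for it in range(n_iter):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(cfg.seed), 0xF1E1D, zlib.crc32(f"{g}/{tp}/{it}".encode())])
            )
            m, _ = _simulated_asw(
                cfg, self.embedding, p, cfg.refine_sims, rng, group=g, timepoint=tp
            )
            slope = max(float(np.interp(p, curve.p_grid, slope_grid)), 0.05)
            p = float(np.clip(p + (target - m) / slope, 0.0, 1.0))
        return p

    def _subject_p(self, group: str, timepoint: str, asw_target: float) -> float:
        """p_stay for one subject: the refined group anchor plus the curve's
        local offset between the subject's target and the anchor target."""
        curve = self.curves[(group, timepoint)]
        anchor_tgt = self.anchor_target[(group, timepoint)]
        lo, hi = curve.mean_asw[0], curve.mean_asw[-1]
        offset = curve.invert(float(np.clip(asw_target, lo, hi))) - curve.invert(
            float(np.clip(anchor_tgt, lo, hi))
        )
        return float(np.clip(self.p_anchor[(group, timepoint)] + offset, 0.0, 1.0))

    def generate(self, seed: Optional[int] = None, baseline_only: bool = False) -> CohortData:
        cfg = self.cfg
        seed = cfg.seed if seed is None else seed
        transcripts: Dict[Tuple[str, str, str], str] = {}
        rows: List[Dict] = []
        truth_subjects: Dict[str, Dict] = {}

        for subject, group, has_followup in self._subject_ids():
            rng = _child_rng(seed, "subject", subject)
            base = self._baseline_covariates(group, rng)
            asw_b = (
                self.anchor_target[(group, "baseline")]
                + base.pop("_z_asw") * self.sd_between[group]
            )
            p_b = self._subject_p(group, "baseline", asw_b)

            change_mu = (
                self.anchor_target[(group, "followup")]
                - self.anchor_target[(group, "baseline")]
            )
            change_sd_tab = cfg.asw_change["HC" if self.null else group][1]
            sd_w = self.curves[(group, "baseline")].sd_at(p_b)
            latent_change_sd = float(
                np.sqrt(max(change_sd_tab ** 2 - 2 * sd_w ** 2 / cfg.n_pictures,
                            (0.2 * change_sd_tab) ** 2))
            )
            follow = self._followup_covariates(group, base, rng, change_mu, latent_change_sd)
            asw_f = asw_b + follow.pop("_asw_change")
            p_f = self._subject_p(group, "followup", asw_f)

            if baseline_only:
                has_followup = False
            timepoints = [("baseline", base, p_b)]
            if has_followup:
                timepoints.append(("followup", follow, p_f))
            truth_subjects[subject] = {
                "group": group, "asw_target_baseline": asw_b,
                "asw_target_followup": asw_f if has_followup else None,
                "p_stay_baseline": p_b,
                "p_stay_followup": p_f if has_followup else None,
            }
            for timepoint, cov, p_stay in timepoints:
                row = {"subject_id": subject, "group": group, "timepoint": timepoint}
                row.update(cov)
                rows.append(row)
                for pic in range(1, cfg.n_pictures + 1):
                    trng = _child_rng(seed, subject, str(pic), timepoint)
                    transcripts[(subject, timepoint, str(pic))] = sample_transcript(
                        cfg, self.embedding, group, timepoint, trng, p_stay=p_stay
                    )

        metadata = pd.DataFrame(rows, columns=METADATA_COLUMNS)
        truth = {
            "seed": int(seed),
            "null": self.null,
            "p_stay_anchor": {f"{g}/{tp}": p for (g, tp), p in self.p_anchor.items()},
            "asw_anchor_targets": {f"{g}/{tp}": v for (g, tp), v in self.anchor_target.items()},
            "sd_between": self.sd_between,
            "config": _config_dict(cfg),
            "subjects": truth_subjects,
        }
        return CohortData(transcripts=transcripts, metadata=metadata, truth=truth)

    # -- covariates ---------------------------------------------------------

    def _baseline_covariates(self, group: str, rng: np.random.Generator) -> Dict:
        cont = ["asw"] + [k for k, v in _CLINICAL.items() if v[group] is not None]
        z = _copula_draw(rng, cont, _COPULA_EDGES[group])
        row: Dict = {}
        for name in cont:
            if name == "asw":
                continue
            mu, sd, lo, hi = _CLINICAL[name][group]
            row[name] = float(np.clip(mu + sd * z[name], lo, hi))
        for name, dist in _CATEGORICAL.items():
            value, p = dist[group]
            hit = rng.random() < p
            if isinstance(value, bool):
                row[name] = bool(hit) if value else (not hit)
            else:
                alt = {"male": "female", ">12": "<=12", ">3": "<=3"}[value]
                row[name] = value if hit else alt

        row["fluency_count"] = int(round(row["fluency_count"]))
        # Stroop raw counts consistent with the targeted IG
        w_mu, c_mu = (100.0, 72.0) if group == "HC" else (93.0, 67.0)
        W = float(np.clip(rng.normal(w_mu, 7.0), 20, 120))
        C = float(np.clip(rng.normal(c_mu, 6.0), 20, 120))
        ig = row.pop("stroop_IG")
        row["stroop_word"] = round(W)
        row["stroop_colour"] = round(C)
        row["stroop_colour_word"] = round(
            max(0.0, ig + (round(W) * round(C)) / (round(W) + round(C)))
        )
        row["stroop_total_correct"] = round(row["stroop_total_correct"])
        # DSST raw oral/written around the targeted total
        total = row.pop("DSST_total")
        half_gap = rng.normal(0.0, 3.0)
        row["dsst_oral"] = max(0, round(total + half_gap))
        row["dsst_written"] = max(0, round(total - half_gap))
        if group == "FES":
            row["PANSS8_total"] = row["PANSS8_pos"] + row["PANSS8_neg"] + row.pop("PANSS8_general")
            row["TLI_total"] = (
                row["TLI_disorganization"] + row["TLI_impoverishment"] + row["TLI_dysregulation"]
            )
            row.update(self._medication(rng))
        else:
            row["TLI_total"] = (
                row["TLI_disorganization"] + row["TLI_impoverishment"] + row["TLI_dysregulation"]
            )
        row["_z_asw"] = z["asw"]
        return row

    def _medication(self, rng: np.random.Generator) -> Dict:
        naive = rng.random() < 0.5
        if naive:
            return {"medication_class": "naive", "daily_dose_DDD": 0.0, "total_dose": 0.0}
        cls = "low_D2_occupancy" if rng.random() < 0.5 else "high_D2_occupancy"
        return {
            "medication_class": cls,
            "daily_dose_DDD": float(np.clip(rng.normal(0.81, 0.49), 0.05, 4.0)),
            "total_dose": float(np.clip(rng.normal(160.7, 110.0), 5.0, 1000.0)),
        }

    def _followup_covariates(
        self,
        group: str,
        base: Dict,
        rng: np.random.Generator,
        asw_change_mu: float,
        asw_change_sd: float,
    ) -> Dict:
        row = {k: v for k, v in base.items() if not k.startswith("_z")}
        if group == "FES":
            names = ["asw_change"] + list(_CHANGE_MARGINALS)
            z = _copula_draw(rng, names, _CHANGE_EDGES)
            row["_asw_change"] = asw_change_mu + asw_change_sd * z["asw_change"]
            for name, (mu, sd) in _CHANGE_MARGINALS.items():
                target = name.replace("_change", "")
                lo, hi = (_CLINICAL[target][group][2:] if target in _CLINICAL else (0, 100))
                row[target] = float(np.clip(row[target] + mu + sd * z[name], lo, hi))
            row["PANSS8_total"] = row["PANSS8_pos"] + row["PANSS8_neg"] + max(
                2.0, row["PANSS8_total"] - base["PANSS8_pos"] - base["PANSS8_neg"] - 3.0
            )
            # everyone is treated by follow-up
            if row["medication_class"] == "naive":
                row["medication_class"] = (
                    "low_D2_occupancy" if rng.random() < 0.5 else "high_D2_occupancy"
                )
        else:
            row["_asw_change"] = rng.normal(asw_change_mu, asw_change_sd)
        return row


def _config_dict(cfg: SynthConfig) -> Dict:
    out = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, dict):
            v = {str(k): val for k, val in v.items()}
        out[f.name] = v
    return out


def generate_cohort(
    cfg: SynthConfig,
    out_dir: str | Path,
    seed: Optional[int] = None,
    model: Optional[SynthModel] = None,
) -> CohortData:
    """Generate a full cohort (embedding, transcripts, metadata CSV,
    truth.json) under ``out_dir``. Same seed -> byte-identical output tree."""
    model = model if model is not None else SynthModel(cfg)
    data = model.generate(seed=seed)
    out = data.write(out_dir)
    from .embeddings import write_embedding_table

    write_embedding_table(model.embedding.table, Path(out) / "embeddings.txt")
    return data
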