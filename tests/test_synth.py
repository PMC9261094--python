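import filecmp
import json
from pathlib import Path

import numpy as np
import pytest

from semsim.simcore import SimConfig, asw_full, eligible_sequence
from semsim.synth import (
    CalibrationError,
    SynthConfig,
    SynthModel,
    calibrate_p_stay,
    generate_cohort,
    make_synthetic_embedding,
    sample_transcript,
)
from semsim.textprep import annotate, default_stoplist, tokenize


def _cosine_matrix(vectors):
    m = np.vstack(vectors)
    m = m / np.linalg.norm(m, axis=1, keepdims=True)
    return m @ m.T


def _asw_of_text(text, embedding, include_stops=False, pair_mode="all_pairs"):
    t = annotate(tokenize(text), default_stoplist(), embedding.table)
    seq = eligible_sequence(t, embedding.table, include_stops=include_stops)
    return asw_full(seq, pair_mode=pair_mode), t


class TestEmbeddingGenerator:
    def test_zero_noise_gives_unit_within_cluster_cosine(self):
        cfg = SynthConfig(within_cluster_noise=0.0, n_clusters=4, vocab_per_cluster=5)
        emb = make_synthetic_embedding(cfg, rng=np.random.default_rng(0))
        for toks in emb.cluster_tokens:
            sims = _cosine_matrix([emb.table.get(t) for t in toks])
            np.testing.assert_allclose(sims, 1.0, atol=1e-12)

    def test_orthogonal_centres_zero_between_cosine(self):
        cfg = SynthConfig(
            n_clusters=2, dim=10, within_cluster_noise=0.0, base_similarity=0.0,
            vocab_per_cluster=3,
        )
        emb = make_synthetic_embedding(cfg, rng=np.random.default_rng(1), orthogonalize=True)
        u = emb.table.get(emb.cluster_tokens[0][0])
        v = emb.table.get(emb.cluster_tokens[1][0])
        assert abs(float(u @ v)) < 1e-10

    def test_within_exceeds_between_under_noise(self):
        cfg = SynthConfig(n_clusters=20, dim=50, within_cluster_noise=0.3, vocab_per_cluster=10)
        emb = make_synthetic_embedding(cfg, rng=np.random.default_rng(2))
        rng = np.random.default_rng(3)
        within, between = [], []
        for _ in range(500):
            c1, c2 = rng.integers(cfg.n_clusters, size=2)
            t1, t2 = rng.integers(cfg.vocab_per_cluster, size=2)
            s = float(
                emb.table.get(emb.cluster_tokens[c1][t1])
                @ emb.table.get(emb.cluster_tokens[c2][t2])
            )
            (within if c1 == c2 else between).append(s)
        assert np.mean(within) > np.mean(between) + 0.1

    def test_oov_surfaces_withheld_from_table(self):
        emb = make_synthetic_embedding(SynthConfig(), rng=np.random.default_rng(4))
        assert all(tok not in emb.table for tok in emb.oov_tokens)
        assert all(tok in emb.table for tok in emb.stop_tokens)


class TestTranscriptSampler:
    def test_single_cluster_limit_gives_unit_asw(self):
        cfg = SynthConfig(within_cluster_noise=0.0, oov_rate=0.0)
        emb = make_synthetic_embedding(cfg, rng=np.random.default_rng(5))
        text = sample_transcript(cfg, emb, "HC", "baseline", np.random.default_rng(6), p_stay=1.0)
        asw, _ = _asw_of_text(text, emb)
        assert asw == pytest.approx(1.0, abs=1e-12)

    def test_alternating_orthogonal_limit_adjacent_zero(self):
        cfg = SynthConfig(
            n_clusters=2, dim=10, within_cluster_noise=0.0, base_similarity=0.0,
            stopword_rate=0.0, oov_rate=0.0, vocab_per_cluster=3,
        )
        emb = make_synthetic_embedding(cfg, rng=np.random.default_rng(7), orthogonalize=True)
        text = sample_transcript(cfg, emb, "HC", "baseline", np.random.default_rng(8), p_stay=0.0)
        asw_adj, _ = _asw_of_text(text, emb, pair_mode="adjacent")
        assert asw_adj == pytest.approx(0.0, abs=1e-10)

    def test_fixed_seed_reproduces_transcript(self):
        cfg = SynthConfig()
        emb = make_synthetic_embedding(cfg, rng=np.random.default_rng(9))
        t1 = sample_transcript(cfg, emb, "FES", "baseline", np.random.default_rng(10), p_stay=0.8)
        t2 = sample_transcript(cfg, emb, "FES", "baseline", np.random.default_rng(10), p_stay=0.8)
        assert t1 == t2

    def test_oov_rate_injects_reported_nonscoring_words(self):
        cfg = SynthConfig(oov_rate=0.2)
        emb = make_synthetic_embedding(cfg, rng=np.random.default_rng(11))
        rng = np.random.default_rng(12)
        text = sample_transcript(cfg, emb, "HC", "baseline", rng, p_stay=0.9, n_words=200)
        asw, transcript = _asw_of_text(text, emb)
        assert transcript.oov_report  # injected surfaces are reported
        assert set(transcript.oov_report) <= set(emb.oov_tokens)
        # removing them from the raw text leaves the similarity unchanged
        cleaned = " ".join(w for w in text.split() if w.rstrip(".") not in emb.oov_tokens)
        asw_clean, _ = _asw_of_text(cleaned, emb)
        assert asw == pytest.approx(asw_clean, abs=1e-12)

    def test_expected_asw_monotone_in_p_stay(self):
        cfg = SynthConfig()
        emb = make_synthetic_embedding(cfg, rng=np.random.default_rng(13))
        means = []
        for p in (0.0, 0.5, 0.8, 0.95, 1.0):
            rng = np.random.default_rng(14)
            vals = []
            for _ in range(200):
                text = sample_transcript(cfg, emb, "HC", "baseline", rng, p_stay=p)
                v, _ = _asw_of_text(text, emb)
                if v is not None:
                    vals.append(v)
            means.append(np.mean(vals))
        assert all(b >= a - 0.002 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0] + 0.05


@pytest.fixture(scope="module")
def emb():
    cfg = SynthConfig(seed=21)
    return cfg, make_synthetic_embedding(cfg, rng=np.random.default_rng(21))


class TestCalibration:

    def test_boundary_target_returns_extreme_p(self, emb):
        cfg, embedding = emb
        rng = np.random.default_rng(22)
        vals = []
        for _ in range(400):
            text = sample_transcript(cfg, embedding, "HC", "baseline", rng, p_stay=1.0)
            v, _ = _asw_of_text(text, embedding)
            vals.append(v)
        top = float(np.mean(vals))
        p = calibrate_p_stay(embedding, top, cfg, n_sim=300)
        assert p > 0.95

    def test_monotone_in_target(self, emb):
        cfg, embedding = emb
        p_low = calibrate_p_stay(embedding, 0.334, cfg, n_sim=300)
        p_high = calibrate_p_stay(embedding, 0.352, cfg, n_sim=300)
        assert p_high > p_low

    def test_unachievable_target_raises(self, emb):
        cfg, embedding = emb
        with pytest.raises(CalibrationError, match="achievable"):
            calibrate_p_stay(embedding, 0.99, cfg, n_sim=100)


class TestCohortGeneration:
    def test_study_shape(self, full_model):
        data = full_model.generate(seed=101)
        md = data.metadata
        assert md.subject_id.nunique() == 82
        assert (md.timepoint == "baseline").sum() == 82
        assert (md.timepoint == "followup").sum() == 33
        base = sum(1 for k in data.transcripts if k[1] == "baseline")
        follow = sum(1 for k in data.transcripts if k[1] == "followup")
        assert base == 246 and follow == 99
        fes_follow = md[(md.timepoint == "followup") & (md.group == "FES")]
        assert len(fes_follow) == 20

    def test_same_seed_byte_identical_trees(self, small_model, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        generate_cohort(small_model.cfg, a, seed=33, model=small_model)
        generate_cohort(small_model.cfg, b, seed=33, model=small_model)
        for rel in ["metadata.csv", "truth.json", "embeddings.txt"]:
            assert (a / rel).read_bytes() == (b / rel).read_bytes()
        ta = sorted(p.name for p in (a / "transcripts").iterdir())
        tb = sorted(p.name for p in (b / "transcripts").iterdir())
        assert ta == tb
        match, mismatch, errors = filecmp.cmpfiles(a / "transcripts", b / "transcripts", ta, shallow=False)
        assert not mismatch and not errors

    def test_truth_file_records_generating_parameters(self, small_model, tmp_path):
        generate_cohort(small_model.cfg, tmp_path, seed=34, model=small_model)
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert "p_stay_anchor" in truth and "subjects" in truth
        assert truth["seed"] == 34

    def test_metadata_marginals_match_targets(self, full_model):
        """Requested group means are reproduced within 3 standard errors."""
        data = full_model.generate(seed=55)
        base = data.metadata[data.metadata.timepoint == "baseline"]
        targets = {
            ("HC", "age"): (21.4, 3.2),
            ("FES", "age"): (22.0, 3.6),
            ("HC", "SOFAS"): (80.2, 10.0),
            ("FES", "SOFAS"): (39.3, 13.3),
            ("HC", "fluency_count"): (26.6, 6.9),
            ("FES", "fluency_count"): (19.8, 6.2),
            ("FES", "PANSS8_pos"): (12.1, 3.0),
        }
        for (group, var), (mu, sd) in targets.items():
            vals = base[base.group == group][var].dropna()
            se = sd / np.sqrt(len(vals))
            assert abs(vals.mean() - mu) <= 3 * se, (group, var, vals.mean())

    def test_dsst_and_stroop_raw_scores_consistent(self, full_model):
        data = full_model.generate(seed=56)
        base = data.metadata[data.metadata.timepoint == "baseline"]
        dsst = (base.dsst_oral + base.dsst_written) / 2
        hc = dsst[base.group == "HC"]
        assert abs(hc.mean() - 68.6) < 3 * 11.3 / np.sqrt(len(hc))
        assert (base.stroop_word + base.stroop_colour > 0).all()
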