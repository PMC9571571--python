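"""Architecture registry, nearest-token extraction, sensitivity and clustering."""

import numpy as np
import pytest

from drugsieve.corpus import SentenceRecord, tokenize
from drugsieve.embedding import EMBED_DIM, EmbeddedSentence
from drugsieve.errors import ContractError, InputError, ParseError
from drugsieve.extraction import (
    ARCHITECTURES,
    ExtractionExample,
    SensitivityReport,
    SplitDataset,
    build_architecture,
    compare_models,
    evaluate_sensitivity,
    extract_compound,
    get_architecture,
    random_baseline,
    read_extraction_csv,
    train_extraction,
)
from drugsieve.net import TrainConfig

# Independent transcription of the eight published layer stacks, written out
# by hand here so a registry typo cannot hide behind its own definition.
EXPECTED_LAYER_STACKS = {
    "A": ["dense:selu", "dense:sigmoid", "dense:relu", "dense:relu", "dense:selu",
          "leaky_relu", "act:selu", "simple_rnn", "dense:selu", "dense:relu",
          "dense:selu", "dense:relu", "dense:selu"],
    "B": ["dense:selu", "dense:sigmoid"],
    "C": ["dense:relu", "dense:selu", "dense:sigmoid"],
    "D": ["dense:selu", "dense:softmax", "prelu"],
    "E": ["dense:selu", "simple_rnn"],
    "F": ["act:selu", "lstm", "leaky_relu", "leaky_relu"],
    "G": ["dense:selu", "prelu", "dense:selu", "simple_rnn", "act:selu", "leaky_relu"],
    "H": ["act:selu", "lstm", "prelu", "leaky_relu", "leaky_relu"],
}


def _summarize(descriptor):
    kind = descriptor[0]
    if kind == "dense":
        assert descriptor[1] == 512
        return f"dense:{descriptor[2]}"
    if kind == "activation":
        return f"act:{descriptor[1]}"
    if kind in ("simple_rnn", "lstm"):
        assert descriptor[1] == 512
        return kind
    return kind


class TestArchitectureRegistry:
    def test_registry_matches_published_table(self):
        assert set(ARCHITECTURES) == set("ABCDEFGH")
        for arch_id, expected in EXPECTED_LAYER_STACKS.items():
            assert [_summarize(d) for d in ARCHITECTURES[arch_id]] == expected, arch_id

    @pytest.mark.parametrize("arch_id", sorted(ARCHITECTURES))
    def test_forward_pass_is_finite_512(self, arch_id):
        model = build_architecture(arch_id, seed=0)
        out = model.predict(np.zeros((1, EMBED_DIM)))
        assert out.shape == (1, EMBED_DIM)
        assert np.all(np.isfinite(out))

    def test_recurrent_architectures_reshape_input(self):
        assert get_architecture("H").has_recurrent
        assert not get_architecture("B").has_recurrent

    def test_unknown_id_rejected(self):
        with pytest.raises(InputError):
            build_architecture("Z")

    def test_bad_reshape_rejected(self):
        with pytest.raises(ContractError):
            build_architecture("H", input_reshape=(30, 16))

    def test_alternate_reshape_accepted(self):
        model = build_architecture("E", input_reshape=(1, 512), seed=0)
        assert model.predict(np.zeros((1, EMBED_DIM))).shape == (1, EMBED_DIM)


def _embedded(tokens, vecs, pred_target=None):
    rec = SentenceRecord("d", 0, " ".join(tokens), list(tokens))
    return EmbeddedSentence(
        sentence=rec,
        sentence_vec=np.zeros(EMBED_DIM) if pred_target is None else pred_target,
        token_vecs=[np.asarray(v) for v in vecs],
    )


class TestExtractCompound:
    def test_single_token(self, stub_model_factory):
        vec = np.ones(EMBED_DIM)
        s = _embedded(["aspirin"], [vec])
        token, dist = extract_compound(stub_model_factory(np.zeros(EMBED_DIM)), s)
        assert token == "aspirin"

    def test_prediction_on_token_three(self, stub_model_factory):
        rng = np.random.default_rng(0)
        vecs = rng.standard_normal((5, EMBED_DIM))
        s = _embedded([f"t{i}" for i in range(5)], vecs)
        token, dist = extract_compound(stub_model_factory(vecs[3]), s)
        assert token == "t3"
        assert dist == 0.0

    def test_tie_broken_by_earliest_position(self, stub_model_factory):
        v = np.ones(EMBED_DIM)
        s = _embedded(["first", "second"], [v, v.copy()])
        token, _ = extract_compound(stub_model_factory(np.zeros(EMBED_DIM)), s)
        assert token == "first"

    def test_zero_tokens_rejected(self, stub_model_factory):
        s = _embedded([], [])
        with pytest.raises(InputError):
            extract_compound(stub_model_factory(np.zeros(EMBED_DIM)), s)

    def test_matches_brute_force_on_1000_random_instances(self, stub_model_factory):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            n_tok = int(rng.integers(1, 9))
            vecs = rng.standard_normal((n_tok, EMBED_DIM))
            pred = rng.standard_normal(EMBED_DIM)
            s = _embedded([f"t{i}" for i in range(n_tok)], vecs)
            token, dist = extract_compound(stub_model_factory(pred), s)
            # brute force: explicit distance loop, earliest-position argmin
            best_i, best_d = 0, float("inf")
            for i, v in enumerate(vecs):
                d = float(np.sqrt(np.sum((v - pred) ** 2)))
                if d < best_d:
                    best_i, best_d = i, d
            assert token == f"t{best_i}"
            assert dist == pytest.approx(best_d)


class TestSensitivity:
    def test_three_true_one_false_is_075(self, stub_model_factory, small_corpus):
        emb = small_corpus.embedder()
        # prediction pinned at the hidden centroid: every extraction is a
        # drug token, so flipping one label manufactures exactly one miss
        examples = [
            ExtractionExample(ex.sentence_text, ex.drug_label)
            for ex in small_corpus.splits.test[:4]
        ]
        examples[0].drug_label = "notindataset"
        rep = evaluate_sensitivity(
            stub_model_factory(small_corpus.hidden_centroid), examples, emb
        )
        assert (rep.n_true, rep.n_false) == (3, 1)
        assert rep.sensitivity == 0.75

    def test_all_correct_is_one(self, stub_model_factory, small_corpus):
        emb = small_corpus.embedder()
        rep = evaluate_sensitivity(
            stub_model_factory(small_corpus.hidden_centroid),
            small_corpus.splits.test,
            emb,
        )
        assert rep.sensitivity == 1.0

    def test_report_arithmetic(self):
        assert SensitivityReport(n_true=3, n_false=1).sensitivity == 0.75
        assert SensitivityReport(n_true=7, n_false=0).sensitivity == 1.0
        with pytest.raises(InputError):
            SensitivityReport(n_true=0, n_false=0).sensitivity

    def test_match_normalization_case_and_punctuation(self, stub_model_factory):
        emb_vec = np.ones(EMBED_DIM) / np.sqrt(EMBED_DIM)
        from drugsieve.embedding import fixture_embedder

        emb = fixture_embedder(seed=0, vocabulary={"Aspirin": emb_vec})
        examples = [ExtractionExample("Aspirin works", "aspirin")]
        rep = evaluate_sensitivity(stub_model_factory(emb_vec), examples, emb)
        assert rep.sensitivity == 1.0

    def test_empty_examples_rejected(self, stub_model_factory, embedder):
        with pytest.raises(InputError):
            evaluate_sensitivity(stub_model_factory(np.zeros(EMBED_DIM)), [], embedder)


class TestRandomBaseline:
    def test_expectation_is_one_over_length(self):
        """Uniform token choice with one drug token among L succeeds with
        probability 1/L; check a 3-standard-error band over 10000 draws."""
        L = 5
        examples = [
            ExtractionExample(
                " ".join(f"w{i}_{j}" for j in range(L - 1)) + " drugX", "drugX"
            )
            for i in range(10000)
        ]
        rep = random_baseline(examples, seed=11)
        p = 1.0 / L
        se = np.sqrt(p * (1 - p) / len(examples))
        assert abs(rep.sensitivity - p) < 3 * se

    def test_single_token_sentences_score_one(self):
        examples = [ExtractionExample("drugA", "drugA") for _ in range(10)]
        assert random_baseline(examples, seed=0).sensitivity == 1.0

    def test_seeded_reproducibility(self):
        examples = [
            ExtractionExample(f"a b c drug{i}", f"drug{i}") for i in range(50)
        ]
        r1 = random_baseline(examples, seed=5)
        r2 = random_baseline(examples, seed=5)
        assert (r1.n_true, r1.n_false) == (r2.n_true, r2.n_false)


class TestCompareModels:
    def test_separated_groups_recovered_exactly(self):
        mat = np.array([[0.6] * 3] * 5 + [[0.1] * 3] * 3)
        ids = list("AEFGH") + list("BCD")
        comp = compare_models(mat, k=2, seed=0, model_ids=ids)
        clusters = comp.clusters()
        assert len(clusters) == 2
        groups = {frozenset(models) for models in clusters.values()}
        assert groups == {frozenset("AEFGH"), frozenset("BCD")}

    def test_k_one_puts_all_models_together(self):
        mat = np.random.default_rng(0).random((8, 3))
        comp = compare_models(mat, k=1, seed=0)
        assert len(set(comp.labels.tolist())) == 1

    def test_k_out_of_range(self):
        mat = np.zeros((4, 3))
        for k in (0, 5):
            with pytest.raises(InputError):
                compare_models(mat, k=k, seed=0)

    def test_noisy_two_cluster_recovery_rate(self):
        """sigma=0.02 noise around two well-separated sensitivity profiles:
        k-means recovers the split in at least 99 of 100 seeded trials."""
        base = np.array([[0.6] * 3] * 5 + [[0.1] * 3] * 3)
        wins = 0
        for trial in range(100):
            rng = np.random.default_rng(1000 + trial)
            mat = base + 0.02 * rng.standard_normal(base.shape)
            comp = compare_models(
                mat, k=2, seed=trial, model_ids=list("AEFGH") + list("BCD")
            )
            groups = {
                frozenset(m) for m in comp.clusters().values()
            }
            wins += groups == {frozenset("AEFGH"), frozenset("BCD")}
        assert wins >= 99


class TestTrainExtraction:
    def test_training_learns_structure_on_small_corpus(self, small_corpus):
        emb = small_corpus.embedder()
        config = TrainConfig(epochs=8, learning_rate=1e-3, seed=2)
        model, hist = train_extraction("E", small_corpus.splits, emb, config)
        assert hist.loss[-1] < hist.loss[0]
        assert len(hist.loss) == 8

    def test_reproducible(self, small_corpus):
        emb = small_corpus.embedder()
        finals = []
        for _ in range(2):
            config = TrainConfig(epochs=2, learning_rate=3e-3, seed=3)
            _, hist = train_extraction("B", small_corpus.splits, emb, config)
            finals.append(hist.loss[-1])
        assert finals[0] == finals[1]

    def test_empty_train_split_rejected(self, embedder):
        with pytest.raises(InputError):
            train_extraction("B", SplitDataset(), embedder, TrainConfig(epochs=1, seed=0))


class TestReadExtractionCsv:
    def test_three_rows(self, tmp_path):
        path = tmp_path / "data.csv"
        path.write_text(
            "sentence,drug\n"
            "aspirin reduces fever,aspirin\n"
            "zileuton inhibits lipoxygenase,zileuton\n"
            "resveratrol is an antioxidant,resveratrol\n"
        )
        examples, excluded = read_extraction_csv(path)
        assert len(examples) == 3 and excluded == 0
        assert examples[0].drug_label == "aspirin"

    def test_label_absent_from_sentence_excluded(self, tmp_path):
        path = tmp_path / "data.csv"
        path.write_text("aspirin reduces fever,ibuprofen\naspirin works,aspirin\n")
        examples, excluded = read_extraction_csv(path)
        assert len(examples) == 1 and excluded == 1

    def test_wrong_column_count(self, tmp_path):
        path = tmp_path / "data.csv"
        path.write_text("only one column\n")
        with pytest.raises(ParseError):
            read_extraction_csv(path)

    def test_multiword_label_matches_informative_token(self, tmp_path):
        path = tmp_path / "data.csv"
        path.write_text("glycyrrhetinic acid inhibits it,glycyrrhetinic acid\n")
        examples, excluded = read_extraction_csv(path)
        assert len(examples) == 1 and excluded == 0
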