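"""Language-model backends: generation, training, gradients, persistence."""

import numpy as np
import pytest

from geomex.model import (
    CapabilityError,
    EarlyStopping,
    GenerationTrace,
    ModelConfig,
    TableLookupAdapter,
    TinyTransformerAdapter,
    TrainConfig,
    TrainingError,
    TransformerLM,
    WordTokenizer,
    fine_tune,
    generate,
)

PROMPT = "<BOS> input <SEP> cell line:"


@pytest.fixture()
def hela_fixture():
    """Table-driven backend generating 'hela -s3' with known probabilities."""
    return TableLookupAdapter(
        {
            PROMPT: {"hela": 0.9, "<EOS>": 0.1},
            PROMPT + " hela": {"-s3": 0.99, "<EOS>": 0.01},
            PROMPT + " hela -s3": {"<EOS>": 1.0},
        }
    )


class TestGeneration:
    def test_immediate_eos_gives_empty_trace(self):
        adapter = TableLookupAdapter({PROMPT: {"<EOS>": 1.0}})
        trace = generate(adapter, PROMPT)
        assert trace.tokens == () and trace.probs == ()
        assert trace.stop_prob == 1.0

    def test_probs_read_off_fixture_table(self, hela_fixture):
        trace = generate(adapter=hela_fixture, prompt=PROMPT)
        assert trace.tokens == ("hela", "-s3")
        assert trace.probs == (0.9, 0.99)

    def test_max_new_tokens_cutoff(self):
        adapter = TableLookupAdapter({}, max_context=64)
        adapter.table = {}  # unknown prompts stop immediately
        looping = TableLookupAdapter({})
        looping.next_distribution = lambda prefix: {"again": 1.0}
        trace = generate(looping, PROMPT, max_new_tokens=1)
        assert trace.tokens == ("again",)
        assert trace.stop_prob is None

    def test_deterministic(self, hela_fixture):
        t1 = generate(hela_fixture, PROMPT)
        t2 = generate(hela_fixture, PROMPT)
        assert t1 == t2

    def test_trace_validation(self):
        with pytest.raises(ValueError):
            GenerationTrace(tokens=("a",), probs=())
        with pytest.raises(ValueError):
            GenerationTrace(tokens=("a",), probs=(1.5,))


class TestNetworkGradients:
    def test_parameter_gradients_match_finite_differences(self):
        """Analytic backprop agrees with central differences on every
        parameter family."""
        model = TransformerLM(
            ModelConfig(vocab_size=17, d_model=16, n_heads=2, n_layers=2, d_ff=24, max_len=24, seed=3)
        )
        rng = np.random.default_rng(5)
        ids = rng.integers(0, 17, size=(2, 10))
        pad = np.ones((2, 10), bool)
        pad[1, 8:] = False
        lmask = np.zeros((2, 9), bool)
        lmask[0, 2:8] = True
        lmask[1, 3:7] = True
        _, grads = model.loss_and_grads(ids, pad, lmask)
        eps = 1e-6
        for name, param in model.params.items():
            idx = tuple(rng.integers(0, s) for s in param.shape)
            orig = param[idx]
            param[idx] = orig + eps
            lp = model.loss_only(ids, pad, lmask)
            param[idx] = orig - eps
            lm = model.loss_only(ids, pad, lmask)
            param[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(numeric, rel=1e-5, abs=1e-9), name

    def test_next_token_distribution_is_normalized(self):
        model = TransformerLM(ModelConfig(vocab_size=11, d_model=8, n_heads=2, n_layers=1, d_ff=16, seed=0))
        probs = model.next_token_distribution([1, 2, 3])
        assert probs.shape == (11,)
        assert np.all(probs >= 0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)


class TestFineTuning:
    EXAMPLES = [
        "<BOS> sample one with k562 cells <SEP> cell line: k562 <EOS>",
        "<BOS> sample two hela cells <SEP> cell line: hela-s3 <EOS>",
        "<BOS> liver tissue chip <SEP> tissue: liver <EOS>",
        "<BOS> male donor prostate <SEP> sex: male <EOS>",
        "<BOS> rna profiling run <SEP> technique: rna-seq <EOS>",
    ]

    def test_zero_epochs_leaves_outputs_unchanged(self):
        adapter = TinyTransformerAdapter(seed=0)
        config = TrainConfig(max_epochs=0, seed=0)
        fine_tune(adapter, self.EXAMPLES, config)
        before = generate(adapter, "<BOS> sample one with k562 cells <SEP> cell line:")
        fine_tune(adapter, self.EXAMPLES, config)
        after = generate(adapter, "<BOS> sample one with k562 cells <SEP> cell line:")
        assert before == after

    def test_memorizes_five_examples(self):
        adapter = TinyTransformerAdapter(seed=1)
        config = TrainConfig(
            learning_rate=3e-3, batch_size=5, max_epochs=150, val_fraction=0.0, seed=1
        )
        fine_tune(adapter, self.EXAMPLES, config)
        for s in self.EXAMPLES:
            head, _, tail = s.rpartition(": ")
            prompt = head + ":"
            target = tail.replace("<EOS>", "").strip()
            trace = generate(adapter, prompt)
            assert " ".join(trace.tokens) == target

    def test_fixed_seed_is_reproducible(self):
        traces = []
        for _ in range(2):
            adapter = TinyTransformerAdapter(seed=2)
            fine_tune(
                adapter,
                self.EXAMPLES,
                TrainConfig(learning_rate=1e-3, batch_size=2, max_epochs=3, val_fraction=0.2, seed=2),
            )
            traces.append(generate(adapter, "<BOS> liver tissue chip <SEP> tissue:"))
        assert traces[0] == traces[1]

    def test_empty_dataset_rejected(self):
        with pytest.raises(TrainingError):
            fine_tune(TinyTransformerAdapter(seed=0), [], TrainConfig())

    def test_non_trainable_adapter_rejected(self):
        with pytest.raises(CapabilityError):
            fine_tune(TableLookupAdapter({}), self.EXAMPLES, TrainConfig())

    def test_save_load_round_trip(self, tmp_path):
        adapter = TinyTransformerAdapter(seed=3)
        fine_tune(adapter, self.EXAMPLES, TrainConfig(learning_rate=1e-3, max_epochs=2, seed=3))
        adapter.save(tmp_path / "m")
        loaded = TinyTransformerAdapter.load(tmp_path / "m")
        prompt = "<BOS> male donor prostate <SEP> sex:"
        assert generate(adapter, prompt) == generate(loaded, prompt)


class TestEarlyStopping:
    def test_stops_after_patience_plus_one_flat_epochs(self):
        stopper = EarlyStopping(patience=2, min_delta=0.0)
        assert stopper.update(1.0) is False  # improvement (from inf)
        assert stopper.update(1.0) is False  # flat 1
        assert stopper.update(1.0) is False  # flat 2
        assert stopper.update(1.0) is True   # flat 3 = patience + 1
        assert stopper.best_epoch == 0

    def test_improvement_resets_wait(self):
        stopper = EarlyStopping(patience=1, min_delta=0.0)
        assert not stopper.update(1.0)
        assert not stopper.update(0.9)
        assert not stopper.update(0.95)
        assert not stopper.update(0.5)
        assert not stopper.update(0.6)
        assert stopper.update(0.6)

    def test_min_delta_counts_small_gains_as_plateau(self):
        stopper = EarlyStopping(patience=0, min_delta=0.1)
        assert not stopper.update(1.0)
        assert stopper.update(0.95)  # gain below min_delta


class TestTokenizer:
    def test_specials_reserved_and_round_trip(self):
        tok = WordTokenizer.build(["hello world", "world again"])
        assert tok.decode(tok.encode("hello world")) == "hello world"
        ids = tok.encode("<BOS> hello <SEP> world <EOS>")
        assert ids[0] == tok.bos_id and ids[-1] == tok.eos_id

    def test_unknown_words_map_to_unk(self):
        tok = WordTokenizer.build(["a b"])
        assert tok.decode(tok.encode("zzz"), skip_special=True) == ""

    def test_save_load(self, tmp_path):
        tok = WordTokenizer.build(["alpha beta gamma"])
        tok.save(tmp_path / "tok.json")
        loaded = WordTokenizer.load(tmp_path / "tok.json")
        assert loaded.itos == tok.itos
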