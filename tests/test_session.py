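"""Annotation session: loading, sorting, edits, finalization, export."""

import json

import pytest

from geomex.extraction import results_from_json
from geomex.model import TableLookupAdapter, TrainConfig
from geomex.records import RawSampleRecord
from geomex.schema import ATTRIBUTE_NAMES
from geomex.session import (
    OnlineConfig,
    SessionError,
    SessionState,
    UserEdit,
    apply_edit,
    export,
    finalize_sample,
    load_samples,
    load_session,
    make_resolver,
    oracle_user,
    save_session,
    sort_queue,
    stop_condition,
)


def _records(n, gse="GSE1"):
    return [
        RawSampleRecord(sample_id=f"GSM{i}", series_id=gse, fields={"title": f"t{i}"})
        for i in range(n)
    ]


def _fixture_session(records=None, table=None):
    return SessionState(adapter=TableLookupAdapter(table or {})), records or _records(3)


def _approve_all(session, sample_id):
    for attr in ATTRIBUTE_NAMES:
        apply_edit(session, sample_id, UserEdit(attr, "confirm"))


class TestLoading:
    def test_gsm_list(self):
        session, records = _fixture_session()
        load_samples(session, [r.sample_id for r in records], make_resolver(records))
        assert len(session.queue) == 3

    def test_gse_expands_to_members(self):
        session, _ = _fixture_session()
        records = _records(5, gse="GSE7")
        load_samples(session, ["GSE7"], make_resolver(records))
        assert len(session.queue) == 5

    def test_duplicates_deduplicated_and_errors_reported(self):
        session, records = _fixture_session()
        resolver = make_resolver(records)
        load_samples(session, ["GSM0", "GSM0", "GSE1", "GSMMISSING"], resolver)
        assert [r.sample_id for r in session.queue] == ["GSM0", "GSM1", "GSM2"]
        assert session.load_errors == ["GSMMISSING"]


class TestSorting:
    def _queue_with_green_counts(self, session, records, green_counts):
        # per-sample fixture tables: n attributes answered confidently
        resolver = make_resolver(records)
        table = {}
        for record, greens in zip(records, green_counts):
            text = f"[title]: {record.fields['title']}"
            for rank, attr in enumerate(ATTRIBUTE_NAMES):
                conf = 0.95 if rank < greens else 0.5
                prompt = f"<BOS> {text.lower()} <SEP> {attr.lower()}:"
                table[prompt] = {"value": conf, "<EOS>": 1 - conf}
                table[prompt + " value"] = {"<EOS>": 1.0}
        session.adapter = TableLookupAdapter(table)
        load_samples(session, [r.sample_id for r in records], resolver)

    def test_most_low_confidence_first(self):
        session, records = _fixture_session()
        # non-green counts [2, 0, 5] -> green counts [13, 15, 10]
        self._queue_with_green_counts(session, records, [13, 15, 10])
        sort_queue(session)
        assert [r.sample_id for r in session.queue] == ["GSM2", "GSM0", "GSM1"]

    def test_all_green_keeps_order(self):
        session, records = _fixture_session()
        self._queue_with_green_counts(session, records, [15, 15, 15])
        sort_queue(session)
        assert [r.sample_id for r in session.queue] == ["GSM0", "GSM1", "GSM2"]

    def test_stable_on_ties(self):
        session, records = _fixture_session()
        self._queue_with_green_counts(session, records, [12, 12, 15])
        sort_queue(session)
        assert [r.sample_id for r in session.queue] == ["GSM0", "GSM1", "GSM2"]

    def test_sort_is_a_permutation(self):
        session, records = _fixture_session()
        self._queue_with_green_counts(session, records, [13, 14, 12])
        before = sorted(r.sample_id for r in session.queue)
        sort_queue(session)
        assert sorted(r.sample_id for r in session.queue) == before


class TestEdits:
    def _loaded(self):
        session, records = _fixture_session()
        load_samples(session, ["GSM0"], make_resolver(records))
        return session

    def test_new_value_replaces(self):
        session = self._loaded()
        apply_edit(
            session,
            "GSM0",
            UserEdit("Tissue", "new-value", "haematopoietic and lymphoid tissue"),
        )
        pred = session.queue[0].predictions["Tissue"]
        assert pred.value == "haematopoietic and lymphoid tissue"
        assert pred.approved and pred.effective_light == "green"

    def test_confirm_keeps_value(self):
        session = self._loaded()
        before = session.queue[0].predictions["Sex"].value
        apply_edit(session, "GSM0", UserEdit("Sex", "confirm"))
        pred = session.queue[0].predictions["Sex"]
        assert pred.value == before and pred.approved

    def test_set_unknown(self):
        session = self._loaded()
        apply_edit(session, "GSM0", UserEdit("Age", "set-unknown"))
        assert session.queue[0].predictions["Age"].value == "unknown"

    def test_edit_validation(self):
        session = self._loaded()
        with pytest.raises(ValueError):
            UserEdit("Tissue", "new-value", "")
        with pytest.raises(ValueError):
            UserEdit("Tissue", "delete")
        with pytest.raises(SessionError):
            apply_edit(session, "GSM0", UserEdit("Flavour", "confirm"))


class TestFinalize:
    def test_requires_full_approval(self):
        session, records = _fixture_session()
        load_samples(session, ["GSM0"], make_resolver(records))
        with pytest.raises(SessionError, match="unapproved"):
            finalize_sample(session, "GSM0")

    def test_bookkeeping_and_store_growth(self):
        session, records = _fixture_session()
        # exclude unknown edits here to observe the store's minimal content
        session.online = OnlineConfig(include_unknown=False)
        load_samples(session, ["GSM0"], make_resolver(records))
        for attr in ATTRIBUTE_NAMES:
            action = UserEdit(attr, "new-value", "v") if attr == "Sex" else UserEdit(attr, "set-unknown")
            apply_edit(session, "GSM0", action)
        finalize_sample(session, "GSM0")
        assert session.queue == []
        assert len(session.annotated_store) == 1
        # unknown values are excluded; only the corrected Sex remains
        assert [ex.task for ex in session.augmentation_store] == ["sex:"]
        with pytest.raises(SessionError):
            apply_edit(session, "GSM0", UserEdit("Sex", "confirm"))

    def test_conservation_across_sort_edit_and_finalize(self):
        session, records = _fixture_session()
        load_samples(session, [r.sample_id for r in records], make_resolver(records))
        total = lambda: len(session.queue) + len(session.annotated_store)
        n0 = total()
        sort_queue(session)
        assert total() == n0
        apply_edit(session, session.queue[0].sample_id, UserEdit("Sex", "confirm"))
        assert total() == n0
        target = session.queue[0].sample_id
        _approve_all(session, target)
        finalize_sample(session, target)
        assert total() == n0
        assert len(session.queue) == n0 - 1


class TestStopCondition:
    def test_empty_queue_stops(self):
        session, _ = _fixture_session()
        assert stop_condition(session) is True

    def test_any_non_green_field_continues(self):
        prompt = "<BOS> [title]: t0 <SEP> sex:"
        session, records = _fixture_session(
            table={prompt: {"male": 0.7, "<EOS>": 0.3}, prompt + " male": {"<EOS>": 1.0}}
        )
        load_samples(session, ["GSM0"], make_resolver(records))
        assert session.queue[0].predictions["Sex"].traffic_light == "yellow"
        assert stop_condition(session) is False

    def test_all_approved_green_stops(self):
        session, records = _fixture_session()
        load_samples(session, ["GSM0"], make_resolver(records))
        _approve_all(session, "GSM0")
        assert stop_condition(session) is True


class TestExportAndCheckpoint:
    def test_empty_session_csv_header_only(self):
        session, _ = _fixture_session()
        text = export(session, "csv")
        lines = text.strip().splitlines()
        assert len(lines) == 1
        assert len(lines[0].split(",")) == 17

    def test_csv_row_matches_table(self):
        session, records = _fixture_session()
        load_samples(session, ["GSM0"], make_resolver(records))
        apply_edit(session, "GSM0", UserEdit("Tissue", "new-value", "liver"))
        _approve_all(session, "GSM0")
        finalize_sample(session, "GSM0")
        text = export(session, "csv")
        import io

        import pandas as pd

        frame = pd.read_csv(io.StringIO(text))
        assert frame.loc[0, "gsm"] == "GSM0"
        assert frame.loc[0, "Tissue"] == "liver"

    def test_json_round_trip(self):
        session, records = _fixture_session()
        load_samples(session, ["GSM0", "GSM1"], make_resolver(records))
        payload = json.loads(export(session, "json"))
        restored = results_from_json(json.dumps(payload["queue"]))
        assert restored == session.queue

    def test_checkpoint_round_trip(self, tmp_path):
        session, records = _fixture_session()
        load_samples(session, ["GSM0"], make_resolver(records))
        apply_edit(session, "GSM0", UserEdit("Sex", "new-value", "male"))
        save_session(session, tmp_path / "ckpt")
        restored = load_session(tmp_path / "ckpt", adapter=session.adapter)
        assert restored.queue == session.queue
        assert restored.augmentation_store == session.augmentation_store


class TestOnlineLearning:
    def test_finalize_retrains_and_duplicate_is_corrected(self, cloned_small_adapter, small_split):
        """After correcting one sample, an identical duplicate is predicted
        with the corrected value (online memorization)."""
        train, test = small_split
        base = [s for s in test if "Cell Line" in s.truth][0]
        record = base.record
        dup = RawSampleRecord(
            sample_id="GSMDUP",
            series_id=record.series_id,
            fields=dict(record.fields),
            characteristics=dict(record.characteristics),
        )
        dup.fields["gsm"] = "gsmdup"
        session = SessionState(
            adapter=cloned_small_adapter,
            train_config=TrainConfig(learning_rate=1e-3, batch_size=12, seed=0),
            online=OnlineConfig(seed=0),
        )
        from geomex.simulate import corpus_to_training_strings

        session.base_dataset = corpus_to_training_strings(train)
        load_samples(session, [record.sample_id, "GSMDUP"], make_resolver([record, dup]))

        corrected = "synthetic-novel-line"
        for attr in ATTRIBUTE_NAMES:
            if attr == "Cell Line":
                apply_edit(session, record.sample_id, UserEdit(attr, "new-value", corrected))
            else:
                truth = base.truth.get(attr)
                edit = (
                    UserEdit(attr, "new-value", truth)
                    if truth
                    else UserEdit(attr, "set-unknown")
                )
                apply_edit(session, record.sample_id, edit)
        finalize_sample(session, record.sample_id)
        dup_result = session.queue[0]
        assert dup_result.sample_id == "GSMDUP"
        assert dup_result.predictions["Cell Line"].value == corrected

    def test_oracle_user_builds_truth_edit_plan(self, small_split):
        _, test = small_split
        session, _ = _fixture_session()
        sample = test[0]
        load_samples(session, [sample.record.sample_id], make_resolver([sample.record]))
        plan = oracle_user({sample.record.sample_id: sample.truth})(session.queue[0])
        assert len(plan) == 15
        by_attr = {e.attribute: e for e in plan}
        for attr, value in sample.truth.items():
            edit = by_attr[attr]
            assert edit.action in ("confirm", "new-value")
            if edit.action == "new-value":
                assert edit.value == value.lower()
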