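import json
import zipfile

import numpy as np
import pytest

from protclass import (
    FeatureMatrix,
    ModelConfig,
    aac_scheme,
    default_config,
    dpc_scheme,
    featurize_dataset,
    load_model,
    predict,
    predict_fasta,
    pseaac_scheme,
    save_model,
    stratified_split,
    train,
)
from protclass.models import ALGORITHMS, ModelArchiveError
from protclass.sequence_io import ProteinRecord


def toy_matrix():
    """Four points split by the first feature's sign."""
    X = np.array([[-2.0, 0.1], [-1.0, -0.2], [1.0, 0.3], [2.0, -0.1]])
    return FeatureMatrix(
        ["a", "b", "c", "d"], X, aac_scheme(), np.array([0, 0, 1, 1]), ["AAC_A", "AAC_C"]
    )


class TestDefaultConfig:
    def test_svc_uses_printed_settings(self):
        cfg = default_config("svc", pseaac_scheme())
        assert cfg.hyperparameters["kernel"] == "rbf"
        assert cfg.hyperparameters["C"] == 10000
        assert cfg.hyperparameters["gamma"] == 100000
        assert cfg.hyperparameters["degree"] == 8  # recorded, inert under rbf
        assert cfg.hyperparameters["probability"] is True

    def test_rf_estimators_depend_on_scheme(self):
        assert default_config("rf", dpc_scheme()).hyperparameters["n_estimators"] == 150
        assert default_config("rf", aac_scheme()).hyperparameters["n_estimators"] == 50

    def test_lr_uses_printed_settings(self):
        hp = default_config("lr", aac_scheme()).hyperparameters
        assert (hp["C"], hp["tol"], hp["penalty"]) == (10, 0.1, "l2")

    def test_unknown_algorithm_lists_valid_names(self):
        with pytest.raises(ValueError, match="svc"):
            default_config("mlp", aac_scheme())

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="banana"):
            ModelConfig("rf", {"banana": 1})


class TestTrain:
    def test_separable_toy_set_memorized_by_svc(self):
        fm = toy_matrix()
        model = train(fm, default_config("svc", fm.scheme))
        assert (predict(model, fm)["label"].to_numpy() == fm.labels).all()

    def test_separable_toy_set_memorized_by_1nn(self):
        fm = toy_matrix()
        model = train(fm, ModelConfig("knn", {"n_neighbors": 1}))
        assert (predict(model, fm)["label"].to_numpy() == fm.labels).all()

    def test_single_class_rejected(self):
        fm = toy_matrix()
        fm.labels[:] = 1
        with pytest.raises(ValueError, match="both classes"):
            train(fm, default_config("rf", fm.scheme))

    def test_rf_training_is_deterministic(self, shifted_matrix):
        tr, te = stratified_split(shifted_matrix, 0.25, seed=3)
        cfg = default_config("rf", tr.scheme, seed=3)
        p1 = predict(train(tr, cfg), te)
        p2 = predict(train(tr, cfg), te)
        assert p1.equals(p2)

    @pytest.mark.parametrize("algo", [a for a in ALGORITHMS if a not in ("svc", "lr")])
    def test_registry_separates_shifted_classes(self, shifted_matrix, algo):
        """Non-degenerate registry members recover a strong planted signal.

        The printed SVC settings (gamma=1e5) and LR settings (tol=0.1)
        degenerate to memorization / majority voting and are exercised by
        the end-to-end acceptance suite instead.
        """
        tr, te = stratified_split(shifted_matrix, 0.25, seed=3)
        model = train(tr, default_config(algo, tr.scheme, seed=3))
        accuracy = (predict(model, te)["label"].to_numpy() == te.labels).mean()
        assert accuracy > 0.8


class TestPredict:
    def test_label_is_thresholded_probability(self, shifted_matrix):
        tr, te = stratified_split(shifted_matrix, 0.25, seed=3)
        model = train(tr, default_config("rf", tr.scheme, seed=3))
        table = predict(model, te)
        assert ((table["probability"] >= 0.5).astype(int) == table["label"]).all()
        assert table["probability"].between(0, 1).all()

    def test_scheme_mismatch_rejected(self, toy_dataset):
        fm_aac = featurize_dataset(toy_dataset, aac_scheme())
        fm_dpc = featurize_dataset(toy_dataset, dpc_scheme())
        model = train(fm_aac, default_config("rf", fm_aac.scheme))
        with pytest.raises(ValueError, match="scheme mismatch"):
            predict(model, fm_dpc)


class TestPredictFasta:
    def test_short_sequence_gets_error_entry_and_run_continues(self, toy_dataset):
        fm = featurize_dataset(toy_dataset, pseaac_scheme(lam=5))
        model = train(fm, default_config("rf", fm.scheme))
        records = [ProteinRecord("tiny", "", "MKV")] + toy_dataset.records[:2]
        table = predict_fasta(model, records)
        assert len(table) == 3
        assert table.loc[0, "error"] != ""
        assert (table.loc[1:, "error"] == "").all()

    def test_reproduces_training_time_predictions(self, toy_dataset):
        fm = featurize_dataset(toy_dataset, pseaac_scheme(lam=5))
        model = train(fm, default_config("rf", fm.scheme))
        direct = predict(model, fm)
        via_fasta = predict_fasta(model, toy_dataset.records)
        np.testing.assert_allclose(
            via_fasta["probability"].to_numpy(float), direct["probability"].to_numpy()
        )

    def test_empty_record_list_gives_empty_table(self, toy_dataset):
        fm = featurize_dataset(toy_dataset, aac_scheme())
        model = train(fm, default_config("rf", fm.scheme))
        table = predict_fasta(model, [])
        assert len(table) == 0
        assert list(table.columns) == ["id", "label", "probability", "error"]


class TestArchive:
    def test_round_trip_preserves_predictions_and_provenance(self, shifted_matrix, tmp_path):
        tr, te = stratified_split(shifted_matrix, 0.25, seed=3)
        model = train(tr, default_config("xgb", tr.scheme, seed=3))
        path = tmp_path / "model.zip"
        save_model(model, path)
        back = load_model(path)
        assert back.provenance == json.loads(json.dumps(model.provenance))
        np.testing.assert_array_equal(
            predict(back, te)["probability"].to_numpy(),
            predict(model, te)["probability"].to_numpy(),
        )

    def test_truncated_archive_rejected(self, toy_dataset, tmp_path):
        fm = featurize_dataset(toy_dataset, aac_scheme())
        model = train(fm, default_config("dt", fm.scheme))
        path = tmp_path / "model.zip"
        save_model(model, path)
        path.write_bytes(path.read_bytes()[:100])
        with pytest.raises(ModelArchiveError):
            load_model(path)

    def test_version_mismatch_rejected(self, toy_dataset, tmp_path):
        fm = featurize_dataset(toy_dataset, aac_scheme())
        model = train(fm, default_config("dt", fm.scheme))
        path = tmp_path / "model.zip"
        save_model(model, path)
        with zipfile.ZipFile(path) as archive:
            metadata = json.loads(archive.read("metadata.json"))
            payload = archive.read("model.joblib")
        metadata["format_version"] = 99
        bad = tmp_path / "bad.zip"
        with zipfile.ZipFile(bad, "w") as archive:
            archive.writestr("metadata.json", json.dumps(metadata))
            archive.writestr("model.joblib", payload)
        with pytest.raises(ModelArchiveError, match="version"):
            load_model(bad)

    def test_prediction_from_archive_alone(self, toy_dataset, tmp_path):
        """predict-from-FASTA is fully determined by the archive contents."""
        fm = featurize_dataset(toy_dataset, pseaac_scheme(lam=5))
        model = train(fm, default_config("rf", fm.scheme))
        before = predict_fasta(model, toy_dataset.records)
        path = tmp_path / "model.zip"
        save_model(model, path)
        after = predict_fasta(load_model(path), toy_dataset.records)
        np.testing.assert_allclose(
            after["probability"].to_numpy(float), before["probability"].to_numpy(float)
        )
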