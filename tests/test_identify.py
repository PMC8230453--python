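"""Serializable identification: training, chaining, XML round trips."""

import numpy as np
import pytest

from wingmorph.identify import (
    ClassifierFormatError, ClassifierSpec, classify_sample,
    read_classifier_xml, train_classifier, write_classifier_xml,
)
from wingmorph.landmark_io import LandmarkConfiguration, Sample
from wingmorph.shapespace import fit_groups, lda_classify, pca
from wingmorph.superimpose import gpa
from wingmorph import synthgen


@pytest.fixture(scope="module")
def trained():
    """A two-stage classifier trained on a 3-group synthetic study."""
    groups = [
        synthgen.GroupSpec("carpatica_intra", 10, area="intra", wings_mean=6),
        synthgen.GroupSpec("carpatica_extra", 10, area="extra",
                           ln_cs_mean=6.44, wings_mean=6),
        synthgen.GroupSpec("carnica", 10, area="reference",
                           reference_taxon="carnica", geography="carnica",
                           wings_mean=6),
    ]
    d2 = np.array([
        [0.0, 9.0, 80.0],
        [9.0, 0.0, 90.0],
        [80.0, 90.0, 0.0],
    ])
    cfg = synthgen.SyntheticConfig(groups=groups, target_d2=d2)
    samples, truth = synthgen.simulate_study(cfg, seed=21, return_truth=True)
    aligned = gpa(samples)
    means, order = aligned.sample_means()
    meta = samples.metadata_frame().loc[order]

    stage1_labels = [
        "carpatica" if a != "reference" else "carnica" for a in meta["area"]
    ]
    stage1 = train_classifier(
        means, stage1_labels, aligned.consensus, name="subspecies", k=10,
        chain={"carpatica": "subpopulation"},
    )
    rom = (meta["area"] != "reference").to_numpy()
    stage2 = train_classifier(
        means[rom], list(meta["area"][rom]), aligned.consensus,
        name="subpopulation", k=10,
    )
    return samples, means, order, meta, stage1, stage2


class TestTraining:
    def test_spec_reproduces_in_memory_classification(self, trained):
        _, means, order, meta, stage1, _ = trained
        space = pca(means, k=10)
        labels = ["carpatica" if a != "reference" else "carnica"
                  for a in meta["area"]]
        model = fit_groups(space.scores, labels)
        for i in range(len(means)):
            in_memory, _ = lda_classify(model, space.scores[i])
            via_spec, _ = lda_classify(
                stage1.group_model(), (means[i] - stage1.mean_vector) @ stage1.basis
            )
            assert in_memory == via_spec

    def test_training_colonies_classified_into_their_groups(self, trained):
        samples, _, order, meta, stage1, stage2 = trained
        correct = 0
        for sid in order:
            path = classify_sample([stage1, stage2], samples[sid])
            expected = (
                "carnica" if meta.loc[sid, "area"] == "reference"
                else meta.loc[sid, "area"]
            )
            correct += path.final_label == expected
        assert correct >= 27  # 90% of 30 well-separated colonies


class TestChaining:
    def test_reference_sample_stops_after_stage_one(self, trained):
        samples, _, order, meta, stage1, stage2 = trained
        sid = meta[meta["area"] == "reference"].index[0]
        path = classify_sample([stage1, stage2], samples[sid])
        assert path.labels == ["carnica"]
        assert "no chained" in path.stopped_reason

    def test_native_sample_follows_two_stages(self, trained):
        samples, _, order, meta, stage1, stage2 = trained
        sid = meta[meta["area"] == "intra"].index[0]
        path = classify_sample([stage1, stage2], samples[sid])
        assert path.labels[0] == "carpatica"
        assert path.labels[1] in ("intra", "extra")
        assert [s.classifier_name for s in path.stages] == \
            ["subspecies", "subpopulation"]

    def test_decision_matches_brute_force_distances(self, trained):
        samples, _, order, _, stage1, stage2 = trained
        sid = order[0]
        path = classify_sample([stage1, stage2], samples[sid])
        for stage, spec in zip(path.stages, (stage1, stage2)):
            scores = np.vstack([
                spec.project_wing(c) for c in samples[sid].configurations
            ])
            x = scores.mean(axis=0)
            Sinv = np.linalg.pinv(spec.pooled_covariance)
            d2 = {
                g: float((x - m) @ Sinv @ (x - m))
                for g, m in zip(spec.group_labels, spec.group_means)
            }
            assert stage.label == min(d2, key=d2.get)
            for g in d2:
                assert stage.distances[g] == pytest.approx(d2[g], rel=1e-9)

    def test_missing_chain_target_errors(self, trained):
        samples, _, order, meta, stage1, _ = trained
        sid = meta[meta["area"] == "intra"].index[0]
        with pytest.raises(ValueError, match="unknown"):
            classify_sample([stage1], samples[sid])

    def test_empty_sample_rejected(self, trained):
        *_, stage1, stage2 = trained
        with pytest.raises(ValueError, match="no wings"):
            classify_sample([stage1, stage2], Sample("empty", [], year=2016))

    def test_deterministic_path(self, trained):
        samples, _, order, _, stage1, stage2 = trained
        p1 = classify_sample([stage1, stage2], samples[order[0]])
        p2 = classify_sample([stage1, stage2], samples[order[0]])
        assert p1.labels == p2.labels
        assert p1.stages[0].distances == p2.stages[0].distances


class TestXml:
    def test_round_trip_preserves_every_numeric_field(self, trained, tmp_path):
        *_, stage1, _ = trained
        path = tmp_path / "stage1.xml"
        write_classifier_xml(stage1, path)
        back = read_classifier_xml(path)
        assert back.name == stage1.name
        assert back.convention == stage1.convention
        assert back.chain == stage1.chain
        assert back.group_labels == stage1.group_labels
        for attr in ("consensus", "mean_vector", "basis", "group_means",
                     "pooled_covariance", "counts"):
            assert np.array_equal(getattr(back, attr), getattr(stage1, attr)), attr

    def test_serialized_classification_equals_in_memory(self, trained, tmp_path):
        samples, means, order, _, stage1, stage2 = trained
        write_classifier_xml(stage1, tmp_path / "s1.xml")
        write_classifier_xml(stage2, tmp_path / "s2.xml")
        chain = [read_classifier_xml(tmp_path / "s1.xml"),
                 read_classifier_xml(tmp_path / "s2.xml")]
        rng = np.random.default_rng(3)
        for _ in range(200):
            sid = order[rng.integers(len(order))]
            mem = classify_sample([stage1, stage2], samples[sid])
            ser = classify_sample(chain, samples[sid])
            assert mem.labels == ser.labels
            for a, b in zip(mem.stages, ser.stages):
                for g in a.distances:
                    assert a.distances[g] == pytest.approx(b.distances[g], abs=1e-9)

    def test_truncated_file_names_missing_element(self, trained, tmp_path):
        *_, stage1, _ = trained
        path = tmp_path / "s.xml"
        write_classifier_xml(stage1, path)
        text = path.read_text()
        cut = text[: text.index("<pooled_covariance>")] + "</wingmorph-classifier>"
        bad = tmp_path / "bad.xml"
        bad.write_text(cut)
        with pytest.raises(ClassifierFormatError, match="pooled_covariance"):
            read_classifier_xml(bad)

    def test_not_xml_rejected(self, tmp_path):
        p = tmp_path / "junk.xml"
        p.write_text("LM=19\n0 0\n")
        with pytest.raises(ClassifierFormatError, match="well-formed"):
            read_classifier_xml(p)

    def test_handwritten_minimal_four_landmark_spec(self, tmp_path):
        # 2 groups in a 1-component space over 4 landmarks (8 variables)
        consensus = np.array([[0.5, 0.5], [-0.5, 0.5], [-0.5, -0.5], [0.5, -0.5]])
        consensus = consensus / np.linalg.norm(consensus)
        basis = np.zeros((8, 1))
        basis[0, 0] = 1.0
        spec = ClassifierSpec(
            name="toy", convention="square-4", consensus=consensus,
            mean_vector=np.zeros(8), basis=basis,
            group_labels=["low", "high"],
            group_means=np.array([[-0.1], [0.1]]),
            pooled_covariance=np.array([[0.01]]),
            counts=np.array([5, 5]),
        )
        path = tmp_path / "toy.xml"
        write_classifier_xml(spec, path)
        loaded = read_classifier_xml(path)
        wing = LandmarkConfiguration(consensus * 100 + 3.0, "w", side="right")
        decision = classify_sample(loaded, Sample("s", [wing], year=2016))
        assert decision.final_label in ("low", "high")
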