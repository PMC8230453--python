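"""Serializable linear-discriminant identification of wing samples.

The study's practical deliverable is identification data: everything
needed to classify a new wing sample without refitting — the alignment
target (consensus shape), the projection basis, group means and the pooled
within-group covariance, plus a chaining rule so a first-stage decision
(e.g. "this is the native subspecies") can hand over to a second-stage
classifier (e.g. "which subpopulation").

The XML dialect here is a documented, versioned schema of this package
(``wingmorph-classifier`` version 1); byte compatibility with any external
tool's identification files is not claimed.  Numbers are serialized with
full ``repr`` precision, so write/read round trips are lossless.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .landmark_io import LandmarkConfiguration, Sample
from .superimpose import align_to_reference
from .shapespace import GroupModel, fit_groups, lda_classify, mahalanobis_sq_point

logger = logging.getLogger(__name__)

SCHEMA_NAME = "wingmorph-classifier"
SCHEMA_VERSION = "1"


class ClassifierFormatError(ValueError):
    """A classifier XML file violates the documented schema."""


@dataclass
class ClassifierSpec:
    """Self-contained linear identification data for one decision stage."""

    name: str
    convention: str  # landmark convention id, e.g. "identifly-19"
    consensus: np.ndarray  # (19, 2) alignment target
    mean_vector: np.ndarray  # (38,) centring vector of the projection
    basis: np.ndarray  # (38, k) projection basis
    group_labels: list[str]
    group_means: np.ndarray  # (g, k)
    pooled_covariance: np.ndarray  # (k, k)
    counts: np.ndarray  # (g,)
    chain: dict[str, str] = field(default_factory=dict)  # label -> next classifier name

    def __post_init__(self) -> None:
        k = self.basis.shape[1]
        g = len(self.group_labels)
        if self.group_means.shape != (g, k):
            raise ValueError("group_means shape inconsistent with basis/labels")
        if self.pooled_covariance.shape != (k, k):
            raise ValueError("pooled_covariance shape inconsistent with basis")
        if self.consensus.shape[0] * 2 != self.basis.shape[0]:
            raise ValueError("consensus and basis dimensions disagree")

    def group_model(self) -> GroupModel:
        g = len(self.group_labels)
        return GroupModel(
            labels=list(self.group_labels),
            means=self.group_means,
            pooled_covariance=self.pooled_covariance,
            df=int(self.counts.sum()) - g,
            counts=self.counts,
            priors=np.full(g, 1.0 / g),
        )

    def project_wing(self, cfg: LandmarkConfiguration, mirror_left: bool = True) -> np.ndarray:
        """Superimpose one wing on the stored consensus and project it."""
        pts = cfg.points
        if mirror_left and cfg.side == "left":
            pts = pts * np.array([-1.0, 1.0])
        t = align_to_reference(pts, self.consensus)
        return (t - self.mean_vector) @ self.basis


def train_classifier(
    colony_means: np.ndarray,
    labels: Sequence[str],
    consensus: np.ndarray,
    name: str,
    convention: str = "identifly-19",
    k: int = 34,
    chain: Optional[dict[str, str]] = None,
) -> ClassifierSpec:
    """Train identification data from colony-mean tangent coordinates.

    Runs PCA (k components) on the colony means and fits group means plus
    the pooled within-group covariance in score space.  Classifying any
    training mean through the resulting spec equals classifying it through
    the in-memory model.
    """
    from .shapespace import pca  # local import to avoid cycle at module load

    X = np.atleast_2d(np.asarray(colony_means, dtype=float))
    space = pca(X, k=k)
    model = fit_groups(space.scores, list(labels))
    return ClassifierSpec(
        name=name,
        convention=convention,
        consensus=np.asarray(consensus, dtype=float),
        mean_vector=space.mean_vector,
        basis=space.basis,
        group_labels=[str(l) for l in model.labels],
        group_means=model.means,
        pooled_covariance=model.pooled_covariance,
        counts=model.counts,
        chain=dict(chain or {}),
    )


@dataclass
class StageDecision:
    classifier_name: str
    label: str
    distances: dict[str, float]  # squared Mahalanobis to each group mean


@dataclass
class DecisionPath:
    stages: list[StageDecision]
    stopped_reason: str

    @property
    def final_label(self) -> str:
        return self.stages[-1].label

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.stages]


def classify_sample(
    specs: Union[ClassifierSpec, Sequence[ClassifierSpec]],
    sample: Sample,
    mirror_left: bool = True,
    aggregate: str = "mean",
) -> DecisionPath:
    """Run a (possibly chained) identification on one sample.

    Each wing is superimposed on the stage's consensus and projected; the
    sample is represented by the mean of per-wing scores (``aggregate=
    "mean"``, the default, mirroring colony-level averaging) or by a
    majority vote of per-wing labels (``aggregate="vote"``).  After stage
    1, a further stage runs iff the decided label has an entry in the
    stage's chaining map; the path records every stage's distances and why
    it stopped.
    """
    chain = [specs] if isinstance(specs, ClassifierSpec) else list(specs)
    if not chain:
        raise ValueError("no classifier given")
    by_name = {s.name: s for s in chain}
    if sample.n_wings < 1:
        raise ValueError(f"sample {sample.sample_id} has no wings")
    for cfg in sample.configurations:
        if not np.isfinite(cfg.points).all():
            raise ValueError(f"wing {cfg.wing_id}: non-finite coordinates")
        if cfg.n_landmarks != chain[0].consensus.shape[0]:
            raise ValueError(
                f"wing {cfg.wing_id}: {cfg.n_landmarks} landmarks, classifier "
                f"convention {chain[0].convention!r} expects "
                f"{chain[0].consensus.shape[0]}"
            )

    stages: list[StageDecision] = []
    spec: Optional[ClassifierSpec] = chain[0]
    reason = ""
    while spec is not None:
        model = spec.group_model()
        scores = np.vstack(
            [spec.project_wing(c, mirror_left=mirror_left) for c in sample.configurations]
        )
        if aggregate == "vote":
            votes = [lda_classify(model, s)[0] for s in scores]
            label = max(spec.group_labels, key=votes.count)
            d2 = mahalanobis_sq_point(model, scores.mean(axis=0))
        elif aggregate == "mean":
            x = scores.mean(axis=0)
            label, _ = lda_classify(model, x)
            d2 = mahalanobis_sq_point(model, x)
        else:
            raise ValueError(f"unknown aggregate {aggregate!r}")
        stages.append(
            StageDecision(spec.name, str(label), dict(zip(spec.group_labels, d2)))
        )
        nxt = spec.chain.get(str(label))
        if nxt is None:
            reason = f"label {label!r} has no chained classifier"
            spec = None
        elif nxt not in by_name:
            raise ValueError(
                f"chain of {stages[-1].classifier_name!r} references unknown "
                f"classifier {nxt!r}"
            )
        else:
            spec = by_name[nxt]
    return DecisionPath(stages=stages, stopped_reason=reason)


# ---------------------------------------------------------------------------
# XML serialization
# ---------------------------------------------------------------------------

def _matrix_text(a: np.ndarray) -> str:
    return "\n".join(" ".join(repr(float(v)) for v in row) for row in np.atleast_2d(a))


def _parse_matrix(el: Optional[ET.Element], path: str, shape: tuple) -> np.ndarray:
    if el is None or el.text is None:
        raise ClassifierFormatError(f"missing element {path}")
    try:
        rows = [
            [float(tok) for tok in line.split()]
            for line in el.text.strip().splitlines()
        ]
        a = np.array(rows, dtype=float)
    except ValueError as exc:
        raise ClassifierFormatError(f"non-numeric content in {path}") from exc
    if a.shape != shape:
        raise ClassifierFormatError(
            f"{path}: expected shape {shape}, got {a.shape}"
        )
    return a


def write_classifier_xml(spec: ClassifierSpec, path: str | Path) -> None:
    """Serialize a classifier spec in the documented XML dialect."""
    root = ET.Element(
        SCHEMA_NAME,
        attrib={
            "version": SCHEMA_VERSION,
            "name": spec.name,
            "convention": spec.convention,
            "n_landmarks": str(spec.consensus.shape[0]),
            "n_components": str(spec.basis.shape[1]),
        },
    )
    ET.SubElement(root, "consensus").text = _matrix_text(spec.consensus)
    ET.SubElement(root, "mean_vector").text = _matrix_text(spec.mean_vector)
    ET.SubElement(root, "basis").text = _matrix_text(spec.basis)
    groups = ET.SubElement(root, "groups")
    for i, label in enumerate(spec.group_labels):
        gel = ET.SubElement(
            groups, "group", attrib={"label": label, "count": str(int(spec.counts[i]))}
        )
        ET.SubElement(gel, "mean").text = _matrix_text(spec.group_means[i])
    ET.SubElement(root, "pooled_covariance").text = _matrix_text(spec.pooled_covariance)
    chain = ET.SubElement(root, "chain")
    for label, nxt in spec.chain.items():
        ET.SubElement(chain, "when", attrib={"label": label, "use": nxt})
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def read_classifier_xml(path: str | Path) -> ClassifierSpec:
    """Read a classifier spec; schema violations name the offending element."""
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ClassifierFormatError(f"not well-formed XML: {exc}") from exc
    if root.tag != SCHEMA_NAME:
        raise ClassifierFormatError(
            f"root element {root.tag!r}, expected {SCHEMA_NAME!r}"
        )
    if root.get("version") != SCHEMA_VERSION:
        raise ClassifierFormatError(
            f"unsupported schema version {root.get('version')!r}"
        )
    try:
        n_lm = int(root.attrib["n_landmarks"])
        k = int(root.attrib["n_components"])
        name = root.attrib["name"]
        convention = root.attrib["convention"]
    except KeyError as exc:
        raise ClassifierFormatError(f"missing root attribute {exc}") from exc

    consensus = _parse_matrix(root.find("consensus"), "consensus", (n_lm, 2))
    mean_vector = _parse_matrix(
        root.find("mean_vector"), "mean_vector", (1, 2 * n_lm)
    ).ravel()
    basis = _parse_matrix(root.find("basis"), "basis", (2 * n_lm, k))
    groups_el = root.find("groups")
    if groups_el is None or len(groups_el) == 0:
        raise ClassifierFormatError("missing element groups/group")
    labels, means, counts = [], [], []
    for gel in groups_el:
        label = gel.get("label")
        if label is None:
            raise ClassifierFormatError("group element without label attribute")
        labels.append(label)
        counts.append(int(gel.get("count", "1")))
        means.append(
            _parse_matrix(gel.find("mean"), f"group[{label}]/mean", (1, k)).ravel()
        )
    pooled = _parse_matrix(root.find("pooled_covariance"), "pooled_covariance", (k, k))
    chain = {}
    chain_el = root.find("chain")
    if chain_el is not None:
        for w in chain_el:
            chain[w.attrib["label"]] = w.attrib["use"]
    return ClassifierSpec(
        name=name,
        convention=convention,
        consensus=consensus,
        mean_vector=mean_vector,
        basis=basis,
        group_labels=labels,
        group_means=np.vstack(means),
        pooled_covariance=pooled,
        counts=np.array(counts, dtype=int),
        chain=chain,
    )
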