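"""Classic univariate wing characters: wing size and the cubital index.

Wing size is the natural logarithm of centroid size; at the reference image
resolution of 2400 dpi it is directly comparable across studies using the
same convention.  The cubital index is the ratio of two vein-segment
lengths of the cubital cell, a traditional honey bee race character; it is
dimensionless and therefore computed on the raw (unaligned) landmarks.

Which landmark pairs bound the cubital veins is a convention of the
landmarking scheme, not something the coordinates themselves declare, so
the pairs ship as a named, editable :class:`CubitalIndexConvention`
("identifly-19" by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landmark_io import LandmarkConfiguration, SampleSet, N_LANDMARKS
from .superimpose import centroid_size

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CubitalIndexConvention:
    """Landmark index pairs (0-based) spanning the two cubital vein segments."""

    name: str
    vein_a: tuple[int, int]
    vein_b: tuple[int, int]

    def __post_init__(self) -> None:
        idx = (*self.vein_a, *self.vein_b)
        if any(not (0 <= i < N_LANDMARKS) for i in idx):
            raise ValueError(f"landmark indices out of range 0..18: {idx}")
        if self.vein_a[0] == self.vein_a[1] or self.vein_b[0] == self.vein_b[1]:
            raise ValueError("degenerate vein: identical endpoints")
        if set(self.vein_a) == set(self.vein_b):
            raise ValueError("vein_a and vein_b must differ")


#: default convention for the 19-landmark scheme used throughout the package
IDENTIFLY_19 = CubitalIndexConvention("identifly-19", vein_a=(15, 16), vein_b=(16, 17))


def wing_size(c: LandmarkConfiguration) -> float:
    """ln(centroid size); on the conventional scale at 2400 dpi."""
    return math.log(centroid_size(c))


def cubital_index(
    c: LandmarkConfiguration, conv: CubitalIndexConvention = IDENTIFLY_19
) -> float:
    """Length of vein_a divided by length of vein_b.

    Invariant to translation, rotation, reflection and uniform scaling of
    the configuration.
    """
    pts = np.asarray(c.points, dtype=float)
    la = float(np.linalg.norm(pts[conv.vein_a[0]] - pts[conv.vein_a[1]]))
    lb = float(np.linalg.norm(pts[conv.vein_b[0]] - pts[conv.vein_b[1]]))
    if lb <= 0.0:
        raise ValueError(f"vein_b {conv.vein_b} has zero length")
    return la / lb


def sample_trait_table(
    samples: SampleSet, conv: CubitalIndexConvention = IDENTIFLY_19
) -> pd.DataFrame:
    """Colony-level trait table: per-sample mean cubital index and ln CS.

    One row per non-empty sample with its metadata; empty samples are
    excluded with a log entry.  Means are plain arithmetic means over wings.
    """
    rows = []
    for s in samples:
        if s.n_wings == 0:
            logger.warning("sample %s has no wings; excluded from trait table", s.sample_id)
            continue
        ci = [cubital_index(c, conv) for c in s.configurations]
        ln_cs = [wing_size(c) for c in s.configurations]
        rows.append(
            s.metadata()
            | {
                "n_wings": s.n_wings,
                "cubital_index": float(np.mean(ci)),
                "ln_centroid_size": float(np.mean(ln_cs)),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
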