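"""Reading, validating and writing wing landmark configurations.

A wing is an ordered set of 19 two-dimensional landmarks digitized on a
forewing image at a known resolution (default 2400 dpi).  Two on-disk
dialects are supported:

* TPS — the community landmark interchange format: ``LM=19`` followed by
  19 ``x y`` lines, then ``IMAGE=``/``ID=`` and an optional ``SCALE=``
  line (interpreted as mm per pixel).  TPS carries coordinates only;
  sample metadata is joined from a separate table.
* a flat CSV with one wing per row (``wing_id, sample_id, side,
  x1..x19, y1..y19`` plus metadata columns), convenient for spreadsheets.

Landmark indices are 0-based in memory; TPS point order is written in the
conventional 1-based file order.  The in-memory coordinate convention is
x rightward, y upward; CSVs digitized with an image origin (y down) can be
read with ``y_down=True`` which flips the y axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_LANDMARKS = 19
N_VARIABLES = 2 * N_LANDMARKS  # each landmark contributes an x and a y

#: metadata columns understood by the CSV dialect, in canonical order
METADATA_COLUMNS = (
    "source",
    "year",
    "area",
    "reference_taxon",
    "latitude",
    "longitude",
    "altitude",
    "mean_annual_temperature",
)


class LandmarkFormatError(ValueError):
    """A landmark file violates the documented dialect."""


class MetadataJoinError(KeyError):
    """A wing record has no matching row in the metadata table."""


@dataclass
class LandmarkConfiguration:
    """One digitized wing: 19 ordered landmarks plus acquisition context."""

    points: np.ndarray
    wing_id: str = ""
    side: str = "right"
    resolution_dpi: float = 2400.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(
                f"points must be an (n, 2) array, got shape {self.points.shape}"
            )

    @property
    def n_landmarks(self) -> int:
        return self.points.shape[0]

    def flat(self) -> np.ndarray:
        """Coordinates flattened landmark-major: x1, y1, x2, y2, ..."""
        return self.points.reshape(-1)


@dataclass
class Sample:
    """A colony (or flower-site) collection of wings with its metadata."""

    sample_id: str
    configurations: list[LandmarkConfiguration]
    source: str = "colony"  # "colony" | "flowers"
    year: int = 2016
    area: str = "intra"  # "intra" | "extra" | "reference"
    reference_taxon: Optional[str] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    altitude: Optional[float] = None
    mean_annual_temperature: Optional[float] = None

    @property
    def period(self) -> str:
        """Collection period: strictly before the year 2000, or after."""
        return "pre2000" if self.year < 2000 else "post2000"

    @property
    def n_wings(self) -> int:
        return len(self.configurations)

    def metadata(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "source": self.source,
            "year": self.year,
            "period": self.period,
            "area": self.area,
            "reference_taxon": self.reference_taxon,
            "latitude": self.latitude,
            "longitude": self.longitude,
            "altitude": self.altitude,
            "mean_annual_temperature": self.mean_annual_temperature,
        }


@dataclass
class SampleSet:
    """An ordered collection of samples with unique ids."""

    samples: list[Sample] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[Sample]:
        return iter(self.samples)

    def __getitem__(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    @property
    def n_wings(self) -> int:
        return sum(s.n_wings for s in self.samples)

    def iter_wings(self) -> Iterator[tuple[Sample, LandmarkConfiguration]]:
        for s in self.samples:
            for c in s.configurations:
                yield s, c

    def metadata_frame(self) -> pd.DataFrame:
        """One row per sample, indexed by sample_id."""
        rows = [s.metadata() | {"n_wings": s.n_wings} for s in self.samples]
        return pd.DataFrame(rows).set_index("sample_id")


def validate_configuration(c: LandmarkConfiguration) -> list[str]:
    """Return all invariant violations of a configuration (never raises).

    An empty list means the wing is well formed: exactly 19 landmarks,
    finite coordinates, positive resolution and no coincident landmarks.
    """
    violations: list[str] = []
    n = c.n_landmarks
    if n != N_LANDMARKS:
        violations.append(f"landmark count {n} != {N_LANDMARKS}")
    bad = np.flatnonzero(~np.isfinite(c.points).all(axis=1))
    for i in bad:
        violations.append(f"landmark {i}: non-finite coordinate")
    if not (np.isfinite(c.resolution_dpi) and c.resolution_dpi > 0):
        violations.append(f"resolution_dpi {c.resolution_dpi} is not positive")
    if c.side not in ("left", "right"):
        violations.append(f"side {c.side!r} is neither 'left' nor 'right'")
    if len(bad) == 0 and n > 1:
        # pairwise coincidence check; n is tiny so the O(n^2) scan is fine
        d2 = np.sum((c.points[:, None, :] - c.points[None, :, :]) ** 2, axis=-1)
        ii, jj = np.nonzero(np.triu(d2 < 1e-12, k=1))
        for i, j in zip(ii, jj):
            violations.append(f"landmarks {i} and {j} coincide")
    return violations


def _require_valid(c: LandmarkConfiguration) -> None:
    v = validate_configuration(c)
    if v:
        raise ValueError(f"invalid configuration {c.wing_id!r}: " + "; ".join(v))


# ---------------------------------------------------------------------------
# TPS dialect
# ---------------------------------------------------------------------------

def _parse_tps_records(text: str) -> list[dict]:
    records: list[dict] = []
    current: Optional[dict] = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        upper = key.upper()
        if upper == "LM":
            current = {"lm": int(value), "points": [], "lineno": lineno}
            records.append(current)
        elif current is None:
            raise LandmarkFormatError(
                f"line {lineno}: content before the first LM= record"
            )
        elif upper in ("IMAGE", "ID", "SCALE"):
            current[upper.lower()] = value.strip()
        else:
            parts = line.split()
            if len(parts) != 2:
                raise LandmarkFormatError(
                    f"line {lineno}: expected 'x y' coordinate pair, got {line!r}"
                )
            try:
                current["points"].append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise LandmarkFormatError(
                    f"line {lineno}: non-numeric coordinate in {line!r}"
                ) from exc
    return records


def read_tps(
    path: str | Path,
    metadata: Optional[pd.DataFrame] = None,
) -> SampleSet:
    """Read a TPS landmark file into a :class:`SampleSet`.

    ``metadata``, if given, is indexed by (or contains a column) ``wing_id``
    and supplies ``sample_id``, ``side`` and the per-sample metadata columns;
    every wing must have a row.  Without a table, wings are grouped into
    samples by the wing_id prefix before the last ``-``.
    """
    path = Path(path)
    records = _parse_tps_records(path.read_text(encoding="utf-8"))
    if metadata is not None and "wing_id" in metadata.columns:
        metadata = metadata.set_index("wing_id")

    configs: list[tuple[str, LandmarkConfiguration]] = []  # (sample_id, cfg)
    for idx, rec in enumerate(records):
        if rec["lm"] != len(rec["points"]):
            raise LandmarkFormatError(
                f"record {idx}: LM={rec['lm']} but {len(rec['points'])} "
                "coordinate lines"
            )
        if rec["lm"] != N_LANDMARKS:
            raise LandmarkFormatError(
                f"record {idx}: LM={rec['lm']} != {N_LANDMARKS}"
            )
        wing_id = rec.get("image") or rec.get("id") or f"wing{idx}"
        dpi = 2400.0
        if "scale" in rec:
            mm_per_px = float(rec["scale"])
            if mm_per_px > 0:
                dpi = 25.4 / mm_per_px
        side = "right"
        if metadata is not None:
            if wing_id not in metadata.index:
                raise MetadataJoinError(
                    f"wing_id {wing_id!r} missing from metadata table"
                )
            row = metadata.loc[wing_id]
            sample_id = str(row["sample_id"])
            side = str(row.get("side", "right"))
        else:
            sample_id = wing_id.rsplit("-", 1)[0]
        configs.append(
            (
                sample_id,
                LandmarkConfiguration(
                    np.array(rec["points"]), wing_id=wing_id, side=side,
                    resolution_dpi=dpi,
                ),
            )
        )

    samples: dict[str, Sample] = {}
    for sample_id, cfg in configs:
        if sample_id not in samples:
            meta: dict = {}
            if metadata is not None:
                row = metadata.loc[cfg.wing_id]
                for col in METADATA_COLUMNS:
                    if col in row.index and pd.notna(row[col]):
                        meta[col] = row[col]
                if "year" in meta:
                    meta["year"] = int(meta["year"])
            samples[sample_id] = Sample(sample_id, [], **meta)
        samples[sample_id].configurations.append(cfg)
    return SampleSet(list(samples.values()), provenance=f"read_tps({path.name})")


def write_tps(samples: SampleSet, path: str | Path) -> None:
    """Write all wings of a sample set as a TPS file (one record per wing)."""
    lines: list[str] = []
    i = 0
    for _, cfg in samples.iter_wings():
        lines.append(f"LM={cfg.n_landmarks}")
        for x, y in cfg.points:
            lines.append(f"{float(x)!r} {float(y)!r}")
        lines.append(f"IMAGE={cfg.wing_id}")
        lines.append(f"ID={i}")
        lines.append(f"SCALE={float(25.4 / cfg.resolution_dpi)!r}")
        i += 1
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _coordinate_columns() -> list[str]:
    return [f"x{i}" for i in range(1, N_LANDMARKS + 1)] + [
        f"y{i}" for i in range(1, N_LANDMARKS + 1)
    ]


def read_landmark_csv(path: str | Path, y_down: bool = False) -> SampleSet:
    """Read the one-wing-per-row CSV dialect.

    ``y_down=True`` flips the y axis for files digitized in image
    coordinates (origin top-left).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["wing_id", "sample_id"] + _coordinate_columns()
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LandmarkFormatError(f"missing columns: {missing}")
    if df["wing_id"].duplicated().any():
        dupes = sorted(df.loc[df["wing_id"].duplicated(), "wing_id"].unique())
        raise LandmarkFormatError(f"duplicate wing_id values: {dupes}")

    samples: dict[str, Sample] = {}
    for row_i, row in df.iterrows():
        coords = np.empty((N_LANDMARKS, 2))
        for i in range(N_LANDMARKS):
            for j, axis in enumerate(("x", "y")):
                v = row[f"{axis}{i + 1}"]
                if pd.isna(v):
                    raise LandmarkFormatError(
                        f"row {row_i}: empty coordinate {axis}{i + 1}"
                    )
                coords[i, j] = float(v)
        if y_down:
            coords[:, 1] = -coords[:, 1]
        cfg = LandmarkConfiguration(
            coords,
            wing_id=str(row["wing_id"]),
            side=str(row.get("side", "right")),
            resolution_dpi=float(row.get("resolution_dpi", 2400.0)),
        )
        sid = str(row["sample_id"])
        if sid not in samples:
            meta = {}
            for col in METADATA_COLUMNS:
                if col in df.columns and pd.notna(row[col]):
                    meta[col] = row[col]
            if "year" in meta:
                meta["year"] = int(meta["year"])
            samples[sid] = Sample(sid, [], **meta)
        samples[sid].configurations.append(cfg)
    return SampleSet(list(samples.values()), provenance=f"read_landmark_csv({Path(path).name})")


def write_landmark_csv(samples: SampleSet, path: str | Path) -> None:
    """Write the CSV counterpart of :func:`read_landmark_csv`."""
    rows = []
    for s, cfg in samples.iter_wings():
        row: dict = {
            "wing_id": cfg.wing_id,
            "sample_id": s.sample_id,
            "side": cfg.side,
            "resolution_dpi": cfg.resolution_dpi,
        }
        for col in METADATA_COLUMNS:
            row[col] = getattr(s, col)
        for i in range(cfg.n_landmarks):
            row[f"x{i + 1}"] = cfg.points[i, 0]
            row[f"y{i + 1}"] = cfg.points[i, 1]
        rows.append(row)
    # repr round-trips float64 exactly; pandas' default formatter does not
    pd.DataFrame(rows).to_csv(path, index=False, float_format=lambda v: repr(float(v)))
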