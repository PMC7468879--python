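"""Shared data types and table I/O for the arteriovenous metabolomics pipeline.

The on-disk interchange format is long (tidy) CSV — one row per
(sample, bucket) or (sample, metabolite) — with UTF-8 encoding, comma
separator, ``.`` decimal and a mandatory header row. Wide matrices are an
in-memory view only. Four tables make up a cohort:

* ``samples.csv``        — sample_id, animal_id, day, vessel, time_min
* ``buckets.csv``        — sample_id, ppm_center, intensity
* ``metabolite_map.csv`` — metabolite, ppm_lo, ppm_hi
* ``outcomes.csv``       — animal_id, day, homa_ir, body_weight
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DAYS = ("D0", "D60")
VESSELS = ("ART", "PV", "HV")
#: Sampling grid in minutes after the meal; 0 is the fasting draw.
TIME_GRID = (0, 60, 180, 330, 510)

ANNOTATION_COLUMNS = ["sample_id", "animal_id", "day", "vessel", "time_min"]


class SchemaError(ValueError):
    """A required column is missing or has the wrong name."""


class ValidationError(ValueError):
    """Table contents violate a declared invariant."""


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {missing}")


def validate_annotations(annotations: pd.DataFrame, time_grid=TIME_GRID) -> pd.DataFrame:
    """Validate a sample-annotation frame and return it with canonical dtypes.

    Enforces the vessel/day vocabularies, the sampling grid, and uniqueness of
    the (animal, day, vessel, time) design cell.
    """
    _require_columns(annotations, ANNOTATION_COLUMNS, "samples")
    ann = annotations[ANNOTATION_COLUMNS].copy()
    ann["time_min"] = ann["time_min"].astype(int)
    bad_day = set(ann["day"]) - set(DAYS)
    if bad_day:
        raise ValidationError(f"unknown day label(s) {sorted(bad_day)}; expected {DAYS}")
    bad_vessel = set(ann["vessel"]) - set(VESSELS)
    if bad_vessel:
        raise ValidationError(f"unknown vessel label(s) {sorted(bad_vessel)}; expected {VESSELS}")
    bad_time = set(ann["time_min"]) - set(time_grid)
    if bad_time:
        raise ValidationError(f"time point(s) {sorted(bad_time)} not on the sampling grid {time_grid}")
    key = ann[["animal_id", "day", "vessel", "time_min"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise ValidationError(f"duplicate (animal, day, vessel, time) tuple: {dup}")
    if ann["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id")
    return ann


@dataclass
class BucketTable:
    """Samples × ppm-bucket intensity matrix with sample annotations.

    ``ppm_centers`` are strictly descending (8.5 → 0.5 convention);
    ``normalized`` records whether rows have been scaled to unit total area.
    """

    intensities: np.ndarray
    ppm_centers: np.ndarray
    annotations: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.ppm_centers = np.asarray(self.ppm_centers, dtype=float)
        if self.intensities.ndim != 2:
            raise ValidationError("intensities must be a 2-D samples × buckets matrix")
        n, p = self.intensities.shape
        if len(self.ppm_centers) != p:
            raise ValidationError("ppm_centers length does not match bucket count")
        if p > 1 and not np.all(np.diff(self.ppm_centers) < 0):
            raise ValidationError("ppm_centers must be strictly descending")
        if np.any(self.intensities < 0):
            raise ValidationError("negative bucket intensity")
        self.annotations = validate_annotations(self.annotations)
        if len(self.annotations) != n:
            raise ValidationError("annotation rows do not match intensity rows")
        if self.normalized:
            sums = self.intensities.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise ValidationError("normalized flag set but row sums differ from 1")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_buckets(self) -> int:
        return self.intensities.shape[1]

    def to_long(self) -> pd.DataFrame:
        sample_ids = np.repeat(self.annotations["sample_id"].to_numpy(), self.n_buckets)
        return pd.DataFrame(
            {
                "sample_id": sample_ids,
                "ppm_center": np.tile(self.ppm_centers, self.n_samples),
                "intensity": self.intensities.ravel(),
            }
        )


@dataclass
class MetaboliteTable:
    """Samples × annotated-metabolite quantification matrix.

    Values are strictly positive: they serve as denominators in the
    arteriovenous ratio formulas downstream.
    """

    values: np.ndarray
    metabolite_names: list[str]
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.metabolite_names = list(self.metabolite_names)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D samples × metabolites matrix")
        if self.values.shape[1] != len(self.metabolite_names):
            raise ValidationError("metabolite_names length does not match column count")
        if np.any(self.values <= 0):
            raise ValidationError("metabolite values must be strictly positive")
        self.annotations = validate_annotations(self.annotations)
        if len(self.annotations) != self.values.shape[0]:
            raise ValidationError("annotation rows do not match value rows")

    def to_long(self) -> pd.DataFrame:
        n, m = self.values.shape
        return pd.DataFrame(
            {
                "sample_id": np.repeat(self.annotations["sample_id"].to_numpy(), m),
                "metabolite": np.tile(np.asarray(self.metabolite_names, dtype=object), n),
                "value": self.values.ravel(),
            }
        )


#: ppm window within which quantification intervals must lie, and the water
#: region they must avoid.
PPM_RANGE = (0.5, 8.5)
WATER_REGION = (4.5, 5.1)


@dataclass
class MetaboliteMap:
    """Metabolite name → ppm interval [lo, hi) used for quantification."""

    entries: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.entries.items():
            if not lo < hi:
                raise ValidationError(f"{name}: empty ppm interval [{lo}, {hi})")
            if lo < PPM_RANGE[0] or hi > PPM_RANGE[1]:
                raise ValidationError(f"{name}: interval outside {PPM_RANGE} ppm")
            if lo < WATER_REGION[1] and hi > WATER_REGION[0]:
                raise ValidationError(f"{name}: interval overlaps the water region {WATER_REGION}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m, lo, hi) for m, (lo, hi) in self.entries.items()],
            columns=["metabolite", "ppm_lo", "ppm_hi"],
        )


@dataclass
class OutcomeTable:
    """Per (animal, day) clinical outcomes: HOMA-IR index and body weight (kg)."""

    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        _require_columns(self.records, ["animal_id", "day", "homa_ir", "body_weight"], "outcomes")
        rec = self.records[["animal_id", "day", "homa_ir", "body_weight"]].copy()
        if rec[["animal_id", "day"]].duplicated().any():
            raise ValidationError("duplicate (animal, day) outcome record")
        if (rec["homa_ir"] <= 0).any() or (rec["body_weight"] <= 0).any():
            raise ValidationError("outcomes must be positive")
        bad_day = set(rec["day"]) - set(DAYS)
        if bad_day:
            raise ValidationError(f"unknown day label(s) {sorted(bad_day)}")
        self.records = rec


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_annotations(df)


def read_bucket_table(buckets_path: str | Path, samples_path: str | Path) -> BucketTable:
    """Read the long-form bucket CSV plus its sample annotations.

    Sample order follows ``samples.csv``; buckets are ordered by descending
    ppm. Every sample must report every bucket exactly once.
    """
    ann = read_samples(samples_path)
    df = pd.read_csv(buckets_path)
    _require_columns(df, ["sample_id", "ppm_center", "intensity"], "buckets")
    if (df["intensity"] < 0).any():
        bad = df.loc[df["intensity"] < 0].iloc[0]
        raise ValidationError(
            f"negative intensity {bad['intensity']} for sample {bad['sample_id']}"
        )
    wide = df.pivot_table(index="sample_id", columns="ppm_center", values="intensity", aggfunc="first")
    if wide.isna().any().any():
        raise ValidationError("bucket grid is ragged: some samples miss some buckets")
    missing = set(ann["sample_id"]) - set(wide.index)
    if missing:
        raise ValidationError(f"samples without bucket rows: {sorted(missing)[:5]}")
    wide = wide.loc[ann["sample_id"], sorted(wide.columns, reverse=True)]
    return BucketTable(
        intensities=wide.to_numpy(),
        ppm_centers=np.asarray(wide.columns, dtype=float),
        annotations=ann,
    )


def read_metabolite_table(metabolites_path: str | Path, samples_path: str | Path) -> MetaboliteTable:
    ann = read_samples(samples_path)
    df = pd.read_csv(metabolites_path)
    _require_columns(df, ["sample_id", "metabolite", "value"], "metabolites")
    wide = df.pivot_table(index="sample_id", columns="metabolite", values="value", aggfunc="first")
    if wide.isna().any().any():
        raise ValidationError("metabolite table is ragged")
    # preserve first-appearance metabolite order from the file
    order = list(dict.fromkeys(df["metabolite"]))
    wide = wide.loc[ann["sample_id"], order]
    return MetaboliteTable(
        values=wide.to_numpy(), metabolite_names=order, annotations=ann
    )


def read_metabolite_map(path: str | Path) -> MetaboliteMap:
    df = pd.read_csv(path)
    _require_columns(df, ["metabolite", "ppm_lo", "ppm_hi"], "metabolite_map")
    entries = {
        str(r.metabolite): (float(r.ppm_lo), float(r.ppm_hi)) for r in df.itertuples()
    }
    return MetaboliteMap(entries)


def read_outcomes(path: str | Path) -> OutcomeTable:
    return OutcomeTable(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _long_frames(obj) -> dict[str, pd.DataFrame]:
    """Map a pipeline object to the named long-form frames it serializes to."""
    if isinstance(obj, BucketTable):
        return {"buckets": obj.to_long(), "samples": obj.annotations}
    if isinstance(obj, MetaboliteTable):
        return {"metabolites": obj.to_long(), "samples": obj.annotations}
    if isinstance(obj, MetaboliteMap):
        return {"metabolite_map": obj.to_frame()}
    if isinstance(obj, OutcomeTable):
        return {"outcomes": obj.records}
    if isinstance(obj, pd.DataFrame):
        return {"table": obj}
    raise TypeError(f"cannot serialize object of type {type(obj).__name__}")


def write_results(tables: dict[str, object], path: str | Path) -> list[str]:
    """Write pipeline outputs as CSV files under ``path``.

    ``tables`` maps an output name to a pipeline object or DataFrame. File
    naming is deterministic (``<name>.csv``, plus ``<name>_samples.csv`` for
    annotated matrices) and floats round-trip exactly (repr serialization).
    Returns the sorted manifest of files written, relative to ``path``.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    for name, obj in sorted(tables.items()):
        frames = _long_frames(obj)
        for kind, df in frames.items():
            if kind in ("table", "buckets", "metabolites", "metabolite_map", "outcomes"):
                fname = f"{name}.csv"
            else:
                fname = f"{name}_{kind}.csv"
            df.to_csv(out / fname, index=False, lineterminator="\n")
            manifest.append(fname)
    return sorted(manifest)
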