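"""Bucket-table reduction: region exclusion, total-area normalization,
and per-metabolite quantification.

Mirrors the standard 1H-NMR workflow: 0.01-ppm buckets over 8.5–0.5 ppm,
the residual-water region (default 4.5–5.1 ppm) excluded, every spectrum
normalized to its own total area (so bucket values are fractions of total
spectral intensity), and each annotated metabolite quantified by summing
the buckets of a non-overlapping signal region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import (
    BucketTable,
    MetaboliteMap,
    MetaboliteTable,
    ValidationError,
    WATER_REGION,
)


@dataclass(frozen=True)
class PpmRegion:
    """Half-open chemical-shift interval [lo, hi) in ppm."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValidationError(f"PpmRegion requires lo < hi, got [{self.lo}, {self.hi})")

    def contains(self, ppm: np.ndarray) -> np.ndarray:
        ppm = np.asarray(ppm, dtype=float)
        return (ppm >= self.lo) & (ppm < self.hi)


#: Default residual-water exclusion window.
DEFAULT_WATER_REGION = PpmRegion(*WATER_REGION)


def exclude_region(table: BucketTable, region: PpmRegion = DEFAULT_WATER_REGION) -> BucketTable:
    """Drop every bucket whose center lies inside ``region``.

    Membership is tested on bucket centers against the half-open interval
    [lo, hi); remaining buckets keep their order. Idempotent.
    """
    keep = ~region.contains(table.ppm_centers)
    if not keep.any():
        raise ValidationError(f"region [{region.lo}, {region.hi}) removes every bucket")
    return BucketTable(
        intensities=table.intensities[:, keep],
        ppm_centers=table.ppm_centers[keep],
        annotations=table.annotations,
        normalized=False,
    )


def normalize_total_area(table: BucketTable) -> BucketTable:
    """Divide each spectrum by its own total area so rows sum to 1.

    Idempotent and scale-invariant; accounts for overall concentration
    differences between plasma samples.
    """
    sums = table.intensities.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        sid = table.annotations["sample_id"].iloc[bad[0]]
        raise ValidationError(f"sample {sid!r} has nonpositive total area; cannot normalize")
    return BucketTable(
        intensities=table.intensities / sums[:, None],
        ppm_centers=table.ppm_centers,
        annotations=table.annotations,
        normalized=True,
    )


def quantify_metabolites(table: BucketTable, mapping: MetaboliteMap) -> MetaboliteTable:
    """Quantify each mapped metabolite as the sum of its interval's buckets.

    The sum (not mean) is proportional to the integrated signal area. The
    table must be normalized first; a map interval covering no bucket, or a
    zero quantification (which would break the downstream AV ratios), is an
    error.
    """
    if not table.normalized:
        raise ValidationError("quantify_metabolites requires a normalized BucketTable")
    names = list(mapping.entries)
    cols = np.empty((table.n_samples, len(names)))
    for j, name in enumerate(names):
        lo, hi = mapping.entries[name]
        member = (table.ppm_centers >= lo) & (table.ppm_centers < hi)
        if not member.any():
            raise ValidationError(f"metabolite {name!r}: interval [{lo}, {hi}) covers no bucket")
        cols[:, j] = table.intensities[:, member].sum(axis=1)
    zero = np.argwhere(cols <= 0)
    if zero.size:
        i, j = zero[0]
        sid = table.annotations["sample_id"].iloc[i]
        raise ValidationError(
            f"metabolite {names[j]!r} quantifies to {cols[i, j]} in sample {sid!r}"
        )
    return MetaboliteTable(values=cols, metabolite_names=names, annotations=table.annotations)
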