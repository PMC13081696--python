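"""Scalar and map-level summaries of lead fields.

Sensitivity of an array to a source is the Euclidean norm of that source's
topography (the corresponding gain-matrix column) scaled by a reference
dipole moment, 100 nAm by default.  The conservation factor quantifies how
much of the summed signal of simultaneously active sources survives mutual
cancellation, and the RE/CC pair compares two topographies of the same
source computed with different forward models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import gaussian_kde

from .forward import LeadField

DEFAULT_MOMENT = 1e-7  # A·m (100 nAm reference dipole)


@dataclass
class SensitivityMap:
    values: np.ndarray          # tesla, one per source
    moment: float               # A·m
    array_name: str = ""
    source_meta: Optional[object] = None
    n_sensor_divisor: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if np.any(self.values < 0):
            raise ValueError("sensitivity values must be nonnegative")

    def mean(self) -> float:
        return float(self.values.mean())


@dataclass
class DensitySummary:
    percentile_1: float
    percentile_95: float
    percentile_99: float
    mode_of_density: float
    mean: float


def sensitivity_map(L: LeadField, moment: float = DEFAULT_MOMENT,
                    array_name: str = "") -> SensitivityMap:
    """Per-source sensitivity: moment times the column norm of the gain."""
    values = moment * np.linalg.norm(L.gain, axis=0)
    return SensitivityMap(values=values, moment=moment,
                          array_name=array_name, source_meta=L.source_meta)


def normalize_per_sensor(smap: SensitivityMap, n_sensors: int) -> SensitivityMap:
    """Divide by the number of *sensors* (a triaxial array divides by its
    sensor count, not its three-fold channel count)."""
    if n_sensors < 1:
        raise ValueError("n_sensors must be >= 1")
    return SensitivityMap(values=smap.values / n_sensors, moment=smap.moment,
                          array_name=smap.array_name, source_meta=smap.source_meta,
                          n_sensor_divisor=n_sensors)


def summarize_density(values, range_clip=None) -> DensitySummary:
    """Percentiles plus the peak of a Gaussian KDE (Silverman bandwidth,
    512-point grid).  Constant input degenerates to that constant."""
    values = np.asarray(values, float).ravel()
    if values.size == 0:
        raise ValueError("empty value set")
    p1, p95, p99 = np.percentile(values, [1, 95, 99])
    if np.ptp(values) == 0:
        mode = float(values[0])
    else:
        lo, hi = range_clip if range_clip is not None else (values.min(), values.max())
        grid = np.linspace(lo, hi, 512)
        kde = gaussian_kde(values, bw_method="silverman")
        mode = float(grid[np.argmax(kde(grid))])
    return DensitySummary(percentile_1=float(p1), percentile_95=float(p95),
                          percentile_99=float(p99), mode_of_density=mode,
                          mean=float(values.mean()))


def region_sensitivity_ratio(map_a: SensitivityMap, map_b: SensitivityMap) -> float:
    """Ratio of mean sensitivities (mean of a over mean of b).

    Region comparisons are phrased as averages over all sources in each
    region, so this is a ratio of means, not a mean of ratios.
    """
    mb = map_b.mean()
    if mb == 0:
        raise ZeroDivisionError("reference map has zero mean sensitivity")
    return map_a.mean() / mb


def conservation_factor(L: LeadField) -> float:
    """C = ||sum_j L_:,j||_2 / sum_j ||L_:,j||_2, in [0, 1].

    C = 1 means the topographies add constructively; C -> 0 means the
    simultaneously active sources cancel.
    """
    col_norms = np.linalg.norm(L.gain, axis=0)
    B = col_norms.sum()
    if B == 0:
        raise ValueError("conservation factor undefined for an all-zero lead field")
    A = np.linalg.norm(L.gain.sum(axis=1))
    return float(A / B)


def topography_error(t_test, t_ref) -> tuple[float, float]:
    """Relative error (percent) and Pearson correlation between topographies.

    The second argument is the reference (the more complete forward model):
    RE = 100 * ||t_test - t_ref|| / ||t_ref||.
    """
    t_test = np.asarray(t_test, float).ravel()
    t_ref = np.asarray(t_ref, float).ravel()
    if t_test.shape != t_ref.shape:
        raise ValueError("topographies must have equal length")
    nref = np.linalg.norm(t_ref)
    if nref == 0:
        raise ValueError("reference topography is zero")
    re = 100.0 * np.linalg.norm(t_test - t_ref) / nref
    if np.std(t_test) == 0 or np.std(t_ref) == 0:
        raise ValueError("correlation undefined for a zero-variance topography")
    cc = float(np.corrcoef(t_test, t_ref)[0, 1])
    return float(re), cc
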