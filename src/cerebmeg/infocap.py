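"""Total information capacity of a sensor array over a source space.

The array is treated as a Gaussian channel: lead fields are whitened by the
(homoscedastic, diagonal) sensor-noise covariance, the whitened rows are
orthogonalized by eigen-decomposition of their Gram matrix — so correlated
sensors are not double counted — and the total information is the Shannon
capacity summed over the orthogonalized channels,

    Itot = 1/2 * sum_i log2(SNR'_i + 1)   [bits],

with SNR'_i the eigenvalues of q^2 * W W^T for whitened gain W.  The source
variance q^2 is a single global scalar calibrated so that the average
per-source SNR on a designated reference array equals one; the same q^2 is
then applied to every array, sensor type and source region so the Itot
values are mutually comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .arrays import SensorArray, mean_neighbor_distance
from .forward import LeadField

#: default noise spectral densities (T/sqrt(Hz)) by sensor type
NOISE_DENSITY = {"squid_mag": 3e-15, "squid_axial_grad": 3e-15,
                 "opm": 1.0e-14, "opm_high": 1.5e-14}


@dataclass
class NoiseModel:
    """Per-channel noise standard deviation in tesla.

    Built from a spectral density (fT/sqrt(Hz)) at a common measurement
    bandwidth; with the default 1 Hz bandwidth the std equals the density.
    Only relative levels between sensor types matter for array comparisons
    at a fixed common bandwidth.
    """

    stds: np.ndarray

    def __post_init__(self) -> None:
        self.stds = np.atleast_1d(np.asarray(self.stds, float))
        if np.any(self.stds <= 0):
            raise ValueError("noise standard deviations must be positive")

    @classmethod
    def homoscedastic(cls, n_channels: int, density: float,
                      bandwidth: float = 1.0) -> "NoiseModel":
        return cls(stds=np.full(n_channels, density * np.sqrt(bandwidth)))

    @classmethod
    def for_array(cls, array: SensorArray, density_by_type=None,
                  bandwidth: float = 1.0) -> "NoiseModel":
        densities = dict(NOISE_DENSITY)
        if density_by_type:
            densities.update(density_by_type)
        stds = [densities[
            "squid_axial_grad" if c.kind == "axial_gradiometer"
            else next(s.sensor_type for s in array.sensors
                      if s.id == c.parent_sensor_id)]
            for c in array.channels()]
        return cls(stds=np.asarray(stds) * np.sqrt(bandwidth))


@dataclass
class InfoCapResult:
    snr_spectrum: np.ndarray   # descending, one per orthogonalized channel
    itot: float                # bits
    n_channels: int
    q2: float                  # source variance, (A·m)^2
    region: str = ""

    def __post_init__(self) -> None:
        self.snr_spectrum = np.asarray(self.snr_spectrum, float)
        if len(self.snr_spectrum) != self.n_channels:
            raise ValueError("spectrum length must equal the channel count")
        if np.any(self.snr_spectrum < 0):
            raise ValueError("SNR spectrum must be nonnegative")
        if abs(self.itot - total_information(self.snr_spectrum)) > 1e-9 * max(1.0, self.itot):
            raise ValueError("itot is not recomputable from the stored spectrum")


def whiten(L: LeadField | np.ndarray, noise: NoiseModel) -> np.ndarray:
    """Divide each channel row by its noise standard deviation."""
    gain = L.gain if isinstance(L, LeadField) else np.asarray(L, float)
    if len(noise.stds) != gain.shape[0]:
        raise ValueError("one noise std per channel required")
    return gain / noise.stds[:, None]


def orthogonal_snrs(whitened_gain: np.ndarray, q2: float) -> np.ndarray:
    """SNRs of the orthogonalized channels: eigenvalues of q2 * W W^T,
    descending; round-off negatives clipped to zero.  The spectrum keeps one
    entry per channel even when the gain is rank deficient."""
    if q2 <= 0:
        raise ValueError("q2 must be positive")
    W = np.asarray(whitened_gain, float)
    if not np.all(np.isfinite(W)):
        raise ValueError("whitened gain must be finite")
    evals = np.linalg.eigvalsh(W @ W.T)
    return np.clip(q2 * evals[::-1], 0.0, None)


def total_information(spectrum) -> float:
    """Itot = 1/2 * sum log2(SNR' + 1), in bits."""
    spectrum = np.asarray(spectrum, float)
    if np.any(spectrum < 0):
        raise ValueError("spectrum must be nonnegative")
    return float(0.5 * np.log2(spectrum + 1.0).sum())


def calibrate_source_variance(reference_whitened_gain: np.ndarray) -> float:
    """q^2 such that the mean per-source SNR on the reference equals one.

    Per-source SNR is q^2 * ||w_:,j||^2, the whitened topography power, so
    q^2 = 1 / mean_j ||w_:,j||^2.
    """
    W = np.asarray(reference_whitened_gain, float)
    power = np.einsum("ij,ij->j", W, W)
    m = power.mean()
    if m == 0:
        raise ValueError("cannot calibrate on an all-zero gain")
    return float(1.0 / m)


def information_capacity(L: LeadField | np.ndarray, noise: NoiseModel, q2: float,
                         region: str = "") -> InfoCapResult:
    """Whiten, orthogonalize and sum: the full pipeline for one array/region."""
    spectrum = orthogonal_snrs(whiten(L, noise), q2)
    return InfoCapResult(snr_spectrum=spectrum, itot=total_information(spectrum),
                         n_channels=len(spectrum), q2=q2, region=region)


def itot_sweep(leadfields_by_region: dict, array: SensorArray,
               sensor_counts: Sequence[int], noise_levels: Sequence[float],
               q2: float, bandwidth: float = 1.0) -> pd.DataFrame:
    """Itot versus sensor count for nested (FPS-prefix) arrays.

    ``leadfields_by_region`` maps region name -> LeadField assembled for the
    *full* array; the k-sensor sub-array's gain is the row prefix, which is
    exact because greedy farthest-point layouts are nested and channels are
    ordered sensor-major.  The whole-brain entry must be the lead field of
    the concatenated source spaces, not a sum of regional results.

    Returns a tidy table (count, noise_level_ft, region, channels, itot_bits,
    mean_neighbor_distance_m, overlap_flag).
    """
    counts = list(sensor_counts)
    if counts != sorted(counts):
        raise ValueError("sensor counts must be ascending")
    per_sensor = 3 if array.channel_mode == "triaxial" else 1
    rows = []
    for k in counts:
        sub = array.subset(k)
        mnd, flag = mean_neighbor_distance(sub) if k >= 2 else (np.nan, False)
        nch = k * per_sensor
        for region, lf in leadfields_by_region.items():
            gain = lf.gain[:nch]
            for density in noise_levels:
                noise = NoiseModel.homoscedastic(nch, density, bandwidth)
                res = information_capacity(LeadField(gain=gain, channel_meta=None),
                                           noise, q2, region=region)
                rows.append(dict(count=k, noise_level_ft=density * 1e15,
                                 region=region, channels=nch,
                                 itot_bits=res.itot,
                                 mean_neighbor_distance_m=mnd,
                                 overlap_flag=bool(flag)))
    return pd.DataFrame(rows)
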