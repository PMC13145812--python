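"""Accelerator pulse structure, monitor-unit definitions and dose-rate maps.

The scanned beam delivers one electron bunch per spot, in raster order, at
the bunch interval of the accelerator; a train holds a fixed number of
bunches, and trains repeat after the train interval.  The per-voxel mean
dose rate is the accumulated dose divided by the span from the first to
the last bunch that contributes materially to that voxel (plus one bunch
length, so a single-bunch voxel sees the instantaneous rate).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

__all__ = [
    "PulseTrain",
    "MUDefinition",
    "DoseRateMap",
    "duty_cycle",
    "mean_pencil_dose_rate",
    "instantaneous_mu_rate",
    "spot_times",
    "accumulate_delivery",
]


@dataclass(frozen=True)
class PulseTrain:
    """Bunch/train timing of the accelerator (defaults: scanned electron beam)."""

    bunch_length_s: float = 30e-12
    bunch_interval_s: float = 1.0e-6
    bunches_per_train: int = 1000
    train_interval_s: float = 99.0e-3   # gap between the end of a train and the next
    instantaneous_dose_rate: float = 2.0e12  # Gy/s within one bunch

    def __post_init__(self) -> None:
        if self.bunch_length_s > self.bunch_interval_s:
            raise ValueError("bunch length must not exceed the bunch interval")
        for f in ("bunch_length_s", "bunch_interval_s", "train_interval_s",
                  "instantaneous_dose_rate"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass(frozen=True)
class MUDefinition:
    """Monitor unit: 1 cGy at the depth of maximum dose over a reference area."""

    reference_area_mm: float = 100.0
    dose_per_mu_Gy: float = 0.01
    spot_spacing_mm: float = 4.0

    @property
    def spots_over_reference(self) -> int:
        n = self.reference_area_mm / self.spot_spacing_mm
        return int(round(n)) ** 2

    @property
    def gy_per_mu_single_spot(self) -> float:
        """Dose a single pencil beam receives from 1 MU (6.25 Gy by default)."""
        return self.dose_per_mu_Gy * self.spots_over_reference


@dataclass
class DoseRateMap:
    """Per-voxel mean dose rate and its delivery window."""

    dose: np.ndarray          # Gy (or relative units) accumulated over the delivery
    mean_rate: np.ndarray     # dose / window duration, Gy/s
    t_first: np.ndarray       # s, +inf where no dose
    t_last: np.ndarray        # s, -inf where no dose


def duty_cycle(train: PulseTrain) -> float:
    """Fraction of time the beam is on within a train: bunch length / interval."""
    return train.bunch_length_s / train.bunch_interval_s


def mean_pencil_dose_rate(train: PulseTrain) -> float:
    """Mean dose rate within one pencil beam: instantaneous rate x duty cycle."""
    return train.instantaneous_dose_rate * duty_cycle(train)


def instantaneous_mu_rate(train: PulseTrain, mu_def: MUDefinition) -> float:
    """Instantaneous MU rate within a bunch (MU/s)."""
    return train.instantaneous_dose_rate / mu_def.gy_per_mu_single_spot


def spot_times(n_spots: int, train: PulseTrain) -> np.ndarray:
    """Delivery time of each spot under the one-bunch-per-spot raster schedule."""
    b = np.arange(n_spots)
    if n_spots > train.bunches_per_train:
        warnings.warn("spot count exceeds bunches per train; schedule spills into later trains")
    train_idx, in_train = divmod(b, train.bunches_per_train)
    train_len = train.bunches_per_train * train.bunch_interval_s
    return train_idx * (train_len + train.train_interval_s) + in_train * train.bunch_interval_s


def accumulate_delivery(
    spot_doses: list[np.ndarray],
    mu: np.ndarray | list[float],
    train: PulseTrain,
    threshold: float = 1e-3,
    total_dose: np.ndarray | None = None,
) -> DoseRateMap:
    """Walk the bunch schedule and accumulate dose and mean dose rate.

    ``spot_doses`` are per-spot dose maps for unit MU; ``mu`` the spot
    weights.  A bunch "contributes" to a voxel when it delivers more than
    ``threshold`` of the voxel's total dose, which keeps Gaussian tails
    from inflating the delivery window.  When ``total_dose`` is supplied
    (e.g. the solver dose), the per-spot kernels are rescaled voxelwise so
    their sum reproduces it exactly -- temporal bookkeeping never changes
    the total dose.
    """
    mu = np.asarray(mu, float)
    if len(spot_doses) != len(mu):
        raise ValueError("need one MU weight per spot kernel")
    times = spot_times(len(mu), train)
    shape = spot_doses[0].shape

    total = np.zeros(shape)
    for d_s, w in zip(spot_doses, mu):
        total += w * d_s
    if total_dose is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(total > 0, total_dose / np.maximum(total, 1e-300), 0.0)
    else:
        scale = None

    t_first = np.full(shape, np.inf)
    t_last = np.full(shape, -np.inf)
    for d_s, w, t in zip(spot_doses, mu, times):
        d = w * d_s
        contributes = d > threshold * total
        t_first[contributes] = np.minimum(t_first[contributes], t)
        t_last[contributes] = np.maximum(t_last[contributes], t)

    dose_out = total * scale if scale is not None else total
    window = t_last - t_first + train.bunch_length_s
    with np.errstate(invalid="ignore"):
        rate = np.where(np.isfinite(window) & (window > 0), dose_out / window, 0.0)
    return DoseRateMap(dose_out, rate, t_first, t_last)
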