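"""Excitation-emission matrix representation, peak localization, and
multi-day peak-stability testing."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import (
    ConfigurationError,
    FormatError,
    InsufficientReplicationError,
    ParameterizationError,
)
from .stats_suite import GroupSample, SnkResult, snk_test

__all__ = [
    "EXCITATION_AXIS",
    "EMISSION_AXIS",
    "EmexMatrix",
    "EmexPeak",
    "AxisStability",
    "StabilityReport",
    "load_emex",
    "save_emex",
    "find_peak",
    "peak_stability",
]

# Standard spectrofluorometer protocol grid: 1 nm steps.
EXCITATION_AXIS = np.arange(350, 551, dtype=float)  # 201 values
EMISSION_AXIS = np.arange(600, 801, dtype=float)    # 201 values


@dataclass(frozen=True)
class EmexMatrix:
    """A 201 x 201 excitation (350-550 nm) x emission (600-800 nm) intensity grid."""

    excitation: np.ndarray
    emission: np.ndarray
    intensity: np.ndarray
    day: Optional[int] = None
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        ex = np.asarray(self.excitation, dtype=float)
        em = np.asarray(self.emission, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        if not np.array_equal(ex, EXCITATION_AXIS):
            raise FormatError(
                f"excitation axis must be 350..550 nm in 1 nm steps ({EXCITATION_AXIS.size} "
                f"values); got {ex.size} values"
            )
        if not np.array_equal(em, EMISSION_AXIS):
            raise FormatError(
                f"emission axis must be 600..800 nm in 1 nm steps ({EMISSION_AXIS.size} "
                f"values); got {em.size} values"
            )
        if it.shape != (ex.size, em.size):
            raise FormatError(f"intensity shape {it.shape} != ({ex.size}, {em.size})")
        if not np.all(np.isfinite(it)):
            raise FormatError("non-finite intensities")
        if it.min() < 0:
            raise FormatError("negative intensities")
        object.__setattr__(self, "excitation", ex)
        object.__setattr__(self, "emission", em)
        object.__setattr__(self, "intensity", it)


@dataclass(frozen=True)
class EmexPeak:
    excitation_nm: float
    emission_nm: float
    intensity: float
    degenerate: bool = False  # flat matrix; location is the lexicographic tie-break


def save_emex(matrix: EmexMatrix, path: Union[str, Path]) -> Path:
    """CSV layout: first row = emission axis, first column = excitation axis,
    body = intensities."""
    path = Path(path)
    df = pd.DataFrame(
        matrix.intensity,
        index=matrix.excitation,
        columns=matrix.emission,
    )
    df.index.name = "excitation_nm"
    df.to_csv(path, float_format="%.10g")
    return path


def load_emex(
    path: Union[str, Path],
    day: Optional[int] = None,
    sample_id: Optional[str] = None,
) -> EmexMatrix:
    """Load and validate an EMEX CSV written by :func:`save_emex`."""
    try:
        df = pd.read_csv(path, index_col=0)
        excitation = df.index.to_numpy(dtype=float)
        emission = np.asarray([float(c) for c in df.columns])
        intensity = df.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"cannot parse EMEX grid from {path}: {exc}") from exc
    for name, axis in (("excitation", excitation), ("emission", emission)):
        if axis.size < 2 or np.any(np.diff(axis) <= 0):
            raise FormatError(f"{name} axis must be strictly increasing")
        steps = np.diff(axis)
        if not np.allclose(steps, steps[0]):
            raise FormatError(f"{name} axis has non-uniform spacing")
    return EmexMatrix(
        excitation=excitation,
        emission=emission,
        intensity=intensity,
        day=day,
        sample_id=sample_id,
    )


def find_peak(matrix: EmexMatrix, smooth: str = "none") -> EmexPeak:
    """Locate the optimal (excitation, emission) pair as the grid argmax.

    ``smooth="median3"`` applies a 3x3 median pre-filter, which suppresses
    single-pixel noise spikes before the argmax. Ties break toward the
    lowest (excitation, emission) pair lexicographically; a flat matrix is
    flagged degenerate.
    """
    if smooth == "median3":
        arr = median_filter(matrix.intensity, size=3, mode="nearest")
    elif smooth == "none":
        arr = matrix.intensity
    else:
        raise ConfigurationError(f"unknown smoothing {smooth!r}")
    degenerate = bool(np.ptp(arr) == 0)
    if degenerate:
        warnings.warn("flat EMEX matrix: peak location is the tie-break corner", stacklevel=2)
    i, j = np.unravel_index(int(np.argmax(arr)), arr.shape)  # first max = lexicographic low
    return EmexPeak(
        excitation_nm=float(matrix.excitation[i]),
        emission_nm=float(matrix.emission[j]),
        intensity=float(arr[i, j]),
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class AxisStability:
    axis: str  # "excitation" | "emission"
    letters: Mapping[str, str]  # day label -> letters
    single_group: bool
    snk: Optional[SnkResult]  # None when all values were identical

    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "letters": dict(self.letters),
            "single_group": self.single_group,
            "snk": self.snk.to_dict() if self.snk is not None else None,
        }


@dataclass(frozen=True)
class StabilityReport:
    excitation: AxisStability
    emission: AxisStability
    alpha: float
    stable: bool

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "stable": self.stable,
            "excitation": self.excitation.to_dict(),
            "emission": self.emission.to_dict(),
        }


def _axis_stability(
    axis: str, by_day: Mapping[int, Sequence[float]], alpha: float
) -> AxisStability:
    labels = [str(day) for day in by_day]
    all_vals = np.concatenate([np.asarray(v, dtype=float) for v in by_day.values()])
    if np.ptp(all_vals) == 0:  # replicates identical everywhere: trivially stable
        return AxisStability(
            axis=axis,
            letters={lab: "a" for lab in labels},
            single_group=True,
            snk=None,
        )
    groups = [
        GroupSample(label=str(day), values=np.asarray(v, dtype=float))
        for day, v in by_day.items()
    ]
    snk = snk_test(groups, alpha=alpha)
    distinct = set(snk.letters.values())
    return AxisStability(
        axis=axis,
        letters=dict(snk.letters),
        single_group=(distinct == {"a"}),
        snk=snk,
    )


def peak_stability(
    peaks_by_day: Union[Mapping[int, Sequence[EmexPeak]], Sequence[tuple[int, EmexPeak]]],
    alpha: float = 0.05,
) -> StabilityReport:
    """ANOVA + SNK on peak excitation and emission coordinates across days.

    The verdict is "stable" iff all days fall in a single homogeneous letter
    group on both axes at the given alpha.
    """
    if not isinstance(peaks_by_day, Mapping):
        grouped: dict[int, list[EmexPeak]] = {}
        for day, pk in peaks_by_day:
            grouped.setdefault(int(day), []).append(pk)
        peaks_by_day = grouped
    if len(peaks_by_day) < 2:
        raise InsufficientReplicationError("need peaks from at least two days")
    for day, pks in peaks_by_day.items():
        if len(pks) < 2:
            raise InsufficientReplicationError(
                f"day {day}: need >= 2 replicate peaks, got {len(pks)}"
            )
    ex = {d: [p.excitation_nm for p in pks] for d, pks in peaks_by_day.items()}
    em = {d: [p.emission_nm for p in pks] for d, pks in peaks_by_day.items()}
    ex_stab = _axis_stability("excitation", ex, alpha)
    em_stab = _axis_stability("emission", em, alpha)
    return StabilityReport(
        excitation=ex_stab,
        emission=em_stab,
        alpha=alpha,
        stable=ex_stab.single_group and em_stab.single_group,
    )
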