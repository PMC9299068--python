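"""Canonical stride-kinematics containers and gait-vector assembly.

A stride is described by nine joint-angle curves (pelvis and hip in all three
planes, knee flexion-extension, ankle dorsi/plantarflexion, and the foot
progression angle), each time-normalized to one gait cycle and sampled at 2%
increments, i.e. 51 points including both endpoints.  Concatenating the nine
curves in a fixed canonical order yields the 459-component *gait vector* that
all downstream linear algebra operates on.

The canonical angle order is a package convention (any fixed order is
mathematically equivalent); it is recorded in every basis file so that vectors
and bases can never be silently misaligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

#: Fixed concatenation order of the nine canonical angles.
CANONICAL_ANGLES: tuple[str, ...] = (
    "pelvic_tilt",
    "pelvic_obliquity",
    "pelvic_rotation",
    "hip_flexion",
    "hip_abduction",
    "hip_rotation",
    "knee_flexion",
    "ankle_dorsiflexion",
    "foot_progression",
)

#: Canonical gait-cycle grid: 0%, 2%, ..., 100% (51 points, endpoints included).
GRID_PERCENT: np.ndarray = np.arange(0.0, 101.0, 2.0)
N_SAMPLES: int = 51
N_ANGLES: int = 9
VECTOR_LENGTH: int = N_ANGLES * N_SAMPLES  # 459

_SIDES = ("left", "right", "unspecified")

#: Column layout of the long-format stride table.
STRIDE_CSV_COLUMNS = (
    "stride_id",
    "subject_id",
    "group_label",
    "side",
    "angle_name",
    "percent",
    "value_deg",
)


@dataclass(frozen=True)
class AngleCurve:
    """One joint-angle curve on the canonical 51-point grid, in degrees."""

    angle_name: str
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.angle_name not in CANONICAL_ANGLES:
            raise InputError(
                f"unknown angle name {self.angle_name!r}; expected one of {CANONICAL_ANGLES}"
            )
        samples = np.asarray(self.samples, dtype=float)
        if samples.shape != (N_SAMPLES,):
            raise InputError(
                f"{self.angle_name}: expected {N_SAMPLES} samples, got shape {samples.shape}"
            )
        if not np.all(np.isfinite(samples)):
            raise InputError(f"{self.angle_name}: non-finite sample values")
        object.__setattr__(self, "samples", samples)


@dataclass(frozen=True)
class StrideKinematics:
    """All nine canonical angle curves for one stride, plus metadata.

    ``group_label`` is either the distinguished string ``"control"`` or an
    ordinal impairment level (stored as a string; ordinal rank is parsed where
    needed by the statistics layer).
    """

    stride_id: str
    subject_id: str
    group_label: str
    curves: Mapping[str, AngleCurve]
    side: str = "unspecified"

    def __post_init__(self) -> None:
        if self.side not in _SIDES:
            raise InputError(f"side must be one of {_SIDES}, got {self.side!r}")
        names = set(self.curves)
        missing = [a for a in CANONICAL_ANGLES if a not in names]
        extra = sorted(names - set(CANONICAL_ANGLES))
        if missing or extra:
            raise InputError(
                f"stride {self.stride_id!r}: missing angles {missing}, unexpected angles {extra}"
            )
        for name, curve in self.curves.items():
            if curve.angle_name != name:
                raise InputError(
                    f"stride {self.stride_id!r}: curve keyed {name!r} is named {curve.angle_name!r}"
                )


@dataclass(frozen=True)
class GaitVector:
    """459-component concatenation of the nine angle curves of one stride."""

    components: np.ndarray
    stride_id: str = ""

    def __post_init__(self) -> None:
        comps = np.asarray(self.components, dtype=float)
        if comps.shape != (VECTOR_LENGTH,):
            raise InputError(
                f"gait vector must have exactly {VECTOR_LENGTH} components, got shape {comps.shape}"
            )
        if not np.all(np.isfinite(comps)):
            raise InputError("gait vector contains non-finite components")
        object.__setattr__(self, "components", comps)


@dataclass
class CohortMatrix:
    """Column-stacked gait vectors (459 x N) with aligned per-column metadata.

    ``metadata`` is a DataFrame with one row per column of ``matrix`` and the
    columns ``stride_id``, ``subject_id``, ``group_label``, ``side``.
    """

    matrix: np.ndarray
    metadata: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != VECTOR_LENGTH:
            raise InputError(
                f"cohort matrix must be {VECTOR_LENGTH} x N, got shape {matrix.shape}"
            )
        if matrix.shape[1] < 1:
            raise InputError("cohort matrix must have at least one column")
        if not np.all(np.isfinite(matrix)):
            raise InputError("cohort matrix contains non-finite entries")
        if len(self.metadata) != matrix.shape[1]:
            raise InputError(
                f"metadata rows ({len(self.metadata)}) do not match columns ({matrix.shape[1]})"
            )
        for col in ("stride_id", "subject_id", "group_label"):
            if col not in self.metadata.columns:
                raise InputError(f"cohort metadata missing column {col!r}")
        if "side" not in self.metadata.columns:
            self.metadata = self.metadata.assign(side="unspecified")
        self.matrix = matrix
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_strides(self) -> int:
        return self.matrix.shape[1]

    def column(self, j: int) -> GaitVector:
        return GaitVector(self.matrix[:, j], stride_id=str(self.metadata.at[j, "stride_id"]))


def resample_curve(
    raw_samples: Sequence[tuple[float, float]] | np.ndarray, angle_name: str
) -> AngleCurve:
    """Linearly interpolate raw (percent, degrees) pairs onto the canonical grid.

    Raw percents must be strictly increasing and cover the full cycle
    [0, 100].  Values already lying on grid points pass through unchanged
    (linear interpolation is exact at its nodes).
    """
    raw = np.asarray(raw_samples, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 2 or raw.shape[0] < 2:
        raise InputError(f"{angle_name}: need >= 2 (percent, value) pairs")
    percent, value = raw[:, 0], raw[:, 1]
    if not np.all(np.isfinite(raw)):
        raise InputError(f"{angle_name}: non-finite raw samples")
    if np.any(np.diff(percent) <= 0):
        raise InputError(f"{angle_name}: raw percents must be strictly increasing")
    if percent[0] > 0.0 or percent[-1] < 100.0:
        raise InputError(
            f"{angle_name}: raw samples must cover [0, 100], got [{percent[0]}, {percent[-1]}]"
        )
    grid_values = np.interp(GRID_PERCENT, percent, value)
    # exact passthrough where a raw sample sits on a grid node (np.interp can
    # introduce ~1 ulp of arithmetic error even at its own nodes)
    idx = np.searchsorted(percent, GRID_PERCENT)
    idx_clip = np.minimum(idx, percent.size - 1)
    on_node = percent[idx_clip] == GRID_PERCENT
    grid_values[on_node] = value[idx_clip[on_node]]
    return AngleCurve(angle_name, grid_values)


def assemble_gait_vector(stride: StrideKinematics) -> GaitVector:
    """Concatenate the nine curves of a stride in canonical order (459 values)."""
    components = np.concatenate(
        [stride.curves[name].samples for name in CANONICAL_ANGLES]
    )
    return GaitVector(components, stride_id=stride.stride_id)


def disassemble_gait_vector(vector: GaitVector) -> dict[str, AngleCurve]:
    """Split a gait vector back into its nine named angle curves."""
    comps = vector.components
    return {
        name: AngleCurve(name, comps[i * N_SAMPLES : (i + 1) * N_SAMPLES])
        for i, name in enumerate(CANONICAL_ANGLES)
    }


def build_cohort_matrix(strides: Iterable[StrideKinematics]) -> CohortMatrix:
    """Stack strides column-wise (input order preserved) with aligned metadata."""
    strides = list(strides)
    if not strides:
        raise InputError("cannot build a cohort matrix from an empty stride collection")
    columns = [assemble_gait_vector(s).components for s in strides]
    meta = pd.DataFrame(
        {
            "stride_id": [s.stride_id for s in strides],
            "subject_id": [s.subject_id for s in strides],
            "group_label": [s.group_label for s in strides],
            "side": [s.side for s in strides],
        }
    )
    return CohortMatrix(np.column_stack(columns), meta)


def strides_to_frame(strides: Iterable[StrideKinematics]) -> pd.DataFrame:
    """Long-format table of strides (one row per angle sample)."""
    records: list[tuple] = []
    for s in strides:
        for name in CANONICAL_ANGLES:
            for pct, val in zip(GRID_PERCENT, s.curves[name].samples):
                records.append(
                    (s.stride_id, s.subject_id, s.group_label, s.side, name, pct, val)
                )
    return pd.DataFrame.from_records(records, columns=STRIDE_CSV_COLUMNS)


def write_strides_csv(strides: Iterable[StrideKinematics], path) -> None:
    strides_to_frame(strides).to_csv(path, index=False)


def frame_to_strides(frame: pd.DataFrame) -> list[StrideKinematics]:
    """Rebuild strides from a long-format table, resampling off-grid percents.

    Each (stride, angle) group is sorted by percent and linearly resampled
    onto the canonical grid, so tables extracted at other (complete-cycle)
    samplings load transparently.
    """
    missing = [c for c in STRIDE_CSV_COLUMNS if c not in frame.columns and c != "side"]
    if missing:
        raise InputError(f"stride table missing required columns {missing}")
    if "side" not in frame.columns:
        frame = frame.assign(side="unspecified")
    strides = []
    for stride_id, g in frame.groupby("stride_id", sort=False):
        subject = str(g["subject_id"].iloc[0])
        group = str(g["group_label"].iloc[0])
        side = str(g["side"].iloc[0])
        curves = {}
        for angle, ga in g.groupby("angle_name", sort=False):
            ga = ga.sort_values("percent")
            raw = ga[["percent", "value_deg"]].to_numpy(dtype=float)
            curves[str(angle)] = resample_curve(raw, str(angle))
        strides.append(
            StrideKinematics(
                stride_id=str(stride_id),
                subject_id=subject,
                group_label=group,
                curves=curves,
                side=side,
            )
        )
    return strides


def read_strides_csv(path) -> list[StrideKinematics]:
    """Read strides from the long-format delimited table written by this package.

    Floats are parsed with the round-trip converter so a write/read cycle is
    bit-exact.
    """
    return frame_to_strides(pd.read_csv(path, float_precision="round_trip"))
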