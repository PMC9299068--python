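"""Deviation-index scoring against a control reference.

A stride's gait vector g is projected onto the first m gait features,
c = F_m' g, and its Euclidean distance d = ||c - c_bar|| to the mean control
feature vector c_bar is computed (by orthonormality this equals the distance
between the m-th order reconstructions in the full 459-dimensional space).
The natural log of d is then standardized against the control cohort's own
log-distances and mapped to the familiar clinical scale:

    index = 100 - 10 * (ln d - mean_ctrl ln d) / sd_ctrl ln d

so the control mean scores 100 and every 10 points below 100 is one control
standard deviation of log-deviation; scores above 100 are possible and mean
"closer to the control mean than the average control stride".  Because
z-scores of the fitting sample have mean 0 and SD 1 exactly, scoring the
reference control cohort itself returns a sample mean of 100 and sample SD
of 10 by construction.

References are cryptographically bound to the basis (and m) they were fitted
with; scoring with a mismatched basis raises instead of silently producing a
number on the wrong scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import GaitBasis, ZERO_NORM_TOL, _as_components
from .errors import DomainError, InputError
from .kinematics import CohortMatrix

logger = logging.getLogger(__name__)

REFERENCE_FORMAT_VERSION = "1.0"


@dataclass
class ControlReference:
    """Control-group scaling reference for the deviation index.

    ``c_bar`` is the mean control feature vector (length m); ``ln_d_mean``
    and ``ln_d_sd`` are the sample mean and SD (n-1 denominator) of the
    natural-log distances of the control strides from ``c_bar``.  With
    ``log_transform=False`` the raw distances are standardized instead (a
    sensitivity-analysis switch; the log scale is the default convention).
    """

    basis_fingerprint: str
    m: int
    c_bar: np.ndarray
    ln_d_mean: float
    ln_d_sd: float
    n_control: int
    log_transform: bool = True

    def __post_init__(self) -> None:
        c = np.asarray(self.c_bar, dtype=float)
        if c.shape != (self.m,):
            raise InputError(f"c_bar must have length m={self.m}, got shape {c.shape}")
        if self.n_control < 2:
            raise InputError("a control reference requires at least 2 control strides")
        if not self.ln_d_sd > 0:
            raise DomainError("reference log-distance SD must be positive")
        self.c_bar = c


@dataclass(frozen=True)
class DeviationScore:
    """Scored stride: distance in feature space, z on the log scale, index."""

    stride_id: str
    raw_distance: float
    z: float
    index: float


def feature_components(g, basis: GaitBasis, m: int) -> np.ndarray:
    """Representation of a gait vector in the first m features: c = F_m' g."""
    comps = _as_components(g)
    if not 1 <= m <= basis.m:
        raise InputError(f"m={m} outside [1, {basis.m}] for this basis")
    return basis.features[:, :m].T @ comps


def _check_bound(basis: GaitBasis, ref: ControlReference) -> None:
    if ref.basis_fingerprint != basis.fingerprint(ref.m):
        raise InputError(
            "control reference is not bound to this basis/m "
            "(fingerprint mismatch); refit or load the matching artifacts"
        )


def fit_control_reference(
    controls: CohortMatrix, basis: GaitBasis, m: int, log_transform: bool = True
) -> ControlReference:
    """Fit the scaling reference from a control cohort.

    Strides at (numerically) zero distance from the control mean are excluded
    from the log statistics with a warning; at least two strides with positive
    distance must remain, and their log-distances must not be all equal.
    """
    if controls.n_strides < 2:
        raise InputError("need at least 2 control strides to fit a reference")
    C = feature_components_matrix(controls, basis, m)
    c_bar = C.mean(axis=1)
    d = np.linalg.norm(C - c_bar[:, None], axis=0)
    positive = d > ZERO_NORM_TOL
    n_dropped = int(np.sum(~positive))
    if n_dropped:
        logger.warning(
            "excluding %d control stride(s) at zero distance from the control mean "
            "from the log-distance statistics",
            n_dropped,
        )
    d_pos = d[positive]
    if d_pos.size < 2:
        raise DomainError(
            "fewer than 2 control strides with positive distance from the mean"
        )
    vals = np.log(d_pos) if log_transform else d_pos
    sd = float(vals.std(ddof=1))
    if not sd > 0:
        raise DomainError(
            "control log-distances have zero spread; the 10-points-per-SD scale "
            "is undefined for this control set"
        )
    return ControlReference(
        basis_fingerprint=basis.fingerprint(m),
        m=m,
        c_bar=c_bar,
        ln_d_mean=float(vals.mean()),
        ln_d_sd=sd,
        n_control=int(d_pos.size),
        log_transform=log_transform,
    )


def feature_components_matrix(cohort: CohortMatrix, basis: GaitBasis, m: int) -> np.ndarray:
    """Feature components of every stride in a cohort; shape (m, N)."""
    if not 1 <= m <= basis.m:
        raise InputError(f"m={m} outside [1, {basis.m}] for this basis")
    return basis.features[:, :m].T @ cohort.matrix


def score(g, basis: GaitBasis, ref: ControlReference) -> DeviationScore:
    """Score a single stride against a fitted control reference."""
    _check_bound(basis, ref)
    c = feature_components(g, basis, ref.m)
    d = float(np.linalg.norm(c - ref.c_bar))
    if d <= ZERO_NORM_TOL:
        raise DomainError(
            "stride is identical to the control mean in feature space (distance 0); "
            "the log-distance is undefined — perturb the input or use a larger m"
        )
    val = np.log(d) if ref.log_transform else d
    z = (val - ref.ln_d_mean) / ref.ln_d_sd
    return DeviationScore(
        stride_id=str(getattr(g, "stride_id", "")),
        raw_distance=d,
        z=float(z),
        index=float(100.0 - 10.0 * z),
    )


def score_cohort(
    cohort: CohortMatrix,
    basis: GaitBasis,
    ref: ControlReference,
    subject_mean: bool = False,
) -> pd.DataFrame:
    """Score every stride of a cohort; one row per column.

    Strides at zero feature-space distance from the control mean are flagged
    (``valid=False``, NaN score) rather than aborting the whole cohort.  With
    ``subject_mean=True`` the per-stride table is aggregated to one row per
    (subject, group) with the mean index.
    """
    _check_bound(basis, ref)
    C = feature_components_matrix(cohort, basis, ref.m)
    d = np.linalg.norm(C - ref.c_bar[:, None], axis=0)
    valid = d > ZERO_NORM_TOL
    with np.errstate(divide="ignore"):
        vals = np.log(d) if ref.log_transform else d
    z = np.where(valid, (vals - ref.ln_d_mean) / ref.ln_d_sd, np.nan)
    index = 100.0 - 10.0 * z
    out = cohort.metadata.loc[:, ["stride_id", "subject_id", "group_label"]].copy()
    out["raw_distance"] = d
    out["z"] = z
    out["index"] = index
    out["valid"] = valid
    if not np.all(valid):
        logger.warning(
            "%d stride(s) at zero distance from the control mean were flagged invalid",
            int(np.sum(~valid)),
        )
    if subject_mean:
        out = (
            out[out["valid"]]
            .groupby(["subject_id", "group_label"], as_index=False)
            .agg(n_strides=("index", "size"), index=("index", "mean"))
        )
    return out


def summarize_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-group descriptives of the index: n, mean, SD, min, max.

    Groups present in the metadata but with no valid score appear with n=0
    and NaN statistics (flagged, not dropped).
    """
    rows = []
    for label, g in scores.groupby("group_label", sort=False):
        vals = g.loc[g.get("valid", True) & g["index"].notna(), "index"].to_numpy(float)
        n = vals.size
        rows.append(
            {
                "group_label": label,
                "n_strides": n,
                "mean_index": float(np.mean(vals)) if n else np.nan,
                "sd_index": float(np.std(vals, ddof=1)) if n > 1 else (0.0 if n else np.nan),
                "min_index": float(np.min(vals)) if n else np.nan,
                "max_index": float(np.max(vals)) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reference file I/O

def save_reference(ref: ControlReference, path) -> None:
    doc = {
        "format_version": REFERENCE_FORMAT_VERSION,
        "basis_fingerprint": ref.basis_fingerprint,
        "m": ref.m,
        "c_bar": ref.c_bar.tolist(),
        "ln_d_mean": ref.ln_d_mean,
        "ln_d_sd": ref.ln_d_sd,
        "n_control": ref.n_control,
        "log_transform": ref.log_transform,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_reference(path) -> ControlReference:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format_version") != REFERENCE_FORMAT_VERSION:
        raise InputError(
            f"unsupported reference format version {doc.get('format_version')!r}"
        )
    return ControlReference(
        basis_fingerprint=doc["basis_fingerprint"],
        m=int(doc["m"]),
        c_bar=np.asarray(doc["c_bar"], dtype=float),
        ln_d_mean=float(doc["ln_d_mean"]),
        ln_d_sd=float(doc["ln_d_sd"]),
        n_control=int(doc["n_control"]),
        log_transform=bool(doc.get("log_transform", True)),
    )
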