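"""Gait-feature basis derivation and quality assessment.

The stride matrix G (459 x N, one column per gait vector) is decomposed with
a singular value decomposition, G = U S V'.  The left singular vectors —
the *gait features* — form an orthonormal basis of the 459-dimensional curve
space, ordered by decreasing singular value.  The first m features give the
best rank-m subspace in the least-squares sense; two quality metrics drive
the choice of m:

* **VAF** (variance accounted for): 100 * sum_{i<=m} s_i^2 / sum_i s_i^2,
  a property of the singular values alone.
* **Reconstruction fidelity** of a stride g: 100 * ||P_m g|| / ||g|| where
  P_m is the orthogonal projection onto the first m features — the fraction
  of the stride's norm captured by its m-th order reconstruction.

No mean-centering is applied before the decomposition: the features must
reconstruct raw angle curves directly, and the convention is recorded in the
basis file so scoring can never mix conventions.

Feature-count selection scans a grid of m and takes the smallest m meeting
both a VAF floor and a mean-fidelity floor (defaults 98% / 98% over a grid
of 10..30); the percentage of strides reconstructed with fidelity >= 95% is
traced alongside but is not a gate.  Monte Carlo cross-validation (default
10 iterations, 5% random column holdout) re-derives the basis on subsamples
and reports the spread of the per-criterion minimal m, declaring the choice
stable when each criterion's minimal m varies by at most one feature.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InputError
from .kinematics import CANONICAL_ANGLES, VECTOR_LENGTH, CohortMatrix, GaitVector

BASIS_FORMAT_VERSION = "1.0"

#: Orthonormality tolerance enforced on every basis: max |F'F - I|.
ORTHONORMALITY_TOL = 1e-10

#: Strides with norm below this are degenerate for fidelity purposes.
ZERO_NORM_TOL = 1e-9


def _as_components(g) -> np.ndarray:
    comps = getattr(g, "components", g)
    comps = np.asarray(comps, dtype=float)
    if comps.shape != (VECTOR_LENGTH,):
        raise InputError(
            f"expected a {VECTOR_LENGTH}-component gait vector, got shape {comps.shape}"
        )
    return comps


@dataclass
class GaitBasis:
    """Ordered orthonormal gait features with their singular values.

    ``features`` is 459 x m with mutually orthonormal columns sorted by
    descending singular value; ``singular_values`` is the full descending
    spectrum of the training matrix.  ``provenance`` records the angle
    order, grid, centering convention and a hash of the training matrix.
    """

    features: np.ndarray
    singular_values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        F = np.asarray(self.features, dtype=float)
        s = np.asarray(self.singular_values, dtype=float)
        if F.ndim != 2 or F.shape[0] != VECTOR_LENGTH:
            raise InputError(f"features must be {VECTOR_LENGTH} x m, got {F.shape}")
        if not 1 <= F.shape[1] <= VECTOR_LENGTH:
            raise InputError(f"feature count m={F.shape[1]} outside [1, {VECTOR_LENGTH}]")
        if np.any(s < 0) or np.any(np.diff(s) > 0):
            raise InputError("singular values must be non-negative and non-increasing")
        gram_err = np.max(np.abs(F.T @ F - np.eye(F.shape[1])))
        if gram_err > ORTHONORMALITY_TOL:
            raise InputError(
                f"feature columns not orthonormal: max |F'F - I| = {gram_err:.3e}"
            )
        self.features = F
        self.singular_values = s

    @property
    def m(self) -> int:
        """Number of stored features."""
        return self.features.shape[1]

    def fingerprint(self, m: int | None = None) -> str:
        """Hash binding this basis (truncated at m features) for artifact pairing."""
        m = self.m if m is None else int(m)
        if not 1 <= m <= self.m:
            raise InputError(f"m={m} outside [1, {self.m}] for this basis")
        h = hashlib.sha256()
        h.update(",".join(CANONICAL_ANGLES).encode())
        h.update(f"|m={m}|".encode())
        h.update(np.ascontiguousarray(self.features[:, :m]).tobytes())
        return h.hexdigest()


@dataclass(frozen=True)
class BasisQuality:
    """Reconstruction quality of a stride set under the first m features.

    ``vaf_percent`` is None when the evaluated set is not the basis's own
    training set (the singular values then do not describe it).
    """

    m: int
    vaf_percent: float | None
    mean_fidelity_percent: float
    fidelity_sd_percent: float
    pct_high_fidelity: float
    high_fidelity_threshold: float
    n_strides: int


@dataclass(frozen=True)
class SelectionCriteria:
    """Quality floors and scan range for the feature-count grid search."""

    vaf_min: float = 98.0
    mean_fidelity_min: float = 98.0
    high_fidelity_threshold: float = 95.0
    m_min: int = 10
    m_max: int = 30

    def __post_init__(self) -> None:
        for name in ("vaf_min", "mean_fidelity_min", "high_fidelity_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 100.0:
                raise InputError(f"{name} must be in (0, 100], got {v}")
        if not (1 <= self.m_min <= self.m_max <= VECTOR_LENGTH):
            raise InputError(
                f"m range [{self.m_min}, {self.m_max}] invalid (must lie in [1, {VECTOR_LENGTH}])"
            )

    @property
    def m_grid(self) -> range:
        return range(self.m_min, self.m_max + 1)


@dataclass
class SelectionResult:
    """Outcome of the feature-count grid search.

    ``m_star`` is the smallest scanned m meeting both the VAF and the
    mean-fidelity floors, or None when no scanned m does ("not reached" is a
    value, not an error).  ``trace`` has one row per scanned m with columns
    m, vaf_percent, mean_fidelity_percent, pct_high_fidelity.
    """

    m_star: int | None
    trace: pd.DataFrame
    criteria: SelectionCriteria

    @property
    def reached(self) -> bool:
        return self.m_star is not None


@dataclass
class StabilityReport:
    """Monte Carlo cross-validation of the feature-count choice.

    Per-iteration minimal m for each criterion separately (None = not reached
    within the scan range), their mean +- SD, and the percentage of retained
    strides reconstructed above the high-fidelity threshold at the joint
    minimal m.  ``stable`` flags whether each criterion's minimal m varied by
    no more than one feature across iterations.
    """

    m_vaf: list[int | None]
    m_fidelity: list[int | None]
    m_joint: list[int | None]
    pct_high_fidelity_at_joint: list[float]
    iterations: int
    holdout_fraction: float
    n_removed: int
    seed: int | None
    criteria: SelectionCriteria

    @staticmethod
    def _mean_sd(values: Sequence[int | None]) -> tuple[float, float]:
        reached = [v for v in values if v is not None]
        if not reached:
            return float("nan"), float("nan")
        arr = np.asarray(reached, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), sd

    @property
    def m_vaf_mean_sd(self) -> tuple[float, float]:
        return self._mean_sd(self.m_vaf)

    @property
    def m_fidelity_mean_sd(self) -> tuple[float, float]:
        return self._mean_sd(self.m_fidelity)

    @property
    def m_joint_mean_sd(self) -> tuple[float, float]:
        return self._mean_sd(self.m_joint)

    @property
    def pct_high_fidelity_mean_sd(self) -> tuple[float, float]:
        arr = np.asarray(self.pct_high_fidelity_at_joint, dtype=float)
        if arr.size == 0:
            return float("nan"), float("nan")
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), sd

    @property
    def stable(self) -> bool:
        """True when each criterion's minimal m spans at most one feature."""
        for values in (self.m_vaf, self.m_fidelity):
            reached = [v for v in values if v is not None]
            if len(reached) < len(values):
                return False
            if max(reached) - min(reached) > 1:
                return False
        return True

    def to_dict(self) -> dict:
        mv, sv = self.m_vaf_mean_sd
        mf, sf = self.m_fidelity_mean_sd
        mj, sj = self.m_joint_mean_sd
        mp, sp = self.pct_high_fidelity_mean_sd
        return {
            "iterations": self.iterations,
            "holdout_fraction": self.holdout_fraction,
            "n_removed": self.n_removed,
            "seed": self.seed,
            "criteria": asdict(self.criteria),
            "m_vaf": self.m_vaf,
            "m_fidelity": self.m_fidelity,
            "m_joint": self.m_joint,
            "pct_high_fidelity_at_joint": self.pct_high_fidelity_at_joint,
            "m_vaf_mean": mv,
            "m_vaf_sd": sv,
            "m_fidelity_mean": mf,
            "m_fidelity_sd": sf,
            "m_joint_mean": mj,
            "m_joint_sd": sj,
            "pct_high_fidelity_mean": mp,
            "pct_high_fidelity_sd": sp,
            "stable": self.stable,
        }


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude component non-negative (in place copy)."""
    U = U.copy()
    idx = np.argmax(np.abs(U), axis=0)
    flip = U[idx, np.arange(U.shape[1])] < 0
    U[:, flip] *= -1.0
    return U


def matrix_sha256(matrix: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(matrix, dtype=float).tobytes()).hexdigest()


def decompose(cohort: CohortMatrix) -> GaitBasis:
    """Full singular value decomposition of a cohort matrix.

    Returns all min(459, N) gait features in descending singular-value order,
    with a deterministic sign convention (each feature's largest-magnitude
    component non-negative).  The sum of squared singular values equals the
    squared Frobenius norm of the input (energy conservation).
    """
    G = cohort.matrix
    if not np.all(np.isfinite(G)):
        raise InputError("cohort matrix contains non-finite entries")
    U, s, _ = np.linalg.svd(G, full_matrices=False)
    U = _fix_signs(U)
    provenance = {
        "format_version": BASIS_FORMAT_VERSION,
        "angle_order": list(CANONICAL_ANGLES),
        "grid": {"start_percent": 0.0, "stop_percent": 100.0, "step_percent": 2.0},
        "centering": False,
        "interpolation": "linear",
        "n_training_strides": cohort.n_strides,
        "training_matrix_sha256": matrix_sha256(G),
        "created": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    return GaitBasis(features=U, singular_values=s, provenance=provenance)


def vaf(singular_values: Sequence[float], m: int) -> float:
    """Variance accounted for by the first m features, in percent."""
    s = np.asarray(singular_values, dtype=float)
    if not 1 <= m <= s.size:
        raise InputError(f"m={m} outside [1, {s.size}]")
    total = float(np.sum(s**2))
    if total == 0.0:
        raise DomainError("all singular values are zero (empty signal)")
    return 100.0 * float(np.sum(s[:m] ** 2)) / total


def reconstruct(g, basis: GaitBasis, m: int) -> GaitVector:
    """m-th order approximation of a gait vector: projection onto the first m features."""
    comps = _as_components(g)
    if not 1 <= m <= basis.m:
        raise InputError(f"m={m} outside [1, {basis.m}] for this basis")
    Fm = basis.features[:, :m]
    approx = Fm @ (Fm.T @ comps)
    return GaitVector(approx, stride_id=getattr(g, "stride_id", ""))


def fidelity(g, g_hat) -> float:
    """Reconstruction fidelity: 100 * ||g_hat|| / ||g||.

    Assumes ``g_hat`` is an orthogonal projection of ``g`` (as produced by
    :func:`reconstruct`), in which case the value lies in [0, 100] — the
    fraction of the stride's norm its reconstruction captures.
    """
    gc = _as_components(g)
    hc = _as_components(g_hat)
    norm_g = float(np.linalg.norm(gc))
    if norm_g < ZERO_NORM_TOL:
        raise DomainError("fidelity undefined for a (near-)zero-norm gait vector")
    return 100.0 * float(np.linalg.norm(hc)) / norm_g


def _fidelity_matrix(G: np.ndarray, basis: GaitBasis, ms: Sequence[int]) -> np.ndarray:
    """Per-stride fidelities at each requested m; shape (len(ms), N).

    Uses cumulative squared feature components, so the whole m-grid costs one
    matrix product.
    """
    norms = np.linalg.norm(G, axis=0)
    if np.any(norms < ZERO_NORM_TOL):
        raise DomainError("cohort contains a (near-)zero-norm stride")
    max_m = max(ms)
    if max_m > basis.m:
        raise InputError(f"m={max_m} exceeds the {basis.m} features of this basis")
    C = basis.features[:, :max_m].T @ G  # (max_m, N)
    cum = np.cumsum(C**2, axis=0)
    idx = np.asarray(ms, dtype=int) - 1
    return 100.0 * np.sqrt(cum[idx, :]) / norms[None, :]


def evaluate_basis(
    cohort: CohortMatrix,
    basis: GaitBasis,
    m: int,
    high_fidelity_threshold: float = 95.0,
) -> BasisQuality:
    """Quality of the m-th order reconstructions of a stride set under a basis.

    VAF is only meaningful when the evaluated set is the basis's own training
    set (it is a function of the training singular values); for any other set
    it is reported as not applicable (None).
    """
    if not 1 <= m <= basis.m:
        raise InputError(f"m={m} outside [1, {basis.m}] for this basis")
    fid = _fidelity_matrix(cohort.matrix, basis, [m])[0]
    is_training = (
        basis.provenance.get("training_matrix_sha256") == matrix_sha256(cohort.matrix)
    )
    vaf_percent = vaf(basis.singular_values, m) if is_training else None
    return BasisQuality(
        m=m,
        vaf_percent=vaf_percent,
        mean_fidelity_percent=float(np.mean(fid)),
        fidelity_sd_percent=float(np.std(fid, ddof=1)) if fid.size > 1 else 0.0,
        pct_high_fidelity=100.0 * float(np.mean(fid >= high_fidelity_threshold)),
        high_fidelity_threshold=high_fidelity_threshold,
        n_strides=cohort.n_strides,
    )


def _selection_trace(
    cohort: CohortMatrix, basis: GaitBasis, criteria: SelectionCriteria
) -> pd.DataFrame:
    ms = [m for m in criteria.m_grid if m <= basis.m]
    if not ms:
        raise InputError(
            f"scan range [{criteria.m_min}, {criteria.m_max}] has no m within the "
            f"{basis.m} available features"
        )
    fid = _fidelity_matrix(cohort.matrix, basis, ms)
    rows = []
    for i, m in enumerate(ms):
        rows.append(
            {
                "m": m,
                "vaf_percent": vaf(basis.singular_values, m),
                "mean_fidelity_percent": float(np.mean(fid[i])),
                "pct_high_fidelity": 100.0
                * float(np.mean(fid[i] >= criteria.high_fidelity_threshold)),
            }
        )
    return pd.DataFrame(rows)


def select_feature_count(
    cohort: CohortMatrix, criteria: SelectionCriteria | None = None
) -> SelectionResult:
    """Grid-search the smallest m meeting both the VAF and mean-fidelity floors.

    Both criteria must hold on the training set itself.  The returned trace
    records VAF, mean fidelity and the high-fidelity percentage for every
    scanned m, whether or not a satisfying m exists.
    """
    criteria = criteria or SelectionCriteria()
    basis = decompose(cohort)
    trace = _selection_trace(cohort, basis, criteria)
    ok = (trace["vaf_percent"] >= criteria.vaf_min) & (
        trace["mean_fidelity_percent"] >= criteria.mean_fidelity_min
    )
    m_star = int(trace.loc[ok, "m"].iloc[0]) if ok.any() else None
    return SelectionResult(m_star=m_star, trace=trace, criteria=criteria)


def monte_carlo_stability(
    cohort: CohortMatrix,
    criteria: SelectionCriteria | None = None,
    iterations: int = 10,
    holdout_fraction: float = 0.05,
    seed: int | None = None,
) -> StabilityReport:
    """Assess stability of the feature-count choice under random column holdout.

    Each iteration removes floor(holdout_fraction * N) strides (at least one)
    uniformly at random without replacement, re-derives the basis on the
    remainder, and records the minimal m meeting each criterion separately,
    plus the high-fidelity percentage (on the retained strides) at the joint
    minimal m.  Small spread — no more than one feature — across iterations
    indicates the training set is large enough for a stable basis.
    """
    criteria = criteria or SelectionCriteria()
    n = cohort.n_strides
    n_removed = max(1, int(np.floor(holdout_fraction * n)))
    if n_removed >= n:
        raise InputError(
            f"holdout of {n_removed} strides would empty the {n}-stride cohort"
        )
    rng = np.random.default_rng(seed)
    m_vaf_list: list[int | None] = []
    m_fid_list: list[int | None] = []
    m_joint_list: list[int | None] = []
    pct_list: list[float] = []
    for _ in range(iterations):
        removed = rng.choice(n, size=n_removed, replace=False)
        keep = np.setdiff1d(np.arange(n), removed)
        sub = CohortMatrix(cohort.matrix[:, keep], cohort.metadata.iloc[keep])
        basis = decompose(sub)
        trace = _selection_trace(sub, basis, criteria)
        vaf_ok = trace["vaf_percent"] >= criteria.vaf_min
        fid_ok = trace["mean_fidelity_percent"] >= criteria.mean_fidelity_min
        joint_ok = vaf_ok & fid_ok
        m_vaf_list.append(int(trace.loc[vaf_ok, "m"].iloc[0]) if vaf_ok.any() else None)
        m_fid_list.append(int(trace.loc[fid_ok, "m"].iloc[0]) if fid_ok.any() else None)
        if joint_ok.any():
            m_joint = int(trace.loc[joint_ok, "m"].iloc[0])
            m_joint_list.append(m_joint)
            pct_list.append(
                float(trace.loc[trace["m"] == m_joint, "pct_high_fidelity"].iloc[0])
            )
        else:
            m_joint_list.append(None)
    return StabilityReport(
        m_vaf=m_vaf_list,
        m_fidelity=m_fid_list,
        m_joint=m_joint_list,
        pct_high_fidelity_at_joint=pct_list,
        iterations=iterations,
        holdout_fraction=holdout_fraction,
        n_removed=n_removed,
        seed=seed,
        criteria=criteria,
    )


# ---------------------------------------------------------------------------
# Basis file I/O (versioned JSON; the loadable analogue of a published basis)

def save_basis(basis: GaitBasis, path, m: int | None = None) -> None:
    """Write a basis (optionally truncated to its first m features) as JSON."""
    m = basis.m if m is None else int(m)
    if not 1 <= m <= basis.m:
        raise InputError(f"m={m} outside [1, {basis.m}] for this basis")
    doc = {
        "format_version": BASIS_FORMAT_VERSION,
        "m": m,
        "angle_order": list(CANONICAL_ANGLES),
        "grid": basis.provenance.get(
            "grid", {"start_percent": 0.0, "stop_percent": 100.0, "step_percent": 2.0}
        ),
        "centering": False,
        "features_row_major": basis.features[:, :m].ravel(order="C").tolist(),
        "singular_values": np.asarray(basis.singular_values, dtype=float).tolist(),
        "provenance": basis.provenance,
        "fingerprint": basis.fingerprint(m),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_basis(path) -> GaitBasis:
    """Load a basis file written by :func:`save_basis` (or any file in its layout)."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format_version") != BASIS_FORMAT_VERSION:
        raise InputError(
            f"unsupported basis format version {doc.get('format_version')!r}"
        )
    if doc.get("angle_order") != list(CANONICAL_ANGLES):
        raise InputError("basis file angle order does not match the canonical order")
    if doc.get("centering", False):
        raise InputError("centered bases are not supported by this scoring convention")
    m = int(doc["m"])
    F = np.asarray(doc["features_row_major"], dtype=float).reshape(VECTOR_LENGTH, m)
    s = np.asarray(doc["singular_values"], dtype=float)
    basis = GaitBasis(features=F, singular_values=s, provenance=doc.get("provenance", {}))
    stored = doc.get("fingerprint")
    if stored is not None and stored != basis.fingerprint(m):
        raise InputError("basis file fingerprint does not match its feature matrix")
    return basis
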