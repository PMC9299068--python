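"""Synthetic gait cohorts with known statistical structure.

No public motion-capture dataset accompanies the index construction, so this
module generates stride cohorts whose ground truth is known by design:

* smooth periodic angle curves built from a three-harmonic population
  template (an offset plus three sinusoids per angle — a modelling
  convenience that mimics the shape of time-normalized joint-angle curves,
  not physiology);
* per-stride biological variability (amplitude jitter, baseline offset,
  phase jitter, white measurement noise);
* severity-graded deviation from the control template — amplitude
  attenuation, systematic baseline drift and phase lag all scale with a
  severity parameter s in [0, 1] — with ordinal labels attached to severity
  bands, emulating the clinical pattern of a deviation index that decreases
  as an ordinal impairment scale worsens;
* low-rank cohorts of exactly known intrinsic dimensionality for testing
  rank recovery and feature-count selection.

Everything is driven by an explicit seed; the same seed reproduces a cohort
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .kinematics import (
    CANONICAL_ANGLES,
    GRID_PERCENT,
    VECTOR_LENGTH,
    AngleCurve,
    CohortMatrix,
    StrideKinematics,
    build_cohort_matrix,
)

N_HARMONICS = 3

# Template parameter ranges (degrees; phases in radians).  The fundamental
# amplitude range 5-30 deg brackets the excursion of typical lower-limb
# sagittal-plane angles over a gait cycle; higher harmonics add waveform
# detail without dominating.
A0_RANGE = (-10.0, 10.0)
A1_RANGE = (5.0, 30.0)
A23_RANGE = (0.0, 8.0)


@dataclass(frozen=True)
class PopulationTemplate:
    """Per-angle harmonic description of a population's mean gait pattern.

    For each canonical angle: offset ``a0`` (deg), harmonic amplitudes
    ``amps`` (deg, harmonics 1..3 of the gait cycle) and phases ``phases``
    (radians).
    """

    params: dict[str, dict[str, np.ndarray]]
    seed: int

    def curve(self, angle: str) -> np.ndarray:
        """Render one angle's template curve on the canonical grid."""
        p = self.params[angle]
        t = GRID_PERCENT / 100.0
        out = np.full_like(t, float(p["a0"]))
        for h in range(N_HARMONICS):
            out = out + p["amps"][h] * np.sin(2.0 * np.pi * (h + 1) * t + p["phases"][h])
        return out


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: its label, size and severity s in [0, 1] (0 = control-like)."""

    label: str
    n_strides: int
    severity: float

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise InputError(f"group {self.label!r}: n_strides must be >= 1")
        if not 0.0 <= self.severity <= 1.0:
            raise InputError(
                f"group {self.label!r}: severity must be in [0, 1], got {self.severity}"
            )


@dataclass(frozen=True)
class GeneratorSpec:
    """Cohort recipe: groups plus the variability and severity-effect scales.

    Per-stride variability (all independent draws):
      * ``amplitude_jitter_sd`` — multiplicative jitter on each harmonic
        amplitude (relative, default 0.05);
      * ``offset_sd`` — per-angle baseline offset (deg, default 2.0);
      * ``phase_jitter_sd`` — per-harmonic phase jitter (rad, default 0.05);
      * ``noise_sd`` — white measurement noise per sample (deg, default 1.0).

    Severity effects at severity s:
      * harmonic amplitudes attenuated by the factor (1 - 0.5 s);
      * an extra per-angle baseline drift with SD 10 s deg;
      * a systematic phase lag of 0.3 s rad on every harmonic.
    """

    groups: tuple[GroupSpec, ...]
    noise_sd: float = 1.0
    amplitude_jitter_sd: float = 0.05
    offset_sd: float = 2.0
    phase_jitter_sd: float = 0.05
    strides_per_subject: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise InputError("generator spec requires at least one group")
        for name in ("noise_sd", "amplitude_jitter_sd", "offset_sd", "phase_jitter_sd"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.strides_per_subject < 1:
            raise InputError("strides_per_subject must be >= 1")
        object.__setattr__(self, "groups", tuple(self.groups))


def make_population_template(seed: int) -> PopulationTemplate:
    """Draw a population template; deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    params: dict[str, dict[str, np.ndarray]] = {}
    for angle in CANONICAL_ANGLES:
        params[angle] = {
            "a0": np.asarray(rng.uniform(*A0_RANGE)),
            "amps": np.array(
                [
                    rng.uniform(*A1_RANGE),
                    rng.uniform(*A23_RANGE),
                    rng.uniform(*A23_RANGE),
                ]
            ),
            "phases": rng.uniform(0.0, 2.0 * np.pi, size=N_HARMONICS),
        }
    return PopulationTemplate(params=params, seed=seed)


def _stride_curves(
    template: PopulationTemplate, spec: GeneratorSpec, severity: float, rng
) -> dict[str, AngleCurve]:
    t = GRID_PERCENT / 100.0
    atten = 1.0 - 0.5 * severity
    lag = 0.3 * severity
    curves = {}
    for angle in CANONICAL_ANGLES:
        p = template.params[angle]
        amps = (
            p["amps"]
            * (1.0 + rng.normal(0.0, spec.amplitude_jitter_sd, size=N_HARMONICS))
            * atten
        )
        phases = p["phases"] + lag + rng.normal(0.0, spec.phase_jitter_sd, size=N_HARMONICS)
        baseline = (
            float(p["a0"])
            + rng.normal(0.0, spec.offset_sd)
            + rng.normal(0.0, 10.0 * severity)
        )
        vals = np.full_like(t, baseline)
        for h in range(N_HARMONICS):
            vals = vals + amps[h] * np.sin(2.0 * np.pi * (h + 1) * t + phases[h])
        vals = vals + rng.normal(0.0, spec.noise_sd, size=t.size)
        curves[angle] = AngleCurve(angle, vals)
    return curves


def generate_cohort(
    template: PopulationTemplate, spec: GeneratorSpec
) -> list[StrideKinematics]:
    """Generate strides for every group of a spec; reproducible under the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    strides: list[StrideKinematics] = []
    for group in spec.groups:
        for i in range(group.n_strides):
            subject = f"{group.label}_subj{i // spec.strides_per_subject:03d}"
            strides.append(
                StrideKinematics(
                    stride_id=f"{group.label}_stride{i:04d}",
                    subject_id=subject,
                    group_label=group.label,
                    curves=_stride_curves(template, spec, group.severity, rng),
                )
            )
    return strides


def generate_control_cohort(
    n_strides: int,
    template: PopulationTemplate | None = None,
    seed: int = 0,
    label: str = "control",
    **spec_kwargs,
) -> CohortMatrix:
    """Convenience wrapper: one severity-0 group as a ready cohort matrix."""
    template = template or make_population_template(seed)
    spec = GeneratorSpec(
        groups=(GroupSpec(label, n_strides, 0.0),), seed=seed, **spec_kwargs
    )
    return build_cohort_matrix(generate_cohort(template, spec))


def generate_low_rank_cohort(
    k: int,
    n: int,
    noise_sd: float = 0.0,
    seed: int | None = None,
    scale: float = 10.0,
) -> CohortMatrix:
    """Cohort drawn exactly from a k-dimensional subspace, plus optional noise.

    Columns are random linear combinations of k fixed random orthonormal
    459-vectors with standard-normal coefficients scaled by ``scale`` (deg;
    the default 10 gives per-stride signal energy comparable to real
    joint-angle excursions, so sub-degree noise is a small perturbation),
    plus white noise of SD ``noise_sd``.  With ``noise_sd=0`` the matrix has
    numerically exact rank k.
    """
    if not 1 <= k <= min(VECTOR_LENGTH, n):
        raise InputError(f"k={k} outside [1, min({VECTOR_LENGTH}, n={n})]")
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((VECTOR_LENGTH, k)))
    coeffs = scale * rng.standard_normal((k, n))
    G = Q @ coeffs
    if noise_sd > 0:
        G = G + rng.normal(0.0, noise_sd, size=G.shape)
    meta = pd.DataFrame(
        {
            "stride_id": [f"lr_stride{j:04d}" for j in range(n)],
            "subject_id": [f"lr_subj{j:04d}" for j in range(n)],
            "group_label": ["synthetic"] * n,
            "side": ["unspecified"] * n,
        }
    )
    return CohortMatrix(G, meta)
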