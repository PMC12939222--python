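"""Depth-dependent caries degradation and inter-tooth variability.

Demineralization is modeled as a parametric perturbation of the affected
layer: for lesion severity ``alpha`` in [0, 1],

    k_i -> k_i (1 - beta_k alpha)
    c_i -> c_i (1 + beta_c alpha)
    m_i -> m_i (1 - beta_m alpha)

i.e. the lesion softens and lightens the layer while increasing its energy
dissipation.  Enamel lesions act on layer 1 with mild coefficients; dentin
lesions act on layer 2 with stronger coefficients and a deeper severity
range, reflecting the assumption that deeper lesions perturb the mechanics
more strongly.  Inter-tooth variability is an independent multiplicative
uniform perturbation of all nine baseline parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mechanics import ToothLayerParams

HEALTHY = "healthy"
ENAMEL_CARIES = "enamel_caries"
DENTIN_CARIES = "dentin_caries"
CLASS_LABELS: tuple[str, ...] = (HEALTHY, ENAMEL_CARIES, DENTIN_CARIES)

#: severity ranges the per-class lesion sampler draws from (uniform)
ALPHA_RANGES: dict[str, tuple[float, float]] = {
    ENAMEL_CARIES: (0.2, 0.5),
    DENTIN_CARIES: (0.4, 0.8),
}


@dataclass(frozen=True)
class CariesCoefficients:
    """Dimensionless degradation coefficients (stiffness, damping, mass)."""

    beta_k: float
    beta_c: float
    beta_m: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta_k <= 1.0 and 0.0 <= self.beta_m <= 1.0):
            raise ValueError("beta_k and beta_m must lie in [0, 1]")
        if self.beta_c < 0.0:
            raise ValueError("beta_c must be non-negative")


ENAMEL_COEFFS = CariesCoefficients(beta_k=0.6, beta_c=0.8, beta_m=0.3)
DENTIN_COEFFS = CariesCoefficients(beta_k=0.8, beta_c=1.0, beta_m=0.3)
DEFAULT_COEFFS: dict[str, CariesCoefficients] = {
    ENAMEL_CARIES: ENAMEL_COEFFS,
    DENTIN_CARIES: DENTIN_COEFFS,
}

#: 1-based index of the layer each lesion class degrades
AFFECTED_LAYER: dict[str, int] = {ENAMEL_CARIES: 1, DENTIN_CARIES: 2}


@dataclass(frozen=True)
class LesionSpec:
    """One sampled lesion: class, severity and the coefficients to apply.

    A healthy spec carries ``alpha = 0`` and no affected layer, and applying
    it leaves the parameters untouched.
    """

    class_label: str
    alpha: float = 0.0
    affected_layer: int | None = None
    coefficients: CariesCoefficients | None = None

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"lesion severity alpha must be in [0, 1], got {self.alpha}")
        if self.class_label == HEALTHY:
            if self.affected_layer is not None:
                raise ValueError("healthy lesion spec cannot name an affected layer")
        else:
            if self.affected_layer not in (1, 2, 3):
                raise ValueError("carious lesion spec needs an affected layer in {1,2,3}")
            if self.coefficients is None:
                raise ValueError("carious lesion spec needs degradation coefficients")


def apply_lesion(params: ToothLayerParams, lesion: LesionSpec) -> ToothLayerParams:
    """Degrade the affected layer's parameters; healthy input passes through.

    Deterministic and, at ``alpha = 0``, the identity.  Raises if the scaled
    parameters would become non-positive.
    """
    if lesion.class_label == HEALTHY or lesion.alpha == 0.0:
        return params
    i = lesion.affected_layer - 1
    beta = lesion.coefficients
    m = params.masses.copy()
    k = params.stiffnesses.copy()
    c = params.dampings.copy()
    k[i] *= 1.0 - beta.beta_k * lesion.alpha
    c[i] *= 1.0 + beta.beta_c * lesion.alpha
    m[i] *= 1.0 - beta.beta_m * lesion.alpha
    values = np.concatenate([m, k, c])
    if np.any(values <= 0.0):
        raise ValueError(
            f"lesion alpha={lesion.alpha} with {beta} drives a parameter non-positive"
        )
    return ToothLayerParams.from_array(values)


def sample_lesion(
    class_label: str,
    rng: np.random.Generator,
    coefficients: CariesCoefficients | None = None,
) -> LesionSpec:
    """Draw a lesion spec for the given screening class.

    Severity is uniform on the class range (enamel [0.2, 0.5], dentin
    [0.4, 0.8]); healthy draws consume no randomness and modify nothing.
    ``coefficients`` overrides the class default (used e.g. for null-effect
    controls with all betas zero).
    """
    if class_label not in CLASS_LABELS:
        raise ValueError(f"unknown class label {class_label!r}")
    if class_label == HEALTHY:
        return LesionSpec(class_label=HEALTHY)
    lo, hi = ALPHA_RANGES[class_label]
    alpha = rng.uniform(lo, hi)
    return LesionSpec(
        class_label=class_label,
        alpha=alpha,
        affected_layer=AFFECTED_LAYER[class_label],
        coefficients=coefficients if coefficients is not None else DEFAULT_COEFFS[class_label],
    )


def perturb_baseline(
    params: ToothLayerParams, pct: float, rng: np.random.Generator
) -> ToothLayerParams:
    """Inter-tooth variability: scale each parameter by U(1-pct, 1+pct).

    The nine multiplicative factors are independent, giving each simulated
    sample its own baseline tooth before any lesion is applied.
    """
    if pct < 0.0:
        raise ValueError(f"perturbation fraction must be >= 0, got {pct}")
    if pct >= 1.0:
        raise ValueError(f"perturbation fraction must be < 1, got {pct}")
    if pct == 0.0:
        return params
    factors = rng.uniform(1.0 - pct, 1.0 + pct, size=9)
    return ToothLayerParams.from_array(params.as_array() * factors)
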