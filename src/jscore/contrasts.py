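"""Orthogonal polynomial contrast encoding of the severity predictors.

Ordered factors are encoded with orthogonal polynomial contrasts over
equally spaced level scores: a k-level factor contributes k-1 columns
(degree 1..k-1), mutually orthonormal and orthogonal to the constant
vector, exactly as R's ``contr.poly``.  A 3-level ordinal indicator thus
yields a linear and a quadratic column; a binary flag yields a single
column.  The contrast basis is a reparameterization of the factor's dummy
encoding: it changes the coefficient basis, not the model space, but keeps
the linear/quadratic components of each ordinal effect directly readable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from jscore.codes import ELIX_CATEGORIES, N_BODY_SYSTEMS
from jscore.features import SeverityFeatures

__all__ = [
    "Variant",
    "VARIANTS",
    "orthogonal_contrasts",
    "ContrastDesign",
    "design_matrix",
]

Variant = Literal["full", "comorbidity", "body_system"]
VARIANTS: tuple[Variant, ...] = ("full", "comorbidity", "body_system")


def orthogonal_contrasts(k: int) -> np.ndarray:
    """Polynomial contrast matrix for a k-level ordered factor.

    Returns a (k, k-1) matrix whose columns are the degree-1..k-1
    orthonormal polynomial contrasts over scores 0..k-1:
    ``C.T @ C == I`` and ``ones @ C == 0``.
    """
    if k < 2:
        raise ValueError(f"ordered factor needs at least 2 levels, got {k}")
    scores = np.arange(k, dtype=float)
    vander = np.vander(scores, k, increasing=True)  # columns 1, x, x^2, ...
    q, r = np.linalg.qr(vander)
    # fix column signs so the top-degree coefficient is positive (R convention)
    q = q * np.sign(np.diag(r))
    return q[:, 1:]


@dataclass(frozen=True)
class ContrastDesign:
    """Column layout of a model variant's design matrix.

    ``full`` uses the 18 ordinal body-system indicators (two contrast
    columns each) plus the 30 binary comorbidity flags (one column each):
    48 predictor variables, 66 design columns.  ``comorbidity`` uses the
    30 flags alone (30 columns); ``body_system`` the 18 ordinals alone
    (36 columns).
    """

    variant: Variant

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown model variant {self.variant!r}")

    @property
    def uses_body_systems(self) -> bool:
        return self.variant in ("full", "body_system")

    @property
    def uses_elixhauser(self) -> bool:
        return self.variant in ("full", "comorbidity")

    @property
    def n_predictors(self) -> int:
        """Number of predictor *variables* (48 / 30 / 18)."""
        return (N_BODY_SYSTEMS if self.uses_body_systems else 0) + (
            len(ELIX_CATEGORIES) if self.uses_elixhauser else 0
        )

    @property
    def n_columns(self) -> int:
        """Number of design-matrix columns (66 / 30 / 36)."""
        return (2 * N_BODY_SYSTEMS if self.uses_body_systems else 0) + (
            len(ELIX_CATEGORIES) if self.uses_elixhauser else 0
        )

    @property
    def column_names(self) -> tuple[str, ...]:
        names: list[str] = []
        if self.uses_body_systems:
            for s in range(1, N_BODY_SYSTEMS + 1):
                names.append(f"bs{s:02d}.L")
                names.append(f"bs{s:02d}.Q")
        if self.uses_elixhauser:
            names.extend(ELIX_CATEGORIES)
        return tuple(names)

    def encode(self, features: SeverityFeatures) -> np.ndarray:
        """Design row for one encounter's features (no intercept column)."""
        parts: list[np.ndarray] = []
        if self.uses_body_systems:
            c3 = orthogonal_contrasts(3)
            parts.append(c3[features.body_system_levels].ravel())
        if self.uses_elixhauser:
            c2 = orthogonal_contrasts(2)
            parts.append(c2[features.elix_flags, 0])
        return np.concatenate(parts)

    def encode_dummy(self, features: SeverityFeatures) -> np.ndarray:
        """Treatment (one-hot, reference level 0) encoding of the same factors.

        Spans the same model space as :meth:`encode`; used for
        reparameterization-equivalence checks.
        """
        parts: list[np.ndarray] = []
        if self.uses_body_systems:
            eye = np.eye(3)[:, 1:]  # indicators for levels 1 and 2
            parts.append(eye[features.body_system_levels].ravel())
        if self.uses_elixhauser:
            parts.append(features.elix_flags.astype(float))
        return np.concatenate(parts)


def design_matrix(
    features: Sequence[SeverityFeatures],
    variant: Variant,
    *,
    encoding: Literal["contrast", "dummy"] = "contrast",
) -> np.ndarray:
    """Stack encoded design rows for a sequence of encounters.

    Vectorized equivalent of encoding each row with
    :meth:`ContrastDesign.encode` (or ``encode_dummy``).
    """
    design = ContrastDesign(variant)
    n = len(features)
    if n == 0:
        return np.empty((0, design.n_columns))
    bsl = np.stack([f.body_system_levels for f in features])
    ef = np.stack([f.elix_flags for f in features])
    parts: list[np.ndarray] = []
    if encoding == "contrast":
        if design.uses_body_systems:
            parts.append(orthogonal_contrasts(3)[bsl].reshape(n, -1))
        if design.uses_elixhauser:
            parts.append(orthogonal_contrasts(2)[ef, 0])
    elif encoding == "dummy":
        if design.uses_body_systems:
            parts.append(np.eye(3)[:, 1:][bsl].reshape(n, -1))
        if design.uses_elixhauser:
            parts.append(ef.astype(float))
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    return np.concatenate(parts, axis=1)
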