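"""Severity regression model: logistic GLM on orthogonal polynomial contrasts.

The probability that an encounter is a high-severity case (APR-DRG SOI 3
or 4) is modelled as

    logit P(high) = b0 + x' b

where x is the contrast-encoded feature row of one of three variants:
``full`` (18 body-system ordinals + 30 comorbidity flags), ``comorbidity``
(flags only) or ``body_system`` (ordinals only).  The fitted probability
is the encounter's severity score: **J_Score** when discharge features are
used, **J_Score_POA** when admission features are used.

The API follows the Model/Results idiom: build a :class:`SeverityModel`
from encounters (or prebuilt arrays), call :meth:`~SeverityModel.fit`,
and work with the returned :class:`SeverityResults` (parameters, standard
errors, ``summary()``, ``predict``, JSON serialization).
Estimation is maximum likelihood via iteratively reweighted least squares
(IRLS), with an optional ridge penalty as the documented escape hatch for
(quasi-)separated data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit, xlogy

from jscore.codes import ReferenceMaps
from jscore.contrasts import ContrastDesign, Variant, design_matrix
from jscore.features import (
    POA_PRESENT_DEFAULT,
    Encounter,
    Phase,
    SeverityFeatures,
    binarize_outcome,
    build_features,
)

__all__ = [
    "SeverityModel",
    "SeverityResults",
    "SeparationError",
    "predict_probability",
]

# |linear predictor| beyond which fitted probabilities are 0/1 to double
# precision; sustained growth past this point under an unpenalized fit is
# the practical signature of (quasi-)separation.
_ETA_SEPARATION = 30.0


class SeparationError(RuntimeError):
    """Perfect or quasi-complete separation under an unpenalized fit."""


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * (xlogy(y, y / mu) + xlogy(1 - y, (1 - y) / (1 - mu))).sum())


class SeverityModel:
    """Binary high-severity outcome regressed on contrast-encoded features.

    Parameters
    ----------
    labels : array of {0,1}
        Binary high-severity outcome per encounter.
    features : sequence of SeverityFeatures, optional
        Per-encounter features; retained so results can re-encode.
    variant : {"full", "comorbidity", "body_system"}
    phase : {"admission", "discharge"}
        Which phase the features describe; metadata only.
    exog : ndarray, optional
        Pre-encoded design matrix (without intercept).  Built from
        ``features`` when omitted.
    """

    def __init__(
        self,
        labels: Sequence[int] | np.ndarray,
        features: Sequence[SeverityFeatures] | None = None,
        *,
        variant: Variant = "body_system",
        phase: Phase = "discharge",
        exog: np.ndarray | None = None,
    ) -> None:
        self.design = ContrastDesign(variant)
        self.variant: Variant = variant
        self.phase: Phase = phase
        self.endog = np.asarray(labels, dtype=float)
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("labels must be binary 0/1")
        if exog is None:
            if features is None:
                raise ValueError("provide either features or exog")
            exog = design_matrix(features, variant)
        exog = np.asarray(exog, dtype=float)
        if exog.ndim != 2 or exog.shape[1] != self.design.n_columns:
            raise ValueError(
                f"design has {exog.shape[1] if exog.ndim == 2 else '?'} columns, "
                f"variant {variant!r} needs {self.design.n_columns}"
            )
        if exog.shape[0] != self.endog.shape[0]:
            raise ValueError("labels and design row counts differ")
        if not np.isfinite(exog).all():
            raise ValueError("design matrix contains non-finite values")
        self.exog = exog

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_encounters(
        cls,
        encounters: Sequence[Encounter],
        maps: ReferenceMaps,
        *,
        variant: Variant = "body_system",
        phase: Phase = "discharge",
        poa_present: frozenset[str] = POA_PRESENT_DEFAULT,
    ) -> "SeverityModel":
        """Build features and outcomes for ``phase`` from raw encounters.

        The outcome binarizes ``admit_soi`` for the admission phase and
        ``discharge_soi`` for discharge.
        """
        feats = [
            build_features(e, maps, phase, poa_present=poa_present)
            for e in encounters
        ]
        soi_attr = "admit_soi" if phase == "admission" else "discharge_soi"
        labels = [binarize_outcome(getattr(e, soi_attr)) for e in encounters]
        return cls(labels, feats, variant=variant, phase=phase)

    @classmethod
    def from_dataframe(
        cls,
        frame,
        *,
        variant: Variant = "body_system",
        phase: Phase = "discharge",
        label_column: str = "high_severity",
    ):
        """Build from a DataFrame holding the label column plus the
        contrast-encoded design columns named per
        :attr:`ContrastDesign.column_names`."""
        design = ContrastDesign(variant)
        exog = frame.loc[:, list(design.column_names)].to_numpy(dtype=float)
        return cls(frame[label_column].to_numpy(), variant=variant, phase=phase, exog=exog)

    @property
    def nobs(self) -> int:
        return self.endog.shape[0]

    # -- estimation -----------------------------------------------------
    def fit(
        self,
        *,
        ridge: float = 0.0,
        tol: float = 1e-8,
        maxiter: int = 100,
        start_params: np.ndarray | None = None,
    ) -> "SeverityResults":
        """Maximum-likelihood logistic fit via IRLS.

        Convergence is declared when the relative deviance change drops
        below ``tol``.  ``ridge`` adds an L2 penalty (excluding the
        intercept) as a fallback for separated data; with ``ridge=0`` a
        diverging linear predictor raises :class:`SeparationError`
        advising the ridge option.
        """
        y = self.endog
        n_pos = int(y.sum())
        if n_pos == 0 or n_pos == self.nobs:
            raise ValueError(
                "outcome is single-class: need at least one high-severity and "
                "one low-severity encounter"
            )
        X = np.column_stack([np.ones(self.nobs), self.exog])
        p = X.shape[1]
        penalty = np.zeros(p)
        penalty[1:] = ridge  # never penalize the intercept
        beta = (
            np.zeros(p) if start_params is None else np.asarray(start_params, float)
        )
        eta = X @ beta
        mu = expit(eta)
        deviance = _binomial_deviance(y, np.clip(mu, 1e-12, 1 - 1e-12))
        converged = False
        iterations = 0
        for iterations in range(1, maxiter + 1):
            w = np.clip(mu * (1.0 - mu), 1e-12, None)
            z = eta + (y - mu) / w
            xtw = X.T * w
            hessian = xtw @ X + np.diag(penalty)
            try:
                beta_new = np.linalg.solve(hessian, xtw @ z)
            except np.linalg.LinAlgError:
                # rank-deficient design (e.g. a level never observed):
                # minimum-norm IRLS step
                beta_new = np.linalg.lstsq(hessian, xtw @ z, rcond=None)[0]
            eta = X @ beta_new
            mu = expit(eta)
            mu_safe = np.clip(mu, 1e-12, 1 - 1e-12)
            dev_new = _binomial_deviance(y, mu_safe) + float(
                penalty @ (beta_new**2)
            )
            beta = beta_new
            if abs(deviance - dev_new) < tol * (abs(dev_new) + 0.1):
                deviance = dev_new
                converged = True
                break
            deviance = dev_new
        if ridge == 0.0:
            # every case classified perfectly with the deviance driven to
            # zero (or a diverging linear predictor that never converged)
            # means the MLE is at infinity
            misclassified = ((mu > 0.5) != (y > 0.5)).mean()
            perfect = misclassified == 0.0 and deviance < 1e-6
            diverged = not converged and np.max(np.abs(eta)) > _ETA_SEPARATION
            if perfect or diverged:
                raise SeparationError(
                    "linear predictor is diverging: the data are perfectly "
                    "or quasi-completely separated; refit with a small "
                    "ridge penalty (fit(ridge=...)) to obtain finite "
                    "coefficients"
                )
        mu_safe = np.clip(mu, 1e-12, 1 - 1e-12)
        llf = float((xlogy(y, mu_safe) + xlogy(1 - y, 1 - mu_safe)).sum())
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        cov = np.linalg.pinv((X.T * w) @ X + np.diag(penalty))
        return SeverityResults(
            model=self,
            params=beta,
            cov_params=cov,
            deviance=_binomial_deviance(y, mu_safe),
            llf=llf,
            iterations=iterations,
            converged=converged,
            ridge=ridge,
        )


@dataclass
class SeverityResults:
    """Fitted severity model: estimates, uncertainty, and scoring."""

    model: SeverityModel
    params: np.ndarray  # intercept first, then design columns
    cov_params: np.ndarray
    deviance: float
    llf: float
    iterations: int
    converged: bool
    ridge: float = 0.0

    # -- accessors ------------------------------------------------------
    @property
    def variant(self) -> Variant:
        return self.model.variant

    @property
    def phase(self) -> Phase:
        return self.model.phase

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def coefficients(self) -> np.ndarray:
        return self.params[1:]

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of (intercept, coefficients)."""
        return np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))

    @property
    def param_names(self) -> tuple[str, ...]:
        return ("intercept",) + self.model.design.column_names

    # -- prediction -----------------------------------------------------
    def linear_predictor(self, features) -> np.ndarray:
        if isinstance(features, SeverityFeatures):
            rows = self.model.design.encode(features)[None, :]
        elif isinstance(features, np.ndarray) and features.ndim == 2:
            rows = features
        else:
            rows = design_matrix(list(features), self.variant)
        if rows.shape[1] != self.model.design.n_columns:
            raise ValueError(
                f"feature encoding width {rows.shape[1]} does not match "
                f"variant {self.variant!r} ({self.model.design.n_columns})"
            )
        return self.params[0] + rows @ self.params[1:]

    def predict(self, features) -> np.ndarray | float:
        """Probability of high severity; scalar for a single
        :class:`SeverityFeatures`, array otherwise."""
        proba = expit(self.linear_predictor(features))
        if isinstance(features, SeverityFeatures):
            return float(proba[0])
        return proba

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        """Plain-text coefficient table with z statistics."""
        from scipy.stats import norm

        se = self.bse
        z = self.params / se
        pvals = 2 * norm.sf(np.abs(z))
        lines = [
            "Severity model (logit link, orthogonal polynomial contrasts)",
            f"variant: {self.variant}   phase: {self.phase}   "
            f"n = {self.model.nobs}",
            f"deviance = {self.deviance:.3f}   log-likelihood = {self.llf:.3f}",
            f"IRLS iterations = {self.iterations}   converged = {self.converged}"
            + (f"   ridge = {self.ridge:g}" if self.ridge else ""),
            "",
            f"{'term':<12}{'coef':>12}{'std err':>12}{'z':>10}{'P>|z|':>10}",
            "-" * 56,
        ]
        for name, b, s, zz, pv in zip(self.param_names, self.params, se, z, pvals):
            lines.append(f"{name:<12}{b:>12.4f}{s:>12.4f}{zz:>10.2f}{pv:>10.3g}")
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------
    def to_dict(self, *, maps_version: str | None = None) -> dict:
        return {
            "format": "jscore-model-v1",
            "variant": self.variant,
            "phase": self.phase,
            "link": "logit",
            "contrast": "orthogonal_polynomial",
            "column_names": list(self.model.design.column_names),
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "bse": self.bse.tolist(),
            "deviance": self.deviance,
            "llf": self.llf,
            "iterations": self.iterations,
            "converged": self.converged,
            "ridge": self.ridge,
            "nobs": self.model.nobs,
            "maps_version": maps_version,
        }

    def save(self, path: str | Path, *, maps_version: str | None = None) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(maps_version=maps_version), indent=1))
        return path

    @classmethod
    def from_dict(cls, doc: dict) -> "SeverityResults":
        if doc.get("format") != "jscore-model-v1":
            raise ValueError(f"unrecognized model document format {doc.get('format')!r}")
        params = np.concatenate([[doc["intercept"]], doc["coefficients"]])
        width = len(doc["coefficients"])
        # results rebuilt from disk carry an empty data container
        model = SeverityModel(
            labels=np.array([0.0, 1.0]),
            variant=doc["variant"],
            phase=doc["phase"],
            exog=np.zeros((2, width)),
        )
        bse = np.asarray(doc.get("bse", np.full(width + 1, np.nan)))
        return cls(
            model=model,
            params=params,
            cov_params=np.diag(bse**2),
            deviance=doc.get("deviance", float("nan")),
            llf=doc.get("llf", float("nan")),
            iterations=doc.get("iterations", 0),
            converged=doc.get("converged", True),
            ridge=doc.get("ridge", 0.0),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SeverityResults":
        return cls.from_dict(json.loads(Path(path).read_text()))


def predict_probability(results: SeverityResults, features: SeverityFeatures) -> float:
    """Functional alias for ``results.predict(features)`` on one encounter."""
    return results.predict(features)
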