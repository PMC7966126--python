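"""Total-score observation models: the CV and BI families.

Eight model families describe a longitudinal total score, crossing

* family — continuous-variable (CV: normal residual on the TS scale) vs
  bounded-integer (BI: probit partition of a latent normal into the n
  integer scores),
* mean scale — structural model directly on the observation scale (TS for
  CV, Z for BI), or on the IRT latent scale Psi mapped through the mean
  link polynomial (pn1 for CV, pn3 for BI),
* SD structure — homoscedastic (one estimated parameter), or IRT-informed
  through the SD link polynomial (pn2 / pn4), optionally elaborated by a
  positive scale factor, lognormal inter-individual variability, or an
  additive term.

Naming follows the S- / SDI- / MI- / I- convention: standard, SD-informed,
mean-informed and fully informed variants.

This module provides the conditional (given random effects) log-likelihood
contributions; marginalization and fitting live in
:mod:`irtlink.estimation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, ndtr, ndtri

from .links import LinkSet

__all__ = [
    "StructuralSpec",
    "ModelSpec",
    "model_spec",
    "structural_psi",
    "cv_obs_loglik",
    "bi_log_pmf",
    "bi_obs_loglik",
    "obs_loglik",
    "MODEL_NAMES",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

SD_STRUCTURES = (
    "homoscedastic",
    "irt_fixed",
    "irt_scaled",
    "irt_scaled_iiv",
    "irt_additive_iiv",
)


@dataclass(frozen=True)
class StructuralSpec:
    """Linear disease-progression structural model.

    ``value = theta1 + theta2 * t - theta3 * X1 (+ eta_baseline + eta_slope * t)``

    where ``theta1`` is the baseline, ``theta2`` the slope per year,
    ``theta3`` an offset effect of the medication covariate ``X1`` (0/1),
    and the eta terms are additive normal random effects on the parameters
    named in ``iiv``.
    """

    has_slope: bool = True
    has_medication: bool = False
    iiv: tuple = ("baseline",)
    correlated_iiv: bool = False
    covariate: str = "MED"

    def __post_init__(self):
        bad = set(self.iiv) - {"baseline", "slope"}
        if bad:
            raise ValueError(f"unknown IIV targets {sorted(bad)}")
        if not self.iiv:
            raise ValueError("IIV map must be nonempty for mixed-effects fits")
        if "slope" in self.iiv and not self.has_slope:
            raise ValueError("IIV on slope requires a slope term")


@dataclass(frozen=True)
class ModelSpec:
    """One of the total-score model families.

    ``family`` is ``'cv'`` or ``'bi'``; ``mean_scale`` is ``'ts'``, ``'z'``
    or ``'psi'``; ``sd_structure`` one of ``SD_STRUCTURES``.  BI models need
    ``n_categories`` (and ``ts_min``) to map scores onto the probit grid.
    """

    family: str
    mean_scale: str
    sd_structure: str
    structural: StructuralSpec
    linkset: LinkSet | None = None
    n_categories: int = 0
    ts_min: int = 0
    name: str = ""

    def __post_init__(self):
        if self.family not in ("cv", "bi"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.mean_scale not in ("ts", "z", "psi"):
            raise ValueError(f"unknown mean scale {self.mean_scale!r}")
        if self.sd_structure not in SD_STRUCTURES:
            raise ValueError(f"unknown sd structure {self.sd_structure!r}")
        if self.mean_scale == "psi" and self.linkset is None:
            raise ValueError("mean scale 'psi' requires a linkset")
        if self.sd_structure != "homoscedastic" and self.linkset is None:
            raise ValueError(f"sd structure {self.sd_structure!r} requires a linkset")
        if self.family == "bi" and self.n_categories < 2:
            raise ValueError("BI models need n_categories >= 2")

    @property
    def needs_sd_eta(self) -> bool:
        return self.sd_structure in ("irt_scaled_iiv", "irt_additive_iiv")


#: the eight canonical Table-style families
MODEL_NAMES = ("S-CV", "SDI-CV", "MI-CV", "I-CV", "S-BI", "SDI-BI", "MI-BI", "I-BI")

_FAMILY_TABLE = {
    "S-CV": ("cv", "ts", "homoscedastic"),
    "SDI-CV": ("cv", "ts", "irt_fixed"),
    "MI-CV": ("cv", "psi", "homoscedastic"),
    "I-CV": ("cv", "psi", "irt_fixed"),
    "S-BI": ("bi", "z", "homoscedastic"),
    "SDI-BI": ("bi", "z", "irt_fixed"),
    "MI-BI": ("bi", "psi", "homoscedastic"),
    "I-BI": ("bi", "psi", "irt_fixed"),
}


def model_spec(
    name: str,
    structural: StructuralSpec,
    linkset: LinkSet | None = None,
    n_categories: int = 0,
    ts_min: int = 0,
    sd_structure: str | None = None,
) -> ModelSpec:
    """Build a :class:`ModelSpec` for one of the canonical family names.

    ``sd_structure`` may override the default of the named family to form
    the SD-elaboration variants (scale factor, IIV, additive term).
    """
    if name not in _FAMILY_TABLE:
        raise ValueError(f"unknown model name {name!r}; choose from {MODEL_NAMES}")
    family, mean_scale, sd = _FAMILY_TABLE[name]
    if sd_structure is not None:
        sd = sd_structure
    return ModelSpec(
        family=family,
        mean_scale=mean_scale,
        sd_structure=sd,
        structural=structural,
        linkset=linkset,
        n_categories=n_categories,
        ts_min=ts_min,
        name=name,
    )


def structural_psi(structural: StructuralSpec, t, X, theta, eta):
    """Evaluate the structural model (on whatever scale the spec uses it).

    ``theta`` maps names to scalars; ``eta`` maps IIV target names to
    per-observation arrays (already expanded from per-subject draws).
    Missing covariates raise a KeyError naming the covariate.
    """
    t = np.asarray(t, dtype=float)
    val = theta["theta1"] + np.zeros_like(t)
    if structural.has_slope:
        val = val + theta["theta2"] * t
    if structural.has_medication:
        if X is None:
            raise KeyError(f"missing covariate {structural.covariate!r}")
        val = val - theta["theta3"] * np.asarray(X, dtype=float)
    if "baseline" in structural.iiv and "baseline" in eta:
        val = val + eta["baseline"]
    if "slope" in structural.iiv and "slope" in eta:
        val = val + eta["slope"] * t
    return val


def _sd_from_structure(spec: ModelSpec, psi, theta, eta, sd_link):
    """Residual SD per observation for the chosen SD structure."""
    floor = spec.linkset.sd_floor if spec.linkset is not None else 1e-3
    if spec.sd_structure == "homoscedastic":
        return np.maximum(theta["sigma"], floor)
    base = sd_link(psi)
    if spec.sd_structure == "irt_fixed":
        sd = base
    elif spec.sd_structure == "irt_scaled":
        sd = base * theta["sd_scale"]
    elif spec.sd_structure == "irt_scaled_iiv":
        sd = base * theta["sd_scale"] * np.exp(eta["sd"])
    elif spec.sd_structure == "irt_additive_iiv":
        sd = base + theta["sd_add"] * np.exp(eta["sd"])
    else:  # pragma: no cover
        raise ValueError(spec.sd_structure)
    return np.maximum(sd, floor)


def _mean_and_psi(spec: ModelSpec, t, X, theta, eta):
    """(mean on observation scale, psi used for the SD link)."""
    pred = structural_psi(spec.structural, t, X, theta, eta)
    if spec.mean_scale == "psi":
        psi = pred
        if spec.family == "cv":
            mu = spec.linkset.mean_ts(psi)
        else:
            mu = spec.linkset.mean_z(psi)
        return mu, psi
    # structural model directly on the observation scale; if an IRT-informed
    # SD is requested, recover psi by inverting the mean link at the
    # prediction (SD as a function of the model's own mean)
    if spec.sd_structure == "homoscedastic" or spec.linkset is None:
        return pred, None
    if spec.family == "cv":
        psi = spec.linkset.psi_from_ts(pred)
    else:
        psi = spec.linkset.psi_from_z(pred)
    return pred, psi


def cv_obs_loglik(spec: ModelSpec, y, t, X, theta, eta):
    """Normal log-density of observed total scores under a CV spec."""
    if spec.family != "cv":
        raise ValueError("cv_obs_loglik requires a CV spec")
    y = np.asarray(y, dtype=float)
    mu, psi = _mean_and_psi(spec, t, X, theta, eta)
    sd = _sd_from_structure(spec, psi, theta, eta, spec.linkset.sd_ts if spec.linkset else None)
    return -0.5 * _LOG_2PI - np.log(sd) - 0.5 * ((y - mu) / sd) ** 2


_CUTS_CACHE: dict = {}


def _probit_cuts(n: int):
    """Probit cut points Z_{k/n}, k = 0..n, with infinite end points."""
    if n not in _CUTS_CACHE:
        cuts = np.empty(n + 1)
        cuts[0], cuts[n] = -np.inf, np.inf
        cuts[1:n] = ndtri(np.arange(1, n) / n)
        _CUTS_CACHE[n] = cuts
    return _CUTS_CACHE[n]


def bi_log_pmf(k, mu, sd, n: int):
    """Log probability of category ``k`` (1..n) in the bounded-integer model.

    The real line is partitioned by the probit cut points
    ``Z_{k/n} = probit(k/n)``; category k receives the normal(mu, sd^2) mass
    between ``Z_{(k-1)/n}`` and ``Z_{k/n}`` (the boundary categories take the
    full tails).  Evaluated in log space so extreme means keep finite
    log-probabilities wherever the mass is nonzero in double precision.
    """
    k = np.asarray(k)
    if np.any(k < 1) or np.any(k > n):
        raise ValueError(f"category index out of range 1..{n}")
    cuts = _probit_cuts(n)
    mu = np.asarray(mu, dtype=float)
    sd = np.asarray(sd, dtype=float)
    a = (cuts[k - 1] - mu) / sd
    b = (cuts[k] - mu) / sd
    return _log_norm_interval(a, b)


def _log_norm_interval(a, b):
    """log(Phi(b) - Phi(a)) for a < b, numerically stable in both tails."""
    a, b = np.broadcast_arrays(np.asarray(a, float), np.asarray(b, float))
    out = np.empty(a.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        # central intervals: direct difference is accurate
        mid = (a < 0) & (b > 0)
        out[mid] = np.log(ndtr(b[mid]) - ndtr(a[mid]))
        # both in the lower tail: work with Phi directly in log space
        low = b <= 0
        la, lb = log_ndtr(a[low]), log_ndtr(b[low])
        out[low] = lb + np.log1p(-np.exp(la - lb))
        # both in the upper tail: mirror to the lower tail
        up = a >= 0
        la, lb = log_ndtr(-b[up]), log_ndtr(-a[up])
        out[up] = lb + np.log1p(-np.exp(la - lb))
    return out


def bi_obs_loglik(spec: ModelSpec, y, t, X, theta, eta):
    """Log pmf of observed total scores under a BI spec.

    Scores map onto categories ``k = TS - minTS + 1`` of the
    ``n = maxTS - minTS + 1`` category probit grid.
    """
    if spec.family != "bi":
        raise ValueError("bi_obs_loglik requires a BI spec")
    y = np.asarray(y)
    k = np.rint(y).astype(int) - spec.ts_min + 1
    if np.any(k < 1) or np.any(k > spec.n_categories):
        raise ValueError(
            f"total score outside [{spec.ts_min}, {spec.ts_min + spec.n_categories - 1}]"
        )
    mu, psi = _mean_and_psi(spec, t, X, theta, eta)
    sd = _sd_from_structure(spec, psi, theta, eta, spec.linkset.sd_z if spec.linkset else None)
    mu = np.broadcast_to(np.asarray(mu, float), k.shape)
    sd = np.broadcast_to(np.asarray(sd, float), k.shape)
    return bi_log_pmf(k, mu, sd, spec.n_categories)


def obs_loglik(spec: ModelSpec, y, t, X, theta, eta):
    """Dispatch to the CV or BI conditional log-likelihood."""
    if spec.family == "cv":
        return cv_obs_loglik(spec, y, t, X, theta, eta)
    return bi_obs_loglik(spec, y, t, X, theta, eta)
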