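"""Fisher information about the latent variable under different models.

For a single observation, the Fisher information about Psi is the variance
of the score function under the observation model:

* IRT (item level): sum over items and categories of
  ``(dP_ms/dPsi)^2 / P_ms`` — the classical item-information sum, the upper
  bound for any statistic computed from the items.
* I-CV (heteroscedastic normal on TS): ``(pn1'/pn2)^2 + 2 (pn2'/pn2)^2``.
* I-BI (probit-partition categorical): ``sum_k (dP_k/dPsi)^2 / P_k`` with
  ``P_k`` the bounded-integer category probabilities through pn3/pn4.
* S-CV (homoscedastic normal on TS): ``(dE(TS|Psi)/dPsi)^2 / sigma^2``; the
  height depends on the residual variance, which in turn depends on the
  score distribution of the dataset the model is fitted to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .links import LinkSet, expected_ts, ts_sd
from .models import bi_log_pmf
from .scale import ScaleDefinition, item_information

__all__ = [
    "InformationCurve",
    "information_irt",
    "information_icv",
    "information_ibi",
    "information_scv",
]


@dataclass
class InformationCurve:
    """Fisher information as a function of Psi for one observation model."""

    psi_grid: np.ndarray
    total: np.ndarray
    model_label: str
    per_item: np.ndarray | None = None  # (n_items, n_grid), IRT only

    def __post_init__(self):
        if np.any(self.total < -1e-12):
            raise ValueError("information must be nonnegative")

    def to_frame(self):
        import pandas as pd

        rows = [
            pd.DataFrame(
                {"psi": self.psi_grid, "model": self.model_label,
                 "information": self.total, "item": "total"}
            )
        ]
        if self.per_item is not None:
            for m, row in enumerate(self.per_item):
                rows.append(
                    pd.DataFrame(
                        {"psi": self.psi_grid, "model": self.model_label,
                         "information": row, "item": f"item_{m + 1:02d}"}
                    )
                )
        return pd.concat(rows, ignore_index=True)


def information_irt(scale: ScaleDefinition, psi_grid) -> InformationCurve:
    """Item-level information: per-item curves and their sum."""
    psi_grid = np.asarray(psi_grid, dtype=float)
    per_item = np.stack([item_information(it, psi_grid) for it in scale.items])
    return InformationCurve(
        psi_grid=psi_grid, total=per_item.sum(axis=0),
        model_label="IRT", per_item=per_item,
    )


def information_icv(linkset: LinkSet, psi_grid) -> InformationCurve:
    """Heteroscedastic-normal information of the fully informed CV model."""
    psi_grid = np.asarray(psi_grid, dtype=float)
    mu_d = linkset.pn1.deriv()(psi_grid)
    sd = np.maximum(linkset.pn2(psi_grid), linkset.sd_floor)
    sd_d = linkset.pn2.deriv()(psi_grid)
    total = (mu_d / sd) ** 2 + 2.0 * (sd_d / sd) ** 2
    return InformationCurve(psi_grid=psi_grid, total=total, model_label="I-CV")


def information_ibi(linkset: LinkSet, psi_grid, n_categories: int | None = None,
                    step: float = 1e-4) -> InformationCurve:
    """Categorical information of the fully informed BI model.

    Category probabilities are evaluated through the pn3/pn4 links and
    differentiated by central differences in Psi (step ``step``).
    """
    psi_grid = np.asarray(psi_grid, dtype=float)
    if n_categories is None:
        lo, hi = linkset.ts_range
        n_categories = int(round(hi - lo)) + 1
    k = np.arange(1, n_categories + 1)

    def cat_probs(psi):
        mu = linkset.mean_z(psi)
        sd = linkset.sd_z(psi)
        return np.exp(bi_log_pmf(k, mu, sd, n_categories))

    total = np.empty_like(psi_grid)
    for i, p in enumerate(psi_grid):
        P = cat_probs(p)
        dP = (cat_probs(p + step) - cat_probs(p - step)) / (2 * step)
        mask = P > 1e-300
        total[i] = float(np.sum(dP[mask] ** 2 / np.maximum(P[mask], 1e-12)))
    return InformationCurve(psi_grid=psi_grid, total=total, model_label="I-BI")


def information_scv(scale: ScaleDefinition, psi_grid, scores=None,
                    sigma: float | None = None) -> InformationCurve:
    """Homoscedastic-CV information ``(dE(TS|Psi)/dPsi)^2 / sigma^2``.

    ``sigma`` may be given directly; otherwise it is implied by the supplied
    empirical score distribution: each observed score is mapped back to a
    Psi through the inverse of E(TS|Psi), and sigma^2 is the average
    conditional variance Var(TS|Psi) over those Psi — the residual variance
    a homoscedastic fit would need to absorb if the item-level model held.
    """
    psi_grid = np.asarray(psi_grid, dtype=float)
    if sigma is None:
        if scores is None or len(np.atleast_1d(scores)) == 0:
            raise ValueError("provide a nonempty score sample or an explicit sigma")
        scores = np.asarray(scores, dtype=float)
        dense = np.linspace(*scale.psi_domain, 2001)
        mean_curve = expected_ts(scale, dense)
        psi_of_score = np.interp(scores, mean_curve, dense)
        sigma = float(np.sqrt(np.mean(ts_sd(scale, psi_of_score) ** 2)))
    # derivative of the analytic mean link by central differences
    h = 1e-5
    dmean = (expected_ts(scale, psi_grid + h) - expected_ts(scale, psi_grid - h)) / (2 * h)
    total = (dmean / sigma) ** 2
    return InformationCurve(psi_grid=psi_grid, total=total, model_label="S-CV")
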