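"""Composite scales as sets of graded-response items.

A composite scale (e.g. the MDS-UPDRS motor subscale) consists of M ordinal
items.  Each item m has S_m ordered response categories with explicit integer
scores, and its response probabilities follow the logistic graded response
model: the probability of reaching at least category s is a logistic curve in
the latent severity variable Psi,

    P(Y_m >= s | Psi) = 1 / (1 + exp(-a_m (Psi - b_{m,s}))),

with discrimination a_m > 0 and ordered thresholds b_{m,s}.  Category
probabilities are differences of adjacent cumulative curves.  The total score
is the sum of the item scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import expit

__all__ = [
    "ItemParams",
    "ScaleDefinition",
    "category_probs",
    "item_information",
    "load_scale",
    "save_scale",
    "reference_scale",
]

#: probability floor used when dividing by category probabilities
PROB_FLOOR = 1e-12


class ScaleValidationError(ValueError):
    """Raised when a scale definition violates its invariants."""


@dataclass(frozen=True)
class ItemParams:
    """Graded-response parameters of one ordinal item.

    Parameters
    ----------
    item_id : str
        Label of the item.
    discrimination : float
        Slope ``a`` of the logistic cumulative curves; must be positive.
    thresholds : tuple of float
        Ordered difficulties ``b_s`` (length ``S_m - 1``); nondecreasing.
    category_scores : tuple of int
        Score contributed by each category (length ``S_m``); strictly
        increasing, e.g. ``(0, 1, 2, 3, 4)`` for an MDS-UPDRS item.
    """

    item_id: str
    discrimination: float
    thresholds: tuple
    category_scores: tuple

    def __post_init__(self):
        object.__setattr__(self, "thresholds", tuple(float(b) for b in self.thresholds))
        object.__setattr__(
            self, "category_scores", tuple(int(s) for s in self.category_scores)
        )
        if not np.isfinite(self.discrimination) or self.discrimination <= 0:
            raise ScaleValidationError(
                f"item {self.item_id!r}: discrimination must be positive, "
                f"got {self.discrimination}"
            )
        b = np.asarray(self.thresholds, dtype=float)
        if b.size < 1 or not np.all(np.isfinite(b)):
            raise ScaleValidationError(
                f"item {self.item_id!r}: needs at least one finite threshold"
            )
        if np.any(np.diff(b) < 0):
            raise ScaleValidationError(
                f"item {self.item_id!r}: thresholds must be nondecreasing, got {tuple(b)}"
            )
        s = np.asarray(self.category_scores, dtype=int)
        if s.size != b.size + 1:
            raise ScaleValidationError(
                f"item {self.item_id!r}: {s.size} category scores for "
                f"{b.size} thresholds (need thresholds + 1)"
            )
        if np.any(np.diff(s) <= 0):
            raise ScaleValidationError(
                f"item {self.item_id!r}: category scores must be strictly increasing"
            )

    @property
    def n_categories(self) -> int:
        return len(self.category_scores)


@dataclass(frozen=True)
class ScaleDefinition:
    """A named collection of graded-response items plus the Psi domain."""

    items: tuple
    name: str = "scale"
    psi_domain: tuple = (-4.0, 8.0)

    def __post_init__(self):
        object.__setattr__(self, "items", tuple(self.items))
        lo, hi = self.psi_domain
        if len(self.items) < 1:
            raise ScaleValidationError("scale needs at least one item")
        if not lo < hi:
            raise ScaleValidationError(f"psi_domain lower must be < upper, got {self.psi_domain}")
        ids = [it.item_id for it in self.items]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ScaleValidationError(f"duplicate item ids: {sorted(dup)}")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def min_total(self) -> int:
        return sum(min(it.category_scores) for it in self.items)

    @property
    def max_total(self) -> int:
        return sum(max(it.category_scores) for it in self.items)

    @property
    def n_total_categories(self) -> int:
        """Number of achievable integer grid points, max - min + 1."""
        return self.max_total - self.min_total + 1


def _cumulative(item: ItemParams, psi):
    """P(Y >= category s | psi) for s = 1..S-1, shape (..., S-1)."""
    psi = np.asarray(psi, dtype=float)
    b = np.asarray(item.thresholds)
    return expit(item.discrimination * (psi[..., None] - b))


def category_probs(item: ItemParams, psi):
    """Category probabilities of one item at latent value(s) ``psi``.

    Returns an array of shape ``psi.shape + (S_m,)``; probabilities are
    differences of adjacent logistic cumulative curves and sum to 1.
    """
    c = _cumulative(item, psi)
    ones = np.ones(c.shape[:-1] + (1,))
    zeros = np.zeros_like(ones)
    upper = np.concatenate([ones, c], axis=-1)
    lower = np.concatenate([c, zeros], axis=-1)
    return upper - lower


def item_information(item: ItemParams, psi):
    """Fisher information about Psi contributed by one item.

    Computed as ``sum_s (dP_s/dPsi)^2 / P_s`` with the analytic derivative of
    the logistic cumulative curves.  Categories with vanishing probability
    contribute zero.
    """
    c = _cumulative(item, psi)
    dc = item.discrimination * c * (1.0 - c)
    zeros = np.zeros(c.shape[:-1] + (1,))
    dP = np.concatenate([zeros, dc], axis=-1) - np.concatenate([dc, zeros], axis=-1)
    P = category_probs(item, psi)
    contrib = np.where(P > 1e-300, dP**2 / np.maximum(P, PROB_FLOOR), 0.0)
    return contrib.sum(axis=-1)


def scale_information(scale: ScaleDefinition, psi):
    """Total Fisher information of the scale: sum over item informations."""
    return sum(item_information(it, psi) for it in scale.items)


# ---------------------------------------------------------------------------
# file I/O — YAML schema:
#   name: <label>
#   psi_domain: [lo, hi]
#   items:
#     - id: <label>
#       discrimination: <a>
#       thresholds: [b1, b2, ...]
#       scores: [s1, s2, ...]
# ---------------------------------------------------------------------------

def load_scale(path) -> ScaleDefinition:
    """Read a scale definition file (YAML schema above) and validate it."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "items" not in raw:
        raise ScaleValidationError(f"{path}: expected a mapping with an 'items' list")
    items = []
    for entry in raw["items"]:
        missing = {"id", "discrimination", "thresholds", "scores"} - set(entry)
        if missing:
            raise ScaleValidationError(
                f"{path}: item {entry.get('id', '<unnamed>')!r} missing fields {sorted(missing)}"
            )
        items.append(
            ItemParams(
                item_id=str(entry["id"]),
                discrimination=float(entry["discrimination"]),
                thresholds=tuple(entry["thresholds"]),
                category_scores=tuple(entry["scores"]),
            )
        )
    domain = tuple(raw.get("psi_domain", (-4.0, 8.0)))
    return ScaleDefinition(items=tuple(items), name=raw.get("name", "scale"), psi_domain=domain)


def save_scale(scale: ScaleDefinition, path) -> None:
    """Write a scale definition to the YAML schema read by :func:`load_scale`."""
    doc = {
        "name": scale.name,
        "psi_domain": [float(x) for x in scale.psi_domain],
        "items": [
            {
                "id": it.item_id,
                "discrimination": float(it.discrimination),
                "thresholds": [float(b) for b in it.thresholds],
                "scores": [int(s) for s in it.category_scores],
            }
            for it in scale.items
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def reference_scale(n_items: int = 33, seed: int = 20210316) -> ScaleDefinition:
    """Deterministic synthetic 33-item, 5-category reference scale.

    Emulates the shape of the MDS-UPDRS motor subscale (33 items scored 0-4,
    maximum total score 132): discriminations are log-normal with median 1.5,
    and each item's four ordered thresholds are placed so that, across items,
    difficulties span roughly Psi in [-2, 6].  The construction is fully
    deterministic for a given seed, so the same scale is rebuilt everywhere.
    """
    rng = np.random.default_rng(seed)
    items = []
    # item locations sweep the disease range; jitter avoids a perfect lattice
    centers = np.linspace(-1.0, 5.0, n_items) + rng.normal(0.0, 0.35, n_items)
    for m in range(n_items):
        a = float(np.exp(np.log(1.5) + rng.normal(0.0, 0.30)))
        spread = rng.uniform(0.6, 1.2)
        offsets = np.sort(rng.normal(0.0, spread, 4))
        b = np.sort(centers[m] + offsets)
        # enforce a minimal gap so adjacent categories stay distinguishable
        for k in range(1, 4):
            b[k] = max(b[k], b[k - 1] + 0.15)
        items.append(
            ItemParams(
                item_id=f"item_{m + 1:02d}",
                discrimination=a,
                thresholds=tuple(b),
                category_scores=(0, 1, 2, 3, 4),
            )
        )
    return ScaleDefinition(items=tuple(items), name="synthetic-motor-33", psi_domain=(-4.0, 8.0))
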