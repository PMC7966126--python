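"""Analytic and polynomial link functions between Psi and total-score moments.

Given a graded-response scale, the conditional distribution of the total
score TS given the latent variable Psi is fully determined by the item
characteristic curves.  This module derives

* ``E(TS | Psi)`` and ``SD(TS | Psi)`` — the mean/SD links used by
  continuous-variable (CV) models,
* ``E(Z | Psi)`` and ``SD(Z | Psi)`` — the corresponding links on the probit
  (Z) scale used by bounded-integer (BI) models,

and approximates each with the lowest-degree Chebyshev polynomial whose
maximum deviation from the analytic function on a dense grid is below a
pre-specified tolerance (0.01 / 0.01 for the CV mean/SD, 0.01 / 0.005 for
the BI mean/SD, over Psi in [-4, 8] by default).

Variance of the total score is the sum of per-item conditional variances
(items are conditionally independent given Psi); each item's variance uses
its own conditional mean.

The Z-scale link uses a representative-z convention: the BI model partitions
the real line into n = maxTS - minTS + 1 intervals by the probit cut points
Z_{k/n}; interior categories are represented by the midpoint of their cut
points and the two boundary categories by the conditional mean of a standard
normal in the corresponding tail.  The mean and SD of that discrete
distribution under P(TS = k | Psi) define the link.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Chebyshev
from scipy.special import ndtri
from scipy.stats import norm

from .scale import ScaleDefinition, category_probs

__all__ = [
    "LinkSet",
    "expected_ts",
    "ts_sd",
    "ts_distribution",
    "z_link",
    "fit_link_polynomial",
    "build_linkset",
    "eval_link",
    "save_linkset",
    "load_linkset",
]

logger = logging.getLogger(__name__)

#: lower clamp applied to SD links to keep likelihoods well defined
SD_FLOOR = 1e-3

#: Chebyshev fit tolerances: (E(TS), SD(TS), E(Z), SD(Z))
DEFAULT_TOLERANCES = (0.01, 0.01, 0.01, 0.005)

_CHECK_GRID_SIZE = 2001


def _item_moments(item, psi):
    """(mean, variance) of one item's score given psi; shapes follow psi."""
    P = category_probs(item, psi)
    s = np.asarray(item.category_scores, dtype=float)
    mean = P @ s
    var = (P * (s - mean[..., None]) ** 2).sum(axis=-1)
    return mean, var


def expected_ts(scale: ScaleDefinition, psi):
    """E(TS | Psi): sum over items of the expected item score."""
    psi = np.asarray(psi, dtype=float)
    out = np.zeros(psi.shape)
    for it in scale.items:
        out += _item_moments(it, psi)[0]
    return out if out.shape else float(out)


def ts_sd(scale: ScaleDefinition, psi):
    """SD(TS | Psi): sqrt of the sum of per-item conditional variances."""
    psi = np.asarray(psi, dtype=float)
    var = np.zeros(psi.shape)
    for it in scale.items:
        var += _item_moments(it, psi)[1]
    out = np.sqrt(var)
    return out if out.shape else float(out)


def ts_distribution(scale: ScaleDefinition, psi: float):
    """Exact P(TS = k | Psi) over k = minTS..maxTS by convolution.

    Items are conditionally independent given Psi, so the total-score pmf is
    the convolution of the per-item score pmfs.
    """
    if scale.n_total_categories > 10_000:
        raise ValueError(
            f"total-score support of {scale.n_total_categories} categories "
            "exceeds the 10^4 convolution limit"
        )
    pmf = np.array([1.0])
    for it in scale.items:
        P = np.asarray(category_probs(it, float(psi)))
        smin, smax = min(it.category_scores), max(it.category_scores)
        dense = np.zeros(smax - smin + 1)
        for s, p in zip(it.category_scores, P):
            dense[s - smin] = p
        pmf = np.convolve(pmf, dense)
    return pmf


def _representative_z(n: int):
    """Representative z value for each of n probit-partition categories."""
    k = np.arange(1, n)
    cuts = ndtri(k / n)  # interior cut points Z_{k/n}
    z = np.empty(n)
    z[1:-1] = 0.5 * (cuts[:-1] + cuts[1:])
    # boundary categories: conditional mean of N(0,1) in the tail
    z[0] = -norm.pdf(cuts[0]) / norm.cdf(cuts[0])
    z[-1] = norm.pdf(cuts[-1]) / norm.sf(cuts[-1])
    return z


def z_link(scale: ScaleDefinition, psi: float):
    """(mean, SD) of the representative Z score implied by P(TS | Psi)."""
    pmf = ts_distribution(scale, psi)
    z = _representative_z(scale.n_total_categories)
    mean = float(pmf @ z)
    sd = float(np.sqrt(pmf @ (z - mean) ** 2))
    return mean, sd


def fit_link_polynomial(fn, domain, tol, max_degree: int = 60):
    """Smallest-degree Chebyshev approximant of ``fn`` meeting ``tol``.

    Starting from degree 1, the candidate polynomial interpolates ``fn`` at
    the Chebyshev points of that degree; the degree is accepted once the
    maximum absolute deviation on a dense (2001-point) equispaced grid over
    ``domain`` is below ``tol``.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    lo, hi = map(float, domain)
    grid = np.linspace(lo, hi, _CHECK_GRID_SIZE)
    vfn = fn if _vectorizable(fn, grid) else np.vectorize(fn)
    target = vfn(grid)
    best_err = np.inf
    for degree in range(1, max_degree + 1):
        poly = Chebyshev.interpolate(vfn, degree, domain=[lo, hi])
        err = float(np.max(np.abs(target - poly(grid))))
        best_err = min(best_err, err)
        if err <= tol:
            return poly, degree
    raise RuntimeError(
        f"no Chebyshev polynomial of degree <= {max_degree} met tolerance "
        f"{tol:g} (best deviation {best_err:.3g})"
    )


def _vectorizable(fn, grid):
    try:
        out = fn(grid[:2])
        return np.shape(out) == grid[:2].shape
    except Exception:
        return False


@dataclass
class LinkSet:
    """The four fitted link polynomials plus their exact analytic handles.

    ``pn1``: Psi -> E(TS);    ``pn2``: Psi -> SD(TS)
    ``pn3``: Psi -> E(Z);     ``pn4``: Psi -> SD(Z)
    """

    pn1: Chebyshev
    pn2: Chebyshev
    pn3: Chebyshev
    pn4: Chebyshev
    domain: tuple
    tolerances: tuple = DEFAULT_TOLERANCES
    degrees: tuple = ()
    analytic: dict | None = None
    sd_floor: float = SD_FLOOR
    ts_range: tuple = (0.0, 132.0)

    # ------------------------------------------------------------------
    def mean_ts(self, psi):
        return eval_link(self.pn1, psi, self.domain)

    def sd_ts(self, psi):
        return eval_link(self.pn2, psi, self.domain, floor=self.sd_floor)

    def mean_z(self, psi):
        return eval_link(self.pn3, psi, self.domain)

    def sd_z(self, psi):
        return eval_link(self.pn4, psi, self.domain, floor=self.sd_floor)

    # inverse mean links: used by SD-only-informed models, where the SD link
    # is expressed as a function of the model's own mean prediction
    def psi_from_ts(self, ts):
        return np.interp(ts, self._mean_ts_grid()[1], self._mean_ts_grid()[0])

    def psi_from_z(self, z):
        return np.interp(z, self._mean_z_grid()[1], self._mean_z_grid()[0])

    def _mean_ts_grid(self):
        if not hasattr(self, "_ts_grid_cache"):
            g = np.linspace(*self.domain, 4001)
            v = self.pn1(g)
            keep = np.concatenate([[True], np.diff(v) > 0])  # force monotone table
            self._ts_grid_cache = (g[keep], v[keep])
        return self._ts_grid_cache

    def _mean_z_grid(self):
        if not hasattr(self, "_z_grid_cache"):
            g = np.linspace(*self.domain, 4001)
            v = self.pn3(g)
            keep = np.concatenate([[True], np.diff(v) > 0])
            self._z_grid_cache = (g[keep], v[keep])
        return self._z_grid_cache


_warned_domains: set = set()


def eval_link(poly: Chebyshev, psi, domain=None, floor: float | None = None):
    """Evaluate a link polynomial; warn outside its domain, clamp SD links.

    The out-of-domain warning is emitted once per domain per process (then
    demoted to debug) so iterative fits do not flood the log.
    """
    psi = np.asarray(psi, dtype=float)
    if domain is not None:
        lo, hi = domain
        if np.any(psi < lo) or np.any(psi > hi):
            level = logging.DEBUG if (lo, hi) in _warned_domains else logging.WARNING
            _warned_domains.add((lo, hi))
            logger.log(
                level, "link polynomial evaluated outside its domain [%g, %g]", lo, hi
            )
    val = poly(psi)
    if floor is not None:
        val = np.maximum(val, floor)
    return val if np.ndim(val) else float(val)


def build_linkset(
    scale: ScaleDefinition,
    tolerances=DEFAULT_TOLERANCES,
    max_degree: int = 60,
) -> LinkSet:
    """Fit pn1..pn4 for ``scale`` at the stated tolerances over its domain."""
    domain = tuple(map(float, scale.psi_domain))

    f_mean_ts = lambda p: expected_ts(scale, p)
    f_sd_ts = lambda p: ts_sd(scale, p)
    f_mean_z = np.vectorize(lambda p: z_link(scale, p)[0])
    f_sd_z = np.vectorize(lambda p: z_link(scale, p)[1])

    pn1, d1 = fit_link_polynomial(f_mean_ts, domain, tolerances[0], max_degree)
    pn2, d2 = fit_link_polynomial(f_sd_ts, domain, tolerances[1], max_degree)
    pn3, d3 = fit_link_polynomial(f_mean_z, domain, tolerances[2], max_degree)
    pn4, d4 = fit_link_polynomial(f_sd_z, domain, tolerances[3], max_degree)

    return LinkSet(
        pn1=pn1,
        pn2=pn2,
        pn3=pn3,
        pn4=pn4,
        domain=domain,
        tolerances=tuple(tolerances),
        degrees=(d1, d2, d3, d4),
        analytic={
            "mean_ts": f_mean_ts,
            "sd_ts": f_sd_ts,
            "mean_z": f_mean_z,
            "sd_z": f_sd_z,
        },
        ts_range=(float(scale.min_total), float(scale.max_total)),
    )


# ---------------------------------------------------------------------------
# plain-text serialization: one block per link with degree, tolerance and the
# Chebyshev-basis coefficients, so fitted links are portable and diffable
# ---------------------------------------------------------------------------

_LINK_NAMES = ("pn1", "pn2", "pn3", "pn4")


def save_linkset(linkset: LinkSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# irtlink link-function file (Chebyshev basis)\n")
        fh.write(f"domain: {float(linkset.domain[0])!r} {float(linkset.domain[1])!r}\n")
        fh.write(f"ts_range: {float(linkset.ts_range[0])!r} {float(linkset.ts_range[1])!r}\n")
        fh.write(f"sd_floor: {float(linkset.sd_floor)!r}\n")
        for name, tol in zip(_LINK_NAMES, linkset.tolerances):
            poly: Chebyshev = getattr(linkset, name)
            fh.write(f"[{name}] degree={len(poly.coef) - 1} tol={float(tol)!r}\n")
            for c in poly.coef:
                fh.write(f"  {float(c)!r}\n")


def load_linkset(path) -> LinkSet:
    domain = None
    ts_range = (0.0, 132.0)
    sd_floor = SD_FLOOR
    coefs: dict[str, list[float]] = {}
    tols: dict[str, float] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("domain:"):
                domain = tuple(float(x) for x in line.split()[1:3])
            elif line.startswith("ts_range:"):
                ts_range = tuple(float(x) for x in line.split()[1:3])
            elif line.startswith("sd_floor:"):
                sd_floor = float(line.split()[1])
            elif line.startswith("["):
                current = line[1 : line.index("]")]
                coefs[current] = []
                tols[current] = float(line.split("tol=")[1])
            else:
                coefs[current].append(float(line))
    if domain is None or set(coefs) != set(_LINK_NAMES):
        raise ValueError(f"{path}: malformed link-function file")
    polys = {n: Chebyshev(np.asarray(coefs[n]), domain=list(domain)) for n in _LINK_NAMES}
    return LinkSet(
        pn1=polys["pn1"],
        pn2=polys["pn2"],
        pn3=polys["pn3"],
        pn4=polys["pn4"],
        domain=domain,
        tolerances=tuple(tols[n] for n in _LINK_NAMES),
        degrees=tuple(len(coefs[n]) - 1 for n in _LINK_NAMES),
        analytic=None,
        sd_floor=sd_floor,
        ts_range=ts_range,
    )
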