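"""Mixed-effects estimation for total-score models.

:class:`TotalScoreModel` binds a :class:`~irtlink.models.ModelSpec` to a
:class:`~irtlink.data.TSDataset`; its :meth:`~TotalScoreModel.fit` maximizes
the marginal likelihood, integrating the subject-level random effects out by
a Laplace approximation at the per-subject joint mode (adaptive
Gauss-Hermite quadrature is available as a verification integrator), and
returns a :class:`TotalScoreResults` with estimates, OFV (-2 log marginal
likelihood, including all constants, so values are comparable across model
families), AIC = OFV + 2p, empirical-Bayes modes and a ``summary()`` table.

The inner mode search is a damped Newton iteration run simultaneously for
all subjects on vectorized conditional log-likelihoods; derivatives with
respect to the (at most three) random effects are central finite
differences.  The outer maximization is a derivative-free Nelder-Mead
search on transformed parameters (log for positive quantities, atanh for
correlations), which is deterministic given the starting point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from .data import TSDataset
from .models import ModelSpec, obs_loglik

__all__ = [
    "TotalScoreModel",
    "TotalScoreResults",
    "ComparisonReport",
    "compare",
    "subject_marginal_loglik",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

_FD_STEP = 1e-4        # random-effect finite-difference step
_INNER_GTOL = 1e-8     # inner Newton gradient tolerance
_INNER_MAXIT = 100


def _param_defs(spec: ModelSpec):
    """Ordered (name, transform) pairs of the estimable parameters."""
    s = spec.structural
    defs = [("theta1", "id")]
    if s.has_slope:
        defs.append(("theta2", "id"))
    if s.has_medication:
        defs.append(("theta3", "id"))
    if spec.sd_structure == "homoscedastic":
        defs.append(("sigma", "log"))
    elif spec.sd_structure in ("irt_scaled", "irt_scaled_iiv"):
        defs.append(("sd_scale", "log"))
    elif spec.sd_structure == "irt_additive_iiv":
        defs.append(("sd_add", "log"))
    if "baseline" in s.iiv:
        defs.append(("omega_baseline", "log"))
    if "slope" in s.iiv:
        defs.append(("omega_slope", "log"))
    if getattr(s, "correlated_iiv", False) and {"baseline", "slope"} <= set(s.iiv):
        defs.append(("corr", "tanh"))
    if spec.needs_sd_eta:
        defs.append(("omega_sd", "log"))
    return defs


def _to_internal(value, transform):
    if transform == "log":
        return np.log(value)
    if transform == "tanh":
        return np.arctanh(value)
    return value


def _to_natural(value, transform):
    if transform == "log":
        return np.exp(value)
    if transform == "tanh":
        return np.tanh(value)
    return value


class TotalScoreModel:
    """A total-score model family bound to a longitudinal dataset.

    Parameters
    ----------
    spec : ModelSpec
        Family, mean scale, SD structure, structural model and links.
    dataset : TSDataset
        Long-format observations.
    """

    def __init__(self, spec: ModelSpec, dataset: TSDataset):
        self.spec = spec
        self.dataset = dataset
        df = dataset.frame
        codes, uniques = pd.factorize(df["ID"], sort=True)
        self.subject_ids = np.asarray(uniques)
        self.subj_idx = np.asarray(codes)
        self.n_subjects = len(uniques)
        self.y = np.asarray(df["DV"], dtype=float)
        self.t = np.asarray(df["TIME"], dtype=float)
        self.X = (
            dataset.covariate(spec.structural.covariate)
            if spec.structural.has_medication
            else None
        )
        self.eta_names = [n for n in ("baseline", "slope") if n in spec.structural.iiv]
        if spec.needs_sd_eta:
            self.eta_names.append("sd")
        self.n_eta = len(self.eta_names)
        self.param_defs = _param_defs(spec)
        self._eta_warm = None

    @classmethod
    def from_dataframe(cls, spec: ModelSpec, frame: pd.DataFrame, ts_range=None):
        return cls(spec, TSDataset(frame=frame.copy(), ts_range=ts_range))

    # ------------------------------------------------------------------
    # conditional likelihood machinery
    # ------------------------------------------------------------------
    def _cond_ll_subjects(self, theta: dict, eta_mat: np.ndarray):
        """Per-subject conditional log-likelihood given eta_mat (N, d)."""
        eta = {
            name: eta_mat[self.subj_idx, j] for j, name in enumerate(self.eta_names)
        }
        ll = obs_loglik(self.spec, self.y, self.t, self.X, theta, eta)
        return np.bincount(self.subj_idx, weights=ll, minlength=self.n_subjects)

    def _omega(self, theta: dict):
        """Random-effect covariance matrix implied by the parameters."""
        d = self.n_eta
        om = np.zeros((d, d))
        for j, name in enumerate(self.eta_names):
            sd = theta[f"omega_{name}"]
            om[j, j] = sd**2
        if "corr" in theta and {"baseline", "slope"} <= set(self.eta_names):
            i = self.eta_names.index("baseline")
            j = self.eta_names.index("slope")
            cov = theta["corr"] * theta["omega_baseline"] * theta["omega_slope"]
            om[i, j] = om[j, i] = cov
        return om

    def _joint(self, theta, omega_inv, omega_logdet, eta_mat):
        """Per-subject joint log density: conditional ll + eta prior."""
        ll = self._cond_ll_subjects(theta, eta_mat)
        quad = np.einsum("nd,de,ne->n", eta_mat, omega_inv, eta_mat)
        prior = -0.5 * (self.n_eta * _LOG_2PI + omega_logdet + quad)
        return ll + prior

    def _inner_modes(self, theta, omega_inv, omega_logdet, eta0=None):
        """Vectorized damped-Newton search for the per-subject joint modes.

        Returns (eta_hat, neg_hessians) where neg_hessians[i] is the
        negative Hessian of the joint log density at subject i's mode.
        """
        N, d = self.n_subjects, self.n_eta
        h = _FD_STEP
        joint = lambda e: self._joint(theta, omega_inv, omega_logdet, e)
        if eta0 is not None:
            eta = eta0.copy()
            f0 = joint(eta)
        else:
            # cold start: the joint surface can be multimodal when link
            # polynomials saturate at the domain edges, so probe a few
            # prior-scaled candidates per axis and start from the best
            omega_sd = np.sqrt(np.diag(np.linalg.inv(omega_inv)))
            eta = np.zeros((N, d))
            f0 = joint(eta)
            for j in range(d):
                for kmul in (-2.0, -1.0, 1.0, 2.0):
                    cand = np.zeros((N, d))
                    cand[:, j] = kmul * omega_sd[j]
                    f_c = joint(cand)
                    better = f_c > f0
                    eta[better] = cand[better]
                    f0 = np.where(better, f_c, f0)
        for _ in range(_INNER_MAXIT):
            grad = np.empty((N, d))
            hess = np.empty((N, d, d))
            fplus = np.empty((N, d))
            fminus = np.empty((N, d))
            for j in range(d):
                step = np.zeros((N, d))
                step[:, j] = h
                fplus[:, j] = joint(eta + step)
                fminus[:, j] = joint(eta - step)
                grad[:, j] = (fplus[:, j] - fminus[:, j]) / (2 * h)
                hess[:, j, j] = (fplus[:, j] - 2 * f0 + fminus[:, j]) / h**2
            for j in range(d):
                for k in range(j + 1, d):
                    sj = np.zeros((N, d)); sj[:, j] = h
                    sk = np.zeros((N, d)); sk[:, k] = h
                    cross = (
                        joint(eta + sj + sk)
                        - joint(eta + sj - sk)
                        - joint(eta - sj + sk)
                        + joint(eta - sj - sk)
                    ) / (4 * h**2)
                    hess[:, j, k] = hess[:, k, j] = cross
            gnorm = np.max(np.abs(grad))
            if gnorm < _INNER_GTOL:
                break
            # damped Newton: -hess is PD at a mode; where it is indefinite
            # (saturating links), shift eigenvalues to force an ascent step
            negH = -hess
            eigmin = np.linalg.eigvalsh(negH)[:, 0]
            lam = np.maximum(0.0, 1e-4 - eigmin)
            H = negH + lam[:, None, None] * np.eye(d)
            delta = np.linalg.solve(H, grad[..., None])[..., 0]
            # per-subject backtracking line search
            alpha = np.ones(N)
            for _bt in range(25):
                trial = eta + alpha[:, None] * delta
                f_trial = joint(trial)
                worse = f_trial < f0 - 1e-12
                if not np.any(worse):
                    break
                alpha[worse] *= 0.5
            improved = f_trial >= f0 - 1e-12
            eta = np.where(improved[:, None], trial, eta)
            f_new = np.where(improved, f_trial, f0)
            if np.max(np.abs(f_new - f0)) < 1e-12 and gnorm < 1e-5:
                f0 = f_new
                break
            f0 = f_new
        neg_hess = -hess
        return eta, neg_hess

    # ------------------------------------------------------------------
    # marginal likelihood
    # ------------------------------------------------------------------
    def marginal_loglik_subjects(self, theta: dict, method="laplace", agq_nodes=9,
                                 warm_start=True):
        """Per-subject log marginal likelihoods for parameter dict ``theta``.

        ``method='laplace'`` (default) uses the Laplace approximation at the
        joint mode; ``'agq'`` uses adaptive Gauss-Hermite quadrature centred
        and scaled at that mode with ``agq_nodes`` nodes per dimension.
        """
        omega = self._omega(theta)
        sign, omega_logdet = np.linalg.slogdet(omega)
        if sign <= 0:
            raise ValueError("random-effect covariance must be positive definite")
        omega_inv = np.linalg.inv(omega)
        eta0 = self._eta_warm if (warm_start and self._eta_warm is not None
                                  and self._eta_warm.shape == (self.n_subjects, self.n_eta)) else None
        eta_hat, negH = self._inner_modes(theta, omega_inv, omega_logdet, eta0)
        if warm_start:
            self._eta_warm = eta_hat
        sgn, logdetH = np.linalg.slogdet(negH)
        if np.any(sgn <= 0):
            # fall back to the prior curvature where the numeric Hessian
            # is not PD (can occur far from the optimum)
            bad = sgn <= 0
            negH[bad] = omega_inv
            sgn, logdetH = np.linalg.slogdet(negH)
        g_hat = self._joint(theta, omega_inv, omega_logdet, eta_hat)
        if method == "laplace":
            ll = g_hat + 0.5 * self.n_eta * _LOG_2PI - 0.5 * logdetH
            return ll, eta_hat
        if method != "agq":
            raise ValueError(f"unknown integration method {method!r}")
        # adaptive GH: eta = eta_hat + sqrt(2) * A z, A = chol(negH^-1)
        d = self.n_eta
        nodes, weights = np.polynomial.hermite.hermgauss(agq_nodes)
        grids = np.meshgrid(*([nodes] * d), indexing="ij")
        Z = np.stack([g.ravel() for g in grids], axis=-1)          # (Q, d)
        W = np.prod(
            np.stack(np.meshgrid(*([weights] * d), indexing="ij"), axis=-1), axis=-1
        ).ravel()                                                   # (Q,)
        cov = np.linalg.inv(negH)
        A = np.linalg.cholesky(cov)                                 # (N, d, d)
        vals = np.empty((len(Z), self.n_subjects))
        for q, z in enumerate(Z):
            eta_q = eta_hat + np.sqrt(2.0) * (A @ z)
            vals[q] = self._joint(theta, omega_inv, omega_logdet, eta_q)
        lse = logsumexp(vals + (Z**2).sum(axis=1)[:, None] + np.log(W)[:, None], axis=0)
        ll = 0.5 * d * np.log(2.0) - 0.5 * logdetH + lse
        return ll, eta_hat

    def ofv(self, theta: dict, method="laplace", **kw):
        """-2 log marginal likelihood at ``theta`` (full constants kept)."""
        ll, _ = self.marginal_loglik_subjects(theta, method=method, **kw)
        return -2.0 * float(ll.sum())

    # ------------------------------------------------------------------
    # fitting
    # ------------------------------------------------------------------
    def default_start(self):
        """Crude data-driven starting values."""
        start = {}
        y, t = self.y, self.t
        spec = self.spec
        if spec.mean_scale == "psi":
            lk = spec.linkset
            psi0 = float(np.median(lk.psi_from_ts(y))) if spec.family == "cv" else None
            if psi0 is None:
                # map scores to z via the BI representative grid midpoint
                psi0 = float(np.median(lk.psi_from_ts(y)))
            start["theta1"] = psi0
            if spec.structural.has_slope:
                start["theta2"] = 0.1
        elif spec.family == "cv":
            start["theta1"] = float(np.mean(y[t <= t.min() + 1e-9]))
            if spec.structural.has_slope:
                start["theta2"] = 1.0
        else:  # BI on the Z scale
            from .models import _probit_cuts
            n = spec.n_categories
            k = np.rint(y).astype(int) - spec.ts_min  # 0..n-1
            zrep = np.concatenate([[-2.5], 0.5 * (_probit_cuts(n)[1:-1][:-1] + _probit_cuts(n)[1:-1][1:]), [2.5]])
            zobs = zrep[np.clip(k, 0, n - 1)]
            start["theta1"] = float(np.mean(zobs[t <= t.min() + 1e-9]))
            if spec.structural.has_slope:
                start["theta2"] = 0.1
        if spec.structural.has_medication:
            start["theta3"] = 0.0
        if spec.sd_structure == "homoscedastic":
            start["sigma"] = float(np.std(y)) * 0.5 if spec.family == "cv" else 0.3
        if "sd_scale" in dict(self.param_defs):
            start["sd_scale"] = 1.0
        if "sd_add" in dict(self.param_defs):
            start["sd_add"] = 0.1
        for name in self.eta_names:
            if name == "sd":
                start["omega_sd"] = 0.2
            else:
                scale_guess = np.std(y) * 0.3 if (spec.mean_scale in ("ts",) and spec.family == "cv") else 0.3
                start[f"omega_{name}"] = float(max(scale_guess, 1e-2))
        if ("corr", "tanh") in self.param_defs:
            start["corr"] = 0.0
        return start

    def fit(self, start=None, fixed=None, method="laplace", maxiter=3000,
            xatol=1e-3, fatol=5e-3, restarts=0, seed=None, verbose=False):
        """Maximize the marginal likelihood; returns :class:`TotalScoreResults`.

        Parameters
        ----------
        start : dict, optional
            Natural-scale starting values; missing entries use
            :meth:`default_start`.
        fixed : dict, optional
            Parameters held at the given values (not counted in ``p``).
        restarts : int
            Additional Nelder-Mead restarts from perturbed starts (the best
            final OFV wins); perturbations drawn from ``seed``.
        """
        fixed = dict(fixed or {})
        start_full = self.default_start()
        start_full.update(start or {})
        free_defs = [(n, tr) for (n, tr) in self.param_defs if n not in fixed]
        if not free_defs:
            raise ValueError("no free parameters to estimate")
        x0 = np.array([_to_internal(start_full[n], tr) for n, tr in free_defs])

        def decode(x):
            theta = dict(fixed)
            for (name, tr), xi in zip(free_defs, x):
                theta[name] = _to_natural(xi, tr)
            return theta

        self._eta_warm = None
        nfev = [0]

        def objective(x):
            nfev[0] += 1
            theta = decode(x)
            try:
                val = self.ofv(theta, method=method)
            except (np.linalg.LinAlgError, ValueError):
                return 1e12
            if not np.isfinite(val):
                return 1e12
            if verbose and nfev[0] % 50 == 0:
                print(f"  eval {nfev[0]}: OFV {val:.3f}")
            return val

        best = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": xatol, "fatol": fatol,
                     "adaptive": len(x0) > 4},
        )
        if restarts:
            rng = np.random.default_rng(seed)
            for _ in range(restarts):
                x_r = best.x + rng.normal(0.0, 0.1, size=len(x0))
                res_r = optimize.minimize(
                    objective, x_r, method="Nelder-Mead",
                    options={"maxiter": maxiter, "xatol": xatol, "fatol": fatol},
                )
                if res_r.fun < best.fun:
                    best = res_r

        theta_hat = decode(best.x)
        ll, eta_hat = self.marginal_loglik_subjects(theta_hat, method=method)
        ofv = -2.0 * float(ll.sum())
        p = len(free_defs)
        eb = pd.DataFrame(eta_hat, columns=[f"eta_{n}" for n in self.eta_names])
        eb.insert(0, "ID", self.subject_ids)
        return TotalScoreResults(
            model=self,
            params={n: float(v) for n, v in theta_hat.items()},
            fixed=fixed,
            ofv=ofv,
            aic=ofv + 2 * p,
            n_parameters=p,
            converged=bool(best.success),
            message=str(best.message),
            n_function_evals=nfev[0],
            eb_modes=eb,
            dataset_fingerprint=self.dataset.fingerprint(),
        )


@dataclass
class TotalScoreResults:
    """Estimation results of a :class:`TotalScoreModel` fit."""

    model: TotalScoreModel
    params: dict
    fixed: dict
    ofv: float
    aic: float
    n_parameters: int
    converged: bool
    message: str
    n_function_evals: int
    eb_modes: pd.DataFrame
    dataset_fingerprint: str

    @property
    def estimates(self) -> dict:
        """Free-parameter estimates (excludes fixed values)."""
        return {k: v for k, v in self.params.items() if k not in self.fixed}

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            f"Total-score model fit: {spec.name or spec.family.upper()}",
            f"  family={spec.family}  mean_scale={spec.mean_scale}  "
            f"sd={spec.sd_structure}",
            f"  subjects: {self.model.n_subjects}   observations: {len(self.model.y)}",
            f"  OFV: {self.ofv:.3f}   parameters: {self.n_parameters}   "
            f"AIC: {self.aic:.3f}",
            f"  converged: {self.converged} ({self.n_function_evals} evaluations)",
            "  estimates:",
        ]
        for name, val in self.estimates.items():
            lines.append(f"    {name:16s} {val: .6g}")
        for name, val in self.fixed.items():
            lines.append(f"    {name:16s} {val: .6g}  (fixed)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model.spec.name or self.model.spec.family,
            "params": self.params,
            "ofv": self.ofv,
            "aic": self.aic,
            "n_parameters": self.n_parameters,
            "converged": self.converged,
            "dataset_fingerprint": self.dataset_fingerprint,
        }


@dataclass
class ComparisonReport:
    """Signed OFV/AIC comparison of a candidate fit against a reference."""

    reference: str
    candidate: str
    delta_ofv: float
    delta_aic: float
    ofv_reference: float
    ofv_candidate: float
    n_parameters_reference: int
    n_parameters_candidate: int

    def __str__(self):
        return (
            f"{self.candidate} vs {self.reference}: "
            f"dOFV {self.delta_ofv:+.3f}  dAIC {self.delta_aic:+.3f}  "
            f"(p: {self.n_parameters_candidate} vs {self.n_parameters_reference})"
        )


def compare(fit_reference: TotalScoreResults, fit_candidate: TotalScoreResults):
    """ΔOFV/ΔAIC report, signed candidate minus reference.

    Both fits must be on the identical dataset (checked by fingerprint).
    """
    if fit_reference.dataset_fingerprint != fit_candidate.dataset_fingerprint:
        raise ValueError("fits are not on the same dataset (fingerprints differ)")
    return ComparisonReport(
        reference=fit_reference.model.spec.name or "reference",
        candidate=fit_candidate.model.spec.name or "candidate",
        delta_ofv=fit_candidate.ofv - fit_reference.ofv,
        delta_aic=fit_candidate.aic - fit_reference.aic,
        ofv_reference=fit_reference.ofv,
        ofv_candidate=fit_candidate.ofv,
        n_parameters_reference=fit_reference.n_parameters,
        n_parameters_candidate=fit_candidate.n_parameters,
    )


def subject_marginal_loglik(spec: ModelSpec, subject_frame: pd.DataFrame,
                            theta: dict, method="laplace", agq_nodes=9):
    """Log marginal likelihood of a single subject's observations.

    Convenience wrapper: builds a one-subject model and integrates its
    random effects with the requested method.  ``theta`` must include the
    omega entries for every random effect of the spec.
    """
    model = TotalScoreModel.from_dataframe(spec, subject_frame)
    if model.n_subjects != 1:
        raise ValueError("subject_frame must contain exactly one subject")
    ll, _ = model.marginal_loglik_subjects(theta, method=method,
                                           agq_nodes=agq_nodes, warm_start=False)
    return float(ll[0])
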