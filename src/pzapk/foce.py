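"""First-order conditional estimation with interaction (FOCE-I) for the
one-compartment steady-state model.

The marginal likelihood of a subject's observations under log-normal
random effects has no closed form; FOCE approximates it by linearising the
model in ``eta`` at each subject's conditional mode ``eta_hat`` (the MAP /
empirical-Bayes estimate).  With ``G_i`` the Jacobian of the prediction in
``eta`` at the mode, the per-subject contribution to the objective function
value (OFV, -2 log-likelihood dropping 2*pi constants) is

    V_i   = G_i Omega G_i' + sigma^2 I
    r_i   = y_i - f_i(eta_hat) + G_i eta_hat
    OFV_i = log|V_i| + r_i' V_i^{-1} r_i

For a purely additive residual error the epsilon-eta interaction term is the
residual variance evaluated at the conditional (not population) prediction,
which coincides with ``sigma^2 I``; the linearisation is still performed at
the conditional mode, which is what distinguishes FOCE from FO.

The inner problem (the conditional mode) is solved for all subjects at once
with a damped Gauss-Newton iteration on the penalised least-squares
objective ``|y - f(eta)|^2 / sigma^2 + eta' Omega^{-1} eta``, always
started from eta = 0 so the objective is a pure function of the
parameters.  The outer problem minimises the summed OFV over
log-transformed positive parameters with L-BFGS-B after a pooled
least-squares pre-fit of the fixed effects.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .data import SubjectRecord
from .modelspec import ETA_NAMES, ModelSpec, ParamSet
from .pk import _conc_ss_flat, is_geriatric_dm

__all__ = ["FoceEngine", "covariate_frame", "foce_ofv", "estimate_ebe", "eta_shrinkage"]

_ETA_FD_STEP = 1e-4  # central-difference step for the eta Jacobian
_BIG_OFV = 1e12


class FitError(RuntimeError):
    """Raised when estimation cannot proceed (bad data / too many failures)."""


def covariate_frame(subjects: Sequence[SubjectRecord], cutoffs=(60, 65, 70)) -> pd.DataFrame:
    """Per-subject covariate table including derived geriatric-DM indicators."""
    rows = []
    for s in subjects:
        c = s.covariates
        row = {
            "age": c.age,
            "sex_male": int(c.sex == "M"),
            "body_weight": c.body_weight,
            "lean_body_weight": c.lean_body_weight,
            "dm": int(c.dm),
            "fed": int(c.feeding == "fed"),
            "renal_disease": int(c.renal_disease),
            "liver_disease": int(c.liver_disease),
            "albumin": c.albumin,
            "total_bilirubin": c.total_bilirubin,
            "ast": c.ast,
            "alt": c.alt,
        }
        for cut in cutoffs:
            row[f"gdm{cut}"] = int(is_geriatric_dm(c.age, c.dm, cut))
            row[f"age{cut}"] = int(c.age >= cut)
        rows.append(row)
    return pd.DataFrame(rows, index=[s.id for s in subjects])


class FoceEngine:
    """Vectorised FOCE-I machinery for a fixed dataset and model spec."""

    def __init__(self, subjects: Sequence[SubjectRecord], spec: ModelSpec):
        subjects = list(subjects)
        if not subjects:
            raise FitError("no subjects")
        for s in subjects:
            if len(s.observations) == 0:
                raise FitError(f"subject {s.id} has no observations; cannot enter the likelihood")
        self.subjects = subjects
        self.spec = spec
        self.n_sub = len(subjects)

        counts = np.array([len(s.observations) for s in subjects])
        self.starts = np.concatenate([[0], np.cumsum(counts)])
        self.n_obs = int(counts.sum())
        self.t = np.concatenate([[o.time for o in s.observations] for s in subjects])
        self.y = np.concatenate([[o.conc for o in s.observations] for s in subjects])
        self.isub = np.repeat(np.arange(self.n_sub), counts)
        self.dose = np.array([s.regimen.dose for s in subjects])
        self.tau = np.array([s.regimen.tau for s in subjects])
        # groups of subjects sharing an observation count, for batched linalg
        self.groups = {
            int(nj): np.flatnonzero(counts == nj) for nj in np.unique(counts)
        }

        self.cov = covariate_frame(subjects)
        self._colvals = {
            e.name: self.cov[e.column].to_numpy(dtype=float) for e in spec.effects
        }
        self._eta_cache = np.zeros((self.n_sub, 3))
        self.last_n_inner_failures = 0

    # -- individual parameters -------------------------------------------------

    def _factors(self, ps: ParamSet) -> dict[str, np.ndarray]:
        fac = {n: np.ones(self.n_sub) for n in ETA_NAMES}
        for e in self.spec.effects:
            x = self._colvals[e.name]
            if e.kind == "allometric":
                f = (x / e.reference) ** e.exponent
            elif e.kind == "power":
                f = (x / e.reference) ** ps.effects[e.name]
            else:  # categorical
                f = 1.0 + ps.effects[e.name] * x
            fac[e.parameter] = fac[e.parameter] * f
        return fac

    def _typical_params(self, ps: ParamSet):
        """Covariate-adjusted typical (eta = 0) parameter arrays, cached:
        the inner eta search re-evaluates predictions many times at fixed
        fixed effects."""
        key = (
            ps.theta["cl"], ps.theta["v"], ps.theta["ka"],
            tuple(sorted(ps.effects.items())),
        )
        cached = getattr(self, "_typical_cache", None)
        if cached is not None and cached[0] == key:
            return cached[1]
        fac = self._factors(ps)
        base = (
            ps.theta["cl"] * fac["cl"],
            ps.theta["v"] * fac["v"],
            ps.theta["ka"] * fac["ka"],
        )
        self._typical_cache = (key, base)
        return base

    def individual_params(self, ps: ParamSet, eta: np.ndarray | None = None):
        """Arrays (CL_i, V_i, Ka_i) for all subjects at the given etas."""
        cl0, v0, ka0 = self._typical_params(ps)
        if eta is None:
            return cl0.copy(), v0.copy(), ka0.copy()
        return cl0 * np.exp(eta[:, 0]), v0 * np.exp(eta[:, 1]), ka0 * np.exp(eta[:, 2])

    def predict(self, ps: ParamSet, eta: np.ndarray | None = None,
                obs_idx: np.ndarray | None = None) -> np.ndarray:
        """Model predictions for every observation row (or a subset)."""
        cl, v, ka = self.individual_params(ps, eta)
        i = self.isub if obs_idx is None else self.isub[obs_idx]
        t = self.t if obs_idx is None else self.t[obs_idx]
        with np.errstate(all="ignore"):
            return _conc_ss_flat(cl[i], v[i], ka[i], self.dose[i], self.tau[i], t)

    def _fj(self, ps: ParamSet, eta: np.ndarray, obs_idx: np.ndarray | None = None):
        """Predictions and their analytic Jacobian in eta.

        With ``g(a) = e^{-a t}/(1 - e^{-a tau})``, ``u = CL/V`` and
        ``P = D Ka / (V (Ka - u))`` the profile is ``C = P (g(u) - g(Ka))``
        and the partials follow by the chain rule; on the log scale
        ``dC/d eta_CL = CL dC/dCL`` etc.  Rows near the Ka ~ ke degeneracy
        fall back to central differences on the per-row parameters.
        """
        cl, v, ka = self.individual_params(ps, eta)
        i = self.isub if obs_idx is None else self.isub[obs_idx]
        t = self.t if obs_idx is None else self.t[obs_idx]
        CL, V, KA, D, TAU = cl[i], v[i], ka[i], self.dose[i], self.tau[i]
        with np.errstate(all="ignore"):
            u = CL / V
            diff = KA - u
            near = np.abs(diff) < 1e-5 * KA
            diff_s = np.where(near, 1.0, diff)
            E_u = np.exp(-u * t)
            A_u = -np.expm1(-u * TAU)
            E_k = np.exp(-KA * t)
            A_k = -np.expm1(-KA * TAU)
            g_u = E_u / A_u
            g_k = E_k / A_k
            P = D * KA / (V * diff_s)
            C = P * (g_u - g_k)
            gp_u = -E_u * (t + TAU * (1.0 - A_u) / A_u) / A_u
            gp_k = -E_k * (t + TAU * (1.0 - A_k) / A_k) / A_k
            dC_du = C / diff_s + P * gp_u
            dC_dKa = C * (1.0 / KA - 1.0 / diff_s) - P * gp_k
            J = np.empty((C.size, 3))
            J[:, 0] = CL * dC_du / V
            J[:, 1] = V * (-C / V + dC_du * (-u / V))
            J[:, 2] = KA * dC_dKa
            f = np.maximum(C, 0.0)

            if near.any():
                idx = np.flatnonzero(near)
                h = _ETA_FD_STEP
                sub = (CL[idx], V[idx], KA[idx], D[idx], TAU[idx], t[idx])
                f[idx] = _conc_ss_flat(*sub)
                for k, scale in enumerate(("cl", "v", "ka")):
                    hi = list(sub)
                    lo = list(sub)
                    hi[k] = sub[k] * np.exp(h)
                    lo[k] = sub[k] * np.exp(-h)
                    J[idx, k] = (_conc_ss_flat(*hi) - _conc_ss_flat(*lo)) / (2 * h)
            bad = ~np.isfinite(J)
            if bad.any():
                J[bad] = 0.0
        return f, J

    # -- inner problem: conditional modes ---------------------------------------

    def _inner_obj(self, ps: ParamSet, eta: np.ndarray, winv: np.ndarray,
                   obs_idx: np.ndarray | None = None) -> np.ndarray:
        """Penalised least-squares objective per subject (all subjects, or
        only those owning the rows in ``obs_idx``; inactive entries are 0)."""
        with np.errstate(all="ignore"):
            f = self.predict(ps, eta, obs_idx)
            f = np.where(np.isfinite(f), f, 1e30)
            y = self.y if obs_idx is None else self.y[obs_idx]
            isub = self.isub if obs_idx is None else self.isub[obs_idx]
            rss = np.bincount(isub, weights=(y - f) ** 2, minlength=self.n_sub)
            obj = rss / ps.sigma**2 + (eta**2 * winv).sum(axis=1)
        return np.where(np.isfinite(obj), obj, np.inf)

    def _gn_modes(self, ps: ParamSet, eta0: np.ndarray, winv: np.ndarray,
                  tol: float, max_iter: int):
        """Damped Gauss-Newton from one starting point; returns (eta, obj)."""
        eta = eta0.copy()
        sigma2 = ps.sigma**2
        obj = self._inner_obj(ps, eta, winv)
        active = np.ones(self.n_sub, dtype=bool)
        for _ in range(max_iter):
            sub_idx = np.flatnonzero(active)
            obs_idx = np.flatnonzero(active[self.isub])
            f, J = self._fj(ps, eta, obs_idx)
            isub_l = self.isub[obs_idx]
            r = self.y[obs_idx] - f
            # per-subject normal equations (J'J/s2 + Winv) delta = J'r/s2 - Winv*eta
            A = np.zeros((len(sub_idx), 3, 3))
            b = np.zeros((len(sub_idx), 3))
            for a in range(3):
                b[:, a] = np.bincount(isub_l, weights=J[:, a] * r,
                                      minlength=self.n_sub)[sub_idx] / sigma2
                for c in range(a, 3):
                    v = np.bincount(isub_l, weights=J[:, a] * J[:, c],
                                    minlength=self.n_sub)[sub_idx] / sigma2
                    A[:, a, c] = v
                    A[:, c, a] = v
            A[:, np.arange(3), np.arange(3)] += winv
            b -= eta[sub_idx] * winv
            # gradient-based freeze: b is -grad/2 of the penalised objective
            at_mode = np.abs(b).max(axis=1) < 1e-7 * (1.0 + np.abs(obj[sub_idx]))
            if at_mode.any():
                active[sub_idx[at_mode]] = False
                keep = ~at_mode
                if not keep.any():
                    break
                sub_idx = sub_idx[keep]
                A, b = A[keep], b[keep]
            try:
                delta = np.linalg.solve(A, b[..., None])[..., 0]
            except np.linalg.LinAlgError:
                delta = np.linalg.solve(A + 1e-8 * np.eye(3), b[..., None])[..., 0]
            delta = np.clip(np.nan_to_num(delta), -4.0, 4.0)

            # per-subject backtracking line search on the active set
            base = eta[sub_idx]
            step = np.ones(len(sub_idx))
            todo = np.ones(len(sub_idx), dtype=bool)
            new_eta = base.copy()
            new_obj = obj[sub_idx].copy()
            eta_work = eta.copy()
            obs_act = np.flatnonzero(active[self.isub])
            for _ls in range(10):
                trial = np.clip(base + (step * todo)[:, None] * delta, -12.0, 12.0)
                eta_work[sub_idx] = np.where(todo[:, None], trial, new_eta)
                obj_t = self._inner_obj(ps, eta_work, winv, obs_act)[sub_idx]
                better = todo & (obj_t <= obj[sub_idx] + 1e-12)
                new_eta[better] = trial[better]
                new_obj[better] = obj_t[better]
                todo &= ~better
                if not todo.any():
                    break
                step[todo] *= 0.5
            moved = np.abs(new_eta - base).max(axis=1)
            gained = obj[sub_idx] - new_obj
            eta[sub_idx] = new_eta
            obj[sub_idx] = new_obj
            # stalled line search, converged step, or negligible improvement
            frozen = todo | (moved < tol) | (gained < 1e-10 * (1.0 + np.abs(new_obj)))
            active[sub_idx[frozen]] = False
            if not active.any():
                break
        return eta, obj

    def eta_modes(self, ps: ParamSet, eta0: np.ndarray | None = None,
                  tol: float = 1e-6, max_iter: int = 40):
        """Conditional (MAP) modes of eta for every subject.

        The Gauss-Newton search always starts from eta = 0 (optionally also
        from a caller-supplied ``eta0``, keeping the better mode per
        subject), so the result depends only on the parameters and the
        data, never on earlier calls -- the objective seen by the outer
        optimizer is a pure function.  Returns ``(eta_hat, n_failures)``
        where a failure is a subject whose gradient did not come close to
        zero.
        """
        winv = 1.0 / np.maximum(ps.omega, 1e-8) ** 2
        best_eta, best_obj = self._gn_modes(ps, np.zeros((self.n_sub, 3)), winv, tol, max_iter)
        if eta0 is not None and np.abs(eta0).max() > 0:
            eta, obj = self._gn_modes(ps, eta0, winv, tol, max_iter)
            take = obj < best_obj - 1e-12
            if take.any():
                best_eta[take] = eta[take]
                best_obj[take] = obj[take]
        eta = best_eta

        # convergence check: gradient of the penalised objective
        sigma2 = ps.sigma**2
        f, J = self._fj(ps, eta)
        r = self.y - f
        g = np.stack(
            [np.bincount(self.isub, weights=J[:, a] * r, minlength=self.n_sub) for a in range(3)],
            axis=1,
        ) / sigma2 - eta * winv
        n_fail = int((np.abs(g).max(axis=1) > 1e-2 * (1 + np.abs(best_obj))).sum())
        return eta, n_fail

    # -- objective ---------------------------------------------------------------

    def ofv_from_modes(self, ps: ParamSet, eta: np.ndarray) -> float:
        """FOCE-I objective given the conditional modes (additive constant:
        2*pi terms dropped, NONMEM convention; only differences are meaningful)."""
        f, J = self._fj(ps, eta)
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(J))):
            return _BIG_OFV
        r = self.y - f + np.einsum("oa,oa->o", J, eta[self.isub])
        om2 = ps.omega**2
        sigma2 = ps.sigma**2
        total = 0.0
        for nj, subs in self.groups.items():
            idx = self.starts[subs][:, None] + np.arange(nj)
            Jg = J[idx]  # (g, nj, 3)
            rg = r[idx]  # (g, nj)
            V = np.einsum("gia,a,gja->gij", Jg, om2, Jg)
            V[:, np.arange(nj), np.arange(nj)] += sigma2
            sign, logdet = np.linalg.slogdet(V)
            if np.any(sign <= 0):
                return _BIG_OFV
            sol = np.linalg.solve(V, rg[..., None])[..., 0]
            total += float(logdet.sum() + (rg * sol).sum())
        return total if np.isfinite(total) else _BIG_OFV

    def ofv(self, ps: ParamSet, update_cache: bool = True) -> float:
        if not np.isfinite(ps.sigma) or ps.sigma <= 0 or np.any(ps.omega < 0):
            return _BIG_OFV
        if np.all(ps.omega < 1e-3):
            # Omega -> 0 limit: conditional modes vanish and the objective
            # tends to the pooled fixed-effects -2 log-likelihood
            eta, n_fail = np.zeros((self.n_sub, 3)), 0
        else:
            eta, n_fail = self.eta_modes(ps)  # history-independent by design
        self.last_n_inner_failures = n_fail
        if update_cache:
            self._eta_cache = eta
        return self.ofv_from_modes(ps, eta)

    def ofv_vector(self, x: np.ndarray) -> float:
        try:
            ps = self.spec.unpack(x)
        except (ValueError, OverflowError):
            return _BIG_OFV
        val = self.ofv(ps)
        return val if np.isfinite(val) else _BIG_OFV

    # -- outer problem -------------------------------------------------------------

    def pooled_prefit(self, ps0: ParamSet) -> ParamSet:
        """Naive pooled nonlinear least squares at eta = 0.

        Refines the fixed effects (and seeds sigma with the pooled residual
        SD) before the FOCE stage; this removes most of the sensitivity of
        the outer quasi-Newton search to crude starting values.
        """
        n_th = 3 + len(self.spec.estimated_effects)
        z0 = self.spec.pack(ps0)[:n_th]

        def resid(z):
            x = np.concatenate([z, self.spec.pack(ps0)[n_th:]])
            try:
                ps = self.spec.unpack(x)
                return self.y - self.predict(ps, None)
            except (ValueError, FloatingPointError):
                return np.full(self.n_obs, 1e6)

        lb = [b[0] for b in self.spec.bounds()[:n_th]]
        ub = [b[1] for b in self.spec.bounds()[:n_th]]
        sol = optimize.least_squares(resid, z0, bounds=(lb, ub), xtol=1e-10, ftol=1e-10)
        x = self.spec.pack(ps0).copy()
        x[:n_th] = sol.x
        ps = self.spec.unpack(x)
        sigma0 = float(np.sqrt(np.mean(sol.fun**2)))
        return ParamSet(theta=ps.theta, effects=ps.effects, omega=ps.omega,
                        sigma=max(sigma0, 1e-3))

    def minimize(self, inits=None, maxiter: int = 300, prefit: bool = True):
        """Minimise the FOCE-I objective; returns the scipy result plus the
        optimal :class:`ParamSet` and conditional modes.

        ``prefit=True`` first refines the fixed effects by pooled least
        squares at eta = 0, which makes the FOCE stage robust to generic
        starting values.
        """
        ps0 = self.spec.initial_paramset(inits) if not isinstance(inits, ParamSet) else inits
        if prefit:
            ps0 = self.pooled_prefit(ps0)
        x0 = self.spec.pack(ps0)
        self._eta_cache = np.zeros((self.n_sub, 3))
        res = optimize.minimize(
            self.ofv_vector,
            x0,
            method="L-BFGS-B",
            bounds=self.spec.bounds(),
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6, "eps": 1e-5},
        )
        ps = self.spec.unpack(res.x)
        eta, n_fail = self.eta_modes(ps)
        self._eta_cache = eta
        ofv = self.ofv_from_modes(ps, eta)
        if n_fail > 0.01 * self.n_sub:
            warnings.warn(
                f"{n_fail}/{self.n_sub} subjects failed the inner eta-mode search",
                RuntimeWarning,
            )
        return res, ps, eta, ofv, n_fail

    # -- standard errors -------------------------------------------------------------

    def standard_errors(self, ps: ParamSet, h: float = 1e-3):
        """Standard errors on the natural scale from a central-difference
        Hessian of the objective in the packed (transformed) parameters.

        ``Cov_x = 2 H^{-1}`` because the objective is -2 log-likelihood; SEs
        for log-transformed parameters are mapped back with the delta method.
        Returns a Series aligned with :meth:`ModelSpec.param_names` (NaN where
        the Hessian is not positive definite).
        """
        x = self.spec.pack(ps)
        k = len(x)
        names = self.spec.param_names()

        def fval(z):
            return self.ofv_vector(z)

        f0 = fval(x)
        H = np.empty((k, k))
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h
            H[i, i] = (fval(x + ei) - 2 * f0 + fval(x - ei)) / h**2
        for i in range(k):
            for j in range(i + 1, k):
                ei = np.zeros(k)
                ej = np.zeros(k)
                ei[i] = h
                ej[j] = h
                H[i, j] = H[j, i] = (
                    fval(x + ei + ej) - fval(x + ei - ej) - fval(x - ei + ej) + fval(x - ei - ej)
                ) / (4 * h**2)
        se_x = np.full(k, np.nan)
        try:
            cov_x = 2.0 * np.linalg.inv(H)
            d = np.diag(cov_x)
            se_x = np.where(d > 0, np.sqrt(np.maximum(d, 0)), np.nan)
        except np.linalg.LinAlgError:
            pass
        # delta method: natural value = exp(x) except raw covariate thetas
        natural = pd.Series(dict(zip(names, np.nan * np.ones(k))))
        values = self.paramset_as_free_series(ps)
        n_eff = len(self.spec.estimated_effects)
        scale = np.array(
            [values.iloc[i] if (i < 3 or i >= 3 + n_eff) else 1.0 for i in range(k)]
        )
        natural[:] = se_x * np.abs(scale)
        return natural

    def paramset_as_free_series(self, ps: ParamSet) -> pd.Series:
        """Natural-scale values of the free parameters, ordered like param_names."""
        vals = [ps.theta["cl"], ps.theta["v"], ps.theta["ka"]]
        vals += [ps.effects[e.name] for e in self.spec.estimated_effects]
        vals += [ps.omega[ETA_NAMES.index(n)] for n in self.spec.estimated_omegas]
        vals.append(ps.sigma)
        return pd.Series(vals, index=self.spec.param_names())


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------


def foce_ofv(subjects: Sequence[SubjectRecord], spec: ModelSpec, ps: ParamSet) -> float:
    """FOCE-I objective function value for a dataset at fixed parameters."""
    return FoceEngine(subjects, spec).ofv(ps)


def estimate_ebe(subject: SubjectRecord, spec: ModelSpec, ps: ParamSet):
    """Empirical-Bayes (MAP) eta for one subject plus individual parameters
    and individual predictions.  A subject without observations gets the
    prior mode ``eta = 0`` with a warning."""
    if len(subject.observations) == 0:
        warnings.warn(f"subject {subject.id} has no observations; returning eta=0", RuntimeWarning)
        from .data import Observation

        stub = subject.with_observations([Observation(time=1.0, conc=0.0)])
        eng = FoceEngine([stub], spec)
        cl, v, ka = eng.individual_params(ps, np.zeros((1, 3)))
        return np.zeros(3), (float(cl[0]), float(v[0]), float(ka[0])), np.array([])
    eng = FoceEngine([subject], spec)
    eta, _ = eng.eta_modes(ps)
    cl, v, ka = eng.individual_params(ps, eta)
    ipred = eng.predict(ps, eta)
    return eta[0], (float(cl[0]), float(v[0]), float(ka[0])), ipred


def eta_shrinkage(ebes: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Per-effect eta-shrinkage: ``100 * (1 - SD(eta_hat) / omega)``, reported
    clipped to [0, 100] (ddof=1 SD)."""
    ebes = np.atleast_2d(np.asarray(ebes, dtype=float))
    if ebes.shape[0] < 2:
        raise ValueError("shrinkage needs at least two subjects")
    omega = np.asarray(omega, dtype=float)
    sd = ebes.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        shr = 100.0 * (1.0 - sd / omega)
    shr = np.where(omega <= 0, np.nan, shr)
    return np.clip(shr, 0.0, 100.0)
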