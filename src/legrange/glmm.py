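"""Binomial GLMM with crossed species and region random intercepts.

The response is the complete species x region matrix Y of non-native
presence.  The linear predictor is

    eta_ij = alpha + b_SS SS_i + sum_k b_k x_ik + sum_z b_z x_jz
             + b_int SS_i u_i + SP[i] + RE[j]          (optionally + CN[c(j)])

with SP[i] ~ N(0, V_species), RE[j] ~ N(0, V_region) crossed random
intercepts and Y_ij ~ Bernoulli(logistic(eta_ij)).

Estimation maximises the Laplace-approximate marginal likelihood.  Given
variance components and fixed effects, the random-effect modes are found
by penalised Newton iteration (PIRLS); because every cell couples one
species to one region the penalised information has an arrow structure —
the species block is diagonal — so each solve reduces, via a Schur
complement, to a dense system of size n_regions (plus continents).  The
outer optimiser runs over the fixed effects together with the log
standard deviations of the variance components, so the fixed effects are
estimated against the full Laplace objective (whose log-determinant term
matters for rare-event data), matching lme4's Laplace scheme.  A fast
profile pass (fixed effects at the joint penalised mode, Nelder-Mead
over the log-SDs alone) supplies the starting point.  Variances pinned
to zero reduce exactly to plain (IRLS) logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "OccupancyGLMM",
    "OccupancyGLMMResults",
    "linear_predictor",
    "fit_both_variants",
    "continent_check",
    "ContinentCheck",
]

_LOG_SD_FLOOR = -12.0
_W_FLOOR = 1e-10


def linear_predictor(
    beta_species, beta_region, species_design, region_design, sp=None, re=None
):
    """Probability matrix P_ij from coefficients, designs and random
    effects.  ``species_design`` (n_s x p_s) must include the intercept
    column; ``sp``/``re`` default to zero."""
    S = np.asarray(species_design, dtype=float)
    a = S @ np.asarray(beta_species, dtype=float)
    if region_design is not None and np.size(beta_region):
        b = np.asarray(region_design, dtype=float) @ np.asarray(beta_region, float)
    else:
        b = np.zeros(1)
    if sp is not None:
        a = a + np.asarray(sp, dtype=float)
    eta = a[:, None] + b[None, :]
    if re is not None:
        eta = eta + np.asarray(re, dtype=float)[None, :]
    return expit(eta)


def _bernoulli_ll(Y, eta):
    # sum y*eta - log(1 + e^eta), numerically stable
    return float(np.sum(Y * eta) - np.sum(np.logaddexp(0.0, eta)))


def _init_beta(Y, p_s):
    beta = np.zeros(p_s)
    ybar = float(np.clip(Y.mean(), 1e-6, 1.0 - 1e-6))
    beta[0] = np.log(ybar / (1.0 - ybar))
    return beta


def _pirls(Y, a_fix, b_fix, Er, pen_r, inv_Vs, state, gtol=1e-10, max_iter=100):
    """Penalised Newton over the random effects at fixed coefficients.

    ``Er`` (n_r x q) holds the region-side random-effect columns with
    ridge penalties ``pen_r``; ``inv_Vs`` > 0 enables the per-species
    intercepts (diagonal block).  Returns the modes, the linear
    predictor, and convergence info.  ``state`` provides warm starts and
    is updated in place.
    """
    n_s, n_r = Y.shape
    q = Er.shape[1]
    use_us = inv_Vs > 0
    u_s = state.get("u_s")
    if u_s is None or u_s.shape != (n_s,) or not use_us:
        u_s = np.zeros(n_s)
    g_r = state.get("g_r")
    if g_r is None or g_r.shape != (q,):
        g_r = np.zeros(q)

    def pen_ll(u_s_v, g_r_v):
        eta = (a_fix + u_s_v)[:, None] + (b_fix + (Er @ g_r_v if q else 0.0))[None, :]
        val = _bernoulli_ll(Y, eta)
        if use_us:
            val -= 0.5 * inv_Vs * float(u_s_v @ u_s_v)
        if q:
            val -= 0.5 * float(np.sum(pen_r * g_r_v**2))
        return val, eta

    cur, eta = pen_ll(u_s, g_r)
    converged = not use_us and q == 0
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        W = np.maximum(mu * (1.0 - mu), _W_FLOOR)
        R = Y - mu
        grad_s = R.sum(axis=1) - inv_Vs * u_s if use_us else np.zeros(0)
        grad_r = (Er.T @ R.sum(axis=0) - pen_r * g_r) if q else np.zeros(0)
        gmax = max(
            np.abs(grad_s).max() if use_us else 0.0,
            np.abs(grad_r).max() if q else 0.0,
            0.0,
        )
        if gmax < gtol:
            converged = True
            break
        if use_us:
            d_s = W.sum(axis=1) + inv_Vs
            if q:
                WE = W @ Er
                G = Er.T @ (Er * W.sum(axis=0)[:, None]) + np.diag(pen_r)
                G -= WE.T @ (WE / d_s[:, None])
                rhs = grad_r - (WE.T / d_s) @ grad_s
                delta_r = np.linalg.solve(G, rhs)
                delta_s = (grad_s - WE @ delta_r) / d_s
            else:
                delta_r = np.zeros(0)
                delta_s = grad_s / d_s
        else:
            G = Er.T @ (Er * W.sum(axis=0)[:, None]) + np.diag(pen_r)
            delta_r = np.linalg.solve(G, grad_r)
            delta_s = np.zeros(0)
        step = 1.0
        for _ in range(40):
            us_new = u_s + step * delta_s if use_us else u_s
            gr_new = g_r + step * delta_r if q else g_r
            new, eta_new = pen_ll(us_new, gr_new)
            if new >= cur - 1e-12:
                break
            step *= 0.5
        if new < cur - 1e-8:
            converged = gmax < 1e-4
            break
        improved = new - cur
        u_s, g_r, cur, eta = us_new, gr_new, new, eta_new
        if improved < 1e-12 * (1.0 + abs(cur)):
            converged = True
            break
    state["u_s"] = u_s.copy()
    state["g_r"] = g_r.copy()
    return {
        "u_s": u_s,
        "g_r": g_r,
        "eta": eta,
        "pen_ll": cur,
        "converged": converged,
        "iterations": it,
    }


def _laplace_ll(Y, eta, u_s, g_r, Er, pen_r, inv_Vs, V_list):
    """Laplace-approximate marginal log-likelihood at the mode.

    ``V_list`` pairs each active variance component with its number of
    levels for the normalising constant.
    """
    n_s, n_r = Y.shape
    q = Er.shape[1]
    use_us = inv_Vs > 0
    mu = expit(eta)
    W = np.maximum(mu * (1.0 - mu), _W_FLOOR)
    ll = _bernoulli_ll(Y, eta)
    pen = 0.0
    if use_us:
        pen += 0.5 * inv_Vs * float(u_s @ u_s)
    if q:
        pen += 0.5 * float(np.sum(pen_r * g_r**2))
    logdet = 0.0
    if use_us:
        d_s = W.sum(axis=1) + inv_Vs
        logdet += float(np.sum(np.log(d_s)))
        if q:
            WE = W @ Er
            G = Er.T @ (Er * W.sum(axis=0)[:, None]) + np.diag(pen_r)
            G -= WE.T @ (WE / d_s[:, None])
            logdet += float(np.linalg.slogdet(G)[1])
    elif q:
        G = Er.T @ (Er * W.sum(axis=0)[:, None]) + np.diag(pen_r)
        logdet += float(np.linalg.slogdet(G)[1])
    norm = sum(n * np.log(v) for v, n in V_list)
    return ll - pen - 0.5 * logdet - 0.5 * norm


def _profile_warmstart(Y, S, Rg, Vs, Vr, state, max_iter=60):
    """Joint Newton over (fixed effects, random modes) at given
    variances: a cheap, good starting point for the outer optimiser."""
    n_s, n_r = Y.shape
    p_s = S.shape[1]
    p_r = 0 if Rg is None else Rg.shape[1]
    use_us, use_ur = Vs > 0, Vr > 0
    blocks, pen = [], []
    if p_r:
        blocks.append(Rg)
        pen.extend([0.0] * p_r)
    if use_ur:
        blocks.append(np.eye(n_r))
        pen.extend([1.0 / Vr] * n_r)
    E = np.hstack(blocks) if blocks else np.zeros((n_r, 0))
    pen = np.asarray(pen)
    q = E.shape[1]
    inv_Vs = 1.0 / Vs if use_us else 0.0

    d = np.zeros(p_s + q)
    d[:p_s] = state.get("beta", _init_beta(Y, p_s))[:p_s]
    u_s = state.get("u_s", np.zeros(n_s))
    if u_s.shape != (n_s,) or not use_us:
        u_s = np.zeros(n_s)

    def eval_pll(dv, usv):
        a = S @ dv[:p_s] + usv
        b = E @ dv[p_s:] if q else np.zeros(n_r)
        eta = a[:, None] + b[None, :]
        v = _bernoulli_ll(Y, eta)
        if q:
            v -= 0.5 * float(np.sum(pen * dv[p_s:] ** 2))
        if use_us:
            v -= 0.5 * inv_Vs * float(usv @ usv)
        return v, eta

    cur, eta = eval_pll(d, u_s)
    for _ in range(max_iter):
        mu = expit(eta)
        W = np.maximum(mu * (1.0 - mu), _W_FLOOR)
        R = Y - mu
        wr, wc = W.sum(axis=1), W.sum(axis=0)
        g_d = np.concatenate(
            [S.T @ R.sum(axis=1), (E.T @ R.sum(axis=0) - pen * d[p_s:]) if q else np.zeros(0)]
        )
        g_s = R.sum(axis=1) - inv_Vs * u_s if use_us else np.zeros(0)
        gmax = max(np.abs(g_d).max(), np.abs(g_s).max() if use_us else 0.0)
        if gmax < 1e-8:
            break
        SW = S * wr[:, None]
        A11 = S.T @ SW
        if q:
            SWE = S.T @ W @ E
            A22 = E.T @ (E * wc[:, None]) + np.diag(pen)
            A = np.block([[A11, SWE], [SWE.T, A22]])
        else:
            A = A11
        if use_us:
            B = np.vstack([SW.T, E.T @ W.T if q else np.zeros((0, n_s))])
            d_s = wr + inv_Vs
            M = A - (B / d_s) @ B.T
            rhs = g_d - (B / d_s) @ g_s
        else:
            M, rhs = A, g_d
        try:
            delta_d = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError:
            delta_d = np.linalg.lstsq(M, rhs, rcond=None)[0]
        delta_s = (g_s - B.T @ delta_d) / d_s if use_us else np.zeros_like(u_s)
        step = 1.0
        for _ in range(40):
            new, eta_new = eval_pll(d + step * delta_d, u_s + step * delta_s)
            if new >= cur - 1e-12:
                break
            step *= 0.5
        if new < cur - 1e-8:
            break
        improved = new - cur
        d, u_s, cur, eta = d + step * delta_d, u_s + step * delta_s, new, eta_new
        if improved < 1e-11 * (1.0 + abs(cur)):
            break

    beta = np.concatenate([d[:p_s], d[p_s : p_s + p_r]])
    out_state = {"u_s": u_s.copy()}
    if use_ur:
        out_state["u_r"] = d[p_s + p_r :].copy()
    return beta, out_state, cur, eta


class OccupancyGLMM:
    """Crossed-random-intercept binomial occupancy model.

    Parameters
    ----------
    Y : DataFrame
        Complete species x region binary response matrix.
    species_design : DataFrame
        Species-level fixed-effect columns (an ``intercept`` column is
        inserted if missing), indexed like ``Y``'s rows.
    region_design : DataFrame, optional
        Region-level fixed-effect columns, indexed like ``Y``'s columns.
    continents : Series, optional
        Continent label per region, enabling the optional third crossed
        intercept.
    """

    def __init__(self, Y, species_design, region_design=None, continents=None):
        Y = pd.DataFrame(Y)
        if not Y.isin([0, 1]).all().all():
            raise ValueError("Y must be binary")
        if Y.shape[0] < 2 or Y.shape[1] < 2:
            raise ValueError("need at least 2 species and 2 regions")
        self.Y = Y
        sd = pd.DataFrame(species_design).loc[Y.index]
        if "intercept" not in sd.columns:
            sd = sd.copy()
            sd.insert(0, "intercept", 1.0)
        elif list(sd.columns)[0] != "intercept":
            cols = ["intercept"] + [c for c in sd.columns if c != "intercept"]
            sd = sd[cols]
        self.species_design = sd
        self.region_design = (
            pd.DataFrame(region_design).loc[Y.columns]
            if region_design is not None
            else None
        )
        self.continents = (
            pd.Series(continents).loc[Y.columns] if continents is not None else None
        )
        self.exog_names = list(self.species_design.columns) + (
            list(self.region_design.columns) if self.region_design is not None else []
        )

    # construction helpers ----------------------------------------------
    @classmethod
    def from_world(cls, world, include_interaction=True):
        """Build the standard design directly from a synthetic world."""
        sp = world.species
        S = pd.DataFrame(index=sp.index)
        S["intercept"] = 1.0
        S["symbiosis"] = sp["symbiotic"].astype(float)
        S["abs_latitude"] = sp["abs_latitude"].astype(float)
        S["native_area"] = sp["native_area"].astype(float)
        S["annual"] = sp["annual"].astype(float)
        S["woody"] = sp["woody"].astype(float)
        S["n_uses"] = sp["n_uses"].astype(float)
        if include_interaction:
            S["symbiosis_x_uses"] = S["symbiosis"] * S["n_uses"]
        Rg = world.regions[["region_area"]].astype(float)
        cont = world.regions["continent_id"]
        return cls(world.Y, S, Rg, cont)

    @classmethod
    def from_design(cls, Y, design, continents=None):
        """From a :class:`~legrange.covariates.DesignMatrix`."""
        S = design.species.copy()
        S.insert(0, "intercept", 1.0)
        return cls(Y, S, design.region, continents)

    @classmethod
    def from_long(
        cls,
        df,
        species_col="species_id",
        region_col="region_id",
        y_col="y",
        species_covariates=(),
        region_covariates=(),
        continents=None,
    ):
        """From a long-format table with one row per species x region cell."""
        Y = df.pivot(index=species_col, columns=region_col, values=y_col)
        if Y.isna().any().any():
            raise ValueError("long table must cover the complete grid")
        S = (
            df.drop_duplicates(species_col)
            .set_index(species_col)[list(species_covariates)]
            .loc[Y.index]
        )
        S.insert(0, "intercept", 1.0)
        Rg = None
        if region_covariates:
            Rg = (
                df.drop_duplicates(region_col)
                .set_index(region_col)[list(region_covariates)]
                .loc[Y.columns]
            )
        return cls(Y.astype(int), S, Rg, continents)

    def subset_species(self, mask) -> "OccupancyGLMM":
        idx = self.Y.index[np.asarray(mask)]
        return OccupancyGLMM(
            self.Y.loc[idx],
            self.species_design.loc[idx],
            self.region_design,
            self.continents,
        )

    # fitting -------------------------------------------------------------
    def _make_objective(
        self, Y, include_continent=False, fix_variances=None, state=None
    ):
        """Closure computing the negative Laplace log-likelihood at a
        packed parameter vector [log-SDs of free components, beta].

        ``Y`` is passed explicitly so bootstrap refits can swap the
        response without rebuilding the model.  Returns
        (free_names, unpack, objective) where objective(x) gives
        (negative log-lik, PIRLS solution).
        """
        S = self.species_design.to_numpy(dtype=float)
        Rg = (
            self.region_design.to_numpy(dtype=float)
            if self.region_design is not None
            else None
        )
        p_s = S.shape[1]
        p_r = 0 if Rg is None else Rg.shape[1]
        n_s, n_r = Y.shape
        comp_names = ["species", "region"] + (["continent"] if include_continent else [])
        cont_onehot = None
        if include_continent:
            if self.continents is None:
                raise ValueError("continent labels required for the third intercept")
            codes = self.continents.astype("category").cat.codes.to_numpy()
            cont_onehot = np.eye(codes.max() + 1)[codes]
        fix = dict(fix_variances or {})
        free = [c for c in comp_names if c not in fix]
        if state is None:
            state = {}

        def unpack(x):
            v = dict(fix)
            for name, xi in zip(free, x[: len(free)]):
                sd = np.exp(np.clip(xi, _LOG_SD_FLOOR, 6.0))
                v[name] = sd * sd
            v.setdefault("continent", 0.0)
            return v, np.asarray(x[len(free) :], dtype=float)

        def region_side(v):
            blocks, pen, sizes = [], [], []
            if v["region"] > 0:
                blocks.append(np.eye(n_r))
                pen.extend([1.0 / v["region"]] * n_r)
                sizes.append(("region", n_r))
            if include_continent and v["continent"] > 0:
                blocks.append(cont_onehot)
                pen.extend([1.0 / v["continent"]] * cont_onehot.shape[1])
                sizes.append(("continent", cont_onehot.shape[1]))
            Er = np.hstack(blocks) if blocks else np.zeros((n_r, 0))
            return Er, np.asarray(pen), sizes

        def objective(x):
            v, beta = unpack(x)
            a_fix = S @ beta[:p_s]
            b_fix = Rg @ beta[p_s:] if p_r else np.zeros(n_r)
            Er, pen_r, sizes = region_side(v)
            inv_Vs = 1.0 / v["species"] if v["species"] > 0 else 0.0
            sol = _pirls(Y, a_fix, b_fix, Er, pen_r, inv_Vs, state)
            V_list = []
            if v["species"] > 0:
                V_list.append((v["species"], n_s))
            for name, size in sizes:
                V_list.append((v[name], size))
            ll = _laplace_ll(
                Y, sol["eta"], sol["u_s"], sol["g_r"], Er, pen_r, inv_Vs, V_list
            )
            sol["sizes"] = sizes
            return -ll, sol

        return free, unpack, region_side, objective

    def fit(
        self,
        *,
        include_continent: bool = False,
        fix_variances: dict | None = None,
        start_varcomp: dict | None = None,
        start_params: pd.Series | np.ndarray | None = None,
        xatol: float = 1e-3,
        ftol: float = 1e-10,
        max_outer_iter: int = 200,
    ) -> "OccupancyGLMMResults":
        """Maximise the Laplace-approximate marginal likelihood.

        ``fix_variances`` pins named components ("species", "region",
        "continent") to given values (0 removes the component);
        ``start_varcomp``/``start_params`` warm-start the optimiser (as
        bootstrap refits do).  ``xatol`` controls the coarse profile
        pass, ``ftol`` the final joint optimisation.  Deterministic
        given data and options.
        """
        Y = self.Y.to_numpy(dtype=float)
        S = self.species_design.to_numpy(dtype=float)
        Rg = (
            self.region_design.to_numpy(dtype=float)
            if self.region_design is not None
            else None
        )
        p_s = S.shape[1]
        p_r = 0 if Rg is None else Rg.shape[1]
        p = p_s + p_r
        n_s, n_r = Y.shape

        comp_names = ["species", "region"] + (["continent"] if include_continent else [])
        fix = dict(fix_variances or {})
        start_vc = dict(start_varcomp or {})
        state: dict = {}
        free, unpack, region_side, objective = self._make_objective(
            Y, include_continent, fix, state
        )

        # starting point ------------------------------------------------
        if start_params is not None:
            beta0 = (
                start_params.reindex(self.exog_names).to_numpy()
                if isinstance(start_params, pd.Series)
                else np.asarray(start_params, dtype=float)
            )
        else:
            vc_guess = {
                c: start_vc.get(c, fix.get(c, 1.0)) for c in ("species", "region")
            }
            # coarse profile pass over the log-SDs for a warm start
            pstate: dict = {}
            if free and start_vc == {}:

                def profile_obj(xv):
                    vloc = dict(fix)
                    for name, xi in zip(free, xv):
                        sd = np.exp(np.clip(xi, _LOG_SD_FLOOR, 6.0))
                        vloc[name] = sd * sd
                    vloc.setdefault("continent", 0.0)
                    beta_p, st, _, _ = _profile_warmstart(
                        Y, S, Rg, vloc["species"], vloc["region"], pstate
                    )
                    pstate["beta"] = beta_p[:p_s]
                    Er, pen_r, sizes = region_side(vloc)
                    inv_Vs = 1.0 / vloc["species"] if vloc["species"] > 0 else 0.0
                    a_fix = S @ beta_p[:p_s]
                    b_fix = Rg @ beta_p[p_s:] if p_r else np.zeros(n_r)
                    lstate = {"u_s": st.get("u_s")}
                    sol = _pirls(Y, a_fix, b_fix, Er, pen_r, inv_Vs, lstate)
                    V_list = []
                    if vloc["species"] > 0:
                        V_list.append((vloc["species"], n_s))
                    for name, size in sizes:
                        V_list.append((vloc[name], size))
                    return -_laplace_ll(
                        Y, sol["eta"], sol["u_s"], sol["g_r"], Er, pen_r, inv_Vs, V_list
                    )

                x0p = np.zeros(len(free))
                optp = minimize(
                    profile_obj,
                    x0p,
                    method="Nelder-Mead",
                    options=dict(xatol=max(xatol, 1e-2), fatol=0.05, maxfev=120),
                )
                for name, xi in zip(free, optp.x):
                    vc_guess[name] = float(np.exp(2 * np.clip(xi, _LOG_SD_FLOOR, 6.0)))
            beta0, wstate, _, _ = _profile_warmstart(
                Y,
                S,
                Rg,
                vc_guess.get("species", fix.get("species", 1.0)),
                vc_guess.get("region", fix.get("region", 1.0)),
                {},
            )
            state.update(wstate)
            start_vc = {**vc_guess, **start_vc}

        x0 = np.concatenate(
            [
                [0.5 * np.log(max(start_vc.get(c, 1.0), 1e-10)) for c in free],
                beta0,
            ]
        )

        n_outer = 0
        outer_success = True
        if p or free:
            opt = minimize(
                lambda x: objective(x)[0],
                x0,
                method="L-BFGS-B",
                options=dict(
                    maxiter=max_outer_iter,
                    ftol=ftol,
                    gtol=1e-6,
                    eps=1e-6,
                ),
            )
            n_outer = int(opt.nit)
            outer_success = bool(opt.success)
            xhat = opt.x
        else:
            xhat = x0
        neg_ll, sol = objective(xhat)
        v_hat, beta_hat = unpack(xhat)

        # conditional covariance of the fixed effects at the optimum
        Er, pen_r, sizes = region_side(v_hat)
        cov = self._conditional_cov(Y, S, Rg, sol["eta"], v_hat, Er, pen_r)
        bse = np.full(p, np.nan)
        if cov is not None:
            bse = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))

        boundary = {
            c: v_hat[c] <= np.exp(2 * (_LOG_SD_FLOOR + 0.1)) for c in free
        }
        re_dict = {"species": pd.Series(sol["u_s"], index=self.Y.index)}
        off = 0
        u_r = np.zeros(n_r)
        for name, size in sizes:
            vals = sol["g_r"][off : off + size]
            off += size
            if name == "region":
                u_r = vals
                re_dict["region"] = pd.Series(vals, index=self.Y.columns)
            else:
                cats = self.continents.astype("category").cat.categories
                re_dict["continent"] = pd.Series(vals, index=list(cats))
        re_dict.setdefault("region", pd.Series(u_r, index=self.Y.columns))

        mu_eta = sol["eta"]
        return OccupancyGLMMResults(
            model=self,
            params=pd.Series(beta_hat, index=self.exog_names),
            bse=pd.Series(bse, index=self.exog_names),
            vc={c: float(v_hat[c]) for c in comp_names},
            random_effects=re_dict,
            llf=-neg_ll,
            converged=bool(sol["converged"] and outer_success),
            inner_iterations=sol["iterations"],
            outer_iterations=n_outer,
            boundary=boundary,
            separation_flag=bool(
                np.abs(mu_eta).max() > 30.0 or np.abs(beta_hat).max() > 20.0
            ),
            fit_state={
                "vc": {c: float(v_hat[c]) for c in comp_names},
                "x_hat": np.asarray(xhat, dtype=float),
                "free": list(free),
                "include_continent": include_continent,
                "fix": dict(fix),
            },
        )

    @staticmethod
    def _conditional_cov(Y, S, Rg, eta, v, Er, pen_r):
        """Fixed-effect block of the inverse penalised information at the
        mode (conditional on the variance components)."""
        n_s, n_r = Y.shape
        p_s = S.shape[1]
        p_r = 0 if Rg is None else Rg.shape[1]
        mu = expit(eta)
        W = np.maximum(mu * (1.0 - mu), _W_FLOOR)
        wr, wc = W.sum(axis=1), W.sum(axis=0)
        blocks = [Rg] if p_r else []
        pens = [0.0] * p_r
        if Er.shape[1]:
            blocks.append(Er)
            pens.extend(pen_r.tolist())
        E = np.hstack(blocks) if blocks else np.zeros((n_r, 0))
        pens = np.asarray(pens)
        q = E.shape[1]
        SW = S * wr[:, None]
        A11 = S.T @ SW
        if q:
            SWE = S.T @ W @ E
            A22 = E.T @ (E * wc[:, None]) + np.diag(pens)
            A = np.block([[A11, SWE], [SWE.T, A22]])
        else:
            A = A11
        if v["species"] > 0:
            B = np.vstack([SW.T, E.T @ W.T if q else np.zeros((0, n_s))])
            d_s = wr + 1.0 / v["species"]
            A = A - (B / d_s) @ B.T
        try:
            inv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            return None
        # reorder so the region fixed effects follow the species ones
        idx = list(range(p_s)) + [p_s + k for k in range(p_r)]
        return inv[np.ix_(idx, idx)]


@dataclass
class OccupancyGLMMResults:
    """Fitted crossed-random-intercept occupancy GLMM."""

    model: OccupancyGLMM
    params: pd.Series
    bse: pd.Series
    vc: dict
    random_effects: dict
    llf: float
    converged: bool
    inner_iterations: int
    outer_iterations: int
    boundary: dict = field(default_factory=dict)
    separation_flag: bool = False
    fit_state: dict = field(default_factory=dict)

    # predictions ---------------------------------------------------------
    def fitted_eta(self, conditional: bool = True) -> pd.DataFrame:
        m = self.model
        p_s = m.species_design.shape[1]
        a = m.species_design.to_numpy(float) @ self.params.to_numpy()[:p_s]
        b = np.zeros(m.Y.shape[1])
        if m.region_design is not None:
            b = m.region_design.to_numpy(float) @ self.params.to_numpy()[p_s:]
        if conditional:
            a = a + self.random_effects["species"].to_numpy()
            b = b + self.random_effects["region"].to_numpy()
            if "continent" in self.random_effects and m.continents is not None:
                b = b + self.random_effects["continent"].loc[m.continents].to_numpy()
        return pd.DataFrame(
            a[:, None] + b[None, :], index=m.Y.index, columns=m.Y.columns
        )

    def fitted_probabilities(self, conditional: bool = True) -> pd.DataFrame:
        eta = self.fitted_eta(conditional=conditional)
        return pd.DataFrame(
            expit(eta.to_numpy()), index=eta.index, columns=eta.columns
        )

    # inference -----------------------------------------------------------
    def parametric_bootstrap(self, B=1000, seed=0, **kw):
        from .bootstrap import parametric_bootstrap

        return parametric_bootstrap(self, B=B, seed=seed, **kw)

    def effect_summary(self, B=1000, seed=0, **kw):
        from .bootstrap import effect_summary

        return effect_summary(self, B=B, seed=seed, **kw)

    def interaction_profile(self, use_levels, B=1000, seed=0, **kw):
        from .bootstrap import interaction_profile

        return interaction_profile(self, use_levels, B=B, seed=seed, **kw)

    # reporting -----------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Crossed random-intercept binomial occupancy GLMM (Laplace ML)",
            f"  n_species={self.model.Y.shape[0]}  n_regions={self.model.Y.shape[1]}"
            f"  cells={self.model.Y.size}",
            f"  log-likelihood (Laplace) = {self.llf:.3f}"
            f"   converged={self.converged}",
            "  variance components: "
            + ", ".join(f"{k}={v:.4g}" for k, v in self.vc.items()),
            "",
            f"  {'coefficient':<22}{'estimate':>10}{'approx SE':>11}",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:<22}{self.params[name]:>10.4f}{self.bse[name]:>11.4f}"
            )
        if any(self.boundary.values()):
            lines.append("  note: variance component at boundary")
        if self.separation_flag:
            lines.append("  note: possible complete separation (|eta| > 30)")
        return "\n".join(lines)

    def write_summary_tsv(self, path, ci_table=None) -> None:
        """Coefficient table as TSV; optionally merges bootstrap CIs."""
        df = pd.DataFrame(
            {"coefficient": self.params.index, "estimate": self.params.values}
        )
        if ci_table is not None:
            df = df.merge(ci_table.reset_index(), on="coefficient", how="left")
        df.to_csv(path, sep="\t", index=False)


def _fd_grad(fun, x, f0=None, eps=1e-5):
    if f0 is None:
        f0 = fun(x)
    g = np.empty(len(x))
    for k in range(len(x)):
        xk = x.copy()
        xk[k] += eps
        g[k] = (fun(xk) - f0) / eps
    return g, f0


class FastRefitter:
    """Quasi-Newton refitter for bootstrap replicates.

    Reuses the original fit's finite-difference Hessian of the Laplace
    objective (computed once) so each replicate needs only a handful of
    gradient steps from the original optimum.  Falls back to the full
    optimiser when the quasi-Newton iteration fails to converge.
    """

    def __init__(self, results: "OccupancyGLMMResults", gtol=2e-2, max_iter=25):
        self.results = results
        self.model = results.model
        st = results.fit_state
        if "x_hat" not in st:
            raise ValueError("results lack refit state; call fit() first")
        self.x_hat = st["x_hat"]
        self.include_continent = st["include_continent"]
        self.fix = st["fix"]
        self.gtol = gtol
        self.max_iter = max_iter
        self.state: dict = {}
        self.exog_names = self.model.exog_names
        # FD Hessian of the objective at the original optimum
        Y0 = self.model.Y.to_numpy(dtype=float)
        fun0 = self._fun_for(Y0)
        n = len(self.x_hat)
        h = 1e-4
        g0, _ = _fd_grad(fun0, self.x_hat)
        H = np.empty((n, n))
        for k in range(n):
            xk = self.x_hat.copy()
            xk[k] += h
            gk, _ = _fd_grad(fun0, xk)
            H[:, k] = (gk - g0) / h
        H = 0.5 * (H + H.T)
        # guard against indefiniteness from FD noise
        w, V = np.linalg.eigh(H)
        w = np.maximum(w, 1e-4 * max(w.max(), 1.0))
        self.H_inv = (V / w) @ V.T

    def _fun_for(self, Yarr):
        free, unpack, _, objective = self.model._make_objective(
            Yarr, self.include_continent, self.fix, self.state
        )
        self._unpack = unpack
        self._free = free
        self._objective = objective
        return lambda x: objective(x)[0]

    def refit(self, Yarr):
        """Refit to a replicate response; returns (params Series, vc
        dict, converged flag)."""
        fun = self._fun_for(Yarr)
        x = self.x_hat.copy()
        f = fun(x)
        converged = False
        for _ in range(self.max_iter):
            g, f = _fd_grad(fun, x, f0=f)
            if np.abs(g).max() < self.gtol:
                converged = True
                break
            dx = -self.H_inv @ g
            step = 1.0
            for _ in range(8):
                f_new = fun(x + step * dx)
                if f_new <= f + 1e-10:
                    break
                step *= 0.5
            if f_new > f + 1e-10:
                break
            x = x + step * dx
            f = f_new
        if not converged:
            # fall back to the full optimiser for this replicate
            refit_model = OccupancyGLMM(
                pd.DataFrame(
                    Yarr.astype(int), index=self.model.Y.index, columns=self.model.Y.columns
                ),
                self.model.species_design,
                self.model.region_design,
                self.model.continents,
            )
            res = refit_model.fit(
                include_continent=self.include_continent,
                fix_variances=self.fix or None,
                start_varcomp=dict(self.results.vc),
                start_params=self.results.params,
            )
            return res.params, res.vc, res.converged
        v, beta = self._unpack(x)
        params = pd.Series(beta, index=self.exog_names)
        return params, {k: float(v[k]) for k in ("species", "region")}, True


def fit_both_variants(model: OccupancyGLMM, **fit_kw):
    """Fit the all-species model and the variant restricted to species
    with at least one non-native region (all region columns kept)."""
    res_all = model.fit(**fit_kw)
    keep = model.Y.sum(axis=1) >= 1
    if not keep.any():
        raise ValueError("no species has a non-native region; variant 2 is empty")
    res_nn = model.subset_species(keep.to_numpy()).fit(**fit_kw)
    return res_all, res_nn


@dataclass
class ContinentCheck:
    variance: float
    recommend_removal: bool
    identifiable: bool
    results: OccupancyGLMMResults | None = None


def continent_check(
    model: OccupancyGLMM, tol: float = 1e-2, **fit_kw
) -> ContinentCheck:
    """Fit with a third crossed continent intercept and report whether it
    explains enough variation to keep."""
    if model.continents is None or model.continents.nunique() < 2:
        return ContinentCheck(np.nan, True, identifiable=False)
    res = model.fit(include_continent=True, **fit_kw)
    v = res.vc.get("continent", 0.0)
    return ContinentCheck(v, bool(v < tol), identifiable=True, results=res)
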