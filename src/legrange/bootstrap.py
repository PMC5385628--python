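"""Parametric-bootstrap inference and effect summaries.

Significance testing follows the simulate-and-refit scheme: B response
matrices are drawn from the fitted model with the species and region
random effects held fixed at their conditional modes, the full model is
refitted to each draw, and empirical quantiles of the refitted fixed
effects give the confidence intervals.  Effect summaries use the same
simulation with all covariates set to zero (symbiosis kept at observed
values), which removes covariate-explained variation in the manner of
least-squares means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

DEFAULT_B = 1000
DEFAULT_LEVELS = (0.95, 0.99, 0.999)


@dataclass
class BootstrapDraws:
    """Refitted fixed-effect vectors from parametric-bootstrap replicates."""

    draws: pd.DataFrame  # successful replicates x coefficients
    converged: np.ndarray  # flag per attempted replicate
    master_seed: int
    n_failed: int

    @property
    def B(self) -> int:
        return len(self.draws)

    def write_csv(self, path) -> None:
        self.draws.to_csv(path, index_label="replicate")


def _replicate_rngs(seed: int, B: int) -> list[np.random.Generator]:
    """Counter-based per-replicate generators: replicate b is reproducible
    independently of execution order."""
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(B)]


def parametric_bootstrap(
    results,
    B: int = DEFAULT_B,
    seed: int = 0,
    conditional: bool = True,
    max_failure_fraction: float = 0.05,
) -> BootstrapDraws:
    """Simulate-and-refit bootstrap of the fixed effects.

    ``conditional=True`` (the default scheme) fixes the random effects at
    their conditional modes when simulating; ``conditional=False`` draws
    fresh random effects from the fitted variance components instead.
    """
    if not results.converged:
        raise ValueError("refusing to bootstrap a non-converged fit")
    from .glmm import FastRefitter

    refitter = FastRefitter(results)
    rngs = _replicate_rngs(seed, B)
    rows = []
    flags = np.zeros(B, dtype=bool)
    eta_hat = results.fitted_eta(conditional=True).to_numpy()
    eta_fixed = results.fitted_eta(conditional=False).to_numpy()
    n_s, n_r = eta_hat.shape
    for b, rng in enumerate(rngs):
        if conditional:
            eta = eta_hat
        else:
            sp = rng.normal(0.0, np.sqrt(results.vc["species"]), n_s)
            re = rng.normal(0.0, np.sqrt(results.vc["region"]), n_r)
            eta = eta_fixed + sp[:, None] + re[None, :]
        Ystar = (rng.random(eta.shape) < expit(eta)).astype(float)
        try:
            params, vc, ok = refitter.refit(Ystar)
        except Exception:
            continue
        flags[b] = ok
        if ok:
            rows.append(params)
    if not rows:
        raise RuntimeError("no bootstrap replicate converged")
    n_failed = B - len(rows)
    if n_failed > max_failure_fraction * B:
        import warnings

        warnings.warn(
            f"{n_failed}/{B} bootstrap replicates failed to converge",
            RuntimeWarning,
            stacklevel=2,
        )
    draws = pd.DataFrame(rows).reset_index(drop=True)
    return BootstrapDraws(draws=draws, converged=flags, master_seed=seed, n_failed=n_failed)


def ci_table(
    draws: BootstrapDraws | pd.DataFrame,
    levels=DEFAULT_LEVELS,
    point_estimates: pd.Series | None = None,
) -> pd.DataFrame:
    """Empirical-quantile confidence intervals per coefficient.

    Quantiles use linear interpolation (type-7).  A coefficient is
    starred when its interval at the given level excludes zero.
    """
    df = draws.draws if isinstance(draws, BootstrapDraws) else draws
    if len(df) < 2:
        raise ValueError("need at least two successful draws")
    out = pd.DataFrame(index=df.columns)
    out.index.name = "coefficient"
    if point_estimates is not None:
        out["estimate"] = point_estimates
    stars = pd.Series("", index=df.columns)
    for level in levels:
        if not 0.0 < level < 1.0:
            raise ValueError(f"confidence level {level} outside (0, 1)")
        lo_q, hi_q = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
        lo = df.quantile(lo_q, interpolation="linear")
        hi = df.quantile(hi_q, interpolation="linear")
        pct = f"{level * 100:g}"
        out[f"lower_{pct}"] = lo
        out[f"upper_{pct}"] = hi
        excludes = (lo > 0) | (hi < 0)
        stars[excludes] += "*"
    out["significance"] = stars
    return out


def _zeroed_eta(results, n_uses=0.0):
    """Linear predictor with covariates at zero, symbiosis observed, and
    random effects at conditional modes; optionally a common human-use
    count for the interaction profile."""
    model = results.model
    S = model.species_design
    params = results.params
    ss = S["symbiosis"].to_numpy() if "symbiosis" in S else np.zeros(len(S))
    a = (
        params["intercept"]
        + params.get("symbiosis", 0.0) * ss
        + params.get("n_uses", 0.0) * n_uses
        + params.get("symbiosis_x_uses", 0.0) * ss * n_uses
        + results.random_effects["species"].to_numpy()
    )
    b = results.random_effects["region"].to_numpy()
    return a[:, None] + b[None, :], ss.astype(bool)


def effect_summary(results, B: int = DEFAULT_B, seed: int = 0) -> pd.DataFrame:
    """Bootstrap group means of the number of introduced regions with all
    covariates at zero and symbiosis at its observed values.

    Returns one row per symbiosis group with the across-replicate mean
    and 2.5/97.5 percentile bounds of the mean per-species row sum.
    """
    eta, symb = _zeroed_eta(results)
    if symb.all() or (~symb).all():
        raise ValueError("both symbiosis groups must be non-empty")
    p = expit(eta)
    rngs = _replicate_rngs(seed, B)
    means = np.empty((B, 2))
    for b, rng in enumerate(rngs):
        Ystar = rng.random(p.shape) < p
        rowsum = Ystar.sum(axis=1)
        means[b, 0] = rowsum[~symb].mean()
        means[b, 1] = rowsum[symb].mean()
    out = pd.DataFrame(
        {
            "group": ["non-symbiotic", "symbiotic"],
            "mean_introduced_regions": means.mean(axis=0),
            "lower_95": np.quantile(means, 0.025, axis=0),
            "upper_95": np.quantile(means, 0.975, axis=0),
        }
    ).set_index("group")
    return out


def interaction_profile(
    results,
    use_levels,
    B: int = DEFAULT_B,
    seed: int = 0,
    fixed_effects_only: bool = False,
) -> pd.DataFrame:
    """Standardised symbiosis effect across human-use levels.

    For each use count u, predicts the per-group expected number of
    non-native regions with ``n_uses = u`` and all other covariates zero,
    then reports (N_s - N_ns) / N_ns: negative values mean symbiotic
    species are predicted to occupy fewer non-native regions.

    With ``fixed_effects_only`` the profile is the deterministic
    expectation without random effects or simulation; otherwise means and
    95% bounds come from B simulated response matrices per level.
    """
    if "symbiosis_x_uses" not in results.params.index:
        raise ValueError("fit does not include the symbiosis x human-uses interaction")
    model = results.model
    n_r = model.Y.shape[1]
    p = results.params
    rows = []
    for u in use_levels:
        if fixed_effects_only:
            eta_s = p["intercept"] + p["symbiosis"] + (p["n_uses"] + p["symbiosis_x_uses"]) * u
            eta_ns = p["intercept"] + p["n_uses"] * u
            n_s_pred = n_r * expit(eta_s)
            n_ns_pred = n_r * expit(eta_ns)
            rows.append((u, (n_s_pred - n_ns_pred) / n_ns_pred, np.nan, np.nan, 0))
            continue
        eta, symb = _zeroed_eta(results, n_uses=float(u))
        prob = expit(eta)
        rngs = _replicate_rngs((seed, int(round(u * 1000))), B)
        vals = []
        dropped = 0
        for rng in rngs:
            Ystar = rng.random(prob.shape) < prob
            rowsum = Ystar.sum(axis=1)
            n_ns = rowsum[~symb].mean()
            if n_ns == 0:
                dropped += 1
                continue
            vals.append((rowsum[symb].mean() - n_ns) / n_ns)
        if not vals:
            raise RuntimeError(f"all replicates dropped at u={u} (N_ns == 0)")
        vals = np.asarray(vals)
        rows.append(
            (
                u,
                vals.mean(),
                np.quantile(vals, 0.025),
                np.quantile(vals, 0.975),
                dropped,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["n_uses", "std_difference", "lower_95", "upper_95", "dropped"],
    ).set_index("n_uses")
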