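"""Joint K-disease Bernoulli-logit model with a multivariate ICAR convolution.

For participant i in district j(i) and disease k,

    logit P(Y_ik = 1) = alpha_k + beta_k' x_i + S_{j(i),k} + V_{j(i),k}

where the J×K structured effects S follow an intrinsic multivariate CAR
prior coupling diseases through a K×K covariance Sigma_s (each row's full
conditional is Normal(mean of neighbour rows, Sigma_s / m_j)), and the
unstructured effects V are iid MVN(0, Sigma_v).  Identification comes from
sum-to-zero constraints on each column of S; intercepts get a flat prior,
fixed effects Normal(0, 10^3), and both inverse covariance matrices get
Wishart(df=K, identity scale) hyperpriors.

Inference is Gibbs sampling with Pólya–Gamma augmentation, which makes
every full conditional Gaussian or Wishart in closed form.  An adaptive
random-walk Metropolis sweep over the same full conditionals is provided
as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cvdmap.polya_gamma import random_polya_gamma
from cvdmap.spatial_graph import AdjacencyGraph, icar_structure


class ModelError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignInfo:
    """Dummy-coded design metadata: column names and reference levels."""

    names: list[str]
    terms: dict[str, list[str]]  # covariate -> ordered levels (reference first)

    def reference_level(self, covariate: str) -> str:
        return self.terms[covariate][0]


def build_design(
    covariates: pd.DataFrame,
    columns: list[str],
    references: dict[str, str] | None = None,
    recode: dict[str, dict[str, str]] | None = None,
) -> tuple[np.ndarray, DesignInfo]:
    """Dummy-code categorical covariates (reference level dropped).

    Numeric columns pass through unchanged; categoricals contribute one
    indicator per non-reference level, named ``col=level``.  The reference
    is *references[col]* when given, else the most frequent level.
    *recode* optionally collapses levels first, e.g.
    ``{"smoking": {"ex_smoker": "ever", "current": "ever"}}`` for a
    two-level instead of three-level coding.
    """
    references = references or {}
    recode = recode or {}
    cols: list[np.ndarray] = []
    names: list[str] = []
    terms: dict[str, list[str]] = {}
    for col in columns:
        s = covariates[col]
        if col in recode:
            s = s.astype(str).replace(recode[col])
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2:
            cols.append(s.to_numpy(dtype=float))
            names.append(col)
            terms[col] = [col]
            continue
        levels = [str(v) for v in pd.unique(s.astype(str).dropna())]
        ref = references.get(col)
        if ref is None:
            ref = str(s.astype(str).mode().iloc[0])
        if ref not in levels:
            raise ModelError(f"reference level {ref!r} not found in column {col!r}")
        ordered = [ref] + sorted(l for l in levels if l != ref)
        terms[col] = ordered
        for lev in ordered[1:]:
            cols.append((s.astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{col}={lev}")
    X = np.column_stack(cols) if cols else np.empty((len(covariates), 0))
    return X, DesignInfo(names=names, terms=terms)


# ---------------------------------------------------------------------------
# Specification and state
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Data and priors for one fit."""

    Y: np.ndarray                      # n×K in {0,1,nan}
    X: np.ndarray                      # n×p design (no intercept column)
    area: np.ndarray                   # n, 0-based district index
    graph: AdjacencyGraph
    disease_names: list[str] = field(default_factory=list)
    design_info: DesignInfo | None = None
    beta_prior_var: float = 1e3
    wishart_df: float | None = None    # default K
    wishart_scale: np.ndarray | None = None  # default identity, both fields
    spatial: bool = True               # False: plain logistic reduction (S=V=0)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.area = np.asarray(self.area, dtype=int)
        n, K = self.Y.shape
        if self.X.shape[0] != n or self.area.shape[0] != n:
            raise ModelError("Y, X and area must align on participants")
        if self.area.min() < 0 or self.area.max() >= self.graph.n_areas:
            raise ModelError("area indices out of range for the graph")
        bad = self.Y[~np.isnan(self.Y)]
        if not np.isin(bad, (0.0, 1.0)).all():
            raise ModelError("Y must be binary or missing")
        if not self.disease_names:
            self.disease_names = [f"disease_{k + 1}" for k in range(K)]
        if self.wishart_df is None:
            self.wishart_df = float(K)
        if self.wishart_scale is None:
            self.wishart_scale = np.eye(K)
        self._icar = icar_structure(self.graph)

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def K(self) -> int:
        return self.Y.shape[1]

    @property
    def J(self) -> int:
        return self.graph.n_areas

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def icar(self):
        return self._icar


@dataclass
class ModelState:
    alpha: np.ndarray     # K
    beta: np.ndarray      # p×K
    S: np.ndarray         # J×K structured
    V: np.ndarray         # J×K unstructured
    Sigma_s: np.ndarray   # K×K
    Sigma_v: np.ndarray   # K×K

    def copy(self) -> "ModelState":
        return ModelState(*(a.copy() for a in
                            (self.alpha, self.beta, self.S, self.V,
                             self.Sigma_s, self.Sigma_v)))


def initial_state(spec: ModelSpec, jitter_rng: np.random.Generator | None = None) -> ModelState:
    """Start at empirical logits, zero effects, modest covariances."""
    with np.errstate(invalid="ignore"):
        prev = np.nanmean(spec.Y, axis=0)
    prev = np.clip(np.nan_to_num(prev, nan=0.5), 0.01, 0.99)
    alpha = np.log(prev / (1 - prev))
    if jitter_rng is not None:
        alpha = alpha + 0.1 * jitter_rng.standard_normal(spec.K)
    return ModelState(
        alpha=alpha,
        beta=np.zeros((spec.p, spec.K)),
        S=np.zeros((spec.J, spec.K)),
        V=np.zeros((spec.J, spec.K)),
        Sigma_s=0.1 * np.eye(spec.K),
        Sigma_v=0.1 * np.eye(spec.K),
    )


# ---------------------------------------------------------------------------
# Model mathematics
# ---------------------------------------------------------------------------

def linear_predictor(state: ModelState, spec: ModelSpec) -> np.ndarray:
    """n×K matrix of eta_ik = alpha_k + beta_k'x_i + S_{j(i)k} + V_{j(i)k}."""
    if state.beta.shape != (spec.p, spec.K):
        raise ModelError(
            f"beta has shape {state.beta.shape}, expected {(spec.p, spec.K)}"
        )
    U = state.S + state.V
    return state.alpha[None, :] + spec.X @ state.beta + U[spec.area]


def log_likelihood(state: ModelState, spec: ModelSpec) -> float:
    """Bernoulli log likelihood over observed cells, stable for extreme eta."""
    eta = linear_predictor(state, spec)
    obs = ~np.isnan(spec.Y)
    y = spec.Y[obs]
    e = eta[obs]
    # y*eta - log(1 + exp(eta)), with log1pexp via logaddexp
    return float(np.sum(y * e - np.logaddexp(0.0, e)))


def micar_conditional(
    S: np.ndarray, j: int, graph: AdjacencyGraph, Sigma_s: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Full conditional of row S_j under the intrinsic multivariate CAR.

    mean = average of neighbour rows, covariance = Sigma_s / m_j.  Islands
    have no conditional (their effect is pinned at 0 by convention).
    """
    nbrs = graph.neighbours[j]
    m = len(nbrs)
    if m == 0:
        raise ModelError(
            f"area {j + 1} is an island: its structured effect is fixed at 0"
        )
    mean = S[nbrs].mean(axis=0)
    return mean, Sigma_s / m


def update_precision(
    effects: np.ndarray,
    prior_df: float,
    prior_scale: np.ndarray,
    kind: str,
    rng: np.random.Generator,
    icar=None,
) -> np.ndarray:
    """Draw a precision matrix from its conjugate Wishart full conditional.

    structured:   crossprod = S'QS (pairwise differences over edges),
                  df* = prior_df + rank(Q) = prior_df + (J - n_components)
    unstructured: crossprod = V'V, df* = prior_df + J
    """
    J, K = effects.shape
    if kind == "structured":
        if icar is None:
            raise ModelError("structured update needs the ICAR structure")
        crossprod = effects.T @ icar.Q @ effects
        df_star = prior_df + icar.rank
    elif kind == "unstructured":
        crossprod = effects.T @ effects
        df_star = prior_df + J
    else:
        raise ModelError(f"unknown precision kind {kind!r}")
    scale_inv = np.linalg.inv(prior_scale) + crossprod
    scale_star = np.linalg.inv(scale_inv)
    scale_star = 0.5 * (scale_star + scale_star.T)
    try:
        np.linalg.cholesky(scale_star)
    except np.linalg.LinAlgError as exc:
        raise ModelError(
            f"Wishart scale for {kind} effects is not SPD; "
            f"eigenvalues {np.linalg.eigvalsh(scale_star)}"
        ) from exc
    draw = stats.wishart.rvs(df=df_star, scale=scale_star, random_state=rng)
    return np.atleast_2d(draw)  # scipy collapses K=1 to a scalar


def recenter(state: ModelState, spec: ModelSpec) -> ModelState:
    """Impose sum-to-zero on each S column, folding the mean into alpha.

    Island areas are pinned at 0 and excluded from the mean, so they stay
    exactly 0.  The linear predictor is unchanged.
    """
    islands = spec.graph.islands
    free = np.setdiff1d(np.arange(spec.J), islands)
    means = state.S[free].mean(axis=0)
    state.S[free] -= means
    state.S[islands] = 0.0
    state.alpha += means
    return state


# ---------------------------------------------------------------------------
# Gibbs sweep (Pólya–Gamma augmentation)
# ---------------------------------------------------------------------------

def _draw_mvn(mean: np.ndarray, precision: np.ndarray, rng) -> np.ndarray:
    """MVN draw parameterised by precision, via Cholesky."""
    L = np.linalg.cholesky(precision)
    z = rng.standard_normal(mean.shape[0])
    return mean + np.linalg.solve(L.T, z)


def mcmc_step(state: ModelState, spec: ModelSpec, rng: np.random.Generator) -> ModelState:
    """One full Gibbs sweep; returns the mutated state."""
    n, K, J, p = spec.n, spec.K, spec.J, spec.p
    obs = ~np.isnan(spec.Y)
    eta = linear_predictor(state, spec)

    # (1) Polya-Gamma latents for observed cells only
    omega = np.zeros((n, K))
    omega[obs] = random_polya_gamma(eta[obs], rng)
    kappa = np.where(obs, np.nan_to_num(spec.Y) - 0.5, 0.0)

    # (2) per-disease block update of (alpha_k, beta_k)
    Xt = np.column_stack([np.ones(n), spec.X])
    U = (state.S + state.V)[spec.area]
    prior_prec = np.diag(np.r_[0.0, np.full(p, 1.0 / spec.beta_prior_var)])
    for k in range(K):
        w = omega[:, k]
        b = Xt.T @ (kappa[:, k] - w * U[:, k])
        P = (Xt * w[:, None]).T @ Xt + prior_prec
        try:
            mean = np.linalg.solve(P, b)
            draw = _draw_mvn(mean, P, rng)
        except np.linalg.LinAlgError as exc:
            raise ModelError(f"Gaussian solve failed for disease {k}") from exc
        state.alpha[k] = draw[0]
        state.beta[:, k] = draw[1:]

    if not spec.spatial:
        return state

    # per-district likelihood aggregates given the new fixed effects
    fixed = state.alpha[None, :] + spec.X @ state.beta
    Wd = np.zeros((J, K))
    Bd = np.zeros((J, K))
    for k in range(K):
        Wd[:, k] = np.bincount(spec.area, weights=omega[:, k], minlength=J)
        Bd[:, k] = np.bincount(
            spec.area, weights=kappa[:, k] - omega[:, k] * fixed[:, k], minlength=J
        )

    # (3) single-site structured effects, systematic sweep
    Sigma_s_inv = np.linalg.inv(state.Sigma_s)
    for j in range(J):
        m = len(spec.graph.neighbours[j])
        if m == 0:
            state.S[j] = 0.0
            continue
        prior_mean, _ = micar_conditional(state.S, j, spec.graph, state.Sigma_s)
        P = m * Sigma_s_inv + np.diag(Wd[j])
        b = m * (Sigma_s_inv @ prior_mean) + (Bd[j] - Wd[j] * state.V[j])
        state.S[j] = _draw_mvn(np.linalg.solve(P, b), P, rng)

    # (4) unstructured effects
    Sigma_v_inv = np.linalg.inv(state.Sigma_v)
    for j in range(J):
        P = Sigma_v_inv + np.diag(Wd[j])
        b = Bd[j] - Wd[j] * state.S[j]
        state.V[j] = _draw_mvn(np.linalg.solve(P, b), P, rng)

    # (5) identify
    recenter(state, spec)

    # (6) covariance hyperparameters
    prec_s = update_precision(
        state.S, spec.wishart_df, spec.wishart_scale, "structured", rng, icar=spec.icar
    )
    prec_v = update_precision(
        state.V, spec.wishart_df, spec.wishart_scale, "unstructured", rng
    )
    state.Sigma_s = np.linalg.inv(prec_s)
    state.Sigma_v = np.linalg.inv(prec_v)
    return state


# ---------------------------------------------------------------------------
# Adaptive random-walk Metropolis cross-check
# ---------------------------------------------------------------------------

def _log_posterior_blocks(state: ModelState, spec: ModelSpec) -> float:
    """Joint log posterior up to a constant (for the Metropolis sweep)."""
    lp = log_likelihood(state, spec)
    lp -= 0.5 * np.sum(state.beta**2) / spec.beta_prior_var
    # intrinsic CAR: -(1/2) tr(Sigma_s^-1 S'QS)
    Sigma_s_inv = np.linalg.inv(state.Sigma_s)
    lp -= 0.5 * float(np.trace(Sigma_s_inv @ state.S.T @ spec.icar.Q @ state.S))
    Sigma_v_inv = np.linalg.inv(state.Sigma_v)
    lp -= 0.5 * float(np.trace(Sigma_v_inv @ state.V.T @ state.V))
    return lp


def mcmc_step_metropolis(
    state: ModelState,
    spec: ModelSpec,
    rng: np.random.Generator,
    scales: dict,
    adapt: bool = False,
    target: float = 0.35,
) -> ModelState:
    """Component-wise adaptive RW Metropolis over the same full conditionals.

    Slow; exists to cross-check the Polya-Gamma Gibbs sampler on small
    instances.  Covariances still update by conjugate Wishart draws.
    """
    def maybe_adapt(key, accepted):
        if adapt:
            scales[key] *= np.exp(0.05 * ((1.0 if accepted else 0.0) - target))

    lp = _log_posterior_blocks(state, spec)
    # fixed effects, one scalar at a time
    for k in range(spec.K):
        for arr, idx, key in [(state.alpha, k, f"alpha_{k}")] + [
            (state.beta, (r, k), f"beta_{r}_{k}") for r in range(spec.p)
        ]:
            old = arr[idx]
            arr[idx] = old + scales.setdefault(key, 0.1) * rng.standard_normal()
            lp_new = _log_posterior_blocks(state, spec)
            if np.log(rng.random()) < lp_new - lp:
                lp = lp_new
                maybe_adapt(key, True)
            else:
                arr[idx] = old
                maybe_adapt(key, False)
    # district effect rows
    for name, arr in (("S", state.S), ("V", state.V)):
        for j in range(spec.J):
            if name == "S" and len(spec.graph.neighbours[j]) == 0:
                continue
            key = f"{name}_{j}"
            old = arr[j].copy()
            arr[j] = old + scales.setdefault(key, 0.1) * rng.standard_normal(spec.K)
            lp_new = _log_posterior_blocks(state, spec)
            if np.log(rng.random()) < lp_new - lp:
                lp = lp_new
                maybe_adapt(key, True)
            else:
                arr[j] = old
                maybe_adapt(key, False)
    recenter(state, spec)
    prec_s = update_precision(
        state.S, spec.wishart_df, spec.wishart_scale, "structured", rng, icar=spec.icar
    )
    prec_v = update_precision(
        state.V, spec.wishart_df, spec.wishart_scale, "unstructured", rng
    )
    state.Sigma_s = np.linalg.inv(prec_s)
    state.Sigma_v = np.linalg.inv(prec_v)
    return state


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

@dataclass
class McmcConfig:
    chains: int = 2
    iterations: int = 10_000
    burnin: int = 5_000
    thin: int = 5
    seed: int = 0
    sampler: str = "pg"  # "pg" | "metropolis"

    def __post_init__(self) -> None:
        if self.burnin >= self.iterations:
            raise ModelError("burnin must be smaller than iterations")
        if self.thin < 1:
            raise ModelError("thin must be >= 1")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, indexed [chain, draw, ...]."""

    alpha: np.ndarray     # C×T×K
    beta: np.ndarray      # C×T×p×K
    S: np.ndarray         # C×T×J×K
    V: np.ndarray         # C×T×J×K
    Sigma_s: np.ndarray   # C×T×K×K
    Sigma_v: np.ndarray   # C×T×K×K
    config: McmcConfig
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws with chain and iteration axes flattened."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    @property
    def converged(self) -> bool:
        return bool(self.rhat) and max(self.rhat.values()) < 1.1


def run_mcmc(spec: ModelSpec, config: McmcConfig) -> PosteriorSamples:
    """Run the sampler; returns retained draws plus split-R̂/ESS diagnostics."""
    from cvdmap.diagnostics import effective_sample_size, gelman_rubin

    C = config.chains
    T = (config.iterations - config.burnin) // config.thin
    store = {
        "alpha": np.empty((C, T, spec.K)),
        "beta": np.empty((C, T, spec.p, spec.K)),
        "S": np.empty((C, T, spec.J, spec.K)),
        "V": np.empty((C, T, spec.J, spec.K)),
        "Sigma_s": np.empty((C, T, spec.K, spec.K)),
        "Sigma_v": np.empty((C, T, spec.K, spec.K)),
    }
    for c in range(C):
        rng = np.random.default_rng([config.seed, c])
        state = initial_state(spec, jitter_rng=rng if C > 1 else None)
        scales: dict = {}
        t = 0
        for it in range(config.iterations):
            if config.sampler == "pg":
                state = mcmc_step(state, spec, rng)
            elif config.sampler == "metropolis":
                state = mcmc_step_metropolis(
                    state, spec, rng, scales, adapt=it < config.burnin
                )
            else:
                raise ModelError(f"unknown sampler {config.sampler!r}")
            if not np.isfinite(state.alpha).all():
                raise ModelError(
                    f"divergent state at chain {c}, iteration {it}: non-finite alpha"
                )
            if it >= config.burnin and (it - config.burnin) % config.thin == 0:
                if t < T:
                    for name in store:
                        store[name][c, t] = getattr(state, name)
                    t += 1
    samples = PosteriorSamples(config=config, **store)
    # monitor the fixed effects (the quantities reported as odds ratios)
    monitored: dict[str, np.ndarray] = {}
    for k in range(spec.K):
        dn = spec.disease_names[k]
        monitored[f"alpha[{dn}]"] = store["alpha"][:, :, k]
        for r in range(spec.p):
            nm = spec.design_info.names[r] if spec.design_info else f"x{r}"
            monitored[f"beta[{dn}:{nm}]"] = store["beta"][:, :, r, k]
    if C >= 2:
        samples.rhat = {k: gelman_rubin(v) for k, v in monitored.items()}
    samples.ess = {k: effective_sample_size(v) for k, v in monitored.items()}
    return samples


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

def posterior_or_table(samples: PosteriorSamples, spec: ModelSpec) -> pd.DataFrame:
    """Posterior-median odds ratios with equal-tailed 95% credible intervals.

    One row per disease × design column; reference levels of categorical
    covariates are included as literal 1.00 rows.
    """
    beta = samples.pooled("beta")  # draws×p×K
    if beta.shape[1] != spec.p:
        raise ModelError("sampled beta does not match the design")
    rows = []
    for k, disease in enumerate(spec.disease_names):
        if spec.design_info is not None:
            for cov, levels in spec.design_info.terms.items():
                if len(levels) == 1:  # numeric column
                    r = spec.design_info.names.index(cov)
                    ors = np.exp(beta[:, r, k])
                    rows.append(_or_row(disease, cov, cov, ors))
                    continue
                rows.append(
                    {
                        "disease": disease, "covariate": cov,
                        "level": levels[0], "or_median": 1.0,
                        "or_low": 1.0, "or_high": 1.0, "reference": True,
                    }
                )
                for lev in levels[1:]:
                    r = spec.design_info.names.index(f"{cov}={lev}")
                    ors = np.exp(beta[:, r, k])
                    rows.append(_or_row(disease, cov, lev, ors))
        else:
            for r in range(spec.p):
                ors = np.exp(beta[:, r, k])
                rows.append(_or_row(disease, f"x{r}", f"x{r}", ors))
    return pd.DataFrame(rows)


def _or_row(disease: str, covariate: str, level: str, ors: np.ndarray) -> dict:
    lo, med, hi = np.percentile(ors, [2.5, 50.0, 97.5])
    return {
        "disease": disease, "covariate": covariate, "level": level,
        "or_median": float(med), "or_low": float(lo), "or_high": float(hi),
        "reference": False,
    }


def spatial_odds(samples: PosteriorSamples, spec: ModelSpec) -> pd.DataFrame:
    """Posterior summaries of exp(U_jk) = exp(S_jk + V_jk) per district/disease.

    Reports the median, 95% credible interval and the exceedance probability
    P(exp(U) > 1) — the probability of excess disease odds in the district.
    """
    U = samples.pooled("S") + samples.pooled("V")  # draws×J×K
    rows = []
    for k, disease in enumerate(spec.disease_names):
        for j in range(spec.J):
            draws = np.exp(U[:, j, k])
            lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
            rows.append(
                {
                    "district": j + 1,
                    "code": spec.graph.codes[j],
                    "disease": disease,
                    "odds_median": float(med),
                    "odds_low": float(lo),
                    "odds_high": float(hi),
                    "exceedance_prob": float((draws > 1.0).mean()),
                }
            )
    return pd.DataFrame(rows)
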