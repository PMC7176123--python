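"""Synthetic survey generator with known ground truth.

Emulates the structure of a national health-examination survey mapped to
health districts: J districts with heavily skewed per-district sample
sizes, categorical covariates drawn at the survey's marginal frequencies,
and K correlated binary disease outcomes generated from the same
multivariate ICAR convolution logistic model the package fits — the
generator and the sampler share one linear predictor and one effect
decomposition, so parameter-recovery tests are exact duals.

Raw clinical fields are back-filled from the generated binary outcomes
(one sufficient positive field per positive outcome, all-negative fields
otherwise) purely so the derivation rules round-trip; this is a
round-trip device, not a physiologic simulator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from cvdmap import model as mdl
from cvdmap import outcomes as oc
from cvdmap import sampi as sp
from cvdmap.spatial_graph import AdjacencyGraph, lattice_graph

#: Marginal category frequencies of the emulated survey (weighted shares).
COVARIATE_FREQUENCIES: dict[str, dict[str, float]] = {
    "sex": {"female": 0.583, "male": 0.417},
    "age_group": {
        "15-24": 0.177, "25-34": 0.150, "35-44": 0.149,
        "45-54": 0.196, "55-64": 0.171, "65+": 0.156,
    },
    "education": {
        "no_school": 0.103, "primary": 0.236, "secondary": 0.357,
        "matric": 0.205, "higher": 0.099,
    },
    "locality": {
        "urban_formal": 0.550, "urban_informal": 0.085,
        "rural_tribal": 0.286, "rural_formal": 0.079,
    },
    "race": {
        "african": 0.794, "white": 0.065, "coloured": 0.110,
        "indian_asian": 0.029, "other": 0.002,
    },
    "bmi_class": {"underweight": 0.051, "normal": 0.357, "overweight": 0.592},
    "smoking": {"never": 0.775, "ex_smoker": 0.189, "current": 0.036},
    "alcohol": {"never": 0.756, "current": 0.244},
    "diabetes": {"no": 0.850, "yes": 0.150},
    "wealth_quintile": {"Q1": 0.210, "Q2": 0.191, "Q3": 0.205, "Q4": 0.206, "Q5": 0.188},
}

#: Marginal prevalence targets for the four conditions.
PREVALENCE_TARGETS: dict[str, float] = {
    "hbp": 0.286, "ihd": 0.054, "stroke": 0.018, "dyslip": 0.531,
}

#: District sample-size law: lognormal calibrated to median 277 and mean 346,
#: truncated to the observed range [22, 1625].
SIZE_LOGNORMAL_MU = float(np.log(277.0))
SIZE_LOGNORMAL_SIGMA = float(np.sqrt(2.0 * np.log(346.0 / 277.0)))
SIZE_RANGE = (22, 1625)


def _default_sigma(K: int, sd: float, rho: float) -> np.ndarray:
    """Exchangeable-correlation covariance with common sd."""
    R = np.full((K, K), rho) + (1 - rho) * np.eye(K)
    return (sd**2) * R


def _default_beta(design: mdl.DesignInfo, K: int) -> np.ndarray:
    """Moderate true effects: protective male, rising age gradient, adiposity."""
    p = len(design.names)
    beta = np.zeros((p, K))
    for r, name in enumerate(design.names):
        if name == "sex=male":
            beta[r, :] = np.log(0.8)
        elif name.startswith("age_group="):
            grade = ["25-34", "35-44", "45-54", "55-64", "65+"].index(name.split("=")[1]) + 1
            for k in range(K):
                top = [3.2, 1.6, 1.6, 0.5][k % 4]
                beta[r, k] = top * grade / 5.0
        elif name == "bmi_class=overweight":
            beta[r, :] = np.log(1.7)
        elif name == "bmi_class=underweight":
            beta[r, :] = np.log(0.8)
        elif name == "diabetes=yes":
            beta[r, :] = np.log(2.0)
        elif name.startswith("sampi_quintile="):
            # deprivation gradient relative to SAMPI1
            grade = int(name.split("SAMPI")[-1]) - 1
            beta[r, :] = 0.08 * grade
    return beta


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic survey draw."""

    graph: AdjacencyGraph | None = None          # default: built per J below
    J: int = 52
    K: int = 4
    n_target: int | None = None                  # scale district sizes to ~n
    model_covariates: list[str] = dfield(
        default_factory=lambda: ["sex", "age_group", "bmi_class", "diabetes"]
    )
    include_sampi: bool = False                  # add the district quintile covariate
    prevalence_targets: dict[str, float] = dfield(
        default_factory=lambda: dict(PREVALENCE_TARGETS)
    )
    true_beta: np.ndarray | None = None          # p×K; default via _default_beta
    Sigma_s: np.ndarray | None = None
    Sigma_v: np.ndarray | None = None
    sampi_range: tuple[float, float] = (0.008, 0.1)
    sampi_spatial: bool = False
    biomarker_consent_rate: float = 0.66
    seed: int = 0

    def __post_init__(self) -> None:
        if self.graph is None:
            side = int(np.ceil(np.sqrt(self.J)))
            rows = int(np.ceil(self.J / side))
            g = lattice_graph(rows, side)
            if g.n_areas != self.J:
                # trim a lattice to exactly J areas by keeping the first J
                keep = list(range(self.J))
                nbrs = [[l for l in g.neighbours[j] if l < self.J] for j in keep]
                g = AdjacencyGraph(n_areas=self.J, neighbours=nbrs,
                                   codes=g.codes[: self.J])
            self.graph = g
        self.J = self.graph.n_areas
        if self.Sigma_s is None:
            self.Sigma_s = _default_sigma(self.K, sd=0.35, rho=0.4)
        if self.Sigma_v is None:
            self.Sigma_v = _default_sigma(self.K, sd=0.20, rho=0.4)
        for name, Sig in (("Sigma_s", self.Sigma_s), ("Sigma_v", self.Sigma_v)):
            if np.linalg.eigvalsh(Sig).min() <= 0:
                raise ValueError(f"{name} must be symmetric positive definite")
        for cond, pi in list(self.prevalence_targets.items())[: self.K]:
            if not 0 < pi < 1:
                raise ValueError(f"infeasible prevalence target {cond}={pi}")

    @property
    def conditions(self) -> list[str]:
        return list(self.prevalence_targets)[: self.K]


@dataclass
class GroundTruth:
    """Everything the generator actually used, for recovery tests."""

    alpha: np.ndarray
    beta: np.ndarray
    beta_names: list[str]
    S: np.ndarray
    V: np.ndarray
    Sigma_s: np.ndarray
    Sigma_v: np.ndarray
    conditions: list[str]
    Y: pd.DataFrame
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "beta_names": self.beta_names,
            "S": self.S.tolist(),
            "V": self.V.tolist(),
            "Sigma_s": self.Sigma_s.tolist(),
            "Sigma_v": self.Sigma_v.tolist(),
            "conditions": self.conditions,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))


def sample_micar_effects(
    graph: AdjacencyGraph, Sigma_s: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw a J×K matrix from the intrinsic multivariate CAR prior.

    The intrinsic joint is improper, so the draw is taken on the identified
    subspace: eigendecompose Q, drop null eigenvectors (one per connected
    component, including islands), and give the coefficient vector of
    eigenvector e_i covariance Sigma_s / lambda_i.  Every column then sums
    to zero within each component and islands are exactly 0.
    """
    if np.linalg.eigvalsh(Sigma_s).min() <= 0:
        raise ValueError("Sigma_s must be symmetric positive definite")
    from cvdmap.spatial_graph import icar_structure

    K = Sigma_s.shape[0]
    ic = icar_structure(graph)
    lam, E = np.linalg.eigh(ic.Q)
    keep = lam > 1e-10
    L = np.linalg.cholesky(Sigma_s)
    Z = rng.standard_normal((int(keep.sum()), K))
    coeffs = (Z @ L.T) / np.sqrt(lam[keep])[:, None]
    return E[:, keep] @ coeffs


def _district_sizes(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = SIZE_RANGE
    sizes = np.empty(cfg.J, dtype=int)
    for j in range(cfg.J):
        while True:
            s = rng.lognormal(SIZE_LOGNORMAL_MU, SIZE_LOGNORMAL_SIGMA)
            if lo <= s <= hi:
                sizes[j] = int(round(s))
                break
    if cfg.n_target is not None:
        scale = cfg.n_target / sizes.sum()
        sizes = np.maximum(2, np.round(sizes * scale).astype(int))
    return sizes


def make_district_sampi(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-district SAMPI scores (within the configured range) and quintiles.

    With *sampi_spatial*, scores are a monotone map of a univariate ICAR
    draw, preserving its spatial autocorrelation; otherwise iid uniform.
    """
    lo, hi = cfg.sampi_range
    if cfg.sampi_spatial:
        z = sample_micar_effects(cfg.graph, np.array([[1.0]]), rng)[:, 0]
        u = (np.argsort(np.argsort(z)) + 0.5) / cfg.J
        scores = lo + (hi - lo) * u
    else:
        scores = rng.uniform(lo, hi, size=cfg.J)
    return pd.DataFrame(
        {
            "district": np.arange(1, cfg.J + 1),
            "code": cfg.graph.codes,
            "sampi": scores,
            "quintile": sp.sampi_quintiles(scores),
        }
    )


def _draw_covariates(
    cfg: GeneratorConfig, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    cols = {}
    for name, freqs in COVARIATE_FREQUENCIES.items():
        levels = list(freqs)
        p = np.array(list(freqs.values()))
        cols[name] = rng.choice(levels, size=n, p=p / p.sum())
    return pd.DataFrame(cols)


def _calibrate_alpha(offset: np.ndarray, target: float) -> float:
    """Solve mean(logistic(alpha + offset)) = target for alpha."""

    def gap(a: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(a + offset))))) - target

    return float(optimize.brentq(gap, -30.0, 30.0))


def _backfill_clinical(
    frame: pd.DataFrame, Y: pd.DataFrame, consent: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill raw fields so derive_outcomes reproduces Y exactly.

    Biomarker consenters receive measurement-based positives when possible;
    non-consenters carry the outcome through self-report flags alone.
    """
    n = len(frame)
    f = frame
    # defaults: all-negative observed evidence
    f["sbp"] = np.where(consent, 120.0, np.nan)
    f["dbp"] = np.where(consent, 70.0, np.nan)
    f["self_hbp"] = 0.0
    f["hbp_medication"] = 0.0
    f["tc"] = np.where(consent, 4.5, np.nan)
    f["tg"] = np.where(consent, 1.0, np.nan)
    f["ldl"] = np.where(consent, 2.5, np.nan)
    f["hdl"] = np.where(consent, 1.6, np.nan)
    f["lipid_drugs"] = 0.0
    f["dyslip_diagnosis"] = 0.0
    f["self_ihd"] = np.asarray(Y["ihd"], dtype=float) if "ihd" in Y else 0.0
    f["self_stroke"] = np.asarray(Y["stroke"], dtype=float) if "stroke" in Y else 0.0

    if "hbp" in Y:
        pos = Y["hbp"].to_numpy() == 1
        route = rng.integers(0, 3, size=n)  # 0 sbp, 1 dbp, 2 self-report
        f.loc[pos & consent & (route == 0), "sbp"] = 152.0
        f.loc[pos & consent & (route == 1), "dbp"] = 96.0
        f.loc[pos & (~consent | (route == 2)), "self_hbp"] = 1.0
    if "dyslip" in Y:
        pos = Y["dyslip"].to_numpy() == 1
        route = rng.integers(0, 4, size=n)  # tc, tg, ldl, diagnosis
        f.loc[pos & consent & (route == 0), "tc"] = 6.8
        f.loc[pos & consent & (route == 1), "tg"] = 2.1
        f.loc[pos & consent & (route == 2), "ldl"] = 4.6
        f.loc[pos & (~consent | (route == 3)), "dyslip_diagnosis"] = 1.0

    # diabetes covariate round-trips through its own rule
    diab = (f["diabetes"] == "yes").to_numpy()
    f["hba1c"] = np.where(consent, np.where(diab, 7.2, 5.4), np.nan)
    f["diabetes_history"] = np.where(diab, 1.0, 0.0)
    f["diabetes_treatment"] = 0.0

    # BMI consistent with the drawn class
    bmi_map = {"underweight": 17.5, "normal": 22.0, "overweight": 29.0}
    f["bmi"] = f["bmi_class"].map(bmi_map).astype(float)
    return f


def generate_population(
    cfg: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one complete synthetic survey.

    Returns (participant records, outcome matrix, ground truth).  The
    records table carries district, covariates, both weight columns and
    back-filled raw fields; ``derive_outcomes(records)`` reproduces the
    returned outcome matrix exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    sizes = _district_sizes(cfg, rng)
    n = int(sizes.sum())
    district = np.repeat(np.arange(1, cfg.J + 1), sizes)

    frame = _draw_covariates(cfg, n, rng)
    frame.insert(0, "district", district)

    covs = list(cfg.model_covariates)
    sampi_table = None
    if cfg.include_sampi:
        sampi_table = make_district_sampi(cfg, rng)
        frame["sampi_quintile"] = frame["district"].map(
            sampi_table.set_index("district")["quintile"]
        )
        covs.append("sampi_quintile")

    references = {
        "sex": "female", "age_group": "15-24", "bmi_class": "normal",
        "diabetes": "no", "education": "no_school", "race": "african",
        "locality": "urban_formal", "smoking": "never", "alcohol": "never",
        "wealth_quintile": "Q1", "sampi_quintile": "SAMPI1",
    }
    X, design = mdl.build_design(frame, covs, references=references)
    beta = cfg.true_beta if cfg.true_beta is not None else _default_beta(design, cfg.K)
    if beta.shape != (X.shape[1], cfg.K):
        raise ValueError(
            f"true_beta has shape {beta.shape}, design needs {(X.shape[1], cfg.K)}"
        )

    S = sample_micar_effects(cfg.graph, cfg.Sigma_s, rng)
    Ls = np.linalg.cholesky(cfg.Sigma_v)
    V = rng.standard_normal((cfg.J, cfg.K)) @ Ls.T

    offset = X @ beta + (S + V)[district - 1]
    alpha = np.array(
        [
            _calibrate_alpha(offset[:, k], cfg.prevalence_targets[cond])
            for k, cond in enumerate(cfg.conditions)
        ]
    )
    eta = alpha[None, :] + offset
    pi = 1.0 / (1.0 + np.exp(-eta))
    Ymat = (rng.random((n, cfg.K)) < pi).astype(float)
    Y = pd.DataFrame(Ymat, columns=cfg.conditions)

    # survey weights: interview weight lognormal, biomarker weight inflated
    w = rng.lognormal(0.0, 0.35, size=n)
    frame["interview_weight"] = w / w.mean()
    consent = rng.random(n) < cfg.biomarker_consent_rate
    frame["biomarker_weight"] = np.where(
        consent, frame["interview_weight"] / cfg.biomarker_consent_rate, np.nan
    )

    frame = _backfill_clinical(frame, Y, consent, rng)
    truth = GroundTruth(
        alpha=alpha, beta=beta, beta_names=design.names, S=S, V=V,
        Sigma_s=cfg.Sigma_s, Sigma_v=cfg.Sigma_v,
        conditions=cfg.conditions, Y=Y, seed=cfg.seed,
    )
    return frame, Y, truth
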