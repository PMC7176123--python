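"""Convergence diagnostics, map exports, and the end-to-end pipeline driver."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class DiagnosticsError(ValueError):
    pass


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor R̂ for one parameter.

    *chains* is (n_chains, n_draws); each chain is halved before the
    classic between/within variance comparison, so slow drift within a
    single chain also inflates the statistic.  Degenerate (zero-variance)
    chains return exactly 1.0.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise DiagnosticsError("split R-hat needs >= 2 chains of equal length")
    n = chains.shape[1] // 2
    if n < 2:
        raise DiagnosticsError("chains too short to split")
    halves = np.vstack([chains[:, :n], chains[:, n: 2 * n]])
    within = halves.var(axis=1, ddof=1).mean()
    if within == 0.0:
        return 1.0
    between = n * halves.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def effective_sample_size(chains: np.ndarray, max_lag: int | None = None) -> float:
    """Multi-chain ESS via Geyer initial-monotone-sequence autocorrelation sums."""
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    C, N = chains.shape
    if N < 4:
        return float(C * N)
    max_lag = max_lag or N - 2
    centred = chains - chains.mean(axis=1, keepdims=True)
    var = centred.var(axis=1, ddof=0).mean()
    if var == 0:
        return float(C * N)
    # mean autocorrelation across chains by FFT
    nfft = int(2 ** np.ceil(np.log2(2 * N)))
    f = np.fft.rfft(centred, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :N].real / N
    rho = (acov / acov[:, :1]).mean(axis=0)
    # Geyer: sum consecutive pairs while positive and monotone
    tau = 1.0
    prev = np.inf
    for t in range(1, max_lag, 2):
        pair = rho[t] + rho[t + 1] if t + 1 < N else rho[t]
        if pair < 0:
            break
        pair = min(pair, prev)
        prev = pair
        tau += 2.0 * pair
    return float(C * N / tau)


# ---------------------------------------------------------------------------
# Map exports
# ---------------------------------------------------------------------------

def export_map_layer(
    district_summaries: pd.DataFrame,
    geojson_in: str | Path,
    geojson_out: str | Path,
    code_column: str = "code",
    id_property: str = "id",
) -> dict:
    """Annotate GeoJSON district polygons with summary attributes.

    Every feature must join 1:1 to a row of *district_summaries* on
    *code_column*; unmatched codes on either side are an error.  All
    numeric columns of the summary become feature properties.
    """
    fc = json.loads(Path(geojson_in).read_text())
    table = district_summaries.set_index(district_summaries[code_column].astype(str))
    feature_codes = []
    for k, feat in enumerate(fc.get("features", [])):
        props = feat.get("properties") or {}
        code = props.get(id_property, feat.get("id"))
        if code is None:
            raise DiagnosticsError(f"feature {k} lacks an {id_property!r} property")
        feature_codes.append(str(code))
    missing = sorted(set(feature_codes) - set(table.index))
    extra = sorted(set(table.index) - set(feature_codes))
    if missing or extra:
        raise DiagnosticsError(
            f"district join failure: codes only in geojson {missing}; "
            f"codes only in summary table {extra}"
        )
    value_cols = [
        c for c in table.columns
        if c != code_column and pd.api.types.is_numeric_dtype(table[c])
    ]
    for feat, code in zip(fc["features"], feature_codes):
        row = table.loc[code]
        feat.setdefault("properties", {})
        for c in value_cols:
            feat["properties"][c] = float(row[c])
    Path(geojson_out).write_text(json.dumps(fc))
    return fc


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Everything needed to reproduce a pipeline run bit-identically."""

    config: dict
    seed: int
    versions: dict = field(default_factory=dict)
    rhat: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)
    converged: bool | None = None
    stages: list[dict] = field(default_factory=list)
    failed_stage: str | None = None

    def record(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, **info})

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "versions": self.versions,
            "rhat": self.rhat,
            "ess": self.ess,
            "converged": self.converged,
            "stages": self.stages,
            "failed_stage": self.failed_stage,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def _versions() -> dict:
    import numpy
    import pandas
    import scipy

    import cvdmap

    return {
        "cvdmap": cvdmap.__version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }


def run_pipeline(config: dict, out_dir: str | Path) -> RunManifest:
    """simulate → derive → estimate → fit (A, then B with SAMPI) → summarise.

    *config* keys (all optional, with small-demo defaults): rows/cols or
    adjacency path, n_target, K, chains, iterations, burnin, thin, seed,
    model ("A", "B", or "both").
    """
    from cvdmap import generator as gen
    from cvdmap import model as mdl
    from cvdmap import outcomes, survey
    from cvdmap.spatial_graph import lattice_graph, read_adjacency, write_winbugs

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(config=dict(config), seed=seed, versions=_versions())
    try:
        # -- simulate -----------------------------------------------------
        if "adjacency" in config:
            graph = read_adjacency(config["adjacency"], config.get("dialect", "winbugs_adj"))
        else:
            graph = lattice_graph(int(config.get("rows", 4)), int(config.get("cols", 5)))
        gcfg = gen.GeneratorConfig(
            graph=graph,
            K=int(config.get("K", 4)),
            n_target=config.get("n_target"),
            seed=seed,
        )
        records, Y, truth = gen.generate_population(gcfg)
        sampi_table = gen.make_district_sampi(gcfg, np.random.default_rng([seed, 91]))
        records.to_csv(out / "participants.csv", index=False)
        sampi_table.to_csv(out / "district_sampi.csv", index=False)
        write_winbugs(graph, out / "adjacency.txt")
        truth.to_json(out / "ground_truth.json")
        manifest.record("simulate", n=len(records), J=graph.n_areas)

        # -- derive (round-trips the generator's outcomes) ----------------
        Y, report = outcomes.derive_outcomes(records)
        Y.to_csv(out / "outcomes.csv", index=False)
        (out / "derivation_report.json").write_text(json.dumps(report.to_dict()))
        manifest.record("derive", **report.missing_counts)

        # -- estimate -----------------------------------------------------
        prev_rows = []
        for cond in outcomes.OUTCOME_NAMES[: gcfg.K]:
            est = survey.weighted_prevalence(Y[cond], records["interview_weight"])
            prev_rows.append(
                {"condition": cond, "p_hat": est.p_hat,
                 "ci_low": est.ci_low, "ci_high": est.ci_high, "n": est.n}
            )
        pd.DataFrame(prev_rows).to_csv(out / "prevalence.csv", index=False)
        manifest.record("estimate", conditions=len(prev_rows))

        # -- fit ----------------------------------------------------------
        model_choice = str(config.get("model", "both"))
        covs = list(config.get("covariates", ["sex", "age_group"]))
        mcfg = mdl.McmcConfig(
            chains=int(config.get("chains", 2)),
            iterations=int(config.get("iterations", 2000)),
            burnin=int(config.get("burnin", 1000)),
            thin=int(config.get("thin", 2)),
            seed=seed,
        )
        frame = records.copy()
        quint = sampi_table.set_index("district")["quintile"]
        frame["sampi_quintile"] = frame["district"].map(quint)
        fits = {}
        for label in ("A", "B"):
            if model_choice not in (label, "both"):
                continue
            use = covs + (["sampi_quintile"] if label == "B" else [])
            X, info = mdl.build_design(frame, use)
            spec = mdl.ModelSpec(
                Y=Y[outcomes.OUTCOME_NAMES[: gcfg.K]].to_numpy(),
                X=X,
                area=frame["district"].to_numpy() - 1,
                graph=graph,
                disease_names=outcomes.OUTCOME_NAMES[: gcfg.K],
                design_info=info,
            )
            samples = mdl.run_mcmc(spec, mcfg)
            ortab = mdl.posterior_or_table(samples, spec)
            odds = mdl.spatial_odds(samples, spec)
            ortab.to_csv(out / f"or_table_model_{label}.csv", index=False)
            odds.to_csv(out / f"spatial_odds_model_{label}.csv", index=False)
            fits[label] = samples
            manifest.record(
                f"fit_{label}", covariates=use,
                max_rhat=max(samples.rhat.values()) if samples.rhat else None,
            )
        last = fits[max(fits)]
        manifest.rhat = {k: round(v, 4) for k, v in last.rhat.items()}
        manifest.ess = {k: round(v, 1) for k, v in last.ess.items()}
        manifest.converged = last.converged
    except Exception as exc:  # stage failure recorded, then re-raised
        manifest.failed_stage = manifest.stages[-1]["stage"] if manifest.stages else "simulate"
        manifest.record("error", message=str(exc))
        manifest.to_json(out / "manifest.json")
        raise
    manifest.to_json(out / "manifest.json")
    return manifest
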