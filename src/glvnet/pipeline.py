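"""End-to-end orchestration: standardize -> smooth -> constrain -> fit -> ensemble.

The pipeline chains the library stages under one seeded configuration and
writes every stage artifact to an output directory, so a run is reproducible
from its config alone.  All stochastic behavior flows from the config seeds;
there is no hidden global randomness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ensemble import Ensemble, build_ensemble, forecast
from .foodweb import TrophicPrior, build_summary_web, classify_trophic_levels, derive_sign_constraints
from .params import GLVParameters, SignConstraintSet
from .preprocessing import smooth_series, standardize_cpue
from .regression import FitResult, PenaltyConfig, fit_lgr, select_penalty_loocv
from .series import (
    AbundanceSeries, ExogenousSeries, GearCatchTable,
    read_abundance_table, write_abundance_table,
)
from .uncertainty import ensemble_confidence, fit_susceptibility, parameter_cv

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything one inference run needs, loadable from YAML/JSON."""

    abundance_path: str
    prior_path: str
    output_dir: str
    dialect: str = "wide"
    site_label: str | None = None
    exogenous_species: str | None = None
    smooth: bool = True
    penalty_grid: tuple[tuple[float, float], ...] = ((0.0, 0.0),)
    ensemble_n: int = 100
    ensemble_sigma: float = 0.2
    ensemble_cutoff: float = 0.25
    forecast_horizon: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        object.__setattr__(
            self, "penalty_grid",
            tuple((float(a), float(b)) for a, b in self.penalty_grid),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        data["penalty_grid"] = tuple(tuple(p) for p in data.get("penalty_grid", [(0.0, 0.0)]))
        cfg = cls(**data)
        for key in ("abundance_path", "prior_path"):
            p = Path(getattr(cfg, key))
            if not p.exists():
                raise FileNotFoundError(f"{key}: {p} does not exist")
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full inference chain and persist every stage artifact.

    Returns a bundle dict with the fitted model, ensemble summaries and (when
    configured) susceptibility scores and forecasts.  Stage failures raise
    with the stage name; artifacts written before the failure remain on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        prior = TrophicPrior.from_config(config.prior_path)
        data = read_abundance_table(
            config.abundance_path, dialect=config.dialect, site_label=config.site_label
        )
        stage = "standardize"
        if isinstance(data, GearCatchTable):
            series = standardize_cpue(data)
        else:
            series = data
        write_abundance_table(series, out / "standardized.tsv")

        stage = "smooth"
        if config.smooth:
            series = smooth_series(series)
        write_abundance_table(series, out / "smoothed.tsv")

        exo = None
        if config.exogenous_species is not None:
            idx = series.species_ids.index(config.exogenous_species)
            exo = ExogenousSeries(times=series.times, values=series.values[idx])
            keep = [s for s in series.species_ids if s != config.exogenous_species]
            mask = np.array([s in keep for s in series.species_ids])
            series = AbundanceSeries(
                species_ids=tuple(np.array(series.species_ids)[mask]),
                times=series.times, values=series.values[mask],
                site_label=series.site_label,
            )

        stage = "constraints"
        assignment = classify_trophic_levels(prior)
        web = build_summary_web(assignment, prior)
        constraints = derive_sign_constraints(web, exogenous_id=config.exogenous_species)
        # align the constraint ordering to the data ordering
        order = [constraints.species_ids.index(s) for s in series.species_ids]
        constraints = SignConstraintSet(
            alpha_sign=constraints.alpha_sign[order],
            beta_sign=constraints.beta_sign[np.ix_(order, order)],
            epsilon_sign=(constraints.epsilon_sign[order]
                          if constraints.epsilon_sign is not None else None),
            species_ids=series.species_ids,
        )
        constraints.to_symbol_table().to_csv(out / "sign_constraints.tsv", sep="\t")

        stage = "penalty-selection"
        grid = [PenaltyConfig(a, b) for a, b in config.penalty_grid]
        if len(grid) > 1:
            penalty = select_penalty_loocv(series, constraints, grid)
        else:
            penalty = grid[0]

        stage = "lgr-fit"
        result: FitResult = fit_lgr(series, constraints=constraints, penalty=penalty)
        result.params.to_json(out / "fit.json")
        _write_json(out / "fit_stats.json", {
            "adjusted_r2": result.adjusted_r2, "smape": result.smape,
            "converged": result.converged,
            "lambda_alpha": penalty.lambda_alpha, "lambda_beta": penalty.lambda_beta,
        })

        stage = "ensemble"
        ens: Ensemble = build_ensemble(
            series, result, n=config.ensemble_n, sigma=config.ensemble_sigma,
            cutoff=config.ensemble_cutoff, constraints=constraints,
            penalty=penalty, seed=config.seed,
        )
        np.savetxt(out / "smape_sample.tsv", ens.all_smape)

        stage = "confidence"
        report = ensemble_confidence(ens, series, constraints=constraints)
        report.to_frame().to_csv(out / "confidence.tsv", sep="\t", index=False)
        alpha_cv, beta_cv = (parameter_cv(ens) if len(ens) >= 2 else (None, None))

        bundle = {
            "series": series, "constraints": constraints, "penalty": penalty,
            "fit": result, "ensemble": ens, "confidence": report,
            "alpha_cv": alpha_cv, "beta_cv": beta_cv,
        }

        if exo is not None:
            stage = "susceptibility"
            fits = [
                fit_susceptibility(m, series, exo, constraints=constraints)
                for m in ens.members
            ]
            mean_eps = np.mean([f.epsilon for f in fits], axis=0)
            mean_score = np.mean([f.score for f in fits], axis=0)
            _write_json(out / "susceptibility.json", {
                "species": list(series.species_ids),
                "mean_epsilon": mean_eps.tolist(),
                "mean_confidence": mean_score.tolist(),
            })
            bundle["susceptibility"] = fits

        if config.forecast_horizon > 0:
            stage = "forecast"
            dt = float(np.median(np.diff(series.times)))
            horizon = np.arange(
                series.times[-1], series.times[-1] + config.forecast_horizon + dt / 2, dt
            )
            fc = forecast(ens, series.values[:, -1], horizon)
            frame = fc.mean.T
            np.savetxt(out / "forecast_mean.tsv", frame)
            np.savetxt(out / "forecast_sd.tsv", fc.sd.T)
            bundle["forecast"] = fc
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2))
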