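"""Replicate simulation studies and field-data-style preprocessing.

``run_replicate_study`` regenerates a scenario's pedigree, simulates
phenotype replicates, runs the selected estimation engines on each
replicate and aggregates: original-scale (co)variance estimates and their
estimation errors (estimate - truth), implied genetic/residual correlations
and heritabilities with empirical 95% intervals across replicates, and
BLUP breeding-value accuracies.  Everything is bit-reproducible given
(scenario, engine set, base seed): replicate r uses seed base_seed + r.

``standardize_and_rescale`` z-scores each trait and returns the rule that
maps (co)variance estimates back to the original scale — the usual device
when traits have wildly different phenotypic variances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .blup import ebv_accuracy, solve_mme
from .cholparam import TraitCovariance
from .exceptions import DegenerateInputError, MultitraitError
from .infer import FitResult, fit_laplace, fit_mcmc, fit_reml, scalar_names
from .model import MultiTraitData
from .relmat import build_a_matrix
from .simulate import Scenario, simulate_traits

__all__ = [
    "StudyResult",
    "run_replicate_study",
    "standardize_and_rescale",
    "RescalingRule",
    "plot_error_boxplots",
]

logger = logging.getLogger("multitrait.study")

#: per-engine keyword defaults used by the study driver
DEFAULT_ENGINE_OPTIONS: dict[str, dict] = {
    "reml": {"n_restarts": 1},
    "laplace": {"n_samples": 2000, "n_restarts": 0},
    "mcmc": {"n_iter": 50_000, "n_burnin": 10_000},
}


@dataclass
class StudyResult:
    """Aggregated tables of a replicate study."""

    scenario: Scenario
    engines: tuple[str, ...]
    estimates: pd.DataFrame  # long: replicate, engine, parameter, true, estimate, error
    accuracies: pd.DataFrame  # replicate, engine, per-trait and mean accuracy
    truth: dict[str, float]
    failures: list[dict] = field(default_factory=list)

    def summary_table(self, parameters: Sequence[str]) -> pd.DataFrame:
        """Replicate mean and empirical 95% interval (2.5/97.5 percentiles)
        of the per-replicate point estimates, per engine."""
        sub = self.estimates[self.estimates["parameter"].isin(parameters)]
        rows = []
        for (param, engine), grp in sub.groupby(["parameter", "engine"], sort=False):
            est = grp["estimate"].to_numpy()
            rows.append(
                {
                    "parameter": param,
                    "engine": engine,
                    "mean": est.mean(),
                    "lower": np.percentile(est, 2.5),
                    "upper": np.percentile(est, 97.5),
                    "true": self.truth[param],
                    "n_replicates": est.size,
                }
            )
        return pd.DataFrame(rows)

    def correlation_table(self) -> pd.DataFrame:
        params = [p for p in self.truth if p.startswith(("r_a_", "r_e_"))]
        return self.summary_table(params)

    def heritability_table(self) -> pd.DataFrame:
        params = [p for p in self.truth if p.startswith("h2_")]
        return self.summary_table(params)

    def accuracy_summary(self) -> pd.DataFrame:
        """Mean EBV accuracy per engine (per trait and trait-averaged)."""
        return self.accuracies.drop(columns="replicate").groupby("engine").mean()

    def mean_errors(self) -> pd.DataFrame:
        """Replicate-mean estimation error and its empirical standard error."""
        grp = self.estimates.groupby(["parameter", "engine"], sort=False)["error"]
        out = grp.agg(["mean", "std", "count"]).reset_index()
        out["se"] = out["std"] / np.sqrt(out["count"])
        return out

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.estimates.to_csv(directory / "estimates.csv", index=False)
        self.accuracies.to_csv(directory / "accuracies.csv", index=False)
        self.correlation_table().to_csv(directory / "correlations.csv", index=False)
        self.heritability_table().to_csv(directory / "heritabilities.csv", index=False)
        self.mean_errors().to_csv(directory / "estimation_errors.csv", index=False)


def _true_scalars(scenario: Scenario) -> dict[str, float]:
    from .infer import compose_samples, _scalar_arrays
    from .cholparam import decompose_cov
    from .model import HyperParams

    theta = HyperParams(decompose_cov(scenario.g0), decompose_cov(scenario.r0))
    g0s, r0s = compose_samples(theta.to_vector()[None, :], scenario.g0.n_traits)
    return {k: float(v[0]) for k, v in _scalar_arrays(g0s, r0s).items()}


_ENGINE_SEED_OFFSET = {"laplace": 1_000_003, "mcmc": 2_000_003}


def run_replicate_study(
    scenario: Scenario,
    engines: Iterable[str] = ("reml", "laplace", "mcmc"),
    n_replicates: int | None = None,
    base_seed: int | None = None,
    engine_options: dict[str, dict] | None = None,
    compute_blup: bool = True,
) -> StudyResult:
    """Run the replicate estimation study for one scenario.

    Engine failures on individual replicates are recorded and skipped; the
    study continues and reports the failure count.
    """
    engines = tuple(engines)
    unknown = set(engines) - {"reml", "laplace", "mcmc"}
    if unknown:
        raise MultitraitError(f"unknown engines: {sorted(unknown)}")
    n_replicates = n_replicates if n_replicates is not None else scenario.n_replicates
    base_seed = base_seed if base_seed is not None else scenario.base_seed
    options = {
        name: {**DEFAULT_ENGINE_OPTIONS[name], **(engine_options or {}).get(name, {})}
        for name in engines
    }
    pedigree = scenario.pedigree()
    A = build_a_matrix(pedigree)
    truth_scalars = _true_scalars(scenario)
    params = scalar_names(scenario.g0.n_traits)
    rows: list[dict] = []
    acc_rows: list[dict] = []
    failures: list[dict] = []
    for r in range(n_replicates):
        seed = base_seed + r
        phenotypes, truth = simulate_traits(
            A, scenario.g0, scenario.r0, seed, trait_names=scenario.trait_names
        )
        data = MultiTraitData(phenotypes, A)
        for engine in engines:
            try:
                fit = _run_engine(engine, data, seed, options[engine])
                for param in params:
                    est = fit.point(param)
                    rows.append(
                        {
                            "replicate": r,
                            "engine": engine,
                            "parameter": param,
                            "true": truth_scalars[param],
                            "estimate": est,
                            "error": est - truth_scalars[param],
                        }
                    )
                if compute_blup:
                    blup = solve_mme(data, fit.g0_hat, fit.r0_hat)
                    acc = ebv_accuracy(blup, truth)
                    acc_rows.append({"replicate": r, "engine": engine, **acc})
            except (MultitraitError, np.linalg.LinAlgError) as err:
                logger.warning("replicate %d engine %s failed: %s", r, engine, err)
                failures.append({"replicate": r, "engine": engine, "error": str(err)})
    if failures:
        logger.warning("%d replicate-engine runs failed", len(failures))
    return StudyResult(
        scenario=scenario,
        engines=engines,
        estimates=pd.DataFrame(rows),
        accuracies=pd.DataFrame(acc_rows),
        truth=truth_scalars,
        failures=failures,
    )


def _run_engine(engine: str, data: MultiTraitData, seed: int, opts: dict) -> FitResult:
    if engine == "reml":
        return fit_reml(data, **opts)
    offset_seed = seed + _ENGINE_SEED_OFFSET[engine]
    if engine == "laplace":
        return fit_laplace(data, seed=offset_seed, **opts)
    return fit_mcmc(data, seed=offset_seed, **opts)


# ---------------------------------------------------------------------------
# phenotype standardization


@dataclass(frozen=True)
class RescalingRule:
    """Maps standardized-scale (co)variance estimates back to trait units."""

    means: np.ndarray
    scales: np.ndarray  # per-trait sample standard deviations

    def rescale_cov(self, cov: np.ndarray | TraitCovariance) -> np.ndarray:
        values = cov.values if isinstance(cov, TraitCovariance) else np.asarray(cov, float)
        return values * np.outer(self.scales, self.scales)

    def standardize_cov(self, cov: np.ndarray | TraitCovariance) -> np.ndarray:
        values = cov.values if isinstance(cov, TraitCovariance) else np.asarray(cov, float)
        return values / np.outer(self.scales, self.scales)


def standardize_and_rescale(data: MultiTraitData) -> tuple[MultiTraitData, RescalingRule]:
    """Z-score each trait; return the standardized data and the inverse rule.

    Covariance estimates from the standardized analysis are mapped back by
    multiplying entry (i, j) with s_i s_j.
    """
    Y = data.phenotypes
    scales = Y.std(ddof=1).to_numpy(dtype=float)
    means_abs = np.abs(Y.mean().to_numpy(dtype=float))
    degenerate = scales <= 1e-12 * (1.0 + means_abs)
    if np.any(degenerate):
        constant = [c for c, bad in zip(Y.columns, degenerate) if bad]
        raise DegenerateInputError(f"constant trait(s): {constant}")
    means = Y.mean().to_numpy(dtype=float)
    standardized = (Y - means) / scales
    new_data = MultiTraitData(standardized, data.full_relmat, data.fixed_design)
    return new_data, RescalingRule(means=means, scales=scales)


def plot_error_boxplots(study: StudyResult, path: str | Path) -> None:
    """Box plots of estimation errors by engine, one panel per component."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = study.estimates
    params = [p for p in df["parameter"].unique() if p.startswith("sigma")]
    ncol = 4
    nrow = int(np.ceil(len(params) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow), squeeze=False)
    for ax, param in zip(axes.flat, params):
        sub = df[df["parameter"] == param]
        groups = [sub[sub["engine"] == e]["error"].to_numpy() for e in study.engines]
        ax.boxplot(groups, tick_labels=list(study.engines))
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_title(param, fontsize=9)
    for ax in axes.flat[len(params):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
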