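"""Model/Results interface over the three-step hidden-mediator pipeline.

``HiddenMediatorModel`` holds the data (genotypes, outcome, known
mediators, covariates); ``fit`` runs sign orientation, the Step-1
regressions with joint IQR outlier filtering, the Step-2 EM mixture fits
on a* and c*, and the Step-3 Gibbs sampler with the label-switching
adjustment.  The returned ``HiddenMediatorResults`` carries the posterior
of b_H, the regression and mixture fits, and a text ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gibbs import PosteriorResult, run_step3_with_adjustment
from .mixture import GmmFit, em_fit_multi
from .regression import RegressionResult, run_step1
from .simulate import GenotypeMatrix, SimulatedDataset


class HiddenMediatorModel:
    """Estimate the effect size b_H of a hidden mediator between a set of
    trait-associated SNPs and a continuous outcome.

    Parameters
    ----------
    genotypes : GenotypeMatrix or array-like
        n x p additive dosage matrix.
    outcome : array-like
        Length-n continuous outcome.
    mediators : DataFrame or array-like
        n x K table of known continuous mediators.
    covariates : DataFrame or array-like, optional
        Continuous covariates adjusted for in the regressions.
    mediator_dag : sequence of (parent_index, child_index), optional
        Known causal edges among the mediators; each child's Step-1
        regression additionally adjusts for its parents.
    standardize : bool
        Standardize outcome and mediators to zero mean / unit sd before
        fitting (the convention for real-data applications).
    """

    def __init__(self, genotypes, outcome, mediators, covariates=None,
                 mediator_dag=None, standardize: bool = False):
        if not isinstance(genotypes, GenotypeMatrix):
            genotypes = np.asarray(genotypes)
            genotypes = GenotypeMatrix(
                genotypes, [f"snp{j + 1}" for j in range(genotypes.shape[1])])
        self.genotypes = genotypes
        self.outcome = np.asarray(outcome, dtype=float)
        self.mediator_names = (
            list(mediators.columns) if isinstance(mediators, pd.DataFrame)
            else [f"M{k + 1}" for k in range(np.atleast_2d(np.asarray(mediators).T).shape[0])])
        self.mediators = np.asarray(mediators, dtype=float)
        if self.mediators.ndim == 1:
            self.mediators = self.mediators[:, None]
        self.covariate_names = (
            list(covariates.columns) if isinstance(covariates, pd.DataFrame)
            else None)
        self.covariates = None if covariates is None \
            else np.asarray(covariates, dtype=float)
        if self.covariates is not None and self.covariates.ndim == 1:
            self.covariates = self.covariates[:, None]
        self.mediator_parent_idx: dict[int, list[int]] = {}
        for edge in (mediator_dag or []):
            parent, child = edge[0], edge[1]
            self.mediator_parent_idx.setdefault(child, []).append(parent)
        self.standardize = standardize
        if standardize:
            self.outcome = _zscore(self.outcome)
            self.mediators = _zscore(self.mediators)
        n = self.genotypes.n
        if not (len(self.outcome) == self.mediators.shape[0] == n):
            raise ValueError("genotypes, outcome and mediators must share n")

    # -- constructors --------------------------------------------------
    @classmethod
    def from_dataframe(cls, phenotypes: pd.DataFrame, genotypes,
                       outcome: str, mediators: list[str],
                       covariates: list[str] | None = None, **kwargs):
        """Build from a phenotype table plus a genotype matrix, naming the
        outcome, mediator and covariate columns."""
        missing = [c for c in [outcome, *mediators, *(covariates or [])]
                   if c not in phenotypes.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns: {missing}")
        cov = phenotypes[covariates] if covariates else None
        return cls(genotypes, phenotypes[outcome].to_numpy(),
                   phenotypes[mediators], cov, **kwargs)

    @classmethod
    def from_simulation(cls, dataset: SimulatedDataset, **kwargs):
        return cls(dataset.genotypes, dataset.outcome, dataset.mediators,
                   dataset.covariates,
                   mediator_dag=[(e[0], e[1]) for e in dataset.config.mediator_dag],
                   **kwargs)

    @classmethod
    def from_files(cls, dosage_path, phenotype_path, outcome: str,
                   mediators: list[str], covariates: list[str] | None = None,
                   dialect: str = "tsv", **kwargs):
        from .io import read_dosage_matrix, read_phenotypes

        G = read_dosage_matrix(dosage_path, dialect=dialect)
        pheno = read_phenotypes(phenotype_path)
        return cls.from_dataframe(pheno, G, outcome, mediators, covariates,
                                  **kwargs)

    # -- fitting -------------------------------------------------------
    def fit(self, em_runs: int = 15, chain_length: int = 30_000,
            burn_in: int = 5_000, prior_var: float = 100.0,
            width_threshold: float = 5.0, outlier_k: float = 3.0,
            orient: bool = True, variance_source: str = "a_star",
            seed: int | None = None) -> "HiddenMediatorResults":
        """Run the full three-step pipeline and return the results object."""
        ss = seed if isinstance(seed, np.random.SeedSequence) \
            else np.random.SeedSequence(seed)
        em_seed_a, em_seed_c, gibbs_seed = ss.spawn(3)
        regression = run_step1(
            self.genotypes, self.mediators, self.covariates, self.outcome,
            mediator_parent_idx=self.mediator_parent_idx,
            outlier_k=outlier_k, orient=orient)
        a_fit = em_fit_multi(regression.a_star_joint, n_runs=em_runs,
                             seed=np.random.default_rng(em_seed_a))
        c_kept = regression.c_star_kept
        c_fit = em_fit_multi(c_kept.values, n_runs=em_runs,
                             seed=np.random.default_rng(em_seed_c))
        posterior = run_step3_with_adjustment(
            c_fit, a_fit, c_kept.values, prior_var=prior_var,
            chain_length=chain_length, burn_in=burn_in,
            seed=gibbs_seed, width_threshold=width_threshold,
            variance_source=variance_source)
        return HiddenMediatorResults(model=self, regression=regression,
                                     a_fit=a_fit, c_fit=c_fit,
                                     posterior=posterior)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)


@dataclass
class HiddenMediatorResults:
    """Estimates, intervals and diagnostics from a fitted model."""

    model: HiddenMediatorModel
    regression: RegressionResult
    a_fit: GmmFit
    c_fit: GmmFit
    posterior: PosteriorResult

    @property
    def b_h_median(self) -> float:
        return self.posterior.median

    @property
    def b_h_mean(self) -> float:
        return self.posterior.mean

    @property
    def hdi_90(self) -> tuple[float, float]:
        return self.posterior.hdi_90

    @property
    def qi_90(self) -> tuple[float, float]:
        return self.posterior.qi_90

    @property
    def n_snps_kept(self) -> int:
        return int(len(self.regression.kept_snps))

    @property
    def n_snps_removed(self) -> int:
        return self.model.genotypes.p - self.n_snps_kept

    def summary(self) -> str:
        med_names = self.model.mediator_names
        lines = [
            "Hidden-mediator effect size estimation",
            "=" * 54,
            f"Individuals: {self.model.genotypes.n:>10}   SNPs: "
            f"{self.model.genotypes.p} ({self.n_snps_removed} removed as outliers)",
            f"Known mediators: {len(med_names)}",
            "",
            "Posterior of b_H",
            "-" * 54,
            f"  median            {self.b_h_median:>10.4f}",
            f"  mean              {self.b_h_mean:>10.4f}",
            f"  90% HDI           ({self.hdi_90[0]:.4f}, {self.hdi_90[1]:.4f})",
            f"  90% QI            ({self.qi_90[0]:.4f}, {self.qi_90[1]:.4f})",
            f"  label flip        {'yes' if self.posterior.flip_applied else 'no'}",
            "",
            "Step-2 mixture fits (noise | effect)",
            "-" * 54,
            f"  a*: weight {self.a_fit.w_noise:.3f} | {self.a_fit.w_effect:.3f}"
            f"   mean {self.a_fit.mu_noise:.4f} | {self.a_fit.mu_effect:.4f}",
            f"  c*: weight {self.c_fit.w_noise:.3f} | {self.c_fit.w_effect:.3f}"
            f"   mean {self.c_fit.mu_noise:.4f} | {self.c_fit.mu_effect:.4f}",
            "",
            "Known-mediator effects on the outcome",
            "-" * 54,
        ]
        for name, b in zip(med_names, self.regression.mediator_coefficients):
            lines.append(f"  {name:<12} {b:>10.4f}")
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {
            "b_h_median": self.b_h_median,
            "b_h_mean": self.b_h_mean,
            "hdi_90": list(self.hdi_90),
            "qi_90": list(self.qi_90),
            "flip_applied": self.posterior.flip_applied,
            "n_snps_kept": self.n_snps_kept,
            "mediator_coefficients":
                np.asarray(self.regression.mediator_coefficients).tolist(),
            "a_fit": self.a_fit.to_json(),
            "c_fit": self.c_fit.to_json(),
        }
        if path is not None:
            Path(path).write_text(json.dumps(d, indent=1))
        return d
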