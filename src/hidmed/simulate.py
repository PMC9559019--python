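"""Synthetic genotype / mediator / outcome data generator.

The generative model: p independent bi-allelic SNPs with additive dosage
coding (Hardy-Weinberg, MAF ~ Uniform), per-SNP effects on each mediator
drawn from a spike-and-slab mixture (a point mass at zero plus a Gaussian
"true effect" component), K observed mediators plus one hidden mediator
built as linear functions of the genotypes, and a continuous outcome that
is a linear combination of all mediators, two environmental covariates and
Gaussian noise.  Every random draw is recorded so the ground truth of each
replicate is available to the evaluation harness.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml


@dataclass
class GenotypeMatrix:
    """Additive dosage matrix (n individuals x p SNPs).

    ``signs`` records the orientation applied to each column relative to the
    coding the matrix was generated/read with (+1 untouched, -1 recoded as
    ``2 - dosage``).
    """

    dosages: np.ndarray
    snp_ids: list[str]
    mafs: np.ndarray | None = None
    signs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        vals = np.unique(self.dosages)
        if not np.isin(vals, [0, 1, 2]).all():
            raise ValueError("dosage entries must be in {0, 1, 2}")
        if len(self.snp_ids) != self.dosages.shape[1]:
            raise ValueError("snp_ids length must equal the number of columns")
        if self.mafs is not None and len(self.mafs) != self.dosages.shape[1]:
            raise ValueError("mafs length must equal the number of columns")
        if self.signs is None:
            self.signs = np.ones(self.dosages.shape[1], dtype=int)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]


@dataclass(frozen=True)
class MixtureSpec:
    """Spike-and-slab effect distribution: 0 w.p. ``1 - prob_nonzero``,
    else Normal(mean, sd^2)."""

    prob_nonzero: float
    mean: float = 0.2
    sd: float = 0.08

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob_nonzero <= 1.0:
            raise ValueError("prob_nonzero must be in [0, 1]")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


# Base-case constants of the generative model.
BASE_KNOWN_EFFECTS = (0.4, 0.2, 0.3, 0.2, 0.4)
BASE_ASSOC_PROBS = (0.5, 0.6, 0.8, 0.2, 0.5)
BASE_MEDIATOR_INTERCEPTS = (50.0, 5.0, 10.0, 6.0, 15.0)
BASE_MEDIATOR_NOISE_SDS = (1.0, 1.0, 1.5, 1.2, 1.0)


@dataclass
class SimulationConfig:
    """All parameters of one simulation scenario.

    ``mediator_dag`` lists directed edges (parent_index, child_index,
    coefficient) among the known mediators; an empty list means independent
    mediators.  ``hierarchy_ratio`` is the (level-1 : level-2) sd ratio of
    the two-level effect hierarchy; ``(0, 1)`` is the flat single-distribution
    case.
    """

    n: int = 100_000
    p: int = 500
    K: int = 5
    known_effects: tuple[float, ...] = BASE_KNOWN_EFFECTS
    pi_H: float = 0.8
    b_H: float = 0.25
    mediator_assoc_probs: tuple[float, ...] = BASE_ASSOC_PROBS
    effect_mean: float = 0.2
    effect_sd: float = 0.08
    mediator_dag: tuple[tuple[int, int, float], ...] = ()
    hierarchy_ratio: tuple[float, float] = (0.0, 1.0)
    maf_range: tuple[float, float] = (0.1, 0.5)
    covariate_means: tuple[float, float] = (7.0, 4.0)
    covariate_sds: tuple[float, float] = (0.5, 0.4)
    covariate_effects: tuple[float, float] = (0.8, -0.3)
    mediator_intercepts: tuple[float, ...] = BASE_MEDIATOR_INTERCEPTS
    hidden_intercept: float = 20.0
    mediator_noise_sds: tuple[float, ...] = BASE_MEDIATOR_NOISE_SDS
    hidden_noise_sd: float = 1.0
    outcome_noise_sd: float = 0.2
    standardize_mediators: bool = False
    seed: int = 0
    setting_id: str = "base"

    def __post_init__(self) -> None:
        if self.n < 1 or self.p < 1 or self.K < 1:
            raise ValueError("n, p and K must be positive")
        if not 0.0 <= self.pi_H <= 1.0:
            raise ValueError("pi_H must be in [0, 1]")
        for name in ("known_effects", "mediator_assoc_probs",
                     "mediator_intercepts", "mediator_noise_sds"):
            if len(getattr(self, name)) != self.K:
                raise ValueError(f"{name} must have length K={self.K}")

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mediator_dag"] = [list(e) for e in self.mediator_dag]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for name in ("known_effects", "mediator_assoc_probs", "hierarchy_ratio",
                     "maf_range", "covariate_means", "covariate_sds",
                     "covariate_effects", "mediator_intercepts",
                     "mediator_noise_sds"):
            if name in d:
                d[name] = tuple(d[name])
        if "mediator_dag" in d:
            d["mediator_dag"] = tuple(
                (int(a), int(b), float(c)) for a, b, c in d["mediator_dag"]
            )
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- named scenario constructors ------------------------------------
    @classmethod
    def base_case(cls, **overrides) -> "SimulationConfig":
        return cls(**overrides)


def _recycle(base: tuple, k: int) -> tuple:
    reps = -(-k // len(base))
    return tuple((base * reps)[:k])


def study_config(setting: str, *, b_H: float = 0.25, p: int = 500,
                  variant: int = 0, seed: int = 0, **overrides) -> SimulationConfig:
    """Build the SimulationConfig for one row of the nine-setting study.

    ``setting`` is one of ``base``, ``setting1`` ... ``setting8``; ``variant``
    selects among semicolon-separated alternatives within a row.
    """
    cfg = SimulationConfig(p=p, b_H=b_H, seed=seed, setting_id=setting)
    if setting == "base":
        pass
    elif setting == "setting1":
        cfg = cfg.replace(pi_H=(0.3, 0.5, 1.0)[variant])
    elif setting == "setting2":
        cfg = cfg.replace(known_effects=(0.4, 0.2, 0.3, -0.2, -0.4))
    elif setting == "setting3":
        cfg = cfg.replace(n=(25_000, 50_000)[variant])
    elif setting == "setting4":
        if variant == 0:
            cfg = cfg.replace(
                K=1, known_effects=(0.4,),
                mediator_assoc_probs=BASE_ASSOC_PROBS[:1],
                mediator_intercepts=BASE_MEDIATOR_INTERCEPTS[:1],
                mediator_noise_sds=BASE_MEDIATOR_NOISE_SDS[:1])
        else:
            cfg = cfg.replace(
                K=10,
                known_effects=(0.4, 0.2, 0.3, 0.2, 0.4, 0.2, 0.1, 0.3, 0.2, 0.2),
                mediator_assoc_probs=_recycle(BASE_ASSOC_PROBS, 10),
                mediator_intercepts=_recycle(BASE_MEDIATOR_INTERCEPTS, 10),
                mediator_noise_sds=_recycle(BASE_MEDIATOR_NOISE_SDS, 10))
    elif setting == "setting5":
        dag = (
            ((0, 1, 0.3),),
            ((0, 1, 0.9),),
            ((0, 1, 0.3), (2, 3, 0.2)),
            ((0, 1, 0.5), (2, 3, 0.4)),
        )[variant]
        cfg = cfg.replace(mediator_dag=dag)
    elif setting == "setting6":
        cfg = cfg.replace(hierarchy_ratio=((1.0, 3.0), (1.0, 1.0))[variant])
    elif setting == "setting7":
        cfg = cfg.replace(b_H=0.0)
    elif setting == "setting8":
        cfg = cfg.replace(p=(20, 40, 700)[variant])
    else:
        raise ValueError(f"unknown setting {setting!r}")
    if overrides:
        cfg = cfg.replace(**overrides)
    return cfg


@dataclass
class SimulatedDataset:
    """One simulated replicate with its full ground truth."""

    genotypes: GenotypeMatrix
    mediators: pd.DataFrame
    hidden_mediator: np.ndarray
    covariates: pd.DataFrame
    outcome: np.ndarray
    truth: dict
    config: SimulationConfig

    def phenotype_frame(self) -> pd.DataFrame:
        df = pd.concat([self.mediators, self.covariates], axis=1)
        df["Y"] = self.outcome
        return df

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.genotypes.dosages,
                     columns=self.genotypes.snp_ids).to_csv(
            directory / "dosages.tsv", sep="\t", index=False)
        pheno = self.phenotype_frame()
        pheno["M_H"] = self.hidden_mediator
        pheno.to_csv(directory / "phenotypes.tsv", sep="\t", index=False)
        truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in self.truth.items()}
        truth["config"] = self.config.to_dict()
        (directory / "truth.json").write_text(json.dumps(truth))


def draw_genotypes(n: int, p: int, maf_low: float = 0.1, maf_high: float = 0.5,
                   seed: int | np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw an n x p dosage matrix of independent SNPs.

    Per-SNP MAF is uniform on [maf_low, maf_high]; dosages are
    Binomial(2, MAF) per individual (Hardy-Weinberg, additive coding).
    """
    if n < 1 or p < 1:
        raise ValueError("n and p must be positive")
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mafs = rng.uniform(maf_low, maf_high, size=p)
    dosages = rng.binomial(2, mafs, size=(n, p)).astype(np.int8)
    ids = [f"snp{j + 1}" for j in range(p)]
    return GenotypeMatrix(dosages=dosages, snp_ids=ids, mafs=mafs)


def draw_effect_vector(p: int, spec: MixtureSpec,
                       rng: np.random.Generator | int | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-SNP effects from the spike-and-slab mixture.

    Returns (values, nonzero_mask)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    mask = rng.random(p) < spec.prob_nonzero
    values = np.zeros(p)
    values[mask] = rng.normal(spec.mean, spec.sd, size=int(mask.sum()))
    return values, mask


def draw_hierarchical_effects(p: int, K_plus_hidden: int, global_mean: float,
                              ratio: tuple[float, float], base_sd: float,
                              assoc_probs: Sequence[float],
                              rng: np.random.Generator | int | None = None
                              ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Two-level effect hierarchy: each mediator gets a centre drawn
    Normal(global_mean, sigma_L1^2); its nonzero SNP effects are
    Normal(centre, sigma_L2^2).  The sd pair is scaled so
    sigma_L1 : sigma_L2 = ratio and sigma_L1^2 + sigma_L2^2 = base_sd^2,
    so ratio (0, 1) reduces exactly to the flat single-distribution draw.
    """
    r1, r2 = ratio
    if r1 < 0 or r2 < 0 or (r1 == 0 and r2 == 0):
        raise ValueError("ratio components must be >= 0 and not both zero")
    if len(assoc_probs) != K_plus_hidden:
        raise ValueError("assoc_probs must have length K_plus_hidden")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    norm = np.hypot(r1, r2)
    sd1 = base_sd * r1 / norm
    sd2 = base_sd * r2 / norm
    out = []
    for prob in assoc_probs:
        if sd1 == 0.0:
            out.append(draw_effect_vector(p, MixtureSpec(prob, global_mean, sd2), rng))
            continue
        center = rng.normal(global_mean, sd1)
        mask = rng.random(p) < prob
        values = np.zeros(p)
        values[mask] = rng.normal(center, sd2, size=int(mask.sum()))
        out.append((values, mask))
    return out


def _toposort(K: int, dag: Sequence[tuple[int, int, float]]) -> list[int]:
    """Kahn topological sort of mediator indices; raises on cycles."""
    children: dict[int, list[int]] = {k: [] for k in range(K)}
    indeg = [0] * K
    for parent, child, _ in dag:
        if not (0 <= parent < K and 0 <= child < K):
            raise ValueError("mediator_dag indices out of range")
        children[parent].append(child)
        indeg[child] += 1
    order = [k for k in range(K) if indeg[k] == 0]
    i = 0
    while i < len(order):
        for ch in children[order[i]]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                order.append(ch)
        i += 1
    if len(order) != K:
        raise ValueError("mediator_dag contains a cycle")
    return order


def simulate_dataset(config: SimulationConfig,
                     seed: int | None = None) -> SimulatedDataset:
    """Generate one replicate under ``config`` (seed overrides config.seed).

    Mediators: M_k = intercept_k + a_k' G + [dag parents] + eps_k.
    Hidden mediator: M_H = intercept_H + a_H' G + eps_H, with nonzero
    probability pi_H for a_H entries.  Outcome:
    Y = b' M + b_H M_H + gamma' C + eps.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    order = _toposort(cfg.K, cfg.mediator_dag)

    G = draw_genotypes(cfg.n, cfg.p, *cfg.maf_range, seed=rng)
    Gd = G.dosages.astype(float)

    probs = list(cfg.mediator_assoc_probs) + [cfg.pi_H]
    effects = draw_hierarchical_effects(
        cfg.p, cfg.K + 1, cfg.effect_mean, cfg.hierarchy_ratio,
        cfg.effect_sd, probs, rng)
    a_vectors = [v for v, _ in effects[:-1]]
    a_masks = [m for _, m in effects[:-1]]
    a_H, a_H_mask = effects[-1]

    M = np.empty((cfg.n, cfg.K))
    parents_of: dict[int, list[tuple[int, float]]] = {k: [] for k in range(cfg.K)}
    for parent, child, coef in cfg.mediator_dag:
        parents_of[child].append((parent, coef))
    for k in order:
        mk = cfg.mediator_intercepts[k] + Gd @ a_vectors[k]
        for parent, coef in parents_of[k]:
            mk = mk + coef * M[:, parent]
        mk = mk + rng.normal(0.0, cfg.mediator_noise_sds[k], size=cfg.n)
        M[:, k] = mk

    M_H = (cfg.hidden_intercept + Gd @ a_H
           + rng.normal(0.0, cfg.hidden_noise_sd, size=cfg.n))

    C = np.column_stack([
        rng.normal(cfg.covariate_means[i], cfg.covariate_sds[i], size=cfg.n)
        for i in range(2)
    ])

    M_out = M
    if cfg.standardize_mediators:
        M_out = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)

    eps = rng.normal(0.0, cfg.outcome_noise_sd, size=cfg.n)
    Y = (M_out @ np.asarray(cfg.known_effects) + cfg.b_H * M_H
         + C @ np.asarray(cfg.covariate_effects) + eps)

    mediators = pd.DataFrame(M_out, columns=[f"M{k + 1}" for k in range(cfg.K)])
    covariates = pd.DataFrame(C, columns=["C1", "C2"])
    truth = {
        "a_vectors": np.asarray(a_vectors),
        "a_masks": np.asarray(a_masks),
        "a_H": a_H,
        "a_H_mask": a_H_mask,
        "b": np.asarray(cfg.known_effects),
        "b_H": cfg.b_H,
        "covariate_effects": np.asarray(cfg.covariate_effects),
        "outcome_noise": eps,
    }
    return SimulatedDataset(genotypes=G, mediators=mediators,
                            hidden_mediator=M_H, covariates=covariates,
                            outcome=Y, truth=truth, config=cfg)
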