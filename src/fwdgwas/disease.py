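"""Penetrance models, prevalence calibration and affection assignment.

Three model families are supported: a two-locus logistic model with
gene-gene and gene-environment interaction terms, a single-locus logistic
model, and an ancestry-linear model for admixed populations.  A plain
genotype-penetrance table is also provided for fully general single-locus
models.  Affection status is assigned independently per individual with
probability equal to the model's penetrance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .popmodel import Individual, Population

__all__ = [
    "LogisticDiseaseModel",
    "SingleLocusLogisticModel",
    "AncestryLinearModel",
    "GenotypePenetranceModel",
    "penetrance",
    "expected_prevalence",
    "calibrate_intercept",
    "assign_affection",
]


@dataclass(frozen=True)
class LogisticDiseaseModel:
    """Two-locus logistic penetrance with GxG and GxE interactions.

    logit P(Y=1 | g1, g2, e) = alpha + beta1 g1 + beta2 g2 + beta3 g1 g2
                               + gamma1 g1 e + gamma2 g2 e

    where g1, g2 count disease-predisposing alleles at the two loci and e is
    a binary environmental exposure with P(e=1) = env_p.
    """

    alpha: float
    beta1: float
    beta2: float
    beta3: float
    gamma1: float
    gamma2: float
    loci: tuple[int, int]
    env_p: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.env_p <= 1.0:
            raise ValueError("env_p must lie in [0, 1]")

    @classmethod
    def half_effect(
        cls,
        alpha: float,
        beta2: float,
        beta3: float,
        gamma2: float,
        loci: tuple[int, int],
        env_p: float = 0.5,
    ) -> "LogisticDiseaseModel":
        """Constructor enforcing beta1 = beta2/2 and gamma1 = gamma2/2,
        so the first locus has half the effect of the second."""
        return cls(alpha, beta2 / 2, beta2, beta3, gamma2 / 2, gamma2, loci, env_p)

    def linear_predictor(self, g1, g2, e):
        g1 = np.asarray(g1, dtype=np.float64)
        g2 = np.asarray(g2, dtype=np.float64)
        e = np.asarray(e, dtype=np.float64)
        return (
            self.alpha
            + self.beta1 * g1
            + self.beta2 * g2
            + self.beta3 * g1 * g2
            + self.gamma1 * g1 * e
            + self.gamma2 * g2 * e
        )


@dataclass(frozen=True)
class SingleLocusLogisticModel:
    """logit P(Y=1) = intercept + slope * g, g = DPA count at one locus."""

    intercept: float
    slope: float
    locus_index: int


@dataclass(frozen=True)
class AncestryLinearModel:
    """P(affected) = base + slope * ancestry, clipped to [0, 1]."""

    base: float = 0.05
    slope: float = 1.0 / 6.0


@dataclass(frozen=True)
class GenotypePenetranceModel:
    """Direct penetrance table (f0, f1, f2) by DPA count at one locus."""

    f: tuple[float, float, float]
    locus_index: int

    def __post_init__(self):
        if min(self.f) < 0 or max(self.f) > 1:
            raise ValueError("penetrances must lie in [0, 1]")


def penetrance(model, individual: Individual, env: int | None = None) -> float:
    """P(affected) for one individual under the given model."""
    if isinstance(model, LogisticDiseaseModel):
        if env is None:
            raise ValueError(
                "the gene-environment model requires the environmental state"
            )
        g1 = individual.genotype(model.loci[0])
        g2 = individual.genotype(model.loci[1])
        return float(expit(model.linear_predictor(g1, g2, env)))
    if isinstance(model, SingleLocusLogisticModel):
        g = individual.genotype(model.locus_index)
        return float(expit(model.intercept + model.slope * g))
    if isinstance(model, AncestryLinearModel):
        return float(np.clip(model.base + model.slope * individual.ancestry, 0, 1))
    if isinstance(model, GenotypePenetranceModel):
        return model.f[individual.genotype(model.locus_index)]
    raise TypeError(f"unknown disease model {type(model).__name__}")


def _hwe(q: float) -> np.ndarray:
    p = 1.0 - q
    return np.array([p * p, 2 * p * q, q * q])


def expected_prevalence(model: LogisticDiseaseModel, q1: float, q2: float) -> float:
    """Exact prevalence by enumeration over the 3 x 3 x 2 genotype-environment
    classes, assuming Hardy-Weinberg proportions and independence of the two
    unlinked loci and the exposure."""
    w1 = _hwe(q1)
    w2 = _hwe(q2)
    we = np.array([1.0 - model.env_p, model.env_p])
    g1, g2, e = np.meshgrid([0, 1, 2], [0, 1, 2], [0, 1], indexing="ij")
    probs = w1[g1] * w2[g2] * we[e]
    return float((probs * expit(model.linear_predictor(g1, g2, e))).sum())


def calibrate_intercept(
    model: LogisticDiseaseModel,
    dpa_freqs: tuple[float, float],
    target_prevalence: float,
    tol: float = 1e-12,
) -> float:
    """Intercept alpha that makes the enumerated prevalence hit the target.

    The prevalence is strictly increasing in alpha, so bisection converges;
    the returned alpha satisfies |prevalence - target| < 1e-10.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must lie in (0, 1)")
    q1, q2 = dpa_freqs
    lo, hi = -60.0, 60.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        m = LogisticDiseaseModel(
            mid, model.beta1, model.beta2, model.beta3,
            model.gamma1, model.gamma2, model.loci, model.env_p,
        )
        if expected_prevalence(m, q1, q2) < target_prevalence:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def _penetrance_vector(model, sp, rng: np.random.Generator) -> np.ndarray:
    """Vectorised penetrance for a whole subpopulation; draws and stores env
    for the gene-environment model."""
    if isinstance(model, LogisticDiseaseModel):
        g1 = sp.genotype(model.loci[0])
        g2 = sp.genotype(model.loci[1])
        env = (rng.random(sp.size) < model.env_p).astype(np.int8)
        sp.env[:] = env
        return expit(model.linear_predictor(g1, g2, env))
    if isinstance(model, SingleLocusLogisticModel):
        g = sp.genotype(model.locus_index)
        return expit(model.intercept + model.slope * g)
    if isinstance(model, AncestryLinearModel):
        return np.clip(model.base + model.slope * sp.ancestry, 0.0, 1.0)
    if isinstance(model, GenotypePenetranceModel):
        return np.asarray(model.f)[sp.genotype(model.locus_index)]
    raise TypeError(f"unknown disease model {type(model).__name__}")


def assign_affection(
    pop: Population, model, rng: np.random.Generator
) -> Population:
    """Assign affection status to every individual in place and return pop.

    Each individual is independently affected with probability equal to its
    penetrance; for the gene-environment model the drawn exposures are
    stored on the subpopulation for later export.
    """
    for sp in pop.subpops:
        if sp.size == 0:
            continue
        pen = _penetrance_vector(model, sp, rng)
        sp.affected[:] = (rng.random(sp.size) < pen).astype(np.int8)
    return pop
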