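"""Drawing analysis-ready samples from an evolved population.

Three designs are supported: uniform random samples, stratified
case-control samples drawn directly from the assigned population, and
rejection-sampled designs for rare diseases (case-control offspring and
affected-offspring trios).  Rejection sampling repeatedly draws a fresh
uniform parent pair, produces one offspring by standard transmission,
assigns affection with the penetrance model, and keeps or discards it
until the quotas fill.  Sample draws never mutate the source population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .disease import penetrance
from .evolve import _gametes_for, mutate_haplotype
from .popmodel import FEMALE, MALE, Individual, Locus, Population, SubPopulation

__all__ = [
    "Sample",
    "SampleQuotaError",
    "draw_random_sample",
    "draw_case_control_direct",
    "draw_case_control_rejection",
    "draw_trios_rejection",
]


class SampleQuotaError(RuntimeError):
    """Raised when a sampling quota cannot be filled; carries achieved counts."""

    def __init__(self, msg: str, achieved: dict):
        super().__init__(msg)
        self.achieved = achieved


@dataclass
class Sample:
    """A drawn sample with pedigree structure.

    Row i of the per-individual arrays describes one sampled person;
    ``haps`` rows (2i, 2i+1) are their phased haplotypes.  ``fid``/``iid``/
    ``pat``/``mat`` follow PED conventions ("0" = founder/unknown);
    ``phenotype`` uses 2 = affected, 1 = unaffected, 0 = missing.
    """

    loci: list[Locus]
    haps: np.ndarray
    fid: list[str]
    iid: list[str]
    pat: list[str]
    mat: list[str]
    sex: np.ndarray
    phenotype: np.ndarray
    env: np.ndarray = field(default=None)
    ancestry: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.fid)
        if self.env is None:
            self.env = np.full(n, -1, dtype=np.int8)
        if self.ancestry is None:
            self.ancestry = np.zeros(n, dtype=np.float64)

    @property
    def n(self) -> int:
        return len(self.fid)

    def genotype(self, i: int, locus_index: int) -> int:
        return int(self.haps[2 * i, locus_index]) + int(
            self.haps[2 * i + 1, locus_index]
        )

    def subset(self, mask: np.ndarray) -> "Sample":
        """Row subset by boolean mask (pedigree links are kept verbatim)."""
        idx = np.flatnonzero(mask)
        rows = np.empty(2 * len(idx), dtype=np.int64)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        return Sample(
            loci=self.loci,
            haps=self.haps[rows],
            fid=[self.fid[i] for i in idx],
            iid=[self.iid[i] for i in idx],
            pat=[self.pat[i] for i in idx],
            mat=[self.mat[i] for i in idx],
            sex=self.sex[idx],
            phenotype=self.phenotype[idx],
            env=self.env[idx],
            ancestry=self.ancestry[idx],
        )

    def allele_counts(self, locus_index: int, mask=None) -> tuple[int, int]:
        """(alt, ref) allele counts over the sample or a boolean row mask."""
        col = self.haps[:, locus_index]
        if mask is not None:
            col = col[np.repeat(mask, 2)]
        alt = int(col.sum())
        return alt, len(col) - alt


def _pheno_code(affected: np.ndarray) -> np.ndarray:
    out = np.zeros(len(affected), dtype=np.int8)
    out[affected == 1] = 2
    out[affected == 0] = 1
    return out


def _sample_from_indices(pop: Population, idx: np.ndarray) -> Sample:
    sp = pop.merged().subpops[0]
    rows = np.empty(2 * len(idx), dtype=np.int64)
    rows[0::2] = 2 * idx
    rows[1::2] = 2 * idx + 1
    n = len(idx)
    return Sample(
        loci=list(pop.loci),
        haps=sp.haps[rows].copy(),
        fid=[f"F{i + 1}" for i in range(n)],
        iid=[f"I{i + 1}" for i in range(n)],
        pat=["0"] * n,
        mat=["0"] * n,
        sex=sp.sex[idx].copy(),
        phenotype=_pheno_code(sp.affected[idx]),
        env=sp.env[idx].copy(),
        ancestry=sp.ancestry[idx].copy(),
    )


def draw_random_sample(pop: Population, n: int, rng: np.random.Generator) -> Sample:
    """Uniform sample of n individuals without replacement."""
    N = pop.size
    if n > N:
        raise ValueError(f"cannot draw {n} individuals from a population of {N}")
    idx = rng.choice(N, size=n, replace=False)
    return _sample_from_indices(pop, idx)


def draw_case_control_direct(
    pop: Population, n_cases: int, n_controls: int, rng: np.random.Generator
) -> Sample:
    """Stratified uniform draw from the assigned affected/unaffected strata."""
    sp = pop.merged().subpops[0]
    cases = np.flatnonzero(sp.affected == 1)
    controls = np.flatnonzero(sp.affected == 0)
    if len(cases) < n_cases or len(controls) < n_controls:
        raise ValueError(
            f"population has {len(cases)} cases / {len(controls)} controls, "
            f"need {n_cases}/{n_controls}; consider rejection sampling"
        )
    idx = np.concatenate(
        [
            rng.choice(cases, size=n_cases, replace=False),
            rng.choice(controls, size=n_controls, replace=False),
        ]
    )
    return _sample_from_indices(pop, idx)


def _offspring_batch(sp, k, probs, mu, rng):
    """k offspring from fresh uniform parent pairs; returns parent indices
    and the offspring gamete pair arrays."""
    fathers = rng.integers(0, sp.size, size=k)
    mothers = rng.integers(0, sp.size, size=k)
    gf = _gametes_for(sp.haps, fathers, probs, rng)
    gm = _gametes_for(sp.haps, mothers, probs, rng)
    if mu > 0.0:
        gf = mutate_haplotype(gf, mu, rng)
        gm = mutate_haplotype(gm, mu, rng)
    return fathers, mothers, gf, gm


def _offspring_affection(model, gf, gm, ancestry, rng):
    """Affection flags (and env draws) for a batch of offspring genotypes."""
    from .disease import (
        AncestryLinearModel,
        GenotypePenetranceModel,
        LogisticDiseaseModel,
        SingleLocusLogisticModel,
    )
    from scipy.special import expit

    k = gf.shape[0]
    env = np.full(k, -1, dtype=np.int8)
    if isinstance(model, LogisticDiseaseModel):
        g1 = gf[:, model.loci[0]].astype(np.int64) + gm[:, model.loci[0]]
        g2 = gf[:, model.loci[1]].astype(np.int64) + gm[:, model.loci[1]]
        env = (rng.random(k) < model.env_p).astype(np.int8)
        pen = expit(model.linear_predictor(g1, g2, env))
    elif isinstance(model, SingleLocusLogisticModel):
        g = gf[:, model.locus_index].astype(np.int64) + gm[:, model.locus_index]
        pen = expit(model.intercept + model.slope * g)
    elif isinstance(model, GenotypePenetranceModel):
        g = gf[:, model.locus_index].astype(np.int64) + gm[:, model.locus_index]
        pen = np.asarray(model.f)[g]
    elif isinstance(model, AncestryLinearModel):
        pen = np.clip(model.base + model.slope * ancestry, 0.0, 1.0)
    else:
        raise TypeError(f"unknown disease model {type(model).__name__}")
    affected = rng.random(k) < pen
    return affected, env


def draw_case_control_rejection(
    pop: Population,
    n_cases: int,
    n_controls: int,
    model,
    rng: np.random.Generator,
    probs: np.ndarray | None = None,
    mu: float = 0.0,
    max_offspring: int = 5_000_000,
) -> Sample:
    """Offspring case-control sample for a rare disease.

    Fresh uniform parent pairs produce one offspring each; the penetrance
    model assigns affection and the offspring fills the first unfilled quota
    matching its status, until both quotas are full.
    """
    from .evolve import interval_recomb_probs

    sp = pop.merged().subpops[0]
    if probs is None:
        probs = interval_recomb_probs(pop.loci)
    want = {"case": n_cases, "control": n_controls}
    got = {"case": 0, "control": 0}
    haps_rows: list[np.ndarray] = []
    sexes: list[int] = []
    envs: list[int] = []
    ancs: list[float] = []
    phenos: list[int] = []
    produced = 0
    while got["case"] < want["case"] or got["control"] < want["control"]:
        if produced >= max_offspring:
            raise SampleQuotaError(
                f"offspring cap {max_offspring} reached with "
                f"{got['case']}/{n_cases} cases and "
                f"{got['control']}/{n_controls} controls",
                dict(got),
            )
        k = min(4096, max_offspring - produced)
        fathers, mothers, gf, gm = _offspring_batch(sp, k, probs, mu, rng)
        anc = 0.5 * (sp.ancestry[fathers] + sp.ancestry[mothers])
        affected, env = _offspring_affection(model, gf, gm, anc, rng)
        produced += k
        for i in range(k):
            key = "case" if affected[i] else "control"
            if got[key] >= want[key]:
                continue
            got[key] += 1
            haps_rows.append(gf[i])
            haps_rows.append(gm[i])
            phenos.append(2 if affected[i] else 1)
            envs.append(int(env[i]))
            ancs.append(float(anc[i]))
            sexes.append(int(rng.integers(0, 2)))
            if got["case"] >= want["case"] and got["control"] >= want["control"]:
                break
    n = len(phenos)
    return Sample(
        loci=list(pop.loci),
        haps=np.vstack(haps_rows) if haps_rows else np.zeros((0, pop.n_loci), np.uint8),
        fid=[f"F{i + 1}" for i in range(n)],
        iid=[f"I{i + 1}" for i in range(n)],
        pat=["0"] * n,
        mat=["0"] * n,
        sex=np.array(sexes, dtype=np.uint8),
        phenotype=np.array(phenos, dtype=np.int8),
        env=np.array(envs, dtype=np.int8),
        ancestry=np.array(ancs, dtype=np.float64),
    )


def draw_trios_rejection(
    pop: Population,
    n_trios: int,
    model,
    rng: np.random.Generator,
    probs: np.ndarray | None = None,
    mu: float = 0.0,
    max_offspring: int = 5_000_000,
) -> Sample:
    """Affected-offspring trio sample.

    Each try draws a fresh uniform parent pair and one offspring; the trio
    is kept iff the offspring is affected.  Family IDs are sequential; the
    same population member may appear in several trios only by chance.
    """
    from .evolve import interval_recomb_probs

    sp = pop.merged().subpops[0]
    if probs is None:
        probs = interval_recomb_probs(pop.loci)
    fam = 0
    produced = 0
    haps_rows: list[np.ndarray] = []
    fid: list[str] = []
    iid: list[str] = []
    pat: list[str] = []
    mat: list[str] = []
    sexes: list[int] = []
    phenos: list[int] = []
    envs: list[int] = []
    ancs: list[float] = []
    while fam < n_trios:
        if produced >= max_offspring:
            raise SampleQuotaError(
                f"offspring cap {max_offspring} reached with {fam}/{n_trios} trios",
                {"trios": fam},
            )
        k = min(4096, max_offspring - produced)
        fathers, mothers, gf, gm = _offspring_batch(sp, k, probs, mu, rng)
        anc = 0.5 * (sp.ancestry[fathers] + sp.ancestry[mothers])
        affected, env = _offspring_affection(model, gf, gm, anc, rng)
        produced += k
        for i in np.flatnonzero(affected):
            fam += 1
            f = f"F{fam}"
            fa, mo = fathers[i], mothers[i]
            # father, mother, affected child
            haps_rows.extend(
                [sp.haps[2 * fa], sp.haps[2 * fa + 1], sp.haps[2 * mo],
                 sp.haps[2 * mo + 1], gf[i], gm[i]]
            )
            fid.extend([f, f, f])
            iid.extend([f"{f}_P1", f"{f}_P2", f"{f}_C"])
            pat.extend(["0", "0", f"{f}_P1"])
            mat.extend(["0", "0", f"{f}_P2"])
            sexes.extend([MALE, FEMALE, int(rng.integers(0, 2))])
            pf = int(sp.affected[fa])
            pm_ = int(sp.affected[mo])
            phenos.extend([pf + 1 if pf >= 0 else 0, pm_ + 1 if pm_ >= 0 else 0, 2])
            envs.extend([int(sp.env[fa]), int(sp.env[mo]), int(env[i])])
            ancs.extend(
                [float(sp.ancestry[fa]), float(sp.ancestry[mo]), float(anc[i])]
            )
            if fam >= n_trios:
                break
    return Sample(
        loci=list(pop.loci),
        haps=np.vstack(haps_rows),
        fid=fid,
        iid=iid,
        pat=pat,
        mat=mat,
        sex=np.array(sexes, dtype=np.uint8),
        phenotype=np.array(phenos, dtype=np.int8),
        env=np.array(envs, dtype=np.int8),
        ancestry=np.array(ancs, dtype=np.float64),
    )
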