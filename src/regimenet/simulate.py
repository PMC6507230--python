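"""Synthetic multi-omics tumor cohorts with known ground truth.

Emulates the structures the workflow is built to detect: bimodal
expression regimes, cliques of genes whose regimes co-occur, genomic
drivers (mutations, deletions, amplifications) that shift a target
gene's regime, and a regime linked to survival. Real-cohort features
such as platform effects, batch structure, and correlated background
noise are deliberately absent; see the methods note for what that
implies about the tests.

Generative model per sample:
- background genes: a single Normal(0, 1);
- bimodal genes: a latent regime z ~ Bernoulli(1 - low_weight);
  expression ~ Normal(Delta * z, 1), so the two modes are separated by
  Delta pooled SDs;
- clique members share one latent Bernoulli(prevalence) draw, flipped
  independently per member with probability epsilon;
- a driver's carriers (Bernoulli(frequency)) have each target's latent
  regime forced to 1 (0 for DEL drivers) with the stated penetrance;
- survival ~ Exponential(lambda0 * exp(beta * z_surv + 0.01*(age-60)))
  with independent exponential censoring calibrated to the requested
  censoring fraction.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import (
    AberrationMatrix,
    ClinicalTable,
    ExpressionMatrix,
    write_aberrations,
    write_clinical,
    write_expression,
)


class SimulationError(ValueError):
    pass


@dataclass
class BimodalGene:
    separation: float = 4.0  # Delta, in pooled-SD units
    low_weight: float = 0.5  # P(regime 0)


@dataclass
class Clique:
    members: list[int]  # indices into the bimodal gene list
    prevalence: float = 0.4  # latent P(regime 1)
    epsilon: float = 0.05  # independent flip noise per member


@dataclass
class Driver:
    modality: str  # MUT | DEL | AMP
    frequency: float  # carrier fraction
    penetrance: float  # P(target regime driven | carrier)
    targets: list[int]  # indices into the bimodal gene list


@dataclass
class SurvivalSpec:
    gene: int  # index into the bimodal gene list
    baseline_rate: float = 0.02  # events per month
    log_hr: float = math.log(2.0)  # beta on regime 1
    censoring_fraction: float = 0.2
    age_mean: float = 60.0
    age_sd: float = 10.0


@dataclass
class SimSpec:
    n_samples: int = 500
    n_background_unimodal: int = 140
    bimodal_genes: list[BimodalGene] = field(default_factory=list)
    cliques: list[Clique] = field(default_factory=list)
    drivers: list[Driver] = field(default_factory=list)
    survival: Optional[SurvivalSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.bimodal_genes:
            if not (0 <= g.low_weight <= 1) or g.separation < 0:
                raise SimulationError("invalid bimodal gene parameters")
        nb = len(self.bimodal_genes)
        for c in self.cliques:
            if not (0 <= c.prevalence <= 1 and 0 <= c.epsilon <= 1):
                raise SimulationError("invalid clique parameters")
            if any(i >= nb for i in c.members):
                raise SimulationError("clique member gene not simulated")
        for d in self.drivers:
            if d.modality not in ("MUT", "DEL", "AMP"):
                raise SimulationError(f"unknown driver modality {d.modality!r}")
            if not (0 <= d.frequency <= 1 and 0 <= d.penetrance <= 1):
                raise SimulationError("invalid driver parameters")
            if any(i >= nb for i in d.targets):
                raise SimulationError("driver target gene not simulated")
        if self.survival is not None:
            if self.survival.gene >= nb:
                raise SimulationError("survival gene not simulated")
            if self.survival.baseline_rate <= 0:
                raise SimulationError("baseline rate must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth paired with the emitted matrices."""

    true_k: dict[str, int]
    latent_regimes: pd.DataFrame  # bimodal genes x samples, 0/1
    planted_pairs: list[tuple[str, str]]  # unordered clique gene pairs
    driver_targets: dict[str, list[str]]  # driver feature label -> target genes
    survival_gene: Optional[str]
    true_hr: Optional[float]
    poor_regime: Optional[int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_k": self.true_k,
                "latent_regimes": {
                    g: [int(v) for v in self.latent_regimes.loc[g]]
                    for g in self.latent_regimes.index
                },
                "samples": list(self.latent_regimes.columns),
                "planted_pairs": [list(p) for p in self.planted_pairs],
                "driver_targets": self.driver_targets,
                "survival_gene": self.survival_gene,
                "true_hr": self.true_hr,
                "poor_regime": self.poor_regime,
            },
            indent=1,
        )


def _bimodal_name(i: int) -> str:
    return f"BM{i:04d}"


def _background_name(i: int) -> str:
    return f"BG{i:04d}"


def simulate_cohort(
    spec: SimSpec,
) -> tuple[ExpressionMatrix, AberrationMatrix, AberrationMatrix, ClinicalTable, SyntheticTruth]:
    """Draw one cohort from the generative model; reproducible from spec.seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    nb = len(spec.bimodal_genes)
    bm_names = [_bimodal_name(i) for i in range(nb)]
    bg_names = [_background_name(i) for i in range(spec.n_background_unimodal)]

    # latent regimes: independent per bimodal gene ...
    z = np.zeros((nb, n), dtype=int)
    for i, g in enumerate(spec.bimodal_genes):
        z[i] = rng.random(n) >= g.low_weight
    # ... except clique members, which share a latent state plus flip noise
    for c in spec.cliques:
        shared = (rng.random(n) < c.prevalence).astype(int)
        for i in c.members:
            flips = rng.random(n) < c.epsilon
            z[i] = np.where(flips, 1 - shared, shared)

    # drivers: carriers drawn at the stated frequency; each target's
    # latent regime driven with the stated penetrance
    mut = pd.DataFrame(0, index=bm_names + bg_names, columns=samples, dtype=int)
    cnv = pd.DataFrame(0, index=bm_names + bg_names, columns=samples, dtype=int)
    driver_targets: dict[str, list[str]] = {}
    for d in spec.drivers:
        carriers = rng.random(n) < d.frequency
        driven_regime = 0 if d.modality == "DEL" else 1
        for t in d.targets:
            takes = carriers & (rng.random(n) < d.penetrance)
            z[t, takes] = driven_regime
        # the aberration is recorded on the first target gene itself
        # (cis driver), so cis-consistency checks are exercised
        host = bm_names[d.targets[0]]
        if d.modality == "MUT":
            mut.loc[host, np.asarray(samples)[carriers]] = 1
        elif d.modality == "DEL":
            cnv.loc[host, np.asarray(samples)[carriers]] = -2
        else:
            cnv.loc[host, np.asarray(samples)[carriers]] = 2
        driver_targets[f"{host}:{d.modality}"] = [bm_names[t] for t in d.targets]

    # expression
    expr = np.empty((nb + len(bg_names), n))
    for i, g in enumerate(spec.bimodal_genes):
        expr[i] = rng.normal(g.separation * z[i], 1.0)
    for j in range(len(bg_names)):
        expr[nb + j] = rng.normal(0.0, 1.0, n)
    expr_df = pd.DataFrame(expr, index=bm_names + bg_names, columns=samples)

    # clinical
    surv_gene = None
    true_hr = None
    poor = None
    age = rng.normal(
        spec.survival.age_mean if spec.survival else 60.0,
        spec.survival.age_sd if spec.survival else 10.0,
        n,
    )
    if spec.survival is not None:
        s = spec.survival
        surv_gene = bm_names[s.gene]
        true_hr = math.exp(abs(s.log_hr))
        poor = 1 if s.log_hr > 0 else 0
        rate = s.baseline_rate * np.exp(s.log_hr * z[s.gene] + 0.01 * (age - 60.0))
    else:
        rate = np.full(n, 0.02) * np.exp(0.01 * (age - 60.0))
    t_event = rng.exponential(1.0 / rate)
    frac = spec.survival.censoring_fraction if spec.survival else 0.0
    if frac > 0:
        # censoring rate solving E[fraction censored] = frac given the
        # drawn event times, under independent exponential censoring
        def expected_censored(rc: float) -> float:
            return float(np.mean(1.0 - np.exp(-rc * t_event))) - frac

        rc = brentq(expected_censored, 1e-12, 1e6)
        t_cens = rng.exponential(1.0 / rc, n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(n, dtype=int)
        time = t_event
    clinical = ClinicalTable(
        pd.DataFrame(
            {"time": np.maximum(time, 1e-6), "event": event, "age": age},
            index=pd.Index(samples, name="sample"),
        )
    )

    planted_pairs = sorted(
        {
            tuple(sorted((bm_names[a], bm_names[b])))
            for c in spec.cliques
            for ii, a in enumerate(c.members)
            for b in c.members[ii + 1:]
        }
    )
    truth = SyntheticTruth(
        true_k={**{g: 2 for g in bm_names}, **{g: 1 for g in bg_names}},
        latent_regimes=pd.DataFrame(z, index=bm_names, columns=samples),
        planted_pairs=[tuple(p) for p in planted_pairs],
        driver_targets=driver_targets,
        survival_gene=surv_gene,
        true_hr=true_hr,
        poor_regime=poor,
    )
    return (
        ExpressionMatrix(expr_df),
        AberrationMatrix(mut, kind="mutation"),
        AberrationMatrix(cnv, kind="cnv"),
        clinical,
        truth,
    )


# ---------------------------------------------------------------------------
# presets — the study conditions every test and demo runs under


def preset_spec(name: str, seed: int = 0) -> SimSpec:
    """Named cohort presets.

    null      200 independent bimodal genes, no planted structure
    cliques   one 5-gene co-occurring clique among 60 bimodal genes
    driver    one mutation driver shifting a target gene's regime
    survival  one gene whose high regime doubles the hazard
    full      clique + MUT driver + DEL driver + survival gene
    """
    bimodal = lambda m: [BimodalGene(separation=4.0, low_weight=0.5) for _ in range(m)]

    def plant_driver_baselines(genes: list[BimodalGene], drivers: list[Driver]) -> None:
        # an aberration-driven regime shift implies the driven regime is
        # rare (5%) at baseline: carriers, not background noise, populate
        # it, as for amplification-driven high expression of ERBB2
        for d in drivers:
            for t in d.targets:
                genes[t].low_weight = 0.05 if d.modality == "DEL" else 0.95

    if name == "null":
        return SimSpec(
            n_samples=500, n_background_unimodal=0,
            bimodal_genes=bimodal(200), seed=seed,
        )
    if name == "cliques":
        return SimSpec(
            n_samples=500, n_background_unimodal=140,
            bimodal_genes=bimodal(60),
            cliques=[Clique(members=[0, 1, 2, 3, 4], prevalence=0.4, epsilon=0.05)],
            seed=seed,
        )
    if name == "driver":
        genes = bimodal(60)
        drivers = [Driver("MUT", frequency=0.2, penetrance=0.9, targets=[10])]
        plant_driver_baselines(genes, drivers)
        return SimSpec(
            n_samples=500, n_background_unimodal=140,
            bimodal_genes=genes, drivers=drivers, seed=seed,
        )
    if name == "survival":
        return SimSpec(
            n_samples=1000, n_background_unimodal=0,
            bimodal_genes=bimodal(20),
            survival=SurvivalSpec(gene=0),
            seed=seed,
        )
    if name == "full":
        genes = bimodal(60)
        drivers = [
            Driver("MUT", frequency=0.2, penetrance=0.9, targets=[10]),
            Driver("DEL", frequency=0.2, penetrance=0.9, targets=[11]),
        ]
        plant_driver_baselines(genes, drivers)
        return SimSpec(
            n_samples=500, n_background_unimodal=140,
            bimodal_genes=genes,
            cliques=[Clique(members=[0, 1, 2, 3, 4], prevalence=0.4, epsilon=0.05)],
            drivers=drivers,
            survival=SurvivalSpec(gene=12),
            seed=seed,
        )
    raise SimulationError(f"unknown preset {name!r}")


def write_demo_cohort(out_dir: str, preset: str, seed: int = 0) -> dict[str, str]:
    """Simulate a preset cohort and write all TSVs plus a truth JSON."""
    spec = preset_spec(preset, seed=seed)
    expr, mut, cnv, clinical, truth = simulate_cohort(spec)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "expression": os.path.join(out_dir, "expression.tsv"),
        "mutation": os.path.join(out_dir, "mutation.tsv"),
        "cnv": os.path.join(out_dir, "cnv.tsv"),
        "clinical": os.path.join(out_dir, "clinical.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_expression(expr, paths["expression"])
    write_aberrations(mut, paths["mutation"])
    write_aberrations(cnv, paths["cnv"])
    write_clinical(clinical, paths["clinical"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write(truth.to_json())
    return paths
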