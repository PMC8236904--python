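"""Seeded generators of synthetic metabolomics tables and in vitro assays.

The metabolomics generator emulates the statistical structure of a
targeted, relative-quantification LC-MS time course on a thymidylate
pathway segment (dTMP -> dTDP -> dTTP): wild-type and hypomorphic-DHFR
mutant strains sampled at 2/4/6/8 h in 2-3 biological replicates, values
normalised to the wild type, multiplicative lognormal noise, and a
detection limit below which values are censored.

Ground truth is a two-enzyme steady-state chain.  Without external dTMP
the upstream (substrate-producing-to-consuming) step is Hill-like with
exponent 2.5 — the diffusion-limited in vivo regime — so mutant substrate
drops are amplified ~(fold)**2.5 in the product pool.  With dTMP in the
medium the substrate is freely diffusing and the chain is plain
Michaelis-Menten.  The regime switch is encoded as a config-level rate-law
choice; the generator does not model the diffusion mechanism itself.
"""

from __future__ import annotations

import zlib
from typing import Iterable

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .chain import EnzymeParams, TwoEnzymeChain, chain_steady_state_hill
from .fitting import DoseResponsePoints
from .fractal import KineticTrace
from .io import MetabolomicsTable

__all__ = [
    "SynthConfig",
    "generate_metabolomics",
    "generate_assay_data",
    "apply_censoring",
    "lognormal_sigma",
]

SUBSTRATE = "dTMP"
PRODUCT = "dTDP"
TRIPHOSPHATE = "dTTP"


def lognormal_sigma(cv: float) -> float:
    """Log-scale sigma of a lognormal with unit mean and the given CV."""
    return float(np.sqrt(np.log1p(cv**2)))


class SynthConfig(BaseModel):
    """Design and ground truth of the synthetic metabolomics experiment.

    Strain fold-drops are the expected dTMP levels relative to WT (the
    anchors measured for the DHFR hypomorphs: 0.5 for W133V, 0.1 for the
    destabilised double mutant I91L+W133V).  The chain truth (equal
    half-saturation constants at the WT anchor, downstream capacity twice
    upstream) places the WT operating point on the rising flank and keeps
    a steady state at every substrate level.
    """

    strains: dict[str, float] = Field(
        default={"WT": 1.0, "W133V": 0.5, "I91L+W133V": 0.1}
    )
    timepoints_h: list[float] = Field(default=[2.0, 4.0, 6.0, 8.0])
    replicates: int = 3
    noise_cv: float = 0.25
    detection_limit: float = 0.005
    # The instrument limit is absolute, so the *relative* (WT-normalised)
    # limit differs per metabolite; dTTP's lower absolute abundance gives
    # it a higher relative limit, which is what censors it in the double
    # mutant while dTDP at ~1% of WT stays measurable.
    detection_limit_overrides: dict[str, float] = Field(default={TRIPHOSPHATE: 0.02})
    seed: int
    # dTMP supplementation arm: doses in the growth medium and the
    # conversion from external dose to intracellular relative substrate.
    dtmp_doses_mM: list[float] = Field(default=[0.25, 0.5, 1.0, 2.0, 5.0])
    supplement_gain_per_mM: float = 1.0
    supplemented_strains: list[str] = Field(default=["WT", "W133V", "I91L+W133V"])
    # Thymidine arm: raises intracellular dTMP through the salvage
    # pathway, i.e. substrate still arrives via the cell's own enzymes,
    # so these points follow the *unsupplemented* (Hill) curve.
    thymidine_doses_mM: list[float] = Field(default=[0.25, 0.5, 1.0, 2.0])
    thymidine_gain_per_mM: float = 0.4
    thymidine_strains: list[str] = Field(default=["WT", "W133V", "I91L+W133V"])
    # Ground-truth chain, per regime.
    hill_exponent_unsupplemented: float = 2.5
    hill_exponent_supplemented: float = 1.0
    downstream_exponent: float = 1.0
    capacity_ratio: float = 2.0  # downstream vmax / upstream vmax
    k_m_rel: float = 0.6  # half-saturation, in WT-substrate units

    @field_validator(
        "replicates",
        "detection_limit",
        "supplement_gain_per_mM",
        "hill_exponent_unsupplemented",
        "hill_exponent_supplemented",
        "downstream_exponent",
        "capacity_ratio",
        "k_m_rel",
    )
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("must be > 0")
        return v

    @field_validator("noise_cv")
    @classmethod
    def _non_negative(cls, v):
        if v < 0:
            raise ValueError("must be >= 0")
        return v

    @field_validator("strains")
    @classmethod
    def _positive_folds(cls, v):
        if not v or any(f <= 0 for f in v.values()):
            raise ValueError("strain fold-drops must be > 0")
        return v

    def chain(self, dtmp_supplemented: bool) -> TwoEnzymeChain:
        m = (
            self.hill_exponent_supplemented
            if dtmp_supplemented
            else self.hill_exponent_unsupplemented
        )
        return TwoEnzymeChain(
            upstream=EnzymeParams(e_total=1.0, k_cat=1.0, k_m=self.k_m_rel, exponent=m),
            downstream=EnzymeParams(
                e_total=1.0,
                k_cat=self.capacity_ratio,
                k_m=self.k_m_rel,
                exponent=self.downstream_exponent,
            ),
            unit="relative",
        )


def _cell_rng(seed: int, *key_parts) -> np.random.Generator:
    """Independent substream per design cell.

    Keys are hashed with CRC32 so adding or removing strains/conditions
    never perturbs the draws of the remaining cells.
    """
    digest = [zlib.crc32(str(part).encode()) for part in key_parts]
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=digest))


def _expected_levels(config: SynthConfig, substrate_rel: float, supplemented: bool):
    """Expected relative (substrate, product, triphosphate) pools.

    Product pools are normalised by the WT steady state of the same
    regime; dTTP tracks dTDP (the dTDP:dTTP ratio is strain-independent).
    """
    chain = config.chain(supplemented)
    s2 = chain_steady_state_hill(chain, substrate_rel)
    s2_wt = chain_steady_state_hill(chain, 1.0)
    product_rel = s2 / s2_wt
    return substrate_rel, product_rel, product_rel


def generate_metabolomics(config: SynthConfig) -> MetabolomicsTable:
    """Generate a long-format synthetic metabolomics table.

    One record per (strain, condition, dose, timepoint, replicate,
    metabolite).  Observed value = expected level x lognormal(mean 1,
    CV = ``noise_cv``); values strictly below the detection limit are
    censored (the stored value is the limit itself).  Deterministic for a
    given seed.
    """
    sigma = lognormal_sigma(config.noise_cv)
    rows = []

    def emit(strain, condition, dose, supplemented, substrate_rel):
        expected = dict(
            zip(
                (SUBSTRATE, PRODUCT, TRIPHOSPHATE),
                _expected_levels(config, substrate_rel, supplemented),
            )
        )
        for tp in config.timepoints_h:
            for rep in range(1, config.replicates + 1):
                rng = _cell_rng(config.seed, strain, condition, dose, tp, rep)
                noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=3)
                for (met, mu), eps in zip(expected.items(), noise):
                    rows.append(
                        {
                            "strain": strain,
                            "condition": condition,
                            "supplement_mM": dose,
                            "timepoint_h": tp,
                            "replicate": rep,
                            "metabolite": met,
                            "relative_abundance": mu * eps,
                            "is_censored": False,
                        }
                    )

    for strain, fold in config.strains.items():
        emit(strain, "minimal+AA", 0.0, supplemented=False, substrate_rel=fold)
    for strain in config.thymidine_strains:
        if strain not in config.strains:
            continue
        fold = config.strains[strain]
        for dose in config.thymidine_doses_mM:
            emit(
                strain,
                "minimal+AA+thymidine",
                dose,
                supplemented=False,  # salvage-derived dTMP stays diffusion-limited
                substrate_rel=fold + config.thymidine_gain_per_mM * dose,
            )
    for strain in config.supplemented_strains:
        if strain not in config.strains:
            continue
        fold = config.strains[strain]
        for dose in config.dtmp_doses_mM:
            emit(
                strain,
                "minimal+AA+dTMP",
                dose,
                supplemented=True,
                substrate_rel=fold + config.supplement_gain_per_mM * dose,
            )

    table = MetabolomicsTable(pd.DataFrame(rows))
    limits = dict(config.detection_limit_overrides)
    for met in (SUBSTRATE, PRODUCT, TRIPHOSPHATE):
        limits.setdefault(met, config.detection_limit)
    return apply_censoring(table, limits)


def apply_censoring(
    table: MetabolomicsTable, limit: float | dict[str, float]
) -> MetabolomicsTable:
    """Censor relative abundances strictly below the detection limit.

    ``limit`` is either one relative limit for every metabolite or a
    per-metabolite mapping (metabolites absent from the mapping are left
    untouched).  Censored records retain the limit itself (an upper
    bound), not the unobservable value.  Idempotent: a second application
    with the same limit changes nothing.
    """
    df = table.df.copy()
    if isinstance(limit, dict):
        if any(v <= 0 for v in limit.values()):
            raise ValueError("detection limits must be > 0")
        per_row = df["metabolite"].map(limit)
    else:
        if limit <= 0:
            raise ValueError("detection limit must be > 0")
        per_row = pd.Series(float(limit), index=df.index)
    below = (df["relative_abundance"] < per_row) & (~df["is_censored"]) & per_row.notna()
    df.loc[below, "relative_abundance"] = per_row[below]
    df.loc[below, "is_censored"] = True
    return MetabolomicsTable(df)


def generate_assay_data(
    truth: dict,
    design: Iterable[float],
    noise_cv: float = 0.0,
    seed: int = 0,
    trace_duration: float = 60.0,
    trace_dt: float = 5.0,
    trace_signal0: float = 100.0,
) -> tuple[DoseResponsePoints, list[KineticTrace]]:
    """Synthetic in vitro assay: dose-rate points plus raw kinetic traces.

    ``truth`` names the generating rate law: ``{"model": "mm", "vmax",
    "km"}`` (rate vs substrate), ``{"model": "hill", ...}``, or
    ``{"model": "4pl", "top", "bottom", "ic50", "slope"}`` (rate vs
    inhibitor).  For each concentration in ``design``, the dose-rate point
    carries multiplicative lognormal noise and the matching trace is a
    linear consumption signal (slope = -true rate) with additive Gaussian
    noise of sd ``noise_cv * trace_signal0 / 100`` per sample, recorded
    every ``trace_dt`` seconds.  Empty designs produce empty outputs.
    """
    design = np.asarray(list(design), dtype=float)
    rng = np.random.default_rng(seed)
    model = truth["model"].lower()
    if model == "mm":
        rates = truth["vmax"] * design / (truth["km"] + design)
    elif model == "hill":
        n = truth["exponent"]
        rates = truth["vmax"] * design**n / (truth["k_half"] ** n + design**n)
    elif model == "4pl":
        ratio = np.where(design > 0, (design / truth["ic50"]) ** truth["slope"], 0.0)
        rates = truth["bottom"] + (truth["top"] - truth["bottom"]) / (1.0 + ratio)
    else:
        raise ValueError(f"unknown truth model {truth['model']!r}")

    sigma = lognormal_sigma(noise_cv)
    noisy = rates * rng.lognormal(-0.5 * sigma**2, sigma, size=len(design))
    points = DoseResponsePoints(
        x=design, y=noisy, x_unit=truth.get("x_unit", "uM"), y_unit="rate"
    )

    times = np.arange(0.0, trace_duration + trace_dt / 2, trace_dt)
    traces = []
    for rate in rates:
        signal = trace_signal0 - rate * times
        signal = signal + rng.normal(0.0, noise_cv * trace_signal0 / 100.0, len(times))
        traces.append(KineticTrace(times=times, values=signal))
    return points, traces
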