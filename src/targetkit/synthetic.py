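"""Synthetic dish-level irradiation experiments.

The generator emulates the structure of the mung-bean assay: groups of
petri dishes (50 beans each) on a fixed dose grid, one control dish per
group at dose 0. Each dish's expected mean sprout length is

    L(D) = control_mean_length * S_k(x_k * D / D37)

so the group's true survival curve passes through exp(-1) at its true
D37. Dish-to-dish variation is multiplicative lognormal with unit mean
(keeping lengths positive and letting normalized rates exceed 100%, as
observed in practice); individual bean lengths scatter additively around
the dish mean and are truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd

from .datasets import DOSE_GRID_GY, GROUP_D37_GY
from .doseresponse import DoseResponseTable
from .hitmodel import k_hit_threshold, survival_probability


@dataclass(frozen=True)
class GroupSpec:
    """One simulated group: its label, true D37 and hit tolerance."""

    group_id: str
    true_d37_gy: float
    hits_tolerated: int = 0


@dataclass(frozen=True)
class SyntheticConfig:
    """Design of a synthetic irradiation experiment.

    Defaults mirror the real assay: the {0,1,2,5,10,20,50,100,200,400} Gy
    grid, one dish of 50 beans per (group, dose), a 50 mm control mean,
    10% dish-level lognormal noise and a 5 mm within-dish bean spread.
    """

    groups: Tuple[GroupSpec, ...]
    doses: Tuple[float, ...] = DOSE_GRID_GY
    dishes_per_dose: int = 1
    beans_per_dish: int = 50
    control_mean_length_mm: float = 50.0
    noise_cv: float = 0.10
    bean_length_sd_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        problems = []
        if not self.groups:
            problems.append("groups must be non-empty")
        for g in self.groups:
            if not (g.true_d37_gy > 0):
                problems.append(f"group {g.group_id!r}: true_d37_gy must be > 0")
            if g.hits_tolerated < 0:
                problems.append(f"group {g.group_id!r}: hits_tolerated must be >= 0")
        if 0.0 not in self.doses:
            problems.append("doses must include the dose-0 control")
        if any(d < 0 for d in self.doses):
            problems.append("doses must be non-negative")
        if len(set(self.doses)) != len(self.doses):
            problems.append("doses must be unique")
        if self.dishes_per_dose < 1:
            problems.append("dishes_per_dose must be >= 1")
        if self.beans_per_dish < 1:
            problems.append("beans_per_dish must be >= 1")
        if not (self.control_mean_length_mm > 0):
            problems.append("control_mean_length_mm must be > 0")
        if self.noise_cv < 0:
            problems.append("noise_cv must be >= 0")
        if self.bean_length_sd_mm < 0:
            problems.append("bean_length_sd_mm must be >= 0")
        if problems:
            raise ValueError("invalid SyntheticConfig: " + "; ".join(problems))


@dataclass(frozen=True)
class DishRecord:
    group_id: str
    dose_gy: float
    dish: int
    bean_lengths_mm: np.ndarray

    @property
    def mean_length_mm(self) -> float:
        return float(np.mean(self.bean_lengths_mm))


@dataclass(frozen=True)
class SyntheticExperiment:
    """Generated dish records plus an echo of the true parameters."""

    config: SyntheticConfig
    records: Tuple[DishRecord, ...]

    def to_frame(self) -> pd.DataFrame:
        """Raw-dialect frame: group,dose_gy,dish,mean_length_mm,n_beans."""
        return pd.DataFrame(
            {
                "group": [r.group_id for r in self.records],
                "dose_gy": [r.dose_gy for r in self.records],
                "dish": [r.dish for r in self.records],
                "mean_length_mm": [r.mean_length_mm for r in self.records],
                "n_beans": [r.bean_lengths_mm.size for r in self.records],
            }
        )

    def to_tables(self) -> List[DoseResponseTable]:
        """Per-group tables with dish means averaged within each dose."""
        tables = []
        frame = self.to_frame()
        for spec in self.config.groups:
            sub = frame[frame["group"] == spec.group_id]
            per_dose = sub.groupby("dose_gy", sort=True).agg(
                mean_length_mm=("mean_length_mm", "mean"),
                n_beans=("n_beans", "sum"),
            )
            tables.append(
                DoseResponseTable(
                    group_id=spec.group_id,
                    doses=per_dose.index.to_numpy(),
                    mean_lengths=per_dose["mean_length_mm"].to_numpy(),
                    n_beans=per_dose["n_beans"].to_numpy(),
                )
            )
        return tables

    @property
    def true_d37(self) -> dict:
        return {g.group_id: g.true_d37_gy for g in self.config.groups}


def expected_mean_length(config: SyntheticConfig, spec: GroupSpec, dose: float) -> float:
    """Noise-free dish mean: control length times the k-hit survival."""
    x_k = k_hit_threshold(spec.hits_tolerated).threshold if spec.hits_tolerated else 1.0
    m = x_k * dose / spec.true_d37_gy
    return config.control_mean_length_mm * survival_probability(m, spec.hits_tolerated)


def generate(config: SyntheticConfig) -> SyntheticExperiment:
    """Draw one full experiment; byte-identical for identical seeds."""
    rng = np.random.default_rng(config.seed)
    # lognormal with unit mean: sigma^2 = ln(1 + cv^2), mu = -sigma^2/2
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
    records = []
    for spec in config.groups:
        for dose in config.doses:
            expected = expected_mean_length(config, spec, dose)
            for dish in range(config.dishes_per_dose):
                noise = rng.lognormal(-0.5 * sigma**2, sigma) if sigma > 0 else 1.0
                dish_mean = expected * noise
                if config.bean_length_sd_mm > 0:
                    lengths = rng.normal(
                        dish_mean, config.bean_length_sd_mm, config.beans_per_dish
                    )
                    np.clip(lengths, 0.0, None, out=lengths)
                else:
                    lengths = np.full(config.beans_per_dish, dish_mean)
                records.append(
                    DishRecord(
                        group_id=spec.group_id,
                        dose_gy=dose,
                        dish=dish,
                        bean_lengths_mm=lengths,
                    )
                )
    return SyntheticExperiment(config=config, records=tuple(records))


def mung_bean_design(
    seed: int = 0,
    noise_cv: float = 0.10,
    dishes_per_dose: int = 1,
    bean_length_sd_mm: float = 5.0,
    hits_tolerated: int = 0,
) -> SyntheticConfig:
    """The ten-group design of the original assay.

    True D37 values are the ones attributed to groups 1-10
    (:data:`targetkit.datasets.GROUP_D37_GY`); each (group, dose) cell is
    one dish of 50 beans on the standard dose grid.
    """
    groups = tuple(
        GroupSpec(group_id=g, true_d37_gy=d37, hits_tolerated=hits_tolerated)
        for g, d37 in GROUP_D37_GY.items()
    )
    return SyntheticConfig(
        groups=groups,
        doses=DOSE_GRID_GY,
        dishes_per_dose=dishes_per_dose,
        beans_per_dish=50,
        control_mean_length_mm=50.0,
        noise_cv=noise_cv,
        bean_length_sd_mm=bean_length_sd_mm,
        seed=seed,
    )
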