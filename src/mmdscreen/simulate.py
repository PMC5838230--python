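"""Synthetic shRNA screen generator with ground-truth effect labels.

Emulates the statistical structure the analysis assumes: several independent
experimental sets, each with an internal control population and a handful of
knockdown constructs; lognormal areas and logit-normal circularities;
additive per-set batch offsets shared by every population of a set (controls
included), which is exactly the structure control-centering removes; and
partial-penetrance effects, modelled as a two-component mixture in which
only a fraction of structures express the phenotype — shRNA silencing is
sporadic, so real knockdown populations are broad mixtures too.

Populations are generated on the transformed (log area, logit circularity)
scale and back-transformed to raw units, so synthetic data enters the
pipeline exactly like a real morphometry table.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .io import ONCOGENE_CONDITIONS, ScreenDataset

EFFECT_CLASSES = (
    "none",
    "small",
    "large",
    "loss_of_symmetry",
    "improved_symmetry",
    "combined",
)

CONTROL_NAME = "control"


@dataclasses.dataclass
class EffectSpec:
    """A construct's planted phenotypic effect.

    Shifts are in units of the control standard deviation on the transformed
    scales; ``inflation`` multiplies the affected component's variance;
    ``penetrance`` is the fraction of structures drawn from the affected
    component.
    """

    effect_class: str = "none"
    area_shift: float = 0.0
    circ_shift: float = 0.0
    inflation: float = 1.0
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in [0, 1]")
        if self.inflation <= 0:
            raise ValueError("variance inflation must be positive")
        if self.effect_class == "none":
            null = (self.area_shift == 0 and self.circ_shift == 0 and self.inflation == 1)
            if not (null or self.penetrance == 0):
                raise ValueError("effect class 'none' requires null shifts or penetrance 0")

    @classmethod
    def from_class(
        cls,
        effect_class: str,
        shift: float = 2.0,
        penetrance: float = 0.8,
        inflation: float = 1.0,
    ) -> "EffectSpec":
        """Canonical directional effect: shift the named trait by ``shift``
        control SDs (negative for small / loss of symmetry)."""
        area, circ = {
            "none": (0.0, 0.0),
            "small": (-shift, 0.0),
            "large": (shift, 0.0),
            "loss_of_symmetry": (0.0, -shift),
            "improved_symmetry": (0.0, shift),
            "combined": (shift, -shift),
        }[effect_class]
        if effect_class == "none":
            penetrance, inflation = 0.0, 1.0
        return cls(effect_class, area, circ, inflation, penetrance)


#: effects may be a mapping keyed by (set_index, construct_index) or a callable
EffectAssigner = Callable[[int, int], EffectSpec]


@dataclasses.dataclass
class SimConfig:
    """Stated world of the synthetic screen.

    Defaults mirror the screen design this framework targets: seven
    independent experimental sets, each with one internal control and 4-12
    knockdown constructs, on the order of 100 structures per population
    (Poisson-dispersed). Control morphometry defaults describe healthy
    acinar structures: median area e^7.5 ~ 1800 px^2 with ~50% lognormal
    spread, and circularity centred at logit^-1(1.4) ~ 0.80. Per-set batch
    offsets (0.25 control SDs by default) model the drift of sets acquired
    years apart.
    """

    n_sets: int = 7
    constructs_per_set: tuple[int, int] = (4, 12)
    structures_per_population: float = 100.0
    mean_log_area: float = 7.5
    sd_log_area: float = 0.5
    mean_logit_circ: float = 1.4
    sd_logit_circ: float = 0.6
    correlation: float = 0.0
    batch_offset_sd: float = 0.25
    effects: Mapping[tuple[int, int], EffectSpec] | EffectAssigner | None = None
    oncogene: str = "none"
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.constructs_per_set
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if not 1 <= lo <= hi:
            raise ValueError("constructs_per_set must be an increasing range >= 1")
        if min(self.sd_log_area, self.sd_logit_circ) <= 0:
            raise ValueError("control standard deviations must be positive")
        if not -1.0 < self.correlation < 1.0:
            raise ValueError("trait correlation must lie in (-1, 1)")
        if self.batch_offset_sd < 0:
            raise ValueError("batch_offset_sd must be >= 0")
        if self.structures_per_population < 2:
            raise ValueError("structures_per_population must be >= 2")
        if self.oncogene not in ONCOGENE_CONDITIONS:
            raise ValueError(f"oncogene must be one of {ONCOGENE_CONDITIONS}")

    def effect_for(self, set_index: int, construct_index: int) -> EffectSpec:
        if self.effects is None:
            return EffectSpec()
        if callable(self.effects):
            return self.effects(set_index, construct_index)
        return self.effects.get((set_index, construct_index), EffectSpec())


def simulate_population(
    config: SimConfig,
    effect: EffectSpec,
    n: int,
    rng: np.random.Generator,
    batch_offset: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Draw one population of raw (area, circularity) structures.

    Each structure comes from a two-component mixture on the transformed
    scale: the control component, or (with probability ``penetrance``) the
    shifted, variance-inflated affected component. The batch offset (in
    control-SD units) is added to both components.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    sds = np.array([config.sd_log_area, config.sd_logit_circ])
    mean = np.array([config.mean_log_area, config.mean_logit_circ]) + np.asarray(
        batch_offset
    ) * sds
    cov = np.array(
        [
            [sds[0] ** 2, config.correlation * sds[0] * sds[1]],
            [config.correlation * sds[0] * sds[1], sds[1] ** 2],
        ]
    )
    affected = rng.random(n) < effect.penetrance
    base = rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")
    values = mean + base
    shift = np.array([effect.area_shift, effect.circ_shift]) * sds
    values[affected] = mean + shift + base[affected] * np.sqrt(effect.inflation)
    area = np.exp(values[:, 0])
    circularity = 1.0 / (1.0 + np.exp(-values[:, 1]))
    return pd.DataFrame({"area": area, "circularity": circularity})


@dataclasses.dataclass
class GroundTruth:
    """Planted effect of every population, for end-to-end verification."""

    frame: pd.DataFrame  # set_id, population_id, is_control, effect fields
    batch_offsets: dict[str, tuple[float, float]]

    def effect_class_of(self, set_id: str, population_id: str) -> str:
        mask = (self.frame["set_id"] == set_id) & (
            self.frame["population_id"] == population_id
        )
        return self.frame.loc[mask, "effect_class"].iloc[0]

    def true_hits(self) -> set[tuple[str, str]]:
        sub = self.frame[(self.frame["effect_class"] != "none") & ~self.frame["is_control"]]
        return {tuple(r) for r in sub[["set_id", "population_id"]].itertuples(index=False)}


def simulate_screen(config: SimConfig) -> tuple[ScreenDataset, GroundTruth]:
    """Generate a full multi-set screen dataset plus its ground truth.

    Fully reproducible from ``config.seed``: the same config yields a
    byte-identical dataset.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.constructs_per_set
    frames, truth_rows = [], []
    offsets: dict[str, tuple[float, float]] = {}
    for s in range(1, config.n_sets + 1):
        set_id = f"set{s:02d}"
        offset = tuple(rng.normal(0.0, config.batch_offset_sd, size=2))
        offsets[set_id] = offset
        n_constructs = int(rng.integers(lo, hi + 1))
        populations = [(CONTROL_NAME, True, EffectSpec())]
        populations += [
            (f"sh{s:02d}_{k:02d}", False, config.effect_for(s - 1, k - 1))
            for k in range(1, n_constructs + 1)
        ]
        for pop_id, is_control, effect in populations:
            n = max(2, int(rng.poisson(config.structures_per_population)))
            pop = simulate_population(config, effect, n, rng, batch_offset=offset)
            pop.insert(0, "structure_id", [f"{set_id}_{pop_id}_{i:04d}" for i in range(n)])
            pop.insert(1, "set_id", set_id)
            pop.insert(2, "population_id", pop_id)
            pop.insert(3, "is_control", is_control)
            pop.insert(4, "oncogene", config.oncogene)
            frames.append(pop)
            truth_rows.append(
                {
                    "set_id": set_id,
                    "population_id": pop_id,
                    "is_control": is_control,
                    **dataclasses.asdict(effect),
                }
            )
    records = pd.concat(frames, ignore_index=True)
    ds = ScreenDataset(
        records=records,
        units="pixel^2",
        provenance=f"synthetic screen, seed={config.seed}",
    )
    truth = GroundTruth(frame=pd.DataFrame(truth_rows), batch_offsets=offsets)
    return ds, truth


def two_class_effects(
    classes: tuple[str, str] = ("small", "large"),
    shift: float = 2.0,
    penetrance: float = 0.8,
) -> EffectAssigner:
    """Assigner planting two effect classes, alternating across constructs.

    Every construct is affected; even construct indices get the first class,
    odd the second. Used for planted-partition recovery experiments.
    """

    def assign(set_index: int, construct_index: int) -> EffectSpec:
        name = classes[construct_index % 2]
        return EffectSpec.from_class(name, shift=shift, penetrance=penetrance)

    return assign
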