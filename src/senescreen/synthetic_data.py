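"""Seeded stochastic simulator of telomere-initiated senescence screens.

Telomerase-deficient cultures grow well at first, decline to a fitness
nadir as telomeres erode, and then a random subset of replicate cultures
escapes senescence ("survivors") while some others go permanently sterile.
The simulator emulates exactly this: a deterministic decline/regrowth
skeleton in log-fitness, plus three stochastic ingredients per culture —
a Bernoulli recovery decision, a geometric recovery delay, and a geometric
sterility time — under multiplicative lognormal measurement noise.

The pace of decline and regrowth is tied to the serial-dilution design:
each passage permits at most ``log2(dilution_factor)`` cell divisions, so
the liquid design (dilution ~1:70, ~6.1 divisions/passage) senesces faster
than the solid pinned design (dilution at most 16-fold, 4 divisions per
passage).  Ground-truth class labels are returned with every simulated
screen so downstream classification can be scored against the generator.

Sizes are produced on the *raw* integrated-intensity scale; the default
initial fitness of 1e6 raw units lands near 4000 units after the
variance-stabilizing power transform (see :mod:`senescreen.profile`),
matching the fitness scale healthy cultures show in real screens.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml

from .plate_model import (
    CultureSeries,
    PlateLayout,
    ScreenDataset,
    WellPosition,
    build_solid_layout,
)

__all__ = [
    "ClassParams",
    "NoiseModel",
    "SimConfig",
    "DEFAULT_DILUTION",
    "preset_classes",
    "simulate_culture",
    "simulate_screen",
    "load_scenario",
    "archetype_scenario",
    "fitness_ladder_scenario",
]

#: Default fold-dilution per passage for each screen design.
DEFAULT_DILUTION = {"liquid": 70.0, "solid": 16.0}


@dataclass(frozen=True)
class ClassParams:
    """Generative parameters for one genotype class.

    Attributes
    ----------
    initial_fitness : raw culture-size units before senescence begins.
    onset_passage : passage after which fitness starts to decline.
    decline_rate : fractional log-fitness lost per division after onset.
    nadir_fraction : fitness floor as a fraction of ``initial_fitness``.
    recovery_prob : probability that a culture ever produces survivors (rho).
    recovery_onset_mean : mean passages after the nadir until regrowth starts
        (geometric, support >= 1).
    regrowth_rate : fractional log-fitness gained per division once
        survivors take over, capped at ``initial_fitness``.
    extinction_prob : per-passage probability that a deeply senescent,
        non-recovering culture becomes permanently sterile.
    """

    label: str
    initial_fitness: float = 1.0e6
    onset_passage: float = 2.0
    decline_rate: float = 0.20
    nadir_fraction: float = 0.007
    recovery_prob: float = 0.50
    recovery_onset_mean: float = 2.0
    regrowth_rate: float = 0.30
    extinction_prob: float = 0.05

    def __post_init__(self) -> None:
        for name in ("recovery_prob", "extinction_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.nadir_fraction < 1.0:
            raise ValueError("nadir_fraction must be in [0, 1)")
        if self.initial_fitness <= 0:
            raise ValueError("initial_fitness must be positive")
        if self.recovery_onset_mean < 1.0:
            raise ValueError("recovery_onset_mean must be >= 1 passage")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal measurement noise with a detection floor.

    ``cv`` is the coefficient of variation of the mean-1 lognormal factor;
    raw sizes falling below ``detection_floor`` are recorded as 0, the way
    an image-quantification tool reports an empty spot.
    """

    cv: float = 0.25
    detection_floor: float = 1.0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.detection_floor < 0:
            raise ValueError("detection_floor must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    """Simulation-wide settings: seed, passage count, design and dilution."""

    seed: int
    passage_count: int
    design: str = "solid"
    dilution_factor: float | None = None
    class_map: Mapping[str, ClassParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.design not in DEFAULT_DILUTION:
            raise ValueError(f"unknown design {self.design!r}")
        if self.dilution_factor is None:
            object.__setattr__(self, "dilution_factor", DEFAULT_DILUTION[self.design])
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        if self.passage_count < 1:
            raise ValueError("passage_count must be positive")

    @property
    def divisions_per_passage(self) -> float:
        return math.log2(self.dilution_factor)


def preset_classes() -> dict[str, ClassParams]:
    """Reference parameter sets for the four canonical genotype classes.

    ``normal`` mirrors wild-type-control-like behaviour: full initial
    fitness, decline beginning after passage 2 (a nadir near passage 6
    under liquid dilution), and survivors in half of the cultures.
    ``no_recovery`` is recombination-deficient-like: lower initial fitness,
    earlier onset, and survivors in only 29% of cultures.
    ``fast_recovery`` is telomere-capping-mutant-like: accelerated entry
    into senescence and early, frequent (81%) recovery.
    ``neutral_nonsensescing`` is a flat, telomerase-proficient-like control.
    """
    return {
        "normal": ClassParams(
            label="normal",
            initial_fitness=1.0e6,
            onset_passage=2.0,
            decline_rate=0.20,
            nadir_fraction=0.007,
            recovery_prob=0.50,
            recovery_onset_mean=2.0,
            regrowth_rate=0.30,
            extinction_prob=0.05,
        ),
        "no_recovery": ClassParams(
            label="no_recovery",
            initial_fitness=5.0e5,
            onset_passage=1.0,
            decline_rate=0.28,
            nadir_fraction=0.004,
            recovery_prob=0.29,
            recovery_onset_mean=3.0,
            regrowth_rate=0.25,
            extinction_prob=0.08,
        ),
        "fast_recovery": ClassParams(
            label="fast_recovery",
            initial_fitness=1.0e6,
            onset_passage=1.0,
            decline_rate=0.30,
            nadir_fraction=0.007,
            recovery_prob=0.81,
            recovery_onset_mean=1.0,
            regrowth_rate=0.40,
            extinction_prob=0.05,
        ),
        "neutral_nonsenescing": ClassParams(
            label="neutral_nonsenescing",
            initial_fitness=1.0e6,
            onset_passage=1.0e9,
            decline_rate=0.0,
            nadir_fraction=0.99,
            recovery_prob=0.0,
            recovery_onset_mean=1.0,
            regrowth_rate=0.0,
            extinction_prob=0.0,
        ),
    }


# ---------------------------------------------------------------------------
# single-culture trajectory
# ---------------------------------------------------------------------------

def _nadir_passage(params: ClassParams, divisions: float) -> float:
    """First passage at which the deterministic decline reaches the floor
    (may exceed the experiment length; inf if fitness never declines)."""
    if params.decline_rate <= 0 or params.nadir_fraction <= 0:
        return math.inf
    drop = -math.log(params.nadir_fraction)
    per_passage = params.decline_rate * divisions
    return params.onset_passage + math.ceil(drop / per_passage)


def simulate_culture(
    params: ClassParams,
    noise: NoiseModel,
    config: SimConfig,
    rng: np.random.Generator,
    position=None,
    genotype: str | None = None,
) -> CultureSeries:
    """Simulate one culture's size trajectory across all passages.

    Deterministic given ``(params, noise, config)`` and the state of
    ``rng``.  The trajectory follows the class skeleton: flat at
    ``initial_fitness`` through ``onset_passage``, exponential decline to
    the nadir at ``decline_rate`` per division, then — for the
    Bernoulli(``recovery_prob``) fraction of cultures — exponential
    regrowth back toward initial fitness after a geometric delay.
    Non-recovering cultures risk permanent sterility (exact zeros) at each
    deeply senescent passage.
    """
    P = config.passage_count
    d = config.divisions_per_passage
    ln_init = math.log(params.initial_fitness)
    ln_floor = ln_init + math.log(params.nadir_fraction) if params.nadir_fraction > 0 else -math.inf

    passages = np.arange(1, P + 1, dtype=float)
    lnf = np.full(P, ln_init)
    declining = passages > params.onset_passage
    lnf[declining] = np.maximum(
        ln_init - params.decline_rate * d * (passages[declining] - params.onset_passage),
        ln_floor,
    )

    nadir = _nadir_passage(params, d)

    recovers = bool(rng.random() < params.recovery_prob)
    if recovers and math.isfinite(nadir):
        delay = int(rng.geometric(1.0 / params.recovery_onset_mean))
        start = nadir + delay
        growing = passages >= start
        if params.regrowth_rate > 0:
            lnf[growing] = np.minimum(
                ln_floor + params.regrowth_rate * d * (passages[growing] - start + 1),
                ln_init,
            )
    extinct_at: float = math.inf
    if not recovers and params.extinction_prob > 0 and math.isfinite(nadir):
        for p in range(max(1, math.ceil(nadir)), P + 1):
            if rng.random() < params.extinction_prob:
                extinct_at = p
                break

    sizes = np.exp(lnf)
    if noise.cv > 0:
        sigma = math.sqrt(math.log1p(noise.cv**2))
        sizes = sizes * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=P)
    sizes[passages >= extinct_at] = 0.0
    sizes[sizes < noise.detection_floor] = 0.0

    return CultureSeries(
        position=position or WellPosition("sim", 1, 1),
        genotype=genotype or params.label,
        sizes=sizes,
    )


# ---------------------------------------------------------------------------
# whole-screen simulation
# ---------------------------------------------------------------------------

def _culture_seed_sequence(seed: int, plate_id: str, row: int, col: int) -> np.random.SeedSequence:
    # stable per-position substream: adding plates never perturbs existing cultures
    plate_key = zlib.crc32(plate_id.encode("utf-8"))
    return np.random.SeedSequence(entropy=seed, spawn_key=(plate_key, row, col))


def simulate_screen(
    layouts: list[PlateLayout],
    config: SimConfig,
    noise: NoiseModel | None = None,
) -> tuple[ScreenDataset, dict[str, str]]:
    """Simulate every assigned position of the given layouts.

    Each culture gets an independent RNG substream derived from
    ``(seed, plate_id, row, col)``, so results are reproducible
    position-by-position regardless of iteration order.

    Returns the raw-scale dataset and a map genotype -> ground-truth class
    label for parameter-recovery scoring.
    """
    noise = noise or NoiseModel()
    truth: dict[str, str] = {}
    cultures: list[CultureSeries] = []
    for layout in layouts:
        for pos in sorted(layout.assignment):
            genotype = layout.assignment[pos]
            try:
                params = config.class_map[genotype]
            except KeyError:
                raise KeyError(
                    f"genotype {genotype!r} on plate {layout.plate_id} has no "
                    "entry in config.class_map"
                ) from None
            truth[genotype] = params.label
            rng = np.random.default_rng(
                _culture_seed_sequence(config.seed, pos.plate_id, pos.row, pos.col)
            )
            cultures.append(
                simulate_culture(params, noise, config, rng, position=pos, genotype=genotype)
            )
    dataset = ScreenDataset(
        cultures=cultures,
        passage_count=config.passage_count,
        scale="raw",
        design=config.design,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# scenario configuration
# ---------------------------------------------------------------------------

def archetype_scenario(
    n_per_class: int = 40,
    replicates: int = 8,
    archetype_replicates: int = 36,
    seed: int = 1,
    design: str = "solid",
    passage_count: int = 22,
    noise_cv: float = 0.25,
) -> dict:
    """Scenario dict for the canonical three-class recovery experiment.

    ``n_per_class`` query genotypes are drawn from each senescing preset
    (normal / no_recovery / fast_recovery) at ``replicates`` cultures each;
    the three archetype genotypes themselves (his3, rad52, rif1) are
    simulated from the same presets at ``archetype_replicates`` cultures,
    mirroring the heavier replication of controls in real screens.
    """
    genotypes: dict[str, dict] = {
        "his3": {"preset": "normal", "replicates": archetype_replicates},
        "rad52": {"preset": "no_recovery", "replicates": archetype_replicates},
        "rif1": {"preset": "fast_recovery", "replicates": archetype_replicates},
    }
    for cls in ("normal", "no_recovery", "fast_recovery"):
        for i in range(n_per_class):
            genotypes[f"{cls}_{i:03d}"] = {"preset": cls, "replicates": replicates}
    return {
        "seed": seed,
        "design": design,
        "passage_count": passage_count,
        "noise": {"cv": noise_cv, "detection_floor": 1.0},
        "genotypes": genotypes,
    }


def fitness_ladder_scenario(
    n_levels: int = 23,
    genotypes_per_level: int = 3,
    replicates: int = 8,
    seed: int = 7,
    base_level: float = 1000.0,
    level_step: float = 500.0,
    noise_cv: float = 0.05,
    lambda_power: float = 0.6,
) -> dict:
    """Scenario with ``n_levels`` groups of non-senescing genotypes at
    well-separated fitness levels — a known-ground-truth instance for
    cluster-recovery experiments (RMS distance separates the levels;
    within-level scatter is noise only).

    Level *i* sits at ``base_level + i * level_step`` on the transformed
    scale; raw initial fitness is back-computed through the power
    transform so the separation is exact after variance stabilization.
    """
    genotypes: dict[str, dict] = {}
    for i in range(n_levels):
        level = base_level + level_step * i
        raw = level ** (1.0 / lambda_power)
        for j in range(genotypes_per_level):
            genotypes[f"lvl{i:02d}_{j}"] = {
                "preset": "neutral_nonsenescing",
                "initial_fitness": raw,
                "replicates": replicates,
            }
    return {
        "seed": seed,
        "design": "solid",
        "passage_count": 22,
        "noise": {"cv": noise_cv, "detection_floor": 0.0},
        "genotypes": genotypes,
    }


def load_scenario(source) -> tuple[list[PlateLayout], SimConfig, NoiseModel]:
    """Build layouts, SimConfig and NoiseModel from a scenario mapping.

    ``source`` is a dict or a path to a YAML file with keys::

        seed: 1                     # mandatory
        design: solid | liquid
        passage_count: 22
        dilution_factor: 16         # optional, defaults by design
        noise: {cv: 0.25, detection_floor: 1.0}
        genotypes:
          his3: normal              # preset name, or
          geneX: {preset: normal, replicates: 8, recovery_prob: 0.7}

    Per-genotype entries may override any :class:`ClassParams` field.
    """
    if not isinstance(source, Mapping):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    if "seed" not in source:
        raise ValueError("scenario must specify a seed")
    presets = preset_classes()
    class_map: dict[str, ClassParams] = {}
    scheme: dict[str, int] = {}
    default_reps = int(source.get("replicates", 8))
    for genotype, entry in source["genotypes"].items():
        if isinstance(entry, str):
            entry = {"preset": entry}
        entry = dict(entry)
        preset_name = entry.pop("preset", "normal")
        if preset_name not in presets:
            raise ValueError(
                f"unknown preset {preset_name!r} for genotype {genotype!r}"
            )
        reps = int(entry.pop("replicates", default_reps))
        overrides = {k: float(v) for k, v in entry.items()}
        class_map[genotype] = replace(presets[preset_name], **overrides)
        scheme[genotype] = reps

    design = source.get("design", "solid")
    config = SimConfig(
        seed=int(source["seed"]),
        passage_count=int(source.get("passage_count", 22 if design == "solid" else 16)),
        design=design,
        dilution_factor=source.get("dilution_factor"),
        class_map=class_map,
    )
    noise_cfg = source.get("noise", {})
    noise = NoiseModel(
        cv=float(noise_cfg.get("cv", 0.25)),
        detection_floor=float(noise_cfg.get("detection_floor", 1.0)),
    )
    layouts = build_solid_layout(
        genotype_list=sorted(scheme),
        replicate_scheme=scheme,
        control_label=None,  # scenarios list every genotype explicitly
        default_replicates=default_reps,
    )
    # scenario layouts inherit the scenario design even when packed 1536-style
    for layout in layouts:
        layout.design = design
    return layouts, config, noise
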