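"""Mutation-rate arithmetic.

Converts a filtered somatic-mutation count, together with the empirically
measured false-positive load and recovery rate, into rates per metre of
physical growth, per year, and per generation, plus the cross-species
per-metre comparison used for tall conifers.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


class RateError(ValueError):
    pass


@dataclass
class RateInputs:
    """Inputs to the rate calculation; defaults mirror the motivating study.

    n_called            high-confidence somatic calls in the real run
    fp_per_experiment   false-positive calls per permutation experiment
    recovery_rate       fraction of planted spikes the pipeline recovers
    total_branch_length_m  summed metres of sampled physical branches
    diploid_callable_bases callable diploid genome size (bases)
    tip_path_m          (min, max) metres from ground to sampled tips
    age_range_yr        (min, max) plausible age of the individual
    generation_height_m (min, max) metres of growth before seed set
    """

    n_called: float = 90.0
    fp_per_experiment: float = 0.11
    recovery_rate: float = 0.2995
    total_branch_length_m: float = 90.1
    diploid_callable_bases: float = 1.21e9
    tip_path_m: tuple[float, float] = (8.4, 20.3)
    age_range_yr: tuple[float, float] = (50.0, 200.0)
    generation_height_m: tuple[float, float] = (15.0, 30.0)

    def __post_init__(self) -> None:
        if not 0 < self.recovery_rate <= 1:
            raise RateError("recovery_rate must be in (0, 1]")
        if self.total_branch_length_m <= 0 or self.diploid_callable_bases <= 0:
            raise RateError("lengths and genome size must be positive")
        for lo, hi in (self.tip_path_m, self.age_range_yr, self.generation_height_m):
            if lo > hi:
                raise RateError("range endpoints must be ordered")


@dataclass
class RateEstimate:
    n_true: float
    n_true_rounded: int
    per_genome_per_metre: float
    per_base_per_metre: float
    per_base_per_year: tuple[float, float]
    per_generation: tuple[float, float]

    def as_dict(self) -> dict:
        return asdict(self)


def corrected_count(n_called: float, fp_per_experiment: float,
                    recovery_rate: float) -> float:
    """True mutation count: (called - expected false positives) / recovery."""
    if recovery_rate <= 0:
        raise RateError("recovery_rate must be positive")
    if fp_per_experiment > n_called:
        raise RateError("false-positive load exceeds the call count")
    return (n_called - fp_per_experiment) / recovery_rate


def per_metre_rates(n_true: float, total_m: float, diploid_bases: float):
    """(per diploid genome per metre, per base per metre)."""
    if total_m <= 0 or diploid_bases <= 0:
        raise RateError("denominators must be positive")
    per_genome = n_true / total_m
    return per_genome, per_genome / diploid_bases


def per_year_range(per_base_per_metre: float, tip_min_m: float, tip_max_m: float,
                   age_min_yr: float, age_max_yr: float) -> tuple[float, float]:
    """Per-base per-year range for a single apical meristem: the slowest
    lineage over the oldest age to the longest lineage over the youngest."""
    if age_min_yr <= 0 or age_max_yr <= 0:
        raise RateError("ages must be positive")
    if tip_min_m > tip_max_m or age_min_yr > age_max_yr:
        raise RateError("ranges must be ordered")
    return (tip_min_m * per_base_per_metre / age_max_yr,
            tip_max_m * per_base_per_metre / age_min_yr)


def per_generation_range(per_base_per_metre: float, height_min_m: float,
                         height_max_m: float) -> tuple[float, float]:
    """Heritable per-generation range assuming a seed forms after
    height_min..height_max metres of linear growth."""
    if height_min_m <= 0 or height_max_m <= 0:
        raise RateError("heights must be positive")
    if height_min_m > height_max_m:
        raise RateError("heights must be ordered")
    return (height_min_m * per_base_per_metre, height_max_m * per_base_per_metre)


def cross_species_per_metre(per_generation_rate: float, height_m: float) -> float:
    """Per-base per-metre rate implied by a per-generation rate and the
    growth (height) separating generations."""
    if height_m <= 0:
        raise RateError("height must be positive")
    return per_generation_rate / height_m


def estimate_rates(inputs: RateInputs) -> RateEstimate:
    n_true = corrected_count(inputs.n_called, inputs.fp_per_experiment,
                             inputs.recovery_rate)
    per_genome, per_base = per_metre_rates(n_true, inputs.total_branch_length_m,
                                           inputs.diploid_callable_bases)
    per_year = per_year_range(per_base, *inputs.tip_path_m, *inputs.age_range_yr)
    per_gen = per_generation_range(per_base, *inputs.generation_height_m)
    return RateEstimate(n_true=n_true, n_true_rounded=round(n_true),
                        per_genome_per_metre=per_genome,
                        per_base_per_metre=per_base,
                        per_base_per_year=per_year,
                        per_generation=per_gen)
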