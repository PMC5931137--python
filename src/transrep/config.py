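"""Simulation and pipeline configuration.

The default :class:`SimConfig` encodes the study design the analysis is
built around: three populations with divergent allele frequencies
(African-American-like, Latino-like, Japanese-American-like), 18 nested
case-control strata (6 per population), 65 risk regions carrying an
index variant tagging a functional variant through block LD, a
chip-plan that removes a fixed set of score variants from a subset of
two populations (Metabochip-style block missingness), and per-variant
imputation INFO scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class StratumSpec:
    label: str
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError(f"stratum {self.label}: counts must be positive")


@dataclass
class PopulationSpec:
    label: str
    n_cases: int
    n_controls: int
    fst: float
    strata: list[StratumSpec]

    def __post_init__(self) -> None:
        if not 0 <= self.fst < 1:
            raise ValueError(f"{self.label}: Fst must be in [0, 1)")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError(f"{self.label}: counts must be positive")
        ca = sum(s.n_cases for s in self.strata)
        co = sum(s.n_controls for s in self.strata)
        if (ca, co) != (self.n_cases, self.n_controls):
            raise ValueError(
                f"{self.label}: stratum counts ({ca} cases, {co} controls) do not "
                f"sum to population totals ({self.n_cases}, {self.n_controls})"
            )


@dataclass
class RegionSpec:
    """One risk region: a block of variants with an index and a functional variant."""

    region_id: str
    chrom: str
    start: int
    end: int
    n_variants: int
    ancestral_freqs: list[float]
    ld_decay_length: float  # base pairs; latent correlation = exp(-distance/length)
    index_variant: str
    functional_variant: str
    target_r2: float  # index-functional r2 aimed for in every population
    functional_or: float  # per-allele odds ratio of the functional variant

    def __post_init__(self) -> None:
        if len(self.ancestral_freqs) != self.n_variants:
            raise ValueError(f"{self.region_id}: need one ancestral frequency per variant")
        ids = self.variant_ids()
        if self.index_variant not in ids or self.functional_variant not in ids:
            raise ValueError(f"{self.region_id}: index/functional variant not in region")
        if not 0 <= self.target_r2 <= 1:
            raise ValueError(f"{self.region_id}: target r2 must be in [0, 1]")
        if self.functional_or <= 0:
            raise ValueError(f"{self.region_id}: odds ratio must be positive")
        if self.start >= self.end:
            raise ValueError(f"{self.region_id}: window start must precede end")

    def variant_ids(self) -> list[str]:
        return [f"{self.region_id}_v{j:02d}" for j in range(self.n_variants)]

    def positions(self) -> np.ndarray:
        """Variant positions, evenly spaced across the window."""
        return np.linspace(self.start, self.end, self.n_variants).round().astype(int)


@dataclass
class CovariateModel:
    """Distributions and disease log-odds of the non-genetic covariates."""

    age_mean: float = 60.0
    age_sd: float = 8.0
    bmi_mean: float = 27.0
    bmi_sd: float = 4.5
    male_fraction: float = 0.5
    beta_age: float = 0.03  # log-odds per year
    beta_sex: float = 0.4  # male vs female
    beta_bmi: float = 0.03  # log-odds per kg/m2


@dataclass
class ChipBlock:
    """A sample subset genotyped on a chip missing a fixed variant set."""

    name: str
    populations: list[str]
    sample_fraction: float
    missing_variants: list[str]

    def __post_init__(self) -> None:
        if not 0 <= self.sample_fraction <= 1:
            raise ValueError(f"chip block {self.name}: fraction must be in [0, 1]")


@dataclass
class InfoModel:
    """Law for per-variant, per-stratum imputation INFO scores.

    A fraction of variant x stratum cells draw from ``low_range`` (below
    the conventional 0.8 filter, to exercise it); the rest draw from
    ``high_range``.  ``forced`` pins named variants to a fixed score in
    every stratum.
    """

    low_fraction: float = 0.03
    low_range: tuple[float, float] = (0.5, 0.8)
    high_range: tuple[float, float] = (0.85, 1.0)
    forced: dict[str, float] = field(default_factory=dict)


@dataclass
class SimConfig:
    populations: list[PopulationSpec]
    regions: list[RegionSpec]
    covariates: CovariateModel = field(default_factory=CovariateModel)
    chip_plan: list[ChipBlock] = field(default_factory=list)
    info_model: InfoModel = field(default_factory=InfoModel)
    baseline_log_odds: float = -3.0
    claims_fraction: float = 0.75  # controls carrying at least one claim record
    prior_condition_fraction: float = 0.35  # samples with a pre-existing condition
    pool_factor: float = 2.5  # source-population size relative to target counts
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("population labels must be unique")
        strata = [s.label for p in self.populations for s in p.strata]
        if len(set(strata)) != len(strata):
            raise ValueError("stratum labels must be unique")

    @property
    def population_labels(self) -> list[str]:
        return [p.label for p in self.populations]

    def all_variant_ids(self) -> list[str]:
        return [v for r in self.regions for v in r.variant_ids()]


def _split_counts(total: int, k: int) -> list[int]:
    base, rem = divmod(total, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def _make_population(
    label: str, n_cases: int, n_controls: int, fst: float, n_strata: int
) -> PopulationSpec:
    cases = _split_counts(n_cases, n_strata)
    controls = _split_counts(n_controls, n_strata)
    strata = [
        StratumSpec(f"{label}_s{i + 1}", ca, co)
        for i, (ca, co) in enumerate(zip(cases, controls))
    ]
    return PopulationSpec(label, n_cases, n_controls, fst, strata)


def _make_regions(
    n_regions: int,
    n_variants: int,
    rng: np.random.Generator,
    functional_or: float = 1.12,
    n_effect_regions: int | None = None,
    target_r2: float = 0.8,
) -> list[RegionSpec]:
    """Regions with ancestral frequencies drawn once from a common-variant law."""
    regions = []
    effect = (
        np.arange(n_regions)
        if n_effect_regions is None
        else rng.choice(n_regions, size=n_effect_regions, replace=False)
    )
    effect = set(int(i) for i in np.atleast_1d(effect))
    for r in range(n_regions):
        freqs = rng.uniform(0.08, 0.5, size=n_variants).round(3)
        rid = f"r{r + 1:02d}"
        mid = n_variants // 2
        # the functional variant rides the same haplotype background as the
        # index, so their ancestral frequencies match
        freqs[min(mid + 2, n_variants - 1)] = freqs[mid]
        freqs = freqs.tolist()
        regions.append(
            RegionSpec(
                region_id=rid,
                chrom=str(r % 22 + 1),
                start=1_000_000 * (r + 1),
                end=1_000_000 * (r + 1) + 200_000,
                n_variants=n_variants,
                ancestral_freqs=freqs,
                ld_decay_length=100_000.0,
                index_variant=f"{rid}_v{mid:02d}",
                functional_variant=f"{rid}_v{min(mid + 2, n_variants - 1):02d}",
                target_r2=target_r2,
                functional_or=functional_or if r in effect else 1.0,
            )
        )
    return regions


def default_config(seed: int = 0) -> SimConfig:
    """Study-scale default: 3 populations, 18 strata, 65 regions x 30 variants.

    Case/control totals match the analyzed study sample: 2,376/4,139
    (African Americans), 2,291/3,818 (Latinos) and 1,368/3,294 (Japanese
    Americans), each split evenly over 6 nested case-control strata.  A
    chip block removes 20 of the 65 index variants from a subset of the
    first and third populations, mirroring Metabochip-style missingness.
    """
    rng = np.random.default_rng(seed)
    pops = [
        _make_population("AFR_AM", 2376, 4139, 0.10, 6),
        _make_population("LAT", 2291, 3818, 0.06, 6),
        _make_population("JPN_AM", 1368, 3294, 0.12, 6),
    ]
    regions = _make_regions(65, 30, rng, functional_or=1.12, n_effect_regions=20)
    chip_missing = [r.index_variant for r in regions[:20]]
    chip = [ChipBlock("metabochip", ["AFR_AM", "JPN_AM"], 0.3, chip_missing)]
    return SimConfig(populations=pops, regions=regions, chip_plan=chip, seed=seed)


def small_config(
    seed: int = 0,
    n_cases: int = 150,
    n_controls: int = 250,
    n_regions: int = 8,
    n_variants: int = 8,
    n_strata: int = 2,
    functional_or: float = 1.12,
    n_effect_regions: int | None = None,
    chip: bool = False,
) -> SimConfig:
    """Reduced design with the same structure, for fast end-to-end runs."""
    rng = np.random.default_rng(seed)
    pops = [
        _make_population("AFR_AM", n_cases, n_controls, 0.10, n_strata),
        _make_population("LAT", n_cases, n_controls, 0.06, n_strata),
        _make_population("JPN_AM", n_cases, n_controls, 0.12, n_strata),
    ]
    regions = _make_regions(
        n_regions, n_variants, rng, functional_or, n_effect_regions
    )
    chip_plan = []
    if chip:
        k = max(1, n_regions // 3)
        chip_plan = [
            ChipBlock(
                "metabochip",
                ["AFR_AM", "JPN_AM"],
                0.3,
                [r.index_variant for r in regions[:k]],
            )
        ]
    return SimConfig(populations=pops, regions=regions, chip_plan=chip_plan, seed=seed)


def null_config(seed: int = 0, **kwargs) -> SimConfig:
    """Small design with every genetic effect set to zero."""
    kwargs.setdefault("functional_or", 1.0)
    kwargs["n_effect_regions"] = 0
    return small_config(seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------


def config_to_yaml(cfg: SimConfig, path) -> None:
    def enc(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return {k: enc(getattr(obj, k)) for k in obj.__dataclass_fields__}
        if isinstance(obj, (list, tuple)):
            return [enc(x) for x in obj]
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        return obj

    Path(path).write_text(yaml.safe_dump(enc(cfg), sort_keys=False))


def config_from_yaml(path) -> SimConfig:
    raw = yaml.safe_load(Path(path).read_text())
    pops = [
        PopulationSpec(
            label=p["label"],
            n_cases=p["n_cases"],
            n_controls=p["n_controls"],
            fst=p["fst"],
            strata=[StratumSpec(**s) for s in p["strata"]],
        )
        for p in raw["populations"]
    ]
    regions = [RegionSpec(**r) for r in raw["regions"]]
    cov = CovariateModel(**raw.get("covariates", {}))
    chip = [ChipBlock(**c) for c in raw.get("chip_plan", [])]
    im_raw = dict(raw.get("info_model", {}))
    if "low_range" in im_raw:
        im_raw["low_range"] = tuple(im_raw["low_range"])
    if "high_range" in im_raw:
        im_raw["high_range"] = tuple(im_raw["high_range"])
    info = InfoModel(**im_raw)
    return SimConfig(
        populations=pops,
        regions=regions,
        covariates=cov,
        chip_plan=chip,
        info_model=info,
        baseline_log_odds=raw.get("baseline_log_odds", -3.0),
        claims_fraction=raw.get("claims_fraction", 0.75),
        prior_condition_fraction=raw.get("prior_condition_fraction", 0.35),
        pool_factor=raw.get("pool_factor", 2.5),
        seed=raw.get("seed", 0),
    )
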