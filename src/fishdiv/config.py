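"""Run configuration for the diversity pipeline.

Every tunable of the analysis lives here so that a single YAML file (or a
single dataclass instance) pins an entire run: rarefaction Monte-Carlo sizes,
PGLS bootstrap settings, model-suite switches and the I/O synonym maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml


@dataclass
class RarefactionConfig:
    """Settings for the quasi-ML allele rarefaction search.

    Defaults follow the procedure this estimator implements: a pool of one
    million Hardy-Weinberg genotypes per candidate, 100 resampling
    replicates, a floor of 2 alleles, no statistical ceiling, and a guard of
    10 candidates past any new optimum before the search stops.
    """

    pool_size: int = 1_000_000
    reps: int = 100
    guard: int = 10
    floor: int = 2
    #: replace the Monte-Carlo inner loop with the closed-form expected
    #: allele count (much faster; identical search logic).
    fast_path: bool = False
    #: hard cap on candidates examined in one search; a pure loop guard for
    #: the saturated regime (tiny n, huge reported count) where the expected
    #: count approaches its ceiling so slowly that the guard never triggers
    #: analytically.
    max_candidates: int = 1000


@dataclass
class PGLSConfig:
    bootstrap_iterations: int = 10_000
    ci_level: float = 0.95
    ci_method: str = "percentile"
    nugget: float = 1e-8
    #: consecutive redraw limit for resamples that empty a factor level
    max_redraws: int = 1000


@dataclass
class SuiteConfig:
    #: minimum usable species for a model to be fitted rather than skipped
    min_n: int = 10
    #: log10-transform fecundity before regression (raw egg counts span
    #: 10^2-10^7, which makes raw-scale slopes uninterpretable)
    log10_fecundity: bool = False
    log10_age: bool = False


@dataclass
class IOConfig:
    #: class names accepted as the bony-fish clade for the PGLS trim
    osteichthyes_synonyms: tuple[str, ...] = ("Osteichthyes", "Actinopterygii")
    #: header synonyms: canonical column -> accepted variants
    column_synonyms: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "species_id": ("species", "binomial", "species_name"),
            "class_rank": ("class", "taxclass"),
            "order_rank": ("order",),
            "family_rank": ("family",),
            "genus_rank": ("genus",),
            "habitat": ("dominant_habitat", "habitat_type"),
            "iucn_category": ("iucn", "iucn_status", "red_list_category"),
            "age_at_maturity": ("min_age_at_maturity", "maturity_years"),
            "fecundity": ("max_fecundity", "fecundity_eggs"),
            "n_individuals": ("n", "sample_size", "individuals"),
            "n_loci": ("loci", "num_loci"),
            "mean_obs_het": ("heterozygosity", "mean_heterozygosity", "ho"),
            "mean_alleles": ("mean_na", "alleles_per_locus", "na"),
            "rarefied_alleles": ("rarefied_na",),
        }
    )
    strict: bool = False


@dataclass
class Config:
    rarefaction: RarefactionConfig = field(default_factory=RarefactionConfig)
    pgls: PGLSConfig = field(default_factory=PGLSConfig)
    suite: SuiteConfig = field(default_factory=SuiteConfig)
    io: IOConfig = field(default_factory=IOConfig)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def _merge(dc_cls, data: Mapping[str, Any]):
    known = {f for f in dc_cls.__dataclass_fields__}
    bad = set(data) - known
    if bad:
        raise KeyError(f"unknown {dc_cls.__name__} keys: {sorted(bad)}")
    return dc_cls(**data)


def load_config(path: str | Path | None = None) -> Config:
    """Load a :class:`Config` from YAML; missing blocks keep their defaults."""
    if path is None:
        return Config()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = Config()
    if "rarefaction" in raw:
        cfg.rarefaction = _merge(RarefactionConfig, raw["rarefaction"])
    if "pgls" in raw:
        cfg.pgls = _merge(PGLSConfig, raw["pgls"])
    if "suite" in raw:
        cfg.suite = _merge(SuiteConfig, raw["suite"])
    if "io" in raw:
        io_raw = dict(raw["io"])
        if "osteichthyes_synonyms" in io_raw:
            io_raw["osteichthyes_synonyms"] = tuple(io_raw["osteichthyes_synonyms"])
        if "column_synonyms" in io_raw:
            io_raw["column_synonyms"] = {
                k: tuple(v) for k, v in io_raw["column_synonyms"].items()
            }
        cfg.io = _merge(IOConfig, io_raw)
    return cfg
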