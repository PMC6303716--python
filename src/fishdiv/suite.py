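"""End-to-end model suite: filters, rarefaction, tree, PGLS, comparisons.

Fourteen models mirror the three questions the analysis asks of the species
table: do habitats differ in diversity (2 models: one per response over all
bony fishes, with marine/freshwater/mixed cell means), do threatened and
not-threatened species differ (4 models: 2 responses x 2 habitats), and how
does diversity relate to age at maturity and fecundity (8 models: 2
responses x 2 habitats x 2 traits, slope models).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import Config
from .pgls import (
    BootstrapCI,
    PGLSFit,
    bootstrap_ci,
    cell_means_design,
    compare_groups,
    gls_fit,
    significant_nonzero,
    slope_design,
)
from .rarefaction import RarefactionSummary, rarefy_table
from .species import (
    ConservationClass,
    SpeciesRecord,
    drop_extinct,
    filter_for_pgls,
    select_best_study,
)
from .taxonomy import brownian_covariance

logger = logging.getLogger(__name__)

RESPONSES = ("mean_obs_het", "rarefied_alleles")
HABITAT_SUBSETS = ("marine", "freshwater")


@dataclass(frozen=True)
class ModelSpec:
    id: str
    response: str            # mean_obs_het | rarefied_alleles
    predictor: str           # habitat | conservation_status | age_at_maturity | fecundity
    subset: str = "all_osteichthyes"   # all_osteichthyes | marine | freshwater
    transform: str = "raw"   # raw | log10 (continuous predictors only)


def default_suite(cfg: Config | None = None) -> list[ModelSpec]:
    """The standard fourteen models.

    Habitat models run on all bony fishes with a three-level cell-means
    design; conservation and life-history models run separately within the
    marine and freshwater subsets.
    """
    cfg = cfg or Config()
    fec_tf = "log10" if cfg.suite.log10_fecundity else "raw"
    age_tf = "log10" if cfg.suite.log10_age else "raw"
    suite: list[ModelSpec] = []
    for resp in RESPONSES:
        short = "het" if resp == "mean_obs_het" else "alleles"
        suite.append(ModelSpec(f"habitat_{short}", resp, "habitat"))
    for resp in RESPONSES:
        short = "het" if resp == "mean_obs_het" else "alleles"
        for hab in HABITAT_SUBSETS:
            suite.append(
                ModelSpec(f"conservation_{short}_{hab}", resp,
                          "conservation_status", hab)
            )
    for resp in RESPONSES:
        short = "het" if resp == "mean_obs_het" else "alleles"
        for hab in HABITAT_SUBSETS:
            suite.append(
                ModelSpec(f"age_{short}_{hab}", resp, "age_at_maturity",
                          hab, age_tf)
            )
            suite.append(
                ModelSpec(f"fecundity_{short}_{hab}", resp, "fecundity",
                          hab, fec_tf)
            )
    return suite


@dataclass
class ModelResult:
    spec: ModelSpec
    n_used: int
    fit: PGLSFit | None = None
    ci: BootstrapCI | None = None
    #: group-difference decisions by the CI-overlap rule (conservative:
    #: per-group intervals share ancestry-level variance that cancels in
    #: the difference)
    comparisons: dict[str, bool] = field(default_factory=dict)
    #: percentile CIs of pairwise coefficient differences from the joint
    #: bootstrap draws
    difference_cis: dict[str, tuple[float, float]] = field(default_factory=dict)
    significant: dict[str, bool] = field(default_factory=dict)
    skipped_reason: str | None = None

    def to_rows(self) -> list[dict]:
        if self.skipped_reason is not None:
            return [{
                "model": self.spec.id, "response": self.spec.response,
                "subset": self.spec.subset, "coefficient": "",
                "estimate": "", "lower": "", "upper": "",
                "significant_nonzero": "", "n": self.n_used,
                "B": "", "skipped": self.skipped_reason,
            }]
        rows = []
        for label in self.ci.estimates:
            rows.append({
                "model": self.spec.id,
                "response": self.spec.response,
                "subset": self.spec.subset,
                "coefficient": label,
                "estimate": self.ci.estimates[label],
                "lower": self.ci.lower[label],
                "upper": self.ci.upper[label],
                "significant_nonzero": self.significant[label],
                "n": self.n_used,
                "B": self.ci.iterations,
                "skipped": "",
            })
        return rows


@dataclass
class SuiteResult:
    models: dict[str, ModelResult]
    filter_counts: dict[str, int]
    rarefaction: RarefactionSummary
    seed: int

    def model(self, model_id: str) -> ModelResult:
        return self.models[model_id]


def _subset_records(records: Sequence[SpeciesRecord], spec: ModelSpec) -> list[SpeciesRecord]:
    recs = list(records)
    if spec.subset in HABITAT_SUBSETS:
        recs = [r for r in recs if r.habitat == spec.subset]
    if spec.response == "mean_obs_het":
        recs = [r for r in recs if r.mean_obs_het is not None]
    if spec.predictor == "conservation_status":
        recs = [r for r in recs if r.conservation in
                (ConservationClass.NOT_THREATENED, ConservationClass.THREATENED)]
    elif spec.predictor in ("age_at_maturity", "fecundity"):
        recs = [r for r in recs if getattr(r, spec.predictor) is not None]
    return recs


def _response_vector(records: Sequence[SpeciesRecord], spec: ModelSpec) -> np.ndarray:
    if spec.response == "mean_obs_het":
        return np.array([r.mean_obs_het for r in records], float)
    return np.array([r.rarefied_alleles for r in records], float)


def _design(records: Sequence[SpeciesRecord], spec: ModelSpec):
    if spec.predictor == "habitat":
        order = [h for h in ("marine", "freshwater", "mixed")
                 if any(r.habitat == h for r in records)]
        values = pd.Categorical([r.habitat for r in records], categories=order)
        d = cell_means_design(np.array(values.astype(str), dtype=object))
        # reorder columns to marine/freshwater/mixed for stable reporting
        idx = [d.labels.index(h) for h in order]
        return type(d)(X=d.X[:, idx], labels=tuple(order), factor=True)
    if spec.predictor == "conservation_status":
        values = np.array([r.conservation.value for r in records], dtype=object)
        order = [s for s in ("not_threatened", "threatened") if s in values]
        d = cell_means_design(values)
        idx = [d.labels.index(s) for s in order]
        return type(d)(X=d.X[:, idx], labels=tuple(order), factor=True)
    x = np.array([getattr(r, spec.predictor) for r in records], float)
    if spec.transform == "log10":
        x = np.log10(x)
    return slope_design(x, label=spec.predictor)


def run_suite(
    records: Sequence[SpeciesRecord],
    suite: Sequence[ModelSpec] | None = None,
    cfg: Config | None = None,
    seed: int = 0,
) -> SuiteResult:
    """Run the full pipeline on parsed records.

    Filter chain: best study per species -> drop extinct -> bony-fish trim
    -> rarefaction (once, shared by every model) -> per-model subsetting,
    design construction, GLS fit, species bootstrap and CI comparisons.
    Everything is deterministic given input order, config and seed.
    """
    cfg = cfg or Config()
    suite = list(suite) if suite is not None else default_suite(cfg)
    rng = np.random.default_rng(seed)

    counts: dict[str, int] = {"input": len(records)}
    recs = select_best_study(records)
    counts["best_study"] = len(recs)
    recs = drop_extinct(recs)
    counts["after_extinct_drop"] = len(recs)
    recs = filter_for_pgls(recs, cfg.io)
    counts["osteichthyes"] = len(recs)

    rare_seed = int(rng.integers(0, 2**31 - 1))
    recs, rare_summary = rarefy_table(recs, cfg.rarefaction, rare_seed)

    results: dict[str, ModelResult] = {}
    for spec in suite:
        model_seed = int(rng.integers(0, 2**31 - 1))
        sub = _subset_records(recs, spec)
        if len(sub) < cfg.suite.min_n:
            logger.warning("model %s skipped: only %d usable species",
                           spec.id, len(sub))
            results[spec.id] = ModelResult(
                spec=spec, n_used=len(sub),
                skipped_reason=f"only {len(sub)} usable species "
                               f"(min_n={cfg.suite.min_n})",
            )
            continue
        design = _design(sub, spec)
        y = _response_vector(sub, spec)
        V = brownian_covariance(sub)
        fit = gls_fit(design, y, V, cfg.pgls.nugget)
        ci = bootstrap_ci(design, y, V, cfg.pgls, model_seed)
        significant = {
            label: significant_nonzero(ci.interval(label))
            for label in design.labels
        }
        comparisons: dict[str, bool] = {}
        difference_cis: dict[str, tuple[float, float]] = {}
        if design.factor:
            for i, a in enumerate(design.labels):
                for b in design.labels[i + 1:]:
                    comparisons[f"{a}_vs_{b}"] = compare_groups(
                        ci.interval(a), ci.interval(b)
                    )
                    difference_cis[f"{a}_vs_{b}"] = ci.difference_interval(
                        a, b, cfg.pgls.ci_level
                    )
        results[spec.id] = ModelResult(
            spec=spec, n_used=len(sub), fit=fit, ci=ci,
            comparisons=comparisons, difference_cis=difference_cis,
            significant=significant,
        )
    return SuiteResult(models=results, filter_counts=counts,
                       rarefaction=rare_summary, seed=seed)


def _headline(result: SuiteResult) -> dict[str, float | None]:
    """Marine-minus-freshwater rarefied-alleles difference, if available."""
    m = result.models.get("habitat_alleles")
    if m is None or m.ci is None:
        return {"marine_minus_freshwater_alleles": None}
    est = m.ci.estimates
    if "marine" in est and "freshwater" in est:
        return {"marine_minus_freshwater_alleles": est["marine"] - est["freshwater"]}
    return {"marine_minus_freshwater_alleles": None}


def results_frame(result: SuiteResult) -> pd.DataFrame:
    rows: list[dict] = []
    for model in result.models.values():
        rows.extend(model.to_rows())
    return pd.DataFrame(rows)


def summarize(result: SuiteResult) -> dict:
    """Machine-readable summary of a suite run (JSON-serializable)."""
    out: dict = {
        "seed": result.seed,
        "filter_counts": result.filter_counts,
        "mean_rarefaction_delta": result.rarefaction.mean_abs_change,
        "models": {},
    }
    out.update(_headline(result))
    for mid, model in result.models.items():
        entry: dict = {
            "response": model.spec.response,
            "predictor": model.spec.predictor,
            "subset": model.spec.subset,
            "transform": model.spec.transform,
            "n": model.n_used,
        }
        if model.skipped_reason is not None:
            entry["skipped"] = model.skipped_reason
        else:
            entry["coefficients"] = {
                label: {
                    "estimate": model.ci.estimates[label],
                    "lower": model.ci.lower[label],
                    "upper": model.ci.upper[label],
                    "significant_nonzero": model.significant[label],
                }
                for label in model.ci.estimates
            }
            entry["comparisons"] = model.comparisons
            entry["difference_cis"] = {
                k: list(v) for k, v in model.difference_cis.items()
            }
            entry["sigma2"] = model.fit.sigma2
            entry["B"] = model.ci.iterations
        out["models"][mid] = entry
    return out


def summarize_markdown(result: SuiteResult) -> str:
    """Human-readable report of the same summary."""
    s = summarize(result)
    lines = ["# Diversity model suite", ""]
    lines.append(f"Seed: {s['seed']}")
    lines.append("Filter chain: " + " -> ".join(
        f"{k}={v}" for k, v in s["filter_counts"].items()))
    lines.append(f"Mean |rarefied - reported| alleles: "
                 f"{s['mean_rarefaction_delta']:.2f}")
    if s["marine_minus_freshwater_alleles"] is not None:
        lines.append(
            "Marine - freshwater rarefied alleles: "
            f"{s['marine_minus_freshwater_alleles']:.2f}"
        )
    lines.append("")
    lines.append("| model | coefficient | estimate | 95% CI | nonzero | n |")
    lines.append("|---|---|---|---|---|---|")
    for mid, entry in s["models"].items():
        if "skipped" in entry:
            lines.append(f"| {mid} | — | skipped: {entry['skipped']} | | | "
                         f"{entry['n']} |")
            continue
        for label, c in entry["coefficients"].items():
            lines.append(
                f"| {mid} | {label} | {c['estimate']:.4g} "
                f"| [{c['lower']:.4g}, {c['upper']:.4g}] "
                f"| {'yes' if c['significant_nonzero'] else 'no'} "
                f"| {entry['n']} |"
            )
    return "\n".join(lines) + "\n"


def write_results(result: SuiteResult, outdir: str | Path) -> dict[str, Path]:
    """Serialize a suite run as TSV, JSON and markdown (byte-deterministic)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tsv": outdir / "results.tsv",
        "json": outdir / "results.json",
        "md": outdir / "results.md",
    }
    results_frame(result).to_csv(paths["tsv"], sep="\t", index=False)
    with open(paths["json"], "w") as fh:
        json.dump(summarize(result), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["md"].write_text(summarize_markdown(result))
    return paths
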