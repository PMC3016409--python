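"""Replicate-level experiment harness: type-I error, power, phasing accuracy.

Each replicate simulates a fresh study resource, runs the full observed +
gene-dropped-null analysis pipeline on it, and records whether the
haplotype-specific test rejected at the chosen level.  Under a null model
the rejection rate estimates the type-I error; under an alternative it
estimates power.  An enumeration cache is shared across replicates since
the same pedigree shapes recur with a limited variety of genotype patterns.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .em import EnumerationCache, PhasingSettings, phase_resource
from .mc import run_analysis, threshold_code
from .sim import (
    DesignSpec,
    DiseaseModel,
    default_pool,
    merge_resources,
    phasing_accuracy,
    risk_haplotype,
    simulate_design,
)
from .stats import AnalysisSpec

log = logging.getLogger(__name__)


@dataclass
class RateResult:
    """Empirical rejection rate over replicates, with its binomial band."""

    rate: float
    rejections: int
    n_replicates: int
    alpha: float
    p_values: np.ndarray

    def binomial_band(self, level: float = 0.95) -> tuple[float, float]:
        """Normal-approximation band for the rejection rate at the true alpha."""
        z = 1.959963984540054 if level == 0.95 else float(
            __import__("scipy.stats", fromlist=["norm"]).norm.ppf(0.5 + level / 2)
        )
        se = (self.alpha * (1 - self.alpha) / self.n_replicates) ** 0.5
        return (self.alpha - z * se, self.alpha + z * se)


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=2 * n)


def _build(
    design: str,
    model: DiseaseModel,
    pool,
    rng: np.random.Generator,
    sizes: dict,
):
    """One resource for a single or two-set mixed design (e.g. TRIOCC)."""
    base = design.replace("CC", "") if design.endswith("CC") and design != "CC" else design
    if base != design:
        spec = _design_spec(base, sizes)
        res, truth = simulate_design(spec, model, pool, rng)
        cc_spec = _design_spec("CC", sizes)
        cc_res, cc_truth = simulate_design(cc_spec, model, pool, rng)
        res = merge_resources(res, cc_res, prefix_b="X")
        truth = dict(truth)
        truth.update({("X" + f, i): v for (f, i), v in cc_truth.items()})
        return res, truth
    return simulate_design(_design_spec(design, sizes), model, pool, rng)


def _design_spec(design: str, sizes: dict) -> DesignSpec:
    kw = dict(sizes)
    if design == "CC":
        return DesignSpec.cc(
            n_cases=kw.get("n_cases", 500), n_controls=kw.get("n_controls", 500),
            missing_rate=kw.get("missing_rate", 0.0),
        )
    if design == "TRIO":
        return DesignSpec.trio(
            n_families=kw.get("n_families", 500),
            missing_rate=kw.get("missing_rate", 0.0),
        )
    if design == "ASP":
        return DesignSpec.asp(
            n_families=kw.get("n_families", 250),
            missing_rate=kw.get("missing_rate", 0.0),
        )
    if design in ("LP1", "LP2"):
        return DesignSpec.lp(
            which=int(design[-1]), n_cases=kw.get("n_cases", 500),
            missing_rate=kw.get("missing_rate", 0.0),
        )
    raise ValueError(f"unknown design {design!r}")


def rejection_rate(
    design: str,
    model: DiseaseModel,
    n_replicates: int,
    n_null: int,
    seed: int,
    alpha: float = 0.05,
    n_markers: int = 15,
    statistic: str = "trend",
    controls: str = "EC",
    sizes: Optional[dict] = None,
    settings: Optional[PhasingSettings] = None,
) -> RateResult:
    """Rejection rate of the haplotype-specific test across replicates.

    The test targets the model's risk haplotype over the full marker set;
    significance per replicate comes from ``n_null`` gene-dropped nulls.
    """
    sizes = sizes or {}
    settings = settings or PhasingSettings()
    pool = default_pool(n_markers)
    spec = AnalysisSpec(
        statistic=statistic,
        target=model.risk_hap,
        loci=None,
        controls=controls,  # type: ignore[arg-type]
        n_null=n_null,
    )
    seeds = _replicate_seeds(seed, n_replicates)
    cache = EnumerationCache()
    pvals = np.empty(n_replicates)
    for r in range(n_replicates):
        rng = np.random.default_rng(int(seeds[2 * r]))
        res, _ = _build(design, model, pool, rng, sizes)
        result = run_analysis(
            res, spec, settings, seed=int(seeds[2 * r + 1]),
            cache=cache, keep_nulls=False,
        )
        pvals[r] = result.p
    rejections = int(np.sum(pvals <= alpha))
    return RateResult(
        rate=rejections / n_replicates,
        rejections=rejections,
        n_replicates=n_replicates,
        alpha=alpha,
        p_values=pvals,
    )


def null_model(q: float = 0.10, n_markers: int = 15, r2: float = 0.8) -> DiseaseModel:
    return DiseaseModel(risk_hap=risk_haplotype(q, n_markers), q=q, grr=1.0, r2=r2)


def alt_model(q: float, grr: float, n_markers: int = 15, r2: float = 0.8) -> DiseaseModel:
    return DiseaseModel(risk_hap=risk_haplotype(q, n_markers), q=q, grr=grr, r2=r2)


def accuracy_comparison(
    design: str,
    seed: int,
    n_markers: int = 15,
    missing_rate: float = 0.05,
    sizes: Optional[dict] = None,
    settings: Optional[PhasingSettings] = None,
) -> dict[str, float]:
    """MLE haplotype accuracy: pedigree-informed vs pedigree-naive phasing.

    One null-model data set is simulated, phased both ways, and scored
    against the hidden true haplotypes (both haplotypes of an individual
    must be correct, imputed positions included).
    """
    sizes = dict(sizes or {})
    sizes["missing_rate"] = missing_rate
    settings = settings or PhasingSettings()
    pool = default_pool(n_markers)
    rng = np.random.default_rng(seed)
    res, truth = _build(design, null_model(n_markers=n_markers), pool, rng, sizes)
    coded = threshold_code(res, settings.threshold)
    informed = phase_resource(coded, settings)
    naive_settings = PhasingSettings(**{**settings.__dict__, "naive": True})
    naive = phase_resource(coded, naive_settings)
    return {
        "informed": phasing_accuracy(informed.mle, truth),
        "naive": phasing_accuracy(naive.mle, truth),
    }
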