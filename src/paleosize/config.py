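"""Run configuration: YAML loading and fail-fast validation.

A run config names the measurement CSV, the clade/metric combinations to
analyze (with optional species-exclusion variants), the resampling plan,
the lineage pairings, and the multiple-comparison policy.  Validation is
fail-fast: every referenced clade, metric, and species must resolve against
the input table before any computation starts, so a run never leaves
partial outputs behind because of a late lookup error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .measurements import Metric

__all__ = ["CladeSpec", "RunConfig", "load_config", "validate_against"]


@dataclass(frozen=True)
class CladeSpec:
    name: str
    metrics: tuple[Metric, ...] = (Metric.MEAN,)
    #: each entry is a set of species excluded in an additional variant run;
    #: the no-exclusion run always happens
    exclude_variants: tuple[tuple[str, ...], ...] = ()


@dataclass(frozen=True)
class RunConfig:
    input: str
    outdir: str = "out"
    seed: int = 0
    n_boot: int = 1000
    coverage: float = 0.5
    alpha: float = 0.05
    m: int | None = None  # None = number of lineage pairs tested
    n_perm: int = 9_999
    include_figures: bool = True
    clades: tuple[CladeSpec, ...] = ()
    lineages: tuple[dict, ...] = ()
    #: simulation scenarios for the `simulate` verb: name -> SimScenario kwargs
    scenarios: dict = field(default_factory=dict)
    sim_reps: int = 200


def load_config(path) -> RunConfig:
    """Load a YAML run config."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    clades = []
    for name, spec in (raw.pop("clades", {}) or {}).items():
        spec = spec or {}
        clades.append(
            CladeSpec(
                name=name,
                metrics=tuple(Metric(m) for m in spec.get("metrics", ["mean"])),
                exclude_variants=tuple(
                    tuple(v) for v in spec.get("exclude_variants", [])
                ),
            )
        )
    lineages = tuple(raw.pop("lineages", []) or [])
    for d in lineages:
        for key in ("name", "fossil_species", "modern_species"):
            if key not in d:
                raise ValueError(f"lineage definition missing {key!r}: {d}")
    return RunConfig(clades=tuple(clades), lineages=lineages, **raw)


def validate_against(config: RunConfig, summaries) -> None:
    """Fail fast if the config references clades/species absent from the data."""
    clades_present = set(summaries["clade"])
    species_present = set(summaries["species"])
    problems = []
    for cs in config.clades:
        if cs.name not in clades_present:
            problems.append(f"clade {cs.name!r} not in input")
        for variant in cs.exclude_variants:
            for sp in variant:
                if sp not in species_present:
                    problems.append(f"excluded species {sp!r} not in input")
    for d in config.lineages:
        for key in ("fossil_species", "modern_species"):
            if d[key] not in species_present:
                problems.append(f"lineage species {d[key]!r} not in input")
    if problems:
        raise ValueError("config validation failed: " + "; ".join(problems))
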