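"""Domain types shared by every stage of the nitrate source-apportionment pipeline.

The central objects are water samples carrying dual nitrate isotopes
(δ¹⁵N–NO₃⁻ vs air-N₂ and δ¹⁸O–NO₃⁻ vs VSMOW, both in ‰) together with
hydrochemical concentrations, and nitrate endmember ("source") profiles
carrying the per-tracer isotope mean/SD and optional fractionation
mean/SD.  Everything downstream — clustering, the Bayesian mixing model,
the diagnostics — consumes these types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

__all__ = [
    "TRACERS",
    "CANONICAL_SOURCE_ORDER",
    "SampleRecord",
    "SourceProfile",
    "MCMCConfig",
    "AnalysisConfig",
]

#: Default tracer names, in the fixed order used for clustering features
#: and likelihood dimensions alike.
TRACERS: tuple[str, ...] = ("d15N_NO3", "d18O_NO3")

#: Conventional reporting order for the four basin endmembers:
#: chemical fertilizer, manure & sewage, atmospheric precipitation, soil N.
CANONICAL_SOURCE_ORDER: tuple[str, ...] = ("CF", "MS", "NP", "SN")

WATER_TYPES = ("surface", "ground")


@dataclass(frozen=True)
class SampleRecord:
    """One water sample: tracers, concentrations, and labels.

    Optional fields use ``None`` for "not measured"; they are never
    silently zero-filled.  Concentrations are stored exactly as given
    (mg/L of the stated species; no N-equivalent conversion).
    """

    sample_id: str
    water_type: str  # "surface" | "ground"
    d15N_NO3: float  # ‰ vs air-N2
    d18O_NO3: float | None  # ‰ vs VSMOW
    region: str = ""
    no3: float | None = None  # mg/L as NO3-
    tn: float | None = None  # mg/L
    nh4: float | None = None  # mg/L
    cond: float | None = None  # µS/cm
    d18O_H2O: float | None = None  # ‰ vs VSMOW

    def __post_init__(self) -> None:
        if self.water_type not in WATER_TYPES:
            raise ValueError(
                f"water_type must be one of {WATER_TYPES}, got {self.water_type!r}"
            )
        if self.no3 is not None and self.no3 < 0:
            raise ValueError(f"sample {self.sample_id}: no3 must be >= 0")

    def tracer(self, name: str) -> float | None:
        """Return the named tracer value, or None when absent."""
        value = getattr(self, name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        return value

    def with_values(self, **kwargs) -> "SampleRecord":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SourceProfile:
    """A nitrate endmember's isotope signature with its uncertainty.

    ``mean``/``sd`` give the per-tracer signature (μ_jk, ω_jk ≥ 0);
    ``frac_mean``/``frac_sd`` give the fractionation shift and its SD
    (λ_jk, τ_jk ≥ 0), defaulting to zero for conservative mixing.
    """

    source_id: str
    mean: dict[str, float]
    sd: dict[str, float]
    frac_mean: dict[str, float] = field(default_factory=dict)
    frac_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tracer, s in self.sd.items():
            if s < 0:
                raise ValueError(
                    f"source {self.source_id}: sd for {tracer} must be >= 0"
                )
        for tracer, s in self.frac_sd.items():
            if s < 0:
                raise ValueError(
                    f"source {self.source_id}: frac_sd for {tracer} must be >= 0"
                )
        # missing fractionation entries default to zero shift / zero spread
        object.__setattr__(
            self,
            "frac_mean",
            {t: self.frac_mean.get(t, 0.0) for t in self.mean},
        )
        object.__setattr__(
            self,
            "frac_sd",
            {t: self.frac_sd.get(t, 0.0) for t in self.mean},
        )

    @property
    def tracers(self) -> tuple[str, ...]:
        return tuple(self.mean)

    def covers(self, tracers: Sequence[str]) -> bool:
        return all(t in self.mean and t in self.sd for t in tracers)


def order_sources(sources: Sequence[SourceProfile]) -> list[SourceProfile]:
    """Order profiles CF, MS, NP, SN when those ids are present, else keep input order."""
    ids = [s.source_id for s in sources]
    if set(ids) <= set(CANONICAL_SOURCE_ORDER):
        return sorted(sources, key=lambda s: CANONICAL_SOURCE_ORDER.index(s.source_id))
    return list(sources)


@dataclass
class MCMCConfig:
    """Sampler settings for the mixing-model fit.

    Defaults are deliberately long (3 chains of 50,000 iterations); tests
    and quick looks should pass shorter chains explicitly.
    """

    n_chains: int = 3
    n_iter: int = 50_000
    n_burn: int = 25_000
    thin: int = 10
    proposal_scale: float = 0.5
    rng_seed: int = 0
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 (convergence diagnostics need it)")
        if not (0 <= self.n_burn < self.n_iter):
            raise ValueError("need 0 <= n_burn < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class AnalysisConfig:
    """Run configuration shared by all pipeline stages."""

    tracers: tuple[str, ...] = TRACERS
    n_clusters_surface: int = 2
    n_clusters_ground: int = 2
    standardize_features: bool = False
    who_no3_threshold: float = 50.0  # mg/L, WHO drinking-water nitrate guideline
    class_v_tn_threshold: float = 2.0  # mg/L, configurable surface-water standard
    alpha: float = 0.01  # two-tailed significance level for correlation screens
    sigma_prior_scale: float = 20.0  # ‰, half-normal scale on residual σ
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.tracers:
            raise ValueError("tracers must be non-empty")
        if self.n_clusters_surface < 1 or self.n_clusters_ground < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.who_no3_threshold <= 0 or self.class_v_tn_threshold <= 0:
            raise ValueError("thresholds must be positive")

    def n_clusters(self, water_type: str) -> int:
        return (
            self.n_clusters_surface if water_type == "surface" else self.n_clusters_ground
        )
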