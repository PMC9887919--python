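"""Healthy Beverage Index (HBI) scoring.

The HBI rates how closely a person's beverage consumption matches
healthy-beverage standards.  The original index has ten components —
eight beverage categories plus total beverage energy and total fluid
adequacy — and ranges 0–100.  The *adapted* variant used for cohorts in
which diet drinks and alcohol are essentially absent removes those two
components (worth 5 points each), giving a 0–90 range.

Component scoring is piecewise-linear and proportional:

* **adequacy** components (more is better up to the standard)::

      points = max_points * min(observed / standard, 1)

* **moderation** components (full credit at or below the standard,
  linearly decreasing to zero at twice the standard)::

      points = max_points * clip(1 - max(0, observed - standard) / standard, 0, 1)

Beverage-category intakes are scored as a share of total fluid, total
beverage energy as a share of total energy intake, and the fluid
requirement as absolute mL/day.  Every standard and point allocation is
configurable; the variant-level sum invariants (100 for the original
index, 90 for the adapted one, and the 5-point weight of each excluded
component) are enforced on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "HBIComponent",
    "HBIConfig",
    "BeverageProfile",
    "HBIScore",
    "ConfigError",
    "ScoringError",
    "load_hbi_config",
    "score_component",
    "compute_hbi",
    "best_compliance_profile",
    "score_cohort",
    "max_score",
    "filter_energy",
    "BEVERAGE_CATEGORIES",
]

#: The eight beverage categories of the original index, in scoring order.
BEVERAGE_CATEGORIES = (
    "water",
    "unsweetened_coffee_tea",
    "low_fat_milk",
    "full_fat_milk",
    "fruit_juice_100",
    "ssb",
    "diet_drinks",
    "alcohol",
)

#: Components the adapted variant removes.
EXCLUDED_IN_ADAPTED = ("diet_drinks", "alcohol")

_BASES = ("fluid_share", "energy_share", "absolute")


class ConfigError(ValueError):
    """Raised when an HBI configuration violates a structural invariant."""


class ScoringError(ValueError):
    """Raised when a beverage profile cannot be scored."""


@dataclass(frozen=True)
class HBIComponent:
    """One scored component of the index.

    Parameters
    ----------
    name
        Component identifier (a beverage category, ``total_bev_energy``
        or ``fluid_requirement``).
    direction
        ``"adequacy"`` (higher intake scores higher, capped) or
        ``"moderation"`` (full points at/below the standard, linear
        decline to zero at twice the standard).
    standard
        The compliance threshold: a share of total fluid for beverage
        categories, a share of total energy for ``total_bev_energy``,
        or absolute mL/day for ``fluid_requirement``.
    max_points
        Points awarded at full compliance.
    basis
        What ``standard`` is expressed against; inferred from ``name``
        by default.
    """

    name: str
    direction: str
    standard: float
    max_points: float
    basis: str = "fluid_share"

    def __post_init__(self) -> None:
        if self.direction not in ("adequacy", "moderation"):
            raise ConfigError(f"unknown direction {self.direction!r} for {self.name}")
        if self.basis not in _BASES:
            raise ConfigError(f"unknown basis {self.basis!r} for {self.name}")
        if not self.standard > 0:
            raise ConfigError(f"standard must be > 0 for {self.name}")
        if self.max_points < 0:
            raise ConfigError(f"max_points must be >= 0 for {self.name}")


@dataclass(frozen=True)
class HBIConfig:
    """A full component registry for one index variant."""

    variant: str
    components: tuple[HBIComponent, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate component names")
        total = sum(c.max_points for c in self.components)
        if self.variant == "original":
            if abs(total - 100) > 1e-9:
                raise ConfigError(f"original variant must sum to 100 points, got {total}")
            for name in EXCLUDED_IN_ADAPTED:
                comp = self.get(name, None)
                if comp is None:
                    raise ConfigError(f"original variant must include {name}")
                if abs(comp.max_points - 5) > 1e-9:
                    raise ConfigError(f"{name} must be worth 5 points in the original variant")
        elif self.variant == "adapted":
            if any(n in names for n in EXCLUDED_IN_ADAPTED):
                raise ConfigError("adapted variant must exclude diet drinks and alcohol")
            if abs(total - 90) > 1e-9:
                raise ConfigError(f"adapted variant must sum to 90 points, got {total}")
        else:
            raise ConfigError(f"unknown variant {self.variant!r}")

    def get(self, name: str, default=None) -> HBIComponent | None:
        for c in self.components:
            if c.name == name:
                return c
        return default


@dataclass(frozen=True)
class BeverageProfile:
    """One participant's daily beverage intakes (mL/day) and energy context."""

    intakes: Mapping[str, float]
    total_bev_energy: float
    total_energy: float
    total_fluid: float

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.intakes.items() if v < 0}
        if bad or self.total_bev_energy < 0 or self.total_energy < 0 or self.total_fluid < 0:
            raise ScoringError("beverage profile fields must be non-negative")


@dataclass(frozen=True)
class HBIScore:
    """Per-component points and their total for one participant."""

    component_points: dict[str, float]
    total: float


# Default standards and point allocations.  The index's published
# definition fixes the component list and the variant maxima (100 / 90,
# with the removed components worth 5 each); the per-component standards
# below are package defaults, replaceable via `overrides`.
_DEFAULT_COMPONENTS: tuple[HBIComponent, ...] = (
    HBIComponent("water", "adequacy", 1.00, 25.0, "fluid_share"),
    HBIComponent("unsweetened_coffee_tea", "adequacy", 0.35, 10.0, "fluid_share"),
    HBIComponent("low_fat_milk", "adequacy", 0.35, 10.0, "fluid_share"),
    HBIComponent("full_fat_milk", "moderation", 0.10, 5.0, "fluid_share"),
    HBIComponent("fruit_juice_100", "moderation", 0.06, 5.0, "fluid_share"),
    HBIComponent("ssb", "moderation", 0.15, 25.0, "fluid_share"),
    HBIComponent("diet_drinks", "moderation", 0.05, 5.0, "fluid_share"),
    HBIComponent("alcohol", "moderation", 0.05, 5.0, "fluid_share"),
    HBIComponent("total_bev_energy", "moderation", 0.12, 5.0, "energy_share"),
    HBIComponent("fluid_requirement", "adequacy", 2000.0, 5.0, "absolute"),
)


def load_hbi_config(variant: str, overrides: str | Path | Mapping | None = None) -> HBIConfig:
    """Build the component registry for a variant, optionally overridden.

    ``overrides`` may be a mapping or a YAML/JSON file path with a
    ``components`` list of ``{name, standard?, max_points?, direction?}``
    entries.  Overrides are applied per component and the variant sum
    invariant is re-validated (so an override that breaks the 90/100
    total raises :class:`ConfigError`).
    """
    comps = list(_DEFAULT_COMPONENTS)
    if variant == "adapted":
        comps = [c for c in comps if c.name not in EXCLUDED_IN_ADAPTED]
    elif variant != "original":
        raise ConfigError(f"unknown variant {variant!r}")

    if overrides is not None:
        if isinstance(overrides, (str, Path)):
            with open(overrides) as fh:
                overrides = yaml.safe_load(fh)
        entries = overrides.get("components", []) if isinstance(overrides, Mapping) else overrides
        by_name = {c.name: c for c in comps}
        for entry in entries:
            name = entry["name"]
            if name not in by_name:
                raise ConfigError(f"override names unknown component {name!r}")
            fields = {k: entry[k] for k in ("direction", "standard", "max_points", "basis") if k in entry}
            by_name[name] = replace(by_name[name], **fields)
        comps = [by_name[c.name] for c in comps]

    return HBIConfig(variant=variant, components=tuple(comps))


def score_component(observed, component: HBIComponent):
    """Score one component; works element-wise on arrays.

    ``observed`` is on the component's own basis (a share for share-based
    components, mL/day for the fluid requirement).
    """
    if not component.standard > 0:
        raise ConfigError(f"standard must be > 0 for {component.name}")
    obs = np.asarray(observed, dtype=float)
    if np.any(obs < 0):
        raise ScoringError(f"negative observed value for {component.name}")
    if component.direction == "adequacy":
        frac = np.minimum(obs / component.standard, 1.0)
    else:
        over = np.maximum(0.0, obs - component.standard) / component.standard
        frac = np.clip(1.0 - over, 0.0, 1.0)
    pts = component.max_points * frac
    return float(pts) if np.isscalar(observed) else pts


def _observed_for(component: HBIComponent, intakes, total_bev_energy, total_energy, total_fluid):
    if component.basis == "fluid_share":
        return intakes.get(component.name, 0.0) / total_fluid
    if component.basis == "energy_share":
        if np.any(np.asarray(total_energy) <= 0):
            raise ScoringError("total_energy must be > 0 to score the beverage-energy share")
        return total_bev_energy / total_energy
    return total_fluid  # absolute fluid requirement


def compute_hbi(profile: BeverageProfile, config: HBIConfig) -> HBIScore:
    """Score one beverage profile under a config.

    Raises :class:`ScoringError` when ``total_fluid`` is zero, since the
    share-based components are then undefined.
    """
    if profile.total_fluid <= 0:
        raise ScoringError("cannot score profile: total_fluid must be > 0")
    points: dict[str, float] = {}
    for comp in config.components:
        obs = _observed_for(
            comp, profile.intakes, profile.total_bev_energy, profile.total_energy, profile.total_fluid
        )
        points[comp.name] = score_component(float(obs), comp)
    return HBIScore(component_points=points, total=float(sum(points.values())))


def score_cohort(cohort: pd.DataFrame, config: HBIConfig, energy_col: str = "energy") -> pd.DataFrame:
    """Vectorised :func:`compute_hbi` over a cohort table.

    Returns a copy with one ``hbi_<component>`` column per component and
    an ``hbi_total`` column.  Participants with ``total_fluid <= 0`` are
    reported by id in the raised error.
    """
    out = cohort.copy()
    fluid = out["total_fluid"].to_numpy(dtype=float)
    if np.any(fluid <= 0):
        bad = out.loc[fluid <= 0, "id"].tolist() if "id" in out else list(np.flatnonzero(fluid <= 0))
        raise ScoringError(f"total_fluid must be > 0; offending participants: {bad}")
    total = np.zeros(len(out))
    for comp in config.components:
        if comp.basis == "fluid_share":
            obs = out[comp.name].to_numpy(dtype=float) / fluid
        elif comp.basis == "energy_share":
            energy = out[energy_col].to_numpy(dtype=float)
            if np.any(energy <= 0):
                raise ScoringError(f"{energy_col} must be > 0 for the beverage-energy share")
            obs = out["total_bev_energy"].to_numpy(dtype=float) / energy
        else:
            obs = fluid
        pts = score_component(obs, comp)
        out[f"hbi_{comp.name}"] = pts
        total = total + pts
    out["hbi_total"] = total
    return out


def best_compliance_profile(config: HBIConfig, total_energy: float = 2000.0) -> BeverageProfile:
    """A profile attaining the configured maximum exactly.

    Meets every adequacy standard (category intakes at
    ``standard * total_fluid``; total fluid at the fluid-requirement
    standard) and reports zero intake on every moderation category.
    Note ``total_fluid`` is reported fluid from all sources, so category
    intakes are not required to sum to it.
    """
    fluid_comp = config.get("fluid_requirement")
    total_fluid = fluid_comp.standard if fluid_comp is not None else 2000.0
    intakes: dict[str, float] = {}
    for comp in config.components:
        if comp.basis != "fluid_share":
            continue
        intakes[comp.name] = comp.standard * total_fluid if comp.direction == "adequacy" else 0.0
    return BeverageProfile(
        intakes=intakes, total_bev_energy=0.0, total_energy=total_energy, total_fluid=total_fluid
    )


def max_score(config: HBIConfig) -> float:
    """Sum of component points — the supremum of :func:`compute_hbi`."""
    return float(sum(c.max_points for c in config.components))


def filter_energy(
    cohort: pd.DataFrame, low: float = 500.0, high: float = 3500.0
) -> tuple[pd.DataFrame, int]:
    """Apply the cohort energy-intake filter.

    Keeps rows with ``low <= energy <= high`` (inclusive bounds: the
    exclusion rule removes intakes strictly outside the range).  Rows
    with missing energy are excluded.  Row order is preserved.
    """
    if "energy" not in cohort.columns:
        raise KeyError("cohort is missing required column 'energy'")
    energy = pd.to_numeric(cohort["energy"], errors="coerce")
    keep = (energy >= low) & (energy <= high)
    keep = keep.fillna(False)
    kept = cohort.loc[keep].copy()
    return kept, int((~keep).sum())
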