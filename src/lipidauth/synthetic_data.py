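"""Synthetic lipidomic feature tables with planted origin markers.

The default world emulates a three-region (NX = Yanchi/Ningxia, GS = Gansu,
IM = Inner Mongolia), two-muscle-part (LT = *M. longissimus thoracis et
lumborum*, KM = knuckle meat) design with six animals per region × part
cell, 1080 lipid species in total:

* 11 acyl-carnitine markers elevated in NX in **both** parts, whose per-group
  means and standard errors follow the published reference template
  (:data:`CARNITINE_TEMPLATES`);
* 2 extra differential lipids confined to LT and 17 confined to KM, so the
  per-part screens recover 13 and 28 candidates and their intersection
  recovers the 11 shared markers;
* 1050 null background lipids with no group structure.

Marker abundances are drawn per group from a zero-truncated normal whose
per-sample spread is derived from the template standard errors
(σ = ``noise_scale`` · SE · √n, where n is the number of animals behind the
reported SE: 6 for NX cells, 12 for the pooled non-NX cells).  Background
lipids are log-normal with per-lipid hyperparameters drawn from a broad
prior spanning realistic peak-area magnitudes.

Two calibrations make the construction deliver its planted screen counts
deterministically enough to test against (see ``docs/methods.md`` for the
margin arithmetic):

* a **planted-ratio floor** (default 4.5): any template cell whose NX/non-NX
  mean ratio falls below the floor has its non-NX mean lowered to
  NX/floor — four knuckle-meat cells of the published template sit just
  below the fold-change cut of 4 and are adjusted, as are a handful of
  marginal cells; adjusted cells are flagged in the template;
* a **dispersion scale** (default 0.12) multiplying the SE-implied
  per-sample σ, keeping the empirical fold change of the weakest planted
  contrast above the cut in ≥ 99 % of generations at n = 6.  The
  SE-faithful world is available with ``noise_scale = 1.0`` but does not
  guarantee recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import FeatureTable

__all__ = [
    "REGIONS",
    "PARTS",
    "CARNITINE_TEMPLATES",
    "GroupSpec",
    "MarkerCell",
    "MarkerTemplate",
    "NoiseModel",
    "SyntheticSpec",
    "ConfigurationError",
    "default_spec",
    "generate",
]

REGIONS = ("NX", "GS", "IM")
PARTS = ("LT", "KM")

#: Published acyl-carnitine marker template: per lipid the (mean, SE) of the
#: peak area in NX-LT, NX-KM, pooled non-NX-LT and pooled non-NX-KM groups.
CARNITINE_TEMPLATES: list[tuple[str, str, tuple, tuple, tuple, tuple]] = [
    ("CAR1", "Carnitine C15:0", (7.51e5, 1.21e5), (1.07e6, 2.12e5), (1.45e5, 3.45e4), (1.27e5, 1.43e4)),
    ("CAR2", "Carnitine C17:1", (1.43e5, 2.15e4), (1.88e5, 4.10e4), (3.38e4, 5.78e3), (3.67e4, 4.23e3)),
    ("CAR3", "Carnitine C8:1-OH", (5.23e5, 9.79e4), (7.49e5, 8.40e4), (1.19e5, 1.73e4), (2.04e5, 2.88e4)),
    ("CAR4", "Carnitine C17:0", (2.67e6, 4.94e5), (4.74e6, 1.18e6), (3.89e5, 1.59e5), (3.24e5, 6.01e4)),
    ("CAR5", "Carnitine C9:0", (7.01e5, 1.28e5), (1.02e6, 1.15e5), (1.58e5, 2.32e4), (2.76e5, 3.83e4)),
    ("CAR6", "Carnitine C12:1", (3.05e5, 2.72e4), (3.94e5, 1.06e5), (5.32e4, 1.05e4), (9.13e4, 1.07e4)),
    ("CAR7", "Carnitine C20:2", (1.53e5, 2.84e4), (2.81e5, 6.67e4), (3.28e4, 6.76e3), (5.25e4, 9.98e3)),
    ("CAR8", "Carnitine C14:1", (1.88e6, 3.00e5), (2.07e6, 7.15e5), (3.64e5, 9.52e4), (4.40e5, 6.88e4)),
    ("CAR9", "Carnitine C14:2", (1.10e5, 2.07e4), (1.20e5, 3.45e4), (2.53e4, 5.08e3), (3.24e4, 5.356e3)),
    ("CAR10", "Carnitine C12-OH", (2.47e5, 1.15e4), (4.83e5, 1.46e5), (5.59e4, 1.03e4), (1.24e5, 1.97e4)),
    ("CAR11", "Carnitine C14-OH", (1.13e5, 6.46e3), (2.49e5, 9.60e4), (2.50e4, 5.54e3), (5.56e4, 9.67e3)),
]


class ConfigurationError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class GroupSpec:
    region: str
    part: str
    n: int = 6

    def __post_init__(self) -> None:
        if self.region not in REGIONS and self.region != "QC":
            raise ConfigurationError(f"unknown region {self.region!r}")
        if self.part not in PARTS and self.part != "QC":
            raise ConfigurationError(f"unknown part {self.part!r}")
        if self.n < 1:
            raise ConfigurationError("group size must be >= 1")


@dataclass(frozen=True)
class MarkerCell:
    """One group cell of a marker template.

    ``n_design`` is the number of animals behind the reported mean/SE and
    converts the SE into the per-sample spread; ``adjusted`` marks cells
    whose mean was synthetically lowered to honour the planted-ratio floor.
    """

    mean: float
    se: float
    n_design: int = 6
    adjusted: bool = False

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.se <= 0:
            raise ConfigurationError("marker means and SEs must be strictly positive")

    def sigma(self, noise_scale: float) -> float:
        return noise_scale * self.se * math.sqrt(self.n_design)


@dataclass(frozen=True)
class MarkerTemplate:
    lipid_id: str
    compound: str
    #: keyed by (group, part) with group in {"NX", "nonNX"}
    cells: dict[tuple[str, str], MarkerCell]
    scope: str = "both"  # {"both", "LT", "KM"}

    def __post_init__(self) -> None:
        if self.scope not in ("both", "LT", "KM"):
            raise ConfigurationError(f"unknown scope {self.scope!r}")
        for key in (("NX", "LT"), ("NX", "KM"), ("nonNX", "LT"), ("nonNX", "KM")):
            if key not in self.cells:
                raise ConfigurationError(f"{self.lipid_id}: missing cell {key}")

    def ratio(self, part: str) -> float:
        """Planted NX / non-NX mean ratio in the given part."""
        return self.cells[("NX", part)].mean / self.cells[("nonNX", part)].mean

    def differential_parts(self) -> tuple[str, ...]:
        return PARTS if self.scope == "both" else (self.scope,)


@dataclass(frozen=True)
class NoiseModel:
    """Distribution family and hyperparameters of the generator."""

    family: str = "truncated-normal"
    noise_scale: float = 0.12
    bg_logmean_range: tuple[float, float] = (9.0, 15.0)
    bg_logsd_range: tuple[float, float] = (0.1, 0.4)
    qc_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.family != "truncated-normal":
            raise ConfigurationError(f"unknown noise family {self.family!r}")
        if self.noise_scale <= 0:
            raise ConfigurationError("noise_scale must be positive")
        for lo, hi in (self.bg_logmean_range, self.bg_logsd_range):
            if not lo < hi:
                raise ConfigurationError("background hyperprior ranges must be ordered")


@dataclass(frozen=True)
class SyntheticSpec:
    groups: tuple[GroupSpec, ...]
    markers: tuple[MarkerTemplate, ...]
    n_background: int
    noise: NoiseModel = NoiseModel()
    n_qc: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background < 0:
            raise ConfigurationError("n_background must be >= 0")

    @property
    def n_lipids(self) -> int:
        return len(self.markers) + self.n_background

    @property
    def n_samples(self) -> int:
        return sum(g.n for g in self.groups)

    def to_json(self, path) -> None:
        doc = asdict(self)
        doc["markers"] = [
            {**asdict(m), "cells": {f"{g}-{p}": asdict(c) for (g, p), c in m.cells.items()}}
            for m in self.markers
        ]
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, default=list)


def _floored(cell_nx: MarkerCell, cell_non: MarkerCell, min_ratio: float) -> MarkerCell:
    """Lower the non-NX mean so the planted ratio meets the floor."""
    if cell_nx.mean / cell_non.mean >= min_ratio:
        return cell_non
    return replace(cell_non, mean=cell_nx.mean / min_ratio, adjusted=True)


def _flat_cell(cell: MarkerCell) -> MarkerCell:
    return replace(cell, adjusted=False)


def default_spec(
    *,
    n_per_group: int = 6,
    n_background: int = 1050,
    min_ratio: float = 4.5,
    noise: NoiseModel = NoiseModel(),
    n_qc: int = 3,
    seed: int = 0,
) -> SyntheticSpec:
    """The default planted world: 11 shared carnitine markers (published
    template), 2 LT-only and 17 KM-only extras, 1050 null lipids, 6 animals
    per region × part group (36 biological samples in all)."""
    markers: list[MarkerTemplate] = []
    for lipid_id, compound, nx_lt, nx_km, non_lt, non_km in CARNITINE_TEMPLATES:
        cells = {
            ("NX", "LT"): MarkerCell(*nx_lt, n_design=6),
            ("NX", "KM"): MarkerCell(*nx_km, n_design=6),
            ("nonNX", "LT"): MarkerCell(*non_lt, n_design=12),
            ("nonNX", "KM"): MarkerCell(*non_km, n_design=12),
        }
        cells[("nonNX", "LT")] = _floored(cells[("NX", "LT")], cells[("nonNX", "LT")], min_ratio)
        cells[("nonNX", "KM")] = _floored(cells[("NX", "KM")], cells[("nonNX", "KM")], min_ratio)
        markers.append(MarkerTemplate(lipid_id, compound, cells, scope="both"))

    by_id = {m.lipid_id: m for m in markers}
    # part-specific extras copy the weakest published contrast of their part
    # (CAR2 in LT, CAR3 in KM) and are flat across groups in the other part.
    weakest_lt = by_id["CAR2"]
    weakest_km = by_id["CAR3"]
    for i in range(2):
        cells = {
            ("NX", "LT"): weakest_lt.cells[("NX", "LT")],
            ("nonNX", "LT"): weakest_lt.cells[("nonNX", "LT")],
            # no contrast in KM: both groups share the non-NX KM cell
            ("NX", "KM"): _flat_cell(weakest_lt.cells[("nonNX", "KM")]),
            ("nonNX", "KM"): _flat_cell(weakest_lt.cells[("nonNX", "KM")]),
        }
        markers.append(
            MarkerTemplate(f"LTX{i + 1}", "LT-specific differential lipid (synthetic)", cells, scope="LT")
        )
    for i in range(17):
        cells = {
            ("NX", "KM"): weakest_km.cells[("NX", "KM")],
            ("nonNX", "KM"): weakest_km.cells[("nonNX", "KM")],
            ("NX", "LT"): _flat_cell(weakest_km.cells[("nonNX", "LT")]),
            ("nonNX", "LT"): _flat_cell(weakest_km.cells[("nonNX", "LT")]),
        }
        markers.append(
            MarkerTemplate(f"KMX{i + 1}", "KM-specific differential lipid (synthetic)", cells, scope="KM")
        )

    groups = tuple(GroupSpec(r, p, n_per_group) for r in REGIONS for p in PARTS)
    return SyntheticSpec(
        groups=groups,
        markers=tuple(markers),
        n_background=n_background,
        noise=noise,
        n_qc=n_qc,
        seed=seed,
    )


def low_signal_spec(
    *,
    ratio: float = 1.3,
    n_per_group: int = 6,
    n_background: int = 0,
    seed: int = 0,
) -> SyntheticSpec:
    """A deliberately hard authentication world for classifier comparison.

    Keeps the 11-marker layout and the published SEs but shrinks every
    NX/non-NX contrast to the given modest ratio and restores the full
    SE-implied within-group dispersion (``noise_scale = 1``), so classes
    overlap and classifier differences become visible.
    """
    markers: list[MarkerTemplate] = []
    for lipid_id, compound, nx_lt, nx_km, non_lt, non_km in CARNITINE_TEMPLATES:
        cells = {}
        for part, nx_cell, non_cell in (("LT", nx_lt, non_lt), ("KM", nx_km, non_km)):
            base = non_cell[0]
            cells[("NX", part)] = MarkerCell(base * ratio, nx_cell[1], n_design=6)
            cells[("nonNX", part)] = MarkerCell(base, non_cell[1], n_design=12)
        markers.append(MarkerTemplate(lipid_id, compound, cells, scope="both"))
    groups = tuple(GroupSpec(r, p, n_per_group) for r in REGIONS for p in PARTS)
    return SyntheticSpec(
        groups=groups,
        markers=tuple(markers),
        n_background=n_background,
        noise=NoiseModel(noise_scale=1.0),
        n_qc=0,
        seed=seed,
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sigma: float, size: int) -> np.ndarray:
    if sigma <= 0:
        raise ConfigurationError("sigma must be positive")
    a = (0.0 - mean) / sigma
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sigma, size=size, random_state=rng)


def generate(spec: SyntheticSpec, seed: int | None = None) -> FeatureTable:
    """Draw one feature table from the spec.  Deterministic under ``seed``
    (falling back to ``spec.seed``); every abundance is strictly positive."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    sample_ids: list[str] = []
    regions: list[str] = []
    parts: list[str] = []
    roles: list[str] = []
    for g in spec.groups:
        for i in range(g.n):
            sample_ids.append(f"{g.region}-{g.part}-{i + 1:02d}")
            regions.append(g.region)
            parts.append(g.part)
            roles.append("sample")

    n_bio = len(sample_ids)
    part_arr = np.array(parts)
    nx_arr = np.array([r == "NX" for r in regions])

    columns: dict[str, np.ndarray] = {}
    planted_mean: dict[str, float] = {}

    for m in spec.markers:
        col = np.empty(n_bio)
        for part in PARTS:
            for group, gmask in (("NX", nx_arr), ("nonNX", ~nx_arr)):
                mask = (part_arr == part) & gmask
                if not mask.any():
                    continue
                cell = m.cells[(group, part)]
                col[mask] = _truncated_normal(
                    rng, cell.mean, cell.sigma(spec.noise.noise_scale), int(mask.sum())
                )
        columns[m.lipid_id] = col
        planted_mean[m.lipid_id] = float(
            np.mean([m.cells[(g, p)].mean for g in ("NX", "nonNX") for p in PARTS])
        )

    lo_m, hi_m = spec.noise.bg_logmean_range
    lo_s, hi_s = spec.noise.bg_logsd_range
    for j in range(spec.n_background):
        lid = f"BG{j + 1:04d}"
        log_mean = rng.uniform(lo_m, hi_m)
        log_sd = rng.uniform(lo_s, hi_s)
        columns[lid] = rng.lognormal(log_mean, log_sd, n_bio)
        planted_mean[lid] = math.exp(log_mean + 0.5 * log_sd**2)

    # pooled QC injections: overall planted mean with small technical noise
    for q in range(spec.n_qc):
        sample_ids.append(f"QC-{q + 1:02d}")
        regions.append("QC")
        parts.append("QC")
        roles.append("qc")
    if spec.n_qc:
        for lid in columns:
            tech = np.exp(rng.normal(0.0, spec.noise.qc_cv, spec.n_qc))
            columns[lid] = np.concatenate([columns[lid], planted_mean[lid] * tech])

    ab = pd.DataFrame(columns, index=pd.Index(sample_ids, name="sample_id"))
    samples = pd.DataFrame(
        {"region": regions, "part": parts, "role": roles},
        index=ab.index,
    )
    return FeatureTable(ab, samples)
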