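"""Differential-lipid screening and cross-part marker intersection.

For each muscle part independently, the Yanchi (NX) vs non-NX contrast is
screened three ways and the candidate set is the Venn intersection of

* the **volcano** set: Welch two-sided t-test p < 0.05 together with an
  extreme fold change (FC > 4 or FC < 0.25), and
* the **VIP** set: OPLS-DA variable importance in projection > 1.6.

Fold change is oriented non-NX / NX, so lipids elevated in Yanchi lamb
appear *down*-regulated — the orientation under which the published
carnitine markers are all "down".  FC and the t-test run on raw peak areas;
the OPLS-DA model (and hence VIP) runs on autoscaled data.

The candidate sets of the two parts are intersected into the final marker
panel, dropping any lipid whose regulation direction disagrees between
parts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .latent import fit_oplsda, vip_scores
from .preprocess import FeatureTable, autoscale

__all__ = [
    "ScreeningThresholds",
    "ScreeningResult",
    "MarkerPanel",
    "t_test",
    "fold_change",
    "volcano_select",
    "screen_part",
    "intersect_panel",
]


@dataclass(frozen=True)
class ScreeningThresholds:
    """p < 0.05, FC > 4 or < 1/4, VIP > 1.6 by default."""

    p_max: float = 0.05
    fc_up: float = 4.0
    vip_min: float = 1.6

    def __post_init__(self) -> None:
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must lie in (0, 1)")
        if self.fc_up <= 1:
            raise ValueError("fc_up must exceed 1")
        if self.vip_min < 0:
            raise ValueError("vip_min must be non-negative")

    @property
    def fc_down(self) -> float:
        return 1.0 / self.fc_up


def _nx_mask(table: FeatureTable) -> np.ndarray:
    mask = table.region.eq("NX").to_numpy()
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("both NX and non-NX need at least 2 samples")
    return mask


def t_test(table: FeatureTable) -> pd.Series:
    """Welch two-sided t-test per lipid for the NX vs non-NX contrast.

    Zero variance in both groups with equal means yields p = 1 by
    convention (no evidence of a difference); with different means, p = 0.
    """
    mask = _nx_mask(table)
    X = table.values()
    a, b = X[mask], X[~mask]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        equal_means = np.isclose(a.mean(axis=0), b.mean(axis=0))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.Series(p, index=table.lipid_ids, name="p_value")


def fold_change(table: FeatureTable) -> pd.Series:
    """Per-lipid fold change, oriented mean(non-NX) / mean(NX)."""
    mask = _nx_mask(table)
    X = table.values()
    nx_mean = X[mask].mean(axis=0)
    non_mean = X[~mask].mean(axis=0)
    if np.any(nx_mean <= 0):
        bad = [l for l, m in zip(table.lipid_ids, nx_mean) if m <= 0]
        raise ValueError(f"non-positive NX group mean for {bad[:5]}")
    return pd.Series(non_mean / nx_mean, index=table.lipid_ids, name="fold_change")


@dataclass
class ScreeningResult:
    """Per-lipid screening statistics and pass flags for one part."""

    part: str
    table: pd.DataFrame  # columns: p_value, fold_change, vip, direction, passes_volcano, passes_vip, selected
    thresholds: ScreeningThresholds

    @property
    def selected(self) -> set[str]:
        return set(self.table.index[self.table["selected"]])

    @property
    def up(self) -> set[str]:
        return set(self.table.index[self.table["passes_volcano"] & self.table["direction"].eq("up")])

    @property
    def down(self) -> set[str]:
        return set(self.table.index[self.table["passes_volcano"] & self.table["direction"].eq("down")])

    def direction_of(self, lipid_id: str) -> str:
        return str(self.table.loc[lipid_id, "direction"])


def _assemble(
    part: str,
    p: pd.Series,
    fc: pd.Series,
    vip: pd.Series,
    thresholds: ScreeningThresholds,
) -> ScreeningResult:
    direction = pd.Series("none", index=p.index)
    direction[(fc > thresholds.fc_up) & (p < thresholds.p_max)] = "up"
    direction[(fc < thresholds.fc_down) & (p < thresholds.p_max)] = "down"
    passes_volcano = direction.ne("none")
    passes_vip = vip > thresholds.vip_min
    df = pd.DataFrame(
        {
            "p_value": p,
            "fold_change": fc,
            "vip": vip,
            "direction": direction,
            "passes_volcano": passes_volcano,
            "passes_vip": passes_vip,
            "selected": passes_volcano & passes_vip,
        }
    )
    return ScreeningResult(part=part, table=df, thresholds=thresholds)


def volcano_select(
    result: ScreeningResult | pd.DataFrame,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
) -> tuple[set[str], set[str]]:
    """(up, down) lipid-id sets by the volcano rule alone."""
    df = result.table if isinstance(result, ScreeningResult) else result
    p, fc = df["p_value"], df["fold_change"]
    up = set(df.index[(fc > thresholds.fc_up) & (p < thresholds.p_max)])
    down = set(df.index[(fc < thresholds.fc_down) & (p < thresholds.p_max)])
    return up, down


def screen_part(
    table: FeatureTable,
    part: str,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
    n_orthogonal: int = 1,
) -> ScreeningResult:
    """Run the full per-part screen (t-test + FC on raw data, VIP on
    autoscaled data) for the NX vs non-NX contrast within one muscle part."""
    sub = table.subset(part=part, biological_only=True)
    if sub.n_samples == 0:
        raise ValueError(f"no biological samples for part {part!r}")
    p = t_test(sub)
    fc = fold_change(sub)
    scaled, _ = autoscale(sub)
    model = fit_oplsda(scaled, sub.nx_labels().to_numpy(), n_orthogonal=n_orthogonal)
    vip = vip_scores(model).vip
    return _assemble(part, p, fc, vip, thresholds)


@dataclass
class MarkerPanel:
    per_part_sets: dict[str, set[str]]
    markers: list[str]  # ordered intersection
    direction: dict[str, str] = field(default_factory=dict)

    @property
    def intersection(self) -> set[str]:
        return set(self.markers)

    def __len__(self) -> int:
        return len(self.markers)


def intersect_panel(lt: ScreeningResult, km: ScreeningResult) -> MarkerPanel:
    """Venn intersection of the per-part candidate sets with a direction
    consistency check; direction-conflicting lipids are dropped with a
    warning.  An empty panel is returned as such — pipeline code decides
    whether that is fatal."""
    lt_set, km_set = lt.selected, km.selected
    ordered = [l for l in lt.table.index if l in lt_set and l in km_set]
    markers, direction = [], {}
    for lipid in ordered:
        d_lt, d_km = lt.direction_of(lipid), km.direction_of(lipid)
        if d_lt != d_km:
            warnings.warn(f"{lipid}: direction conflict between parts ({d_lt} vs {d_km}); dropped")
            continue
        markers.append(lipid)
        direction[lipid] = d_lt
    return MarkerPanel(
        per_part_sets={lt.part: lt_set, km.part: km_set},
        markers=markers,
        direction=direction,
    )
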