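"""Haplogroup frequency tables and northern/southern route attribution.

Route attribution is an input heuristic, not an inference: a table assigns
each founder haplogroup to the northern or southern entry route into Sahul
(or marks it intrusive, i.e. a Late Glacial/postglacial arrival excluded
from the founder denominator).  Haplogroups not listed explicitly inherit
the nearest listed ancestor's route through the reference haplogroup tree;
region-specific overrides allow context-dependent calls (e.g. haplogroup Q
lineages are intrusive in Australia but indigenous in New Guinea).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .haplotree import ReferenceHaplogroupTree
from .mito_io import ValidationError

ROUTES = ("northern", "southern", "intrusive")


class UnresolvedHaplogroupError(ValidationError):
    def __init__(self, labels: Sequence[str]):
        self.labels = sorted(set(labels))
        super().__init__(f"no route assignment resolves for haplogroup(s): {self.labels}")


@dataclass(frozen=True)
class RouteTable:
    assignments: Mapping[str, str]

    def __post_init__(self):
        bad = {r for r in self.assignments.values() if r not in ROUTES}
        if bad:
            raise ValidationError(f"unknown route(s) {sorted(bad)}; valid: {ROUTES}")


def read_route_table(path: str | Path) -> RouteTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return RouteTable(dict(zip(df["haplogroup"], df["route"])))


def read_overrides(path: str | Path) -> dict[tuple[str, str], str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {(r.region, r.haplogroup): r.route for r in df.itertuples()}


def resolve_route(
    haplogroup: str,
    region: str,
    routes: RouteTable,
    ref_tree: ReferenceHaplogroupTree | None = None,
    region_overrides: Mapping[tuple[str, str], str] | None = None,
) -> str | None:
    """Walk from the haplogroup toward the root; at each level a region
    override beats the base table.  Returns None when nothing resolves."""
    overrides = region_overrides or {}
    labels = [haplogroup]
    if ref_tree is not None and haplogroup in ref_tree.nodes:
        labels = ref_tree.path_to_root(haplogroup)
    for label in labels:
        if (region, label) in overrides:
            return overrides[(region, label)]
        if label in routes.assignments:
            return routes.assignments[label]
    return None


@dataclass(frozen=True)
class RegionSummary:
    region_label: str
    n_total: int
    n_intrusive: int
    route_fractions: Mapping[str, float]  # % of nonintrusive lineages
    intrusive_pct_of_total: float
    flagged: bool = False  # True when every lineage is intrusive

    def rounded(self) -> dict[str, int]:
        """Display percentages, half-up to integers."""
        return {
            r: int(Decimal(str(f)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
            for r, f in self.route_fractions.items()
        }


def haplogroup_frequencies(
    samples: Sequence[tuple[str, str, str]] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-region haplogroup counts and percentages.

    ``samples`` rows are (sample_id, region_label, haplogroup).  Raises on
    duplicate sample ids.  Deterministic ordering: region, then haplogroup.
    """
    df = _as_frame(samples)
    out = (
        df.groupby(["region_label", "haplogroup"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = out.groupby("region_label")["count"].transform("sum")
    out["percent"] = 100.0 * out["count"] / totals
    return out


def _as_frame(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        df = samples[["sample_id", "region_label", "haplogroup"]].copy()
    else:
        df = pd.DataFrame(samples, columns=["sample_id", "region_label", "haplogroup"])
    if df.empty:
        raise ValidationError("no samples supplied")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ValidationError(f"duplicate sample_id(s): {dups}")
    return df


def attribute_routes(
    samples: Sequence[tuple[str, str, str]] | pd.DataFrame,
    routes: RouteTable,
    ref_tree: ReferenceHaplogroupTree | None = None,
    region_overrides: Mapping[tuple[str, str], str] | None = None,
) -> list[RegionSummary]:
    """Per-region route composition of the founder (nonintrusive) lineages.

    Intrusive samples are excluded from the route-fraction denominator but
    reported both as a count and as a percentage of the total sample, so
    either convention can be read off.  Unresolvable haplogroups raise an
    explicit error listing the offending labels.
    """
    df = _as_frame(samples)
    resolved = []
    missing = []
    for row in df.itertuples():
        r = resolve_route(row.haplogroup, row.region_label, routes, ref_tree, region_overrides)
        if r is None:
            missing.append(row.haplogroup)
        resolved.append(r)
    if missing:
        raise UnresolvedHaplogroupError(missing)
    df = df.assign(route=resolved)

    summaries = []
    for region, grp in df.groupby("region_label", sort=True):
        n_total = len(grp)
        n_intr = int((grp["route"] == "intrusive").sum())
        founders = grp[grp["route"] != "intrusive"]
        if founders.empty:
            summaries.append(RegionSummary(region, n_total, n_intr, {},
                                           100.0 * n_intr / n_total, flagged=True))
            continue
        fractions = {
            route: 100.0 * int((founders["route"] == route).sum()) / len(founders)
            for route in ("northern", "southern")
        }
        summaries.append(
            RegionSummary(region, n_total, n_intr, fractions,
                          100.0 * n_intr / n_total)
        )
    return summaries


def summaries_to_frame(summaries: Sequence[RegionSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({
            "region_label": s.region_label,
            "n_total": s.n_total,
            "n_intrusive": s.n_intrusive,
            "intrusive_pct_of_total": s.intrusive_pct_of_total,
            "northern_pct": s.route_fractions.get("northern", float("nan")),
            "southern_pct": s.route_fractions.get("southern", float("nan")),
            "flagged": s.flagged,
        })
    return pd.DataFrame(rows)
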