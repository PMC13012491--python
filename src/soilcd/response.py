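"""Classification of cadmium-responsive taxa and summary accounting.

Two complementary definitions of responsiveness are implemented:

* **composition** — taxa differentially abundant between the high and low
  natural soil-Cd categories (low as reference), with the sign of the
  log-fold change giving the direction;
* **activity** — set logic over the spiking assay: a taxon enriched over
  the S -> P/E course of the experiment in the Cd-spiked arm that is NOT
  enriched in the paired control arm responds to cadmium; a taxon enriched
  in both arms merely grows on the culture medium and is labelled
  non-response.

Soil Cd concentrations are bucketed into low/medium/high categories with
left-closed bounds (defaults 1 and 2 mg/kg) so every concentration maps to
exactly one category. Core-taxon partitions (Venn regions over categories
or farms) use a prevalence/detection occurrence rule.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .diffabund import Contrast, DiffAbundResult, differential_abundance
from .io import CountTable

__all__ = [
    "ResponsiveCall",
    "ResponseSummary",
    "assign_cd_category",
    "classify_composition_responders",
    "classify_activity_responders",
    "timepoint_enrichment",
    "core_taxa",
    "summarize_response",
]

CD_CATEGORIES = ("low", "medium", "high")


@dataclass(frozen=True)
class ResponsiveCall:
    """One taxon called responsive, with its evidence trail."""

    taxon_id: str
    evidence: str      # composition | activity
    direction: str     # positive | negative
    contrast: str      # e.g. "high-vs-low" or "spiked:P|E-vs-S"


@dataclass(frozen=True)
class ResponseSummary:
    """Responder accounting over a taxon universe at one rank."""

    n_taxa_total: int
    n_responsive: int
    n_positive: int
    n_negative: int
    rank: str = "asv"

    @property
    def fraction_responsive(self) -> float:
        return self.n_responsive / self.n_taxa_total

    @property
    def fraction_positive(self) -> float:
        return self.n_positive / self.n_taxa_total

    @property
    def fraction_negative(self) -> float:
        return self.n_negative / self.n_taxa_total

    @property
    def fraction_stable(self) -> float:
        return 1.0 - self.fraction_responsive

    def to_dict(self) -> dict:
        return {
            "n_taxa_total": self.n_taxa_total,
            "n_responsive": self.n_responsive,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "fraction_responsive": self.fraction_responsive,
            "fraction_positive": self.fraction_positive,
            "fraction_negative": self.fraction_negative,
            "fraction_stable": self.fraction_stable,
            "rank": self.rank,
        }


def assign_cd_category(cd_soil: float, config: PipelineConfig | None = None) -> str:
    """low / medium / high for a soil Cd concentration in mg/kg.

    Bounds are left-closed: low [0, b1), medium [b1, b2), high [b2, inf),
    so the assignment is total and single-valued on [0, inf).
    """
    config = config or PipelineConfig()
    if not np.isfinite(cd_soil):
        raise ValueError("cd_soil must be finite")
    if cd_soil < 0:
        raise ValueError("cd_soil must be >= 0 (mg kg^-1)")
    b1, b2 = config.cd_category_bounds
    if cd_soil < b1:
        return "low"
    if cd_soil < b2:
        return "medium"
    return "high"


def classify_composition_responders(
    da: Sequence[DiffAbundResult],
    alpha: float = 0.05,
    rank: str = "asv",
    contrast_label: str = "high-vs-low",
) -> tuple[list[ResponsiveCall], ResponseSummary]:
    """Responsive taxa from a high-vs-low differential-abundance run.

    A taxon is responsive iff its BH-adjusted q <= alpha; direction follows
    the sign of the log-fold change. The summary denominator is every taxon
    in the result list (tested taxa plus reported structural zeros).
    """
    if not da:
        raise ValueError("empty differential-abundance result")
    calls: list[ResponsiveCall] = []
    for r in da:
        if r.structural_zero or not np.isfinite(r.q) or r.q > alpha:
            continue
        direction = "positive" if r.lfc > 0 else "negative"
        calls.append(ResponsiveCall(r.taxon_id, "composition", direction, contrast_label))
    summary = summarize_response(calls, [r.taxon_id for r in da], rank=rank)
    return calls, summary


def classify_activity_responders(
    enriched_spiked: Mapping[str, int],
    enriched_control: Iterable[str],
    contrast_label: str = "spiked:P|E-vs-S",
) -> list[ResponsiveCall]:
    """Set logic of the spiking assay: spiked-only enrichment means response.

    ``enriched_spiked`` maps taxon -> sign of its enrichment in the spiked
    arm; ``enriched_control`` lists taxa enriched in the control arm. Taxa
    enriched in both arms grew on the medium, not on Cd, and are excluded.
    """
    control = set(enriched_control)
    calls = []
    for taxon in sorted(set(enriched_spiked) - control):
        sign = enriched_spiked[taxon]
        direction = "positive" if sign > 0 else "negative"
        calls.append(ResponsiveCall(taxon, "activity", direction, contrast_label))
    return calls


def timepoint_enrichment(
    table: CountTable,
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
    rule: str = "union",
) -> dict[str, dict[str, int]]:
    """Per-arm enriched taxa over the assay course (S as reference).

    Within each arm (control, spiked) the differential-abundance model is
    run for P-vs-S and E-vs-S. A taxon is enriched when significantly
    *increased* (positive direction) in either contrast (``rule='union'``,
    the default) or in both (``rule='intersection'``). Returns
    ``{arm: {taxon: +1}}``.
    """
    config = config or PipelineConfig()
    if rule not in ("union", "intersection"):
        raise ValueError("rule must be 'union' or 'intersection'")
    meta = metadata.set_index("sample_id")
    out: dict[str, dict[str, int]] = {}
    for arm in ("control", "spiked"):
        arm_samples = [
            s for s in table.samples
            if meta.loc[s, "treatment"] == arm and meta.loc[s, "timepoint"] in ("S", "P", "E")
        ]
        sub = table.select_samples(arm_samples)
        tps = set(meta.loc[arm_samples, "timepoint"])
        if "S" not in tps or not ({"P", "E"} & tps):
            missing = "S" if "S" not in tps else "P/E"
            raise ValueError(f"arm {arm!r} is missing timepoint {missing}")
        arm_meta = metadata[metadata["sample_id"].isin(arm_samples)]
        per_contrast: list[set[str]] = []
        for later in ("P", "E"):
            if later not in tps:
                continue
            da = differential_abundance(
                sub, arm_meta, Contrast("timepoint", "S", later), config
            )
            per_contrast.append({r.taxon_id for r in da if r.direction == "positive"})
        merged = set.union(*per_contrast) if rule == "union" else set.intersection(*per_contrast)
        out[arm] = {t: 1 for t in sorted(merged)}
    return out


def core_taxa(
    table: CountTable,
    grouping: Sequence[str],
    config: PipelineConfig | None = None,
) -> dict[frozenset[str], int]:
    """Venn partition counts of taxon occurrence across groups.

    A taxon occurs in a group iff its relative abundance reaches the
    detection threshold in at least the prevalence fraction of the group's
    samples (both thresholds from the config; defaults 0.001 prevalence,
    1/100 detection). Returns region -> count, keyed by the frozenset of
    groups a taxon occurs in; taxa occurring nowhere are not counted.
    """
    config = config or PipelineConfig()
    grouping = np.asarray([str(g) for g in grouping])
    if len(grouping) != table.n_samples:
        raise ValueError("grouping length must match sample count")
    levels = list(pd.unique(grouping))
    rel = table.relative_abundance()
    occurs: dict[str, np.ndarray] = {}
    for g in levels:
        cols = grouping == g
        if cols.sum() == 0:
            raise ValueError(f"group {g!r} has no samples")
        detected = rel[:, cols] >= config.detection_threshold
        occurs[g] = detected.mean(axis=1) >= config.prevalence_threshold
    regions: Counter[frozenset[str]] = Counter()
    for i in range(table.n_taxa):
        region = frozenset(g for g in levels if occurs[g][i])
        if region:
            regions[region] += 1
    return dict(regions)


def summarize_response(
    calls: Sequence[ResponsiveCall],
    universe: Sequence[str],
    rank: str = "asv",
) -> ResponseSummary:
    """Responder fractions over a taxon universe.

    Positive and negative calls partition the responsive set; responsive
    plus stable fractions sum to one.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty taxon universe")
    ids = {c.taxon_id for c in calls}
    stray = ids - set(universe)
    if stray:
        raise ValueError(f"calls outside the universe: {sorted(stray)[:5]}")
    n_pos = sum(1 for c in calls if c.direction == "positive")
    n_neg = sum(1 for c in calls if c.direction == "negative")
    return ResponseSummary(
        n_taxa_total=len(universe),
        n_responsive=len(calls),
        n_positive=n_pos,
        n_negative=n_neg,
        rank=rank,
    )
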