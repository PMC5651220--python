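"""Per-residue ligand-contact-based scoring (LCBSR) over energy-tiered pose ensembles.

The score of a residue r within one energy tier is

    LCBSR(r) = log(NCo - NCl) - log(NH / CCl)

where NCo, NCl and NH are the total numbers of contact, clash and
hydrogen-bond *events* between r and any ligand atom summed over every pose
in the tier, and CCl is the number of poses in which r clashes at least
once. Poses are tiered by binding energy with strict thresholds (default
−2.0, −3.0, −4.0 kcal/mol); tiers are nested, so a residue touched by
strongly binding poses accrues the term up to three times, which up-weights
residues contacted by the best-energy conformations. Per-experiment scores
are summed across independent blind-docking experiments, and residues seen
in too few experiments are dropped.

The logarithm is natural by default (base-10 selectable). A term is
*degenerate* — undefined, contributing 0 — when NCo − NCl ≤ 0, NH = 0 or
CCl = 0; a pseudocount mode (NH+1, CCl+1) is available instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Mapping, Optional, Sequence, Tuple

from .errors import ConfigurationError
from .interactions import (
    InteractionParams,
    PoseInteractionRecord,
    enumerate_pose_interactions,
)
from .structures import Pose, PoseEnsemble, Receptor, ResidueKey

__all__ = [
    "TierSpec",
    "InteractionCounts",
    "ResidueScore",
    "AggregatedScore",
    "tier_poses",
    "accumulate_counts",
    "lcbsr_term",
    "score_experiment",
    "aggregate_experiments",
]

LogBase = Literal["natural", "10"]
DegeneratePolicy = Literal["undefined", "pseudocount"]

DEFAULT_TIERS = (-2.0, -3.0, -4.0)


@dataclass(frozen=True)
class TierSpec:
    """Strictly decreasing binding-energy thresholds (kcal/mol).

    Tier t keeps poses with binding_energy < thresholds[t], so successive
    tiers are nested subsets.
    """

    thresholds: Tuple[float, ...] = DEFAULT_TIERS

    def __post_init__(self) -> None:
        object.__setattr__(self, "thresholds", tuple(self.thresholds))
        if not self.thresholds:
            raise ConfigurationError("TierSpec needs at least one threshold")
        if any(b >= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ConfigurationError(
                f"tier thresholds must be strictly decreasing: {self.thresholds}"
            )

    @property
    def n_tiers(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class InteractionCounts:
    """The four LCBSR operands for one residue in one tier."""

    n_contacts: int = 0          # NCo: contact events over all tier poses
    n_clashes: int = 0           # NCl: clash events over all tier poses
    n_hbonds: int = 0            # NH:  H-bond events over all tier poses
    n_clash_conformers: int = 0  # CCl: poses with >=1 clash with this residue

    def __post_init__(self) -> None:
        if min(self.n_contacts, self.n_clashes, self.n_hbonds,
               self.n_clash_conformers) < 0:
            raise ConfigurationError("interaction counts must be non-negative")
        if self.n_clash_conformers > self.n_clashes:
            raise ConfigurationError(
                "clash-conformer count cannot exceed clash-event count"
            )

    def __add__(self, other: "InteractionCounts") -> "InteractionCounts":
        return InteractionCounts(
            self.n_contacts + other.n_contacts,
            self.n_clashes + other.n_clashes,
            self.n_hbonds + other.n_hbonds,
            self.n_clash_conformers + other.n_clash_conformers,
        )

    @property
    def is_zero(self) -> bool:
        return (self.n_contacts | self.n_clashes | self.n_hbonds
                | self.n_clash_conformers) == 0


@dataclass
class ResidueScore:
    """One residue's per-tier terms and summed score within one experiment."""

    residue_key: ResidueKey
    experiment_id: str
    tier_scores: Tuple[Optional[float], ...]
    tier_counts: Tuple[InteractionCounts, ...] = ()

    @property
    def experiment_score(self) -> float:
        return sum(s for s in self.tier_scores if s is not None)

    @property
    def is_degenerate(self) -> bool:
        """True when no tier produced a defined term."""
        return all(s is None for s in self.tier_scores)


@dataclass
class AggregatedScore:
    """Cross-experiment summary for one residue."""

    residue_key: ResidueKey
    experiment_scores: Dict[str, float] = field(default_factory=dict)
    presence: int = 0
    final_score: float = 0.0


def tier_poses(ensemble: PoseEnsemble, tiers: TierSpec = TierSpec()) -> List[List[Pose]]:
    """Nested pose subsets: subset t holds poses with energy strictly below
    thresholds[t]. A pose at exactly the threshold is excluded."""
    return [
        [p for p in ensemble.poses if p.binding_energy < threshold]
        for threshold in tiers.thresholds
    ]


def _accumulate_records(
    records: Sequence[PoseInteractionRecord],
) -> Dict[ResidueKey, InteractionCounts]:
    counts: Dict[ResidueKey, List[int]] = {}
    for rec in records:
        keys = set(rec.contacts) | set(rec.clashes) | set(rec.hbonds)
        for key in keys:
            c = counts.setdefault(key, [0, 0, 0, 0])
            c[0] += rec.contacts.get(key, 0)
            c[1] += rec.clashes.get(key, 0)
            c[2] += rec.hbonds.get(key, 0)
            c[3] += 1 if key in rec.clashing_residues else 0
    return {
        key: InteractionCounts(*c)
        for key, c in counts.items()
        if any(c)
    }


def accumulate_counts(
    poses: Sequence[Pose],
    receptor: Receptor,
    params: InteractionParams = InteractionParams(),
) -> Dict[ResidueKey, InteractionCounts]:
    """Sum per-residue contact/clash/H-bond events over a pose subset.

    NCo, NCl and NH are event totals; CCl counts poses with at least one
    clash. Residues with all-zero counts are omitted.
    """
    records = [enumerate_pose_interactions(p, receptor, params) for p in poses]
    return _accumulate_records(records)


def _log(x: float, base: LogBase) -> float:
    return math.log10(x) if base == "10" else math.log(x)


def lcbsr_term(
    counts: InteractionCounts,
    log_base: LogBase = "natural",
    degenerate_policy: DegeneratePolicy = "undefined",
) -> Optional[float]:
    """log(NCo − NCl) − log(NH / CCl), or None when the operands are degenerate.

    Under the default policy the term is undefined (None) whenever
    NCo − NCl ≤ 0, NH = 0 or CCl = 0. The pseudocount policy adds 1 to NH
    and CCl before testing, so only NCo − NCl ≤ 0 stays undefined.
    """
    nco_m_ncl = counts.n_contacts - counts.n_clashes
    nh, ccl = counts.n_hbonds, counts.n_clash_conformers
    if degenerate_policy == "pseudocount":
        nh, ccl = nh + 1, ccl + 1
    if nco_m_ncl <= 0 or nh <= 0 or ccl <= 0:
        return None
    return _log(float(nco_m_ncl), log_base) - _log(nh / ccl, log_base)


def score_experiment(
    ensemble: PoseEnsemble,
    receptor: Receptor,
    tiers: TierSpec = TierSpec(),
    params: InteractionParams = InteractionParams(),
    log_base: LogBase = "natural",
    degenerate_policy: DegeneratePolicy = "undefined",
    sum_counts_first: bool = False,
) -> Dict[ResidueKey, ResidueScore]:
    """Score every receptor residue against one blind-docking experiment.

    Each pose is enumerated once; its record is then folded into every tier
    whose threshold its energy beats. With ``sum_counts_first`` the per-tier
    counts are summed into a single operand set and scored once instead of
    summing the per-tier scores.
    """
    records = {
        p.index: enumerate_pose_interactions(p, receptor, params)
        for p in ensemble.poses
    }
    tier_records = [
        [records[p.index] for p in subset]
        for subset in tier_poses(ensemble, tiers)
    ]
    per_tier_counts = [_accumulate_records(recs) for recs in tier_records]

    residues = sorted({key for tier in per_tier_counts for key in tier})
    out: Dict[ResidueKey, ResidueScore] = {}
    zero = InteractionCounts()
    for key in residues:
        tier_counts = tuple(tier.get(key, zero) for tier in per_tier_counts)
        if sum_counts_first:
            total = sum(tier_counts, zero)
            term = lcbsr_term(total, log_base, degenerate_policy)
            out[key] = ResidueScore(key, ensemble.experiment_id, (term,), (total,))
        else:
            terms = tuple(
                lcbsr_term(c, log_base, degenerate_policy) if not c.is_zero else None
                for c in tier_counts
            )
            out[key] = ResidueScore(key, ensemble.experiment_id, terms, tier_counts)
    return out


def aggregate_experiments(
    score_maps: Sequence[Mapping[ResidueKey, ResidueScore]],
    min_presence: int = 2,
) -> Dict[ResidueKey, AggregatedScore]:
    """Sum experiment scores per residue and drop residues seen in too few
    experiments.

    A residue *appears* in an experiment when at least one of its tier terms
    is defined there. Residues with presence < min_presence are excluded.
    """
    if not score_maps:
        raise ConfigurationError("need at least one experiment score map")
    if min_presence > len(score_maps):
        raise ConfigurationError(
            f"min_presence={min_presence} exceeds the number of experiments "
            f"({len(score_maps)})"
        )
    merged: Dict[ResidueKey, AggregatedScore] = {}
    for smap in score_maps:
        for key, rscore in smap.items():
            agg = merged.setdefault(key, AggregatedScore(residue_key=key))
            agg.experiment_scores[rscore.experiment_id] = rscore.experiment_score
            if not rscore.is_degenerate:
                agg.presence += 1
            agg.final_score += rscore.experiment_score
    return {
        key: agg for key, agg in merged.items() if agg.presence >= min_presence
    }
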