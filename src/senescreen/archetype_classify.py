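"""Archetype-based classification of senescence profiles.

Every genotype's mean density profile (MDP) is correlated against three
archetypal profiles:

* **normal** — wild-type-control-like entry into and partial recovery from
  senescence (membership: r > 0.85);
* **no_recovery** — accelerated senescence with failure to produce
  survivors (membership: r > 0.5 *and* an absolute early-fitness filter —
  mean size at passage 2 below C^s = C_ave - 0.5 * C_sd, computed over all
  individual double-mutant culture sizes at that passage);
* **fast_recovery** — accelerated entry into *and* exit from senescence
  (membership: the top-k most correlated genotypes, default k = 20, since
  a strict r cutoff leaves almost no members of this class).

Memberships are non-exclusive.  Alongside classification, the module
computes each genotype's recovered fraction: the share of its replicate
cultures reaching a size threshold (default 1000 transformed units) by a
deadline passage (default 19).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .plate_model import ScreenDataset
from .profile import MDP, pearson_correlation

__all__ = [
    "Passage2Filter",
    "ArchetypeConfig",
    "ClassAssignment",
    "RankedList",
    "CLASS_LABELS",
    "compute_passage2_filter",
    "rank_by_archetype",
    "assign_classes",
    "recovered_fraction",
    "class_recovery_summary",
    "write_classification_table",
    "write_ranked_list",
]

CLASS_LABELS = ("normal", "no_recovery", "fast_recovery")


@dataclass(frozen=True)
class Passage2Filter:
    """Early-fitness cutoff for no-recovery membership.

    ``c_ave`` and ``c_sd`` are the mean and standard deviation of *all*
    individual culture sizes at the filter passage; the cutoff is
    ``c_s = c_ave - 0.5 * c_sd``.  A genotype passes when its mean size at
    that passage is below ``c_s`` — i.e. it is already sicker than the
    bulk of the screen early on.
    """

    c_ave: float
    c_sd: float
    passage: int = 2
    scale: str = "transformed"

    def __post_init__(self) -> None:
        if self.c_sd < 0:
            raise ValueError("c_sd must be non-negative")

    @property
    def c_s(self) -> float:
        return self.c_ave - 0.5 * self.c_sd

    def passes(self, mdp: MDP) -> bool:
        return bool(mdp.mean[self.passage - 1] < self.c_s)


@dataclass(frozen=True)
class ArchetypeConfig:
    """Thresholds and archetype identities for classification."""

    normal_archetype: str = "his3"
    no_recovery_archetype: str = "rad52"
    fast_recovery_archetype: str = "rif1"
    r_normal: float = 0.85
    r_no_recovery: float = 0.5
    fast_recovery_top_k: int = 20
    recovery_size_threshold: float = 1000.0
    recovery_passage: int = 19
    recovery_mode: str = "by_passage"
    filter_passage: int = 2

    def __post_init__(self) -> None:
        for name in ("r_normal", "r_no_recovery"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1), got {v}")
        if self.fast_recovery_top_k < 1:
            raise ValueError("fast_recovery_top_k must be >= 1")
        if self.recovery_mode not in ("by_passage", "at_passage"):
            raise ValueError(f"unknown recovery_mode {self.recovery_mode!r}")

    @property
    def archetypes(self) -> dict[str, str]:
        return {
            "normal": self.normal_archetype,
            "no_recovery": self.no_recovery_archetype,
            "fast_recovery": self.fast_recovery_archetype,
        }


@dataclass
class ClassAssignment:
    """One genotype's correlations, filter outcome and memberships."""

    genotype: str
    n_repeats: int
    r_normal: float | None
    r_no_recovery: float | None
    r_fast_recovery: float | None
    passes_p2_filter: bool
    memberships: set[str] = field(default_factory=set)
    recovered_fraction: float = 0.0


@dataclass
class RankedList:
    """Genotypes ordered by decreasing correlation to one archetype.

    The archetype itself ranks first (r = 1 with itself); genotypes whose
    correlation is undefined (constant profile) sort after all defined
    values.  Ties are broken by genotype label.
    """

    archetype: str
    entries: list[tuple[str, float | None]]


def compute_passage2_filter(
    dataset: ScreenDataset, passage: int = 2
) -> Passage2Filter:
    """Compute the early-fitness cutoff from all individual culture sizes
    (not genotype means) at the given passage."""
    sizes = dataset.sizes_at_passage(passage)  # validates the passage range
    c_ave = float(np.mean(sizes))
    c_sd = float(np.std(sizes, ddof=1)) if sizes.size > 1 else 0.0
    return Passage2Filter(c_ave=c_ave, c_sd=c_sd, passage=passage, scale=dataset.scale)


def _sort_key(item: tuple[str, float | None]):
    genotype, r = item
    # defined r first (descending), undefined last; ties alphabetical
    return (r is None, -(r if r is not None else 0.0), genotype)


def rank_by_archetype(mdps: Mapping[str, MDP], archetype: str) -> RankedList:
    """Rank every genotype by Pearson r of its MDP to the archetype MDP."""
    if archetype not in mdps:
        raise KeyError(f"archetype {archetype!r} not among the provided MDPs")
    ref = mdps[archetype]
    entries: list[tuple[str, float | None]] = []
    for genotype, mdp in mdps.items():
        if genotype == archetype:
            entries.append((genotype, 1.0))
        else:
            entries.append((genotype, pearson_correlation(mdp, ref)))
    entries.sort(key=_sort_key)
    return RankedList(archetype=archetype, entries=entries)


def _top_k_members(ranked: RankedList, k: int) -> set[str]:
    """Top-k genotypes by r; all genotypes tied at the k-th r value are
    included (stable superset rule)."""
    defined = [(g, r) for g, r in ranked.entries if r is not None]
    if len(defined) <= k:
        return {g for g, _ in defined}
    cutoff = defined[k - 1][1]
    return {g for g, r in defined if r >= cutoff}


def assign_classes(
    mdps: Mapping[str, MDP],
    dataset: ScreenDataset,
    cfg: ArchetypeConfig | None = None,
    p2_filter: Passage2Filter | None = None,
) -> dict[str, ClassAssignment]:
    """Classify every genotype against the three archetypes.

    Memberships are non-exclusive.  An undefined correlation to an
    archetype (constant profile) excludes that membership, never grants it.
    """
    cfg = cfg or ArchetypeConfig()
    for cls, label in cfg.archetypes.items():
        if label not in mdps:
            raise KeyError(f"{cls} archetype {label!r} not among the provided MDPs")
    if p2_filter is None:
        p2_filter = compute_passage2_filter(dataset, cfg.filter_passage)

    refs = {cls: mdps[label] for cls, label in cfg.archetypes.items()}
    fast_rank = rank_by_archetype(mdps, cfg.fast_recovery_archetype)
    fast_members = _top_k_members(fast_rank, cfg.fast_recovery_top_k)

    assignments: dict[str, ClassAssignment] = {}
    for genotype, mdp in mdps.items():
        rs: dict[str, float | None] = {}
        for cls, ref in refs.items():
            if genotype == cfg.archetypes[cls]:
                rs[cls] = 1.0
            else:
                rs[cls] = pearson_correlation(mdp, ref)
        passes = p2_filter.passes(mdp)
        memberships: set[str] = set()
        if rs["normal"] is not None and rs["normal"] > cfg.r_normal:
            memberships.add("normal")
        if (
            rs["no_recovery"] is not None
            and rs["no_recovery"] > cfg.r_no_recovery
            and passes
        ):
            memberships.add("no_recovery")
        if genotype in fast_members:
            memberships.add("fast_recovery")
        assignments[genotype] = ClassAssignment(
            genotype=genotype,
            n_repeats=mdp.n_repeats,
            r_normal=rs["normal"],
            r_no_recovery=rs["no_recovery"],
            r_fast_recovery=rs["fast_recovery"],
            passes_p2_filter=passes,
            memberships=memberships,
            recovered_fraction=recovered_fraction(dataset, genotype, cfg),
        )
    return assignments


def recovered_fraction(
    dataset: ScreenDataset, genotype: str, cfg: ArchetypeConfig | None = None
) -> float:
    """Fraction of a genotype's replicate cultures that recovered.

    Recovery means regrowth out of senescence: cultures start healthy and
    decline, so simply being large at some early passage is not recovery.
    ``by_passage`` mode (default): a culture counts as recovered if, at or
    after its own fitness nadir (the minimum of its full trajectory) and no
    later than the deadline passage, its size reaches the threshold.  A
    culture whose nadir falls after the deadline is still declining and has
    not recovered.  ``at_passage`` tests only the size at the deadline
    passage itself.  Both modes are non-decreasing in the deadline and
    non-increasing in the threshold.
    """
    cfg = cfg or ArchetypeConfig()
    if cfg.recovery_passage > dataset.passage_count:
        raise ValueError(
            f"recovery passage {cfg.recovery_passage} exceeds experiment "
            f"length {dataset.passage_count}"
        )
    mat = dataset.size_matrix(genotype)
    if cfg.recovery_mode == "by_passage":
        nadir_idx = mat.argmin(axis=1)
        peak = np.array(
            [
                row[i : cfg.recovery_passage].max() if i < cfg.recovery_passage else -np.inf
                for row, i in zip(mat, nadir_idx)
            ]
        )
    else:
        peak = mat[:, cfg.recovery_passage - 1]
    return float(np.mean(peak >= cfg.recovery_size_threshold))


def class_recovery_summary(
    assignments: Mapping[str, ClassAssignment],
    dataset: ScreenDataset | None = None,
    cfg: ArchetypeConfig | None = None,
) -> dict[str, float | None]:
    """Unweighted mean recovered fraction of the member genotypes of each
    class; None (flagged) for an empty class."""
    out: dict[str, float | None] = {}
    for cls in CLASS_LABELS:
        fracs = [
            a.recovered_fraction for a in assignments.values() if cls in a.memberships
        ]
        out[cls] = float(np.mean(fracs)) if fracs else None
    return out


def write_classification_table(
    assignments: Mapping[str, ClassAssignment], path
) -> None:
    def fmt(r: float | None) -> str:
        return "NA" if r is None else repr(r)

    with open(path, "w") as fh:
        fh.write(
            "genotype\tn_repeats\tr_normal\tr_no_recovery\tr_fast_recovery\t"
            "passes_p2_filter\tmemberships\trecovered_fraction\n"
        )
        for genotype in sorted(assignments):
            a = assignments[genotype]
            fh.write(
                f"{a.genotype}\t{a.n_repeats}\t{fmt(a.r_normal)}\t"
                f"{fmt(a.r_no_recovery)}\t{fmt(a.r_fast_recovery)}\t"
                f"{int(a.passes_p2_filter)}\t"
                f"{';'.join(sorted(a.memberships))}\t{a.recovered_fraction!r}\n"
            )


def write_ranked_list(ranked: RankedList, path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tgenotype\tr\n")
        for i, (genotype, r) in enumerate(ranked.entries, start=1):
            fh.write(f"{i}\t{genotype}\t{'NA' if r is None else repr(r)}\n")
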