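"""Reconstructing ascendant genealogies from a fully-recorded population.

A sample of living adults ("genealogists") each trace their direct
ancestors back up to nine generations (parents to 7x-great-grandparents,
at most 2 + 4 + ... + 2^9 = 1022 positions).  Because the tracing starts
from survivors, extinct lineages are invisible — the fundamental selection
in ascendant genealogies.  Family trees from different genealogists share
ancestors, so their union carries duplicates; pedigree collapse can even
duplicate an ancestor within a single tree.  Collateral kin enter by adding
every child of every direct ancestor (siblings, aunts/uncles, up to
7x-great-aunts/uncles).  Selective omission removes a random fraction of a
class of members (children dead before five, or women who reached 15 but
stayed childless) from otherwise complete lineages.

Attributions are the unit of accounting: one row per (genealogist, member,
kin type, generation).  The deduplicated member set is a *view* of the
attributions, never a mutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import FEMALE, OPEN, PopulationRegistry
from .measures import PopulationView

logger = logging.getLogger(__name__)

KIN_EGO = "ego"
KIN_ANCESTOR = "direct_ancestor"
KIN_OFFSPRING = "ancestor_offspring"

ATTR_COLUMNS = ["genealogist_pid", "member_pid", "kin_type", "generation"]


@dataclass
class ExperimentConfig:
    """Sampling, tracing and omission settings for subset construction."""

    sample_fraction: float = 0.10
    min_ego_age_years: int = 18
    reference_month: int | None = None  # default: end of the final main year
    max_generations: int = 9
    omission_target: str = "none"  # none | under5_deaths | childless_women
    omission_proportion: float = 0.0
    child_age_threshold_years: int = 5
    childless_min_age_years: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.omission_proportion <= 1.0:
            raise ValueError("omission_proportion must lie in [0, 1]")
        if self.omission_target not in ("none", "under5_deaths", "childless_women"):
            raise ValueError(f"unknown omission target {self.omission_target!r}")
        if self.child_age_threshold_years <= 0 or self.childless_min_age_years <= 0:
            raise ValueError("age thresholds must be positive")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")


def default_reference_month(registry: PopulationRegistry) -> int:
    """End of the final main-period year recorded in the registry metadata."""
    cfg = registry.meta.get("config")
    if cfg is None:
        raise ValueError("registry carries no config metadata; "
                         "pass reference_month explicitly")
    return (cfg["end_year"] + 1) * 12 - 1


@dataclass
class GenealogicalSubset:
    """Merged family trees: an attribution multiset plus provenance.

    ``attributions`` has one row per (genealogist, member, kin type,
    generation) — the same member may appear under many genealogists and,
    through pedigree collapse, several times within one tree.
    ``member_set`` is the deduplicated view.
    """

    attributions: pd.DataFrame
    registry_token: str
    provenance: dict = field(default_factory=dict)

    @property
    def member_set(self) -> np.ndarray:
        return np.unique(self.attributions["member_pid"].to_numpy())

    @property
    def genealogists(self) -> np.ndarray:
        return np.unique(self.attributions["genealogist_pid"].to_numpy())

    def attribution_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(member pids, attribution multiplicities)."""
        return np.unique(self.attributions["member_pid"].to_numpy(),
                         return_counts=True)

    def dedup(self) -> "GenealogicalSubset":
        """One attribution per member (idempotent)."""
        a = self.attributions.sort_values(ATTR_COLUMNS, kind="stable")
        a = a.drop_duplicates(subset="member_pid", keep="first").reset_index(drop=True)
        prov = dict(self.provenance, deduplicated=True)
        return GenealogicalSubset(a, self.registry_token, prov)

    def to_view(self, registry: PopulationRegistry, mode: str = "dedup",
                label: str | None = None) -> PopulationView:
        """Measure view: ``dedup`` weights members once, ``attributions``
        weights them by their number of appearances across trees."""
        if registry.token != self.registry_token:
            raise ValueError("subset does not belong to this registry")
        pids, counts = self.attribution_counts()
        if mode == "dedup":
            weights = np.ones(len(pids))
        elif mode == "attributions":
            weights = counts.astype(float)
        else:
            raise ValueError(f"unknown view mode {mode!r}")
        return PopulationView(registry, member_pids=pids, weights=weights,
                              label=label or mode)

    # -- io -------------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# registry_token={self.registry_token}\n")
            self.attributions[ATTR_COLUMNS].to_csv(fh, index=False,
                                                   lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GenealogicalSubset":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("# registry_token="):
                raise ValueError(f"{path}: not a subset file (bad header)")
            token = header.strip().split("=", 1)[1]
            df = pd.read_csv(fh)
        if list(df.columns) != ATTR_COLUMNS:
            raise ValueError(f"{path}: unexpected subset columns")
        return cls(df, token)


# ---------------------------------------------------------------------------
# genealogist sampling


def sample_genealogists(registry: PopulationRegistry, config: ExperimentConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Simple random sample of adults alive at the reference month.

    The sample size is round-half-even of fraction x eligible count.
    """
    ref = config.reference_month if config.reference_month is not None \
        else default_reference_month(registry)
    if not registry.span[0] <= ref <= registry.span[1]:
        raise ValueError(f"reference month {ref} outside registry span {registry.span}")
    alive = registry.alive_at(ref)
    age_ok = (ref - registry.birth_month) >= config.min_ego_age_years * 12
    eligible = registry.pids[alive & age_ok]
    if len(eligible) == 0:
        raise ValueError("no eligible genealogists at the reference month")
    k = round(config.sample_fraction * len(eligible))
    if k <= 0:
        raise ValueError("empty sample requested")
    return np.sort(rng.choice(eligible, size=k, replace=False))


# ---------------------------------------------------------------------------
# tracing


def trace_direct_ancestors(registry: PopulationRegistry, ego: int,
                           max_generations: int = 9) -> GenealogicalSubset:
    """Trace one genealogist's direct-ancestor positions.

    One attribution per *occupied* pedigree position: positions whose parent
    is unrecorded are simply absent, and pedigree collapse legitimately
    yields repeated pids within the tree.
    """
    return trace_ancestor_trees(registry, np.array([ego]), max_generations)


def trace_ancestor_trees(registry: PopulationRegistry, egos: np.ndarray,
                         max_generations: int = 9) -> GenealogicalSubset:
    """Trace and merge the ascendant trees of many genealogists at once."""
    egos = np.asarray(egos, dtype=np.int64)
    genos = [egos]
    members = [egos]
    gens = [np.zeros(len(egos), dtype=np.int64)]
    kins = [np.full(len(egos), KIN_EGO, dtype=object)]

    geno, pid = egos, egos
    for g in range(1, max_generations + 1):
        mothers = registry.mother_pid[pid - 1]
        fathers = registry.father_pid[pid - 1]
        nxt_geno = np.concatenate([geno, geno])
        nxt_pid = np.concatenate([mothers, fathers])
        keep = nxt_pid > 0
        geno, pid = nxt_geno[keep], nxt_pid[keep]
        if len(pid) == 0:
            break
        genos.append(geno)
        members.append(pid)
        gens.append(np.full(len(pid), g, dtype=np.int64))
        kins.append(np.full(len(pid), KIN_ANCESTOR, dtype=object))

    attributions = pd.DataFrame({
        "genealogist_pid": np.concatenate(genos),
        "member_pid": np.concatenate(members),
        "kin_type": np.concatenate(kins),
        "generation": np.concatenate(gens),
    })
    return GenealogicalSubset(attributions, registry.token,
                              {"max_generations": max_generations,
                               "n_genealogists": len(egos)})


def add_ancestor_offspring(subset: GenealogicalSubset, registry: PopulationRegistry,
                           max_offspring_generation: int | None = None) -> GenealogicalSubset:
    """Add every child of every direct ancestor (collateral kin).

    Offspring of a generation-g ancestor are labelled
    ``ancestor_offspring`` with generation g (siblings for g = 1, aunts and
    uncles for g = 2, ...).  ``max_offspring_generation`` restricts which
    ancestor generations contribute offspring, for incremental variants.
    The input member set is always a subset of the output's.
    """
    if registry.token != subset.registry_token:
        raise ValueError("subset does not belong to this registry")
    a = subset.attributions
    anc = a[a["kin_type"] == KIN_ANCESTOR]
    if max_offspring_generation is not None:
        anc = anc[anc["generation"] <= max_offspring_generation]
    offsets, kids = registry._children_csr()
    pids = anc["member_pid"].to_numpy()
    starts = offsets[pids]
    lens = offsets[pids + 1] - starts
    total = int(lens.sum())
    if total:
        # CSR gather of all children of all ancestor attributions
        take = np.arange(total) - np.repeat(np.cumsum(lens) - lens, lens) \
            + np.repeat(starts, lens)
        rows = pd.DataFrame({
            "genealogist_pid": np.repeat(anc["genealogist_pid"].to_numpy(), lens),
            "member_pid": kids[take],
            "kin_type": KIN_OFFSPRING,
            "generation": np.repeat(anc["generation"].to_numpy(), lens),
        })
        attributions = pd.concat([a, rows], ignore_index=True)
    else:
        attributions = a.copy()
    prov = dict(subset.provenance, offspring=True,
                max_offspring_generation=max_offspring_generation)
    return GenealogicalSubset(attributions, subset.registry_token, prov)


def merge_trees(subsets: Sequence[GenealogicalSubset]) -> GenealogicalSubset:
    """Concatenate attribution multisets from one registry.

    With-duplicates statistics count attributions; without-duplicates
    statistics use the member set.  Merging is associative and
    order-insensitive on the member set.
    """
    if not subsets:
        raise ValueError("nothing to merge")
    token = subsets[0].registry_token
    if any(s.registry_token != token for s in subsets):
        raise ValueError("cannot merge subsets from different registries")
    attributions = pd.concat([s.attributions for s in subsets], ignore_index=True)
    return GenealogicalSubset(attributions, token, {"merged": len(subsets)})


# ---------------------------------------------------------------------------
# selective omission


def eligible_for_omission(registry: PopulationRegistry, target: str,
                          config: ExperimentConfig) -> np.ndarray:
    """Pids in the registry-ground-truth omission class.

    ``under5_deaths``: death age in completed years below the threshold.
    ``childless_women``: women who reached the minimum age (or were still
    alive past it) with zero recorded children ever.
    """
    b, d = registry.birth_month, registry.death_month
    if target == "under5_deaths":
        mask = (d != OPEN) & (d - b < config.child_age_threshold_years * 12)
    elif target == "childless_women":
        end = registry.span[1]
        attained = np.where(d == OPEN, end - b, d - b)
        kids = registry.child_counts()[1:]
        mask = (registry.sex == FEMALE) \
            & (attained >= config.childless_min_age_years * 12) & (kids == 0)
    else:
        raise ValueError(f"unknown omission target {target!r}")
    return registry.pids[mask]


def omit_individuals(subset: GenealogicalSubset, registry: PopulationRegistry,
                     config: ExperimentConfig,
                     rng: np.random.Generator) -> GenealogicalSubset:
    """Randomly remove a fraction of an omission class from the subset.

    Operates on the deduplicated subset.  round(proportion x eligible)
    members are removed uniformly at random; eligibility comes from
    registry ground truth, not from what the subset itself records.  With
    identically seeded generators the removal sets are nested across
    proportions (the random order of eligible members is drawn once).
    """
    if not 0.0 <= config.omission_proportion <= 1.0:
        raise ValueError("omission proportion must lie in [0, 1]")
    if registry.token != subset.registry_token:
        raise ValueError("subset does not belong to this registry")
    base = subset.dedup()
    eligible = np.intersect1d(base.member_set,
                              eligible_for_omission(registry, config.omission_target,
                                                    config))
    k = round(config.omission_proportion * len(eligible))
    removed = eligible[rng.permutation(len(eligible))[:k]]
    keep = ~base.attributions["member_pid"].isin(removed)
    prov = dict(base.provenance, omission_target=config.omission_target,
                omission_proportion=config.omission_proportion,
                n_eligible=int(len(eligible)), n_removed=int(k))
    return GenealogicalSubset(base.attributions[keep].reset_index(drop=True),
                              subset.registry_token, prov)
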