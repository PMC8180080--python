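"""Core data model for compound-abundance profiles.

A study profile is a compounds x samples table of non-negative peak
abundances in which an exact zero means "not detected".  Samples carry a
binary group label (``case`` = cancer, ``control`` = non-cancer) and can be
partitioned into a marker-discovery cohort and an independent test cohort.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

CASE = "case"
CONTROL = "control"

#: accepted spellings of the two group labels in input files
_GROUP_ALIASES = {
    "case": CASE,
    "cancer": CASE,
    "bladder cancer": CASE,
    "bladder_cancer": CASE,
    "control": CONTROL,
    "hernia": CONTROL,
}

#: name fragments of common GC-MS background species (column bleed etc.)
DEFAULT_CONTAMINANT_PATTERNS = (
    r"siloxane",
    r"silanol",
    r"phthalate",
)


def canonical_group(label: str) -> str:
    """Map an input group label to the canonical ``case``/``control``."""
    key = str(label).strip().lower()
    try:
        return _GROUP_ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unknown group label {label!r}; expected one of "
            f"{sorted(set(_GROUP_ALIASES))}"
        ) from None


@dataclass(frozen=True)
class CompoundRecord:
    """Metadata for one measured compound.

    Parameters
    ----------
    compound_id : str
        Opaque stable identifier, unique within a profile.
    name : str
        Chemical / derivative name as reported by the peak-picking software.
    mass : int
        Nominal m/z (positive).
    metabolite : str
        Metabolite annotation; ``"unknown"`` when no identification exists.
    is_contaminant : bool
        True for instrument-background species (e.g. siloxane derivatives),
        which are excluded from candidate markers.
    """

    compound_id: str
    name: str
    mass: int
    metabolite: str = "unknown"
    is_contaminant: bool = False

    def __post_init__(self) -> None:
        if int(self.mass) <= 0:
            raise ValueError(
                f"compound {self.compound_id!r}: mass must be positive, got {self.mass}"
            )


class ProfileMatrix:
    """Compounds x samples abundance matrix with group labels.

    Invariants enforced at construction: all abundances are finite and
    >= 0 (zero encodes "not detected"), compound and sample identifiers are
    unique, and both groups are represented.
    """

    def __init__(
        self,
        compounds: Sequence[CompoundRecord],
        sample_ids: Sequence[str],
        groups: Sequence[str],
        abundance: np.ndarray,
    ):
        self.compounds = list(compounds)
        self.sample_ids = [str(s) for s in sample_ids]
        self.groups = np.asarray([canonical_group(g) for g in groups], dtype=object)
        self.abundance = np.asarray(abundance, dtype=float)
        self._validate()
        self._index = {c.compound_id: i for i, c in enumerate(self.compounds)}

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        m, n = len(self.compounds), len(self.sample_ids)
        if self.abundance.shape != (m, n):
            raise ValueError(
                f"abundance shape {self.abundance.shape} does not match "
                f"{m} compounds x {n} samples"
            )
        if len(self.groups) != n:
            raise ValueError("one group label required per sample")
        ids = [c.compound_id for c in self.compounds]
        dup = _first_duplicate(ids)
        if dup is not None:
            raise ValueError(f"duplicated compound_id {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"duplicated sample id {dup!r}")
        if not np.all(np.isfinite(self.abundance)):
            i, j = np.argwhere(~np.isfinite(self.abundance))[0]
            raise ValueError(
                f"non-finite abundance for compound {ids[i]!r}, "
                f"sample {self.sample_ids[j]!r} (impute missing cells as 0 first)"
            )
        if np.any(self.abundance < 0):
            i, j = np.argwhere(self.abundance < 0)[0]
            raise ValueError(
                f"negative abundance for compound {ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        for grp in (CASE, CONTROL):
            if not np.any(self.groups == grp):
                raise ValueError(f"profile has no {grp!r} samples")

    # -- accessors -------------------------------------------------------
    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def compound_ids(self) -> list[str]:
        return [c.compound_id for c in self.compounds]

    @property
    def case_mask(self) -> np.ndarray:
        return self.groups == CASE

    @property
    def case_ids(self) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.groups) if g == CASE]

    @property
    def control_ids(self) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.groups) if g == CONTROL]

    def compound_index(self, compound_id: str) -> int:
        try:
            return self._index[compound_id]
        except KeyError:
            raise KeyError(f"unknown compound_id {compound_id!r}") from None

    def compound(self, compound_id: str) -> CompoundRecord:
        return self.compounds[self.compound_index(compound_id)]

    def values(self, compound_id: str) -> np.ndarray:
        """Abundance row for one compound, aligned to ``sample_ids``."""
        return self.abundance[self.compound_index(compound_id)]

    def group_values(self, compound_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(case values, control values) for one compound."""
        row = self.values(compound_id)
        mask = self.case_mask
        return row[mask], row[~mask]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ProfileMatrix":
        """New profile restricted to ``sample_ids`` (kept in matrix order)."""
        wanted = set(sample_ids)
        missing = wanted - set(self.sample_ids)
        if missing:
            raise KeyError(f"unknown sample id(s): {sorted(missing)}")
        keep = [i for i, s in enumerate(self.sample_ids) if s in wanted]
        return ProfileMatrix(
            self.compounds,
            [self.sample_ids[i] for i in keep],
            self.groups[keep],
            self.abundance[:, keep],
        )

    def equals(self, other: "ProfileMatrix") -> bool:
        return (
            self.compounds == other.compounds
            and self.sample_ids == other.sample_ids
            and list(self.groups) == list(other.groups)
            and np.array_equal(self.abundance, other.abundance)
        )


def _first_duplicate(items: Sequence) -> object | None:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def flag_contaminants(
    pm: ProfileMatrix, patterns: Sequence[str] = DEFAULT_CONTAMINANT_PATTERNS
) -> ProfileMatrix:
    """Return a copy with ``is_contaminant`` set where a compound name
    matches any of the (case-insensitive) regex ``patterns``.

    Flags already set in the input metadata are preserved; the denylist only
    adds flags.  This mirrors the manual curation of instrument-background
    species, which is otherwise supplied as explicit input metadata.
    """
    regexes = [re.compile(p, re.IGNORECASE) for p in patterns]
    compounds = [
        replace(c, is_contaminant=True)
        if not c.is_contaminant and any(r.search(c.name) for r in regexes)
        else c
        for c in pm.compounds
    ]
    return ProfileMatrix(compounds, pm.sample_ids, pm.groups, pm.abundance)


@dataclass(frozen=True)
class CohortSplit:
    """A partition of samples into discovery and independent-test cohorts."""

    discovery_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.discovery_ids) & set(self.test_ids):
            raise ValueError("discovery and test cohorts overlap")


def _largest_remainder(counts: Sequence[int], total: int) -> list[int]:
    """Apportion ``total`` over groups proportionally to ``counts``.

    Integer parts first, then remaining units to the largest fractional
    remainders (ties to the larger group, then lower index).
    """
    n = sum(counts)
    quotas = [c * total / n for c in counts]
    base = [int(np.floor(q)) for q in quotas]
    remaining = total - sum(base)
    order = sorted(
        range(len(counts)),
        key=lambda i: (-(quotas[i] - base[i]), -counts[i], i),
    )
    for i in order[:remaining]:
        base[i] += 1
    return base


def split_cohorts(pm: ProfileMatrix, discovery_size: int, seed: int) -> CohortSplit:
    """Split samples into discovery and test cohorts, proportionally by group.

    The per-group discovery counts are the largest-remainder rounding of
    ``group_n * discovery_size / total_n``; within each group membership is a
    seeded simple random sample.  The remainder forms the test cohort.  With
    63 cases and 61 controls and ``discovery_size=100`` this yields the
    51/49 discovery and 12/12 test allocation used in the study design this
    pipeline follows.
    """
    if not 2 <= discovery_size < pm.n_samples:
        raise ValueError(
            f"discovery_size must be in [2, {pm.n_samples - 1}], got {discovery_size}"
        )
    group_samples = {
        CASE: pm.case_ids,
        CONTROL: pm.control_ids,
    }
    labels = [CASE, CONTROL]
    counts = [len(group_samples[g]) for g in labels]
    alloc = _largest_remainder(counts, discovery_size)
    for g, n_g, k_g in zip(labels, counts, alloc):
        if k_g == 0 or k_g == n_g:
            raise ValueError(
                f"allocation leaves group {g!r} empty in one cohort "
                f"({k_g} of {n_g} to discovery)"
            )
    rng = np.random.default_rng(seed)
    discovery: list[str] = []
    for g, k_g in zip(labels, alloc):
        members = group_samples[g]
        chosen = rng.choice(len(members), size=k_g, replace=False)
        discovery.extend(members[i] for i in sorted(chosen))
    discovery_set = set(discovery)
    test = [s for s in pm.sample_ids if s not in discovery_set]
    discovery = [s for s in pm.sample_ids if s in discovery_set]
    return CohortSplit(tuple(discovery), tuple(test), seed)
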