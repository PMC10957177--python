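"""Region ontology and per-animal count tables.

The analysis operates on a three-level brain-region hierarchy (major
divisions -> coarse summary structures -> fine areas, Allen-atlas style
acronyms) and on tidy per-(subject, region) tables of c-Fos-positive
cell counts, sampled areas (mm^2) and densities (cells/mm^2).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "LEVELS",
    "DIVISIONS",
    "RegionOntology",
    "Contrast",
    "CANONICAL_CONTRASTS",
    "load_ontology",
    "write_ontology",
    "default_ontology",
    "load_counts",
    "validate_counts",
    "write_counts",
    "aggregate_to_level",
    "check_contrast",
]

#: Hierarchy levels, root first.
LEVELS = ("division", "coarse53", "fine201")

#: The six canonical major divisions.
DIVISIONS = ("CTX", "CNU", "TH", "HY", "MB", "HB")

COUNT_COLUMNS = ["subject_id", "group", "region_acronym", "cell_count", "area", "density"]

_DENSITY_RTOL = 1e-9


@dataclass(frozen=True)
class RegionOntology:
    """Validated three-level region hierarchy.

    Wraps a table with columns ``acronym, name, level, parent_acronym``.
    Acronyms are unique across all levels; every non-division region has
    exactly one parent at the level immediately above.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        required = {"acronym", "name", "level", "parent_acronym"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"ontology table lacks columns: {sorted(missing)}")
        bad_levels = set(df["level"]) - set(LEVELS)
        if bad_levels:
            raise ValueError(f"unknown ontology levels: {sorted(bad_levels)}")
        dup = df["acronym"][df["acronym"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate region acronym(s): {sorted(set(dup))}")
        level_of = dict(zip(df["acronym"], df["level"]))
        parent_level = {"coarse53": "division", "fine201": "coarse53"}
        for _, row in df.iterrows():
            parent = row["parent_acronym"]
            if row["level"] == "division":
                if parent not in (None, "") and not pd.isna(parent):
                    raise ValueError(f"division {row['acronym']!r} must not have a parent")
                continue
            if parent in (None, "") or pd.isna(parent):
                raise ValueError(f"orphan region {row['acronym']!r} ({row['level']}) has no parent")
            if parent not in level_of:
                raise ValueError(f"region {row['acronym']!r} has unknown parent {parent!r}")
            if level_of[parent] != parent_level[row["level"]]:
                raise ValueError(
                    f"region {row['acronym']!r} ({row['level']}) has parent "
                    f"{parent!r} at level {level_of[parent]!r}"
                )
        object.__setattr__(self, "_level_of", level_of)
        object.__setattr__(self, "_parent_of", dict(zip(df["acronym"], df["parent_acronym"])))

    @property
    def acronyms(self) -> list[str]:
        return list(self.table["acronym"])

    def regions_at(self, level: str) -> list[str]:
        if level not in LEVELS:
            raise ValueError(f"unknown level {level!r}")
        return list(self.table.loc[self.table["level"] == level, "acronym"])

    def level_of(self, acronym: str) -> str:
        try:
            return self._level_of[acronym]
        except KeyError:
            raise KeyError(f"unknown region acronym {acronym!r}") from None

    def parent_of(self, acronym: str) -> str | None:
        self.level_of(acronym)
        parent = self._parent_of[acronym]
        if parent in (None, "") or pd.isna(parent):
            return None
        return parent

    def ancestor_at(self, acronym: str, level: str) -> str:
        """Walk parent links from *acronym* up to *level*."""
        current: str | None = acronym
        while current is not None:
            if self.level_of(current) == level:
                return current
            current = self.parent_of(current)
        raise ValueError(f"region {acronym!r} has no ancestor at level {level!r}")

    def children_of(self, acronym: str) -> list[str]:
        self.level_of(acronym)
        mask = self.table["parent_acronym"] == acronym
        return list(self.table.loc[mask, "acronym"])

    def division_of(self, acronym: str) -> str:
        return self.ancestor_at(acronym, "division")


@dataclass(frozen=True)
class Contrast:
    """A (treatment, control) group pair."""

    treatment: str
    control: str

    def __post_init__(self) -> None:
        if self.treatment == self.control:
            raise ValueError("treatment and control groups must differ")


#: The study's canonical contrasts: ketamine vs saline injection,
#: isoflurane vs undisturbed home cage.
CANONICAL_CONTRASTS = (Contrast("KET", "saline"), Contrast("ISO", "homecage"))


def check_contrast(counts: pd.DataFrame, contrast: Contrast, min_subjects: int = 2) -> None:
    """Ensure both contrast groups are present with enough subjects."""
    for grp in (contrast.treatment, contrast.control):
        n = counts.loc[counts["group"] == grp, "subject_id"].nunique()
        if n < min_subjects:
            raise ValueError(f"group {grp!r} has {n} subject(s); need >= {min_subjects}")


def load_ontology(path) -> RegionOntology:
    """Read an ontology CSV (columns acronym, name, level, parent_acronym)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df["parent_acronym"] = df["parent_acronym"].replace("", None)
    return RegionOntology(df.reset_index(drop=True))


def write_ontology(ontology: RegionOntology, path) -> None:
    out = ontology.table.copy()
    out["parent_acronym"] = out["parent_acronym"].fillna("")
    out.to_csv(path, index=False)


def default_ontology() -> RegionOntology:
    """Bundled starter ontology.

    Covers the six major divisions and the commonly reported coarse
    structures and fine areas (Allen Mouse Brain Atlas acronyms).  It is
    a convenience subset, not the full 53/201-region atlas partition;
    analyses accept any valid ontology.
    """
    ref = importlib.resources.files("fosmap") / "data" / "default_ontology.csv"
    with importlib.resources.as_file(ref) as path:
        return load_ontology(path)


def validate_counts(
    df: pd.DataFrame,
    ontology: RegionOntology | None = None,
    recompute_density: bool = True,
) -> pd.DataFrame:
    """Validate (and normalize) a tidy counts table.

    Checks column presence, non-negative integer counts, positive areas,
    one row per (subject, region), one group per subject and (optionally)
    that every acronym exists in *ontology*.  Density is recomputed as
    cell_count / area unless ``recompute_density=False``, in which case a
    supplied density column must satisfy the identity to 1e-9 relative.
    """
    required = ["subject_id", "group", "region_acronym", "cell_count", "area"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"counts table lacks columns: {missing}")
    out = df.copy().reset_index(drop=True)

    counts = pd.to_numeric(out["cell_count"], errors="coerce")
    bad = out.index[counts.isna() | (counts < 0) | (counts % 1 != 0)]
    if len(bad):
        raise ValueError(f"invalid cell_count at row(s) {list(bad[:5])}: must be non-negative integers")
    out["cell_count"] = counts.astype(int)

    area = pd.to_numeric(out["area"], errors="coerce")
    bad = out.index[area.isna() | (area <= 0)]
    if len(bad):
        raise ValueError(f"non-positive area at row(s) {list(bad[:5])}")
    out["area"] = area.astype(float)

    if "density" in out.columns and not recompute_density:
        dens = pd.to_numeric(out["density"], errors="coerce")
        expected = out["cell_count"] / out["area"]
        ok = np.isclose(dens, expected, rtol=_DENSITY_RTOL, atol=0.0)
        if not ok.all():
            raise ValueError(f"density != cell_count/area at row(s) {list(out.index[~ok][:5])}")
        out["density"] = dens
    else:
        out["density"] = out["cell_count"] / out["area"]

    dup = out.duplicated(subset=["subject_id", "region_acronym"])
    if dup.any():
        pairs = out.loc[dup, ["subject_id", "region_acronym"]].values[:5].tolist()
        raise ValueError(f"duplicate (subject, region) row(s): {pairs}")
    groups_per_subject = out.groupby("subject_id")["group"].nunique()
    multi = groups_per_subject[groups_per_subject > 1]
    if len(multi):
        raise ValueError(f"subject(s) in more than one group: {sorted(multi.index)}")

    if ontology is not None:
        known = set(ontology.acronyms)
        unknown = sorted(set(out["region_acronym"]) - known)
        if unknown:
            raise ValueError(f"region acronym(s) absent from ontology: {unknown[:10]}")
    return out[COUNT_COLUMNS]


def load_counts(path, ontology: RegionOntology | None = None) -> pd.DataFrame:
    """Read a tidy counts CSV; density is recomputed from count and area."""
    return validate_counts(pd.read_csv(path), ontology=ontology)


def write_counts(df: pd.DataFrame, path) -> None:
    df[COUNT_COLUMNS].to_csv(path, index=False)


def aggregate_to_level(
    counts: pd.DataFrame,
    ontology: RegionOntology,
    level: str,
    missing: str = "error",
) -> pd.DataFrame:
    """Aggregate a counts table to a coarser ontology level.

    Counts and areas are pooled over children (area-weighted density:
    summed count / summed area), never averaged, so density stays
    physically meaningful.

    Parameters
    ----------
    missing : {"error", "ignore"}
        Policy when a subject lacks rows for some children of a target
        region: ``"error"`` raises listing the gaps; ``"ignore"``
        aggregates the children that are present.
    """
    if level not in ("coarse53", "division"):
        raise ValueError("aggregation target must be 'coarse53' or 'division'")
    if missing not in ("error", "ignore"):
        raise ValueError("missing policy must be 'error' or 'ignore'")
    out = counts.copy()
    out["_target"] = [ontology.ancestor_at(a, level) for a in out["region_acronym"]]

    if missing == "error":
        # every subject must cover the same child set per target region
        child_sets = out.groupby("_target")["region_acronym"].agg(lambda s: frozenset(s))
        gaps = []
        for (subject, target), grp in out.groupby(["subject_id", "_target"]):
            absent = child_sets[target] - set(grp["region_acronym"])
            if absent:
                gaps.append((subject, target, sorted(absent)))
        if gaps:
            raise ValueError(f"missing child region rows (subject, target, children): {gaps[:5]}")

    agg = (
        out.groupby(["subject_id", "group", "_target"], as_index=False)
        .agg(cell_count=("cell_count", "sum"), area=("area", "sum"))
        .rename(columns={"_target": "region_acronym"})
    )
    agg["density"] = agg["cell_count"] / agg["area"]
    return agg[COUNT_COLUMNS].sort_values(["subject_id", "region_acronym"]).reset_index(drop=True)


def density_table(counts: pd.DataFrame, regions: Iterable[str] | None = None) -> pd.DataFrame:
    """Pivot a counts table to a subjects x regions density matrix."""
    wide = counts.pivot(index="subject_id", columns="region_acronym", values="density")
    if regions is not None:
        wide = wide.reindex(columns=list(regions))
    return wide
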