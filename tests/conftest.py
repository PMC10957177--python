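import numpy as np
import pandas as pd
import pytest

from fosmap.regions import RegionOntology, validate_counts


@pytest.fixture
def toy_ontology() -> RegionOntology:
    """Two divisions, three coarse regions, five fine regions."""
    rows = [
        ("CTX", "Cerebral cortex", "division", None),
        ("HY", "Hypothalamus", "division", None),
        ("MO", "Somatomotor areas", "coarse53", "CTX"),
        ("SS", "Somatosensory areas", "coarse53", "CTX"),
        ("LZ", "Lateral zone", "coarse53", "HY"),
        ("MOp", "Primary motor area", "fine201", "MO"),
        ("MOs", "Secondary motor area", "fine201", "MO"),
        ("SSp", "Primary somatosensory area", "fine201", "SS"),
        ("LHA", "Lateral hypothalamic area", "fine201", "LZ"),
        ("TU", "Tuberal nucleus", "fine201", "LZ"),
    ]
    return RegionOntology(pd.DataFrame(rows, columns=["acronym", "name", "level", "parent_acronym"]))


def make_counts(groups: dict[str, dict[str, list[float]]], area: float = 1.0) -> pd.DataFrame:
    """Build a counts table from {group: {region: [per-subject densities]}}.

    Densities are interpreted with area 1 mm^2 (so count == density)
    unless *area* is given, in which case counts scale accordingly.
    """
    rows = []
    for group, regions in groups.items():
        n = len(next(iter(regions.values())))
        for i in range(n):
            for region, dens in regions.items():
                rows.append((f"{group}{i + 1}", group, region, int(round(dens[i] * area)), area))
    df = pd.DataFrame(rows, columns=["subject_id", "group", "region_acronym", "cell_count", "area"])
    return validate_counts(df)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
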