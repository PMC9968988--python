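import hypothesis
import numpy as np
import pandas as pd
import pytest

from mmpscreen.screen_io import PlateReadout, TargetAnnotationTable

hypothesis.settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[hypothesis.HealthCheck.function_scoped_fixture],
)
hypothesis.settings.load_profile("default")


def make_annotations(records):
    """Build a normalized annotation table from (compound, target, pic50, primary) tuples."""
    table, _ = TargetAnnotationTable.from_records(
        {
            "compound_id": c,
            "target_id": t,
            "pic50": p,
            "is_primary": prim,
        }
        for c, t, p, prim in records
    )
    return table


def make_plate(wells):
    """Build a plate from (well_id, role, compound, replicate, fluor, viability) tuples."""
    df = pd.DataFrame(
        wells,
        columns=["well_id", "role", "compound_id", "replicate", "fluorescence", "viability"],
    )
    return PlateReadout(df)


def random_annotation_records(rng, n_compounds=20, n_targets=10, missing_rate=0.1):
    """Random raw annotation records for oracle/property tests."""
    records = []
    for i in range(n_compounds):
        cid = f"C{i:03d}"
        k = rng.integers(1, max(2, n_targets // 2))
        targets = rng.choice(n_targets, size=int(k), replace=False)
        primary_j = int(rng.integers(0, len(targets)))
        for j, t in enumerate(targets):
            missing = rng.random() < missing_rate
            records.append(
                (
                    cid,
                    f"T{int(t):03d}",
                    None if missing else float(np.round(rng.uniform(3, 11), 3)),
                    j == primary_j,
                )
            )
    return records


@pytest.fixture
def toy_annotations():
    return make_annotations(
        [
            ("A", "GSK3B", 7.9, True),
            ("A", "CDK2", 6.5, False),
            ("B", "GSK3B", 9.1, True),
            ("B", "CDK2", 5.0, False),
            ("C", "MAPK14", 8.0, True),
            ("C", "CDK2", None, False),
        ]
    )


@pytest.fixture
def toy_plate():
    return make_plate(
        [
            ("w1", "MFS_DMSO", None, 1, 1000.0, np.nan),
            ("w2", "MFS_DMSO", None, 2, 1000.0, np.nan),
            ("w3", "CORR", None, 1, 400.0, np.nan),
            ("w4", "REFERENCE_DRUG", None, 1, 450.0, np.nan),
            ("w5", "TREATED", "X", 1, 400.0, 0.9),
            ("w6", "TREATED", "X", 2, 440.0, 0.95),
            ("w7", "TREATED", "Y", 1, 1000.0, 0.9),
            ("w8", "TREATED", "Z", 1, 500.0, 0.2),
        ]
    )
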