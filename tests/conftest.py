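import numpy as np
import pandas as pd
import pytest

import ethokit as ek
from ethokit.time_utils import days, hours, mins


@pytest.fixture
def small_table() -> ek.LinkedBehaviourTable:
    """Three animals, 100 reads each at 60 s, with genotype/sex metavariables."""
    rng = np.random.default_rng(42)
    rows = []
    for i, animal in enumerate("ABC"):
        t = 60.0 * np.arange(100)
        rows.append(
            pd.DataFrame(
                {"id": animal, "t": t, "activity": rng.poisson(1 + i, size=100)}
            )
        )
    data = pd.concat(rows, ignore_index=True)
    meta = pd.DataFrame(
        {
            "id": list("ABC"),
            "genotype": ["wt", "wt", "mut"],
            "sex": ["F", "M", "F"],
            "baseline_days": [3, 4, 3],
        }
    )
    return ek.link(meta, data)


def make_activity_table(
    n_per_group: int = 5,
    amplitude: float = 1.0,
    period: float = hours(25),
    duration: float = days(6),
    seed: int = 0,
    genotypes: tuple[str, str] = ("ctrl", "ctrl"),
) -> ek.LinkedBehaviourTable:
    """Simulated monitor-style activity table with a two-level genotype column."""
    chunks, meta_rows = [], []
    for i in range(2 * n_per_group):
        spec = ek.ActivitySimSpec(
            amplitude=amplitude, period=period, duration=duration, seed=seed + i
        )
        df = ek.simulate_activity(spec)
        animal = f"fly|{i:02d}"
        df.insert(0, "id", animal)
        chunks.append(df)
        meta_rows.append({"id": animal, "genotype": genotypes[i % 2]})
    table = ek.link(pd.DataFrame(meta_rows), pd.concat(chunks, ignore_index=True))
    return ek.derive_moving(table)
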