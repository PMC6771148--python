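import numpy as np
import pandas as pd
import pytest

from rosetta import (
    DataPool,
    Dataset,
    ExtractionConfig,
    MeasurementCatalog,
    SigmaSpec,
    StudyConfig,
    apply_test_condition,
    harmonize,
    simulate_control,
)
from rosetta.benchmark import score_correlation_table


def make_pool(frames: dict[str, pd.DataFrame], catalog: MeasurementCatalog) -> DataPool:
    return DataPool(
        catalog=catalog,
        datasets=[Dataset(dataset_id=k, values=v) for k, v in frames.items()],
    )


@pytest.fixture(scope="session")
def catalog9():
    from rosetta import default_catalog

    return default_catalog()


@pytest.fixture(scope="session")
def small_pool():
    """Three tiny overlapping datasets over measures m1..m3 (no domains)."""
    catalog = MeasurementCatalog(("m1", "m2", "m3"))
    rng = np.random.default_rng(99)
    base = rng.standard_normal((60, 3))
    base[:, 1] = 0.8 * base[:, 0] + 0.6 * rng.standard_normal(60)
    base[:, 2] = 0.5 * base[:, 0] + 0.86 * rng.standard_normal(60)
    frame = pd.DataFrame(base, columns=["m1", "m2", "m3"],
                         index=[f"s{i}" for i in range(60)])
    frames = {
        "a": frame.iloc[:20][["m1", "m2"]],
        "b": frame.iloc[20:40][["m2", "m3"]],
        "c": frame.iloc[40:][["m1", "m3"]],
    }
    return make_pool(frames, catalog)


@pytest.fixture(scope="session")
def study1_run():
    """One seeded Study-1-style replicate: control pool, test pool, both harmonized."""
    spec = SigmaSpec(rho_within=0.75, rho_between=0.5)
    cfg = StudyConfig(n_total=3000, seed=42)
    control = simulate_control(spec, cfg)
    test = apply_test_condition(control, "aligned")
    ecfg = ExtractionConfig(k=3)
    full = harmonize(control, ecfg)
    harmonized = harmonize(test, ecfg)
    return {
        "spec": spec,
        "control": control,
        "test": test,
        "full_scores": full,
        "test_scores": harmonized,
        "table": score_correlation_table(harmonized, full),
    }
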