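import numpy as np
import pandas as pd
import pytest

from translatomix import ExpressionMatrix, SampleDesign, SimulationSpec, simulate_study

NULL_PROPORTIONS = {
    "not_regulated": 1.0,
    "transcription_only": 0.0,
    "translation_only": 0.0,
    "both_same_direction": 0.0,
    "opposite": 0.0,
}


def geter_sample_ids() -> list[str]:
    """12 samples of an eIF4E-silencing polysome-profiling study:
    biological duplicates x (total, heavy, light) x (NS control, E4
    experiment)."""
    ids = []
    for tag in ("T", "H", "L"):
        for grp in ("NS", "4E"):
            for rep in (1, 2):
                ids.append(f"R{rep}_{grp}_TamR_{tag}")
    return ids


@pytest.fixture
def geter_design() -> SampleDesign:
    assignment = {}
    for s in geter_sample_ids():
        cond = "control" if "_NS_" in s else "experiment"
        frac = {"T": 0, "H": 1, "L": 2}[s.rsplit("_", 1)[1]]
        assignment[s] = (cond, frac)
    return SampleDesign(
        platform="rnaseq",
        engine="moderated_lm",
        control_label="NS",
        experiment_label="E4",
        n_fractions=2,
        assignment=assignment,
    )


@pytest.fixture
def geter_counts(geter_design) -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    samples = geter_sample_ids()
    counts = rng.poisson(500, size=(50, len(samples))).astype(float)
    return ExpressionMatrix(
        values=pd.DataFrame(
            counts, index=[f"g{i}" for i in range(50)], columns=samples
        ),
        platform="rnaseq",
    )


@pytest.fixture(scope="session")
def null_study():
    """All-null counts study at the standard benchmark size."""
    spec = SimulationSpec(
        n_genes=2000, n_fractions=2, n_replicates=3, dispersion=0.1,
        proportions=dict(NULL_PROPORTIONS), seed=1,
    )
    return simulate_study(spec)


@pytest.fixture(scope="session")
def planted_study():
    """Default-proportion study with planted 4-fold effects, n=4."""
    spec = SimulationSpec(n_genes=2000, n_fractions=2, n_replicates=4, seed=1)
    return simulate_study(spec)


def binomial_interval(p0: float, n: int) -> tuple[float, float]:
    """Central 95% normal-approximation interval for a binomial fraction."""
    half = 1.96 * np.sqrt(p0 * (1 - p0) / n)
    return p0 - half, p0 + half
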