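import numpy as np
import pytest

from dtukit.config import RunConfig
from dtukit.model import AnnotationMap, ExperimentData, ReplicateQuant
from dtukit.simulate import SimulationConfig, simulate_experiment


def make_replicate(sample_id, tx_ids, counts, bootstrap=None, unit="counts"):
    return ReplicateQuant(
        sample_id=sample_id,
        transcript_ids=np.asarray(tx_ids, dtype=object),
        abundance=np.asarray(counts, dtype=float),
        bootstrap=bootstrap,
        unit=unit,
    )


def make_experiment(tx_ids, annotation_pairs, counts_a, counts_b, bootstraps_a=None, bootstraps_b=None):
    """Build an ExperimentData from per-replicate count lists."""
    reps_a = [
        make_replicate(f"A{i + 1}", tx_ids, c, None if bootstraps_a is None else bootstraps_a[i])
        for i, c in enumerate(counts_a)
    ]
    reps_b = [
        make_replicate(f"B{i + 1}", tx_ids, c, None if bootstraps_b is None else bootstraps_b[i])
        for i, c in enumerate(counts_b)
    ]
    return ExperimentData(
        condition_a=reps_a,
        condition_b=reps_b,
        annotation=AnnotationMap(annotation_pairs),
        library_sizes={},
    )


@pytest.fixture
def two_gene_experiment():
    """g1 has 2 isoforms with a clean proportion swap; g2 is a stable
    single-isoform gene."""
    tx = ["t1", "t2", "t3"]
    ann = [("t1", "g1"), ("t2", "g1"), ("t3", "g2")]
    counts_a = [[80, 20, 50], [82, 18, 55], [78, 22, 45]]
    counts_b = [[20, 80, 50], [18, 82, 52], [22, 78, 48]]
    return make_experiment(tx, ann, counts_a, counts_b)


@pytest.fixture(scope="session")
def sim_null():
    """A small null dataset with bootstraps (no injected DTU)."""
    return simulate_experiment(
        SimulationConfig(n_genes=250, n_bootstrap=30, seed=11)
    )


@pytest.fixture(scope="session")
def sim_dtu():
    """A small injected-DTU dataset with bootstraps."""
    return simulate_experiment(
        SimulationConfig(
            n_genes=400,
            mean_log=np.log(1000),
            sd_log=0.5,
            n_dtu_genes=30,
            min_injected_dprop=0.4,
            n_bootstrap=30,
            dispersion=0.01,
            seed=5,
        )
    )


@pytest.fixture
def benchmark_config():
    """The thresholds the validation experiments run at (no abundance
    pre-filter)."""
    return RunConfig(abundance_threshold=0.0, seed=0)
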