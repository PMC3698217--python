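import numpy as np
import pandas as pd
import pytest

from stimdur.cascade import (
    CHX_SERIES_TIMES,
    NoiseModel,
    StimulusProtocol,
    StudyConfig,
    build_default_cascade,
    generate_study,
    simulate_kinetics,
)


@pytest.fixture(scope="session")
def small_spec():
    """Tiny labelled cascade reused across simulator tests."""
    return build_default_cascade(8, 4, 8, seed=11)


@pytest.fixture(scope="session")
def small_config():
    """Reduced study for fast pipeline tests (same noise as defaults)."""
    return StudyConfig(n_primary=20, n_secondary=8, n_unresponsive=92)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(7, small_config)


@pytest.fixture(scope="session")
def sustained_trajectories(small_spec):
    protocol = StimulusProtocol(14.0, (1.0, 2.0, 4.0, 8.0, 14.0))
    return simulate_kinetics(small_spec, protocol)


def make_ratio_dataset(
    n_genes: int,
    times: tuple[float, ...],
    n_reps: int,
    rng: np.random.Generator,
    sigma_per_gene=None,
    signal: pd.DataFrame | None = None,
    basal: float = 8.0,
    shared_refs: bool = True,
):
    """Build a matrix + sheet with transient/sustained/untreated arms.

    Treated values are basal + optional per-(gene, arm, time) signal +
    iid Gaussian noise; the untreated references get independent noise of
    the same scale, so the log ratios are exactly Gaussian.  With
    ``shared_refs=False`` the two treated arms live in disjoint replicate
    blocks, each with its own reference arrays, so the arm-contrast errors
    are independent (the assumption of the per-gene linear model; a shared
    reference makes the contrast conservative instead).
    """
    genes = [f"g{i:04d}" for i in range(n_genes)]
    sigma = np.broadcast_to(
        np.asarray(sigma_per_gene if sigma_per_gene is not None else 0.1),
        (n_genes,),
    )
    arm_reps = {
        "transient": range(1, n_reps + 1),
        "sustained": (range(1, n_reps + 1) if shared_refs
                      else range(n_reps + 1, 2 * n_reps + 1)),
    }
    arm_reps["untreated"] = (range(1, n_reps + 1) if shared_refs
                             else range(1, 2 * n_reps + 1))
    cols, rows = {}, []
    for cond in ("untreated", "transient", "sustained"):
        for t in times:
            for rep in arm_reps[cond]:
                sid = f"{cond}:t{t:g}:r{rep}"
                y = basal + rng.normal(0.0, sigma, size=n_genes)
                if signal is not None and cond != "untreated":
                    y = y + signal.get((cond, t), pd.Series(0.0, index=genes)).to_numpy()
                cols[sid] = y
                rows.append(dict(sample_id=sid, experiment_id="sim",
                                 condition=cond, time_h=float(t), replicate=rep))
    matrix = pd.DataFrame(cols, index=pd.Index(genes, name="probe_id"))
    sheet = pd.DataFrame(rows)
    return matrix, sheet
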