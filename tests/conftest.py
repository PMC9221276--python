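import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cypsom import OccupancyModelParams, RateDesign, generate_rate_dataset


@pytest.fixture(scope="session")
def mdz_params():
    """Homotropic MDZ parameters: stepwise Kds 5.1/14.7 uM, f4oh 0 -> 0.35."""
    return OccupancyModelParams()


@pytest.fixture(scope="session")
def noiseless_dataset(mdz_params):
    """12-point homotropic saturation curve, 0.5-100 uM, no noise."""
    design = RateDesign(
        s_grid=tuple(np.geomspace(0.5, 100.0, 12)), x_levels=(0.0,), seed=11,
    )
    return generate_rate_dataset(mdz_params, design)


@pytest.fixture(scope="session")
def noisy_kd_recovery_errors():
    """Relative errors of kd_prod_s over 20 seeded noisy refits.

    5% proportional noise, 12 substrate points x 3 effector levels.
    """
    from cypsom import fit_rate_data

    true = OccupancyModelParams(kd_allo_x=14.7, f4oh_sx=0.35)
    errors = []
    for rep in range(20):
        design = RateDesign(
            s_grid=tuple(np.geomspace(0.5, 100.0, 12)),
            x_levels=(0.0, 5.0, 15.0),
            noise_model="proportional", noise_scale=0.05, seed=1000 + rep,
        )
        data = generate_rate_dataset(true, design)
        init = true.with_updates(kd_prod_s=3.0, kd_allo_s=20.0)
        fit = fit_rate_data(data, init, free=("kd_prod_s", "kd_allo_s"),
                            seed=rep, n_starts=4)
        errors.append(abs(fit.params.kd_prod_s - 5.1) / 5.1)
    return errors


@pytest.fixture(scope="session")
def toy_trajectory(tmp_path_factory):
    """A 1000-frame toy trajectory plus its ground-truth labels."""
    from cypsom import TrajectorySpec, generate_toy_trajectory
    from cypsom.synthetic import _BASE_CONTACTS

    d = tmp_path_factory.mktemp("toy")
    spec = TrajectorySpec(
        n_frames=1000, productive_probability=0.52,
        selective_probability=0.8, contact_probabilities=_BASE_CONTACTS,
        condition="baseline", seed=42,
    )
    top, trj = d / "toy.pdb", d / "toy.dcd"
    labels = generate_toy_trajectory(spec, top, trj)
    return {"spec": spec, "topology": top, "trajectory": trj, "labels": labels}
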