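import numpy as np
import pytest

from menisq import (
    BiParams,
    EchoSchedule,
    MonoParams,
    PhantomSpec,
    RegionSpec,
    f_test,
    fit_bi,
    fit_mono,
)

# the 12-echo multi-echo schedule used for the orientation experiment
TE12 = (0.82, 1.82, 2.82, 7.23, 9.23, 11.23, 13.39, 15.39, 17.39, 19.55, 21.55, 23.55)
# the 9 single-echo times of the histology-correlation experiment
TE9 = (0.4, 0.7, 1.2, 1.7, 2.5, 4.0, 6.0, 8.0, 12.0)


@pytest.fixture(scope="session")
def schedule12() -> EchoSchedule:
    return EchoSchedule(TE12)


@pytest.fixture(scope="session")
def schedule9() -> EchoSchedule:
    return EchoSchedule(TE9)


def band_region(label=1, decay_kind="mono", params=None, coeff=0.0, **ranges) -> RegionSpec:
    """A box region; with no ranges it covers the whole grid."""
    if params is None:
        params = MonoParams(100.0, 10.0, 0.0)
    return RegionSpec(
        label=label,
        geometry="band",
        geometry_params=ranges,
        decay_kind=decay_kind,
        iso_params=params,
        anisotropy_rate_coeff=coeff,
    )


def uniform_phantom(
    shape=(10, 10, 1),
    params=None,
    decay_kind="mono",
    noise_model="gaussian",
    snr=35.0,
    seed=0,
    angle=54.7356103172,
    coeff=0.0,
) -> PhantomSpec:
    """A phantom whose single region fills the whole grid."""
    return PhantomSpec(
        grid_shape=shape,
        voxel_size_mm=(0.25, 0.25, 0.4),
        regions=(band_region(1, decay_kind, params, coeff),),
        fiber_angle_deg=angle,
        noise_model=noise_model,
        snr_first_echo=snr,
        seed=seed,
    )


def zonal_phantom(noise_model="none", snr=35.0, seed=0, shape=(16, 16, 2)) -> PhantomSpec:
    """Triangle body + rim layer + tendon-like band + a well-separated bi zone."""
    regions = (
        RegionSpec(
            label=1,
            geometry="triangle_bulk",
            geometry_params={"vertices_mm": [(0.4, 0.4), (3.6, 0.4), (2.0, 3.6)]},
            decay_kind="mono",
            iso_params=MonoParams(80.0, 15.0, 0.0),
        ),
        RegionSpec(
            label=2,
            geometry="rim_layer",
            geometry_params={"vertices_mm": [(0.4, 0.4), (3.6, 0.4), (2.0, 3.6)]},
            decay_kind="mono",
            iso_params=MonoParams(90.0, 11.7, 0.0),
        ),
        RegionSpec(
            label=3,
            geometry="band",
            geometry_params={"x_mm": (0.5, 1.5), "y_mm": (0.0, 0.4)},
            decay_kind="bi",
            iso_params=BiParams(60.0, 40.0, 1.5, 15.0, 0.0),
        ),
    )
    return PhantomSpec(
        grid_shape=shape,
        voxel_size_mm=(0.25, 0.25, 0.4),
        regions=regions,
        fiber_angle_deg=54.7356103172,
        noise_model=noise_model,
        snr_first_echo=snr,
        seed=seed,
    )


@pytest.fixture(scope="session")
def mono_truth_ftest_sim(schedule12):
    """Large mono-truth simulation shared by the type-I checks.

    5000 independent voxels with S = 100 exp(-TE/10 ms), Gaussian noise at
    first-echo SNR 35, both models fitted, nested F-test p-values collected.
    """
    te = schedule12.array
    clean = 100.0 * np.exp(-te / 10.0)
    noise_sd = clean[0] / 35.0
    rng = np.random.default_rng(20260930)
    n_vox = 5000
    p_values = np.full(n_vox, np.nan)
    converged = np.zeros(n_vox, dtype=bool)
    for i in range(n_vox):
        y = clean + rng.normal(0.0, noise_sd, te.size)
        m = fit_mono(y, schedule12)
        b = fit_bi(y, schedule12, mono=m)
        converged[i] = m.converged and b.converged
        if converged[i]:
            p_values[i] = f_test(m.sse, b.sse, te.size)[1]
    return {"p_values": p_values, "converged": converged, "noise_sd": noise_sd}
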