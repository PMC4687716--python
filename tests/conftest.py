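import numpy as np
import pytest

from hydikit.gradients import DWIDataset
from hydikit.phantom import (
    AcquisitionSpec,
    CompartmentSpec,
    PhantomSpec,
    build_phantom,
    compartment_signal,
    make_gradient_scheme,
)
from hydikit.qbi import SphereGrid

SMALL_ACQ = AcquisitionSpec(grid_shape=(12, 12, 6))


@pytest.fixture(scope="session")
def sphere():
    return SphereGrid.icosphere(3)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small noiseless phantom: exact forward model, all regions present."""
    spec = PhantomSpec(acquisition=SMALL_ACQ, nominal_snr=None, seed=0)
    return build_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Small phantom at the study's nominal shell-1 SNR of 40."""
    spec = PhantomSpec(acquisition=SMALL_ACQ, nominal_snr=40.0, seed=0)
    return build_phantom(spec)


def single_tensor_dataset(
    eigenvalues=(1.7e-3, 3.0e-4, 3.0e-4),
    axis=(1.0, 0.0, 0.0),
    shell_bvalues=(3000.0,),
    n_dirs=60,
    s0=1000.0,
    grid=(2, 2, 1),
    seed=0,
):
    """Tiny one-compartment dataset with a known tensor in every voxel."""
    acq = AcquisitionSpec(
        shell_bvalues=shell_bvalues, directions_per_shell=n_dirs, n_b0=1,
        grid_shape=grid,
    )
    gtab = make_gradient_scheme(acq, seed=seed)
    comp = CompartmentSpec.from_axis(eigenvalues, axis, 1.0)
    sig = compartment_signal(gtab, [comp], s0)
    signal = np.broadcast_to(sig, (*grid, len(gtab))).copy()
    dataset = DWIDataset(signal, np.eye(4), gtab)
    return dataset, comp
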