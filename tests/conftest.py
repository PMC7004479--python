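import warnings

import numpy as np
import pytest

import venomdecomplex as vd


@pytest.fixture(scope="session")
def reference():
    """Packaged D. siamensis (Thailand/Indonesia) comparison fixture."""
    return vd.load_reference_proteomes()


@pytest.fixture(scope="session")
def thai_truth():
    return vd.make_truth(11, preset="thai-like")


@pytest.fixture(scope="session")
def thai_experiment(thai_truth):
    chrom, bounds = vd.simulate_chromatogram(thai_truth)
    sim = vd.simulate_psms(thai_truth)
    return thai_truth, chrom, bounds, sim


@pytest.fixture()
def gaussian_trace():
    """Two unit-height Gaussians with a 3:1 area ratio on a dense grid."""
    t = np.arange(0.0, 100.0, 0.1)
    y = 3.0 / (2 * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - 30) / 2) ** 2)
    y += 1.0 / (2 * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - 70) / 2) ** 2)
    return vd.Chromatogram(t, y)


def run_end_to_end(truth):
    """Simulate one experiment and run the full analysis chain on it."""
    chrom, bounds = vd.simulate_chromatogram(truth)
    sim = vd.simulate_psms(truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return vd.analyze_experiment(
            chrom, bounds, sim.records, truth.family_map(),
            unidentified=truth.unidentified_fractions, venom_id=truth.venom_id,
        )
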