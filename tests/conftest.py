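import numpy as np
import pytest

import poolfreq as pf
from poolfreq.calibration import CalibrationData
from poolfreq.simulate import SignalModel, make_world


@pytest.fixture(scope="session")
def zero_noise_pipeline():
    """A noise-free world run end to end through the two-step estimator.

    Panel maf fixed at 0.5 so every reference cluster is well populated;
    the calibration fit uses the polymorphic pool cells, which lie exactly
    on the generating curve.
    """
    model = SignalModel(noise_sd=0.0, mean_jitter_sd=0.0)
    world = make_world(n_snps=300, n_lines=100, n_pops=4, model=model,
                       seed=7, maf_distribution=lambda r, n: np.full(n, 0.5))
    stats = pf.compute_cluster_stats(world.panel_fir, world.panel_calls)
    kept = pf.filter_snps([pf.weighted_deviation(cs) for cs in stats], 30.0)
    data = CalibrationData(world.pool_fir.values, world.pool_expected,
                           world.pool_samples)
    fit = pf.fit_logistic(*data.pairs(None, world.pool_samples,
                                      polymorphic_only=True))
    fm = pf.estimate_frequencies(world.fir_bulks, stats, fit, kept)
    return world, stats, kept, fit, fm


@pytest.fixture(scope="session")
def noisy_pipeline():
    """A realistic noisy world (well-separated clusters, wd mostly > 50)."""
    model = SignalModel(sd_aa=0.015, sd_bb=0.015)
    world = make_world(n_snps=1500, n_lines=100, n_pops=4, model=model,
                       seed=11, n_replicated_pops=2)
    stats = pf.compute_cluster_stats(world.panel_fir, world.panel_calls)
    kept = pf.filter_snps([pf.weighted_deviation(cs) for cs in stats], 50.0)
    configs = {s: list(world.pool_classes.loc[s])
               for s in world.pool_classes.index if s in kept}
    selected = pf.select_calibration_snps(configs, n_per_class=80, seed=1)
    data = CalibrationData(world.pool_fir.values.loc[selected],
                           world.pool_expected.loc[selected],
                           world.pool_samples)
    fit = pf.fit_logistic(*data.pairs())
    fm = pf.estimate_frequencies(world.fir_bulks, stats, fit, kept)
    return world, stats, kept, fit, fm, data
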