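import pytest
from hypothesis import HealthCheck, settings

from peakstate import classify as pc
from peakstate import expression as pe
from peakstate import peaks as pp
from peakstate import targets as pt
from peakstate.synthetic import SimConfig, simulate_study

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def zero_noise_study():
    """A complete simulated study with no measurement noise."""
    return simulate_study(SimConfig(seed=11, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_study():
    """A study at the default noise settings (effect 2.0, sd 0.25)."""
    return simulate_study(SimConfig(seed=12))


def run_pipeline(study):
    """Run DE, peak calling, assignment and classification on a study."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        probes = pe.de_table(study.expression)
    genes = pe.reconcile_genes(probes)
    peak_sets = {
        cond: pp.call_peaks(study.reads[cond], study.reads["input"], study.chrom_sizes)
        for cond in ("ab", "scrib_ab")
    }
    flags = pt.assign_targets(peak_sets, study.genes, chrom_lengths=study.chrom_sizes)
    flags = pc.filter_to_array_universe(flags, study.expression["gene_id"])
    classes = pc.classify_genes(genes, flags)
    return {
        "probes": probes,
        "genes": genes,
        "peaks": peak_sets,
        "flags": flags,
        "classes": classes,
    }


@pytest.fixture(scope="session")
def zero_noise_pipeline(zero_noise_study):
    return run_pipeline(zero_noise_study)
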