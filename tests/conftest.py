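import pytest
from hypothesis import settings

import cardiosig as cs

settings.register_profile("suite", max_examples=50, deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort (800 genes, 14/10/10 samples) for fast unit tests."""
    config = cs.SimConfig(n_dcm=14, n_icm=10, n_nf=10, n_genes=800, seed=7)
    matrix, samples, truth = cs.generate_cohort(config)
    return config, matrix, samples, truth


@pytest.fixture(scope="session")
def default_run():
    """Full study-sized run (5000 genes, 37/13/14) through the adjusted pipeline."""
    config = cs.SimConfig(seed=11)
    matrix, samples, truth = cs.generate_cohort(config)
    logm = cs.log_transform(matrix)
    adjusted = cs.adjust_expression(logm, samples)
    comparisons = [("DCM", "NF"), ("ICM", "NF"), ("ICM", "DCM")]
    results = {c: cs.call_degs(adjusted.rpkm, samples, c) for c in comparisons}
    raw_results = {c: cs.call_degs(matrix, samples, c) for c in comparisons[:2]}
    signatures = cs.partition_signatures(
        results[("DCM", "NF")], results[("ICM", "NF")], results[("ICM", "DCM")]
    )
    return {
        "config": config,
        "matrix": matrix,
        "samples": samples,
        "truth": truth,
        "adjusted": adjusted,
        "results": results,
        "raw_results": raw_results,
        "signatures": signatures,
    }
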