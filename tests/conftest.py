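import pytest

from chargeseq import run_pipeline, sheet_from_design, simulate_fastq
from chargeseq.presets import benchmark_design, benchmark_reference


@pytest.fixture(scope="session")
def toy_ref():
    """20-entry toy reference: 10 anticodon groups x 2 genes, 72-78 nt bodies."""
    return benchmark_reference(seed=0)


@pytest.fixture(scope="session")
def clean_sim(toy_ref):
    """Error-free simulated library, 2000 pairs/sample."""
    design = benchmark_design(seed=3, n_reads=2000)
    design.error_rate = 0.0
    r1, r2, truth = simulate_fastq(design, toy_ref)
    return design, r1, r2, truth


@pytest.fixture(scope="session")
def clean_run(toy_ref, clean_sim):
    design, r1, r2, truth = clean_sim
    sheet = sheet_from_design(design)
    result = run_pipeline(toy_ref, sheet, zip(r1, r2))
    return sheet, result, truth


@pytest.fixture(scope="session")
def noisy_run(toy_ref):
    """Simulated library at the benchmark error rate (0.002), 2000 pairs/sample."""
    design = benchmark_design(seed=4, n_reads=2000)
    r1, r2, truth = simulate_fastq(design, toy_ref)
    sheet = sheet_from_design(design)
    result = run_pipeline(toy_ref, sheet, zip(r1, r2))
    return design, sheet, result, truth
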