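import pytest

from circlact import detect, synth


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared across the suite."""
    return synth.generate_study(synth.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def anchor_index(study):
    return detect.build_anchor_index(study.genome, detect.DetectorConfig().anchor_length)


@pytest.fixture(scope="session")
def detected(study, anchor_index):
    """Calls + report of the default detector on the study's reads."""
    calls, report = detect.call_circrnas(
        study.reads, anchor_index, study.genome, detect.DetectorConfig()
    )
    return calls, report


def truth_coords(study):
    return {
        (c.interval.chrom, c.interval.start, c.interval.end, c.interval.strand): c
        for c in study.truth.circles
    }
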