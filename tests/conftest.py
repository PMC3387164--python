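import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def descriptor_table():
    from allerscreen.pd_metric import load_descriptor_table

    return load_descriptor_table()


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(text, name="seqs.fasta"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
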