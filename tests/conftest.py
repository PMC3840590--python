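import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def ranked_file(tmp_path):
    """A small ranked results file with header, dupes and missing symbols."""
    path = tmp_path / "ranked.tsv"
    path.write_text(
        "probe_id\tgene_symbol\n"
        "p1\tFoxp2\n"
        "p2\t\n"
        "p3\tNpy\n"
        "p4\tfoxp2\n"
        "p5\tDrd2\n"
        "p6\t---\n"
        "p7\tTac1\n",
        encoding="utf-8",
    )
    return path


@pytest.fixture
def genelist_file(tmp_path):
    path = tmp_path / "autism.txt"
    path.write_text("# comment\nFoxp2\nFOXP2\nNpy\nScn1a\n\n", encoding="utf-8")
    return path
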