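import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "adjnet",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("adjnet")

#: The worked pipe-delimited sample: comments, a corner cell, and a shared
#: "distance." column-name prefix.
LISTING_CONTENT = (
    "# With row and column names, the cell at (0, 0) is ignored\n"
    '# PIPE delimited adjacency matrix, with column name prefix "distance."\n'
    "Rows|distance.nodeA|distance.nodeB|distance.nodeC\n"
    "nodeA|0|2.0|1.45\n"
)


@pytest.fixture
def listing_path(tmp_path):
    path = tmp_path / "listing1.adj"
    path.write_text(LISTING_CONTENT)
    return str(path)


@pytest.fixture
def write_file(tmp_path):
    def _write(name, content):
        path = tmp_path / name
        path.write_text(content)
        return str(path)

    return _write
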