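import pytest

from patentscape.preprocess import CleanConfig


@pytest.fixture(scope="session")
def clean_cfg() -> CleanConfig:
    """Default cleaning config, loaded once per session."""
    return CleanConfig()


@pytest.fixture
def toy_corpus_file(tmp_path):
    """Write a small patent table and return its path."""

    def _write(rows, header="patent_id,year,novelty,use", sep=","):
        path = tmp_path / "corpus.csv"
        lines = [header] + [sep.join(str(x) for x in row) for row in rows]
        path.write_text("\n".join(lines) + "\n", "utf-8")
        return path

    return _write
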