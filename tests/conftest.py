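import pytest

from pvsignal.cohort import DrugQuery
from pvsignal.dedup import build_analysis_set
from pvsignal.pipeline import load_quarters
from pvsignal.synthetic import default_config, generate

TKI_QUERIES = {
    "Tucatinib": DrugQuery("Tucatinib", ("TUCATINIB", "TUKYSA")),
    "Lapatinib": DrugQuery("Lapatinib", ("LAPATINIB", "TYKERB")),
    "Neratinib": DrugQuery("Neratinib", ("NERATINIB", "NERLYNX")),
}


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A 10k-report synthetic extract shared across the suite."""
    cfg = default_config(101, n_quarters=4, n_reports_per_quarter=2500)
    out = tmp_path_factory.mktemp("sim_small")
    manifest = generate(cfg, out)
    return cfg, out, manifest


@pytest.fixture(scope="session")
def small_aset(small_sim):
    _, out, _ = small_sim
    return build_analysis_set(load_quarters(out))


@pytest.fixture
def quarter_writer(tmp_path):
    """Factory writing hand-crafted '$'-delimited table files."""

    def _write(name, header, rows):
        path = tmp_path / name
        lines = [header] + list(rows)
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    _write.dir = tmp_path
    return _write
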